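"""JSON REST interface over a catalog and query engine.

Endpoints
---------
``GET /measurements``
    Every registered measurement: id, name, type (file / computed /
    genome), format, annotations (plus source ids for computed ones).
``GET /data?measurement=ID&chr=C&start=S&end=E[&bins=B][&requestId=N]``
    Columnar payload of a range query::

        {"requestId": N, "error": null,
         "data": {"rows": {"chrom": ..., "start": [...], "end": [...]},
                  "values": {"<column>": [...]}}}

    Numbers are serialized at full precision; the missing marker becomes
    JSON ``null``. Malformed parameters give 400, unknown measurement or
    chromosome 404, parser/compute failures 500 with the message in
    ``error``.

The server is a threaded stdlib HTTP server: overlapping requests are
accepted and, because query results never depend on completion order,
any interleaving returns the same per-request payloads as serial
execution.
"""
from __future__ import annotations

import json
import logging
import math
import threading
import time
import urllib.parse
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from typing import Optional

import numpy as np
import pandas as pd

from .core import GenomicRange
from .errors import TrackQueryError, UnknownChromosome, UnknownMeasurement
from .measurements import Catalog, FileMeasurement, GenomeAnnotation
from .query_engine import QueryEngine
from .transform import ComputeSpec

logger = logging.getLogger(__name__)


def _jsonable(value):
    if value is None:
        return None
    if isinstance(value, (np.floating, float)):
        f = float(value)
        return None if math.isnan(f) or math.isinf(f) else f
    if isinstance(value, (np.integer, int)):
        return int(value)
    if isinstance(value, (np.bool_, bool)):
        return bool(value)
    if pd.isna(value):
        return None
    return value


def frame_payload(frame: pd.DataFrame) -> dict:
    """Columnar JSON payload for an interval frame."""
    rows = {
        "chrom": [str(c) for c in frame["chrom"]],
        "start": [int(s) for s in frame["start"]],
        "end": [int(e) for e in frame["end"]],
    }
    values = {}
    for col in frame.columns:
        if col in ("chrom", "start", "end"):
            continue
        values[col] = [_jsonable(v) for v in frame[col]]
    return {"rows": rows, "values": values}


def measurement_listing(catalog: Catalog) -> list[dict]:
    out = []
    for entry in catalog:
        if isinstance(entry, ComputeSpec):
            out.append({
                "id": entry.id, "name": entry.name, "type": "computed",
                "format": "computed",
                "source_ids": list(entry.source_ids),
                "annotations": dict(entry.annotations),
            })
        elif isinstance(entry, GenomeAnnotation):
            out.append({
                "id": entry.id, "name": entry.id, "type": "genome",
                "format": entry.format,
                "annotations": dict(entry.annotations),
            })
        elif isinstance(entry, FileMeasurement):
            out.append({
                "id": entry.id, "name": entry.name, "type": "file",
                "format": entry.format,
                "annotations": dict(entry.annotations),
            })
    return out


def handle_data_params(params: dict) -> tuple[str, GenomicRange,
                                              Optional[int], int]:
    """Validate /data query parameters; ValueError means HTTP 400."""
    try:
        measurement = params["measurement"]
        chrom = params["chr"]
        start = int(params["start"])
        end = int(params["end"])
    except (KeyError, ValueError, TypeError) as exc:
        raise ValueError(f"malformed parameters: {exc}") from exc
    bins = None
    if params.get("bins") is not None:
        try:
            bins = int(params["bins"])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed bins: {exc}") from exc
        if bins < 1:
            raise ValueError("bins must be >= 1")
    if start < 0 or start >= end:
        raise ValueError(f"bad range [{start}, {end})")
    request_id = 0
    if params.get("requestId") is not None:
        try:
            request_id = int(params["requestId"])
        except (ValueError, TypeError):
            request_id = 0
    return measurement, GenomicRange(chrom, start, end), bins, request_id


def _make_handler(engine: QueryEngine):
    class Handler(BaseHTTPRequestHandler):
        protocol_version = "HTTP/1.1"

        def log_message(self, fmt, *args):
            logger.info("%s " + fmt, self.address_string(), *args)

        def _send(self, status: int, payload: dict) -> None:
            body = json.dumps(payload).encode("utf-8")
            self.send_response(status)
            self.send_header("Content-Type", "application/json")
            self.send_header("Content-Length", str(len(body)))
            self.send_header("Access-Control-Allow-Origin", "*")
            self.end_headers()
            self.wfile.write(body)

        def do_GET(self):
            t0 = time.perf_counter()
            parsed = urllib.parse.urlparse(self.path)
            params = {k: v[0] for k, v in
                      urllib.parse.parse_qs(parsed.query).items()}
            request_id = 0
            try:
                request_id = int(params.get("requestId", 0))
            except ValueError:
                pass
            try:
                if parsed.path == "/measurements":
                    self._send(200, {
                        "requestId": request_id, "error": None,
                        "data": measurement_listing(engine.catalog)})
                elif parsed.path == "/data":
                    mid, rng, bins, request_id = handle_data_params(
                        params)
                    result = engine.get_data(mid, rng, bins)
                    hits = (engine.cache.hits
                            if engine.cache is not None else 0)
                    logger.info(
                        "data measurement=%s range=%s bins=%s %.1fms "
                        "cache_hits=%d", mid, rng, bins,
                        (time.perf_counter() - t0) * 1e3, hits)
                    self._send(200, {
                        "requestId": request_id, "error": None,
                        "data": frame_payload(result.frame)})
                else:
                    self._send(404, {"requestId": request_id,
                                     "error": f"no route {parsed.path}",
                                     "data": None})
            except ValueError as exc:
                self._send(400, {"requestId": request_id,
                                 "error": str(exc), "data": None})
            except (UnknownMeasurement, UnknownChromosome) as exc:
                self._send(404, {"requestId": request_id,
                                 "error": str(exc), "data": None})
            except TrackQueryError as exc:
                self._send(500, {"requestId": request_id,
                                 "error": str(exc), "data": None})
            except Exception as exc:  # pragma: no cover - last resort
                logger.exception("unhandled error")
                self._send(500, {"requestId": request_id,
                                 "error": f"internal error: {exc}",
                                 "data": None})

    return Handler


class ApiServer:
    """Threaded REST server over a query engine."""

    def __init__(self, engine: QueryEngine, host: str = "127.0.0.1",
                 port: int = 0) -> None:
        self.engine = engine
        self._httpd = ThreadingHTTPServer((host, port),
                                          _make_handler(engine))
        self.host = host
        self.port = self._httpd.server_address[1]
        self._thread: Optional[threading.Thread] = None

    def url(self, path: str = "") -> str:
        return f"http://{self.host}:{self.port}{path}"

    def start(self) -> "ApiServer":
        self._thread = threading.Thread(target=self._httpd.serve_forever,
                                        daemon=True)
        self._thread.start()
        return self

    def serve_forever(self) -> None:
        self._httpd.serve_forever()

    def stop(self) -> None:
        self._httpd.shutdown()
        self._httpd.server_close()
        if self._thread is not None:
            self._thread.join(timeout=5)

    def __enter__(self) -> "ApiServer":
        return self.start()

    def __exit__(self, *exc) -> None:
        self.stop()
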