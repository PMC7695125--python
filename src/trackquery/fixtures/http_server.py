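"""Local HTTP server honoring (or deliberately ignoring) Range headers.

Lets every remote-access code path be tested hermetically: the same
fixture file is queried through ``http://127.0.0.1:<port>/...`` and
compared with the local answer, and a server configured with
``ignore_ranges=True`` exercises the refusal path for hosts that stream
whole files instead of honoring RFC 7233.
"""
from __future__ import annotations

import os
import threading
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer


def _make_handler(directory: str, ignore_ranges: bool):
    class Handler(BaseHTTPRequestHandler):
        protocol_version = "HTTP/1.1"

        def log_message(self, *args):  # silence test output
            pass

        def do_GET(self):
            rel = self.path.lstrip("/")
            path = os.path.normpath(os.path.join(directory, rel))
            if not path.startswith(os.path.abspath(directory)) or \
                    not os.path.isfile(path):
                self.send_error(404)
                return
            size = os.path.getsize(path)
            range_header = self.headers.get("Range")
            if range_header and not ignore_ranges:
                spec = range_header.split("=", 1)[1].split(",")[0]
                lo_s, hi_s = spec.split("-", 1)
                lo = int(lo_s) if lo_s else 0
                hi = int(hi_s) if hi_s else size - 1
                if lo >= size:
                    self.send_response(416)
                    self.send_header("Content-Range", f"bytes */{size}")
                    self.send_header("Content-Length", "0")
                    self.end_headers()
                    return
                hi = min(hi, size - 1)
                length = hi - lo + 1
                with open(path, "rb") as fh:
                    fh.seek(lo)
                    body = fh.read(length)
                self.send_response(206)
                self.send_header("Content-Range",
                                 f"bytes {lo}-{hi}/{size}")
                self.send_header("Content-Length", str(len(body)))
                self.end_headers()
                self.wfile.write(body)
            else:
                with open(path, "rb") as fh:
                    body = fh.read()
                self.send_response(200)
                self.send_header("Content-Length", str(len(body)))
                self.end_headers()
                self.wfile.write(body)

    return Handler


class FixtureServer:
    """Serve a directory over HTTP with range support; context manager."""

    def __init__(self, directory: str, port: int = 0,
                 ignore_ranges: bool = False) -> None:
        self.directory = os.path.abspath(directory)
        self._httpd = ThreadingHTTPServer(
            ("127.0.0.1", port),
            _make_handler(self.directory, ignore_ranges))
        self.port = self._httpd.server_address[1]
        self._thread: threading.Thread | None = None

    def url(self, name: str) -> str:
        return f"http://127.0.0.1:{self.port}/{name}"

    def start(self) -> "FixtureServer":
        self._thread = threading.Thread(
            target=self._httpd.serve_forever, daemon=True)
        self._thread.start()
        return self

    def stop(self) -> None:
        self._httpd.shutdown()
        self._httpd.server_close()
        if self._thread is not None:
            self._thread.join(timeout=5)

    def __enter__(self) -> "FixtureServer":
        return self.start()

    def __exit__(self, *exc) -> None:
        self.stop()


def serve_fixtures(directory: str, port: int = 0,
                   ignore_ranges: bool = False) -> FixtureServer:
    """Start (and return) a running fixture server."""
    return FixtureServer(directory, port, ignore_ranges).start()
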