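"""Catalog of queryable measurements.

A *measurement* is anything with an id that can answer a genomic-range
query: a file-backed track (BigWig, BigBed, Tabix table), a genome
annotation (Tabix-indexed gene table with name lookup), or a computed
measurement (:class:`~trackquery.transform.ComputeSpec`). Catalogs load
from a JSON configuration or a tab-delimited manifest; files are never
opened or probed at load time — the first query opens them.

Config dialect: a JSON list of objects ``{id, name, url, file_type:
"bigwig"|"bigbed"|"tabix", annotation: {...}, columns: [...], genome:
str}``; unknown keys are ignored with a warning.
"""
from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .core import GenomicRange
from .errors import ConfigError, DuplicateId, UnknownGene, UnknownMeasurement
from .transform import ComputeSpec

logger = logging.getLogger(__name__)

VALID_FORMATS = ("bigwig", "bigbed", "tabix")

_KNOWN_KEYS = {"id", "name", "url", "uri", "file_type", "format",
               "annotation", "annotations", "columns", "genome"}


@dataclass
class FileMeasurement:
    id: str
    name: str
    uri: str
    format: str
    annotations: dict = field(default_factory=dict)
    column_schema: Optional[Sequence[str]] = None
    genome_tag: str = ""

    def __post_init__(self) -> None:
        if self.format not in VALID_FORMATS:
            raise ConfigError(
                f"measurement {self.id!r}: unknown format "
                f"{self.format!r} (expected one of {VALID_FORMATS})")


@dataclass
class GenomeAnnotation:
    """A Tabix-indexed gene table supporting gene-name -> range lookup."""

    id: str
    uri: str
    column_schema: Sequence[str] = ("gene",)
    gene_column: str = "gene"
    annotations: dict = field(default_factory=dict)
    format: str = "tabix"


class Catalog:
    """Ordered, unique-id registry of measurements."""

    def __init__(self) -> None:
        self._entries: dict[str, Union[FileMeasurement, ComputeSpec,
                                       GenomeAnnotation]] = {}

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, mid: str) -> bool:
        return mid in self._entries

    def __getitem__(self, mid: str):
        try:
            return self._entries[mid]
        except KeyError:
            raise UnknownMeasurement(
                f"measurement {mid!r} not registered "
                f"(catalog has {list(self._entries)})") from None

    def __iter__(self):
        return iter(self._entries.values())

    def ids(self) -> list[str]:
        return list(self._entries)

    def add(self, entry) -> "Catalog":
        if entry.id in self._entries:
            raise DuplicateId(f"measurement id {entry.id!r} already "
                              "registered")
        self._entries[entry.id] = entry
        return self


def _parse_entry(obj: dict, position: int) -> FileMeasurement:
    if not isinstance(obj, dict):
        raise ConfigError(f"entry {position}: expected an object, got "
                          f"{type(obj).__name__}")
    unknown = set(obj) - _KNOWN_KEYS
    if unknown:
        logger.warning("config entry %s: ignoring unknown keys %s",
                       obj.get("id", position), sorted(unknown))
    mid = obj.get("id")
    uri = obj.get("url", obj.get("uri"))
    fmt = obj.get("file_type", obj.get("format"))
    if not mid:
        raise ConfigError(f"entry {position}: missing 'id'")
    if not uri:
        raise ConfigError(f"entry {mid!r}: missing 'url'")
    if not fmt:
        raise ConfigError(f"entry {mid!r}: missing 'file_type'")
    return FileMeasurement(
        id=str(mid),
        name=str(obj.get("name", mid)),
        uri=str(uri),
        format=str(fmt).lower(),
        annotations=dict(obj.get("annotation",
                                 obj.get("annotations", {})) or {}),
        column_schema=obj.get("columns"),
        genome_tag=str(obj.get("genome", "")),
    )


def load_config(source: Union[str, list]) -> Catalog:
    """Build a catalog from a JSON config (path, text, or parsed list).

    No file is opened here; laziness means a config of N entries costs
    zero backend reads until the first query.
    """
    if isinstance(source, list):
        entries = source
    else:
        text = source
        if not source.lstrip().startswith(("[", "{")) and \
                os.path.exists(source):
            with open(source, "r", encoding="utf-8") as fh:
                text = fh.read()
        try:
            entries = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"config is not valid JSON: {exc}") from exc
        if isinstance(entries, dict):
            entries = entries.get("measurements", [entries])
    if not isinstance(entries, list):
        raise ConfigError("config must be a JSON list of measurement "
                          "entries")
    catalog = Catalog()
    for i, obj in enumerate(entries):
        meas = _parse_entry(obj, i)
        if meas.id in catalog:
            raise ConfigError(f"duplicate measurement id {meas.id!r}")
        catalog.add(meas)
    return catalog


def serialize_config(catalog: Catalog) -> str:
    """JSON text reloadable by :func:`load_config` (file entries only)."""
    entries = []
    for entry in catalog:
        if isinstance(entry, FileMeasurement):
            entries.append({
                "id": entry.id, "name": entry.name, "url": entry.uri,
                "file_type": entry.format,
                "annotation": entry.annotations,
                "columns": (list(entry.column_schema)
                            if entry.column_schema else None),
                "genome": entry.genome_tag,
            })
    return json.dumps(entries, indent=2)


def import_manifest(source: str) -> list[FileMeasurement]:
    """Batch-load measurements from a tab-delimited manifest.

    Columns ``id``, ``url`` and ``file_type`` are required (header row
    names them); every other column is folded into the annotations map.
    """
    text = source
    if "\t" not in source and "\n" not in source and os.path.exists(source):
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ConfigError("manifest is empty (no header row)")
    header = lines[0].rstrip("\n").split("\t")
    required = {"id", "url", "file_type"}
    missing = required - set(header)
    if missing:
        raise ConfigError(f"manifest header missing columns "
                          f"{sorted(missing)}")
    out = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.rstrip("\n").split("\t")
        if len(fields) != len(header):
            raise ConfigError(
                f"manifest line {lineno}: {len(fields)} fields for "
                f"{len(header)} columns")
        row = dict(zip(header, fields))
        annotations = {k: v for k, v in row.items()
                       if k not in required and k != "name"}
        out.append(FileMeasurement(
            id=row["id"], name=row.get("name", row["id"]),
            uri=row["url"], format=row["file_type"].lower(),
            annotations=annotations))
    return out


def add_computed_measurement(catalog: Catalog,
                             spec: ComputeSpec) -> Catalog:
    """Register a computed measurement; sources must already exist.

    Sources may themselves be computed (evaluation recurses).
    """
    for sid in spec.source_ids:
        if sid not in catalog:
            raise UnknownMeasurement(
                f"computed measurement {spec.id!r}: source {sid!r} not "
                "in catalog")
    return catalog.add(spec)


def add_genome(catalog: Catalog, genome_id: str, uri: str,
               column_schema: Sequence[str] = ("gene",),
               gene_column: str = "gene") -> Catalog:
    """Register a Tabix-indexed genome annotation for navigational
    queries (range -> genes, gene name -> range)."""
    if gene_column not in column_schema:
        raise ConfigError(
            f"genome {genome_id!r}: gene column {gene_column!r} absent "
            f"from schema {list(column_schema)}")
    return catalog.add(GenomeAnnotation(
        id=genome_id, uri=uri, column_schema=tuple(column_schema),
        gene_column=gene_column))


class GeneIndex:
    """Name -> range map over a genome annotation, built lazily.

    Tabix indexes position, not names, so the first lookup scans the
    whole table once and caches the map.
    """

    def __init__(self, genome: GenomeAnnotation, tabix_file) -> None:
        self._genome = genome
        self._tabix = tabix_file
        self._map: Optional[dict[str, GenomicRange]] = None

    def _build(self) -> dict[str, GenomicRange]:
        text = self._tabix.read_all_text()
        index = self._tabix.index
        gene_pos = list(self._genome.column_schema).index(
            self._genome.gene_column)
        mapping: dict[str, GenomicRange] = {}
        for lineno, line in enumerate(text.split("\n")):
            if not line or line.startswith(index.meta_char):
                continue
            if lineno < index.skip_lines:
                continue
            fields = line.split("\t")
            chrom = fields[index.col_seq - 1]
            beg = int(fields[index.col_beg - 1])
            stop = int(fields[index.col_end - 1]) if index.col_end else \
                beg + 1
            if not index.zero_based:
                beg -= 1
            skip_cols = {index.col_seq - 1, index.col_beg - 1}
            if index.col_end > 0:
                skip_cols.add(index.col_end - 1)
            rest = [f for i, f in enumerate(fields)
                    if i not in skip_cols]
            if gene_pos < len(rest):
                mapping.setdefault(rest[gene_pos],
                                   GenomicRange(chrom, beg, stop))
        return mapping

    def lookup(self, gene_name: str) -> GenomicRange:
        if self._map is None:
            self._map = self._build()
        try:
            return self._map[gene_name]
        except KeyError:
            raise UnknownGene(
                f"gene {gene_name!r} not in annotation "
                f"{self._genome.id!r}") from None
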