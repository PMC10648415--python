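"""Readers, writers and validated containers for every table the pipeline touches.

All external data enters through this module: differential-expression (DE)
tables per RNA layer, back-splice-junction (BSJ) count matrices with sample
metadata, circRNA->miRNA and miRNA->mRNA prediction tables, GMT gene-set
collections, and qPCR Ct tables.  Every reader validates its input against
the type invariants and raises :class:`FormatError` with a located message
(column name, row number, cell coordinates) on violation.

Conventions
-----------
* TSV, UTF-8, no quoting.  Missing adjusted p-values are written as empty
  fields; readers also accept ``NA``.
* Genomic coordinates are stored 0-based half-open.  The textual form
  ``chrom:start-end:strand`` is interpreted as 1-based inclusive (the form
  used by circBase and genome browsers) and converted on parse.
* miRNA identifiers are normalised to lower case before any join (the
  literature mixes ``let-7``/``miR`` capitalisation); the original spelling
  is preserved for display in ``mirna_label``.
"""
from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "Layer",
    "Confidence",
    "DERecord",
    "DETable",
    "CountMatrix",
    "CircId",
    "CircMirEdge",
    "MirMrnaEdge",
    "GeneSetCollection",
    "CtTable",
    "normalize_mirna_id",
    "parse_circ_id",
    "read_de_table",
    "write_de_table",
    "read_bsj_matrix",
    "write_count_matrix",
    "read_circ_mir_table",
    "write_circ_mir_table",
    "read_mir_mrna_table",
    "write_mir_mrna_table",
    "read_gmt",
    "read_ct_table",
    "write_ct_table",
    "write_network",
    "read_network_edge_tsv",
]


class FormatError(ValueError):
    """A file or record violates the format contract of its table type."""


class Layer(str, enum.Enum):
    """RNA layer of the tripartite network."""

    MRNA = "mRNA"
    MIRNA = "miRNA"
    CIRCRNA = "circRNA"

    @classmethod
    def coerce(cls, value: "Layer | str") -> "Layer":
        if isinstance(value, Layer):
            return value
        for member in cls:
            if member.value.lower() == str(value).lower():
                return member
        raise FormatError(f"unknown RNA layer {value!r}; expected one of "
                          f"{[m.value for m in cls]}")


class Confidence(enum.IntEnum):
    """Ordered prediction-confidence classes (MirDIP-style)."""

    LOW = 0
    MEDIUM = 1
    HIGH = 2
    VERY_HIGH = 3

    @classmethod
    def coerce(cls, value: "Confidence | str | int") -> "Confidence":
        if isinstance(value, Confidence):
            return value
        if isinstance(value, int):
            return cls(value)
        key = str(value).strip().lower().replace(" ", "_").replace("-", "_")
        try:
            return cls[key.upper()]
        except KeyError:
            raise FormatError(
                f"unknown confidence class {value!r}; expected one of "
                f"{[m.name.lower() for m in cls]}") from None


def normalize_mirna_id(mirna_id: str) -> str:
    """Lower-case a miRNA identifier for joining across resources.

    ``hsa-miR-196b-5p`` and ``hsa-mir-196b-5p`` denote the same mature
    miRNA; tables from different databases mix the conventions.
    """
    return mirna_id.strip().lower()


def _check_prob(name: str, value: float, where: str = "") -> None:
    if not (0.0 <= value <= 1.0):
        suffix = f" ({where})" if where else ""
        raise FormatError(f"{name} out of [0,1]: {value!r}{suffix}")


@dataclass(frozen=True)
class DERecord:
    """Differential-expression statistics for one feature of one layer."""

    feature_id: str
    layer: Layer
    log2fc: float
    p: float
    padj: float | None = None
    mean_expr: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.log2fc):
            raise FormatError(f"log2fc not finite for {self.feature_id!r}")
        _check_prob("p", self.p, self.feature_id)
        if self.padj is not None:
            _check_prob("padj", self.padj, self.feature_id)
            if self.padj < self.p - 1e-12:
                raise FormatError(
                    f"padj < p for {self.feature_id!r} "
                    f"({self.padj!r} < {self.p!r})")
        if self.mean_expr is not None and self.mean_expr < 0:
            raise FormatError(f"mean_expr < 0 for {self.feature_id!r}")


@dataclass(frozen=True)
class DETable:
    """Validated per-layer DE table with unique feature ids."""

    layer: Layer
    records: tuple[DERecord, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        dups: list[str] = []
        for rec in self.records:
            if rec.layer is not self.layer:
                raise FormatError(
                    f"record {rec.feature_id!r} has layer {rec.layer.value}, "
                    f"table is {self.layer.value}")
            if rec.feature_id in seen:
                dups.append(rec.feature_id)
            seen.add(rec.feature_id)
        if dups:
            raise FormatError(
                f"duplicated feature_id(s) in {self.layer.value} table: "
                f"{sorted(set(dups))}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[DERecord]:
        return iter(self.records)

    @property
    def feature_ids(self) -> tuple[str, ...]:
        return tuple(r.feature_id for r in self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": [r.feature_id for r in self.records],
                "log2fc": [r.log2fc for r in self.records],
                "p": [r.p for r in self.records],
                "padj": [r.padj for r in self.records],
            }
        )


@dataclass(frozen=True)
class CountMatrix:
    """Integer count matrix (features x samples) with group/batch metadata.

    Holds either a BSJ count matrix (junctions as features) or gene-level
    RNA-seq counts; each sample carries a group label in {case, control}
    and an optional batch label.
    """

    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray
    groups: tuple[str, ...]
    batches: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.feature_ids),
                                                len(self.sample_ids)):
            raise FormatError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise FormatError("counts must be integers")
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            i, j = np.argwhere(counts < 0)[0]
            raise FormatError(
                f"negative count at feature {self.feature_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}")
        object.__setattr__(self, "counts", np.ascontiguousarray(counts))
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise FormatError("duplicate feature ids in count matrix")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids in count matrix")
        if len(self.groups) != len(self.sample_ids):
            raise FormatError("every sample needs a group label")
        bad = sorted(set(self.groups) - {"case", "control"})
        if bad:
            raise FormatError(f"group label(s) outside {{case, control}}: {bad}")
        if self.batches is not None and len(self.batches) != len(self.sample_ids):
            raise FormatError("batch labels do not match samples")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.feature_ids),
                            columns=list(self.sample_ids))

    def meta_frame(self) -> pd.DataFrame:
        meta = pd.DataFrame({"sample_id": list(self.sample_ids),
                             "group": list(self.groups)})
        if self.batches is not None:
            meta["batch"] = list(self.batches)
        return meta


_CIRCBASE_RE = re.compile(r"^hsa_circ_\d{7}$")
_COORD_RE = re.compile(r"^(?P<chrom>[\w.]+):(?P<start>\d+)-(?P<end>\d+):(?P<strand>[+-])$")


@dataclass(frozen=True)
class CircId:
    """A circRNA identity: circBase alias and/or genomic BSJ coordinates.

    Coordinates are 0-based half-open.  Strand is stored verbatim and never
    used for matching -- identifiers match by string throughout the pipeline.
    """

    alias: str | None = None
    host_gene: str | None = None
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.alias is not None and not _CIRCBASE_RE.match(self.alias):
            raise FormatError(
                f"alias {self.alias!r} does not match hsa_circ_<7 digits>")
        has_coords = self.chrom is not None
        if has_coords:
            if self.start is None or self.end is None:
                raise FormatError("coordinates require start and end")
            if not (0 <= self.start < self.end):
                raise FormatError(
                    f"start must be < end (and >= 0); got "
                    f"{self.start}-{self.end}")
        if self.strand is not None and self.strand not in {"+", "-"}:
            raise FormatError(f"strand must be + or -, got {self.strand!r}")
        if self.alias is None and not has_coords:
            raise FormatError("CircId needs an alias or coordinates")


def parse_circ_id(text: str) -> CircId:
    """Parse a circBase alias or a ``chrom:start-end:strand`` locus string.

    The textual coordinate form is 1-based inclusive and is converted to the
    internal 0-based half-open convention.
    """
    text = text.strip()
    if _CIRCBASE_RE.match(text):
        return CircId(alias=text)
    m = _COORD_RE.match(text)
    if m:
        start1, end1 = int(m["start"]), int(m["end"])
        if start1 > end1:
            raise FormatError(f"start must be < end in {text!r}")
        if start1 < 1:
            raise FormatError(f"1-based coordinate must be >= 1 in {text!r}")
        return CircId(chrom=m["chrom"], start=start1 - 1, end=end1,
                      strand=m["strand"])
    raise FormatError(
        f"unrecognized circRNA identifier {text!r}; expected circBase alias "
        "hsa_circ_<7 digits> or chrom:start-end:strand")


@dataclass(frozen=True)
class CircMirEdge:
    """A predicted circRNA->miRNA interaction with source provenance."""

    circ_id: str
    mirna_id: str
    sources: frozenset[str]
    site_count: int | None = None
    mirna_label: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sources", frozenset(self.sources))
        if not self.sources:
            raise FormatError(
                f"edge {self.circ_id}->{self.mirna_id} has no source label")
        if self.site_count is not None and self.site_count < 1:
            raise FormatError("site_count must be >= 1 when present")
        object.__setattr__(self, "mirna_label",
                           self.mirna_label or self.mirna_id)
        object.__setattr__(self, "mirna_id", normalize_mirna_id(self.mirna_id))

    @property
    def key(self) -> tuple[str, str]:
        return (self.circ_id, self.mirna_id)


@dataclass(frozen=True)
class MirMrnaEdge:
    """A predicted miRNA->mRNA interaction with resource count and confidence."""

    mirna_id: str
    gene_id: str
    resource_count: int
    confidence_class: Confidence
    mirna_label: str | None = None

    def __post_init__(self) -> None:
        if self.resource_count < 1:
            raise FormatError(
                f"resource_count must be >= 1 for "
                f"{self.mirna_id}->{self.gene_id}")
        object.__setattr__(self, "confidence_class",
                           Confidence.coerce(self.confidence_class))
        object.__setattr__(self, "mirna_label",
                           self.mirna_label or self.mirna_id)
        object.__setattr__(self, "mirna_id", normalize_mirna_id(self.mirna_id))

    @property
    def key(self) -> tuple[str, str]:
        return (self.mirna_id, self.gene_id)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (GMT-style) for over-representation analysis."""

    sets: Mapping[str, frozenset[str]]
    descriptions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {term!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)


@dataclass(frozen=True)
class CtTable:
    """Long-format qPCR Ct measurements: one row per technical replicate."""

    data: pd.DataFrame  # columns: sample_id, group, gene_id, ct

    def __post_init__(self) -> None:
        required = ["sample_id", "group", "gene_id", "ct"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise FormatError(f"Ct table missing column(s): {missing}")
        df = self.data[required].copy()
        ct = pd.to_numeric(df["ct"], errors="coerce")
        bad = df.index[~np.isfinite(ct) | (ct <= 0)]
        if len(bad):
            raise FormatError(
                f"Ct values must be finite and > 0; first offending row "
                f"index {bad[0]}")
        df["ct"] = ct.astype(float)
        object.__setattr__(self, "data", df.reset_index(drop=True))

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(sorted(self.data["gene_id"].unique()))

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(sorted(self.data["group"].unique()))

    def replicate_means(self) -> pd.DataFrame:
        """Mean Ct per (sample, gene), collapsing technical replicates."""
        return (self.data.groupby(["sample_id", "group", "gene_id"],
                                  as_index=False)["ct"].mean())


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                           na_values=[], encoding="utf-8")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed TSV structure
        raise FormatError(f"cannot parse {path}: {exc}") from exc


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: str | Path) -> None:
    for col in cols:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")


def _to_float(value: str, column: str, row: int, path: str | Path,
              optional: bool = False) -> float | None:
    value = value.strip()
    if value in {"", "NA", "NaN", "nan"}:
        if optional:
            return None
        raise FormatError(f"{path}: row {row}: empty value in column {column!r}")
    try:
        return float(value)
    except ValueError:
        raise FormatError(
            f"{path}: row {row}: non-numeric value {value!r} in column "
            f"{column!r}") from None


def read_de_table(path: str | Path, layer: Layer | str) -> DETable:
    """Read a per-layer DE table (feature_id, log2fc, p, padj) from TSV.

    ``padj`` may be empty (common for the circRNA layer, where the canonical
    p-value is used for thresholding).
    """
    layer = Layer.coerce(layer)
    df = _read_tsv(path)
    _require_columns(df, ["feature_id", "log2fc", "p", "padj"], path)
    records = []
    for row_num, row in enumerate(df.itertuples(index=False), start=2):
        rec = DERecord(
            feature_id=str(row.feature_id),
            layer=layer,
            log2fc=_to_float(row.log2fc, "log2fc", row_num, path),
            p=_to_float(row.p, "p", row_num, path),
            padj=_to_float(row.padj, "padj", row_num, path, optional=True),
        )
        records.append(rec)
    return DETable(layer=layer, records=tuple(records))


def write_de_table(table: DETable, path: str | Path) -> None:
    df = table.to_frame()
    df["padj"] = df["padj"].map(lambda v: "" if v is None or pd.isna(v) else repr(v))
    df.to_csv(path, sep="\t", index=False)


def read_bsj_matrix(counts_path: str | Path, meta_path: str | Path) -> CountMatrix:
    """Read a junction x sample count TSV plus (sample_id, group, batch) metadata.

    Samples present in the counts but absent from the metadata are an error;
    metadata rows for samples absent from the counts are ignored.
    """
    cdf = _read_tsv(counts_path)
    if cdf.shape[1] < 2:
        raise FormatError(f"{counts_path}: need a feature column plus >=1 sample")
    feature_col = cdf.columns[0]
    sample_ids = [str(c) for c in cdf.columns[1:]]
    feature_ids = [str(v) for v in cdf[feature_col]]
    counts = np.empty((len(feature_ids), len(sample_ids)), dtype=np.int64)
    for j, sample in enumerate(sample_ids):
        col = cdf[cdf.columns[j + 1]]
        for i, raw in enumerate(col):
            raw = str(raw).strip()
            try:
                value = int(raw)
            except ValueError:
                raise FormatError(
                    f"{counts_path}: non-integer count {raw!r} at feature "
                    f"{feature_ids[i]!r}, sample {sample!r}") from None
            if value < 0:
                raise FormatError(
                    f"{counts_path}: negative count {value} at feature "
                    f"{feature_ids[i]!r}, sample {sample!r}")
            counts[i, j] = value

    mdf = _read_tsv(meta_path)
    _require_columns(mdf, ["sample_id", "group"], meta_path)
    meta = {str(r.sample_id): r for r in mdf.itertuples(index=False)}
    missing = [s for s in sample_ids if s not in meta]
    if missing:
        raise FormatError(
            f"{meta_path}: sample(s) in counts but not in metadata: {missing}")
    groups = []
    batches = []
    has_batch = "batch" in mdf.columns
    for s in sample_ids:
        g = str(meta[s].group).strip()
        if g not in {"case", "control"}:
            raise FormatError(
                f"{meta_path}: sample {s!r} has group {g!r}, expected "
                "'case' or 'control'")
        groups.append(g)
        if has_batch:
            batches.append(str(meta[s].batch).strip())
    return CountMatrix(
        feature_ids=tuple(feature_ids),
        sample_ids=tuple(sample_ids),
        counts=counts,
        groups=tuple(groups),
        batches=tuple(batches) if has_batch else None,
    )


def write_count_matrix(matrix: CountMatrix, counts_path: str | Path,
                       meta_path: str | Path) -> None:
    df = matrix.to_frame()
    df.insert(0, "feature_id", list(matrix.feature_ids))
    df.to_csv(counts_path, sep="\t", index=False)
    matrix.meta_frame().to_csv(meta_path, sep="\t", index=False)


def read_circ_mir_table(path: str | Path, source: str | None = None) -> list[CircMirEdge]:
    """Read circRNA->miRNA predictions.

    The TSV needs columns ``circ_id`` and ``mirna_id``; provenance comes from
    a ``sources`` column (``|``-separated labels) or, failing that, from the
    ``source`` argument tagging the whole table.  An untagged table is an
    error: every prediction must be attributable to a database.
    """
    df = _read_tsv(path)
    _require_columns(df, ["circ_id", "mirna_id"], path)
    has_col = "sources" in df.columns
    if not has_col and source is None:
        raise FormatError(
            f"{path}: prediction table has no 'sources' column and no source "
            "label was given; tag the table with its database of origin")
    edges = []
    for row_num, row in enumerate(df.itertuples(index=False), start=2):
        if has_col:
            labels = frozenset(s for s in str(row.sources).split("|") if s)
            if not labels:
                raise FormatError(f"{path}: row {row_num}: empty sources field")
        else:
            labels = frozenset({source})
        edges.append(CircMirEdge(circ_id=str(row.circ_id),
                                 mirna_id=str(row.mirna_id),
                                 sources=labels))
    return edges


def write_circ_mir_table(edges: Iterable[CircMirEdge], path: str | Path) -> None:
    rows = [{"circ_id": e.circ_id, "mirna_id": e.mirna_label,
             "sources": "|".join(sorted(e.sources))} for e in edges]
    pd.DataFrame(rows, columns=["circ_id", "mirna_id", "sources"]).to_csv(
        path, sep="\t", index=False)


def read_mir_mrna_table(path: str | Path) -> list[MirMrnaEdge]:
    """Read miRNA->mRNA predictions with resource count and confidence class."""
    df = _read_tsv(path)
    _require_columns(df, ["mirna_id", "gene_id", "resource_count",
                          "confidence_class"], path)
    edges = []
    seen: set[tuple[str, str]] = set()
    for row_num, row in enumerate(df.itertuples(index=False), start=2):
        try:
            rc = int(str(row.resource_count).strip())
        except ValueError:
            raise FormatError(
                f"{path}: row {row_num}: non-integer resource_count "
                f"{row.resource_count!r}") from None
        edge = MirMrnaEdge(mirna_id=str(row.mirna_id), gene_id=str(row.gene_id),
                           resource_count=rc,
                           confidence_class=Confidence.coerce(row.confidence_class))
        if edge.key in seen:
            raise FormatError(
                f"{path}: row {row_num}: duplicate (mirna, gene) pair "
                f"{edge.key}")
        seen.add(edge.key)
        edges.append(edge)
    return edges


def write_mir_mrna_table(edges: Iterable[MirMrnaEdge], path: str | Path) -> None:
    rows = [{"mirna_id": e.mirna_label, "gene_id": e.gene_id,
             "resource_count": e.resource_count,
             "confidence_class": e.confidence_class.name.lower()}
            for e in edges]
    pd.DataFrame(rows, columns=["mirna_id", "gene_id", "resource_count",
                                "confidence_class"]).to_csv(path, sep="\t",
                                                            index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: per line ``term<TAB>description<TAB>member...``."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line_num, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {line_num}: GMT lines need >=3 tab-"
                    f"separated fields, got {len(fields)}")
            term, desc, *members = fields
            if term in sets:
                raise FormatError(
                    f"{path}: line {line_num}: duplicate term {term!r}")
            members = [m for m in members if m]
            if not members:
                raise FormatError(
                    f"{path}: line {line_num}: gene set {term!r} is empty")
            sets[term] = frozenset(members)
            descriptions[term] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def read_ct_table(path: str | Path) -> CtTable:
    """Read a long-format qPCR Ct table (sample_id, group, gene_id, ct)."""
    df = _read_tsv(path)
    _require_columns(df, ["sample_id", "group", "gene_id", "ct"], path)
    for row_num, raw in enumerate(df["ct"], start=2):
        try:
            value = float(str(raw).strip())
        except ValueError:
            raise FormatError(
                f"{path}: row {row_num}: non-numeric Ct {raw!r}") from None
        if not math.isfinite(value) or value <= 0:
            raise FormatError(
                f"{path}: row {row_num}: Ct must be finite and > 0, got {value}")
    return CtTable(data=df)


def write_ct_table(table: CtTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# network export
# ---------------------------------------------------------------------------

_EDGE_TSV_COLUMNS = [
    "circ_id", "mirna_id", "mrna_id",
    "circ_log2fc", "mirna_log2fc", "mrna_log2fc",
    "circ_stat", "mirna_stat", "mrna_stat",
    "circ_mir_sources", "mm_resource_count",
]


def write_network(network, path: str | Path, fmt: str = "edge_tsv") -> None:
    """Export a ceRNA network as edge TSV, SIF or GraphML.

    * ``edge_tsv`` -- one line per circRNA-miRNA-mRNA triple; round-trips
      losslessly through :func:`read_network_edge_tsv`.
    * ``sif`` -- Cytoscape simple-interaction format with interaction labels
      ``sponges`` (circ->miR) and ``targets`` (miR->mRNA), deduplicated.
    * ``graphml`` -- nodes carry ``layer`` and ``regulation_sign`` attributes.
    """
    path = Path(path)
    triples = sorted(network.triples,
                     key=lambda t: (t.circ.feature_id, t.mirna.feature_id,
                                    t.mrna.feature_id))
    if fmt == "edge_tsv":
        rows = []
        for t in triples:
            rows.append({
                "circ_id": t.circ.feature_id,
                "mirna_id": t.mirna.feature_id,
                "mrna_id": t.mrna.feature_id,
                "circ_log2fc": repr(t.circ.log2fc),
                "mirna_log2fc": repr(t.mirna.log2fc),
                "mrna_log2fc": repr(t.mrna.log2fc),
                "circ_stat": repr(t.circ.stat),
                "mirna_stat": repr(t.mirna.stat),
                "mrna_stat": repr(t.mrna.stat),
                "circ_mir_sources": "|".join(sorted(t.circ_mir_sources)),
                "mm_resource_count": t.mm_resource_count,
            })
        pd.DataFrame(rows, columns=_EDGE_TSV_COLUMNS).to_csv(path, sep="\t",
                                                             index=False)
    elif fmt == "sif":
        lines: list[str] = []
        seen: set[tuple[str, str, str]] = set()
        for t in triples:
            for a, rel, b in ((t.circ.feature_id, "sponges", t.mirna.feature_id),
                              (t.mirna.feature_id, "targets", t.mrna.feature_id)):
                if (a, rel, b) not in seen:
                    seen.add((a, rel, b))
                    lines.append(f"{a}\t{rel}\t{b}")
        path.write_text("\n".join(lines) + ("\n" if lines else ""),
                        encoding="utf-8")
    elif fmt == "graphml":
        import networkx as nx

        g = nx.DiGraph()
        for t in triples:
            for feat in (t.circ, t.mirna, t.mrna):
                g.add_node(feat.feature_id, layer=feat.layer.value,
                           regulation_sign=int(feat.sign))
            g.add_edge(t.circ.feature_id, t.mirna.feature_id,
                       interaction="sponges",
                       sources="|".join(sorted(t.circ_mir_sources)))
            g.add_edge(t.mirna.feature_id, t.mrna.feature_id,
                       interaction="targets",
                       resource_count=int(t.mm_resource_count))
        nx.write_graphml(g, path)
    else:
        raise FormatError(f"unknown network format {fmt!r}; expected "
                          "edge_tsv, sif or graphml")


def read_network_edge_tsv(path: str | Path):
    """Rebuild a :class:`~circernet.cernet.CeRNANetwork` from an edge TSV."""
    from .cernet import CeRNANetwork, CeRNATriple, SignedFeature

    df = _read_tsv(path)
    _require_columns(df, _EDGE_TSV_COLUMNS, path)
    triples = []
    for row_num, row in enumerate(df.itertuples(index=False), start=2):
        def num(value, col=None):
            return _to_float(str(value), col or "?", row_num, path)

        triples.append(CeRNATriple(
            circ=SignedFeature(str(row.circ_id), Layer.CIRCRNA,
                               num(row.circ_log2fc, "circ_log2fc"),
                               num(row.circ_stat, "circ_stat")),
            mirna=SignedFeature(str(row.mirna_id), Layer.MIRNA,
                                num(row.mirna_log2fc, "mirna_log2fc"),
                                num(row.mirna_stat, "mirna_stat")),
            mrna=SignedFeature(str(row.mrna_id), Layer.MRNA,
                               num(row.mrna_log2fc, "mrna_log2fc"),
                               num(row.mrna_stat, "mrna_stat")),
            circ_mir_sources=frozenset(
                s for s in str(row.circ_mir_sources).split("|") if s),
            mm_resource_count=int(str(row.mm_resource_count)),
        ))
    return CeRNANetwork(triples=frozenset(triples))
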