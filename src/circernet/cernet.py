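"""The ceRNA inference cascade: abundance filter, DE gating, prediction
merging and filtering, counter-regulation (inverse-modulation) filters,
tripartite network assembly, summary and hub ranking.

The model is the competing-endogenous-RNA hypothesis: a circRNA that sponges
a miRNA de-represses that miRNA's mRNA targets, so in a case/control
contrast a functional sponge triple should show opposite differential-
expression signs on the circRNA-miRNA edge and on the miRNA-mRNA edge
(hence the circRNA and the de-repressed mRNA move together).  Each stage
here is a set-level filter; the assembled network is the join of the two
surviving edge layers on the shared miRNA.

Threshold defaults follow the study conditions this pipeline emulates:
BSJ abundance >= 5 reads in at least 50% of samples, mRNA padj < 0.01,
circRNA p < 0.05 with |log2FC| >= 1, miRNA adjusted p < 0.05, and
miRNA->mRNA predictions with >= 5 supporting resources at high confidence.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .tabio import (
    CircMirEdge,
    Confidence,
    CountMatrix,
    DETable,
    FormatError,
    Layer,
    MirMrnaEdge,
)

__all__ = [
    "ThresholdConfig",
    "SignedFeature",
    "CeRNATriple",
    "CeRNANetwork",
    "FilterReport",
    "MergeResult",
    "InverseFilterResult",
    "NetworkSummary",
    "abundance_filter",
    "de_threshold_filter",
    "merge_circ_mirna_predictions",
    "filter_mirna_mrna_predictions",
    "inverse_modulation_filter",
    "assemble_network",
    "network_summary",
    "rank_hubs",
]


@dataclass(frozen=True)
class ThresholdConfig:
    """All tunable gates of the cascade, with the study defaults.

    bsj_min_reads / bsj_min_sample_frac
        A junction is kept when at least ``ceil(frac * n_samples)`` samples
        show >= ``bsj_min_reads`` reads.
    mrna_padj_max
        BH-adjusted p gate for the mRNA layer (no fold-change gate there).
    circ_p_max / circ_abs_lfc_min
        Canonical p and absolute log2 fold-change gates for circRNAs.
    mirna_padj_max
        Adjusted-p gate for the miRNA layer (falls back to raw p when the
        table carries no adjusted values).
    mm_min_resources / mm_min_confidence
        Provenance gates for miRNA->mRNA predictions.
    """

    bsj_min_reads: int = 5
    bsj_min_sample_frac: float = 0.5
    mrna_padj_max: float = 0.01
    circ_p_max: float = 0.05
    circ_abs_lfc_min: float = 1.0
    mirna_padj_max: float = 0.05
    mm_min_resources: int = 5
    mm_min_confidence: Confidence = Confidence.HIGH

    def __post_init__(self) -> None:
        if self.bsj_min_reads < 0:
            raise ValueError("bsj_min_reads must be >= 0")
        if not (0.0 <= self.bsj_min_sample_frac <= 1.0):
            raise ValueError("bsj_min_sample_frac must be in [0,1]")
        for name in ("mrna_padj_max", "circ_p_max", "mirna_padj_max"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1]")
        if self.circ_abs_lfc_min < 0:
            raise ValueError("circ_abs_lfc_min must be >= 0")
        if self.mm_min_resources < 1:
            raise ValueError("mm_min_resources must be >= 1")
        object.__setattr__(self, "mm_min_confidence",
                           Confidence.coerce(self.mm_min_confidence))


@dataclass(frozen=True)
class SignedFeature:
    """A differentially expressed feature with its regulation direction."""

    feature_id: str
    layer: Layer
    log2fc: float
    stat: float  # the statistic that gated this feature (padj or p)

    def __post_init__(self) -> None:
        if self.log2fc == 0 or not math.isfinite(self.log2fc):
            raise ValueError(
                f"signed feature {self.feature_id!r} needs a nonzero finite "
                "log2fc")

    @property
    def sign(self) -> int:
        return 1 if self.log2fc > 0 else -1


@dataclass(frozen=True)
class CeRNATriple:
    """One sign-consistent circRNA-miRNA-mRNA sponge interaction."""

    circ: SignedFeature
    mirna: SignedFeature
    mrna: SignedFeature
    circ_mir_sources: frozenset[str] = frozenset()
    mm_resource_count: int = 1

    def __post_init__(self) -> None:
        if self.circ.sign != -self.mirna.sign or self.mirna.sign != -self.mrna.sign:
            raise ValueError(
                "sign-inconsistent triple "
                f"({self.circ.feature_id}:{self.circ.sign:+d}, "
                f"{self.mirna.feature_id}:{self.mirna.sign:+d}, "
                f"{self.mrna.feature_id}:{self.mrna.sign:+d}); the counter-"
                "regulation filters must run before assembly")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.circ.feature_id, self.mirna.feature_id,
                self.mrna.feature_id)


@dataclass(frozen=True)
class CeRNANetwork:
    """A set of ceRNA triples plus per-layer node views."""

    triples: frozenset[CeRNATriple]

    def __len__(self) -> int:
        return len(self.triples)

    @property
    def triple_keys(self) -> frozenset[tuple[str, str, str]]:
        return frozenset(t.key for t in self.triples)

    @property
    def circ_mir_edges(self) -> frozenset[tuple[str, str]]:
        return frozenset((t.circ.feature_id, t.mirna.feature_id)
                         for t in self.triples)

    @property
    def mir_mrna_edges(self) -> frozenset[tuple[str, str]]:
        return frozenset((t.mirna.feature_id, t.mrna.feature_id)
                         for t in self.triples)

    def nodes(self, layer: Layer) -> frozenset[str]:
        picker = {Layer.CIRCRNA: lambda t: t.circ,
                  Layer.MIRNA: lambda t: t.mirna,
                  Layer.MRNA: lambda t: t.mrna}[layer]
        return frozenset(picker(t).feature_id for t in self.triples)


@dataclass(frozen=True)
class FilterReport:
    """Input/output feature counts of one filtering stage."""

    stage: str
    n_in: int
    n_out: int

    def __post_init__(self) -> None:
        if self.n_out > self.n_in:
            raise ValueError("a filter cannot emit more features than it saw")


def abundance_filter(matrix: CountMatrix, cfg: ThresholdConfig
                     ) -> tuple[CountMatrix, FilterReport]:
    """Drop junctions not reaching ``bsj_min_reads`` in enough samples.

    "At least 50% of the samples" uses ceiling semantics: with 39 samples the
    requirement is 20.
    """
    n_required = math.ceil(round(cfg.bsj_min_sample_frac * matrix.n_samples, 9))
    ok = (matrix.counts >= cfg.bsj_min_reads).sum(axis=1) >= n_required
    kept = CountMatrix(
        feature_ids=tuple(f for f, keep in zip(matrix.feature_ids, ok) if keep),
        sample_ids=matrix.sample_ids,
        counts=matrix.counts[np.asarray(ok, dtype=bool)],
        groups=matrix.groups,
        batches=matrix.batches,
    )
    report = FilterReport(stage="bsj_abundance", n_in=matrix.n_features,
                          n_out=kept.n_features)
    return kept, report


def de_threshold_filter(table: DETable, cfg: ThresholdConfig
                        ) -> frozenset[SignedFeature]:
    """Apply the layer-specific significance gate and attach regulation signs.

    mRNA: padj < ``mrna_padj_max`` (no fold-change gate).
    circRNA: p < ``circ_p_max`` and |log2FC| >= ``circ_abs_lfc_min``.
    miRNA: padj < ``mirna_padj_max`` (raw p when padj is absent).
    Features with log2fc == 0 are never retained.
    """
    retained: set[SignedFeature] = set()
    for rec in table:
        if table.layer is Layer.MRNA:
            if rec.padj is None:
                raise FormatError(
                    f"mRNA record {rec.feature_id!r} lacks padj, required "
                    "for the mRNA gate")
            keep = rec.padj < cfg.mrna_padj_max
            stat = rec.padj
        elif table.layer is Layer.CIRCRNA:
            keep = (rec.p < cfg.circ_p_max
                    and abs(rec.log2fc) >= cfg.circ_abs_lfc_min)
            stat = rec.p
        else:  # miRNA
            stat = rec.padj if rec.padj is not None else rec.p
            keep = stat < cfg.mirna_padj_max
        if keep and rec.log2fc != 0:
            retained.add(SignedFeature(feature_id=rec.feature_id,
                                       layer=table.layer,
                                       log2fc=rec.log2fc, stat=stat))
    return frozenset(retained)


@dataclass(frozen=True)
class MergeResult:
    """Union of per-database circRNA->miRNA predictions with provenance."""

    edges: tuple[CircMirEdge, ...]
    no_match_circs: tuple[str, ...]  # queried circRNAs absent from every source


def merge_circ_mirna_predictions(tables: Sequence[Iterable[CircMirEdge]],
                                 circ_universe: Iterable[str] | None = None
                                 ) -> MergeResult:
    """Union circRNA->miRNA predictions across databases.

    Duplicate (circ, miRNA) pairs collapse into one edge whose ``sources``
    is the union of the contributing labels; combination is deliberately a
    union, not an intersection — a pair predicted by any single database
    qualifies, with provenance preserved for audit.  ``circ_universe`` lists
    the circRNAs that were queried, so the coverage report can name those
    with no match in any source.
    """
    merged: dict[tuple[str, str], CircMirEdge] = {}
    for table in tables:
        for edge in table:
            prev = merged.get(edge.key)
            if prev is None:
                merged[edge.key] = edge
            else:
                merged[edge.key] = CircMirEdge(
                    circ_id=prev.circ_id, mirna_id=prev.mirna_id,
                    sources=prev.sources | edge.sources,
                    site_count=prev.site_count,
                    mirna_label=prev.mirna_label)
    covered = {c for (c, _m) in merged}
    if circ_universe is None:
        no_match: tuple[str, ...] = ()
    else:
        no_match = tuple(sorted(set(circ_universe) - covered))
    edges = tuple(sorted(merged.values(), key=lambda e: e.key))
    return MergeResult(edges=edges, no_match_circs=no_match)


def filter_mirna_mrna_predictions(edges: Iterable[MirMrnaEdge],
                                  cfg: ThresholdConfig
                                  ) -> tuple[MirMrnaEdge, ...]:
    """Keep predictions with enough resources at high-enough confidence."""
    return tuple(e for e in edges
                 if e.confidence_class >= cfg.mm_min_confidence
                 and e.resource_count >= cfg.mm_min_resources)


@dataclass(frozen=True)
class InverseFilterResult:
    """Counter-regulation filter outcome for one edge layer."""

    retained: tuple
    concordant_count: int  # both endpoints DE but with the same sign
    dropped_non_de_count: int  # at least one endpoint not differentially expressed


def _edge_endpoints(edge) -> tuple[str, str]:
    if isinstance(edge, CircMirEdge):
        return edge.circ_id, edge.mirna_id
    if isinstance(edge, MirMrnaEdge):
        return edge.mirna_id, edge.gene_id
    raise TypeError(f"unsupported edge type {type(edge).__name__}")


def inverse_modulation_filter(edges: Iterable,
                              de_a: Iterable[SignedFeature],
                              de_b: Iterable[SignedFeature]
                              ) -> InverseFilterResult:
    """Keep edges whose two endpoints are DE with opposite signs.

    Edges whose endpoints are both DE but share a sign are counted as
    concordant (the class the study reports separately as evidence that
    inverse modulation dominates); edges with a non-DE endpoint are counted
    in ``dropped_non_de_count``.
    """
    sign_a = {f.feature_id: f.sign for f in de_a}
    sign_b = {f.feature_id: f.sign for f in de_b}
    retained = []
    concordant = 0
    non_de = 0
    for edge in edges:
        a, b = _edge_endpoints(edge)
        if a not in sign_a or b not in sign_b:
            non_de += 1
        elif sign_a[a] * sign_b[b] == -1:
            retained.append(edge)
        else:
            concordant += 1
    return InverseFilterResult(retained=tuple(retained),
                               concordant_count=concordant,
                               dropped_non_de_count=non_de)


def assemble_network(circ_mir: Iterable[CircMirEdge],
                     mir_mrna: Iterable[MirMrnaEdge],
                     signed: Mapping[Layer, Iterable[SignedFeature]]
                     ) -> CeRNANetwork:
    """Join the two inverse-filtered edge layers on the shared miRNA.

    Triples are the relational product {(c, m, g) : (c,m) in circ_mir and
    (m,g) in mir_mrna}.  Every triple is re-checked against the sign
    invariant (circ and mRNA move together, opposite to the miRNA); a
    violation means the inputs were not inverse-filtered and is an error.
    miRNAs with no surviving mRNA target simply contribute no triples and
    are therefore absent from the network's node tables.
    """
    features: dict[tuple[Layer, str], SignedFeature] = {}
    for layer, feats in signed.items():
        for f in feats:
            features[(Layer.coerce(layer), f.feature_id)] = f

    by_mirna: dict[str, list[MirMrnaEdge]] = {}
    for edge in mir_mrna:
        by_mirna.setdefault(edge.mirna_id, []).append(edge)

    triples: set[CeRNATriple] = set()
    for cm in circ_mir:
        for mm in by_mirna.get(cm.mirna_id, ()):
            try:
                circ = features[(Layer.CIRCRNA, cm.circ_id)]
                mirna = features[(Layer.MIRNA, cm.mirna_id)]
                mrna = features[(Layer.MRNA, mm.gene_id)]
            except KeyError as exc:
                raise ValueError(
                    f"edge endpoint {exc.args[0]} has no signed DE record; "
                    "run the inverse-modulation filter first") from None
            triples.add(CeRNATriple(circ=circ, mirna=mirna, mrna=mrna,
                                    circ_mir_sources=cm.sources,
                                    mm_resource_count=mm.resource_count))
    return CeRNANetwork(triples=frozenset(triples))


@dataclass(frozen=True)
class NetworkSummary:
    """Per-circRNA sponge summary plus layer-level node counts.

    ``total_interactions`` counts triples; ``n_mrnas`` counts distinct mRNA
    nodes — the two need not agree because one mRNA can be targeted by
    several miRNAs, so both are reported.
    """

    per_circ: Mapping[str, tuple[tuple[str, ...], int]]  # circ -> (miRNAs, n triples)
    total_interactions: int
    n_circs: int
    n_mirnas: int
    n_mrnas: int

    def to_rows(self) -> list[dict]:
        rows = []
        for circ in sorted(self.per_circ):
            mirnas, count = self.per_circ[circ]
            rows.append({"circ_id": circ, "mirnas": "|".join(mirnas),
                         "mirna_degree": len(mirnas),
                         "interaction_count": count})
        return rows


def network_summary(network: CeRNANetwork) -> NetworkSummary:
    """Group triples by circRNA; totals are conserved by construction."""
    per_circ: dict[str, tuple[tuple[str, ...], int]] = {}
    for circ in network.nodes(Layer.CIRCRNA):
        mine = [t for t in network.triples if t.circ.feature_id == circ]
        mirnas = tuple(sorted({t.mirna.feature_id for t in mine}))
        per_circ[circ] = (mirnas, len(mine))
    total = sum(count for _m, count in per_circ.values())
    assert total == len(network.triples)
    return NetworkSummary(
        per_circ=per_circ,
        total_interactions=total,
        n_circs=len(network.nodes(Layer.CIRCRNA)),
        n_mirnas=len(network.nodes(Layer.MIRNA)),
        n_mrnas=len(network.nodes(Layer.MRNA)),
    )


def rank_hubs(network: CeRNANetwork) -> list[tuple[str, int, int]]:
    """Rank circRNAs as sponge hubs.

    Sort key: miRNA degree (descending), then interaction count
    (descending), then identifier (lexicographic tie-break).
    """
    summary = network_summary(network)
    rows = [(circ, len(mirnas), count)
            for circ, (mirnas, count) in summary.per_circ.items()]
    rows.sort(key=lambda r: (-r[1], -r[2], r[0]))
    return rows
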