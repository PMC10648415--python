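"""Synthetic inputs with the statistical structure the inference assumes.

The generator plants a ground-truth tripartite sponge network — sign-
consistent circRNA-miRNA-mRNA triples (circRNA and mRNA move together,
opposite to the miRNA) — and emits everything the pipeline consumes:

* negative-binomial count matrices for the mRNA and circRNA (BSJ) layers,
  with planted differential expression of a stated log2 effect size and
  additive batch offsets on the log2 mean (batches balanced across groups);
* a miRNA DE table emitted directly (mirroring a study design where miRNA
  profiling comes from a separate dataset rather than the same RNA-seq);
* prediction tables carrying the true edges plus three decoy classes that
  each probe one downstream filter: concordant-sign circ-miR pairs (the
  inverse-modulation filter must drop them), miR-mRNA edges with a non-DE
  endpoint (the DE gate must drop them), and miR-mRNA edges supported by
  too few resources (the provenance gate must drop them);
* qPCR Ct tables with planted fold changes.

All generators are pure functions of (params, seed): each draws from its
own child stream of the configured seed, so regenerating any one table is
reproducible in isolation.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .cernet import CeRNANetwork
from .tabio import (
    CircMirEdge,
    Confidence,
    CountMatrix,
    CtTable,
    DERecord,
    DETable,
    Layer,
    MirMrnaEdge,
)

__all__ = [
    "SimParams",
    "GroundTruth",
    "LevelReport",
    "RecoveryReport",
    "simulate_ground_truth",
    "simulate_counts",
    "simulate_mirna_de",
    "simulate_prediction_tables",
    "simulate_ct_table",
    "evaluate_recovery",
]

_SOURCES = ("encori", "circinteractome", "circatlas")


@dataclass(frozen=True)
class SimParams:
    """Study conditions for the synthetic cohort.

    Defaults emulate a modest two-group RNA-seq contrast: 20 samples per
    group in 3 batches, planted |log2FC| of 2 for DE features, NB dispersion
    0.1 (variance = mu + 0.1 mu^2), baseline mean 100 counts, batch offsets
    with SD 0.25 on the log2 mean.  ``de_fraction`` controls how many nodes
    per layer are differentially expressed at all; non-DE nodes are needed
    as endpoints for the non-DE decoy class.

    ``n_background_mrna`` / ``n_background_circ`` add non-DE features that
    are not part of the planted network.  Real count matrices are dominated
    by unchanged features; without that bulk, planting strong fold changes
    on most features shifts the total library size between groups and
    total-count CPM normalisation makes null features look regulated.  A
    ``low_abundance_frac`` share of the background circRNA junctions is
    simulated near the detection floor so the abundance filter has real
    work to do.
    """

    n_circ: int = 20
    n_mirna: int = 30
    n_mrna: int = 60
    n_background_mrna: int = 400
    n_background_circ: int = 200
    low_abundance_frac: float = 0.25
    n_case: int = 20
    n_control: int = 20
    n_batches: int = 3
    planted_triples: int = 30
    decoy_concordant_edges: int = 0
    decoy_nonde_edges: int = 0
    decoy_low_resource_edges: int = 0
    lfc_magnitude: float = 2.0
    nb_dispersion: float = 0.1
    baseline_mean: float = 100.0
    batch_sd: float = 0.25
    true_edge_pass_rate: float = 1.0
    de_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_circ", "n_mirna", "n_mrna", "n_background_mrna",
                     "n_background_circ", "n_case", "n_control",
                     "planted_triples", "decoy_concordant_edges",
                     "decoy_nonde_edges", "decoy_low_resource_edges"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be > 0")
        if self.batch_sd < 0:
            raise ValueError("batch_sd must be >= 0")
        for name in ("true_edge_pass_rate", "de_fraction",
                     "low_abundance_frac"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in [0,1]")


@dataclass(frozen=True)
class GroundTruth:
    """The planted network: per-layer DE signs, true triples, decoy edges."""

    de_signs: Mapping[Layer, Mapping[str, int]]
    true_triples: frozenset[tuple[str, str, str]]
    decoys: Mapping[str, frozenset[tuple[str, str]]] = field(
        default_factory=dict)

    def __post_init__(self) -> None:
        for c, m, g in self.true_triples:
            sc = self.de_signs[Layer.CIRCRNA][c]
            sm = self.de_signs[Layer.MIRNA][m]
            sg = self.de_signs[Layer.MRNA][g]
            if not (sc != 0 and sc == -sm and sc == sg):
                raise ValueError(
                    f"planted triple ({c},{m},{g}) violates sign "
                    f"consistency: {sc:+d}/{sm:+d}/{sg:+d}")

    @property
    def true_circ_mir(self) -> frozenset[tuple[str, str]]:
        return frozenset((c, m) for c, m, _g in self.true_triples)

    @property
    def true_mir_mrna(self) -> frozenset[tuple[str, str]]:
        return frozenset((m, g) for _c, m, g in self.true_triples)


def _rng(params_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, params_seed])


def _layer_ids(params: SimParams) -> dict[Layer, list[str]]:
    """Core (network-candidate) ids per layer; background ids kept apart."""
    return {
        Layer.CIRCRNA: [f"circ_{i:03d}" for i in range(params.n_circ)],
        Layer.MIRNA: [f"hsa-mir-sim-{i:03d}" for i in range(params.n_mirna)],
        Layer.MRNA: [f"GENE{i:04d}" for i in range(params.n_mrna)],
    }


def _background_ids(params: SimParams) -> dict[Layer, list[str]]:
    return {
        Layer.CIRCRNA: [f"bgcirc_{i:04d}"
                        for i in range(params.n_background_circ)],
        Layer.MRNA: [f"bgGENE{i:04d}"
                     for i in range(params.n_background_mrna)],
    }


def _assign_signs(ids: list[str], de_fraction: float,
                  rng: np.random.Generator) -> dict[str, int]:
    n_de = int(round(de_fraction * len(ids)))
    de_idx = set(rng.choice(len(ids), size=n_de, replace=False).tolist()) \
        if ids else set()
    return {fid: (int(rng.choice([-1, 1])) if i in de_idx else 0)
            for i, fid in enumerate(ids)}


def _sample_pairs(candidates: list[tuple], n: int, what: str,
                  rng: np.random.Generator) -> list[tuple]:
    if n > len(candidates):
        raise ValueError(
            f"requested {n} {what} but only {len(candidates)} are feasible")
    if n == 0:
        return []
    idx = rng.choice(len(candidates), size=n, replace=False)
    return [candidates[i] for i in sorted(idx.tolist())]


def simulate_ground_truth(params: SimParams) -> GroundTruth:
    """Plant DE signs, sign-consistent triples and labelled decoy edges.

    Raises when the request is infeasible, stating the bound (e.g. more
    triples than sign-consistent (circ, miR, mRNA) combinations exist).
    Decoy edges never duplicate true edges.
    """
    rng = _rng(params.seed, 1)
    ids = _layer_ids(params)
    signs = {layer: _assign_signs(ids[layer], params.de_fraction, rng)
             for layer in ids}
    for layer, bg in _background_ids(params).items():
        for fid in bg:
            signs[layer][fid] = 0
        ids[layer] = ids[layer] + bg

    def with_sign(layer: Layer, s: int) -> list[str]:
        return [fid for fid in ids[layer] if signs[layer][fid] == s]

    # Each miRNA gets exactly one sponge circRNA, so the planted triple set
    # is closed under the (circ,miR) x (miR,mRNA) relational product -- the
    # only structure a join on the shared miRNA can recover exactly.
    mg_pool: list[tuple[str, str]] = []
    for s in (1, -1):
        if with_sign(Layer.CIRCRNA, s):
            mg_pool.extend(itertools.product(with_sign(Layer.MIRNA, -s),
                                             with_sign(Layer.MRNA, s)))
    mg_pairs = _sample_pairs(mg_pool, params.planted_triples,
                             "planted sign-consistent (miRNA, mRNA) pairs",
                             rng)
    sponge_of: dict[str, str] = {}
    triples = []
    for m, g in mg_pairs:
        if m not in sponge_of:
            candidates = with_sign(Layer.CIRCRNA, -signs[Layer.MIRNA][m])
            sponge_of[m] = candidates[int(rng.integers(len(candidates)))]
        triples.append((sponge_of[m], m, g))
    true_triples = frozenset(triples)
    true_cm = {(c, m) for c, m, _g in true_triples}
    true_mm = {(m, g) for _c, m, g in true_triples}

    concordant_pool = [
        (c, m)
        for s in (1, -1)
        for c, m in itertools.product(with_sign(Layer.CIRCRNA, s),
                                      with_sign(Layer.MIRNA, s))
        if (c, m) not in true_cm
    ]
    nonde_pool = [
        (m, g)
        for m in ids[Layer.MIRNA] if signs[Layer.MIRNA][m] != 0
        for g in with_sign(Layer.MRNA, 0)
    ]
    low_resource_pool = [
        (m, g)
        for s in (1, -1)
        for m, g in itertools.product(with_sign(Layer.MIRNA, s),
                                      with_sign(Layer.MRNA, -s))
        if (m, g) not in true_mm
    ]
    decoys = {
        "concordant": frozenset(_sample_pairs(
            concordant_pool, params.decoy_concordant_edges,
            "concordant circRNA-miRNA decoys", rng)),
        "non_de": frozenset(_sample_pairs(
            nonde_pool, params.decoy_nonde_edges,
            "non-DE miRNA-mRNA decoys", rng)),
        "low_resource": frozenset(_sample_pairs(
            low_resource_pool, params.decoy_low_resource_edges,
            "low-resource miRNA-mRNA decoys", rng)),
    }
    return GroundTruth(de_signs=signs, true_triples=true_triples,
                       decoys=decoys)


def _sample_layout(params: SimParams) -> tuple[list[str], list[str], list[str]]:
    """Sample ids, groups, and batches; batches balanced across groups."""
    samples, groups, batches = [], [], []
    for group, n in (("case", params.n_case), ("control", params.n_control)):
        for i in range(n):
            samples.append(f"{group}_{i + 1:02d}")
            groups.append(group)
            batches.append(f"batch{i % params.n_batches + 1}")
    return samples, groups, batches


def simulate_counts(gt: GroundTruth, params: SimParams
                    ) -> dict[Layer, CountMatrix]:
    """NB count matrices for the mRNA and circRNA layers.

    Case-group mean = baseline * 2^(sign * lfc_magnitude); each (feature,
    batch) pair adds N(0, batch_sd) to the log2 mean.  Variance follows the
    RNA-seq convention var = mu + dispersion * mu^2; dispersion 0 degrades
    to Poisson.
    """
    rng = _rng(params.seed, 2)
    samples, groups, batches = _sample_layout(params)
    batch_names = sorted(set(batches))
    out: dict[Layer, CountMatrix] = {}
    for layer in (Layer.MRNA, Layer.CIRCRNA):
        signs = gt.de_signs[layer]
        feature_ids = list(signs)
        n_feat = len(feature_ids)
        batch_offsets = rng.normal(0.0, params.batch_sd,
                                   size=(n_feat, len(batch_names)))
        batch_idx = np.array([batch_names.index(b) for b in batches])
        is_case = np.array([g == "case" for g in groups], dtype=float)
        sign_vec = np.array([signs[f] for f in feature_ids], dtype=float)
        baseline = np.full(n_feat, float(params.baseline_mean))
        if layer is Layer.CIRCRNA:
            # a share of background junctions sits near the detection floor
            bg_idx = [i for i, f in enumerate(feature_ids)
                      if f.startswith("bgcirc_")]
            n_low = int(round(params.low_abundance_frac * len(bg_idx)))
            low = rng.choice(len(bg_idx), size=n_low, replace=False) \
                if n_low else []
            for j in np.asarray(low, dtype=int):
                baseline[bg_idx[j]] = 2.0
        log2_mean = (np.log2(baseline)[:, None]
                     + np.outer(sign_vec * params.lfc_magnitude, is_case)
                     + batch_offsets[:, batch_idx])
        mu = np.power(2.0, log2_mean)
        if params.nb_dispersion < 1e-9:
            counts = rng.poisson(mu)
        else:
            shape = 1.0 / params.nb_dispersion
            p = shape / (shape + mu)
            counts = rng.negative_binomial(shape, p)
        out[layer] = CountMatrix(feature_ids=tuple(feature_ids),
                                 sample_ids=tuple(samples),
                                 counts=counts.astype(np.int64),
                                 groups=tuple(groups),
                                 batches=tuple(batches))
    return out


def simulate_mirna_de(gt: GroundTruth, params: SimParams) -> DETable:
    """Emit the miRNA layer directly as a DE table.

    DE miRNAs get log2FC = sign * lfc_magnitude plus small noise and a tiny
    adjusted p; non-DE miRNAs get near-zero log2FC and a large p.
    """
    rng = _rng(params.seed, 3)
    records = []
    for mirna, sign in gt.de_signs[Layer.MIRNA].items():
        if sign != 0:
            lfc = sign * params.lfc_magnitude + rng.normal(0, 0.1)
            if lfc == 0 or np.sign(lfc) != sign:  # tiny effect + noise edge case
                lfc = sign * max(abs(lfc), 1e-6)
            p = float(10.0 ** rng.uniform(-10, -5))
            padj = min(1.0, p * 10)
        else:
            lfc = float(rng.normal(0, 0.05))
            p = float(rng.uniform(0.2, 1.0))
            padj = min(1.0, p * 1.3)
        records.append(DERecord(feature_id=mirna, layer=Layer.MIRNA,
                                log2fc=float(lfc), p=p, padj=float(padj)))
    return DETable(layer=Layer.MIRNA, records=tuple(records))


def simulate_prediction_tables(gt: GroundTruth, params: SimParams
                               ) -> tuple[list[CircMirEdge], list[MirMrnaEdge]]:
    """Prediction tables containing true edges plus the decoy classes.

    Each true circRNA-miRNA edge appears (with >= 1 database source) with
    probability ``true_edge_pass_rate``; each true miRNA-mRNA edge gets
    resource_count >= 5 at high confidence with the same probability and is
    otherwise emitted with a failing resource count.  Concordant decoys get
    passing provenance (only the sign filter may remove them); non-DE decoys
    get passing provenance (only the DE gate may remove them); low-resource
    decoys get resource_count in [1, 4].
    """
    rng = _rng(params.seed, 4)
    cm_edges: list[CircMirEdge] = []
    for c, m in sorted(gt.true_circ_mir):
        if rng.random() <= params.true_edge_pass_rate and \
                params.true_edge_pass_rate > 0:
            n_src = int(rng.integers(1, len(_SOURCES) + 1))
            src = rng.choice(_SOURCES, size=n_src, replace=False)
            cm_edges.append(CircMirEdge(circ_id=c, mirna_id=m,
                                        sources=frozenset(src.tolist())))
    for c, m in sorted(gt.decoys.get("concordant", ())):
        src = rng.choice(_SOURCES)
        cm_edges.append(CircMirEdge(circ_id=c, mirna_id=m,
                                    sources=frozenset({str(src)})))

    mm_edges: list[MirMrnaEdge] = []
    for m, g in sorted(gt.true_mir_mrna):
        if rng.random() <= params.true_edge_pass_rate and \
                params.true_edge_pass_rate > 0:
            rc = int(rng.integers(5, 21))
            conf = Confidence.HIGH if rng.random() < 0.7 else Confidence.VERY_HIGH
        else:
            rc = int(rng.integers(1, 5))
            conf = Confidence.HIGH
        mm_edges.append(MirMrnaEdge(mirna_id=m, gene_id=g, resource_count=rc,
                                    confidence_class=conf))
    for m, g in sorted(gt.decoys.get("non_de", ())):
        mm_edges.append(MirMrnaEdge(mirna_id=m, gene_id=g,
                                    resource_count=int(rng.integers(5, 21)),
                                    confidence_class=Confidence.HIGH))
    for m, g in sorted(gt.decoys.get("low_resource", ())):
        mm_edges.append(MirMrnaEdge(mirna_id=m, gene_id=g,
                                    resource_count=int(rng.integers(1, 5)),
                                    confidence_class=Confidence.HIGH))
    return cm_edges, mm_edges


def simulate_ct_table(planted_lfc: Mapping[str, float], n_per_group: int,
                      noise_sd: float, reference_gene: str, seed: int,
                      groups: tuple[str, str] = ("case", "control"),
                      n_replicates: int = 3) -> CtTable:
    """qPCR Ct table with planted log2 fold changes.

    The second entry of ``groups`` is the baseline: its Ct for gene g sits
    at a gene-specific baseline cycle; the first group's Ct is shifted by
    -planted_lfc[g] (one cycle per doubling), with N(0, noise_sd) per
    replicate measurement.  The reference gene must have planted_lfc = 0.
    """
    import pandas as pd

    if reference_gene not in planted_lfc:
        raise ValueError("reference gene must appear in planted_lfc")
    if planted_lfc[reference_gene] != 0:
        raise ValueError("reference gene must have planted_lfc = 0")
    rng = np.random.default_rng([5, seed])
    baseline = {g: float(rng.uniform(20, 26)) for g in planted_lfc}
    alt, ctrl = groups
    rows = []
    for group in (alt, ctrl):
        for i in range(n_per_group):
            sample = f"{group}_{i + 1:02d}"
            for gene, lfc in planted_lfc.items():
                shift = -lfc if group == alt else 0.0
                for _rep in range(n_replicates):
                    ct_value = baseline[gene] + shift + rng.normal(0, noise_sd)
                    rows.append({"sample_id": sample, "group": group,
                                 "gene_id": gene, "ct": ct_value})
    return CtTable(data=pd.DataFrame(rows))


@dataclass(frozen=True)
class LevelReport:
    """Precision/recall at one level (triples or one edge layer).

    Precision is None when nothing was predicted; recall is None when the
    true set is empty; F1 is None when either is None and 0 when both are 0.
    """

    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float | None:
        return None if self.tp + self.fp == 0 else self.tp / (self.tp + self.fp)

    @property
    def recall(self) -> float | None:
        return None if self.tp + self.fn == 0 else self.tp / (self.tp + self.fn)

    @property
    def f1(self) -> float | None:
        p, r = self.precision, self.recall
        if p is None or r is None:
            return None
        return 0.0 if p + r == 0 else 2 * p * r / (p + r)

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn,
                "precision": self.precision, "recall": self.recall,
                "f1": self.f1}


@dataclass(frozen=True)
class RecoveryReport:
    """Planted-network recovery at triple level and per edge layer."""

    triples: LevelReport
    circ_mir: LevelReport
    mir_mrna: LevelReport

    def to_dict(self) -> dict:
        return {"triples": self.triples.to_dict(),
                "circ_mir": self.circ_mir.to_dict(),
                "mir_mrna": self.mir_mrna.to_dict()}


def _score(inferred: frozenset, true: frozenset) -> LevelReport:
    tp = len(inferred & true)
    return LevelReport(tp=tp, fp=len(inferred) - tp, fn=len(true) - tp)


def evaluate_recovery(inferred: CeRNANetwork, gt: GroundTruth
                      ) -> RecoveryReport:
    """Score an inferred network against the planted ground truth."""
    return RecoveryReport(
        triples=_score(inferred.triple_keys, gt.true_triples),
        circ_mir=_score(inferred.circ_mir_edges, gt.true_circ_mir),
        mir_mrna=_score(inferred.mir_mrna_edges, gt.true_mir_mrna),
    )
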