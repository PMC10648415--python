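"""Stand-in differential-expression testing and shared statistics.

This module deliberately does NOT re-implement DESeq2 or limma-voom.  The
downstream cascade only consumes a regulation sign and a significance call
per feature, so the stand-in is a Welch (unequal-variance) t-test on log-CPM
values with Benjamini-Hochberg FDR, optionally preceded by per-batch mean
centering.  It is documented as non-equivalent to the negative-binomial /
moderated-variance models used on real cohorts.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .tabio import CountMatrix, DERecord, DETable, FormatError, Layer

__all__ = [
    "DesignInfo",
    "log_cpm",
    "two_group_de",
    "bh_adjust",
    "compare_groups",
]

_P_FLOOR = float(np.finfo(np.float64).tiny)


@dataclass(frozen=True)
class DesignInfo:
    """Two-group design with optional batch labels, one entry per sample."""

    groups: tuple[str, ...]
    batches: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        bad = sorted(set(self.groups) - {"case", "control"})
        if bad:
            raise FormatError(f"group labels outside {{case, control}}: {bad}")
        for label in ("case", "control"):
            if self.groups.count(label) < 2:
                raise FormatError(
                    f"group {label!r} has fewer than 2 samples; cannot test")
        if self.batches is not None and len(self.batches) != len(self.groups):
            raise FormatError("batch labels do not match sample count")

    @classmethod
    def from_matrix(cls, matrix: CountMatrix) -> "DesignInfo":
        return cls(groups=matrix.groups, batches=matrix.batches)

    @property
    def case_mask(self) -> np.ndarray:
        return np.array([g == "case" for g in self.groups])


def log_cpm(matrix: CountMatrix, pseudocount: float = 0.5) -> np.ndarray:
    """Log2 counts-per-million with a pseudocount.

    value = log2((count + pc) / (library_size + 2*pc) * 1e6), library size
    being the column total (for BSJ matrices: total BSJ reads per sample).
    A sample with zero total reads carries no information and is rejected.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    libsize = matrix.counts.sum(axis=0)
    zero = np.flatnonzero(libsize == 0)
    if zero.size:
        raise FormatError(
            f"sample {matrix.sample_ids[zero[0]]!r} has zero total counts")
    return np.log2((matrix.counts + pseudocount)
                   / (libsize + 2.0 * pseudocount) * 1e6)


def two_group_de(values: np.ndarray, design: DesignInfo,
                 feature_ids: Sequence[str], layer: Layer | str
                 ) -> DETable:
    """Per-feature case-vs-control Welch test on an already-log matrix.

    log2FC is mean(case) - mean(control); p is the two-sided Welch t
    p-value; padj is Benjamini-Hochberg over all features.  When batches
    are present each feature is batch-mean-centered first (sufficient for
    balanced designs; a simplification relative to covariate modelling).

    Degenerate features (zero variance in both groups) get p = 1 when the
    group means agree and the smallest positive float when they differ.
    """
    layer = Layer.coerce(layer)
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != len(feature_ids):
        raise ValueError("values must be features x samples matching feature_ids")
    if values.shape[1] != len(design.groups):
        raise ValueError("design does not match the number of samples")

    if design.batches is not None:
        values = values.copy()
        for batch in set(design.batches):
            cols = np.array([b == batch for b in design.batches])
            values[:, cols] -= values[:, cols].mean(axis=1, keepdims=True)

    case = values[:, design.case_mask]
    ctrl = values[:, ~design.case_mask]
    lfc = case.mean(axis=1) - ctrl.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _t, p = sps.ttest_ind(case, ctrl, axis=1, equal_var=False)
    p = np.asarray(p, dtype=float)
    degenerate = (case.var(axis=1) == 0) & (ctrl.var(axis=1) == 0)
    p[degenerate & (lfc == 0)] = 1.0
    p[degenerate & (lfc != 0)] = _P_FLOOR
    p = np.clip(np.nan_to_num(p, nan=1.0), _P_FLOOR, 1.0)
    padj = bh_adjust(p.tolist())
    records = tuple(
        DERecord(feature_id=str(fid), layer=layer, log2fc=float(l),
                 p=float(pv), padj=float(pa))
        for fid, l, pv, pa in zip(feature_ids, lfc, p, padj))
    return DETable(layer=layer, records=records)


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def compare_groups(values_a: Sequence[float], values_b: Sequence[float],
                   method: str = "t_test") -> tuple[float, float]:
    """Two-sided two-group comparison: Welch t-test or Mann-Whitney U.

    The Mann-Whitney p is exact for small tie-free samples and uses the
    tie-corrected normal approximation otherwise.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if method == "t_test":
        if a.size < 2 or b.size < 2:
            raise ValueError("t-test needs >= 2 values per group")
        if a.var() == 0 and b.var() == 0:
            return (0.0, 1.0) if a.mean() == b.mean() else (np.inf, _P_FLOOR)
        stat, p = sps.ttest_ind(a, b, equal_var=False)
    elif method == "mann_whitney":
        if a.size < 1 or b.size < 1:
            raise ValueError("Mann-Whitney needs >= 1 value per group")
        if np.unique(np.concatenate([a, b])).size == 1:
            return float(a.size * b.size / 2), 1.0  # everything tied
        ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
        mw_method = "auto" if ties else (
            "exact" if max(a.size, b.size) <= 10 else "auto")
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided",
                                   method=mw_method)
    else:
        raise ValueError(f"unknown method {method!r}; use 't_test' or "
                         "'mann_whitney'")
    return float(stat), float(min(p, 1.0))
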