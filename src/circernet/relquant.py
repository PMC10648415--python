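"""Relative quantification for the qPCR validation arm.

Classic ΔΔCt math with amplification efficiency fixed at 2: technical
replicates are collapsed by arithmetic mean of Ct, each sample's target Ct
is normalised against a reference gene (ΔCt), and log2 relative expression
is -(ΔCt - mean ΔCt of the control group), so the control group averages 0
by construction.  The same math serves case/control tissue comparisons,
circular-to-linear host-gene ratios, and pull-down enrichment against a
non-targeting control oligo.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .destats import compare_groups
from .tabio import CtTable, FormatError

__all__ = ["RelExprResult", "delta_delta_ct", "circ_linear_ratio",
           "pulldown_enrichment"]


@dataclass(frozen=True)
class RelExprResult:
    """Per-sample log2 relative expression for one gene (or ratio)."""

    gene_id: str
    sample_ids: tuple[str, ...]
    groups: tuple[str, ...]
    log2_rel_expr: tuple[float, ...]
    group_means: dict
    p: float
    method: str

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.log2_rel_expr)):
            raise ValueError(f"non-finite relative expression for {self.gene_id}")

    def values_for(self, group: str) -> list[float]:
        return [v for g, v in zip(self.groups, self.log2_rel_expr)
                if g == group]


def _per_sample_ct(ct: CtTable, gene: str) -> pd.DataFrame:
    means = ct.replicate_means()
    sub = means[means["gene_id"] == gene]
    if sub.empty:
        raise FormatError(f"gene {gene!r} absent from the Ct table")
    return sub.set_index("sample_id")


def delta_delta_ct(ct: CtTable, target: str, reference: str,
                   control_group: str, method: str = "t_test"
                   ) -> RelExprResult:
    """Per-sample log2 relative expression of ``target`` by ΔΔCt.

    ΔCt = Ct(target) - Ct(reference) per sample (replicates averaged first);
    log2 relative expression = -(ΔCt - mean ΔCt of ``control_group``).
    The comparison p-value contrasts the control group against the pooled
    remaining samples with the chosen two-sided test.
    """
    tgt = _per_sample_ct(ct, target)
    ref = _per_sample_ct(ct, reference)
    missing_ref = sorted(set(tgt.index) - set(ref.index))
    if missing_ref:
        raise FormatError(
            f"reference gene {reference!r} not measured in sample(s) "
            f"{missing_ref}")
    samples = list(tgt.index)
    groups = [str(tgt.loc[s, "group"]) for s in samples]
    if control_group not in groups:
        raise FormatError(f"control group {control_group!r} has no samples "
                          f"for gene {target!r}")
    dct = np.array([tgt.loc[s, "ct"] - ref.loc[s, "ct"] for s in samples])
    control_mask = np.array([g == control_group for g in groups])
    log2_rel = -(dct - dct[control_mask].mean())
    group_means = {g: float(log2_rel[[gg == g for gg in groups]].mean())
                   for g in sorted(set(groups))}
    other = log2_rel[~control_mask]
    if other.size >= 2 and control_mask.sum() >= 2:
        _stat, p = compare_groups(other, log2_rel[control_mask], method=method)
    else:
        p = float("nan")
    return RelExprResult(gene_id=target, sample_ids=tuple(samples),
                         groups=tuple(groups),
                         log2_rel_expr=tuple(float(v) for v in log2_rel),
                         group_means=group_means, p=float(p), method=method)


def circ_linear_ratio(circ: RelExprResult, lin: RelExprResult,
                      method: str | None = None) -> RelExprResult:
    """Per-sample circ-to-linear ratio on the log2 scale.

    ratio = circ.log2 - lin.log2 per sample; an increase means the circular
    form rises relative to its host linear transcript (host-independence of
    the circRNA's regulation).
    """
    if circ.sample_ids != lin.sample_ids or circ.groups != lin.groups:
        raise FormatError("circ and linear results cover different samples")
    method = method or circ.method
    values = np.array(circ.log2_rel_expr) - np.array(lin.log2_rel_expr)
    groups = circ.groups
    group_means = {g: float(values[[gg == g for gg in groups]].mean())
                   for g in sorted(set(groups))}
    # the control group is whichever group both inputs centre at 0
    zero_groups = [g for g, m in circ.group_means.items()
                   if abs(m) < 1e-9 and abs(lin.group_means.get(g, 1.0)) < 1e-9]
    control = zero_groups[0] if zero_groups else sorted(set(groups))[0]
    mask = np.array([g == control for g in groups])
    other = values[~mask]
    if other.size >= 2 and mask.sum() >= 2:
        _stat, p = compare_groups(other, values[mask], method=method)
    else:
        p = float("nan")
    return RelExprResult(gene_id=f"{circ.gene_id}/{lin.gene_id}",
                         sample_ids=circ.sample_ids, groups=groups,
                         log2_rel_expr=tuple(float(v) for v in values),
                         group_means=group_means, p=float(p), method=method)


def pulldown_enrichment(ct: CtTable, target: str, reference: str,
                        pulldown_group: str, negctr_group: str,
                        method: str = "t_test") -> RelExprResult:
    """Enrichment of ``target`` in a pull-down versus a non-targeting control.

    Identical math to :func:`delta_delta_ct` with the negative-control group
    as baseline: a positive mean log2 value in the pull-down group means the
    transcript is enriched by the capture.
    """
    present = set(ct.data["group"].unique())
    for g in (pulldown_group, negctr_group):
        if g not in present:
            raise FormatError(f"group {g!r} absent from the Ct table")
    return delta_delta_ct(ct, target=target, reference=reference,
                          control_group=negctr_group, method=method)
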