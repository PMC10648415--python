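"""Independent brute-force oracles.

These deliberately avoid the package's own code paths: plain loops, plain
arithmetic, exhaustive enumeration.  They exist to check the vectorised /
library-backed implementations on small instances.
"""
from itertools import combinations
from math import comb


def bh_oracle(pvalues):
    """Benjamini-Hochberg step-up: sort, scale, cumulative-min, unsort."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [None] * m
    running_min = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        scaled = pvalues[i] * m / rank_from_end
        running_min = min(running_min, scaled)
        adjusted[i] = min(1.0, running_min)
    return adjusted


def hypergeom_tail_enum(k, K, n, N):
    """P(X >= k) by explicit enumeration of all C(N, n) draws."""
    total = 0
    hits = 0
    items = list(range(N))
    marked = set(range(K))
    for draw in combinations(items, n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


def hypergeom_tail_comb(k, K, n, N):
    """P(X >= k) by summing counting ratios with exact integer combinatorics."""
    numerator = sum(comb(K, j) * comb(N - K, n - j)
                    for j in range(k, min(K, n) + 1) if n - j <= N - K)
    return numerator / comb(N, n)


def mannwhitney_exact_oracle(a, b):
    """Two-sided exact Mann-Whitney p by enumeration of label assignments.

    Tie-free inputs only.  Matches the convention of doubling the smaller
    tail including the observed statistic.
    """
    pooled = list(a) + list(b)
    na = len(a)
    u_obs = sum(1 for x in a for y in b if x > y)
    total = 0
    count_ge = 0
    count_le = 0
    for idx in combinations(range(len(pooled)), na):
        grp_a = [pooled[i] for i in idx]
        grp_b = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        u = sum(1 for x in grp_a for y in grp_b if x > y)
        total += 1
        count_ge += u >= u_obs
        count_le += u <= u_obs
    return min(1.0, 2 * min(count_ge, count_le) / total)


def cascade_oracle(circ_rows, mirna_rows, mrna_rows, cm_edges, mm_edges, cfg):
    """Joint enumeration of all (circ, miR, mRNA) combinations.

    rows: dicts feature -> (log2fc, p, padj); cm_edges: set of (circ, mir);
    mm_edges: dict (mir, gene) -> (resource_count, confidence_rank with
    high=2, very_high=3).  Applies every cascade predicate at once and
    returns the surviving triple keys.
    """
    conf_rank_min = int(cfg.mm_min_confidence)
    triples = set()
    for c, (c_lfc, c_p, _c_padj) in circ_rows.items():
        for m, (m_lfc, _m_p, m_padj) in mirna_rows.items():
            for g, (g_lfc, _g_p, g_padj) in mrna_rows.items():
                if (c, m) not in cm_edges:
                    continue
                if (m, g) not in mm_edges:
                    continue
                rc, conf = mm_edges[(m, g)]
                if rc < cfg.mm_min_resources or conf < conf_rank_min:
                    continue
                if not (c_p < cfg.circ_p_max
                        and abs(c_lfc) >= cfg.circ_abs_lfc_min):
                    continue
                if not (m_padj < cfg.mirna_padj_max):
                    continue
                if not (g_padj < cfg.mrna_padj_max):
                    continue
                if c_lfc == 0 or m_lfc == 0 or g_lfc == 0:
                    continue
                sc = 1 if c_lfc > 0 else -1
                sm = 1 if m_lfc > 0 else -1
                sg = 1 if g_lfc > 0 else -1
                if sc == -sm and sg == -sm:
                    triples.add((c, m, g))
    return triples
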