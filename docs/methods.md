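# Methods

## The model

circernet infers circRNA-centered competing-endogenous-RNA (ceRNA) networks
from a two-group (case vs. control) transcriptomic contrast. The underlying
model is the sponge hypothesis: a circRNA carrying miRNA response elements
sequesters that miRNA, de-repressing the miRNA's mRNA targets. In a
differential-expression contrast a functional sponge triple
(circRNA, miRNA, mRNA) should therefore be *counter-regulated* along both
edges — sign(circRNA) = −sign(miRNA) and sign(miRNA) = −sign(mRNA), which
forces the circRNA and the de-repressed mRNA to move together.

The inference is a deterministic filter cascade over set-valued inputs:

1. **Abundance filter** (circRNA layer): a back-splice junction (BSJ) is
   kept when at least `ceil(frac · n_samples)` samples show at least
   `min_reads` reads. Defaults: 5 reads in at least 50% of samples, with
   ceiling semantics ("at least half" of 39 samples means 20).
2. **DE gates** per layer: mRNA — BH-adjusted p < 0.01, no fold-change
   gate; circRNA — canonical p < 0.05 *and* |log2FC| ≥ 1; miRNA — adjusted
   p < 0.05, falling back to the raw p when the table carries no adjusted
   values. Features with log2FC = 0 are never retained. All cut-offs sit in
   a single `ThresholdConfig` and tightening any of them can only shrink
   the final network (tested property).
3. **Prediction merging**: circRNA→miRNA predictions from several
   databases are combined by *union* with provenance preserved —
   a pair predicted by any source qualifies; queried circRNAs matched by
   no source are listed in a coverage report. miRNA→mRNA predictions are
   gated on aggregate provenance: ≥ 5 supporting resources at
   confidence ≥ high (ordered enum low < medium < high < very_high).
4. **Counter-regulation (inverse-modulation) filter** on each edge layer:
   an edge survives only when both endpoints are differentially expressed
   with opposite signs. Edges with two same-sign DE endpoints are counted
   separately as *concordant* (the class whose rarity supports the sponge
   assumption); edges with a non-DE endpoint are counted as such.
5. **Assembly**: the network is the relational join of the two surviving
   edge layers on the shared miRNA — triples {(c,m,g) : (c,m) retained and
   (m,g) retained}. Every triple is re-checked against the sign invariant;
   a violation is a programming error, not data. miRNAs without surviving
   targets drop out of the node tables.
6. **Summary and hubs**: per-circRNA miRNA lists and interaction counts
   (conserved: the counts sum to the triple total), distinct node counts
   per layer, and hub ranking by miRNA degree, then interaction count,
   then identifier. Interaction totals and distinct-mRNA counts are
   reported separately because one mRNA can be targeted by several miRNAs.

miRNA identifiers are case-folded before any join (databases mix
`let-7`/`miR` capitalisation); the original spelling is kept for display.
Genomic coordinates are stored 0-based half-open; the textual
`chrom:start-end:strand` form is read as 1-based inclusive and converted.
Strand is never used for matching — identifiers match by string.

## The differential-expression stand-in

Published cohort analyses of this kind use DESeq2 (genes) and limma-voom
(BSJ counts). The cascade consumes only a sign and a significance call per
feature, so `destats` deliberately substitutes a transparent stand-in:
log2 CPM with pseudocount 0.5 (`log2((c + 0.5)/(lib + 1) · 1e6)`), a
two-sided Welch t-test per feature, and Benjamini–Hochberg FDR. It is
*not* equivalent to the negative-binomial or moderated-variance models and
is documented as such; on real cohorts users should import externally
computed DE tables instead. Degenerate features (zero variance in both
groups) get p = 1 when group means agree and the smallest positive float
when they differ, keeping behaviour deterministic.

Batch handling is per-batch mean-centering before testing — sufficient for
batches balanced across groups (which the simulator guarantees), and a
simplification relative to including batch covariates in the model. Under
the global null the stand-in's type-I error is calibrated (rejection
fraction ≈ 0.05 at α = 0.05 over 2,500 null features; asserted in the
acceptance suite within [0.03, 0.07]).

Group comparisons for the qPCR arm use the two-sided Welch t-test or the
Mann–Whitney U test; the latter is exact for small tie-free samples and
uses the tie-corrected normal approximation otherwise.

## Over-representation analysis

`enrich` is a plain one-sided hypergeometric tail test per gene set, summed
in log space, with BH FDR across tested terms and fold enrichment
(k/n)/(K/N). The universe defaults to the expressed genes of the
experiment, never the whole genome; no annotation databases are bundled and
no identifier mapping is attempted. Because the hypergeometric tail is
discrete, its p-values are super-uniform: the null rejection fraction at
0.05 is slightly *below* nominal (≈ 0.03–0.04 in the calibration runs),
which is the expected conservative behaviour, not an error.

## Relative quantification (ΔΔCt)

Classic ΔΔCt with amplification efficiency fixed at 2 and no
standard-curve correction: technical replicates are collapsed by
arithmetic mean of Ct; ΔCt = Ct(target) − Ct(reference) per sample; the
per-sample log2 relative expression is −(ΔCt − mean ΔCt of the control
group), so the control group is centred at 0 by construction. The same
math serves tissue contrasts, pull-down enrichment against a non-targeting
control oligo, and the circ-to-linear ratio, which is the per-sample
difference of the circular and host-linear log2 values (an increase means
the circular form moves independently of its host gene). The reference
gene is user-specified — there is no default housekeeping gene. Results
are shift-invariant under adding a constant to all Ct values of a sample.

## The synthetic cohort

`simdata` generates every input the pipeline consumes, as a pure function
of (parameters, seed); each table draws from its own child stream so any
one table can be regenerated in isolation.

**Planted structure.** Signs (+1/−1/0) are assigned per layer
(`de_fraction`, default 0.7, of the network-candidate nodes are DE), and
`planted_triples` sign-consistent triples are planted with each miRNA
sponged by exactly one circRNA. That restriction makes the planted set
closed under the relational product of its two edge layers — the only
shape a join on the shared miRNA can recover exactly, and the shape the
published five-circRNA sponge table itself has (each miRNA listed under
one circRNA). Infeasible requests fail with the feasibility bound.

**Counts.** mRNA and circRNA layers are negative-binomial
(var = μ + φμ², φ = `nb_dispersion`, default 0.1; φ → 0 degrades to
Poisson) around `baseline_mean` (default 100), with the case-group mean
multiplied by `2^(sign · lfc_magnitude)` (default effect |log2FC| = 2) and
a N(0, `batch_sd`) offset per (feature, batch) on the log2 mean (default
0.25). Samples: 20 per group in 3 batches, batches balanced across groups.
The miRNA layer is emitted directly as a DE table — mirroring a design
where miRNA profiling comes from a separate dataset — with planted signs,
near-zero p for DE miRNAs and null statistics otherwise.

**Background features.** Each count layer carries non-DE background
features outside the network (defaults 400 mRNA, 200 circRNA junctions, a
quarter of the latter near the detection floor so the abundance filter has
real work). This is not cosmetic: real count matrices are dominated by
unchanged features, and with total-count CPM normalisation that stable
mass is what keeps library sizes comparable between groups. Without it,
planting strong fold changes on most features shifts every library and
null features masquerade as regulated (a composition artefact that
median-of-ratios normalisations are designed to absorb).

**Decoys.** Three labelled classes, each probing exactly one filter and
never duplicating true edges: *concordant* circRNA–miRNA pairs (same-sign
DE endpoints; only the counter-regulation filter can drop them), *non-DE*
miRNA–mRNA edges (one endpoint not DE; passing provenance), and
*low-resource* miRNA–mRNA edges (counter-regulated DE endpoints but only
1–4 supporting resources). `true_edge_pass_rate` controls the sensitivity
of the simulated prediction databases (default 1.0).

**Ct tables.** Gene-wise baseline cycles are drawn uniformly in [20, 26];
the case group's Ct is shifted by −planted_log2FC (one cycle per doubling)
with N(0, `noise_sd`) per replicate (3 replicates/sample). At zero noise
the ΔΔCt pipeline recovers planted fold changes exactly (asserted).

**Recovery scoring.** Precision/recall/F1 at triple level and per edge
layer. Precision is `null` when nothing was predicted and recall `null`
when the true set is empty — never a silent 0/0.

**What passing the synthetic suite does and does not show.** The recovery
anchor (precision = recall = 1 with all true edges predicted, no decoys,
dispersion 0.05, |log2FC| = 2, 20 samples/group) demonstrates the cascade's
logic is exact, not that real cohorts behave this way: real data have
incomplete and biased prediction databases, effect sizes far below 2 log2
units, unbalanced batches, and DE tools with their own error profiles.
The simulator also does not model read-level noise, isoform ambiguity of
back-splice junctions, or correlated expression between features.

## Problem sizes and numerical choices

Default study conditions (20+20 samples, ~660 count features, 30 planted
triples) run the full pipeline in about a second; the acceptance script's
calibration runs use 2,500 null features and 3,000 null enrichment tests.
Ties in hub ranking break by identifier; sample-fraction thresholds round
by ceiling after guarding against floating-point dust (`round(·, 9)`);
p-values are floored at the smallest positive double rather than 0 so
downstream log transforms stay finite.

## Known limitations

* The DE stand-in is not DESeq2/voom; its log2FC estimates carry the
  composition bias of total-count normalisation when many features change.
* Union merging of prediction databases maximises sensitivity and
  inherits every source's false positives; provenance is preserved so
  stricter per-source policies can be applied downstream.
* ORA assumes an unstructured universe (no gene-length or expression bias
  correction) and one-sided over-representation only.
* ΔΔCt assumes perfect doubling per cycle; no efficiency calibration.
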