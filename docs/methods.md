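# Methods

## Data model and conventions

A *chiasma record* is one scored chiasma: sample, cell, bivalent, arm
(1 or 2), and relative position `rel_pos ∈ [0, 1]` along the arm.
Positions are measured from the centromere (0) toward the telomere (1);
this orientation is a package convention, chosen because "proximal" is
defined relative to the centromere. Univalent pairs carry no chiasma
records — they appear only in the bivalent table with
`chiasma_count = 0` — so positional percentages run over chiasmata while
per-cell frequencies still see every scored cell. Bivalents with more
than two arms (trivalents, which occur rarely in triploid material) are
out of scope and rejected at validation.

All tables are UTF-8 TSV with fixed headers; floats are written with
full `repr` precision so write→read round-trips are bit-exact.

## Regional classification

Each arm is divided into three regions of equal length. The intervals
are half-open — proximal `[0, lower)`, interstitial `[lower, upper)`,
distal `[upper, 1]`, defaults `lower = 1/3`, `upper = 2/3` — making the
partition total and order-independent; boundary handling is a package
decision (the convention at exact cut points is not determined by the
counts being reproduced, which never fall on a boundary). Display
percentages and means are rounded half-up to one decimal; exact values
are kept on the summary objects. Two printed one-decimal cells in the
source material are arithmetically inconsistent with their own counts
(18/1033 = 1.74 % prints as 1.8; 48/419 = 11.46 % prints as 11.4); the
package reports the arithmetically correct 1.7 and 11.5.

Bivalent configuration follows metaphase-I morphology: *ring* (≥ 1
chiasma on each arm), *open* (all chiasmata on one arm),
*univalent_pair* (none). Finer cytological types are surfaced as a
region-annotation string (e.g. `ring: distal+distal`); a ring whose
chiasmata are all proximal is annotated `cross:` (cross-bivalent
morphology) rather than made a separate class, because the published
type names come without quantitative criteria.

## Contingency statistics

Pearson's χ² is computed from the explicit expected matrix with no
continuity correction; Cramér's V is the uncorrected
`sqrt(chi2 / (n min(r−1, c−1)))`. No bias-corrected V and no Yates
correction: the reproducible published pairwise values (0.95, 0.87,
0.34) recompute exactly under the plain formulas only. Pairwise
comparisons test each unordered sample pair on its own 2×c sub-table;
columns empty in both rows are dropped and flagged; Bonferroni uses
m = number of pairs actually tested (6 for four samples). The published
overall statistic (χ² = 1966.4, V = 0.62) and the three pairwise values
involving the triploid (0.72, 0.49, 0.24) do *not* recompute from the
published regional counts (this package obtains 1909.7 / 0.61 and
0.65 / 0.54 / 0.32); the underlying triploid counts evidently differed
from the printed table. These values are documented here and are not
asserted anywhere.

p-values are kept at full precision internally; text output floors the
display at `< 1e-300`.

## Focus-count statistics

Per-sample marker means are `total signals / total cells` per marker;
the class I share is the MLH1 percentage of the combined per-cell mean,
rounded to integer percent (display mirrors the published table:
means to one decimal, shares as integers).

Because the two markers are scored on different slides, the per-cell
ratio is estimated on the *artificial population*: all
`n_MLH1 × n_MUS81` cell pairs, each contributing
`r = MLH1 count / MUS81 count`. Pairs with a zero denominator are
excluded and tallied, never imputed. The default estimator is the
weighted mean with inverse weights `w = 1/r` — algebraically the
harmonic mean — which damps pairs with extreme large ratios; zero
ratios receive the weight floor `ε = 1e−9`. An
inverse-absolute-deviation scheme (`w = 1/(|r − median| + ε)`) and the
unweighted mean are provided as sensitivity alternatives. The
slide-consistency diagnostic checks that the ratio of slide means falls
inside the central 95 % percentile interval of the pair ratios; a
percentile-containment rule was chosen because no specific test is
named for this comparison in the source material.

Group comparisons are two-sided Wilcoxon rank-sum (Mann–Whitney) tests
— independent groups, since cells come from distinct slides and
species. The exact enumeration null is used when the combined size is
≤ 12 with no ties; otherwise the normal approximation with tie and
continuity corrections (both via `scipy.stats.mannwhitneyu`). Families
of comparisons are adjusted with Benjamini–Hochberg FDR
(`statsmodels`).

## Synthetic PMC generator

The generator emulates what the analysis consumes, not meiosis itself:

* **Chiasma counts.** Per bivalent: with probability `univalent_rate`
  the pair is a univalent pair (0 chiasmata); otherwise k ≥ 1 is drawn
  from a zero-truncated Poisson(λ) — the simplest count model honouring
  the obligate-crossover rule. λ is invertible from a target mean per
  paired bivalent via `λ/(1−e^{−λ})`.
* **Positions.** Arms are assigned uniformly (no arm-length data is
  modelled); positions are Beta(α, β) on [0, 1]. Region probabilities
  are analytic in the Beta CDF, so presets are calibrated by
  Nelder–Mead on (log α, log β) against a target regional triple
  (residual tolerance 1e−4).
* **Interference.** An optional hard-core rule redraws an arm's
  positions until all pairwise distances reach `d` (≤ 100 attempts,
  then the best draw is kept and the bivalent flagged
  `interference_unmet`). A configuration whose count cannot fit
  (`(k−1)·d ≥ 1`) raises. This rejection scheme is adequate at ≤ 3
  chiasmata per arm; a gamma-renewal interference process is a
  non-goal.
* **Foci.** Independent Poisson counts per marker on two synthetic
  slides, mirroring the separate-slide design.

All draws come from one `numpy.random.Generator` seeded from the config
(the focus stream uses seed + 1 so focus and chiasma draws do not
interleave), giving byte-identical files for identical configs.

Preset parameters derive from the published marginals: Beta shapes from
the regional count proportions, λ from chiasmata per scored bivalent,
univalent rate from the shortfall of scored bivalents against 8 per
cell (0 for *A. cepa*, ≈ 0.011 for *A. fistulosum*, ≈ 0.114 for the F1
diploid, ≈ 0.004 for the triploid), focus λs from per-marker per-cell
means, and cell numbers from the cells scored (54/43/35/29). These are
*emulation targets*, not inferred parameters — the source material
reports no per-bivalent count distribution or univalent rate — so
passing recovery tests shows the pipeline is self-consistent, not that
real PMC data follow these distributions. Real data differ in known
ways the generator ignores: unequal arm lengths, chromosome-size
effects on chiasma number, genuine interference structure, and
non-Poisson overdispersion of focus counts.

## Transcript identity

The longest ATG…stop ORF is searched in the three forward frames
(transcripts are assumed sense-strand; a `both_strands` flag adds the
reverse complement). ORFs must terminate at an in-sequence stop codon;
ties break to the smallest start. Translation uses the standard code;
`N` in a codon yields `X`. Equal-length proteins are compared position
by position — this reproduces the published equal-length identity
fractions (e.g. 724/725) — while unequal lengths fall back to global
alignment (match +1, mismatch 0, linear gap −1) with identity over the
alignment length. Published domain-level identities require domain
coordinates that were not printed; `pairwise_identity` accepts any
sub-sequences, so users with coordinates can reproduce them, but none
are bundled. The GenBank transcripts themselves are not redistributed;
tests exercise the module on synthetic transcript pairs constructed to
the same lengths and polymorphism counts.

## Problem sizes and numerical choices

The simulator-based checks use 150–200 cells per sample (≈ 1 200–1 600
bivalents), enough to pin regional shares within ±3 percentage points;
Monte Carlo distributional checks use 10⁴–10⁵ draws with 3σ tolerances.
Beta calibration runs from six starts to avoid the α↔β reflection
ambiguity trapping the search in the wrong skew. Degenerate inputs
(empty groups, zero marginals, all-excluded ratio pairs, missing
markers) raise with messages naming the offending row, column, marker
or sample; a sample missing one marker is flagged and skipped rather
than fatal in the model-level analysis.
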