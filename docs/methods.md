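# Methods

`xgage` implements a cross-species gene-set enrichment meta-comparison for
plant responses to insect egg deposition (E), larval feeding (F) and their
combination (EF), each against untreated controls (C). The pipeline has
four stages — signal preprocessing, homology-based GO annotation transfer,
a GAGE-style enrichment statistic, and a k-of-n meta-classification — plus
a synthetic-data generator that provides a ground truth for every stage.

## Signal preprocessing

Input is a probes × samples matrix of positive one-colour intensities with
structural dark-corner control spots per array.

1. **Detection filter.** The detection threshold of each array is
   `detect_factor` × the `detect_quantile` quantile of its control spots
   (defaults 1.5 × Q90; quantiles by linear interpolation of order
   statistics, the "type 7" convention). A probe is removed when it falls
   below threshold in *every* sample of at least one treatment; control
   spots never enter the analysis matrix.
2. **Background correction.** Per array, the median control-spot signal is
   subtracted and results are floored at `background_offset` (default 0.5)
   so log transforms stay finite. This is a deliberate simplification of a
   normexp-style model: it preserves within-array ordering exactly, and
   downstream statistics act on fold changes, where an additive background
   error is second-order. A plug-in corrector callable is accepted for
   users who want a parametric background fit.
3. **Quantile normalisation** across arrays (each column's order statistics
   replaced by the row means of the column-sorted matrix); idempotent and
   rank-preserving.
4. **Probe averaging** by gene identifier (arithmetic mean; unmapped probes
   dropped).
5. **Variance filter.** Per gene, the coefficient of variation (sd/mean
   across all samples) is computed and the top `keep_fraction` (default
   40 %) most variable genes are retained; ties break lexicographically by
   gene id so runs are reproducible.

Pre-normalised matrices (e.g. RNA-seq) enter the chain at step 4
(`skip_array_steps=True`).

## Annotation transfer

Species without curated GO annotation inherit terms through BLAST best
hits: per query, the hit with the smallest E-value (ties: highest bit
score, then smallest subject id) wins, subject to E ≤ 1e-5. A gene takes
its primary-reference homologue's terms; failing that, its
secondary-reference homologue's; otherwise it stays unannotated, so no gene
ever mixes the two sources. Terms outside the `biological_process`
namespace are dropped, the full ancestral closure over `is_a` and `part_of`
edges is applied (both relations by default; configurable), and — after
closure — terms absent from the primary reference's own closed vocabulary
are removed so all species share one comparable term universe. Note the
consequence: a secondary-specific term is itself removed but its shared
ancestors survive.

Gene sets are the measured genes annotated to each term, retained only at
sizes 3–1500: below three genes a set carries no testable signal, above
1500 it is an uninformative catch-all. Because membership is intersected
with the genes measured in each dataset, the same term may have different
sizes — or fail the size bound — per species and time point.

## Enrichment statistic

For a contrast (say E vs C), per-gene log2 fold changes are formed
one-on-one for every (treatment sample, reference sample) combination; in
block-paired designs, one column per block (treatment minus reference
within the block), which cancels block-level shifts exactly.

Per fold-change column, each gene set is compared against the *all-gene*
background with a Welch two-sample t statistic (Welch–Satterthwaite
degrees of freedom). The background deliberately includes the set; the
complement background is available as a switch. Upper- and lower-tail
p-values give separate up- and down-regulation tests, clamped to
[1e-15, 1 − 1e-15] before the normal quantile transform.

Evidence is combined across columns with Stouffer's method,
z = Σ zᵢ / √k with zᵢ = Φ⁻¹(1 − pᵢ). One-on-one columns from the same
replicates are not independent: columns sharing a treatment (or reference)
sample have null correlation 1/2, so the z-sum of a 3 × 3 design has null
variance 27, not 9, and plain 1/√k scaling inflates the false-positive
rate to roughly 0.17 at nominal 0.05. `run_gage` therefore standardises
the z-sum by its exact design-implied null variance
(k + 2 Σ ρ, with ρ read off the shared-sample structure) by default; for
paired or otherwise disjoint columns this reduces to the classic 1/√k. The
unadjusted behaviour remains available (`correlation_adjust=False`), and
the standalone `stouffer_combine` is the textbook formula.

Benjamini–Hochberg FDR is applied across gene sets, separately per
direction and per contrast within each dataset, matching the way
per-column FDR values are reported. The whole statistic is antisymmetric:
negating every fold change swaps the up and down tables bitwise.

## Meta-classification

Across combinations (species–insect pairs, possibly with several harvest
time points), the analysis is restricted to the **common universe**: terms
with a result row in every combination and every time point. A term is
significant in a combination when FDR < α (strict; α = 0.05) — for
multi-time-point combinations under `timepoint_mode="any"` (default) one
significant time point suffices; the stricter "all" mode is exposed
because either reading is defensible for the conformability step. A term
is **conformable** when significant in ≥ k of n combinations (3 of 4 for
the egg contrast, 4 of 5 for feeding in the emulated study). The
**analogous** response is the intersection of the E-vs-C and F-vs-C
conformable sets; the **enhanced core** additionally requires
conformability in EF vs F. Multi-time-point combinations contribute one
vote, not one per time point. Percentages are integer-rounded (half away
from zero). Up and down classifications are fully independent; a term may
be conformably up in one contrast and down in another.

## Synthetic data generator

The generator emulates the study layout rather than any real organism:

- a rooted random GO-like DAG (default 800 shared terms plus 10
  secondary-only terms that never occur in the primary reference — these
  exercise the vocabulary-comparability rule), each non-root term with 1–3
  parents;
- a primary reference of 4000 genes, each directly annotated with 1–3
  non-root terms (ancestors arrive via closure), and a parallel secondary
  reference that mirrors it with occasional secondary-only terms;
- four species whose genes map one-to-one to reference genes; 90 % get a
  true best hit (E ≤ 1e-6) plus up to two decoy hits with strictly worse
  E-values, the rest may get a secondary hit (50 %) and/or a sub-threshold
  primary hit that the E-value ceiling must reject;
- log-normal intensities: log2 signal = gene baseline N(8, 1.5) +
  treatment effect + block shift (for the one block-paired combination,
  emulating a three-replicate paired design) + N(0, noise_sd); control
  spots from N(4, 0.5) on the log2 scale sit well below gene signals; 2 %
  of probes are forced below the detection threshold in all samples of one
  treatment (dropout);
- planted effects per contrast: E-planted terms shift the E arm, F-planted
  terms shift F *and* EF (feeding damage is present in both), EF-vs-F-
  planted terms shift only EF (the egg-primed amplification). Opposite-
  direction planted groups must be gene-disjoint (`member_disjoint_from`
  in `sample_planted_terms`), otherwise their shifts cancel and the ground
  truth is incoherent.

Defaults: `effect_size=2.0` (log2), `noise_sd=0.25`, three replicates per
arm, full C/E/F/EF factorial. The source study does not report its noise
magnitudes, so these are chosen as a realistic-but-testable operating
point and fixed. Every artifact draws from its own random stream keyed on
(master seed, artifact id), so adding a species is guaranteed not to
perturb another species' data, and identical configurations are
bit-identical.

What the generator does **not** emulate: sequence-level data, RNA-seq
count noise (a log-normal matrix stands in), probe-level spatial
artifacts, cross-hybridisation, and correlated co-expression beyond the
planted effects. Passing tests therefore demonstrate the pipeline's rules
and statistics are implemented correctly and calibrated under the stated
noise model — not that the biological conclusions of any real dataset
would be reproduced.

## Numerical choices and degenerate inputs

- Zero variance in both set and background: t = 0, both one-sided p = 0.5.
- CV of an all-zero gene is defined as 0 (cannot occur after flooring).
- p-value clamp 1e-15 avoids infinite normal quantiles while preserving
  order.
- Best-hit, variance-filter and planted-term sampling tie-breaks are all
  lexicographic, making every output deterministic.
- BH adjustment delegates to statsmodels (`fdr_bh`); Stouffer, the Welch
  set-vs-background statistic and its correlation adjustment are
  implemented here and cross-checked in tests against scipy's independent
  routines and against gene-label permutation.

## Problem sizes

Tests and the acceptance script run four-combination studies with 4000
reference genes (8000 probes), 800 GO terms and three replicates per arm —
roughly 700 gene sets per combination after filtering. This desk-scale
operating point keeps a full study run under half a minute while leaving
every rule (detection, size bounds, universes, k-of-n) with non-trivial
work to do.

## Known limitations

- The median-control-spot background correction is cruder than a
  parametric normexp fit; with strongly varying true backgrounds the
  plug-in corrector should be used.
- The correlation adjustment assumes equal noise variance across samples
  within a contrast's arms when deriving ρ = 1/2 for sample-sharing
  columns; grossly heteroscedastic arrays would make it approximate.
- Null p-values of overlapping (closure-related) gene sets are mutually
  dependent; families of such sets can deviate jointly even though each
  set's marginal test is calibrated, which is why conformability across
  independent combinations — not single-dataset significance — is the
  unit of inference.
- The functional grouping of gene sets into named categories is accepted
  only as a user-supplied table; it is not computed.
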