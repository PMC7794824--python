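# Methods

This note documents the models, parameter choices and numerical conventions
behind `mimscout`, and what its synthetic benchmarks do and do not establish
about real data.

## The motif and its patterns

The MYC-interaction motif (MIM) is a six-residue short linear motif (SLiM),
`[L/F] L N [K/R] [V/L] A`, whose core positions — L, N and A at motif
positions 2, 3 and 6 — are individually required for binding to MYC
transcription factors. Three built-in degenerate patterns express decreasing
stringency:

| name     | pattern                 | intent                                |
|----------|-------------------------|---------------------------------------|
| `core`   | `xLNxxA`                | required positions only               |
| `strict` | `[LF]LN[KR][VL]A`       | the full consensus                    |
| `phi`    | `[LVFI]LN[KR][IFLV]A`   | relaxed similarity-search tolerance   |

Scanning is exact: a window matches iff every residue lies in the
corresponding allowed set. All windows are reported, including overlapping
ones, because real proteins can carry several motif instances. Masked (`X`)
residues — produced by the opt-in `mask` input policy for non-canonical
letters — never match any position, including wildcards, so corrupted input
can suppress but never fabricate a hit. Coordinates are 1-based and
inclusive throughout files and reports.

## Profile search and empirical significance

A seed alignment collects ungapped motif-region windows (motif plus `flank`
residues on each side, `flank` in 0–20). Windows truncated by a sequence
terminus are padded with a neutral symbol. Column probabilities are

    p_c(a) = (count_c(a) + pad_c * q(a) + alpha * q(a)) / (n + alpha)

where `q` is the background (by default the database's own residue
frequencies, add-one smoothed; a uniform background is available), `alpha`
the pseudocount (default 0.5, Jeffreys-style), and each neutral pad
contributes the background vector to its column — this keeps every column a
proper distribution and makes padded columns uninformative, and it reduces to
the plain pseudocount formula for unpadded seeds. Scores are
`sum_c log2(p_c(a_c)/q(a_c))` in bits; the neutral symbol scores 0 bits.

Significance is empirical, not Karlin–Altschul analytic (re-deriving that
calibration is out of scope here). The null is the score distribution over
windows of per-sequence Fisher–Yates shuffles of the (taxonomy-filtered)
database itself, at least 100,000 windows by default, generated once per
search from the caller's RNG seed and re-scored under each iteration's
profile so rounds are comparable. The p-value of score `s` is the empirical
exceedance fraction below the null's 99th percentile and, beyond it, an
exponential tail `0.01 * exp(-(s - s99)/beta)` with `beta` the mean excess of
the top 1% of null scores — a conservative (heavier-than-Gaussian) tail that
still lets genuinely extreme scores reach small p-values. E-value =
`N_windows * p`. E-values are non-increasing in score by construction.

Iteration appends the hit windows to the seed, re-estimates the profile and
re-searches, stopping when the hit set is unchanged or after
`max_iterations` (default 5). Hit sets are not guaranteed to grow
monotonically — a sharpened profile may drop borderline windows — so only
termination is guaranteed. The default E-value cutoff of 1e-3 is a package
choice (the underlying analysis reports only "significant hits") and is
exposed as a flag, as are the pseudocount and background.

## Context signature

Composition tracks follow the sliding-window profiler convention: the value
at a position is `(count(plus) - count(minus)) / covered` over a centered
window (default 15 residues); at the termini the window truncates and the
denominator is the covered length (the original tool's terminus convention is
not published; this one keeps values in [-1, 1] everywhere). Two standard
tracks are `+RK-DE` (net positive charge) and `+PST-RK` (small hydrophilic
bias).

Disorder is approximated by a composition proxy: the window mean of the
TOP-IDP per-residue disorder propensity scale, min-max rescaled to [0, 1].
This is a deliberate, documented stand-in for sequence-specific disorder
predictors (IUPred-class tools), good enough to separate strongly
order-biased from disorder-biased segments; it carries no positional model
and should not be read as a per-residue disorder probability.

The three-feature call for a motif hit:

1. **local-order dip within an IDR** — the proxy averaged over the hit span
   must lie at least `dip_depth` (default 0.05) below its mean over the
   surrounding ±25 residues, *and* the hit must sit inside a maximal run of
   proxy ≥ 0.5 of length ≥ 30;
2. **net positive charge** — mean `+RK-DE` over the span ±5 residues > 0;
3. **flank bias** — mean `+PST-RK` over the two 15-residue flanks > 0.

The dip is evaluated on a short-window proxy (default window 7, comparable
to the motif length) while the IDR run uses the broad window (default 21).
A single broad window cannot resolve a 6-residue ordered island: smoothing
spreads the motif's signal into the surround and caps the measurable depth
near the threshold itself, so the dip would become a coin flip. Separating
the two length scales is the package's design choice. All thresholds are
package defaults exposed in configuration; the source analysis describes the
features only qualitatively. Hits closer than a flank width to a terminus
are evaluated on the residues available and flagged `truncated`.

## Conservation contrast

Column conservation uses the strict >50% rule: a consensus exists only when
one residue occupies strictly more than half of the non-gap entries (3/6 does
not qualify). `identity_fraction` is the plurality share and is defined for
every column; similarity uses a standard physicochemical partition
(`AVLIM, FWY, ST, KR, DE, NQ, C, G, P, H`), configurable because shading
tools do not publish their grouping.

The contrast statistic is `mean identity(motif columns) − mean identity
(flank columns)`; identity rather than similarity feeds it because the
motif's core positions are defined by identity. Significance comes from
permuting the motif/flank labels over the pooled columns (default 1000
permutations, seeded), with the +1 correction so p is never exactly 0. Under
an exchangeable null the p-value is super-uniform. No phylogenetic
correction is applied: the statistic treats columns, not taxa, as the unit,
and the synthetic benchmark matches that assumption.

## Helicity from secondary chemical shifts

Secondary chemical shift: `SCS = observed Cα − random-coil(sequence, T, pH)`.
The packaged random-coil model has per-residue base shifts in the magnitude
range of the standard sequence-corrected IDP reference sets, additive
neighbor corrections at offsets −2..+2 (parameterizing mainly the strong
effect of a following proline), a uniform small temperature coefficient
(−0.0015 ppm/°C from a 25 °C reference) and a Henderson–Hasselbalch pH
correction for D, E, H and C (relative to pH 7.0). Synthetic shift tables
are generated from this same model, so all round-trip and recovery tests are
independent of which published table edition the base values follow; only
analyses of *real* shift tables would inherit the table's absolute accuracy.

Residues with SCS > 0.1 ppm are called transiently helical. Fractional
helicity is the peak SCS divided by a full-helix delta of 3.0 ppm, clamped to
[0, 1]; 3.0 ppm is the constant that reproduces both printed anchor pairs
(0.75 ppm → 25%, 0.36 ppm → 12%) exactly, and sits in the conventional
3–3.1 ppm range for a fully formed helix. The peak (not the segment mean)
is used because the anchors are phrased in terms of the highest SCS value; a
segment-mean estimator is available behind a flag. Negative SCS is reported
but never converted to a strand fraction. Shift-table conditions default to
5 °C and pH 7.0, the acquisition conditions of the motif peptides.

## Synthetic data

`make_proteome` builds records as an 80-residue order-biased segment followed
by a 120-residue disorder-biased segment. Composition vectors are package
choices calibrated once so the disorder proxy separates the segments by at
least 0.2 (measured ≈ 0.33 on average):

* disordered segment: P .20, E .22, S .18, K .14, G .10, Q .06, R .05,
  T .03, D .01, N .01 — no L or A, so the core pattern cannot arise there by
  chance;
* ordered segment: enriched L, V, I, F, W, A with small amounts of the rest;
* rewritten motif flanks (`r2r3_like`): 0.15 of the mass on P/S/T and the
  rest on G/Q/N — realizing the ContextSpec `flank_bias` target of 0.15 on
  the `+PST-RK` track — with no R/K/D/E, so the planted motif's own basic
  residue dominates the local net charge, as in confirmed motif contexts.

`r2r3_like` records plant a `strict`-pattern instance (positions sampled
uniformly from the allowed sets) in the disordered segment, ≥15 residues
from its edges, with 15 residues rewritten on each side; `trihelix_like`
records plant a `core` instance inside the ordered segment; `negative`
records plant nothing and are redrawn (up to 1000 times) until they contain
no core match. MSAs derive every row from one uniformly sampled ancestral
row by i.i.d. per-column substitution at a motif-specific and a
flank-specific rate — no phylogeny, which is sufficient for testing a
column-exchangeable permutation statistic and nothing more. Shift tables add
`helicity_profile × 3.0 ppm` plus Gaussian noise (default σ = 0.02 ppm) to
the random-coil prediction, with an optional ×0.8 dip at designated core
positions.

What passing the synthetic benchmarks shows: the scanner is exact, the
search separates planted signal from a matched-composition background, the
context call separates the two planted context classes, the permutation test
holds its level, and helicity is recovered to ±0.02 at experimental noise.
What it does not show: performance on real proteomes, where disorder is not
a two-segment caricature, motif flanks carry charge, and conservation has
phylogenetic structure. The package's defaults (E-cutoff, signature
thresholds) should be treated as starting points on real data.

## Reproducibility and problem sizes

Every stochastic step takes an explicit RNG seed (`numpy.random.default_rng`)
and the pipeline fans one global seed out to stages by fixed offsets (+1000
search, +2000 conservation), so stages rerun in isolation reproducibly and
two runs with the same seed write byte-identical reports (reports and logs
contain no timestamps). The bundled benchmarks use 50–200 synthetic records
of length 200, 100,000-window nulls, 500 null alignments at 200 permutations,
and 50 replicates per helicity level — sizes chosen so the whole suite runs
in seconds while keeping the binomial margins of the pass criteria
comfortable.

## Known limitations

* The disorder proxy is compositional only; it cannot see context a trained
  predictor would (e.g. hidden structure in low-complexity charged regions).
* Empirical E-values depend on the shuffled-null size; below p ≈ 1e-7 they
  rest on the exponential tail extrapolation.
* The profile model is ungapped; motifs interrupted by insertions are out of
  reach (full HMM search is explicitly out of scope).
* Fractional helicity from a single peak Cα SCS is a coarse estimate; it
  ignores residue-specific full-helix deltas and chemical-shift referencing
  errors in real data.
* Conservation contrast has no tree correction; dense sampling of one clade
  inflates apparent conservation of all columns equally but can still bias
  the permutation null on real alignments.
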