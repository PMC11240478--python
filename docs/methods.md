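# Methods

## The inference procedure

The pipeline treats two spectra of the same dataset as paired samples: each
frequency point contributes one pair (same frequency, two experimental
conditions). All inference is the two-sided Wilcoxon signed-rank test on
those pairs, at a strict significance rule p < α (default α = 0.05).

Given paired series $x, y$ of length $n$:

1. $d_i = x_i - y_i$; pairs with $d_i = 0$ are removed (Wilcoxon's original
   convention; Pratt's zero handling is out of scope). $n_\text{eff}$ pairs
   remain; if none do, the comparison is degenerate and p = 1.
2. $|d_i|$ are ranked, midranks on ties; $W^+$ and $W^-$ are the rank sums
   of positive and negative differences, and the statistic is their minimum.
3. The two-sided p-value is $\min\!\big(1,\, 2 P_0(W \le \min(W^+,W^-))\big)$
   against the null distribution $P_0$ of a one-sided rank sum under random
   signs.

### Null distribution paths

- **Exact (tie-free, $n_\text{eff} \le 25$)**: $P_0$ over all $2^n$ sign
  assignments of ranks $1..n$, computed by a dynamic program over achievable
  rank sums (integer counts; the division by $2^n$ is a power of two, so the
  reported p is the exact rational rounded once). The cutoff 25 is
  comfortable for the DP and beyond it the normal approximation is
  indistinguishable at the reported precision.
- **Normal approximation ($n_\text{eff} \ge 10$, or any size with ties
  above the exact cutoff)**: $W^+$ standardized by mean $n(n+1)/4$ and
  variance $n(n+1)(2n+1)/24 - \sum_t (t^3-t)/48$ over tied groups of size
  $t$, continuity correction 1/2. At $n = 20$ the worst-case absolute error
  versus the exact distribution is 0.0083 over *all* possible statistics.
- **Small tied samples ($n_\text{eff} < 10$ with ties)**: enumeration over
  the observed midranks on a doubled-integer lattice, since the generic
  rank-1..n table does not apply under midranks.

A separate brute-force oracle (explicit iteration over all sign vectors,
tail of $\min(W^+, W^-)$) exists purely as a test cross-check; it shares no
code path with the DP. The two formulations are provably equal: the doubled
lower tail and the min-statistic tail coincide except when both rank sums
can be $\le$ the observed minimum simultaneously, which forces the cap at 1
in both.

### Tables

Within each modality, five pairwise contrasts are tested over the entire
frequency domain (support medium ± NP, normal ± NP, tumor ± NP, normal vs
tumor, normal+NP vs tumor+NP) plus a difference-of-differences row; the
banded tables repeat the four cell contrasts and the DoD within each 1-THz
window (default edges 0.06, 1, 2, 3, 4 THz). Band membership is half-open
[lo, hi) with the final band closed, so a partition never double-counts an
edge frequency. The support-medium contrast is reported only in full-domain
tables, matching the study design this pipeline mirrors. Bands with fewer
than 2 usable grid points are a hard error — a p-value from fewer pairs is
meaningless.

The DoD sign conventions are frozen: tumor minus normal, with-NP minus
without-NP, and in cross-modality pairs the ATR-derived series is the first
argument. The cross-modality table rows are d1–d2 (tumor−normal), d3–d4
(NP effect on normal), d5–d6 (NP effect on tumor), d7–d8 (tumor−normal under
NP).

### Multiplicity and pseudo-replication

By default the tables report **raw per-cell p-values** — reproducing the
reference procedure, which reports many cells without correction. An
optional Holm step-down correction (`correction: holm`) adjusts across all
cells of one table; adjusted values then drive the significance flags while
raw values remain available.

Treating adjacent frequency points as independent pairs is
pseudo-replication when spectra are autocorrelated: the effective sample
size, and hence significance, is inflated. The pipeline keeps the
frequency-point pairing (fidelity first) and exposes two honest probes:
`decimate_step = k` keeps every k-th point, and the generator's AR(1) noise
mode produces autocorrelated spectra on which the inflation can be measured.

## Band ranking

For a paired comparison a vs b, each band gets (i) the signed-rank p-value
restricted to the band and (ii) the mean absolute enhancement
$\overline{|a-b|}$. Bands sort by ascending p, ties broken by descending
enhancement, then ascending lower edge — significance first, visible
contrast second, a deterministic total order always. No automatic
change-point search: sub-band claims are explored by passing finer edges.

## Synthetic data: the stated world

Real spectra for this problem exist only as published figures, so every
pipeline stage is exercised on a generator with the statistical structure
the analysis assumes:

    signal(modality, type) = baseline(modality) + offset(type)
                             + band-confined effects + noise

- **Grid**: 0.06–4.0 THz at 0.01 THz → 395 points. The span is the
  instrument's; the spacing is a round default (the true resolution is not
  published).
- **Baselines**: low-order polynomials per modality (ATR absorbance rising
  and flattening, transmission decaying). Arbitrary units; only
  between-condition differences matter to rank-based inference.
- **Effects**: FLAT adds the magnitude uniformly inside the band;
  GAUSSIAN_BUMP is centred at the band midpoint with width (hi−lo)/4 and
  truncated to zero at the band edges, so "effect only in band X" is an
  exact, testable statement.
- **Noise**: i.i.d. Gaussian per frequency point, default sd 0.1 signal
  units — the independence that pairing-by-point implicitly assumes. The
  AR(1) mode (stationary, marginal sd preserved) deliberately violates it.
- **Reproducibility**: all draws come from numpy's PCG64 (`default_rng`)
  under a single config seed; replicate studies derive child seeds from a
  `SeedSequence` of that seed. Fixed seed ⇒ bit-identical datasets.

What a green test on this world establishes: the pipeline detects effects
with the assumed structure at the stated signal-to-noise, keeps its type-I
error at the nominal level under independence, and is deterministic and
structurally faithful. What it does not establish: anything about real
cell spectra — water absorption lines, baseline drift, correlated
instrument noise and figure-level effect sizes are all outside the
generator.

## Numerical choices

- CSV I/O writes floats with `repr` (shortest exact decimal), and reads
  with round-trip float parsing, so write→read is bit-exact for every
  double.
- Mismatched grids are an error, never resampled: interpolation would
  manufacture pairs for a paired test.
- Zero differences are dropped before ranking; exact-path p-values are
  computed from integer subset counts; two-sided p is capped at 1 in every
  path.
- Significance is strictly p < α; boundary p = α is not significant.

## Known limitations

- Single spectrum per condition: between-replicate biological variance is
  not modelled; the paired test sees only frequency-point noise.
- The per-cell type-I error is nominal (Monte Carlo: 0.0502 ± 0.0007 at
  n = 95), not conservative: with 68 table cells and no correction, some
  false positives per full analysis are expected under the null.
- Effect sizes and noise levels in the generator are plausible placeholders,
  not calibrated to real instruments.
- One-sided alternatives, Hodges–Lehmann effect sizes, confidence bands and
  FDR control beyond Holm are out of scope.
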