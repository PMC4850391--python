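# Methods

## The experimental model

One trial lasts 6.25 s. A peripheral disc (7.5° eccentricity, 1.75° radius)
oscillates sinusoidally in luminance between black and white at the
entrainment frequency `f`; phase is defined so that φ = 0 is the luminance
*minimum* (black) and ±π the maximum, `L(φ) = 255·(1 − cos φ)/2` on an
abstract 0–255 scale (no cd/m² calibration is attempted). Within each trial
2–4 targets (probabilities 0.5 / 0.375 / 0.125) are flashed at times drawn
uniformly over the feasible set that avoids the first and last 800 ms and
keeps ≥ 800 ms between targets (order-statistics sampling on the gap-reduced
interval, which is exactly uniform on the constrained simplex). Target
positions are fixed layout constants spaced by cortical magnification
(9-position layout: eccentricities 5.4/2.9/1.5° per quadrant; 5-position
layout: 5.4° to 2.9° geometrically interleaved); the position nearest the
disc is tagged `is_adjacent_to_disc`.

Each target is assigned to one of 8 equal phase bins centred on
−π + k·π/4; bins are half-open with boundary ties going to the upper bin
(a documented convention — any consistent tie rule gives the same statistics
almost surely).

## The synthetic observer

Detection of a target of luminance `L` at position `j` and phase `φ` is
Bernoulli with

    p = γ + (1 − γ − λ) · σ(s·(log L − log θ_j)) · (1 + (m_j/2)·cos(φ − φ_j)),

clipped to [0, 1]. Defaults: guess rate γ = 0 (detection task, no forced
choice), lapse λ = 0.02 (a typical attentional-lapse allowance), logistic
slope s = 8 per log-luminance unit (a moderately steep near-threshold
psychometric function), threshold θ = 100 on the 0–255 scale. The phase gain
multiplies the asymptote term only, so `m_j` is interpretable as the
peak-to-trough modulation fraction at threshold: with the staircase holding
the mean hit rate at 0.5, the induced hit-rate modulation is ≈ `m_j/2`.

Preferred phases implement the local/global structure: the disc-adjacent
position carries a local phase (default −π/4) and all others a common global
phase (default −3π/4). The π/2 offset is an arbitrary but identifiable
choice — the phenomenon constrains the *existence* of an offset, not its
value. Default depths per position are (0.50, 0.45, 0.42, 0.40, 0.38),
which at a 50% baseline produce a ≈ 22% mean peak-to-trough performance
modulation, strongest nearest the disc; depths are scaled ×1.3 at 5 Hz and
×0.35 at 15 Hz to reproduce the reported frequency ordering (5 Hz > IAF ≫
15 Hz).

Target luminance follows an independent per-position multiplicative
1-up/1-down staircase (hit → L/1.1, miss → L·1.1, capped at 255), whose
equilibrium is the 50% point of the psychometric function. No burn-in is
discarded anywhere in the analysis. The run size is set by
`targets_per_cell` (default 33 expected targets per phase-bin × position
cell, ≈ 503 trials for 5 positions).

What the generator does *not* emulate: reaction times, false alarms, eye
movements, saccadic suppression, masking dynamics, attention fluctuations,
session structure, or any between-subject variability in thresholds, slopes
or preferred phases (all subjects share one parameter set unless configured
otherwise). Passing tests therefore show that the statistical machinery is
correct and calibrated for data with this structure — not that real
observers satisfy the model.

## Analysis

Hit rate is computed per phase bin; empty bins stay flagged-NaN and are
excluded from fits with a warning (≥ 3 usable bins required; with a 2-bin
design both bins suffice). The cosine fit is linear least squares on the
design {1, cos φ, sin φ} solved by pseudo-inverse: for full equally spaced
coverage this equals the first-harmonic Fourier projection, and for
degenerate designs (e.g. 2 opposite bins) the minimum-norm solution drops
the unidentifiable sine component, giving amplitude = half the rate
difference. Flat curves get amplitude 0, phase 0 by convention and a
`degenerate` flag so phase-based tests can refuse them. Group (fixed-effect)
curves are unweighted means of subject rates per bin — trial counts are
nearly balanced by design — with counts summed for surrogate construction.

### Monte Carlo tests

*Amplitude*: for each surrogate, every subject's per-bin hits are redrawn
Binomial(n_bin, pooled rate) under the equal-performance null, averaged
across subjects, and fitted by the same code path as the observed data.
`p_raw` is the proportion of surrogate amplitudes ≥ the observed one
(ties counted within 1e-9 relative tolerance, since observed and surrogate
statistics share one fit implementation and differ only by float noise);
`(r+1)/(n+1)` is reported alongside as a conservative bound. The default
surrogate count is 50,000; the CLI demo profile uses 2,000.

*Phase difference*: the statistic is the absolute principal-value circular
distance in [0, π] between the two group-level fitted phases. Surrogates
redraw each location's per-bin trials (summed counts across subjects) at the
bin-wise two-location average rate — the common-phase null.

FDR correction is Benjamini–Hochberg, applied within an experiment across
positions (amplitude family) or across position pairs (phase family); the
method is isolated behind `fdr_adjust` and swappable.

### Comparisons

The frequency × position ANOVA is a balanced fixed-effects decomposition
(statsmodels OLS, type-II sums of squares; identical to type-I/III on
balanced data); unbalanced or deficient designs are rejected rather than
silently reweighted. Post-hoc pairwise tests are Welch t-tests FDR-corrected
over the requested family; a Tukey HSD (studentized-range) variant is
provided for the one-way position family. The Watson–Williams test uses the
standard F statistic with the `1 + 3/(8κ)` correction, κ estimated from the
pooled resultant length by the usual piecewise approximation; it warns when
the mean resultant length is below 0.45, where the approximation degrades.
The 2×2 chi-square is Pearson without continuity correction (the printed
selection result holds with or without it).

### Controls

*SOA control*: the disc is flashed once at full luminance, targets offset by
±50, 37.5, 25, 12.5 or 0 ms. Performance per SOA is mapped to phase by
φ = 2π·SOA/100 ms; the ±50 ms endpoints describe the same point of the
cycle and are averaged into a single ±π point, leaving 8 phase points that
run through the identical fit + amplitude-test machinery.

*Luminance control*: the disc is flashed at levels 64/128/192/255
simultaneously with the target. Bin centres (−π … 3π/4) receive the rates
measured at levels 255, 192, 128, 64, 64, 64, 128, 192 — level 64 also
standing in for the unpresentable zero-luminance flash at φ = 0. The mirror
symmetry of this construction zeroes the first-harmonic sine coefficient, so
fitted phases are exactly 0 or π. Surrogates are drawn at the granularity of
the four original levels (each level's trial count, pooled null rate) and
pushed through the same rearrangement, so they share the symmetry and the
amplitude test compares like with like. The quantized level list (192 at
±3π/4 rather than the continuous-sinusoid 218) is treated as the display's
rounding and used verbatim for this control only; the simulator itself uses
the continuous L(φ).

## Numerical and scale choices

- Angles are always radians in [−π, π) (`wrap_phase`); times seconds; SOAs ms.
- MC p-values are raw proportions and may be exactly 0.
- Problem sizes in the test suite: unit tests run at a few subjects and
  reduced surrogate counts; the study-scale recovery check uses 15 subjects,
  5 positions, ~33 targets/cell and 2,000 surrogates, and the calibration
  checks use 500 repetitions × 1,000 surrogates — sizes chosen to make the
  binomial error of each check several times smaller than its tolerance.
- All randomness flows through a single `numpy.random.Generator`; fixed
  seeds give bit-identical datasets and identical p-values.

## Known limitations

- Fixed-effect inference only: significance is assessed on grand averages
  against surrogate grand averages; no hierarchical/mixed modeling.
- The cosine fit considers the first harmonic only.
- The fitted amplitude of noisy data is positively biased (Rice-type bias of
  a vector norm); the surrogate test accounts for this under the null, but
  per-subject amplitude means at small trial counts inherit a small upward
  bias.
- The Watson–Williams test is parametric and unreliable at low
  concentration; the permutation cross-check in the test suite covers the
  concentrated regime only.
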