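"""Monte Carlo surrogate tests for oscillatory amplitude and phase differences.

Both tests are empirical fixed-effect tests: the observed statistic is
computed on the across-subject grand-average performance curve and compared
with the same statistic on surrogate grand averages simulated under an
explicit null.

* Amplitude test null: performance is equal across phase bins, so every
  trial of a subject is a Bernoulli draw at that subject's pooled hit rate,
  keeping each subject's per-bin trial counts fixed.
* Phase-difference test null: two locations oscillate with a common
  preferred phase, so each location's trials are Bernoulli draws at the
  bin-wise average rate of the two locations, keeping each location's
  (summed-over-subjects) per-bin trial counts fixed.

p-values are the raw proportion of surrogates whose statistic reaches or
exceeds the observed one (they can be exactly 0); the conservative
``(r + 1) / (n + 1)`` bound is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .analysis import (
    BinnedPerformance,
    CosineFit,
    bin_performance,
    fit_cosine,
    fit_cosine_rates,
    group_average_bins,
)
from .design import PhaseBinning, wrap_phase

__all__ = [
    "MCResult",
    "mc_amplitude_test",
    "mc_phase_difference_test",
    "fdr_adjust",
    "amplitude_tests_by_position",
    "phase_difference_tests",
    "circular_distance",
]


def circular_distance(a, b) -> np.ndarray | float:
    """Absolute principal-value phase difference ``|wrap(a - b)|`` in [0, pi]."""
    d = np.abs(wrap_phase(np.asarray(a, dtype=float) - b))
    return d if np.ndim(d) else float(d)


@dataclass
class MCResult:
    """Outcome of one surrogate test."""

    observed_statistic: float  # cosine half-amplitude, or |phase difference|
    n_surrogates: int
    p_raw: float  # proportion of surrogates >= observed (can be 0)
    p_conservative: float  # (r + 1) / (n + 1)
    surrogate_quantiles: dict[float, float]
    significant_fdr: bool | None = None  # filled by a family-wise FDR pass

    @staticmethod
    def from_surrogates(observed: float, surrogate_stats: np.ndarray) -> "MCResult":
        n = len(surrogate_stats)
        # ">= observed" up to float noise, so exact ties from the shared fit
        # code path count as reaching the observed statistic
        tol = 1e-9 * max(1.0, abs(observed))
        r = int(np.sum(surrogate_stats >= observed - tol))
        qs = (0.5, 0.95, 0.99)
        return MCResult(
            observed_statistic=float(observed),
            n_surrogates=n,
            p_raw=r / n,
            p_conservative=(r + 1) / (n + 1),
            surrogate_quantiles={
                q: float(np.quantile(surrogate_stats, q)) for q in qs
            },
        )


def mc_amplitude_test(
    binned_per_subject: list[BinnedPerformance],
    n_surrogates: int = 50_000,
    rng: np.random.Generator | int | None = None,
) -> tuple[MCResult, CosineFit]:
    """Fixed-effect surrogate test of the oscillatory amplitude at one position.

    The observed statistic is the cosine half-amplitude fitted to the
    across-subject average of the per-bin hit rates.  Each surrogate redraws
    every subject's per-bin hit counts as Binomial(n_bin, pooled rate) under
    the equal-performance null, averages across subjects and fits the same
    cosine.  Returns the Monte Carlo result and the observed group fit.
    """
    if not binned_per_subject:
        raise ValueError("need at least one subject")
    rng = np.random.default_rng(rng)
    group = group_average_bins(binned_per_subject)
    observed_fit = fit_cosine(group)
    centers = group.bin_centers

    rate_sum = None
    n_used = None
    for b in binned_per_subject:
        counts = np.asarray(b.n_targets)
        if np.sum(counts) == 0:
            raise ValueError(f"subject curve at {b.position_id!r} has no targets")
        p0 = b.pooled_rate
        hits = rng.binomial(counts[None, :].repeat(n_surrogates, axis=0), p0)
        with np.errstate(invalid="ignore", divide="ignore"):
            rates = np.where(counts[None, :] > 0, hits / counts[None, :], np.nan)
        contrib = np.where(np.isnan(rates), 0.0, rates)
        used = (counts > 0).astype(float)
        rate_sum = contrib if rate_sum is None else rate_sum + contrib
        n_used = used if n_used is None else n_used + used
    mean_rates = rate_sum / n_used[None, :]

    mask = n_used > 0
    fits = fit_cosine_rates(centers[mask], mean_rates[:, mask])
    result = MCResult.from_surrogates(observed_fit.half_amplitude, fits[:, 1])
    return result, observed_fit


def mc_phase_difference_test(
    binned_a: BinnedPerformance,
    binned_b: BinnedPerformance,
    n_surrogates: int = 50_000,
    rng: np.random.Generator | int | None = None,
) -> MCResult:
    """Surrogate test of the preferred-phase difference between two locations.

    Inputs are the group-level curves (across-subject mean rates with
    summed per-bin trial counts).  The observed statistic is the absolute
    circular distance between the two fitted preferred phases.  Under the
    common-phase null each location's per-bin trials are redrawn Bernoulli at
    the bin-wise average of the two locations' rates.
    """
    rng = np.random.default_rng(rng)
    fit_a = fit_cosine(binned_a)
    fit_b = fit_cosine(binned_b)
    if fit_a.degenerate or fit_b.degenerate:
        raise ValueError("phase difference undefined for a flat (degenerate) fit")
    if binned_a.n_bins != binned_b.n_bins or not np.allclose(
        binned_a.bin_centers, binned_b.bin_centers
    ):
        raise ValueError("locations must share one phase binning")
    observed = circular_distance(fit_a.preferred_phase, fit_b.preferred_phase)

    centers = binned_a.bin_centers
    p_null = np.nanmean(np.vstack([binned_a.hit_rate, binned_b.hit_rate]), axis=0)
    mask = (
        np.isfinite(p_null)
        & (np.asarray(binned_a.n_targets) > 0)
        & (np.asarray(binned_b.n_targets) > 0)
    )
    if mask.sum() < 3:
        raise ValueError("need >= 3 bins with data at both locations")

    phases = []
    for b in (binned_a, binned_b):
        counts = np.asarray(b.n_targets)[mask]
        hits = rng.binomial(counts[None, :].repeat(n_surrogates, axis=0), p_null[mask])
        rates = hits / counts[None, :]
        phases.append(fit_cosine_rates(centers[mask], rates)[:, 2])
    surrogate_d = circular_distance(phases[0], phases[1])
    return MCResult.from_surrogates(observed, surrogate_d)


def fdr_adjust(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up over a family of p-values.

    Returns ``(reject flags, adjusted p-values)`` at FDR level ``q``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def amplitude_tests_by_position(
    datasets,
    position_ids: list[str],
    binning: PhaseBinning,
    n_surrogates: int = 50_000,
    rng: np.random.Generator | int | None = None,
    q: float = 0.05,
) -> pd.DataFrame:
    """Amplitude test per position, FDR-corrected across positions."""
    rng = np.random.default_rng(rng)
    rows = []
    for pid in position_ids:
        binned = [bin_performance(ds, pid, binning) for ds in datasets]
        res, fit = mc_amplitude_test(binned, n_surrogates, rng)
        rows.append(
            {
                "position": pid,
                "baseline": fit.baseline,
                "half_amplitude": fit.half_amplitude,
                "peak_to_trough": fit.peak_to_trough,
                "phase_rad": fit.preferred_phase,
                "p_raw": res.p_raw,
                "p_conservative": res.p_conservative,
                "n_surrogates": res.n_surrogates,
            }
        )
    out = pd.DataFrame(rows)
    reject, p_adj = fdr_adjust(out["p_raw"].to_numpy(), q)
    out["p_fdr"] = p_adj
    out["significant_fdr"] = reject
    return out


def phase_difference_tests(
    datasets,
    position_ids: list[str],
    binning: PhaseBinning,
    n_surrogates: int = 50_000,
    rng: np.random.Generator | int | None = None,
    q: float = 0.05,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Pairwise preferred-phase difference tests, FDR-corrected over pairs."""
    rng = np.random.default_rng(rng)
    groups = {
        pid: group_average_bins([bin_performance(ds, pid, binning) for ds in datasets])
        for pid in position_ids
    }
    if pairs is None:
        pairs = list(combinations(position_ids, 2))
    rows = []
    for a, b in pairs:
        res = mc_phase_difference_test(groups[a], groups[b], n_surrogates, rng)
        rows.append(
            {
                "position_a": a,
                "position_b": b,
                "phase_difference_rad": res.observed_statistic,
                "p_raw": res.p_raw,
                "p_conservative": res.p_conservative,
                "n_surrogates": res.n_surrogates,
            }
        )
    out = pd.DataFrame(rows)
    reject, p_adj = fdr_adjust(out["p_raw"].to_numpy(), q)
    out["p_fdr"] = p_adj
    out["significant_fdr"] = reject
    return out
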