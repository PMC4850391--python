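"""Phase-binned hit rates and first-harmonic cosine fits.

The core descriptive statistic: hit rate per phase bin, fitted with

    rate(phi) = baseline + A * cos(phi - preferred_phase)

by unweighted least squares over the bin means.  ``A`` (the half-amplitude)
is reported doubled as the peak-to-trough modulation, fitted performance at
the preferred phase minus performance at the opposite phase.  For equally
spaced bins covering the full cycle the least-squares solution coincides with
the first-harmonic Fourier projection of the bin rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import PhaseBinning, wrap_phase
from .observer import SubjectDataset

__all__ = [
    "BinnedPerformance",
    "CosineFit",
    "bin_performance",
    "fit_cosine",
    "fit_cosine_rates",
    "group_average_bins",
    "modulation_depth",
    "fit_table",
]

_DEGENERATE_AMP = 1e-12


@dataclass
class BinnedPerformance:
    """Per-bin target/hit counts for one subject x position (or a group)."""

    position_id: str
    bin_centers: np.ndarray  # radians
    n_targets: np.ndarray  # int per bin
    n_hits: np.ndarray | None  # int per bin; None for group averages
    hit_rate: np.ndarray | None = None  # filled from counts when None

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.n_targets = np.asarray(self.n_targets)
        if self.n_hits is not None:
            self.n_hits = np.asarray(self.n_hits)
            if np.any(self.n_hits > self.n_targets) or np.any(self.n_hits < 0):
                raise ValueError("need 0 <= n_hits <= n_targets in every bin")
        if self.hit_rate is None:
            with np.errstate(invalid="ignore", divide="ignore"):
                self.hit_rate = np.where(
                    self.n_targets > 0, self.n_hits / self.n_targets, np.nan
                )
        else:
            self.hit_rate = np.asarray(self.hit_rate, dtype=float)

    @property
    def n_bins(self) -> int:
        return len(self.bin_centers)

    @property
    def defined(self) -> np.ndarray:
        """Mask of bins with at least one target (hit rate defined)."""
        return np.asarray(self.n_targets) > 0

    @property
    def pooled_rate(self) -> float:
        """Across-bin hit rate (total hits / total targets)."""
        if self.n_hits is None:
            raise ValueError("pooled rate needs per-bin hit counts")
        total = int(np.sum(self.n_targets))
        if total == 0:
            raise ValueError("no targets")
        return float(np.sum(self.n_hits) / total)


@dataclass
class CosineFit:
    """3-parameter cosine description of a binned performance curve."""

    baseline: float
    half_amplitude: float
    preferred_phase: float  # radians in [-pi, pi)
    degenerate: bool = False  # flat input; phase fixed to 0 by convention

    @property
    def peak_to_trough(self) -> float:
        return 2.0 * self.half_amplitude

    def predict(self, phi) -> np.ndarray:
        return self.baseline + self.half_amplitude * np.cos(
            np.asarray(phi, dtype=float) - self.preferred_phase
        )


def bin_performance(
    dataset: SubjectDataset, position_id: str, binning: PhaseBinning
) -> BinnedPerformance:
    """Count targets and hits per phase bin at one position.

    Bins without targets are kept (rate NaN) and flagged via ``defined``.
    """
    events = [t for t in dataset.targets if t.position_id == position_id]
    if not events:
        raise ValueError(f"no targets at position {position_id!r}")
    bins = np.array([t.phase_bin for t in events])
    hits = np.array([t.detected for t in events], dtype=int)
    n_targets = np.bincount(bins, minlength=binning.n_bins)
    n_hits = np.bincount(bins, weights=hits, minlength=binning.n_bins).astype(int)
    if len(n_targets) > binning.n_bins:
        raise ValueError("phase_bin index outside the binning")
    return BinnedPerformance(position_id, binning.bin_centers, n_targets, n_hits)


def _design(centers: np.ndarray) -> np.ndarray:
    return np.column_stack(
        [np.ones_like(centers), np.cos(centers), np.sin(centers)]
    )


def fit_cosine_rates(centers: np.ndarray, rates: np.ndarray) -> np.ndarray:
    """Vectorised fit of ``baseline + a cos(phi) + b sin(phi)`` to rows of
    ``rates`` at phases ``centers``; returns an ``(n, 3)`` array of
    ``(baseline, half_amplitude, preferred_phase)``.

    Solved by pseudo-inverse of the shared design matrix, i.e. minimum-norm
    least squares; with fewer than 3 distinct phases the sine (or cosine)
    component falls out of the column space and its coefficient is 0, which
    e.g. for 2 opposite bins yields half the rate difference as amplitude.
    """
    rates = np.atleast_2d(np.asarray(rates, dtype=float))
    X = _design(np.asarray(centers, dtype=float))
    coef = rates @ np.linalg.pinv(X).T  # (n, 3): c, alpha, beta
    amp = np.hypot(coef[:, 1], coef[:, 2])
    phase = np.where(
        amp > _DEGENERATE_AMP, np.arctan2(coef[:, 2], coef[:, 1]), 0.0
    )
    return np.column_stack([coef[:, 0], amp, wrap_phase(phase)])


def fit_cosine(binned: BinnedPerformance) -> CosineFit:
    """Least-squares cosine fit over the defined bins of one curve.

    Empty bins are dropped with a warning; fewer than 3 usable bins (2 for a
    2-bin design) is an error.  A flat curve yields amplitude 0, phase 0 and
    the ``degenerate`` flag.
    """
    mask = binned.defined & np.isfinite(binned.hit_rate)
    min_usable = min(3, binned.n_bins)
    if mask.sum() < min_usable:
        raise ValueError(
            f"cosine fit needs >= {min_usable} bins with data, have {int(mask.sum())}"
        )
    if mask.sum() < binned.n_bins:
        warnings.warn(
            f"{binned.n_bins - int(mask.sum())} empty bin(s) excluded from the "
            f"cosine fit at position {binned.position_id!r}",
            stacklevel=2,
        )
    baseline, amp, phase = fit_cosine_rates(
        binned.bin_centers[mask], binned.hit_rate[mask]
    )[0]
    degenerate = amp <= _DEGENERATE_AMP
    return CosineFit(float(baseline), float(amp), float(phase), degenerate)


def group_average_bins(binned_list: list[BinnedPerformance]) -> BinnedPerformance:
    """Fixed-effect group curve: unweighted mean of subject hit rates per bin.

    Subjects' empty bins are ignored bin-wise; per-bin target counts are
    summed and retained for surrogate construction.
    """
    if not binned_list:
        raise ValueError("need at least one subject")
    first = binned_list[0]
    for b in binned_list[1:]:
        if b.n_bins != first.n_bins or not np.allclose(b.bin_centers, first.bin_centers):
            raise ValueError("all subjects must share one phase binning")
        if b.position_id != first.position_id:
            raise ValueError("all subjects must be binned at the same position")
    rates = np.vstack([b.hit_rate for b in binned_list])
    counts = np.vstack([b.n_targets for b in binned_list])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_rate = np.nanmean(rates, axis=0)
    return BinnedPerformance(
        first.position_id,
        first.bin_centers,
        counts.sum(axis=0),
        n_hits=None,
        hit_rate=mean_rate,
    )


def modulation_depth(fit: CosineFit) -> float:
    """Peak-to-trough modulation: fitted performance at the preferred phase
    minus at the opposite phase, i.e. twice the half-amplitude."""
    return fit.peak_to_trough


def fit_table(
    datasets: list[SubjectDataset],
    position_ids: list[str],
    binning: PhaseBinning,
) -> pd.DataFrame:
    """Per-(subject, position) cosine-fit summary table."""
    rows = []
    for ds in datasets:
        for pid in position_ids:
            binned = bin_performance(ds, pid, binning)
            fit = fit_cosine(binned)
            rows.append(
                {
                    "subject": ds.subject,
                    "position": pid,
                    "baseline": fit.baseline,
                    "half_amplitude": fit.half_amplitude,
                    "peak_to_trough": fit.peak_to_trough,
                    "phase_rad": fit.preferred_phase,
                    "n_targets": int(np.sum(binned.n_targets)),
                    "degenerate": fit.degenerate,
                }
            )
    return pd.DataFrame(rows)
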