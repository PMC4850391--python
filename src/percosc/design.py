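"""Fixed experimental geometry and deterministic phase/luminance/SOA maps.

The paradigm: a peripheral disc oscillates sinusoidally in luminance between
black and white at a fixed entrainment frequency while near-threshold targets
are flashed at several eccentric positions.  Everything downstream (phase
binning, cosine fits, surrogate tests) is anchored to the conventions defined
here:

* Phase convention: ``phi = 0`` at the luminance *minimum* (black disc),
  increasing with time; luminance is ``255 * (1 - cos(phi)) / 2`` on an
  abstract 0-255 scale.
* Angles are radians wrapped to ``[-pi, pi)``; times are seconds; SOAs are
  milliseconds.
* Phase bins are half-open sectors centred on ``-pi + k * 2*pi/n`` with ties
  on a boundary assigned to the upper bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Position",
    "PhaseBinning",
    "ExperimentConfig",
    "wrap_phase",
    "phase_at_time",
    "luminance_at_phase",
    "assign_phase_bin",
    "soa_to_phase",
    "exp1_positions",
    "exp2_positions",
    "SOA_GRID_MS",
    "SOA_REFERENCE_PERIOD_MS",
    "LUMINANCE_LEVELS",
    "CONTROL2_LEVEL_BY_BIN",
    "DEFAULT_TARGET_COUNT_PROBS",
]

#: signed SOAs (ms) of the flashed-disc masking control, spanning one 100 ms
#: cycle of a nominal 10 Hz alpha oscillation.
SOA_GRID_MS: tuple[float, ...] = (-50.0, -37.5, -25.0, -12.5, 0.0, 12.5, 25.0, 37.5, 50.0)
SOA_REFERENCE_PERIOD_MS: float = 100.0

#: disc luminance levels used in the luminance-flash control.
LUMINANCE_LEVELS: tuple[int, ...] = (64, 128, 192, 255)

#: luminance level standing in for each of the 8 phase-bin centres
#: (-pi, -3pi/4, ..., 3pi/4) when the luminance control is rearranged into an
#: emulated oscillatory cycle.  Level 64 substitutes for the unpresentable
#: 0-luminance flash at phase 0.
CONTROL2_LEVEL_BY_BIN: tuple[int, ...] = (255, 192, 128, 64, 64, 64, 128, 192)

DEFAULT_TARGET_COUNT_PROBS: dict[int, float] = {2: 0.5, 3: 0.375, 4: 0.125}


def wrap_phase(phi):
    """Wrap angle(s) into ``[-pi, pi)``."""
    return np.mod(np.asarray(phi, dtype=float) + np.pi, 2.0 * np.pi) - np.pi


@dataclass(frozen=True)
class Position:
    """One target location, placed by cortical magnification.

    Eccentricities are stored verbatim as experiment constants; no
    magnification formula is applied at run time.
    """

    id: str
    eccentricity: float  # degrees of visual angle
    quadrant: str
    is_adjacent_to_disc: bool = False

    def __post_init__(self) -> None:
        if not self.eccentricity > 0:
            raise ValueError(f"eccentricity must be > 0, got {self.eccentricity}")


def exp1_positions() -> list[Position]:
    """Nine-location layout: three eccentricities in each of three quadrants.

    Position 1 (5.4 deg, upper left) is the location nearest the oscillating
    disc (7.5 deg eccentricity, 1.75 deg radius).
    """
    ecc = {"1": 5.4, "2": 2.9, "3": 1.5, "4": 1.5, "5": 2.9, "6": 5.4, "7": 1.5, "8": 2.9, "9": 5.4}
    quad = {
        "1": "UL", "2": "UL", "3": "UL",
        "4": "UR", "5": "UR", "6": "UR",
        "7": "LL", "8": "LL", "9": "LL",
    }
    return [
        Position(pid, ecc[pid], quad[pid], is_adjacent_to_disc=(pid == "1"))
        for pid in "123456789"
    ]


def exp2_positions() -> list[Position]:
    """Five-location layout: positions 1 and 2 of the nine-location layout
    plus three geometrically interleaved eccentricities, all in the upper-left
    quadrant."""
    eccs = [5.4 * (2.9 / 5.4) ** (k / 4) for k in range(5)]
    return [
        Position(str(i + 1), round(e, 2), "UL", is_adjacent_to_disc=(i == 0))
        for i, e in enumerate(eccs)
    ]


@dataclass(frozen=True)
class PhaseBinning:
    """Partition of the cycle ``[-pi, pi)`` into equal half-open sectors."""

    n_bins: int = 8

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError(f"n_bins must be >= 2, got {self.n_bins}")

    @property
    def bin_width(self) -> float:
        return 2.0 * np.pi / self.n_bins

    @property
    def bin_centers(self) -> np.ndarray:
        """Centres ``-pi + k * width`` for ``k = 0 .. n_bins-1``."""
        return -np.pi + np.arange(self.n_bins) * self.bin_width

    def assign(self, phi):
        return assign_phase_bin(phi, self)


def phase_at_time(t, f: float, phase_offset: float = 0.0):
    """Oscillation phase at time ``t`` (s) for frequency ``f`` (Hz).

    ``phi(t) = wrap(2*pi*f*t + phase_offset)``; periodic with period ``1/f``.
    """
    if not f > 0:
        raise ValueError(f"frequency must be positive, got {f}")
    return wrap_phase(2.0 * np.pi * f * np.asarray(t, dtype=float) + phase_offset)


def luminance_at_phase(phi):
    """Disc luminance ``L(phi) = 255 * (1 - cos(phi)) / 2`` on the 0-255 scale.

    Black (0) at phase 0, white (255) at +-pi; even in ``phi``.
    """
    phi = np.asarray(phi, dtype=float)
    if not np.all(np.isfinite(phi)):
        raise ValueError("phase must be finite")
    return 255.0 * (1.0 - np.cos(phi)) / 2.0


def assign_phase_bin(phi, binning: PhaseBinning):
    """Index of the sector containing ``phi`` (wrapped to ``[-pi, pi)``).

    Sector ``k`` is ``[center_k - w/2, center_k + w/2)``; exact boundaries
    belong to the upper bin.
    """
    w = binning.bin_width
    phi = wrap_phase(phi)
    idx = np.floor((phi + np.pi + 0.5 * w) / w).astype(int) % binning.n_bins
    return idx if np.ndim(phi) else int(idx)


def soa_to_phase(soa_ms, reference_period_ms: float = SOA_REFERENCE_PERIOD_MS):
    """Map a signed SOA (ms) onto the phase ``2*pi*soa/period``.

    The nine-point grid +-50, 37.5, 25, 12.5, 0 ms maps to -pi ... pi at the
    100 ms reference period; both endpoints correspond to the same point of
    the cycle and are merged downstream.
    """
    soa = np.asarray(soa_ms, dtype=float)
    if np.any(np.abs(soa) > reference_period_ms / 2.0 + 1e-9):
        raise ValueError(
            f"|SOA| must not exceed half the reference period "
            f"({reference_period_ms / 2.0} ms)"
        )
    out = 2.0 * np.pi * soa / reference_period_ms
    return out if np.ndim(soa_ms) else float(out)


@dataclass
class ExperimentConfig:
    """Run-level constants of one entrainment experiment."""

    entrainment_frequency: float = 9.6  # Hz; IAF-like default
    trial_duration: float = 6.25  # s
    edge_margin: float = 0.8  # s, excluded at both trial ends
    min_gap: float = 0.8  # s, minimum between successive targets
    response_window: float = 0.8  # s
    n_phase_bins: int = 8
    target_count_probs: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_TARGET_COUNT_PROBS)
    )
    n_surrogates: int = 50_000
    fdr_q: float = 0.05
    positions: list[Position] = field(default_factory=exp2_positions)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.target_count_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"target_count_probs must sum to 1, got {total}")
        if any(p < 0 for p in self.target_count_probs.values()):
            raise ValueError("target_count_probs must be non-negative")
        max_count = max(self.target_count_probs)
        span = self.trial_duration - 2.0 * self.edge_margin
        if span < (max_count - 1) * self.min_gap:
            raise ValueError(
                f"trial too short: {max_count} targets need "
                f"{(max_count - 1) * self.min_gap:.2f} s between margins, have {span:.2f} s"
            )
        if self.n_phase_bins < 2:
            raise ValueError("n_phase_bins must be >= 2")
        if self.n_surrogates < 1:
            raise ValueError("n_surrogates must be >= 1")
        n_adj = sum(p.is_adjacent_to_disc for p in self.positions)
        if self.positions and n_adj != 1:
            raise ValueError(
                f"exactly one position must be adjacent to the disc, got {n_adj}"
            )

    @property
    def binning(self) -> PhaseBinning:
        return PhaseBinning(self.n_phase_bins)

    @property
    def position_ids(self) -> list[str]:
        return [p.id for p in self.positions]
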