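"""Synthetic observers: trial schedules, staircases, phase-modulated detection.

The generative model stands in for the human observers the analysis was
designed for.  Detection of a target of luminance ``L`` at oscillation phase
``phi`` and position ``j`` is Bernoulli with

    p = guess + (1 - guess - lapse) * sigmoid(slope * (log L - log theta_j))
                                    * (1 + (m_j / 2) * cos(phi - phi_j))

clipped to [0, 1]: a logistic psychometric function of log-luminance whose
asymptote is multiplicatively gain-modulated by the entraining cycle.  ``m_j``
is the peak-to-trough modulation fraction and ``phi_j`` the preferred phase at
position ``j``; the position nearest the disc carries a "local" preferred
phase, all others share a "global" one.  Target luminance is adapted by a
multiplicative 1-up/1-down staircase whose equilibrium is the 50% point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import (
    LUMINANCE_LEVELS,
    SOA_GRID_MS,
    ExperimentConfig,
    Position,
    assign_phase_bin,
    phase_at_time,
    soa_to_phase,
    wrap_phase,
)

__all__ = [
    "ObserverModel",
    "TargetEvent",
    "SubjectDataset",
    "draw_target_count",
    "draw_target_schedule",
    "detection_probability",
    "staircase_update",
    "simulate_experiment",
    "simulate_soa_control",
    "simulate_luminance_control",
    "default_observer",
    "DEFAULT_GLOBAL_PHASE",
    "DEFAULT_LOCAL_PHASE",
    "DEFAULT_DEPTHS_IAF",
    "FREQUENCY_DEPTH_SCALE",
]

# Study-condition defaults for the generative observer.  Depths are
# multiplicative peak-to-trough fractions m; at a ~50% staircase-held hit rate
# the induced hit-rate modulation is ~m/2, so the IAF defaults average to
# ~22% peak-to-trough performance modulation, strongest nearest the disc.
DEFAULT_DEPTHS_IAF: tuple[float, ...] = (0.50, 0.45, 0.42, 0.40, 0.38)
#: entrainment is stronger at 5 Hz and much weaker at 15 Hz than at IAF.
FREQUENCY_DEPTH_SCALE: dict[float, float] = {5.0: 1.3, 15.0: 0.35}
DEFAULT_GLOBAL_PHASE: float = -3 * math.pi / 4
DEFAULT_LOCAL_PHASE: float = -math.pi / 4  # disc-adjacent position; pi/2 ahead


@dataclass
class ObserverModel:
    """Per-position psychometric and entrainment parameters of one observer."""

    threshold_per_position: dict[str, float]  # luminance (0-255] at 50% detection
    modulation_depth_per_position: dict[str, float]  # peak-to-trough fraction m
    preferred_phase_per_position: dict[str, float]  # radians in [-pi, pi)
    slope: float = 8.0  # logistic steepness per log-luminance unit
    guess_rate: float = 0.0
    lapse_rate: float = 0.02

    def __post_init__(self) -> None:
        if not 0.0 <= self.guess_rate + self.lapse_rate < 1.0:
            raise ValueError("guess_rate + lapse_rate must lie in [0, 1)")
        for pid, m in self.modulation_depth_per_position.items():
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"modulation depth at {pid} must be in [0, 1], got {m}")
        self.preferred_phase_per_position = {
            pid: float(wrap_phase(phi))
            for pid, phi in self.preferred_phase_per_position.items()
        }

    @classmethod
    def from_local_global(
        cls,
        positions: list[Position],
        depths,
        global_phase: float = DEFAULT_GLOBAL_PHASE,
        local_phase: float = DEFAULT_LOCAL_PHASE,
        threshold: float = 100.0,
        **kwargs,
    ) -> "ObserverModel":
        """Build an observer with one local and one shared global phase.

        ``depths`` is a scalar or one value per position (same order).
        """
        if np.isscalar(depths):
            depths = [float(depths)] * len(positions)
        if len(depths) != len(positions):
            raise ValueError("need one modulation depth per position")
        phases = {
            p.id: (local_phase if p.is_adjacent_to_disc else global_phase)
            for p in positions
        }
        return cls(
            threshold_per_position={p.id: float(threshold) for p in positions},
            modulation_depth_per_position={
                p.id: float(m) for p, m in zip(positions, depths)
            },
            preferred_phase_per_position=phases,
            **kwargs,
        )

    def with_zero_modulation(self) -> "ObserverModel":
        return replace(
            self,
            modulation_depth_per_position={
                k: 0.0 for k in self.modulation_depth_per_position
            },
        )


def default_observer(config: ExperimentConfig, **kwargs) -> ObserverModel:
    """Observer under the study's default conditions for ``config``'s layout,
    with modulation depth scaled by entrainment frequency."""
    scale = FREQUENCY_DEPTH_SCALE.get(round(config.entrainment_frequency, 1), 1.0)
    base = list(DEFAULT_DEPTHS_IAF)
    if len(config.positions) != len(base):
        base = [base[min(i, len(base) - 1)] for i in range(len(config.positions))]
    depths = [min(1.0, d * scale) for d in base]
    return ObserverModel.from_local_global(config.positions, depths, **kwargs)


@dataclass
class TargetEvent:
    """One near-threshold flash and its outcome."""

    subject: str
    trial_index: int
    position_id: str
    onset: float  # s from trial start
    luminance: float  # 0-255
    phase_at_onset: float  # radians in [-pi, pi)
    phase_bin: int
    detected: bool
    soa_ms: float | None = None  # masking control only
    disc_level: float | None = None  # luminance control only


@dataclass
class SubjectDataset:
    """All targets of one (simulated or recorded) observer."""

    subject: str
    entrainment_frequency: float
    targets: list[TargetEvent] = field(default_factory=list)
    staircase_trace: list[tuple[str, float, bool]] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return len({t.trial_index for t in self.targets})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": [t.subject for t in self.targets],
                "trial": [t.trial_index for t in self.targets],
                "position": [t.position_id for t in self.targets],
                "onset_s": [t.onset for t in self.targets],
                "luminance": [t.luminance for t in self.targets],
                "phase_rad": [t.phase_at_onset for t in self.targets],
                "bin": [t.phase_bin for t in self.targets],
                "detected": [int(t.detected) for t in self.targets],
                "soa_ms": np.array(
                    [np.nan if t.soa_ms is None else t.soa_ms for t in self.targets]
                ),
                "disc_level": np.array(
                    [
                        np.nan if t.disc_level is None else t.disc_level
                        for t in self.targets
                    ]
                ),
            }
        )


def draw_target_count(probs: dict[int, float], rng: np.random.Generator, size=None):
    """Number of targets in a trial, drawn from ``probs`` (count -> probability)."""
    counts = np.array(sorted(probs))
    p = np.array([probs[int(c)] for c in counts], dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"malformed target-count distribution: {probs}")
    out = rng.choice(counts, size=size, p=p)
    return out if size is not None else int(out)


def draw_target_schedule(
    n: int, config: ExperimentConfig, rng: np.random.Generator
) -> np.ndarray:
    """Sorted onset times of ``n`` targets, uniform over the feasible set.

    Feasible onsets lie in ``[edge_margin, trial_duration - edge_margin]``
    with successive gaps >= ``min_gap``.  Sampling subtracts the mandatory
    gaps, draws order statistics of the uniform on the residual interval and
    adds the gaps back, which is exactly uniform on the constrained simplex.
    """
    lo = config.edge_margin
    hi = config.trial_duration - config.edge_margin
    slack = (hi - lo) - (n - 1) * config.min_gap
    if n < 1 or slack < 0:
        raise ValueError(
            f"cannot place {n} targets with {config.min_gap} s gaps "
            f"in [{lo}, {hi}] s"
        )
    u = np.sort(rng.uniform(0.0, slack, size=n))
    return lo + u + np.arange(n) * config.min_gap


def detection_probability(
    obs: ObserverModel, position_id: str, target_luminance, phi
) -> np.ndarray | float:
    """Probability of a hit for a target at ``position_id``.

    Logistic in log-luminance, cosine-gain modulated by phase; clipped to
    [0, 1].  At threshold luminance with zero modulation, zero guess and zero
    lapse the value is exactly 0.5.
    """
    theta = obs.threshold_per_position[position_id]
    m = obs.modulation_depth_per_position[position_id]
    phi_pref = obs.preferred_phase_per_position[position_id]
    L = np.asarray(target_luminance, dtype=float)
    x = obs.slope * (np.log(L) - np.log(theta))
    base = 1.0 / (1.0 + np.exp(-x))
    gain = 1.0 + 0.5 * m * np.cos(np.asarray(phi, dtype=float) - phi_pref)
    p = obs.guess_rate + (1.0 - obs.guess_rate - obs.lapse_rate) * base * gain
    p = np.clip(p, 0.0, 1.0)
    return p if np.ndim(p) else float(p)


def staircase_update(
    current_luminance: float, hit: bool, step: float = 1.1, ceiling: float = 255.0
) -> float:
    """Multiplicative 1-up/1-down update: divide on a hit, multiply on a miss
    (capped at ``ceiling``).  Equilibrium is the 50% detection point."""
    if not step > 1.0:
        raise ValueError(f"step must exceed 1, got {step}")
    if hit:
        return current_luminance / step
    return min(current_luminance * step, ceiling)


def _n_trials_for(config: ExperimentConfig, targets_per_cell: float) -> int:
    expected_count = sum(k * p for k, p in config.target_count_probs.items())
    total = targets_per_cell * config.n_phase_bins * len(config.positions)
    return max(1, int(round(total / expected_count)))


def simulate_experiment(
    config: ExperimentConfig,
    observer: ObserverModel,
    n_subjects: int,
    targets_per_cell: float = 33.0,
    rng: np.random.Generator | int | None = None,
    staircase_step: float = 1.1,
    staircase_start: float | None = None,
) -> list[SubjectDataset]:
    """Simulate ``n_subjects`` observers through the entrainment paradigm.

    Each trial lasts ``config.trial_duration`` s with 2-4 targets scheduled
    under the margin and gap rules; the disc starts each trial at a random
    phase, so target phases cover the cycle uniformly.  The number of trials
    is sized so the expected target count per (phase bin, position) cell is
    ``targets_per_cell`` (the study averaged ~33).  Target luminance follows
    an independent per-position staircase; outcomes are Bernoulli draws from
    :func:`detection_probability`.
    """
    rng = np.random.default_rng(rng)
    binning = config.binning
    position_ids = config.position_ids
    n_trials = _n_trials_for(config, targets_per_cell)
    datasets = []
    for s in range(n_subjects):
        subject = f"S{s + 1:02d}"
        staircase = {
            pid: (
                staircase_start
                if staircase_start is not None
                else observer.threshold_per_position[pid]
            )
            for pid in position_ids
        }
        ds = SubjectDataset(subject, config.entrainment_frequency)
        for trial in range(n_trials):
            n_targets = draw_target_count(config.target_count_probs, rng)
            onsets = draw_target_schedule(n_targets, config, rng)
            phase_offset = rng.uniform(-np.pi, np.pi)
            pids = rng.choice(position_ids, size=n_targets)
            for onset, pid in zip(onsets, pids):
                phi = float(
                    phase_at_time(onset, config.entrainment_frequency, phase_offset)
                )
                L = staircase[pid]
                p = detection_probability(observer, pid, L, phi)
                hit = bool(rng.random() < p)
                ds.targets.append(
                    TargetEvent(
                        subject=subject,
                        trial_index=trial,
                        position_id=str(pid),
                        onset=float(onset),
                        luminance=float(L),
                        phase_at_onset=phi,
                        phase_bin=assign_phase_bin(phi, binning),
                        detected=hit,
                    )
                )
                ds.staircase_trace.append((str(pid), float(L), hit))
                staircase[pid] = staircase_update(L, hit, staircase_step)
        datasets.append(ds)
    return datasets


def simulate_soa_control(
    config: ExperimentConfig,
    observer: ObserverModel,
    n_subjects: int,
    targets_per_level: float = 30.0,
    rng: np.random.Generator | int | None = None,
    soa_modulation: float = 0.0,
    soa_preferred_phase: float = 0.0,
    staircase_step: float = 1.1,
) -> list[SubjectDataset]:
    """Masking control: the disc is flashed once at full luminance and each
    target is offset from the flash by an SOA from the nine-point grid.

    Detection follows the same psychometric model with the cosine gain driven
    by the SOA-mapped phase and depth ``soa_modulation`` (0 under the no-
    masking null).  Stored phases use :func:`soa_to_phase`.
    """
    rng = np.random.default_rng(rng)
    position_ids = config.position_ids
    grid = np.array(SOA_GRID_MS)
    n_targets_total = int(round(targets_per_level * len(grid) * len(position_ids)))
    datasets = []
    base_obs = replace(
        observer,
        modulation_depth_per_position={
            pid: soa_modulation for pid in observer.modulation_depth_per_position
        },
        preferred_phase_per_position={
            pid: soa_preferred_phase for pid in observer.preferred_phase_per_position
        },
    )
    binning = config.binning
    for s in range(n_subjects):
        subject = f"S{s + 1:02d}"
        staircase = {pid: observer.threshold_per_position[pid] for pid in position_ids}
        ds = SubjectDataset(subject, config.entrainment_frequency)
        soas = rng.choice(grid, size=n_targets_total)
        pids = rng.choice(position_ids, size=n_targets_total)
        for i, (soa, pid) in enumerate(zip(soas, pids)):
            phi = soa_to_phase(float(soa))
            L = staircase[pid]
            p = detection_probability(base_obs, pid, L, wrap_phase(phi))
            hit = bool(rng.random() < p)
            ds.targets.append(
                TargetEvent(
                    subject=subject,
                    trial_index=i,
                    position_id=str(pid),
                    onset=config.edge_margin,
                    luminance=float(L),
                    phase_at_onset=float(wrap_phase(phi)),
                    phase_bin=assign_phase_bin(phi, binning),
                    detected=hit,
                    soa_ms=float(soa),
                )
            )
            ds.staircase_trace.append((str(pid), float(L), hit))
            staircase[pid] = staircase_update(L, hit, staircase_step)
        datasets.append(ds)
    return datasets


def simulate_luminance_control(
    config: ExperimentConfig,
    observer: ObserverModel,
    n_subjects: int,
    targets_per_level: float = 60.0,
    rng: np.random.Generator | int | None = None,
    level_effect: float = 0.0,
    staircase_step: float = 1.1,
) -> list[SubjectDataset]:
    """Luminance control: the disc is flashed simultaneously with each target
    at one of four luminance levels.

    ``level_effect`` linearly tilts detection probability with disc level
    (positive values: brighter flash masks more), scaled so it is the
    hit-rate difference between the extreme levels.
    """
    rng = np.random.default_rng(rng)
    position_ids = config.position_ids
    levels = np.array(LUMINANCE_LEVELS, dtype=float)
    n_targets_total = int(round(targets_per_level * len(levels) * len(position_ids)))
    null_obs = observer.with_zero_modulation()
    datasets = []
    for s in range(n_subjects):
        subject = f"S{s + 1:02d}"
        staircase = {pid: observer.threshold_per_position[pid] for pid in position_ids}
        ds = SubjectDataset(subject, config.entrainment_frequency)
        lvls = rng.choice(levels, size=n_targets_total)
        pids = rng.choice(position_ids, size=n_targets_total)
        span = levels.max() - levels.min()
        for i, (lvl, pid) in enumerate(zip(lvls, pids)):
            L = staircase[pid]
            p = detection_probability(null_obs, pid, L, 0.0)
            p = float(np.clip(p - level_effect * (lvl - levels.mean()) / span, 0.0, 1.0))
            hit = bool(rng.random() < p)
            ds.targets.append(
                TargetEvent(
                    subject=subject,
                    trial_index=i,
                    position_id=str(pid),
                    onset=config.edge_margin,
                    luminance=float(L),
                    phase_at_onset=0.0,
                    phase_bin=0,
                    detected=hit,
                    disc_level=float(lvl),
                )
            )
            ds.staircase_trace.append((str(pid), float(L), hit))
            staircase[pid] = staircase_update(L, hit, staircase_step)
        datasets.append(ds)
    return datasets
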