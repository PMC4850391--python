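"""Reading and writing target tables and run configurations.

Target tables are tab-separated text with a one-line header; angles are
radians in [-pi, pi), onsets in seconds, SOAs in milliseconds, luminance on
the 0-255 scale.  A JSON sidecar (``<table>.meta.json``) records the
entrainment frequency and the timing/binning constants needed to re-validate
the rows on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import ExperimentConfig, PhaseBinning, Position, assign_phase_bin
from .observer import ObserverModel, SubjectDataset, TargetEvent

__all__ = [
    "write_targets",
    "read_targets",
    "load_config",
    "observer_from_config",
]

_COLUMNS = [
    "subject",
    "trial",
    "position",
    "onset_s",
    "luminance",
    "phase_rad",
    "bin",
    "detected",
    "soa_ms",
    "disc_level",
]


def write_targets(
    datasets: list[SubjectDataset], path, config: ExperimentConfig | None = None
) -> Path:
    """Write all subjects' target events to one TSV; returns the path.

    A ``.meta.json`` sidecar stores frequency and validation constants.
    """
    path = Path(path)
    frames = [ds.to_frame() for ds in datasets]
    table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=_COLUMNS)
    )
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")
    meta = {
        "entrainment_frequency": datasets[0].entrainment_frequency if datasets else None,
        "n_subjects": len(datasets),
    }
    if config is not None:
        meta.update(
            trial_duration=config.trial_duration,
            edge_margin=config.edge_margin,
            min_gap=config.min_gap,
            n_phase_bins=config.n_phase_bins,
        )
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))
    return path


class TargetTableError(ValueError):
    """Malformed or invariant-violating target table."""


def read_targets(path, config: ExperimentConfig | None = None) -> list[SubjectDataset]:
    """Read a target table back into :class:`SubjectDataset` objects.

    When ``config`` is given (or a sidecar provides the constants), each row
    is checked against the timing and binning invariants; violations raise
    :class:`TargetTableError` naming the offending row (1-based, excluding
    the header).
    """
    import warnings

    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path} is empty: returning no datasets", stacklevel=2)
        return []
    missing = [c for c in _COLUMNS[:8] if c not in table.columns]
    if missing:
        raise TargetTableError(f"{path}: missing column(s) {missing}")
    if table.empty:
        warnings.warn(f"{path} has no rows: returning no datasets", stacklevel=2)
        return []

    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    frequency = meta.get("entrainment_frequency")
    if config is not None:
        dur = config.trial_duration
        margin = config.edge_margin
        gap = config.min_gap
        binning = config.binning
        frequency = frequency or config.entrainment_frequency
    elif {"trial_duration", "edge_margin", "min_gap", "n_phase_bins"} <= meta.keys():
        dur, margin, gap = meta["trial_duration"], meta["edge_margin"], meta["min_gap"]
        binning = PhaseBinning(meta["n_phase_bins"])
    else:
        dur = margin = gap = binning = None

    datasets: dict[str, SubjectDataset] = {}
    is_control = table["soa_ms"].notna().any() if "soa_ms" in table else False
    is_lum_control = table["disc_level"].notna().any() if "disc_level" in table else False
    for i, row in enumerate(table.itertuples(index=False), start=1):
        if dur is not None and not is_control and not is_lum_control:
            if not margin - 1e-9 <= row.onset_s <= dur - margin + 1e-9:
                raise TargetTableError(
                    f"{path} row {i}: onset {row.onset_s} s outside "
                    f"[{margin}, {dur - margin}] s"
                )
            if int(row.bin) != assign_phase_bin(row.phase_rad, binning):
                raise TargetTableError(
                    f"{path} row {i}: bin {row.bin} inconsistent with phase "
                    f"{row.phase_rad}"
                )
        if not 0 <= row.detected <= 1:
            raise TargetTableError(f"{path} row {i}: detected must be 0/1")
        ds = datasets.setdefault(
            str(row.subject),
            SubjectDataset(str(row.subject), float(frequency or np.nan)),
        )
        ds.targets.append(
            TargetEvent(
                subject=str(row.subject),
                trial_index=int(row.trial),
                position_id=str(row.position),
                onset=float(row.onset_s),
                luminance=float(row.luminance),
                phase_at_onset=float(row.phase_rad),
                phase_bin=int(row.bin),
                detected=bool(row.detected),
                soa_ms=None if pd.isna(getattr(row, "soa_ms", np.nan)) else float(row.soa_ms),
                disc_level=None
                if pd.isna(getattr(row, "disc_level", np.nan))
                else float(row.disc_level),
            )
        )
    if dur is not None and gap is not None and not is_control and not is_lum_control:
        for ds in datasets.values():
            by_trial: dict[int, list[float]] = {}
            for t in ds.targets:
                by_trial.setdefault(t.trial_index, []).append(t.onset)
            for trial, onsets in by_trial.items():
                onsets = sorted(onsets)
                gaps = np.diff(onsets)
                if len(gaps) and gaps.min() < gap - 1e-9:
                    raise TargetTableError(
                        f"{path}: subject {ds.subject} trial {trial} violates the "
                        f"{gap} s minimum gap"
                    )
    return list(datasets.values())


def load_config(path) -> dict:
    """Load a YAML run configuration into plain sections.

    Returns a dict with keys ``experiment`` (an :class:`ExperimentConfig`),
    ``observer`` (raw mapping or None) and ``run`` (raw mapping).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    exp = dict(raw.get("experiment", {}))
    if "positions" in exp:
        exp["positions"] = [Position(**p) for p in exp["positions"]]
    if "target_count_probs" in exp:
        exp["target_count_probs"] = {
            int(k): float(v) for k, v in exp["target_count_probs"].items()
        }
    try:
        config = ExperimentConfig(**exp)
    except TypeError as err:
        raise ValueError(f"invalid experiment config key: {err}") from err
    return {
        "experiment": config,
        "observer": raw.get("observer"),
        "run": dict(raw.get("run", {})),
    }


def observer_from_config(config: ExperimentConfig, observer_section: dict | None) -> ObserverModel:
    """Build the generative observer from the ``observer`` config section."""
    from .observer import default_observer

    if not observer_section:
        return default_observer(config)
    sec = dict(observer_section)
    kwargs = {
        k: sec.pop(k)
        for k in ("slope", "guess_rate", "lapse_rate")
        if k in sec
    }
    return ObserverModel.from_local_global(
        config.positions,
        sec.pop("depths", list(np.full(len(config.positions), 0.4))),
        global_phase=float(sec.pop("global_phase", -3 * np.pi / 4)),
        local_phase=float(sec.pop("local_phase", -np.pi / 4)),
        threshold=float(sec.pop("threshold", 100.0)),
        **kwargs,
    )
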