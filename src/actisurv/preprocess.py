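"""Raw actigraphy to fixed-length model inputs.

The processing chain is fixed in order: truncate each recording to the
analysis horizon (first 24 or 48 h of admission), screen eligibility
(recordings shorter than the horizon or with a tracking interruption longer
than the gap tolerance are excluded), average each channel over consecutive
non-overlapping blocks of samples, and zero-pad the block-averaged sequences
to a common length for batched training.  Dataset splitting is stratified by
outcome with a floor rule per class.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .simulate import ActigraphySeries, PatientMeta

__all__ = [
    "PreprocessConfig",
    "ProcessedTensor",
    "SplitAssignment",
    "truncate_to_horizon",
    "is_eligible",
    "block_average",
    "pad_batch",
    "split_dataset",
    "process_cohort",
    "write_tensors_csv",
    "write_splits_csv",
    "read_splits_csv",
]

PARTITIONS = ("train", "validation", "test")


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing parameters.

    horizon_h
        Analysis horizon in hours from admission (24 or 48 in practice).
    block_window
        Number of consecutive samples averaged into one model timestep.
    max_gap_tolerance_min
        Longest tolerated contiguous off-wrist/missing run, in minutes;
        anything longer counts as a tracking interruption and excludes the
        recording.
    pad_value
        Value used to fill padded timesteps (zero-padding by default).
    pad_position
        "end" pads after the observed data (default, keeps the clinically
        earliest data at fixed positions); "front" is available for
        sensitivity checks.
    offwrist_as_zero
        If True, off-wrist samples enter block means as zero activity instead
        of being excluded from the mean.
    """

    horizon_h: float = 48.0
    block_window: int = 20
    max_gap_tolerance_min: float = 60.0
    pad_value: float = 0.0
    pad_position: str = "end"
    offwrist_as_zero: bool = False

    def __post_init__(self) -> None:
        if self.horizon_h <= 0:
            raise ValueError("horizon_h must be positive")
        if self.block_window < 1:
            raise ValueError("block_window must be >= 1")
        if self.max_gap_tolerance_min < 0:
            raise ValueError("max_gap_tolerance_min must be nonnegative")
        if self.pad_position not in ("end", "front"):
            raise ValueError("pad_position must be 'end' or 'front'")


@dataclass
class ProcessedTensor:
    """Fixed-length block-averaged model input for one patient.

    ``values`` has shape (length, 3) with channels (activity, angle, spin);
    ``valid_length`` counts the timesteps actually observed — rows beyond it
    (or before it, under front-padding) hold the pad value.
    """

    patient_id: str
    values: np.ndarray
    valid_length: int
    label: Optional[int] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 2 or self.values.shape[1] != 3:
            raise ValueError("values must have shape (length, 3)")
        if not 0 <= self.valid_length <= len(self.values):
            raise ValueError("valid_length must lie in [0, padded_length]")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class SplitAssignment:
    """Mapping patient_id -> partition in {train, validation, test}."""

    assignment: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {p for p in self.assignment.values() if p not in PARTITIONS}
        if bad:
            raise ValueError(f"unknown partitions: {sorted(bad)}")

    def ids(self, partition: str) -> list[str]:
        return sorted(k for k, v in self.assignment.items() if v == partition)

    def counts(self) -> dict[str, int]:
        return {p: len(self.ids(p)) for p in PARTITIONS}


def truncate_to_horizon(
    series: ActigraphySeries, cfg: PreprocessConfig
) -> ActigraphySeries:
    """Keep only samples in [start_time, start_time + horizon_h).

    Recordings shorter than the horizon pass through unchanged; exclusion is
    the eligibility screen's job.
    """
    if len(series) == 0:
        raise ValueError("series is empty")
    n_keep = int(math.ceil(cfg.horizon_h * 3600.0 / series.interval_s))
    if n_keep >= len(series):
        return series
    return ActigraphySeries(
        patient_id=series.patient_id,
        start_time=series.start_time,
        interval_s=series.interval_s,
        activity=series.activity[:n_keep],
        angle=series.angle[:n_keep],
        spin=series.spin[:n_keep],
        worn=series.worn[:n_keep],
    )


def _longest_gap_min(series: ActigraphySeries) -> float:
    """Longest contiguous not-worn (or missing-activity) run, in minutes."""
    missing = ~series.worn | ~np.isfinite(series.activity)
    if not missing.any():
        return 0.0
    # run-length encode the missing mask
    padded = np.concatenate(([False], missing, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    run_lengths = edges[1::2] - edges[0::2]
    return float(run_lengths.max()) * series.interval_s / 60.0


def is_eligible(
    series: ActigraphySeries, cfg: PreprocessConfig
) -> tuple[bool, str]:
    """Eligibility screen applied after horizon truncation.

    A recording is eligible iff its span covers the full horizon ("data
    volume" rule) and no contiguous off-wrist/missing run within the horizon
    exceeds the gap tolerance ("tracking interruption" rule).  Returns
    (eligible, reason); the reason names the failed rule.
    """
    window = truncate_to_horizon(series, cfg)
    if window.duration_h < cfg.horizon_h:
        return False, (
            f"data volume below horizon ({window.duration_h:.1f} h < "
            f"{cfg.horizon_h:g} h)"
        )
    gap = _longest_gap_min(window)
    if gap > cfg.max_gap_tolerance_min:
        return False, (
            f"tracking interruption ({gap:.0f} min gap > "
            f"{cfg.max_gap_tolerance_min:g} min tolerance)"
        )
    return True, "eligible"


def block_average(
    series: ActigraphySeries, cfg: PreprocessConfig
) -> ProcessedTensor:
    """Average each channel over non-overlapping windows of block_window samples.

    A trailing partial window is averaged over its actual sample count.
    Off-wrist samples are excluded from window means (a fully off-wrist
    window yields the pad value) unless ``cfg.offwrist_as_zero`` maps them to
    zero activity instead.
    """
    n = len(series)
    if n == 0:
        raise ValueError("series is empty")
    w = cfg.block_window
    n_windows = math.ceil(n / w)
    stacked = np.column_stack(
        [
            np.asarray(series.activity, dtype=np.float64),
            np.asarray(series.angle, dtype=np.float64),
            np.asarray(series.spin, dtype=np.float64),
        ]
    )
    if cfg.offwrist_as_zero:
        stacked[~series.worn] = 0.0
    pad_rows = n_windows * w - n
    if pad_rows:
        stacked = np.vstack([stacked, np.full((pad_rows, 3), np.nan)])
    blocks = stacked.reshape(n_windows, w, 3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)  # all-NaN windows
        means = np.nanmean(blocks, axis=1)
    means[~np.isfinite(means)] = cfg.pad_value
    return ProcessedTensor(
        patient_id=series.patient_id,
        values=means.astype(np.float32),
        valid_length=n_windows,
    )


def pad_batch(
    tensors: Sequence[ProcessedTensor], cfg: PreprocessConfig
) -> list[ProcessedTensor]:
    """Pad every tensor to the batch's maximum valid_length with pad_value.

    Padding goes at the end of each sequence (or the front, per config);
    valid_length is preserved.
    """
    if not tensors:
        raise ValueError("tensor list is empty")
    target = max(len(t) for t in tensors)
    out = []
    for t in tensors:
        deficit = target - len(t)
        if deficit == 0:
            out.append(t)
            continue
        pad = np.full((deficit, 3), cfg.pad_value, dtype=np.float32)
        if cfg.pad_position == "end":
            values = np.vstack([t.values, pad])
        else:
            values = np.vstack([pad, t.values])
        out.append(
            ProcessedTensor(
                patient_id=t.patient_id,
                values=values,
                valid_length=t.valid_length,
                label=t.label,
            )
        )
    return out


def split_dataset(
    labels: dict[str, int],
    ratios: Sequence[float],
    seed: int,
    override: Optional[dict[int, tuple[int, int, int]]] = None,
) -> SplitAssignment:
    """Stratified train/validation/test split with a per-class floor rule.

    Each class contributes floor(ratio * n_class) patients to train, then
    floor(ratio * n_class) to validation (three-way ratios only), and the
    remainder to test.  Within-class assignment is randomised by ``seed``.
    ``override`` maps class label -> explicit (train, validation, test)
    counts and reproduces splits that do not follow the floor rule.
    """
    if len(ratios) not in (2, 3):
        raise ValueError("ratios must have length 2 (train,test) or 3 (train,val,test)")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    if any(r < 0 for r in ratios):
        raise ValueError("ratios must be nonnegative")
    classes = sorted(set(labels.values()))
    if not classes:
        raise ValueError("labels is empty")
    three_way = len(ratios) == 3

    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for cls in classes:
        ids = sorted(pid for pid, lab in labels.items() if lab == cls)
        rng.shuffle(ids)
        n_cls = len(ids)
        if override is not None:
            if cls not in override:
                raise ValueError(f"override missing class {cls}")
            n_train, n_val, n_test = override[cls]
            if n_train + n_val + n_test != n_cls:
                raise ValueError(
                    f"override counts for class {cls} sum to "
                    f"{n_train + n_val + n_test}, expected {n_cls}"
                )
        else:
            n_train = math.floor(ratios[0] * n_cls)
            n_val = math.floor(ratios[1] * n_cls) if three_way else 0
            n_test = n_cls - n_train - n_val
        for pid in ids[:n_train]:
            assignment[pid] = "train"
        for pid in ids[n_train : n_train + n_val]:
            assignment[pid] = "validation"
        for pid in ids[n_train + n_val :]:
            assignment[pid] = "test"

    split = SplitAssignment(assignment)
    wanted = ["train", "test"]
    if three_way and override is None:
        wanted.insert(1, "validation")
    for part in wanted:
        if not split.ids(part):
            warnings.warn(f"partition '{part}' is empty", stacklevel=2)
    return split


def process_cohort(
    cohort: Sequence[tuple[ActigraphySeries, PatientMeta]],
    cfg: PreprocessConfig,
) -> tuple[list[ProcessedTensor], dict[str, str]]:
    """Full chain for a cohort: truncate, screen, block-average, pad.

    Returns the padded tensors (labels attached from metadata) and a mapping
    patient_id -> exclusion reason for the screened-out recordings.
    """
    tensors: list[ProcessedTensor] = []
    excluded: dict[str, str] = {}
    for series, meta in cohort:
        window = truncate_to_horizon(series, cfg)
        ok, reason = is_eligible(series, cfg)
        if not ok:
            excluded[meta.patient_id] = reason
            continue
        tensor = block_average(window, cfg)
        tensor.label = meta.outcome
        tensors.append(tensor)
    if not tensors:
        raise ValueError("no eligible recordings in cohort")
    return pad_batch(tensors, cfg), excluded


# ---------------------------------------------------------------------------
# on-disk formats


def write_tensors_csv(tensors: Sequence[ProcessedTensor], path: str | Path) -> None:
    """Long-format CSV `patient_id,timestep,activity,angle,spin` (padded rows included)."""
    frames = []
    for t in tensors:
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": t.patient_id,
                    "timestep": np.arange(len(t)),
                    "activity": t.values[:, 0],
                    "angle": t.values[:, 1],
                    "spin": t.values[:, 2],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_splits_csv(split: SplitAssignment, path: str | Path) -> None:
    df = pd.DataFrame(
        sorted(split.assignment.items()), columns=["patient_id", "partition"]
    )
    df.to_csv(path, index=False)


def read_splits_csv(path: str | Path) -> SplitAssignment:
    df = pd.read_csv(path)
    return SplitAssignment(dict(zip(df["patient_id"].astype(str), df["partition"])))
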