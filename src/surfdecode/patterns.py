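"""From voxel time series to per-block multivoxel response patterns.

The prescribed order of operations: z-score each selected voxel's time
series within a run (population SD), shift the series 4 s to absorb the
hemodynamic delay, average over the 8 volumes of each experimental
block, and remove baseline differences by subtracting the mean pattern
(per run by default, or globally).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .synth import AIR_OFF, FIXATION, BlockSchedule, RunData

NON_PATTERN_LABELS = (FIXATION, AIR_OFF)


@dataclass
class PatternSet:
    """Per-block multivoxel response vectors with their labels.

    ``X`` is patterns x voxels; ``conditions``, ``runs`` and
    ``block_indices`` are parallel arrays. ``voxel_indices`` records
    which voxels of the source grid the columns refer to.
    """

    X: np.ndarray
    conditions: np.ndarray
    runs: np.ndarray
    block_indices: np.ndarray
    voxel_indices: np.ndarray
    centered: bool = False

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.conditions = np.asarray(self.conditions)
        self.runs = np.asarray(self.runs, dtype=int)
        self.block_indices = np.asarray(self.block_indices, dtype=int)
        n = self.X.shape[0]
        if not (len(self.conditions) == len(self.runs) == len(self.block_indices) == n):
            raise ValueError("label arrays must match the number of patterns")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("patterns contain non-finite values")

    @property
    def n_patterns(self) -> int:
        return self.X.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.X.shape[1]

    def subset_voxels(self, cols: np.ndarray) -> "PatternSet":
        cols = np.asarray(cols, dtype=int)
        return replace(
            self, X=self.X[:, cols], voxel_indices=self.voxel_indices[cols]
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "run_id": self.runs,
                "block_index": self.block_indices,
                "condition": self.conditions,
            }
        )
        vox = pd.DataFrame(
            self.X, columns=[f"v{int(i)}" for i in self.voxel_indices]
        )
        return pd.concat([df, vox], axis=1)


def zscore_timeseries(
    run: RunData, voxel_indices: np.ndarray | None = None
) -> np.ndarray:
    """Per-voxel z-scored time series (mean 0, population SD 1) for one run."""
    if run.n_volumes < 2:
        raise ValueError("need at least 2 volumes to z-score")
    idx = (
        np.arange(run.n_voxels)
        if voxel_indices is None
        else np.asarray(voxel_indices, dtype=int)
    )
    x = run.signal[idx]
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)  # population (1/N) convention
    flat = np.flatnonzero(sd[:, 0] == 0)
    if len(flat):
        raise ValueError(
            f"zero-variance voxel(s) {idx[flat].tolist()} cannot be z-scored; "
            "drop them before extraction"
        )
    return (x - mu) / sd


def extract_block_patterns(
    series: np.ndarray,
    schedule: BlockSchedule,
    tr: float = 2.0,
    shift_s: float = 4.0,
    window_volumes: int = 8,
    voxel_indices: np.ndarray | None = None,
    run_id: int | None = None,
) -> PatternSet:
    """One pattern per experimental block: the per-voxel mean over
    volumes [onset + shift, onset + shift + window).

    ``series`` is voxels x volumes (typically the z-scored run).
    Fixation (and air-off) blocks yield no pattern. The shift must be a
    whole number of volumes and every window must fall inside the run.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    shift = shift_s / tr
    if abs(shift - round(shift)) > 1e-9:
        raise ValueError(f"shift_s={shift_s} is not divisible by tr={tr}")
    shift_vol = int(round(shift))
    T = series.shape[1]
    if T != schedule.n_volumes:
        raise ValueError(
            f"series has {T} volumes but the schedule spans {schedule.n_volumes}"
        )

    rows, conds, blocks = [], [], []
    for bi, b in enumerate(schedule.blocks):
        if b.label in NON_PATTERN_LABELS:
            continue
        start = b.onset_volume + shift_vol
        stop = start + window_volumes
        if stop > T:
            raise ValueError(
                f"shifted window [{start}, {stop}) for block {bi} "
                f"({b.label}) exceeds the run length {T}"
            )
        rows.append(series[:, start:stop].mean(axis=1))
        conds.append(b.label)
        blocks.append(bi)

    rid = schedule.run_id if run_id is None else run_id
    return PatternSet(
        X=np.array(rows),
        conditions=np.array(conds),
        runs=np.full(len(rows), rid),
        block_indices=np.array(blocks),
        voxel_indices=(
            np.arange(series.shape[0])
            if voxel_indices is None
            else np.asarray(voxel_indices, dtype=int)
        ),
    )


def concat_patterns(sets: list[PatternSet]) -> PatternSet:
    """Stack per-run pattern sets (same voxel columns) into one set."""
    if not sets:
        raise ValueError("nothing to concatenate")
    first = sets[0]
    for s in sets[1:]:
        if not np.array_equal(s.voxel_indices, first.voxel_indices):
            raise ValueError("pattern sets cover different voxels")
    return PatternSet(
        X=np.vstack([s.X for s in sets]),
        conditions=np.concatenate([s.conditions for s in sets]),
        runs=np.concatenate([s.runs for s in sets]),
        block_indices=np.concatenate([s.block_indices for s in sets]),
        voxel_indices=first.voxel_indices,
        centered=all(s.centered for s in sets),
    )


def center_patterns(ps: PatternSet, scope: str = "per_run") -> PatternSet:
    """Subtract the mean pattern vector within each scope group.

    ``per_run`` removes each run's mean pattern (run-baseline removal);
    ``global`` subtracts the grand mean pattern. Idempotent.
    """
    X = ps.X.copy()
    if scope == "per_run":
        for r in np.unique(ps.runs):
            m = ps.runs == r
            X[m] -= X[m].mean(axis=0, keepdims=True)
    elif scope == "global":
        X -= X.mean(axis=0, keepdims=True)
    else:
        raise ValueError(f"unknown centering scope {scope!r}")
    return replace(ps, X=X, centered=True)


def run_to_patterns(
    run: RunData,
    voxel_indices: np.ndarray | None = None,
    tr: float = 2.0,
    shift_s: float = 4.0,
    window_volumes: int = 8,
) -> PatternSet:
    """Convenience: z-score a run's selected voxels and extract block
    patterns (centering is applied later, across whatever grouping the
    caller chooses)."""
    z = zscore_timeseries(run, voxel_indices)
    return extract_block_patterns(
        z,
        run.schedule,
        tr=tr,
        shift_s=shift_s,
        window_volumes=window_volumes,
        voxel_indices=voxel_indices,
        run_id=run.run_id,
    )
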