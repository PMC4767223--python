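"""Run-level quality control: global-signal variance exclusion.

A run's global signal is the mean BOLD signal across voxels at each
volume. It is converted to percent signal change around its temporal
mean, and the variance (in squared percent) of that time course is the
QC statistic. Runs whose variance exceeds the threshold (default
0.23 %^2 on the percent-change scale, the only scale-free reading of the
criterion) are excluded. The statistic is invariant to rescaling the raw
signal, so exclusion does not depend on scanner units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .synth import RunData

DEFAULT_THRESHOLD = 0.23


def global_signal_variance(run: RunData) -> float:
    """Variance over time of the percent-signal-change global time course.

    g(t) = 100 * (gbar(t) - mean(gbar)) / mean(gbar), with gbar(t) the
    mean over voxels at volume t; returns var(g) with the population
    (1/N) denominator, in %^2.
    """
    if run.n_volumes < 2:
        raise ValueError("need at least 2 volumes to compute a variance")
    g = run.signal.mean(axis=0)
    m = g.mean()
    if m == 0:
        raise ValueError("global signal has zero mean; percent change undefined")
    pct = 100.0 * (g - m) / m
    return float(pct.var())


@dataclass
class QCEntry:
    run_id: int
    participant_id: int
    global_signal_variance: float
    excluded: bool


@dataclass
class QCReport:
    threshold: float
    entries: list[QCEntry] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "participant_id": e.participant_id,
                    "run_id": e.run_id,
                    "global_signal_variance": e.global_signal_variance,
                    "excluded": e.excluded,
                }
                for e in self.entries
            ]
        )

    @property
    def n_excluded(self) -> int:
        return sum(e.excluded for e in self.entries)


def exclude_runs(
    runs: list[RunData], threshold: float = DEFAULT_THRESHOLD
) -> tuple[list[RunData], QCReport]:
    """Partition runs by the global-signal-variance criterion.

    Runs with variance strictly above ``threshold`` are excluded; the
    report lists every run. Raises if the threshold is non-positive or
    if no run survives (the pipeline cannot proceed without data).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    report = QCReport(threshold=threshold)
    kept: list[RunData] = []
    for run in runs:
        v = global_signal_variance(run)
        excl = bool(v > threshold)
        report.entries.append(
            QCEntry(run.run_id, run.participant_id, v, excl)
        )
        if not excl:
            kept.append(run)
    if not kept:
        raise ValueError(
            f"all {len(runs)} runs exceed the QC threshold {threshold}; "
            "nothing left to analyse"
        )
    return kept, report
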