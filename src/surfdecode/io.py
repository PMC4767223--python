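"""Serialisation: schedules as JSON, runs as NIfTI, tables as CSV/PNG.

Simulated runs are written as 4-D NIfTI volumes (voxels laid out along
the first axis of a Nx1x1xT grid — the pipeline is ROI-based, so no
spatial structure is implied) with the block schedule as a JSON
sidecar. Stimulus images round-trip through 8-bit PNG.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

from .qc import QCReport
from .synth import Block, BlockSchedule, RunData


def schedule_to_dict(schedule: BlockSchedule) -> dict:
    return {
        "run_id": schedule.run_id,
        "blocks": [asdict(b) for b in schedule.blocks],
    }


def schedule_from_dict(d: dict) -> BlockSchedule:
    return BlockSchedule(
        blocks=tuple(Block(**b) for b in d["blocks"]),
        run_id=d.get("run_id", 0),
    )


def save_schedule(schedule: BlockSchedule, path: str | Path) -> None:
    Path(path).write_text(json.dumps(schedule_to_dict(schedule), indent=1))


def load_schedule(path: str | Path) -> BlockSchedule:
    return schedule_from_dict(json.loads(Path(path).read_text()))


def save_run_nifti(run: RunData, path: str | Path) -> None:
    """Write a run as NIfTI (voxels x 1 x 1 x volumes) plus a schedule
    sidecar ``<path>.json``."""
    path = Path(path)
    data = run.signal[:, None, None, :].astype(np.float32)
    img = nib.Nifti1Image(data, affine=np.eye(4))
    img.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(img, str(path))
    sidecar = schedule_to_dict(run.schedule)
    sidecar["participant_id"] = run.participant_id
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def load_run_nifti(path: str | Path) -> RunData:
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)[:, 0, 0, :]
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    pid = sidecar.pop("participant_id", 0)
    schedule = schedule_from_dict(sidecar)
    return RunData(data, schedule, participant_id=pid, run_id=schedule.run_id)


def save_qc_report(report: QCReport, path: str | Path) -> None:
    report.to_frame().to_csv(path, index=False)


def save_image_png(img: np.ndarray, path: str | Path) -> None:
    """Write a [0, 1] float image as 8-bit grayscale PNG."""
    a = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)
    iio.imwrite(Path(path), (a * 255).round().astype(np.uint8))


def load_image_png(path: str | Path) -> np.ndarray:
    """Read a grayscale PNG back to [0, 1] floats."""
    a = np.asarray(iio.imread(Path(path)), dtype=float)
    if a.ndim == 3:  # collapse any colour channels
        a = a.mean(axis=2)
    return a / 255.0
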