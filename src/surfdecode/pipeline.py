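"""Participant-level wiring of the full analysis chain.

For one participant: QC-filter the runs, fit the concatenated-run GLM,
select voxels on the all-conditions-vs-fixation contrast (or the air
localiser contrast for somatosensory-style ROIs), z-score and extract
block patterns, center them per run, and assemble the labelled dataset
for a contrast. These helpers exist so scripts, tests and the
acceptance run all exercise one code path.
"""

from __future__ import annotations

import numpy as np

from . import glm as glm_mod
from . import qc as qc_mod
from .decode import ContrastSpec, Dataset
from .patterns import center_patterns, concat_patterns, run_to_patterns
from .synth import ParticipantData


def select_participant_voxels(
    runs,
    n_voxels: int = 250,
    hrf: str = "double_gamma",
    tr: float = 2.0,
) -> np.ndarray:
    """Top positive-t voxels for the all-conditions-vs-fixation contrast."""
    fit = glm_mod.fit_glm(runs, tr=tr, hrf=hrf)
    sel = glm_mod.select_voxels(
        fit,
        glm_mod.task_vs_baseline_contrast(fit),
        mode="top_positive",
        n=n_voxels,
    )
    return sel.voxel_indices


def participant_dataset(
    participant: ParticipantData,
    contrast: ContrastSpec,
    n_voxels: int = 250,
    qc_threshold: float | None = qc_mod.DEFAULT_THRESHOLD,
    hrf: str = "double_gamma",
    tr: float = 2.0,
    shift_s: float = 4.0,
    window_volumes: int = 8,
    centering: str = "per_run",
) -> Dataset:
    """Full chain from one participant's raw runs to a decodable dataset."""
    runs = participant.runs
    if qc_threshold is not None:
        runs, _ = qc_mod.exclude_runs(runs, threshold=qc_threshold)
    vox = select_participant_voxels(runs, n_voxels=n_voxels, hrf=hrf, tr=tr)
    if len(vox) == 0:
        raise ValueError(
            f"participant {participant.participant_id}: no voxels selected"
        )
    sets = [
        run_to_patterns(r, vox, tr=tr, shift_s=shift_s,
                        window_volumes=window_volumes)
        for r in runs
    ]
    ps = center_patterns(concat_patterns(sets), scope=centering)
    from .decode import assemble_dataset

    return assemble_dataset(ps, contrast)


def study_datasets(
    participants: list[ParticipantData],
    contrast: ContrastSpec,
    **kwargs,
) -> list[Dataset]:
    """One assembled dataset per participant (shared pipeline settings)."""
    return [participant_dataset(p, contrast, **kwargs) for p in participants]


def null_boundary_experiment(
    contrast_name: str,
    n_participants: int = 16,
    n_runs: int = 9,
    n_perm: int = 1000,
    seed=None,
    n_voxels_sim: int = 100,
    n_voxels_select: int = 250,
):
    """End-to-end permutation-null baseline for one design and contrast.

    Simulates ``n_participants`` null participants (zero pattern
    amplitude, so labels carry no information), runs the full pipeline
    (QC, GLM voxel selection, pattern extraction, per-run centering,
    contrast assembly) and builds the shuffled-label null of the
    group-mean leave-one-run-out accuracy. Returns the
    ``NullDistribution`` whose ``boundary`` is the significance
    baseline plotted against decoding accuracies.
    """
    import numpy as np

    from .permute import permutation_null
    from .synth import DesignSpec, EffectSpec, simulate_study

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    sim_ss, perm_ss = ss.spawn(2)
    design = DesignSpec(n_runs=n_runs)
    effect = EffectSpec(n_voxels=n_voxels_sim, pattern_amplitude=0.0)
    study = simulate_study(design, effect, n_participants=n_participants,
                           seed=sim_ss)
    contrast = ContrastSpec.named(contrast_name)
    datasets = study_datasets(study, contrast, n_voxels=n_voxels_select)
    return permutation_null(datasets, n_perm=n_perm, seed=perm_ss,
                            contrast_name=contrast_name)
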