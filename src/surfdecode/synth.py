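"""Seeded generators for every input the decoding pipeline consumes.

The generator emulates a block-design visual fMRI study of surface
material perception: 368-s runs of 23 16-s blocks (7 fixation + 16
experimental blocks in four conditions — Glossy, Glossy Control, Rough,
Rough Control — four repeats each), TR = 2 s, four dummy volumes that
are generated and then discarded, a somatosensory air-puff localiser run
(10 on / 10 off blocks), 1-back task behaviour at a configurable d',
and procedural grayscale stimulus images whose statistics mirror the
four render classes.

The multivoxel effect is a condition-specific unit-norm spatial pattern
scaled in percent signal change, superimposed on a shared task response,
convolved with an HRF and embedded in AR(1) noise plus a slow
scanner-wide sinusoidal drift. A master seed expands deterministically
into participant / run / pattern streams, so every dataset is exactly
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, signal

from .hrf import hrf_kernel

CONDITIONS = ("G", "GC", "R", "RC")
FIXATION = "FIX"
AIR_ON = "AIR_ON"
AIR_OFF = "AIR_OFF"


# ---------------------------------------------------------------------------
# specs and containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignSpec:
    """Structural parameters of one experimental run.

    Defaults reproduce the study design: 16-s blocks, TR 2 s, four
    conditions repeated four times, fixation blocks interposed after the
    3rd, 5th, 8th, 11th and 13th stimulus blocks plus one leading and
    one trailing fixation block (23 blocks, 368 s, 184 volumes after
    removing 4 dummy volumes).
    """

    tr: float = 2.0
    block_len: float = 16.0
    n_dummy_volumes: int = 4
    conditions: tuple[str, ...] = CONDITIONS
    repeats_per_condition: int = 4
    fixation_positions: tuple[int, ...] = (3, 5, 8, 11, 13)  # 1-based stim index
    n_runs: int = 9
    stimuli_per_block: int = 16  # 15 unique + 1 repeat (the 1-back target)
    stim_on_ms: float = 500.0
    stim_off_ms: float = 500.0

    def __post_init__(self) -> None:
        ratio = self.block_len / self.tr
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"block_len ({self.block_len}) must be divisible by tr ({self.tr})"
            )
        if self.repeats_per_condition < 1 or self.n_runs < 1:
            raise ValueError("repeats_per_condition and n_runs must be >= 1")

    @property
    def volumes_per_block(self) -> int:
        return int(round(self.block_len / self.tr))

    @property
    def n_experimental_blocks(self) -> int:
        return len(self.conditions) * self.repeats_per_condition

    @property
    def n_fixation_blocks(self) -> int:
        return len(self.fixation_positions) + 2

    @property
    def n_blocks(self) -> int:
        return self.n_experimental_blocks + self.n_fixation_blocks

    @property
    def n_volumes(self) -> int:
        """Volumes per run after dummy removal."""
        return self.n_blocks * self.volumes_per_block

    @property
    def run_duration_s(self) -> float:
        return self.n_blocks * self.block_len


@dataclass(frozen=True)
class EffectSpec:
    """Amplitude and noise structure of the simulated BOLD response.

    ``pattern_amplitude`` and ``shared_amplitude`` are percent signal
    change relative to ``baseline``; ``noise_sd``, ``drift_amplitude``
    and ``baseline`` share raw signal units (baseline 100 makes one raw
    unit equal one percent). ``ar1_coef`` is the lag-1 autocorrelation of
    the stationary noise; ``drift_period`` is in seconds.
    """

    n_voxels: int = 100
    pattern_amplitude: float = 0.5
    shared_amplitude: float = 0.5
    noise_sd: float = 1.0
    ar1_coef: float = 0.3
    drift_amplitude: float = 0.3
    drift_period: float = 128.0
    baseline: float = 100.0
    hrf: str = "double_gamma"

    def __post_init__(self) -> None:
        if self.n_voxels < 1:
            raise ValueError("n_voxels must be >= 1")
        if not 0 <= self.ar1_coef < 1:
            raise ValueError("ar1_coef must lie in [0, 1)")
        if self.noise_sd < 0 or self.drift_amplitude < 0:
            raise ValueError("noise_sd and drift_amplitude must be >= 0")
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")


@dataclass(frozen=True)
class BehaviorSpec:
    """1-back task model: one target and 14 non-target decisions per block.

    Equal-variance signal-detection convention:
    P(hit) = Phi(d'/2 - criterion), P(false alarm) = Phi(-d'/2 - criterion).
    """

    true_dprime: float = 2.07
    criterion: float = 0.0
    targets_per_block: int = 1
    nontargets_per_block: int = 14


@dataclass(frozen=True)
class Block:
    label: str
    onset_volume: int  # 0-based, counted after dummy removal
    n_volumes: int


@dataclass(frozen=True)
class BlockSchedule:
    """Ordered, contiguous tiling of one run by labelled blocks."""

    blocks: tuple[Block, ...]
    run_id: int = 0

    def __post_init__(self) -> None:
        pos = 0
        for b in self.blocks:
            if b.onset_volume != pos:
                raise ValueError(
                    f"blocks must tile the run contiguously; block at "
                    f"{b.onset_volume} expected at {pos}"
                )
            pos += b.n_volumes

    @property
    def n_volumes(self) -> int:
        return sum(b.n_volumes for b in self.blocks)

    def blocks_with_label(self, *labels: str) -> tuple[Block, ...]:
        return tuple(b for b in self.blocks if b.label in labels)

    @property
    def experimental_blocks(self) -> tuple[Block, ...]:
        return tuple(
            b for b in self.blocks if b.label not in (FIXATION, AIR_OFF)
        )


@dataclass
class RunData:
    """Voxels x volumes signal matrix for one run plus its schedule."""

    signal: np.ndarray
    schedule: BlockSchedule
    participant_id: int = 0
    run_id: int = 0

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a voxels x volumes matrix")
        if self.signal.shape[1] != self.schedule.n_volumes:
            raise ValueError(
                f"signal has {self.signal.shape[1]} volumes but the schedule "
                f"spans {self.schedule.n_volumes}"
            )
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")

    @property
    def n_voxels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.signal.shape[1]


@dataclass
class BehaviorOutcome:
    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.hits, self.misses, self.false_alarms, self.correct_rejections)


@dataclass
class ParticipantData:
    """All simulated runs for one participant."""

    participant_id: int
    runs: list[RunData]
    localiser: RunData
    behavior: BehaviorOutcome
    condition_patterns: dict[str, np.ndarray] = field(repr=False, default_factory=dict)


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

def build_design(spec: DesignSpec, seed=None) -> BlockSchedule:
    """Build one run's block schedule with a pseudo-random condition order.

    The condition sequence is a seeded shuffle of ``repeats_per_condition``
    copies of each condition; fixation blocks are interposed after the
    configured (1-based) stimulus-block positions, plus one leading and
    one trailing fixation block.
    """
    rng = np.random.default_rng(seed)
    order = np.repeat(spec.conditions, spec.repeats_per_condition)
    rng.shuffle(order)

    nv = spec.volumes_per_block
    labels: list[str] = [FIXATION]
    for i, cond in enumerate(order, start=1):
        labels.append(str(cond))
        if i in spec.fixation_positions:
            labels.append(FIXATION)
    labels.append(FIXATION)

    blocks = []
    pos = 0
    for lab in labels:
        blocks.append(Block(lab, pos, nv))
        pos += nv
    return BlockSchedule(tuple(blocks))


def build_localiser_design(
    spec: DesignSpec | None = None, n_blocks: int = 20
) -> BlockSchedule:
    """Alternating air-on / air-off schedule (air-on first), 16-s blocks."""
    spec = spec or DesignSpec()
    nv = spec.volumes_per_block
    blocks = []
    for i in range(n_blocks):
        lab = AIR_ON if i % 2 == 0 else AIR_OFF
        blocks.append(Block(lab, i * nv, nv))
    return BlockSchedule(tuple(blocks))


# ---------------------------------------------------------------------------
# voxel patterns
# ---------------------------------------------------------------------------

def condition_patterns(
    n_voxels: int, conditions: tuple[str, ...], rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Unit-norm, mutually orthogonal (hence linearly independent)
    per-condition voxel patterns drawn from a seeded Gaussian."""
    if n_voxels < len(conditions):
        raise ValueError("need at least as many voxels as conditions")
    raw = rng.standard_normal((n_voxels, len(conditions)))
    q, _ = np.linalg.qr(raw)
    q = q * np.sign(q[0, :])  # fix the QR sign ambiguity for determinism
    return {c: q[:, i].copy() for i, c in enumerate(conditions)}


# ---------------------------------------------------------------------------
# time-series simulation
# ---------------------------------------------------------------------------

def _ar1_noise(
    shape: tuple[int, int], sd: float, phi: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary AR(1) noise with marginal SD ``sd`` along the last axis."""
    if sd == 0:
        return np.zeros(shape)
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    e = rng.standard_normal(shape) * innov_sd
    e[..., 0] = rng.standard_normal(shape[:-1]) * sd  # stationary start
    return signal.lfilter([1.0], [1.0, -phi], e, axis=-1)


def simulate_run(
    schedule: BlockSchedule,
    effect: EffectSpec,
    seed=None,
    patterns: dict[str, np.ndarray] | None = None,
    participant_id: int = 0,
    n_dummy_volumes: int = 4,
    tr: float = 2.0,
) -> RunData:
    """Simulate one run of voxel time series for ``schedule``.

    signal = baseline * (1 + conv(boxcars) . (shared + amp*pattern)/100)
             + drift + AR(1) noise.

    ``n_dummy_volumes`` baseline volumes are prepended for the
    convolution timeline and then discarded; block onsets are 0-based
    post-dummy volume indices. ``patterns`` maps condition labels to
    per-voxel vectors; if omitted they are drawn from ``seed`` (pass the
    participant's patterns explicitly to share them across runs).
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    pattern_rng, noise_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    labels = sorted({b.label for b in schedule.blocks} - {FIXATION, AIR_OFF})
    if patterns is None:
        patterns = condition_patterns(effect.n_voxels, tuple(labels), pattern_rng)
    nv = effect.n_voxels
    for lab in labels:
        if lab not in patterns:
            raise ValueError(f"no pattern supplied for condition {lab!r}")
        if patterns[lab].shape != (nv,):
            raise ValueError(
                f"pattern for {lab!r} has shape {patterns[lab].shape}, "
                f"expected ({nv},)"
            )

    n_dummy = int(n_dummy_volumes)
    total = schedule.n_volumes + n_dummy
    kernel = hrf_kernel(tr, effect.hrf)

    # fractional modulation per voxel per volume (dummy timeline included)
    frac = np.zeros((nv, total))
    for lab in labels:
        box = np.zeros(total)
        for b in schedule.blocks_with_label(lab):
            start = b.onset_volume + n_dummy
            box[start : start + b.n_volumes] = 1.0
        conv = np.convolve(box, kernel)[:total]
        amp = (effect.shared_amplitude + effect.pattern_amplitude * patterns[lab]) / 100.0
        frac += amp[:, None] * conv[None, :]

    sig = effect.baseline * (1.0 + frac)

    phase = noise_rng.uniform(0, 2 * np.pi)  # drawn always: stable stream layout
    if effect.drift_amplitude > 0:
        t = np.arange(total) * tr
        sig = sig + effect.drift_amplitude * np.sin(
            2 * np.pi * t / effect.drift_period + phase
        )[None, :]

    sig = sig + _ar1_noise((nv, total), effect.noise_sd, effect.ar1_coef, noise_rng)

    sig = sig[:, n_dummy:]
    return RunData(sig, schedule, participant_id=participant_id, run_id=schedule.run_id)


def simulate_localiser_run(
    effect: EffectSpec,
    seed=None,
    responsive_fraction: float = 0.5,
    participant_id: int = 0,
) -> RunData:
    """Simulate one somatosensory air-puff localiser run.

    A seeded random subset of ``responsive_fraction`` of the voxels
    responds to air-on blocks with ``effect.shared_amplitude`` percent
    signal change; the rest are silent.
    """
    if not 0 <= responsive_fraction <= 1:
        raise ValueError("responsive_fraction must lie in [0, 1]")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    pick_ss, run_ss = ss.spawn(2)
    rng = np.random.default_rng(pick_ss)
    nv = effect.n_voxels
    n_resp = int(round(responsive_fraction * nv))
    responsive = np.zeros(nv)
    responsive[rng.choice(nv, size=n_resp, replace=False)] = 1.0

    schedule = build_localiser_design()
    # the air-on response is univariate: an on/off indicator in the
    # pattern slot scaled by shared_amplitude percent signal change
    eff = replace(
        effect,
        pattern_amplitude=effect.shared_amplitude,
        shared_amplitude=0.0,
    )
    return simulate_run(
        schedule, eff, seed=run_ss, patterns={AIR_ON: responsive},
        participant_id=participant_id,
    )


def simulate_behavior(
    spec: BehaviorSpec, n_blocks: int, seed=None
) -> BehaviorOutcome:
    """Simulate 1-back hits / misses / false alarms / correct rejections.

    Each block contributes ``targets_per_block`` target decisions with
    P(hit) = Phi(d'/2 - c) and ``nontargets_per_block`` non-target
    decisions with P(FA) = Phi(-d'/2 - c).
    """
    from scipy.stats import norm

    if not np.isfinite(spec.true_dprime):
        raise ValueError("true_dprime must be finite")
    rng = np.random.default_rng(seed)
    p_hit = norm.cdf(spec.true_dprime / 2.0 - spec.criterion)
    p_fa = norm.cdf(-spec.true_dprime / 2.0 - spec.criterion)
    n_targets = n_blocks * spec.targets_per_block
    n_nontargets = n_blocks * spec.nontargets_per_block
    hits = int(rng.binomial(n_targets, p_hit))
    fas = int(rng.binomial(n_nontargets, p_fa))
    return BehaviorOutcome(
        hits=hits,
        misses=n_targets - hits,
        false_alarms=fas,
        correct_rejections=n_nontargets - fas,
    )


def simulate_study(
    design: DesignSpec,
    effect: EffectSpec,
    n_participants: int = 16,
    seed=None,
    behavior: BehaviorSpec | None = None,
    localiser_responsive_fraction: float = 0.5,
) -> list[ParticipantData]:
    """Simulate a full study: per participant, ``design.n_runs``
    experimental runs (shared condition patterns, independent noise),
    one localiser run, and 1-back behaviour.

    Participant-level seeds are spawned deterministically from the
    master seed, so datasets are reproducible and participants are
    statistically independent.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    behavior = behavior or BehaviorSpec()
    master = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    out: list[ParticipantData] = []
    for pid, pss in enumerate(master.spawn(n_participants)):
        pat_ss, loc_ss, beh_ss, *run_ss = pss.spawn(3 + design.n_runs)
        patterns = condition_patterns(
            effect.n_voxels, design.conditions, np.random.default_rng(pat_ss)
        )
        runs = []
        for r, rss in enumerate(run_ss):
            sched_ss, sim_ss = rss.spawn(2)
            sched = build_design(design, seed=sched_ss)
            sched = BlockSchedule(sched.blocks, run_id=r)
            runs.append(
                simulate_run(
                    sched, effect, seed=sim_ss, patterns=patterns,
                    participant_id=pid, n_dummy_volumes=design.n_dummy_volumes,
                    tr=design.tr,
                )
            )
        loc = simulate_localiser_run(
            effect, seed=loc_ss,
            responsive_fraction=localiser_responsive_fraction,
            participant_id=pid,
        )
        beh = simulate_behavior(
            behavior, n_blocks=design.n_experimental_blocks * design.n_runs,
            seed=beh_ss,
        )
        out.append(ParticipantData(pid, runs, loc, beh, patterns))
    return out


# ---------------------------------------------------------------------------
# stimulus images
# ---------------------------------------------------------------------------

STIMULUS_KINDS = ("glossy", "matte", "rough", "painted")


def generate_stimulus_image(
    kind: str,
    level: int,
    size: int = 128,
    seed=None,
    feature_amplitude: float = 1.0,
) -> np.ndarray:
    """Procedural grayscale stand-in for one rendered stimulus.

    All kinds share a smooth shading field on a mid-gray background.
    ``glossy`` adds sparse high-luminance specular blobs (raising
    histogram skew); ``rough`` modulates the shading with a wave texture
    (raising contrast); ``painted`` applies the same wave texture to
    reflectance, leaving the shading untouched; ``matte`` is the bare
    shading. ``level`` (1-5) scales the kind-specific feature;
    ``feature_amplitude`` 0 yields a uniform image. Deterministic under
    ``seed``; values in [0, 1].
    """
    if kind not in STIMULUS_KINDS:
        raise ValueError(f"kind must be one of {STIMULUS_KINDS}, got {kind!r}")
    if not 1 <= level <= 5:
        raise ValueError("level must lie in 1..5")
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    shade_rng, wave_rng, blob_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    # smooth shading field, unit variance
    shade = ndimage.gaussian_filter(shade_rng.standard_normal((size, size)),
                                    sigma=size / 16.0, mode="wrap")
    shade = shade / max(shade.std(), 1e-12)

    # banded wave texture (shared by rough and painted)
    yy, xx = np.mgrid[0:size, 0:size] / size
    warp = ndimage.gaussian_filter(wave_rng.standard_normal((size, size)),
                                   sigma=size / 8.0, mode="wrap")
    warp = warp / max(warp.std(), 1e-12)
    wave = np.sin(2 * np.pi * (6 * xx + 4 * yy + 0.35 * warp))

    fa = feature_amplitude
    base = 0.5 + 0.10 * fa * shade

    if kind == "matte":
        img = base
    elif kind == "rough":
        img = 0.5 + 0.10 * fa * shade * (1.0 + 0.18 * level * wave)
    elif kind == "painted":
        img = base * (1.0 + 0.06 * fa * level * wave)
    else:  # glossy: sparse positive specular highlights
        impulses = np.zeros((size, size))
        n_blobs = 8
        idx = blob_rng.choice(size * size, size=n_blobs, replace=False)
        impulses.flat[idx] = 1.0
        blobs = ndimage.gaussian_filter(impulses, sigma=size / 48.0, mode="wrap")
        blobs = blobs / max(blobs.max(), 1e-12)
        img = base + 0.45 * fa * (0.5 + 0.1 * level) * blobs

    return np.clip(img, 0.0, 1.0)
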