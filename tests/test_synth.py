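"""Generator structure, determinism, and closed-form signal checks."""

import numpy as np
import pytest
from scipy import stats as sps

import surfdecode as sd
from surfdecode import glm
from surfdecode.synth import (
    AIR_OFF,
    AIR_ON,
    FIXATION,
    BehaviorSpec,
    build_localiser_design,
    condition_patterns,
    generate_stimulus_image,
    simulate_behavior,
    simulate_localiser_run,
)


class TestBuildDesign:
    def test_default_schedule_structure(self, default_schedule, default_design):
        sched, spec = default_schedule, default_design
        assert len(sched.blocks) == 23
        assert sched.n_volumes == 184
        assert sched.n_volumes * spec.tr == 368.0
        labels = [b.label for b in sched.blocks]
        for cond in spec.conditions:
            assert labels.count(cond) == 4
        assert labels.count(FIXATION) == 7
        assert all(b.n_volumes == 8 for b in sched.blocks)

    def test_fixation_interposed_at_configured_positions(self, default_schedule):
        labels = [b.label for b in default_schedule.blocks]
        assert labels[0] == FIXATION and labels[-1] == FIXATION
        # count stimulus blocks before each interior fixation block
        stim_seen, fix_after = 0, []
        for lab in labels[1:-1]:
            if lab == FIXATION:
                fix_after.append(stim_seen)
            else:
                stim_seen += 1
        assert fix_after == [3, 5, 8, 11, 13]

    def test_schedule_volume_accounting(self, default_schedule):
        exp = sum(b.n_volumes for b in default_schedule.experimental_blocks)
        fix = sum(
            b.n_volumes for b in default_schedule.blocks_with_label(FIXATION)
        )
        assert exp == 128 and fix == 56 and exp + fix == 184

    def test_condition_order_is_seeded(self, default_design):
        a = sd.build_design(default_design, seed=1)
        b = sd.build_design(default_design, seed=1)
        c = sd.build_design(default_design, seed=2)
        assert [x.label for x in a.blocks] == [x.label for x in b.blocks]
        assert [x.label for x in a.blocks] != [x.label for x in c.blocks]

    def test_indivisible_block_length_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            sd.DesignSpec(tr=2.0, block_len=15.0)


class TestSimulateRun:
    def test_no_effect_no_noise_is_flat_baseline(self, default_schedule):
        eff = sd.EffectSpec(
            n_voxels=5, pattern_amplitude=0, shared_amplitude=0,
            noise_sd=0, drift_amplitude=0,
        )
        run = sd.simulate_run(default_schedule, eff, seed=0)
        assert np.allclose(run.signal, eff.baseline)

    def test_same_seed_bit_identical(self, default_schedule, small_effect):
        a = sd.simulate_run(default_schedule, small_effect, seed=42)
        b = sd.simulate_run(default_schedule, small_effect, seed=42)
        assert np.array_equal(a.signal, b.signal)

    def test_delay_hrf_plateau_matches_convolution_oracle(self, default_schedule):
        """Noise-free pure-delay generation: the signal inside a block's
        shifted window equals baseline*(1 + (shared + a*p_v)/100), as a
        hand convolution of the boxcar with a 2-volume delta predicts."""
        nv = 6
        eff = sd.EffectSpec(
            n_voxels=nv, pattern_amplitude=0.8, shared_amplitude=0.5,
            noise_sd=0, drift_amplitude=0, hrf="delay",
        )
        pats = condition_patterns(nv, ("G", "GC", "R", "RC"),
                                  np.random.default_rng(3))
        run = sd.simulate_run(default_schedule, eff, seed=0, patterns=pats)
        shift = 2  # 4 s / 2 s TR
        for b in default_schedule.experimental_blocks:
            expected = eff.baseline * (
                1 + (eff.shared_amplitude + eff.pattern_amplitude * pats[b.label]) / 100
            )
            window = run.signal[:, b.onset_volume + shift : b.onset_volume + shift + b.n_volumes]
            assert np.allclose(window, expected[:, None], atol=1e-12)

    def test_condition_patterns_unit_norm_independent(self):
        pats = condition_patterns(20, ("G", "GC", "R", "RC"),
                                  np.random.default_rng(0))
        M = np.column_stack(list(pats.values()))
        assert np.allclose(np.linalg.norm(M, axis=0), 1.0)
        assert np.linalg.matrix_rank(M) == 4


class TestSimulateStudy:
    def test_study_structure(self, default_design, null_effect):
        study = sd.simulate_study(default_design, null_effect,
                                  n_participants=3, seed=5)
        assert len(study) == 3
        for p in study:
            assert len(p.runs) == default_design.n_runs
            assert all(r.n_volumes == 184 for r in p.runs)
            assert p.localiser.n_volumes == 160
        # same participant patterns shared across runs, distinct across people
        assert not np.allclose(
            study[0].condition_patterns["G"], study[1].condition_patterns["G"]
        )

    def test_master_seed_changes_noise_not_structure(self, default_design, null_effect):
        a = sd.simulate_study(default_design, null_effect, n_participants=1, seed=1)
        b = sd.simulate_study(default_design, null_effect, n_participants=1, seed=2)
        assert not np.allclose(a[0].runs[0].signal, b[0].runs[0].signal)
        for ra, rb in zip(a[0].runs, b[0].runs):
            la = sorted(x.label for x in ra.schedule.experimental_blocks)
            lb = sorted(x.label for x in rb.schedule.experimental_blocks)
            assert la == lb  # same condition multiset, realisations differ

    def test_single_participant_reproducible(self, default_design, null_effect):
        a = sd.simulate_study(default_design, null_effect, n_participants=1, seed=9)
        b = sd.simulate_study(default_design, null_effect, n_participants=1, seed=9)
        assert np.array_equal(a[0].runs[3].signal, b[0].runs[3].signal)


class TestLocaliser:
    def test_alternating_blocks(self):
        sched = build_localiser_design()
        labels = [b.label for b in sched.blocks]
        assert len(labels) == 20
        assert labels[::2] == [AIR_ON] * 10 and labels[1::2] == [AIR_OFF] * 10
        assert all(b.n_volumes == 8 for b in sched.blocks)

    def test_zero_responsive_fraction_centres_t_on_zero(self):
        eff = sd.EffectSpec(n_voxels=60, shared_amplitude=1.0)
        run = simulate_localiser_run(eff, seed=4, responsive_fraction=0.0)
        fit = glm.fit_glm([run])
        t = fit.t_map(glm.air_contrast(fit))
        assert abs(t.mean()) < 3 * t.std(ddof=1) / np.sqrt(len(t))

    def test_air_t_grows_as_noise_shrinks(self):
        """With every voxel responsive, the on-off t statistic increases
        monotonically as noise goes to zero (t ~ amplitude / noise)."""
        mins = []
        for noise in (1.0, 0.3, 0.1):
            eff = sd.EffectSpec(n_voxels=10, shared_amplitude=1.0,
                                noise_sd=noise, drift_amplitude=0.0)
            run = simulate_localiser_run(eff, seed=11, responsive_fraction=1.0)
            fit = glm.fit_glm([run])
            mins.append(fit.t_map(glm.air_contrast(fit)).min())
        assert mins[0] < mins[1] < mins[2]
        assert mins[2] > 20


class TestBehavior:
    def test_zero_dprime_rates_near_half(self):
        out = simulate_behavior(
            BehaviorSpec(true_dprime=0.0, criterion=0.0), n_blocks=4000, seed=0
        )
        hr = out.hits / (out.hits + out.misses)
        fa = out.false_alarms / (out.false_alarms + out.correct_rejections)
        assert abs(hr - 0.5) < 0.03 and abs(fa - 0.5) < 0.01

    def test_dprime_recovered_within_binomial_ci(self):
        """Recovered d' from simulated counts matches the generating d'
        within a CI propagated from the binomial SEs of both rates."""
        from surfdecode.stats import dprime

        spec = BehaviorSpec(true_dprime=2.0)
        out = simulate_behavior(spec, n_blocks=3000, seed=7)
        res = dprime(*out.as_tuple())
        n_sig = out.hits + out.misses
        n_noise = out.false_alarms + out.correct_rejections
        # delta-method SE of d' from the two binomial rates
        se = np.sqrt(
            res.hit_rate * (1 - res.hit_rate) / n_sig
            / sps.norm.pdf(sps.norm.ppf(res.hit_rate)) ** 2
            + res.fa_rate * (1 - res.fa_rate) / n_noise
            / sps.norm.pdf(sps.norm.ppf(res.fa_rate)) ** 2
        )
        assert abs(res.d_prime - 2.0) < 3 * se

    def test_criterion_shift_leaves_dprime_invariant(self):
        """A conservative criterion lowers both rates but not d'."""
        from surfdecode.stats import dprime

        n = 40000
        neutral = simulate_behavior(
            BehaviorSpec(true_dprime=1.5, criterion=0.0), n, seed=1
        )
        shifted = simulate_behavior(
            BehaviorSpec(true_dprime=1.5, criterion=0.6), n, seed=1
        )
        d0 = dprime(*neutral.as_tuple())
        d1 = dprime(*shifted.as_tuple())
        assert d1.hit_rate < d0.hit_rate and d1.fa_rate < d0.fa_rate
        assert abs(d0.d_prime - d1.d_prime) < 0.08


class TestStimulusImages:
    def test_deterministic_under_seed(self):
        a = generate_stimulus_image("rough", 3, size=64, seed=5)
        b = generate_stimulus_image("rough", 3, size=64, seed=5)
        assert np.array_equal(a, b)

    def test_glossy_raises_skew_over_matte(self):
        from surfdecode.imstats import image_stats

        for seed in (0, 1, 2):
            g = generate_stimulus_image("glossy", 3, size=96, seed=seed)
            m = generate_stimulus_image("matte", 3, size=96, seed=seed)
            assert image_stats(g).skew > image_stats(m).skew

    def test_rough_raises_contrast_over_matte(self):
        from surfdecode.imstats import image_stats

        for seed in (0, 1, 2):
            r = generate_stimulus_image("rough", 4, size=96, seed=seed)
            m = generate_stimulus_image("matte", 4, size=96, seed=seed)
            assert image_stats(r).contrast > image_stats(m).contrast

    def test_zero_amplitude_is_uniform(self):
        from surfdecode.imstats import image_stats

        img = generate_stimulus_image("painted", 2, size=32, seed=0,
                                      feature_amplitude=0.0)
        s = image_stats(img)
        assert s.contrast == 0.0 and s.skew == 0.0

    def test_invalid_kind_and_level_rejected(self):
        with pytest.raises(ValueError):
            generate_stimulus_image("shiny", 1, seed=0)
        with pytest.raises(ValueError):
            generate_stimulus_image("glossy", 6, seed=0)
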