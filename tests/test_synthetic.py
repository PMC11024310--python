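"""Generator contracts: templates, label runs, rendering, determinism."""
import numpy as np
import pytest

import microsem as m
from microsem.core import STATES
from microsem.synthetic import (DEFAULT_TEMPLATE_CORR, GroundTruthSpec,
                                uniform_transition_matrix)


class TestGroupTemplates:
    def test_zero_perturbation_is_identity(self):
        hc, scz = m.make_group_templates(perturb_classes={"B", "D"},
                                         perturb_strength=0.0, seed=3)
        assert np.allclose(m.template_correlation(hc, scz), 1.0, atol=1e-12)

    def test_unperturbed_classes_are_shared(self):
        hc, scz = m.make_group_templates(perturb_classes={"B"},
                                         perturb_strength=0.7, seed=3)
        for cls in ("A", "C", "D"):
            assert np.allclose(hc.map_for(cls), scz.map_for(cls))
        assert not np.allclose(hc.map_for("B"), scz.map_for("B"))

    def test_correlation_decreases_monotonically_with_strength(self):
        corrs = []
        for s in np.linspace(0.0, 1.0, 9):
            hc, scz = m.make_group_templates(perturb_classes={"B"},
                                             perturb_strength=float(s), seed=5)
            corrs.append(m.template_correlation(hc, scz)[1])
        assert np.all(np.diff(corrs) < 0)

    def test_full_perturbation_decorrelates(self):
        # strength 1 rotates into an orthogonal direction: |corr| ~ 0,
        # far below 0.5 for every seed
        for seed in range(25):
            hc, scz = m.make_group_templates(perturb_classes={"B"},
                                             perturb_strength=1.0, seed=seed)
            assert m.template_correlation(hc, scz)[1] < 0.5

    def test_reference_correlations_match_targets(self):
        hc, scz = m.make_group_templates(seed=9)
        corr = m.template_correlation(hc, scz)
        assert corr[STATES.index("B")] == pytest.approx(
            DEFAULT_TEMPLATE_CORR["B"], abs=1e-9)
        assert corr[STATES.index("D")] == pytest.approx(
            DEFAULT_TEMPLATE_CORR["D"], abs=1e-9)
        assert corr[0] == pytest.approx(1.0) and corr[2] == pytest.approx(1.0)

    def test_strength_for_correlation_inverts_the_rotation(self):
        for target in (0.1, 0.68, 0.86, 0.99):
            s = m.strength_for_correlation(target)
            assert np.cos(s * np.pi / 2) == pytest.approx(target, abs=1e-12)

    def test_maps_are_zero_mean_unit_norm(self):
        hc, scz = m.make_group_templates(seed=2)
        for ts in (hc, scz):
            assert np.allclose(ts.maps.mean(axis=1), 0.0, atol=1e-12)
            assert np.allclose(np.linalg.norm(ts.maps, axis=1), 1.0,
                               atol=1e-12)

    def test_too_few_channels_rejected(self):
        with pytest.raises(ValueError):
            m.make_group_templates(n_channels=2)


def _ab_cycle_spec(seed=0, duration_dist="fixed"):
    """A->B->A chain with 100 ms states (25 samples at 250 Hz)."""
    hc, scz = m.make_group_templates(seed=seed)
    p = np.zeros((4, 4))
    p[0, 1] = 1.0  # A -> B
    p[1, 0] = 1.0  # B -> A
    p[2, 0] = 1.0  # C -> A (unreachable)
    p[3, 0] = 1.0  # D -> A (unreachable)
    durs = {s: 100.0 for s in STATES}
    return GroundTruthSpec(
        templates_by_group={"HC": hc, "SCZ": scz},
        transition_by_group={"HC": p, "SCZ": p.copy()},
        mean_duration_ms_by_group={"HC": dict(durs), "SCZ": dict(durs)},
        duration_dist=duration_dist, seed=seed,
        subject_duration_jitter=0.0, subject_amp_jitter=0.0)


class TestLabelRuns:
    def test_deterministic_alternating_chain(self):
        spec = _ab_cycle_spec()
        runs = m.simulate_label_runs(spec, "HC", 1.0, seed=4)
        assert len(runs) == 10
        assert all(n == 25 for _, n in runs)
        states = [s for s, _ in runs]
        assert set(states) <= {0, 1}
        assert all(a != b for a, b in zip(states, states[1:]))

    def test_runs_cover_exact_sample_count(self, spec):
        for dur in (1.0, 7.3, 30.0):
            runs = m.simulate_label_runs(spec, "SCZ", dur, seed=8)
            assert sum(n for _, n in runs) == int(round(dur * spec.fs))

    def test_occurrence_matches_stationary_distribution(self, spec):
        # eigen-analysis oracle: run-state frequencies over 500 s lie
        # within 3 SE of the chain's stationary distribution
        runs = m.simulate_label_runs(spec, "SCZ", 500.0, seed=12)
        states = np.array([s for s, _ in runs])
        pi = m.stationary_run_distribution(spec.transition_by_group["SCZ"])
        n = len(states)
        for k in range(4):
            freq = np.mean(states == k)
            se = np.sqrt(pi[k] * (1 - pi[k]) / n)
            assert abs(freq - pi[k]) < 3 * se

    def test_seeded_determinism(self, spec):
        a = m.simulate_label_runs(spec, "HC", 20.0, seed=99)
        b = m.simulate_label_runs(spec, "HC", 20.0, seed=99)
        assert a == b

    def test_invalid_inputs_rejected(self, spec):
        with pytest.raises(ValueError):
            m.simulate_label_runs(spec, "HC", 0.0, seed=1)
        bad = np.zeros((4, 4))
        with pytest.raises(ValueError):
            GroundTruthSpec(
                templates_by_group=spec.templates_by_group,
                transition_by_group={"HC": bad, "SCZ": bad},
                mean_duration_ms_by_group=spec.mean_duration_ms_by_group)


class TestRenderEEG:
    def test_noise_free_samples_are_template_multiples(self, spec, gt_templates):
        hc_t, _ = gt_templates
        nf = m.default_spec(seed=spec.seed, noise_sd=0.0)
        runs = m.simulate_label_runs(nf, "HC", 2.0, seed=6)
        sim = m.render_eeg(runs, hc_t, nf, seed=6)
        x = sim.segment.data
        for t in range(0, x.shape[1], 37):
            g = hc_t.maps[sim.labels[t]]
            resid = x[:, t] - (g @ x[:, t]) * g
            assert np.linalg.norm(resid) < 1e-12

    def test_noise_free_gfp_equals_scaled_envelope(self, spec, gt_templates):
        # GFP(t) = a_t * GFP(template) = ||x_t|| / sqrt(N) for unit maps
        hc_t, _ = gt_templates
        nf = m.default_spec(seed=spec.seed, noise_sd=0.0)
        runs = m.simulate_label_runs(nf, "HC", 2.0, seed=6)
        sim = m.render_eeg(runs, hc_t, nf, seed=6)
        x = sim.segment.data
        expected = np.linalg.norm(x, axis=0) / np.sqrt(x.shape[0])
        assert np.allclose(m.gfp(x), expected, atol=1e-12)

    def test_rendered_eeg_is_average_referenced(self, spec, gt_templates):
        hc_t, _ = gt_templates
        runs = m.simulate_label_runs(spec, "HC", 2.0, seed=7)
        sim = m.render_eeg(runs, hc_t, spec, seed=7)
        assert np.max(np.abs(sim.segment.data.mean(axis=0))) < 1e-10

    def test_channel_mismatch_and_empty_runs_rejected(self, spec):
        small_hc, _ = m.make_group_templates(n_channels=7, seed=1)
        with pytest.raises(ValueError):
            m.render_eeg([(0, 10)], small_hc, spec, seed=1)
        with pytest.raises(ValueError):
            m.render_eeg([], spec.templates_by_group["HC"], spec, seed=1)

    def test_cohort_is_deterministic(self, spec):
        a = m.simulate_cohort(spec, subjects_per_group=2, duration_s=5, seed=3)
        b = m.simulate_cohort(spec, subjects_per_group=2, duration_s=5, seed=3)
        for ra, rb in zip(a, b):
            assert ra.record.subject_id == rb.record.subject_id
            assert np.array_equal(ra.record.data, rb.record.data)
            assert np.array_equal(ra.labels, rb.labels)


class TestExpectedTemporalParams:
    def test_internal_identities(self, spec):
        for group in ("HC", "SCZ"):
            exp = m.expected_temporal_params(spec, group)
            assert exp["TCR"].sum() == pytest.approx(1.0, abs=1e-12)
            assert np.allclose(exp["OPS"] * exp["MD"] / 1000.0, exp["TCR"],
                               atol=1e-12)
            assert exp["run_frequency"].sum() == pytest.approx(1.0)
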