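"""Temporal, semantic (n-gram) and quality feature families."""
import numpy as np
import pytest
from scipy import stats

import microsem as m
from microsem.core import LabelSequence, STATES, expand_runs
from microsem.features import (FeatureConfig, brute_force_gram_counts,
                               quality_metrics, semantic_features)
from .conftest import make_segment


def _seq(runs, fs=250.0):
    """LabelSequence from (state_letter, n_samples) run pairs."""
    idx = [(STATES.index(s), n) for s, n in runs]
    return LabelSequence(labels=expand_runs(idx), fs=fs)


class TestTemporalFeatures:
    def test_alternating_hand_example(self):
        # 1 s at 250 Hz, alternating A/B runs of 25 samples (100 ms)
        seq = _seq([("A", 25), ("B", 25)] * 5)
        tf = m.temporal_features(seq)
        assert tf.md_ms[0] == pytest.approx(100.0)
        assert tf.ops_per_s[0] == pytest.approx(5.0)
        assert tf.tcr[0] == pytest.approx(0.5)

    def test_single_state_sequence(self):
        seq = _seq([("C", 500)])  # 2 s
        tf = m.temporal_features(seq)
        assert tf.tcr[2] == pytest.approx(1.0)
        assert tf.ops_per_s[2] == pytest.approx(0.5)  # 1 run / 2 s
        assert tf.md_ms[[0, 1, 3]].tolist() == [0.0, 0.0, 0.0]

    def test_tcr_sums_to_one_and_identity(self, spec):
        runs = m.simulate_label_runs(spec, "SCZ", 30.0, seed=23)
        seq = LabelSequence(labels=expand_runs(runs), fs=spec.fs)
        tf = m.temporal_features(seq)
        assert tf.tcr.sum() == pytest.approx(1.0, abs=1e-9)
        # TCR ~ OPS * MD / 1000 up to end effects (one run per state)
        assert np.allclose(tf.ops_per_s * tf.md_ms / 1000.0, tf.tcr,
                           atol=2.0 / seq.duration_s)


class TestSubsequenceStats:
    def test_frequency_hand_example(self):
        seq = _seq([("A", 10), ("B", 10)] * 3)  # runs A,B,A,B,A,B
        s2 = m.subsequence_stats(seq, 2)
        assert s2.f("AB") == pytest.approx(3 / 5)
        assert s2.f("BA") == pytest.approx(2 / 5)
        assert s2.f("AC") == 0.0
        assert sum(g.f for g in s2.table.values()) == pytest.approx(1.0)

    def test_duration_hand_example(self):
        # runs A(100 ms), B(50 ms), A(100 ms) at 1 kHz
        seq = _seq([("A", 100), ("B", 50), ("A", 100)], fs=1000.0)
        s1 = m.subsequence_stats(seq, 1)
        assert s1.table["A"].d_ms == pytest.approx(100.0)
        assert s1.table["B"].d_ms == pytest.approx(50.0)
        s2 = m.subsequence_stats(seq, 2)
        assert s2.table["AB"].d_ms == pytest.approx(75.0)
        assert s2.table["BA"].d_ms == pytest.approx(75.0)

    @pytest.mark.parametrize("l", [1, 2, 3, 4])
    def test_counts_match_enumeration_oracle(self, l):
        rng = np.random.default_rng(l)
        labels = []
        prev = -1
        for _ in range(300):
            s = int(rng.integers(0, 4))
            while s == prev:
                s = int(rng.integers(0, 4))
            labels.extend([s] * int(rng.integers(1, 6)))
            prev = s
        seq = LabelSequence(labels=np.array(labels), fs=250.0)
        run_string = "".join(STATES[s] for s, _ in m.compress_runs(seq))
        oracle = brute_force_gram_counts(run_string, l)
        ours = m.subsequence_stats(seq, l)
        assert {g: st.occ for g, st in ours.table.items()} == oracle
        assert sum(g.f for g in ours.table.values()) == pytest.approx(1.0)

    def test_length_one_frequency_is_proportional_to_ops(self, spec):
        runs = m.simulate_label_runs(spec, "HC", 60.0, seed=29)
        seq = LabelSequence(labels=expand_runs(runs), fs=spec.fs)
        s1 = m.subsequence_stats(seq, 1)
        tf = m.temporal_features(seq)
        f1 = np.array([s1.f(s) for s in STATES])
        ratio = tf.ops_per_s / f1
        assert np.ptp(ratio) / ratio.mean() < 0.01  # constant ratio

    def test_invalid_lengths_rejected(self):
        seq = _seq([("A", 5), ("B", 5)])
        with pytest.raises(ValueError):
            m.subsequence_stats(seq, 3)
        with pytest.raises(ValueError):
            m.subsequence_stats(seq, 0)


class TestQualityMetrics:
    def _noise_free(self, group="HC", seconds=2.0, seed=37):
        nf = m.default_spec(seed=1, noise_sd=0.0)
        t = nf.templates_by_group[group]
        sim = m.render_eeg(m.simulate_label_runs(nf, group, seconds, seed=seed),
                           t, nf, seed=seed, group=group)
        return sim, t

    def test_exact_fit_limits(self):
        sim, t = self._noise_free()
        seq = m.assign_labels(sim.segment, t)
        q = quality_metrics(sim.segment, seq, t)
        assert abs(q.msc - 1.0) < 1e-9
        assert abs(q.gev - 1.0) < 1e-9
        assert q.err < 1e-9
        assert q.w < 1e-9

    def test_gev_decreases_with_noise(self):
        # Spearman rho < 0 across 10 noise levels at a fixed seed
        gevs = []
        for noise in np.linspace(0.0, 0.3, 10):
            spec_n = m.default_spec(seed=1, noise_sd=float(noise))
            t = spec_n.templates_by_group["HC"]
            sim = m.render_eeg(
                m.simulate_label_runs(spec_n, "HC", 4.0, seed=41),
                t, spec_n, seed=41, group="HC")
            seq = m.assign_labels(sim.segment, t)
            gevs.append(quality_metrics(sim.segment, seq, t).gev)
        rho = stats.spearmanr(np.arange(10), gevs).statistic
        assert rho < 0

    def test_literal_gev_variant_differs(self, spec, gt_templates):
        hc_t, _ = gt_templates
        sim = m.render_eeg(m.simulate_label_runs(spec, "HC", 2.0, seed=43),
                           hc_t, spec, seed=43)
        seq = m.assign_labels(sim.segment, hc_t)
        std = quality_metrics(sim.segment, seq, hc_t, gev_variant="standard")
        lit = quality_metrics(sim.segment, seq, hc_t, gev_variant="literal")
        assert std.gev != lit.gev
        assert 0.0 <= std.gev <= 1.0

    def test_peak_restricted_dispersion_option(self, spec, gt_templates):
        hc_t, _ = gt_templates
        sim = m.render_eeg(m.simulate_label_runs(spec, "HC", 2.0, seed=44),
                           hc_t, spec, seed=44)
        seq = m.assign_labels(sim.segment, hc_t)
        full = quality_metrics(sim.segment, seq, hc_t,
                               dispersion_domain="all")
        peaks = quality_metrics(sim.segment, seq, hc_t,
                                dispersion_domain="peaks")
        assert peaks.w != full.w
        assert peaks.msc == full.msc  # only w is affected


class TestQualityFeatures:
    def test_identical_template_sets_give_unit_ratios(self, spec,
                                                      gt_templates):
        hc_t, _ = gt_templates
        sim = m.render_eeg(m.simulate_label_runs(spec, "HC", 2.0, seed=47),
                           hc_t, spec, seed=47, group="HC")
        dual = m.build_dual_sequences(sim.segment, hc_t, hc_t)
        values, names = m.quality_features(dual, sim.segment, hc_t, hc_t)
        assert len(values) == len(names) == 16
        ratios = values[[i for i, n in enumerate(names) if "ratio" in n]]
        diffs = values[[i for i, n in enumerate(names) if "diff" in n]]
        assert np.allclose(ratios, 1.0, atol=1e-9)
        assert np.allclose(diffs, 0.0, atol=1e-9)


class TestAssembledVector:
    def test_default_layout_is_49_dims(self, spec, gt_templates):
        hc_t, scz_t = gt_templates
        sim = m.render_eeg(m.simulate_label_runs(spec, "HC", 4.0, seed=53),
                           hc_t, spec, seed=53, group="HC")
        dual = m.build_dual_sequences(sim.segment, hc_t, scz_t)
        fv = m.assemble_features(sim.segment, dual, hc_t, scz_t)
        assert fv.values.size == 49
        assert [len(fv.blocks[b]) for b in ("quality", "semantic", "temporal")] \
            == [16, 21, 12]
        assert sorted(fv.blocks["quality"] + fv.blocks["semantic"]
                      + fv.blocks["temporal"]) == list(range(49))

    def test_identical_segments_give_identical_vectors(self, spec,
                                                       gt_templates):
        hc_t, scz_t = gt_templates
        sim = m.render_eeg(m.simulate_label_runs(spec, "SCZ", 4.0, seed=59),
                           scz_t, spec, seed=59, group="SCZ")
        dual = m.build_dual_sequences(sim.segment, hc_t, scz_t)
        a = m.assemble_features(sim.segment, dual, hc_t, scz_t)
        b = m.assemble_features(sim.segment, dual, hc_t, scz_t)
        assert np.array_equal(a.values, b.values)

    def test_invalid_gram_config_rejected(self):
        with pytest.raises(ValueError):
            FeatureConfig(trigrams=("ABX",))
        with pytest.raises(ValueError):
            FeatureConfig(trigrams=("AAB",))  # self-repeat impossible on runs

    def test_semantic_block_names_match_values(self):
        seq = _seq([("A", 10), ("B", 10), ("A", 10), ("C", 10)])
        values, names = semantic_features(seq)
        assert len(values) == len(names) == 21
        f2_ab = values[names.index("s_f2_AB")]
        assert f2_ab == pytest.approx(1 / 3)
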