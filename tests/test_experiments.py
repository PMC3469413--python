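"""Epoch sampling, comparison orchestration, jitter, sweeps, coherence."""

import numpy as np
import pandas as pd
import pytest

import phasecode as pc
from phasecode.experiments import _draw_lags, build_response_arrays


class TestSampleEpochs:
    def test_exact_tiling_edge_case(self):
        es = pc.sample_epochs((0, 1600), K=10, T=160.0, rng=np.random.default_rng(0))
        assert sorted(es.starts) == list(range(0, 1600, 160))

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError):
            pc.sample_epochs((0, 1500), K=10, T=160.0)

    def test_never_overlapping(self):
        rng = np.random.default_rng(1)
        for _ in range(500):
            es = pc.sample_epochs((1000, 5000), K=10, T=160.0, rng=rng)
            starts = np.sort(np.asarray(es.starts))
            assert np.all(np.diff(starts) >= 160)
            assert starts[0] >= 1000 and starts[-1] + 160 <= 5000

    def test_deterministic_under_seeded_rng(self):
        a = pc.sample_epochs((0, 4000), rng=np.random.default_rng(3))
        b = pc.sample_epochs((0, 4000), rng=np.random.default_rng(3))
        assert a.starts == b.starts


def test_epochset_overlap_rejected():
    with pytest.raises(ValueError):
        pc.EpochSet(starts=(0, 100), T=160.0)


def test_jitterspec_negative_rejected():
    with pytest.raises(ValueError):
        pc.JitterSpec(-1.0)


def test_lags_uniform_support():
    lags = _draw_lags(np.random.default_rng(0), (100_000,), J=80.0)
    assert lags.min() >= -40.0 and lags.max() <= 40.0
    assert abs(lags.mean()) < 0.5


class TestRunComparison:
    def test_rerun_is_bit_identical(self, entrained_recording):
        specs = [pc.CodeSpec("time"), pc.CodeSpec("count_scalar")]
        a = pc.run_comparison(entrained_recording, specs, n_sets=2, seed=5)
        b = pc.run_comparison(entrained_recording, specs, n_sets=2, seed=5)
        pd.testing.assert_frame_equal(a.table, b.table)
        pd.testing.assert_frame_equal(a.epochs, b.epochs)

    def test_single_set_matches_first_of_many(self, entrained_recording):
        specs = [pc.CodeSpec("time")]
        one = pc.run_comparison(entrained_recording, specs, n_sets=1, seed=5)
        many = pc.run_comparison(entrained_recording, specs, n_sets=3, seed=5)
        assert (
            one.table.loc[0, "percent_correct"]
            == many.table.loc[many.table["set"] == 0, "percent_correct"].iloc[0]
        )

    def test_mixed_T_rejected(self, entrained_recording):
        with pytest.raises(ValueError):
            pc.run_comparison(
                entrained_recording,
                [pc.CodeSpec("time", T=160.0), pc.CodeSpec("time", T=80.0)],
            )

    def test_partitioned_codes_beat_count_on_entrained_unit(self, entrained_recording):
        specs = [
            pc.CodeSpec("time"),
            pc.CodeSpec("phase"),
            pc.CodeSpec("count_scalar"),
            pc.CodeSpec("dual"),
        ]
        res = pc.run_comparison(entrained_recording, specs, n_sets=3, seed=2)
        count = res.mean_pc("count_scalar")
        assert res.mean_pc("time") > count + 3
        assert res.mean_pc("phase") > count + 3
        assert res.mean_pc("dual") > count + 3

    def test_shuffled_count_tracks_scalar_count(self, entrained_recording):
        specs = [pc.CodeSpec("count_shuffled"), pc.CodeSpec("count_scalar")]
        res = pc.run_comparison(entrained_recording, specs, n_sets=3, seed=2)
        assert res.mean_pc("count_shuffled") == pytest.approx(
            res.mean_pc("count_scalar"), abs=3.0
        )

    def test_shuffled_and_scalar_count_indistinguishable_across_units(self):
        """Across 40 units the bin-shuffled and 1-D spike-count codes give
        statistically indistinguishable performance (paired t, alpha=0.01)
        and a small mean difference."""
        from phasecode.stats_report import paired_t

        specs = [pc.CodeSpec("count_shuffled"), pc.CodeSpec("count_scalar")]
        sh, sc = [], []
        for u in range(40):
            cfg = pc.GeneratorConfig(
                duration_ms=6000, n_trials=20, entrainment_kappa=8.0,
                phase_coupling=0.6, rate_mod_depth=0.8, noise_amplitude=1.5,
                seed=700 + u,
            )
            rec = pc.generate_dataset(cfg)
            res = pc.run_comparison(rec, specs, n_sets=1, seed=900 + u)
            sh.append(res.mean_pc("count_shuffled"))
            sc.append(res.mean_pc("count_scalar"))
        _, p = paired_t(sh, sc)
        assert p > 0.01
        assert abs(np.mean(sh) - np.mean(sc)) < 1.5


class TestJitter:
    def test_zero_jitter_identical_to_standard(self, entrained_recording):
        specs = [pc.CodeSpec("time"), pc.CodeSpec("phase")]
        plain = pc.run_comparison(entrained_recording, specs, n_sets=2, seed=4)
        zero = pc.run_comparison(
            entrained_recording, specs, n_sets=2, seed=4, jitter=pc.JitterSpec(0.0)
        )
        pd.testing.assert_frame_equal(plain.table, zero.table)

    def test_jittered_codebook_decodes_unshifted_test_trials(self, entrained_recording):
        """With jitter the codebook differs but the test side equals the
        unjittered ensembles (only the codebook is blurred)."""
        rec = entrained_recording
        es = pc.sample_epochs((1000, 5000), K=4, T=160.0, rng=np.random.default_rng(0))
        code = pc.CodeSpec("time")
        true_arrays = build_response_arrays(rec.spikes, code, es)
        lags = _draw_lags(np.random.default_rng(1), (4, rec.n_trials), 80.0)
        jit_arrays = build_response_arrays(rec.spikes, code, es, lags=lags)
        assert any(
            not np.array_equal(a, b) for a, b in zip(true_arrays, jit_arrays)
        )

    def test_large_jitter_degrades_time_code(self, entrained_recording):
        specs = [pc.CodeSpec("time")]
        table = pc.jitter_robustness(
            entrained_recording, specs, (0.0, 160.0), n_sets=3, seed=6
        )
        m = table.groupby("J")["percent_correct"].mean()
        assert m[0.0] > m[160.0]


def test_entrainment_sensitivity():
    """Phase-code performance rises with entrainment; the time code is
    comparatively insensitive when the rate modulation is fixed."""
    phase_pc, time_pc = {}, {}
    specs = [pc.CodeSpec("time"), pc.CodeSpec("phase")]
    for kappa in (0.0, 8.0):
        vals_p, vals_t = [], []
        for u in range(6):
            cfg = pc.GeneratorConfig(
                duration_ms=6000, n_trials=20, entrainment_kappa=kappa,
                phase_coupling=0.6, rate_mod_depth=0.8, noise_amplitude=1.0,
                seed=300 + u,
            )
            rec = pc.generate_dataset(cfg)
            res = pc.run_comparison(rec, specs, n_sets=2, seed=600 + u)
            vals_p.append(res.mean_pc("phase"))
            vals_t.append(res.mean_pc("time"))
        phase_pc[kappa], time_pc[kappa] = np.mean(vals_p), np.mean(vals_t)
    d_phase = phase_pc[8.0] - phase_pc[0.0]
    d_time = abs(time_pc[8.0] - time_pc[0.0])
    assert d_phase > 2.0
    assert d_time < d_phase


def test_single_bin_codes_collapse_to_count(entrained_recording=None):
    """N=1 time and phase vectors equal the scalar count, so all three codes
    decode identically on shared epoch sets."""
    cfg = pc.GeneratorConfig(duration_ms=5000, n_trials=12, seed=21)
    rec = pc.generate_dataset(cfg)
    specs = [
        pc.CodeSpec("time", N=1),
        pc.CodeSpec("phase", N=1),
        pc.CodeSpec("count_scalar"),
    ]
    res = pc.run_comparison(rec, specs, n_sets=2, seed=8)
    by_code = res.table.groupby("code")["percent_correct"].apply(list)
    assert by_code["time"] == by_code["phase"] == by_code["count_scalar"]


def test_parameter_sweep_grid_shape(entrained_recording):
    table = pc.parameter_sweep(
        entrained_recording, T_values=(80.0, 160.0), N_values=(2, 8),
        n_sets=1, seed=3,
    )
    assert len(table) == (2 + 2) * 3
    assert set(table["sweep"]) == {"T", "N"}


def test_frequency_sweep_row_per_center(entrained_recording):
    table = pc.frequency_sweep(
        entrained_recording, centers_hz=(4, 12, 28), n_sets=1, seed=3
    )
    assert table["center_hz"].tolist() == [4, 12, 28]
    assert np.isfinite(table["ratio"]).all()


def test_noise_level_none_reproduces_standard_run(entrained_recording):
    cfg = entrained_recording.config
    specs = [pc.CodeSpec("count_scalar")]
    table = pc.noise_level_experiment(cfg, specs, levels_db=(None,), n_sets=2, seed=5)
    res = pc.run_comparison(entrained_recording, specs, n_sets=2, seed=5)
    assert table.loc[0, "mean_pc"] == res.mean_pc("count_scalar")


class TestCoherenceCorrelation:
    def test_degenerate_constant_coherence_flagged(self):
        """Perfect entrainment with a noise-free LFP gives coherence 1 for
        every epoch: the correlation is undefined and flagged, not zero."""
        cfg = pc.GeneratorConfig(
            duration_ms=6000, n_trials=12, entrainment_kappa=np.inf,
            noise_amplitude=0.0, freq_jitter_hz=0.0, seed=13,
        )
        rec = pc.generate_dataset(cfg)
        res = pc.run_comparison(rec, [pc.CodeSpec("phase")], n_sets=2, seed=1)
        table = pc.coherence_performance_correlation(res)
        row = table.iloc[0]
        assert row["n_degenerate"] == 2
        assert np.isnan(row["pearson"]) and np.isnan(row["spearman"])

    def test_phase_code_tracks_coherence(self, entrained_recording, theta_phase):
        res = pc.run_comparison(
            entrained_recording,
            [pc.CodeSpec("phase"), pc.CodeSpec("count_scalar")],
            n_sets=8,
            seed=17,
        )
        table = pc.coherence_performance_correlation(res).set_index("code")
        assert table.loc["phase", "n_sets"] > 0
        assert np.isfinite(table.loc["phase", "spearman"])
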