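"""Synthetic-data generator: determinism, calibration, regime structure."""

import dataclasses
import math

import numpy as np
import pytest

from slicephys.fm_kinetics import fit_cohort
from slicephys.network_metrics import stats_from_times
from slicephys.synthetic_data import (
    DestainSimConfig,
    EvokedParams,
    FiringRegime,
    RateDist,
    SimConfig,
    biphasic_template,
    destain_curve,
    draw_spike_train,
    simulate_cohort,
    simulate_destain_cohort,
    simulate_evoked_sweep,
    simulate_recording,
)


def _zero_rate_config() -> SimConfig:
    return SimConfig(
        n_animals_per_genotype=1,
        n_slices_per_animal=1,
        n_channels=4,
        n_traces=5,
        genotype_params={
            "wt": FiringRegime(kind="tonic", rate=0.0),
            "mut": FiringRegime(kind="burst", burst_rate=0.0),
        },
        seed=1,
    )


class TestMEACohort:
    def test_zero_rate_gives_noise_only_recordings(self):
        recs, gt = simulate_cohort(_zero_rate_config())
        assert len(recs) == 4  # 2 genotypes x 1 animal x 1 slice x 2 conditions
        for truth in gt.recordings.values():
            assert all(t.size == 0 for t in truth.spike_times)
        # noise only: nothing near the waveform scale
        assert max(np.abs(r.samples).max() for r in recs) < 0.021

    def test_seeded_determinism_bit_identical(self, small_config):
        r1, t1 = simulate_recording(small_config, "mut", 0, 1, "highk")
        r2, t2 = simulate_recording(small_config, "mut", 0, 1, "highk")
        assert np.array_equal(r1.samples, r2.samples)
        for a, b in zip(t1.spike_times, t2.spike_times):
            assert np.array_equal(a, b)

    def test_spike_times_sorted_and_in_range(self, small_config):
        _, truth = simulate_recording(small_config, "mut", 1, 0, "highk")
        dur = small_config.duration
        for t in truth.spike_times:
            assert np.all(np.diff(t) > 0)
            if t.size:
                assert t[0] >= 0 and t[-1] < dur

    def test_tonic_counts_match_poisson_tail_bound(self):
        """A 2 sp/s tonic channel over 600 s: count within 3*sqrt(1200) of
        1200 in >= 99% of seeded replicates (Poisson tail bound)."""
        regime = FiringRegime(kind="tonic", rate=2.0)
        inside = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = draw_spike_train(rng, regime, 600.0).size
            if abs(n - 1200) <= 3 * math.sqrt(1200):
                inside += 1
        assert inside >= 99

    def test_tonic_counts_pass_poisson_dispersion_test(self):
        """Across 64 channels the count dispersion is Poisson (alpha=0.01)."""
        from scipy.stats import chi2

        regime = FiringRegime(kind="tonic", rate=2.0)
        rng = np.random.default_rng(42)
        lam = 2.0 * 600.0
        counts = np.array(
            [draw_spike_train(rng, regime, 600.0).size for _ in range(64)]
        )
        stat = np.sum((counts - lam) ** 2 / lam)
        lo, hi = chi2.ppf([0.005, 0.995], df=64)
        assert lo < stat < hi

    def test_burst_regime_directions_match_ground_truth_expectations(self):
        """Interrupted-Poisson channels: lower overall frequency, higher
        active frequency, shorter ISI than tonic wild-type channels."""
        wt = FiringRegime(kind="tonic", rate=2.0)
        mut = FiringRegime(kind="burst", burst_rate=20.0, burst_mean_s=0.3,
                           gap_mean_s=5.7)
        assert mut.overall_rate() < wt.overall_rate()
        rng = np.random.default_rng(5)
        rows = {"wt": [], "mut": []}
        for name, regime in (("wt", wt), ("mut", mut)):
            for _ in range(40):
                t = draw_spike_train(rng, regime, 600.0)
                s = stats_from_times(t, 600, 1.0)
                rows[name].append(
                    (s.frequency, s.active_frequency or 0.0, s.mean_isi or np.nan)
                )
        wt_f, wt_af, wt_isi = np.nanmean(np.array(rows["wt"]), axis=0)
        mut_f, mut_af, mut_isi = np.nanmean(np.array(rows["mut"]), axis=0)
        assert mut_f < wt_f
        assert mut_af > wt_af
        assert mut_isi < wt_isi

    def test_waveform_template_peaks_are_exact(self):
        for fs in (4000.0, 20000.0):
            tpl = biphasic_template(fs, 0.05, -0.04)
            assert tpl.max() == pytest.approx(0.05)
            assert tpl.min() == pytest.approx(-0.04)
            assert np.argmax(tpl) < np.argmin(tpl)  # positive lobe first

    def test_default_noise_keeps_threshold_crossings_rare(self):
        cfg = SimConfig()
        assert cfg.noise_crossing_probability() < 1e-6

    @pytest.mark.parametrize(
        "field, value, match",
        [
            ("n_traces", 0, "n_traces"),
            ("noise_sd", -0.1, "noise_sd"),
            ("sampling_rate", 1500.0, "sampling_rate"),
            ("lfp_fraction", 1.5, "lfp_fraction"),
        ],
    )
    def test_invalid_configs_name_the_offending_field(self, field, value, match):
        cfg = dataclasses.replace(SimConfig(), **{field: value})
        with pytest.raises(ValueError, match=match):
            cfg.validate()

    def test_region_layout_must_cover_channels(self):
        cfg = SimConfig(n_channels=8)
        cfg.region_layout = ["DG"] * 5
        with pytest.raises(ValueError, match="region_layout"):
            cfg.validate()

    def test_subthreshold_waveform_rejected(self):
        cfg = SimConfig(
            genotype_params={"wt": FiringRegime(kind="tonic", rate=1.0,
                                                amp_pos=0.015)}
        )
        with pytest.raises(ValueError, match="amp_pos"):
            cfg.validate()


class TestEvokedSweeps:
    def test_zero_current_gives_zero_truth(self):
        sweep, truth = simulate_evoked_sweep(0.0, EvokedParams())
        assert truth == {"volley_amp": 0.0, "fepsp_amp": 0.0}
        assert np.allclose(sweep.voltage, 0.0)

    def test_truth_amplitudes_monotone_in_current(self):
        p = EvokedParams()
        amps = [simulate_evoked_sweep(c, p)[1]["fepsp_amp"]
                for c in range(0, 101, 10)]
        assert np.all(np.diff(amps) >= 0)

    def test_negative_current_rejected(self):
        with pytest.raises(ValueError):
            simulate_evoked_sweep(-1.0)


class TestDestainCohort:
    def test_closed_form_value_matches_exponential(self):
        """With k=0.1/s, pool=1, F0=1, background=0 and no noise the trace at
        t0 + 10 s equals exp(-1)."""
        t = np.arange(0, 60, 0.5)
        f = destain_curve(t, k=0.1, pool=1.0, t0=10.0, f0=1.0, background=0.0)
        assert f[t == 20.0][0] == pytest.approx(math.exp(-1.0), abs=1e-12)

    def test_zero_pool_gives_flat_trace(self):
        t = np.arange(0, 100, 0.5)
        f = destain_curve(t, 0.1, 0.0, 30.0, 1.0, 0.2)
        assert np.allclose(f, 1.2)  # no releasable pool: constant F0 + bg
        cfg = DestainSimConfig(
            n_boutons=3, groups=("wt",),
            rate_distribution={"wt": RateDist()},
            pool_fraction={"wt": 0.0}, pool_sd=0.0, noise_sd=0.0, seed=0,
        )
        with pytest.raises(ValueError, match="pool_fraction"):
            cfg.validate()

    def test_seeded_determinism(self):
        cfg = DestainSimConfig(n_boutons=5, groups=("wt", "mut"), seed=9)
        tr1, gt1 = simulate_destain_cohort(cfg)
        tr2, gt2 = simulate_destain_cohort(cfg)
        assert gt1.equals(gt2)
        for a, b in zip(tr1, tr2):
            assert np.array_equal(a.fluorescence, b.fluorescence)

    def test_nonpositive_frame_interval_rejected(self):
        with pytest.raises(ValueError, match="frame_interval"):
            DestainSimConfig(frame_interval=0.0).validate()

    def test_rescue_distribution_invariants_enforced(self):
        cfg = DestainSimConfig()
        cfg.rate_distribution = dict(cfg.rate_distribution)
        cfg.rate_distribution["mut+28:0+30:0"] = RateDist(k_median=0.2)
        with pytest.raises(ValueError, match="rescue"):
            cfg.validate()

    def test_mutant_mixture_is_bimodal_after_fitting(self):
        """With fraction_fast=0.5 the fitted rate distribution splits around
        the geometric midpoint of the two component medians."""
        cfg = DestainSimConfig(
            n_boutons={"mut": 300}, groups=("mut",), noise_sd=0.005, seed=4,
            rate_distribution={
                "mut": RateDist(k_median=0.05, sigma=0.25, fraction_fast=0.5,
                                k_fast_median=0.2, fast_sigma=0.25)
            },
            pool_fraction={"mut": 0.6},
        )
        traces, _ = simulate_destain_cohort(cfg)
        kin = fit_cohort(traces)
        ks = kin[kin["fit_ok"]]["k"].to_numpy()
        mid = math.sqrt(0.05 * 0.2)
        frac_fast = np.mean(ks > mid)
        assert 0.35 < frac_fast < 0.65
        slow_med = np.median(ks[ks <= mid])
        fast_med = np.median(ks[ks > mid])
        assert fast_med / slow_med > 2.0
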