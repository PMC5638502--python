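"""Sweeps, noise-robustness studies and clinical-case presets."""

import numpy as np
import pytest

from hemoradar import experiments as ex, phantom as ph


SMALL = ex.SweepConfig(frequencies=(1e9,), volumes_ml=(0.0, 2.0, 4.0),
                       depths_m=(0.06,), spacing=0.002)


class TestRunSweep:
    def test_zero_volume_only_gives_zero_dz(self):
        cfg = ex.SweepConfig(frequencies=(1e9,), volumes_ml=(0.0,),
                             depths_m=(0.06,), spacing=0.002)
        df = ex.run_sweep(cfg)
        assert (df["dz_abs_ohm"] == 0.0).all()

    def test_baseline_equal_to_volume_gives_zero(self):
        cfg = ex.SweepConfig(frequencies=(1e9,), volumes_ml=(4.0,),
                             baseline_volume_ml=4.0, depths_m=(0.06,),
                             spacing=0.002)
        df = ex.run_sweep(cfg)
        assert (df["dz_abs_ohm"] == 0.0).all()

    def test_deterministic_repeat_run(self):
        a = ex.run_sweep(SMALL)
        b = ex.run_sweep(SMALL)
        assert a.equals(b)

    def test_depth_ordering_at_every_frequency(self):
        """4 ml at 6 cm reads higher than at 11 cm for all frequencies."""
        cfg = ex.SweepConfig(frequencies=(1e8, 5e8, 1e9),
                             volumes_ml=(0.0, 4.0), depths_m=(0.06, 0.11),
                             spacing=0.002)
        df = ex.run_sweep(cfg)
        sel = df[df.volume_ml == 4.0].pivot(index="frequency_hz",
                                            columns="depth_m",
                                            values="dz_abs_ohm")
        assert (sel[0.06] > sel[0.11]).all()

    def test_rows_per_grid_point_and_schema(self):
        cfg = ex.SweepConfig(frequencies=(5e8, 1e9), volumes_ml=(0.0, 2.0),
                             depths_m=(0.06,), tilt_angles_deg=(0.0, 5.0),
                             repeats=2, spacing=0.002)
        df = ex.run_sweep(cfg)
        assert len(df) == 2 * 2 * 1 * 2 * 2
        assert list(df.columns) == ex.SWEEP_COLUMNS
        # |dZ| column consistent with the complex columns
        assert np.allclose(df["dz_abs_ohm"],
                           np.hypot(df["dz_re_ohm"], df["dz_im_ohm"]))

    def test_oversized_lesion_flagged_not_dropped(self):
        cfg = ex.SweepConfig(frequencies=(1e9,), volumes_ml=(0.0, 4.0, 400.0),
                             depths_m=(0.06,), spacing=0.002)
        df = ex.run_sweep(cfg)
        assert len(df) == 3
        assert bool(df.loc[df.volume_ml == 400.0, "flagged"].iloc[0])
        assert not df.loc[df.volume_ml == 4.0, "flagged"].iloc[0]

    def test_tilt_changes_reading_smoothly(self):
        cfg = ex.SweepConfig(frequencies=(1e9,), volumes_ml=(0.0, 4.0),
                             depths_m=(0.06,), tilt_angles_deg=(0.0, 5.0, 10.0),
                             spacing=0.002)
        df = ex.run_sweep(cfg)
        vals = df[df.volume_ml == 4.0].sort_values("angle_deg")["dz_abs_ohm"]
        v0, v5, v10 = vals.to_numpy()
        assert abs(v5 - v0) / v0 < abs(v10 - v0) / v0


class TestPcsNormalization:
    def test_sphere_normalization_divides_by_great_circle(self):
        cfg = ex.SweepConfig(frequencies=(1e9,), volumes_ml=(0.0, 4.0),
                             lesion_ratios=(1.0, 1.0, 1.0), depths_m=(0.06,),
                             spacing=0.002)
        df = ex.run_sweep(cfg)
        with pytest.warns(UserWarning):
            norm = ex.pcs_normalized_curves(df)
        r = ph.ellipsoid_semi_axes(4.0, (1, 1, 1))[0]
        row = df[df.volume_ml == 4.0].iloc[0]
        assert row["pcs_m2"] == pytest.approx(np.pi * r ** 2, rel=1e-9)
        assert norm["re_dz_over_pcs"].iloc[0] == pytest.approx(
            abs(row["dz_re_ohm"]) / row["pcs_m2"])

    def test_orientation_pcs_ratio_matches_closed_form(self):
        """Equal-volume 2:2:1 vs 1:1:2 lesions have PCS ratio 2^(4/3)."""
        v = 10.0
        flat = ph.EllipsoidLesion((0, 0, 0), ph.ellipsoid_semi_axes(v, (2, 2, 1)))
        tall = ph.EllipsoidLesion((0, 0, 0), ph.ellipsoid_semi_axes(v, (1, 1, 2)))
        ratio = (ph.projected_cross_section(flat, (0, 0, 1))
                 / ph.projected_cross_section(tall, (0, 0, 1)))
        assert ratio == pytest.approx(2 ** (4 / 3), rel=1e-9)

    def test_row_accounting(self):
        df = ex.run_sweep(SMALL)
        with pytest.warns(UserWarning):
            norm = ex.pcs_normalized_curves(df)
        assert len(norm) == int((df["pcs_m2"] > 0).sum())


class TestPropertyNoise:
    def _scene(self):
        cfg = ex.SweepConfig(frequencies=(1e9,), volumes_ml=(0.0, 3.0),
                             lesion_ratios=(1.0, 1.0, 1.0), depths_m=(0.07,),
                             spacing=0.002)
        head = ph.make_layered_head(cfg.layers, cfg.spacing,
                                    padding=cfg.spacing)
        baseline = head
        current = ph.insert_lesion(head, ex.make_lesion(cfg, 3.0, 0.07))
        src = ex.make_source(cfg, 1e9)
        return baseline, current, src

    def test_zero_noise_reproduces_noiseless(self):
        baseline, current, src = self._scene()
        spec = ex.NoiseSpec("property_noise", 0.0, repeats=5, seed=1)
        res = ex.property_noise_experiment(baseline, current, src, 1e9, spec)
        assert np.allclose(res["samples"], res["noiseless_dz"])

    def test_five_percent_noise_is_unbiased(self):
        """Mean |dZ| over 200 repeats within 3 SEM of noiseless."""
        baseline, current, src = self._scene()
        spec = ex.NoiseSpec("property_noise", 5.0, repeats=200, seed=11)
        res = ex.property_noise_experiment(baseline, current, src, 1e9, spec)
        assert (abs(res["mean_abs"] - res["noiseless_abs"])
                <= 3 * res["sem_abs"] + 1e-15)

    def test_volume_pattern_survives_five_percent_noise(self):
        cfg = ex.SweepConfig(frequencies=(1e9,),
                             volumes_ml=tuple(np.linspace(0.0, 4.25, 6)),
                             lesion_ratios=(1.0, 1.0, 1.0), depths_m=(0.07,),
                             spacing=0.002)
        spec = ex.NoiseSpec("property_noise", 5.0, repeats=100, seed=3)
        res = ex.property_noise_volume_study(cfg, spec, frequency=1e9,
                                             depth=0.07)
        assert res["pattern_preserved_fraction"] >= 0.95

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ex.NoiseSpec("property_noise", 100.0)
        with pytest.raises(ValueError):
            ex.NoiseSpec("snr_noise", -3.0)
        with pytest.raises(ValueError):
            ex.NoiseSpec("salt_and_pepper", 1.0)


class TestSnrNoise:
    DZ = np.array([0.5 + 0.2j, 1.1 - 0.4j, 2.0 + 1.5j, 3.1 - 0.3j])

    def test_snr_definition_voltage_ratio(self):
        # a 100:1 voltage ratio is 40 dB
        assert 20 * np.log10(100.0) == pytest.approx(40.0)
        assert 10 ** (-40.0 / 20.0) == pytest.approx(0.01)

    def test_infinite_snr_limit_recovers_clean_signal(self):
        res = ex.snr_experiment(self.DZ, snr_db=300.0, repeats=10, seed=0)
        assert np.max(np.abs(res["differences"])) < 1e-10

    def test_error_histogram_peaks_at_origin(self):
        """40 dB, 500 repeats: mean difference within 3 SEM of zero."""
        res = ex.snr_experiment(self.DZ, snr_db=40.0, repeats=500, seed=5)
        assert abs(res["mean_diff"]) <= 3 * res["sem_diff"]

    def test_lower_snr_spreads_more(self):
        lo = ex.snr_experiment(self.DZ, snr_db=40.0, repeats=300, seed=2)
        hi = ex.snr_experiment(self.DZ, snr_db=50.0, repeats=300, seed=2)
        assert lo["std_diff"] > hi["std_diff"]

    def test_seeded_reproducibility(self):
        a = ex.snr_experiment(self.DZ, 40.0, repeats=50, seed=9)
        b = ex.snr_experiment(self.DZ, 40.0, repeats=50, seed=9)
        assert np.array_equal(a["differences"], b["differences"])


class TestAveragedMeasurement:
    def test_single_repeat_is_single_measurement(self):
        mean, sem = ex.averaged_measurement(1.0 + 1.0j, snr_db=40.0,
                                            repeats=1, seed=4)
        assert sem == 0.0
        assert mean != 0

    def test_fixed_seed_reproducible(self):
        a = ex.averaged_measurement(2.0 + 0.5j, 40.0, repeats=128, seed=21)
        b = ex.averaged_measurement(2.0 + 0.5j, 40.0, repeats=128, seed=21)
        assert a == b

    def test_averaging_shrinks_error_by_sqrt_n(self):
        """Std of the 128-repeat mean is sqrt(128) below single-shot."""
        dz = 2.0 + 0.5j
        means, singles = [], []
        for k in range(50):
            mean, _ = ex.averaged_measurement(dz, 40.0, repeats=128, seed=100 + k)
            means.append(mean)
            rng = np.random.default_rng(100 + k)
            noisy = ex._noisy_delta_z(np.array([dz]), 40.0, 128, rng)[:, 0]
            singles.append(noisy)
        means = np.array(means)
        singles = np.concatenate(singles)
        std_mean = np.sqrt(means.real.var(ddof=1) + means.imag.var(ddof=1))
        std_single = np.sqrt(singles.real.var(ddof=1) + singles.imag.var(ddof=1))
        assert std_single / std_mean == pytest.approx(np.sqrt(128), rel=0.15)


class TestCasePresets:
    def test_subarachnoid_preset(self):
        cfg = ex.case_preset("subarachnoid_deep_sphere")
        assert cfg.frequencies == (1e9,)
        assert cfg.lesion_ratios == (1.0, 1.0, 1.0)
        assert cfg.standoff == pytest.approx(0.005)
        assert cfg.depths_m == (0.10,)

    def test_intraparenchymal_preset(self):
        cfg = ex.case_preset("intraparenchymal_4to1_ellipsoid")
        assert sorted(cfg.lesion_ratios) == [1.0, 1.0, 4.0]
        assert max(cfg.lesion_ratios) == cfg.lesion_ratios[2]  # major axis on boresight
        assert cfg.standoff == pytest.approx(0.005)

    def test_presets_run_end_to_end(self):
        cfg = ex.case_preset("subarachnoid_deep_sphere")
        import dataclasses
        cfg = dataclasses.replace(cfg, volumes_ml=(0.0, 5.0), spacing=0.002)
        df = ex.run_sweep(cfg)
        assert len(df) == 2
        assert df.loc[df.volume_ml == 5.0, "dz_abs_ohm"].iloc[0] > 0

    def test_unknown_preset_raises(self):
        with pytest.raises(ValueError):
            ex.case_preset("epidural")
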