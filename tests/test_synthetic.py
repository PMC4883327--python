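"""Synthetic measurement generator: kinetics, determinism, class structure."""

import dataclasses
import math

import numpy as np
import pytest

from rosenose.features import PhaseSchedule
from rosenose.gcms import label_dataset, total_key_constituents
from rosenose.synthetic import (
    GeneratorConfig,
    SensorSpec,
    config_from_yaml,
    config_to_yaml,
    default_config,
    generate_constituent_table,
    generate_dataset,
    generate_transient,
    write_measurements_csv,
)

SENSOR = SensorSpec("S1", "test", 100_000.0, 0.05, (0.75, 0.10))


class TestSchedule:
    def test_default_cycle_is_760_s(self):
        s = PhaseSchedule()
        assert s.total_s == 760.0
        assert len(s.times()) == 760
        assert s.injection_start_s == 60.0 and s.recovery_start_s == 260.0

    @pytest.mark.parametrize("bad", [
        dict(baseline_s=0), dict(injection_s=-5), dict(sample_period_s=0),
    ])
    def test_nonpositive_durations_rejected(self, bad):
        with pytest.raises(ValueError):
            PhaseSchedule(**bad)


class TestTransient:
    def test_noiseless_plateau_at_half_depth(self):
        """depth 0.5 from 100 kOhm baseline settles at 50 kOhm."""
        tr = generate_transient("C1", SENSOR, depth=0.5, tau_rise=20.0)
        inj_end = tr.R[(tr.t >= 250) & (tr.t < 260)]
        assert inj_end == pytest.approx(50_000.0, rel=1e-4)
        assert np.all(tr.R[tr.t < 60] == 100_000.0)

    def test_noiseless_rise_is_first_order(self):
        """R(t) follows Rf + (Ri-Rf)exp(-(t-60)/tau) exactly during injection."""
        tau = 20.0
        tr = generate_transient("C2", SENSOR, depth=0.4, tau_rise=tau)
        inj = (tr.t >= 60) & (tr.t < 260)
        expected = 60_000.0 + 40_000.0 * np.exp(-(tr.t[inj] - 60.0) / tau)
        np.testing.assert_array_equal(tr.R[inj], expected)

    def test_t90_matches_closed_form(self):
        """Time to 90% of the drop is tau*ln(10), found by dense sampling."""
        tau = 20.0
        sched = PhaseSchedule(sample_period_s=0.01)
        tr = generate_transient("C2", SENSOR, sched, depth=0.5, tau_rise=tau)
        Ri, Rf = 100_000.0, 50_000.0
        level = Ri - 0.9 * (Ri - Rf)
        t90 = tr.t[(tr.t >= 60) & (tr.R <= level)][0] - 60.0
        assert t90 == pytest.approx(tau * math.log(10), abs=0.011)

    def test_monotone_class_effect(self):
        """Higher-quality class gives a deeper response on every sensor."""
        depths = {}
        for cls in ("C1", "C2", "C3"):
            tr = generate_transient(cls, SENSOR)
            depths[cls] = 1.0 - tr.R[tr.t == 259][0] / 100_000.0
        assert depths["C1"] < depths["C2"] < depths["C3"]

    def test_depth_out_of_range_rejected(self):
        for bad in (0.0, 1.0, 1.5, -0.2):
            with pytest.raises(ValueError, match="depth"):
                generate_transient("C1", SENSOR, depth=bad)

    def test_noise_requires_rng(self):
        with pytest.raises(ValueError, match="rng"):
            generate_transient("C1", SENSOR, depth=0.3, noise_cv=0.05)

    def test_all_samples_positive_under_noise(self, rng):
        tr = generate_transient("C1", SENSOR, rng=rng, depth=0.3, noise_cv=0.1)
        assert np.all(tr.R > 0)


class TestDataset:
    def test_default_size_and_label_marginals(self, default_dataset):
        measurements, labels, _ = default_dataset
        assert len(measurements) == 150
        assert {c: labels.count(c) for c in ("C1", "C2", "C3")} == {
            "C1": 60, "C2": 45, "C3": 45,
        }
        assert all(len(m.transients) == 7 for m in measurements)

    def test_small_grid(self, tiny_dataset):
        measurements, labels, _ = tiny_dataset
        assert len(measurements) == 9
        assert sorted(set(labels)) == ["C1", "C2", "C3"]

    def test_labels_derive_from_constituent_totals(self, default_dataset):
        _, labels, profiles = default_dataset
        from rosenose.gcms import assign_quality_class

        by_genotype = label_dataset(profiles)
        for p in profiles:
            assert by_genotype[p.genotype_id] == assign_quality_class(
                total_key_constituents(p)
            )

    def test_same_seed_reproduces_byte_identical_csv(self, tmp_path):
        cfg = default_config(n_genotypes=2, replicates_per_genotype=2,
                            genotype_classes=("C1", "C3"),
                            genotype_coords={"g1": (0.2, 0.2), "g2": (0.6, 0.6)})
        paths = []
        for run in ("a", "b"):
            meas, _, _ = generate_dataset(cfg)
            p = tmp_path / f"{run}.csv"
            write_measurements_csv(meas, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_different_seeds_differ(self):
        m1, _, _ = generate_dataset(default_config(n_genotypes=1, rng_seed=1,
                                                   replicates_per_genotype=1,
                                                   genotype_classes=("C1",)))
        m2, _, _ = generate_dataset(default_config(n_genotypes=1, rng_seed=2,
                                                   replicates_per_genotype=1,
                                                   genotype_classes=("C1",)))
        assert not np.array_equal(m1[0].transients["S1"].R, m2[0].transients["S1"].R)

    def test_noiseless_dataset_matches_closed_form(self):
        """With all noise off, every curve equals its piecewise exponential."""
        from rosenose.synthetic import _closed_form_curve, _DEFAULT_SENSORS

        cfg = default_config(noise_cv=0.0, depth_jitter_cv=0.0,
                             replicates_per_genotype=1)
        meas, _, _ = generate_dataset(cfg)
        coords = cfg.genotype_coords
        for m in meas[:3]:
            for s in _DEFAULT_SENSORS:
                tr = m.transients[s.sensor_id]
                d = s.depth_at(coords[m.genotype])
                expected = _closed_form_curve(
                    tr.t, tr.schedule, s.baseline_ohm, d, cfg.tau_rise, cfg.tau_recovery
                )
                np.testing.assert_array_equal(tr.R, expected)


class TestConstituentTable:
    def test_totals_fall_in_class_ranges(self):
        cfg = default_config(rng_seed=3)
        profiles = generate_constituent_table(cfg)
        labels = label_dataset(profiles)
        for p, cls in zip(profiles, cfg.genotype_classes):
            lo, hi = cfg.class_spec[cls]
            assert lo <= total_key_constituents(p) <= hi
            assert labels[p.genotype_id] == cls

    def test_custom_narrow_range(self):
        cfg = default_config(n_genotypes=4, genotype_classes=("C1",) * 4,
                            class_spec={"C1": (2.0, 9.0)})
        profiles = generate_constituent_table(cfg)
        assert all(2.0 <= total_key_constituents(p) <= 9.0 for p in profiles)
        assert set(label_dataset(profiles).values()) == {"C1"}

    def test_infeasible_range_rejected(self):
        with pytest.raises(ValueError):
            default_config(class_spec={"C1": (9.0, 2.0), "C2": (12, 45), "C3": (52, 80)})

    def test_reference_mode_returns_packaged_table(self, reference_profiles):
        cfg = default_config(use_reference_profiles=True)
        profiles = generate_constituent_table(cfg)
        assert [p.genotype_id for p in profiles] == [p.genotype_id for p in reference_profiles]
        assert total_key_constituents(profiles[-1]) == pytest.approx(76.77)

    def test_deterministic(self):
        cfg = default_config(rng_seed=11)
        t1 = generate_constituent_table(cfg)
        t2 = generate_constituent_table(cfg)
        assert all(a.percents == b.percents for a, b in zip(t1, t2))


class TestConfig:
    @pytest.mark.parametrize("bad", [
        dict(replicates_per_genotype=0),
        dict(noise_cv=-0.1),
        dict(tau_rise=0.0),
        dict(genotype_classes=("C1",)),
        dict(genotype_classes=("C9",) * 10),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            dataclasses.replace(GeneratorConfig(), **bad)

    def test_yaml_round_trip(self, tmp_path):
        cfg = default_config(rng_seed=42, noise_cv=0.03)
        path = tmp_path / "config.yaml"
        config_to_yaml(cfg, path)
        assert config_from_yaml(path) == cfg
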