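import numpy as np
import pytest
from scipy import stats

from sigres.chdir import ShrinkageParams, batch_directions, cosine_distance
from sigres.io_core import assemble_batches
from sigres.synthetic_data import (
    SimulationConfig,
    bliss_gr,
    gr_curve_value,
    make_gr_params,
    simulate_combo,
    simulate_counts,
    simulate_expression,
)


def tiny(**kw) -> SimulationConfig:
    base = dict(
        n_genes=40, n_cell_lines=2, n_drugs=4, n_classes=2, J=3, N=6,
        time_points=(24.0,), seed=7,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestConfig:
    def test_doses_must_increase(self):
        with pytest.raises(ValueError):
            SimulationConfig(doses=(1.0, 1.0, 2.0))

    def test_default_doses_span_250_fold(self):
        cfg = SimulationConfig()
        assert cfg.doses[-1] / cfg.doses[0] == pytest.approx(250.0)
        assert len(cfg.doses) == 6

    def test_shared_fraction_bounds(self):
        with pytest.raises(ValueError):
            tiny(shared_fraction=1.5)
        with pytest.raises(ValueError):
            tiny(shared_fraction=-0.1)

    def test_amplitude_monotone_in_dose(self):
        cfg = tiny(effect_size=2.0)
        amps = [cfg.amplitude(d) for d in cfg.doses]
        assert all(a < b for a, b in zip(amps, amps[1:]))


class TestSimulateExpression:
    def test_deterministic_given_seed(self):
        m1, _ = simulate_expression(tiny())
        m2, _ = simulate_expression(tiny())
        np.testing.assert_array_equal(m1.values, m2.values)

    def test_different_seed_differs(self):
        m1, _ = simulate_expression(tiny())
        m2, _ = simulate_expression(tiny(seed=8))
        assert not np.array_equal(m1.values, m2.values)

    def test_well_bookkeeping(self):
        cfg = tiny()
        m, _ = simulate_expression(cfg)
        # (N controls + drugs x doses) x J plates x lines x times
        per_plate = cfg.N + cfg.n_drugs * len(cfg.doses)
        assert m.n_wells == per_plate * cfg.J * 2
        m.validate()

    def test_null_config_exchangeable_with_controls(self):
        # effect_size = 0: treated wells match controls; pooled two-sample
        # test non-significant in nearly all repeated sims (10 here)
        n_nonsig = 0
        for seed in range(10):
            cfg = tiny(effect_size=0.0, seed=seed, plate_effect_sd=0.0)
            m, _ = simulate_expression(cfg)
            treated = np.concatenate(
                [m.values[:, i] for i, w in enumerate(m.wells)
                 if not w.is_vehicle]
            )
            control = np.concatenate(
                [m.values[:, i] for i, w in enumerate(m.wells)
                 if w.is_vehicle]
            )
            p = stats.mannwhitneyu(treated, control).pvalue
            n_nonsig += p > 0.01
        assert n_nonsig >= 9

    def test_shared_fraction_one_directions_identical_across_lines(self):
        cfg = tiny(shared_fraction=1.0)
        _, truth = simulate_expression(cfg)
        for drug in cfg.drugs:
            d1 = truth.direction_for(drug, "CL1")
            d2 = truth.direction_for(drug, "CL2")
            assert cosine_distance(d1, d2) == pytest.approx(0.0)

    def test_shared_fraction_zero_directions_differ(self):
        cfg = tiny(shared_fraction=0.0)
        _, truth = simulate_expression(cfg)
        for drug in cfg.drugs:
            d1 = truth.direction_for(drug, "CL1")
            d2 = truth.direction_for(drug, "CL2")
            assert cosine_distance(d1, d2) > 0.5

    def test_planted_directions_unit_norm(self):
        _, truth = simulate_expression(tiny())
        for v in truth.directions.values():
            assert np.linalg.norm(v) == pytest.approx(1.0)

    def test_recovery_oracle(self):
        # large effect -> chdir recovers the planted direction
        cfg = tiny(effect_size=4.0, noise_sd=0.05,
                   specific_amplitude_range=(1.0, 1.0))
        m, truth = simulate_expression(cfg)
        batch = assemble_batches(m)[0]
        _, sigs = batch_directions(batch, ShrinkageParams(gamma=1.0))
        top_dose = max(cfg.doses)
        for key, sig in sigs.items():
            if key[2] == top_dose:
                planted = truth.direction_for(key[1], key[0])
                assert cosine_distance(sig.vector, planted) < 0.1

    def test_rotation_mode_rotates_with_dose(self):
        cfg = tiny(n_rotation_classes=1, effect_size=4.0, noise_sd=0.02,
                   shared_fraction=1.0, rotation_max_deg=60.0)
        m, truth = simulate_expression(cfg)
        batch = assemble_batches(m)[0]
        _, sigs = batch_directions(batch, ShrinkageParams(gamma=1.0))
        rot_class = next(iter(truth.rotation_classes))
        rot_drug = next(d for d in cfg.drugs
                        if truth.class_of_drug[d] == rot_class)
        fix_drug = next(d for d in cfg.drugs
                        if truth.class_of_drug[d] != rot_class)
        lo, hi = cfg.doses[0], cfg.doses[-1]
        line = batch.cell_line
        d_rot = cosine_distance(
            sigs[(line, rot_drug, lo, 24.0)].vector,
            sigs[(line, rot_drug, hi, 24.0)].vector,
        )
        d_fix = cosine_distance(
            sigs[(line, fix_drug, lo, 24.0)].vector,
            sigs[(line, fix_drug, hi, 24.0)].vector,
        )
        assert d_rot > d_fix + 0.1


class TestSimulateCounts:
    def test_resistant_line_gr_near_one(self):
        cfg = tiny()
        params = {(d, l): (1.0, 1.0, 2.0) for d in cfg.drugs
                  for l in cfg.cell_lines}
        cfg = tiny(gr_params=params, count_noise_sd=0.01)
        counts = simulate_counts(cfg)
        from sigres.gr_metrics import gr_table

        table = gr_table(counts)
        assert np.allclose(table["GR"], 1.0, atol=0.1)

    def test_cytotoxic_below_day0(self):
        cfg = tiny()
        params = {(d, l): (-1.0 + 1e-9, 0.05, 3.0) for d in cfg.drugs
                  for l in cfg.cell_lines}
        cfg = tiny(gr_params=params, count_noise_sd=0.01)
        counts = simulate_counts(cfg)
        top = counts.data[
            (counts.data["concentration"] == max(cfg.doses))
            & counts.data["drug2"].isna()
        ]
        x0 = counts.day0_counts("CL1").mean()
        assert (top["count"] < x0).all()

    def test_nonpositive_day0_rejected(self):
        with pytest.raises(ValueError):
            tiny(day0_count=0.0)

    def test_missing_gr_params_rejected(self):
        cfg = tiny(gr_params={})
        with pytest.raises(ValueError):
            simulate_counts(cfg)

    def test_make_gr_params_deterministic(self):
        assert make_gr_params(tiny()) == make_gr_params(tiny())

    def test_table_validates(self):
        counts = simulate_counts(tiny())
        counts.validate()


class TestSimulateCombo:
    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            simulate_combo(tiny(), "superadditive")

    def test_bliss_zero_noise_gives_zero_eob(self):
        from sigres.synergy import checkerboard_from_counts

        cfg = tiny(count_noise_sd=1e-12)
        counts = simulate_combo(cfg, "bliss_independent")
        for res in checkerboard_from_counts(counts):
            assert res.eob_mean == pytest.approx(0.0, abs=1e-6)

    def test_antagonistic_negative_eob(self):
        from sigres.synergy import checkerboard_from_counts

        cfg = tiny(count_noise_sd=1e-12, planted_eob=0.2)
        counts = simulate_combo(cfg, "antagonistic")
        means = [r.eob_mean for r in checkerboard_from_counts(counts)]
        assert np.mean(means) < -0.1
        assert all(m < 1e-6 for m in means)

    def test_synergistic_recovery(self):
        from sigres.synergy import checkerboard_from_counts

        cfg = tiny(count_noise_sd=0.02, planted_eob=0.3)
        counts = simulate_combo(cfg, "synergistic")
        means = [r.eob_mean for r in checkerboard_from_counts(counts)]
        assert np.mean(means) == pytest.approx(0.3, abs=0.05)

    def test_bliss_helper_matches_formula(self):
        for ga, gb in [(0.5, 0.5), (1.0, 0.3), (-0.2, 0.8)]:
            ea, eb = 1 - ga, 1 - gb
            assert bliss_gr(ga, gb) == pytest.approx(
                1 - (ea + eb - ea * eb)
            )
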