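import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sigres.variability import (
    class_medians,
    cross_line_sd,
    dose_shift,
    gr_aoc_sd,
    rank_correlation,
    scs_cv,
)


class TestScsCv:
    def _df(self, scs_by_line, drug="d1", conc=1.0):
        return pd.DataFrame(
            [
                {"cell_line": line, "drug": drug, "concentration": conc,
                 "SCS": v, "target_class": "tc"}
                for line, v in scs_by_line.items()
            ]
        )

    def test_identical_scs_zero_cv(self):
        out = scs_cv(self._df({"A": 2.0, "B": 2.0, "C": 2.0}))
        assert out["cv"].iloc[0] == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        out = scs_cv(self._df({"A": 1.0, "B": 2.0, "C": 3.0}))
        assert out["cv"].iloc[0] == pytest.approx(0.5)

    def test_single_line_group_skipped(self):
        out = scs_cv(self._df({"A": 1.0}))
        assert out.empty

    def test_nonpositive_mean_skipped(self):
        out = scs_cv(self._df({"A": 0.0, "B": 0.0}))
        assert out.empty


class TestGrAocSd:
    def test_identical_zero(self):
        df = pd.DataFrame(
            [{"cell_line": l, "drug": "d", "GR_AOC": 0.5} for l in "ABC"]
        )
        assert gr_aoc_sd(df)["sd"].iloc[0] == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        df = pd.DataFrame(
            [{"cell_line": "A", "drug": "d", "GR_AOC": 0.2},
             {"cell_line": "B", "drug": "d", "GR_AOC": 0.4}]
        )
        assert gr_aoc_sd(df)["sd"].iloc[0] == pytest.approx(
            np.sqrt(0.02), abs=1e-4
        )

    def test_single_line_skipped(self):
        df = pd.DataFrame([{"cell_line": "A", "drug": "d", "GR_AOC": 0.2}])
        assert gr_aoc_sd(df).empty

    def test_planted_sensitivity_ordering(self):
        rng = np.random.default_rng(0)
        rows = []
        for d in range(10):
            for line in "ABCD":
                rows.append({"cell_line": line, "drug": f"u{d}",
                             "target_class": "uniform",
                             "GR_AOC": 0.5 + rng.normal(0, 0.02)})
                rows.append({"cell_line": line, "drug": f"v{d}",
                             "target_class": "variable",
                             "GR_AOC": rng.uniform(0.0, 1.0)})
        out = gr_aoc_sd(pd.DataFrame(rows))
        med = class_medians(out, "sd")
        assert med["uniform"] < med["variable"]


class TestDoseShift:
    def _sigs(self, rng, rotate=False):
        g = 30
        base = rng.standard_normal(g)
        base /= np.linalg.norm(base)
        orth = rng.standard_normal(g)
        orth -= (orth @ base) * base
        orth /= np.linalg.norm(orth)
        sigs = {}
        for li, line in enumerate(["CL1", "CL2"]):
            for drug, cls in [("dA", "rot"), ("dB", "fix")]:
                for dose in (0.1, 10.0):
                    if cls == "rot" and rotate and dose == 10.0:
                        v = np.cos(0.8) * base + np.sin(0.8) * orth
                    else:
                        v = base
                    noise = 0.02 * rng.standard_normal(g)
                    v = v + noise
                    sigs[(line, drug, dose, 24.0)] = v / np.linalg.norm(v)
        return sigs

    def test_identical_cds_zero_distance(self, rng):
        sigs = self._sigs(rng, rotate=False)
        out = dose_shift(sigs, 0.1, 10.0,
                         target_class_of={"dA": "rot", "dB": "fix"})
        for dist in out:
            assert np.all(dist.distances < 0.05)

    def test_rotation_class_dominates(self, rng):
        sigs = self._sigs(rng, rotate=True)
        out = dose_shift(sigs, 0.1, 10.0,
                         target_class_of={"dA": "rot", "dB": "fix"})
        by_class = {d.target_class: d.distances for d in out}
        assert by_class["rot"].min() > by_class["fix"].max()

    def test_rotation_mode_simulation_dominates(self):
        # generator rotation mode: that class's dose-shift distribution
        # stochastically dominates (one-sided Mann-Whitney)
        from sigres.chdir import ShrinkageParams, batch_directions
        from sigres.io_core import assemble_batches
        from sigres.synthetic_data import SimulationConfig, simulate_expression

        cfg = SimulationConfig(
            n_genes=60, n_cell_lines=3, n_drugs=20, n_classes=2,
            J=3, N=6, time_points=(24.0,), effect_size=4.0, noise_sd=0.05,
            shared_fraction=1.0, n_rotation_classes=1, seed=13,
        )
        m, truth = simulate_expression(cfg)
        sigs = {}
        for batch in assemble_batches(m):
            _, s = batch_directions(batch, ShrinkageParams(gamma=1.0))
            sigs.update({k: v.vector for k, v in s.items()})
        out = dose_shift(
            sigs, cfg.doses[0], cfg.doses[-1],
            target_class_of=truth.class_of_drug,
        )
        rot_cls = next(iter(truth.rotation_classes))
        rot = next(d for d in out if d.target_class == rot_cls)
        fix = next(d for d in out if d.target_class != rot_cls)
        assert len(rot.distances) >= 20
        p = stats.mannwhitneyu(rot.distances, fix.distances,
                               alternative="greater").pvalue
        assert p < 0.01

    def test_missing_dose_skipped(self, rng):
        sigs = {("CL1", "dA", 0.1, 24.0): np.array([1.0, 0.0])}
        out = dose_shift(sigs, 0.1, 10.0)
        assert out == []

    def test_between_class_baseline_attached(self, rng):
        sigs = self._sigs(rng)
        out = dose_shift(sigs, 0.1, 10.0,
                         target_class_of={"dA": "a", "dB": "b"})
        assert all(d.baseline is not None for d in out)


class TestCrossLineSd:
    def test_constant_abundance_zero(self):
        df = pd.DataFrame({"L1": [10.0], "L2": [10.0]}, index=["p1"])
        out, _ = cross_line_sd(df, {"p1": "g"})
        assert out["sd"].iloc[0] == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        df = pd.DataFrame({"L1": [10.0], "L2": [100.0]}, index=["p1"])
        out, _ = cross_line_sd(df, {"p1": "g"})
        assert out["sd"].iloc[0] == pytest.approx(np.sqrt(0.5), abs=1e-6)

    def test_nonpositive_rejected(self):
        df = pd.DataFrame({"L1": [0.0], "L2": [1.0]}, index=["p1"])
        with pytest.raises(ValueError):
            cross_line_sd(df, {"p1": "g"})

    def test_planted_group_difference_detected(self):
        rng = np.random.default_rng(5)
        n = 20
        entities = [f"hi{i}" for i in range(n)] + [f"lo{i}" for i in range(n)]
        data = np.vstack(
            [10 ** rng.normal(2, 1.0, (n, 4)), 10 ** rng.normal(2, 0.1, (n, 4))]
        )
        df = pd.DataFrame(data, index=entities,
                          columns=["L1", "L2", "L3", "L4"])
        groups = {e: ("RTK" if e.startswith("hi") else "signaling")
                  for e in entities}
        out, p = cross_line_sd(df, groups, test_pair=("RTK", "signaling"))
        assert p < 0.01
        med = out.groupby("group")["sd"].median()
        assert med["RTK"] > med["signaling"]


class TestRankCorrelation:
    def test_increasing(self):
        rho, _ = rank_correlation([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)

    def test_decreasing(self):
        rho, _ = rank_correlation([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_tie_handling_matches_brute_force(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 3.0, 6.0]
        rho, _ = rank_correlation(x, y)
        rx = stats.rankdata(x)  # average ranks
        ry = stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            rank_correlation([1, 1, 1], [1, 2, 3])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            rank_correlation([1, 2], [1, 2])
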