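import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sexstrat.ld import LdMatrix
from sexstrat.mr import (
    GRID_ALPHA,
    InstrumentSet,
    MrResult,
    build_instrument_set,
    call_sex_specific_mr,
    mr_egger,
    restrict_to_dmet,
    run_mr_grid,
    select_instruments,
)
from sexstrat.regions import GeneRegion
from sexstrat.simulate import simulate_mr_scenario
from conftest import make_table
from oracles import wls_line


def _inst(bx, by, by_se, bx_se=None, stratum="combined"):
    n = len(bx)
    df = pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(n)], "chrom": "1",
        "pos": 1000 + np.arange(n),
        "bx": bx, "bx_se": bx_se if bx_se is not None else [0.01] * n,
        "by": by, "by_se": by_se,
    })
    return InstrumentSet("exposure", "outcome", stratum, df)


class TestMrEgger:
    def test_exact_proportional_fit(self):
        bx = [0.1, 0.2, 0.3, 0.4]
        res = mr_egger(_inst(bx, [0.05, 0.10, 0.15, 0.20], [0.01] * 4))
        assert res.slope == pytest.approx(0.5, abs=1e-12)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)

    def test_exact_fit_with_intercept(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 0.1 + 0.5 * bx
        res = mr_egger(_inst(bx, by, [0.01] * 4))
        assert res.slope == pytest.approx(0.5, abs=1e-12)
        assert res.intercept == pytest.approx(0.1, abs=1e-12)

    def test_matches_closed_form_wls_oracle(self):
        bx = np.array([0.12, 0.31, 0.22])
        by = np.array([0.10, 0.12, 0.05])
        by_se = np.array([0.02, 0.05, 0.03])
        res = mr_egger(_inst(bx, by, by_se))
        w = 1.0 / by_se**2
        intercept, slope, se_i_unit, se_s_unit, sigma = wls_line(bx, by, w)
        assert res.slope == pytest.approx(slope, abs=1e-10)
        assert res.intercept == pytest.approx(intercept, abs=1e-10)
        infl = max(sigma, 1.0)
        assert res.slope_se == pytest.approx(se_s_unit * infl, abs=1e-10)
        assert res.intercept_se == pytest.approx(se_i_unit * infl, abs=1e-10)
        t = slope / (se_s_unit * infl)
        assert res.slope_p == pytest.approx(2 * sps.t.sf(abs(t), 1), rel=1e-10)

    def test_scale_equivariance_in_outcome(self):
        rng = np.random.default_rng(5)
        bx = rng.uniform(0.05, 0.4, 10)
        by = 0.02 + 0.3 * bx + rng.normal(0, 0.05, 10)
        by_se = rng.uniform(0.01, 0.05, 10)
        r1 = mr_egger(_inst(bx, by, by_se))
        k = 3.7
        r2 = mr_egger(_inst(bx, k * by, k * by_se))
        assert r2.slope == pytest.approx(k * r1.slope, rel=1e-10)
        assert r2.intercept == pytest.approx(k * r1.intercept, rel=1e-10)
        assert r2.slope_se == pytest.approx(k * r1.slope_se, rel=1e-10)
        assert r2.slope_p == pytest.approx(r1.slope_p, rel=1e-10)

    def test_orientation_invariance(self):
        rng = np.random.default_rng(6)
        bx = rng.uniform(0.05, 0.4, 8)
        by = 0.3 * bx + rng.normal(0, 0.02, 8)
        by_se = np.full(8, 0.02)
        r1 = mr_egger(_inst(bx, by, by_se))
        bx2, by2 = bx.copy(), by.copy()
        bx2[3] *= -1
        by2[3] *= -1
        r2 = mr_egger(_inst(bx2, by2, by_se))
        assert r2.slope == pytest.approx(r1.slope, rel=1e-12)
        assert r2.intercept == pytest.approx(r1.intercept, rel=1e-12)

    def test_too_few_instruments_rejected(self):
        with pytest.raises(ValueError):
            mr_egger(_inst([0.1, 0.2], [0.05, 0.1], [0.01, 0.01]))

    def test_all_zero_exposure_rejected(self):
        with pytest.raises(ValueError):
            mr_egger(_inst([0.0, 0.0, 0.0], [0.1, 0.1, 0.1], [0.01] * 3))

    def test_theta_recovery_under_balanced_pleiotropy(self):
        slopes = []
        for seed in range(60):
            exp, out, _ = simulate_mr_scenario(
                0.3, pleiotropy_mode="balanced", n_inst=50, seed=seed)
            inst = _inst(exp.df["beta"], out.df["beta"], out.df["se"],
                         bx_se=exp.df["se"])
            slopes.append(mr_egger(inst).slope)
        assert np.mean(slopes) == pytest.approx(0.3, abs=0.05)


class TestSelectInstruments:
    def _table(self, pvals, pos=None):
        rows = [{"pos": (pos[i] if pos else 1000 + i), "pval": p,
                 "beta": 0.1, "se": 0.01} for i, p in enumerate(pvals)]
        return make_table(rows)

    def test_threshold_applied(self):
        table = self._table([1e-9, 1e-7])
        got = select_instruments(table, ld=LdMatrix(
            table.variant_ids.tolist(), np.eye(2)))
        assert got == [table.variant_ids[0]]

    def test_correlated_pair_clumps_to_smaller_p(self):
        table = self._table([1e-9, 1e-10])
        ld = LdMatrix(table.variant_ids.tolist(),
                      np.array([[1.0, 0.9], [0.9, 1.0]]))
        got = select_instruments(table, ld=ld, clump_r2=0.001)
        assert got == [table.variant_ids[1]]

    def test_no_significant_variants_empty(self):
        assert select_instruments(self._table([0.5, 0.2])) == []


class TestSexSpecificCall:
    def _res(self, p):
        return MrResult(0.3, 0.1, p, 0.0, 0.1, 0.5, 10)

    def test_male_specific_at_grid_threshold(self):
        assert GRID_ALPHA == pytest.approx(0.05 / 5394)
        got = call_sex_specific_mr(self._res(0.2), self._res(1e-7), self._res(0.3))
        assert got == "male_specific"

    def test_female_specific(self):
        got = call_sex_specific_mr(self._res(0.2), self._res(0.3), self._res(1e-7))
        assert got == "female_specific"

    def test_all_significant_not_sex_specific(self):
        got = call_sex_specific_mr(self._res(1e-8), self._res(1e-8), self._res(1e-8))
        assert got == "not_sex_specific"

    def test_nothing_significant_none(self):
        assert call_sex_specific_mr(self._res(0.5), self._res(0.5), self._res(0.5)) == "none"

    def test_absent_result_counts_as_not_significant(self):
        assert call_sex_specific_mr(None, self._res(1e-7), None) == "male_specific"


class TestRestrictToDmet:
    def _regions(self):
        return [GeneRegion("g", "1", "+", 1000, flank=50)]

    def test_all_inside_identity(self):
        inst = _inst([0.1, 0.2, 0.3], [0.05, 0.1, 0.15], [0.01] * 3)
        sub, status = restrict_to_dmet(inst, self._regions())
        assert status == "ok" and len(sub) == 3

    def test_none_inside_underpowered(self):
        inst = _inst([0.1, 0.2, 0.3], [0.05, 0.1, 0.15], [0.01] * 3)
        far = [GeneRegion("g", "2", "+", 1000, flank=50)]
        sub, status = restrict_to_dmet(inst, far)
        assert status == "underpowered" and sub is None

    def test_matches_bruteforce_containment(self, rng):
        n = 30
        df = pd.DataFrame({
            "variant_id": [f"v{i}" for i in range(n)], "chrom": "1",
            "pos": rng.integers(1, 5000, n),
            "bx": rng.uniform(0.05, 0.3, n), "bx_se": 0.01,
            "by": rng.uniform(-0.1, 0.1, n), "by_se": 0.02})
        inst = InstrumentSet("e", "o", "combined", df)
        regs = [GeneRegion(f"g{i}", "1", "+", int(t), flank=200)
                for i, t in enumerate(rng.integers(300, 4500, 5))]
        sub, status = restrict_to_dmet(inst, regs)
        want = [any(r.contains("1", p) for r in regs) for p in df["pos"]]
        if sum(want) >= 3:
            assert status == "ok"
            assert sub.df["variant_id"].tolist() == df.loc[want, "variant_id"].tolist()
        else:
            assert status == "underpowered"


class TestGrid:
    def _strata_tables(self, trait_id, seed, theta=0.5):
        tables = {}
        for i, stratum in enumerate(("combined", "male", "female")):
            exp, out, _ = simulate_mr_scenario(theta, n_inst=10, seed=seed + i)
            exp.trait_id = f"{trait_id}_exp"
            out.trait_id = f"{trait_id}_out"
            exp.stratum = out.stratum = stratum
            tables[stratum] = (exp, out)
        return tables

    def test_grid_completes_all_cells(self):
        exposures, outcomes = {}, {}
        for t, seed in (("t1", 10), ("t2", 20)):
            per = self._strata_tables(t, seed)
            exposures[f"{t}_exp"] = {s: per[s][0] for s in per}
            outcomes[f"{t}_out"] = {s: per[s][1] for s in per}
        grid = run_mr_grid(exposures, outcomes)
        assert len(grid) == 2 * 2 * 3
        assert set(grid["status"]) <= {"ok", "no_instruments", "too_few_instruments"}
        ok = grid[grid["status"] == "ok"]
        assert len(ok) > 0 and ok["n_inst"].min() >= 3

    def test_no_instruments_recorded_not_raised(self):
        weak = make_table([{"pos": 1000 + i, "pval": 0.5} for i in range(5)])
        out = make_table([{"pos": 1000 + i} for i in range(5)])
        grid = run_mr_grid({"e": {"combined": weak}}, {"o": {"combined": out}},
                           strata=("combined",))
        assert grid["status"].tolist() == ["no_instruments"]

    def test_missing_stratum_recorded(self):
        exp, out, _ = simulate_mr_scenario(0.3, n_inst=5, seed=1)
        grid = run_mr_grid({"e": {"combined": exp}}, {"o": {"combined": out}},
                           strata=("combined", "male"))
        by_stratum = grid.set_index("stratum")["status"]
        assert by_stratum["male"] == "missing_stratum"


class TestBuildInstrumentSet:
    def test_outcome_harmonized_by_allele(self):
        exp = make_table([{"pos": 100, "effect_allele": "A", "other_allele": "G",
                           "beta": 0.2, "pval": 1e-9}])
        out = make_table([{"pos": 100, "effect_allele": "G", "other_allele": "A",
                           "beta": 0.1}])
        inst = build_instrument_set(exp, out, exp.variant_ids.tolist())
        assert inst.df["by"].iloc[0] == pytest.approx(-0.1)
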