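"""Boltzmann weighting, shift scaling, error statistics and the DP4+ engine."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.special import gammaln

from fpcrevise import dft_nmr as dn
from fpcrevise.dft_nmr import (Conformer, ConformerEnsemble, DP4ParameterError,
                               DP4Parameters, EnsembleError, NucleusRecord,
                               ScalingFactors, R_KCAL)


def _ensemble(energies, shield_rows, nuclei=None, candidate_id="cand"):
    ids = [f"C-{i + 1}" for i in range(len(shield_rows[0]))]
    nuclei = nuclei or {n: NucleusRecord(n, "C", "sp2") for n in ids}
    e = np.asarray(energies, dtype=float)
    e -= e.min()
    return ConformerEnsemble(
        candidate_id=candidate_id,
        conformers=tuple(
            Conformer(float(ei), dict(zip(ids, row)))
            for ei, row in zip(e, shield_rows)
        ),
        nuclei=nuclei,
    )


class TestEnsembleIO:
    def _frame(self):
        rows = []
        for conf, e in (("c1", 0.0), ("c2", 0.5)):
            for i, s in enumerate((120.0, 80.0, 30.0)):
                rows.append(("cand", conf, e, f"C-{i + 1}", "C",
                             "sp2" if i == 0 else "sp3", s + (1 if conf == "c2" else 0)))
        return pd.DataFrame(rows, columns=[
            "candidate_id", "conformer_id", "rel_energy_kcal", "nucleus_id",
            "element", "hybridization", "shielding_ppm"])

    def test_toy_parse(self, tmp_path):
        path = tmp_path / "ens.csv"
        self._frame().to_csv(path, index=False)
        (ens,) = dn.read_ensemble_table(path)
        assert ens.candidate_id == "cand"
        assert np.allclose(ens.energies, [0.0, 0.5])
        assert set(ens.nuclei) == {"C-1", "C-2", "C-3"}

    def test_kj_conversion(self, tmp_path):
        df = self._frame()
        df.loc[df["conformer_id"] == "c2", "rel_energy_kcal"] = 4.184
        path = tmp_path / "ens.csv"
        df.to_csv(path, index=False)
        (ens,) = dn.read_ensemble_table(path, energies_in_kj=True)
        assert ens.energies[1] == pytest.approx(1.0)

    def test_missing_shielding_located(self, tmp_path):
        df = self._frame()
        df.loc[2, "shielding_ppm"] = np.nan
        path = tmp_path / "ens.csv"
        df.to_csv(path, index=False)
        with pytest.raises(EnsembleError, match=r"c1.*C-3"):
            dn.read_ensemble_table(path)

    def test_inconsistent_nucleus_set(self, tmp_path):
        df = self._frame().drop(index=5)  # drop C-3 from conformer c2
        path = tmp_path / "ens.csv"
        df.to_csv(path, index=False)
        with pytest.raises(EnsembleError, match="C-3"):
            dn.read_ensemble_table(path)


class TestEnergyFilter:
    def test_boundary_inclusive(self):
        ens = _ensemble([0.0, 2.9, 3.0, 3.1], [[100.0]] * 4)
        out = dn.filter_energy_window(ens, 3.0)
        assert np.allclose(out.energies, [0.0, 2.9, 3.0])

    def test_single_conformer_unchanged(self):
        ens = _ensemble([0.0], [[100.0]])
        assert dn.filter_energy_window(ens).conformers == ens.conformers

    def test_matches_brute_force_on_random_ensembles(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = rng.integers(1, 12)
            energies = np.concatenate([[0.0], rng.uniform(0, 6, n - 1)])
            ens = _ensemble(energies, [[100.0]] * n)
            w = float(rng.uniform(0.5, 5.0))
            kept = dn.filter_energy_window(ens, w).energies
            brute = [e for e in ens.energies if e <= w]
            assert np.allclose(kept, brute)


class TestBoltzmannWeights:
    def test_single_and_symmetric(self):
        assert dn.boltzmann_weights([0.0]) == pytest.approx([1.0])
        assert np.allclose(dn.boltzmann_weights([2.0, 2.0]), [0.5, 0.5])

    def test_two_state_closed_form(self):
        w = dn.boltzmann_weights([0.0, 1.0], T=298.15)
        expected = 1.0 / (1.0 + math.exp(-1.0 / (R_KCAL * 298.15)))
        assert expected == pytest.approx(0.844, abs=5e-4)
        assert w[0] == pytest.approx(expected, abs=1e-10)

    def test_offset_invariance_and_monotonicity(self):
        rng = np.random.default_rng(3)
        e = np.sort(rng.uniform(0, 5, 8))
        w1 = dn.boltzmann_weights(e)
        w2 = dn.boltzmann_weights(e + 123.4)
        assert np.allclose(w1, w2, atol=1e-12)
        assert np.all(np.diff(w1) <= 1e-15)

    @given(st.lists(st.floats(0, 50), min_size=1, max_size=20),
           st.floats(10, 1000))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_weights_sum_to_one(self, energies, T):
        w = dn.boltzmann_weights(energies, T=T)
        assert abs(w.sum() - 1.0) < 1e-12
        assert (w >= 0).all()

    def test_empty_rejected(self):
        with pytest.raises(EnsembleError):
            dn.boltzmann_weights([])


class TestAverageShieldings:
    def test_identical_conformers(self):
        ens = _ensemble([0.0, 1.0], [[100.0, 50.0], [100.0, 50.0]])
        avg = dn.average_shieldings(ens, [0.3, 0.7])
        assert avg == {"C-1": pytest.approx(100.0), "C-2": pytest.approx(50.0)}

    def test_weighted_mean(self):
        ens = _ensemble([0.0, 0.5], [[100.0], [104.0]])
        avg = dn.average_shieldings(ens, [0.75, 0.25])
        assert avg["C-1"] == pytest.approx(101.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        rows = rng.normal(100, 5, size=(5, 4))
        ens = _ensemble(np.concatenate([[0], rng.uniform(0, 3, 4)]), rows)
        w = dn.boltzmann_weights(ens.energies)
        avg = dn.average_shieldings(ens, w)
        for j, nid in enumerate(sorted(avg)):
            brute = sum(w[i] * ens.conformers[i].shieldings[nid]
                        for i in range(5))
            assert avg[nid] == pytest.approx(brute, abs=1e-12)

    def test_equivalence_group_collapsed(self):
        ids = ["H-a", "H-b", "H-c", "C-1"]
        nuclei = {
            "H-a": NucleusRecord("H-a", "H", "sp3", "Me-7"),
            "H-b": NucleusRecord("H-b", "H", "sp3", "Me-7"),
            "H-c": NucleusRecord("H-c", "H", "sp3", "Me-7"),
            "C-1": NucleusRecord("C-1", "C", "sp3"),
        }
        ens = ConformerEnsemble(
            candidate_id="c",
            conformers=(Conformer(0.0, dict(zip(ids, [30.0, 31.0, 32.0, 150.0]))),),
            nuclei=nuclei,
        )
        avg = dn.average_shieldings(ens, [1.0])
        assert set(avg) == {"Me-7", "C-1"}
        assert avg["Me-7"] == pytest.approx(31.0)

    def test_weight_length_mismatch(self):
        ens = _ensemble([0.0, 0.5], [[100.0], [104.0]])
        with pytest.raises(EnsembleError, match="weights"):
            dn.average_shieldings(ens, [1.0])


class TestScaling:
    FACTORS = ScalingFactors(factors={"C": (-1.05, 186.5), "H": (-1.08, 31.9)})

    def test_fixed_point(self):
        out = dn.scale_shifts_global({"C-1": 186.5}, self.FACTORS, {"C-1": "C"})
        assert out["C-1"] == pytest.approx(0.0)

    def test_worked_example(self):
        out = dn.scale_shifts_global({"C-1": 100.0}, self.FACTORS, {"C-1": "C"})
        assert out["C-1"] == pytest.approx((186.5 - 100.0) / 1.05, abs=1e-9)
        assert out["C-1"] == pytest.approx(82.381, abs=1e-3)

    def test_inverse_identity(self):
        rng = np.random.default_rng(11)
        for delta in rng.uniform(0, 200, 20):
            sigma = dn.inverse_scale(delta, "C", self.FACTORS)
            back = dn.scale_shifts_global({"x": sigma}, self.FACTORS,
                                          {"x": "C"})["x"]
            assert back == pytest.approx(delta, abs=1e-10)

    def test_missing_element_rejected(self):
        with pytest.raises(DP4ParameterError, match="N"):
            dn.scale_shifts_global({"N-1": 100.0}, self.FACTORS, {"N-1": "N"})

    def test_unscaled_shifts(self):
        ref = {"C": 190.0}
        out = dn.unscaled_shifts({"C-1": 60.0}, ref, {"C-1": "C"})
        assert out["C-1"] == pytest.approx(130.0)
        out0 = dn.unscaled_shifts({"C-1": 190.0}, ref, {"C-1": "C"})
        assert out0["C-1"] == pytest.approx(0.0)

    @given(st.floats(-50, 250), st.floats(-50, 250))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_unscaled_affine_slope_minus_one(self, s1, s2):
        ref = {"C": 190.0}
        d1 = dn.unscaled_shifts({"x": s1}, ref, {"x": "C"})["x"]
        d2 = dn.unscaled_shifts({"x": s2}, ref, {"x": "C"})["x"]
        assert d2 - d1 == pytest.approx(-(s2 - s1), abs=1e-9)


class TestRegressionScale:
    def test_identity_fit(self):
        exp = {f"C-{i}": 20.0 * i for i in range(1, 6)}
        scaled, fits = dn.regression_scale(exp, exp, {n: "C" for n in exp})
        m, b = fits["C"]
        assert m == pytest.approx(1.0, abs=1e-12)
        assert b == pytest.approx(0.0, abs=1e-9)
        for n in exp:
            assert scaled[n] == pytest.approx(exp[n], abs=1e-9)

    def test_exact_linear_relation_removed(self):
        exp = {f"C-{i}": 15.0 * i + 5 for i in range(1, 8)}
        calc = {n: 2 * v + 5 for n, v in exp.items()}
        scaled, _ = dn.regression_scale(calc, exp, {n: "C" for n in exp})
        for n in exp:
            assert scaled[n] == pytest.approx(exp[n], abs=1e-10)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(23)
        x = rng.uniform(0, 200, 10)
        y = 0.95 * x + 3 + rng.normal(0, 1, 10)
        exp = {f"C-{i}": x[i] for i in range(10)}
        calc = {f"C-{i}": y[i] for i in range(10)}
        _, fits = dn.regression_scale(calc, exp, {n: "C" for n in exp})
        X = np.column_stack([x, np.ones(10)])
        m_ref, b_ref = np.linalg.solve(X.T @ X, X.T @ y)
        assert fits["C"][0] == pytest.approx(m_ref, abs=1e-10)
        assert fits["C"][1] == pytest.approx(b_ref, abs=1e-10)

    def test_too_few_points_rejected(self):
        exp = {"C-1": 10.0, "C-2": 20.0}
        with pytest.raises(EnsembleError, match=">= 3"):
            dn.regression_scale(exp, exp, {n: "C" for n in exp})


class TestErrorStats:
    def test_zero_errors(self):
        exp = {"C-1": 100.0, "C-2": 50.0}
        cmp_ = dn.error_stats(exp, exp)
        assert cmp_.mae == 0.0 and cmp_.rmsd == 0.0

    def test_hand_set_errors(self):
        exp = {"a": 10.0, "b": 20.0, "c": 30.0}
        calc = {"a": 11.0, "b": 18.0, "c": 33.0}  # errors 1, -2, 3
        cmp_ = dn.error_stats(calc, exp)
        assert cmp_.mae == pytest.approx(2.0)
        assert cmp_.rmsd == pytest.approx(math.sqrt(14 / 3))

    def test_element_restriction(self):
        calc = {"C-1": 101.0, "H-1": 5.1}
        exp = {"C-1": 100.0, "H-1": 5.0}
        elements = {"C-1": "C", "H-1": "H"}
        c = dn.error_stats(calc, exp, elements=elements, element="C")
        assert list(c.errors) == ["C-1"]
        with pytest.raises(EnsembleError, match="no shared"):
            dn.error_stats({"C-1": 1.0}, {"H-1": 2.0}, elements=elements,
                           element="H")

    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_mae_bounded_by_rmsd(self, errors):
        exp = {f"n{i}": 0.0 for i in range(len(errors))}
        calc = {f"n{i}": e for i, e in enumerate(errors)}
        cmp_ = dn.error_stats(calc, exp)
        assert cmp_.mae <= cmp_.rmsd + 1e-12


class TestTLikelihood:
    def test_mode_at_mu(self):
        p = (1.5, 2.0, 5.0)
        at_mu = dn.t_likelihood(1.5, p)
        assert at_mu > dn.t_likelihood(1.0, p)
        assert at_mu > dn.t_likelihood(2.0, p)

    def test_normal_limit(self):
        for e in (-2.0, 0.0, 1.3):
            tval = dn.t_likelihood(e, (0.0, 2.0, 1e6))
            nval = stats.norm.pdf(e, scale=2.0)
            assert tval == pytest.approx(nval, abs=1e-4)

    def test_gamma_closed_form(self):
        mu, sigma, nu, e = 0.0, 2.0, 5.0, 1.0
        z = (e - mu) / sigma
        log_f = (gammaln((nu + 1) / 2) - gammaln(nu / 2)
                 - 0.5 * math.log(nu * math.pi)
                 - (nu + 1) / 2 * math.log1p(z * z / nu)) - math.log(sigma)
        assert dn.t_likelihood(e, (mu, sigma, nu)) == pytest.approx(
            math.exp(log_f), rel=1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(DP4ParameterError):
            dn.t_likelihood(0.0, (0.0, -1.0, 5.0))


PARAMS = DP4Parameters(
    scaled={"C": (0.0, 2.0, 10.0), "H": (0.0, 0.2, 10.0)},
    unscaled={"C": {"sp2": (0.0, 3.0, 10.0), "sp3": (0.0, 2.5, 10.0)},
              "H": {"sp3": (0.0, 0.3, 10.0)}},
)


def _nuclei(n_c=4, n_h=0):
    out = {f"C-{i + 1}": NucleusRecord(f"C-{i + 1}", "C",
                                       "sp2" if i % 2 else "sp3")
           for i in range(n_c)}
    out.update({f"H-{i + 1}": NucleusRecord(f"H-{i + 1}", "H", "sp3")
                for i in range(n_h)})
    return out


class TestDP4Plus:
    def test_identical_candidates_split_evenly(self):
        nuclei = _nuclei()
        shifts = {n: 100.0 + i for i, n in enumerate(nuclei)}
        cands = [("a", shifts, shifts), ("b", shifts, shifts)]
        res = dn.dp4_plus(cands, shifts, PARAMS, nuclei)
        assert res.total["a"] == 0.5 and res.total["b"] == 0.5
        assert res.scaled_only["a"] == 0.5
        assert res.carbon_only["b"] == 0.5

    def test_matches_brute_force_product(self):
        nuclei = _nuclei()
        rng = np.random.default_rng(31)
        exp = {n: float(rng.uniform(10, 180)) for n in nuclei}
        cands = []
        for cid in ("a", "b", "c"):
            scaled = {n: exp[n] + rng.normal(0, 2) for n in exp}
            unscaled = {n: exp[n] + rng.normal(0, 3) for n in exp}
            cands.append((cid, scaled, unscaled))
        res = dn.dp4_plus(cands, exp, PARAMS, nuclei)
        brute = []
        for cid, scaled, unscaled in cands:
            prod = 1.0
            for n in exp:
                rec = nuclei[n]
                prod *= dn.t_likelihood(scaled[n] - exp[n],
                                        PARAMS.lookup(rec.element, "scaled"))
                prod *= dn.t_likelihood(
                    unscaled[n] - exp[n],
                    PARAMS.lookup(rec.element, "unscaled", rec.hybridization))
            brute.append(prod)
        brute = np.array(brute) / sum(brute)
        for (cid, *_), p in zip(cands, brute):
            assert res.total[cid] == pytest.approx(p, abs=1e-12)

    def test_probability_families_sum_to_one(self, dp4_scenario):
        from fpcrevise.dft_nmr import candidate_shift_maps
        sc = dp4_scenario
        maps = [candidate_shift_maps(e, sc.exp_shifts, sc.factors, sc.sigma_ref)
                for e in (sc.correct, sc.incorrect)]
        cands = [(e.candidate_id, m["regression_scaled"], m["unscaled"])
                 for e, m in zip((sc.correct, sc.incorrect), maps)]
        res = dn.dp4_plus(cands, sc.exp_shifts,
                          dn.default_dp4_parameters(), sc.nuclei)
        for fam in (res.total, res.scaled_only, res.unscaled_only,
                    res.carbon_only, res.proton_only):
            assert abs(sum(fam.values()) - 1.0) < 1e-12

    def test_order_invariance(self):
        nuclei = _nuclei()
        rng = np.random.default_rng(37)
        exp = {n: float(rng.uniform(10, 180)) for n in nuclei}
        cands = []
        for cid in ("a", "b"):
            cands.append((cid,
                          {n: exp[n] + rng.normal(0, 2) for n in exp},
                          {n: exp[n] + rng.normal(0, 3) for n in exp}))
        r1 = dn.dp4_plus(cands, exp, PARAMS, nuclei)
        r2 = dn.dp4_plus(cands[::-1], exp, PARAMS, nuclei)
        for cid in ("a", "b"):
            assert r1.total[cid] == pytest.approx(r2.total[cid], abs=1e-14)

    def test_coverage_mismatch_rejected(self):
        nuclei = _nuclei()
        shifts = {n: 100.0 for n in nuclei}
        partial = dict(list(shifts.items())[:-1])
        with pytest.raises(EnsembleError, match="coverage"):
            dn.dp4_plus([("a", shifts, shifts), ("b", partial, partial)],
                        shifts, PARAMS, nuclei)

    def test_missing_parameter_key_named(self):
        nuclei = {"C-1": NucleusRecord("C-1", "C", "sp2")}
        params = DP4Parameters(scaled={"C": (0.0, 2.0, 10.0)},
                               unscaled={"C": {"sp3": (0.0, 2.0, 10.0)}})
        shifts = {"C-1": 100.0}
        other = {"C-1": 101.0}
        with pytest.raises(DP4ParameterError, match="sp2"):
            dn.dp4_plus([("a", shifts, shifts), ("b", other, other)],
                        shifts, params, nuclei)

    def test_single_candidate_rejected(self):
        with pytest.raises(EnsembleError, match="2 candidates"):
            dn.dp4_plus([("a", {"C-1": 1.0}, {"C-1": 1.0})], {"C-1": 1.0},
                        PARAMS, _nuclei(1))


class TestDefaultConfigs:
    def test_bundled_tables_load_and_validate(self):
        fac = dn.default_scaling_factors()
        assert set(fac.factors) == {"C", "H"}
        assert all(slope < 0 for slope, _ in fac.factors.values())
        par = dn.default_dp4_parameters()
        assert par.lookup("C", "scaled")[1] > 0
        assert par.lookup("C", "unscaled", "sp2")[2] > 0
        assert par.lookup("H", "unscaled", "sp3")[1] > 0
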