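"""TI quadrature, error propagation, linkage cycle and table readers."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdbind import (
    ConformerEnergy,
    FreeEnergyResult,
    HarmonicTIModel,
    InhibitionData,
    TautomerEquilibrium,
    TIProfile,
    bound_tautomer_ratio,
    datasets,
    entropy_decomposition,
    gen_ti_samples,
    ic50_to_ddmu,
    integrate_ti,
    read_lambda_table,
    relative_binding_ddg,
    tautomer_equilibrium,
    ti_profile_from_tables,
)
from mdbind.exceptions import FormatError, ValidationError
from mdbind.thermo import R_KJ_PER_MOL_K

RT300 = R_KJ_PER_MOL_K * 300.0


def _profile_from_means(lambdas, means, temperature=300.0):
    """Noise-free profile: each λ holds two copies of its exact mean."""
    return TIProfile(lambdas=lambdas,
                     dhdl_samples=[[m, m] for m in means],
                     temperature=temperature)


class TestIntegrateTI:
    def test_zero_samples_zero_result(self):
        prof = _profile_from_means(np.linspace(0, 1, 5), np.zeros(5))
        res = integrate_ti(prof)
        assert res.value == 0.0
        assert res.standard_error == 0.0

    def test_harmonic_recovery_within_3se(self):
        model = HarmonicTIModel(1.0, 4.0, 300.0)
        prof = gen_ti_samples(model, np.linspace(0, 1, 21), 5000, seed=42)
        res = integrate_ti(prof)
        assert res.standard_error > 0
        assert abs(res.value - model.exact_delta_f) <= 3 * res.standard_error

    def test_noise_free_quadrature_error(self):
        model = HarmonicTIModel(1.0, 4.0, 300.0)
        lam = np.linspace(0, 1, 101)
        means = [0.5 * 3.0 * RT300 / model.k(l) for l in lam]
        res = integrate_ti(_profile_from_means(lam, means))
        assert abs(res.value - model.exact_delta_f) < 1e-3

    def test_simpson_beats_trapezoid_on_smooth_integrand(self):
        model = HarmonicTIModel(1.0, 4.0, 300.0)
        lam = np.linspace(0, 1, 21)
        means = [0.5 * 3.0 * RT300 / model.k(l) for l in lam]
        prof = _profile_from_means(lam, means)
        err_t = abs(integrate_ti(prof).value - model.exact_delta_f)
        err_s = abs(integrate_ti(prof, rule="simpson").value
                    - model.exact_delta_f)
        assert err_s < err_t

    def test_nonuniform_grid_trapezoid(self):
        lam = np.array([0.0, 0.1, 0.3, 0.6, 1.0])
        means = 2.0 * lam  # ∫ 2λ dλ = 1, trapezoid exact for linear f
        res = integrate_ti(_profile_from_means(lam, means))
        assert res.value == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("k1,k2,temp", [
        (1.0, 4.0, 300.0), (2.0, 0.5, 300.0), (1.0, 9.0, 323.0),
        (5.0, 5.0, 280.0), (0.3, 3.0, 350.0),
    ])
    def test_harmonic_grid_of_models(self, k1, k2, temp):
        model = HarmonicTIModel(k1, k2, temp)
        prof = gen_ti_samples(model, np.linspace(0, 1, 21), 4000,
                              seed=int(10 * (k1 + k2 + temp)))
        res = integrate_ti(prof)
        tol = 3 * res.standard_error if res.standard_error else 1e-12
        assert abs(res.value - model.exact_delta_f) <= tol

    @given(st.floats(-5.0, 5.0))
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_linearity_in_integrand(self, c):
        model = HarmonicTIModel(1.0, 4.0, 300.0)
        prof = gen_ti_samples(model, np.linspace(0, 1, 11), 50, seed=1)
        base = integrate_ti(prof).value
        scaled = TIProfile(prof.lambdas, [c * s for s in prof.dhdl_samples],
                           prof.temperature)
        assert integrate_ti(scaled).value == pytest.approx(
            c * base, abs=1e-9 * max(1.0, abs(c)))

    def test_single_lambda_rejected(self):
        with pytest.raises(ValidationError):
            TIProfile(np.array([0.0]), [[1.0, 2.0]], 300.0)

    def test_grid_must_span_unit_interval(self):
        with pytest.raises(ValidationError):
            TIProfile(np.array([0.0, 0.5]), [[1, 2], [1, 2]], 300.0)


class TestRelativeBinding:
    def test_single_system_reference(self):
        res = relative_binding_ddg(
            {"x": FreeEnergyResult(10.0, 3.0, 300.0)}, "x")
        assert res["x"].value == 0.0
        assert res["x"].standard_error == 0.0

    def test_error_propagation(self):
        res = relative_binding_ddg({
            "a": FreeEnergyResult(10.0, 3.0, 300.0),
            "b": FreeEnergyResult(4.0, 4.0, 300.0),
        }, "b")
        assert res["a"].value == pytest.approx(6.0)
        assert res["a"].standard_error == pytest.approx(5.0)
        assert res["b"].value == 0.0

    def test_order_invariance(self):
        d1 = {"a": FreeEnergyResult(1.0, 1.0, 300.0),
              "b": FreeEnergyResult(2.0, 2.0, 300.0)}
        d2 = dict(reversed(d1.items()))
        r1 = relative_binding_ddg(d1, "a")
        r2 = relative_binding_ddg(d2, "a")
        assert r1 == r2

    def test_mixed_temperatures_rejected(self):
        with pytest.raises(ValidationError):
            relative_binding_ddg({
                "a": FreeEnergyResult(1.0, 1.0, 300.0),
                "b": FreeEnergyResult(2.0, 2.0, 323.0),
            }, "a")


class TestEntropyDecomposition:
    def test_temperature_independent_ddg_means_zero_entropy(self):
        out = entropy_decomposition(FreeEnergyResult(5.0, 1.0, 300.0),
                                    FreeEnergyResult(5.0, 1.0, 323.0))
        assert out.delta_delta_s == 0.0
        assert out.consistent_with_zero_entropy

    def test_published_300_323_values_for_strong_tautomer(self):
        # ΔΔG = 16±12 kJ/mol at 300 K and 11±16 at 323 K decompose into
        # ΔΔS = 0.217±0.870 kJ/(mol·K): entropy indistinguishable from zero
        out = entropy_decomposition(FreeEnergyResult(16.0, 12.0, 300.0),
                                    FreeEnergyResult(11.0, 16.0, 323.0))
        assert out.delta_delta_s == pytest.approx(5.0 / 23.0, abs=5e-4)
        assert out.delta_delta_s_se == pytest.approx(0.870, abs=5e-3)
        assert out.consistent_with_zero_entropy

    def test_linear_model_identity(self):
        # ΔΔG(T) = a − s·T exactly ⇒ ΔΔS = s, ΔΔH = a
        a, s = 40.0, 0.12
        out = entropy_decomposition(
            FreeEnergyResult(a - s * 300.0, 0.0, 300.0),
            FreeEnergyResult(a - s * 323.0, 0.0, 323.0))
        assert out.delta_delta_s == pytest.approx(s, abs=1e-12)
        assert out.delta_delta_h == pytest.approx(a, abs=1e-9)

    def test_equal_temperatures_rejected(self):
        with pytest.raises(ValidationError):
            entropy_decomposition(FreeEnergyResult(1.0, 1.0, 300.0),
                                  FreeEnergyResult(1.0, 1.0, 300.0))


class TestCheng_Prusoff:
    def test_equal_ic50_zero(self):
        a = InhibitionData(1e-6, 1e-5, 1e-5)
        assert ic50_to_ddmu(a, a, 300.0) == 0.0

    def test_ratio_e_gives_rt(self):
        a = InhibitionData(1e-6, 1e-5, 1e-5)
        b = InhibitionData(math.e * 1e-6, 1e-5, 1e-5)
        assert ic50_to_ddmu(a, b, 300.0) == pytest.approx(2.494, abs=1e-3)

    def test_ratio_100(self):
        a = InhibitionData(1e-7, 1e-5, 1e-5)
        b = InhibitionData(1e-5, 1e-5, 1e-5)
        assert ic50_to_ddmu(a, b, 300.0) == pytest.approx(11.48, abs=0.01)

    def test_unequal_conditions_warn_and_use_full_form(self):
        a = InhibitionData(1e-6, 1e-5, 1e-5)
        b = InhibitionData(1e-6, 2e-5, 1e-5)
        with pytest.warns(UserWarning, match="Cheng"):
            out = ic50_to_ddmu(a, b, 300.0)
        assert out == pytest.approx(RT300 * math.log(b.ki / a.ki))


class TestTautomerEquilibrium:
    def test_equal_totals_unit_constant(self):
        confs = [ConformerEnergy("a1", "a", -10.0, -60.0),
                 ConformerEnergy("b1", "b", -20.0, -50.0)]
        eq = tautomer_equilibrium(confs, 300.0)
        assert eq.K == pytest.approx(1.0, abs=1e-12)
        assert eq.delta_mu == pytest.approx(0.0, abs=1e-12)

    def test_two_state_closed_form(self):
        confs = [ConformerEnergy("a1", "a", 0.0, -72.0),
                 ConformerEnergy("b1", "b", 0.0, -79.1)]
        eq = tautomer_equilibrium(confs, 300.0)
        assert eq.K == pytest.approx(math.exp(-7.1 / RT300), rel=1e-12)
        assert eq.K == pytest.approx(0.058, abs=0.001)

    def test_duplicated_conformer_partition_factor(self):
        confs = [ConformerEnergy("a1", "a", 0.0, -72.0),
                 ConformerEnergy("b1", "b", 0.0, -79.1)]
        base = tautomer_equilibrium(confs, 300.0)
        doubled = tautomer_equilibrium(
            confs + [ConformerEnergy("a1x", "a", 0.0, -72.0)], 300.0)
        assert doubled.K == pytest.approx(2.0 * base.K, rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_brute_force_partition_oracle(self, seed):
        rng = np.random.default_rng(seed)
        confs = []
        for i in range(rng.integers(1, 6)):
            confs.append(ConformerEnergy(f"a{i}", "a",
                                         rng.uniform(-5, 8),
                                         rng.uniform(-80, -55)))
        for i in range(rng.integers(1, 6)):
            confs.append(ConformerEnergy(f"b{i}", "b",
                                         rng.uniform(-5, 8),
                                         rng.uniform(-80, -55)))
        eq = tautomer_equilibrium(confs, 300.0)
        za = sum(math.exp(-c.solution_free_energy / RT300)
                 for c in confs if c.tautomer == "a")
        zb = sum(math.exp(-c.solution_free_energy / RT300)
                 for c in confs if c.tautomer == "b")
        assert eq.K == pytest.approx(za / zb, rel=1e-12)

    def test_unreachable_conformer_is_irrelevant(self):
        confs = [ConformerEnergy("a1", "a", 0.0, -72.0),
                 ConformerEnergy("b1", "b", 0.0, -79.1)]
        base = tautomer_equilibrium(confs, 300.0)
        extra = tautomer_equilibrium(
            confs + [ConformerEnergy("aX", "a", 1e6, 0.0)], 300.0)
        assert extra.K == pytest.approx(base.K, rel=1e-12)

    def test_missing_side_rejected(self):
        with pytest.raises(ValidationError):
            tautomer_equilibrium([ConformerEnergy("a1", "a", 0.0, -72.0)],
                                 300.0)

    def test_k_delta_mu_consistency_enforced(self):
        with pytest.raises(ValidationError):
            TautomerEquilibrium(K=0.5, delta_mu=0.0, temperature=300.0)


class TestBoundTautomerRatio:
    def test_neutral_cycle(self):
        eq = TautomerEquilibrium(1.0, 0.0, 300.0)
        assert bound_tautomer_ratio(eq, 5.0, 5.0, 300.0) == 1.0

    def test_published_worked_example(self):
        # K = 0.21 with ΔΔμ_a = 16 and ΔΔμ_b = 0 kJ/mol at 300 K gives a
        # bound-tautomer ratio of ≈3.5e-4
        ratio = bound_tautomer_ratio(0.21, 16.0, 0.0, 300.0)
        assert ratio == pytest.approx(3.5e-4, rel=0.05)

    def test_cancellation_construction(self):
        dd = -RT300 * math.log(2.0)
        assert bound_tautomer_ratio(0.5, dd, 0.0, 300.0) == \
            pytest.approx(1.0, rel=1e-12)

    @given(st.floats(0.01, 10.0), st.floats(-20.0, 20.0))
    @settings(deadline=None, derandomize=True, max_examples=40)
    def test_monotonicity(self, k, gap):
        base = bound_tautomer_ratio(k, gap, 0.0, 300.0)
        assert bound_tautomer_ratio(2 * k, gap, 0.0, 300.0) > base
        assert bound_tautomer_ratio(k, gap + 1.0, 0.0, 300.0) < base


class TestReaders:
    def test_lambda_table_formats(self, tmp_path):
        p = tmp_path / "dhdl.xvg"
        p.write_text("# comment\n@ xaxis label\n0.0 1.5\n0.1, 1.6\n0.2\t1.7\n")
        x, y = read_lambda_table(p)
        np.testing.assert_allclose(x, [0.0, 0.1, 0.2])
        np.testing.assert_allclose(y, [1.5, 1.6, 1.7])

    def test_lambda_table_error_reports_line(self, tmp_path):
        p = tmp_path / "bad.xvg"
        p.write_text("0.0 1.5\noops nan?\n")
        with pytest.raises(FormatError, match=":2"):
            read_lambda_table(p)

    def test_profile_from_tables(self, tmp_path):
        paths = {}
        for lam in (0.0, 0.5, 1.0):
            p = tmp_path / f"lam_{lam}.xvg"
            p.write_text("".join(f"{t} {lam + 0.1 * t}\n" for t in range(6)))
            paths[lam] = p
        prof = ti_profile_from_tables(paths, 300.0)
        np.testing.assert_allclose(prof.lambdas, [0.0, 0.5, 1.0])
        assert all(s.size == 6 for s in prof.dhdl_samples)

    def test_bundled_binding_table(self):
        table = datasets.binding_free_energies()
        assert set(table) == {"1a", "1b", "2"}
        assert table["1a"][300.0].value == 16.0
        assert table["1a"][323.0].standard_error == 16.0
        assert table["2"][300.0].value == 79.0

    def test_bundled_conformer_table_direct_summation(self):
        confs = datasets.conformer_energies()
        assert len(confs) == 6
        eq = tautomer_equilibrium(confs, 300.0)
        # independent direct summation over the six printed rows
        za = sum(math.exp(-(g + h) / RT300) for g, h in
                 [(0.0, -72.0), (-0.7, -67.8), (3.2, -62.3)])
        zb = sum(math.exp(-(g + h) / RT300) for g, h in
                 [(-3.8, -75.3), (-3.6, -71.1), (6.5, -76.6)])
        assert eq.K == pytest.approx(za / zb, rel=1e-12)
        assert eq.K == pytest.approx(0.0606, abs=0.001)
        assert eq.delta_mu == pytest.approx(6.99, abs=0.01)
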