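"""ITC one-site isotherm and Hill dose-response fitting."""

import numpy as np
import pytest

from formstress import (
    HillModel, ItcExperiment, ItcModel, ItcProtocol, SeededConfig,
    fit_hill, fit_itc, gen_itc_thermogram, gen_mst_curve, hill_response,
    itc_forward, subtract_blank, ucal_to_uj,
)
from formstress.errors import (
    FlatCurveError, UnidentifiableKdWarning, UnitMismatchError, ValidationError,
)


def one_site_cumulative_heat(model, protocol):
    """Independent re-derivation of the cumulative heat after each
    injection, via the binding quadratic solved with numpy roots."""
    v = protocol.injection_volumes_ul
    dV = np.cumsum(v)
    V0 = protocol.cell_volume_ul
    M0 = protocol.cell_protein_uM * 1e-6
    L = protocol.syringe_ligand_mM * 1e-3 * (dV / V0) * (1 - dV / (2 * V0))
    M = M0 * (1 - dV / (2 * V0)) / (1 + dV / (2 * V0))
    dH = model.dH_kcal_per_mol * 4184.0
    Kd = model.Kd_mM * 1e-3
    Q = []
    for Mt, Lt in zip(M, L):
        # [ML] solves x^2 - (Lt + n Mt + Kd) x + n Mt Lt = 0, bound root
        roots = np.roots([1.0, -(Lt + model.n_sites * Mt + Kd), model.n_sites * Mt * Lt])
        ml = min(r.real for r in roots if r.real >= 0)
        Q.append(ml * dH * V0 * 1e-6)
    return np.array(Q) * 1e6  # uJ


class TestItcForward:
    def test_zero_enthalpy_means_zero_heats(self, itc_protocol):
        q = itc_forward(ItcModel(1.0, 8.0, 0.0 + 1e-300), itc_protocol)
        assert np.allclose(q, 0.0)

    def test_tight_binding_pre_equivalence_heat(self):
        # Kd -> 0: every injected mole binds, dQ = dH x moles injected
        prot = ItcProtocol(syringe_ligand_mM=1.0, n_injections=8, cell_protein_uM=50.0)
        q = itc_forward(ItcModel(1.0, 1e-9, -22.65), prot)
        mol = 2e-6 * 1e-3  # 2 uL of 1 mM
        expected = -22.65 * 1e3 * 4.184 * mol * 1e6
        assert q[1:4] == pytest.approx(expected, rel=1e-4)

    def test_saturation_asymptote(self):
        # ligand far beyond equivalence: cumulative heat -> n dH V0 Mt
        prot = ItcProtocol(syringe_ligand_mM=500.0, n_injections=20)
        model = ItcModel(1.0, 0.01, -10.0)
        q = itc_forward(model, prot)
        cum = one_site_cumulative_heat(model, prot)
        v = prot.injection_volumes_ul
        dV = np.cumsum(v)
        Mt = prot.cell_protein_uM * 1e-6 * (1 - dV / (2 * prot.cell_volume_ul)) / (
            1 + dV / (2 * prot.cell_volume_ul))
        expected_final = -10.0 * 4184 * prot.cell_volume_ul * 1e-6 * Mt[-1] * 1e6
        assert cum[-1] == pytest.approx(expected_final, rel=1e-3)
        assert abs(q[-1]) < abs(q[1]) * 1e-2  # heats die off at saturation

    def test_per_injection_heats_sum_to_cumulative_with_perfusion(self, itc_protocol):
        model = ItcModel(1.2, 5.0, -15.0)
        dq = itc_forward(model, itc_protocol)
        Q = one_site_cumulative_heat(model, itc_protocol)
        v = itc_protocol.injection_volumes_ul
        Qprev = np.concatenate(([0.0], Q[:-1]))
        perfusion = (v / itc_protocol.cell_volume_ul) * (Q + Qprev) / 2.0
        assert np.sum(dq) == pytest.approx(Q[-1] + np.sum(perfusion), rel=1e-9)

    def test_matches_independent_quadratic_solution(self, itc_protocol):
        model = ItcModel(0.9, 12.0, -20.0)
        dq = itc_forward(model, itc_protocol)
        Q = one_site_cumulative_heat(model, itc_protocol)
        v = itc_protocol.injection_volumes_ul
        Qprev = np.concatenate(([0.0], Q[:-1]))
        expected = Q - Qprev + (v / itc_protocol.cell_volume_ul) * (Q + Qprev) / 2.0
        assert dq == pytest.approx(expected, rel=1e-8)

    def test_tight_binding_inflection_at_molar_ratio_n(self):
        # at Kd ~ 0 the titration saturates exactly when the molar
        # ratio of injected ligand to protein reaches the stoichiometry
        for n_sites in (1.0, 2.0):
            prot = ItcProtocol(syringe_ligand_mM=2.0, n_injections=40,
                               cell_protein_uM=50.0)
            q = itc_forward(ItcModel(n_sites, 1e-6, -20.0), prot)
            dV = np.cumsum(prot.injection_volumes_ul)
            Lt = prot.syringe_ligand_mM * 1e-3 * (dV / prot.cell_volume_ul) * (
                1 - dV / (2 * prot.cell_volume_ul))
            Mt = prot.cell_protein_uM * 1e-6 * (1 - dV / (2 * prot.cell_volume_ul)) / (
                1 + dV / (2 * prot.cell_volume_ul))
            ratio = Lt / Mt
            # steepest change in per-injection heat brackets molar ratio n
            drop = np.argmax(np.abs(np.diff(q[1:])))
            assert abs(ratio[1 + drop] - n_sites) < 0.2


class TestSubtractBlank:
    def test_blank_equal_to_sample_gives_zero(self, itc_protocol):
        heats = np.linspace(-30, -5, itc_protocol.n_injections)
        exp = ItcExperiment(itc_protocol, heats, heats)
        assert np.allclose(subtract_blank(exp), 0.0)

    def test_elementwise_subtraction_and_discard_removal(self, itc_protocol):
        n = itc_protocol.n_injections
        sample = np.full(n, -10.0)
        sample[1] = -8.0
        blank = np.full(n, -2.0)
        corrected = subtract_blank(ItcExperiment(itc_protocol, sample, blank))
        assert len(corrected) == n - 1  # throw-away excluded
        assert corrected[0] == pytest.approx(-6.0)
        assert corrected[1] == pytest.approx(-8.0)

    def test_mixed_units_rejected(self, itc_protocol):
        n = itc_protocol.n_injections
        exp = ItcExperiment(itc_protocol, np.zeros(n), np.zeros(n),
                            sample_units="uJ", blank_units="ucal")
        with pytest.raises(UnitMismatchError):
            subtract_blank(exp)

    def test_length_mismatch_rejected(self, itc_protocol):
        with pytest.raises(ValidationError):
            ItcExperiment(itc_protocol, np.zeros(3), np.zeros(3))

    def test_ucal_conversion(self):
        assert ucal_to_uj(1.0) == pytest.approx(4.184)


class TestFitItc:
    def test_noise_free_round_trip_exact(self, itc_protocol):
        exp = gen_itc_thermogram(itc_protocol, 1.0, 8.0, -22.65, -2.0,
                                 SeededConfig(1, 1, 0.0))
        fit = fit_itc(subtract_blank(exp), itc_protocol)
        assert fit.model.n_sites == pytest.approx(1.0, rel=1e-6)
        assert fit.model.Kd_mM == pytest.approx(8.0, rel=1e-6)
        assert fit.model.dH_kcal_per_mol == pytest.approx(-22.65, rel=1e-6)

    def test_noise_free_round_trip_other_parameters(self):
        prot = ItcProtocol(syringe_ligand_mM=2.0, n_injections=40, cell_protein_uM=50.0)
        exp = gen_itc_thermogram(prot, 2.0, 0.05, -12.0, 1.5, SeededConfig(2, 1, 0.0))
        fit = fit_itc(subtract_blank(exp), prot)
        assert fit.model.n_sites == pytest.approx(2.0, rel=1e-5)
        assert fit.model.Kd_mM == pytest.approx(0.05, rel=1e-4)
        assert fit.model.dH_kcal_per_mol == pytest.approx(-12.0, rel=1e-5)

    def test_all_zero_heats_unidentifiable(self, itc_protocol):
        with pytest.warns(UnidentifiableKdWarning):
            fit = fit_itc(np.zeros(itc_protocol.n_injections - 1), itc_protocol, fix_n=1.0)
        assert abs(fit.model.dH_kcal_per_mol) < 1e-3

    def test_requires_six_injections(self):
        prot = ItcProtocol(n_injections=5)
        with pytest.raises(ValidationError):
            fit_itc(np.zeros(4), prot)

    def test_heat_array_length_checked(self, itc_protocol):
        with pytest.raises(ValidationError):
            fit_itc(np.zeros(7), itc_protocol)


class TestHill:
    def test_half_saturation_is_midpoint(self):
        assert hill_response(8.0, 1.0, 0.0, 8.0, 1.0) == pytest.approx(0.5)
        assert hill_response(8.0, 900.0, 850.0, 8.0, 2.0) == pytest.approx(875.0)

    def test_zero_concentration_gives_baseline(self):
        assert hill_response(0.0, 1.0, 0.2, 8.0, 1.0) == pytest.approx(0.2)

    def test_noise_free_round_trip_exact(self):
        model = HillModel(1.0, 0.0, 8.01, 1.0)
        concs = 100.0 / 2 ** np.arange(16)
        df = gen_mst_curve(model, concs, SeededConfig(3, 3, 0.0))
        fit = fit_hill(df["concentration_mM"], df["f_norm"])
        assert fit.model.Kd_mM == pytest.approx(8.01, rel=1e-6)
        assert fit.model.n == pytest.approx(1.0, rel=1e-6)
        assert fit.model.F_max == pytest.approx(1.0, rel=1e-6)

    def test_round_trip_with_baseline_and_cooperativity(self):
        model = HillModel(920.0, 860.0, 3.0, 1.7)
        concs = 50.0 / 2 ** np.arange(12)
        df = gen_mst_curve(model, concs, SeededConfig(4, 2, 0.0))
        fit = fit_hill(df["concentration_mM"], df["f_norm"])
        assert fit.model.Kd_mM == pytest.approx(3.0, rel=1e-5)
        assert fit.model.n == pytest.approx(1.7, rel=1e-5)
        assert fit.model.F_min == pytest.approx(860.0, rel=1e-6)

    def test_strict_printed_form_forces_zero_baseline(self):
        model = HillModel(1.0, 0.0, 8.0, 1.0)
        concs = 100.0 / 2 ** np.arange(16)
        df = gen_mst_curve(model, concs, SeededConfig(5, 1, 0.0))
        fit = fit_hill(df["concentration_mM"], df["f_norm"], strict_printed_form=True)
        assert fit.model.F_min == 0.0
        assert fit.model.Kd_mM == pytest.approx(8.0, rel=1e-6)

    def test_flat_curve_rejected(self):
        concs = [0.1, 1.0, 10.0, 50.0, 100.0]
        with pytest.raises(FlatCurveError):
            fit_hill(concs, [5.0] * 5)

    def test_needs_five_distinct_concentrations(self):
        with pytest.raises(ValidationError):
            fit_hill([1, 2, 4, 8], [0.1, 0.2, 0.4, 0.6])

    def test_model_invariants(self):
        with pytest.raises(ValidationError):
            HillModel(1.0, 0.0, -1.0, 1.0)
        with pytest.raises(ValidationError):
            HillModel(0.0, 1.0, 8.0, 1.0)  # F_max < F_min
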