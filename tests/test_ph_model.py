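"""pH-partition model: ionization, prediction, fitting, profile shapes."""

import numpy as np
import pytest

from pampakit.phmodel import (
    PHProfileFit,
    UnderdeterminedFitError,
    fit_ph_profile,
    fraction_unionized,
    ph_of_max_permeability,
    predict_pe_ampholyte,
    predict_pe_monoprotic,
    select_pka,
)
from pampakit.plate import DrugInfo
from pampakit.reference import LIPIDS, PHProfilePoint, load_drug_info, load_table2_fixture
from pampakit.simulate import generate_ph_dataset

ACID = DrugInfo("acid-probe", 200.0, (4.59,), "acid", 50.0)
BASE = DrugInfo("base-probe", 200.0, (9.54,), "base", 50.0)
AMPHO = DrugInfo("ampho-probe", 300.0, (6.26, 8.63), "ampholyte", 50.0)


class TestFractionUnionized:
    def test_half_ionized_at_the_pka(self):
        assert fraction_unionized(5.0, 5.0, "acid") == pytest.approx(0.5)
        assert fraction_unionized(5.0, 5.0, "base") == pytest.approx(0.5)

    def test_one_log_unit_above_acid_pka(self):
        assert fraction_unionized(5.59, 4.59, "acid") == pytest.approx(1 / 11, rel=1e-3)

    def test_ibuprofen_at_physiological_ph(self):
        # 1/(1 + 10^(7.4-4.59))
        assert fraction_unionized(7.4, 4.59, "acid") == pytest.approx(1.55e-3, rel=5e-3)

    def test_neutral_class_is_exactly_one(self):
        assert fraction_unionized(7.4, 4.59, "neutral") == 1.0


class TestPrediction:
    def test_without_uwl_pe_approaches_membrane_permeability(self):
        pm = 1e-4 / (10 ** (5.0 - 4.59) + 1)
        pe = predict_pe_monoprotic(5.0, 1e-4, 1e3, 4.59, "acid")
        assert pe == pytest.approx(pm, rel=1e-6)

    def test_fully_unionized_acid_sees_series_resistances(self):
        pe = predict_pe_monoprotic(0.59, 1e-4, 2e-5, 4.59, "acid")
        assert pe == pytest.approx(1 / (1 / 2e-5 + 1 / 1e-4), rel=1e-3)

    def test_hand_evaluated_point(self):
        expected = 1.0 / (1 / 2e-5 + (10 ** (4.6 - 4.59) + 1) / 1e-4)
        assert predict_pe_monoprotic(4.6, 1e-4, 2e-5, 4.59, "acid") == pytest.approx(
            expected, rel=1e-12
        )
        assert expected == pytest.approx(1.42e-5, rel=5e-3)

    def test_prediction_bounded_by_uwl_permeability(self):
        ph = np.linspace(0, 14, 141)
        for klass in ("acid", "base"):
            pe = predict_pe_monoprotic(ph, 1e-4, 2e-5, 7.0, klass)
            assert np.all(pe < 2e-5)

    def test_resistance_additivity_identity(self):
        ph = np.linspace(2, 12, 51)
        po, pu = 3e-5, 1.2e-5
        pe = predict_pe_monoprotic(ph, po, pu, 6.5, "base")
        lhs = 1.0 / pe - 1.0 / pu
        rhs = (10 ** (6.5 - ph) + 1) / po
        assert np.allclose(lhs, rhs, rtol=1e-10)

    def test_ampholyte_plateau_between_well_separated_pkas(self):
        pe = predict_pe_ampholyte(6.0, 1e-4, 2e-5, 9.0, 3.0)  # acidic 9, basic 3
        assert pe == pytest.approx(1 / (1 / 2e-5 + 1 / 1e-4), rel=1e-2)

    def test_ampholyte_peaks_midway_between_pkas(self):
        ph = np.linspace(2, 12, 10001)
        pe = predict_pe_ampholyte(ph, 1e-4, 2e-5, 6.26, 8.63)
        assert ph[np.argmax(pe)] == pytest.approx((6.26 + 8.63) / 2, abs=2e-3)


class TestPkaSelection:
    def test_monoprotic_uses_pka_nearest_window_centre(self):
        famotidine = DrugInfo("Famotidine", 337.45, (7.24, 11.19), "base", 40.0)
        assert select_pka(famotidine, (4.6, 9.32)) == (7.24,)

    def test_ampholyte_uses_outermost_pair(self):
        amoxicillin = DrugInfo("Amoxicillin", 419.46, (2.6, 7.31, 9.53), "ampholyte", 93.0)
        assert select_pka(amoxicillin, (4.6, 9.32)) == (2.6, 9.53)


class TestFitting:
    @pytest.mark.parametrize(
        "drug,po,pu",
        [(ACID, 1e-4, 2e-5), (BASE, 5e-4, 3e-5), (AMPHO, 8e-5, 1.5e-5)],
    )
    def test_noiseless_points_recover_parameters_exactly(self, drug, po, pu):
        grid = np.linspace(4.0, 10.0, 9)
        pts = generate_ph_dataset(
            po, pu, drug.pKa_values, drug.ionization_class, grid, noise_cv=0.0, seed=1
        )
        fit = fit_ph_profile(pts, drug)
        assert fit.converged
        assert fit.intrinsic_permeability == pytest.approx(po, rel=1e-4)
        assert fit.uwl_permeability == pytest.approx(pu, rel=1e-4)

    def test_fitted_pka_reproduces_the_curve_despite_degeneracy(self):
        # (P_o, P_u, pKa) are not separately identifiable for a monoprotic
        # profile: only 1/P_u + 1/P_o and 10^-pKa / P_o enter the model.
        # A free-pKa fit must still reproduce the observed curve exactly.
        grid = np.linspace(3.5, 10.0, 12)
        pts = generate_ph_dataset(1e-4, 2e-5, 4.59, "acid", grid, noise_cv=0.0, seed=2)
        fit = fit_ph_profile(pts, ACID, fit_pKa=True)
        assert fit.converged
        for p in pts:
            assert fit.predict(p.pH) == pytest.approx(p.pe_cm_per_s, rel=1e-6)
        # the identifiable combinations match the generating parameters
        series = 1 / fit.uwl_permeability + 1 / fit.intrinsic_permeability
        slope = 10 ** (-fit.pKa_used[0]) / fit.intrinsic_permeability
        assert series == pytest.approx(1 / 2e-5 + 1 / 1e-4, rel=1e-6)
        assert slope == pytest.approx(10**-4.59 / 1e-4, rel=1e-6)

    def test_under_determined_profile_rejected(self):
        pts = [PHProfilePoint(5.0, 1e-5), PHProfilePoint(7.0, 5e-6)]
        with pytest.raises(UnderdeterminedFitError):
            fit_ph_profile(pts, ACID)

    def test_recovery_improves_as_noise_shrinks(self):
        grid = np.linspace(4.0, 10.0, 9)
        medians = []
        for cv in (0.15, 0.05, 0.0):
            errs = []
            for rep in range(40):
                pts = generate_ph_dataset(
                    1e-4, 2e-5, 4.59, "acid", grid, noise_cv=cv, seed=900 + rep
                )
                fit = fit_ph_profile(pts, ACID)
                errs.append(
                    abs(np.log(fit.intrinsic_permeability) - np.log(1e-4))
                    + abs(np.log(fit.uwl_permeability) - np.log(2e-5))
                )
            medians.append(float(np.median(errs)))
        assert medians[0] > medians[1] > medians[2]
        assert medians[2] == pytest.approx(0.0, abs=1e-6)

    def test_reciprocal_weighting_also_recovers_noiseless_truth(self):
        grid = np.linspace(4.0, 10.0, 9)
        pts = generate_ph_dataset(1e-4, 2e-5, 4.59, "acid", grid, noise_cv=0.0, seed=3)
        fit = fit_ph_profile(pts, ACID, weighting="reciprocal")
        assert fit.intrinsic_permeability == pytest.approx(1e-4, rel=1e-5)


@pytest.fixture(scope="module")
def fits():
    drugs = load_drug_info()
    return {
        key: fit_ph_profile(points, drugs[key[0]])
        for key, points in load_table2_fixture().items()
    }


class TestReferenceProfiles:
    def test_all_reference_fits_converge(self, fits):
        assert all(f.converged for f in fits.values())

    def test_acid_profiles_fall_with_ph(self, fits):
        for name in ("Chloramphenicol", "Ibuprofen"):
            for lipid in LIPIDS:
                f = fits[(name, lipid)]
                assert f.predict(4.6) > f.predict(9.32)

    def test_base_profiles_rise_with_ph(self, fits):
        for name in ("Atenolol", "Cimetidine", "Famotidine", "Metformin",
                     "Metoprolol", "Ranitidine"):
            for lipid in LIPIDS:
                f = fits[(name, lipid)]
                assert f.predict(9.32) > f.predict(4.98)

    def test_predictions_stay_below_uwl_ceiling(self, fits):
        ph = np.linspace(4.6, 9.32, 60)
        for f in fits.values():
            assert np.all(f.predict(ph) < f.uwl_permeability)


class TestMaxLocation:
    def test_acid_peaks_at_low_end_of_range(self):
        fit = _fit(ACID, 1e-4, 2e-5)
        assert ph_of_max_permeability(fit, (4.0, 10.0)) == 4.0

    def test_base_peaks_at_high_end_of_range(self):
        fit = _fit(BASE, 1e-4, 2e-5)
        assert ph_of_max_permeability(fit, (4.0, 10.0)) == 10.0

    def test_norfloxacin_like_ampholyte_peaks_near_seven_and_a_half(self):
        fit = _fit(AMPHO, 1e-4, 2e-5)
        peak = ph_of_max_permeability(fit, (4.6, 9.32))
        assert peak == pytest.approx(7.445, abs=0.01)
        assert 6.26 < peak < 8.63

    def test_non_converged_fit_is_refused(self):
        fit = PHProfileFit("acid", (4.59,), 1e-4, 2e-5, 0.0, False, 5, (4.0, 10.0))
        with pytest.raises(ValueError):
            ph_of_max_permeability(fit)


def _fit(drug, po, pu):
    grid = np.linspace(4.0, 10.0, 9)
    pts = generate_ph_dataset(
        po, pu, drug.pKa_values, drug.ionization_class, grid, noise_cv=0.0, seed=7
    )
    return fit_ph_profile(pts, drug)
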