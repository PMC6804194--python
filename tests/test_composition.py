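"""PA compositional metrics: mDP, percentages, aMW, GPC quantiles."""

import numpy as np
import pytest

from pasorption import (
    GPCTrace,
    SubunitProfile,
    average_mw,
    mdp,
    molar_mass_at_quantile,
    percent_gallo,
    percent_galloylation,
)
from pasorption.composition import DEFAULT_MW, SPECIES
from pasorption.synth import default_gpc_calibration, generate_gpc_trace


def _profile(**kwargs):
    """Shorthand: keys like ec_ext=8.0 -> ('epicatechin', 'extension')."""
    species = {"c": "catechin", "ec": "epicatechin",
               "ecg": "epicatechin_gallate", "egc": "epigallocatechin"}
    pos = {"t": "terminal", "ext": "extension"}
    amounts = {}
    for key, nmol in kwargs.items():
        sp, p = key.rsplit("_", 1)
        amounts[(species[sp], pos[p])] = nmol
    return SubunitProfile(amounts=amounts)


class TestMdp:
    def test_terminal_plus_extension(self):
        assert mdp(_profile(c_t=1.0, ec_ext=3.0)) == pytest.approx(4.0)

    def test_monomers_only(self):
        assert mdp(_profile(c_t=2.0, ec_t=3.0)) == pytest.approx(1.0)

    def test_mixed_species(self):
        profile = _profile(c_t=0.5, ec_t=0.5, ec_ext=8.0, egc_ext=1.0)
        assert mdp(profile) == pytest.approx(10.0)

    def test_no_terminal_units_rejected(self):
        with pytest.raises(ZeroDivisionError):
            mdp(_profile(ec_ext=5.0))


class TestPercentages:
    def test_galloylation_fraction(self):
        profile = _profile(ecg_ext=2.0, ec_t=1.0, ec_ext=7.0)
        assert percent_galloylation(profile) == pytest.approx(20.0)

    def test_no_gallate(self):
        assert percent_galloylation(_profile(ec_t=1.0, ec_ext=9.0)) == 0.0

    def test_all_gallate_bound(self):
        assert percent_galloylation(_profile(ecg_t=1.0, ecg_ext=4.0)) == pytest.approx(100.0)

    def test_gallo_fraction(self):
        profile = _profile(egc_ext=1.0, ec_t=1.0, ec_ext=8.0)
        assert percent_gallo(profile) == pytest.approx(10.0)

    def test_gallo_difference_in_percentage_points(self):
        control = _profile(egc_ext=20.0, ec_t=10.0, ec_ext=70.0)
        trial = _profile(egc_ext=23.0, ec_t=10.0, ec_ext=67.0)
        assert percent_gallo(trial) - percent_gallo(control) == pytest.approx(3.0)


class TestAverageMw:
    def test_pure_catechin_monomer(self):
        assert average_mw(_profile(c_t=5.0)) == pytest.approx(290.27)

    def test_all_epicatechin_tetramer(self):
        profile = _profile(ec_t=1.0, ec_ext=3.0)
        assert average_mw(profile) == pytest.approx(4 * 290.27)

    def test_matches_brute_force_on_random_profiles(self, rng):
        """aMW equals total subunit mass over terminal moles (algebraic identity)."""
        for _ in range(25):
            amounts = {}
            for sp in SPECIES:
                for pos in ("terminal", "extension"):
                    if rng.random() < 0.7:
                        amounts[(sp, pos)] = float(rng.uniform(0.1, 20.0))
            if not any(pos == "terminal" for _, pos in amounts):
                amounts[("catechin", "terminal")] = 1.0
            profile = SubunitProfile(amounts=amounts)
            brute = sum(n * DEFAULT_MW[sp] for (sp, _), n in amounts.items()) / sum(
                n for (sp, pos), n in amounts.items() if pos == "terminal"
            )
            assert average_mw(profile) == pytest.approx(brute, rel=1e-12)

    def test_percent_metrics_bounded_and_mdp_at_least_one(self, rng):
        for _ in range(25):
            amounts = {(sp, pos): float(rng.uniform(0.0, 10.0))
                       for sp in SPECIES for pos in ("terminal", "extension")}
            amounts[("epicatechin", "terminal")] += 0.5
            profile = SubunitProfile(amounts=amounts)
            assert mdp(profile) >= 1.0
            assert 0.0 <= percent_galloylation(profile) <= 100.0
            assert 0.0 <= percent_gallo(profile) <= 100.0


def _brute_quantile(trace: GPCTrace, quantile: float) -> float:
    """Independent oracle: explicit cumulative sum over sorted masses."""
    mw = 10.0 ** np.interp(trace.elution_mL, trace.cal_elution_mL, trace.cal_log10_mw)
    w = trace.signal * np.gradient(trace.elution_mL)
    order = np.argsort(mw)
    mw, w = mw[order], w[order]
    cum = np.cumsum(w) / np.sum(w)
    return float(np.interp(quantile, cum, mw))


class TestMolarMassAtQuantile:
    def test_monodisperse_sample_at_any_quantile(self):
        cal_e, cal_m = default_gpc_calibration()
        elution = float(np.interp(np.log10(2000.0), cal_m[::-1], cal_e[::-1]))
        trace = GPCTrace(elution_mL=[elution], signal=[1.0],
                         cal_elution_mL=cal_e, cal_log10_mw=cal_m)
        for q in (0.1, 0.5, 0.9):
            assert molar_mass_at_quantile(trace, q) == pytest.approx(2000.0, rel=1e-9)

    def test_narrow_peak_centers_on_its_mw(self):
        trace = generate_gpc_trace([(np.log10(2000.0), 0.02, 1.0)])
        assert molar_mass_at_quantile(trace, 0.5) == pytest.approx(2000.0, rel=0.01)

    def test_equal_mass_peaks_high_quantile(self):
        trace = generate_gpc_trace([(3.0, 0.02, 0.5), (np.log10(3000.0), 0.02, 0.5)])
        # the 90 % cumulative-mass point sits inside the high-MW peak
        assert molar_mass_at_quantile(trace, 0.90) == pytest.approx(3000.0, rel=0.05)

    def test_median_matches_brute_force(self):
        trace = generate_gpc_trace([(3.0, 0.05, 0.5), (np.log10(3000.0), 0.05, 0.5)])
        for q in (0.25, 0.5, 0.75, 0.9):
            assert molar_mass_at_quantile(trace, q) == pytest.approx(
                _brute_quantile(trace, q), rel=1e-6
            )

    def test_non_decreasing_in_quantile(self, rng):
        trace = generate_gpc_trace(
            [(2.5, 0.2, 0.3), (3.2, 0.15, 0.4), (4.0, 0.1, 0.3)], seed=7, noise_cv=0.05
        )
        quantiles = np.linspace(0.05, 0.95, 19)
        values = [molar_mass_at_quantile(trace, q) for q in quantiles]
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_all_zero_signal_rejected(self):
        cal_e, cal_m = default_gpc_calibration()
        trace = GPCTrace(elution_mL=[12.0, 13.0], signal=[0.0, 0.0],
                         cal_elution_mL=cal_e, cal_log10_mw=cal_m)
        with pytest.raises(ValueError, match="all-zero"):
            molar_mass_at_quantile(trace, 0.9)

    @pytest.mark.parametrize("q", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_quantile_rejected(self, q):
        trace = generate_gpc_trace([(3.0, 0.1, 1.0)])
        with pytest.raises(ValueError):
            molar_mass_at_quantile(trace, q)

    def test_calibration_must_decrease(self):
        with pytest.raises(ValueError, match="monotone decreasing"):
            GPCTrace(elution_mL=[1.0, 2.0], signal=[1.0, 1.0],
                     cal_elution_mL=[1.0, 2.0], cal_log10_mw=[2.0, 3.0])
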