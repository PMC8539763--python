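import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import endosyncom as es
from endosyncom.truth import INHIBITED, PROMOTED


def _line_standards(slope=0.01, intercept=0.05, concs=(0, 20, 40, 60, 80, 100)):
    return pd.DataFrame(
        {"concentration": concs, "absorbance": [slope * c + intercept for c in concs]}
    )


def test_fit_standard_curve_exact_line():
    curve = es.fit_standard_curve(_line_standards(), assay="iaa", wavelength_nm=535)
    assert curve.slope == pytest.approx(0.01)
    assert curve.intercept == pytest.approx(0.05)
    assert curve.r_squared == pytest.approx(1.0)
    assert curve.concentration_range == (0.0, 100.0)


def test_fit_standard_curve_preconditions():
    with pytest.raises(ValueError, match="3 distinct"):
        es.fit_standard_curve([(0.0, 0.1), (10.0, 0.2)])
    with pytest.raises(ValueError, match="3 distinct"):
        es.fit_standard_curve([(5.0, 0.1), (5.0, 0.2), (5.0, 0.3)])


def test_fit_standard_curve_noisy_slope_within_2se():
    rng = np.random.default_rng(3)
    concs = np.tile(np.array([0, 25, 50, 75, 100.0]), 4)
    absorb = 0.012 * concs + 0.05 + rng.normal(0, 0.01, concs.size)
    curve = es.fit_standard_curve(
        pd.DataFrame({"concentration": concs, "absorbance": absorb})
    )
    from scipy import stats as sps

    se = sps.linregress(concs, absorb).stderr
    assert abs(curve.slope - 0.012) < 2 * se


def test_inverse_predict_round_trip_and_floor():
    curve = es.fit_standard_curve(_line_standards())
    assert es.inverse_predict(curve, curve.intercept) == pytest.approx(0.0)
    for conc in (0.0, 12.5, 66.3, 100.0):
        assert es.inverse_predict(curve, curve.predict(conc)) == pytest.approx(conc)
    # below-intercept absorbance floors at zero
    assert es.inverse_predict(curve, 0.0) == 0.0


def test_inverse_predict_flags_extrapolation_and_zero_slope():
    curve = es.fit_standard_curve(_line_standards())
    with pytest.warns(UserWarning, match="outside"):
        es.inverse_predict(curve, curve.predict(150.0))
    flat = es.StandardCurve("x", 0.0, 0.1, 1.0, (0.0, 1.0))
    with pytest.raises(ValueError, match="zero slope"):
        es.inverse_predict(flat, 0.5)


@given(conc=st.floats(min_value=0, max_value=100, allow_nan=False))
def test_inverse_predict_is_left_inverse_of_predict(conc):
    curve = es.StandardCurve("iaa", 0.012, 0.05, 1.0, (0.0, 100.0))
    assert es.inverse_predict(curve, curve.predict(conc)) == pytest.approx(
        conc, rel=1e-9, abs=1e-9
    )


@pytest.mark.parametrize(
    "a_sample, a_control, expected",
    [(0.5, 0.5, 0.0), (0.0, 0.5, 100.0), (0.05, 0.5, 90.0)],
)
def test_dpph_scavenging_values(a_sample, a_control, expected):
    assert es.dpph_scavenging(a_sample, a_control) == pytest.approx(expected)


def test_dpph_domain():
    with pytest.raises(ValueError):
        es.dpph_scavenging(0.1, 0.0)
    with pytest.raises(ValueError):
        es.dpph_scavenging(-0.1, 0.5)


@given(
    a1=st.floats(min_value=0, max_value=1, allow_nan=False),
    a2=st.floats(min_value=0, max_value=1, allow_nan=False),
)
def test_dpph_antitone_in_sample_absorbance(a1, a2):
    lo, hi = sorted((a1, a2))
    assert es.dpph_scavenging(lo, 0.7) >= es.dpph_scavenging(hi, 0.7)


def _profile_frame(rows):
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "strain"
    return frame


def test_score_pgpt_counts():
    profile = _profile_frame(
        {
            "none": {"iaa_mg_l": 0.0, "siderophore_units": 0.0,
                     "dpph_pct": 0.0, "phosphate_mg_l": 0.0},
            "all": {"iaa_mg_l": 50.0, "siderophore_units": 0.3,
                    "dpph_pct": 80.0, "phosphate_mg_l": 100.0},
            "partial": {"iaa_mg_l": 50.0, "siderophore_units": 0.0,
                        "dpph_pct": 80.0, "phosphate_mg_l": 0.0},
        }
    )
    scored = es.score_pgpt(profile)
    assert scored.loc["none", "pgpt_count"] == 0
    assert scored.loc["all", "pgpt_count"] == 4
    assert scored.loc["partial", "pgpt_count"] == 2
    assert scored.loc["partial", "has_dpph_pct"]


def test_score_pgpt_missing_trait_excluded_and_monotone():
    profile = _profile_frame(
        {"x": {"iaa_mg_l": 50.0, "siderophore_units": np.nan,
               "dpph_pct": 80.0, "phosphate_mg_l": 100.0}}
    )
    scored = es.score_pgpt(profile)
    assert scored.loc["x", "pgpt_count"] == 3
    # raising any trait value never lowers the count
    bumped = profile.copy()
    bumped.loc["x", "siderophore_units"] = 1.0
    assert es.score_pgpt(bumped).loc["x", "pgpt_count"] >= 3


def test_quantify_traits_requires_standards(catalog, truth):
    samples, standards = es.simulate_trait_assays(catalog, truth, noise_sd=0.0, seed=5)
    with pytest.raises(ValueError, match="standard series"):
        es.quantify_traits(samples, standards[standards["assay"] == "iaa"])


def test_quantified_counts_match_truth_at_low_noise(catalog, truth):
    """Planted ability counts survive 0.02-absorbance assay noise."""
    samples, standards = es.simulate_trait_assays(catalog, truth, noise_sd=0.02, seed=5)
    profile = es.quantify_traits(samples, standards)
    scored = es.score_pgpt(profile)
    expected = es.score_pgpt(truth.trait_levels.rename_axis("strain"))
    agree = (
        scored["pgpt_count"].sort_index() == expected["pgpt_count"].sort_index()
    ).mean()
    assert agree >= 0.95


def test_compare_pgpt_by_class_detects_planted_shift(classification_from_truth):
    rng = np.random.default_rng(1)
    cls = classification_from_truth
    counts = {}
    for strain, response in zip(cls["strain"], cls["response"]):
        base = 3 if response == PROMOTED else 1
        counts[strain] = {
            "iaa_mg_l": 50.0 if base >= 2 else 0.0,
            "siderophore_units": 0.3 if base >= 3 else 0.0,
            "dpph_pct": 80.0,
            "phosphate_mg_l": 100.0 if rng.random() < (0.8 if base >= 2 else 0.2) else 0.0,
        }
    scored = es.score_pgpt(_profile_frame(counts))
    result = es.compare_pgpt_by_class(scored, cls)
    assert result["bacteria"].p_value < 0.05
    assert result["fungi"].p_value < 0.05


def test_compare_pgpt_by_class_empty_class_warns(catalog):
    cls = catalog.to_frame().rename(columns={"code": "strain"})
    cls["response"] = INHIBITED
    cls["label"] = np.where(cls["kingdom"] == "bacterium", "TNB", "TNF")
    profile = _profile_frame(
        {s: {"iaa_mg_l": 0.0, "siderophore_units": 0.0, "dpph_pct": 0.0,
             "phosphate_mg_l": 0.0} for s in cls["strain"]}
    )
    with pytest.warns(UserWarning, match="skipped"):
        result = es.compare_pgpt_by_class(es.score_pgpt(profile), cls)
    assert result["bacteria"] is None and result["fungi"] is None
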