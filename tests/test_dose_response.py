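import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

import endosyncom as es
from endosyncom.catalog import BACTERIUM
from endosyncom.truth import INHIBITED, PROMOTED

positive = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False)


@pytest.mark.parametrize(
    "value, reference, expected",
    [(2.0, 1.0, 1.0), (5.5, 5.5, 0.0), (1.0, 4.0, -2.0), (8.0, 1.0, 3.0)],
)
def test_log2_fold_change_values(value, reference, expected):
    assert es.log2_fold_change(value, reference) == pytest.approx(expected)


@pytest.mark.parametrize("value, reference", [(0.0, 1.0), (1.0, 0.0), (-1.0, 1.0)])
def test_log2_fold_change_domain(value, reference):
    with pytest.raises(ValueError):
        es.log2_fold_change(value, reference)


@given(value=positive, reference=positive)
def test_log2_fold_change_antisymmetry(value, reference):
    assert es.log2_fold_change(value, reference) == pytest.approx(
        -es.log2_fold_change(reference, value)
    )


@given(value=positive, reference=positive, bump=positive)
def test_log2_fold_change_monotone_in_value(value, reference, bump):
    assert es.log2_fold_change(value + bump, reference) >= es.log2_fold_change(
        value, reference
    )


def _profile(control, treated_by_conc, kingdom=BACTERIUM, times=(0.0, 48.0)):
    """Tiny long-format profile; treated_by_conc maps conc -> replicate values."""
    rows = []
    for t in times:
        scale = 0.01 if t == 0.0 else 1.0
        for rep, v in enumerate(control, start=1):
            rows.append(
                {"strain": "X", "kingdom": kingdom, "concentration_uM": 0.0,
                 "replicate": rep, "time": t, "value": v * scale}
            )
        for conc, values in treated_by_conc.items():
            for rep, v in enumerate(values, start=1):
                rows.append(
                    {"strain": "X", "kingdom": kingdom, "concentration_uM": conc,
                     "replicate": rep, "time": t, "value": v * scale}
                )
    return pd.DataFrame(rows)


def test_profile_log2fc_identity_and_doubling():
    control = [1.0, 1.0, 1.0]
    same = _profile(control, {100.0: [1.0, 1.0, 1.0], 250.0: [1.0, 1.0, 1.0]})
    summary = es.profile_log2fc(same)
    assert np.allclose(summary["mean_log2fc"], 0.0)
    double = _profile(control, {100.0: [2.0, 2.0, 2.0], 250.0: [2.0, 2.0, 2.0]})
    summary = es.profile_log2fc(double)
    assert np.allclose(summary["mean_log2fc"], 1.0)


def test_profile_log2fc_missing_control_or_replicates():
    profile = _profile([1.0, 1.0], {100.0: [1.5, 1.5], 250.0: [1.0, 1.0]})
    with pytest.raises(ValueError, match="control"):
        es.profile_log2fc(profile[profile["concentration_uM"] > 0])
    single = _profile([1.0], {100.0: [1.5], 250.0: [1.0]})
    with pytest.raises(ValueError, match="replicates"):
        es.profile_log2fc(single)


def test_initial_baseline_scores_growth_from_t0():
    profile = _profile([1.0, 1.0], {100.0: [2.0, 2.0], 250.0: [2.0, 2.0]})
    fcs = es.replicate_log2fc(profile, baseline="initial")
    # endpoint / (0.01 x endpoint) = 100-fold growth from inoculum
    assert np.allclose(fcs["log2fc"], np.log2(100.0))


def _brute_force_label(fcs, decision=(100.0, 250.0), alpha=0.05):
    """Independent re-implementation of the decision rule."""
    dec = fcs[fcs["concentration_uM"].isin(decision)]["log2fc"].to_numpy()
    if dec.std(ddof=1) == 0:
        significant = dec.mean() != 0
    else:
        significant = sps.ttest_1samp(dec, 0).pvalue < alpha
    if significant and dec.mean() != 0:
        return PROMOTED if dec.mean() > 0 else INHIBITED
    return PROMOTED if fcs["log2fc"].mean() > 0 else INHIBITED


@pytest.mark.parametrize("pattern_id", range(16))
def test_classify_strain_matches_brute_force_on_sign_patterns(pattern_id):
    """Agreement with an exhaustive oracle over +/- patterns at 4 concentrations."""
    signs = [(pattern_id >> k) & 1 for k in range(4)]
    concs = (20.0, 50.0, 100.0, 250.0)
    rng = np.random.default_rng(pattern_id)
    rows = []
    for conc, s in zip(concs, signs):
        base = 0.6 if s else -0.6
        for rep in range(1, 4):
            rows.append(
                {"concentration_uM": conc, "replicate": rep,
                 "log2fc": base + rng.normal(0, 0.02)}
            )
    fcs = pd.DataFrame(rows)
    label, score, p = es.classify_strain(fcs)
    assert label == _brute_force_label(fcs)
    # decision score is the mean over the decision concentrations
    expected = fcs[fcs["concentration_uM"].isin((100.0, 250.0))]["log2fc"].mean()
    assert score == pytest.approx(expected)


def test_classify_strain_mixed_profile_is_inhibited():
    """Low-dose promotion with medium/high-dose inhibition counts as inhibited."""
    rows = []
    for conc, fc in [(20.0, 0.3), (50.0, 0.2), (100.0, -0.8), (250.0, -1.2)]:
        for rep in range(1, 6):
            rows.append({"concentration_uM": conc, "replicate": rep,
                         "log2fc": fc + 0.01 * rep})
    label, _, _ = es.classify_strain(pd.DataFrame(rows))
    assert label == INHIBITED


def test_classify_strain_requires_decision_concentrations():
    fcs = pd.DataFrame({"concentration_uM": [20.0] * 3, "replicate": [1, 2, 3],
                        "log2fc": [0.1, 0.2, 0.3]})
    with pytest.raises(ValueError, match="decision concentrations"):
        es.classify_strain(fcs)


def test_classify_panel_partitions_and_recovers_truth(catalog, truth):
    """At 5% measurement noise the planted labels are recovered >= 95%."""
    dose = es.simulate_dose_response(catalog, truth=truth, noise_sd=0.05, seed=7)
    classification, contingency = es.classify_panel(dose, catalog)
    labels = classification.set_index("strain")
    n_bac = labels[labels["kingdom"] == "bacterium"]
    n_fun = labels[labels["kingdom"] == "fungus"]
    assert (n_bac["label"].isin(["TPB", "TNB"])).all()
    assert (n_fun["label"].isin(["TPF", "TNF"])).all()
    assert len(n_bac) == 27 and len(n_fun) == 26
    agreement = (labels["response"] == truth.response_class).mean()
    assert agreement >= 0.95
    assert contingency.to_numpy().sum() == 53


def test_classify_panel_unknown_strain(catalog, truth):
    dose = es.simulate_dose_response(catalog, truth=truth, noise_sd=0.0, seed=1)
    dose.loc[0, "strain"] = "GHOST"
    with pytest.raises(ValueError, match="unknown strains"):
        es.classify_panel(dose, catalog)


def test_classify_panel_empty():
    classification, contingency = es.classify_panel(
        pd.DataFrame(columns=["strain", "kingdom", "concentration_uM",
                              "replicate", "time", "value"]),
        es.generate_catalog(0, 0, phylum_profile={}),
    )
    assert classification.empty and contingency.empty
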