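import warnings

import numpy as np
import pandas as pd
import pytest

import endosyncom as es
from endosyncom.truth import PHENOTYPES, TREATMENT_CONCENTRATIONS


@pytest.fixture(scope="module")
def null_truth(catalog):
    return es.null_truth(catalog)


def _constant_factor_truth(catalog, factor):
    truth = es.null_truth(catalog)
    truth.effect_size.loc[:, :] = factor
    return truth


def test_dose_response_determinism_and_positivity(catalog, truth):
    a = es.simulate_dose_response(catalog, truth=truth, noise_sd=0.05, seed=9)
    b = es.simulate_dose_response(catalog, truth=truth, noise_sd=0.05, seed=9)
    pd.testing.assert_frame_equal(a, b)
    assert (a["value"] > 0).all()
    # full grid: 53 strains x 5 concentrations x 5 replicates x 5 time points
    assert len(a) == 53 * 5 * 5 * 5


def test_dose_response_null_effect_equals_control(catalog, null_truth):
    """Unit effect factors and zero noise: treated endpoints equal controls."""
    dose = es.simulate_dose_response(catalog, truth=null_truth, noise_sd=0.0, seed=2)
    for strain, profile in dose.groupby("strain"):
        endpoint = profile[profile["time"] == profile["time"].max()]
        values = endpoint.groupby("concentration_uM")["value"].mean()
        assert np.allclose(values, values.loc[0.0])


def test_dose_response_factor_two_gives_log2fc_one(catalog):
    """A planted two-fold capacity factor forces log2FC of exactly 1."""
    truth = _constant_factor_truth(catalog, 2.0)
    dose = es.simulate_dose_response(catalog, truth=truth, noise_sd=0.0, seed=2)
    matrix = es.log2fc_matrix(dose)
    assert np.allclose(matrix.to_numpy(), 1.0)


def test_dose_response_requires_control(catalog, truth):
    with pytest.raises(ValueError, match="control"):
        es.simulate_dose_response(
            catalog, concentrations=(20.0, 50.0), truth=truth, seed=1
        )
    with pytest.raises(ValueError, match="missing for concentrations"):
        es.simulate_dose_response(
            catalog, concentrations=(0.0, 33.0), truth=truth, seed=1
        )


@pytest.mark.parametrize("geometry", ["bb_vshape", "ff_dual", "bf_streak"])
def test_interaction_plates_null_and_determinism(catalog, null_truth, geometry):
    a = es.simulate_interaction_plates(catalog, null_truth, geometry, noise_sd=0.0, seed=4)
    b = es.simulate_interaction_plates(catalog, null_truth, geometry, noise_sd=0.0, seed=4)
    pd.testing.assert_frame_equal(a, b)
    measure_cols = [c for c in a.columns if c not in ("actor", "target", "geometry", "replicate")]
    assert (a[measure_cols] > 0).to_numpy().all()
    matrix = es.build_interaction_matrix(a)
    assert np.allclose(matrix.long["mean_ii"], 0.0)


def test_interaction_planted_effect_recovered_exactly(catalog, truth):
    """Zero noise: downstream II equals the planted fraction x 100."""
    for geometry in ("bb_vshape", "ff_dual", "bf_streak"):
        raw = es.simulate_interaction_plates(catalog, truth, geometry, noise_sd=0.0, seed=4)
        matrix = es.build_interaction_matrix(raw)
        eff = truth.interaction_effect.query("geometry == @geometry").set_index(
            ["actor", "target"]
        )["effect"]
        merged = matrix.long.set_index(["actor", "target"]).join(eff)
        assert np.allclose(merged["mean_ii"], merged["effect"] * 100.0)


def test_interaction_unknown_geometry(catalog, truth):
    with pytest.raises(ValueError, match="unknown geometry"):
        es.simulate_interaction_plates(catalog, truth, "tt_spiral", seed=1)


def test_trait_assay_round_trip_exact(catalog):
    """Planted 66.3 mg/L IAA passes through forward + inverse untouched."""
    truth = es.null_truth(catalog)
    truth.trait_levels.loc[:, "iaa_mg_l"] = 66.3
    truth.trait_levels.loc[:, "dpph_pct"] = 90.0
    truth.trait_levels.loc[:, "phosphate_mg_l"] = 137.8
    truth.trait_levels.loc[:, "siderophore_units"] = 0.3
    samples, standards = es.simulate_trait_assays(catalog, truth, noise_sd=0.0, seed=6)
    profile = es.quantify_traits(samples, standards)
    assert np.allclose(profile["iaa_mg_l"], 66.3)
    assert np.allclose(profile["dpph_pct"], 90.0)
    assert np.allclose(profile["phosphate_mg_l"], 137.8)
    assert np.allclose(profile["siderophore_units"], 0.3)


def test_trait_assay_zero_level_reads_zero(catalog, null_truth):
    samples, standards = es.simulate_trait_assays(catalog, null_truth, noise_sd=0.0, seed=6)
    profile = es.quantify_traits(samples, standards)
    assert np.allclose(profile[["iaa_mg_l", "phosphate_mg_l", "siderophore_units"]], 0.0)


def test_pot_experiment_planted_percent_change(catalog, classification_from_truth):
    """A planted 1.15 fractional gain reads back as exactly 115.00%."""
    truth = es.null_truth(catalog)
    truth.pot_effects.loc["ABF", "root_length_cm"] = 1.15
    designs = es.build_syncoms(classification_from_truth, catalog)
    raw, standards = es.simulate_pot_experiment(designs, truth, noise_sd=0.0, seed=8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-variance letters fallback
        out = es.evaluate_pot(raw, designs, standards)
    row = out.query("design == 'ABF' and phenotype == 'root_length_cm'").iloc[0]
    assert row["pct_vs_ck"] == pytest.approx(115.00, abs=1e-9)
    null_rows = out.query("design != 'ABF' or phenotype != 'root_length_cm'")
    assert np.allclose(null_rows["pct_vs_ck"], 0.0)


def test_pot_experiment_rejects_unknown_strains(catalog, truth):
    bogus = {"CK": es.SynComDesign("CK", ("NOPE",), "CK")}
    with pytest.raises(ValueError, match="unknown strains"):
        es.simulate_pot_experiment(bogus, truth, seed=1)


def test_write_dataset_manifest(tmp_path, catalog, truth):
    dose = es.simulate_dose_response(catalog, truth=truth, noise_sd=0.0, seed=1)
    manifest = es.write_dataset(
        str(tmp_path), {"dose_response": dose}, truth=truth, parameters={"seed": 1}
    )
    import yaml

    with open(manifest) as fh:
        meta = yaml.safe_load(fh)
    assert meta["parameters"]["seed"] == 1
    assert (tmp_path / meta["files"]["dose_response"]).exists()
    restored = es.PlantedTruth.from_dir(str(tmp_path / "truth"))
    pd.testing.assert_series_equal(restored.response_class, truth.response_class)
    pd.testing.assert_frame_equal(restored.effect_size, truth.effect_size)


def test_truth_validation(catalog):
    truth = es.null_truth(catalog)
    truth.effect_size.iloc[0, 0] = -1.0
    with pytest.raises(ValueError, match="positive"):
        es.PlantedTruth(
            truth.response_class,
            truth.effect_size,
            truth.interaction_effect,
            truth.trait_levels,
            truth.pot_effects,
        )


def test_reference_pot_effects_compose_reference_contrasts():
    """Class-community growth effects compose vs-ABF contrasts onto CK scale."""
    pot = es.reference_pot_effects()
    abf = pot.at["ABF", "root_length_cm"]
    tp = pot.at["TPB&TPF", "root_length_cm"]
    assert (1 + tp) / (1 + abf) - 1 == pytest.approx(2.0398)
    assert pot.at["AF", "chlorophyll_mg_g"] == pytest.approx(-0.4218)
    assert set(pot.index) == {"CK", "AB", "AF", "ABF", "TPB&TPF", "TNB&TNF"}
    assert list(pot.columns) == list(PHENOTYPES)
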