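"""End-to-end orchestration of the screening-to-SynCom pipeline on
synthetic panels: simulate every assay from a planted truth, then run
classification, interaction scoring, trait quantification, SynCom
construction and pot evaluation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dose_response, interaction, simulate, syncom, traits
from .catalog import StrainCatalog, default_catalog
from .truth import GEOMETRIES, PlantedTruth, null_truth, reference_profile_truth


@dataclass
class ScreenResult:
    """Everything one pipeline run produces."""

    catalog: StrainCatalog
    truth: PlantedTruth
    dose: pd.DataFrame
    classification: pd.DataFrame
    contingency: pd.DataFrame
    matrices: dict[str, interaction.InteractionMatrix]
    received: dict[str, dict]
    trait_samples: pd.DataFrame
    trait_standards: pd.DataFrame
    trait_profiles: pd.DataFrame
    pgpt: pd.DataFrame
    syncoms: dict[str, syncom.SynComDesign]
    pot_raw: pd.DataFrame
    pot_standards: pd.DataFrame
    pot_outcomes: pd.DataFrame


def _child_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % (2**31)) for s in state]


def run_screen(
    seed: int = 42,
    catalog: StrainCatalog | None = None,
    truth: PlantedTruth | None = None,
    null: bool = False,
    dose_noise: float = 0.05,
    plate_noise: float = 0.05,
    trait_noise: float = 0.02,
    pot_noise: float = 0.1,
    dose_replicates: int = 5,
    plate_replicates: int = 3,
    trait_replicates: int = 3,
    rule: dose_response.ClassificationRule = dose_response.ClassificationRule(),
) -> ScreenResult:
    """Simulate a full screening campaign and analyse it.

    With ``null=True`` (or an explicit all-null ``truth``) and all noise
    levels at zero, every downstream score — log2 fold change, interaction
    index, pot percent change — is exactly zero.
    """
    catalog = catalog or default_catalog()
    seeds = _child_seeds(seed, 8)
    if truth is None:
        truth = null_truth(catalog) if null else reference_profile_truth(catalog, seed=seeds[0])

    dose = simulate.simulate_dose_response(
        catalog,
        truth=truth,
        replicates=dose_replicates,
        noise_sd=dose_noise,
        seed=seeds[1],
    )
    classification, contingency = dose_response.classify_panel(dose, catalog, rule)

    matrices: dict[str, interaction.InteractionMatrix] = {}
    received: dict[str, dict] = {}
    for i, geometry in enumerate(GEOMETRIES):
        raw = simulate.simulate_interaction_plates(
            catalog,
            truth,
            geometry,
            noise_sd=plate_noise,
            replicates=plate_replicates,
            seed=seeds[2] + i,
        )
        matrices[geometry] = interaction.build_interaction_matrix(raw)
        received[geometry] = interaction.aggregate_received_effects(
            matrices[geometry], classification
        )

    trait_samples, trait_standards = simulate.simulate_trait_assays(
        catalog, truth, noise_sd=trait_noise, replicates=trait_replicates, seed=seeds[3]
    )
    trait_profiles = traits.quantify_traits(trait_samples, trait_standards)
    pgpt = traits.score_pgpt(trait_profiles)

    syncoms = syncom.build_syncoms(classification, catalog)
    pot_raw, pot_standards = simulate.simulate_pot_experiment(
        syncoms, truth, noise_sd=pot_noise, seed=seeds[4]
    )
    pot_outcomes = syncom.evaluate_pot(pot_raw, syncoms, pot_standards)

    return ScreenResult(
        catalog=catalog,
        truth=truth,
        dose=dose,
        classification=classification,
        contingency=contingency,
        matrices=matrices,
        received=received,
        trait_samples=trait_samples,
        trait_standards=trait_standards,
        trait_profiles=trait_profiles,
        pgpt=pgpt,
        syncoms=syncoms,
        pot_raw=pot_raw,
        pot_standards=pot_standards,
        pot_outcomes=pot_outcomes,
    )
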