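"""Planted ground truth for synthetic screening panels.

A :class:`PlantedTruth` bundles every latent quantity the simulators need and
the recovery tests check against: the true triterpenoid response class of each
strain, its multiplicative growth-effect factor at each assay concentration,
the signed pairwise interaction effect on each plate geometry, the true
plant-growth-promotion trait levels, and the fractional pot-experiment effect
of each synthetic community relative to uninoculated controls.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import BACTERIUM, FUNGUS, StrainCatalog

PROMOTED = "promoted"
INHIBITED = "inhibited"

#: assay concentrations of the triterpenoid mixture, µM (0 = solvent control)
DEFAULT_CONCENTRATIONS: tuple[float, ...] = (0.0, 20.0, 50.0, 100.0, 250.0)

#: treatment concentrations carried in the effect-size grid
TREATMENT_CONCENTRATIONS: tuple[float, ...] = (20.0, 50.0, 100.0, 250.0)

GEOMETRIES = ("bb_vshape", "ff_dual", "bf_streak")

SYNCOM_NAMES = ("CK", "AB", "AF", "ABF", "TPB&TPF", "TNB&TNF")

PHENOTYPES = (
    "root_length_cm",
    "plant_height_cm",
    "dry_weight_g",
    "chlorophyll_mg_g",
    "polyphenol_mg_g",
    "flavonoid_mg_g",
    "total_sugar_mg_g",
    "total_triterpenoid_mg_g",
)

TRAIT_COLUMNS = ("iaa_mg_l", "siderophore_units", "dpph_pct", "phosphate_mg_l")

# Fraction of strains per phylum whose growth the triterpenoid mixture
# promotes in the reference screening profile.  With the default panel these
# shares give exactly 13 promoted / 14 inhibited bacteria and 11 promoted /
# 15 inhibited fungi.
PROMOTED_SHARE: dict[str, float] = {
    "Firmicutes": 5 / 7,
    "Bacteroidetes": 4 / 5,
    "Actinobacteria": 0.0,
    "Proteobacteria": 4 / 11,
    "Ascomycota": 8 / 17,
    "Basidiomycota": 3 / 7,
    "Zygomycota": 0.0,
}

# Capacity-scaling factors per treatment concentration (µM).  Promoted
# strains gain capacity monotonically; inhibited strains either lose it
# monotonically or show a slight low-dose boost followed by clear inhibition
# at the 100/250 µM decision concentrations.
_PROMOTED_FACTORS = {20.0: 1.10, 50.0: 1.25, 100.0: 1.45, 250.0: 1.70}
_INHIBITED_FACTORS_MONO = {20.0: 0.95, 50.0: 0.85, 100.0: 0.62, 250.0: 0.45}
_INHIBITED_FACTORS_BOOST = {20.0: 1.08, 50.0: 1.04, 100.0: 0.68, 250.0: 0.50}

# Reference pot-experiment effects, expressed as fractional changes of the
# treatment mean over the stated baseline arm.  Growth phenotypes for the
# class-restricted communities are defined against the full community (ABF)
# and composed onto the control scale below.
_POT_VS_CK = {
    "AB": {
        "root_length_cm": 0.9896, "plant_height_cm": 0.1845, "dry_weight_g": 0.35,
        "chlorophyll_mg_g": 0.08, "polyphenol_mg_g": 0.1112, "flavonoid_mg_g": 0.0916,
        "total_sugar_mg_g": 0.2766, "total_triterpenoid_mg_g": 0.6697,
    },
    "AF": {
        "root_length_cm": 0.8202, "plant_height_cm": 0.0449, "dry_weight_g": 0.10,
        "chlorophyll_mg_g": -0.4218, "polyphenol_mg_g": 0.2837, "flavonoid_mg_g": 0.5813,
        "total_sugar_mg_g": 0.1787, "total_triterpenoid_mg_g": 0.4913,
    },
    "ABF": {
        "root_length_cm": 1.15, "plant_height_cm": 0.4255, "dry_weight_g": 0.60,
        "chlorophyll_mg_g": 0.12, "polyphenol_mg_g": 0.1376, "flavonoid_mg_g": 0.25,
        "total_sugar_mg_g": 0.6291, "total_triterpenoid_mg_g": 0.7878,
    },
}
_POT_VS_ABF = {
    "TPB&TPF": {
        "root_length_cm": 2.0398, "plant_height_cm": 0.6198, "dry_weight_g": 0.90,
        "chlorophyll_mg_g": 0.20,
    },
    "TNB&TNF": {
        "root_length_cm": 0.0573, "plant_height_cm": -0.103, "dry_weight_g": 0.03,
        "chlorophyll_mg_g": -0.02,
    },
}
# metabolite effects for the class-restricted communities are stated vs CK
_POT_VS_CK_CLASS = {
    "TPB&TPF": {
        "polyphenol_mg_g": 0.5666, "flavonoid_mg_g": 1.0221,
        "total_sugar_mg_g": 1.0396, "total_triterpenoid_mg_g": 2.4054,
    },
    "TNB&TNF": {
        "polyphenol_mg_g": 0.0856, "flavonoid_mg_g": 0.086,
        "total_sugar_mg_g": 0.2475, "total_triterpenoid_mg_g": 0.6851,
    },
}


@dataclass
class PlantedTruth:
    """Ground truth behind one synthetic dataset.

    Attributes
    ----------
    response_class
        Series mapping strain code -> ``"promoted"`` / ``"inhibited"``.
    effect_size
        DataFrame indexed by strain code, float concentration columns (µM),
        holding the multiplicative capacity factor (> 0).
    interaction_effect
        Long DataFrame with columns ``actor, target, geometry, effect``;
        ``effect`` is the signed fractional change (> −1) of the target's
        measurement under the actor.
    trait_levels
        DataFrame indexed by strain code with columns ``iaa_mg_l,
        siderophore_units, dpph_pct, phosphate_mg_l``.
    pot_effects
        DataFrame indexed by SynCom name with phenotype columns; fractional
        change of the treatment mean over the uninoculated control (CK).
    """

    response_class: pd.Series
    effect_size: pd.DataFrame
    interaction_effect: pd.DataFrame
    trait_levels: pd.DataFrame
    pot_effects: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.effect_size.to_numpy() <= 0).any():
            raise ValueError("effect factors must be strictly positive")
        if (self.interaction_effect["effect"].to_numpy() <= -1).any():
            raise ValueError("interaction effects must be > -1")
        if (self.pot_effects.to_numpy() <= -1).any():
            raise ValueError("pot effects must be > -1")

    # -- persistence --------------------------------------------------------
    def to_dir(self, path: str) -> None:
        """Serialize every component as CSV under ``path``."""
        os.makedirs(path, exist_ok=True)
        self.response_class.rename("response").rename_axis("code").to_csv(
            os.path.join(path, "response_class.csv")
        )
        self.effect_size.rename_axis("code").to_csv(os.path.join(path, "effect_size.csv"))
        self.interaction_effect.to_csv(
            os.path.join(path, "interaction_effect.csv"), index=False
        )
        self.trait_levels.rename_axis("code").to_csv(os.path.join(path, "trait_levels.csv"))
        self.pot_effects.rename_axis("design").to_csv(os.path.join(path, "pot_effects.csv"))

    @classmethod
    def from_dir(cls, path: str) -> "PlantedTruth":
        response = pd.read_csv(os.path.join(path, "response_class.csv"), index_col="code")[
            "response"
        ]
        effect = pd.read_csv(os.path.join(path, "effect_size.csv"), index_col="code")
        effect.columns = effect.columns.astype(float)
        interaction = pd.read_csv(os.path.join(path, "interaction_effect.csv"))
        traits = pd.read_csv(os.path.join(path, "trait_levels.csv"), index_col="code")
        pot = pd.read_csv(os.path.join(path, "pot_effects.csv"), index_col="design")
        return cls(response, effect, interaction, traits, pot)


def _compose_pot_effects() -> pd.DataFrame:
    rows: dict[str, dict[str, float]] = {"CK": {p: 0.0 for p in PHENOTYPES}}
    for name, effects in _POT_VS_CK.items():
        rows[name] = {p: effects[p] for p in PHENOTYPES}
    for name in ("TPB&TPF", "TNB&TNF"):
        row: dict[str, float] = {}
        for p in PHENOTYPES:
            if p in _POT_VS_CK_CLASS[name]:
                row[p] = _POT_VS_CK_CLASS[name][p]
            else:
                # stated against the full community; compose onto the CK scale
                vs_abf = _POT_VS_ABF[name][p]
                abf_vs_ck = _POT_VS_CK["ABF"][p]
                row[p] = (1.0 + vs_abf) * (1.0 + abf_vs_ck) - 1.0
        rows[name] = row
    frame = pd.DataFrame.from_dict(rows, orient="index").loc[list(SYNCOM_NAMES)]
    return frame[list(PHENOTYPES)]


def reference_pot_effects() -> pd.DataFrame:
    """Reference planted pot effects (fractional change vs CK) per SynCom."""
    return _compose_pot_effects()


def _assign_response_classes(catalog: StrainCatalog) -> pd.Series:
    """Per-phylum promoted shares applied in catalog order."""
    labels: dict[str, str] = {}
    for kingdom in (BACTERIUM, FUNGUS):
        strains = [s for s in catalog if s.kingdom == kingdom]
        by_phylum: dict[str, list[str]] = {}
        for s in strains:
            by_phylum.setdefault(s.phylum, []).append(s.code)
        for phylum, codes in by_phylum.items():
            share = PROMOTED_SHARE.get(phylum, 0.5)
            k = int(round(share * len(codes)))
            for i, code in enumerate(codes):
                labels[code] = PROMOTED if i < k else INHIBITED
    out = pd.Series({s.code: labels[s.code] for s in catalog}, name="response")
    out.index.name = "code"
    return out


def reference_profile_truth(
    catalog: StrainCatalog,
    seed: int = 42,
    concentrations: Sequence[float] = TREATMENT_CONCENTRATIONS,
) -> PlantedTruth:
    """Planted truth reproducing the reference screening profile.

    Response classes follow the per-phylum promoted shares of the reference
    screen (13 promoted / 14 inhibited bacteria, 11 / 15 fungi on the default
    panel); effect factors, pairwise interaction effects and trait levels are
    drawn reproducibly from ``seed``; pot effects are the reference
    percent-change settings.
    """
    rng = np.random.default_rng(seed)
    response = _assign_response_classes(catalog)

    concentrations = tuple(float(c) for c in concentrations)
    rows = {}
    for i, strain in enumerate(catalog):
        promoted = response[strain.code] == PROMOTED
        if promoted:
            base = _PROMOTED_FACTORS
        else:
            base = _INHIBITED_FACTORS_MONO if i % 2 == 0 else _INHIBITED_FACTORS_BOOST
        jitter = rng.uniform(0.85, 1.15)
        rows[strain.code] = {
            c: 1.0 + (base.get(c, 1.0) - 1.0) * jitter for c in concentrations
        }
    effect = pd.DataFrame.from_dict(rows, orient="index")[list(concentrations)]
    effect.index.name = "code"

    interaction = _draw_interaction_effects(catalog, response, rng)
    traits = _draw_trait_levels(catalog, response, rng)
    pot = reference_pot_effects()
    return PlantedTruth(response, effect, interaction, traits, pot)


def _draw_interaction_effects(
    catalog: StrainCatalog, response: pd.Series, rng: np.random.Generator
) -> pd.DataFrame:
    """Signed fractional effects for every directed pair on each geometry.

    Within-kingdom interactions lean cooperative and bacterium->fungus
    interactions antagonistic, mirroring the prevailing pattern in endophyte
    co-culture screens; triterpenoid-promoted targets are slightly more
    likely to receive facilitation, the community-dominance pattern the
    received-effect comparison is designed to detect.
    """
    bac = [s.code for s in catalog.bacteria]
    fun = [s.code for s in catalog.fungi]
    records: list[tuple[str, str, str, float]] = []

    def draw(target: str, p_promoted: float, p_inhibited: float) -> float:
        p = p_promoted if response[target] == PROMOTED else p_inhibited
        sign = 1.0 if rng.random() < p else -1.0
        return sign * rng.uniform(0.05, 0.6)

    for a in bac:
        for t in bac:
            if a != t:
                records.append((a, t, "bb_vshape", draw(t, 0.75, 0.55)))
    for a in fun:
        for t in fun:
            if a != t:
                records.append((a, t, "ff_dual", draw(t, 0.75, 0.55)))
    for a in bac:
        for t in fun:
            records.append((a, t, "bf_streak", draw(t, 0.35, 0.25)))
    return pd.DataFrame(records, columns=["actor", "target", "geometry", "effect"])


def _draw_trait_levels(
    catalog: StrainCatalog, response: pd.Series, rng: np.random.Generator
) -> pd.DataFrame:
    """True PGPT levels; promoted strains carry abilities more often.

    Levels sit well away from the default positivity cutoffs so that planted
    ability counts are unambiguous at the simulated assay noise.
    """
    rows = {}
    for strain in catalog:
        promoted = response[strain.code] == PROMOTED
        p_iaa, p_dpph, p_sid, p_pho = (
            (0.8, 0.7, 0.6, 0.6) if promoted else (0.35, 0.3, 0.25, 0.3)
        )
        iaa = rng.uniform(10.0, 70.0) if rng.random() < p_iaa else 0.0
        dpph = rng.uniform(60.0, 95.0) if rng.random() < p_dpph else rng.uniform(15.0, 40.0)
        sid = rng.uniform(0.15, 0.5) if rng.random() < p_sid else 0.0
        pho = rng.uniform(30.0, 140.0) if rng.random() < p_pho else 0.0
        rows[strain.code] = {
            "iaa_mg_l": iaa,
            "siderophore_units": sid,
            "dpph_pct": dpph,
            "phosphate_mg_l": pho,
        }
    frame = pd.DataFrame.from_dict(rows, orient="index")[list(TRAIT_COLUMNS)]
    frame.index.name = "code"
    return frame


def null_truth(
    catalog: StrainCatalog,
    concentrations: Sequence[float] = TREATMENT_CONCENTRATIONS,
) -> PlantedTruth:
    """All-null truth: unit growth factors, zero interactions, zero effects.

    In the noise-free limit every downstream score (log2FC, interaction
    index, percent change) must be exactly zero on data simulated from this
    truth.
    """
    codes = list(catalog.codes)
    response = pd.Series(INHIBITED, index=pd.Index(codes, name="code"), name="response")
    effect = pd.DataFrame(
        1.0, index=codes, columns=[float(c) for c in concentrations]
    )
    effect.index.name = "code"

    bac = [s.code for s in catalog.bacteria]
    fun = [s.code for s in catalog.fungi]
    records = (
        [(a, t, "bb_vshape", 0.0) for a in bac for t in bac if a != t]
        + [(a, t, "ff_dual", 0.0) for a in fun for t in fun if a != t]
        + [(a, t, "bf_streak", 0.0) for a in bac for t in fun]
    )
    interaction = pd.DataFrame(records, columns=["actor", "target", "geometry", "effect"])
    traits = pd.DataFrame(0.0, index=codes, columns=list(TRAIT_COLUMNS))
    traits.index.name = "code"
    pot = pd.DataFrame(0.0, index=list(SYNCOM_NAMES), columns=list(PHENOTYPES))
    pot.index.name = "design"
    return PlantedTruth(response, effect, interaction, traits, pot)
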