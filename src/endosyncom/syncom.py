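"""Synthetic-community construction and pot-experiment evaluation.

Six communities are built from the growth classification of the screening
panel:

* ``CK`` — uninoculated control (empty membership);
* ``AB`` — all bacteria; ``AF`` — all fungi; ``ABF`` — their union;
* ``TPB&TPF`` — every triterpenoid-promoted strain;
* ``TNB&TNF`` — every triterpenoid-inhibited strain.

Pot outcomes (root length, plant height, dry weight, chlorophyll and four
metabolite contents) are summarized as percent changes against the control
(CK) and against the full community (ABF), with ANOVA + posthoc letters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from . import stats as stats_report
from .catalog import BACTERIUM, FUNGUS, StrainCatalog
from .traits import fit_standard_curve, inverse_predict
from .truth import INHIBITED, PROMOTED, SYNCOM_NAMES


@dataclass(frozen=True)
class SynComDesign:
    """Named membership list over the strain catalog."""

    name: str
    members: tuple[str, ...]
    baseline: str  # evaluation baseline arm: "CK" or "ABF"


def build_syncoms(
    classification: pd.DataFrame, catalog: StrainCatalog
) -> dict[str, SynComDesign]:
    """Construct the six SynCom designs from a panel classification.

    ``classification`` must carry one row per catalog strain (columns
    ``strain, kingdom, response``).  The returned designs satisfy:
    CK = ∅, AB = all bacteria, AF = all fungi, ABF = AB ∪ AF,
    TPB&TPF ∪ TNB&TNF = ABF with empty intersection.
    """
    if set(classification["strain"]) != set(catalog.codes):
        raise ValueError("classification does not cover the catalog exactly")
    cls = classification.set_index("strain")

    bacteria = tuple(s.code for s in catalog.bacteria)
    fungi = tuple(s.code for s in catalog.fungi)
    promoted = tuple(
        code for code in catalog.codes if cls.at[code, "response"] == PROMOTED
    )
    inhibited = tuple(
        code for code in catalog.codes if cls.at[code, "response"] == INHIBITED
    )
    return {
        "CK": SynComDesign("CK", (), "CK"),
        "AB": SynComDesign("AB", bacteria, "CK"),
        "AF": SynComDesign("AF", fungi, "CK"),
        "ABF": SynComDesign("ABF", bacteria + fungi, "CK"),
        "TPB&TPF": SynComDesign("TPB&TPF", promoted, "ABF"),
        "TNB&TNF": SynComDesign("TNB&TNF", inhibited, "ABF"),
    }


def percent_change(treatment_mean: float, baseline_mean: float) -> float:
    """(treatment − baseline)/baseline × 100; baseline must be positive."""
    if baseline_mean <= 0:
        raise ValueError("baseline mean must be strictly positive")
    return (treatment_mean - baseline_mean) / baseline_mean * 100.0


def chlorophyll_conc_mg_l(
    a645, a663, coefficients: tuple[float, float] = (20.2, 8.02)
):
    """Total chlorophyll in the extract (mg/L) from A645/A663 absorbances.

    Classical Arnon-type coefficients for 80 % acetone extracts by default.
    """
    a645 = np.asarray(a645, dtype=float)
    a663 = np.asarray(a663, dtype=float)
    if np.any(a645 < 0) or np.any(a663 < 0):
        raise ValueError("absorbances must be non-negative")
    c1, c2 = coefficients
    out = c1 * a645 + c2 * a663
    return float(out) if out.ndim == 0 else out


def chlorophyll_content(
    a645,
    a663,
    fresh_mass_g: float,
    extract_volume_ml: float,
    coefficients: tuple[float, float] = (20.2, 8.02),
):
    """Total chlorophyll per gram fresh tissue (mg/g)."""
    if fresh_mass_g <= 0 or extract_volume_ml <= 0:
        raise ValueError("mass and extract volume must be strictly positive")
    conc = chlorophyll_conc_mg_l(a645, a663, coefficients)
    return conc * (extract_volume_ml / 1000.0) / fresh_mass_g


@dataclass(frozen=True)
class PotConfig:
    """Extraction bookkeeping for pot-experiment phenotypes.

    Chlorophyll: ``leaf_mass_g`` fresh leaf extracted in
    ``extract_volume_ml`` of 80 % acetone.  Metabolites: ``powder_mass_g``
    dry powder extracted in ``solvent_volume_ml`` solvent, so content per
    gram = extract concentration (mg/L) × volume(L) / mass(g).
    """

    chlorophyll_coefficients: tuple[float, float] = (20.2, 8.02)
    leaf_mass_g: float = 0.2
    extract_volume_ml: float = 8.0
    powder_mass_g: float = 1.0
    solvent_volume_ml: float = 50.0


METABOLITE_ASSAYS = ("polyphenol", "flavonoid", "total_sugar", "total_triterpenoid")


def _plant_phenotypes(
    raw: pd.DataFrame,
    curves: Mapping[str, object],
    config: PotConfig,
) -> pd.DataFrame:
    """Wide per-plant phenotype values derived from the raw measurement table."""
    wide = raw.pivot_table(
        index=["design", "pot", "plant"], columns="measure", values="value"
    )
    out = pd.DataFrame(index=wide.index)
    for direct in ("root_length_cm", "plant_height_cm", "dry_weight_g"):
        if direct in wide.columns:
            out[direct] = wide[direct]
    if {"chl_a645", "chl_a663"} <= set(wide.columns):
        out["chlorophyll_mg_g"] = chlorophyll_content(
            wide["chl_a645"].to_numpy(),
            wide["chl_a663"].to_numpy(),
            config.leaf_mass_g,
            config.extract_volume_ml,
            config.chlorophyll_coefficients,
        )
    scale = config.solvent_volume_ml / 1000.0 / config.powder_mass_g
    for assay in METABOLITE_ASSAYS:
        col = f"abs_{assay}"
        if col in wide.columns:
            conc = inverse_predict(
                curves[assay], wide[col].to_numpy(), warn_extrapolation=False
            )
            out[f"{assay}_mg_g"] = conc * scale
    return out.reset_index()


def evaluate_pot(
    raw: pd.DataFrame,
    designs: Mapping[str, SynComDesign],
    standards: pd.DataFrame,
    config: PotConfig = PotConfig(),
    posthoc: str = "duncan",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Summarize pot outcomes per design × phenotype.

    Requires the control (CK) and full-community (ABF) arms in ``raw`` as the
    two percent-change baselines.  Metabolite absorbances are converted
    through curves fitted to ``standards``.  Returns one row per design ×
    phenotype with ``n, mean, sd, pct_vs_ck, pct_vs_abf, letter`` (letters
    from one-way ANOVA + posthoc across designs within each phenotype).
    """
    present = set(raw["design"])
    missing = sorted(set(designs) - present)
    if missing:
        raise ValueError(f"designs missing from the pot table: {missing}")
    for arm in ("CK", "ABF"):
        if arm not in present:
            raise ValueError(f"baseline arm {arm!r} missing from the pot table")

    curves = {}
    for assay in METABOLITE_ASSAYS:
        series = standards[standards["assay"] == assay]
        if series.empty:
            raise ValueError(f"standard series for {assay!r} is missing")
        curves[assay] = fit_standard_curve(series, assay=assay)

    plants = _plant_phenotypes(raw, curves, config)
    phenotypes = [c for c in plants.columns if c not in ("design", "pot", "plant")]
    design_order = [d for d in SYNCOM_NAMES if d in present] + sorted(
        present - set(SYNCOM_NAMES)
    )

    rows = []
    for phenotype in phenotypes:
        groups = {
            d: plants.loc[plants["design"] == d, phenotype].dropna().to_numpy()
            for d in design_order
        }
        letters = stats_report.anova_letters(groups, alpha=alpha, posthoc=posthoc)
        letter_map = dict(zip(letters["group"], letters["letter"]))
        ck_mean = float(groups["CK"].mean())
        abf_mean = float(groups["ABF"].mean())
        for d in design_order:
            vals = groups[d]
            mean = float(vals.mean())
            rows.append(
                {
                    "phenotype": phenotype,
                    "design": d,
                    "n": len(vals),
                    "mean": mean,
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                    "pct_vs_ck": percent_change(mean, ck_mean),
                    "pct_vs_abf": percent_change(mean, abf_mean),
                    "letter": letter_map[d],
                }
            )
    return pd.DataFrame(rows)
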