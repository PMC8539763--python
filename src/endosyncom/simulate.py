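"""Synthetic plate, colorimetric and pot-experiment data generators.

Every generator is deterministic given its seed, returns tidy pandas frames,
and plants its effects so that the noise-free limit reproduces the downstream
scores exactly:

* growth curves are logistic with the triterpenoid effect acting
  multiplicatively on the carrying capacity, and the inoculum standardized
  relative to capacity, so a planted factor *f* yields an endpoint log2 fold
  change of exactly log2(*f*);
* interaction plates scale the treated measurement so the interaction index
  recovers the planted fraction × 100 exactly at zero noise;
* colorimetric assays push true trait levels through linear standard curves;
* pot phenotypes scale uninoculated-control means by (1 + planted effect).

Measurement noise is multiplicative log-normal (keeps all plate measurements
strictly positive); absorbance noise is additive Gaussian truncated at zero.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .catalog import BACTERIUM, FUNGUS, StrainCatalog
from .truth import DEFAULT_CONCENTRATIONS, PlantedTruth

#: sampling times; hours for bacterial OD600, days for fungal fresh mass
BACTERIAL_TIMES_H = (0.0, 12.0, 24.0, 48.0, 72.0)
FUNGAL_TIMES_D = (0.0, 3.0, 6.0, 9.0, 12.0)

#: scored endpoint per kingdom (48 h for bacteria, day 12 for fungi)
ENDPOINT_TIME = {BACTERIUM: 48.0, FUNGUS: 12.0}

#: inoculum as a fraction of carrying capacity
_INOCULUM_FRACTION = 0.01

#: reagent-only absorbances for the two curve-free colorimetric assays
DPPH_CONTROL_ABSORBANCE = 0.7
CAS_BLANK_ABSORBANCE = 0.9

#: uninoculated-control phenotype means for the pot experiment
CONTROL_PHENOTYPES: dict[str, float] = {
    "root_length_cm": 5.0,
    "plant_height_cm": 8.0,
    "dry_weight_g": 0.4,
    "chlorophyll_mg_g": 1.5,
    "polyphenol_mg_g": 12.0,
    "flavonoid_mg_g": 10.0,
    "total_sugar_mg_g": 40.0,
    "total_triterpenoid_mg_g": 20.0,
}


@dataclass(frozen=True)
class TrueAssayCurve:
    """Latent linear map concentration -> absorbance used by the generators."""

    assay: str
    slope: float
    intercept: float
    standards: tuple[float, ...]
    wavelength_nm: float

    def forward(self, concentration):
        return self.slope * np.asarray(concentration, dtype=float) + self.intercept


def default_assay_curves() -> dict[str, TrueAssayCurve]:
    """Latent standard curves for every colorimetric assay in the pipeline.

    IAA (Salkowski, 535 nm) and soluble phosphate (Mo–Sb, 720 nm) quantify
    strain traits; glucose, rutin, gallic-acid and nigranoic-acid curves
    quantify plant metabolites.  Slopes/intercepts are typical working-range
    values for the respective spectrophotometric methods.
    """
    return {
        "iaa": TrueAssayCurve("iaa", 0.012, 0.05, (0, 10, 25, 50, 75, 100), 535),
        "phosphate": TrueAssayCurve("phosphate", 0.006, 0.04, (0, 25, 50, 100, 150), 720),
        "total_sugar": TrueAssayCurve(
            "total_sugar", 0.0004, 0.02, (0, 250, 500, 1000, 1500, 2000), 490
        ),
        "flavonoid": TrueAssayCurve("flavonoid", 0.0015, 0.03, (0, 50, 100, 200, 350, 500), 510),
        "polyphenol": TrueAssayCurve("polyphenol", 0.002, 0.02, (0, 50, 100, 200, 350, 500), 760),
        "total_triterpenoid": TrueAssayCurve(
            "total_triterpenoid", 0.0008, 0.03, (0, 250, 500, 1000, 1500, 2000), 545
        ),
    }


def _lognormal_noise(rng: np.random.Generator, sd: float, size: int) -> np.ndarray:
    if sd <= 0:
        return np.ones(size)
    return np.exp(rng.normal(0.0, sd, size))


def _truncated_normal_noise(rng: np.random.Generator, sd: float, values: np.ndarray) -> np.ndarray:
    if sd <= 0:
        return values
    return np.maximum(values + rng.normal(0.0, sd, values.shape), 0.0)


def _logistic_fraction(t: np.ndarray, rate: float, f0: float) -> np.ndarray:
    """N(t)/K for logistic growth started at N(0) = f0·K."""
    return f0 / (f0 + (1.0 - f0) * np.exp(-rate * t))


def simulate_dose_response(
    catalog: StrainCatalog,
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS,
    truth: PlantedTruth | None = None,
    replicates: int = 5,
    noise_sd: float = 0.05,
    seed: int = 42,
) -> pd.DataFrame:
    """Endpoint growth grids per strain × concentration × replicate.

    Bacterial rows carry OD600 time courses (h), fungal rows mycelium fresh
    mass (g, days).  The solvent control (0 µM) must be among
    ``concentrations``.  Columns: ``strain, kingdom, concentration_uM,
    replicate, time, value``.
    """
    if truth is None:
        raise ValueError("a PlantedTruth is required")
    concentrations = sorted(float(c) for c in concentrations)
    if 0.0 not in concentrations:
        raise ValueError("the solvent control concentration (0 uM) must be present")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    missing = [
        c for c in concentrations if c != 0.0 and c not in set(truth.effect_size.columns)
    ]
    if missing:
        raise ValueError(f"planted effect sizes missing for concentrations {missing}")

    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for strain in catalog:
        if strain.kingdom == BACTERIUM:
            times, rate, capacity = (
                np.array(BACTERIAL_TIMES_H),
                rng.uniform(0.15, 0.35),
                rng.uniform(0.8, 1.4),
            )
        else:
            times, rate, capacity = (
                np.array(FUNGAL_TIMES_D),
                rng.uniform(0.5, 0.9),
                rng.uniform(0.5, 1.5),
            )
        growth = _logistic_fraction(times, rate, _INOCULUM_FRACTION)
        for conc in concentrations:
            factor = 1.0 if conc == 0.0 else float(truth.effect_size.at[strain.code, conc])
            clean = capacity * factor * growth
            for rep in range(1, replicates + 1):
                noisy = clean * _lognormal_noise(rng, noise_sd, len(times))
                for t, v in zip(times, noisy):
                    rows.append(
                        {
                            "strain": strain.code,
                            "kingdom": strain.kingdom,
                            "concentration_uM": conc,
                            "replicate": rep,
                            "time": t,
                            "value": v,
                        }
                    )
    return pd.DataFrame(rows)


_GEOMETRY_COLUMNS = {
    "bb_vshape": ("d25_ea_mm", "d10_ea_mm", "d25_ca_mm", "d10_ca_mm"),
    "ff_dual": ("s_ea", "s_ca"),
    "bf_streak": ("d_ea_mm", "d_ca_mm"),
}


def simulate_interaction_plates(
    catalog: StrainCatalog,
    truth: PlantedTruth,
    geometry: str,
    noise_sd: float = 0.05,
    replicates: int = 3,
    seed: int = 42,
) -> pd.DataFrame:
    """Raw plate measurements for one interaction geometry.

    * ``bb_vshape`` — V-shape co-inoculation of bacterial pairs; the target's
      colony diameter is read 25 mm and 10 mm from the V on experiment (EA)
      and mono-culture control (CA) plates.  The planted effect lands on the
      near (10 mm) experimental colony as D10-EA = D10-CA / (1 + effect), so
      the ratio-of-ratios index recovers effect × 100 exactly at zero noise.
    * ``ff_dual`` — fungal dual culture; colony areas S-EA vs S-CA.
    * ``bf_streak`` — bacterial streak challenging a fungal plug; colony
      diameters D-EA vs D-CA.
    """
    if geometry not in _GEOMETRY_COLUMNS:
        raise ValueError(f"unknown geometry {geometry!r}")
    pairs = truth.interaction_effect.query("geometry == @geometry")
    unknown = sorted(
        (set(pairs["actor"]) | set(pairs["target"])) - set(catalog.codes)
    )
    if unknown:
        raise ValueError(f"interaction effects reference unknown strains: {unknown}")
    if (pairs["effect"] <= -1).any():
        raise ValueError("interaction effects must be > -1")

    rng = np.random.default_rng(seed)
    targets = sorted(set(pairs["target"]))
    baselines: dict[str, tuple[float, ...]] = {}
    for t in targets:
        if geometry == "bb_vshape":
            baselines[t] = (rng.uniform(6.0, 10.0), rng.uniform(6.0, 10.0))
        elif geometry == "ff_dual":
            baselines[t] = (rng.uniform(300.0, 1200.0),)
        else:
            baselines[t] = (rng.uniform(20.0, 40.0),)
    if any(b <= 0 for base in baselines.values() for b in base):
        raise ValueError("nonpositive baseline measurement")

    rows: list[dict] = []
    for actor, target, _, effect in pairs[["actor", "target", "geometry", "effect"]].itertuples(
        index=False
    ):
        base = baselines[target]
        for rep in range(1, replicates + 1):
            if geometry == "bb_vshape":
                d25, d10 = base
                eps = _lognormal_noise(rng, noise_sd, 4)
                row = {
                    "d25_ea_mm": d25 * eps[0],
                    "d10_ea_mm": d10 / (1.0 + effect) * eps[1],
                    "d25_ca_mm": d25 * eps[2],
                    "d10_ca_mm": d10 * eps[3],
                }
            elif geometry == "ff_dual":
                (s,) = base
                eps = _lognormal_noise(rng, noise_sd, 2)
                row = {"s_ea": s * (1.0 + effect) * eps[0], "s_ca": s * eps[1]}
            else:
                (d,) = base
                eps = _lognormal_noise(rng, noise_sd, 2)
                row = {"d_ea_mm": d * (1.0 + effect) * eps[0], "d_ca_mm": d * eps[1]}
            rows.append(
                {"actor": actor, "target": target, "geometry": geometry, "replicate": rep, **row}
            )
    return pd.DataFrame(rows)


def standard_series(
    curves: Mapping[str, TrueAssayCurve],
    noise_sd: float = 0.0,
    seed: int = 42,
) -> pd.DataFrame:
    """Standard-curve calibration tables (assay, concentration, absorbance)."""
    rng = np.random.default_rng(seed)
    rows = []
    for assay, curve in curves.items():
        conc = np.asarray(curve.standards, dtype=float)
        absorb = _truncated_normal_noise(rng, noise_sd, curve.forward(conc))
        for c, a in zip(conc, absorb):
            rows.append({"assay": assay, "concentration": c, "absorbance": a})
    return pd.DataFrame(rows)


def simulate_trait_assays(
    catalog: StrainCatalog,
    truth: PlantedTruth,
    curves: Mapping[str, TrueAssayCurve] | None = None,
    noise_sd: float = 0.02,
    replicates: int = 3,
    seed: int = 42,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw colorimetric readings for the four PGPT assays.

    Returns ``(samples, standards)``.  ``samples`` columns: ``strain, assay,
    replicate, absorbance, reference_absorbance`` — the reference column
    carries the reagent control for DPPH and the no-strain blank for the CAS
    siderophore assay, NaN otherwise.  ``standards`` holds the IAA and
    phosphate calibration series.
    """
    if curves is None:
        curves = {k: v for k, v in default_assay_curves().items() if k in ("iaa", "phosphate")}
    for needed in ("iaa", "phosphate"):
        if needed not in curves:
            raise ValueError(f"a standard curve for {needed!r} is required")

    rng = np.random.default_rng(seed)
    standards = standard_series(curves, noise_sd=noise_sd, seed=int(rng.integers(2**31)))

    rows = []
    for strain in catalog:
        levels = truth.trait_levels.loc[strain.code]
        for rep in range(1, replicates + 1):
            a_iaa = curves["iaa"].forward(levels["iaa_mg_l"])
            a_pho = curves["phosphate"].forward(levels["phosphate_mg_l"])
            a_dpph_ref = DPPH_CONTROL_ABSORBANCE
            a_dpph = a_dpph_ref * (1.0 - levels["dpph_pct"] / 100.0)
            a_sid_ref = CAS_BLANK_ABSORBANCE
            a_sid = a_sid_ref - levels["siderophore_units"]
            vals = _truncated_normal_noise(
                rng,
                noise_sd,
                np.array([a_iaa, a_pho, a_dpph, a_dpph_ref, a_sid, a_sid_ref], dtype=float),
            )
            rows.extend(
                [
                    {"strain": strain.code, "assay": "iaa", "replicate": rep,
                     "absorbance": vals[0], "reference_absorbance": np.nan},
                    {"strain": strain.code, "assay": "phosphate", "replicate": rep,
                     "absorbance": vals[1], "reference_absorbance": np.nan},
                    {"strain": strain.code, "assay": "dpph", "replicate": rep,
                     "absorbance": vals[2], "reference_absorbance": vals[3]},
                    {"strain": strain.code, "assay": "siderophore", "replicate": rep,
                     "absorbance": vals[4], "reference_absorbance": vals[5]},
                ]
            )
    return pd.DataFrame(rows), standards


def simulate_pot_experiment(
    designs: Mapping[str, "object"],
    truth: PlantedTruth,
    curves: Mapping[str, TrueAssayCurve] | None = None,
    pots: int = 3,
    plants_per_pot: int = 3,
    noise_sd: float = 0.1,
    seed: int = 42,
    leaf_mass_g: float = 0.2,
    extract_volume_ml: float = 8.0,
    chlorophyll_coefficients: tuple[float, float] = (20.2, 8.02),
    powder_mass_g: float = 1.0,
    solvent_volume_ml: float = 50.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-plant pot-experiment measurements for every SynCom arm.

    Growth phenotypes (root length, plant height, dry weight) are emitted as
    direct values; chlorophyll as A645/A663 absorbance pairs; the four
    metabolites as assay absorbances through the latent standard curves.
    Treatment means equal control means scaled by (1 + planted effect); noise
    is multiplicative log-normal on the phenotype before the measurement
    transform.  Returns ``(long measurements, metabolite standards)``.
    """
    if curves is None:
        curves = {
            k: v
            for k, v in default_assay_curves().items()
            if k in ("total_sugar", "flavonoid", "polyphenol", "total_triterpenoid")
        }
    known = set(truth.response_class.index)
    for name, design in designs.items():
        members = getattr(design, "members", design)
        unknown = sorted(set(members) - known)
        if unknown:
            raise ValueError(f"design {name!r} references unknown strains: {unknown}")
        if name not in truth.pot_effects.index:
            raise ValueError(f"no planted pot effect for design {name!r}")

    rng = np.random.default_rng(seed)
    standards = standard_series(curves, noise_sd=0.0, seed=int(rng.integers(2**31)))

    c1, c2 = chlorophyll_coefficients
    rows = []
    for name in designs:
        effects = truth.pot_effects.loc[name]
        for pot in range(1, pots + 1):
            for plant in range(1, plants_per_pot + 1):
                values = {
                    p: CONTROL_PHENOTYPES[p]
                    * (1.0 + effects[p])
                    * _lognormal_noise(rng, noise_sd, 1)[0]
                    for p in CONTROL_PHENOTYPES
                }
                meas = {
                    "root_length_cm": values["root_length_cm"],
                    "plant_height_cm": values["plant_height_cm"],
                    "dry_weight_g": values["dry_weight_g"],
                }
                # chlorophyll content -> equal-absorbance A645/A663 pair
                conc_mg_l = values["chlorophyll_mg_g"] * 1000.0 * leaf_mass_g / extract_volume_ml
                a = conc_mg_l / (c1 + c2)
                meas["chl_a645"] = a
                meas["chl_a663"] = a
                # metabolite content (mg/g powder) -> extract conc -> absorbance
                for assay in curves:
                    content = values[f"{assay}_mg_g"]
                    conc = content * powder_mass_g * 1000.0 / solvent_volume_ml
                    meas[f"abs_{assay}"] = float(curves[assay].forward(conc))
                for measure, value in meas.items():
                    rows.append(
                        {"design": name, "pot": pot, "plant": plant,
                         "measure": measure, "value": value}
                    )
    return pd.DataFrame(rows), standards


def write_dataset(
    outdir: str,
    tables: Mapping[str, pd.DataFrame],
    truth: PlantedTruth | None = None,
    parameters: Mapping[str, object] | None = None,
) -> str:
    """Write one CSV per table plus a YAML manifest; returns the manifest path."""
    os.makedirs(outdir, exist_ok=True)
    files = {}
    for name, table in tables.items():
        path = os.path.join(outdir, f"{name}.csv")
        table.to_csv(path, index=False)
        files[name] = os.path.basename(path)
    if truth is not None:
        truth_dir = os.path.join(outdir, "truth")
        truth.to_dir(truth_dir)
        files["truth"] = "truth/"
    manifest = {"files": files, "parameters": dict(parameters or {})}
    manifest_path = os.path.join(outdir, "manifest.yaml")
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest_path
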