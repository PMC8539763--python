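"""Plant-growth-promotion trait (PGPT) quantification from colorimetric assays.

Four traits are screened per strain: indole-3-acetic acid production
(Salkowski reagent, 535 nm), siderophore production (liquid CAS assay,
630 nm), DPPH radical scavenging, and phosphate solubilization (Mo–Sb
colorimetry, 720 nm).  IAA and phosphate are quantified by inverse prediction
through linear standard curves; DPPH is the percent drop of the radical's
absorbance against the reagent control; siderophore output is reported in
blank-referenced absorbance units (CAS decolorization), since the assay has
no canonical standard analyte — a user-supplied curve can convert it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats as stats_report
from .catalog import BACTERIUM, FUNGUS
from .truth import INHIBITED, PROMOTED, TRAIT_COLUMNS


@dataclass(frozen=True)
class StandardCurve:
    """Fitted linear map absorbance = slope · concentration + intercept."""

    assay: str
    slope: float
    intercept: float
    r_squared: float
    concentration_range: tuple[float, float]
    wavelength_nm: float | None = None

    def predict(self, concentration):
        """Forward map: expected absorbance at a concentration."""
        return self.slope * np.asarray(concentration, dtype=float) + self.intercept


def fit_standard_curve(
    standards: pd.DataFrame | list[tuple[float, float]],
    assay: str = "",
    wavelength_nm: float | None = None,
) -> StandardCurve:
    """Ordinary least-squares line through a standard series.

    ``standards`` is a (concentration, absorbance) table with at least three
    distinct concentrations.
    """
    if isinstance(standards, pd.DataFrame):
        conc = standards["concentration"].to_numpy(dtype=float)
        absorb = standards["absorbance"].to_numpy(dtype=float)
    else:
        arr = np.asarray(standards, dtype=float)
        conc, absorb = arr[:, 0], arr[:, 1]
    if len(np.unique(conc)) < 3:
        raise ValueError("at least 3 distinct standard concentrations are required")
    res = sps.linregress(conc, absorb)
    if res.slope == 0:
        raise ValueError("degenerate standard series: zero slope")
    return StandardCurve(
        assay=assay,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        concentration_range=(float(conc.min()), float(conc.max())),
        wavelength_nm=wavelength_nm,
    )


def inverse_predict(curve: StandardCurve, absorbance, warn_extrapolation: bool = True):
    """Concentration from absorbance: (A − intercept)/slope, floored at 0.

    Warns when the prediction falls outside the standard range.
    """
    if curve.slope == 0:
        raise ValueError("cannot invert a curve with zero slope")
    absorbance = np.asarray(absorbance, dtype=float)
    conc = np.maximum((absorbance - curve.intercept) / curve.slope, 0.0)
    lo, hi = curve.concentration_range
    if warn_extrapolation and np.any((conc < lo - 1e-12) | (conc > hi + 1e-12)):
        warnings.warn(
            f"inverse prediction outside the {curve.assay or 'standard'} range "
            f"[{lo}, {hi}]",
            stacklevel=2,
        )
    return float(conc) if conc.ndim == 0 else conc


def dpph_scavenging(a_sample, a_control):
    """DPPH radical scavenging % = (A_control − A_sample)/A_control × 100."""
    a_sample = np.asarray(a_sample, dtype=float)
    a_control = np.asarray(a_control, dtype=float)
    if np.any(a_control <= 0):
        raise ValueError("DPPH control absorbance must be strictly positive")
    if np.any(a_sample < 0):
        raise ValueError("sample absorbance must be non-negative")
    out = (a_control - a_sample) / a_control * 100.0
    return float(out) if out.ndim == 0 else out


def quantify_traits(
    samples: pd.DataFrame,
    standards: pd.DataFrame,
    wavelengths: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-strain trait profile from raw assay readings.

    ``samples`` columns: ``strain, assay, replicate, absorbance,
    reference_absorbance`` (reference = reagent control for ``dpph``, CAS
    blank for ``siderophore``).  ``standards`` holds the ``iaa`` and
    ``phosphate`` calibration series.  Curve-based assays average the
    replicate absorbances before a single inverse prediction (flooring each
    replicate separately would bias blank-level readings upward); DPPH and
    siderophore are referenced within replicate and then averaged.  Returns a
    frame indexed by strain with columns ``iaa_mg_l, siderophore_units,
    dpph_pct, phosphate_mg_l``.
    """
    wavelengths = wavelengths or {"iaa": 535.0, "phosphate": 720.0}
    curves = {}
    for assay in ("iaa", "phosphate"):
        series = standards[standards["assay"] == assay]
        if series.empty:
            raise ValueError(f"standard series for {assay!r} is missing")
        curves[assay] = fit_standard_curve(
            series, assay=assay, wavelength_nm=wavelengths.get(assay)
        )

    rows: dict[str, dict[str, float]] = {}
    for (strain, assay), sub in samples.groupby(["strain", "assay"]):
        rows.setdefault(strain, {})
        if assay == "iaa":
            mean_abs = float(sub["absorbance"].mean())
            rows[strain]["iaa_mg_l"] = inverse_predict(curves["iaa"], mean_abs)
        elif assay == "phosphate":
            mean_abs = float(sub["absorbance"].mean())
            rows[strain]["phosphate_mg_l"] = inverse_predict(curves["phosphate"], mean_abs)
        elif assay == "dpph":
            pct = dpph_scavenging(
                sub["absorbance"].to_numpy(), sub["reference_absorbance"].to_numpy()
            )
            rows[strain]["dpph_pct"] = float(np.clip(np.mean(pct), None, 100.0))
        elif assay == "siderophore":
            units = sub["reference_absorbance"].to_numpy() - sub["absorbance"].to_numpy()
            rows[strain]["siderophore_units"] = float(max(np.mean(units), 0.0))
        else:
            raise ValueError(f"unknown assay {assay!r}")
    profile = pd.DataFrame.from_dict(rows, orient="index")
    profile.index.name = "strain"
    for col in TRAIT_COLUMNS:
        if col not in profile.columns:
            profile[col] = np.nan
    return profile[list(TRAIT_COLUMNS)].sort_index()


@dataclass(frozen=True)
class PgptThresholds:
    """Positivity cutoffs for counting a trait as an ability.

    Curve-based cutoffs follow the blank + 3·SD detection-limit convention
    at a typical 0.02 absorbance noise (3 × 0.02 / slope), ``dpph_pct`` the
    common 50 %-scavenging criterion, and the siderophore cutoff the same
    3·SD rule on blank-referenced CAS absorbance.  None is an assay
    constant; every value is overridable.
    """

    iaa_mg_l: float = 5.0
    siderophore_units: float = 0.05
    dpph_pct: float = 50.0
    phosphate_mg_l: float = 10.0

    def as_dict(self) -> dict[str, float]:
        return {
            "iaa_mg_l": self.iaa_mg_l,
            "siderophore_units": self.siderophore_units,
            "dpph_pct": self.dpph_pct,
            "phosphate_mg_l": self.phosphate_mg_l,
        }


def score_pgpt(
    profile: pd.DataFrame, thresholds: PgptThresholds = PgptThresholds()
) -> pd.DataFrame:
    """Count traits above their positivity cutoffs per strain.

    A missing (NaN) trait is marked untested and excluded from the count.
    Adds one boolean column per trait (``has_<trait>``) plus ``pgpt_count``.
    """
    cuts = thresholds.as_dict()
    out = profile.copy()
    count = np.zeros(len(out), dtype=int)
    for col, cut in cuts.items():
        values = out[col] if col in out.columns else pd.Series(np.nan, index=out.index)
        positive = (values > cut).fillna(False)
        out[f"has_{col}"] = positive.astype(bool)
        count += positive.astype(int).to_numpy()
    out["pgpt_count"] = count
    return out


def compare_pgpt_by_class(
    pgpt: pd.DataFrame, classification: pd.DataFrame
) -> dict:
    """Compare PGPT ability counts between growth classes, per kingdom.

    Returns ``{"summary": frame, "bacteria": GroupComparison | None,
    "fungi": GroupComparison | None}``; a kingdom's comparison is skipped
    with a warning when either class has fewer than two strains.
    """
    cls = classification.set_index("strain")
    unknown = sorted(set(pgpt.index) - set(cls.index))
    if unknown:
        raise ValueError(f"classification lacks strains: {unknown}")
    merged = pgpt.join(cls[["kingdom", "response", "label"]], how="inner")

    summary = (
        merged.groupby(["kingdom", "label"])["pgpt_count"]
        .agg(n="count", mean="mean", sd="std", median="median")
        .reset_index()
    )

    results: dict[str, object] = {"summary": summary}
    for kingdom, key in ((BACTERIUM, "bacteria"), (FUNGUS, "fungi")):
        sub = merged[merged["kingdom"] == kingdom]
        groups = {
            resp: grp["pgpt_count"].to_numpy()
            for resp, grp in sub.groupby("response")
        }
        if (
            PROMOTED in groups
            and INHIBITED in groups
            and all(len(groups[g]) >= 2 for g in (PROMOTED, INHIBITED))
        ):
            results[key] = stats_report.rank_test(
                groups[PROMOTED], groups[INHIBITED], labels=(PROMOTED, INHIBITED)
            )
        else:
            warnings.warn(
                f"PGPT comparison skipped for {key}: a class has fewer than 2 strains",
                stacklevel=2,
            )
            results[key] = None
    return results
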