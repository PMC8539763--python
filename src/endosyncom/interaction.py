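"""Binary interaction-index (II) scoring on three plate geometries.

All three indices are percent fold changes of a target's growth in the
presence of an actor relative to a mono-culture control; II < 0 means growth
inhibition, II > 0 facilitation.

* bacterium→bacterium (V-shape):
  II = [(D25-EA / D10-EA) / (D25-CA / D10-CA) − 1] × 100,
  with D25/D10 the neighbouring colony diameters 25 and 10 mm from the V on
  experiment (EA) and control (CA) plates;
* fungus→fungus (dual culture): II = (S-EA / S-CA − 1) × 100 on colony areas;
* bacterium→fungus (streak): the same form on fungal colony diameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as stats_report

GEOMETRY_COLUMNS = {
    "bb_vshape": ("d25_ea_mm", "d10_ea_mm", "d25_ca_mm", "d10_ca_mm"),
    "ff_dual": ("s_ea", "s_ca"),
    "bf_streak": ("d_ea_mm", "d_ca_mm"),
}


def bb_interaction_index(d25_ea, d10_ea, d25_ca, d10_ca):
    """V-shape index on two-distance diameter ratios (all diameters > 0)."""
    arrs = [np.asarray(x, dtype=float) for x in (d25_ea, d10_ea, d25_ca, d10_ca)]
    if any(np.any(a <= 0) for a in arrs):
        raise ValueError("colony diameters must be strictly positive")
    d25_ea, d10_ea, d25_ca, d10_ca = arrs
    out = ((d25_ea / d10_ea) / (d25_ca / d10_ca) - 1.0) * 100.0
    return float(out) if out.ndim == 0 else out


def ff_interaction_index(s_ea, s_ca):
    """Dual-culture index on colony areas; S-EA ≥ 0, S-CA > 0."""
    s_ea = np.asarray(s_ea, dtype=float)
    s_ca = np.asarray(s_ca, dtype=float)
    if np.any(s_ca <= 0):
        raise ValueError("control colony area must be strictly positive")
    if np.any(s_ea < 0):
        raise ValueError("experimental colony area must be non-negative")
    out = (s_ea / s_ca - 1.0) * 100.0
    return float(out) if out.ndim == 0 else out


def bf_interaction_index(d_ea, d_ca):
    """Streak-assay index on fungal colony diameters (same form as ff)."""
    return ff_interaction_index(d_ea, d_ca)


@dataclass
class InteractionMatrix:
    """Mean II per ordered actor→target pair, one geometry per matrix."""

    geometry: str
    long: pd.DataFrame  # actor, target, mean_ii, sd_ii, n
    wide: pd.DataFrame  # actor rows × target columns of mean II


def record_interaction_index(raw: pd.DataFrame) -> pd.Series:
    """Per-record II for a single-geometry raw table."""
    geometries = raw["geometry"].unique()
    if len(geometries) != 1:
        raise ValueError(f"mixed geometries in one table: {sorted(geometries)}")
    geometry = geometries[0]
    if geometry not in GEOMETRY_COLUMNS:
        raise ValueError(f"unknown geometry {geometry!r}")
    cols = GEOMETRY_COLUMNS[geometry]
    missing = [c for c in cols if c not in raw.columns]
    if missing:
        raise ValueError(f"geometry {geometry!r} requires measurement columns {missing}")
    if geometry == "bb_vshape":
        ii = bb_interaction_index(*(raw[c].to_numpy() for c in cols))
    elif geometry == "ff_dual":
        ii = ff_interaction_index(raw[cols[0]].to_numpy(), raw[cols[1]].to_numpy())
    else:
        ii = bf_interaction_index(raw[cols[0]].to_numpy(), raw[cols[1]].to_numpy())
    return pd.Series(np.atleast_1d(ii), index=raw.index, name="ii")


def build_interaction_matrix(raw: pd.DataFrame) -> InteractionMatrix:
    """Average per-replicate IIs into an ordered actor × target matrix.

    Replicate indices are computed first and then averaged (mean of
    per-replicate IIs, not II of mean measurements).
    """
    work = raw.copy()
    work["ii"] = record_interaction_index(work)
    geometry = work["geometry"].iloc[0]
    long = (
        work.groupby(["actor", "target"])["ii"]
        .agg(mean_ii="mean", sd_ii="std", n="count")
        .reset_index()
    )
    wide = long.pivot(index="actor", columns="target", values="mean_ii")
    return InteractionMatrix(geometry=geometry, long=long, wide=wide)


def aggregate_received_effects(
    matrix: InteractionMatrix,
    classification: pd.DataFrame,
    paired: bool = False,
) -> dict:
    """Distribution of IIs received by each target, grouped by target class.

    For every target strain the mean II received from all actors (self pairs
    excluded) is computed; targets are then grouped by their growth class
    (promoted vs inhibited by the triterpenoid mixture) and the two groups
    compared with a rank test.  Returns a dict with ``per_target``,
    ``group_summary`` and ``comparison`` (None, with a warning, when a group
    has fewer than two strains).
    """
    long = matrix.long[matrix.long["actor"] != matrix.long["target"]]
    received = (
        long.groupby("target")["mean_ii"].mean().rename("mean_received_ii").reset_index()
    )
    cls = classification.set_index("strain")
    unknown = sorted(set(received["target"]) - set(cls.index))
    if unknown:
        raise ValueError(f"classification lacks strains: {unknown}")
    received["response"] = cls.loc[received["target"], "response"].to_numpy()
    received["label"] = cls.loc[received["target"], "label"].to_numpy()

    group_summary = (
        received.groupby("label")["mean_received_ii"]
        .agg(n="count", mean="mean", sd="std", median="median")
        .reset_index()
    )

    groups = {
        resp: sub["mean_received_ii"].to_numpy()
        for resp, sub in received.groupby("response")
    }
    comparison = None
    if len(groups) == 2 and all(len(v) >= 2 for v in groups.values()):
        keys = sorted(groups)
        comparison = stats_report.rank_test(
            groups[keys[0]], groups[keys[1]], paired=paired, labels=tuple(keys)
        )
    else:
        warnings.warn(
            "received-effect comparison skipped: need two classes with >= 2 strains each",
            stacklevel=2,
        )
    return {"per_target": received, "group_summary": group_summary, "comparison": comparison}
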