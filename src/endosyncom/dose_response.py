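"""Dose–response scoring: log2 fold changes and growth classification.

Each strain is grown under a gradient of triterpenoid-mixture concentrations
(solvent-only control at 0 µM).  Endpoint readouts — OD600 at 48 h for
bacteria, mycelium fresh mass at day 12 for fungi — are converted to log2
fold changes against the solvent control, and the strain is classified as
triterpenoid-promoted (TPB/TPF) or -inhibited (TNB/TNF) from the mean log2FC
at the medium-to-high decision concentrations (100 and 250 µM by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .catalog import BACTERIUM, FUNGUS, StrainCatalog
from .simulate import ENDPOINT_TIME
from .truth import INHIBITED, PROMOTED

CLASS_LABELS = {
    (BACTERIUM, PROMOTED): "TPB",
    (BACTERIUM, INHIBITED): "TNB",
    (FUNGUS, PROMOTED): "TPF",
    (FUNGUS, INHIBITED): "TNF",
}


def log2_fold_change(value, reference):
    """log2(value / reference); a value of 1.0 means a two-fold increase.

    Both inputs must be strictly positive (scalars or arrays).
    """
    value = np.asarray(value, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if np.any(value <= 0) or np.any(reference <= 0):
        raise ValueError("log2 fold change requires strictly positive measurements")
    out = np.log2(value / reference)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ClassificationRule:
    """Decision rule for promoted/inhibited calls.

    The strain is labelled from the mean log2FC over ``decision_concentrations``
    when a one-sample t test of the replicate log2FCs against zero is
    significant at ``alpha``; otherwise by the sign of the grand mean over all
    concentrations (an exactly zero grand mean is labelled inhibited).
    ``baseline`` selects the log2FC reference: the solvent control endpoint
    (default) or each culture's own initial value.
    """

    decision_concentrations: tuple[float, ...] = (100.0, 250.0)
    alpha: float = 0.05
    baseline: str = "solvent_control"

    def __post_init__(self) -> None:
        if self.baseline not in ("solvent_control", "initial"):
            raise ValueError(f"unknown baseline {self.baseline!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def _endpoint_frame(profile: pd.DataFrame, endpoint_time: float | None) -> pd.DataFrame:
    if endpoint_time is None:
        kingdoms = profile["kingdom"].unique()
        if len(kingdoms) != 1:
            raise ValueError("profile must cover a single strain/kingdom")
        endpoint_time = ENDPOINT_TIME[kingdoms[0]]
    endpoint = profile[profile["time"] == endpoint_time]
    if endpoint.empty:
        raise ValueError(f"no measurements at endpoint time {endpoint_time}")
    return endpoint


def replicate_log2fc(
    profile: pd.DataFrame,
    baseline: str = "solvent_control",
    endpoint_time: float | None = None,
) -> pd.DataFrame:
    """Per-replicate endpoint log2 fold changes for one strain.

    ``profile`` is the long dose–response table restricted to one strain
    (columns ``concentration_uM, replicate, time, value, kingdom``).  With the
    solvent-control baseline each treated replicate endpoint is compared to
    the mean control (0 µM) endpoint; with the ``initial`` baseline each
    culture's endpoint is compared to its own value at time zero.
    Returns columns ``concentration_uM, replicate, log2fc``.
    """
    endpoint = _endpoint_frame(profile, endpoint_time)
    counts = endpoint.groupby("concentration_uM")["replicate"].nunique()
    if (counts < 2).any():
        raise ValueError("at least 2 replicates per concentration are required")

    if baseline == "solvent_control":
        control = endpoint[endpoint["concentration_uM"] == 0.0]
        if control.empty:
            raise ValueError("solvent control (0 uM) measurements are missing")
        ref = float(control["value"].mean())
        treated = endpoint[endpoint["concentration_uM"] > 0.0]
        out = treated[["concentration_uM", "replicate"]].copy()
        out["log2fc"] = log2_fold_change(treated["value"].to_numpy(), ref)
    elif baseline == "initial":
        t0 = profile[profile["time"] == 0.0]
        if t0.empty:
            raise ValueError("initial (time 0) measurements are missing")
        merged = endpoint.merge(
            t0[["concentration_uM", "replicate", "value"]],
            on=["concentration_uM", "replicate"],
            suffixes=("", "_t0"),
        )
        merged = merged[merged["concentration_uM"] > 0.0]
        out = merged[["concentration_uM", "replicate"]].copy()
        out["log2fc"] = log2_fold_change(
            merged["value"].to_numpy(), merged["value_t0"].to_numpy()
        )
    else:
        raise ValueError(f"unknown baseline {baseline!r}")
    return out.sort_values(["concentration_uM", "replicate"]).reset_index(drop=True)


def profile_log2fc(
    profile: pd.DataFrame,
    baseline: str = "solvent_control",
    endpoint_time: float | None = None,
) -> pd.DataFrame:
    """Mean ± SD log2 fold change per concentration for one strain."""
    fcs = replicate_log2fc(profile, baseline=baseline, endpoint_time=endpoint_time)
    summary = (
        fcs.groupby("concentration_uM")["log2fc"]
        .agg(mean_log2fc="mean", sd_log2fc="std", n="count")
        .reset_index()
    )
    return summary


def classify_strain(
    replicate_fcs: pd.DataFrame, rule: ClassificationRule = ClassificationRule()
) -> tuple[str, float, float]:
    """Label one strain promoted/inhibited from its replicate log2FCs.

    Returns ``(label, decision_score, p_value)`` where the decision score is
    the mean log2FC over the rule's decision concentrations.  With zero
    replicate variance the t test degenerates; a nonzero mean is then taken
    as decisive.
    """
    missing = [
        c for c in rule.decision_concentrations
        if c not in set(replicate_fcs["concentration_uM"])
    ]
    if missing:
        raise ValueError(f"log2FC summary lacks decision concentrations {missing}")

    decision = replicate_fcs[
        replicate_fcs["concentration_uM"].isin(rule.decision_concentrations)
    ]["log2fc"].to_numpy()
    mean_dec = float(decision.mean())
    if decision.std(ddof=1) == 0 or len(decision) < 2:
        pvalue = 0.0 if mean_dec != 0.0 else 1.0
    else:
        pvalue = float(sps.ttest_1samp(decision, 0.0).pvalue)

    if pvalue < rule.alpha and mean_dec != 0.0:
        label = PROMOTED if mean_dec > 0 else INHIBITED
    else:
        grand = float(replicate_fcs["log2fc"].mean())
        label = PROMOTED if grand > 0 else INHIBITED
    return label, mean_dec, pvalue


def classify_panel(
    dose: pd.DataFrame,
    catalog: StrainCatalog,
    rule: ClassificationRule = ClassificationRule(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every strain in a dose–response table.

    Returns ``(classification, contingency)``:

    * ``classification`` — one row per strain with ``strain, kingdom, phylum,
      response, label, decision_log2fc, p_value``; labels are TPB/TNB for
      bacteria and TPF/TNF for fungi and partition each kingdom's panel.
    * ``contingency`` — phylum × label strain counts.
    """
    unknown = sorted(set(dose["strain"]) - set(catalog.codes))
    if unknown:
        raise ValueError(f"dose table references unknown strains: {unknown}")

    rows = []
    for strain_code, profile in dose.groupby("strain", sort=False):
        record = catalog.get(strain_code)
        fcs = replicate_log2fc(profile, baseline=rule.baseline)
        response, score, pvalue = classify_strain(fcs, rule)
        rows.append(
            {
                "strain": strain_code,
                "kingdom": record.kingdom,
                "phylum": record.phylum,
                "response": response,
                "label": CLASS_LABELS[(record.kingdom, response)],
                "decision_log2fc": score,
                "p_value": pvalue,
            }
        )
    classification = pd.DataFrame(
        rows,
        columns=["strain", "kingdom", "phylum", "response", "label",
                 "decision_log2fc", "p_value"],
    )
    if classification.empty:
        contingency = pd.DataFrame()
    else:
        contingency = (
            classification.groupby(["phylum", "label"]).size().unstack(fill_value=0)
        )
    return classification, contingency


def log2fc_matrix(
    dose: pd.DataFrame, baseline: str = "solvent_control"
) -> pd.DataFrame:
    """Strain × concentration matrix of mean log2FCs (heatmap-ready)."""
    rows = {}
    for strain_code, profile in dose.groupby("strain", sort=False):
        summary = profile_log2fc(profile, baseline=baseline)
        rows[strain_code] = dict(
            zip(summary["concentration_uM"], summary["mean_log2fc"])
        )
    matrix = pd.DataFrame.from_dict(rows, orient="index").sort_index(axis=1)
    matrix.index.name = "strain"
    return matrix
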