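"""Statistical comparisons and report writers shared across the pipeline.

Rank tests
    Unpaired contrasts use the Wilcoxon rank-sum (Mann–Whitney) form: the
    exact permutation null is enumerated for combined n ≤ 12, and the normal
    approximation with tie correction is used otherwise.  Paired contrasts
    use the Wilcoxon signed-rank test.

ANOVA with posthoc letters
    One-way ANOVA followed by Duncan's multiple range test (studentized-range
    critical values at Duncan's protection levels) or Fisher's LSD, compacted
    into a letter display where groups sharing a letter are not significantly
    different.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


def significance_stars(p: float) -> str:
    """Asterisk convention: * p<0.05, ** p<0.01, *** p<0.001, else 'ns'."""
    if np.isnan(p):
        return "na"
    if not 0 <= p <= 1:
        raise ValueError("p-value outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class GroupComparison:
    """Two-group comparison summary."""

    labels: tuple[str, str]
    n: tuple[int, int]
    means: tuple[float, float]
    sds: tuple[float, float]
    medians: tuple[float, float]
    test: str
    statistic: float
    p_value: float
    stars: str = field(init=False)

    def __post_init__(self) -> None:
        self.stars = significance_stars(self.p_value)


def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided exact rank-sum p by enumerating all group assignments.

    Midranks handle ties; the p-value is the fraction of assignments whose
    rank sum deviates from its null mean at least as much as observed.
    Returns (rank-sum statistic of the first group, p).
    """
    combined = np.concatenate([a, b])
    ranks = sps.rankdata(combined)
    n1, n = len(a), len(combined)
    observed = float(ranks[:n1].sum())
    mu = n1 * (n + 1) / 2.0
    dev = abs(observed - mu)
    count = 0
    total = 0
    for idx in itertools.combinations(range(n), n1):
        w = ranks[list(idx)].sum()
        if abs(w - mu) >= dev - 1e-9:
            count += 1
        total += 1
    return observed, count / total


def rank_test(
    group_a,
    group_b,
    paired: bool = False,
    labels: tuple[str, str] = ("A", "B"),
    exact_max_n: int = 12,
) -> GroupComparison:
    """Two-sided rank test between two groups.

    Unpaired data use the rank-sum (Mann–Whitney) form — exact enumeration
    when the combined sample size is at most ``exact_max_n``, otherwise the
    tie-corrected normal approximation.  Paired data use the Wilcoxon
    signed-rank test and require equal lengths.  Groups too small for any
    inference yield ``p = nan`` with a warning.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("each group needs at least one observation")

    summary = dict(
        labels=labels,
        n=(len(a), len(b)),
        means=(float(a.mean()), float(b.mean())),
        sds=(float(a.std(ddof=1)) if len(a) > 1 else np.nan,
             float(b.std(ddof=1)) if len(b) > 1 else np.nan),
        medians=(float(np.median(a)), float(np.median(b))),
    )

    if paired:
        if len(a) != len(b):
            raise ValueError("paired test requires equal group lengths")
        diffs = a - b
        if np.all(diffs == 0):
            return GroupComparison(
                **summary, test="wilcoxon_signed_rank", statistic=0.0, p_value=1.0
            )
        res = sps.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
        return GroupComparison(
            **summary,
            test="wilcoxon_signed_rank",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
        )

    if len(a) < 2 or len(b) < 2:
        warnings.warn("group too small for rank-sum inference; p set to nan", stacklevel=2)
        return GroupComparison(
            **summary, test="rank_sum", statistic=np.nan, p_value=np.nan
        )

    if len(a) + len(b) <= exact_max_n:
        statistic, p = _exact_rank_sum_p(a, b)
        return GroupComparison(
            **summary, test="rank_sum_exact", statistic=statistic, p_value=p
        )

    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        # degenerate all-identical input: asymptotic form divides by zero
        return GroupComparison(**summary, test="rank_sum", statistic=np.nan, p_value=1.0)
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return GroupComparison(
        **summary, test="rank_sum", statistic=float(res.statistic), p_value=float(res.pvalue)
    )


# ---------------------------------------------------------------------------
# ANOVA + posthoc compact letter display
# ---------------------------------------------------------------------------


def _pairwise_nonsignificance(
    labels: list[str],
    means: dict[str, float],
    nobs: dict[str, int],
    mse: float,
    df_error: int,
    alpha: float,
    method: str,
) -> dict[tuple[str, str], bool]:
    """True where a pair is NOT significantly different."""
    order = sorted(labels, key=lambda g: means[g])
    nonsig: dict[tuple[str, str], bool] = {}
    if method == "lsd":
        tcrit = sps.t.ppf(1 - alpha / 2, df_error)
        for g1, g2 in itertools.combinations(labels, 2):
            se = math.sqrt(mse * (1 / nobs[g1] + 1 / nobs[g2]))
            nonsig[frozenset((g1, g2))] = abs(means[g1] - means[g2]) <= tcrit * se
        return nonsig

    # Duncan's multiple range: step-down over spans of the mean ordering.
    # A window whose range falls below its least significant range shields
    # every pair inside it (declared nonsignificant, not tested further).
    k = len(order)
    n_h = k / sum(1 / nobs[g] for g in order)  # harmonic mean group size
    shielded: set[frozenset] = set()
    for span in range(k, 1, -1):
        alpha_p = 1 - (1 - alpha) ** (span - 1)
        q = sps.studentized_range.ppf(1 - alpha_p, span, df_error)
        least_range = q * math.sqrt(mse / n_h)
        for start in range(0, k - span + 1):
            g_lo, g_hi = order[start], order[start + span - 1]
            if frozenset((g_lo, g_hi)) in shielded:
                continue
            if abs(means[g_hi] - means[g_lo]) <= least_range:
                shielded |= {
                    frozenset((order[i], order[j]))
                    for i in range(start, start + span)
                    for j in range(i + 1, start + span)
                }
    for g1, g2 in itertools.combinations(labels, 2):
        nonsig[frozenset((g1, g2))] = frozenset((g1, g2)) in shielded
    return nonsig


def _letters_from_nonsig(
    labels_by_mean_desc: list[str], nonsig: dict[frozenset, bool]
) -> dict[str, str]:
    """Compact letter display from the nonsignificance relation.

    Maximal cliques of the 'not significantly different' graph become
    letters, ordered by descending group mean.
    """
    k = len(labels_by_mean_desc)
    idx = {g: i for i, g in enumerate(labels_by_mean_desc)}

    def compatible(subset: tuple[str, ...]) -> bool:
        return all(
            nonsig.get(frozenset((g1, g2)), True)
            for g1, g2 in itertools.combinations(subset, 2)
        )

    cliques: list[tuple[str, ...]] = []
    for size in range(k, 0, -1):
        for subset in itertools.combinations(labels_by_mean_desc, size):
            if compatible(subset) and not any(set(subset) <= set(c) for c in cliques):
                cliques.append(subset)
    cliques.sort(key=lambda c: min(idx[g] for g in c))

    letters = {g: "" for g in labels_by_mean_desc}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for i, clique in enumerate(cliques):
        letter = alphabet[i % len(alphabet)] * (i // len(alphabet) + 1)
        for g in clique:
            letters[g] += letter
    return {g: "".join(sorted(v)) for g, v in letters.items()}


def anova_letters(
    groups: dict[str, "np.ndarray | list[float]"],
    alpha: float = 0.05,
    posthoc: str = "duncan",
) -> pd.DataFrame:
    """One-way ANOVA with a posthoc compact letter display.

    ``groups`` maps label -> replicate values (≥ 2 groups, each n ≥ 2).
    Groups sharing a letter are not significantly different at ``alpha``
    under Duncan's multiple range test (default) or Fisher's LSD.  When every
    group has zero within-group variance the letters fall back to the exact
    ordering of the means, with a warning.

    Returns a DataFrame (group, n, mean, sd, letter) sorted by descending
    mean, with ANOVA results in ``.attrs``.
    """
    if posthoc not in ("duncan", "lsd"):
        raise ValueError(f"unknown posthoc method {posthoc!r}")
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    if any(len(v) < 2 for v in arrays.values()):
        raise ValueError("each group needs at least two observations")

    labels = list(arrays)
    means = {g: float(v.mean()) for g, v in arrays.items()}
    sds = {g: float(v.std(ddof=1)) for g, v in arrays.items()}
    nobs = {g: len(v) for g, v in arrays.items()}
    order_desc = sorted(labels, key=lambda g: -means[g])

    n_total = sum(nobs.values())
    df_error = n_total - len(labels)
    sse = sum(((v - means[g]) ** 2).sum() for g, v in arrays.items())
    mse = sse / df_error if df_error > 0 else 0.0

    if mse == 0.0:
        warnings.warn(
            "zero within-group variance everywhere; letters assigned by exact "
            "ordering of the means",
            stacklevel=2,
        )
        distinct = sorted({means[g] for g in labels}, reverse=True)
        alphabet = "abcdefghijklmnopqrstuvwxyz"
        letters = {
            g: alphabet[distinct.index(means[g]) % len(alphabet)] for g in labels
        }
        f_stat, p_value = np.inf if len(distinct) > 1 else np.nan, (
            0.0 if len(distinct) > 1 else np.nan
        )
    else:
        f_stat, p_value = (
            float(x) for x in sps.f_oneway(*(arrays[g] for g in labels))
        )
        nonsig = _pairwise_nonsignificance(
            labels, means, nobs, mse, df_error, alpha, posthoc
        )
        letters = _letters_from_nonsig(order_desc, nonsig)

    out = pd.DataFrame(
        {
            "group": order_desc,
            "n": [nobs[g] for g in order_desc],
            "mean": [means[g] for g in order_desc],
            "sd": [sds[g] for g in order_desc],
            "letter": [letters[g] for g in order_desc],
        }
    )
    out.attrs["anova_F"] = f_stat
    out.attrs["anova_p"] = p_value
    out.attrs["posthoc"] = posthoc
    out.attrs["alpha"] = alpha
    return out


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------


def write_heatmap_matrix(matrix: pd.DataFrame, path: str) -> None:
    """Write a labelled rectangular matrix as CSV (heatmap-ready)."""
    matrix.to_csv(path)


def write_report(sections: dict[str, pd.DataFrame], path: str) -> None:
    """Write a markdown report with one table section per pipeline output."""
    lines = ["# Screening pipeline report", ""]
    for title, table in sections.items():
        lines.append(f"## {title}")
        lines.append("")
        lines.append("```")
        lines.append(table.to_string(index=False) if not table.empty else "(empty)")
        lines.append("```")
        lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
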