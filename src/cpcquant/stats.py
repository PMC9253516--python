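"""Group-comparison statistics and phenotype scoring.

The rank-based route (Kruskal-Wallis with Dunn's post hoc z tests) serves
the rescue-experiment intensity tables; the parametric route (one-way ANOVA
with Dunnett's many-to-one comparisons) serves the tethering ratios;
Pearson chi-square on 2x2 collapses serves phenotype rates; and chromosome
alignment is scored into the three standard categories.  Standard test
machinery is delegated to scipy/statsmodels; Dunn's z statistics (not
available there) are computed from pooled ranks with tie correction.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "kruskal_dunn",
    "anova_dunnett",
    "rate_test",
    "classify_alignment",
    "significance_stars",
]

_STAR_LEVELS = [(1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")]


def significance_stars(p: float) -> str:
    """Render a p-value with the usual asterisk convention (ns above 0.05)."""
    for level, stars in _STAR_LEVELS:
        if p <= level:
            return stars
    return "ns"


def _split_groups(table: pd.DataFrame):
    if not {"value", "group"} <= set(table.columns):
        raise ValueError("table needs 'value' and 'group' columns")
    if table["value"].isna().any():
        raise ValueError("missing values must be filtered before comparison")
    groups = list(dict.fromkeys(table["group"]))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    samples = {g: table.loc[table["group"] == g, "value"].to_numpy(float) for g in groups}
    for g, v in samples.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    return groups, samples


def kruskal_dunn(table: pd.DataFrame, adjust: str = "holm"):
    """Kruskal-Wallis H across groups plus Dunn's pairwise post hoc tests.

    Dunn's z for groups i, j compares mean pooled ranks,

        z = (Rbar_i - Rbar_j) / sqrt(A (1/n_i + 1/n_j)),
        A = N(N+1)/12 - sum(t^3 - t) / (12 (N - 1)),

    with t the tie-group sizes; two-sided normal p-values are adjusted by
    ``adjust`` (holm, bonferroni or sidak).  All-identical data returns
    H = 0 and p = 1 with no rejections.

    Returns (H, p_global, DataFrame of pairwise comparisons with stars).
    """
    groups, samples = _split_groups(table)
    values = np.concatenate([samples[g] for g in groups])
    if np.ptp(values) == 0:
        pairs = pd.DataFrame(
            [
                {"group1": a, "group2": b, "z": 0.0, "p_unadj": 1.0, "p_adj": 1.0, "stars": "ns"}
                for a, b in combinations(groups, 2)
            ]
        )
        return 0.0, 1.0, pairs

    H, p_global = sps.kruskal(*[samples[g] for g in groups])

    ranks = sps.rankdata(values)
    N = len(values)
    sizes = {g: len(samples[g]) for g in groups}
    mean_ranks = {}
    start = 0
    for g in groups:
        n = sizes[g]
        mean_ranks[g] = ranks[start : start + n].mean()
        start += n
    _, counts = np.unique(values, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (N - 1))
    A = N * (N + 1) / 12.0 - tie_term

    rows = []
    for a, b in combinations(groups, 2):
        se = np.sqrt(A * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group1": a, "group2": b, "z": z, "p_unadj": p})
    pairs = pd.DataFrame(rows)
    pairs["p_adj"] = multipletests(pairs["p_unadj"], method=adjust)[1]
    pairs["stars"] = pairs["p_adj"].map(significance_stars)
    return float(H), float(p_global), pairs


def anova_dunnett(table: pd.DataFrame, control: str):
    """One-way ANOVA F plus Dunnett's many-to-one comparisons vs a control.

    Returns (F, p_global, DataFrame with one row per treatment group).
    """
    groups, samples = _split_groups(table)
    if control not in samples:
        raise ValueError(f"control label {control!r} absent from table")
    treatments = [g for g in groups if g != control]
    F, p_global = sps.f_oneway(*[samples[g] for g in groups])
    res = sps.dunnett(*[samples[g] for g in treatments], control=samples[control])
    out = pd.DataFrame(
        {
            "group": treatments,
            "control": control,
            "statistic": res.statistic,
            "p_adj": res.pvalue,
        }
    )
    out["stars"] = out["p_adj"].map(significance_stars)
    return float(F), float(p_global), out


def rate_test(counts, group_labels, control: str) -> pd.DataFrame:
    """Pearson chi-square of each group against the control on 2x2 collapses.

    ``counts`` is a 2 x k contingency table, rows = phenotype present/absent,
    columns = groups.  Each non-control column is tested against the control
    column with the (uncorrected) Pearson chi-square.
    """
    tab = np.asarray(counts, dtype=float)
    if tab.shape[0] != 2:
        raise ValueError("counts must be a 2 x k table (phenotype x group)")
    if tab.shape[1] != len(group_labels):
        raise ValueError("one label per column required")
    if control not in group_labels:
        raise ValueError(f"control label {control!r} absent")
    ci = list(group_labels).index(control)
    rows = []
    for j, g in enumerate(group_labels):
        if j == ci:
            continue
        sub = np.array([tab[:, ci], tab[:, j]])
        if (sub.sum(axis=0) == 0).any() or (sub.sum(axis=1) == 0).any():
            raise ValueError(f"zero margin in {control!r} vs {g!r} table")
        chi2, p, _, expected = sps.chi2_contingency(sub, correction=False)
        if (expected <= 0).any():
            raise ValueError("expected counts must be positive")
        rows.append({"group": g, "control": control, "chi2": float(chi2), "p": float(p),
                     "stars": significance_stars(p)})
    return pd.DataFrame(rows)


def classify_alignment(n_misaligned: int) -> str:
    """Score chromosome alignment: 0 -> complete; 1-3 -> mild; >3 -> severe."""
    if int(n_misaligned) != n_misaligned or n_misaligned < 0:
        raise ValueError("n_misaligned must be a nonnegative integer")
    n = int(n_misaligned)
    if n == 0:
        return "complete"
    if n <= 3:
        return "mild"
    return "severe"
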