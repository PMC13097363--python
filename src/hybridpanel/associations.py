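"""Statistical layer: grouped correlations with BH correction, group
comparisons (ANOVA + Tukey HSD with compact letter display, rank-sum),
domestication cross-type labelling, ploidy binning, and the no-intercept
heterosis regression with standardized coefficients."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "bh_adjust",
    "significance_stars",
    "grouped_correlation",
    "GroupComparison",
    "compare_groups",
    "compact_letter_display",
    "label_cross_type",
    "fit_heterosis_model",
    "bin_ploidy",
]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sorted raw p are multiplied by m/rank and a running minimum from the
    largest p downward enforces monotonicity; results are capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def grouped_correlation(
    records: pd.DataFrame,
    group_keys: list[str],
    x: str,
    y: str,
    method: str = "pearson",
    min_n: int = 3,
) -> pd.DataFrame:
    """Per-group correlation between two columns with BH-adjusted p-values.

    Groups smaller than ``min_n`` or with zero variance in x or y are
    flagged (``note`` column) and excluded from the BH family. All
    remaining cells of the grid form one adjustment family.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    rows = []
    for keys, grp in records.groupby(group_keys, sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        sub = grp[[x, y]].dropna()
        row = dict(zip(group_keys, keys))
        row.update({"x_name": x, "y_name": y, "n": len(sub)})
        if len(sub) < min_n:
            row.update(r=np.nan, p_raw=np.nan, note="too_few")
        elif sub[x].nunique() < 2 or sub[y].nunique() < 2:
            row.update(r=np.nan, p_raw=np.nan, note="zero_variance")
        else:
            res = corr(sub[x], sub[y])
            row.update(r=float(res.statistic), p_raw=float(res.pvalue), note="")
        rows.append(row)
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    defined = out["p_raw"].notna()
    if defined.any():
        out.loc[defined, "p_adj"] = bh_adjust(out.loc[defined, "p_raw"].to_numpy())
    out["flag"] = out["p_adj"].map(lambda q: significance_stars(q) if np.isfinite(q) else "")
    return out


def compact_letter_display(
    groups: list[str], significant: set[tuple[str, str]]
) -> dict[str, str]:
    """Compact letter display: groups sharing a letter are not significantly
    different. ``significant`` holds unordered pairs that differ.

    Insertion algorithm: each group joins every letter class containing no
    group it differs from; a new class is opened when none admits it.
    """
    sig = {tuple(sorted(p)) for p in significant}
    compatible = {
        g: {h for h in groups if h != g and tuple(sorted((g, h))) not in sig}
        for g in groups
    }

    # letter classes are the maximal cliques of the "not different" graph
    # (Bron-Kerbosch; group counts here are small)
    cliques: list[set[str]] = []

    def extend(r: set[str], p: set[str], x: set[str]) -> None:
        if not p and not x:
            cliques.append(r)
            return
        for v in list(p):
            extend(r | {v}, p & compatible[v], x & compatible[v])
            p = p - {v}
            x = x | {v}

    extend(set(), set(groups), set())
    cliques.sort(key=lambda c: min(groups.index(g) for g in c))
    letters = {g: "" for g in groups}
    for letter, cls in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for g in groups:
            if g in cls:
                letters[g] += letter
    return letters


@dataclass
class GroupComparison:
    """Result of a k-group comparison."""

    test: str
    statistic: float
    p_value: float
    pairwise: pd.DataFrame | None  # Tukey HSD table (anova_tukey only)
    letters: dict[str, str] | None
    group_means: dict[str, float]


def compare_groups(values, labels, test: str = "anova_tukey", alpha: float = 0.05) -> GroupComparison:
    """Compare groups of observations.

    ``anova_tukey``: one-way ANOVA F test plus Tukey HSD pairwise adjusted
    p-values and a compact letter display at ``alpha``. ``wilcoxon``:
    two-sided unpaired rank-sum (Mann-Whitney) test for exactly two groups.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels differ in length")
    names = sorted(pd.unique(labels))
    samples = [values[labels == g] for g in names]
    if len(names) < 2 or any(len(s) == 0 for s in samples):
        raise ValueError("need >= 2 non-empty groups")
    means = {g: float(np.mean(s)) for g, s in zip(names, samples)}

    if test == "wilcoxon":
        if len(names) != 2:
            raise ValueError("wilcoxon test needs exactly 2 groups")
        res = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
        return GroupComparison("wilcoxon", float(res.statistic), float(res.pvalue),
                               None, None, means)
    if test != "anova_tukey":
        raise ValueError(f"unknown test {test!r}")
    if any(len(s) < 2 for s in samples):
        raise ValueError("ANOVA needs >= 2 observations per group")
    f_stat, f_p = stats.f_oneway(*samples)
    tukey = stats.tukey_hsd(*samples)
    rows = []
    sig_pairs: set[tuple[str, str]] = set()
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            p = float(tukey.pvalue[i, j])
            rows.append({"group_a": names[i], "group_b": names[j], "p_adj": p})
            if p < alpha:
                sig_pairs.add((names[i], names[j]))
    letters = compact_letter_display(names, sig_pairs)
    return GroupComparison("anova_tukey", float(f_stat), float(f_p),
                           pd.DataFrame(rows), letters, means)


def label_cross_type(metadata: pd.DataFrame) -> pd.Series:
    """DD/DW/WW cross-type label per hybrid, from parental domestication.

    Mating-competent parents inherit the label of the wild-type strain they
    derive from. Hybrids with a missing parental label get NA.
    """
    idx = metadata.set_index("strain_id")
    dom = idx["domestication"].to_dict()
    wt_of = idx.loc[idx["role"] == "mating_competent", "parent_a"].to_dict()

    def status(strain: str) -> str | None:
        d = dom.get(strain)
        if d in ("domesticated", "wild"):
            return d
        wt = wt_of.get(strain)
        d = dom.get(wt)
        return d if d in ("domesticated", "wild") else None

    out = {}
    for row in metadata.itertuples():
        if row.role != "hybrid":
            continue
        da, db = status(row.parent_a), status(row.parent_b)
        if da is None or db is None:
            out[row.strain_id] = pd.NA
        else:
            n_dom = (da == "domesticated") + (db == "domesticated")
            out[row.strain_id] = {2: "DD", 1: "DW", 0: "WW"}[n_dom]
    return pd.Series(out, name="cross_type")


def fit_heterosis_model(
    records: pd.DataFrame,
    g_col: str = "ibs_distance",
    p_col: str = "ploidy_measured",
    bph_col: str = "bph",
    medium_col: str = "medium",
    bph_floor: float = 1e-9,
    cond_max: float = 1e8,
) -> pd.DataFrame:
    """Per-medium no-intercept OLS of log1p(BPH) on genetic distance and ploidy.

    The response is log1p(BPH), sign-preserving on (-1, inf); BPH values at
    exactly -1 are floored at ``-1 + bph_floor`` and flagged in the
    ``n_floored`` column. Standardized beta_j = b_j * sd(x_j) / sd(y) with
    ordinary mean-centered standard deviations; the no-intercept R^2 is
    1 - RSS / sum(y^2). p-values are two-sided t tests with n - 2 df.
    """
    out = []
    for medium, grp in records.groupby(medium_col, sort=True):
        sub = grp[[g_col, p_col, bph_col]].dropna()
        if len(sub) < 3:
            continue
        bph = sub[bph_col].to_numpy(dtype=float)
        if np.any(bph < -1):
            raise ValueError(f"{medium}: BPH below -1")
        floored = bph <= -1.0
        bph = np.where(floored, -1.0 + bph_floor, bph)
        y = np.log1p(bph)
        X = sub[[g_col, p_col]].to_numpy(dtype=float)
        cond = np.linalg.cond(X)
        if cond > cond_max:
            raise ValueError(
                f"{medium}: predictors nearly collinear (condition number {cond:.3g})"
            )
        b, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ b
        rss = float(resid @ resid)
        n, k = X.shape
        sigma2 = rss / (n - k)
        cov = sigma2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))
        tvals = b / se
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df=n - k)
        sd_y = float(np.std(y, ddof=1))
        beta_std = b * X.std(axis=0, ddof=1) / sd_y if sd_y > 0 else np.full(k, np.nan)
        tot = float(y @ y)
        out.append(
            {
                "medium": medium,
                "n": n,
                "coef_G": float(b[0]),
                "coef_P": float(b[1]),
                "beta_std_G": float(beta_std[0]),
                "beta_std_P": float(beta_std[1]),
                "p_G": float(pvals[0]),
                "p_P": float(pvals[1]),
                "r_squared": 1.0 - rss / tot if tot > 0 else np.nan,
                "n_floored": int(floored.sum()),
            }
        )
    return pd.DataFrame(out)


def bin_ploidy(ploidies, edges: tuple[float, ...] = (2.5, 3.5, 4.5)) -> pd.Series:
    """Bin ploidy values into right-closed intervals at the given edges.

    Default edges (2.5, 3.5, 4.5) yield bins "<=2.5", "(2.5,3.5]",
    "(3.5,4.5]", ">4.5"; a value exactly on an edge falls in the lower bin.
    """
    edges = tuple(edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError(f"bin edges not strictly increasing: {edges}")
    labels = [f"<={edges[0]:g}"]
    labels += [f"({a:g},{b:g}]" for a, b in zip(edges, edges[1:])]
    labels += [f">{edges[-1]:g}"]
    cut = pd.cut(
        np.asarray(ploidies, dtype=float),
        bins=[-np.inf, *edges, np.inf],
        right=True,
        labels=labels,
    )
    return pd.Series(cut)
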