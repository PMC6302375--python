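"""Per-metabolite differential-abundance screening across regions.

One-way ANOVA with Benjamini-Hochberg FDR control selects metabolites
whose concentration differs among groups; pairwise Welch t-tests with
log2 fold changes then resolve which regions drive each difference, and
region signatures count the metabolites characteristically high or low
in each region.

Location tests (ANOVA, Welch) operate on log2-transformed
concentrations by default — MS-derived concentrations are approximately
lognormal, and the transform restores the tests' nominal calibration —
while log2 fold changes are always ratios of raw group means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .profiles import MetaboliteProfile, ProfileError

__all__ = [
    "one_way_anova",
    "bh_fdr",
    "welch_t",
    "log2fc",
    "anova_table",
    "significant_metabolites",
    "pairwise_table",
    "region_signature",
    "RegionSignature",
]


def _split_groups(values: np.ndarray, groups) -> list[np.ndarray]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups.tolist()))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    out = []
    for lab in labels:
        sub = values[..., groups == lab]
        if sub.shape[-1] < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 samples")
        out.append(sub)
    return out


def one_way_anova(values, groups) -> tuple[float, float]:
    """Classical fixed-effects one-way ANOVA.

    F = MS_between / MS_within with (g-1, n-g) degrees of freedom;
    returns ``(F, p)``.  Raises if any group has fewer than 2 samples or
    all values are identical (F undefined).
    """
    parts = _split_groups(values, groups)
    if np.ptp(np.concatenate(parts, axis=-1)) == 0:
        raise ValueError("all values identical: F statistic undefined")
    res = stats.f_oneway(*parts)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1, returned in the
    input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1-D vector")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's two-sample t-test with Satterthwaite degrees of freedom.

    Returns ``(t, df, p)`` with a two-sided p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        raise ValueError("both samples have zero variance")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def log2fc(x, y) -> float:
    """log2 of the ratio of sample means (raw concentration scale)."""
    mx = float(np.mean(x))
    my = float(np.mean(y))
    if mx <= 0 or my <= 0:
        raise ValueError("log2 fold change requires positive group means")
    return float(np.log2(mx / my))


def _test_values(profile: MetaboliteProfile, log_transform: bool) -> np.ndarray:
    if not log_transform:
        return profile.values
    if np.any(profile.values <= 0):
        raise ProfileError("log transform requires strictly positive concentrations")
    return np.log2(profile.values)


def anova_table(profile: MetaboliteProfile, log_transform: bool = True) -> pd.DataFrame:
    """Per-metabolite ANOVA screen: columns metabolite, F, p, q.

    The BH adjustment runs across all metabolites of the profile.
    """
    values = _test_values(profile, log_transform)
    parts = _split_groups(values, profile.groups)
    res = stats.f_oneway(*parts, axis=-1)
    F = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    bad = ~np.isfinite(p)
    if bad.any():
        names = [profile.metabolite_ids[i] for i in np.flatnonzero(bad)]
        raise ValueError(f"ANOVA undefined (constant values) for: {names}")
    return pd.DataFrame(
        {"metabolite": profile.metabolite_ids, "F": F, "p": p, "q": bh_fdr(p)}
    )


def significant_metabolites(
    profile: MetaboliteProfile,
    q_threshold: float = 0.01,
    log_transform: bool = True,
) -> list[str]:
    """Metabolites passing the ANOVA + BH screen at q < q_threshold."""
    table = anova_table(profile, log_transform=log_transform)
    return table.loc[table["q"] < q_threshold, "metabolite"].tolist()


def pairwise_table(
    profile: MetaboliteProfile,
    metabolites: list[str] | None = None,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Welch t-test + log2 fold change for every (metabolite, group pair).

    Columns: metabolite, group_a, group_b, t, df, p, log2fc.  The t-test
    runs on (log) concentrations; log2fc always on raw group means, with
    a positive value meaning higher in ``group_a``.
    """
    if metabolites is None:
        metabolites = profile.metabolite_ids
    values = _test_values(profile, log_transform)
    raw = profile.values
    labels = profile.group_labels
    cols = {g: profile.group_columns(g) for g in labels}
    index = {m: i for i, m in enumerate(profile.metabolite_ids)}
    records = []
    for m in metabolites:
        i = index[m]
        for a_i, ga in enumerate(labels):
            for gb in labels[a_i + 1 :]:
                t, df, p = welch_t(values[i, cols[ga]], values[i, cols[gb]])
                fc = log2fc(raw[i, cols[ga]], raw[i, cols[gb]])
                records.append((m, ga, gb, t, df, p, fc))
    return pd.DataFrame(
        records, columns=["metabolite", "group_a", "group_b", "t", "df", "p", "log2fc"]
    )


@dataclass
class RegionSignature:
    """Characteristically high / low metabolites per region.

    ``high[g]`` lists the significant metabolites whose concentration is
    elevated in region g relative to every other region (all pairwise
    Welch p < alpha and all log2FC > 0); ``low[g]`` analogously with all
    log2FC < 0.
    """

    high: dict[str, list[str]]
    low: dict[str, list[str]]
    alpha: float
    rule: str

    @property
    def counts(self) -> dict[str, dict[str, int]]:
        return {
            g: {"high": len(self.high[g]), "low": len(self.low[g])}
            for g in self.high
        }


def region_signature(
    profile: MetaboliteProfile,
    significant: list[str],
    alpha: float = 0.05,
    rule: str = "all",
    log_transform: bool = True,
) -> RegionSignature:
    """Count region-characteristic metabolites among the significant set.

    rule="all" (default): a metabolite is characteristic-high for group
    g iff versus EVERY other group the Welch p < alpha and log2FC > 0
    (strictest consistent reading; signatures are region-exclusive).
    rule="any": at least one pairwise comparison significant, and all
    significant comparisons share the sign.
    """
    if rule not in ("all", "any"):
        raise ValueError("rule must be 'all' or 'any'")
    labels = profile.group_labels
    if len(labels) < 3:
        raise ValueError("region signatures need >= 3 groups")
    unknown = set(significant) - set(profile.metabolite_ids)
    if unknown:
        raise ValueError(f"significant metabolites not in profile: {sorted(unknown)}")
    values = _test_values(profile, log_transform)
    raw = profile.values
    cols = {g: profile.group_columns(g) for g in labels}
    index = {m: i for i, m in enumerate(profile.metabolite_ids)}
    high: dict[str, list[str]] = {g: [] for g in labels}
    low: dict[str, list[str]] = {g: [] for g in labels}
    for m in significant:
        i = index[m]
        for g in labels:
            others = [o for o in labels if o != g]
            ps, fcs = [], []
            for o in others:
                _, _, p = welch_t(values[i, cols[g]], values[i, cols[o]])
                ps.append(p)
                fcs.append(log2fc(raw[i, cols[g]], raw[i, cols[o]]))
            ps = np.array(ps)
            fcs = np.array(fcs)
            if rule == "all":
                if np.all(ps < alpha) and np.all(fcs > 0):
                    high[g].append(m)
                elif np.all(ps < alpha) and np.all(fcs < 0):
                    low[g].append(m)
            else:
                sig = ps < alpha
                if sig.any() and np.all(fcs[sig] > 0):
                    high[g].append(m)
                elif sig.any() and np.all(fcs[sig] < 0):
                    low[g].append(m)
    return RegionSignature(high=high, low=low, alpha=alpha, rule=rule)
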