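"""Metabolite concentration profiles: domain types, file I/O, normalization.

A profile is a metabolites x samples matrix of (relative) concentrations
with per-metabolite category annotations and per-sample group labels
(brain regions in the motivating study design).  Every downstream stage
— univariate screening, PCA, and the correlation-network analysis —
consumes this one container.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: Fixed vocabulary of metabolite categories used by the synthetic
#: generator (eight classes of small molecules).
CATEGORIES = (
    "amino acids",
    "carbohydrates",
    "cofactors and vitamins",
    "energy",
    "lipids",
    "nucleotides",
    "peptides",
    "xenobiotics",
)

#: Default group (region) labels: olfactory bulb, frontal cortex,
#: hippocampus, cerebellum.
DEFAULT_GROUPS = ("OB", "FCX", "HC", "CBL")


class ProfileError(ValueError):
    """Invalid profile content (duplicates, non-finite values, bad shapes)."""


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ProfileError(f"duplicate {what} ID: {x!r}")
        seen.add(x)


@dataclass
class MetaboliteProfile:
    """Metabolites x samples concentration matrix with annotations.

    Parameters
    ----------
    metabolite_ids : list of str
        Unique row identifiers.
    categories : list of str
        Per-metabolite category label (same length as ``metabolite_ids``).
    sample_ids : list of str
        Unique column identifiers.
    groups : list of str
        Per-sample group label (same length as ``sample_ids``).
    values : ndarray of shape (n_metabolites, n_samples)
        Strictly finite concentrations in arbitrary units.
    """

    metabolite_ids: list[str]
    categories: list[str]
    sample_ids: list[str]
    groups: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.metabolite_ids = list(self.metabolite_ids)
        self.categories = list(self.categories)
        self.sample_ids = list(self.sample_ids)
        self.groups = list(self.groups)
        self.values = np.asarray(self.values, dtype=float)
        if not self.metabolite_ids:
            raise ProfileError("profile has no metabolites")
        if not self.sample_ids:
            raise ProfileError("profile has no samples")
        _check_unique(self.metabolite_ids, "metabolite")
        _check_unique(self.sample_ids, "sample")
        if len(self.categories) != len(self.metabolite_ids):
            raise ProfileError("categories length does not match metabolite_ids")
        if len(self.groups) != len(self.sample_ids):
            raise ProfileError("groups length does not match sample_ids")
        if any(not g for g in self.groups):
            raise ProfileError("every sample needs a non-empty group label")
        if self.values.shape != (len(self.metabolite_ids), len(self.sample_ids)):
            raise ProfileError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.metabolite_ids)}, {len(self.sample_ids)})"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ProfileError(
                f"non-finite value at metabolite {self.metabolite_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def group_labels(self) -> list[str]:
        """Distinct group labels in order of first appearance."""
        return list(dict.fromkeys(self.groups))

    def group_columns(self, group: str) -> np.ndarray:
        """Column indices of the samples belonging to ``group``."""
        idx = np.array([j for j, g in enumerate(self.groups) if g == group], dtype=int)
        if idx.size == 0:
            raise ProfileError(f"unknown group {group!r}")
        return idx

    def row(self, metabolite_id: str) -> np.ndarray:
        try:
            i = self.metabolite_ids.index(metabolite_id)
        except ValueError:
            raise ProfileError(f"unknown metabolite {metabolite_id!r}") from None
        return self.values[i]

    def subset(self, metabolite_ids: list[str]) -> "MetaboliteProfile":
        """Row-subset preserving the requested order."""
        index = {m: i for i, m in enumerate(self.metabolite_ids)}
        rows = [index[m] for m in metabolite_ids]  # KeyError -> caller bug
        return replace(
            self,
            metabolite_ids=list(metabolite_ids),
            categories=[self.categories[i] for i in rows],
            values=self.values[rows],
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy wide table: metabolite_id, category, one column per sample."""
        df = pd.DataFrame(self.values, columns=self.sample_ids)
        df.insert(0, "category", self.categories)
        df.insert(0, "metabolite_id", self.metabolite_ids)
        return df


@dataclass
class NormalizedProfile(MetaboliteProfile):
    """A profile carrying a normalization provenance tag."""

    normalization_method: str = "none"

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.normalization_method not in ("studentized_residual", "zscore", "none"):
            raise ProfileError(
                f"unknown normalization method {self.normalization_method!r}"
            )


# ---------------------------------------------------------------------------
# File I/O
#
# Dialect: TSV by default (CSV available), UTF-8, "." decimal separator.
# The concentration matrix has columns [metabolite_id, category, <samples...>];
# sample -> group lives in a companion annotation table with columns
# [sample_id, group].
# ---------------------------------------------------------------------------

_SEP = {"tsv": "\t", "csv": ","}


def read_profile(path, annotations, format: str = "tsv") -> MetaboliteProfile:
    """Read a profile matrix plus its sample-annotation table.

    Parameters
    ----------
    path : path-like
        Concentration matrix file (header = metabolite_id, category, samples).
    annotations : path-like
        Sample annotation table with columns ``sample_id`` and ``group``.
    format : {"tsv", "csv"}
    """
    sep = _SEP[format]
    df = pd.read_csv(path, sep=sep, dtype={"metabolite_id": str, "category": str})
    if "metabolite_id" not in df.columns or "category" not in df.columns:
        raise ProfileError(f"{path}: expected 'metabolite_id' and 'category' columns")
    sample_ids = [c for c in df.columns if c not in ("metabolite_id", "category")]
    ann = pd.read_csv(annotations, sep=sep, dtype=str)
    if "sample_id" not in ann.columns or "group" not in ann.columns:
        raise ProfileError(f"{annotations}: expected 'sample_id' and 'group' columns")
    group_of = dict(zip(ann["sample_id"], ann["group"]))
    missing = [s for s in sample_ids if s not in group_of or not group_of[s]]
    if missing:
        raise ProfileError(f"samples lacking a group annotation: {missing}")
    raw = df[sample_ids]
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise ProfileError(
            f"non-numeric cell at row {df['metabolite_id'].iloc[i]!r}, "
            f"column {sample_ids[j]!r}"
        )
    return MetaboliteProfile(
        metabolite_ids=df["metabolite_id"].tolist(),
        categories=df["category"].tolist(),
        sample_ids=sample_ids,
        groups=[group_of[s] for s in sample_ids],
        values=numeric.to_numpy(dtype=float),
    )


def write_profile(profile: MetaboliteProfile, path, annotations, format: str = "tsv") -> None:
    """Write a profile (and its sample annotations) so that
    :func:`read_profile` parses it back losslessly (values to 1e-12)."""
    sep = _SEP[format]
    profile.to_frame().to_csv(path, sep=sep, index=False, float_format="%.17g")
    pd.DataFrame(
        {"sample_id": profile.sample_ids, "group": profile.groups}
    ).to_csv(annotations, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def _row_stats(profile: MetaboliteProfile):
    mean = profile.values.mean(axis=1, keepdims=True)
    sd = profile.values.std(axis=1, ddof=1, keepdims=True)
    constant = np.flatnonzero(sd[:, 0] == 0)
    if constant.size:
        names = [profile.metabolite_ids[i] for i in constant]
        raise ProfileError(f"constant metabolite rows (zero variance): {names}")
    return mean, sd


def normalize_zscore(profile: MetaboliteProfile) -> NormalizedProfile:
    """Per-metabolite z-score across all samples: z = (x - mean) / sd (ddof=1).

    Each output row has mean 0 and sample standard deviation 1.
    """
    mean, sd = _row_stats(profile)
    return NormalizedProfile(
        metabolite_ids=profile.metabolite_ids,
        categories=profile.categories,
        sample_ids=profile.sample_ids,
        groups=profile.groups,
        values=(profile.values - mean) / sd,
        normalization_method="zscore",
    )


def normalize_studentized(profile: MetaboliteProfile) -> NormalizedProfile:
    """Internally studentized residuals of the per-metabolite mean model.

    r_i = (x_i - mean) / (s * sqrt(1 - 1/n)) with s the sample SD; this is
    the z-score scaled by 1/sqrt(1 - 1/n).  Requires n >= 3 samples.
    """
    n = profile.n_samples
    if n < 3:
        raise ProfileError("studentized normalization needs >= 3 samples")
    mean, sd = _row_stats(profile)
    scale = sd * math.sqrt(1.0 - 1.0 / n)
    return NormalizedProfile(
        metabolite_ids=profile.metabolite_ids,
        categories=profile.categories,
        sample_ids=profile.sample_ids,
        groups=profile.groups,
        values=(profile.values - mean) / scale,
        normalization_method="studentized_residual",
    )


def group_mean_variance(profile: MetaboliteProfile) -> pd.DataFrame:
    """Per-(metabolite, group) mean and within-group variance (ddof=1).

    The mean-variance table summarizes within-group measurement spread,
    one row per metabolite per group.
    """
    records = []
    for group in profile.group_labels:
        cols = profile.group_columns(group)
        if cols.size < 2:
            raise ProfileError(f"group {group!r} has fewer than 2 samples")
        sub = profile.values[:, cols]
        means = sub.mean(axis=1)
        variances = sub.var(axis=1, ddof=1)
        for m, mu, var in zip(profile.metabolite_ids, means, variances):
            records.append((m, group, mu, var))
    return pd.DataFrame(records, columns=["metabolite", "group", "mean", "variance"])
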