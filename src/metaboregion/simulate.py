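"""Synthetic region-structured metabolomics data with planted ground truth.

The generator emulates a four-region brain metabolome study design:
215 metabolites over 8 categories, 4 regions x 6 replicates, a subset of
metabolites with region effects, and a handful of planted co-varying
metabolite modules (each larger than 10 members) on a lognormal noise
background.

Model (log-concentration scale), drawn in a fixed stream order
(categories -> baselines -> region effects -> module factors -> noise):

    x[m, s] = mu_m + delta[m, g(s)] + module term + noise term

* Background metabolite:  noise term = noise_sd * eps,  eps ~ N(0, 1).
* Module member of module j with loading lambda:
      sqrt(lambda) * f[j, s]  +  sqrt(1 - lambda) * noise_sd * eps
  with a per-module, per-sample latent factor f ~ N(0, 1).  At
  noise_sd = 1 the within-module correlation of log-values equals
  lambda exactly, so the loading directly dials module tightness.
* Region effect: each affected metabolite receives a contrast — one
  region shifted by +effect_size and a second by -effect_size on the
  log scale — the "characteristically high / low in a region" pattern.

Concentrations are emitted as exp(x), hence strictly positive and
lognormal.  A single integer seed drives one generator stream, so equal
seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .profiles import CATEGORIES, DEFAULT_GROUPS, MetaboliteProfile

__all__ = [
    "SyntheticConfig",
    "SyntheticGroundTruth",
    "generate_dataset",
    "recovery_score",
]


def _default_category_proportions() -> dict[str, float]:
    # Lipids and amino acids jointly predominate; the remaining six
    # categories share the rest equally.
    props = {"lipids": 0.35, "amino acids": 0.25}
    rest = (1.0 - 0.60) / 6.0
    for c in CATEGORIES:
        props.setdefault(c, rest)
    return props


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study design.

    Defaults reproduce the emulated design: 215 metabolites, 4 groups of
    6 replicates, 70 region-affected metabolites, and 5 planted modules
    of sizes 12, 12, 12, 12, 13 (61 metabolites in modules).
    """

    n_metabolites: int = 215
    groups: Sequence[str] = DEFAULT_GROUPS
    replicates_per_group: int = 6
    category_proportions: Mapping[str, float] = field(
        default_factory=_default_category_proportions
    )
    n_affected: int = 70
    effect_size: float = 1.0  # additive log-scale shift, in noise-SD units
    n_modules: int = 5
    module_sizes: Sequence[int] = (12, 12, 12, 12, 13)
    module_loading: float = 0.8  # within-module log-correlation at noise_sd=1
    noise_sd: float = 1.0
    baseline_log_mean_range: tuple[float, float] = (0.0, 4.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_metabolites < 1:
            raise ValueError("n_metabolites must be positive")
        if len(self.groups) < 2:
            raise ValueError("need at least 2 groups")
        if self.replicates_per_group < 2:
            raise ValueError("need at least 2 replicates per group")
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes length must equal n_modules")
        for sz in self.module_sizes:
            if sz <= 10:
                raise ValueError(f"module size {sz} violates the >10 rule")
        if sum(self.module_sizes) > self.n_metabolites:
            raise ValueError("module sizes sum exceeds n_metabolites")
        if not 0.0 <= self.module_loading <= 1.0:
            raise ValueError("module_loading must lie in [0, 1]")
        if self.n_affected < 0 or self.n_affected > self.n_metabolites:
            raise ValueError("n_affected must lie in [0, n_metabolites]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        total = sum(self.category_proportions.get(c, 0.0) for c in CATEGORIES)
        if abs(total - 1.0) > 1e-8:
            raise ValueError("category proportions must sum to 1 over the vocabulary")

    @property
    def n_samples(self) -> int:
        return len(self.groups) * self.replicates_per_group


@dataclass
class SyntheticGroundTruth:
    """Planted structure: the oracle for recovery tests.

    ``module_membership`` maps every metabolite ID to its planted module
    name or ``None``; ``affected_table`` has one row per planted
    (metabolite, group, shift).
    """

    module_membership: dict[str, str | None]
    affected_table: pd.DataFrame
    seed: int
    config: SyntheticConfig

    def module_members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for m, lab in self.module_membership.items():
            if lab is not None:
                out.setdefault(lab, []).append(m)
        return out

    def affected_metabolites(self) -> list[str]:
        return list(dict.fromkeys(self.affected_table["metabolite"]))


def _category_counts(config: SyntheticConfig) -> list[int]:
    """Largest-remainder apportionment of metabolites to categories."""
    props = [config.category_proportions.get(c, 0.0) for c in CATEGORIES]
    exact = [p * config.n_metabolites for p in props]
    counts = [int(np.floor(e)) for e in exact]
    short = config.n_metabolites - sum(counts)
    remainders = sorted(
        range(len(CATEGORIES)), key=lambda i: exact[i] - counts[i], reverse=True
    )
    for i in remainders[:short]:
        counts[i] += 1
    return counts


def generate_dataset(
    config: SyntheticConfig | None = None,
) -> tuple[MetaboliteProfile, SyntheticGroundTruth]:
    """Generate a profile and its planted ground truth.

    Module members occupy the leading rows; region-affected metabolites
    are drawn disjointly from module members so the network and
    univariate screens probe separate planted structure.
    """
    if config is None:
        config = SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_met = config.n_metabolites
    n_samp = config.n_samples
    width = max(3, len(str(n_met)))
    met_ids = [f"met_{i + 1:0{width}d}" for i in range(n_met)]
    sample_ids = [
        f"{g}_{r + 1}" for g in config.groups for r in range(config.replicates_per_group)
    ]
    group_of_sample = np.repeat(np.arange(len(config.groups)), config.replicates_per_group)

    # stream order: categories -> baselines -> effects -> factors -> noise
    counts = _category_counts(config)
    category_pool = np.repeat(np.arange(len(CATEGORIES)), counts)
    categories = [CATEGORIES[i] for i in rng.permutation(category_pool)]

    lo, hi = config.baseline_log_mean_range
    mu = rng.uniform(lo, hi, size=n_met)

    # planted region effects: a +e/-e contrast between two regions
    membership = np.full(n_met, -1, dtype=int)
    idx = 0
    for j, sz in enumerate(config.module_sizes):
        membership[idx : idx + sz] = j
        idx += sz
    in_module = idx
    if config.n_affected > n_met - in_module:
        raise ValueError(
            "n_affected exceeds the metabolites left outside planted modules"
        )
    affected_rows = np.arange(in_module, in_module + config.n_affected)
    delta = np.zeros((n_met, len(config.groups)))
    affected_records = []
    for a in affected_rows:
        up, down = rng.choice(len(config.groups), size=2, replace=False)
        delta[a, up] = config.effect_size
        delta[a, down] = -config.effect_size
        affected_records.append((met_ids[a], config.groups[up], config.effect_size))
        affected_records.append((met_ids[a], config.groups[down], -config.effect_size))

    factors = rng.standard_normal((max(config.n_modules, 1), n_samp))
    noise = rng.standard_normal((n_met, n_samp))

    lam = config.module_loading
    x = mu[:, None] + delta[:, group_of_sample]
    is_member = membership >= 0
    x[~is_member] += config.noise_sd * noise[~is_member]
    if is_member.any():
        x[is_member] += (
            np.sqrt(lam) * factors[membership[is_member]]
            + np.sqrt(1.0 - lam) * config.noise_sd * noise[is_member]
        )

    profile = MetaboliteProfile(
        metabolite_ids=met_ids,
        categories=categories,
        sample_ids=sample_ids,
        groups=[config.groups[g] for g in group_of_sample],
        values=np.exp(x),
    )
    module_membership = {
        m: (f"planted_{membership[i] + 1}" if membership[i] >= 0 else None)
        for i, m in enumerate(met_ids)
    }
    truth = SyntheticGroundTruth(
        module_membership=module_membership,
        affected_table=pd.DataFrame(
            affected_records, columns=["metabolite", "group", "shift"]
        ),
        seed=config.seed,
        config=config,
    )
    return profile, truth


def planted_factors(config: SyntheticConfig) -> np.ndarray:
    """Replay the generator stream and return the latent module factors
    (n_modules x n_samples) used by :func:`generate_dataset` for this
    config.  Useful as an oracle for eigen-metabolite recovery."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    counts = _category_counts(config)
    rng.permutation(np.repeat(np.arange(len(CATEGORIES)), counts))
    rng.uniform(*config.baseline_log_mean_range, size=config.n_metabolites)
    for _ in range(config.n_affected):
        rng.choice(len(config.groups), size=2, replace=False)
    return rng.standard_normal((max(config.n_modules, 1), config.n_samples))


def recovery_score(assignment, truth: SyntheticGroundTruth) -> float:
    """Adjusted Rand index between detected and planted partitions,
    restricted to the metabolites planted in modules.

    ``assignment`` is a :class:`~metaboregion.network.ModuleAssignment`
    (anything with a ``labels`` mapping metabolite -> module name or
    None works).  1 means perfect recovery up to label permutation;
    0 is chance level.
    """
    labels = assignment.labels if hasattr(assignment, "labels") else dict(assignment)
    planted = [m for m, lab in truth.module_membership.items() if lab is not None]
    if not set(planted) <= set(labels):
        missing = sorted(set(planted) - set(labels))[:5]
        raise ValueError(f"assignment lacks planted metabolites, e.g. {missing}")
    true_part = [truth.module_membership[m] for m in planted]
    det_part = [labels[m] if labels[m] is not None else "unassigned" for m in planted]
    return float(adjusted_rand_score(true_part, det_part))
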