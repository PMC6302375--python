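"""Weighted correlation network analysis of metabolite profiles.

The stage runs: pairwise correlation S -> soft-threshold adjacency
a_ij = |s_ij|^beta -> scale-free topology check (p(k) ~ k^-gamma) ->
topological overlap omega_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)
-> dissimilarity d_ij = 1 - omega_ij -> complete-linkage hierarchical
clustering -> dynamic branch cut -> iterative module assignment ->
eigen-metabolites (module PC1), hub metabolites, and per-region
correlation panels.

Modules must be connected subtrees of the cut dendrogram with strictly
more than 10 members; metabolites never entering a module are labeled
unassigned.  Clustering and cutting repeat on the residual set until no
new module appears.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .profiles import MetaboliteProfile, NormalizedProfile, ProfileError
from .univariate import one_way_anova

__all__ = [
    "SymmetricMatrix",
    "NetworkParams",
    "ConnectivityVector",
    "ScaleFreeFit",
    "Dendrogram",
    "Module",
    "ModuleAssignment",
    "EigenMetabolite",
    "correlation_matrix",
    "soft_threshold",
    "connectivity",
    "scale_free_fit",
    "choose_beta",
    "topological_overlap",
    "dissimilarity",
    "hierarchical_cluster",
    "cut_tree_dynamic",
    "detect_modules",
    "eigen_metabolite",
    "module_hub",
    "eigen_region_anova",
    "region_correlation_panels",
]

#: Module naming follows the conventional color sequence of weighted
#: network analyses, assigned largest module first.
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
)

_ROLES = ("correlation", "adjacency", "overlap", "dissimilarity")


@dataclass
class SymmetricMatrix:
    """Square symmetric matrix keyed by metabolite IDs with a role tag.

    Roles and their invariants:

    * ``correlation``: entries in [-1, 1], unit diagonal.
    * ``adjacency``: entries in [0, 1], zero diagonal.
    * ``overlap``: entries in [0, 1], unit diagonal.
    * ``dissimilarity``: entries in [0, 1], zero diagonal.
    """

    ids: list[str]
    values: np.ndarray
    role: str

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if self.role not in _ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("matrix is not symmetric within 1e-12")
        diag = np.diag(self.values)
        off = self.values[~np.eye(n, dtype=bool)] if n > 1 else np.array([])
        lo, hi = (-1.0, 1.0) if self.role == "correlation" else (0.0, 1.0)
        if off.size and (off.min() < lo - 1e-12 or off.max() > hi + 1e-12):
            raise ValueError(f"{self.role} entries outside [{lo}, {hi}]")
        want = 1.0 if self.role in ("correlation", "overlap") else 0.0
        if not np.allclose(diag, want, atol=1e-12):
            raise ValueError(f"{self.role} diagonal must be {want}")

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class NetworkParams:
    """Tunable parameters of the network stage.

    beta=11 is the soft-threshold power; min_module_size_exclusive=10
    means accepted modules have strictly more than 10 members;
    cut_height_quantile positions the branch cut within the range of
    dendrogram merge heights (see :func:`cut_tree_dynamic`).
    """

    beta: float = 11.0
    correlation_kind: str = "pearson"
    adjacency_mode: str = "unsigned"
    min_module_size_exclusive: int = 10
    cut_height_quantile: float = 0.99
    max_iterations: int = 10
    r2_min: float = 0.8

    def validate(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if self.correlation_kind not in ("pearson", "spearman"):
            raise ValueError("correlation_kind must be 'pearson' or 'spearman'")
        if self.adjacency_mode not in ("unsigned", "signed"):
            raise ValueError("adjacency_mode must be 'unsigned' or 'signed'")
        if not 0.0 < self.cut_height_quantile <= 1.0:
            raise ValueError("cut_height_quantile must lie in (0, 1]")
        if self.min_module_size_exclusive < 1:
            raise ValueError("min_module_size_exclusive must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class ConnectivityVector:
    ids: list[str]
    k: np.ndarray

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=float)
        if self.k.min(initial=0.0) < 0:
            raise ValueError("connectivity must be non-negative")


@dataclass
class ScaleFreeFit:
    """Goodness of the power-law fit p(k) ~ k^-gamma on binned connectivities."""

    r_squared: float
    gamma_hat: float
    n_bins: int
    bin_centers: np.ndarray
    frequencies: np.ndarray


@dataclass
class Dendrogram:
    """Binary merge tree from agglomerative clustering.

    ``merges`` is the (n-1) x 4 SciPy linkage encoding; heights are
    non-decreasing under complete linkage.
    """

    ids: list[str]
    merges: np.ndarray

    def __post_init__(self) -> None:
        self.merges = np.asarray(self.merges, dtype=float)
        n = len(self.ids)
        if self.merges.shape != (n - 1, 4):
            raise ValueError("merges must be an (n-1) x 4 linkage matrix")

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


@dataclass
class EigenMetabolite:
    """Module summary profile: first principal component over samples of
    the standardized member submatrix (unit norm, oriented so the mean
    correlation with members is non-negative)."""

    sample_ids: list[str]
    scores: np.ndarray
    variance_explained: float
    flipped: bool = False


@dataclass
class Module:
    name: str
    members: list[str]
    iteration_found: int
    eigen: EigenMetabolite | None = None
    hub: str | None = None
    hub_score: float | None = None
    membership_scores: dict[str, float] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ModuleAssignment:
    """Per-metabolite module label plus per-module details.

    ``labels`` maps every profile metabolite to a module name or None
    (unassigned).  Module member sets are disjoint and every module has
    strictly more members than the configured size bound.
    """

    labels: dict[str, str | None]
    modules: list[Module]
    iteration_count: int

    @property
    def module_names(self) -> list[str]:
        return [m.name for m in self.modules]

    def members_of(self, name: str) -> list[str]:
        for m in self.modules:
            if m.name == name:
                return list(m.members)
        raise KeyError(name)


# ---------------------------------------------------------------------------
# Correlation and adjacency
# ---------------------------------------------------------------------------

def _network_values(profile: MetaboliteProfile, log_transform: bool) -> np.ndarray:
    """Values the network stage correlates: log2 concentrations by
    default for raw profiles (lognormal data), untouched otherwise."""
    if isinstance(profile, NormalizedProfile) or not log_transform:
        return profile.values
    if np.any(profile.values <= 0):
        raise ProfileError("log transform requires strictly positive concentrations")
    return np.log2(profile.values)


def correlation_matrix(
    profile: MetaboliteProfile,
    kind: str = "pearson",
    log_transform: bool = True,
) -> SymmetricMatrix:
    """Pairwise metabolite correlation across all samples."""
    if profile.n_samples < 3:
        raise ProfileError("correlations need at least 3 samples")
    X = _network_values(profile, log_transform)
    sd = X.std(axis=1, ddof=1)
    if np.any(sd == 0):
        names = [profile.metabolite_ids[i] for i in np.flatnonzero(sd == 0)]
        raise ProfileError(f"constant metabolite rows: {names}")
    if kind == "pearson":
        S = np.corrcoef(X)
    elif kind == "spearman":
        ranks = np.apply_along_axis(stats.rankdata, 1, X)
        S = np.corrcoef(ranks)
    else:
        raise ValueError(f"unknown correlation kind {kind!r}")
    S = np.clip((S + S.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return SymmetricMatrix(ids=profile.metabolite_ids, values=S, role="correlation")


def soft_threshold(S: SymmetricMatrix, params: NetworkParams) -> SymmetricMatrix:
    """Soft-threshold adjacency a_ij = |s_ij|^beta (zero diagonal).

    The signed-preserving mode (literal s^beta) is kept behind
    ``adjacency_mode='signed'``; with odd beta it yields negative
    values, which are clipped to 0 with a warning.
    """
    if S.role != "correlation":
        raise ValueError("soft_threshold expects a correlation matrix")
    params.validate()
    if params.adjacency_mode == "unsigned":
        A = np.abs(S.values) ** params.beta
    else:
        A = np.sign(S.values) * np.abs(S.values) ** params.beta
        if (A < 0).any():
            warnings.warn(
                "signed adjacency produced negative entries; clipping at 0",
                stacklevel=2,
            )
            A = np.clip(A, 0.0, None)
    np.fill_diagonal(A, 0.0)
    return SymmetricMatrix(ids=S.ids, values=A, role="adjacency")


def connectivity(A: SymmetricMatrix) -> ConnectivityVector:
    """Node connectivity k_i = sum_{u != i} a_iu."""
    if A.role != "adjacency":
        raise ValueError("connectivity expects an adjacency matrix")
    return ConnectivityVector(ids=A.ids, k=A.values.sum(axis=1))


def scale_free_fit(k: ConnectivityVector | np.ndarray, n_bins: int = 10) -> ScaleFreeFit:
    """Fit p(k) ~ k^-gamma on equal-width connectivity bins.

    Regresses log10(frequency) on log10(bin center) over the non-empty
    bins; returns the R-squared of that line and gamma_hat = -slope.
    """
    kv = k.k if isinstance(k, ConnectivityVector) else np.asarray(k, dtype=float)
    if np.unique(kv).size < 2:
        raise ValueError("degenerate connectivity distribution (all values equal)")
    counts, edges = np.histogram(kv, bins=n_bins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    keep = (counts > 0) & (centers > 0)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 usable bins for the power-law fit")
    x = np.log10(centers[keep])
    y = np.log10(counts[keep] / counts.sum())
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0
    return ScaleFreeFit(
        r_squared=r2,
        gamma_hat=float(-res.slope),
        n_bins=int(keep.sum()),
        bin_centers=centers[keep],
        frequencies=counts[keep] / counts.sum(),
    )


@dataclass
class BetaSelection:
    beta: float
    table: pd.DataFrame
    warned: bool


def choose_beta(
    S: SymmetricMatrix,
    candidates: Sequence[float] | None = None,
    r2_min: float = 0.8,
    override: float | None = None,
    n_bins: int = 10,
) -> BetaSelection:
    """Pick the smallest soft power whose scale-free fit reaches r2_min.

    If no candidate qualifies, the candidate with maximal R-squared is
    returned with ``warned=True``.  An explicit ``override`` bypasses
    selection entirely (the fit table is still reported).
    """
    if candidates is None:
        candidates = list(range(1, 21))
    candidates = sorted(candidates)
    if not candidates:
        raise ValueError("empty candidate list")
    rows = []
    for b in candidates:
        A = soft_threshold(S, NetworkParams(beta=b))
        try:
            fit = scale_free_fit(connectivity(A), n_bins=n_bins)
            rows.append((b, fit.r_squared, fit.gamma_hat))
        except ValueError:
            rows.append((b, np.nan, np.nan))
    table = pd.DataFrame(rows, columns=["beta", "r_squared", "gamma_hat"])
    if override is not None:
        return BetaSelection(beta=float(override), table=table, warned=False)
    ok = table.dropna(subset=["r_squared"])
    qualifying = ok[ok["r_squared"] >= r2_min]
    if len(qualifying):
        return BetaSelection(
            beta=float(qualifying["beta"].iloc[0]), table=table, warned=False
        )
    if not len(ok):
        raise ValueError("no candidate produced a valid scale-free fit")
    best = ok.loc[ok["r_squared"].idxmax(), "beta"]
    warnings.warn(
        f"no candidate beta reached R^2 >= {r2_min}; using best fit beta={best}",
        stacklevel=2,
    )
    return BetaSelection(beta=float(best), table=table, warned=True)


# ---------------------------------------------------------------------------
# Topological overlap, clustering, branch cut
# ---------------------------------------------------------------------------

def topological_overlap(A: SymmetricMatrix) -> SymmetricMatrix:
    """Topological overlap omega_ij = (l_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij)
    with l_ij = sum_{u != i,j} a_iu a_uj; unit diagonal.

    Interconnectedness of a pair combines their direct edge with their
    shared neighborhood; entries lie in [0, 1].
    """
    if A.role != "adjacency":
        raise ValueError("topological_overlap expects an adjacency matrix")
    a = A.values
    k = a.sum(axis=1)
    # zero diagonal makes the matrix product skip u == i and u == j
    L = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    omega = (L + a) / denom
    np.fill_diagonal(omega, 1.0)
    omega = np.clip((omega + omega.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(omega, 1.0)
    return SymmetricMatrix(ids=A.ids, values=omega, role="overlap")


def dissimilarity(omega: SymmetricMatrix) -> SymmetricMatrix:
    """d_ij = 1 - omega_ij (zero diagonal)."""
    if omega.role != "overlap":
        raise ValueError("dissimilarity expects an overlap matrix")
    D = 1.0 - omega.values
    np.fill_diagonal(D, 0.0)
    return SymmetricMatrix(ids=omega.ids, values=D, role="dissimilarity")


def hierarchical_cluster(D: SymmetricMatrix) -> Dendrogram:
    """Agglomerative complete-linkage clustering of the dissimilarity."""
    if D.role != "dissimilarity":
        raise ValueError("hierarchical_cluster expects a dissimilarity matrix")
    if D.n < 2:
        raise ValueError("clustering needs at least 2 metabolites")
    Z = linkage(squareform(D.values, checks=False), method="complete")
    return Dendrogram(ids=D.ids, merges=Z)


def cut_tree_dynamic(dend: Dendrogram, params: NetworkParams) -> np.ndarray:
    """Branch cut: candidate clusters are the connected subtrees below
    the cut height; only candidates larger than the size bound survive.

    The cut height follows the joining-height-range convention of the
    dynamic tree cut: h* = h05 + q * (hmax - h05), where h05 and hmax
    are the 5th percentile and maximum of the merge heights and
    q = ``cut_height_quantile``.  Anchoring at the low percentile keeps
    the cut below the bulk of near-1 background merges of a topological-
    overlap dendrogram, so structureless profiles yield no candidate of
    meaningful size while genuine co-varying branches (which merge far
    below the background) survive intact.

    Returns an int array of candidate labels in leaf order; -1 marks
    unassigned leaves.
    """
    params.validate()
    heights = dend.heights
    h05 = float(np.quantile(heights, 0.05))
    h_star = h05 + params.cut_height_quantile * (float(heights.max()) - h05)
    flat = fcluster(dend.merges, t=h_star, criterion="distance")
    labels = np.full(len(dend.ids), -1, dtype=int)
    next_label = 0
    for c in np.unique(flat):
        members = np.flatnonzero(flat == c)
        if members.size > params.min_module_size_exclusive:
            labels[members] = next_label
            next_label += 1
    return labels


# ---------------------------------------------------------------------------
# Module detection loop
# ---------------------------------------------------------------------------

def detect_modules(
    profile: MetaboliteProfile,
    params: NetworkParams | None = None,
    log_transform: bool = True,
) -> ModuleAssignment:
    """Iterative module assignment.

    Each round runs correlation -> soft threshold (fixed beta) ->
    topological overlap -> dissimilarity -> complete linkage -> branch
    cut on the currently unassigned metabolites; newly accepted modules
    are removed and the round repeats until no new module appears,
    ``max_iterations`` is reached, or too few metabolites remain.
    Leftovers are permanently labeled unassigned.  The procedure is
    deterministic given profile and params.
    """
    if params is None:
        params = NetworkParams()
    params.validate()
    min_size = params.min_module_size_exclusive
    if profile.n_metabolites < min_size + 2:
        raise ProfileError(
            f"need at least {min_size + 2} metabolites for module detection"
        )
    ids = list(profile.metabolite_ids)
    active = list(ids)
    found: list[Module] = []
    iteration = 0
    while iteration < params.max_iterations and len(active) >= min_size + 2:
        iteration += 1
        sub = profile.subset(active)
        S = correlation_matrix(
            sub, kind=params.correlation_kind, log_transform=log_transform
        )
        A = soft_threshold(S, params)
        D = dissimilarity(topological_overlap(A))
        dend = hierarchical_cluster(D)
        labels = cut_tree_dynamic(dend, params)
        new = 0
        for c in np.unique(labels[labels >= 0]):
            members = [active[i] for i in np.flatnonzero(labels == c)]
            found.append(Module(name="", members=members, iteration_found=iteration))
            new += 1
        if new == 0:
            break
        taken = {m for mod in found for m in mod.members}
        active = [m for m in active if m not in taken]

    # name by size (largest first), then discovery order, then first member
    found.sort(key=lambda m: (-m.size, m.iteration_found, m.members[0]))
    for i, mod in enumerate(found):
        mod.name = (
            MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module_{i + 1}"
        )
        mod.eigen = eigen_metabolite(profile, mod.members, log_transform=log_transform)
        mod.hub, mod.membership_scores = module_hub(
            profile, mod.members, mod.eigen, log_transform=log_transform
        )
        mod.hub_score = mod.membership_scores[mod.hub]
    labels_map: dict[str, str | None] = {m: None for m in ids}
    for mod in found:
        for m in mod.members:
            labels_map[m] = mod.name
    return ModuleAssignment(labels=labels_map, modules=found, iteration_count=iteration)


# ---------------------------------------------------------------------------
# Eigen-metabolites, hubs, region structure
# ---------------------------------------------------------------------------

def eigen_metabolite(
    profile: MetaboliteProfile,
    members: Sequence[str],
    log_transform: bool = True,
) -> EigenMetabolite:
    """First principal component over samples of the standardized
    member submatrix; unit norm, oriented to non-negative mean member
    correlation; reports the fraction of module variance explained."""
    members = list(members)
    if len(members) < 2:
        raise ValueError("eigen-metabolite needs at least 2 members")
    sub = profile.subset(members)
    X = _network_values(sub, log_transform)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant member rows")
    Z = (X - mean) / sd
    U, s, Vt = np.linalg.svd(Z - Z.mean(axis=1, keepdims=True), full_matrices=False)
    scores = Vt[0]
    var_explained = float(s[0] ** 2 / np.sum(s**2))
    member_corr = np.array([np.corrcoef(Z[i], scores)[0, 1] for i in range(len(members))])
    flipped = bool(member_corr.mean() < 0)
    if flipped:
        scores = -scores
    return EigenMetabolite(
        sample_ids=list(profile.sample_ids),
        scores=scores,
        variance_explained=var_explained,
        flipped=flipped,
    )


def module_hub(
    profile: MetaboliteProfile,
    members: Sequence[str],
    eigen: EigenMetabolite,
    log_transform: bool = True,
) -> tuple[str, dict[str, float]]:
    """Hub = member maximizing |cor(member profile, eigen-metabolite)|.

    The membership score (often written kME) lies in [0, 1]; ties break
    lexicographically on metabolite ID.
    """
    members = list(members)
    sub = profile.subset(members)
    X = _network_values(sub, log_transform)
    scores = {}
    for i, m in enumerate(members):
        scores[m] = float(abs(np.corrcoef(X[i], eigen.scores)[0, 1]))
    hub = min(scores, key=lambda m: (-scores[m], m))
    return hub, scores


def eigen_region_anova(eigen: EigenMetabolite, groups: Sequence[str]) -> float:
    """One-way ANOVA p-value of the eigen-metabolite scores across groups."""
    _, p = one_way_anova(eigen.scores, list(groups))
    return p


def region_correlation_panels(
    profile: MetaboliteProfile,
    assignment: ModuleAssignment,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Pairwise member correlations per module, within each region and
    merged over all samples.

    Long format: columns module, panel (group label or "merged"),
    metabolite_a, metabolite_b, correlation — the data behind per-region
    correlation density/contour panels.
    """
    labels = profile.group_labels
    for g in labels:
        if profile.group_columns(g).size < 3:
            raise ProfileError(f"group {g!r} has fewer than 3 samples")
    X = _network_values(profile, log_transform)
    index = {m: i for i, m in enumerate(profile.metabolite_ids)}
    panels = [(g, profile.group_columns(g)) for g in labels]
    panels.append(("merged", np.arange(profile.n_samples)))
    records = []
    for mod in assignment.modules:
        rows = [index[m] for m in mod.members]
        for panel, cols in panels:
            sub = X[np.ix_(rows, cols)]
            sd = sub.std(axis=1, ddof=1)
            if np.any(sd == 0):
                raise ProfileError(
                    f"constant member values in panel {panel!r} of module {mod.name}"
                )
            C = np.corrcoef(sub)
            for ai in range(len(rows)):
                for bi in range(ai + 1, len(rows)):
                    records.append(
                        (
                            mod.name,
                            panel,
                            mod.members[ai],
                            mod.members[bi],
                            float(C[ai, bi]),
                        )
                    )
    return pd.DataFrame(
        records,
        columns=["module", "panel", "metabolite_a", "metabolite_b", "correlation"],
    )
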