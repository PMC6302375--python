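"""Principal component analysis of metabolite profiles.

PCA runs over samples (observations) with metabolites as features, so
scores place the 24 samples in latent space and loadings weight the
metabolites.  Input is normally the z-scored profile: MS intensities
span orders of magnitude, and per-metabolite standardization stops a
few high-abundance compounds from dominating the components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SKPCA

from .profiles import MetaboliteProfile

__all__ = ["PCAResult", "pca", "top_loadings"]


@dataclass
class PCAResult:
    sample_ids: list[str]
    metabolite_ids: list[str]
    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # metabolites x components (orthonormal columns)
    explained_variance_ratio: np.ndarray
    centered: bool = True
    scaled: bool = False

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.n_components)]
        df = pd.DataFrame(self.scores, columns=cols)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.n_components)]
        df = pd.DataFrame(self.loadings, columns=cols)
        df.insert(0, "metabolite_id", self.metabolite_ids)
        return df


def pca(profile: MetaboliteProfile, n_components: int = 2) -> PCAResult:
    """PCA of the profile transposed to samples x metabolites.

    Components are ordered by decreasing explained variance.  Sign
    convention: every loading column is oriented so its largest-
    magnitude element is positive (scores flipped accordingly), making
    output deterministic across linear-algebra backends.
    """
    max_comp = min(profile.n_metabolites, profile.n_samples - 1)
    if not 1 <= n_components <= max_comp:
        raise ValueError(
            f"n_components must lie in [1, {max_comp}] "
            f"(min of n_metabolites and n_samples - 1)"
        )
    X = profile.values.T  # samples x metabolites
    if np.any(X.std(axis=0) == 0):
        bad = [
            profile.metabolite_ids[i]
            for i in np.flatnonzero(X.std(axis=0) == 0)
        ]
        raise ValueError(f"constant metabolite rows: {bad}")
    model = _SKPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_.T  # metabolites x components
    # deterministic orientation
    for j in range(n_components):
        k = np.argmax(np.abs(loadings[:, j]))
        if loadings[k, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PCAResult(
        sample_ids=list(profile.sample_ids),
        metabolite_ids=list(profile.metabolite_ids),
        scores=scores,
        loadings=loadings,
        explained_variance_ratio=np.asarray(model.explained_variance_ratio_),
    )


def top_loadings(result: PCAResult, component: int, n: int = 10) -> list[tuple[str, float]]:
    """The n metabolites with largest |loading| on a component (0-based),
    sorted by |loading| descending, ties broken by metabolite ID."""
    if not 0 <= component < result.n_components:
        raise ValueError(f"component {component} out of range")
    if n > len(result.metabolite_ids):
        raise ValueError("n exceeds the number of metabolites")
    col = result.loadings[:, component]
    order = sorted(
        range(len(col)), key=lambda i: (-abs(col[i]), result.metabolite_ids[i])
    )
    return [(result.metabolite_ids[i], float(col[i])) for i in order[:n]]
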