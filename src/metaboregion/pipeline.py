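"""End-to-end orchestration: normalize -> univariate -> PCA -> network.

``run_pipeline`` executes the stages in order on a profile read from
disk, writes every stage table as TSV, and assembles a deterministic
JSON summary (stable key order, no timestamps) so reruns with the same
configuration are byte-identical.  Provenance (package version,
parameters) goes to a separate sidecar file.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .network import (
    NetworkParams,
    correlation_matrix,
    detect_modules,
    eigen_region_anova,
    region_correlation_panels,
    soft_threshold,
    topological_overlap,
)
from .pca import pca, top_loadings
from .profiles import (
    MetaboliteProfile,
    normalize_studentized,
    normalize_zscore,
    read_profile,
)
from .univariate import (
    anova_table,
    pairwise_table,
    region_signature,
    significant_metabolites,
)

logger = logging.getLogger("metaboregion")

SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """All knobs of the full pipeline, mirroring the study defaults:
    FDR cutoff 0.01, pairwise alpha 0.05, soft power 11, exclusive
    module-size bound 10."""

    profile_path: str = ""
    annotation_path: str = ""
    output_dir: str = "metaboregion_out"
    file_format: str = "tsv"
    normalization: str = "zscore"  # zscore | studentized_residual | none
    q_threshold: float = 0.01
    alpha: float = 0.05
    signature_rule: str = "all"
    n_components: int = 2
    top_n: int = 10
    pca_subset_significant: bool = False
    network: NetworkParams = field(default_factory=NetworkParams)
    seed: int = 0  # used only by synthetic runs; recorded for provenance

    def validate(self) -> None:
        if not 0 < self.q_threshold < 1:
            raise ValueError("q_threshold must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.normalization not in ("zscore", "studentized_residual", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        self.network.validate()

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        net = NetworkParams(**data.pop("network", {}))
        return cls(network=net, **data)


def summarize(assignment, univariate: pd.DataFrame, signature, pca_result,
              q_threshold: float = 0.01) -> dict:
    """Machine-readable run summary with a fixed schema version."""
    significant = univariate.loc[univariate["q"] < q_threshold, "metabolite"]
    summary = {
        "schema_version": SCHEMA_VERSION,
        "n_metabolites": int(len(univariate)),
        "significant_count": int(len(significant)),
        "region_signature_counts": signature.counts if signature else {},
        "module_count": len(assignment.modules),
        "module_sizes": {m.name: m.size for m in assignment.modules},
        "hubs": {
            m.name: {"metabolite": m.hub, "score": round(m.hub_score, 6)}
            for m in assignment.modules
        },
        "unassigned_count": sum(1 for v in assignment.labels.values() if v is None),
        "iteration_count": assignment.iteration_count,
        "explained_variance_ratio": [
            round(float(v), 6) for v in pca_result.explained_variance_ratio
        ],
    }
    # bug guard: the schema must serialize deterministically
    json.dumps(summary, sort_keys=True)
    return summary


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write all stage outputs.

    Returns the JSON summary dict.  Raises :class:`PipelineError`
    naming the failing stage on any error.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn):
        logger.info("stage %s", name)
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    profile = stage(
        "read",
        lambda: read_profile(
            config.profile_path, config.annotation_path, format=config.file_format
        ),
    )

    def _normalize():
        if config.normalization == "zscore":
            return normalize_zscore(profile)
        if config.normalization == "studentized_residual":
            return normalize_studentized(profile)
        return profile

    normalized = stage("normalize", _normalize)

    def _univariate():
        table = anova_table(profile)
        table.to_csv(out / "univariate_anova.tsv", sep="\t", index=False)
        sig = table.loc[table["q"] < config.q_threshold, "metabolite"].tolist()
        pw = pairwise_table(profile, metabolites=sig)
        pw.to_csv(out / "univariate_pairwise.tsv", sep="\t", index=False)
        sig_counts = (
            region_signature(profile, sig, alpha=config.alpha, rule=config.signature_rule)
            if len(profile.group_labels) >= 3
            else None
        )
        return table, sig, sig_counts

    table, sig, signature = stage("univariate", _univariate)

    def _pca():
        prof = normalized if config.normalization != "none" else normalize_zscore(profile)
        if config.pca_subset_significant and sig:
            prof = prof.subset(sig)
        result = pca(prof, n_components=config.n_components)
        result.scores_frame().to_csv(out / "pca_scores.tsv", sep="\t", index=False)
        result.loadings_frame().to_csv(out / "pca_loadings.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "component": [f"PC{i+1}" for i in range(result.n_components)],
                "explained_variance_ratio": result.explained_variance_ratio,
            }
        ).to_csv(out / "pca_explained_variance.tsv", sep="\t", index=False)
        tops = []
        for c in range(result.n_components):
            for met, loading in top_loadings(result, c, n=min(config.top_n, len(prof.metabolite_ids))):
                tops.append((f"PC{c+1}", met, loading))
        pd.DataFrame(tops, columns=["component", "metabolite", "loading"]).to_csv(
            out / "pca_top_loadings.tsv", sep="\t", index=False
        )
        return result

    pca_result = stage("pca", _pca)

    def _network():
        assignment = detect_modules(profile, config.network)
        rows = []
        for m in profile.metabolite_ids:
            lab = assignment.labels[m]
            mod = next((x for x in assignment.modules if x.name == lab), None)
            rows.append(
                (
                    m,
                    lab if lab is not None else "unassigned",
                    mod.membership_scores.get(m) if mod else None,
                    bool(mod and mod.hub == m),
                )
            )
        pd.DataFrame(
            rows, columns=["metabolite", "module", "membership_score", "is_hub"]
        ).to_csv(out / "network_modules.tsv", sep="\t", index=False)
        eig_rows = {
            m.name: dict(zip(profile.sample_ids, m.eigen.scores))
            for m in assignment.modules
        }
        pd.DataFrame(eig_rows).T.rename_axis("module").to_csv(
            out / "network_eigen_metabolites.tsv", sep="\t"
        )
        S = correlation_matrix(profile, kind=config.network.correlation_kind)
        A = soft_threshold(S, config.network)
        omega = topological_overlap(A)
        ii, jj = [list(x) for x in zip(*[
            (i, j) for i in range(S.n) for j in range(i + 1, S.n)
        ])] if S.n > 1 else ([], [])
        pd.DataFrame(
            {
                "metabolite_a": [S.ids[i] for i in ii],
                "metabolite_b": [S.ids[j] for j in jj],
                "adjacency": A.values[ii, jj],
                "overlap": omega.values[ii, jj],
            }
        ).to_csv(out / "network_edges.tsv", sep="\t", index=False)
        if assignment.modules and min(
            profile.group_columns(g).size for g in profile.group_labels
        ) >= 3:
            region_correlation_panels(profile, assignment).to_csv(
                out / "network_region_panels.tsv", sep="\t", index=False
            )
        anova_p = {
            m.name: eigen_region_anova(m.eigen, profile.groups)
            for m in assignment.modules
        }
        return assignment, anova_p

    assignment, eigen_p = stage("network", _network)

    summary = stage(
        "summarize",
        lambda: summarize(assignment, table, signature, pca_result, config.q_threshold),
    )
    summary["eigen_anova_p"] = {k: round(v, 8) for k, v in eigen_p.items()}
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    provenance = {
        "package_version": __version__,
        "config": _config_dict(config),
    }
    (out / "provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True) + "\n"
    )
    return summary


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return d
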