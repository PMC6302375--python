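import numpy as np
import pytest

from metaboregion import (
    MetaboliteProfile,
    SyntheticConfig,
    generate_dataset,
    write_profile,
)


def make_profile(values, groups=None, metabolite_ids=None, categories=None,
                 sample_ids=None):
    """Small hand-built profile for unit tests."""
    values = np.asarray(values, dtype=float)
    n_met, n_samp = values.shape
    if metabolite_ids is None:
        metabolite_ids = [f"m{i}" for i in range(n_met)]
    if categories is None:
        categories = ["lipids"] * n_met
    if sample_ids is None:
        sample_ids = [f"s{j}" for j in range(n_samp)]
    if groups is None:
        half = n_samp // 2
        groups = ["A"] * half + ["B"] * (n_samp - half)
    return MetaboliteProfile(
        metabolite_ids=metabolite_ids,
        categories=categories,
        sample_ids=sample_ids,
        groups=groups,
        values=values,
    )


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study design (seed 0)."""
    return generate_dataset(SyntheticConfig(seed=0))


@pytest.fixture
def toy_profile():
    rng = np.random.default_rng(42)
    return make_profile(
        np.exp(rng.normal(1.0, 0.5, size=(6, 8))),
        groups=["A", "A", "B", "B", "C", "C", "D", "D"],
    )


@pytest.fixture
def toy_files(tmp_path, toy_profile):
    prof = tmp_path / "profile.tsv"
    ann = tmp_path / "samples.tsv"
    write_profile(toy_profile, prof, ann)
    return prof, ann
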