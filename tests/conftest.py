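"""Shared fixtures: one default synthetic study reused across test modules."""

import warnings

import numpy as np
import pandas as pd
import pytest

from nfcnkit import (LigandReceptorSpec, SyntheticConfig,
                     build_interaction_trajectory, generate_immune_counts,
                     generate_spatial_spots, lognormalize, regress_and_scale,
                     select_connected)

FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def study():
    """Default synthetic immune study: counts, planted truth, config."""
    cfg = SyntheticConfig(seed=FIXTURE_SEED)
    counts, truth = generate_immune_counts(cfg)
    return cfg, counts, truth


@pytest.fixture(scope="session")
def lognorm(study):
    _, counts, _ = study
    return lognormalize(counts)


@pytest.fixture(scope="session")
def scaled(study, lognorm):
    _, _, truth = study
    cov = pd.DataFrame({"batch": pd.Categorical(truth.batches)})
    return regress_and_scale(lognorm, cov)


@pytest.fixture(scope="session")
def grid(study):
    cfg, counts, truth = study
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_spatial_spots(cfg, counts, truth)


@pytest.fixture(scope="session")
def lr_spec(study):
    _, _, truth = study
    p = truth.program_gene_members
    return LigandReceptorSpec(
        ligand_genes=p["ligand"], induction_genes=p["induction"],
        receptor_genes=p["receptor"], activation_genes=p["activation"],
        target_cell_labels=frozenset({"Teff", "Texh"}))


@pytest.fixture(scope="session")
def signatures(study):
    _, _, truth = study
    return {t: truth.program_gene_members[f"markers_{t}"]
            for t in ("myeloidA", "myeloidB", "Teff", "Texh", "tumor", "other")}


@pytest.fixture(scope="session")
def trajectory(scaled, lr_spec, study):
    _, _, truth = study
    return build_interaction_trajectory(scaled, lr_spec, truth.cell_labels)


@pytest.fixture(scope="session")
def pairs(trajectory):
    return select_connected(trajectory)


def rng_for(case: str, offset: int = 0) -> np.random.Generator:
    """Deterministic per-test generator so tests stay order-independent."""
    import zlib

    base = zlib.crc32(case.encode())
    return np.random.default_rng(base + offset)
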