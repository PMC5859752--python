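"""Shared fixtures: one synthetic germline repertoire, a small background
transcriptome and the derived genome bundle, reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from igrecon.filterreads import FilterResources
from igrecon.simulate import (
    BackgroundTranscriptome,
    ReadConfig,
    build_reference_bundle,
    simulate_cell,
    simulate_cell_reads,
    synthetic_germline_db,
)

DB_SEED = 20240901


@pytest.fixture(scope="session")
def db():
    return synthetic_germline_db(DB_SEED)


@pytest.fixture(scope="session")
def background():
    # small background keeps genome indexing fast in unit tests
    rng = np.random.default_rng(DB_SEED + 1)
    return BackgroundTranscriptome.generate(rng, n_genes=40)


@pytest.fixture(scope="session")
def bundle(db, background):
    rng = np.random.default_rng(DB_SEED + 2)
    return build_reference_bundle(db, background, rng)


@pytest.fixture(scope="session")
def resources(db, bundle):
    genome, loci, genes = bundle
    return FilterResources.from_germline(
        db, genome=genome, locus_table=loci, gene_annotation=genes
    )


@pytest.fixture(scope="session")
def small_cell(db):
    return simulate_cell(db, "cell001", np.random.default_rng(DB_SEED + 3))


@pytest.fixture(scope="session")
def small_readset(small_cell, background):
    config = ReadConfig(total_reads=12000)
    return simulate_cell_reads(
        small_cell, background, config, np.random.default_rng(small_cell.seed)
    )
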