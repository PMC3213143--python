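"""Shared fixtures: the default synthetic dataset is generated once per
session and reused by unit and acceptance tests."""

from __future__ import annotations

import pytest

from erisift import classify, duplex_phasing, simdata
from erisift.classify import AnnotationIndex
from erisift.mapper import GenomeIndex, map_reads


@pytest.fixture(scope="session")
def default_dataset():
    """(genome, libraries, truth) under the default configuration."""
    return simdata.simulate(simdata.SimulationConfig())


@pytest.fixture(scope="session")
def mapped_default(default_dataset):
    genome, libraries, _ = default_dataset
    index = GenomeIndex(genome.chroms)
    return {key: map_reads(reads, index) for key, reads in libraries.items()}


@pytest.fixture(scope="session")
def annindex_default(default_dataset):
    genome, _, _ = default_dataset
    return AnnotationIndex(genome.features)


@pytest.fixture(scope="session")
def profiles_default(default_dataset, mapped_default, annindex_default):
    return {
        (g, s): classify.profile(lib, annindex_default, genotype=g, stage=s)
        for (g, s), lib in mapped_default.items()
    }


@pytest.fixture(scope="session")
def ergo1_ids(default_dataset):
    genome, _, _ = default_dataset
    return sorted(f.id for f in genome.features if f.truth_class == "ergo1_target")


@pytest.fixture(scope="session")
def duplex_records_default(default_dataset, mapped_default):
    """Duplex records per library for all libraries with 26G guides."""
    genome, _, _ = default_dataset
    out = {}
    for key, lib in mapped_default.items():
        guides = []
        for feat in genome.features:
            if feat.truth_class in {"ergo1_target", "alg34_target"}:
                guides.extend(duplex_phasing.guides_for_feature(feat, lib))
        if guides:
            out[key] = duplex_phasing.find_passengers(guides, lib)
    return out
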