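"""Shared fixtures: bundled species tables and the synthetic battery."""

from __future__ import annotations

import pytest

from mitoprofiler import annotation_model as am
from mitoprofiler import genome_io as gio
from mitoprofiler.synthetic_data import (SyntheticSpec, generate_mitogenome,
                                         write_fixture_set)

SPECIES = ("parkeri", "ventripunctata", "pleskei")


def load_species(species: str):
    rows = gio.read_feature_tsv(
        gio.bundled_path(f"nanorana_{species}_features.tsv"))
    genome, report = am.validate_annotation(rows, identifier=species)
    return genome, report, rows


@pytest.fixture(scope="session")
def species_tables():
    """{species: (genome, validation report, raw rows)} for the three tables."""
    return {s: load_species(s) for s in SPECIES}


@pytest.fixture(scope="session")
def default_synthetic():
    """(genome, truth) for the default synthetic genome, seed 1."""
    return generate_mitogenome(SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def fixture_battery(tmp_path_factory):
    """Directory holding the standard written fixture battery (seed 0)."""
    out = tmp_path_factory.mktemp("battery")
    write_fixture_set(out, seed=0)
    return out
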