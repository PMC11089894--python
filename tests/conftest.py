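import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from integronhgt.model import CassetteRecord
from integronhgt.simulate import CommunityConfig, generate_community


@pytest.fixture(scope="session")
def small_community():
    """A small deterministic community with 6 planted cross-species events."""
    config = CommunityConfig(
        n_species=5,
        genomes_per_species=1,
        cassettes_per_genome=8,
        n_planted_hgt=6,
        cross_site_hgt_fraction=0.5,
        cassette_length_range=(60, 120),
        seed=11,
    )
    return generate_community(config)


def make_cassette(cid, species="Species_X", seq="ACGT" * 20, site="rhizosphere",
                  genome=None, clade="Clade_0", attc=None):
    return CassetteRecord(
        cassette_id=cid,
        genome_id=genome or f"{species}_g0",
        species_label=species,
        clade_label=clade,
        plant_site=site,
        sequence=seq,
        attc_sequence=attc,
    )
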