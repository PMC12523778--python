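import pytest

from mitokit.datasets import huangshanensis_annotation, huangshanensis_skeleton
from mitokit.synthetic import GenomeSpec, MutationPlan, generate_genome, \
    generate_species_pair

#: the 13 mitochondrial protein-coding genes in genomic order
PCG_NAMES = ["ND1", "ND2", "COX1", "COX2", "atp8", "atp6", "COX3", "ND3",
             "ND4L", "ND4", "ND5", "ND6", "Cytb"]


@pytest.fixture(scope="session")
def published_annotation():
    """(features, genome_length) of the published 37-gene annotation."""
    return huangshanensis_annotation()


@pytest.fixture(scope="session")
def skeleton_genome():
    """Published annotation on an undetermined sequence (geometry only)."""
    return huangshanensis_skeleton()


@pytest.fixture(scope="session")
def synthetic_genome():
    """One deterministic synthetic mitogenome with its ground-truth ledger."""
    return generate_genome(GenomeSpec(seed=42))


@pytest.fixture(scope="session")
def species_pair():
    """Base + derived genome pair where only ND5 carries an excess of
    nonsynonymous planted changes."""
    plans = {name: MutationPlan(8, 1) for name in PCG_NAMES}
    plans["ND5"] = MutationPlan(2, 10)
    base, derived, ledger = generate_species_pair(GenomeSpec(seed=7), plans)
    return base, derived, ledger, plans
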