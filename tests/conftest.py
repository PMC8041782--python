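"""Shared fixtures: small synthetic reference sets and simulation configs."""

import pytest

from trapscreen.synth import (
    LocusSpec,
    MockCommunityDesign,
    SimulationConfig,
    generate_species_profiles,
)

THREE_LOCI = {
    "COI": LocusSpec(length=300, within_divergence=0.02, between_divergence=0.10),
    "12S": LocusSpec(length=250, within_divergence=0.02, between_divergence=0.10),
    "18S": LocusSpec(length=280, within_divergence=0.0, between_divergence=0.05),
}


@pytest.fixture(scope="session")
def locus_specs():
    return dict(THREE_LOCI)


@pytest.fixture(scope="session")
def profiles(locus_specs):
    """3 genera x 2 species over 2 phyla; 18S is conserved within genera."""
    return generate_species_profiles(
        3, 2, locus_specs, seed=11, phyla=("Arthropoda", "Chordata")
    )


@pytest.fixture(scope="session")
def arthropod_profiles(locus_specs):
    """4 genera x 2 species, one phylum — for classification fixtures."""
    return generate_species_profiles(4, 2, locus_specs, seed=23)


def unique_dual_config(samples, seed=0, reads=10_000, s=0.0, loci=("COI",)):
    share = {l: 1.0 / len(loci) for l in loci}
    share[loci[0]] += 1.0 - sum(share.values())
    i5 = tuple(f"i5-{k}" for k in range(len(samples)))
    i7 = tuple(f"i7-{k}" for k in range(len(samples)))
    return SimulationConfig(
        seed=seed,
        reads_per_library=reads,
        locus_share=share,
        switch_rate_s=s,
        indexing_mode="unique_dual",
        i5_values=i5,
        i7_values=i7,
        sample_index_map={smp: (i5[k], i7[k]) for k, smp in enumerate(samples)},
    )
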