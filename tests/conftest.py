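import pytest

from ltrarch.config import RunConfig
from ltrarch.mining import profile_from_spec
from ltrarch.pipeline import annotate_genome
from ltrarch.synth import ElementBlueprint, make_profile_library, plant_elements

ALL_STRUCTURES = ("S1", "S2", "S3", "S4", "S5", "NO_ARH")


@pytest.fixture(scope="session")
def library():
    return make_profile_library(1)


@pytest.fixture(scope="session")
def library_by_name(library):
    return {s.name: s for s in library}


@pytest.fixture(scope="session")
def profiles(library):
    return [profile_from_spec(s) for s in library]


@pytest.fixture(scope="session")
def profiles_by_name(profiles):
    return {p.name: p for p in profiles}


def make_cohort(library, profiles, *, seed=7, ltr_divergence=0.0, domain_divergence=0.0,
                degrade_native_rh=False, degrade_distal_arh=False,
                structures=ALL_STRUCTURES, genome_length=200_000, genome_id="g1"):
    """Plant one element per requested structure and annotate the genome."""
    bps = [
        ElementBlueprint(
            structure=s,
            seed=i,
            ltr_divergence=ltr_divergence,
            domain_divergence=domain_divergence,
            degrade_native_rh=degrade_native_rh and s != "NO_ARH",
            degrade_distal_arh=degrade_distal_arh and s == "S5",
        )
        for i, s in enumerate(structures)
    ]
    genome, truths = plant_elements(
        genome_length, bps, gc=0.4, seed=seed, library=library, genome_id=genome_id
    )
    annotated = annotate_genome(genome, profiles, RunConfig())
    return genome, truths, annotated


@pytest.fixture(scope="session")
def clean_cohort(library, profiles):
    """Noise-free cohort: one element per structure, annotated."""
    return make_cohort(library, profiles)


@pytest.fixture(scope="session")
def degraded_cohort(library, profiles):
    """All ARH-bearing elements with degraded native RH; S5 distal ARH degraded."""
    return make_cohort(
        library, profiles, seed=11, degrade_native_rh=True, degrade_distal_arh=True
    )


def match_truth(chain, truths):
    """The planted truth whose span contains the chain span, or None."""
    for t in truths:
        if t.span[0] <= chain.span[0] and chain.span[1] <= t.span[1]:
            return t
    return None
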