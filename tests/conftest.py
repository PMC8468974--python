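import numpy as np
import pytest

import codonlens as cl
from codonlens.synthetic import at_biased_composition


@pytest.fixture(scope="session")
def code():
    return cl.standard_code()


def ecoli_like_spec(seed=0, n_genes=200, mean_length=300):
    """Balanced bacterial-like host regime (coding GC ~0.50, preferred ~57%)."""
    return cl.SyntheticSpec(
        n_genes=n_genes,
        mean_length=mean_length,
        gc_target=0.50,
        preference_concentration=0.57,
        seed=seed,
    )


def fungal_like_spec(seed=1, n_genes=200, mean_length=300):
    """AT-rich anaerobic-fungus-like source regime (GC ~0.28, preferred ~83%)."""
    return cl.SyntheticSpec(
        n_genes=n_genes,
        mean_length=mean_length,
        gc_target=0.28,
        preference_concentration=0.83,
        preferred_map=cl.at_richest_preferred_map(),
        amino_acid_composition=at_biased_composition(),
        seed=seed,
    )


@pytest.fixture(scope="session")
def host_world(code):
    """A generated host genome with its measured profile and CAI model."""
    spec = ecoli_like_spec()
    profile_true = cl.generate_host_profile(spec, code)
    genome = cl.generate_genome(profile_true, spec, code)
    counts = cl.aggregate(genome)
    profile = cl.usage_profile(counts, code, source_label="host")
    model = cl.fit_adaptiveness(counts, code, reference_label="host")
    return {
        "spec": spec,
        "profile_true": profile_true,
        "genome": genome,
        "counts": counts,
        "profile": profile,
        "model": model,
    }


@pytest.fixture(scope="session")
def source_world(code):
    spec = fungal_like_spec()
    profile_true = cl.generate_host_profile(spec, code)
    genome = cl.generate_genome(profile_true, spec, code)
    counts = cl.aggregate(genome)
    profile = cl.usage_profile(counts, code, source_label="source")
    return {
        "spec": spec,
        "profile_true": profile_true,
        "genome": genome,
        "counts": counts,
        "profile": profile,
    }


def random_cds(rng, n_codons, code, record_id="g"):
    """A uniformly random QC-clean CDS (start, coding codons, single stop)."""
    coding = sorted(code.coding_codons)
    body = "".join(rng.choice(coding) for _ in range(n_codons))
    stop = rng.choice(sorted(code.stop_codons))
    return cl.CdsRecord(id=record_id, seq="AUG" + body + stop)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
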