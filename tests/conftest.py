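import pytest

from museomt.simdata import (default_study_trio,
                             generate_reference_trio, sample_haplotypes,
                             simulate_reads, uniform_coverage_params)


@pytest.fixture(scope="session")
def small_trio():
    """4-kb ((A,B),C) panel with the 78-bp B-specific control-region
    insertion; shared across tests that only read it."""
    return generate_reference_trio(default_study_trio(4000, seed=1))


@pytest.fixture(scope="session")
def specimen_a(small_trio):
    """One specimen from species A: haplotype, cleaned-ready raw reads and
    truth table at uniform 5x coverage."""
    ref = small_trio.references["A"]
    haps, variants = sample_haplotypes(ref, 1, 3, seed=11)
    hap_id, hap = next(iter(haps.items()))
    sim = simulate_reads(hap, uniform_coverage_params(5.0, seed=7),
                         haplotype_id=hap_id)
    return {"ref": ref, "hap_id": hap_id, "haplotype": hap,
            "variants": variants, "sim": sim}
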