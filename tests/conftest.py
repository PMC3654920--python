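import pytest

from trnahalf import (
    MixtureSpec, PreprocessParams, ReferenceSpec, FamilySpec,
    build_index, build_synthetic_reference, default_reference_spec,
    preprocess_reads, simulate_sample,
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc_indep(seq: str) -> str:
    """Reverse complement written independently of the package's helper."""
    return "".join(_COMP[b] for b in reversed(seq))


@pytest.fixture(scope="session")
def default_ref():
    """The full study-conditions reference (7 families, 101 tRNA loci)."""
    return build_synthetic_reference(default_reference_spec(seed=1))


@pytest.fixture(scope="session")
def default_index(default_ref):
    genome, _ = default_ref
    return build_index(genome, 14)


@pytest.fixture(scope="session")
def small_ref():
    """A compact (<100 kb) reference for exhaustive-oracle comparisons."""
    spec = ReferenceSpec(
        families=[
            FamilySpec("Gly", "GCC", 5),
            FamilySpec("Val", "AAC", 3),
            FamilySpec("His", "GTG", 1),
        ],
        n_mirna=6,
        n_repeat_regions=3,
        n_rrna=1,
        n_other_smrna=1,
        chrom_sizes={"chrA": 30_000, "chrB": 20_000},
        seed=11,
    )
    return build_synthetic_reference(spec)


@pytest.fixture(scope="session")
def clean_sample(default_ref):
    """One simulated, adapter-trimmed 20k-read library plus its truth table."""
    genome, track = default_ref
    sim = simulate_sample(genome, track, MixtureSpec(n_reads=20_000), seed=5,
                          sample_id="s1")
    clean, stats = preprocess_reads(sim.reads, PreprocessParams())
    return sim, clean, stats
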