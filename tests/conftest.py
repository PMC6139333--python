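import numpy as np
import pytest

from abcoal.data_model import LocusAlignment, MultilocusDataset

BASES = "ACGT"


def random_alignment(
    rng: np.random.Generator,
    n_per_species: tuple[int, ...] = (4, 4),
    length: int = 30,
    theta_like: float = 0.2,
    missing: float = 0.0,
    locus_id: str = "locus",
) -> LocusAlignment:
    """A random alignment with shared ancestry-free mutations: a random
    ancestral string with per-sequence substitutions, optional N/- noise."""
    anc = rng.integers(0, 4, size=length)
    seqs, labels = [], []
    for si, n in enumerate(n_per_species):
        for _ in range(n):
            s = anc.copy()
            nmut = rng.poisson(theta_like * length)
            for _ in range(nmut):
                p = rng.integers(length)
                s[p] = (s[p] + 1 + rng.integers(3)) % 4
            chars = [BASES[b] for b in s]
            for p in range(length):
                if rng.random() < missing:
                    chars[p] = "N-"[rng.integers(2)]
            seqs.append("".join(chars))
            labels.append(f"sp{si}")
    return LocusAlignment(locus_id=locus_id, sequences=seqs, species_labels=labels)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_dataset(rng):
    loci = [
        random_alignment(rng, (5, 4, 4), 40, locus_id=f"l{i}") for i in range(3)
    ]
    return MultilocusDataset(loci=loci, species=["sp0", "sp1", "sp2"])
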