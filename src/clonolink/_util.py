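"""Shared helpers: deterministic RNG derivation, codon sampling, translation."""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

NUCLEOTIDES = np.array(list("ACGT"))

# All 61 sense codons (stop codons excluded) so random CDR3s stay productive.
_STOPS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = np.array(
    [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT" if a + b + c not in _STOPS]
)


def derive_rng(seed: int, *labels: str) -> np.random.Generator:
    """Derive an independent generator from a root seed and string labels.

    Stable across runs and platforms: labels are hashed into the entropy pool
    of a ``SeedSequence``.
    """
    entropy = [seed] + [int.from_bytes(lab.encode(), "little") % (2**63) for lab in labels]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(NUCLEOTIDES, size=length))


def random_cdr3_nt(rng: np.random.Generator, n_codons: int) -> str:
    """Random stop-free CDR3 nucleotide sequence of ``3 * n_codons`` nt."""
    return "".join(rng.choice(SENSE_CODONS, size=n_codons))


def translate_nt(nt: str) -> str:
    return str(Seq(nt).translate())


def mutate_sequence(
    rng: np.random.Generator, seq: str, rate: float
) -> tuple[str, np.ndarray]:
    """Apply per-site substitutions at ``rate``; return (mutant, positions).

    Each selected site is replaced by one of the three other bases.
    """
    arr = np.array(list(seq))
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hit:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr), hit
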