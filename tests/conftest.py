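"""Shared fixtures and the brute-force k-mer counting oracle."""

from __future__ import annotations

import numpy as np
import pytest

from kmerdelta import GenomeSpec, simulate_genome

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def oracle_count(seq_or_seqs, k: int, min_count: int = 1, canonical: bool = True) -> dict[str, int]:
    """List every window, canonicalize by explicit comparison, tally."""
    seqs = [seq_or_seqs] if isinstance(seq_or_seqs, str) else list(seq_or_seqs)
    tally: dict[str, int] = {}
    for seq in seqs:
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if any(ch not in "ACGT" for ch in w):
                continue
            if canonical:
                rc = revcomp(w)
                w = w if w <= rc else rc
            tally[w] = tally.get(w, 0) + 1
    return {w: n for w, n in tally.items() if n >= min_count}


def random_dna(rng: np.random.Generator, length: int, with_n: bool = False) -> str:
    alphabet = "ACGTN" if with_n else "ACGT"
    probs = [0.23, 0.23, 0.23, 0.23, 0.08] if with_n else None
    return "".join(rng.choice(list(alphabet), size=length, p=probs))


@pytest.fixture(scope="session")
def small_genome():
    """A small diploid genome with all repeat families planted."""
    spec = GenomeSpec(
        unique_len=100_000,
        heterozygosity=0.005,
        satellite=(145, 300),
        te=(2_000, 8, 0.02),
        rdna=(3_000, 10),
        organelle=(50_000, 5.0),
        seed=42,
    )
    return simulate_genome(spec)
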