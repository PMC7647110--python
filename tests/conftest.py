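"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest

from bscount import build_dictionary, generate_synthetic_genome

ACGT = set("ACGT")

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp_str(seq: str) -> str:
    return "".join(COMPLEMENT.get(b, "N") for b in reversed(seq))


def naive_bs_counts(sequence: str, k: int) -> Counter:
    """Brute-force two-strand word counter (the oracle for compute_bs).

    Scans the forward strand and its reverse complement independently,
    counting every clean k-window 5'->3'.
    """
    counts: Counter = Counter()
    sequence = sequence.upper()
    for strand in (sequence, revcomp_str(sequence)):
        for i in range(len(strand) - k + 1):
            word = strand[i : i + k]
            if set(word) <= ACGT:
                counts[word] += 1
    return counts


@pytest.fixture(scope="session")
def dict1():
    return build_dictionary(1)


@pytest.fixture(scope="session")
def dict2():
    return build_dictionary(2)


@pytest.fixture(scope="session")
def dict3():
    return build_dictionary(3)


@pytest.fixture(scope="session")
def dict6():
    return build_dictionary(6)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_genomes():
    """Five 8 kb synthetic genomes shared across tests (read-only)."""
    rng = np.random.default_rng(42)
    return [generate_synthetic_genome(8000, rng, id=f"g{i}") for i in range(5)]
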