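"""Barcode spectra: reverse-complement-symmetric k-mer count vectors.

The *compositional spectrum* (CS) of a DNA sequence is the vector of
counts of every length-k word over {A, C, G, T} read 5'->3'.  Because the
strand of origin of a sequenced word is unknown, the spectra here are
symmetrized over both strands: the *barcode spectrum* (BS) assigns to each
word ``w`` the number of occurrences of ``w`` plus the number of
occurrences of ``revcomp(w)`` on the forward strand (equivalently, the
count of ``w`` over both strands read 5'->3').  A BS is therefore a
4^k-dimensional nonnegative integer vector invariant under reverse
complementing the input sequence.

Words are ordered lexicographically with A < C < G < T; position 0 is
``AAA...A`` and position 4^k - 1 is ``TTT...T``.  Counts are kept as raw
integers, never frequencies: linear (in)dependence between spectra — the
property everything downstream relies on — is invariant to scale, and
integer counts allow exact-arithmetic cross-checks.

Any k-window containing a non-ACGT letter (N and other IUPAC ambiguity
codes are tolerated on input) contributes to neither strand, so for a
clean sequence of length L the total BS mass is exactly 2*(L - k + 1).
"""

from __future__ import annotations

import gzip
import itertools
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "KmerDictionary",
    "GenomeRecord",
    "BarcodeSpectrum",
    "SpectrumError",
    "build_dictionary",
    "compute_bs",
    "pairwise_angles",
    "read_fasta",
    "reverse_complement",
    "write_spectra_matrix",
    "write_spectra_long",
    "read_spectra_matrix",
]

BASES = "ACGT"

#: byte -> 2-bit code; 4 marks a non-ACGT letter (window is skipped)
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


class SpectrumError(ValueError):
    """Raised for invalid spectra inputs (bad k, short sequence, ...)."""


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a nucleotide string (case preserved)."""
    return sequence.translate(_COMPLEMENT)[::-1]


def encode_sequence(sequence: str) -> np.ndarray:
    """Map a nucleotide string to uint8 codes A,C,G,T -> 0..3, other -> 4."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def decode_sequence(codes: np.ndarray) -> str:
    """Inverse of :func:`encode_sequence` for clean (0..3) codes."""
    return _DECODE[codes].tobytes().decode("ascii")


@dataclass(frozen=True)
class KmerDictionary:
    """The word support of a spectrum: all 4^k words in lexicographic order.

    Parameters
    ----------
    k : int
        Word length.  The ambient space dimension is ``4**k`` (4096 for the
        default k=6).
    """

    k: int

    def __post_init__(self) -> None:
        if not isinstance(self.k, (int, np.integer)) or not 1 <= self.k <= 12:
            raise SpectrumError(f"word length k must be an integer in [1, 12], got {self.k!r}")

    @property
    def size(self) -> int:
        return 4**self.k

    @cached_property
    def words(self) -> tuple[str, ...]:
        return tuple("".join(p) for p in itertools.product(BASES, repeat=self.k))

    @cached_property
    def index(self) -> dict[str, int]:
        return {w: i for i, w in enumerate(self.words)}

    @cached_property
    def revcomp_permutation(self) -> np.ndarray:
        """perm[i] = index of the reverse complement of word i (an involution)."""
        x = np.arange(self.size, dtype=np.int64)
        rc = np.zeros_like(x)
        for _ in range(self.k):
            rc = rc * 4 + (3 - x % 4)
            x //= 4
        return rc

    def word_index(self, word: str) -> int:
        try:
            return self.index[word.upper()]
        except KeyError:
            raise SpectrumError(f"{word!r} is not a length-{self.k} ACGT word") from None


def build_dictionary(k: int = 6) -> KmerDictionary:
    """Build the k-mer dictionary (4^k words, lexicographic, A<C<G<T)."""
    return KmerDictionary(k)


@dataclass(frozen=True)
class GenomeRecord:
    """A named nucleotide sequence (a genome, or any long fragment)."""

    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BarcodeSpectrum:
    """A 4^k count vector over both strands of one source sequence."""

    dictionary: KmerDictionary
    counts: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (self.dictionary.size,):
            raise SpectrumError(
                f"counts must have shape ({self.dictionary.size},), got {counts.shape}"
            )
        if np.any(counts < 0):
            raise SpectrumError("spectrum counts must be nonnegative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def count(self, word: str) -> int:
        return int(self.counts[self.dictionary.word_index(word)])


def _counts_from_codes(codes: np.ndarray, dictionary: KmerDictionary) -> np.ndarray:
    """BS count vector from a 0..4 code array; windows touching code 4 are skipped."""
    k = dictionary.k
    if codes.size < k:
        raise SpectrumError(f"sequence of length {codes.size} is shorter than k={k}")
    windows = sliding_window_view(codes, k)
    valid = (windows < 4).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    word_codes = windows[valid].astype(np.int64) @ powers
    forward = np.bincount(word_codes, minlength=dictionary.size)
    return forward + forward[dictionary.revcomp_permutation]


def compute_bs(record: GenomeRecord, dictionary: KmerDictionary) -> BarcodeSpectrum:
    """Barcode spectrum of one sequence.

    ``counts[w]`` is the number of occurrences of ``w`` plus the number of
    occurrences of ``revcomp(w)`` on the forward strand; the result is
    symmetric under the reverse-complement permutation and sums to
    ``2*(L - k + 1)`` for a clean length-L sequence.
    """
    if not record.sequence:
        raise SpectrumError(f"record {record.id!r} has an empty sequence")
    if len(record.sequence) < dictionary.k:
        raise SpectrumError(
            f"record {record.id!r} is shorter ({len(record.sequence)}) than k={dictionary.k}"
        )
    counts = _counts_from_codes(encode_sequence(record.sequence), dictionary)
    return BarcodeSpectrum(dictionary, counts, record.id)


def pairwise_angles(spectra: Sequence[BarcodeSpectrum]) -> np.ndarray:
    """Angles (radians) between all unordered pairs of spectra.

    For nonnegative count vectors every angle lies in [0, pi/2]; two long
    unrelated genomes sit far from 0, which is what makes their spectra
    usable as linearly independent signatures.
    """
    if len(spectra) < 2:
        raise SpectrumError("need at least two spectra for pairwise angles")
    dictionary = spectra[0].dictionary
    if any(s.dictionary.k != dictionary.k for s in spectra):
        raise SpectrumError("all spectra must share one dictionary")
    matrix = np.asarray([s.counts for s in spectra], dtype=float)
    norms = np.linalg.norm(matrix, axis=1)
    if np.any(norms == 0):
        raise SpectrumError("angle undefined for an all-zero spectrum")
    unit = matrix / norms[:, None]
    cos = np.clip(unit @ unit.T, -1.0, 1.0)
    iu = np.triu_indices(len(spectra), k=1)
    return np.arccos(cos[iu])


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read FASTA (plain or gzip) into records; ids are the first header token."""
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    try:
        with opener(path, "rt") as handle:
            records = [
                GenomeRecord(id=rec.id, sequence=str(rec.seq).upper())
                for rec in SeqIO.parse(handle, "fasta")
            ]
    except OSError as exc:
        raise SpectrumError(f"cannot read FASTA {path}: {exc}") from exc
    if not records:
        raise SpectrumError(f"no FASTA records found in {path}")
    return records


def spectra_frame(spectra: Iterable[BarcodeSpectrum]) -> pd.DataFrame:
    """Wide DataFrame: one row per source_id, one column per word."""
    spectra = list(spectra)
    if not spectra:
        raise SpectrumError("no spectra to tabulate")
    dictionary = spectra[0].dictionary
    return pd.DataFrame(
        np.asarray([s.counts for s in spectra]),
        index=pd.Index([s.source_id for s in spectra], name="source_id"),
        columns=list(dictionary.words),
    )


def write_spectra_matrix(spectra: Iterable[BarcodeSpectrum], path: str | Path) -> None:
    """Write the wide words-by-source TSV (header row of 4^k words)."""
    spectra_frame(spectra).to_csv(path, sep="\t")


def write_spectra_long(spectra: Iterable[BarcodeSpectrum], path: str | Path) -> None:
    """Long TSV (source_id, word, count); intended for small k only."""
    frame = spectra_frame(spectra)
    long = frame.stack().rename_axis(["source_id", "word"]).rename("count").reset_index()
    long.to_csv(path, sep="\t", index=False)


def read_spectra_matrix(path: str | Path) -> tuple[pd.DataFrame, KmerDictionary]:
    """Read a wide spectra TSV back; k is inferred from the column count."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    n_cols = frame.shape[1]
    k = round(np.log(n_cols) / np.log(4)) if n_cols else 0
    if n_cols == 0 or 4**k != n_cols:
        raise SpectrumError(f"column count {n_cols} is not a power of 4")
    return frame, build_dictionary(k)
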