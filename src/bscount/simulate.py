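"""Simulation of metagenome samples and their barcode spectra.

A *sample* of a medium is a random draw of organisms from a large parent
population, so the copy number of each genome fluctuates independently
from sample to sample.  Two multiplicity models are supported:

* ``normal`` — each genome's copy number is an integer-rounded draw from
  Normal(m, sigma), clipped below at zero;
* ``discrete`` — each genome j has a finite value set a_j of nonnegative
  integers and its copy number is drawn from it (uniformly, or with
  supplied probabilities), independently of the other genomes.

Sequencing loss and error are emulated at the spectrum level, the way the
pooled k-mer data would look: each genome g gets a *fragment set*
G(g, f) of spectra of error-bearing fragments covering a fraction f of
the genome, and a sample spectrum is the sum, over genomes, of t_g
fragment spectra chosen uniformly with replacement (t_g = the genome's
copy number in that sample).  Letter errors are independent substitutions
at a fixed per-letter rate (no indels).

Fragments are built two ways: ``random_window`` takes contiguous windows
of length round(f*L) at uniform random starts, treating the genome as
circular (bacterial chromosomes usually are); ``partition_exclusion``
cuts the genome into 10 equal parts and forms the 10 concatenations that
each omit one part (f = 0.9, pairwise difference 20%).

Synthetic genomes are i.i.d. uniform ACGT strings.  At the default length
of 50 kb their 6-mer spectra are pairwise far from collinear — the same
linear-independence premise that holds for real bacterial genomes — while
staying cheap enough for simulation studies at hundreds of replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .spectra import (
    BarcodeSpectrum,
    GenomeRecord,
    KmerDictionary,
    SpectrumError,
    _counts_from_codes,
    build_dictionary,
    decode_sequence,
    encode_sequence,
    read_spectra_matrix,
    spectra_frame,
)

__all__ = [
    "MultiplicityModel",
    "FragmentSet",
    "SampleSet",
    "generate_synthetic_genome",
    "mutate_letters",
    "make_fragment_set",
    "draw_multiplicities",
    "synthesize_sample",
    "generate_sample_set",
    "iter_samples",
]

#: A vector of genome multiplicities (VGM): one nonnegative integer copy
#: number per genome.  Represented as a 1-D numpy integer array.
VGM = np.ndarray


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    return rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)


@dataclass(frozen=True)
class MultiplicityModel:
    """How per-genome copy numbers fluctuate across samples.

    Use the :meth:`normal` / :meth:`discrete` constructors rather than the
    raw dataclass.
    """

    kind: str
    m: float | None = None
    sigma: float | None = None
    value_sets: tuple[tuple[int, ...], ...] | None = None
    probs: tuple[tuple[float, ...], ...] | None = None

    def __post_init__(self) -> None:
        if self.kind == "normal":
            if self.m is None or self.m <= 0:
                raise ValueError("normal model requires mean copy number m > 0")
            if self.sigma is None or self.sigma < 0:
                raise ValueError("normal model requires sigma >= 0")
        elif self.kind == "discrete":
            if not self.value_sets:
                raise ValueError("discrete model requires nonempty value sets")
            for vs in self.value_sets:
                if len(vs) == 0:
                    raise ValueError("every value set must be nonempty")
                if any((not float(v).is_integer()) or v < 0 for v in vs):
                    raise ValueError("value sets must contain nonnegative integers")
            if self.probs is not None:
                if len(self.probs) != len(self.value_sets):
                    raise ValueError("one probability row per value set required")
                for vs, pr in zip(self.value_sets, self.probs):
                    if len(pr) != len(vs):
                        raise ValueError("probability row length must match its value set")
                    if not np.isclose(sum(pr), 1.0) or any(p < 0 for p in pr):
                        raise ValueError("probability rows must be nonnegative and sum to 1")
        else:
            raise ValueError(f"unknown multiplicity model kind {self.kind!r}")

    @classmethod
    def normal(cls, m: float, sigma: float) -> "MultiplicityModel":
        """Integer-rounded Normal(m, sigma) copy numbers, clipped at 0."""
        return cls(kind="normal", m=m, sigma=sigma)

    @classmethod
    def discrete(
        cls,
        value_sets: Sequence[Sequence[int]],
        probs: Sequence[Sequence[float]] | None = None,
    ) -> "MultiplicityModel":
        """Independent draws from per-genome finite value sets."""
        return cls(
            kind="discrete",
            value_sets=tuple(tuple(int(v) for v in vs) for vs in value_sets),
            probs=None if probs is None else tuple(tuple(float(p) for p in pr) for pr in probs),
        )

    @classmethod
    def uniform_discrete(cls, values: Sequence[int], n_genomes: int) -> "MultiplicityModel":
        """Same value set, uniform probabilities, for every genome."""
        return cls.discrete([tuple(values)] * n_genomes)


@dataclass
class FragmentSet:
    """The spectra G(g, f) of error-bearing fragments of one genome."""

    genome_id: str
    coverage: float
    fragment_spectra: list[BarcodeSpectrum]
    scheme: str = "random_window"

    def __post_init__(self) -> None:
        ks = {s.dictionary.k for s in self.fragment_spectra}
        if len(ks) > 1:
            raise ValueError("all fragment spectra must share one dictionary")

    def __len__(self) -> int:
        return len(self.fragment_spectra)

    @property
    def matrix(self) -> np.ndarray:
        return np.asarray([s.counts for s in self.fragment_spectra])


@dataclass
class SampleSet:
    """An N_samples x 4^k matrix of per-sample barcode spectra."""

    matrix: np.ndarray
    sample_ids: list[str]
    dictionary: KmerDictionary
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != self.dictionary.size:
            raise ValueError(
                f"matrix must be 2-D with {self.dictionary.size} columns, got {self.matrix.shape}"
            )
        if len(self.sample_ids) != self.matrix.shape[0]:
            raise ValueError("one sample id per row required")
        if np.any(self.matrix < 0):
            raise ValueError("sample spectra must be nonnegative")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    def subset(self, n: int) -> "SampleSet":
        """The first n samples (in draw order)."""
        return SampleSet(self.matrix[:n], self.sample_ids[:n], self.dictionary, self.provenance)

    def to_tsv(self, path) -> None:
        import pandas as pd

        frame = pd.DataFrame(
            self.matrix,
            index=pd.Index(self.sample_ids, name="source_id"),
            columns=list(self.dictionary.words),
        )
        frame.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "SampleSet":
        frame, dictionary = read_spectra_matrix(path)
        return cls(frame.to_numpy(), [str(i) for i in frame.index], dictionary)


def generate_synthetic_genome(
    length: int,
    rng_seed: np.random.Generator | int | None = None,
    id: str | None = None,
    markov_order: int = 2,
    composition_alpha: float = 5.0,
) -> GenomeRecord:
    """A random genome with a genome-specific oligonucleotide composition.

    Each genome is sampled from its own random Markov chain of order
    ``markov_order`` whose conditional letter distributions are drawn
    from a symmetric Dirichlet(``composition_alpha``).  This mimics the
    defining feature of real genomes that the whole approach rests on:
    distinct species differ *systematically* in oligonucleotide usage
    (GC content alone spans roughly 25-75% across bacteria, with further
    di- and trinucleotide biases on top), so their k-mer spectra point in
    well-separated directions and are pairwise far from collinear.  With
    plain uniform i.i.d. letters all spectra would collapse onto the
    flat-composition direction and differ only by sampling noise, which
    no pair of real species does; order-0 bias alone lives on a
    3-parameter manifold and cannot make many spectra simultaneously
    well-separated.  The defaults (order 2, alpha=5) give a GC-content
    spread of about +-0.1 and a pairwise-angle distribution between
    distinct genomes' 6-mer spectra that is broad and bounded away from
    zero, as observed for real bacterial libraries.

    ``markov_order=0`` recovers i.i.d. letters (still with a random
    genome-specific composition).  Reproducible for a fixed seed.
    """
    if length < 1:
        raise ValueError(f"genome length must be positive, got {length}")
    if markov_order < 0:
        raise ValueError("markov_order must be >= 0")
    rng = _as_rng(rng_seed)
    if markov_order == 0:
        probs = rng.dirichlet([composition_alpha] * 4)
        codes = rng.choice(4, size=length, p=probs).astype(np.uint8)
        return GenomeRecord(id=id or f"synth{length}", sequence=decode_sequence(codes))
    n_states = 4**markov_order
    transition = rng.dirichlet([composition_alpha] * 4, size=n_states)
    # pre-draw a pool of conditional letters per state, then walk the chain
    pools = [rng.choice(4, size=length, p=transition[s]).tolist() for s in range(n_states)]
    taken = [0] * n_states
    out = rng.integers(0, 4, size=markov_order).tolist()
    state = 0
    for c in out:
        state = (state * 4 + c) % n_states
    mask = n_states // 4
    for _ in range(length - markov_order):
        nxt = pools[state][taken[state]]
        taken[state] += 1
        out.append(nxt)
        state = (state % mask) * 4 + nxt if markov_order > 1 else nxt
    codes = np.asarray(out[:length], dtype=np.uint8)
    return GenomeRecord(id=id or f"synth{length}", sequence=decode_sequence(codes))


def _mutate_codes(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each clean letter with prob `rate` by a different letter."""
    if not 0 <= rate < 1:
        raise ValueError(f"substitution rate must lie in [0, 1), got {rate}")
    if rate == 0:
        return codes
    out = codes.copy()
    hit = np.flatnonzero((rng.random(codes.size) < rate) & (codes < 4))
    # adding 1..3 mod 4 guarantees the new letter differs from the original
    out[hit] = (out[hit] + rng.integers(1, 4, size=hit.size, dtype=np.uint8)) % 4
    return out


def mutate_letters(
    sequence: str, rate: float, rng: np.random.Generator | int | None = None
) -> str:
    """Independent per-letter substitutions at probability `rate`.

    Non-ACGT letters are left untouched; length is always preserved.
    """
    rng = _as_rng(rng)
    codes = encode_sequence(sequence)
    mutated = _mutate_codes(codes, rate, rng)
    if np.any(codes >= 4):
        # splice mutated clean letters back around the ambiguous ones
        out = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8).copy()
        clean = codes < 4
        out[clean] = np.frombuffer(b"ACGT", dtype=np.uint8)[mutated[clean]]
        return out.tobytes().decode("ascii")
    return decode_sequence(mutated)


def make_fragment_set(
    genome: GenomeRecord,
    coverage: float,
    n_fragments: int = 20,
    scheme: str = "random_window",
    letter_error_rate: float = 1e-3,
    rng: np.random.Generator | int | None = None,
    dictionary: KmerDictionary | None = None,
) -> FragmentSet:
    """Build G(g, f): spectra of `n_fragments` error-bearing fragments.

    ``random_window`` draws contiguous windows of length round(f*L) at
    uniform random starts on the circular genome.  ``partition_exclusion``
    (f=0.9, n_fragments=10) cuts the genome into 10 equal parts and takes
    the 10 concatenations each omitting one part.
    """
    rng = _as_rng(rng)
    dictionary = dictionary or build_dictionary(6)
    if not 0 < coverage <= 1:
        raise ValueError(f"coverage must lie in (0, 1], got {coverage}")
    codes = encode_sequence(genome.sequence)
    L = codes.size
    spectra: list[BarcodeSpectrum] = []

    if scheme == "random_window":
        frag_len = int(round(coverage * L))
        if frag_len < dictionary.k:
            raise ValueError(
                f"fragment length {frag_len} (f={coverage}, L={L}) is below k={dictionary.k}"
            )
        doubled = np.concatenate([codes, codes])
        # full coverage must reproduce the genome spectrum exactly, so do
        # not rotate (a rotated circular window would add junction words)
        starts = (
            np.zeros(n_fragments, dtype=np.int64)
            if frag_len >= L
            else rng.integers(0, L, size=n_fragments)
        )
        for i, start in enumerate(starts):
            frag = _mutate_codes(doubled[start : start + frag_len], letter_error_rate, rng)
            counts = _counts_from_codes(frag, dictionary)
            spectra.append(
                BarcodeSpectrum(dictionary, counts, f"{genome.id}|w{i}@{start}")
            )
    elif scheme == "partition_exclusion":
        if n_fragments != 10 or abs(coverage - 0.9) > 1e-9:
            raise ValueError("partition_exclusion requires coverage=0.9 and n_fragments=10")
        parts = np.array_split(codes, 10)
        for i in range(10):
            frag = np.concatenate([p for j, p in enumerate(parts) if j != i])
            frag = _mutate_codes(frag, letter_error_rate, rng)
            counts = _counts_from_codes(frag, dictionary)
            spectra.append(BarcodeSpectrum(dictionary, counts, f"{genome.id}|excl{i}"))
    else:
        raise ValueError(f"unknown fragment scheme {scheme!r}")

    return FragmentSet(genome.id, coverage, spectra, scheme)


def draw_multiplicities(
    model: MultiplicityModel, n_genomes: int, rng: np.random.Generator | int | None = None
) -> VGM:
    """One vector of genome multiplicities (independent across genomes)."""
    if n_genomes < 1:
        raise ValueError("need at least one genome")
    rng = _as_rng(rng)
    if model.kind == "normal":
        draws = np.rint(rng.normal(model.m, model.sigma, size=n_genomes))
        return np.clip(draws, 0, None).astype(np.int64)
    value_sets = model.value_sets
    if len(value_sets) == 1 and n_genomes > 1:
        value_sets = value_sets * n_genomes
    if len(value_sets) != n_genomes:
        raise ValueError(
            f"model has {len(model.value_sets)} value sets but {n_genomes} genomes requested"
        )
    out = np.empty(n_genomes, dtype=np.int64)
    for i, vs in enumerate(value_sets):
        p = None if model.probs is None else model.probs[i]
        out[i] = rng.choice(np.asarray(vs), p=p)
    return out


def synthesize_sample(
    fragment_sets: Sequence[FragmentSet],
    vgm: VGM,
    rng: np.random.Generator | int | None = None,
    sample_id: str = "sample",
) -> BarcodeSpectrum:
    """One sample spectrum: sum of t_g random fragment spectra per genome.

    Each of the t_g copies of genome g contributes one fragment spectrum
    chosen uniformly with replacement from G(g, f); zero multiplicity
    contributes nothing.
    """
    vgm = np.asarray(vgm)
    if len(fragment_sets) != vgm.size:
        raise ValueError(
            f"{len(fragment_sets)} fragment sets but multiplicity vector of length {vgm.size}"
        )
    rng = _as_rng(rng)
    dictionary = fragment_sets[0].fragment_spectra[0].dictionary
    counts = np.zeros(dictionary.size, dtype=np.int64)
    for fs, t in zip(fragment_sets, vgm):
        if t > 0:
            picks = rng.integers(0, len(fs), size=int(t))
            for j in picks:
                counts += fs.fragment_spectra[j].counts
    return BarcodeSpectrum(dictionary, counts, sample_id)


def _build_fragment_sets(
    genomes: Sequence[GenomeRecord],
    coverage: float,
    n_fragments: int,
    scheme: str,
    letter_error_rate: float,
    rng: np.random.Generator,
    dictionary: KmerDictionary,
) -> list[FragmentSet]:
    return [
        make_fragment_set(
            g, coverage, n_fragments, scheme, letter_error_rate, rng, dictionary
        )
        for g in genomes
    ]


def iter_samples(
    fragment_sets: Sequence[FragmentSet],
    model: MultiplicityModel,
    rng: np.random.Generator | int | None = None,
) -> Iterator[BarcodeSpectrum]:
    """Endless stream of independent sample spectra (for sequential basis building)."""
    rng = _as_rng(rng)
    i = 0
    while True:
        vgm = draw_multiplicities(model, len(fragment_sets), rng)
        yield synthesize_sample(fragment_sets, vgm, rng, sample_id=f"s{i}")
        i += 1


def generate_sample_set(
    genomes: Sequence[GenomeRecord],
    model: MultiplicityModel,
    coverage: float = 0.75,
    n_samples: int = 50,
    rng_seed: np.random.Generator | int | None = None,
    n_fragments: int = 20,
    scheme: str = "random_window",
    letter_error_rate: float = 1e-3,
    k: int = 6,
) -> SampleSet:
    """Simulate a full sample set for a metagenome of the given genomes.

    Fragment sets G(g, f) are built once per genome; each of the
    `n_samples` rows then draws an independent multiplicity vector and
    sums the corresponding randomly chosen fragment spectra.
    """
    if not genomes:
        raise ValueError("need at least one genome")
    rng = _as_rng(rng_seed)
    dictionary = build_dictionary(k)
    fragment_sets = _build_fragment_sets(
        genomes, coverage, n_fragments, scheme, letter_error_rate, rng, dictionary
    )
    rows, ids = [], []
    for i in range(n_samples):
        vgm = draw_multiplicities(model, len(genomes), rng)
        spec = synthesize_sample(fragment_sets, vgm, rng, sample_id=f"s{i}")
        rows.append(spec.counts)
        ids.append(spec.source_id)
    provenance = {
        "n_genomes": len(genomes),
        "genome_ids": [g.id for g in genomes],
        "model": {
            "kind": model.kind,
            "m": model.m,
            "sigma": model.sigma,
            "value_sets": model.value_sets,
        },
        "coverage": coverage,
        "n_fragments": n_fragments,
        "scheme": scheme,
        "letter_error_rate": letter_error_rate,
        "n_samples": n_samples,
        "k": k,
        "rng_seed": rng_seed if not isinstance(rng_seed, np.random.Generator) else "generator",
    }
    return SampleSet(np.asarray(rows), ids, dictionary, provenance)
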