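"""Counting unknown genomes with virtual samples from a known-genome library.

If some genomes are already available as barcode spectra (a library),
the metagenome question can be sharpened: how many genomes in the medium
are *not* in the library?  Virtual samples are fabricated from the
spectra of selected library genomes and appended to the real samples;
running the genome-count estimator on the combined set yields a total
dimension Z that counts the metagenome genomes plus the library genomes
absent from it.  Subtracting the number of distinct library genomes added
(p1 present + p2 absent) leaves the number of unknown genomes,
Z - (p1 + p2) = p - p1.

Four virtual-sample designs are supported (1: one clean library spectrum
per sample; 2: random clean mixtures; 3: one error-bearing fragment
spectrum per sample; 4: random error-bearing mixtures).  Clean singles
work best: mixtures fold several genome directions into each row, and
errors blur the library directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dimension import DimensionEstimate, estimate_genome_count
from .simulate import SampleSet, make_fragment_set, _as_rng
from .spectra import BarcodeSpectrum, GenomeRecord, KmerDictionary, compute_bs

__all__ = [
    "SpectraLibrary",
    "VirtualDesign",
    "build_virtual_samples",
    "count_unknown_genomes",
]


@dataclass
class SpectraLibrary:
    """Known genomes as full-genome barcode spectra (plus sequences if kept).

    Sequences are only needed for the error-bearing designs (3 and 4),
    which rebuild fragment spectra on the fly.
    """

    entries: dict[str, BarcodeSpectrum]
    dictionary: KmerDictionary
    records: dict[str, GenomeRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gid, spec in self.entries.items():
            if spec.dictionary.k != self.dictionary.k:
                raise ValueError(f"library entry {gid!r} uses a different dictionary")

    @classmethod
    def from_genomes(
        cls, genomes: Sequence[GenomeRecord], dictionary: KmerDictionary
    ) -> "SpectraLibrary":
        ids = [g.id for g in genomes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate genome ids in library")
        entries = {g.id: compute_bs(g, dictionary) for g in genomes}
        return cls(entries, dictionary, {g.id: g for g in genomes})

    def __contains__(self, gid: str) -> bool:
        return gid in self.entries

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class VirtualDesign:
    """Recipe for fabricating virtual samples from library spectra.

    design: ``single_clean`` | ``mixture_clean`` | ``single_error`` |
    ``mixture_error`` (the numbered designs 1-4).  Mixtures include each
    selected genome with probability 1/2 (empty mixtures are redrawn) at
    an integer coefficient drawn uniformly from ``mixture_size_range``.
    Error designs replace each genome spectrum by the spectrum of one
    error-bearing fragment at the given coverage and letter-error rate.
    """

    design: str = "single_clean"
    n_virtual: int | None = None
    mixture_size_range: tuple[int, int] = (1, 3)
    include_prob: float = 0.5
    coverage: float = 0.75
    letter_error_rate: float = 1e-3

    _NAMES = ("single_clean", "mixture_clean", "single_error", "mixture_error")

    def __post_init__(self) -> None:
        if self.design not in self._NAMES:
            raise ValueError(
                f"design must be one of {self._NAMES}, got {self.design!r}"
            )
        lo, hi = self.mixture_size_range
        if not (1 <= lo <= hi):
            raise ValueError("mixture coefficients must satisfy 1 <= lo <= hi")

    @classmethod
    def numbered(cls, number: int, **kwargs) -> "VirtualDesign":
        """Designs by their conventional numbers 1-4."""
        try:
            return cls(design=cls._NAMES[number - 1], **kwargs)
        except IndexError:
            raise ValueError(f"design number must be 1-4, got {number}") from None

    @property
    def is_mixture(self) -> bool:
        return self.design.startswith("mixture")

    @property
    def with_error(self) -> bool:
        return self.design.endswith("error")


def _error_spectrum(
    library: SpectraLibrary, gid: str, design: VirtualDesign, rng: np.random.Generator
) -> np.ndarray:
    record = library.records.get(gid)
    if record is None:
        raise ValueError(
            f"error-bearing design needs the sequence of {gid!r}; "
            "build the library with from_genomes"
        )
    fs = make_fragment_set(
        record,
        design.coverage,
        n_fragments=1,
        letter_error_rate=design.letter_error_rate,
        rng=rng,
        dictionary=library.dictionary,
    )
    return fs.fragment_spectra[0].counts


def build_virtual_samples(
    library: SpectraLibrary,
    selected_ids: Sequence[str],
    design: VirtualDesign,
    rng: np.random.Generator | int | None = None,
) -> SampleSet:
    """Fabricate virtual sample spectra from the selected library genomes.

    Single designs produce one row per selected genome (cycling if
    n_virtual is larger, so every genome is always covered); mixture
    designs default to twice as many rows as genomes.
    """
    rng = _as_rng(rng)
    selected = list(selected_ids)
    if not selected:
        raise ValueError("no library genomes selected")
    unknown = [g for g in selected if g not in library]
    if unknown:
        raise ValueError(f"ids not in library: {unknown}")
    if len(set(selected)) != len(selected):
        raise ValueError("duplicate ids in selection")

    if design.is_mixture:
        # error-bearing mixtures are all linearly independent, so extra
        # rows help; clean mixtures carry no information beyond the
        # number of genomes and extra rows only create an exact-rank
        # degeneracy inside the noisy stack
        n_virtual = design.n_virtual or (
            2 * len(selected) if design.with_error else len(selected)
        )
    else:
        n_virtual = design.n_virtual or len(selected)
        if n_virtual < len(selected):
            raise ValueError(
                "single-genome designs need at least one virtual sample per genome"
            )

    rows, ids = [], []
    for i in range(n_virtual):
        if design.is_mixture:
            while True:
                included = [g for g in selected if rng.random() < design.include_prob]
                if included:
                    break
            lo, hi = design.mixture_size_range
            row = np.zeros(library.dictionary.size, dtype=np.int64)
            for gid in included:
                coef = int(rng.integers(lo, hi + 1))
                base = (
                    _error_spectrum(library, gid, design, rng)
                    if design.with_error
                    else library.entries[gid].counts
                )
                row = row + coef * base
            ids.append(f"virt{i}|mix{len(included)}")
        else:
            gid = selected[i % len(selected)]
            row = (
                _error_spectrum(library, gid, design, rng)
                if design.with_error
                else library.entries[gid].counts.copy()
            )
            ids.append(f"virt{i}|{gid}")
        rows.append(np.asarray(row))
    provenance = {
        "design": design.design,
        "selected_ids": selected,
        "n_virtual": n_virtual,
    }
    return SampleSet(np.asarray(rows), ids, library.dictionary, provenance)


def count_unknown_genomes(
    real: SampleSet,
    virtual: SampleSet | None,
    n_library_added: int,
    method: str = "auto",
    rescale_virtual: bool = True,
    virtual_scale: float = 0.2,
    return_estimate: bool = False,
) -> int | tuple[int, DimensionEstimate]:
    """Number of metagenome genomes absent from the library.

    Stacks real and virtual rows, estimates the total dimension Z, and
    returns Z - n_library_added, clamped at zero (a negative difference
    means the estimate undershot and is reported as 0 with a note).

    ``rescale_virtual`` scales every virtual row to ``virtual_scale``
    times the median real-row Euclidean norm before stacking.  The scale
    of a sample row is arbitrary (linear dependence is scale-invariant),
    but the PCA residual geometry is not: a real sample sums on the
    order of m * p fragment spectra while a virtual sample holds a
    single genome spectrum, so unscaled virtual directions can sit
    orders of magnitude below the real rows and drown in their
    sequencing noise.  The default 0.2 aims at the amplitude of a single
    genome's contribution to a real sample: well above the noise floor,
    yet small enough not to dwarf the genome signal or amplify the
    virtual rows' own errors into spurious dimensions.
    """
    if n_library_added < 0:
        raise ValueError("n_library_added must be >= 0")
    if virtual is None or virtual.n_samples == 0:
        if n_library_added:
            raise ValueError("n_library_added > 0 but no virtual samples supplied")
        combined = real
    else:
        if virtual.dictionary.k != real.dictionary.k:
            raise ValueError("real and virtual sample sets use different dictionaries")
        vmat = virtual.matrix.astype(float)
        if rescale_virtual:
            if virtual_scale <= 0:
                raise ValueError("virtual_scale must be positive")
            target = virtual_scale * float(
                np.median(np.linalg.norm(real.matrix.astype(float), axis=1))
            )
            norms = np.linalg.norm(vmat, axis=1)
            if np.any(norms == 0):
                raise ValueError("virtual sample with an all-zero spectrum")
            vmat = vmat * (target / norms)[:, None]
        combined = SampleSet(
            np.vstack([real.matrix.astype(float), vmat]),
            list(real.sample_ids) + list(virtual.sample_ids),
            real.dictionary,
            {"real": real.provenance, "virtual": virtual.provenance},
        )
    if method == "auto" and combined is not real:
        # decide exact vs PCA on the real data alone: a clean but
        # rank-deficient virtual block must not drag noisy real samples
        # onto the exact-rank path
        from .dimension import incremental_rank

        real_rank = incremental_rank(real.matrix)
        method = "rank" if real_rank < real.n_samples else "pca"
    estimate = estimate_genome_count(
        combined, method=method, prefer_peak=(method == "pca")
    )
    count = estimate.genome_count - n_library_added
    if count < 0:
        estimate.notes.append(
            f"estimated total dimension {estimate.genome_count} fell below the "
            f"{n_library_added} library genomes added; clamping to 0"
        )
        count = 0
    return (count, estimate) if return_estimate else count
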