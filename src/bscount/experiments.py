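"""Scripted simulation experiments at configurable (desk) scale.

These reproduce, at reduced replicate counts, the simulation studies that
characterize the method: the probability that n random samples of an
n-genome metagenome are linearly dependent (with its logistic fit), the
reliability of genome-count recovery as samples accumulate, and the
comparison of virtual-sample designs for counting unknown genomes.

Linear dependence of samples is tested on the integer multiplicity
matrices over exact rationals: when the genome spectra themselves are
linearly independent (the working premise, and a checked property of the
synthetic genomes), n sample spectra are dependent exactly when their
n x n multiplicity matrix is singular, so the reduction is lossless and
free of floating-point tolerance artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .dimension import NoMarkerPattern, estimate_genome_count
from .exactrank import integer_rank
from .simulate import (
    MultiplicityModel,
    draw_multiplicities,
    generate_sample_set,
    generate_synthetic_genome,
)
from .virtual import SpectraLibrary, VirtualDesign, build_virtual_samples, count_unknown_genomes

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "run_dependence_curve",
    "exact_dependence_probability",
    "fit_logistic",
    "run_reliability_curve",
    "run_virtual_table",
]


@dataclass
class ExperimentConfig:
    """Flat configuration for the scripted experiments.

    Defaults mirror the simulation study conditions: 50 kb genomes,
    Normal(10, 3) multiplicities, 75% coverage fragments with a 1/1000
    letter-error rate, 20 fragments per genome.
    """

    experiment: str = "reliability_curve"
    replicates: int = 50
    seed: int = 0
    n_genomes: int = 10
    genome_length: int = 50_000
    m: float = 10.0
    sigma: float = 3.0
    sigmas: tuple[float, ...] = (3.0,)
    coverage: float = 0.75
    n_fragments: int = 20
    letter_error_rate: float = 1e-3
    k: int = 6
    n_samples_min: int = 5
    n_samples_max: int = 25
    value_set: tuple[int, ...] = (0, 1)
    n_range: tuple[int, ...] = tuple(range(1, 13))
    n_library: int = 20
    n_shared: int = 10
    designs: tuple[int, ...] = (1, 2, 3, 4)
    correct_band: int = 1
    outdir: str | None = None

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("sigmas", "value_set", "n_range", "designs"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _dependent(matrix: np.ndarray) -> bool:
    return integer_rank(matrix.tolist()) < matrix.shape[0]


def run_dependence_curve(
    value_set: Sequence[int] = (0, 1),
    n_range: Sequence[int] = tuple(range(1, 13)),
    replicates: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """P(n random samples of an n-genome metagenome are linearly dependent).

    For each n, draws n multiplicity vectors with i.i.d. coordinates from
    `value_set` and tests singularity of the n x n matrix exactly.
    """
    if replicates < 100:
        warnings.warn(f"replicates={replicates} < 100: the estimate will be noisy")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    values = np.asarray(value_set, dtype=np.int64)
    rows = []
    for n in n_range:
        hits = 0
        for _ in range(replicates):
            mat = values[rng.integers(0, values.size, size=(n, n))]
            hits += _dependent(mat)
        rows.append({"n_genomes": n, "p_dependent": hits / replicates})
        logger.info("dependence n=%d p=%.4f", n, hits / replicates)
    return pd.DataFrame(rows)


def exact_dependence_probability(value_set: Sequence[int], n: int) -> float:
    """Exhaustive dependence probability over all n x n multiplicity matrices."""
    values = list(dict.fromkeys(int(v) for v in value_set))
    s = len(values)
    total = s ** (n * n)
    if n > 4 or total > 2_000_000:
        raise ValueError(f"instance too large for enumeration (s={s}, n={n})")
    import itertools

    hits = 0
    for flat in itertools.product(values, repeat=n * n):
        mat = np.asarray(flat, dtype=np.int64).reshape(n, n)
        hits += _dependent(mat)
    return hits / total


def fit_logistic(points: pd.DataFrame | Sequence[tuple[float, float]]) -> dict:
    """Least-squares fit of y = a / (1 + exp(-k (x - xc))) to (x, y) points."""
    from scipy.optimize import curve_fit

    if isinstance(points, pd.DataFrame):
        x = points.iloc[:, 0].to_numpy(dtype=float)
        y = points.iloc[:, 1].to_numpy(dtype=float)
    else:
        arr = np.asarray(points, dtype=float)
        x, y = arr[:, 0], arr[:, 1]
    if x.size < 4:
        raise ValueError("need at least 4 points to fit the three-parameter logistic")
    if np.ptp(y) < 1e-12:
        return {
            "a": float(y[0]), "k": 0.0, "xc": float(np.median(x)),
            "residual_norm": 0.0, "converged": False, "degenerate": True,
        }

    def model(x, a, kk, xc):
        return a / (1.0 + np.exp(-kk * (x - xc)))

    p0 = (float(y.max()), 1.0, float(np.median(x)))
    try:
        popt, _ = curve_fit(model, x, y, p0=p0, maxfev=20000)
        resid = float(np.linalg.norm(y - model(x, *popt)))
        converged = True
    except RuntimeError as exc:
        logger.warning("logistic fit did not converge: %s", exc)
        popt, resid, converged = p0, float("nan"), False
    a, kk, xc = (float(v) for v in popt)
    return {
        "a": a, "k": kk, "xc": xc,
        "residual_norm": resid, "converged": converged, "degenerate": False,
    }


def _estimate_or_none(samples) -> int | None:
    try:
        return estimate_genome_count(samples).genome_count
    except (NoMarkerPattern, ValueError):
        return None


def run_reliability_curve(config: ExperimentConfig) -> pd.DataFrame:
    """Fraction of replicates recovering the genome count within +-1 vs N.

    Each replicate simulates a fresh metagenome (new random genomes and
    fragment sets), generates n_samples_max samples once, and estimates
    the genome count on every prefix of length N.
    """
    rng = np.random.default_rng(config.seed)
    p = config.n_genomes
    n_values = list(range(config.n_samples_min, config.n_samples_max + 1))
    results = []
    for sigma in config.sigmas or (config.sigma,):
        correct = {n: 0 for n in n_values}
        for rep in range(config.replicates):
            genomes = [
                generate_synthetic_genome(config.genome_length, rng, id=f"g{j}")
                for j in range(p)
            ]
            samples = generate_sample_set(
                genomes,
                MultiplicityModel.normal(config.m, sigma),
                coverage=config.coverage,
                n_samples=config.n_samples_max,
                rng_seed=rng,
                n_fragments=config.n_fragments,
                letter_error_rate=config.letter_error_rate,
                k=config.k,
            )
            for n in n_values:
                est = _estimate_or_none(samples.subset(n))
                if est is not None and abs(est - p) <= config.correct_band:
                    correct[n] += 1
        for n in n_values:
            results.append(
                {
                    "sigma": sigma,
                    "n_samples": n,
                    "fraction_correct": correct[n] / config.replicates,
                }
            )
        logger.info(
            "reliability sigma=%.1f max fraction=%.2f",
            sigma,
            max(correct.values()) / config.replicates,
        )
    return pd.DataFrame(results)


def run_virtual_table(config: ExperimentConfig) -> pd.DataFrame:
    """Percent of correct unknown-genome counts per virtual-sample design.

    Protocol: a metagenome of `n_genomes` genomes, `n_shared` of which
    come from a library of `n_library` genomes; all library genomes are
    added virtually, so the expected answer is
    n_genomes - n_shared unknown genomes.
    """
    rng = np.random.default_rng(config.seed)
    expected = config.n_genomes - config.n_shared
    rows = []
    for sigma in config.sigmas or (config.sigma,):
        for design_no in config.designs:
            design = VirtualDesign.numbered(
                design_no,
                coverage=config.coverage,
                letter_error_rate=config.letter_error_rate,
            )
            hits = 0
            for rep in range(config.replicates):
                library_genomes = [
                    generate_synthetic_genome(config.genome_length, rng, id=f"lib{j}")
                    for j in range(config.n_library)
                ]
                extra = [
                    generate_synthetic_genome(config.genome_length, rng, id=f"novel{j}")
                    for j in range(config.n_genomes - config.n_shared)
                ]
                meta_genomes = library_genomes[: config.n_shared] + extra
                samples = generate_sample_set(
                    meta_genomes,
                    MultiplicityModel.normal(config.m, sigma),
                    coverage=config.coverage,
                    n_samples=config.n_samples_max,
                    rng_seed=rng,
                    n_fragments=config.n_fragments,
                    letter_error_rate=config.letter_error_rate,
                    k=config.k,
                )
                dictionary = samples.dictionary
                library = SpectraLibrary.from_genomes(library_genomes, dictionary)
                virtual = build_virtual_samples(
                    library, [g.id for g in library_genomes], design, rng
                )
                try:
                    count = count_unknown_genomes(samples, virtual, config.n_library)
                except (NoMarkerPattern, ValueError):
                    count = None
                if count is not None and abs(count - expected) <= config.correct_band:
                    hits += 1
            rows.append(
                {
                    "design": design_no,
                    "sigma": sigma,
                    "n_samples": config.n_samples_max,
                    "percent_correct": 100.0 * hits / config.replicates,
                }
            )
            logger.info(
                "virtual design=%d sigma=%.1f percent=%.1f",
                design_no, sigma, rows[-1]["percent_correct"],
            )
    return pd.DataFrame(rows)


def run_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Dispatch on config.experiment and write outputs + provenance if outdir set."""
    logger.info("experiment=%s seed=%d digest=%s", config.experiment, config.seed, config.digest())
    if config.experiment == "dependence_curve":
        table = run_dependence_curve(
            config.value_set, config.n_range, config.replicates,
            np.random.default_rng(config.seed),
        )
    elif config.experiment == "reliability_curve":
        table = run_reliability_curve(config)
    elif config.experiment == "virtual_table":
        table = run_virtual_table(config)
    elif config.experiment == "marker_demo":
        rng = np.random.default_rng(config.seed)
        genomes = [
            generate_synthetic_genome(config.genome_length, rng, id=f"g{j}")
            for j in range(config.n_genomes)
        ]
        samples = generate_sample_set(
            genomes,
            MultiplicityModel.normal(config.m, config.sigma),
            coverage=config.coverage,
            n_samples=config.n_samples_max,
            rng_seed=rng,
            n_fragments=config.n_fragments,
            letter_error_rate=config.letter_error_rate,
            k=config.k,
        )
        est = estimate_genome_count(samples)
        curves = est.curves
        table = pd.DataFrame(
            {
                "n": curves.n,
                "f": curves.f,
                "d1": np.concatenate([curves.d1, [np.nan]]),
                "d2": np.concatenate([curves.d2, [np.nan, np.nan]]),
            }
        )
        table.attrs["genome_count"] = est.genome_count
        logger.info("marker demo: estimated %d genomes (peak at n=%s)",
                    est.genome_count, est.peak_index)
    else:
        raise ValueError(f"unknown experiment {config.experiment!r}")
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / f"{config.experiment}.tsv", sep="\t", index=False)
        config.to_yaml(outdir / f"{config.experiment}.config.yaml")
    return table
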