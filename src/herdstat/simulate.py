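"""Synthetic genotype panels with known population-genetic structure.

Three generators, each targeting one estimator so that the downstream
statistics can be validated by parameter recovery:

* :func:`simulate_divergent_populations` — Balding–Nichols subpopulation
  frequencies around a common ancestor; the divergence parameter ``theta``
  equals the expected Weir–Cockerham F_ST between any two populations.
* :func:`simulate_wright_fisher` — discrete-generation forward simulation
  of a diploid random-mating population with recombination, so linkage
  disequilibrium decays with genetic distance according to the effective
  size ``diploid_size`` (Ne equals census N by construction: no selection,
  no sex structure, no overlapping generations, no mutation — polymorphism
  is maintained by founding every locus at frequency 0.5).
* :func:`simulate_families` — paternal half-sib families on top of a base
  population, giving GRM blocks with a known pedigree expectation (0.25
  between half sibs).

All generators are bit-reproducible given their spec (which embeds the
seed), and emit :class:`~herdstat.io.GenotypeDataset` panels that the rest
of the package consumes directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeDataset

__all__ = [
    "DivergenceSimSpec",
    "WrightFisherSimSpec",
    "FamilySimSpec",
    "simulate_divergent_populations",
    "simulate_wright_fisher",
    "simulate_families",
    "inject_missingness",
]

#: 1 Morgan per 100 Mb, the map-scale convention used throughout.
DEFAULT_MORGAN_PER_BP = 1e-8


@dataclass(frozen=True)
class DivergenceSimSpec:
    """Balding–Nichols divergence simulation parameters.

    ``theta`` is the divergence parameter in (0, 1): subpopulation
    frequencies are Beta(p(1-θ)/θ, (1-p)(1-θ)/θ) around the ancestral
    frequency p, so the expected pairwise Weir–Cockerham F_ST is θ.
    """

    n_populations: int = 2
    n_per_population: int = 200
    n_markers: int = 5000
    theta: float = 0.10
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    marker_spacing: int = 55_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.theta < 1.0:
            raise ValueError(f"theta={self.theta} outside (0, 1)")
        for name in ("n_populations", "n_per_population", "n_markers"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.ancestral_freq_range
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("ancestral_freq_range must be within (0, 1)")


@dataclass(frozen=True)
class WrightFisherSimSpec:
    """Forward Wright–Fisher simulation parameters.

    ``diploid_size`` is the census (= effective) number of diploids per
    generation.  Crossovers are placed independently per adjacent marker
    interval with probability ``marker_spacing * morgan_per_bp`` — an
    adequate small-c approximation of Haldane's map at typical SNP-chip
    spacings.
    """

    diploid_size: int = 100
    n_chromosomes: int = 2
    markers_per_chromosome: int = 500
    marker_spacing: int = 50_000
    n_generations: int = 200
    morgan_per_bp: float = DEFAULT_MORGAN_PER_BP
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "diploid_size",
            "n_chromosomes",
            "markers_per_chromosome",
            "marker_spacing",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        if self.morgan_per_bp <= 0:
            raise ValueError("morgan_per_bp must be positive")


@dataclass(frozen=True)
class FamilySimSpec:
    """Paternal half-sib family structure on a base population."""

    n_sires: int = 10
    progeny_per_sire: int = 20
    base_spec: DivergenceSimSpec = field(
        default_factory=lambda: DivergenceSimSpec(
            n_populations=1, n_per_population=200, theta=1e-3
        )
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sires <= 0 or self.progeny_per_sire <= 0:
            raise ValueError("counts must be positive")


def _synthetic_map(n_markers: int, spacing: int, n_chromosomes: int = 1) -> pd.DataFrame:
    per = int(np.ceil(n_markers / n_chromosomes))
    chroms, poss = [], []
    for c in range(n_chromosomes):
        k = min(per, n_markers - c * per)
        if k <= 0:
            break
        chroms += [f"chr{c + 1}"] * k
        poss += list(spacing * (1 + np.arange(k)))
    return pd.DataFrame(
        {
            "id": [f"snp{i + 1}" for i in range(n_markers)],
            "chrom": chroms,
            "pos": np.asarray(poss, dtype=np.int64),
        }
    )


def simulate_divergent_populations(spec: DivergenceSimSpec) -> GenotypeDataset:
    """Draw genotypes for ``n_populations`` subpopulations under the
    Balding–Nichols model.

    Per marker: ancestral frequency p ~ Uniform(ancestral_freq_range);
    each population's frequency ~ Beta with mean p and variance
    θ·p(1−p); genotypes ~ Binomial(2, population frequency).  Markers sit
    on a single synthetic chromosome at fixed spacing; loci are unlinked
    (no LD beyond the structure-induced covariance).
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, spec.n_markers)
    ratio = (1.0 - spec.theta) / spec.theta
    blocks = []
    for _ in range(spec.n_populations):
        p_pop = rng.beta(p_anc * ratio, (1.0 - p_anc) * ratio)
        blocks.append(rng.binomial(2, p_pop, (spec.n_per_population, spec.n_markers)))
    dosages = np.vstack(blocks).astype(float)
    n_total = spec.n_populations * spec.n_per_population
    samples = pd.DataFrame(
        {
            "id": [f"ind{i + 1}" for i in range(n_total)],
            "group": np.repeat(
                [f"pop{k + 1}" for k in range(spec.n_populations)],
                spec.n_per_population,
            ),
        }
    )
    return GenotypeDataset(dosages, _synthetic_map(spec.n_markers, spec.marker_spacing), samples)


def _meiosis(
    haplos: np.ndarray, parents: np.ndarray, recomb_p: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One recombinant gamete per parent in ``parents``.

    ``haplos`` is (n_diploid, 2, L); ``recomb_p`` the per-interval
    crossover probability (length L-1).  The starting haplotype is chosen
    uniformly and switched after each interval that recombines.
    """
    k, L = len(parents), haplos.shape[2]
    start = rng.integers(0, 2, size=(k, 1))
    cross = rng.random((k, L - 1)) < recomb_p
    which = (start + np.concatenate([np.zeros((k, 1), dtype=int), np.cumsum(cross, axis=1)], axis=1)) % 2
    rows = np.arange(k)[:, None]
    return haplos[parents[:, None], which, np.arange(L)[None, :]]


def simulate_wright_fisher(
    spec: WrightFisherSimSpec, n_sample: int | None = None
) -> tuple[GenotypeDataset, np.ndarray]:
    """Forward-simulate drift and recombination, returning an unphased
    dosage panel and the underlying phased haplotypes.

    Founder haplotypes carry each allele independently with probability
    0.5.  Each generation, every offspring draws two parents uniformly
    with replacement and receives one recombinant gamete from each.
    Adjacent intervals recombine with probability
    ``marker_spacing * morgan_per_bp`` within chromosomes and 0.5 across
    chromosome boundaries.

    ``n_sample`` diploids (default: all) are returned, restricted to loci
    still polymorphic in the sampled set; the phased haplotypes of the
    sampled individuals are returned alongside for use as an oracle (shape
    ``(n_sample, 2, n_polymorphic_loci)``).
    """
    rng = np.random.default_rng(spec.seed)
    N = spec.diploid_size
    markers = _synthetic_map(
        spec.n_chromosomes * spec.markers_per_chromosome,
        spec.marker_spacing,
        spec.n_chromosomes,
    )
    L = len(markers)
    same_chrom = markers["chrom"].to_numpy()[1:] == markers["chrom"].to_numpy()[:-1]
    recomb_p = np.where(
        same_chrom, min(spec.marker_spacing * spec.morgan_per_bp, 0.5), 0.5
    )

    haplos = (rng.random((N, 2, L)) < 0.5).astype(np.int8)
    for _ in range(spec.n_generations):
        gam1 = _meiosis(haplos, rng.integers(0, N, N), recomb_p, rng)
        gam2 = _meiosis(haplos, rng.integers(0, N, N), recomb_p, rng)
        haplos = np.stack([gam1, gam2], axis=1).astype(np.int8)

    if n_sample is None or n_sample >= N:
        take = np.arange(N)
    else:
        take = rng.choice(N, n_sample, replace=False)
    sampled = haplos[take]
    dosages = sampled.sum(axis=1).astype(float)
    freq = dosages.mean(axis=0) / 2.0
    poly = (freq > 0) & (freq < 1)
    if not poly.any():
        raise ValueError(
            "all loci fixed in the sample; increase diploid_size or reduce n_generations"
        )
    samples = pd.DataFrame(
        {"id": [f"wf{i + 1}" for i in range(len(take))], "group": "wf"}
    )
    data = GenotypeDataset(
        dosages[:, poly], markers.loc[poly].reset_index(drop=True), samples
    )
    return data, sampled[:, :, poly]


def simulate_families(spec: FamilySimSpec) -> GenotypeDataset:
    """Generate paternal half-sib families from a base population.

    Sires and dams are drawn from a near-panmictic Balding–Nichols base;
    each progeny receives one gamete from its sire and one from a dam
    drawn at random per progeny, gametes formed by independent Mendelian
    sampling per marker (loci unlinked).  The group label is the sire
    family.  The returned panel contains progeny only.
    """
    base = simulate_divergent_populations(spec.base_spec)
    rng = np.random.default_rng(spec.seed)
    n_base = base.n_samples
    if n_base < spec.n_sires + 1:
        raise ValueError(
            f"base population of {n_base} cannot supply {spec.n_sires} sires plus dams"
        )
    perm = rng.permutation(n_base)
    sires = perm[: spec.n_sires]
    dams = perm[spec.n_sires:]
    X = base.dosages

    def gamete(parent_rows: np.ndarray) -> np.ndarray:
        # B-allele transmitted with prob 0 / 0.5 / 1 for dosage 0 / 1 / 2
        return (rng.random(parent_rows.shape) < parent_rows / 2.0).astype(float)

    rows, ids, groups = [], [], []
    for s_i, sire in enumerate(sires):
        sire_rows = np.repeat(X[[sire]], spec.progeny_per_sire, axis=0)
        dam_pick = rng.choice(dams, spec.progeny_per_sire, replace=True)
        rows.append(gamete(sire_rows) + gamete(X[dam_pick]))
        ids += [f"fam{s_i + 1}_prog{j + 1}" for j in range(spec.progeny_per_sire)]
        groups += [f"fam{s_i + 1}"] * spec.progeny_per_sire
    samples = pd.DataFrame({"id": ids, "group": groups})
    return GenotypeDataset(np.vstack(rows), base.markers.copy(), samples)


def inject_missingness(
    data: GenotypeDataset,
    marker_rate: float = 0.0,
    sample_rate: float = 0.0,
    seed: int = 0,
) -> GenotypeDataset:
    """Blank dosage cells independently for QC testing.

    Two independent cell-level processes are applied: a marker-wise one
    (each cell missing with probability ``marker_rate``, drawn marker by
    marker) and a sample-wise one (probability ``sample_rate``, drawn
    sample by sample); a cell is missing if either selects it.  With one
    rate zero this is plain i.i.d. missingness at the other rate.
    """
    for name, rate in (("marker_rate", marker_rate), ("sample_rate", sample_rate)):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"{name}={rate} outside [0, 1)")
    X = data.dosages.copy()
    if marker_rate > 0.0 or sample_rate > 0.0:
        rng = np.random.default_rng(seed)
        mask = np.zeros(X.shape, dtype=bool)
        if marker_rate > 0.0:
            mask |= rng.random(X.shape) < marker_rate
        if sample_rate > 0.0:
            mask |= rng.random(X.shape) < sample_rate
        X[mask] = np.nan
    return GenotypeDataset(X, data.markers.copy(), data.samples.copy())
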