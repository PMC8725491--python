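"""Depth-limited pairwise linkage disequilibrium, LD-decay curves,
non-syntenic LD and LD-based historical effective population size.

For every marker, r-squared is computed against each of the ``max_depth``
markers that succeed it in genome order (depth = rank offset).  Pairs
whose window crosses a chromosome boundary form the non-syntenic set,
whose mean r² estimates the sampling noise floor (≈ 1/N for N samples).
From unphased genotypes r² is the squared Pearson correlation of dosage
vectors (composite LD); on phased haplotypes this converges to the
classical (p_AB - p_A p_B)² / (p_A q_A p_B q_B) under random mating.

The decay curve restricts to markers that have the full ``max_depth``
same-chromosome successors, averages r² per depth, and maps depth to a
nominal physical distance via the panel's mean adjacent marker spacing.
Effective population size follows Sved's drift-recombination equilibrium
rearranged as Ne_t = (1 - r²) / (4 c r²), with c the recombination
fraction in Morgans at the bin's distance (1 Morgan = 100 Mb by default)
and t = 1/(2c) generations ago; the "current" Ne is read at the bin whose
t is nearest 20 generations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeDataset
from .simulate import DEFAULT_MORGAN_PER_BP

__all__ = [
    "LDRecords",
    "LDDecayCurve",
    "NonSyntenicLD",
    "NeTrajectory",
    "pairwise_ld",
    "full_depth_syntenic_markers",
    "mean_adjacent_spacing",
    "syntenic_decay",
    "nonsyntenic_ld",
    "sample_size_experiment",
    "hill_robertson_correction",
    "ne_from_ld",
    "haplotype_r_squared",
]


@dataclass
class LDRecords:
    """Pairwise r² records within a fixed successor window.

    ``records`` columns: ``a`` and ``b`` (marker indices in genome order),
    ``depth`` (b's rank after a, 1..max_depth), ``same_chromosome``,
    ``r_squared``.  Pairs involving a monomorphic marker have undefined r²
    and are dropped (counted in ``n_skipped``).
    """

    records: pd.DataFrame
    max_depth: int
    n_samples: int
    n_skipped: int


@dataclass
class LDDecayCurve:
    """Mean syntenic r² per depth with nominal distances."""

    table: pd.DataFrame  # depth, distance_bp, mean_r2, n_pairs
    mean_adjacent_spacing: float
    n_full_depth_markers: int

    @property
    def adjacent_r2(self) -> float:
        return float(self.table["mean_r2"].iloc[0])


@dataclass
class NonSyntenicLD:
    mean_r2: float
    n_pairs: int
    sample_size: int


@dataclass
class NeTrajectory:
    """(c, t, Ne) per depth bin, restricted to t in [2, 500]."""

    table: pd.DataFrame  # depth, distance_bp, c_morgans, t_generations, mean_r2, ne
    current_ne: float
    current_t: float


def _corr_sq(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Columnwise squared Pearson correlation between paired columns of X
    and Y; NaN where either column has zero variance."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    num = (Xc * Yc).sum(axis=0)
    den = np.sqrt((Xc**2).sum(axis=0) * (Yc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    r2 = r**2
    r2[~np.isfinite(r2)] = np.nan
    return r2


def pairwise_ld(data: GenotypeDataset, max_depth: int = 400) -> LDRecords:
    """r² between every marker and its next ``max_depth`` successors in
    global genome order (windows may cross chromosome boundaries; such
    pairs are flagged non-syntenic)."""
    X = data.dosages
    if np.isnan(X).any():
        raise ValueError("missing dosages; impute before computing LD")
    m = data.n_markers
    if m < 2:
        raise ValueError("need at least two markers")
    chrom = data.markers["chrom"].to_numpy()
    frames = []
    n_skipped = 0
    for d in range(1, min(max_depth, m - 1) + 1):
        a = np.arange(m - d)
        r2 = _corr_sq(X[:, :-d], X[:, d:])
        ok = ~np.isnan(r2)
        n_skipped += int((~ok).sum())
        frames.append(
            pd.DataFrame(
                {
                    "a": a[ok],
                    "b": a[ok] + d,
                    "depth": d,
                    "same_chromosome": chrom[a[ok]] == chrom[a[ok] + d],
                    "r_squared": r2[ok],
                }
            )
        )
    records = pd.concat(frames, ignore_index=True)
    return LDRecords(
        records=records,
        max_depth=max_depth,
        n_samples=data.n_samples,
        n_skipped=n_skipped,
    )


def full_depth_syntenic_markers(markers: pd.DataFrame, max_depth: int) -> np.ndarray:
    """Indices of markers whose next ``max_depth`` successors in genome
    order all lie on the same chromosome (each chromosome's last
    ``max_depth`` markers drop out; chromosomes with <= max_depth markers
    contribute none)."""
    chrom = markers["chrom"].to_numpy()
    m = len(chrom)
    keep = []
    start = 0
    for i in range(1, m + 1):
        if i == m or chrom[i] != chrom[start]:
            size = i - start
            if size > max_depth:
                keep.append(np.arange(start, i - max_depth))
            start = i
    return np.concatenate(keep) if keep else np.array([], dtype=int)


def mean_adjacent_spacing(markers: pd.DataFrame) -> float:
    """Mean gap between adjacent markers within chromosomes, in bp."""
    gaps = []
    for _, sub in markers.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        if len(pos) > 1:
            gaps.append(np.diff(pos))
    if not gaps:
        raise ValueError("no chromosome has two markers")
    return float(np.concatenate(gaps).mean())


def syntenic_decay(ld: LDRecords, markers: pd.DataFrame) -> LDDecayCurve:
    """Mean r² per depth over the full-depth syntenic marker set, with
    nominal distance = depth × mean adjacent spacing."""
    full = full_depth_syntenic_markers(markers, ld.max_depth)
    if full.size == 0:
        raise ValueError(
            f"no marker has {ld.max_depth} same-chromosome successors; "
            "reduce max_depth"
        )
    rec = ld.records
    sub = rec[rec["a"].isin(full)]
    spacing = mean_adjacent_spacing(markers)
    by = sub.groupby("depth")["r_squared"]
    table = pd.DataFrame(
        {
            "depth": by.mean().index,
            "distance_bp": by.mean().index * spacing,
            "mean_r2": by.mean().to_numpy(),
            "n_pairs": by.size().to_numpy(),
        }
    ).reset_index(drop=True)
    return LDDecayCurve(
        table=table,
        mean_adjacent_spacing=spacing,
        n_full_depth_markers=int(full.size),
    )


def nonsyntenic_ld(ld: LDRecords) -> NonSyntenicLD:
    """Single mean r² over the cross-chromosome pairs of the depth window."""
    rec = ld.records
    cross = rec.loc[~rec["same_chromosome"], "r_squared"]
    if cross.empty:
        raise ValueError(
            "no cross-chromosome pairs within the depth window "
            "(single chromosome?); non-syntenic LD undefined"
        )
    return NonSyntenicLD(
        mean_r2=float(cross.mean()), n_pairs=int(cross.size), sample_size=ld.n_samples
    )


def sample_size_experiment(
    data: GenotypeDataset,
    exponents: list[float],
    seed: int = 0,
    max_depth: int = 400,
) -> pd.DataFrame:
    """Non-syntenic LD at sample sizes N = 2^n for each exponent.

    For each N, a random subset of individuals (without replacement) is
    drawn and the non-syntenic mean recomputed; the returned table carries
    N, 1/N, the mean r² and the pair count.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for n_exp in exponents:
        N = int(round(2.0**n_exp))
        if N < 2:
            raise ValueError(f"sample size 2^{n_exp} < 2")
        if N > data.n_samples:
            raise ValueError(f"sample size {N} exceeds panel size {data.n_samples}")
        if N == data.n_samples:
            sub = data
        else:
            sub = data.subset_samples(np.sort(rng.choice(data.n_samples, N, replace=False)))
        res = nonsyntenic_ld(pairwise_ld(sub, max_depth))
        rows.append(
            {
                "exponent": n_exp,
                "N": N,
                "inv_N": 1.0 / N,
                "mean_r2": res.mean_r2,
                "n_pairs": res.n_pairs,
            }
        )
    return pd.DataFrame(rows)


def hill_robertson_correction(
    r_squared: float | np.ndarray, n_samples: int, mode: str = "subtract"
) -> tuple[np.ndarray, np.ndarray]:
    """Remove the finite-sample expectation 1/n from r² estimates.

    ``mode="subtract"`` returns max(r² - 1/n, 0) with a flag where the
    raw difference was negative (small true LD at small n inevitably goes
    negative); ``mode="report"`` returns the uncorrected value, with the
    1/n expectation in place of the flag array.
    """
    if n_samples < 2:
        raise ValueError("need at least two samples")
    r2 = np.asarray(r_squared, dtype=float)
    expectation = 1.0 / n_samples
    if mode == "report":
        return r2, np.full_like(r2, expectation)
    if mode != "subtract":
        raise ValueError(f"unknown mode {mode!r}")
    corrected = r2 - expectation
    floored = corrected < 0
    return np.clip(corrected, 0.0, None), floored


def ne_from_ld(
    curve: LDDecayCurve,
    morgan_per_bp: float = DEFAULT_MORGAN_PER_BP,
    current_t: float = 20.0,
    t_range: tuple[float, float] = (2.0, 500.0),
) -> NeTrajectory:
    """Historical effective size per depth bin.

    c = distance × morgan_per_bp (Morgans), t = 1/(2c) generations ago,
    Ne_t = (1 - r²)/(4 c r²).  Bins with r² = 0 are undefined (NaN,
    flagged); r² = 1 gives Ne = 0 (flagged).  The trajectory is reported
    for t within ``t_range``; the "current" Ne is the bin whose t is
    nearest ``current_t`` (ties to the smaller t).
    """
    tab = curve.table.copy()
    c = tab["distance_bp"].to_numpy() * morgan_per_bp
    if np.any(c <= 0):
        raise ValueError("non-positive recombination distances")
    r2 = tab["mean_r2"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ne = (1.0 - r2) / (4.0 * c * r2)
    ne = np.where(r2 <= 0.0, np.nan, ne)
    t = 1.0 / (2.0 * c)
    tab["c_morgans"] = c
    tab["t_generations"] = t
    tab["ne"] = ne
    tab["flag"] = np.where(r2 <= 0, "r2_zero", np.where(r2 >= 1, "r2_one", ""))

    # nearest-t bin over all bins; ties broken toward the smaller t
    order = np.lexsort((t, np.abs(t - current_t)))
    best = order[0]
    lo, hi = t_range
    reported = tab[(tab["t_generations"] >= lo) & (tab["t_generations"] <= hi)]
    return NeTrajectory(
        table=reported.reset_index(drop=True),
        current_ne=float(ne[best]),
        current_t=float(t[best]),
    )


def haplotype_r_squared(hapA: np.ndarray, hapB: np.ndarray) -> float:
    """Classical haplotype-frequency r² for two biallelic loci.

    ``hapA`` and ``hapB`` are 0/1 allele arrays over the same gametes:
    r² = (p_AB - p_A p_B)² / (p_A(1-p_A) p_B(1-p_B)).  Used as the
    phased-data oracle for the dosage-correlation estimator.
    """
    hapA = np.asarray(hapA, dtype=float).ravel()
    hapB = np.asarray(hapB, dtype=float).ravel()
    pA = hapA.mean()
    pB = hapB.mean()
    pAB = (hapA * hapB).mean()
    den = pA * (1.0 - pA) * pB * (1.0 - pB)
    if den == 0.0:
        raise ValueError("monomorphic locus; r² undefined")
    return float((pAB - pA * pB) ** 2 / den)
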