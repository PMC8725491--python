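"""Heterozygosity summaries and Weir–Cockerham F_ST.

Expected heterozygosity per marker is H_exp = 2p(1-p) under Hardy–Weinberg
equilibrium; observed heterozygosity H_obs is the proportion of
heterozygous (dosage 1) genotypes.  Population divergence is estimated by
the Weir–Cockerham variance-component estimator

    theta_W = sum_i a_i / sum_i (a_i + b_i + c_i),

a ratio of sums across markers — never a mean of per-marker ratios — with
a, b, c the among-population, among-individual and within-individual
components.  Negative per-marker components are kept in the sums; markers
monomorphic across the groups under comparison contribute nothing and are
skipped (counted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AlleleFrequencySet, GenotypeDataset, allele_frequencies

__all__ = [
    "HeterozygositySummary",
    "FstComponents",
    "FstMatrix",
    "expected_heterozygosity",
    "observed_heterozygosity",
    "group_genotype_stats",
    "weir_cockerham_components",
    "pairwise_fst",
]


@dataclass
class HeterozygositySummary:
    group: str
    n_samples: int
    per_marker_expected: np.ndarray | None = None
    per_marker_observed: np.ndarray | None = None
    markers_excluded: int = 0

    @property
    def mean_expected(self) -> float:
        return float(np.mean(self.per_marker_expected))

    @property
    def sd_expected(self) -> float:
        return float(np.std(self.per_marker_expected, ddof=1))

    @property
    def mean_observed(self) -> float:
        return float(np.mean(self.per_marker_observed))

    @property
    def sd_observed(self) -> float:
        return float(np.std(self.per_marker_observed, ddof=1))


@dataclass
class FstComponents:
    """Per-marker a/b/c variance components and the ratio-of-sums theta."""

    per_marker_a: np.ndarray
    per_marker_b: np.ndarray
    per_marker_c: np.ndarray
    markers_used: int
    markers_skipped: int

    @property
    def theta_w(self) -> float:
        num = self.per_marker_a.sum()
        den = (self.per_marker_a + self.per_marker_b + self.per_marker_c).sum()
        return float(num / den)


@dataclass
class FstMatrix:
    groups: list[str]
    values: pd.DataFrame  # symmetric, NaN diagonal

    def to_table(self, decimals: int | None = None) -> pd.DataFrame:
        """Upper-triangle layout with a blank diagonal, as conventionally
        reported for pairwise divergence tables."""
        out = self.values.copy()
        mask = np.tril(np.ones(out.shape, dtype=bool))
        out = out.where(~mask, np.nan)
        return out.round(decimals) if decimals is not None else out


def expected_heterozygosity(
    freqs: AlleleFrequencySet, group: str | None = None
) -> HeterozygositySummary:
    """Per-marker H_exp = 2p(1-p) with mean and SD across markers."""
    p = freqs.frequencies
    h = 2.0 * p * (1.0 - p)
    return HeterozygositySummary(
        group=group or freqs.scope,
        n_samples=int(freqs.n_samples_used.max(initial=0)),
        per_marker_expected=h,
    )


def observed_heterozygosity(data: GenotypeDataset, group: str = "all") -> HeterozygositySummary:
    """Per-marker heterozygote proportion among non-missing genotypes of the
    group; markers with no observed genotype in the group are excluded and
    counted."""
    if group == "all":
        X = data.dosages
    else:
        X = data.dosages[data.group_indices(group)]
    obs = ~np.isnan(X)
    n_obs = obs.sum(axis=0)
    ok = n_obs > 0
    with np.errstate(invalid="ignore"):
        h = np.where(X == 1, 1.0, 0.0).sum(axis=0)[ok] / n_obs[ok]
    return HeterozygositySummary(
        group=group,
        n_samples=X.shape[0],
        per_marker_observed=h,
        markers_excluded=int((~ok).sum()),
    )


def group_genotype_stats(
    data: GenotypeDataset, groups: list[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-marker (n, p, h) for each group: non-missing sample count,
    B-allele frequency, observed heterozygote proportion.  Arrays are
    (n_markers, n_groups)."""
    m = data.n_markers
    n = np.zeros((m, len(groups)))
    p = np.zeros((m, len(groups)))
    h = np.zeros((m, len(groups)))
    for k, g in enumerate(groups):
        X = data.dosages[data.group_indices(g)]
        obs = ~np.isnan(X)
        n[:, k] = obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[:, k] = np.nansum(X, axis=0) / (2.0 * n[:, k])
            h[:, k] = np.where(X == 1, 1.0, 0.0).sum(axis=0) / n[:, k]
    return n, p, h


def weir_cockerham_components(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> FstComponents:
    """Weir–Cockerham a/b/c components from per-marker per-group summaries.

    Parameters are (n_markers, r) arrays of group sample sizes ``n``,
    allele frequencies ``p`` and observed heterozygote proportions ``h``
    (from genotypes, not a Hardy–Weinberg assumption).  Markers where any
    group has n < 2, or that are monomorphic across the groups, are
    skipped and counted.
    """
    n = np.atleast_2d(np.asarray(n, dtype=float))
    p = np.atleast_2d(np.asarray(p, dtype=float))
    h = np.atleast_2d(np.asarray(h, dtype=float))
    if not (n.shape == p.shape == h.shape):
        raise ValueError("n, p, h must have identical shapes")
    r = n.shape[1]
    if r < 2:
        raise ValueError("need at least two groups")

    usable = (n >= 2).all(axis=1)

    nbar = n.sum(axis=1) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (r * nbar - (n**2).sum(axis=1) / (r * nbar)) / (r - 1)
        pbar = (n * p).sum(axis=1) / (r * nbar)
        s2 = (n * (p - pbar[:, None]) ** 2).sum(axis=1) / ((r - 1) * nbar)
        hbar = (n * h).sum(axis=1) / (r * nbar)

        a = (nbar / n_c) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0

    mono = (pbar <= 0.0) | (pbar >= 1.0)
    keep = usable & ~mono & np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    if not keep.any():
        raise ValueError("every marker skipped (monomorphic or undersized groups)")
    return FstComponents(
        per_marker_a=a[keep],
        per_marker_b=b[keep],
        per_marker_c=c[keep],
        markers_used=int(keep.sum()),
        markers_skipped=int((~keep).sum()),
    )


def pairwise_fst(data: GenotypeDataset, groups: list[str] | None = None) -> FstMatrix:
    """Weir–Cockerham theta for every unordered group pair, each pair using
    only its own two groups' frequencies.  Singleton groups yield NaN
    entries (undefined)."""
    groups = groups or data.groups
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    n, p, h = group_genotype_stats(data, groups)
    K = len(groups)
    M = np.full((K, K), np.nan)
    for i in range(K):
        for j in range(i + 1, K):
            cols = [i, j]
            try:
                comp = weir_cockerham_components(n[:, cols], p[:, cols], h[:, cols])
            except ValueError:
                continue  # undefined pair (singleton group or all skipped)
            M[i, j] = M[j, i] = comp.theta_w
    return FstMatrix(groups=list(groups), values=pd.DataFrame(M, index=groups, columns=groups))
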