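"""VanRaden genomic relationship matrix, genomic inbreeding, group-block
relatedness and GRM principal components.

G = (M - 2P)(M - 2P)' / (2 * sum_j p_j (1 - p_j)), with M the sample-by-
marker dosage matrix and P the matrix repeating the reference B-allele
frequency p_j in column j.  When the reference frequencies are computed
from the included samples themselves, every column of G sums to zero, so
the mean off-diagonal relatedness is slightly negative by construction.

Genomic inbreeding is F_VR = G_ii - 1.  Group-level relatedness is the
mean of the relevant off-diagonal block of G (diagonal excluded within a
group); each group additionally gets an "external mean" — its mean
relatedness to every sample outside the group — used as the diagonal
replacement in block-relatedness heatmap layouts.

Recomputing G on a sample subset with frequencies from that subset is not
the same as slicing the full-panel G: re-centering changes every entry,
typically lowering the mean diagonal when the subset is more homogeneous
than the full panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AlleleFrequencySet, GenotypeDataset, allele_frequencies

__all__ = [
    "GRMatrix",
    "InbreedingSummary",
    "GroupRelatednessMatrix",
    "PCAResult",
    "compute_grm",
    "genomic_inbreeding",
    "group_relatedness",
    "grm_pca",
]


@dataclass
class GRMatrix:
    sample_ids: list[str]
    groups: pd.Series
    values: np.ndarray
    reference_frequencies: AlleleFrequencySet
    denominator: float

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def mean_diagonal(self) -> float:
        return float(np.mean(np.diag(self.values)))


@dataclass
class InbreedingSummary:
    per_sample: pd.Series  # F_VR = G_ii - 1, indexed by sample id
    per_group: pd.DataFrame  # n, min, mean, sd, max per group
    mean_diagonal: float


@dataclass
class GroupRelatednessMatrix:
    groups: list[str]
    block_means: pd.DataFrame  # symmetric; within-group entries exclude the diagonal
    internal_relatedness: pd.Series  # NaN for singleton groups
    external_mean: pd.Series  # mean relatedness to all samples outside the group


@dataclass
class PCAResult:
    scores: pd.DataFrame  # sample by PC1..PCK, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray
    pov: np.ndarray  # per-component proportion of variance
    n_clamped: int  # negative eigenvalues clamped to zero for POV

    @property
    def cumulative_pov(self) -> np.ndarray:
        return np.cumsum(self.pov)


def compute_grm(
    data: GenotypeDataset,
    reference_frequencies: AlleleFrequencySet | None = None,
) -> GRMatrix:
    """Build the VanRaden GRM from a complete (imputed) dosage panel.

    If ``reference_frequencies`` is omitted the frequencies are computed
    from the included samples, which centers G exactly (zero column sums).
    """
    X = data.dosages
    if np.isnan(X).any():
        raise ValueError("missing dosages; impute before building the GRM")
    if reference_frequencies is None:
        reference_frequencies = allele_frequencies(data)
    p = reference_frequencies.frequencies
    if len(p) != data.n_markers:
        raise ValueError("reference frequencies do not match marker count")
    denom = float(2.0 * np.sum(p * (1.0 - p)))
    if denom == 0.0:
        raise ValueError("all markers monomorphic in the reference set")
    Z = X - 2.0 * p
    G = (Z @ Z.T) / denom
    return GRMatrix(
        sample_ids=list(data.samples["id"]),
        groups=data.samples["group"].copy(),
        values=G,
        reference_frequencies=reference_frequencies,
        denominator=denom,
    )


def genomic_inbreeding(grm: GRMatrix) -> InbreedingSummary:
    """Per-sample F_VR = G_ii - 1 with per-group min / mean±SD / max."""
    f = pd.Series(np.diag(grm.values) - 1.0, index=grm.sample_ids, name="F_VR")
    by = f.groupby(grm.groups.to_numpy(), sort=False)
    per_group = pd.DataFrame(
        {
            "n": by.size(),
            "min": by.min(),
            "mean": by.mean(),
            "sd": by.std(ddof=1),
            "max": by.max(),
        }
    )
    return InbreedingSummary(
        per_sample=f, per_group=per_group, mean_diagonal=grm.mean_diagonal
    )


def group_relatedness(grm: GRMatrix) -> GroupRelatednessMatrix:
    """Mean off-diagonal GRM blocks per group pair.

    Within-group means exclude the diagonal of G; a singleton group has no
    within-group pairs and its internal relatedness is NaN.  The external
    mean is the mean of each group's rows over all columns outside the
    group (the diagonal-replacement vector of block-relatedness plots).
    """
    groups = list(dict.fromkeys(grm.groups))
    G = grm.values
    K = len(groups)
    idx = {g: np.flatnonzero((grm.groups == g).to_numpy()) for g in groups}
    block = np.full((K, K), np.nan)
    internal = {}
    external = {}
    all_idx = np.arange(grm.n)
    for a, ga in enumerate(groups):
        ia = idx[ga]
        sub = G[np.ix_(ia, ia)]
        if len(ia) > 1:
            off = sub[~np.eye(len(ia), dtype=bool)]
            block[a, a] = off.mean()
        internal[ga] = block[a, a]
        outside = np.setdiff1d(all_idx, ia, assume_unique=True)
        external[ga] = (
            float(G[np.ix_(ia, outside)].mean()) if outside.size else np.nan
        )
        for b in range(a + 1, K):
            ib = idx[groups[b]]
            block[a, b] = block[b, a] = float(G[np.ix_(ia, ib)].mean())
    return GroupRelatednessMatrix(
        groups=groups,
        block_means=pd.DataFrame(block, index=groups, columns=groups),
        internal_relatedness=pd.Series(internal, name="internal"),
        external_mean=pd.Series(external, name="external"),
    )


def grm_pca(grm: GRMatrix, n_components: int = 40) -> PCAResult:
    """Top-K eigendecomposition of G.

    Scores are eigenvector * sqrt(eigenvalue); the proportion of variance
    uses trace(G) (= total eigenvalue mass) as denominator.  Negative
    eigenvalues — numerically possible although G is PSD in exact
    arithmetic — are clamped to zero for POV and counted.  The sign of
    each component is fixed so its largest-magnitude loading is positive.
    """
    G = grm.values
    if not np.allclose(G, G.T, atol=1e-10):
        raise ValueError("GRM is not symmetric")
    n_components = min(n_components, grm.n)
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1][:n_components]
    lam = evals[order]
    V = evecs[:, order]
    for k in range(V.shape[1]):
        j = np.argmax(np.abs(V[:, k]))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
    n_clamped = int((lam < 0).sum())
    lam_pos = np.clip(lam, 0.0, None)
    total = float(np.trace(G))
    pov = lam_pos / total if total > 0 else np.zeros_like(lam_pos)
    scores = V * np.sqrt(lam_pos)
    cols = [f"PC{k + 1}" for k in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=grm.sample_ids, columns=cols),
        eigenvalues=lam,
        pov=pov,
        n_clamped=n_clamped,
    )
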