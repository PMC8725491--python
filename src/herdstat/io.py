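"""Genotype panel input/output, quality control and allele frequencies.

The central container is :class:`GenotypeDataset`: a diploid biallelic SNP
panel coded as B-allele dosages (0/1/2, NaN for missing) under the Illumina
AB calling convention, together with a marker map (chromosome, base-pair
position) and per-sample group labels (breed / country / bloodline).

Three plain-text dialects are supported:

``plink-ped``
    ``<prefix>.ped`` / ``<prefix>.map``.  Six leading ped columns
    (FID IID PAT MAT SEX PHENO), then two space-separated alleles per
    marker, ``A``/``B`` letters, ``0 0`` for missing.  The family id
    column carries the group label.
``additive-table``
    ``<prefix>.raw`` (header row of marker ids, one row per sample with
    a leading sample id, integer dosages, ``NA`` missing),
    ``<prefix>.map`` and ``<prefix>.groups``.
``dosage-matrix``
    ``<prefix>.dosages.tsv`` in the same layout as ``.raw`` but
    tab-separated, plus ``<prefix>.map`` and ``<prefix>.groups``.

The groups file is two-column delimited (sample id, group), with an
optional third country column.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeDataset",
    "QCThresholds",
    "QCReport",
    "AlleleFrequencySet",
    "read_genotypes",
    "write_genotypes",
    "apply_qc",
    "mean_impute",
    "allele_frequencies",
]

FORMATS = ("plink-ped", "additive-table", "dosage-matrix")


class GenotypeFormatError(ValueError):
    """Malformed or inconsistent genotype input files."""


class EmptyPanelError(ValueError):
    """An operation removed or was given every marker or sample."""


@dataclass
class GenotypeDataset:
    """A diploid SNP panel with marker map and sample metadata.

    Parameters
    ----------
    dosages
        ``(n_samples, n_markers)`` float array of B-allele counts in
        ``{0, 1, 2}``; missing genotypes are ``NaN``.
    markers
        Marker table with columns ``id``, ``chrom``, ``pos`` (1-based bp),
        in genome order: chromosomes in order of first appearance,
        positions strictly increasing within each chromosome.
    samples
        Sample table with columns ``id``, ``group`` and optionally
        ``country``.
    """

    dosages: np.ndarray
    markers: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.markers = self.markers.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n, m = self.dosages.shape
        if len(self.samples) != n:
            raise ValueError(f"{len(self.samples)} sample rows for {n} dosage rows")
        if len(self.markers) != m:
            raise ValueError(f"{len(self.markers)} marker rows for {m} dosage columns")
        if self.samples["id"].duplicated().any():
            dup = self.samples["id"][self.samples["id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate sample id {dup!r}")
        if self.markers["id"].duplicated().any():
            dup = self.markers["id"][self.markers["id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate marker id {dup!r}")
        if "group" not in self.samples or self.samples["group"].isna().any():
            raise ValueError("every sample needs a group label")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and (vals.min() < 0 or vals.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")
        for chrom, sub in self.markers.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom!r}"
                )

    # -- conveniences -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def groups(self) -> list[str]:
        """Group labels in order of first appearance."""
        return list(dict.fromkeys(self.samples["group"]))

    def group_indices(self, group: str) -> np.ndarray:
        idx = np.flatnonzero((self.samples["group"] == group).to_numpy())
        if idx.size == 0:
            raise KeyError(f"no samples in group {group!r}")
        return idx

    def subset_samples(self, index: np.ndarray | list[int]) -> "GenotypeDataset":
        index = np.asarray(index)
        return GenotypeDataset(
            self.dosages[index], self.markers.copy(), self.samples.iloc[index]
        )

    def subset_markers(self, index: np.ndarray | list[int]) -> "GenotypeDataset":
        index = np.asarray(index)
        return GenotypeDataset(
            self.dosages[:, index], self.markers.iloc[index], self.samples.copy()
        )

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            np.array_equal(self.dosages, other.dosages, equal_nan=True)
            and self.markers.reset_index(drop=True).equals(
                other.markers.reset_index(drop=True)
            )
            and self.samples.reset_index(drop=True).equals(
                other.samples.reset_index(drop=True)
            )
        )


@dataclass(frozen=True)
class QCThresholds:
    """Marker/sample retention thresholds; all strict (">") comparisons."""

    min_maf: float = 0.01
    min_marker_call_rate: float = 0.95
    min_sample_call_rate: float = 0.95

    def __post_init__(self) -> None:
        for name in ("min_maf", "min_marker_call_rate", "min_sample_call_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QCReport:
    markers_removed_by_rule: dict[str, int]
    samples_removed: int
    markers_retained: int
    samples_retained: int

    @property
    def markers_removed(self) -> int:
        return sum(self.markers_removed_by_rule.values())


@dataclass
class AlleleFrequencySet:
    """Per-marker B-allele frequencies over a named sample scope."""

    frequencies: np.ndarray
    n_samples_used: np.ndarray
    scope: str = "all"

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.n_samples_used = np.asarray(self.n_samples_used, dtype=int)
        ok = self.frequencies[~np.isnan(self.frequencies)]
        if ok.size and (ok.min() < 0 or ok.max() > 1):
            raise ValueError("frequencies outside [0, 1]")


# ---------------------------------------------------------------------------
# reading / writing


def _sort_genome_order(
    markers: pd.DataFrame, dosages: np.ndarray
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sort markers into genome order: chromosomes by first appearance,
    positions ascending within chromosome."""
    chrom_rank = {c: i for i, c in enumerate(dict.fromkeys(markers["chrom"]))}
    order = np.lexsort(
        (markers["pos"].to_numpy(), markers["chrom"].map(chrom_rank).to_numpy())
    )
    return markers.iloc[order].reset_index(drop=True), dosages[:, order]


def _read_map(path: Path) -> pd.DataFrame:
    mp = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    if mp.shape[1] < 4:
        raise GenotypeFormatError(f"{path}: expected 4 map columns, got {mp.shape[1]}")
    out = pd.DataFrame(
        {"id": mp[1], "chrom": mp[0], "pos": mp[3].astype(np.int64)}
    )
    return out


def _read_groups(path: Path) -> pd.DataFrame:
    gr = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    if gr.shape[1] < 2:
        raise GenotypeFormatError(f"{path}: groups file needs >= 2 columns")
    out = pd.DataFrame({"id": gr[0], "group": gr[1]})
    if gr.shape[1] >= 3:
        out["country"] = gr[2]
    return out


def _read_ped(prefix: Path) -> GenotypeDataset:
    markers = _read_map(prefix.with_suffix(".map"))
    m = len(markers)
    ids, groups, rows = [], [], []
    bad_markers: set[str] = set()
    with open(prefix.with_suffix(".ped")) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * m:
                raise GenotypeFormatError(
                    f"{prefix}.ped line {lineno}: {len(fields) - 6} allele fields "
                    f"for {m} map markers"
                )
            groups.append(fields[0])
            ids.append(fields[1])
            a1 = fields[6::2]
            a2 = fields[7::2]
            row = np.empty(m)
            for j, (x, y) in enumerate(zip(a1, a2)):
                if x == "0" or y == "0":
                    row[j] = np.nan
                    continue
                if x not in "AB" or y not in "AB":
                    bad_markers.add(markers["id"].iloc[j])
                    row[j] = np.nan
                    continue
                row[j] = (x == "B") + (y == "B")
            rows.append(row)
    if bad_markers:
        raise GenotypeFormatError(
            "non-biallelic (non-AB) alleles at markers: " + ", ".join(sorted(bad_markers))
        )
    samples = pd.DataFrame({"id": ids, "group": groups})
    dosages = np.vstack(rows) if rows else np.empty((0, m))
    markers, dosages = _sort_genome_order(markers, dosages)
    return GenotypeDataset(dosages, markers, samples)


def _read_table(prefix: Path, ext: str, sep: str) -> GenotypeDataset:
    markers = _read_map(prefix.with_suffix(".map"))
    tab = pd.read_csv(Path(str(prefix) + ext), sep=sep, na_values=["NA"])
    sample_ids = tab.iloc[:, 0].astype(str)
    dosages = tab.iloc[:, 1:].to_numpy(dtype=float)
    header_ids = list(tab.columns[1:])
    if len(header_ids) != len(markers):
        raise GenotypeFormatError(
            f"{prefix}{ext}: {len(header_ids)} dosage columns for "
            f"{len(markers)} map markers"
        )
    if header_ids != list(markers["id"]):
        # allow map in different order than the table header
        try:
            perm = [header_ids.index(i) for i in markers["id"]]
        except ValueError as e:
            raise GenotypeFormatError(f"{prefix}{ext}: header/map marker id mismatch") from e
        dosages = dosages[:, perm]
    groups = _read_groups(prefix.with_suffix(".groups"))
    samples = pd.DataFrame({"id": sample_ids}).merge(groups, on="id", how="left")
    if samples["group"].isna().any():
        missing = samples.loc[samples["group"].isna(), "id"].iloc[0]
        raise GenotypeFormatError(f"sample {missing!r} absent from groups file")
    markers, dosages = _sort_genome_order(markers, dosages)
    return GenotypeDataset(dosages, markers, samples)


def read_genotypes(prefix: str | Path, format: str = "dosage-matrix") -> GenotypeDataset:
    """Read a genotype panel from ``prefix`` in one of the supported dialects.

    Markers are returned in genome order regardless of file order.
    """
    prefix = Path(prefix)
    if format == "plink-ped":
        return _read_ped(prefix)
    if format == "additive-table":
        return _read_table(prefix, ".raw", r"\s+")
    if format == "dosage-matrix":
        return _read_table(prefix, ".dosages.tsv", "\t")
    raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")


def _write_map(markers: pd.DataFrame, path: Path) -> None:
    out = pd.DataFrame(
        {0: markers["chrom"], 1: markers["id"], 2: 0, 3: markers["pos"]}
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def _write_groups(samples: pd.DataFrame, path: Path) -> None:
    cols = ["id", "group"] + (["country"] if "country" in samples else [])
    samples[cols].to_csv(path, sep="\t", header=False, index=False)


def write_genotypes(
    data: GenotypeDataset, prefix: str | Path, format: str = "dosage-matrix"
) -> None:
    """Write ``data`` under ``prefix`` in the chosen dialect (lossless for
    integer dosages; plink-ped cannot represent fractional imputed values)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    _write_map(data.markers, prefix.with_suffix(".map"))
    if format == "plink-ped":
        allele = {0.0: "A A", 1.0: "A B", 2.0: "B B"}
        with open(prefix.with_suffix(".ped"), "w") as fh:
            for i in range(data.n_samples):
                lead = [
                    str(data.samples["group"].iloc[i]),
                    str(data.samples["id"].iloc[i]),
                    "0", "0", "0", "-9",
                ]
                geno = [
                    "0 0" if np.isnan(d) else allele[float(d)]
                    for d in data.dosages[i]
                ]
                fh.write(" ".join(lead + geno) + "\n")
        return
    if format in ("additive-table", "dosage-matrix"):
        sep = " " if format == "additive-table" else "\t"
        ext = ".raw" if format == "additive-table" else ".dosages.tsv"
        tab = pd.DataFrame(data.dosages, columns=list(data.markers["id"]))
        # keep integer look where possible
        tab = tab.convert_dtypes()
        tab.insert(0, "sample_id", data.samples["id"].to_numpy())
        tab.to_csv(Path(str(prefix) + ext), sep=sep, index=False, na_rep="NA")
        _write_groups(data.samples, prefix.with_suffix(".groups"))
        return
    raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")


# ---------------------------------------------------------------------------
# quality control and frequencies


def apply_qc(
    data: GenotypeDataset, thresholds: QCThresholds = QCThresholds()
) -> tuple[GenotypeDataset, QCReport]:
    """Apply marker call-rate, sample call-rate and MAF filters, in that
    order, recomputing allele frequencies after sample removal (MAF depends
    on the surviving sample set).  All comparisons are strict."""
    X = data.dosages
    n, m = X.shape
    obs = ~np.isnan(X)

    marker_cr = obs.mean(axis=0)
    keep_m1 = marker_cr > thresholds.min_marker_call_rate
    removed_cr = int(m - keep_m1.sum())

    obs1 = obs[:, keep_m1]
    sample_cr = obs1.mean(axis=1) if keep_m1.any() else np.zeros(n)
    keep_s = sample_cr > thresholds.min_sample_call_rate
    removed_s = int(n - keep_s.sum())

    X2 = X[np.ix_(keep_s, keep_m1)]
    obs2 = ~np.isnan(X2)
    with np.errstate(invalid="ignore"):
        p = np.nansum(X2, axis=0) / (2.0 * obs2.sum(axis=0))
    maf = np.minimum(p, 1.0 - p)
    keep_m2 = np.nan_to_num(maf, nan=0.0) > thresholds.min_maf
    removed_maf = int(keep_m1.sum() - keep_m2.sum())

    if not keep_m2.any() or not keep_s.any():
        raise EmptyPanelError(
            "quality control removed every marker or sample "
            f"(markers: call-rate {removed_cr}, MAF {removed_maf}; "
            f"samples: {removed_s})"
        )

    marker_idx = np.flatnonzero(keep_m1)[keep_m2]
    out = GenotypeDataset(
        data.dosages[np.ix_(np.flatnonzero(keep_s), marker_idx)],
        data.markers.iloc[marker_idx],
        data.samples.iloc[np.flatnonzero(keep_s)],
    )
    report = QCReport(
        markers_removed_by_rule={"call_rate": removed_cr, "maf": removed_maf},
        samples_removed=removed_s,
        markers_retained=out.n_markers,
        samples_retained=out.n_samples,
    )
    return out, report


def mean_impute(data: GenotypeDataset) -> GenotypeDataset:
    """Replace missing dosages by the marker mean over non-missing samples.

    A documented stand-in for haplotype-based imputation: it preserves
    allele frequencies exactly but carries no linkage information, so
    imputed cells are fractional dosages.
    """
    X = data.dosages.copy()
    obs = ~np.isnan(X)
    n_obs = obs.sum(axis=0)
    if np.any(n_obs == 0):
        bad = data.markers["id"].iloc[int(np.argmin(n_obs))]
        raise EmptyPanelError(f"marker {bad!r} has no observed genotypes")
    col_mean = np.nansum(X, axis=0) / n_obs
    miss_i, miss_j = np.nonzero(~obs)
    X[miss_i, miss_j] = col_mean[miss_j]
    return GenotypeDataset(X, data.markers.copy(), data.samples.copy())


def allele_frequencies(
    data: GenotypeDataset, sample_subset: str = "all"
) -> AlleleFrequencySet:
    """B-allele frequency per marker: dosage sum over non-missing samples
    of the subset, divided by twice their count.

    ``sample_subset`` is ``"all"`` or a group label.
    """
    if sample_subset == "all":
        X = data.dosages
    else:
        X = data.dosages[data.group_indices(sample_subset)]
    if X.shape[0] == 0:
        raise ValueError("empty sample subset")
    obs = ~np.isnan(X)
    n_used = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nansum(X, axis=0) / (2.0 * n_used)
    return AlleleFrequencySet(p, n_used, scope=sample_subset)
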