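"""Config-driven orchestration of the full analysis:

QC -> imputation -> allele frequencies -> heterozygosity -> pairwise F_ST
-> GRM / inbreeding / block relatedness / PCA -> LD decay -> Ne.

A run is described by a :class:`PipelineConfig` (YAML-serializable).  The
input panel is either read from disk or simulated by one of the built-in
generators.  Every stage writes labelled delimited tables under the output
directory, mirroring the conventional report layouts: a per-group
diversity table (N, H_exp ± SD, H_obs ± SD, F_VR min/mean±SD/max), an
upper-triangle pairwise F_ST matrix, block-relatedness means with the
external-mean diagonal-replacement column, PCA scores and proportions of
variance, and per-group LD decay / Ne trajectories with an adjacent-LD /
non-syntenic-LD / Ne summary.

Groups smaller than ``ld.min_group_size`` (default 64) are excluded from
the LD/Ne tables — sample sizes below that inflate r² by roughly 1/N —
but are retained, flagged, everywhere else.  Named exceptions can be
forced in via ``ld.group_size_overrides``.

Randomness: a single master seed is split deterministically per stage, so
a full rerun with the same config is byte-identical table for table, and
any stage can be re-run in isolation.
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diversity import expected_heterozygosity, observed_heterozygosity, pairwise_fst
from .grm import compute_grm, genomic_inbreeding, grm_pca, group_relatedness
from .io import (
    GenotypeDataset,
    QCThresholds,
    allele_frequencies,
    apply_qc,
    mean_impute,
    read_genotypes,
)
from .ld import ne_from_ld, nonsyntenic_ld, pairwise_ld, syntenic_decay
from .simulate import (
    DivergenceSimSpec,
    FamilySimSpec,
    WrightFisherSimSpec,
    inject_missingness,
    simulate_divergent_populations,
    simulate_families,
    simulate_wright_fisher,
)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "make_report", "ALL_STAGES"]

ALL_STAGES = (
    "panel",
    "qc",
    "freq",
    "diversity",
    "fst",
    "grm",
    "relatedness",
    "pca",
    "ld",
    "ne",
)

_FLOAT_FMT = "%.10g"


@dataclass
class LDConfig:
    max_depth: int = 400
    min_group_size: int = 64
    group_size_overrides: list[str] = field(default_factory=list)
    morgan_per_bp: float = 1e-8
    current_t: float = 20.0
    maf_rerun: float | None = None  # optional stricter-MAF sensitivity rerun


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run bit-identically."""

    seed: int = 0
    input_prefix: str | None = None
    input_format: str = "dosage-matrix"
    simulation: dict | None = None  # {"kind": ..., **spec fields}
    missing_marker_rate: float = 0.0
    missing_sample_rate: float = 0.0
    qc: QCThresholds = field(default_factory=QCThresholds)
    grm_subsets: dict[str, list[str]] = field(default_factory=dict)
    pca_components: int = 40
    ld: LDConfig = field(default_factory=LDConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "qc" in raw:
            raw["qc"] = QCThresholds(**raw["qc"])
        if "ld" in raw:
            raw["ld"] = LDConfig(**raw["ld"])
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    stage_counts: dict[str, dict]
    timestamps: dict[str, float]
    outputs: list[str]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


class StageError(RuntimeError):
    def __init__(self, stage: str, completed: list[str], cause: Exception):
        super().__init__(f"stage {stage!r} failed after {completed}: {cause}")
        self.stage = stage
        self.completed = completed


def _stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage 31-bit seed derived from the master seed
    (stable across processes, unlike the built-in string hash)."""
    tag = zlib.crc32(stage.encode())
    ss = np.random.SeedSequence([master, tag])
    return int(ss.generate_state(1)[0] % (2**31))


def _load_panel(config: PipelineConfig) -> GenotypeDataset:
    if config.simulation is not None:
        sim = dict(config.simulation)
        kind = sim.pop("kind")
        sim.setdefault("seed", _stage_seed(config.seed, "simulate"))
        if kind == "divergence":
            data = simulate_divergent_populations(DivergenceSimSpec(**sim))
        elif kind == "wright_fisher":
            n_sample = sim.pop("n_sample", None)
            data, _ = simulate_wright_fisher(WrightFisherSimSpec(**sim), n_sample)
        elif kind == "families":
            base = sim.pop("base_spec", None)
            if base is not None:
                sim["base_spec"] = DivergenceSimSpec(**base)
            data = simulate_families(FamilySimSpec(**sim))
        else:
            raise ValueError(f"unknown simulation kind {kind!r}")
        if config.missing_marker_rate or config.missing_sample_rate:
            data = inject_missingness(
                data,
                config.missing_marker_rate,
                config.missing_sample_rate,
                seed=_stage_seed(config.seed, "missingness"),
            )
        return data
    if config.input_prefix is None:
        raise ValueError("config needs either input_prefix or simulation")
    return read_genotypes(config.input_prefix, config.input_format)


def _write(df: pd.DataFrame, path: Path, index_label: str | None = None) -> str:
    df.to_csv(
        path,
        sep="\t",
        float_format=_FLOAT_FMT,
        index=index_label is not None,
        index_label=index_label,
    )
    return path.name


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    stages: tuple[str, ...] = ALL_STAGES,
) -> RunManifest:
    """Execute the analysis and write its tables under ``outdir``.

    ``stages`` selects which stages write outputs; prerequisite
    computation always runs in memory so any single stage is re-runnable
    from the config alone.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, dict] = {}
    stamps: dict[str, float] = {"start": time.time()}
    outputs: list[str] = []
    completed: list[str] = []
    want = set(stages)
    unknown = want - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}; choose from {ALL_STAGES}")

    def run_stage(name, fn):
        try:
            fn()
        except Exception as e:  # noqa: BLE001 - abort with stage context
            raise StageError(name, completed, e) from e
        completed.append(name)
        stamps[name] = time.time()

    state: dict = {}

    def st_panel():
        data = _load_panel(config)
        state["raw"] = data
        counts["panel"] = {"samples": data.n_samples, "markers": data.n_markers}
        if "panel" in want:
            from .io import write_genotypes

            write_genotypes(data, outdir / "panel", "dosage-matrix")
            outputs.extend(
                ["panel.dosages.tsv", "panel.map", "panel.groups"]
            )

    def st_qc():
        data, report = apply_qc(state["raw"], config.qc)
        state["qc"] = data
        state["imputed"] = mean_impute(data)
        counts["qc"] = {
            "markers_removed_call_rate": report.markers_removed_by_rule["call_rate"],
            "markers_removed_maf": report.markers_removed_by_rule["maf"],
            "samples_removed": report.samples_removed,
            "markers_retained": report.markers_retained,
            "samples_retained": report.samples_retained,
        }
        if "qc" in want:
            outputs.append(
                _write(pd.DataFrame([counts["qc"]]), outdir / "qc_report.tsv")
            )

    def st_freq():
        data = state["imputed"]
        freqs = allele_frequencies(data)
        state["freqs"] = freqs
        counts["freq"] = {"markers": len(freqs.frequencies)}
        if "freq" in want:
            tab = pd.DataFrame(
                {
                    "marker": data.markers["id"],
                    "chrom": data.markers["chrom"],
                    "pos": data.markers["pos"],
                    "b_allele_freq": freqs.frequencies,
                    "n_samples": freqs.n_samples_used,
                }
            )
            outputs.append(_write(tab, outdir / "allele_frequencies.tsv"))

    def st_diversity():
        data = state["imputed"]
        rows = []
        for g in data.groups:
            he = expected_heterozygosity(allele_frequencies(data, g), g)
            ho = observed_heterozygosity(state["qc"], g)
            rows.append(
                {
                    "group": g,
                    "n": he.n_samples,
                    "h_exp_mean": he.mean_expected,
                    "h_exp_sd": he.sd_expected,
                    "h_obs_mean": ho.mean_observed,
                    "h_obs_sd": ho.sd_observed,
                }
            )
        state["diversity"] = pd.DataFrame(rows)
        counts["diversity"] = {"groups": len(rows)}
        if "diversity" in want:
            outputs.append(
                _write(state["diversity"], outdir / "heterozygosity_by_group.tsv")
            )

    def st_fst():
        data = state["imputed"]
        if len(data.groups) < 2:
            counts["fst"] = {"pairs": 0}
            return
        mat = pairwise_fst(data)
        counts["fst"] = {"pairs": int(np.isfinite(mat.values.to_numpy()).sum() // 2)}
        if "fst" in want:
            outputs.append(
                _write(mat.to_table(), outdir / "fst_matrix.tsv", index_label="group")
            )

    def st_grm():
        data = state["imputed"]
        grm = compute_grm(data)
        state["grm"] = grm
        inb = genomic_inbreeding(grm)
        state["inbreeding"] = inb
        counts["grm"] = {"dimension": grm.n, "mean_diagonal": grm.mean_diagonal}
        if "grm" in want:
            dense = pd.DataFrame(
                grm.values, index=grm.sample_ids, columns=grm.sample_ids
            )
            outputs.append(_write(dense, outdir / "grm_dense.tsv", index_label="id"))
            iu = np.triu_indices(grm.n)
            sparse = pd.DataFrame(
                {
                    "id1": np.asarray(grm.sample_ids)[iu[0]],
                    "id2": np.asarray(grm.sample_ids)[iu[1]],
                    "value": grm.values[iu],
                }
            )
            outputs.append(_write(sparse, outdir / "grm_sparse.tsv"))
            outputs.append(
                _write(
                    inb.per_sample.to_frame(),
                    outdir / "inbreeding_per_sample.tsv",
                    index_label="id",
                )
            )
            outputs.append(
                _write(
                    inb.per_group, outdir / "inbreeding_by_group.tsv", index_label="group"
                )
            )
            # per-group diversity + inbreeding summary (headline layout)
            div = state["diversity"].merge(
                inb.per_group[["min", "mean", "sd", "max"]].rename(
                    columns=lambda c: f"f_vr_{c}"
                ),
                left_on="group",
                right_index=True,
            )
            outputs.append(_write(div, outdir / "diversity_summary.tsv"))
        # named subset GRMs, re-centered on their own frequencies
        for name, groups in config.grm_subsets.items():
            idx = np.flatnonzero(data.samples["group"].isin(groups).to_numpy())
            sub = compute_grm(data.subset_samples(idx))
            state[f"grm:{name}"] = sub
            counts["grm"][f"subset_{name}_mean_diagonal"] = sub.mean_diagonal
            if "grm" in want:
                sub_inb = genomic_inbreeding(sub)
                outputs.append(
                    _write(
                        sub_inb.per_group,
                        outdir / f"inbreeding_by_group_{name}.tsv",
                        index_label="group",
                    )
                )

    def st_relatedness():
        rel = group_relatedness(state["grm"])
        state["relatedness"] = rel
        counts["relatedness"] = {"groups": len(rel.groups)}
        if "relatedness" in want:
            tab = rel.block_means.copy()
            tab["external_mean"] = rel.external_mean
            outputs.append(
                _write(tab, outdir / "block_relatedness.tsv", index_label="group")
            )
            for name in config.grm_subsets:
                sub_rel = group_relatedness(state[f"grm:{name}"])
                sub_tab = sub_rel.block_means.copy()
                sub_tab["external_mean"] = sub_rel.external_mean
                outputs.append(
                    _write(
                        sub_tab,
                        outdir / f"block_relatedness_{name}.tsv",
                        index_label="group",
                    )
                )

    def st_pca():
        pca = grm_pca(state["grm"], config.pca_components)
        state["pca"] = pca
        counts["pca"] = {"components": len(pca.pov)}
        if "pca" in want:
            scores = pca.scores.copy()
            scores.insert(0, "group", state["grm"].groups.to_numpy())
            outputs.append(_write(scores, outdir / "pca_scores.tsv", index_label="id"))
            pov = pd.DataFrame(
                {
                    "component": np.arange(1, len(pca.pov) + 1),
                    "eigenvalue": pca.eigenvalues,
                    "pov": pca.pov,
                    "cumulative_pov": pca.cumulative_pov,
                }
            )
            outputs.append(_write(pov, outdir / "pca_pov.tsv"))

    def st_ld():
        data = state["imputed"]
        ldc = config.ld
        included, excluded = [], []
        for g in data.groups:
            size = int((data.samples["group"] == g).sum())
            if size >= ldc.min_group_size or g in ldc.group_size_overrides:
                included.append(g)
            else:
                excluded.append((g, size))
        state["ld_excluded"] = excluded
        summaries = []
        state["ld_curves"] = {}
        for g in included:
            sub = data.subset_samples(data.group_indices(g))
            if ldc.maf_rerun is not None:
                p = allele_frequencies(sub).frequencies
                keep = np.minimum(p, 1 - p) > ldc.maf_rerun
                sub = sub.subset_markers(np.flatnonzero(keep))
            rec = pairwise_ld(sub, ldc.max_depth)
            curve = syntenic_decay(rec, sub.markers)
            state["ld_curves"][g] = curve
            try:
                ns = nonsyntenic_ld(rec).mean_r2
            except ValueError:
                ns = np.nan
            summaries.append(
                {
                    "group": g,
                    "n": sub.n_samples,
                    "ld_adjacent": curve.adjacent_r2,
                    "ld_nonsyntenic": ns,
                    "caution": "small_n" if sub.n_samples < ldc.min_group_size else "",
                }
            )
            if "ld" in want:
                outputs.append(_write(curve.table, outdir / f"ld_decay_{g}.tsv"))
        state["ld_summary"] = pd.DataFrame(summaries)
        counts["ld"] = {
            "groups_included": len(included),
            "groups_excluded": len(excluded),
        }

    def st_ne():
        ldc = config.ld
        rows = []
        for g, curve in state["ld_curves"].items():
            traj = ne_from_ld(curve, ldc.morgan_per_bp, ldc.current_t)
            rows.append(
                {"group": g, "ne_current": traj.current_ne, "t_bin": traj.current_t}
            )
            if "ne" in want:
                outputs.append(_write(traj.table, outdir / f"ne_trajectory_{g}.tsv"))
        ne_tab = pd.DataFrame(rows)
        if "ne" in want or "ld" in want:
            summary = state["ld_summary"].merge(
                ne_tab[["group", "ne_current"]], on="group", how="left"
            )
            outputs.append(_write(summary, outdir / "ld_ne_summary.tsv"))
        counts["ne"] = {"groups": len(rows)}

    run_stage("panel", st_panel)
    run_stage("qc", st_qc)
    run_stage("freq", st_freq)
    run_stage("diversity", st_diversity)
    run_stage("fst", st_fst)
    run_stage("grm", st_grm)
    run_stage("relatedness", st_relatedness)
    run_stage("pca", st_pca)
    run_stage("ld", st_ld)
    run_stage("ne", st_ne)

    stamps["end"] = time.time()
    manifest = RunManifest(
        config=config.to_dict(),
        version=__version__,
        seed=config.seed,
        stage_counts=counts,
        timestamps=stamps,
        outputs=sorted(set(outputs)),
    )
    manifest.save(outdir / "manifest.json")
    return manifest


def excluded_note(excluded: list[tuple[str, int]]) -> str:
    if not excluded:
        return "No groups excluded from LD/Ne."
    items = ", ".join(f"{g} (n={n})" for g, n in excluded)
    return f"Excluded from LD/Ne (below minimum group size): {items}."


def make_report(outdir: str | Path) -> Path:
    """Assemble a navigable markdown summary of a finished run.

    Missing tables are listed rather than fatal.  Timestamps are excluded
    so re-runs from the same manifest produce byte-identical report
    bodies.
    """
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    lines = [
        "# Analysis report",
        "",
        f"herdstat version {manifest['version']}, master seed {manifest['seed']}.",
        "",
        "## Stage record counts",
        "",
    ]
    for stage, rec in manifest["stage_counts"].items():
        fields = ", ".join(f"{k}={v}" for k, v in rec.items())
        lines.append(f"- **{stage}**: {fields}")
    lines += ["", "## Tables", ""]
    missing = []
    for name in manifest["outputs"]:
        if (outdir / name).exists():
            lines.append(f"- [{name}]({name})")
        else:
            missing.append(name)
    if missing:
        lines += ["", "## Missing tables", ""]
        lines += [f"- {name}" for name in missing]
    ld_summary = outdir / "ld_ne_summary.tsv"
    if ld_summary.exists():
        tab = pd.read_csv(ld_summary, sep="\t")
        flagged = tab[tab["caution"].notna() & (tab["caution"] != "")]
        if not flagged.empty:
            lines += ["", "## Cautions", ""]
            for _, row in flagged.iterrows():
                lines.append(
                    f"- LD/Ne for group {row['group']} is based on n={row['n']} "
                    "(below the minimum group size); treat with caution."
                )
    qc_counts = manifest["stage_counts"].get("ld", {})
    if qc_counts.get("groups_excluded"):
        lines += [
            "",
            f"{qc_counts['groups_excluded']} group(s) were excluded from the "
            "LD/Ne stages for falling below the minimum group size.",
        ]
    body = "\n".join(lines) + "\n"
    path = outdir / "report.md"
    path.write_text(body)
    return path
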