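"""Manifest-driven orchestration of the full repertoire analysis.

Given a study manifest — one row per sample with ``sample_id, subject_id,
tissue, phase, condition, file`` — the pipeline ingests every clone table,
computes per-sample diversity and homeostasis, pairwise lymph-node/joint
overlap with the same-animal diagonal, V/J gene-usage matrices with PCA
and per-gene group comparisons, cross-site top-clone rank correlations,
and the group statistics enumerated from the manifest's factor structure
(early vs late within tissue, inflamed vs control within phase).

All interpretation-sensitive settings (identity level, overlap scale, D50
reference total, absent-clone policy, usage weighting) live in one
:class:`AnalysisConfig`; a hash of the config is stamped on every output
table so reruns are attributable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity as dv
from . import gene_usage as gu
from . import overlap as ov
from . import stats as st
from . import tracking as tr
from .io import read_airr, read_clone_table
from .models import Repertoire, RepertoireError

log = logging.getLogger(__name__)

MANIFEST_COLUMNS = ["sample_id", "subject_id", "tissue", "phase", "condition", "file"]


@dataclass(frozen=True)
class AnalysisConfig:
    identity_level: str = "nt"       # clonality / D50 / homeostasis key
    overlap_level: str = "aa"        # exact-sharing key
    overlap_scale: float = 1.0
    reference_total: str = "top10k"  # D50 large-sample branch reference
    weighting: str = "reads"         # gene-usage weighting
    n_components: int = 2
    top_n: int = 10
    min_reads: int = 2               # read-threshold clone count
    absent_policy: str = "censor_to_Uplus1"
    alpha: float = 0.05
    input_format: str = "airr"       # airr | mixcr | irepertoire

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class ResultsBundle:
    diversity: pd.DataFrame
    homeostasis: pd.DataFrame
    overlap_long: pd.DataFrame
    overlap_matrices: dict[str, ov.OverlapMatrix]
    paired_overlap: pd.DataFrame
    usage: gu.GeneUsageMatrix | None
    pca: gu.PcaResult | None
    gene_comparison: pd.DataFrame | None
    tracking: pd.DataFrame
    group_comparisons: pd.DataFrame
    config_hash: str
    log_lines: list[str] = field(default_factory=list)


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise RepertoireError(f"manifest lacks columns: {missing}")
    if manifest["sample_id"].duplicated().any():
        dup = manifest.loc[manifest["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise RepertoireError(f"duplicate sample_id in manifest: {dup!r}")
    return manifest


def load_repertoires(
    manifest: pd.DataFrame, config: AnalysisConfig, base_dir: str | Path = "."
) -> list[Repertoire]:
    base = Path(base_dir)
    reps = []
    for row in manifest.itertuples(index=False):
        path = base / row.file
        if not path.exists():
            raise RepertoireError(f"sample {row.sample_id!r}: input file missing: {path}")
        meta = dict(
            sample_id=row.sample_id, subject_id=row.subject_id,
            tissue=row.tissue, phase=row.phase, condition=row.condition,
        )
        if config.input_format == "airr":
            reps.append(read_airr(path, **meta))
        else:
            reps.append(read_clone_table(path, dialect=config.input_format, **meta))
    return reps


def _group_rows(values: dict[str, float], groups: dict[str, list[str]]):
    """Welch + Student comparisons for every 2-level contrast in ``groups``."""
    rows = []
    names = list(groups)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a = [values[s] for s in groups[names[i]] if s in values and np.isfinite(values[s])]
            b = [values[s] for s in groups[names[j]] if s in values and np.isfinite(values[s])]
            if len(a) < 2 or len(b) < 2:
                continue
            for fn in (st.student_t, st.welch_t):
                cmp_ = fn(a, b, labels=(names[i], names[j]))
                rows.append((names[i], names[j], cmp_))
    return rows


def run_pipeline(
    manifest: pd.DataFrame,
    config: AnalysisConfig = AnalysisConfig(),
    *,
    repertoires: list[Repertoire] | None = None,
    base_dir: str | Path = ".",
    out_dir: str | Path | None = None,
) -> ResultsBundle:
    """Execute the full analysis; fails loudly, never partially."""
    manifest = validate_manifest(manifest)
    cfg_hash = config.hash()
    lines = [f"config_hash={cfg_hash}"]
    if repertoires is None:
        repertoires = load_repertoires(manifest, config, base_dir)
    by_id = {r.sample_id: r for r in repertoires}
    if set(by_id) != set(manifest["sample_id"]):
        raise RepertoireError("repertoires do not match manifest sample_ids")

    # ---- per-sample diversity & homeostasis
    div_rows, hom_rows = [], []
    for sid in manifest["sample_id"]:
        rep = by_id[sid]
        res = dv.d50(rep, config.identity_level, config.reference_total)
        hom = dv.homeostasis_profile(rep, config.identity_level)
        div_rows.append(
            {
                "sample_id": sid, "subject_id": rep.subject_id, "tissue": rep.tissue,
                "phase": rep.phase, "condition": rep.condition,
                "clonality": res.clonality, "d50": res.d50, "branch": res.branch,
                "total_reads": rep.total_reads,
                "top_n_proportion": dv.top_n_proportion(rep, config.top_n, config.identity_level),
                f"clones_ge{config.min_reads}": dv.count_clones_at_least(
                    rep, config.min_reads, config.identity_level
                ),
                "median_clone_reads": dv.median_clone_frequency(rep, config.identity_level),
                "config_hash": cfg_hash,
            }
        )
        hom_rows.append(
            {"sample_id": sid, "tissue": rep.tissue, "phase": rep.phase,
             "condition": rep.condition,
             **{f"bin_{e}": p for e, p in zip(hom.bin_edges, hom.proportions)},
             "remainder": hom.remainder, "config_hash": cfg_hash}
        )
        lines.append(f"{sid}: d50_branch={res.branch}")
    diversity_df = pd.DataFrame(div_rows)
    homeostasis_df = pd.DataFrame(hom_rows)

    # ---- overlap per (phase, condition): pLN rows × joint columns
    matrices: dict[str, ov.OverlapMatrix] = {}
    long_frames, paired_rows = [], []
    for (phase, cond), sub in manifest.groupby(["phase", "condition"], dropna=False):
        plns = [by_id[s] for s in sub.loc[sub["tissue"] == "pLN", "sample_id"]]
        joints = [by_id[s] for s in sub.loc[sub["tissue"] == "joint", "sample_id"]]
        if not plns or not joints:
            continue
        m = ov.overlap_matrix(plns, joints, config.overlap_level, config.overlap_scale)
        key = f"{phase}_{cond}"
        matrices[key] = m
        lf = m.to_long()
        lf.insert(0, "group", key)
        lf["config_hash"] = cfg_hash
        long_frames.append(lf)
        pairing = {}
        for p in plns:
            mates = [j.sample_id for j in joints if j.subject_id == p.subject_id]
            if len(mates) == 1:
                pairing[p.sample_id] = mates[0]
        if pairing and len(pairing) == len(plns):
            for row_id, value in ov.paired_diagonal(m, pairing):
                paired_rows.append(
                    {"group": key, "phase": phase, "condition": cond,
                     "pln": row_id, "joint": pairing[row_id], "overlap_index": value,
                     "config_hash": cfg_hash}
                )
    overlap_long = (
        pd.concat(long_frames, ignore_index=True)
        if long_frames
        else pd.DataFrame(columns=["group", "row_id", "col_id", "shared", "index", "config_hash"])
    )
    paired_df = pd.DataFrame(paired_rows)

    # ---- V usage, PCA, per-gene comparison (inflamed samples)
    usage = pca = gene_cmp = None
    inflamed = manifest[manifest["condition"] == "inflamed"]
    if len(inflamed) >= 3:
        ureps = [by_id[s] for s in inflamed["sample_id"]]
        usage = gu.usage_matrix(ureps, "V", config.weighting)
        ncomp = min(config.n_components, len(ureps) - 1, len(usage.gene_labels))
        pca = gu.usage_pca(usage, ncomp)
        uf = usage.to_frame()
        late_pln = inflamed[(inflamed["phase"] == "late") & (inflamed["tissue"] == "pLN")]
        early_pln = inflamed[(inflamed["phase"] == "early") & (inflamed["tissue"] == "pLN")]
        if len(late_pln) >= 2 and len(early_pln) >= 2:
            gene_cmp = gu.compare_gene_usage(
                uf.loc[early_pln["sample_id"]], uf.loc[late_pln["sample_id"]],
                alpha=config.alpha,
            )
            gene_cmp["config_hash"] = cfg_hash

    # ---- cross-site top-clone tracking per subject
    track_rows = []
    for subject, sub in manifest.groupby("subject_id"):
        pl = sub[sub["tissue"] == "pLN"]["sample_id"]
        jt = sub[sub["tissue"] == "joint"]["sample_id"]
        if len(pl) != 1 or len(jt) != 1:
            continue
        res = tr.cross_site_ranks(
            by_id[jt.iloc[0]], by_id[pl.iloc[0]], config.top_n,
            config.overlap_level, config.absent_policy,
        )
        meta = sub.iloc[0]
        track_rows.append(
            {"subject_id": subject, "phase": meta["phase"], "condition": meta["condition"],
             "rho": res.rho, "p_value": res.p_value, "n_absent": res.n_absent,
             "normality_p": res.normality_p, "note": res.note, "config_hash": cfg_hash}
        )
    tracking_df = pd.DataFrame(track_rows)

    # ---- group comparisons enumerated from the factor structure
    cmp_rows = []
    metrics = ["clonality", "d50", "top_n_proportion", f"clones_ge{config.min_reads}"]
    for tissue in manifest["tissue"].dropna().unique():
        tiss = diversity_df[diversity_df["tissue"] == tissue]
        for metric in metrics:
            # early vs late within inflamed
            infl = tiss[tiss["condition"] == "inflamed"]
            groups = {
                ph: list(infl.loc[infl["phase"] == ph, "sample_id"]) for ph in ("early", "late")
            }
            vals = dict(zip(tiss["sample_id"], tiss[metric]))
            for la, lb, cmp_ in _group_rows(vals, groups):
                cmp_rows.append(
                    {"tissue": tissue, "metric": metric, "contrast": "phase",
                     "group_a": la, "group_b": lb, "test": cmp_.test,
                     "statistic": cmp_.statistic, "p_value": cmp_.p_value,
                     "significant": cmp_.significant, "config_hash": cfg_hash}
                )
            # inflamed vs control within phase
            for ph in ("early", "late"):
                phase_df = tiss[tiss["phase"] == ph]
                groups = {
                    c: list(phase_df.loc[phase_df["condition"] == c, "sample_id"])
                    for c in ("inflamed", "control")
                }
                for la, lb, cmp_ in _group_rows(vals, groups):
                    cmp_rows.append(
                        {"tissue": tissue, "metric": metric, "contrast": f"condition@{ph}",
                         "group_a": la, "group_b": lb, "test": cmp_.test,
                         "statistic": cmp_.statistic, "p_value": cmp_.p_value,
                         "significant": cmp_.significant, "config_hash": cfg_hash}
                    )
    group_df = pd.DataFrame(cmp_rows)

    bundle = ResultsBundle(
        diversity_df, homeostasis_df, overlap_long, matrices, paired_df,
        usage, pca, gene_cmp, tracking_df, group_df, cfg_hash, lines,
    )
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def write_bundle(bundle: ResultsBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.diversity.to_csv(out / "diversity.tsv", sep="\t", index=False)
    bundle.homeostasis.to_csv(out / "homeostasis.tsv", sep="\t", index=False)
    bundle.overlap_long.to_csv(out / "overlap_long.tsv", sep="\t", index=False)
    bundle.paired_overlap.to_csv(out / "paired_overlap.tsv", sep="\t", index=False)
    bundle.tracking.to_csv(out / "tracking.tsv", sep="\t", index=False)
    bundle.group_comparisons.to_csv(out / "group_comparisons.tsv", sep="\t", index=False)
    for key, m in bundle.overlap_matrices.items():
        m.to_frame().to_csv(out / f"overlap_matrix_{key}.tsv", sep="\t")
    if bundle.usage is not None:
        bundle.usage.to_frame().to_csv(out / "v_usage.tsv", sep="\t")
    if bundle.pca is not None:
        pd.DataFrame(
            bundle.pca.scores,
            index=bundle.pca.sample_ids,
            columns=[f"PC{i+1}" for i in range(bundle.pca.scores.shape[1])],
        ).to_csv(out / "pca_scores.tsv", sep="\t")
        pd.DataFrame(
            bundle.pca.loadings,
            index=bundle.pca.gene_labels,
            columns=[f"PC{i+1}" for i in range(bundle.pca.loadings.shape[1])],
        ).to_csv(out / "pca_loadings.tsv", sep="\t")
    if bundle.gene_comparison is not None:
        bundle.gene_comparison.to_csv(out / "gene_comparison.tsv", sep="\t", index=False)
    (out / "run_log.txt").write_text("\n".join(bundle.log_lines) + "\n")


def render_report(bundle: ResultsBundle, out_dir: str | Path) -> list[str]:
    """Render basic figure analogues; plotting failures never corrupt tables."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    notes: list[str] = []

    def _fig(name: str, fn) -> None:
        try:
            fig = fn()
            fig.savefig(out / name, dpi=120, bbox_inches="tight")
            plt.close(fig)
            written.append(name)
        except Exception as exc:  # noqa: BLE001 - report, never fail the run
            notes.append(f"{name}: skipped ({exc})")

    def _homeostasis():
        df = bundle.homeostasis.set_index("sample_id")
        bins = [c for c in df.columns if c.startswith("bin_")]
        fig, ax = plt.subplots(figsize=(max(6, len(df) * 0.4), 4))
        bottom = np.zeros(len(df))
        for b in bins:
            ax.bar(df.index, df[b], bottom=bottom, label=b)
            bottom += df[b].to_numpy()
        ax.set_ylabel("fraction of reads")
        ax.legend(fontsize=6)
        ax.tick_params(axis="x", rotation=90, labelsize=6)
        return fig

    def _diversity():
        df = bundle.diversity
        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        for ax, metric in zip(axes, ("clonality", "d50")):
            for i, (grp, sub) in enumerate(df.groupby(["tissue", "phase"], dropna=False)):
                ax.scatter([i] * len(sub), sub[metric], label="/".join(map(str, grp)))
            ax.set_title(metric)
            ax.tick_params(axis="x", labelbottom=False)
        axes[1].legend(fontsize=6)
        return fig

    def _overlap():
        keys = list(bundle.overlap_matrices)
        fig, axes = plt.subplots(1, max(len(keys), 1), figsize=(4 * max(len(keys), 1), 4))
        axes = np.atleast_1d(axes)
        for ax, key in zip(axes, keys):
            m = bundle.overlap_matrices[key]
            im = ax.imshow(m.values, cmap="viridis")
            ax.set_title(key, fontsize=8)
            fig.colorbar(im, ax=ax, shrink=0.7)
        return fig

    def _pca():
        if bundle.pca is None:
            raise RuntimeError("no PCA in bundle")
        fig, ax = plt.subplots(figsize=(5, 4))
        groups = bundle.pca.group_labels or ["sample"] * len(bundle.pca.sample_ids)
        for grp in sorted(set(groups)):
            idx = [i for i, g in enumerate(groups) if g == grp]
            ax.scatter(bundle.pca.scores[idx, 0], bundle.pca.scores[idx, 1], label=grp)
        evf = bundle.pca.explained_variance_fraction
        ax.set_xlabel(f"PC1 ({evf[0]:.0%})")
        if len(evf) > 1:
            ax.set_ylabel(f"PC2 ({evf[1]:.0%})")
        ax.legend(fontsize=6)
        return fig

    def _tracking():
        df = bundle.tracking
        fig, ax = plt.subplots(figsize=(5, 4))
        for i, (grp, sub) in enumerate(df.groupby(["phase", "condition"], dropna=False)):
            ax.scatter([i] * len(sub), sub["rho"], label="/".join(map(str, grp)))
        ax.set_ylabel("Spearman rho (joint top clones vs pLN rank)")
        ax.legend(fontsize=6)
        ax.tick_params(axis="x", labelbottom=False)
        return fig

    _fig("homeostasis.png", _homeostasis)
    _fig("diversity.png", _diversity)
    _fig("overlap_heatmaps.png", _overlap)
    _fig("pca.png", _pca)
    _fig("rank_correlation.png", _tracking)

    index = ["# Report", "", "Figures:"] + [f"- {w}" for w in written]
    if notes:
        index += ["", "Omitted panels:"] + [f"- {n}" for n in notes]
    (out / "index.md").write_text("\n".join(index) + "\n")
    return written
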