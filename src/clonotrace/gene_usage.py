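"""TRBV/TRBJ gene-usage frequencies, PCA, and per-gene group comparison.

Usage frequencies summarize repertoire composition on the simplex over the
observed gene labels; the default weighting is by reads (each clone
contributes its read mass), with clone weighting (each unique clone counts
once) available because published figures rarely state which was used.

PCA operates on the sample × gene frequency matrix, column-centered but not
variance-scaled: frequencies already share a scale, and unit-scaling rare
genes would amplify noise.  A deterministic sign convention (the
largest-magnitude loading of each component is positive) keeps scores
reproducible across library versions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .models import Repertoire, RepertoireError, _gene_sort_key
from .io import collapse_clones

log = logging.getLogger(__name__)


def gene_frequencies(
    rep: Repertoire, segment: str = "V", weighting: str = "reads"
) -> pd.Series:
    """Per-gene usage fractions for one repertoire (sums to 1)."""
    if segment not in ("V", "J"):
        raise ValueError("segment must be 'V' or 'J'")
    if weighting not in ("reads", "clones"):
        raise ValueError("weighting must be 'reads' or 'clones'")
    col = "v_gene" if segment == "V" else "j_gene"
    df = collapse_clones(rep, "nt").clones
    resolvable = df[col] != ""
    n_unres = int((~resolvable).sum())
    if n_unres:
        log.info("%s: %d clones with unresolvable %s label excluded", rep.sample_id, n_unres, col)
    df = df[resolvable]
    if df.empty:
        raise RepertoireError(f"{rep.sample_id}: no resolvable {col} labels")
    if weighting == "reads":
        counts = df.groupby(col)["reads"].sum()
    else:
        counts = df.groupby(col).size()
    freqs = counts / counts.sum()
    return freqs.reindex(sorted(freqs.index, key=_gene_sort_key)).astype(float)


@dataclass
class GeneUsageMatrix:
    sample_ids: list[str]
    gene_labels: list[str]
    frequencies: np.ndarray  # samples × genes, rows on the simplex
    weighting: str
    segment: str
    group_labels: list[str] | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.frequencies, index=self.sample_ids, columns=self.gene_labels)


def usage_matrix(
    reps: list[Repertoire],
    segment: str = "V",
    weighting: str = "reads",
    group_by: tuple[str, ...] = ("tissue", "phase"),
) -> GeneUsageMatrix:
    """Dense sample × gene frequency matrix over the union of observed genes."""
    if len(reps) < 2:
        raise RepertoireError("usage_matrix requires at least two samples")
    ids = [r.sample_id for r in reps]
    if len(set(ids)) != len(ids):
        raise RepertoireError("duplicate sample_id in usage_matrix input")
    per_sample = {r.sample_id: gene_frequencies(r, segment, weighting) for r in reps}
    genes = sorted({g for s in per_sample.values() for g in s.index}, key=_gene_sort_key)
    mat = np.zeros((len(reps), len(genes)))
    for i, r in enumerate(reps):
        mat[i] = per_sample[r.sample_id].reindex(genes).fillna(0.0).to_numpy()
    groups = [
        "/".join(str(getattr(r, a)) for a in group_by if getattr(r, a) is not None)
        for r in reps
    ]
    return GeneUsageMatrix(ids, genes, mat, weighting, segment, groups)


@dataclass
class PcaResult:
    sample_ids: list[str]
    gene_labels: list[str]
    scores: np.ndarray  # samples × components
    loadings: np.ndarray  # genes × components
    explained_variance_fraction: np.ndarray
    group_labels: list[str] | None = None


def usage_pca(m: GeneUsageMatrix, n_components: int = 2) -> PcaResult:
    """PCA on centered (unscaled) usage frequencies with fixed sign convention."""
    n_samples, n_genes = m.frequencies.shape
    if n_samples < 3:
        raise RepertoireError("usage_pca requires at least 3 samples")
    if n_components > min(n_samples - 1, n_genes):
        raise ValueError("n_components exceeds min(samples-1, genes)")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(m.frequencies)
    loadings = pca.components_.T  # genes × components
    # sign convention: largest-|loading| entry of each component is positive
    for k in range(n_components):
        top = np.argmax(np.abs(loadings[:, k]))
        if loadings[top, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    return PcaResult(
        list(m.sample_ids),
        list(m.gene_labels),
        scores,
        loadings,
        pca.explained_variance_ratio_,
        list(m.group_labels) if m.group_labels else None,
    )


def sidak_adjust(pvals: np.ndarray) -> np.ndarray:
    """Šidák family-wise adjustment: 1 − (1 − p)^m over m comparisons."""
    p = np.asarray(pvals, dtype=float)
    return 1.0 - (1.0 - p) ** p.size


def compare_gene_usage(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    alpha: float = 0.05,
    test: str = "student",
) -> pd.DataFrame:
    """Per-gene two-sample comparison with Šidák family-wise correction.

    ``group_a``/``group_b`` are sample × gene frequency frames (e.g. row
    subsets of :meth:`GeneUsageMatrix.to_frame`); columns are aligned on
    their union, absent genes densified to 0.  Returns one row per gene
    with the t statistic, raw and Šidák-adjusted p-values, and a
    significance flag at ``alpha``.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise RepertoireError("each group needs at least 2 samples")
    genes = sorted(set(group_a.columns) | set(group_b.columns), key=_gene_sort_key)
    a = group_a.reindex(columns=genes).fillna(0.0).to_numpy()
    b = group_b.reindex(columns=genes).fillna(0.0).to_numpy()
    stats_, pvals = [], []
    equal_var = test == "student"
    for j in range(len(genes)):
        if np.var(a[:, j]) == 0 and np.var(b[:, j]) == 0:
            if a[:, j].mean() == b[:, j].mean():
                t, p = 0.0, 1.0
            else:
                t, p = np.inf, 0.0
        else:
            t, p = stats.ttest_ind(a[:, j], b[:, j], equal_var=equal_var)
        stats_.append(float(t))
        pvals.append(float(p))
    adj = sidak_adjust(np.array(pvals))
    return pd.DataFrame(
        {
            "gene": genes,
            "mean_a": a.mean(axis=0),
            "mean_b": b.mean(axis=0),
            "statistic": stats_,
            "p_value": pvals,
            "p_sidak": adj,
            "significant": adj < alpha,
        }
    )
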