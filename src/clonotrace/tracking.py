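"""Rank clones and track the top clones of one tissue in its paired tissue.

The cross-site analysis asks: where do the inflamed joint's most expanded
clones sit in the same animal's draining lymph-node repertoire?  Ranks are
dense (1 = most abundant, no ties after deterministic tie-breaking), clones
are matched by exact identity key (amino-acid level by default, matching
the overlap analysis), and concordance is summarized by Spearman's rank
correlation.  A D'Agostino–Pearson normality statistic is reported
alongside as an informational gate; it never switches the estimator.

A joint clone absent from the lymph node has no rank there.  The default
policy censors it to rank U+1 (just beyond the lymph-node repertoire) so
all top-N clones enter the correlation; ``absent_policy="drop"`` excludes
absent clones instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import Repertoire
from .io import collapse_clones


@dataclass(frozen=True)
class RankedClone:
    key: str
    reads: int
    rank: int
    sample_id: str


@dataclass
class CrossSiteRankResult:
    subject_id: str
    pairs: list[tuple[str, int, int | None]]  # (key, joint rank, pln rank or None)
    n_absent: int
    rho: float  # nan when undefined
    p_value: float
    normality_stat: float
    normality_p: float
    normality_note: str
    note: str = ""


def top_clones(rep: Repertoire, n: int, level: str = "aa") -> list[RankedClone]:
    """The n most abundant clones under the deterministic ordering."""
    if n < 1:
        raise ValueError("n must be >= 1")
    collapsed = collapse_clones(rep, level)
    keys = collapsed.identity_keys(level)
    reads = collapsed.clones["reads"]
    out = []
    for i in range(min(n, len(collapsed))):
        out.append(RankedClone(keys.iloc[i], int(reads.iloc[i]), i + 1, rep.sample_id))
    return out


def rank_of(rep: Repertoire, key: str, level: str = "aa") -> int | None:
    """Dense rank of ``key`` in the repertoire, or None if absent."""
    collapsed = collapse_clones(rep, level)
    keys = collapsed.identity_keys(level)
    hits = np.flatnonzero(keys.to_numpy() == key)
    return int(hits[0]) + 1 if hits.size else None


def rank_map(rep: Repertoire, level: str = "aa") -> dict[str, int]:
    """Identity key → dense rank for a whole repertoire (single pass)."""
    collapsed = collapse_clones(rep, level)
    return {k: i + 1 for i, k in enumerate(collapsed.identity_keys(level))}


def cross_site_ranks(
    joint: Repertoire,
    pln: Repertoire,
    n: int = 10,
    level: str = "aa",
    absent_policy: str = "censor_to_Uplus1",
) -> CrossSiteRankResult:
    """Map the joint's top-n clones into the paired lymph node's ranking.

    Orientation is fixed (joint → pLN); transposing the arguments answers a
    different question.  See the module docstring for the absent policy.
    """
    if absent_policy not in ("censor_to_Uplus1", "drop"):
        raise ValueError("absent_policy must be 'censor_to_Uplus1' or 'drop'")
    if joint.subject_id and pln.subject_id and joint.subject_id != pln.subject_id:
        warnings.warn(
            f"cross-site pairing across subjects: {joint.subject_id} vs {pln.subject_id}",
            stacklevel=2,
        )
    top = top_clones(joint, n, level)
    pln_ranks = rank_map(pln, level)
    u_pln = len(pln_ranks)
    pairs = [(c.key, c.rank, pln_ranks.get(c.key)) for c in top]
    n_absent = sum(1 for _, _, r in pairs if r is None)

    if absent_policy == "censor_to_Uplus1":
        usable = [(jr, pr if pr is not None else u_pln + 1) for _, jr, pr in pairs]
    else:
        usable = [(jr, pr) for _, jr, pr in pairs if pr is not None]

    subject = joint.subject_id or pln.subject_id
    if len(usable) < 3:
        return CrossSiteRankResult(
            subject, pairs, n_absent, float("nan"), float("nan"),
            float("nan"), float("nan"), "not computed",
            note=f"fewer than 3 usable pairs ({len(usable)})",
        )
    jr = np.array([p[0] for p in usable], dtype=float)
    pr = np.array([p[1] for p in usable], dtype=float)
    if np.all(pr == pr[0]):
        return CrossSiteRankResult(
            subject, pairs, n_absent, float("nan"), float("nan"),
            float("nan"), float("nan"), "not computed",
            note="constant paired ranks; correlation undefined",
        )
    rho, p = stats.spearmanr(jr, pr)
    if len(pr) >= 8:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            k2, norm_p = stats.normaltest(pr)
        norm_note = "normal" if norm_p >= 0.05 else "non-normal"
    else:
        k2, norm_p, norm_note = float("nan"), float("nan"), "n < 8, gate not applicable"
    return CrossSiteRankResult(
        subject, pairs, n_absent, float(rho), float(p), float(k2), float(norm_p), norm_note
    )


def presence_table(
    keys: list[str], reps: list[Repertoire], level: str = "aa"
) -> pd.DataFrame:
    """Boolean keys × samples table of exact-key occurrence."""
    if not keys:
        raise ValueError("presence_table requires a non-empty key list")
    data = {}
    for rep in reps:
        rep_keys = rep.unique_keys(level)
        data[rep.sample_id] = [k in rep_keys for k in keys]
    return pd.DataFrame(data, index=keys)
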