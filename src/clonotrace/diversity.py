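"""Per-repertoire clonality and diversity statistics.

*Clonality* here is a richness count: the number of unique CDR3β sequences
(at a configurable identity level) in the repertoire.  *Diversity* is the
D50 index: the percentage of ranked clones needed to accumulate half of the
reads.  Low D50 means the repertoire is dominated by few expanded clones; a
perfectly even repertoire has D50 ≈ 50.

The D50 has two branches depending on the number of unique sequences U:

* U ≥ 10,000 — restrict to the 10,000 most abundant clones, find the
  smallest rank r whose cumulative reads reach half the reference total,
  and report ``r * 100 / 10,000``.
* U < 10,000 — use all clones and report ``r * 100 / U``.

For the large-sample branch the reference total defaults to the summed
reads of the top 10,000 clones (``reference_total="top10k"``); computing
the 50% point against all reads is available via ``reference_total="all"``.

*Clonal-space homeostasis* partitions read mass across fixed rank bins —
the top 10 clones, the next 25, 500, 3,000, 10,000 and 100,000 — i.e. rank
intervals (0,10], (10,35], (35,535], (535,3535], (3535,13535],
(13535,113535].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .models import Repertoire, RepertoireError
from .io import collapse_clones

log = logging.getLogger(__name__)

D50_RANK_CAP = 10_000
HOMEOSTASIS_EDGES = (10, 35, 535, 3_535, 13_535, 113_535)


@dataclass(frozen=True)
class DiversityResult:
    sample_id: str
    clonality: int
    d50: float
    branch: str  # "ge10k" | "lt10k"


@dataclass(frozen=True)
class HomeostasisProfile:
    sample_id: str
    proportions: tuple[float, ...]
    remainder: float  # read mass beyond rank 113,535
    bin_edges: tuple[int, ...] = HOMEOSTASIS_EDGES


def _sorted_reads(rep: Repertoire, level: str) -> np.ndarray:
    """Read counts of unique clones at ``level``, deterministically ranked."""
    collapsed = collapse_clones(rep, level)
    return collapsed.clones["reads"].to_numpy()


def clonality(rep: Repertoire, level: str = "nt") -> int:
    """Number of unique identity keys — the study's clonality measure."""
    if not len(rep):
        return 0
    return int(rep.identity_keys(level).nunique())


def d50(
    rep: Repertoire, level: str = "nt", reference_total: str = "top10k"
) -> DiversityResult:
    """The D50 diversity index with its two-branch formula (see module docs)."""
    if not len(rep):
        raise RepertoireError("D50 is undefined for an empty repertoire")
    if reference_total not in ("top10k", "all"):
        raise ValueError("reference_total must be 'top10k' or 'all'")
    reads = _sorted_reads(rep, level)
    u = len(reads)
    if u >= D50_RANK_CAP:
        top = reads[:D50_RANK_CAP]
        total = top.sum() if reference_total == "top10k" else reads.sum()
        cum = np.cumsum(top)
        r = int(np.argmax(cum >= total / 2)) + 1
        value = r * 100.0 / D50_RANK_CAP
        branch = "ge10k"
    else:
        total = reads.sum()
        cum = np.cumsum(reads)
        r = int(np.argmax(cum >= total / 2)) + 1
        value = r * 100.0 / u
        branch = "lt10k"
    return DiversityResult(rep.sample_id, u, value, branch)


def homeostasis_profile(rep: Repertoire, level: str = "nt") -> HomeostasisProfile:
    """Fraction of total reads in each fixed clone-rank bin."""
    if not len(rep):
        raise RepertoireError("homeostasis profile is undefined for an empty repertoire")
    reads = _sorted_reads(rep, level)
    total = reads.sum()
    cum = np.concatenate([[0], np.cumsum(reads)])
    edges = (0,) + HOMEOSTASIS_EDGES
    props = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        lo_i = min(lo, len(reads))
        hi_i = min(hi, len(reads))
        props.append((cum[hi_i] - cum[lo_i]) / total)
    remainder = (total - cum[min(HOMEOSTASIS_EDGES[-1], len(reads))]) / total
    if remainder > 0:
        log.info("%s: %.4f read mass beyond rank %d", rep.sample_id, remainder, HOMEOSTASIS_EDGES[-1])
    return HomeostasisProfile(rep.sample_id, tuple(float(p) for p in props), float(remainder))


def top_n_proportion(rep: Repertoire, n: int, level: str = "nt") -> float:
    """Fraction of reads carried by the n most abundant clones."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not len(rep):
        raise RepertoireError("top_n_proportion is undefined for an empty repertoire")
    reads = _sorted_reads(rep, level)
    return float(reads[: min(n, len(reads))].sum() / reads.sum())


def count_clones_at_least(rep: Repertoire, min_reads: int, level: str = "nt") -> int:
    """Number of unique clones supported by at least ``min_reads`` reads."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    if not len(rep):
        return 0
    reads = _sorted_reads(rep, level)
    return int((reads >= min_reads).sum())


def median_clone_frequency(rep: Repertoire, level: str = "nt") -> int:
    """Lower median of the clone read-count distribution.

    The lower-median convention keeps the threshold an achievable integer
    count for even-sized clone sets (used to pick the data-driven
    ``min_reads`` cutoff from a control sample).
    """
    if not len(rep):
        raise RepertoireError("median is undefined for an empty repertoire")
    reads = np.sort(_sorted_reads(rep, level))
    return int(reads[(len(reads) - 1) // 2])
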