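"""Exact CDR3β sequence sharing between repertoires.

The normalized overlap index between two repertoires is the number of
exactly shared CDR3β amino-acid sequences divided by the product of the two
repertoires' total read counts:

    index = |shared aa sequences| / (R1 × R2) × scale

The raw-read-product denominator yields very small values at typical
sequencing depths; ``scale`` (default 1) is a reporting multiplier only.
A variant normalizing by the product of unique clone counts is provided as
``normalized_overlap(..., denominator="clones")`` for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import Repertoire, RepertoireError


def shared_sequences(a: Repertoire, b: Repertoire, level: str = "aa") -> int:
    """Count of identity keys present in both repertoires (exact match)."""
    if not len(a) or not len(b):
        return 0
    return len(a.unique_keys(level) & b.unique_keys(level))


def normalized_overlap(
    a: Repertoire,
    b: Repertoire,
    level: str = "aa",
    scale: float = 1.0,
    denominator: str = "reads",
) -> float:
    """Normalized overlap index between two repertoires (symmetric)."""
    if not len(a) or not len(b):
        raise RepertoireError(
            "normalized overlap undefined for empty repertoire "
            f"({a.sample_id if not len(a) else b.sample_id})"
        )
    s = shared_sequences(a, b, level)
    if denominator == "reads":
        denom = a.total_reads * b.total_reads
    elif denominator == "clones":
        denom = len(a.unique_keys(level)) * len(b.unique_keys(level))
    else:
        raise ValueError("denominator must be 'reads' or 'clones'")
    return s / denom * scale


@dataclass
class OverlapMatrix:
    """All-pairs normalized overlap between two repertoire collections."""

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray  # normalized indices, scale applied
    raw_shared: np.ndarray  # integer shared-sequence counts
    scale: float = 1.0
    level: str = "aa"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, r in enumerate(self.row_ids):
            for j, c in enumerate(self.col_ids):
                rows.append((r, c, int(self.raw_shared[i, j]), float(self.values[i, j])))
        return pd.DataFrame(rows, columns=["row_id", "col_id", "shared", "index"])


def overlap_matrix(
    rows: list[Repertoire],
    cols: list[Repertoire],
    level: str = "aa",
    scale: float = 1.0,
) -> OverlapMatrix:
    """Pairwise overlap matrix; samples ordered by ``sample_id``."""
    for rep in list(rows) + list(cols):
        if not len(rep):
            raise RepertoireError(f"empty repertoire in overlap matrix: {rep.sample_id}")
    rows = sorted(rows, key=lambda r: r.sample_id)
    cols = sorted(cols, key=lambda r: r.sample_id)
    row_sets = [r.unique_keys(level) for r in rows]
    col_sets = [c.unique_keys(level) for c in cols]
    shared = np.zeros((len(rows), len(cols)), dtype=np.int64)
    values = np.zeros_like(shared, dtype=float)
    for i, (rr, rs) in enumerate(zip(rows, row_sets)):
        for j, (cc, cs) in enumerate(zip(cols, col_sets)):
            s = len(rs & cs)
            shared[i, j] = s
            values[i, j] = s / (rr.total_reads * cc.total_reads) * scale
    return OverlapMatrix(
        [r.sample_id for r in rows], [c.sample_id for c in cols], values, shared, scale, level
    )


def paired_diagonal(
    m: OverlapMatrix, pairing: dict[str, str]
) -> list[tuple[str, float]]:
    """Per-subject overlap values for a row→column sample pairing.

    ``pairing`` maps each row sample id to its same-animal column sample id;
    values are matched by id, not position, so column order is irrelevant.
    """
    col_index = {c: j for j, c in enumerate(m.col_ids)}
    out = []
    for i, row_id in enumerate(m.row_ids):
        if row_id not in pairing:
            raise RepertoireError(f"row sample {row_id!r} has no pairing")
        col_id = pairing[row_id]
        if col_id not in col_index:
            raise RepertoireError(f"paired sample {col_id!r} not among columns")
        out.append((row_id, float(m.values[i, col_index[col_id]])))
    return out
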