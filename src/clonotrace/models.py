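"""Core domain types: clones and repertoires.

A *clone* (clonotype) is a set of T cells sharing an identical TCRβ
rearrangement, operationalized as an identical CDR3β sequence — at the
nucleotide or amino-acid level, optionally together with the TRBV/TRBJ gene
labels.  A *repertoire* is one sample's clone table plus its study metadata
(tissue, disease phase, condition, subject).

Repertoires are backed by a :class:`pandas.DataFrame` with one row per clone
and a fixed deterministic ordering (reads descending, ties broken by the
lexicographically smallest CDR3β nucleotide sequence) so that every ranked
statistic downstream is reproducible.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

TISSUES = ("pLN", "joint")
PHASES = ("early", "late")
CONDITIONS = ("inflamed", "control")
IDENTITY_LEVELS = ("nt", "aa", "nt_vj", "aa_vj")

#: canonical column order of the clone table
CLONE_COLUMNS = ["cdr3_nt", "cdr3_aa", "v_gene", "j_gene", "reads"]

_NT_RE = re.compile(r"^[ACGT]+$")


class RepertoireError(ValueError):
    """Raised when a clone table violates the repertoire contract."""


def strip_allele(gene: str) -> str:
    """Normalize a V/J gene call to the gene level.

    Allele suffixes (``TRBV12-1*01`` → ``TRBV12-1``) and aligner score
    annotations (``TRBV12-1*00(932.1)``) are removed; for multi-hit calls
    only the first hit is kept.  Usage is reported at gene level, so calls
    differing only in allele must aggregate.
    """
    g = str(gene).split(",")[0]
    g = g.split("*")[0]
    g = g.split("(")[0]
    return g.strip()


@dataclass(frozen=True)
class Clone:
    """One clonotype: CDR3β sequences, gene segments and its read support."""

    cdr3_nt: str
    cdr3_aa: str
    v_gene: str
    j_gene: str
    reads: int

    def __post_init__(self) -> None:
        if self.reads < 1:
            raise RepertoireError(f"clone reads must be >= 1, got {self.reads}")
        if not self.cdr3_nt:
            raise RepertoireError("cdr3_nt must be non-empty")


def _gene_sort_key(label: str) -> tuple:
    """Numeric-aware sort key so TRBV2 < TRBV12-1 < TRBV13-1."""
    parts = re.split(r"(\d+)", label)
    return tuple(int(p) if p.isdigit() else p for p in parts)


class Repertoire:
    """One sample's clone set with study metadata.

    Parameters
    ----------
    clones
        Either a DataFrame with columns ``cdr3_nt, cdr3_aa, v_gene, j_gene,
        reads`` or an iterable of :class:`Clone`.
    sample_id, subject_id, tissue, phase, condition
        Study metadata.  ``tissue``/``phase``/``condition`` are validated
        against the study vocabulary when given.
    validate
        Check the clone-table invariants (positive integer reads, non-empty
        A/C/G/T CDR3β nucleotide sequences).
    """

    def __init__(
        self,
        clones: pd.DataFrame | Iterable[Clone] | None = None,
        *,
        sample_id: str = "sample",
        subject_id: str = "",
        tissue: str | None = None,
        phase: str | None = None,
        condition: str | None = None,
        validate: bool = True,
    ) -> None:
        if clones is None:
            df = pd.DataFrame(columns=CLONE_COLUMNS)
        elif isinstance(clones, pd.DataFrame):
            df = clones.copy()
        else:
            df = pd.DataFrame([c.__dict__ for c in clones], columns=CLONE_COLUMNS)

        missing = [c for c in CLONE_COLUMNS if c not in df.columns]
        if missing:
            raise RepertoireError(f"clone table lacks columns: {missing}")
        df = df[CLONE_COLUMNS]

        if len(df):
            df["cdr3_nt"] = df["cdr3_nt"].astype(str)
            df["cdr3_aa"] = df["cdr3_aa"].fillna("").astype(str)
            df["v_gene"] = df["v_gene"].fillna("").astype(str)
            df["j_gene"] = df["j_gene"].fillna("").astype(str)
            if validate:
                reads = pd.to_numeric(df["reads"], errors="coerce")
                if reads.isna().any() or (reads < 1).any():
                    bad = df.loc[reads.isna() | (reads < 1)].index[0]
                    raise RepertoireError(
                        f"clone at row {bad}: reads must be a positive integer"
                    )
                if (reads != reads.round()).any():
                    raise RepertoireError("reads must be integral")
                df["reads"] = reads.astype(np.int64)
                bad_nt = ~df["cdr3_nt"].str.fullmatch(_NT_RE)
                if bad_nt.any():
                    raise RepertoireError(
                        "cdr3_nt must be a non-empty string over {A,C,G,T}; "
                        f"offending value: {df.loc[bad_nt, 'cdr3_nt'].iloc[0]!r}"
                    )
            else:
                df["reads"] = df["reads"].astype(np.int64)
            # deterministic ordering: reads desc, then cdr3_nt lexicographic
            df = df.sort_values(
                ["reads", "cdr3_nt"], ascending=[False, True], kind="mergesort"
            )
        df = df.reset_index(drop=True)

        for name, value, allowed in (
            ("tissue", tissue, TISSUES),
            ("phase", phase, PHASES),
            ("condition", condition, CONDITIONS),
        ):
            if value is not None and value not in allowed:
                raise RepertoireError(f"{name} must be one of {allowed}, got {value!r}")

        self._df = df
        self.sample_id = sample_id
        self.subject_id = subject_id
        self.tissue = tissue
        self.phase = phase
        self.condition = condition

    # -- accessors -----------------------------------------------------

    @property
    def clones(self) -> pd.DataFrame:
        """The clone table in deterministic order (treat as read-only)."""
        return self._df

    @property
    def total_reads(self) -> int:
        return int(self._df["reads"].sum())

    @property
    def n_clones(self) -> int:
        """Number of rows of the clone table (pre-collapse entries count separately)."""
        return len(self._df)

    @property
    def metadata(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "subject_id": self.subject_id,
            "tissue": self.tissue,
            "phase": self.phase,
            "condition": self.condition,
        }

    def identity_keys(self, level: str = "nt") -> pd.Series:
        """Clone identity key per row at the requested level.

        ``nt``/``aa`` use the CDR3β sequence alone; ``nt_vj``/``aa_vj``
        append the TRBV and TRBJ gene labels.
        """
        if level not in IDENTITY_LEVELS:
            raise RepertoireError(f"identity level must be one of {IDENTITY_LEVELS}")
        df = self._df
        if not len(df):
            return pd.Series([], dtype=str)
        seq = df["cdr3_nt"] if level.startswith("nt") else df["cdr3_aa"]
        if level.endswith("_vj"):
            return seq + "|" + df["v_gene"] + "|" + df["j_gene"]
        return seq.copy()

    def unique_keys(self, level: str = "nt") -> set[str]:
        return set(self.identity_keys(level))

    def iter_clones(self) -> Iterator[Clone]:
        for row in self._df.itertuples(index=False):
            yield Clone(row.cdr3_nt, row.cdr3_aa, row.v_gene, row.j_gene, int(row.reads))

    def with_metadata(self, **kwargs) -> "Repertoire":
        meta = self.metadata
        meta.update(kwargs)
        return Repertoire(self._df, validate=False, **meta)

    # -- dunder --------------------------------------------------------

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Repertoire):
            return NotImplemented
        return self.metadata == other.metadata and self._df.equals(other._df)

    def __repr__(self) -> str:
        return (
            f"Repertoire(sample_id={self.sample_id!r}, n_clones={self.n_clones}, "
            f"total_reads={self.total_reads}, tissue={self.tissue}, "
            f"phase={self.phase}, condition={self.condition})"
        )
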