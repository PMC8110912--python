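"""Read, validate, collapse, pool and write clonotype tables.

Two on-disk carriers are supported: the AIRR Rearrangement TSV (community
standard; columns ``junction``, ``junction_aa``, ``v_call``, ``j_call``,
``duplicate_count``) and generic/MiXCR-style clone tables mapped onto the
same fields through a column map.  All readers strip gene-allele suffixes
and enforce strict positive read counts by default; a lenient mode imputes
missing/zero counts to 1 for tables that only list clone presence.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .models import CLONE_COLUMNS, Repertoire, RepertoireError, strip_allele

log = logging.getLogger(__name__)


class FormatError(RepertoireError):
    """A clone table does not conform to the declared format."""


class ConfigError(RepertoireError):
    """An unknown dialect or unusable column map."""


# ---------------------------------------------------------------------------
# translation

_std = CodonTable.unambiguous_dna_by_id[1]
_CODON: dict[str, str] = dict(_std.forward_table)
for _stop in _std.stop_codons:
    _CODON[_stop] = "*"


def translate_cdr3(cdr3_nt: str) -> str:
    """Translate an in-frame CDR3β nucleotide sequence.

    Uses the standard codon table; stop codons render as ``'*'``.
    Raises :class:`FormatError` for out-of-frame or ambiguous input.
    """
    if len(cdr3_nt) % 3 != 0:
        raise FormatError(
            f"CDR3 length {len(cdr3_nt)} is not a multiple of 3: {cdr3_nt!r}"
        )
    try:
        return "".join(_CODON[cdr3_nt[i : i + 3]] for i in range(0, len(cdr3_nt), 3))
    except KeyError as exc:
        raise FormatError(f"ambiguous or non-ACGT codon {exc} in {cdr3_nt!r}") from None


def _maybe_translate(nt: str) -> str:
    if len(nt) % 3 == 0:
        try:
            return translate_cdr3(nt)
        except FormatError:
            return ""
    return ""


# ---------------------------------------------------------------------------
# readers

AIRR_COLUMNS = {
    "cdr3_nt": "junction",
    "cdr3_aa": "junction_aa",
    "v_gene": "v_call",
    "j_gene": "j_call",
    "reads": "duplicate_count",
}

#: built-in clone-table dialects (column name on disk per clone field);
#: the same maps are what the YAML config documents.
DIALECTS: dict[str, dict[str, str]] = {
    "mixcr": {
        "cdr3_nt": "nSeqCDR3",
        "cdr3_aa": "aaSeqCDR3",
        "v_gene": "allVHitsWithScore",
        "j_gene": "allJHitsWithScore",
        "reads": "cloneCount",
    },
    "irepertoire": {
        "cdr3_nt": "CDR3_nt",
        "cdr3_aa": "CDR3_aa",
        "v_gene": "V",
        "j_gene": "J",
        "reads": "copy",
    },
}

_REQUIRED = ("cdr3_nt", "v_gene", "j_gene", "reads")


def _frame_from_table(
    raw: pd.DataFrame, colmap: dict[str, str], path: Path, lenient: bool
) -> pd.DataFrame:
    for field in _REQUIRED:
        col = colmap.get(field)
        if col is None or col not in raw.columns:
            raise FormatError(f"{path}: missing mandatory column {col or field!r}")
    df = pd.DataFrame(
        {
            "cdr3_nt": raw[colmap["cdr3_nt"]].astype(str).str.upper(),
            "v_gene": raw[colmap["v_gene"]].map(strip_allele),
            "j_gene": raw[colmap["j_gene"]].map(strip_allele),
        }
    )
    aa_col = colmap.get("cdr3_aa")
    if aa_col is not None and aa_col in raw.columns:
        df["cdr3_aa"] = raw[aa_col].fillna("").astype(str)
        derive = df["cdr3_aa"] == ""
    else:
        df["cdr3_aa"] = ""
        derive = pd.Series(True, index=df.index)
    if derive.any():
        df.loc[derive, "cdr3_aa"] = df.loc[derive, "cdr3_nt"].map(_maybe_translate)

    counts = pd.to_numeric(raw[colmap["reads"]], errors="coerce")
    bad = counts.isna() | (counts < 1)
    if bad.any():
        if lenient:
            counts = counts.where(~bad, 1.0)
        else:
            # +2: one for the header line, one for 0-based indexing
            line = int(bad.idxmax()) + 2
            raise FormatError(
                f"{path}: unparseable or non-positive count at line {line} "
                f"(value {raw.loc[bad.idxmax(), colmap['reads']]!r}); "
                "use lenient=True to impute 1"
            )
    df["reads"] = counts.round().astype(np.int64)
    return df[CLONE_COLUMNS]


def read_airr(path, *, lenient: bool = False, **metadata) -> Repertoire:
    """Read an AIRR Rearrangement TSV into a :class:`Repertoire`.

    ``metadata`` (sample_id, subject_id, tissue, phase, condition) is
    attached to the result; ``sample_id`` defaults to the file stem.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    metadata.setdefault("sample_id", path.stem)
    if raw.empty:
        log.warning("%s: header-only table, empty repertoire", path)
        for field in _REQUIRED:
            if AIRR_COLUMNS[field] not in raw.columns:
                raise FormatError(f"{path}: missing mandatory column {AIRR_COLUMNS[field]!r}")
        return Repertoire(None, **metadata)
    df = _frame_from_table(raw, AIRR_COLUMNS, path, lenient)
    return Repertoire(df, **metadata)


def read_clone_table(
    path,
    dialect: str = "mixcr",
    *,
    column_map: dict[str, str] | None = None,
    lenient: bool = False,
    **metadata,
) -> Repertoire:
    """Read a MiXCR-style / vendor / generic clone table.

    ``dialect`` selects a built-in column map (``mixcr``, ``irepertoire``)
    or ``generic`` with a user-supplied ``column_map`` keyed by clone field
    (``cdr3_nt``, ``cdr3_aa``, ``v_gene``, ``j_gene``, ``reads``).
    """
    path = Path(path)
    if dialect == "generic":
        if not column_map:
            raise ConfigError("generic dialect requires a column_map")
        colmap = column_map
    elif dialect in DIALECTS:
        colmap = DIALECTS[dialect] if column_map is None else {**DIALECTS[dialect], **column_map}
    else:
        raise ConfigError(
            f"unknown dialect {dialect!r}; known: {sorted(DIALECTS) + ['generic']}"
        )
    raw = pd.read_csv(path, sep="\t", dtype=str)
    metadata.setdefault("sample_id", path.stem)
    if raw.empty:
        log.warning("%s: header-only table, empty repertoire", path)
        return Repertoire(None, **metadata)
    df = _frame_from_table(raw, colmap, path, lenient)
    return Repertoire(df, **metadata)


# ---------------------------------------------------------------------------
# collapse / pool

def collapse_clones(rep: Repertoire, level: str = "nt") -> Repertoire:
    """Merge clones sharing the identity key at ``level``; reads are summed.

    The representative sequence/gene fields of a merged clone come from the
    member with the highest reads (ties: lexicographically smallest
    ``cdr3_nt``) — i.e. the first member under the repertoire's
    deterministic ordering.  Total reads are conserved; the operation is
    idempotent.
    """
    if not len(rep):
        return rep.with_metadata()
    df = rep.clones.copy()
    df["_key"] = rep.identity_keys(level).values
    agg = df.groupby("_key", sort=False).agg(
        cdr3_nt=("cdr3_nt", "first"),
        cdr3_aa=("cdr3_aa", "first"),
        v_gene=("v_gene", "first"),
        j_gene=("j_gene", "first"),
        reads=("reads", "sum"),
    )
    return Repertoire(agg.reset_index(drop=True), validate=False, **rep.metadata)


def pool_repertoires(
    reps: list[Repertoire], level: str = "nt", sample_id: str | None = None
) -> Repertoire:
    """Concatenate repertoires and collapse — the pooled-control construction.

    All inputs should share tissue/phase/condition (a warning is emitted
    otherwise); pooled total reads equal the sum of the inputs' totals.
    """
    if not reps:
        raise RepertoireError("pool_repertoires requires at least one repertoire")
    first = reps[0]
    for r in reps[1:]:
        if (r.tissue, r.phase, r.condition) != (first.tissue, first.phase, first.condition):
            warnings.warn(
                f"pooling repertoires with differing metadata: {r.sample_id} vs {first.sample_id}",
                stacklevel=2,
            )
    frames = [r.clones for r in reps if len(r)]
    meta = first.metadata
    meta["sample_id"] = sample_id or "+".join(r.sample_id for r in reps)
    meta["subject_id"] = "pooled"
    if not frames:
        return Repertoire(None, **meta)
    combined = Repertoire(pd.concat(frames, ignore_index=True), validate=False, **meta)
    return collapse_clones(combined, level)


# ---------------------------------------------------------------------------
# writer

def write_repertoire(rep: Repertoire, path, format: str = "airr") -> None:
    """Write a repertoire's clone table as TSV (clone order is deterministic)."""
    path = Path(path)
    df = rep.clones
    if format == "airr":
        out = pd.DataFrame(
            {
                "sequence_id": [f"{rep.sample_id}-{i:06d}" for i in range(len(df))],
                "junction": df["cdr3_nt"],
                "junction_aa": df["cdr3_aa"],
                "v_call": df["v_gene"],
                "j_call": df["j_gene"],
                "duplicate_count": df["reads"],
            }
        )
    elif format == "generic_tsv":
        out = df
    else:
        raise ConfigError(f"unknown output format {format!r}")
    out.to_csv(path, sep="\t", index=False)
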