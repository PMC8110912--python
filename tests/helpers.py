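"""Shared test utilities and independent oracles.

The oracles here are deliberately naive (sorted lists, python loops,
closed-form expressions) and never call the implementation they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from clonotrace import Repertoire

_TRANS = str.maketrans("0123", "ACGT")


def nt_codes(n: int, length: int = 12) -> list[str]:
    """n distinct A/C/G/T strings (base-4 encoded integers)."""
    return [np.base_repr(i, 4).zfill(length).translate(_TRANS) for i in range(n)]


def rep_from_reads(reads, nts=None, aas=None, vs=None, js=None, **meta) -> Repertoire:
    """Build a repertoire from a read-count vector with synthetic keys."""
    reads = list(reads)
    n = len(reads)
    df = pd.DataFrame(
        {
            "cdr3_nt": nts if nts is not None else nt_codes(n),
            "cdr3_aa": aas if aas is not None else [f"A{i}" for i in range(n)],
            "v_gene": vs if vs is not None else ["TRBV1"] * n,
            "j_gene": js if js is not None else ["TRBJ1-1"] * n,
            "reads": reads,
        }
    )
    return Repertoire(df, validate=False, **meta)


# ---------------------------------------------------------------------------
# independent oracles


def d50_bruteforce(clones: list[tuple[str, int]]) -> tuple[float, str]:
    """Brute-force cumulative-sum D50 on (nt, reads) pairs.

    Mirrors the printed two-branch definition directly: sort by reads
    descending (ties by sequence), walk ranks until half the reference
    total is reached.
    """
    ordered = sorted(clones, key=lambda c: (-c[1], c[0]))
    u = len(ordered)
    if u >= 10_000:
        top = ordered[:10_000]
        half = sum(r for _, r in top) / 2
        acc = 0
        for i, (_, r) in enumerate(top):
            acc += r
            if acc >= half:
                return (i + 1) * 100.0 / 10_000, "ge10k"
    half = sum(r for _, r in ordered) / 2
    acc = 0
    for i, (_, r) in enumerate(ordered):
        acc += r
        if acc >= half:
            return (i + 1) * 100.0 / u, "lt10k"
    raise AssertionError("unreachable")


def random_reads(rng: np.random.Generator, u: int) -> np.ndarray:
    """Heavy-tailed positive integer read counts for u clones."""
    return rng.zipf(a=1.8, size=u).clip(max=100_000)


def student_t_textbook(a, b) -> tuple[float, float]:
    """Pooled-variance t statistic and two-sided p from the textbook formula."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * tdist.sf(abs(t), na + nb - 2)
    return t, p


def welch_t_textbook(a, b) -> tuple[float, float]:
    """Welch statistic with Welch–Satterthwaite df, from the formula."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2 * tdist.sf(abs(t), df)
    return t, p
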