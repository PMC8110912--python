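"""Synthetic paired lymph-node / joint TCRβ repertoire cohorts.

The generator emulates the statistical structure of antigen-experienced CD4
T-cell repertoires in an inflammatory-arthritis study design:

* each repertoire is a mixture of a few *expanded* clones carrying a
  designed fraction of the read mass (``expanded_mass``) and a heavy-tailed
  *background* of clones with Zipf-distributed probabilities;
* reads are sampled multinomially at a chosen depth from the fixed clone
  probabilities (no PCR/UMI error model — the analysis consumes clone
  tables, upstream noise is out of scope);
* CDR3β nucleotide sequences are random in-frame codon strings (length
  27–45 nt), unique at both the nucleotide and amino-acid level within a
  generating context, so exact-match identity is well defined;
* paired samples realize a designed number of shared CDR3β amino-acid
  sequences exactly at the clone-universe level before read sampling, and
  an arm rule controls whether the joint's expanded clones come from the
  lymph node's most abundant clones (late-phase rule) or are partly de
  novo (early-phase rule).

Expanded-clone probabilities decay geometrically (``expanded_decay``, 1.0
recovers a uniform split) so that the within-top ranking of expanded
clones is stable across the paired samples — the property the cross-site
rank-correlation analysis depends on.

Every generative parameter is recorded in the cohort manifest, and one
master seed expands to per-subject seeds via a documented counter scheme
(``seed_k = (master_seed * 100_003 + k) mod 2^31``), so any single sample
is regenerable in isolation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .models import Repertoire
from .io import translate_cdr3, write_repertoire

_BASES = np.array(list("ACGT"))
_CDR3_LENGTHS = tuple(range(27, 46, 3))

MOUSE_TRBV = [
    "TRBV1", "TRBV2", "TRBV3", "TRBV4", "TRBV5", "TRBV12-1", "TRBV12-2",
    "TRBV13-1", "TRBV13-2", "TRBV13-3", "TRBV14", "TRBV15", "TRBV16",
    "TRBV17", "TRBV19", "TRBV20", "TRBV23", "TRBV26", "TRBV29", "TRBV31",
]
MOUSE_TRBJ = [
    "TRBJ1-1", "TRBJ1-2", "TRBJ1-3", "TRBJ1-4", "TRBJ1-5",
    "TRBJ2-1", "TRBJ2-2", "TRBJ2-3", "TRBJ2-4", "TRBJ2-5", "TRBJ2-7",
]


def _profile(weights: dict[str, float], labels: list[str]) -> dict[str, float]:
    """Dense normalized categorical profile: named weights, rest uniform."""
    rest = [g for g in labels if g not in weights]
    remaining = 1.0 - sum(weights.values())
    prof = dict(weights)
    for g in rest:
        prof[g] = remaining / len(rest)
    total = sum(prof.values())
    return {g: w / total for g, w in prof.items()}


#: baseline TRBV profile, concentrated on the genes dominating early-phase
#: inflamed repertoires (TRBV12-1, 12-2, 13-1)
BASE_V_PROFILE = _profile({"TRBV12-1": 0.16, "TRBV12-2": 0.14, "TRBV13-1": 0.12}, MOUSE_TRBV)
#: broadened profile shifted toward TRBV1/2/3/5/19, emulating the expanded
#: range of V genes accumulating in late-phase lymph nodes
LATE_PLN_V_PROFILE = _profile(
    {"TRBV1": 0.09, "TRBV2": 0.09, "TRBV3": 0.08, "TRBV5": 0.08, "TRBV19": 0.09,
     "TRBV12-1": 0.05, "TRBV12-2": 0.05, "TRBV13-1": 0.04},
    MOUSE_TRBV,
)
DEFAULT_J_PROFILE = _profile({}, MOUSE_TRBJ)


@dataclass(frozen=True)
class RepertoireSpec:
    """Generative parameters for one repertoire.

    ``expanded_mass`` is the total clone-probability mass of the
    ``n_expanded`` dominant clones; the remaining mass goes to
    ``n_background`` clones with Zipf(``tail_exponent``) weights.
    """

    n_expanded: int = 10
    expanded_mass: float = 0.3
    n_background: int = 5_000
    tail_exponent: float = 0.6
    depth: int = 50_000
    expanded_decay: float = 0.85
    v_profile: tuple[tuple[str, float], ...] = tuple(sorted(BASE_V_PROFILE.items()))
    j_profile: tuple[tuple[str, float], ...] = tuple(sorted(DEFAULT_J_PROFILE.items()))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not (0 <= self.expanded_mass < 1):
            raise ValueError("expanded_mass must lie in [0, 1)")
        if self.n_background < 1:
            raise ValueError("n_background must be >= 1")
        if self.tail_exponent <= 0 or self.expanded_decay <= 0:
            raise ValueError("tail_exponent and expanded_decay must be > 0")
        for name in ("v_profile", "j_profile"):
            w = np.array([p for _, p in getattr(self, name)])
            if w.size == 0 or (w < 0).any() or abs(w.sum() - 1) > 1e-9:
                raise ValueError(f"{name} must be a probability simplex")

    @property
    def n_clones(self) -> int:
        return self.n_expanded + self.n_background


def clone_probabilities(spec: RepertoireSpec) -> np.ndarray:
    """Designed clone probabilities, expanded clones first, background after.

    Expanded: geometric weights with ratio ``expanded_decay`` summing to
    ``expanded_mass``.  Background: Zipf rank weights ``k^(-s)`` summing to
    ``1 - expanded_mass``.
    """
    parts = []
    if spec.n_expanded > 0 and spec.expanded_mass > 0:
        w = spec.expanded_decay ** np.arange(spec.n_expanded)
        parts.append(w / w.sum() * spec.expanded_mass)
    else:
        parts.append(np.zeros(spec.n_expanded))
    ranks = np.arange(1, spec.n_background + 1, dtype=float)
    bg = ranks ** (-spec.tail_exponent)
    parts.append(bg / bg.sum() * (1.0 - spec.expanded_mass))
    p = np.concatenate(parts)
    return p / p.sum()


class SequenceFactory:
    """Mint CDR3β nucleotide sequences unique at nt AND aa level.

    One factory per generating context (e.g. per subject pair) guarantees
    that sequence sharing between repertoires occurs only where the design
    says so.
    """

    def __init__(self) -> None:
        self._nt: set[str] = set()
        self._aa: set[str] = set()

    def new(self, rng: np.random.Generator) -> tuple[str, str]:
        while True:
            length = int(rng.choice(_CDR3_LENGTHS))
            nt = "".join(_BASES[rng.integers(0, 4, length)])
            aa = translate_cdr3(nt)
            if nt not in self._nt and aa not in self._aa:
                self._nt.add(nt)
                self._aa.add(aa)
                return nt, aa


def _draw_genes(rng: np.random.Generator, profile, n: int) -> np.ndarray:
    labels = np.array([g for g, _ in profile])
    probs = np.array([p for _, p in profile])
    return rng.choice(labels, size=n, p=probs)


def build_universe(
    spec: RepertoireSpec, rng: np.random.Generator, factory: SequenceFactory | None = None
) -> pd.DataFrame:
    """Clone universe (nt, aa, V, J) in design-probability order."""
    factory = factory or SequenceFactory()
    seqs = [factory.new(rng) for _ in range(spec.n_clones)]
    return pd.DataFrame(
        {
            "cdr3_nt": [s[0] for s in seqs],
            "cdr3_aa": [s[1] for s in seqs],
            "v_gene": _draw_genes(rng, spec.v_profile, spec.n_clones),
            "j_gene": _draw_genes(rng, spec.j_profile, spec.n_clones),
        }
    )


def sample_reads(
    universe: pd.DataFrame,
    spec: RepertoireSpec,
    rng: np.random.Generator,
    **metadata,
) -> Repertoire:
    """Multinomial read sampling; clones drawing zero reads are dropped."""
    probs = clone_probabilities(spec)
    if len(universe) != len(probs):
        raise ValueError("universe size does not match spec clone count")
    counts = rng.multinomial(spec.depth, probs)
    keep = counts > 0
    df = universe.loc[keep].copy()
    df["reads"] = counts[keep]
    return Repertoire(df, validate=False, **metadata)


def generate_repertoire(spec: RepertoireSpec, **metadata) -> Repertoire:
    """Generate one repertoire from its spec (deterministic in ``spec.seed``)."""
    rng = np.random.default_rng(spec.seed)
    universe = build_universe(spec, rng)
    metadata.setdefault("sample_id", f"sim{spec.seed}")
    return sample_reads(universe, spec, rng, **metadata)


def generate_paired_sample(
    rule: str,
    pln_spec: RepertoireSpec,
    joint_spec: RepertoireSpec,
    sharing: int,
    seed: int,
    *,
    subject_id: str = "subject",
    phase: str | None = None,
    condition: str | None = None,
    early_source_pool: int = 500,
    early_absent_fraction: float = 0.5,
) -> tuple[Repertoire, Repertoire]:
    """Generate a same-animal (pLN, joint) pair with designed sharing.

    ``sharing`` CDR3β amino-acid sequences are common to the two clone
    universes, realized exactly before read sampling.  Under the ``late``
    rule the joint's expanded clones are the lymph node's most abundant
    clones in matching order; under ``early``/``control`` a fraction
    ``early_absent_fraction`` of them is de novo and the rest is drawn at
    random from the lymph node's top ``early_source_pool`` clones.
    """
    if rule not in ("early", "late", "control"):
        raise ValueError("rule must be 'early', 'late' or 'control'")
    rng = np.random.default_rng(seed)
    factory = SequenceFactory()
    pln_universe = build_universe(pln_spec, rng, factory)
    n_pln = len(pln_universe)
    ne = joint_spec.n_expanded

    if rule == "late":
        if sharing < ne:
            raise ValueError("late rule needs sharing >= joint n_expanded")
        shared_exp_idx = list(range(ne))
        n_denovo_exp = 0
    else:
        n_denovo_exp = int(round(early_absent_fraction * ne))
        pool = min(early_source_pool, n_pln)
        picks = rng.choice(pool, size=ne - n_denovo_exp, replace=False)
        shared_exp_idx = sorted(int(i) for i in picks)

    if sharing < len(shared_exp_idx) or sharing > min(n_pln, joint_spec.n_clones):
        raise ValueError(
            f"infeasible sharing={sharing} (expanded shared {len(shared_exp_idx)}, "
            f"universe sizes {n_pln}/{joint_spec.n_clones})"
        )

    # remaining shared slots: most abundant pLN clones not already shared
    used = set(shared_exp_idx)
    n_shared_bg = sharing - len(shared_exp_idx)
    shared_bg_idx = [i for i in range(n_pln) if i not in used][:n_shared_bg]
    if len(shared_bg_idx) < n_shared_bg:
        raise ValueError("infeasible sharing: pLN universe too small")
    n_bg_denovo = joint_spec.n_background - len(shared_bg_idx)
    if n_bg_denovo < 0:
        raise ValueError("sharing exceeds the joint's background capacity")

    def _rows(indices) -> pd.DataFrame:
        return pln_universe.iloc[indices][["cdr3_nt", "cdr3_aa"]].reset_index(drop=True)

    def _fresh(n: int) -> pd.DataFrame:
        seqs = [factory.new(rng) for _ in range(n)]
        return pd.DataFrame({"cdr3_nt": [s[0] for s in seqs], "cdr3_aa": [s[1] for s in seqs]})

    if rule == "late":
        expanded = _rows(shared_exp_idx)  # pLN order preserved → aligned ranks
    else:
        expanded = pd.concat([_rows(shared_exp_idx), _fresh(n_denovo_exp)], ignore_index=True)
        expanded = expanded.iloc[rng.permutation(len(expanded))].reset_index(drop=True)

    background = pd.concat([_rows(shared_bg_idx), _fresh(n_bg_denovo)], ignore_index=True)
    joint_universe = pd.concat([expanded, background], ignore_index=True)
    joint_universe["v_gene"] = _draw_genes(rng, joint_spec.v_profile, len(joint_universe))
    joint_universe["j_gene"] = _draw_genes(rng, joint_spec.j_profile, len(joint_universe))

    pln = sample_reads(
        pln_universe, pln_spec, rng,
        sample_id=f"{subject_id}_pLN", subject_id=subject_id,
        tissue="pLN", phase=phase, condition=condition,
    )
    joint = sample_reads(
        joint_universe, joint_spec, rng,
        sample_id=f"{subject_id}_joint", subject_id=subject_id,
        tissue="joint", phase=phase, condition=condition,
    )
    return pln, joint


# ---------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class ArmSpec:
    name: str
    phase: str
    condition: str
    rule: str
    pln: RepertoireSpec
    joint: RepertoireSpec
    sharing: int
    early_absent_fraction: float = 0.5


@dataclass(frozen=True)
class CohortSpec:
    arms: tuple[ArmSpec, ...]
    n_subjects: int = 5
    master_seed: int = 0
    #: relative half-width of the per-subject uniform jitter applied to
    #: expanded_mass and n_background (biological between-animal variation)
    subject_jitter: float = 0.05


def default_cohort_spec(
    master_seed: int = 0, n_subjects: int = 5, depth: int = 50_000
) -> CohortSpec:
    """The default study design: early/late inflamed arms plus controls.

    Design values are chosen to emulate the repertoire contrasts of the
    modeled study: early lymph nodes with the top-10 clones carrying ~18%
    of reads, late lymph nodes nearly even (~2%) with a much larger and
    broader clone pool, joints dominated by ~10 clones carrying a fixed
    ~44% of reads at both phases, and cross-site amino-acid sharing higher
    at the early phase (400 designed shared sequences) than late (100).
    """
    late_v = tuple(sorted(LATE_PLN_V_PROFILE.items()))
    early_pln = RepertoireSpec(10, 0.18, 4_200, 0.6, depth)
    late_pln = RepertoireSpec(10, 0.02, 12_000, 0.4, depth, v_profile=late_v)
    joint = RepertoireSpec(10, 0.44, 4_500, 0.6, depth)
    # adjuvant-only controls: lymph nodes share the late inflamed design
    # (inflammation without antigen leaves the same pLN structure, only
    # between-animal noise distinguishes the groups); joints keep a large
    # clone pool but the top clones carry only ~29% of reads
    ctrl_pln = RepertoireSpec(10, 0.02, 12_000, 0.4, depth)
    ctrl_joint = RepertoireSpec(10, 0.29, 4_500, 0.6, depth)
    return CohortSpec(
        arms=(
            ArmSpec("early_inflamed", "early", "inflamed", "early", early_pln, joint, 400),
            ArmSpec("late_inflamed", "late", "inflamed", "late", late_pln, joint, 100),
            ArmSpec("control", "late", "control", "control", ctrl_pln, ctrl_joint, 60),
        ),
        n_subjects=n_subjects,
        master_seed=master_seed,
    )


def subject_seed(master_seed: int, counter: int) -> int:
    """Documented counter scheme expanding the master seed per subject."""
    return (master_seed * 100_003 + counter) % 2**31


def _jittered(spec: RepertoireSpec, rng: np.random.Generator, jitter: float) -> RepertoireSpec:
    if jitter <= 0:
        return spec
    mass = spec.expanded_mass * (1 + rng.uniform(-jitter, jitter))
    nbg = max(1, int(round(spec.n_background * (1 + rng.uniform(-jitter, jitter)))))
    return dataclasses.replace(spec, expanded_mass=min(mass, 0.99), n_background=nbg)


def generate_cohort(
    spec: CohortSpec, out_dir: str | Path | None = None
) -> tuple[list[Repertoire], pd.DataFrame]:
    """Generate all paired samples of a cohort plus a design manifest.

    When ``out_dir`` is given, AIRR TSVs and ``manifest.tsv`` are written
    there; regenerating with the same spec is byte-identical.
    """
    reps: list[Repertoire] = []
    rows = []
    counter = 0
    for arm in spec.arms:
        for s in range(spec.n_subjects):
            seed = subject_seed(spec.master_seed, counter)
            counter += 1
            subject_id = f"{arm.name}_m{s + 1}"
            jit_rng = np.random.default_rng(seed + 1)
            pln_spec = _jittered(arm.pln, jit_rng, spec.subject_jitter)
            joint_spec = _jittered(arm.joint, jit_rng, spec.subject_jitter)
            pln, joint = generate_paired_sample(
                arm.rule, pln_spec, joint_spec, arm.sharing, seed,
                subject_id=subject_id, phase=arm.phase, condition=arm.condition,
                early_absent_fraction=arm.early_absent_fraction,
            )
            for rep, rspec in ((pln, pln_spec), (joint, joint_spec)):
                reps.append(rep)
                rows.append(
                    {
                        "sample_id": rep.sample_id,
                        "subject_id": subject_id,
                        "tissue": rep.tissue,
                        "phase": arm.phase,
                        "condition": arm.condition,
                        "arm": arm.name,
                        "rule": arm.rule,
                        "seed": seed,
                        "depth": rspec.depth,
                        "n_expanded": rspec.n_expanded,
                        "expanded_mass": rspec.expanded_mass,
                        "n_background": rspec.n_background,
                        "tail_exponent": rspec.tail_exponent,
                        "expanded_decay": rspec.expanded_decay,
                        "sharing": arm.sharing,
                        "file": f"{rep.sample_id}.tsv",
                    }
                )
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for rep in reps:
            write_repertoire(rep, out_dir / f"{rep.sample_id}.tsv", format="airr")
        manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return reps, manifest
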