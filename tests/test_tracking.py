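"""Clone ranking and cross-site top-clone correlation."""

import math

import numpy as np
import pytest

import clonotrace as ct
from helpers import nt_codes, rep_from_reads


def aa_rep(pairs, **kw):
    """Repertoire from (aa, reads) pairs with distinct nt backing."""
    aas = [a for a, _ in pairs]
    reads = [r for _, r in pairs]
    return rep_from_reads(reads, nts=nt_codes(len(pairs)), aas=aas, **kw)


class TestTopClones:
    def test_ordering_and_ranks(self):
        rep = aa_rep([("A", 5), ("B", 3), ("C", 1)])
        top = ct.top_clones(rep, 2)
        assert [(c.key, c.rank) for c in top] == [("A", 1), ("B", 2)]

    def test_tie_break_lexicographic(self):
        # equal reads: the lexicographically smaller backing nt wins rank 1
        rep = rep_from_reads([5, 5], nts=["CCCGGG", "AAATTT"], aas=["Z", "Y"])
        top = ct.top_clones(rep, 2, level="nt")
        assert top[0].key == "AAATTT" and top[0].rank == 1

    def test_n_beyond_unique_count(self):
        rep = aa_rep([("A", 2), ("B", 1)])
        assert len(ct.top_clones(rep, 10)) == 2

    def test_consistency_with_top_n_proportion(self, rng):
        u = 50
        rep = rep_from_reads(rng.integers(1, 100, u), nts=nt_codes(u),
                             aas=[f"A{i}" for i in range(u)])
        top = ct.top_clones(rep, 10)
        assert sum(c.reads for c in top) / rep.total_reads == pytest.approx(
            ct.top_n_proportion(rep, 10, level="aa")
        )

    def test_invalid_n(self, small_rep):
        with pytest.raises(ValueError):
            ct.top_clones(small_rep, 0)


class TestRankOf:
    def test_most_abundant_is_rank_one(self):
        rep = aa_rep([("A", 5), ("B", 3)])
        assert ct.rank_of(rep, "A") == 1

    def test_absent_key(self):
        rep = aa_rep([("A", 5)])
        assert ct.rank_of(rep, "ZZZ") is None

    def test_ranks_are_permutation(self, rng):
        u = 40
        rep = rep_from_reads(rng.integers(1, 30, u), nts=nt_codes(u),
                             aas=[f"A{i}" for i in range(u)])
        ranks = sorted(ct.rank_of(rep, f"A{i}") for i in range(u))
        assert ranks == list(range(1, u + 1))

    def test_consistent_with_top_clones(self, rng):
        u = 30
        rep = rep_from_reads(rng.integers(1, 30, u), nts=nt_codes(u),
                             aas=[f"A{i}" for i in range(u)])
        for c in ct.top_clones(rep, 10):
            assert ct.rank_of(rep, c.key) == c.rank


class TestCrossSiteRanks:
    def test_identical_repertoires_give_rho_one(self, rng):
        u = 20
        rep = rep_from_reads(rng.integers(1, 100, u), nts=nt_codes(u),
                             aas=[f"A{i}" for i in range(u)], subject_id="m1")
        res = ct.cross_site_ranks(rep, rep)
        assert res.n_absent == 0 and res.rho == pytest.approx(1.0)

    def test_all_absent_drop_policy_undefined(self):
        joint = aa_rep([(f"J{i}", 10 - i) for i in range(10)], subject_id="m1")
        pln = aa_rep([(f"P{i}", 5) for i in range(10)], subject_id="m1")
        res = ct.cross_site_ranks(joint, pln, absent_policy="drop")
        assert res.n_absent == 10 and math.isnan(res.rho)
        assert "fewer than 3" in res.note

    def test_censor_policy_assigns_u_plus_one(self):
        joint = aa_rep([("A", 9), ("B", 8), ("X", 7), ("Y", 6)], subject_id="m1")
        pln = aa_rep([("A", 5), ("B", 4), ("C", 3)], subject_id="m1")
        res = ct.cross_site_ranks(joint, pln, n=4)
        ranks = {k: r for k, _, r in res.pairs}
        assert ranks["A"] == 1 and ranks["B"] == 2
        assert ranks["X"] is None and res.n_absent == 2
        # censored clones enter the correlation at rank U+1 = 4
        assert not math.isnan(res.rho)

    def test_cross_subject_warns(self):
        a = aa_rep([("A", 2), ("B", 1), ("C", 1)], subject_id="m1")
        b = aa_rep([("A", 2), ("B", 1), ("C", 1)], subject_id="m2")
        with pytest.warns(UserWarning, match="cross-site"):
            ct.cross_site_ranks(a, b)

    def test_normality_gate_reported_not_acted_on(self, rng):
        u = 30
        rep = rep_from_reads(rng.integers(1, 100, u), nts=nt_codes(u),
                             aas=[f"A{i}" for i in range(u)], subject_id="m1")
        res = ct.cross_site_ranks(rep, rep, n=10)
        # n = 10 pairs >= 8: the D'Agostino-Pearson statistic is computed
        assert not math.isnan(res.normality_stat)
        assert res.rho == pytest.approx(1.0)  # estimator unchanged by the gate

    def test_generator_late_vs_early_contrast(self):
        pln_spec = ct.RepertoireSpec(10, 0.18, 2_000, 0.6, 30_000)
        joint_spec = ct.RepertoireSpec(10, 0.44, 2_000, 0.6, 30_000)
        pln_l, joint_l = ct.generate_paired_sample(
            "late", pln_spec, joint_spec, 100, 3, subject_id="late1"
        )
        pln_e, joint_e = ct.generate_paired_sample(
            "early", pln_spec, joint_spec, 100, 4, subject_id="early1"
        )
        late = ct.cross_site_ranks(joint_l, pln_l)
        early = ct.cross_site_ranks(joint_e, pln_e)
        assert late.n_absent == 0
        assert late.rho > abs(early.rho)


class TestPresenceTable:
    def test_rows_and_columns(self):
        r1 = aa_rep([("A", 2), ("B", 1)], sample_id="s1")
        r2 = aa_rep([("B", 3), ("C", 1)], sample_id="s2")
        t = ct.presence_table(["A", "B", "C"], [r1, r2])
        assert t.loc["A"].tolist() == [True, False]
        assert t.loc["B"].tolist() == [True, True]

    def test_row_sums_match_shared_counts(self, rng):
        reps = []
        for i in range(3):
            aas = [f"A{j}" for j in rng.choice(20, 10, replace=False)]
            reps.append(rep_from_reads(rng.integers(1, 9, 10), nts=nt_codes(10), aas=aas,
                                       sample_id=f"s{i}"))
        keys = [f"A{j}" for j in range(20)]
        t = ct.presence_table(keys, reps)
        for rep in reps:
            expected = sum(1 for k in keys if k in rep.unique_keys("aa"))
            assert t[rep.sample_id].sum() == expected

    def test_empty_keys_error(self, small_rep):
        with pytest.raises(ValueError):
            ct.presence_table([], [small_rep])

    def test_late_rule_joint_top10_all_present(self):
        pln, joint = ct.generate_paired_sample(
            "late", ct.RepertoireSpec(10, 0.3, 1_000, 0.6, 20_000),
            ct.RepertoireSpec(10, 0.44, 1_000, 0.6, 20_000), 50, 5,
        )
        keys = [c.key for c in ct.top_clones(joint, 10)]
        t = ct.presence_table(keys, [pln])
        assert t.all().all()
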