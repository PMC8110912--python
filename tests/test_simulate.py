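"""Synthetic repertoire and paired-cohort generation."""

import numpy as np
import pandas as pd
import pytest

import clonotrace as ct
from clonotrace.simulate import clone_probabilities, subject_seed


class TestCloneProbabilities:
    def test_simplex_and_mass_split(self):
        spec = ct.RepertoireSpec(10, 0.46, 500, 0.8, 10_000)
        p = clone_probabilities(spec)
        assert p.sum() == pytest.approx(1.0)
        assert p[:10].sum() == pytest.approx(0.46)
        assert np.all(np.diff(p[:10]) <= 0) and np.all(np.diff(p[10:]) <= 0)

    def test_uniform_decay_recovers_even_split(self):
        spec = ct.RepertoireSpec(5, 0.5, 100, 1.0, 1_000, expanded_decay=1.0)
        p = clone_probabilities(spec)
        assert np.allclose(p[:5], 0.1)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ct.RepertoireSpec(depth=0)
        with pytest.raises(ValueError):
            ct.RepertoireSpec(expanded_mass=1.0)


class TestGenerateRepertoire:
    def test_same_spec_same_seed_identical(self):
        spec = ct.RepertoireSpec(5, 0.3, 300, 0.7, 5_000, seed=11)
        assert ct.generate_repertoire(spec) == ct.generate_repertoire(spec)

    def test_different_seed_differs(self):
        a = ct.generate_repertoire(ct.RepertoireSpec(5, 0.3, 300, 0.7, 5_000, seed=1))
        b = ct.generate_repertoire(ct.RepertoireSpec(5, 0.3, 300, 0.7, 5_000, seed=2))
        assert a != b

    def test_depth_conserved_and_zero_clones_dropped(self):
        rep = ct.generate_repertoire(ct.RepertoireSpec(0, 0.0, 5_000, 0.9, 2_000, seed=3))
        assert rep.total_reads == 2_000
        assert (rep.clones["reads"] >= 1).all()
        assert rep.n_clones <= 5_000

    def test_uniform_limit_d50_near_50(self):
        # flat background, deep sampling: the repertoire is near-even
        spec = ct.RepertoireSpec(0, 0.0, 100, 1e-6, 1_000_000, seed=4)
        res = ct.d50(ct.generate_repertoire(spec))
        assert res.d50 == pytest.approx(50.0, abs=2.0)

    def test_expanded_mass_recovered_by_top10(self):
        spec = ct.RepertoireSpec(10, 0.46, 5_000, 0.5, 1_000_000, seed=5)
        rep = ct.generate_repertoire(spec)
        assert ct.top_n_proportion(rep, 10) == pytest.approx(0.46, abs=0.01)

    def test_cdr3s_are_in_frame_and_translated(self):
        rep = ct.generate_repertoire(ct.RepertoireSpec(2, 0.2, 50, 0.7, 1_000, seed=6))
        lengths = rep.clones["cdr3_nt"].str.len()
        assert ((lengths % 3) == 0).all()
        assert (lengths >= 27).all() and (lengths <= 45).all()
        for nt, aa in zip(rep.clones["cdr3_nt"], rep.clones["cdr3_aa"]):
            assert ct.translate_cdr3(nt) == aa


class TestGeneratePairedSample:
    PLN = ct.RepertoireSpec(10, 0.2, 800, 0.6, 20_000)
    JOINT = ct.RepertoireSpec(10, 0.44, 800, 0.6, 20_000)

    def test_zero_sharing_yields_disjoint_universes(self):
        pln, joint = ct.generate_paired_sample("early", self.PLN, self.JOINT, 0, 7,
                                               early_absent_fraction=1.0)
        assert ct.shared_sequences(pln, joint) == 0

    def test_designed_sharing_realized_without_dropout(self):
        # small universes + deep sampling: every clone receives >= 1 read,
        # so the realized overlap equals the designed one exactly
        pln_spec = ct.RepertoireSpec(4, 0.4, 40, 0.3, 200_000)
        joint_spec = ct.RepertoireSpec(4, 0.5, 40, 0.3, 200_000)
        s = 12
        pln, joint = ct.generate_paired_sample("late", pln_spec, joint_spec, s, 8)
        assert pln.n_clones == pln_spec.n_clones  # no dropout
        assert joint.n_clones == joint_spec.n_clones
        assert ct.shared_sequences(pln, joint) == s
        assert ct.normalized_overlap(pln, joint) == pytest.approx(
            s / (pln.total_reads * joint.total_reads)
        )

    def test_late_rule_joint_expanded_from_pln_top(self):
        pln, joint = ct.generate_paired_sample("late", self.PLN, self.JOINT, 100, 9)
        top_joint = {c.key for c in ct.top_clones(joint, 10)}
        pln_keys = pln.unique_keys("aa")
        assert top_joint <= pln_keys

    def test_early_rule_some_top_clones_absent(self):
        pln, joint = ct.generate_paired_sample(
            "early", self.PLN, self.JOINT, 100, 10, early_absent_fraction=0.5
        )
        res = ct.cross_site_ranks(joint, pln)
        assert res.n_absent >= 1

    def test_infeasible_sharing_errors(self):
        with pytest.raises(ValueError, match="sharing"):
            ct.generate_paired_sample("late", self.PLN, self.JOINT, 5, 1)  # < n_expanded
        with pytest.raises(ValueError, match="infeasible|capacity"):
            ct.generate_paired_sample("late", self.PLN, self.JOINT, 5_000, 1)


class TestGenerateCohort:
    def test_sample_counts_and_manifest(self, tmp_path):
        spec = ct.default_cohort_spec(master_seed=5, n_subjects=2, depth=2_000)
        reps, manifest = ct.generate_cohort(spec, tmp_path)
        assert len(reps) == 2 * 2 * 3  # subjects × tissues × arms
        assert len(manifest) == len(reps)
        assert set(manifest["tissue"]) == {"pLN", "joint"}
        assert (tmp_path / "manifest.tsv").exists()
        for f in manifest["file"]:
            assert (tmp_path / f).exists()

    def test_regeneration_is_byte_identical(self, tmp_path):
        spec = ct.default_cohort_spec(master_seed=6, n_subjects=1, depth=1_500)
        ct.generate_cohort(spec, tmp_path / "a")
        ct.generate_cohort(spec, tmp_path / "b")
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_single_sample_regenerable_from_manifest_seed(self, tmp_path):
        spec = ct.default_cohort_spec(master_seed=7, n_subjects=2, depth=1_500)
        _, manifest = ct.generate_cohort(spec)
        # the counter scheme is documented: subject k of the flattened
        # arm × subject grid has seed (master*100003 + k) mod 2^31
        assert manifest["seed"].iloc[0] == subject_seed(7, 0)
        assert manifest["seed"].nunique() == len(manifest) // 2  # one per subject

    def test_manifest_round_trips_through_pipeline_reader(self, tmp_path):
        spec = ct.default_cohort_spec(master_seed=8, n_subjects=2, depth=1_500)
        reps, manifest = ct.generate_cohort(spec, tmp_path)
        from clonotrace.pipeline import AnalysisConfig, load_repertoires, validate_manifest

        loaded = load_repertoires(validate_manifest(manifest), AnalysisConfig(), tmp_path)
        by_id = {r.sample_id: r for r in loaded}
        for rep in reps:
            assert by_id[rep.sample_id] == rep


class TestDesignedContrasts:
    def test_d50_decreases_with_expanded_mass(self):
        values = []
        for mass in (0.1, 0.3, 0.5, 0.7):
            d50s = [
                ct.d50(ct.generate_repertoire(
                    ct.RepertoireSpec(10, mass, 2_000, 0.5, 50_000, seed=s)
                )).d50
                for s in range(5)
            ]
            values.append(np.mean(d50s))
        assert all(values[i] > values[i + 1] for i in range(3))
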