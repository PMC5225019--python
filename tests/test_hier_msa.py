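"""Sub-alignment refinement, templates, projection and hiHMM assembly."""
import numpy as np
import pytest

from himsa.alphabet import AA_INDEX
from himsa.bpps_model import Hierarchy, PatternSet
from himsa.config import SamplerConfig
from himsa.hier_msa import (
    HiMSA,
    _legalize_row,
    assemble_hihmm,
    build_template,
    build_templates,
    build_himsa,
    compose_to_root,
    project_to_root,
    purge_redundant,
    refine_subgroup_alignment,
)
from himsa.state import AlignmentState
from tests.conftest import make_seqs


def fast_cfg(**kw):
    base = dict(
        seed=0,
        msa_sweeps=2,
        msa_refine_sweeps=2,
        architecture_rounds=1,
        outer_rounds=1,
        max_cycles=5,
        patience=3,
        burn_in_sweeps=3,
        min_leaf_sequences=4,
    )
    base.update(kw)
    return SamplerConfig(**base)


class TestPurge:
    def test_exact_duplicates_removed_and_present_after_rethread(self, rng):
        strings = ["ACDEWY"] * 3 + ["WYWYWY"]
        seqs = make_seqs(strings)
        L = 6
        aln = AlignmentState(np.tile(np.arange(L), (4, 1)), np.full(4, L))
        X = np.tile(np.array([[AA_INDEX[c] for c in s] for s in strings]), 1)
        kept, purged = purge_redundant(X, 0.95)
        assert list(kept) == [0, 3]
        assert list(purged) == [1, 2]
        out = refine_subgroup_alignment(seqs, aln, np.arange(4), fast_cfg(), rng)
        # every sequence still has a row in the final sub-alignment
        assert out.num_sequences == 4
        out.check()

    def test_distinct_sequences_all_kept(self):
        X = np.array([[0, 1, 2], [3, 4, 5], [6, 7, 8]])
        kept, purged = purge_redundant(X, 0.95)
        assert list(kept) == [0, 1, 2] and purged.size == 0


class TestLegalizeRow:
    def test_run_before_deletion_promoted(self):
        # residues 0..2; columns: match(0), deleted, match(2): residue 1
        # strands between matches separated by a deletion -> promoted
        row = np.array([0, -1, 2])
        fixed = _legalize_row(row, 3)
        assert list(fixed) == [0, 1, 2]
        AlignmentState(fixed[None, :], np.array([3])).check()

    def test_trailing_run_after_deletions(self):
        row = np.array([0, -1, -1])
        fixed = _legalize_row(row, 3)
        AlignmentState(fixed[None, :], np.array([3])).check()

    def test_leading_run_before_first_match(self):
        row = np.array([-1, -1, 2])
        fixed = _legalize_row(row, 3)
        AlignmentState(fixed[None, :], np.array([3])).check()

    def test_already_legal_untouched(self):
        row = np.array([0, 1, -1])
        assert list(_legalize_row(row, 2)) == [0, 1, -1]


class TestTemplates:
    def test_identity_template(self):
        par = AlignmentState(np.array([[0, 1], [0, 1]]), np.array([2, 2]))
        child = AlignmentState(np.array([[0, 1]]), np.array([2]))
        t = build_template(par, np.array([0, 1]), child, np.array([0]))
        assert t == {0: 0, 1: 1}

    def test_child_only_column_marked_insert(self):
        # child aligns position 1 (an insert in the parent view) as its own
        # middle column
        par = AlignmentState(np.array([[0, 2]]), np.array([3]))
        child = AlignmentState(np.array([[0, 1, 2]]), np.array([3]))
        t = build_template(par, np.array([0]), child, np.array([0]))
        assert t == {0: 0, 1: None, 2: 1}

    def test_three_level_composition_matches_direct(self):
        root = AlignmentState(np.array([[0, 1, 2]] * 2), np.array([3, 3]))
        mid = AlignmentState(np.array([[0, 1, 2]] * 2), np.array([3, 3]))
        leaf = AlignmentState(np.array([[0, 2]]), np.array([3]))
        H = Hierarchy.trivial(2)
        H.parent[2] = 0
        H.parent[3] = 2
        H.assignment[:] = 3
        hm = HiMSA(hierarchy=H)
        hm.node_rows = {0: np.array([0, 1]), 2: np.array([0, 1]), 3: np.array([0])}
        hm.sub_alignments = {0: root, 2: mid, 3: leaf}
        build_templates(hm)
        direct = build_template(root, np.array([0, 1]), leaf, np.array([0]))
        composed = {c: compose_to_root(hm, 3, c) for c in range(2)}
        assert composed == direct


class TestProjection:
    def test_identity_projection_is_noop(self):
        H = Hierarchy.trivial(2)
        H.parent[2] = 0
        H.assignment[:] = 2
        root = AlignmentState(np.array([[0, 1], [0, 1]]), np.array([2, 2]))
        hm = HiMSA(hierarchy=H)
        hm.node_rows = {0: np.array([0, 1]), 2: np.array([0, 1])}
        hm.sub_alignments = {0: root, 2: root.copy()}
        build_templates(hm)
        out = project_to_root(hm, root)
        assert np.array_equal(out.match_map, root.match_map)

    def test_unmapped_child_column_inserted_into_root(self):
        H = Hierarchy.trivial(2)
        H.parent[2] = 0
        H.assignment[:] = 2
        root = AlignmentState(np.array([[0, 2], [0, 2]]), np.array([3, 3]))
        child = AlignmentState(np.array([[0, 1, 2], [0, 1, 2]]), np.array([3, 3]))
        hm = HiMSA(hierarchy=H)
        hm.node_rows = {0: np.array([0, 1]), 2: np.array([0, 1])}
        hm.sub_alignments = {0: root, 2: child}
        build_templates(hm)
        out = project_to_root(hm, root)
        assert out.num_columns == 3
        assert np.array_equal(out.match_map[0], np.array([0, 1, 2]))
        out.check()


class TestHiHMM:
    def _toy(self):
        """Two leaves; column 1 diverges between them, column 0 shared."""
        strings = ["AWC", "AWC", "AWC", "AYC", "AYC", "AYC"]
        seqs = make_seqs(strings)
        aln = AlignmentState(np.tile(np.arange(3), (6, 1)), np.full(6, 3))
        H = Hierarchy.trivial(6)
        H.parent[2] = 0
        H.parent[3] = 0
        H.assignment[:3] = 2
        H.assignment[3:] = 3
        pat = PatternSet()
        pat.set_node(2, {1: frozenset({AA_INDEX["W"]})})
        pat.set_node(3, {1: frozenset({AA_INDEX["Y"]})})
        return seqs, aln, H, pat

    def test_ownership_and_lineage_emissions(self, rng):
        seqs, aln, H, pat = self._toy()
        hm = build_himsa(
            seqs, aln, H, fast_cfg(msa_refine_sweeps=0, refine_architecture=False), rng
        )
        hh = assemble_hihmm(hm, pat, seqs)
        W, Y = AA_INDEX["W"], AA_INDEX["Y"]
        # column 1 owned by each leaf: emissions differ between leaf HMMs
        e2 = hh.emissions[2]
        e3 = hh.emissions[3]
        assert e2[1, W] > 0.5 and e3[1, Y] > 0.5
        assert e2[1, W] > e3[1, W]
        # column 0 owned by the root: identical in every HMM
        assert np.allclose(hh.emissions[0][0], e2[0])
        assert np.allclose(hh.emissions[0][0], e3[0])

    def test_node_weights_proportional_to_effective_sizes(self, rng):
        seqs, aln, H, pat = self._toy()
        # leaf 2 members weigh 1.0 each (3 eff), leaf 3 members 1/3 (1 eff)
        for r in seqs.records[3:]:
            r.weight = 1 / 3
        hm = build_himsa(
            seqs, aln, H, fast_cfg(msa_refine_sweeps=0, refine_architecture=False), rng
        )
        hh = assemble_hihmm(hm, pat, seqs)
        assert hh.weights[2] == pytest.approx(0.75)
        assert hh.weights[3] == pytest.approx(0.25)
        assert sum(hh.weights.values()) == pytest.approx(1.0)

    def test_generativity_favours_true_node(self, rng):
        seqs, aln, H, pat = self._toy()
        hm = build_himsa(
            seqs, aln, H, fast_cfg(msa_refine_sweeps=0, refine_architecture=False), rng
        )
        hh = assemble_hihmm(hm, pat, seqs)
        gen = np.random.default_rng(0)
        for node, sibling in ((2, 3), (3, 2)):
            own = sib = 0.0
            for _ in range(30):
                codes = hh.emit(node, gen)
                own += hh.log_likelihood(node, codes)
                sib += hh.log_likelihood(sibling, codes)
            assert own > sib

    def test_residue_conservation_along_lineage(self, rng):
        seqs, aln, H, pat = self._toy()
        hm = build_himsa(
            seqs, aln, H, fast_cfg(msa_refine_sweeps=0, refine_architecture=False), rng
        )
        # each residue of each sequence appears at most once per level
        for node, rows in hm.node_rows.items():
            sub = hm.sub_alignments[node]
            for r in range(sub.num_sequences):
                matched = sub.match_map[r][sub.match_map[r] >= 0]
                assert len(set(matched.tolist())) == len(matched)
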