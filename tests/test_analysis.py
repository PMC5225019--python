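"""delta-BILD profiles and contrast-alignment rendering."""
import math
import warnings

import numpy as np
import pytest

from himsa.alphabet import AA_INDEX, BACKGROUND
from himsa.analysis import (
    DeltaBildProfile,
    delta_bild,
    delta_bild_profile,
    frequency_digit,
    profile_table,
    render_contrast_alignment,
    render_lineage,
    text_to_rtf,
)
from himsa.bpps_model import Hierarchy, PatternSet, build_contrast_alignment
from himsa.msa_model import bild_score, uniform_prior
from tests.test_bpps import two_leaf_hierarchy


def _xw(rows):
    X = np.array(rows, dtype=np.int64)
    return X, np.ones(X.shape[0])


class TestDeltaBild:
    def test_absent_subgroup_scores_zero(self):
        R = AA_INDEX["R"]
        X, w = _xw([[R], [R], [R], [R]])
        val = delta_bild(0, np.array([], dtype=np.int64), X, w, uniform_prior(0.5))
        assert val == pytest.approx(0.0)

    def test_divergent_split_positive_closed_form(self):
        R, E = AA_INDEX["R"], AA_INDEX["E"]
        n = 20
        X, w = _xw([[R]] * n + [[E]] * n)
        prior = uniform_prior(0.5)
        null = np.full(20, 0.05)
        got = delta_bild(0, np.arange(n), X, w, prior, null)

        def oracle_bild(counts):
            tot = 10.0
            out = math.lgamma(tot) - math.lgamma(sum(counts) + tot)
            for c in counts:
                out += math.lgamma(c + 0.5) - math.lgamma(0.5)
            out -= sum(counts) * math.log(0.05)
            return out / math.log(2)

        cg = [0.0] * 20
        cg[R] = n
        cr = [0.0] * 20
        cr[E] = n
        ca = [0.0] * 20
        ca[R] = n
        ca[E] = n
        expected = oracle_bild(cg) + oracle_bild(cr) - oracle_bild(ca)
        assert got == pytest.approx(expected)
        assert got > 0

    def test_homogeneous_split_not_positive_in_expectation(self, rng):
        """Splitting one composition in two pays the prior twice: the mean
        delta-BILD over resampled splits is non-positive."""
        prior = uniform_prior(0.5)
        vals = []
        for _ in range(300):
            codes = rng.choice(20, size=40, p=BACKGROUND)
            X = codes[:, None]
            vals.append(
                delta_bild(0, np.arange(20), X, np.ones(40), prior)
            )
        assert np.mean(vals) < 0

    def test_symmetry_of_partitions(self):
        R, E = AA_INDEX["R"], AA_INDEX["E"]
        X, w = _xw([[R]] * 5 + [[E]] * 7)
        prior = uniform_prior(0.5)
        a = delta_bild(0, np.arange(5), X, w, prior)
        b = delta_bild(0, np.arange(5, 12), X, w, prior)
        assert a == pytest.approx(b)


class TestDeltaBildProfile:
    def _planted(self):
        """Three subgroups, 12 columns; columns 2, 5, 9 discriminate."""
        rng = np.random.default_rng(0)
        K, w = 60, 12
        X = rng.choice(20, size=(K, w), p=BACKGROUND)
        special = {2: "R", 5: "W", 9: "H"}
        groups = [np.arange(0, 20), np.arange(20, 40), np.arange(40, 60)]
        for (j, aa), rows in zip(special.items(), groups):
            X[rows, j] = AA_INDEX[aa]
        H = Hierarchy.trivial(K)
        H.parent[2] = 0
        H.parent[3] = 0
        H.parent[4] = 0
        H.assignment[groups[0]] = 2
        H.assignment[groups[1]] = 3
        H.assignment[groups[2]] = 4
        return X, H, sorted(special)

    def test_planted_columns_top_and_flagged(self):
        X, H, special = self._planted()
        prof = delta_bild_profile(X, np.ones(X.shape[0]), H, uniform_prior(0.5))
        top3 = set(np.argsort(-prof.normalized)[:3].tolist())
        assert top3 == set(special)
        assert set(np.nonzero(prof.flags)[0].tolist()) <= set(special)
        assert prof.flags.sum() >= 1

    def test_normalization_range_and_rank_preserved(self):
        X, H, _ = self._planted()
        prof = delta_bild_profile(X, np.ones(X.shape[0]), H, uniform_prior(0.5))
        assert prof.normalized.min() == pytest.approx(0.0)
        assert prof.normalized.max() == pytest.approx(100.0)
        assert np.array_equal(np.argsort(prof.raw), np.argsort(prof.normalized))

    def test_flags_affine_invariant(self):
        """mean+2SD flagging commutes with the affine normalization."""
        X, H, _ = self._planted()
        prof = delta_bild_profile(X, np.ones(X.shape[0]), H, uniform_prior(0.5))
        raw_flags = prof.raw > prof.raw.mean() + 2 * prof.raw.std()
        assert np.array_equal(raw_flags, prof.flags)

    def test_degenerate_scores_warn_and_zero(self):
        K = 12
        H = Hierarchy.trivial(K)
        H.parent[2] = 0
        H.parent[3] = 0
        H.assignment[:6] = 2
        H.assignment[6:] = 3
        X = np.full((K, 3), AA_INDEX["A"], dtype=np.int64)
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            prof = delta_bild_profile(X, np.ones(K), H, uniform_prior(0.5))
        assert prof.degenerate
        assert np.all(prof.normalized == 0)
        assert any("degenerate" in str(r.message) for r in rec)

    def test_single_subgroup_rejected(self):
        K = 10
        H = Hierarchy.trivial(K)
        H.parent[2] = 0
        H.assignment[:] = 2
        with pytest.raises(ValueError):
            delta_bild_profile(np.zeros((K, 2), dtype=np.int64), np.ones(K), H)

    def test_profile_table_format(self):
        X, H, _ = self._planted()
        prof = delta_bild_profile(X, np.ones(X.shape[0]), H, uniform_prior(0.5))
        table = profile_table(prof)
        lines = table.strip().splitlines()
        assert lines[0].startswith("column\t")
        assert len(lines) == X.shape[1] + 1
        assert lines[1].split("\t")[0] == "1"  # 1-based


class TestRendering:
    def test_frequency_digit_bounds(self):
        assert frequency_digit(0.65) == 6
        assert frequency_digit(0.28) == 2
        assert frequency_digit(0.0) == 0
        assert frequency_digit(1.0) == 9  # capped single digit
        for f in np.linspace(0.01, 0.999, 37):
            d = frequency_digit(float(f))
            assert d <= 10 * f < d + 1 or (f > 0.999)

    def _contrast(self):
        H = two_leaf_hierarchy(20)
        G, A_, K_ = AA_INDEX["G"], AA_INDEX["A"], AA_INDEX["K"]
        col0 = [G] * 13 + [A_] * 5 + [K_] * 2  # 65 % G, 25 % A, 10 % K
        X = np.array([[c, K_] for c in col0], dtype=np.int64)
        H.assignment[:] = 2  # all foreground under node 2
        pat = PatternSet()
        pat.set_node(2, {0: frozenset({G, A_})})
        ca = build_contrast_alignment(H, 2, X, np.ones(20), pat, 0.05)
        return ca, X

    def test_consensus_and_digits(self):
        ca, X = self._contrast()
        text = render_contrast_alignment(ca, X, np.ones(20))
        lines = text.splitlines()
        cons = next(l for l in lines if l.startswith("cons"))
        freq = next(l for l in lines if l.startswith("freq1"))
        assert cons[6] == "G"
        assert freq[6] == "6"  # 65 % -> '6'
        co2 = next(l for l in lines if l.startswith("co2"))
        freq2 = next(l for l in lines if l.startswith("freq2"))
        assert co2[6] == "A" and freq2[6] == "2"

    def test_below_threshold_residues_dropped(self):
        # every residue at 5 %: no consensus entries
        X = np.arange(20, dtype=np.int64)[:, None]
        H = two_leaf_hierarchy(20)
        H.assignment[:] = 2
        ca = build_contrast_alignment(H, 2, X, np.ones(20), PatternSet(), 0.05)
        text = render_contrast_alignment(ca, X, np.ones(20))
        assert not any(l.startswith("cons") for l in text.splitlines())

    def test_effective_count_reported(self):
        ca, X = self._contrast()
        text = render_contrast_alignment(ca, X, np.full(20, 0.5))
        assert "effective sequences = 10.0" in text

    def test_lineage_block_count(self):
        H = two_leaf_hierarchy(8)
        X = np.zeros((8, 2), dtype=np.int64)
        text = render_lineage(H, 2, X, np.ones(8), PatternSet())
        assert text.count("contrast alignment") == 2  # root + leaf

    def test_rtf_digit_styling(self):
        ca, X = self._contrast()
        text = render_contrast_alignment(ca, X, np.ones(20))
        rtf = text_to_rtf(text)
        assert rtf.startswith(r"{\rtf1")
        # '6' stays plain, digits 7-9 are wrapped in the red style
        assert r"{\cf2 6}" not in rtf
        plain = [l for l in text.splitlines() if l.startswith("freq")]
        if any(ch in "789" for l in plain for ch in l):
            assert r"{\cf2" in rtf
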