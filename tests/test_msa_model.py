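"""Column marginals, transition prior, joint posterior and Gibbs moves.

The enumeration oracle used here is written from scratch (explicit Gamma
functions over explicitly enumerated paths) and shares no code with the
implementation it checks.
"""
import itertools
import math

import numpy as np
import pytest

from himsa.alphabet import AA_INDEX, BACKGROUND
from himsa.msa_model import (
    background_prior,
    bild_score,
    builtin_mixture,
    log_column_marginal,
    log_joint,
    log_transition_prior,
    resample_sequence,
    uniform_prior,
)
from himsa.seqio import SequenceRecord, SequenceSet
from himsa.state import AlignmentState, TransitionCounts, TransitionPriors
from tests.conftest import make_seqs


# ----------------------------------------------------------------------
# Independent oracle
# ----------------------------------------------------------------------

def oracle_column_marginal(counts, beta):
    """Dirichlet-multinomial marginal via direct lgamma arithmetic."""
    n = sum(counts)
    tot = sum(beta)
    out = math.lgamma(tot) - math.lgamma(n + tot)
    for c, b in zip(counts, beta):
        out += math.lgamma(c + b) - math.lgamma(b)
    return out


def oracle_transition_block(counts, priors):
    """One Dirichlet-multinomial block: counts/priors are parallel lists."""
    out = math.lgamma(sum(priors)) - math.lgamma(sum(counts) + sum(priors))
    for c, p in zip(counts, priors):
        out += math.lgamma(c + p) - math.lgamma(p)
    return out


def enumerate_rows(length, w):
    """All legal match_map rows for a sequence of the given length."""
    rows = []
    for picks in itertools.product([-1] + list(range(length)), repeat=w):
        vals = [v for v in picks if v >= 0]
        if vals != sorted(set(vals)) or (vals and vals != sorted(vals)):
            continue
        try:
            a = AlignmentState(np.array([picks]), np.array([length]))
            a.check()
        except Exception:
            continue
        rows.append(picks)
    return rows


def oracle_log_joint(strings, rows, beta, tpriors):
    """Unnormalised log posterior computed independently: per-column
    Dirichlet-multinomial, fixed-background inserts, and per-position
    transition blocks tallied by walking each path by hand."""
    K = len(strings)
    w = len(rows[0])
    codes = [[AA_INDEX[c] for c in s] for s in strings]
    # columns
    total = 0.0
    for j in range(w):
        counts = [0.0] * 20
        for k in range(K):
            p = rows[k][j]
            if p >= 0:
                counts[codes[k][p]] += 1.0
        if sum(counts):
            total += oracle_column_marginal(counts, beta)
    # unaligned background
    for k in range(K):
        matched = {p for p in rows[k] if p >= 0}
        for i, c in enumerate(codes[k]):
            if i not in matched:
                total += math.log(BACKGROUND[c])
    # transitions: walk each path
    names = ["mm", "mi", "md", "im", "ii", "dm", "dd"]
    counts = {t: [0.0] * (w + 1) for t in names}
    for k in range(K):
        pos, prev = 0, "M"
        events = []
        for j in range(1, w + 1):
            p = rows[k][j - 1]
            if p >= 0:
                events.append((j, "M", p - pos))
                pos = p + 1
                prev = "M"
            else:
                events.append((j, "D", 0))
                prev = "D"
        events.append((w + 1, "M", len(codes[k]) - pos))
        prev = "M"
        for j, kind, nins in events:
            at = j - 1
            if nins > 0:
                counts["mi"][at] += 1
                counts["ii"][at] += nins - 1
                counts["im"][at] += 1
                src = "I"
            else:
                src = prev
            if kind == "M":
                if nins == 0:
                    counts["mm" if src == "M" else "dm"][at] += 1
                prev = "M"
            else:
                counts["md" if src == "M" else "dd"][at] += 1
                prev = "D"
    tp = tpriors
    for j in range(w + 1):
        total += oracle_transition_block(
            [counts["mm"][j], counts["mi"][j], counts["md"][j]],
            [tp.n_mm, tp.n_mi, tp.n_md],
        )
        total += oracle_transition_block(
            [counts["ii"][j], counts["im"][j]], [tp.n_ii, tp.n_im]
        )
        total += oracle_transition_block(
            [counts["dd"][j], counts["dm"][j]], [tp.n_dd, tp.n_dm]
        )
    return total


# ----------------------------------------------------------------------
# Column marginal
# ----------------------------------------------------------------------

class TestColumnMarginal:
    def test_empty_column_is_log_one(self):
        assert log_column_marginal(np.zeros(20), uniform_prior(1.0)) == 0.0

    def test_single_observation_equals_prior_mean(self):
        counts = np.zeros(20)
        counts[AA_INDEX["A"]] = 1
        val = log_column_marginal(counts, background_prior(1.0))
        assert val == pytest.approx(math.log(BACKGROUND[AA_INDEX["A"]]))

    def test_closed_form_a2_c1(self):
        counts = np.zeros(20)
        counts[AA_INDEX["A"]] = 2
        counts[AA_INDEX["C"]] = 1
        expected = math.log(
            math.gamma(20) / math.gamma(23) * math.gamma(3) * math.gamma(2)
        )
        assert log_column_marginal(counts, uniform_prior(1.0)) == pytest.approx(expected)

    def test_mixture_is_weighted_average(self):
        counts = np.zeros(20)
        counts[3] = 4
        mix = builtin_mixture()
        parts = [
            oracle_column_marginal(counts, alphas) for alphas in mix.alphas
        ]
        expected = math.log(
            sum(w * math.exp(p) for w, p in zip(mix.weights, parts))
        )
        assert log_column_marginal(counts, mix) == pytest.approx(expected)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            log_column_marginal(np.full(20, -1.0), uniform_prior(1.0))


# ----------------------------------------------------------------------
# Transition prior
# ----------------------------------------------------------------------

class TestTransitionPrior:
    def test_all_zero_counts_is_log_one(self):
        tc = TransitionCounts(np.zeros((7, 3)), TransitionPriors())
        assert log_transition_prior(tc) == 0.0

    def test_single_mm_with_unit_priors(self):
        pri = TransitionPriors(1, 1, 1, 1, 1, 1, 1)
        c = np.zeros((7, 2))
        c[0, 0] = 1  # one M->M at position 0
        tc = TransitionCounts(c, pri)
        assert log_transition_prior(tc) == pytest.approx(math.log(1 / 3))

    def test_positional_factorisation(self):
        pri = TransitionPriors(1, 1, 1, 1, 1, 1, 1)
        c = np.zeros((7, 3))
        c[0, 0] = 1
        c[0, 1] = 1
        tc = TransitionCounts(c, pri)
        assert log_transition_prior(tc) == pytest.approx(2 * math.log(1 / 3))

    def test_nonpositive_priors_rejected(self):
        with pytest.raises(ValueError):
            TransitionPriors(n_mm=0.0)


# ----------------------------------------------------------------------
# Joint posterior vs enumeration
# ----------------------------------------------------------------------

class TestLogJoint:
    def test_zero_columns_is_background_only(self):
        seqs = make_seqs(["AC"])
        aln = AlignmentState(np.zeros((1, 0), dtype=int), np.array([2]))
        expected = math.log(BACKGROUND[AA_INDEX["A"]]) + math.log(
            BACKGROUND[AA_INDEX["C"]]
        )
        # plus the insert-run transition block at position 0
        tp = TransitionPriors()
        expected += oracle_transition_block([0, 1, 0], [tp.n_mm, tp.n_mi, tp.n_md])
        expected += oracle_transition_block([1, 1], [tp.n_ii, tp.n_im])
        assert log_joint(seqs, aln, uniform_prior(1.0)) == pytest.approx(expected)

    def test_two_identical_sequences_hand_value(self):
        seqs = make_seqs(["AC", "AC"])
        aln = AlignmentState(np.array([[0, 1], [0, 1]]), np.array([2, 2]))
        got = log_joint(seqs, aln, uniform_prior(1.0))
        expected = oracle_log_joint(
            ["AC", "AC"], [(0, 1), (0, 1)], [1.0] * 20, TransitionPriors()
        )
        assert got == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        "strings,w",
        [
            (["AC", "AC"], 1),
            (["ACD", "AD"], 2),
            (["WC", "WC", "W"], 2),
            (["ACDE"], 2),
        ],
    )
    def test_oracle_equivalence_all_alignments(self, strings, w):
        """exp(log_joint) ratios match exhaustive enumeration to 10
        significant digits on every legal alignment of small instances."""
        prior = uniform_prior(1.0)
        tp = TransitionPriors()
        per_seq = [enumerate_rows(len(s), w) for s in strings]
        vals_impl, vals_oracle = [], []
        for combo in itertools.product(*per_seq):
            mm = np.array(combo)
            aln = AlignmentState(mm, np.array([len(s) for s in strings]))
            try:
                aln.check()
            except Exception:
                continue
            seqs = make_seqs(strings)
            vals_impl.append(log_joint(seqs, aln, prior, tp))
            vals_oracle.append(oracle_log_joint(strings, combo, [1.0] * 20, tp))
        assert len(vals_impl) >= 2
        ref_i, ref_o = vals_impl[0], vals_oracle[0]
        for vi, vo in zip(vals_impl, vals_oracle):
            assert vi - ref_i == pytest.approx(vo - ref_o, abs=1e-10)


# ----------------------------------------------------------------------
# Gibbs resampling
# ----------------------------------------------------------------------

class TestResampleSequence:
    def test_requires_rng(self, two_ac):
        seqs, aln = two_ac
        with pytest.raises(ValueError):
            resample_sequence(seqs, aln, 1, None, uniform_prior(1.0))

    def test_degenerate_conditional_returns_only_path(self, rng):
        # length-1 sequence against a 1-column model: either matched or
        # deleted-with-leading-insert; make the match overwhelming by
        # stacking identical partners
        seqs = make_seqs(["W"] * 6)
        aln = AlignmentState(np.zeros((6, 1), dtype=int), np.ones(6, dtype=int))
        out = resample_sequence(seqs, aln, 5, rng, uniform_prior(0.05))
        assert out.match_map[5, 0] in (0, -1)

    def test_empirical_matches_enumeration(self, rng):
        """Empirical path frequencies over 10,000 updates match the
        enumerated conditional within 3 standard errors."""
        strings = ["AC", "AC"]
        prior = uniform_prior(1.0)
        tp = TransitionPriors()
        # enumerate conditional of sequence 1 given sequence 0 fixed
        rows = enumerate_rows(2, 1)
        logps = {}
        for r in rows:
            mm = np.array([[0], list(r)])
            aln = AlignmentState(mm, np.array([2, 2]))
            try:
                aln.check()
            except Exception:
                continue
            logps[r] = oracle_log_joint(strings, [(0,), r], [1.0] * 20, tp)
        z = max(logps.values())
        probs = {r: math.exp(v - z) for r, v in logps.items()}
        tot = sum(probs.values())
        probs = {r: v / tot for r, v in probs.items()}

        seqs = make_seqs(strings)
        aln = AlignmentState(np.array([[0], [0]]), np.array([2, 2]))
        n = 10_000
        freq = {r: 0 for r in probs}
        for _ in range(n):
            aln = resample_sequence(seqs, aln, 1, rng, prior, tp)
            freq[tuple(aln.match_map[1])] += 1
        for r, p in probs.items():
            se = math.sqrt(p * (1 - p) / n)
            assert abs(freq[r] / n - p) < 3 * se + 1e-9


# ----------------------------------------------------------------------
# BILD
# ----------------------------------------------------------------------

class TestBild:
    def test_empty_column_zero(self):
        assert bild_score(np.zeros(20), uniform_prior(0.5)) == 0.0

    def test_single_obs_prior_mean_equals_null(self):
        counts = np.zeros(20)
        counts[AA_INDEX["G"]] = 1
        assert bild_score(counts, background_prior(1.0), BACKGROUND) == pytest.approx(0.0)

    def test_ten_identical_closed_form(self):
        counts = np.zeros(20)
        counts[AA_INDEX["W"]] = 10
        null = np.full(20, 0.05)
        got = bild_score(counts, uniform_prior(0.5), null)
        expected = (
            oracle_column_marginal(counts.tolist(), [0.5] * 20)
            - 10 * math.log(0.05)
        ) / math.log(2)
        assert got == pytest.approx(expected)
        assert got > 0

    def test_monotone_in_conservation_depth(self):
        null = np.full(20, 0.05)
        prior = uniform_prior(0.5)
        vals = []
        for n in range(1, 40):
            counts = np.zeros(20)
            counts[AA_INDEX["W"]] = n
            vals.append(bild_score(counts, prior, null))
        first_pos = next(i for i, v in enumerate(vals) if v > 0)
        tail = vals[first_pos:]
        assert all(b > a for a, b in zip(tail, tail[1:]))

    def test_zero_null_with_count_rejected(self):
        counts = np.zeros(20)
        counts[0] = 1
        null = np.zeros(20)
        null[1] = 1.0
        with pytest.raises(ValueError):
            bild_score(counts, uniform_prior(0.5), null)
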