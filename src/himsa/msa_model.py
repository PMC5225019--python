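"""Dirichlet-multinomial MSA model and single-sequence Gibbs resampling.

The alignment posterior factorises into per-column Dirichlet(-mixture)
multinomial marginals for the residues in match columns, a fixed background
frequency term for insert/unaligned residues, and an integrated
position-specific transition prior (the implicit gap penalties).  The same
integrated marginal supplies absolute bit-lengths for the MDL accounting
and the Bayesian integral log-odds (BILD) column scores.

Gibbs resampling of one sequence draws emission and transition parameters
from their leave-one-out posteriors and then samples the sequence's path by
forward filtering / stochastic traceback.  Because the parameter draw
marginalises exactly, the resulting path is a draw from the collapsed
conditional, and the sweep leaves exp(log_joint) invariant.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .alphabet import BACKGROUND, N_AA
from .seqio import SequenceSet, count_all_columns
from .state import AlignmentState, TransitionCounts, TransitionPriors

LOG2 = np.log(2.0)


# ----------------------------------------------------------------------
# Emission prior
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class DirichletMixture:
    """Mixture of Dirichlet priors over 20-dim residue frequency vectors."""

    weights: tuple
    alphas: tuple  # tuple of length-20 tuples

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.size == 0 or abs(w.sum() - 1.0) > 1e-9 or np.any(w <= 0):
            raise ValueError("mixture weights must be positive and sum to 1")
        for a in self.alphas:
            if len(a) != N_AA or any(x <= 0 for x in a):
                raise ValueError("each pseudocount vector needs 20 positive entries")

    @property
    def n_components(self) -> int:
        return len(self.weights)

    def alpha_matrix(self) -> np.ndarray:
        return np.asarray(self.alphas, dtype=float)


def background_prior(concentration: float = 1.0) -> DirichletMixture:
    """Single-component prior whose mean is the standard background."""
    return DirichletMixture(
        weights=(1.0,), alphas=(tuple(BACKGROUND * concentration),)
    )


def uniform_prior(beta: float = 0.5) -> DirichletMixture:
    """Single-component symmetric Dirichlet(beta,...,beta)."""
    return DirichletMixture(weights=(1.0,), alphas=(tuple([beta] * N_AA),))


_CLASSES = ("FYW", "ILVM", "KRH", "DE", "STNQ", "GA", "P", "C")


def builtin_mixture(class_mass: float = 4.0, class_share: float = 0.8) -> DirichletMixture:
    """Small packaged mixture: one background component plus one component
    per broad biochemical class, each concentrating most of its mass on the
    class residues.  A light-weight stand-in for the large published
    mixtures, adequate for moderate column depths."""
    from .alphabet import AA_INDEX

    weights = [0.5] + [0.5 / len(_CLASSES)] * len(_CLASSES)
    alphas = [tuple(BACKGROUND * 1.0)]
    for cls in _CLASSES:
        a = BACKGROUND * (1 - class_share) * class_mass
        for ch in cls:
            a[AA_INDEX[ch]] += class_share * class_mass / len(cls)
        alphas.append(tuple(a))
    return DirichletMixture(weights=tuple(weights), alphas=tuple(alphas))


# ----------------------------------------------------------------------
# Column marginal and BILD
# ----------------------------------------------------------------------

def log_column_marginal(counts: np.ndarray, prior: DirichletMixture) -> float:
    """Log Dirichlet(-mixture) multinomial marginal of weighted counts.

    log sum_c w_c * G(|b_c|)/G(n+|b_c|) * prod_i G(h_i+b_ci)/G(b_ci).
    Fully normalised, so differences double as data description lengths.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("negative counts")
    n = counts.sum()
    if n == 0:
        return 0.0
    A = prior.alpha_matrix()  # (C, 20)
    tot = A.sum(axis=1)
    comp = (
        gammaln(tot)
        - gammaln(n + tot)
        + (gammaln(counts[None, :] + A) - gammaln(A)).sum(axis=1)
    )
    return float(logsumexp(comp + np.log(prior.weights)))


def column_log_marginals(counts: np.ndarray, prior: DirichletMixture) -> np.ndarray:
    """Vectorised log_column_marginal over rows of a (w, 20) count matrix."""
    counts = np.asarray(counts, dtype=float)
    A = prior.alpha_matrix()
    tot = A.sum(axis=1)  # (C,)
    n = counts.sum(axis=1)  # (w,)
    comp = (
        gammaln(tot)[None, :]
        - gammaln(n[:, None] + tot[None, :])
        + (gammaln(counts[:, None, :] + A[None, :, :]) - gammaln(A)[None, :, :]).sum(
            axis=2
        )
    )
    out = logsumexp(comp + np.log(prior.weights)[None, :], axis=1)
    out[n == 0] = 0.0
    return out


def bild_score(
    counts: np.ndarray, prior: DirichletMixture, null: np.ndarray | None = None
) -> float:
    """Bayesian integral log-odds of a column, in bits.

    log2 of the ratio between the integrated Dirichlet-mixture marginal of
    the column's (weighted) residue counts and their probability under a
    fixed null frequency vector.  Positive scores justify a match state.
    """
    counts = np.asarray(counts, dtype=float)
    null = BACKGROUND if null is None else np.asarray(null, dtype=float)
    if np.any((null <= 0) & (counts > 0)):
        raise ValueError("zero null frequency with non-zero count")
    with np.errstate(divide="ignore"):
        log_null = np.where(counts > 0, np.log(np.where(null > 0, null, 1.0)), 0.0)
    return (log_column_marginal(counts, prior) - float(counts @ log_null)) / LOG2


# ----------------------------------------------------------------------
# Transition prior (integrated position-specific gap penalties)
# ----------------------------------------------------------------------

def log_transition_prior(tc: TransitionCounts) -> float:
    """Log of the product over positions of the three Gamma-ratio blocks
    (match-, insert- and delete-sourced transitions), i.e. the marginal
    probability of all observed transitions under per-position Dirichlet
    priors on the transition distributions."""
    tc.check()
    p = tc.priors
    mm, mi, md, im, ii, dm, dd = (tc[t] for t in ("mm", "mi", "md", "im", "ii", "dm", "dd"))
    m_tot = mm + mi + md
    i_tot = im + ii
    d_tot = dm + dd
    out = (
        gammaln(mm + p.n_mm) + gammaln(mi + p.n_mi) + gammaln(md + p.n_md)
        - gammaln(p.n_mm) - gammaln(p.n_mi) - gammaln(p.n_md)
        + gammaln(p.n_m) - gammaln(m_tot + p.n_m)
    )
    out = out + (
        gammaln(ii + p.n_ii) + gammaln(im + p.n_im)
        - gammaln(p.n_ii) - gammaln(p.n_im)
        + gammaln(p.n_i) - gammaln(i_tot + p.n_i)
    )
    out = out + (
        gammaln(dd + p.n_dd) + gammaln(dm + p.n_dm)
        - gammaln(p.n_dd) - gammaln(p.n_dm)
        + gammaln(p.n_d) - gammaln(d_tot + p.n_d)
    )
    return float(out.sum())


# ----------------------------------------------------------------------
# Joint
# ----------------------------------------------------------------------

def unaligned_log_background(
    seqs: SequenceSet, aln: AlignmentState, background: np.ndarray | None = None
) -> float:
    """Weighted log-probability of all insert/unaligned residues under the
    fixed background frequencies."""
    bg = BACKGROUND if background is None else background
    log_bg = np.log(bg)
    total = 0.0
    for k, rec in enumerate(seqs):
        codes = rec.codes
        matched = aln.match_map[k]
        matched = matched[matched >= 0]
        mask = np.ones(codes.shape[0], dtype=bool)
        mask[matched] = False
        ins = codes[mask]
        ins = ins[ins >= 0]
        if ins.size:
            total += rec.weight * float(log_bg[ins].sum())
    return total


def log_joint(
    seqs: SequenceSet,
    aln: AlignmentState,
    prior: DirichletMixture | None = None,
    tpriors: TransitionPriors | None = None,
    background: np.ndarray | None = None,
) -> float:
    """Unnormalised log posterior of an alignment state (natural log).

    Sum of the per-column integrated marginals, the fixed-background term
    for unaligned residues, and the integrated transition prior.  This is
    the sampler's target up to an additive constant; -log2 of it is the
    data description length used by the MDL ledger.
    """
    prior = prior or background_prior()
    aln.check()
    counts = count_all_columns(seqs, aln)
    col_term = float(column_log_marginals(counts, prior).sum())
    bg_term = unaligned_log_background(seqs, aln, background)
    tr_term = log_transition_prior(aln.transition_counts(tpriors))
    return col_term + bg_term + tr_term


def data_dl_bits(*args, **kwargs) -> float:
    """Description length of the aligned data in bits (see log_joint)."""
    return -log_joint(*args, **kwargs) / LOG2


# ----------------------------------------------------------------------
# Gibbs resampling of one sequence
# ----------------------------------------------------------------------

def _sample_column_thetas(
    counts: np.ndarray, prior: DirichletMixture, rng: np.random.Generator
) -> np.ndarray:
    """Draw theta_j ~ posterior(theta | counts_j) for every column.

    Mixture handled exactly: component sampled from its posterior weight,
    then a Dirichlet draw from the chosen component's posterior."""
    w = counts.shape[0]
    A = prior.alpha_matrix()
    C = prior.n_components
    if C == 1:
        alpha_post = counts + A[0][None, :]
    else:
        tot = A.sum(axis=1)
        n = counts.sum(axis=1)
        comp_ll = (
            gammaln(tot)[None, :]
            - gammaln(n[:, None] + tot[None, :])
            + (gammaln(counts[:, None, :] + A[None, :, :]) - gammaln(A)[None, :, :]).sum(axis=2)
            + np.log(prior.weights)[None, :]
        )
        comp_ll -= logsumexp(comp_ll, axis=1, keepdims=True)
        picks = np.array(
            [rng.choice(C, p=np.exp(comp_ll[j])) for j in range(w)], dtype=int
        )
        alpha_post = counts + A[picks]
    # vectorised Dirichlet via gamma draws
    g = rng.gamma(shape=alpha_post)
    g = np.maximum(g, 1e-300)
    return g / g.sum(axis=1, keepdims=True)


def _sample_transition_probs(
    tc: TransitionCounts, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Draw position-specific transition probabilities from their
    Dirichlet posteriors; returns log-prob arrays keyed by type."""
    p = tc.priors
    w1 = tc.w + 1
    out = {}
    trip = rng.gamma(
        shape=np.stack(
            [tc["mm"] + p.n_mm, tc["mi"] + p.n_mi, tc["md"] + p.n_md], axis=1
        )
    )
    trip = np.maximum(trip, 1e-300)
    trip /= trip.sum(axis=1, keepdims=True)
    out["mm"], out["mi"], out["md"] = np.log(trip).T
    pair = rng.gamma(shape=np.stack([tc["im"] + p.n_im, tc["ii"] + p.n_ii], axis=1))
    pair = np.maximum(pair, 1e-300)
    pair /= pair.sum(axis=1, keepdims=True)
    out["im"], out["ii"] = np.log(pair).T
    pair = rng.gamma(shape=np.stack([tc["dm"] + p.n_dm, tc["dd"] + p.n_dd], axis=1))
    pair = np.maximum(pair, 1e-300)
    pair /= pair.sum(axis=1, keepdims=True)
    out["dm"], out["dd"] = np.log(pair).T
    assert out["mm"].shape == (w1,)
    return out


def posterior_mean_emissions(
    counts: np.ndarray, prior: DirichletMixture
) -> np.ndarray:
    """(w, 20) posterior-mean emission frequencies under the mixture."""
    counts = np.asarray(counts, dtype=float)
    A = prior.alpha_matrix()
    tot = A.sum(axis=1)
    n = counts.sum(axis=1)
    means = (counts[:, None, :] + A[None, :, :]) / (
        n[:, None, None] + tot[None, :, None]
    )
    if prior.n_components == 1:
        return means[:, 0, :]
    comp_ll = (
        gammaln(tot)[None, :]
        - gammaln(n[:, None] + tot[None, :])
        + (gammaln(counts[:, None, :] + A[None, :, :]) - gammaln(A)[None, :, :]).sum(axis=2)
        + np.log(prior.weights)[None, :]
    )
    comp_ll -= logsumexp(comp_ll, axis=1, keepdims=True)
    return (np.exp(comp_ll)[:, :, None] * means).sum(axis=1)


def posterior_mean_log_transitions(tc: TransitionCounts) -> dict[str, np.ndarray]:
    """Posterior-mean transition probabilities (log), per position."""
    p = tc.priors
    m_tot = tc["mm"] + tc["mi"] + tc["md"] + p.n_m
    i_tot = tc["im"] + tc["ii"] + p.n_i
    d_tot = tc["dm"] + tc["dd"] + p.n_d
    return {
        "mm": np.log((tc["mm"] + p.n_mm) / m_tot),
        "mi": np.log((tc["mi"] + p.n_mi) / m_tot),
        "md": np.log((tc["md"] + p.n_md) / m_tot),
        "im": np.log((tc["im"] + p.n_im) / i_tot),
        "ii": np.log((tc["ii"] + p.n_ii) / i_tot),
        "dm": np.log((tc["dm"] + p.n_dm) / d_tot),
        "dd": np.log((tc["dd"] + p.n_dd) / d_tot),
    }


NEG_INF = -np.inf


def _forward(
    codes: np.ndarray,
    log_theta: np.ndarray,  # (w, 20) log emission for match columns
    log_bg: np.ndarray,  # (20,) insert emissions
    lt: dict[str, np.ndarray],  # log transition probs, arrays (w+1,)
    op: str = "sum",
):
    """Log-space forward pass ('sum') or Viterbi pass ('max').

    Returns (fM, fD, fI, total).

    fM[j, i]: path prefixes ending just after emitting match column j having
    consumed i residues (j=0 is Begin).  fI[j, i]: currently in insert state
    I_j with i consumed.  fD[j, i]: in delete state D_j.
    """
    combine = np.logaddexp if op == "sum" else np.maximum
    L = codes.shape[0]
    w = log_theta.shape[0]
    fM = np.full((w + 1, L + 1), NEG_INF)
    fD = np.full((w + 1, L + 1), NEG_INF)
    fI = np.full((w + 1, L + 1), NEG_INF)
    fM[0, 0] = 0.0
    # emission lookups; 'X' (code -1) emits with probability one
    def em_match(j):  # vector over residue prefix positions 1..L
        e = np.where(codes >= 0, log_theta[j - 1, np.maximum(codes, 0)], 0.0)
        return e  # e[i-1] is emission of residue consumed as i-th

    e_ins = np.where(codes >= 0, log_bg[np.maximum(codes, 0)], 0.0)

    for j in range(0, w + 1):
        # insert state I_j: sequential in i, vectorised via accumulate trick
        # fI[j, i] = lse( fM[j, i-1] + mi[j], fI[j, i-1] + ii[j] ) + e_ins[i-1]
        mi, ii = lt["mi"][j], lt["ii"][j]
        src = fM[j, :-1] + mi  # contribution entering the run at i
        # q[m] = fM[j, m] + mi - (m+1) ii - P[m];  fI[j,i] = i*ii + P[i] + lse_{m<i} q[m]
        P = np.concatenate([[0.0], np.cumsum(e_ins)])  # P[i] = sum of first i inserts
        idx = np.arange(L + 1)
        q = fM[j, :] + mi - (idx + 1) * ii - P
        with np.errstate(invalid="ignore"):
            cum = combine.accumulate(q)
        fI[j, 1:] = idx[1:] * ii + P[1:] + cum[:-1]
        del src
        if j == w:
            break
        # delete column j+1 (elementwise in i)
        fD[j + 1] = combine(fM[j] + lt["md"][j], fD[j] + lt["dd"][j])
        # match column j+1
        em = em_match(j + 1)
        prev = combine(
            combine(fM[j, :-1] + lt["mm"][j], fI[j, :-1] + lt["im"][j]),
            fD[j, :-1] + lt["dm"][j],
        )
        fM[j + 1, 1:] = prev + em
    total = combine(
        combine(fM[w, L] + lt["mm"][w], fI[w, L] + lt["im"][w]),
        fD[w, L] + lt["dm"][w],
    )
    return fM, fD, fI, float(total)


def _traceback(
    fM: np.ndarray,
    fD: np.ndarray,
    fI: np.ndarray,
    lt: dict[str, np.ndarray],
    L: int,
    rng: np.random.Generator | None,
    greedy: bool = False,
) -> np.ndarray:
    """Stochastic (or greedy/Viterbi) traceback; returns the match_map row."""
    w = fM.shape[0] - 1
    row = np.full(w, -1, dtype=np.int64)

    def pick(logps):
        mx = max(logps)
        if mx == NEG_INF:
            raise RuntimeError("traceback dead end")
        if greedy:
            return logps.index(mx)
        pr = [np.exp(v - mx) for v in logps]
        r = rng.random() * sum(pr)
        acc = 0.0
        for idx, v in enumerate(pr):
            acc += v
            if r <= acc:
                return idx
        return len(pr) - 1

    state, j, i = "E", w, L
    while not (state == "M" and j == 0):
        if state == "E":
            choice = pick([fM[w, L] + lt["mm"][w], fI[w, L] + lt["im"][w], fD[w, L] + lt["dm"][w]])
            state = ("M", "I", "D")[choice]
            continue
        if state == "M":
            # arrived in M_j having consumed residue i-1 at column j
            row[j - 1] = i - 1
            choice = pick(
                [
                    fM[j - 1, i - 1] + lt["mm"][j - 1],
                    fI[j - 1, i - 1] + lt["im"][j - 1],
                    fD[j - 1, i - 1] + lt["dm"][j - 1],
                ]
            )
            state = ("M", "I", "D")[choice]
            j, i = j - 1, i - 1
            continue
        if state == "D":
            choice = pick([fM[j - 1, i] + lt["md"][j - 1], fD[j - 1, i] + lt["dd"][j - 1]])
            state = ("M", "D")[choice]
            j = j - 1
            continue
        # insert state I_j: residue i-1 was emitted here; step left within run
        choice = pick([fM[j, i - 1] + lt["mi"][j], fI[j, i - 1] + lt["ii"][j]])
        state = ("M", "I")[choice]
        i = i - 1
    return row


def _path_logprob_given_params(
    codes: np.ndarray,
    row: np.ndarray,
    L: int,
    log_theta: np.ndarray,
    log_bg: np.ndarray,
    lt: dict[str, np.ndarray],
) -> float:
    """Log joint probability of (path, residues) under fixed parameters."""
    tmp = AlignmentState(row[None, :], np.array([L]))
    total = 0.0
    pos = 0
    prev = "M"
    for j, kind, nins in tmp._events(0):
        at = j - 1
        if nins > 0:
            total += lt["mi"][at] + (nins - 1) * lt["ii"][at] + lt["im"][at]
            for s in range(pos, pos + nins):
                if codes[s] >= 0:
                    total += log_bg[codes[s]]
            pos += nins
            src = "I"
        else:
            src = prev
        if kind == "M":
            if nins == 0:
                total += lt["mm"][at] if src == "M" else lt["dm"][at]
            if j <= tmp.num_columns:  # not the End pseudo-column
                if codes[pos] >= 0:
                    total += log_theta[j - 1, codes[pos]]
                pos += 1
            prev = "M"
        else:
            total += lt["md"][at] if src == "M" else lt["dd"][at]
            prev = "D"
    return float(total)


def _collapsed_path_logprob(
    codes: np.ndarray,
    row: np.ndarray,
    L: int,
    counts_minus: np.ndarray,
    tc_minus: np.ndarray,
    prior: DirichletMixture,
    tpriors: TransitionPriors,
    log_bg: np.ndarray,
    weight: float = 1.0,
    transition_scale: float = 1.0,
) -> float:
    """Unnormalised collapsed conditional of one sequence's path.

    Column-marginal ratios plus the background term for inserts plus the
    transition Gamma-ratio increment, all relative to the leave-one-out
    state (constant offsets cancel in Metropolis ratios).
    """
    tmp = AlignmentState(row[None, :], np.array([L]))
    mask = row >= 0
    cols = np.nonzero(mask)[0]
    ccodes = codes[row[mask]]
    ok = ccodes >= 0
    cols, ccodes = cols[ok], ccodes[ok]
    if cols.size:
        base = column_log_marginals(counts_minus[cols], prior)
        plus = counts_minus[cols].copy()
        plus[np.arange(cols.size), ccodes] += weight
        total = float((column_log_marginals(plus, prior) - base).sum())
    else:
        total = 0.0
    matched = set(int(p) for p in row[mask])
    for s in range(L):
        if s not in matched and codes[s] >= 0:
            total += weight * float(log_bg[codes[s]])
    tc_k = tmp.seq_transition_counts(0)
    total += transition_scale * (
        log_transition_prior(TransitionCounts(tc_minus + tc_k, tpriors))
        - log_transition_prior(TransitionCounts(tc_minus, tpriors))
    )
    return total


def _metropolized_path_update(
    codes: np.ndarray,
    cur_row: np.ndarray,
    L: int,
    counts_minus: np.ndarray,
    tc_minus: np.ndarray,
    prior: DirichletMixture,
    tpriors: TransitionPriors,
    log_bg: np.ndarray,
    rng: np.random.Generator,
    transition_scale: float = 1.0,
) -> np.ndarray:
    """One exact collapsed-posterior update of a single sequence's path.

    Emission/transition parameters are drawn from their leave-one-out
    posteriors, a candidate path is sampled from the resulting HMM by
    forward filtering / stochastic traceback, and the candidate is accepted
    by Metropolis-Hastings with the exact collapsed ratio.  Because the
    proposal closely tracks the collapsed conditional, acceptance is high,
    and detailed balance w.r.t. exp(log_joint) holds exactly.

    ``transition_scale`` < 1 tempers the gap-penalty (transition) part of
    both the proposal and the target — the annealing handle used early in
    alignment sampling to let column coherence condense; at 1.0 the move
    targets the untempered posterior.
    """
    theta = _sample_column_thetas(np.maximum(counts_minus, 0.0), prior, rng)
    lt = _sample_transition_probs(TransitionCounts(tc_minus, tpriors), rng)
    if transition_scale != 1.0:
        lt = {k: transition_scale * v for k, v in lt.items()}
    log_theta = np.log(theta)
    fM, fD, fI, logZ = _forward(codes, log_theta, log_bg, lt)
    prop_row = _traceback(fM, fD, fI, lt, L, rng)
    if np.array_equal(prop_row, cur_row):
        return prop_row
    lq_prop = _path_logprob_given_params(codes, prop_row, L, log_theta, log_bg, lt) - logZ
    lq_cur = _path_logprob_given_params(codes, cur_row, L, log_theta, log_bg, lt) - logZ
    lpi_prop = _collapsed_path_logprob(
        codes, prop_row, L, counts_minus, tc_minus, prior, tpriors, log_bg,
        transition_scale=transition_scale,
    )
    lpi_cur = _collapsed_path_logprob(
        codes, cur_row, L, counts_minus, tc_minus, prior, tpriors, log_bg,
        transition_scale=transition_scale,
    )
    log_acc = (lpi_prop - lpi_cur) + (lq_cur - lq_prop)
    if log_acc >= 0 or rng.random() < np.exp(log_acc):
        return prop_row
    return cur_row


def resample_sequence(
    seqs: SequenceSet,
    aln: AlignmentState,
    k: int,
    rng: np.random.Generator,
    prior: DirichletMixture | None = None,
    tpriors: TransitionPriors | None = None,
    background: np.ndarray | None = None,
) -> AlignmentState:
    """Update sequence k's path, leaving exp(log_joint) invariant.

    A Metropolised draw: the proposal comes from an HMM whose parameters
    are sampled from their leave-one-out posteriors, and acceptance uses
    the exact collapsed ratio, so the move satisfies detailed balance with
    respect to the integrated alignment posterior (unit weights).
    """
    if rng is None:
        raise ValueError("an explicit numpy Generator is required")
    prior = prior or background_prior()
    tpriors = tpriors or TransitionPriors()
    bg = BACKGROUND if background is None else background
    K = len(seqs)
    if K < 2:
        raise ValueError("need at least two sequences to resample one")

    others = SequenceSet([r for i, r in enumerate(seqs) if i != k])
    sub = AlignmentState(
        np.delete(aln.match_map, k, axis=0), np.delete(aln.seq_lengths, k)
    )
    counts = count_all_columns(others, sub)
    tc_minus = aln.transition_counts(tpriors, exclude=k).counts
    codes = seqs[k].codes
    row = _metropolized_path_update(
        codes,
        aln.match_map[k].copy(),
        codes.shape[0],
        counts,
        tc_minus,
        prior,
        tpriors,
        np.log(bg),
        rng,
    )
    new = aln.copy()
    new.match_map[k] = row
    return new


def viterbi_align(
    codes: np.ndarray,
    counts: np.ndarray,
    tc: TransitionCounts,
    prior: DirichletMixture | None = None,
    background: np.ndarray | None = None,
) -> np.ndarray:
    """Deterministic best-path alignment of one sequence to a profile.

    The profile is summarised by posterior-mean emissions (from the column
    counts) and posterior-mean transitions; used e.g. to re-thread purged
    near-duplicates after subgroup refinement.
    """
    prior = prior or background_prior()
    bg = BACKGROUND if background is None else background
    theta = posterior_mean_emissions(counts, prior)
    lt = posterior_mean_log_transitions(tc)
    fM, fD, fI, _ = _forward(codes, np.log(theta), np.log(bg), lt, op="max")
    return _traceback(fM, fD, fI, lt, codes.shape[0], None, greedy=True)


# ----------------------------------------------------------------------
# Architecture moves (MDL-gated match-column add/delete)
# ----------------------------------------------------------------------

def _insert_runs(aln: AlignmentState, lengths: np.ndarray) -> list[np.ndarray]:
    """Per slot j = 0..w, array (K,) of insert-run starts and lengths.

    Returns list of (start, length) pairs per slot as a (K, 2) array; start
    is the sequence position of the first residue in the run at I_j.
    """
    K, w = aln.match_map.shape
    out = []
    prev_end = np.zeros(K, dtype=np.int64)  # pos after last consumed residue
    maps = aln.match_map
    # compute, per sequence, consumed position after each column
    for j in range(w + 1):
        if j < w:
            nxt = maps[:, j]
        else:
            nxt = lengths
        run = np.zeros((K, 2), dtype=np.int64)
        if j < w:
            has = nxt >= 0
            run[:, 0] = prev_end
            run[has, 1] = nxt[has] - prev_end[has]
            prev_end = np.where(has, nxt + 1, prev_end)
        else:
            run[:, 0] = prev_end
            run[:, 1] = lengths - prev_end
        out.append(run)
    return out


def _threaded_candidate(
    run: np.ndarray, o: int, from_end: bool, K: int
) -> np.ndarray:
    """Thread one candidate column from an insert-run slot.

    Each sequence with residues in the run contributes the residue at
    offset ``o`` from the run's start (or end); shorter runs clamp to their
    nearest residue so the split stays path-legal.  Sequences with empty
    runs take a deletion.
    """
    has = run[:, 1] > 0
    offs = np.minimum(o, run[:, 1] - 1)
    newcol = np.full(K, -1, dtype=np.int64)
    if from_end:
        newcol[has] = run[has, 0] + run[has, 1] - 1 - offs[has]
    else:
        newcol[has] = run[has, 0] + offs[has]
    return newcol


def adjust_architecture(
    seqs: SequenceSet,
    aln: AlignmentState,
    prior: DirichletMixture | None = None,
    null: np.ndarray | None = None,
    path_bits_per_seq: float = 0.5,
    max_rounds: int = 4,
    max_offset: int = 12,
    max_adds: int = 60,
) -> AlignmentState:
    """Greedy MDL adjustment of the match-column architecture.

    Deletion pass: a match column whose BILD score fails to pay the path
    cost of its participating (weighted) sequences is demoted to inserts.
    Addition pass: candidate columns are threaded out of insert runs at
    offsets from either run end (so a conserved position up to
    ``max_offset`` residues past an existing anchor column can nucleate),
    and the best-gain candidate is added while its BILD score exceeds the
    path cost.  Gibbs path sweeps between calls refine the threading.
    """
    from .mdl import architecture_gain_bits

    prior = prior or background_prior()
    null = BACKGROUND if null is None else null
    aln = aln.copy()
    weights = seqs.weights
    codes = [r.codes for r in seqs]
    K = len(seqs)

    def col_counts(newcol: np.ndarray) -> np.ndarray:
        cc = np.zeros(N_AA)
        for k in np.nonzero(newcol >= 0)[0]:
            code = codes[k][newcol[k]]
            if code >= 0:
                cc[code] += weights[k]
        return cc

    for _ in range(max_rounds):
        changed = False
        # ---- deletions
        counts = count_all_columns(seqs, aln)
        j = 0
        while j < aln.num_columns:
            cj = counts[j]
            gain = architecture_gain_bits(
                bild_score(cj, prior, null), path_bits_per_seq * cj.sum()
            )
            if gain < 0 and aln.num_columns > 1:
                cand = AlignmentState(
                    np.delete(aln.match_map, j, axis=1), aln.seq_lengths
                )
                try:
                    cand.check()
                except Exception:
                    j += 1
                    continue
                aln = cand
                counts = np.delete(counts, j, axis=0)
                changed = True
                continue
            j += 1
        # ---- additions (repeat best-first until nothing pays)
        for _add in range(max_adds):
            runs = _insert_runs(aln, aln.seq_lengths)
            best = None
            for j, run in enumerate(runs):
                max_len = int(run[:, 1].max(initial=0))
                if max_len == 0:
                    continue
                for from_end in (False, True):
                    for o in range(min(max_len, max_offset)):
                        newcol = _threaded_candidate(run, o, from_end, K)
                        cc = col_counts(newcol)
                        gain = architecture_gain_bits(
                            bild_score(cc, prior, null),
                            path_bits_per_seq * cc.sum(),
                        )
                        if gain > 0 and (best is None or gain > best[0]):
                            best = (gain, j, newcol)
            if best is None:
                break
            _, j, newcol = best
            mm = np.insert(aln.match_map, j, newcol, axis=1)
            cand = AlignmentState(mm, aln.seq_lengths)
            try:
                cand.check()
            except Exception:
                break
            aln = cand
            changed = True
        if not changed:
            break
    return aln


def _seq_col_contrib(rec, row: np.ndarray):
    """(columns, codes) of sequence's weighted match-column contributions."""
    mask = row >= 0
    cols = np.nonzero(mask)[0]
    codes = rec.codes[row[mask]]
    ok = codes >= 0
    return cols[ok], codes[ok]


def gibbs_sweep(
    seqs: SequenceSet,
    aln: AlignmentState,
    rng: np.random.Generator,
    prior: DirichletMixture | None = None,
    tpriors: TransitionPriors | None = None,
    order: np.ndarray | None = None,
    n_sweeps: int = 1,
    transition_scale: float | list | None = None,
) -> AlignmentState:
    """Full sweeps of single-sequence resampling with incremental counts.

    Maintains the column and transition tallies across moves so a sweep is
    O(K (w + L)) instead of O(K^2 w); each per-sequence step draws the same
    collapsed conditional as :func:`resample_sequence`.

    ``transition_scale`` may be a scalar or a per-sweep schedule (length
    ``n_sweeps``) tempering the gap penalties (see
    :func:`_metropolized_path_update`).
    """
    prior = prior or background_prior()
    tpriors = tpriors or TransitionPriors()
    log_bg = np.log(BACKGROUND)
    K = len(seqs)
    aln = aln.copy()
    weights = seqs.weights
    counts = count_all_columns(seqs, aln)
    tc_rows = np.stack([aln.seq_transition_counts(k) for k in range(K)])
    tc_total = tc_rows.sum(axis=0)
    if transition_scale is None:
        schedule = [1.0] * n_sweeps
    elif np.isscalar(transition_scale):
        schedule = [float(transition_scale)] * n_sweeps
    else:
        schedule = list(transition_scale)
        assert len(schedule) == n_sweeps
    for sweep_i in range(n_sweeps):
        lam = schedule[sweep_i]
        scan = rng.permutation(K) if order is None else order
        for k in scan:
            k = int(k)
            rec = seqs[k]
            cols, codes = _seq_col_contrib(rec, aln.match_map[k])
            counts[cols, codes] -= weights[k]
            tc_minus = tc_total - tc_rows[k]
            ccodes = rec.codes
            aln.match_map[k] = _metropolized_path_update(
                ccodes,
                aln.match_map[k].copy(),
                ccodes.shape[0],
                np.maximum(counts, 0.0),
                tc_minus,
                prior,
                tpriors,
                log_bg,
                rng,
                transition_scale=lam,
            )
            cols, codes = _seq_col_contrib(rec, aln.match_map[k])
            counts[cols, codes] += weights[k]
            new_tc = aln.seq_transition_counts(k)
            tc_total += new_tc - tc_rows[k]
            tc_rows[k] = new_tc
    return aln
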