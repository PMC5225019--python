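"""Minimum-description-length accounting for hierarchical HMM selection.

The model side of the two-part code is itemised as: the number of nodes in
the hierarchy (geometric prior), the rooted unlabeled tree shape (uniform
over the Catalan count), the discriminating columns and residue sets per
node, the node assignment of each (effectively independent) sequence, and
the extra match states with the sequence paths through them.  The data
side is the negative base-2 log of the integrated alignment likelihood, so
model selection and posterior sampling share one currency (bits).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass
class DLLedger:
    """Itemised description lengths in bits."""

    node_count_bits: float = 0.0
    tree_bits: float = 0.0
    pattern_bits: float = 0.0
    assignment_bits: float = 0.0
    path_bits: float = 0.0
    data_bits: float = 0.0
    extras: dict = field(default_factory=dict)

    @property
    def total(self) -> float:
        return (
            self.node_count_bits
            + self.tree_bits
            + self.pattern_bits
            + self.assignment_bits
            + self.path_bits
            + self.data_bits
        )

    @property
    def model_bits(self) -> float:
        """Model cost excluding the data term."""
        return self.total - self.data_bits

    def items(self):
        return {
            "node_count_bits": self.node_count_bits,
            "tree_bits": self.tree_bits,
            "pattern_bits": self.pattern_bits,
            "assignment_bits": self.assignment_bits,
            "path_bits": self.path_bits,
            "data_bits": self.data_bits,
            "total": self.total,
        }.items()


def catalan(n: int) -> int:
    """Exact Catalan number C_n = (2n)! / ((n+1)! n!).

    C_n counts the rooted, unlabeled (ordered) trees on n+1 nodes; in the
    bit-accounting below ``n`` nodes admit C_n distinct hierarchy shapes.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return math.comb(2 * n, n) // (n + 1)


def tree_dl_bits(n: int, exact: bool = False) -> float:
    """Bits to name one rooted unlabeled tree on n nodes.

    Uniform prior over the C_n shapes.  The default uses the asymptotic
    C_n ~ 4^n / (n^{3/2} sqrt(pi)), i.e. 2n - 1.5 log2 n - 0.6 bits; with
    ``exact=True`` returns log2 C_n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if exact:
        return math.log2(catalan(n))
    return 2.0 * n - 1.5 * math.log2(n) - 0.6


def node_count_dl_bits(n: int, x: float = 0.99) -> float:
    """Bits to transmit the node count n under a geometric prior.

    P(n) = (1 - x) x^(n-1), so DL(n) = -log2(1-x) - (n-1) log2(x).  With x
    near one the choice of n is nearly free, leaving model selection to the
    data-fit terms.
    """
    if not (0 < x < 1):
        raise ValueError("geometric factor x must be in (0, 1)")
    if n < 1:
        raise ValueError("n must be >= 1")
    return -math.log2(1.0 - x) - (n - 1) * math.log2(x)


def pattern_dl_bits(c: int, t: float = 10.0, p: float = 0.1) -> float:
    """Bits per node to describe which of c columns are discriminating.

    Each column is discriminating with prior p, and a discriminating column
    names one of ~t allowed residue sets: c [ -(1-p) log2(1-p) - p log2(p/t) ].
    """
    if c < 0:
        raise ValueError("c must be >= 0")
    if t < 1:
        raise ValueError("t must be >= 1")
    if not (0 < p < 1):
        raise ValueError("pattern prior p must be in (0, 1)")
    if c == 0:
        return 0.0
    return c * (-(1 - p) * math.log2(1 - p) - p * math.log2(p / t))


def assignment_dl_bits(n: int, s_eff: float, node_priors=None) -> float:
    """Bits to assign s_eff effectively independent sequences to n nodes.

    Uniform node prior: s_eff * log2(n).  ``node_priors`` may instead give a
    sequence of per-sequence prior probabilities (one per sequence, the
    prior of its assigned node); the cost is then sum(-log2 prior).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if s_eff < 0:
        raise ValueError("s_eff must be >= 0")
    if node_priors is not None:
        return float(sum(-math.log2(q) for q in node_priors))
    return s_eff * math.log2(n)


def total_model_dl(
    n: int,
    s_eff: float,
    c: int,
    t: float = 10.0,
    p: float = 0.1,
    x: float = 0.99,
    path_bits: float = 0.0,
    data_bits: float = 0.0,
) -> DLLedger:
    """Assemble the itemised ledger for one concrete hierarchical model."""
    return DLLedger(
        node_count_bits=node_count_dl_bits(n, x),
        tree_bits=tree_dl_bits(n) if n > 1 else tree_dl_bits(n, exact=True),
        pattern_bits=n * pattern_dl_bits(c, t, p),
        assignment_bits=assignment_dl_bits(n, s_eff),
        path_bits=path_bits,
        data_bits=data_bits,
    )


def architecture_gain_bits(bild_bits: float, path_cost_bits: float) -> float:
    """MDL accept/reject margin for adding a match state.

    Aligning a new column pays ``path_cost_bits`` (describing each affected
    sequence's extra path choice) and earns the column's Bayesian integral
    log-odds score; the column is admissible iff the margin is positive.
    """
    if path_cost_bits < 0:
        raise ValueError("path cost must be >= 0")
    return bild_bits - path_cost_bits
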