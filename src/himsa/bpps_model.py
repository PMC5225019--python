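"""Bayesian partitioning with pattern selection: hierarchy, patterns, and
foreground/background contrast likelihood.

A hierarchy is a rooted tree whose nodes carry disjoint sequence sets; one
*contrast alignment* exists per node, pairing the node's subtree (the
foreground) against the remainder of the parent's subtree (the background).
The root's background is unrelated protein, modelled by standard amino-acid
frequencies.  A special *reject node* (a child of the root that carries no
pattern and participates in no contrast) absorbs unalignable sequences.

Each node may carry a discriminating pattern: a small set of alignment
columns, each with a residue set drawn from a fixed catalog of biologically
sensible groupings, required to contain the foreground consensus residue.
Foreground emissions at a pattern column mix a uniform distribution over
the residue set with a fraction ``alpha`` of background contamination.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .alphabet import AA, AA_INDEX, BACKGROUND, N_AA

LOG2 = np.log(2.0)


# ----------------------------------------------------------------------
# Hierarchy
# ----------------------------------------------------------------------

class HierarchyError(ValueError):
    pass


@dataclass
class Hierarchy:
    """Rooted tree with per-node sequence assignments and a reject node."""

    parent: dict = field(default_factory=dict)  # node -> parent (root -> None)
    root: int = 0
    reject: int = 1
    height_limit: int = 5
    assignment: np.ndarray | None = None  # per-sequence node id

    @classmethod
    def trivial(cls, n_sequences: int, height_limit: int = 5) -> "Hierarchy":
        """Root + reject, all sequences at the root."""
        h = cls(
            parent={0: None, 1: 0},
            root=0,
            reject=1,
            height_limit=height_limit,
            assignment=np.zeros(n_sequences, dtype=np.int64),
        )
        return h

    # -- structure -----------------------------------------------------
    @property
    def nodes(self) -> list[int]:
        return sorted(self.parent)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def children(self, n: int) -> list[int]:
        return sorted(c for c, p in self.parent.items() if p == n)

    def subtree(self, n: int) -> list[int]:
        """Descendants of n including n; the reject node never appears in
        any subtree other than its own."""
        out = [n]
        stack = [n]
        while stack:
            cur = stack.pop()
            for c in self.children(cur):
                if c == self.reject and n != self.reject:
                    continue
                out.append(c)
                stack.append(c)
        return out if n != self.reject else [self.reject]

    def depth(self, n: int) -> int:
        d = 0
        while self.parent[n] is not None:
            n = self.parent[n]
            d += 1
        return d

    def height(self) -> int:
        return max(self.depth(n) for n in self.parent)

    def lineage(self, n: int) -> list[int]:
        """Root-first path of nodes from the root down to n."""
        path = [n]
        while self.parent[path[-1]] is not None:
            path.append(self.parent[path[-1]])
        return path[::-1]

    def check(self) -> None:
        roots = [n for n, p in self.parent.items() if p is None]
        if roots != [self.root]:
            raise HierarchyError("exactly one root required")
        if self.parent.get(self.reject) != self.root:
            raise HierarchyError("reject node must be a child of the root")
        if self.height() > self.height_limit:
            raise HierarchyError("tree exceeds the height limit")
        if self.assignment is not None:
            known = set(self.parent)
            if not set(np.unique(self.assignment)) <= known:
                raise HierarchyError("sequence assigned to unknown node")

    def copy(self) -> "Hierarchy":
        return Hierarchy(
            parent=dict(self.parent),
            root=self.root,
            reject=self.reject,
            height_limit=self.height_limit,
            assignment=None if self.assignment is None else self.assignment.copy(),
        )

    def new_node_id(self) -> int:
        return max(self.parent) + 1

    def node_sequences(self, n: int) -> np.ndarray:
        """Indices of sequences assigned to node n itself."""
        return np.nonzero(self.assignment == n)[0]

    def subtree_sequences(self, n: int) -> np.ndarray:
        members = np.isin(self.assignment, self.subtree(n))
        return np.nonzero(members)[0]

    def major_subgroups(self) -> list[int]:
        """Subtrees directly attached to the root (excluding the reject)."""
        return [c for c in self.children(self.root) if c != self.reject]

    # -- serialisation -------------------------------------------------
    def to_newick(self) -> str:
        def render(n: int) -> str:
            kids = self.children(n)
            if not kids:
                return str(n)
            return "(" + ",".join(render(c) for c in kids) + ")" + str(n)

        return render(self.root) + ";"

    @classmethod
    def from_newick(
        cls, text: str, reject: int | None = None, height_limit: int = 5
    ) -> "Hierarchy":
        import dendropy

        tree = dendropy.Tree.get(data=text, schema="newick")
        parent: dict[int, int | None] = {}

        def label_of(nd) -> int:
            lab = nd.taxon.label if nd.taxon else nd.label
            return int(lab)

        for nd in tree.preorder_node_iter():
            lab = label_of(nd)
            parent[lab] = None if nd.parent_node is None else label_of(nd.parent_node)
        root = [n for n, p in parent.items() if p is None][0]
        if reject is None:
            kids = sorted(c for c, p in parent.items() if p == root)
            reject = kids[0] if kids else root
        return cls(parent=parent, root=root, reject=reject, height_limit=height_limit)


# ----------------------------------------------------------------------
# Residue-set catalog
# ----------------------------------------------------------------------

_GROUPS = [
    "DE", "KR", "GA", "ST", "NQ",       # classic biochemical pairs
    "FY", "FW", "YW", "FYW",            # aromatic
    "IL", "IV", "IM", "LV", "LM", "VM", "ILVM",  # aliphatic
]


def allowed_residue_sets(decay: float = 0.4) -> list[tuple[frozenset, float]]:
    """Catalog of permitted pattern residue sets with priors.

    Singletons plus standard biochemical groupings; prior proportional to
    decay^(|set|-1), normalised over the catalog.
    """
    sets = [frozenset({AA_INDEX[a]}) for a in AA]
    sets += [frozenset(AA_INDEX[ch] for ch in g) for g in _GROUPS]
    raw = np.array([decay ** (len(s) - 1) for s in sets])
    pri = raw / raw.sum()
    return list(zip(sets, pri.tolist()))


def sets_containing(catalog, residue: int):
    return [(s, p) for s, p in catalog if residue in s]


@dataclass
class PatternSet:
    """Per-node discriminating columns and residue sets."""

    patterns: dict = field(default_factory=dict)  # node -> {col: frozenset}
    max_patterns: int = 25

    def columns(self, node: int) -> dict:
        return self.patterns.get(node, {})

    def set_node(self, node: int, cols: dict) -> None:
        if len(cols) > self.max_patterns:
            raise ValueError(
                f"node {node}: {len(cols)} pattern columns exceed the cap "
                f"{self.max_patterns}"
            )
        self.patterns[node] = dict(cols)

    def copy(self) -> "PatternSet":
        return PatternSet(
            {n: dict(c) for n, c in self.patterns.items()}, self.max_patterns
        )

    def n_columns(self, node: int) -> int:
        return len(self.patterns.get(node, {}))


# ----------------------------------------------------------------------
# Compositions and mixing
# ----------------------------------------------------------------------

def posterior_mean_theta(counts: np.ndarray, pseudocount_mass: float = 1.0) -> np.ndarray:
    """Posterior-mean residue frequencies from (weighted) counts with a
    background-proportional Dirichlet prior.  Works on (w, 20) or (20,)."""
    counts = np.asarray(counts, dtype=float)
    prior = BACKGROUND * pseudocount_mass
    if counts.ndim == 1:
        return (counts + prior) / (counts.sum() + pseudocount_mass)
    return (counts + prior[None, :]) / (
        counts.sum(axis=1, keepdims=True) + pseudocount_mass
    )


def pattern_set_distribution(residues: frozenset) -> np.ndarray:
    """Uniform distribution over the residues of a pattern set."""
    v = np.zeros(N_AA)
    for r in residues:
        v[r] = 1.0
    return v / v.sum()


def mixed_foreground(
    residues: frozenset,
    theta_bg: np.ndarray,
    alpha: float,
    mix_toward_background: bool = False,
) -> np.ndarray:
    """Foreground emission distribution at a pattern column.

    Default: (1-alpha) * uniform(set) + alpha * theta_bg, reading alpha as
    the fraction of background contamination among foreground sequences.
    ``mix_toward_background=True`` gives the transposed reading
    (1-alpha) * theta_bg + alpha * uniform(set).
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    u = pattern_set_distribution(residues)
    if mix_toward_background:
        return (1 - alpha) * theta_bg + alpha * u
    return (1 - alpha) * u + alpha * theta_bg


# ----------------------------------------------------------------------
# Contrast alignments
# ----------------------------------------------------------------------

@dataclass
class ContrastAlignment:
    """Foreground/background partition at one node, with pattern columns."""

    node: int
    foreground: np.ndarray  # sequence indices
    background: np.ndarray  # sequence indices (empty at the root)
    pattern_columns: dict  # col -> frozenset
    theta_bg: np.ndarray  # (w, 20) background composition
    divergence: dict  # col -> bar height (semi-log scale)
    alpha: float = 0.0


def _column_counts(X: np.ndarray, weights: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """(w, 20) weighted counts over the selected rows of a coded matrix."""
    w = X.shape[1]
    counts = np.zeros((w, N_AA))
    if rows.size == 0:
        return counts
    sub = X[rows]
    wt = weights[rows]
    for j in range(w):
        col = sub[:, j]
        ok = col >= 0
        np.add.at(counts[j], col[ok], wt[ok])
    return counts


def build_contrast_alignment(
    H: Hierarchy,
    node: int,
    X: np.ndarray,
    weights: np.ndarray,
    patterns: PatternSet,
    alpha: float = 0.05,
    mix_toward_background: bool = False,
) -> ContrastAlignment:
    """Construct the contrast alignment for one node.

    Foreground: sequences of the node's subtree.  Background: the rest of
    the parent's subtree; for the root the background is unrelated protein
    (standard frequencies).  The divergence bar at a pattern column is
    log10(1 + lambda) with lambda the per-column foreground log-ratio term
    in nats.
    """
    if node == H.reject:
        raise HierarchyError("the reject node has no contrast alignment")
    fg = H.subtree_sequences(node)
    if node == H.root:
        bg = np.array([], dtype=np.int64)
        theta_bg = np.tile(BACKGROUND, (X.shape[1], 1))
    else:
        par = H.parent[node]
        fg_set = set(fg.tolist())
        bg = np.array(
            [i for i in H.subtree_sequences(par) if i not in fg_set], dtype=np.int64
        )
        theta_bg = posterior_mean_theta(_column_counts(X, weights, bg))
    cols = patterns.columns(node)
    divergence = {}
    for j, rset in cols.items():
        fmix = mixed_foreground(rset, theta_bg[j], alpha, mix_toward_background)
        with np.errstate(divide="ignore"):
            ratio = np.log(np.maximum(fmix, 1e-300)) - np.log(theta_bg[j])
        lam = 0.0
        for i in fg:
            r = X[i, j]
            if r >= 0:
                lam += weights[i] * ratio[r]
        divergence[j] = float(np.log10(1.0 + max(lam, 0.0)))
    return ContrastAlignment(
        node=node,
        foreground=fg,
        background=bg,
        pattern_columns=dict(cols),
        theta_bg=theta_bg,
        divergence=divergence,
        alpha=alpha,
    )


# ----------------------------------------------------------------------
# Priors and likelihood
# ----------------------------------------------------------------------

def node_assignment_priors(H: Hierarchy) -> dict:
    """Prior over node assignment: root 0.25, reject 0.70, the rest share
    0.05 equally; renormalised when only root and reject exist."""
    n = H.n_nodes
    if n < 2:
        raise HierarchyError("hierarchy must contain a root and a reject node")
    if n == 2:
        return {H.root: 0.25 / 0.95, H.reject: 0.70 / 0.95}
    others = [x for x in H.parent if x not in (H.root, H.reject)]
    pri = {H.root: 0.25, H.reject: 0.70}
    for x in others:
        pri[x] = 0.05 / len(others)
    return pri


def log_likelihood_bpps(
    X: np.ndarray,
    H: Hierarchy,
    patterns: PatternSet,
    alpha: dict,
    weights: np.ndarray | None = None,
    mix_toward_background: bool = False,
    theta: dict | None = None,
) -> float:
    """The contrast-likelihood of the data (natural log).

    For every node's contrast alignment: a background composition term over
    foreground plus background sequences at every column, and, at pattern
    columns only, the foreground log-ratio correction.  Columns are treated
    as statistically independent.  ``theta`` may supply precomputed (w, 20)
    background compositions per node; otherwise posterior means are used.
    """
    H.check()
    K, w = X.shape
    weights = np.ones(K) if weights is None else weights
    total = 0.0
    for node in H.parent:
        if node == H.reject:
            continue
        a = float(alpha.get(node, 0.0))
        if not (0.0 <= a <= 1.0):
            raise ValueError(f"alpha for node {node} outside [0, 1]")
        ca = build_contrast_alignment(
            H, node, X, weights, patterns, a, mix_toward_background
        )
        th = ca.theta_bg if theta is None else theta[node]
        log_th = np.log(th)
        rows = np.concatenate([ca.foreground, ca.background])
        for i in rows:
            xs = X[i]
            ok = xs >= 0
            total += weights[i] * float(log_th[ok, xs[ok]].sum())
        for j, rset in ca.pattern_columns.items():
            fmix = mixed_foreground(rset, th[j], a, mix_toward_background)
            with np.errstate(divide="ignore"):
                ratio = np.log(np.maximum(fmix, 1e-300)) - log_th[j]
            for i in ca.foreground:
                r = X[i, j]
                if r >= 0:
                    total += weights[i] * float(ratio[r])
    return total


def pattern_gain_bits(
    X: np.ndarray,
    weights: np.ndarray,
    fg: np.ndarray,
    theta_bg_j: np.ndarray,
    j: int,
    rset: frozenset,
    alpha: float,
    mix_toward_background: bool = False,
) -> float:
    """Foreground log2-ratio gain of declaring column j discriminating."""
    fmix = mixed_foreground(rset, theta_bg_j, alpha, mix_toward_background)
    ratio = (np.log(fmix) - np.log(theta_bg_j)) / LOG2
    col = X[fg, j]
    ok = col >= 0
    if not np.any(ok):
        return 0.0
    return float((weights[fg][ok] * ratio[col[ok]]).sum())
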