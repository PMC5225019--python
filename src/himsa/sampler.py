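"""MCMC orchestration over hierarchies with simulated annealing.

The sampler alternates (in macro-cycles) between structural tree moves
(attach/remove leaves, insert internal nodes, move subtrees), per-node
pattern sampling, contamination updates and sequence reassignment, all
targeting the MDL-penalised posterior

    objective(bits) = sum_nodes foreground pattern log2-ratio gains
                      + sum_seq w_i log2 prior(node_i)
                      - node-count bits - tree bits - pattern bits.

The global background term of the contrast likelihood is invariant across
the states being compared and is omitted.  Structural proposals are
accepted by Metropolis with geometric cooling; the best-visited state is
returned after a greedy (zero-temperature) finish.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alphabet import BACKGROUND, N_AA
from .bpps_model import (
    Hierarchy,
    HierarchyError,
    PatternSet,
    _column_counts,
    allowed_residue_sets,
    mixed_foreground,
    posterior_mean_theta,
    sets_containing,
)
from .config import SamplerConfig
from .mdl import DLLedger, node_count_dl_bits, tree_dl_bits
from .msa_model import (
    adjust_architecture,
    background_prior,
    data_dl_bits,
    gibbs_sweep,
)
from .seqio import SequenceSet, compute_weights
from .state import AlignmentState

LOG2 = math.log(2.0)


# ----------------------------------------------------------------------
# Working state
# ----------------------------------------------------------------------

@dataclass
class BppsState:
    """Everything the hierarchy sampler mutates."""

    X: np.ndarray  # (K, w) residue codes at match columns, -1 = gap
    weights: np.ndarray
    H: Hierarchy
    patterns: PatternSet
    alpha: dict = field(default_factory=dict)

    def copy(self) -> "BppsState":
        return BppsState(
            self.X, self.weights, self.H.copy(), self.patterns.copy(), dict(self.alpha)
        )


def node_priors(H: Hierarchy, cfg: SamplerConfig) -> dict:
    n = H.n_nodes
    if n == 2:
        z = cfg.root_prior + cfg.reject_prior
        return {H.root: cfg.root_prior / z, H.reject: cfg.reject_prior / z}
    others = [x for x in H.parent if x not in (H.root, H.reject)]
    pri = {H.root: cfg.root_prior, H.reject: cfg.reject_prior}
    for x in others:
        pri[x] = cfg.other_prior_total / len(others)
    return pri


def background_thetas(state: BppsState, nodes=None) -> dict:
    """Per-node contrast compositions.

    For each pattern-capable node, returns (theta_bg, theta_pool): the
    posterior-mean composition of the background partition (the rest of the
    parent's subtree) and of the pooled parent subtree.  The root's
    background and pool are the fixed standard frequencies (its contrast is
    against unrelated protein).
    """
    w = state.X.shape[1]
    out = {}
    todo = state.H.parent if nodes is None else nodes
    flat = np.tile(BACKGROUND, (w, 1))
    for node in todo:
        if node == state.H.reject:
            continue
        if node == state.H.root:
            out[node] = (flat, flat)
            continue
        par = state.H.parent[node]
        fg = set(state.H.subtree_sequences(node).tolist())
        pool_rows = state.H.subtree_sequences(par)
        bg = np.array([i for i in pool_rows if i not in fg], dtype=np.int64)
        theta_bg = posterior_mean_theta(_column_counts(state.X, state.weights, bg))
        theta_pool = posterior_mean_theta(
            _column_counts(state.X, state.weights, pool_rows)
        )
        out[node] = (theta_bg, theta_pool)
    return out


# ----------------------------------------------------------------------
# Pattern machinery
# ----------------------------------------------------------------------

def _two_sample_gain(
    counts_fg: np.ndarray,
    counts_bg: np.ndarray,
    theta_bg_j: np.ndarray,
    theta_pool_j: np.ndarray,
    rset: frozenset,
    alpha: float,
    integrated: bool = True,
) -> float:
    """Two-sample contrast gain (bits) of one pattern column.

    The foreground is scored under the alpha-contaminated pattern-set
    distribution.  With ``integrated=True`` (used for node worth, move
    acceptance and the objective) the split of the pooled counts into
    foreground plus background is scored by the ratio of integrated
    Dirichlet-multinomial marginals marg(bg)/marg(fg+bg): splitting
    identical compositions then pays the prior twice, so a null column has
    negative expected gain and the criterion is self-penalising.  With
    ``integrated=False`` (the fast plug-in form used only to score
    sampling proposals) the posterior-mean compositions stand in for the
    marginals.  At the root the background is the fixed standard-frequency
    model either way.
    """
    fmix = mixed_foreground(rset, theta_bg_j, alpha)
    with np.errstate(divide="ignore"):
        lfmix = np.where(counts_fg > 0, np.log(np.maximum(fmix, 1e-300)), 0.0)
    g = float(counts_fg @ lfmix)
    if counts_bg is None:
        g -= float(counts_fg @ np.log(BACKGROUND))
    elif integrated:
        from .msa_model import log_column_marginal

        prior = _gain_prior()
        g += log_column_marginal(counts_bg, prior)
        g -= log_column_marginal(counts_fg + counts_bg, prior)
    else:
        lp = np.log(theta_pool_j)
        g += float(counts_bg @ (np.log(theta_bg_j) - lp))
        g -= float(counts_fg @ lp)
    return g / LOG2


def _gain_prior():
    global _GAIN_PRIOR
    try:
        return _GAIN_PRIOR
    except NameError:
        from .msa_model import background_prior as _bp

        _GAIN_PRIOR = _bp(1.0)
        return _GAIN_PRIOR


def sample_patterns(
    state: BppsState,
    node: int,
    thetas: dict,
    cfg: SamplerConfig,
    rng: np.random.Generator,
    temperature: float = 1.0,
    greedy: bool = False,
) -> None:
    """Redraw the node's discriminating columns and residue sets in place.

    Column j is selected with probability proportional to
    p * prior(set) * 2^(gain/T) against (1-p) for no pattern, where gain is
    the foreground log2-ratio sum; at most ``max_patterns`` columns are
    kept (the best by gain).
    """
    H = state.H
    if node == H.reject:
        raise HierarchyError("the reject node carries no pattern")
    X, weights = state.X, state.weights
    w = X.shape[1]
    fg = H.subtree_sequences(node)
    if fg.size == 0:
        state.patterns.patterns[node] = {}
        return
    catalog = allowed_residue_sets(cfg.set_prior_decay)
    theta_bg, theta_pool = thetas[node]
    a = state.alpha.get(node, 0.05)
    counts = _column_counts(X, weights, fg)
    if node == H.root:
        bg_counts = np.zeros_like(counts)
    else:
        par = H.parent[node]
        fg_set = set(fg.tolist())
        bg = np.array(
            [i for i in H.subtree_sequences(par) if i not in fg_set],
            dtype=np.int64,
        )
        bg_counts = _column_counts(X, weights, bg)
    log_p = math.log2(cfg.pattern_prior)
    log_1p = math.log2(1 - cfg.pattern_prior)
    chosen = {}
    gains = {}
    for j in range(w):
        if counts[j].sum() <= 0:
            continue
        consensus = int(np.argmax(counts[j]))
        cands = sets_containing(catalog, consensus)
        logw = [log_1p]
        entries = [None]
        for rset, pri in cands:
            g = _two_sample_gain(
                counts[j], bg_counts[j], theta_bg[j], theta_pool[j], rset, a,
                integrated=False,
            )
            logw.append(log_p + math.log2(pri) + g / max(temperature, 1e-9))
            entries.append((rset, g))
        logw = np.array(logw)
        if greedy:
            pick = int(np.argmax(logw))
        else:
            pr = np.exp((logw - logw.max()) * LOG2)
            pr /= pr.sum()
            pick = int(rng.choice(len(pr), p=pr))
        if entries[pick] is not None:
            rset, g = entries[pick]
            chosen[j] = rset
            gains[j] = g
    if len(chosen) > cfg.max_patterns:
        keep = sorted(gains, key=gains.get, reverse=True)[: cfg.max_patterns]
        chosen = {j: chosen[j] for j in keep}
    state.patterns.patterns[node] = chosen


def sample_alpha(
    state: BppsState,
    node: int,
    thetas: dict,
    cfg: SamplerConfig,
    rng: np.random.Generator,
    greedy: bool = False,
) -> None:
    """Gibbs update of the node's background-contamination fraction over a
    grid, under a Beta(1, b) prior favouring low contamination."""
    cols = state.patterns.columns(node)
    if not cols:
        state.alpha[node] = cfg.alpha_grid[1]
        return
    H = state.H
    fg = H.subtree_sequences(node)
    X, weights = state.X, state.weights
    theta_bg, _ = thetas[node]
    b = cfg.alpha_beta_b
    logw = []
    for a in cfg.alpha_grid:
        tot = (b - 1) * math.log1p(-a) / LOG2  # Beta(1,b) log2-density (+const)
        for j, rset in cols.items():
            fmix = mixed_foreground(rset, theta_bg[j], a)
            lf = np.log(fmix) / LOG2
            col = X[fg, j]
            ok = col >= 0
            tot += float((weights[fg][ok] * lf[col[ok]]).sum())
        logw.append(tot)
    logw = np.array(logw)
    pr = np.exp((logw - logw.max()) * LOG2)
    pr /= pr.sum()
    if greedy:
        # grid point nearest the posterior mean, not the mode: keeps the
        # contamination estimate from collapsing onto a brittle extreme
        mean_a = float(np.dot(pr, np.array(cfg.alpha_grid)))
        pick = int(np.argmin(np.abs(np.array(cfg.alpha_grid) - mean_a)))
    else:
        pick = int(rng.choice(len(pr), p=pr))
    state.alpha[node] = float(cfg.alpha_grid[pick])


# ----------------------------------------------------------------------
# Objective
# ----------------------------------------------------------------------

def pattern_cost_bits(state: BppsState, node: int, cfg: SamplerConfig) -> float:
    """Description length of the node's pattern selection."""
    catalog = dict(allowed_residue_sets(cfg.set_prior_decay))
    w = state.X.shape[1]
    cols = state.patterns.columns(node)
    p = cfg.pattern_prior
    cost = (w - len(cols)) * (-math.log2(1 - p))
    for j, rset in cols.items():
        cost += -math.log2(p) - math.log2(catalog[rset])
    return cost


def _contrast_counts(state: BppsState, node: int):
    """Weighted (w, 20) residue counts of the node's foreground and
    background partitions (background is None at the root)."""
    H = state.H
    fg = H.subtree_sequences(node)
    counts_fg = _column_counts(state.X, state.weights, fg)
    if node == H.root:
        return counts_fg, None
    par = H.parent[node]
    fg_set = set(fg.tolist())
    bg = np.array(
        [i for i in H.subtree_sequences(par) if i not in fg_set], dtype=np.int64
    )
    return counts_fg, _column_counts(state.X, state.weights, bg)


def node_gain_bits(
    state: BppsState, node: int, thetas: dict, cfg: SamplerConfig
) -> float:
    """Total two-sample contrast gain of the node's pattern columns."""
    cols = state.patterns.columns(node)
    if not cols:
        return 0.0
    theta_bg, theta_pool = thetas[node]
    a = state.alpha.get(node, 0.05)
    counts_fg, counts_bg = _contrast_counts(state, node)
    total = 0.0
    for j, rset in cols.items():
        total += _two_sample_gain(
            counts_fg[j],
            None if counts_bg is None else counts_bg[j],
            theta_bg[j],
            theta_pool[j],
            rset,
            a,
        )
    return total


def node_worth_bits(
    state: BppsState, node: int, thetas: dict, cfg: SamplerConfig
) -> float:
    """Objective improvement contributed by the node's pattern relative to
    carrying no pattern at all (gain minus selection cost difference)."""
    cols = state.patterns.columns(node)
    if not cols:
        return 0.0
    catalog = dict(allowed_residue_sets(cfg.set_prior_decay))
    p = cfg.pattern_prior
    worth = node_gain_bits(state, node, thetas, cfg)
    for j, rset in cols.items():
        worth += math.log2(p) + math.log2(catalog[rset]) - math.log2(1 - p)
    return worth


def objective_bits(state: BppsState, cfg: SamplerConfig, thetas: dict | None = None) -> float:
    """MDL-penalised log-posterior (bits, up to an additive constant).

    Sum over nodes of two-sample contrast gains at pattern columns, plus
    the weighted node-assignment prior term, minus pattern, node-count and
    tree description lengths."""
    H = state.H
    thetas = thetas or background_thetas(state)
    total = 0.0
    pri = node_priors(H, cfg)
    lab = state.H.assignment
    logpri = np.array([math.log2(pri[z]) for z in lab])
    total += float((state.weights * logpri).sum())
    for node in H.parent:
        if node == H.reject:
            continue
        total += node_gain_bits(state, node, thetas, cfg)
        total -= pattern_cost_bits(state, node, cfg)
    n = H.n_nodes
    total -= node_count_dl_bits(n, cfg.geometric_factor)
    total -= tree_dl_bits(n)
    return total


# ----------------------------------------------------------------------
# Assignment sampling
# ----------------------------------------------------------------------

def sample_assignments(
    state: BppsState,
    cfg: SamplerConfig,
    rng: np.random.Generator,
    thetas: dict | None = None,
    temperature: float = 1.0,
    restrict: np.ndarray | None = None,
    candidates: list | None = None,
    greedy: bool = False,
) -> None:
    """Sequential Gibbs sweep over sequence-node assignments (in place).

    The conditional for a sequence is proportional to its node prior times
    2^(lineage pattern gain).  Contrast backgrounds are updated after every
    accepted move, so a subgroup's pull strengthens as its members leave
    the background — the cascade that lets a nascent subgroup absorb its
    class.  ``restrict`` limits which sequences move and ``candidates``
    limits the target nodes (both used for leaf burn-in).
    """
    del thetas  # computed incrementally below
    H = state.H
    X, weights = state.X, state.weights
    K, w = X.shape
    nodes = H.nodes
    pri = node_priors(H, cfg)
    logpri = {z: math.log2(pri[z]) for z in nodes}
    subtree_nodes = {z: set(H.subtree(z)) for z in nodes}
    pattern_nodes = [
        z for z in nodes if z != H.reject and state.patterns.columns(z)
    ]
    # per pattern-bearing node: its pattern columns, incrementally
    # maintained bg counts there, the (sweep-fixed) pooled composition,
    # and the current fg-side and bg-side log2 ratios vs the pool
    info = {}
    for z in pattern_nodes:
        cols = sorted(state.patterns.columns(z))
        rsets = [state.patterns.columns(z)[j] for j in cols]
        if z == H.root:
            bg_counts = None
            pool = np.tile(BACKGROUND, (len(cols), 1))
        else:
            par = H.parent[z]
            bg = [
                i
                for i in range(K)
                if H.assignment[i] in subtree_nodes[par]
                and H.assignment[i] not in subtree_nodes[z]
            ]
            pool_rows = [
                i for i in range(K) if H.assignment[i] in subtree_nodes[par]
            ]
            bg_counts = np.zeros((len(cols), N_AA))
            pool_counts = np.zeros((len(cols), N_AA))
            for ci, j in enumerate(cols):
                col = X[bg, j] if bg else np.empty(0, dtype=np.int64)
                ok = col >= 0
                np.add.at(bg_counts[ci], col[ok], np.asarray(weights)[bg][ok])
                colp = X[pool_rows, j] if pool_rows else np.empty(0, dtype=np.int64)
                okp = colp >= 0
                np.add.at(
                    pool_counts[ci], colp[okp], np.asarray(weights)[pool_rows][okp]
                )
            pool = (pool_counts + BACKGROUND[None, :]) / (
                pool_counts.sum(axis=1, keepdims=True) + 1.0
            )
        info[z] = {
            "cols": cols,
            "rsets": rsets,
            "bg": bg_counts,
            "pool": pool,
            "alpha": state.alpha.get(z, 0.05),
        }

    def refresh_ratio(z):
        d = info[z]
        if d["bg"] is None:
            th = np.tile(BACKGROUND, (len(d["cols"]), 1))
        else:
            th = (d["bg"] + BACKGROUND[None, :]) / (
                d["bg"].sum(axis=1, keepdims=True) + 1.0
            )
        Rf = np.zeros((len(d["cols"]), N_AA))
        Rb = np.zeros((len(d["cols"]), N_AA))
        lp = np.log(d["pool"]) / math.log(2)
        for ci, rset in enumerate(d["rsets"]):
            from .bpps_model import mixed_foreground

            fmix = mixed_foreground(rset, th[ci], d["alpha"])
            Rf[ci] = np.log(fmix) / math.log(2) - lp[ci]
            Rb[ci] = np.log(th[ci]) / math.log(2) - lp[ci]
        d["ratio_fg"] = Rf
        d["ratio_bg"] = Rb

    for z in pattern_nodes:
        refresh_ratio(z)

    def node_gain(i, z, side):
        d = info[z]
        R = d["ratio_fg"] if side == "fg" else d["ratio_bg"]
        g = 0.0
        for ci, j in enumerate(d["cols"]):
            r = X[i, j]
            if r >= 0:
                g += R[ci, r]
        return g

    def bg_update(z, i, sign):
        d = info[z]
        if d["bg"] is None:
            return
        wt = weights[i]
        for ci, j in enumerate(d["cols"]):
            r = X[i, j]
            if r >= 0:
                d["bg"][ci, r] = max(d["bg"][ci, r] + sign * wt, 0.0)
        refresh_ratio(z)

    parent_sub = {
        z: subtree_nodes[H.parent[z]] for z in pattern_nodes if z != H.root
    }

    cand_set = None if candidates is None else set(candidates)
    targets = [z for z in nodes if cand_set is None or z in cand_set]
    rows = np.arange(K) if restrict is None else np.asarray(restrict)
    order = rows[rng.permutation(rows.size)] if not greedy else rows
    T = max(temperature, 1e-9)
    for i in order:
        i = int(i)
        old = int(H.assignment[i])
        scores = []
        for z in targets:
            g = logpri[z]
            if z != H.reject:
                for h in pattern_nodes:
                    if z in subtree_nodes[h]:
                        g += node_gain(i, h, "fg")
                    elif h != H.root and z in parent_sub[h]:
                        g += node_gain(i, h, "bg")
            scores.append(g)
        s = np.array(scores) / T
        if greedy:
            pick = int(np.argmax(s))
        else:
            pr = np.exp((s - s.max()) * LOG2)
            pr /= pr.sum()
            pick = int(rng.choice(len(targets), p=pr))
        new = targets[pick]
        if new == old:
            continue
        H.assignment[i] = new
        # update the contrast backgrounds whose membership changed
        for z in pattern_nodes:
            if z == H.root:
                continue
            par = H.parent[z]
            was_bg = old in subtree_nodes[par] and old not in subtree_nodes[z]
            is_bg = new in subtree_nodes[par] and new not in subtree_nodes[z]
            if was_bg and not is_bg:
                bg_update(z, i, -1.0)
            elif is_bg and not was_bg:
                bg_update(z, i, +1.0)


# ----------------------------------------------------------------------
# Structural moves
# ----------------------------------------------------------------------

MOVE_KINDS = ("add_leaf", "delete_node", "insert_internal", "move_subtree")


def propose_move(
    H: Hierarchy, kind: str, rng: np.random.Generator
) -> Hierarchy | None:
    """Propose a structural candidate; None signals an illegal/rejected
    proposal (e.g. the height limit would be violated).

    add_leaf attaches an empty child; delete_node reassigns the node's
    sequences to its parent (children are promoted); insert_internal
    interposes a new node above a chosen child; move_subtree reparents a
    subtree.  The reject node and the root are never removed or moved.
    """
    H = H.copy()
    protected = {H.root, H.reject}
    if kind == "add_leaf":
        parents = [n for n in H.parent if n != H.reject and H.depth(n) < H.height_limit]
        if not parents:
            return None
        if H.assignment is not None:
            # favour parents whose own pool has sequences to give away
            wts = np.array(
                [H.node_sequences(n).size + (H.node_sequences(H.reject).size if n == H.root else 0) + 5.0 for n in parents]
            )
            par = parents[int(rng.choice(len(parents), p=wts / wts.sum()))]
        else:
            par = parents[int(rng.integers(len(parents)))]
        nid = H.new_node_id()
        H.parent[nid] = par
        return H
    if kind == "delete_node":
        cands = [n for n in H.parent if n not in protected]
        if not cands:
            return None
        node = cands[int(rng.integers(len(cands)))]
        par = H.parent[node]
        for c in H.children(node):
            H.parent[c] = par
        if H.assignment is not None:
            H.assignment[H.assignment == node] = par
        del H.parent[node]
        return H
    if kind == "insert_internal":
        cands = [n for n in H.parent if n not in protected]
        if not cands:
            return None
        child = cands[int(rng.integers(len(cands)))]
        par = H.parent[child]
        nid = H.new_node_id()
        H.parent[nid] = par
        H.parent[child] = nid
        if H.height() > H.height_limit:
            return None
        return H
    if kind == "move_subtree":
        cands = [n for n in H.parent if n not in protected]
        if not cands:
            return None
        node = cands[int(rng.integers(len(cands)))]
        sub = set(H.subtree(node))
        targets = [n for n in H.parent if n not in sub and n != H.reject and n != H.parent[node]]
        if not targets:
            return None
        tgt = targets[int(rng.integers(len(targets)))]
        H.parent[node] = tgt
        if H.height() > H.height_limit:
            return None
        return H
    raise ValueError(f"unknown move kind {kind!r}")


def _seed_leaf(
    state: BppsState,
    leaf: int,
    cfg: SamplerConfig,
    rng: np.random.Generator,
) -> bool:
    """Seed a freshly attached leaf with a coherent subset of its parent's
    pool, then burn it in (pattern <-> restricted assignment sweeps)."""
    H = state.H
    par = H.parent[leaf]
    pool = list(H.node_sequences(par))
    if par == H.root:
        pool += list(H.node_sequences(H.reject))
    pool = np.array(sorted(pool), dtype=np.int64)
    if pool.size < cfg.min_leaf_sequences:
        return False
    seed_i = int(pool[int(rng.integers(pool.size))])
    X = state.X
    # discriminative similarity: a shared residue is evidence of common
    # subgroup membership in proportion to how non-universal it is at that
    # column; universally conserved (family-wide) columns carry ~no weight,
    # and rare chance matches are ignored
    K, w = X.shape
    colw = np.zeros((w, N_AA))
    for j in range(w):
        col = X[:, j]
        ok = col >= 0
        if not np.any(ok):
            continue
        freq = np.bincount(col[ok], minlength=N_AA) / ok.sum()
        colw[j] = np.where(freq >= 0.15, -np.log2(np.maximum(freq, 1e-9)), 0.0)
    ref = X[seed_i]
    sims = np.zeros(pool.size)
    for idx, i in enumerate(pool):
        m = (ref >= 0) & (X[i] == ref)
        js = np.nonzero(m)[0]
        sims[idx] = colw[js, ref[js]].sum()
    take = pool[np.argsort(-sims)[: max(cfg.min_leaf_sequences, pool.size // 4)]]
    state.H.assignment[take] = leaf
    restrict = pool
    needed = set(H.lineage(leaf)) | {par}
    cands = [par, leaf] + ([H.reject] if par == H.root else [])
    for _ in range(cfg.burn_in_sweeps):
        thetas = background_thetas(state, nodes=needed)
        sample_patterns(state, leaf, thetas, cfg, rng)
        sample_alpha(state, leaf, thetas, cfg, rng)
        sample_assignments(
            state, cfg, rng, thetas, restrict=restrict, candidates=cands
        )
        if H.node_sequences(leaf).size == 0:
            return False
    return H.node_sequences(leaf).size >= _leaf_floor(cfg, final=False)


def _leaf_floor(cfg: SamplerConfig, final: bool) -> int:
    """Leaf-size floor: the full requirement applies to the final model; a
    relaxed floor is used while sampling so nascent subgroups can grow
    through subsequent realignment rounds."""
    return cfg.min_leaf_sequences if final else max(5, cfg.min_leaf_sequences // 6)


def _constraints_ok(
    state: BppsState, cfg: SamplerConfig, thetas: dict, final: bool = False
) -> bool:
    H = state.H
    floor = _leaf_floor(cfg, final)
    for node in H.parent:
        if node in (H.root, H.reject):
            continue
        kids = H.children(node)
        if not kids and H.node_sequences(node).size < floor:
            return False
        # a single-child node without its own sequence support duplicates
        # its child's contrast and is disallowed
        if len(kids) == 1 and H.node_sequences(node).size < floor:
            return False
        if node_worth_bits(state, node, thetas, cfg) < cfg.min_node_bits:
            return False
    return True


def extract_leaf(
    state: BppsState,
    cfg: SamplerConfig,
    rng: np.random.Generator,
    tries: int = 8,
) -> bool:
    """Best-of-N seeded leaf extraction (in place).

    Several independently seeded candidate leaves are burned in and the one
    with the largest discriminating worth is adopted, provided it clears
    the exploratory evidence bar (the final round still applies the full
    MDL criterion to every node).  This is the initialisation half of the
    attach-leaf move: proposing from a coherent seed rather than from thin
    air is what makes subgroup discovery reliable at realistic noise.
    """
    parents = [state.H.root]
    sizes = {
        n: state.H.node_sequences(n).size
        for n in state.H.parent
        if n not in (state.H.root, state.H.reject)
    }
    if sizes:
        big = max(sizes, key=sizes.get)
        if sizes[big] >= 2 * cfg.min_leaf_sequences and state.H.depth(big) < state.H.height_limit:
            parents.append(big)  # allow splitting an oversized subgroup
    best = None
    for t in range(tries):
        par = parents[t % len(parents)]
        newH = state.H.copy()
        leaf = newH.new_node_id()
        newH.parent[leaf] = par
        cand = BppsState(
            state.X, state.weights, newH, state.patterns.copy(), dict(state.alpha)
        )
        if not _seed_leaf(cand, leaf, cfg, rng):
            continue
        thetas = background_thetas(cand, nodes={leaf})
        worth = node_worth_bits(cand, leaf, thetas, cfg)
        if worth >= cfg.min_node_bits and (best is None or worth > best[0]):
            full = background_thetas(cand)
            if _constraints_ok(cand, cfg, full, final=False):
                best = (worth, cand)
    if best is None:
        return False
    state.H = best[1].H
    state.patterns = best[1].patterns
    state.alpha = best[1].alpha
    return True


def attempt_structural_move(
    state: BppsState,
    kind: str,
    cfg: SamplerConfig,
    rng: np.random.Generator,
    temperature: float,
    current_obj: float,
    final: bool = True,
) -> tuple[BppsState, float, bool]:
    """Propose, burn in, and Metropolis-accept one structural move.

    During exploratory (non-final) rounds a new leaf whose pattern carries
    substantial discriminating information is admitted even when the
    current MDL-penalised posterior disfavours it: nascent subgroups only
    reveal their full evidence after their sub-alignment has been refined,
    and the final round re-judges every node under the full criterion.
    """
    newH = propose_move(state.H, kind, rng)
    if newH is None:
        return state, current_obj, False
    cand = BppsState(state.X, state.weights, newH, state.patterns.copy(), dict(state.alpha))
    if kind == "add_leaf":
        leaf = max(newH.parent)
        if not _seed_leaf(cand, leaf, cfg, rng):
            return state, current_obj, False
    else:
        # refresh patterns of the structurally affected nodes only
        affected = set()
        if kind == "insert_internal":
            affected.add(max(newH.parent))
        old_nodes = set(state.H.parent)
        affected |= {n for n in newH.parent if n not in old_nodes}
        for n in newH.parent:
            if newH.parent.get(n) != state.H.parent.get(n):
                affected.add(n)
        affected = {n for n in affected if n in newH.parent and n != newH.reject}
        if affected:
            thetas = background_thetas(cand, nodes=affected)
            for node in affected:
                sample_patterns(cand, node, thetas, cfg, rng, temperature)
    cand.patterns.patterns = {
        n: c for n, c in cand.patterns.patterns.items() if n in cand.H.parent
    }
    cand.alpha = {n: a for n, a in cand.alpha.items() if n in cand.H.parent}
    thetas = background_thetas(cand)
    if not _constraints_ok(cand, cfg, thetas, final=final):
        return state, current_obj, False
    cand_obj = objective_bits(cand, cfg, thetas)
    delta = cand_obj - current_obj
    if delta >= 0 or rng.random() < math.exp(delta * LOG2 / max(temperature, 1e-9)):
        return cand, cand_obj, True
    if not final and kind == "add_leaf":
        leaf = max(cand.H.parent)
        if node_worth_bits(cand, leaf, thetas, cfg) >= cfg.min_node_bits:
            return cand, cand_obj, True
    return state, current_obj, False


# ----------------------------------------------------------------------
# Full pipeline
# ----------------------------------------------------------------------

@dataclass
class RunResult:
    hierarchy: Hierarchy
    patterns: PatternSet
    alignment: AlignmentState
    sequences: SequenceSet  # with final weights
    ledger: DLLedger
    trace: list
    alpha: dict = field(default_factory=dict)
    himsa: object | None = None

    @property
    def X(self) -> np.ndarray:
        return build_code_matrix(self.sequences, self.alignment)


def initial_alignment(seqs: SequenceSet) -> AlignmentState:
    """Ungapped seed alignment: thread each sequence from its start against
    w = median-length match columns."""
    lengths = seqs.lengths
    w = int(np.median(lengths))
    K = len(seqs)
    mm = np.full((K, w), -1, dtype=np.int64)
    for k, L in enumerate(lengths):
        n = min(w, int(L))
        mm[k, :n] = np.arange(n)
    aln = AlignmentState(mm, lengths)
    aln.check()
    return aln


def build_code_matrix(seqs: SequenceSet, aln: AlignmentState) -> np.ndarray:
    """(K, w) residue codes at match columns; -1 for deletions and 'X'."""
    K, w = aln.match_map.shape
    X = np.full((K, w), -1, dtype=np.int64)
    for k, rec in enumerate(seqs):
        row = aln.match_map[k]
        mask = row >= 0
        X[k, mask] = rec.codes[row[mask]]
    return X


def viterbi_polish(
    seqs: SequenceSet, aln: AlignmentState, rounds: int = 2
) -> AlignmentState:
    """Deterministic polish: re-thread every sequence by Viterbi against the
    profile implied by the current alignment."""
    from .msa_model import viterbi_align
    from .seqio import count_all_columns

    prior = background_prior()
    for _ in range(rounds):
        counts = count_all_columns(seqs, aln)
        tc = aln.transition_counts()
        mm = aln.match_map.copy()
        for k, rec in enumerate(seqs):
            mm[k] = viterbi_align(rec.codes, counts, tc, prior)
        aln = AlignmentState(mm, aln.seq_lengths)
    aln.check()
    return aln


def sample_msa(
    seqs: SequenceSet,
    cfg: SamplerConfig,
    rng: np.random.Generator,
    aln: AlignmentState | None = None,
) -> AlignmentState:
    """MSA stage: Gibbs path sampling, MDL architecture adjustment, and a
    deterministic Viterbi polish."""
    prior = background_prior()
    aln = initial_alignment(seqs) if aln is None else aln
    if len(seqs) >= 2 and cfg.msa_sweeps > 0:
        # gap-penalty annealing: start with tempered transition costs so
        # column coherence can condense, then restore the full model
        n = cfg.msa_sweeps
        schedule = [
            cfg.gap_anneal_start
            + (1.0 - cfg.gap_anneal_start) * i / max(n - 1, 1)
            for i in range(n)
        ]
        aln = gibbs_sweep(
            seqs, aln, rng, prior, n_sweeps=n, transition_scale=schedule
        )
    if cfg.refine_architecture and len(seqs) >= 2:
        # alternate MDL architecture moves with path resampling so newly
        # nucleated anchor columns can recruit their stragglers
        for _ in range(cfg.architecture_rounds):
            aln = adjust_architecture(
                seqs, aln, prior, path_bits_per_seq=cfg.path_bits_per_seq
            )
            if cfg.msa_refine_sweeps > 0:
                aln = gibbs_sweep(
                    seqs, aln, rng, prior, n_sweeps=cfg.msa_refine_sweeps
                )
            aln = viterbi_polish(seqs, aln, rounds=1)
    elif len(seqs) >= 2:
        aln = viterbi_polish(seqs, aln)
    return aln


def sample_hierarchy(
    state: BppsState,
    cfg: SamplerConfig,
    rng: np.random.Generator,
    final: bool = True,
    initial_temperature: float | None = None,
    max_cycles: int | None = None,
) -> tuple[BppsState, list]:
    """BPPS stage: annealed MCMC over hierarchies; returns the best state
    visited (by MDL-penalised posterior) and the per-cycle trace.

    The annealing temperature governs the structural Metropolis moves;
    pattern and assignment sampling never run hotter than T = 1 (proper
    Gibbs), because overheated assignment sweeps trigger avalanche
    collapse of established subgroups via the background-dilution
    feedback.
    """
    trace = []
    thetas = background_thetas(state)
    obj = objective_bits(state, cfg, thetas)
    best = state.copy()
    best_obj = obj
    stall = 0
    t0 = cfg.initial_temperature if initial_temperature is None else initial_temperature
    n_cycles = cfg.max_cycles if max_cycles is None else max_cycles
    for cycle in range(n_cycles):
        T = max(t0 * cfg.cooling**cycle, cfg.min_temperature)
        T_gibbs = min(T, 1.0)
        for kind in rng.permutation(MOVE_KINDS):
            state, obj, _ = attempt_structural_move(
                state, str(kind), cfg, rng, T, obj, final=final
            )
        thetas = background_thetas(state)
        for node in state.H.parent:
            if node == state.H.reject:
                continue
            sample_patterns(state, node, thetas, cfg, rng, T_gibbs)
            sample_alpha(state, node, thetas, cfg, rng)
        sample_assignments(state, cfg, rng, thetas, temperature=T_gibbs)
        thetas = background_thetas(state)
        obj = objective_bits(state, cfg, thetas)
        if obj > best_obj + cfg.improvement_tol:
            best, best_obj = state.copy(), obj
            stall = 0
        else:
            stall += 1
        trace.append((cycle, obj, best_obj, state.H.n_nodes, T))
        if stall >= cfg.patience:
            break
    if final:
        state = best.copy()
    # greedy finish
    thetas = background_thetas(state)
    for node in state.H.parent:
        if node == state.H.reject:
            continue
        sample_patterns(state, node, thetas, cfg, rng, greedy=True)
        sample_alpha(state, node, thetas, cfg, rng, greedy=True)
    sample_assignments(state, cfg, rng, thetas, greedy=True)
    _cleanup(state, cfg, final=final)
    obj = objective_bits(state, cfg)
    if final and obj < best_obj:
        state = best
        obj = best_obj
    best_obj = max(best_obj, obj)
    trace.append((len(trace), obj, best_obj, state.H.n_nodes, 0.0))
    return state, trace


def _cleanup(state: BppsState, cfg: SamplerConfig, final: bool = True) -> None:
    """Remove nodes violating the leaf-size or information floors."""
    floor = _leaf_floor(cfg, final)
    changed = True
    while changed:
        changed = False
        thetas = background_thetas(state)
        for node in list(state.H.parent):
            if node in (state.H.root, state.H.reject):
                continue
            kids = state.H.children(node)
            bad = (not kids and state.H.node_sequences(node).size < floor) or (
                node_worth_bits(state, node, thetas, cfg) < cfg.min_node_bits
            )
            if bad:
                par = state.H.parent[node]
                for c in kids:
                    state.H.parent[c] = par
                state.H.assignment[state.H.assignment == node] = par
                del state.H.parent[node]
                state.patterns.patterns.pop(node, None)
                state.alpha.pop(node, None)
                changed = True
                break


def classify_and_thread(
    seqs: SequenceSet,
    aln: AlignmentState,
    H: Hierarchy,
    cfg: SamplerConfig,
    transition_scale: float = 0.4,
) -> tuple[AlignmentState, Hierarchy]:
    """Joint re-threading and re-assignment against lineage-specific
    profiles.

    Every sequence is Viterbi-aligned against the emission profile of each
    candidate node (root and every major-subgroup subtree, with emissions
    estimated from that subtree's members only, i.e. the hierarchical
    model's lineage-specific view) and against the reject null (background
    frequencies, no match states).  The sequence adopts the node with the
    highest prior-weighted path likelihood together with the corresponding
    path.  This is what lets a subgroup recruit members whose conserved
    residues only align once the subgroup's own sharp emissions, rather
    than the diluted family profile, do the pulling.
    """
    from .msa_model import (
        _forward,
        _traceback,
        posterior_mean_emissions,
        posterior_mean_log_transitions,
    )
    from .seqio import count_all_columns

    prior_em = background_prior()
    K = len(seqs)
    w = aln.num_columns
    log_bg = np.log(BACKGROUND)
    tc = aln.transition_counts()
    lt = posterior_mean_log_transitions(tc)
    if transition_scale != 1.0:
        # membership evidence lives in the emissions; tempering the gap
        # penalties keeps path-rearrangement costs from vetoing a clearly
        # better-fitting subgroup (the same scale applies to every
        # candidate and to the reject null, so the comparison stays fair)
        lt = {k: transition_scale * v for k, v in lt.items()}
    pri = node_priors(H, cfg)
    candidates = [H.root] + [
        n for n in H.nodes if n not in (H.root, H.reject)
    ]

    def node_counts(node):
        rows = H.subtree_sequences(node) if node != H.root else np.array(
            [i for i in range(K) if H.assignment[i] != H.reject], dtype=np.int64
        )
        if rows.size == 0:
            rows = np.arange(K)
        sub = SequenceSet([seqs[int(i)] for i in rows])
        return count_all_columns(
            sub, AlignmentState(aln.match_map[rows], aln.seq_lengths[rows])
        )

    root_counts = node_counts(H.root)
    log_root = np.log(posterior_mean_emissions(root_counts, prior_em))
    thetas = {H.root: log_root}
    for node in candidates[1:]:
        counts = node_counts(node)
        log_sub = np.log(posterior_mean_emissions(counts, prior_em))
        # lineage-specific emissions only where the subtree genuinely
        # diverges from the family profile; elsewhere the subtree inherits
        # the parent estimate (column ownership), which avoids penalising
        # candidate members with small-sample noise at ordinary columns
        n_sub = counts.sum(axis=1).max()
        div = counts * (log_sub - log_root)
        # threshold well above the ~chi^2/2 overfitting level of a
        # small-sample column estimate, so only genuinely divergent
        # (ownable) columns get lineage-specific emissions
        gate = div.sum(axis=1) > max(10.0, 0.5 * float(n_sub))
        th = log_root.copy()
        th[gate] = log_sub[gate]
        thetas[node] = th
    new_map = aln.match_map.copy()
    new_assign = H.assignment.copy()
    for k in range(K):
        codes = seqs[k].codes
        L = codes.shape[0]
        best = None
        # reject null: the single-insert-state architecture — all residues
        # emitted from the background through the insert state at the
        # model's first position
        ins = codes[codes >= 0]
        null_score = (
            float(log_bg[ins].sum())
            + lt["mi"][0]
            + max(L - 1, 0) * lt["ii"][0]
            + lt["im"][0]
            + math.log(pri[H.reject])
        )
        for node in candidates:
            fM, fD, fI, tot = _forward(codes, thetas[node], log_bg, lt, op="max")
            score = tot + math.log(pri[node])
            if best is None or score > best[0]:
                best = (score, node, fM, fD, fI)
        if best[0] >= null_score:
            _, node, fM, fD, fI = best
            new_map[k] = _traceback(fM, fD, fI, lt, L, None, greedy=True)
            if int(new_assign[k]) not in H.subtree(node):
                new_assign[k] = node
        else:
            new_assign[k] = H.reject
    out = AlignmentState(new_map, aln.seq_lengths)
    out.check()
    H2 = H.copy()
    H2.assignment = new_assign
    return out, H2


def run(seqs: SequenceSet, config: SamplerConfig | None = None) -> RunResult:
    """Full pipeline, deterministic given ``config.seed``.

    Stage 1 samples a flat alignment (Gibbs path sampling with gap-penalty
    annealing plus MDL architecture moves).  Stage 2 iterates: annealed
    hierarchy sampling (structure, patterns, contamination, assignments),
    then recursive subgroup realignment whose refinements are projected
    back into the root alignment so the next round can recruit sequences
    that only align well once their subgroup's columns are coherent.  The
    final round re-samples patterns greedily and enforces the leaf-size
    and per-node information floors.
    """
    from .hier_msa import refine_himsa  # late import to avoid a cycle

    cfg = config or SamplerConfig()
    if len(seqs) == 0:
        raise ValueError("no input sequences")
    rng = np.random.default_rng(cfg.seed)
    rng_msa, rng_bpps, rng_refine = rng.spawn(3)

    aln = sample_msa(seqs, cfg, rng_msa)
    if aln.num_columns == 0:
        raise ValueError("alignment collapsed to zero match columns")

    def greedy_eval(seqs_w, aln_c, H, alpha):
        """Fresh greedy-pattern state on the candidate alignment plus the
        MDL-penalised hierarchy objective used to ratchet across rounds.

        The data-alignment posterior is deliberately excluded from the
        ratchet: its scale (thousands of bits across architecture changes)
        would drown the hierarchy terms, and alignment improvements only
        matter here through the contrast gains they enable, which the
        objective already measures."""
        X = build_code_matrix(seqs_w, aln_c)
        st = BppsState(
            X, seqs_w.weights, H, PatternSet(max_patterns=cfg.max_patterns), dict(alpha)
        )
        th = background_thetas(st)
        for node in st.H.parent:
            if node == st.H.reject:
                continue
            sample_patterns(st, node, th, cfg, rng_bpps, greedy=True)
            sample_alpha(st, node, th, cfg, rng_bpps, greedy=True)
        metric = objective_bits(st, cfg)
        return st, metric

    state = None
    hm = None
    best = None  # (metric, seqs, aln, H, alpha, hm)
    trace: list = []
    for outer in range(max(cfg.outer_rounds, 1)):
        seqs = compute_weights(seqs, aln)
        X = build_code_matrix(seqs, aln)
        if state is None:
            H = Hierarchy.trivial(len(seqs), height_limit=cfg.height_limit)
            state = BppsState(
                X, seqs.weights, H, PatternSet(max_patterns=cfg.max_patterns), {}
            )
        else:
            # carry the hierarchy and assignments; patterns are re-sampled
            # in the new column coordinates
            state = BppsState(
                X,
                seqs.weights,
                state.H,
                PatternSet(max_patterns=cfg.max_patterns),
                dict(state.alpha),
            )
        gentle = outer > 0
        thetas = background_thetas(state)
        for node in state.H.parent:
            if node == state.H.reject:
                continue
            sample_patterns(state, node, thetas, cfg, rng_bpps, greedy=gentle)
            sample_alpha(state, node, thetas, cfg, rng_bpps, greedy=gentle)
        sample_assignments(state, cfg, rng_bpps, temperature=1.0, greedy=gentle)
        # seeded leaf extraction: up to two coherent new subgroups per round
        for _ in range(2):
            if not extract_leaf(state, cfg, rng_bpps):
                break
            thetas = background_thetas(state)
            sample_assignments(state, cfg, rng_bpps, thetas, temperature=1.0)
        state, tr = sample_hierarchy(
            state,
            cfg,
            rng_bpps,
            final=False,
            initial_temperature=cfg.initial_temperature if outer == 0 else 1.0,
            max_cycles=cfg.max_cycles if outer == 0 else 8,
        )
        trace.extend(tr)
        state, aln, hm = refine_himsa(seqs, aln, state, cfg, rng_refine)
        if cfg.refine_architecture and len(seqs) >= 2:
            # subgroup columns made coherent by the refinement can now pay
            # their way into the root architecture; lineage-specific
            # re-threading then lets outside sequences align to them and
            # be recruited
            prior = background_prior()
            aln = adjust_architecture(
                seqs, aln, prior, path_bits_per_seq=cfg.path_bits_per_seq
            )
            aln, newH = classify_and_thread(seqs, aln, state.H, cfg)
            state.H = newH
        # round-level ratchet: a round is one large blocked proposal over
        # the hierarchy; its outcome is kept only when the MDL-penalised
        # hierarchy objective improves on the best seen, otherwise the
        # next round retries from the best snapshot
        seqs_eval = compute_weights(seqs, aln)
        st_eval, metric = greedy_eval(seqs_eval, aln, state.H, state.alpha)
        trace.append((len(trace), metric, metric, state.H.n_nodes, -1.0))
        if best is None or metric > best[0]:
            best = (
                metric,
                seqs_eval,
                aln.copy(),
                st_eval.H.copy(),
                dict(st_eval.alpha),
                hm,
            )
        else:
            _, seqs, aln, H_b, alpha_b, hm = best
            state = BppsState(
                build_code_matrix(seqs, aln),
                seqs.weights,
                H_b.copy(),
                PatternSet(max_patterns=cfg.max_patterns),
                dict(alpha_b),
            )

    _, seqs, aln, H_best, alpha_best, hm = best
    state = BppsState(
        build_code_matrix(seqs, aln),
        seqs.weights,
        H_best,
        PatternSet(max_patterns=cfg.max_patterns),
        dict(alpha_best),
    )
    thetas = background_thetas(state)
    for node in state.H.parent:
        if node == state.H.reject:
            continue
        sample_patterns(state, node, thetas, cfg, rng_bpps, greedy=True)
        sample_alpha(state, node, thetas, cfg, rng_bpps, greedy=True)

    # growth iterations on the best state: refine subgroups, project, and
    # re-classify so straggler members of established subgroups are pulled
    # in by the lineage-specific profiles before the hard floors apply
    for _ in range(2):
        if not state.H.major_subgroups():
            break
        state, aln, hm = refine_himsa(seqs, aln, state, cfg, rng_refine)
        if cfg.refine_architecture and len(seqs) >= 2:
            aln = adjust_architecture(
                seqs, aln, background_prior(), path_bits_per_seq=cfg.path_bits_per_seq
            )
        aln, newH = classify_and_thread(seqs, aln, state.H, cfg)
        state.H = newH
        seqs = compute_weights(seqs, aln)
        state = BppsState(
            build_code_matrix(seqs, aln),
            seqs.weights,
            state.H,
            PatternSet(max_patterns=cfg.max_patterns),
            dict(state.alpha),
        )
        thetas = background_thetas(state)
        for node in state.H.parent:
            if node == state.H.reject:
                continue
            sample_patterns(state, node, thetas, cfg, rng_bpps, greedy=True)
            sample_alpha(state, node, thetas, cfg, rng_bpps, greedy=True)

    # final pattern re-sampling only (assignments come from the
    # hierarchical classification) and the hard model floors
    _cleanup(state, cfg, final=True)
    thetas = background_thetas(state)
    for node in state.H.parent:
        if node == state.H.reject:
            continue
        sample_patterns(state, node, thetas, cfg, rng_bpps, greedy=True)
    final_obj = objective_bits(state, cfg)
    trace.append((len(trace), final_obj, final_obj, state.H.n_nodes, 0.0))

    pri = node_priors(state.H, cfg)
    n = state.H.n_nodes
    ledger = DLLedger(
        node_count_bits=node_count_dl_bits(n, cfg.geometric_factor),
        tree_bits=tree_dl_bits(n) if n > 1 else 0.0,
        pattern_bits=sum(
            pattern_cost_bits(state, z, cfg)
            for z in state.H.parent
            if z != state.H.reject
        ),
        assignment_bits=float(
            sum(
                -w * math.log2(pri[z])
                for w, z in zip(seqs.weights, state.H.assignment)
            )
        ),
        path_bits=0.0,
        data_bits=data_dl_bits(seqs, aln),
    )
    return RunResult(
        hierarchy=state.H,
        patterns=state.patterns,
        alignment=aln,
        sequences=seqs,
        ledger=ledger,
        trace=trace,
        alpha=state.alpha,
        himsa=hm,
    )
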