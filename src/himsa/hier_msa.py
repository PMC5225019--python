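"""Hierarchical MSA construction: subgroup realignment, templates,
column ownership, lineage-specific emissions and node weights.

Once a flat alignment has been partitioned into a hierarchy, each node's
sequence set is realigned on its own (recursively from the root's children
down), so that regions conserved only within the subgroup gain match
columns and regions deleted subgroup-wide lose them.  Template maps relate
each child's columns to its parent's columns through the coordinates of the
shared sequences.  Every discriminating column is owned by the shallowest
node whose pattern includes it, and the corresponding emission table in the
per-node HMMs is estimated from the subtree rooted at the owner.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import BACKGROUND, N_AA
from .bpps_model import Hierarchy, PatternSet, allowed_residue_sets, sets_containing
from .config import SamplerConfig
from .mdl import architecture_gain_bits
from .msa_model import (
    DirichletMixture,
    adjust_architecture,
    background_prior,
    bild_score,
    gibbs_sweep,
    viterbi_align,
)
from .seqio import SequenceSet, count_all_columns
from .state import AlignmentState

LOG2 = np.log(2.0)


@dataclass
class HiMSA:
    """Per-node sub-alignments plus the maps tying them together."""

    hierarchy: Hierarchy
    node_rows: dict = field(default_factory=dict)  # node -> seq indices (global)
    sub_alignments: dict = field(default_factory=dict)  # node -> AlignmentState
    templates: dict = field(default_factory=dict)  # child -> {child_col: parent_col|None}
    ownership: dict = field(default_factory=dict)  # root col -> owning node
    insert_patterns: dict = field(default_factory=dict)  # node -> {local col: set}


@dataclass
class HiHMM:
    """One HMM per node with lineage-specific emissions and node weights."""

    hierarchy: Hierarchy
    emissions: dict = field(default_factory=dict)  # node -> (w_node, 20)
    columns_owner: dict = field(default_factory=dict)  # node -> list of owners per col
    weights: dict = field(default_factory=dict)  # node -> weight (sums to 1)

    def log_likelihood(self, node: int, col_codes: np.ndarray) -> float:
        """Emission log-likelihood of a column-coded sequence under the
        node's HMM (gaps and 'X' contribute nothing)."""
        E = self.emissions[node]
        ok = (col_codes >= 0) & (np.arange(col_codes.size) < E.shape[0])
        js = np.nonzero(ok)[0]
        return float(np.log(E[js, col_codes[js]]).sum())

    def emit(self, node: int, rng: np.random.Generator) -> np.ndarray:
        """Sample one gapless column-coded sequence from the node's HMM."""
        E = self.emissions[node]
        return np.array(
            [rng.choice(E.shape[1], p=E[j] / E[j].sum()) for j in range(E.shape[0])],
            dtype=np.int64,
        )


# ----------------------------------------------------------------------
# Purge / re-thread
# ----------------------------------------------------------------------

def purge_redundant(
    X: np.ndarray, identity: float = 0.95
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy removal of sequences >= `identity` identical (over co-aligned
    match columns) to an already kept one.  Returns (kept, purged) row
    indices."""
    K = X.shape[0]
    kept: list[int] = []
    purged: list[int] = []
    for i in range(K):
        dup = False
        xi = X[i]
        for j in kept:
            xj = X[j]
            m = (xi >= 0) & (xj >= 0)
            n = int(m.sum())
            if n and (xi[m] == xj[m]).sum() / n >= identity:
                dup = True
                break
        (purged if dup else kept).append(i)
    return np.array(kept, dtype=np.int64), np.array(purged, dtype=np.int64)


def _restrict(aln: AlignmentState, rows: np.ndarray) -> AlignmentState:
    return AlignmentState(aln.match_map[rows].copy(), aln.seq_lengths[rows].copy())


def _code_matrix(subset: SequenceSet, aln: AlignmentState) -> np.ndarray:
    X = np.full((len(subset), aln.num_columns), -1, dtype=np.int64)
    for r, rec in enumerate(subset):
        row = aln.match_map[r]
        mask = row >= 0
        X[r, mask] = rec.codes[row[mask]]
    return X


def refine_subgroup_alignment(
    subset: SequenceSet,
    parent_aln: AlignmentState,
    local_rows: np.ndarray,
    cfg: SamplerConfig,
    rng: np.random.Generator,
    prior: DirichletMixture | None = None,
) -> AlignmentState:
    """Realign one node's sequences starting from the parent's alignment.

    ``subset`` holds the node's sequences in the same order as
    ``local_rows`` indexes the parent's alignment rows.  Highly similar
    sequences (>= cfg.purge_identity) are removed first and re-threaded by
    Viterbi afterwards; Gibbs path sweeps then an MDL architecture
    adjustment extend the sub-alignment into subgroup-specific regions and
    drop subgroup-deleted columns.
    """
    prior = prior or background_prior()
    sub = _restrict(parent_aln, local_rows)
    if len(subset) < 2:
        return sub
    X = _code_matrix(subset, sub)
    kept, purged = purge_redundant(X, cfg.purge_identity)
    core = SequenceSet([subset[int(i)] for i in kept])
    core_aln = _restrict(sub, kept)
    if len(core) >= 2 and cfg.msa_refine_sweeps > 0:
        core_aln = gibbs_sweep(core, core_aln, rng, prior, n_sweeps=cfg.msa_refine_sweeps)
    if cfg.refine_architecture:
        core_aln = adjust_architecture(
            core, core_aln, prior, path_bits_per_seq=cfg.path_bits_per_seq
        )
    # re-thread everything (kept rows keep their sampled paths; purged rows
    # are Viterbi-aligned against the refined profile)
    w = core_aln.num_columns
    counts = count_all_columns(core, core_aln)
    tc = core_aln.transition_counts()
    mm = np.full((len(subset), w), -1, dtype=np.int64)
    for r, i in enumerate(kept):
        mm[i] = core_aln.match_map[r]
    for i in purged:
        mm[i] = viterbi_align(subset[int(i)].codes, counts, tc, prior)
    out = AlignmentState(mm, sub.seq_lengths)
    out.check()
    return out


# ----------------------------------------------------------------------
# Templates and ownership
# ----------------------------------------------------------------------

def build_template(
    parent_aln: AlignmentState,
    parent_rows: np.ndarray,
    child_aln: AlignmentState,
    child_rows: np.ndarray,
) -> dict:
    """Map child sub-alignment columns to parent columns via the residue
    coordinates of the shared sequences (majority vote); child-only insert
    columns map to None."""
    pos_of = {int(k): r for r, k in enumerate(parent_rows)}
    shared = [int(k) for k in child_rows if int(k) in pos_of]
    template: dict[int, int | None] = {}
    for c in range(child_aln.num_columns):
        votes: dict[int | None, int] = {}
        for r_child, k in enumerate(child_rows):
            k = int(k)
            if k not in pos_of:
                continue
            p = child_aln.match_map[r_child, c]
            if p < 0:
                continue
            prow = parent_aln.match_map[pos_of[k]]
            hit = np.nonzero(prow == p)[0]
            tgt = int(hit[0]) if hit.size else None
            votes[tgt] = votes.get(tgt, 0) + 1
        if votes:
            template[c] = max(votes, key=votes.get)
        else:
            template[c] = None
    del shared
    return template


def build_templates(hm: HiMSA) -> dict:
    """Templates for every parent-child pair of the hierarchy."""
    H = hm.hierarchy
    out = {}
    for node in H.parent:
        par = H.parent[node]
        if par is None or node == H.reject:
            continue
        if node not in hm.sub_alignments or par not in hm.sub_alignments:
            continue
        out[node] = build_template(
            hm.sub_alignments[par], hm.node_rows[par],
            hm.sub_alignments[node], hm.node_rows[node],
        )
    hm.templates = out
    return out


def compose_to_root(hm: HiMSA, node: int, col: int):
    """Follow templates up the lineage; returns the root column or None if
    the column is a lineage-local insert."""
    H = hm.hierarchy
    cur = col
    while H.parent[node] is not None:
        t = hm.templates.get(node)
        if t is None:
            return None
        cur = t.get(cur)
        if cur is None:
            return None
        node = H.parent[node]
    return cur


def assign_ownership(hm: HiMSA, patterns: PatternSet) -> dict:
    """Each discriminating root column is owned by the shallowest node whose
    pattern includes it; the root owns everything else."""
    H = hm.hierarchy
    root_w = hm.sub_alignments[H.root].num_columns
    owner = {j: H.root for j in range(root_w)}
    by_depth = sorted(
        (n for n in H.parent if n != H.reject), key=H.depth
    )
    for node in by_depth:
        for j in patterns.columns(node):
            if j in owner and owner[j] == H.root and node != H.root:
                owner[j] = node
    hm.ownership = owner
    return owner


# ----------------------------------------------------------------------
# Pattern search within subgroup-specific insert regions
# ----------------------------------------------------------------------

def pattern_search_insert_regions(
    hm: HiMSA,
    node: int,
    seqs: SequenceSet,
    cfg: SamplerConfig,
    rng: np.random.Generator,
    alpha: float = 0.05,
) -> dict:
    """Look for discriminating residues in the node's insert columns.

    Insert columns are absent from the background alignment, so standard
    amino-acid frequencies serve as the background; a column is selected
    when its foreground log2-ratio gain beats the pattern selection cost.
    """
    H = hm.hierarchy
    if node == H.root or node == H.reject:
        return {}
    aln = hm.sub_alignments.get(node)
    t = hm.templates.get(node)
    if aln is None or t is None:
        return {}
    rows = hm.node_rows[node]
    subset = SequenceSet([seqs[int(k)] for k in rows])
    counts = count_all_columns(subset, aln)
    catalog = allowed_residue_sets(cfg.set_prior_decay)
    p = cfg.pattern_prior
    found = {}
    for c in range(aln.num_columns):
        if t.get(c) is not None:
            continue  # not an insert column
        cc = counts[c]
        tot = cc.sum()
        if tot <= 0:
            continue
        consensus = int(np.argmax(cc))
        best = None
        for rset, pri in sets_containing(catalog, consensus):
            from .bpps_model import mixed_foreground

            fmix = mixed_foreground(rset, BACKGROUND, alpha)
            ratio = (np.log(fmix) - np.log(BACKGROUND)) / LOG2
            gain = float(cc @ ratio) + np.log2(p * pri) - np.log2(1 - p)
            if best is None or gain > best[0]:
                best = (gain, rset)
        if best is not None and best[0] > 0:
            found[c] = best[1]
    if found:
        hm.insert_patterns[node] = {**hm.insert_patterns.get(node, {}), **found}
    return found


# ----------------------------------------------------------------------
# hiHMM assembly
# ----------------------------------------------------------------------

def assemble_hihmm(
    hm: HiMSA,
    patterns: PatternSet,
    seqs: SequenceSet,
) -> HiHMM:
    """Per-node HMM emission tables with lineage-specific estimation and
    node weights proportional to down-weighted assigned-sequence fractions."""
    H = hm.hierarchy
    assign_ownership(hm, patterns)
    out = HiHMM(hierarchy=H)
    # subtree counts at root coordinates
    root_aln = hm.sub_alignments[H.root]
    root_rows = hm.node_rows[H.root]
    subtree_counts = {}
    for node in H.parent:
        if node == H.reject:
            continue
        members = set(int(i) for i in H.subtree_sequences(node))
        rows = np.array([r for r, k in enumerate(root_rows) if int(k) in members])
        sub = SequenceSet([seqs[int(root_rows[r])] for r in rows])
        subtree_counts[node] = count_all_columns(sub, _restrict(root_aln, rows)) if rows.size else np.zeros((root_aln.num_columns, N_AA))
    for node in H.parent:
        if node == H.reject:
            continue
        aln = hm.sub_alignments[node]
        rows = hm.node_rows[node]
        subset = SequenceSet([seqs[int(k)] for k in rows])
        local_counts = count_all_columns(subset, aln)
        E = np.zeros((aln.num_columns, N_AA))
        owners = []
        lineage = H.lineage(node)
        for c in range(aln.num_columns):
            root_col = compose_to_root(hm, node, c) if node != H.root else c
            if root_col is None:
                owner = node  # lineage-local insert column
                cc = local_counts[c]
            else:
                # ownership is resolved along this node's lineage: the
                # shallowest ancestor whose pattern claims the column owns
                # it here, even if a sibling subtree also claims it
                owner = H.root
                for anc in lineage:
                    if anc != H.root and root_col in patterns.columns(anc):
                        owner = anc
                        break
                cc = subtree_counts[owner][root_col]
            owners.append(owner)
            E[c] = (cc + BACKGROUND) / (cc.sum() + 1.0)
        out.emissions[node] = E
        out.columns_owner[node] = owners
    wsum = 0.0
    raw = {}
    for node in H.parent:
        if node == H.reject:
            continue
        own = H.node_sequences(node)
        raw[node] = float(sum(seqs[int(i)].weight for i in own))
        wsum += raw[node]
    if wsum <= 0:
        raw = {n: 1.0 for n in raw}
        wsum = float(len(raw))
    out.weights = {n: v / wsum for n, v in raw.items()}
    return out


# ----------------------------------------------------------------------
# Projection of refined sub-alignments back to root coordinates
# ----------------------------------------------------------------------

def _legalize_row(row: np.ndarray, L: int) -> np.ndarray:
    """Repair a match-map row so insert runs never abut deletions.

    Residues stranded between matches that are separated by deleted
    columns are promoted into the deleted columns nearest the downstream
    match (nearest the upstream match for the trailing segment), which
    always yields a legal profile-HMM path.
    """
    row = row.copy()
    w = row.shape[0]
    matched = [j for j in range(w) if row[j] >= 0]
    # inter-match and leading segments: fill deleted columns adjacent to
    # the downstream match with the run residues adjacent to it
    prev_pos = -1
    prev_col = -1
    for j in matched:
        p = int(row[j])
        run = p - prev_pos - 1
        deleted = list(range(prev_col + 1, j))
        m = min(run, len(deleted))
        if m > 0:
            for i in range(m):
                row[deleted[len(deleted) - m + i]] = p - m + i
        prev_pos = p
        prev_col = j
    # trailing segment: fill deleted columns adjacent to the last match
    run = L - prev_pos - 1
    deleted = list(range(prev_col + 1, w))
    m = min(run, len(deleted))
    for i in range(m):
        row[deleted[i]] = prev_pos + 1 + i
    return row


def project_to_root(hm: HiMSA, root_aln: AlignmentState) -> AlignmentState:
    """Rewrite the root alignment using the refined sub-alignments.

    Every sequence that belongs to a refined node has its root row rebuilt
    by carrying each sub-alignment column through the composed templates to
    its root column; sub-alignment columns without a root counterpart
    (regions first made coherent inside the subgroup) are *inserted* into
    the root architecture after their nearest mapped neighbour, so they
    become visible to family-level pattern selection and to sequences
    outside the subgroup.  All rows are legalised afterwards.
    """
    H = hm.hierarchy
    K, w = root_aln.match_map.shape
    nodes = [n for n in sorted(hm.sub_alignments, key=H.depth) if n != H.root]
    root_cols = {
        node: [
            compose_to_root(hm, node, c)
            for c in range(hm.sub_alignments[node].num_columns)
        ]
        for node in nodes
    }
    # plan insertion of unmapped sub columns: anchor = nearest mapped root
    # column to the left (-1 for none)
    inserts: dict[int, list] = {}  # anchor -> [(node, sub_col), ...]
    slot_of: dict[tuple, int] = {}
    for node in nodes:
        anchor = -1
        for c, rc in enumerate(root_cols[node]):
            if rc is not None:
                anchor = rc
            else:
                inserts.setdefault(anchor, []).append((node, c))
    # new column layout: for anchor a, inserted columns follow column a
    new_w = w + sum(len(v) for v in inserts.values())
    old_to_new = np.zeros(w, dtype=np.int64)
    pos = 0
    for ins in inserts.get(-1, []):
        slot_of[ins] = pos
        pos += 1
    for j in range(w):
        old_to_new[j] = pos
        pos += 1
        for ins in inserts.get(j, []):
            slot_of[ins] = pos
            pos += 1
    assert pos == new_w
    # re-index everybody's existing rows
    new_map = np.full((K, new_w), -1, dtype=np.int64)
    new_map[:, old_to_new] = root_aln.match_map
    # rebuild rows of refined-node members (deeper nodes overwrite)
    for node in nodes:
        rows = hm.node_rows[node]
        sub = hm.sub_alignments[node]
        rcs = root_cols[node]
        for r, k in enumerate(rows):
            k = int(k)
            newrow = np.full(new_w, -1, dtype=np.int64)
            last_col = -1
            last_pos = -1
            for c in range(sub.num_columns):
                p = sub.match_map[r, c]
                if p < 0:
                    continue
                rc = rcs[c]
                tgt = old_to_new[rc] if rc is not None else slot_of[(node, c)]
                if tgt > last_col and p > last_pos:
                    newrow[tgt] = p
                    last_col, last_pos = int(tgt), int(p)
            new_map[k] = newrow
    for k in range(K):
        new_map[k] = _legalize_row(new_map[k], int(root_aln.seq_lengths[k]))
    out = AlignmentState(new_map, root_aln.seq_lengths)
    out.check()
    return out


# ----------------------------------------------------------------------
# Driver used by the sampler pipeline
# ----------------------------------------------------------------------

def build_himsa(
    seqs: SequenceSet,
    aln: AlignmentState,
    H: Hierarchy,
    cfg: SamplerConfig,
    rng: np.random.Generator,
) -> HiMSA:
    """Recursive subgroup realignment from the root's children downward."""
    hm = HiMSA(hierarchy=H)
    all_rows = np.arange(len(seqs), dtype=np.int64)
    reject_rows = set(int(i) for i in H.node_sequences(H.reject))
    root_rows = np.array([i for i in all_rows if int(i) not in reject_rows], dtype=np.int64)
    hm.node_rows[H.root] = root_rows
    hm.sub_alignments[H.root] = _restrict(aln, root_rows)
    order = sorted((n for n in H.parent if n not in (H.root, H.reject)), key=H.depth)
    for node in order:
        members = set(int(i) for i in H.subtree_sequences(node))
        rows = np.array([i for i in all_rows if int(i) in members], dtype=np.int64)
        if rows.size == 0:
            continue
        par = H.parent[node]
        par_rows = hm.node_rows.get(par)
        par_aln = hm.sub_alignments.get(par)
        if par_aln is None:
            continue
        # positions of this node's sequences within the parent's rows
        lut = {int(k): r for r, k in enumerate(par_rows)}
        local = np.array([lut[int(k)] for k in rows if int(k) in lut], dtype=np.int64)
        rows = np.array([int(k) for k in rows if int(k) in lut], dtype=np.int64)
        hm.node_rows[node] = rows
        subset = SequenceSet([seqs[int(k)] for k in rows])
        hm.sub_alignments[node] = (
            refine_subgroup_alignment(subset, par_aln, local, cfg, rng)
            if rows.size >= 2
            else _restrict(par_aln, local)
        )
    build_templates(hm)
    return hm


def refine_himsa(
    seqs: SequenceSet,
    aln: AlignmentState,
    state,
    cfg: SamplerConfig,
    rng: np.random.Generator,
    project: bool = True,
):
    """Pipeline step: build the hierarchical MSA, search insert regions for
    extra patterns, project the refinements back into the root alignment,
    and return (state, root alignment, HiMSA)."""
    hm = build_himsa(seqs, aln, state.H, cfg, rng)
    for node in state.H.parent:
        if node in (state.H.root, state.H.reject):
            continue
        pattern_search_insert_regions(hm, node, seqs, cfg, rng)
    assign_ownership(hm, state.patterns)
    if project and len(hm.sub_alignments) > 1:
        aln = project_to_root(hm, aln)
    return state, aln, hm
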