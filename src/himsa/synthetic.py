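"""Planted hierarchical models: generate sequences with known structure.

A planted model fixes a small hierarchy, per-node discriminating columns
with residue sets and conservation strengths, a background composition and
an indel rate.  Emitting from it yields sequences together with their true
node labels and true alignment, so hierarchy recovery, pattern recovery and
alignment accuracy can all be scored offline against a known truth.

The emulated process mirrors the generative reading of the hierarchical
HMM: a sequence assigned to node ``z`` emits, at each core column, either a
residue from the pattern-set distribution of the shallowest owning node on
its lineage (with the planted conservation strength) or a background draw;
indels perturb the path at a small rate.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from sklearn.metrics import adjusted_rand_score

from .alphabet import AA, AA_INDEX, BACKGROUND, N_AA
from .bpps_model import Hierarchy, PatternSet, pattern_set_distribution
from .seqio import SequenceRecord, SequenceSet
from .state import AlignmentState


@dataclass
class PlantedModel:
    """Realised planted model: tree, patterns, emissions, sizes."""

    hierarchy: Hierarchy
    patterns: PatternSet  # node -> {col: frozenset of residue codes}
    strengths: dict  # node -> probability mass on the set at its columns
    node_counts: dict  # node -> number of sequences to emit
    core_length: int
    background: np.ndarray
    indel_rate: float
    insert_regions: dict = field(default_factory=dict)  # node -> [(slot, length)]
    seed: int = 0

    def emission_table(self, node: int) -> np.ndarray:
        """(core_length, 20) lineage-specific emission distribution for a
        node: pattern columns owned by the shallowest lineage node carrying
        them use the strength-mixed set distribution; all else background."""
        tab = np.tile(self.background, (self.core_length, 1))
        for anc in self.hierarchy.lineage(node):
            s = self.strengths.get(anc, 0.9)
            for j, rset in self.patterns.columns(anc).items():
                tab[j] = s * pattern_set_distribution(rset) + (1 - s) * self.background
        return tab


#: Default planted conditions: three subgroups of 60 sequences over a
#: 120-column core, 8 discriminating columns per subgroup at conservation
#: 0.9, indel rate 0.02 — plus 12 root-level (family-wide) conserved
#: columns emulating the canonical residues that define a superfamily's
#: shared core.  Without family-wide conservation the sequences would not
#: constitute a homologous family at all and no aligner could anchor them.
DEFAULT_SPEC = {
    "n_leaves": 3,
    "seqs_per_leaf": 60,
    "core_length": 120,
    "patterns_per_leaf": 8,
    "strength": 0.9,
    "indel_rate": 0.02,
    "root_patterns": 12,
    "height_limit": 5,
}


def load_spec(path) -> dict:
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    merged = dict(DEFAULT_SPEC)
    merged.update(spec or {})
    return merged


def plant(spec: dict | None = None, seed: int = 0) -> PlantedModel:
    """Realise a planted model from a spec dict; deterministic given seed."""
    spec = {**DEFAULT_SPEC, **(spec or {})}
    rng = np.random.default_rng(seed)
    n_leaves = int(spec["n_leaves"])
    core = int(spec["core_length"])
    per_leaf = int(spec["patterns_per_leaf"])
    n_root = int(spec.get("root_patterns", 0))
    if n_leaves < 0 or core < 1:
        raise ValueError("invalid planted spec")
    H = Hierarchy.trivial(0, height_limit=int(spec["height_limit"]))
    leaves = []
    for _ in range(n_leaves):
        nid = H.new_node_id()
        H.parent[nid] = H.root
        leaves.append(nid)
    need = n_root + n_leaves * per_leaf
    if need > core:
        raise ValueError("more pattern columns requested than core columns")
    cols = rng.choice(core, size=need, replace=False)
    patterns = PatternSet(max_patterns=max(25, per_leaf, n_root))
    strengths = {}
    ptr = 0
    aas = list(range(N_AA))

    def random_singleton():
        return frozenset({int(rng.choice(aas))})

    if n_root:
        patterns.set_node(
            H.root, {int(c): random_singleton() for c in cols[:n_root]}
        )
        strengths[H.root] = float(spec["strength"])
        ptr = n_root
    for leaf in leaves:
        sel = cols[ptr : ptr + per_leaf]
        ptr += per_leaf
        patterns.set_node(leaf, {int(c): random_singleton() for c in sel})
        strengths[leaf] = float(spec["strength"])
    node_counts = {leaf: int(spec["seqs_per_leaf"]) for leaf in leaves}
    if n_leaves == 0:
        node_counts[H.root] = int(spec.get("seqs_per_leaf", 60))
    insert_regions = {
        int(n): [(int(s), int(l)) for s, l in regions]
        for n, regions in (spec.get("insert_regions") or {}).items()
    }
    return PlantedModel(
        hierarchy=H,
        patterns=patterns,
        strengths=strengths,
        node_counts=node_counts,
        core_length=core,
        background=BACKGROUND.copy(),
        indel_rate=float(spec["indel_rate"]),
        insert_regions=insert_regions,
        seed=seed,
    )


def emit(
    planted: PlantedModel, seed: int = 0
) -> tuple[SequenceSet, np.ndarray, AlignmentState]:
    """Sample sequences from the planted model.

    Returns the sequences, the true node label per sequence, and the true
    alignment of every sequence against the planted core columns.  Indels
    are placed so that every path is legal for a profile HMM without
    insert<->delete transitions.
    """
    rng = np.random.default_rng(seed)
    H = planted.hierarchy
    w = planted.core_length
    d = planted.indel_rate
    records, labels, maps, lengths = [], [], [], []
    sid = 0
    for node in sorted(planted.node_counts):
        tab = planted.emission_table(node)
        regions = planted.insert_regions.get(node, [])
        for _ in range(planted.node_counts[node]):
            deleted = rng.random(w) < d
            matched = ~deleted
            # insert runs: only after a matched column (or start) and before
            # a matched column (or end), so paths stay legal
            residues = []
            row = np.full(w, -1, dtype=np.int64)
            pos = 0

            def legal_slot(j):  # run preceding column j (0..w)
                prev_ok = j == 0 or matched[j - 1]
                nxt_ok = j == w or matched[j]
                return prev_ok and nxt_ok

            region_at = {slot: length for slot, length in regions}
            for j in range(w + 1):
                n_ins = 0
                if j in region_at and legal_slot(j):
                    n_ins += region_at[j]
                if legal_slot(j) and rng.random() < d:
                    n_ins += int(rng.geometric(0.5))
                for _ in range(n_ins):
                    residues.append(int(rng.choice(N_AA, p=BACKGROUND)))
                    pos += 1
                if j < w and matched[j]:
                    residues.append(int(rng.choice(N_AA, p=tab[j])))
                    row[j] = pos
                    pos += 1
            if not residues:  # fully deleted sequence: force one match
                jmid = w // 2
                residues.append(int(rng.choice(N_AA, p=tab[jmid])))
                row[:] = -1
                row[jmid] = 0
            seq = "".join(AA[c] for c in residues)
            records.append(
                SequenceRecord(id=f"s{sid:04d}", description=f"s{sid:04d} node={node}", residues=seq)
            )
            labels.append(node)
            maps.append(row)
            lengths.append(len(seq))
            sid += 1
    seqs = SequenceSet(records)
    aln = AlignmentState(np.array(maps), np.array(lengths))
    aln.check()
    return seqs, np.array(labels), aln


def emit_null(
    n_sequences: int = 100, length: int = 100, seed: int = 0
) -> SequenceSet:
    """Sequences drawn i.i.d. from the background composition (no signal)."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_sequences):
        codes = rng.choice(N_AA, size=length, p=BACKGROUND)
        records.append(
            SequenceRecord(id=f"n{i:04d}", description=f"n{i:04d}", residues="".join(AA[c] for c in codes))
        )
    return SequenceSet(records)


# ----------------------------------------------------------------------
# Recovery scoring
# ----------------------------------------------------------------------

def map_columns(truth: AlignmentState, inferred: AlignmentState) -> dict:
    """Map inferred match columns to true core columns by majority vote of
    the sequence positions they align."""
    K, w_t = truth.match_map.shape
    _, w_i = inferred.match_map.shape
    # per sequence: position -> true column
    pos_to_true = []
    for k in range(K):
        lut = {}
        for j in range(w_t):
            p = truth.match_map[k, j]
            if p >= 0:
                lut[int(p)] = j
        pos_to_true.append(lut)
    mapping = {}
    for j in range(w_i):
        votes = {}
        for k in range(K):
            p = inferred.match_map[k, j]
            if p >= 0:
                t = pos_to_true[k].get(int(p))
                if t is not None:
                    votes[t] = votes.get(t, 0) + 1
        if votes:
            mapping[j] = max(votes, key=votes.get)
    return mapping


def score_recovery(
    truth_labels: np.ndarray,
    planted: PlantedModel,
    inferred_h: Hierarchy,
    inferred_patterns: PatternSet,
    truth_aln: AlignmentState | None = None,
    inferred_aln: AlignmentState | None = None,
) -> dict:
    """Score an inferred hierarchy against the planted truth.

    Returns adjusted Rand index of leaf assignments, pattern-column recall
    and precision (a planted column is recovered when some inferred node
    selects the corresponding column with an overlapping residue set), and,
    when both alignments are given, column accuracy on the core columns.
    """
    inferred_labels = inferred_h.assignment
    if inferred_labels is None or len(inferred_labels) != len(truth_labels):
        raise ValueError("inferred assignment missing or of wrong length")
    ari = float(adjusted_rand_score(truth_labels, inferred_labels))

    col_map = None
    if truth_aln is not None and inferred_aln is not None:
        col_map = map_columns(truth_aln, inferred_aln)

    def inferred_selects(true_col: int, rset: frozenset) -> bool:
        for node, cols in inferred_patterns.patterns.items():
            for jc, iset in cols.items():
                jt = jc if col_map is None else col_map.get(jc)
                if jt == true_col and (iset & rset):
                    return True
        return False

    planted_cols = []
    for node, cols in planted.patterns.patterns.items():
        for j, rset in cols.items():
            planted_cols.append((j, rset))
    recovered = sum(1 for j, rset in planted_cols if inferred_selects(j, rset))
    recall = recovered / len(planted_cols) if planted_cols else 1.0

    inferred_cols = []
    for node, cols in inferred_patterns.patterns.items():
        for jc, iset in cols.items():
            jt = jc if col_map is None else col_map.get(jc)
            inferred_cols.append((jt, iset))
    truth_lookup = {}
    for j, rset in planted_cols:
        truth_lookup.setdefault(j, set()).update(rset)
    hits = sum(
        1
        for jt, iset in inferred_cols
        if jt is not None and (truth_lookup.get(jt, set()) & iset)
    )
    precision = hits / len(inferred_cols) if inferred_cols else 1.0

    out = {"ari": ari, "pattern_recall": recall, "pattern_precision": precision}
    if col_map is not None and truth_aln is not None:
        agree = tot = 0
        K, w_i = inferred_aln.match_map.shape
        for jc, jt in col_map.items():
            for k in range(K):
                p_t = truth_aln.match_map[k, jt]
                if p_t >= 0:
                    tot += 1
                    if inferred_aln.match_map[k, jc] == p_t:
                        agree += 1
        out["column_accuracy"] = agree / tot if tot else 1.0
    return out
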