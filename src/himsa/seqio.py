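"""Sequence and alignment IO, redundancy down-weighting, residue counting.

Sequences are plain FASTA; alignments use the A2M dialect of aligned FASTA
(uppercase = match column, lowercase = insert, '-' = deletion, '.' ignored
padding), which encodes each sequence's HMM path directly.  Coordinates are
1-based in user-facing output and 0-based internally.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .alphabet import AA_INDEX, N_AA, clean_residues, encode
from .state import AlignmentState, a2m_to_state


class FastaFormatError(ValueError):
    pass


@dataclass
class SequenceRecord:
    """A weighted protein sequence over the 20 amino acids plus 'X'."""

    id: str
    description: str
    residues: str
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r}: empty residue string")
        if not (0 < self.weight <= 1):
            raise ValueError(f"sequence {self.id!r}: weight must be in (0, 1]")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def codes(self) -> np.ndarray:
        return encode(self.residues)


@dataclass
class SequenceSet:
    """Ordered collection of SequenceRecords with unique ids."""

    records: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for r in self.records:
            if r.id in seen:
                raise FastaFormatError(f"duplicate sequence id {r.id!r}")
            seen.add(r.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i: int) -> SequenceRecord:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def weights(self) -> np.ndarray:
        return np.array([r.weight for r in self.records])

    @property
    def effective_size(self) -> float:
        return float(sum(r.weight for r in self.records))

    @property
    def lengths(self) -> np.ndarray:
        return np.array([len(r) for r in self.records], dtype=np.int64)

    def codes_list(self) -> list[np.ndarray]:
        return [r.codes for r in self.records]


# ----------------------------------------------------------------------
# FASTA / A2M
# ----------------------------------------------------------------------

def _check_fasta_shape(text: str) -> None:
    """Pre-scan raw FASTA text so format errors can name the line."""
    saw_header = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        s = line.strip()
        if not s:
            continue
        if s.startswith(">"):
            if len(s) == 1:
                raise FastaFormatError(f"line {lineno}: empty FASTA header")
            saw_header = True
        elif not saw_header:
            raise FastaFormatError(
                f"line {lineno}: sequence data before any FASTA header"
            )
    if not saw_header:
        raise FastaFormatError("line 1: no FASTA records found (empty file?)")


def read_fasta(path: str | Path) -> SequenceSet:
    """Read unaligned protein FASTA; weights initialised to 1."""
    text = Path(path).read_text()
    _check_fasta_shape(text)
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        residues = clean_residues(str(rec.seq).replace("-", "").replace(".", ""))
        records.append(
            SequenceRecord(id=rec.id, description=rec.description, residues=residues)
        )
    return SequenceSet(records)


def write_fasta(seqs: SequenceSet, path: str | Path, wrap: int = 60) -> None:
    recs = [
        _BioRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in seqs
    ]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")
    del wrap  # Biopython wraps at 60; parameter kept for interface stability


def read_a2m(path: str | Path) -> tuple[SequenceSet, AlignmentState]:
    """Read an A2M alignment; returns sequences (ungapped) and the state."""
    text = Path(path).read_text()
    _check_fasta_shape(text)
    ids, descs, rows = [], [], []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        ids.append(rec.id)
        descs.append(rec.description)
        rows.append(str(rec.seq))
    state, ungapped = a2m_to_state(rows)
    records = [
        SequenceRecord(id=i, description=d, residues=clean_residues(s))
        for i, d, s in zip(ids, descs, ungapped)
    ]
    return SequenceSet(records), state


def write_a2m(seqs: SequenceSet, aln: AlignmentState, path: str | Path) -> None:
    with open(path, "w") as fh:
        for k, r in enumerate(seqs):
            fh.write(f">{r.description or r.id}\n")
            fh.write(aln.to_a2m_row(k, r.residues) + "\n")


def write_weights_tsv(seqs: SequenceSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tweight\n")
        for r in seqs:
            fh.write(f"{r.id}\t{r.weight:.6f}\n")


def banded_similarity(
    seqs: SequenceSet,
    band: int = 6,
    gap_cost: float = 3.0,
    mismatch: float = 1.0,
) -> np.ndarray:
    """Alignment-free pairwise similarity tolerant to small indel jitter.

    A banded global alignment DP (diagonal offset limited to ``band``) is
    run between every pair, vectorised over partners; matches are rewarded
    by residue rarity (-log background frequency), so shared conserved
    residues dominate over chance identity.  Used to seed subgroup growth
    before any trustworthy alignment exists.
    """
    from .alphabet import BACKGROUND

    K = len(seqs)
    L = int(seqs.lengths.max())
    A = np.full((K, L), -1, dtype=np.int64)
    for k, rec in enumerate(seqs):
        c = rec.codes
        A[k, : c.shape[0]] = c
    rarity = -np.log(BACKGROUND)
    W = 2 * band + 1
    NEG = -1e9
    sim = np.zeros((K, K))
    lens = seqs.lengths
    pad = np.full((K, band + 1), -2, dtype=np.int64)  # never matches
    Apad = np.concatenate([pad[:, :band], A, pad], axis=1)  # shift-safe
    for i in range(K):
        Li = int(lens[i])
        a = A[i, :Li]
        # H[j, b]: best score having consumed a[:p] and partner[:p+d],
        # diagonal offset d = b - band
        H = np.full((K, W), NEG)
        H[:, band] = 0.0
        for b in range(band + 1, W):  # leading gaps in a (consume b only)
            H[:, b] = H[:, b - 1] - gap_cost * (b - band)
        for p in range(Li):
            if a[p] >= 0:
                block = Apad[:, p : p + W] == a[p]  # columns are offsets
                M = np.where(block, rarity[a[p]], -mismatch)
            else:
                M = np.full((K, W), -mismatch)
            newH = H + M  # consume both at same offset
            # consume a[p] against a gap in partner: offset decreases
            newH[:, :-1] = np.maximum(newH[:, :-1], H[:, 1:] - gap_cost)
            # consume partner residue against gap in a: offset increases
            for b in range(1, W):
                newH[:, b] = np.maximum(newH[:, b], newH[:, b - 1] - gap_cost)
            H = newH
        # close at the partner's true end (d must equal len_j - len_i);
        # out-of-band length differences pay linear tail gaps
        out = np.full(K, NEG)
        for b in range(W):
            d = b - band
            tail = np.abs(lens - (Li + d))
            out = np.maximum(out, H[:, b] - gap_cost * tail)
        sim[i] = out
    return (sim + sim.T) / 2.0


# ----------------------------------------------------------------------
# Counting and weighting
# ----------------------------------------------------------------------

def count_column(
    seqs: SequenceSet, aln: AlignmentState, j: int, weighted: bool = True
) -> np.ndarray:
    """Weighted residue counts for match column j (0-based internally).

    Sequences with a deletion at j and 'X' residues contribute nothing.
    """
    w = aln.num_columns
    if not (0 <= j < w):
        raise IndexError(f"column {j} out of range 0..{w - 1}")
    counts = np.zeros(N_AA)
    for k, rec in enumerate(seqs):
        p = aln.match_map[k, j]
        if p < 0:
            continue
        code = AA_INDEX.get(rec.residues[p], -1)
        if code < 0:
            continue
        counts[code] += rec.weight if weighted else 1.0
    return counts


def count_all_columns(
    seqs: SequenceSet, aln: AlignmentState, weighted: bool = True
) -> np.ndarray:
    """(w, 20) matrix of per-column weighted counts; vectorised."""
    K, w = aln.match_map.shape
    counts = np.zeros((w, N_AA))
    weights = seqs.weights if weighted else np.ones(K)
    for k, rec in enumerate(seqs):
        row = aln.match_map[k]
        mask = row >= 0
        codes = rec.codes[row[mask]]
        ok = codes >= 0
        cols = np.nonzero(mask)[0][ok]
        np.add.at(counts, (cols, codes[ok]), weights[k])
    return counts


def compute_weights(
    seqs: SequenceSet, aln: AlignmentState, identity: float = 0.62
) -> SequenceSet:
    """Redundancy down-weighting by identity clustering over match columns.

    Sequences are single-linkage clustered at >= ``identity`` fractional
    identity (computed over columns where both are aligned), and each
    sequence receives weight 1/|its cluster|, so a cluster of near-copies
    contributes one effectively independent sequence while mutually
    dissimilar sequences keep weight 1.  Deterministic, order-independent
    (the clustering is symmetric) and permutation-equivariant.
    """
    K, w = aln.match_map.shape
    if w == 0:
        raise ValueError("cannot weight sequences: alignment has zero match columns")
    if len(seqs) != K:
        raise ValueError("sequence/alignment size mismatch")
    # code matrix at match columns
    X = np.full((K, w), -1, dtype=np.int64)
    for k, rec in enumerate(seqs):
        row = aln.match_map[k]
        mask = row >= 0
        X[k, mask] = rec.codes[row[mask]]
    # union-find single linkage
    parent = list(range(K))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    present = X >= 0
    for i in range(K):
        for j in range(i + 1, K):
            both = present[i] & present[j]
            n = int(both.sum())
            if n == 0:
                continue
            ident = float((X[i, both] == X[j, both]).sum()) / n
            if ident >= identity:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    sizes: dict[int, int] = {}
    for k in range(K):
        sizes[find(k)] = sizes.get(find(k), 0) + 1
    records = [
        SequenceRecord(r.id, r.description, r.residues, 1.0 / sizes[find(k)])
        for k, r in enumerate(seqs)
    ]
    return SequenceSet(records)
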