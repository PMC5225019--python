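"""Alignment state: match-column map, implied HMM paths and transition counts.

An alignment of K sequences against a profile of ``w`` match columns is
stored as a K x w integer matrix ``match_map``: entry (k, j) is the 0-based
sequence position aligned to match column j, or -1 for a deletion.  Runs of
unconsumed residues between consecutive matched positions are insert-state
emissions; residues before the first and after the last matched position
are emitted by the flanking insert states I_0 and I_w.

The profile HMM has states Begin, M_j, I_j, D_j, End with the seven
transition types M->M, M->I, M->D, I->M, I->I, D->M, D->D (no I<->D
transitions).  Consequently an insert run may only directly follow a match
state: a map placing residues between two match columns that are separated
by a deletion is rejected as inconsistent.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class AlignmentError(ValueError):
    """Raised when an alignment state violates its invariants."""


# Transition type order used throughout: indexes into count arrays.
TRANS_TYPES = ("mm", "mi", "md", "im", "ii", "dm", "dd")


@dataclass
class TransitionPriors:
    """Pseudocounts for the seven position-specific transition types.

    Defaults strongly favour match continuation (transitions into match
    states carry pseudocount 10, all others 1), making gaps implicitly
    costly while remaining data-driven once real transitions accumulate.
    """

    n_mm: float = 10.0
    n_mi: float = 1.0
    n_md: float = 1.0
    n_im: float = 10.0
    n_ii: float = 1.0
    n_dm: float = 10.0
    n_dd: float = 1.0

    def __post_init__(self) -> None:
        for name in ("n_mm", "n_mi", "n_md", "n_im", "n_ii", "n_dm", "n_dd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"transition prior {name} must be positive")

    @property
    def n_m(self) -> float:
        return self.n_mm + self.n_mi + self.n_md

    @property
    def n_i(self) -> float:
        return self.n_im + self.n_ii

    @property
    def n_d(self) -> float:
        return self.n_dm + self.n_dd


@dataclass
class TransitionCounts:
    """Per-position transition counts N_xy[j] for j = 0..w (w+1 slots).

    Index j holds transitions out of the states at column j; the Begin
    state occupies column 0 (treated as a match), End is entered from
    column w.
    """

    counts: np.ndarray  # shape (7, w+1), order TRANS_TYPES
    priors: TransitionPriors = field(default_factory=TransitionPriors)

    @property
    def w(self) -> int:
        return self.counts.shape[1] - 1

    def __getitem__(self, kind: str) -> np.ndarray:
        return self.counts[TRANS_TYPES.index(kind)]

    def check(self) -> None:
        if self.counts.shape[0] != 7:
            raise AlignmentError("transition count array must have 7 rows")
        if np.any(self.counts < 0):
            raise AlignmentError("negative transition count")


@dataclass
class AlignmentState:
    """Match-column map plus derived per-sequence HMM paths."""

    match_map: np.ndarray  # (K, w) int, -1 = deletion
    seq_lengths: np.ndarray  # (K,) int

    def __post_init__(self) -> None:
        self.match_map = np.asarray(self.match_map, dtype=np.int64)
        self.seq_lengths = np.asarray(self.seq_lengths, dtype=np.int64)

    @property
    def num_sequences(self) -> int:
        return self.match_map.shape[0]

    @property
    def num_columns(self) -> int:
        return self.match_map.shape[1]

    def copy(self) -> "AlignmentState":
        return AlignmentState(self.match_map.copy(), self.seq_lengths.copy())

    # ------------------------------------------------------------------
    def check(self) -> None:
        """Validate invariants; raises AlignmentError naming the offender."""
        K, w = self.match_map.shape
        if self.seq_lengths.shape != (K,):
            raise AlignmentError("seq_lengths/match_map shape mismatch")
        for k in range(K):
            row = self.match_map[k]
            defined = row[row >= 0]
            if np.any(defined >= self.seq_lengths[k]):
                raise AlignmentError(f"sequence {k}: aligned position out of range")
            if np.any(np.diff(defined) <= 0):
                raise AlignmentError(f"sequence {k}: match positions not increasing")
            # walk to verify insert runs only follow matches
            self._events(k)

    def _events(self, k: int):
        """Yield per-column path events for sequence k.

        Events are tuples (j, kind, n_ins) where kind is 'M' or 'D' for the
        state entered at column j (1-based; j = w+1 denotes End) and n_ins
        is the size of the insert run emitted at I_{j-1} just before it.
        """
        row = self.match_map[k]
        w = row.shape[0]
        pos = 0
        prev = "M"
        events = []
        for j in range(1, w + 1):
            p = row[j - 1]
            if p >= 0:
                nins = int(p) - pos
                if nins < 0:
                    raise AlignmentError(f"sequence {k}: position reused at column {j}")
                if nins > 0 and prev == "D":
                    raise AlignmentError(
                        f"sequence {k}: insert run adjacent to deletion before column {j}"
                    )
                events.append((j, "M", nins))
                pos = int(p) + 1
                prev = "M"
            else:
                events.append((j, "D", 0))
                prev = "D"
        nins = int(self.seq_lengths[k]) - pos
        if nins < 0:
            raise AlignmentError(f"sequence {k}: length inconsistent with map")
        if nins > 0 and prev == "D" and w > 0:
            raise AlignmentError(f"sequence {k}: trailing insert run after deletion")
        events.append((w + 1, "M", nins))  # End treated as match entry
        return events

    # ------------------------------------------------------------------
    def seq_transition_counts(self, k: int) -> np.ndarray:
        """(7, w+1) transition tallies contributed by sequence k alone."""
        w = self.num_columns
        c = np.zeros((7, w + 1))
        idx = {t: i for i, t in enumerate(TRANS_TYPES)}
        prev = "M"
        for j, kind, nins in self._events(k):
            at = j - 1  # transitions out of column j-1 states
            if nins > 0:
                c[idx["mi"], at] += 1
                c[idx["ii"], at] += nins - 1
                c[idx["im"], at] += 1
                src = "I"
            else:
                src = prev
            if kind == "M":
                if nins > 0:
                    pass  # entry into M already counted via im above
                elif src == "M":
                    c[idx["mm"], at] += 1
                else:
                    c[idx["dm"], at] += 1
                prev = "M"
            else:  # deletion
                if src == "M":
                    c[idx["md"], at] += 1
                else:
                    c[idx["dd"], at] += 1
                prev = "D"
        return c

    def transition_counts(
        self, priors: TransitionPriors | None = None, exclude: int | None = None
    ) -> TransitionCounts:
        """Tally the seven transition types at each position.

        ``exclude`` leaves one sequence out (used by the Gibbs sampler).
        """
        c = np.zeros((7, self.num_columns + 1))
        for k in range(self.num_sequences):
            if k == exclude:
                continue
            c += self.seq_transition_counts(k)
        return TransitionCounts(c, priors or TransitionPriors())

    # ------------------------------------------------------------------
    def to_a2m_row(self, k: int, residues: str) -> str:
        """Render sequence k in A2M: uppercase match, lowercase insert, '-' delete."""
        out = []
        pos = 0
        row = self.match_map[k]
        for j in range(self.num_columns):
            p = row[j]
            if p >= 0:
                out.append(residues[pos:p].lower())
                out.append(residues[p].upper())
                pos = p + 1
            else:
                out.append("-")
        out.append(residues[pos:].lower())
        return "".join(out)


def a2m_to_state(rows: list[str]) -> tuple[AlignmentState, list[str]]:
    """Parse A2M rows (uppercase match / '-' delete / lowercase insert).

    Returns the AlignmentState and the ungapped residue strings.  All rows
    must agree on the number of match columns (uppercase + '-').
    """
    maps = []
    seqs = []
    w_ref = None
    for i, row in enumerate(rows):
        cols = []
        pos = 0
        chars = []
        for ch in row:
            if ch in "-":
                cols.append(-1)
            elif ch == ".":
                continue
            elif ch.isupper():
                cols.append(pos)
                chars.append(ch)
                pos += 1
            elif ch.islower():
                chars.append(ch.upper())
                pos += 1
            else:
                raise AlignmentError(f"row {i + 1}: illegal alignment character {ch!r}")
        if w_ref is None:
            w_ref = len(cols)
        elif len(cols) != w_ref:
            raise AlignmentError(
                f"row {i + 1}: {len(cols)} match columns, expected {w_ref}"
            )
        maps.append(cols)
        seqs.append("".join(chars))
    if w_ref is None:
        raise AlignmentError("empty alignment")
    state = AlignmentState(
        np.array(maps, dtype=np.int64),
        np.array([len(s) for s in seqs], dtype=np.int64),
    )
    state.check()
    return state, seqs
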