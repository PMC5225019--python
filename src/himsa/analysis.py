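"""Post-hoc statistics and reporting.

Two deliverables: (1) the delta-BILD functional-specificity profile, which
ranks alignment columns by how strongly major subgroups diverge from the
superfamily composition, and (2) plain-text (and minimal RTF) renderings of
contrast alignments in the standard notation: consensus lines, frequency
digits in integer tenths, pattern dots and semi-logarithmic divergence bars.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .alphabet import AA, BACKGROUND, N_AA
from .bpps_model import ContrastAlignment, Hierarchy, PatternSet, build_contrast_alignment
from .msa_model import DirichletMixture, background_prior, bild_score
from .seqio import SequenceSet


# ----------------------------------------------------------------------
# delta-BILD
# ----------------------------------------------------------------------

def _col_counts(X: np.ndarray, weights: np.ndarray, rows: np.ndarray, j: int) -> np.ndarray:
    out = np.zeros(N_AA)
    col = X[rows, j]
    ok = col >= 0
    np.add.at(out, col[ok], weights[rows][ok])
    return out


def delta_bild(
    j: int,
    subgroup_rows: np.ndarray,
    X: np.ndarray,
    weights: np.ndarray,
    prior: DirichletMixture | None = None,
    null: np.ndarray | None = None,
) -> float:
    """delta-BILD of column j for one major subgroup, in bits.

    BILD(subgroup) + BILD(rest of superfamily) - BILD(whole superfamily):
    positive when the subgroup's residue composition at j diverges from the
    rest; zero when the subgroup contributes no residues at j.
    """
    prior = prior or background_prior()
    null = BACKGROUND if null is None else null
    all_rows = np.arange(X.shape[0])
    cg = _col_counts(X, weights, subgroup_rows, j)
    call = _col_counts(X, weights, all_rows, j)
    crest = np.maximum(call - cg, 0.0)
    return (
        bild_score(cg, prior, null)
        + bild_score(crest, prior, null)
        - bild_score(call, prior, null)
    )


@dataclass
class DeltaBildProfile:
    raw: np.ndarray  # per-column average delta-BILD in bits
    normalized: np.ndarray  # linear [0, 100]
    flags: np.ndarray  # > mean + 2 SD of the normalized scores
    degenerate: bool = False


def delta_bild_profile(
    X: np.ndarray,
    weights: np.ndarray,
    H: Hierarchy,
    prior: DirichletMixture | None = None,
    null: np.ndarray | None = None,
) -> DeltaBildProfile:
    """Average delta-BILD per column over the major subgroups (subtrees
    attached directly to the root), linearly normalised to [0, 100], with
    columns more than two standard deviations above the mean flagged."""
    majors = H.major_subgroups()
    if len(majors) < 2:
        raise ValueError("delta-BILD profile needs at least two major subgroups")
    prior = prior or background_prior()
    w = X.shape[1]
    raw = np.zeros(w)
    member_rows = {
        g: np.array(sorted(H.subtree_sequences(g)), dtype=np.int64) for g in majors
    }
    for j in range(w):
        vals = [
            delta_bild(j, member_rows[g], X, weights, prior, null) for g in majors
        ]
        raw[j] = float(np.mean(vals))
    lo, hi = raw.min(), raw.max()
    if hi - lo <= 0:
        warnings.warn("degenerate delta-BILD range; all normalized scores are 0")
        norm = np.zeros(w)
        flags = np.zeros(w, dtype=bool)
        return DeltaBildProfile(raw, norm, flags, degenerate=True)
    norm = 100.0 * (raw - lo) / (hi - lo)
    mu, sd = norm.mean(), norm.std()
    flags = norm > mu + 2 * sd
    return DeltaBildProfile(raw, norm, flags)


def profile_table(profile: DeltaBildProfile) -> str:
    """TSV rendering (1-based columns)."""
    lines = ["column\traw_bits\tnormalized\tflag"]
    for j, (r, n, f) in enumerate(
        zip(profile.raw, profile.normalized, profile.flags), start=1
    ):
        lines.append(f"{j}\t{r:.4f}\t{n:.2f}\t{int(f)}")
    return "\n".join(lines) + "\n"


# ----------------------------------------------------------------------
# Contrast-alignment rendering
# ----------------------------------------------------------------------

def frequency_digit(f: float) -> int:
    """Integer-tenths digit for a frequency: 0.65 -> 6 (60-70%)."""
    if not (0.0 <= f <= 1.0):
        raise ValueError("frequency outside [0, 1]")
    return min(9, int(f * 10.0))


def _column_consensus(counts: np.ndarray, max_lines: int = 3, min_freq: float = 0.1):
    """Up to three (residue, frequency) pairs occurring most frequently and
    in >= min_freq of the weighted sequences, most frequent first."""
    tot = counts.sum()
    if tot <= 0:
        return []
    freqs = counts / tot
    order = np.argsort(-freqs)
    out = []
    for r in order[:max_lines]:
        if freqs[r] >= min_freq:
            out.append((int(r), float(freqs[r])))
    return out


def render_contrast_alignment(
    ca: ContrastAlignment,
    X: np.ndarray,
    weights: np.ndarray,
    representatives: list[int] | None = None,
    seq_names: list[str] | None = None,
) -> str:
    """Plain-text block for one node's contrast alignment.

    Lines: divergence bars (semi-log), pattern dots, representative
    sequences (pattern-matching residues uppercase, others lowercase),
    consensus residues (up to three lines), frequency digits in integer
    tenths, and the weighted ('effective') number of aligned sequences.
    """
    fg = ca.foreground
    w = X.shape[1]
    counts = np.zeros((w, N_AA))
    for j in range(w):
        counts[j] = _col_counts(X, weights, fg, j)
    eff = float(weights[fg].sum())
    pat = ca.pattern_columns
    reps = list(representatives or list(fg[: min(3, fg.size)]))

    bar_line = []
    dot_line = []
    for j in range(w):
        if j in pat:
            bar = ca.divergence.get(j, 0.0)
            bar_line.append(str(min(9, int(bar))))
            dot_line.append(".")
        else:
            bar_line.append(" ")
            dot_line.append(" ")
    lines = [f"node {ca.node} contrast alignment"]
    lines.append("bars  " + "".join(bar_line))
    lines.append("dots  " + "".join(dot_line))
    for i in reps:
        row = []
        for j in range(w):
            r = X[i, j]
            if r < 0:
                row.append("-")
            elif j in pat and r in pat[j]:
                row.append(AA[r].upper())
            else:
                row.append(AA[r].lower())
        name = seq_names[i] if seq_names else f"seq{i}"
        lines.append(f"{name:<5.5s} " + "".join(row))
    cons = [_column_consensus(counts[j]) for j in range(w)]
    n_lines = max((len(c) for c in cons), default=0)
    digit_rows = []
    for level in range(n_lines):
        res_row, dig_row = [], []
        for j in range(w):
            if level < len(cons[j]):
                r, f = cons[j][level]
                res_row.append(AA[r])
                dig_row.append(str(frequency_digit(f)))
            else:
                res_row.append(" ")
                dig_row.append(" ")
        label = "cons" if level == 0 else f"co{level + 1:<2d}"
        lines.append(f"{label:<5s} " + "".join(res_row))
        digit_rows.append(dig_row)
    for level, dig_row in enumerate(digit_rows):
        tag = "wt_res_freqs" if level == 0 else ""
        suffix = f"  ({eff:.1f})" if level == 0 else ""
        lines.append(f"freq{level + 1:<2d}" + "".join(dig_row) + suffix)
    lines.append(f"wt_res_freqs: effective sequences = {eff:.1f}")
    return "\n".join(lines) + "\n"


def render_lineage(
    H: Hierarchy,
    leaf: int,
    X: np.ndarray,
    weights: np.ndarray,
    patterns: PatternSet,
    alpha: dict | None = None,
    representatives: list[int] | None = None,
    seq_names: list[str] | None = None,
) -> str:
    """One contrast-alignment block per node on the root-to-leaf path,
    root first, concatenated."""
    if leaf not in H.parent:
        raise ValueError(f"unknown node {leaf}")
    alpha = alpha or {}
    blocks = []
    reps = representatives
    if reps is None:
        fg = H.subtree_sequences(leaf)
        reps = list(fg[: min(3, fg.size)])
    for node in H.lineage(leaf):
        if node == H.reject:
            continue
        ca = build_contrast_alignment(
            H, node, X, weights, patterns, float(alpha.get(node, 0.05))
        )
        blocks.append(
            render_contrast_alignment(ca, X, weights, reps, seq_names)
        )
    return "\n".join(blocks)


# ----------------------------------------------------------------------
# Minimal RTF
# ----------------------------------------------------------------------

_RTF_HEADER = (
    r"{\rtf1\ansi{\fonttbl{\f0\fmodern Courier;}}"
    r"{\colortbl;\red0\green0\blue0;\red255\green0\blue0;}"
    r"\f0\fs18 "
)


def text_to_rtf(text: str) -> str:
    """Wrap a rendered block in a minimal RTF document.

    Frequency digits 5-6 stay in the default (black) style; 7-9 are set in
    the red style, mirroring the standard contrast-alignment notation.
    """
    out = [_RTF_HEADER]
    for line in text.splitlines():
        is_digit_line = line.startswith("freq")
        chunk = []
        for ch in line:
            esc = ch
            if ch in "\\{}":
                esc = "\\" + ch
            if is_digit_line and ch in "789":
                chunk.append(r"{\cf2 " + esc + "}")
            else:
                chunk.append(esc)
        out.append("".join(chunk) + r"\line ")
    out.append("}")
    return "\n".join(out)
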