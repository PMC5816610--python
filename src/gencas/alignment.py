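"""Center-star multiple alignment of orthologous nucleotide regions.

The first sequence is the designated reference (the star center).  Every
other sequence is globally aligned to it with affine gap costs (Gotoh), and
the pairwise alignments are merged on reference coordinates: the gap pattern
inserted into the reference is the union (per-position maximum) of the
insertions required by each pairwise alignment.

Scoring: match +1, mismatch -1, a gap of length L costs
``gap_open + L * gap_extend`` (default -5 - L).  Traceback ties prefer the
diagonal move, then the vertical (gap in the second sequence), then the
horizontal, making alignments deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

_NEG = -1e12


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment of two sequences as gapped strings."""

    aligned_a: str
    aligned_b: str
    score: float


@dataclass(frozen=True)
class MultipleAlignment:
    """Rows are gapped strings of equal length; row 0 is the reference."""

    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def reference_columns(self) -> list[int]:
        """Column indices where the reference row is ungapped, in order."""
        return [c for c, ch in enumerate(self.rows[0]) if ch != "-"]

    def column_pairings(self, row: int) -> set[tuple[int, int]]:
        """Homology pairs (reference position, row position) implied by the
        alignment — columns where both the reference and ``row`` are
        ungapped."""
        pairs = set()
        i = j = 0
        for ref_ch, ch in zip(self.rows[0], self.rows[row]):
            if ref_ch != "-" and ch != "-":
                pairs.add((i, j))
            if ref_ch != "-":
                i += 1
            if ch != "-":
                j += 1
        return pairs


def pairwise_global(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
) -> PairwiseAlignment:
    """Global affine-gap alignment (Gotoh), deterministic traceback.

    The DP rows are vectorised with numpy; the horizontal-gap matrix is
    computed with a prefix-maximum scan, exact for ``gap_open <= 0`` because
    splitting one gap into two adjacent gaps can never win.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    n, m = len(a), len(b)
    av = np.frombuffer(a.upper().encode(), dtype=np.uint8)
    bv = np.frombuffer(b.upper().encode(), dtype=np.uint8)
    oe = gap_open + gap_extend

    H = np.full((n + 1, m + 1), _NEG)
    F = np.full((n + 1, m + 1), _NEG)  # gap in b (vertical move)
    E = np.full((n + 1, m + 1), _NEG)  # gap in a (horizontal move)
    js = np.arange(m + 1, dtype=float)
    H[0, 0] = 0.0
    H[0, 1:] = gap_open + gap_extend * js[1:]
    E[0, 1:] = H[0, 1:]
    for i in range(1, n + 1):
        F[i] = np.maximum(F[i - 1] + gap_extend, H[i - 1] + oe)
        sub = np.where(bv == av[i - 1], match, mismatch)
        M = np.full(m + 1, _NEG)
        M[1:] = H[i - 1, :-1] + sub
        MF = np.maximum(M, F[i])
        # E[i,j] = max_k<j (H[k] + open + extend*(j-k)); prefix-max over
        # MF[k]-extend*k is exact since adjacent gaps never beat one gap
        prefix = np.maximum.accumulate(MF - gap_extend * js)
        E[i, 1:] = gap_open + gap_extend * js[1:] + prefix[:-1]
        H[i] = np.maximum(MF, E[i])
        H[i, 0] = gap_open + gap_extend * i
        F[i, 0] = H[i, 0]

    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    state = "H"
    while i > 0 or j > 0:
        if state == "H":
            if i == 0:
                state = "E"
                continue
            if j == 0:
                state = "F"
                continue
            diag = H[i - 1, j - 1] + (match if av[i - 1] == bv[j - 1] else mismatch)
            if H[i, j] == diag:
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i -= 1
                j -= 1
            elif H[i, j] == F[i, j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            out_a.append(a[i - 1])
            out_b.append("-")
            from_h = H[i - 1, j] + oe
            if i > 1 and F[i, j] != from_h:
                i -= 1  # stay in F
            else:
                i -= 1
                state = "H"
        else:  # E
            out_a.append("-")
            out_b.append(b[j - 1])
            from_h = H[i, j - 1] + oe
            if j > 1 and E[i, j] != from_h:
                j -= 1
            else:
                j -= 1
                state = "H"
    return PairwiseAlignment("".join(reversed(out_a)), "".join(reversed(out_b)), float(H[n, m]))


def _split_on_reference(aln: PairwiseAlignment) -> tuple[list[str], list[str]]:
    """Decompose a pairwise alignment on reference coordinates.

    Returns (insertions, aligned) where ``insertions[k]`` holds the second
    sequence's characters inserted before reference residue ``k`` (length
    ``len(ref)+1``) and ``aligned[k]`` is the character aligned to reference
    residue ``k`` ('-' for a deletion).
    """
    insertions: list[str] = [""]
    aligned: list[str] = []
    for ra, rb in zip(aln.aligned_a, aln.aligned_b):
        if ra == "-":
            insertions[-1] += rb
        else:
            aligned.append(rb)
            insertions.append("")
    return insertions, aligned


def align_orthologous_regions(
    seqs: Sequence[str],
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
) -> MultipleAlignment:
    """Center-star progressive alignment; ``seqs[0]`` is the reference."""
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    for s in seqs:
        if not s:
            raise ValueError("sequences must be non-empty")
        if len(s) > 5000:
            raise ValueError("sequences longer than 5000 nt are not supported")
    ref = seqs[0].upper()
    decomposed = [
        _split_on_reference(pairwise_global(ref, s, match, mismatch, gap_open, gap_extend))
        for s in seqs[1:]
    ]
    L = len(ref)
    ins_len = [0] * (L + 1)
    for insertions, _ in decomposed:
        for k, chunk in enumerate(insertions):
            ins_len[k] = max(ins_len[k], len(chunk))

    def build_row(insertions: list[str], aligned: list[str]) -> str:
        parts = []
        for k in range(L + 1):
            chunk = insertions[k]
            parts.append(chunk + "-" * (ins_len[k] - len(chunk)))
            if k < L:
                parts.append(aligned[k])
        return "".join(parts)

    rows = [build_row([""] * (L + 1), list(ref))]
    for insertions, aligned in decomposed:
        rows.append(build_row(insertions, aligned))
    return MultipleAlignment(tuple(rows))
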