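"""Position weight matrices for transcription-factor binding sites.

A motif is a 4xL log-odds matrix (rows A, C, G, T, scores in bits against a
background distribution).  Motifs can be loaded from a simple matrix file
(four whitespace-delimited rows) or expanded from an IUPAC consensus string:
each base allowed by the code receives an equal share of one count per
column, a pseudocount of 0.25 per base is added, and the column is
normalised before taking log2 against the background.

The default CRP model is the palindromic consensus TGTGA-N6-TCACA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifModel:
    """A named log-odds motif with its background distribution."""

    name: str
    matrix: np.ndarray  # shape (4, L), bits
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != 4 or self.matrix.shape[1] < 4:
            raise ValueError("matrix must be 4 x L with L >= 4")
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def max_score(self) -> float:
        """Best attainable bit score (sum of per-column maxima)."""
        return float(self.matrix.max(axis=0).sum())

    def score(self, site: str) -> float:
        """Log-odds score of a site of the motif's length (N scores the
        background expectation of the column, i.e. the mean row)."""
        site = site.upper()
        if len(site) != self.length:
            raise ValueError(f"site length {len(site)} != motif length {self.length}")
        total = 0.0
        for j, ch in enumerate(site):
            i = _BASE_INDEX.get(ch)
            total += self.matrix[:, j].mean() if i is None else self.matrix[i, j]
        return float(total)

    def score_all(self, seq: str, reverse: bool = False) -> np.ndarray:
        """Scores of every window of ``seq`` (on the given strand)."""
        seq = reverse_complement(seq) if reverse else seq.upper()
        n, L = len(seq), self.length
        if n < L:
            return np.empty(0)
        idx = np.frombuffer(seq.encode(), dtype=np.uint8)
        code = np.full(256, -1, dtype=np.int64)
        for b, i in _BASE_INDEX.items():
            code[ord(b)] = i
        bi = code[idx]
        col_mean = self.matrix.mean(axis=0)
        scores = np.zeros(n - L + 1)
        for j in range(L):
            col = bi[j : j + n - L + 1]
            vals = np.where(col >= 0, self.matrix[np.clip(col, 0, 3), j], col_mean[j])
            scores += vals
        if reverse:
            scores = scores[::-1]  # window k on - strand starts at n-L-k on +
        return scores

    @classmethod
    def from_consensus(
        cls,
        consensus: str,
        name: str = "consensus",
        pseudocount: float = 0.25,
        background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    ) -> "MotifModel":
        consensus = consensus.upper()
        L = len(consensus)
        counts = np.zeros((4, L))
        for j, ch in enumerate(consensus):
            allowed = IUPAC.get(ch)
            if allowed is None:
                raise ValueError(f"not an IUPAC code: {ch!r}")
            for b in allowed:
                counts[_BASE_INDEX[b], j] = 1.0 / len(allowed)
        counts += pseudocount
        probs = counts / counts.sum(axis=0, keepdims=True)
        bg = np.asarray(background).reshape(4, 1)
        return cls(name=name, matrix=np.log2(probs / bg), background=tuple(background))

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "MotifModel":
        """Load a motif from a matrix file (4 rows A/C/G/T, whitespace
        delimited) or from a single-line IUPAC consensus."""
        path = Path(path)
        lines = [l.strip() for l in path.read_text().splitlines() if l.strip() and not l.startswith("#")]
        name = name or path.stem
        if len(lines) == 1:
            return cls.from_consensus(lines[0], name=name)
        if len(lines) != 4:
            raise ValueError(f"motif file must have 1 (consensus) or 4 (matrix) rows, got {len(lines)}")
        rows = []
        for line in lines:
            fields = line.split()
            if fields and fields[0].rstrip(":").upper() in _BASE_INDEX:
                fields = fields[1:]
            rows.append([float(x) for x in fields])
        return cls(name=name, matrix=np.asarray(rows))


#: Palindromic CRP consensus: two pentamer half-sites separated by a 6-bp spacer.
CRP_CONSENSUS = "TGTGANNNNNNTCACA"


def default_crp_motif() -> MotifModel:
    return MotifModel.from_consensus(CRP_CONSENSUS, name="CRP")
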