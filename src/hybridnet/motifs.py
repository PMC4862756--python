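"""Position-frequency motifs from sets of enriched 8-mers.

Significant 8-mers (e.g. the E2F-only or SBF-only sets from a cross-binding
comparison) are summarized as one motif by a deterministic greedy
alignment: the highest-scoring 8-mer seeds the motif, and every other
8-mer is placed at the offset (within +/-4) and orientation (forward or
reverse complement) that matches the most seed positions. Counts over the
eight seed-anchored columns give the position-frequency matrix, and each
column's IUPAC consensus letter is the smallest degeneracy code covering
all bases at frequency >= 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .sequtils import BASES, revcomp

MAX_OFFSET = 4
CONSENSUS_FREQ = 0.2

IUPAC_CODES: dict[frozenset, str] = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H", frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}


@dataclass
class MotifPFM:
    """8-column motif: base counts, probabilities, IUPAC consensus."""

    counts: np.ndarray  # (4, 8), rows in ACGT order
    consensus: str
    support: int  # number of contributing 8-mers

    @property
    def probabilities(self) -> np.ndarray:
        return self.counts / self.counts.sum(axis=0, keepdims=True)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(BASES))

    def to_jaspar(self, name: str = "motif") -> str:
        """JASPAR-style 4-row count matrix text."""
        lines = [f">{name} {self.consensus}"]
        for base, row in zip(BASES, self.counts):
            cells = " ".join(f"{int(c):5d}" for c in row)
            lines.append(f"{base}  [{cells} ]")
        return "\n".join(lines) + "\n"


def _align_to_seed(seed: str, kmer: str) -> tuple[int, str]:
    """Best (offset, oriented sequence) placement of ``kmer`` against the
    seed; ties prefer smaller |offset|, then forward, then smaller offset."""
    best = None
    for orient_rank, oriented in enumerate((kmer, revcomp(kmer))):
        for offset in range(-MAX_OFFSET, MAX_OFFSET + 1):
            matches = sum(
                1
                for p in range(8)
                if 0 <= p - offset < 8 and seed[p] == oriented[p - offset]
            )
            key = (-matches, abs(offset), orient_rank, offset)
            if best is None or key < best[0]:
                best = (key, offset, oriented)
    return best[1], best[2]


def build_motif(kmers: Mapping[str, float]) -> MotifPFM:
    """Align scored 8-mers to the top-scoring seed and tabulate a PFM.

    ``kmers`` maps each 8-mer to its E-score; score ties for the seed break
    lexicographically. Each 8-mer contributes count 1 at every seed column
    its placement covers.
    """
    if not kmers:
        raise ValueError("cannot build a motif from an empty 8-mer set")
    if any(len(k) != 8 for k in kmers):
        raise ValueError("motif construction expects 8-mers")
    seed = min(kmers, key=lambda k: (-kmers[k], k))
    counts = np.zeros((4, 8))
    for i, base in enumerate(seed):
        counts[BASES.index(base), i] += 1
    for kmer in kmers:
        if kmer == seed:
            continue
        offset, oriented = _align_to_seed(seed, kmer)
        for p in range(8):
            if 0 <= p - offset < 8:
                counts[BASES.index(oriented[p - offset]), p] += 1
    freqs = counts / counts.sum(axis=0, keepdims=True)
    consensus = "".join(
        IUPAC_CODES[frozenset(b for b, f in zip(BASES, col) if f >= CONSENSUS_FREQ)]
        for col in freqs.T
    )
    return MotifPFM(counts=counts, consensus=consensus, support=len(kmers))
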