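"""Universal array design: de Bruijn sequences and probe segmentation.

A universal array covers every k-mer in a maximally compact way: the probe
set tiles a de Bruijn sequence of order k, a circular string over ACGT in
which each k-mer occurs exactly once. Segmenting with an overlap of k-1
nucleotides between adjacent probes guarantees no k-mer window is lost at
probe boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from ..sequtils import BASES


@dataclass(frozen=True)
class ArrayDesign:
    """Geometry of a universal probe set.

    order_k is the k-mer completeness order; adjacent probes share
    ``overlap`` terminal nucleotides (overlap = order_k - 1 preserves k-mer
    coverage exactly); ``circular`` closes the source sequence end-to-start.
    """

    order_k: int = 10
    probe_length: int = 36
    overlap: int = 9
    circular: bool = True
    alphabet: str = BASES

    def __post_init__(self):
        if self.order_k < 1:
            raise ValueError("order_k must be >= 1")
        if self.probe_length < self.order_k:
            raise ValueError("probe_length must be >= order_k")
        if not 0 <= self.overlap < self.probe_length:
            raise ValueError("overlap must satisfy 0 <= overlap < probe_length")

    @property
    def step(self) -> int:
        return self.probe_length - self.overlap


@dataclass
class ProbeSet:
    """Probe sequences with stable string ids."""

    ids: list[str]
    sequences: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences differ in length")

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(zip(self.ids, self.sequences))


@lru_cache(maxsize=8)
def de_bruijn_sequence(order_k: int, alphabet: str = BASES) -> str:
    """Lexicographically least de Bruijn sequence of the given order.

    Deterministic FKM construction (concatenation of Lyndon words whose
    lengths divide order_k). The returned string has length
    ``len(alphabet)**order_k`` and, read circularly, contains every k-mer
    over the alphabet exactly once.
    """
    if order_k < 1:
        raise ValueError("order_k must be >= 1")
    n_sym = len(alphabet)
    a = [0] * (n_sym * order_k)
    out: list[int] = []

    def db(t: int, p: int) -> None:
        if t > order_k:
            if order_k % p == 0:
                out.extend(a[1 : p + 1])
        else:
            a[t] = a[t - p]
            db(t + 1, p)
            for j in range(a[t - p] + 1, n_sym):
                a[t] = j
                db(t + 1, t)

    db(1, 1)
    return "".join(alphabet[c] for c in out)


def segment_probes(sequence: str, design: ArrayDesign) -> ProbeSet:
    """Tile a (circular) source sequence into probes.

    Probes start every ``design.step`` nucleotides. On a circular sequence
    ceil(L/step) probes are produced (the last wraps around), so every
    k-mer window of the source appears in at least one probe; when step
    divides L the within-probe k-mer multiset equals the circular
    sequence's k-mer multiset exactly. Non-circular sequences must satisfy
    step | (L - probe_length).
    """
    bad = set(sequence.upper()) - set(design.alphabet)
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    seq = sequence.upper()
    L = len(seq)
    step = design.step
    if design.circular:
        n_probes = -(-L // step)
        doubled = seq + seq
        seqs = [doubled[s : s + design.probe_length] for s in range(0, n_probes * step, step)]
    else:
        if (L - design.probe_length) % step != 0:
            raise ValueError(
                "non-circular sequence length incompatible with probe step; "
                "need step | (length - probe_length)"
            )
        seqs = [seq[s : s + design.probe_length] for s in range(0, L - design.probe_length + 1, step)]
    width = len(str(max(len(seqs) - 1, 0)))
    ids = [f"probe_{i:0{width}d}" for i in range(len(seqs))]
    return ProbeSet(ids=ids, sequences=seqs)
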