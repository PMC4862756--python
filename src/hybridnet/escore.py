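"""Rank-based 8-mer enrichment scores (E-scores) for universal PBM data.

The E-score of a k-mer measures how strongly the probes containing that
k-mer (the *foreground*) are shifted toward the top of the intensity
ranking relative to all other probes (the *background*). Following the
universal-PBM convention, only the brighter half of each group enters the
statistic: with F' the top ``ceil(|F|/2)`` foreground probes and B' the top
``ceil(|B|/2)`` background probes,

    E = U / (|F'| * |B'|) - 1/2,

where U is the Wilcoxon-Mann-Whitney count of (foreground, background)
pairs in which the foreground probe is brighter (ties counted half). E is
bounded in [-0.5, +0.5], reaches +0.5 exactly when every F' probe outranks
every B' probe, and is invariant under any strictly increasing transform of
the intensities. An E-score of at least 0.37 marks a k-mer as a significant
binding site (false positive rate ~0.001 on a universal array).

Probes are double-stranded, so each 8-mer and its reverse complement are
the same binding site: scores are reported per *canonical* 8-mer, the
lexicographic minimum of the pair. For k=8 there are (4^8 + 4^4)/2 = 32,896
canonical 8-mers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Set

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .sequtils import (
    canonical_codes,
    decode_kmer,
    encode,
    kmer_window_codes,
    revcomp,
)
from .simulate.arrays import ProbeSet
from .simulate.intensities import IntensitySample

DEFAULT_CUTOFF = 0.37


class KmerClass(str, Enum):
    """Cross-binding class of an 8-mer between two proteins."""

    common = "common"
    A_only = "A_only"
    B_only = "B_only"
    neither = "neither"


def canonicalize(kmer: str) -> str:
    """Strand-collapsed form of a k-mer: min(kmer, revcomp(kmer)).

    Idempotent. Raises ``ValueError`` on non-ACGT characters.
    """
    upper = kmer.upper()
    if not upper or any(c not in "ACGT" for c in upper):
        raise ValueError(f"invalid k-mer: {kmer!r}")
    return min(upper, revcomp(upper))


def count_canonical_kmers(k: int) -> int:
    """Number of strand-collapsed k-mers: (4^k + 4^(k/2))/2 for even k
    (palindromes are their own reverse complement), 4^k/2 for odd k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    pal = 4 ** (k // 2) if k % 2 == 0 else 0
    return (4**k + pal) // 2


@dataclass
class KmerIndex:
    """Canonical k-mer -> foreground probe index, in compressed form.

    ``codes`` are the sorted canonical k-mer codes present in the probe set;
    probe indices for code ``codes[i]`` live in
    ``probe_rows[indptr[i]:indptr[i+1]]``. A probe is foreground for a
    canonical k-mer iff any of its k-nt windows canonicalizes to it (the
    reverse strand is thereby covered); each probe counts once per k-mer.
    """

    k: int
    probe_ids: list[str]
    codes: np.ndarray
    indptr: np.ndarray
    probe_rows: np.ndarray

    @property
    def n_kmers(self) -> int:
        return len(self.codes)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    def kmers(self) -> list[str]:
        return [decode_kmer(int(c), self.k) for c in self.codes]

    def foreground_sizes(self) -> np.ndarray:
        return np.diff(self.indptr)

    def foreground(self, kmer: str) -> Set[str]:
        """Probe ids whose windows contain ``kmer`` on either strand."""
        canon = canonicalize(kmer)
        code = int(encode(canon).astype(np.int64) @ (4 ** np.arange(self.k - 1, -1, -1)))
        i = np.searchsorted(self.codes, code)
        if i == len(self.codes) or self.codes[i] != code:
            return set()
        rows = self.probe_rows[self.indptr[i] : self.indptr[i + 1]]
        return {self.probe_ids[r] for r in rows}


def build_kmer_index(probes: ProbeSet, k: int = 8) -> KmerIndex:
    """Index every canonical k-mer occurring in a probe set."""
    if len(probes) == 0:
        raise ValueError("probe set is empty")
    pairs_row = []
    pairs_code = []
    lengths = {len(s) for s in probes.sequences}
    if len(lengths) == 1 and lengths.pop() >= k:
        # equal-length fast path: one coded matrix, vectorized windows
        mat = np.vstack([encode(s) for s in probes.sequences])
        n, L = mat.shape
        win = np.lib.stride_tricks.sliding_window_view(mat, k, axis=1)
        powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
        codes = win.astype(np.int64) @ powers
        codes[(win == 255).any(axis=2)] = -1
        codes = canonical_codes(codes.ravel(), k)
        rows = np.repeat(np.arange(n, dtype=np.int64), L - k + 1)
        keep = codes >= 0
        pairs_row.append(rows[keep])
        pairs_code.append(codes[keep])
    else:
        for i, seq in enumerate(probes.sequences):
            codes = canonical_codes(kmer_window_codes(encode(seq), k), k)
            codes = codes[codes >= 0]
            pairs_row.append(np.full(len(codes), i, dtype=np.int64))
            pairs_code.append(codes)
    rows = np.concatenate(pairs_row) if pairs_row else np.empty(0, np.int64)
    codes = np.concatenate(pairs_code) if pairs_code else np.empty(0, np.int64)
    # dedupe (probe, kmer) pairs, then group by kmer code
    key = codes * len(probes) + rows
    key = np.unique(key)
    codes = key // len(probes)
    rows = key % len(probes)
    uniq, counts = np.unique(codes, return_counts=True)
    indptr = np.concatenate([[0], np.cumsum(counts)])
    return KmerIndex(
        k=k,
        probe_ids=list(probes.ids),
        codes=uniq,
        indptr=indptr,
        probe_rows=rows,
    )


@dataclass
class EscoreTable:
    """All canonical 8-mer E-scores for one protein.

    ``table`` is indexed by canonical k-mer string with columns ``escore``
    (in [-0.5, +0.5]) and ``foreground_size`` (probe count).
    """

    protein_id: str
    table: pd.DataFrame
    k: int = 8

    @property
    def scores(self) -> pd.Series:
        return self.table["escore"]

    def __getitem__(self, kmer: str) -> float:
        return float(self.table.at[canonicalize(kmer), "escore"])

    def __contains__(self, kmer: str) -> bool:
        return canonicalize(kmer) in self.table.index

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="kmer")

    @classmethod
    def from_tsv(cls, path, protein_id: str) -> "EscoreTable":
        df = pd.read_csv(path, sep="\t", index_col="kmer")
        k = len(df.index[0]) if len(df) else 8
        return cls(protein_id=protein_id, table=df, k=k)


def _top_half(values: np.ndarray) -> np.ndarray:
    take = int(np.ceil(len(values) / 2))
    return np.sort(values)[::-1][:take]


def escore_from_values(
    foreground_values: np.ndarray,
    background_values: np.ndarray,
    top_half: bool = True,
) -> float:
    """E-score from raw foreground/background intensity values.

    With ``top_half`` (the universal-PBM convention) only the brighter
    ceil(n/2) probes of each group enter the rank comparison; without it
    the statistic is the plain rescaled Wilcoxon-Mann-Whitney U over the
    full groups (which is exactly antisymmetric under order reversal).
    Exact tie handling via average ranks.
    """
    f = np.asarray(foreground_values, dtype=float)
    b = np.asarray(background_values, dtype=float)
    if len(f) == 0 or len(b) == 0:
        raise ValueError("foreground and background must both be nonempty")
    if top_half:
        f = _top_half(f)
        b = _top_half(b)
    ranks = rankdata(np.concatenate([f, b]))
    u = ranks[: len(f)].sum() - len(f) * (len(f) + 1) / 2
    return float(u / (len(f) * len(b)) - 0.5)


def escore(intensities: IntensitySample, foreground: Iterable[str]) -> float:
    """E-score of a single foreground probe set against the rest.

    Exact tie handling (ties between foreground and background get half
    weight, via average ranks). Foreground must be a nonempty strict subset
    of the probes.
    """
    fg = set(foreground)
    all_ids = set(intensities.probe_ids)
    if not fg or not fg < all_ids:
        raise ValueError("foreground must be a nonempty strict subset of the probe set")
    mask = np.fromiter((p in fg for p in intensities.probe_ids), bool, len(intensities.probe_ids))
    return escore_from_values(intensities.values[mask], intensities.values[~mask])


def escore_table(
    intensities: IntensitySample, index: KmerIndex, protein_id: str = "protein"
) -> EscoreTable:
    """E-scores for every indexed canonical k-mer via one global ranking.

    Intensities are assumed continuous (the vectorized path breaks exact
    ties by probe order; use :func:`escore` for tie-exact single scores).
    K-mers whose foreground covers the whole array are dropped (no
    background to rank against).
    """
    if list(intensities.probe_ids) != list(index.probe_ids):
        raise ValueError("probe ids of intensities and index do not match")
    x = intensities.values
    n = len(x)
    order = np.argsort(-x, kind="stable")
    pos = np.empty(n, dtype=np.int64)
    pos[order] = np.arange(n)

    counts = index.foreground_sizes()
    groups = np.repeat(np.arange(index.n_kmers), counts)
    q = pos[index.probe_rows]
    sort_idx = np.lexsort((q, groups))
    q = q[sort_idx]
    within = np.arange(len(q)) - np.repeat(index.indptr[:-1], counts)

    f_top = (counts + 1) // 2
    b = n - counts
    b_top = (b + 1) // 2
    # For the i-th brightest foreground probe at global (descending) rank
    # q_i, the number of top-half background probes it outranks is
    # b_top - (q_i - i), floored at 0.
    contrib = np.repeat(b_top, counts).astype(np.float64) - (q - within)
    np.clip(contrib, 0, None, out=contrib)
    contrib[within >= np.repeat(f_top, counts)] = 0.0
    u = np.zeros(index.n_kmers)
    np.add.at(u, groups, contrib)

    with np.errstate(divide="ignore", invalid="ignore"):
        e = u / (f_top * b_top) - 0.5
    kmers = index.kmers()
    df = pd.DataFrame(
        {"escore": e, "foreground_size": counts},
        index=pd.Index(kmers, name="kmer"),
    )
    df = df[b > 0]
    return EscoreTable(protein_id=protein_id, table=df, k=index.k)


def significant_kmers(table: EscoreTable, cutoff: float = DEFAULT_CUTOFF) -> Set[str]:
    """Canonical k-mers with E-score >= cutoff."""
    if not (-0.5 < cutoff <= 0.5):
        raise ValueError("cutoff must lie in (-0.5, 0.5]")
    s = table.scores
    return set(s.index[s >= cutoff])


def classify_kmers(
    table_a: EscoreTable, table_b: EscoreTable, cutoff: float = DEFAULT_CUTOFF
) -> pd.Series:
    """Partition the canonical k-mer domain into common / A-only / B-only /
    neither by whether each protein's E-score clears the cutoff."""
    if not table_a.table.index.equals(table_b.table.index):
        raise ValueError("E-score tables cover different k-mer domains")
    a = table_a.scores >= cutoff
    b = table_b.scores >= cutoff
    out = pd.Series(KmerClass.neither.value, index=table_a.table.index, name="class")
    out[a & b] = KmerClass.common.value
    out[a & ~b] = KmerClass.A_only.value
    out[~a & b] = KmerClass.B_only.value
    return out
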