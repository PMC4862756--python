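"""Promoter scanning with 8-mer E-scores and binding-region calling.

A promoter is scanned in 1-nt steps: each 8-nt window (both strands, via
canonicalization) is looked up in a protein's E-score table. A binding
region is a maximal run of at least two consecutive windows scoring at or
above the cutoff (0.37 by default); its interval spans from the first
window's start to the last window's end, so the minimum region is 9 nt.
Two proteins' regions on the same promoter are *common* when they overlap
by at least one full 8-mer (intersection >= 8 nt), whether nested or
partially overlapping; all other regions keep their single-TF label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .escore import DEFAULT_CUTOFF, EscoreTable, canonicalize

REGION_CLASSES = ("A_only", "B_only", "common")


@dataclass
class ScanProfile:
    """Per-position window E-scores along one promoter.

    ``scores[i]`` is the E-score of the canonical form of sequence[i:i+8];
    NaN marks unavailable windows (non-ACGT characters, or 8-mers missing
    from the table).
    """

    promoter_id: str
    scores: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)


@dataclass(frozen=True)
class BindingRegion:
    """Half-open [start, end) interval called for one TF on one promoter."""

    promoter_id: str
    start: int
    end: int
    tf: str
    mean_escore: float = math.nan
    region_class: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    def intersection(self, other: "BindingRegion") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def scan_promoter(
    sequence: str, table: EscoreTable, promoter_id: str = "promoter"
) -> ScanProfile:
    """E-score lookup for every 8-nt window of a promoter."""
    k = table.k
    if len(sequence) < k:
        raise ValueError(f"promoter shorter than {k} nt")
    seq = sequence.upper()
    scores = np.full(len(seq) - k + 1, np.nan)
    lookup = table.scores
    for i in range(len(scores)):
        window = seq[i : i + k]
        try:
            canon = canonicalize(window)
        except ValueError:
            continue  # non-ACGT character: window unavailable
        if canon in lookup.index:
            scores[i] = lookup[canon]
    return ScanProfile(promoter_id=promoter_id, scores=scores)


def call_regions(
    profile: ScanProfile,
    cutoff: float = DEFAULT_CUTOFF,
    min_run: int = 2,
    tf: str = "TF",
    k: int = 8,
) -> list[BindingRegion]:
    """Maximal runs of >= min_run consecutive windows with score >= cutoff.

    Unavailable windows break runs. Region interval = [first_window,
    last_window + k); output sorted by start and pairwise disjoint.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    hot = np.nan_to_num(profile.scores, nan=-np.inf) >= cutoff
    regions = []
    i = 0
    n = len(hot)
    while i < n:
        if hot[i]:
            j = i
            while j + 1 < n and hot[j + 1]:
                j += 1
            if j - i + 1 >= min_run:
                regions.append(
                    BindingRegion(
                        promoter_id=profile.promoter_id,
                        start=i,
                        end=j + k,
                        tf=tf,
                        mean_escore=float(np.mean(profile.scores[i : j + 1])),
                    )
                )
            i = j + 1
        i += 1
    return regions


@dataclass
class OverlapResult:
    """Classified regions of two TFs on one promoter."""

    regions_a: list[BindingRegion]
    regions_b: list[BindingRegion]
    common_pairs: list[tuple[BindingRegion, BindingRegion, tuple[int, int]]]

    @property
    def regions(self) -> list[BindingRegion]:
        return self.regions_a + self.regions_b


def classify_region_overlaps(
    regions_a: Iterable[BindingRegion],
    regions_b: Iterable[BindingRegion],
    min_overlap: int = 8,
) -> OverlapResult:
    """Label regions common / A-only / B-only by full-8-mer overlap.

    A pair is common iff the interval intersection covers at least one full
    8-mer (>= ``min_overlap`` nt), regardless of nesting or relative
    length. Regions in no common pair keep their TF-only label.
    """
    regions_a = list(regions_a)
    regions_b = list(regions_b)
    promoters = {r.promoter_id for r in regions_a + regions_b}
    if len(promoters) > 1:
        raise ValueError(f"regions span multiple promoters: {sorted(promoters)}")
    index_pairs = []
    in_pair_a: set[int] = set()
    in_pair_b: set[int] = set()
    for i, a in enumerate(regions_a):
        for j, b in enumerate(regions_b):
            inter = a.intersection(b)
            if inter >= min_overlap:
                lo = max(a.start, b.start)
                index_pairs.append((i, j, (lo, lo + inter)))
                in_pair_a.add(i)
                in_pair_b.add(j)
    out_a = [
        replace(a, region_class="common" if i in in_pair_a else "A_only")
        for i, a in enumerate(regions_a)
    ]
    out_b = [
        replace(b, region_class="common" if j in in_pair_b else "B_only")
        for j, b in enumerate(regions_b)
    ]
    pairs = [(out_a[i], out_b[j], span) for i, j, span in index_pairs]
    return OverlapResult(regions_a=out_a, regions_b=out_b, common_pairs=pairs)


@dataclass
class PromoterSummary:
    """Cohort-level tallies of A-only / B-only / common binding regions."""

    per_promoter: pd.DataFrame  # rows = promoters, columns = region classes
    totals: dict[str, int]
    fraction_with: dict[str, float]


def summarize_promoters(
    results: Mapping[str, OverlapResult],
) -> PromoterSummary:
    """Per-promoter and cohort counts of region classes.

    Exclusive regions count individually; each common pair counts once.
    """
    rows = {}
    for promoter_id, result in results.items():
        rows[promoter_id] = {
            "A_only": sum(r.region_class == "A_only" for r in result.regions),
            "B_only": sum(r.region_class == "B_only" for r in result.regions),
            "common": len(result.common_pairs),
        }
    per_promoter = pd.DataFrame.from_dict(rows, orient="index", dtype=int)
    if per_promoter.empty:
        per_promoter = pd.DataFrame(columns=list(REGION_CLASSES), dtype=int)
    per_promoter = per_promoter.reindex(columns=list(REGION_CLASSES), fill_value=0)
    totals = {c: int(per_promoter[c].sum()) for c in REGION_CLASSES}
    n = len(per_promoter)
    fraction_with = {
        c: float((per_promoter[c] > 0).mean()) if n else 0.0 for c in REGION_CLASSES
    }
    return PromoterSummary(
        per_promoter=per_promoter, totals=totals, fraction_with=fraction_with
    )
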