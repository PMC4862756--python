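"""Clade-level presence/absence matrices and G1/S network states.

Per-genome family member counts are folded into a clade x family boolean
matrix: a clade shows a family when at least one of its sequenced genomes
has at least one member. Each genome is also classified by which side of
the G1/S transcription-factor split it carries — the ancestral E2F/DP-type
families, the fungal KilA-N-type families (SBF/MBF, APSES, ...), both
(a hybrid network, the chytrid pattern), or neither.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .domains import LABEL_BOTH, DualClassification

STATE_ANCESTRAL = "ancestral_only"
STATE_FUNGAL = "fungal_only"
STATE_HYBRID = "hybrid"
STATE_NEITHER = "neither"


def aggregate_presence(
    calls: pd.DataFrame, clades: Mapping[str, str]
) -> pd.DataFrame:
    """Boolean clade x family matrix from genome x family member counts.

    Entry (clade, family) is True iff some genome mapped to the clade has
    count >= 1 for the family. Every genome row must appear in the clade
    map.
    """
    if (calls.to_numpy() < 0).any():
        raise ValueError("member counts must be >= 0")
    unmapped = sorted(set(calls.index) - set(clades))
    if unmapped:
        raise ValueError(f"genomes missing from the clade map: {unmapped}")
    present = calls >= 1
    clade_of = pd.Series({g: clades[g] for g in calls.index}, name="clade")
    out = present.groupby(clade_of).any()
    out.index.name = "clade"
    return out


def classify_network(
    calls: pd.DataFrame,
    ancestral_families: Iterable[str],
    fungal_families: Iterable[str],
) -> pd.Series:
    """Per-genome network state from family member counts.

    hybrid = at least one member on both the ancestral (E2F/DP-type) and
    fungal (KilA-N-type) family lists; ancestral_only / fungal_only /
    neither otherwise. The two family lists must be disjoint.
    """
    ancestral = list(ancestral_families)
    fungal = list(fungal_families)
    overlap = sorted(set(ancestral) & set(fungal))
    if overlap:
        raise ValueError(f"families listed on both sides: {overlap}")
    missing = sorted((set(ancestral) | set(fungal)) - set(calls.columns))
    if missing:
        raise ValueError(f"families absent from the calls table: {missing}")
    has_anc = (calls[ancestral] >= 1).any(axis=1)
    has_fun = (calls[fungal] >= 1).any(axis=1)
    out = pd.Series(STATE_NEITHER, index=calls.index, name="state")
    out[has_anc & ~has_fun] = STATE_ANCESTRAL
    out[~has_anc & has_fun] = STATE_FUNGAL
    out[has_anc & has_fun] = STATE_HYBRID
    return out


def orthogonality_report(
    classifications: Iterable[DualClassification],
) -> list[DualClassification]:
    """Proteins significant for both domain families (expected empty on
    well-separated families). Reporting is the contract; a non-empty list
    never raises."""
    return [c for c in classifications if c.label == LABEL_BOTH]
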