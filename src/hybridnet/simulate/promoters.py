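"""Synthetic promoter sequences with planted binding sites.

Promoters emulate 1000-bp upstream regions: uniform ACGT background with
chosen sites written at fixed offsets on the forward strand, so the
promoter-scanning stage can be tested against known truth.
"""

from __future__ import annotations

import numpy as np

from ..sequtils import BASES

Plant = tuple[int, int, str]  # (promoter index, 0-based offset, site)


def simulate_promoters(
    n: int,
    length: int = 1000,
    plants: list[Plant] | None = None,
    seed: int = 0,
) -> dict[str, str]:
    """Named promoter set: i.i.d. uniform background plus planted sites.

    Plants within one promoter must not overlap (overlap would make the
    planted truth ambiguous). Bit-reproducible for a fixed seed.
    """
    plants = plants or []
    for idx, offset, site in plants:
        if not 0 <= idx < n:
            raise ValueError(f"plant refers to promoter {idx} outside 0..{n - 1}")
        if offset < 0 or offset + len(site) > length:
            raise ValueError(f"plant {site!r} at offset {offset} exceeds promoter length")
        if set(site.upper()) - set(BASES):
            raise ValueError(f"plant {site!r} contains non-ACGT characters")
    by_promoter: dict[int, list[tuple[int, int]]] = {}
    for idx, offset, site in plants:
        for s, e in by_promoter.get(idx, []):
            if offset < e and s < offset + len(site):
                raise ValueError(f"overlapping plants in promoter {idx}")
        by_promoter.setdefault(idx, []).append((offset, offset + len(site)))

    rng = np.random.default_rng(seed)
    width = len(str(max(n - 1, 0)))
    promoters = {}
    seqs = []
    for i in range(n):
        seqs.append(rng.choice(list(BASES), size=length))
    for idx, offset, site in plants:
        seqs[idx][offset : offset + len(site)] = list(site.upper())
    for i in range(n):
        promoters[f"promoter_{i:0{width}d}"] = "".join(seqs[i])
    return promoters
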