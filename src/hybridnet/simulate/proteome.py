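"""Toy proteomes for exercising the dual domain-profile classifier.

A proteome holds members of two unrelated transcription-factor families
(copies of family exemplars with random per-site substitutions) plus
background proteins drawn i.i.d. from a uniform 1/20 amino-acid
composition. Truth labels are recorded so sensitivity/specificity of the
downstream classification can be measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
UNIFORM_AA_BACKGROUND = {a: 1.0 / len(AMINO_ACIDS) for a in AMINO_ACIDS}

LABEL_A = "familyA"
LABEL_B = "familyB"
LABEL_BG = "background"


@dataclass
class FamilyProfileSpec:
    """Exemplar set defining one protein family for simulation.

    ``exemplars`` are equal-length (aligned) amino-acid strings; emitted
    family members are exemplar copies with per-site substitutions at
    ``substitution_rate``.
    """

    name: str
    exemplars: tuple[str, ...]
    substitution_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        self.exemplars = tuple(self.exemplars)
        if not self.exemplars:
            raise ValueError("exemplar set must be nonempty")
        if len({len(e) for e in self.exemplars}) != 1:
            raise ValueError("exemplars must all have equal length")
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError("substitution_rate must lie in [0, 1]")

    @property
    def length(self) -> int:
        return len(self.exemplars[0])


def make_family_spec(
    name: str,
    length: int = 150,
    n_exemplars: int = 3,
    divergence: float = 0.1,
    substitution_rate: float = 0.05,
    seed: int = 0,
) -> FamilyProfileSpec:
    """Random family: one ancestral sequence plus diverged exemplar copies.

    Two specs built with different seeds are non-homologous (independent
    random ancestors), mimicking structurally unrelated families.
    """
    rng = np.random.default_rng(seed)
    ancestor = "".join(rng.choice(list(AMINO_ACIDS), size=length))
    exemplars = [ancestor]
    for _ in range(n_exemplars - 1):
        exemplars.append(_mutate(ancestor, divergence, rng))
    return FamilyProfileSpec(
        name=name, exemplars=tuple(exemplars), substitution_rate=substitution_rate, seed=seed
    )


@dataclass
class SyntheticProteome:
    """Simulated protein set with ground-truth family labels."""

    proteins: dict[str, str]
    truth_labels: dict[str, str]

    def __post_init__(self):
        if set(self.proteins) != set(self.truth_labels):
            raise ValueError("truth_labels must cover exactly the protein ids")

    def __len__(self) -> int:
        return len(self.proteins)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        choices = AMINO_ACIDS.replace(seq[i], "")
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def simulate_proteome(
    spec_a: FamilyProfileSpec,
    spec_b: FamilyProfileSpec,
    n_a: int = 10,
    n_b: int = 10,
    n_bg: int = 25,
    bg_length: int = 200,
    seed: int = 0,
) -> SyntheticProteome:
    """Emit a labeled proteome with n_a + n_b family members and n_bg
    background proteins. Bit-reproducible for a fixed seed."""
    if min(n_a, n_b, n_bg) < 0:
        raise ValueError("counts must be >= 0")
    if set(spec_a.exemplars) & set(spec_b.exemplars):
        raise ValueError("family specs share an exemplar")
    rng = np.random.default_rng(seed)
    proteins: dict[str, str] = {}
    labels: dict[str, str] = {}
    for spec, n, label, tag in (
        (spec_a, n_a, LABEL_A, "A"),
        (spec_b, n_b, LABEL_B, "B"),
    ):
        for i in range(n):
            exemplar = spec.exemplars[rng.integers(len(spec.exemplars))]
            pid = f"{tag}_{i:03d}"
            proteins[pid] = _mutate(exemplar, spec.substitution_rate, rng)
            labels[pid] = label
    for i in range(n_bg):
        pid = f"bg_{i:03d}"
        proteins[pid] = "".join(rng.choice(list(AMINO_ACIDS), size=bg_length))
        labels[pid] = LABEL_BG
    return SyntheticProteome(proteins=proteins, truth_labels=labels)
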