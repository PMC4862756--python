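"""Simulated probe fluorescence with an optional planted motif.

The generative model is multiplicative noise around a planted signal:

    log I(probe) = baseline_mu + effect_size * max(0, best_lod) + eps,

where ``best_lod`` is the highest log-odds of the planted PWM (vs the
uniform background) over all 8-nt windows of the probe on either strand,
and eps ~ Normal(0, noise_sd). With no planted PWM (or effect_size 0) the
intensities are i.i.d. lognormal — the null an E-score analysis assumes.
Because the E-score is rank-based, baseline_mu only sets the (arbitrary)
fluorescence scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..sequtils import BASES, encode
from .arrays import ProbeSet


def pwm_from_consensus(consensus: str, dominant: float = 0.925) -> np.ndarray:
    """Sharp probability matrix for a consensus site: the consensus base
    gets ``dominant`` probability per column, the rest split evenly."""
    if not 0.25 < dominant <= 1.0:
        raise ValueError("dominant must lie in (0.25, 1]")
    off = (1.0 - dominant) / 3.0
    pwm = np.full((len(consensus), 4), off)
    for i, b in enumerate(consensus.upper()):
        pwm[i, BASES.index(b)] = dominant
    return pwm


@dataclass
class IntensityModel:
    """Parameters of the probe fluorescence simulator (log-intensity units)."""

    baseline_mu: float = 7.0
    effect_size: float = 1.0
    noise_sd: float = 0.3
    planted_pwm: np.ndarray | None = None  # (width, 4) probabilities over ACGT
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.planted_pwm is not None:
            pwm = np.asarray(self.planted_pwm, dtype=float)
            if pwm.ndim != 2 or pwm.shape[1] != 4:
                raise ValueError("planted_pwm must be a (width, 4) matrix")
            if not np.allclose(pwm.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("planted_pwm columns must each sum to 1")
            self.planted_pwm = pwm


@dataclass
class IntensitySample:
    """Measured or simulated probe intensities (strictly positive)."""

    probe_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.probe_ids) != len(self.values):
            raise ValueError("probe_ids and values differ in length")

    def __len__(self) -> int:
        return len(self.values)


def _best_window_lod(sequences: list[str], pwm: np.ndarray) -> np.ndarray:
    """Best PWM log-odds (vs uniform 0.25) over all windows, both strands."""
    width = pwm.shape[0]
    logodds = np.log(np.clip(pwm, 1e-12, None) / 0.25)
    rc_logodds = logodds[::-1, ::-1]  # reverse positions, complement bases
    best = np.full(len(sequences), -np.inf)
    lengths = {len(s) for s in sequences}
    if len(lengths) == 1 and (L := lengths.pop()) >= width:
        mat = np.vstack([encode(s) for s in sequences]).astype(np.int64)
        win = np.lib.stride_tricks.sliding_window_view(mat, width, axis=1)
        cols = np.arange(width)
        fwd = logodds[cols, win].sum(axis=2)
        rev = rc_logodds[cols, win].sum(axis=2)
        best = np.maximum(fwd.max(axis=1), rev.max(axis=1))
    else:
        for i, s in enumerate(sequences):
            codes = encode(s).astype(np.int64)
            if len(codes) < width:
                continue
            win = np.lib.stride_tricks.sliding_window_view(codes, width)
            cols = np.arange(width)
            best[i] = max(
                logodds[cols, win].sum(axis=1).max(),
                rc_logodds[cols, win].sum(axis=1).max(),
            )
    return np.where(np.isfinite(best), best, 0.0)


def simulate_intensities(probes: ProbeSet, model: IntensityModel) -> IntensitySample:
    """Draw one array's worth of intensities under the planted-motif model.

    Bit-reproducible for a fixed model seed.
    """
    rng = np.random.default_rng(model.seed)
    log_i = np.full(len(probes), model.baseline_mu, dtype=float)
    if model.planted_pwm is not None and model.effect_size != 0.0:
        lod = _best_window_lod(probes.sequences, model.planted_pwm)
        log_i += model.effect_size * np.clip(lod, 0.0, None)
    log_i += rng.normal(0.0, model.noise_sd, size=len(probes))
    return IntensitySample(probe_ids=list(probes.ids), values=np.exp(log_i))
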