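"""Threshold-scaled 8-bit projection of profile emission scores.

The filter threshold t (in bits) is the score whose Gumbel tail probability
equals the requested P-value. Scores are rescaled by tau = 256/t so that an
accumulated ungapped segment passes the threshold exactly when the 8-bit
accumulator reaches 256. Each emission's negative-log score s becomes

    s' = 2*tau - s*tau*log2(e)

(the bit score against a uniform 1/4 background, times tau), rounded half
away from zero and saturated to the signed 8-bit range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .phmm_io import ProfileHMM
from .ssv_core import ssv_max_scores_batch

LOG2E = math.log2(math.e)


class CalibrationError(RuntimeError):
    pass


@dataclass
class ProjectedModel:
    """tau-scaled signed 8-bit emission scores for one model."""

    source: ProfileHMM
    threshold_bits: float
    tau: float
    scores8: np.ndarray
    clamped_count: int
    p_value: float | None = None

    @property
    def K(self) -> int:
        return self.scores8.shape[0]


def threshold_from_gumbel(p: float, mu: float, lam: float, adjust_bits: float = 0.0) -> float:
    """Score whose Gumbel survival probability equals ``p``, plus an offset.

    The survival convention is P(S >= s) = 1 - exp(-exp(-lam*(s - mu))), so
    the threshold is s = mu - ln(-ln(1 - p))/lam + adjust_bits.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie in (0, 1)")
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    return mu - math.log(-math.log1p(-p)) / lam + adjust_bits


def gumbel_survival(s: float, mu: float, lam: float) -> float:
    """P(S >= s) under the Gumbel convention used by threshold_from_gumbel."""
    return -math.expm1(-math.exp(-lam * (s - mu)))


def compute_tau(t: float) -> float:
    """Scaling factor mapping threshold score t (bits) to accumulator 256."""
    if t <= 0:
        raise ValueError("threshold must be > 0")
    return 256.0 / t


def bit_scores(hmm: ProfileHMM) -> np.ndarray:
    """Full-precision emission bit scores against the uniform background.

    Entry (j, c) is log2(e^{-s} / (1/4)) = 2 - s*log2(e).
    """
    return 2.0 - hmm.match_scores * LOG2E


def project_unrounded(hmm: ProfileHMM, tau: float) -> np.ndarray:
    """tau-scaled emission scores before rounding/saturation."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    return 2.0 * tau - hmm.match_scores * (tau * LOG2E)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.trunc(x + np.copysign(0.5, x))


def reproject_scores(
    hmm: ProfileHMM, tau: float, p_value: float | None = None
) -> ProjectedModel:
    """Quantize a model's emissions to tau-scaled signed 8-bit integers.

    Rounding is half away from zero; values outside [-128, 127] saturate and
    are counted in ``clamped_count``.
    """
    unrounded = project_unrounded(hmm, tau)
    rounded = _round_half_away(unrounded)
    clamped = np.clip(rounded, -128, 127)
    clamped_count = int(np.sum(rounded != clamped))
    return ProjectedModel(
        source=hmm,
        threshold_bits=256.0 / tau,
        tau=tau,
        scores8=clamped.astype(np.int8),
        clamped_count=clamped_count,
        p_value=p_value,
    )


def project_model(
    hmm: ProfileHMM,
    p_value: float = 0.02,
    adjust_bits: float = 0.0,
    mu: float | None = None,
    lam: float | None = None,
) -> ProjectedModel:
    """Derive the threshold from Gumbel parameters and project the model.

    Gumbel parameters default to the model's own (from its STATS line or a
    prior calibration); explicit ``mu``/``lam`` override them.
    """
    if mu is None:
        mu = hmm.gumbel_mu
    if lam is None:
        lam = hmm.gumbel_lambda
    if mu is None or lam is None:
        raise ValueError(
            f"model {hmm.name!r} has no Gumbel parameters; calibrate or supply them"
        )
    t = threshold_from_gumbel(p_value, mu, lam, adjust_bits)
    projected = reproject_scores(hmm, compute_tau(t), p_value=p_value)
    return projected


def fit_gumbel(
    samples: np.ndarray, fixed_lambda: float | None = None
) -> tuple[float, float]:
    """Maximum-likelihood Gumbel (mu, lambda) for a sample of maxima.

    With ``fixed_lambda`` the scale is held and only the location is
    estimated (closed-form MLE). For maximum ungapped bit scores the
    asymptotic scale is ln 2, and holding it there tracks the upper tail
    noticeably better than the free two-parameter fit.
    """
    samples = np.asarray(samples, dtype=float)
    if np.ptp(samples) < 1e-12:
        raise CalibrationError("degenerate score distribution: all maxima equal")
    if fixed_lambda is None:
        loc, scale = stats.gumbel_r.fit(samples)
        return float(loc), float(1.0 / scale)
    if fixed_lambda <= 0:
        raise ValueError("fixed_lambda must be > 0")
    center = samples.mean()  # subtracted for exp() stability
    mu = center - math.log(np.mean(np.exp(-fixed_lambda * (samples - center)))) / fixed_lambda
    return float(mu), float(fixed_lambda)


LN2 = math.log(2.0)


def calibrate_gumbel_by_simulation(
    hmm: ProfileHMM,
    n_seqs: int,
    seq_len: int,
    seed: int,
    fixed_lambda: float | None = LN2,
) -> tuple[float, float]:
    """Fit Gumbel (mu, lambda) to simulated maximum ungapped bit scores.

    Simulates ``n_seqs`` i.i.d. uniform random sequences of ``seq_len``
    residues, computes each sequence's maximum ungapped segment bit score at
    full precision, and fits the Gumbel parameters by maximum likelihood.
    By default the scale is held at its asymptotic bit-score value ln 2 and
    only the location is estimated; pass ``fixed_lambda=None`` for the free
    two-parameter fit. Deterministic under a fixed seed.
    """
    if n_seqs < 100:
        raise ValueError("n_seqs must be >= 100 for a usable fit")
    if seq_len < hmm.K:
        raise ValueError("seq_len must be >= the model length")
    rng = np.random.default_rng(seed)
    scores = bit_scores(hmm)
    maxima = np.empty(n_seqs)
    # batch to bound memory at ~32 MB of codes per block
    block = max(1, min(n_seqs, 32_000_000 // max(seq_len, 1)))
    done = 0
    while done < n_seqs:
        b = min(block, n_seqs - done)
        codes = rng.integers(0, 4, size=(b, seq_len), dtype=np.uint8)
        maxima[done : done + b] = ssv_max_scores_batch(codes, scores)
        done += b
    return fit_gumbel(maxima, fixed_lambda=fixed_lambda)
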