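"""Gumbel (extreme-value) calibration of profile scores and e-values.

Local-alignment bit scores of random background sequences follow a Gumbel
distribution; each profile is calibrated by scoring ``n_random`` sequences
drawn i.i.d. from its background composition (lengths resampled from the
training alignment rows by default) and fitting location ``mu`` (bits) and
scale ``lambda`` (1/bits) by maximum likelihood. The e-value of a hit at
bit score ``s`` against a database of ``N`` sequences is then

    E(s) = N * P_gumbel(S >= s) = N * (1 - exp(-exp(-lambda * (s - mu)))).
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np
from scipy.stats import gumbel_r

from .profile import ProfileHMM
from .scoring import forward_bits


def fit_gumbel(scores) -> tuple[float, float]:
    """Maximum-likelihood Gumbel fit; returns (mu, lambda)."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2 or np.std(scores) == 0:
        raise ValueError("degenerate score distribution (zero variance)")
    loc, scale = gumbel_r.fit(scores)
    return float(loc), float(1.0 / scale)


def sample_null_scores(
    profile: ProfileHMM,
    n_random: int,
    length_dist: Optional[Callable] = None,
    seed: int = 0,
) -> np.ndarray:
    """Forward bit scores of ``n_random`` background sequences (seeded)."""
    rng = np.random.default_rng(seed)
    if length_dist is not None:
        lengths = np.asarray(length_dist(rng, n_random), dtype=int)
    elif profile.training_lengths:
        lengths = rng.choice(np.asarray(profile.training_lengths), size=n_random)
    else:
        lengths = np.full(n_random, profile.M)
    lengths = np.maximum(lengths, 1)
    pool = rng.choice(20, size=int(lengths.sum()), p=profile.null_freqs)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    scores = np.empty(n_random)
    for i in range(n_random):
        scores[i] = forward_bits(profile, pool[offsets[i] : offsets[i + 1]])
    return scores


def calibrate_evd(
    profile: ProfileHMM,
    n_random: int = 5000,
    length_dist: Optional[Callable] = None,
    seed: int = 0,
) -> tuple[float, float]:
    """Fit and attach Gumbel parameters to ``profile`` (deterministic per seed)."""
    if n_random < 100:
        raise ValueError("n_random must be >= 100")
    scores = sample_null_scores(profile, n_random, length_dist, seed)
    mu, lam = fit_gumbel(scores)
    profile.evd_mu = mu
    profile.evd_lambda = lam
    profile.metadata["calibration_seed"] = seed
    return mu, lam


def evalue(profile: ProfileHMM, bit_score, db_size: int):
    """Expected number of false hits at ``bit_score`` in ``db_size`` sequences."""
    if not profile.calibrated:
        raise ValueError(f"profile {profile.name} is not EVD-calibrated")
    if db_size < 1:
        raise ValueError("db_size must be >= 1")
    tail = gumbel_r.sf(bit_score, loc=profile.evd_mu, scale=1.0 / profile.evd_lambda)
    return db_size * tail
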