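"""Circular statistics for segment directions.

The directional question — do the flies prefer some bearing relative to the
sun (or the observer)? — is answered with Moore's modified Rayleigh (MMR)
test: each straight flight segment contributes its circular mean direction
and its resultant vector length, and the test rank-weights the directions by
length so long, highly directed segments count more.  The null distribution
of the statistic

    R* = sqrt(X^2 + Y^2) / n^(3/2),
    X = sum_i rank_i cos(theta_i),  Y = sum_i rank_i sin(theta_i)

is sampled by Monte Carlo (angles uniform on the circle, rank weights kept),
which is exact for the small, tie-prone segment counts encountered here; the
published critical-value table serves only as a cross-check in the tests.

Axial (bimodal) preferences, e.g. flying at +/- 90 degrees to the sun, are
detected by first doubling the angles modulo 360 degrees, which folds a
two-opposite-modes distribution into a unimodal one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .kinematics import wrap_angle


def circular_mean(angles_deg: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Weighted circular mean, degrees in (-180, 180].

    Raises ``ValueError`` when the resultant vanishes (e.g. two opposite
    equal-weight directions), where the mean is undefined.
    """
    a = np.radians(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        raise ValueError("need at least one angle")
    w = np.ones_like(a) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != a.shape:
        raise ValueError("weights must match angles")
    C = float(np.sum(w * np.cos(a)))
    S = float(np.sum(w * np.sin(a)))
    if np.hypot(C, S) < 1e-12 * max(np.sum(np.abs(w)), 1e-300):
        raise ValueError("zero resultant: circular mean undefined")
    return float(wrap_angle(np.degrees(np.arctan2(S, C))))


def resultant_length(angles_deg: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Magnitude of the (weighted) vector sum of unit direction vectors."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    w = np.ones_like(a) if weights is None else np.asarray(weights, dtype=float)
    return float(np.hypot(np.sum(w * np.cos(a)), np.sum(w * np.sin(a))))


@dataclass
class MMRResult:
    """Weighted Moore's modified Rayleigh test outcome."""

    r_star: float
    mean_angle: float  # deg, direction of the rank-weighted resultant
    p_value: float
    n: int
    n_mc: int
    seed: int | None = None

    @property
    def significant(self) -> bool:
        return self.p_value <= 0.05


def _mmr_statistic(angles_rad: np.ndarray, ranks: np.ndarray) -> tuple[float, float, float]:
    X = float(np.sum(ranks * np.cos(angles_rad)))
    Y = float(np.sum(ranks * np.sin(angles_rad)))
    n = angles_rad.size
    return np.hypot(X, Y) / n**1.5, X, Y


def mmr_null_sample(
    ranks: np.ndarray, n_mc: int, rng: np.random.Generator
) -> np.ndarray:
    """Null R* values: uniform angles, the observed rank weights kept."""
    ranks = np.asarray(ranks, dtype=float)
    n = ranks.size
    out = np.empty(n_mc)
    chunk = max(1, int(2_000_000 / max(n, 1)))
    done = 0
    while done < n_mc:
        m = min(chunk, n_mc - done)
        theta = rng.uniform(0.0, 2.0 * np.pi, size=(m, n))
        X = np.cos(theta) @ ranks
        Y = np.sin(theta) @ ranks
        out[done : done + m] = np.hypot(X, Y) / n**1.5
        done += m
    return out


def mmr_test(
    angles_deg: np.ndarray,
    lengths: np.ndarray,
    n_mc: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> MMRResult:
    """Rank-weighted Moore's modified Rayleigh test with a Monte-Carlo null.

    ``lengths`` enter only through their ascending ranks (ties receive mean
    ranks); the Monte-Carlo p-value is (1 + #{null R* >= observed}) / (1 + n_mc),
    never exactly zero.  Deterministic given ``seed`` (or a supplied ``rng``).
    """
    angles = np.asarray(angles_deg, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if angles.ndim != 1 or angles.shape != lengths.shape:
        raise ValueError("angles and lengths must be matching 1-D arrays")
    n = angles.size
    if n < 3:
        raise ValueError("MMR test needs at least 3 (angle, length) pairs")
    if np.any(lengths <= 0):
        raise ValueError("vector lengths must be positive")
    ranks = rankdata(lengths)  # ascending, mean ranks for ties
    r_star, X, Y = _mmr_statistic(np.radians(angles), ranks)
    if rng is None:
        rng = np.random.default_rng(seed)
    # the null depends only on the multiset of ranks; sorting makes the
    # Monte-Carlo p-value invariant to the order segments were supplied in
    null = mmr_null_sample(np.sort(ranks), n_mc, rng)
    p = (1.0 + int(np.sum(null >= r_star))) / (1.0 + n_mc)
    mean_angle = float(wrap_angle(np.degrees(np.arctan2(Y, X))))
    return MMRResult(
        r_star=float(r_star), mean_angle=mean_angle, p_value=float(p), n=n, n_mc=n_mc, seed=seed
    )


def mmr_critical_value(
    n: int, alpha: float = 0.05, n_mc: int = 200_000, seed: int | None = 0
) -> float:
    """Monte-Carlo (1 - alpha) quantile of the null R* for untied ranks 1..n."""
    rng = np.random.default_rng(seed)
    null = mmr_null_sample(np.arange(1, n + 1, dtype=float), n_mc, rng)
    return float(np.quantile(null, 1.0 - alpha))


def axial_transform(angles_deg: np.ndarray) -> np.ndarray:
    """Angle doubling: theta -> 2 theta mod 360, folding axial data unimodal."""
    a = np.mod(np.asarray(angles_deg, dtype=float), 360.0)
    return np.mod(2.0 * a, 360.0)


def rotate_reference(angles_deg: np.ndarray, reference_azimuth: float) -> np.ndarray:
    """Express directions relative to a new reference azimuth (sun -> observer).

    Elementwise subtraction wrapped to (-180, 180]; a common rotation leaves
    R* unchanged, only the mean angle moves.
    """
    return wrap_angle(np.asarray(angles_deg, dtype=float) - reference_azimuth)
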