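"""Temporal synchronisation of two unsynchronised camera streams.

Consumer cameras cannot be genlocked, so each video films a bank of eight
LEDs driven by a microcontroller that counts at 25 Hz in reflected binary
(Gray) code.  Decoding the LED intensities in both videos yields two integer
counter sequences that are aligned by cross-correlation with single-frame
accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

N_LEDS = 8
COUNTER_MODULUS = 2**N_LEDS


class SyncError(RuntimeError):
    """Raised when the two counter sequences cannot be aligned unambiguously."""


def gray_encode(n: int) -> np.ndarray:
    """Encode a counter value as an 8-bit reflected binary (Gray) code.

    Bit 0 of the returned vector is the least significant bit (LED 0).
    """
    n = int(n)
    if not 0 <= n < COUNTER_MODULUS:
        raise ValueError(f"counter value {n} outside 0..{COUNTER_MODULUS - 1}")
    g = n ^ (n >> 1)
    return np.array([(g >> i) & 1 for i in range(N_LEDS)], dtype=np.uint8)


def gray_decode(bits: np.ndarray) -> int:
    """Invert :func:`gray_encode`: 8-bit Gray code vector -> integer."""
    bits = np.asarray(bits)
    if bits.shape != (N_LEDS,):
        raise ValueError(f"expected {N_LEDS} bits, got shape {bits.shape}")
    g = 0
    for i in range(N_LEDS):
        g |= int(bits[i]) << i
    n = g
    n ^= n >> 1
    n ^= n >> 2
    n ^= n >> 4
    return n


def binarize_leds(
    intensities: np.ndarray,
    min_separation: float = 1.0,
    bimodality_ratio: float = 4.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Threshold per-channel LED intensity traces into 0/1 bits.

    Each channel is split at the midpoint between its two intensity modes
    (two-means clustering on the 1-D intensities).  A channel without bimodal
    structure over the clip (a high counter bit that never toggles, a dead
    LED) cannot be assigned a level and is flagged invalid; its bits are
    returned as zero.  "Bimodal" requires the mode separation to exceed both
    ``min_separation`` and ``bimodality_ratio`` times the within-mode spread,
    so pure sensor noise on a constant channel is not split into fake modes.
    Consistent zeroing of the same stuck channels in both cameras leaves the
    cross-correlation alignment unaffected.

    Returns
    -------
    bits : (n_frames, 8) uint8 array
    valid : (8,) bool array, False for flagged channels
    """
    intensities = np.asarray(intensities, dtype=float)
    if intensities.ndim != 2 or intensities.shape[1] != N_LEDS:
        raise ValueError("intensities must be (n_frames, 8)")
    if intensities.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    n = intensities.shape[0]
    bits = np.zeros((n, N_LEDS), dtype=np.uint8)
    valid = np.ones(N_LEDS, dtype=bool)
    for ch in range(N_LEDS):
        v = intensities[:, ch]
        lo, hi = float(v.min()), float(v.max())
        m0, m1 = lo, hi
        if hi - lo >= min_separation:
            # two-means in 1-D, initialised at the extremes
            for _ in range(20):
                thr = 0.5 * (m0 + m1)
                low, high = v[v <= thr], v[v > thr]
                if low.size == 0 or high.size == 0:
                    break
                new0, new1 = low.mean(), high.mean()
                if np.isclose(new0, m0) and np.isclose(new1, m1):
                    break
                m0, m1 = new0, new1
        thr = 0.5 * (m0 + m1)
        low, high = v[v <= thr], v[v > thr]
        within = max(
            float(low.std()) if low.size else 0.0, float(high.std()) if high.size else 0.0
        )
        if m1 - m0 < max(min_separation, bimodality_ratio * within):
            valid[ch] = False
            logger.warning("LED channel %d has no bimodal structure; excluded", ch)
            continue
        bits[:, ch] = (v > thr).astype(np.uint8)
    return bits, valid


def decode_counts(intensities: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Binarize an LED trace and decode each frame's Gray code to an integer.

    Returns the per-frame counter values and the channel validity mask.
    Flagged channels contribute 0 bits, so the decoded sequence is consistent
    between cameras as long as the same channels are stuck in both.
    """
    bits, valid = binarize_leds(intensities)
    counts = np.array([gray_decode(row) for row in bits], dtype=int)
    return counts, valid


@dataclass
class SyncResult:
    """Frame offset of camera B relative to camera A.

    ``offset`` is positive when B's stream lags A's: ``B[j] == A[j - offset]``
    on the decoded counter sequences, i.e. frame ``k`` of A shows the same
    instant as frame ``k + offset`` of B.
    """

    offset: int
    confidence: float
    score: float
    decoded_counts_a: np.ndarray = field(repr=False)
    decoded_counts_b: np.ndarray = field(repr=False)


def _run_lengths(counts: np.ndarray) -> int:
    """Median run length of constant stretches (frames per counter tick)."""
    change = np.flatnonzero(np.diff(counts) != 0)
    if change.size < 2:
        return 1
    runs = np.diff(change)
    return max(int(np.median(runs)), 1)


def synchronise(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    max_lag: int | None = None,
    min_confidence: float = 1.5,
    min_overlap: int = 20,
) -> SyncResult:
    """Align two decoded counter sequences by maximising frame agreement.

    The matching score at lag ``k`` is the fraction of equal counter values
    over the overlap of ``A[i]`` and ``B[i + k]``; the offset is the argmax.
    Because each counter value persists for several frames (10 at 250 fps and
    a 25 Hz counter), lags within one counter period of the true offset score
    almost as high; the confidence ratio therefore compares the best peak to
    the best score *outside* one counter period of it.
    """
    counts_a = np.asarray(counts_a, dtype=int)
    counts_b = np.asarray(counts_b, dtype=int)
    if counts_a.size < 2 or counts_b.size < 2:
        raise ValueError("counter sequences too short")
    if max_lag is None:
        max_lag = min(counts_a.size, counts_b.size) // 2
    lags = np.arange(-max_lag, max_lag + 1)
    scores = np.full(lags.size, -np.inf)
    for idx, k in enumerate(lags):
        # compare A[i] with B[i + k]
        a0, a1 = max(0, -k), min(counts_a.size, counts_b.size - k)
        if a1 - a0 < min_overlap:
            continue
        seg_a = counts_a[a0:a1]
        seg_b = counts_b[a0 + k : a1 + k]
        scores[idx] = float(np.mean(seg_a == seg_b))
    if not np.isfinite(scores).any():
        raise SyncError("no lag with sufficient overlap")
    best = int(np.argmax(scores))
    period = _run_lengths(counts_a)
    away = np.abs(lags - lags[best]) >= period
    second = float(scores[away].max()) if away.any() and np.isfinite(scores[away]).any() else 0.0
    second = max(second, 1e-12)
    confidence = float(scores[best]) / second
    if confidence < min_confidence:
        raise SyncError(
            f"ambiguous synchronisation: best score {scores[best]:.3f} at lag "
            f"{lags[best]}, next peak {second:.3f} (confidence {confidence:.2f})"
        )
    return SyncResult(
        offset=int(lags[best]),
        confidence=confidence,
        score=float(scores[best]),
        decoded_counts_a=counts_a,
        decoded_counts_b=counts_b,
    )
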