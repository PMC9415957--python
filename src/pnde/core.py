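"""Poincaré plot entropies for univariate time series.

The Poincaré plot of a series ``s`` is the scatter of delayed pairs
``(x_i, x_{i+tau})`` built after shifting the series to nonnegative values
(``x = s - min(s)``), so every point lies in the first quadrant.  Partitioning
the quadrant into ``W`` concentric annuli ("sector rings") of equal radial
width yields an occupancy probability set ``p_k``; Shannon entropy of that
set is the distribution entropy (DE).

DE is blind to *where* the occupied rings sit: permuting the ring
probabilities leaves it unchanged.  The nonextensive distribution entropy
(NDE) fixes this by deriving a per-ring Tsallis parameter ``q_k`` from the
reverse-subtracted distance of each ring's center to the origin, so distal
(high-amplitude) rings receive small ``q`` and hence large weight, and
summing the generalized-entropy terms

    S = sum_k (p_k - p_k**q_k) / (q_k - 1)

which recovers Shannon entropy in the ``q_k -> 1`` limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PositiveSeries",
    "PoincarePoints",
    "RingPartition",
    "EntropyValue",
    "to_positive_series",
    "build_poincare_points",
    "partition_sector_rings",
    "distribution_entropy",
    "tsallis_entropy",
    "nonextensive_params",
    "nne",
    "nde",
    "de",
]

# q this close to 1 is evaluated by the Shannon limit -p*ln(p) to avoid 0/0
_Q_ONE_TOL = 1e-8


@dataclass(frozen=True)
class PositiveSeries:
    """Min-subtracted series: ``values = s - min(s)``, so ``min(values) == 0``."""

    values: np.ndarray
    offset: float  # the subtracted minimum of the raw series


@dataclass(frozen=True)
class PoincarePoints:
    """Delayed-pair scatter ``(x_i, x_{i+delay})`` in the first quadrant."""

    x: np.ndarray  # abscissae, length N - delay
    y: np.ndarray  # ordinates
    delay: int


@dataclass(frozen=True)
class RingPartition:
    """Equal-width sector-ring partition of the Poincaré scatter.

    Ring ``k`` (1-based) is the annulus ``[L_{k-1}, L_k)`` with ``L_0 = 0``;
    the outermost ring is closed at ``L_max`` so the farthest point is always
    counted.  ``degenerate`` flags the all-points-at-origin case
    (``L_max == 0``), where all mass is placed in ring 1 by convention.
    """

    W: int
    L_max: float
    dl: float
    radii: np.ndarray          # L_k, k = 1..W, strictly increasing, L_W = L_max
    counts: np.ndarray         # Snum_k
    probabilities: np.ndarray  # p_k = Snum_k / n_points
    degenerate: bool = False

    @property
    def n_points(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class EntropyValue:
    """An entropy measurement in nats, tagged with the method that produced it."""

    value: float
    method: str  # one of {"DE", "TSALLIS", "NNE", "NDE"}
    W: int
    meta: dict = field(default_factory=dict)


def _as_series(series: Sequence[float]) -> np.ndarray:
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if arr.size < 2:
        raise ValueError(f"series must have at least 2 samples, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("series contains non-finite values")
    return arr


def to_positive_series(series: Sequence[float]) -> PositiveSeries:
    """Shift a raw series so its minimum is exactly zero.

    Returns the shifted values together with the subtracted minimum, which is
    the only record needed to undo the shift.
    """
    arr = _as_series(series)
    offset = float(arr.min())
    return PositiveSeries(values=arr - offset, offset=offset)


def build_poincare_points(x: PositiveSeries, delay: int = 1) -> PoincarePoints:
    """Pair each sample with its ``delay``-step successor.

    ``delay=1`` gives the standard-form Poincaré plot relating adjacent
    samples; the pair count is ``N - delay``.
    """
    if delay < 1:
        raise ValueError(f"delay must be >= 1, got {delay}")
    v = x.values
    if v.size <= delay:
        raise ValueError(
            f"series of length {v.size} too short for delay {delay}"
        )
    return PoincarePoints(x=v[:-delay], y=v[delay:], delay=delay)


def partition_sector_rings(points: PoincarePoints, W: int) -> RingPartition:
    """Bin Poincaré points into ``W`` equal-width annuli about the origin.

    The radial coordinate of a point is its Euclidean norm.  ``L_max`` is the
    largest radial distance in the scatter and ``dl = L_max / W`` the ring
    width.  When every point sits at the origin the partition is degenerate:
    all mass goes to ring 1 and callers should map the entropy to 0.
    """
    if W < 1:
        raise ValueError(f"ring count W must be >= 1, got {W}")
    if points.x.size == 0:
        raise ValueError("empty point set")
    d = np.hypot(points.x, points.y)
    L_max = float(d.max())
    n = d.size
    counts = np.zeros(W, dtype=np.int64)
    if L_max == 0.0:
        counts[0] = n
        return RingPartition(
            W=W, L_max=0.0, dl=0.0,
            radii=np.zeros(W), counts=counts,
            probabilities=counts / n, degenerate=True,
        )
    dl = L_max / W
    # half-open rings [L_{k-1}, L_k); the outermost point (d == L_max) would
    # index ring W+1, so clip it into the closed last ring
    idx = np.minimum((d / dl).astype(np.int64), W - 1)
    counts = np.bincount(idx, minlength=W).astype(np.int64)
    radii = dl * np.arange(1, W + 1)
    radii[-1] = L_max  # guard against round-off on the outer boundary
    return RingPartition(
        W=W, L_max=L_max, dl=dl, radii=radii,
        counts=counts, probabilities=counts / n,
    )


def distribution_entropy(partition: RingPartition) -> EntropyValue:
    """Shannon entropy of the ring-occupancy probabilities, in nats.

    ``0 * log 0`` is taken as 0; the value lies in ``[0, ln W]`` and equals 0
    for a degenerate (single-occupied-ring) partition.
    """
    p = partition.probabilities
    nz = p > 0
    value = float(-(p[nz] * np.log(p[nz])).sum()) if not partition.degenerate else 0.0
    return EntropyValue(value=max(value, 0.0), method="DE", W=partition.W,
                        meta={"degenerate": partition.degenerate})


def tsallis_entropy(p: Sequence[float], q: float) -> float:
    """Classical Tsallis entropy ``(1 - sum p_i**q) / (q - 1)`` for scalar q.

    Undefined at ``q = 1``; use :func:`distribution_entropy` for the Shannon
    limit.
    """
    if q == 1:
        raise ValueError("q = 1 is the Shannon limit; use distribution_entropy")
    p = np.asarray(p, dtype=float)
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("probabilities must sum to 1")
    nz = p > 0
    return float((1.0 - (p[nz] ** q).sum()) / (q - 1.0))


def nonextensive_params(partition: RingPartition) -> np.ndarray:
    """Per-ring Tsallis parameters from reverse-subtracted ring-center distance.

    Ring ``k`` has center distance ``(k - 1/2) * dl``; reverse subtraction
    from ``L_max`` gives

        q_k = 1 + L_max - (k - 1) * dl - dl / 2

    so the innermost ring carries the largest ``q`` (smallest weight) and the
    outermost the smallest, ``q_W = 1 + dl/2 > 1``.  The parameters are in the
    input's native amplitude units; no normalization is applied.
    """
    if partition.degenerate or partition.dl == 0.0:
        raise ValueError("degenerate partition (L_max = 0) has no q-set; "
                         "map the series to entropy 0 instead")
    k = np.arange(partition.W, dtype=float)
    return 1.0 + partition.L_max - k * partition.dl - partition.dl / 2.0


def nne(p: Sequence[float], q: Sequence[float]) -> float:
    """Nonextensive entropy with a per-ring parameter set.

    Sums ``(p_k - p_k**q_k) / (q_k - 1)`` over rings.  Empty rings and rings
    holding all mass contribute 0; ``q_k`` within 1e-8 of 1 is evaluated by
    its Shannon limit ``-p_k ln p_k`` for continuity.  Nonnegative for all
    valid inputs.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"p and q length mismatch: {p.shape} vs {q.shape}")
    if np.any(q < 1.0 - _Q_ONE_TOL):
        raise ValueError("all q_k must be >= 1")
    total = 0.0
    nz = p > 0
    near1 = nz & (np.abs(q - 1.0) < _Q_ONE_TOL)
    gen = nz & ~near1
    if near1.any():
        total += float(-(p[near1] * np.log(p[near1])).sum())
    if gen.any():
        total += float(((p[gen] - p[gen] ** q[gen]) / (q[gen] - 1.0)).sum())
    return total


def nde(series: Sequence[float], W: int = 50, delay: int = 1) -> EntropyValue:
    """Poincaré plot nonextensive distribution entropy of a raw series.

    Composes min-subtraction, delayed-pair construction, sector-ring
    partitioning, the distance-derived q-set, and the nonextensive sum.  A
    constant series (degenerate scatter) scores 0.  The result is invariant
    to adding a constant to the input but, unlike DE, not to rescaling it:
    the q-set carries the amplitude scale through ``L_max``.
    """
    pos = to_positive_series(series)
    pts = build_poincare_points(pos, delay=delay)
    part = partition_sector_rings(pts, W)
    meta = {"delay": delay, "offset": pos.offset, "L_max": part.L_max}
    if part.degenerate:
        return EntropyValue(value=0.0, method="NDE", W=W,
                            meta={**meta, "degenerate": True})
    q = nonextensive_params(part)
    return EntropyValue(value=nne(part.probabilities, q), method="NDE", W=W,
                        meta=meta)


def de(series: Sequence[float], W: int = 50, delay: int = 1) -> EntropyValue:
    """Poincaré plot distribution entropy of a raw series (Shannon, in nats)."""
    pos = to_positive_series(series)
    pts = build_poincare_points(pos, delay=delay)
    part = partition_sector_rings(pts, W)
    ev = distribution_entropy(part)
    return EntropyValue(value=ev.value, method="DE", W=W,
                        meta={"delay": delay, "offset": pos.offset,
                              "L_max": part.L_max,
                              "degenerate": part.degenerate})
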