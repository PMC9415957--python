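"""Exact-covariance fractional Brownian motion simulation.

Fractional Brownian motion (fBm) with Hurst index H is the centered Gaussian
process with covariance E[B_t B_s] = (t^{2H} + s^{2H} - |t-s|^{2H}) / 2 on an
integer time grid, so Var(B_t) = t^{2H}.  Its unit-step increments form
fractional Gaussian noise (fGn), a stationary process whose autocovariance
follows in closed form; sampling fGn exactly and cumulating gives an exact
fBm path.  Sampling uses Davies-Harte circulant embedding (O(n log n)) with a
Cholesky fallback should the embedding produce a negative eigenvalue.

H = 0.5 is ordinary Brownian motion; H > 0.5 gives persistent (positively
correlated) increments, H < 0.5 anti-persistent ones.  The degenerate H = 1
process is the perfectly correlated line B_t = t * Z.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FbmSpec", "fgn_autocovariance", "generate_fgn", "generate_fbm"]


@dataclass(frozen=True)
class FbmSpec:
    """Simulation request: Hurst index H in (0, 1], length n >= 2, RNG seed."""

    H: float
    n: int
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.H <= 1.0:
            raise ValueError(f"Hurst index must be in (0, 1], got {self.H}")
        if self.n < 2:
            raise ValueError(f"series length must be >= 2, got {self.n}")


def fgn_autocovariance(H: float, lag) -> np.ndarray | float:
    """Autocovariance of unit-variance fGn at integer lag(s).

    gamma(k) = (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H}) / 2, with gamma(0) = 1.
    For H = 0.5 the increments are white: gamma(k) = 0 for k >= 1.
    """
    if not 0.0 < H < 1.0:
        raise ValueError(f"Hurst index must be in (0, 1), got {H}")
    k = np.abs(np.asarray(lag, dtype=float))
    g = 0.5 * ((k + 1) ** (2 * H) - 2 * k ** (2 * H) + np.abs(k - 1) ** (2 * H))
    return float(g) if np.isscalar(lag) else g


def _fgn_davies_harte(H: float, n: int, rng: np.random.Generator) -> np.ndarray | None:
    """Circulant-embedding fGn sample, or None if the embedding fails."""
    gamma = fgn_autocovariance(H, np.arange(n))
    # first row of the 2n-circulant embedding of the Toeplitz covariance
    row = np.concatenate([gamma, [0.0], gamma[:0:-1]])
    m = 2 * n
    lam = np.fft.fft(row).real
    if np.any(lam < -1e-10 * lam.max()):
        return None
    lam = np.maximum(lam, 0.0)
    # Hermitian random spectrum: W[k] = sqrt(lam_k / 2m) (a_k + i b_k) with
    # W[m-k] = conj(W[k]); the 0 and Nyquist bins are real with weight lam/m
    a = rng.standard_normal(n + 1)
    b = rng.standard_normal(n + 1)
    w = np.zeros(m, dtype=complex)
    w[0] = np.sqrt(lam[0] / m) * a[0]
    w[n] = np.sqrt(lam[n] / m) * a[n]
    half = np.sqrt(lam[1:n] / (2.0 * m)) * (a[1:n] + 1j * b[1:n])
    w[1:n] = half
    w[n + 1:] = np.conj(half[::-1])
    return np.fft.fft(w)[:n].real


def _fgn_cholesky(H: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """O(n^3) exact fallback via the Toeplitz covariance factor."""
    from scipy.linalg import cholesky, toeplitz

    cov = toeplitz(fgn_autocovariance(H, np.arange(n)))
    return cholesky(cov, lower=True) @ rng.standard_normal(n)


def generate_fgn(H: float, n: int, seed: int = 0) -> np.ndarray:
    """Exact sample of n fractional Gaussian noise values, seeded."""
    rng = np.random.default_rng(seed)
    out = _fgn_davies_harte(H, n, rng)
    if out is None:  # pragma: no cover - embedding is valid for all H in (0,1)
        out = _fgn_cholesky(H, n, np.random.default_rng(seed))
    return out


def generate_fbm(spec: FbmSpec) -> np.ndarray:
    """Exact fBm path of length ``spec.n`` with B_0 = 0.

    Increments are stationary Gaussian with the exact fGn autocovariance, so
    the path has Var(B_t) = t^{2H} without any synthesis approximation.
    Seeded runs are bit-reproducible.
    """
    if spec.H == 1.0:
        z = np.random.default_rng(spec.seed).standard_normal()
        return z * np.arange(spec.n, dtype=float)
    increments = generate_fgn(spec.H, spec.n - 1, spec.seed)
    path = np.empty(spec.n)
    path[0] = 0.0
    np.cumsum(increments, out=path[1:])
    return path
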