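"""Orientation-sampling and distribution diagnostics.

* generalized sampling parameter Xi of a bond-vector set (0 = optimal
  orientational sampling, 1 = collinear);
* powder-style histogram reading of (Da, Rh) from a set of normalized
  couplings, and the expected histogram for uniformly distributed vectors;
* dipolar-wave fitting of sequential amide couplings along a helix;
* the Monte-Carlo distribution of normalized scalar products P for random
  tensor pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation


__all__ = [
    "sampling_xi",
    "HistogramEstimate",
    "histogram_estimate",
    "expected_histogram",
    "DipolarWave",
    "dipolar_wave_fit",
    "random_P_distribution",
]


def _unit5(vectors: np.ndarray) -> np.ndarray:
    """Map unit 3-vectors b to unit 5-vectors representing b b^T - I/3
    (the direction each vector probes in Saupe-tensor space)."""
    b = np.asarray(vectors, dtype=float)
    b = b / np.linalg.norm(b, axis=1, keepdims=True)
    bx, by, bz = b[:, 0], b[:, 1], b[:, 2]
    s3 = np.sqrt(3.0)
    f = np.column_stack([bz ** 2 - 1.0 / 3.0,
                         (bx ** 2 - by ** 2) / s3,
                         2.0 * bx * by / s3,
                         2.0 * bx * bz / s3,
                         2.0 * by * bz / s3])
    return f / np.linalg.norm(f, axis=1, keepdims=True)


def sampling_xi(vectors) -> float:
    """Generalized sampling parameter Xi of a set of bond vectors.

    Each unit vector probes one direction in the five-dimensional space of
    Saupe tensor components.  Xi measures how uniformly those directions
    cover that space through the determinant (generalized variance) of
    their 5x5 second-moment matrix M — the D-optimality efficiency of the
    RDC design:

        Xi = 1 - [5^5 det(M)]^(1/5),   M = (1/N) sum_k f_k f_k^T

    with f_k the unit 5-vector of bond vector b_k.  Isotropic sampling
    gives M = I/5 and Xi = 0 (optimal); coplanar/collinear sets make M
    singular and Xi = 1 (the tensor is not determined).  Xi is invariant
    under global rotations and under sign flips of individual vectors.
    """
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2 or vectors.shape[1] != 3 or len(vectors) < 2:
        raise ValueError("sampling_xi needs >= 2 three-dimensional vectors")
    f = _unit5(vectors)
    M = f.T @ f / len(f)
    det = max(float(np.linalg.det(M)), 0.0)
    return float(1.0 - (5.0 ** 5 * det) ** 0.2)


@dataclass(frozen=True)
class HistogramEstimate:
    """Powder-pattern reading of a normalized-RDC distribution."""

    Da_est: float
    Rh_est: float
    D_zz: float
    D_yy: float
    D_xx: float
    bin_width: float
    n: int
    degenerate: bool = False


def histogram_estimate(normalized_rdcs, bins: int = 30) -> HistogramEstimate:
    """Estimate (Da, Rh) from the extrema of a normalized-RDC distribution.

    For well-sampled orientations the distribution approaches the powder
    pattern with support [D_yy, D_zz] (taking Da > 0): the extremum of
    larger magnitude is D_zz = 2 Da, the opposite extremum is D_yy, and
    D_xx (the singular mode of the pattern) follows from tracelessness,
    D_xx = -(D_zz + D_yy).  Rh = (2/3)(D_xx - D_yy)/D_zz.  Intended as a
    rough, structure-free estimate; warns below 30 values.
    """
    d = np.asarray(list(normalized_rdcs), dtype=float)
    if d.size < 5:
        raise ValueError(f"histogram estimate needs >= 5 values, got {d.size}")
    if d.size < 30:
        import warnings
        warnings.warn(f"histogram estimate from only {d.size} values is unreliable")
    lo, hi = float(d.min()), float(d.max())
    width = (hi - lo) / bins
    if hi - lo <= 0 or not np.isfinite(width):
        return HistogramEstimate(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, d.size,
                                 degenerate=True)
    if abs(hi) >= abs(lo):
        dzz, dyy = hi, lo
    else:
        dzz, dyy = lo, hi
    dxx = -(dzz + dyy)
    da = dzz / 2.0
    rh = (2.0 / 3.0) * (dxx - dyy) / dzz
    return HistogramEstimate(Da_est=da, Rh_est=float(np.clip(rh, 0.0, 2.0 / 3.0)),
                             D_zz=dzz, D_yy=dyy, D_xx=dxx,
                             bin_width=width, n=d.size)


def expected_histogram(Da: float, Rh: float, n: int = 10000, bins: int = 30,
                       seed: int = 0, bin_range=None):
    """Histogram of D = Da[(3 cos^2 th - 1) + (3/2) Rh sin^2 th cos 2ph]
    over uniformly distributed orientations (seeded, area-preserving
    sampling in (cos th, ph)).  Returns (bin_edges, counts) with counts
    summing to n."""
    if n < 1000:
        raise ValueError("expected_histogram needs n >= 1000 orientations")
    rng = np.random.default_rng(seed)
    cos_t = rng.uniform(-1.0, 1.0, size=n)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    sin2 = 1.0 - cos_t ** 2
    d = Da * ((3.0 * cos_t ** 2 - 1.0) + 1.5 * Rh * sin2 * np.cos(2.0 * phi))
    counts, edges = np.histogram(d, bins=bins, range=bin_range)
    return edges, counts


@dataclass(frozen=True)
class DipolarWave:
    """Sinusoid fit D(i) = mean + amplitude * cos(2 pi i / period + phase)."""

    period: float
    amplitude: float
    phase: float
    mean: float
    rms_residual: float
    flat: bool = False


def dipolar_wave_fit(residue_rdcs, period_grid=None) -> DipolarWave:
    """Fit the dipolar wave to (residue number, amide RDC) points.

    Sequential amide couplings along an alpha-helix trace a sinusoid with
    the helical periodicity (~3.6 residues).  A coarse grid over the period
    (default 2.5-6.0 residues) with a linear solve for the remaining
    parameters is followed by local nonlinear refinement.  A (near-)
    constant input has no identifiable period and is returned flagged
    ``flat``.
    """
    pts = sorted((int(i), float(d)) for i, d in residue_rdcs)
    if len(pts) < 5:
        raise ValueError(f"dipolar wave fit needs >= 5 points, got {len(pts)}")
    i = np.array([p[0] for p in pts], dtype=float)
    d = np.array([p[1] for p in pts], dtype=float)
    spread = d.max() - d.min()
    scale = max(abs(d).max(), 1.0)
    if spread < 1e-9 * scale:
        return DipolarWave(period=np.nan, amplitude=0.0, phase=0.0,
                           mean=float(d.mean()), rms_residual=0.0, flat=True)
    if period_grid is None:
        period_grid = np.arange(2.5, 6.01, 0.02)

    def lin_fit(T):
        A = np.column_stack([np.ones_like(i), np.cos(2 * np.pi * i / T),
                             np.sin(2 * np.pi * i / T)])
        coef, *_ = np.linalg.lstsq(A, d, rcond=None)
        r = A @ coef - d
        return coef, float(r @ r)

    best_T, best_sse, best_coef = None, np.inf, None
    for T in period_grid:
        coef, sse = lin_fit(T)
        if sse < best_sse:
            best_T, best_sse, best_coef = T, sse, coef

    def resid(x):
        m, a, b, T = x
        return m + a * np.cos(2 * np.pi * i / T) + b * np.sin(2 * np.pi * i / T) - d

    sol = least_squares(resid, [*best_coef, best_T],
                        bounds=([-np.inf] * 3 + [1.5], [np.inf] * 3 + [20.0]))
    m, a, b, T = sol.x
    amp = float(np.hypot(a, b))
    phase = float(np.degrees(np.arctan2(-b, a)))
    rms = float(np.sqrt(np.mean(sol.fun ** 2)))
    return DipolarWave(period=float(T), amplitude=amp, phase=phase,
                       mean=float(m), rms_residual=rms)


def random_P_distribution(n_pairs: int = 10000, seed: int = 0, bins: int = 20):
    """Monte-Carlo distribution of P(S_i, S_j) for random tensor pairs.

    Tensors have uniformly random orientations (Haar-distributed rotations)
    and rhombicity uniform in [0, 2/3].  Returns a dict with the |P|
    histogram over [0, 1] (matching the convention that the distribution is
    reported on that range), the signed-P histogram over [-1, 1], and the
    raw P samples.
    """
    if n_pairs < 2:
        raise ValueError("need at least 2 pairs")
    rng = np.random.default_rng(seed)

    def batch(n):
        mats = Rotation.random(num=n, random_state=rng).as_matrix()
        rh = rng.uniform(0.0, 2.0 / 3.0, size=n)
        # principal values for Da = 1: (-(1 - 3Rh/2), -(1 + 3Rh/2), 2)
        lam = np.column_stack([-(1 - 1.5 * rh), -(1 + 1.5 * rh),
                               np.full(n, 2.0)])
        m = np.einsum("nij,nj,nkj->nik", mats, lam, mats)
        s3 = np.sqrt(3.0)
        v = np.column_stack([m[:, 2, 2], (m[:, 0, 0] - m[:, 1, 1]) / s3,
                             2 * m[:, 0, 1] / s3, 2 * m[:, 0, 2] / s3,
                             2 * m[:, 1, 2] / s3])
        return v / np.linalg.norm(v, axis=1, keepdims=True)

    vi = batch(n_pairs)
    vj = batch(n_pairs)
    P = np.sum(vi * vj, axis=1)
    abs_counts, abs_edges = np.histogram(np.abs(P), bins=bins, range=(0.0, 1.0))
    sgn_counts, sgn_edges = np.histogram(P, bins=2 * bins, range=(-1.0, 1.0))
    return {
        "P": P,
        "abs_edges": abs_edges, "abs_counts": abs_counts,
        "signed_edges": sgn_edges, "signed_counts": sgn_counts,
    }
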