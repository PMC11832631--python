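"""Saupe alignment-tensor algebra and jackknife uncertainty estimators.

The Saupe (alignment) tensor S is a 3x3 symmetric traceless order matrix
that maps a unit internuclear vector b to the predicted residual dipolar
coupling D = b^T S b, expressed here in Hz on the 15N-1H normalized scale.
Tensors are compared through their five-component vector representation

    s = [S_zz, (1/sqrt3)(S_xx - S_yy), (2/sqrt3) S_xy,
         (2/sqrt3) S_xz, (2/sqrt3) S_yz]

whose normalized scalar product P(S_i, S_j) = s_i . s_j / (|s_i| |s_j|) is
a rotation- and scale-invariant similarity of two alignments (1 for
identical orientation and rhombicity).

Conventions
-----------
* principal values are ordered by magnitude, |S_zz| >= |S_yy| >= |S_xx|;
* the alignment magnitude is Da = S_zz / 2 (signed), so a bond collinear
  with the principal z axis predicts D = 2 Da;
* the rhombicity is Rh = (2/3)(S_xx - S_yy)/S_zz, which the magnitude
  ordering confines to [0, 2/3];
* the generalized alignment strength is G = {Da^2 (4 + 3 Rh^2) / 5}^(1/2),
  a rotation-invariant scalar in Hz.

Jackknife spreads over N leave-one-out tensors S_i with mean <S>:

    eps(S) = sqrt(N) * RMS{1 - P(S_i, <S>)}   (orientation/rhombicity)
    eps(G) = sqrt(N) * RMS(G_i - <G>) / <G>   (fractional strength)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "SaupeTensor",
    "AlignmentParams",
    "saupe_to_vec5",
    "vec5_to_saupe",
    "scalar_product_P",
    "tensor_params",
    "mean_tensor",
    "epsilon_S",
    "epsilon_G",
]

_RTOL = 1e-12
_SQRT3 = np.sqrt(3.0)


@dataclass(frozen=True)
class SaupeTensor:
    """Validated 3x3 symmetric traceless order matrix (Hz, NH-normalized)."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError(f"Saupe tensor must be 3x3, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValueError("Saupe tensor has non-finite entries")
        scale = max(np.abs(m).max(), 1.0)
        if np.abs(m - m.T).max() > 1e-9 * scale:
            raise ValueError("Saupe tensor must be symmetric")
        if abs(np.trace(m)) > 1e-9 * scale:
            raise ValueError("Saupe tensor must be traceless")
        # exact symmetrization/trace removal of representation noise
        m = 0.5 * (m + m.T)
        m = m - np.eye(3) * (np.trace(m) / 3.0)
        m.flags.writeable = False
        object.__setattr__(self, "matrix", m)

    @classmethod
    def from_vec5(cls, v) -> "SaupeTensor":
        return vec5_to_saupe(v)

    @classmethod
    def from_params(cls, Da: float, Rh: float, rotation=None) -> "SaupeTensor":
        """Tensor with principal values (2Da, -Da(1 + 3Rh/2), -Da(1 - 3Rh/2));
        ``rotation`` (3x3 or scipy Rotation) carries the principal axis system
        into the molecular frame."""
        if not 0.0 <= Rh <= 2.0 / 3.0:
            raise ValueError(f"rhombicity {Rh} outside [0, 2/3]")
        szz = 2.0 * Da
        syy = -Da * (1.0 + 1.5 * Rh)
        sxx = -Da * (1.0 - 1.5 * Rh)
        m = np.diag([sxx, syy, szz])
        if rotation is not None:
            R = rotation.as_matrix() if isinstance(rotation, Rotation) else np.asarray(rotation)
            m = R @ m @ R.T
        return cls(m)

    def rotated(self, rotation) -> "SaupeTensor":
        R = rotation.as_matrix() if isinstance(rotation, Rotation) else np.asarray(rotation)
        return SaupeTensor(R @ self.matrix @ R.T)

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(saupe_to_vec5(self)))

    def __mul__(self, c: float) -> "SaupeTensor":
        return SaupeTensor(self.matrix * float(c))

    __rmul__ = __mul__


@dataclass(frozen=True)
class AlignmentParams:
    """Derived alignment-tensor parameters.

    Da : signed magnitude in Hz (NH-normalized); Rh : rhombicity in
    [0, 2/3]; G : generalized alignment strength in Hz; euler : z-y-z
    extrinsic Euler angles (degrees) of the principal axis system;
    eigenvalues : principal values ordered (S_xx, S_yy, S_zz) by
    increasing magnitude.
    """

    Da: float
    Rh: float
    G: float
    euler: tuple
    eigenvalues: tuple


def _as_tensor(S) -> SaupeTensor:
    return S if isinstance(S, SaupeTensor) else SaupeTensor(np.asarray(S, dtype=float))


def saupe_to_vec5(S) -> np.ndarray:
    """Five-dimensional Saupe vector [S_zz, (S_xx-S_yy)/sqrt3, 2S_xy/sqrt3,
    2S_xz/sqrt3, 2S_yz/sqrt3]; |s|^2 = (2/3) |S|_F^2."""
    m = _as_tensor(S).matrix
    return np.array([
        m[2, 2],
        (m[0, 0] - m[1, 1]) / _SQRT3,
        2.0 * m[0, 1] / _SQRT3,
        2.0 * m[0, 2] / _SQRT3,
        2.0 * m[1, 2] / _SQRT3,
    ])


def vec5_to_saupe(v) -> SaupeTensor:
    """Inverse of :func:`saupe_to_vec5` (exact round trip)."""
    v = np.asarray(v, dtype=float)
    if v.shape != (5,):
        raise ValueError(f"Saupe vector must have 5 components, got {v.shape}")
    szz = v[0]
    diff = v[1] * _SQRT3            # S_xx - S_yy
    sxx = 0.5 * (diff - szz)        # with S_xx + S_yy = -S_zz
    syy = 0.5 * (-diff - szz)
    sxy = 0.5 * _SQRT3 * v[2]
    sxz = 0.5 * _SQRT3 * v[3]
    syz = 0.5 * _SQRT3 * v[4]
    return SaupeTensor(np.array([[sxx, sxy, sxz],
                                 [sxy, syy, syz],
                                 [sxz, syz, szz]]))


def scalar_product_P(Si, Sj) -> float:
    """Normalized scalar product P(S_i, S_j) in [-1, 1]."""
    vi = saupe_to_vec5(Si)
    vj = saupe_to_vec5(Sj)
    ni = np.linalg.norm(vi)
    nj = np.linalg.norm(vj)
    if ni == 0.0 or nj == 0.0:
        raise ValueError("normalized scalar product undefined for a zero tensor")
    return float(np.clip(vi @ vj / (ni * nj), -1.0, 1.0))


def tensor_params(S) -> AlignmentParams:
    """Eigen-parameters of a Saupe tensor under the magnitude-ordering
    convention (see module docstring)."""
    m = _as_tensor(S).matrix
    vals, vecs = np.linalg.eigh(m)
    order = np.argsort(np.abs(vals))            # (x, y, z) by |eigenvalue|
    vals = vals[order]
    vecs = vecs[:, order]
    sxx, syy, szz = vals
    if szz == 0.0:
        raise ValueError("degenerate tensor: largest principal value is zero")
    Da = szz / 2.0
    Rh = (2.0 / 3.0) * (sxx - syy) / szz
    G = float(np.sqrt(Da * Da * (4.0 + 3.0 * Rh * Rh) / 5.0))
    if np.linalg.det(vecs) < 0:
        vecs = vecs.copy()
        vecs[:, 0] = -vecs[:, 0]
    import warnings
    with warnings.catch_warnings():
        # axially symmetric tensors gimbal-lock the zyz angles; any valid
        # representative is fine for reporting
        warnings.simplefilter("ignore", UserWarning)
        euler = tuple(Rotation.from_matrix(vecs).as_euler("zyz", degrees=True))
    return AlignmentParams(Da=float(Da), Rh=float(Rh), G=G,
                           euler=euler, eigenvalues=(float(sxx), float(syy), float(szz)))


def mean_tensor(tensors) -> SaupeTensor:
    """Element-wise average <S> of Saupe tensors (equivalently of their
    five-dimensional vectors)."""
    ms = [_as_tensor(t).matrix for t in tensors]
    if not ms:
        raise ValueError("cannot average an empty tensor list")
    return SaupeTensor(np.mean(ms, axis=0))


def epsilon_S(tensors, mean=None) -> float:
    """Jackknife orientation/rhombicity spread eps(S) = sqrt(N) *
    RMS{1 - P(S_i, <S>)} over N >= 2 leave-one-out tensors."""
    tensors = list(tensors)
    if len(tensors) < 2:
        raise ValueError("eps(S) needs at least 2 jackknife tensors")
    mS = mean_tensor(tensors) if mean is None else _as_tensor(mean)
    dev = np.array([1.0 - scalar_product_P(t, mS) for t in tensors])
    # sqrt(N) * sqrt(sum(dev^2)/N) = sqrt(sum(dev^2))
    return float(np.sqrt(np.sum(dev ** 2)))


def epsilon_G(G_values, mean_G=None) -> float:
    """Jackknife fractional alignment-strength spread eps(G) = sqrt(N) *
    RMS(G_i - <G>) / <G>."""
    g = np.asarray(list(G_values), dtype=float)
    if g.size < 2:
        raise ValueError("eps(G) needs at least 2 jackknife values")
    mg = float(np.mean(g)) if mean_G is None else float(mean_G)
    if mg == 0.0:
        raise ValueError("eps(G) undefined for <G> = 0")
    return float(np.sqrt(np.sum((g - mg) ** 2)) / abs(mg))
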