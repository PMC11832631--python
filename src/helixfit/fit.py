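"""RDC records, NH-scale normalization, SVD tensor fitting and jackknifing.

The measured couplings are first normalized to the interaction strength of
the backbone 15N-1H amide pair by the ratio of dipolar constants
(gamma_a gamma_b / r_ab^3), after which all coupling types are fitted on a
common scale with equal unit weights (per-record errors, when supplied,
are used as inverse-variance weights instead).

The Saupe tensor is obtained as the least-squares solution of the linear
system D_k = b_k^T S b_k over its five free components, solved by singular
value decomposition of the N x 5 design matrix with rows

    [bz^2 - bx^2,  by^2 - bx^2,  2 bx by,  2 bx bz,  2 by bz]

for the unknowns (S_zz, S_yy, S_xy, S_xz, S_yz); S_xx follows from the
trace.  Uncertainties come from jackknifing: N leave-one-out fits give a
set of tensors {S_i} and strengths {G_i}, from which eps(S), eps(G), <G>
and the jackknifed quality factor Q_jk are computed.  Q_jk evaluates each
omitted coupling against the fit that excluded it and therefore does not
share the small-N optimism of the standard Q factor.

Quality-factor normalization: the reported Q and Q_jk use the "powder"
denominator sqrt{2 Da^2 (4 + 3 Rh^2) / 5} so that Q_jk converges to Q for
large N; the variant without the factor 2 is also computed (``Q_jk_norm1``).

The core fit is exposed as a scikit-learn style estimator,
:class:`SaupeTensorFit` (and its jackknifing subclass
:class:`JackknifeSaupeFit`): ``fit(X, y)`` takes an (N, 3) array of unit
internuclear vectors and N normalized couplings, ``predict(X)`` returns
b^T S b, and fitted attributes carry a trailing underscore.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .tensor import (AlignmentParams, SaupeTensor, epsilon_G, epsilon_S,
                     mean_tensor, tensor_params)

__all__ = [
    "RDCRecord",
    "RDCSet",
    "FitResult",
    "COUPLING_TYPES",
    "GAMMA",
    "DEFAULT_DISTANCES",
    "infer_coupling_type",
    "normalization_factor",
    "SaupeTensorFit",
    "JackknifeSaupeFit",
    "svd_fit",
    "jackknife_rdc",
    "jackknife_residue",
    "predict_rdcs",
    "amide_plane_atoms",
]

# magnetogyric ratios, 1e7 rad s^-1 T^-1
GAMMA = {"H": 26.752, "C": 6.728, "N": -2.713}

# coupling type -> (nucleus_i, nucleus_j, effective internuclear distance / A)
# two-bond distances are fixed effective values, not recomputed per structure
DEFAULT_DISTANCES = {
    "NH": ("N", "H", 1.02),
    "CAHA": ("C", "H", 1.09),
    "CN": ("C", "N", 1.329),
    "CAC": ("C", "C", 1.525),
    "CHN": ("C", "H", 2.05),
    "CHA": ("C", "H", 2.13),
}

COUPLING_TYPES = tuple(DEFAULT_DISTANCES)

# (atom_i, atom_j, residue_j - residue_i) -> coupling type
_PAIR_TO_TYPE = {
    ("N", "H", 0): "NH",
    ("CA", "HA", 0): "CAHA",
    ("C", "N", 1): "CN",
    ("CA", "C", 0): "CAC",
    ("C", "H", 1): "CHN",
    ("C", "HA", 0): "CHA",
}


def infer_coupling_type(atom_i: str, atom_j: str, residue_i: int, residue_j: int) -> str:
    """Coupling type from the atom pair and residue offset (either atom order)."""
    key = (atom_i.upper(), atom_j.upper(), residue_j - residue_i)
    if key in _PAIR_TO_TYPE:
        return _PAIR_TO_TYPE[key]
    rkey = (atom_j.upper(), atom_i.upper(), residue_i - residue_j)
    if rkey in _PAIR_TO_TYPE:
        return _PAIR_TO_TYPE[rkey]
    raise ValueError(
        f"unknown coupling: {atom_i}({residue_i})-{atom_j}({residue_j})")


def normalization_factor(coupling_type: str, distances=None) -> float:
    """Scale factor bringing a raw coupling of the given type onto the NH
    scale: ratio of the NH dipolar constant to the pair's,
    |gamma_N gamma_H| / r_NH^3  over  |gamma_a gamma_b| / r_ab^3.
    """
    table = DEFAULT_DISTANCES if distances is None else distances
    if coupling_type not in table:
        raise ValueError(f"unknown coupling type {coupling_type!r}")
    na, nb, r = table[coupling_type]
    nn, nh, rnh = table["NH"]
    const_nh = abs(GAMMA[nn] * GAMMA[nh]) / rnh ** 3
    const_ab = abs(GAMMA[na] * GAMMA[nb]) / r ** 3
    return const_nh / const_ab


@dataclass(frozen=True)
class RDCRecord:
    """One measured residual dipolar coupling (raw Hz, author numbering)."""

    residue_i: int
    atom_i: str
    residue_j: int
    atom_j: str
    D: float
    error: float | None = None
    chain: str = "A"

    def __post_init__(self):
        if not np.isfinite(self.D):
            raise ValueError(f"non-finite coupling for {self}")
        # validates the atom pair / offset combination
        self.coupling_type

    @property
    def coupling_type(self) -> str:
        return infer_coupling_type(self.atom_i, self.atom_j,
                                   self.residue_i, self.residue_j)

    def __str__(self):
        return (f"{self.coupling_type}({self.chain}:{self.residue_i}"
                f"{self.atom_i}-{self.residue_j}{self.atom_j})")


class RDCSet:
    """A list of RDC records plus the per-type normalization to the NH scale.

    Duplicate (chain, residue_i, coupling_type) entries are rejected.
    """

    def __init__(self, records, distances=None):
        self.records = list(records)
        self.distances = dict(DEFAULT_DISTANCES if distances is None else distances)
        seen = {}
        for k, rec in enumerate(self.records):
            key = (rec.chain, rec.residue_i, rec.coupling_type)
            if key in seen:
                raise ValueError(
                    f"duplicate RDC for {rec} (records {seen[key]} and {k})")
            seen[key] = k

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def factor(self, coupling_type: str) -> float:
        return normalization_factor(coupling_type, self.distances)

    def normalized(self) -> np.ndarray:
        """Couplings on the NH scale (Hz)."""
        return np.array([r.D * self.factor(r.coupling_type) for r in self.records])

    def normalized_errors(self) -> np.ndarray | None:
        """NH-scale errors, or None when no record carries one."""
        if all(r.error is None for r in self.records):
            return None
        errs = []
        for r in self.records:
            if r.error is None or r.error <= 0:
                raise ValueError(f"missing/invalid error on {r} in a weighted set")
            errs.append(r.error * self.factor(r.coupling_type))
        return np.array(errs)

    def subset(self, keep) -> "RDCSet":
        """New set with records selected by a boolean mask or index list."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            recs = [r for r, k in zip(self.records, keep) if k]
        else:
            recs = [self.records[int(i)] for i in keep]
        return RDCSet(recs, self.distances)

    def for_residues(self, residues) -> "RDCSet":
        """Records whose both atoms lie within the given residue-number set."""
        residues = set(residues)
        return self.subset([r.residue_i in residues and r.residue_j in residues
                            for r in self.records])


def _design_matrix(vectors: np.ndarray) -> np.ndarray:
    b = np.asarray(vectors, dtype=float)
    bx, by, bz = b[:, 0], b[:, 1], b[:, 2]
    return np.column_stack([bz ** 2 - bx ** 2, by ** 2 - bx ** 2,
                            2 * bx * by, 2 * bx * bz, 2 * by * bz])


def _x_to_tensor(x: np.ndarray) -> SaupeTensor:
    szz, syy, sxy, sxz, syz = x
    sxx = -szz - syy
    return SaupeTensor(np.array([[sxx, sxy, sxz],
                                 [sxy, syy, syz],
                                 [sxz, syz, szz]]))


class SaupeTensorFit(BaseEstimator, RegressorMixin):
    """Least-squares Saupe tensor from unit bond vectors and normalized RDCs.

    Parameters
    ----------
    rcond : float
        Singular-value cutoff (relative to the largest) below which the
        design matrix is treated as rank deficient; the minimum-norm
        solution is then returned and ``rank_`` reports the effective rank.

    Attributes (after ``fit``)
    --------------------------
    tensor_ : SaupeTensor            fitted order matrix
    params_ : AlignmentParams        Da, Rh, G, Euler angles, eigenvalues
    Q_ : float                       quality factor rms(res)/powder-norm
    rank_, condition_, singular_values_ : design-matrix diagnostics
    """

    def __init__(self, rcond: float = 1e-8):
        self.rcond = rcond

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError(f"X must be (N, 3) unit vectors, got {X.shape}")
        if y.shape != (X.shape[0],):
            raise ValueError("y length must match X")
        n = X.shape[0]
        if n < 5:
            raise ValueError(f"SVD tensor fit needs >= 5 RDCs, got {n}")
        A = _design_matrix(X)
        d = y.copy()
        if sample_weight is not None:
            w = np.sqrt(np.asarray(sample_weight, dtype=float))
            A = A * w[:, None]
            d = d * w
        x, _, rank, sing = np.linalg.lstsq(A, d, rcond=self.rcond)
        self.rank_ = int(rank)
        self.singular_values_ = sing
        self.condition_ = float(sing[0] / sing[-1]) if sing[-1] > 0 else np.inf
        if rank < 5:
            import warnings
            warnings.warn(
                f"rank-deficient RDC design matrix (rank {rank} < 5, "
                f"condition {self.condition_:.3g}); minimum-norm solution returned")
        self.tensor_ = _x_to_tensor(x)
        self.params_ = tensor_params(self.tensor_)
        resid = self.predict(X) - y
        self.residuals_ = resid
        self.Q_ = float(np.sqrt(np.mean(resid ** 2)) / _powder_norm(self.params_))
        return self

    def predict(self, X):
        check_is_fitted(self, "tensor_")
        X = np.asarray(X, dtype=float)
        return np.einsum("ki,ij,kj->k", X, self.tensor_.matrix, X)


def _powder_norm(params: AlignmentParams) -> float:
    """sqrt{2 Da^2 (4 + 3 Rh^2) / 5}: rms of b^T S b over isotropically
    distributed b (the standard Q-factor denominator)."""
    return float(np.sqrt(2.0 * params.Da ** 2 * (4.0 + 3.0 * params.Rh ** 2) / 5.0))


class JackknifeSaupeFit(SaupeTensorFit):
    """Saupe tensor fit with leave-one-out jackknife statistics.

    In addition to the :class:`SaupeTensorFit` attributes, ``fit`` sets:

    Q_jk_ : float        jackknifed quality factor (powder normalization)
    Q_jk_norm1_ : float  same without the factor 2 in the denominator
    eps_S_, eps_G_ : jackknife spreads of orientation/rhombicity and strength
    mean_G_ : float      average of the N leave-one-out G values (Hz)
    mean_tensor_ : SaupeTensor   element-wise average of leave-one-out tensors
    jack_tensors_ : list[SaupeTensor]
    jack_G_ : ndarray
    loo_predictions_ : ndarray   prediction for each omitted coupling
    """

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n = X.shape[0]
        if n < 6:
            raise ValueError(
                f"jackknifing needs >= 6 RDCs (5 fit parameters), got {n}")
        super().fit(X, y, sample_weight=sample_weight)
        tensors, gs, loo_pred, denom = [], [], np.empty(n), np.empty(n)
        base = SaupeTensorFit(rcond=self.rcond)
        for i in range(n):
            keep = np.arange(n) != i
            wi = None if sample_weight is None else np.asarray(sample_weight)[keep]
            base.fit(X[keep], y[keep], sample_weight=wi)
            tensors.append(base.tensor_)
            gs.append(base.params_.G)
            loo_pred[i] = base.predict(X[i:i + 1])[0]
            denom[i] = base.params_.Da ** 2 * (4.0 + 3.0 * base.params_.Rh ** 2) / 5.0
        self.jack_tensors_ = tensors
        self.jack_G_ = np.asarray(gs)
        self.loo_predictions_ = loo_pred
        sq = (loo_pred - y) ** 2
        self.Q_jk_norm1_ = float(np.sqrt(np.mean(sq / denom)))
        self.Q_jk_ = float(np.sqrt(np.mean(sq / (2.0 * denom))))
        self.mean_tensor_ = mean_tensor(tensors)
        self.mean_G_ = float(np.mean(self.jack_G_))
        self.eps_S_ = epsilon_S(tensors, self.mean_tensor_)
        self.eps_G_ = epsilon_G(self.jack_G_, self.mean_G_)
        return self


@dataclass
class FitResult:
    """Per-helix SVD fit with jackknife statistics."""

    tensor: SaupeTensor
    params: AlignmentParams
    Q: float
    n_rdc: int
    D_meas: np.ndarray
    D_pred: np.ndarray
    rank: int
    condition: float
    Q_jk: float | None = None
    Q_jk_norm1: float | None = None
    eps_S: float | None = None
    eps_G: float | None = None
    mean_G: float | None = None
    jack_tensors: list = field(default_factory=list)
    jack_G: np.ndarray | None = None
    records: list = field(default_factory=list)

    @classmethod
    def from_estimator(cls, est: SaupeTensorFit, y, records=None) -> "FitResult":
        res = cls(tensor=est.tensor_, params=est.params_, Q=est.Q_,
                  n_rdc=len(y), D_meas=np.asarray(y),
                  D_pred=np.asarray(y) + est.residuals_,
                  rank=est.rank_, condition=est.condition_,
                  records=list(records) if records is not None else [])
        if isinstance(est, JackknifeSaupeFit):
            res.Q_jk = est.Q_jk_
            res.Q_jk_norm1 = est.Q_jk_norm1_
            res.eps_S = est.eps_S_
            res.eps_G = est.eps_G_
            res.mean_G = est.mean_G_
            res.jack_tensors = est.jack_tensors_
            res.jack_G = est.jack_G_
        return res


def _weights_from(rdcs: RDCSet):
    errs = rdcs.normalized_errors()
    if errs is None:
        return None
    return 1.0 / errs ** 2


def svd_fit(rdcs: RDCSet, vectors, weights=None) -> FitResult:
    """SVD fit of an RDC set against its unit bond vectors (no jackknife).

    ``vectors`` is an (N, 3) array aligned with the records; per-record
    errors, when present, supply inverse-variance weights unless explicit
    ``weights`` are given.
    """
    y = rdcs.normalized()
    w = _weights_from(rdcs) if weights is None else np.asarray(weights, dtype=float)
    est = SaupeTensorFit().fit(np.asarray(vectors, dtype=float), y, sample_weight=w)
    return FitResult.from_estimator(est, y, rdcs.records)


def jackknife_rdc(rdcs: RDCSet, vectors, weights=None) -> FitResult:
    """Full per-RDC jackknife fit: tensor, Q, Q_jk, eps(S), eps(G), <G>."""
    y = rdcs.normalized()
    w = _weights_from(rdcs) if weights is None else np.asarray(weights, dtype=float)
    est = JackknifeSaupeFit().fit(np.asarray(vectors, dtype=float), y, sample_weight=w)
    return FitResult.from_estimator(est, y, rdcs.records)


def amide_plane_atoms(residue: int, side: str = "N") -> set:
    """Atoms of the peptide plane flanking ``residue``.

    side='N': the N-terminal amide plane of the residue, i.e. C', O of the
    preceding residue plus N, H, CA of the residue itself.  side='C': its
    C-terminal plane (own C', O plus N, H, CA of the next residue).
    """
    if side == "N":
        return {(residue - 1, "C"), (residue - 1, "O"),
                (residue, "N"), (residue, "H"), (residue, "CA")}
    if side == "C":
        return {(residue, "C"), (residue, "O"),
                (residue + 1, "N"), (residue + 1, "H"), (residue + 1, "CA")}
    raise ValueError(f"side must be 'N' or 'C', got {side!r}")


def plane_mask(rdcs: RDCSet, residue: int, side: str = "N") -> np.ndarray:
    """True for records with any atom in the given amide plane."""
    plane = amide_plane_atoms(residue, side)
    return np.array([
        (r.residue_i, r.atom_i) in plane or (r.residue_j, r.atom_j) in plane
        for r in rdcs])


def jackknife_residue(rdcs: RDCSet, vectors, residue: int,
                      side: str = "N") -> FitResult:
    """Jackknife fit after removing every RDC touching ``residue``'s amide
    plane (residue-level jackknife / terminal culling primitive)."""
    drop = plane_mask(rdcs, residue, side)
    keep = ~drop
    if keep.sum() < 6:
        raise ValueError(
            f"removing residue {residue} ({side}-side plane) leaves "
            f"{int(keep.sum())} RDCs; jackknifing needs >= 6")
    return jackknife_rdc(rdcs.subset(keep), np.asarray(vectors)[keep])


def predict_rdcs(tensor, vectors) -> np.ndarray:
    """Normalized couplings b^T S b for each unit vector."""
    m = tensor.matrix if isinstance(tensor, SaupeTensor) else np.asarray(tensor)
    b = np.asarray(vectors, dtype=float)
    return np.einsum("ki,ij,kj->k", b, m, b)
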