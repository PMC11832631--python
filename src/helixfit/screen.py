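"""Helix screening and the per-helix fitting workflow.

Segments called helical upstream (e.g. from chemical-shift-based secondary
structure) are screened — split at prolines, dropped when shorter than the
minimum length or carrying too few couplings — then each surviving helix is
fitted by SVD with jackknifing, either against the experimental coordinates
or against an idealized helix superimposed on the segment's heavy backbone
atoms (N, CA, C').  Optionally the terminal amide planes are tested by
residue-level jackknifing and culled when their removal improves Q_jk by
more than a configurable relative threshold.  Cross-helix agreement is
summarized by the matrix of normalized scalar products P(S_i, S_j) and by
each helix's P against the tensor from a pooled fit of all couplings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fit import FitResult, RDCSet, jackknife_rdc, plane_mask
from .geometry import (BACKBONE_HEAVY, HelixSegment, IdealHelixParams,
                       DEFAULT_IDEAL_PARAMS, Structure, bond_vector,
                       build_ideal_helix, place_amide_protons, superpose)
from .tensor import SaupeTensor, scalar_product_P, tensor_params

__all__ = [
    "ScreenConfig",
    "HelixReport",
    "screen_segments",
    "select_segment_rdcs",
    "helix_vectors",
    "cull_terminal",
    "fit_helix",
    "pooled_fit",
    "cross_helix_matrix",
    "reorient_domain",
]


@dataclass(frozen=True)
class ScreenConfig:
    """Screening and fitting options."""

    min_helix_length: int = 5
    min_rdc_count: int = 8
    cull_terminal: bool = True
    cull_improvement_threshold: float = 0.20
    coordinate_mode: str = "both"       # ideal | xray | both
    ideal_params: IdealHelixParams = DEFAULT_IDEAL_PARAMS

    def __post_init__(self):
        if self.min_helix_length < 5:
            raise ValueError("min_helix_length must be >= 5")
        if self.min_rdc_count < 6:
            raise ValueError("min_rdc_count must be >= 6 (jackknife needs 6)")
        if self.coordinate_mode not in ("ideal", "xray", "both"):
            raise ValueError(f"bad coordinate_mode {self.coordinate_mode!r}")


@dataclass
class HelixReport:
    """Outcome of fitting one screened helix."""

    segment: HelixSegment
    culled: list = field(default_factory=list)
    fit_ideal: FitResult | None = None
    fit_xray: FitResult | None = None
    flags: list = field(default_factory=list)
    cull_log: list = field(default_factory=list)
    # records/vectors actually fitted (after culling), per mode
    records: RDCSet | None = None
    vectors_ideal: np.ndarray | None = None
    vectors_xray: np.ndarray | None = None

    @property
    def ok(self) -> bool:
        return self.fit_ideal is not None or self.fit_xray is not None

    def primary_fit(self) -> FitResult:
        fit = self.fit_ideal if self.fit_ideal is not None else self.fit_xray
        if fit is None:
            raise ValueError(f"no successful fit for {self.segment}")
        return fit


def screen_segments(segments, sequence: dict, rdcs: RDCSet,
                    cfg: ScreenConfig = ScreenConfig()):
    """Split segments at prolines and drop short / data-poor fragments.

    ``sequence`` maps author residue number -> 3-letter residue name.
    Returns (accepted segments, skip log); the skip log lists
    (segment, reason) for every dropped fragment.  Idempotent on its own
    output.
    """
    accepted, skipped = [], []
    for seg in segments:
        for r in range(seg.first, seg.last + 1):
            if r not in sequence:
                raise ValueError(f"{seg} extends outside the sequence "
                                 f"(residue {r} unknown)")
        # split into maximal proline-free runs: a helix ends at the residue
        # preceding a Pro and restarts at the residue following it
        runs, start = [], None
        for r in range(seg.first, seg.last + 1):
            if sequence[r].upper() == "PRO":
                if start is not None:
                    runs.append((start, r - 1))
                start = None
            elif start is None:
                start = r
        if start is not None:
            runs.append((start, seg.last))
        multi = len(runs) > 1
        for j, (a, b) in enumerate(runs):
            label = seg.label + (f".{j + 1}" if multi and seg.label else "")
            frag = HelixSegment(seg.chain, a, b, label or f"{a}-{b}")
            if len(frag) < cfg.min_helix_length:
                skipped.append((frag, f"length {len(frag)} < "
                                f"{cfg.min_helix_length}"))
                continue
            n = len(select_segment_rdcs(frag, rdcs))
            if n < cfg.min_rdc_count:
                skipped.append((frag, f"insufficient RDCs ({n} < "
                                f"{cfg.min_rdc_count})"))
                continue
            accepted.append(frag)
    return accepted, skipped


def select_segment_rdcs(seg: HelixSegment, rdcs: RDCSet) -> RDCSet:
    """Records attributable to a segment: both atoms inside [first, last],
    plus the sequential couplings reaching back to the carbonyl of
    first-1 (they report on the segment's N-terminal amide plane)."""
    def keep(r):
        if r.chain != seg.chain:
            return False
        lo, hi = seg.first, seg.last
        inside = lo <= r.residue_i <= hi and lo <= r.residue_j <= hi
        nterm = (r.residue_i == lo - 1 and r.atom_i == "C"
                 and lo <= r.residue_j <= hi)
        return inside or nterm
    return rdcs.subset([keep(r) for r in rdcs])


def _ideal_reference(seg: HelixSegment, structure: Structure,
                     params: IdealHelixParams) -> Structure:
    """Idealized helix superimposed on the segment's N, CA, C' atoms.

    Built with one extra N-terminal residue so the first residue's amide
    plane (H, preceding C'/O) exists in the model; the superposition uses
    only the segment residues proper.
    """
    ideal = build_ideal_helix(len(seg) + 1, params=params,
                              first_seqid=seg.first - 1, chain=seg.chain)
    sel = [(r, a) for r in range(seg.first, seg.last + 1)
           for a in BACKBONE_HEAVY if structure.has_atom(r, a)]
    missing = 3 * len(seg) - len(sel)
    if missing:
        sel = [(r, a) for r, a in sel if ideal.has_atom(r, a)]
    sup = superpose(ideal, structure, atoms=sel)
    return sup.transformed


def helix_vectors(seg: HelixSegment, rdcs: RDCSet, structure: Structure,
                  mode: str, params: IdealHelixParams = DEFAULT_IDEAL_PARAMS):
    """Unit bond vectors for a segment's records in the given coordinate mode.

    Returns (RDCSet of resolvable records, (N, 3) vectors, skip log).
    ``mode='xray'`` uses the experimental coordinates (amide protons placed
    where absent); ``mode='ideal'`` uses an idealized helix best-fit
    superimposed on the segment backbone.
    """
    if mode == "ideal":
        ref = _ideal_reference(seg, structure, params)
    elif mode == "xray":
        ref = place_amide_protons(structure, nh_length=params.n_h)
    else:
        raise ValueError(f"mode must be 'ideal' or 'xray', got {mode!r}")
    vecs, keep, skip_log = [], [], []
    for rec in rdcs:
        try:
            vecs.append(bond_vector(ref, rec))
            keep.append(True)
        except KeyError as exc:
            keep.append(False)
            skip_log.append((rec, str(exc)))
    return rdcs.subset(keep), np.asarray(vecs, dtype=float), skip_log


def cull_terminal(seg: HelixSegment, rdcs: RDCSet, vectors,
                  cfg: ScreenConfig = ScreenConfig()):
    """Decide, per terminus, whether dropping its amide-plane RDCs improves
    the jackknifed fit enough to cull the terminal residue.

    Each terminus is tested independently against the uncalled baseline:
    the terminal residue is culled iff the relative drop in Q_jk meets
    ``cfg.cull_improvement_threshold``.  At most one residue per terminus.
    Returns (kept RDCSet, kept vectors, culled residue list, decision log).
    """
    vectors = np.asarray(vectors, dtype=float)
    base = jackknife_rdc(rdcs, vectors)
    culled, log = [], []
    drop = np.zeros(len(rdcs), dtype=bool)
    for residue, side in ((seg.first, "N"), (seg.last, "C")):
        mask = plane_mask(rdcs, residue, side)
        if not mask.any():
            log.append((residue, side, None, "no amide-plane RDCs"))
            continue
        if (~mask).sum() < 6:
            log.append((residue, side, None,
                        "culling would leave < 6 RDCs; skipped"))
            continue
        trial = jackknife_rdc(rdcs.subset(~mask), vectors[~mask])
        if base.Q_jk > 1e-8:
            gain = (base.Q_jk - trial.Q_jk) / base.Q_jk
        else:
            gain = 0.0      # an (essentially) perfect fit cannot improve
        decision = gain >= cfg.cull_improvement_threshold
        log.append((residue, side, gain,
                    f"Q_jk {base.Q_jk:.3f} -> {trial.Q_jk:.3f}"
                    f"{' culled' if decision else ''}"))
        if decision:
            culled.append(residue)
            drop |= mask
    if drop.any() and (~drop).sum() < 6:
        # combined culling starved the fit; keep the baseline
        return rdcs, vectors, [], log + [(None, None, None,
                                          "combined culling left < 6 RDCs; "
                                          "reverted")]
    return rdcs.subset(~drop), vectors[~drop], culled, log


def fit_helix(seg: HelixSegment, rdcs: RDCSet, structure: Structure,
              cfg: ScreenConfig = ScreenConfig()) -> HelixReport:
    """Fit one screened helix in the configured coordinate mode(s).

    Culling decisions (when enabled) are made on the ideal-coordinate fit
    when available, otherwise on the experimental one, and the same culled
    record set is then fitted in every requested mode.
    """
    report = HelixReport(segment=seg)
    seg_rdcs = select_segment_rdcs(seg, rdcs)
    if len(seg_rdcs) < 6:
        report.flags.append(f"skipped: {len(seg_rdcs)} RDCs < 6")
        return report
    modes = {"ideal": ("ideal",), "xray": ("xray",),
             "both": ("ideal", "xray")}[cfg.coordinate_mode]
    resolved = {}
    for mode in modes:
        sub, vecs, skips = helix_vectors(seg, seg_rdcs, structure, mode,
                                         cfg.ideal_params)
        for rec, msg in skips:
            report.flags.append(f"{mode}: skipped {rec}: {msg}")
        if len(sub) >= 6:
            resolved[mode] = (sub, vecs)
        else:
            report.flags.append(f"{mode}: only {len(sub)} resolvable RDCs")
    if not resolved:
        return report
    lead = "ideal" if "ideal" in resolved else "xray"
    sub, vecs = resolved[lead]
    if cfg.cull_terminal:
        sub, vecs, culled, log = cull_terminal(seg, sub, vecs, cfg)
        report.culled = culled
        report.cull_log = log
        if culled:
            keep_keys = {(r.chain, r.residue_i, r.coupling_type) for r in sub}
            for mode in list(resolved):
                s2, v2 = resolved[mode]
                mask = np.array([(r.chain, r.residue_i, r.coupling_type)
                                 in keep_keys for r in s2])
                resolved[mode] = (s2.subset(mask), v2[mask])
    for mode, (s2, v2) in resolved.items():
        try:
            fr = jackknife_rdc(s2, v2)
        except ValueError as exc:
            report.flags.append(f"{mode}: fit failed: {exc}")
            continue
        if fr.rank < 5:
            report.flags.append(f"{mode}: rank-deficient design matrix")
        if mode == "ideal":
            report.fit_ideal = fr
            report.vectors_ideal = v2
        else:
            report.fit_xray = fr
            report.vectors_xray = v2
        report.records = s2
    return report


def pooled_fit(reports, mode: str = "ideal") -> FitResult:
    """Single-tensor SVD fit pooling the normalized RDCs of all helices
    (the global alignment tensor)."""
    recs, vecs = [], []
    for rep in reports:
        fr = rep.fit_ideal if mode == "ideal" else rep.fit_xray
        v = rep.vectors_ideal if mode == "ideal" else rep.vectors_xray
        if fr is None or v is None:
            continue
        recs.extend(rep.records.records)
        vecs.append(v)
    if not vecs:
        raise ValueError("no successful helix fits to pool")
    pooled = RDCSet(recs)
    return jackknife_rdc(pooled, np.vstack(vecs))


def cross_helix_matrix(reports, mode: str = "ideal", global_fit=None):
    """Pairwise P(S_i, S_j) among helix tensors plus each helix vs the
    pooled (global) tensor.

    Returns (labels, symmetric matrix with unit diagonal, P-vs-global
    array, global FitResult).  Helices without a successful fit in the
    requested mode are excluded (logged in the labels they lack).
    """
    fits, labels = [], []
    for rep in reports:
        fr = rep.fit_ideal if mode == "ideal" else rep.fit_xray
        if fr is not None:
            fits.append(fr)
            labels.append(rep.segment.label or str(rep.segment))
    if len(fits) < 2:
        raise ValueError("cross-helix matrix needs >= 2 successful fits")
    if global_fit is None:
        global_fit = pooled_fit(reports, mode=mode)
    m = len(fits)
    P = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            P[i, j] = P[j, i] = scalar_product_P(fits[i].tensor, fits[j].tensor)
    Pg = np.array([scalar_product_P(f.tensor, global_fit.tensor) for f in fits])
    return labels, P, Pg, global_fit


def reorient_domain(structure: Structure, residues, reference: SaupeTensor,
                    target: SaupeTensor, min_rhombicity: float = 0.02) -> Structure:
    """Rotate the selected residues so the target tensor's principal axis
    system coincides with the reference's.

    Axis correspondence is by eigenvalue magnitude rank; the fourfold
    proper-rotation sign ambiguity of the principal axes is resolved by the
    trial rotation of smallest angle (all four leave the rotated tensor,
    hence P against the reference, identical).  The rotation is applied
    about the centroid of the selected residues.  Near-axially-symmetric
    tensors (Rh below ``min_rhombicity``) are rejected: their transverse
    axes are not defined.
    """
    residues = set(residues)
    pr = tensor_params(reference)
    pt = tensor_params(target)
    for name, p in (("reference", pr), ("target", pt)):
        if p.Rh < min_rhombicity:
            raise ValueError(f"{name} tensor is (near-)axially symmetric "
                             f"(Rh = {p.Rh:.3f}); orientation under-determined")

    def frame(S):
        vals, vecs = np.linalg.eigh(S.matrix)
        order = np.argsort(np.abs(vals))
        v = vecs[:, order]
        if np.linalg.det(v) < 0:
            v[:, 0] = -v[:, 0]
        return v
    Vr, Vt = frame(reference), frame(target)
    trials = []
    for sx, sy in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        D = np.diag([sx, sy, sx * sy])
        R = Vr @ D @ Vt.T
        ang = np.degrees(np.arccos(np.clip((np.trace(R) - 1) / 2, -1, 1)))
        p = scalar_product_P(target.rotated(R), reference)
        trials.append((p, ang, R))
    # the four proper sign combinations give identical P up to round-off;
    # among the (near-)maximal ones take the smallest rotation
    pmax = max(p for p, _, _ in trials)
    R = min((t for t in trials if t[0] >= pmax - 1e-9), key=lambda t: t[1])[2]
    sel = [r for r in structure if r.seqid in residues]
    if not sel:
        raise ValueError("no residues selected for reorientation")
    centroid = np.mean([xyz for r in sel for xyz in r.atoms.values()], axis=0)
    out = structure.copy()
    for res in out:
        if res.seqid in residues:
            for name in res.atoms:
                res.atoms[name] = R @ (res.atoms[name] - centroid) + centroid
    return out
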