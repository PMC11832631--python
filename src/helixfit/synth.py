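"""Synthetic structures and RDC sets with known ground truth.

Emulates the experimental setting end to end: idealized helices (optionally
bundled into rigid units with distinct alignment tensors, the flexibly
linked two-domain scenario), raw per-type couplings obtained by
de-normalizing b^T S b from the NH scale, and Gaussian measurement noise
whose per-type sigma scales with the inverse of the dipolar interaction
constant — so that on the normalized scale every coupling type carries the
same error, matching the equal-weight fitting convention.

All randomness flows through a single integer seed; a fixed seed gives
bit-reproducible output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .fit import COUPLING_TYPES, RDCRecord, RDCSet, normalization_factor
from .geometry import (COUPLING_ATOMS, HelixSegment, Residue, Structure,
                       build_ideal_helix)
from .tensor import SaupeTensor

__all__ = [
    "SynthSpec",
    "generate_rdcs",
    "jitter_structure",
    "make_two_domain_fixture",
    "TwoDomainFixture",
]

DEFAULT_TYPES = ("NH", "CAHA", "CN", "CAC", "CHN")


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for the two-domain synthetic fixture.

    Each rigid unit (domain) has its own alignment tensor given as
    (Da / Hz, Rh, zyz Euler angles / deg); ``helices`` lists
    (length, unit_index) pairs.  ``noise_sigma`` is the NH-scale Gaussian
    noise in Hz; ``outlier_residues`` maps a residue number to a rotation
    angle (deg) applied to its amide-plane bond vectors before couplings
    are generated, emulating a locally non-helical terminus.
    """

    tensors: tuple = ((10.0, 0.3, (0.0, 0.0, 0.0)),
                      (10.0, 0.3, (0.0, 60.0, 0.0)))
    helices: tuple = ((12, 0), (10, 0), (12, 1), (10, 1))
    coupling_types: tuple = DEFAULT_TYPES
    noise_sigma: float = 0.0
    seed: int = 0
    coord_jitter: float = 0.0
    outlier_residues: dict = field(default_factory=dict)


def _plane_residues(record) -> set:
    """Residues whose N-terminal amide plane contains either atom of the
    record (used to decide which records an outlier rotation touches)."""
    out = set()
    for res, atom in ((record.residue_i, record.atom_i),
                      (record.residue_j, record.atom_j)):
        if atom in ("N", "H", "CA"):
            out.add(res)
        if atom in ("C", "O"):
            out.add(res + 1)
    return out


def generate_rdcs(structure: Structure, tensor: SaupeTensor,
                  coupling_types=DEFAULT_TYPES, noise_sigma: float = 0.0,
                  seed: int = 0, residues=None, chain: str = "A",
                  outlier_residues=None, with_errors: bool = False) -> RDCSet:
    """Generate raw-scale RDCs D = (b^T S b)/W_pq + noise from a structure.

    noise per type is Gaussian with sigma = noise_sigma / W_pq (NH-scale
    sigma divided by the type's normalization factor), i.e. errors scale
    with the inverse of the dipolar interaction constants.  Records whose
    atoms are missing are skipped.  ``outlier_residues`` rotates the bond
    vectors belonging to the listed residues' amide planes by the given
    angle (deg) about a seeded random axis before evaluating the tensor.
    """
    rng = np.random.default_rng(seed)
    outlier_residues = dict(outlier_residues or {})
    out_rot = {}
    for res, ang in outlier_residues.items():
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        out_rot[res] = Rotation.from_rotvec(np.radians(ang) * axis).as_matrix()
    ids = [r.seqid for r in structure] if residues is None else list(residues)
    records = []
    for t in coupling_types:
        if t not in COUPLING_TYPES:
            raise ValueError(f"unknown coupling type {t!r}")
        (oi, ai), (oj, aj) = COUPLING_ATOMS[t]
        w = normalization_factor(t)
        for seqid in ids:
            ri, rj = seqid + oi, seqid + oj
            if not (structure.has_atom(ri, ai) and structure.has_atom(rj, aj)):
                continue
            b = structure.atom(rj, aj) - structure.atom(ri, ai)
            b = b / np.linalg.norm(b)
            rec_stub = RDCRecord(ri, ai, rj, aj, 0.0, chain=chain)
            for res in _plane_residues(rec_stub) & set(out_rot):
                b = out_rot[res] @ b
            d_nh = float(b @ tensor.matrix @ b)
            noise = rng.normal(0.0, noise_sigma / w) if noise_sigma > 0 else 0.0
            records.append(RDCRecord(ri, ai, rj, aj, d_nh / w + noise,
                                     error=(noise_sigma / w if with_errors and
                                            noise_sigma > 0 else None),
                                     chain=chain))
    return RDCSet(records)


def jitter_structure(structure: Structure, sigma: float, seed: int = 0) -> Structure:
    """Add isotropic Gaussian displacement (sigma in A) to every atom."""
    rng = np.random.default_rng(seed)
    out = structure.copy()
    for res in out:
        for name in res.atoms:
            res.atoms[name] = res.atoms[name] + rng.normal(0.0, sigma, size=3)
    return out


@dataclass
class TwoDomainFixture:
    structure: Structure
    rdcs: RDCSet
    segments: list
    truth: dict


def make_two_domain_fixture(spec: SynthSpec = SynthSpec()) -> TwoDomainFixture:
    """Two helix bundles, each a rigid unit with its own alignment tensor.

    Helices of a unit are rotated into distinct orientations (seeded) and
    translated apart; numbering leaves a 4-residue gap between helices so
    no spurious peptide bonds or shared amide planes arise.  The truth
    record stores each unit's tensor and the helix-to-unit map.
    """
    rng = np.random.default_rng(spec.seed)
    tensors = [SaupeTensor.from_params(da, rh, Rotation.from_euler(
        "zyz", eul, degrees=True)) for da, rh, eul in spec.tensors]
    if any(u >= len(tensors) for _, u in spec.helices):
        raise ValueError("helix references a rigid unit with no tensor")
    residues, segments, helix_unit = [], [], []
    next_id = 1
    offset = np.zeros(3)
    for k, (length, unit) in enumerate(spec.helices):
        if length < 5:
            raise ValueError("fixture helices must have >= 5 residues")
        helix = build_ideal_helix(length + 1, first_seqid=next_id - 1)
        R = Rotation.random(random_state=rng).as_matrix()
        helix = helix.transformed(R, offset)
        if spec.coord_jitter > 0:
            helix = jitter_structure(helix, spec.coord_jitter,
                                     seed=int(rng.integers(2 ** 31)))
        residues.extend(helix.residues)
        segments.append(HelixSegment("A", next_id, next_id + length - 1,
                                     label=f"H{k + 1}"))
        helix_unit.append(unit)
        next_id += length + 5          # 4-residue numbering gap between helices
        offset = offset + np.array([20.0, 0.0, 0.0])
    structure = Structure(residues)
    all_records = []
    for seg, unit in zip(segments, helix_unit):
        ids = range(seg.first, seg.last + 1)
        sub = generate_rdcs(structure, tensors[unit], spec.coupling_types,
                            noise_sigma=spec.noise_sigma,
                            seed=int(np.random.default_rng(
                                (spec.seed, seg.first)).integers(2 ** 31)),
                            residues=ids,
                            outlier_residues={r: a for r, a in
                                              spec.outlier_residues.items()
                                              if seg.first <= r <= seg.last})
        all_records.extend(sub.records)
    truth = {
        "tensors": tensors,
        "helix_unit": dict(zip([s.label for s in segments], helix_unit)),
        "G": [float(np.sqrt((da ** 2) * (4 + 3 * rh ** 2) / 5))
              for da, rh, _ in spec.tensors],
    }
    return TwoDomainFixture(structure, RDCSet(all_records), segments, truth)
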