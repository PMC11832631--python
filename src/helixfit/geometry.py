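"""Backbone geometry: structures, idealized helices, superposition, bond vectors.

Coordinates are in Angstrom throughout.  A :class:`Structure` is a minimal
ordered container of residues with named backbone atoms (PDB v3 names:
``N``, ``CA``, ``C``, ``O``, ``H`` for the amide proton, ``HA``).  Idealized
alpha-helices are built from internal coordinates by chain extension (the
NeRF construction), amide protons are placed assuming standard in-plane
geometry, and rigid-body superposition uses the least-squares (Kabsch)
rotation with the determinant constrained to +1 so reflections are never
returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Residue",
    "Structure",
    "HelixSegment",
    "IdealHelixParams",
    "SuperpositionResult",
    "build_ideal_helix",
    "place_amide_protons",
    "superpose",
    "helix_axis",
    "bond_vector",
    "measure_dihedral",
    "measure_angle",
]

BACKBONE_HEAVY = ("N", "CA", "C")


@dataclass
class Residue:
    """One amino-acid residue: 3-letter name, author sequence number, chain id,
    and a name -> xyz mapping for its atoms."""

    name: str
    seqid: int
    chain: str = "A"
    atoms: dict = field(default_factory=dict)

    def __contains__(self, atom: str) -> bool:
        return atom in self.atoms

    def __getitem__(self, atom: str) -> np.ndarray:
        return self.atoms[atom]

    def copy(self) -> "Residue":
        return Residue(self.name, self.seqid, self.chain,
                       {k: np.array(v, dtype=float) for k, v in self.atoms.items()})


class Structure:
    """Ordered collection of residues, indexable by author residue number.

    Residue numbering follows the source (1-based author numbering, gaps
    allowed); no renumbering is ever applied.
    """

    def __init__(self, residues):
        self.residues = list(residues)
        self._index = {r.seqid: i for i, r in enumerate(self.residues)}
        if len(self._index) != len(self.residues):
            raise ValueError("duplicate residue numbers in structure")

    def __len__(self):
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    def __contains__(self, seqid: int) -> bool:
        return seqid in self._index

    def residue(self, seqid: int) -> Residue:
        try:
            return self.residues[self._index[seqid]]
        except KeyError:
            raise KeyError(f"no residue {seqid} in structure") from None

    def atom(self, seqid: int, name: str) -> np.ndarray:
        res = self.residue(seqid)
        try:
            return res.atoms[name]
        except KeyError:
            raise KeyError(f"residue {seqid} ({res.name}) has no atom {name!r}") from None

    def has_atom(self, seqid: int, name: str) -> bool:
        return seqid in self._index and name in self.residue(seqid).atoms

    def copy(self) -> "Structure":
        return Structure([r.copy() for r in self.residues])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a copy with every atom mapped to R @ x + t."""
        out = self.copy()
        for res in out.residues:
            for name in res.atoms:
                res.atoms[name] = rotation @ res.atoms[name] + translation
        return out

    def coords(self, selection) -> np.ndarray:
        """Stack coordinates for an iterable of (seqid, atom_name) pairs."""
        return np.array([self.atom(s, a) for s, a in selection], dtype=float)

    def sequence(self) -> dict:
        """Author residue number -> 3-letter residue name."""
        return {r.seqid: r.name for r in self.residues}


@dataclass(frozen=True)
class HelixSegment:
    """Inclusive residue range flagged as helical (author numbering)."""

    chain: str
    first: int
    last: int
    label: str = ""

    def __post_init__(self):
        if self.last < self.first:
            raise ValueError(f"segment {self.label!r}: last < first")

    def __len__(self):
        return self.last - self.first + 1

    def __str__(self):
        lab = self.label or "helix"
        return f"{lab}({self.chain}:{self.first}-{self.last})"


@dataclass(frozen=True)
class IdealHelixParams:
    """Internal coordinates of the idealized alpha-helix.

    Defaults: the canonical idealized alpha-helix torsions (phi = -65 deg,
    psi = -40 deg, trans peptide bond) with Engh-Huber-style backbone bond
    lengths and angles.  These reproduce the standard helical geometry:
    3.6 residues per turn, ~1.5 A rise per residue, and backbone N-H
    vectors tilted ~15.8 deg from the helix axis.  The full set is a plain
    dataclass so alternative ideal geometries can be dropped in from a
    config file.
    """

    phi: float = -65.0
    psi: float = -40.0
    omega: float = 180.0
    # bond lengths, Angstrom
    n_ca: float = 1.458
    ca_c: float = 1.525
    c_n: float = 1.329
    c_o: float = 1.231
    n_h: float = 1.02
    ca_ha: float = 1.09
    # bond angles, degrees
    ang_n_ca_c: float = 111.2
    ang_ca_c_n: float = 116.2
    ang_c_n_ca: float = 121.7
    ang_ca_c_o: float = 120.8

    def __post_init__(self):
        for nm in ("n_ca", "ca_c", "c_n", "c_o", "n_h", "ca_ha"):
            v = getattr(self, nm)
            if not 0.8 < v < 2.0:
                raise ValueError(f"bond length {nm}={v} outside (0.8, 2.0) A")
        for nm in ("ang_n_ca_c", "ang_ca_c_n", "ang_c_n_ca", "ang_ca_c_o"):
            v = getattr(self, nm)
            if not 90.0 < v < 180.0:
                raise ValueError(f"bond angle {nm}={v} outside (90, 180) deg")


DEFAULT_IDEAL_PARAMS = IdealHelixParams()


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


def _nerf(a, b, c, length, angle_deg, torsion_deg):
    """Place atom D given chain A-B-C-D: |C-D|, angle(B,C,D), torsion(A,B,C,D)."""
    theta = np.radians(angle_deg)
    tau = np.radians(torsion_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = length * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(tau), -np.sin(theta) * np.sin(tau)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def measure_dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle (degrees, IUPAC sign) of the chain p1-p2-p3-p4."""
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m = np.cross(n1, _unit(b2))
    return float(np.degrees(np.arctan2(m @ n2, n1 @ n2)))


def measure_angle(p1, p2, p3) -> float:
    """Bond angle at p2 in degrees."""
    u, v = _unit(p1 - p2), _unit(p3 - p2)
    return float(np.degrees(np.arccos(np.clip(u @ v, -1.0, 1.0))))


def build_ideal_helix(n: int,
                      params: IdealHelixParams = DEFAULT_IDEAL_PARAMS,
                      first_seqid: int = 1,
                      chain: str = "A",
                      resname: str = "ALA") -> Structure:
    """Build an n-residue idealized helix with exact (phi, psi, omega) repetition.

    Every residue carries N, CA, C, O, HA; the amide H is present from the
    second residue onward (residue 1 has no preceding carbonyl to define the
    amide plane, so its H is omitted by construction).
    """
    if n < 2:
        raise ValueError("ideal helix needs at least 2 residues")
    p = params
    # seed residue 1 in an arbitrary frame; the helix is later superposed anyway
    N = [np.zeros(3)]
    CA = [np.array([p.n_ca, 0.0, 0.0])]
    th = np.radians(p.ang_n_ca_c)
    C = [CA[0] + p.ca_c * np.array([-np.cos(th), np.sin(th), 0.0])]
    for i in range(1, n):
        N.append(_nerf(N[i - 1], CA[i - 1], C[i - 1], p.c_n, p.ang_ca_c_n, p.psi))
        CA.append(_nerf(CA[i - 1], C[i - 1], N[i], p.n_ca, p.ang_c_n_ca, p.omega))
        C.append(_nerf(C[i - 1], N[i], CA[i], p.ca_c, p.ang_n_ca_c, p.phi))
    residues = []
    for i in range(n):
        atoms = {"N": N[i], "CA": CA[i], "C": C[i]}
        # carbonyl O in the peptide plane, anti to the next amide N
        atoms["O"] = _nerf(N[i], CA[i], C[i], p.c_o, p.ang_ca_c_o, p.psi + 180.0)
        # HA on the tetrahedral direction out of the N-CA-C plane
        v1 = _unit(N[i] - CA[i])
        v2 = _unit(C[i] - CA[i])
        bis = _unit(v1 + v2)
        perp = _unit(np.cross(v1, v2))
        half = np.radians(0.5 * 109.5)
        atoms["HA"] = CA[i] + p.ca_ha * (-bis * np.cos(half) + perp * np.sin(half))
        residues.append(Residue(resname, first_seqid + i, chain, atoms))
    out = Structure(residues)
    return place_amide_protons(out, nh_length=p.n_h)


def place_amide_protons(s: Structure, nh_length: float = 1.02,
                        overwrite: bool = False) -> Structure:
    """Place amide protons assuming standard in-plane geometry.

    H sits in the C'(i-1)-N(i)-CA(i) plane on the external bisector (trans
    to both heavy-atom substituents of N) at ``nh_length``.  Residues whose
    anchors (previous C' or own CA) are missing are skipped; existing H
    atoms are kept unless ``overwrite``.
    """
    out = s.copy()
    for k, res in enumerate(out.residues):
        if "H" in res.atoms and not overwrite:
            continue
        if res.name == "PRO":
            continue
        if k == 0:
            continue
        prev = out.residues[k - 1]
        if prev.seqid != res.seqid - 1 or "C" not in prev.atoms:
            continue
        if "N" not in res.atoms or "CA" not in res.atoms:
            continue
        n = res.atoms["N"]
        u1 = _unit(prev.atoms["C"] - n)
        u2 = _unit(res.atoms["CA"] - n)
        res.atoms["H"] = n + nh_length * _unit(-(u1 + u2))
    return out


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    transformed: Structure | None = None


def _kabsch(mobile_xyz: np.ndarray, target_xyz: np.ndarray):
    """Proper-rotation least-squares superposition of paired coordinate sets."""
    mc = mobile_xyz.mean(axis=0)
    tc = target_xyz.mean(axis=0)
    P = mobile_xyz - mc
    Q = target_xyz - tc
    H = P.T @ Q
    U, sing, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    moved = (R @ mobile_xyz.T).T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target_xyz) ** 2, axis=1))))
    return R, t, rmsd


def superpose(mobile: Structure, target: Structure, atoms=None) -> SuperpositionResult:
    """Optimal rigid superposition of ``mobile`` onto ``target``.

    ``atoms`` is a list of (seqid, atom_name) pairs resolved in both
    structures; by default the N, CA, C atoms of all residues common to
    both.  Reflections are excluded (det(R) = +1).
    """
    if atoms is None:
        common = sorted(set(r.seqid for r in mobile) & set(r.seqid for r in target))
        atoms = [(s, a) for s in common for a in BACKBONE_HEAVY
                 if mobile.has_atom(s, a) and target.has_atom(s, a)]
    if len(atoms) < 3:
        raise ValueError(f"superposition needs >= 3 atom pairs, got {len(atoms)}")
    R, t, rmsd = _kabsch(mobile.coords(atoms), target.coords(atoms))
    return SuperpositionResult(R, t, rmsd, mobile.transformed(R, t))


def helix_axis(s: Structure, seg: HelixSegment) -> np.ndarray:
    """Helix axis as the screw axis of the one-residue-shift CA superposition.

    The optimal rigid transform mapping CA(first..last-1) onto
    CA(first+1..last) is a screw motion about the helix axis; its rotation
    axis, oriented N-terminus -> C-terminus, is returned as a unit vector.
    """
    ids = [r for r in range(seg.first, seg.last + 1) if s.has_atom(r, "CA")]
    if len(ids) < 4:
        raise ValueError(f"helix axis for {seg} needs >= 4 CA atoms, got {len(ids)}")
    a = np.array([s.atom(r, "CA") for r in ids[:-1]])
    b = np.array([s.atom(r, "CA") for r in ids[1:]])
    R, t, _ = _kabsch(a, b)
    axis = Rotation.from_matrix(R).as_rotvec()
    axis = _unit(axis)
    # orient along chain direction
    if axis @ (b[-1] - a[0]) < 0:
        axis = -axis
    return axis


# atom pair defining each coupling type, as (residue offset, atom name) for the
# two nuclei, offsets relative to the record's amide-bearing residue i
COUPLING_ATOMS = {
    "NH": ((0, "N"), (0, "H")),
    "CAHA": ((0, "CA"), (0, "HA")),
    "CN": ((-1, "C"), (0, "N")),      # sequential 1D(C'N): C' of i-1 to N of i
    "CAC": ((0, "CA"), (0, "C")),
    "CHN": ((-1, "C"), (0, "H")),     # two-bond 2D(C'HN)
    "CHA": ((0, "C"), (0, "HA")),     # two-bond 2D(C'HA)
}


def bond_vector(s: Structure, record) -> np.ndarray:
    """Unit internuclear vector for an RDC record (sign is immaterial: the
    predicted coupling b^T S b is even in b)."""
    try:
        a = s.atom(record.residue_i, record.atom_i)
        b = s.atom(record.residue_j, record.atom_j)
    except KeyError as exc:
        raise KeyError(f"cannot resolve atoms for {record}: {exc}") from None
    return _unit(b - a)
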