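"""File readers/writers and run configuration.

Formats
-------
RDC table (plain text, '#' comments):
    RESID_I ATOM_I RESID_J ATOM_J D_HZ [ERR_HZ] [CHAIN]
Segment list:
    LABEL CHAIN FIRST LAST
PDB: ATOM records of a single model read through gemmi (first altloc kept,
insertion-coded residues rejected).  Reports are JSON (canonical) with a
derived human-readable text summary.
"""

from __future__ import annotations

import json

import numpy as np
import gemmi
import yaml

from .fit import RDCRecord, RDCSet
from .geometry import HelixSegment, IdealHelixParams, Residue, Structure

__all__ = [
    "read_rdc_table",
    "write_rdc_table",
    "read_segments",
    "write_segments",
    "read_pdb",
    "write_pdb",
    "report_to_dict",
    "write_report",
    "text_summary",
    "load_config",
]

REPORT_SCHEMA_VERSION = 1

_BACKBONE_KEEP = {"N", "CA", "C", "O", "H", "HA", "HN", "HA2", "CB"}


def read_rdc_table(path) -> RDCSet:
    """Parse an RDC table; coupling types are inferred from the atom pair
    and residue offset, duplicates and malformed lines raise with line
    numbers."""
    records, lines = [], {}
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tok = line.split()
            if len(tok) < 5:
                raise ValueError(f"{path}:{ln}: expected at least 5 columns: {raw!r}")
            try:
                ri, ai, rj, aj = int(tok[0]), tok[1].upper(), int(tok[2]), tok[3].upper()
                d = float(tok[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed line: {exc}") from None
            err, chain = None, "A"
            rest = tok[5:]
            if rest and _is_float(rest[0]):
                err = float(rest[0])
                rest = rest[1:]
            if rest:
                chain = rest[0]
            try:
                rec = RDCRecord(ri, ai, rj, aj, d, error=err, chain=chain)
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: {exc}") from None
            key = (rec.chain, rec.residue_i, rec.coupling_type)
            if key in lines:
                raise ValueError(
                    f"{path}:{ln}: duplicate RDC for residue {rec.residue_i} "
                    f"type {rec.coupling_type} (first seen on line {lines[key]})")
            lines[key] = ln
            records.append(rec)
    return RDCSet(records)


def _is_float(tok: str) -> bool:
    try:
        float(tok)
    except ValueError:
        return False
    return True


def write_rdc_table(path, rdcs: RDCSet) -> None:
    with open(path, "w") as fh:
        fh.write("# RESID_I ATOM_I RESID_J ATOM_J D_HZ [ERR_HZ] [CHAIN]\n")
        for r in rdcs:
            err = "" if r.error is None else f" {r.error:.6g}"
            fh.write(f"{r.residue_i} {r.atom_i} {r.residue_j} {r.atom_j} "
                     f"{r.D:.6g}{err} {r.chain}\n")


def read_segments(path) -> list:
    """Read 'LABEL CHAIN FIRST LAST' lines into HelixSegment objects."""
    out = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tok = line.split()
            if len(tok) != 4:
                raise ValueError(f"{path}:{ln}: expected 'LABEL CHAIN FIRST LAST'")
            try:
                out.append(HelixSegment(tok[1], int(tok[2]), int(tok[3]),
                                        label=tok[0]))
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: {exc}") from None
    return out


def write_segments(path, segments) -> None:
    with open(path, "w") as fh:
        fh.write("# LABEL CHAIN FIRST LAST\n")
        for s in segments:
            fh.write(f"{s.label or 'H'} {s.chain} {s.first} {s.last}\n")


def read_pdb(path, chain: str | None = None) -> Structure:
    """Read backbone atoms from the first model of a PDB file.

    ``chain`` defaults to the first chain present; the first altloc is
    kept, residues with insertion codes raise (renumber upstream).
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    model = st[0]
    if chain is None:
        if len(model) == 0:
            raise ValueError(f"{path}: no chains")
        ch = model[0]
    else:
        ch = model.find_chain(chain)
        if ch is None:
            raise ValueError(f"{path}: no chain {chain!r}")
    residues = []
    for res in ch:
        if not any(a.name in ("CA", "N") for a in res):
            continue        # waters/ligands
        seqid = res.seqid
        if seqid.icode and seqid.icode.strip():
            raise ValueError(
                f"{path}: residue {seqid.num}{seqid.icode} has an insertion "
                f"code; renumber the structure first")
        atoms = {}
        for atom in res:
            alt = atom.altloc.strip("\x00 ")
            if alt and alt != "A":      # keep the first altloc only
                continue
            name = "H" if atom.name == "HN" else atom.name
            if name in atoms:
                continue
            atoms[name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
        residues.append(Residue(res.name, seqid.num, ch.name, atoms))
    if not residues:
        raise ValueError(f"{path}: no amino-acid residues in chain {ch.name}")
    return Structure(residues)


def write_pdb(path, structure: Structure) -> None:
    """Write a Structure as a single-model PDB file (via gemmi)."""
    st = gemmi.Structure()
    st.name = "helixfit"
    model = gemmi.Model("1")
    chains = {}
    for res in structure:
        ch = chains.setdefault(res.chain, gemmi.Chain(res.chain))
        gres = gemmi.Residue()
        gres.name = res.name
        gres.seqid = gemmi.SeqId(res.seqid, " ")
        for name, xyz in res.atoms.items():
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(name[0] if name[0] != "H" else "H")
            atom.pos = gemmi.Position(*map(float, xyz))
            gres.add_atom(atom)
        ch.add_residue(gres)
    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    doc = st.make_pdb_string()
    with open(path, "w") as fh:
        fh.write(doc)


def _fit_block(fr) -> dict:
    if fr is None:
        return None
    return {
        "Da": fr.params.Da, "Rh": fr.params.Rh, "G": fr.params.G,
        "euler_zyz": list(fr.params.euler),
        "Q": fr.Q, "Q_jk": fr.Q_jk, "Q_jk_norm1": fr.Q_jk_norm1,
        "eps_S": fr.eps_S, "eps_G": fr.eps_G, "mean_G": fr.mean_G,
        "N": fr.n_rdc, "rank": fr.rank, "condition": fr.condition,
    }


def report_to_dict(reports, cross=None, skipped=None, extras=None) -> dict:
    """Assemble the canonical JSON report from helix reports and the
    cross-helix block produced by :func:`helixfit.screen.cross_helix_matrix`."""
    helices = []
    for rep in reports:
        helices.append({
            "segment": {"label": rep.segment.label, "chain": rep.segment.chain,
                        "first": rep.segment.first, "last": rep.segment.last},
            "culled": list(rep.culled),
            "flags": list(rep.flags),
            "ideal": _fit_block(rep.fit_ideal),
            "xray": _fit_block(rep.fit_xray),
        })
    out = {"schema_version": REPORT_SCHEMA_VERSION, "helices": helices}
    if skipped:
        out["skipped"] = [{"segment": str(s), "reason": r} for s, r in skipped]
    if cross is not None:
        labels, P, Pg, global_fit = cross
        out["cross_helix"] = {
            "labels": list(labels),
            "P_matrix": np.asarray(P).tolist(),
            "P_vs_global": np.asarray(Pg).tolist(),
            "global": _fit_block(global_fit),
        }
    if extras:
        out.update(extras)
    return out


def write_report(path, report: dict) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")


def text_summary(report: dict) -> str:
    """Human-readable summary derived from the JSON report."""
    lines = []
    for h in report.get("helices", []):
        seg = h["segment"]
        head = f"{seg['label'] or 'helix'} {seg['chain']}:{seg['first']}-{seg['last']}"
        lines.append(head)
        for mode in ("ideal", "xray"):
            blk = h.get(mode)
            if not blk:
                continue
            lines.append(
                f"  {mode:>5}: N={blk['N']:3d}  Da={blk['Da']:7.3f} Hz  "
                f"Rh={blk['Rh']:5.3f}  G={blk['G']:6.3f} Hz  "
                f"Q_jk={blk['Q_jk']:.3f}  eps(G)={blk['eps_G']:.3f}  "
                f"eps(S)={blk['eps_S']:.3f}")
        if h["culled"]:
            lines.append(f"  culled terminal residues: {h['culled']}")
    cross = report.get("cross_helix")
    if cross:
        lines.append("P(S_i, S_j) vs global tensor:")
        for lab, p in zip(cross["labels"], cross["P_vs_global"]):
            lines.append(f"  {lab}: {p:.3f}")
    for s in report.get("skipped", []):
        lines.append(f"skipped {s['segment']}: {s['reason']}")
    return "\n".join(lines)


_KNOWN_KEYS = {
    "pdb", "rdc", "segments", "report", "chain", "mode", "min_helix_length",
    "min_rdc_count", "cull_terminal", "cull_improvement_threshold",
    "ideal_params", "distances", "seed", "log_level",
}


def load_config(path) -> dict:
    """Load a YAML run configuration, rejecting unknown keys."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(cfg) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    if "ideal_params" in cfg:
        cfg["ideal_params"] = IdealHelixParams(**cfg["ideal_params"])
    return cfg
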