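"""Backbone I/O, dihedral geometry and side-chain reconstruction.

Reads protein backbones from PDB text (via gemmi), computes φ/ψ/ω dihedrals,
rebuilds side-chain heavy atoms from rotamer χ angles by sequential
internal-coordinate (NeRF) construction against a packaged ideal-geometry
table, and writes predicted full-atom structures back to PDB.

All angles in the public contract are degrees in (−180, 180]; radians are
internal only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence

import gemmi
import numpy as np

log = logging.getLogger(__name__)

AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: number of side-chain χ dihedrals per amino acid
CHI_COUNT = {
    "ALA": 0, "GLY": 0, "CYS": 1, "SER": 1, "THR": 1, "VAL": 1,
    "ASN": 2, "ASP": 2, "HIS": 2, "ILE": 2, "LEU": 2, "PHE": 2,
    "PRO": 2, "TRP": 2, "TYR": 2, "GLN": 3, "GLU": 3, "MET": 3,
    "ARG": 4, "LYS": 4,
}

#: atom-name quadruples defining χ1..χ4 (standard IUPAC definitions)
CHI_ATOMS = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}

DEFAULT_CHAIN_BREAK = 4.5  # Å, CA–CA distance above which a break is declared


class StructureError(ValueError):
    """Raised for unusable structure input (duplicate/missing backbone atoms)."""


class GeometryError(ValueError):
    """Raised when a dihedral is geometrically undefined."""


@dataclass(frozen=True)
class AtomCoord:
    """One heavy atom: element symbol, PDB atom name and position in Å."""

    element: str
    name: str
    position: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"bad position for atom {self.name}: {self.position}")
        object.__setattr__(self, "position", pos)


@dataclass
class ResidueBackbone:
    """A residue's identity, backbone atoms and backbone dihedrals.

    ``index`` is the 0-based position in the parsed chain order; ``label``
    preserves the author chain/residue numbering for reporting.  ``phi`` is
    None at a chain start, ``psi``/``omega`` at a chain end or across a
    detected chain break.
    """

    index: int
    aa: str
    atoms: Dict[str, AtomCoord]
    chain: str = "A"
    resseq: int = 1
    icode: str = ""
    phi: Optional[float] = None
    psi: Optional[float] = None
    omega: Optional[float] = None

    @property
    def label(self) -> str:
        return f"{self.chain}{self.resseq}{self.icode}".strip()

    def pos(self, name: str) -> np.ndarray:
        return self.atoms[name].position


@dataclass
class SideChainConformation:
    """Side-chain heavy atoms of one residue at a given χ vector."""

    residue_index: int
    chi: List[float]
    atoms: List[AtomCoord] = field(default_factory=list)


# ---------------------------------------------------------------------------
# dihedral geometry


def compute_dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle of the p2–p3 axis, IUPAC convention, degrees.

    Returns values in (−180, 180].  Raises :class:`GeometryError` for
    degenerate geometry (coincident consecutive points or collinear triples)
    instead of returning a silent number.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    for b in (b1, b2, b3):
        if np.linalg.norm(b) < 1e-9:
            raise GeometryError("coincident consecutive points")
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise GeometryError("collinear points, dihedral undefined")
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    ang = -math.degrees(math.atan2(np.dot(m, n2), np.dot(n1, n2)))
    return wrap_angle(ang)


def wrap_angle(deg: float) -> float:
    """Map an angle in degrees to (−180, 180]."""
    a = (deg + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def place_atom(a3, a2, a1, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: position a new atom bonded to ``a1``.

    The new atom D satisfies |D−a1| = bond, angle(D, a1, a2) = angle_deg and
    dihedral(a3, a2, a1, D) = torsion_deg.
    """
    a1, a2, a3 = (np.asarray(p, dtype=float) for p in (a1, a2, a3))
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    d = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        bond * math.sin(ang) * math.sin(tor),
    ])
    bc = a1 - a2
    bc /= np.linalg.norm(bc)
    ab = a2 - a3
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-9:
        raise GeometryError("collinear reference frame for atom placement")
    n /= norm
    m = np.column_stack([bc, np.cross(n, bc), n])
    return a1 + m @ d


# ---------------------------------------------------------------------------
# PDB parsing


def parse_backbone(pdb_text: str) -> List[ResidueBackbone]:
    """Parse PDB ATOM records into ordered :class:`ResidueBackbone` records.

    Only the 20 standard amino acids of model 1 are kept.  Alternate
    locations are resolved to the highest occupancy (first wins on a tie).
    A residue with two copies of the same backbone atom at the same altloc,
    or with any of N/CA/C/O missing, is a hard error.
    """
    structure = gemmi.read_pdb_string(pdb_text)
    if len(structure) == 0:
        raise StructureError("no model in PDB input")
    model = structure[0]
    residues: List[ResidueBackbone] = []
    for chain in model:
        for res in chain:
            if res.name not in AA3:
                continue
            seen: Dict[tuple, gemmi.Atom] = {}
            for atom in res:
                key = (atom.name, atom.altloc)
                if key in seen and atom.name in BACKBONE_ATOMS + ("CB",):
                    raise StructureError(
                        f"duplicate backbone atom {atom.name} in residue "
                        f"{chain.name} {res.seqid.num}{res.seqid.icode}".strip()
                    )
                seen.setdefault(key, atom)
            # collapse altlocs: highest occupancy, first on tie
            best: Dict[str, gemmi.Atom] = {}
            for (name, _), atom in seen.items():
                cur = best.get(name)
                if cur is None or atom.occ > cur.occ:
                    best[name] = atom
            atoms: Dict[str, AtomCoord] = {}
            for name in BACKBONE_ATOMS + ("CB",):
                if name in best:
                    a = best[name]
                    atoms[name] = AtomCoord(
                        element=a.element.name or name[0],
                        name=name,
                        position=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    )
            missing = [n for n in BACKBONE_ATOMS if n not in atoms]
            if missing:
                raise StructureError(
                    f"residue {chain.name} {res.seqid.num}{res.seqid.icode} "
                    f"missing backbone atoms: {','.join(missing)}".strip()
                )
            residues.append(
                ResidueBackbone(
                    index=len(residues),
                    aa=res.name,
                    atoms=atoms,
                    chain=chain.name,
                    resseq=res.seqid.num,
                    icode=(res.seqid.icode or "").strip(),
                )
            )
    if not residues:
        raise StructureError("no standard amino-acid ATOM records found")
    return residues


def parse_side_chain_chis(pdb_text: str) -> Dict[int, List[Optional[float]]]:
    """Measure χ angles of every residue of a full-atom PDB.

    Returns a mapping from the parsed residue index to its χ list (length =
    the amino acid's canonical χ count, entries None where atoms are absent).
    """
    structure = gemmi.read_pdb_string(pdb_text)
    model = structure[0]
    out: Dict[int, List[Optional[float]]] = {}
    idx = 0
    for chain in model:
        for res in chain:
            if res.name not in AA3:
                continue
            pos: Dict[str, np.ndarray] = {}
            for atom in res:
                if atom.name not in pos:
                    pos[atom.name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
            chis: List[Optional[float]] = []
            for quad in CHI_ATOMS.get(res.name, []):
                if all(a in pos for a in quad):
                    chis.append(compute_dihedral(*(pos[a] for a in quad)))
                else:
                    chis.append(None)
            out[idx] = chis
            idx += 1
    return out


def annotate_backbone_dihedrals(
    residues: Sequence[ResidueBackbone],
    chain_break: float = DEFAULT_CHAIN_BREAK,
) -> List[ResidueBackbone]:
    """Fill φ/ψ/ω in place; termini and chain breaks stay undefined.

    φ_i = C(i−1)–N(i)–CA(i)–C(i); ψ_i = N(i)–CA(i)–C(i)–N(i+1);
    ω_i = CA(i)–C(i)–N(i+1)–CA(i+1).  Two residues are consecutive only if
    they share a chain and their CA–CA distance is within ``chain_break``.
    """
    def consecutive(a: ResidueBackbone, b: ResidueBackbone) -> bool:
        if a.chain != b.chain:
            return False
        d = np.linalg.norm(a.pos("CA") - b.pos("CA"))
        if d > chain_break:
            log.warning(
                "chain break between %s and %s (CA-CA %.2f Å)", a.label, b.label, d
            )
            return False
        return True

    res = list(residues)
    for i, r in enumerate(res):
        prev = res[i - 1] if i > 0 and consecutive(res[i - 1], r) else None
        nxt = res[i + 1] if i + 1 < len(res) and consecutive(r, res[i + 1]) else None
        try:
            if prev is not None:
                r.phi = compute_dihedral(
                    prev.pos("C"), r.pos("N"), r.pos("CA"), r.pos("C")
                )
            if nxt is not None:
                r.psi = compute_dihedral(
                    r.pos("N"), r.pos("CA"), r.pos("C"), nxt.pos("N")
                )
                r.omega = compute_dihedral(
                    r.pos("CA"), r.pos("C"), nxt.pos("N"), nxt.pos("CA")
                )
        except GeometryError as exc:
            log.warning("undefined dihedral at %s: %s", r.label, exc)
    return res


# ---------------------------------------------------------------------------
# side-chain construction

_GEOMETRY_TABLE: Optional[Dict[str, list]] = None


def _geometry_table() -> Dict[str, list]:
    global _GEOMETRY_TABLE
    if _GEOMETRY_TABLE is None:
        table: Dict[str, list] = {}
        text = (
            resources.files("rotamrf.data")
            .joinpath("sidechain_geometry.tsv")
            .read_text()
        )
        for line in text.splitlines():
            if not line or line.startswith("#"):
                continue
            res, atom, a1, a2, a3, bond, angle, chi, delta = line.split("\t")
            table.setdefault(res, []).append(
                (atom, a1, a2, a3, float(bond), float(angle), int(chi), float(delta))
            )
        _GEOMETRY_TABLE = table
    return _GEOMETRY_TABLE


def build_side_chain(residue: ResidueBackbone, chi: Sequence[float]) -> SideChainConformation:
    """Place side-chain heavy atoms for ``residue`` at the given χ angles.

    Atoms are constructed sequentially by internal coordinates from the
    packaged ideal-geometry table; χ values are consumed in order χ1..χ4 and
    must match the amino acid's canonical count.  GLY yields no atoms, ALA
    only CB.
    """
    aa = residue.aa
    if aa == "GLY":
        if len(chi) != 0:
            raise ValueError("GLY takes no chi angles")
        return SideChainConformation(residue.index, [], [])
    if aa not in AA3:
        raise ValueError(f"unsupported residue code {aa!r}")
    n_chi = CHI_COUNT[aa]
    if len(chi) != n_chi:
        raise ValueError(f"{aa} needs {n_chi} chi angles, got {len(chi)}")
    pos: Dict[str, np.ndarray] = {
        "N": residue.pos("N"), "CA": residue.pos("CA"), "C": residue.pos("C")
    }
    atoms: List[AtomCoord] = []
    for atom, a1, a2, a3, bond, angle, chi_k, delta in _geometry_table()[aa]:
        torsion = (chi[chi_k - 1] + delta) if chi_k else delta
        p = place_atom(pos[a3], pos[a2], pos[a1], bond, angle, torsion)
        pos[atom] = p
        atoms.append(AtomCoord(element=atom[0], name=atom, position=p))
    return SideChainConformation(residue.index, [wrap_angle(c) for c in chi], atoms)


def side_chain_chis(residue: ResidueBackbone, conf: SideChainConformation) -> List[float]:
    """Recompute χ angles from a built side chain (round-trip check)."""
    pos = {"N": residue.pos("N"), "CA": residue.pos("CA"), "C": residue.pos("C")}
    pos.update({a.name: a.position for a in conf.atoms})
    return [
        compute_dihedral(*(pos[a] for a in quad))
        for quad in CHI_ATOMS.get(residue.aa, [])
    ]


# ---------------------------------------------------------------------------
# PDB writing


def _format_atom(serial: int, name: str, res: ResidueBackbone, p: np.ndarray,
                 element: str) -> str:
    pad_name = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:5d} {pad_name:<4s} {res.aa:<3s} {res.chain[:1]:1s}"
        f"{res.resseq:4d}{(res.icode or ' '):1s}   "
        f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {element:>2s}"
    )


def write_structure(
    residues: Sequence[ResidueBackbone],
    assignments: Optional[Dict[int, SideChainConformation]] = None,
) -> str:
    """Emit PDB text: input backbone coordinates plus assigned side chains.

    Backbone positions are copied unchanged (8.3f PDB convention); side-chain
    atoms follow the backbone of their residue in construction order.
    """
    assignments = assignments or {}
    lines: List[str] = []
    serial = 1
    for res in residues:
        for name in BACKBONE_ATOMS:
            a = res.atoms[name]
            lines.append(_format_atom(serial, name, res, a.position, a.element))
            serial += 1
        conf = assignments.get(res.index)
        if conf is not None:
            for a in conf.atoms:
                lines.append(_format_atom(serial, a.name, res, a.position, a.element))
                serial += 1
        elif "CB" in res.atoms:
            a = res.atoms["CB"]
            lines.append(_format_atom(serial, "CB", res, a.position, a.element))
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
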