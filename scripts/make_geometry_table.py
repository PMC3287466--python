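"""Derive the ideal side-chain geometry table from CCD residue templates.

For every heavy side-chain atom of the 20 standard amino acids this script
measures the ideal bond length, bond angle and torsion offset from biotite's
bundled Chemical Component Dictionary coordinates and writes them to
src/rotamrf/data/sidechain_geometry.tsv.  Atoms whose torsion is controlled
by a chi angle carry the chi index and an offset relative to that chi
(0 for the atom that defines the chi, a measured branch offset otherwise);
all other atoms carry an absolute ideal torsion.

Run from the repository root:  python scripts/make_geometry_table.py
"""

from pathlib import Path

import numpy as np
import biotite.structure.info as info

# atom, frame (a1, a2, a3), chi index (0 = fixed torsion)
# The atom is bonded to a1; bond angle is atom-a1-a2; torsion is
# dihedral(a3, a2, a1, atom).
TOPOLOGY = {
    "ALA": [("CB", "CA", "N", "C", 0)],
    "ARG": [
        ("CB", "CA", "N", "C", 0),
        ("CG", "CB", "CA", "N", 1),
        ("CD", "CG", "CB", "CA", 2),
        ("NE", "CD", "CG", "CB", 3),
        ("CZ", "NE", "CD", "CG", 4),
        ("NH1", "CZ", "NE", "CD", 0),
        ("NH2", "CZ", "NE", "CD", 0),
    ],
    "ASN": [
        ("CB", "CA", "N", "C", 0),
        ("CG", "CB", "CA", "N", 1),
        ("OD1", "CG", "CB", "CA", 2),
        ("ND2", "CG", "CB", "CA", 2),
    ],
    "ASP": [
        ("CB", "CA", "N", "C", 0),
        ("CG", "CB", "CA", "N", 1),
        ("OD1", "CG", "CB", "CA", 2),
        ("OD2", "CG", "CB", "CA", 2),
    ],
    "CYS": [("CB", "CA", "N", "C", 0), ("SG", "CB", "CA", "N", 1)],
    "GLN": [
        ("CB", "CA", "N", "C", 0),
        ("CG", "CB", "CA", "N", 1),
        ("CD", "CG", "CB", "CA", 2),
        ("OE1", "CD", "CG", "CB", 3),
        ("NE2", "CD", "CG", "CB", 3),
    ],
    "GLU": [
        ("CB", "CA", "N", "C", 0),
        ("CG", "CB", "CA", "N", 1),
        ("CD", "CG", "CB", "CA", 2),
        ("OE1", "CD", "CG", "CB", 3),
        ("OE2", "CD", "CG", "CB", 3),
    ],
    "HIS": [
        ("CB", "CA", "N", "C", 0),
        ("CG", "CB", "CA", "N", 1),
        ("ND1", "CG", "CB", "CA", 2),
        ("CD2", "CG", "CB", "CA", 2),
        ("CE1", "ND1", "CG", "CB", 0),
        ("NE2", "CD2", "CG", "CB", 0),
    ],
    "ILE": [
        ("CB", "CA", "N", "C", 0),
        ("CG1", "CB", "CA", "N", 1),
        ("CG2", "CB", "CA", "N", 1),
        ("CD1", "CG1", "CB", "CA", 2),
    ],
    "LEU": [
        ("CB", "CA", "N", "C", 0),
        ("CG", "CB", "CA", "N", 1),
        ("CD1", "CG", "CB", "CA", 2),
        ("CD2", "CG", "CB", "CA", 2),
    ],
    "LYS": [
        ("CB", "CA", "N", "C", 0),
        ("CG", "CB", "CA", "N", 1),
        ("CD", "CG", "CB", "CA", 2),
        ("CE", "CD", "CG", "CB", 3),
        ("NZ", "CE", "CD", "CG", 4),
    ],
    "MET": [
        ("CB", "CA", "N", "C", 0),
        ("CG", "CB", "CA", "N", 1),
        ("SD", "CG", "CB", "CA", 2),
        ("CE", "SD", "CG", "CB", 3),
    ],
    "PHE": [
        ("CB", "CA", "N", "C", 0),
        ("CG", "CB", "CA", "N", 1),
        ("CD1", "CG", "CB", "CA", 2),
        ("CD2", "CG", "CB", "CA", 2),
        ("CE1", "CD1", "CG", "CB", 0),
        ("CE2", "CD2", "CG", "CB", 0),
        ("CZ", "CE1", "CD1", "CG", 0),
    ],
    "PRO": [
        ("CB", "CA", "N", "C", 0),
        ("CG", "CB", "CA", "N", 1),
        ("CD", "CG", "CB", "CA", 2),
    ],
    "SER": [("CB", "CA", "N", "C", 0), ("OG", "CB", "CA", "N", 1)],
    "THR": [
        ("CB", "CA", "N", "C", 0),
        ("OG1", "CB", "CA", "N", 1),
        ("CG2", "CB", "CA", "N", 1),
    ],
    "TRP": [
        ("CB", "CA", "N", "C", 0),
        ("CG", "CB", "CA", "N", 1),
        ("CD1", "CG", "CB", "CA", 2),
        ("CD2", "CG", "CB", "CA", 2),
        ("NE1", "CD1", "CG", "CB", 0),
        ("CE2", "CD2", "CG", "CB", 0),
        ("CE3", "CD2", "CG", "CB", 0),
        ("CZ2", "CE2", "CD2", "CG", 0),
        ("CZ3", "CE3", "CD2", "CG", 0),
        ("CH2", "CZ2", "CE2", "CD2", 0),
    ],
    "TYR": [
        ("CB", "CA", "N", "C", 0),
        ("CG", "CB", "CA", "N", 1),
        ("CD1", "CG", "CB", "CA", 2),
        ("CD2", "CG", "CB", "CA", 2),
        ("CE1", "CD1", "CG", "CB", 0),
        ("CE2", "CD2", "CG", "CB", 0),
        ("CZ", "CE1", "CD1", "CG", 0),
        ("OH", "CZ", "CE1", "CD1", 0),
    ],
    "VAL": [
        ("CB", "CA", "N", "C", 0),
        ("CG1", "CB", "CA", "N", 1),
        ("CG2", "CB", "CA", "N", 1),
    ],
}

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


def dihedral(p1, p2, p3, p4):
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return -np.degrees(np.arctan2(np.dot(m, n2), np.dot(n1, n2)))


def angle(p1, p2, p3):
    v1, v2 = p1 - p2, p3 - p2
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))


def main():
    out = Path(__file__).resolve().parents[1] / "src/rotamrf/data/sidechain_geometry.tsv"
    lines = ["# res\tatom\ta1\ta2\ta3\tbond_A\tangle_deg\tchi\tdelta_deg"]
    for res, rows in sorted(TOPOLOGY.items()):
        tmpl = info.residue(res)
        pos = {n: tmpl.coord[i] for i, n in enumerate(tmpl.atom_name)}
        chis = [dihedral(*(pos[a] for a in q)) for q in CHI_ATOMS.get(res, [])]
        for atom, a1, a2, a3, chi in rows:
            b = np.linalg.norm(pos[atom] - pos[a1])
            ang = angle(pos[atom], pos[a1], pos[a2])
            tor = dihedral(pos[a3], pos[a2], pos[a1], pos[atom])
            delta = ((tor - chis[chi - 1] + 180.0) % 360.0) - 180.0 if chi else tor
            if chi and abs(delta) < 1e-6:
                delta = 0.0
            lines.append(
                f"{res}\t{atom}\t{a1}\t{a2}\t{a3}\t{b:.4f}\t{ang:.3f}\t{chi}\t{delta:.3f}"
            )
    out.write_text("\n".join(lines) + "\n")
    print(f"wrote {out} ({len(lines) - 1} rows)")


if __name__ == "__main__":
    main()
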