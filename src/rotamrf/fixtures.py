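"""Deterministic synthetic data: backbones, rotamer libraries and toy MRFs.

These generators make every pipeline stage testable without downloading
structures or licensed libraries.  They aim at geometric and statistical
validity, not at reproducing PDB-wide rotamer statistics: a helix fixture
is an ideal-geometry poly-peptide, and the library generator draws
Dirichlet priors around canonical gauche−/gauche+/trans χ values.

Everything is reproducible: the same spec and seed give byte-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .interaction_graph import InteractionGraph
from .potentials import EnergyParams, MarkovRandomField, vertex_energy
from .rotamer_library import RotamerLibrary, RotamerRecord, parse_library
from .structure_io import (
    CHI_COUNT,
    AtomCoord,
    ResidueBackbone,
    SideChainConformation,
    annotate_backbone_dihedrals,
    build_side_chain,
    place_atom,
    write_structure,
)

# ideal backbone internal coordinates (Å, degrees)
_BOND_N_CA, _BOND_CA_C, _BOND_C_N, _BOND_C_O = 1.458, 1.525, 1.329, 1.231
_ANG_N_CA_C, _ANG_CA_C_N, _ANG_C_N_CA, _ANG_CA_C_O = 111.2, 116.2, 121.7, 120.8

HELIX_PHI, HELIX_PSI = -57.0, -47.0
EXTENDED_PHI, EXTENDED_PSI = -139.0, 135.0


@dataclass
class FixtureSpec:
    n_residues: int
    sequence: Optional[Sequence[str]] = None  # 3-letter codes; default poly-SER
    mode: str = "helix"                       # helix | extended | perturbed
    noise_sigma: float = 0.05                 # Å, perturbed mode
    seed: int = 0

    def __post_init__(self):
        if self.n_residues < 1:
            raise ValueError("need at least one residue")
        if self.mode not in ("helix", "extended", "perturbed"):
            raise ValueError(f"unknown backbone mode {self.mode!r}")


def _phi_psi(mode: str) -> Tuple[float, float]:
    if mode == "extended":
        return EXTENDED_PHI, EXTENDED_PSI
    return HELIX_PHI, HELIX_PSI


def make_backbone(spec: FixtureSpec) -> Tuple[str, List[ResidueBackbone]]:
    """Build an ideal-geometry backbone; returns (PDB text, annotated residues).

    Helix mode uses φ=−57°, ψ=−47°; extended mode φ=−139°, ψ=135°; perturbed
    mode is a helix with seeded Gaussian coordinate noise of ``noise_sigma``
    Å (topology-preserving at the default amplitude).
    """
    n = spec.n_residues
    seq = list(spec.sequence) if spec.sequence else ["SER"] * n
    if len(seq) != n:
        raise ValueError("sequence length does not match n_residues")
    phi, psi = _phi_psi(spec.mode)

    coords: List[Dict[str, np.ndarray]] = []
    ncac: List[Dict[str, np.ndarray]] = []
    pos_n = np.array([0.0, 0.0, 0.0])
    pos_ca = np.array([_BOND_N_CA, 0.0, 0.0])
    ang = np.radians(180.0 - _ANG_N_CA_C)
    pos_c = pos_ca + _BOND_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    ncac.append({"N": pos_n, "CA": pos_ca, "C": pos_c})
    for i in range(1, n):
        prev = ncac[-1]
        nn = place_atom(prev["N"], prev["CA"], prev["C"], _BOND_C_N, _ANG_CA_C_N, psi)
        ca = place_atom(prev["CA"], prev["C"], nn, _BOND_N_CA, _ANG_C_N_CA, 180.0)
        cc = place_atom(prev["C"], nn, ca, _BOND_CA_C, _ANG_N_CA_C, phi)
        ncac.append({"N": nn, "CA": ca, "C": cc})
    for i in range(n):
        at = dict(ncac[i])
        if i + 1 < n:
            # carbonyl O in the peptide plane, anti to the next N
            at["O"] = place_atom(ncac[i + 1]["N"], at["CA"], at["C"],
                                 _BOND_C_O, _ANG_CA_C_O, 180.0)
        else:
            at["O"] = place_atom(at["N"], at["CA"], at["C"],
                                 _BOND_C_O, _ANG_CA_C_O, 0.0)
        coords.append(at)

    if spec.mode == "perturbed":
        rng = np.random.default_rng(spec.seed)
        for at in coords:
            for name in at:
                at[name] = at[name] + rng.normal(0.0, spec.noise_sigma, 3)

    residues = []
    for i, (aa, at) in enumerate(zip(seq, coords)):
        atoms = {
            name: AtomCoord(element=name[0], name=name, position=p)
            for name, p in at.items()
        }
        residues.append(ResidueBackbone(index=i, aa=aa, atoms=atoms, chain="A", resseq=i + 1))
    # CB from ideal geometry (chi-independent first atom of every side chain)
    for res in residues:
        if res.aa != "GLY":
            conf = build_side_chain(res, [-60.0] * CHI_COUNT[res.aa])
            res.atoms["CB"] = next(a for a in conf.atoms if a.name == "CB")

    residues = annotate_backbone_dihedrals(residues)
    pdb_text = write_structure(residues, {})
    return pdb_text, residues


_CANONICAL_CHI = (-60.0, 60.0, 180.0)


def make_library(
    aas: Sequence[str],
    bins: Sequence[Tuple[float, float]] = ((-60.0, -40.0),),
    rotamers_per_bin: int = 3,
    concentration: float = 5.0,
    seed: int = 0,
    chi_jitter: float = 8.0,
) -> str:
    """Generate Dunbrack-style (2002 dialect) library text.

    Per (aa, φ-bin, ψ-bin): ``rotamers_per_bin`` records with Dirichlet
    (symmetric, given concentration) priors sorted descending and χ means
    near canonical gauche±/trans values with Gaussian jitter.
    """
    if rotamers_per_bin < 1:
        raise ValueError("need at least one rotamer per bin")
    rng = np.random.default_rng(seed)
    lines = ["# synthetic backbone-dependent rotamer library"]
    for aa in aas:
        aa = aa.upper()
        n_chi = CHI_COUNT[aa]
        if n_chi == 0:
            continue
        for phi, psi in bins:
            probs = rng.dirichlet([concentration] * rotamers_per_bin)
            probs = np.sort(probs)[::-1]
            probs = probs / probs.sum()
            # χ1 classes drawn without replacement so candidates stay distinct
            chi1_classes = rng.permutation(len(_CANONICAL_CHI)).tolist()
            for k in range(rotamers_per_bin):
                chis, rid = [], []
                for c in range(4):
                    if c >= n_chi:
                        chis.append(0.0)
                        rid.append(0)
                        continue
                    if c == 0:
                        cls = chi1_classes[k % len(_CANONICAL_CHI)]
                    else:
                        cls = int(rng.integers(0, len(_CANONICAL_CHI)))
                    rid.append(cls + 1)
                    chis.append(
                        float(_CANONICAL_CHI[cls] + rng.normal(0.0, chi_jitter))
                    )
                sig = [10.0 if c < n_chi else 0.0 for c in range(4)]
                inter = "  ".join(
                    f"{c:8.1f} {s:6.1f}" for c, s in zip(chis, sig)
                )
                rid_s = " ".join(str(x) for x in rid)
                lines.append(
                    f"{aa:<4s} {phi:6.0f} {psi:6.0f}  1  {rid_s}  "
                    f"{probs[k]:.6f}  {inter}"
                )
    if len(lines) == 1:
        raise ValueError("no chi-bearing amino acids requested")
    return "\n".join(lines) + "\n"


def make_toy_mrf(
    n_vertices: int,
    topology: str = "chain",
    states: int = 3,
    seed: int = 0,
) -> MarkovRandomField:
    """Random small MRF with i.i.d. standard-normal log-potentials.

    Topologies: chain, tree (random), cycle, complete.  Sized for the exact
    enumeration oracle.
    """
    rng = np.random.default_rng(seed)
    if topology == "chain":
        edges = [(i, i + 1) for i in range(n_vertices - 1)]
    elif topology == "cycle":
        edges = [(i, (i + 1) % n_vertices) for i in range(n_vertices)]
    elif topology == "complete":
        edges = [(i, j) for i in range(n_vertices) for j in range(i + 1, n_vertices)]
    elif topology == "tree":
        edges = [(int(rng.integers(0, i)), i) for i in range(1, n_vertices)]
    else:
        raise ValueError(f"unknown topology {topology!r}")
    edges = [tuple(sorted(e)) for e in edges if e[0] != e[1]]
    graph = InteractionGraph(
        vertices=list(range(n_vertices)),
        edges={frozenset(e) for e in edges},
        candidates={
            i: [RotamerRecord("SER", (k + 1, 0, 0, 0), 1.0 / states, (0.0,))
                for k in range(states)]
            for i in range(n_vertices)
        },
    )
    vertex_potentials = {
        i: np.exp(rng.standard_normal(states)) for i in range(n_vertices)
    }
    edge_potentials = {
        e: np.exp(rng.standard_normal((states, states))) for e in sorted(set(edges))
    }
    return MarkovRandomField(graph, vertex_potentials, edge_potentials)


@dataclass
class GroundTruthBundle:
    """A backbone, a library, and a full-atom truth with known rotamers."""

    backbone_pdb: str
    truth_pdb: str
    library_text: str
    residues: List[ResidueBackbone]
    library: RotamerLibrary
    true_rotamer_index: Dict[int, int]
    true_chis: Dict[int, List[float]]


def make_ground_truth_bundle(
    n_residues: int = 12,
    sequence: Optional[Sequence[str]] = None,
    mode: str = "helix",
    truth_choice: str = "top",
    seed: int = 0,
    rotamers_per_bin: int = 3,
    params: Optional[EnergyParams] = None,
) -> GroundTruthBundle:
    """Backbone + library + truth structure whose side chains sit on library rotamers.

    ``truth_choice``: "top" places every residue at its most probable
    rotamer (so the input library's top-1 prediction is 100% correct by
    construction); "min_energy" places each residue at the candidate with
    the lowest backbone-clash vertex energy (ties to the higher prior),
    giving a physically consistent truth that clash-aware inference can
    recover.
    """
    from .interaction_graph import build_graph  # cycle-free local import

    if sequence is None:
        rng = np.random.default_rng(seed + 1)
        pool = ["SER", "CYS", "VAL", "THR"]
        sequence = [pool[int(rng.integers(0, len(pool)))] for _ in range(n_residues)]
    spec = FixtureSpec(n_residues=n_residues, sequence=sequence, mode=mode, seed=seed)
    backbone_pdb, residues = make_backbone(spec)
    lib_text = make_library(
        sorted(set(sequence)),
        bins=((-60.0, -40.0), (-139.0, 135.0)),
        rotamers_per_bin=rotamers_per_bin,
        seed=seed,
    )
    lib = parse_library(lib_text)
    graph = build_graph(residues, lib=lib)
    params = params or EnergyParams()

    true_idx: Dict[int, int] = {}
    assignments: Dict[int, SideChainConformation] = {}
    true_chis: Dict[int, List[float]] = {}
    for res in residues:
        cands = graph.candidates[res.index]
        if truth_choice == "top":
            k = 0
        elif truth_choice == "min_energy":
            energies = [
                vertex_energy(res.index, rot, residues, graph, params)
                for rot in cands
            ]
            k = int(np.argmin(energies))
        else:
            raise ValueError(f"unknown truth_choice {truth_choice!r}")
        true_idx[res.index] = k
        chi = list(cands[k].chi_means)
        true_chis[res.index] = chi
        if CHI_COUNT[res.aa] > 0:
            assignments[res.index] = build_side_chain(res, chi)
    truth_pdb = write_structure(residues, assignments)
    return GroundTruthBundle(
        backbone_pdb=backbone_pdb,
        truth_pdb=truth_pdb,
        library_text=lib_text,
        residues=residues,
        library=lib,
        true_rotamer_index=true_idx,
        true_chis=true_chis,
    )
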