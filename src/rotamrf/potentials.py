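"""Vertex and edge energies and their Boltzmann potentials.

The energy model is the SCWRL-style repulsive-only scheme: a piecewise
linear approximation of the repulsive part of the Lennard-Jones 12-6
potential between heavy-atom pairs, a log-prior term k_d·ln(p_max/p) that
favours well-populated rotamers, and an optional simplified side-chain
hydrogen-bond reward.  Energies are turned into strictly positive MRF
potentials via exp(−E/k_BT); per-vertex/per-edge energies are shifted by
their minimum before exponentiation (a pure rescaling — marginals are
invariant) so large clash energies cannot underflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .interaction_graph import InteractionGraph
from .rotamer_library import RotamerRecord, floored_probability
from .structure_io import ResidueBackbone, SideChainConformation, build_side_chain

BACKBONE_FRAME_ATOMS = ("N", "CA", "C", "O", "CB")  # CB as pseudo-backbone


def _default_radii() -> Dict[str, float]:
    text = resources.files("rotamrf.data").joinpath("atom_radii.tsv").read_text()
    radii = {}
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        el, r = line.split("\t")
        radii[el] = float(r)
    return radii


@dataclass
class HBondParams:
    """Simplified side-chain hydrogen-bond term.

    A Gaussian distance well of depth ``weight`` (kcal/mol, negative =
    favourable) around ``distance_opt`` between side-chain donor and
    acceptor heavy atoms, gated by a minimum angle at the donor between its
    covalent antecedent and the acceptor.
    """

    enabled: bool = True
    weight: float = -2.0
    distance_opt: float = 2.8
    distance_width: float = 0.3
    angle_min: float = 90.0


@dataclass
class EnergyParams:
    """All tunable constants of the energy model (defaults as published)."""

    kBT: float = 0.6          # kcal/mol
    k_d: float = 3.0          # log-prior scale
    E_max: float = 10.0       # clash saturation
    k_sc: float = 0.8254      # ramp onset as a fraction of r_a + r_b
    contact_threshold: float = 10.0  # Å, interaction-graph rule
    clash_enabled: bool = True
    radius_table: Dict[str, float] = field(default_factory=_default_radii)
    hbond: HBondParams = field(default_factory=HBondParams)

    def __post_init__(self):
        if self.kBT <= 0 or self.E_max <= 0 or not (0 < self.k_sc < 1):
            raise ValueError("invalid energy parameters")
        if any(r <= 0 for r in self.radius_table.values()):
            raise ValueError("interaction radii must be positive")

    def radius(self, element: str) -> float:
        return self.radius_table[element.upper()]


@dataclass
class MarkovRandomField:
    """Per-vertex potential vectors and per-edge potential matrices."""

    graph: InteractionGraph
    vertex_potentials: Dict[int, np.ndarray]
    edge_potentials: Dict[Tuple[int, int], np.ndarray]  # keyed by sorted pair

    def n_states(self, i: int) -> int:
        return len(self.vertex_potentials[i])

    def edge_matrix(self, i: int, j: int) -> np.ndarray:
        """Potential matrix indexed (state_i, state_j) for any orientation."""
        if i < j:
            return self.edge_potentials[(i, j)]
        return self.edge_potentials[(j, i)].T


# ---------------------------------------------------------------------------
# atomic energies


def atom_pair_energy(d: float, r_a: float, r_b: float, params: EnergyParams) -> float:
    """Piecewise repulsive energy between two atoms at distance ``d``.

    0 for d ≥ r_ab, E_max for d ≤ k_sc·r_ab, linear in between
    (r_ab = r_a + r_b).  Continuous and non-increasing in d.
    """
    r_ab = r_a + r_b
    lo = params.k_sc * r_ab
    if d >= r_ab:
        return 0.0
    if d <= lo:
        return params.E_max
    return params.E_max * (r_ab - d) / (r_ab - lo)


def _pairwise_clash(atoms_a: Sequence, atoms_b: Sequence, params: EnergyParams) -> float:
    if not atoms_a or not atoms_b:
        return 0.0
    pa = np.stack([a.position for a in atoms_a])
    pb = np.stack([b.position for b in atoms_b])
    ra = np.array([params.radius(a.element) for a in atoms_a])
    rb = np.array([params.radius(b.element) for b in atoms_b])
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
    r_ab = ra[:, None] + rb[None, :]
    lo = params.k_sc * r_ab
    ramp = params.E_max * (r_ab - d) / (r_ab - lo)
    e = np.where(d >= r_ab, 0.0, np.where(d <= lo, params.E_max, ramp))
    return float(e.sum())


# hydrogen-bond donors/acceptors among side-chain heavy atoms, with the
# donor's covalent antecedent (for the angle gate)
_HB_DONORS: Dict[str, List[Tuple[str, str]]] = {
    "SER": [("OG", "CB")], "THR": [("OG1", "CB")], "TYR": [("OH", "CZ")],
    "CYS": [("SG", "CB")], "ASN": [("ND2", "CG")], "GLN": [("NE2", "CD")],
    "LYS": [("NZ", "CE")], "TRP": [("NE1", "CD1")],
    "ARG": [("NE", "CD"), ("NH1", "CZ"), ("NH2", "CZ")],
    "HIS": [("ND1", "CG"), ("NE2", "CD2")],
}
_HB_ACCEPTORS: Dict[str, List[str]] = {
    "ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"], "ASN": ["OD1"],
    "GLN": ["OE1"], "SER": ["OG"], "THR": ["OG1"], "TYR": ["OH"],
    "HIS": ["ND1", "NE2"], "MET": ["SD"],
}


def hbond_energy(
    donor_res: ResidueBackbone,
    acceptor_res: ResidueBackbone,
    conf_donor: SideChainConformation,
    conf_acceptor: SideChainConformation,
    params: HBondParams,
) -> float:
    """Side-chain-mediated hydrogen-bond energy (≤ 0) between two residues.

    Sums, over eligible donor/acceptor heavy-atom pairs, a Gaussian distance
    well around ``distance_opt`` gated by the antecedent–donor–acceptor
    angle.  Returns 0 when disabled or when no pair is in range.
    """
    if not params.enabled:
        return 0.0
    donors = _HB_DONORS.get(donor_res.aa, [])
    acceptors = _HB_ACCEPTORS.get(acceptor_res.aa, [])
    if not donors or not acceptors:
        return 0.0
    dpos = {a.name: a.position for a in conf_donor.atoms}
    apos = {a.name: a.position for a in conf_acceptor.atoms}
    total = 0.0
    for dname, antecedent in donors:
        if dname not in dpos or antecedent not in dpos:
            continue
        d_at, ant = dpos[dname], dpos[antecedent]
        for aname in acceptors:
            if aname not in apos:
                continue
            acc = apos[aname]
            dist = float(np.linalg.norm(acc - d_at))
            if dist < 1e-6 or dist > params.distance_opt + 4 * params.distance_width:
                continue
            v1, v2 = ant - d_at, acc - d_at
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            angle = math.degrees(math.acos(float(np.clip(cosang, -1.0, 1.0))))
            if angle < params.angle_min:
                continue
            total += params.weight * math.exp(
                -((dist - params.distance_opt) ** 2) / (2 * params.distance_width**2)
            )
    return total


# ---------------------------------------------------------------------------
# vertex / edge energies


def prior_energy(rot: RotamerRecord, p_max: float, params: EnergyParams) -> float:
    """k_d·ln(p_max/p): 0 for the most probable rotamer, grows as p falls."""
    return params.k_d * math.log(
        floored_probability(p_max) / floored_probability(rot.probability)
    )


def vertex_energy(
    i: int,
    rot: RotamerRecord,
    residues: Sequence[ResidueBackbone],
    graph: InteractionGraph,
    params: EnergyParams,
    conf: Optional[SideChainConformation] = None,
) -> float:
    """Prior term plus side-chain/backbone clash sum for rotamer ``rot`` at ``i``.

    The clash sum runs over the rotamer's side-chain atoms against the
    N/CA/C/O/CB frame atoms of every neighbouring residue in the graph.
    """
    cands = graph.candidates[i]
    p_max = cands[0].probability if cands else 1.0
    e = prior_energy(rot, p_max, params)
    if not params.clash_enabled:
        return e
    if conf is None:
        conf = build_side_chain(residues[i], list(rot.chi_means))
    for j in graph.neighbors(i):
        frame = [residues[j].atoms[n] for n in BACKBONE_FRAME_ATOMS
                 if n in residues[j].atoms]
        e += _pairwise_clash(conf.atoms, frame, params)
    return e


def edge_energy(
    i: int,
    j: int,
    rot_i: RotamerRecord,
    rot_j: RotamerRecord,
    residues: Sequence[ResidueBackbone],
    params: EnergyParams,
    conf_i: Optional[SideChainConformation] = None,
    conf_j: Optional[SideChainConformation] = None,
) -> float:
    """Side-chain/side-chain clash sum plus the hydrogen-bond term."""
    if conf_i is None:
        conf_i = build_side_chain(residues[i], list(rot_i.chi_means))
    if conf_j is None:
        conf_j = build_side_chain(residues[j], list(rot_j.chi_means))
    e = _pairwise_clash(conf_i.atoms, conf_j.atoms, params) if params.clash_enabled else 0.0
    if params.hbond.enabled:
        e += hbond_energy(residues[i], residues[j], conf_i, conf_j, params.hbond)
        e += hbond_energy(residues[j], residues[i], conf_j, conf_i, params.hbond)
    return e


def boltzmann_potential(E, kBT: float):
    """exp(−E/k_BT), elementwise on arrays."""
    return np.exp(-np.asarray(E, dtype=float) / kBT)


def assemble_mrf(
    residues: Sequence[ResidueBackbone],
    graph: InteractionGraph,
    params: Optional[EnergyParams] = None,
) -> MarkovRandomField:
    """Evaluate all energies and exponentiate into an MRF.

    Side chains for every candidate rotamer are built once and reused across
    the vertex and edge terms.  Each energy block is shifted by its minimum
    before exp (overflow safety; marginals unchanged).
    """
    params = params or EnergyParams()
    confs: Dict[int, List[SideChainConformation]] = {}
    for res in residues:
        confs[res.index] = [
            build_side_chain(res, list(r.chi_means)) for r in graph.candidates[res.index]
        ]

    vertex_potentials: Dict[int, np.ndarray] = {}
    for res in residues:
        i = res.index
        e = np.array([
            vertex_energy(i, rot, residues, graph, params, conf)
            for rot, conf in zip(graph.candidates[i], confs[i])
        ])
        vertex_potentials[i] = boltzmann_potential(e - e.min(), params.kBT)

    edge_potentials: Dict[Tuple[int, int], np.ndarray] = {}
    for i, j in graph.edge_list():
        mat = np.array([
            [
                edge_energy(i, j, ri, rj, residues, params, ci, cj)
                for rj, cj in zip(graph.candidates[j], confs[j])
            ]
            for ri, ci in zip(graph.candidates[i], confs[i])
        ])
        edge_potentials[(i, j)] = boltzmann_potential(mat - mat.min(), params.kBT)
    return MarkovRandomField(graph, vertex_potentials, edge_potentials)


def params_with(params: EnergyParams, **overrides) -> EnergyParams:
    """Copy ``params`` with field overrides (hbond fields via hbond=...)."""
    return replace(params, **overrides)
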