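"""Structure I/O and chemical perception.

Reads and writes PDB files (MODEL-aware, so a multi-model file becomes a
trajectory), perceives covalent bonds from a covalent-radius table,
identifies the ligand-like molecule, defines the binding site and counts
rotatable bonds.  Coordinates are in Å, partial charges in elementary
charges, frame times in ns.

CONECT records are ignored on input: connectivity is always re-perceived
from geometry, which keeps generated and experimental structures on the
same footing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .errors import (
    EmptyInputError,
    FormatError,
    InconsistentTrajectoryError,
    NoLigandError,
    ParameterMissingError,
    PreconditionError,
)

# Classic (Pauling-style) single-bond covalent radii, Å.
COVALENT_RADII: dict[str, float] = {
    "H": 0.37, "C": 0.77, "N": 0.75, "O": 0.73, "F": 0.71,
    "P": 1.06, "S": 1.02, "CL": 0.99, "BR": 1.14, "I": 1.33,
    "NA": 1.54, "K": 1.96, "MG": 1.30, "CA": 1.74, "ZN": 1.25, "FE": 1.17,
}

# Pauling electronegativities for the fallback charge assigner.
ELECTRONEGATIVITY: dict[str, float] = {
    "H": 2.20, "C": 2.55, "N": 3.04, "O": 3.44, "F": 3.98,
    "P": 2.19, "S": 2.58, "CL": 3.16, "BR": 2.96, "I": 2.66,
}

WATER_RESNAMES = {"HOH", "WAT", "TIP", "TIP3", "TIP4", "SOL"}

DEFAULT_BOND_SLACK = 0.45  # Å added to the sum of covalent radii


@dataclass(frozen=True)
class Atom:
    """A single atom; a convenience view into :class:`MolecularSystem` arrays."""

    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_seq: int
    insertion_code: str
    position: np.ndarray
    partial_charge: float
    is_hetero: bool


class MolecularSystem:
    """Atoms, perceived bonds and residue grouping for one structure.

    Per-atom fields are stored as parallel arrays; ``bonds`` is a set of
    unordered index pairs and is empty until :func:`perceive_bonds` runs.
    """

    def __init__(self, serials, names, elements, residue_names, chain_ids,
                 residue_seqs, insertion_codes, coords, charges=None,
                 is_hetero=None, bonds=None):
        n = len(serials)
        self.serials = np.asarray(serials, dtype=int)
        self.names = list(names)
        self.elements = [e.upper() for e in elements]
        self.residue_names = list(residue_names)
        self.chain_ids = list(chain_ids)
        self.residue_seqs = np.asarray(residue_seqs, dtype=int)
        self.insertion_codes = list(insertion_codes)
        self.coords = np.asarray(coords, dtype=float).reshape(n, 3)
        self.charges = (np.zeros(n) if charges is None
                        else np.asarray(charges, dtype=float))
        self.is_hetero = (np.zeros(n, dtype=bool) if is_hetero is None
                          else np.asarray(is_hetero, dtype=bool))
        self.bonds: set[tuple[int, int]] = set(bonds) if bonds else set()
        if not np.all(np.isfinite(self.coords)):
            raise PreconditionError("non-finite coordinates")
        if not np.all(np.isfinite(self.charges)):
            raise PreconditionError("non-finite partial charges")

    def __len__(self) -> int:
        return len(self.serials)

    @property
    def n_atoms(self) -> int:
        return len(self.serials)

    def atom(self, i: int) -> Atom:
        return Atom(
            serial=int(self.serials[i]), name=self.names[i],
            element=self.elements[i], residue_name=self.residue_names[i],
            chain_id=self.chain_ids[i], residue_seq=int(self.residue_seqs[i]),
            insertion_code=self.insertion_codes[i],
            position=self.coords[i].copy(),
            partial_charge=float(self.charges[i]),
            is_hetero=bool(self.is_hetero[i]),
        )

    def residue_key(self, i: int) -> tuple[str, int, str, str]:
        """Identity of the residue owning atom *i*: (chain, seq, icode, name)."""
        return (self.chain_ids[i], int(self.residue_seqs[i]),
                self.insertion_codes[i], self.residue_names[i])

    def residues(self) -> list[tuple[tuple, np.ndarray]]:
        """Residues in first-appearance order as (key, atom index array)."""
        order: dict[tuple, list[int]] = {}
        for i in range(self.n_atoms):
            order.setdefault(self.residue_key(i), []).append(i)
        return [(k, np.asarray(v, dtype=int)) for k, v in order.items()]

    def bond_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from(self.bonds)
        return g

    def with_coords(self, coords: np.ndarray) -> "MolecularSystem":
        """Shallow copy sharing identity/bond data but with new coordinates."""
        return MolecularSystem(
            self.serials, self.names, self.elements, self.residue_names,
            self.chain_ids, self.residue_seqs, self.insertion_codes,
            coords, self.charges, self.is_hetero, self.bonds)

    def subset(self, indices) -> "MolecularSystem":
        """New system restricted to ``indices``; bonds re-indexed."""
        indices = np.asarray(indices, dtype=int)
        remap = {int(old): new for new, old in enumerate(indices)}
        bonds = {tuple(sorted((remap[i], remap[j])))
                 for i, j in self.bonds if i in remap and j in remap}
        return MolecularSystem(
            self.serials[indices], [self.names[i] for i in indices],
            [self.elements[i] for i in indices],
            [self.residue_names[i] for i in indices],
            [self.chain_ids[i] for i in indices],
            self.residue_seqs[indices],
            [self.insertion_codes[i] for i in indices],
            self.coords[indices], self.charges[indices],
            self.is_hetero[indices], bonds)


@dataclass
class Trajectory:
    """Ordered frames sharing one topology.

    ``topology`` carries atom identity/charges/bonds; ``coords`` has shape
    (n_frames, n_atoms, 3); ``times`` is in ns and strictly increasing.
    """

    topology: MolecularSystem
    coords: np.ndarray
    times: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1] != self.topology.n_atoms:
            raise InconsistentTrajectoryError(
                "coordinate array does not match topology atom count")
        if len(self.times) != len(self.coords):
            raise InconsistentTrajectoryError("len(times) != n_frames")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise PreconditionError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.coords)

    def frame(self, i: int) -> MolecularSystem:
        return self.topology.with_coords(self.coords[i])


@dataclass(frozen=True)
class LigandSelection:
    """Atom indices (into one MolecularSystem) forming the ligand."""

    atom_indices: tuple[int, ...]

    def __post_init__(self):
        if len(self.atom_indices) == 0:
            raise PreconditionError("empty ligand selection")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.atom_indices, dtype=int)


# ---------------------------------------------------------------------------
# PDB I/O


def read_charge_table(path) -> dict[int, float]:
    """Read a sidecar charge CSV with header ``serial,charge_e``."""
    df = pd.read_csv(path)
    if not {"serial", "charge_e"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns serial,charge_e")
    return {int(s): float(q) for s, q in zip(df["serial"], df["charge_e"])}


def read_pdb(path, multi_model: bool = True, charges=None,
             snapshot_interval_ns: float = 0.1) -> Trajectory:
    """Read a (possibly multi-MODEL) PDB file into a :class:`Trajectory`.

    Parameters
    ----------
    charges : None | "occupancy" | path
        Source of partial charges: all-zero (None), the occupancy column,
        or a sidecar CSV mapping serial to charge.
    snapshot_interval_ns : float
        Spacing of frame time stamps (0-based) when the file holds several
        MODEL blocks.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure("sys", str(path))
    except PDBConstructionException as exc:
        raise FormatError(f"{path}: {exc}") from exc

    frames = []
    occupancies = []
    identity = None
    for model in structure:
        serials, names, elements, resnames = [], [], [], []
        chains, resseqs, icodes, coords, hetero, occ = [], [], [], [], [], []
        for chain in model:
            for residue in chain:
                hetfield, resseq, icode = residue.id
                for atom in residue:
                    serials.append(atom.serial_number)
                    names.append(atom.get_name())
                    elements.append(atom.element or atom.get_name()[0])
                    resnames.append(residue.get_resname().strip())
                    chains.append(chain.id)
                    resseqs.append(resseq)
                    icodes.append(icode.strip())
                    coords.append(atom.coord)
                    hetero.append(hetfield.strip() != "")
                    occ.append(atom.get_occupancy() or 0.0)
        if not serials:
            continue
        frame_id = (tuple(names), tuple(resnames), tuple(chains),
                    tuple(resseqs))
        if identity is None:
            identity = frame_id
        elif frame_id != identity:
            raise InconsistentTrajectoryError(
                f"{path}: MODEL blocks differ in atom identity")
        frames.append((serials, names, elements, resnames, chains, resseqs,
                       icodes, np.array(coords, dtype=float)))
        occupancies.append(np.array(occ))
        if not multi_model:
            break

    if not frames:
        raise EmptyInputError(f"{path}: no ATOM or HETATM records")

    s0 = frames[0]
    charge_arr = np.zeros(len(s0[0]))
    if charges == "occupancy":
        charge_arr = occupancies[0]
    elif charges is not None:
        table = read_charge_table(charges)
        charge_arr = np.array([table.get(int(s), 0.0) for s in s0[0]])

    hetero0 = [False] * len(s0[0])
    # recover hetero flags from the first model (Bio.PDB keeps them per residue)
    idx = 0
    for chain in next(iter(structure)):
        for residue in chain:
            het = residue.id[0].strip() != ""
            for _ in residue:
                hetero0[idx] = het
                idx += 1

    topo = MolecularSystem(
        serials=s0[0], names=s0[1], elements=s0[2], residue_names=s0[3],
        chain_ids=s0[4], residue_seqs=s0[5], insertion_codes=s0[6],
        coords=s0[7], charges=charge_arr, is_hetero=hetero0)
    coords = np.stack([f[7] for f in frames])
    times = np.arange(len(frames)) * snapshot_interval_ns
    return Trajectory(topology=topo, coords=coords, times=times)


def _pdb_atom_line(record: str, serial: int, name: str, resname: str,
                   chain: str, resseq: int, icode: str, xyz, occ: float,
                   element: str) -> str:
    if len(name) < 4 and len(element) == 1:
        name_field = f" {name:<3s}"
    else:
        name_field = f"{name:<4s}"
    return (f"{record:<6s}{serial:>5d} {name_field} {resname:>3s} "
            f"{chain:1s}{resseq:>4d}{icode or ' ':1s}   "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occ:6.2f}{0.0:6.2f}"
            f"          {element.rjust(2)[:2]}")


def write_pdb(obj, path, charges_in_occupancy: bool = False) -> None:
    """Write a MolecularSystem or Trajectory as a (multi-MODEL) PDB file."""
    if isinstance(obj, MolecularSystem):
        traj = Trajectory(obj, obj.coords[None, :, :], np.array([0.0]))
    else:
        traj = obj
    sys_ = traj.topology
    lines = []
    multi = traj.n_frames > 1
    for f in range(traj.n_frames):
        if multi:
            lines.append(f"MODEL     {f + 1:>4d}")
        for i in range(sys_.n_atoms):
            record = "HETATM" if sys_.is_hetero[i] else "ATOM"
            occ = float(sys_.charges[i]) if charges_in_occupancy else 1.0
            lines.append(_pdb_atom_line(
                record, int(sys_.serials[i]), sys_.names[i],
                sys_.residue_names[i], sys_.chain_ids[i],
                int(sys_.residue_seqs[i]), sys_.insertion_codes[i],
                traj.coords[f, i], occ, sys_.elements[i]))
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_charge_table(system: MolecularSystem, path) -> None:
    pd.DataFrame({"serial": system.serials,
                  "charge_e": system.charges}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Perception


def perceive_bonds(system: MolecularSystem,
                   slack: float = DEFAULT_BOND_SLACK) -> MolecularSystem:
    """Assign bonds: (i, j) bonded iff d(i, j) <= r_cov(i) + r_cov(j) + slack.

    H–H pairs are never bonded.  Returns the same system with ``bonds`` set.
    """
    radii = np.empty(system.n_atoms)
    for i, el in enumerate(system.elements):
        if el not in COVALENT_RADII:
            raise ParameterMissingError(f"no covalent radius for element {el!r}")
        radii[i] = COVALENT_RADII[el]
    bonds: set[tuple[int, int]] = set()
    if system.n_atoms > 1:
        tree = cKDTree(system.coords)
        rmax = 2 * radii.max() + slack
        for i, j in tree.query_pairs(rmax):
            if system.elements[i] == "H" and system.elements[j] == "H":
                continue
            d = np.linalg.norm(system.coords[i] - system.coords[j])
            if d <= radii[i] + radii[j] + slack:
                bonds.add((min(i, j), max(i, j)))
    system.bonds = bonds
    return system


def detect_ligand(system: MolecularSystem) -> LigandSelection:
    """Largest connected hetero component, excluding waters and ions.

    Ties broken toward the component containing the lowest atom serial.
    Raises :class:`NoLigandError` when no candidate exists (apo structure).
    """
    residue_sizes: dict[tuple, int] = {}
    for key, idx in system.residues():
        residue_sizes[key] = len(idx)
    candidate = np.zeros(system.n_atoms, dtype=bool)
    for i in range(system.n_atoms):
        if not system.is_hetero[i]:
            continue
        key = system.residue_key(i)
        if key[3].upper() in WATER_RESNAMES:
            continue
        if residue_sizes[key] == 1:  # single-atom residue = ion
            continue
        candidate[i] = True
    if not candidate.any():
        raise NoLigandError("no ligand-like hetero molecule found")
    g = system.bond_graph().subgraph(np.flatnonzero(candidate))
    components = [sorted(c) for c in nx.connected_components(g)]
    if not components:
        raise NoLigandError("no ligand-like hetero molecule found")
    best = min(components,
               key=lambda c: (-len(c), min(int(system.serials[i]) for i in c)))
    return LigandSelection(atom_indices=tuple(int(i) for i in best))


def binding_site(system: MolecularSystem, ligand: LigandSelection,
                 cutoff: float = 8.0) -> list[tuple]:
    """Residue keys with any atom within ``cutoff`` Å of any ligand atom.

    The ligand's own residue(s) are excluded; result ordered by chain then
    sequence number then insertion code.
    """
    if cutoff <= 0:
        raise PreconditionError("cutoff must be positive")
    lig_idx = ligand.as_array()
    lig_keys = {system.residue_key(i) for i in lig_idx}
    d = cdist(system.coords, system.coords[lig_idx]).min(axis=1)
    hits = []
    for key, idx in system.residues():
        if key in lig_keys:
            continue
        if d[idx].min() <= cutoff:
            hits.append(key)
    return sorted(hits, key=lambda k: (k[0], k[1], k[2]))


def _is_amide_cn(system: MolecularSystem, g: nx.Graph, i: int, j: int) -> bool:
    """Heuristic amide C–N: the carbon carries a terminal oxygen."""
    if {system.elements[i], system.elements[j]} != {"C", "N"}:
        return False
    c = i if system.elements[i] == "C" else j
    for nb in g.neighbors(c):
        if system.elements[nb] == "O":
            heavy_nbs = [x for x in g.neighbors(nb) if system.elements[x] != "H"]
            if heavy_nbs == [c]:
                return True
    return False


def count_rotatable_bonds(mol: MolecularSystem) -> int:
    """Acyclic heavy–heavy single bonds with >=1 extra heavy neighbour on
    each end; amide C–N bonds excluded."""
    g = mol.bond_graph()
    bridges = set(frozenset(b) for b in nx.bridges(g))
    heavy = [el != "H" for el in mol.elements]
    n = 0
    for i, j in mol.bonds:
        if not (heavy[i] and heavy[j]):
            continue
        if frozenset((i, j)) not in bridges:  # in a ring
            continue
        hi = sum(1 for x in g.neighbors(i) if heavy[x] and x != j)
        hj = sum(1 for x in g.neighbors(j) if heavy[x] and x != i)
        if hi < 1 or hj < 1:
            continue
        if _is_amide_cn(mol, g, i, j):
            continue
        n += 1
    return n


def assign_fallback_charges(system: MolecularSystem,
                            transfer: float = 0.2) -> MolecularSystem:
    """Electronegativity-difference charges: q_i = sum over bonds of
    ``transfer * (chi_i - chi_j) / chi_max``-style transfer.

    A crude single-pass Gasteiger-like fallback for structures arriving
    without a sidecar charge table; provenance should be logged by callers.
    """
    q = np.zeros(system.n_atoms)
    for i, j in system.bonds:
        ei, ej = system.elements[i], system.elements[j]
        chi_i = ELECTRONEGATIVITY.get(ei)
        chi_j = ELECTRONEGATIVITY.get(ej)
        if chi_i is None or chi_j is None:
            continue
        t = transfer * (chi_j - chi_i)
        q[i] += t
        q[j] -= t
    system.charges = q
    return system
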