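"""Nonbonded force-field terms.

Implements 12-6 Lennard-Jones van der Waals, Coulomb electrostatics with a
constant or distance-dependent dielectric, and a directional 10-12·cos²θ
hydrogen-bond term, plus the ligand–residue and ligand–protein interaction
energies built from them.  Per the source tooling's definition, the
per-residue interaction energy is the sum of vdW + electrostatic terms only;
the hydrogen-bond term enters only the whole-complex score.

Polarization and metal–ligand terms of the original directional force field
are not implemented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import ParameterMissingError, SingularityError
from .structio import LigandSelection, MolecularSystem

COULOMB_K = 332.06       # kcal·Å/(mol·e²)
GAS_CONSTANT = 0.0019872  # kcal/(mol·K)


@dataclass(frozen=True)
class AtomTypeParams:
    """Element-level nonbonded parameters."""

    sigma: float              # Å
    epsilon: float            # kcal/mol
    covalent_radius: float    # Å
    solvation_parameter: float  # kcal/(mol·Å²), atomic solvation parameter
    hbond_role: str = "none"  # none | donor-heavy | polar-H | acceptor


# Minimal element-keyed table (OPLS-like LJ, Eisenberg-style solvation).
ELEMENT_PARAMS: dict[str, AtomTypeParams] = {
    "H": AtomTypeParams(2.50, 0.030, 0.37, 0.000),
    "C": AtomTypeParams(3.50, 0.066, 0.77, 0.016),
    "N": AtomTypeParams(3.25, 0.170, 0.75, -0.006, "acceptor"),
    "O": AtomTypeParams(3.00, 0.210, 0.73, -0.006, "acceptor"),
    "S": AtomTypeParams(3.55, 0.250, 1.02, 0.021),
    "P": AtomTypeParams(3.74, 0.200, 1.06, 0.016),
    "F": AtomTypeParams(2.94, 0.061, 0.71, 0.012),
    "CL": AtomTypeParams(3.40, 0.300, 0.99, 0.012),
    "BR": AtomTypeParams(3.60, 0.470, 1.14, 0.012),
    "I": AtomTypeParams(3.80, 0.600, 1.33, 0.012),
}


def load_param_overrides(path) -> dict[str, AtomTypeParams]:
    """Merge a user CSV ``element,sigma,epsilon,solvation_parameter`` over
    the bundled table."""
    table = dict(ELEMENT_PARAMS)
    df = pd.read_csv(path)
    for _, row in df.iterrows():
        el = str(row["element"]).upper()
        base = table.get(el, AtomTypeParams(3.5, 0.1, 0.77, 0.0))
        table[el] = replace(base, sigma=float(row["sigma"]),
                            epsilon=float(row["epsilon"]),
                            solvation_parameter=float(row["solvation_parameter"]))
    return table


def params_for_element(element: str,
                       table: dict[str, AtomTypeParams] | None = None
                       ) -> AtomTypeParams:
    table = table or ELEMENT_PARAMS
    el = element.upper()
    if el not in table:
        raise ParameterMissingError(f"no nonbonded parameters for element {el!r}")
    return table[el]


@dataclass(frozen=True)
class NonbondedModel:
    """Settings shared by all nonbonded evaluations."""

    coulomb_constant: float = COULOMB_K
    dielectric_mode: str = "constant"  # constant | distance-dependent
    dielectric_value: float = 1.0
    cutoff: float = 12.0               # Å
    temperature: float = 300.0         # K
    gas_constant: float = GAS_CONSTANT
    hbond_epsilon: float = 2.0         # kcal/mol well depth
    hbond_sigma: float = 2.9           # Å donor–acceptor optimum
    hbond_distance_max: float = 3.5    # Å detection threshold
    param_table: tuple = ()            # optional ((element, AtomTypeParams), ...)

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.dielectric_value < 1:
            raise ValueError("dielectric_value must be >= 1")

    @property
    def rt(self) -> float:
        return self.gas_constant * self.temperature

    def params(self) -> dict[str, AtomTypeParams]:
        return dict(self.param_table) if self.param_table else ELEMENT_PARAMS


DEFAULT_MODEL = NonbondedModel()


def vdw_energy(params_i: AtomTypeParams, params_j: AtomTypeParams, r: float,
               cutoff: float = DEFAULT_MODEL.cutoff) -> float:
    """12-6 Lennard-Jones with arithmetic-mean σ, geometric-mean ε."""
    if r <= 0:
        raise SingularityError("vdw_energy at r <= 0")
    if r > cutoff:
        return 0.0
    sigma = 0.5 * (params_i.sigma + params_j.sigma)
    eps = math.sqrt(params_i.epsilon * params_j.epsilon)
    sr6 = (sigma / r) ** 6
    return 4.0 * eps * (sr6 * sr6 - sr6)


def elec_energy(q_i: float, q_j: float, r: float,
                model: NonbondedModel = DEFAULT_MODEL) -> float:
    """Coulomb energy; ε_eff is constant or ε·r (distance-dependent)."""
    if r <= 0:
        raise SingularityError("elec_energy at r <= 0")
    if r > model.cutoff:
        return 0.0
    eps_eff = model.dielectric_value
    if model.dielectric_mode == "distance-dependent":
        eps_eff *= r
    return model.coulomb_constant * q_i * q_j / (eps_eff * r)


def hbond_energy(r_da: float, theta_dha: float, eps_hb: float = 2.0,
                 sigma_hb: float = 2.9,
                 cutoff: float = DEFAULT_MODEL.cutoff) -> float:
    """Directional 10-12 hydrogen-bond term: ε[5(σ/r)¹² − 6(σ/r)¹⁰]·cos²θ.

    Zero for θ < 90° (angular gate) and beyond the cutoff; −ε at the
    optimum (r = σ, θ = 180°).
    """
    if r_da <= 0:
        raise SingularityError("hbond_energy at r <= 0")
    if theta_dha <= 90.0 or r_da > cutoff:
        return 0.0
    sr10 = (sigma_hb / r_da) ** 10
    sr12 = sr10 * (sigma_hb / r_da) ** 2
    return eps_hb * (5.0 * sr12 - 6.0 * sr10) * math.cos(
        math.radians(theta_dha)) ** 2


def _lj_arrays(system: MolecularSystem, indices: np.ndarray,
               table: dict[str, AtomTypeParams]):
    sig = np.empty(len(indices))
    eps = np.empty(len(indices))
    for k, i in enumerate(indices):
        p = params_for_element(system.elements[int(i)], table)
        sig[k] = p.sigma
        eps[k] = p.epsilon
    return sig, eps


def pairwise_nonbonded(system: MolecularSystem, idx_i, idx_j,
                       model: NonbondedModel = DEFAULT_MODEL) -> float:
    """Sum of vdW + electrostatic energies over the idx_i × idx_j pairs."""
    idx_i = np.asarray(idx_i, dtype=int)
    idx_j = np.asarray(idx_j, dtype=int)
    table = model.params()
    r = cdist(system.coords[idx_i], system.coords[idx_j])
    if np.any(r == 0):
        raise SingularityError("coincident atoms in nonbonded evaluation")
    sig_i, eps_i = _lj_arrays(system, idx_i, table)
    sig_j, eps_j = _lj_arrays(system, idx_j, table)
    sigma = 0.5 * (sig_i[:, None] + sig_j[None, :])
    eps = np.sqrt(eps_i[:, None] * eps_j[None, :])
    sr6 = (sigma / r) ** 6
    e_vdw = 4.0 * eps * (sr6 * sr6 - sr6)
    qq = system.charges[idx_i][:, None] * system.charges[idx_j][None, :]
    eps_eff = model.dielectric_value
    if model.dielectric_mode == "distance-dependent":
        eps_eff = eps_eff * r
    e_el = model.coulomb_constant * qq / (eps_eff * r)
    mask = r <= model.cutoff
    return float(((e_vdw + e_el) * mask).sum())


def residue_interaction(system: MolecularSystem, ligand_indices,
                        residue_indices,
                        model: NonbondedModel = DEFAULT_MODEL) -> float:
    """Ligand–residue interaction energy: vdW + electrostatics only."""
    return pairwise_nonbonded(system, ligand_indices, residue_indices, model)


def polar_hydrogens(system: MolecularSystem) -> list[tuple[int, int]]:
    """(heavy donor, H) pairs: hydrogens bonded to N or O."""
    out = []
    for i, j in sorted(system.bonds):
        ei, ej = system.elements[i], system.elements[j]
        if ei == "H" and ej in ("N", "O"):
            out.append((j, i))
        elif ej == "H" and ei in ("N", "O"):
            out.append((i, j))
    return out


def find_hbond_pairs(system: MolecularSystem, ligand: LigandSelection,
                     model: NonbondedModel = DEFAULT_MODEL
                     ) -> list[tuple[int, int, int]]:
    """Cross ligand/protein donor–H···acceptor triples within the detection
    distance and with θ(D–H···A) ≥ 90°."""
    lig = set(int(i) for i in ligand.atom_indices)
    acceptors = [i for i in range(system.n_atoms)
                 if system.elements[i] in ("N", "O")]
    triples = []
    for d, h in polar_hydrogens(system):
        for a in acceptors:
            if a in (d, h):
                continue
            if (d in lig) == (a in lig):  # must cross the interface
                continue
            r_da = float(np.linalg.norm(system.coords[d] - system.coords[a]))
            if r_da > model.hbond_distance_max:
                continue
            if dha_angle(system.coords[d], system.coords[h],
                         system.coords[a]) >= 90.0:
                triples.append((d, h, a))
    return triples


def dha_angle(d: np.ndarray, h: np.ndarray, a: np.ndarray) -> float:
    """Donor–hydrogen–acceptor angle in degrees."""
    v1 = d - h
    v2 = a - h
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def ligand_protein_energy(system: MolecularSystem, ligand: LigandSelection,
                          model: NonbondedModel = DEFAULT_MODEL) -> float:
    """Whole-complex score: Σ residue interactions + Σ directional H-bond
    terms over detected donor–acceptor pairs."""
    lig_idx = ligand.as_array()
    lig_keys = {system.residue_key(int(i)) for i in lig_idx}
    total = 0.0
    for key, idx in system.residues():
        if key in lig_keys:
            continue
        total += residue_interaction(system, lig_idx, idx, model)
    for d, h, a in find_hbond_pairs(system, ligand, model):
        r_da = float(np.linalg.norm(system.coords[d] - system.coords[a]))
        theta = dha_angle(system.coords[d], system.coords[h], system.coords[a])
        total += hbond_energy(r_da, theta, model.hbond_epsilon,
                              model.hbond_sigma, model.cutoff)
    return total
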