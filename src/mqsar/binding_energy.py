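"""Binding-free-energy decomposition.

ΔG_bind = E_interaction + E_strain + ΔG_desolvation + TΔS_rotors + E_induced_fit

with the convention that favourable terms are negative (the interaction
energy of a binder) and costs enter as positive numbers (strain,
desolvation, rotor-entropy loss, induced fit).  The affinity scale is
pIC50 = −ΔG / (ln 10 · R · T), treating IC50 as a proxy for Kd.

Desolvation uses a solvent-accessible-surface-area (SASA) continuum
surrogate: ΔG_desolv = Σ_atoms ASP(element) · SASA(atom), evaluated on the
designated reference (global-minimum) conformer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ParameterMissingError, PreconditionError
from .forcefield import (GAS_CONSTANT, NonbondedModel, DEFAULT_MODEL,
                         params_for_element)
from .structio import MolecularSystem

LN10 = math.log(10.0)

# Bondi-style van der Waals radii for SASA, Å.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98,
}


@dataclass(frozen=True)
class EnergyComponents:
    """The five decomposition terms, kcal/mol (costs positive)."""

    e_interaction: float = 0.0
    e_strain: float = 0.0
    dg_desolvation: float = 0.0
    tds_rotors: float = 0.0
    e_induced_fit: float = 0.0

    def __post_init__(self):
        if self.e_strain < 0:
            raise PreconditionError("strain energy must be >= 0")
        if self.tds_rotors < 0:
            raise PreconditionError("rotor entropy penalty must be >= 0")

    def total(self) -> float:
        return (self.e_interaction + self.e_strain + self.dg_desolvation
                + self.tds_rotors + self.e_induced_fit)


@dataclass(frozen=True)
class AffinityEstimate:
    delta_g: float      # kcal/mol
    pic50: float        # −log10 IC50 [M]
    uncertainty: float = 0.0  # pIC50 units


def pic50_from_delta_g(delta_g: float, temperature: float = 300.0) -> float:
    return -delta_g / (LN10 * GAS_CONSTANT * temperature)


def delta_g_from_pic50(pic50: float, temperature: float = 300.0) -> float:
    return -pic50 * LN10 * GAS_CONSTANT * temperature


def sasa(system: MolecularSystem, probe: float = 1.4, points: int = 960,
         radii: np.ndarray | None = None) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Shrake–Rupley), Å².

    ``radii`` overrides the bundled van der Waals radii per atom.
    """
    import biotite.structure as struc

    if probe < 0:
        raise PreconditionError("probe radius must be >= 0")
    if radii is None:
        radii = np.empty(system.n_atoms)
        for i, el in enumerate(system.elements):
            if el not in VDW_RADII:
                raise ParameterMissingError(f"no vdW radius for element {el!r}")
            radii[i] = VDW_RADII[el]
    else:
        radii = np.asarray(radii, dtype=float)
    arr = struc.AtomArray(system.n_atoms)
    arr.coord = np.asarray(system.coords, dtype=np.float32)
    arr.element = np.array(system.elements, dtype="U2")
    areas = struc.sasa(arr, probe_radius=probe, point_number=points,
                       vdw_radii=radii, ignore_ions=False)
    return np.nan_to_num(np.asarray(areas, dtype=float))


def desolvation_energy(system: MolecularSystem, probe: float = 1.4,
                       points: int = 960,
                       model: NonbondedModel = DEFAULT_MODEL) -> float:
    """Σ_atoms ASP(element) × SASA(atom) on the reference conformer."""
    areas = sasa(system, probe=probe, points=points)
    table = model.params()
    total = 0.0
    for i, el in enumerate(system.elements):
        total += params_for_element(el, table).solvation_parameter * areas[i]
    return total


def entropy_penalty(n_rotors: int, per_rotor: float = 0.4,
                    fraction_constrained: float = 1.0) -> float:
    """Rotor-entropy loss: n_rotors × fraction constrained × cost/rotor."""
    if n_rotors < 0 or per_rotor < 0:
        raise PreconditionError("n_rotors and per_rotor must be >= 0")
    if not 0.0 <= fraction_constrained <= 1.0:
        raise PreconditionError("fraction_constrained must lie in [0, 1]")
    return n_rotors * fraction_constrained * per_rotor


def strain_energy(pose_conf_energy: float, global_min_energy: float,
                  tolerance: float = 1e-6) -> float:
    """max(0, E_pose − E_min); warns when the pose undercuts the reference."""
    if pose_conf_energy < global_min_energy - tolerance:
        import warnings
        warnings.warn("pose energy below the designated global minimum; "
                      "inconsistent reference conformer", stacklevel=2)
    return max(0.0, pose_conf_energy - global_min_energy)


def pose_filter(conf_energies, window: float = 10.0) -> list[int]:
    """Indices of poses within ``window`` kcal/mol of the best pose."""
    energies = np.asarray(conf_energies, dtype=float)
    if energies.size == 0:
        raise PreconditionError("empty energy list")
    if window <= 0:
        raise PreconditionError("window must be positive")
    threshold = energies.min() + window
    return [int(i) for i in np.flatnonzero(energies <= threshold)]


def binding_free_energy(components: EnergyComponents,
                        model: NonbondedModel = DEFAULT_MODEL
                        ) -> AffinityEstimate:
    """Sum the decomposition and convert to the pIC50 scale."""
    dg = components.total()
    return AffinityEstimate(delta_g=dg,
                            pic50=pic50_from_delta_g(dg, model.temperature))
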