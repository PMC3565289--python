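"""Synthetic-data generators.

The experimental FimH structures behind the published surrogate model are
not public, so every input the other modules need is generated here with
known ground truth: a toy binding pocket (simplified residues on a sphere
around a small polar ligand), QSAR datasets whose affinities are computed
from a known surrogate model plus controllable Gaussian noise (Gaussian in
pIC50 space, i.e. log-normal in IC50), and scripted trajectories with
optional contact-loss events.  All generators are pure functions of
(parameters, seed), and each returns a manifest whose hash certifies
bitwise reproducibility.

A packaged transcription of the published 52-compound affinity table
(experimental/predicted pIC50 and residuals; structures undisclosed) is
exposed via :func:`load_table1_fixture`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .errors import FixtureCorruptionError, PreconditionError
from .forcefield import DEFAULT_MODEL, NonbondedModel
from .structio import (LigandSelection, MolecularSystem, Trajectory,
                       assign_fallback_charges, perceive_bonds)
from .surrogate_qsar import (GAConfig, ModelFamily, N_LABELS, PoseEnsemble,
                             QsarDataset, QsarEntry, SurrogateModel,
                             build_envelope, classify_atoms, model_predict)

TABLE1_SHA256 = \
    "0c889c549e389aed6a1599cf23ff854b090ab3398cb5223b50da07a8b0f7f03a"

MIN_CONTACT_DISTANCE = 2.2  # Å clash-free guarantee between fragments


@dataclass
class GeneratorManifest:
    """Bookkeeping emitted by every generator; hash certifies identity."""

    seed: int
    counts: dict = field(default_factory=dict)
    ground_truth: dict | None = None
    noise_sd: float = 0.0
    extras: dict = field(default_factory=dict)

    def to_json(self) -> dict:
        return {"seed": self.seed, "counts": self.counts,
                "ground_truth": self.ground_truth,
                "noise_sd": self.noise_sd, "extras": self.extras}

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_json(), sort_keys=True).encode()).hexdigest()


def _fibonacci_directions(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


# ligand template: small polar molecule (two carbons, hydroxyl, amine)
_U45 = np.array([np.cos(np.pi / 4), np.sin(np.pi / 4), 0.0])
_LIGAND_TEMPLATE = [
    # name, element, position
    ("C1", "C", np.array([0.0, 0.0, 0.0])),
    ("C2", "C", np.array([1.52, 0.0, 0.0])),
    ("O1", "O", np.array([1.52, 0.0, 0.0]) + 1.43 * _U45),
    ("HO1", "H", np.array([1.52, 0.0, 0.0]) + (1.43 + 0.96) * _U45),
    ("N1", "N", 1.47 * np.array([-0.5, -np.sin(np.pi / 3), 0.0])),
    ("HN1", "H", (1.47 + 1.01) * np.array([-0.5, -np.sin(np.pi / 3), 0.0])),
]


def make_toy_pocket(n_residues: int = 10, seed: int = 0,
                    hbond_partner: bool = True
                    ) -> tuple[MolecularSystem, LigandSelection,
                               GeneratorManifest]:
    """Simplified binding pocket: 3-atom residues on a sphere (radius 7 Å)
    around a small polar ligand at the origin.

    When ``hbond_partner`` is set, the residue nearest the ligand hydroxyl
    is flipped so its carbonyl oxygen points inward 3.2 Å from the ligand
    oxygen, providing a ready-made donor–acceptor pair (recorded in the
    manifest).  The geometry is clash-free: non-bonded inter-fragment
    contacts stay >= 2.2 Å.
    """
    if n_residues < 1:
        raise PreconditionError("n_residues must be >= 1")
    rng = np.random.default_rng(seed)

    serials, names, elements, resnames = [], [], [], []
    chains, resseqs, icodes, coords, hetero = [], [], [], [], []

    def add_atom(name, element, xyz, resname, chain, resseq, het):
        serials.append(len(serials) + 1)
        names.append(name)
        elements.append(element)
        resnames.append(resname)
        chains.append(chain)
        resseqs.append(resseq)
        icodes.append("")
        coords.append(np.asarray(xyz, dtype=float))
        hetero.append(het)

    directions = _fibonacci_directions(n_residues)
    special = None
    if hbond_partner:
        special = int(np.argmax(directions @ _U45))
        directions = directions.copy()
        directions[special] = _U45

    lig_o = _LIGAND_TEMPLATE[2][2]
    radius = 7.0
    donor_index = acceptor_index = None
    for r, u in enumerate(directions):
        resseq = r + 1
        if r == special:
            # flipped residue: acceptor oxygen points at the ligand hydroxyl
            o_pos = lig_o + 3.2 * _U45
            add_atom("O", "O", o_pos, "PKT", "A", resseq, False)
            add_atom("C", "C", o_pos + 1.23 * _U45, "PKT", "A", resseq, False)
            add_atom("H", "H", o_pos + (1.23 + 1.10) * _U45, "PKT", "A",
                     resseq, False)
            acceptor_index = len(serials) - 3
        else:
            rr = radius + rng.uniform(-0.1, 0.1)
            add_atom("H", "H", (rr - 1.10) * u, "PKT", "A", resseq, False)
            add_atom("C", "C", rr * u, "PKT", "A", resseq, False)
            add_atom("O", "O", (rr + 1.23) * u, "PKT", "A", resseq, False)

    lig_start = len(serials)
    for name, el, xyz in _LIGAND_TEMPLATE:
        add_atom(name, el, xyz, "LIG", "L", 1, True)
        if name == "O1":
            donor_index = len(serials) - 1

    system = MolecularSystem(serials, names, elements, resnames, chains,
                             resseqs, icodes, np.array(coords),
                             is_hetero=hetero)
    perceive_bonds(system)
    assign_fallback_charges(system)
    ligand = LigandSelection(tuple(range(lig_start, system.n_atoms)))

    # clash check between non-bonded atoms of different residues
    d = cdist(system.coords, system.coords)
    min_sep = np.inf
    for i in range(system.n_atoms):
        for j in range(i + 1, system.n_atoms):
            if system.residue_key(i) == system.residue_key(j):
                continue
            min_sep = min(min_sep, d[i, j])
    if min_sep < MIN_CONTACT_DISTANCE - 1e-9:
        raise PreconditionError(
            f"generated pocket has clashes (min separation {min_sep:.2f} A)")

    manifest = GeneratorManifest(
        seed=seed,
        counts={"atoms": system.n_atoms, "residues": n_residues,
                "ligand_atoms": len(ligand.atom_indices)},
        extras={"min_separation_A": round(float(min_sep), 6),
                "donor_index": donor_index,
                "acceptor_index": acceptor_index,
                "hbond_residue_seq": (special + 1
                                      if special is not None else None),
                "coord_hash": hashlib.sha256(
                    np.ascontiguousarray(system.coords).tobytes()
                ).hexdigest()})
    return system, ligand, manifest


def _random_ligand(rng: np.random.Generator, ligand_id: str
                   ) -> MolecularSystem:
    """Self-avoiding random-walk molecule of 5-9 heavy atoms (C/N/O) with
    hydrogens on a random subset of N/O; charges from the fallback
    assigner."""
    n_heavy = int(rng.integers(5, 10))
    positions = [np.zeros(3)]
    elements = ["C"]
    for _ in range(n_heavy - 1):
        base = positions[int(rng.integers(0, len(positions)))]
        for _attempt in range(100):
            v = rng.standard_normal(3)
            v /= np.linalg.norm(v)
            cand = base + 1.5 * v
            if all(np.linalg.norm(cand - p) > 1.25 for p in positions):
                positions.append(cand)
                break
        else:
            positions.append(base + 1.5 * v)
        elements.append(str(rng.choice(["C", "N", "O"], p=[0.5, 0.2, 0.3])))
    # decorate polar heavy atoms with hydrogens
    n0 = len(positions)
    for i in range(n0):
        if elements[i] in ("N", "O") and rng.random() < 0.5:
            v = rng.standard_normal(3)
            v /= np.linalg.norm(v)
            positions.append(positions[i] + 0.98 * v)
            elements.append("H")
    coords = np.asarray(positions)
    coords -= coords[:n0].mean(axis=0)
    n = len(coords)
    system = MolecularSystem(
        serials=np.arange(1, n + 1), names=[f"{el}{i}" for i, el in
                                            enumerate(elements, 1)],
        elements=elements, residue_names=["LIG"] * n, chain_ids=["L"] * n,
        residue_seqs=[1] * n, insertion_codes=[""] * n, coords=coords,
        is_hetero=[True] * n)
    perceive_bonds(system)
    assign_fallback_charges(system)
    return system


def simulate_qsar_dataset(true_model: SurrogateModel | None = None,
                          n_ligands: int = 40, poses_per_ligand: int = 3,
                          noise_sd: float = 0.0, seed: int = 0,
                          envelope_spacing: float = 5.5,
                          train_fraction: float = 0.7,
                          nb: NonbondedModel = DEFAULT_MODEL
                          ) -> tuple[QsarDataset, SurrogateModel,
                                     GeneratorManifest]:
    """QSAR dataset with known ground truth.

    Random small ligands are posed near the pocket origin (random rigid
    rotations/translations per pose); affinities are
    ``model_predict(true_model, ensemble) + N(0, noise_sd)`` with a 70/30
    train/test split.  When ``true_model`` is None a random ground-truth
    model is drawn on the envelope built from the training poses (the
    envelope must derive from the poses, so the model cannot precede them).
    """
    if n_ligands < 8:
        raise PreconditionError("n_ligands must be >= 8")
    if not 1 <= poses_per_ligand <= 8:
        raise PreconditionError("poses_per_ligand must be 1..8")
    rng = np.random.default_rng(seed)

    ensembles = []
    for k in range(n_ligands):
        mol = _random_ligand(rng, f"L{k + 1:03d}")
        poses = []
        for p in range(poses_per_ligand):
            rot = Rotation.random(rng=rng).as_matrix()
            shift = rng.uniform(-1.5, 1.5, size=3)
            poses.append(mol.with_coords(mol.coords @ rot.T + shift))
        conf_e = np.sort(rng.uniform(0.0, 6.0, size=poses_per_ligand))
        ensembles.append(PoseEnsemble(ligand_id=f"L{k + 1:03d}", poses=poses,
                                      conf_energies=conf_e,
                                      atom_classes=classify_atoms(mol)))

    order = rng.permutation(n_ligands)
    n_train = int(round(train_fraction * n_ligands))
    splits = np.empty(n_ligands, dtype=object)
    splits[order[:n_train]] = "train"
    splits[order[n_train:]] = "test"

    envelope = build_envelope(
        [ensembles[i] for i in range(n_ligands) if splits[i] == "train"],
        spacing=envelope_spacing)

    if true_model is None:
        # redraw until the ground truth carries usable signal: a model
        # whose raw predictions barely vary encodes no structure–activity
        # relationship and would only test noise amplification
        best = None
        for _ in range(50):
            labels = rng.choice(N_LABELS, size=len(envelope),
                                p=[0.2, 0.15, 0.15, 0.1, 0.1, 0.1, 0.2])
            cand = SurrogateModel(envelope=envelope, labels=labels)
            raw_c = np.array([model_predict(cand, e, nb) for e in ensembles])
            if best is None or raw_c.std() > best[2]:
                best = (labels, raw_c, float(raw_c.std()))
            if raw_c.std() >= 0.4:
                break
        labels, raw, _ = best
        true_model = SurrogateModel(envelope=envelope, labels=labels)
        # place the synthetic affinities in a realistic pIC50 range
        # (centre 7, spread ~1.2 log units, cf. typical lead-series tables)
        scale = 1.2 / max(raw.std(), 1e-6)
        true_model = SurrogateModel(envelope=envelope, labels=labels,
                                    cal_a=float(scale),
                                    cal_b=float(7.0 - scale * raw.mean()))

    entries = []
    for i, ens in enumerate(ensembles):
        y = model_predict(true_model, ens, nb) + rng.normal(0.0, noise_sd)
        entries.append(QsarEntry(ligand_id=ens.ligand_id, ensemble=ens,
                                 exp_pic50=float(y), split=str(splits[i])))
    dataset = QsarDataset(entries=entries, envelope=envelope)

    manifest = GeneratorManifest(
        seed=seed,
        counts={"ligands": n_ligands, "poses_per_ligand": poses_per_ligand,
                "n_train": dataset.n_train, "n_test": dataset.n_test,
                "envelope_particles": len(envelope)},
        ground_truth={
            "labels": "".join(str(int(v)) for v in true_model.labels),
            "induced_fit_scenario": true_model.induced_fit_scenario,
            "solvation_scenario": true_model.solvation_scenario,
            "cal_a": true_model.cal_a, "cal_b": true_model.cal_b},
        noise_sd=noise_sd,
        extras={"envelope_spacing": envelope_spacing,
                "affinities": [round(e.exp_pic50, 9) for e in entries]})
    return dataset, true_model, manifest


def make_toy_trajectory(system: MolecularSystem,
                        ligand: LigandSelection | None = None,
                        n_frames: int = 20, jitter_sd: float = 0.0,
                        event: tuple | None = None,
                        interval_ns: float = 0.1, seed: int = 0
                        ) -> tuple[Trajectory, GeneratorManifest]:
    """Trajectory of Gaussian-jittered copies of ``system``.

    ``event = (target, frame_k, displacement)`` rigidly displaces the named
    residue (a structio residue key) or the ligand (``"ligand"``) by
    ``displacement`` Å radially away from the complex from frame_k onward —
    a scripted contact-loss mimicking a breaking interaction.
    """
    if n_frames < 2:
        raise PreconditionError("n_frames must be >= 2")
    rng = np.random.default_rng(seed)
    target_idx = None
    direction = None
    frame_k = None
    displacement = 0.0
    if event is not None:
        target, frame_k, displacement = event
        if not 0 <= frame_k < n_frames:
            raise PreconditionError("event frame outside the trajectory")
        if target == "ligand":
            if ligand is None:
                raise PreconditionError("event targets the ligand but no "
                                        "ligand selection was given")
            target_idx = ligand.as_array()
        else:
            matches = [idx for key, idx in system.residues() if key == target]
            if not matches:
                raise PreconditionError(f"event residue {target!r} not found")
            target_idx = matches[0]
        center = system.coords[target_idx].mean(axis=0)
        rest = np.setdiff1d(np.arange(system.n_atoms), target_idx)
        origin = system.coords[rest].mean(axis=0) if len(rest) else np.zeros(3)
        direction = center - origin
        norm = np.linalg.norm(direction)
        direction = (direction / norm if norm > 1e-9
                     else np.array([1.0, 0.0, 0.0]))

    coords = np.empty((n_frames, system.n_atoms, 3))
    for f in range(n_frames):
        frame = system.coords + rng.normal(0.0, jitter_sd,
                                           size=system.coords.shape)
        if event is not None and f >= frame_k:
            frame[target_idx] += displacement * direction
        coords[f] = frame
    times = np.arange(n_frames) * interval_ns
    traj = Trajectory(topology=system, coords=coords, times=times)
    manifest = GeneratorManifest(
        seed=seed,
        counts={"frames": n_frames, "atoms": system.n_atoms},
        extras={"jitter_sd": jitter_sd, "interval_ns": interval_ns,
                "event": None if event is None else {
                    "target": list(event[0]) if event[0] != "ligand"
                    else "ligand",
                    "frame": frame_k, "displacement_A": displacement},
                "coord_hash": hashlib.sha256(
                    np.ascontiguousarray(coords).tobytes()).hexdigest()})
    return traj, manifest


def load_table1_fixture() -> pd.DataFrame:
    """The packaged 52-compound affinity table (pIC50 scale).

    Columns: compound_no, exp_pic50, pred_pic50, residual (= pred − exp as
    printed).  The published minus sign (U+2212) is normalised to an ASCII
    hyphen.  Verifies the recorded checksum before parsing.
    """
    path = resources.files("mqsar.data") / "fimh_affinity_table.csv"
    raw = path.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != TABLE1_SHA256:
        raise FixtureCorruptionError(
            f"affinity table checksum mismatch: {digest}")
    import io
    df = pd.read_csv(io.BytesIO(raw))
    if len(df) != 52:
        raise FixtureCorruptionError("affinity table must have 52 records")
    return df
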