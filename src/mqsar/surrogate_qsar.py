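"""Quasi-atomistic receptor-surrogate multi-dimensional QSAR.

A binding site is replaced by an *envelope* of property-labelled virtual
particles wrapped around the union of the training ligands' docking poses.
Each ligand is represented by a pose ensemble (the 4D axis, up to 8 poses);
each surrogate model additionally commits to one of six induced-fit
scenarios (5D; discrete envelope dilation levels with a linear energy
penalty) and one of two solvation scenarios (6D; buried vs solvent-exposed
site).  A genetic algorithm evolves a family of such models against
experimental affinities, and predictions are reported in consensus mode as
the family mean ± standard deviation.

Scoring model
-------------
Each particle interacts with its nearest ligand atom within 4.5 Å through a
bundled property-compatibility table (kcal/mol), attenuated by a Gaussian
distance taper centred at 3.0 Å (width 1.0 Å).  Pose scores are combined
over the ensemble with Boltzmann weights derived from the conformer
energies, via ΔG = −RT ln Σ_i w_i exp(−ΔG_i/RT), which is invariant under
pose duplication.  A per-model linear calibration maps the raw converted
score onto the pIC50 scale.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist
from scipy.special import logsumexp

from .binding_energy import LN10, VDW_RADII
from .errors import (ParameterMissingError, PreconditionError,
                     UndefinedMetricError)
from .forcefield import DEFAULT_MODEL, NonbondedModel
from .structio import MolecularSystem

# --- particle property alphabet -------------------------------------------

PROPERTY_LABELS = ("hydrophobic", "donor", "acceptor", "positive",
                   "negative", "neutral", "void")
N_LABELS = len(PROPERTY_LABELS)

ATOM_CLASSES = ("hydrophobic", "donor", "acceptor", "positive",
                "negative", "neutral")

# Property-compatibility energies, kcal/mol: rows = particle label,
# columns = ligand atom class.  Negative = favourable contact.
COMPAT_TABLE = np.array([
    # hydroph  donor  accept  posit  negat  neutral
    [-0.8,     0.3,   0.3,    0.5,   0.5,   0.0],   # hydrophobic particle
    [0.2,      0.8,  -1.5,    0.8,  -0.8,   0.0],   # H-bond donor particle
    [0.2,     -1.5,   0.8,   -0.8,   0.8,   0.0],   # H-bond acceptor particle
    [0.3,      0.5,  -1.0,    2.0,  -2.5,   0.0],   # positively charged
    [0.3,     -1.0,   0.5,   -2.5,   2.0,   0.0],   # negatively charged
    [0.0,      0.0,   0.0,    0.0,   0.0,   0.0],   # neutral particle
    [0.0,      0.0,   0.0,    0.0,   0.0,   0.0],   # void
])

VOID = PROPERTY_LABELS.index("void")

INTERACTION_RANGE = 4.5     # Å particle–atom pairing range
TAPER_CENTER = 3.0          # Å optimum contact distance
TAPER_WIDTH = 1.0           # Å Gaussian width
DILATION_STEP = 0.1         # Å per induced-fit scenario level
K_INDUCED_FIT = 2.0         # kcal/mol per Å of envelope dilation
C_SOLVATION = 0.5           # kcal/mol penalty for a solvent-exposed site
N_IF_SCENARIOS = 6
N_SOLV_SCENARIOS = 2
MAX_POSES_DEFAULT = 8


def classify_atoms(system: MolecularSystem) -> np.ndarray:
    """Map each atom to a property class index (see ``ATOM_CLASSES``).

    Requires perceived bonds (to find polar hydrogens and donor heavy
    atoms).  Charged classes trigger at |q| >= 0.5 e.
    """
    g = system.bond_graph()
    classes = np.full(system.n_atoms, ATOM_CLASSES.index("neutral"), dtype=int)
    for i in range(system.n_atoms):
        el = system.elements[i]
        q = system.charges[i]
        if q >= 0.5:
            classes[i] = ATOM_CLASSES.index("positive")
        elif q <= -0.5:
            classes[i] = ATOM_CLASSES.index("negative")
        elif el == "H":
            heavies = [system.elements[j] for j in g.neighbors(i)]
            if any(h in ("N", "O") for h in heavies):
                classes[i] = ATOM_CLASSES.index("donor")
        elif el in ("N", "O"):
            has_h = any(system.elements[j] == "H" for j in g.neighbors(i))
            classes[i] = ATOM_CLASSES.index("donor" if has_h else "acceptor")
        elif el in ("C", "S", "P", "F", "CL", "BR", "I"):
            classes[i] = ATOM_CLASSES.index("hydrophobic")
    return classes


# --- domain types ----------------------------------------------------------


@dataclass
class PoseEnsemble:
    """Up to ``max_poses`` docking poses of one ligand (the 4D axis)."""

    ligand_id: str
    poses: list[MolecularSystem]
    conf_energies: np.ndarray
    atom_classes: np.ndarray | None = None
    max_poses: int = MAX_POSES_DEFAULT

    def __post_init__(self):
        self.conf_energies = np.asarray(self.conf_energies, dtype=float)
        if len(self.conf_energies) != len(self.poses):
            raise PreconditionError("one conformer energy per pose required")
        if not np.all(np.isfinite(self.conf_energies)):
            raise PreconditionError("conformer energies must be finite")
        # exact duplicates are one microstate: counting them twice would
        # double their statistical weight for no physical reason
        seen, keep = set(), []
        for i, (pose, e) in enumerate(zip(self.poses, self.conf_energies)):
            key = (round(float(e), 9), np.round(pose.coords, 6).tobytes())
            if key not in seen:
                seen.add(key)
                keep.append(i)
        if len(keep) < len(self.poses):
            self.poses = [self.poses[i] for i in keep]
            self.conf_energies = self.conf_energies[keep]
        if not 1 <= len(self.poses) <= self.max_poses:
            raise PreconditionError(
                f"{self.ligand_id}: need 1..{self.max_poses} poses")
        if self.atom_classes is None:
            self.atom_classes = classify_atoms(self.poses[0])


@dataclass
class SurrogateModel:
    """One envelope instance: particle labels + scenario choices."""

    envelope: np.ndarray              # (P, 3) particle positions, Å
    labels: np.ndarray                # (P,) indices into PROPERTY_LABELS
    induced_fit_scenario: int = 0     # 0..5 (5D axis)
    solvation_scenario: int = 0       # 0 buried, 1 exposed (6D axis)
    cal_a: float = 1.0                # linear calibration: pIC50 = a·raw + b
    cal_b: float = 0.0

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.envelope):
            raise PreconditionError("one label per envelope particle")
        if not 0 <= self.induced_fit_scenario < N_IF_SCENARIOS:
            raise PreconditionError("induced-fit scenario out of range")
        if not 0 <= self.solvation_scenario < N_SOLV_SCENARIOS:
            raise PreconditionError("solvation scenario out of range")

    @property
    def dilation(self) -> float:
        return DILATION_STEP * self.induced_fit_scenario

    @property
    def induced_fit_penalty(self) -> float:
        return K_INDUCED_FIT * self.dilation


@dataclass
class GAConfig:
    """Genetic-algorithm settings (all logged with trained families)."""

    population: int = 400
    generations: int = 300
    tournament_size: int = 4
    crossover_rate: float = 0.8
    mutation_rate: float = 0.02
    mutation_rate_start: float | None = 0.15  # annealed to mutation_rate
    plateau: int = 30
    family_size: int = 200
    lambda_q2: float = 0.25
    envelope_spacing: float = 1.5
    elite_refine: bool = True       # memetic coordinate sweep on the elite
    immigrant_fraction: float = 0.1  # random chromosomes injected per generation
    family_fitness_window: float = 0.05  # max fitness gap to the best member
    restart_on_plateau: bool = True  # soft restart instead of early stop


@dataclass
class ModelFamily:
    """A consensus family of surrogate models sharing one envelope."""

    envelope: np.ndarray
    members: list[SurrogateModel]
    config: GAConfig = field(default_factory=GAConfig)
    seed: int = 0

    def __post_init__(self):
        if not self.members:
            raise PreconditionError("a model family cannot be empty")


@dataclass
class QsarEntry:
    ligand_id: str
    ensemble: PoseEnsemble
    exp_pic50: float
    split: str  # train | test


@dataclass
class QsarDataset:
    entries: list[QsarEntry]
    envelope: np.ndarray | None = None

    def subset(self, split: str) -> list[QsarEntry]:
        return [e for e in self.entries if e.split == split]

    @property
    def n_train(self) -> int:
        return len(self.subset("train"))

    @property
    def n_test(self) -> int:
        return len(self.subset("test"))


@dataclass
class ValidationReport:
    q2: float
    r2_pred: float
    fraction_within_factor10: float
    yscramble_q2_distribution: list[float] = field(default_factory=list)


# --- envelope construction -------------------------------------------------


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit-sphere points (golden-section spiral)."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def build_envelope(ensembles: list[PoseEnsemble], spacing: float = 0.8,
                   shell_offset: float = 1.4) -> np.ndarray:
    """Particle positions on the solvent-contact surface of the pose union.

    Sphere points are generated per atom at r_vdw + shell_offset, points
    buried inside any other atom's shell are discarded, and survivors are
    thinned so no two particles lie closer than 0.7 × spacing.
    Deterministic for a fixed input order.
    """
    if not ensembles:
        raise PreconditionError("at least one pose ensemble required")
    if spacing <= 0:
        raise PreconditionError("spacing must be positive")
    centers, radii = [], []
    for ens in ensembles:
        for pose in ens.poses:
            for i, el in enumerate(pose.elements):
                centers.append(pose.coords[i])
                radii.append(VDW_RADII.get(el, 1.7) + shell_offset)
    centers = np.asarray(centers)
    radii = np.asarray(radii)

    tree = cKDTree(centers)
    rmax = radii.max()
    kept: list[np.ndarray] = []
    cell = 0.7 * spacing
    grid: dict[tuple[int, int, int], list[int]] = {}

    def _is_clear(pt: np.ndarray) -> bool:
        cx, cy, cz = (int(math.floor(c / cell)) for c in pt)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    for k in grid.get((cx + dx, cy + dy, cz + dz), ()):
                        if np.linalg.norm(kept[k] - pt) < cell:
                            return False
        return True

    for a in range(len(centers)):
        n_pts = max(1, int(round(4.0 * math.pi * radii[a] ** 2 / spacing ** 2)))
        pts = centers[a] + radii[a] * _fibonacci_sphere(n_pts)
        for pt in pts:
            buried = False
            for j in tree.query_ball_point(pt, rmax):
                if j != a and np.linalg.norm(pt - centers[j]) < radii[j] - 1e-6:
                    buried = True
                    break
            if buried or not _is_clear(pt):
                continue
            idx = len(kept)
            kept.append(pt)
            key = tuple(int(math.floor(c / cell)) for c in pt)
            grid.setdefault(key, []).append(idx)
    if not kept:
        raise PreconditionError("envelope construction produced no particles")
    return np.asarray(kept)


# --- scoring ---------------------------------------------------------------


def _taper(d: np.ndarray) -> np.ndarray:
    g = np.exp(-((d - TAPER_CENTER) ** 2) / (2.0 * TAPER_WIDTH ** 2))
    return np.where(d <= INTERACTION_RANGE, g, 0.0)


def pose_features(envelope: np.ndarray, pose: MolecularSystem,
                  atom_classes: np.ndarray):
    """Per-particle (nearest-atom class, gain per dilation scenario).

    Returns ``classes`` with shape (P,) and ``gains`` with shape (6, P);
    particles with no atom in range at a given dilation have zero gain.
    """
    if atom_classes is None:
        raise ParameterMissingError("pose atoms are not property-typed")
    d = cdist(envelope, pose.coords)
    nearest = d.argmin(axis=1)
    dmin = d[np.arange(len(envelope)), nearest]
    classes = np.asarray(atom_classes, dtype=int)[nearest]
    dilations = DILATION_STEP * np.arange(N_IF_SCENARIOS)
    gains = _taper(dmin[None, :] + dilations[:, None])
    return classes, gains


def score_pose_against_model(model: SurrogateModel, pose: MolecularSystem,
                             atom_classes: np.ndarray | None = None) -> float:
    """Surrogate score of one pose (kcal/mol, lower = better binder)."""
    if atom_classes is None:
        atom_classes = classify_atoms(pose)
    classes, gains = pose_features(model.envelope, pose, atom_classes)
    contrib = COMPAT_TABLE[model.labels, classes] * gains[model.induced_fit_scenario]
    return float(contrib.sum() + model.induced_fit_penalty
                 + C_SOLVATION * model.solvation_scenario)


def boltzmann_weights(energies, temperature: float = 300.0,
                      gas_constant: float = DEFAULT_MODEL.gas_constant
                      ) -> np.ndarray:
    """Normalised exp(−E/RT) weights, computed with a max shift."""
    e = np.asarray(energies, dtype=float)
    if e.size == 0:
        raise PreconditionError("empty energy list")
    if temperature <= 0:
        raise PreconditionError("temperature must be positive")
    x = -(e - e.min()) / (gas_constant * temperature)
    w = np.exp(x)
    return w / w.sum()


def log_boltzmann_weights(energies, temperature: float = 300.0,
                          gas_constant: float = DEFAULT_MODEL.gas_constant
                          ) -> np.ndarray:
    """log of :func:`boltzmann_weights`, safe for effectively-zero weights."""
    e = np.asarray(energies, dtype=float)
    if e.size == 0:
        raise PreconditionError("empty energy list")
    if temperature <= 0:
        raise PreconditionError("temperature must be positive")
    x = -(e - e.min()) / (gas_constant * temperature)
    return x - logsumexp(x)


def _combine_pose_scores(scores: np.ndarray, log_w: np.ndarray,
                         rt: float) -> float:
    """Boltzmann-combined ΔG = −RT ln Σ w_i exp(−ΔG_i/RT)."""
    return float(-rt * logsumexp(log_w - scores / rt))


def model_predict(model: SurrogateModel, ensemble: PoseEnsemble,
                  nb: NonbondedModel = DEFAULT_MODEL) -> float:
    """Predicted pIC50 of one ligand under one surrogate model."""
    scores = np.array([
        score_pose_against_model(model, pose, ensemble.atom_classes)
        for pose in ensemble.poses])
    log_w = log_boltzmann_weights(ensemble.conf_energies, nb.temperature,
                                  nb.gas_constant)
    dg = _combine_pose_scores(scores, log_w, nb.rt)
    raw = -dg / (LN10 * nb.rt)
    return model.cal_a * raw + model.cal_b


def family_predict(family: ModelFamily, ensemble: PoseEnsemble,
                   nb: NonbondedModel = DEFAULT_MODEL) -> tuple[float, float]:
    """Consensus prediction: (mean, population sd) over family members."""
    preds = np.array([model_predict(m, ensemble, nb) for m in family.members])
    return float(preds.mean()), float(preds.std())


# --- vectorised dataset features for GA training ---------------------------


class _DatasetFeatures:
    """Precomputed per-pose features so GA fitness is pure array algebra."""

    def __init__(self, envelope: np.ndarray, entries: list[QsarEntry],
                 nb: NonbondedModel):
        self.nb = nb
        self.rt = nb.rt
        classes, gains, log_w, slices = [], [], [], []
        start = 0
        for e in entries:
            lw = log_boltzmann_weights(e.ensemble.conf_energies,
                                       nb.temperature, nb.gas_constant)
            for pose, lwi in zip(e.ensemble.poses, lw):
                c, g = pose_features(envelope, pose, e.ensemble.atom_classes)
                classes.append(c)
                gains.append(g)
                log_w.append(float(lwi))
            slices.append((start, start + len(e.ensemble.poses)))
            start += len(e.ensemble.poses)
        self.classes = np.stack(classes)                 # (n_poses, P)
        self.gains = np.stack(gains, axis=1)             # (6, n_poses, P)
        self.log_w = np.asarray(log_w)                   # (n_poses,)
        self.slices = slices
        self.y = np.array([e.exp_pic50 for e in entries])

    def raw_predict(self, labels: np.ndarray, scen: np.ndarray,
                    solv: np.ndarray) -> np.ndarray:
        """Raw (uncalibrated) pIC50 for each (member, ligand)."""
        lookup = COMPAT_TABLE[labels[:, None, :], self.classes[None, :, :]]
        gains = self.gains[scen]                          # (M, n_poses, P)
        scores = (lookup * gains).sum(axis=2)             # (M, n_poses)
        scores += (K_INDUCED_FIT * DILATION_STEP * scen
                   + C_SOLVATION * solv)[:, None]
        out = np.empty((len(labels), len(self.slices)))
        for li, (a, b) in enumerate(self.slices):
            arg = self.log_w[None, a:b] - scores[:, a:b] / self.rt
            dg = -self.rt * logsumexp(arg, axis=1)
            out[:, li] = -dg / (LN10 * self.rt)
        return out


def _calibrate(raw: np.ndarray, y: np.ndarray):
    """Vectorised per-member least-squares pIC50 calibration.

    Returns (a, b, rmse, q2_loo) arrays; q2_loo is the closed-form
    leave-one-out r² of the two-parameter linear fit.
    """
    n = raw.shape[1]
    xm = raw.mean(axis=1, keepdims=True)
    ym = y.mean()
    dx = raw - xm
    sxx = (dx ** 2).sum(axis=1)
    sxy = (dx * (y - ym)).sum(axis=1)
    a = np.where(sxx > 1e-12, sxy / np.where(sxx > 1e-12, sxx, 1.0), 0.0)
    b = ym - a * xm[:, 0]
    pred = a[:, None] * raw + b[:, None]
    resid = pred - y[None, :]
    rmse = np.sqrt((resid ** 2).mean(axis=1))
    ssy = ((y - ym) ** 2).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        h = 1.0 / n + dx ** 2 / np.where(sxx > 1e-12, sxx, np.inf)[:, None]
        e_loo = resid / np.maximum(1.0 - h, 1e-9)
    q2 = np.where(ssy > 1e-12, 1.0 - (e_loo ** 2).sum(axis=1) / ssy, 0.0)
    return a, b, rmse, q2


def ga_train(dataset: QsarDataset, config: GAConfig | None = None,
             seed: int = 0, nb: NonbondedModel = DEFAULT_MODEL) -> ModelFamily:
    """Evolve a family of surrogate models against the training split.

    Tournament selection, uniform crossover, per-gene mutation; fitness is
    −RMSE(train) − λ·(1 − q²_LOO of the linear calibration).  Fully
    reproducible from (seed, config).
    """
    config = config or GAConfig()
    train = dataset.subset("train")
    if len(train) < 8:
        raise PreconditionError("need at least 8 training entries")
    envelope = dataset.envelope
    if envelope is None:
        envelope = build_envelope([e.ensemble for e in train],
                                  spacing=config.envelope_spacing)
    feats = _DatasetFeatures(envelope, train, nb)
    P = len(envelope)
    M = config.population
    rng = np.random.default_rng(seed)

    labels = rng.integers(0, N_LABELS, size=(M, P))
    scen = rng.integers(0, N_IF_SCENARIOS, size=M)
    solv = rng.integers(0, N_SOLV_SCENARIOS, size=M)

    def fitness(lb, sc, sv):
        raw = feats.raw_predict(lb, sc, sv)
        a, b, rmse, q2 = _calibrate(raw, feats.y)
        return -rmse - config.lambda_q2 * (1.0 - q2), a, b

    def refine(lab0, sc0, sv0):
        """Steepest-ascent coordinate sweep over one chromosome."""
        lab0, sc0, sv0 = lab0.copy(), int(sc0), int(sv0)
        f0 = fitness(lab0[None, :], np.array([sc0]), np.array([sv0]))[0][0]
        for _sweep in range(3 * P):
            n_cand = P * N_LABELS + N_IF_SCENARIOS + N_SOLV_SCENARIOS
            cl = np.tile(lab0, (n_cand, 1))
            cs = np.full(n_cand, sc0)
            cv = np.full(n_cand, sv0)
            for p in range(P):
                cl[p * N_LABELS:(p + 1) * N_LABELS, p] = np.arange(N_LABELS)
            o = P * N_LABELS
            cs[o:o + N_IF_SCENARIOS] = np.arange(N_IF_SCENARIOS)
            cv[o + N_IF_SCENARIOS:] = np.arange(N_SOLV_SCENARIOS)
            fc = fitness(cl, cs, cv)[0]
            k = int(fc.argmax())
            if fc[k] <= f0 + 1e-12:
                break
            lab0, sc0, sv0, f0 = cl[k], int(cs[k]), int(cv[k]), fc[k]
        return lab0, sc0, sv0

    best_fit = -np.inf
    stall = 0
    m_start = (config.mutation_rate_start
               if config.mutation_rate_start is not None
               else config.mutation_rate)
    for _gen in range(config.generations):
        # exponential mutation annealing: explore early, refine late
        frac = _gen / max(config.generations - 1, 1)
        m_rate = config.mutation_rate * (m_start / config.mutation_rate) ** (
            1.0 - frac) if m_start > config.mutation_rate else \
            config.mutation_rate
        fit, _, _ = fitness(labels, scen, solv)
        if config.elite_refine:
            # memetic step: local search from the elite and from a random
            # individual (the latter keeps alternative basins in play)
            worst = np.argsort(fit)
            for slot, bi in enumerate((int(fit.argmax()),
                                       int(rng.integers(0, M)))):
                rl, rs, rv = refine(labels[bi], scen[bi], solv[bi])
                wi = int(worst[slot])
                labels[wi], scen[wi], solv[wi] = rl, rs, rv
                fit[wi] = fitness(rl[None, :], np.array([rs]),
                                  np.array([rv]))[0][0]
        gen_best = fit.max()
        if gen_best > best_fit + 1e-9:
            best_fit = gen_best
            stall = 0
        else:
            stall += 1
            if stall >= config.plateau:
                if not config.restart_on_plateau:
                    break
                # soft restart: keep the elite, redraw everyone else
                keep = np.argsort(-fit)[:2]
                fresh = rng.integers(0, N_LABELS, size=(M, P))
                fresh[:2] = labels[keep]
                labels = fresh
                s_new = rng.integers(0, N_IF_SCENARIOS, size=M)
                v_new = rng.integers(0, N_SOLV_SCENARIOS, size=M)
                s_new[:2] = scen[keep]
                v_new[:2] = solv[keep]
                scen, solv = s_new, v_new
                stall = 0
                continue
        order = np.argsort(-fit)
        elite = order[:2]
        n_off = M - len(elite)
        # tournament selection of two parent sets
        t1 = rng.integers(0, M, size=(n_off, config.tournament_size))
        t2 = rng.integers(0, M, size=(n_off, config.tournament_size))
        p1 = t1[np.arange(n_off), fit[t1].argmax(axis=1)]
        p2 = t2[np.arange(n_off), fit[t2].argmax(axis=1)]
        # uniform crossover
        do_cx = rng.random(n_off) < config.crossover_rate
        mask = rng.random((n_off, P)) < 0.5
        child_lab = np.where(mask, labels[p1], labels[p2])
        child_lab[~do_cx] = labels[p1][~do_cx]
        pick = rng.random(n_off) < 0.5
        child_scen = np.where(pick, scen[p1], scen[p2])
        child_solv = np.where(~pick, solv[p1], solv[p2])
        child_scen[~do_cx] = scen[p1][~do_cx]
        child_solv[~do_cx] = solv[p1][~do_cx]
        # mutation
        mut = rng.random((n_off, P)) < m_rate
        child_lab[mut] = rng.integers(0, N_LABELS, size=int(mut.sum()))
        mscen = rng.random(n_off) < m_rate
        child_scen[mscen] = rng.integers(0, N_IF_SCENARIOS, size=int(mscen.sum()))
        msolv = rng.random(n_off) < m_rate
        child_solv[msolv] = rng.integers(0, N_SOLV_SCENARIOS, size=int(msolv.sum()))
        # random immigrants keep the population from collapsing early
        n_imm = int(config.immigrant_fraction * n_off)
        if n_imm:
            child_lab[-n_imm:] = rng.integers(0, N_LABELS, size=(n_imm, P))
            child_scen[-n_imm:] = rng.integers(0, N_IF_SCENARIOS, size=n_imm)
            child_solv[-n_imm:] = rng.integers(0, N_SOLV_SCENARIOS, size=n_imm)
        labels = np.vstack([labels[elite], child_lab])
        scen = np.concatenate([scen[elite], child_scen])
        solv = np.concatenate([solv[elite], child_solv])

    fit, a, b = fitness(labels, scen, solv)
    # consensus members: distinct near-optimal models (clones of one
    # optimum add no information; far-from-optimal ones add only noise)
    order = np.argsort(-fit, kind="stable")
    members, seen = [], set()
    fit_best = fit[order[0]]
    for i in order:
        if fit[i] < fit_best - config.family_fitness_window:
            break
        key = (labels[i].tobytes(), int(scen[i]), int(solv[i]))
        if key in seen:
            continue
        seen.add(key)
        members.append(SurrogateModel(
            envelope=envelope, labels=labels[i].copy(),
            induced_fit_scenario=int(scen[i]),
            solvation_scenario=int(solv[i]),
            cal_a=float(a[i]), cal_b=float(b[i])))
        if len(members) >= config.family_size:
            break
    return ModelFamily(envelope=envelope, members=members, config=config,
                       seed=seed)


def make_trainer(config: GAConfig | None = None,
                 nb: NonbondedModel = DEFAULT_MODEL):
    """A ``trainer(dataset, seed) -> ModelFamily`` closure for CV/scrambling."""
    def trainer(dataset: QsarDataset, seed: int = 0) -> ModelFamily:
        return ga_train(dataset, config=config, seed=seed, nb=nb)
    return trainer


# --- validation metrics -----------------------------------------------------


def _stratified_folds(y: np.ndarray, n_folds: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Fold labels, stratified by affinity: sort, then deal each block of
    ``n_folds`` consecutive compounds into shuffled folds."""
    order = np.argsort(y + 1e-9 * rng.standard_normal(len(y)), kind="stable")
    folds = np.empty(len(y), dtype=int)
    for start in range(0, len(y), n_folds):
        block = order[start:start + n_folds]
        assign = rng.permutation(n_folds)[:len(block)]
        folds[block] = assign
    return folds


def cross_validated_r2(model_or_trainer, dataset: QsarDataset,
                       n_folds: int = 5, seed: int = 0,
                       nb: NonbondedModel = DEFAULT_MODEL) -> float:
    """q² = 1 − PRESS/SS_tot over held-out predictions.

    With a trainer callable the family is retrained on each fold's
    complement (the honest protocol); with a pre-trained family the
    held-out entries are simply scored.
    """
    if n_folds < 2:
        raise PreconditionError("need at least 2 folds")
    entries = dataset.subset("train") or dataset.entries
    if len(entries) < n_folds:
        raise PreconditionError("fewer training entries than folds")
    y = np.array([e.exp_pic50 for e in entries])
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(y, n_folds, rng)
    preds = np.empty(len(entries))
    for f in range(n_folds):
        held = np.flatnonzero(folds == f)
        if callable(model_or_trainer):
            sub = QsarDataset(
                entries=[QsarEntry(e.ligand_id, e.ensemble, e.exp_pic50,
                                   "test" if i in held else "train")
                         for i, e in enumerate(entries)],
                envelope=dataset.envelope)
            family = model_or_trainer(sub, int(rng.integers(0, 2 ** 31)))
        else:
            family = model_or_trainer
        for i in held:
            preds[i] = family_predict(family, entries[i].ensemble, nb)[0]
    press = float(((preds - y) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise UndefinedMetricError("zero affinity variance")
    return 1.0 - press / ss_tot


def predictive_r2(pred_test, exp_test, train_mean: float
                  ) -> tuple[float, float]:
    """External-test r² and the fraction of compounds predicted within a
    factor of 10 (|Δlog10| <= 1.0, inclusive)."""
    pred = np.asarray(pred_test, dtype=float)
    exp = np.asarray(exp_test, dtype=float)
    if pred.size == 0 or pred.shape != exp.shape:
        raise PreconditionError("test vectors must be non-empty, equal length")
    denom = float(((exp - train_mean) ** 2).sum())
    if denom == 0:
        raise UndefinedMetricError("test affinities equal the training mean")
    r2 = 1.0 - float(((pred - exp) ** 2).sum()) / denom
    fraction = float((np.abs(pred - exp) <= 1.0 + 1e-12).mean())
    return r2, fraction


def y_scramble(dataset: QsarDataset, trainer, n_rounds: int = 10,
               seed: int = 0, n_folds: int = 3,
               nb: NonbondedModel = DEFAULT_MODEL) -> dict:
    """Label-permutation control: retrain on scrambled affinities and
    record the cross-validated q² per round."""
    if n_rounds < 1:
        raise PreconditionError("n_rounds must be >= 1")
    rng = np.random.default_rng(seed)
    train = dataset.subset("train")
    q2s = []
    for _ in range(n_rounds):
        perm = rng.permutation(len(train))
        scrambled = QsarDataset(
            entries=[QsarEntry(e.ligand_id, e.ensemble,
                               train[perm[i]].exp_pic50, "train")
                     for i, e in enumerate(train)],
            envelope=dataset.envelope)
        q2s.append(cross_validated_r2(trainer, scrambled, n_folds=n_folds,
                                      seed=int(rng.integers(0, 2 ** 31)),
                                      nb=nb))
    q2s = [float(q) for q in q2s]
    return {"q2_rounds": q2s, "mean": float(np.mean(q2s)),
            "max": float(np.max(q2s)), "n_rounds": n_rounds}


@dataclass(frozen=True)
class ConsensusResult:
    accepted: bool
    reasons: tuple[str, ...] = ()


def consensus_flag(quasar_pred: float, ff_score: float, e_site: float,
                   e_water: float, ff_threshold: float = 0.0
                   ) -> ConsensusResult:
    """Accept iff the direct force-field score is favourable and the ligand
    does not prefer bulk water over the site (tie resolved toward binding)."""
    for v in (quasar_pred, ff_score, e_site, e_water):
        if not np.isfinite(v):
            raise PreconditionError("consensus inputs must be finite")
    reasons = []
    if ff_score > ff_threshold:
        reasons.append("unfavourable force-field score")
    if e_site > e_water:
        reasons.append("prefers water")
    return ConsensusResult(accepted=not reasons, reasons=tuple(reasons))


# --- serialization ----------------------------------------------------------

FAMILY_FORMAT_VERSION = 1


def family_to_json(family: ModelFamily) -> dict:
    return {
        "format_version": FAMILY_FORMAT_VERSION,
        "envelope": np.round(family.envelope, 6).tolist(),
        "members": [
            {"labels": "".join(str(int(v)) for v in m.labels),
             "induced_fit_scenario": m.induced_fit_scenario,
             "solvation_scenario": m.solvation_scenario,
             "cal_a": m.cal_a, "cal_b": m.cal_b}
            for m in family.members],
        "config": asdict(family.config),
        "seed": family.seed,
    }


def family_from_json(doc: dict) -> ModelFamily:
    envelope = np.asarray(doc["envelope"], dtype=float)
    members = [SurrogateModel(
        envelope=envelope,
        labels=np.array([int(c) for c in m["labels"]]),
        induced_fit_scenario=int(m["induced_fit_scenario"]),
        solvation_scenario=int(m["solvation_scenario"]),
        cal_a=float(m["cal_a"]), cal_b=float(m["cal_b"]))
        for m in doc["members"]]
    return ModelFamily(envelope=envelope, members=members,
                       config=GAConfig(**doc["config"]), seed=doc["seed"])


def save_family(family: ModelFamily, path) -> None:
    with open(path, "w") as fh:
        json.dump(family_to_json(family), fh)


def load_family(path) -> ModelFamily:
    with open(path) as fh:
        return family_from_json(json.load(fh))


def family_hash(family: ModelFamily) -> str:
    return hashlib.sha256(
        json.dumps(family_to_json(family), sort_keys=True).encode()
    ).hexdigest()


# --- dataset manifest I/O ---------------------------------------------------


def write_dataset(dataset: QsarDataset, outdir) -> None:
    """Serialize a dataset: per-ligand multi-model pose PDBs (charges in the
    occupancy column), a manifest CSV ``ligand_id,pose_file,exp_pic50,split``
    (+ conformer energies) and the envelope as JSON."""
    import os
    import pandas as pd
    from .structio import Trajectory, write_pdb

    os.makedirs(outdir, exist_ok=True)
    rows = []
    for e in dataset.entries:
        pose_file = f"{e.ligand_id}.pdb"
        poses = e.ensemble.poses
        coords = np.stack([p.coords for p in poses])
        traj = Trajectory(topology=poses[0], coords=coords,
                          times=np.arange(len(poses), dtype=float))
        write_pdb(traj, os.path.join(outdir, pose_file),
                  charges_in_occupancy=True)
        rows.append({
            "ligand_id": e.ligand_id, "pose_file": pose_file,
            "exp_pic50": f"{e.exp_pic50:.9g}", "split": e.split,
            "conf_energies": "|".join(f"{x:.9g}"
                                      for x in e.ensemble.conf_energies)})
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "manifest.csv"),
                              index=False)
    if dataset.envelope is not None:
        with open(os.path.join(outdir, "envelope.json"), "w") as fh:
            json.dump({"envelope": np.round(dataset.envelope, 6).tolist()},
                      fh)


def load_dataset(indir) -> QsarDataset:
    """Read a dataset directory written by :func:`write_dataset`."""
    import os
    import pandas as pd
    from .structio import perceive_bonds, read_pdb

    manifest = pd.read_csv(os.path.join(indir, "manifest.csv"))
    entries = []
    for _, row in manifest.iterrows():
        traj = read_pdb(os.path.join(indir, row["pose_file"]),
                        charges="occupancy")
        poses = [traj.frame(i) for i in range(traj.n_frames)]
        perceive_bonds(poses[0])
        classes = classify_atoms(poses[0])
        conf_e = np.array([float(x)
                           for x in str(row["conf_energies"]).split("|")])
        ens = PoseEnsemble(ligand_id=str(row["ligand_id"]), poses=poses,
                           conf_energies=conf_e, atom_classes=classes)
        entries.append(QsarEntry(ligand_id=str(row["ligand_id"]),
                                 ensemble=ens,
                                 exp_pic50=float(row["exp_pic50"]),
                                 split=str(row["split"])))
    envelope = None
    env_path = os.path.join(indir, "envelope.json")
    if os.path.exists(env_path):
        with open(env_path) as fh:
            envelope = np.asarray(json.load(fh)["envelope"], dtype=float)
    return QsarDataset(entries=entries, envelope=envelope)
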