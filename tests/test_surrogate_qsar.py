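"""Receptor-surrogate mQSAR: envelope, scoring, GA, validation metrics."""

import math

import numpy as np
import pytest

from mqsar.errors import PreconditionError, UndefinedMetricError
from mqsar.forcefield import DEFAULT_MODEL
from mqsar.binding_energy import VDW_RADII
from mqsar.structio import MolecularSystem
from mqsar.surrogate_qsar import (ATOM_CLASSES, COMPAT_TABLE, C_SOLVATION,
                                  DILATION_STEP, GAConfig, INTERACTION_RANGE,
                                  K_INDUCED_FIT, ModelFamily, PoseEnsemble,
                                  SurrogateModel, TAPER_CENTER, TAPER_WIDTH,
                                  boltzmann_weights, build_envelope,
                                  classify_atoms, consensus_flag,
                                  cross_validated_r2, family_from_json,
                                  family_hash, family_predict, family_to_json,
                                  ga_train, make_trainer, model_predict,
                                  predictive_r2, score_pose_against_model,
                                  y_scramble)

from conftest import chain_molecule


def _single_atom_pose(element="O", charge=0.0, xyz=(0.0, 0.0, 0.0)):
    pose = MolecularSystem(
        serials=[1], names=[element], elements=[element],
        residue_names=["LIG"], chain_ids=["L"], residue_seqs=[1],
        insertion_codes=[""], coords=[list(xyz)], charges=[charge],
        is_hetero=[True])
    pose.bonds = set()
    return pose


class TestEnvelope:
    def test_single_atom_sphere_point_count(self):
        pose = _single_atom_pose("C")
        ens = PoseEnsemble("x", [pose], [0.0], atom_classes=np.array([0]))
        spacing = 0.8
        env = build_envelope([ens], spacing=spacing, shell_offset=1.4)
        area = 4 * math.pi * (VDW_RADII["C"] + 1.4) ** 2
        assert abs(len(env) - area / spacing ** 2) < 0.2 * area / spacing ** 2
        radii = np.linalg.norm(env, axis=1)
        np.testing.assert_allclose(radii, VDW_RADII["C"] + 1.4, rtol=1e-9)

    def test_deterministic_for_identical_input(self):
        pose = _single_atom_pose("C")
        ens = PoseEnsemble("x", [pose], [0.0], atom_classes=np.array([0]))
        e1 = build_envelope([ens, ens], spacing=1.0)
        e2 = build_envelope([ens, ens], spacing=1.0)
        np.testing.assert_array_equal(e1, e2)

    def test_disjoint_addition_only_adds_coverage(self):
        a = _single_atom_pose("C")
        b = _single_atom_pose("C", xyz=(30.0, 0.0, 0.0))
        ens_a = PoseEnsemble("a", [a], [0.0], atom_classes=np.array([0]))
        ens_b = PoseEnsemble("b", [b], [0.0], atom_classes=np.array([0]))
        small = build_envelope([ens_a], spacing=1.0)
        big = build_envelope([ens_a, ens_b], spacing=1.0)
        assert {tuple(p) for p in small} <= {tuple(p) for p in big}

    def test_empty_input_rejected(self):
        with pytest.raises(PreconditionError):
            build_envelope([], spacing=1.0)


class TestScoring:
    def test_all_void_gives_penalty_only(self):
        pose = _single_atom_pose("C")
        env = np.array([[3.0, 0, 0], [0, 3.0, 0]])
        model = SurrogateModel(env, labels=[6, 6], induced_fit_scenario=3,
                               solvation_scenario=1)
        expected = K_INDUCED_FIT * 3 * DILATION_STEP + C_SOLVATION
        assert score_pose_against_model(model, pose, np.array([0])) == \
            pytest.approx(expected, rel=1e-12)

    def test_single_contact_table_value(self):
        # donor particle at the taper optimum from one acceptor atom
        pose = _single_atom_pose("O")
        env = np.array([[TAPER_CENTER, 0.0, 0.0]])
        model = SurrogateModel(env, labels=[1])
        acceptor = np.array([ATOM_CLASSES.index("acceptor")])
        assert score_pose_against_model(model, pose, acceptor) == \
            pytest.approx(COMPAT_TABLE[1, 2], rel=1e-12)

    def test_matches_brute_force_loop(self, small_dataset):
        dataset, true_model, _ = small_dataset
        ens = dataset.entries[0].ensemble
        pose = ens.poses[0]
        model = true_model
        total = model.induced_fit_penalty + \
            C_SOLVATION * model.solvation_scenario
        for p, particle in enumerate(model.envelope):
            d = [np.linalg.norm(particle - pose.coords[j])
                 for j in range(pose.n_atoms)]
            j = int(np.argmin(d))
            deff = d[j] + model.dilation
            if deff > INTERACTION_RANGE:
                continue
            gain = math.exp(-((deff - TAPER_CENTER) ** 2)
                            / (2 * TAPER_WIDTH ** 2))
            total += COMPAT_TABLE[model.labels[p],
                                  ens.atom_classes[j]] * gain
        assert score_pose_against_model(model, pose, ens.atom_classes) == \
            pytest.approx(total, rel=1e-9)


class TestBoltzmannWeights:
    def test_equal_energies_uniform(self):
        np.testing.assert_allclose(boltzmann_weights([1.0] * 4), 0.25)

    def test_rt_ln2_gap(self):
        rt = DEFAULT_MODEL.rt
        w = boltzmann_weights([0.0, rt * math.log(2.0)])
        np.testing.assert_allclose(w, [2 / 3, 1 / 3], rtol=1e-12)

    def test_normalised_positive_even_for_extreme_energies(self):
        w = boltzmann_weights([0.0, 1e5, -1e5])
        assert w.sum() == pytest.approx(1.0)
        assert np.all(w >= 0)


class TestModelPredict:
    def test_single_pose_equals_converted_score(self, small_dataset):
        dataset, model, _ = small_dataset
        ens = dataset.entries[0].ensemble
        single = PoseEnsemble(ens.ligand_id, [ens.poses[0]], [0.0],
                              atom_classes=ens.atom_classes)
        from mqsar.binding_energy import LN10
        score = score_pose_against_model(model, ens.poses[0],
                                         ens.atom_classes)
        expected = model.cal_a * (-score / (LN10 * DEFAULT_MODEL.rt)) \
            + model.cal_b
        assert model_predict(model, single) == pytest.approx(expected,
                                                             rel=1e-9)

    def test_invariant_under_pose_duplication(self, small_dataset):
        dataset, model, _ = small_dataset
        ens = dataset.entries[0].ensemble
        doubled = PoseEnsemble(
            ens.ligand_id, list(ens.poses) + [ens.poses[0]],
            list(ens.conf_energies) + [ens.conf_energies[0]],
            atom_classes=ens.atom_classes)
        assert model_predict(model, doubled) == pytest.approx(
            model_predict(model, ens), rel=1e-9)

    def test_invariant_under_pose_permutation(self, small_dataset):
        dataset, model, _ = small_dataset
        ens = dataset.entries[1].ensemble
        perm = PoseEnsemble(ens.ligand_id, ens.poses[::-1],
                            ens.conf_energies[::-1],
                            atom_classes=ens.atom_classes)
        assert model_predict(model, perm) == pytest.approx(
            model_predict(model, ens), rel=1e-9)

    def test_unreachable_pose_has_zero_weight(self, small_dataset):
        dataset, model, _ = small_dataset
        ens = dataset.entries[0].ensemble
        extended = PoseEnsemble(
            ens.ligand_id, list(ens.poses) + [ens.poses[0]],
            list(ens.conf_energies) + [1e6], atom_classes=ens.atom_classes)
        assert model_predict(model, extended) == pytest.approx(
            model_predict(model, ens), rel=1e-9)


class TestFamilyPredict:
    def test_identical_members_zero_sd(self, small_dataset):
        dataset, model, _ = small_dataset
        family = ModelFamily(model.envelope, [model, model, model])
        mean, sd = family_predict(family, dataset.entries[0].ensemble)
        assert sd == 0.0
        assert mean == pytest.approx(
            model_predict(model, dataset.entries[0].ensemble))

    def test_mean_and_population_sd(self, small_dataset):
        dataset, model, _ = small_dataset
        env = model.envelope
        lo = SurrogateModel(env, model.labels, cal_a=0.0, cal_b=6.0)
        hi = SurrogateModel(env, model.labels, cal_a=0.0, cal_b=8.0)
        mean, sd = family_predict(ModelFamily(env, [lo, hi]),
                                  dataset.entries[0].ensemble)
        assert mean == pytest.approx(7.0)
        assert sd == pytest.approx(1.0)

    def test_member_permutation_invariant(self, small_dataset):
        dataset, model, _ = small_dataset
        env = model.envelope
        members = [SurrogateModel(env, model.labels, cal_a=0.0, cal_b=b)
                   for b in (5.0, 6.0, 9.0)]
        ens = dataset.entries[0].ensemble
        assert family_predict(ModelFamily(env, members), ens) == \
            family_predict(ModelFamily(env, members[::-1]), ens)


class TestGaTrain:
    def test_recovers_noiseless_ground_truth(self, small_dataset,
                                             fast_ga_config):
        dataset, true_model, _ = small_dataset
        family = ga_train(dataset, fast_ga_config, seed=2)
        train = dataset.subset("train")
        preds = np.array([family_predict(family, e.ensemble)[0]
                          for e in train])
        y = np.array([e.exp_pic50 for e in train])
        assert np.sqrt(((preds - y) ** 2).mean()) <= 0.2

    def test_same_seed_bitwise_identical(self, small_dataset,
                                         fast_ga_config):
        dataset, _, _ = small_dataset
        f1 = ga_train(dataset, fast_ga_config, seed=9)
        f2 = ga_train(dataset, fast_ga_config, seed=9)
        assert family_hash(f1) == family_hash(f2)
        for m1, m2 in zip(f1.members, f2.members):
            np.testing.assert_array_equal(m1.labels, m2.labels)

    def test_too_few_training_entries_rejected(self, small_dataset,
                                               fast_ga_config):
        from mqsar.surrogate_qsar import QsarDataset
        dataset, _, _ = small_dataset
        tiny = QsarDataset(entries=dataset.subset("train")[:4],
                           envelope=dataset.envelope)
        with pytest.raises(PreconditionError):
            ga_train(tiny, fast_ga_config, seed=0)

    def test_serialization_round_trip(self, small_dataset, fast_ga_config):
        dataset, _, _ = small_dataset
        family = ga_train(dataset, fast_ga_config, seed=3)
        back = family_from_json(family_to_json(family))
        assert family_hash(back) == family_hash(family)


class TestValidationMetrics:
    def test_perfect_predictions(self):
        r2, frac = predictive_r2([6.0, 7.0, 8.0], [6.0, 7.0, 8.0], 7.0)
        assert r2 == pytest.approx(1.0)
        assert frac == 1.0

    def test_factor_of_ten_boundary_inclusive(self):
        r2, frac = predictive_r2([6.0, 8.0], [7.0, 7.0], 6.0)
        assert frac == 1.0

    def test_hand_computed_four_points(self):
        pred = np.array([6.2, 7.1, 6.8, 8.0])
        exp = np.array([6.0, 7.5, 6.5, 8.2])
        train_mean = 6.9
        num = ((pred - exp) ** 2).sum()
        den = ((exp - train_mean) ** 2).sum()
        r2, frac = predictive_r2(pred, exp, train_mean)
        assert r2 == pytest.approx(1 - num / den, rel=1e-12)
        assert frac == 1.0

    def test_zero_denominator_raises(self):
        with pytest.raises(UndefinedMetricError):
            predictive_r2([6.0, 6.5], [7.0, 7.0], 7.0)

    def test_q2_zero_for_mean_predictor(self, small_dataset):
        dataset, model, _ = small_dataset
        train = dataset.subset("train")
        ybar = float(np.mean([e.exp_pic50 for e in train]))
        mean_model = SurrogateModel(model.envelope, model.labels,
                                    cal_a=0.0, cal_b=ybar)
        family = ModelFamily(model.envelope, [mean_model])
        q2 = cross_validated_r2(family, dataset, n_folds=3, seed=0)
        assert q2 == pytest.approx(0.0, abs=1e-9)

    def test_q2_manual_press_arithmetic(self, small_dataset):
        # a fixed (non-retrained) family: q2 must equal 1 - PRESS/SS
        dataset, model, _ = small_dataset
        family = ModelFamily(model.envelope, [model])
        train = dataset.subset("train")
        y = np.array([e.exp_pic50 for e in train])
        preds = np.array([family_predict(family, e.ensemble)[0]
                          for e in train])
        expected = 1 - ((preds - y) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        q2 = cross_validated_r2(family, dataset, n_folds=4, seed=1)
        assert q2 == pytest.approx(expected, rel=1e-9)


class TestYScramble:
    def test_deterministic_and_degrades_q2(self, small_dataset):
        dataset, _, _ = small_dataset
        trainer = make_trainer(GAConfig(population=20, generations=10,
                                        family_size=3))
        r1 = y_scramble(dataset, trainer, n_rounds=2, seed=4, n_folds=3)
        r2_ = y_scramble(dataset, trainer, n_rounds=2, seed=4, n_folds=3)
        assert r1["q2_rounds"] == r2_["q2_rounds"]
        assert r1["n_rounds"] == 2


class TestConsensusFlag:
    def test_accept_when_both_criteria_hold(self):
        assert consensus_flag(7.0, -5.0, -8.0, -3.0).accepted

    def test_flags_water_preference(self):
        res = consensus_flag(7.0, -5.0, -2.0, -3.0)
        assert not res.accepted
        assert "prefers water" in res.reasons

    def test_tie_resolved_toward_binding(self):
        assert consensus_flag(7.0, -5.0, -3.0, -3.0).accepted

    def test_unfavourable_ff_score_flagged(self):
        res = consensus_flag(7.0, 2.0, -8.0, -3.0)
        assert not res.accepted
        assert "unfavourable force-field score" in res.reasons


def test_classify_atoms_rules():
    mol = chain_molecule(["C", "O", "H"], spacing=1.0)
    # C(hydrophobic), O bonded to H (donor), polar H (donor)
    classes = classify_atoms(mol)
    assert classes[0] == ATOM_CLASSES.index("hydrophobic")
    assert classes[1] == ATOM_CLASSES.index("donor")
    assert classes[2] == ATOM_CLASSES.index("donor")
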