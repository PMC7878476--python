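"""Distance-satisfaction scoring against brute-force oracles and under
geometric transformations."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from xlintegrate.ensemble_satisfaction import (
    StructureEnsemble, StructureModel, pair_distance, read_pdb_ensemble,
    satisfied, score_ensemble, threshold_sensitivity, write_pdb_ensemble,
)
from xlintegrate.linker_chemistry import REGISTRY
from xlintegrate.synthetic_data import (
    gen_chain, gen_ensemble, plant_crosslinks, stage_rng,
)
from xlintegrate.xl_tables import CrosslinkRecord


def ca_model(coords, model_id="1"):
    return StructureModel(
        model_id=model_id,
        atoms={i + 1: {"CA": np.asarray(c, dtype=float)}
               for i, c in enumerate(coords)},
        restypes={i + 1: "A" for i in range(len(coords))})


def make_link(a, b, chem="ADH"):
    spec = REGISTRY[chem]
    ta = sorted(spec.reactive_pair[0])[0]
    tb = sorted(spec.reactive_pair[1])[0]
    return CrosslinkRecord("P", a, ta, "P", b, tb, chem, "syn")


class TestPairDistance:
    def test_three_four_five(self):
        model = ca_model([[0, 0, 0], [3, 4, 0]])
        assert pair_distance(model, 1, 2) == pytest.approx(5.0)

    def test_identical_coordinates(self):
        model = ca_model([[1, 1, 1], [1, 1, 1]])
        assert pair_distance(model, 1, 2) == 0.0

    def test_missing_residue_named(self):
        model = ca_model([[0, 0, 0], [1, 0, 0]])
        with pytest.raises(KeyError, match="99"):
            pair_distance(model, 1, 99)

    def test_matches_norm_oracle(self, rng):
        coords = rng.normal(size=(30, 3)) * 20
        model = ca_model(coords)
        for _ in range(10):
            a, b = rng.choice(30, size=2, replace=False) + 1
            assert pair_distance(model, a, b) == pytest.approx(
                float(np.linalg.norm(coords[a - 1] - coords[b - 1])))

    def test_cb_rule_falls_back_to_ca(self):
        model = ca_model([[0, 0, 0], [3, 4, 0]])
        assert pair_distance(model, 1, 2, atom_rule="CB") == pytest.approx(5.0)


class TestSatisfied:
    @pytest.mark.parametrize("chem, distance, expected", [
        ("ADH", 20.9, True),     # below 21 Å bound
        ("ADH", 21.0, True),     # inclusive boundary
        ("ADH", 21.1, False),    # above bound
        ("DMTMM", 16.0, True),   # inclusive boundary
        ("DMTMM", 16.1, False),
    ])
    def test_threshold_boundaries(self, chem, distance, expected):
        model = ca_model([[0, 0, 0], [distance, 0, 0]])
        assert satisfied(make_link(1, 2, chem), model) is expected

    def test_unknown_chemistry_rejected(self):
        model = ca_model([[0, 0, 0], [1, 0, 0]])
        link = CrosslinkRecord("P", 1, "K", "P", 2, "E", "NOPE", "syn")
        with pytest.raises(KeyError, match="NOPE"):
            satisfied(link, model)


class TestScoreEnsemble:
    def test_all_links_planted_under_threshold(self, small_chain):
        ens = gen_ensemble(small_chain, 1, 0.0, seed=1)
        links, _ = plant_crosslinks(ens.models[0], "DMTMM", 5, 0, seed=2)
        report = score_ensemble(links, ens)
        assert report.per_model_counts[0] == 5
        assert (report.per_link_fractions == 1.0).all()

    def test_empty_inputs_rejected(self, small_ensemble):
        with pytest.raises(ValueError):
            score_ensemble([], small_ensemble)
        with pytest.raises(ValueError):
            score_ensemble([make_link(1, 2)], StructureEnsemble([]))

    def test_matches_brute_force_double_loop(self, small_ensemble):
        """Oracle equivalence on a 20-model x 14-link instance."""
        links, _ = plant_crosslinks(
            small_ensemble.models[0], "ADH", 7, 7, seed=3)
        report = score_ensemble(links, small_ensemble)
        for i, model in enumerate(small_ensemble.models):
            for j, link in enumerate(links):
                xa = model.atoms[link.residue_a]["CA"]
                xb = model.atoms[link.residue_b]["CA"]
                d = float(np.sqrt(((xa - xb) ** 2).sum()))
                assert report.satisfied[i, j] == (
                    d <= REGISTRY[link.chemistry].max_distance)

    def test_histogram_mass_conservation(self, small_ensemble):
        links, _ = plant_crosslinks(
            small_ensemble.models[0], "DMTMM", 4, 4, seed=8)
        report = score_ensemble(links, small_ensemble)
        assert sum(report.histogram().values()) == len(small_ensemble)

    def test_scaling_coordinates_never_increases_counts(self, small_chain):
        ens = gen_ensemble(small_chain, 5, 0.5, seed=4)
        links, _ = plant_crosslinks(ens.models[0], "ADH", 6, 2, seed=5)
        before = score_ensemble(links, ens).per_model_counts
        scaled = StructureEnsemble([
            StructureModel(m.model_id,
                           {r: {"CA": a["CA"] * 10.0} for r, a in m.atoms.items()},
                           dict(m.restypes))
            for m in ens.models])
        after = score_ensemble(links, scaled).per_model_counts
        assert (after <= before).all()

    def test_rigid_motion_invariance(self, small_chain):
        ens = gen_ensemble(small_chain, 3, 1.0, seed=6)
        links, _ = plant_crosslinks(ens.models[0], "DMTMM", 5, 3, seed=7)
        rot = Rotation.from_rotvec([0.3, -1.1, 0.7])
        moved = StructureEnsemble([
            StructureModel(m.model_id,
                           {r: {"CA": rot.apply(a["CA"]) + np.array([5., -3., 12.])}
                            for r, a in m.atoms.items()},
                           dict(m.restypes))
            for m in ens.models])
        np.testing.assert_array_equal(
            score_ensemble(links, ens).satisfied,
            score_ensemble(links, moved).satisfied)

    def test_missing_residue_flagged_not_dropped(self):
        full = ca_model([[0, 0, 0], [5, 0, 0], [10, 0, 0]], "1")
        partial = StructureModel("2", {1: full.atoms[1], 2: full.atoms[2]},
                                 {1: "A", 2: "A"})
        links = [make_link(1, 3, "ADH")]
        report = score_ensemble(links, StructureEnsemble([full, partial]))
        assert report.satisfied[0, 0]
        assert not report.satisfied[1, 0]
        assert report.flagged_missing[1, 0]

    def test_best_model_ties_all_reported(self):
        m1 = ca_model([[0, 0, 0], [5, 0, 0]], "1")
        m2 = ca_model([[0, 0, 0], [6, 0, 0]], "2")
        report = score_ensemble([make_link(1, 2)],
                                StructureEnsemble([m1, m2]))
        assert report.best_models == ["1", "2"]


class TestThresholdSensitivity:
    def test_zero_like_and_huge_thresholds(self, small_ensemble):
        links, _ = plant_crosslinks(
            small_ensemble.models[0], "ADH", 3, 3, seed=9)
        counts = threshold_sensitivity(links, small_ensemble,
                                       [0.01, 1e6])
        assert (counts[:, 0] == 0).all()
        assert (counts[:, 1] == len(links)).all()

    def test_monotone_and_matches_brute_force(self, small_ensemble):
        links, _ = plant_crosslinks(
            small_ensemble.models[0], "ADH", 5, 5, seed=10)
        thresholds = [5.0, 10.0, 20.0, 40.0]
        counts = threshold_sensitivity(links, small_ensemble, thresholds)
        assert (np.diff(counts, axis=1) >= 0).all()
        for i, model in enumerate(small_ensemble.models):
            for k, t in enumerate(thresholds):
                expected = sum(
                    np.linalg.norm(model.atoms[l.residue_a]["CA"]
                                   - model.atoms[l.residue_b]["CA"]) <= t
                    for l in links)
                assert counts[i, k] == expected

    def test_nonpositive_threshold_rejected(self, small_ensemble):
        with pytest.raises(ValueError):
            threshold_sensitivity([], small_ensemble, [0.0])


class TestPdbRoundTrip:
    def test_multi_model_round_trip(self, tmp_path, small_chain):
        ens = gen_ensemble(small_chain, 3, 1.0, seed=11)
        path = tmp_path / "ensemble.pdb"
        write_pdb_ensemble(ens, str(path))
        back = read_pdb_ensemble(str(path))
        assert len(back) == 3
        for orig, loaded in zip(ens.models, back.models):
            assert loaded.residues() == orig.residues()
            for r in orig.residues():
                np.testing.assert_allclose(
                    loaded.atoms[r]["CA"], orig.atoms[r]["CA"], atol=1e-3)
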