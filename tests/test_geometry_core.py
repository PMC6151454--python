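"""Superposition, ensemble statistics and screw decomposition."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cambind.errors import DegeneracyError, PairingError
from cambind.geometry_core import (
    RigidTransform,
    ensemble_rmsd_to_mean,
    screw_decompose,
    superpose,
)
from cambind.structure_io import CoordinateSet, SelectionSpec
from cambind.synthetic_data import ToyComplexParams, make_toy_complex

from conftest import grid_min_rmsd


def _cs(coords):
    coords = np.asarray(coords, dtype=float)
    return CoordinateSet(labels=[("A", i, "CA") for i in range(len(coords))],
                         coords=coords)


class TestSuperpose:
    def test_identical_sets_give_zero_rmsd_and_identity(self):
        pts = _cs(np.random.default_rng(0).normal(0, 5, (10, 3)))
        res = superpose(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(res.transform.rotation, np.eye(3), atol=1e-9)

    def test_recovers_constructed_rotation_and_translation(self):
        rng = np.random.default_rng(1)
        ref = _cs(rng.normal(0, 5, (8, 3)))
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        t = np.array([1.0, 2.0, 3.0])
        mobile = _cs(ref.coords @ R.T + t)
        res = superpose(mobile, ref)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        recovered = res.transform
        assert np.allclose(recovered.rotation @ R, np.eye(3), atol=1e-9)
        assert np.allclose(recovered.apply(mobile.coords), ref.coords, atol=1e-9)

    def test_rmsd_symmetric_in_argument_order(self):
        rng = np.random.default_rng(2)
        a = _cs(rng.normal(0, 3, (12, 3)))
        b = _cs(a.coords + rng.normal(0, 0.5, (12, 3)))
        assert superpose(a, b).rmsd == pytest.approx(superpose(b, a).rmsd, abs=1e-9)

    def test_superposed_rmsd_never_exceeds_raw_rmsd(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.normal(0, 4, (7, 3))
            b = rng.normal(0, 4, (7, 3))
            raw = float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
            assert superpose(_cs(a), _cs(b)).rmsd <= raw + 1e-12

    def test_matches_rotation_grid_oracle_on_noisy_clouds(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            a = rng.normal(0, 3, (5, 3))
            b = a @ Rotation.random(random_state=rng).as_matrix().T
            b += rng.normal(0, 0.3, (5, 3))
            assert superpose(_cs(a), _cs(b)).rmsd == pytest.approx(
                grid_min_rmsd(a, b), abs=1e-3
            )

    def test_length_mismatch_and_degenerate_inputs_raise(self):
        with pytest.raises(PairingError):
            superpose(_cs(np.zeros((4, 3))), _cs(np.zeros((5, 3))))
        with pytest.raises(DegeneracyError):
            superpose(_cs(np.zeros((2, 3))), _cs(np.zeros((2, 3))))
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(DegeneracyError):
            superpose(_cs(line), _cs(line))


class TestEnsembleStats:
    def test_identical_models_give_zero(self):
        ens = make_toy_complex(ToyComplexParams(n_models=3))
        stats = ensemble_rmsd_to_mean(ens, SelectionSpec("P", (1, 24), "backbone"))
        assert stats.mean_rmsd == pytest.approx(0.0, abs=1e-9)
        assert stats.sd_rmsd == pytest.approx(0.0, abs=1e-9)

    def test_pure_rigid_motion_between_models_gives_zero(self):
        from cambind.structure_io import Atom, Residue, StructureEnsemble

        base = make_toy_complex(ToyComplexParams()).models[0]
        R = Rotation.from_euler("xyz", [10, 40, 70], degrees=True).as_matrix()
        t = np.array([5.0, -3.0, 2.0])
        moved = [
            Residue(r.chain_id, r.seq_number, r.res_name,
                    [Atom(a.name, a.element, R @ a.coords + t) for a in r.atoms],
                    r.het)
            for r in base
        ]
        ens = StructureEnsemble(models=[base, moved])
        stats = ensemble_rmsd_to_mean(ens, SelectionSpec("P", (1, 24), "backbone"))
        assert stats.mean_rmsd == pytest.approx(0.0, abs=1e-6)

    def test_gaussian_noise_matches_closed_form(self):
        # m noisy copies about their mean: E[RMSD] ~ sigma*sqrt(3)*sqrt((m-1)/m)
        sigma, m = 0.5, 20
        ens = make_toy_complex(ToyComplexParams(noise_sigma=sigma, n_models=m, seed=11))
        stats = ensemble_rmsd_to_mean(ens, SelectionSpec("P", (1, 24), "backbone"))
        expected = sigma * np.sqrt(3.0) * np.sqrt((m - 1) / m)
        assert stats.mean_rmsd == pytest.approx(expected, rel=0.10)


class TestScrewDecompose:
    def test_identity_transform(self):
        s = screw_decompose(RigidTransform.identity())
        assert s.angle == pytest.approx(0.0, abs=1e-9)
        assert s.translation_along_axis == pytest.approx(0.0, abs=1e-9)

    def test_half_turn_about_z(self):
        R = Rotation.from_euler("z", 180, degrees=True).as_matrix()
        s = screw_decompose(RigidTransform(R, np.zeros(3)))
        assert s.angle == pytest.approx(180.0, abs=1e-6)
        assert abs(s.axis[2]) == pytest.approx(1.0, abs=1e-9)

    def test_pure_translation_axis_along_translation(self):
        t = np.array([3.0, 4.0, 0.0])
        s = screw_decompose(RigidTransform(np.eye(3), t))
        assert s.angle == pytest.approx(0.0, abs=1e-9)
        assert s.translation_along_axis == pytest.approx(5.0)
        assert np.allclose(s.axis, t / 5.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_roundtrip_on_random_transforms(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            t = RigidTransform(
                Rotation.random(random_state=rng).as_matrix(),
                rng.normal(0, 10, 3),
            )
            back = screw_decompose(t).recompose()
            assert np.abs(back.rotation - t.rotation).max() < 1e-6
            assert np.abs(back.translation - t.translation).max() < 1e-6
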