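"""Superposition, ensemble RMSD classification and the Welch comparison."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy import stats

from tsh3scan.ensembles import (
    ConformerSet,
    RegionSpec,
    compare_ensembles,
    fraction_tandem,
    gww_gly_distance,
    read_multi_model_pdb,
    rmsd_to_reference,
    superpose,
    write_multi_model_pdb,
)
from tsh3scan.synthetic import gen_conformers, make_reference_tandem


def grid_oracle_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Brute-force minimum RMSD over a hierarchically refined rotation grid.

    Independent of the SVD path: rotations are enumerated as Euler angles,
    the translation is removed by centering, and the grid is refined around
    the best cell until the angular step is ~1e-4 rad.
    """
    Pc = mobile - mobile.mean(axis=0)
    Qc = reference - reference.mean(axis=0)
    n = len(Pc)
    center = np.zeros(3)
    span = np.pi
    best = np.inf
    for _ in range(8):
        grids = [np.linspace(c - span, c + span, 13) for c in center]
        A, B, C = np.meshgrid(*grids, indexing="ij")
        angles = np.stack([A.ravel(), B.ravel(), C.ravel()], axis=1)
        mats = Rotation.from_euler("zyz", angles).as_matrix()
        rotated = np.einsum("rij,nj->rni", mats, Pc)
        rmsds = np.sqrt(((rotated - Qc) ** 2).sum(axis=(1, 2)) / n)
        k = int(np.argmin(rmsds))
        if rmsds[k] < best:
            best = float(rmsds[k])
            center = angles[k]
        span /= 4.0
    return best


def _toy_points(rng, n=4):
    return rng.normal(scale=5.0, size=(n, 3))


def _rigid(rng, points):
    R = Rotation.random(random_state=np.random.RandomState(int(rng.integers(2**31)))).as_matrix()
    t = rng.normal(scale=20.0, size=3)
    return points @ R.T + t


class TestSuperpose:
    def test_identity(self, rng):
        pts = _toy_points(rng, 10)
        res = superpose(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert not res.degenerate

    def test_rigid_motion_invariance(self, rng):
        pts = _toy_points(rng, 12)
        for _ in range(5):
            moved = _rigid(rng, pts)
            res = superpose(moved, pts)
            assert res.rmsd < 1e-8
            # returned transform actually maps mobile onto reference
            back = moved @ res.rotation.T + res.translation
            assert np.allclose(back, pts, atol=1e-8)
            assert np.linalg.det(res.rotation) == pytest.approx(1.0)

    def test_agrees_with_rotation_grid_oracle(self, rng):
        for _ in range(5):
            mobile = _toy_points(rng, 4)
            reference = _toy_points(rng, 4)
            res = superpose(mobile, reference)
            assert res.rmsd == pytest.approx(
                grid_oracle_rmsd(mobile, reference), abs=1e-3
            )

    def test_agrees_with_mdanalysis(self, rng):
        from MDAnalysis.analysis.rms import rmsd as mda_rmsd

        for _ in range(5):
            mobile = _toy_points(rng, 25)
            reference = _toy_points(rng, 25)
            ours = superpose(mobile, reference).rmsd
            theirs = mda_rmsd(mobile, reference, center=True, superposition=True)
            assert ours == pytest.approx(theirs, abs=1e-9)

    def test_symmetric_under_swap(self, rng):
        a, b = _toy_points(rng, 9), _toy_points(rng, 9)
        assert superpose(a, b).rmsd == pytest.approx(superpose(b, a).rmsd, abs=1e-10)

    def test_superposed_never_exceeds_unsuperposed(self, rng):
        for _ in range(20):
            a, b = _toy_points(rng, 8), _toy_points(rng, 8)
            raw = float(np.sqrt(((a - b) ** 2).sum() / len(a)))
            assert superpose(a, b).rmsd <= raw + 1e-12

    def test_reflection_not_allowed(self, rng):
        pts = _toy_points(rng, 6)
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        res = superpose(mirrored, pts)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0)
        assert res.rmsd > 1e-6  # a proper rotation cannot undo a reflection

    def test_collinear_flagged_but_solved(self):
        line = np.array([[float(i), 0.0, 0.0] for i in range(5)])
        res = superpose(line, line[::-1])
        assert res.degenerate
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_bad_inputs_rejected(self, rng):
        pts = _toy_points(rng, 5)
        with pytest.raises(ValueError, match="mismatch"):
            superpose(pts, pts[:4])
        with pytest.raises(ValueError, match="at least 3"):
            superpose(pts[:2], pts[:2])


class TestRmsdToReference:
    def test_rigid_motions_give_zero(self, rng):
        region = RegionSpec(((1, 20),))
        reference = {i + 1: np.array(p) for i, p in enumerate(_toy_points(rng, 20))}
        ref_arr = np.array([reference[i] for i in sorted(reference)])
        models = []
        for _ in range(5):
            moved = _rigid(rng, ref_arr)
            models.append({i + 1: moved[i] for i in range(20)})
        rmsds = rmsd_to_reference(ConformerSet("rigid", models), reference, region)
        assert np.allclose(rmsds, 0.0, atol=1e-8)

    def test_gaussian_noise_scaling(self, rng):
        """Per-coordinate Gaussian noise sigma gives mean RMSD near
        sigma*sqrt(3) (slightly below after removing the 6 fitted rigid
        degrees of freedom)."""
        region = RegionSpec(((160, 211), (229, 283)))
        reference = make_reference_tandem(region)
        resids = region.residue_ids()
        sigma = 1.0
        models = []
        for _ in range(30):
            models.append({r: reference[r] + rng.normal(scale=sigma, size=3) for r in resids})
        rmsds = rmsd_to_reference(ConformerSet("noise", models), reference, region)
        assert np.mean(rmsds) == pytest.approx(sigma * np.sqrt(3.0), rel=0.10)
        # per-model agreement with an independent superposition route
        from MDAnalysis.analysis.rms import rmsd as mda_rmsd

        ref_arr = np.array([reference[r] for r in resids])
        for model, ours in zip(models[:5], rmsds[:5]):
            arr = np.array([model[r] for r in resids])
            assert ours == pytest.approx(
                mda_rmsd(arr, ref_arr, center=True, superposition=True), abs=1e-9
            )

    def test_planted_fractions(self):
        conformers, manifest = gen_conformers(
            n_models=30, near_native_fraction=0.2, seed=13
        )
        reference = make_reference_tandem()
        rmsds = rmsd_to_reference(conformers, reference)
        assert fraction_tandem(rmsds, 5.0) == pytest.approx(0.2)
        labels = [manifest.ensemble_labels[("construct", i)] for i in range(30)]
        assert [r < 5.0 for r in rmsds] == labels

    def test_missing_residue_named_in_error(self, rng):
        region = RegionSpec(((1, 5),))
        reference = {i: np.array([float(i), 0.0, 1.0 * i**2]) for i in range(1, 6)}
        models = [dict(reference), {k: v for k, v in reference.items() if k != 3}]
        with pytest.raises(ValueError, match="model 1") as err:
            rmsd_to_reference(ConformerSet("broken", models), reference, region)
        assert "3" in str(err.value)


class TestCompareEnsembles:
    def test_identical_lists(self):
        a = [2.0, 3.0, 4.0, 5.0]
        cmp = compare_ensembles(a, list(a))
        assert cmp.t_statistic == pytest.approx(0.0)
        assert cmp.p_value == pytest.approx(1.0)

    def test_separated_constants_with_jitter(self, rng):
        a = 2.0 + rng.normal(scale=1e-3, size=20)
        b = 10.0 + rng.normal(scale=1e-3, size=20)
        cmp = compare_ensembles(a, b, threshold=5.0)
        assert cmp.p_value < 1e-10
        assert cmp.fraction_tandem_a == 1.0
        assert cmp.fraction_tandem_b == 0.0

    def test_welch_matches_hand_calculation(self):
        a = [2.1, 2.0, 1.9, 2.2]
        b = [10.2, 9.9, 10.1]
        ma, mb = np.mean(a), np.mean(b)
        va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
        se2 = va / len(a) + vb / len(b)
        t_hand = (ma - mb) / np.sqrt(se2)
        df = se2**2 / (
            (va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1)
        )
        p_hand = 2.0 * stats.t.sf(abs(t_hand), df)
        cmp = compare_ensembles(a, b)
        assert cmp.t_statistic == pytest.approx(t_hand, abs=1e-6)
        assert cmp.p_value == pytest.approx(p_hand, abs=1e-6)

    def test_p_invariant_under_swap(self, rng):
        a = list(rng.normal(4.0, 1.0, size=15))
        b = list(rng.normal(6.0, 2.0, size=12))
        assert compare_ensembles(a, b).p_value == pytest.approx(
            compare_ensembles(b, a).p_value
        )

    def test_zero_variance_equal_means_convention(self):
        cmp = compare_ensembles([3.0, 3.0], [3.0, 3.0])
        assert (cmp.t_statistic, cmp.p_value) == (0.0, 1.0)

    def test_fraction_monotone_in_threshold(self, rng):
        rmsds = list(rng.uniform(0.0, 12.0, size=40))
        fracs = [fraction_tandem(rmsds, thr) for thr in (1.0, 3.0, 5.0, 8.0, 15.0)]
        assert fracs == sorted(fracs)

    def test_short_lists_rejected(self):
        with pytest.raises(ValueError):
            compare_ensembles([1.0], [2.0, 3.0])


class TestGwwDistance:
    def test_examples(self):
        model = {
            5: np.array([0.0, 0.0, 0.0]),
            70: np.array([3.0, 4.0, 0.0]),
            80: np.array([0.0, 0.0, 0.0]),
        }
        assert gww_gly_distance(model, 5, 70) == pytest.approx(5.0)
        assert gww_gly_distance(model, 5, 80) == pytest.approx(0.0)

    def test_random_pairs_match_norm(self, rng):
        for _ in range(50):
            p, q = rng.normal(size=3), rng.normal(size=3)
            model = {1: p, 2: q}
            assert gww_gly_distance(model, 1, 2) == pytest.approx(
                float(np.linalg.norm(p - q))
            )

    def test_missing_residue(self):
        with pytest.raises(ValueError, match="99"):
            gww_gly_distance({1: np.zeros(3)}, 1, 99)


class TestPdbRoundtrip:
    def test_write_read_preserves_ca_coordinates(self, tmp_path, rng):
        region = RegionSpec(((160, 211), (229, 283)))
        conformers, _ = gen_conformers(
            n_models=4, near_native_fraction=0.5, region=region, seed=17
        )
        path = tmp_path / "ensemble.pdb"
        write_multi_model_pdb(conformers, path)
        loaded = read_multi_model_pdb(path)
        assert len(loaded.models) == 4
        for orig, back in zip(conformers.models, loaded.models):
            assert sorted(orig) == sorted(back)
            for resid in orig:
                assert np.allclose(orig[resid], back[resid], atol=2e-3)
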