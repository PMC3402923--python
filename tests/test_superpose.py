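"""Kabsch fitting against a brute-force rotation-grid oracle, and
alignment-guided ensemble superposition."""

import numpy as np
import pytest

from resfunc.conservation import make_aligned_set
from resfunc.superpose import (
    CorrespondenceError,
    FitError,
    kabsch_fit,
    superpose_ensemble,
    superpose_structure,
)
from resfunc.synth import synth_helix


# --- independent oracle -----------------------------------------------------

def _euler_zyx(alpha, beta, gamma):
    ca, sa = np.cos(alpha), np.sin(alpha)
    cb, sb = np.cos(beta), np.sin(beta)
    cg, sg = np.cos(gamma), np.sin(gamma)
    rz = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
    ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    rx = np.array([[1, 0, 0], [0, cg, -sg], [0, sg, cg]])
    return rz @ ry @ rx


def grid_min_rmsd(mobile, target, levels=8, steps=13):
    """Brute-force minimum RMSD over proper rotations by nested Euler-angle
    grid refinement; the optimal translation for a fixed rotation aligns
    the centroids, so only rotations are searched."""
    a = mobile - mobile.mean(axis=0)
    b = target - target.mean(axis=0)
    center = np.zeros(3)
    width = np.pi
    best = np.inf
    for _ in range(levels):
        axes = [center[i] + np.linspace(-width, width, steps) for i in range(3)]
        for alpha in axes[0]:
            for beta in axes[1]:
                for gamma in axes[2]:
                    rot = _euler_zyx(alpha, beta, gamma)
                    rmsd = np.sqrt(np.mean(np.sum((a @ rot.T - b) ** 2, axis=1)))
                    if rmsd < best:
                        best = rmsd
                        center = np.array([alpha, beta, gamma])
        # keep two grid spacings on each side so a curved valley in Euler
        # space cannot strand the refinement one cell away from the optimum
        width = 4 * width / (steps - 1)
    return best


# --- kabsch_fit -------------------------------------------------------------

def _rotvec(v):
    theta = np.linalg.norm(v)
    if theta < 1e-12:
        return np.eye(3)
    k = v / theta
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(theta) * kx + (1 - np.cos(theta)) * kx @ kx


class TestKabschFit:
    def test_identical_sets_give_zero_rmsd_identity_rotation(self, rng):
        pts = rng.normal(size=(6, 3))
        res = kabsch_fit(pts, pts)
        assert res.rmsd < 1e-12
        assert np.allclose(res.rotation, np.eye(3), atol=1e-10)

    def test_recovers_applied_rigid_transform(self, rng):
        pts = rng.normal(size=(5, 3))
        rot = _euler_zyx(np.pi / 2, 0, 0)  # 90 degrees about z
        target = pts @ rot.T + np.array([1.0, 2.0, 3.0])
        res = kabsch_fit(pts, target)
        assert res.rmsd < 1e-10
        assert np.allclose(res.rotation, rot, atol=1e-9)
        assert np.allclose(res.translation, [1, 2, 3], atol=1e-9)

    def test_rotation_is_always_proper(self, rng):
        for _ in range(20):
            res = kabsch_fit(rng.normal(size=(5, 3)), rng.normal(size=(5, 3)))
            assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_mirror_image_cannot_be_fit_to_zero(self, rng):
        pts = rng.normal(size=(6, 3))
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        assert kabsch_fit(pts, mirrored).rmsd > 0.1

    def test_rmsd_symmetric_in_arguments(self, rng):
        a, b = rng.normal(size=(7, 3)), rng.normal(size=(7, 3))
        assert kabsch_fit(a, b).rmsd == pytest.approx(
            kabsch_fit(b, a).rmsd, abs=1e-9
        )

    def test_rmsd_invariant_under_rigid_transform_of_inputs(self, rng):
        a, b = rng.normal(size=(6, 3)), rng.normal(size=(6, 3))
        base = kabsch_fit(a, b).rmsd
        rot = _rotvec(rng.normal(size=3))
        moved = a @ rot.T + rng.normal(size=3) * 5
        assert kabsch_fit(moved, b).rmsd == pytest.approx(base, abs=1e-9)

    def test_rmsd_squared_is_mean_squared_deviation(self, rng):
        a, b = rng.normal(size=(6, 3)), rng.normal(size=(6, 3))
        res = kabsch_fit(a, b)
        assert res.rmsd**2 == pytest.approx(
            np.mean(res.per_residue_deviation**2), rel=1e-12
        )

    def test_too_few_pairs_rejected(self):
        with pytest.raises(FitError, match="3 pairs"):
            kabsch_fit(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_geometry_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(FitError, match="collinear"):
            kabsch_fit(line, line)

    def test_matches_grid_oracle_on_stretched_triangle(self):
        mobile = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
        target = np.array([[0.0, 0, 0], [2, 0, 0], [0, 1, 0]])
        fitted = kabsch_fit(mobile, target).rmsd
        oracle = grid_min_rmsd(mobile, target)
        assert fitted == pytest.approx(oracle, abs=1e-3)
        assert fitted <= oracle + 1e-9  # the closed form is the true minimum


# --- ensemble superposition -------------------------------------------------

def identity_correspondence(ids, sequence):
    return make_aligned_set("corr", [(i, sequence) for i in ids], ids[0])


class TestSuperposeEnsemble:
    def test_reference_alone_fits_itself_exactly(self, helix20):
        corr = identity_correspondence(["helix20"], helix20.sequence)
        (res,) = superpose_ensemble([helix20], helix20, corr)
        assert res.rmsd < 1e-9
        assert res.n_pairs == 20

    def test_rigidly_moved_copy_fits_to_zero(self, helix20, rng):
        rot = _rotvec(rng.normal(size=3))
        moved = helix20.transformed(rot, np.array([4.0, -2.0, 7.0]))
        corr = identity_correspondence(["helix20"], helix20.sequence)
        results = superpose_ensemble([helix20, moved], helix20, corr)
        assert all(r.rmsd < 1e-9 for r in results)

    def test_output_independent_of_structure_order(self, helix20, rng):
        import dataclasses

        noisy = dataclasses.replace(
            helix20, id="noisy", coords=helix20.coords + rng.normal(size=(20, 3)) * 0.4
        )
        corr = make_aligned_set(
            "corr",
            [("helix20", helix20.sequence), ("noisy", helix20.sequence)],
            "helix20",
        )
        fwd = superpose_ensemble([helix20, noisy], helix20, corr)
        rev = superpose_ensemble([noisy, helix20], helix20, corr)
        by_id_fwd = {r.mobile_id: r.rmsd for r in fwd}
        by_id_rev = {r.mobile_id: r.rmsd for r in rev}
        assert by_id_fwd == pytest.approx(by_id_rev)

    def test_local_displacement_shows_only_in_its_window(self):
        import dataclasses

        reference = synth_helix(60, model_id="ref")
        coords = reference.coords.copy()
        coords[29:50] += np.array([2.0, 0.0, 0.0])  # residues 30-50 shifted
        shifted = dataclasses.replace(reference, id="shifted", coords=coords)
        corr = make_aligned_set(
            "corr",
            [("ref", reference.sequence), ("shifted", reference.sequence)],
            "ref",
        )
        res = superpose_structure(shifted, reference, corr)
        inside = res.per_residue_deviation[29:50]
        outside = np.concatenate(
            [res.per_residue_deviation[:29], res.per_residue_deviation[50:]]
        )
        assert inside.mean() > outside.mean()
        assert inside.min() > 0.5

    def test_alignment_gap_columns_are_skipped(self):
        reference = synth_helix(10, model_id="ref")
        shorter = synth_helix(8, model_id="mob")
        corr = make_aligned_set(
            "corr",
            [("ref", reference.sequence), ("mob", shorter.sequence + "--")],
            "ref",
        )
        res = superpose_structure(shorter, reference, corr)
        assert res.n_pairs == 8

    def test_sequence_mismatch_is_a_correspondence_error(self, helix20):
        corr = make_aligned_set(
            "corr", [("helix20", "W" * 20)], "helix20"
        )
        with pytest.raises(CorrespondenceError):
            superpose_structure(helix20, helix20, corr)

    def test_study_ensemble_recovered_near_construction_noise(self, study):
        results = superpose_ensemble(
            list(study.ensemble), study.reference_structure, study.correspondence
        )
        rmsds = [r.rmsd for r in results if r.mobile_id != "SRY"]
        # members were built as rigid moves + 0.5 Å/coordinate noise, so the
        # fitted rmsd must sit near 0.5 * sqrt(3), far from the rigid offsets
        assert all(0.5 < r < 1.3 for r in rmsds)
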