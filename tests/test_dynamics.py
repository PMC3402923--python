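"""Frame subsampling and per-residue RMSD profiles."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from resfunc.dynamics import (
    Trajectory,
    TrajectoryError,
    annotate_dynamics,
    compare_dynamics,
    per_residue_rmsd,
    subsample_frames,
)
from resfunc.synth import FluctuationSpec, synth_helix, synth_trajectory


def static_trajectory(n_res=6, n_frames=5, interval=1.0):
    ref = synth_helix(n_res, model_id="ref")
    return synth_trajectory(
        ref, FluctuationSpec(sigma=np.zeros(n_res), n_frames=n_frames,
                             frame_interval_ps=interval, seed=0)
    )


class TestSubsample:
    def test_1000ps_at_25ps_keeps_41_frames(self):
        traj = static_trajectory(n_frames=1001, interval=1.0)
        sub = subsample_frames(traj, 25.0)
        assert sub.n_frames == 41
        assert sub.frame_interval_ps == 25.0
        assert sub.duration_ps == 1000.0

    def test_matching_interval_is_identity(self):
        traj = static_trajectory(n_frames=5, interval=25.0)
        assert subsample_frames(traj, 25.0) is traj

    def test_non_multiple_interval_rejected(self):
        traj = static_trajectory(n_frames=10, interval=5.0)
        with pytest.raises(TrajectoryError, match="multiple"):
            subsample_frames(traj, 7.0)

    def test_time_zero_frame_always_kept(self):
        traj = static_trajectory(n_frames=11, interval=5.0)
        sub = subsample_frames(traj, 10.0)
        assert sub.times_ps[0] == 0.0
        assert sub.n_frames == 6


class TestPerResidueRmsd:
    def test_static_trajectory_scores_zero_everywhere(self):
        profile = per_residue_rmsd(static_trajectory(), fit="ca")
        assert np.allclose(profile.mean_rmsd, 0.0, atol=1e-12)

    def test_single_residue_displacement_closed_form(self):
        # one residue displaced by 0 then d with no fitting: rmsd = d / sqrt(2)
        ref = synth_helix(5, model_id="r")
        d = 1.8
        moved = ref.coords.copy()
        moved[2] += np.array([d, 0.0, 0.0])
        frames = (
            ref,
            dataclasses.replace(ref, id="f1"),
            dataclasses.replace(ref, id="f2", coords=moved),
        )
        profile = per_residue_rmsd(
            Trajectory(frames=frames, frame_interval_ps=25.0), fit="none"
        )
        assert profile.mean_rmsd[2] == pytest.approx(d / np.sqrt(2))
        assert np.allclose(np.delete(profile.mean_rmsd, 2), 0.0)

    def test_gaussian_sigma_recovery_without_fit(self):
        # E||eps||^2 = 3 sigma^2, so rmsd_i -> sigma_i * sqrt(3)
        sigma = np.linspace(0.5, 1.5, 10)
        ref = synth_helix(10, model_id="r")
        traj = synth_trajectory(
            ref, FluctuationSpec(sigma=sigma, n_frames=501, seed=11)
        )
        profile = per_residue_rmsd(traj, fit="none")
        assert np.all(np.abs(profile.mean_rmsd / (sigma * np.sqrt(3)) - 1) < 0.05)

    @pytest.mark.parametrize("n_frames,tol", [(51, 0.25), (201, 0.12), (1001, 0.06)])
    def test_recovery_bias_shrinks_with_frame_count(self, n_frames, tol):
        sigma = np.full(8, 0.8)
        ref = synth_helix(8, model_id="r")
        traj = synth_trajectory(
            ref, FluctuationSpec(sigma=sigma, n_frames=n_frames, seed=5)
        )
        profile = per_residue_rmsd(traj, fit="none")
        rel = np.abs(profile.mean_rmsd / (sigma * np.sqrt(3)) - 1)
        assert rel.mean() < tol

    def test_invariant_under_constant_rigid_transform_with_fit(self, rng):
        sigma = np.full(12, 0.6)
        ref = synth_helix(12, model_id="r")
        traj = synth_trajectory(
            ref, FluctuationSpec(sigma=sigma, n_frames=40, seed=3)
        )
        theta = 0.8
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        shift = np.array([3.0, -7.0, 2.0])
        moved = Trajectory(
            frames=tuple(f.transformed(rot, shift) for f in traj.frames),
            frame_interval_ps=traj.frame_interval_ps,
        )
        base = per_residue_rmsd(traj, fit="ca").mean_rmsd
        transformed = per_residue_rmsd(moved, fit="ca").mean_rmsd
        assert np.allclose(base, transformed, atol=1e-6)

    def test_mean_square_profile_matches_whole_structure_deviation(self):
        # Parseval-style identity of the definition (no fitting)
        sigma = np.linspace(0.2, 1.0, 6)
        ref = synth_helix(6, model_id="r")
        traj = synth_trajectory(
            ref, FluctuationSpec(sigma=sigma, n_frames=30, seed=9)
        )
        profile = per_residue_rmsd(traj, fit="none")
        coords = traj.coords_array()
        whole = np.mean(np.sum((coords[1:] - coords[0]) ** 2, axis=2))
        assert np.mean(profile.mean_rmsd**2) == pytest.approx(whole)

    def test_single_frame_rejected(self):
        ref = synth_helix(5)
        traj = Trajectory(frames=(ref,), frame_interval_ps=25.0)
        with pytest.raises(TrajectoryError, match="2 frames"):
            per_residue_rmsd(traj)


class TestCompareDynamics:
    def test_profile_against_itself_is_all_zero(self):
        traj = static_trajectory()
        p = per_residue_rmsd(traj)
        df = compare_dynamics(p, p)
        assert np.allclose(df["delta"], 0.0)
        assert df.attrs["flagged"] == []

    def test_doubled_sigma_residue_has_largest_delta(self):
        n = 20
        focus = 7  # 0-based index of residue 8
        ref = synth_helix(n, model_id="r")
        sigma = np.full(n, 0.5)
        sigma_var = sigma.copy()
        sigma_var[focus] *= 2
        a = per_residue_rmsd(
            synth_trajectory(ref, FluctuationSpec(sigma, 201, seed=21)), fit="none"
        )
        b = per_residue_rmsd(
            synth_trajectory(ref, FluctuationSpec(sigma_var, 201, seed=22)), fit="none"
        )
        df = compare_dynamics(a, b)
        assert df["delta"].idxmax() == focus
        assert df.loc[focus, "delta"] > 0

    def test_mismatched_numbering_rejected(self):
        p5 = per_residue_rmsd(static_trajectory(n_res=5))
        p6 = per_residue_rmsd(static_trajectory(n_res=6))
        with pytest.raises(TrajectoryError, match="numbering"):
            compare_dynamics(p5, p6)


class TestAnnotateDynamics:
    def test_missing_or_empty_tier_table_defaults_to_no_variant(self):
        profile = per_residue_rmsd(static_trajectory())
        for tiers in (None, pd.DataFrame(columns=["position", "tier"])):
            df = annotate_dynamics(profile, tiers)
            assert set(df["tier"]) == {"NO_VARIANT"}
            assert list(df.attrs["tier_means"]) == ["NO_VARIANT"]

    def test_conserved_tier_has_lowest_mean_rmsd_by_construction(self):
        n = 30
        conserved = list(range(1, 11))
        sigma = np.array([0.3 if i + 1 in conserved else 1.0 for i in range(n)])
        ref = synth_helix(n, model_id="r")
        profile = per_residue_rmsd(
            synth_trajectory(ref, FluctuationSpec(sigma, 301, seed=2)), fit="none"
        )
        tiers = pd.DataFrame(
            {"position": conserved, "tier": ["HMG_CONSERVED"] * len(conserved)}
        )
        df = annotate_dynamics(profile, tiers)
        means = df.attrs["tier_means"]
        assert means["HMG_CONSERVED"] < means["NO_VARIANT"]
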