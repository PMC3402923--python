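"""Peptide displacement in the receptor frame and condition ranking."""

import dataclasses
import math

import numpy as np
import pytest

from resfunc.docking import (
    ComplexTrajectory,
    Condition,
    DockingError,
    compare_conditions,
    peptide_displacement,
)
from resfunc.dynamics import Trajectory
from resfunc.synth import synth_complex_trajectory, synth_helix, tether_stationary_mean


def build_complex(frame_edits, n_rec=10, n_pep=4, condition=Condition.DOCKED):
    """Complex trajectory from a list of (receptor shift, peptide shift)."""
    rec = synth_helix(n_rec, chain="A")
    pep = synth_helix(n_pep, chain="B", start_number=200)
    base = np.vstack([rec.coords, pep.coords + np.array([10.0, 0, 0])])
    numbers = np.concatenate([rec.residue_numbers, pep.residue_numbers])
    names = rec.residue_names + pep.residue_names
    chains = rec.chains + pep.chains
    frames = []
    for t, (rec_shift, pep_shift) in enumerate([(0, 0)] + list(frame_edits)):
        coords = base.copy()
        coords[:n_rec] += rec_shift
        coords[n_rec:] += pep_shift
        frames.append(
            dataclasses.replace(
                synth_helix(n_rec + n_pep),
                id=f"f{t}",
                residue_numbers=numbers,
                residue_names=names,
                coords=coords,
                chains=chains,
            )
        )
    traj = Trajectory(frames=tuple(frames), frame_interval_ps=25.0)
    return ComplexTrajectory(
        trajectory=traj,
        receptor_residues=frozenset(int(r) for r in rec.residue_numbers),
        peptide_residues=frozenset(int(r) for r in pep.residue_numbers),
        condition=condition,
    )


class TestPeptideDisplacement:
    def test_static_complex_scores_zero(self):
        cplx = build_complex([(0.0, 0.0)] * 4)
        series = peptide_displacement(cplx)
        assert np.allclose(series.displacement, 0.0, atol=1e-12)

    def test_pure_peptide_translation_measured_exactly(self):
        shift = np.array([3.0, 0.0, 4.0])  # length 5
        cplx = build_complex([(0.0, shift)])
        series = peptide_displacement(cplx)
        assert series.displacement[0] == pytest.approx(5.0, abs=1e-9)

    def test_joint_translation_cancels_in_receptor_frame(self):
        shift = np.array([2.0, -1.0, 3.0])
        cplx = build_complex([(shift, shift)])
        series = peptide_displacement(cplx)
        assert series.displacement[0] == pytest.approx(0.0, abs=1e-9)

    def test_invariant_under_global_rigid_transform(self):
        cplx = build_complex([(0.0, np.array([1.0, 2.0, 0.0]))] * 3)
        base = peptide_displacement(cplx).displacement
        theta = 1.1
        rot = np.array(
            [
                [math.cos(theta), -math.sin(theta), 0],
                [math.sin(theta), math.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        moved = dataclasses.replace(
            cplx,
            trajectory=Trajectory(
                frames=tuple(
                    f.transformed(rot, np.array([5.0, 6.0, 7.0]))
                    for f in cplx.trajectory.frames
                ),
                frame_interval_ps=25.0,
            ),
        )
        assert np.allclose(peptide_displacement(moved).displacement, base, atol=1e-9)

    def test_com_metric_ignores_internal_noise(self, rng):
        internal = rng.normal(size=(4, 3)) * 0.3
        internal -= internal.mean(axis=0)  # pure shape change, no COM shift
        cplx = build_complex([(0.0, internal)])
        com = peptide_displacement(cplx, metric="com")
        rmsd = peptide_displacement(cplx, metric="rmsd")
        assert com.displacement[0] == pytest.approx(0.0, abs=1e-9)
        assert rmsd.displacement[0] > 0.1

    def test_empty_selection_rejected(self):
        cplx = build_complex([(0.0, 0.0)])
        with pytest.raises(DockingError, match="non-empty"):
            ComplexTrajectory(
                trajectory=cplx.trajectory,
                receptor_residues=cplx.receptor_residues | cplx.peptide_residues,
                peptide_residues=frozenset(),
                condition=Condition.FREE,
            )

    def test_selections_must_cover_trajectory(self):
        cplx = build_complex([(0.0, 0.0)])
        with pytest.raises(DockingError, match="cover"):
            ComplexTrajectory(
                trajectory=cplx.trajectory,
                receptor_residues=cplx.receptor_residues,
                peptide_residues=frozenset(list(cplx.peptide_residues)[:-1]),
                condition=Condition.FREE,
            )


class TestSyntheticRegimes:
    def test_free_with_zero_step_is_static(self):
        rec, pep = synth_helix(8), synth_helix(4)
        cplx = synth_complex_trajectory(
            rec, pep, Condition.FREE,
            params={"step": 0.0, "receptor_sigma": 0.0},
            seed=1, n_frames=20,
        )
        series = peptide_displacement(cplx)
        assert np.allclose(series.displacement, 0.0, atol=1e-12)

    def test_docked_mean_matches_tether_stationary_value(self):
        # rigid pose offsets ~ N(0, sigma^2 I): E|g| = 2 sigma sqrt(2/pi)
        sigma = 0.5
        means = []
        for seed in range(8):
            cplx = synth_complex_trajectory(
                synth_helix(8), synth_helix(4), Condition.DOCKED,
                params={"tether_sigma": sigma, "receptor_sigma": 0.0},
                seed=seed, n_frames=101,
            )
            means.append(peptide_displacement(cplx).mean_displacement)
        grand = np.mean(means)
        se = np.std(means, ddof=1) / math.sqrt(len(means))
        assert abs(grand - tether_stationary_mean(sigma)) < 3 * max(se, 1e-3)

    def test_random_walk_displacement_grows_with_time(self):
        cplx = synth_complex_trajectory(
            synth_helix(8), synth_helix(4), Condition.FREE,
            params={"step": 0.5, "receptor_sigma": 0.0},
            seed=3, n_frames=121,
        )
        d = peptide_displacement(cplx).displacement
        third = len(d) // 3
        assert d[-third:].mean() > d[:third].mean()

    def test_tethered_displacement_is_bounded(self):
        cplx = synth_complex_trajectory(
            synth_helix(8), synth_helix(4), Condition.DOCKED,
            params={"tether_sigma": 0.5, "receptor_sigma": 0.0},
            seed=3, n_frames=121,
        )
        d = peptide_displacement(cplx).displacement
        third = len(d) // 3
        # no systematic growth: late and early thirds agree within noise
        assert d[-third:].mean() < d[:third].mean() + 3 * d.std()


class TestCompareConditions:
    def make_series(self, seed, condition, **params):
        cplx = synth_complex_trajectory(
            synth_helix(10), synth_helix(4), condition,
            params=params, seed=seed, n_frames=61,
        )
        return peptide_displacement(cplx)

    def test_identical_series_tie_with_zero_difference(self):
        a = self.make_series(1, Condition.DOCKED, tether_sigma=0.5)
        b = dataclasses.replace(a, condition=Condition.FREE)
        df = compare_conditions([a, b])
        assert df.attrs["pairwise"][("DOCKED", "FREE")] == pytest.approx(0.0)

    def test_intermediate_tether_ranks_in_the_middle(self):
        series = [
            self.make_series(5, Condition.DOCKED, tether_sigma=0.5),
            self.make_series(6, Condition.DOCKED_ALA, tether_sigma=1.0),
            self.make_series(7, Condition.FREE, step=0.5),
        ]
        df = compare_conditions(series)
        assert list(df["condition"]) == ["FREE", "DOCKED_ALA", "DOCKED"]

    def test_duplicate_condition_labels_rejected(self):
        a = self.make_series(1, Condition.DOCKED, tether_sigma=0.5)
        with pytest.raises(DockingError, match="duplicate"):
            compare_conditions([a, a])

    def test_single_series_rejected(self):
        a = self.make_series(1, Condition.DOCKED, tether_sigma=0.5)
        with pytest.raises(DockingError, match="2 conditions"):
            compare_conditions([a])
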