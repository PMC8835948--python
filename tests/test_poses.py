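"""Pose screening: reference points, distances, RMSD grouping, descriptors."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import biotite.structure as struc

from spectrobind import poses as ps
from spectrobind import simulate
from spectrobind.poses import (
    InvalidStructureError,
    Pose,
    dda_distance,
    distance_timeseries,
    filter_by_distance,
    group_models,
    load_pose_set,
    mir_5prime_point,
    pairwise_ligand_rmsd,
    pocket_charge_descriptor,
    screen_poses,
    trp_ring_center,
)

from conftest import make_atoms, make_pose


def _rotate_pose(pose, rot, shift=(0.0, 0.0, 0.0)):
    out_rec = pose.receptor.copy()
    out_lig = pose.ligand.copy()
    out_rec.coord = rot.apply(out_rec.coord) + np.asarray(shift)
    out_lig.coord = rot.apply(out_lig.coord) + np.asarray(shift)
    return Pose(receptor=out_rec, ligand=out_lig, rank=pose.rank, model_id=pose.model_id)


# ---------------------------------------------------------------------------
# Reference points

def test_trp_ring_center_is_centroid_and_equivariant(toy_pose):
    center = trp_ring_center(toy_pose)
    rec = toy_pose.receptor
    ring = rec[(rec.res_id == 214) & np.isin(rec.atom_name, ps.TRP_RING_ATOMS)]
    np.testing.assert_allclose(center, ring.coord.mean(axis=0) / 10.0, rtol=1e-12)
    shifted = toy_pose.receptor.copy()
    shifted.coord = shifted.coord + np.array([10.0, 20.0, 30.0])  # 1,2,3 nm
    moved = Pose(receptor=shifted, ligand=toy_pose.ligand, rank=1)
    np.testing.assert_allclose(
        trp_ring_center(moved), center + np.array([1.0, 2.0, 3.0]), atol=1e-10
    )


def test_trp_ring_center_missing_atoms_listed():
    rec = make_atoms(
        [(214, "TRP", n, "C", (0, 0, 0)) for n in ("CG", "CD1", "CD2", "NE1")]
    )
    lig = make_atoms([(1, "U", "P", "P", (1, 1, 1))], chain_id="B")
    with pytest.raises(InvalidStructureError, match="CE2"):
        trp_ring_center(Pose(receptor=rec, ligand=lig, rank=1))


def test_mir_5prime_point_p_and_fallbacks():
    lig_p = make_atoms([(1, "U", "P", "P", (10.0, 10.0, 10.0))], chain_id="B")
    rec = make_atoms([(1, "GLY", "CA", "C", (0, 0, 0))])
    fp = mir_5prime_point(Pose(receptor=rec, ligand=lig_p, rank=1))
    np.testing.assert_allclose(fp.coord, (1.0, 1.0, 1.0))
    assert fp.atom_name == "P" and not fp.fallback

    lig_o = make_atoms([(1, "U", "O5'", "O", (20.0, 0.0, 0.0))], chain_id="B")
    fp2 = mir_5prime_point(Pose(receptor=rec, ligand=lig_o, rank=1))
    np.testing.assert_allclose(fp2.coord, (2.0, 0.0, 0.0))
    assert fp2.fallback and fp2.atom_name == "O5'"

    with pytest.raises(InvalidStructureError):
        mir_5prime_point(
            Pose(receptor=rec, ligand=make_atoms([(1, "U", "C1'", "C", (0, 0, 0))], "B"), rank=1)
        )


def test_mir_5prime_point_selected_by_residue_number_not_order():
    # residue 2 appears first in the file ordering
    lig = make_atoms(
        [(2, "G", "P", "P", (50.0, 0, 0)), (1, "U", "P", "P", (10.0, 0, 0))],
        chain_id="B",
    )
    rec = make_atoms([(1, "GLY", "CA", "C", (0, 0, 0))])
    fp = mir_5prime_point(Pose(receptor=rec, ligand=lig, rank=1))
    np.testing.assert_allclose(fp.coord, (1.0, 0, 0))


# ---------------------------------------------------------------------------
# Distances

def test_dda_distance_by_construction():
    pose = make_pose(dda_nm=4.2)
    assert dda_distance(pose) == pytest.approx(4.2, abs=1e-5)


def test_dda_distance_rotation_invariant(rng):
    pose = make_pose(dda_nm=4.2)
    d0 = dda_distance(pose)
    for _ in range(5):
        rot = Rotation.random(random_state=rng.integers(2**31))
        assert dda_distance(_rotate_pose(pose, rot, rng.normal(size=3))) == pytest.approx(
            d0, abs=1e-5
        )


def test_distance_timeseries_constant_and_mean():
    p1, p2 = make_pose(4.0), make_pose(4.2)
    series, mean = distance_timeseries([p1, p2])
    np.testing.assert_allclose(series, [4.0, 4.2], atol=1e-5)
    assert mean == pytest.approx(4.1, abs=1e-5)


def test_distance_timeseries_oscillating_trajectory():
    frames, truth = simulate.gen_trajectory(
        n_frames=100, dda_base=4.1, amplitude=0.1, noise_sd=0.0, seed=1
    )
    series, mean = distance_timeseries(frames)
    assert mean == pytest.approx(4.1, abs=0.01)
    np.testing.assert_allclose(series, truth["dda_true_nm"], atol=1e-6)


# ---------------------------------------------------------------------------
# Window filter

def test_filter_by_distance_spec_example():
    poses_set = [make_pose(d, rank=i + 1) for i, d in enumerate([3.0, 4.0, 4.5, 5.5])]
    report = filter_by_distance(poses_set, measured_R=4.3, tolerance=0.5, dye_offset=0.1)
    selected = sorted(round(r.d_da, 1) for r in report.selected)
    assert selected == [4.0, 4.5]


def test_filter_table_distances_all_selected():
    """The six shortlisted models' initial distances all pass the default window."""
    initial = [4.2, 4.3, 3.8, 3.8, 4.3, 3.7]
    poses_set = [make_pose(d, rank=i + 1) for i, d in enumerate(initial)]
    report = filter_by_distance(poses_set)
    assert len(report.selected) == 6


def test_filter_all_pass_with_infinite_window():
    poses_set = [make_pose(d, rank=i + 1) for i, d in enumerate([1.0, 4.0, 9.0])]
    report = filter_by_distance(poses_set, measured_R=5.0, tolerance=1e6, dye_offset=0.0)
    assert len(report.selected) == 3


def test_filter_agrees_with_brute_force_scan():
    poses_list, truth = simulate.gen_pose_set(n=100, dda_mean=4.0, dda_sd=0.9, seed=5)
    report = filter_by_distance(poses_list)
    lo, hi = report.window
    brute = {
        p.model_id
        for p, d in zip(poses_list, truth["dda_true_nm"])
        if lo <= d + report.dye_offset <= hi
    }
    assert {r.model_id for r in report.selected} == brute


def test_window_formulations_equivalent():
    report = filter_by_distance([make_pose(4.0)], measured_R=4.3, tolerance=0.5,
                                dye_offset=0.1)
    lo, hi = report.window
    blo, bhi = report.bare_window
    assert (blo, bhi) == pytest.approx((lo - 0.1, hi - 0.1))
    for rec in report.records:
        assert rec.selected == (lo <= rec.d_da + 0.1 <= hi) == (blo <= rec.d_da <= bhi)


# ---------------------------------------------------------------------------
# RMSD and grouping

def test_rmsd_identity_and_translation():
    pose = make_pose(4.0)
    assert pairwise_ligand_rmsd(pose, pose) == pytest.approx(0.0, abs=1e-6)
    moved = Pose(receptor=pose.receptor.copy(), ligand=pose.ligand.copy(), rank=2)
    moved.ligand.coord = moved.ligand.coord + np.array([2.0, 0.0, 0.0])  # 0.2 nm
    assert pairwise_ligand_rmsd(pose, moved) == pytest.approx(0.2, abs=1e-6)


def test_rmsd_removed_by_superposition(rng):
    """A globally rotated copy has zero ligand RMSD after receptor superposition."""
    pose = make_pose(4.0)
    for _ in range(5):
        rot = Rotation.random(random_state=rng.integers(2**31))
        rotated = _rotate_pose(pose, rot, rng.normal(scale=5.0, size=3))
        assert pairwise_ligand_rmsd(pose, rotated) == pytest.approx(0.0, abs=1e-6)


def test_rmsd_atom_mismatch_error():
    pose = make_pose(4.0)
    noP = make_pose(4.0, with_phosphate=False)
    with pytest.raises(InvalidStructureError):
        pairwise_ligand_rmsd(pose, noP)


def test_group_models_two_groups():
    a = make_pose(4.0, rank=1)
    b = make_pose(4.0, rank=2)  # identical placement to a
    c = make_pose(4.0, direction=(1.0, 0.0, 0.0), rank=3)  # far away
    groups = group_models([c, a, b], rmsd_threshold=0.1)
    assert [len(g) for g in groups] == [2, 1]
    assert groups[0][0].rank == 1  # representative = lowest rank
    assert groups[1][0].rank == 3


def test_group_models_degenerate_thresholds():
    trio = [make_pose(4.0, rank=i + 1) for i in range(3)]
    assert len(group_models(trio, rmsd_threshold=1e3)) == 1
    assert len(group_models(trio, rmsd_threshold=0.0)) == 3


def test_screen_produces_valid_partition():
    poses_list, _ = simulate.gen_pose_set(n=30, seed=9)
    report = screen_poses(poses_list)
    selected = report.selected
    group_ids = {r.group_id for r in selected}
    assert all(r.group_id is not None for r in selected)
    for gid in group_ids:
        members = [r for r in selected if r.group_id == gid]
        reps = [r for r in members if r.representative]
        assert len(reps) == 1
        assert reps[0].rank == min(m.rank for m in members)
    assert all(r.group_id is None for r in report.records if not r.selected)


# ---------------------------------------------------------------------------
# Pocket charge

def test_pocket_charge_constructed_pocket():
    rec = make_atoms(
        [(214, "TRP", n, "C", c) for n, c in zip(ps.TRP_RING_ATOMS, np.zeros((9, 3)))]
        + [
            (10, "ARG", "CZ", "C", (1.0, 0, 0)),
            (11, "ARG", "CZ", "C", (0, 1.0, 0)),
            (12, "ARG", "CZ", "C", (0, 0, 1.0)),
            (13, "GLU", "CD", "C", (1.0, 1.0, 0)),
            (20, "LYS", "NZ", "N", (90.0, 0, 0)),  # far: outside any cutoff
        ]
    )
    lig = make_atoms([(1, "U", "P", "P", (0.5, 0.5, 0.5))], chain_id="B")
    pose = Pose(receptor=rec, ligand=lig, rank=1)
    net, residues = pocket_charge_descriptor(pose, cutoff=0.5)
    names = {r for _, r in residues}
    assert net == 3 - 1 + 0  # 3 Arg, 1 Glu, Trp neutral
    assert "LYS" not in names


def test_pocket_charge_empty_and_monotone():
    rec = make_atoms([(10, "ARG", "CZ", "C", (100.0, 0, 0))])
    lig = make_atoms([(1, "U", "P", "P", (0, 0, 0))], chain_id="B")
    pose = Pose(receptor=rec, ligand=lig, rank=1)
    net, residues = pocket_charge_descriptor(pose, cutoff=0.5)
    assert net == 0 and residues == []
    prev: set = set()
    for cutoff in (1.0, 5.0, 11.0):
        _, res = pocket_charge_descriptor(pose, cutoff=cutoff)
        ids = {i for i, _ in res}
        assert prev <= ids
        prev = ids
    assert prev == {10}


# ---------------------------------------------------------------------------
# I/O

def test_pose_set_pdb_roundtrip(tmp_path):
    poses_list, truth = simulate.gen_pose_set(n=8, seed=13)
    path = tmp_path / "poses.pdb"
    simulate.write_pose_set(poses_list, truth, path)
    loaded = load_pose_set(path)
    assert len(loaded) == 8
    for orig, back in zip(poses_list, loaded):
        assert dda_distance(back) == pytest.approx(dda_distance(orig), abs=1e-3)
    assert (tmp_path / "poses.pdb.truth.json").exists()


def test_report_tsv(tmp_path):
    import pandas as pd

    poses_list, _ = simulate.gen_pose_set(n=10, seed=3)
    report = screen_poses(poses_list)
    out = tmp_path / "report.tsv"
    ps.report_to_tsv(report, out)
    df = pd.read_csv(out, sep="\t")
    assert list(df.columns) == [
        "model_id", "rank", "D_DA_nm", "selected", "group_id", "representative",
    ]
    assert len(df) == 10
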