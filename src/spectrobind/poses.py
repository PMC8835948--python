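"""FRET-restrained screening of rigid docking poses of a protein-RNA complex.

Each pose carries a receptor (protein) and a ligand (RNA) as biotite
``AtomArray`` objects.  The donor-acceptor surrogate distance D_DA is
measured from the centroid of the nine indole-ring heavy atoms of the donor
tryptophan to the ligand's 5'-terminal phosphorus (with O5'/C5' fallback).
Poses are kept when D_DA plus the dye-linker offset falls inside the
experimentally measured distance window, grouped by ligand RMSD after
receptor C-alpha superposition (greedy single linkage in docking-rank
order), and one representative — the best-ranked member — is chosen per
group.  A trajectory of frames can be monitored with the same distance.

Coordinates are Angstrom in files (PDB convention) and nm in every report;
the conversion is centralised in ``A_PER_NM``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "A_PER_NM",
    "TRP_RING_ATOMS",
    "Pose",
    "PoseRecord",
    "DistanceReport",
    "FivePrimePoint",
    "InvalidStructureError",
    "trp_ring_center",
    "mir_5prime_point",
    "dda_distance",
    "filter_by_distance",
    "pairwise_ligand_rmsd",
    "group_models",
    "screen_poses",
    "distance_timeseries",
    "pocket_charge_descriptor",
    "load_pose_set",
    "report_to_tsv",
]

A_PER_NM = 10.0

#: the nine heavy atoms of the tryptophan indole ring system
TRP_RING_ATOMS = ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2")

#: formal charges of receptor residues at physiological pH
RESIDUE_CHARGE = {"ARG": 1, "LYS": 1, "ASP": -1, "GLU": -1}


class InvalidStructureError(ValueError):
    pass


@dataclass
class Pose:
    """A docking pose: receptor and ligand atom arrays plus docking rank."""

    receptor: struc.AtomArray
    ligand: struc.AtomArray
    rank: int
    model_id: str = ""

    def __post_init__(self) -> None:
        if self.ligand.array_length() == 0:
            raise InvalidStructureError("ligand is empty")
        if not self.model_id:
            self.model_id = f"model_{self.rank}"


class FivePrimePoint(NamedTuple):
    coord: np.ndarray  # nm
    atom_name: str  # "P", "O5'" or "C5'"
    fallback: bool  # True when P was absent


@dataclass
class PoseRecord:
    model_id: str
    rank: int
    d_da: float  # nm, bare geometric distance
    selected: bool
    group_id: int | None = None
    representative: bool = False


@dataclass
class DistanceReport:
    """Per-pose screening outcome plus the window actually applied."""

    records: list[PoseRecord]
    dye_offset: float  # nm
    window: tuple[float, float]  # nm, on D_DA + dye_offset
    fallback_atoms: dict[str, str] = field(default_factory=dict)

    @property
    def selected(self) -> list[PoseRecord]:
        return [r for r in self.records if r.selected]

    @property
    def representatives(self) -> list[PoseRecord]:
        return [r for r in self.records if r.representative]

    @property
    def bare_window(self) -> tuple[float, float]:
        """The equivalent window on the bare D_DA (offset subtracted)."""
        return (self.window[0] - self.dye_offset, self.window[1] - self.dye_offset)


def trp_ring_center(pose: Pose, residue_number: int = 214) -> np.ndarray:
    """Centroid (nm) of the indole-ring heavy atoms of the donor tryptophan."""
    rec = pose.receptor
    sel = rec[(rec.res_id == residue_number) & (rec.res_name == "TRP")]
    if sel.array_length() == 0:
        raise InvalidStructureError(f"no TRP residue {residue_number} in receptor")
    present = set(sel.atom_name)
    missing = [a for a in TRP_RING_ATOMS if a not in present]
    if missing:
        raise InvalidStructureError(
            f"TRP {residue_number} missing indole ring atoms: {missing}"
        )
    ring = sel[np.isin(sel.atom_name, TRP_RING_ATOMS)]
    return ring.coord.mean(axis=0) / A_PER_NM


def mir_5prime_point(pose: Pose) -> FivePrimePoint:
    """Coordinate (nm) of the ligand's 5'-terminal reference atom.

    Uses the phosphorus of the 5'-terminal (lowest-numbered) nucleotide;
    falls back to O5' then C5' when no phosphate is present, recording the
    fallback.  Selection is by residue number, not file order.
    """
    lig = pose.ligand
    first = int(lig.res_id.min())
    nt = lig[lig.res_id == first]
    for name, fb in (("P", False), ("O5'", True), ("C5'", True)):
        hit = nt[nt.atom_name == name]
        if hit.array_length() > 0:
            return FivePrimePoint(hit.coord[0] / A_PER_NM, name, fb)
    raise InvalidStructureError(
        f"5'-terminal nucleotide {first} has none of P/O5'/C5'"
    )


def dda_distance(pose: Pose, donor_residue: int = 214) -> float:
    """Euclidean donor-acceptor surrogate distance in nm."""
    center = trp_ring_center(pose, donor_residue)
    tip = mir_5prime_point(pose).coord
    return float(np.linalg.norm(center - tip))


def filter_by_distance(
    poses: Sequence[Pose],
    measured_R: float = 4.3,
    tolerance: float = 0.5,
    dye_offset: float = 0.1,
    donor_residue: int = 214,
) -> DistanceReport:
    """Keep poses whose D_DA + dye_offset lies within measured_R +/- tolerance.

    With the defaults (R = 4.3 nm, tol = 0.5 nm, offset = 0.1 nm) the window
    on the dye-corrected distance is [3.9, 4.9] nm, equivalently [3.8, 4.8]
    nm on the bare D_DA.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    lo, hi = measured_R - tolerance, measured_R + tolerance
    records, fallbacks = [], {}
    for pose in poses:
        d = dda_distance(pose, donor_residue)
        fp = mir_5prime_point(pose)
        if fp.fallback:
            fallbacks[pose.model_id] = fp.atom_name
        records.append(
            PoseRecord(
                model_id=pose.model_id,
                rank=pose.rank,
                d_da=d,
                selected=lo <= d + dye_offset <= hi,
            )
        )
    return DistanceReport(
        records=records, dye_offset=dye_offset, window=(lo, hi), fallback_atoms=fallbacks
    )


def _matched_selection(
    a: struc.AtomArray, b: struc.AtomArray, atom_names: Sequence[str]
) -> tuple[struc.AtomArray, struc.AtomArray]:
    sa = a[np.isin(a.atom_name, atom_names)]
    sb = b[np.isin(b.atom_name, atom_names)]
    key_a = list(zip(sa.res_id.tolist(), sa.atom_name.tolist()))
    key_b = list(zip(sb.res_id.tolist(), sb.atom_name.tolist()))
    if key_a != key_b:
        only_a = sorted(set(key_a) - set(key_b))
        only_b = sorted(set(key_b) - set(key_a))
        raise InvalidStructureError(
            f"atom-set mismatch between poses: only in A {only_a}, only in B {only_b}"
        )
    return sa, sb


def pairwise_ligand_rmsd(
    pose_a: Pose,
    pose_b: Pose,
    ligand_atoms: Sequence[str] = ("P",),
    superpose_atoms: Sequence[str] = ("CA",),
) -> float:
    """Ligand RMSD (nm) after least-squares superposition of the receptors.

    The receptors are superposed on their C-alpha atoms (optimal Kabsch
    rotation + translation); the fitted transform is applied to pose B's
    ligand and the RMSD is evaluated over the ligand reference atoms
    (default: phosphorus).
    """
    ca_a, ca_b = _matched_selection(pose_a.receptor, pose_b.receptor, superpose_atoms)
    if ca_a.array_length() < 3:
        raise InvalidStructureError("need >= 3 superposition atoms on the receptor")
    _, transform = struc.superimpose(ca_a, ca_b)
    lig_a, lig_b = _matched_selection(pose_a.ligand, pose_b.ligand, ligand_atoms)
    if lig_a.array_length() == 0:
        raise InvalidStructureError(f"no ligand atoms named {list(ligand_atoms)}")
    lig_b_fit = transform.apply(lig_b)
    return float(struc.rmsd(lig_a, lig_b_fit)) / A_PER_NM


def group_models(
    poses: Sequence[Pose],
    rmsd_threshold: float = 0.1,
    ligand_atoms: Sequence[str] = ("P",),
) -> list[list[Pose]]:
    """Greedy single-linkage grouping of poses in docking-rank order.

    Poses are visited by ascending rank; a pose joins the first existing
    group containing any member within ``rmsd_threshold`` (nm), else founds a
    new group.  Deterministic for a given rank ordering; the first-ranked
    member of each group is its representative (index 0 of each sublist).
    """
    if rmsd_threshold < 0:
        raise ValueError("rmsd_threshold must be non-negative")
    ordered = sorted(poses, key=lambda p: p.rank)
    groups: list[list[Pose]] = []
    for pose in ordered:
        placed = False
        for grp in groups:
            if any(
                pairwise_ligand_rmsd(member, pose, ligand_atoms) < rmsd_threshold
                for member in grp
            ):
                grp.append(pose)
                placed = True
                break
        if not placed:
            groups.append([pose])
    return groups


def screen_poses(
    poses: Sequence[Pose],
    measured_R: float = 4.3,
    tolerance: float = 0.5,
    dye_offset: float = 0.1,
    rmsd_threshold: float = 0.1,
    donor_residue: int = 214,
) -> DistanceReport:
    """Full screen: distance filter, then RMSD grouping of the survivors."""
    report = filter_by_distance(poses, measured_R, tolerance, dye_offset, donor_residue)
    selected_ids = {r.model_id for r in report.selected}
    survivors = [p for p in poses if p.model_id in selected_ids]
    groups = group_models(survivors, rmsd_threshold)
    by_id = {r.model_id: r for r in report.records}
    for gid, grp in enumerate(groups):
        for k, pose in enumerate(grp):
            rec = by_id[pose.model_id]
            rec.group_id = gid
            rec.representative = k == 0
    return report


def distance_timeseries(
    frames: Sequence[Pose], donor_residue: int = 214
) -> tuple[np.ndarray, float]:
    """Per-frame D_DA along a trajectory and its arithmetic mean (nm)."""
    if not frames:
        raise ValueError("empty trajectory")
    dists = []
    for i, frame in enumerate(frames):
        try:
            dists.append(dda_distance(frame, donor_residue))
        except InvalidStructureError as err:
            raise InvalidStructureError(f"frame {i}: {err}") from err
    arr = np.asarray(dists)
    return arr, float(arr.mean())


def pocket_charge_descriptor(
    pose: Pose, cutoff: float = 0.5
) -> tuple[int, list[tuple[int, str]]]:
    """Net formal charge of receptor residues contacting the ligand.

    A residue contacts the ligand when any of its atoms lies within
    ``cutoff`` nm of any ligand atom; Arg/Lys count +1, Asp/Glu -1, others 0.
    Returns (net charge, [(res_id, res_name), ...]).  This is a light
    electrostatic-complementarity descriptor, not a Poisson-Boltzmann
    calculation.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    from scipy.spatial.distance import cdist

    rec, lig = pose.receptor, pose.ligand
    dmin = cdist(rec.coord, lig.coord).min(axis=1) / A_PER_NM
    contact_mask = dmin <= cutoff
    residues: list[tuple[int, str]] = []
    seen = set()
    for rid, rname in zip(rec.res_id[contact_mask], rec.res_name[contact_mask]):
        key = int(rid)
        if key not in seen:
            seen.add(key)
            residues.append((key, str(rname)))
    net = sum(RESIDUE_CHARGE.get(rname, 0) for _, rname in residues)
    return net, residues


# ---------------------------------------------------------------------------
# I/O

def load_pose_set(
    path: str | Path, receptor_chain: str = "A", ligand_chain: str = "B"
) -> list[Pose]:
    """Load a multi-MODEL PDB pose set, splitting receptor and ligand by chain."""
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    poses = []
    for i in range(stack.stack_depth()):
        arr = stack[i]
        receptor = arr[arr.chain_id == receptor_chain]
        ligand = arr[arr.chain_id == ligand_chain]
        if receptor.array_length() == 0:
            raise InvalidStructureError(f"model {i + 1}: no chain {receptor_chain}")
        poses.append(Pose(receptor=receptor, ligand=ligand, rank=i + 1))
    return poses


def report_to_tsv(report: DistanceReport, path: str | Path) -> None:
    """Write the screening report as TSV."""
    import pandas as pd

    rows = [
        {
            "model_id": r.model_id,
            "rank": r.rank,
            "D_DA_nm": round(r.d_da, 4),
            "selected": r.selected,
            "group_id": r.group_id if r.group_id is not None else "",
            "representative": r.representative,
        }
        for r in report.records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
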