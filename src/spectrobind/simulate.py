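"""Synthetic instrument data with the statistical structure the pipeline assumes.

Generators for: 1:1-binding quenching titrations with multiplicative
lognormal noise; multi-exponential TCSPC decays convolved with a Gaussian
IRF under Poisson counting noise; Bell-Evans rupture-force ensembles drawn
by exact inverse-CDF sampling; AFM retract curves with an eFJC tether
stretch; and toy receptor/ligand pose sets with a controllable donor-
acceptor distance distribution, written as standards-compliant PDB.

Every generator is a pure function of (parameters, seed) — a fixed seed
yields byte-identical output — and returns the ground-truth parameters
alongside the data.  The ``write_*`` helpers persist data with a JSON
provenance sidecar holding those truths.

Defaults mirror the study conditions the pipeline targets: 5 uM fluorophore
titrated with 0.5-15 uM quencher; TCSPC at 0.055 ns/channel over 50 ns with
a 0.8 ns FWHM IRF and 1e4 peak counts; rupture ensembles at nN/s loading
rates around a ~110 pN modal force; pose sets of 50 models with D_DA
centred near 4 nm.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .forcespec import KB, ForceCurve, efjc_force
from .poses import A_PER_NM, Pose, TRP_RING_ATOMS, trp_ring_center
from .quench import TitrationSeries, sv_quadratic_predict
from .tcspc import DecayTrace, multiexp_model, reconvolve

__all__ = [
    "gen_titration",
    "biexponential_for_mean",
    "gen_decay",
    "sample_rupture_forces",
    "gen_force_curve",
    "gen_pose_set",
    "gen_trajectory",
    "write_titration_csv",
    "write_decay_table",
    "write_pose_set",
    "DEFAULT_QUENCHER_GRID",
]

#: default titration design: zero point plus 0.5-15 uM quencher (molar)
DEFAULT_QUENCHER_GRID = np.array(
    [0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 7.5, 10.0, 12.5, 15.0]
) * 1e-6


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sig2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sig2 / 2.0, sigma=np.sqrt(sig2), size=size)


# ---------------------------------------------------------------------------
# Quenching titrations

def gen_titration(
    K_SV_true: float = 2.7e4,
    hsa0: float = 5e-6,
    quencher_concs: np.ndarray | None = None,
    noise_cv: float = 0.02,
    model: str = "linear",
    f0: float = 1e6,
    seed: int = 0,
) -> tuple[TitrationSeries, dict]:
    """Simulate a quenching titration.

    ``model="linear"`` gives F = F0/(1 + K [Q]); ``model="quadratic"`` gives
    F = F0 (1 - fraction_quenched) from the 1:1 depletion expression.  All
    intensities (including the zero-quencher point) carry multiplicative
    lognormal noise with coefficient of variation ``noise_cv``.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    q = DEFAULT_QUENCHER_GRID.copy() if quencher_concs is None else np.asarray(
        quencher_concs, dtype=float
    )
    if model == "linear":
        f = f0 / (1.0 + K_SV_true * q)
    elif model == "quadratic":
        f = f0 * (1.0 - sv_quadratic_predict(K_SV_true, hsa0, q))
    else:
        raise ValueError(f"unknown model {model!r}")
    rng = np.random.default_rng(seed)
    f = f * _lognormal_factor(rng, noise_cv, f.shape)
    series = TitrationSeries(fluorophore_conc=hsa0, quencher_concs=q, intensities=f)
    truth = {
        "kind": "titration",
        "K_SV_true": K_SV_true,
        "hsa0": hsa0,
        "noise_cv": noise_cv,
        "model": model,
        "f0": f0,
        "seed": seed,
    }
    return series, truth


# ---------------------------------------------------------------------------
# TCSPC decays

def biexponential_for_mean(
    target_mean: float, tau_ratio: tuple[float, float] = (0.4, 1.15)
) -> list[tuple[float, float]]:
    """Two (amplitude, lifetime) components whose amplitude-weighted mean is
    exactly ``target_mean`` ns.

    Lifetimes are ``tau_ratio`` times the target mean (one below, one above);
    amplitudes (summing to 1) follow from the lever rule.
    """
    lo, hi = tau_ratio
    if not (lo < 1.0 < hi):
        raise ValueError("tau_ratio must bracket 1")
    tau1, tau2 = lo * target_mean, hi * target_mean
    a1 = (tau2 - target_mean) / (tau2 - tau1)
    return [(a1, tau1), (1.0 - a1, tau2)]


def gen_decay(
    components: Sequence[tuple[float, float]],
    irf_fwhm: float = 0.8,
    channel_width: float = 0.055,
    time_window: float = 50.0,
    peak_counts: float = 1e4,
    irf_center: float = 3.0,
    background: float = 0.0,
    noise: bool = True,
    seed: int = 0,
) -> tuple[DecayTrace, dict]:
    """Simulate a TCSPC decay: multi-exponential x Gaussian IRF + Poisson noise.

    The model decay is convolved with a unit-area Gaussian IRF (FWHM
    ``irf_fwhm`` ns centred at ``irf_center`` ns), scaled so the convolved
    peak reaches ``peak_counts``, then Poisson-sampled.  The IRF trace
    (scaled to the same peak and Poisson-sampled) is attached to the trace.
    With ``irf_fwhm=0`` a single-channel delta IRF is used; with
    ``noise=False`` counts are left at their exact expectations.
    """
    if peak_counts < 100:
        raise ValueError("peak_counts must be >= 100")
    n = int(round(time_window / channel_width))
    times = np.arange(n) * channel_width
    decay = multiexp_model(0.0, components, times)
    if irf_fwhm > 0:
        sigma = irf_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        irf_shape = np.exp(-0.5 * ((times - irf_center) / sigma) ** 2)
    else:
        irf_shape = np.zeros(n)
        irf_shape[0] = 1.0
    expected = reconvolve(decay, irf_shape) + background
    scale = peak_counts / expected.max()
    expected = expected * scale
    irf_trace = irf_shape / irf_shape.max() * peak_counts

    rng = np.random.default_rng(seed)
    if noise:
        counts = rng.poisson(expected).astype(float)
        irf_counts = rng.poisson(irf_trace).astype(float)
    else:
        counts, irf_counts = expected, irf_trace

    scaled = [(a * scale, tau) for a, tau in components]
    from .tcspc import average_lifetime

    truth = {
        "kind": "decay",
        "components": [list(c) for c in scaled],
        "avg_lifetime_true": average_lifetime(components),
        "irf_fwhm": irf_fwhm,
        "channel_width": channel_width,
        "peak_counts": peak_counts,
        "background": background * scale,
        "seed": seed,
    }
    trace = DecayTrace(
        times=times, counts=counts, irf_counts=irf_counts, channel_width=channel_width
    )
    return trace, truth


# ---------------------------------------------------------------------------
# Rupture forces and force curves

def sample_rupture_forces(
    k_off: float,
    x_beta: float,
    r: float,
    T: float = 298.0,
    n: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Exact inverse-CDF sample of the Bell-Evans rupture-force distribution.

    F = (kBT/x_beta) ln[1 - (r x_beta/(k_off kBT)) ln(1-u)], u ~ U(0,1).
    Parameters as in :func:`spectrobind.forcespec.bell_evans_predict`;
    returns forces in pN.
    """
    if min(k_off, x_beta, r, T, n) <= 0:
        raise ValueError("all parameters must be positive")
    rng = np.random.default_rng(seed)
    u = rng.uniform(0.0, 1.0, size=n)
    kbt = KB * T
    x = x_beta * 1e-9
    rr = r * 1e-9
    f = (kbt / x) * np.log(1.0 - (rr * x / (k_off * kbt)) * np.log1p(-u))
    return f * 1e12  # N -> pN


def gen_force_curve(
    rupture_force: float = 110.0,
    k_eff: float = 0.02,
    velocity: float = 1000.0,
    k_syst: float = 0.005,
    contour: float = 27.0,
    kuhn: float = 0.7,
    z_max: float = 150.0,
    dz: float = 0.25,
    noise_nm: float = 0.02,
    tether: bool = True,
    seed: int = 0,
) -> tuple[ForceCurve, dict]:
    """Simulate a retract curve with an eFJC tether stretch ending in a rupture.

    Force units pN, lengths nm.  The tether engages at z = 0; the
    deflection follows -F_eFJC(z)/k_eff until the force reaches
    ``rupture_force``, then jumps to the baseline.  ``tether=False`` yields
    a flat (no-event) curve.
    """
    rng = np.random.default_rng(seed)
    z = np.arange(0.0, z_max, dz)
    defl = np.zeros_like(z)
    truth: dict = {
        "kind": "force_curve",
        "rupture_force": rupture_force if tether else None,
        "k_eff": k_eff,
        "velocity": velocity,
        "k_syst": k_syst,
        "contour": contour,
        "seed": seed,
    }
    if tether:
        force = efjc_force(z, contour, kuhn)
        engaged = force < rupture_force
        # rupture at the first grid point whose tether force exceeds the target
        idx = int(np.argmax(~engaged)) if not engaged.all() else z.size
        defl[:idx] = -force[:idx] / (k_eff * 1e3)  # pN / (N/m) = pm -> nm via 1e3
        if 0 < idx < z.size:
            # rupture happens exactly at the target force
            defl[idx - 1] = -rupture_force / (k_eff * 1e3)
        truth["rupture_index"] = idx
        truth["rupture_length"] = float(z[idx - 1]) if idx > 0 else 0.0
    defl = defl + rng.normal(0.0, noise_nm, size=z.size)
    curve = ForceCurve(z=z, deflection=defl, k_eff=k_eff, velocity=velocity, k_syst=k_syst)
    return curve, truth


# ---------------------------------------------------------------------------
# Toy structures

def _hexagon(center: np.ndarray, radius: float = 1.39) -> np.ndarray:
    ang = np.deg2rad(np.arange(0, 360, 60))
    return center + radius * np.stack([np.cos(ang), np.sin(ang), np.zeros(6)], axis=1)


def _trp_sidechain_template() -> dict[str, np.ndarray]:
    """Idealised planar indole ring (Angstrom) plus stub backbone atoms.

    The six-membered ring is a regular hexagon of side 1.39 A; the
    five-membered ring is fused on the CD2-CE2 edge.  Geometry is idealised
    — ring-centroid arithmetic, not chemistry, is what consumers need.
    """
    hexa = _hexagon(np.zeros(3))
    # order around the hexagon: CD2, CE3, CZ3, CH2, CZ2, CE2
    six = dict(zip(("CD2", "CE3", "CZ3", "CH2", "CZ2", "CE2"), hexa))
    cd2, ce2 = six["CD2"], six["CE2"]
    mid = (cd2 + ce2) / 2.0
    edge = ce2 - cd2
    # outward normal to the shared edge, in-plane
    perp = np.array([edge[1], -edge[0], 0.0])
    perp /= np.linalg.norm(perp)
    if np.dot(perp, mid - hexa.mean(axis=0)) < 0:
        perp = -perp
    s = np.linalg.norm(edge)
    # pentagon on the shared edge: CG adjacent to CD2, NE1 adjacent to CE2,
    # CD1 at the apex
    cg = mid - edge * 0.81 + perp * s * 0.95
    ne1 = mid + edge * 0.81 + perp * s * 0.95
    cd1 = mid + perp * s * 1.54
    five = {"CG": cg, "NE1": ne1, "CD1": cd1}
    cb = six["CD2"] + (six["CD2"] - mid) * 1.1
    backbone = {
        "CB": cb,
        "CA": cb + np.array([1.5, 0.0, 0.0]),
        "N": cb + np.array([2.0, 1.2, 0.0]),
        "C": cb + np.array([2.6, -1.0, 0.0]),
        "O": cb + np.array([3.8, -1.0, 0.0]),
    }
    return {**six, **five, **backbone}


def _build_receptor(donor_residue: int = 214) -> struc.AtomArray:
    """Rigid toy receptor: a CA scaffold, a complete Trp, and charged residues."""
    atoms: list[struc.Atom] = []

    def add(res_id, res_name, atom_name, coord, element):
        atoms.append(
            struc.Atom(
                np.asarray(coord, dtype=float),
                chain_id="A",
                res_id=res_id,
                res_name=res_name,
                atom_name=atom_name,
                element=element,
                hetero=False,
            )
        )

    # helical CA scaffold (non-collinear, for superposition)
    for i in range(12):
        theta = np.deg2rad(100.0 * i)
        add(
            200 + i, "GLY", "CA",
            [2.3 * np.cos(theta) - 12.0, 2.3 * np.sin(theta), 1.5 * i],
            "C",
        )
    # the donor tryptophan
    for name, coord in _trp_sidechain_template().items():
        elem = name[0] if name[0] in ("N", "O") else "C"
        add(donor_residue, "TRP", name, coord, elem)
    # charged residues near the eventual binding region
    add(300, "ARG", "CA", [6.0, 2.0, 0.0], "C")
    add(300, "ARG", "CZ", [8.0, 3.0, 0.0], "C")
    add(301, "LYS", "CA", [6.0, -2.0, 0.0], "C")
    add(301, "LYS", "NZ", [8.0, -3.0, 0.0], "N")
    add(302, "GLU", "CA", [-6.0, 6.0, 3.0], "C")
    add(302, "GLU", "CD", [-7.5, 7.0, 3.0], "C")
    return struc.array(atoms)


def _build_ligand(
    p1_coord: np.ndarray,
    direction: np.ndarray,
    n_nt: int = 5,
    sequence: str = "UGCGG",
    with_phosphate: bool = True,
) -> struc.AtomArray:
    """Linear toy RNA built 5'->3' by residue number, ~6 A per nucleotide."""
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    # two in-plane offsets orthogonal to the chain axis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, direction)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    ortho = np.cross(direction, helper)
    ortho /= np.linalg.norm(ortho)
    atoms: list[struc.Atom] = []
    for i in range(n_nt):
        base = np.asarray(p1_coord, dtype=float) + direction * (6.0 * i)
        res_name = sequence[i % len(sequence)]
        names = [("P", base, "P")] if (with_phosphate or i > 0) else []
        names += [
            ("O5'", base + ortho * 1.6, "O"),
            ("C5'", base + ortho * 2.9 + direction * 0.8, "C"),
        ]
        for name, coord, elem in names:
            atoms.append(
                struc.Atom(
                    coord, chain_id="B", res_id=i + 1, res_name=res_name,
                    atom_name=name, element=elem, hetero=False,
                )
            )
    return struc.array(atoms)


def gen_pose_set(
    n: int = 50,
    dda_mean: float = 4.0,
    dda_sd: float = 0.7,
    donor_residue: int = 214,
    seed: int = 0,
) -> tuple[list[Pose], dict]:
    """Toy docking pose set with a controlled donor-acceptor distance spread.

    One rigid receptor is shared by all poses; each pose places the ligand's
    5'-terminal phosphorus at a distance drawn from Normal(dda_mean, dda_sd)
    nm from the Trp ring centroid, in a uniformly random direction, with the
    chain extending in a random orientation.  Per-pose true distances are
    recorded in the returned truth dict.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    receptor = _build_receptor(donor_residue)
    ref_pose = Pose(receptor=receptor, ligand=_build_ligand(np.zeros(3), [1, 0, 0]), rank=0)
    center_nm = trp_ring_center(ref_pose, donor_residue)
    poses: list[Pose] = []
    truths: list[float] = []
    for i in range(n):
        d = float(rng.normal(dda_mean, dda_sd))
        d = max(d, 0.5)  # keep geometrically sensible
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        w = rng.normal(size=3)
        w /= np.linalg.norm(w)
        p1 = (center_nm + d * u) * A_PER_NM
        ligand = _build_ligand(p1, w)
        pose = Pose(receptor=receptor.copy(), ligand=ligand, rank=i + 1,
                    model_id=f"model_{i + 1}")
        poses.append(pose)
        truths.append(float(np.linalg.norm(p1 / A_PER_NM - center_nm)))
    truth = {
        "kind": "poses",
        "n": n,
        "dda_mean": dda_mean,
        "dda_sd": dda_sd,
        "donor_residue": donor_residue,
        "seed": seed,
        "dda_true_nm": truths,
    }
    return poses, truth


def gen_trajectory(
    n_frames: int = 100,
    dda_base: float = 4.1,
    amplitude: float = 0.1,
    period: int = 20,
    noise_sd: float = 0.02,
    donor_residue: int = 214,
    seed: int = 0,
) -> tuple[list[Pose], dict]:
    """Toy trajectory: the ligand oscillates radially about a base distance.

    D_DA(t) = dda_base + amplitude sin(2 pi t / period) + Gaussian jitter.
    """
    rng = np.random.default_rng(seed)
    receptor = _build_receptor(donor_residue)
    ref_pose = Pose(receptor=receptor, ligand=_build_ligand(np.zeros(3), [1, 0, 0]), rank=0)
    center_nm = trp_ring_center(ref_pose, donor_residue)
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    w = rng.normal(size=3)
    w /= np.linalg.norm(w)
    frames: list[Pose] = []
    dists: list[float] = []
    for t in range(n_frames):
        d = dda_base + amplitude * np.sin(2.0 * np.pi * t / period)
        d += rng.normal(0.0, noise_sd)
        p1 = (center_nm + d * u) * A_PER_NM
        frames.append(
            Pose(receptor=receptor.copy(), ligand=_build_ligand(p1, w),
                 rank=t + 1, model_id=f"frame_{t + 1}")
        )
        dists.append(float(d))
    truth = {
        "kind": "trajectory",
        "n_frames": n_frames,
        "dda_base": dda_base,
        "amplitude": amplitude,
        "noise_sd": noise_sd,
        "seed": seed,
        "dda_true_nm": dists,
    }
    return frames, truth


# ---------------------------------------------------------------------------
# Persistence with provenance sidecars

def _write_sidecar(path: Path, truth: dict) -> None:
    sidecar = path.with_suffix(path.suffix + ".truth.json")
    sidecar.write_text(json.dumps(truth, indent=2))


def write_titration_csv(series: TitrationSeries, truth: dict, path: str | Path) -> None:
    """Write a titration (micromolar units) plus its provenance sidecar."""
    path = Path(path)
    lines = [
        f"# fluorophore_conc: {series.fluorophore_conc * 1e6:g}",
        "# unit: uM",
        f"# emission_wavelength: {series.emission_wavelength:g}",
        "quencher_conc,intensity",
    ]
    for q, f in zip(series.quencher_concs, series.intensities):
        lines.append(f"{q * 1e6:.6g},{f:.8g}")
    path.write_text("\n".join(lines) + "\n")
    _write_sidecar(path, truth)


def write_decay_table(trace: DecayTrace, truth: dict, path: str | Path) -> None:
    """Write a decay as CSV (time_ns, counts[, irf]) plus provenance sidecar."""
    path = Path(path)
    header = "time_ns,counts" + (",irf" if trace.irf_counts is not None else "")
    rows = [header]
    for i in range(trace.times.size):
        row = f"{trace.times[i]:.6g},{trace.counts[i]:.0f}"
        if trace.irf_counts is not None:
            row += f",{trace.irf_counts[i]:.0f}"
        rows.append(row)
    path.write_text("\n".join(rows) + "\n")
    _write_sidecar(path, truth)


def write_pose_set(poses: Sequence[Pose], truth: dict, path: str | Path) -> None:
    """Write poses as a multi-MODEL PDB plus provenance sidecar."""
    path = Path(path)
    merged = [pose.receptor + pose.ligand for pose in poses]
    stack = struc.stack(merged)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))
    _write_sidecar(path, truth)
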