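"""Structural descriptors of the bilayer.

Area per lipid (box cross-section over lipids per leaflet), mass density
profiles along the membrane normal, P-P membrane thickness from density-peak
maxima (with a symmetrization-based error estimate), deuterium order
parameters of the acyl chains and lateral lipid diffusion from in-plane MSD.
The membrane normal is the box z-axis throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._msd import check_unwrapped, fit_diffusion, msd_curve
from .errors import ParseError, SelectionError
from .traj_model import AtomSelection, Trajectory
from .units import AMU_KG, nm2_per_ps_to_cm2_per_s, nm2_per_ps_to_nm2_per_ns

__all__ = [
    "DensityProfile",
    "ThicknessResult",
    "StructureSummary",
    "LateralDiffusion",
    "area_per_lipid",
    "density_profile",
    "membrane_thickness",
    "order_parameters",
    "lateral_diffusion",
]


@dataclass
class DensityProfile:
    bin_centers: np.ndarray  # nm, relative to the bilayer midplane
    density: np.ndarray  # kg m^-3
    symmetrized: bool
    selection_label: str
    bin_width: float


@dataclass
class ThicknessResult:
    thickness: float  # nm (unsymmetrized profile)
    error: float  # |sym - unsym|
    thickness_sym: float
    thickness_unsym: float


@dataclass
class LateralDiffusion:
    lags_ps: np.ndarray
    msd: np.ndarray  # nm^2
    d_nm2_ns: float
    d_cm2_s: float
    fit_se_nm2_ns: float
    fit_window: slice


@dataclass
class StructureSummary:
    apl_mean: float
    apl_sd: float
    thickness: float
    thickness_error: float
    scd: dict = field(default_factory=dict)  # chain -> list of (carbon, -S_CD)


def _midplane(traj: Trajectory, frame_index: int) -> float:
    """Bilayer midplane: mean z of P atoms if present, else of all atoms."""
    atoms = traj.atoms
    p_idx = np.flatnonzero(atoms.atom_name.astype(str) == "P")
    z = traj.frames[frame_index].coordinates[:, 2]
    return float(z[p_idx].mean() if len(p_idx) else z.mean())


def area_per_lipid(
    traj: Trajectory, lipids_per_leaflet: int, frame_window: slice | None = None
) -> tuple[np.ndarray, float, float]:
    """Per-frame APL = Lx*Ly / lipids_per_leaflet; returns (series, mean, SD)."""
    if lipids_per_leaflet <= 0:
        raise ParseError("lipids_per_leaflet must be positive")
    frames = traj.frames[frame_window] if frame_window else traj.frames
    if len(frames) == 0:
        raise ParseError("no frames in the requested window")
    series = np.array([fr.box[0] * fr.box[1] / lipids_per_leaflet for fr in frames])
    return series, float(series.mean()), float(series.std())


def density_profile(
    traj: Trajectory,
    selection: AtomSelection,
    bin_width: float = 0.05,
    symmetrize: bool = False,
) -> DensityProfile:
    """Frame-averaged mass density along z, centered on the bilayer midplane."""
    if len(selection) == 0:
        raise SelectionError("density_profile: empty selection")
    masses = traj.atoms.mass[selection.indices]
    box = traj.frames[0].box
    half = box[2] / 2.0
    edges = np.arange(-half, half + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    hist = np.zeros(len(centers))
    for i, fr in enumerate(traj.frames):
        z = fr.coordinates[selection.indices, 2] - _midplane(traj, i)
        z = (z + half) % box[2] - half  # wrap into [-Lz/2, Lz/2)
        hist += np.histogram(z, bins=edges, weights=masses)[0]
    hist /= traj.n_frames
    if symmetrize:
        hist = 0.5 * (hist + hist[::-1])
    volume_m3 = bin_width * box[0] * box[1] * 1e-27
    density = hist * AMU_KG / volume_m3
    return DensityProfile(centers, density, symmetrize, selection.label, bin_width)


def _parabolic_vertex(x: np.ndarray, y: np.ndarray, i: int) -> float:
    if i <= 0 or i >= len(x) - 1:
        return float(x[i])
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom == 0:
        return float(x[i])
    return float(x[i] + 0.5 * (y[i - 1] - y[i + 1]) / denom * (x[i + 1] - x[i]))


def _pp_distance(profile: DensityProfile) -> float:
    z, rho = profile.bin_centers, profile.density
    upper = z > 0
    lower = z < 0
    if rho[upper].max(initial=0) == 0 or rho[lower].max(initial=0) == 0:
        raise ParseError("membrane_thickness: fewer than two density peaks")
    iu = np.flatnonzero(upper)[np.argmax(rho[upper])]
    il = np.flatnonzero(lower)[np.argmax(rho[lower])]
    return _parabolic_vertex(z, rho, iu) - _parabolic_vertex(z, rho, il)


def membrane_thickness(
    traj: Trajectory, p_atom_name: str = "P", bin_width: float = 0.01
) -> ThicknessResult:
    """P-P distance from density-peak maxima (3-point parabolic refinement).

    The quoted error is the difference between the symmetrized and
    unsymmetrized determinations.
    """
    sel = traj.atoms.select(atom_name=p_atom_name, label="P")
    if len(sel) == 0:
        raise SelectionError(f"no '{p_atom_name}' atoms for thickness")
    unsym = _pp_distance(density_profile(traj, sel, bin_width, symmetrize=False))
    sym = _pp_distance(density_profile(traj, sel, bin_width, symmetrize=True))
    return ThicknessResult(
        thickness=unsym,
        error=abs(sym - unsym),
        thickness_sym=sym,
        thickness_unsym=unsym,
    )


def order_parameters(traj: Trajectory, chain_map: dict) -> dict:
    """Per-carbon -S_CD with S_CD = <(3 cos^2 beta - 1)/2>, beta the C-H angle
    to the membrane normal; averaged over lipids, hydrogens and frames.

    chain_map: {chain: [(carbon_name, [hydrogen_names]), ...]}.
    """
    atoms = traj.atoms
    names = atoms.atom_name.astype(str)
    out: dict[str, list] = {}
    for chain, carbons in chain_map.items():
        rows = []
        for carbon, hydrogens in carbons:
            if not hydrogens:
                raise SelectionError(f"carbon '{carbon}' has no mapped hydrogens")
            c_idx = np.flatnonzero(names == carbon)
            if len(c_idx) == 0:
                raise SelectionError(f"no atoms named '{carbon}' in the system")
            acc = 0.0
            count = 0
            for h_name in hydrogens:
                h_idx = np.flatnonzero(names == h_name)
                if len(h_idx) != len(c_idx):
                    raise SelectionError(
                        f"hydrogen '{h_name}' does not pair 1:1 with '{carbon}'"
                    )
                for fr in traj.frames:
                    v = fr.coordinates[h_idx] - fr.coordinates[c_idx]
                    cos_b = v[:, 2] / np.linalg.norm(v, axis=1)
                    acc += np.sum((3.0 * cos_b**2 - 1.0) / 2.0)
                    count += len(v)
            rows.append((carbon, float(-acc / count)))
        out[chain] = rows
    return out


def lateral_diffusion(
    traj: Trajectory,
    selection: AtomSelection,
    fit_window: tuple[float, float] = (0.1, 0.5),
) -> LateralDiffusion:
    """D_xy from in-plane MSD over multiple origins: slope/4 on the window."""
    if len(selection) == 0:
        raise SelectionError("lateral_diffusion: empty selection")
    if traj.n_frames < 3:
        raise ParseError("need at least 3 frames for a diffusion estimate")
    pos = traj.coordinate_array(selection)[:, :, :2]
    check_unwrapped(pos, traj.frames[0].box)
    msd = msd_curve(pos)
    times = np.array([fr.time for fr in traj.frames])
    lags = times - times[0]
    d_nm2_ps, se, window = fit_diffusion(lags, msd, n_dim=2, fit_window=fit_window)
    return LateralDiffusion(
        lags_ps=lags,
        msd=msd,
        d_nm2_ns=nm2_per_ps_to_nm2_per_ns(d_nm2_ps),
        d_cm2_s=nm2_per_ps_to_cm2_per_s(d_nm2_ps),
        fit_se_nm2_ns=nm2_per_ps_to_nm2_per_ns(se),
        fit_window=window,
    )
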