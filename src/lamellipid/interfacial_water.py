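"""Water structure and dynamics at the membrane interface.

Radial distribution functions around lipid reference atoms, first-hydration-
shell assignment (default cutoff 0.3 nm, the first g(r) minimum), angular
ordering of shell waters (cos(theta) between the headgroup->oxygen vector and
the oxygen->H-midpoint vector), distance-resolved and cumulative cos(theta),
dipole tilt vs z, and Einstein-relation 3-D diffusion (MSD slope / 6).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._msd import check_unwrapped, fit_diffusion, msd_curve
from ._neighbors import neighbor_pairs
from .errors import GeometryError, ParseError, SelectionError
from .traj_model import AtomSelection, Frame, Trajectory, minimum_image
from .units import nm2_per_ps_to_cm2_per_s

__all__ = [
    "RDFResult",
    "AngularProfile",
    "DiffusionEstimate",
    "rdf",
    "shell_waters",
    "angular_distribution",
    "costheta_vs_distance",
    "dipole_tilt_profile",
    "water_diffusion",
]


@dataclass
class RDFResult:
    r: np.ndarray  # bin centers, nm
    g: np.ndarray  # dimensionless
    reference_label: str
    target_label: str
    r_max: float
    dr: float
    counts: np.ndarray  # raw pair counts per bin (all frames)


@dataclass
class AngularProfile:
    cos_grid: np.ndarray | None = None  # bin centers in [-1, 1]
    density: np.ndarray | None = None  # probability density over cos(theta)
    r: np.ndarray | None = None  # distance-bin centers
    mean_costheta: np.ndarray | None = None
    cumulative: np.ndarray | None = None  # running sum of cos(theta) vs distance
    z: np.ndarray | None = None  # z-bin centers for the dipole tilt
    mean_cosphi: np.ndarray | None = None


@dataclass
class DiffusionEstimate:
    lags_ps: np.ndarray
    msd: np.ndarray  # nm^2
    d_cm2_s: float
    fit_se_cm2_s: float
    fit_window: slice


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _water_sites(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """(oxygen indices, matching (n,2) hydrogen indices) for all waters."""
    atoms = traj.atoms
    is_wat = atoms.is_water
    el = atoms.element.astype(str)
    o_idx = np.flatnonzero(is_wat & (el == "O"))
    h_by_res: dict[int, list] = {}
    for idx in np.flatnonzero(is_wat & (el == "H")):
        h_by_res.setdefault(int(atoms.residue_id[idx]), []).append(idx)
    h_idx = np.empty((len(o_idx), 2), dtype=int)
    for k, oi in enumerate(o_idx):
        hs = h_by_res.get(int(atoms.residue_id[oi]), [])
        if len(hs) != 2:
            raise ParseError(
                f"water residue {atoms.residue_id[oi]} does not have 2 hydrogens"
            )
        h_idx[k] = hs
    return o_idx, h_idx


def _nearest_reference(o_pos, ref_pos, box, r_max):
    """Per water O within r_max of any reference: (water rows, ref rows, dist)."""
    ia, ib, dist = neighbor_pairs(o_pos, ref_pos, box, r_max)
    if len(ia) == 0:
        return ia, ib, dist
    order = np.lexsort((dist, ia))
    ia_s, ib_s, d_s = ia[order], ib[order], dist[order]
    first = np.unique(ia_s, return_index=True)[1]
    return ia_s[first], ib_s[first], d_s[first]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def rdf(
    traj: Trajectory,
    ref_selection: AtomSelection,
    target_selection: AtomSelection,
    r_max: float = 1.0,
    dr: float = 0.002,
) -> RDFResult:
    """g(r) of target atoms around reference atoms under minimum image.

    Normalized per reference atom by the spherical-shell volume and the bulk
    target number density N_target/V; self-pairs (shared atom indices) are
    excluded.
    """
    box = traj.frames[0].box
    if r_max > box.min() / 2.0 + 1e-12:
        raise GeometryError(
            f"r_max={r_max} exceeds half the smallest box edge ({box.min() / 2:.3f})"
        )
    if len(ref_selection) == 0 or len(target_selection) == 0:
        raise SelectionError("rdf: empty selection")
    edges = np.arange(0.0, r_max + dr, dr)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.zeros(len(centers))
    for fr in traj.frames:
        ia, ib, dist = neighbor_pairs(
            fr.coordinates[ref_selection.indices],
            fr.coordinates[target_selection.indices],
            fr.box,
            r_max,
        )
        same = (
            ref_selection.indices[ia] == target_selection.indices[ib]
        )
        counts += np.histogram(dist[~same], bins=edges)[0]
    volume = float(np.prod(box))
    rho = len(target_selection) / volume
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    norm = traj.n_frames * len(ref_selection) * shell_vol * rho
    g = counts / norm
    return RDFResult(
        r=centers,
        g=g,
        reference_label=ref_selection.label,
        target_label=target_selection.label,
        r_max=r_max,
        dr=dr,
        counts=counts,
    )


def shell_waters(
    traj: Trajectory,
    ref_selection: AtomSelection,
    cutoff: float = 0.3,
    frame_index: int = 0,
) -> AtomSelection:
    """Water oxygens within ``cutoff`` of any reference atom (minimum image)."""
    if len(ref_selection) == 0:
        raise SelectionError("shell_waters: empty reference selection")
    frame = traj.frames[frame_index]
    o_idx, _ = _water_sites(traj)
    ia, _, _ = neighbor_pairs(
        frame.coordinates[o_idx],
        frame.coordinates[ref_selection.indices],
        frame.box,
        cutoff,
    )
    return AtomSelection(indices=o_idx[np.unique(ia)], label="first-shell-water-O")


def _costheta_frame(fr, o_idx, h_idx, ref_idx, box, r_max):
    """Per-water (distance-to-nearest-ref, cos theta) for waters within r_max."""
    o_pos = fr.coordinates[o_idx]
    rows, ref_rows, dist = _nearest_reference(
        o_pos, fr.coordinates[ref_idx], box, r_max
    )
    # a reference atom that IS the water oxygen gives a zero v1; drop it
    nonzero = dist > 1e-12
    rows, ref_rows, dist = rows[nonzero], ref_rows[nonzero], dist[nonzero]
    if len(rows) == 0:
        return dist, np.empty(0)
    v1 = minimum_image(fr.coordinates[ref_idx][ref_rows], o_pos[rows], box)
    hmid = 0.5 * (fr.coordinates[h_idx[rows, 0]] + fr.coordinates[h_idx[rows, 1]])
    v2 = hmid - o_pos[rows]
    cos_t = np.einsum("ij,ij->i", v1, v2) / (
        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
    )
    return dist, np.clip(cos_t, -1.0, 1.0)


def angular_distribution(
    traj: Trajectory,
    ref_selection: AtomSelection,
    cutoff: float = 0.3,
    n_bins: int = 40,
) -> AngularProfile:
    """Probability density of cos(theta) for first-shell waters.

    v1 points from the nearest reference heavy atom to the water oxygen, v2
    from the oxygen to the midpoint of its hydrogens.
    """
    o_idx, h_idx = _water_sites(traj)
    if len(o_idx) == 0:
        raise SelectionError("no waters in the system")
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    hist = np.zeros(n_bins)
    total = 0
    for fr in traj.frames:
        _, cos_t = _costheta_frame(fr, o_idx, h_idx, ref_selection.indices, fr.box, cutoff)
        hist += np.histogram(cos_t, bins=edges)[0]
        total += len(cos_t)
    if total == 0:
        raise SelectionError("no shell waters found within the cutoff")
    density = hist / total / np.diff(edges)
    return AngularProfile(cos_grid=0.5 * (edges[:-1] + edges[1:]), density=density)


def costheta_vs_distance(
    traj: Trajectory,
    ref_selection: AtomSelection,
    r_max: float = 2.0,
    dr: float = 0.05,
) -> AngularProfile:
    """Mean cos(theta) binned by distance to the nearest reference atom, plus
    the cumulative running sum of per-water cos(theta) over distance-ordered
    waters (frame-averaged); the last cumulative value equals the mean total
    sum of cos(theta) over all waters within r_max."""
    o_idx, h_idx = _water_sites(traj)
    edges = np.arange(0.0, r_max + dr, dr)
    nb = len(edges) - 1
    sum_cos = np.zeros(nb)
    n_in_bin = np.zeros(nb)
    cum = np.zeros(nb)
    for fr in traj.frames:
        dist, cos_t = _costheta_frame(
            fr, o_idx, h_idx, ref_selection.indices, fr.box, r_max
        )
        which = np.clip(np.digitize(dist, edges) - 1, 0, nb - 1)
        np.add.at(sum_cos, which, cos_t)
        np.add.at(n_in_bin, which, 1.0)
        per_bin = np.zeros(nb)
        np.add.at(per_bin, which, cos_t)
        cum += np.cumsum(per_bin)
    with np.errstate(invalid="ignore"):
        mean_cos = np.where(n_in_bin > 0, sum_cos / n_in_bin, np.nan)
    return AngularProfile(
        r=0.5 * (edges[:-1] + edges[1:]),
        mean_costheta=mean_cos,
        cumulative=cum / traj.n_frames,
    )


def dipole_tilt_profile(
    traj: Trajectory,
    bin_width: float = 0.1,
    center_on_midplane: bool = True,
) -> AngularProfile:
    """Mean cos(phi) of the water dipole (O -> H-midpoint) vs z.

    z is measured from the bilayer midplane (mean z of P atoms) when present,
    else from the box center.
    """
    o_idx, h_idx = _water_sites(traj)
    box = traj.frames[0].box
    half = box[2] / 2.0
    edges = np.arange(-half, half + bin_width, bin_width)
    nb = len(edges) - 1
    sum_cos = np.zeros(nb)
    counts = np.zeros(nb)
    p_idx = np.flatnonzero(traj.atoms.atom_name.astype(str) == "P")
    for fr in traj.frames:
        if center_on_midplane and len(p_idx):
            mid = fr.coordinates[p_idx, 2].mean()
        else:
            mid = half
        o_pos = fr.coordinates[o_idx]
        hmid = 0.5 * (fr.coordinates[h_idx[:, 0]] + fr.coordinates[h_idx[:, 1]])
        dip = hmid - o_pos
        cos_p = dip[:, 2] / np.linalg.norm(dip, axis=1)
        z = (o_pos[:, 2] - mid + half) % box[2] - half
        which = np.clip(np.digitize(z, edges) - 1, 0, nb - 1)
        np.add.at(sum_cos, which, cos_p)
        np.add.at(counts, which, 1.0)
    with np.errstate(invalid="ignore"):
        mean_cos = np.where(counts > 0, sum_cos / counts, np.nan)
    return AngularProfile(z=0.5 * (edges[:-1] + edges[1:]), mean_cosphi=mean_cos)


def water_diffusion(
    traj: Trajectory,
    selection: AtomSelection | None = None,
    fit_window: tuple[float, float] = (0.1, 0.5),
) -> DiffusionEstimate:
    """Einstein-relation 3-D diffusion: D = MSD slope / 6, in cm^2 s^-1.

    Requires unwrapped coordinates and at least 3 frames; defaults to all
    water oxygens.
    """
    if traj.n_frames < 3:
        raise ParseError("need at least 3 frames for a diffusion estimate")
    if selection is None:
        selection = traj.atoms.water_oxygens()
    if len(selection) == 0:
        raise SelectionError("water_diffusion: empty selection")
    pos = traj.coordinate_array(selection)
    check_unwrapped(pos, traj.frames[0].box)
    msd = msd_curve(pos)
    times = np.array([fr.time for fr in traj.frames])
    lags = times - times[0]
    d_nm2_ps, se, window = fit_diffusion(lags, msd, n_dim=3, fit_window=fit_window)
    return DiffusionEstimate(
        lags_ps=lags,
        msd=msd,
        d_cm2_s=nm2_per_ps_to_cm2_per_s(d_nm2_ps),
        fit_se_cm2_s=nm2_per_ps_to_cm2_per_s(se),
        fit_window=window,
    )
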