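"""Ground-truth generators: UL/ML bilayer pseudo-trajectories and melting data.

The bilayer builder places coarse pseudo-lipids (headgroup beads, carboxylate
and glycerol oxygens, ester carbonyls, chain carbons with two explicit
pseudo-hydrogens each) on a jittered lattice at a target area per lipid, with
phosphorus planes at +/- pp_thickness/2 about the box midplane.  Rigid 3-site
waters fill the remaining z-slab at liquid density, and monovalent cations are
dropped near carboxylate oxygens (auto-neutralization: one per anionic lipid).

`evolve` turns the single frame into a pseudo-trajectory: waters perform
unbiased Gaussian random walks at a known diffusion coefficient, lipids
2-D walks in the membrane plane, and water orientations are re-sampled from
the configured orientation model each frame.  Every ground-truth parameter is
recoverable by the corresponding analysis module, which is the package's main
parameter-recovery test surface.

Unilamellar (UL) vs multilamellar (ML) presets differ only in the water slab:
6400 waters with z-box 9.4-11.2 nm (UL) against 2781 waters with z-box
6.5-7.5 nm (ML), at identical lipid content.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._neighbors import neighbor_pairs
from .errors import GeometryError, ParseError
from .melting_curves import SpectraMatrix, Thermogram, boltzmann_profile
from .traj_model import AtomTable, Frame, Trajectory
from .units import cm2_per_s_to_nm2_per_ps

__all__ = [
    "WaterOrientation",
    "BilayerSpec",
    "MeltingSpec",
    "build_bilayer",
    "evolve",
    "make_spectra",
    "make_dsc",
    "default_chain_map",
    "spec_to_dict",
    "DEFAULT_HEADGROUP_NAMES",
    "PRESETS",
    "preset",
]

#: Heavy atoms treated as the lipid-headgroup reference set (phosphate,
#: carboxylate, glycerol-terminal oxygens) for shells and water orientation.
DEFAULT_HEADGROUP_NAMES = ("P", "OP1", "OP2", "CC", "OC1", "OC2", "OG1", "OG2")

_OH_BOND = 0.09572  # nm
_HOH_HALF_ANGLE = np.deg2rad(104.5 / 2.0)
_CH_BOND = 0.109  # nm
_BULK_WATER_NUMBER_DENSITY = 33.37  # molecules per nm^3 at ~298 K
_CAPACITY_SLACK = 1.10


@dataclass(frozen=True)
class WaterOrientation:
    """Water-orientation model used when (re)sampling hydrogen positions.

    kind:
      'isotropic'      uniformly random dipoles
      'shell_oriented' waters within ``BilayerSpec.orientation_cutoff`` of a
                       headgroup atom get cos(theta) concentrated around
                       cos(angle_deg) w.r.t. the headgroup->oxygen vector
                       (spread ~ 1/sqrt(kappa)); others isotropic
      'z_flip'         dipoles along -z above the midplane and +z below
                       (jitter ~ 1/sqrt(kappa)); yields an antisymmetric
                       dipole-tilt profile
    """

    kind: str = "isotropic"
    angle_deg: float = 130.0
    kappa: float = 20.0

    def __post_init__(self):
        if self.kind not in ("isotropic", "shell_oriented", "z_flip"):
            raise ParseError(f"unknown water orientation model '{self.kind}'")


@dataclass(frozen=True)
class BilayerSpec:
    """Ground-truth parameters of a synthetic solvated bilayer.

    Units: nm, nm^2; water_D in cm^2/s (converted internally); lipid_Dxy in
    nm^2/ns.  ``n_cations=None`` auto-neutralizes (one cation per anionic
    lipid).
    """

    n_dpps: int = 122
    n_dppg: int = 6
    lipids_per_leaflet: int = 64
    apl_target: float = 0.458
    pp_thickness: float = 4.514
    chain_length: int = 16
    chain_order: float | tuple = 0.28
    z_box: float = 11.2
    n_waters: int = 6400
    n_cations: int | None = None
    water_orientation: WaterOrientation = field(default_factory=WaterOrientation)
    orientation_cutoff: float = 0.35
    water_D: float = 3.12e-5  # cm^2 s^-1
    shell_water_D: float | None = None  # cm^2 s^-1; defaults to water_D
    lipid_Dxy: float = 9.1e-3  # nm^2 ns^-1
    lattice_jitter: float = 0.03  # nm, in-plane and z jitter of beads
    seed: int = 0

    def __post_init__(self):
        if self.n_dpps + self.n_dppg != 2 * self.lipids_per_leaflet:
            raise ParseError(
                "n_dpps + n_dppg must equal 2 * lipids_per_leaflet "
                f"({self.n_dpps}+{self.n_dppg} != 2*{self.lipids_per_leaflet})"
            )
        if self.pp_thickness >= self.z_box:
            raise GeometryError("pp_thickness must be smaller than z_box")
        if self.apl_target <= 0 or self.z_box <= 0:
            raise GeometryError("apl_target and z_box must be positive")
        orders = np.atleast_1d(np.asarray(self.chain_order, dtype=float))
        if np.any(orders < 0) or np.any(orders > 0.5):
            raise ParseError("chain_order (-S_CD target) must lie in [0, 0.5]")

    @property
    def n_lipids(self) -> int:
        return self.n_dpps + self.n_dppg

    @property
    def cation_count(self) -> int:
        return self.n_lipids if self.n_cations is None else self.n_cations

    @property
    def box_xy(self) -> float:
        """Edge length of the square cross-section, from APL x lipids/leaflet."""
        return float(np.sqrt(self.apl_target * self.lipids_per_leaflet))

    @property
    def n_chain_carbons(self) -> int:
        return self.chain_length - 1

    def order_profile(self) -> np.ndarray:
        orders = np.atleast_1d(np.asarray(self.chain_order, dtype=float))
        if len(orders) == 1:
            return np.full(self.n_chain_carbons, orders[0])
        if len(orders) != self.n_chain_carbons:
            raise ParseError(
                f"chain_order must be scalar or length {self.n_chain_carbons}"
            )
        return orders


#: Table-driven presets for the four simulated systems (gel at 35 C, fluid at
#: 65 C); geometry, order level and diffusion ground truths follow the
#: reference systems they emulate.
PRESETS: dict[str, BilayerSpec] = {
    "UL35": BilayerSpec(
        apl_target=0.458, pp_thickness=4.514, z_box=11.2, n_waters=6400,
        chain_order=0.28, water_D=3.12e-5, lipid_Dxy=0.91e-2,
        water_orientation=WaterOrientation("shell_oriented"),
    ),
    "UL65": BilayerSpec(
        apl_target=0.578, pp_thickness=4.057, z_box=9.4, n_waters=6400,
        chain_order=0.12, water_D=4.16e-5, lipid_Dxy=4.24e-2,
        water_orientation=WaterOrientation("shell_oriented"),
    ),
    "ML35": BilayerSpec(
        apl_target=0.462, pp_thickness=4.516, z_box=7.5, n_waters=2781,
        chain_order=0.28, water_D=1.83e-5, lipid_Dxy=0.25e-2,
        water_orientation=WaterOrientation("shell_oriented"),
        orientation_cutoff=1.6,
    ),
    "ML65": BilayerSpec(
        apl_target=0.563, pp_thickness=4.194, z_box=6.5, n_waters=2781,
        chain_order=0.12, water_D=2.30e-5, lipid_Dxy=3.94e-2,
        water_orientation=WaterOrientation("shell_oriented"),
        orientation_cutoff=1.15,
    ),
}


def preset(name: str, seed: int = 0, **overrides) -> BilayerSpec:
    if name not in PRESETS:
        raise ParseError(f"unknown preset '{name}' (choose from {sorted(PRESETS)})")
    return dataclasses.replace(PRESETS[name], seed=seed, **overrides)


def default_chain_map(chain_length: int = 16) -> dict:
    """Chain-name map consumed by the order-parameter analysis: per chain a
    list of (carbon name, [hydrogen names])."""
    return {
        chain: [
            (f"C{i}{tag}", [f"H{i}{tag}1", f"H{i}{tag}2"])
            for i in range(2, chain_length + 1)
        ]
        for chain, tag in (("sn1", "A"), ("sn2", "B"))
    }


def spec_to_dict(spec) -> dict:
    d = dataclasses.asdict(spec)
    return json.loads(json.dumps(d, default=str))


# ---------------------------------------------------------------------------
# bilayer construction
# ---------------------------------------------------------------------------


def _random_unit_vectors(rng, n):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _perpendicular_unit(rng, u):
    """Random unit vectors perpendicular to each row of u."""
    helper = _random_unit_vectors(rng, len(u))
    w = np.cross(u, helper)
    norms = np.linalg.norm(w, axis=1, keepdims=True)
    # regenerate the rare near-parallel helper
    bad = norms[:, 0] < 1e-8
    while bad.any():
        helper[bad] = _random_unit_vectors(rng, bad.sum())
        w[bad] = np.cross(u[bad], helper[bad])
        norms = np.linalg.norm(w, axis=1, keepdims=True)
        bad = norms[:, 0] < 1e-8
    return w / norms


def _water_hydrogens(o_pos, dipoles, rng):
    """Hydrogen positions for rigid 3-site waters given unit dipole directions."""
    w = _perpendicular_unit(rng, dipoles)
    h1 = o_pos + _OH_BOND * (np.cos(_HOH_HALF_ANGLE) * dipoles + np.sin(_HOH_HALF_ANGLE) * w)
    h2 = o_pos + _OH_BOND * (np.cos(_HOH_HALF_ANGLE) * dipoles - np.sin(_HOH_HALF_ANGLE) * w)
    return h1, h2


def _chain_ch_directions(rng, n, s_cd):
    """Unit C-H directions whose ensemble -S_CD equals s_cd.

    Mixture model: with probability p = 2 s_cd the C-H vector lies in the
    membrane plane (beta = 90 deg, contributes -S_CD = 0.5), otherwise it is
    isotropic (contributes 0); the mixture mean is exactly s_cd.
    """
    p = 2.0 * s_cd
    planar = rng.random(n) < p
    dirs = _random_unit_vectors(rng, n)
    if planar.any():
        phi = rng.uniform(0, 2 * np.pi, planar.sum())
        dirs[planar] = np.column_stack(
            [np.cos(phi), np.sin(phi), np.zeros(planar.sum())]
        )
    return dirs


_LIPID_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974}


def _lipid_template(spec: BilayerSpec):
    """(name, element, offset) records for one pseudo-lipid in the upper
    leaflet, offsets relative to the P bead; the lower leaflet mirrors z."""
    recs = [
        ("P", "P", (0.0, 0.0, 0.0)),
        ("OP1", "O", (0.07, 0.0, 0.05)),
        ("OP2", "O", (-0.07, 0.0, 0.05)),
        ("N", "N", (0.0, 0.12, 0.25)),
        ("HN1", "H", (0.08, 0.12, 0.31)),
        ("HN2", "H", (-0.08, 0.12, 0.31)),
        ("HN3", "H", (0.0, 0.22, 0.28)),
        ("CC", "C", (0.12, -0.12, 0.35)),
        ("OC1", "O", (0.18, -0.12, 0.40)),
        ("OC2", "O", (0.06, -0.19, 0.38)),
        ("CGL", "C", (0.0, 0.0, -0.20)),
        ("OG1", "O", (0.08, 0.0, -0.24)),
        ("OG2", "O", (-0.08, 0.0, -0.24)),
        ("C21", "C", (-0.14, 0.10, -0.33)),
        ("O21", "O", (-0.20, 0.16, -0.28)),
        ("C31", "C", (0.14, 0.10, -0.33)),
        ("O31", "O", (0.20, 0.16, -0.28)),
    ]
    n_c = spec.n_chain_carbons
    top = 0.45  # first chain carbon sits this far below the P bead
    reach = max(spec.pp_thickness / 2.0 - 0.05, top + 0.1)
    dz = (reach - top) / max(n_c - 1, 1)
    for tag, x_off in (("A", -0.18), ("B", 0.18)):
        for j in range(n_c):
            i = j + 2
            z = -(top + j * dz)
            recs.append((f"C{i}{tag}", "C", (x_off, 0.0, z)))
            # placeholder H offsets; directions are overwritten per order model
            recs.append((f"H{i}{tag}1", "H", (x_off + _CH_BOND, 0.0, z)))
            recs.append((f"H{i}{tag}2", "H", (x_off - _CH_BOND, 0.0, z)))
    return recs


def build_bilayer(spec: BilayerSpec) -> Trajectory:
    """Construct the single-frame synthetic system described by ``spec``."""
    rng = np.random.default_rng(spec.seed)
    L = spec.box_xy
    box = np.array([L, L, spec.z_box])
    mid = spec.z_box / 2.0
    template = _lipid_template(spec)
    n_per_lipid = len(template)
    n_lip = spec.n_lipids
    order_profile = spec.order_profile()

    # residue names: DPPG distributed evenly through the lipid list
    resnames_lip = np.array(["DPPS"] * n_lip, dtype=object)
    if spec.n_dppg:
        step = max(n_lip // spec.n_dppg, 1)
        pg_idx = (np.arange(spec.n_dppg) * step + step // 2) % n_lip
        resnames_lip[np.unique(pg_idx)[: spec.n_dppg]] = "DPPG"
        # ensure exact count even under index collisions
        short = spec.n_dppg - int(np.sum(resnames_lip == "DPPG"))
        if short > 0:
            pool = np.flatnonzero(resnames_lip == "DPPS")
            resnames_lip[pool[:short]] = "DPPG"

    # lattice sites per leaflet
    n_side = int(np.ceil(np.sqrt(spec.lipids_per_leaflet)))
    cell = L / n_side
    sites = np.array(
        [((i + 0.5) * cell, (j + 0.5) * cell) for i in range(n_side) for j in range(n_side)]
    )[: spec.lipids_per_leaflet]

    names, elements, res_names, res_ids, coords = [], [], [], [], []
    rid = 0
    for leaflet, sign in (("upper", +1.0), ("lower", -1.0)):
        for k in range(spec.lipids_per_leaflet):
            lip = rid  # lipid serial
            rid += 1
            x0, y0 = sites[k] + rng.normal(0, spec.lattice_jitter, 2)
            zp = mid + sign * spec.pp_thickness / 2.0
            base = np.array([x0, y0, zp])
            jitter = rng.normal(0, spec.lattice_jitter, (n_per_lipid, 3))
            chain_carbon_pos = {}
            for t, (name, el, off) in enumerate(template):
                pos = base + np.array([off[0], off[1], sign * off[2]]) + jitter[t]
                if name.startswith("C") and name[1:-1].isdigit():
                    chain_carbon_pos[name] = pos
                names.append(name)
                elements.append(el)
                res_names.append(resnames_lip[lip])
                res_ids.append(lip + 1)
                coords.append(pos)
            # amine hydrogens ride the jittered N (fixed covalent geometry)
            n_off = dict((rec[0], rec[2]) for rec in template)
            n_idx = len(names) - n_per_lipid + _template_index(template, "N")
            for hn in ("HN1", "HN2", "HN3"):
                rel = np.array(n_off[hn]) - np.array(n_off["N"])
                idx = len(names) - n_per_lipid + _template_index(template, hn)
                coords[idx] = coords[n_idx] + rel * np.array([1.0, 1.0, sign])
            # rewrite chain hydrogens with order-parameter-model directions
            for tag in ("A", "B"):
                for j in range(spec.n_chain_carbons):
                    i = j + 2
                    cpos = chain_carbon_pos[f"C{i}{tag}"]
                    dirs = _chain_ch_directions(rng, 2, order_profile[j])
                    for h, d in zip((1, 2), dirs):
                        idx = len(names) - n_per_lipid + _template_index(
                            template, f"H{i}{tag}{h}"
                        )
                        coords[idx] = cpos + _CH_BOND * d

    lipid_coords = np.asarray(coords)

    # waters fill the slab outside the P planes
    gap = 0.05
    half_slab_lo = (0.0, mid - spec.pp_thickness / 2.0 - gap)
    half_slab_hi = (mid + spec.pp_thickness / 2.0 + gap, spec.z_box)
    slab_height = (half_slab_lo[1] - half_slab_lo[0]) + (half_slab_hi[1] - half_slab_hi[0])
    capacity = L * L * slab_height * _BULK_WATER_NUMBER_DENSITY * _CAPACITY_SLACK
    if spec.n_waters > capacity:
        raise GeometryError(
            f"{spec.n_waters} waters exceed slab capacity at liquid density "
            f"({capacity:.0f} for {slab_height:.2f} nm of water)"
        )
    o_xy = rng.uniform(0, L, (spec.n_waters, 2))
    frac = (half_slab_lo[1] - half_slab_lo[0]) / slab_height
    lower = rng.random(spec.n_waters) < frac
    o_z = np.where(
        lower,
        rng.uniform(half_slab_lo[0], half_slab_lo[1], spec.n_waters),
        rng.uniform(half_slab_hi[0], half_slab_hi[1], spec.n_waters),
    )
    o_pos = np.column_stack([o_xy, o_z])
    headgroup_pos = lipid_coords[
        np.isin(np.array(names, dtype=object), DEFAULT_HEADGROUP_NAMES)
    ]
    dipoles = _sample_dipoles(rng, o_pos, headgroup_pos, box, mid, spec)
    h1, h2 = _water_hydrogens(o_pos, dipoles, rng)

    for w in range(spec.n_waters):
        rid += 1
        for name, el, pos in (("OW", "O", o_pos[w]), ("HW1", "H", h1[w]), ("HW2", "H", h2[w])):
            names.append(name)
            elements.append(el)
            res_names.append("SOL")
            res_ids.append(rid)
            coords.append(pos)

    # cations near carboxylate oxygens
    n_cat = spec.cation_count
    oc_pos = lipid_coords[
        np.isin(np.array(names[: n_lip * n_per_lipid], dtype=object), ("OC1", "OC2"))
    ]
    pick = rng.integers(0, len(oc_pos), n_cat)
    offs = _random_unit_vectors(rng, n_cat) * rng.uniform(0.26, 0.31, (n_cat, 1))
    cat_pos = oc_pos[pick] + offs
    for c in range(n_cat):
        rid += 1
        names.append("NA")
        elements.append("NA")
        res_names.append("NA")
        res_ids.append(rid)
        coords.append(cat_pos[c])

    elements_arr = np.array(elements, dtype=object)
    masses = np.array(
        [_LIPID_MASSES.get(str(e), 22.990) for e in elements_arr], dtype=float
    )
    atoms = AtomTable(
        atom_id=np.arange(len(names)),
        atom_name=np.array(names, dtype=object),
        element=elements_arr,
        residue_name=np.array(res_names, dtype=object),
        residue_id=np.array(res_ids, dtype=int),
        mass=masses,
    )
    frame = Frame(np.asarray(coords), box, time=0.0)
    return Trajectory(atoms, [frame], timestep=1.0)


def _template_index(template, name):
    for i, rec in enumerate(template):
        if rec[0] == name:
            return i
    raise KeyError(name)


def _sample_dipoles(rng, o_pos, headgroup_pos, box, mid, spec: BilayerSpec):
    """Unit dipole directions for each water under the configured model."""
    model = spec.water_orientation
    n = len(o_pos)
    dipoles = _random_unit_vectors(rng, n)
    if model.kind == "isotropic" or n == 0:
        return dipoles
    sigma = 1.0 / np.sqrt(model.kappa)
    if model.kind == "z_flip":
        base = np.where(o_pos[:, 2:3] > mid, -1.0, 1.0) * np.array([0.0, 0.0, 1.0])
        noisy = base + rng.normal(0, sigma, (n, 3))
        return noisy / np.linalg.norm(noisy, axis=1, keepdims=True)
    # shell_oriented
    ia, ib, dist = neighbor_pairs(o_pos, headgroup_pos, box, spec.orientation_cutoff)
    if len(ia) == 0:
        return dipoles
    order = np.lexsort((dist, ia))
    ia_s = ia[order]
    first = np.unique(ia_s, return_index=True)[1]
    shell_w = ia_s[first]
    nearest_ref = ib[order][first]
    from .traj_model import minimum_image

    v1 = minimum_image(headgroup_pos[nearest_ref], o_pos[shell_w], box)
    v1 /= np.linalg.norm(v1, axis=1, keepdims=True)
    cos_t = np.clip(
        rng.normal(np.cos(np.deg2rad(model.angle_deg)), sigma, len(shell_w)), -1.0, 1.0
    )
    sin_t = np.sqrt(1.0 - cos_t**2)
    perp = _perpendicular_unit(rng, v1)
    dipoles[shell_w] = cos_t[:, None] * v1 + sin_t[:, None] * perp
    return dipoles


# ---------------------------------------------------------------------------
# pseudo-dynamics
# ---------------------------------------------------------------------------


def evolve(traj: Trajectory, n_steps: int, dt: float, spec: BilayerSpec) -> Trajectory:
    """Random-walk dynamics with known diffusion ground truth.

    Water oxygens take 3-D Gaussian steps of per-dimension variance
    2 D dt (D from ``spec.water_D``, converted to nm^2/ps); whole lipids take
    2-D steps at ``spec.lipid_Dxy``; hydrogens follow their parent molecule
    and water orientations are re-sampled each frame.  Coordinates stay
    unwrapped.  Deterministic for a fixed ``spec.seed``.
    """
    if dt <= 0:
        raise ParseError("dt must be positive")
    if traj.n_frames != 1:
        raise ParseError("evolve expects the single-frame output of build_bilayer")
    rng = np.random.default_rng((spec.seed, 0xE0F))
    atoms = traj.atoms
    frame0 = traj.frames[0]
    box = frame0.box
    mid = box[2] / 2.0

    is_wat = atoms.is_water
    o_idx = np.flatnonzero(is_wat & (atoms.element.astype(str) == "O"))
    h_idx = np.flatnonzero(is_wat & (atoms.element.astype(str) == "H"))
    h_idx = h_idx.reshape(len(o_idx), 2)  # builder order: OW, HW1, HW2 per residue

    lipid_mask = np.isin(atoms.residue_name.astype(str), ("DPPS", "DPPG"))
    lipid_rids = np.unique(atoms.residue_id[lipid_mask])
    lipid_atom_groups = [
        np.flatnonzero(lipid_mask & (atoms.residue_id == rid)) for rid in lipid_rids
    ]
    names = atoms.atom_name.astype(str)
    headgroup_idx = np.flatnonzero(lipid_mask & np.isin(names, DEFAULT_HEADGROUP_NAMES))

    # chain C-H groups for per-frame orientation re-sampling
    order_profile = spec.order_profile()
    chain_groups = []  # (carbon_idx, h1_idx, h2_idx, target -S_CD)
    for tag in ("A", "B"):
        for j in range(spec.n_chain_carbons):
            i = j + 2
            c_idx = np.flatnonzero(names == f"C{i}{tag}")
            h1 = np.flatnonzero(names == f"H{i}{tag}1")
            h2 = np.flatnonzero(names == f"H{i}{tag}2")
            if len(c_idx) and len(h1) == len(c_idx) and len(h2) == len(c_idx):
                chain_groups.append((c_idx, h1, h2, order_profile[j]))

    d_w = cm2_per_s_to_nm2_per_ps(spec.water_D)
    d_shell = (
        cm2_per_s_to_nm2_per_ps(spec.shell_water_D)
        if spec.shell_water_D is not None
        else d_w
    )
    sd_w = np.sqrt(2.0 * d_w * dt)
    sd_shell = np.sqrt(2.0 * d_shell * dt)
    d_xy = spec.lipid_Dxy / 1000.0  # nm^2/ns -> nm^2/ps
    sd_lip = np.sqrt(2.0 * d_xy * dt)

    # shell membership fixed at t=0 (only relevant when shell D differs)
    per_water_sd = np.full(len(o_idx), sd_w)
    if spec.shell_water_D is not None and len(headgroup_idx):
        ia, _, _ = neighbor_pairs(
            frame0.coordinates[o_idx],
            frame0.coordinates[headgroup_idx],
            box,
            spec.orientation_cutoff,
        )
        per_water_sd[np.unique(ia)] = sd_shell

    frames = [frame0.copy()]
    coords = frame0.coordinates.copy()
    for step in range(1, n_steps + 1):
        coords = coords.copy()
        # water translation
        disp = rng.normal(0, 1.0, (len(o_idx), 3)) * per_water_sd[:, None]
        coords[o_idx] += disp
        # lipid 2-D translation (rigid per lipid)
        lip_disp = rng.normal(0, sd_lip, (len(lipid_atom_groups), 2))
        for g, d2 in zip(lipid_atom_groups, lip_disp):
            coords[g, 0] += d2[0]
            coords[g, 1] += d2[1]
        # re-sample chain C-H orientations from the order-parameter model
        for c_idx, h1g, h2g, s_cd in chain_groups:
            dirs = _chain_ch_directions(rng, 2 * len(c_idx), s_cd)
            cpos = coords[c_idx]
            coords[h1g] = cpos + _CH_BOND * dirs[: len(c_idx)]
            coords[h2g] = cpos + _CH_BOND * dirs[len(c_idx) :]
        # re-sample water orientations about the new oxygen positions
        o_pos = coords[o_idx]
        dipoles = _sample_dipoles(
            rng, o_pos, coords[headgroup_idx], box, mid, spec
        )
        h1, h2 = _water_hydrogens(o_pos, dipoles, rng)
        coords[h_idx[:, 0]] = h1
        coords[h_idx[:, 1]] = h2
        frames.append(Frame(coords, box.copy(), frame0.time + step * dt))
    return Trajectory(atoms, frames, timestep=dt)


# ---------------------------------------------------------------------------
# melting data
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MeltingSpec:
    """Ground truth for a synthetic temperature-dependent spectral set.

    transitions: list of (center degC, width degC, amplitude) sigmoids in the
    concentration profile c(T); absorbance(lambda, T) = s(lambda) c(T) + noise.
    """

    transitions: tuple = ((53.9, 1.0, -1.0),)
    baseline_intercept: float = 2.0
    baseline_slope: float = 0.0
    wavelengths: tuple = tuple(np.arange(250.0, 300.5, 1.0))
    temperatures: tuple = tuple(np.arange(40.0, 65.25, 0.25))
    band_center: float = 272.0
    band_width: float = 18.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if len(self.wavelengths) == 0 or len(self.temperatures) == 0:
            raise ParseError("wavelength and temperature grids must be non-empty")
        t = np.asarray(self.temperatures)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ParseError("temperature grid must be strictly increasing")
        for _, w, _ in self.transitions:
            if w <= 0:
                raise ParseError("transition widths must be positive")


def make_spectra(spec: MeltingSpec) -> SpectraMatrix:
    """Rank-1 bilinear spectra with known concentration/spectral profiles."""
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.temperatures, dtype=float)
    wl = np.asarray(spec.wavelengths, dtype=float)
    centers = [tr[0] for tr in spec.transitions]
    widths = [tr[1] for tr in spec.transitions]
    amps = [tr[2] for tr in spec.transitions]
    c = (
        spec.baseline_intercept
        + spec.baseline_slope * t
        + boltzmann_profile(t, 0.0, centers, widths, amps)
    )
    s = np.exp(-0.5 * ((wl - spec.band_center) / spec.band_width) ** 2)
    d = np.outer(s, c)
    if spec.noise_sd > 0:
        d = d + rng.normal(0, spec.noise_sd, d.shape)
    return SpectraMatrix(
        wavelengths=wl,
        temperatures=t,
        absorbance=d,
        truth={
            "c": c,
            "s": s,
            "transitions": list(spec.transitions),
        },
    )


def make_dsc(
    transitions: list[dict],
    baseline: tuple[float, float] = (0.0, 0.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    temperatures: np.ndarray | None = None,
) -> Thermogram:
    """Synthetic thermogram: baseline plus two-sided-Gaussian endotherms.

    Each transition dict has keys center (degC), area (integrated enthalpy),
    width_left, width_right (degC).  The peak amplitude is chosen so the
    integrated area equals the requested value exactly.
    """
    t = (
        np.arange(30.0, 70.05, 0.05)
        if temperatures is None
        else np.asarray(temperatures, dtype=float)
    )
    rng = np.random.default_rng(seed)
    slope, intercept = baseline
    y = intercept + slope * t
    for tr in transitions:
        c = tr["center"]
        wl = tr.get("width_left", tr.get("width", 0.5))
        wr = tr.get("width_right", tr.get("width", 0.5))
        if wl <= 0 or wr <= 0:
            raise ParseError("DSC peak widths must be positive")
        amp = tr["area"] / (np.sqrt(np.pi / 2.0) * (wl + wr))
        width = np.where(t < c, wl, wr)
        y = y + amp * np.exp(-0.5 * ((t - c) / width) ** 2)
    if noise_sd > 0:
        y = y + rng.normal(0, noise_sd, len(t))
    return Thermogram(t, y, truth={"transitions": list(transitions), "baseline": baseline})


# ---------------------------------------------------------------------------
# ground-truth serialization (CLI support)
# ---------------------------------------------------------------------------


def write_ground_truth(path: str | Path, spec) -> None:
    Path(path).write_text(json.dumps(spec_to_dict(spec), indent=2) + "\n")
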