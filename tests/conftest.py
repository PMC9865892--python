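"""Shared fixtures: small synthetic systems built programmatically."""

import numpy as np
import pytest

from lamellipid import synthetic_data as sd
from lamellipid.traj_model import AtomTable, Frame, Trajectory


def make_water_table(n_waters: int) -> AtomTable:
    """AtomTable of n 3-site waters (OW, HW1, HW2)."""
    names, elements, resnames, resids = [], [], [], []
    for w in range(n_waters):
        for name, el in (("OW", "O"), ("HW1", "H"), ("HW2", "H")):
            names.append(name)
            elements.append(el)
            resnames.append("SOL")
            resids.append(w + 1)
    masses = {"O": 15.999, "H": 1.008}
    return AtomTable(
        atom_id=np.arange(3 * n_waters),
        atom_name=np.array(names, dtype=object),
        element=np.array(elements, dtype=object),
        residue_name=np.array(resnames, dtype=object),
        residue_id=np.array(resids, dtype=int),
        mass=np.array([masses[e] for e in elements]),
    )


def make_point_table(n, element="C", resname="GAS", mass=12.011):
    """n independent single-atom residues (ideal-gas style)."""
    return AtomTable(
        atom_id=np.arange(n),
        atom_name=np.array([f"{element}{i}" for i in range(n)], dtype=object),
        element=np.array([element] * n, dtype=object),
        residue_name=np.array([resname] * n, dtype=object),
        residue_id=np.arange(1, n + 1),
        mass=np.full(n, mass),
    )


def water_trajectory(o_pos, dipoles, box, n_frames=1, times=None):
    """Trajectory of rigid waters at given O positions and unit dipoles."""
    o_pos = np.asarray(o_pos, dtype=float)
    dipoles = np.asarray(dipoles, dtype=float)
    dipoles = dipoles / np.linalg.norm(dipoles, axis=1, keepdims=True)
    rng = np.random.default_rng(0)
    table = make_water_table(len(o_pos))
    frames = []
    for i in range(n_frames):
        h1, h2 = sd._water_hydrogens(o_pos, dipoles, rng)
        coords = np.empty((3 * len(o_pos), 3))
        coords[0::3] = o_pos
        coords[1::3] = h1
        coords[2::3] = h2
        t = times[i] if times is not None else float(i)
        frames.append(Frame(coords, box, time=t))
    return Trajectory(table, frames, timestep=1.0)


@pytest.fixture(scope="session")
def small_bilayer_spec():
    """A light bilayer (32 lipids, 400 waters) for fast structural tests."""
    return sd.BilayerSpec(
        n_dpps=30,
        n_dppg=2,
        lipids_per_leaflet=16,
        apl_target=0.5,
        pp_thickness=4.0,
        z_box=9.0,
        n_waters=400,
        water_D=1.0e-5,
        lipid_Dxy=5e-3,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bilayer(small_bilayer_spec):
    return sd.build_bilayer(small_bilayer_spec)


@pytest.fixture(scope="session")
def default_bilayer():
    """The full default system (122 DPPS + 6 DPPG, 6400 waters)."""
    return sd.build_bilayer(sd.BilayerSpec(seed=7))
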