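"""Geometric hydrogen-bond detection, classification and cation contacts.

A hydrogen bond is a (donor heavy atom, hydrogen, acceptor) triple with
minimum-image donor-acceptor distance below the cutoff (default 0.3 nm) and
H-donor-acceptor angle, vertex at the donor, below the angular cutoff
(default 30 deg).  Acceptors are all O and N atoms; donors are O/N atoms
carrying at least one covalently bound hydrogen (bond assignment by nearest
heavy atom, configurable).  Counts are classified into lipid-lipid,
water-water, water-lipid and water-moiety classes and optionally normalized
per molecule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from ._neighbors import neighbor_pairs
from .errors import ParseError, SelectionError
from .traj_model import AtomSelection, AtomTable, Frame, Trajectory, minimum_image

__all__ = [
    "HBondCriteria",
    "HBond",
    "HBondReport",
    "PerMolecule",
    "infer_donors",
    "detect_hbonds",
    "detect_hbonds_arrays",
    "count_by_class",
    "normalize_per_molecule",
    "ion_contacts",
    "DEFAULT_GROUP_MAP",
]

#: Lipid-moiety membership by atom name: phosphate, ester carbonyl,
#: carboxylate and glycerol oxygens.
DEFAULT_GROUP_MAP = {
    "PO2": ("OP1", "OP2"),
    "C=O": ("O21", "O31"),
    "COO": ("OC1", "OC2"),
    "glycerol": ("OG1", "OG2"),
}

_COVALENT_H_CUTOFF = 0.125  # nm; O-H ~0.096, N-H ~0.10


@dataclass(frozen=True)
class HBondCriteria:
    max_da_distance: float = 0.3  # nm, strict <
    max_hda_angle_deg: float = 30.0  # strict <, vertex at the donor

    def __post_init__(self):
        if self.max_da_distance <= 0:
            raise ParseError("donor-acceptor cutoff must be positive")
        if not (0 < self.max_hda_angle_deg < 90):
            raise ParseError("H-donor-acceptor angle cutoff must be in (0, 90) deg")


class HBond(NamedTuple):
    donor: int
    hydrogen: int
    acceptor: int


class PerMolecule(NamedTuple):
    value: float  # full precision
    rounded: float  # two decimals


@dataclass
class HBondReport:
    per_frame: dict  # class -> np.ndarray of per-frame counts
    mean: dict  # class -> float
    sd: dict  # class -> float
    per_molecule: dict  # class -> PerMolecule (where applicable)
    n_lipids: int
    n_waters: int
    criteria: HBondCriteria


# ---------------------------------------------------------------------------
# donor inference
# ---------------------------------------------------------------------------


def infer_donors(
    atoms: AtomTable,
    frame: Frame,
    max_bond: float = _COVALENT_H_CUTOFF,
) -> dict[int, list[int]]:
    """Map donor heavy atoms (O/N) to their covalently bound hydrogens.

    Each hydrogen is assigned to the nearest heavy atom of its own residue;
    the assignment counts as a donor bond only when that atom is O or N and
    lies within ``max_bond``.
    """
    el = atoms.element.astype(str)
    donors: dict[int, list[int]] = {}
    h_all = np.flatnonzero(el == "H")
    if len(h_all) == 0:
        return donors
    for rid in np.unique(atoms.residue_id[h_all]):
        res_mask = atoms.residue_id == rid
        heavies = np.flatnonzero(res_mask & (el != "H"))
        hyds = np.flatnonzero(res_mask & (el == "H"))
        if len(heavies) == 0:
            continue
        d = np.linalg.norm(
            frame.coordinates[hyds][:, None, :] - frame.coordinates[heavies][None, :, :],
            axis=-1,
        )
        nearest = np.argmin(d, axis=1)
        best = d[np.arange(len(hyds)), nearest]
        for h, k, dist in zip(hyds, nearest, best):
            heavy = heavies[k]
            if dist <= max_bond and el[heavy] in ("O", "N"):
                donors.setdefault(int(heavy), []).append(int(h))
    return donors


def _default_acceptors(atoms: AtomTable) -> np.ndarray:
    el = atoms.element.astype(str)
    return np.flatnonzero((el == "O") | (el == "N"))


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def _donor_arrays(donors: dict, atoms: AtomTable):
    """Flatten the donor->hydrogens map into vectorizable arrays."""
    donor_idx = np.fromiter(donors.keys(), dtype=int)
    h_counts = np.empty(len(donor_idx), dtype=int)
    h_flat = []
    for i, d in enumerate(donor_idx):
        hyds = donors[int(d)]
        if not hyds:
            raise SelectionError(
                f"donor atom {d} ({atoms.atom_name[d]}) has no hydrogens"
            )
        h_counts[i] = len(hyds)
        h_flat.extend(hyds)
    offsets = np.concatenate([[0], np.cumsum(h_counts)[:-1]])
    return donor_idx, np.asarray(h_flat, dtype=int), h_counts, offsets


def detect_hbonds_arrays(
    frame: Frame,
    atoms: AtomTable,
    donors: dict[int, list[int]] | None = None,
    acceptors: np.ndarray | AtomSelection | None = None,
    criteria: HBondCriteria = HBondCriteria(),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized core of :func:`detect_hbonds`; returns (donor, H, acceptor)
    index arrays."""
    if donors is None:
        donors = infer_donors(atoms, frame)
    empty = (np.empty(0, dtype=int),) * 3
    if not donors:
        return empty
    donor_idx, h_flat, h_counts, offsets = _donor_arrays(donors, atoms)
    if acceptors is None:
        acceptor_idx = _default_acceptors(atoms)
    elif isinstance(acceptors, AtomSelection):
        acceptor_idx = acceptors.indices
    else:
        acceptor_idx = np.asarray(acceptors, dtype=int)
    if len(acceptor_idx) == 0:
        return empty

    ia, ib, dist = neighbor_pairs(
        frame.coordinates[donor_idx],
        frame.coordinates[acceptor_idx],
        frame.box,
        criteria.max_da_distance,
    )
    keep = (dist < criteria.max_da_distance) & (donor_idx[ia] != acceptor_idx[ib])
    ia, ib = ia[keep], ib[keep]
    if len(ia) == 0:
        return empty

    # expand each candidate pair over the donor's hydrogens
    counts = h_counts[ia]
    rep = np.repeat(np.arange(len(ia)), counts)
    within = np.arange(counts.sum()) - np.repeat(np.cumsum(counts) - counts, counts)
    h_atoms = h_flat[offsets[ia][rep] + within]
    d_atoms = donor_idx[ia][rep]
    a_atoms = acceptor_idx[ib][rep]

    coords = frame.coordinates
    da = minimum_image(coords[d_atoms], coords[a_atoms], frame.box)
    dh = minimum_image(coords[d_atoms], coords[h_atoms], frame.box)
    da /= np.linalg.norm(da, axis=1, keepdims=True)
    dh_norm = np.linalg.norm(dh, axis=1)
    valid = dh_norm > 0
    cos_a = np.full(len(d_atoms), -1.0)
    cos_a[valid] = np.einsum("ij,ij->i", dh[valid], da[valid]) / dh_norm[valid]
    cos_max = np.cos(np.deg2rad(criteria.max_hda_angle_deg))
    hit = cos_a > cos_max  # angle strictly below the cutoff
    return d_atoms[hit], h_atoms[hit], a_atoms[hit]


def detect_hbonds(
    frame: Frame,
    atoms: AtomTable,
    donors: dict[int, list[int]] | None = None,
    acceptors: np.ndarray | AtomSelection | None = None,
    criteria: HBondCriteria = HBondCriteria(),
) -> list[HBond]:
    """All (donor, H, acceptor) triples satisfying the geometric criteria.

    A donor may bond several acceptors simultaneously; donors without a bound
    hydrogen raise an error naming the atom.
    """
    d, h, a = detect_hbonds_arrays(frame, atoms, donors, acceptors, criteria)
    return [HBond(int(di), int(hi), int(ai)) for di, hi, ai in zip(d, h, a)]


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

_CLASSES = (
    "lipid-lipid",
    "water-water",
    "water-lipid",
    "water-PO2",
    "water-C=O",
    "water-COO",
    "water-glycerol",
)


def count_by_class(
    traj: Trajectory,
    criteria: HBondCriteria = HBondCriteria(),
    group_map: dict | None = None,
    lipid_resnames: tuple = ("DPPS", "DPPG"),
    exclude_intramolecular: bool = True,
    donors: dict[int, list[int]] | None = None,
) -> HBondReport:
    """Frame-resolved hydrogen-bond counts per class pair.

    Water-moiety classes count water-lipid bonds whose lipid-side atom belongs
    to the named group; they are a subset of the water-lipid class.
    Intra-molecular lipid-lipid bonds are excluded by default.
    """
    atoms = traj.atoms
    group_map = DEFAULT_GROUP_MAP if group_map is None else group_map
    is_wat = atoms.is_water
    is_lip = np.isin(atoms.residue_name.astype(str), lipid_resnames)
    names = atoms.atom_name.astype(str)
    group_index = np.full(len(atoms), -1, dtype=int)
    group_names = list(group_map.keys())
    for gi, group in enumerate(group_names):
        group_index[np.isin(names, group_map[group])] = gi

    if donors is None:
        donors = infer_donors(atoms, traj.frames[0])
    per_frame = {c: np.zeros(traj.n_frames) for c in _CLASSES}
    for fi, fr in enumerate(traj.frames):
        d, _, a = detect_hbonds_arrays(fr, atoms, donors=donors, criteria=criteria)
        ll = is_lip[d] & is_lip[a]
        if exclude_intramolecular:
            ll &= atoms.residue_id[d] != atoms.residue_id[a]
        ww = is_wat[d] & is_wat[a]
        wl = (is_wat[d] & is_lip[a]) | (is_lip[d] & is_wat[a])
        per_frame["lipid-lipid"][fi] = int(ll.sum())
        per_frame["water-water"][fi] = int(ww.sum())
        per_frame["water-lipid"][fi] = int(wl.sum())
        lipid_side = np.where(is_lip[a], a, d)[wl]
        for gi, group in enumerate(group_names):
            per_frame[f"water-{group}"][fi] = int(
                np.sum(group_index[lipid_side] == gi)
            )
    mean = {c: float(v.mean()) for c, v in per_frame.items()}
    sd = {c: float(v.std(ddof=1)) if len(v) > 1 else 0.0 for c, v in per_frame.items()}
    n_lipids = len(np.unique(atoms.residue_id[is_lip]))
    n_waters = len(np.unique(atoms.residue_id[is_wat]))
    per_molecule = {}
    if n_lipids:
        per_molecule["lipid-lipid"] = normalize_per_molecule(mean["lipid-lipid"], n_lipids)
    if n_waters:
        per_molecule["water-water"] = normalize_per_molecule(mean["water-water"], n_waters)
    return HBondReport(
        per_frame=per_frame,
        mean=mean,
        sd=sd,
        per_molecule=per_molecule,
        n_lipids=n_lipids,
        n_waters=n_waters,
        criteria=criteria,
    )


def normalize_per_molecule(total_count: float, n_molecules: int) -> PerMolecule:
    """Exact quotient total/n, carried at full precision and to two decimals."""
    if n_molecules <= 0:
        raise ParseError("n_molecules must be positive")
    value = total_count / n_molecules
    return PerMolecule(value=value, rounded=round(value, 2))


# ---------------------------------------------------------------------------
# ion contacts
# ---------------------------------------------------------------------------


def ion_contacts(
    traj: Trajectory,
    ion_selection: AtomSelection,
    group_selection: AtomSelection,
    cutoff: float = 0.32,
) -> tuple[np.ndarray, float, float]:
    """Per-frame count of ion-group atom pairs within ``cutoff``; mean +/- SD."""
    if cutoff <= 0:
        raise ParseError("cutoff must be positive")
    if len(ion_selection) == 0 or len(group_selection) == 0:
        raise SelectionError("ion_contacts: empty selection")
    counts = np.zeros(traj.n_frames)
    for fi, fr in enumerate(traj.frames):
        ia, _, _ = neighbor_pairs(
            fr.coordinates[ion_selection.indices],
            fr.coordinates[group_selection.indices],
            fr.box,
            cutoff,
        )
        counts[fi] = len(ia)
    sd = float(counts.std(ddof=1)) if len(counts) > 1 else 0.0
    return counts, float(counts.mean()), sd
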