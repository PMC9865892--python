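"""Data model, readers/writers and periodic-geometry primitives.

The model is deliberately small: an :class:`AtomTable` (identity, chemistry,
mass), a sequence of :class:`Frame` objects (coordinates in nm, orthorhombic
box, time in ps) and a :class:`Trajectory` tying them together.  Single-frame
structures are read and written in GRO and PDB dialects (via MDAnalysis);
multi-frame trajectories use a documented plain-text container (see
:func:`write_trajectory`).

Coordinates are stored unwrapped by default so Einstein-relation diffusion
estimators remain meaningful; :func:`wrap_frame` / :func:`unwrap_trajectory`
convert between conventions, tracking per-atom image counters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import GeometryError, ParseError, SelectionError
from .units import ELEMENT_MASSES, WATER_RESNAMES, angstrom_to_nm, nm_to_angstrom

__all__ = [
    "AtomTable",
    "Frame",
    "Trajectory",
    "AtomSelection",
    "minimum_image",
    "minimum_image_distance",
    "assign_leaflets",
    "wrap_frame",
    "unwrap_trajectory",
    "load_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "write_csv_with_metadata",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AtomTable:
    """Per-atom identity table shared by all frames of a trajectory.

    Invariants (enforced by :meth:`validate`): atom ids unique and contiguous
    from 0; positive masses; every water residue has exactly one O and two H.
    """

    atom_id: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    residue_name: np.ndarray
    residue_id: np.ndarray
    mass: np.ndarray
    water_resnames: tuple = WATER_RESNAMES

    def __post_init__(self):
        object.__setattr__(self, "atom_id", np.asarray(self.atom_id, dtype=int))
        object.__setattr__(self, "atom_name", np.asarray(self.atom_name, dtype=object))
        object.__setattr__(self, "element", np.asarray(self.element, dtype=object))
        object.__setattr__(self, "residue_name", np.asarray(self.residue_name, dtype=object))
        object.__setattr__(self, "residue_id", np.asarray(self.residue_id, dtype=int))
        object.__setattr__(self, "mass", np.asarray(self.mass, dtype=float))
        self.validate()

    def validate(self) -> None:
        n = len(self.atom_id)
        for name in ("atom_name", "element", "residue_name", "residue_id", "mass"):
            if len(getattr(self, name)) != n:
                raise ParseError(f"AtomTable column '{name}' has wrong length")
        if not np.array_equal(self.atom_id, np.arange(n)):
            raise ParseError("atom ids must be unique and contiguous from 0")
        if n and not np.all(self.mass > 0):
            bad = int(self.atom_id[self.mass <= 0][0])
            raise ParseError(f"atom {bad} has non-positive mass")
        # water residues must be 3-site: 1 O + 2 H
        is_wat = np.isin(self.residue_name.astype(str), self.water_resnames)
        if is_wat.any():
            for rid in np.unique(self.residue_id[is_wat]):
                el = self.element[self.residue_id == rid].astype(str)
                if not (np.sum(el == "O") == 1 and np.sum(el == "H") == 2):
                    raise ParseError(
                        f"water residue {rid} is not a 3-site (1 O + 2 H) water"
                    )

    def __len__(self) -> int:
        return len(self.atom_id)

    @property
    def n_atoms(self) -> int:
        return len(self)

    @property
    def is_water(self) -> np.ndarray:
        return np.isin(self.residue_name.astype(str), self.water_resnames)

    def select(
        self,
        residue_name: str | Sequence[str] | None = None,
        atom_name: str | Sequence[str] | None = None,
        element: str | Sequence[str] | None = None,
        label: str | None = None,
    ) -> "AtomSelection":
        """Boolean-AND selection on residue name / atom name / element."""
        mask = np.ones(len(self), dtype=bool)
        for value, column in (
            (residue_name, self.residue_name),
            (atom_name, self.atom_name),
            (element, self.element),
        ):
            if value is not None:
                values = [value] if isinstance(value, str) else list(value)
                mask &= np.isin(column.astype(str), values)
        if label is None:
            parts = [str(v) for v in (residue_name, atom_name, element) if v is not None]
            label = "&".join(parts) or "all"
        return AtomSelection(indices=np.flatnonzero(mask), label=label)

    def water_oxygens(self) -> "AtomSelection":
        idx = np.flatnonzero(self.is_water & (self.element.astype(str) == "O"))
        return AtomSelection(indices=idx, label="water-O")


@dataclass(frozen=True)
class AtomSelection:
    """Validated, duplicate-free index set into an :class:`AtomTable`."""

    indices: np.ndarray
    label: str = ""

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=int)
        if idx.ndim != 1:
            raise SelectionError("selection indices must be 1-D")
        if len(np.unique(idx)) != len(idx):
            raise SelectionError(f"selection '{self.label}' contains duplicates")
        if len(idx) and idx.min() < 0:
            raise SelectionError(f"selection '{self.label}' has negative indices")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class Frame:
    """One configuration: coordinates (nm), orthorhombic box (nm), time (ps)."""

    coordinates: np.ndarray
    box: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        if not np.all(self.box > 0):
            raise GeometryError(f"box lengths must be positive, got {self.box}")

    @property
    def n_atoms(self) -> int:
        return len(self.coordinates)

    def copy(self) -> "Frame":
        return Frame(self.coordinates.copy(), self.box.copy(), self.time)


@dataclass
class Trajectory:
    """An atom table plus an ordered sequence of frames."""

    atoms: AtomTable
    frames: list
    timestep: float = 1.0

    def __post_init__(self):
        for i, fr in enumerate(self.frames):
            if fr.n_atoms != len(self.atoms):
                raise ParseError(
                    f"frame {i} has {fr.n_atoms} atoms, table has {len(self.atoms)}"
                )
        times = np.array([fr.time for fr in self.frames])
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ParseError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coordinate_array(self, selection: AtomSelection | None = None) -> np.ndarray:
        """Stack coordinates into (n_frames, n_atoms_selected, 3)."""
        if selection is None:
            return np.stack([fr.coordinates for fr in self.frames])
        return np.stack([fr.coordinates[selection.indices] for fr in self.frames])

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]


# ---------------------------------------------------------------------------
# periodic geometry
# ---------------------------------------------------------------------------


def minimum_image(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement b - a under an orthorhombic box.

    Each component of the result lies in (-L/2, L/2].  Broadcasts over
    leading dimensions of ``a`` and ``b``.
    """
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise GeometryError(f"box lengths must be positive, got {box}")
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    d = d - box * np.round(d / box)
    # np.round sends -L/2 exactly to -L/2; fold onto the (+L/2] side
    d = np.where(d <= -box / 2, d + box, d)
    return d


def minimum_image_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    return np.linalg.norm(minimum_image(a, b, box), axis=-1)


def assign_leaflets(
    frame: Frame,
    atoms: AtomTable,
    lipid_selection: AtomSelection,
    ref_atom_name: str = "P",
) -> dict:
    """Split lipids into 'upper'/'lower' leaflets by reference-atom z.

    The midplane is the mean z of all reference atoms; lipids whose reference
    atom sits above it are 'upper'.  Returns ``{residue_id: label}``.  If all
    lipids fall on one side a warning is emitted and a single leaflet returned.
    """
    sel_names = atoms.atom_name[lipid_selection.indices].astype(str)
    ref_idx = lipid_selection.indices[sel_names == ref_atom_name]
    if len(ref_idx) == 0:
        raise SelectionError(f"no '{ref_atom_name}' atoms in lipid selection")
    z = frame.coordinates[ref_idx, 2]
    midplane = z.mean()
    labels = {}
    for idx, zi in zip(ref_idx, z):
        rid = int(atoms.residue_id[idx])
        labels[rid] = "upper" if zi > midplane else "lower"
    values = set(labels.values())
    if len(values) == 1:
        warnings.warn(
            "all lipids on one side of the midplane: single leaflet", stacklevel=2
        )
    return labels


def wrap_frame(frame: Frame) -> tuple[Frame, np.ndarray]:
    """Wrap coordinates into [0, L) per dimension; also return image counters."""
    images = np.floor(frame.coordinates / frame.box).astype(int)
    wrapped = frame.coordinates - images * frame.box
    return Frame(wrapped, frame.box.copy(), frame.time), images


def unwrap_trajectory(traj: Trajectory) -> Trajectory:
    """Remove periodic jumps by minimum-image continuity between frames.

    Assumes no atom moves more than L/2 per frame interval; per-atom image
    counters are accumulated from the first frame.
    """
    if traj.n_frames == 0:
        return traj
    out = [traj.frames[0].copy()]
    prev = out[0].coordinates
    for fr in traj.frames[1:]:
        step = minimum_image(prev, fr.coordinates, fr.box)
        new = prev + step
        out.append(Frame(new, fr.box.copy(), fr.time))
        prev = new
    return Trajectory(traj.atoms, out, traj.timestep)


# ---------------------------------------------------------------------------
# structure I/O (GRO / PDB via MDAnalysis)
# ---------------------------------------------------------------------------

_SUPPORTED_FORMATS = ("gro", "pdb")


def _infer_element(name: str) -> str:
    name = name.strip()
    if name[:2].upper() == "NA":
        return "NA"
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise ParseError(f"cannot infer element from atom name '{name}'")


def _masses_from_elements(elements: np.ndarray) -> np.ndarray:
    masses = np.empty(len(elements))
    for i, el in enumerate(elements):
        try:
            masses[i] = ELEMENT_MASSES[str(el)]
        except KeyError:
            raise ParseError(f"no mass for element '{el}'") from None
    return masses


def load_structure(path: str | Path, format: str | None = None) -> tuple[AtomTable, Frame]:
    """Read a single-frame coordinate file (GRO or PDB) into the data model.

    Coordinates are converted to nm regardless of source units.  Triclinic
    boxes are rejected; a missing box is an error.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in _SUPPORTED_FORMATS:
        raise ParseError(f"unsupported coordinate format '{fmt}' (use gro or pdb)")

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path), format=fmt)
        except Exception as exc:  # pragma: no cover - message passthrough
            raise ParseError(f"failed to parse {path}: {exc}") from exc

    dims = u.dimensions
    if dims is None or not np.all(np.asarray(dims[:3]) > 0):
        raise ParseError(f"{path}: missing or invalid box record")
    if not np.allclose(dims[3:], 90.0, atol=1e-3):
        raise GeometryError(f"{path}: triclinic boxes are unsupported (angles {dims[3:]})")

    if hasattr(u.atoms, "ids"):
        ids = np.asarray(u.atoms.ids)
        if len(np.unique(ids)) != len(ids):
            raise ParseError(f"{path}: duplicated atom ids in coordinate file")

    names = u.atoms.names.astype(object)
    elements = np.array([_infer_element(n) for n in names], dtype=object)
    table = AtomTable(
        atom_id=np.arange(len(names)),
        atom_name=names,
        element=elements,
        residue_name=u.atoms.resnames.astype(object),
        residue_id=u.atoms.resids.astype(int),
        mass=_masses_from_elements(elements),
    )
    frame = Frame(
        coordinates=angstrom_to_nm(u.atoms.positions.astype(float)),
        box=angstrom_to_nm(np.asarray(dims[:3], dtype=float)),
        time=0.0,
    )
    return table, frame


def write_structure(path: str | Path, atoms: AtomTable, frame: Frame) -> None:
    """Write a single-frame GRO or PDB file (dialect from the extension)."""
    path = Path(path)
    fmt = path.suffix.lstrip(".").lower()
    if fmt not in _SUPPORTED_FORMATS:
        raise ParseError(f"unsupported coordinate format '{fmt}' (use gro or pdb)")

    import MDAnalysis as mda

    resids = atoms.residue_id
    uniq, resindex = np.unique(resids, return_inverse=True)
    u = mda.Universe.empty(
        n_atoms=len(atoms),
        n_residues=len(uniq),
        atom_resindex=resindex,
        trajectory=True,
    )
    u.add_TopologyAttr("names", atoms.atom_name.astype(str))
    resnames = [str(atoms.residue_name[resids == rid][0]) for rid in uniq]
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", uniq)
    u.atoms.positions = nm_to_angstrom(frame.coordinates)
    u.dimensions = np.concatenate([nm_to_angstrom(frame.box), [90.0, 90.0, 90.0]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


# ---------------------------------------------------------------------------
# multi-frame plain-text trajectory container
# ---------------------------------------------------------------------------

_TRAJ_MAGIC = "#LAMELLIPID-TRAJ v1"


def write_trajectory(path: str | Path, traj: Trajectory) -> None:
    """Write the documented plain-text trajectory container.

    Layout::

        #LAMELLIPID-TRAJ v1
        #natoms <N>  timestep_ps <dt>
        #atom <id> <name> <element> <resname> <resid> <mass>   (N lines)
        #frame <time_ps> <Lx> <Ly> <Lz>
        x y z                                                  (N lines, nm)
        ... further frames ...
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{_TRAJ_MAGIC}\n")
        fh.write(f"#natoms {len(traj.atoms)}  timestep_ps {traj.timestep:g}\n")
        a = traj.atoms
        for i in range(len(a)):
            fh.write(
                f"#atom {a.atom_id[i]} {a.atom_name[i]} {a.element[i]} "
                f"{a.residue_name[i]} {a.residue_id[i]} {a.mass[i]:.4f}\n"
            )
        for fr in traj.frames:
            fh.write(
                f"#frame {fr.time:.6f} {fr.box[0]:.6f} {fr.box[1]:.6f} {fr.box[2]:.6f}\n"
            )
            np.savetxt(fh, fr.coordinates, fmt="%.6f")


def read_trajectory(path: str | Path) -> Trajectory:
    """Read the plain-text trajectory container written by :func:`write_trajectory`."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    with path.open() as fh:
        first = fh.readline().rstrip("\n")
        if first != _TRAJ_MAGIC:
            raise ParseError(f"{path}:1: not a lamellipid trajectory file")
        header = fh.readline().split()
        try:
            n_atoms = int(header[1])
            timestep = float(header[3])
        except (IndexError, ValueError):
            raise ParseError(f"{path}:2: malformed header line") from None
        cols: dict[str, list] = {k: [] for k in ("id", "name", "el", "rn", "ri", "m")}
        for lineno in range(3, 3 + n_atoms):
            parts = fh.readline().split()
            if len(parts) != 7 or parts[0] != "#atom":
                raise ParseError(f"{path}:{lineno}: malformed atom record")
            for key, val in zip(cols, parts[1:]):
                cols[key].append(val)
        atoms = AtomTable(
            atom_id=np.array(cols["id"], dtype=int),
            atom_name=np.array(cols["name"], dtype=object),
            element=np.array(cols["el"], dtype=object),
            residue_name=np.array(cols["rn"], dtype=object),
            residue_id=np.array(cols["ri"], dtype=int),
            mass=np.array(cols["m"], dtype=float),
        )
        frames = []
        lineno = 2 + n_atoms
        while True:
            line = fh.readline()
            lineno += 1
            if not line:
                break
            parts = line.split()
            if parts[0] != "#frame" or len(parts) != 5:
                raise ParseError(f"{path}:{lineno}: expected frame header")
            time, lx, ly, lz = map(float, parts[1:])
            coords = np.loadtxt(fh, max_rows=n_atoms).reshape(n_atoms, 3)
            lineno += n_atoms
            frames.append(Frame(coords, np.array([lx, ly, lz]), time))
    return Trajectory(atoms, frames, timestep)


# ---------------------------------------------------------------------------
# tidy CSV output with a metadata header
# ---------------------------------------------------------------------------


def write_csv_with_metadata(path: str | Path, df, metadata: dict) -> None:
    """Write a pandas DataFrame as CSV preceded by '# key: value' header lines."""
    path = Path(path)
    with path.open("w") as fh:
        for key, value in metadata.items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)
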