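"""Structures, trajectories and atom selections.

The in-memory containers are thin columnar wrappers around numpy arrays:
a :class:`Structure` is one conformation (one PDB model or one trajectory
frame with its topology), a :class:`Trajectory` is an ordered stack of
coordinate frames sharing one topology and a frame->time mapping in ns.

PDB parsing and writing are delegated to biotite; DCD trajectories go
through MDAnalysis.  Residue numbers are always the author (deposited)
numbering and are never renumbered, so residues can be addressed by the
identifiers used in the structural literature (e.g. the alpha7-helix
E293-K305 of the LFA-1 I domain).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

__all__ = [
    "BACKBONE_ATOMS",
    "METAL_ELEMENTS",
    "PDBParseError",
    "SelectionError",
    "TrajectoryError",
    "Atom",
    "Structure",
    "Trajectory",
    "SelectionSpec",
    "Selection",
    "read_pdb",
    "write_pdb",
    "read_trajectory",
    "write_trajectory",
    "resolve_selection",
    "find_midas_ion",
]

#: Backbone atom set used for all backbone RMSD observables.  The carbonyl
#: oxygen is included deliberately: fits and measurements are over *all*
#: backbone heavy atoms, not Calpha only.
BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: Elements accepted as a MIDAS metal ion (divalent cations seen in
#: integrin I-domain structures).
METAL_ELEMENTS = frozenset({"CA", "MG", "MN"})


class PDBParseError(ValueError):
    """A PDB record could not be parsed (message carries the line number)."""


class SelectionError(ValueError):
    """A selection resolved to nothing, or was ambiguous."""


class TrajectoryError(ValueError):
    """Trajectory/topology inconsistency (atom counts, unsupported format)."""


@dataclass(frozen=True)
class Atom:
    """One atom of a structure, in author numbering."""

    serial: int
    name: str
    element: str
    res_name: str
    res_id: int
    chain: str
    coords: np.ndarray
    hetero: bool = False
    occupancy: float = 1.0
    altloc: str = ""


class Structure:
    """A single conformation: parallel per-atom annotation arrays + coordinates.

    Parameters are array-likes of equal length; ``coords`` has shape
    ``(n_atoms, 3)`` in Angstrom.  ``(chain, res_id, name)`` is unique per
    model once the alternate-location policy has been applied.
    """

    def __init__(
        self,
        name: Sequence[str],
        element: Sequence[str],
        res_name: Sequence[str],
        res_id: Sequence[int],
        chain: Sequence[str],
        coords: np.ndarray,
        serial: Sequence[int] | None = None,
        hetero: Sequence[bool] | None = None,
        occupancy: Sequence[float] | None = None,
        altloc: Sequence[str] | None = None,
        model_id: int = 1,
        metadata: Mapping | None = None,
    ):
        n = len(name)
        if n < 1:
            raise ValueError("a Structure needs at least one atom")
        self.name = np.asarray(name, dtype="U6")
        self.element = np.asarray(element, dtype="U2")
        self.res_name = np.asarray(res_name, dtype="U5")
        self.res_id = np.asarray(res_id, dtype=np.int64)
        self.chain = np.asarray(chain, dtype="U4")
        self.coords = np.asarray(coords, dtype=np.float64)
        self.serial = (
            np.arange(1, n + 1, dtype=np.int64)
            if serial is None
            else np.asarray(serial, dtype=np.int64)
        )
        self.hetero = (
            np.zeros(n, dtype=bool) if hetero is None else np.asarray(hetero, dtype=bool)
        )
        self.occupancy = (
            np.ones(n) if occupancy is None else np.asarray(occupancy, dtype=np.float64)
        )
        self.altloc = (
            np.full(n, "", dtype="U1") if altloc is None else np.asarray(altloc, dtype="U1")
        )
        self.model_id = int(model_id)
        self.metadata = dict(metadata) if metadata else {}

        for arr, label in (
            (self.element, "element"),
            (self.res_name, "res_name"),
            (self.res_id, "res_id"),
            (self.chain, "chain"),
            (self.serial, "serial"),
            (self.hetero, "hetero"),
            (self.occupancy, "occupancy"),
            (self.altloc, "altloc"),
        ):
            if len(arr) != n:
                raise ValueError(f"annotation '{label}' has length {len(arr)} != {n}")
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords must have shape ({n}, 3), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates contain non-finite values")
        keys = set(zip(self.chain, self.res_id, self.name, self.altloc))
        if len(keys) != n:
            raise ValueError("(chain, res_id, name, altloc) is not unique within the model")

    @property
    def n_atoms(self) -> int:
        return len(self.name)

    def __len__(self) -> int:
        return self.n_atoms

    def atom(self, index: int) -> Atom:
        return Atom(
            serial=int(self.serial[index]),
            name=str(self.name[index]),
            element=str(self.element[index]),
            res_name=str(self.res_name[index]),
            res_id=int(self.res_id[index]),
            chain=str(self.chain[index]),
            coords=self.coords[index].copy(),
            hetero=bool(self.hetero[index]),
            occupancy=float(self.occupancy[index]),
            altloc=str(self.altloc[index]),
        )

    def residues(self) -> list[tuple[str, int]]:
        """Unique ``(chain, res_id)`` pairs in file order."""
        seen: dict[tuple[str, int], None] = {}
        for c, r in zip(self.chain, self.res_id):
            seen.setdefault((str(c), int(r)), None)
        return list(seen)

    def with_coords(self, coords: np.ndarray, model_id: int | None = None) -> "Structure":
        """A new Structure sharing all annotations but carrying new coordinates."""
        return Structure(
            name=self.name,
            element=self.element,
            res_name=self.res_name,
            res_id=self.res_id,
            chain=self.chain,
            coords=np.asarray(coords, dtype=np.float64),
            serial=self.serial,
            hetero=self.hetero,
            occupancy=self.occupancy,
            altloc=self.altloc,
            model_id=self.model_id if model_id is None else model_id,
            metadata=self.metadata,
        )

    def atom_index(self, chain: str, res_id: int, name: str) -> int:
        """Index of a single named atom; raises :class:`SelectionError` if absent."""
        mask = (self.chain == chain) & (self.res_id == res_id) & (self.name == name)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise SelectionError(f"no atom {name} in residue {chain}:{res_id}")
        if idx.size > 1:
            raise SelectionError(f"atom {name} in residue {chain}:{res_id} is ambiguous")
        return int(idx[0])


@dataclass
class Trajectory:
    """An ordered stack of coordinate frames over one topology.

    ``frames`` has shape ``(n_frames, n_atoms, 3)`` in Angstrom;
    ``time_per_frame`` maps frame index to simulation time in ns.
    """

    topology: Structure
    frames: np.ndarray
    time_per_frame: float
    origin_time: float = 0.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise TrajectoryError(f"frames must have shape (F, N, 3), got {self.frames.shape}")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise TrajectoryError(
                f"atom count mismatch: topology has {self.topology.n_atoms} atoms, "
                f"frames have {self.frames.shape[1]}"
            )
        if self.time_per_frame <= 0:
            raise TrajectoryError("time_per_frame must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Frame times in ns."""
        return self.origin_time + self.time_per_frame * np.arange(self.n_frames)

    def frame(self, index: int) -> Structure:
        return self.topology.with_coords(self.frames[index], model_id=index + 1)


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _validate_pdb_text(path: Path) -> None:
    # biotite does not report line numbers on failure, so pre-scan the
    # coordinate records cheaply and attribute errors to a line.
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            record = line.rstrip("\n")
            if len(record) < 54:
                raise PDBParseError(
                    f"{path}:{lineno}: ATOM/HETATM record shorter than the coordinate fields"
                )
            try:
                int(record[22:26])
                float(record[30:38])
                float(record[38:46])
                float(record[46:54])
            except ValueError as err:
                raise PDBParseError(
                    f"{path}:{lineno}: malformed ATOM/HETATM record ({err})"
                ) from None


def _apply_altloc_policy(array: "struc.AtomArray") -> "struc.AtomArray":
    """Collapse alternate locations to a single conformer.

    Policy: keep the highest-occupancy conformer of each
    ``(chain, res_id, atom name)`` group; ties go to the alphabetically
    first altloc letter, which makes the resulting topology deterministic.
    """
    try:
        altloc = array.get_annotation("altloc_id")
    except ValueError:
        return array
    occupancy = array.get_annotation("occupancy")
    best: dict[tuple, tuple] = {}
    for i in range(array.array_length()):
        key = (array.chain_id[i], int(array.res_id[i]), array.atom_name[i])
        rank = (-float(occupancy[i]), str(altloc[i]), i)
        if key not in best or rank < best[key][0]:
            best[key] = (rank, i)
    keep = np.zeros(array.array_length(), dtype=bool)
    keep[[i for _, i in best.values()]] = True
    return array[keep]


def _structure_from_array(array: "struc.AtomArray", model_id: int, metadata: Mapping) -> Structure:
    try:
        serial = array.get_annotation("atom_id")
    except ValueError:
        serial = None
    try:
        occupancy = array.get_annotation("occupancy")
    except ValueError:
        occupancy = None
    try:
        altloc = np.char.replace(array.get_annotation("altloc_id"), ".", "")
    except ValueError:
        altloc = None
    return Structure(
        name=array.atom_name,
        element=array.element,
        res_name=array.res_name,
        res_id=array.res_id,
        chain=array.chain_id,
        coords=array.coord,
        serial=serial,
        hetero=array.hetero,
        occupancy=occupancy,
        altloc=altloc,
        model_id=model_id,
        metadata=metadata,
    )


def read_pdb(path, model: int | str = "all"):
    """Read a PDB file.

    Parameters
    ----------
    path
        PDB file with ATOM/HETATM (and optionally MODEL/ENDMDL) records.
        HETATM records (metal ions, waters) are retained and flagged.
    model
        ``"all"`` returns a list of :class:`Structure` (one per model,
        a single-element list for single-model files); an integer (1-based)
        returns that model only.

    Returns
    -------
    Structure or list of Structure
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such PDB file: {path}")
    _validate_pdb_text(path)
    pdb_file = pdbio.PDBFile.read(str(path))
    n_models = pdb_file.get_model_count()
    metadata = {"source": str(path)}

    def one(m: int) -> Structure:
        array = pdb_file.get_structure(
            model=m, altloc="all", extra_fields=["occupancy", "atom_id"]
        )
        array = _apply_altloc_policy(array)
        return _structure_from_array(array, model_id=m, metadata=metadata)

    if model == "all":
        return [one(m) for m in range(1, n_models + 1)]
    model = int(model)
    if not 1 <= model <= n_models:
        raise ValueError(f"model {model} absent: {path} has {n_models} model(s)")
    return one(model)


def _to_atom_array(structure: Structure) -> "struc.AtomArray":
    array = struc.AtomArray(structure.n_atoms)
    array.coord = structure.coords
    array.chain_id = structure.chain
    array.res_id = structure.res_id
    array.res_name = structure.res_name
    array.atom_name = structure.name
    array.element = structure.element
    array.hetero = structure.hetero
    array.set_annotation("occupancy", structure.occupancy)
    array.set_annotation("b_factor", np.zeros(structure.n_atoms))
    array.set_annotation("atom_id", structure.serial)
    return array


def write_pdb(path, obj) -> None:
    """Write a :class:`Structure`, a list of Structures (multi-model) or a
    :class:`Trajectory` (one model per frame) as a PDB file."""
    path = Path(path)
    if isinstance(obj, Structure):
        array = _to_atom_array(obj)
    elif isinstance(obj, Trajectory):
        template = _to_atom_array(obj.topology)
        array = struc.stack(
            [_with_coord(template, frame) for frame in obj.frames]
        )
    else:
        structures = list(obj)
        if not structures:
            raise ValueError("nothing to write")
        array = struc.stack([_to_atom_array(s) for s in structures])
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(array)
    pdb_file.write(str(path))


def _with_coord(template: "struc.AtomArray", coords: np.ndarray) -> "struc.AtomArray":
    out = template.copy()
    out.coord = np.asarray(coords, dtype=np.float32)
    return out


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def read_trajectory(topology_path, traj_path, time_per_frame: float,
                    origin_time: float = 0.0) -> Trajectory:
    """Read a trajectory from a multi-model PDB or a DCD file.

    ``time_per_frame`` is in ns.  For multi-model PDB, ``topology_path``
    may equal ``traj_path`` (or be None) in which case the first model
    provides the topology.
    """
    if time_per_frame <= 0:
        raise TrajectoryError("time_per_frame must be positive")
    traj_path = Path(traj_path)
    suffix = traj_path.suffix.lower()
    if suffix in (".pdb", ".ent"):
        models = read_pdb(traj_path, model="all")
        if topology_path is None or Path(topology_path) == traj_path:
            topology = models[0]
        else:
            topology = read_pdb(topology_path, model=1)
        for i, m in enumerate(models):
            if m.n_atoms != topology.n_atoms:
                raise TrajectoryError(
                    f"atom count mismatch: topology has {topology.n_atoms} atoms "
                    f"but frame {i + 1} has {m.n_atoms}"
                )
        frames = np.stack([m.coords for m in models])
    elif suffix == ".dcd":
        if topology_path is None:
            raise TrajectoryError("a topology PDB is required to read a DCD trajectory")
        topology = read_pdb(topology_path, model=1)
        from MDAnalysis.coordinates.DCD import DCDReader

        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", category=DeprecationWarning)
            with DCDReader(str(traj_path)) as reader:
                if reader.n_atoms != topology.n_atoms:
                    raise TrajectoryError(
                        f"atom count mismatch: topology has {topology.n_atoms} atoms "
                        f"but trajectory has {reader.n_atoms}"
                    )
                frames = np.stack([ts.positions.astype(np.float64) for ts in reader])
    else:
        raise TrajectoryError(f"unsupported trajectory format: {traj_path}")
    return Trajectory(topology, frames, time_per_frame, origin_time)


def write_trajectory(path, trajectory: Trajectory) -> None:
    """Write a trajectory as multi-model PDB (``.pdb``) or DCD (``.dcd``)."""
    path = Path(path)
    if path.suffix.lower() in (".pdb", ".ent"):
        write_pdb(path, trajectory)
        return
    if path.suffix.lower() != ".dcd":
        raise TrajectoryError(f"unsupported trajectory format: {path}")
    import MDAnalysis as mda

    n = trajectory.topology.n_atoms
    universe = mda.Universe.empty(n, trajectory=True)
    with warnings.catch_warnings():
        # synthetic frames carry no unit cell; MDAnalysis warns per frame
        warnings.filterwarnings("ignore", message="No dimensions set")
        with mda.Writer(str(path), n_atoms=n, format="DCD") as writer:
            for frame in trajectory.frames:
                universe.atoms.positions = frame
                writer.write(universe.atoms)


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionSpec:
    """Declarative atom selection: chain AND residue filter AND atom-name filter.

    ``resid_ranges`` are inclusive ``(first, last)`` pairs in author
    numbering.  Hydrogens are always excluded (crystal references lack
    them); HETATM atoms are excluded unless ``include_hetero`` is set.
    """

    chain: str | None = None
    resid_ranges: tuple[tuple[int, int], ...] | None = None
    resids: tuple[int, ...] | None = None
    atom_names: tuple[str, ...] | None = None
    include_hetero: bool = False

    @classmethod
    def coerce(cls, spec) -> "SelectionSpec":
        if isinstance(spec, cls):
            return spec
        if isinstance(spec, Mapping):
            ranges = spec.get("resid_ranges")
            if ranges is not None:
                ranges = tuple((int(a), int(b)) for a, b in ranges)
            resids = spec.get("resids")
            if resids is not None:
                resids = tuple(int(r) for r in resids)
            names = spec.get("atom_names")
            if names is not None:
                names = tuple(str(n) for n in names)
            return cls(
                chain=spec.get("chain"),
                resid_ranges=ranges,
                resids=resids,
                atom_names=names,
                include_hetero=bool(spec.get("include_hetero", False)),
            )
        raise TypeError(f"cannot interpret {spec!r} as a selection")

    def backbone(self) -> "SelectionSpec":
        return replace(self, atom_names=BACKBONE_ATOMS)


@dataclass(frozen=True, eq=False)
class Selection:
    """A spec resolved against one topology: sorted unique atom indices."""

    spec: SelectionSpec
    indices: np.ndarray

    def __len__(self) -> int:
        return len(self.indices)


def resolve_selection(structure: Structure, spec) -> Selection:
    """Resolve a :class:`SelectionSpec` (or mapping) against a structure.

    Deterministic: the same (topology, spec) always yields the same
    indices, in topology order.  An empty result is an error, as is a
    residue filter that matches residues in more than one chain while no
    chain was named.
    """
    spec = SelectionSpec.coerce(spec)
    mask = structure.element != "H"
    if not spec.include_hetero:
        mask &= ~structure.hetero
    if spec.chain is not None:
        mask &= structure.chain == spec.chain
    has_resid_filter = spec.resid_ranges is not None or spec.resids is not None
    if has_resid_filter:
        resmask = np.zeros(structure.n_atoms, dtype=bool)
        if spec.resid_ranges is not None:
            for lo, hi in spec.resid_ranges:
                resmask |= (structure.res_id >= lo) & (structure.res_id <= hi)
        if spec.resids is not None:
            resmask |= np.isin(structure.res_id, np.asarray(spec.resids))
        mask &= resmask
    if spec.atom_names is not None:
        mask &= np.isin(structure.name, np.asarray(spec.atom_names))
    indices = np.flatnonzero(mask)
    if indices.size == 0:
        raise SelectionError(f"selection matched no atoms: {spec}")
    if spec.chain is None and has_resid_filter:
        chains = np.unique(structure.chain[indices])
        if len(chains) > 1:
            raise SelectionError(
                f"ambiguous chain: residue filter matches chains {list(chains)}; "
                f"name a chain explicitly"
            )
    return Selection(spec=spec, indices=indices)


def find_midas_ion(structure: Structure, element: str | None = None) -> int:
    """Index of the single MIDAS metal ion (HETATM with a divalent-metal element).

    Exactly one candidate must exist; more than one is an error unless a
    specific element is requested that disambiguates.
    """
    elements = {element.upper()} if element else METAL_ELEMENTS
    mask = structure.hetero & np.isin(structure.element, sorted(elements))
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise SelectionError(f"no metal ion (elements {sorted(elements)}) found")
    if idx.size > 1:
        labels = [f"{structure.chain[i]}:{structure.res_id[i]}" for i in idx]
        raise SelectionError(f"ambiguous metal ion, candidates at {labels}")
    return int(idx[0])
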