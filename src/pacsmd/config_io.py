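"""Run configuration, directory layout, and structure/trajectory I/O.

The run is controlled by a single TOML file using the cascade-MD keyword
set (``simulator``, ``type``, ``n_replica``, ``max_cycle``, ``threshold``,
``d_threshold``, ``bound_threshold``, ``frame_sel``, ``selection1`` ..
``selection4``, ``reference``, ``analyzer``, ``mdconf``).  Coordinates are
nanometres in memory; PDB files on disk keep their native angstroms.
"""

from __future__ import annotations

import dataclasses
import re
import tomllib
import warnings
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, ValidationError

__all__ = [
    "Config", "ConfigError", "FormatError", "LayoutError", "RunLayout",
    "Snapshot", "PACS_TYPES", "load_config", "read_structure",
    "write_structure", "read_trajectory", "write_trajectory",
]

#: The implemented cascade-selection variants.
PACS_TYPES = ("target", "rmsd", "dissociation", "association", "a_d", "ee",
              "template")


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


class FormatError(ValueError):
    """Unparseable or empty structure/trajectory file."""


class LayoutError(ValueError):
    """A path does not follow the trial/cycle/replica scheme."""


# ---------------------------------------------------------------------------
# Snapshot
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class Snapshot:
    """One frame: coordinates (nm), optional velocities and masses, and the
    provenance indices (trial, cycle, replica, frame) that locate it in a
    cascade run."""

    coords: np.ndarray
    velocities: Optional[np.ndarray] = None
    masses: Optional[np.ndarray] = None
    atom_names: Optional[list[str]] = None
    resids: Optional[np.ndarray] = None
    trial: int = 0
    cycle: int = 0
    replica: int = 0
    frame: int = 0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def copy(self) -> "Snapshot":
        return Snapshot(
            coords=self.coords.copy(),
            velocities=None if self.velocities is None else self.velocities.copy(),
            masses=None if self.masses is None else np.asarray(self.masses).copy(),
            atom_names=None if self.atom_names is None else list(self.atom_names),
            resids=None if self.resids is None else np.asarray(self.resids).copy(),
            trial=self.trial, cycle=self.cycle,
            replica=self.replica, frame=self.frame,
        )

    def with_provenance(self, *, trial: int | None = None, cycle: int | None = None,
                        replica: int | None = None, frame: int | None = None
                        ) -> "Snapshot":
        snap = self.copy()
        if trial is not None:
            snap.trial = trial
        if cycle is not None:
            snap.cycle = cycle
        if replica is not None:
            snap.replica = replica
        if frame is not None:
            snap.frame = frame
        return snap


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------


class Config(BaseModel):
    """Validated, immutable run configuration."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    simulator: str
    type: str
    n_replica: int = Field(ge=1)
    max_cycle: int = Field(default=10, ge=1)
    threshold: Optional[float] = Field(default=None, gt=0)
    d_threshold: Optional[float] = Field(default=None, gt=0)
    bound_threshold: Optional[int] = Field(default=None, ge=1)
    frame_sel: Optional[int] = Field(default=None, ge=1)
    selection1: Optional[str] = None
    selection2: Optional[str] = None
    selection3: Optional[str] = None
    selection4: Optional[str] = None
    reference: Optional[str] = None
    analyzer: str = "internal"
    mdconf: Optional[str] = None
    structure: Optional[str] = None
    template: Optional[str] = None
    trial: int = Field(default=1, ge=1)
    seed: int = 0


#: Keywords consumed from the configuration file.
KNOWN_KEYS = frozenset(Config.model_fields)

_MANDATORY = ("simulator", "type", "n_replica")


def _validate(flat: dict) -> Config:
    for key in _MANDATORY:
        if key not in flat:
            raise ConfigError(f"missing mandatory keyword '{key}'")
    if flat["type"] not in PACS_TYPES:
        raise ConfigError(
            f"unknown type '{flat['type']}'; expected one of {list(PACS_TYPES)}")
    # selection3/selection4 default to selection1/selection2
    flat = dict(flat)
    if flat.get("selection3") is None and flat.get("selection1") is not None:
        flat["selection3"] = flat["selection1"]
    if flat.get("selection4") is None and flat.get("selection2") is not None:
        flat["selection4"] = flat["selection2"]
    try:
        return Config(**flat)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"]) or "config"
        raise ConfigError(f"invalid keyword '{loc}': {first['msg']}") from None


def load_config(path: str | Path) -> Config:
    """Parse and validate a TOML run configuration.

    Unknown keywords are reported as warnings (backends may carry extra
    keys), never silently dropped.  Missing mandatory keywords and unknown
    ``type`` tags raise :class:`ConfigError`.
    """
    text = Path(path).read_text()
    try:
        data = tomllib.loads(text)
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"{path}: {exc}") from None
    flat = {}
    for key, value in data.items():
        if isinstance(value, dict):
            warnings.warn(f"{path}: ignoring configuration table [{key}]",
                          stacklevel=2)
            continue
        if key not in KNOWN_KEYS:
            warnings.warn(f"{path}: unknown keyword '{key}' ignored",
                          stacklevel=2)
            continue
        flat[key] = value
    return _validate(flat)


def config_from_dict(data: dict) -> Config:
    """Validate an in-memory keyword dictionary (same rules as a file)."""
    return _validate({k: v for k, v in data.items() if k in KNOWN_KEYS})


# ---------------------------------------------------------------------------
# Directory layout
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class RunLayout:
    """Deterministic ``trial{T:03d}/cycle{C:03d}/replica{R:03d}`` scheme.

    Trials are 1-based; cycles and replicas 0-based with cycle 0 being the
    initialisation run.
    """

    root: Path
    trial: int

    _PATTERN = re.compile(
        r"trial(\d{3})[/\\]cycle(\d{3})[/\\]replica(\d{3})[/\\]?$")

    def trial_dir(self) -> Path:
        return Path(self.root) / f"trial{self.trial:03d}"

    def cycle_dir(self, cycle: int) -> Path:
        return self.trial_dir() / f"cycle{cycle:03d}"

    def replica_dir(self, cycle: int, replica: int) -> Path:
        return self.cycle_dir(cycle) / f"replica{replica:03d}"

    @classmethod
    def parse(cls, path: str | Path) -> tuple[int, int, int]:
        """Recover (trial, cycle, replica) from a replica directory path."""
        m = cls._PATTERN.search(str(path))
        if m is None:
            raise LayoutError(f"not a replica path: {path}")
        return tuple(int(g) for g in m.groups())  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Structure I/O
# ---------------------------------------------------------------------------


def _default_masses(names: Sequence[str]) -> np.ndarray:
    """Element masses guessed from atom names; unit mass as fallback."""
    from biotite.structure.info import mass as element_mass

    out = np.ones(len(names))
    for i, name in enumerate(names):
        letters = "".join(ch for ch in name if ch.isalpha())
        for candidate in (letters[:2].capitalize(), letters[:1].upper()):
            if not candidate:
                continue
            try:
                m = element_mass(candidate)
            except KeyError:
                continue
            if m:
                out[i] = m
                break
    return out


def _element_of(name: str) -> str:
    letters = "".join(ch for ch in name if ch.isalpha())
    return (letters[:1] or "C").upper()


def _snapshot_to_atom_array(snap: Snapshot):
    from biotite.structure import AtomArray

    n = snap.n_atoms
    arr = AtomArray(n)
    arr.coord = np.asarray(snap.coords, dtype=np.float32) * 10.0  # nm -> A
    names = snap.atom_names or [f"C{i + 1}" for i in range(n)]
    resids = snap.resids if snap.resids is not None else np.arange(1, n + 1)
    arr.atom_name = np.asarray(names, dtype="U6")
    arr.res_id = np.asarray(resids, dtype=int)
    arr.res_name = np.full(n, "TOY", dtype="U5")
    arr.chain_id = np.full(n, "A", dtype="U4")
    arr.element = np.array([_element_of(nm) for nm in names], dtype="U2")
    arr.hetero = np.full(n, True)
    return arr


def _atom_array_to_snapshot(arr, masses: np.ndarray | None = None) -> Snapshot:
    names = list(arr.atom_name)
    if masses is None:
        masses = _default_masses(names)
    return Snapshot(
        coords=np.asarray(arr.coord, dtype=float) / 10.0,  # A -> nm
        masses=masses,
        atom_names=names,
        resids=np.asarray(arr.res_id, dtype=int),
    )


def read_structure(path: str | Path) -> Snapshot:
    """Read a single structure (PDB or ``.npz`` coordinate table) in nm."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".pdb":
        from biotite.structure.io.pdb import PDBFile

        try:
            arr = PDBFile.read(str(path)).get_structure(model=1)
        except Exception as exc:
            raise FormatError(f"{path}: cannot parse PDB ({exc})") from exc
        if arr.array_length() == 0:
            raise FormatError(f"{path}: file contains no atoms")
        return _atom_array_to_snapshot(arr)
    if path.suffix.lower() == ".npz":
        frames = read_trajectory(path)
        if len(frames) != 1:
            raise FormatError(f"{path}: expected a single-frame table")
        return frames[0]
    raise FormatError(f"{path}: unsupported structure format "
                      f"'{path.suffix}' (use .pdb or .npz)")


def write_structure(snap: Snapshot, path: str | Path) -> None:
    """Write a single structure; format chosen by suffix (.pdb or .npz)."""
    path = Path(path)
    if path.suffix.lower() == ".pdb":
        from biotite.structure.io.pdb import PDBFile

        pdb = PDBFile()
        pdb.set_structure(_snapshot_to_atom_array(snap))
        pdb.write(str(path))
        return
    if path.suffix.lower() == ".npz":
        write_trajectory([snap], path, "table")
        return
    raise FormatError(f"{path}: unsupported structure format '{path.suffix}'")


# ---------------------------------------------------------------------------
# Trajectory I/O
# ---------------------------------------------------------------------------

_FORMATS = ("xyz", "pdb", "table")

_SUFFIX_TO_FORMAT = {".xyz": "xyz", ".pdb": "pdb", ".npz": "table"}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in _FORMATS:
            raise ValueError(f"unknown trajectory format '{fmt}'; "
                             f"expected one of {list(_FORMATS)}")
        return fmt
    try:
        return _SUFFIX_TO_FORMAT[path.suffix.lower()]
    except KeyError:
        raise ValueError(f"cannot infer trajectory format from '{path}'") from None


def write_trajectory(frames: Sequence[Snapshot], path: str | Path,
                     fmt: str | None = None) -> None:
    """Write frames to disk.  Formats: ``xyz`` (text, nm), ``pdb``
    (multi-model, angstrom) or ``table`` (``.npz`` float64 arrays)."""
    frames = list(frames)
    if not frames:
        raise ValueError("cannot write an empty trajectory")
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "xyz":
        names = frames[0].atom_names or [f"C{i + 1}"
                                         for i in range(frames[0].n_atoms)]
        with open(path, "w") as fh:
            for snap in frames:
                fh.write(f"{snap.n_atoms}\n")
                fh.write(f"frame {snap.frame} cycle {snap.cycle} "
                         f"replica {snap.replica} (nm)\n")
                for name, xyz in zip(names, snap.coords):
                    fh.write(f"{name} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n")
        return
    if fmt == "pdb":
        from biotite.structure import stack
        from biotite.structure.io.pdb import PDBFile

        arrays = stack([_snapshot_to_atom_array(s) for s in frames])
        pdb = PDBFile()
        pdb.set_structure(arrays)
        pdb.write(str(path))
        return
    # table
    coords = np.stack([s.coords for s in frames])
    payload: dict[str, np.ndarray] = {
        "coords": coords,
        "provenance": np.array([[s.trial, s.cycle, s.replica, s.frame]
                                for s in frames], dtype=int),
    }
    if all(s.velocities is not None for s in frames):
        payload["velocities"] = np.stack([s.velocities for s in frames])
    first = frames[0]
    if first.masses is not None:
        payload["masses"] = np.asarray(first.masses, dtype=float)
    if first.atom_names is not None:
        payload["atom_names"] = np.asarray(first.atom_names, dtype="U8")
    if first.resids is not None:
        payload["resids"] = np.asarray(first.resids, dtype=int)
    np.savez(path, **payload)


def read_trajectory(path: str | Path, fmt: str | None = None) -> list[Snapshot]:
    """Read a trajectory written by :func:`write_trajectory`."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "xyz":
        frames = []
        with open(path) as fh:
            lines = fh.read().splitlines()
        i = 0
        while i < len(lines):
            try:
                n = int(lines[i].split()[0])
            except (ValueError, IndexError):
                raise FormatError(f"{path}: bad atom count at line {i + 1}")
            block = lines[i + 2:i + 2 + n]
            names, coords = [], []
            for j, line in enumerate(block):
                parts = line.split()
                if len(parts) < 4:
                    raise FormatError(f"{path}: bad record at line {i + 3 + j}")
                names.append(parts[0])
                coords.append([float(p) for p in parts[1:4]])
            frames.append(Snapshot(coords=np.array(coords),
                                   atom_names=names, frame=len(frames)))
            i += 2 + n
        if not frames:
            raise FormatError(f"{path}: empty trajectory")
        return frames
    if fmt == "pdb":
        from biotite.structure.io.pdb import PDBFile

        stk = PDBFile.read(str(path)).get_structure()
        if stk.array_length() == 0:
            raise FormatError(f"{path}: file contains no atoms")
        masses = _default_masses(list(stk.atom_name))
        frames = []
        for i in range(stk.stack_depth()):
            snap = _atom_array_to_snapshot(stk[i], masses=masses)
            snap.frame = i
            frames.append(snap)
        return frames
    data = np.load(path, allow_pickle=False)
    coords = data["coords"]
    prov = data["provenance"]
    velocities = data["velocities"] if "velocities" in data else None
    masses = data["masses"] if "masses" in data else None
    names = list(data["atom_names"]) if "atom_names" in data else None
    resids = data["resids"] if "resids" in data else None
    frames = []
    for i in range(coords.shape[0]):
        frames.append(Snapshot(
            coords=coords[i],
            velocities=None if velocities is None else velocities[i],
            masses=masses, atom_names=names, resids=resids,
            trial=int(prov[i, 0]), cycle=int(prov[i, 1]),
            replica=int(prov[i, 2]), frame=int(prov[i, 3]),
        ))
    return frames
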