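"""Coarse-grained configuration model and coordinate I/O.

A :class:`Frame` holds one configuration of a coarse-grained system in an
orthorhombic periodic box: bead positions (nm), bead/molecule identities and
charges.  All downstream analyses consume Frames, so file formats are isolated
here.  GRO files are read and written with bit-exact fixed columns; XTC
trajectories are delegated to MDAnalysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import numpy as np

__all__ = [
    "Bead",
    "Frame",
    "MoleculeRegistry",
    "DEFAULT_REGISTRY",
    "read_coordinates",
    "write_coordinates",
    "iter_trajectory",
    "minimum_image_displacement",
    "GroParseError",
]


class GroParseError(ValueError):
    """Raised when a GRO file cannot be parsed; names the offending line."""


class Bead(NamedTuple):
    """One coarse-grained interaction site (~4 heavy atoms)."""

    bead_id: int
    name: str
    molecule_id: int
    molecule_type: str
    bead_type: str
    charge: float
    position: tuple[float, float, float]


#: molecule-type classes used throughout the analyses
LIPID_TYPES = frozenset({"DPPC", "DLiPC", "CHOL"})
SOLVENT_TYPES = frozenset({"W", "WF", "ION", "NA+", "CL-", "NA", "CL"})


@dataclass(frozen=True)
class MoleculeRegistry:
    """Classify molecule types into lipid / solvent / peptide.

    Anything not registered as lipid or solvent is treated as peptide, so new
    peptide names need no registration.
    """

    lipids: frozenset[str] = LIPID_TYPES
    solvent: frozenset[str] = SOLVENT_TYPES

    def classify(self, molecule_type: str) -> str:
        if molecule_type in self.lipids:
            return "lipid"
        if molecule_type in self.solvent:
            return "solvent"
        return "peptide"


DEFAULT_REGISTRY = MoleculeRegistry()


@dataclass
class Frame:
    """One configuration: parallel per-bead arrays plus the periodic box.

    Attributes
    ----------
    positions : (N, 3) float array, nm
    names : (N,) str array — bead names (PO4, C1A, BB, ...)
    molecule_ids : (N,) int array — beads of one molecule are contiguous
    molecule_types : (N,) str array — DPPC, DLiPC, CHOL, W, CL-, peptide name
    bead_types : (N,) str array — force-field type tokens
    charges : (N,) float array, elementary charges
    box : (3,) float array — orthorhombic edge lengths, nm
    time : float, ns
    """

    positions: np.ndarray
    names: np.ndarray
    molecule_ids: np.ndarray
    molecule_types: np.ndarray
    bead_types: np.ndarray
    charges: np.ndarray
    box: np.ndarray
    time: float = 0.0
    registry: MoleculeRegistry = field(default=DEFAULT_REGISTRY, repr=False)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        n = len(self.positions)
        self.names = np.asarray(self.names, dtype=object)
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=np.int64)
        self.molecule_types = np.asarray(self.molecule_types, dtype=object)
        self.bead_types = np.asarray(self.bead_types, dtype=object)
        self.charges = np.asarray(self.charges, dtype=float)
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        for arr, label in (
            (self.names, "names"),
            (self.molecule_ids, "molecule_ids"),
            (self.molecule_types, "molecule_types"),
            (self.bead_types, "bead_types"),
            (self.charges, "charges"),
        ):
            if len(arr) != n:
                raise ValueError(f"{label} length {len(arr)} != {n} positions")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite bead position")
        if np.any(self.box <= 0):
            raise ValueError(f"box edges must be positive, got {self.box}")

    # -- convenience ------------------------------------------------------

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @classmethod
    def from_beads(cls, beads: Sequence[Bead], box, time: float = 0.0,
                   registry: MoleculeRegistry = DEFAULT_REGISTRY) -> "Frame":
        return cls(
            positions=np.array([b.position for b in beads], dtype=float).reshape(-1, 3),
            names=np.array([b.name for b in beads], dtype=object),
            molecule_ids=np.array([b.molecule_id for b in beads], dtype=np.int64),
            molecule_types=np.array([b.molecule_type for b in beads], dtype=object),
            bead_types=np.array([b.bead_type for b in beads], dtype=object),
            charges=np.array([b.charge for b in beads], dtype=float),
            box=box,
            time=time,
            registry=registry,
        )

    def beads(self) -> Iterator[Bead]:
        for i in range(self.n_beads):
            yield Bead(i, self.names[i], int(self.molecule_ids[i]),
                       self.molecule_types[i], self.bead_types[i],
                       float(self.charges[i]), tuple(self.positions[i]))

    def wrapped(self) -> "Frame":
        """Copy with every position component wrapped into [0, box)."""
        out = self.copy()
        out.positions = np.mod(out.positions, out.box)
        return out

    def copy(self) -> "Frame":
        return Frame(self.positions.copy(), self.names.copy(),
                     self.molecule_ids.copy(), self.molecule_types.copy(),
                     self.bead_types.copy(), self.charges.copy(),
                     self.box.copy(), self.time, self.registry)

    def classes(self) -> np.ndarray:
        """Per-bead class in {lipid, solvent, peptide}."""
        lut = {t: self.registry.classify(t) for t in set(self.molecule_types)}
        return np.array([lut[t] for t in self.molecule_types], dtype=object)

    def select(self, mask: np.ndarray) -> np.ndarray:
        """Indices where boolean ``mask`` holds (thin helper)."""
        return np.flatnonzero(mask)


# -- periodic geometry ----------------------------------------------------


def minimum_image_displacement(a, b, box) -> np.ndarray:
    """Minimum-image displacement vector(s) from ``a`` to ``b``.

    Each component of ``b - a`` is shifted by integer multiples of the box
    edge so that its magnitude is at most half the edge.  Supports broadcast
    over leading axes.
    """
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError(f"box edges must be positive, got {box}")
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    return d - box * np.round(d / box)


def minimum_image_distance(a, b, box) -> np.ndarray:
    """Minimum-image Euclidean distance from ``a`` to ``b``."""
    return np.linalg.norm(minimum_image_displacement(a, b, box), axis=-1)


# -- GRO I/O ---------------------------------------------------------------
# Fixed columns: resid(5) resname(5) name(5) serial(5) x(8.3) y(8.3) z(8.3)


def read_coordinates(path, registry: MoleculeRegistry = DEFAULT_REGISTRY) -> Frame:
    """Read a GRO coordinate file into a :class:`Frame`.

    Only orthorhombic boxes are accepted; a triclinic box line (9 numbers with
    nonzero off-diagonals) raises :class:`GroParseError` rather than being
    silently truncated.  Charges and bead types are not stored in GRO files;
    bead_type defaults to the bead name and charges to zero (use a force-field
    table to fill them in).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise GroParseError(f"{path}: GRO file needs title, count and box lines")
    try:
        n_atoms = int(lines[1].strip())
    except ValueError as exc:
        raise GroParseError(f"{path}, line 2: invalid atom count {lines[1]!r}") from exc
    if len(lines) < n_atoms + 3:
        raise GroParseError(
            f"{path}: declared {n_atoms} atoms but file has only "
            f"{len(lines) - 3} coordinate lines")

    pos = np.empty((n_atoms, 3), dtype=float)
    names = np.empty(n_atoms, dtype=object)
    mol_ids = np.empty(n_atoms, dtype=np.int64)
    mol_types = np.empty(n_atoms, dtype=object)
    for i in range(n_atoms):
        ln = lines[2 + i]
        lineno = 3 + i
        if len(ln) < 44:
            raise GroParseError(f"{path}, line {lineno}: truncated atom line")
        try:
            mol_ids[i] = int(ln[0:5])
            mol_types[i] = ln[5:10].strip()
            names[i] = ln[10:15].strip()
            pos[i, 0] = float(ln[20:28])
            pos[i, 1] = float(ln[28:36])
            pos[i, 2] = float(ln[36:44])
        except ValueError as exc:
            raise GroParseError(f"{path}, line {lineno}: malformed atom line {ln!r}") from exc

    box_fields = lines[2 + n_atoms].split()
    if len(box_fields) not in (3, 9):
        raise GroParseError(f"{path}, line {3 + n_atoms}: malformed box line")
    try:
        box_vals = [float(v) for v in box_fields]
    except ValueError as exc:
        raise GroParseError(f"{path}, line {3 + n_atoms}: malformed box line") from exc
    if len(box_vals) == 9 and any(v != 0.0 for v in box_vals[3:]):
        raise GroParseError(f"{path}: triclinic boxes are not supported")
    box = np.array(box_vals[:3])

    return Frame(positions=pos, names=names, molecule_ids=mol_ids,
                 molecule_types=mol_types, bead_types=names.copy(),
                 charges=np.zeros(n_atoms), box=box, registry=registry)


def write_coordinates(frame: Frame, path, title: str = "memphase frame") -> None:
    """Write ``frame`` as a standard GRO file (3-decimal nm columns)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{title}, t= {frame.time:.3f}\n")
        fh.write(f"{frame.n_beads:5d}\n")
        for i in range(frame.n_beads):
            resid = int(frame.molecule_ids[i]) % 100000
            serial = (i + 1) % 100000
            x, y, z = frame.positions[i]
            fh.write(f"{resid:5d}{frame.molecule_types[i]:<5.5s}"
                     f"{frame.names[i]:>5.5s}{serial:5d}"
                     f"{x:8.3f}{y:8.3f}{z:8.3f}\n")
        fh.write(f"{frame.box[0]:10.5f}{frame.box[1]:10.5f}{frame.box[2]:10.5f}\n")


def iter_trajectory(topology, trajectory=None,
                    registry: MoleculeRegistry = DEFAULT_REGISTRY) -> Iterator[Frame]:
    """Yield Frames from a GRO file, or from an XTC trajectory via MDAnalysis.

    With only ``topology`` given, yields the single GRO frame.  With a
    trajectory, positions are taken per frame from MDAnalysis (converted from
    Å to nm); identities come from the topology.
    """
    if trajectory is None:
        yield read_coordinates(topology, registry=registry)
        return
    import warnings

    import MDAnalysis as mda

    ref = read_coordinates(topology, registry=registry)
    with warnings.catch_warnings():
        # mass/type guessing is irrelevant here: identities come from `ref`
        warnings.simplefilter("ignore")
        u = mda.Universe(str(topology), str(trajectory))
    for ts in u.trajectory:
        fr = ref.copy()
        fr.positions = ts.positions.astype(float) / 10.0
        fr.box = np.asarray(ts.dimensions[:3], dtype=float) / 10.0
        fr.time = float(ts.time) / 1000.0  # ps -> ns
        yield fr
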