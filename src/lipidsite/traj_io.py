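"""Trajectory and topology ingestion for coarse-grained membrane systems.

Coordinates are stored in nanometres throughout. A trajectory is a static
bead topology plus an ``(n_frames, n_beads, 3)`` coordinate array with
per-frame orthorhombic box lengths and a fixed *effective-time* spacing
between saved frames.

Two input routes exist:

* standard MD formats (GRO/PDB topology, XTC/DCD coordinates) read through
  MDAnalysis, with bead typing inferred from residue/bead names via a
  configurable mapping table;
* a documented whitespace-delimited plain-text fixture format
  (:func:`write_fixture` / :func:`load_trajectory`) that round-trips
  coordinates bitwise, used by the synthetic generator and the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from .errors import FormatError, ParameterError, SelectionError, StructuralError

__all__ = [
    "MoleculeType",
    "Topology",
    "Trajectory",
    "LeafletAssignment",
    "load_trajectory",
    "write_fixture",
    "assign_leaflets",
    "effective_time",
    "DEFAULT_RESNAME_MAP",
    "DEFAULT_PHOSPHATE_BEADS",
]

MARTINI_TIME_FACTOR = 4.0


class MoleculeType(str, Enum):
    PROTEIN = "PROTEIN"
    CDL = "CDL"
    POPC = "POPC"
    POPE = "POPE"
    WATER = "WATER"
    OTHER = "OTHER"


#: phosphate beads expected per lipid type (topology invariant)
PHOSPHATES_PER_LIPID = {
    MoleculeType.CDL.value: 2,
    MoleculeType.POPC.value: 1,
    MoleculeType.POPE.value: 1,
}

_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MLZ",  # trimethyllysine
}

#: residue name -> molecule type; editable so MARTINI naming dialects fit
DEFAULT_RESNAME_MAP = {
    **{aa: MoleculeType.PROTEIN for aa in _AMINO_ACIDS},
    "CDL": MoleculeType.CDL,
    "CDL2": MoleculeType.CDL,
    "CL": MoleculeType.CDL,
    "CL4P": MoleculeType.CDL,
    "CARD": MoleculeType.CDL,
    "POPC": MoleculeType.POPC,
    "POPE": MoleculeType.POPE,
    "W": MoleculeType.WATER,
    "WN": MoleculeType.WATER,
    "SOL": MoleculeType.WATER,
}

#: bead names flagged as lipid phosphates
DEFAULT_PHOSPHATE_BEADS = {
    "PO4", "PO41", "PO42", "PO1", "PO2", "P", "P1", "P2", "P8", "P9",
}


@dataclass
class Topology:
    """Per-bead labels for one system.

    ``residue_index`` is meaningful for protein beads only; non-protein beads
    carry -1.
    """

    bead_id: np.ndarray
    molecule_id: np.ndarray
    molecule_type: np.ndarray
    residue_index: np.ndarray
    residue_name: np.ndarray
    bead_name: np.ndarray
    is_phosphate: np.ndarray

    def __post_init__(self):
        self.bead_id = np.asarray(self.bead_id, dtype=np.int64)
        self.molecule_id = np.asarray(self.molecule_id, dtype=np.int64)
        self.molecule_type = np.asarray(self.molecule_type, dtype="U8")
        self.residue_index = np.asarray(self.residue_index, dtype=np.int64)
        self.residue_name = np.asarray(self.residue_name, dtype="U8")
        self.bead_name = np.asarray(self.bead_name, dtype="U8")
        self.is_phosphate = np.asarray(self.is_phosphate, dtype=bool)
        self.validate()

    @property
    def n_beads(self) -> int:
        return self.bead_id.size

    def validate(self) -> None:
        n = self.n_beads
        for name in ("molecule_id", "molecule_type", "residue_index",
                     "residue_name", "bead_name", "is_phosphate"):
            if getattr(self, name).shape != (n,):
                raise StructuralError(f"topology field {name!r} has wrong length")
        if n == 0:
            return
        if not np.array_equal(np.sort(self.bead_id), np.arange(n)):
            raise StructuralError("bead_ids must be unique and contiguous from 0")
        known = {m.value for m in MoleculeType}
        bad = set(np.unique(self.molecule_type)) - known
        if bad:
            raise StructuralError(f"unknown molecule types: {sorted(bad)}")
        prot = self.molecule_type == MoleculeType.PROTEIN.value
        if np.any(self.residue_index[prot] < 0):
            raise StructuralError("protein beads must carry a valid residue_index")
        # phosphate-count invariants per lipid molecule
        for mtype, expected in PHOSPHATES_PER_LIPID.items():
            sel = self.molecule_type == mtype
            for mol in np.unique(self.molecule_id[sel]):
                got = int(np.sum(self.is_phosphate[sel & (self.molecule_id == mol)]))
                if got != expected:
                    raise StructuralError(
                        f"{mtype} molecule {mol} has {got} phosphate beads, "
                        f"expected {expected}"
                    )

    # -- selections -------------------------------------------------------
    def protein_indices(self) -> np.ndarray:
        return np.flatnonzero(self.molecule_type == MoleculeType.PROTEIN.value)

    def molecules_of_type(self, mtype) -> np.ndarray:
        mtype = MoleculeType(mtype).value
        return np.unique(self.molecule_id[self.molecule_type == mtype])

    def lipid_molecule_ids(self) -> np.ndarray:
        lip = np.isin(self.molecule_type,
                      [MoleculeType.CDL.value, MoleculeType.POPC.value,
                       MoleculeType.POPE.value])
        return np.unique(self.molecule_id[lip])

    def beads_of_molecule(self, molecule_id: int) -> np.ndarray:
        return np.flatnonzero(self.molecule_id == molecule_id)

    def molecule_type_of(self, molecule_id: int) -> str:
        beads = self.beads_of_molecule(molecule_id)
        if beads.size == 0:
            raise SelectionError(f"no molecule with id {molecule_id}")
        return str(self.molecule_type[beads[0]])


@dataclass
class Trajectory:
    """Bead coordinates (nm) over frames with effective-time spacing (ns)."""

    topology: Topology
    coords: np.ndarray
    box: np.ndarray
    frame_spacing: float
    is_atomistic: bool = False

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.box = np.asarray(self.box, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise StructuralError("coords must have shape (n_frames, n_beads, 3)")
        if self.coords.shape[1] != self.topology.n_beads:
            raise StructuralError(
                f"coordinate bead count {self.coords.shape[1]} does not match "
                f"topology bead count {self.topology.n_beads}"
            )
        if self.box.shape != (self.coords.shape[0], 3):
            raise StructuralError("box must have shape (n_frames, 3)")
        if np.any(self.box <= 0):
            raise StructuralError("box lengths must be positive")
        if self.frame_spacing <= 0:
            raise ParameterError("frame_spacing must be > 0")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_beads(self) -> int:
        return self.coords.shape[1]

    @property
    def total_time(self) -> float:
        """Total simulation time T = (n_frames - 1) * frame_spacing, in ns."""
        return (self.n_frames - 1) * self.frame_spacing


@dataclass
class LeafletAssignment:
    """Lipid molecule -> leaflet ('inner'/'outer'), split at midplane_z."""

    leaflet: dict = field(default_factory=dict)
    midplane_z: float = float("nan")

    def __getitem__(self, molecule_id: int) -> str:
        return self.leaflet[molecule_id]

    def lipids(self, leaflet: str) -> list:
        return sorted(m for m, l in self.leaflet.items() if l == leaflet)


# ---------------------------------------------------------------------------
# fixture format
# ---------------------------------------------------------------------------
#
# topology file::
#
#     # lipidsite topology v1
#     <n_beads>
#     <bead_id> <molecule_id> <molecule_type> <residue_index> <residue_name> <bead_name> <is_phosphate>
#     ...
#
# coordinates file::
#
#     # lipidsite coords v1
#     n_beads <n> frame_spacing <dt_ns>
#     frame <k>
#     box <lx> <ly> <lz>
#     <bead_id> <x> <y> <z>
#     ...
#
# Floats are written with shortest round-trip repr, so write->read is bitwise.

def write_fixture(traj: Trajectory, topology_path, coords_path) -> None:
    """Write a trajectory in the plain-text fixture format."""
    top = traj.topology
    with open(topology_path, "w") as fh:
        fh.write("# lipidsite topology v1\n")
        fh.write(f"{top.n_beads}\n")
        for i in range(top.n_beads):
            fh.write(
                f"{top.bead_id[i]} {top.molecule_id[i]} {top.molecule_type[i]} "
                f"{top.residue_index[i]} {top.residue_name[i]} {top.bead_name[i]} "
                f"{int(top.is_phosphate[i])}\n"
            )
    with open(coords_path, "w") as fh:
        fh.write("# lipidsite coords v1\n")
        fh.write(f"n_beads {traj.n_beads} frame_spacing {traj.frame_spacing!r}\n")
        for f in range(traj.n_frames):
            fh.write(f"frame {f}\n")
            fh.write("box " + " ".join(repr(float(v)) for v in traj.box[f]) + "\n")
            for b in range(traj.n_beads):
                x, y, z = traj.coords[f, b]
                fh.write(f"{b} {float(x)!r} {float(y)!r} {float(z)!r}\n")


def _read_fixture_topology(path) -> Topology:
    rows = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    body = [ln for ln in lines if ln and not ln.startswith("#")]
    if not body:
        raise FormatError(f"{path}: empty topology file")
    try:
        n = int(body[0])
    except ValueError as exc:
        raise FormatError(f"{path}: bad bead count line {body[0]!r}") from exc
    if len(body) - 1 != n:
        raise FormatError(
            f"{path}: declared {n} beads but found {len(body) - 1} bead lines"
        )
    for k, ln in enumerate(body[1:], start=2):
        parts = ln.split()
        if len(parts) != 7:
            raise FormatError(f"{path}: malformed bead line {k}: {ln!r}")
        rows.append(parts)
    arr = list(zip(*rows))
    return Topology(
        bead_id=np.array(arr[0], dtype=np.int64),
        molecule_id=np.array(arr[1], dtype=np.int64),
        molecule_type=np.array(arr[2]),
        residue_index=np.array(arr[3], dtype=np.int64),
        residue_name=np.array(arr[4]),
        bead_name=np.array(arr[5]),
        is_phosphate=np.array(arr[6], dtype=np.int64).astype(bool),
    )


def _read_fixture_coords(path, n_beads_expected):
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if not lines or not lines[0].startswith("n_beads"):
        raise FormatError(f"{path}: missing 'n_beads ... frame_spacing ...' header")
    hdr = lines[0].split()
    try:
        n_beads = int(hdr[1])
        frame_spacing = float(hdr[3])
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{path}: bad header {lines[0]!r}") from exc
    if n_beads_expected is not None and n_beads != n_beads_expected:
        raise StructuralError(
            f"{path}: coordinate file has {n_beads} beads but topology has "
            f"{n_beads_expected}"
        )
    frames, boxes = [], []
    i = 1
    frame_no = 0
    while i < len(lines):
        if not lines[i].startswith("frame"):
            raise FormatError(f"{path}: expected 'frame' marker, got {lines[i]!r}")
        i += 1
        if i >= len(lines) or not lines[i].startswith("box"):
            raise FormatError(f"{path}: frame {frame_no} missing box line")
        box = [float(v) for v in lines[i].split()[1:4]]
        i += 1
        xyz = np.empty((n_beads, 3))
        seen = np.zeros(n_beads, dtype=bool)
        for _ in range(n_beads):
            if i >= len(lines):
                raise FormatError(f"{path}: truncated frame {frame_no}")
            parts = lines[i].split()
            if len(parts) != 4:
                raise FormatError(f"{path}: malformed coordinate line {lines[i]!r}")
            b = int(parts[0])
            xyz[b] = [float(parts[1]), float(parts[2]), float(parts[3])]
            seen[b] = True
            i += 1
        if not seen.all():
            raise FormatError(f"{path}: frame {frame_no} missing beads")
        frames.append(xyz)
        boxes.append(box)
        frame_no += 1
    if not frames:
        raise FormatError(f"{path}: no frames")
    return np.array(frames), np.array(boxes), frame_spacing


def _classify(residue_names, bead_names, resname_map, phosphate_beads):
    types = np.empty(len(residue_names), dtype="U8")
    for i, rn in enumerate(residue_names):
        types[i] = MoleculeType(resname_map.get(rn, MoleculeType.OTHER)).value
    isp = np.array([bn in phosphate_beads for bn in bead_names], dtype=bool)
    # phosphate flag only meaningful on lipids
    lip = np.isin(types, [MoleculeType.CDL.value, MoleculeType.POPC.value,
                          MoleculeType.POPE.value])
    return types, isp & lip


def _load_mdanalysis(topology_path, coords_path, frame_spacing,
                     resname_map, phosphate_beads):
    import MDAnalysis as mda

    if frame_spacing is None:
        raise ParameterError(
            "frame_spacing (effective ns between saved frames) is required for "
            "MD-format input"
        )
    try:
        if coords_path is None or Path(coords_path) == Path(topology_path):
            u = mda.Universe(str(topology_path))
        else:
            u = mda.Universe(str(topology_path), str(coords_path))
    except Exception as exc:  # MDAnalysis raises many parser-specific types
        raise FormatError(f"could not parse {topology_path}/{coords_path}: {exc}") from exc

    resnames = u.atoms.resnames
    types, isp = _classify(resnames, u.atoms.names, resname_map, phosphate_beads)
    # one molecule per residue for non-protein; the whole protein is molecule 0
    resids = u.atoms.resindices
    molecule_id = np.where(types == MoleculeType.PROTEIN.value, -1, resids + 1)
    residue_index = np.where(types == MoleculeType.PROTEIN.value,
                             u.atoms.resids, -1)
    prot_mol = 0
    molecule_id = np.where(molecule_id == -1, prot_mol, molecule_id)
    top = Topology(
        bead_id=np.arange(u.atoms.n_atoms),
        molecule_id=molecule_id,
        molecule_type=types,
        residue_index=residue_index,
        residue_name=resnames,
        bead_name=u.atoms.names,
        is_phosphate=isp,
    )
    frames, boxes = [], []
    for ts in u.trajectory:
        dims = ts.dimensions
        if dims is None or np.any(dims[:3] <= 0):
            raise StructuralError("trajectory frame lacks box dimensions")
        if not np.allclose(dims[3:], 90.0, atol=1e-3):
            raise StructuralError(
                "triclinic boxes are not supported; box angles must be 90 degrees"
            )
        frames.append(ts.positions / 10.0)  # A -> nm
        boxes.append(dims[:3] / 10.0)
    return Trajectory(top, np.array(frames), np.array(boxes), frame_spacing)


_MD_TOP_EXT = {".gro", ".pdb"}
_MD_CRD_EXT = {".xtc", ".dcd", ".trr", ".gro", ".pdb"}


def load_trajectory(topology_path, coords_path=None, frame_spacing=None,
                    resname_map=None, phosphate_beads=None,
                    is_atomistic=False) -> Trajectory:
    """Load a trajectory from MD formats or the plain-text fixture format.

    Parameters
    ----------
    topology_path
        GRO/PDB file, or a fixture topology file.
    coords_path
        XTC/DCD/GRO file, or a fixture coordinates file. May be omitted for
        single-frame GRO/PDB input.
    frame_spacing
        Effective time between saved frames in ns. Required for MD formats;
        for fixture input it is read from the header (an explicit value
        overrides it).
    """
    resname_map = dict(DEFAULT_RESNAME_MAP if resname_map is None else resname_map)
    phosphate_beads = set(DEFAULT_PHOSPHATE_BEADS if phosphate_beads is None
                          else phosphate_beads)
    top_path = Path(topology_path)
    if not top_path.exists():
        raise FormatError(f"no such file: {top_path}")
    ext = top_path.suffix.lower()
    if ext in _MD_TOP_EXT:
        traj = _load_mdanalysis(top_path, coords_path, frame_spacing,
                                resname_map, phosphate_beads)
    else:
        if coords_path is None:
            raise ParameterError("fixture input requires a coordinates file")
        crd_path = Path(coords_path)
        if not crd_path.exists():
            raise FormatError(f"no such file: {crd_path}")
        top = _read_fixture_topology(top_path)
        coords, box, dt = _read_fixture_coords(crd_path, top.n_beads)
        traj = Trajectory(top, coords, box,
                          frame_spacing if frame_spacing is not None else dt)
    traj.is_atomistic = bool(is_atomistic)
    return traj


# ---------------------------------------------------------------------------
# leaflet assignment & effective time
# ---------------------------------------------------------------------------

def assign_leaflets(traj: Trajectory, reference_frame: int = 0,
                    check_flips: bool = False) -> LeafletAssignment:
    """Assign each lipid to the inner or outer leaflet.

    A lipid is ``inner`` if the mean z of its phosphate bead(s) at the
    reference frame lies below the midplane (the mean phosphate z over all
    lipids), else ``outer``. Assignment is taken at a single frame: lipids in
    a planar patch do not flip on the timescales analysed here. With
    ``check_flips`` the assignment is re-evaluated at every frame and lipids
    whose side disagrees with the reference in >10% of frames are warned
    about.
    """
    top = traj.topology
    phos = top.is_phosphate
    if not np.any(phos):
        warnings.warn("no lipids with phosphate beads; empty leaflet assignment")
        return LeafletAssignment({}, float("nan"))
    z = traj.coords[reference_frame, :, 2]
    midplane = float(np.mean(z[phos]))
    mapping = {}
    for mol in top.lipid_molecule_ids():
        beads = np.flatnonzero((top.molecule_id == mol) & phos)
        if beads.size == 0:
            continue
        mapping[int(mol)] = "inner" if float(np.mean(z[beads])) < midplane else "outer"
    sides = set(mapping.values())
    if mapping and len(sides) == 1:
        warnings.warn(
            "all lipids assigned to one leaflet (degenerate z distribution)"
        )
    assignment = LeafletAssignment(mapping, midplane)
    if check_flips:
        disagree = {m: 0 for m in mapping}
        for f in range(traj.n_frames):
            zf = traj.coords[f, :, 2]
            mid_f = float(np.mean(zf[phos]))
            for mol in mapping:
                beads = np.flatnonzero((top.molecule_id == mol) & phos)
                side = "inner" if float(np.mean(zf[beads])) < mid_f else "outer"
                if side != mapping[mol]:
                    disagree[mol] += 1
        flippers = [m for m, c in disagree.items() if c > 0.1 * traj.n_frames]
        if flippers:
            warnings.warn(f"possible leaflet flips for lipids {flippers}")
    return assignment


def effective_time(raw_time, factor: float = MARTINI_TIME_FACTOR):
    """Convert raw coarse-grained simulation time to effective time.

    Coarse-grained dynamics run faster than atomistic dynamics; the
    conventional conversion multiplies simulation time by ``factor``
    (default 4).
    """
    raw = np.asarray(raw_time, dtype=float)
    if factor <= 0:
        raise ParameterError("factor must be > 0")
    if np.any(raw < 0):
        raise ParameterError("raw_time must be non-negative")
    out = raw * factor
    return float(out) if np.isscalar(raw_time) else out
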