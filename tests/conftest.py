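import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from lipidsite.contacts import ResidueContactTable
from lipidsite.traj_io import Topology, Trajectory


def build_topology(layout):
    """Topology from a compact layout: list of (molecule_type, [(bead_name, is_phos), ...]).

    Protein molecules get sequential residue indices, one residue per bead.
    """
    rows = {k: [] for k in ("bead_id", "molecule_id", "molecule_type",
                            "residue_index", "residue_name", "bead_name",
                            "is_phosphate")}
    bead = 0
    res = 0
    for mol, (mtype, beads) in enumerate(layout):
        for name, isp in beads:
            rows["bead_id"].append(bead)
            rows["molecule_id"].append(mol)
            rows["molecule_type"].append(mtype)
            rows["residue_index"].append(res if mtype == "PROTEIN" else -1)
            rows["residue_name"].append("ALA" if mtype == "PROTEIN" else mtype)
            rows["bead_name"].append(name)
            rows["is_phosphate"].append(isp)
            bead += 1
            if mtype == "PROTEIN":
                res += 1
    return Topology(**{k: np.array(v) for k, v in rows.items()})


CDL_BEADS = [("PO41", True), ("PO42", True), ("C1A", False), ("C1B", False),
             ("C2A", False), ("C2B", False)]
PL_BEADS = [("PO4", True), ("C1A", False), ("C2A", False)]


def make_trajectory(layout, coords, box=(10.0, 10.0, 10.0), frame_spacing=1.2,
                    **kw):
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    boxes = np.tile(np.asarray(box, dtype=float), (coords.shape[0], 1))
    return Trajectory(build_topology(layout), coords, boxes, frame_spacing, **kw)


def make_table(events, n_frames, residues=None, cutoff=0.7, frame_spacing=1.2):
    """ResidueContactTable from [(frame, lipid_id, residue), ...]."""
    events = sorted(events)
    frame = np.array([e[0] for e in events], dtype=np.int64)
    lipid = np.array([e[1] for e in events], dtype=np.int64)
    res = np.array([e[2] for e in events], dtype=np.int64)
    if residues is None:
        residues = np.unique(res) if len(events) else np.arange(1)
    return ResidueContactTable(frame, lipid, res, n_frames, cutoff,
                               frame_spacing, residues=np.asarray(residues))


@pytest.fixture
def simple_cdl_traj():
    """1 protein bead + 1 CDL (6 beads), 3 frames, 10 nm box."""
    layout = [("PROTEIN", [("BB", False)]), ("CDL", CDL_BEADS)]
    rng = np.random.default_rng(0)
    coords = rng.uniform(1, 9, size=(3, 7, 3))
    return make_trajectory(layout, coords)
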