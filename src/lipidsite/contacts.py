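"""Protein-lipid contact detection under periodic boundaries.

The interaction rules implemented here operate on *smoothed* minimum
bead-bead distances between a lipid and the protein:

* ``headgroup`` mode: the lipid headgroup interacts in a frame when at
  least one of its phosphate beads is within the cutoff of any protein
  bead (distances smoothed first);
* ``whole_lipid`` mode: the lipid interacts when at least four distinct
  lipid beads each lie within the cutoff of some protein bead.

Smoothing is a centred running average over a fixed number of frames
(default 50, i.e. 60 ns at 1.2 ns frame spacing) and removes the fast
on-off flicker caused by thermal noise; it is applied to the distance
series, not to the boolean masks. Maximal runs of interacting frames
become :class:`InteractionIntervalSet` entries, the raw material of the
survival analysis in :mod:`lipidsite.residence`.

:func:`residue_contact_table` records, per frame and per cardiolipin, the
protein residues whose beads lie within the cutoff of either cardiolipin
phosphate bead; this table feeds the residue-pair coincidence metric in
:mod:`lipidsite.sites`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ModeError, ParameterError, SelectionError
from .traj_io import MoleculeType, Trajectory

__all__ = [
    "DistanceSeries",
    "ContactMask",
    "Interval",
    "InteractionIntervalSet",
    "ResidueContactTable",
    "min_distance_series",
    "smooth_series",
    "running_mean",
    "contact_mask",
    "contact_masks",
    "extract_intervals",
    "residue_contact_table",
    "atomistic_contact_frequency",
]

HEADGROUP = "headgroup"
WHOLE_LIPID = "whole_lipid"
DEFAULT_CUTOFF_NM = 0.7
DEFAULT_SMOOTHING_WINDOW = 50
WHOLE_LIPID_MIN_BEADS = 4


# ---------------------------------------------------------------------------
# periodic minimum-image distances
# ---------------------------------------------------------------------------

def minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors.

    Orthorhombic boxes only; ``box`` broadcasts against ``delta``.
    """
    return delta - box * np.round(delta / box)


def _min_dist_to_ref(traj: Trajectory, sel_idx: np.ndarray,
                     ref_idx: np.ndarray) -> np.ndarray:
    """Per-frame minimum-image distance from each selected bead to the
    nearest reference bead; returns ``(n_frames, len(sel_idx))``."""
    if sel_idx.size == 0 or ref_idx.size == 0:
        raise SelectionError("empty bead selection")
    n_frames = traj.n_frames
    out = np.empty((n_frames, sel_idx.size))
    # frame chunks keep the (chunk, n_sel, n_ref, 3) scratch array small
    chunk = max(1, int(4_000_000 / max(1, sel_idx.size * ref_idx.size)))
    for f0 in range(0, n_frames, chunk):
        f1 = min(n_frames, f0 + chunk)
        d = (traj.coords[f0:f1, sel_idx, None, :]
             - traj.coords[f0:f1, None, ref_idx, :])
        d = minimum_image(d, traj.box[f0:f1, None, None, :])
        d2 = np.einsum("fabx,fabx->fab", d, d)
        out[f0:f1] = np.sqrt(d2.min(axis=2))
    return out


# ---------------------------------------------------------------------------
# distance series and smoothing
# ---------------------------------------------------------------------------

@dataclass
class DistanceSeries:
    """Per-frame minimum lipid-protein distance (nm) for one lipid."""

    lipid_id: int
    values: np.ndarray
    frame_spacing: float
    smoothed: bool = False
    window: int = 1

    @property
    def effective_span_ns(self) -> float:
        """Time span of the smoothing window (window x frame spacing)."""
        return self.window * self.frame_spacing


@dataclass
class ContactMask:
    lipid_id: int
    mode: str
    values: np.ndarray
    cutoff: float
    window: int = 1

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=bool)


@dataclass
class Interval:
    """Closed frame interval [start_frame, end_frame] of continuous contact."""

    start_frame: int
    end_frame: int
    duration: float  # ns, counts frames inclusively
    censored_left: bool = False
    censored_right: bool = False


@dataclass
class InteractionIntervalSet:
    lipid_id: int
    intervals: list
    frame_spacing: float
    n_frames: int

    def __post_init__(self):
        prev_end = -1
        for iv in self.intervals:
            if iv.start_frame <= prev_end:
                raise ParameterError("intervals must be disjoint and ordered")
            prev_end = iv.end_frame

    @property
    def durations(self) -> np.ndarray:
        return np.array([iv.duration for iv in self.intervals])

    def continuous_intervals(self) -> list:
        """Intervals as continuous-time (start_ns, end_ns) pairs.

        A run of k frames starting at frame s covers [s*dt, (s+k)*dt), i.e.
        its length equals the inclusive frame-count duration.
        """
        dt = self.frame_spacing
        return [(iv.start_frame * dt, iv.start_frame * dt + iv.duration)
                for iv in self.intervals]

    def to_records(self) -> list:
        return [
            {
                "lipid_id": self.lipid_id,
                "start_frame": iv.start_frame,
                "end_frame": iv.end_frame,
                "duration_ns": iv.duration,
                "censored_left": iv.censored_left,
                "censored_right": iv.censored_right,
            }
            for iv in self.intervals
        ]


def running_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centred running mean with the window truncated at the edges.

    Works along axis 0 of 1-D or 2-D input; output length is unchanged. For
    even windows the centre is taken half a frame to the left (window
    [i - w//2, i + w//2 - 1] plus the centre conventions below).
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if window < 1:
        raise ParameterError("window must be >= 1")
    if window > n:
        raise ParameterError(f"window {window} exceeds series length {n}")
    half_l = (window - 1) // 2
    half_r = window // 2
    idx = np.arange(n)
    lo = np.maximum(0, idx - half_l)
    hi = np.minimum(n, idx + half_r + 1)
    cs = np.concatenate([np.zeros((1,) + values.shape[1:]),
                         np.cumsum(values, axis=0)], axis=0)
    counts = (hi - lo).astype(float)
    if values.ndim == 1:
        return (cs[hi] - cs[lo]) / counts
    return (cs[hi] - cs[lo]) / counts[:, None]


def min_distance_series(traj: Trajectory, lipid_id: int,
                        lipid_bead_filter: str = "phosphates",
                        protein_selection: np.ndarray | None = None
                        ) -> DistanceSeries:
    """Per-frame minimum distance between a lipid and the protein.

    ``lipid_bead_filter`` selects which lipid beads enter the minimum:
    ``"phosphates"`` (headgroup) or ``"all"``.
    """
    top = traj.topology
    beads = top.beads_of_molecule(lipid_id)
    if beads.size == 0:
        raise SelectionError(f"no lipid with molecule id {lipid_id}")
    if lipid_bead_filter == "phosphates":
        beads = beads[top.is_phosphate[beads]]
        if beads.size == 0:
            raise SelectionError(f"lipid {lipid_id} has no phosphate beads")
    elif lipid_bead_filter != "all":
        raise ParameterError(f"unknown lipid_bead_filter {lipid_bead_filter!r}")
    ref = (np.asarray(protein_selection) if protein_selection is not None
           else top.protein_indices())
    if ref.size == 0:
        raise SelectionError("empty protein selection")
    d = _min_dist_to_ref(traj, beads, ref).min(axis=1)
    return DistanceSeries(int(lipid_id), d, traj.frame_spacing)


def smooth_series(series: DistanceSeries,
                  window: int = DEFAULT_SMOOTHING_WINDOW) -> DistanceSeries:
    """Smooth a distance series by a centred running average."""
    return DistanceSeries(
        lipid_id=series.lipid_id,
        values=running_mean(series.values, window),
        frame_spacing=series.frame_spacing,
        smoothed=True,
        window=window,
    )


# ---------------------------------------------------------------------------
# contact masks
# ---------------------------------------------------------------------------

def contact_masks(traj: Trajectory, lipid_ids, mode: str = HEADGROUP,
                  cutoff: float = DEFAULT_CUTOFF_NM,
                  smoothing_window: int = DEFAULT_SMOOTHING_WINDOW,
                  protein_selection: np.ndarray | None = None) -> dict:
    """Contact masks for many lipids at once (shared distance computation).

    Returns ``{lipid_id: ContactMask}``.
    """
    if mode not in (HEADGROUP, WHOLE_LIPID):
        raise ParameterError(f"unknown contact mode {mode!r}")
    if cutoff <= 0:
        raise ParameterError("cutoff must be > 0")
    top = traj.topology
    lipid_ids = np.asarray(sorted(int(m) for m in lipid_ids))
    ref = (np.asarray(protein_selection) if protein_selection is not None
           else top.protein_indices())
    if ref.size == 0:
        raise SelectionError("empty protein selection")

    sel = np.flatnonzero(np.isin(top.molecule_id, lipid_ids))
    if mode == HEADGROUP:
        sel = sel[top.is_phosphate[sel]]
    if sel.size == 0:
        raise SelectionError("selected lipids contribute no beads")
    order = np.argsort(top.molecule_id[sel], kind="stable")
    sel = sel[order]
    owner = top.molecule_id[sel]
    starts = np.flatnonzero(np.r_[True, np.diff(owner) != 0])
    mols_present = owner[starts]

    dists = _min_dist_to_ref(traj, sel, ref)  # (F, n_sel)
    masks = {}
    if mode == HEADGROUP:
        # min over the lipid's phosphate beads, then smooth, then threshold
        per_lipid = np.minimum.reduceat(dists, starts, axis=1)
        if smoothing_window > 1:
            per_lipid = running_mean(per_lipid, smoothing_window)
        inside = per_lipid <= cutoff
        for k, mol in enumerate(mols_present):
            masks[int(mol)] = ContactMask(int(mol), mode, inside[:, k],
                                          cutoff, smoothing_window)
    else:
        # smooth each bead's series, threshold, then count beads per lipid
        if smoothing_window > 1:
            dists = running_mean(dists, smoothing_window)
        inside = dists <= cutoff
        counts = np.add.reduceat(inside.astype(np.int32), starts, axis=1)
        ok = counts >= WHOLE_LIPID_MIN_BEADS
        for k, mol in enumerate(mols_present):
            masks[int(mol)] = ContactMask(int(mol), mode, ok[:, k],
                                          cutoff, smoothing_window)
    for mol in lipid_ids:
        if int(mol) not in masks:
            raise SelectionError(f"no lipid with molecule id {mol}")
    return masks


def contact_mask(traj: Trajectory, lipid_id: int, mode: str = HEADGROUP,
                 cutoff: float = DEFAULT_CUTOFF_NM,
                 smoothing_window: int = DEFAULT_SMOOTHING_WINDOW,
                 protein_selection: np.ndarray | None = None) -> ContactMask:
    """Per-frame interaction mask for one lipid (see module docstring)."""
    return contact_masks(traj, [lipid_id], mode, cutoff, smoothing_window,
                         protein_selection)[int(lipid_id)]


def extract_intervals(mask, frame_spacing: float | None = None
                      ) -> InteractionIntervalSet:
    """Run-length encode a contact mask into interaction intervals.

    Durations count frames inclusively: ``(end - start + 1) * frame_spacing``.
    Intervals touching the first/last frame are flagged censored.
    """
    if isinstance(mask, ContactMask):
        values = mask.values
        lipid_id = mask.lipid_id
    else:
        values = np.asarray(mask, dtype=bool)
        lipid_id = -1
    if frame_spacing is None:
        raise ParameterError("frame_spacing is required")
    n = values.size
    if n < 1:
        raise ParameterError("mask must have at least one frame")
    padded = np.r_[False, values, False]
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2] - 1
    intervals = [
        Interval(
            start_frame=int(s),
            end_frame=int(e),
            duration=(int(e) - int(s) + 1) * frame_spacing,
            censored_left=(s == 0),
            censored_right=(e == n - 1),
        )
        for s, e in zip(starts, ends)
    ]
    return InteractionIntervalSet(int(lipid_id), intervals, frame_spacing, n)


# ---------------------------------------------------------------------------
# residue-cardiolipin contact tables
# ---------------------------------------------------------------------------

@dataclass
class ResidueContactTable:
    """Sparse (frame, cardiolipin, residue) phosphate-contact events.

    One row per protein residue whose beads lie within ``cutoff`` of at least
    one phosphate bead of the given cardiolipin in the given frame.
    """

    frame: np.ndarray
    lipid_id: np.ndarray
    residue: np.ndarray
    n_frames: int
    cutoff: float
    frame_spacing: float
    residues: np.ndarray = field(default=None)  # all protein residue indices

    def __post_init__(self):
        self.frame = np.asarray(self.frame, dtype=np.int64)
        self.lipid_id = np.asarray(self.lipid_id, dtype=np.int64)
        self.residue = np.asarray(self.residue, dtype=np.int64)
        if self.residues is None:
            self.residues = np.unique(self.residue)
        else:
            self.residues = np.asarray(self.residues, dtype=np.int64)
        if self.residue.size and not np.all(np.isin(self.residue, self.residues)):
            raise ParameterError("contact table names residues missing from "
                                 "the residue list")

    @property
    def n_events(self) -> int:
        return self.frame.size

    def lipid_ids_present(self) -> np.ndarray:
        return np.unique(self.lipid_id)

    def filter_lipids(self, keep) -> "ResidueContactTable":
        keep = np.asarray(list(keep))
        m = np.isin(self.lipid_id, keep)
        return ResidueContactTable(self.frame[m], self.lipid_id[m],
                                   self.residue[m], self.n_frames, self.cutoff,
                                   self.frame_spacing, self.residues)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": self.frame, "lipid_id": self.lipid_id,
                             "residue": self.residue})


def _grouped_within(traj, phos_idx, phos_owner, prot_idx, prot_res, cutoff):
    """Yield (frame, cdl_index, residue_index) arrays of contact events."""
    # sort phosphates by owning molecule, protein beads by residue
    p_order = np.argsort(phos_owner, kind="stable")
    phos_idx, phos_owner = phos_idx[p_order], phos_owner[p_order]
    p_starts = np.flatnonzero(np.r_[True, np.diff(phos_owner) != 0])
    cdl_ids = phos_owner[p_starts]
    r_order = np.argsort(prot_res, kind="stable")
    prot_idx, prot_res = prot_idx[r_order], prot_res[r_order]
    r_starts = np.flatnonzero(np.r_[True, np.diff(prot_res) != 0])
    residues = prot_res[r_starts]

    cut2 = cutoff * cutoff
    n_frames = traj.n_frames
    chunk = max(1, int(4_000_000 / max(1, phos_idx.size * prot_idx.size)))
    frames_out, lip_out, res_out = [], [], []
    for f0 in range(0, n_frames, chunk):
        f1 = min(n_frames, f0 + chunk)
        d = (traj.coords[f0:f1, phos_idx, None, :]
             - traj.coords[f0:f1, None, prot_idx, :])
        d = minimum_image(d, traj.box[f0:f1, None, None, :])
        within = np.einsum("fabx,fabx->fab", d, d) <= cut2
        by_cdl = np.logical_or.reduceat(within, p_starts, axis=1)
        by_res = np.logical_or.reduceat(by_cdl, r_starts, axis=2)
        fi, ci, ri = np.nonzero(by_res)
        frames_out.append(fi + f0)
        lip_out.append(cdl_ids[ci])
        res_out.append(residues[ri])
    return (np.concatenate(frames_out), np.concatenate(lip_out),
            np.concatenate(res_out))


def residue_contact_table(traj: Trajectory,
                          cutoff: float = DEFAULT_CUTOFF_NM,
                          lipid_ids=None) -> ResidueContactTable:
    """Per-frame sets of protein residues contacted by cardiolipin phosphates.

    A residue is contacted by a cardiolipin in a frame when at least one of
    its beads lies within ``cutoff`` (minimum-image) of at least one of the
    cardiolipin's phosphate beads. Distances are *not* smoothed here.
    """
    if cutoff <= 0:
        raise ParameterError("cutoff must be > 0")
    top = traj.topology
    prot_idx = top.protein_indices()
    if prot_idx.size == 0:
        raise SelectionError("trajectory has no protein beads")
    if np.any(top.residue_index[prot_idx] < 0):
        raise SelectionError("protein residues are not labelled")
    if lipid_ids is None:
        lipid_ids = top.molecules_of_type(MoleculeType.CDL)
    lipid_ids = np.asarray(lipid_ids)
    empty = ResidueContactTable(
        np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0, np.int64),
        traj.n_frames, cutoff, traj.frame_spacing,
        residues=np.unique(top.residue_index[prot_idx]))
    if lipid_ids.size == 0:
        warnings.warn("no cardiolipin in trajectory; empty contact table")
        return empty
    phos_sel = np.flatnonzero(np.isin(top.molecule_id, lipid_ids)
                              & top.is_phosphate)
    if phos_sel.size == 0:
        warnings.warn("selected lipids have no phosphate beads; empty table")
        return empty
    frames, lips, res = _grouped_within(
        traj, phos_sel, top.molecule_id[phos_sel], prot_idx,
        top.residue_index[prot_idx], cutoff)
    order = np.lexsort((res, lips, frames))
    return ResidueContactTable(frames[order], lips[order], res[order],
                               traj.n_frames, cutoff, traj.frame_spacing,
                               residues=empty.residues)


def atomistic_contact_frequency(traj: Trajectory,
                                cutoff_nm: float = 0.3) -> pd.Series:
    """Per-residue count of frames with a cardiolipin phosphate within cutoff.

    Atomistic analogue of the bead contact rule: a residue interacts with a
    cardiolipin headgroup in a frame when any cardiolipin phosphate atom is
    within 3 A (0.3 nm) of any atom of the residue. The trajectory must be
    flagged atomistic.
    """
    if not traj.is_atomistic:
        raise ModeError("atomistic_contact_frequency requires an atomistic "
                        "trajectory (is_atomistic=True)")
    if cutoff_nm <= 0:
        raise ParameterError("cutoff must be > 0")
    top = traj.topology
    prot_idx = top.protein_indices()
    if prot_idx.size == 0:
        raise SelectionError("trajectory has no protein atoms")
    residues = np.unique(top.residue_index[prot_idx])
    counts = pd.Series(0, index=pd.Index(residues, name="residue"),
                       dtype=np.int64)
    cdl_ids = top.molecules_of_type(MoleculeType.CDL)
    if cdl_ids.size == 0 or traj.n_frames == 0:
        return counts
    phos_sel = np.flatnonzero(np.isin(top.molecule_id, cdl_ids)
                              & top.is_phosphate)
    if phos_sel.size == 0:
        return counts
    frames, _, res = _grouped_within(
        traj, phos_sel, top.molecule_id[phos_sel], prot_idx,
        top.residue_index[prot_idx], cutoff_nm)
    if frames.size:
        # count frames, not (frame, cdl) pairs: dedupe on (frame, residue)
        key = frames * (residues.max() + 1) + res
        uniq = np.unique(key)
        res_u = uniq % (residues.max() + 1)
        add = pd.Series(res_u).value_counts()
        counts.loc[add.index] += add.values
    return counts
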