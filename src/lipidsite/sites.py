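"""Binding-site identification by residue-pair coincidence clustering.

Residues that are repeatedly contacted *simultaneously* by the same
cardiolipin headgroup belong to one binding site. For a leaflet l the
pairwise metric is

    d_l(res_i, res_j) = 1 - (1/N_int,l) * sum_n sum_t chi_{n,t}(res_i, res_j)

where chi_{n,t} is 1 when phosphate beads of the n-th cardiolipin are within
the contact cutoff of both residues at frame t, and N_int,l is the total
number of (residue, cardiolipin, frame) contact events in the leaflet --
the only normalisation that keeps d in [0, 1] by construction. d = 1 means
no single cardiolipin ever touches both residues at once; low d marks
recurrent coincidence. Matrices from repeat simulations are combined by a
weighted average (weights default to each repeat's N_int,l), and residues
are grouped by single-linkage hierarchical clustering with the dendrogram
cut at a configurable height.

Because N_int,l counts every residue contact in the leaflet, most pair
distances sit very close to 1; the default cut height of 0.995 keeps only
residue pairs with genuinely recurrent co-contact in one cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .contacts import ResidueContactTable, extract_intervals
from .errors import EstimationError, ParameterError, StructuralError
from .residence import ResidenceFit, select_fit, survival_correlation

__all__ = [
    "PairDistanceMatrix",
    "BindingSite",
    "OccupancyTimeline",
    "pair_distance_matrix",
    "average_matrices",
    "cluster_sites",
    "site_occupancy_timeline",
    "site_residence_times",
    "plot_occupancy",
]

DEFAULT_CUT_HEIGHT = 0.995
DEFAULT_MIN_SIZE = 2
DEFAULT_MIN_RESIDUES = 2


@dataclass
class PairDistanceMatrix:
    """Residue-pair coincidence metric for one leaflet.

    ``d = 1 - pair_counts / n_int`` elementwise; the diagonal holds
    ``1 - (single-residue contact count)/n_int``.
    """

    leaflet: str
    residues: np.ndarray
    d: np.ndarray
    pair_counts: np.ndarray
    n_int: int
    n_cdl: int

    def __post_init__(self):
        self.residues = np.asarray(self.residues, dtype=np.int64)
        self.d = np.asarray(self.d, dtype=float)
        self.pair_counts = np.asarray(self.pair_counts, dtype=np.int64)
        n = self.residues.size
        if self.d.shape != (n, n) or self.pair_counts.shape != (n, n):
            raise StructuralError("matrix shapes do not match residue list")
        if not np.allclose(self.d, self.d.T):
            raise StructuralError("d must be symmetric")
        if np.any(self.d < -1e-12) or np.any(self.d > 1 + 1e-12):
            raise StructuralError("d must lie in [0, 1]")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.residues, columns=self.residues)


@dataclass
class BindingSite:
    site_id: int
    label: str
    residues: frozenset
    leaflet: str

    def sorted_residues(self) -> list:
        return sorted(self.residues)


@dataclass
class OccupancyTimeline:
    """Per-frame occupying cardiolipin for one site (-1 = unoccupied)."""

    site_id: int
    occupant: np.ndarray
    occupancy_fraction: float
    frame_spacing: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": np.arange(self.occupant.size),
                             "lipid_id": self.occupant})


# ---------------------------------------------------------------------------
# pair-distance matrices
# ---------------------------------------------------------------------------

def _iter_contact_groups(table: ResidueContactTable):
    """Yield residue arrays for each (frame, cardiolipin) group."""
    if table.n_events == 0:
        return
    order = np.lexsort((table.residue, table.lipid_id, table.frame))
    frm = table.frame[order]
    lip = table.lipid_id[order]
    res = table.residue[order]
    change = np.flatnonzero(np.r_[True, (np.diff(frm) != 0)
                                  | (np.diff(lip) != 0)])
    bounds = np.r_[change, frm.size]
    for k in range(change.size):
        yield res[bounds[k]:bounds[k + 1]]


def pair_distance_matrix(table: ResidueContactTable, leaflet: str = "inner",
                         assignment=None,
                         residues=None) -> PairDistanceMatrix:
    """Residue-pair coincidence matrix from a contact table.

    If ``assignment`` (a :class:`~lipidsite.traj_io.LeafletAssignment`) is
    given the table is restricted to cardiolipins of ``leaflet``; otherwise
    the table is used as-is and ``leaflet`` is only a label.
    """
    if assignment is not None:
        keep = [m for m in table.lipid_ids_present()
                if assignment.leaflet.get(int(m)) == leaflet]
        table = table.filter_lipids(keep)
    residues = np.unique(np.asarray(
        table.residues if residues is None else residues, dtype=np.int64))
    n = residues.size
    pair_counts = np.zeros((n, n), dtype=np.int64)
    n_int = 0
    for group in _iter_contact_groups(table):
        idx = np.searchsorted(residues, group)
        pair_counts[np.ix_(idx, idx)] += 1
        n_int += group.size
    n_cdl = int(table.lipid_ids_present().size)
    if n_int == 0:
        warnings.warn(f"no residue-cardiolipin interactions in leaflet "
                      f"{leaflet!r}; all distances set to 1")
        d = np.ones((n, n))
    else:
        d = 1.0 - pair_counts / n_int
    return PairDistanceMatrix(leaflet, residues, d, pair_counts, n_int, n_cdl)


def average_matrices(matrices, weights=None) -> PairDistanceMatrix:
    """Weighted elementwise average of repeat-simulation distance matrices.

    Weights default to each repeat's total interaction count N_int,l, so
    repeats with more interaction evidence count more.
    """
    matrices = list(matrices)
    if not matrices:
        raise ParameterError("need at least one matrix")
    first = matrices[0]
    for m in matrices[1:]:
        if not np.array_equal(m.residues, first.residues):
            raise StructuralError("matrices have mismatched residue sets")
        if m.leaflet != first.leaflet:
            raise StructuralError("matrices come from different leaflets")
    if weights is None:
        weights = [m.n_int for m in matrices]
    weights = np.asarray(weights, dtype=float)
    if weights.size != len(matrices) or np.any(weights < 0) or weights.sum() <= 0:
        raise ParameterError("weights must be non-negative and not all zero")
    w = weights / weights.sum()
    d = sum(wi * m.d for wi, m in zip(w, matrices))
    pair_counts = sum(m.pair_counts for m in matrices)
    return PairDistanceMatrix(first.leaflet, first.residues, d, pair_counts,
                              n_int=int(sum(m.n_int for m in matrices)),
                              n_cdl=first.n_cdl)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def cluster_sites(matrix: PairDistanceMatrix,
                  cut_height: float = DEFAULT_CUT_HEIGHT,
                  min_size: int = DEFAULT_MIN_SIZE) -> list:
    """Single-linkage clustering of the coincidence matrix into binding sites.

    Only residues with at least one recorded contact participate (a residue
    never contacted carries no coincidence information). The dendrogram is
    cut at ``cut_height``; clusters smaller than ``min_size`` are discarded.
    Sites are ordered (and labelled) by their lowest residue index.
    """
    if not (0 < cut_height <= 1):
        raise ParameterError("cut_height must lie in (0, 1]")
    active = np.flatnonzero(np.diag(matrix.pair_counts) > 0)
    if active.size < max(min_size, 2):
        return []
    d_sub = matrix.d[np.ix_(active, active)]
    condensed = squareform(d_sub, checks=False)
    Z = linkage(condensed, method="single")
    labels = fcluster(Z, t=cut_height, criterion="distance")
    clusters = {}
    for res_pos, lab in zip(active, labels):
        clusters.setdefault(lab, []).append(int(matrix.residues[res_pos]))
    groups = [sorted(g) for g in clusters.values() if len(g) >= min_size]
    groups.sort(key=lambda g: g[0])  # deterministic: lowest residue first
    return [
        BindingSite(site_id=k, label=f"{matrix.leaflet}-{k + 1}",
                    residues=frozenset(g), leaflet=matrix.leaflet)
        for k, g in enumerate(groups)
    ]


# ---------------------------------------------------------------------------
# occupancy and per-site residence
# ---------------------------------------------------------------------------

def _site_contact_counts(table: ResidueContactTable, residue_set):
    """Dense (n_frames, n_lipids) count of site residues contacted, plus the
    sorted lipid-id axis."""
    lipids = table.lipid_ids_present()
    counts = np.zeros((table.n_frames, lipids.size), dtype=np.int32)
    if table.n_events:
        in_site = np.isin(table.residue, sorted(residue_set))
        if in_site.any():
            li = np.searchsorted(lipids, table.lipid_id[in_site])
            np.add.at(counts, (table.frame[in_site], li), 1)
    return counts, lipids


def site_occupancy_timeline(site: BindingSite, table: ResidueContactTable,
                            min_residues: int = DEFAULT_MIN_RESIDUES
                            ) -> OccupancyTimeline:
    """Which cardiolipin (if any) occupies a site in each frame.

    A cardiolipin occupies the site when it contacts at least
    ``min_residues`` of the site's residues (suppresses grazing contacts);
    ties go to the lipid contacting the most residues, then the lowest
    lipid id.
    """
    counts, lipids = _site_contact_counts(table, site.residues)
    occupant = np.full(table.n_frames, -1, dtype=np.int64)
    frac = 0.0
    if lipids.size:
        counts = np.where(counts >= min_residues, counts, 0)
        best = counts.argmax(axis=1)  # first max -> lowest lipid id on ties
        val = counts[np.arange(table.n_frames), best]
        occupant = np.where(val > 0, lipids[best], -1)
        frac = float(np.mean(occupant >= 0))
    return OccupancyTimeline(site.site_id, occupant, frac,
                             table.frame_spacing)


def site_residence_times(sites, table: ResidueContactTable, T: float,
                         model: str = "auto",
                         min_residues: int = DEFAULT_MIN_RESIDUES,
                         dt_lag: float = 1.0, max_lag=None,
                         min_windows: int = 10) -> ResidenceFit:
    """Residence time of cardiolipin at a site (or a class of sites).

    Per cardiolipin, a site-contact mask is built (contact = at least
    ``min_residues`` residues of one site within the cutoff), continuous
    intervals are extracted, and the survival correlation is fitted with the
    requested model. Pass a list of sites to aggregate a user-labelled site
    class (e.g. the crystallographic sites versus the matrix-helix sites).
    """
    if isinstance(sites, BindingSite):
        sites = [sites]
    if not sites:
        raise ParameterError("need at least one site")
    lipids = table.lipid_ids_present()
    if lipids.size == 0:
        raise EstimationError("contact table is empty")
    any_mask = np.zeros((table.n_frames, lipids.size), dtype=bool)
    for site in sites:
        counts, _ = _site_contact_counts(table, site.residues)
        any_mask |= counts >= min_residues
    interval_sets = [
        extract_intervals(any_mask[:, k], table.frame_spacing)
        for k in range(lipids.size)
    ]
    if not any(s.intervals for s in interval_sets):
        raise EstimationError("no cardiolipin ever contacts the site(s)")
    curve = survival_correlation(interval_sets, T, dt_lag=dt_lag,
                                 max_lag=max_lag)
    return select_fit(curve, model=model, min_windows=min_windows)


def plot_occupancy(timelines, labels=None, ax=None):
    """Strip chart of per-site occupancy timelines (one row per site)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 0.5 + 0.4 * len(timelines)))
    for row, tl in enumerate(timelines):
        occ = tl.occupant >= 0
        if occ.any():
            iv = extract_intervals(occ, tl.frame_spacing)
            spans = [(s * tl.frame_spacing, d)
                     for (s, d) in ((i.start_frame, i.duration)
                                    for i in iv.intervals)]
            ax.broken_barh(spans, (row + 0.1, 0.8))
    ax.set_yticks([r + 0.5 for r in range(len(timelines))])
    ax.set_yticklabels(labels if labels is not None
                       else [str(tl.site_id) for tl in timelines])
    ax.set_xlabel("time (ns)")
    ax.set_ylabel("site")
    return ax
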