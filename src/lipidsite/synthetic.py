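"""Synthetic coarse-grained membrane trajectories with known binding kinetics.

The generator emulates the *statistical* structure of a two-leaflet bilayer
patch around a static membrane-protein scaffold, so that every stage of the
contact/residence/site pipeline can be validated against planted ground
truth without running molecular dynamics:

* the protein is a rigid scaffold of one backbone bead per residue, placed
  on two rings (one per leaflet headgroup plane) of a cylinder;
* lipids are rigid point-clusters (cardiolipin: 2 phosphate beads + 4 tail
  beads; POPC/POPE: 1 phosphate + 2 tails) that diffuse laterally as 2-D
  Brownian motion with periodic wrapping;
* planted binding sites sit on the rings; an unbound lipid of a selected
  type entering the capture range binds with probability
  1 - exp(-k_on * w * dt) per frame (w = type selectivity weight), sits with
  its phosphate within contact range of the site residues (plus Gaussian
  flicker), and unbinds after an exponentially distributed dwell with rate
  k_off. Sites hold one lipid at a time;
* a nonspecific "background" surface attachment with a short exponential
  dwell models the annular lipid shell: any lipid close to the scaffold may
  stick briefly at its current position;
* unbound lipids are kept outside an excluded-volume shell around the
  scaffold, so every protein contact is the result of a logged binding
  event and the emitted :class:`GroundTruth` covers all contacts.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .contacts import Interval, InteractionIntervalSet
from .errors import ParameterError
from .traj_io import MoleculeType, Topology, Trajectory

__all__ = [
    "PlantedSite",
    "SyntheticConfig",
    "GroundTruth",
    "BindingEvent",
    "compose_bilayer",
    "simulate_interval_ensemble",
    "default_config",
    "generate_trajectory",
    "ground_truth_intervals",
    "BACKGROUND_SITE_ID",
]

BACKGROUND_SITE_ID = -1

# rigid bead offsets (x, z_toward_midplane) per lipid type; phosphates first
_CDL_OFFSETS = [
    ("PO41", 0.00, 0.0, True),
    ("PO42", 0.00, 0.3, True),
    ("C1A", 0.00, 0.5, False),
    ("C1B", 0.15, 0.5, False),
    ("C2A", 0.00, 1.0, False),
    ("C2B", 0.15, 1.0, False),
]
_PL_OFFSETS = [
    ("PO4", 0.00, 0.0, True),
    ("C1A", 0.00, 0.5, False),
    ("C2A", 0.00, 1.0, False),
]
_LIPID_OFFSETS = {
    MoleculeType.CDL.value: _CDL_OFFSETS,
    MoleculeType.POPC.value: _PL_OFFSETS,
    MoleculeType.POPE.value: _PL_OFFSETS,
}


@dataclass
class PlantedSite:
    """A planted binding site on one leaflet ring of the scaffold.

    Rates are per-nanosecond: ``k_on`` applies per eligible free lipid per
    frame (scaled by the lipid-type selectivity weight), ``k_off`` sets the
    exponential dwell (mean dwell = 1/k_off ns).
    """

    site_id: int
    leaflet: str                    # 'inner' | 'outer'
    angle: float                    # anchor angle on the ring, radians
    k_on: float                     # ns^-1 per eligible free lipid
    k_off: float                    # ns^-1
    selectivity: dict = field(default_factory=lambda: {"CDL": 1.0})
    residues: tuple = ()            # filled in by the generator from geometry

    def weight(self, molecule_type: str) -> float:
        return float(self.selectivity.get(molecule_type, 0.0))


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic benchmark.

    Defaults mirror the regimes of the analysed system: ~20 us of effective
    time at 1.2 ns frame spacing, a 9:7:4 POPC:POPE:CDL bilayer, planted
    cardiolipin-selective sites with ~2 us dwell on the inner leaflet and a
    150 ns nonspecific surface dwell for the annular shell.
    """

    n_residues_per_ring: int = 30
    scaffold_radius: float = 1.5          # nm
    box: tuple = (15.0, 15.0, 10.0)       # nm
    leaflet_offset: float = 2.0           # headgroup planes at mid_z +/- offset
    lipids_per_leaflet: int = 40
    ratio: tuple = (9, 7, 4)              # POPC : POPE : CDL
    D: float = 0.01                       # lateral diffusion, nm^2/ns
    flicker_sd: float = 0.05              # positional jitter, nm
    T: float = 20000.0                    # ns
    frame_spacing: float = 1.2            # ns
    capture_radius: float = 1.0           # nm, site capture range
    exclusion_margin: float = 0.9         # nm beyond scaffold radius
    anchor_offset: float = 0.45           # nm, anchor outward of the ring
    site_residue_cutoff: float = 0.7      # nm, defines planted residue sets
    refractory_frames: int = 2            # frames before re-binding allowed
    background_k_on: float = 0.005        # ns^-1 while in the surface band
    background_mean_dwell: float = 150.0  # ns
    background_band: float = 0.5          # nm, width of the attachment band
    background_site_margin: float = 0.9   # rad, keep clear of planted anchors
    sites: list = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if self.T <= 0 or self.frame_spacing <= 0:
            raise ParameterError("T and frame_spacing must be positive")
        if self.lipids_per_leaflet < 0 or self.n_residues_per_ring < 1:
            raise ParameterError("counts must be non-negative")
        if self.D < 0 or self.flicker_sd < 0:
            raise ParameterError("D and flicker_sd must be non-negative")
        if any(v <= 0 for v in self.box) or self.scaffold_radius <= 0:
            raise ParameterError("box and scaffold radius must be positive")
        for s in self.sites:
            if s.k_on < 0 or s.k_off <= 0:
                raise ParameterError(f"site {s.site_id}: rates must be positive")
            if s.leaflet not in ("inner", "outer"):
                raise ParameterError(f"site {s.site_id}: bad leaflet")
        per_leaflet = {}
        for s in self.sites:
            per_leaflet.setdefault(s.leaflet, []).append(s)

    @property
    def n_frames(self) -> int:
        return int(math.floor(self.T / self.frame_spacing + 1e-9)) + 1


@dataclass
class BindingEvent:
    lipid_id: int
    site_id: int          # BACKGROUND_SITE_ID for nonspecific attachment
    bind_time: float      # ns
    unbind_time: float    # ns, clipped to T
    censored: bool = False  # still bound at the end of the trajectory


@dataclass
class GroundTruth:
    """Planted binding intervals and site memberships."""

    events: list
    lipid_leaflet: dict
    site_residues: dict
    T: float

    def dwell_times(self, site_ids=None, include_censored: bool = False
                    ) -> np.ndarray:
        out = []
        for ev in self.events:
            if site_ids is not None and ev.site_id not in site_ids:
                continue
            if ev.censored and not include_censored:
                continue
            out.append(ev.unbind_time - ev.bind_time)
        return np.asarray(out)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"lipid_id": ev.lipid_id, "site_id": ev.site_id,
             "bind_time": ev.bind_time, "unbind_time": ev.unbind_time,
             "censored": ev.censored}
            for ev in self.events
        ])


def simulate_interval_ensemble(n_lipids: int, events_per_lipid: int,
                               mean_dwells, weights=None, seed=None,
                               gap_factor: float = 2.0):
    """Draw i.i.d. exponential dwell intervals for an ensemble of lipids.

    Dwells come from ``Exp(mean)`` with the mean drawn from ``mean_dwells``
    with probabilities ``weights`` (a scalar mean gives a single population).
    Per lipid, events are laid down sequentially with deterministic gaps of
    ``gap_factor * max(mean_dwells)`` so that intervals never overlap and
    none touches t = 0. Returns ``(interval_sets, T)`` where interval_sets
    is a list (per lipid) of continuous ``(start_ns, end_ns)`` pairs and T
    comfortably contains every interval (no censoring).

    This is the direct statistical analogue of the survival analysis'
    assumptions and serves as a ground-truth generator for parameter
    recovery: the survival correlation of such an ensemble decays as the
    dwell-weighted mixture of exponentials.
    """
    mean_dwells = np.atleast_1d(np.asarray(mean_dwells, dtype=float))
    if np.any(mean_dwells <= 0):
        raise ParameterError("mean dwells must be positive")
    if weights is None:
        weights = np.ones(mean_dwells.size) / mean_dwells.size
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)
    gap = gap_factor * float(mean_dwells.max())
    sets, t_max = [], 0.0
    for _ in range(n_lipids):
        cursor = gap
        ivs = []
        comps = rng.choice(mean_dwells.size, size=events_per_lipid, p=weights)
        dwells = rng.exponential(mean_dwells[comps])
        for d in dwells:
            ivs.append((cursor, cursor + d))
            cursor += d + gap
        sets.append(ivs)
        t_max = max(t_max, cursor)
    return sets, t_max + gap


def compose_bilayer(n_lipids: int, ratio=(9, 7, 4)) -> tuple:
    """Apportion lipids to (POPC, POPE, CDL) by largest remainder.

    A 125-lipid patch at 9:7:4 yields (56, 44, 25).
    """
    if n_lipids < 0:
        raise ParameterError("n_lipids must be >= 0")
    ratio = tuple(float(r) for r in ratio)
    if any(r < 0 for r in ratio) or sum(ratio) == 0:
        raise ParameterError("ratio components must be >= 0, not all zero")
    total = sum(ratio)
    quotas = [n_lipids * r / total for r in ratio]
    counts = [int(math.floor(q)) for q in quotas]
    remainder = n_lipids - sum(counts)
    by_frac = sorted(range(3), key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in by_frac[:remainder]:
        counts[i] += 1
    return tuple(counts)


def default_config(outer_sites: bool = False, **overrides) -> SyntheticConfig:
    """The standard synthetic benchmark configuration.

    Three cardiolipin-selective sites on the inner leaflet with mean dwell
    2 us (k_off = 5e-4 ns^-1); with ``outer_sites`` three more on the outer
    leaflet at interleaved angles. Keyword overrides are applied on top.
    """
    sites = [
        PlantedSite(site_id=k, leaflet="inner", angle=k * 2 * math.pi / 3,
                    k_on=0.05, k_off=5e-4)
        for k in range(3)
    ]
    if outer_sites:
        sites += [
            PlantedSite(site_id=3 + k, leaflet="outer",
                        angle=math.pi / 3 + k * 2 * math.pi / 3,
                        k_on=0.05, k_off=5e-4)
            for k in range(3)
        ]
    cfg = SyntheticConfig(sites=sites)
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _ring_geometry(cfg: SyntheticConfig):
    """Residue positions on the two leaflet rings.

    Inner-ring residues are 0..n-1, outer-ring residues n..2n-1.
    """
    n = cfg.n_residues_per_ring
    cx, cy = cfg.box[0] / 2.0, cfg.box[1] / 2.0
    z_mid = cfg.box[2] / 2.0
    planes = {"inner": z_mid - cfg.leaflet_offset,
              "outer": z_mid + cfg.leaflet_offset}
    angles = 2 * math.pi * np.arange(n) / n
    ring_xy = np.column_stack([cx + cfg.scaffold_radius * np.cos(angles),
                               cy + cfg.scaffold_radius * np.sin(angles)])
    return (cx, cy), planes, angles, ring_xy


def _site_anchor_and_residues(cfg, site, center, angles, ring_xy):
    cx, cy = center
    r = cfg.scaffold_radius + cfg.anchor_offset
    ax = cx + r * math.cos(site.angle)
    ay = cy + r * math.sin(site.angle)
    dist = np.hypot(ring_xy[:, 0] - ax, ring_xy[:, 1] - ay)
    local = np.flatnonzero(dist <= cfg.site_residue_cutoff)
    offset = 0 if site.leaflet == "inner" else cfg.n_residues_per_ring
    return (ax, ay), tuple(int(i) + offset for i in local)


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

def _build_topology(cfg, lipid_types, lipid_leaflet):
    rows = {k: [] for k in ("bead_id", "molecule_id", "molecule_type",
                            "residue_index", "residue_name", "bead_name",
                            "is_phosphate")}
    bead = 0
    n = cfg.n_residues_per_ring
    for res in range(2 * n):
        rows["bead_id"].append(bead)
        rows["molecule_id"].append(0)
        rows["molecule_type"].append(MoleculeType.PROTEIN.value)
        rows["residue_index"].append(res)
        rows["residue_name"].append("ALA")
        rows["bead_name"].append("BB")
        rows["is_phosphate"].append(False)
        bead += 1
    lipid_bead_slices = []
    for li, mtype in enumerate(lipid_types):
        mol = li + 1
        start = bead
        for name, _, _, isp in _LIPID_OFFSETS[mtype]:
            rows["bead_id"].append(bead)
            rows["molecule_id"].append(mol)
            rows["molecule_type"].append(mtype)
            rows["residue_index"].append(-1)
            rows["residue_name"].append(mtype)
            rows["bead_name"].append(name)
            rows["is_phosphate"].append(isp)
            bead += 1
        lipid_bead_slices.append((start, bead))
    top = Topology(**{k: np.array(v) for k, v in rows.items()})
    return top, lipid_bead_slices


def generate_trajectory(config: SyntheticConfig, seed=None):
    """Generate a trajectory with planted kinetics plus its ground truth.

    Returns ``(Trajectory, GroundTruth)``. All randomness derives from
    ``seed`` (falls back to ``config.seed``); the same seed reproduces the
    trajectory bit for bit.
    """
    cfg = config
    cfg.validate()
    seed = cfg.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    rng, rng_noise = [np.random.default_rng(s) for s in ss.spawn(2)]

    center, planes, angles, ring_xy = _ring_geometry(cfg)
    cx, cy = center
    n_frames = cfg.n_frames
    dt = cfg.frame_spacing
    lx, ly = cfg.box[0], cfg.box[1]

    # resolve planted-site geometry
    sites = []
    for s in cfg.sites:
        anchor, residues = _site_anchor_and_residues(cfg, s, center, angles,
                                                     ring_xy)
        sites.append((replace(s, residues=residues), anchor))
    taken = {}
    for s, _ in sites:
        for r in s.residues:
            if r in taken:
                raise ParameterError(
                    f"planted sites {taken[r]} and {s.site_id} overlap at "
                    f"residue {r}")
            taken[r] = s.site_id

    # lipid census: per leaflet, POPC/POPE/CDL by largest remainder
    popc, pope, cdl = compose_bilayer(cfg.lipids_per_leaflet, cfg.ratio)
    lipid_types, lipid_leaflet_list = [], []
    for leaflet in ("inner", "outer"):
        lipid_types += ([MoleculeType.POPC.value] * popc
                        + [MoleculeType.POPE.value] * pope
                        + [MoleculeType.CDL.value] * cdl)
        lipid_leaflet_list += [leaflet] * (popc + pope + cdl)
    n_lip = len(lipid_types)
    lipid_leaflet = {li + 1: lf for li, lf in enumerate(lipid_leaflet_list)}

    top, lipid_slices = _build_topology(cfg, lipid_types, lipid_leaflet_list)

    # initial positions: uniform in the box, outside the excluded shell
    r_excl = cfg.scaffold_radius + cfg.exclusion_margin
    xy = rng.uniform([0, 0], [lx, ly], size=(n_lip, 2))
    for _ in range(100):
        d = np.hypot(xy[:, 0] - cx, xy[:, 1] - cy)
        bad = d < r_excl
        if not bad.any():
            break
        xy[bad] = rng.uniform([0, 0], [lx, ly], size=(int(bad.sum()), 2))

    step_sd = math.sqrt(2.0 * cfg.D * dt)
    # per-lipid state
    FREE, SITE, BG = 0, 1, 2
    state = np.zeros(n_lip, dtype=np.int8)
    bound_site = np.full(n_lip, -1, dtype=np.int64)   # index into `sites`
    unbind_at = np.full(n_lip, np.inf)
    refractory_until = np.full(n_lip, -1, dtype=np.int64)  # frame index
    bg_anchor = np.zeros((n_lip, 2))
    open_event = [None] * n_lip
    site_occupant = np.full(len(sites), -1, dtype=np.int64)
    type_arr = np.array(lipid_types)
    leaflet_arr = np.array(lipid_leaflet_list)
    site_anchor_xy = np.array([a for _, a in sites]) if sites else np.zeros((0, 2))
    site_angles = np.array([s.angle for s, _ in sites])
    bg_dwell = cfg.background_mean_dwell

    events = []
    xy_hist = np.empty((n_frames, n_lip, 2))

    def release(li, t):
        ev = open_event[li]
        if ev is not None:
            events.append(ev)
            open_event[li] = None
        if state[li] == SITE:
            site_occupant[bound_site[li]] = -1
        state[li] = FREE
        bound_site[li] = -1
        unbind_at[li] = np.inf

    for f in range(n_frames):
        t = f * dt
        # 1. releases due this frame
        for li in np.flatnonzero((state != FREE) & (unbind_at <= t)):
            # park the lipid just outside the excluded shell at its angle
            if state[li] == SITE:
                ang = site_angles[bound_site[li]]
            else:
                ang = math.atan2(xy[li, 1] - cy, xy[li, 0] - cx)
            release(li, t)
            rr = r_excl + 0.2
            xy[li] = (cx + rr * math.cos(ang)) % lx, (cy + rr * math.sin(ang)) % ly
            refractory_until[li] = f + cfg.refractory_frames

        # 2. Brownian step for free lipids, wrap, excluded shell
        steps = rng.normal(0.0, step_sd, size=(n_lip, 2))
        free = state == FREE
        xy[free] += steps[free]
        xy[:, 0] %= lx
        xy[:, 1] %= ly
        dx, dy = xy[:, 0] - cx, xy[:, 1] - cy
        rad = np.hypot(dx, dy)
        push = free & (rad < r_excl)
        if push.any():
            scale = np.where(rad[push] > 1e-9, r_excl / rad[push], 0.0)
            xy[push, 0] = cx + dx[push] * scale
            xy[push, 1] = cy + dy[push] * scale
            zero = push & (rad <= 1e-9)
            if zero.any():
                ang = rng.uniform(0, 2 * math.pi, int(zero.sum()))
                xy[zero, 0] = cx + r_excl * np.cos(ang)
                xy[zero, 1] = cy + r_excl * np.sin(ang)
            rad = np.hypot(xy[:, 0] - cx, xy[:, 1] - cy)

        eligible_base = (state == FREE) & (refractory_until <= f)

        # 3. planted-site binding (single occupancy, lowest lipid id wins)
        for si, (s, anchor) in enumerate(sites):
            if site_occupant[si] >= 0 or s.k_on <= 0:
                continue
            w = np.array([s.weight(tp) for tp in type_arr])
            near = (eligible_base & (leaflet_arr == s.leaflet) & (w > 0)
                    & (np.hypot(xy[:, 0] - anchor[0], xy[:, 1] - anchor[1])
                       <= cfg.capture_radius))
            cand = np.flatnonzero(near)
            if cand.size == 0:
                continue
            p = 1.0 - np.exp(-s.k_on * w[cand] * dt)
            hits = cand[rng.random(cand.size) < p]
            if hits.size == 0:
                continue
            li = int(hits.min())
            state[li] = SITE
            bound_site[li] = si
            eligible_base[li] = False
            site_occupant[si] = li
            dwell = rng.exponential(1.0 / s.k_off)
            unbind_at[li] = t + dwell
            open_event[li] = BindingEvent(li + 1, s.site_id, t,
                                          min(t + dwell, cfg.T),
                                          censored=(t + dwell > cfg.T))
            xy[li] = anchor

        # 4. nonspecific background attachment in the surface band
        if cfg.background_k_on > 0:
            in_band = (eligible_base & (rad >= r_excl - 1e-9)
                       & (rad <= r_excl + cfg.background_band))
            if sites:
                ang_lip = np.arctan2(xy[:, 1] - cy, xy[:, 0] - cx)
                for si, (s, _) in enumerate(sites):
                    dang = np.abs(np.angle(np.exp(1j * (ang_lip - s.angle))))
                    in_band &= ~((leaflet_arr == s.leaflet)
                                 & (dang < cfg.background_site_margin))
            cand = np.flatnonzero(in_band)
            if cand.size:
                p = 1.0 - math.exp(-cfg.background_k_on * dt)
                hits = cand[rng.random(cand.size) < p]
                for li in hits:
                    li = int(li)
                    state[li] = BG
                    ang = math.atan2(xy[li, 1] - cy, xy[li, 0] - cx)
                    rr = cfg.scaffold_radius + cfg.anchor_offset
                    bg_anchor[li] = (cx + rr * math.cos(ang),
                                     cy + rr * math.sin(ang))
                    xy[li] = bg_anchor[li]
                    dwell = rng.exponential(bg_dwell)
                    unbind_at[li] = t + dwell
                    open_event[li] = BindingEvent(
                        li + 1, BACKGROUND_SITE_ID, t,
                        min(t + dwell, cfg.T), censored=(t + dwell > cfg.T))

        xy_hist[f] = xy

    for li in range(n_lip):  # flush still-bound lipids
        if open_event[li] is not None:
            events.append(open_event[li])
    events.sort(key=lambda ev: (ev.lipid_id, ev.bind_time))

    # ---- assemble coordinates --------------------------------------------
    n_prot = 2 * cfg.n_residues_per_ring
    n_beads = top.n_beads
    coords = np.empty((n_frames, n_beads, 3))
    coords[:, :cfg.n_residues_per_ring, 0] = ring_xy[:, 0]
    coords[:, :cfg.n_residues_per_ring, 1] = ring_xy[:, 1]
    coords[:, :cfg.n_residues_per_ring, 2] = planes["inner"]
    coords[:, cfg.n_residues_per_ring:n_prot, 0] = ring_xy[:, 0]
    coords[:, cfg.n_residues_per_ring:n_prot, 1] = ring_xy[:, 1]
    coords[:, cfg.n_residues_per_ring:n_prot, 2] = planes["outer"]

    # per lipid bead: owner index, x-offset, z-offset (signed toward midplane)
    owners, xoffs, zoffs = [], [], []
    for li, mtype in enumerate(lipid_types):
        sign = 1.0 if lipid_leaflet_list[li] == "inner" else -1.0
        for _, ox, oz, _ in _LIPID_OFFSETS[mtype]:
            owners.append(li)
            xoffs.append(ox)
            zoffs.append(planes[lipid_leaflet_list[li]] + sign * oz)
    owners = np.array(owners)
    xoffs = np.array(xoffs)
    zoffs = np.array(zoffs)
    lipid_beads = np.s_[n_prot:n_beads]
    coords[:, lipid_beads, 0] = xy_hist[:, owners, 0] + xoffs
    coords[:, lipid_beads, 1] = xy_hist[:, owners, 1]
    coords[:, lipid_beads, 2] = zoffs
    if cfg.flicker_sd > 0:
        coords[:, lipid_beads, :] += rng_noise.normal(
            0.0, cfg.flicker_sd, size=(n_frames, owners.size, 3))
    coords[:, lipid_beads, 0] %= lx
    coords[:, lipid_beads, 1] %= ly

    box = np.tile(np.asarray(cfg.box, dtype=float), (n_frames, 1))
    traj = Trajectory(top, coords, box, dt)
    gt = GroundTruth(
        events=events,
        lipid_leaflet=lipid_leaflet,
        site_residues={s.site_id: tuple(s.residues) for s, _ in sites},
        T=cfg.T,
    )
    return traj, gt


def ground_truth_intervals(gt: GroundTruth, frame_spacing: float,
                           n_frames: int | None = None,
                           site_ids=None) -> dict:
    """Discretise ground-truth bind/unbind events to the frame grid.

    Continuous event times are mapped to frames by round-half-up on
    time/frame_spacing; censored flags mark intervals touching the
    trajectory boundaries. Returns ``{lipid_id: InteractionIntervalSet}``
    covering every lipid that has at least one (selected) event.
    """
    if frame_spacing <= 0:
        raise ParameterError("frame_spacing must be > 0")
    if n_frames is None:
        n_frames = int(math.floor(gt.T / frame_spacing + 1e-9)) + 1
    per_lipid = {}
    for ev in gt.events:
        if site_ids is not None and ev.site_id not in site_ids:
            continue
        per_lipid.setdefault(ev.lipid_id, []).append(ev)
    out = {}
    for lipid_id, evs in sorted(per_lipid.items()):
        raw = []
        for ev in sorted(evs, key=lambda e: e.bind_time):
            start = int(math.floor(ev.bind_time / frame_spacing + 0.5))
            end = int(math.floor(ev.unbind_time / frame_spacing + 0.5))
            start = max(start, 0)
            end = min(end, n_frames - 1)
            if end < start:
                continue
            cl = ev.bind_time <= 0.0
            cr = ev.censored or end >= n_frames - 1
            if raw and start <= raw[-1][1]:  # merge post-discretisation overlap
                prev = raw[-1]
                raw[-1] = (prev[0], max(prev[1], end), prev[2], prev[3] or cr)
            else:
                raw.append((start, end, cl, cr))
        intervals = [
            Interval(s, e, (e - s + 1) * frame_spacing, cl, cr)
            for s, e, cl, cr in raw
        ]
        if intervals:
            out[lipid_id] = InteractionIntervalSet(lipid_id, intervals,
                                                   frame_spacing, n_frames)
    return out
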