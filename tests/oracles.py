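"""Independent brute-force oracles used to validate the implementation.

These deliberately use the dumbest possible enumeration strategies and share
no code with the library paths they check.
"""

import itertools

import numpy as np


def min_image_distance_oracle(a, b, box):
    """Minimum-image distance by trying all 27 periodic shifts."""
    best = np.inf
    for sx, sy, sz in itertools.product((-1, 0, 1), repeat=3):
        shift = np.array([sx * box[0], sy * box[1], sz * box[2]])
        d = np.linalg.norm(np.asarray(a) - (np.asarray(b) + shift))
        best = min(best, d)
    return best


def sigma_oracle(interval_sets, T, dt):
    """Survival correlation by exhaustive enumeration of (nu, t) windows.

    ``interval_sets``: per lipid, list of continuous (start, end) pairs.
    Returns (lags, sigma) with sigma normalised by sigma(0).
    """
    lags = np.arange(0.0, T - 1e-9, dt)
    nus = np.arange(0.0, T + 1e-9, dt)
    active = [s for s in interval_sets]
    raw = np.zeros(lags.size)
    n_possible = np.zeros(lags.size)
    for k, t in enumerate(lags):
        for nu in nus:
            if nu + t > T + 1e-9:
                continue
            n_possible[k] += 1
            for ivs in active:
                for (a, b) in ivs:
                    if a - 1e-9 <= nu and nu + t <= min(b, T) + 1e-9:
                        raw[k] += 1
                        break
    n_lipids = sum(1 for ivs in active
                   if any(_covers_any_nu(ivs, nus, T) for _ in [0]))
    sigma_u = raw / (max(n_lipids, 1) * n_possible)
    return lags, sigma_u / sigma_u[0]


def _covers_any_nu(ivs, nus, T):
    return any(a - 1e-9 <= nu <= min(b, T) + 1e-9
               for (a, b) in ivs for nu in nus)


def dmatrix_oracle(contact_sets, residues):
    """Pair-coincidence matrix by naive event counting.

    ``contact_sets``: iterable of residue sets, one per (frame, cardiolipin)
    pair with any contact. Returns (d, pair_counts, n_int).
    """
    residues = list(residues)
    pos = {r: i for i, r in enumerate(residues)}
    n = len(residues)
    pair_counts = np.zeros((n, n), dtype=int)
    n_int = 0
    for s in contact_sets:
        s = sorted(s)
        n_int += len(s)
        for ri in s:
            for rj in s:
                pair_counts[pos[ri], pos[rj]] += 1
    d = np.ones((n, n)) if n_int == 0 else 1.0 - pair_counts / n_int
    return d, pair_counts, n_int


def contact_sets_oracle(coords, box, phos_idx_by_cdl, beads_by_residue,
                        cutoff):
    """Per-frame, per-cardiolipin residue contact sets by brute force."""
    out = {}
    n_frames = coords.shape[0]
    for f in range(n_frames):
        for cdl, phos in phos_idx_by_cdl.items():
            hit = set()
            for res, beads in beads_by_residue.items():
                found = False
                for p in phos:
                    for bidx in beads:
                        if min_image_distance_oracle(
                                coords[f, p], coords[f, bidx],
                                box[f]) <= cutoff:
                            found = True
                            break
                    if found:
                        break
                if found:
                    hit.add(res)
            if hit:
                out[(f, cdl)] = hit
    return out
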