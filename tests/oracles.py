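"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by brute force or closed form, never
through the code path it checks.
"""

import itertools

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def grid_search_rmsd(moving: np.ndarray, fixed: np.ndarray,
                     coarse_step_deg: float = 15.0) -> float:
    """Minimum RMSD over rigid motions by Euler-angle grid + local refinement.

    Independent of the Kabsch implementation: translations are handled by
    centering, rotations by exhaustive coarse search refined with Nelder-Mead.
    """
    moving = np.asarray(moving, float) - np.asarray(moving, float).mean(axis=0)
    fixed = np.asarray(fixed, float) - np.asarray(fixed, float).mean(axis=0)

    def rmsd_of(angles):
        rot = Rotation.from_euler("zyx", angles, degrees=True)
        return np.sqrt(((rot.apply(moving) - fixed) ** 2).sum(axis=1).mean())

    grid = np.arange(-180.0, 180.0, coarse_step_deg)
    mid = grid[(grid >= -90.0) & (grid <= 90.0)]
    best_angles, best = None, np.inf
    for angles in itertools.product(grid, mid, grid):
        r = rmsd_of(angles)
        if r < best:
            best, best_angles = r, angles
    res = minimize(rmsd_of, best_angles, method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 4000})
    return float(min(best, res.fun))


def greedy_disulfide_matching(sg_positions: dict, cutoff: float) -> set:
    """Brute-force closest-partner-wins matching over all CYS pairs.

    ``sg_positions`` maps residue key -> Sγ coordinate.
    """
    keys = sorted(sg_positions)
    dists = []
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            d = float(np.linalg.norm(sg_positions[a] - sg_positions[b]))
            if d <= cutoff:
                dists.append((d, a, b))
    dists.sort()
    used, pairs = set(), set()
    for _, a, b in dists:
        if a in used or b in used:
            continue
        used.update((a, b))
        pairs.add(frozenset((a, b)))
    return pairs


def geometric_mean_score(features: dict, library) -> float:
    """Direct re-evaluation of the geometric probability formula."""
    factors = []
    for name, value in features.items():
        hist = library.feature_histograms[name]
        d = hist.density_at(value)
        if d == 0.0:
            return 0.0
        factors.append(d / hist.max_density)
    return float(np.prod(factors) ** (1.0 / len(factors)))
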