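"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: superposition via
Horn's quaternion eigen-decomposition, RMSD via a rotation-grid search with
local refinement, and template matching via exhaustive enumeration of all
residue tuples and symmetric atom mappings.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def quaternion_superpose(mobile: np.ndarray, target: np.ndarray):
    """Horn's closed-form quaternion solution for the optimal rigid fit."""
    P = np.asarray(mobile, float)
    Q = np.asarray(target, float)
    n = len(P)
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    S = Pc.T @ Qc  # S[a, b] = sum_i Pc[i, a] * Qc[i, b]
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    evals, evecs = np.linalg.eigh(K)
    lam = evals[-1]
    q = evecs[:, -1]  # (w, x, y, z)
    R = Rotation.from_quat([q[1], q[2], q[3], q[0]]).as_matrix()
    del lam  # the eigenvalue identity loses precision near zero residual
    rmsd = float(np.sqrt(np.mean(np.sum((Pc @ R.T - Qc) ** 2, axis=1))))
    return R, rmsd


def grid_refine_rmsd(a: np.ndarray, b: np.ndarray, grid_step_deg: float = 30.0) -> float:
    """Minimum RMSD by brute rotation-grid search plus local refinement."""
    A = np.asarray(a, float)
    B = np.asarray(b, float)
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)

    def cost(euler):
        R = Rotation.from_euler("zyx", euler).as_matrix()
        return float(np.sqrt(np.mean(np.sum((Ac @ R.T - Bc) ** 2, axis=1))))

    grid = np.arange(0.0, 2 * np.pi, np.radians(grid_step_deg))
    best = np.inf
    best_euler = None
    for e in itertools.product(grid, repeat=3):
        c = cost(e)
        if c < best:
            best, best_euler = c, e
    res = minimize(cost, best_euler, method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000})
    return min(best, float(res.fun))


def brute_force_matches(template, structure, delta: float, rho: float):
    """All template occurrences by exhaustive enumeration.

    Enumerates every assignment of groups to distinct residues whose types
    the template accepts, every injective symmetric atom mapping, checks the
    full pairwise distance constraint, fits, and keeps hits with RMSD <= rho
    -- deduplicated per unordered residue set to the lowest RMSD.
    """
    n_groups = template.n_groups
    group_idxs = [template.group_atom_indices(g) for g in range(n_groups)]
    dmat = template.dmat
    tcoords = template.coords

    per_group = []
    for g in range(n_groups):
        opts = []
        for res in structure.residues():
            pools = []
            ok = True
            for i in group_idxs[g]:
                names = template.atoms[i].allowed_names(res.restype)
                pool = [res.atom(nm) for nm in names if res.has_atom(nm)]
                if not pool:
                    ok = False
                    break
                pools.append(pool)
            if not ok:
                continue
            for combo in itertools.product(*pools):
                if len({a.name for a in combo}) == len(combo):
                    opts.append((res, combo))
        per_group.append(opts)

    results = {}
    for choice in itertools.product(*per_group):
        residues = [res for res, _ in choice]
        if len({r.id for r in residues}) != n_groups:
            continue
        coords = np.empty((len(template.atoms), 3))
        for g, (_, combo) in enumerate(choice):
            for i, atom in zip(group_idxs[g], combo):
                coords[i] = atom.xyz
        d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        if np.any(np.abs(d - dmat) > delta + 1e-12):
            continue
        _, rmsd = quaternion_superpose(tcoords, coords)
        if rmsd > rho:
            continue
        key = frozenset(r.id for r in residues)
        if key not in results or rmsd < results[key][0]:
            results[key] = (rmsd, tuple(r.id for r in residues))
    return results
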