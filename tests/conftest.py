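"""Shared fixtures and independent test oracles.

The oracles here deliberately avoid the code paths they are used to check:
the quaternion-grid superposition oracle never touches the SVD solver, and
the exhaustive-subset GDT oracle enumerates every subset superposition
instead of running the fragment-seeded search.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from confdiv.structure_io import CalphaStructure, build_correspondence
from confdiv.metrics import GDT_THRESHOLDS, kabsch_superpose, tm_d0


def make_structure(
    coords,
    nums=None,
    sid="fix",
    chain="A",
    model_number=1,
    amino_acids=(),
) -> CalphaStructure:
    coords = np.asarray(coords, dtype=float)
    if nums is None:
        nums = np.arange(1, len(coords) + 1)
    return CalphaStructure(
        structure_id=sid,
        model_number=model_number,
        chain_id=chain,
        res_nums=np.asarray(nums),
        coords=coords,
        amino_acids=tuple(amino_acids),
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation from a normalised quaternion."""
    q = rng.normal(size=4)
    w, x, y, z = q / np.linalg.norm(q)
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def rmsd_for_rotation(P: np.ndarray, Q: np.ndarray, R: np.ndarray) -> float:
    """RMSD under a fixed rotation with the translation optimised out
    (centroid alignment), used by the quaternion-grid oracle."""
    Pr = P @ R.T
    diff = (Pr - Pr.mean(axis=0)) - (Q - Q.mean(axis=0))
    return float(np.sqrt((diff**2).sum() / len(P)))


def quaternion_grid_rmsd(
    P: np.ndarray, Q: np.ndarray, seed: int = 0, coarse: int = 3000,
    stages: int = 6, per_stage: int = 2000,
) -> float:
    """Brute-force minimum RMSD over a staged random quaternion grid.

    Stage one samples rotations uniformly; later stages resample in a
    shrinking neighbourhood of the incumbent.  Entirely independent of the
    SVD-based solver.
    """
    rng = np.random.default_rng(seed)
    best_q, best = None, np.inf
    quats = rng.normal(size=(coarse, 4))
    quats /= np.linalg.norm(quats, axis=1, keepdims=True)
    for q in quats:
        w, x, y, z = q
        R = np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ]
        )
        r = rmsd_for_rotation(P, Q, R)
        if r < best:
            best, best_q = r, q
    scale = 0.3
    for _ in range(stages):
        pert = best_q + scale * rng.normal(size=(per_stage, 4))
        pert /= np.linalg.norm(pert, axis=1, keepdims=True)
        for q in pert:
            w, x, y, z = q
            R = np.array(
                [
                    [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                    [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                    [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
                ]
            )
            r = rmsd_for_rotation(P, Q, R)
            if r < best:
                best, best_q = r, q
        scale *= 0.25
    return best


def exhaustive_gdt(model: CalphaStructure, reference: CalphaStructure) -> float:
    """GDT_TS by enumerating the superposition of every aligned subset of
    size >= 3 and counting residues under each threshold; feasible only for
    small structures."""
    corr = build_correspondence(model, reference)
    P = model.coords[corr.model_indices]
    Q = reference.coords[corr.reference_indices]
    n = len(P)
    dists = []
    for k in range(3, n + 1):
        for subset in combinations(range(n), k):
            idx = list(subset)
            R, t, _ = kabsch_superpose(P[idx], Q[idx])
            dists.append(np.linalg.norm(P @ R.T + t - Q, axis=1))
    dists = np.asarray(dists)
    fracs = [
        (dists <= thr).sum(axis=1).max() / corr.n_reference
        for thr in GDT_THRESHOLDS
    ]
    return float(np.mean(fracs))


def tm_restart_oracle(
    P: np.ndarray, Q: np.ndarray, n_reference: int, seed: int = 1,
    restarts: int = 40,
) -> float:
    """Best TM-score found by dense Nelder-Mead restarts from random rigid
    transforms; independent of the fragment-seeded search and of the
    analytic-gradient refinement."""
    from scipy.optimize import minimize

    rng = np.random.default_rng(seed)
    d0 = tm_d0(n_reference)

    def rotvec_matrix(v):
        theta = np.linalg.norm(v)
        if theta < 1e-12:
            return np.eye(3)
        k = v / theta
        K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)

    def neg(x):
        R = rotvec_matrix(x[:3])
        d2 = ((P @ R.T + x[3:] - Q) ** 2).sum(axis=1)
        return -float((1.0 / (1.0 + d2 / d0**2)).sum())

    best = np.inf
    for _ in range(restarts):
        v = rng.normal(size=3)
        v = v / np.linalg.norm(v) * rng.uniform(0, np.pi)
        t0 = Q.mean(axis=0) - rotvec_matrix(v) @ P.mean(axis=0)
        res = minimize(
            neg, np.concatenate([v, t0]), method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-12},
        )
        best = min(best, res.fun)
    return -best / n_reference


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160509)
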