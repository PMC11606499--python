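"""Shell geometry: capsomere planes, inter-capsomere angles, RMSD, diameter.

Adjacent capsomeres are compared through their fitted mean planes.  The
vertical bend between two capsomeres (the alpha angle) is the angle
between their outward plane normals.  The horizontal twist (the beta
angle) is the residual in-plane rotation left after the bend is removed:
capsomere B's subunit directions are rotated onto A's plane about the
axis ``n_A x n_B`` and compared with A's subunit directions modulo the
capsomere's rotational symmetry.  On an ideal faceted lattice whose
capsomeres follow the hexagonal lattice directions, beta is exactly
zero for every interface, while alpha concentrates at facet edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structio import Capsomere

__all__ = [
    "FittedPlane",
    "InterfaceAngles",
    "fit_plane",
    "interface_angles",
    "superpose_rmsd",
    "measure_diameter",
    "capsomere_adjacency",
    "angle_survey",
]


class GeometryError(ValueError):
    pass


@dataclass
class FittedPlane:
    point: np.ndarray
    normal: np.ndarray   # unit; outward from shell centroid when supplied
    rms_residual: float


def fit_plane(points: np.ndarray,
              shell_centroid: np.ndarray | None = None) -> FittedPlane:
    """Least-squares plane through ``points`` (smallest principal axis).

    With ``shell_centroid`` given, the normal is oriented away from it
    (outward for a point on a closed shell).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise GeometryError("plane fitting needs >= 3 points in 3D")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1e-300):
        raise GeometryError("points are collinear; plane is undefined")
    normal = vt[2]
    if shell_centroid is not None:
        if np.dot(normal, centroid - np.asarray(shell_centroid)) < 0:
            normal = -normal
    rms = math.sqrt(float(np.mean((centered @ normal) ** 2)))
    return FittedPlane(point=centroid, normal=normal, rms_residual=rms)


@dataclass
class InterfaceAngles:
    alpha: float   # degrees, vertical bend between fitted planes, [0, 90]
    beta: float    # degrees, residual in-plane twist in the symmetry domain


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    c = float(np.dot(u, v))
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        return np.eye(3) if c > 0 else -np.eye(3) + 2 * np.outer(u, u)
    axis = axis / s
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    e1 = np.cross(normal, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(normal, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(normal, e1)


def _symmetry_phase(dirs: np.ndarray, fold: int,
                    e1: np.ndarray, e2: np.ndarray) -> float:
    """Mean angular phase of an n-fold direction set, in radians.

    The n-fold circular mean is invariant under relabelling of the
    directions and defined modulo ``2*pi/fold``.
    """
    z = 0j
    for d in dirs:
        theta = math.atan2(float(np.dot(d, e2)), float(np.dot(d, e1)))
        z += complex(math.cos(fold * theta), math.sin(fold * theta))
    if abs(z) < 1e-9:
        raise GeometryError("direction set has no well-defined phase")
    return math.atan2(z.imag, z.real) / fold


def _fold_angle(delta: float, period: float) -> float:
    """Fold an angle difference into (-period/2, period/2]."""
    delta = (delta + period / 2.0) % period - period / 2.0
    if delta == -period / 2.0:
        delta = period / 2.0
    return delta


def _vertex_directions(cap: Capsomere, normal: np.ndarray) -> np.ndarray:
    dirs = cap.subunit_centroids - cap.centroid
    dirs = dirs - np.outer(dirs @ normal, normal)
    norms = np.linalg.norm(dirs, axis=1)
    if np.any(norms < 1e-9):
        raise GeometryError("degenerate subunit geometry")
    return dirs / norms[:, None]


def pair_angles(nA: np.ndarray, dirsA: np.ndarray, foldA: int,
                nB: np.ndarray, dirsB: np.ndarray, foldB: int,
                centerA: np.ndarray, centerB: np.ndarray) -> InterfaceAngles:
    """Alpha/beta between two oriented capsomere frames.

    For capsomeres of equal symmetry order the twist is measured by
    mapping B's in-plane direction set onto A's plane (rotation about
    ``n_A x n_B``) and taking the phase difference modulo ``360/fold``.
    For mixed pentamer-hexamer pairs the two symmetry orders share no
    common period, so each capsomere's twist is taken relative to the
    projected interface direction and the difference reported.
    """
    # atan2 form keeps full precision for near-parallel normals
    alpha = math.degrees(math.atan2(float(np.linalg.norm(np.cross(nA, nB))),
                                    float(np.dot(nA, nB))))
    if alpha > 90.0:
        alpha = 180.0 - alpha

    if foldA == foldB:
        R = _rotation_between(nB, nA)
        mapped = dirsB @ R.T
        e1, e2 = _plane_basis(nA)
        period = 2.0 * math.pi / foldA
        delta = _fold_angle(_symmetry_phase(mapped, foldA, e1, e2)
                            - _symmetry_phase(dirsA, foldA, e1, e2), period)
        beta = abs(math.degrees(delta))
    else:
        beta_parts = []
        for n, dirs, fold, here, there in (
                (nA, dirsA, foldA, centerA, centerB),
                (nB, dirsB, foldB, centerB, centerA)):
            d = there - here
            d = d - np.dot(d, n) * n
            nd = np.linalg.norm(d)
            if nd < 1e-9:
                raise GeometryError("capsomere centres coincide in projection")
            d /= nd
            e1, e2 = _plane_basis(n)
            ref = math.atan2(float(np.dot(d, e2)), float(np.dot(d, e1)))
            phase = _symmetry_phase(dirs, fold, e1, e2)
            beta_parts.append(_fold_angle(phase - ref, 2.0 * math.pi / fold))
        beta = abs(math.degrees(beta_parts[0] - beta_parts[1]))
    return InterfaceAngles(alpha=alpha, beta=beta)


def interface_angles(capA: Capsomere, capB: Capsomere,
                     shell_centroid: np.ndarray | None = None,
                     max_distance: float | None = None) -> InterfaceAngles:
    """Bend (alpha) and twist (beta) between two adjacent capsomeres."""
    if capA.kind == "unknown" or capB.kind == "unknown":
        raise GeometryError("cannot measure angles for unknown capsomeres")
    dist = float(np.linalg.norm(capA.centroid - capB.centroid))
    if max_distance is None:
        rA = float(np.linalg.norm(capA.points - capA.centroid, axis=1).max())
        rB = float(np.linalg.norm(capB.points - capB.centroid, axis=1).max())
        max_distance = 1.5 * (rA + rB)
    if dist > max_distance:
        raise GeometryError(
            f"capsomeres are {dist:.1f} A apart (> {max_distance:.1f} A): not adjacent")
    if shell_centroid is None:
        shell_centroid = 0.5 * (capA.centroid + capB.centroid) - 1e3 * (
            np.cross(capA.subunit_centroids[0] - capA.centroid,
                     capA.subunit_centroids[1] - capA.centroid))
        # fallback orientation; callers on closed shells should supply it
    pA = fit_plane(capA.points, shell_centroid)
    pB = fit_plane(capB.points, shell_centroid)
    return pair_angles(pA.normal, _vertex_directions(capA, pA.normal),
                       capA.subunit_count,
                       pB.normal, _vertex_directions(capB, pB.normal),
                       capB.subunit_count,
                       capA.centroid, capB.centroid)


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def _kabsch_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """RMSD after optimal proper-rotation superposition of P onto Q."""
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    S[-1] *= d
    msd = max(0.0, (np.sum(Pc ** 2) + np.sum(Qc ** 2) - 2.0 * np.sum(S)) / len(P))
    return math.sqrt(msd)


def _cyclic_point_sets(cap: Capsomere) -> list[np.ndarray]:
    """Subunit point blocks ordered by azimuth around the fitted normal."""
    plane = fit_plane(cap.points)
    e1, e2 = _plane_basis(plane.normal)
    order = sorted(
        range(cap.subunit_count),
        key=lambda i: math.atan2(
            float(np.dot(cap.subunit_centroids[i] - cap.centroid, e2)),
            float(np.dot(cap.subunit_centroids[i] - cap.centroid, e1))),
    )
    return [cap.subunit_points[i] for i in order]


def superpose_rmsd(capA: Capsomere, capB: Capsomere) -> float:
    """Least-squares rigid RMSD between two capsomeres.

    The subunit correspondence is searched over the capsomere's cyclic
    symmetry (5 or 6 rotations; no reflections, proteins are chiral)
    and the minimum RMSD returned.
    """
    if capA.subunit_count != capB.subunit_count:
        raise GeometryError("capsomeres have different subunit counts")
    blocksA = _cyclic_point_sets(capA)
    blocksB = _cyclic_point_sets(capB)
    sizes = [len(b) for b in blocksA]
    if sizes != [len(b) for b in blocksB]:
        raise GeometryError("subunits have mismatched point counts")
    P = np.vstack(blocksA)
    n = capA.subunit_count
    best = math.inf
    # the fitted normal's sign is arbitrary, so the azimuthal traversal of B
    # may be reversed relative to A; both traversals are tried (superposition
    # itself remains proper-rotation only)
    for ordering in (blocksB, blocksB[::-1]):
        for shift in range(n):
            Q = np.vstack(ordering[shift:] + ordering[:shift])
            if len(Q) != len(P):
                raise GeometryError("subunits have mismatched point counts")
            best = min(best, _kabsch_rmsd(P, Q))
    return best


# ---------------------------------------------------------------------------
# diameter
# ---------------------------------------------------------------------------

def measure_diameter(centroids: np.ndarray, mode: str = "diagonal_average",
                     seed: int = 0) -> float:
    """Shell diameter from capsomere centroids.

    ``diagonal_average`` emulates measuring a particle image by drawing
    three diagonals through the centre at 60-degree steps (in a seeded
    random projection plane) and averaging the extents.  ``circumsphere``
    and ``insphere`` are twice the maximal/minimal centroid radius.
    """
    pts = np.asarray(centroids, dtype=float)
    if len(pts) < 12:
        raise GeometryError("diameter needs >= 12 centroids")
    center = pts.mean(axis=0)
    radii = np.linalg.norm(pts - center, axis=1)
    if mode == "circumsphere":
        return 2.0 * float(radii.max())
    if mode == "insphere":
        return 2.0 * float(radii.min())
    if mode != "diagonal_average":
        raise ValueError(f"unknown diameter mode {mode!r}")
    rng = np.random.default_rng(seed)
    # random orthonormal pair (u, v) spanning the projection plane
    m = rng.standard_normal((3, 3))
    q, _ = np.linalg.qr(m)
    u, v = q[:, 0], q[:, 1]
    theta0 = rng.uniform(0.0, 2.0 * math.pi)
    rel = pts - center
    extents = []
    for j in range(3):
        theta = theta0 + j * math.pi / 3.0
        d = math.cos(theta) * u + math.sin(theta) * v
        proj = rel @ d
        extents.append(float(proj.max() - proj.min()))
    return float(np.mean(extents))


# ---------------------------------------------------------------------------
# surveys over a segmented shell
# ---------------------------------------------------------------------------

def capsomere_adjacency(caps: list[Capsomere],
                        factor: float = 1.2) -> set[tuple[int, int]]:
    """Adjacent capsomere pairs: centre distance within ``factor`` times
    the median nearest-neighbour spacing."""
    centroids = np.array([c.centroid for c in caps])
    tree = cKDTree(centroids)
    dist, _ = tree.query(centroids, k=2)
    spacing = float(np.median(dist[:, 1]))
    pairs = tree.query_pairs(r=factor * spacing)
    return {tuple(sorted(p)) for p in pairs}


def angle_survey(caps: list[Capsomere],
                 classes: list,
                 shell_centroid: np.ndarray | None = None) -> pd.DataFrame:
    """Per-interface-class alpha/beta statistics.

    ``classes`` follows the lattice module's interface-class ordering
    (pentamer-hexamer before hexamer-hexamer, then descending orbit
    size); edges index into ``caps``.
    """
    if shell_centroid is None:
        shell_centroid = np.mean([c.centroid for c in caps], axis=0)
    rows = []
    for cls in classes:
        alphas, betas = [], []
        for a, b in sorted(cls.edges):
            ia = interface_angles(caps[a], caps[b], shell_centroid)
            alphas.append(ia.alpha)
            betas.append(ia.beta)
        rows.append({
            "class": cls.label,
            "kind": cls.kind,
            "n_edges": len(cls.edges),
            "alpha_mean": float(np.mean(alphas)),
            "alpha_min": float(np.min(alphas)),
            "alpha_max": float(np.max(alphas)),
            "beta_mean": float(np.mean(betas)),
            "beta_min": float(np.min(betas)),
            "beta_max": float(np.max(betas)),
        })
    return pd.DataFrame(rows)
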