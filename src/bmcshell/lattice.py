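"""Caspar-Klug icosahedral and prolate shell lattices.

A closed bacterial-microcompartment (or virus capsid) shell built from
hexameric and pentameric capsomeres is described by the Caspar-Klug
triangulation number ``T = h^2 + hk + k^2``, where ``(h, k)`` count the
two lattice steps separating adjacent pentamers on the underlying
hexagonal lattice.  An icosahedral shell then carries exactly 12
pentamers and ``10(T - 1)`` hexamers.  Five-fold elongated (prolate)
shells add an equatorial tube of facets characterised by the elongation
number ``Q = hh' + hk' + kk'`` and carry ``10(T - 1) + 5(Q - T)``
hexamers.

This module constructs the faceted polyhedral embedding of such
lattices (flat triangular faces folded from a single hexagonal sheet),
derives the rigid symmetry group directly from the pentamer positions,
and partitions the capsomere-capsomere contact edges into
symmetry-equivalence classes ("interfaces").
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, cKDTree

__all__ = [
    "LatticeParams",
    "ShellClass",
    "Composition",
    "Site",
    "ShellLattice",
    "InterfaceClass",
    "AsymmetricUnit",
    "triangulation_number",
    "elongation_number",
    "shell_class",
    "predict_composition",
    "build_lattice",
    "classify_interfaces",
    "classify_edges",
    "asymmetric_unit",
    "detect_point_symmetry",
]

_SQRT3 = math.sqrt(3.0)

#: Neighbouring capsomeres are closer than 1.2x the lattice spacing on the
#: faceted embedding; second neighbours stay above ~1.6x even across folds.
ADJACENCY_FACTOR = 1.2


class LatticeError(ValueError):
    """Invalid lattice parameters or an inconsistent lattice."""


# ---------------------------------------------------------------------------
# parameters and closed-form stoichiometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LatticeParams:
    """Caspar-Klug indices ``(h, k)`` and optional elongation ``(h', k')``."""

    h: int
    k: int
    h_prime: int | None = None
    k_prime: int | None = None

    def __post_init__(self) -> None:
        for name in ("h", "k"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise LatticeError(f"{name} must be a non-negative integer, got {v!r}")
        if self.h + self.k < 1:
            raise LatticeError("h = k = 0 describes no lattice")
        primes = (self.h_prime, self.k_prime)
        if (primes[0] is None) != (primes[1] is None):
            raise LatticeError("h' and k' must be given together")
        if self.is_prolate:
            for name in ("h_prime", "k_prime"):
                v = getattr(self, name)
                if not isinstance(v, (int, np.integer)) or v < 0:
                    raise LatticeError(f"{name} must be a non-negative integer, got {v!r}")
            if elongation_number(self) < triangulation_number(self):
                raise LatticeError(
                    f"Q = {elongation_number(self)} < T = {triangulation_number(self)}: "
                    "an oblate body is not supported by this construction"
                )

    @property
    def is_prolate(self) -> bool:
        return self.h_prime is not None

    @property
    def is_chiral(self) -> bool:
        """A lattice with ``h = 0``, ``k = 0`` or ``h = k`` is achiral
        (mirror symmetric); all other index pairs are chiral."""
        return not (self.h == 0 or self.k == 0 or self.h == self.k)

    def mirrored(self) -> "LatticeParams":
        """Swap ``(h, k) -> (k, h)`` (and primes), the mirror-image lattice."""
        return LatticeParams(self.k, self.h, self.k_prime, self.h_prime)


@dataclass(frozen=True)
class ShellClass:
    """Shell geometry class: triangulation number and optional elongation."""

    T: int
    Q: int | None = None

    @property
    def is_prolate(self) -> bool:
        return self.Q is not None and self.Q > self.T


@dataclass(frozen=True)
class Composition:
    """Capsomere stoichiometry of one closed shell."""

    n_pentamers: int
    n_hexamers: int
    n_linker_sites: int | None = None

    @property
    def n_capsomeres(self) -> int:
        return self.n_pentamers + self.n_hexamers


def triangulation_number(params: LatticeParams) -> int:
    """``T = h^2 + hk + k^2`` for the icosahedral facet."""
    h, k = params.h, params.k
    return h * h + h * k + k * k


def elongation_number(params: LatticeParams) -> int:
    """``Q = hh' + hk' + kk'`` for the elongated (prolate) facet."""
    if params.h_prime is None or params.k_prime is None:
        raise LatticeError("elongation number requires h' and k'")
    return params.h * params.h_prime + params.h * params.k_prime + params.k * params.k_prime


def shell_class(params: LatticeParams) -> ShellClass:
    T = triangulation_number(params)
    if params.is_prolate:
        return ShellClass(T=T, Q=elongation_number(params))
    return ShellClass(T=T)


def predict_composition(sc: ShellClass, conformers_per_au: int | None = None) -> Composition:
    """Closed-form capsomere counts for a shell class.

    Any closed shell has 12 pentamers.  Icosahedral shells carry
    ``10(T-1)`` hexamers; prolate shells add ``5(Q-T)`` tube hexamers.
    With a per-asymmetric-unit linker multiplicity ``c`` (copies of the
    scaffolding-protein C-terminus resolved per icosahedral asymmetric
    unit), the shell binds ``60 c`` linker chains.
    """
    n_hex = 10 * (sc.T - 1)
    if sc.is_prolate:
        n_hex += 5 * (sc.Q - sc.T)
    n_linker = None if conformers_per_au is None else 60 * conformers_per_au
    return Composition(n_pentamers=12, n_hexamers=n_hex, n_linker_sites=n_linker)


# ---------------------------------------------------------------------------
# lattice sites and the built lattice
# ---------------------------------------------------------------------------

@dataclass
class Site:
    """One capsomere position on the shell surface.

    ``normal`` points outward; ``tangent`` is a unit in-plane reference
    direction aligned with the hexagonal-lattice bond directions of the
    facet the site sits on (half-fold averaged for sites on facet
    edges), so that an ideal capsomere placed with one vertex along
    ``tangent`` has zero residual twist against its neighbours.
    """

    position: np.ndarray
    kind: str  # "pentamer" | "hexamer"
    normal: np.ndarray
    tangent: np.ndarray | None = None


@dataclass
class ShellLattice:
    params: LatticeParams
    edge_spacing: float
    sites: list[Site]
    adjacency: set[tuple[int, int]]
    symmetry_ops: list[np.ndarray] = field(default_factory=list)  # proper rotations
    improper_ops: list[np.ndarray] = field(default_factory=list)
    spherized: bool = False

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.sites])

    @property
    def kinds(self) -> list[str]:
        return [s.kind for s in self.sites]

    def composition(self) -> Composition:
        kinds = self.kinds
        return Composition(
            n_pentamers=kinds.count("pentamer"),
            n_hexamers=kinds.count("hexamer"),
        )

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b in self.adjacency:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ShellLattice":
        """Rigidly transformed copy; symmetry ops are conjugated accordingly.

        Symmetry operations of the transformed lattice act about the
        transformed centre, i.e. ``x -> R S R^T (x - t') + t'`` with
        ``t'`` the image of the original centre; here we keep storing
        the 3x3 parts and let consumers re-centre, so we conjugate.
        """
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        sites = [
            Site(
                position=R @ s.position + t,
                kind=s.kind,
                normal=R @ s.normal,
                tangent=None if s.tangent is None else R @ s.tangent,
            )
            for s in self.sites
        ]
        return ShellLattice(
            params=self.params,
            edge_spacing=self.edge_spacing,
            sites=sites,
            adjacency=set(self.adjacency),
            symmetry_ops=[R @ S @ R.T for S in self.symmetry_ops],
            improper_ops=[R @ S @ R.T for S in self.improper_ops],
            spherized=self.spherized,
        )

    @property
    def center(self) -> np.ndarray:
        """Shell centre: mean pentamer position (exact centre by symmetry)."""
        pent = [s.position for s in self.sites if s.kind == "pentamer"]
        return np.mean(pent, axis=0)

    # -- exports ----------------------------------------------------------
    def to_json(self, classes: list["InterfaceClass"] | None = None) -> str:
        edge_class = {}
        if classes is not None:
            for c in classes:
                for e in c.edges:
                    edge_class[e] = c.label
        data = {
            "params": {
                "h": self.params.h,
                "k": self.params.k,
                "h_prime": self.params.h_prime,
                "k_prime": self.params.k_prime,
            },
            "T": triangulation_number(self.params),
            "Q": elongation_number(self.params) if self.params.is_prolate else None,
            "edge_spacing": self.edge_spacing,
            "sites": [
                {
                    "index": i,
                    "ordinal": i + 1,
                    "kind": s.kind,
                    "position": [round(float(x), 6) for x in s.position],
                    "normal": [round(float(x), 6) for x in s.normal],
                }
                for i, s in enumerate(self.sites)
            ],
            "adjacency": [
                {
                    "sites": [a, b],
                    "ordinals": [a + 1, b + 1],
                    "interface_class": edge_class.get((a, b)),
                }
                for a, b in sorted(self.adjacency)
            ],
        }
        return json.dumps(data, indent=1)

    def to_pseudoatom_pdb(self, classes: list["InterfaceClass"] | None = None) -> str:
        """One HETATM pseudo-atom per site; B-factor = interface-class label
        of the site's lowest-numbered incident edge (0 if unclassified)."""
        site_class = {}
        if classes is not None:
            for c in classes:
                for a, b in sorted(c.edges):
                    site_class.setdefault(a, c.label)
                    site_class.setdefault(b, c.label)
        lines = []
        for i, s in enumerate(self.sites):
            x, y, z = s.position
            name = "PNT" if s.kind == "pentamer" else "HEX"
            lines.append(
                f"HETATM{i + 1:5d}  X   {name} A{(i + 1) % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{float(site_class.get(i, 0)):6.2f}"
                f"           X"
            )
        lines.append("END")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# construction of the faceted embedding
# ---------------------------------------------------------------------------

def _cart(ij: tuple[int, int]) -> np.ndarray:
    """Hexagonal-lattice integer coordinates -> 2D cartesian (unit spacing)."""
    i, j = ij
    return np.array([i + 0.5 * j, (_SQRT3 / 2.0) * j])


def _points_in_triangle(q0, q1, q2):
    """All integer lattice points inside/on the CCW triangle (exact test)."""
    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    assert cross(q0, q1, q2) > 0, "triangle must be counter-clockwise"
    lo_i = min(q0[0], q1[0], q2[0])
    hi_i = max(q0[0], q1[0], q2[0])
    lo_j = min(q0[1], q1[1], q2[1])
    hi_j = max(q0[1], q1[1], q2[1])
    pts = []
    for i in range(lo_i, hi_i + 1):
        for j in range(lo_j, hi_j + 1):
            p = (i, j)
            if cross(q0, q1, p) >= 0 and cross(q1, q2, p) >= 0 and cross(q2, q0, p) >= 0:
                pts.append(p)
    return pts


def _icosahedron_vertices() -> np.ndarray:
    """Regular icosahedron, edge length 2, centred at the origin."""
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    v = []
    for a in (-1.0, 1.0):
        for b in (-phi, phi):
            v.append((0.0, a, b))
            v.append((a, b, 0.0))
            v.append((b, 0.0, a))
    return np.array(v)


def _face_map(corners3d: np.ndarray, chart: list[tuple[int, int]], a: float):
    """Isometric affine map from the 2D chart triangle onto a 3D face.

    Returns ``(origin3d, M)`` with ``M`` a 3x2 matrix of orthonormal
    columns (images of the chart's cartesian basis) so that
    ``x3d = origin3d + M @ (a * (_cart(p) - _cart(chart[0])))``.
    """
    p0, p1, p2 = (_cart(c) for c in chart)
    A2 = np.column_stack([p1 - p0, p2 - p0]) * a
    A3 = np.column_stack([corners3d[1] - corners3d[0], corners3d[2] - corners3d[0]])
    M = A3 @ np.linalg.inv(A2)
    return corners3d[0], M


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Proper rotation taking unit vector u to unit vector v (minimal angle)."""
    c = float(np.dot(u, v))
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any perpendicular axis
        perp = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(u, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return 2.0 * np.outer(perp, perp) - np.eye(3)
    axis = axis / s
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def _assemble(faces: list[tuple[np.ndarray, list[tuple[int, int]]]],
              a: float, params: LatticeParams) -> ShellLattice:
    """Fold chart triangles onto 3D faces and merge shared boundary sites."""
    raw_pos = []
    raw_kind = []
    raw_face = []        # face index per raw point
    face_frames = []     # per face: (M 3x2, outward normal)
    for f_idx, (corners3d, chart) in enumerate(faces):
        origin, M = _face_map(corners3d, chart, a)
        n = np.cross(M[:, 0], M[:, 1])
        n /= np.linalg.norm(n)
        centroid = corners3d.mean(axis=0)
        if np.dot(n, centroid) <= 0:
            raise LatticeError("face oriented inward; inconsistent construction")
        face_frames.append((M, n))
        corner_set = set(chart)
        p0c = _cart(chart[0])
        for ij in _points_in_triangle(*chart):
            raw_pos.append(origin + M @ (a * (_cart(ij) - p0c)))
            raw_kind.append("pentamer" if ij in corner_set else "hexamer")
            raw_face.append(f_idx)

    raw_pos = np.array(raw_pos)
    tol = 1e-6 * a
    tree = cKDTree(raw_pos)
    groups = tree.query_ball_point(raw_pos, r=tol)
    site_of_raw = np.full(len(raw_pos), -1, dtype=int)
    sites: list[Site] = []
    site_faces: list[list[int]] = []
    for i in range(len(raw_pos)):
        if site_of_raw[i] >= 0:
            continue
        members = groups[i]
        idx = len(sites)
        for m in members:
            site_of_raw[m] = idx
        kinds = {raw_kind[m] for m in members}
        if len(kinds) != 1:
            raise LatticeError("inconsistent site kind during merging")
        owning = sorted({raw_face[m] for m in members})
        normal = np.sum([face_frames[f][1] for f in owning], axis=0)
        normal /= np.linalg.norm(normal)
        sites.append(Site(position=raw_pos[members].mean(axis=0),
                          kind=kinds.pop(), normal=normal))
        site_faces.append(owning)

    # adjacency by centre distance on the faceted embedding
    pos = np.array([s.position for s in sites])
    tree = cKDTree(pos)
    pairs = tree.query_pairs(r=ADJACENCY_FACTOR * a)
    adjacency = {tuple(sorted(p)) for p in pairs}

    # degree / Euler consistency
    deg = {i: 0 for i in range(len(sites))}
    for x, y in adjacency:
        deg[x] += 1
        deg[y] += 1
    for i, s in enumerate(sites):
        want = 5 if s.kind == "pentamer" else 6
        if deg[i] != want:
            raise LatticeError(
                f"site {i} ({s.kind}) has degree {deg[i]}, expected {want}; "
                "lattice construction is inconsistent"
            )

    # in-plane tangent reference per site (lattice-aligned, half-fold averaged)
    for i, s in enumerate(sites):
        owning = site_faces[i]
        if len(owning) == 1:
            M, nf = face_frames[owning[0]]
            s.tangent = M[:, 0].copy()
        elif len(owning) == 2:
            M, nf = face_frames[owning[0]]
            R = _rotation_between(nf, s.normal)
            s.tangent = R @ M[:, 0]
        else:
            # vertex site: n-fold circular mean of projected neighbour bonds
            nbrs = [j for j in range(len(sites))
                    if tuple(sorted((i, j))) in adjacency]
            n = s.normal
            e1 = np.cross(n, [1.0, 0.0, 0.0])
            if np.linalg.norm(e1) < 1e-6:
                e1 = np.cross(n, [0.0, 1.0, 0.0])
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(n, e1)
            fold = len(nbrs)
            z = 0.0 + 0.0j
            for j in nbrs:
                d = sites[j].position - s.position
                d = d - np.dot(d, n) * n
                theta = math.atan2(np.dot(d, e2), np.dot(d, e1))
                z += complex(math.cos(fold * theta), math.sin(fold * theta))
            psi = math.atan2(z.imag, z.real) / fold
            s.tangent = math.cos(psi) * e1 + math.sin(psi) * e2

    lattice = ShellLattice(params=params, edge_spacing=a,
                           sites=sites, adjacency=adjacency)
    proper, improper = detect_point_symmetry(pos, [s.kind for s in sites],
                                             adjacency, tol=1e-5 * a)
    lattice.symmetry_ops = proper
    lattice.improper_ops = improper
    return lattice


def _build_icosahedral(params: LatticeParams, a: float) -> ShellLattice:
    h, k = params.h, params.k
    T = triangulation_number(params)
    L = math.sqrt(T) * a
    verts = _icosahedron_vertices() * (L / 2.0)
    hull = ConvexHull(verts)
    chart = [(0, 0), (h, k), (-k, h + k)]
    faces = []
    for simplex in hull.simplices:
        tri = verts[simplex]
        n = np.cross(tri[1] - tri[0], tri[2] - tri[0])
        if np.dot(n, tri.mean(axis=0)) < 0:
            tri = tri[[0, 2, 1]]
        faces.append((tri, chart))
    return _assemble(faces, a, params)


def _build_prolate(params: LatticeParams, a: float) -> ShellLattice:
    h, k = params.h, params.k
    hp, kp = params.h_prime, params.k_prime
    T = triangulation_number(params)
    L_T = math.sqrt(T) * a
    # pentagonal caps are icosahedral caps: ring circumradius and apex height
    R = L_T / (2.0 * math.sin(math.pi / 5.0))
    h_apex = math.sqrt(L_T * L_T - R * R)

    # Ring edge vector P1 and downward elongation vector D on the unrolled
    # tube; D is fixed by requiring the mid-band facet area cross(D, P1) = Q
    # with the outward-CCW corner order (ring1_i, ring2_i, ring1_{i+1}).
    # D and D + m*P1 label the same tube (the ring pairing is shifted by m
    # steps), so the least-skew realisable representative is used.
    P1 = (h, k)
    D0 = (kp, -hp - kp)
    reps = sorted(
        ((D0[0] + m * P1[0], D0[1] + m * P1[1]) for m in range(-4, 5)),
        key=lambda d: np.linalg.norm(_cart(d)),
    )

    candidates = []
    for D in reps:
        d1 = np.linalg.norm(_cart(D)) * a
        d2 = np.linalg.norm(_cart(P1) - _cart(D)) * a
        # ring-to-ring twist phi and axial drop dz solving the two edge lengths
        A = (math.cos(2 * math.pi / 5) - 1.0) * 2 * R * R
        B = math.sin(2 * math.pi / 5) * 2 * R * R
        c = d1 * d1 - d2 * d2
        rho = math.hypot(A, B)
        if abs(c) > rho + 1e-9:
            continue
        base = math.atan2(B, A)
        delta = math.acos(max(-1.0, min(1.0, c / rho)))
        for phi in (base + delta, base - delta):
            dz2 = d1 * d1 - 2 * R * R * (1.0 - math.cos(phi))
            if dz2 > 1e-9:
                candidates.append((phi, math.sqrt(dz2), D))
    if not candidates:
        raise LatticeError(
            f"prolate parameters (h,k)=({h},{k}), (h',k')=({hp},{kp}) are not "
            "realisable as a closed 5-fold tube")

    last_error: Exception | None = None
    for phi, dz, D in candidates:
        try:
            zr = dz / 2.0
            apex_t = np.array([0.0, 0.0, zr + h_apex])
            apex_b = np.array([0.0, 0.0, -zr - h_apex])
            ring1 = np.array([[R * math.cos(2 * math.pi * i / 5),
                               R * math.sin(2 * math.pi * i / 5), zr]
                              for i in range(5)])
            ring2 = np.array([[R * math.cos(2 * math.pi * i / 5 + phi),
                               R * math.sin(2 * math.pi * i / 5 + phi), -zr]
                              for i in range(5)])
            cap_chart = [(0, 0), (h, k), (-k, h + k)]
            up_chart = [(0, 0), D, P1]
            down_chart = [D, (D[0] + P1[0], D[1] + P1[1]), P1]
            faces = []
            for i in range(5):
                j = (i + 1) % 5
                for tri in (np.array([apex_t, ring1[i], ring1[j]]),):
                    n = np.cross(tri[1] - tri[0], tri[2] - tri[0])
                    if np.dot(n, tri.mean(axis=0)) < 0:
                        tri = tri[[0, 2, 1]]
                    faces.append((tri, cap_chart))
                faces.append((np.array([ring1[i], ring2[i], ring1[j]]), up_chart))
                faces.append((np.array([ring2[i], ring2[j], ring1[j]]), down_chart))
                for tri in (np.array([apex_b, ring2[j], ring2[i]]),):
                    n = np.cross(tri[1] - tri[0], tri[2] - tri[0])
                    if np.dot(n, tri.mean(axis=0)) < 0:
                        tri = tri[[0, 2, 1]]
                    faces.append((tri, cap_chart))
            return _assemble(faces, a, params)
        except LatticeError as exc:
            last_error = exc
    raise LatticeError(f"prolate construction failed: {last_error}")


def build_lattice(params: LatticeParams, edge_spacing: float = 1.0,
                  spherize: bool = False) -> ShellLattice:
    """Construct the faceted shell lattice for ``params``.

    The canonical embedding keeps the 20 (or 30, prolate) triangular
    facets flat, so inter-capsomere bend concentrates at facet edges.
    With ``spherize=True`` sites are instead projected radially onto the
    circumscribed sphere (normals become radial).
    """
    if edge_spacing <= 0:
        raise LatticeError("edge_spacing must be positive")
    if params.is_prolate and elongation_number(params) > triangulation_number(params):
        lattice = _build_prolate(params, edge_spacing)
    else:
        lattice = _build_icosahedral(params, edge_spacing)
    if spherize:
        radius = max(np.linalg.norm(s.position) for s in lattice.sites)
        for s in lattice.sites:
            r = np.linalg.norm(s.position)
            s.normal = s.position / r
            s.position = s.normal * radius
            t = s.tangent - np.dot(s.tangent, s.normal) * s.normal
            s.tangent = t / np.linalg.norm(t)
        lattice.spherized = True
    return lattice


# ---------------------------------------------------------------------------
# symmetry detection and interface classification
# ---------------------------------------------------------------------------

def detect_point_symmetry(positions: np.ndarray, kinds: list[str],
                          adjacency: set[tuple[int, int]], tol: float):
    """Find the rigid point group of a capsomere arrangement.

    Candidate orthogonal maps are generated from ordered pairs of
    pentamer positions congruent to a reference pair and kept when they
    permute the full site set (kind-preserving) and the adjacency edge
    set.  Returns ``(proper_ops, improper_ops)`` as 3x3 matrices acting
    about the pentamer centroid.
    """
    positions = np.asarray(positions, dtype=float)
    pent_idx = [i for i, knd in enumerate(kinds) if knd == "pentamer"]
    if len(pent_idx) < 2:
        raise LatticeError("symmetry detection needs at least two pentamers")
    center = positions[pent_idx].mean(axis=0)
    pos = positions - center
    P = pos[pent_idx]

    def frame(p, q, flip=False):
        u1 = p / np.linalg.norm(p)
        w = q - np.dot(q, u1) * u1
        nw = np.linalg.norm(w)
        if nw < 1e-9 * np.linalg.norm(p):
            return None
        u2 = w / nw
        u3 = np.cross(u1, u2)
        if flip:
            u3 = -u3
        return np.column_stack([u1, u2, u3])

    # reference: pentamer 0 and its nearest non-degenerate pentamer
    p0 = P[0]
    order = np.argsort([np.linalg.norm(q - p0) for q in P])
    q0 = None
    for j in order[1:]:
        if frame(p0, P[j]) is not None:
            q0 = P[j]
            break
    if q0 is None:
        raise LatticeError("degenerate pentamer arrangement")
    F0 = frame(p0, q0)
    F0m = frame(p0, q0, flip=True)
    d0 = np.linalg.norm(q0 - p0)
    r_p0, r_q0 = np.linalg.norm(p0), np.linalg.norm(q0)

    tree = cKDTree(pos)
    kinds_arr = np.array(kinds)
    edges = {tuple(sorted(e)) for e in adjacency}

    def valid(U):
        mapped = pos @ U.T
        dist, idx = tree.query(mapped)
        if dist.max() > tol:
            return None
        if len(set(idx.tolist())) != len(pos):
            return None
        if not np.all(kinds_arr[idx] == kinds_arr):
            return None
        mapped_edges = {tuple(sorted((idx[a], idx[b]))) for a, b in edges}
        if mapped_edges != edges:
            raise LatticeError("symmetry op permutes sites but not edges")
        return idx

    proper, improper = [], []
    seen = set()
    rel_tol = max(tol, 1e-6 * d0)
    for i, p in enumerate(P):
        if abs(np.linalg.norm(p) - r_p0) > rel_tol:
            continue
        for j, q in enumerate(P):
            if i == j:
                continue
            if abs(np.linalg.norm(q - p) - d0) > rel_tol:
                continue
            if abs(np.linalg.norm(q) - r_q0) > rel_tol:
                continue
            F = frame(p, q)
            if F is None:
                continue
            for F0x, bucket in ((F0, proper), (F0m, improper)):
                U = F @ F0x.T
                key = tuple(np.round(U, 6).ravel())
                if key in seen:
                    continue
                if valid(U) is not None:
                    seen.add(key)
                    bucket.append(U)
    return proper, improper


@dataclass
class InterfaceClass:
    """A symmetry-equivalence class of capsomere-capsomere contact edges."""

    kind: str                       # "pentamer-hexamer" | "hexamer-hexamer" | ...
    orbit_size: int
    representative_edge: tuple[int, int]
    label: int                      # 1-based ordinal
    edges: set[tuple[int, int]] = field(default_factory=set)


def _edge_orbits(n_sites: int, edges: list[tuple[int, int]],
                 permutations: list[np.ndarray]) -> list[set[tuple[int, int]]]:
    index = {e: i for i, e in enumerate(edges)}
    parent = list(range(len(edges)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    for perm in permutations:
        for e_i, (a, b) in enumerate(edges):
            m = tuple(sorted((int(perm[a]), int(perm[b]))))
            union(e_i, index[m])
    orbits: dict[int, set] = {}
    for e_i, e in enumerate(edges):
        orbits.setdefault(find(e_i), set()).add(e)
    return list(orbits.values())


_KIND_ORDER = {"pentamer-pentamer": 0, "pentamer-hexamer": 1, "hexamer-hexamer": 2}


def classify_edges(positions: np.ndarray, kinds: list[str],
                   adjacency: set[tuple[int, int]],
                   ops: list[np.ndarray], tol: float) -> list[InterfaceClass]:
    """Partition contact edges into orbits under the given point group.

    Works on any capsomere arrangement (built lattice or segmented
    structure); ``ops`` act about the pentamer centroid and must
    permute sites and edges (checked).
    """
    if not ops:
        raise LatticeError("no symmetry operations supplied")
    positions = np.asarray(positions, dtype=float)
    pent = [i for i, knd in enumerate(kinds) if knd == "pentamer"]
    center = positions[pent].mean(axis=0) if pent else positions.mean(axis=0)
    pos = positions - center
    tree = cKDTree(pos)
    perms = []
    edges = sorted(adjacency)
    edge_set = set(edges)
    for U in ops:
        mapped = pos @ U.T
        dist, idx = tree.query(mapped)
        if dist.max() > tol or len(set(idx.tolist())) != len(pos):
            raise LatticeError("symmetry op does not permute the site set")
        mapped_edges = {tuple(sorted((int(idx[a]), int(idx[b])))) for a, b in edge_set}
        if mapped_edges != edge_set:
            raise LatticeError("symmetry op does not permute the edge set")
        perms.append(idx)

    orbits = _edge_orbits(len(positions), edges, perms)
    group_order = len(ops)
    records = []
    for orbit in orbits:
        rep = min(orbit)
        a, b = rep
        knd = "-".join(sorted((kinds[a], kinds[b]),
                              key=lambda s: 0 if s == "pentamer" else 1))
        if group_order % len(orbit) != 0:
            raise LatticeError(
                f"orbit size {len(orbit)} does not divide group order {group_order}")
        records.append((knd, orbit, rep))
    records.sort(key=lambda r: (_KIND_ORDER[r[0]], -len(r[1]), r[2]))
    return [
        InterfaceClass(kind=knd, orbit_size=len(orbit),
                       representative_edge=rep, label=i + 1, edges=orbit)
        for i, (knd, orbit, rep) in enumerate(records)
    ]


def classify_interfaces(lattice: ShellLattice,
                        merge_mirror: bool | None = None) -> list[InterfaceClass]:
    """Partition lattice contact edges into symmetry-equivalence classes.

    ``merge_mirror=None`` (default) merges mirror-related orbits exactly
    when the lattice is achiral (``k = 0`` or ``h = k``), reproducing a
    minimal class count on achiral shells, while chiral shells are
    classified under the rotation group only.
    """
    if merge_mirror is None:
        merge_mirror = not lattice.params.is_chiral
    ops = list(lattice.symmetry_ops)
    if merge_mirror:
        ops = ops + list(lattice.improper_ops)
    return classify_edges(lattice.positions, lattice.kinds, lattice.adjacency,
                          ops, tol=1e-5 * lattice.edge_spacing)


@dataclass
class AsymmetricUnit:
    """Minimal site set whose symmetry orbit covers the whole shell."""

    hexamer_sites: list[int]
    pentamer_sites: list[int]
    hexamer_equivalents: float       # hexamers per asymmetric unit (may be fractional)
    pentamer_subunits: float         # pentamer subunits per asymmetric unit
    group_order: int


def asymmetric_unit(lattice: ShellLattice) -> AsymmetricUnit:
    """Greedy set of orbit representatives under the rotation group.

    For an icosahedral shell (group order 60), the asymmetric unit holds
    ``n_hexamers / 60`` hexamer equivalents and one pentamer subunit
    (12 pentamers x 5 subunits / 60); fractional hexamer occupancy is
    reported as such (e.g. 2.5 for a 150-hexamer shell).
    """
    ops = lattice.symmetry_ops
    if not ops:
        raise LatticeError("lattice has no symmetry operations")
    positions = lattice.positions
    pent = [i for i, knd in enumerate(lattice.kinds) if knd == "pentamer"]
    pos = positions - positions[pent].mean(axis=0)
    tree = cKDTree(pos)
    tol = 1e-5 * lattice.edge_spacing
    perms = []
    for U in ops:
        _, idx = tree.query(pos @ U.T)
        perms.append(idx)
    covered = np.zeros(len(pos), dtype=bool)
    hex_sites, pent_sites = [], []
    for i in range(len(pos)):
        if covered[i]:
            continue
        (hex_sites if lattice.kinds[i] == "hexamer" else pent_sites).append(i)
        for perm in perms:
            covered[perm[i]] = True
    comp = lattice.composition()
    order = len(ops)
    return AsymmetricUnit(
        hexamer_sites=hex_sites,
        pentamer_sites=pent_sites,
        hexamer_equivalents=comp.n_hexamers / order,
        pentamer_subunits=comp.n_pentamers * 5.0 / order,
        group_order=order,
    )
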