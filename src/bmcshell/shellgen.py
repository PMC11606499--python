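"""Synthetic shells and linker sequences with known ground truth.

Every downstream stage (segmentation, interface classification, angle
measurement, motif scanning) is testable without any deposited
structure: this module instantiates idealized shells by placing
pseudo-atomic hexamer/pentamer templates on the faceted lattice, and
emits linker sequences with [IV][TS]G motifs planted at known
positions.  Each artifact comes with a manifest recording the ground
truth, and output is bit-reproducible for a fixed seed.

The default edge spacing of 65 A reproduces the observed diameters of
recombinant alpha-carboxysome shells (a faceted T=9 shell then spans
~37 nm and a T=19 shell ~54 nm, circumsphere).
"""

from __future__ import annotations

import json
import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import lattice as lat
from .geometry import pair_angles
from .structio import AtomRecord, write_structure

__all__ = [
    "CapsomereTemplate",
    "SyntheticShellSpec",
    "SyntheticLinkerSpec",
    "ShellModel",
    "LinkerRecord",
    "make_template",
    "generate_shell",
    "generate_two_capsomere_fixture",
    "generate_linker",
]

#: Default capsomere centre-to-centre spacing, in Angstrom.
DEFAULT_EDGE_SPACING = 65.0

_AMINO = "ACDEFGHIKLMNPQRSTVWY"
_MOTIF_RE = re.compile(r"(?=([IV][TS]G))")


@dataclass(frozen=True)
class CapsomereTemplate:
    """Pseudo-atomic capsomere: n subunits of wedge-shaped point sets.

    Subunit wedges run from near the symmetry axis (where neighbouring
    subunits touch) out to the ring radius, so a single tight distance
    cutoff groups subunits of one capsomere without bridging to the
    next capsomere.  The wedge is chiral (no internal mirror), which
    keeps superposition unambiguous.
    """

    kind: str                      # "pentamer" | "hexamer"
    ring_radius: float
    inner_radius: float
    local_points: np.ndarray       # (n_subunits, points_per_subunit, 3)

    @property
    def n_subunits(self) -> int:
        return 5 if self.kind == "pentamer" else 6

    @property
    def points_per_subunit(self) -> int:
        return self.local_points.shape[1]


def make_template(kind: str, ring_radius: float = 26.0,
                  inner_radius: float = 3.6) -> CapsomereTemplate:
    """Build a flat wedge template with 7 points per subunit."""
    if kind not in ("pentamer", "hexamer"):
        raise ValueError(f"unknown capsomere kind {kind!r}")
    n = 5 if kind == "pentamer" else 6
    r_in, r_out = inner_radius, ring_radius
    r1 = r_in + (r_out - r_in) / 3.0
    r2 = r_in + 2.0 * (r_out - r_in) / 3.0
    w = math.radians(12.0)
    polar = [(r_in, 0.0), (r1, 0.0), (r2, 0.0), (r_out, 0.0),
             (r2, +w), (r2, -w), (0.8 * r_out, +0.5 * w)]
    pts = np.zeros((n, len(polar), 3))
    for j in range(n):
        theta0 = 2.0 * math.pi * j / n
        for p, (r, dth) in enumerate(polar):
            th = theta0 + dth
            pts[j, p] = (r * math.cos(th), r * math.sin(th), 0.0)
    return CapsomereTemplate(kind=kind, ring_radius=ring_radius,
                             inner_radius=inner_radius, local_points=pts)


@dataclass(frozen=True)
class SyntheticShellSpec:
    """Parameters of one synthetic shell (lattice, scale, noise, seed)."""

    h: int
    k: int
    h_prime: int | None = None
    k_prime: int | None = None
    edge_spacing: float = DEFAULT_EDGE_SPACING
    noise_sigma: float = 0.0
    seed: int = 0
    ring_radius_factor: float = 0.40
    inner_radius_factor: float = 0.055

    def lattice_params(self) -> lat.LatticeParams:
        return lat.LatticeParams(self.h, self.k, self.h_prime, self.k_prime)


@dataclass
class ShellModel:
    """A generated shell: atoms, the lattice it came from, and the truth."""

    atoms: list[AtomRecord]
    lattice: lat.ShellLattice
    manifest: dict

    def write(self, path, fmt: str | None = None) -> None:
        write_structure(self.atoms, path, fmt)

    def write_manifest(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)


_CHAIN36 = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"
_CHAIN62 = _CHAIN36[:26] + "abcdefghijklmnopqrstuvwxyz" + _CHAIN36[26:]


def _chain_name(i: int, total: int) -> str:
    if total <= len(_CHAIN62):
        return _CHAIN62[i]
    if total <= len(_CHAIN36) ** 2:
        return _CHAIN36[i // 36] + _CHAIN36[i % 36]
    raise ValueError("too many chains to name")


def _site_frame(site: lat.Site) -> np.ndarray:
    """Orthonormal frame (t1, t2, n) columns for a lattice site."""
    n = site.normal
    t1 = site.tangent - np.dot(site.tangent, n) * n
    t1 /= np.linalg.norm(t1)
    return np.column_stack([t1, np.cross(n, t1), n])


def generate_shell(spec: SyntheticShellSpec) -> ShellModel:
    """Instantiate a pseudo-atomic shell on the faceted lattice.

    One chain per capsomere subunit; residue name ``UNK`` marks the
    pseudo-atomic granularity.  Capsomere subunits point along the
    hexagonal-lattice bond directions of their facet, so every
    interface of the noise-free shell has zero twist by construction.
    The manifest records capsomere membership, kinds, interface classes
    and per-interface true alpha/beta angles.
    """
    a = spec.edge_spacing
    if spec.noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if spec.noise_sigma > 0.25 * a:
        raise ValueError(
            f"noise_sigma {spec.noise_sigma} > 0.25 x edge_spacing: capsomere "
            "adjacency would be ambiguous")
    if spec.noise_sigma > 0.10 * a:
        warnings.warn("noise_sigma above 0.1 x edge_spacing: segmentation "
                      "may be unreliable", stacklevel=2)

    params = spec.lattice_params()
    shell_lattice = lat.build_lattice(params, edge_spacing=a)
    templates = {
        kind: make_template(kind,
                            ring_radius=spec.ring_radius_factor * a,
                            inner_radius=spec.inner_radius_factor * a)
        for kind in ("pentamer", "hexamer")
    }
    n_chains = sum(5 if s.kind == "pentamer" else 6 for s in shell_lattice.sites)
    rng = np.random.default_rng(spec.seed)

    atoms: list[AtomRecord] = []
    cap_entries = []
    chain_counter = 0
    for s_idx, site in enumerate(shell_lattice.sites):
        tmpl = templates[site.kind]
        frame = _site_frame(site)
        chains = []
        for j in range(tmpl.n_subunits):
            cname = _chain_name(chain_counter, n_chains)
            chain_counter += 1
            chains.append(cname)
            world = site.position + tmpl.local_points[j] @ frame.T
            if spec.noise_sigma > 0:
                world = world + rng.normal(0.0, spec.noise_sigma, world.shape)
            for p in range(tmpl.points_per_subunit):
                atoms.append(AtomRecord(
                    chain=cname, resname="UNK", resnum=1,
                    atom=f"C{p + 1}", element="C",
                    position=world[p]))
        cap_entries.append({
            "index": s_idx,
            "kind": site.kind,
            "chains": chains,
            "center": [round(float(x), 6) for x in site.position],
            "normal": [round(float(x), 6) for x in site.normal],
        })

    classes = lat.classify_interfaces(shell_lattice)
    edge_class = {}
    for c in classes:
        for e in c.edges:
            edge_class[e] = c.label
    interfaces = []
    for aa, bb in sorted(shell_lattice.adjacency):
        sA, sB = shell_lattice.sites[aa], shell_lattice.sites[bb]
        fA, fB = _site_frame(sA), _site_frame(sB)
        foldA = 5 if sA.kind == "pentamer" else 6
        foldB = 5 if sB.kind == "pentamer" else 6
        dirsA = np.array([fA @ np.array([math.cos(2 * math.pi * j / foldA),
                                         math.sin(2 * math.pi * j / foldA), 0.0])
                          for j in range(foldA)])
        dirsB = np.array([fB @ np.array([math.cos(2 * math.pi * j / foldB),
                                         math.sin(2 * math.pi * j / foldB), 0.0])
                          for j in range(foldB)])
        ang = pair_angles(sA.normal, dirsA, foldA, sB.normal, dirsB, foldB,
                          sA.position, sB.position)
        interfaces.append({
            "sites": [aa, bb],
            "class": edge_class[(aa, bb)],
            "alpha": round(ang.alpha, 9),
            "beta": round(ang.beta, 9),
        })

    comp = shell_lattice.composition()
    manifest = {
        "seed": spec.seed,
        "params": {"h": spec.h, "k": spec.k,
                   "h_prime": spec.h_prime, "k_prime": spec.k_prime},
        "T": lat.triangulation_number(params),
        "Q": lat.elongation_number(params) if params.is_prolate else None,
        "edge_spacing": a,
        "noise_sigma": spec.noise_sigma,
        "composition": {"n_pentamers": comp.n_pentamers,
                        "n_hexamers": comp.n_hexamers},
        "capsomeres": cap_entries,
        "interfaces": interfaces,
        "classes": [{"label": c.label, "kind": c.kind,
                     "orbit_size": c.orbit_size} for c in classes],
    }
    return ShellModel(atoms=atoms, lattice=shell_lattice, manifest=manifest)


def generate_two_capsomere_fixture(alpha: float, beta: float = 0.0,
                                   kind_a: str = "hexamer",
                                   kind_b: str = "hexamer",
                                   spacing: float = DEFAULT_EDGE_SPACING,
                                   noise_sigma: float = 0.0,
                                   seed: int = 0):
    """Two capsomeres with fitted-plane angles equal to (alpha, beta).

    Capsomere A lies in the z=0 plane with one subunit pointing at B;
    B is hinged about the midpoint by ``alpha`` degrees and twisted
    about its own normal by ``beta`` degrees.  Returns
    ``(atoms, truth)`` where truth records the requested angles.
    """
    if not (0.0 <= alpha < 90.0):
        raise ValueError("alpha must be in [0, 90) degrees")
    rng = np.random.default_rng(seed)
    tmplA = make_template(kind_a, ring_radius=0.40 * spacing,
                          inner_radius=0.055 * spacing)
    tmplB = make_template(kind_b, ring_radius=0.40 * spacing,
                          inner_radius=0.055 * spacing)

    al = math.radians(alpha)
    be = math.radians(beta)
    # hinge about the y-axis line through the midpoint (spacing/2, 0, 0)
    Ry = np.array([[math.cos(al), 0.0, math.sin(al)],
                   [0.0, 1.0, 0.0],
                   [-math.sin(al), 0.0, math.cos(al)]])
    centerA = np.zeros(3)
    mid = np.array([spacing / 2.0, 0.0, 0.0])
    centerB = mid + Ry @ (np.array([spacing, 0.0, 0.0]) - mid)
    frameA = np.eye(3)                      # subunit 0 along +x, toward B
    Rz_pi = np.array([[-1.0, 0.0, 0.0], [0.0, -1.0, 0.0], [0.0, 0.0, 1.0]])
    frameB = Ry @ Rz_pi                     # subunit 0 back toward A
    nB = frameB[:, 2]
    K = np.array([[0, -nB[2], nB[1]], [nB[2], 0, -nB[0]], [-nB[1], nB[0], 0]])
    Rtwist = np.eye(3) + math.sin(be) * K + (1 - math.cos(be)) * (K @ K)
    frameB = Rtwist @ frameB

    atoms: list[AtomRecord] = []
    chain_i = 0
    for tmpl, center, frame in ((tmplA, centerA, frameA), (tmplB, centerB, frameB)):
        for j in range(tmpl.n_subunits):
            cname = _CHAIN62[chain_i]
            chain_i += 1
            world = center + tmpl.local_points[j] @ frame.T
            if noise_sigma > 0:
                world = world + rng.normal(0.0, noise_sigma, world.shape)
            for p in range(tmpl.points_per_subunit):
                atoms.append(AtomRecord(
                    chain=cname, resname="UNK", resnum=1,
                    atom=f"C{p + 1}", element="C", position=world[p]))
    truth = {"alpha": alpha, "beta": beta, "spacing": spacing,
             "noise_sigma": noise_sigma, "seed": seed}
    return atoms, truth


# ---------------------------------------------------------------------------
# linker sequences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticLinkerSpec:
    """A linker sequence with [IV][TS]G motifs planted at known positions."""

    length: int
    motif_positions: tuple[int, ...] = ()   # 1-based start positions
    motif_choices: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        pos = sorted(self.motif_positions)
        for p in pos:
            if p < 1 or p + 2 > self.length:
                raise ValueError(f"motif at {p} does not fit in length {self.length}")
        for p, q in zip(pos, pos[1:]):
            if q - p < 3:
                raise ValueError(f"motifs at {p} and {q} overlap")
        if self.motif_choices is not None:
            if len(self.motif_choices) != len(self.motif_positions):
                raise ValueError("one motif choice per position required")
            for t in self.motif_choices:
                if not re.fullmatch(r"[IV][TS]G", t):
                    raise ValueError(f"{t!r} does not match [IV][TS]G")


@dataclass
class LinkerRecord:
    id: str
    sequence: str
    manifest: dict

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.id}\n")
            for i in range(0, len(self.sequence), 60):
                fh.write(self.sequence[i:i + 60] + "\n")


def generate_linker(spec: SyntheticLinkerSpec) -> LinkerRecord:
    """Random linker with planted motifs and a motif-free background.

    Background residues are drawn uniformly from the 20 amino acids;
    accidental [IV][TS]G occurrences outside the planted positions are
    removed by redrawing background characters (rejection sampling).
    """
    rng = np.random.default_rng(spec.seed)
    seq = [_AMINO[i] for i in rng.integers(0, len(_AMINO), spec.length)]
    planted: set[int] = set()
    triplets = []
    positions = sorted(spec.motif_positions)
    choice_by_pos = dict(zip(sorted(spec.motif_positions), spec.motif_choices or ()))
    for p in positions:
        triplet = choice_by_pos.get(p)
        if triplet is None:
            triplet = "IV"[rng.integers(0, 2)] + "TS"[rng.integers(0, 2)] + "G"
        for off, ch in enumerate(triplet):
            seq[p - 1 + off] = ch
            planted.add(p - 1 + off)
        triplets.append(triplet)

    planted_starts = {p - 1 for p in positions}
    for _ in range(10_000):
        dirty = [m.start() for m in _MOTIF_RE.finditer("".join(seq))
                 if m.start() not in planted_starts]
        if not dirty:
            break
        for start in dirty:
            mutable = [i for i in range(start, start + 3) if i not in planted]
            i = mutable[0]  # guaranteed non-empty: planted motifs cannot
            # combine into an unplanted match without a background residue
            seq[i] = _AMINO[rng.integers(0, len(_AMINO))]
    else:
        raise RuntimeError("rejection sampling failed to converge")

    sequence = "".join(seq)
    manifest = {
        "seed": spec.seed,
        "length": spec.length,
        "motif_positions": list(positions),
        "motif_triplets": triplets,
    }
    return LinkerRecord(id=f"synthetic_linker_seed{spec.seed}",
                        sequence=sequence, manifest=manifest)
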