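"""End-to-end analysis of a multi-capsomere shell structure.

Given the atoms of an assembled shell (real or synthetic), this module
segments chains into capsomeres, detects the shell's rigid point group
from the pentamer arrangement, classifies capsomere-capsomere contacts
into symmetry-equivalence classes, surveys per-class bend/twist angles
and measures the shell diameter.  It is the computational core behind
the ``analyze`` command.
"""

from __future__ import annotations

import numpy as np

from . import geometry, lattice, structio

__all__ = ["analyze_structure"]


def analyze_structure(atoms: list[structio.AtomRecord],
                      merge_mirror: bool | None = None,
                      symmetry_tol_factor: float = 0.02,
                      diameter_seed: int = 0) -> dict:
    """Segment, classify and measure one shell structure.

    ``merge_mirror=None`` merges mirror-related interface classes
    exactly when the detected point group contains improper operations
    (i.e. the arrangement itself is achiral).  Capsomeres with subunit
    counts other than 5 or 6 are reported but excluded from
    classification.  Returns a dict with the segmented capsomeres,
    interface classes, angle survey (DataFrame) and diameters.
    """
    caps = structio.segment_capsomeres(atoms)
    known = [c for c in caps if c.kind != "unknown"]
    unknown = [c for c in caps if c.kind == "unknown"]
    kinds = [c.kind for c in known]
    n_pent = kinds.count("pentamer")
    n_hex = kinds.count("hexamer")
    centroids = np.array([c.centroid for c in known])

    adjacency = geometry.capsomere_adjacency(known)
    from scipy.spatial import cKDTree

    tree = cKDTree(centroids)
    dist, _ = tree.query(centroids, k=2)
    spacing = float(np.median(dist[:, 1]))

    proper, improper = lattice.detect_point_symmetry(
        centroids, kinds, adjacency, tol=symmetry_tol_factor * spacing)
    if merge_mirror is None:
        merge_mirror = bool(improper)
    ops = proper + (improper if merge_mirror else [])
    classes = lattice.classify_edges(centroids, kinds, adjacency, ops,
                                     tol=symmetry_tol_factor * spacing)
    survey = geometry.angle_survey(known, classes)
    shell_centroid = centroids.mean(axis=0)

    t_est = None
    if n_pent == 12 and n_hex % 10 == 0:
        t_est = n_hex // 10 + 1
    return {
        "capsomeres": known,
        "unknown_capsomeres": unknown,
        "n_pentamers": n_pent,
        "n_hexamers": n_hex,
        "t_if_icosahedral": t_est,
        "edge_spacing_estimate": spacing,
        "adjacency": adjacency,
        "symmetry_order": len(ops),
        "n_proper_ops": len(proper),
        "n_improper_ops": len(improper),
        "classes": classes,
        "angle_survey": survey,
        "shell_centroid": shell_centroid,
        "diameters": {
            mode: geometry.measure_diameter(centroids, mode, seed=diameter_seed)
            for mode in ("diagonal_average", "circumsphere", "insphere")
        },
    }
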