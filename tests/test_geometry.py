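"""Plane fitting, interface angles, superposition RMSD, diameters."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from bmcshell import geometry as geo
from bmcshell.shellgen import (SyntheticShellSpec, generate_shell,
                               generate_two_capsomere_fixture)
from bmcshell.structio import AtomRecord, segment_capsomeres


def _hexagon(radius=10.0, z=0.0):
    return np.array([[radius * math.cos(2 * math.pi * j / 6),
                      radius * math.sin(2 * math.pi * j / 6), z]
                     for j in range(6)])


# ---------------------------------------------------------------------------
# plane fitting
# ---------------------------------------------------------------------------

def test_fit_plane_regular_hexagon_exact():
    plane = geo.fit_plane(_hexagon())
    assert abs(plane.normal[2]) == pytest.approx(1.0, abs=1e-12)
    assert plane.rms_residual == pytest.approx(0.0, abs=1e-12)


def test_fit_plane_three_points_exact():
    pts = np.array([[0, 0, 1.0], [1, 0, 1.0], [0, 1, 1.0]])
    plane = geo.fit_plane(pts)
    assert abs(plane.normal[2]) == pytest.approx(1.0, abs=1e-12)


def test_fit_plane_outward_orientation():
    plane = geo.fit_plane(_hexagon(z=50.0), shell_centroid=np.zeros(3))
    assert plane.normal[2] > 0


def test_fit_plane_rejects_collinear_and_tiny_input():
    with pytest.raises(geo.GeometryError):
        geo.fit_plane(np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2.0]]))
    with pytest.raises(geo.GeometryError):
        geo.fit_plane(np.array([[0, 0, 0], [1, 0, 0.0]]))


def test_fit_plane_noise_normal_within_two_degrees(rng):
    worst = 0.0
    for _ in range(100):
        pts = _hexagon() + rng.normal(0, 0.1, (6, 3))
        n = geo.fit_plane(pts).normal
        ang = math.degrees(math.acos(min(1.0, abs(n[2]))))
        worst = max(worst, ang)
    assert worst < 2.0


# ---------------------------------------------------------------------------
# interface angles
# ---------------------------------------------------------------------------

def test_coplanar_aligned_hexamers_zero_angles():
    atoms, _ = generate_two_capsomere_fixture(0.0, 0.0)
    caps = segment_capsomeres(atoms)
    got = geo.interface_angles(caps[0], caps[1])
    assert got.alpha == pytest.approx(0.0, abs=1e-9)
    assert got.beta == pytest.approx(0.0, abs=1e-9)


def test_angles_symmetric_under_argument_swap():
    atoms, _ = generate_two_capsomere_fixture(24.0, 9.0)
    caps = segment_capsomeres(atoms)
    ab = geo.interface_angles(caps[0], caps[1])
    ba = geo.interface_angles(caps[1], caps[0])
    assert ab.alpha == pytest.approx(ba.alpha, abs=1e-9)
    assert ab.beta == pytest.approx(ba.beta, abs=1e-9)


def test_angles_invariant_under_rigid_transform(rng):
    atoms, _ = generate_two_capsomere_fixture(18.0, 5.0)
    caps = segment_capsomeres(atoms)
    ref = geo.interface_angles(caps[0], caps[1])
    R = Rotation.random(random_state=3).as_matrix()
    t = rng.uniform(-50, 50, 3)
    moved = [AtomRecord(a.chain, a.resname, a.resnum, a.atom, a.element,
                        R @ a.position + t) for a in atoms]
    caps2 = segment_capsomeres(moved)
    got = geo.interface_angles(caps2[0], caps2[1])
    assert got.alpha == pytest.approx(ref.alpha, abs=1e-8)
    assert got.beta == pytest.approx(ref.beta, abs=1e-8)


def test_non_adjacent_pair_rejected():
    atoms, _ = generate_two_capsomere_fixture(0.0, 0.0, spacing=300.0)
    caps = segment_capsomeres(atoms)
    with pytest.raises(geo.GeometryError, match="not adjacent"):
        geo.interface_angles(caps[0], caps[1], max_distance=100.0)


def test_intra_facet_interfaces_are_flat(t9_shell):
    """Hexamer pairs interior to one triangular facet have alpha = 0."""
    flat = [i for i in t9_shell.manifest["interfaces"]
            if i["alpha"] < 1e-9]
    assert flat  # the faceted T=9 shell has a flat hexamer-hexamer class
    bent = [i for i in t9_shell.manifest["interfaces"]
            if i["alpha"] > 1e-9]
    assert all(i["alpha"] <= 45.0 for i in bent)  # icosahedral dihedral bound


def test_spherized_lattice_bends_everywhere():
    from bmcshell import lattice as lat

    lattice = lat.build_lattice(lat.LatticeParams(3, 0), spherize=True)
    pos = lattice.positions
    for a, b in sorted(lattice.adjacency)[:40]:
        na, nb = lattice.sites[a].normal, lattice.sites[b].normal
        ang = math.degrees(math.acos(np.clip(np.dot(na, nb), -1, 1)))
        assert ang > 1.0


# ---------------------------------------------------------------------------
# superposition RMSD
# ---------------------------------------------------------------------------

def _hexamer_capsomere(seed=0, rotate_subunits=0, noise=0.0, transform=True):
    atoms, _ = generate_two_capsomere_fixture(0.0, 0.0, spacing=500.0,
                                              noise_sigma=noise, seed=seed)
    caps = segment_capsomeres(atoms)
    return caps[0], caps[1]


def test_rmsd_zero_for_rigid_copy(rng):
    capA, _ = _hexamer_capsomere()
    R = Rotation.random(random_state=5).as_matrix()
    t = rng.uniform(-30, 30, 3)
    moved_pts = [p @ R.T + t for p in capA.subunit_points]
    from bmcshell.structio import Capsomere

    capB = Capsomere(chains=list(capA.chains), kind=capA.kind,
                     centroid=np.vstack(moved_pts).mean(axis=0),
                     subunit_centroids=np.array([p.mean(axis=0)
                                                 for p in moved_pts]),
                     points=np.vstack(moved_pts), subunit_points=moved_pts)
    assert geo.superpose_rmsd(capA, capB) == pytest.approx(0.0, abs=1e-9)


def test_rmsd_zero_after_one_subunit_step_rotation():
    capA, _ = _hexamer_capsomere()
    step = Rotation.from_euler("z", 60, degrees=True).as_matrix()
    moved_pts = [p @ step.T for p in capA.subunit_points]
    from bmcshell.structio import Capsomere

    capB = Capsomere(chains=list(capA.chains), kind=capA.kind,
                     centroid=np.vstack(moved_pts).mean(axis=0),
                     subunit_centroids=np.array([p.mean(axis=0)
                                                 for p in moved_pts]),
                     points=np.vstack(moved_pts), subunit_points=moved_pts)
    assert geo.superpose_rmsd(capA, capB) == pytest.approx(0.0, abs=1e-9)


def test_rmsd_noise_oracle_within_twenty_percent(rng):
    """Noisy copy vs original: RMSD ~ sigma * sqrt(3)."""
    sigma = 0.5
    capA, _ = _hexamer_capsomere()
    vals = []
    for _ in range(50):
        noisy = [p + rng.normal(0, sigma, p.shape) for p in capA.subunit_points]
        from bmcshell.structio import Capsomere

        capB = Capsomere(chains=list(capA.chains), kind=capA.kind,
                         centroid=np.vstack(noisy).mean(axis=0),
                         subunit_centroids=np.array([p.mean(axis=0)
                                                     for p in noisy]),
                         points=np.vstack(noisy), subunit_points=noisy)
        vals.append(geo.superpose_rmsd(capA, capB))
    expected = sigma * math.sqrt(3.0)
    assert abs(np.mean(vals) - expected) / expected < 0.20


def test_rmsd_rejects_mismatched_counts():
    capA, _ = _hexamer_capsomere()
    atoms, _ = generate_two_capsomere_fixture(0.0, 0.0, kind_a="pentamer",
                                              spacing=500.0)
    capP = segment_capsomeres(atoms)[0] if \
        segment_capsomeres(atoms)[0].kind == "pentamer" else \
        segment_capsomeres(atoms)[1]
    with pytest.raises(geo.GeometryError):
        geo.superpose_rmsd(capA, capP)


# ---------------------------------------------------------------------------
# diameter
# ---------------------------------------------------------------------------

def test_circumsphere_diameter_of_spherical_cloud(rng):
    r = 200.0
    half = rng.standard_normal((250, 3))
    half = r * half / np.linalg.norm(half, axis=1)[:, None]
    pts = np.vstack([half, -half])  # antipodal pairs: centroid is exact
    assert geo.measure_diameter(pts, "circumsphere") == pytest.approx(2 * r)
    assert geo.measure_diameter(pts, "insphere") == pytest.approx(2 * r)


def test_icosahedron_circumsphere_insphere_ratio():
    from bmcshell import lattice as lat

    lattice = lat.build_lattice(lat.LatticeParams(1, 0), edge_spacing=10.0)
    pos = lattice.positions
    ratio = (geo.measure_diameter(pos, "circumsphere")
             / geo.measure_diameter(pos, "insphere"))
    # vertices all lie on the circumsphere, so centroid radii are equal
    assert ratio == pytest.approx(1.0, abs=1e-9)
    # circumradius/edge for a regular icosahedron
    edge = min(np.linalg.norm(pos[a] - pos[b])
               for a, b in lattice.adjacency)
    circ = geo.measure_diameter(pos, "circumsphere") / 2.0
    assert circ / edge == pytest.approx(math.sin(2 * math.pi / 5), abs=1e-9)


@pytest.mark.parametrize("seed", [0, 1, 17])
def test_diagonal_average_on_sphere_within_one_percent(seed, rng):
    r = 150.0
    pts = rng.standard_normal((2000, 3))
    pts = r * pts / np.linalg.norm(pts, axis=1)[:, None]
    d = geo.measure_diameter(pts, "diagonal_average", seed=seed)
    assert abs(d - 2 * r) / (2 * r) < 0.01


def test_diameter_needs_enough_centroids():
    with pytest.raises(geo.GeometryError):
        geo.measure_diameter(np.zeros((5, 3)))


# ---------------------------------------------------------------------------
# survey
# ---------------------------------------------------------------------------

def test_angle_survey_matches_manifest(t9_shell):
    from bmcshell.pipeline import analyze_structure

    res = analyze_structure(t9_shell.atoms)
    survey = res["angle_survey"]
    assert len(survey) == 4
    assert list(survey["kind"])[0] == "pentamer-hexamer"
    # survey alphas match the manifest's per-class truth
    man = {}
    for e in t9_shell.manifest["interfaces"]:
        man.setdefault(e["class"], set()).add(round(e["alpha"], 6))
    man_alphas = sorted(next(iter(v)) for v in man.values())
    got_alphas = sorted(round(a, 6) for a in survey["alpha_mean"])
    assert got_alphas == man_alphas
    # per-class dispersion vanishes by symmetry
    assert float((survey["alpha_max"] - survey["alpha_min"]).max()) < 1e-6
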