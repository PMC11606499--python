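# Methods

## Lattice model

A closed shell of hexameric and pentameric capsomeres is modelled as a
Caspar–Klug lattice. The indices *(h, k)* count the two hexagonal
lattice steps between adjacent five-fold vertices; the triangulation
number T = h² + hk + k² is the facet area in units of the smallest
facet, and a closed icosahedral shell has 12 pentamers (one per
five-fold vertex, forced by the Euler characteristic) and 10(T − 1)
hexamers. Prolate (5-fold elongated) shells insert a tube of ten
triangular facets between two icosahedral caps; the tube facet is
spanned by the ring-edge vector *(h, k)* and an elongation vector
*(h′, k′)* with Q = hh′ + hk′ + kk′, adding 5(Q − T) hexamers.

### Construction

The canonical embedding is the *faceted* polyhedron. Each triangular
face is an isometric affine image of a lattice triangle cut from one
hexagonal sheet (corners on lattice points, counter-clockwise seen
from outside); integer points inside each face are enumerated with
exact integer barycentric tests, mapped to 3D, and merged across
shared edges and vertices. Consistency across folds follows from the
hexagonal lattice's inversion symmetry about edge midpoints; the
construction is validated by brute-force counting (composition
formulas for all T ≤ 25 and several prolate classes) and by the degree
invariant (pentamers 5 neighbours, hexamers 6).

For prolate shells the tube vector D = (k′, −h′−k′) satisfies
cross(D, P1) = Q with the outward-oriented corner order; D and
D + m·P1 describe the same tube with the ring pairing relabelled, so
the least-skew realisable representative is embedded (the ring twist
and axial rise solve the two cross-edge length equations; both
solution branches are tried). Without this canonicalisation some
index choices (e.g. (h′,k′) = (4,0) for T=9 Q=12) have no symmetric
tube solution even though an equivalent representative does.

A `spherize` option projects sites radially onto the circumsphere for
comparison; the faceted embedding is canonical because bend then
concentrates at facet edges, mirroring the observation that
pentamer-proximal interfaces bend while intra-facet hexamer–hexamer
interfaces stay flat.

### Adjacency and symmetry

Two sites are adjacent when their centre distance is within 1.2× the
lattice spacing: on the faceted embedding first neighbours sit at
0.93–1.0× spacing (folds only shorten distances) while second
neighbours stay above ~1.6×, so the cutoff separates shells with ≥30%
margin. The rigid point group is detected from the pentamer positions
alone: candidate orthogonal maps are generated from ordered pentamer
pairs congruent to a reference pair (proper and mirror frames) and
kept when they permute all sites kind-preservingly and permute the
adjacency edge set. This yields the 60 rotations (plus 60 improper
operations for achiral lattices) of icosahedral shells and the
10-element dihedral group of 5-fold prolate shells, without assuming
either.

Interface classes are orbits of contact edges under the group.
Mirror-related orbits are merged exactly when the lattice is achiral
(h = 0, k = 0 or h = k) — one consistent rule that yields the minimal
4 classes for T = 9 and the maximal 10 for T = 19; whether the
published interface counts used mirror merging is not stated, so the
rule is exposed as a `merge_mirror` switch. Classes are ordered
pentamer–hexamer first, then by descending orbit size with a
lexicographic representative tie-break; sites are 0-based internally
and printed 1-based.

## Synthetic shells

The generator places rigid pseudo-atomic capsomere templates on
lattice sites: 5 or 6 wedge-shaped subunits of 7 points each (one
chain per subunit, residue `UNK`), spanning 0.055–0.40× the lattice
spacing so that subunits of one capsomere touch near the axis while
neighbouring capsomeres stay ~13 Å apart at default scale. The wedge
is chiral, keeping superposition and orientation recovery unambiguous.

Capsomere orientation follows the hexagonal lattice: each site carries
a tangent reference along its facet's lattice directions, half-fold
rotated for sites on facet edges and symmetry-averaged at vertices.
This is the unique twist-free orientation field of the faceted
geometry: every pentamer–hexamer interface of an icosahedral shell
and every interface of chiral shells (T = 13, T = 19, whose hexamers
all lie inside facets) has β = 0 exactly. A geometric residual
remains where no twist-free choice exists: the 60 vertex-adjacent
edge-hexamer pairs of achiral shells carry an intrinsic 3.4° twist
(T = 9), and prolate ring pentamers sit on an asymmetric vertex figure.
These are properties of the idealised faceted geometry, not
measurement error, and they do not contradict the zero twist of
pentamer–hexamer interfaces.

Defaults are chosen once to match the real system: 65 Å
centre-to-centre spacing reproduces the observed shell diameters
(faceted circumsphere 37.1 nm for T = 9 through 53.9 nm for T = 19),
and the faceted pentamer–hexamer bend (29.3°–41.6° across shell
classes, 31.7° for T = 9) brackets the measured 29.4°–31.5°. Gaussian
coordinate noise is per-atom; above 0.1× spacing the generator warns
and above 0.25× it refuses (adjacency becomes ambiguous). One seeded
stream per artifact; manifests record seeds, capsomere membership,
interface classes and true per-interface angles, and output is
byte-reproducible for a fixed seed.

What the synthetic shells do *not* emulate: side-chain chemistry
(contact analysis rejects them and uses residue-level fixtures),
capsomere-internal flexibility, partial occupancy, and the
paralog heterogeneity of real shells. Tests passing on synthetic
shells therefore validate the geometric machinery, not cryo-EM-scale
measurements, which require deposited models.

## Segmentation

Chains are grouped into capsomeres by single-linkage clustering at a
5 Å heavy-atom contact cutoff (first altloc kept, hydrogens ignored,
residue numbering preserved verbatim). Sparse pseudo-atomic chains
lose atom-level contacts under noise, so when component sizes are
inconsistent with 5/6-mers a second level clusters chain centroids at
1.45× their median nearest-neighbour distance — robust because
capsomere centres sit a full lattice spacing apart. Segmentation is
exact for noise up to 0.05× spacing (20/20 seeds) and components with
other subunit counts are labelled `unknown`, never dropped.

## Angles, RMSD, diameters

Capsomere planes are least-squares fits over all subunit points
(smallest principal axis), oriented outward from the shell centroid.
α is the angle between outward normals (atan2 form, precise near 0°).
β maps capsomere B's subunit directions onto A's plane by the minimal
rotation about n_A × n_B and takes the n-fold circular-mean phase
difference, folded into (−180/n, 180/n]; for mixed pentamer–hexamer
pairs, which share no common period, each capsomere's phase is taken
relative to the projected interface direction and the difference
reported. Whether the published twist is measured about the interface
axis or the symmetry axis is not stated; the interface-direction
variant is what the mixed-pair path implements.

Capsomere RMSD is proper-rotation Kabsch, minimised over the 5/6
cyclic subunit correspondences; both azimuthal traversal directions
are tried because the fitted normal's sign is arbitrary (no
reflections enter the superposition itself). Shell diameter offers
three modes: twice the maximal/minimal centroid radius, and a
`diagonal_average` that emulates measuring particle images — three
centre-crossing extents at 60° steps in a seeded random projection
plane, averaged (default seed 0, recorded in run logs).

## Contact chemistry

Hydrogen bonds are cross-group N/O⋯N/O heavy-atom pairs within 3.5 Å;
salt bridges are Asp/Glu carboxylate oxygens within 4.0 Å of
Arg/Lys(/His, configurable) basic nitrogens. No angular term is
applied — the interface descriptions being reproduced are
residue-pair lists without geometry conditions — and cutoffs are
configurable. SASA is Shrake–Rupley with a deterministic
golden-spiral point set (960 points/atom default, probe 1.4 Å) over
Bondi (1964) van der Waals radii (table named in every result);
single-sphere accuracy is <0.5% and two-sphere buried area <1% against
closed forms. Buried area reports both the total
SASA(A)+SASA(B)−SASA(A∪B) and its half, because the per-side vs total
convention is ambiguous in the literature; the convention string
travels with the number.

## Motifs

[IV][TS]G scanning reports all overlapping matches (the biological
motifs are consecutive repeats) via regex lookahead, validated against
a sliding-window oracle. Fragment annotations default to the five
structurally resolved linker fragments (F1 607–647, F2 685–700,
F3 712–731, F4 702–735, F5 770–869 in full-length numbering); the
linker protein's own sequence is not bundled, so fragment-level tests
use synthetic sequences. Register shift between two motif series is
the integer offset maximising exact position coincidences (ties
reported, squared-mismatch fallback when series share no position).

## Problem sizes and limitations

Tests and the acceptance script run entirely on generated data: shells
up to T = 19 (192 capsomeres, ~8000 pseudo-atoms), 100-seed Monte
Carlo for angle recovery, 1000-configuration contact-search
cross-checks, 1000-sequence scanner oracles. Quantities that require
the deposited cryo-EM models — absolute capsomere RMSD ranges,
measured interface-angle spreads, the reported buried areas of linker
fragments — are out of reach at this scale; the corresponding
machinery is validated on synthetic oracles and the qualitative
ordering (pentamer-proximal interfaces bend, intra-facet interfaces
stay flat) is asserted instead. The prolate symmetry detector assumes
an intact 5-fold tube; partially assembled or defective shells will
fall back to smaller groups and coarser interface classes.
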