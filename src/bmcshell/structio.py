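"""Structure and sequence I/O plus capsomere segmentation.

Reading and writing of PDB/mmCIF goes through gemmi; this module keeps
a deliberately flat in-memory representation (a list of
:class:`AtomRecord`) because every downstream computation works on
coordinates, chain identity and residue identity only.  Chains of a
multi-chain assembly are grouped into capsomeres (hexamers/pentamers)
by single-linkage clustering at a tight heavy-atom contact cutoff:
subunits within one capsomere are in close contact, while neighbouring
capsomeres sit at lattice spacing and only touch at looser distances,
so a single tight cutoff separates the two contact levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

__all__ = [
    "AtomRecord",
    "Capsomere",
    "ParseError",
    "read_structure",
    "write_structure",
    "read_fasta",
    "segment_capsomeres",
]

#: Heavy-atom distance below which two chains belong to one capsomere.
INTRA_CAPSOMERE_CUTOFF = 5.0


class ParseError(ValueError):
    """A structure file that does not parse under the named standard."""


@dataclass
class AtomRecord:
    """One atom as read from a coordinate file (numbering kept verbatim)."""

    chain: str
    resname: str
    resnum: int
    atom: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class Capsomere:
    """One shell building block: a clustered group of subunit chains."""

    chains: list[str]
    kind: str                      # "pentamer" | "hexamer" | "unknown"
    centroid: np.ndarray
    subunit_centroids: np.ndarray  # (n_subunits, 3)
    points: np.ndarray             # all member heavy-atom coordinates
    subunit_points: list[np.ndarray] = field(default_factory=list)

    @property
    def subunit_count(self) -> int:
        return len(self.chains)


def _detect_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in ("pdb", "mmcif", "cif"):
            raise ValueError(f"unknown format {fmt!r}")
        return "pdb" if fmt == "pdb" else "mmcif"
    suffix = Path(path).suffix.lower()
    return "pdb" if suffix in (".pdb", ".ent") else "mmcif"


def read_structure(path: str | Path, fmt: str | None = None,
                   model_index: int | None = None) -> list[AtomRecord]:
    """Read all atoms of one model from a PDB or mmCIF file.

    Files containing several models are rejected unless ``model_index``
    (0-based) picks one.  Residue numbering is preserved verbatim.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt_name = _detect_format(path, fmt)
    try:
        if fmt_name == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path}: no models found")
    if len(st) > 1 and model_index is None:
        raise ParseError(
            f"{path}: {len(st)} models present; pass model_index to select one")
    model = st[model_index or 0]
    atoms: list[AtomRecord] = []
    for chain in model:
        for res in chain:
            for atom in res:
                if atom.altloc not in ("", "\0", "A"):
                    continue  # keep first altloc only
                pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                if not np.all(np.isfinite(pos)):
                    raise ParseError(
                        f"{path}: non-finite coordinates in chain {chain.name} "
                        f"residue {res.seqid.num}")
                atoms.append(AtomRecord(
                    chain=chain.name,
                    resname=res.name,
                    resnum=res.seqid.num,
                    atom=atom.name,
                    element=atom.element.name,
                    position=pos,
                    occupancy=atom.occ,
                    bfactor=atom.b_iso,
                ))
    if not atoms:
        raise ParseError(f"{path}: file contains no atoms")
    return atoms


def write_structure(atoms: list[AtomRecord], path: str | Path,
                    fmt: str | None = None) -> None:
    """Write atoms as PDB or mmCIF (format from extension unless given).

    PDB output requires single-character chain names; larger assemblies
    should be written as mmCIF.
    """
    path = Path(path)
    fmt_name = _detect_format(path, fmt)
    # group records first: gemmi's add_residue/add_chain copy their argument,
    # so the hierarchy must be assembled bottom-up
    by_chain: dict[str, dict[tuple[int, str], list[AtomRecord]]] = {}
    chain_order: list[str] = []
    for rec in atoms:
        if rec.chain not in by_chain:
            by_chain[rec.chain] = {}
            chain_order.append(rec.chain)
        by_chain[rec.chain].setdefault((rec.resnum, rec.resname), []).append(rec)

    st = gemmi.Structure()
    st.name = path.stem
    model = gemmi.Model("1")
    for cname in chain_order:
        chain = gemmi.Chain(cname)
        for (resnum, resname), recs in by_chain[cname].items():
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(resnum, " ")
            for rec in recs:
                atom = gemmi.Atom()
                atom.name = rec.atom
                atom.element = gemmi.Element(rec.element)
                atom.pos = gemmi.Position(*rec.position)
                atom.occ = rec.occupancy
                atom.b_iso = rec.bfactor
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    if fmt_name == "pdb":
        if any(len(c) > 1 for c in chain_order):
            raise ValueError(
                "PDB chain names are single characters; write mmCIF for "
                f"assemblies with {len(chain_order)} chains")
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as ``(identifier, sequence)`` pairs."""
    from Bio import SeqIO

    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def segment_capsomeres(atoms: list[AtomRecord],
                       contact_cutoff: float = INTRA_CAPSOMERE_CUTOFF
                       ) -> list[Capsomere]:
    """Group chains into capsomeres by tight heavy-atom contact.

    Chains whose heavy atoms approach within ``contact_cutoff`` are
    single-linkage clustered; each connected component is one capsomere,
    labelled pentamer/hexamer by its subunit count (anything else is
    kept as ``unknown``, never dropped).  If that clustering yields
    inconsistent subunit counts (sparse pseudo-atomic chains under
    coordinate noise lose atom-level contacts), a coarser second level
    clusters chain centroids at a threshold derived from their
    nearest-neighbour spacing, which is robust because capsomere
    centres sit a full lattice spacing apart.  The result is sorted by
    capsomere centroid for order-independence.
    """
    heavy = [a for a in atoms if not a.is_hydrogen]
    chain_names = sorted({a.chain for a in heavy})
    if len(chain_names) < 2:
        raise ValueError("segmentation needs at least two chains")
    chain_index = {c: i for i, c in enumerate(chain_names)}
    coords = np.array([a.position for a in heavy])
    labels = np.array([chain_index[a.chain] for a in heavy])
    n = len(chain_names)

    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=contact_cutoff, output_type="ndarray")
    if len(pairs):
        ci = labels[pairs[:, 0]]
        cj = labels[pairs[:, 1]]
        mask = ci != cj
    else:
        ci = cj = np.zeros(0, dtype=int)
        mask = np.zeros(0, dtype=bool)
    graph = coo_matrix((np.ones(mask.sum()), (ci[mask], cj[mask])), shape=(n, n))
    n_comp, comp = connected_components(graph, directed=False)

    sizes = np.bincount(comp)
    if n > 2 and np.any(~np.isin(sizes, (5, 6))):
        # second level: single-linkage on chain centroids
        cents = np.array([coords[labels == i].mean(axis=0) for i in range(n)])
        ctree = cKDTree(cents)
        nn_dist, _ = ctree.query(cents, k=2)
        threshold = 1.45 * float(np.median(nn_dist[:, 1]))
        cpairs = ctree.query_pairs(r=threshold, output_type="ndarray")
        if len(cpairs):
            graph = coo_matrix((np.ones(len(cpairs)),
                                (cpairs[:, 0], cpairs[:, 1])), shape=(n, n))
            n_comp, comp = connected_components(graph, directed=False)

    caps: list[Capsomere] = []
    for c in range(n_comp):
        members = [chain_names[i] for i in range(n) if comp[i] == c]
        sub_pts = []
        for m in members:
            pts = coords[labels == chain_index[m]]
            sub_pts.append(pts)
        sub_centroids = np.array([p.mean(axis=0) for p in sub_pts])
        count = len(members)
        kind = {5: "pentamer", 6: "hexamer"}.get(count, "unknown")
        caps.append(Capsomere(
            chains=members,
            kind=kind,
            centroid=sub_centroids.mean(axis=0),
            subunit_centroids=sub_centroids,
            points=np.vstack(sub_pts),
            subunit_points=sub_pts,
        ))
    caps.sort(key=lambda cp: tuple(np.round(cp.centroid, 6)))
    return caps
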