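"""[IV][TS]G motif scanning and linker-fragment bookkeeping.

The C-terminal domain of the alpha-carboxysome scaffolding protein
CsoS2 anchors to shell hexamers through short repetitive
Ile(Val)-Thr(Ser)-Gly tripeptides.  This module scans sequences for
the degenerate [IV][TS]G pattern (all overlapping matches reported),
tracks the named CsoS2-C fragments F1-F5 with their residue ranges in
full-length CsoS2 numbering, and aligns two motif series to detect a
register shift (a binding site displaced by a whole number of motifs).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "MotifHit",
    "FragmentAnnotation",
    "DEFAULT_FRAGMENTS",
    "scan_motifs",
    "fragment_overlap",
    "motif_register_shift",
]

_PATTERN = re.compile(r"(?=([IV][TS]G))")
_VALID = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class MotifHit:
    position: int   # 1-based start
    triplet: str
    context: str    # up to 3 flanking residues on each side

    def __post_init__(self) -> None:
        if not re.fullmatch(r"[IV][TS]G", self.triplet):
            raise ValueError(f"{self.triplet!r} does not match [IV][TS]G")


@dataclass(frozen=True)
class FragmentAnnotation:
    """A named linker fragment with 1-based inclusive residue bounds."""

    name: str
    start: int
    end: int
    note: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.name}: start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


#: Structurally resolved CsoS2-C fragments (full-length CsoS2 numbering).
DEFAULT_FRAGMENTS = (
    FragmentAnnotation("F1", 607, 647, "Gln607-Gln647"),
    FragmentAnnotation("F2", 685, 700, "Met685-Asn700"),
    FragmentAnnotation("F3", 712, 731, "Arg712-Arg731"),
    FragmentAnnotation("F4", 702, 735, "Ile702-Arg735"),
    FragmentAnnotation("F5", 770, 869, "Lys770-Gly869"),
)


def scan_motifs(sequence: str, context: int = 3) -> list[MotifHit]:
    """All (possibly overlapping) [IV][TS]G matches, in sequence order.

    The sequence is upper-cased first; any non-amino-acid character is
    rejected with its 1-based position.
    """
    seq = sequence.upper()
    for i, ch in enumerate(seq):
        if ch not in _VALID:
            raise ValueError(
                f"invalid amino-acid character {ch!r} at position {i + 1}")
    hits = []
    for m in _PATTERN.finditer(seq):
        s = m.start()
        hits.append(MotifHit(
            position=s + 1,
            triplet=m.group(1),
            context=seq[max(0, s - context):s + 3 + context]))
    return hits


def fragment_overlap(fragments: list[FragmentAnnotation] | None = None) -> list[dict]:
    """Pairwise overlap intervals between fragments (inclusive bounds)."""
    frags = list(DEFAULT_FRAGMENTS if fragments is None else fragments)
    if len(frags) < 2:
        raise ValueError("need at least two fragments")
    out = []
    for i, a in enumerate(frags):
        for b in frags[i + 1:]:
            lo = max(a.start, b.start)
            hi = min(a.end, b.end)
            out.append({
                "a": a.name, "b": b.name,
                "overlap_start": lo if lo <= hi else None,
                "overlap_end": hi if lo <= hi else None,
                "overlap_length": max(0, hi - lo + 1),
            })
    return out


def motif_register_shift(hits_a: list[MotifHit],
                         hits_b: list[MotifHit]) -> dict:
    """Best alignment offset of two motif series, in whole motifs.

    Offset ``s`` means motif ``j`` of series B occupies the position of
    motif ``j + s`` of series A (series share a coordinate system, e.g.
    two overlapping fragments of one protein).  The offset maximising
    the number of exact position coincidences wins; with no coincidence
    at all, the offset minimising the summed squared position mismatch
    of the aligned overlap is reported.  Ties are listed.
    """
    if not hits_a or not hits_b:
        raise ValueError("both motif series must be non-empty")
    pa = [h.position for h in hits_a]
    pb = [h.position for h in hits_b]
    scores: dict[int, tuple[int, float]] = {}
    for s in range(-(len(pb) - 1), len(pa)):
        exact = 0
        sq = 0.0
        n_overlap = 0
        for j, p in enumerate(pb):
            i = j + s
            if 0 <= i < len(pa):
                n_overlap += 1
                if pa[i] == p:
                    exact += 1
                sq += float(pa[i] - p) ** 2
        if n_overlap:
            scores[s] = (exact, -sq / n_overlap)
    best = max(scores.values())
    offsets = sorted(s for s, v in scores.items() if v == best)
    return {"offset": offsets[0], "ties": offsets,
            "exact_matches": best[0]}
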