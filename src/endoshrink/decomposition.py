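"""Domain/linker length decomposition.

Each curated protein's total length is split into the summed length of its
surviving functional-domain intervals and the remainder — the linker length
(all residues not annotated as part of a domain). Conservation
``total = domain + linker`` holds exactly by construction and is asserted
pipeline-wide.

Nested-domain resolution happens once, in curation; this module trusts its
input and fails loudly on overlapping intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .curation import OrthologSet
from .io_formats import DomainHit, ProteinRecord


@dataclass(frozen=True)
class LengthDecomposition:
    protein_id: str
    total_len: int
    domain_len: int
    linker_len: int

    def __post_init__(self) -> None:
        if self.linker_len != self.total_len - self.domain_len:
            raise ValueError("linker_len must equal total_len - domain_len")
        if self.linker_len < 0:
            raise ValueError(
                f"{self.protein_id}: domain total {self.domain_len} exceeds "
                f"protein length {self.total_len}"
            )


def decompose(
    protein: ProteinRecord, surviving_hits: Sequence[DomainHit]
) -> LengthDecomposition:
    """Split a protein's length into domain and linker totals.

    ``surviving_hits`` must be the post-curation non-overlapping intervals;
    overlap here is a contract violation and raises.
    """
    ordered = sorted(surviving_hits, key=lambda h: h.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start <= a.end:
            raise ValueError(
                f"{protein.protein_id}: overlapping domain intervals "
                f"({a.start},{a.end}) and ({b.start},{b.end}); curation must "
                "resolve overlaps first"
            )
    if ordered and ordered[-1].end > protein.length:
        raise ValueError(
            f"{protein.protein_id}: domain end {ordered[-1].end} beyond length"
        )
    domain_len = sum(h.span for h in ordered)
    return LengthDecomposition(
        protein.protein_id, protein.length, domain_len, protein.length - domain_len
    )


def decompose_set(oset: OrthologSet) -> dict[str, LengthDecomposition]:
    """Decompose every member of a curated set, keyed by protein_id."""
    return {
        prot.protein_id: decompose(prot, oset.resolved_hits.get(prot.protein_id, ()))
        for _, prot in oset.members
    }


def decompose_all(
    sets: Sequence[OrthologSet],
) -> dict[str, Mapping[str, LengthDecomposition]]:
    """Decompositions for all curated sets, keyed by group_id then protein_id."""
    return {s.group_id: decompose_set(s) for s in sets}
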