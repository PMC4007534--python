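"""Ortholog-set curation.

Raw ortholog clusters are filtered down to analyzable sets by three rules:
(1) every member shares the same ordered domain architecture, where a domain
entirely nested inside a larger one is absorbed by the larger and any partial
overlap disqualifies the protein; (2) the sample standard deviation of member
total lengths is below a threshold (default 30 aa — larger spreads in reduced
genomes almost always trace to gene fusions); (3) each lifestyle group (OIE /
nonOIE) contributes a minimum number of members so per-group dispersion is
defined.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Mapping, Sequence

from .io_formats import DomainHit, OrthologGroup, ProteinRecord, SpeciesMeta


class _Excluded:
    """Sentinel: protein disqualified by partially overlapping domains."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "EXCLUDED"


EXCLUDED = _Excluded()

EXCLUSION_REASONS = (
    "architecture_mismatch",
    "overlap_excluded_member",
    "sd_too_large",
    "missing_lifestyle_group",
    "inparalogs",
    "domain_free",
)


@dataclass(frozen=True)
class OrthologSet:
    """A curated orthologous protein set (≤1 member per species).

    ``resolved_hits`` maps protein_id to the surviving, non-overlapping domain
    intervals (nested hits already absorbed) used downstream for length
    decomposition.
    """

    group_id: str
    members: tuple[tuple[SpeciesMeta, ProteinRecord], ...]
    architecture: tuple[str, ...]
    length_sd: float
    resolved_hits: Mapping[str, tuple[DomainHit, ...]]

    def lengths(self, lifestyle: str | None = None) -> list[int]:
        return [
            p.length
            for m, p in self.members
            if lifestyle is None or m.lifestyle == lifestyle
        ]

    def members_of(self, lifestyle: str) -> list[ProteinRecord]:
        return [p for m, p in self.members if m.lifestyle == lifestyle]


@dataclass(frozen=True)
class Exclusion:
    group_id: str
    reason: str
    detail: str = ""


def resolve_hits(
    hits: Sequence[DomainHit], evalue_max: float = 1.0
) -> tuple[DomainHit, ...] | None:
    """Apply e-value filtering and nesting resolution to one protein's hits.

    Returns surviving non-overlapping hits sorted by start, or None when two
    surviving intervals partially overlap (the protein is disqualified).
    """
    kept = sorted(
        (h for h in hits if h.evalue <= evalue_max),
        key=lambda h: (h.start, -h.end, h.evalue),
    )
    surviving: list[DomainHit] = []
    for h in kept:
        nested = False
        for other in kept:
            if other is h:
                continue
            if other.start <= h.start and h.end <= other.end:
                if (other.end - other.start) > (h.end - h.start):
                    nested = True  # strictly larger container absorbs h
                    break
                if (other.end - other.start) == (h.end - h.start):
                    # identical span: keep the better e-value / earlier sort
                    if kept.index(other) < kept.index(h):
                        nested = True
                        break
        if not nested:
            surviving.append(h)
    for a, b in zip(surviving, surviving[1:]):
        if b.start <= a.end:  # partial overlap survives nesting → disqualify
            return None
    return tuple(surviving)


def architecture_of(
    protein: ProteinRecord,
    hits: Sequence[DomainHit],
    evalue_max: float = 1.0,
) -> tuple[str, ...] | _Excluded:
    """Ordered domain-accession architecture of a protein, or EXCLUDED.

    Hits above ``evalue_max`` are dropped; a hit whose interval is entirely
    contained in another's is absorbed by the encompassing hit; any remaining
    partial overlap disqualifies the protein (returns EXCLUDED).
    """
    for h in hits:
        if h.protein_id != protein.protein_id:
            raise ValueError(
                f"hit on {h.protein_id} passed with protein {protein.protein_id}"
            )
    resolved = resolve_hits(hits, evalue_max)
    if resolved is None:
        return EXCLUDED
    return tuple(h.domain_accession for h in resolved)


def curate_sets(
    groups: Sequence[OrthologGroup],
    proteomes: Mapping[str, list[ProteinRecord]],
    hits: Sequence[DomainHit],
    meta: Sequence[SpeciesMeta],
    sd_max: float = 30.0,
    evalue_max: float = 1.0,
    min_oie: int = 2,
    min_nonoie: int = 2,
    allow_domain_free: bool = False,
) -> tuple[list[OrthologSet], list[Exclusion]]:
    """Filter raw ortholog groups into curated :class:`OrthologSet` objects.

    Returns the retained sets (sorted by group_id) and an exclusion log with
    one record per rejected group. All cross-references must resolve.
    """
    if not groups:
        raise ValueError("no ortholog groups supplied")
    meta_by_id = {m.species_id: m for m in meta}
    prot_by_key: dict[tuple[str, str], ProteinRecord] = {}
    for sid, records in proteomes.items():
        for rec in records:
            prot_by_key[(sid, rec.protein_id)] = rec
    hits_by_protein: dict[str, list[DomainHit]] = {}
    for h in hits:
        hits_by_protein.setdefault(h.protein_id, []).append(h)

    retained: list[OrthologSet] = []
    excluded: list[Exclusion] = []
    for group in sorted(groups, key=lambda g: g.group_id):
        species_seen = [sid for sid, _ in group.members]
        if len(set(species_seen)) != len(species_seen):
            dups = sorted({s for s in species_seen if species_seen.count(s) > 1})
            excluded.append(
                Exclusion(group.group_id, "inparalogs", f"species {','.join(dups)}")
            )
            continue

        members: list[tuple[SpeciesMeta, ProteinRecord]] = []
        for sid, pid in group.members:
            if sid not in meta_by_id:
                raise KeyError(f"group {group.group_id}: unknown species {sid}")
            if (sid, pid) not in prot_by_key:
                raise KeyError(f"group {group.group_id}: unknown protein {sid}|{pid}")
            members.append((meta_by_id[sid], prot_by_key[(sid, pid)]))

        archs: dict[str, tuple[str, ...] | _Excluded] = {}
        resolved: dict[str, tuple[DomainHit, ...]] = {}
        overlap_member = None
        for _, prot in members:
            res = resolve_hits(hits_by_protein.get(prot.protein_id, []), evalue_max)
            if res is None:
                overlap_member = prot.protein_id
                break
            archs[prot.protein_id] = tuple(h.domain_accession for h in res)
            resolved[prot.protein_id] = res
        if overlap_member is not None:
            excluded.append(
                Exclusion(group.group_id, "overlap_excluded_member", overlap_member)
            )
            continue
        unique_archs = set(archs.values())
        if len(unique_archs) > 1:
            excluded.append(
                Exclusion(
                    group.group_id,
                    "architecture_mismatch",
                    f"{len(unique_archs)} distinct architectures",
                )
            )
            continue
        architecture = unique_archs.pop()
        if not architecture and not allow_domain_free:
            excluded.append(Exclusion(group.group_id, "domain_free"))
            continue

        n_oie = sum(1 for m, _ in members if m.lifestyle == "OIE")
        n_non = sum(1 for m, _ in members if m.lifestyle == "nonOIE")
        if n_oie < min_oie or n_non < min_nonoie:
            excluded.append(
                Exclusion(
                    group.group_id,
                    "missing_lifestyle_group",
                    f"OIE={n_oie} nonOIE={n_non}",
                )
            )
            continue

        lengths = [p.length for _, p in members]
        sd = statistics.stdev(lengths) if len(lengths) > 1 else 0.0
        if not sd < sd_max:
            excluded.append(
                Exclusion(group.group_id, "sd_too_large", f"sd={sd:.6g}")
            )
            continue

        retained.append(
            OrthologSet(group.group_id, tuple(members), architecture, sd, resolved)
        )
    return retained, excluded
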