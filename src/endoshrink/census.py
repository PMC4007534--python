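"""Maximum-protein-length census and large-protein categorization.

The longest protein in any OIE proteome of a clade sets that clade's cutoff;
every nonOIE protein strictly longer is a "large protein". Large proteins are
assigned to core cellular processes or secondary/unknown processes from an
auditable category map (direct id mapping and/or ordered keyword rules), the
two categories' length distributions are compared with a Mann–Whitney test,
and each core large protein is checked for a shortened OIE ortholog —
an alignment with >65% identity covering >80% of the OIE protein's length,
either from precomputed BLAST tabular hits or by internal Smith–Waterman
(BLOSUM62, affine gap open 11 / extend 1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats

from .io_formats import BlastHit, ProteinRecord, SpeciesMeta
from .variability import mann_whitney

CENSUS_CATEGORIES = ("core", "secondary_or_unknown", "unassigned")


@dataclass(frozen=True)
class CensusEntry:
    protein_id: str
    species_id: str
    length: int
    category: str = "unassigned"
    oie_ortholog_found: bool = False


@dataclass(frozen=True)
class CladeCutoff:
    clade: str
    cutoff_aa: int


@dataclass(frozen=True)
class CategoryMap:
    """Reproducible core/secondary assignment: id map plus ordered keyword rules."""

    id_map: Mapping[str, str]
    keyword_rules: tuple[tuple[str, str], ...] = ()

    @classmethod
    def read(cls, path) -> "CategoryMap":
        """Read a TSV with columns kind (id|keyword), key, category."""
        id_map: dict[str, str] = {}
        rules: list[tuple[str, str]] = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != ["kind", "key", "category"]:
                raise ValueError(f"{path}: bad category-map header {header}")
            for line in fh:
                if not line.strip():
                    continue
                kind, key, cat = line.rstrip("\n").split("\t")
                if cat not in ("core", "secondary_or_unknown"):
                    raise ValueError(f"{path}: unknown category {cat!r}")
                if kind == "id":
                    id_map[key] = cat
                elif kind == "keyword":
                    rules.append((key.lower(), cat))
                else:
                    raise ValueError(f"{path}: unknown kind {kind!r}")
        return cls(id_map, tuple(rules))

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("kind\tkey\tcategory\n")
            for key, cat in sorted(self.id_map.items()):
                fh.write(f"id\t{key}\t{cat}\n")
            for key, cat in self.keyword_rules:
                fh.write(f"keyword\t{key}\t{cat}\n")


def max_lengths(
    proteomes: Mapping[str, Sequence[ProteinRecord]], meta: Sequence[SpeciesMeta]
) -> list[dict]:
    """Per-species maximum protein length (ties → lexicographically smallest id)."""
    by_id = {m.species_id: m for m in meta}
    rows = []
    for sid in sorted(proteomes):
        recs = proteomes[sid]
        if not recs:
            raise ValueError(f"empty proteome for {sid}")
        best = min((r for r in recs if r.length == max(x.length for x in recs)),
                   key=lambda r: r.protein_id)
        rows.append(
            {
                "species_id": sid,
                "lifestyle": by_id[sid].lifestyle,
                "max_length": best.length,
                "protein_id": best.protein_id,
            }
        )
    return rows


def derive_cutoff(
    meta: Sequence[SpeciesMeta], max_length_table: Sequence[dict], clade: str
) -> CladeCutoff:
    """Clade cutoff = maximum protein length over the clade's OIE proteomes."""
    oie_max = [
        row["max_length"] for row in max_length_table if row["lifestyle"] == "OIE"
    ]
    if not oie_max:
        raise ValueError(f"no OIE species in clade {clade}")
    return CladeCutoff(clade, int(max(oie_max)))


def extract_large(
    proteomes: Mapping[str, Sequence[ProteinRecord]],
    meta: Sequence[SpeciesMeta],
    cutoff: CladeCutoff,
) -> list[CensusEntry]:
    """nonOIE proteins strictly longer than the OIE cutoff, as census entries."""
    if cutoff.cutoff_aa <= 0:
        raise ValueError("cutoff must be positive")
    lifestyles = {m.species_id: m.lifestyle for m in meta}
    out = []
    for sid in sorted(proteomes):
        if lifestyles[sid] != "nonOIE":
            continue
        for rec in proteomes[sid]:
            if rec.length > cutoff.cutoff_aa:
                out.append(CensusEntry(rec.protein_id, sid, rec.length))
    return out


def categorize(
    entries: Sequence[CensusEntry],
    category_map: CategoryMap,
    descriptions: Mapping[str, str] | None = None,
) -> tuple[list[CensusEntry], list[str]]:
    """Assign core / secondary_or_unknown from the map; unmapped stay unassigned.

    Direct id mappings take precedence; keyword rules are applied in order to
    the protein's annotation text (``descriptions``), first match wins.
    Returns the categorized entries and the ids left unassigned.
    """
    out: list[CensusEntry] = []
    unassigned: list[str] = []
    for e in entries:
        cat = category_map.id_map.get(e.protein_id)
        if cat is None and descriptions is not None:
            text = descriptions.get(e.protein_id, "").lower()
            for kw, rule_cat in category_map.keyword_rules:
                if kw in text:
                    cat = rule_cat
                    break
        if cat is None:
            unassigned.append(e.protein_id)
            out.append(e)
        else:
            out.append(replace(e, category=cat))
    return out, unassigned


def compare_categories(entries: Sequence[CensusEntry]) -> dict:
    """Mann–Whitney comparison of large-protein lengths, core vs secondary.

    Reports U, a tie/continuity-corrected normal z, its χ² (= z²) equivalent,
    the two-sided p-value, and per-category n / mean / median.
    """
    core = [e.length for e in entries if e.category == "core"]
    sec = [e.length for e in entries if e.category == "secondary_or_unknown"]
    if len(core) < 2 or len(sec) < 2:
        raise ValueError("need ≥2 entries per category")
    a = np.asarray(core, float)
    b = np.asarray(sec, float)
    u = float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic").statistic)
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    _, tie_counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    mu = n1 * n2 / 2
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sigma = np.sqrt(n1 * n2 / 12 * (n + 1 - tie_term))
    z = 0.0 if sigma == 0 else float((u - mu - np.sign(u - mu) * 0.5) / sigma)
    return {
        "U": u,
        "z": z,
        "chi2": z * z,
        "p": mann_whitney(a, b),
        "core_n": n1,
        "core_mean": float(a.mean()),
        "core_median": float(np.median(a)),
        "secondary_n": n2,
        "secondary_mean": float(b.mean()),
        "secondary_median": float(np.median(b)),
    }


# ---------------------------------------------------------------------------
# OIE-ortholog detection


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def alignment_identity_coverage(
    query_seq: str, subject_seq: str, aligner: Align.PairwiseAligner | None = None
) -> tuple[float, float]:
    """Smith–Waterman identity (%) and subject coverage (%) of the best local hit.

    Identity = matches / alignment columns, gap columns included in the
    denominator (stricter than BLAST's matches/alignment-length over only the
    reported HSP). Coverage = aligned subject span / subject length.
    """
    if aligner is None:
        aligner = _make_aligner()
    alns = aligner.align(query_seq, subject_seq)
    if len(alns) == 0 or alns.score <= 0:
        return 0.0, 0.0
    aln = alns[0]
    counts = aln.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    if columns == 0:
        return 0.0, 0.0
    identity = 100.0 * counts.identities / columns
    subject_segments = aln.aligned[1]
    span = int(subject_segments[-1][1] - subject_segments[0][0])
    coverage = 100.0 * span / len(subject_seq)
    return identity, coverage


def _shares_kmer(a: str, b: str, k: int = 10) -> bool:
    if len(a) < k or len(b) < k:
        return True  # too short to screen; align directly
    kmers = {a[i : i + k] for i in range(len(a) - k + 1)}
    return any(b[i : i + k] in kmers for i in range(len(b) - k + 1))


def find_oie_ortholog(
    large_protein: ProteinRecord,
    oie_proteomes: Mapping[str, Sequence[ProteinRecord]] | None = None,
    blast_hits: Sequence[BlastHit] | None = None,
    subject_lengths: Mapping[str, int] | None = None,
    min_identity: float = 65.0,
    min_coverage: float = 80.0,
) -> tuple[bool, str | None]:
    """Does a large protein have a (shortened) OIE ortholog?

    True iff some OIE protein aligns with identity > ``min_identity`` percent
    over > ``min_coverage`` percent of the OIE (subject) protein's length.
    Uses precomputed BLAST tabular hits when given (``subject_lengths``
    resolves subject lengths, defaulting to the supplied OIE proteomes),
    otherwise internal Smith–Waterman with a shared-k-mer prescreen.
    Returns (found, best subject id).
    """
    if blast_hits is None and oie_proteomes is None:
        raise ValueError("supply either blast_hits or oie_proteomes")

    if blast_hits is not None:
        if subject_lengths is None:
            if oie_proteomes is None:
                raise ValueError("blast_hits need subject_lengths or oie_proteomes")
            subject_lengths = {
                r.protein_id: r.length
                for recs in oie_proteomes.values()
                for r in recs
            }
        best: tuple[float, str] | None = None
        for h in blast_hits:
            if h.query_id != large_protein.protein_id:
                continue
            slen = subject_lengths.get(h.subject_id)
            if slen is None:
                continue
            coverage = 100.0 * (abs(h.send - h.sstart) + 1) / slen
            if h.pct_identity > min_identity and coverage > min_coverage:
                if best is None or h.pct_identity > best[0]:
                    best = (h.pct_identity, h.subject_id)
        return (best is not None), (best[1] if best else None)

    aligner = _make_aligner()
    best = None
    for recs in oie_proteomes.values():
        for oie_prot in recs:
            if not _shares_kmer(large_protein.sequence, oie_prot.sequence):
                continue
            identity, coverage = alignment_identity_coverage(
                large_protein.sequence, oie_prot.sequence, aligner
            )
            if identity > min_identity and coverage > min_coverage:
                if best is None or identity > best[0]:
                    best = (identity, oie_prot.protein_id)
    return (best is not None), (best[1] if best else None)


def annotate_orthologs(
    entries: Sequence[CensusEntry],
    proteomes: Mapping[str, Sequence[ProteinRecord]],
    meta: Sequence[SpeciesMeta],
    **kwargs,
) -> list[CensusEntry]:
    """Fill ``oie_ortholog_found`` for every census entry by internal alignment."""
    lifestyles = {m.species_id: m.lifestyle for m in meta}
    oie = {sid: recs for sid, recs in proteomes.items() if lifestyles[sid] == "OIE"}
    by_key = {
        (r.species_id, r.protein_id): r for recs in proteomes.values() for r in recs
    }
    out = []
    for e in entries:
        rec = by_key[(e.species_id, e.protein_id)]
        found, _ = find_oie_ortholog(rec, oie_proteomes=oie, **kwargs)
        out.append(replace(e, oie_ortholog_found=found))
    return out
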