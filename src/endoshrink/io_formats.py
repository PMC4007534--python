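"""Readers, writers and validators for the pipeline's external file formats.

All coordinates are 1-based inclusive (Pfam convention). Tabular outputs are
TSV with a header line; floats are printed with 6 significant digits. The only
gap character is ``'-'``; ``'.'`` is normalized to ``'-'`` on read with a
warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

LIFESTYLES = ("OIE", "nonOIE")

#: amino-acid alphabet accepted in proteome FASTA files
RESIDUES = set("ACDEFGHIKLMNPQRSTVWYX")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class SpeciesMeta:
    """One species: id, taxonomic family, lifestyle (OIE/nonOIE), genome size (Mb)."""

    species_id: str
    family: str
    lifestyle: str
    genome_size_mb: float

    def __post_init__(self) -> None:
        if not self.species_id or any(c.isspace() for c in self.species_id):
            raise FormatError(f"invalid species_id {self.species_id!r}")
        if self.lifestyle not in LIFESTYLES:
            raise FormatError(
                f"lifestyle must be one of {LIFESTYLES}, got {self.lifestyle!r}"
            )
        if not self.genome_size_mb > 0:
            raise FormatError(f"genome_size_mb must be > 0, got {self.genome_size_mb}")


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence; ``length`` is always the residue count."""

    protein_id: str
    species_id: str
    sequence: str
    length: int = field(init=False)

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        bad = set(seq) - RESIDUES
        if bad:
            raise FormatError(
                f"protein {self.protein_id}: non-amino-acid characters {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "length", len(seq))


@dataclass(frozen=True)
class DomainHit:
    """One annotated domain interval on a protein (1-based inclusive)."""

    protein_id: str
    domain_accession: str
    domain_name: str
    start: int
    end: int
    evalue: float

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise FormatError(
                f"bad domain interval ({self.start},{self.end}) on {self.protein_id}"
            )
        if self.evalue < 0:
            raise FormatError(f"negative e-value on {self.protein_id}")

    @property
    def span(self) -> int:
        """Domain length in residues (end − start + 1)."""
        return self.end - self.start + 1


@dataclass(frozen=True)
class OrthologGroup:
    """Raw ortholog cluster as read from an OrthoMCL-style groups file."""

    group_id: str
    members: tuple[tuple[str, str], ...]  # (species_id, protein_id)


@dataclass(frozen=True)
class AlignmentBlock:
    """A multiple sequence alignment: equal-width rows over residues ∪ {'-'}."""

    group_id: str
    rows: tuple[tuple[str, str], ...]  # (protein_id, aligned string)
    width: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.rows:
            raise FormatError(f"alignment {self.group_id}: no rows")
        widths = {len(s) for _, s in self.rows}
        if len(widths) != 1:
            raise FormatError(
                f"alignment {self.group_id}: ragged rows (widths {sorted(widths)})"
            )
        object.__setattr__(self, "width", widths.pop())

    def degapped(self, protein_id: str) -> str:
        for pid, row in self.rows:
            if pid == protein_id:
                return row.replace("-", "")
        raise KeyError(protein_id)

    def total_gaps(self) -> int:
        return sum(row.count("-") for _, row in self.rows)


@dataclass(frozen=True)
class BlastHit:
    """One row of NCBI BLAST tabular output (outfmt 6, 12 columns)."""

    query_id: str
    subject_id: str
    pct_identity: float
    align_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0 <= self.pct_identity <= 100:
            raise FormatError(f"pct_identity {self.pct_identity} outside [0,100]")
        if self.align_length <= 0:
            raise FormatError("align_length must be positive")


# ---------------------------------------------------------------------------
# readers


def read_species_meta(path: str | Path) -> list[SpeciesMeta]:
    """Read the species metadata TSV (species_id, family, lifestyle, genome_size_mb)."""
    path = Path(path)
    out: list[SpeciesMeta] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expect = ["species_id", "family", "lifestyle", "genome_size_mb"]
        if header != expect:
            raise FormatError(f"{path}: expected header {expect}, got {header}")
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}:{ln}: expected 4 columns")
            m = SpeciesMeta(parts[0], parts[1], parts[2], float(parts[3]))
            if m.species_id in seen:
                raise FormatError(f"{path}: duplicate species_id {m.species_id}")
            seen.add(m.species_id)
            out.append(m)
    return out


def read_proteomes(
    paths: Sequence[str | Path], meta: Sequence[SpeciesMeta]
) -> dict[str, list[ProteinRecord]]:
    """Load one FASTA proteome per species; the file stem is the species id.

    Duplicate protein ids within a file, empty files and species absent from
    the metadata table are errors.
    """
    known = {m.species_id for m in meta}
    proteomes: dict[str, list[ProteinRecord]] = {}
    for p in paths:
        p = Path(p)
        species_id = p.stem
        if species_id not in known:
            raise FormatError(f"{p}: species {species_id!r} not in metadata table")
        records: list[ProteinRecord] = []
        seen: set[str] = set()
        for rec in SeqIO.parse(str(p), "fasta"):
            if rec.id in seen:
                raise FormatError(f"{p}: duplicate protein_id {rec.id}")
            seen.add(rec.id)
            records.append(ProteinRecord(rec.id, species_id, str(rec.seq)))
        if not records:
            raise FormatError(f"{p}: empty proteome")
        proteomes[species_id] = records
    return proteomes


DOMAIN_HEADER = ["protein_id", "domain_accession", "domain_name", "start", "end", "evalue"]


def read_domain_table(
    path: str | Path,
    proteomes: Mapping[str, list[ProteinRecord]],
    on_error: str = "warn",
) -> list[DomainHit]:
    """Read the Pfam-style domain TSV and validate hits against protein lengths.

    Hits whose ``end`` exceeds the protein length, and hits on unknown
    proteins, are skipped with a warning when ``on_error='warn'`` (the
    default) or raise with ``on_error='raise'``. Returned hits are sorted by
    (protein_id, start).
    """
    if on_error not in ("warn", "raise"):
        raise ValueError("on_error must be 'warn' or 'raise'")
    lengths = {
        rec.protein_id: rec.length for recs in proteomes.values() for rec in recs
    }

    def problem(msg: str) -> None:
        if on_error == "raise":
            raise FormatError(msg)
        warnings.warn(msg, stacklevel=2)

    hits: list[DomainHit] = []
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != DOMAIN_HEADER:
            raise FormatError(f"{path}: expected header {DOMAIN_HEADER}, got {header}")
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 6:
                raise FormatError(f"{path}:{ln}: expected 6 columns")
            try:
                hit = DomainHit(
                    parts[0], parts[1], parts[2], int(parts[3]), int(parts[4]),
                    float(parts[5]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: malformed row ({exc})") from exc
            if hit.protein_id not in lengths:
                problem(f"{path}:{ln}: unknown protein {hit.protein_id}; skipped")
                continue
            if hit.end > lengths[hit.protein_id]:
                problem(
                    f"{path}:{ln}: domain end {hit.end} beyond protein "
                    f"{hit.protein_id} length {lengths[hit.protein_id]}; rejected"
                )
                continue
            hits.append(hit)
    hits.sort(key=lambda h: (h.protein_id, h.start, h.end))
    return hits


def read_groups(path: str | Path) -> list[OrthologGroup]:
    """Read an OrthoMCL-dialect groups file: ``gid: spA|p1 spB|p2 ...``."""
    groups: list[OrthologGroup] = []
    seen: set[str] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if ":" not in line:
                raise FormatError(f"{path}:{ln}: missing ':' separator")
            gid, rest = line.split(":", 1)
            gid = gid.strip()
            if gid in seen:
                raise FormatError(f"{path}: duplicate group id {gid}")
            seen.add(gid)
            members = []
            for tok in rest.split():
                if "|" not in tok:
                    raise FormatError(f"{path}:{ln}: malformed member {tok!r}")
                sid, pid = tok.split("|", 1)
                members.append((sid, pid))
            groups.append(OrthologGroup(gid, tuple(members)))
    return groups


def read_alignment(path: str | Path, group_id: str | None = None) -> AlignmentBlock:
    """Read an aligned FASTA file into an :class:`AlignmentBlock`.

    ``'.'`` gap characters are normalized to ``'-'`` with a warning.
    """
    path = Path(path)
    rows: list[tuple[str, str]] = []
    dotted = False
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq).upper()
        if "." in s:
            dotted = True
            s = s.replace(".", "-")
        rows.append((rec.id, s))
    if dotted:
        warnings.warn(f"{path}: '.' gap characters normalized to '-'", stacklevel=2)
    if group_id is None:
        group_id = path.stem.split(".")[0]
    return AlignmentBlock(group_id, tuple(rows))


def read_blast_tab(path: str | Path) -> list[BlastHit]:
    """Read 12-column NCBI BLAST tabular output (``-outfmt 6``)."""
    hits: list[BlastHit] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 12:
                raise FormatError(f"{path}:{ln}: expected 12 columns, got {len(parts)}")
            try:
                hits.append(
                    BlastHit(
                        parts[0], parts[1], float(parts[2]), int(parts[3]),
                        int(parts[4]), int(parts[5]), int(parts[6]), int(parts[7]),
                        int(parts[8]), int(parts[9]), float(parts[10]),
                        float(parts[11]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-numeric field ({exc})") from exc
    return hits


def validate_alignment(
    block: AlignmentBlock, proteins: Mapping[str, ProteinRecord]
) -> None:
    """Check that each alignment row, gaps removed, equals its source sequence."""
    for pid, row in block.rows:
        if pid not in proteins:
            raise FormatError(f"alignment {block.group_id}: unknown protein {pid}")
        if row.replace("-", "") != proteins[pid].sequence:
            raise FormatError(
                f"alignment {block.group_id}: row {pid} does not match its "
                f"protein sequence after gap removal"
            )


# ---------------------------------------------------------------------------
# writers


def fmt_value(v) -> str:
    if isinstance(v, bool):
        return str(v)
    if isinstance(v, float):
        if math.isnan(v):
            return "NA"
        return f"{v:.6g}"
    return str(v)


def write_table(records: Iterable, path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write dataclass records (or mappings) as TSV; floats at 6 sig. digits."""
    records = list(records)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if not records:
        with open(path, "w") as fh:
            if columns:
                fh.write("\t".join(columns) + "\n")
        return
    first = records[0]
    if columns is None:
        if hasattr(first, "__dataclass_fields__"):
            columns = [f.name for f in fields(first)]
        else:
            columns = list(first.keys())
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for rec in records:
            get = rec.get if isinstance(rec, Mapping) else lambda c: getattr(rec, c)
            fh.write("\t".join(fmt_value(get(c)) for c in columns) + "\n")


def write_species_meta(meta: Sequence[SpeciesMeta], path: str | Path) -> None:
    write_table(meta, path)


def write_proteome(records: Sequence[ProteinRecord], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.protein_id, description="") for r in records),
        str(path), "fasta",
    )


def write_domain_table(hits: Sequence[DomainHit], path: str | Path) -> None:
    write_table(hits, path, columns=DOMAIN_HEADER)


def write_groups(groups: Sequence[OrthologGroup], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for g in groups:
            toks = " ".join(f"{sid}|{pid}" for sid, pid in g.members)
            fh.write(f"{g.group_id}: {toks}\n")


def write_alignment(block: AlignmentBlock, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for pid, row in block.rows:
            fh.write(f">{pid}\n{row}\n")


def write_blast_tab(hits: Sequence[BlastHit], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id, h.subject_id, f"{h.pct_identity:.2f}",
                        h.align_length, h.mismatches, h.gap_opens, h.qstart,
                        h.qend, h.sstart, h.send, f"{h.evalue:.3g}",
                        f"{h.bitscore:.1f}",
                    )
                )
                + "\n"
            )
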