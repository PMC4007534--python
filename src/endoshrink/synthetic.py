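"""Synthetic proteome bundles with the statistical structure the analysis assumes.

The generator emulates, at desk scale, the comparative setting the pipeline
analyzes: two lifestyle groups of bacterial species whose ortholog lengths
differ in *variance* but not in mean (OIE copies receive larger random indel
length offsets than nonOIE copies), shared ordered domain architectures
across every member of a set, indels biased toward the sequence terminuses,
and large accessory proteins planted only in nonOIE proteomes — plus a few
"core" large proteins whose shortened OIE counterparts remain detectable at
the >65% identity / >80% coverage thresholds.

Every ortholog set starts from one random base sequence with 1–3
non-overlapping planted domains. Per-species copies apply point
substitutions (default 2%, low enough that planted identity thresholds hold
deterministically) and at most one indel confined to a linker region, whose
signed length is drawn from a normal with the lifestyle's jitter SD. Because
indels never touch domains, domain totals are constant within a set and all
length variance is linker variance — the decomposition ground truth is exact
by construction. Alignments are reconstructed from the recorded edits (a
deterministic "toy aligner": no heuristic search), so removing gaps recovers
every input sequence exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .census import CategoryMap
from .io_formats import (
    AlignmentBlock,
    DomainHit,
    OrthologGroup,
    ProteinRecord,
    SpeciesMeta,
    write_alignment,
    write_domain_table,
    write_groups,
    write_proteome,
    write_species_meta,
)

AA = "ACDEFGHIKLMNPQRSTVWY"

# linker geometry of planted base sequences (aa residues)
TAIL_MIN = 45
GAP_MIN = 12
DOMAIN_MIN, DOMAIN_MAX = 30, 80


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the analyzed comparison: OIE ortholog copies jitter with
    SD 10 aa versus 2 aa for nonOIE, 80% of indels land in the terminal 10%
    of the sequence, and each nonOIE proteome carries two large accessory
    proteins (≥1,600 aa, secondary processes) absent from OIE proteomes. The
    longest OIE protein is a planted 1,420-aa anchor, the clade's census
    cutoff; core large proteins sit between the cutoff and 1,600 aa and keep
    shortened OIE counterparts.
    """

    seed: int = 0
    n_species_oie: int = 6
    n_species_nonoie: int = 6
    n_sets: int = 50
    base_length_range: tuple[int, int] = (240, 600)
    domain_count_range: tuple[int, int] = (1, 3)
    jitter_sd_oie: float = 10.0
    jitter_sd_nonoie: float = 2.0
    substitution_rate: float = 0.02
    terminal_indel_fraction: float = 0.8
    terminal_window: float = 0.1
    n_large_accessory_per_nonoie: int = 2
    large_length_range: tuple[int, int] = (1600, 3000)
    n_core_large_pairs: int = 2
    oie_anchor_length: int = 1420
    core_large_length_range: tuple[int, int] = (1450, 1600)
    core_counterpart_length_range: tuple[int, int] = (1250, 1420)
    n_replicates: int = 3
    plant_errors: bool = False

    def __post_init__(self) -> None:
        for lo, hi in (
            self.base_length_range, self.domain_count_range,
            self.large_length_range, self.core_large_length_range,
            self.core_counterpart_length_range,
        ):
            if lo > hi:
                raise ValueError(f"invalid range ({lo},{hi})")
        if self.jitter_sd_oie < 0 or self.jitter_sd_nonoie < 0:
            raise ValueError("jitter SDs must be ≥ 0")
        if not 0 <= self.terminal_indel_fraction <= 1:
            raise ValueError("terminal_indel_fraction must be in [0,1]")
        if not 0 < self.terminal_window <= 0.5:
            raise ValueError("terminal_window must be in (0, 0.5]")
        lo = self.base_length_range[0]
        need = 2 * TAIL_MIN + DOMAIN_MIN
        if lo < need:
            raise ValueError(
                f"base_length_range minimum {lo} cannot hold two {TAIL_MIN}-aa "
                f"tails and one domain (need ≥ {need})"
            )
        if self.core_counterpart_length_range[1] > self.oie_anchor_length:
            raise ValueError("core counterparts must not exceed the OIE anchor")


@dataclass
class SimTruth:
    """Generator bookkeeping used by tests as ground truth."""

    decomposition: dict[str, tuple[int, int, int]] = field(default_factory=dict)
    set_base_len: dict[str, int] = field(default_factory=dict)
    large_accessory_ids: list[str] = field(default_factory=list)
    core_pairs: list[tuple[str, str]] = field(default_factory=list)
    anchor_id: str | None = None
    cutoff: int | None = None


@dataclass
class SimBundle:
    config: SimConfig
    meta: list[SpeciesMeta]
    proteomes: dict[str, list[ProteinRecord]]
    groups: list[OrthologGroup]
    domain_hits: list[DomainHit]
    alignments: dict[str, list[AlignmentBlock]]  # group_id → replicate blocks
    category_map: CategoryMap
    truth: SimTruth


# ---------------------------------------------------------------------------
# toy alignment from recorded edits


def toy_align(
    group_id: str,
    base_len: int,
    rows: Sequence[tuple[str, str, frozenset[int], Mapping[int, str]]],
) -> AlignmentBlock:
    """Reconstruct the alignment implied by recorded per-sequence edits.

    Each row is (protein_id, substituted base copy of length ``base_len``,
    deleted base indices, insertions keyed by 0-based after-index, −1 for a
    prefix). No heuristic search: columns are the base positions plus one
    block per insertion site sized to the longest insertion there. Removing
    gaps from a row recovers that sequence exactly.
    """
    ins_width: dict[int, int] = {}
    for _, _, _, insertions in rows:
        for p, s in insertions.items():
            ins_width[p] = max(ins_width.get(p, 0), len(s))
    aligned: list[tuple[str, str]] = []
    for pid, sub_seq, deleted, insertions in rows:
        if len(sub_seq) != base_len:
            raise ValueError(f"{pid}: substituted copy length != base length")
        parts: list[str] = []
        for p in sorted(ins_width):
            if p == -1:
                ins = insertions.get(-1, "")
                parts.append(ins + "-" * (ins_width[-1] - len(ins)))
        for i in range(base_len):
            parts.append("-" if i in deleted else sub_seq[i])
            if i in ins_width:
                ins = insertions.get(i, "")
                parts.append(ins + "-" * (ins_width[i] - len(ins)))
        aligned.append((pid, "".join(parts)))
    return AlignmentBlock(group_id, tuple(aligned))


def _apply_edits(
    sub_seq: str, deleted: frozenset[int], insertions: Mapping[int, str]
) -> str:
    out = [insertions.get(-1, "")]
    for i, c in enumerate(sub_seq):
        if i not in deleted:
            out.append(c)
        if i in insertions:
            out.append(insertions[i])
    return "".join(out)


# ---------------------------------------------------------------------------
# generation helpers


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AA), size=n))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            alt = AA.replace(chars[i], "")
            chars[i] = alt[rng.integers(len(alt))]
    return "".join(chars)


def _plan_domains(
    rng: np.random.Generator, base_len: int, count_range: tuple[int, int]
) -> list[tuple[int, int]]:
    """Plant non-overlapping 1-based domain intervals with ≥TAIL_MIN tails."""
    max_n = (base_len - 2 * TAIL_MIN + GAP_MIN) // (DOMAIN_MIN + GAP_MIN)
    lo = min(count_range[0], max_n)
    hi = min(count_range[1], max_n)
    n = int(rng.integers(lo, hi + 1))
    budget = base_len - 2 * TAIL_MIN - GAP_MIN * (n - 1)
    lens = []
    for k in range(n):
        cap = min(DOMAIN_MAX, budget - DOMAIN_MIN * (n - 1 - k))
        lens.append(int(rng.integers(DOMAIN_MIN, cap + 1)))
        budget -= lens[-1]
    slack = budget  # leftover linker residues to distribute
    extra = rng.multinomial(slack, [1.0 / (n + 1)] * (n + 1))
    intervals = []
    pos = TAIL_MIN + int(extra[0])  # 0-based start of first domain
    for k in range(n):
        start = pos + 1
        end = start + lens[k] - 1
        intervals.append((start, end))
        pos = end + GAP_MIN + int(extra[k + 1]) if k + 1 < n else end
    return intervals


def _linker_regions(
    base_len: int, domains: Sequence[tuple[int, int]]
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """(terminal, internal) linker regions as 0-based inclusive index ranges."""
    if not domains:
        return [(0, base_len - 1)], []
    terminal = [(0, domains[0][0] - 2), (domains[-1][1], base_len - 1)]
    internal = [
        (domains[k][1], domains[k + 1][0] - 2) for k in range(len(domains) - 1)
    ]
    return terminal, internal


def _draw_indel(
    rng: np.random.Generator,
    base_len: int,
    domains: Sequence[tuple[int, int]],
    jitter_sd: float,
    terminal_fraction: float,
    terminal_window: float = 0.1,
) -> tuple[frozenset[int], dict[int, str]]:
    """One linker-confined indel with signed length ~ round(N(0, jitter_sd)).

    With probability ``terminal_fraction`` the indel goes into the terminal
    ``terminal_window`` fraction of the sequence (intersected with the tail
    linker); otherwise its position is uniform over all linker regions.
    """
    offset = int(round(rng.normal(0.0, jitter_sd))) if jitter_sd > 0 else 0
    if offset == 0:
        return frozenset(), {}
    terminal, internal = _linker_regions(base_len, domains)
    all_regions = terminal + internal
    if rng.random() < terminal_fraction:
        w = max(12, int(round(terminal_window * base_len)))
        n_tail = (terminal[0][0], min(terminal[0][1], terminal[0][0] + w - 1))
        c_tail = (max(terminal[-1][0], terminal[-1][1] - w + 1), terminal[-1][1])
        region = (n_tail, c_tail)[int(rng.integers(2))]
    else:
        region = all_regions[rng.integers(len(all_regions))]
    r_lo, r_hi = region
    region_len = r_hi - r_lo + 1
    if offset < 0:
        d = min(-offset, max(region_len - 6, 0))
        if d == 0:
            return frozenset(), {}
        s = int(rng.integers(r_lo, r_hi - d + 2))
        return frozenset(range(s, s + d)), {}
    p = int(rng.integers(r_lo - 1, r_hi + 1))  # insert after index p
    return frozenset(), {p: _random_seq(rng, offset)}


# ---------------------------------------------------------------------------
# dataset generation


def simulate_dataset(config: SimConfig, out_dir: str | Path | None = None) -> SimBundle:
    """Generate a full, internally consistent synthetic input bundle.

    A fixed seed yields a byte-identical bundle on disk. When ``out_dir`` is
    given, all input files (metadata, proteome FASTAs, groups, domain table,
    replicate alignments, category map) are written there.
    """
    rng = np.random.default_rng(config.seed)

    meta: list[SpeciesMeta] = []
    for i in range(config.n_species_oie):
        meta.append(
            SpeciesMeta(
                f"OIE{i:02d}", "Simulobacteriaceae", "OIE",
                round(float(rng.uniform(0.24, 0.9)), 3),
            )
        )
    for i in range(config.n_species_nonoie):
        meta.append(
            SpeciesMeta(
                f"NON{i:02d}", "Simulobacteriaceae", "nonOIE",
                round(float(rng.uniform(2.0, 6.1)), 3),
            )
        )

    proteomes: dict[str, list[ProteinRecord]] = {m.species_id: [] for m in meta}
    groups: list[OrthologGroup] = []
    hits: list[DomainHit] = []
    alignments: dict[str, list[AlignmentBlock]] = {}
    truth = SimTruth()
    set_info: list[dict] = []  # kept for error planting

    for g in range(config.n_sets):
        gid = f"g{g:03d}"
        base_len = int(rng.integers(*config.base_length_range, endpoint=True))
        domains = _plan_domains(rng, base_len, config.domain_count_range)
        base_seq = _random_seq(rng, base_len)
        accs = [f"PF{g * 10 + k:05d}" for k in range(len(domains))]
        domain_total = sum(e - s + 1 for s, e in domains)
        truth.set_base_len[gid] = base_len

        members: list[tuple[str, str]] = []
        rows = []
        for m in meta:
            sd = config.jitter_sd_oie if m.lifestyle == "OIE" else config.jitter_sd_nonoie
            pid = f"{m.species_id}_{gid}"
            sub_seq = _mutate(rng, base_seq, config.substitution_rate)
            deleted, insertions = _draw_indel(
                rng, base_len, domains, sd, config.terminal_indel_fraction,
                config.terminal_window,
            )
            seq = _apply_edits(sub_seq, deleted, insertions)
            proteomes[m.species_id].append(ProteinRecord(pid, m.species_id, seq))
            members.append((m.species_id, pid))
            rows.append((pid, sub_seq, deleted, insertions))
            # shift planted domain coordinates by net indel offset upstream
            ins_len = {p: len(s) for p, s in insertions.items()}
            for (s0, e0), acc in zip(domains, accs):
                shift = sum(l for p, l in ins_len.items() if p < s0 - 1)
                shift -= sum(1 for d in deleted if d < s0 - 1)
                hits.append(
                    DomainHit(
                        pid, acc, f"dom_{acc}", s0 + shift, e0 + shift,
                        float(f"{10 ** rng.uniform(-30, -5):.3g}"),
                    )
                )
            truth.decomposition[pid] = (
                len(seq), domain_total, len(seq) - domain_total
            )
        groups.append(OrthologGroup(gid, tuple(members)))
        base_block = toy_align(gid, base_len, rows)
        reps = []
        for r in range(config.n_replicates):
            order = rng.permutation(len(rows))
            reps.append(
                AlignmentBlock(gid, tuple(base_block.rows[i] for i in order))
            )
        alignments[gid] = reps
        set_info.append({"gid": gid, "members": members, "domains": domains,
                         "accs": accs, "base_seq": base_seq})

    # --- census structure -------------------------------------------------
    id_map: dict[str, str] = {}
    oie_ids = [m.species_id for m in meta if m.lifestyle == "OIE"]
    non_ids = [m.species_id for m in meta if m.lifestyle == "nonOIE"]
    plant_census = (
        config.n_large_accessory_per_nonoie > 0 or config.n_core_large_pairs > 0
    )
    if plant_census:
        anchor_id = f"{oie_ids[0]}_anchor"
        proteomes[oie_ids[0]].append(
            ProteinRecord(anchor_id, oie_ids[0],
                          _random_seq(rng, config.oie_anchor_length))
        )
        truth.anchor_id = anchor_id
        truth.cutoff = config.oie_anchor_length
        for sid in non_ids:
            for j in range(config.n_large_accessory_per_nonoie):
                pid = f"{sid}_acc{j}"
                n = int(rng.integers(*config.large_length_range, endpoint=True))
                proteomes[sid].append(ProteinRecord(pid, sid, _random_seq(rng, n)))
                truth.large_accessory_ids.append(pid)
                id_map[pid] = "secondary_or_unknown"
        for k in range(config.n_core_large_pairs):
            sid = non_ids[k % len(non_ids)]
            osid = oie_ids[k % len(oie_ids)]
            big_len = int(
                rng.integers(*config.core_large_length_range, endpoint=True)
            )
            small_len = int(
                rng.integers(*config.core_counterpart_length_range, endpoint=True)
            )
            big_seq = _random_seq(rng, big_len)
            big_pid, small_pid = f"{sid}_corelg{k}", f"{osid}_core{k}"
            proteomes[sid].append(ProteinRecord(big_pid, sid, big_seq))
            proteomes[osid].append(
                ProteinRecord(
                    small_pid, osid,
                    _mutate(rng, big_seq[:small_len], config.substitution_rate),
                )
            )
            truth.core_pairs.append((big_pid, small_pid))
            id_map[big_pid] = "core"
    category_map = CategoryMap(
        id_map,
        (("polyketide", "secondary_or_unknown"), ("polymerase", "core")),
    )

    if config.plant_errors:
        _plant_errors(rng, proteomes, groups, hits, set_info, meta)

    bundle = SimBundle(
        config, meta, proteomes, groups, hits, alignments, category_map, truth
    )
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def _plant_errors(rng, proteomes, groups, hits, set_info, meta) -> None:
    """Append deliberately invalid groups to exercise exclusion logging."""
    oie0 = next(m.species_id for m in meta if m.lifestyle == "OIE")
    non0 = next(m.species_id for m in meta if m.lifestyle == "nonOIE")
    if len(set_info) < 2:
        raise ValueError("plant_errors needs at least 2 ortholog sets")
    s0, s1 = set_info[0], set_info[1]
    s2, s3 = set_info[-2], set_info[-1]

    # inparalogs: one species contributes two proteins
    groups.append(
        OrthologGroup(
            "zz_err_inparalog",
            ((oie0, f"{oie0}_{s0['gid']}"), (oie0, f"{oie0}_{s1['gid']}"),
             (non0, f"{non0}_{s0['gid']}")),
        )
    )
    # partially overlapping domains disqualify a member
    seq = _random_seq(rng, 300)
    proteomes[oie0].append(ProteinRecord("ERR_overlap", oie0, seq))
    hits.append(DomainHit("ERR_overlap", "PF99001", "errdomA", 50, 149, 1e-10))
    hits.append(DomainHit("ERR_overlap", "PF99002", "errdomB", 100, 199, 1e-10))
    groups.append(OrthologGroup("zz_err_overlap", ((oie0, "ERR_overlap"),)))
    # gene-fusion-like member inflates the length SD past the threshold
    fused = ProteinRecord(
        "ERR_fusion", non0, s2["base_seq"] + _random_seq(rng, 300)
    )
    proteomes[non0].append(fused)
    for (st, en), acc in zip(s2["domains"], s2["accs"]):
        hits.append(DomainHit("ERR_fusion", acc, f"dom_{acc}", st, en, 1e-10))
    fmembers = tuple(
        (sid, pid) if sid != non0 else (non0, "ERR_fusion")
        for sid, pid in s2["members"]
    )
    groups.append(OrthologGroup("zz_err_fusion", fmembers))
    # one member carries an extra domain → architecture mismatch
    base3 = s3["base_seq"]
    proteomes[oie0].append(ProteinRecord("ERR_arch", oie0, base3))
    for (st, en), acc in zip(s3["domains"], s3["accs"]):
        hits.append(DomainHit("ERR_arch", acc, f"dom_{acc}", st, en, 1e-10))
    hits.append(
        DomainHit("ERR_arch", "PF99003", "extradom", len(base3) - 34,
                  len(base3) - 5, 1e-10)
    )
    amembers = tuple(
        (sid, pid) if sid != oie0 else (oie0, "ERR_arch")
        for sid, pid in s3["members"]
    )
    groups.append(OrthologGroup("zz_err_arch", amembers))


# ---------------------------------------------------------------------------
# disk layout


def write_bundle(bundle: SimBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_species_meta(bundle.meta, out / "meta.tsv")
    for sid in sorted(bundle.proteomes):
        write_proteome(bundle.proteomes[sid], out / "proteomes" / f"{sid}.faa")
    write_groups(bundle.groups, out / "groups.txt")
    write_domain_table(
        sorted(bundle.domain_hits, key=lambda h: (h.protein_id, h.start, h.end)),
        out / "domains.tsv",
    )
    for gid in sorted(bundle.alignments):
        for r, block in enumerate(bundle.alignments[gid]):
            write_alignment(block, out / "alignments" / f"{gid}.rep{r}.afa")
    bundle.category_map.write(out / "category_map.tsv")


def config_from_mapping(d: Mapping) -> SimConfig:
    """Build a SimConfig from a YAML-style mapping, tuple-izing the ranges."""
    kwargs = dict(d)
    for key in (
        "base_length_range", "domain_count_range", "large_length_range",
        "core_large_length_range", "core_counterpart_length_range",
    ):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    names = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(kwargs) - names
    if unknown:
        raise ValueError(f"unknown SimConfig fields: {sorted(unknown)}")
    return SimConfig(**kwargs)


def simulate_length_table(
    rng: np.random.Generator,
    n_sets: int,
    n_oie: int,
    n_nonoie: int,
    sd_oie: float,
    sd_nonoie: float,
    base_length_range: tuple[int, int] = (240, 600),
) -> tuple[np.ndarray, np.ndarray]:
    """Lengths-only twin of :func:`simulate_dataset` (same length model).

    Returns (n_sets × n_oie, n_sets × n_nonoie) integer length arrays where
    each row's lengths are one base length plus rounded normal jitter. Used
    for calibration studies where sequences themselves are not needed.
    """
    bases = rng.integers(*base_length_range, size=n_sets, endpoint=True)
    oie = bases[:, None] + np.round(rng.normal(0, sd_oie, (n_sets, n_oie))).astype(int)
    non = bases[:, None] + np.round(
        rng.normal(0, sd_nonoie, (n_sets, n_nonoie))
    ).astype(int)
    return oie, non
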