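"""High-level pipeline stages over a bundle directory.

The CLI subcommands, the numbered analysis drivers and the acceptance script
all go through these functions; each stage returns in-memory results and can
write its TSV outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from . import census as census_mod
from . import curation, decomposition, gap_profile, io_formats, variability
from .census import CategoryMap
from .io_formats import AlignmentBlock, write_table


@dataclass
class BundleInputs:
    meta: list
    proteomes: dict
    groups: list
    domain_hits: list
    alignments: dict[str, list[AlignmentBlock]]
    category_map: CategoryMap | None


def load_bundle_dir(data_dir: str | Path, validate_alignments: bool = True) -> BundleInputs:
    """Load a simulate-layout data directory and cross-validate its files."""
    d = Path(data_dir)
    meta = io_formats.read_species_meta(d / "meta.tsv")
    fastas = sorted((d / "proteomes").glob("*.faa"))
    if not fastas:
        raise FileNotFoundError(f"no proteome FASTAs under {d/'proteomes'}")
    proteomes = io_formats.read_proteomes(fastas, meta)
    groups = io_formats.read_groups(d / "groups.txt")
    hits = io_formats.read_domain_table(d / "domains.tsv", proteomes)
    by_id = {
        r.protein_id: r for recs in proteomes.values() for r in recs
    }
    alignments: dict[str, list[AlignmentBlock]] = {}
    for path in sorted((d / "alignments").glob("*.afa")):
        block = io_formats.read_alignment(path)
        if validate_alignments:
            io_formats.validate_alignment(block, by_id)
        alignments.setdefault(block.group_id, []).append(block)
    cmap_path = d / "category_map.tsv"
    cmap = CategoryMap.read(cmap_path) if cmap_path.exists() else None
    return BundleInputs(meta, proteomes, groups, hits, alignments, cmap)


def run_curation(
    inputs: BundleInputs,
    sd_max: float = 30.0,
    evalue_max: float = 1.0,
    out_dir: str | Path | None = None,
):
    sets, exclusions = curation.curate_sets(
        inputs.groups, inputs.proteomes, inputs.domain_hits, inputs.meta,
        sd_max=sd_max, evalue_max=evalue_max,
    )
    if out_dir is not None:
        out = Path(out_dir)
        write_table(
            [
                {
                    "group_id": s.group_id,
                    "n_members": len(s.members),
                    "architecture": ";".join(s.architecture),
                    "length_sd": s.length_sd,
                }
                for s in sets
            ],
            out / "sets.tsv",
            columns=["group_id", "n_members", "architecture", "length_sd"],
        )
        write_table(exclusions, out / "exclusions.tsv",
                    columns=["group_id", "reason", "detail"])
    return sets, exclusions


def run_decomposition(sets, out_dir: str | Path | None = None):
    decomps = decomposition.decompose_all(sets)
    if out_dir is not None:
        rows = []
        for s in sets:
            for m, p in s.members:
                d = decomps[s.group_id][p.protein_id]
                rows.append(
                    {
                        "protein_id": p.protein_id,
                        "species_id": m.species_id,
                        "group_id": s.group_id,
                        "total_len": d.total_len,
                        "domain_len": d.domain_len,
                        "linker_len": d.linker_len,
                    }
                )
        write_table(rows, Path(out_dir) / "decomposition.tsv")
    return decomps


def run_variability(sets, decomps, meta, out_dir: str | Path | None = None):
    """Dispersion, classification, group comparison, regressions and bubbles."""
    dispersions = variability.dispersion_records(sets, decomps, "total")
    classifications = variability.classify_sets(sets, decomps, "total")
    summary = variability.summarize_classification(classifications)
    comparison = variability.group_comparison_table(dispersions)
    averages = variability.per_species_average_lengths(sets)
    var_avg = variability.variance_of_averages(averages, meta)
    genome = {m.species_id: m.genome_size_mb for m in meta}
    fit = None
    if len(averages) >= 3:
        sids = sorted(averages)
        fit = variability.fit_regression(
            [genome[s] for s in sids], [averages[s] for s in sids]
        )
    bubbles = [row for s in sets for row in variability.bubble_table(s)]
    if out_dir is not None:
        out = Path(out_dir)
        write_table(dispersions, out / "dispersion.tsv")
        write_table(summary, out / "classification.tsv")
        write_table(comparison, out / "group_comparison.tsv")
        reg_rows = [
            {"response": "avg_ortholog_length_vs_genome_size",
             "slope": fit.slope, "intercept": fit.intercept,
             "r_squared": fit.r_squared, "p_value": fit.p_value, "n": fit.n}
        ] if fit else []
        write_table(reg_rows, out / "regressions.tsv",
                    columns=["response", "slope", "intercept", "r_squared",
                             "p_value", "n"])
        write_table(bubbles, out / "bubbles.tsv",
                    columns=["group_id", "lifestyle", "length", "proportion"])
        write_table(
            [{"lifestyle": k, "variance_of_averages": v} for k, v in var_avg.items()],
            out / "variance_of_averages.tsv",
            columns=["lifestyle", "variance_of_averages"],
        )
    return {
        "dispersions": dispersions,
        "classifications": classifications,
        "summary": summary,
        "comparison": comparison,
        "variance_of_averages": var_avg,
        "regression": fit,
        "bubbles": bubbles,
    }


def run_gap_profile(
    alignments: Mapping[str, Sequence[AlignmentBlock]],
    out_dir: str | Path | None = None,
):
    """Averaged 10(+1)-section gap profiles and terminal bias per ortholog set."""
    rows = []
    for gid in sorted(alignments):
        mean_counts, bias = gap_profile.profile_with_replicates(alignments[gid])
        rows.append(
            {
                "group_id": gid,
                **{f"s{i+1}": mean_counts[i] for i in range(11)},
                "terminal_bias": bias,
            }
        )
    if out_dir is not None:
        write_table(
            rows, Path(out_dir) / "gap_profile.tsv",
            columns=["group_id"] + [f"s{i+1}" for i in range(11)] + ["terminal_bias"],
        )
    return rows


def run_census(
    inputs: BundleInputs,
    clade: str = "synthetic",
    out_dir: str | Path | None = None,
    align_orthologs: bool = True,
):
    """Maximum-length table, large-protein extraction, categorization, tests."""
    table = census_mod.max_lengths(inputs.proteomes, inputs.meta)
    cutoff = census_mod.derive_cutoff(inputs.meta, table, clade)
    entries = census_mod.extract_large(inputs.proteomes, inputs.meta, cutoff)
    unassigned: list[str] = []
    if inputs.category_map is not None:
        entries, unassigned = census_mod.categorize(entries, inputs.category_map)
    if align_orthologs:
        entries = census_mod.annotate_orthologs(entries, inputs.proteomes, inputs.meta)
    comparison = None
    n_core = sum(1 for e in entries if e.category == "core")
    n_sec = sum(1 for e in entries if e.category == "secondary_or_unknown")
    if n_core >= 2 and n_sec >= 2:
        comparison = census_mod.compare_categories(entries)
    if out_dir is not None:
        out = Path(out_dir)
        write_table(table, out / "max_lengths.tsv",
                    columns=["species_id", "lifestyle", "max_length", "protein_id"])
        write_table(entries, out / "census.tsv")
        if comparison is not None:
            write_table([comparison], out / "category_comparison.tsv")
    return {
        "max_lengths": table,
        "cutoff": cutoff,
        "entries": entries,
        "unassigned": unassigned,
        "comparison": comparison,
    }


def run_all(
    data_dir: str | Path,
    out_dir: str | Path,
    sd_max: float = 30.0,
    evalue_max: float = 1.0,
    clade: str = "synthetic",
) -> dict:
    """Execute curate → decompose → varstats, gap profile and census."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = load_bundle_dir(data_dir)
    sets, exclusions = run_curation(inputs, sd_max, evalue_max, out)
    decomps = run_decomposition(sets, out)
    varres = run_variability(sets, decomps, inputs.meta, out)
    curated_aln = {
        gid: blocks for gid, blocks in inputs.alignments.items()
        if gid in {s.group_id for s in sets}
    }
    gap_rows = run_gap_profile(curated_aln, out)
    census_res = run_census(inputs, clade, out)
    return {
        "inputs": inputs,
        "sets": sets,
        "exclusions": exclusions,
        "decompositions": decomps,
        "variability": varres,
        "gap_profile": gap_rows,
        "census": census_res,
    }
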