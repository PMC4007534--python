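"""Positional gap profiling of ortholog alignments.

Each alignment is divided along its columns into 10 equal sections of
floor(width/10) columns, plus an 11th C-terminal section holding the
remainder when the width is not divisible by 10. Gap characters ('-') are
counted per section, pooled over all rows. Replicate alignments (the same
sequences aligned after shuffling input order) are averaged, and a terminal
bias statistic — the fraction of mean gap counts falling in sections
1, 2, 9, 10 and 11 — summarizes whether indels concentrate at the protein
terminuses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import AlignmentBlock

#: section indices (0-based) counted as terminal in an 11-section profile
TERMINAL_SECTIONS = (0, 1, 8, 9, 10)


@dataclass(frozen=True)
class SectionProfile:
    group_id: str
    section_counts: tuple[int, ...]
    section_widths: tuple[int, ...]
    replicate_id: int = 0

    def __post_init__(self) -> None:
        if len(self.section_counts) != len(self.section_widths):
            raise ValueError("counts/widths length mismatch")


def section_bounds(width: int) -> list[tuple[int, int]]:
    """1-based inclusive column intervals of the 10(+1) sections.

    Widths below 10 are rejected rather than producing zero-width sections.
    """
    if width < 10:
        raise ValueError(f"alignment width {width} < 10")
    size = width // 10
    bounds = [(i * size + 1, (i + 1) * size) for i in range(10)]
    if width % 10:
        bounds.append((10 * size + 1, width))
    return bounds


def profile_alignment(block: AlignmentBlock, replicate_id: int = 0) -> SectionProfile:
    """Count gaps per section, pooled over all alignment rows."""
    bounds = section_bounds(block.width)
    counts = []
    for start, end in bounds:
        counts.append(sum(row.count("-", start - 1, end) for _, row in block.rows))
    return SectionProfile(
        block.group_id,
        tuple(counts),
        tuple(end - start + 1 for start, end in bounds),
        replicate_id,
    )


def per_row_profiles(block: AlignmentBlock) -> dict[str, tuple[int, ...]]:
    """Long-format per-sequence gap counts (same sections as the pooled profile)."""
    bounds = section_bounds(block.width)
    return {
        pid: tuple(row.count("-", s - 1, e) for s, e in bounds)
        for pid, row in block.rows
    }


def terminal_bias(mean_counts: Sequence[float]) -> float:
    """Fraction of mean gap counts in the terminal sections (1,2,9,10,11).

    NaN for a gap-free alignment.
    """
    arr = np.asarray(mean_counts, dtype=float)
    total = arr.sum()
    if total == 0:
        return float("nan")
    idx = [i for i in TERMINAL_SECTIONS if i < arr.size]
    return float(arr[idx].sum() / total)


def profile_with_replicates(
    blocks: Sequence[AlignmentBlock],
) -> tuple[np.ndarray, float]:
    """Average section gap counts over replicate alignments + terminal bias.

    Replicates must align the same sequence set (row identity check); widths
    may differ between replicates (heuristic aligners need not agree), so
    profiles are padded with zeros to 11 sections before averaging.
    """
    if not blocks:
        raise ValueError("no replicate alignments supplied")
    ids0 = sorted(pid for pid, _ in blocks[0].rows)
    for b in blocks[1:]:
        if sorted(pid for pid, _ in b.rows) != ids0:
            raise ValueError(
                f"replicates of {blocks[0].group_id} align different sequence sets"
            )
    mat = np.zeros((len(blocks), 11))
    for i, b in enumerate(blocks):
        counts = profile_alignment(b, replicate_id=i).section_counts
        mat[i, : len(counts)] = counts
    mean_counts = mat.mean(axis=0)
    return mean_counts, terminal_bias(mean_counts)
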