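"""Per-position 5'P count tracks: loading, CPM normalization, replicate
pooling and pairwise log2 comparison.

Tracks are sparse maps keyed by ``(chromosome, strand, position)``; the two
genomic strands live in separate bedGraph files and are tagged with the
strand at load time. Comparison semantics: a fixed pseudocount is added to
both sides of every ratio and positions where both inputs are zero are
skipped rather than scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "GENOTYPES",
    "TrackError",
    "RawProfile",
    "NormalizedProfile",
    "ComparisonTrack",
    "load_bedgraph",
    "write_bedgraph",
    "cpm_normalize",
    "merge_replicates",
    "replicate_correlation",
    "log2_compare",
]

GENOTYPES = ("wild_type", "xrn4", "dne1_xrn4", "cap_pare", "other")

Key = tuple[str, str, int]


class TrackError(ValueError):
    """Malformed or inconsistent count-track input."""


def _check_genotype(genotype: str) -> None:
    if genotype not in GENOTYPES:
        raise TrackError(f"unknown genotype {genotype!r}; expected one of {GENOTYPES}")


@dataclass
class RawProfile:
    """Sparse per-position raw 5'-end counts for one library."""

    library_id: str
    genotype: str
    replicate: int
    counts: dict[Key, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_genotype(self.genotype)
        self.counts = {k: int(v) for k, v in self.counts.items() if v != 0}
        for k, v in self.counts.items():
            if v < 0:
                raise TrackError(f"negative count {v} at {k}")

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class NormalizedProfile:
    """Per-position CPM values for one library (or a replicate pool)."""

    library_id: str
    genotype: str
    replicate: int
    values: dict[Key, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_genotype(self.genotype)

    def get(self, key: Key) -> float:
        return self.values.get(key, 0.0)


@dataclass
class ComparisonTrack:
    """log2((numerator + pc) / (denominator + pc)) per position.

    Positions where both inputs are zero are absent; their count is kept in
    ``skipped_zero_pairs``.
    """

    numerator_id: str
    denominator_id: str
    pseudocount: float
    values: dict[Key, float]
    skipped_zero_pairs: int = 0

    def get(self, key: Key) -> Optional[float]:
        return self.values.get(key)


# ------------------------------------------------------------------- bedGraph


def load_bedgraph(
    path: str | Path,
    strand: str,
    library_id: str,
    genotype: str,
    replicate: int = 1,
) -> RawProfile:
    """Read a 4-column bedGraph (0-based half-open) for one strand.

    Width-w intervals are expanded to w per-base entries with the interval's
    value. Overlapping intervals and negative values are errors; zero-valued
    intervals are dropped.
    """
    if strand not in ("+", "-"):
        raise TrackError(f"strand must be '+' or '-', got {strand!r}")
    counts: dict[Key, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise TrackError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            chrom, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if e <= s:
                raise TrackError(f"{path}:{lineno}: empty interval [{s},{e})")
            if v < 0:
                raise TrackError(f"{path}:{lineno}: negative value {v}")
            iv = int(round(v))
            if iv == 0:
                continue
            for pos in range(s, e):
                key = (chrom, strand, pos)
                if key in counts:
                    raise TrackError(f"{path}:{lineno}: overlapping interval at {key}")
                counts[key] = iv
    return RawProfile(library_id=library_id, genotype=genotype, replicate=replicate, counts=counts)


def write_bedgraph(values: dict[Key, float | int], strand: str, path: str | Path) -> None:
    """Write one strand of a sparse track as 4-column bedGraph, collapsing
    runs of adjacent positions with equal value."""
    keys = sorted(k for k in values if k[1] == strand)
    with open(path, "w") as fh:
        run_chrom, run_start, run_end, run_val = None, 0, 0, None
        for chrom, _, pos in keys:
            val = values[(chrom, strand, pos)]
            if (
                run_chrom == chrom
                and pos == run_end
                and run_val is not None
                and val == run_val
            ):
                run_end += 1
                continue
            if run_chrom is not None:
                fh.write(f"{run_chrom}\t{run_start}\t{run_end}\t{_fmt(run_val)}\n")
            run_chrom, run_start, run_end, run_val = chrom, pos, pos + 1, val
        if run_chrom is not None:
            fh.write(f"{run_chrom}\t{run_start}\t{run_end}\t{_fmt(run_val)}\n")


def _fmt(v: float | int) -> str:
    if isinstance(v, int) or float(v).is_integer():
        return str(int(v))
    return f"{v:.6g}"


# ---------------------------------------------------------------- operations


def cpm_normalize(raw: RawProfile) -> NormalizedProfile:
    """Counts-per-million: value = count * 1e6 / library total."""
    total = raw.total
    if total == 0:
        raise TrackError(f"library {raw.library_id} is empty (total = 0)")
    scale = 1e6 / total
    values = {k: v * scale for k, v in raw.counts.items()}
    return NormalizedProfile(
        library_id=raw.library_id,
        genotype=raw.genotype,
        replicate=raw.replicate,
        values=values,
    )


def merge_replicates(profiles: list[NormalizedProfile]) -> NormalizedProfile:
    """Per-position arithmetic mean of CPM across replicates.

    Absent positions count as 0; positions with mean 0 are dropped. All
    profiles must share a genotype.
    """
    if not profiles:
        raise TrackError("merge_replicates requires at least one profile")
    genotypes = {p.genotype for p in profiles}
    if len(genotypes) != 1:
        raise TrackError(f"cannot merge mixed genotypes: {sorted(genotypes)}")
    n = len(profiles)
    acc: dict[Key, float] = {}
    for p in profiles:
        for k, v in p.values.items():
            acc[k] = acc.get(k, 0.0) + v
    values = {k: s / n for k, s in acc.items() if s > 0}
    return NormalizedProfile(
        library_id="+".join(p.library_id for p in profiles),
        genotype=profiles[0].genotype,
        replicate=0,
        values=values,
    )


def replicate_correlation(
    a: NormalizedProfile, b: NormalizedProfile, min_cpm: float = 1.0
) -> tuple[float, float]:
    """Pearson r and R^2 over positions with CPM >= min_cpm in either
    profile (absent positions treated as 0)."""
    keys = {k for k, v in a.values.items() if v >= min_cpm}
    keys |= {k for k, v in b.values.items() if v >= min_cpm}
    if len(keys) < 3:
        raise TrackError(
            f"only {len(keys)} positions with CPM >= {min_cpm}; need >= 3"
        )
    keys = sorted(keys)
    xa = np.array([a.get(k) for k in keys])
    xb = np.array([b.get(k) for k in keys])
    r = float(np.corrcoef(xa, xb)[0, 1])
    return r, r * r


def log2_compare(
    numerator: NormalizedProfile,
    denominator: NormalizedProfile,
    pseudocount: float = 0.01,
) -> ComparisonTrack:
    """log2 fold-change track over the key union, skipping 0-over-0 pairs."""
    keys = set(numerator.values) | set(denominator.values)
    values: dict[Key, float] = {}
    skipped = 0
    for k in keys:
        a = numerator.get(k)
        b = denominator.get(k)
        if a == 0.0 and b == 0.0:
            skipped += 1
            continue
        # log difference, not log-of-ratio: antisymmetry is then exact
        values[k] = math.log2(a + pseudocount) - math.log2(b + pseudocount)
    return ComparisonTrack(
        numerator_id=numerator.library_id,
        denominator_id=denominator.library_id,
        pseudocount=pseudocount,
        values=values,
        skipped_zero_pairs=skipped,
    )
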