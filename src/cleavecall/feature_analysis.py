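"""Site-feature analytics: region assignment, metagene and junction
profiles, sequence-window extraction, degenerate-motif scanning, k-mer
differential enrichment, set-overlap tests, half-life and decap-abundance
group comparisons.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import GenomeSequence, TranscriptModel
from .degradome_quant import ComparisonTrack, Key, NormalizedProfile
from .site_caller import DecapCatalog, PipelineConfig

__all__ = [
    "MotifSpec",
    "MetageneProfile",
    "JunctionProfile",
    "MotifPositionalDistribution",
    "OverlapResult",
    "HalfLifeComparison",
    "assign_region",
    "metagene_profile",
    "junction_distance_profile",
    "extract_window_sequences",
    "scan_motif",
    "iupac_to_regex",
    "motif_positional_distribution",
    "kmer_differential_enrichment",
    "set_overlap_test",
    "halflife_group_compare",
    "decap_abundance_shift",
    "bh_adjust",
]

IUPAC = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "U": "T",
    "R": "AG",
    "Y": "CT",
    "S": "CG",
    "W": "AT",
    "K": "GT",
    "M": "AC",
    "B": "CGT",
    "D": "AGT",
    "H": "ACT",
    "V": "ACG",
    "N": "ACGT",
}


@dataclass
class MotifSpec:
    iupac_pattern: str = "YGGWG"
    window_halfwidth: int = 20
    coarse_bin: int = 5
    inset_halfwidth: int = 5

    def __post_init__(self) -> None:
        if not self.iupac_pattern:
            raise ValueError("empty motif pattern")
        bad = set(self.iupac_pattern.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC codes: {sorted(bad)}")
        self.iupac_pattern = self.iupac_pattern.upper().replace("U", "T")


# ------------------------------------------------------------------- regions


def assign_region(site: Key, tx: TranscriptModel) -> str:
    """One of 5UTR / CDS / 3UTR / intron / noncoding-exon for a site on tx."""
    chrom, strand, pos = site
    if chrom != tx.chromosome or strand != tx.strand:
        raise ValueError(f"site {site} not on transcript {tx.transcript_id}")
    s = tx.genomic_to_transcript(pos)  # raises CoordinateError outside span
    if s is None:
        return "intron"
    if not tx.is_protein_coding or tx.cds_span is None:
        return "noncoding-exon"
    lo, hi = tx.cds_transcript_interval()
    if s < lo:
        return "5UTR"
    if s >= hi:
        return "3UTR"
    return "CDS"


# ------------------------------------------------------------------ metagene


@dataclass
class MetageneProfile:
    """Per-region 100-bin site-occurrence histogram (1% bins)."""

    bins: dict[str, np.ndarray] = field(
        default_factory=lambda: {
            "5UTR": np.zeros(100, dtype=int),
            "CDS": np.zeros(100, dtype=int),
            "3UTR": np.zeros(100, dtype=int),
        }
    )
    n_sites_assigned: int = 0
    n_skipped: int = 0


def _region_interval(tx: TranscriptModel, region: str) -> Optional[tuple[int, int]]:
    if tx.cds_span is None:
        return None
    lo, hi = tx.cds_transcript_interval()
    if region == "5UTR":
        return (0, lo) if lo > 0 else None
    if region == "CDS":
        return (lo, hi)
    if region == "3UTR":
        return (hi, tx.length) if hi < tx.length else None
    return None


def metagene_profile(
    sites: Iterable[tuple[Key, str]],
    transcripts: dict[str, TranscriptModel],
) -> MetageneProfile:
    """Bin each (site, transcript_id) pair into 100 relative-position bins of
    its region. Intronic/noncoding sites and sites whose transcript lacks the
    region are skipped with a count."""
    prof = MetageneProfile()
    for key, tid in sites:
        tx = transcripts.get(tid)
        if tx is None:
            prof.n_skipped += 1
            continue
        region = assign_region(key, tx)
        if region not in prof.bins:
            prof.n_skipped += 1
            continue
        interval = _region_interval(tx, region)
        if interval is None:
            prof.n_skipped += 1
            continue
        lo, hi = interval
        s = tx.genomic_to_transcript(key[2])
        rel = (s - lo) / (hi - lo)
        b = min(99, int(rel * 100))
        prof.bins[region][b] += 1
        prof.n_sites_assigned += 1
    return prof


# ----------------------------------------------------------------- junctions


@dataclass
class JunctionProfile:
    """Relative frequency of sites 1..50 nt upstream of an exon junction."""

    distances: np.ndarray = field(default_factory=lambda: np.zeros(50))
    counts: np.ndarray = field(default_factory=lambda: np.zeros(50, dtype=int))
    n_sites_in_window: int = 0
    n_sites_considered: int = 0


def junction_distance_profile(
    sites: Iterable[tuple[Key, str]],
    transcripts: dict[str, TranscriptModel],
    decap_catalog: Optional[DecapCatalog] = None,
    max_distance: int = 50,
) -> JunctionProfile:
    """Distance (spliced coordinates) from each CDS site of a nuclear coding
    transcript to the nearest downstream exon junction; a site on the last
    base of the upstream exon has distance 1. Distances > max_distance or
    sites with no downstream junction are excluded from the window count.
    Sites at catalogued decap positions are skipped entirely.
    """
    prof = JunctionProfile(
        distances=np.zeros(max_distance), counts=np.zeros(max_distance, dtype=int)
    )
    for key, tid in sites:
        tx = transcripts.get(tid)
        if tx is None or not (tx.is_protein_coding and tx.is_nuclear):
            continue
        if decap_catalog is not None and key in decap_catalog.positions:
            continue
        if assign_region(key, tx) != "CDS":
            continue
        prof.n_sites_considered += 1
        s = tx.genomic_to_transcript(key[2])
        downstream = [j.transcript_coordinate for j in tx.junctions() if j.transcript_coordinate >= s]
        if not downstream:
            continue
        d = min(downstream) - s + 1
        if 1 <= d <= max_distance:
            prof.counts[d - 1] += 1
            prof.n_sites_in_window += 1
    if prof.n_sites_in_window > 0:
        prof.distances = prof.counts / prof.n_sites_in_window
    return prof


# ----------------------------------------------------------- sequence windows


def extract_window_sequences(
    sites: Iterable[tuple[Key, str]],
    genome: GenomeSequence,
    transcripts: dict[str, TranscriptModel],
    spec: Optional[MotifSpec] = None,
) -> tuple[dict[Key, str], int]:
    """Sense-strand spliced windows of length 2*halfwidth with the site base
    at index halfwidth. Windows truncated by transcript ends are dropped;
    returns (windows, n_dropped)."""
    spec = spec or MotifSpec()
    hw = spec.window_halfwidth
    windows: dict[Key, str] = {}
    dropped = 0
    spliced_cache: dict[str, str] = {}
    for key, tid in sites:
        tx = transcripts.get(tid)
        if tx is None:
            dropped += 1
            continue
        s = tx.genomic_to_transcript(key[2])
        if s is None or s - hw < 0 or s + hw > tx.length:
            dropped += 1
            continue
        if tid not in spliced_cache:
            spliced_cache[tid] = tx.spliced_sequence(genome)
        windows[key] = spliced_cache[tid][s - hw : s + hw]
    return windows, dropped


# --------------------------------------------------------------- motif scan


def iupac_to_regex(pattern: str) -> str:
    parts = []
    for c in pattern.upper().replace("U", "T"):
        if c not in IUPAC:
            raise ValueError(f"invalid IUPAC code {c!r}")
        exp = IUPAC[c]
        parts.append(exp if len(exp) == 1 else f"[{exp}]")
    return "".join(parts)


def scan_motif(seqs: Sequence[str], spec: Optional[MotifSpec] = None) -> list[list[int]]:
    """All (possibly overlapping) match start offsets of the IUPAC pattern in
    each sequence (DNA space; U mapped to T)."""
    spec = spec or MotifSpec()
    rx = re.compile(f"(?=({iupac_to_regex(spec.iupac_pattern)}))")
    out: list[list[int]] = []
    for seq in seqs:
        seq = seq.upper().replace("U", "T")
        out.append([m.start() for m in rx.finditer(seq)])
    return out


@dataclass
class MotifPositionalDistribution:
    coarse_edges: np.ndarray
    coarse_counts: np.ndarray
    inset_offsets: np.ndarray
    inset_counts: np.ndarray
    inset_fraction: float
    n_sequences: int
    n_hits: int


def motif_positional_distribution(
    hits: Sequence[Sequence[int]], spec: Optional[MotifSpec] = None
) -> MotifPositionalDistribution:
    """Coarse (5-nt bins over the whole window) and inset (1-nt bins over
    +/- inset_halfwidth) histograms of motif start offsets relative to the
    site base, plus the fraction of sequences with >= 1 inset hit.

    Offsets are re-expressed relative to the site base (offset 0 = motif
    starting on the site base; 5'-ward offsets negative).
    """
    spec = spec or MotifSpec()
    hw, ins = spec.window_halfwidth, spec.inset_halfwidth
    edges = np.arange(-hw, hw + 1, spec.coarse_bin)
    coarse = np.zeros(len(edges) - 1, dtype=int)
    inset_off = np.arange(-ins, ins + 1)
    inset = np.zeros(len(inset_off), dtype=int)
    n_hits = 0
    n_inset_seqs = 0
    for seq_hits in hits:
        has_inset = False
        for o in seq_hits:
            rel = o - hw
            n_hits += 1
            b = np.searchsorted(edges, rel, side="right") - 1
            if 0 <= b < len(coarse):
                coarse[b] += 1
            if -ins <= rel <= ins:
                inset[rel + ins] += 1
                has_inset = True
        if has_inset:
            n_inset_seqs += 1
    n_seq = len(hits)
    return MotifPositionalDistribution(
        coarse_edges=edges,
        coarse_counts=coarse,
        inset_offsets=inset_off,
        inset_counts=inset,
        inset_fraction=n_inset_seqs / n_seq if n_seq else 0.0,
        n_sequences=n_seq,
        n_hits=n_hits,
    )


# ------------------------------------------------------------ k-mer testing


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    if n == 0:
        return np.array([])
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def kmer_differential_enrichment(
    target_seqs: Sequence[str],
    control_seqs: Sequence[str],
    k_min: int = 5,
    k_max: int = 7,
) -> pd.DataFrame:
    """Exhaustive per-sequence presence/absence k-mer enrichment.

    Every k-mer (k_min..k_max) present in at least one target sequence is
    scored with an upper-tail hypergeometric test on the number of target
    sequences containing it, drawn from the pooled sequence set, then
    BH-adjusted jointly across all tested k-mers.
    """
    if not target_seqs or not control_seqs:
        raise ValueError("both sequence sets must be non-empty")
    shortest = min(len(s) for s in itertools.chain(target_seqs, control_seqs))
    if k_max > shortest:
        raise ValueError(f"k_max={k_max} exceeds shortest sequence length {shortest}")

    def kmer_sets(seqs: Sequence[str]) -> list[set[str]]:
        out = []
        for s in seqs:
            s = s.upper().replace("U", "T")
            ks: set[str] = set()
            for k in range(k_min, k_max + 1):
                for i in range(len(s) - k + 1):
                    ks.add(s[i : i + k])
            out.append(ks)
        return out

    tgt_sets = kmer_sets(target_seqs)
    ctl_sets = kmer_sets(control_seqs)
    universe: set[str] = set().union(*tgt_sets)
    n_t, n_c = len(tgt_sets), len(ctl_sets)
    M = n_t + n_c
    rows = []
    for kmer in sorted(universe):
        t = sum(kmer in s for s in tgt_sets)
        c = sum(kmer in s for s in ctl_sets)
        p = float(stats.hypergeom.sf(t - 1, M, t + c, n_t))
        rows.append((kmer, t, c, p))
    frame = pd.DataFrame(rows, columns=["kmer", "target_count", "control_count", "p"])
    frame["q"] = bh_adjust(frame["p"].to_numpy())
    frame = frame.sort_values(["p", "kmer"], kind="mergesort").reset_index(drop=True)
    return frame


# ------------------------------------------------------------- set overlaps


@dataclass
class OverlapResult:
    observed: int
    hypergeom_p: float
    fisher_odds: float
    fisher_p: float
    permutation_p: float
    n_permutations: int
    seed: int


def set_overlap_test(
    set_a: set,
    set_b: set,
    universe: set,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> OverlapResult:
    """Overlap enrichment of two subsets of a universe: upper-tail
    hypergeometric p, Fisher odds ratio, and a seeded Monte Carlo permutation
    p from equal-size random draws."""
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("sets must be subsets of the universe")
    n_u, n_a, n_b = len(universe), len(set_a), len(set_b)
    obs = len(set_a & set_b)
    hyper_p = float(stats.hypergeom.sf(obs - 1, n_u, n_b, n_a))
    table = [
        [obs, n_a - obs],
        [n_b - obs, n_u - n_a - n_b + obs],
    ]
    odds, fisher_p = stats.fisher_exact(table, alternative="greater")
    rng = np.random.default_rng(seed)
    uni = np.array(sorted(universe), dtype=object)
    b_set = set_b
    hits = 0
    for _ in range(n_permutations):
        draw = rng.choice(uni, size=n_a, replace=False)
        if sum(x in b_set for x in draw) >= obs:
            hits += 1
    perm_p = (1 + hits) / (1 + n_permutations)
    return OverlapResult(
        observed=obs,
        hypergeom_p=hyper_p,
        fisher_odds=float(odds),
        fisher_p=float(fisher_p),
        permutation_p=perm_p,
        n_permutations=n_permutations,
        seed=seed,
    )


# -------------------------------------------------------- group comparisons


@dataclass
class HalfLifeComparison:
    median_a: float
    median_b: float
    p_value: float
    frac_short_a: float
    frac_short_b: float
    n_a: int
    n_b: int
    short_threshold: float


def _exact_ranksum_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided exact permutation p for the rank-sum statistic with
    midranks; feasible for small groups."""
    pooled = list(x) + list(y)
    ranks = stats.rankdata(pooled)
    m, n = len(x), len(pooled)
    obs = ranks[:m].sum()
    mu = m * ranks.sum() / n
    thr = abs(obs - mu) - 1e-12
    total = 0
    extreme = 0
    for combo in itertools.combinations(range(n), m):
        total += 1
        w = ranks[list(combo)].sum()
        if abs(w - mu) >= thr:
            extreme += 1
    return extreme / total


def ranksum_test(x: Sequence[float], y: Sequence[float], exact_max_n: int = 8) -> float:
    """Two-sided rank-sum p: exact permutation for small groups, otherwise
    tie-corrected normal approximation (Mann-Whitney)."""
    if len(x) <= exact_max_n and len(y) <= exact_max_n:
        return _exact_ranksum_p(x, y)
    return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def halflife_group_compare(
    targets: set[str],
    nontargets: set[str],
    table: dict[str, float],
    short_threshold: float = 60.0,
) -> HalfLifeComparison:
    """Compare half-life distributions of two transcript sets after joining
    with a transcript -> t1/2 (minutes) table."""
    a = [table[t] for t in sorted(targets) if t in table]
    b = [table[t] for t in sorted(nontargets) if t in table]
    if len(a) < 3 or len(b) < 3:
        raise ValueError(f"insufficient data after join: {len(a)} vs {len(b)} values")
    p = ranksum_test(a, b)
    return HalfLifeComparison(
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        p_value=p,
        frac_short_a=float(np.mean([v <= short_threshold for v in a])),
        frac_short_b=float(np.mean([v <= short_threshold for v in b])),
        n_a=len(a),
        n_b=len(b),
        short_threshold=short_threshold,
    )


def decap_abundance_shift(
    catalog: DecapCatalog,
    fc_xrn4_wt: ComparisonTrack,
    fc_double_wt: ComparisonTrack,
    xrn4_track: NormalizedProfile,
    double_track: NormalizedProfile,
    transcripts: list[TranscriptModel],
    targets: set[str],
    cfg: Optional[PipelineConfig] = None,
) -> dict[str, dict[str, object]]:
    """Mutant-vs-wild-type log2 FC distributions at eligible decapping
    positions, split into target vs rest transcript groups.

    Eligible: catalogued decap position with CPM >= decap_min_cpm in both
    mutant tracks and xrn4-vs-wild-type log2 FC >= 1.
    """
    from .site_caller import _build_exon_index, _lookup_transcript

    cfg = cfg or PipelineConfig()
    index = _build_exon_index(transcripts)
    groups: dict[str, dict[str, list[float]]] = {
        "target": {"xrn4": [], "double": []},
        "rest": {"xrn4": [], "double": []},
    }
    for key in sorted(catalog.positions):
        if xrn4_track.get(key) < cfg.decap_min_cpm:
            continue
        if double_track.get(key) < cfg.decap_min_cpm:
            continue
        fx = fc_xrn4_wt.get(key)
        if fx is None or fx < 1.0:
            continue
        fd = fc_double_wt.get(key)
        if fd is None:
            continue
        tid = _lookup_transcript(index, key)
        if tid is None:
            continue
        grp = "target" if tid in targets else "rest"
        groups[grp]["xrn4"].append(fx)
        groups[grp]["double"].append(fd)
    out: dict[str, dict[str, object]] = {}
    for grp, vals in groups.items():
        x, d = vals["xrn4"], vals["double"]
        p = ranksum_test(x, d) if len(x) >= 3 and len(d) >= 3 else float("nan")
        out[grp] = {
            "fc_xrn4_wt": x,
            "fc_double_wt": d,
            "median_xrn4": float(np.median(x)) if x else float("nan"),
            "median_double": float(np.median(d)) if d else float("nan"),
            "p_value": p,
            "n": len(x),
        }
    return out
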