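"""Cleavage-site calling cascade.

Contrast logic: 5'P positions that overaccumulate in the exonuclease-null
genotype relative to wild type (CPM >= 5, log2 FC >= 2) and additionally
relative to the endonuclease/exonuclease double mutant (log2 FC >= 2) are
candidate endonucleolytic cleavage sites. Candidates near the TSS or a
catalogued decapping position, with non-unique tag sequences, or on
transcripts whose full-length abundance dropped in the double mutant are
removed. Per transcript the single most abundant surviving candidate is
kept and classified: MaxSeq when it is the transcript's most abundant 5'P
position overall, MajorInternal when it ranks second behind a catalogued
decapping position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .annotation_io import GenomeSequence, TranscriptModel, reverse_complement
from .degradome_quant import ComparisonTrack, Key, NormalizedProfile

__all__ = [
    "PipelineConfig",
    "DecapCatalog",
    "CandidateSite",
    "TargetSets",
    "CascadeResult",
    "prefilter_low_abundance",
    "build_decap_catalog",
    "call_xrn4_sensitive",
    "call_dne1_dependent",
    "filter_decap_proximity",
    "filter_uniqueness",
    "filter_expression",
    "classify_maxseq_major",
    "define_control_sets",
    "run_cascade",
    "sites_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    min_xrn4_cpm: float = 5.0
    prefilter_min_cpm: float = 1.0
    min_log2fc_xrn4_vs_wt: float = 2.0
    min_log2fc_xrn4_vs_double: float = 2.0
    decap_min_cpm: float = 5.0
    exclusion_window: int = 5
    uniqueness_k: int = 20
    pseudocount: float = 0.01
    nontarget_fc_window: tuple[float, float] = (-0.25, 0.25)
    other_fc_window: tuple[float, float] = (-0.25, 0.25)
    expression_drop_log2fc: float = -0.58
    expression_fdr: float = 0.05

    def __post_init__(self) -> None:
        for win in (self.nontarget_fc_window, self.other_fc_window):
            if win[0] > win[1]:
                raise ValueError(f"fold-change window {win} not ordered")


@dataclass
class DecapCatalog:
    """Decapping/TSS positions used for exclusion and MajorInternal logic."""

    positions: set[Key] = field(default_factory=set)
    per_transcript: dict[str, dict[str, object]] = field(default_factory=dict)

    def near(self, key: Key, window: int) -> bool:
        chrom, strand, pos = key
        for d in range(-window, window + 1):
            if (chrom, strand, pos + d) in self.positions:
                return True
        return False


@dataclass
class CandidateSite:
    chromosome: str
    strand: str
    position: int
    transcript_id: Optional[str] = None
    xrn4_cpm: float = 0.0
    wt_cpm: float = 0.0
    double_cpm: float = 0.0
    fc_xrn4_wt: Optional[float] = None
    fc_xrn4_double: Optional[float] = None
    site_class: str = "unclassified"
    region: str = ""
    filter_trace: list[str] = field(default_factory=list)

    @property
    def key(self) -> Key:
        return (self.chromosome, self.strand, self.position)


@dataclass
class TargetSets:
    targets: set[str]
    nontargets: set[str]
    others: set[str]
    nontarget_fc_window: tuple[float, float] = (-0.25, 0.25)
    other_fc_window: tuple[float, float] = (-0.25, 0.25)


@dataclass
class CascadeResult:
    sites: list[CandidateSite]
    dropped: list[CandidateSite]
    target_sets: TargetSets
    survivor_counts: dict[str, int]


# ------------------------------------------------------------------- filters


def prefilter_low_abundance(
    xrn4_track: NormalizedProfile, cfg: PipelineConfig
) -> set[Key]:
    """Positions with merged xrn4 CPM >= prefilter threshold."""
    return {k for k, v in xrn4_track.values.items() if v >= cfg.prefilter_min_cpm}


def build_decap_catalog(
    cap_pare: NormalizedProfile,
    transcripts: Iterable[TranscriptModel],
    cfg: PipelineConfig,
) -> DecapCatalog:
    """Catalog of decapping positions (Cap-PARE CPM >= threshold) plus every
    annotated TSS."""
    cat = DecapCatalog()
    decap_keys = {k for k, v in cap_pare.values.items() if v >= cfg.decap_min_cpm}
    cat.positions |= decap_keys
    for tx in transcripts:
        tss_key = (tx.chromosome, tx.strand, tx.tss)
        cat.positions.add(tss_key)
        lo, hi = tx.span
        tx_decaps = {
            k for k in decap_keys
            if k[0] == tx.chromosome and k[1] == tx.strand and lo <= k[2] < hi
        }
        cat.per_transcript[tx.transcript_id] = {
            "tss": tx.tss,
            "decaps": {k[2] for k in tx_decaps},
        }
    return cat


def call_xrn4_sensitive(
    xrn4_track: NormalizedProfile,
    fc_xrn4_wt: ComparisonTrack,
    cfg: PipelineConfig,
    positions: Optional[set[Key]] = None,
) -> list[CandidateSite]:
    """Positions with xrn4 CPM >= min_xrn4_cpm and log2 FC (xrn4/wt) >=
    threshold. ``positions`` optionally restricts the scan (prefilter)."""
    keys = positions if positions is not None else set(xrn4_track.values)
    out: list[CandidateSite] = []
    for k in sorted(keys):
        cpm = xrn4_track.get(k)
        if cpm < cfg.min_xrn4_cpm:
            continue
        fc = fc_xrn4_wt.get(k)
        if fc is None or fc < cfg.min_log2fc_xrn4_vs_wt:
            continue
        out.append(
            CandidateSite(
                chromosome=k[0],
                strand=k[1],
                position=k[2],
                xrn4_cpm=cpm,
                fc_xrn4_wt=fc,
                filter_trace=["xrn4_sensitive:pass"],
            )
        )
    return out


def call_dne1_dependent(
    candidates: list[CandidateSite],
    fc_xrn4_double: ComparisonTrack,
    cfg: PipelineConfig,
) -> list[CandidateSite]:
    kept: list[CandidateSite] = []
    for c in candidates:
        fc = fc_xrn4_double.get(c.key)
        if fc is None:
            c.filter_trace.append("dne1_dependent:fail:no-signal-in-contrast")
            continue
        c.fc_xrn4_double = fc
        if fc >= cfg.min_log2fc_xrn4_vs_double:
            c.filter_trace.append("dne1_dependent:pass")
            kept.append(c)
        else:
            c.filter_trace.append("dne1_dependent:fail")
    return kept


def filter_decap_proximity(
    candidates: list[CandidateSite], catalog: DecapCatalog, cfg: PipelineConfig
) -> list[CandidateSite]:
    """Remove candidates within +/- exclusion_window nt (inclusive) of any
    catalogued decap/TSS position."""
    kept: list[CandidateSite] = []
    for c in candidates:
        if catalog.near(c.key, cfg.exclusion_window):
            c.filter_trace.append("decap_proximity:fail")
            logger.debug("dropped %s: decap/TSS proximity", c.key)
        else:
            c.filter_trace.append("decap_proximity:pass")
            kept.append(c)
    return kept


def _count_overlapping(haystack: str, needle: str) -> int:
    n, start = 0, 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return n
        n += 1
        start = i + 1


def site_kmer(
    site: CandidateSite,
    tx: TranscriptModel,
    genome: GenomeSequence,
    k: int,
) -> Optional[str]:
    """The k-mer of the surviving fragment's 5' end, read 3'-ward along the
    spliced transcript; None when it runs off the transcript end."""
    s = tx.genomic_to_transcript(site.position)
    if s is None:
        return None
    if s + k > tx.length:
        return None
    return tx.spliced_sequence(genome)[s : s + k]


def filter_uniqueness(
    candidates: list[CandidateSite],
    genome: GenomeSequence,
    transcripts: list[TranscriptModel],
    cfg: PipelineConfig,
) -> list[CandidateSite]:
    """Keep candidates whose k-mer occurs exactly once in the genome (both
    strands) and exactly once in the spliced transcriptome."""
    tx_by_id = {t.transcript_id: t for t in transcripts}
    spliced = {t.transcript_id: t.spliced_sequence(genome) for t in transcripts}
    chrom_seqs = list(genome.chromosomes.values())
    chrom_rcs = [reverse_complement(s) for s in chrom_seqs]
    kept: list[CandidateSite] = []
    for c in candidates:
        tx = tx_by_id.get(c.transcript_id)
        if tx is None:
            c.filter_trace.append("uniqueness:fail:unannotated")
            continue
        kmer = site_kmer(c, tx, genome, cfg.uniqueness_k)
        if kmer is None:
            c.filter_trace.append("uniqueness:fail:edge")
            continue
        g_hits = sum(_count_overlapping(s, kmer) for s in chrom_seqs)
        g_hits += sum(_count_overlapping(s, kmer) for s in chrom_rcs)
        t_hits = sum(_count_overlapping(s, kmer) for s in spliced.values())
        if g_hits == 1 and t_hits == 1:
            c.filter_trace.append("uniqueness:pass")
            kept.append(c)
        else:
            c.filter_trace.append(f"uniqueness:fail:genome={g_hits},tx={t_hits}")
    return kept


def filter_expression(
    candidates: list[CandidateSite],
    rnaseq_table: Optional[pd.DataFrame],
    cfg: PipelineConfig,
) -> list[CandidateSite]:
    """Drop candidates on transcripts whose full-length abundance fell
    significantly in the double mutant (one-sided: decreases only).

    The table needs columns transcript_id, log2fc_double_vs_xrn4, fdr.
    ``None`` is a documented passthrough (all retained, warning logged).
    """
    if rnaseq_table is None:
        logger.warning("no RNA-seq table supplied; expression filter skipped")
        for c in candidates:
            c.filter_trace.append("expression:pass:no-table")
        return list(candidates)
    required = {"transcript_id", "log2fc_double_vs_xrn4", "fdr"}
    missing = required - set(rnaseq_table.columns)
    if missing:
        raise ValueError(f"RNA-seq table missing columns: {sorted(missing)}")
    table = rnaseq_table.set_index("transcript_id")
    kept: list[CandidateSite] = []
    for c in candidates:
        if c.transcript_id not in table.index:
            logger.warning("transcript %s absent from RNA-seq table", c.transcript_id)
            c.filter_trace.append("expression:pass:no-row")
            kept.append(c)
            continue
        row = table.loc[c.transcript_id]
        if (
            row["log2fc_double_vs_xrn4"] <= cfg.expression_drop_log2fc
            and row["fdr"] <= cfg.expression_fdr
        ):
            c.filter_trace.append("expression:fail")
            logger.debug("dropped %s: expression drop", c.key)
        else:
            c.filter_trace.append("expression:pass")
            kept.append(c)
    return kept


# ------------------------------------------------------------ classification


def _transcript_positions(
    tx: TranscriptModel, track: NormalizedProfile
) -> list[tuple[Key, float, int]]:
    """(key, CPM, spliced coord) for every exonic track position on tx,
    ranked most-abundant first, ties toward the 5'-most spliced coordinate."""
    lo, hi = tx.span
    rows: list[tuple[Key, float, int]] = []
    for k, v in track.values.items():
        if k[0] != tx.chromosome or k[1] != tx.strand:
            continue
        if not lo <= k[2] < hi:
            continue
        s = tx.genomic_to_transcript(k[2])
        if s is None:
            continue
        rows.append((k, v, s))
    rows.sort(key=lambda r: (-r[1], r[2]))
    return rows


def classify_maxseq_major(
    candidates: list[CandidateSite],
    xrn4_track: NormalizedProfile,
    catalog: DecapCatalog,
    transcripts: list[TranscriptModel],
    cfg: PipelineConfig,
) -> tuple[list[CandidateSite], list[CandidateSite]]:
    """Keep the single most abundant surviving candidate per transcript and
    label it MaxSeq / MajorInternal; others are dropped with a trace.

    Returns (classified, dropped).
    """
    tx_by_id = {t.transcript_id: t for t in transcripts}
    by_tx: dict[str, list[CandidateSite]] = {}
    for c in candidates:
        by_tx.setdefault(c.transcript_id, []).append(c)
    classified: list[CandidateSite] = []
    dropped: list[CandidateSite] = []
    for tid, group in sorted(by_tx.items()):
        tx = tx_by_id[tid]

        def sort_key(c: CandidateSite) -> tuple[float, int]:
            s = tx.genomic_to_transcript(c.position)
            return (-c.xrn4_cpm, s if s is not None else tx.length)

        group.sort(key=sort_key)
        best, rest = group[0], group[1:]
        for c in rest:
            c.filter_trace.append("classify:fail:not-most-abundant-candidate")
            dropped.append(c)
        ranked = _transcript_positions(tx, xrn4_track)
        rank = next((i for i, r in enumerate(ranked) if r[0] == best.key), None)
        if rank == 0:
            best.site_class = "MaxSeq"
            best.filter_trace.append("classify:MaxSeq")
            classified.append(best)
        elif rank == 1 and catalog.near(ranked[0][0], cfg.exclusion_window):
            best.site_class = "MajorInternal"
            best.filter_trace.append("classify:MajorInternal")
            classified.append(best)
        else:
            best.filter_trace.append("classify:fail:unclassified")
            dropped.append(best)
    return classified, dropped


def define_control_sets(
    fc_xrn4_double: ComparisonTrack,
    fc_xrn4_wt: ComparisonTrack,
    xrn4_track: NormalizedProfile,
    transcripts: list[TranscriptModel],
    classified: list[CandidateSite],
    cfg: PipelineConfig,
) -> TargetSets:
    """Targets / nontargets / others with priority targets > nontargets >
    others.

    Nontargets: transcripts carrying an XRN4-sensitive 5'P site (abundance
    and xrn4-vs-wild-type FC thresholds) whose xrn4-vs-double log2 FC lies
    inside the nontarget window. Others: transcripts with a site whose
    xrn4-vs-wild-type FC lies inside the other window, excluding the first
    two sets. Only positions passing the abundance prefilter count as sites.
    """
    targets = {c.transcript_id for c in classified}
    eligible = {
        k for k, v in xrn4_track.values.items() if v >= cfg.prefilter_min_cpm
    }
    index = _build_exon_index(transcripts)
    nt_lo, nt_hi = cfg.nontarget_fc_window
    ot_lo, ot_hi = cfg.other_fc_window
    nontargets: set[str] = set()
    others: set[str] = set()
    for k in eligible:
        tid = _lookup_transcript(index, k)
        if tid is None or tid in targets:
            continue
        if xrn4_track.get(k) < cfg.min_xrn4_cpm:
            continue
        fc_xw = fc_xrn4_wt.get(k)
        if fc_xw is None or fc_xw < cfg.min_log2fc_xrn4_vs_wt:
            continue
        fc_xd = fc_xrn4_double.get(k)
        if fc_xd is not None and nt_lo <= fc_xd <= nt_hi:
            nontargets.add(tid)
    for k in eligible:
        tid = _lookup_transcript(index, k)
        if tid is None or tid in targets or tid in nontargets:
            continue
        fc_xw = fc_xrn4_wt.get(k)
        if fc_xw is not None and ot_lo <= fc_xw <= ot_hi:
            others.add(tid)
    return TargetSets(
        targets=targets,
        nontargets=nontargets,
        others=others,
        nontarget_fc_window=cfg.nontarget_fc_window,
        other_fc_window=cfg.other_fc_window,
    )


# ------------------------------------------------------------- orchestration


def _build_exon_index(
    transcripts: list[TranscriptModel],
) -> dict[tuple[str, str], list[tuple[int, int, str]]]:
    idx: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
    for tx in transcripts:
        lo, hi = tx.span
        idx.setdefault((tx.chromosome, tx.strand), []).append((lo, hi, tx.transcript_id))
    for v in idx.values():
        v.sort()
    return idx


def _lookup_transcript(
    index: dict[tuple[str, str], list[tuple[int, int, str]]], key: Key
) -> Optional[str]:
    spans = index.get((key[0], key[1]))
    if not spans:
        return None
    pos = key[2]
    for lo, hi, tid in spans:
        if lo > pos:
            break
        if pos < hi:
            return tid
    return None


def _not_in(all_items: list, kept: list) -> list:
    kept_ids = {id(c) for c in kept}
    return [c for c in all_items if id(c) not in kept_ids]


def run_cascade(
    xrn4_track: NormalizedProfile,
    wt_track: NormalizedProfile,
    double_track: NormalizedProfile,
    cap_pare_track: NormalizedProfile,
    genome: GenomeSequence,
    transcripts: list[TranscriptModel],
    cfg: Optional[PipelineConfig] = None,
    rnaseq_table: Optional[pd.DataFrame] = None,
) -> CascadeResult:
    """Run the full filter cascade on merged tracks and return classified
    sites, dropped candidates, control sets, and per-filter survivor counts."""
    from .degradome_quant import log2_compare

    cfg = cfg or PipelineConfig()
    counts: dict[str, int] = {}
    dropped: list[CandidateSite] = []

    prefiltered = prefilter_low_abundance(xrn4_track, cfg)
    counts["prefilter"] = len(prefiltered)

    fc_xw = log2_compare(xrn4_track, wt_track, cfg.pseudocount)
    fc_xd = log2_compare(xrn4_track, double_track, cfg.pseudocount)

    cands = call_xrn4_sensitive(xrn4_track, fc_xw, cfg, positions=prefiltered)
    counts["xrn4_sensitive"] = len(cands)

    kept = call_dne1_dependent(cands, fc_xd, cfg)
    dropped += _not_in(cands, kept)
    cands = kept
    counts["dne1_dependent"] = len(cands)

    # annotate transcript + per-position CPMs before positional filters
    index = _build_exon_index(transcripts)
    annotated: list[CandidateSite] = []
    for c in cands:
        tid = _lookup_transcript(index, c.key)
        if tid is None:
            c.filter_trace.append("annotate:fail:unannotated")
            dropped.append(c)
            continue
        c.transcript_id = tid
        c.wt_cpm = wt_track.get(c.key)
        c.double_cpm = double_track.get(c.key)
        annotated.append(c)
    cands = annotated
    counts["annotated"] = len(cands)

    catalog = build_decap_catalog(cap_pare_track, transcripts, cfg)
    kept = filter_decap_proximity(cands, catalog, cfg)
    dropped += _not_in(cands, kept)
    cands = kept
    counts["decap_proximity"] = len(cands)

    kept = filter_uniqueness(cands, genome, transcripts, cfg)
    dropped += _not_in(cands, kept)
    cands = kept
    counts["uniqueness"] = len(cands)

    kept = filter_expression(cands, rnaseq_table, cfg)
    dropped += _not_in(cands, kept)
    cands = kept
    counts["expression"] = len(cands)

    classified, cls_dropped = classify_maxseq_major(
        cands, xrn4_track, catalog, transcripts, cfg
    )
    dropped += cls_dropped
    counts["classified"] = len(classified)

    # region assignment for the final table
    from .feature_analysis import assign_region

    tx_by_id = {t.transcript_id: t for t in transcripts}
    for c in classified:
        c.region = assign_region(c.key, tx_by_id[c.transcript_id])

    target_sets = define_control_sets(
        fc_xd, fc_xw, xrn4_track, transcripts, classified, cfg
    )
    return CascadeResult(
        sites=classified,
        dropped=dropped,
        target_sets=target_sets,
        survivor_counts=counts,
    )


def sites_to_frame(sites: list[CandidateSite]) -> pd.DataFrame:
    rows = [
        {
            "transcript_id": c.transcript_id,
            "chromosome": c.chromosome,
            "strand": c.strand,
            "position": c.position,
            "xrn4_cpm": round(c.xrn4_cpm, 4),
            "wt_cpm": round(c.wt_cpm, 4),
            "double_cpm": round(c.double_cpm, 4),
            "fc_xrn4_wt": round(c.fc_xrn4_wt, 4) if c.fc_xrn4_wt is not None else None,
            "fc_xrn4_double": round(c.fc_xrn4_double, 4)
            if c.fc_xrn4_double is not None
            else None,
            "site_class": c.site_class,
            "region": c.region,
            "filter_trace": ";".join(c.filter_trace),
        }
        for c in sites
    ]
    frame = pd.DataFrame(
        rows,
        columns=[
            "transcript_id",
            "chromosome",
            "strand",
            "position",
            "xrn4_cpm",
            "wt_cpm",
            "double_cpm",
            "fc_xrn4_wt",
            "fc_xrn4_double",
            "site_class",
            "region",
            "filter_trace",
        ],
    )
    return frame.sort_values(
        ["chromosome", "strand", "position"], kind="mergesort"
    ).reset_index(drop=True)
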