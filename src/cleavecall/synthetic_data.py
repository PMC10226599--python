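"""Seeded simulator for multi-genotype 5'P degradome datasets.

Generates a random genome, multi-exon coding transcript models, and raw
per-position count tracks for wild type, exonuclease-null (xrn4), the
endonuclease/exonuclease double mutant, and a decap-marking (Cap-PARE)
library, with planted ground truth for recovery scoring.

Noise model: per-position background counts are negative binomial around a
transcript-abundance-scaled mean, placed uniformly along spliced
transcripts. Spikes are Poisson and added on top of background:

* cleavage spikes (target transcripts, inside the CDS) have mean
  ``cleavage_spike_cpm`` in xrn4 and that mean divided by
  ``2**cleavage_effect_log2`` in wild type and the double mutant — the
  intermediate accumulates only when the endonuclease cleaves and the
  exonuclease cannot degrade it;
* decapping spikes sit at the transcript 5' end, accumulate in both
  exonuclease-null genotypes, and are multiplied by a redistribution
  factor >= 1 in the double mutant.

The planted uniqueness k-mer at each cleavage site is re-drawn until it is
genome-unique; the degenerate G-rich motif is written at a configurable
offset next to each planted cut.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .annotation_io import (
    GenomeSequence,
    TranscriptModel,
    reverse_complement,
    write_genome,
)
from .degradome_quant import RawProfile, write_bedgraph

__all__ = [
    "SimulationConfig",
    "TranscriptTruth",
    "SyntheticTruth",
    "SimulatedDataset",
    "RecoveryResult",
    "simulate_annotation",
    "simulate_degradome",
    "simulate_dataset",
    "write_dataset",
    "evaluate_recovery",
]

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

CLASS_TARGET = "dne1_target"
CLASS_DECAP = "decap_only"
CLASS_INSENSITIVE = "xrn4_insensitive"


@dataclass
class SimulationConfig:
    seed: int
    n_transcripts: int = 200
    utr5_range: tuple[int, int] = (150, 300)
    cds_range: tuple[int, int] = (900, 1800)
    utr3_range: tuple[int, int] = (200, 400)
    exon_count_range: tuple[int, int] = (1, 4)
    intron_length_range: tuple[int, int] = (80, 200)
    fraction_target: float = 0.3
    fraction_decap_only: float = 0.3
    fraction_insensitive: float = 0.4
    depth: int = 2_000_000
    replicates: int = 2
    nb_dispersion: float = 10.0
    cleavage_effect_log2: float = 3.0
    decap_effect_log2: float = 3.0
    decap_redistribution: float = 1.0
    cleavage_spike_cpm: float = 50.0
    decap_spike_cpm: float = 100.0
    motif_rate: float = 1.0
    motif_pattern: str = "YGGWG"
    motif_offsets: tuple[int, ...] = (2,)
    uniqueness_k: int = 20
    n_chromosomes: int = 4
    spacer: int = 300
    abundance_sigma: float = 0.5
    background_fraction: float = 0.15
    cap_background_fraction: float = 0.02
    decap_sigma: float = 0.8
    cleavage_abundance_floor: float = 0.5
    halflife_target_median: float = 55.0
    halflife_other_median: float = 120.0
    halflife_sigma: float = 0.4

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        frac = self.fraction_target + self.fraction_decap_only + self.fraction_insensitive
        if frac > 1 + 1e-9:
            raise ValueError(f"class fractions sum to {frac} > 1")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.decap_redistribution < 1.0:
            raise ValueError("decap_redistribution must be >= 1")


@dataclass
class TranscriptTruth:
    transcript_id: str
    class_label: str
    cleavage_spliced: Optional[int] = None
    cleavage_genomic: Optional[int] = None
    decap_genomic: int = 0
    motif_offset: Optional[int] = None
    abundance: float = 1.0
    expected_spike_cpm: dict[str, float] = field(default_factory=dict)


@dataclass
class SyntheticTruth:
    seed: int
    records: list[TranscriptTruth]
    transcripts: list[TranscriptModel]

    def planted_targets(self) -> list[TranscriptTruth]:
        return [r for r in self.records if r.class_label == CLASS_TARGET]


@dataclass
class SimulatedDataset:
    genome: GenomeSequence
    truth: SyntheticTruth
    profiles: dict[tuple[str, int], RawProfile]
    cap_pare: RawProfile
    rnaseq: pd.DataFrame
    halflife: pd.DataFrame
    config: SimulationConfig


# --------------------------------------------------------------- annotation


def _random_seq(rng: np.random.Generator, n: int) -> list[str]:
    return list(_BASES[rng.integers(0, 4, size=n)])


def _instantiate_motif(pattern: str, rng: np.random.Generator) -> str:
    from .feature_analysis import IUPAC

    return "".join(
        c if len(IUPAC[c]) == 1 else IUPAC[c][rng.integers(0, len(IUPAC[c]))]
        for c in pattern.upper().replace("U", "T")
    )


def _draw_exon_cuts(
    rng: np.random.Generator, length: int, n_exons: int, min_exon: int = 45
) -> list[int]:
    if n_exons <= 1:
        return []
    for _ in range(200):
        cuts = sorted(rng.choice(np.arange(min_exon, length - min_exon), size=n_exons - 1, replace=False).tolist())
        ok = all(b - a >= min_exon for a, b in zip([0] + cuts, cuts + [length]))
        if ok:
            return cuts
    raise RuntimeError("could not place exon boundaries")


def simulate_annotation(
    cfg: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple[GenomeSequence, SyntheticTruth]:
    """Random coding transcripts on synthetic chromosomes with planted,
    genome-unique cleavage k-mers and adjacent degenerate motifs."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n = cfg.n_transcripts
    n_target = int(round(cfg.fraction_target * n))
    n_decap = int(round(cfg.fraction_decap_only * n))
    labels = (
        [CLASS_TARGET] * n_target
        + [CLASS_DECAP] * n_decap
        + [CLASS_INSENSITIVE] * (n - n_target - n_decap)
    )
    labels = [labels[i] for i in rng.permutation(n)]

    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    chrom_parts: dict[str, list[str]] = {c: [] for c in chrom_names}
    chrom_len: dict[str, int] = {c: 0 for c in chrom_names}

    models: list[TranscriptModel] = []
    records: list[TranscriptTruth] = []
    k = cfg.uniqueness_k

    for i in range(n):
        tid = f"TX{i + 1:04d}"
        label = labels[i]
        u5 = int(rng.integers(cfg.utr5_range[0], cfg.utr5_range[1] + 1))
        cds = int(rng.integers(cfg.cds_range[0], cfg.cds_range[1] + 1))
        u3 = int(rng.integers(cfg.utr3_range[0], cfg.utr3_range[1] + 1))
        L = u5 + cds + u3
        n_exons = int(rng.integers(cfg.exon_count_range[0], cfg.exon_count_range[1] + 1))
        cuts = _draw_exon_cuts(rng, L, n_exons)
        strand = "+" if rng.random() < 0.5 else "-"
        spliced = _random_seq(rng, L)

        cleavage_spliced: Optional[int] = None
        motif_offset: Optional[int] = None
        if label == CLASS_TARGET:
            lo = max(u5 + 6, 25)
            hi = u5 + cds - (k + 6)
            cand = np.arange(lo, hi)
            # the uniqueness k-mer must not span an exon junction
            mask = np.ones(len(cand), dtype=bool)
            for j in cuts:  # junction after spliced base j-1
                jj = j - 1
                mask &= ~((cand <= jj) & (cand + k - 2 >= jj))
            cand = cand[mask]
            if len(cand) == 0:
                raise RuntimeError(f"{tid}: no junction-free cleavage placement")
            cleavage_spliced = int(cand[rng.integers(0, len(cand))])
            if rng.random() < cfg.motif_rate:
                motif_offset = int(
                    cfg.motif_offsets[rng.integers(0, len(cfg.motif_offsets))]
                )
                motif = _instantiate_motif(cfg.motif_pattern, rng)
                start = cleavage_spliced + motif_offset
                if 0 <= start and start + len(motif) <= L:
                    spliced[start : start + len(motif)] = list(motif)

        # pre-mRNA: interleave exon pieces with random introns
        bounds = [0] + cuts + [L]
        exon_pieces = [spliced[a:b] for a, b in zip(bounds, bounds[1:])]
        pre: list[str] = []
        exon_pre_iv: list[tuple[int, int]] = []
        for j, piece in enumerate(exon_pieces):
            a = len(pre)
            pre.extend(piece)
            exon_pre_iv.append((a, len(pre)))
            if j < len(exon_pieces) - 1:
                ilen = int(
                    rng.integers(cfg.intron_length_range[0], cfg.intron_length_range[1] + 1)
                )
                pre.extend(_random_seq(rng, ilen))
        pre_len = len(pre)
        locus = pre if strand == "+" else list(reverse_complement("".join(pre)))

        chrom = chrom_names[i % cfg.n_chromosomes]
        chrom_parts[chrom].extend(_random_seq(rng, cfg.spacer))
        chrom_len[chrom] += cfg.spacer
        start = chrom_len[chrom]
        chrom_parts[chrom].extend(locus)
        chrom_len[chrom] += pre_len

        if strand == "+":
            exons = [(start + a, start + b) for a, b in exon_pre_iv]
        else:
            exons = [(start + pre_len - b, start + pre_len - a) for a, b in exon_pre_iv]
        model = TranscriptModel(
            transcript_id=tid,
            gene_id=f"G{i + 1:04d}",
            chromosome=chrom,
            strand=strand,
            exons=exons,
            cds_span=None,
            is_protein_coding=True,
            is_nuclear=True,
        )
        g1 = model.transcript_to_genomic(u5)
        g2 = model.transcript_to_genomic(u5 + cds - 1)
        model.cds_span = (min(g1, g2), max(g1, g2) + 1)

        rec = TranscriptTruth(
            transcript_id=tid,
            class_label=label,
            cleavage_spliced=cleavage_spliced,
            cleavage_genomic=(
                model.transcript_to_genomic(cleavage_spliced)
                if cleavage_spliced is not None
                else None
            ),
            decap_genomic=model.tss,
            motif_offset=motif_offset,
        )
        models.append(model)
        records.append(rec)

    for chrom in chrom_names:
        chrom_parts[chrom].extend(_random_seq(rng, cfg.spacer))
        chrom_len[chrom] += cfg.spacer

    # uniqueness repair: re-draw planted k-mers until genome-unique
    _ensure_unique_kmers(cfg, rng, chrom_parts, models, records)

    genome = GenomeSequence(
        name=f"sim{cfg.seed}",
        chromosomes={c: "".join(chrom_parts[c]) for c in chrom_names},
    )
    truth = SyntheticTruth(seed=cfg.seed, records=records, transcripts=models)
    return genome, truth


def _spliced_base(chrom_parts: dict[str, list[str]], tx: TranscriptModel, s: int) -> str:
    g = tx.transcript_to_genomic(s)
    b = chrom_parts[tx.chromosome][g]
    return b if tx.strand == "+" else _COMP[b]


def _set_spliced_base(
    chrom_parts: dict[str, list[str]], tx: TranscriptModel, s: int, base: str
) -> None:
    g = tx.transcript_to_genomic(s)
    chrom_parts[tx.chromosome][g] = base if tx.strand == "+" else _COMP[base]


def _count_overlapping(haystack: str, needle: str) -> int:
    n, start = 0, 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return n
        n += 1
        start = i + 1


def _ensure_unique_kmers(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    chrom_parts: dict[str, list[str]],
    models: list[TranscriptModel],
    records: list[TranscriptTruth],
    max_retries: int = 50,
) -> None:
    k = cfg.uniqueness_k
    by_id = {m.transcript_id: m for m in models}
    for _ in range(max_retries):
        genome_strs = {c: "".join(p) for c, p in chrom_parts.items()}
        rc_strs = {c: reverse_complement(s) for c, s in genome_strs.items()}
        dirty = False
        for rec in records:
            if rec.cleavage_spliced is None:
                continue
            tx = by_id[rec.transcript_id]
            c = rec.cleavage_spliced
            kmer = "".join(_spliced_base(chrom_parts, tx, c + j) for j in range(k))
            hits = sum(_count_overlapping(s, kmer) for s in genome_strs.values())
            hits += sum(_count_overlapping(s, kmer) for s in rc_strs.values())
            if hits == 1:
                continue
            dirty = True
            # redraw bases of the k-mer outside the planted motif span
            protected = set()
            if rec.motif_offset is not None:
                m0 = c + rec.motif_offset
                protected = set(range(m0, m0 + len(cfg.motif_pattern)))
            for s in range(c, c + k):
                if s in protected:
                    continue
                _set_spliced_base(chrom_parts, tx, s, str(_BASES[rng.integers(0, 4)]))
        if not dirty:
            return
    raise RuntimeError("could not make all planted k-mers genome-unique")


# ---------------------------------------------------------------- degradome

GENOTYPE_ORDER = ("wild_type", "xrn4", "dne1_xrn4")


def _spike_means(
    cfg: SimulationConfig,
    rec: TranscriptTruth,
    cleav_scale: float,
    decap_scale: float,
) -> dict[str, dict[str, float]]:
    """Expected spike CPM per genotype for one transcript (cleavage and
    genotype-dependent decap components), scaled by transcript abundance."""
    eff = 2.0 ** cfg.cleavage_effect_log2
    deff = 2.0 ** cfg.decap_effect_log2
    cleav = {g: 0.0 for g in GENOTYPE_ORDER + ("cap_pare",)}
    decap = {g: 0.0 for g in GENOTYPE_ORDER + ("cap_pare",)}
    if rec.class_label == CLASS_TARGET:
        s = cfg.cleavage_spike_cpm * cleav_scale
        cleav["xrn4"] = s
        cleav["wild_type"] = s / eff
        cleav["dne1_xrn4"] = s / eff
    if rec.class_label in (CLASS_TARGET, CLASS_DECAP):
        d = cfg.decap_spike_cpm * decap_scale
        decap["xrn4"] = d
        decap["dne1_xrn4"] = d * cfg.decap_redistribution
        decap["wild_type"] = d / deff
        decap["cap_pare"] = d
    return {"cleavage": cleav, "decap": decap}


def simulate_degradome(
    cfg: SimulationConfig,
    truth: SyntheticTruth,
    rng: Optional[np.random.Generator] = None,
) -> SimulatedDataset:
    """Raw profiles for the three genotypes x replicates, plus a Cap-PARE
    profile, an RNA-seq abundance table and a half-life table.

    Depth budget per library: a thin uniform background along spliced
    transcripts (``background_fraction`` of depth, identical in every
    genotype), the genotype-dependent cleavage/decap spikes, and a
    constitutive genotype-independent 5'-end flux at the TSS of
    insensitive-class transcripts that absorbs the remaining depth, so
    library totals land within sampling error of the configured depth. The
    Cap-PARE library instead spreads the non-background depth over every
    transcript's TSS (it marks decapping sites, not decay intermediates).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    models = truth.transcripts
    records = truth.records
    n = len(models)
    abundance = np.exp(rng.normal(0.0, cfg.abundance_sigma, size=n))
    decap_jitter = np.exp(rng.normal(0.0, cfg.decap_sigma, size=n))
    for rec, a in zip(records, abundance):
        rec.abundance = float(a)
    lengths = np.array([m.length for m in models])
    weight_sum = float(np.sum(abundance * lengths))
    a_sum = float(np.sum(abundance))

    # genomic coordinate array per transcript, in spliced order
    gpos: list[np.ndarray] = []
    for m in models:
        arr = np.concatenate([np.arange(s, e) for s, e in m.exons])
        if m.strand == "-":
            arr = arr[::-1]
        gpos.append(arr)

    cleav_scale = np.maximum(abundance, cfg.cleavage_abundance_floor)
    decap_scale = abundance * decap_jitter
    spikes = [
        _spike_means(cfg, rec, float(cleav_scale[i]), float(decap_scale[i]))
        for i, rec in enumerate(records)
    ]
    per_count = cfg.depth / 1e6  # counts per CPM unit

    insensitive_idx = [
        i for i, r in enumerate(records) if r.class_label == CLASS_INSENSITIVE
    ]
    a_ins = float(np.sum(abundance[insensitive_idx])) if insensitive_idx else 0.0

    def expected_spike_total(genotype: str) -> float:
        return sum(
            (sp["cleavage"][genotype] + sp["decap"][genotype]) * per_count
            for sp in spikes
        )

    def make_library(genotype: str, replicate: int, library_id: str) -> RawProfile:
        bg_frac = (
            cfg.cap_background_fraction
            if genotype == "cap_pare"
            else cfg.background_fraction
        )
        bg_total = bg_frac * cfg.depth
        spike_total = expected_spike_total(genotype)
        sink_total = max(cfg.depth - bg_total - spike_total, 0.0)
        # constitutive TSS flux: insensitive transcripts for genotype
        # libraries, all transcripts for the decap-marking library
        if genotype == "cap_pare":
            sink_idx, sink_a = list(range(n)), a_sum
        else:
            sink_idx, sink_a = insensitive_idx, a_ins
        sink_mask = np.zeros(n, dtype=bool)
        sink_mask[sink_idx] = True
        size = cfg.nb_dispersion
        counts: dict[tuple[str, str, int], int] = {}
        for t_idx, m in enumerate(models):
            mu = bg_total * abundance[t_idx] / weight_sum
            p = size / (size + mu)
            vec = rng.negative_binomial(size, p, size=m.length)
            sp = spikes[t_idx]
            cl_cpm = sp["cleavage"][genotype]
            if cl_cpm > 0 and records[t_idx].cleavage_spliced is not None:
                vec[records[t_idx].cleavage_spliced] += rng.poisson(cl_cpm * per_count)
            dc_cpm = sp["decap"][genotype]
            if dc_cpm > 0:
                vec[0] += rng.poisson(dc_cpm * per_count)
            if sink_a > 0 and sink_mask[t_idx]:
                vec[0] += rng.poisson(sink_total * abundance[t_idx] / sink_a)
            nz = np.nonzero(vec)[0]
            chrom, strand = m.chromosome, m.strand
            garr = gpos[t_idx]
            for s_idx in nz:
                counts[(chrom, strand, int(garr[s_idx]))] = int(vec[s_idx])
        return RawProfile(
            library_id=library_id, genotype=genotype, replicate=replicate, counts=counts
        )

    profiles: dict[tuple[str, int], RawProfile] = {}
    for genotype in GENOTYPE_ORDER:
        for rep in range(1, cfg.replicates + 1):
            profiles[(genotype, rep)] = make_library(
                genotype, rep, f"{genotype}_rep{rep}"
            )
    cap = make_library("cap_pare", 1, "cap_pare_rep1")

    for rec, sp in zip(records, spikes):
        rec.expected_spike_cpm = {g: sp["cleavage"][g] for g in GENOTYPE_ORDER}

    # RNA-seq: no systematic target-transcript difference between genotypes
    rpkm_base = 20.0 * abundance
    noise_x = np.exp(rng.normal(0.0, 0.05, size=n))
    noise_d = np.exp(rng.normal(0.0, 0.05, size=n))
    rpkm_x = rpkm_base * noise_x
    rpkm_d = rpkm_base * noise_d
    rnaseq = pd.DataFrame(
        {
            "transcript_id": [m.transcript_id for m in models],
            "rpkm_xrn4": np.round(rpkm_x, 4),
            "rpkm_double": np.round(rpkm_d, 4),
            "log2fc_double_vs_xrn4": np.round(np.log2(rpkm_d / rpkm_x), 4),
            "fdr": np.round(rng.uniform(0.2, 1.0, size=n), 4),
        }
    )

    is_target = np.array([r.class_label == CLASS_TARGET for r in records])
    med = np.where(is_target, cfg.halflife_target_median, cfg.halflife_other_median)
    halflife = pd.DataFrame(
        {
            "transcript_id": [m.transcript_id for m in models],
            "halflife_min": np.round(
                med * np.exp(rng.normal(0.0, cfg.halflife_sigma, size=n)), 2
            ),
        }
    )

    genome = GenomeSequence(name=f"sim{cfg.seed}", chromosomes={})  # placeholder
    return SimulatedDataset(
        genome=genome,
        truth=truth,
        profiles=profiles,
        cap_pare=cap,
        rnaseq=rnaseq,
        halflife=halflife,
        config=cfg,
    )


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Annotation + degradome in one deterministic pass under cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    genome, truth = simulate_annotation(cfg, rng)
    ds = simulate_degradome(cfg, truth, rng)
    ds.genome = genome
    return ds


# ------------------------------------------------------------------- output


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> list[Path]:
    """Emit FASTA, GFF3, per-library per-strand bedGraphs, RNA-seq and
    half-life TSVs, a truth TSV and a YAML config echo. Returns the paths."""
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []

    fa = outdir / "genome.fa"
    write_genome(ds.genome, fa)
    paths.append(fa)

    gff = outdir / "annotation.gff3"
    write_gff3(ds.truth.transcripts, gff)
    paths.append(gff)

    def emit(profile: RawProfile, stem: str) -> None:
        for strand, tag in (("+", "plus"), ("-", "minus")):
            p = outdir / f"{stem}.{tag}.bedgraph"
            write_bedgraph(profile.counts, strand, p)
            paths.append(p)

    for (genotype, rep), profile in sorted(ds.profiles.items()):
        emit(profile, f"{genotype}_rep{rep}")
    emit(ds.cap_pare, "cap_pare_rep1")

    rp = outdir / "rnaseq.tsv"
    ds.rnaseq.to_csv(rp, sep="\t", index=False)
    paths.append(rp)
    hp = outdir / "halflife.tsv"
    ds.halflife.to_csv(hp, sep="\t", index=False)
    paths.append(hp)

    tp = outdir / "truth.tsv"
    rows = []
    for rec in ds.truth.records:
        rows.append(
            {
                "transcript_id": rec.transcript_id,
                "class_label": rec.class_label,
                "cleavage_spliced": rec.cleavage_spliced,
                "cleavage_genomic": rec.cleavage_genomic,
                "decap_genomic": rec.decap_genomic,
                "motif_offset": rec.motif_offset,
                "abundance": round(rec.abundance, 6),
            }
        )
    pd.DataFrame(rows).to_csv(tp, sep="\t", index=False)
    paths.append(tp)

    cp = outdir / "config.yaml"
    with open(cp, "w") as fh:
        yaml.safe_dump(asdict(ds.config), fh, sort_keys=True)
    paths.append(cp)
    return paths


def write_gff3(transcripts: list[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for tx in sorted(transcripts, key=lambda t: (t.chromosome, t.span[0], t.transcript_id)):
            lo, hi = tx.span
            fh.write(
                f"{tx.chromosome}\tsim\tgene\t{lo + 1}\t{hi}\t.\t{tx.strand}\t.\t"
                f"ID={tx.gene_id}\n"
            )
            fh.write(
                f"{tx.chromosome}\tsim\tmRNA\t{lo + 1}\t{hi}\t.\t{tx.strand}\t.\t"
                f"ID={tx.transcript_id};Parent={tx.gene_id}\n"
            )
            for j, (s, e) in enumerate(tx.exons, 1):
                fh.write(
                    f"{tx.chromosome}\tsim\texon\t{s + 1}\t{e}\t.\t{tx.strand}\t.\t"
                    f"ID={tx.transcript_id}.exon{j};Parent={tx.transcript_id}\n"
                )
            if tx.cds_span is not None:
                cs, ce = tx.cds_span
                for j, (s, e) in enumerate(tx.exons, 1):
                    a, b = max(s, cs), min(e, ce)
                    if a < b:
                        fh.write(
                            f"{tx.chromosome}\tsim\tCDS\t{a + 1}\t{b}\t.\t{tx.strand}\t0\t"
                            f"ID={tx.transcript_id}.cds{j};Parent={tx.transcript_id}\n"
                        )


# ------------------------------------------------------------------ scoring


@dataclass
class RecoveryResult:
    precision: float
    recall: float
    f1: float
    true_positives: int
    false_positives: int
    false_negatives: int
    no_calls: bool
    per_class: dict[str, dict[str, int]]


def evaluate_recovery(
    called_sites,
    truth: SyntheticTruth,
    tolerance_nt: int = 0,
) -> RecoveryResult:
    """Score called sites against planted cleavage positions.

    A call is a true positive iff it lies within ``tolerance_nt`` of a
    planted position on the correct transcript; each planted site can be
    matched at most once. ``called_sites`` needs transcript_id and position
    attributes (CandidateSite works).
    """
    planted = {
        r.transcript_id: r for r in truth.records if r.cleavage_genomic is not None
    }
    matched: set[str] = set()
    tp = fp = 0
    for call in called_sites:
        rec = planted.get(call.transcript_id)
        if (
            rec is not None
            and rec.transcript_id not in matched
            and abs(call.position - rec.cleavage_genomic) <= tolerance_nt
        ):
            matched.add(rec.transcript_id)
            tp += 1
        else:
            fp += 1
    fn = len(planted) - tp
    n_calls = tp + fp
    no_calls = n_calls == 0
    precision = tp / n_calls if n_calls else 0.0
    recall = tp / len(planted) if planted else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    per_class: dict[str, dict[str, int]] = {}
    for rec in truth.records:
        d = per_class.setdefault(rec.class_label, {"planted": 0, "recovered": 0})
        if rec.cleavage_genomic is not None:
            d["planted"] += 1
            if rec.transcript_id in matched:
                d["recovered"] += 1
    return RecoveryResult(
        precision=precision,
        recall=recall,
        f1=f1,
        true_positives=tp,
        false_positives=fp,
        false_negatives=fn,
        no_calls=no_calls,
        per_class=per_class,
    )
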