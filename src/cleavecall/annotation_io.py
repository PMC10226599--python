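"""Genome sequence and transcript-model handling.

All internal coordinates are 0-based, half-open on the forward genomic
strand; GFF3/GTF (1-based, closed) is converted at the parser boundary.
A 5'P site's genomic coordinate is the 5'-most base of the surviving 3'
fragment, which on minus-strand transcripts is the numerically larger
genomic end of the fragment.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GenomeSequence",
    "TranscriptModel",
    "ExonJunction",
    "AnnotationError",
    "CoordinateError",
    "load_genome",
    "write_genome",
    "load_annotation",
    "select_representative_isoforms",
    "reverse_complement",
]

_VALID_BASES = frozenset("ACGTN")

#: chromosome names treated as organellar (everything else is nuclear)
ORGANELLE_NAMES = frozenset(
    {"chrm", "chrc", "mt", "pt", "mito", "chloroplast", "chrmt", "chrpt"}
)


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation/sequence input."""


class CoordinateError(ValueError):
    """A genomic position outside the queried transcript's span."""


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class GenomeSequence:
    """A named set of chromosome sequences (A/C/G/T/N, uppercase)."""

    name: str
    chromosomes: dict[str, str]

    def __post_init__(self) -> None:
        for chrom, seq in self.chromosomes.items():
            if not seq:
                raise AnnotationError(f"chromosome {chrom!r} has empty sequence")
            bad = set(seq.upper()) - _VALID_BASES
            if bad:
                raise AnnotationError(
                    f"chromosome {chrom!r} contains invalid bases {sorted(bad)}"
                )
            self.chromosomes[chrom] = seq.upper()

    def length(self, chrom: str) -> int:
        return len(self.chromosomes[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.chromosomes[chrom][start:end]


@dataclass(frozen=True)
class ExonJunction:
    """One exon-exon boundary in spliced-transcript coordinates.

    ``transcript_coordinate`` is the 0-based spliced position of the last
    base of the upstream exon.
    """

    transcript_id: str
    junction_index: int
    transcript_coordinate: int


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]
    cds_span: Optional[tuple[int, int]] = None
    is_protein_coding: bool = False
    is_nuclear: bool = True
    # caches, built lazily
    _cum: list[int] = field(default_factory=list, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        exons = sorted(self.exons)
        for (s, e) in exons:
            if e <= s:
                raise AnnotationError(f"{self.transcript_id}: empty exon [{s},{e})")
        for (_, e0), (s1, _) in zip(exons, exons[1:]):
            if s1 < e0:
                raise AnnotationError(f"{self.transcript_id}: overlapping exons")
        self.exons = exons
        if self.cds_span is not None:
            cs, ce = self.cds_span
            if ce <= cs:
                raise AnnotationError(f"{self.transcript_id}: empty CDS span")
            span = (exons[0][0], exons[-1][1])
            if cs < span[0] or ce > span[1]:
                raise AnnotationError(
                    f"{self.transcript_id}: CDS {self.cds_span} outside exon union"
                )
        self._cum = []
        tot = 0
        for s, e in exons:
            tot += e - s
            self._cum.append(tot)

    # ------------------------------------------------------------------ basics

    @property
    def length(self) -> int:
        return self._cum[-1]

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def tss(self) -> int:
        """Genomic position of the 5'-most transcribed base."""
        if self.strand == "+":
            return self.exons[0][0]
        return self.exons[-1][1] - 1

    def junctions(self) -> list[ExonJunction]:
        n = len(self.exons)
        if n < 2:
            return []
        if self.strand == "+":
            lens = [e - s for s, e in self.exons]
        else:
            lens = [e - s for s, e in reversed(self.exons)]
        out: list[ExonJunction] = []
        cum = 0
        for i, ln in enumerate(lens[:-1]):
            cum += ln
            out.append(ExonJunction(self.transcript_id, i, cum - 1))
        return out

    # ------------------------------------------------- coordinate conversions

    def _plus_offset(self, pos: int) -> Optional[int]:
        """Offset of genomic ``pos`` along the exon union in genomic order,
        or None if intronic; raises for positions outside the span."""
        lo, hi = self.span
        if pos < lo or pos >= hi:
            raise CoordinateError(
                f"position {pos} outside span [{lo},{hi}) of {self.transcript_id}"
            )
        i = bisect.bisect_right([s for s, _ in self.exons], pos) - 1
        s, e = self.exons[i]
        if pos >= e:
            return None
        prev = self._cum[i - 1] if i > 0 else 0
        return prev + (pos - s)

    def genomic_to_transcript(self, pos: int) -> Optional[int]:
        """Spliced 0-based coordinate of genomic ``pos``; None if intronic."""
        off = self._plus_offset(pos)
        if off is None:
            return None
        if self.strand == "+":
            return off
        return self.length - 1 - off

    def transcript_to_genomic(self, s: int) -> int:
        if not 0 <= s < self.length:
            raise CoordinateError(
                f"spliced coordinate {s} out of [0,{self.length}) for {self.transcript_id}"
            )
        off = s if self.strand == "+" else self.length - 1 - s
        i = bisect.bisect_left(self._cum, off + 1)
        prev = self._cum[i - 1] if i > 0 else 0
        es, _ = self.exons[i]
        return es + (off - prev)

    def spliced_sequence(self, genome: GenomeSequence) -> str:
        parts = [genome.fetch(self.chromosome, s, e) for s, e in self.exons]
        seq = "".join(parts)
        if self.strand == "-":
            seq = reverse_complement(seq)
        return seq

    def cds_transcript_interval(self) -> Optional[tuple[int, int]]:
        """CDS as a half-open interval in spliced coordinates, or None."""
        if self.cds_span is None:
            return None
        cs, ce = self.cds_span
        a = self.genomic_to_transcript(cs)
        b = self.genomic_to_transcript(ce - 1)
        if a is None or b is None:
            raise AnnotationError(
                f"{self.transcript_id}: CDS boundary falls in an intron"
            )
        lo, hi = min(a, b), max(a, b)
        return (lo, hi + 1)


# ---------------------------------------------------------------------- FASTA


def load_genome(path: str | Path, name: Optional[str] = None) -> GenomeSequence:
    path = Path(path)
    chroms: dict[str, str] = {}
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in chroms:
                raise AnnotationError(f"duplicate chromosome name {rec.id!r}")
            chroms[rec.id] = str(rec.seq)
    except ValueError as exc:  # Biopython parse failure
        raise AnnotationError(f"malformed FASTA {path}: {exc}") from exc
    if not chroms:
        raise AnnotationError(f"no FASTA records in {path}")
    return GenomeSequence(name=name or path.stem, chromosomes=chroms)


def write_genome(genome: GenomeSequence, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in genome.chromosomes:
            fh.write(f">{chrom}\n")
            seq = genome.chromosomes[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ----------------------------------------------------------------------- GFF3


def _is_nuclear(chrom: str) -> bool:
    return chrom.lower() not in ORGANELLE_NAMES


def load_annotation(
    path: str | Path, genome: GenomeSequence
) -> list[TranscriptModel]:
    """Parse a GFF3 or GTF file into validated transcript models.

    Transcripts on chromosomes absent from ``genome`` are rejected, as are
    exons outside chromosome bounds and CDS features not covered by exons.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    models: list[TranscriptModel] = []
    tx_types = {"mRNA", "transcript", "ncRNA", "lnc_RNA", "tRNA", "rRNA", "snoRNA"}
    for feat in db.all_features():
        if feat.featuretype not in tx_types:
            continue
        tid = feat.attributes.get("ID", [None])[0] or feat.attributes.get(
            "transcript_id", [None]
        )[0]
        if tid is None:
            raise AnnotationError(f"transcript feature at {feat.seqid}:{feat.start} lacks an id")
        gid = feat.attributes.get("Parent", [None])[0] or feat.attributes.get(
            "gene_id", [tid]
        )[0]
        chrom = feat.seqid
        if chrom not in genome.chromosomes:
            raise AnnotationError(
                f"transcript {tid} on chromosome {chrom!r} absent from genome"
            )
        exons: list[tuple[int, int]] = []
        cds_lo, cds_hi = None, None
        for child in db.children(feat.id):
            iv = (child.start - 1, child.end)  # GFF 1-based closed -> half-open
            if child.featuretype == "exon":
                exons.append(iv)
            elif child.featuretype == "CDS":
                cds_lo = iv[0] if cds_lo is None else min(cds_lo, iv[0])
                cds_hi = iv[1] if cds_hi is None else max(cds_hi, iv[1])
        if not exons:
            raise AnnotationError(f"transcript {tid} has no exon features")
        clen = genome.length(chrom)
        for s, e in exons:
            if s < 0 or e > clen:
                raise AnnotationError(
                    f"transcript {tid}: exon [{s},{e}) outside chromosome bounds (len {clen})"
                )
        cds = None
        if cds_lo is not None:
            cds = (cds_lo, cds_hi)
        model = TranscriptModel(
            transcript_id=tid,
            gene_id=gid,
            chromosome=chrom,
            strand=feat.strand,
            exons=exons,
            cds_span=cds,
            is_protein_coding=cds is not None,
            is_nuclear=_is_nuclear(chrom),
        )
        if cds is not None:
            # both CDS endpoints must be exonic
            if (
                model.genomic_to_transcript(cds[0]) is None
                or model.genomic_to_transcript(cds[1] - 1) is None
            ):
                raise AnnotationError(
                    f"transcript {tid}: CDS {cds} not covered by exons"
                )
        models.append(model)
    return models


def select_representative_isoforms(
    transcripts: Iterable[TranscriptModel],
) -> list[TranscriptModel]:
    """One isoform per gene: longest CDS, tie-break longest transcript,
    then lexicographically smallest transcript id."""
    best: dict[str, TranscriptModel] = {}
    for tx in transcripts:
        cds_len = 0
        if tx.cds_span is not None:
            iv = tx.cds_transcript_interval()
            cds_len = iv[1] - iv[0]
        key = (-cds_len, -tx.length, tx.transcript_id)
        cur = best.get(tx.gene_id)
        if cur is None:
            best[tx.gene_id] = tx
            continue
        cur_cds = 0
        if cur.cds_span is not None:
            civ = cur.cds_transcript_interval()
            cur_cds = civ[1] - civ[0]
        cur_key = (-cur_cds, -cur.length, cur.transcript_id)
        if key < cur_key:
            best[tx.gene_id] = tx
    return sorted(best.values(), key=lambda t: t.transcript_id)
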