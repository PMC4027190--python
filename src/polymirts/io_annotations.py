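"""Input/output for the standard formats and allele-aware SNP window construction.

Readers cover mature-miRNA FASTA, 11-column refFlat transcript annotation, genome
FASTA and a simple SNP table (TSV: rs_id, chrom, 0-based position, reference
allele, alternate allele).  All readers tolerate gzip-compressed files.

Downstream logic is RNA-space: DNA is normalized to RNA (T -> U, uppercase) at
parse time.  Internal coordinates are 0-based half-open; report output is
1-based.  For a minus-strand transcript the mRNA-sense alleles stored on a
:class:`SNPContext` are the complements of the genomic alleles.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqUtils import seq3

from .errors import ReferenceMismatchError, ValidationError

RNA_ALPHABET = frozenset("ACGU")
DNA_ALPHABET = frozenset("ACGT")

_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def to_rna(seq: str) -> str:
    """Uppercase and normalize T->U."""
    return seq.upper().replace("T", "U")


def revcomp_dna(seq: str) -> str:
    return seq.upper().translate(_DNA_COMPLEMENT)[::-1]


def complement_dna(base: str) -> str:
    return base.upper().translate(_DNA_COMPLEMENT)


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


class Region(str, Enum):
    """Transcript region holding a SNP."""

    FIVE_UTR = "5'UTR"
    CDS = "CDS"
    THREE_UTR = "3'UTR"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MiRNARecord:
    """A named mature miRNA sequence, 5'->3', RNA alphabet."""

    name: str
    sequence: str

    def __post_init__(self):
        seq = to_rna(self.sequence)
        object.__setattr__(self, "sequence", seq)
        if not self.name:
            raise ValidationError("miRNA record with empty name")
        if not seq:
            raise ValidationError(f"miRNA {self.name!r} has an empty sequence")
        bad = set(seq) - RNA_ALPHABET
        if bad:
            raise ValidationError(
                f"miRNA {self.name!r} contains non-ACGU characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TranscriptAnnotation:
    """One refFlat transcript: exon structure plus CDS bounds (genomic, 0-based half-open)."""

    gene: str
    transcript_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValidationError(f"{self.transcript_id}: strand must be + or -")
        if len(self.exon_starts) != len(self.exon_ends):
            raise ValidationError(
                f"{self.transcript_id}: exonStarts/exonEnds length mismatch"
            )
        prev_end = -1
        for s, e in zip(self.exon_starts, self.exon_ends):
            if s >= e:
                raise ValidationError(f"{self.transcript_id}: empty or inverted exon {s}-{e}")
            if s < prev_end:
                raise ValidationError(
                    f"{self.transcript_id}: exons unsorted or overlapping at {s}"
                )
            prev_end = e
        if not (self.tx_start <= self.exon_starts[0] and self.exon_ends[-1] <= self.tx_end):
            raise ValidationError(f"{self.transcript_id}: exons outside tx bounds")
        if self.cds_start < self.cds_end:  # coding
            if not (self.exon_starts[0] <= self.cds_start and self.cds_end <= self.exon_ends[-1]):
                raise ValidationError(f"{self.transcript_id}: CDS outside exon span")

    @property
    def exon_count(self) -> int:
        return len(self.exon_starts)

    @property
    def mrna_length(self) -> int:
        return sum(e - s for s, e in zip(self.exon_starts, self.exon_ends))

    @property
    def is_coding(self) -> bool:
        return self.cds_start < self.cds_end

    # -- coordinate mapping -------------------------------------------------

    def genomic_to_transcript(self, gpos: int) -> Optional[int]:
        """Map a genomic position to a 0-based mRNA-sense transcript position.

        Returns None for intronic / out-of-transcript positions.
        """
        offset = 0
        plus_pos = None
        for s, e in zip(self.exon_starts, self.exon_ends):
            if s <= gpos < e:
                plus_pos = offset + (gpos - s)
                break
            offset += e - s
        if plus_pos is None:
            return None
        if self.strand == "+":
            return plus_pos
        return self.mrna_length - 1 - plus_pos

    def transcript_sequence(self, genome: Mapping[str, str]) -> str:
        """mRNA-sense transcript sequence as RNA."""
        chrom_seq = _chrom_seq(genome, self.chrom, self.transcript_id)
        dna = "".join(chrom_seq[s:e] for s, e in zip(self.exon_starts, self.exon_ends))
        if self.strand == "-":
            dna = revcomp_dna(dna)
        return to_rna(dna)

    def cds_span_transcript(self) -> Optional[tuple[int, int]]:
        """CDS interval in transcript coordinates (0-based half-open), mRNA sense."""
        if not self.is_coding:
            return None
        # positions of first/last coding base in plus-strand transcript coords
        first = self._plus_transcript_pos(self.cds_start)
        last = self._plus_transcript_pos(self.cds_end - 1)
        if self.strand == "+":
            return first, last + 1
        n = self.mrna_length
        return n - 1 - last, n - first

    def _plus_transcript_pos(self, gpos: int) -> int:
        offset = 0
        for s, e in zip(self.exon_starts, self.exon_ends):
            if s <= gpos < e:
                return offset + (gpos - s)
            offset += e - s
        raise ValidationError(
            f"{self.transcript_id}: genomic position {gpos} not exonic"
        )

    def region_of(self, tpos: int) -> Region:
        """Region (5'UTR / CDS / 3'UTR) of a transcript position."""
        if not 0 <= tpos < self.mrna_length:
            raise ValidationError(f"{self.transcript_id}: transcript position {tpos} out of range")
        span = self.cds_span_transcript()
        if span is None:
            # non-coding transcript: treat the whole mRNA as 3'UTR-like
            return Region.THREE_UTR
        cs, ce = span
        if tpos < cs:
            return Region.FIVE_UTR
        if tpos < ce:
            return Region.CDS
        return Region.THREE_UTR


@dataclass(frozen=True)
class SNPRecord:
    """One biallelic SNP; ``allele_a`` is the reference allele by convention.

    Alleles are genomic-sense single nucleotides, or "-" for a deletion allele
    (at most one of the two).
    """

    rs_id: str
    chrom: str
    position: int  # 0-based genomic
    allele_a: str
    allele_b: str

    def __post_init__(self):
        object.__setattr__(self, "allele_a", self.allele_a.upper())
        object.__setattr__(self, "allele_b", self.allele_b.upper())
        if self.allele_a == self.allele_b:
            raise ValidationError(f"{self.rs_id}: alleles must differ")
        if self.allele_a == "-" and self.allele_b == "-":
            raise ValidationError(f"{self.rs_id}: at most one allele may be a deletion")
        for al in (self.allele_a, self.allele_b):
            if al != "-" and (len(al) != 1 or al not in DNA_ALPHABET):
                raise ValidationError(f"{self.rs_id}: bad allele {al!r}")
        if self.position < 0:
            raise ValidationError(f"{self.rs_id}: negative position")

    @property
    def is_deletion(self) -> bool:
        return "-" in (self.allele_a, self.allele_b)


@dataclass(frozen=True)
class SNPContext:
    """A SNP placed on one transcript, with both allele-specific mRNA-sense windows.

    ``window_a``/``window_b`` carry allele A / allele B and differ only at the
    SNP offset (or by one deleted base).  ``allele_a_mrna``/``allele_b_mrna``
    are the alleles in mRNA-sense orientation.  ``codon_number`` is 1-based and
    defined only for CDS SNPs.
    """

    snp: SNPRecord
    transcript_id: str
    region: Region
    transcript_position: int
    window_a: str
    window_b: str
    snp_offset_a: int
    snp_offset_b: int
    allele_a_mrna: str
    allele_b_mrna: str
    codon_number: Optional[int] = None
    codon_offset: Optional[int] = None

    @property
    def rs_id(self) -> str:
        return self.snp.rs_id

    def window(self, allele: str) -> str:
        return self.window_a if allele.upper() == "A" else self.window_b

    def snp_offset(self, allele: str) -> int:
        return self.snp_offset_a if allele.upper() == "A" else self.snp_offset_b

    def allele_base(self, allele: str) -> str:
        return self.allele_a_mrna if allele.upper() == "A" else self.allele_b_mrna


@dataclass(frozen=True)
class Consequence:
    """Coding-consequence label plus the residue-style ID string (e.g. Asn38Ser)."""

    label: str  # missense | synonymous | stop_gained | stop_lost | start_lost | frameshift | utr
    ident: str


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_mirnas(path) -> list[MiRNARecord]:
    """Read mature miRNA sequences from FASTA, normalizing to uppercase RNA."""
    records: list[MiRNARecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if not rec.id:
                raise ValidationError(f"{path}: FASTA record with empty name")
            if rec.id in seen:
                raise ValidationError(f"{path}: duplicate miRNA name {rec.id!r}")
            seen.add(rec.id)
            records.append(MiRNARecord(rec.id, str(rec.seq)))
    if not records:
        raise ValidationError(f"{path}: no FASTA records found")
    return records


def write_mirnas(records: Iterable[MiRNARecord], path) -> None:
    recs = [SeqRecord(Seq(r.sequence), id=r.name, description="") for r in records]
    SeqIO.write(recs, str(path), "fasta")


def read_genome(path) -> dict[str, str]:
    """Read a genome/transcriptome FASTA into a dict of uppercase DNA strings."""
    genome: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in genome:
                raise ValidationError(f"{path}: duplicate sequence name {rec.id!r}")
            genome[rec.id] = str(rec.seq).upper()
    if not genome:
        raise ValidationError(f"{path}: no FASTA records found")
    return genome


def write_genome(genome: Mapping[str, str], path) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in genome.items()]
    SeqIO.write(recs, str(path), "fasta")


_REFFLAT_COLUMNS = 11


def read_refflat(path) -> list[TranscriptAnnotation]:
    """Read 11-column refFlat (geneName, name, chrom, strand, txStart, txEnd,
    cdsStart, cdsEnd, exonCount, exonStarts, exonEnds)."""
    out: list[TranscriptAnnotation] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _REFFLAT_COLUMNS:
                raise ValidationError(
                    f"{path}:{lineno}: expected {_REFFLAT_COLUMNS} columns, got {len(cols)}"
                )
            try:
                starts = tuple(int(x) for x in cols[9].rstrip(",").split(",") if x)
                ends = tuple(int(x) for x in cols[10].rstrip(",").split(",") if x)
                exon_count = int(cols[8])
                tx = TranscriptAnnotation(
                    gene=cols[0],
                    transcript_id=cols[1],
                    chrom=cols[2],
                    strand=cols[3],
                    tx_start=int(cols[4]),
                    tx_end=int(cols[5]),
                    cds_start=int(cols[6]),
                    cds_end=int(cols[7]),
                    exon_starts=starts,
                    exon_ends=ends,
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: unparseable field: {exc}") from exc
            if exon_count != len(starts):
                raise ValidationError(
                    f"{path}:{lineno}: exonCount {exon_count} != {len(starts)} exonStarts"
                )
            out.append(tx)
    return out


def write_refflat(transcripts: Iterable[TranscriptAnnotation], path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(
                "\t".join(
                    [
                        t.gene,
                        t.transcript_id,
                        t.chrom,
                        t.strand,
                        str(t.tx_start),
                        str(t.tx_end),
                        str(t.cds_start),
                        str(t.cds_end),
                        str(t.exon_count),
                        ",".join(str(x) for x in t.exon_starts) + ",",
                        ",".join(str(x) for x in t.exon_ends) + ",",
                    ]
                )
                + "\n"
            )


def read_snps(path) -> list[SNPRecord]:
    """Read SNP TSV: rs_id, chrom, 0-based position, allele_a (reference), allele_b."""
    out: list[SNPRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 5:
                raise ValidationError(f"{path}:{lineno}: expected 5 columns, got {len(cols)}")
            try:
                out.append(
                    SNPRecord(cols[0], cols[1], int(cols[2]), cols[3], cols[4])
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: unparseable position: {exc}") from exc
    return out


def write_snps(snps: Iterable[SNPRecord], path) -> None:
    with open(path, "w") as fh:
        for s in snps:
            fh.write(f"{s.rs_id}\t{s.chrom}\t{s.position}\t{s.allele_a}\t{s.allele_b}\n")


def _chrom_seq(genome: Mapping[str, str], chrom: str, what: str) -> str:
    try:
        return genome[chrom]
    except KeyError:
        raise ValidationError(f"{what}: chromosome {chrom!r} not in genome") from None


# ---------------------------------------------------------------------------
# SNP window construction
# ---------------------------------------------------------------------------

DEFAULT_FLANK = 30


def build_snp_context(
    snp: SNPRecord,
    tx: TranscriptAnnotation,
    genome: Mapping[str, str],
    flank: int = DEFAULT_FLANK,
) -> Optional[SNPContext]:
    """Construct the allele-specific mRNA-sense windows around a SNP on one transcript.

    Returns None when the SNP is not exonic on this transcript (or on another
    chromosome).  Raises ReferenceMismatchError when the declared reference
    allele (allele_a) disagrees with the genome base at the SNP position.
    """
    if flank < 1:
        raise ValidationError("flank must be >= 1")
    if snp.chrom != tx.chrom:
        return None
    tpos = tx.genomic_to_transcript(snp.position)
    if tpos is None:
        return None

    chrom_seq = _chrom_seq(genome, tx.chrom, snp.rs_id)
    genome_base = chrom_seq[snp.position : snp.position + 1].upper()
    if snp.allele_a == "-":
        raise ValidationError(
            f"{snp.rs_id}: reference allele cannot be a deletion in this model"
        )
    if genome_base != snp.allele_a:
        raise ReferenceMismatchError(
            f"{snp.rs_id}: reference allele {snp.allele_a} does not match genome "
            f"base {genome_base!r} at {tx.chrom}:{snp.position}"
        )

    mrna = tx.transcript_sequence(genome)  # RNA, mRNA sense
    # mRNA-sense alleles (RNA alphabet); complement for minus strand
    def to_mrna_allele(al: str) -> str:
        if al == "-":
            return "-"
        if tx.strand == "-":
            al = complement_dna(al)
        return to_rna(al)

    allele_a_mrna = to_mrna_allele(snp.allele_a)
    allele_b_mrna = to_mrna_allele(snp.allele_b)
    if mrna[tpos] != allele_a_mrna:
        raise ReferenceMismatchError(
            f"{snp.rs_id}: transcript base {mrna[tpos]} != mRNA-sense reference "
            f"allele {allele_a_mrna} at transcript position {tpos}"
        )

    start = max(0, tpos - flank)
    end = min(len(mrna), tpos + flank + 1)
    window_a = mrna[start:end]
    offset = tpos - start
    if allele_b_mrna == "-":
        window_b = window_a[:offset] + window_a[offset + 1 :]
        # the junction base: offset clipped into the shorter window
        offset_b = min(offset, max(len(window_b) - 1, 0))
    else:
        window_b = window_a[:offset] + allele_b_mrna + window_a[offset + 1 :]
        offset_b = offset

    region = tx.region_of(tpos)
    codon_number = codon_offset = None
    if region is Region.CDS:
        cs, _ = tx.cds_span_transcript()
        cds_pos = tpos - cs
        codon_number = cds_pos // 3 + 1
        codon_offset = cds_pos % 3

    return SNPContext(
        snp=snp,
        transcript_id=tx.transcript_id,
        region=region,
        transcript_position=tpos,
        window_a=window_a,
        window_b=window_b,
        snp_offset_a=offset,
        snp_offset_b=offset_b,
        allele_a_mrna=allele_a_mrna,
        allele_b_mrna=allele_b_mrna,
        codon_number=codon_number,
        codon_offset=codon_offset,
    )


# ---------------------------------------------------------------------------
# Coding-consequence annotation
# ---------------------------------------------------------------------------


def _aa3(aa: str) -> str:
    if aa == "*":
        return "Ter"
    return seq3(aa)


def annotate_consequence(ctx: SNPContext, cds_sequence: str) -> Consequence:
    """Classify the allele change and build the residue-style ID string.

    For UTR SNPs the ID mirrors the convention ``3'UTR-<ref><pos><alt>`` with a
    1-based position inside that UTR.  For CDS SNPs the standard genetic code
    is applied to the reference (allele A) and alternate (allele B) codons:
    missense ``Asn38Ser``, synonymous ``Gly344=``, stop gained ``Cys302Ter``,
    stop lost ``Ter123Gln``, start lost ``Met1Lys`` and deletion alleles
    ``Ala608fs`` (frameshift).
    """
    if ctx.region is not Region.CDS:
        span_tag = "5'UTR" if ctx.region is Region.FIVE_UTR else "3'UTR"
        # position within the UTR is derived from the codon-free transcript
        # position relative to the window; report the SNP's transcript position
        # 1-based within the region when known, else just the alleles.
        ref = ctx.allele_a_mrna
        alt = ctx.allele_b_mrna
        pos = ctx.transcript_position + 1  # 1-based transcript position fallback
        return Consequence("utr", f"{span_tag}-{ref}{pos}{alt}")

    cds = to_rna(cds_sequence)
    if ctx.codon_number is None or ctx.codon_offset is None:
        raise ValidationError(f"{ctx.rs_id}: CDS context without codon assignment")
    cds_pos = (ctx.codon_number - 1) * 3 + ctx.codon_offset
    if cds_pos >= len(cds):
        raise ValidationError(f"{ctx.rs_id}: codon {ctx.codon_number} beyond CDS end")

    if ctx.allele_b_mrna == "-":
        codon_start = (ctx.codon_number - 1) * 3
        codon = cds[codon_start : codon_start + 3]
        aa = _translate_codon(codon, ctx)
        return Consequence("frameshift", f"{_aa3(aa)}{ctx.codon_number}fs")

    codon_start = (ctx.codon_number - 1) * 3
    ref_codon = cds[codon_start : codon_start + 3]
    if len(ref_codon) < 3:
        raise ValidationError(f"{ctx.rs_id}: truncated codon at CDS end")
    if ref_codon[ctx.codon_offset] != ctx.allele_a_mrna:
        raise ValidationError(
            f"{ctx.rs_id}: CDS base {ref_codon[ctx.codon_offset]} != reference allele "
            f"{ctx.allele_a_mrna} at codon {ctx.codon_number}.{ctx.codon_offset}"
        )
    alt_codon = (
        ref_codon[: ctx.codon_offset] + ctx.allele_b_mrna + ref_codon[ctx.codon_offset + 1 :]
    )
    ref_aa = _translate_codon(ref_codon, ctx)
    alt_aa = _translate_codon(alt_codon, ctx)

    n = ctx.codon_number
    if ref_aa == alt_aa:
        return Consequence("synonymous", f"{_aa3(ref_aa)}{n}=")
    if alt_aa == "*":
        return Consequence("stop_gained", f"{_aa3(ref_aa)}{n}Ter")
    if ref_aa == "*":
        return Consequence("stop_lost", f"Ter{n}{_aa3(alt_aa)}")
    if n == 1 and ref_aa == "M":
        return Consequence("start_lost", f"Met1{_aa3(alt_aa)}")
    return Consequence("missense", f"{_aa3(ref_aa)}{n}{_aa3(alt_aa)}")


def _translate_codon(codon: str, ctx: SNPContext) -> str:
    bad = set(codon) - RNA_ALPHABET
    if bad or len(codon) != 3:
        raise ValidationError(
            f"{ctx.rs_id}: codon {codon!r} contains non-ACGU characters or is truncated"
        )
    return str(Seq(codon).translate())
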