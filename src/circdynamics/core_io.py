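"""Shared domain types and plain-text format I/O.

All genomic intervals are 0-based half-open everywhere inside the package.
BED output matches that convention natively; GTF (1-based inclusive,
Ensembl dialect) is converted at the read/write boundary and nowhere else.

A circRNA's identity is the tuple ``(contig, start, end, strand)``; the
string id ``circ_<contig>_<start>_<end>`` is derived for output and never
parsed back.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Optional

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

VALID_BASES = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class Transcript:
    transcript_id: str
    exons: list[tuple[int, int]]  # [start, end), sorted by start
    cds_span: Optional[tuple[int, int]] = None

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class GeneModel:
    gene_id: str
    contig: str
    strand: str  # '+' or '-'
    biotype: str  # protein_coding | lncRNA | other
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)

    def validate(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"{self.gene_id}: bad strand {self.strand!r}")
        for tx in self.transcripts:
            if tx.exons != sorted(tx.exons):
                raise FormatError(f"{tx.transcript_id}: exons not sorted by start")
            for (s1, e1), (s2, e2) in zip(tx.exons, tx.exons[1:]):
                if s2 < e1:
                    raise FormatError(f"{tx.transcript_id}: overlapping exons")
            for s, e in tx.exons:
                if e <= s:
                    raise FormatError(f"{tx.transcript_id}: empty exon [{s},{e})")
            if tx.cds_span is not None:
                if self.biotype != "protein_coding":
                    raise FormatError(
                        f"{self.gene_id}: CDS present under biotype {self.biotype}"
                    )
                cs, ce = tx.cds_span
                covered = sum(
                    max(0, min(e, ce) - max(s, cs)) for s, e in tx.exons
                )
                if cs < tx.start or ce > tx.end or covered <= 0:
                    raise FormatError(
                        f"{tx.transcript_id}: cds_span outside exon union"
                    )


@dataclass
class GenomeBundle:
    """Genome sequences plus gene models; coordinate authority for all stages."""

    sequences: dict[str, str]
    genes: list[GeneModel]

    def validate(self) -> None:
        for g in self.genes:
            if g.contig not in self.sequences:
                raise FormatError(f"{g.gene_id}: unknown contig {g.contig}")
            clen = len(self.sequences[g.contig])
            for tx in g.transcripts:
                for s, e in tx.exons:
                    if s < 0 or e > clen:
                        raise FormatError(
                            f"{tx.transcript_id}: exon [{s},{e}) outside "
                            f"contig {g.contig} (length {clen})"
                        )
            g.validate()

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def transcript_sequence(self, gene: GeneModel, tx: Transcript) -> str:
        """Spliced transcript sequence, transcript sense (5'->3')."""
        seq = "".join(self.sequences[gene.contig][s:e] for s, e in tx.exons)
        return seq if gene.strand == "+" else revcomp(seq)


@dataclass
class CircCandidate:
    contig: str
    start: int  # first base of circle, 0-based
    end: int  # one past last base
    strand: str
    junction_reads: dict[str, int] = field(default_factory=dict)
    flank_donor: str = ""
    flank_acceptor: str = ""

    @property
    def circ_id(self) -> str:
        return f"circ_{self.contig}_{self.start}_{self.end}"

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.contig, self.start, self.end, self.strand)

    def check_flanks(self, sequences: dict[str, str]) -> bool:
        """GT-AG rule re-checked from genome.

        Plus strand: AG|circle|GT in genomic forward orientation.  Minus
        strand: the reverse complement (AC before start, CT after end).
        """
        seq = sequences[self.contig]
        if self.start < 2 or self.end + 2 > len(seq):
            return False
        left = seq[self.start - 2 : self.start]
        right = seq[self.end : self.end + 2]
        if self.strand == "+":
            return left == "AG" and right == "GT"
        return left == "AC" and right == "CT"


@dataclass
class Sample:
    sample_id: str
    library: str  # rminus | rnaser
    timepoint: str  # t0 | t24 | t48
    total_mapped_reads: int = 0


@dataclass
class ReadPair:
    read_id: str
    mate1_seq: str
    mate2_seq: str
    mate1_qual: str
    mate2_qual: str
    library: str = ""
    timepoint: str = ""


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered name -> uppercase sequence map.

    Duplicate record names and characters outside ACGTN are errors.
    """
    out: dict[str, str] = {}
    with open(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            name = title.split()[0]
            if name in out:
                raise FormatError(f"duplicate FASTA record name: {name}")
            seq = seq.upper()
            bad = set(seq) - VALID_BASES
            if bad:
                raise FormatError(
                    f"record {name}: invalid characters {sorted(bad)}"
                )
            out[name] = seq
    return out


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_MATE_SUFFIX = re.compile(r"/[12]$")


def _strip_mate(read_id: str) -> str:
    return _MATE_SUFFIX.sub("", read_id)


def read_fastq_pair(path1, path2) -> Iterator[ReadPair]:
    """Lazily yield mate pairs from two matched FASTQ files.

    Ids must match after stripping a ``/1``-``/2`` suffix; unequal record
    counts are an error.
    """
    with open(path1) as f1, open(path2) as f2:
        it1 = FastqGeneralIterator(f1)
        it2 = FastqGeneralIterator(f2)
        while True:
            r1 = next(it1, None)
            r2 = next(it2, None)
            if r1 is None and r2 is None:
                return
            if r1 is None or r2 is None:
                raise FormatError("FASTQ mate files have unequal record counts")
            id1 = _strip_mate(r1[0].split()[0])
            id2 = _strip_mate(r2[0].split()[0])
            if id1 != id2:
                raise FormatError(f"mismatched read ids: {id1!r} vs {id2!r}")
            yield ReadPair(id1, r1[1].upper(), r2[1].upper(), r1[2], r2[2])


def write_fastq_pair(pairs, path1, path2) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.read_id}/1\n{p.mate1_seq}\n+\n{p.mate1_qual}\n")
            f2.write(f"@{p.read_id}/2\n{p.mate2_seq}\n+\n{p.mate2_qual}\n")


# ---------------------------------------------------------------------------
# GTF

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')

_GTF_COLS = [
    "contig", "source", "feature", "start", "end",
    "score", "strand", "frame", "attributes",
]


def _parse_attrs(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_gtf(path) -> list[GeneModel]:
    """Parse an Ensembl-dialect GTF into gene models.

    GTF exon [s, e] (1-based inclusive) becomes [s-1, e) internally.
    Exons are stored sorted by genomic start regardless of strand.
    """
    genes: dict[str, GeneModel] = {}
    tx_of: dict[str, Transcript] = {}
    tx_gene: dict[str, str] = {}
    cds_bounds: dict[str, list[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise FormatError(f"line {lineno}: expected 9 GTF columns")
            contig, _src, feature, start, end, _score, strand, _frame, attrs = fields
            if feature not in ("gene", "transcript", "exon", "CDS"):
                continue
            a = _parse_attrs(attrs)
            if "gene_id" not in a:
                raise FormatError(f"line {lineno}: missing gene_id attribute")
            gid = a["gene_id"]
            s, e = int(start) - 1, int(end)
            if gid not in genes:
                genes[gid] = GeneModel(gid, contig, strand, "other")
            if "gene_biotype" in a:
                bt = a["gene_biotype"]
                genes[gid].biotype = bt if bt in ("protein_coding", "lncRNA") else "other"
            if feature == "gene":
                continue
            tid = a.get("transcript_id")
            if tid is None:
                raise FormatError(f"line {lineno}: missing transcript_id")
            if tid not in tx_of:
                tx_of[tid] = Transcript(tid, [])
                tx_gene[tid] = gid
                genes[gid].transcripts.append(tx_of[tid])
            if feature == "exon":
                tx_of[tid].exons.append((s, e))
            elif feature == "CDS":
                cds_bounds.setdefault(tid, [s, e])
                cds_bounds[tid][0] = min(cds_bounds[tid][0], s)
                cds_bounds[tid][1] = max(cds_bounds[tid][1], e)
    for tid, tx in tx_of.items():
        tx.exons.sort()
        if tid in cds_bounds:
            tx.cds_span = tuple(cds_bounds[tid])
    out = [g for g in genes.values() if g.transcripts]
    for g in out:
        g.validate()
    return out


def write_gtf(genes: list[GeneModel], path) -> None:
    """Emit gene/transcript/exon/CDS features, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        for g in genes:
            base = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            fh.write(
                f"{g.contig}\tcircdynamics\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{base}\n"
            )
            for tx in g.transcripts:
                ta = f'{base} transcript_id "{tx.transcript_id}";'
                fh.write(
                    f"{g.contig}\tcircdynamics\ttranscript\t{tx.start + 1}\t"
                    f"{tx.end}\t.\t{g.strand}\t.\t{ta}\n"
                )
                for s, e in tx.exons:
                    fh.write(
                        f"{g.contig}\tcircdynamics\texon\t{s + 1}\t{e}\t.\t"
                        f"{g.strand}\t.\t{ta}\n"
                    )
                if tx.cds_span is not None:
                    cs, ce = tx.cds_span
                    for s, e in tx.exons:
                        os_, oe = max(s, cs), min(e, ce)
                        if os_ < oe:
                            fh.write(
                                f"{g.contig}\tcircdynamics\tCDS\t{os_ + 1}\t{oe}"
                                f"\t.\t{g.strand}\t0\t{ta}\n"
                            )


# ---------------------------------------------------------------------------
# BED


def write_circ_bed(candidates: list[CircCandidate], path) -> None:
    """BED6: contig, start, end, derived id, total junction reads, strand."""
    rows = sorted(candidates, key=lambda c: (c.contig, c.start, c.end))
    with open(path, "w") as fh:
        for c in rows:
            score = sum(c.junction_reads.values())
            fh.write(
                f"{c.contig}\t{c.start}\t{c.end}\t{c.circ_id}\t{score}\t{c.strand}\n"
            )


def read_circ_bed(path) -> list[CircCandidate]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise FormatError(f"line {lineno}: expected >=6 BED columns")
            contig, start, end, _name, score, strand = fields[:6]
            c = CircCandidate(contig, int(start), int(end), strand)
            if int(score) > 0:
                c.junction_reads["bed"] = int(score)
            out.append(c)
    return out


# ---------------------------------------------------------------------------
# TSV

def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
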