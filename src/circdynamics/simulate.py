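"""Synthetic stranded total-RNA libraries with circular transcripts.

Emulates the study design this package analyses: one cell population
sampled at three timepoints (t0/t24/t48) and sequenced twice per
timepoint — once untreated (``rminus``) and once after RNase R digestion
(``rnaser``) — as 2 x 125 bp stranded paired-end reads.

The generator builds a toy genome whose introns all carry canonical
GT..AG borders (and whose transcript termini are flanked by AG/GT as
well, so every exon-run back-splice validates against the genome),
chooses exon runs as circRNA templates, assigns molecule abundances with
a configurable circular:linear coupling, and samples fragments.

RNase R is modelled as independent Bernoulli survival per molecule
(circles survive with high probability, linear molecules with low
probability); library depth for treated samples scales with the
surviving mass, i.e. the per-molecule sequencing rate is held constant
across the treated/untreated pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core_io import (
    CircCandidate,
    FormatError,
    GeneModel,
    GenomeBundle,
    ReadPair,
    Sample,
    Transcript,
    revcomp,
    write_fasta,
    write_fastq_pair,
    write_gtf,
    write_tsv,
)

LIBRARIES = ("rminus", "rnaser")
TIMEPOINTS = ("t0", "t24", "t48")
SAMPLE_IDS = tuple(f"{lib}_{tp}" for lib in LIBRARIES for tp in TIMEPOINTS)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    seed: int = 42
    contig_name: str = "chrT"
    contig_length: Optional[int] = 100_000  # pad/check; None = content-sized
    n_genes: int = 20
    n_lncrna: int = 2
    exons_per_gene: tuple[int, int] = (4, 8)
    exon_len: tuple[int, int] = (150, 350)
    intron_len: tuple[int, int] = (80, 320)
    read_len: int = 125
    frag_len_mean: float = 250.0
    frag_len_sd: float = 30.0
    n_circ: int = 30
    n_antisense_circ: int = 1
    n_intergenic_circ: int = 1
    circ_exon_count_dist: dict[int, float] = field(
        default_factory=lambda: {1: 0.10, 2: 0.40, 3: 0.35, 4: 0.10, 5: 0.05}
    )
    circ_fraction_model: str = "saturating"  # independent | saturating | constant
    circ_fraction: float = 0.1  # constant model
    circ_cmax: float = 20.0  # saturating model ceiling (molecules)
    circ_K: float = 100.0  # saturating half-point (linear molecules)
    linear_mu: float = math.log(60.0)  # log-normal linear molecules
    linear_sigma: float = 1.0
    p_survive_linear: float = 0.05
    p_survive_circ: float = 0.9
    depth_per_sample: int = 10_000
    error_rate: float = 0.001
    unspliced_fraction: float = 0.05
    n_up: int = 4
    n_down: int = 4
    effect_up: float = 2.5
    effect_down: float = 0.4

    def validate(self) -> None:
        if not (0.0 <= self.p_survive_linear <= self.p_survive_circ <= 1.0):
            raise ValueError(
                "RNase R must degrade linear RNA preferentially: require "
                "0 <= p_survive_linear <= p_survive_circ <= 1"
            )
        if self.effect_up <= 1.5:
            raise ValueError("effect_up must exceed 1.5 to be screenable")
        if self.effect_down >= 0.67:
            raise ValueError("effect_down must be below 0.67 to be screenable")
        if self.exon_len[0] < self.read_len:
            raise ValueError("exon_len minimum must be >= read_len so that "
                             "junction reads stay within terminal exons")
        total = sum(self.circ_exon_count_dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("circ_exon_count_dist must sum to 1")


@dataclass
class CircTemplate:
    circ_id: str
    contig: str
    start: int
    end: int
    strand: str
    gene_id: Optional[str]
    exons: list[tuple[int, int]]  # genomic intervals making up the circle
    category: str  # CDS | 5UTR | 3UTR | lncRNA | antisense | unannotated
    seq: str = ""  # spliced circular sequence, transcript sense
    de_direction: str = "unchanged"
    effect: float = 1.0

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def key(self):
        return (self.contig, self.start, self.end, self.strand)


@dataclass
class GroundTruth:
    templates: list[CircTemplate]
    # per (feature_id, sample_id): expected and drawn molecule counts
    abundance: pd.DataFrame = None
    # junction-spanning read records (filled by simulate_reads)
    junction_reads: pd.DataFrame = None
    samples: list[Sample] = field(default_factory=list)

    def template(self, circ_id: str) -> CircTemplate:
        for t in self.templates:
            if t.circ_id == circ_id:
                return t
        raise KeyError(circ_id)


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


# ---------------------------------------------------------------------------
# Genome construction


def build_toy_genome(config: SimConfig, rng: Optional[np.random.Generator] = None
                     ) -> GenomeBundle:
    """Random multi-exon genome on both strands with canonical splice borders.

    Every intron begins GT and ends AG in transcript sense; additionally the
    dinucleotide immediately upstream of each transcript's first exon is AG
    and the one downstream of its last exon is GT, so back-splices over any
    contiguous exon run (including terminal exons) carry genomic AG|circle|GT
    flanks.  Includes lncRNA genes and an antisense-overlapping gene pair.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    parts: list[str] = []
    cursor = 0
    genes: list[GeneModel] = []
    spacers: list[tuple[int, int]] = []  # intergenic intervals for planting

    def emit(seq: str) -> int:
        nonlocal cursor
        parts.append(seq)
        start = cursor
        cursor += len(seq)
        return start

    for gi in range(config.n_genes):
        sp_len = int(rng.integers(200, 401))
        sp_start = emit(_rand_seq(rng, sp_len))
        spacers.append((sp_start, sp_start + sp_len))
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = "lncRNA" if gi < config.n_lncrna else "protein_coding"
        n_ex = int(rng.integers(config.exons_per_gene[0],
                                config.exons_per_gene[1] + 1))
        exon_lens = rng.integers(config.exon_len[0], config.exon_len[1] + 1,
                                 n_ex)
        intron_lens = rng.integers(config.intron_len[0],
                                   config.intron_len[1] + 1, n_ex - 1)
        # Build the gene block in transcript sense, then orient.
        block = ["AG"]
        sense_exons: list[tuple[int, int]] = []  # block-local, sense coords
        pos = 2
        for i, el in enumerate(exon_lens):
            block.append(_rand_seq(rng, int(el)))
            sense_exons.append((pos, pos + int(el)))
            pos += int(el)
            if i < n_ex - 1:
                il = int(intron_lens[i])
                block.append("GT" + _rand_seq(rng, il - 4) + "AG")
                pos += il
        block.append("GT")
        pos += 2
        block_seq = "".join(block)
        assert len(block_seq) == pos
        if strand == "-":
            block_seq = revcomp(block_seq)
            sense_exons = [(pos - e, pos - s) for s, e in sense_exons]
            sense_exons.reverse()
        g_start = emit(block_seq)
        exons = [(g_start + s, g_start + e) for s, e in sense_exons]
        gid = f"G{gi:03d}"
        tx = Transcript(f"T{gi:03d}", exons)
        if biotype == "protein_coding" and n_ex >= 3:
            # first/last genomic exon fully untranslated so UTR-only circles exist
            tx.cds_span = (exons[1][0] + 3, exons[-2][1] - 3)
        elif biotype == "protein_coding":
            tx.cds_span = (exons[0][0] + 3, exons[-1][1] - 3)
        genes.append(GeneModel(gid, config.contig_name, strand, biotype, [tx]))

    tail_start = emit(_rand_seq(rng, int(rng.integers(300, 500))))
    spacers.append((tail_start, cursor))
    seq = "".join(parts)
    if config.contig_length is not None:
        if len(seq) > config.contig_length:
            raise FormatError(
                f"gene content ({len(seq)} bp) exceeds contig_length "
                f"{config.contig_length}"
            )
        seq += _rand_seq(rng, config.contig_length - len(seq))

    # antisense-overlapping annotation: a 1-exon lncRNA opposite a host gene
    host = next((g for g in genes if g.biotype == "protein_coding"), None)
    if host is not None:
        a_start = host.start + 50
        a_exon = (a_start, min(a_start + 250, host.end - 10))
        anti_strand = "-" if host.strand == "+" else "+"
        genes.append(GeneModel("GAS00", config.contig_name, anti_strand,
                               "lncRNA", [Transcript("TAS00", [a_exon])]))

    bundle = GenomeBundle({config.contig_name: seq}, genes)
    bundle._spacers = spacers  # used for planting non-exonic circles
    bundle.validate()
    return bundle


# ---------------------------------------------------------------------------
# Circle templates


def _exonic_category(gene: GeneModel, tx: Transcript,
                     run: list[tuple[int, int]]) -> str:
    if gene.biotype == "lncRNA":
        return "lncRNA"
    if gene.biotype != "protein_coding" or tx.cds_span is None:
        return "unannotated"
    cs, ce = tx.cds_span
    if any(s < ce and e > cs for s, e in run):
        return "CDS"
    start, end = run[0][0], run[-1][1]
    if gene.strand == "+":
        return "5UTR" if end <= cs else "3UTR"
    return "5UTR" if start >= ce else "3UTR"


def _spliced_circ_seq(bundle: GenomeBundle, strand: str,
                      exons: list[tuple[int, int]], contig: str) -> str:
    seq = "".join(bundle.sequences[contig][s:e] for s, e in exons)
    return seq if strand == "+" else revcomp(seq)


def choose_circ_templates(bundle: GenomeBundle, config: SimConfig,
                          rng: Optional[np.random.Generator] = None
                          ) -> list[CircTemplate]:
    """Sample exon-run circRNA templates plus planted non-exonic circles.

    Exon counts are drawn from ``circ_exon_count_dist`` (mode at 2-3 exons);
    a gene may host more than one template.  Antisense/intergenic circles are
    carved from intron or spacer sequence with their canonical flank
    dinucleotides written into the genome.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    ks = np.array(sorted(config.circ_exon_count_dist))
    ps = np.array([config.circ_exon_count_dist[k] for k in ks], dtype=float)
    ps = ps / ps.sum()

    candidates: list[tuple[GeneModel, Transcript]] = [
        (g, tx) for g in bundle.genes for tx in g.transcripts
        if g.gene_id != "GAS00"
    ]
    max_templates = sum(
        len(tx.exons) * (len(tx.exons) + 1) // 2 for _, tx in candidates
    )
    if config.n_circ > max_templates:
        raise FormatError(
            f"n_circ={config.n_circ} exceeds available exon runs "
            f"({max_templates})"
        )
    templates: list[CircTemplate] = []
    seen: set = set()
    attempts = 0
    while len(templates) < config.n_circ and attempts < 50 * config.n_circ:
        attempts += 1
        g, tx = candidates[int(rng.integers(len(candidates)))]
        k = min(int(rng.choice(ks, p=ps)), len(tx.exons))
        i0 = int(rng.integers(0, len(tx.exons) - k + 1))
        run = tx.exons[i0 : i0 + k]
        start, end = run[0][0], run[-1][1]
        key = (g.contig, start, end, g.strand)
        if key in seen:
            continue
        seen.add(key)
        t = CircTemplate(
            circ_id=f"circ_{g.contig}_{start}_{end}",
            contig=g.contig, start=start, end=end, strand=g.strand,
            gene_id=g.gene_id, exons=list(run),
            category=_exonic_category(g, tx, run),
        )
        t.seq = _spliced_circ_seq(bundle, g.strand, run, g.contig)
        templates.append(t)
    if len(templates) < config.n_circ:
        raise FormatError("could not place the requested number of templates")

    templates.extend(_plant_nonexonic(bundle, config, rng))
    _assign_de(templates, config, rng)
    return templates


def _plant_nonexonic(bundle: GenomeBundle, config: SimConfig,
                     rng: np.random.Generator) -> list[CircTemplate]:
    contig = config.contig_name
    seq = list(bundle.sequences[contig])
    out: list[CircTemplate] = []

    def plant(interval: tuple[int, int], strand: str, category: str):
        lo, hi = interval
        length = min(int(rng.integers(160, 241)), hi - lo - 12)
        if length < 150:
            return None
        s = lo + 6
        e = s + length
        if strand == "+":
            seq[s - 2 : s] = "AG"
            seq[e : e + 2] = "GT"
        else:
            seq[s - 2 : s] = "AC"
            seq[e : e + 2] = "CT"
        t = CircTemplate(
            circ_id=f"circ_{contig}_{s}_{e}", contig=contig, start=s, end=e,
            strand=strand, gene_id=None, exons=[(s, e)], category=category,
        )
        return t

    # antisense: inside an intron of a multi-exon protein-coding gene,
    # opposite strand
    planted = 0
    for g in bundle.genes:
        if planted >= config.n_antisense_circ:
            break
        if g.biotype != "protein_coding":
            continue
        tx = g.transcripts[0]
        for (s1, e1), (s2, e2) in zip(tx.exons, tx.exons[1:]):
            if s2 - e1 < 180:
                continue
            # keep the intron's own terminal GT/AG dinucleotides intact
            t = plant((e1 + 8, s2 - 8), "-" if g.strand == "+" else "+",
                      "antisense")
            if t is not None:
                out.append(t)
                planted += 1
                break
    # intergenic
    planted = 0
    for sp in getattr(bundle, "_spacers", []):
        if planted >= config.n_intergenic_circ:
            break
        t = plant(sp, "+", "unannotated")
        if t is not None:
            out.append(t)
            planted += 1

    bundle.sequences[contig] = "".join(seq)
    for t in out:
        t.seq = _spliced_circ_seq(bundle, t.strand, t.exons, t.contig)
    return out


def _assign_de(templates: list[CircTemplate], config: SimConfig,
               rng: np.random.Generator) -> None:
    exonic = [t for t in templates if t.gene_id is not None]
    order = rng.permutation(len(exonic))
    n_up, n_down = config.n_up, config.n_down
    if n_up + n_down > len(exonic):
        raise FormatError("too many DE circles for the template count")
    for idx in order[:n_up]:
        exonic[idx].de_direction = "up"
        exonic[idx].effect = config.effect_up
    for idx in order[n_up : n_up + n_down]:
        exonic[idx].de_direction = "down"
        exonic[idx].effect = config.effect_down


# ---------------------------------------------------------------------------
# Abundances


def _circ_fraction(model: str, linear: float, config: SimConfig,
                   rng: np.random.Generator) -> float:
    if model == "constant":
        return config.circ_fraction
    if model == "saturating":
        # circ molecules saturate with host expression, so the circ:linear
        # ratio falls as the host rises
        return config.circ_cmax / (config.circ_K + linear)
    if model == "independent":
        return float(rng.lognormal(math.log(0.1), 0.5))
    raise ValueError(f"unknown circ_fraction_model {model!r}")


def assign_abundances(truth: GroundTruth, bundle: GenomeBundle,
                      config: SimConfig,
                      rng: Optional[np.random.Generator] = None
                      ) -> GroundTruth:
    """Per-sample expected molecule counts for every circle and host gene.

    Linear abundance per gene is log-normal and constant over time; circular
    abundance couples to it through the chosen fraction model; planted DE
    effects multiply the circle at t24/t48; RNase R samples carry the
    survival-probability expectation.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    linear: dict[str, float] = {}
    for g in bundle.genes:
        linear[g.gene_id] = float(rng.lognormal(config.linear_mu,
                                                config.linear_sigma))
    rows = []
    for g in bundle.genes:
        for lib in LIBRARIES:
            surv = config.p_survive_linear if lib == "rnaser" else 1.0
            for tp in TIMEPOINTS:
                rows.append({
                    "feature_id": g.gene_id, "kind": "linear",
                    "gene_id": g.gene_id,
                    "sample_id": f"{lib}_{tp}",
                    "expected_molecules": linear[g.gene_id] * surv,
                })
    for t in truth.templates:
        base_lin = linear.get(t.gene_id, 50.0) if t.gene_id else 50.0
        frac = _circ_fraction(config.circ_fraction_model, base_lin, config, rng)
        base = frac * base_lin
        for lib in LIBRARIES:
            surv = config.p_survive_circ if lib == "rnaser" else 1.0
            for tp in TIMEPOINTS:
                eff = t.effect if tp in ("t24", "t48") else 1.0
                rows.append({
                    "feature_id": t.circ_id, "kind": "circ",
                    "gene_id": t.gene_id,
                    "sample_id": f"{lib}_{tp}",
                    "expected_molecules": base * eff * surv,
                })
    truth.abundance = pd.DataFrame(rows)
    return truth


# ---------------------------------------------------------------------------
# Read simulation


def _rolling_slice(seq: str, start: int, length: int) -> str:
    """Slice of a circular sequence starting at ``start``, wrapping as needed."""
    L = len(seq)
    reps = (start + length) // L + 1
    return (seq * reps)[start : start + length]


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    k = rng.binomial(len(seq), rate)
    if k == 0:
        return seq
    arr = bytearray(seq, "ascii")
    for pos in rng.integers(0, len(seq), k):
        old = arr[pos]
        choices = [b for b in b"ACGT" if b != old]
        arr[pos] = choices[int(rng.integers(3))]
    return arr.decode()


def _arc_span_offset(a: int, read_len: int, L: int) -> int:
    """Offset of the back-splice inside a read covering circle arc [a, a+rl).

    Returns the number of read bases before the junction, or -1 when the
    read does not cross it.  ``a`` is taken modulo L.
    """
    a = a % L
    if a + read_len > L:
        return L - a
    return -1


def simulate_reads(truth: GroundTruth, bundle: GenomeBundle, config: SimConfig,
                   rng: Optional[np.random.Generator] = None
                   ) -> dict[str, list[ReadPair]]:
    """Sample stranded read pairs per sample and record junction-read truth.

    Fragments are multinomial over templates with weight molecules x length;
    circle fragments start uniformly on the circumference and wrap (rolling
    circle); mate1 carries the transcript-sense strand.  Treated-library
    depth scales with surviving RNA mass (constant per-molecule rate).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    if truth.abundance is None:
        raise ValueError("assign_abundances must run first")
    rl = config.read_len
    exp = truth.abundance.set_index(["feature_id", "sample_id"])[
        "expected_molecules"]

    # transcript-sense sequences for linear templates
    linear_seqs: dict[str, tuple[str, str]] = {}
    for g in bundle.genes:
        tx = g.transcripts[0]
        spliced = bundle.transcript_sequence(g, tx)
        pre = bundle.sequences[g.contig][tx.start : tx.end]
        if g.strand == "-":
            pre = revcomp(pre)
        linear_seqs[g.gene_id] = (spliced, pre)

    # one RNA pool per timepoint: the untreated library samples it
    # directly, the treated one samples the binomially thinned aliquot
    pool: dict[tuple[str, str], int] = {}
    for tp in TIMEPOINTS:
        for g in bundle.genes:
            pool[(g.gene_id, tp)] = int(rng.poisson(
                exp.get((g.gene_id, f"rminus_{tp}"), 0.0)))
        for t in truth.templates:
            pool[(t.circ_id, tp)] = int(rng.poisson(
                exp.get((t.circ_id, f"rminus_{tp}"), 0.0)))

    reads_per_sample: dict[str, list[ReadPair]] = {}
    truth_rows = []
    samples = []
    for lib in LIBRARIES:
        for tp in TIMEPOINTS:
            sid = f"{lib}_{tp}"
            entries = []  # (template_id, circ_template|None, seq, circular, count)
            for g in bundle.genes:
                m = pool[(g.gene_id, tp)]
                if lib == "rnaser":
                    m = rng.binomial(m, config.p_survive_linear)
                spliced, pre = linear_seqs[g.gene_id]
                if m > 0:
                    entries.append((g.gene_id, None, spliced, False,
                                    m * (1 - config.unspliced_fraction)))
                    if len(pre) > len(spliced):
                        entries.append((g.gene_id + ":pre", None, pre, False,
                                        m * config.unspliced_fraction))
            for t in truth.templates:
                m = pool[(t.circ_id, tp)]
                if lib == "rnaser":
                    m = rng.binomial(m, config.p_survive_circ)
                if m > 0:
                    entries.append((t.circ_id, t, t.seq, True, float(m)))
            masses = np.array([c * len(s) for _, _, s, _, c in entries])
            # expected untreated mass incl. the unspliced split, so the
            # per-molecule sequencing rate matches the untreated library
            f = config.unspliced_fraction
            full_mass = sum(
                exp.get((g.gene_id, f"rminus_{tp}"), 0.0)
                * ((1 - f) * len(linear_seqs[g.gene_id][0])
                   + (f * len(linear_seqs[g.gene_id][1])
                      if len(linear_seqs[g.gene_id][1])
                      > len(linear_seqs[g.gene_id][0]) else
                      f * len(linear_seqs[g.gene_id][0])))
                for g in bundle.genes
            ) + sum(
                exp.get((t.circ_id, f"rminus_{tp}"), 0.0) * len(t.seq)
                for t in truth.templates
            )
            if lib == "rminus":
                depth = config.depth_per_sample
            else:
                depth = int(round(config.depth_per_sample
                                  * masses.sum() / full_mass))
            counts = rng.multinomial(depth, masses / masses.sum())
            pairs: list[ReadPair] = []
            serial = 0
            for (tid, tmpl, seq, circular, _m), n_frag in zip(entries, counts):
                if n_frag == 0:
                    continue
                L = len(seq)
                lens = rng.normal(config.frag_len_mean, config.frag_len_sd,
                                  n_frag)
                lens = np.clip(np.rint(lens), rl, None).astype(int)
                if not circular:
                    lens = np.minimum(lens, L)
                    starts = np.floor(
                        rng.random(n_frag) * (L - lens + 1)).astype(int)
                else:
                    starts = rng.integers(0, L, n_frag)
                for fl, st in zip(lens, starts):
                    fl, st = int(fl), int(st)
                    frag = (_rolling_slice(seq, st, fl) if circular
                            else seq[st : st + fl])
                    m1 = _mutate(frag[:rl], rng, config.error_rate)
                    m2 = _mutate(revcomp(frag[-rl:]), rng, config.error_rate)
                    rid = f"{sid}:{serial}"
                    serial += 1
                    pairs.append(ReadPair(rid, m1, m2, "I" * rl, "I" * rl,
                                          library=lib, timepoint=tp))
                    if circular:
                        off1 = _arc_span_offset(st, rl, L)
                        off2 = _arc_span_offset(st + fl - rl, rl, L)
                        if off1 >= 0 or off2 >= 0:
                            truth_rows.append({
                                "read_id": rid, "sample_id": sid,
                                "circ_id": tid,
                                "mate1_offset": off1, "mate2_offset": off2,
                            })
            reads_per_sample[sid] = pairs
            samples.append(Sample(sid, lib, tp, total_mapped_reads=0))
    truth.junction_reads = pd.DataFrame(
        truth_rows,
        columns=["read_id", "sample_id", "circ_id", "mate1_offset",
                 "mate2_offset"],
    )
    truth.samples = samples
    return reads_per_sample


# ---------------------------------------------------------------------------
# Count-level simulation (fast statistical path)


@dataclass
class CountSimConfig:
    """Direct simulation of junction/linear read-count tables.

    Skips sequence space entirely: expectations follow the same abundance
    and survival model as the read simulator, observed counts are Poisson.
    Used for screening power and correlation analyses at gene counts that
    would be wasteful to push through read-level simulation.
    """

    seed: int = 7
    n_up: int = 50
    n_down: int = 50
    n_null: int = 400
    effect_up: float = 2.5
    effect_down: float = 0.4
    junction_cov: tuple[float, float] = (10.0, 60.0)
    linear_cov: tuple[float, float] = (80.0, 800.0)
    fraction_model: str = "independent"
    circ_fraction: float = 0.1
    circ_cmax: float = 8.0
    circ_K: float = 200.0
    p_survive_circ: float = 0.9
    p_survive_linear: float = 0.05
    rnaser_gain: float = 4.0  # per-mass sequencing-rate boost after digestion
    total_mapped: int = 20_000_000
    linear_de: int = 0  # genes whose linear RNA shares the circ effect


def simulate_count_tables(cfg: CountSimConfig,
                          rng: Optional[np.random.Generator] = None
                          ) -> dict[str, pd.DataFrame]:
    """Return calls/linear/samples/truth tables for the 2x3 grid."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_up + cfg.n_down + cfg.n_null
    directions = (["up"] * cfg.n_up + ["down"] * cfg.n_down
                  + ["unchanged"] * cfg.n_null)
    lin_base = rng.uniform(*cfg.linear_cov, n)
    if cfg.fraction_model == "independent":
        circ_base = rng.uniform(*cfg.junction_cov, n)
    elif cfg.fraction_model == "constant":
        circ_base = cfg.circ_fraction * lin_base
    elif cfg.fraction_model == "saturating":
        circ_base = cfg.circ_cmax * lin_base / (cfg.circ_K + lin_base)
    else:
        raise ValueError(cfg.fraction_model)
    effect = np.where(np.array(directions) == "up", cfg.effect_up,
                      np.where(np.array(directions) == "down",
                               cfg.effect_down, 1.0))
    lin_effect = np.ones(n)
    if cfg.linear_de:
        lin_effect[:cfg.linear_de] = effect[:cfg.linear_de]

    call_rows, lin_rows, fpkm_rows, sample_rows = [], [], [], []
    for lib in LIBRARIES:
        circ_scale = cfg.p_survive_circ * cfg.rnaser_gain if lib == "rnaser" else 1.0
        lin_scale = cfg.p_survive_linear * cfg.rnaser_gain if lib == "rnaser" else 1.0
        for tp in TIMEPOINTS:
            sid = f"{lib}_{tp}"
            e = effect if tp != "t0" else 1.0
            le = lin_effect if tp != "t0" else 1.0
            jc = rng.poisson(circ_base * e * circ_scale)
            lc = rng.poisson(lin_base * le * lin_scale)
            # whole-gene fragment counts: an independent, deeper
            # measurement of the same linear abundance (the FPKM proxy)
            gc = rng.poisson(lin_base * le * lin_scale * 10.0)
            tm = int(cfg.total_mapped * rng.uniform(0.9, 1.1))
            sample_rows.append({"sample_id": sid, "library": lib,
                                "timepoint": tp, "total_mapped_reads": tm})
            for i in range(n):
                call_rows.append({"circ_id": f"c{i:04d}", "sample_id": sid,
                                  "junction_reads": int(jc[i])})
                lin_rows.append({"gene_id": f"g{i:04d}", "sample_id": sid,
                                 "linear_reads": int(lc[i])})
                fpkm_rows.append({"gene_id": f"g{i:04d}", "sample_id": sid,
                                  "gene_reads": int(gc[i])})
    truth = pd.DataFrame({
        "circ_id": [f"c{i:04d}" for i in range(n)],
        "gene_id": [f"g{i:04d}" for i in range(n)],
        "direction": directions,
        "circ_base": circ_base,
        "linear_base": lin_base,
    })
    return {
        "calls": pd.DataFrame(call_rows),
        "linear": pd.DataFrame(lin_rows),
        "gene": pd.DataFrame(fpkm_rows),
        "samples": pd.DataFrame(sample_rows),
        "truth": truth,
    }


# ---------------------------------------------------------------------------
# Disk output


def write_simulation(outdir, bundle: GenomeBundle, truth: GroundTruth,
                     reads: dict[str, list[ReadPair]]) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.sequences, outdir / "genome.fa")
    write_gtf(bundle.genes, outdir / "genes.gtf")
    for sid, pairs in reads.items():
        write_fastq_pair(pairs, outdir / f"{sid}_1.fastq",
                         outdir / f"{sid}_2.fastq")
    cat = pd.DataFrame([{
        "circ_id": t.circ_id, "contig": t.contig, "start": t.start,
        "end": t.end, "strand": t.strand, "gene_id": t.gene_id or "",
        "category": t.category, "exon_count": t.exon_count,
        "length": t.length, "de_direction": t.de_direction,
        "effect": t.effect,
    } for t in truth.templates])
    write_tsv(cat, outdir / "truth_circ.tsv")
    write_tsv(truth.abundance, outdir / "truth_expression.tsv")
    if truth.junction_reads is not None:
        write_tsv(truth.junction_reads, outdir / "truth_junction_reads.tsv")


def run_simulation(config: SimConfig, outdir=None):
    """Build genome, templates, abundances and reads in one deterministic call."""
    rng = np.random.default_rng(config.seed)
    bundle = build_toy_genome(config, rng)
    templates = choose_circ_templates(bundle, config, rng)
    truth = GroundTruth(templates=templates)
    assign_abundances(truth, bundle, config, rng)
    reads = simulate_reads(truth, bundle, config, rng)
    if outdir is not None:
        write_simulation(outdir, bundle, truth, reads)
    return bundle, truth, reads
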