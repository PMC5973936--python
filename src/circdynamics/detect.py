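"""Back-spliced junction discovery.

Reads are first aligned end-to-end against the genome and all annotated
spliced transcripts with a small mismatch budget.  Reads that fail to
align linearly are split into terminal anchors; anchor pairs placed
head-to-tail (the 3' anchor upstream of the 5' anchor on the same
contig) seed breakpoint resolution: both anchors are extended toward the
read interior and the unique best-scoring breakpoint whose genomic
flanks read AG | circle | GT (reverse-complemented on the minus strand)
is accepted.  Ambiguous breakpoints, non-canonical flanks, repetitive
placements and mate-inconsistent reads are rejected, each under a
counted category.

The aligner is exact-seed / mismatch-verified and targets toy-scale
genomes; anchor candidate loci are recovered through quarter-seed
pigeonholing so that every placement within the mismatch budget is
enumerated (which is what makes brute-force oracle equivalence
attainable).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core_io import CircCandidate, GenomeBundle, ReadPair, Sample, revcomp

ANCHOR_LEN = 20
MAX_MM = 2
MAX_CIRC_LEN = 100_000
SEED_LEN = 20
ANCHOR_SEED_LEN = 5  # quarter seeds: <=2 mismatches leave >=2 exact quarters


def _to_arr(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


@dataclass
class Placement:
    space: str  # 'genome' | 'tx'
    name: str  # contig or transcript id
    start: int
    orient: str  # 'fwd' | 'rc' relative to the stored sequence
    mm: int


@dataclass
class JunctionEvidence:
    read_id: str
    mate: int
    contig: str
    start: int
    end: int
    strand: str
    mm: int
    breakpoint_offset: int
    n_best_loci: int  # max over the two anchors


class GenomeIndex:
    """Seed tables over the genome (+ strand) and spliced transcripts."""

    def __init__(self, bundle: GenomeBundle):
        self.bundle = bundle
        if not bundle.sequences or all(len(s) == 0
                                       for s in bundle.sequences.values()):
            raise ValueError("empty genome")
        self.contig_arr = {n: _to_arr(s) for n, s in bundle.sequences.items()}
        # transcript sense sequences with genomic projection metadata
        self.tx_seq: dict[str, np.ndarray] = {}
        self.tx_meta: dict[str, tuple] = {}  # tid -> (gene, tx)
        for g in bundle.genes:
            for tx in g.transcripts:
                s = bundle.transcript_sequence(g, tx)
                self.tx_seq[tx.transcript_id] = _to_arr(s)
                self.tx_meta[tx.transcript_id] = (g, tx)
        self.seed_index: dict[bytes, list[tuple[str, str, int]]] = defaultdict(list)
        for name, arr in self.contig_arr.items():
            b = arr.tobytes()
            for i in range(len(b) - SEED_LEN + 1):
                self.seed_index[b[i : i + SEED_LEN]].append(("genome", name, i))
        for name, arr in self.tx_seq.items():
            b = arr.tobytes()
            for i in range(len(b) - SEED_LEN + 1):
                self.seed_index[b[i : i + SEED_LEN]].append(("tx", name, i))
        self.anchor_index: dict[bytes, list[tuple[str, int]]] = defaultdict(list)
        for name, arr in self.contig_arr.items():
            b = arr.tobytes()
            for i in range(len(b) - ANCHOR_SEED_LEN + 1):
                self.anchor_index[b[i : i + ANCHOR_SEED_LEN]].append((name, i))

    # ---------------- end-to-end alignment ----------------

    def _space_arr(self, space: str, name: str) -> np.ndarray:
        return self.contig_arr[name] if space == "genome" else self.tx_seq[name]

    def map_end_to_end(self, seq: str, max_mm: int = MAX_MM) -> list[Placement]:
        """All best placements of the full read, both orientations."""
        best: list[Placement] = []
        best_mm = max_mm + 1
        n = len(seq)
        if n < SEED_LEN:
            return []
        for orient, s in (("fwd", seq), ("rc", revcomp(seq))):
            arr = _to_arr(s)
            b = arr.tobytes()
            offsets = list(range(0, n - SEED_LEN + 1, SEED_LEN))
            if offsets[-1] != n - SEED_LEN:
                offsets.append(n - SEED_LEN)
            seen = set()
            for off in offsets:
                for space, name, pos in self.seed_index.get(
                        b[off : off + SEED_LEN], ()):
                    start = pos - off
                    if start < 0:
                        continue
                    key = (space, name, start, orient)
                    if key in seen:
                        continue
                    seen.add(key)
                    ref = self._space_arr(space, name)
                    if start + n > len(ref):
                        continue
                    mm = int(np.count_nonzero(ref[start : start + n] != arr))
                    if mm < best_mm:
                        best_mm = mm
                        best = [Placement(space, name, start, orient, mm)]
                    elif mm == best_mm and mm <= max_mm:
                        best.append(Placement(space, name, start, orient, mm))
        return best if best_mm <= max_mm else []

    # ---------------- anchor mapping ----------------

    def map_anchor(self, anchor: str, max_mm: int = MAX_MM
                   ) -> list[tuple[str, int, int]]:
        """Best-scoring loci of a 20-nt anchor on the + genome.

        Returns (contig, position, mismatches) for every locus achieving
        the minimum mismatch count (if that minimum is <= max_mm).
        Candidate loci come from exact quarter-seed hits, which is
        exhaustive for <= 2 mismatches in a 20-mer.
        """
        arr = _to_arr(anchor)
        n = len(anchor)
        q = ANCHOR_SEED_LEN
        cand: set[tuple[str, int]] = set()
        for off in range(0, n - q + 1, q):
            for name, pos in self.anchor_index.get(
                    anchor[off : off + q].encode(), ()):
                start = pos - off
                if start >= 0:
                    cand.add((name, start))
        hits = []
        best = max_mm + 1
        for name, start in cand:
            ref = self.contig_arr[name]
            if start + n > len(ref):
                continue
            mm = int(np.count_nonzero(ref[start : start + n] != arr))
            if mm < best:
                best = mm
                hits = [(name, start, mm)]
            elif mm == best and mm <= max_mm:
                hits.append((name, start, mm))
        return hits if best <= max_mm else []


@dataclass
class AlignResult:
    """Per-sample linear alignment outcome."""

    placements: dict[tuple[str, int], list[Placement]] = field(
        default_factory=dict)
    unmapped: list[tuple[str, int, str]] = field(default_factory=list)
    total_mapped_reads: int = 0


def align_linear(pairs: list[ReadPair], index: GenomeIndex,
                 max_mm: int = MAX_MM) -> AlignResult:
    """End-to-end alignment of every mate; unmapped mates are forwarded."""
    res = AlignResult()
    for p in pairs:
        for mate, seq in ((1, p.mate1_seq), (2, p.mate2_seq)):
            placements = index.map_end_to_end(seq, max_mm)
            if placements:
                res.placements[(p.read_id, mate)] = placements
                res.total_mapped_reads += 1
            else:
                res.unmapped.append((p.read_id, mate, seq))
    return res


def extract_anchors(seq: str, anchor_len: int = ANCHOR_LEN
                    ) -> Optional[tuple[str, str]]:
    """First and last ``anchor_len`` bases; None when the read is too short."""
    if len(seq) < 2 * anchor_len:
        return None
    return seq[:anchor_len], seq[-anchor_len:]


def _flank_strand(garr: np.ndarray, s: int, e: int) -> Optional[str]:
    """Strand implied by the genomic flank dinucleotides, or None."""
    if s < 2 or e + 2 > len(garr):
        return None
    left = garr[s - 2 : s].tobytes()
    right = garr[e : e + 2].tobytes()
    if left == b"AG" and right == b"GT":
        return "+"
    if left == b"AC" and right == b"CT":
        return "-"
    return None


def resolve_breakpoint(seq: str, contig: str, left_locus: int,
                       right_locus: int, index: GenomeIndex,
                       anchor_len: int = ANCHOR_LEN, max_mm: int = MAX_MM,
                       max_circ_len: int = MAX_CIRC_LEN):
    """Enumerate breakpoint offsets for one head-to-tail anchor pair.

    ``left_locus`` places seq[:anchor_len], ``right_locus`` places
    seq[-anchor_len:], with right_locus < left_locus.  For breakpoint
    offset b, the head seq[:b] sits at [left_locus, left_locus+b) (the
    circle's end side) and the tail seq[b:] at [s, right_locus+anchor_len)
    (the circle's start side).  Returns (candidates, reject_reasons):
    candidates are (start, end, strand, mm, b) with canonical flanks and
    mm <= max_mm.
    """
    garr = index.contig_arr[contig]
    n = len(seq)
    arr = _to_arr(seq)
    reasons: set[str] = set()
    out = []
    glen = len(garr)
    tail_origin = right_locus + anchor_len - n
    # pad references where the extension window leaves the contig; the
    # valid breakpoint range below never reads the padded bytes
    head_ref = np.zeros(n, dtype=np.uint8)
    h_take = min(n, glen - left_locus)
    if h_take <= 0:
        return out, reasons
    head_ref[:h_take] = garr[left_locus : left_locus + h_take]
    tail_ref = np.zeros(n, dtype=np.uint8)
    t_skip = max(0, -tail_origin)
    tail_ref[t_skip:] = garr[tail_origin + t_skip : right_locus + anchor_len]
    head_mm = np.cumsum(np.concatenate(([0], (arr != head_ref).astype(int))))
    tail_diff = (arr != tail_ref).astype(int)
    tail_mm = np.concatenate((np.cumsum(tail_diff[::-1])[::-1], [0]))
    # keep 2-nt flank lookups and both blocks inside the contig
    b_lo = max(anchor_len, 2 - tail_origin)
    b_hi = min(n - anchor_len, glen - 2 - left_locus)
    for b in range(b_lo, b_hi + 1):
        s = tail_origin + b
        e = left_locus + b
        if e <= s:
            continue
        if e - s > max_circ_len:
            reasons.add("span_exceeded")
            continue
        mm = int(head_mm[b] + tail_mm[b])
        if mm > max_mm:
            reasons.add("too_many_mm")
            continue
        strand = _flank_strand(garr, s, e)
        if strand is None:
            reasons.add("no_gtag")
            continue
        out.append((s, e, strand, mm, b))
    return out, reasons


def _expected_orient(strand: str, mate: int) -> str:
    # dUTP convention as simulated: mate1 carries transcript sense
    return "fwd" if (strand == "+") == (mate == 1) else "rc"


def junction_candidates(seq: str, mate: int, index: GenomeIndex,
                        anchor_len: int = ANCHOR_LEN, max_mm: int = MAX_MM,
                        max_circ_len: int = MAX_CIRC_LEN):
    """Resolve one unmapped mate into a junction call or a reject category.

    Tries both read orientations against the + genome; collects breakpoint
    candidates over all head-to-tail anchor locus pairs; requires a unique
    best-scoring candidate, canonical flanks and strand agreement with the
    stranded library layout.
    """
    all_cands = []  # (s, e, strand, mm, b, orient, n_best_loci)
    reasons: Counter = Counter()
    had_pair = False
    for orient in ("fwd", "rc"):
        s_or = seq if orient == "fwd" else revcomp(seq)
        anchors = extract_anchors(s_or, anchor_len)
        if anchors is None:
            return None, "short_read"
        left_hits = index.map_anchor(anchors[0], max_mm)
        right_hits = index.map_anchor(anchors[1], max_mm)
        n_loci = max(len(left_hits), len(right_hits), 1)
        for lc, lp, _ in left_hits:
            for rc_, rp, _ in right_hits:
                if lc != rc_ or rp >= lp:
                    continue
                had_pair = True
                cands, why = resolve_breakpoint(
                    s_or, lc, lp, rp, index, anchor_len, max_mm, max_circ_len)
                reasons.update(why)
                for (s, e, strand, mm, b) in cands:
                    all_cands.append((lc, s, e, strand, mm, b, orient, n_loci))
    if not all_cands:
        if not had_pair:
            return None, "no_anchor_pair"
        for cat in ("no_gtag", "too_many_mm", "span_exceeded"):
            if cat in reasons:
                return None, cat
        return None, "no_anchor_pair"
    best_mm = min(c[4] for c in all_cands)
    best = {(c[0], c[1], c[2], c[3], c[5]): c for c in all_cands
            if c[4] == best_mm}
    if len(best) > 1:
        return None, "ambiguous"
    (contig, s, e, strand, mm, b, orient, n_loci) = next(iter(best.values()))
    if _expected_orient(strand, mate) != orient:
        return None, "strand_conflict"
    return JunctionEvidence("", mate, contig, s, e, strand, mm, b,
                            n_loci), "accepted"


# ---------------------------------------------------------------------------
# mate consistency


def _genomic_footprint(p: Placement, index: GenomeIndex, read_len: int):
    """Genomic (contig, start, end, genome_orient) of a placement."""
    if p.space == "genome":
        return (p.name, p.start, p.start + read_len, p.orient)
    gene, tx = index.tx_meta[p.name]
    tlen = sum(e - s for s, e in tx.exons)
    if gene.strand == "+":
        t0, t1 = p.start, p.start + read_len
        gor = p.orient
    else:
        t0, t1 = tlen - (p.start + read_len), tlen - p.start
        gor = "rc" if p.orient == "fwd" else "fwd"
    # project [t0, t1) in genomic-sorted exon space
    pos = 0
    gs = ge = None
    for s, e in tx.exons:
        ln = e - s
        if gs is None and t0 < pos + ln:
            gs = s + max(0, t0 - pos)
        if t1 <= pos + ln:
            ge = s + (t1 - pos)
            break
        pos += ln
    if ge is None:
        ge = tx.exons[-1][1]
    if gs is None:
        gs = tx.exons[0][0]
    return (gene.contig, gs, ge, gor)


def check_mate_consistency(ev: JunctionEvidence, mate_placements,
                           mate_evidence, index: GenomeIndex,
                           read_len: int) -> bool:
    """True iff the junction read's mate supports a circular template.

    The mate must map inside [start, end) on the circle's strand with the
    orientation a stranded circular fragment implies, or itself span the
    same back-splice.
    """
    other = 2 if ev.mate == 1 else 1
    if mate_evidence is not None and (
            mate_evidence.contig, mate_evidence.start, mate_evidence.end,
            mate_evidence.strand) == (ev.contig, ev.start, ev.end, ev.strand):
        return True
    if not mate_placements:
        return False
    want = _expected_orient(ev.strand, other)
    for p in mate_placements:
        contig, gs, ge, gor = _genomic_footprint(p, index, read_len)
        if contig == ev.contig and gs >= ev.start and ge <= ev.end \
                and gor == want:
            return True
    return False


# ---------------------------------------------------------------------------
# per-sample pipeline and merging


@dataclass
class DetectionResult:
    calls: list[CircCandidate]
    samples: list[Sample]
    rejections: dict[str, Counter]
    alignments: dict[str, AlignResult] = field(default_factory=dict)
    read_len: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.calls:
            for sid, jr in sorted(c.junction_reads.items()):
                rows.append({
                    "contig": c.contig, "start": c.start, "end": c.end,
                    "strand": c.strand, "circ_id": c.circ_id,
                    "sample_id": sid, "junction_reads": jr,
                })
        return pd.DataFrame(rows, columns=[
            "contig", "start", "end", "strand", "circ_id", "sample_id",
            "junction_reads"])


def detect_sample(pairs: list[ReadPair], sample: Sample, index: GenomeIndex,
                  anchor_len: int = ANCHOR_LEN, max_mm: int = MAX_MM,
                  max_circ_len: int = MAX_CIRC_LEN):
    """Align, resolve junctions and apply the mate-consistency check.

    Returns (evidence by junction key, AlignResult, rejection counter).
    A pair contributes at most one junction read even when both mates span
    the back-splice.
    """
    res = align_linear(pairs, index, max_mm)
    sample.total_mapped_reads = res.total_mapped_reads
    rej: Counter = Counter()
    read_len = len(pairs[0].mate1_seq) if pairs else 0
    evidence: dict[tuple[str, int], JunctionEvidence] = {}
    for read_id, mate, seq in res.unmapped:
        ev, status = junction_candidates(seq, mate, index, anchor_len, max_mm,
                                         max_circ_len)
        if ev is None:
            rej[status] += 1
            continue
        ev.read_id = read_id
        key = (read_id, mate)
        evidence[key] = ev
    # mate-consistency, then collapse pairs to fragments
    support: dict[tuple, dict[str, JunctionEvidence]] = defaultdict(dict)
    for (read_id, mate), ev in evidence.items():
        other = 2 if mate == 1 else 1
        ok = check_mate_consistency(
            ev, res.placements.get((read_id, other)),
            evidence.get((read_id, other)), index, read_len)
        if not ok:
            rej["mate_inconsistent"] += 1
            continue
        key = (ev.contig, ev.start, ev.end, ev.strand)
        support[key].setdefault(read_id, ev)  # fragment counted once
    return support, res, rej


def filter_repetitive(support: dict, index: GenomeIndex,
                      anchor_len: int = ANCHOR_LEN,
                      rej: Optional[Counter] = None) -> dict:
    """Drop junctions with multi-locus anchors or duplicated junction context."""
    out = {}
    for key, frags in support.items():
        contig, s, e, strand = key
        if any(ev.n_best_loci > 1 for ev in frags.values()):
            if rej is not None:
                rej["repetitive"] += len(frags)
            continue
        garr = index.contig_arr[contig]
        junction = (garr[e - anchor_len : e].tobytes()
                    + garr[s : s + anchor_len].tobytes()).decode()
        genome = index.bundle.sequences[contig]
        if genome.count(junction) + revcomp(genome).count(junction) > 0:
            if rej is not None:
                rej["repetitive"] += len(frags)
            continue
        out[key] = frags
    return out


def call_circrnas(per_sample_support: dict[str, dict],
                  index: GenomeIndex) -> list[CircCandidate]:
    """Merge junction evidence across samples into circRNA candidates."""
    merged: dict[tuple, CircCandidate] = {}
    for sid, support in per_sample_support.items():
        for (contig, s, e, strand), frags in support.items():
            if (contig, s, e, strand) not in merged:
                garr = index.contig_arr[contig]
                donor = garr[e : e + 2].tobytes().decode()
                acceptor = garr[s - 2 : s].tobytes().decode()
                merged[(contig, s, e, strand)] = CircCandidate(
                    contig, s, e, strand, {}, donor, acceptor)
            merged[(contig, s, e, strand)].junction_reads[sid] = len(frags)
    return sorted(merged.values(), key=lambda c: (c.contig, c.start, c.end))


def detect_experiment(reads_per_sample: dict[str, list[ReadPair]],
                      bundle: GenomeBundle, samples: list[Sample],
                      anchor_len: int = ANCHOR_LEN, max_mm: int = MAX_MM,
                      max_circ_len: int = MAX_CIRC_LEN,
                      index: Optional[GenomeIndex] = None) -> DetectionResult:
    """Run detection over every sample and merge calls."""
    if index is None:
        index = GenomeIndex(bundle)
    by_id = {s.sample_id: s for s in samples}
    per_sample_support = {}
    rejections = {}
    alignments = {}
    read_len = 0
    for sid, pairs in reads_per_sample.items():
        if pairs:
            read_len = len(pairs[0].mate1_seq)
        support, res, rej = detect_sample(
            pairs, by_id[sid], index, anchor_len, max_mm, max_circ_len)
        support = filter_repetitive(support, index, anchor_len, rej)
        per_sample_support[sid] = support
        rejections[sid] = rej
        alignments[sid] = res
    calls = call_circrnas(per_sample_support, index)
    return DetectionResult(calls, samples, rejections, alignments, read_len)
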