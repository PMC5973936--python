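"""miRNA response-element prediction on circRNA sequences.

Seed matching follows the canonical site classes: a 6mer pairs the
target with miRNA positions 2-7, 7mer-m8 extends pairing to position 8,
7mer-A1 adds an adenosine opposite position 1, and an 8mer has both.
The scan runs on the circularised sequence (the first 7 bases appended)
so sites straddling the back-splice junction are found once, reported
modulo the circle length.

Duplex quality is scored with a simplified local alignment of the
reverse-complemented miRNA against the site region (match +5, G:U
wobble +1, mismatch -3, gap open -8, gap extend -2; the seed region is
gap-free).  A candidate miRNA passes overall when it has a >= 7mer seed
site, a pairing score over threshold, and appears in the supplied CLIP
support table — the three-way intersection is the sponge verdict.

Sequences are normalised to the RNA alphabet (T -> U) at the module
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import CircCandidate, GenomeBundle, revcomp
from .quantify import matched_transcript

SEED_SPAN = 8  # miRNA positions 1-8 define every site class
PAIRING_THRESHOLD = 80.0
MATCH, WOBBLE, MISMATCH = 5.0, 1.0, -3.0
GAP_OPEN, GAP_EXTEND = -8.0, -2.0
SITE_CONTEXT = 30  # upstream bases handed to the pairing scorer

_RNA_COMP = str.maketrans("ACGU", "UGCA")


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def rna_revcomp(seq: str) -> str:
    return seq.translate(_RNA_COMP)[::-1]


@dataclass
class MirnaSite:
    circ_id: str
    mirna_id: str
    site_start: int  # 0-based on the circular sequence, start of the match
    seed_class: str  # 6mer | 7mer-A1 | 7mer-m8 | 8mer
    pairing_score: float = float("nan")
    spans_junction: bool = False


@dataclass
class SpongeVerdict:
    mirna_id: str
    passes_seed: bool
    passes_pairing: bool
    passes_clip: bool

    @property
    def final(self) -> bool:
        return self.passes_seed and self.passes_pairing and self.passes_clip


def circ_sequence(circ: CircCandidate, bundle: GenomeBundle
                  ) -> tuple[str, bool]:
    """Spliced circular sequence (transcript sense); flagged for non-exonic.

    Non-exonic circles fall back to the genomic span, strand-oriented.
    """
    match = matched_transcript(circ, bundle)
    if match is not None:
        g, tx, i, j = match
        seq = "".join(bundle.sequences[circ.contig][s:e]
                      for s, e in tx.exons[i : j + 1])
        return (seq if g.strand == "+" else revcomp(seq)), False
    seq = bundle.sequences[circ.contig][circ.start : circ.end]
    return (seq if circ.strand == "+" else revcomp(seq)), True


_CLASS_RANK = {"6mer": 0, "7mer-A1": 1, "7mer-m8": 2, "8mer": 3}
_CLASS_SPAN = {"6mer": 6, "7mer-A1": 7, "7mer-m8": 7, "8mer": 8}


def _classify_placement(ext: str, pos: int, seed7_rc: str, seed6_rc: str):
    """Maximal class for the miRNA placement with position 1 opposite
    ``pos``; returns (class, site start) or None.

    A placement that pairs positions 2-8 subsumes its own 2-7 sub-match,
    so each placement yields at most one site; the seed complement reads
    3'->5' of the miRNA and ends immediately before ``pos``.
    """
    cands = []
    if ext[pos - 7 : pos] == seed7_rc:
        cands.append(("8mer" if ext[pos] == "A" else "7mer-m8", pos - 7))
    if ext[pos - 6 : pos] == seed6_rc:
        cands.append(("7mer-A1" if ext[pos] == "A" else "6mer", pos - 6))
    if not cands:
        return None
    return max(cands, key=lambda c: _CLASS_RANK[c[0]])


def seed_match_sites(circ_seq: str, mirna_seq: str, circ_id: str = "",
                     mirna_id: str = "") -> list[MirnaSite]:
    """All seed-match sites on a circular sequence, junction-aware.

    The scan extends the sequence by SEED_SPAN-1 bases so sites crossing
    the back-splice are seen once; positions are reported modulo the
    circle length and deduplicated by start position.
    """
    circ_seq = to_rna(circ_seq)
    mirna_seq = to_rna(mirna_seq)
    if len(mirna_seq) < SEED_SPAN:
        raise ValueError("miRNA shorter than 8 nt")
    L = len(circ_seq)
    ext = circ_seq + circ_seq[:SEED_SPAN]  # covers junction sites incl. A1
    seed7_rc = rna_revcomp(mirna_seq[1:8])
    seed6_rc = rna_revcomp(mirna_seq[1:7])
    # one placement per circle position; overlapping sites at the same
    # start keep their maximal class
    best: dict[int, MirnaSite] = {}
    for pos in range(7, L + 7):
        hit = _classify_placement(ext, pos, seed7_rc, seed6_rc)
        if hit is None:
            continue
        cls, start = hit
        start %= L
        site = MirnaSite(circ_id, mirna_id, start, cls,
                         spans_junction=start + _CLASS_SPAN[cls] > L)
        prev = best.get(site.site_start)
        if prev is None or _CLASS_RANK[cls] > _CLASS_RANK[prev.seed_class]:
            best[site.site_start] = site
    return sorted(best.values(), key=lambda s: s.site_start)


def pairing_score(site_region: str, mirna_seq: str) -> float:
    """Local duplex alignment score of the miRNA against a target region.

    The reverse complement of the miRNA is aligned to the region with
    affine gaps; alignment through the seed rows (miRNA positions 2-8)
    must be gap-free.  Implemented as a banded-free Gotoh recursion with
    gap states disabled on seed rows.
    """
    q = rna_revcomp(to_rna(mirna_seq))  # query rows, 3'->5' of the miRNA
    t = to_rna(site_region)
    n, m = len(q), len(t)
    # miRNA position of each query row: q[i] corresponds to miRNA base
    # n - i (1-based), so rows with miRNA position 2..8 are seed rows
    seed_row = [2 <= (n - i) <= 8 for i in range(n)]

    def pair(a: str, b: str) -> float:
        # q is already reverse-complemented, so Watson-Crick pairing of the
        # underlying miRNA base with the target is plain equality here
        if a == b:
            return MATCH
        # wobble in rc space: query C vs target U (miRNA G:U),
        # query A vs target G (miRNA U:G)
        if (a, b) in (("C", "U"), ("A", "G")):
            return WOBBLE
        return MISMATCH

    NEG = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in query (target consumed)
    F = np.full((n + 1, m + 1), NEG)  # gap in target (query consumed)
    best = 0.0
    for i in range(1, n + 1):
        allow_gap = not seed_row[i - 1]
        for j in range(1, m + 1):
            if allow_gap:
                E[i, j] = max(H[i, j - 1] + GAP_OPEN + GAP_EXTEND,
                              E[i, j - 1] + GAP_EXTEND)
                F[i, j] = max(H[i - 1, j] + GAP_OPEN + GAP_EXTEND,
                              F[i - 1, j] + GAP_EXTEND)
            diag = H[i - 1, j - 1] + pair(q[i - 1], t[j - 1])
            H[i, j] = max(0.0, diag, E[i, j], F[i, j])
            if H[i, j] > best:
                best = H[i, j]
    return float(best)


def site_region(circ_seq: str, site: MirnaSite,
                context: int = SITE_CONTEXT) -> str:
    """Site plus upstream context on the circular sequence."""
    circ_seq = to_rna(circ_seq)
    L = len(circ_seq)
    ext = circ_seq * 3
    end = site.site_start + SEED_SPAN + L  # middle copy
    start = max(0, end - (SEED_SPAN + context))
    return ext[start:end]


def predict_sites(circ_seq: str, mirnas: dict[str, str], circ_id: str = ""
                  ) -> list[MirnaSite]:
    """Seed sites with pairing scores for every miRNA."""
    out = []
    for mid, mseq in mirnas.items():
        for site in seed_match_sites(circ_seq, mseq, circ_id, mid):
            site.pairing_score = pairing_score(
                site_region(circ_seq, site), mseq)
            out.append(site)
    return out


def intersect_predictions(sites: list[MirnaSite], clip_mirnas: set[str],
                          score_threshold: float = PAIRING_THRESHOLD
                          ) -> list[SpongeVerdict]:
    """Three-way verdict per miRNA: seed class, pairing score, CLIP support."""
    by_mirna: dict[str, list[MirnaSite]] = {}
    for s in sites:
        by_mirna.setdefault(s.mirna_id, []).append(s)
    out = []
    for mid in sorted(by_mirna):
        ss = by_mirna[mid]
        seed_ok = any(s.seed_class in ("7mer-A1", "7mer-m8", "8mer")
                      for s in ss)
        pair_ok = any(s.pairing_score >= score_threshold for s in ss)
        out.append(SpongeVerdict(mid, seed_ok, pair_ok, mid in clip_mirnas))
    return out


def sponge_table(circ_id: str, sites: list[MirnaSite],
                 verdicts: list[SpongeVerdict]) -> pd.DataFrame:
    rank = {"6mer": 0, "7mer-A1": 1, "7mer-m8": 2, "8mer": 3}
    rows = []
    by_mirna: dict[str, list[MirnaSite]] = {}
    for s in sites:
        by_mirna.setdefault(s.mirna_id, []).append(s)
    for v in verdicts:
        ss = by_mirna.get(v.mirna_id, [])
        rows.append({
            "circ_id": circ_id, "mirna_id": v.mirna_id, "n_sites": len(ss),
            "best_class": max((s.seed_class for s in ss),
                              key=lambda c: rank[c], default=""),
            "best_score": max((s.pairing_score for s in ss),
                              default=float("nan")),
            "passes_seed": v.passes_seed, "passes_pairing": v.passes_pairing,
            "passes_clip": v.passes_clip, "final": v.final,
        })
    return pd.DataFrame(rows)
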