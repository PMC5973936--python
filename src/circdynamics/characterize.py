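"""Descriptive analytics of the high-confidence circRNA set.

Covers genomic origin (CDS / 5'UTR / 3'UTR / lncRNA / antisense /
unannotated), exon counts, circles-per-gene, the circ:linear ratio vs
host expression correlation (the splicing by-product test), the
relationship between circRNA and host linear regulation, read trimming
for cross-dataset comparisons, and Venn-style cell-type specificity.

Category precedence is sense-exonic > lncRNA > antisense > unannotated,
with CDS dominating UTR within the exonic class.  The linear direction
used for host-relation classes comes from the untreated library only:
after RNase R digestion linear fold changes are meaningless.
"""

from __future__ import annotations

from collections import Counter
from itertools import combinations
from typing import Iterable, Optional

import pandas as pd
from scipy import stats

from .core_io import CircCandidate, GenomeBundle, ReadPair
from .quantify import matched_transcript
from .screen import FC_DOWN, FC_UP

CATEGORIES = ("CDS", "5UTR", "3UTR", "lncRNA", "antisense", "unannotated")


def classify_genomic_origin(circ: CircCandidate,
                            bundle: GenomeBundle) -> str:
    """Single genomic category per circle.

    Exonic (both breakpoints on exon borders of a sense transcript):
    CDS when any constituent exon overlaps the coding span, otherwise
    5'UTR/3'UTR by position relative to it.  Then: inside a sense lncRNA's
    exons -> lncRNA; overlapping any opposite-strand gene -> antisense;
    else unannotated.
    """
    match = matched_transcript(circ, bundle)
    if match is not None:
        g, tx, i, j = match
        run = tx.exons[i : j + 1]
        if g.biotype == "lncRNA":
            return "lncRNA"
        if g.biotype == "protein_coding" and tx.cds_span is not None:
            cs, ce = tx.cds_span
            if any(s < ce and e > cs for s, e in run):
                return "CDS"
            if g.strand == "+":
                return "5UTR" if circ.end <= cs else "3UTR"
            return "5UTR" if circ.start >= ce else "3UTR"
        return "unannotated"
    for g in bundle.genes:
        if g.contig != circ.contig or g.strand != circ.strand:
            continue
        if g.biotype != "lncRNA":
            continue
        for tx in g.transcripts:
            covered = sum(
                max(0, min(e, circ.end) - max(s, circ.start))
                for s, e in tx.exons)
            if covered == circ.end - circ.start:
                return "lncRNA"
    for g in bundle.genes:
        if g.contig == circ.contig and g.strand != circ.strand \
                and g.start < circ.end and g.end > circ.start:
            return "antisense"
    return "unannotated"


def exon_count(circ: CircCandidate, bundle: GenomeBundle) -> Optional[int]:
    """Annotated exons of the matched transcript inside [start, end).

    None for circles that do not align to exon borders (non-exonic).
    """
    match = matched_transcript(circ, bundle)
    if match is None:
        return None
    _g, _tx, i, j = match
    return j - i + 1


def circ_per_gene(circs: Iterable[CircCandidate], bundle: GenomeBundle
                  ) -> pd.DataFrame:
    """Distinct confidence-set circles per host gene, plus fraction single."""
    per_gene: Counter = Counter()
    for c in circs:
        match = matched_transcript(c, bundle)
        if match is None:
            continue
        per_gene[match[0].gene_id] += 1
    df = pd.DataFrame(sorted(per_gene.items()),
                      columns=["gene_id", "n_circ"])
    return df


def fraction_single(per_gene: pd.DataFrame) -> float:
    if len(per_gene) == 0:
        return float("nan")
    return float((per_gene.n_circ == 1).mean())


def host_representative(circ_ids: list[str],
                        expression: pd.DataFrame) -> str:
    """The gene's representative circle: highest summed untreated expression.

    Ties break to the lexicographically smallest id, deterministically.
    """
    sub = expression[
        (expression.feature_kind == "circ")
        & expression.feature_id.isin(circ_ids)
        & expression.sample_id.str.startswith("rminus_")]
    totals = sub.groupby("feature_id")["normalized"].sum()
    totals = totals.reindex(circ_ids).fillna(0.0)
    best = totals.max()
    return sorted(cid for cid in circ_ids if totals[cid] == best)[0]


def linear_direction(fc24: float, fc48: float) -> str:
    """Direction of the host linear RNA from the two untreated fold changes."""
    if fc24 > FC_UP and fc48 > FC_UP:
        return "up"
    if fc24 < FC_DOWN and fc48 < FC_DOWN:
        return "down"
    return "unchanged"


def classify_host_relation(circ_direction: str, lin_direction: str) -> str:
    """Partition of (circ, linear) direction pairs.

    changed circ + unchanged linear -> independent; same changed direction
    -> concordant; opposite -> reciprocal; unchanged circ -> both_unchanged.
    """
    if circ_direction == "unchanged":
        return "both_unchanged"
    if lin_direction == "unchanged":
        return "independent"
    return "concordant" if circ_direction == lin_direction else "reciprocal"


def ratio_expression_correlation(ratios, host_expr) -> tuple[float, float]:
    """Spearman correlation of circ:linear ratio with host expression.

    One representative circle per gene; refuses fewer than 10 genes.
    """
    ratios = list(ratios)
    host_expr = list(host_expr)
    if len(ratios) < 10:
        raise ValueError(
            f"need >= 10 host genes for a rank correlation, got {len(ratios)}")
    rho, p = stats.spearmanr(ratios, host_expr)
    return float(rho), float(p)


def trim_reads(pairs: Iterable[ReadPair], target_len: int
               ) -> list[ReadPair]:
    """3' truncation of both mates (and qualities) to ``target_len``."""
    out = []
    for p in pairs:
        if target_len > len(p.mate1_seq) or target_len > len(p.mate2_seq):
            raise ValueError("target_len exceeds read length")
        out.append(ReadPair(
            p.read_id, p.mate1_seq[:target_len], p.mate2_seq[:target_len],
            p.mate1_qual[:target_len], p.mate2_qual[:target_len],
            p.library, p.timepoint))
    return out


def cell_specific_sets(named_sets: dict[str, set]) -> pd.DataFrame:
    """All Venn region cardinalities plus per-set specific fractions.

    Returns a frame with one row per non-empty combination of set names
    (region = elements in exactly those sets) and a companion column of
    per-set specificity accessible via :func:`specific_fractions`.
    """
    if len(named_sets) < 2:
        raise ValueError("need at least two named sets")
    names = sorted(named_sets)
    rows = []
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(named_sets[n] for n in combo))
            outside = set.union(
                *(named_sets[n] for n in names if n not in combo)) \
                if len(combo) < len(names) else set()
            rows.append({
                "region": "&".join(combo),
                "n_sets": r,
                "count": len(inside - outside),
            })
    return pd.DataFrame(rows)


def specific_fractions(named_sets: dict[str, set]) -> dict[str, float]:
    out = {}
    for name, s in named_sets.items():
        others = set.union(*(v for k, v in named_sets.items() if k != name)) \
            if len(named_sets) > 1 else set()
        out[name] = len(s - others) / len(s) if s else float("nan")
    return out
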