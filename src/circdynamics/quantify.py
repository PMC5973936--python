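"""Expression computation for circular and linear transcripts.

Circular abundance is the back-splice junction read count normalised to
reads per 10^8 mapped reads.  Linear abundance at a circRNA locus is
estimated from the two boundary events immediately flanking the circle:
reads spanning the linear splice from the neighbouring exon into the
circle's terminal exon, plus reads crossing that exon's outer
exon-intron boundary, averaged over the two flanks.  Host-gene
expression is a plain FPKM over the gene's exon model, with fragments
overlapping several genes assigned fractionally.

Fragments (read pairs), not individual mates, are the counting unit for
linear quantities; junction support follows the same fragment rule in
the detection stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .core_io import CircCandidate, GeneModel, GenomeBundle, Transcript
from .detect import AlignResult, DetectionResult, GenomeIndex, _genomic_footprint

SCALE = 1e8


def normalize_circ(junction_reads: float, total_mapped: int) -> float:
    """Junction reads per 10^8 mapped reads."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    return junction_reads / total_mapped * SCALE


def circ_linear_ratio(circ_norm: float, linear_norm: float,
                      eps: float = 0.0) -> float:
    """circ / (linear + eps); eps is one raw read on the normalised scale."""
    if linear_norm + eps <= 0:
        return float("nan")
    return circ_norm / (linear_norm + eps)


def matched_transcript(circ: CircCandidate, bundle: GenomeBundle
                       ) -> Optional[tuple[GeneModel, Transcript, int, int]]:
    """Sense transcript whose exon borders coincide with both breakpoints.

    Returns (gene, transcript, first_exon_idx, last_exon_idx) in genomic
    exon order, or None for a non-exonic circle.
    """
    for g in bundle.genes:
        if g.contig != circ.contig or g.strand != circ.strand:
            continue
        for tx in g.transcripts:
            i = j = None
            for k, (s, e) in enumerate(tx.exons):
                if s == circ.start:
                    i = k
                if e == circ.end:
                    j = k
            if i is not None and j is not None and i <= j:
                return g, tx, i, j
    return None


def footprint_table(align: AlignResult, index: GenomeIndex,
                    read_len: int) -> pd.DataFrame:
    """Genomic footprints of every best placement of every mapped mate."""
    rows = []
    for (read_id, mate), placements in align.placements.items():
        for p in placements:
            contig, gs, ge, gor = _genomic_footprint(p, index, read_len)
            rows.append({
                "read_id": read_id, "mate": mate, "space": p.space,
                "name": p.name, "contig": contig, "g_start": gs, "g_end": ge,
                "orient": gor,
            })
    return pd.DataFrame(rows, columns=[
        "read_id", "mate", "space", "name", "contig", "g_start", "g_end", "orient"])


@dataclass
class FlankEstimate:
    raw: float  # mean of the two per-flank fragment totals
    one_sided: bool = False
    nonexonic: bool = False


def quantify_linear_flanking(circ: CircCandidate, ftable: pd.DataFrame,
                             bundle: GenomeBundle,
                             min_overhang: int = 10) -> FlankEstimate:
    """Linear RNA evidence at the two boundaries flanking the circle.

    Upstream flank (genomic left of ``start``): fragments whose spliced
    alignment crosses from the neighbouring exon into the circle's first
    exon, plus fragments whose genomic alignment crosses the first exon's
    upstream exon-intron boundary.  Downstream flank mirrored at ``end``.
    Terminal-exon circles use the available side only; circles whose
    boundaries match no annotated exon are counted from exon-intron
    boundary reads alone and flagged.
    """
    match = matched_transcript(circ, bundle)
    sub = ftable[ftable.contig == circ.contig]

    def crossing(df, pos):
        m = (df.g_start <= pos - min_overhang) & (df.g_end >= pos + min_overhang)
        return set(df.read_id[m])

    if match is None:
        frags = crossing(sub[sub.space == "genome"], circ.start) \
            | crossing(sub[sub.space == "genome"], circ.end)
        return FlankEstimate(float(len(frags)), nonexonic=True)

    g, tx, i, j = match
    tx_sub = sub[(sub.space == "tx") & (sub.name == tx.transcript_id)]
    gen_sub = sub[sub.space == "genome"]
    totals = []
    # upstream flank at the circle's first exon
    if i > 0:
        u_end = tx.exons[i - 1][1]
        spliced = set(tx_sub.read_id[
            (tx_sub.g_start <= u_end - min_overhang)
            & (tx_sub.g_end >= circ.start + min_overhang)])
        intron = crossing(gen_sub, circ.start)
        totals.append(len(spliced | intron))
    # downstream flank at the circle's last exon
    if j < len(tx.exons) - 1:
        d_start = tx.exons[j + 1][0]
        spliced = set(tx_sub.read_id[
            (tx_sub.g_start <= circ.end - min_overhang)
            & (tx_sub.g_end >= d_start + min_overhang)])
        intron = crossing(gen_sub, circ.end)
        totals.append(len(spliced | intron))
    if not totals:
        return FlankEstimate(0.0, one_sided=True)
    return FlankEstimate(sum(totals) / len(totals),
                         one_sided=(len(totals) == 1))


# ---------------------------------------------------------------------------
# FPKM


def _gene_exon_union(gene: GeneModel) -> list[tuple[int, int]]:
    ivs = sorted(iv for tx in gene.transcripts for iv in tx.exons)
    out: list[list[int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def fragment_gene_assignment(ftable: pd.DataFrame, bundle: GenomeBundle,
                             index: GenomeIndex) -> pd.DataFrame:
    """Fractional exonic fragment counts per gene (1/n over overlapped genes)."""
    tx_gene = {tx.transcript_id: g.gene_id
               for g in bundle.genes for tx in g.transcripts}
    unions = {g.gene_id: (_gene_exon_union(g), g.contig) for g in bundle.genes}
    frag_genes: dict[str, set[str]] = {}
    for row in ftable.itertuples():
        genes = frag_genes.setdefault(row.read_id, set())
        if row.space == "tx":
            genes.add(tx_gene[row.name])
        else:
            for gid, (ivs, contig) in unions.items():
                if contig != row.contig:
                    continue
                if any(row.g_start < e and row.g_end > s for s, e in ivs):
                    genes.add(gid)
    counts = {g.gene_id: 0.0 for g in bundle.genes}
    assigned = 0
    for genes in frag_genes.values():
        if not genes:
            continue
        assigned += 1
        w = 1.0 / len(genes)
        for gid in genes:
            counts[gid] += w
    return pd.DataFrame({
        "gene_id": list(counts), "fragments": list(counts.values()),
    }), assigned


def compute_fpkm(exonic_fragments: float, exonic_length: int,
                 total_fragments: int) -> float:
    """Fragments per kilobase of exon model per million mapped fragments."""
    if exonic_length <= 0:
        raise ValueError("zero-length gene model")
    if total_fragments <= 0:
        raise ValueError("no mapped fragments")
    return exonic_fragments / (exonic_length / 1e3) / (total_fragments / 1e6)


# ---------------------------------------------------------------------------
# experiment-level assembly


def quantify_experiment(det: DetectionResult, bundle: GenomeBundle,
                        index: GenomeIndex,
                        min_overhang: int = 10) -> pd.DataFrame:
    """Long-format expression table over all samples.

    feature_kind: ``circ`` (normalised junction reads), ``linear_flank``
    (normalised flanking-boundary fragments per circRNA) and ``gene_fpkm``.
    """
    rows = []
    by_id = {s.sample_id: s for s in det.samples}
    for sid, align in det.alignments.items():
        total_reads = by_id[sid].total_mapped_reads
        ftable = footprint_table(align, index, det.read_len)
        n_pairs = ftable.read_id.nunique()
        for c in det.calls:
            raw = c.junction_reads.get(sid, 0)
            rows.append({
                "feature_id": c.circ_id, "feature_kind": "circ",
                "sample_id": sid, "raw": raw,
                "normalized": normalize_circ(raw, total_reads),
                "flag": "",
            })
            fl = quantify_linear_flanking(c, ftable, bundle, min_overhang)
            flag = ("nonexonic" if fl.nonexonic
                    else "one_sided" if fl.one_sided else "")
            rows.append({
                "feature_id": c.circ_id, "feature_kind": "linear_flank",
                "sample_id": sid, "raw": fl.raw,
                "normalized": normalize_circ(fl.raw, total_reads),
                "flag": flag,
            })
        gene_counts, assigned = fragment_gene_assignment(ftable, bundle, index)
        for row in gene_counts.itertuples():
            gene = bundle.gene(row.gene_id)
            exonic_len = sum(e - s for s, e in _gene_exon_union(gene))
            rows.append({
                "feature_id": row.gene_id, "feature_kind": "gene_fpkm",
                "sample_id": sid, "raw": row.fragments,
                "normalized": compute_fpkm(row.fragments, exonic_len,
                                           max(assigned, 1)),
                "flag": "",
            })
    return pd.DataFrame(rows, columns=[
        "feature_id", "feature_kind", "sample_id", "raw", "normalized",
        "flag"])
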