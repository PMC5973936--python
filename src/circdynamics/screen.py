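"""High-confidence set construction and the fold-change consensus screen.

A circRNA enters the high-confidence set when it is detected (at least
``min_reads`` junction reads, default 2) in the untreated and the
RNase R-treated library at the same timepoint, for at least one of the
three timepoints.  The differential screen computes four fold changes
against the same-library t0 baseline (t24 and t48 in each library),
calls a direction when at least three of the four exceed 1.5 (up) or
fall below 0.67 (down) with the remaining value on the same side of
1.0, and then demotes calls lacking junction-read support: upregulation
needs >= 3 junction reads at t24 or t48 in both libraries,
downregulation needs >= 3 at t0 in both.

This is a deterministic rule-based screen, not a statistical test — no
dispersion model and no multiple-testing correction, by design.
Thresholds are strict inequalities; values equal to a threshold do not
pass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .core_io import read_circ_bed
from .quantify import SCALE

FC_UP = 1.5
FC_DOWN = 0.67
MIN_DETECT_READS = 2
MIN_SUPPORT_READS = 3

LIBRARIES = ("rminus", "rnaser")
TIMEPOINTS = ("t0", "t24", "t48")
FC_COLS = ("fc_rminus_t24", "fc_rminus_t48", "fc_rnaser_t24", "fc_rnaser_t48")


@dataclass
class ConfidenceSet:
    members: list[str]  # circ ids
    annotation_status: dict[str, str] = field(default_factory=dict)

    def __contains__(self, circ_id: str) -> bool:
        return circ_id in set(self.members)


@dataclass
class RegulationCall:
    circ_id: str
    fold_changes: tuple[float, float, float, float]
    direction: str  # up | down | unchanged
    support_pass: bool
    raw_direction: str = "unchanged"  # before the support filter


def _counts_grid(calls: pd.DataFrame) -> pd.DataFrame:
    """(circ_id x sample_id) junction-read matrix; absent cells are 0."""
    grid = calls.pivot_table(index="circ_id", columns="sample_id",
                             values="junction_reads", aggfunc="sum",
                             fill_value=0)
    missing = [f"{lib}_{tp}" for lib in LIBRARIES for tp in TIMEPOINTS
               if f"{lib}_{tp}" not in grid.columns]
    if missing:
        raise ValueError(f"sample grid incomplete; absent cells: {missing}")
    return grid


def build_confidence_set(calls: pd.DataFrame,
                         min_reads: int = MIN_DETECT_READS) -> ConfidenceSet:
    """Same-timepoint co-detection in both library types.

    ``calls``: long table with circ_id, sample_id, junction_reads for the
    full 2x3 grid.
    """
    grid = _counts_grid(calls)
    members = []
    for circ_id, row in grid.iterrows():
        for tp in TIMEPOINTS:
            if row[f"rminus_{tp}"] >= min_reads \
                    and row[f"rnaser_{tp}"] >= min_reads:
                members.append(circ_id)
                break
    return ConfidenceSet(sorted(members))


def annotate_known(conf: ConfidenceSet, calls_meta: pd.DataFrame,
                   known_bed_path) -> ConfidenceSet:
    """Exact-coordinate match against a known-circRNA catalog (BED6)."""
    known = {(c.contig, c.start, c.end, c.strand)
             for c in read_circ_bed(known_bed_path)}
    meta = calls_meta.drop_duplicates("circ_id").set_index("circ_id")
    for cid in conf.members:
        r = meta.loc[cid]
        key = (r["contig"], int(r["start"]), int(r["end"]), r["strand"])
        conf.annotation_status[cid] = (
            "annotated" if key in known else "novel")
    return conf


def fold_change_grid(expression: pd.DataFrame, circ_id: str,
                     samples: pd.DataFrame) -> tuple[float, float, float, float]:
    """Four fold changes on normalised values, baseline = same-library t0.

    A pseudocount equal to one raw read on the baseline sample's
    normalised scale is added symmetrically to numerator and denominator:
    fold changes stay finite at zero baselines and are exactly invariant
    to depth rescaling of any non-baseline sample.
    """
    sub = expression[(expression.feature_id == circ_id)
                     & (expression.feature_kind == "circ")]
    norm = sub.set_index("sample_id")["normalized"]
    total = samples.set_index("sample_id")["total_mapped_reads"]
    out = []
    for lib in LIBRARIES:
        base_sid = f"{lib}_t0"
        eps = SCALE / total[base_sid]
        for tp in ("t24", "t48"):
            sid = f"{lib}_{tp}"
            out.append((norm.get(sid, 0.0) + eps)
                       / (norm.get(base_sid, 0.0) + eps))
    return tuple(out)


def classify_direction(fc4) -> str:
    """At least three of four beyond the threshold, fourth on the same side."""
    fc4 = list(fc4)
    if any(math.isnan(x) for x in fc4):
        raise ValueError("NaN fold change")
    n_up = sum(x > FC_UP for x in fc4)
    n_down = sum(x < FC_DOWN for x in fc4)
    if n_up == 4 or (n_up == 3 and all(x > 1.0 for x in fc4)):
        return "up"
    if n_down == 4 or (n_down == 3 and all(x < 1.0 for x in fc4)):
        return "down"
    return "unchanged"


def support_filter(counts_row: pd.Series, direction: str,
                   min_reads: int = MIN_SUPPORT_READS) -> bool:
    """Junction-read support for a direction call, in both libraries.

    Up: >= min_reads at t24 or t48 within each library.
    Down: >= min_reads at t0 within each library.
    """
    if direction == "up":
        return all(
            max(counts_row[f"{lib}_t24"], counts_row[f"{lib}_t48"])
            >= min_reads for lib in LIBRARIES)
    if direction == "down":
        return all(counts_row[f"{lib}_t0"] >= min_reads for lib in LIBRARIES)
    raise ValueError(f"direction must be up or down, got {direction!r}")


def screen_differential(conf: ConfidenceSet, expression: pd.DataFrame,
                        calls: pd.DataFrame,
                        samples: pd.DataFrame) -> pd.DataFrame:
    """Full screen over the high-confidence set with audit columns."""
    grid = _counts_grid(calls)
    rows = []
    for cid in conf.members:
        fc4 = fold_change_grid(expression, cid, samples)
        raw_dir = classify_direction(fc4)
        if raw_dir == "unchanged":
            direction, passed = "unchanged", False
        else:
            passed = support_filter(grid.loc[cid], raw_dir)
            direction = raw_dir if passed else "unchanged"
        rows.append({
            "circ_id": cid,
            "annotation_status": conf.annotation_status.get(cid, ""),
            **dict(zip(FC_COLS, (round(x, 6) for x in fc4))),
            "raw_direction": raw_dir,
            "support_pass": passed,
            "direction": direction,
        })
    return pd.DataFrame(rows, columns=[
        "circ_id", "annotation_status", *FC_COLS, "raw_direction",
        "support_pass", "direction"])
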