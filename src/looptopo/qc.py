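"""Interaction-call QC: drop short-range and low-count loops, merge
duplicates that join the same pair of annotated genomic elements.

Thresholds are deliberately mandatory in pipeline configs and echoed in
every log — published analyses state these filters but rarely their
cutoffs, so results must never be silently threshold-dependent.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

from .core import Interval, Loop

DEFAULT_MIN_DISTANCE = 10_000
DEFAULT_MIN_COUNT = 4


def filter_short_range(loops: Sequence[Loop], min_distance: int = DEFAULT_MIN_DISTANCE,
                       log: dict | None = None) -> list[Loop]:
    """Keep loops whose anchor-midpoint distance is >= min_distance."""
    if min_distance < 0:
        raise ValueError("min_distance must be >= 0")
    kept = [l for l in loops if l.anchor_distance() >= min_distance]
    if log is not None:
        log["filter_short_range"] = {"in": len(loops), "out": len(kept),
                                     "removed": len(loops) - len(kept),
                                     "min_distance": min_distance}
    return kept


def filter_low_count(loops: Sequence[Loop], min_count: int = DEFAULT_MIN_COUNT,
                     condition_rule: str = "max", conditions: Sequence[str] | None = None,
                     log: dict | None = None) -> list[Loop]:
    """Keep loops whose counts satisfy ``condition_rule`` vs min_count.

    rule "max": max across conditions >= min_count (default);
    rule "any": at least one condition >= min_count (same as max);
    rule "all": every condition >= min_count.
    """
    if condition_rule not in ("any", "all", "max"):
        raise ValueError(f"unknown condition_rule {condition_rule!r}")
    kept = []
    for l in loops:
        conds = conditions if conditions is not None else list(l.counts)
        for c in conds:
            if c not in l.counts:
                raise KeyError(f"loop {l.id!r} missing condition {c!r}")
        vals = [l.counts[c] for c in conds]
        ok = (min(vals) >= min_count) if condition_rule == "all" else (max(vals) >= min_count)
        if ok:
            kept.append(l)
    if log is not None:
        log["filter_low_count"] = {"in": len(loops), "out": len(kept),
                                   "removed": len(loops) - len(kept),
                                   "min_count": min_count, "rule": condition_rule}
    return kept


def _assign_element(anchor: Interval, elements: Sequence[tuple[str, Interval]],
                    max_gap: int = 2500) -> str | None:
    # midpoint containment first, then nearest element midpoint within max_gap
    mid = anchor.midpoint
    containing = [eid for eid, iv in elements
                  if iv.chrom == anchor.chrom and iv.start <= mid < iv.end]
    if containing:
        return sorted(containing)[0]
    best, best_d = None, max_gap + 1
    for eid, iv in elements:
        if iv.chrom != anchor.chrom:
            continue
        d = abs(iv.midpoint - mid)
        if d < best_d or (d == best_d and (best is None or eid < best)):
            best, best_d = eid, d
    return best if best_d <= max_gap else None


def merge_identical_element_loops(loops: Sequence[Loop],
                                  elements: Sequence[tuple[str, Interval]],
                                  max_gap: int = 2500,
                                  log: dict | None = None) -> list[Loop]:
    """Merge loops whose ordered anchor-element assignment is identical.

    ``elements`` are (element_id, Interval) pairs.  Anchors are assigned by
    midpoint containment, falling back to the nearest element within
    ``max_gap`` bp; a loop with any unassigned anchor is exempt from
    merging (conservative: never merge on weak evidence).  Merged records
    take the element spans as anchors and sum counts per condition; the
    constituent ids are preserved in the merged id.
    """
    element_span = {eid: iv for eid, iv in elements}
    groups: dict[tuple[str, str], list[Loop]] = {}
    passthrough: list[Loop] = []
    for l in loops:
        ea = _assign_element(l.anchorL, elements, max_gap)
        eb = _assign_element(l.anchorR, elements, max_gap)
        if ea is None or eb is None:
            passthrough.append(l)
            continue
        groups.setdefault((ea, eb), []).append(l)

    merged: list[Loop] = []
    for (ea, eb), members in groups.items():
        if len(members) == 1:
            merged.append(members[0])
            continue
        counts: dict[str, int] = {}
        for m in members:
            for cond, c in m.counts.items():
                counts[cond] = counts.get(cond, 0) + c
        first = min(members, key=lambda m: m.id)
        merged_id = first.id + "|merged:" + ",".join(
            sorted(m.id for m in members if m is not first))
        sa, sb = element_span[ea], element_span[eb]
        if (sa.start, sa.end) > (sb.start, sb.end):
            sa, sb = sb, sa
        merged.append(Loop(id=merged_id, anchorL=sa, anchorR=sb, counts=counts,
                           strength=max(m.strength for m in members)))
    out = passthrough + merged
    out.sort(key=lambda l: (l.chrom, l.anchorL.start, l.anchorR.start, l.id))
    if log is not None:
        log["merge_identical_element_loops"] = {
            "in": len(loops), "out": len(out), "removed": len(loops) - len(out)}
    return out


def run_qc(loops: Sequence[Loop], elements: Sequence[tuple[str, Interval]] | None = None,
           min_distance: int = DEFAULT_MIN_DISTANCE, min_count: int = DEFAULT_MIN_COUNT,
           condition_rule: str = "max", conditions: Sequence[str] | None = None,
           log: dict | None = None) -> list[Loop]:
    """Full QC chain: distance filter, count filter, duplicate merge."""
    log = log if log is not None else {}
    out = filter_short_range(loops, min_distance, log=log)
    out = filter_low_count(out, min_count, condition_rule, conditions, log=log)
    if elements is not None:
        out = merge_identical_element_loops(out, elements, log=log)
    log["total"] = {"in": len(loops), "out": len(out),
                    "removed": len(loops) - len(out)}
    return out
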