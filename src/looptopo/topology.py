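"""Spatial classification of regulatory interactions against structural loops.

Each regulatory (H3K27ac) interaction ``h`` is related to every structural
(CTCF) loop ``c`` through one of five geometric relations, evaluated on the
structural loop's span ``S`` (anchor-midpoint span by default):

* ``contain``  — ``h`` subtends ``S``: left anchor midpoint <= S.start and
  right anchor midpoint >= S.end, where sharing an anchor with ``c`` counts
  as containment at that edge.  Subtype = number of same-side shared
  anchors: 0 -> I, 1 -> II, 2 -> III (III is identical to the structural
  loop, bound at both anchors).
* ``cross``    — exactly one anchor midpoint strictly inside ``S`` and the
  other strictly outside, and not contain.
* ``inside``   — both anchor midpoints strictly inside ``S``, no shared
  anchor.
* ``neighbor`` — exactly one anchor shared with ``c`` (either side) and the
  other anchor midpoint strictly outside ``S`` (``h`` extends away from the
  loop body).
* ``outside``  — none of the above; represented as "no relation".

A whole-interaction label aggregates the relations over all structural
loops: one relation type -> that category; contain + cross ->
``contain_and_cross``; no relations -> ``outside``; any other mixture ->
``other_composite`` (retained verbatim, never forced into a simpler bin).

Every geometric knob (slack, span mode, strictness) is an explicit
parameter recorded in reports, because published class schematics rarely
pin these choices down.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .core import Interval, Loop, LoopIndex, intervals_overlap, loop_span

CATEGORIES = (
    "contain",
    "cross",
    "contain_and_cross",
    "neighbor",
    "inside",
    "outside",
    "other_composite",
)

_SUBTYPES = {0: "I", 1: "II", 2: "III"}


@dataclass(frozen=True)
class PairRelation:
    """Relation of one regulatory interaction to one structural loop."""

    relation: str                    # contain | cross | neighbor | inside
    contain_subtype: str | None      # "I" / "II" / "III" iff relation == contain
    ctcf_loop_id: str
    ctcf_strength: float
    shared_left: bool = False        # h.anchorL shares c.anchorL (same side)
    shared_right: bool = False       # h.anchorR shares c.anchorR (same side)


@dataclass
class TopologyLabel:
    """Aggregate label of one interaction against the whole loop set."""

    loop_id: str
    relations: list[PairRelation] = field(default_factory=list)
    category: str = "outside"
    max_contain_strength: float | None = None
    max_cross_strength: float | None = None

    @property
    def contain_subtype(self) -> str | None:
        """Subtype when the label is pure contain with a unique subtype."""
        subs = {r.contain_subtype for r in self.relations if r.relation == "contain"}
        if self.category == "contain" and len(subs) == 1:
            return subs.pop()
        return None


def relate_pair(h: Loop, c: Loop, slack: int = 0,
                span_mode: str = "midpoint") -> PairRelation | None:
    """Relation of regulatory loop ``h`` to structural loop ``c``, or None.

    Returns None when ``h`` bears no qualifying relation to ``c``
    (the "outside" case), including all trans pairs.
    """
    if h.chrom != c.chrom:
        return None
    S = loop_span(c, span_mode)
    lmid, rmid = h.anchorL.midpoint, h.anchorR.midpoint

    # same-side anchor sharing (drives contain subtypes)
    sharedL = intervals_overlap(h.anchorL, c.anchorL, slack)
    sharedR = intervals_overlap(h.anchorR, c.anchorR, slack)
    # any-side sharing per h anchor (drives the neighbor relation)
    hl_shared = sharedL or intervals_overlap(h.anchorL, c.anchorR, slack)
    hr_shared = sharedR or intervals_overlap(h.anchorR, c.anchorL, slack)

    def rel(name: str, subtype: str | None = None) -> PairRelation:
        return PairRelation(name, subtype, c.id, c.strength, sharedL, sharedR)

    # contain: h subtends S; sharing counts as containment at that edge
    if (lmid <= S.start or sharedL) and (rmid >= S.end or sharedR):
        return rel("contain", _SUBTYPES[int(sharedL) + int(sharedR)])

    l_in = S.start < lmid < S.end
    r_in = S.start < rmid < S.end
    l_out = lmid < S.start or lmid > S.end
    r_out = rmid < S.start or rmid > S.end

    if (l_in and r_out) or (r_in and l_out):
        return rel("cross")
    if l_in and r_in and not (hl_shared or hr_shared):
        return rel("inside")
    if int(hl_shared) + int(hr_shared) == 1:
        if (hl_shared and r_out) or (hr_shared and l_out):
            return rel("neighbor")
    return None


def _aggregate(loop_id: str, relations: list[PairRelation]) -> TopologyLabel:
    label = TopologyLabel(loop_id=loop_id, relations=relations)
    kinds = {r.relation for r in relations}
    if not kinds:
        label.category = "outside"
    elif len(kinds) == 1:
        label.category = next(iter(kinds))
    elif kinds == {"contain", "cross"}:
        label.category = "contain_and_cross"
    else:
        label.category = "other_composite"
    contains = [r.ctcf_strength for r in relations if r.relation == "contain"]
    crosses = [r.ctcf_strength for r in relations if r.relation == "cross"]
    label.max_contain_strength = max(contains) if contains else None
    label.max_cross_strength = max(crosses) if crosses else None
    return label


def classify_topology(h: Loop, ctcf_loops: Sequence[Loop] | LoopIndex,
                      slack: int = 0, span_mode: str = "midpoint") -> TopologyLabel:
    """Classify one interaction against a structural loop collection.

    ``ctcf_loops`` may be a pre-built :class:`LoopIndex` (reused across
    many interactions) or a plain sequence.  Candidate retrieval pads the
    query window by the interaction's own span length plus slack, which is
    sufficient for every relation (verified against the exhaustive oracle
    in the test-suite).
    """
    index = ctcf_loops if isinstance(ctcf_loops, LoopIndex) else LoopIndex(ctcf_loops)
    start = h.anchorL.start
    end = h.anchorR.end
    pad = (end - start) + slack + 1
    relations = []
    for c in index.query(h.chrom, start, end, pad=pad):
        r = relate_pair(h, c, slack=slack, span_mode=span_mode)
        if r is not None:
            relations.append(r)
    return _aggregate(h.id, relations)


def classify_all(h_loops: Sequence[Loop], ctcf_loops: Sequence[Loop],
                 slack: int = 0, span_mode: str = "midpoint") -> list[TopologyLabel]:
    index = LoopIndex(ctcf_loops)
    return [classify_topology(h, index, slack=slack, span_mode=span_mode)
            for h in h_loops]


def category_distribution(labels: Iterable[TopologyLabel]) -> pd.DataFrame:
    """Counts and percentages per category (the Fig.-2B-style table)."""
    labels = list(labels)
    rows = []
    n = len(labels)
    counts = {cat: 0 for cat in CATEGORIES}
    for lab in labels:
        counts[lab.category] += 1
    for cat in CATEGORIES:
        pct = 100.0 * counts[cat] / n if n else float("nan")
        rows.append({"category": cat, "count": counts[cat], "percent": pct})
    return pd.DataFrame(rows)


def labels_to_frame(labels: Iterable[TopologyLabel]) -> pd.DataFrame:
    """Flatten labels for TSV output / joins with differential results."""
    rows = []
    for lab in labels:
        rows.append({
            "loop_id": lab.loop_id,
            "category": lab.category,
            "contain_subtype": lab.contain_subtype or "n/a",
            "n_relations": len(lab.relations),
            "max_contain_strength": lab.max_contain_strength,
            "max_cross_strength": lab.max_cross_strength,
        })
    return pd.DataFrame(
        rows,
        columns=["loop_id", "category", "contain_subtype", "n_relations",
                 "max_contain_strength", "max_cross_strength"],
    )


def solo_anchor_report(labels: Sequence[TopologyLabel], h_loops: Sequence[Loop],
                       annotate=None) -> pd.DataFrame:
    """Non-structural ("solo") anchors of pure contain-II interactions.

    For each contain-category interaction with a unique subtype II
    relation, emits the anchor NOT shared with the structural loop.
    ``annotate`` is an optional callable Interval -> str used to attach a
    functional annotation (e.g. promoter/enhancer) to each solo anchor.
    Subtype-III interactions contribute nothing by definition (both
    anchors shared).
    """
    by_id = {l.id: l for l in h_loops}
    rows = []
    for lab in labels:
        if lab.category != "contain" or lab.contain_subtype != "II":
            continue
        rel = next(r for r in lab.relations if r.relation == "contain")
        h = by_id[lab.loop_id]
        solo = h.anchorR if rel.shared_left else h.anchorL
        rows.append({
            "loop_id": lab.loop_id,
            "solo_side": "R" if rel.shared_left else "L",
            "chrom": solo.chrom,
            "start": solo.start,
            "end": solo.end,
            "annotation": annotate(solo) if annotate is not None else "n/a",
        })
    return pd.DataFrame(
        rows, columns=["loop_id", "solo_side", "chrom", "start", "end", "annotation"]
    )
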