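"""Anchor and interaction typing against CTCF/enhancer/promoter catalogs,
plus descriptive genomics (looping fraction, nearest-neighbor spacing).

Anchor vocabulary: C (CTCF), E (enhancer), P (promoter) and composites
(CE, CP, EP, CEP), rendered with C first.  Interaction classes collapse
the functional part of each anchor to the familiar PP / EE / EP labels,
keeping structural CTCF co-binding in a separate field.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import GenomeSpec, Interval, Loop, intervals_overlap


@dataclass(frozen=True)
class AnchorLabel:
    ctcf: bool
    enhancer: bool
    promoter: bool

    @property
    def composite(self) -> str:
        s = ("C" if self.ctcf else "") + ("E" if self.enhancer else "") + (
            "P" if self.promoter else "")
        return s or "none"

    @property
    def functional(self) -> str:
        """Single-letter functional code: P beats E beats C beats none."""
        if self.promoter:
            return "P"
        if self.enhancer:
            return "E"
        if self.ctcf:
            return "C"
        return "N"


def _any_overlap(anchor: Interval, catalog: Sequence[Interval], slack: int) -> bool:
    return any(intervals_overlap(anchor, iv, slack) for iv in catalog)


def label_anchor(anchor: Interval, ctcf_peaks: Sequence[Interval],
                 enhancers: Sequence[Interval], promoters: Sequence[Interval],
                 slack: int = 0) -> AnchorLabel:
    """Label one anchor by overlap with each annotation catalog."""
    return AnchorLabel(
        ctcf=_any_overlap(anchor, ctcf_peaks, slack),
        enhancer=_any_overlap(anchor, enhancers, slack),
        promoter=_any_overlap(anchor, promoters, slack),
    )


@dataclass(frozen=True)
class InteractionClass:
    """Symmetric functional class of an interaction plus structural note."""

    label: str        # e.g. "PP", "EP", "EE", "EN", ...
    structural: str   # which sides carry CTCF: "", "C-left", "C-right", "C-both"


def classify_interaction(l: Loop, labelL: AnchorLabel, labelR: AnchorLabel) -> InteractionClass:
    """Unordered functional pair label; invariant to swapping anchors."""
    pair = "".join(sorted((labelL.functional, labelR.functional)))
    if labelL.ctcf and labelR.ctcf:
        structural = "C-both"
    elif labelL.ctcf:
        structural = "C-left"
    elif labelR.ctcf:
        structural = "C-right"
    else:
        structural = ""
    return InteractionClass(label=pair, structural=structural)


def promoter_windows(gene_models: pd.DataFrame, upstream: int = 1000,
                     downstream: int = 1000, genome: GenomeSpec | None = None,
                     ) -> pd.DataFrame:
    """Strand-aware windows around each TSS (default -1000..+1000 bp).

    Returns a frame with gene_id, chrom, start, end, strand.  Windows are
    clipped to chromosome bounds when a genome is supplied; a gene whose
    strand is missing/invalid raises.
    """
    rows = []
    for rec in gene_models.itertuples(index=False):
        strand = getattr(rec, "strand")
        if strand not in ("+", "-"):
            raise ValueError(f"gene {rec.gene_id!r} has no usable strand: {strand!r}")
        tss = int(rec.tss)
        if strand == "+":
            start, end = tss - upstream, tss + downstream
        else:
            start, end = tss - downstream, tss + upstream
        start = max(0, start)
        if genome is not None:
            end = min(end, genome.chrom_sizes[rec.chrom])
        rows.append({"gene_id": rec.gene_id, "chrom": rec.chrom,
                     "start": start, "end": end, "strand": strand})
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def windows_to_intervals(windows: pd.DataFrame) -> list[Interval]:
    return [Interval(r.chrom, int(r.start), int(r.end),
                     getattr(r, "strand", "."))
            for r in windows.itertuples(index=False)]


def looping_fraction(sites: Sequence[Interval], interactions: Sequence[Loop],
                     slack: int = 0) -> tuple[int, int, float]:
    """(n_looping, n_total, fraction): a site "loops" iff it overlaps any
    interaction anchor."""
    anchors = [a for l in interactions for a in (l.anchorL, l.anchorR)]
    by_chrom: dict[str, list[Interval]] = {}
    for a in anchors:
        by_chrom.setdefault(a.chrom, []).append(a)
    n_loop = 0
    for s in sites:
        if _any_overlap(s, by_chrom.get(s.chrom, ()), slack):
            n_loop += 1
    total = len(sites)
    return n_loop, total, (n_loop / total if total else float("nan"))


def nearest_neighbor_distance(sites: Sequence[Interval]) -> pd.DataFrame:
    """Midpoint distance to the closest other site on the same chromosome.

    Sites alone on their chromosome get a missing (NaN) distance.
    """
    rows = []
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for i, s in enumerate(sites):
        by_chrom.setdefault(s.chrom, []).append((i, s.midpoint))
    dist = np.full(len(sites), np.nan)
    for chrom, items in by_chrom.items():
        if len(items) < 2:
            continue
        items.sort(key=lambda t: t[1])
        mids = np.array([m for _, m in items], dtype=np.int64)
        gaps = np.diff(mids)
        for k, (i, _) in enumerate(items):
            cand = []
            if k > 0:
                cand.append(gaps[k - 1])
            if k < len(items) - 1:
                cand.append(gaps[k])
            dist[i] = min(cand)
    for i, s in enumerate(sites):
        rows.append({"chrom": s.chrom, "start": s.start, "end": s.end,
                     "nn_distance": dist[i]})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "nn_distance"])


def annotate_interactions(loops: Sequence[Loop], ctcf_peaks: Sequence[Interval],
                          enhancers: Sequence[Interval], promoters: Sequence[Interval],
                          slack: int = 0) -> pd.DataFrame:
    """Per-interaction anchor and class annotation table."""
    rows = []
    for l in loops:
        la = label_anchor(l.anchorL, ctcf_peaks, enhancers, promoters, slack)
        lb = label_anchor(l.anchorR, ctcf_peaks, enhancers, promoters, slack)
        cls = classify_interaction(l, la, lb)
        rows.append({"loop_id": l.id, "anchorL_label": la.composite,
                     "anchorR_label": lb.composite, "class": cls.label,
                     "structural": cls.structural})
    return pd.DataFrame(rows, columns=["loop_id", "anchorL_label", "anchorR_label",
                                       "class", "structural"])
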