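"""Accessibility integration: differential window counts, CTCF-overlap
partition of lost sites, fixed-width site-centered windows, promoter
annotation and strand-aware motif-to-TSS distances.

Differential calling reuses the interaction machinery (CPM + exact
binomial + BH) so both assays share one declared code path.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .core import GenomeSpec, Interval, intervals_overlap
from .differential import bh_fdr, call_differential

DEFAULT_WINDOW = 300


def call_differential_accessibility(window_counts: pd.DataFrame, pre: str, post: str,
                                    alpha: float = 0.05, min_lfc: float = 1.0,
                                    pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-window differential accessibility (shared caller).

    ``window_counts`` needs columns window_id, chrom, start, end plus one
    count column per condition.
    """
    tot_pre = int(window_counts[pre].sum())
    tot_post = int(window_counts[post].sum())
    if tot_pre == 0 and tot_post == 0:
        out = window_counts[["window_id", "chrom", "start", "end"]].copy()
        out["log2fc"] = 0.0
        out["pvalue"] = 1.0
        out["fdr"] = 1.0
        out["call"] = "unchanged"
        return out
    df = pd.DataFrame({
        "loop_id": window_counts["window_id"],
        "count_pre": window_counts[pre].astype(int),
        "count_post": window_counts[post].astype(int),
        "norm_pre": window_counts[pre] * 1e6 / max(tot_pre, 1),
        "norm_post": window_counts[post] * 1e6 / max(tot_post, 1),
    })
    df["log2fc"] = np.log2((df["norm_post"] + pseudocount)
                           / (df["norm_pre"] + pseudocount))
    df.attrs["totals"] = {pre: tot_pre, post: tot_post}
    res = call_differential(df, alpha=alpha, min_lfc=min_lfc)
    res = res.rename(columns={"loop_id": "window_id"})
    return window_counts[["window_id", "chrom", "start", "end"]].merge(
        res[["window_id", "log2fc", "pvalue", "fdr", "call"]], on="window_id")


def _windows_as_intervals(df: pd.DataFrame) -> list[Interval]:
    return [Interval(r.chrom, int(r.start), int(r.end))
            for r in df.itertuples(index=False)]


def partition_by_ctcf_overlap(down_sites: pd.DataFrame, ctcf_peaks: Sequence[Interval],
                              ctcf_motifs: Sequence[Interval], slack: int = 0,
                              ) -> tuple[pd.DataFrame, pd.DataFrame, float, float]:
    """Split lost-accessibility sites on CTCF peak overlap.

    Returns (group1, group2, peak_overlap_fraction, group2_motif_fraction):
    group1 overlaps a CTCF peak; group2 is the remainder, for which the
    fraction containing a CTCF motif is also reported.  group1 and group2
    partition the input.
    """
    peaks_by_chrom: dict[str, list[Interval]] = {}
    for p in ctcf_peaks:
        peaks_by_chrom.setdefault(p.chrom, []).append(p)
    motifs_by_chrom: dict[str, list[Interval]] = {}
    for m in ctcf_motifs:
        motifs_by_chrom.setdefault(m.chrom, []).append(m)

    in_g1 = []
    has_motif = []
    for r in down_sites.itertuples(index=False):
        iv = Interval(r.chrom, int(r.start), int(r.end))
        in_g1.append(any(intervals_overlap(iv, p, slack)
                         for p in peaks_by_chrom.get(iv.chrom, ())))
        has_motif.append(any(intervals_overlap(iv, m, slack)
                             for m in motifs_by_chrom.get(iv.chrom, ())))
    mask = np.asarray(in_g1, dtype=bool)
    group1 = down_sites.loc[mask].reset_index(drop=True)
    group2 = down_sites.loc[~mask].reset_index(drop=True)
    frac = float(mask.mean()) if len(mask) else 0.0
    g2_motif = (float(np.asarray(has_motif)[~mask].mean())
                if (~mask).any() else float("nan"))
    return group1, group2, frac, g2_motif


def ctcf_centered_windows(sites: Sequence[Interval], width: int = DEFAULT_WINDOW,
                          genome: GenomeSpec | None = None) -> list[Interval]:
    """Fixed-width windows centered on each site midpoint (summitless BED:
    the midpoint is the center).  Clipped at chromosome bounds."""
    if width <= 0:
        raise ValueError("width must be > 0")
    if width % 2:
        raise ValueError("width must be even")
    half = width // 2
    out = []
    for s in sites:
        center = s.midpoint
        start = max(0, center - half)
        end = center + half
        if genome is not None:
            end = min(end, genome.chrom_sizes[s.chrom])
        out.append(Interval(s.chrom, start, end, s.strand))
    return out


def promoter_fraction_of_down_sites(down_sites: pd.DataFrame,
                                    promoter_windows: pd.DataFrame,
                                    slack: int = 0) -> tuple[int, set]:
    """(number of lost sites inside promoter windows, distinct genes hit).

    A site spanning several promoters counts once but hits each gene.
    """
    wins = [(r.gene_id, Interval(r.chrom, int(r.start), int(r.end)))
            for r in promoter_windows.itertuples(index=False)]
    n_sites = 0
    genes: set = set()
    for r in down_sites.itertuples(index=False):
        iv = Interval(r.chrom, int(r.start), int(r.end))
        hit = [g for g, w in wins if intervals_overlap(iv, w, slack)]
        if hit:
            n_sites += 1
            genes.update(hit)
    return n_sites, genes


def motif_tss_distance(motifs: Sequence[Interval], gene_models: pd.DataFrame,
                       gene_subset: Sequence[str] | None = None,
                       window: int = 1000, bin_width: int = 10,
                       ) -> tuple[pd.DataFrame, dict]:
    """Signed motif-center-to-TSS distances, flipped so negative = upstream.

    Each gene is assigned its nearest motif center within ``window`` bp of
    the TSS; genes without one are excluded and counted in the summary.
    Summary reports the median and the mode of a ``bin_width``-bp
    histogram (bin centers).
    """
    genes = gene_models
    if gene_subset is not None:
        wanted = set(gene_subset)
        genes = genes[genes["gene_id"].isin(wanted)]
    centers_by_chrom: dict[str, np.ndarray] = {}
    for m in motifs:
        centers_by_chrom.setdefault(m.chrom, [])
    for m in motifs:
        centers_by_chrom[m.chrom].append(m.midpoint)  # type: ignore[attr-defined]
    centers_by_chrom = {c: np.sort(np.asarray(v, dtype=np.int64))
                        for c, v in centers_by_chrom.items()}
    rows = []
    n_excluded = 0
    for r in genes.itertuples(index=False):
        tss = int(r.tss)
        centers = centers_by_chrom.get(r.chrom)
        if centers is None or centers.size == 0:
            n_excluded += 1
            continue
        idx = int(np.argmin(np.abs(centers - tss)))
        center = int(centers[idx])
        if abs(center - tss) > window:
            n_excluded += 1
            continue
        signed = center - tss
        if r.strand == "-":
            signed = -signed
        rows.append({"gene_id": r.gene_id, "motif_center": center,
                     "signed_distance": signed})
    df = pd.DataFrame(rows, columns=["gene_id", "motif_center", "signed_distance"])
    summary: dict = {"n_genes": len(df), "n_excluded": n_excluded,
                     "median": float("nan"), "mode": float("nan"),
                     "bin_width": bin_width}
    if len(df):
        vals = df["signed_distance"].to_numpy()
        summary["median"] = float(np.median(vals))
        lo = (vals.min() // bin_width) * bin_width
        hi = ((vals.max() // bin_width) + 1) * bin_width
        edges = np.arange(lo, hi + bin_width, bin_width)
        hist, _ = np.histogram(vals, bins=edges)
        k = int(np.argmax(hist))
        summary["mode"] = float((edges[k] + edges[k + 1]) / 2)
    return df, summary
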