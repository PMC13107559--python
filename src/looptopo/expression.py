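"""Expression-side set algebra: differential genes, cross-dataset
intersections, promoter CTCF flags, wt/mut rescue typing and the
loop-dependent vs loop-independent mechanism partition.

The differential caller is intentionally self-contained (pooled-count
exact rate-ratio test + BH), declared in its output rather than emulating
any particular external RNA-seq stack.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import Interval, intervals_overlap
from .differential import bh_fdr

RESCUE_CLASSES = ("loop_independent", "loop_dependent", "not_rescued", "n/a")
DEFAULT_RESCUE_TOLERANCE = 0.5


def percent_report(numerator: int, denominator: int, decimals: int = 1) -> tuple[float, str]:
    """Render a printed fraction as a percentage, round-half-up.

    Returns (value, "value% (num/den)").  Exact decimal arithmetic so
    e.g. (106, 128, 1) -> 82.8 and not a float-rounding artifact.
    """
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    if numerator < 0:
        raise ValueError("numerator must be >= 0")
    quantum = Decimal(1).scaleb(-decimals)
    pct = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(
        quantum, rounding=ROUND_HALF_UP)
    return float(pct), f"{pct}% ({numerator}/{denominator})"


def _condition_columns(design: Mapping[str, str], condition: str) -> list[str]:
    cols = [s for s, c in design.items() if c == condition]
    if not cols:
        raise KeyError(f"no samples for condition {condition!r} in design")
    return cols


def call_degs(counts: pd.DataFrame, design: Mapping[str, str], pre: str, post: str,
              alpha: float = 0.05, min_lfc: float = 1.0,
              pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-gene differential call between two conditions.

    ``counts`` is genes x samples (index = gene_id); ``design`` maps sample
    column -> condition name.  Replicate counts are pooled per condition
    and tested with an exact rate-ratio (binomial) test against the
    depth-share null; log2fc is computed on CPM-normalized condition means.
    """
    pre_cols = _condition_columns(design, pre)
    post_cols = _condition_columns(design, post)
    if len(pre_cols) < 2 or len(post_cols) < 2:
        raise ValueError("need >= 2 replicates per condition")
    pre_pool = counts[pre_cols].sum(axis=1).astype(int)
    post_pool = counts[post_cols].sum(axis=1).astype(int)
    tot_pre, tot_post = int(pre_pool.sum()), int(post_pool.sum())
    if tot_pre == 0 or tot_post == 0:
        raise ValueError("degenerate design: zero library total")
    share = tot_post / (tot_pre + tot_post)
    npre = pre_pool * 1e6 / tot_pre
    npost = post_pool * 1e6 / tot_post
    log2fc = np.log2((npost + pseudocount) / (npre + pseudocount))
    pvals = np.ones(len(counts))
    for i, (a, b) in enumerate(zip(pre_pool.to_numpy(), post_pool.to_numpy())):
        n = int(a) + int(b)
        if n > 0:
            pvals[i] = stats.binomtest(int(b), n, share).pvalue
    fdr = bh_fdr(pvals)
    sig = (fdr <= alpha) & (np.abs(log2fc) >= min_lfc)
    status = np.where(~sig, "unchanged", np.where(log2fc > 0, "up", "down"))
    out = pd.DataFrame({
        "gene_id": counts.index, "count_pre": pre_pool.to_numpy(),
        "count_post": post_pool.to_numpy(), "log2fc": log2fc.to_numpy(),
        "pvalue": pvals, "fdr": fdr, "deg_status": status,
    })
    out.attrs["test"] = {"name": "pooled exact rate-ratio (binomial)",
                         "alpha": alpha, "min_lfc": min_lfc}
    return out


def intersect_deg_sets(named_sets: Mapping[str, set], ) -> tuple[set, pd.DataFrame]:
    """Intersection across all named gene sets plus a membership table."""
    if len(named_sets) < 2:
        raise ValueError("need >= 2 sets to intersect")
    names = list(named_sets)
    if len(set(names)) != len(names):
        raise ValueError("set names collide")
    universe = sorted(set().union(*named_sets.values()))
    table = pd.DataFrame(
        {name: [g in named_sets[name] for g in universe] for name in names},
        index=pd.Index(universe, name="gene_id"),
    )
    common = set(universe)
    for name in names:
        common &= set(named_sets[name])
    table["in_all"] = [g in common for g in universe]
    return common, table


def flag_promoter_ctcf(gene_ids: Sequence[str], promoter_windows: pd.DataFrame,
                       ctcf_peaks: Sequence[Interval], slack: int = 0,
                       ) -> tuple[pd.Series, float]:
    """Flag genes with any CTCF peak overlapping their promoter window."""
    by_chrom: dict[str, list[Interval]] = {}
    for p in ctcf_peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    win = promoter_windows.set_index("gene_id")
    flags = {}
    for g in gene_ids:
        if g not in win.index:
            flags[g] = False
            continue
        r = win.loc[g]
        iv = Interval(r["chrom"], int(r["start"]), int(r["end"]))
        flags[g] = any(intervals_overlap(iv, p, slack)
                       for p in by_chrom.get(iv.chrom, ()))
    series = pd.Series(flags, name="promoter_ctcf")
    frac = float(series.mean()) if len(series) else float("nan")
    return series, frac


def mean_by_condition(counts: pd.DataFrame, design: Mapping[str, str],
                      normalize: bool = True) -> pd.DataFrame:
    """Per-gene mean (CPM-normalized by default) for each condition."""
    conds = sorted(set(design.values()))
    data = {}
    for cond in conds:
        cols = _condition_columns(design, cond)
        block = counts[cols].astype(float)
        if normalize:
            block = block * 1e6 / block.sum(axis=0)
        data[cond] = block.mean(axis=1)
    return pd.DataFrame(data)


def exclude_iaa_responsive(counts: pd.DataFrame, design: Mapping[str, str],
                           control: str, iaa_conditions: Sequence[str],
                           alpha: float = 0.05, min_lfc: float = 1.0) -> set:
    """Genes DE in the SAME direction vs control in every IAA-containing
    condition regardless of construct — auxin artifacts, removed before
    rescue classification."""
    status = None
    for cond in iaa_conditions:
        res = call_degs(counts, design, control, cond, alpha=alpha, min_lfc=min_lfc)
        s = res.set_index("gene_id")["deg_status"]
        status = s if status is None else status.where(status == s, other="unchanged")
    return set(status[status != "unchanged"].index)


def classify_rescue(counts: pd.DataFrame, design: Mapping[str, str],
                    deg_down: Sequence[str], control: str = "untreated",
                    wt: str = "oeCTCFwt_IAA", mut: str = "oeCTCFmut_IAA",
                    tolerance: float = DEFAULT_RESCUE_TOLERANCE,
                    pseudocount: float = 1.0) -> pd.Series:
    """Rescue class per depletion-responsive gene.

    rescued_under(c): |log2(mean_c / mean_control)| <= tolerance on
    CPM-normalized means.  loop_independent = rescued under the
    non-looping mutant (regardless of wt); loop_dependent = rescued under
    wt but not mut; not_rescued = neither.  Invariant to uniform depth
    scaling of any condition because means are CPM-normalized.
    """
    for cond in (control, wt, mut):
        _condition_columns(design, cond)  # raises if missing
    means = mean_by_condition(counts, design, normalize=True)
    out = {}
    for g in deg_down:
        base = means.at[g, control] + pseudocount
        rescued_wt = abs(math.log2((means.at[g, wt] + pseudocount) / base)) <= tolerance
        rescued_mut = abs(math.log2((means.at[g, mut] + pseudocount) / base)) <= tolerance
        if rescued_mut:
            out[g] = "loop_independent"
        elif rescued_wt:
            out[g] = "loop_dependent"
        else:
            out[g] = "not_rescued"
    return pd.Series(out, name="rescue_class")


MECHANISM_BUCKETS = ("loop_independent_candidate", "cooperative", "loop_only", "neither")


def genes_with_down_interactions(diff_results: pd.DataFrame,
                                 interaction_classes: pd.DataFrame,
                                 loops, promoter_windows: pd.DataFrame,
                                 slack: int = 0,
                                 classes: Sequence[str] = ("EP", "PP")) -> set:
    """Genes whose promoter window overlaps an anchor of a down-called
    EP/PP interaction (the gene <-> interaction assignment rule)."""
    down_ids = set(diff_results.loc[diff_results["call"] == "down", "loop_id"])
    cls = interaction_classes.set_index("loop_id")["class"]
    wanted = [l for l in loops
              if l.id in down_ids and cls.get(l.id, "") in classes]
    hit = set()
    for r in promoter_windows.itertuples(index=False):
        win = Interval(r.chrom, int(r.start), int(r.end))
        for l in wanted:
            if (intervals_overlap(win, l.anchorL, slack)
                    or intervals_overlap(win, l.anchorR, slack)):
                hit.add(r.gene_id)
                break
    return hit


def partition_deg_by_mechanism(deg_down: Sequence[str],
                               promoter_ctcf: Mapping[str, bool],
                               down_ep_pp_genes: set) -> pd.DataFrame:
    """Three-way-plus partition of depletion-downregulated genes.

    loop_independent_candidate: promoter CTCF, no down EP/PP interaction;
    cooperative: both; loop_only: down EP/PP without promoter CTCF;
    neither: neither signal.  Always a true partition of ``deg_down``.
    """
    rows = []
    for g in deg_down:
        has_ctcf = bool(promoter_ctcf.get(g, False))
        has_loop = g in down_ep_pp_genes
        if has_ctcf and not has_loop:
            bucket = "loop_independent_candidate"
        elif has_ctcf and has_loop:
            bucket = "cooperative"
        elif has_loop:
            bucket = "loop_only"
        else:
            bucket = "neither"
        rows.append({"gene_id": g, "promoter_ctcf": has_ctcf,
                     "down_ep_pp": has_loop, "bucket": bucket})
    return pd.DataFrame(rows, columns=["gene_id", "promoter_ctcf",
                                       "down_ep_pp", "bucket"])
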