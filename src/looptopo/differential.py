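"""Per-interaction differential strength analysis between two conditions.

Normalization is plain CPM; the default significance machinery is an exact
two-sided binomial test of the post-condition count against the no-change
null (depth-share expectation), followed by Benjamini-Hochberg FDR.  The
caller is transparent and pluggable; every report names the test and its
thresholds.  A self-contained two-sided Mann-Whitney U test (exact
enumeration for small groups, tie/continuity-corrected normal
approximation otherwise) backs the group comparisons.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import Loop
from .topology import TopologyLabel

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_LFC = 1.0
DEFAULT_PSEUDOCOUNT = 1.0

# exact MWU enumeration bound: all C(n+m, n) arrangements are enumerated
# when min(n, m) <= 8 and n + m <= EXACT_MAX_TOTAL
EXACT_MAX_TOTAL = 20


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def _library_totals(loops: Sequence[Loop], conditions: Sequence[str]) -> dict[str, int]:
    totals = {c: 0 for c in conditions}
    for l in loops:
        for c in conditions:
            if c not in l.counts:
                raise KeyError(f"loop {l.id!r} missing condition {c!r}")
            totals[c] += l.counts[c]
    return totals


def normalize_and_fold_change(loops: Sequence[Loop], pre: str, post: str,
                              pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """CPM-normalize and compute log2 fold change post vs pre.

    norm_x = count_x * 1e6 / total_x;  log2fc = log2((norm_post + pc) /
    (norm_pre + pc)).  Zero library totals are a hard error.
    """
    totals = _library_totals(loops, (pre, post))
    for c, t in totals.items():
        if t <= 0:
            raise ValueError(f"library total for condition {c!r} is zero")
    rows = []
    for l in loops:
        cpre, cpost = l.counts[pre], l.counts[post]
        npre = cpre * 1e6 / totals[pre]
        npost = cpost * 1e6 / totals[post]
        rows.append({
            "loop_id": l.id,
            "count_pre": cpre, "count_post": cpost,
            "norm_pre": npre, "norm_post": npost,
            "log2fc": math.log2((npost + pseudocount) / (npre + pseudocount)),
        })
    df = pd.DataFrame(rows, columns=["loop_id", "count_pre", "count_post",
                                     "norm_pre", "norm_post", "log2fc"])
    df.attrs["totals"] = totals
    return df


def call_differential(df: pd.DataFrame, alpha: float = DEFAULT_ALPHA,
                      min_lfc: float = DEFAULT_MIN_LFC,
                      test: str = "binomial") -> pd.DataFrame:
    """Attach pvalue / fdr / call columns to a normalize_and_fold_change frame.

    The default test treats each loop's post count as Binomial(total,
    depth_share) under the no-change null, with depth_share =
    total_post / (total_pre + total_post) from the library totals.
    Call = up/down iff fdr <= alpha AND |log2fc| >= min_lfc.
    """
    if test != "binomial":
        raise ValueError(f"unknown test {test!r}")
    totals = df.attrs.get("totals")
    if totals is None:
        totals = {"pre": int(df["count_pre"].sum()), "post": int(df["count_post"].sum())}
        share = totals["post"] / (totals["pre"] + totals["post"])
    else:
        tvals = list(totals.values())
        share = tvals[1] / (tvals[0] + tvals[1])
    pvals = np.ones(len(df))
    for i, (cpre, cpost) in enumerate(zip(df["count_pre"], df["count_post"])):
        n = int(cpre) + int(cpost)
        if n > 0:
            pvals[i] = stats.binomtest(int(cpost), n, share).pvalue
    out = df.copy()
    out["pvalue"] = pvals
    out["fdr"] = bh_fdr(pvals)
    sig = (out["fdr"] <= alpha) & (out["log2fc"].abs() >= min_lfc)
    call = np.where(~sig, "unchanged", np.where(out["log2fc"] > 0, "up", "down"))
    out["call"] = call
    out.attrs["totals"] = totals
    out.attrs["test"] = {"name": "two-sided exact binomial", "alpha": alpha,
                         "min_lfc": min_lfc}
    return out


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group a via midranks (handles ties)."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    ra = ranks[: a.size].sum()
    return ra - a.size * (a.size + 1) / 2.0


def mann_whitney_u(groupA: Sequence[float], groupB: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration of all C(n+m, n) group assignments when
    min(n, m) <= 8 and n + m <= 20; otherwise the normal approximation
    with tie correction and continuity correction.  Two identical,
    zero-variance groups give p = 1.
    """
    a = np.asarray(groupA, dtype=float)
    b = np.asarray(groupB, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n, m = a.size, b.size
    u = _u_statistic(a, b)
    nm = n * m

    if min(n, m) <= 8 and n + m <= EXACT_MAX_TOTAL:
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        offset = n * (n + 1) / 2.0
        # exact permutation distribution of U over all assignments
        us = np.fromiter(
            (sum(c) - offset for c in itertools.combinations(ranks, n)),
            dtype=float,
        )
        observed_dev = abs(u - nm / 2.0)
        # tiny epsilon guards float equality on midrank sums
        p = float(np.mean(np.abs(us - nm / 2.0) >= observed_dev - 1e-9))
        return u, min(1.0, p)

    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    nt = n + m
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (nt * (nt - 1))
    var = nm / 12.0 * (nt + 1 - tie_term)
    if var <= 0:
        return u, 1.0  # all observations identical
    z = (abs(u - nm / 2.0) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = 2.0 * stats.norm.sf(z)
    return u, min(1.0, p)


# ---------------------------------------------------------------------------
# Stratified / per-class reports
# ---------------------------------------------------------------------------

def _label_frame(labels) -> pd.DataFrame:
    from .topology import labels_to_frame

    if isinstance(labels, pd.DataFrame):
        return labels
    return labels_to_frame(labels)


def stratify_by_ctcf_strength(labels, results: pd.DataFrame, n_bins: int = 2,
                              which: str = "cross") -> pd.DataFrame:
    """Fold-change distributions of one category binned by structural-loop
    strength (quantile bins; default median split -> weak/strong), plus
    pairwise MWU p-values between adjacent strata.

    which="cross" bins cross-type interactions on max_cross_strength;
    which="contain" bins contain-type on max_contain_strength.
    """
    lab = _label_frame(labels)
    col = "max_cross_strength" if which == "cross" else "max_contain_strength"
    sub = lab[lab["category"] == which].merge(results, on="loop_id")
    sub = sub.dropna(subset=[col])
    if sub.empty:
        return pd.DataFrame(columns=["stratum", "boundary_low", "boundary_high",
                                     "n", "median_log2fc", "mwu_p_vs_prev"])
    edges = np.quantile(sub[col], np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) < 2:  # all strengths identical: one degenerate stratum
        vals = sub["log2fc"].to_numpy()
        return pd.DataFrame([{
            "stratum": "all", "boundary_low": edges[0], "boundary_high": edges[0],
            "n": len(vals), "median_log2fc": float(np.median(vals)),
            "mwu_p_vs_prev": np.nan}])
    names = (["weak", "strong"] if len(edges) - 1 == 2
             else [f"q{i}" for i in range(len(edges) - 1)])
    sub = sub.copy()
    sub["stratum"] = pd.cut(sub[col], bins=edges, labels=names, include_lowest=True)
    rows = []
    prev_vals = None
    for i, name in enumerate(names):
        vals = sub.loc[sub["stratum"] == name, "log2fc"].to_numpy()
        p = np.nan
        if prev_vals is not None and len(prev_vals) and len(vals):
            _, p = mann_whitney_u(prev_vals, vals)
        rows.append({"stratum": str(name), "boundary_low": edges[i],
                     "boundary_high": edges[i + 1], "n": len(vals),
                     "median_log2fc": float(np.median(vals)) if len(vals) else np.nan,
                     "mwu_p_vs_prev": p})
        prev_vals = vals
    return pd.DataFrame(rows)


def contain_cross_balance(labels, results: pd.DataFrame) -> pd.DataFrame:
    """Per contain_and_cross interaction: strength bins of both relations
    plus the balance statistic log2(max_contain / max_cross)."""
    lab = _label_frame(labels)
    sub = lab[lab["category"] == "contain_and_cross"].merge(results, on="loop_id")
    sub = sub.dropna(subset=["max_contain_strength", "max_cross_strength"]).copy()
    if sub.empty:
        return pd.DataFrame(columns=["loop_id", "contain_bin", "cross_bin",
                                     "balance", "log2fc"])
    cmed = sub["max_contain_strength"].median()
    xmed = sub["max_cross_strength"].median()
    sub["contain_bin"] = np.where(sub["max_contain_strength"] > cmed, "strong", "weak")
    sub["cross_bin"] = np.where(sub["max_cross_strength"] > xmed, "strong", "weak")
    sub["balance"] = np.log2(sub["max_contain_strength"] / sub["max_cross_strength"])
    return sub[["loop_id", "contain_bin", "cross_bin", "balance", "log2fc"]]


def class_response_report(labels, results: pd.DataFrame,
                          reference: str = "outside") -> pd.DataFrame:
    """Per-category (and contain-subtype) fold-change summary with MWU
    p-value against the reference (outside) category."""
    lab = _label_frame(labels)
    merged = lab.merge(results, on="loop_id", how="inner")
    missing = set(lab["loop_id"]) - set(results["loop_id"])
    if missing:
        raise KeyError(f"labels without differential results: {sorted(missing)[:5]}"
                       f" ({len(missing)} total)")
    ref_vals = merged.loc[merged["category"] == reference, "log2fc"].to_numpy()

    def summarize(name: str, vals: np.ndarray) -> dict:
        p = np.nan
        if name != reference and len(vals) and len(ref_vals):
            _, p = mann_whitney_u(vals, ref_vals)
        q1, q3 = (np.percentile(vals, [25, 75]) if len(vals) else (np.nan, np.nan))
        return {"group": name, "n": len(vals),
                "median_log2fc": float(np.median(vals)) if len(vals) else np.nan,
                "iqr_low": q1, "iqr_high": q3, "mwu_p_vs_outside": p}

    rows = []
    from .topology import CATEGORIES

    for cat in CATEGORIES:
        vals = merged.loc[merged["category"] == cat, "log2fc"].to_numpy()
        rows.append(summarize(cat, vals))
    for sub in ("I", "II", "III"):
        sel = (merged["category"] == "contain") & (merged["contain_subtype"] == sub)
        rows.append(summarize(f"contain_{sub}", merged.loc[sel, "log2fc"].to_numpy()))
    return pd.DataFrame(rows)
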