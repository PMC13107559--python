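"""Synthetic study generator with planted ground truth.

Builds a complete miniature degron study on a two-chromosome genome:

* ``chrS`` carries the structural architecture — convergent-motif CTCF
  loops laid out in disjoint slots — and the regulatory (H3K27ac)
  interactions planted around them so that each interaction satisfies
  exactly one topology relation under the default classifier settings
  (slack 0, midpoint spans).  Slot geometry guarantees unambiguity:
  every planted interaction relates only to the loop(s) of its own slot.
* ``chrG`` carries the gene models, promoter-proximal CTCF peaks/motifs
  (centered ~57 bp upstream of the TSS), accessibility windows and
  non-looping H3K27ac peaks.

Condition effects are multiplicative on negative-binomial count means:
contain-type interactions are weakened on depletion (subtype III most,
then II), the strong-insulator half of cross-type interactions is
enhanced, a fraction of CTCF accessibility windows collapses sharply and
is restored under both wt and mut re-expression, and planted
differentially expressed genes follow configurable rescue patterns
(loop-independent: rescued by wt and mut; loop-dependent: wt only).

Everything is a deterministic function of one integer seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from .core import GenomeSpec, Interval, Loop

SLOT_UNITS = 16          # a slot is 16 B-units wide; see layout below
MIN_B_PER_ANCHOR = 2     # require B >= 2 * anchor_width for safe jitter

CONDITIONS = ("untreated", "IAA", "oeCTCFwt_IAA", "oeCTCFmut_IAA")

DEFAULT_CLASS_MIX = {
    "contain_I": 0.10,
    "contain_II": 0.15,
    "contain_III": 0.20,
    "contain_and_cross": 0.33,
    "cross": 0.04,
    "neighbor": 0.07,
    "inside": 0.07,
    "outside": 0.04,
}

DEFAULT_DEPLETION_EFFECT = {
    "contain_I": 1.0,
    "contain_II": 0.5,
    "contain_III": 0.25,
    "contain_and_cross": 1.0,
    "cross": 1.0,          # overridden for strong-insulator hosts, see below
    "neighbor": 1.0,
    "inside": 1.0,
    "outside": 1.0,
}

CLASS_TO_CATEGORY = {
    "contain_I": "contain", "contain_II": "contain", "contain_III": "contain",
    "contain_and_cross": "contain_and_cross", "cross": "cross",
    "neighbor": "neighbor", "inside": "inside", "outside": "outside",
}


@dataclass
class SimConfig:
    """All knobs of the synthetic study.  ``seed`` fully determines output."""

    seed: int = 0
    chrS_length: int = 20_000_000
    chrG_length: int = 20_000_000
    n_ctcf_loops: int = 200
    double_slot_fraction: float = 1 / 3
    anchor_width: int = 1000
    motif_width: int = 20
    n_h3k27ac_interactions: int = 1000
    interaction_slot_fraction: float = 0.5
    class_mix: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    ambiguous_fraction: float = 0.0
    strength_lognormal: tuple = (3.0, 1.0)
    depletion_effect: dict = field(default_factory=lambda: dict(DEFAULT_DEPLETION_EFFECT))
    cross_strong_effect: float = 1.8
    cross_strong_quantile: float = 0.5
    count_scale: float = 3.0
    nb_size: float = 80.0
    sequencing_depth: dict = field(default_factory=lambda: {c: 1.0 for c in CONDITIONS})
    # accessibility
    atac_window: int = 300
    atac_mean: float = 100.0
    atac_affected_fraction: float = 0.4
    atac_effect: float = 0.3
    n_background_windows: int = 1000
    n_weak_sites: int = 60
    # expression
    n_genes: int = 2000
    deg_fraction: float = 0.06
    deg_up_n: int = 20
    deg_log2fc: float = -1.5
    deg_min_mean: float = 120.0   # planted DEGs are detectably expressed
    rescue_mix: dict = field(default_factory=lambda: {
        "loop_independent": 0.7, "loop_dependent": 0.2, "not_rescued": 0.1})
    background_promoter_ctcf_fraction: float = 0.2
    expr_lognormal: tuple = (4.0, 1.0)
    n_replicates: int = 3
    promoter_motif_offset: int = 57
    promoter_motif_jitter: int = 5
    n_nonlooping_h3k27ac: int = 300
    peak_width: int = 200

    def __post_init__(self) -> None:
        mix_sum = sum(self.class_mix.values())
        if abs(mix_sum - 1.0) > 1e-9:
            raise ValueError(f"class_mix must sum to 1, got {mix_sum}")
        unknown = set(self.class_mix) - set(CLASS_TO_CATEGORY)
        if unknown:
            raise ValueError(f"unknown topology classes in class_mix: {sorted(unknown)}")
        for k, v in self.depletion_effect.items():
            if v <= 0:
                raise ValueError(f"depletion_effect[{k!r}] must be > 0")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per condition")

    @property
    def genome(self) -> GenomeSpec:
        return GenomeSpec({"chrS": self.chrS_length, "chrG": self.chrG_length})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown simulation config keys: {sorted(unknown)}")
        d = dict(d)
        for tup_key in ("strength_lognormal", "expr_lognormal"):
            if tup_key in d and isinstance(d[tup_key], list):
                d[tup_key] = tuple(d[tup_key])
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted labels: one row per simulated entity."""

    interactions: pd.DataFrame   # id, class, category, subtype, ctcf_loop_id, effect, ambiguous
    atac: pd.DataFrame           # window_id, affected, effect, group
    genes: pd.DataFrame          # gene_id, chrom, tss, strand, deg, promoter_ctcf, rescue, mechanism

    def to_dict(self) -> dict:
        return {"interactions": self.interactions.to_dict(orient="list"),
                "atac": self.atac.to_dict(orient="list"),
                "genes": self.genes.to_dict(orient="list")}

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(interactions=pd.DataFrame(d["interactions"]),
                   atac=pd.DataFrame(d["atac"]),
                   genes=pd.DataFrame(d["genes"]))


@dataclass
class SyntheticStudy:
    config: SimConfig
    ctcf_loops: list
    ctcf_peaks: list
    ctcf_motifs: list
    weak_motifs: list
    h3k27ac_interactions: list
    h3k27ac_peaks: list
    enhancers: list
    gene_models: pd.DataFrame
    promoter_peaks: list
    promoter_motifs: list
    atac_windows: pd.DataFrame
    expression_counts: pd.DataFrame
    design: dict
    truth: GroundTruth

    @property
    def all_ctcf_peaks(self) -> list:
        return list(self.ctcf_peaks) + list(self.promoter_peaks)

    @property
    def all_ctcf_motifs(self) -> list:
        return (list(self.ctcf_motifs) + list(self.promoter_motifs)
                + list(self.weak_motifs))


# ---------------------------------------------------------------------------
# slot layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Slot:
    index: int
    start: int
    B: int
    double: bool

    def pos(self, units: float) -> int:
        return self.start + int(round(units * self.B))


def _slot_layout(cfg: SimConfig) -> list[_Slot]:
    n = cfg.n_ctcf_loops
    if n == 0:
        return []
    slot_len = cfg.chrS_length // n
    B = slot_len // SLOT_UNITS
    if B < MIN_B_PER_ANCHOR * cfg.anchor_width:
        raise ValueError(
            "infeasible density: chrS_length too small for n_ctcf_loops at "
            f"anchor_width={cfg.anchor_width} (need slot unit B >= "
            f"{MIN_B_PER_ANCHOR * cfg.anchor_width}, got {B})")
    n_double = int(round(n * cfg.double_slot_fraction))
    if n_double >= n:
        n_double = n - 1
    return [_Slot(i, i * slot_len, B, i < n_double) for i in range(n)]


def _anchor(chrom: str, center: int, width: int, strand: str = ".") -> Interval:
    return Interval(chrom, center - width // 2, center - width // 2 + width, strand)


def _nb(rng: np.random.Generator, mean, size_param: float):
    """Negative-binomial draw(s) with shape k and the given mean."""
    mean = np.asarray(mean, dtype=float)
    p = size_param / (size_param + np.maximum(mean, 1e-12))
    draw = rng.negative_binomial(size_param, p, size=mean.shape or None)
    return np.where(mean <= 0, 0, draw)


# ---------------------------------------------------------------------------
# stage 1: CTCF architecture
# ---------------------------------------------------------------------------

def simulate_ctcf_architecture(cfg: SimConfig):
    """(motifs, peaks, loops): convergent-motif loops in disjoint slots.

    Primary loops sit at slot units 4 and 12; "double" slots carry a
    secondary loop at units 8 and 10 (used for contain & cross planting).
    Strengths are log-normal; counts negative-binomial around
    strength x count_scale x condition depth.  Also returns a set of
    weak, peak-less motifs on chrG (accessibility Group-2 material) via
    the study builder.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    slots = _slot_layout(cfg)
    mu, sigma = cfg.strength_lognormal
    motifs: list[Interval] = []
    peaks: list[Interval] = []
    loops: list[Loop] = []
    aw, mw = cfg.anchor_width, cfg.motif_width

    def add_loop(lid: str, cl: int, cr: int) -> Loop:
        strength = float(rng.lognormal(mu, sigma))
        counts = {}
        for cond in CONDITIONS:
            m = strength * cfg.count_scale * cfg.sequencing_depth[cond]
            counts[cond] = int(_nb(rng, m, cfg.nb_size))
        loop = Loop(id=lid,
                    anchorL=_anchor("chrS", cl, aw),
                    anchorR=_anchor("chrS", cr, aw),
                    counts=counts, strength=strength)
        motifs.append(_anchor("chrS", cl, mw, "+"))
        motifs.append(_anchor("chrS", cr, mw, "-"))
        peaks.append(loop.anchorL)
        peaks.append(loop.anchorR)
        loops.append(loop)
        return loop

    for slot in slots:
        add_loop(f"ctcf_{slot.index:05d}", slot.pos(4), slot.pos(12))
        if slot.double:
            add_loop(f"ctcf_{slot.index:05d}b", slot.pos(8), slot.pos(10))
    return motifs, peaks, loops


# ---------------------------------------------------------------------------
# stage 2: planted regulatory interactions
# ---------------------------------------------------------------------------

def _class_counts(cfg: SimConfig) -> dict[str, int]:
    """Largest-remainder apportionment of n interactions over class_mix."""
    n = cfg.n_h3k27ac_interactions
    items = sorted(cfg.class_mix.items())
    raw = {k: v * n for k, v in items}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    rem = n - sum(counts.values())
    order = sorted(items, key=lambda kv: raw[kv[0]] - counts[kv[0]], reverse=True)
    for k, _ in order[:rem]:
        counts[k] += 1
    return counts


def plant_h3k27ac_interactions(cfg: SimConfig, ctcf_loops: list):
    """Plant interactions class by class; returns (interactions, truth frame).

    Geometry (slot units; primary span S = [4B, 12B), secondary
    S2 = [8B, 10B)):

    =================  =======================================================
    contain_III        both anchors identical to the primary loop's
    contain_II         left anchor shared, right anchor center in [13B, 15B]
    contain_I          anchors in [1.5B, 3B] and [13B, 15B]
    cross              anchors in [5B, 7B] (inside S) and [13B, 15B] (outside)
    inside             anchors in [5B, 7B] and [9B, 11B]
    neighbor           right anchor = primary left anchor, left in [0.5B, 2B]
    outside            anchors in [0.5B, 1B] and [2.8B, 3.4B]
    contain_and_cross  double slots: anchors in [5B, 7B] and [13B, 15B]
                       (contains the secondary loop, crosses the primary)
    =================  =======================================================

    Only contain_and_cross uses double slots; all other classes use single
    slots, so every placement bears exactly the planted relation set.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    slots = _slot_layout(cfg)
    # regulatory interactions occupy only a fraction of the structural
    # slots, keeping union coverage of interactions below that of loops
    frac = cfg.interaction_slot_fraction
    singles = [s for s in slots if not s.double]
    doubles = [s for s in slots if s.double]
    singles = singles[: max(1, int(round(len(singles) * frac)))] if singles else []
    doubles = doubles[: max(1, int(round(len(doubles) * frac)))] if doubles else []
    by_id = {l.id: l for l in ctcf_loops}
    counts_per_class = _class_counts(cfg)
    needs_loops = any(k != "outside" and v > 0 for k, v in counts_per_class.items())
    if needs_loops and not ctcf_loops:
        raise ValueError("non-outside classes requested but no CTCF loops supplied")
    if counts_per_class.get("contain_and_cross", 0) > 0 and not doubles:
        raise ValueError("contain_and_cross requested but no double slots "
                         "(raise double_slot_fraction)")
    if any(v > 0 and k != "contain_and_cross" for k, v in counts_per_class.items()) \
            and needs_loops and not singles:
        raise ValueError("single-loop classes requested but no single slots")

    primary_strengths = np.array(
        [by_id[f"ctcf_{s.index:05d}"].strength for s in slots]) if slots else np.array([])
    cross_cut = (float(np.quantile(primary_strengths, cfg.cross_strong_quantile))
                 if primary_strengths.size else np.inf)

    mu, sigma = cfg.strength_lognormal
    aw = cfg.anchor_width
    interactions: list[Loop] = []
    truth_rows: list[dict] = []

    def jitter_center(slot: _Slot, lo: float, hi: float) -> int:
        return slot.pos(lo) + int(rng.integers(0, max(1, slot.pos(hi) - slot.pos(lo))))

    def emit(klass: str, slot: _Slot, anchorL: Interval, anchorR: Interval,
             host: Loop, effect: float, ambiguous: bool = False,
             planted_subtype: str = "n/a") -> None:
        idx = len(interactions)
        strength = float(rng.lognormal(mu, sigma))
        counts = {}
        for cond in CONDITIONS:
            m = strength * cfg.count_scale * cfg.sequencing_depth[cond]
            if cond == "IAA":
                m *= effect
            counts[cond] = int(_nb(rng, m, cfg.nb_size))
        interactions.append(Loop(id=f"h3k_{idx:05d}", anchorL=anchorL,
                                 anchorR=anchorR, counts=counts, strength=strength))
        truth_rows.append({
            "id": f"h3k_{idx:05d}", "class": klass,
            "category": CLASS_TO_CATEGORY.get(klass, "ambiguous"),
            "subtype": planted_subtype, "ctcf_loop_id": host.id if host else "n/a",
            "effect": effect, "ambiguous": ambiguous, "slot": slot.index,
        })

    for klass in sorted(counts_per_class):
        n_k = counts_per_class[klass]
        pool = doubles if klass == "contain_and_cross" else singles
        if klass == "outside" and not pool:
            pool = slots
        for j in range(n_k):
            slot = pool[j % len(pool)]
            primary = by_id[f"ctcf_{slot.index:05d}"]
            effect = cfg.depletion_effect[klass]
            subtype = "n/a"
            if klass == "contain_III":
                aL, aR = primary.anchorL, primary.anchorR
                subtype = "III"
            elif klass == "contain_II":
                aL = primary.anchorL
                aR = _anchor("chrS", jitter_center(slot, 13, 15), aw)
                subtype = "II"
            elif klass == "contain_I":
                aL = _anchor("chrS", jitter_center(slot, 1.5, 3), aw)
                aR = _anchor("chrS", jitter_center(slot, 13, 15), aw)
                subtype = "I"
            elif klass == "cross":
                aL = _anchor("chrS", jitter_center(slot, 5, 7), aw)
                aR = _anchor("chrS", jitter_center(slot, 13, 15), aw)
                if primary.strength >= cross_cut:
                    effect = cfg.cross_strong_effect
            elif klass == "inside":
                aL = _anchor("chrS", jitter_center(slot, 5, 7), aw)
                aR = _anchor("chrS", jitter_center(slot, 9, 11), aw)
            elif klass == "neighbor":
                aL = _anchor("chrS", jitter_center(slot, 0.5, 2), aw)
                aR = primary.anchorL
            elif klass == "outside":
                aL = _anchor("chrS", jitter_center(slot, 0.5, 1), aw)
                aR = _anchor("chrS", jitter_center(slot, 2.8, 3.4), aw)
            elif klass == "contain_and_cross":
                aL = _anchor("chrS", jitter_center(slot, 5, 7), aw)
                aR = _anchor("chrS", jitter_center(slot, 13, 15), aw)
            else:  # pragma: no cover - guarded in SimConfig
                raise ValueError(f"unplaceable class {klass!r}")
            emit(klass, slot, aL, aR, primary, effect, planted_subtype=subtype)

    # optional deliberately ambiguous placements (contain of two loops with
    # differing subtypes) to exercise precedence handling downstream
    n_amb = int(round(cfg.ambiguous_fraction * cfg.n_h3k27ac_interactions))
    consecutive = [(a, b) for a, b in zip(singles, singles[1:])
                   if b.index == a.index + 1]
    if n_amb and not consecutive:
        raise ValueError("ambiguous placements requested but no consecutive "
                         "single slots available")
    for j in range(n_amb):
        s1, s2 = consecutive[j % len(consecutive)]
        p1 = by_id[f"ctcf_{s1.index:05d}"]
        aL = p1.anchorL
        aR = _anchor("chrS", jitter_center(s2, 13, 14), aw)
        emit("ambiguous_contain", s1, aL, aR, p1, 1.0, ambiguous=True)

    truth = pd.DataFrame(truth_rows, columns=["id", "class", "category", "subtype",
                                              "ctcf_loop_id", "effect", "ambiguous",
                                              "slot"])
    return interactions, truth


# ---------------------------------------------------------------------------
# stage 3: genes + expression
# ---------------------------------------------------------------------------

def simulate_genes(cfg: SimConfig, interactions: list, interaction_truth: pd.DataFrame):
    """Gene models with planted DEG / rescue / promoter-CTCF structure.

    Loop-dependent down-genes take their TSS at the left anchor of the
    strongest planted contain_III interactions (each in a distinct slot) so
    their promoter windows overlap anchors of robustly depleted EP/PP
    interactions.  All other genes live on an even grid along chrG;
    promoter-CTCF genes get a peak plus a motif centered ~57 bp upstream
    of the TSS (strand-aware).
    """
    rng = np.random.default_rng([cfg.seed, 3])
    n_down = int(round(cfg.deg_fraction * cfg.n_genes))
    n_ld = int(round(n_down * cfg.rescue_mix["loop_dependent"]))
    n_li = int(round(n_down * cfg.rescue_mix["loop_independent"]))
    n_nr = n_down - n_ld - n_li
    if n_nr < 0:
        raise ValueError("rescue_mix proportions exceed 1")

    by_id = {l.id: l for l in interactions}
    c3 = interaction_truth[interaction_truth["class"] == "contain_III"]
    # one gene per slot; rank host interactions by untreated count for power
    best_per_slot: dict[int, tuple[int, str]] = {}
    for r in c3.itertuples(index=False):
        cnt = by_id[r.id].counts["untreated"]
        cur = best_per_slot.get(r.slot)
        if cur is None or cnt > cur[0]:
            best_per_slot[r.slot] = (cnt, r.id)
    hosts = sorted(best_per_slot.values(), reverse=True)[:n_ld]
    if len(hosts) < n_ld:
        raise ValueError(
            f"need {n_ld} distinct contain_III slots for loop-dependent genes, "
            f"have {len(hosts)}")

    rows = []
    promoter_peaks: list[Interval] = []
    promoter_motifs: list[Interval] = []

    def plant_promoter_site(chrom: str, tss: int, strand: str) -> None:
        off = cfg.promoter_motif_offset + int(
            rng.integers(-cfg.promoter_motif_jitter, cfg.promoter_motif_jitter + 1))
        center = tss - off if strand == "+" else tss + off
        promoter_motifs.append(_anchor(chrom, center, cfg.motif_width, strand))
        promoter_peaks.append(_anchor(chrom, center, cfg.peak_width))

    for k, (_, hid) in enumerate(hosts):
        h = by_id[hid]
        tss = h.anchorL.midpoint
        rows.append({"gene_id": f"gene_ld_{k:04d}", "chrom": "chrS", "tss": tss,
                     "strand": "+", "deg": "down", "promoter_ctcf": True,
                     "rescue": "loop_dependent", "mechanism": "loop_dependent",
                     "host_interaction": hid})

    n_chrG = cfg.n_genes - n_ld
    spacing = cfg.chrG_length // (n_chrG + 1)
    if spacing < 4000:
        raise ValueError("infeasible density: chrG_length too small for n_genes")
    order = rng.permutation(n_chrG)
    li_set = set(order[:n_li])
    nr_set = set(order[n_li:n_li + n_nr])
    up_set = set(order[n_li + n_nr:n_li + n_nr + cfg.deg_up_n])
    rest = order[n_li + n_nr + cfg.deg_up_n:]
    n_bg_ctcf = int(round(cfg.background_promoter_ctcf_fraction * len(rest)))
    bg_ctcf_set = set(rest[:n_bg_ctcf])

    for g in range(n_chrG):
        tss = (g + 1) * spacing
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        if g in li_set:
            deg, rescue, mech, pc = "down", "loop_independent", "loop_independent", True
        elif g in nr_set:
            deg, rescue, mech, pc = "down", "not_rescued", "none", False
        elif g in up_set:
            deg, rescue, mech, pc = "up", "loop_independent", "loop_independent", True
        else:
            deg, rescue, mech, pc = "none", "n/a", "none", g in bg_ctcf_set
        if pc:
            plant_promoter_site("chrG", tss, strand)
        rows.append({"gene_id": f"gene_{g:05d}", "chrom": "chrG", "tss": tss,
                     "strand": strand, "deg": deg, "promoter_ctcf": pc,
                     "rescue": rescue, "mechanism": mech,
                     "host_interaction": "n/a"})

    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand", "deg",
                                        "promoter_ctcf", "rescue", "mechanism",
                                        "host_interaction"])
    return genes, promoter_peaks, promoter_motifs


def simulate_expression(cfg: SimConfig, gene_truth: pd.DataFrame):
    """Replicated count table across the four conditions.

    Planted down-genes drop by ``deg_log2fc`` under depletion;
    loop-independent genes return to baseline under both rescue
    constructs, loop-dependent only under wt, not-rescued under neither.
    DEG baselines are floored at the log-normal median so planted effects
    are statistically visible at the configured replicate number.
    """
    rng = np.random.default_rng([cfg.seed, 4])
    emu, esigma = cfg.expr_lognormal
    n = len(gene_truth)
    base = rng.lognormal(emu, esigma, size=n)
    is_deg = (gene_truth["deg"] != "none").to_numpy()
    base = np.where(is_deg, np.maximum(base, cfg.deg_min_mean), base)
    fc = 2.0 ** cfg.deg_log2fc
    up_fc = 2.0 ** abs(cfg.deg_log2fc)

    mean = {cond: base.copy() for cond in CONDITIONS}
    deg = gene_truth["deg"].to_numpy()
    rescue = gene_truth["rescue"].to_numpy()
    down = deg == "down"
    up = deg == "up"
    mean["IAA"] = np.where(down, base * fc, np.where(up, base * up_fc, base))
    restored_wt = down & np.isin(rescue, ["loop_independent", "loop_dependent"])
    restored_mut = down & (rescue == "loop_independent")
    # up-genes: loop-independent upregulation reverts under either construct
    mean["oeCTCFwt_IAA"] = np.where(restored_wt | up, base, mean["IAA"])
    mean["oeCTCFmut_IAA"] = np.where(restored_mut | up, base, mean["IAA"])

    data = {}
    design = {}
    for cond in CONDITIONS:
        depth = cfg.sequencing_depth[cond]
        for r in range(cfg.n_replicates):
            col = f"{cond}_rep{r + 1}"
            data[col] = _nb(rng, mean[cond] * depth, cfg.nb_size).astype(int)
            design[col] = cond
    counts = pd.DataFrame(data, index=pd.Index(gene_truth["gene_id"], name="gene_id"))
    return counts, design


# ---------------------------------------------------------------------------
# stage 4: accessibility
# ---------------------------------------------------------------------------

def simulate_atac(cfg: SimConfig, ctcf_peaks: list, weak_motifs: list = ()):
    """(window count table, truth frame).

    One window per CTCF peak (and per weak, peak-less motif site) plus
    background windows on chrG.  An ``atac_affected_fraction`` of the
    peak windows — and every weak site — loses accessibility under
    depletion (counts scaled by ``atac_effect``) and is restored under
    both rescue constructs.
    """
    rng = np.random.default_rng([cfg.seed, 5])
    w = cfg.atac_window
    half = w // 2
    rows = []
    for i, p in enumerate(ctcf_peaks):
        c = p.midpoint
        rows.append({"window_id": f"atacC_{i:05d}", "chrom": p.chrom,
                     "start": max(0, c - half), "end": c + half,
                     "group": "peak"})
    for i, m in enumerate(weak_motifs):
        c = m.midpoint
        rows.append({"window_id": f"atacW_{i:05d}", "chrom": m.chrom,
                     "start": max(0, c - half), "end": c + half,
                     "group": "motif_only"})
    stride = max(w * 4, cfg.chrG_length // max(cfg.n_background_windows + 1, 1))
    for i in range(cfg.n_background_windows):
        c = (i + 1) * stride + stride // 3
        if c + half > cfg.chrG_length:
            break
        rows.append({"window_id": f"atacB_{i:05d}", "chrom": "chrG",
                     "start": c - half, "end": c + half, "group": "background"})
    df = pd.DataFrame(rows)

    n_peak = int((df["group"] == "peak").sum())
    n_aff = int(round(cfg.atac_affected_fraction * n_peak))
    aff_idx = rng.choice(n_peak, size=n_aff, replace=False) if n_aff else np.array([], int)
    affected = np.zeros(len(df), dtype=bool)
    affected[aff_idx] = True
    affected |= (df["group"] == "motif_only").to_numpy()

    effect = np.where(affected, cfg.atac_effect, 1.0)
    for cond in CONDITIONS:
        m = np.full(len(df), cfg.atac_mean) * cfg.sequencing_depth[cond]
        if cond == "IAA":
            m = m * effect
        df[cond] = _nb(rng, m, cfg.nb_size).astype(int)

    truth = pd.DataFrame({"window_id": df["window_id"], "affected": affected,
                          "effect": effect, "group": df["group"]})
    return df, truth


# ---------------------------------------------------------------------------
# study assembly
# ---------------------------------------------------------------------------

def _n_loop_dependent(cfg: SimConfig) -> int:
    n_down = int(round(cfg.deg_fraction * cfg.n_genes))
    return int(round(n_down * cfg.rescue_mix["loop_dependent"]))


def _gene_grid_spacing(cfg: SimConfig) -> int:
    n_chrG = max(cfg.n_genes - _n_loop_dependent(cfg), 1)
    return cfg.chrG_length // (n_chrG + 1)


def _weak_motif_sites(cfg: SimConfig) -> list[Interval]:
    rng = np.random.default_rng([cfg.seed, 6])
    spacing = _gene_grid_spacing(cfg)
    out = []
    for i in range(cfg.n_weak_sites):
        pos = (i + 1) * spacing + 2 * spacing // 3
        if pos + cfg.motif_width >= cfg.chrG_length:
            break
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        out.append(_anchor("chrG", pos, cfg.motif_width, strand))
    return out


def _nonlooping_h3k27ac(cfg: SimConfig) -> list[Interval]:
    spacing = _gene_grid_spacing(cfg)
    out = []
    for i in range(cfg.n_nonlooping_h3k27ac):
        pos = (i + 1) * spacing + spacing // 4
        if pos + cfg.peak_width >= cfg.chrG_length:
            break
        out.append(_anchor("chrG", pos, cfg.peak_width))
    return out


def _unique_intervals(ivs: list[Interval]) -> list[Interval]:
    seen = set()
    out = []
    for iv in ivs:
        key = (iv.chrom, iv.start, iv.end)
        if key not in seen:
            seen.add(key)
            out.append(iv)
    return out


def simulate_study(cfg: SimConfig) -> SyntheticStudy:
    """Run every stage and assemble the full synthetic study."""
    motifs, peaks, loops = simulate_ctcf_architecture(cfg)
    interactions, itruth = plant_h3k27ac_interactions(cfg, loops)
    genes, promoter_peaks, promoter_motifs = simulate_genes(cfg, interactions, itruth)
    counts, design = simulate_expression(cfg, genes)
    weak = _weak_motif_sites(cfg)
    atac_df, atruth = simulate_atac(cfg, _unique_intervals(peaks + promoter_peaks), weak)

    anchors = _unique_intervals(
        [a for l in interactions for a in (l.anchorL, l.anchorR)])
    h3k_peaks = anchors + _nonlooping_h3k27ac(cfg)

    # enhancers: interaction anchors that do not overlap a promoter window
    prom_spans = [(r.chrom, int(r.tss) - 1000, int(r.tss) + 1000)
                  for r in genes.itertuples(index=False)]
    prom_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in prom_spans:
        prom_by_chrom.setdefault(c, []).append((s, e))
    enhancers = []
    for a in anchors:
        hit = any(s < a.end and a.start < e
                  for s, e in prom_by_chrom.get(a.chrom, ()))
        if not hit:
            enhancers.append(a)

    truth = GroundTruth(interactions=itruth, atac=atruth,
                        genes=genes.drop(columns=["host_interaction"]))
    gene_models = genes[["gene_id", "chrom", "tss", "strand"]].copy()
    return SyntheticStudy(
        config=cfg, ctcf_loops=loops, ctcf_peaks=peaks, ctcf_motifs=motifs,
        weak_motifs=weak, h3k27ac_interactions=interactions,
        h3k27ac_peaks=h3k_peaks, enhancers=enhancers, gene_models=gene_models,
        promoter_peaks=promoter_peaks, promoter_motifs=promoter_motifs,
        atac_windows=atac_df, expression_counts=counts, design=design,
        truth=truth)


def write_study(study: SyntheticStudy, outdir) -> dict:
    """Write every study artifact as plain text; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfgd = study.config.to_dict()
    h = lio.config_hash(cfgd)
    paths = {}

    def p(name: str) -> Path:
        paths[name] = outdir / name
        return paths[name]

    lio.write_bedpe(study.ctcf_loops, p("ctcf_loops.bedpe"), CONDITIONS, h)
    lio.write_bedpe(study.h3k27ac_interactions, p("h3k27ac_interactions.bedpe"),
                    CONDITIONS, h)
    lio.write_bed(study.ctcf_peaks, p("ctcf_peaks.bed"), cfg_hash=h)
    lio.write_bed(study.all_ctcf_motifs, p("ctcf_motifs.bed"), cfg_hash=h)
    lio.write_bed(study.promoter_peaks, p("promoter_ctcf_peaks.bed"), cfg_hash=h)
    lio.write_bed(study.h3k27ac_peaks, p("h3k27ac_peaks.bed"), cfg_hash=h)
    lio.write_bed(study.enhancers, p("enhancers.bed"), cfg_hash=h)
    lio.write_table(study.gene_models, p("gene_models.tsv"), h)
    lio.write_table(study.atac_windows, p("atac_windows.tsv"), h)
    lio.write_table(study.expression_counts.reset_index(), p("expression_counts.tsv"), h)
    lio.write_json({"design": study.design}, p("design.json"), h)
    lio.write_json(study.truth.to_dict(), p("truth.json"), h)
    lio.write_json({"config": cfgd}, p("simconfig.json"), h)
    return paths
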