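"""Readers and writers for the plain-text formats the pipeline speaks.

BEDPE for paired-anchor loops, BED6 for peaks/motifs, TSV for tables and
JSON for ground truth / provenance.  All readers skip ``#`` comment lines
and report malformed lines with their 1-based line number; all writers
emit a provenance header comment (tool version + config hash) so outputs
are self-describing.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .core import Interval, Loop, canonicalize_loop

TOOL_VERSION = "looptopo-0.1.0"


class FormatError(ValueError):
    """Malformed record in a standard-format file; message names the line."""


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serializable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _header(cfg_hash: str | None) -> str:
    return f"# {TOOL_VERSION} config_hash={cfg_hash or 'na'}\n"


def _parse_int(token: str, path, lineno: int, what: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise FormatError(
            f"{path}:{lineno}: non-integer {what} {token!r}"
        ) from None


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path) -> list[Interval]:
    """Read a BED3/BED6 file into Intervals (strand from column 6)."""
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 columns")
            chrom = fields[0]
            start = _parse_int(fields[1], path, lineno, "start")
            end = _parse_int(fields[2], path, lineno, "end")
            if end <= start:
                raise FormatError(f"{path}:{lineno}: end <= start")
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-." else "."
            out.append(Interval(chrom, start, end, strand))
    return out


def write_bed(intervals: Sequence[Interval], path, names: Sequence[str] | None = None,
              scores: Sequence[float] | None = None, cfg_hash: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(cfg_hash))
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"iv{i}"
            score = scores[i] if scores is not None else 0
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# BEDPE
# ---------------------------------------------------------------------------

def read_bedpe(path, conditions: Sequence[str] = ()) -> list[Loop]:
    """Read BEDPE into canonical Loops.

    Layout: ``chrom1 start1 end1 chrom2 start2 end2 name score strand1
    strand2 [count ...]``.  Extra numeric columns beyond the tenth are
    mapped, in order, onto the supplied condition names.  The ``score``
    column carries the loop strength.
    """
    out: list[Loop] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 10 + len(conditions):
                raise FormatError(
                    f"{path}:{lineno}: expected >= {10 + len(conditions)} "
                    f"columns, found {len(fields)}"
                )
            c1 = fields[0]
            s1 = _parse_int(fields[1], path, lineno, "start1")
            e1 = _parse_int(fields[2], path, lineno, "end1")
            c2 = fields[3]
            s2 = _parse_int(fields[4], path, lineno, "start2")
            e2 = _parse_int(fields[5], path, lineno, "end2")
            if e1 <= s1 or e2 <= s2:
                raise FormatError(f"{path}:{lineno}: end <= start")
            name = fields[6]
            try:
                strength = float(fields[7])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric score {fields[7]!r}"
                ) from None
            st1 = fields[8] if fields[8] in "+-." else "."
            st2 = fields[9] if fields[9] in "+-." else "."
            counts = {
                cond: _parse_int(fields[10 + k], path, lineno, f"count[{cond}]")
                for k, cond in enumerate(conditions)
            }
            loop = Loop(
                id=name,
                anchorL=Interval(c1, s1, e1, st1),
                anchorR=Interval(c2, s2, e2, st2),
                counts=counts,
                strength=strength,
            )
            out.append(canonicalize_loop(loop))
    return out


def write_bedpe(loops: Sequence[Loop], path, conditions: Sequence[str] = (),
                cfg_hash: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(cfg_hash))
        for l in loops:
            a, b = l.anchorL, l.anchorR
            row = [
                a.chrom, a.start, a.end, b.chrom, b.start, b.end,
                l.id, repr(l.strength), a.strand, b.strand,
            ]
            row += [l.counts[c] for c in conditions]
            fh.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_table(df: pd.DataFrame, path, cfg_hash: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(cfg_hash))
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_gene_models(path) -> pd.DataFrame:
    """Gene model TSV with required columns gene_id, chrom, tss, strand."""
    df = read_table(path)
    missing = {"gene_id", "chrom", "tss", "strand"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing gene-model columns {sorted(missing)}")
    return df


def write_json(obj, path, cfg_hash: str | None = None) -> None:
    payload = {"_provenance": {"tool": TOOL_VERSION, "config_hash": cfg_hash or "na"},
               **obj}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True, default=_jsonable))


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonable(x):
    import numpy as np

    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (set, frozenset)):
        return sorted(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")
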