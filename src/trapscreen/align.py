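"""Pairwise alignment utilities built on edlib.

Two identity conventions are exposed, both defined as matched columns
over total alignment columns (gap columns count):

* :func:`global_identity` — Needleman–Wunsch, end gaps penalised.
  Used for similarity clustering.
* :func:`overlap_identity` — end gaps of the longer sequence are free
  (edlib "HW" infix mode, shorter sequence as the query).  Used for the
  contaminant screen, where reference records routinely extend past the
  contaminant template.

Coordinates are 0-based half-open throughout this module.
"""

from __future__ import annotations

import re

import edlib

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMP)[::-1]


def cigar_ops(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def _identity_from(result: dict) -> float:
    cols = sum(n for n, _ in cigar_ops(result["cigar"]))
    if cols == 0:
        return 0.0
    return (cols - result["editDistance"]) / cols


def global_identity(a: str, b: str) -> float:
    """NW identity; end gaps penalised."""
    if not a or not b:
        return 0.0
    return _identity_from(edlib.align(a, b, mode="NW", task="path"))


def overlap_identity(a: str, b: str) -> float:
    """Identity over the best placement of the shorter sequence in the longer."""
    if not a or not b:
        return 0.0
    q, t = (a, b) if len(a) <= len(b) else (b, a)
    return _identity_from(edlib.align(q, t, mode="HW", task="path"))


def align_columns(query: str, target: str, mode: str = "NW") -> list[tuple[int, int]]:
    """Column list of an optimal alignment as ``(query_pos, target_pos)`` pairs.

    A gap on either side is reported as -1 for that sequence.  In "HW"
    mode the query is aligned to the best infix of the target and
    columns outside the infix are not reported.
    """
    res = edlib.align(query, target, mode=mode, task="path")
    qi = 0
    ti = res["locations"][0][0] if mode == "HW" else 0
    cols: list[tuple[int, int]] = []
    for n, op in cigar_ops(res["cigar"]):
        for _ in range(n):
            if op in "=XM":
                cols.append((qi, ti))
                qi += 1
                ti += 1
            elif op == "I":  # consumes query only
                cols.append((qi, -1))
                qi += 1
            else:  # "D": consumes target only
                cols.append((-1, ti))
                ti += 1
    return cols


def map_query_region_to_target(
    query: str, target: str, region: tuple[int, int], mode: str = "HW"
) -> tuple[tuple[int, int] | None, float]:
    """Project a query interval onto the target through an optimal alignment.

    Returns ``((start, end), coverage)`` where ``start:end`` is the
    target slice aligned to query positions ``region[0]:region[1]`` and
    coverage is the fraction of region positions aligned to a target
    base (not a gap).  Returns ``(None, 0.0)`` when nothing aligns.
    """
    lo, hi = region
    if not 0 <= lo < hi <= len(query):
        raise ValueError(f"bad region {region} for query of length {len(query)}")
    hits = [t for q, t in align_columns(query, target, mode=mode) if lo <= q < hi and t >= 0]
    coverage = len(hits) / (hi - lo)
    if not hits:
        return None, 0.0
    return (min(hits), max(hits) + 1), coverage
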