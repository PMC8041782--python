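"""Index-switching contamination rate and detection threshold.

During Illumina sequencing a small fraction of reads acquire the index
of another library at one end ("index hopping"), mis-assigning them
across samples.  With unique dual indexing every single-end switch
lands on an index pair never applied during library preparation, so the
fraction of reads on invalid pairs measures the single-end switching
rate c.  A read is only mis-assigned to another sample when *both* ends
switch onto that sample's pair, so c² bounds the residual
misidentification rate and serves as a per-library relative-abundance
detection threshold: taxon observations below it are treated as
switching artefacts and removed.

Under combinatorial indexing some single-switch destinations are valid
pairs of other samples, so invalid-pair reads undercount switching; the
estimator scales by the ratio of single-switch-reachable cells to the
invalid ones among them (uniform-destination assumption), reducing to
the naive invalid-read fraction for unique dual indexes.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class IndexPairCounts:
    i5_values: tuple[str, ...]
    i7_values: tuple[str, ...]
    counts: dict[tuple[str, str], int]  # complete grid
    valid_pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.valid_pairs:
            raise ValueError("valid_pairs must be non-empty")
        grid = {(a, b) for a in self.i5_values for b in self.i7_values}
        if not self.valid_pairs <= grid:
            raise ValueError("valid_pairs outside the declared index grid")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("read counts must be >= 0")

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def invalid_reads(self) -> int:
        return sum(v for pair, v in self.counts.items() if pair not in self.valid_pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(a, b, self.counts[(a, b)]) for a in self.i5_values for b in self.i7_values],
            columns=["i5", "i7", "reads"],
        )


@dataclass(frozen=True)
class ContaminationStats:
    """Single-end switching rate c and residual threshold t = c²."""

    c: float
    t: float
    total_reads: int
    invalid_reads: int
    n_offdiag_cells: int
    n_invalid_cells: int

    def __post_init__(self) -> None:
        if not 0 <= self.c <= 1:
            raise ValueError("c must lie in [0, 1]")
        if abs(self.t - self.c**2) > 1e-15:
            raise ValueError("t must equal c squared")

    @property
    def c_percent(self) -> float:
        return 100.0 * self.c

    @property
    def t_percent(self) -> float:
        return 100.0 * self.t

    def to_dict(self) -> dict:
        return {
            "c": self.c, "t": self.t,
            "c_percent": self.c_percent, "t_percent": self.t_percent,
            "total_reads": self.total_reads, "invalid_reads": self.invalid_reads,
            "n_offdiag_cells": self.n_offdiag_cells,
            "n_invalid_cells": self.n_invalid_cells,
        }


def tally_index_pairs(
    observations,
    valid_pairs,
    i5_values: tuple[str, ...] | None = None,
    i7_values: tuple[str, ...] | None = None,
) -> IndexPairCounts:
    """Complete-grid tally from per-read pairs or pre-tallied counts.

    ``observations`` is an iterable of (i5, i7) observations or a
    mapping/DataFrame of pre-tallied counts.  Index pools default to
    the values occurring in ``valid_pairs``; observed values outside
    the pools raise.
    """
    valid = frozenset(tuple(p) for p in valid_pairs)
    if i5_values is None:
        i5_values = tuple(sorted({p[0] for p in valid}))
    if i7_values is None:
        i7_values = tuple(sorted({p[1] for p in valid}))
    counts = {(a, b): 0 for a in i5_values for b in i7_values}
    if isinstance(observations, pd.DataFrame):
        items = [((r.i5, r.i7), int(r.reads)) for r in observations.itertuples()]
    elif isinstance(observations, dict):
        items = [(tuple(k), int(v)) for k, v in observations.items()]
    else:
        items = [(tuple(obs), 1) for obs in observations]
    for pair, n in items:
        if pair not in counts:
            raise ValueError(f"index pair {pair} outside declared pools")
        counts[pair] += n
    return IndexPairCounts(i5_values, i7_values, counts, valid)


def single_switch_cells(counts: IndexPairCounts) -> set[tuple[str, str]]:
    """Grid cells reachable from any valid pair by switching exactly one end."""
    reach: set[tuple[str, str]] = set()
    for a, b in counts.valid_pairs:
        reach.update((a, y) for y in counts.i7_values if y != b)
        reach.update((x, b) for x in counts.i5_values if x != a)
    return reach


def estimate_contamination(counts: IndexPairCounts) -> ContaminationStats:
    """Single-end switching rate from the invalid-pair read fraction.

    c = (R_invalid / R_total) x (C_offdiag / C_invalid): the invalid
    read fraction, scaled up by how many single-switch destinations are
    themselves valid pairs (the factor is 1 under unique dual
    indexing).  t = c² is the residual double-switch threshold.
    """
    if counts.total_reads <= 0:
        raise ValueError("total reads must be positive")
    reach = single_switch_cells(counts)
    invalid_cells = reach - counts.valid_pairs
    if not invalid_cells:
        raise ValueError(
            "no invalid single-switch destination cells: switching rate not "
            "identifiable from a saturated combinatorial grid"
        )
    c = (counts.invalid_reads / counts.total_reads) * (len(reach) / len(invalid_cells))
    c = min(c, 1.0)
    return ContaminationStats(
        c=c, t=c**2,
        total_reads=counts.total_reads, invalid_reads=counts.invalid_reads,
        n_offdiag_cells=len(reach), n_invalid_cells=len(invalid_cells),
    )


def apply_threshold(
    taxon_table: pd.DataFrame, t: float
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Zero per-library relative abundances strictly below t.

    ``taxon_table`` is taxa x libraries in fractions.  Abundances are
    not renormalised afterwards, so retained values stay interpretable
    against the original library depth.  Returns the filtered table and
    a (library, taxon, abundance) report of removals.
    """
    if not 0 <= t <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    filtered = taxon_table.copy()
    removals = []
    for lib in taxon_table.columns:
        col = taxon_table[lib]
        drop = col[(col > 0) & (col < t)]
        for taxon, ab in drop.items():
            removals.append((lib, taxon, float(ab)))
        filtered.loc[drop.index, lib] = 0.0
    report = pd.DataFrame(removals, columns=["library", "taxon", "abundance"])
    return filtered, report
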