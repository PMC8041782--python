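"""Multi-locus detection calling against known mock-community designs.

Per-locus taxon abundances are merged by arithmetic mean over the loci
with reads in a library, detections are called as strictly positive
post-threshold combined abundance, and each pool's observed taxa are
compared with its known composition to yield false positives (observed
but absent from the design) and false negatives (designed but not
observed).  Congeners that a conserved locus cannot separate are mapped
to a shared display label on both sides of the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .lineage import RANKS
from .synth import META_COLS, MockCommunityDesign


def taxon_abundance_table(
    annotated: pd.DataFrame, label_col: str = "taxon_label"
) -> dict[str, pd.DataFrame]:
    """Per-locus taxa x libraries relative-abundance tables from an annotated ASV table.

    Abundances are read fractions within each (library, locus); a
    library with zero reads at a locus keeps an all-zero column there.
    """
    sample_cols = [c for c in annotated.columns
                   if c not in META_COLS and c not in _ANNOTATION_COLS]
    out: dict[str, pd.DataFrame] = {}
    for locus, sub in annotated.groupby("locus"):
        grouped = sub.groupby(label_col)[sample_cols].sum()
        totals = grouped.sum(axis=0)
        out[locus] = grouped.div(totals.where(totals > 0, 1.0), axis=1)
    return out


_ANNOTATION_COLS = set(RANKS) | {f"support_{r}" for r in RANKS} | {
    "assigned_rank", "species_label", "taxon_label",
}


def combine_loci(
    per_locus_tables: dict[str, pd.DataFrame],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean abundance across loci with reads, plus per-taxon locus support.

    For each library only loci whose table column carries reads (sum
    > 0) enter the mean; a library with no reads at any locus is
    dropped with a warning.  Returns ``(combined, support)`` where
    support counts the loci detecting each taxon per library.
    """
    import warnings

    taxa = sorted(set().union(*(t.index for t in per_locus_tables.values())))
    libraries = sorted(set().union(*(t.columns for t in per_locus_tables.values())))
    combined = pd.DataFrame(0.0, index=taxa, columns=libraries)
    support = pd.DataFrame(0, index=taxa, columns=libraries)
    dropped = []
    for lib in libraries:
        present = [
            t for t in per_locus_tables.values()
            if lib in t.columns and t[lib].sum() > 0
        ]
        if not present:
            dropped.append(lib)
            continue
        for t in present:
            col = t[lib].reindex(taxa, fill_value=0.0)
            combined[lib] += col
            support[lib] += (col > 0).astype(int)
        combined[lib] /= len(present)
    if dropped:
        warnings.warn(f"libraries with no reads at any locus dropped: {dropped}")
        combined = combined.drop(columns=dropped)
        support = support.drop(columns=dropped)
    return combined, support


@dataclass
class PoolResult:
    pool_id: str
    expected: dict[str, float]  # display label -> expected abundance (count/size)
    observed: dict[str, float]  # display label -> combined abundance
    false_positives: list[str] = field(default_factory=list)
    false_negatives: list[str] = field(default_factory=list)

    @property
    def all_detected(self) -> bool:
        return not self.false_negatives


@dataclass
class DetectionReport:
    pools: list[PoolResult]

    @property
    def fraction_all_detected(self) -> float:
        return sum(p.all_detected for p in self.pools) / len(self.pools)

    @property
    def fraction_fp_free(self) -> float:
        return sum(not p.false_positives for p in self.pools) / len(self.pools)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.pools:
            for label in sorted(set(p.expected) | set(p.observed)):
                rows.append({
                    "pool": p.pool_id, "taxon": label,
                    "expected_abundance": p.expected.get(label, 0.0),
                    "observed_abundance": p.observed.get(label, 0.0),
                    "call": ("FP" if label in p.false_positives
                             else "FN" if label in p.false_negatives
                             else "detected"),
                })
        return pd.DataFrame(rows)


def evaluate_detections(
    combined: pd.DataFrame,
    designs: list[MockCommunityDesign],
    t: float | None = None,
    aggregation_map: dict[str, str] | None = None,
    observable_labels: set[str] | None = None,
) -> DetectionReport:
    """FP/FN calls per pool; detection = positive post-threshold abundance.

    ``aggregation_map`` maps species names to display labels (e.g. two
    conserved-locus congeners to one slash-joined label) and is applied
    to designs and observations alike.  When ``t`` is given the
    threshold is applied here first.
    """
    from .contam import apply_threshold

    agg = aggregation_map or {}
    table = combined
    if t is not None:
        table, _ = apply_threshold(combined, t)
    pools = []
    for design in designs:
        expected: dict[str, float] = {}
        for species, count in design.counts.items():
            if count <= 0:
                continue
            label = agg.get(species, species)
            if observable_labels is not None and label not in observable_labels:
                raise ValueError(f"design species {species!r} maps to unobservable label {label!r}")
            expected[label] = expected.get(label, 0.0) + count / design.size
        if design.pool_id not in table.columns:
            observed: dict[str, float] = {}
        else:
            col = table[design.pool_id]
            observed = {agg.get(tx, tx): 0.0 for tx in col.index}
            for tx, ab in col.items():
                observed[agg.get(tx, tx)] += float(ab)
            observed = {lab: ab for lab, ab in observed.items() if ab > 0}
        fps = sorted(set(observed) - set(expected))
        fns = sorted(set(expected) - set(observed))
        pools.append(PoolResult(design.pool_id, expected, observed, fps, fns))
    return DetectionReport(pools)


def locus_overlap(
    detected_labels: dict[str, set[str]],
) -> dict[frozenset[str], int]:
    """Distinct labels detected by exactly each non-empty locus subset.

    ``detected_labels`` maps locus -> set of rank labels it detected.
    The returned counts over subsets sum to the number of distinct
    labels overall.
    """
    all_labels = set().union(*detected_labels.values()) if detected_labels else set()
    out: dict[frozenset[str], int] = {}
    for label in all_labels:
        subset = frozenset(l for l, labs in detected_labels.items() if label in labs)
        out[subset] = out.get(subset, 0) + 1
    return out


def detected_labels_by_locus(annotated: pd.DataFrame, rank: str) -> dict[str, set[str]]:
    """Per-locus sets of rank labels carried by ASVs with at least one read."""
    if rank not in annotated.columns and rank != "species":
        raise ValueError(f"unknown rank {rank!r}")
    col = "species_label" if rank == "species" else rank
    sample_cols = [c for c in annotated.columns
                   if c not in META_COLS and c not in _ANNOTATION_COLS]
    out: dict[str, set[str]] = {}
    for locus, sub in annotated.groupby("locus"):
        with_reads = sub[sub[sample_cols].sum(axis=1) > 0]
        out[locus] = set(with_reads[col].dropna())
    return out


def group_read_proportion(
    annotated: pd.DataFrame, rank: str, group: str
) -> pd.Series:
    """Per-library fraction of classified reads labelled ``group`` at ``rank``.

    Pooled across loci.  Libraries with zero classified reads report
    NaN (undefined).
    """
    if rank not in annotated.columns:
        raise ValueError(f"unknown rank {rank!r}")
    sample_cols = [c for c in annotated.columns
                   if c not in META_COLS and c not in _ANNOTATION_COLS]
    classified = annotated[annotated[rank].notna()]
    totals = classified[sample_cols].sum()
    in_group = classified[classified[rank] == group][sample_cols].sum()
    return in_group / totals.where(totals > 0)
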