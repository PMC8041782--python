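"""Reference-database curation for multi-locus metabarcoding.

Public marker-gene repositories carry duplicated, truncated, poorly
identified, endosymbiont-derived and misannotated records; training a
taxonomic classifier on them propagates those errors into every
downstream detection.  This module applies a four-rule decontamination
cascade, trims records to the primer-bounded amplicon region, and
exports classifier training sets:

1. length bounds and exact-sequence deduplication,
2. removal of records with insufficient identification ("sp.", "aff.", ...),
3. removal of records highly similar to a symbiont/contaminant panel
   (e.g. *Wolbachia*, a near-universal insect endosymbiont whose
   sequences frequently masquerade as host barcodes),
4. similarity clustering and removal of minority-lineage members of
   clusters that span more than one phylum, class or order.

Each removal is logged with the first rule that matched; the cascade is
idempotent on its own output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .align import global_identity, overlap_identity, map_query_region_to_target
from .lineage import Lineage, is_binomial

DEFAULT_EXCLUSION_TERMS = (
    "sp.",
    "nr.",
    "aff.",
    "cf.",
    "gen.",
    "complex",
    "hybrid",
    "environmental",
    "uncultured",
    "undescribed",
)

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}


@dataclass(frozen=True)
class TaxonRecord:
    """One reference sequence for one locus with its lineage and provenance."""

    record_id: str
    locus: str
    sequence: str
    lineage: Lineage
    source: str = "public"  # public | in_house | contaminant
    raw_label: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.record_id}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CurationParams:
    min_len: int = 200
    max_len: int = 3000
    exclusion_terms: tuple[str, ...] = DEFAULT_EXCLUSION_TERMS
    contaminant_identity: float = 0.95
    cluster_identity: float = 0.99

    def __post_init__(self) -> None:
        if not 0 < self.min_len < self.max_len:
            raise ValueError("need 0 < min_len < max_len")
        for v in (self.contaminant_identity, self.cluster_identity):
            if not 0 < v <= 1:
                raise ValueError("identity thresholds must lie in (0, 1]")


@dataclass(frozen=True)
class LogEntry:
    record_id: str
    rule: str  # "1".."4" or "trim"
    action: str  # removed | trimmed | kept
    detail: str = ""


@dataclass
class CurationLog:
    entries: list[LogEntry] = field(default_factory=list)

    def add(self, record_id: str, rule: str, action: str, detail: str = "") -> None:
        self.entries.append(LogEntry(record_id, rule, action, detail))

    def removed_ids(self, rule: str | None = None) -> set[str]:
        return {
            e.record_id
            for e in self.entries
            if e.action == "removed" and (rule is None or e.rule == rule)
        }

    def extend(self, other: "CurationLog") -> None:
        self.entries.extend(other.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.record_id, e.rule, e.action, e.detail) for e in self.entries],
            columns=["record_id", "rule", "action", "detail"],
        )


@dataclass(frozen=True)
class Primer:
    forward: str  # 5'->3' on the forward strand
    reverse: str  # 5'->3' on the reverse strand
    amplicon_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        for p in (self.forward, self.reverse):
            if not p:
                raise ValueError("primers must be non-empty")
            bad = set(p.upper()) - set(IUPAC_SETS)
            if bad:
                raise ValueError(f"non-IUPAC characters in primer: {sorted(bad)}")


#: Per-locus primer pairs.
PrimerSet = dict[str, Primer]


# ---------------------------------------------------------------------------
# Rule 1: length bounds and duplicates
# ---------------------------------------------------------------------------

def filter_length_duplicates(
    records: list[TaxonRecord], params: CurationParams
) -> tuple[list[TaxonRecord], CurationLog]:
    """Drop out-of-range lengths and exact duplicates (first id kept).

    Removal is strict: lengths of exactly ``min_len`` or ``max_len`` are
    retained.  A duplicate is an identical sequence carrying the same
    taxon label at the same locus — distinct species legitimately share
    a sequence at conserved loci and both copies are needed for exact
    species matching.  Among duplicates the smallest record_id survives.
    """
    log = CurationLog()
    sized: list[TaxonRecord] = []
    for rec in records:
        if len(rec) < params.min_len:
            log.add(rec.record_id, "1", "removed", f"length {len(rec)} < {params.min_len}")
        elif len(rec) > params.max_len:
            log.add(rec.record_id, "1", "removed", f"length {len(rec)} > {params.max_len}")
        else:
            sized.append(rec)

    def dedup_key(rec: TaxonRecord) -> tuple:
        return (rec.locus, rec.sequence, rec.lineage.species or rec.raw_label)

    keep_id: dict[tuple, str] = {}
    for rec in sorted(sized, key=lambda r: r.record_id):
        keep_id.setdefault(dedup_key(rec), rec.record_id)
    kept = []
    for rec in sized:
        first = keep_id[dedup_key(rec)]
        if rec.record_id == first:
            kept.append(rec)
        else:
            log.add(rec.record_id, "1", "removed", f"duplicate of {first}")
    return kept, log


# ---------------------------------------------------------------------------
# Rule 2: insufficient identification
# ---------------------------------------------------------------------------

def _has_exclusion_term(text: str, terms: tuple[str, ...]) -> str | None:
    tokens = [t.lower() for t in text.split()]
    for term in terms:
        if term.lower() in tokens:
            return term
    return None


def filter_unidentified(
    records: list[TaxonRecord], params: CurationParams
) -> tuple[list[TaxonRecord], CurationLog]:
    """Drop records whose label flags insufficient identification.

    A record is removed when its raw label or species name carries any
    exclusion term as a whitespace-delimited token, or when it lacks a
    complete binomial species name.
    """
    log = CurationLog()
    kept = []
    for rec in records:
        term = _has_exclusion_term(rec.raw_label, params.exclusion_terms)
        if term is None and rec.lineage.species:
            term = _has_exclusion_term(rec.lineage.species, params.exclusion_terms)
        if term is not None:
            log.add(rec.record_id, "2", "removed", f"exclusion term {term!r}")
        elif not is_binomial(rec.lineage.species):
            log.add(rec.record_id, "2", "removed", "no complete binomial species name")
        else:
            kept.append(rec)
    return kept, log


# ---------------------------------------------------------------------------
# Rule 3: contaminant screen
# ---------------------------------------------------------------------------

def filter_contaminants(
    records: list[TaxonRecord],
    contaminant_records: list[TaxonRecord],
    params: CurationParams,
) -> tuple[list[TaxonRecord], CurationLog]:
    """Drop records exceeding the identity threshold against a contaminant panel.

    Identity is matches over alignment columns with end gaps free
    (overlap identity); removal requires identity strictly greater than
    ``params.contaminant_identity``.
    """
    if not contaminant_records:
        raise ValueError("contaminant panel must be non-empty")
    log = CurationLog()
    kept = []
    for rec in records:
        best = max(overlap_identity(rec.sequence, c.sequence) for c in contaminant_records)
        if best > params.contaminant_identity:
            log.add(rec.record_id, "3", "removed", f"contaminant identity {best:.4f}")
        else:
            kept.append(rec)
    return kept, log


# ---------------------------------------------------------------------------
# Rule 4: similarity clustering and misannotation removal
# ---------------------------------------------------------------------------

def greedy_cluster(records: list[TaxonRecord], identity_threshold: float) -> list[list[TaxonRecord]]:
    """Greedy centroid clustering, global identity, end gaps penalised.

    Records are visited longest-first (record_id breaks ties); each
    joins the earliest-founded centroid reaching the threshold, else
    founds its own cluster.  The founder is each cluster's first member.
    """
    order = sorted(records, key=lambda r: (-len(r), r.record_id))
    clusters: list[list[TaxonRecord]] = []
    for rec in order:
        for cluster in clusters:
            if global_identity(rec.sequence, cluster[0].sequence) >= identity_threshold:
                cluster.append(rec)
                break
        else:
            clusters.append([rec])
    return clusters


def cluster_and_flag_misannotations(
    records: list[TaxonRecord], params: CurationParams
) -> tuple[list[TaxonRecord], CurationLog]:
    """Remove minority-lineage members of lineage-mixed similarity clusters.

    Clusters at ``cluster_identity`` whose members disagree at phylum,
    class or order are treated as containing misannotations: at the
    first discordant rank, members outside the majority label are
    removed; a tied vote falls back to the centroid's label.
    """
    log = CurationLog()
    removed: set[str] = set()
    by_locus: dict[str, list[TaxonRecord]] = {}
    for rec in records:
        by_locus.setdefault(rec.locus, []).append(rec)
    for locus_records in by_locus.values():
        for cluster in greedy_cluster(locus_records, params.cluster_identity):
            for rank in ("phylum", "class", "order"):
                labelled = [(r, r.lineage.get(rank)) for r in cluster if r.lineage.get(rank)]
                labels = {lab for _, lab in labelled}
                if len(labels) <= 1:
                    continue
                counts = {lab: sum(1 for _, l2 in labelled if l2 == lab) for lab in labels}
                top = max(counts.values())
                winners = [lab for lab, n in counts.items() if n == top]
                majority = winners[0] if len(winners) == 1 else cluster[0].lineage.get(rank)
                for rec, lab in labelled:
                    if lab != majority and rec.record_id not in removed:
                        removed.add(rec.record_id)
                        log.add(
                            rec.record_id, "4", "removed",
                            f"mixed cluster at {rank}: {lab} vs majority {majority}",
                        )
    kept = [r for r in records if r.record_id not in removed]
    return kept, log


# ---------------------------------------------------------------------------
# Primer-region trimming
# ---------------------------------------------------------------------------

def iupac_match_position(seq: str, primer: str, start: int, max_mismatch: int = 0) -> bool:
    if start < 0 or start + len(primer) > len(seq):
        return False
    mm = 0
    for p, b in zip(primer.upper(), seq[start : start + len(primer)].upper()):
        if b not in IUPAC_SETS.get(p, set()):
            mm += 1
            if mm > max_mismatch:
                return False
    return True


def find_primer(seq: str, primer: str, max_mismatch: int = 0) -> int | None:
    """Left-most start of an IUPAC-aware, indel-free primer match, or None."""
    for i in range(len(seq) - len(primer) + 1):
        if iupac_match_position(seq, primer, i, max_mismatch):
            return i
    return None


def locate_amplicon_interior(seed_sequence: str, primer: Primer) -> tuple[int, int]:
    """0-based half-open coordinates of the region between (excluding) primers."""
    from .align import revcomp

    f = find_primer(seed_sequence, primer.forward)
    if f is None:
        raise ValueError("forward primer not found in seed amplicon")
    rrc = revcomp(primer.reverse)
    r = None
    for i in range(len(seed_sequence) - len(rrc), f + len(primer.forward) - 1, -1):
        if iupac_match_position(seed_sequence, rrc, i):
            r = i
            break
    if r is None:
        raise ValueError("reverse primer not found in seed amplicon")
    return f + len(primer.forward), r


def trim_to_primer_region(
    records: list[TaxonRecord],
    primers: PrimerSet,
    seed_records: list[TaxonRecord],
    min_coverage: float = 0.8,
) -> tuple[list[TaxonRecord], CurationLog]:
    """Trim each record to its locus's primer-bounded region.

    Each record is aligned to the best-matching in-house seed amplicon
    of its locus; the columns spanning the seed's interior (between and
    excluding the primer binding sites) define the trimmed record.
    Records covering less than ``min_coverage`` of the region are
    removed.  Log coordinates are 1-based inclusive.
    """
    seeds_by_locus: dict[str, list[tuple[TaxonRecord, tuple[int, int]]]] = {}
    for seed in seed_records:
        if seed.locus not in primers:
            raise ValueError(f"no primers for seed locus {seed.locus!r}")
        region = locate_amplicon_interior(seed.sequence, primers[seed.locus])
        seeds_by_locus.setdefault(seed.locus, []).append((seed, region))

    log = CurationLog()
    out: list[TaxonRecord] = []
    for rec in records:
        if rec.locus not in seeds_by_locus:
            raise ValueError(f"no seed amplicon for locus {rec.locus!r}")
        seed, region = max(
            seeds_by_locus[rec.locus],
            key=lambda sr: overlap_identity(rec.sequence, sr[0].sequence),
        )
        span, coverage = map_query_region_to_target(seed.sequence, rec.sequence, region)
        if span is None or coverage < min_coverage:
            log.add(rec.record_id, "trim", "removed", f"region coverage {coverage:.2f} < {min_coverage}")
            continue
        lo, hi = span
        out.append(replace(rec, sequence=rec.sequence[lo:hi]))
        log.add(rec.record_id, "trim", "trimmed", f"kept {lo + 1}..{hi} of {len(rec)} (seed {seed.record_id})")
    return out, log


# ---------------------------------------------------------------------------
# Cascade and export
# ---------------------------------------------------------------------------

def curate(
    records: list[TaxonRecord],
    params: CurationParams,
    contaminant_records: list[TaxonRecord],
    primers: PrimerSet | None = None,
    seed_records: list[TaxonRecord] | None = None,
) -> tuple[list[TaxonRecord], CurationLog]:
    """Run the full cascade 1 -> 2 -> 3 -> 4 (-> trim when primers given)."""
    log = CurationLog()
    kept, sub = filter_length_duplicates(records, params)
    log.extend(sub)
    kept, sub = filter_unidentified(kept, params)
    log.extend(sub)
    kept, sub = filter_contaminants(kept, contaminant_records, params)
    log.extend(sub)
    kept, sub = cluster_and_flag_misannotations(kept, params)
    log.extend(sub)
    if primers is not None:
        if not seed_records:
            raise ValueError("primer trimming requires seed records")
        kept, sub = trim_to_primer_region(kept, primers, seed_records)
        log.extend(sub)
    return kept, log


def export_training_set(records: list[TaxonRecord]) -> tuple[list[str], list[str], CurationLog]:
    """Format curated records for classifier training and exact matching.

    Returns FASTA lines for (a) the genus-level lineage-string training
    file (ranks phylum..genus) and (b) the species-assignment file with
    ``ID Genus species`` headers, both ordered by record_id.  Records
    without a genus rank are excluded from (a) and logged; records
    without a species binomial are silently absent from (b).
    """
    log = CurationLog()
    genus_lines: list[str] = []
    species_lines: list[str] = []
    for rec in sorted(records, key=lambda r: r.record_id):
        if rec.lineage.genus:
            header = rec.lineage.truncate("genus").to_header()
            genus_lines += [f">{rec.record_id} {header}", rec.sequence]
        else:
            log.add(rec.record_id, "trim", "kept", "missing genus rank; excluded from training set")
        if is_binomial(rec.lineage.species):
            species_lines += [f">{rec.record_id} {rec.lineage.species}", rec.sequence]
    return genus_lines, species_lines, log
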