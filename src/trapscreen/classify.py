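"""Taxonomic assignment of amplicon sequence variants.

A naive-Bayes word-frequency classifier in the style of the RDP
classifier: 8-base words, Wang-style smoothed genus-conditional word
probabilities, and bootstrap resampling of one eighth of the query's
distinct words to estimate per-rank assignment confidence.  Assignments
are truncated at the lowest rank whose bootstrap support reaches the
minimum (default 80%); queries failing the cutoff at phylum are
unassigned.  Species-level assignment is by exact full-sequence
matching against trimmed references, with congeners that are identical
at a conserved locus reported as an aggregated slash-joined label.

Words are canonicalised (lexicographic minimum of a word and its
reverse complement) so classification is strand-insensitive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import revcomp
from .lineage import RANKS, Lineage
from .refdb import TaxonRecord
from .synth import META_COLS

CLASSIFIER_RANKS = RANKS[:5]  # phylum .. genus


@dataclass(frozen=True)
class ClassifierParams:
    n_bootstrap: int = 100
    bootstrap_fraction: float = 0.125
    min_support: float = 0.80
    min_word_evidence: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.bootstrap_fraction <= 1:
            raise ValueError("bootstrap_fraction must lie in (0, 1]")
        if not 0 <= self.min_support <= 1:
            raise ValueError("min_support must lie in [0, 1]")
        if not 0 <= self.min_word_evidence <= 1:
            raise ValueError("min_word_evidence must lie in [0, 1]")


def canonical_words(seq: str, k: int) -> list[str]:
    """Sorted distinct canonical k-mers (ACGT windows only)."""
    s = seq.upper()
    words = set()
    for i in range(len(s) - k + 1):
        w = s[i : i + k]
        if set(w) <= set("ACGT"):
            words.add(min(w, revcomp(w)))
    return sorted(words)


@dataclass
class ClassifierModel:
    """Trained word-frequency model for one locus."""

    locus: str
    k: int
    genera: list[str]  # alphabetical
    genus_lineages: dict[str, tuple[str, ...]]  # genus -> labels phylum..genus
    word_index: dict[str, int]
    cond_log: np.ndarray = field(repr=False)  # (G, W) log genus-conditional probs
    unknown_log: np.ndarray = field(repr=False)  # (G,) log prob of an unseen word
    n_train: int = 0


def train(records: list[TaxonRecord], k: int = 8) -> ClassifierModel:
    """Fit Wang-style smoothed word probabilities from curated references.

    Word prior P_i = (n(w_i)+0.5)/(N+1) over N training sequences;
    genus-conditional probability (m(w_i)+P_i)/(M+1) for m occurrences
    among a genus's M sequences.  Presence is per distinct word per
    sequence.
    """
    usable = [r for r in records if r.lineage.genus]
    if not usable:
        raise ValueError("training requires at least one record with a genus rank")
    loci = {r.locus for r in usable}
    if len(loci) > 1:
        raise ValueError(f"one model per locus; got {sorted(loci)}")
    genera = sorted({r.lineage.genus for r in usable})
    genus_lineages: dict[str, tuple[str, ...]] = {}
    seq_words: list[tuple[str, list[str]]] = []
    for r in sorted(usable, key=lambda r: r.record_id):
        genus_lineages.setdefault(r.lineage.genus, r.lineage.truncate("genus").names)
        seq_words.append((r.lineage.genus, canonical_words(r.sequence, k)))
    vocab = sorted({w for _, ws in seq_words for w in ws})
    word_index = {w: i for i, w in enumerate(vocab)}
    N = len(seq_words)
    n_w = np.zeros(len(vocab))
    m = np.zeros((len(genera), len(vocab)))
    M = np.zeros(len(genera))
    g_idx = {g: i for i, g in enumerate(genera)}
    for genus, ws in seq_words:
        gi = g_idx[genus]
        M[gi] += 1
        for w in ws:
            wi = word_index[w]
            n_w[wi] += 1
            m[gi, wi] += 1
    prior = (n_w + 0.5) / (N + 1)
    cond = (m + prior[None, :]) / (M[:, None] + 1)
    unseen_prior = 0.5 / (N + 1)
    unknown = unseen_prior / (M + 1)
    return ClassifierModel(
        locus=next(iter(loci)), k=k, genera=genera, genus_lineages=genus_lineages,
        word_index=word_index, cond_log=np.log(cond), unknown_log=np.log(unknown),
        n_train=N,
    )


@dataclass
class Assignment:
    labels: dict[str, str]  # rank -> label, phylum..genus
    supports: dict[str, float]  # rank -> bootstrap support
    assigned_rank: str | None  # lowest supported rank, None if unassigned
    species_label: str | None = None

    @property
    def taxon_label(self) -> str | None:
        """Display label at the lowest confident rank (species wins when matched)."""
        if self.species_label:
            return self.species_label
        if self.assigned_rank is None:
            return None
        label = self.labels[self.assigned_rank]
        return f"{label} spp." if self.assigned_rank == "genus" else label


def truncate_at_support(
    labels: dict[str, str], supports: dict[str, float], min_support: float
) -> str | None:
    """Lowest rank r with support >= min_support at r and every higher rank."""
    assigned = None
    for rank in CLASSIFIER_RANKS:
        if supports.get(rank, 0.0) >= min_support:
            assigned = rank
        else:
            break
    return assigned


def word_log_likelihoods(model: ClassifierModel, words: list[str]) -> np.ndarray:
    """(G, W) per-word genus log-likelihood matrix for a query's word list."""
    L = np.empty((len(model.genera), len(words)))
    for j, w in enumerate(words):
        i = model.word_index.get(w)
        L[:, j] = model.cond_log[:, i] if i is not None else model.unknown_log
    return L


def classify_sequence(
    model: ClassifierModel, query: str, params: ClassifierParams,
    rng: np.random.Generator | None = None,
) -> Assignment:
    """Genus-level naive-Bayes call with bootstrap per-rank support.

    The winning genus maximises the summed log conditional probability
    of the query's distinct canonical words (alphabetical tie-break).
    Each bootstrap draw resamples ceil(W * bootstrap_fraction) words
    with replacement; per-rank support is the fraction of draws whose
    winner agrees with the overall winner at that rank.

    Queries sharing almost no words with the training vocabulary
    (fraction below ``min_word_evidence``) carry no usable signal — a
    deterministic tie-break would otherwise hand them spuriously
    confident calls — and are returned unassigned, which also serves as
    the out-of-scope-phylum exclusion for sequences foreign to the
    training set's coverage.
    """
    if len(query) < model.k:
        raise ValueError(f"query shorter than word size {model.k}")
    words = canonical_words(query, model.k)
    if not words:
        return Assignment({}, {}, None)
    known = sum(1 for w in words if w in model.word_index)
    if known / len(words) < params.min_word_evidence:
        return Assignment({}, {}, None)
    L = word_log_likelihoods(model, words)
    best = int(np.argmax(L.sum(axis=1)))  # first max = alphabetical tie-break
    best_lineage = model.genus_lineages[model.genera[best]]
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    d = math.ceil(len(words) * params.bootstrap_fraction)
    idx = rng.integers(0, len(words), size=(params.n_bootstrap, d))
    draw_scores = L[:, idx].sum(axis=2)  # (G, n_bootstrap)
    winners = np.argmax(draw_scores, axis=0)
    labels = dict(zip(CLASSIFIER_RANKS, best_lineage))
    supports = {}
    for ri, rank in enumerate(CLASSIFIER_RANKS):
        agree = np.fromiter(
            (model.genus_lineages[model.genera[w]][ri] == best_lineage[ri] for w in winners),
            dtype=bool, count=len(winners),
        )
        supports[rank] = float(agree.mean())
    assigned = truncate_at_support(labels, supports, params.min_support)
    return Assignment(labels, supports, assigned)


def assign_species_exact(query: str, species_records: list[TaxonRecord]) -> str | None:
    """Exact full-sequence species match, strand-insensitive.

    One matching species returns its binomial; several distinct species
    (conserved-locus congeners) return an aggregated label — shared
    genus as ``Genus a/b`` with epithets sorted, otherwise sorted full
    binomials slash-joined.  No match returns None.
    """
    q = query.upper()
    qrc = revcomp(q)
    hits = sorted({
        r.lineage.species for r in species_records
        if r.lineage.species and r.sequence.upper() in (q, qrc)
    })
    if not hits:
        return None
    if len(hits) == 1:
        return hits[0]
    genera = {h.split()[0] for h in hits}
    if len(genera) == 1:
        epithets = sorted(h.split(maxsplit=1)[1] for h in hits)
        return f"{genera.pop()} {'/'.join(epithets)}"
    return "/".join(hits)


def classify_table(
    asv_table: pd.DataFrame,
    models: dict[str, ClassifierModel],
    species_records: dict[str, list[TaxonRecord]],
    params: ClassifierParams,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annotate an ASV table with assignments; drop phylum-unassigned ASVs.

    Returns the annotated table (lineage labels, supports, species and
    display labels appended) and a per-locus per-rank assignment-count
    report.  One RNG seeded from ``params.rng_seed`` drives all
    bootstrap draws, in table row order.
    """
    missing = sorted(set(asv_table["locus"]) - set(models))
    if missing:
        raise ValueError(f"no classifier model for loci: {missing}")
    rng = np.random.default_rng(params.rng_seed)
    rows = []
    report_counts: dict[tuple[str, str], int] = {}
    for _, row in asv_table.iterrows():
        locus = row["locus"]
        asn = classify_sequence(models[locus], row["sequence"], params, rng=rng)
        if asn.assigned_rank is not None:
            asn.species_label = assign_species_exact(
                row["sequence"], species_records.get(locus, [])
            )
        lowest = "species" if asn.species_label else asn.assigned_rank
        if lowest is not None:
            report_counts[(locus, lowest)] = report_counts.get((locus, lowest), 0) + 1
        else:
            report_counts[(locus, "unassigned")] = report_counts.get((locus, "unassigned"), 0) + 1
        annotated = dict(row)
        for rank in CLASSIFIER_RANKS:
            annotated[rank] = asn.labels.get(rank)
            annotated[f"support_{rank}"] = asn.supports.get(rank)
        annotated["assigned_rank"] = lowest
        annotated["species_label"] = asn.species_label
        annotated["taxon_label"] = asn.taxon_label
        rows.append(annotated)
    annotated_df = pd.DataFrame(rows)
    keep = annotated_df["assigned_rank"].notna()
    annotated_df = annotated_df[keep].reset_index(drop=True)
    report = pd.DataFrame(
        [(locus, rank, n) for (locus, rank), n in sorted(report_counts.items())],
        columns=["locus", "rank", "n_asvs"],
    )
    return annotated_df, report
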