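"""Synthetic trap-catch simulator.

Generates every input the detection pipeline consumes, with the
statistical structure the analysis assumes:

* multi-locus reference sets with hierarchical divergence — within-genus
  differences strictly smaller than between-genus differences, including
  a conserved-locus mode (within-genus divergence 0) in which congeners
  share an identical template, as happens for slowly evolving rRNA loci;
* reference databases with planted curation defects (duplicates,
  out-of-range lengths, "sp." labels, cross-phylum mislabels, symbiont
  contaminants) and a manifest naming each planted record;
* mock communities of 100–1000 individuals with rare target species,
  read counts drawn multinomially with per-species per-locus
  amplification bias;
* index switching: each read's i5 and i7 are independently replaced
  with probability s by a uniform draw from the in-use pool, under
  combinatorial or unique-dual indexing.

One amplicon sequence variant per species per locus: sequencing error
and intraspecific variation are not simulated — the pipeline starts
post-denoising.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .lineage import Lineage
from .refdb import TaxonRecord

META_COLS = ["asv_id", "locus", "sequence"]
BASES = np.array(list("ACGT"))


def _sub_rng(seed: int, *tags: str | int) -> np.random.Generator:
    """Independent child RNG, stable across runs and platforms."""
    key = [seed] + [zlib.crc32(str(t).encode()) for t in tags]
    return np.random.default_rng(np.random.SeedSequence(key))


def _alpha(i: int) -> str:
    """0 -> 'a', 1 -> 'b', ..., 26 -> 'aa': alphabetic index suffix."""
    out = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        out = chr(ord("a") + rem) + out
    return out


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def _mutate(rng: np.random.Generator, seq: str, positions: np.ndarray) -> str:
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusSpec:
    """Template length and divergence structure for one locus."""

    length: int
    within_divergence: float
    between_divergence: float

    def __post_init__(self) -> None:
        for v in (self.within_divergence, self.between_divergence):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"divergence must lie in [0, 1], got {v}")
        if self.between_divergence <= self.within_divergence:
            raise ValueError("between-genus divergence must exceed within-genus divergence")
        if self.length < 1:
            raise ValueError("locus length must be positive")


@dataclass(frozen=True)
class SpeciesProfile:
    species_name: str
    lineage: Lineage
    templates: dict[str, str]  # locus -> template sequence
    bias: dict[str, float]  # locus -> amplification efficiency factor

    def __post_init__(self) -> None:
        for locus, t in self.templates.items():
            if not t or set(t) - set("ACGT"):
                raise ValueError(f"{self.species_name}/{locus}: template must be non-empty ACGT")
        for locus, b in self.bias.items():
            if not np.isfinite(b) or b < 0:
                raise ValueError(f"{self.species_name}/{locus}: bias must be finite and >= 0")


@dataclass(frozen=True)
class MockCommunityDesign:
    pool_id: str
    counts: dict[str, int]  # species_name -> individuals

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("specimen counts must be >= 0")
        if self.size <= 0:
            raise ValueError("pool must contain at least one specimen")

    @property
    def size(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    reads_per_library: int
    locus_share: dict[str, float]
    switch_rate_s: float
    indexing_mode: str  # "combinatorial" | "unique_dual"
    i5_values: tuple[str, ...]
    i7_values: tuple[str, ...]
    sample_index_map: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        if not 0.0 <= self.switch_rate_s <= 1.0:
            raise ValueError("switch_rate_s must lie in [0, 1]")
        if abs(sum(self.locus_share.values()) - 1.0) > 1e-9:
            raise ValueError("locus_share must sum to 1")
        if self.indexing_mode not in ("combinatorial", "unique_dual"):
            raise ValueError(f"unknown indexing_mode {self.indexing_mode!r}")
        pairs = list(self.sample_index_map.values())
        if len(set(pairs)) != len(pairs):
            raise ValueError("sample index pairs must be distinct")
        for i5, i7 in pairs:
            if i5 not in self.i5_values or i7 not in self.i7_values:
                raise ValueError(f"index pair ({i5}, {i7}) outside declared pools")
        if self.indexing_mode == "unique_dual":
            i5s = [p[0] for p in pairs]
            i7s = [p[1] for p in pairs]
            if len(set(i5s)) != len(i5s) or len(set(i7s)) != len(i7s):
                raise ValueError("unique_dual mode forbids reusing any i5 or i7 across samples")

    @property
    def valid_pairs(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.sample_index_map.values())


@dataclass(frozen=True)
class PlantingSpec:
    n_duplicates: int = 0
    n_short: int = 0
    n_long: int = 0
    n_unidentified: int = 0
    n_mislabelled: int = 0
    n_contaminant: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.__dict__.values()):
            raise ValueError("planting counts must be >= 0")

    def total(self) -> int:
        return sum(self.__dict__.values())


# ---------------------------------------------------------------------------
# Species profiles
# ---------------------------------------------------------------------------

def generate_species_profiles(
    n_genera: int,
    n_species_per_genus: int,
    locus_specs: dict[str, LocusSpec],
    seed: int,
    phyla: tuple[str, ...] = ("Arthropoda",),
    bias_log2_sd: float = 0.0,
) -> list[SpeciesProfile]:
    """Species with hierarchical template divergence, one genus per family.

    Per locus, mutations away from a shared root sequence are placed on
    disjoint position blocks: each genus mutates round(between*L)
    dedicated positions and each species a further round(within*L), so
    every within-genus pairwise identity strictly exceeds every
    between-genus identity, and within-genus divergence 0 yields
    byte-identical congeneric templates.
    """
    if n_genera < 1 or n_species_per_genus < 1:
        raise ValueError("need at least one genus and one species per genus")
    roots: dict[str, str] = {}
    blocks: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for locus, spec in locus_specs.items():
        rng = _sub_rng(seed, "root", locus)
        nb = round(spec.between_divergence * spec.length)
        nw = round(spec.within_divergence * spec.length)
        need = n_genera * nb + n_genera * n_species_per_genus * nw
        if need > spec.length:
            raise ValueError(f"{locus}: length {spec.length} too short for requested divergence")
        roots[locus] = _random_seq(rng, spec.length)
        perm = rng.permutation(spec.length)
        gpos = perm[: n_genera * nb].reshape(n_genera, nb)
        if nw > 0:
            spos = perm[n_genera * nb : need].reshape(n_genera * n_species_per_genus, nw)
        else:
            spos = np.empty((n_genera * n_species_per_genus, 0), dtype=int)
        blocks[locus] = (gpos, spos)

    profiles: list[SpeciesProfile] = []
    for g in range(n_genera):
        genus = f"Genus{_alpha(g)}"
        phylum = phyla[g % len(phyla)]
        lineage_head = (
            phylum,
            f"Class{_alpha(phyla.index(phylum))}",
            f"Order{_alpha(g)}",
            f"Family{_alpha(g)}",
            genus,
        )
        genus_templates = {}
        for locus, spec in locus_specs.items():
            rng = _sub_rng(seed, "genus", locus, g)
            gpos, _ = blocks[locus]
            genus_templates[locus] = _mutate(rng, roots[locus], gpos[g])
        for s in range(n_species_per_genus):
            species = f"{genus} {_alpha(s)}species"
            templates = {}
            bias = {}
            for locus, spec in locus_specs.items():
                rng = _sub_rng(seed, "species", locus, g, s)
                _, spos = blocks[locus]
                row = g * n_species_per_genus + s
                templates[locus] = _mutate(rng, genus_templates[locus], spos[row])
                brng = _sub_rng(seed, "bias", locus, g, s)
                bias[locus] = float(2.0 ** brng.normal(0.0, bias_log2_sd)) if bias_log2_sd > 0 else 1.0
            profiles.append(
                SpeciesProfile(species, Lineage(lineage_head + (species,)), templates, bias)
            )
    return profiles


# ---------------------------------------------------------------------------
# Reference database with planted defects
# ---------------------------------------------------------------------------

def make_contaminant_set(n: int, length: int, seed: int) -> list[TaxonRecord]:
    """Synthetic symbiont-like contaminant panel (not real *Wolbachia*)."""
    rng = _sub_rng(seed, "contaminant")
    panel = []
    for i in range(n):
        panel.append(
            TaxonRecord(
                record_id=f"CONTAM{i + 1:02d}",
                locus="COI",
                sequence=_random_seq(rng, length),
                lineage=Lineage(("Proteobacteria", "Alphaproteobacteria", "Rickettsiales",
                                 "Anaplasmataceae", "Symbiontella", f"Symbiontella ficta{i + 1}")),
                source="contaminant",
                raw_label=f"Symbiontella ficta{i + 1}",
            )
        )
    return panel


def generate_reference_database(
    profiles: list[SpeciesProfile],
    planting: PlantingSpec,
    seed: int,
    contaminant_records: list[TaxonRecord] | None = None,
) -> tuple[list[TaxonRecord], list[tuple[str, str]], list[TaxonRecord]]:
    """Clean per-species per-locus records plus planted curation defects.

    Returns ``(records, manifest, contaminant_panel)`` where the
    manifest lists ``(record_id, defect_class)`` for every planted
    record.  Planted ids sort after the clean ``REF``-prefixed ids so
    deduplication keeps the clean twin.
    """
    if not profiles:
        raise ValueError("profiles must be non-empty")
    rng = _sub_rng(seed, "refdb")
    records: list[TaxonRecord] = []
    i = 0
    for prof in profiles:
        for locus, template in sorted(prof.templates.items()):
            i += 1
            records.append(
                TaxonRecord(f"REF{i:04d}", locus, template, prof.lineage,
                            source="public", raw_label=prof.species_name)
            )
    clean = list(records)
    manifest: list[tuple[str, str]] = []

    def plant(rec: TaxonRecord, defect: str) -> None:
        records.append(rec)
        manifest.append((rec.record_id, defect))

    if planting.n_duplicates > len(clean):
        raise ValueError("cannot plant more duplicates than clean records")
    for j, src in enumerate(rng.choice(len(clean), size=planting.n_duplicates, replace=False)):
        c = clean[int(src)]
        plant(TaxonRecord(f"ZDUP{j + 1:02d}", c.locus, c.sequence, c.lineage,
                          source="public", raw_label=c.raw_label), "duplicate")

    for j in range(planting.n_short):
        c = clean[int(rng.integers(len(clean)))]
        plant(TaxonRecord(f"ZSHORT{j + 1:02d}", c.locus,
                          _random_seq(rng, int(rng.integers(60, 180))),
                          c.lineage, source="public", raw_label=c.raw_label), "short")
    for j in range(planting.n_long):
        c = clean[int(rng.integers(len(clean)))]
        plant(TaxonRecord(f"ZLONG{j + 1:02d}", c.locus,
                          _random_seq(rng, int(rng.integers(3001, 3400))),
                          c.lineage, source="public", raw_label=c.raw_label), "long")

    if planting.n_unidentified > len(clean):
        raise ValueError("cannot plant more 'sp.' records than clean records")
    for j, src in enumerate(rng.choice(len(clean), size=planting.n_unidentified, replace=False)):
        c = clean[int(src)]
        genus = c.lineage.genus or "Incertus"
        npos = max(1, len(c.sequence) // 100)
        seq = _mutate(rng, c.sequence, rng.choice(len(c.sequence), size=npos, replace=False))
        plant(TaxonRecord(f"ZSP{j + 1:02d}", c.locus, seq,
                          Lineage(c.lineage.names[:5] + (f"{genus} sp.",)),
                          source="public", raw_label=f"{genus} sp."), "unidentified")

    if planting.n_mislabelled:
        phyla = sorted({p.lineage.phylum for p in profiles})
        if len(phyla) < 2:
            raise ValueError("mislabel planting needs profiles from >= 2 phyla")
        candidates = [c for c in clean if len(c.sequence) >= 200 + 1]
        picks = rng.choice(len(candidates), size=planting.n_mislabelled, replace=False)
        for j, src in enumerate(picks):
            c = candidates[int(src)]
            # one substitution, one trailing base dropped: identity >= 99%
            # against the clean twin but shorter, so the twin founds the cluster
            seq = _mutate(rng, c.sequence, np.array([int(rng.integers(len(c.sequence)))]))[:-1]
            other = [p for p in profiles if p.lineage.phylum != c.lineage.phylum]
            donor = other[int(rng.integers(len(other)))]
            plant(TaxonRecord(f"ZMIS{j + 1:02d}", c.locus, seq, donor.lineage,
                              source="public", raw_label=donor.species_name), "mislabelled")

    panel = contaminant_records if contaminant_records is not None else (
        make_contaminant_set(3, 400, seed) if planting.n_contaminant else []
    )
    for j in range(planting.n_contaminant):
        t = panel[int(rng.integers(len(panel)))]
        npos = max(1, round(0.02 * len(t.sequence)))
        seq = _mutate(rng, t.sequence, rng.choice(len(t.sequence), size=npos, replace=False))
        c = clean[int(rng.integers(len(clean)))]
        plant(TaxonRecord(f"ZCONT{j + 1:02d}", c.locus, seq, c.lineage,
                          source="public", raw_label=c.raw_label), "contaminant")

    return records, manifest, panel


# ---------------------------------------------------------------------------
# Mock communities and libraries
# ---------------------------------------------------------------------------

def generate_mock_designs(
    profiles: list[SpeciesProfile],
    sizes: tuple[int, ...] = (100, 250, 500, 1000),
    rare_species: str | None = None,
) -> list[MockCommunityDesign]:
    """One pool per size; the rare target species gets exactly 1 specimen.

    The remaining specimens are split as evenly as possible across the
    other species (earlier species absorb the remainder).
    """
    names = [p.species_name for p in profiles]
    rare = rare_species if rare_species is not None else names[-1]
    if rare not in names:
        raise ValueError(f"rare species {rare!r} has no profile")
    others = [n for n in names if n != rare]
    designs = []
    for size in sizes:
        remaining = size - 1
        base, extra = divmod(remaining, len(others))
        counts = {n: base + (1 if k < extra else 0) for k, n in enumerate(others)}
        counts[rare] = 1
        designs.append(MockCommunityDesign(f"Pool{size}", counts))
    return designs


def simulate_library(
    design: MockCommunityDesign,
    profiles: list[SpeciesProfile],
    config: SimulationConfig,
) -> pd.DataFrame:
    """Multinomial read counts for one library, one column per the pool id.

    Reads are first split across loci by ``locus_share``, then within a
    locus across species with probability proportional to specimen
    count x amplification bias.  Species lacking a template at a locus
    contribute nothing there (warned once per species/locus).
    """
    by_name = {p.species_name: p for p in profiles}
    missing = sorted(set(design.counts) - set(by_name))
    if missing:
        raise ValueError(f"no profile for design species: {missing}")
    rng = _sub_rng(config.seed, "library", design.pool_id)
    loci = sorted(config.locus_share)
    locus_reads = rng.multinomial(config.reads_per_library,
                                  [config.locus_share[l] for l in loci])
    rows = []
    for locus, n_reads in zip(loci, locus_reads):
        species, weights = [], []
        for name, count in sorted(design.counts.items()):
            prof = by_name[name]
            if locus not in prof.templates:
                if count > 0:
                    warnings.warn(f"{name} has no {locus} template; 0 reads at this locus")
                continue
            species.append(prof)
            weights.append(count * prof.bias.get(locus, 1.0))
        weights = np.asarray(weights, dtype=float)
        if weights.sum() <= 0:
            counts = np.zeros(len(species), dtype=int)
        else:
            counts = rng.multinomial(n_reads, weights / weights.sum())
        for prof, c in zip(species, counts):
            rows.append({
                "asv_id": f"{locus}:{prof.species_name.replace(' ', '_')}",
                "locus": locus,
                "sequence": prof.templates[locus],
                design.pool_id: int(c),
            })
    return pd.DataFrame(rows, columns=META_COLS + [design.pool_id])


def merge_libraries(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Outer-join single-library tables on ASV identity; absent counts are 0."""
    merged = tables[0]
    for t in tables[1:]:
        merged = merged.merge(t, on=META_COLS, how="outer")
    sample_cols = [c for c in merged.columns if c not in META_COLS]
    merged[sample_cols] = merged[sample_cols].fillna(0).astype(int)
    return merged.sort_values("asv_id", ignore_index=True)


# ---------------------------------------------------------------------------
# Index switching
# ---------------------------------------------------------------------------

def _destination_grid(config: SimulationConfig, pair: tuple[str, str]) -> np.ndarray:
    """P(read of a sample lands on cell (x, y)) under independent-end switching."""
    s = config.switch_rate_s
    n5, n7 = len(config.i5_values), len(config.i7_values)
    p5 = np.full(n5, s / n5)
    p5[config.i5_values.index(pair[0])] += 1.0 - s
    p7 = np.full(n7, s / n7)
    p7[config.i7_values.index(pair[1])] += 1.0 - s
    return np.outer(p5, p7)


def expected_invalid_fraction(config: SimulationConfig,
                              sample_weights: dict[str, float] | None = None) -> float:
    """Closed-form expected fraction of reads landing on invalid index pairs."""
    valid = config.valid_pairs
    cells = [(i, j) for i in range(len(config.i5_values)) for j in range(len(config.i7_values))]
    invalid_mask = np.array([
        (config.i5_values[i], config.i7_values[j]) not in valid for i, j in cells
    ]).reshape(len(config.i5_values), len(config.i7_values))
    samples = list(config.sample_index_map)
    if sample_weights is None:
        w = {smp: 1.0 / len(samples) for smp in samples}
    else:
        tot = sum(sample_weights.values())
        w = {smp: sample_weights[smp] / tot for smp in samples}
    return float(sum(
        w[smp] * _destination_grid(config, pair)[invalid_mask].sum()
        for smp, pair in config.sample_index_map.items()
    ))


def switch_rate_for_contamination(target_invalid_fraction: float,
                                  config: SimulationConfig) -> float:
    """Per-end switch rate s whose expected invalid-pair fraction equals the target."""
    from dataclasses import replace as _dc_replace

    def f(s: float) -> float:
        return expected_invalid_fraction(_dc_replace(config, switch_rate_s=s)) - target_invalid_fraction

    if target_invalid_fraction <= 0:
        return 0.0
    return float(brentq(f, 0.0, 1.0, xtol=1e-12))


def simulate_index_switching(
    libraries: pd.DataFrame,
    config: SimulationConfig,
) -> tuple["pd.DataFrame", pd.DataFrame, dict[str, int]]:
    """Apply per-read independent-end index switching to a multi-sample table.

    Returns ``(index_pair_counts, contaminated_table, totals)``:
    a long-format (i5, i7, reads) frame over the full index grid, the
    per-sample ASV table after cross-contamination (reads landing on
    another sample's valid pair move there; invalid pairs become
    undetermined), and totals proving read conservation.
    """
    samples = [c for c in libraries.columns if c not in META_COLS]
    unknown = sorted(set(samples) - set(config.sample_index_map))
    if unknown:
        raise ValueError(f"samples without index assignment: {unknown}")
    rng = _sub_rng(config.seed, "switch")
    n5, n7 = len(config.i5_values), len(config.i7_values)
    grid_totals = np.zeros((n5, n7), dtype=np.int64)
    pair_owner = {pair: smp for smp, pair in config.sample_index_map.items()}
    out_counts = {smp: np.zeros(len(libraries), dtype=np.int64) for smp in samples}
    undetermined = 0
    generated = 0
    for smp in samples:
        probs = _destination_grid(config, config.sample_index_map[smp]).ravel()
        col = libraries[smp].to_numpy()
        for row_idx in np.nonzero(col)[0]:
            n = int(col[row_idx])
            generated += n
            dest = rng.multinomial(n, probs).reshape(n5, n7)
            grid_totals += dest
            for (i, j) in zip(*np.nonzero(dest)):
                pair = (config.i5_values[i], config.i7_values[j])
                c = int(dest[i, j])
                owner = pair_owner.get(pair)
                if owner is None:
                    undetermined += c
                else:
                    out_counts[owner][row_idx] += c
    contaminated = libraries[META_COLS].copy()
    for smp in samples:
        contaminated[smp] = out_counts[smp]
    pairs = pd.DataFrame(
        [(config.i5_values[i], config.i7_values[j], int(grid_totals[i, j]))
         for i in range(n5) for j in range(n7)],
        columns=["i5", "i7", "reads"],
    )
    assigned = int(sum(arr.sum() for arr in out_counts.values()))
    totals = {"generated": generated, "assigned": assigned, "undetermined": undetermined}
    assert assigned + undetermined == generated
    return pairs, contaminated, totals


# ---------------------------------------------------------------------------
# Optional FASTQ emitter (exercises the qc module only)
# ---------------------------------------------------------------------------

def emit_fastq(table: pd.DataFrame, sample: str, primers=None, quality_char: str = "D") -> list[str]:
    """FASTQ lines for one sample at uniform Q35; primers re-attached if given."""
    from .align import revcomp

    lines = []
    k = 0
    for _, row in table.iterrows():
        n = int(row[sample])
        seq = row["sequence"]
        if primers is not None and row["locus"] in primers:
            p = primers[row["locus"]]
            seq = p.forward + seq + revcomp(p.reverse)
        for _ in range(n):
            k += 1
            lines += [f"@{sample}_read{k} {row['asv_id']}", seq, "+", quality_char * len(seq)]
    return lines
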