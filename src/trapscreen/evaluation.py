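"""Desk-scale evaluation experiments for the pipeline.

The study this pipeline targets benchmarks detection on real MiSeq runs
of mock insect communities; those read sets are not reproducible at
desk scale.  The experiments here are the property-level substitutes:
each runs the full relevant code path on simulator output and measures
a recovery or contrast statistic with known expectations.

All experiments are deterministic given their base seed and derive
per-replicate RNG streams from it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import classify as _classify
from . import contam as _contam
from . import detect as _detect
from . import refdb as _refdb
from . import synth as _synth
from .synth import LocusSpec, MockCommunityDesign, SimulationConfig

THREE_LOCI = {
    "COI": LocusSpec(length=300, within_divergence=0.02, between_divergence=0.10),
    "12S": LocusSpec(length=250, within_divergence=0.02, between_divergence=0.10),
    "18S": LocusSpec(length=280, within_divergence=0.0, between_divergence=0.05),
}


def _unique_dual(samples, seed, reads, s, loci=("COI",)):
    share = dict.fromkeys(loci, 1.0 / len(loci))
    share[loci[0]] += 1.0 - sum(share.values())
    i5 = tuple(f"i5-{k:02d}" for k in range(len(samples)))
    i7 = tuple(f"i7-{k:02d}" for k in range(len(samples)))
    return SimulationConfig(
        seed=seed, reads_per_library=reads, locus_share=share, switch_rate_s=s,
        indexing_mode="unique_dual", i5_values=i5, i7_values=i7,
        sample_index_map={smp: (i5[k], i7[k]) for k, smp in enumerate(samples)},
    )


def _combinatorial(samples, seed, reads, s, loci=("COI",)):
    if len(samples) > 4:
        raise ValueError("saturated 2x2 combinatorial grid supports four samples")
    share = dict.fromkeys(loci, 1.0 / len(loci))
    share[loci[0]] += 1.0 - sum(share.values())
    i5, i7 = ("i5-a", "i5-b"), ("i7-a", "i7-b")
    combos = [(a, b) for a in i5 for b in i7]
    return SimulationConfig(
        seed=seed, reads_per_library=reads, locus_share=share, switch_rate_s=s,
        indexing_mode="combinatorial", i5_values=i5, i7_values=i7,
        sample_index_map={smp: combos[k] for k, smp in enumerate(samples)},
    )


# ---------------------------------------------------------------------------
# Worked threshold example
# ---------------------------------------------------------------------------

def worked_threshold_example(
    c_target: float = 0.0108, total_reads: int = 1_000_000
) -> _contam.ContaminationStats:
    """Estimate c and t from a unique-dual tally whose invalid fraction is c_target.

    With two libraries on a 2x2 unique-dual grid the estimator's
    correction factor is 1, so the constructed tally recovers exactly
    the requested single-end rate and its squared residual threshold.
    """
    invalid = round(c_target * total_reads)
    counts = _contam.tally_index_pairs(
        {
            ("a5", "a7"): (total_reads - invalid) // 2,
            ("b5", "b7"): total_reads - invalid - (total_reads - invalid) // 2,
            ("a5", "b7"): invalid // 2,
            ("b5", "a7"): invalid - invalid // 2,
        },
        frozenset({("a5", "a7"), ("b5", "b7")}),
    )
    return _contam.estimate_contamination(counts)


# ---------------------------------------------------------------------------
# Estimator recovery
# ---------------------------------------------------------------------------

@dataclass
class RecoveryResult:
    estimates: np.ndarray
    true_c: float
    tolerance: float

    @property
    def fraction_within(self) -> float:
        return float(np.mean(np.abs(self.estimates - self.true_c) <= self.tolerance))


def run_estimator_recovery(
    n_seeds: int = 200,
    reads_total: int = 100_000,
    true_c: float = 0.01,
    tolerance: float = 0.002,
    base_seed: int = 0,
) -> RecoveryResult:
    """Simulate switching at a known rate and re-estimate it from tallies.

    Four unique-dual libraries share ``reads_total`` reads; the per-end
    switch rate is chosen so the expected invalid-pair fraction equals
    ``true_c``.
    """
    samples = ["A", "B", "C", "D"]
    per_lib = reads_total // len(samples)
    base_cfg = _unique_dual(samples, seed=0, reads=per_lib, s=0.0)
    s = _synth.switch_rate_for_contamination(true_c, base_cfg)
    libs = pd.DataFrame({
        "asv_id": ["COI:x"], "locus": ["COI"], "sequence": ["ACGT" * 10],
        **{smp: [per_lib] for smp in samples},
    })
    estimates = []
    for k in range(n_seeds):
        cfg = replace(base_cfg, seed=base_seed + k, switch_rate_s=s)
        pairs, _, _ = _synth.simulate_index_switching(libs, cfg)
        counts = _contam.tally_index_pairs(
            {(r.i5, r.i7): r.reads for r in pairs.itertuples()},
            cfg.valid_pairs, cfg.i5_values, cfg.i7_values,
        )
        estimates.append(_contam.estimate_contamination(counts).c)
    return RecoveryResult(np.asarray(estimates), true_c, tolerance)


# ---------------------------------------------------------------------------
# Combinatorial vs unique-dual contrast
# ---------------------------------------------------------------------------

def cross_sample_false_positive_reads(
    original: pd.DataFrame, contaminated: pd.DataFrame
) -> int:
    """Reads assigned after switching to a sample that generated none of them."""
    samples = [c for c in original.columns if c not in _synth.META_COLS]
    orig = original[samples].to_numpy()
    cont = contaminated[samples].to_numpy()
    return int(cont[orig == 0].sum())


def run_indexing_contrast(
    n_seeds: int = 50,
    reads_per_library: int = 20_000,
    s: float = 0.01,
    base_seed: int = 0,
) -> pd.DataFrame:
    """False-positive read counts under combinatorial vs unique-dual indexing.

    Four pools with pairwise-disjoint species pairs at identical switch
    rate and depth; every cross-sample read is a false positive read.
    """
    profiles = _synth.generate_species_profiles(4, 2, {"COI": THREE_LOCI["COI"]}, seed=1701)
    names = [p.species_name for p in profiles]
    samples = [f"Pool-{k}" for k in range(4)]
    designs = [
        MockCommunityDesign(samples[k], {names[2 * k]: 249, names[2 * k + 1]: 1})
        for k in range(4)
    ]
    rows = []
    for k in range(n_seeds):
        seed = base_seed + k
        counts = {}
        for mode, make in (("combinatorial", _combinatorial), ("unique_dual", _unique_dual)):
            cfg = make(samples, seed=seed, reads=reads_per_library, s=s)
            libs = _synth.merge_libraries(
                [_synth.simulate_library(d, profiles, cfg) for d in designs]
            )
            _, contaminated, _ = _synth.simulate_index_switching(libs, cfg)
            counts[mode] = cross_sample_false_positive_reads(libs, contaminated)
        rows.append({"seed": seed, **counts})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# End-to-end mock-community recovery
# ---------------------------------------------------------------------------

def conserved_locus_aggregation_map(profiles, locus: str = "18S") -> dict[str, str]:
    """Species -> display label, slash-joining congeners identical at ``locus``."""
    by_genus: dict[str, list] = {}
    for p in profiles:
        by_genus.setdefault(p.lineage.genus, []).append(p)
    agg: dict[str, str] = {}
    for genus, members in by_genus.items():
        groups: dict[str, list[str]] = {}
        for p in members:
            groups.setdefault(p.templates.get(locus, p.species_name), []).append(p.species_name)
        for names in groups.values():
            if len(names) > 1:
                epithets = sorted(n.split(maxsplit=1)[1] for n in names)
                label = f"{genus} {'/'.join(epithets)}"
                for n in names:
                    agg[n] = label
    return agg


@dataclass
class MockRecoveryResult:
    per_seed: pd.DataFrame  # seed, all_detected, fp_free, threshold

    @property
    def fraction_seeds_all_detected(self) -> float:
        return float(self.per_seed["all_detected"].mean())

    @property
    def fraction_seeds_fp_free(self) -> float:
        return float(self.per_seed["fp_free"].mean())


def run_mock_recovery(
    n_seeds: int = 20,
    reads_per_library: int = 50_000,
    true_c: float = 0.01,
    base_seed: int = 0,
) -> MockRecoveryResult:
    """Full pipeline on mock pools of 100-1000 individuals with rare targets.

    Unit amplification biases; unique dual indexing at the switch rate
    giving a 1% expected invalid fraction; per-seed threshold t = c_hat²
    estimated from that seed's own index tallies.  Three common species
    anchor every pool; each pool additionally carries one single-specimen
    target species absent from the other pools, so cross-sample switching
    shows up as false positives unless removed by thresholding.
    """
    loci = tuple(THREE_LOCI)
    profiles = _synth.generate_species_profiles(5, 2, THREE_LOCI, seed=4242)
    names = [p.species_name for p in profiles]
    common = [names[0], names[2], names[4]]  # one species of genera a-c
    targets = [names[6], names[7], names[8], names[9]]  # genera d and e
    sizes = [100, 250, 500, 1000]
    designs = []
    for k, size in enumerate(sizes):
        counts = {targets[k]: 1}
        base, extra = divmod(size - 1, len(common))
        for i, n in enumerate(common):
            counts[n] = base + (1 if i < extra else 0)
        designs.append(MockCommunityDesign(f"Pool{size}", counts))
    samples = [d.pool_id for d in designs]
    agg = conserved_locus_aggregation_map(profiles)

    records, _, _ = _synth.generate_reference_database(profiles, _synth.PlantingSpec(), seed=4242)
    models = {
        locus: _classify.train([r for r in records if r.locus == locus]) for locus in loci
    }
    species_records = {locus: [r for r in records if r.locus == locus] for locus in loci}

    base_cfg = _unique_dual(samples, seed=0, reads=reads_per_library, s=0.0, loci=loci)
    s = _synth.switch_rate_for_contamination(true_c, base_cfg)

    rows = []
    for k in range(n_seeds):
        cfg = replace(base_cfg, seed=base_seed + k, switch_rate_s=s)
        libs = _synth.merge_libraries(
            [_synth.simulate_library(d, profiles, cfg) for d in designs]
        )
        pairs, contaminated, _ = _synth.simulate_index_switching(libs, cfg)
        counts = _contam.tally_index_pairs(
            {(r.i5, r.i7): r.reads for r in pairs.itertuples()},
            cfg.valid_pairs, cfg.i5_values, cfg.i7_values,
        )
        stats = _contam.estimate_contamination(counts)
        params = _classify.ClassifierParams(rng_seed=base_seed + k)
        annotated, _ = _classify.classify_table(contaminated, models, species_records, params)
        per_locus = _detect.taxon_abundance_table(annotated)
        combined, _ = _detect.combine_loci(per_locus)
        report = _detect.evaluate_detections(combined, designs, t=stats.t,
                                             aggregation_map=agg)
        rows.append({
            "seed": base_seed + k,
            "all_detected": report.fraction_all_detected == 1.0,
            "fp_free": report.fraction_fp_free == 1.0,
            "threshold": stats.t,
        })
    return MockRecoveryResult(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Curation completeness
# ---------------------------------------------------------------------------

@dataclass
class CurationFixtureResult:
    per_fixture: pd.DataFrame

    @property
    def fraction_defects_removed_by_matching_rule(self) -> float:
        return float(
            self.per_fixture["defects_removed"].sum() / self.per_fixture["defects_planted"].sum()
        )

    @property
    def fraction_clean_retained(self) -> float:
        return float(
            self.per_fixture["clean_kept"].sum() / self.per_fixture["clean_total"].sum()
        )


RULE_FOR_DEFECT = {
    "duplicate": "1", "short": "1", "long": "1",
    "unidentified": "2", "contaminant": "3", "mislabelled": "4",
}


def run_curation_fixtures(n_fixtures: int = 50, base_seed: int = 0) -> CurationFixtureResult:
    """Random planted-defect fixtures through the full cascade.

    Counts, per fixture, the planted defects removed by their matching
    rule and the clean records retained.
    """
    specs = {"COI": THREE_LOCI["COI"], "18S": THREE_LOCI["18S"]}
    params = _refdb.CurationParams()
    rows = []
    for k in range(n_fixtures):
        seed = base_seed + k
        rng = np.random.default_rng(seed)
        profiles = _synth.generate_species_profiles(
            3, 2, specs, seed=seed, phyla=("Arthropoda", "Chordata")
        )
        planting = _synth.PlantingSpec(
            n_duplicates=int(rng.integers(0, 3)),
            n_short=int(rng.integers(0, 3)),
            n_long=int(rng.integers(0, 2)),
            n_unidentified=int(rng.integers(0, 3)),
            n_mislabelled=int(rng.integers(1, 3)),
            n_contaminant=int(rng.integers(1, 3)),
        )
        records, manifest, panel = _synth.generate_reference_database(
            profiles, planting, seed=seed
        )
        kept, log = _refdb.curate(records, params, panel)
        by_rule = {rule: log.removed_ids(rule) for rule in ("1", "2", "3", "4")}
        removed_ok = sum(
            1 for rid, defect in manifest if rid in by_rule[RULE_FOR_DEFECT[defect]]
        )
        clean_ids = {r.record_id for r in records if r.record_id.startswith("REF")}
        rows.append({
            "seed": seed,
            "defects_planted": len(manifest),
            "defects_removed": removed_ok,
            "clean_total": len(clean_ids),
            "clean_kept": len(clean_ids - log.removed_ids()),
        })
    return CurationFixtureResult(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Classifier recovery
# ---------------------------------------------------------------------------

@dataclass
class ClassifierRecoveryResult:
    per_query: pd.DataFrame

    @property
    def fraction_recovered(self) -> float:
        return float(self.per_query["recovered"].mean())


def run_classifier_recovery(
    n_queries: int = 1000,
    divergence: float = 0.03,
    base_seed: int = 0,
) -> ClassifierRecoveryResult:
    """Genus recovery for queries diverged from references.

    Training set: 6 genera x 2 species (2% within, 10% between genera);
    each query mutates a random reference at ``divergence`` of its
    positions.  A query is recovered when the winning genus is its
    source's genus with bootstrap support >= 0.80.
    """
    profiles = _synth.generate_species_profiles(
        6, 2, {"COI": THREE_LOCI["COI"]}, seed=9090
    )
    records, _, _ = _synth.generate_reference_database(profiles, _synth.PlantingSpec(), seed=9090)
    model = _classify.train(records)
    rng = np.random.default_rng(base_seed)
    params = _classify.ClassifierParams(rng_seed=base_seed)
    class_rng = np.random.default_rng(base_seed + 1)
    n_mut = round(divergence * THREE_LOCI["COI"].length)
    rows = []
    for _ in range(n_queries):
        src = profiles[int(rng.integers(len(profiles)))]
        seq = src.templates["COI"]
        positions = rng.choice(len(seq), size=n_mut, replace=False)
        out = list(seq)
        for p in positions:
            out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
        asn = _classify.classify_sequence(model, "".join(out), params, rng=class_rng)
        ok = (
            asn.labels.get("genus") == src.lineage.genus
            and asn.supports.get("genus", 0.0) >= 0.80
        )
        rows.append({"genus": src.lineage.genus, "recovered": ok,
                     "support": asn.supports.get("genus", 0.0)})
    return ClassifierRecoveryResult(pd.DataFrame(rows))


def identical_query_supports(base_seed: int = 0) -> list[float]:
    """Genus bootstrap support for queries equal to training references."""
    profiles = _synth.generate_species_profiles(
        6, 2, {"COI": THREE_LOCI["COI"]}, seed=9090
    )
    records, _, _ = _synth.generate_reference_database(profiles, _synth.PlantingSpec(), seed=9090)
    model = _classify.train(records)
    params = _classify.ClassifierParams(rng_seed=base_seed)
    supports = []
    for p in profiles:
        asn = _classify.classify_sequence(model, p.templates["COI"], params)
        assert asn.labels["genus"] == p.lineage.genus
        supports.append(asn.supports["genus"])
    return supports
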