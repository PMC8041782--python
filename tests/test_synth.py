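"""Synthetic-data generator: divergence structure, abundance model, switching."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from trapscreen.align import global_identity
from trapscreen.synth import (
    LocusSpec,
    MockCommunityDesign,
    PlantingSpec,
    SimulationConfig,
    generate_mock_designs,
    generate_reference_database,
    generate_species_profiles,
    merge_libraries,
    simulate_index_switching,
    simulate_library,
    switch_rate_for_contamination,
    expected_invalid_fraction,
)

from conftest import THREE_LOCI, unique_dual_config


# --- species profiles ------------------------------------------------------

class TestSpeciesProfiles:
    def test_conserved_locus_yields_identical_congeners(self, profiles):
        by_genus = {}
        for p in profiles:
            by_genus.setdefault(p.lineage.genus, []).append(p)
        for members in by_genus.values():
            seqs = {p.templates["18S"] for p in members}
            assert len(seqs) == 1

    def test_determinism_same_seed_byte_identical(self, locus_specs):
        a = generate_species_profiles(2, 2, locus_specs, seed=7)
        b = generate_species_profiles(2, 2, locus_specs, seed=7)
        assert a == b
        c = generate_species_profiles(2, 2, locus_specs, seed=8)
        assert a != c

    def test_within_genus_identity_exceeds_between_genus(self, profiles):
        """Brute-force pairwise identity over all template pairs."""
        for locus in ("COI", "12S"):
            within, between = [], []
            for i, p in enumerate(profiles):
                for q in profiles[i + 1 :]:
                    ident = global_identity(p.templates[locus], q.templates[locus])
                    (within if p.lineage.genus == q.lineage.genus else between).append(ident)
            assert min(within) > max(between)

    def test_invalid_divergence_rejected(self):
        with pytest.raises(ValueError):
            LocusSpec(300, within_divergence=-0.1, between_divergence=0.1)
        with pytest.raises(ValueError):
            LocusSpec(300, within_divergence=0.2, between_divergence=1.4)
        with pytest.raises(ValueError):
            LocusSpec(300, within_divergence=0.2, between_divergence=0.1)

    def test_length_too_short_for_divergence_rejected(self):
        specs = {"COI": LocusSpec(20, 0.2, 0.4)}
        with pytest.raises(ValueError, match="too short"):
            generate_species_profiles(5, 5, specs, seed=0)


# --- reference database planting ------------------------------------------

class TestReferencePlanting:
    def test_zero_planting_gives_clean_records_only(self, profiles):
        records, manifest, _ = generate_reference_database(profiles, PlantingSpec(), seed=3)
        assert manifest == []
        assert len(records) == len(profiles) * len(THREE_LOCI)
        assert all(r.record_id.startswith("REF") for r in records)

    def test_planted_short_record_present_and_listed(self, profiles):
        records, manifest, _ = generate_reference_database(
            profiles, PlantingSpec(n_short=1), seed=3
        )
        shorts = [r for r in records if len(r.sequence) < 200]
        assert len(shorts) == 1
        assert manifest == [(shorts[0].record_id, "short")]

    def test_mislabelled_records_cluster_with_other_phylum(self, profiles):
        """All-pairs identity: each planted mislabel is >=99% identical to a
        clean record whose lineage names a different phylum."""
        records, manifest, _ = generate_reference_database(
            profiles, PlantingSpec(n_mislabelled=2), seed=5
        )
        clean = [r for r in records if r.record_id.startswith("REF")]
        for rid, defect in manifest:
            assert defect == "mislabelled"
            rec = next(r for r in records if r.record_id == rid)
            partners = [
                c for c in clean
                if c.locus == rec.locus
                and global_identity(rec.sequence, c.sequence) >= 0.99
            ]
            assert partners
            assert all(c.lineage.phylum != rec.lineage.phylum for c in partners)

    def test_mislabel_planting_needs_two_phyla(self, arthropod_profiles):
        with pytest.raises(ValueError, match="2 phyla"):
            generate_reference_database(
                arthropod_profiles, PlantingSpec(n_mislabelled=1), seed=0
            )

    def test_overplanting_rejected(self, profiles):
        with pytest.raises(ValueError):
            generate_reference_database(
                profiles, PlantingSpec(n_duplicates=1000), seed=0
            )

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        dup=st.integers(0, 3), short=st.integers(0, 2), long=st.integers(0, 2),
        unid=st.integers(0, 3), mis=st.integers(0, 2), cont=st.integers(0, 2),
    )
    def test_manifest_matches_planting_counts(self, profiles, dup, short, long, unid, mis, cont):
        planting = PlantingSpec(dup, short, long, unid, mis, cont)
        records, manifest, _ = generate_reference_database(profiles, planting, seed=9)
        tally = pd.Series([d for _, d in manifest]).value_counts().to_dict()
        assert tally.get("duplicate", 0) == dup
        assert tally.get("short", 0) == short
        assert tally.get("long", 0) == long
        assert tally.get("unidentified", 0) == unid
        assert tally.get("mislabelled", 0) == mis
        assert tally.get("contaminant", 0) == cont
        assert len(records) == len(profiles) * len(THREE_LOCI) + planting.total()


# --- library simulation ----------------------------------------------------

class TestSimulateLibrary:
    def test_even_pool_splits_reads_evenly(self, profiles):
        two = profiles[:2]
        design = MockCommunityDesign("P", {p.species_name: 50 for p in two})
        cfg = unique_dual_config(["P"], seed=1, reads=10_000)
        table = simulate_library(design, two, cfg)
        frac = table["P"].to_numpy() / table["P"].sum()
        sd = np.sqrt(0.5 * 0.5 / 10_000)
        assert np.all(np.abs(frac - 0.5) < 3 * sd)

    def test_single_species_gets_all_reads(self, profiles):
        one = profiles[:1]
        design = MockCommunityDesign("P", {one[0].species_name: 10})
        cfg = unique_dual_config(["P"], seed=1, reads=5_000, loci=("COI", "12S", "18S"))
        table = simulate_library(design, one, cfg)
        assert table["P"].sum() == 5_000
        assert set(table["locus"]) == {"COI", "12S", "18S"}

    def test_rare_species_fraction_within_exact_binomial_bounds(self, profiles):
        """999:1 pool at 100k reads: rare-species counts respect the exact
        central 99% binomial interval (coverage checked over 20 seeds)."""
        two = profiles[:2]
        design = MockCommunityDesign(
            "P", {two[0].species_name: 999, two[1].species_name: 1}
        )
        lo, hi = stats.binom.interval(0.99, 100_000, 1 / 1000)
        inside = 0
        for seed in range(20):
            cfg = unique_dual_config(["P"], seed=seed, reads=100_000)
            table = simulate_library(design, two, cfg)
            rare = int(table.loc[table["asv_id"].str.contains(
                two[1].species_name.replace(" ", "_")), "P"].iloc[0])
            inside += lo <= rare <= hi
        assert inside >= 18  # P(<18 | true coverage 0.99) ~ 1e-3

    def test_missing_template_warns_and_contributes_zero(self, profiles):
        from dataclasses import replace
        p0 = profiles[0]
        no18s = replace(
            p0,
            templates={k: v for k, v in p0.templates.items() if k != "18S"},
            bias={k: v for k, v in p0.bias.items() if k != "18S"},
        )
        design = MockCommunityDesign("P", {no18s.species_name: 5})
        cfg = unique_dual_config(["P"], seed=1, reads=300, loci=("COI", "18S"))
        with pytest.warns(UserWarning, match="no 18S template"):
            table = simulate_library(design, [no18s], cfg)
        assert table.loc[table["locus"] == "18S", "P"].sum() == 0

    def test_bias_shifts_observed_abundance(self, locus_specs):
        from dataclasses import replace
        profs = generate_species_profiles(1, 2, locus_specs, seed=2)
        boosted = replace(profs[0], bias={l: 3.0 for l in profs[0].templates})
        design = MockCommunityDesign(
            "P", {boosted.species_name: 50, profs[1].species_name: 50}
        )
        cfg = unique_dual_config(["P"], seed=9, reads=30_000)
        table = simulate_library(design, [boosted, profs[1]], cfg)
        frac = table.set_index("asv_id")["P"] / table["P"].sum()
        heavy = frac[f"COI:{boosted.species_name.replace(' ', '_')}"]
        assert abs(heavy - 0.75) < 0.02  # 3:1 efficiency at equal counts


# --- index switching -------------------------------------------------------

def _library_frame(samples, reads_each):
    return pd.DataFrame(
        {"asv_id": ["COI:x"], "locus": ["COI"], "sequence": ["ACGT" * 10],
         **{smp: [reads_each] for smp in samples}}
    )


class TestIndexSwitching:
    def test_rate_zero_is_identity(self, profiles):
        cfg = unique_dual_config(["A", "B"], seed=5, s=0.0)
        libs = _library_frame(["A", "B"], 1000)
        pairs, contaminated, totals = simulate_index_switching(libs, cfg)
        assert totals["undetermined"] == 0
        pd.testing.assert_frame_equal(contaminated, libs)

    def test_read_conservation_exact(self):
        cfg = unique_dual_config(["A", "B", "C"], seed=6, s=0.05)
        libs = _library_frame(["A", "B", "C"], 4000)
        pairs, contaminated, totals = simulate_index_switching(libs, cfg)
        assert totals["assigned"] + totals["undetermined"] == totals["generated"] == 12000
        assert pairs["reads"].sum() == 12000
        sample_cols = ["A", "B", "C"]
        assert contaminated[sample_cols].to_numpy().sum() == totals["assigned"]

    def test_invalid_fraction_matches_enumeration_oracle(self):
        cfg = unique_dual_config(["A", "B"], seed=12, s=0.01)
        libs = _library_frame(["A", "B"], 500_000)
        _, _, totals = simulate_index_switching(libs, cfg)
        expected = exact_invalid_probability(cfg)
        observed = totals["undetermined"] / totals["generated"]
        sd = np.sqrt(expected * (1 - expected) / 1_000_000)
        assert abs(observed - expected) < 3 * sd
        # and the package closed form agrees with the oracle exactly
        assert expected == pytest.approx(expected_invalid_fraction(cfg), abs=1e-12)

    def test_determinism(self):
        cfg = unique_dual_config(["A", "B"], seed=13, s=0.02)
        libs = _library_frame(["A", "B"], 10_000)
        out1 = simulate_index_switching(libs, cfg)
        out2 = simulate_index_switching(libs, cfg)
        pd.testing.assert_frame_equal(out1[0], out2[0])
        pd.testing.assert_frame_equal(out1[1], out2[1])

    def test_switch_rate_inversion_round_trips(self):
        cfg = unique_dual_config(["A", "B", "C", "D"], s=0.0)
        from dataclasses import replace
        s = switch_rate_for_contamination(0.01, cfg)
        assert 0 < s < 0.02
        assert expected_invalid_fraction(replace(cfg, switch_rate_s=s)) == pytest.approx(0.01)


def exact_invalid_probability(config):
    """Oracle: sum over the 4 switch outcomes x uniform destinations."""
    s = config.switch_rate_s
    n5, n7 = len(config.i5_values), len(config.i7_values)
    valid = config.valid_pairs
    per_sample = []
    for a, b in config.sample_index_map.values():
        mass = 0.0
        for x in config.i5_values:
            for y in config.i7_values:
                if (x, y) in valid:
                    continue
                p = 0.0
                if x == a and y == b:
                    p += (1 - s) * (1 - s)  # no replacement at either end
                if y == b:
                    p += s / n5 * (1 - s)  # i5 replaced (maybe by itself), i7 kept
                if x == a:
                    p += (1 - s) * s / n7
                p += (s / n5) * (s / n7)
                mass += p
        per_sample.append(mass)
    return float(np.mean(per_sample))


# --- designs ---------------------------------------------------------------

def test_mock_designs_sizes_and_rare_singleton(profiles):
    designs = generate_mock_designs(profiles, sizes=(100, 250, 500, 1000))
    assert [d.size for d in designs] == [100, 250, 500, 1000]
    rare = profiles[-1].species_name
    for d in designs:
        assert d.counts[rare] == 1


def test_design_invariants_enforced():
    with pytest.raises(ValueError):
        MockCommunityDesign("P", {"a b": -1, "c d": 5})
    with pytest.raises(ValueError):
        MockCommunityDesign("P", {})


def test_config_validation_rejects_reused_unique_dual_index():
    with pytest.raises(ValueError, match="unique_dual"):
        SimulationConfig(
            seed=0, reads_per_library=10, locus_share={"COI": 1.0},
            switch_rate_s=0.0, indexing_mode="unique_dual",
            i5_values=("a", "b"), i7_values=("c", "d"),
            sample_index_map={"s1": ("a", "c"), "s2": ("a", "d")},
        )


def test_merge_libraries_outer_join_fills_zeros(profiles):
    d1 = MockCommunityDesign("P1", {profiles[0].species_name: 10})
    d2 = MockCommunityDesign("P2", {profiles[1].species_name: 10})
    cfg = unique_dual_config(["P1", "P2"], seed=3, reads=100)
    merged = merge_libraries([
        simulate_library(d1, profiles, cfg), simulate_library(d2, profiles, cfg)
    ])
    assert merged[["P1", "P2"]].to_numpy().sum() == 200
    first_only = merged[merged["asv_id"].str.contains(
        profiles[0].species_name.replace(" ", "_"))]
    assert (first_only["P2"] == 0).all()
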