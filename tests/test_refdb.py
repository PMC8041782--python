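"""Curation cascade: rule behaviour, boundary cases, clustering, trimming."""

import pytest

from trapscreen.align import revcomp
from trapscreen.lineage import Lineage
from trapscreen.refdb import (
    CurationParams,
    Primer,
    TaxonRecord,
    cluster_and_flag_misannotations,
    curate,
    export_training_set,
    filter_contaminants,
    filter_length_duplicates,
    filter_unidentified,
    greedy_cluster,
    locate_amplicon_interior,
    trim_to_primer_region,
)
from trapscreen.synth import PlantingSpec, generate_reference_database
from trapscreen.align import global_identity

PARAMS = CurationParams()
ARTHRO = Lineage(("Arthropoda", "Insecta", "Hemiptera", "Aphididae", "Diuraphis",
                  "Diuraphis noxia"))


def rec(record_id, seq, lineage=ARTHRO, locus="COI", raw=None):
    return TaxonRecord(record_id, locus, seq, lineage,
                       raw_label=raw if raw is not None else (lineage.species or ""))


def random_seq(n, seed=0):
    import numpy as np
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


class TestLengthDuplicates:
    def test_short_record_removed(self):
        kept, log = filter_length_duplicates([rec("A", random_seq(150))], PARAMS)
        assert kept == [] and log.removed_ids("1") == {"A"}

    def test_boundary_lengths_kept(self):
        records = [rec("A", random_seq(200, 1)), rec("B", random_seq(3000, 2))]
        kept, log = filter_length_duplicates(records, PARAMS)
        assert len(kept) == 2 and not log.entries

    def test_duplicate_keeps_first_id(self):
        s = random_seq(300, 3)
        kept, log = filter_length_duplicates([rec("B", s), rec("A", s)], PARAMS)
        assert [r.record_id for r in kept] == ["A"]
        assert log.removed_ids("1") == {"B"}

    def test_identical_sequence_different_species_both_kept(self):
        other = Lineage(ARTHRO.names[:5] + ("Diuraphis mexicana",))
        s = random_seq(300, 4)
        kept, _ = filter_length_duplicates([rec("A", s), rec("B", s, other)], PARAMS)
        assert len(kept) == 2

    def test_empty_input(self):
        kept, log = filter_length_duplicates([], PARAMS)
        assert kept == [] and not log.entries


class TestUnidentified:
    @pytest.mark.parametrize(
        "raw,removed",
        [
            ("Acizzia sp.", True),
            ("Diuraphis noxia", False),
            ("Aphis nr. craccivora", True),
            ("Bactericera environmental sample", True),
        ],
    )
    def test_exclusion_terms_as_tokens(self, raw, removed):
        lineage = (
            ARTHRO if not removed
            else Lineage(ARTHRO.names[:5] + (raw,))
        )
        kept, log = filter_unidentified([rec("A", random_seq(300), lineage, raw=raw)], PARAMS)
        assert (kept == []) is removed

    def test_missing_binomial_removed_without_term(self):
        genus_only = Lineage(ARTHRO.names[:5])
        kept, log = filter_unidentified([rec("A", random_seq(300), genus_only)], PARAMS)
        assert kept == []
        assert any("binomial" in e.detail for e in log.entries)


class TestContaminants:
    def test_identical_to_contaminant_removed(self):
        s = random_seq(400, 5)
        panel = [rec("W1", s)]
        kept, log = filter_contaminants([rec("A", s)], panel, PARAMS)
        assert kept == [] and log.removed_ids("3") == {"A"}

    def test_distant_record_kept(self):
        kept, _ = filter_contaminants(
            [rec("A", random_seq(400, 6))], [rec("W1", random_seq(400, 7))], PARAMS
        )
        assert len(kept) == 1

    def test_exact_95_percent_identity_kept(self):
        """Removal needs identity strictly above 0.95: a 100-base pair with
        exactly 95 matching columns sits on the boundary and survives."""
        base = random_seq(100, 8)
        mutated = list(base)
        for i in (7, 23, 41, 67, 89):  # scattered so gaps cannot help
            mutated[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[i]]
        mutated = "".join(mutated)
        assert global_identity(base, mutated) == pytest.approx(0.95)
        kept, _ = filter_contaminants([rec("A", mutated)], [rec("W1", base)], PARAMS)
        assert len(kept) == 1

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            filter_contaminants([rec("A", random_seq(100))], [], PARAMS)


class TestClustering:
    def test_minority_phylum_member_removed(self):
        s = random_seq(300, 9)
        chordate = Lineage(("Chordata", "Aves", "Passeriformes", "Corvidae",
                            "Corvus", "Corvus corax"))
        records = [
            rec("A", s), rec("B", s[:-1] + ("A" if s[-1] != "A" else "C")),
            rec("C", s[:-2], chordate),
        ]
        kept, log = cluster_and_flag_misannotations(records, PARAMS)
        assert log.removed_ids("4") == {"C"}
        assert {r.record_id for r in kept} == {"A", "B"}

    def test_homogeneous_clusters_untouched(self):
        records = [rec("A", random_seq(300, 10)), rec("B", random_seq(300, 11))]
        kept, log = cluster_and_flag_misannotations(records, PARAMS)
        assert len(kept) == 2 and not log.entries

    def test_membership_matches_all_pairs_replay(self):
        """Greedy clustering equals a brute-force replay over the all-pairs
        identity matrix with the same length-desc/id visiting order."""
        base = random_seq(200, 12)
        variants = {
            "A": base,
            "B": base[:-1],                      # ~99.5% to A
            "C": base[:100] + random_seq(100, 13),  # ~50%
            "D": base[:-3],                      # ~98.5% to A -> own cluster
        }
        records = [rec(k, v) for k, v in variants.items()]
        clusters = greedy_cluster(records, PARAMS.cluster_identity)

        order = sorted(records, key=lambda r: (-len(r.sequence), r.record_id))
        ident = {
            (a.record_id, b.record_id): global_identity(a.sequence, b.sequence)
            for a in records for b in records
        }
        replay: list[list[str]] = []
        for r in order:
            for cl in replay:
                if ident[(r.record_id, cl[0])] >= PARAMS.cluster_identity:
                    cl.append(r.record_id)
                    break
            else:
                replay.append([r.record_id])
        got = [[m.record_id for m in cl] for cl in clusters]
        assert got == replay

    def test_tie_resolved_toward_centroid(self):
        """1-vs-1 mixed cluster: the member discordant with the (longer)
        centroid is removed, the centroid kept."""
        s = random_seq(300, 14)
        chordate = Lineage(("Chordata", "Aves", "Passeriformes", "Corvidae",
                            "Corvus", "Corvus corax"))
        records = [rec("A", s), rec("B", s[:-2], chordate)]
        kept, log = cluster_and_flag_misannotations(records, PARAMS)
        assert [r.record_id for r in kept] == ["A"]
        assert log.removed_ids("4") == {"B"}


class TestTrim:
    FWD = "ACGTACGTAC"
    REV = "TTGCAGGCAT"  # 5'->3' on the reverse strand

    def make_seed(self, interior):
        return self.FWD + interior + revcomp(self.REV)

    def test_interior_located_excluding_primers(self):
        interior = random_seq(250, 15)
        seed = self.make_seed(interior)
        lo, hi = locate_amplicon_interior(seed, Primer(self.FWD, self.REV))
        assert seed[lo:hi] == interior

    def test_record_equal_to_seed_trims_to_interior(self):
        interior = random_seq(250, 16)
        seed_rec = rec("SEED", self.make_seed(interior))
        primers = {"COI": Primer(self.FWD, self.REV)}
        out, log = trim_to_primer_region([rec("A", self.make_seed(interior))],
                                         primers, [seed_rec])
        assert out[0].sequence == interior

    def test_substituted_record_trims_to_same_coordinates(self):
        """Five interior substitutions leave the alignment gap-free, so the
        trimmed slice is exactly the mutated interior."""
        interior = random_seq(250, 17)
        seed_rec = rec("SEED", self.make_seed(interior))
        mutated = list(interior)
        for i in (10, 60, 120, 180, 240):
            mutated[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[i]]
        mutated = "".join(mutated)
        primers = {"COI": Primer(self.FWD, self.REV)}
        out, _ = trim_to_primer_region([rec("A", self.make_seed(mutated))],
                                       primers, [seed_rec])
        assert out[0].sequence == mutated

    def test_low_coverage_record_removed(self):
        interior = random_seq(250, 18)
        seed_rec = rec("SEED", self.make_seed(interior))
        primers = {"COI": Primer(self.FWD, self.REV)}
        half = rec("A", interior[:125])
        out, log = trim_to_primer_region([half], primers, [seed_rec])
        assert out == [] and log.removed_ids() == {"A"}

    def test_trim_monotone_in_length(self):
        interior = random_seq(250, 19)
        seed_rec = rec("SEED", self.make_seed(interior))
        primers = {"COI": Primer(self.FWD, self.REV)}
        records = [rec("A", self.make_seed(interior)), rec("B", interior)]
        out, _ = trim_to_primer_region(records, primers, [seed_rec])
        for before, after in zip(records, out):
            assert len(after.sequence) <= len(before.sequence)

    def test_missing_seed_locus_errors(self):
        primers = {"COI": Primer(self.FWD, self.REV)}
        with pytest.raises(ValueError, match="18S"):
            trim_to_primer_region([rec("A", random_seq(100), locus="18S")], primers,
                                  [rec("SEED", self.make_seed(random_seq(250, 20)))])


class TestExport:
    def test_full_lineage_record_in_both_files(self):
        genus, species, _ = export_training_set([rec("A", random_seq(300, 21))])
        assert len(genus) == 2 and len(species) == 2
        assert genus[0].endswith("Diuraphis") and species[0].endswith("Diuraphis noxia")

    def test_record_without_species_only_in_genus_file(self):
        genus_only = Lineage(ARTHRO.names[:5])
        genus, species, _ = export_training_set([rec("A", random_seq(300, 22), genus_only)])
        assert len(genus) == 2 and species == []

    def test_export_deterministic(self):
        records = [rec("B", random_seq(300, 23)), rec("A", random_seq(300, 24))]
        assert export_training_set(records) == export_training_set(list(reversed(records)))


class TestCascade:
    def _fixture(self, seed):
        from trapscreen.synth import LocusSpec, generate_species_profiles
        specs = {
            "COI": LocusSpec(300, 0.02, 0.10),
            "18S": LocusSpec(280, 0.0, 0.05),
        }
        profiles = generate_species_profiles(
            3, 2, specs, seed=seed, phyla=("Arthropoda", "Chordata")
        )
        return generate_reference_database(
            profiles, PlantingSpec(2, 1, 1, 2, 2, 2), seed=seed
        )

    def test_conservation_and_single_removal_entry(self):
        records, _, panel = self._fixture(31)
        kept, log = curate(records, PARAMS, panel)
        removal_entries = [e for e in log.entries if e.action == "removed"]
        assert len(kept) + len(removal_entries) == len(records)
        ids = [e.record_id for e in removal_entries]
        assert len(ids) == len(set(ids))  # no record removed twice

    def test_planted_defects_removed_by_matching_rule(self):
        records, manifest, panel = self._fixture(32)
        kept, log = curate(records, PARAMS, panel)
        rule_for = {"duplicate": "1", "short": "1", "long": "1",
                    "unidentified": "2", "contaminant": "3", "mislabelled": "4"}
        by_rule = {rule: log.removed_ids(rule) for rule in ("1", "2", "3", "4")}
        for rid, defect in manifest:
            assert rid in by_rule[rule_for[defect]], (rid, defect)
        planted = {rid for rid, _ in manifest}
        assert log.removed_ids() == planted  # zero clean records removed

    def test_idempotence_on_own_output(self):
        records, _, panel = self._fixture(33)
        kept, _ = curate(records, PARAMS, panel)
        again, log = curate(kept, PARAMS, panel)
        assert [r.record_id for r in again] == [r.record_id for r in kept]
        assert log.removed_ids() == set()
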