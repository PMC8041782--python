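"""Plain-text readers and writers for the pipeline's interchange formats.

Reference FASTA headers carry semicolon-delimited lineage strings
(``>ID Root;Phylum;...;Genus_species``); ASV tables are TSV with
``asv_id``, ``locus``, ``sequence`` metadata columns followed by one
integer column per sample; index tallies are long-format TSV
(i5, i7, reads) plus a valid-pair TSV; configs are YAML.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .lineage import Lineage
from .qc import Read
from .refdb import Primer, PrimerSet, TaxonRecord
from .synth import (
    META_COLS,
    LocusSpec,
    MockCommunityDesign,
    SimulationConfig,
)


# --- reference FASTA -------------------------------------------------------

def read_lineage_fasta(path, locus: str, source: str = "public") -> list[TaxonRecord]:
    records = []
    with open(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            record_id, _, rest = title.partition(" ")
            lineage = Lineage.from_header(rest) if rest else Lineage(("Unknown",))
            raw = lineage.names[-1]
            records.append(
                TaxonRecord(record_id, locus, seq.upper(), lineage, source=source, raw_label=raw)
            )
    return records


def write_lineage_fasta(records: list[TaxonRecord], path) -> None:
    with open(path, "w") as handle:
        for rec in sorted(records, key=lambda r: r.record_id):
            handle.write(f">{rec.record_id} {rec.lineage.to_header()}\n{rec.sequence}\n")


def write_reference_fastas(records: list[TaxonRecord], out_dir) -> dict[str, Path]:
    """One lineage FASTA per locus, named ``<locus>.fasta``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    loci = sorted({r.locus for r in records})
    for locus in loci:
        p = out_dir / f"{locus}.fasta"
        write_lineage_fasta([r for r in records if r.locus == locus], p)
        paths[locus] = p
    return paths


# --- ASV tables ------------------------------------------------------------

def read_asv_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"asv_id": str, "locus": str, "sequence": str})
    for col in df.columns:
        if col not in META_COLS:
            df[col] = df[col].astype(int)
    return df


def write_asv_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


# --- index pair tallies ----------------------------------------------------

def read_index_pairs(pairs_path, valid_path):
    """(pairs DataFrame, valid-pair set) from long-format TSVs."""
    pairs = pd.read_csv(pairs_path, sep="\t", dtype={"i5": str, "i7": str})
    valid = pd.read_csv(valid_path, sep="\t", dtype=str)
    valid_set = frozenset(zip(valid["i5"], valid["i7"]))
    return pairs, valid_set


def write_index_pairs(pairs: pd.DataFrame, valid_pairs, pairs_path, valid_path) -> None:
    pairs.to_csv(pairs_path, sep="\t", index=False)
    pd.DataFrame(sorted(valid_pairs), columns=["i5", "i7"]).to_csv(
        valid_path, sep="\t", index=False
    )


# --- FASTQ -----------------------------------------------------------------

def read_fastq(path) -> list[Read]:
    reads = []
    with open(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            reads.append(Read(title.split()[0], seq.upper(),
                              tuple(ord(c) - 33 for c in qual)))
    return reads


def write_fastq_lines(lines: list[str], path) -> None:
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# --- YAML configs ----------------------------------------------------------

def load_primer_set(path) -> PrimerSet:
    raw = yaml.safe_load(Path(path).read_text())
    primers = {}
    for locus, spec in raw.items():
        rng = spec.get("amplicon_range")
        primers[locus] = Primer(
            forward=spec["forward"], reverse=spec["reverse"],
            amplicon_range=tuple(rng) if rng else None,
        )
    return primers


def dump_primer_set(primers: PrimerSet, path) -> None:
    raw = {
        locus: {
            "forward": p.forward, "reverse": p.reverse,
            **({"amplicon_range": list(p.amplicon_range)} if p.amplicon_range else {}),
        }
        for locus, p in primers.items()
    }
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=True))


def load_designs(path) -> list[MockCommunityDesign]:
    raw = yaml.safe_load(Path(path).read_text())
    return [MockCommunityDesign(d["pool_id"], {k: int(v) for k, v in d["counts"].items()})
            for d in raw]


def dump_designs(designs: list[MockCommunityDesign], path) -> None:
    raw = [{"pool_id": d.pool_id, "counts": d.counts} for d in designs]
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


def load_simulation_config(path) -> tuple[SimulationConfig, dict]:
    """(SimulationConfig, full raw mapping) from a sim YAML.

    The raw mapping may additionally carry ``profiles`` (generator
    settings) and ``designs`` sections used by the simulate driver.
    """
    raw = yaml.safe_load(Path(path).read_text())
    config = SimulationConfig(
        seed=int(raw["seed"]),
        reads_per_library=int(raw["reads_per_library"]),
        locus_share={k: float(v) for k, v in raw["locus_share"].items()},
        switch_rate_s=float(raw["switch_rate"]),
        indexing_mode=raw["indexing_mode"],
        i5_values=tuple(raw["i5"]),
        i7_values=tuple(raw["i7"]),
        sample_index_map={k: tuple(v) for k, v in raw["samples"].items()},
    )
    return config, raw


def load_locus_specs(raw: dict) -> dict[str, LocusSpec]:
    return {
        locus: LocusSpec(
            length=int(s["length"]),
            within_divergence=float(s["within_divergence"]),
            between_divergence=float(s["between_divergence"]),
        )
        for locus, s in raw.items()
    }
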