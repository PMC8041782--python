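#!/usr/bin/env python
"""Run the four-rule decontamination cascade on the simulated reference
database and verify that every planted defect falls to its matching rule.

Reads results/sim/, writes results/curated/: per-locus curated FASTA,
classifier training sets, and the curation log.
"""

import sys
from pathlib import Path

import pandas as pd

from trapscreen import io as tio
from trapscreen import refdb


def main(out_root: Path = Path("results")) -> None:
    sim = out_root / "sim"
    out = out_root / "curated"
    out.mkdir(parents=True, exist_ok=True)

    records = []
    for f in sorted((sim / "reference").glob("*.fasta")):
        records += tio.read_lineage_fasta(f, locus=f.stem)
    panel = tio.read_lineage_fasta(sim / "contaminants.fasta", locus="COI",
                                   source="contaminant")
    kept, log = refdb.curate(records, refdb.CurationParams(), panel)
    tio.write_reference_fastas(kept, out / "fasta")
    log.to_frame().to_csv(out / "curation_log.tsv", sep="\t", index=False)
    genus_lines, species_lines, _ = refdb.export_training_set(kept)
    (out / "training_genus.fasta").write_text("\n".join(genus_lines) + "\n")
    (out / "training_species.fasta").write_text("\n".join(species_lines) + "\n")

    manifest = pd.read_csv(sim / "planted_manifest.tsv", sep="\t")
    removed = log.removed_ids()
    planted = set(manifest["record_id"])
    per_rule = log.to_frame().query("action == 'removed'")["rule"].value_counts()

    print(f"curation: kept {len(kept)} of {len(records)} records")
    print("removals by rule:", {k: int(v) for k, v in per_rule.items()})
    print(f"planted defects removed: {len(planted & removed)}/{len(planted)}; "
          f"clean records removed: {len(removed - planted)}")


if __name__ == "__main__":
    main(Path(sys.argv[1]) if len(sys.argv) > 1 else Path("results"))
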