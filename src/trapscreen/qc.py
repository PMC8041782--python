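"""Read-level quality control.

Three rules applied upstream of (or in place of) denoising:

* primer trimming — reads are demultiplexed to a locus by an
  IUPAC-aware, indel-free match of the forward primer at the 5' end
  (one mismatch tolerated), and the reverse primer's reverse complement
  is removed from the 3' end when present;
* expected-error filtering — a read is discarded when its Phred-derived
  expected error count EE = sum(10^(-Q/10)) exceeds the cap, when it
  carries an ambiguous N, or when it is too short;
* COI pseudogene screening — nuclear mitochondrial copies (NUMTs)
  accumulate frame shifts and stop codons; each COI sequence is aligned
  to an in-house amplicon of known reading frame and discarded when its
  net interior indel length breaks the frame or its inherited-frame
  translation (invertebrate mitochondrial code) contains a stop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq

from .align import align_columns, revcomp
from .refdb import PrimerSet, find_primer, iupac_match_position


@dataclass(frozen=True)
class QCParams:
    max_expected_errors: float = 2.0
    disallow_ambiguous: bool = True
    min_len: int = 100  # exclusive: reads must be strictly longer

    def __post_init__(self) -> None:
        if self.max_expected_errors < 0 or self.min_len < 0:
            raise ValueError("max_expected_errors and min_len must be >= 0")


@dataclass(frozen=True)
class Read:
    read_id: str
    sequence: str
    qualities: tuple[int, ...]  # Phred-scaled

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")


def expected_errors(qualities) -> float:
    q = np.asarray(qualities, dtype=float)
    return float(np.sum(10.0 ** (-q / 10.0)))


def trim_primers(
    reads: list[Read], primers: PrimerSet, max_mismatch: int = 1
) -> tuple[dict[str, list[Read]], dict[str, int]]:
    """Assign reads to loci by 5'-anchored forward-primer match and trim.

    Returns per-locus read lists and discard counts keyed
    ``no_primer`` / ``ambiguous``.  The reverse complement of the
    reverse primer is removed from the 3' end when found downstream of
    the forward primer (rightmost placement, same mismatch tolerance).
    """
    out: dict[str, list[Read]] = {locus: [] for locus in primers}
    counts = {"no_primer": 0, "ambiguous": 0}
    for read in reads:
        hits = [
            locus for locus, p in primers.items()
            if iupac_match_position(read.sequence, p.forward, 0, max_mismatch)
        ]
        if not hits:
            counts["no_primer"] += 1
            continue
        if len(hits) > 1:
            counts["ambiguous"] += 1
            continue
        locus = hits[0]
        p = primers[locus]
        start = len(p.forward)
        seq = read.sequence[start:]
        qual = read.qualities[start:]
        rrc = revcomp(p.reverse)
        for i in range(len(seq) - len(rrc), -1, -1):
            if iupac_match_position(seq, rrc, i, max_mismatch):
                seq, qual = seq[:i], qual[:i]
                break
        out[locus].append(Read(read.read_id, seq, qual))
    return out, counts


def filter_reads(reads: list[Read], params: QCParams) -> tuple[list[Read], dict[str, int]]:
    """Expected-error / ambiguity / length filter with per-reason counts.

    Reason precedence when several apply: max_ee, then ambiguous, then
    too_short.
    """
    kept: list[Read] = []
    counts = {"max_ee": 0, "ambiguous": 0, "too_short": 0}
    for read in reads:
        if read.qualities is None:
            raise ValueError(f"{read.read_id}: qualities required")
        if expected_errors(read.qualities) > params.max_expected_errors:
            counts["max_ee"] += 1
        elif params.disallow_ambiguous and "N" in read.sequence.upper():
            counts["ambiguous"] += 1
        elif len(read.sequence) <= params.min_len:
            counts["too_short"] += 1
        else:
            kept.append(read)
    return kept, counts


@dataclass(frozen=True)
class FrameReference:
    """In-house COI amplicon with a known codon phase.

    ``frame_start`` is the 0-based position of the first complete codon.
    """

    sequence: str
    frame_start: int = 0
    genetic_code: int = 5  # invertebrate mitochondrial

    def __post_init__(self) -> None:
        prot = translate_frame(self.sequence, self.frame_start, self.genetic_code)
        if "*" in prot:
            raise ValueError("frame reference must translate stop-free in its stated frame")


def translate_frame(seq: str, frame_start: int, table: int = 5) -> str:
    coding = seq[frame_start:]
    coding = coding[: len(coding) - len(coding) % 3]
    return str(Seq(coding).translate(table=table))


def screen_coi_pseudogenes(
    asv_sequences: dict[str, str],
    frame_reference: FrameReference,
    locus: str = "COI",
) -> dict[str, tuple[bool, str]]:
    """Keep/discard verdicts for COI ASVs against a reading-frame reference.

    An ASV is discarded when (a) the net interior indel length of its
    global alignment to the reference is not a multiple of 3 (frame
    shift), or (b) its translation in the inherited frame contains a
    stop codon.  Verdicts are ``{asv_id: (keep, reason)}``.
    """
    if locus != "COI":
        raise ValueError(f"pseudogene screen applies to COI only, got {locus!r}")
    verdicts: dict[str, tuple[bool, str]] = {}
    ref = frame_reference.sequence
    for asv_id, seq in asv_sequences.items():
        cols = align_columns(seq, ref, mode="NW")
        aligned = [k for k, (q, t) in enumerate(cols) if q >= 0 and t >= 0]
        if not aligned:
            verdicts[asv_id] = (False, "unalignable")
            continue
        first, last = aligned[0], aligned[-1]
        interior = cols[first : last + 1]
        net_indel = sum(1 for q, t in interior if t < 0) - sum(1 for q, t in interior if q < 0)
        if net_indel % 3 != 0:
            verdicts[asv_id] = (False, f"frame shift (net interior indel {net_indel})")
            continue
        q0, t0 = cols[first]
        phase = (t0 - frame_reference.frame_start) % 3
        start = q0 + (-phase) % 3
        prot = translate_frame(seq, start, frame_reference.genetic_code)
        if "*" in prot:
            verdicts[asv_id] = (False, "internal stop codon")
        else:
            verdicts[asv_id] = (True, "ok")
    return verdicts
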