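"""Hierarchical taxonomic lineages and their FASTA-header serialisation.

A lineage is a contiguous run of rank labels from phylum downward
(phylum, class, order, family, genus, species); lower ranks may be
absent but gaps are not allowed.  The species label is a full binomial
("Genus epithet"); in headers the internal space becomes an underscore.
"""

from __future__ import annotations

from dataclasses import dataclass

RANKS: tuple[str, ...] = ("phylum", "class", "order", "family", "genus", "species")

#: Header prefix used by lineage-string training FASTA files.
ROOT_LABEL = "Root"


@dataclass(frozen=True)
class Lineage:
    """Ordered rank labels from phylum downward, no gaps."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.names) <= len(RANKS):
            raise ValueError(f"lineage must span 1..{len(RANKS)} ranks, got {len(self.names)}")
        if any(not isinstance(n, str) or not n for n in self.names):
            raise ValueError(f"lineage ranks must be non-empty strings: {self.names!r}")

    def get(self, rank: str) -> str | None:
        i = RANKS.index(rank)
        return self.names[i] if i < len(self.names) else None

    @property
    def phylum(self) -> str:
        return self.names[0]

    @property
    def genus(self) -> str | None:
        return self.get("genus")

    @property
    def species(self) -> str | None:
        return self.get("species")

    @property
    def lowest_rank(self) -> str:
        return RANKS[len(self.names) - 1]

    def truncate(self, rank: str) -> "Lineage":
        """Lineage cut at `rank` (inclusive); errors if `rank` is absent."""
        i = RANKS.index(rank)
        if i >= len(self.names):
            raise ValueError(f"rank {rank!r} absent from lineage {self.names!r}")
        return Lineage(self.names[: i + 1])

    def to_header(self) -> str:
        """Semicolon-delimited string ``Root;Phylum;...`` with underscored species."""
        parts = [ROOT_LABEL] + [n.replace(" ", "_") for n in self.names]
        return ";".join(parts)

    @classmethod
    def from_header(cls, text: str) -> "Lineage":
        parts = [p for p in text.strip().split(";") if p]
        if parts and parts[0] == ROOT_LABEL:
            parts = parts[1:]
        return cls(tuple(p.replace("_", " ") for p in parts))


def is_binomial(name: str | None) -> bool:
    """True for a complete two-word species name of plain alphabetic tokens."""
    if not name:
        return False
    toks = name.split()
    return len(toks) == 2 and all(t.replace("-", "").isalpha() for t in toks)
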