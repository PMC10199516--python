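"""Core record types: genome bins (MAGs) and biosynthetic gene clusters (BGCs).

A MAG (metagenome-assembled genome) carries the fermentation habitat it was
recovered from plus CheckM-style quality estimates; a BGC is represented by
its class label and the ordered list of protein-domain annotations along the
cluster, which is the only sequence-level information the downstream
distance computations use.
"""

from __future__ import annotations

from dataclasses import dataclass, field


#: The dominant BGC classes; anything else is folded into "other".
BGC_CLASSES = (
    "RiPP",
    "NRPS",
    "PKS",
    "terpene",
    "siderophore",
    "arylpolyene",
    "betalactone",
    "ectoine",
    "other",
)


@dataclass(frozen=True)
class MagRecord:
    """One genome bin with its habitat label and quality metrics."""

    mag_id: str
    habitat: str
    completeness: float
    contamination: float
    group: str | None = None  # milk-based | plant-based
    taxonomy: tuple[str, ...] | None = None
    source: str = "this-study"

    def __post_init__(self) -> None:
        if not self.mag_id:
            raise ValueError("mag_id must be non-empty")
        if not self.habitat:
            raise ValueError(f"MAG {self.mag_id}: habitat must be non-empty")
        if not 0.0 <= self.completeness <= 100.0:
            raise ValueError(
                f"MAG {self.mag_id}: completeness {self.completeness} not in [0, 100]"
            )
        if self.contamination < 0.0:
            raise ValueError(
                f"MAG {self.mag_id}: contamination {self.contamination} < 0"
            )


def normalize_bgc_class(label: str) -> str:
    """Map a raw class label onto the closed class set (unknown -> "other")."""
    return label if label in BGC_CLASSES else "other"


@dataclass(frozen=True)
class BgcRecord:
    """One biosynthetic gene cluster as an ordered protein-domain string.

    ``domains`` may legitimately be empty (fragmented clusters with no
    annotated domain); distance functions treat that case explicitly.
    Reference records (MIBiG-like entries or ecosystem reference BGCs) have
    ``is_reference`` set and contribute no habitat downstream.
    """

    bgc_id: str
    mag_id: str
    bgc_class: str
    domains: tuple[str, ...] = ()
    is_reference: bool = False
    ecosystem: str | None = None  # food | gut | ocean | soil | mibig

    def __post_init__(self) -> None:
        if not self.bgc_id:
            raise ValueError("bgc_id must be non-empty")
        object.__setattr__(self, "bgc_class", normalize_bgc_class(self.bgc_class))
        object.__setattr__(self, "domains", tuple(self.domains))


def check_unique_ids(bgcs) -> None:
    """Raise if any bgc_id occurs twice in the catalog."""
    seen: set[str] = set()
    for b in bgcs:
        if b.bgc_id in seen:
            raise ValueError(f"duplicate bgc_id {b.bgc_id!r}")
        seen.add(b.bgc_id)
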