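"""Curated pyroptosis-regulator gene catalog and generic gene-set I/O.

The catalog splits pyroptosis regulator genes (PRGs) into *positive*
regulators (genes whose activity promotes pyroptotic cell death — the
inflammasome sensors, caspases, gasdermins, inflammatory cytokines) and
*negative* regulators (genes reported to restrain it).  The two directions
are scored separately by ssGSEA and subtracted to form the pyroptosis
potential index; see :mod:`pyroppi.scoring`.

Gene sets travel in the MSigDB GMT dialect (name TAB description TAB
member...).  Symbols are matched case-sensitively after whitespace
trimming; no alias resolution is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable


class GmtParseError(ValueError):
    """A GMT line could not be parsed (fewer than 3 fields, duplicate name)."""


class CatalogCoverageError(ValueError):
    """A catalog direction has no members left after restriction."""


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols.

    ``members`` is stored as a frozenset; symbols must be non-empty strings
    and the set itself non-empty.
    """

    name: str
    description: str = ""
    members: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        cleaned = frozenset(m.strip() for m in self.members)
        if not cleaned:
            raise ValueError(f"gene set {self.name!r} has no members")
        if any(not m for m in cleaned):
            raise ValueError(f"gene set {self.name!r} contains empty symbols")
        object.__setattr__(self, "members", cleaned)

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class DirectionalCatalog:
    """A pair of disjoint gene sets: positive and negative regulators."""

    positive: GeneSet
    negative: GeneSet

    def __post_init__(self) -> None:
        overlap = self.positive.members & self.negative.members
        if overlap:
            raise ValueError(
                f"positive and negative sets overlap: {sorted(overlap)}"
            )

    def swapped(self) -> "DirectionalCatalog":
        """Catalog with directions exchanged (negates the PPI exactly)."""
        return DirectionalCatalog(positive=self.negative, negative=self.positive)

    @property
    def all_members(self) -> frozenset[str]:
        return self.positive.members | self.negative.members


# Positive (pro-pyroptosis) regulators: inflammasome sensors and adaptors,
# inflammatory caspases, the gasdermin family, effector cytokines and
# granzymes.
_POSITIVE = (
    "AIM2", "CASP1", "CASP3", "CASP4", "CASP5", "CASP6", "CASP8", "CASP9",
    "ELANE", "GPX4", "GSDMA", "GSDMB", "GSDMC", "GSDMD", "GSDME", "IL18",
    "IL1B", "NLRC4", "NLRP1", "NLRP2", "NLRP3", "NLRP6", "NLRP7", "NOD1",
    "NOD2", "PJVK", "PLCG1", "PYCARD", "SCAF11", "TNF", "P2RX7", "STAT3",
    "CD274", "MEFV", "GZMA", "GZMB", "TP53", "MAPK8", "MAPK9", "ROS1",
    "NAIP", "TLR2", "TRIM21", "CARD8", "TIRAP", "TICAM1",
)

# Negative (anti-pyroptosis) regulators.
_NEGATIVE = (
    "PRKACA", "PANX1", "BRAF", "MAP2K1", "EEF2K", "EGFR", "SIRT1", "XIST",
    "IFI16", "DPP8", "DPP9", "NEK7",
)


def packaged_prg_catalog() -> DirectionalCatalog:
    """The curated pyroptosis-regulator catalog shipped with the package.

    46 positive and 12 negative regulators, 58 symbols in total, transcribed
    verbatim from the source enumeration.  Note: the source prose states a
    total of 57 PRGs while enumerating 58 distinct symbols; the enumerated
    lists are the operative input and are kept verbatim, and it is unclear
    which symbol the curators intended to exclude (CD274/PD-L1 appears in
    the positive list and is also a widely used immune-checkpoint gene).
    Symbols are stored under the names used in the enumeration (e.g. GSDME
    rather than its alias DFNA5, PJVK rather than DFNB59).
    """
    return DirectionalCatalog(
        positive=GeneSet(
            name="PRG_positive",
            description="positive (pro-pyroptosis) regulator genes",
            members=frozenset(_POSITIVE),
        ),
        negative=GeneSet(
            name="PRG_negative",
            description="negative (anti-pyroptosis) regulator genes",
            members=frozenset(_NEGATIVE),
        ),
    )


def load_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file into a list of gene sets.

    Each non-blank line must have at least three tab-separated fields:
    name, description, then one or more member symbols.  Duplicate member
    symbols within a line are collapsed; duplicate set names across lines
    are an error.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name, description, *members = fields
            name = name.strip()
            if name in seen:
                raise GmtParseError(f"{path}: line {lineno}: duplicate set name {name!r}")
            seen.add(name)
            members = [m.strip() for m in members if m.strip()]
            if not members:
                raise GmtParseError(f"{path}: line {lineno}: set {name!r} has no members")
            sets.append(GeneSet(name=name, description=description, members=frozenset(members)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    """Write gene sets to GMT, members sorted for deterministic output."""
    path = Path(path)
    with path.open("w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.members)]) + "\n")


def catalog_to_gmt(catalog: DirectionalCatalog, path: str | Path) -> None:
    write_gmt([catalog.positive, catalog.negative], path)


def catalog_from_gmt(path: str | Path) -> DirectionalCatalog:
    """Read a two-set GMT (first line positive, second negative)."""
    sets = load_gmt(path)
    if len(sets) != 2:
        raise GmtParseError(
            f"{path}: a directional catalog GMT must contain exactly 2 sets, got {len(sets)}"
        )
    return DirectionalCatalog(positive=sets[0], negative=sets[1])


@dataclass(frozen=True)
class RestrictionReport:
    """Symbols dropped from each direction when intersecting with the assay."""

    dropped_positive: frozenset[str]
    dropped_negative: frozenset[str]

    @property
    def empty(self) -> bool:
        return not (self.dropped_positive or self.dropped_negative)


def restrict_to_measured(
    catalog: DirectionalCatalog, measured: Iterable[str]
) -> tuple[DirectionalCatalog, RestrictionReport]:
    """Intersect both catalog directions with the measured gene universe.

    Returns the restricted catalog and a report of dropped symbols per
    direction.  Raises :class:`CatalogCoverageError` if either direction
    loses all of its members.
    """
    measured_set = {str(m).strip() for m in measured}
    if not measured_set:
        raise ValueError("measured gene universe is empty")
    kept_pos = catalog.positive.members & measured_set
    kept_neg = catalog.negative.members & measured_set
    if not kept_pos or not kept_neg:
        missing = "positive" if not kept_pos else "negative"
        raise CatalogCoverageError(
            f"no {missing}-regulator genes are present in the measured universe"
        )
    restricted = DirectionalCatalog(
        positive=GeneSet(
            name=catalog.positive.name,
            description=catalog.positive.description,
            members=frozenset(kept_pos),
        ),
        negative=GeneSet(
            name=catalog.negative.name,
            description=catalog.negative.description,
            members=frozenset(kept_neg),
        ),
    )
    report = RestrictionReport(
        dropped_positive=frozenset(catalog.positive.members - kept_pos),
        dropped_negative=frozenset(catalog.negative.members - kept_neg),
    )
    return restricted, report


def catalog_to_table(catalog: DirectionalCatalog):
    """Two-column view (symbol, direction) as a pandas DataFrame."""
    import pandas as pd

    rows = [(g, "positive") for g in sorted(catalog.positive.members)]
    rows += [(g, "negative") for g in sorted(catalog.negative.members)]
    return pd.DataFrame(rows, columns=["symbol", "direction"])
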