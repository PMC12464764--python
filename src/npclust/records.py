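"""Core domain types: compound records and ordered compound sets.

A :class:`CompoundRecord` is one published structure with its identity,
SMILES, origin kingdom and year of first report.  A :class:`CompoundSet`
is an ordered, identifier-unique collection of records — the in-memory
analogue of one compound-table file.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Iterator, Optional

from rdkit import Chem

KINGDOMS = ("bacterium", "fungus", "other", "unknown")

#: Aliases accepted on input and normalised to the fixed vocabulary.
#: Cyanobacteria are bacteria for the purposes of the bacterial/fungal split.
_KINGDOM_ALIASES = {
    "bacterium": "bacterium",
    "bacteria": "bacterium",
    "bacterial": "bacterium",
    "cyanobacterium": "bacterium",
    "cyanobacteria": "bacterium",
    "fungus": "fungus",
    "fungi": "fungus",
    "fungal": "fungus",
    "other": "other",
    "unknown": "unknown",
    "": "unknown",
}

MIN_YEAR = 1800


class CompoundError(ValueError):
    """Raised for invalid compound data (bad SMILES, duplicate ids, bad years)."""


def normalize_kingdom(value: Optional[str]) -> str:
    """Map a free-text origin label onto {bacterium, fungus, other, unknown}.

    Unrecognised labels become ``other`` (the source asserted *some* origin);
    empty/missing values become ``unknown``.
    """
    if value is None:
        return "unknown"
    key = str(value).strip().lower()
    if key in ("nan", "none", "na"):
        return "unknown"
    return _KINGDOM_ALIASES.get(key, "other")


def structure_key_from_smiles(smiles: str) -> str:
    """Canonical isomeric SMILES used as the deduplication key.

    Stereochemistry is retained: stereoisomeric natural products are
    distinct compounds and must not collapse onto one key.  Raises
    :class:`CompoundError` if the SMILES does not parse.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise CompoundError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class CompoundRecord:
    """One compound: identity, structure and discovery metadata."""

    compound_id: str
    smiles: str
    structure_key: str
    name: Optional[str] = None
    kingdom: str = "unknown"
    year: Optional[int] = None

    @classmethod
    def from_fields(
        cls,
        compound_id: str,
        smiles: str,
        name: Optional[str] = None,
        kingdom: Optional[str] = None,
        year: Optional[int] = None,
    ) -> "CompoundRecord":
        """Validate raw fields and build a record.

        Raises :class:`CompoundError` on an unparseable SMILES or an
        out-of-range year ([1800, current year]).
        """
        key = structure_key_from_smiles(smiles)
        if year is not None:
            year = int(year)
            this_year = datetime.date.today().year
            if not (MIN_YEAR <= year <= this_year):
                raise CompoundError(
                    f"year {year} for {compound_id!r} outside [{MIN_YEAR}, {this_year}]"
                )
        return cls(
            compound_id=str(compound_id),
            smiles=smiles,
            structure_key=key,
            name=name,
            kingdom=normalize_kingdom(kingdom),
            year=year,
        )


@dataclass
class CompoundSet:
    """Ordered collection of compound records with unique identifiers."""

    records: list[CompoundRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.compound_id in seen:
                raise CompoundError(f"duplicate compound_id: {rec.compound_id!r}")
            seen.add(rec.compound_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CompoundRecord]:
        return iter(self.records)

    def __getitem__(self, compound_id: str) -> CompoundRecord:
        try:
            return self._index[compound_id]
        except AttributeError:
            self._index = {r.compound_id: r for r in self.records}
            return self._index[compound_id]

    def __contains__(self, compound_id: str) -> bool:
        try:
            self[compound_id]
            return True
        except KeyError:
            return False

    @property
    def ids(self) -> list[str]:
        return [r.compound_id for r in self.records]
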