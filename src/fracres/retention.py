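"""Per-family duplicate-retention indices after whole-genome duplication.

The retention index of a gene family counts in how many species of the
clade the family is still maintained in duplicate (copy count at or above
a threshold, 2 by default).  For a three-species clade the index runs
from 0 ("all singletons") to 3 ("all duplicates").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import FormatError, InputError, ValidationError

logger = logging.getLogger(__name__)

#: Fractionation-resistance category labels, indexed by retention index.
RETENTION_LABELS = (
    "all singletons",
    "mostly singletons",
    "mostly duplicates",
    "all duplicates",
)


@dataclass
class GeneFamily:
    """One gene family: per-species tuples of member gene identifiers.

    The per-species copy count is the length of the member tuple; species
    in which the family was fully lost may simply be absent (count 0).
    """

    family_id: str
    members: dict = field(default_factory=dict)  # species -> tuple of gene ids

    def copy_count(self, species: str) -> int:
        return len(self.members.get(species, ()))

    def counts(self, species: Sequence[str] | None = None) -> dict:
        sp = species if species is not None else list(self.members)
        return {s: self.copy_count(s) for s in sp}


def retention_index(
    family: GeneFamily,
    duplicate_threshold: int = 2,
    species: Sequence[str] | None = None,
) -> int:
    """Number of species in which ``family`` keeps >= threshold copies.

    ``species`` restricts (and orders) the clade; species missing from the
    family count as 0 copies.  A family with no genes at all is invalid.
    """
    if duplicate_threshold < 2:
        raise ValidationError("duplicate_threshold must be >= 2")
    counts = family.counts(species)
    if all(c == 0 for c in family.counts(None).values()) or not family.members:
        raise ValidationError(f"family {family.family_id} has no gene copies in any species")
    return sum(c >= duplicate_threshold for c in counts.values())


def retention_category(index: int, n_species: int = 3) -> str:
    """Map a retention index to its fractionation-resistance label.

    Labels are defined for three-species clades only: 0 -> all singletons,
    1 -> mostly singletons, 2 -> mostly duplicates, 3 -> all duplicates.
    """
    if n_species != 3:
        raise ValidationError("retention categories are defined for 3-species clades")
    if not isinstance(index, (int,)) or isinstance(index, bool):
        try:
            if float(index) != int(index):
                raise ValueError
            index = int(index)
        except (TypeError, ValueError):
            raise ValidationError(f"retention index must be an integer, got {index!r}")
    if not 0 <= index <= n_species:
        raise ValidationError(f"retention index {index} outside 0..{n_species}")
    return RETENTION_LABELS[index]


@dataclass(frozen=True)
class RetentionRecord:
    family_id: str
    retention_index: int
    category_label: str


def retention_records(
    families: Iterable[GeneFamily],
    duplicate_threshold: int = 2,
    species: Sequence[str] | None = None,
) -> list[RetentionRecord]:
    records = []
    for fam in families:
        idx = retention_index(fam, duplicate_threshold, species)
        records.append(RetentionRecord(fam.family_id, idx, retention_category(idx)))
    return records


def tabulate_retention(
    families: Iterable[GeneFamily],
    duplicate_threshold: int = 2,
    species: Sequence[str] | None = None,
) -> pd.Series:
    """Count families per fractionation-resistance category.

    Returns a Series over the four labels in index order (0..3); counts
    sum to the number of families.
    """
    families = list(families)
    if not families:
        raise ValidationError("no gene families to tabulate")
    counts = dict.fromkeys(RETENTION_LABELS, 0)
    for fam in families:
        counts[retention_category(retention_index(fam, duplicate_threshold, species))] += 1
    return pd.Series(counts, name="n_families")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_family_table(path: str | Path, form: str = "auto") -> list[GeneFamily]:
    """Read a gene-family table.

    Long form (default): TSV with columns family_id, species, gene_id —
    one row per gene copy.  Wide form: family_id plus one copy-count
    column per species; placeholder gene identifiers are synthesized.
    ``form='auto'`` picks long when a gene_id column is present.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"family table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if form == "auto":
        form = "long" if "gene_id" in df.columns else "wide"
    if form == "long":
        required = {"family_id", "species", "gene_id"}
        if not required.issubset(df.columns):
            raise FormatError(f"long family table needs columns {sorted(required)}")
        families: dict[str, GeneFamily] = {}
        for fam_id, sub in df.groupby("family_id", sort=True):
            members = {
                sp: tuple(g.gene_id for g in grp.itertuples())
                for sp, grp in sub.groupby("species", sort=True)
            }
            families[fam_id] = GeneFamily(family_id=fam_id, members=members)
        return list(families.values())
    if form == "wide":
        if "family_id" not in df.columns:
            raise FormatError("wide family table needs a family_id column")
        species = [c for c in df.columns if c != "family_id"]
        out = []
        for rec in df.to_dict("records"):
            fam_id = rec["family_id"]
            members = {}
            for sp in species:
                n = int(rec[sp])
                if n < 0:
                    raise FormatError(f"negative copy count for family {fam_id}, {sp}")
                if n:
                    members[sp] = tuple(f"{fam_id}|{sp}|{i + 1}" for i in range(n))
            out.append(GeneFamily(family_id=fam_id, members=members))
        return out
    raise FormatError(f"unknown family table form: {form!r}")


def write_retention_csv(
    records: Iterable[RetentionRecord], path: str | Path
) -> None:
    df = pd.DataFrame(
        [(r.family_id, r.retention_index, r.category_label) for r in records],
        columns=["family_id", "retention_index", "category_label"],
    )
    df.to_csv(path, index=False)


def gene_species_map(families: Iterable[GeneFamily]) -> pd.DataFrame:
    """Flatten families to one row per gene: gene_id, species, family_id."""
    rows = [
        (gene, sp, fam.family_id)
        for fam in families
        for sp, genes in fam.members.items()
        for gene in genes
    ]
    return pd.DataFrame(rows, columns=["gene_id", "species", "family_id"])
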