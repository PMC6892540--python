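"""Master taxonomy construction, name reconciliation, and DNA-sampling typing.

A species-level comparative analysis is only as coherent as the mapping
between sequence labels and accepted species names. This module maintains a
master taxonomy (species -> genus/family/order, extant or recently-extinct
status, provenance), reconciles external name lists against it through a
synonym table, applies add/remove ledgers with full count accounting, and
classifies every species by DNA-sampling type:

  type 1  sampled for >= 1 gene                  (no constraint needed)
  type 2  unsampled, >= 1 sampled congener       (constrain to genus)
  type 3  none in genus, >= 1 sampled confamilial (constrain to family)
  type 4  none in family, >= 1 sampled in order   (constrain to order)

Species with no sampled ordinal relative are reported separately (orphans);
their placement requires an explicitly configured sibling-clade target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "MasterTaxonomy",
    "SynonymTable",
    "TaxonTyping",
    "ReconciliationReport",
    "LedgerSummary",
    "TaxonomyError",
    "reconcile_names",
    "apply_ledger",
    "classify_sampling_types",
]

PROVENANCE_CATEGORIES = (
    "base",
    "added-new",
    "added-domestic",
    "added-extinct",
)

_COLUMNS = ["species", "genus", "family", "order", "status", "provenance"]


class TaxonomyError(ValueError):
    """Raised on ledger or record validation failures."""


@dataclass
class MasterTaxonomy:
    """Species records with rank membership, status, and provenance.

    Backed by a pandas DataFrame with columns
    ``species, genus, family, order, status, provenance``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.table.columns]
        if missing:
            raise TaxonomyError(f"missing columns: {missing}")
        self.table = self.table[_COLUMNS].reset_index(drop=True)
        dupes = self.table["species"][self.table["species"].duplicated()]
        if len(dupes):
            raise TaxonomyError(f"duplicate binomials: {sorted(set(dupes))[:5]}")
        for col in ("genus", "family", "order"):
            if self.table[col].isna().any() or (self.table[col] == "").any():
                raise TaxonomyError(f"every species needs a {col}")

    @classmethod
    def from_records(cls, records) -> "MasterTaxonomy":
        return cls(pd.DataFrame(list(records), columns=_COLUMNS))

    @classmethod
    def read_csv(cls, path) -> "MasterTaxonomy":
        return cls(pd.read_csv(path, dtype=str))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @property
    def species(self) -> list[str]:
        return self.table["species"].tolist()

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, binomial: str) -> bool:
        return binomial in set(self.table["species"])

    def n_extant(self) -> int:
        return int((self.table["status"] == "extant").sum())

    def counts_by_provenance(self) -> dict[str, int]:
        return self.table["provenance"].value_counts().to_dict()


@dataclass
class SynonymTable:
    """Many-to-one mapping of variant names to accepted binomials."""

    pairs: dict[str, str]

    @classmethod
    def from_pairs(cls, pairs) -> "SynonymTable":
        return cls(dict(pairs))

    @classmethod
    def read_csv(cls, path) -> "SynonymTable":
        df = pd.read_csv(path, dtype=str)
        return cls(dict(zip(df["variant"], df["accepted"])))

    def lookup(self, name: str) -> str | None:
        return self.pairs.get(name)


@dataclass
class ReconciliationReport:
    """Outcome of matching an external name list against the master."""

    matched_direct: list[str]
    matched_synonym: list[tuple[str, str]]  # (input name, accepted binomial)
    unmatched: list[str]
    accepted_species: list[str]  # deduplicated, input order of first hit

    @property
    def n_inputs(self) -> int:
        return len(self.matched_direct) + len(self.matched_synonym) + len(self.unmatched)


def _to_binomial(name: str) -> str:
    """Truncate a trinomial (subspecies) to its parent binomial."""
    parts = name.replace("_", " ").split()
    return " ".join(parts[:2]) if len(parts) > 2 else " ".join(parts)


def _is_ambiguous(name: str) -> bool:
    tokens = name.replace("_", " ").lower().split()
    return any(t in {"cf.", "cf", "sp.", "sp", "aff.", "aff"} for t in tokens)


def reconcile_names(
    names,
    syn: SynonymTable,
    master: MasterTaxonomy,
    overrides: dict[str, str] | None = None,
) -> ReconciliationReport:
    """Assign each external name to matched-direct / matched-synonym / unmatched.

    Subspecies (trinomials) are truncated to their parent binomial before
    matching; names with ambiguous epithets ("cf.", "sp.") are flagged
    unmatched unless resolved by the ``overrides`` table. Junior synonyms
    collapse: many inputs can map to one accepted binomial, which appears
    once in ``accepted_species``.
    """
    overrides = overrides or {}
    valid = set(master.species)
    direct: list[str] = []
    via_syn: list[tuple[str, str]] = []
    unmatched: list[str] = []
    accepted: list[str] = []
    seen: set[str] = set()

    def accept(binomial: str) -> None:
        if binomial not in seen:
            seen.add(binomial)
            accepted.append(binomial)

    for raw in names:
        if raw in overrides:
            target = overrides[raw]
            if target in valid:
                via_syn.append((raw, target))
                accept(target)
            else:
                unmatched.append(raw)
            continue
        if _is_ambiguous(raw):
            unmatched.append(raw)
            continue
        name = _to_binomial(raw)
        if name in valid:
            direct.append(raw)
            accept(name)
            continue
        hit = syn.lookup(name) or syn.lookup(raw)
        if hit is not None and hit in valid:
            via_syn.append((raw, hit))
            accept(hit)
        else:
            unmatched.append(raw)

    return ReconciliationReport(direct, via_syn, unmatched, accepted)


@dataclass
class LedgerSummary:
    base_total: int
    added: dict[str, int]
    removed: int
    net_change: int
    final_total: int


def apply_ledger(
    base: MasterTaxonomy,
    additions: dict[str, list[dict]] | None = None,
    removals: list[str] | None = None,
) -> tuple[MasterTaxonomy, LedgerSummary]:
    """Apply categorized additions and removals to a base taxonomy.

    ``additions`` maps a provenance category (``added-new``,
    ``added-domestic``, ``added-extinct``) to lists of species records;
    ``removals`` lists binomials synonymized out of the base list. The
    summary reconciles: final = base + sum(additions) - removals.
    """
    additions = additions or {}
    removals = removals or []
    existing = set(base.species)

    rows = [base.table]
    added_counts: dict[str, int] = {}
    for category, records in additions.items():
        recs = []
        for rec in records:
            rec = dict(rec)
            sp = rec["species"]
            if sp in existing:
                raise TaxonomyError(f"duplicate addition: {sp!r} already present")
            existing.add(sp)
            rec.setdefault("status", "extant")
            rec["provenance"] = category
            recs.append(rec)
        added_counts[category] = len(recs)
        if recs:
            rows.append(pd.DataFrame(recs, columns=_COLUMNS))

    merged = pd.concat(rows, ignore_index=True)
    removal_set = set(removals)
    present = set(merged["species"])
    missing = removal_set - present
    if missing:
        raise TaxonomyError(f"removal of absent species: {sorted(missing)}")
    merged = merged[~merged["species"].isin(removal_set)]

    final = MasterTaxonomy(merged.reset_index(drop=True))
    summary = LedgerSummary(
        base_total=len(base),
        added=added_counts,
        removed=len(removal_set),
        net_change=sum(added_counts.values()) - len(removal_set),
        final_total=len(final),
    )
    assert summary.final_total == summary.base_total + summary.net_change
    return final, summary


@dataclass
class TaxonTyping:
    """Per-species DNA-sampling type and taxonomic constraint target."""

    table: pd.DataFrame  # columns: species, type, rank, target
    orphans: list[str] = field(default_factory=list)

    def type_of(self, species: str) -> int:
        row = self.table.loc[self.table["species"] == species]
        if row.empty:
            raise KeyError(species)
        return int(row["type"].iloc[0])

    def counts(self) -> dict[int, int]:
        """Counts per type, with orphans (no sampled ordinal relative) excluded
        from type 4 — they are reported via :attr:`orphans`."""
        sub = self.table.loc[~self.table["orphan"]]
        return {int(k): int(v) for k, v in sub["type"].value_counts().items()}

    def missing_species(self) -> list[str]:
        return self.table.loc[self.table["type"] > 1, "species"].tolist()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def classify_sampling_types(
    master: MasterTaxonomy,
    dna_sampled,
    orphan_targets: dict[str, str] | None = None,
) -> TaxonTyping:
    """Classify every species by DNA-sampling type 1-4.

    ``orphan_targets`` optionally maps an order name to a configured
    sibling-clade target for species with no sampled ordinal relative;
    such species are still listed as orphans but carry that target at rank
    ``order``.
    """
    sampled = set(dna_sampled)
    unknown = sampled - set(master.species)
    if unknown:
        raise TaxonomyError(f"dna_sampled not in master: {sorted(unknown)[:5]}")
    orphan_targets = orphan_targets or {}

    t = master.table
    genus_sampled = set(t.loc[t["species"].isin(sampled), "genus"])
    family_sampled = set(t.loc[t["species"].isin(sampled), "family"])
    order_sampled = set(t.loc[t["species"].isin(sampled), "order"])

    rows = []
    orphans: list[str] = []
    for sp, genus, family, order in zip(
        t["species"], t["genus"], t["family"], t["order"]
    ):
        if sp in sampled:
            rows.append((sp, 1, "none", "", False))
        elif genus in genus_sampled:
            rows.append((sp, 2, "genus", genus, False))
        elif family in family_sampled:
            rows.append((sp, 3, "family", family, False))
        elif order in order_sampled:
            rows.append((sp, 4, "order", order, False))
        else:
            orphans.append(sp)
            target = orphan_targets.get(order, "")
            rows.append((sp, 4, "order", target, True))

    table = pd.DataFrame(
        rows, columns=["species", "type", "rank", "target", "orphan"]
    )
    return TaxonTyping(table, orphans)
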