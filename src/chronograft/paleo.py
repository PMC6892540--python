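"""Fossil-occurrence summaries and zombie-lineage screening.

Per-clade "fossil stem maximum" ages are derived from genus-level
occurrence tables (Paleobiology Database export style): ichnotaxa and
occurrences with uncertain genus assignments are excluded, remaining rows
are grouped by genus, and the oldest per-genus maximum stratigraphic age
within the clade is reported.

A "zombie lineage" is a clade whose molecular crown-age interval lies
entirely below a fossil-implied minimum age for that crown — the fossils
say the crown must be older than the molecules allow. The conflict is
flagged when the HPD upper bound is strictly younger than the fossil
minimum, and its magnitude is reported conservatively from that upper
bound (and additionally from the posterior mean age when supplied).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "OccurrenceTable",
    "ZombieResult",
    "PaleoError",
    "max_stem_age",
    "zombie_check",
]


class PaleoError(ValueError):
    pass


_OCC_COLUMNS = ["genus", "clade", "min_ma", "max_ma", "ichnotaxon", "uncertain_genus"]


@dataclass
class OccurrenceTable:
    """Genus-level fossil occurrences with stratigraphic age ranges."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _OCC_COLUMNS if c not in self.table.columns]
        if missing:
            raise PaleoError(f"missing occurrence columns: {missing}")
        t = self.table
        if (t["min_ma"] < 0).any() or (t["max_ma"] < t["min_ma"]).any():
            raise PaleoError("need max_ma >= min_ma >= 0 in every row")

    @classmethod
    def from_records(cls, records) -> "OccurrenceTable":
        return cls(pd.DataFrame(list(records), columns=_OCC_COLUMNS))

    @classmethod
    def read_pbdb_csv(cls, path) -> "OccurrenceTable":
        """Read a PBDB-style occurrence export.

        Expects columns ``genus``, ``order`` (used as the clade), ``max_ma``,
        ``min_ma``; flags are derived from the identification qualifiers in
        ``flags``/``difference`` columns when present (``ichno`` marks
        ichnotaxa; a ``?`` or ``cf.`` in the genus qualifier marks an
        uncertain genus).
        """
        df = pd.read_csv(path)
        flags = df.get("flags", pd.Series([""] * len(df))).fillna("").astype(str)
        qualifier = (
            df.get("primary_reso", pd.Series([""] * len(df))).fillna("").astype(str)
        )
        out = pd.DataFrame(
            {
                "genus": df["genus"],
                "clade": df["order"],
                "min_ma": df["min_ma"].astype(float),
                "max_ma": df["max_ma"].astype(float),
                "ichnotaxon": flags.str.contains("ichno", case=False),
                "uncertain_genus": qualifier.str.contains(r"\?|cf\.|aff\.", regex=True),
            }
        )
        return cls(out)

    def filtered(self) -> pd.DataFrame:
        t = self.table
        return t.loc[~t["ichnotaxon"] & ~t["uncertain_genus"]]

    def __len__(self) -> int:
        return len(self.table)


def max_stem_age(occ: OccurrenceTable, clade: str) -> float | None:
    """Oldest per-genus maximum stratigraphic age within a clade.

    Ichnotaxa and uncertain genera are excluded first; returns ``None`` when
    the clade has no usable occurrences (an explicit no-data result).
    """
    sub = occ.filtered()
    sub = sub.loc[sub["clade"] == clade]
    if sub.empty:
        return None
    per_genus = sub.groupby("genus")["max_ma"].max()
    return float(per_genus.max())


@dataclass
class ZombieResult:
    flagged: bool
    magnitude: float  # fossil_min - hpd_hi when flagged, else 0
    magnitude_from_mean: float | None = None


def zombie_check(
    crown_hpd: tuple[float, float],
    fossil_min: float,
    crown_mean: float | None = None,
) -> ZombieResult:
    """Flag a molecular crown age younger than a fossil-implied minimum.

    Flagged iff the HPD upper bound is strictly below ``fossil_min``; the
    magnitude is how far the fossil minimum exceeds that bound (zero when
    not flagged). Depends only on the upper bound, never the lower.
    """
    lo, hi = crown_hpd
    if hi < lo:
        raise PaleoError("HPD interval must satisfy hi >= lo")
    flagged = hi < fossil_min
    magnitude = fossil_min - hi if flagged else 0.0
    from_mean = None
    if crown_mean is not None:
        from_mean = max(0.0, fossil_min - crown_mean) if flagged else 0.0
    return ZombieResult(flagged, magnitude, from_mean)
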