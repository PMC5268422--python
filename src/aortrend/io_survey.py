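"""Catch-table ingestion and community selection for trawl-survey data.

The survey data model is a long-format table of tow-level catches
(region, year, tow, species, count) plus a *tow roster*: the full set of
tow identifiers per region-year, so that tows in which a species caught
nothing are recoverable as explicit zeros.  Occupancy denominators and
negative-binomial fits both require those zeros.

Community membership within a region is decided once, for all years, by
the ranked selection index

    S_i = H_i / H_max + y_i / y_tot

where ``H_i`` is species *i*'s total catch over all survey years,
``H_max`` the regional maximum of those totals, ``y_i`` the number of
surveyed years in which the species was caught at least once, and
``y_tot`` the total number of surveyed years.  S lies in (0, 2]; the top
``n`` species (default 30) form the community.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("region", "year", "tow", "species", "count")


class CatchTableError(ValueError):
    """Malformed or invalid catch-table input."""


@dataclass
class CatchTable:
    """Validated long-format catch records plus per-(region, year) tow roster.

    ``records`` holds one row per (region, year, tow, species) with a
    non-negative integer count; zero-count rows are dropped after their tows
    are folded into the roster.  ``tow_roster`` maps (region, year) to the
    sorted tuple of all tow identifiers sampled that year, a superset of the
    tows appearing in ``records``.
    """

    records: pd.DataFrame
    tow_roster: dict[tuple[str, int], tuple[str, ...]] = field(default_factory=dict)

    @property
    def regions(self) -> list[str]:
        return sorted({r for r, _ in self.tow_roster})

    def years(self, region: str) -> list[int]:
        ys = sorted(y for r, y in self.tow_roster if r == region)
        if not ys:
            raise KeyError(f"unknown region {region!r}")
        return ys

    def species(self, region: str) -> list[str]:
        sub = self.records[self.records["region"] == region]
        return sorted(sub["species"].unique())

    def n_tows(self, region: str, year: int) -> int:
        return len(self.tow_roster[(region, year)])

    def counts_vector(self, region: str, year: int, species: str) -> np.ndarray:
        """Counts of ``species`` over the full tow roster (zeros included)."""
        roster = self.tow_roster[(region, year)]
        sub = self.records[
            (self.records["region"] == region)
            & (self.records["year"] == year)
            & (self.records["species"] == species)
        ]
        by_tow = dict(zip(sub["tow"], sub["count"]))
        return np.array([by_tow.get(t, 0) for t in roster], dtype=np.int64)

    def year_matrix(self, region: str, year: int, species: list[str]) -> np.ndarray:
        """Species x tows count matrix over the full roster for one year."""
        roster = self.tow_roster[(region, year)]
        tow_index = {t: j for j, t in enumerate(roster)}
        mat = np.zeros((len(species), len(roster)), dtype=np.int64)
        sp_index = {s: i for i, s in enumerate(species)}
        sub = self.records[
            (self.records["region"] == region) & (self.records["year"] == year)
        ]
        for sp, tow, count in zip(sub["species"], sub["tow"], sub["count"]):
            i = sp_index.get(sp)
            if i is not None:
                mat[i, tow_index[tow]] = count
        return mat


@dataclass(frozen=True)
class SpeciesScore:
    """One species' selection-index components and score for a region."""

    species: str
    H_i: int
    H_max: int
    y_i: int
    y_tot: int
    S: float


def _validate_records(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CatchTableError(f"missing required column(s): {', '.join(missing)}")
    df = df.loc[:, list(REQUIRED_COLUMNS)].copy()

    count_num = pd.to_numeric(df["count"], errors="coerce")
    bad = count_num.isna() | (count_num != count_num.round()) | (count_num < 0)
    if bad.any():
        row = int(df.index[bad][0])
        raise CatchTableError(
            f"count must be a non-negative integer; offending row index {row} "
            f"(count={df['count'].iloc[int(np.flatnonzero(bad.to_numpy())[0])]!r})"
        )
    df["count"] = count_num.astype(np.int64)

    year_num = pd.to_numeric(df["year"], errors="coerce")
    if year_num.isna().any() or (year_num != year_num.round()).any():
        row = int(df.index[year_num.isna() | (year_num != year_num.round())][0])
        raise CatchTableError(f"year must be an integer; offending row index {row}")
    df["year"] = year_num.astype(np.int64)
    df["region"] = df["region"].astype(str)
    df["tow"] = df["tow"].astype(str)
    df["species"] = df["species"].astype(str)
    return df


def build_catch_table(
    df: pd.DataFrame,
    tow_roster: dict[tuple[str, int], tuple[str, ...]] | None = None,
) -> CatchTable:
    """Validate a raw records frame and assemble a :class:`CatchTable`.

    Duplicate (region, year, tow, species) rows are summed — raw survey
    exports often split a haul across length or sex classes.  Zero-count
    rows contribute their tow to the roster but are dropped from records.
    """
    df = _validate_records(df)

    # roster must see every sampled tow, including tows present only via
    # zero-count rows
    observed: dict[tuple[str, int], set[str]] = {}
    for region, year, tow in zip(df["region"], df["year"], df["tow"]):
        observed.setdefault((str(region), int(year)), set()).add(str(tow))

    df = df[df["count"] > 0]
    df = (
        df.groupby(["region", "year", "tow", "species"], as_index=False)["count"]
        .sum()
        .sort_values(["region", "year", "tow", "species"], kind="stable")
        .reset_index(drop=True)
    )

    if tow_roster is None:
        roster = {key: tuple(sorted(tows)) for key, tows in observed.items()}
    else:
        roster = {k: tuple(sorted(v)) for k, v in tow_roster.items()}
        for key, tows in observed.items():
            if key not in roster:
                raise CatchTableError(f"roster missing (region, year)={key}")
            extra = tows - set(roster[key])
            if extra:
                raise CatchTableError(
                    f"tows {sorted(extra)} in records but not in roster for {key}"
                )
    return CatchTable(records=df, tow_roster=roster)


def read_catch_table(path, tow_roster_path=None) -> CatchTable:
    """Read a catch CSV (columns region, year, tow, species, count).

    The optional roster CSV carries either explicit tow lists
    (region, year, tow) or per-year tow counts (region, year, n_tows);
    with counts, synthetic identifiers ``t001..`` are generated.  Without
    a roster, the roster is inferred as the distinct tows observed —
    which understates effort only if some tow caught none of the listed
    species, so supplying a roster file is recommended.
    """
    df = pd.read_csv(path)
    roster = _read_roster(tow_roster_path) if tow_roster_path is not None else None
    return build_catch_table(df, roster)


def _read_roster(path) -> dict[tuple[str, int], tuple[str, ...]]:
    df = pd.read_csv(path)
    if {"region", "year", "tow"} <= set(df.columns):
        roster: dict[tuple[str, int], set[str]] = {}
        for region, year, tow in zip(df["region"], df["year"], df["tow"]):
            roster.setdefault((str(region), int(year)), set()).add(str(tow))
        return {k: tuple(sorted(v)) for k, v in roster.items()}
    if {"region", "year", "n_tows"} <= set(df.columns):
        out = {}
        for region, year, n in zip(df["region"], df["year"], df["n_tows"]):
            n = int(n)
            width = max(3, len(str(n)))
            out[(str(region), int(year))] = tuple(
                f"t{j + 1:0{width}d}" for j in range(n)
            )
        return out
    raise CatchTableError(
        "roster CSV needs columns (region, year, tow) or (region, year, n_tows)"
    )


def write_catch_table(table: CatchTable, path, roster_path=None) -> None:
    """Write records (and optionally the explicit tow roster) as CSV."""
    table.records.to_csv(path, index=False)
    if roster_path is not None:
        rows = [
            {"region": r, "year": y, "tow": t}
            for (r, y), tows in sorted(table.tow_roster.items())
            for t in tows
        ]
        pd.DataFrame(rows, columns=["region", "year", "tow"]).to_csv(
            roster_path, index=False
        )


def selection_index(table: CatchTable, region: str) -> list[SpeciesScore]:
    """Score every species ever caught in ``region`` by S = H_i/H_max + y_i/y_tot.

    Returned sorted by S descending, ties broken by species label ascending.
    """
    sub = table.records[table.records["region"] == region]
    if sub.empty:
        raise KeyError(f"unknown or empty region {region!r}")
    y_tot = len(table.years(region))
    totals = sub.groupby("species")["count"].sum()
    years_present = sub.groupby("species")["year"].nunique()
    h_max = int(totals.max())
    scores = [
        SpeciesScore(
            species=sp,
            H_i=int(totals[sp]),
            H_max=h_max,
            y_i=int(years_present[sp]),
            y_tot=y_tot,
            S=float(totals[sp]) / h_max + float(years_present[sp]) / y_tot,
        )
        for sp in totals.index
    ]
    return sorted(scores, key=lambda sc: (-sc.S, sc.species))


def select_community(
    scores: list[SpeciesScore], n: int = 30, allow_fewer: bool = False
) -> list[str]:
    """Top-``n`` species by S; the same set serves every year of the region.

    Ties spanning rank ``n`` are resolved by species label ascending so the
    selection is deterministic across runs and input orderings.
    """
    if n < 2:
        raise ValueError("community size n must be >= 2")
    ordered = sorted(scores, key=lambda sc: (-sc.S, sc.species))
    if len(ordered) < n:
        if not allow_fewer:
            raise ValueError(
                f"only {len(ordered)} species scored but n={n}; "
                "pass allow_fewer=True to accept all"
            )
        logger.warning(
            "only %d species available for requested community of %d",
            len(ordered),
            n,
        )
        return [sc.species for sc in ordered]
    return [sc.species for sc in ordered[:n]]
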