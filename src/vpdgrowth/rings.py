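"""Ring-width series I/O, basal-area-increment conversion and site summaries.

Units: ring widths in mm, radii in cm, basal area and increments in cm^2.
Tucson (rwl) files are read and written in both common dialects, detected
from the stop marker: 999 means 0.01 mm precision, -9999 means 0.001 mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RingSeries",
    "BAISeries",
    "read_rwl",
    "write_rwl",
    "read_long_csv",
    "write_long_csv",
    "widths_to_bai",
    "apply_juvenile_filter",
    "site_summary",
]


class RwlFormatError(ValueError):
    """Malformed Tucson file."""


@dataclass
class RingSeries:
    """One tree's contiguous, dated annual ring widths (mm)."""

    tree_id: str
    widths: np.ndarray
    first_year: int
    site_id: str | None = None
    species: str | None = None
    pith_present: bool | None = None
    pith_offset_mm: float = 0.0

    def __post_init__(self):
        self.widths = np.asarray(self.widths, dtype=float)
        if self.widths.ndim != 1 or len(self.widths) < 1:
            raise ValueError(f"series {self.tree_id}: need >= 1 ring width")
        if np.any(self.widths <= 0):
            raise ValueError(f"series {self.tree_id}: ring widths must be positive")

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.widths) - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)

    def __len__(self) -> int:
        return len(self.widths)


@dataclass
class BAISeries:
    """Per-year basal area increments derived from one ring series.

    ``bai[t] = pi * (R_t^2 - R_{t-1}^2)`` with radii accumulated from the
    innermost measured ring; ``ba_prev`` is the cumulative basal area at
    the start of each year and ``age`` counts years since the innermost
    measured ring (ring-count age, never re-zeroed by filtering).
    """

    tree_id: str
    years: np.ndarray
    bai: np.ndarray
    ba_prev: np.ndarray
    age: np.ndarray
    site_id: str | None = None
    species: str | None = None
    excluded: bool = False
    exclusion_reason: str | None = None
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.bai)

    @property
    def final_ba(self) -> float:
        """Basal area (cm^2) after the last retained ring."""
        return float(self.ba_prev[-1] + self.bai[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "tree_id": self.tree_id,
            "site_id": self.site_id,
            "species": self.species,
            "year": self.years,
            "bai": self.bai,
            "ba_prev": self.ba_prev,
            "age": self.age,
        })


# ---------------------------------------------------------------------------
# Tucson / rwl format


def read_rwl(path) -> list[RingSeries]:
    """Read a Tucson-format ring width file.

    Width precision (0.01 vs 0.001 mm) is auto-detected per series from
    the *terminal* stop marker (999 vs -9999); 999 earlier in a series is
    a legitimate value.  Duplicate series identifiers and malformed
    decade rows raise :class:`RwlFormatError` with line numbers.
    """
    raw: dict[str, list[tuple[int, list[int], int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        lines = fh.readlines()
    if not any(line.strip() for line in lines):
        warnings.warn(f"{path}: empty rwl file", stacklevel=2)
        return []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        sid = line[:8].strip()
        rest = line[8:].split()
        if not sid or not rest:
            raise RwlFormatError(f"{path}:{lineno}: cannot parse series id / decade")
        try:
            decade = int(rest[0])
        except ValueError as exc:
            raise RwlFormatError(f"{path}:{lineno}: bad decade year {rest[0]!r}") from exc
        tokens = rest[1:]
        if not tokens:
            raise RwlFormatError(f"{path}:{lineno}: decade row with no values")
        vals = []
        for tok in tokens:
            try:
                vals.append(int(tok))
            except ValueError as exc:
                raise RwlFormatError(f"{path}:{lineno}: bad width token {tok!r}") from exc
        if sid not in raw:
            raw[sid] = []
            order.append(sid)
        raw[sid].append((decade, vals, lineno))
    out = []
    for sid in order:
        chunks = sorted(raw[sid], key=lambda c: c[0])
        if len({c[0] for c in chunks}) != len(chunks):
            raise RwlFormatError(f"{path}: duplicate decade rows for series {sid!r}")
        first_year = chunks[0][0]
        values: list[int] = []
        expect = first_year
        for decade, vals, lineno in chunks:
            if decade != expect:
                raise RwlFormatError(
                    f"{path}:{lineno}: series {sid!r} non-contiguous decade row "
                    f"(expected start {expect}, got {decade})"
                )
            values.extend(vals)
            # the stop marker closes the series but occupies no year slot
            n_data = len(vals) - (1 if vals and vals[-1] in (999, -9999) else 0)
            expect = decade + n_data
        if values and values[-1] == -9999:
            prec, values = 0.001, values[:-1]
        elif values and values[-1] == 999:
            prec, values = 0.01, values[:-1]
        else:
            warnings.warn(f"{path}: series {sid!r} has no stop marker; assuming 0.01 mm")
            prec = 0.01
        widths = np.array(values, dtype=float) * prec
        out.append(RingSeries(tree_id=sid, widths=widths, first_year=first_year))
    return out


def write_rwl(series_list: list[RingSeries], path, precision: float = 0.001) -> None:
    """Write series to a Tucson file at 0.001 or 0.01 mm precision."""
    if precision not in (0.001, 0.01):
        raise ValueError("precision must be 0.001 or 0.01 mm")
    if not series_list:
        raise ValueError("refusing to write an empty rwl file")
    stop = "-9999" if precision == 0.001 else "999"
    with open(path, "w") as fh:
        for rs in series_list:
            sid = str(rs.tree_id)[:8]
            scaled = np.rint(rs.widths / precision).astype(int)
            limit = 99999 if precision == 0.001 else 999 - 1
            if np.any(scaled > limit):
                raise ValueError(
                    f"series {rs.tree_id}: width too large for {precision} mm rwl dialect"
                )
            scaled = np.maximum(scaled, 1)  # zero after rounding would read as missing
            year = rs.first_year
            vals = scaled.tolist() + [stop]
            i = 0
            while i < len(vals):
                row_start = year + i
                # rows break at decade boundaries
                n = 10 - (row_start % 10) if row_start % 10 else 10
                chunk = vals[i:i + n]
                fields = "".join(f"{v:>6}" for v in chunk)
                fh.write(f"{sid:<8}{row_start:>4}{fields}\n")
                i += n


def read_long_csv(path) -> list[RingSeries]:
    """Read a long-format CSV: tree_id,site_id,species,year,width_mm."""
    df = pd.read_csv(path)
    out = []
    for tid, grp in df.groupby("tree_id", sort=True):
        grp = grp.sort_values("year")
        yrs = grp["year"].to_numpy()
        if len(yrs) > 1 and not np.all(np.diff(yrs) == 1):
            raise ValueError(f"tree {tid}: non-contiguous years in long CSV")
        out.append(RingSeries(
            tree_id=str(tid),
            widths=grp["width_mm"].to_numpy(),
            first_year=int(yrs[0]),
            site_id=str(grp["site_id"].iloc[0]) if "site_id" in grp else None,
            species=str(grp["species"].iloc[0]) if "species" in grp else None,
        ))
    return out


def write_long_csv(series_list: list[RingSeries], path) -> None:
    frames = [
        pd.DataFrame({
            "tree_id": rs.tree_id,
            "site_id": rs.site_id,
            "species": rs.species,
            "year": rs.years,
            "width_mm": rs.widths,
        })
        for rs in series_list
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# BAI conversion and filtering


def widths_to_bai(rs: RingSeries) -> BAISeries:
    """Convert ring widths (mm) to annual basal area increments (cm^2).

    Radii accumulate from the innermost measured ring (plus an optional
    pith offset, default 0).  The telescoping identity
    ``sum(bai) = pi * (R_end^2 - R_start^2)`` holds exactly.
    """
    r0 = rs.pith_offset_mm / 10.0
    radii = r0 + np.cumsum(rs.widths) / 10.0  # cm
    r_prev = np.concatenate([[r0], radii[:-1]])
    bai = np.pi * (radii**2 - r_prev**2)
    ba_prev = np.pi * r_prev**2
    age = np.arange(1, len(rs.widths) + 1)
    return BAISeries(
        tree_id=rs.tree_id, years=rs.years, bai=bai, ba_prev=ba_prev, age=age,
        site_id=rs.site_id, species=rs.species,
    )


def apply_juvenile_filter(bs: BAISeries, n_exclude: int = 10,
                          min_retained_years: int = 25) -> BAISeries:
    """Drop the first ``n_exclude`` rings (juvenile growth).

    Ages keep counting from the innermost measured ring and retained
    ``ba_prev`` values still include the juvenile radius.  Trees left with
    fewer than ``min_retained_years`` rings are flagged excluded (never
    raised)."""
    if n_exclude < 0:
        raise ValueError("n_exclude must be >= 0")
    k = min(n_exclude, len(bs))
    out = BAISeries(
        tree_id=bs.tree_id,
        years=bs.years[k:].copy(),
        bai=bs.bai[k:].copy(),
        ba_prev=bs.ba_prev[k:].copy(),
        age=bs.age[k:].copy(),
        site_id=bs.site_id,
        species=bs.species,
        meta=dict(bs.meta, n_juvenile_excluded=k, total_rings=len(bs)),
    )
    if len(out) < min_retained_years:
        out.excluded = True
        out.exclusion_reason = (
            f"insufficient rings: {len(out)} retained < {min_retained_years} required"
        )
    return out


def site_summary(bai_list: list[BAISeries], site_meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per site-species mean ring-count age, mean final basal area, tree count.

    Age is the total ring count of each tree (minimum age from ring
    counts, including any juvenile rings recorded in ``meta``)."""
    rows = []
    for bs in bai_list:
        if bs.excluded:
            continue
        rows.append({
            "site_id": bs.site_id,
            "species": bs.species,
            "tree_id": bs.tree_id,
            "age": bs.meta.get("total_rings", int(bs.age[-1])),
            "final_ba": bs.final_ba,
        })
    if not rows:
        return pd.DataFrame(columns=["site_id", "species", "n_trees", "mean_age", "mean_ba"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["site_id", "species"], dropna=False)
        .agg(n_trees=("tree_id", "count"), mean_age=("age", "mean"), mean_ba=("final_ba", "mean"))
        .reset_index()
    )
    if site_meta is not None:
        out = out.merge(site_meta, on="site_id", how="left")
    return out
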