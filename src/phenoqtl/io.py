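"""Delimited-text readers and writers for phenology, environment and
genotype tables.

All tables are plain comma- or tab-separated text (auto-detected between
those two only; anything else is an error, not a guess).  Dates are
accepted either as integer day offsets or as ISO-8601 calendar dates; the
internal representation is always integer offsets from a reference date
(the earliest germination by default), and the conversion is logged.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np
import pandas as pd

from .photothermal import EnvironmentSeries
from .qtl import GeneticMap, RILGenotypes, _CHAR_TO_CODE
from ._log import RunLog

__all__ = [
    "PHENOLOGY_COLUMNS",
    "read_phenology",
    "write_phenology",
    "read_environment",
    "write_environment",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
]

#: Date columns of the on-disk phenology layout, in event order.
_DATE_COLUMNS = {
    "germination_date": "germination",
    "bolting_date": "bolting",
    "flowering_init_date": "flowering_init",
    "flowering_term_date": "flowering_term",
    "senescence_date": "senescence",
}
PHENOLOGY_COLUMNS = [
    "plant_id",
    "accession",
    "regime",
    "cohort",
    *_DATE_COLUMNS,
    "leaves_at_bolting",
    "rosette_diameter_mm",
    "fruit_count",
]
_EVENT_ORDER = list(_DATE_COLUMNS.values())


def _sniff_sep(path: Path) -> str:
    first = Path(path).open().readline()
    if "\t" in first:
        return "\t"
    if "," in first:
        return ","
    raise ValueError(f"{path}: only comma- or tab-delimited files are accepted")


def _parse_dates(col: pd.Series, reference: _dt.date | None):
    """Integer offsets pass through; ISO dates become offsets from reference."""
    numeric = pd.to_numeric(col, errors="coerce")
    if numeric.notna().sum() == col.notna().sum():
        return numeric.astype(float), reference, False
    parsed = pd.to_datetime(col, format="ISO8601", errors="raise")
    if reference is None:
        reference = parsed.min().date()
    offsets = (parsed - pd.Timestamp(reference)).dt.days.astype(float)
    return offsets, reference, True


def read_phenology(path, log: RunLog | None = None) -> pd.DataFrame:
    """Read a phenology table (one row per plant) and validate it.

    Rows whose present events violate the ordering
    germination <= bolting <= flowering initiation <= termination <=
    senescence are rejected with their (1-based, header-exclusive) row
    numbers; duplicate plant ids are rejected too.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in PHENOLOGY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    dupes = df.loc[df["plant_id"].duplicated(), "plant_id"].tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate plant id(s) {dupes}")

    reference = None
    iso_any = False
    for disk, mem in _DATE_COLUMNS.items():
        try:
            df[mem], reference, iso = _parse_dates(df[disk], reference)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: unparseable dates in column {disk!r}: {exc}") from None
        iso_any = iso_any or iso
    df = df.drop(columns=list(_DATE_COLUMNS))

    events = df[_EVENT_ORDER].to_numpy(float)
    bad_rows = []
    for i in range(events.shape[0]):
        present = events[i][~np.isnan(events[i])]
        if np.any(np.diff(present) < 0):
            bad_rows.append(i + 1)
    if bad_rows:
        raise ValueError(f"{path}: event ordering violated in row(s) {bad_rows}")

    if log is not None:
        log.event(
            "read_phenology",
            path=str(path),
            rows=len(df),
            delimiter="tab" if sep == "\t" else "comma",
            dates="iso8601" if iso_any else "offsets",
            reference_date=str(reference) if reference else None,
        )
    return df


def write_phenology(df: pd.DataFrame, path, force: bool = False) -> None:
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    out = df.copy()
    for disk, mem in _DATE_COLUMNS.items():
        out[disk] = out[mem]
    out = out[[c for c in PHENOLOGY_COLUMNS if c in out.columns]]
    out.to_csv(path, index=False)


def read_environment(
    path, mode: str = "daily", daylight_path=None, label: str = "", log: RunLog | None = None
) -> EnvironmentSeries:
    """Read a daily environment table, or aggregate a raw logger file.

    Daily mode expects columns day, mean_daylight_temp, photoperiod_hours.
    Logger mode expects columns day, hour, temp plus a separate daylight
    table (day, sunrise, sunset) and routes through the daylight-window
    aggregation; days with no daylight reading are a hard error here.
    """
    from .photothermal import daylight_mean_from_log

    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep)
    if mode == "daily":
        need = {"day", "mean_daylight_temp", "photoperiod_hours"}
        if not need.issubset(df.columns):
            raise ValueError(f"{path}: daily mode needs columns {sorted(need)}")
        days = df["day"].to_numpy()
        jumps = np.flatnonzero(np.diff(days) != 1)
        if jumps.size:
            gaps = [f"{days[j]}..{days[j + 1]}" for j in jumps]
            raise ValueError(f"{path}: non-contiguous days; gap(s) at {gaps}")
        series = EnvironmentSeries(
            day=days,
            temp=df["mean_daylight_temp"].to_numpy(float),
            photoperiod=df["photoperiod_hours"].to_numpy(float),
            label=label,
        )
    elif mode == "logger":
        if daylight_path is None:
            raise ValueError("logger mode needs a daylight table (day, sunrise, sunset)")
        daylight = pd.read_csv(Path(daylight_path), sep=_sniff_sep(Path(daylight_path)))
        series, gaps = daylight_mean_from_log(df, daylight, label=label)
        if gaps:
            raise ValueError(f"{path}: no daylight readings on day(s) {gaps}")
    else:
        raise ValueError(f"unknown environment mode {mode!r}")
    if log is not None:
        log.event("read_environment", path=str(path), mode=mode, days=int(series.day.size))
    return series


def write_environment(series: EnvironmentSeries, path, force: bool = False) -> None:
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    series.to_frame().to_csv(path, index=False)


def read_genotypes(path, log: RunLog | None = None) -> tuple[GeneticMap, RILGenotypes]:
    """Read a rotated genotype file: rows = markers, columns = lines.

    Layout: columns ``marker, chromosome, pos_cm`` followed by one column
    per line holding codes A/B/- (missing also accepted as NA or empty).
    Markers are sorted by (chromosome order of appearance, position) with
    a log event if re-sorting was needed.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype={"chromosome": str})
    need = ["marker", "chromosome", "pos_cm"]
    if df.columns[:3].tolist() != need:
        raise ValueError(f"{path}: first columns must be {need}")
    line_ids = df.columns[3:].tolist()
    if not line_ids:
        raise ValueError(f"{path}: no line columns found")

    sorted_df = df.sort_values(
        ["chromosome", "pos_cm"],
        key=lambda s: s.map({c: i for i, c in enumerate(dict.fromkeys(df["chromosome"]))})
        if s.name == "chromosome"
        else s,
        kind="stable",
    ).reset_index(drop=True)
    resorted = not sorted_df["marker"].equals(df["marker"].reset_index(drop=True))
    df = sorted_df

    codes = np.full((len(line_ids), len(df)), -1, dtype=np.int8)
    raw = df[line_ids].to_numpy(dtype=object).T  # lines x markers
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                continue
            cell = str(cell).strip()
            if cell in ("", "NA", "-"):
                continue
            if cell not in _CHAR_TO_CODE:
                raise ValueError(
                    f"{path}: unknown allele code {cell!r} for line {line_ids[i]!r}, "
                    f"marker {df['marker'].iat[j]!r}"
                )
            codes[i, j] = _CHAR_TO_CODE[cell]

    gmap = GeneticMap(df[need].copy())
    geno = RILGenotypes(line_ids=line_ids, matrix=codes, map=gmap)
    if log is not None:
        log.event(
            "read_genotypes",
            path=str(path),
            lines=len(line_ids),
            markers=gmap.n_markers,
            resorted=resorted,
        )
    return gmap, geno


def write_genotypes(geno: RILGenotypes, path, force: bool = False) -> None:
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    chars = geno.to_char()
    cols = {lid: chars[i, :] for i, lid in enumerate(geno.line_ids)}
    out = pd.concat(
        [geno.map.table.reset_index(drop=True), pd.DataFrame(cols)], axis=1
    )
    out.to_csv(path, index=False)


def read_phenotypes(path, trait: str | None = None, log: RunLog | None = None) -> pd.Series:
    """Read a line-phenotype table: column ``line_id`` plus one column per trait."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    if "line_id" not in df.columns:
        raise ValueError(f"{path}: needs a line_id column")
    traits = [c for c in df.columns if c != "line_id"]
    if not traits:
        raise ValueError(f"{path}: no trait columns")
    if trait is None:
        trait = traits[0]
    if trait not in traits:
        raise ValueError(f"{path}: trait {trait!r} not among {traits}")
    if log is not None:
        log.event("read_phenotypes", path=str(path), trait=trait, lines=len(df))
    s = df.set_index("line_id")[trait].astype(float)
    s.name = trait
    return s


def write_phenotypes(means: pd.Series, path, force: bool = False) -> None:
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    means.rename_axis("line_id").reset_index().to_csv(path, index=False)
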