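"""Readers and writers for the tabular and grid input formats.

All tables are comma-separated UTF-8 with a required header row and "."
decimals.  Empty cells denote missing values (e.g. an unavailable LD50).
Land cover is read from an ESRI ASCII grid (.asc) plus a class-map CSV
(code,name,group).
"""

from __future__ import annotations

import logging
from datetime import date
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    CompoundTox,
    LandCoverClass,
    LandCoverGrid,
    PesticideClass,
    PollenSample,
    ResidueRecord,
    SprayEvent,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_toxdb",
    "write_toxdb",
    "default_toxdb",
    "load_survey_residues",
    "read_residues",
    "write_residues",
    "read_sprays",
    "write_sprays",
    "read_pollen",
    "write_pollen",
    "read_classmap",
    "read_grid",
    "write_grid",
    "read_sites",
    "write_sites",
]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


# ---------------------------------------------------------------------------
# toxicity database

def read_toxdb(path) -> dict[str, CompoundTox]:
    """Read a compound toxicity table keyed by compound name.

    Schema: compound,pclass,contact_ld50_ug_per_bee,oral_ld50_ug_per_bee.
    Empty LD50 cells are preserved as missing (None), never as zero.
    Duplicate compound names and non-positive LD50s are hard errors.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(
        df, ["compound", "pclass", "contact_ld50_ug_per_bee", "oral_ld50_ug_per_bee"], path
    )
    out: dict[str, CompoundTox] = {}
    for i, row in df.iterrows():
        name = str(row["compound"]).strip()
        if name in out:
            raise ValueError(f"{path}: duplicate compound {name!r} (row {i + 2})")
        try:
            rec = CompoundTox(
                name=name,
                pclass=PesticideClass(str(row["pclass"]).strip().lower()),
                contact_ld50=None if pd.isna(row["contact_ld50_ug_per_bee"]) else float(row["contact_ld50_ug_per_bee"]),
                oral_ld50=None if pd.isna(row["oral_ld50_ug_per_bee"]) else float(row["oral_ld50_ug_per_bee"]),
            )
        except ValueError as e:
            raise ValueError(f"{path} row {i + 2}: {e}") from e
        out[name] = rec
    return out


def write_toxdb(toxdb: dict[str, CompoundTox], path) -> None:
    rows = [
        {
            "compound": t.name,
            "pclass": t.pclass.value,
            "contact_ld50_ug_per_bee": t.contact_ld50,
            "oral_ld50_ug_per_bee": t.oral_ld50,
        }
        for t in toxdb.values()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def _data_path(name: str):
    return resources.files("pollenrisk.data").joinpath(name)


def default_toxdb() -> dict[str, CompoundTox]:
    """The bundled 25-compound toxicity panel (14 insecticides, 10
    fungicides, 1 herbicide) used throughout the worked examples."""
    with resources.as_file(_data_path("toxdb_default.csv")) as p:
        return read_toxdb(p)


def load_survey_residues() -> pd.DataFrame:
    """Bundled published survey of mean residues (mean of positive
    detections, ppb), detection counts and LODs for the default panel."""
    with resources.as_file(_data_path("survey_residues.csv")) as p:
        return pd.read_csv(p, float_precision="round_trip")


def survey_residue_records() -> list[ResidueRecord]:
    """Expand the bundled survey into per-site residue records.

    Each compound with n positive detections becomes n records at its mean
    residue (so the mean-of-detections summary reproduces the survey);
    never-detected compounds become a single non-detect record.  A nominal
    LOD of 0.1 ppb is used: detection flags are set by construction here and
    the summary statistics do not depend on the LOD.
    """
    survey = load_survey_residues()
    out: list[ResidueRecord] = []
    for _, row in survey.iterrows():
        n = int(row["n_detections"])
        if n == 0:
            out.append(ResidueRecord.from_measurement("S01", row["compound"], 0.0, 0.1))
            continue
        for i in range(n):
            out.append(
                ResidueRecord.from_measurement(
                    f"S{i + 1:02d}", row["compound"], float(row["mean_residue_ppb"]), 0.1
                )
            )
    return out


# ---------------------------------------------------------------------------
# residues

def read_residues(path) -> list[ResidueRecord]:
    """Read per-site residue concentrations.

    Schema: site_id,compound,concentration_ppb,lod_ppb.  Concentrations
    below the LOD are coerced to 0 (non-detect) with a logged warning;
    negative concentrations are hard errors.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["site_id", "compound", "concentration_ppb", "lod_ppb"], path)
    out = []
    for i, row in df.iterrows():
        conc = float(row["concentration_ppb"])
        lod = float(row["lod_ppb"])
        if conc < 0:
            raise ValueError(
                f"{path} row {i + 2}: negative concentration {conc} for "
                f"{row['site_id']}/{row['compound']}"
            )
        if 0 < conc < lod:
            logger.warning(
                "%s row %d: %s/%s concentration %g below LOD %g; coerced to 0",
                path, i + 2, row["site_id"], row["compound"], conc, lod,
            )
        out.append(
            ResidueRecord.from_measurement(
                str(row["site_id"]), str(row["compound"]), conc, lod
            )
        )
    return out


def write_residues(records: Iterable[ResidueRecord], path) -> None:
    rows = [
        {
            "site_id": r.site_id,
            "compound": r.compound,
            "concentration_ppb": r.concentration,
            "lod_ppb": r.lod,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# spray records

def read_sprays(path) -> list[SprayEvent]:
    """Read spray records: site_id,compound,date,pct_ai,app_rate_kg_per_ha,
    during_bloom.  Dates are ISO-8601; during_bloom is an explicit boolean
    column (true/false or 1/0)."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(
        df, ["site_id", "compound", "date", "pct_ai", "app_rate_kg_per_ha", "during_bloom"], path
    )
    out = []
    for i, row in df.iterrows():
        raw = str(row["during_bloom"]).strip().lower()
        if raw in {"true", "1", "yes"}:
            bloom = True
        elif raw in {"false", "0", "no"}:
            bloom = False
        else:
            raise ValueError(f"{path} row {i + 2}: bad during_bloom value {raw!r}")
        try:
            out.append(
                SprayEvent(
                    site_id=str(row["site_id"]),
                    compound=str(row["compound"]),
                    date=date.fromisoformat(str(row["date"])),
                    pct_ai=float(row["pct_ai"]),
                    app_rate=float(row["app_rate_kg_per_ha"]),
                    during_bloom=bloom,
                )
            )
        except ValueError as e:
            raise ValueError(f"{path} row {i + 2}: {e}") from e
    return out


def write_sprays(events: Iterable[SprayEvent], path) -> None:
    rows = [
        {
            "site_id": e.site_id,
            "compound": e.compound,
            "date": e.date.isoformat(),
            "pct_ai": e.pct_ai,
            "app_rate_kg_per_ha": e.app_rate,
            "during_bloom": e.during_bloom,
        }
        for e in events
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# pollen counts

def read_pollen(path) -> list[PollenSample]:
    """Read long-format morphotype counts: site_id,morphotype,count."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["site_id", "morphotype", "count"], path)
    out = []
    for site_id, grp in df.groupby("site_id", sort=True):
        dup = grp["morphotype"][grp["morphotype"].duplicated()]
        if len(dup):
            raise ValueError(
                f"{path}: duplicate morphotype rows for site {site_id}: "
                f"{sorted(set(dup))}"
            )
        counts = {str(m): int(c) for m, c in zip(grp["morphotype"], grp["count"])}
        out.append(PollenSample.from_counts(str(site_id), counts))
    return out


def write_pollen(samples: Iterable[PollenSample], path) -> None:
    rows = [
        {"site_id": s.site_id, "morphotype": m, "count": c}
        for s in samples
        for m, c in sorted(s.counts.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# land cover

def read_classmap(path) -> dict[int, LandCoverClass]:
    """Read a land-cover class map: code,name,group."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["code", "name", "group"], path)
    out: dict[int, LandCoverClass] = {}
    for i, row in df.iterrows():
        code = int(row["code"])
        if code in out:
            raise ValueError(f"{path} row {i + 2}: duplicate code {code}")
        out[code] = LandCoverClass(str(row["name"]), str(row["group"]).strip().lower())
    return out


def default_classmap() -> dict[int, LandCoverClass]:
    with resources.as_file(_data_path("landcover_groups.csv")) as p:
        return read_classmap(p)


def read_grid(path, classmap_path=None, class_map=None) -> LandCoverGrid:
    """Read an ESRI ASCII grid (.asc) with its class map.

    The six-line header (ncols, nrows, xllcorner, yllcorner, cellsize,
    NODATA_value; the last optional) is followed by nrows of ncols integer
    codes, top row first.  Unknown class codes are a hard error listing the
    offending codes.
    """
    if class_map is None:
        if classmap_path is None:
            raise ValueError("read_grid needs classmap_path or class_map")
        class_map = read_classmap(classmap_path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
            if key not in header:
                raise ValueError(f"{path}: missing ASCII grid header field {key}")
        codes = np.loadtxt(fh, dtype=np.int32, ndmin=2)
    if codes.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"{path}: grid body shape {codes.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    return LandCoverGrid(
        codes=codes,
        cell_size=header["cellsize"],
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        class_map=class_map,
        nodata=int(header.get("nodata_value", -9999)),
    )


def write_grid(grid: LandCoverGrid, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.xll:g}\n")
        fh.write(f"yllcorner {grid.yll:g}\n")
        fh.write(f"cellsize {grid.cell_size:g}\n")
        fh.write(f"NODATA_value {grid.nodata}\n")
        np.savetxt(fh, grid.codes, fmt="%d")


# ---------------------------------------------------------------------------
# site coordinates

def read_sites(path) -> dict[str, tuple[float, float]]:
    """Read hive locations: site_id,x_m,y_m -> {site_id: (x, y)}."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["site_id", "x_m", "y_m"], path)
    out: dict[str, tuple[float, float]] = {}
    for i, row in df.iterrows():
        sid = str(row["site_id"])
        if sid in out:
            raise ValueError(f"{path} row {i + 2}: duplicate site {sid}")
        out[sid] = (float(row["x_m"]), float(row["y_m"]))
    return out


def write_sites(sites: dict[str, tuple[float, float]], path) -> None:
    rows = [{"site_id": s, "x_m": x, "y_m": y} for s, (x, y) in sites.items()]
    pd.DataFrame(rows).to_csv(path, index=False)
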