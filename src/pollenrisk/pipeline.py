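"""Full-analysis orchestration: risk tables, composition, buffers, regressions.

`analyze_study` takes in-memory inputs (as produced by the readers or the
synthetic generator) and returns all result tables plus a JSON-able summary;
`run` drives it from a YAML config of file paths and writes the flat CSV
outputs, so each stage is independently diffable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import hazard as hz
from . import io as _io
from . import landscape as ls
from . import pollen as pl
from .core import (
    CompoundTox,
    ExposureParams,
    LandCoverGrid,
    PollenSample,
    RegulatoryThresholds,
    ResidueRecord,
    SprayEvent,
)
from .stats import ols

logger = logging.getLogger(__name__)

__all__ = ["analyze_study", "run", "PipelineResult"]

# fixed regression panel: (predictor column, response column)
_REGRESSIONS = (
    ("pct_natural", "focal_fraction"),
    ("pct_agricultural", "focal_fraction"),
    ("pct_apple", "focal_fraction"),
    ("pct_apple", "total_residue_ppb"),
    ("focal_fraction", "total_residue_ppb"),
    ("focal_fraction", "fungicide_ppb"),
    ("focal_fraction", "insecticide_ppb"),
    ("focal_fraction", "total_contact_phq"),
    ("richness", "insecticide_ppb"),
    ("richness", "total_contact_phq"),
    ("pui_all", "total_contact_phq"),
    ("pui_panel", "total_contact_phq"),
)


@dataclass
class PipelineResult:
    site_risk: pd.DataFrame
    compound_summary: pd.DataFrame
    pui: pd.DataFrame
    pollen_composition: pd.DataFrame
    buffers: pd.DataFrame
    regressions: pd.DataFrame
    summary: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.site_risk.to_csv(out / "site_risk.csv", index=False)
        self.compound_summary.to_csv(out / "compound_summary.csv", index=False)
        self.pui.to_csv(out / "pui.csv", index=False)
        self.pollen_composition.to_csv(out / "pollen_composition.csv", index=False)
        self.buffers.to_csv(out / "buffers.csv", index=False)
        self.regressions.to_csv(out / "regressions.csv", index=False)
        (out / "summary.json").write_text(json.dumps(self.summary, indent=2, sort_keys=True))


def _site_risk_table(
    residues: Sequence[ResidueRecord],
    toxdb: Mapping[str, CompoundTox],
    sprays: Sequence[SprayEvent],
    exposure: ExposureParams,
    thresholds: RegulatoryThresholds,
) -> tuple[pd.DataFrame, dict[str, hz.SiteRisk]]:
    by_site: dict[str, list[ResidueRecord]] = {}
    for r in residues:
        by_site.setdefault(r.site_id, []).append(r)
    risks: dict[str, hz.SiteRisk] = {}
    rows = []
    for sid in sorted(by_site):
        site_sprays = [e for e in sprays if e.site_id == sid]
        sr = hz.site_risk(by_site[sid], toxdb, site_sprays, exposure, thresholds)
        risks[sid] = sr
        fung = sum(
            (cp.contact_phq or 0.0)
            for c, cp in sr.compound_phq.items()
            if toxdb[c].pclass.value == "fungicide"
        )
        rows.append(
            {
                "site_id": sid,
                "total_contact_phq": sr.total_contact_phq,
                "total_oral_phq": sr.total_oral_phq,
                "pct_ld50_contact": sr.pct_ld50_contact,
                "pct_ld50_oral": sr.pct_ld50_oral,
                "epa_acute_contact": sr.loc_flags["epa_acute_contact"],
                "efsa_acute_contact": sr.loc_flags["efsa_acute_contact"],
                "efsa_chronic_oral": sr.loc_flags["efsa_chronic_oral"],
                "nonspray_fraction_contact": sr.nonspray_fraction_contact,
                "nonspray_fraction_oral": sr.nonspray_fraction_oral,
            }
        )
    return pd.DataFrame(rows), risks


def _residue_class_totals(
    residues: Sequence[ResidueRecord], toxdb: Mapping[str, CompoundTox]
) -> pd.DataFrame:
    rows: dict[str, dict[str, float]] = {}
    for r in residues:
        d = rows.setdefault(
            r.site_id,
            {"total_residue_ppb": 0.0, "fungicide_ppb": 0.0, "insecticide_ppb": 0.0, "herbicide_ppb": 0.0},
        )
        if not r.detected:
            continue
        d["total_residue_ppb"] += r.concentration
        d[f"{toxdb[r.compound].pclass.value}_ppb"] += r.concentration
    return pd.DataFrame(
        [{"site_id": s, **v} for s, v in sorted(rows.items())]
    )


def analyze_study(
    residues: Sequence[ResidueRecord],
    toxdb: Mapping[str, CompoundTox],
    sprays: Sequence[SprayEvent] = (),
    pollen_samples: Sequence[PollenSample] = (),
    grid: Optional[LandCoverGrid] = None,
    sites: Optional[Mapping[str, tuple[float, float]]] = None,
    exposure: ExposureParams = ExposureParams(),
    thresholds: RegulatoryThresholds = RegulatoryThresholds(),
    focal_morphotype: str = "Malus",
    radii: Sequence[float] = ls.DEFAULT_RADII,
    sporadic_threshold: float = 0.03,
    seed: Optional[int] = None,
) -> PipelineResult:
    """Run the full analysis on in-memory inputs.

    Landscape metrics are computed only when both ``grid`` and ``sites`` are
    given; pollen metrics only when samples are given.  Partial runs produce
    numbers identical to the corresponding slice of a full run.
    """
    site_df, risks = _site_risk_table(residues, toxdb, sprays, exposure, thresholds)
    summary_rows = hz.summary_rounded(hz.summarize_compounds(residues, toxdb))
    compound_df = pd.DataFrame(summary_rows)

    panel = {r.compound for r in residues}
    pui_rows = []
    for sid in site_df["site_id"]:
        res = hz.pui([e for e in sprays if e.site_id == sid], toxdb, panel=panel)
        pui_rows.append(
            {
                "site_id": sid,
                "pui_all": res.pui_all,
                "pui_panel": res.pui_panel,
                "n_events": res.n_events,
            }
        )
    pui_df = pd.DataFrame(pui_rows)

    if pollen_samples:
        retained = pl.classify_sporadic(pollen_samples, sporadic_threshold)
        comps = [pl.composition(s, retained, focal_morphotype) for s in pollen_samples]
        pollen_df = pd.DataFrame(
            [
                {
                    "site_id": c.site_id,
                    "focal_fraction": c.focal_fraction,
                    "richness": c.richness,
                    "other_fraction": c.other_fraction,
                }
                for c in sorted(comps, key=lambda c: c.site_id)
            ]
        )
    else:
        pollen_df = pd.DataFrame(columns=["site_id", "focal_fraction", "richness", "other_fraction"])

    buffers_df = pd.DataFrame(
        columns=["site_id", "radius_m", "pct_natural", "pct_agricultural", "pct_apple", "pct_other", "n_cells"]
    )
    selected_radius = None
    if grid is not None and sites is not None:
        buf_rows = []
        summaries: dict[float, list[ls.BufferSummary]] = {}
        for radius in radii:
            summaries[radius] = [
                ls.buffer_percent(grid, xy, radius, site_id=sid) for sid, xy in sites.items()
            ]
            buf_rows += [
                {
                    "site_id": b.site_id,
                    "radius_m": b.radius,
                    "pct_natural": b.pct_natural,
                    "pct_agricultural": b.pct_agricultural,
                    "pct_apple": b.pct_apple,
                    "pct_other": b.pct_other,
                    "n_cells": b.n_cells,
                }
                for b in summaries[radius]
            ]
        buffers_df = pd.DataFrame(buf_rows)
        if len(pollen_df) >= 3:
            response = dict(zip(pollen_df["site_id"], pollen_df["focal_fraction"]))
            try:
                selected_radius = ls.select_scale(summaries, response)
            except ValueError as e:
                logger.warning("buffer-scale selection skipped: %s", e)

    # merged per-site frame for the regression panel
    merged = site_df.merge(_residue_class_totals(residues, toxdb), on="site_id")
    merged = merged.merge(pui_df, on="site_id", how="left")
    if len(pollen_df):
        merged = merged.merge(pollen_df, on="site_id", how="left")
    if selected_radius is not None:
        sel = buffers_df[buffers_df["radius_m"] == selected_radius]
        merged = merged.merge(
            sel[["site_id", "pct_natural", "pct_agricultural", "pct_apple"]],
            on="site_id",
            how="left",
        )

    reg_rows = []
    for xcol, ycol in _REGRESSIONS:
        if xcol not in merged.columns or ycol not in merged.columns:
            continue
        sub = merged[[xcol, ycol]].dropna()
        if len(sub) < 3 or sub[xcol].nunique() < 2:
            continue
        r = ols(sub[xcol].to_numpy(), sub[ycol].to_numpy())
        reg_rows.append(
            {
                "predictor": xcol,
                "response": ycol,
                "n": r.n,
                "slope": r.slope,
                "intercept": r.intercept,
                "r_squared": r.r_squared,
                "f_stat": r.f_stat,
                "df1": r.df[0],
                "df2": r.df[1],
                "p_value": r.p_value,
                "aic": r.aic,
            }
        )
    reg_df = pd.DataFrame(reg_rows)

    # aggregate attribution: sum of unsprayed PHQ over sum of total PHQ
    agg = {}
    for route, attr in (("contact", "contact_phq"), ("oral", "oral_phq")):
        tot = uns = 0.0
        for sid, sr in risks.items():
            sprayed = {e.compound for e in sprays if e.site_id == sid and e.during_bloom}
            for comp, cp in sr.compound_phq.items():
                v = getattr(cp, attr)
                if v is None:
                    continue
                tot += v
                if comp not in sprayed:
                    uns += v
        agg[route] = uns / tot if tot > 0 else 0.0

    detected_pairs = [(r.site_id, r.compound) for r in residues if r.detected]
    sprayed_at = {(e.site_id, e.compound) for e in sprays if e.during_bloom}
    n_unsprayed = sum(1 for p in detected_pairs if p not in sprayed_at)

    summary = {
        "n_sites": int(len(site_df)),
        "loc_exceedances": {
            k: int(site_df[k].sum())
            for k in ("epa_acute_contact", "efsa_acute_contact", "efsa_chronic_oral")
        },
        "nonspray_share_contact": agg["contact"],
        "nonspray_share_oral": agg["oral"],
        "frac_detections_unsprayed": (
            n_unsprayed / len(detected_pairs) if detected_pairs else 0.0
        ),
        "selected_radius_m": selected_radius,
        "seed": seed,
    }
    return PipelineResult(
        site_risk=site_df,
        compound_summary=compound_df,
        pui=pui_df,
        pollen_composition=pollen_df,
        buffers=buffers_df,
        regressions=reg_df,
        summary=summary,
    )


def _config_exposure(cfg: dict) -> ExposureParams:
    e = cfg.get("exposure", {})
    return ExposureParams(
        bee_mass_mg=e.get("bee_mass_mg", 100.0),
        contact_mass_mg=e.get("contact_mass_mg", 100.0),
        oral_rate_mg_per_day=e.get("oral_rate_mg_per_day", 9.4),
        duration_days=e.get("duration_days", 10.0),
    )


def _config_thresholds(cfg: dict) -> RegulatoryThresholds:
    t = cfg.get("thresholds", {})
    return RegulatoryThresholds(
        epa_acute_contact_rq=t.get("epa_acute_contact", 0.4),
        efsa_acute_contact_etr=t.get("efsa_acute_contact", 0.2),
        efsa_chronic_oral_etr=t.get("efsa_chronic_oral", 0.03),
    )


def run(config_path, out_dir=None) -> PipelineResult:
    """Run the pipeline from a YAML config of input paths and options.

    Required keys: ``inputs.residues``, ``inputs.toxdb``.  Optional:
    ``inputs.sprays``, ``inputs.pollen``, ``inputs.grid`` +
    ``inputs.class_map`` + ``inputs.sites``, ``exposure.*``,
    ``thresholds.*``, ``focal_morphotype``, ``radii``, ``out_dir``.
    The config hash and seed are logged and echoed into the summary.
    """
    config_path = Path(config_path)
    raw = config_path.read_text()
    cfg = yaml.safe_load(raw) or {}
    cfg_hash = hashlib.sha256(raw.encode()).hexdigest()[:16]
    logger.info("config %s hash=%s seed=%s", config_path, cfg_hash, cfg.get("seed"))

    inputs = cfg.get("inputs", {})
    base = config_path.parent

    def _p(key):
        v = inputs.get(key)
        return None if v is None else (base / v if not Path(v).is_absolute() else Path(v))

    if _p("residues") is None or _p("toxdb") is None:
        raise ValueError(f"{config_path}: inputs.residues and inputs.toxdb are required")
    toxdb = _io.read_toxdb(_p("toxdb"))
    residues = _io.read_residues(_p("residues"))
    sprays = _io.read_sprays(_p("sprays")) if _p("sprays") else []
    pollen_samples = _io.read_pollen(_p("pollen")) if _p("pollen") else []
    grid = sites = None
    if _p("grid") and _p("class_map") and _p("sites"):
        grid = _io.read_grid(_p("grid"), _p("class_map"))
        sites = _io.read_sites(_p("sites"))

    result = analyze_study(
        residues,
        toxdb,
        sprays,
        pollen_samples,
        grid,
        sites,
        exposure=_config_exposure(cfg),
        thresholds=_config_thresholds(cfg),
        focal_morphotype=cfg.get("focal_morphotype", "Malus"),
        radii=tuple(cfg.get("radii", ls.DEFAULT_RADII)),
        seed=cfg.get("seed"),
    )
    result.summary["config_hash"] = cfg_hash
    dest = out_dir or cfg.get("out_dir")
    if dest is not None:
        result.write(base / dest if not Path(dest).is_absolute() else dest)
    return result
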