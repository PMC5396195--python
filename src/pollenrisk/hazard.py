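"""Hazard quotients, use index, exposure conversion and risk classification.

The pollen hazard quotient (PHQ) of a compound is its beebread residue
concentration (ng/g pollen, i.e. ppb) divided by the honey bee LD50 for the
route (µg/bee), kept deliberately in that raw convention; a site's total PHQ
per route sums the per-compound quotients under the additivity assumption.
Totals are converted to percent of LD50 via simple exposure assumptions
(100 mg pollen contacted acutely; 9.4 mg/day ingested over a 10-day bloom)
and compared against regulatory levels of concern: EPA Tier 1 acute-contact
risk quotient 0.4, EFSA acute-contact ETR 0.2, EFSA chronic-oral ETR 0.03.

The spray-record-based Pesticide Use Index (PUI) of a site sums
(1/contact LD50) x (fraction active ingredient) x (application rate in
kg product/ha) over during-bloom applications.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .core import (
    CompoundTox,
    ExposureParams,
    RegulatoryThresholds,
    ResidueRecord,
    Route,
    SprayEvent,
    round_half_up,
)

logger = logging.getLogger(__name__)

__all__ = [
    "phq_raw",
    "pct_of_ld50",
    "classify_loc",
    "attribute_spray_status",
    "site_risk",
    "pui",
    "summarize_compounds",
    "CompoundPhq",
    "SiteRisk",
    "PuiResult",
    "CompoundSummary",
]

LOC_KEYS = ("epa_acute_contact", "efsa_acute_contact", "efsa_chronic_oral")


def phq_raw(concentration: float, ld50: Optional[float]) -> Optional[float]:
    """Raw pollen hazard quotient: residue (ppb) / LD50 (µg/bee).

    No unit rescaling is applied here; the quotient keeps the raw
    ppb-per-(µg/bee) convention of the source metric.  A missing LD50
    returns ``None`` (a route-skip signal, not an exception).
    """
    if ld50 is None:
        return None
    if ld50 <= 0:
        raise ValueError(f"LD50 must be > 0, got {ld50}")
    if concentration < 0:
        raise ValueError(f"concentration must be >= 0, got {concentration}")
    return concentration / ld50


def pct_of_ld50(total_phq: float, route: Route | str, exposure: ExposureParams = ExposureParams()) -> float:
    """Convert a total PHQ to percent of LD50 under the exposure assumptions.

    ppb x grams-of-pollen gives ng of pesticide; /1000 gives µg; the /LD50
    is already inside the PHQ.  At the defaults this is total_phq x 1e-2 for
    contact (100 mg = 0.1 g contacted) and total_phq x 9.4e-3 for oral
    (9.4 mg/day x 10 days = 0.094 g ingested).
    """
    if total_phq < 0:
        raise ValueError(f"total_phq must be >= 0, got {total_phq}")
    route = Route(route)  # raises on unknown route
    if route is Route.CONTACT:
        grams = exposure.contact_mass_mg / 1000.0
    else:
        grams = exposure.oral_rate_mg_per_day * exposure.duration_days / 1000.0
    return total_phq * grams / 1000.0 * 100.0


def classify_loc(
    pct_contact: float,
    pct_oral: float,
    thresholds: RegulatoryThresholds = RegulatoryThresholds(),
) -> dict[str, bool]:
    """Flag level-of-concern exceedance per agency and route.

    A flag is true iff the exposure fraction (percent/100) STRICTLY exceeds
    the threshold; boundary equality counts as non-exceedance.  Each
    agency/route is evaluated independently.
    """
    if pct_contact < 0 or pct_oral < 0:
        raise ValueError("percent-of-LD50 values must be >= 0")
    return {
        "epa_acute_contact": pct_contact / 100.0 > thresholds.epa_acute_contact_rq,
        "efsa_acute_contact": pct_contact / 100.0 > thresholds.efsa_acute_contact_etr,
        "efsa_chronic_oral": pct_oral / 100.0 > thresholds.efsa_chronic_oral_etr,
    }


@dataclass(frozen=True)
class CompoundPhq:
    """Per-compound hazard quotients at one site; a route with a missing
    LD50 appears in ``skipped_routes`` and contributes nothing."""

    contact_phq: Optional[float]
    oral_phq: Optional[float]
    skipped_routes: frozenset[str] = frozenset()


@dataclass(frozen=True)
class SiteRisk:
    """Aggregated hazard quotients, exposure percents, regulatory flags and
    sprayed/non-sprayed risk partition for one site."""

    site_id: str
    compound_phq: Mapping[str, CompoundPhq]
    total_contact_phq: float
    total_oral_phq: float
    pct_ld50_contact: float
    pct_ld50_oral: float
    loc_flags: Mapping[str, bool]
    nonspray_fraction_contact: float
    nonspray_fraction_oral: float


def _sprayed_compounds(sprays: Iterable[SprayEvent], site_id: str) -> set[str]:
    return {e.compound for e in sprays if e.site_id == site_id and e.during_bloom}


def attribute_spray_status(
    compound_phq: Mapping[str, CompoundPhq],
    sprays: Sequence[SprayEvent],
    site_id: str,
) -> tuple[float, float]:
    """Fraction of each route's total PHQ from compounds NOT sprayed during
    bloom at this site.

    A compound counts as "sprayed" iff a during-bloom spray event for it
    exists at the site.  Defined as 0 when the route total is 0.
    """
    sprayed = _sprayed_compounds(sprays, site_id)
    out = []
    for attr in ("contact_phq", "oral_phq"):
        total = 0.0
        unsprayed = 0.0
        for name, cp in compound_phq.items():
            v = getattr(cp, attr)
            if v is None:
                continue
            total += v
            if name not in sprayed:
                unsprayed += v
        out.append(unsprayed / total if total > 0 else 0.0)
    return out[0], out[1]


def site_risk(
    residues: Sequence[ResidueRecord],
    toxdb: Mapping[str, CompoundTox],
    sprays: Sequence[SprayEvent] = (),
    exposure: ExposureParams = ExposureParams(),
    thresholds: RegulatoryThresholds = RegulatoryThresholds(),
) -> SiteRisk:
    """Aggregate one site's residues into a :class:`SiteRisk`.

    Route totals sum ``phq_raw`` over detected compounds with an available
    LD50; a compound lacking a route's LD50 is recorded in its
    ``skipped_routes``.  A residue compound absent from the toxicity
    database is a hard error.
    """
    if not residues:
        raise ValueError("site_risk needs at least one residue record")
    site_ids = {r.site_id for r in residues}
    if len(site_ids) != 1:
        raise ValueError(f"residues span multiple sites: {sorted(site_ids)}")
    site_id = site_ids.pop()

    per_compound: dict[str, CompoundPhq] = {}
    tot_contact = 0.0
    tot_oral = 0.0
    for r in residues:
        if r.compound not in toxdb:
            raise ValueError(f"{site_id}: compound {r.compound!r} missing from toxdb")
        if not r.detected:
            continue
        tox = toxdb[r.compound]
        c = phq_raw(r.concentration, tox.contact_ld50)
        o = phq_raw(r.concentration, tox.oral_ld50)
        skipped = frozenset(
            route for route, v in (("contact", c), ("oral", o)) if v is None
        )
        per_compound[r.compound] = CompoundPhq(c, o, skipped)
        tot_contact += c or 0.0
        tot_oral += o or 0.0

    pct_c = pct_of_ld50(tot_contact, Route.CONTACT, exposure)
    pct_o = pct_of_ld50(tot_oral, Route.ORAL, exposure)
    ns_c, ns_o = attribute_spray_status(per_compound, sprays, site_id)
    return SiteRisk(
        site_id=site_id,
        compound_phq=per_compound,
        total_contact_phq=tot_contact,
        total_oral_phq=tot_oral,
        pct_ld50_contact=pct_c,
        pct_ld50_oral=pct_o,
        loc_flags=classify_loc(pct_c, pct_o, thresholds),
        nonspray_fraction_contact=ns_c,
        nonspray_fraction_oral=ns_o,
    )


@dataclass(frozen=True)
class PuiResult:
    """Spray-record use index for one site, over all compounds and over a
    restricted panel (e.g. only compounds quantifiable in pollen)."""

    site_id: str
    pui_all: float
    pui_panel: float
    n_events: int


def pui(
    events: Sequence[SprayEvent],
    toxdb: Mapping[str, CompoundTox],
    panel: Optional[set[str]] = None,
) -> PuiResult:
    """Pesticide Use Index: sum over during-bloom applications of
    (1 / contact LD50) x (pct_ai / 100) x app_rate.

    Events whose compound lacks a contact LD50 in the database are skipped
    with a warning.  ``pui_panel`` restricts the sum to ``panel`` compounds
    (equal to ``pui_all`` when no panel is given).  An empty event list is
    valid and yields 0.
    """
    site_ids = {e.site_id for e in events}
    if len(site_ids) > 1:
        raise ValueError(f"events span multiple sites: {sorted(site_ids)}")
    site_id = site_ids.pop() if site_ids else ""
    total = 0.0
    total_panel = 0.0
    n = 0
    for e in events:
        if not e.during_bloom:
            continue
        tox = toxdb.get(e.compound)
        if tox is None or tox.contact_ld50 is None:
            logger.warning(
                "%s: no contact LD50 for sprayed compound %s; event skipped",
                site_id, e.compound,
            )
            continue
        term = (1.0 / tox.contact_ld50) * (e.pct_ai / 100.0) * e.app_rate
        total += term
        if panel is None or e.compound in panel:
            total_panel += term
        n += 1
    return PuiResult(site_id=site_id, pui_all=total, pui_panel=total_panel, n_events=n)


@dataclass(frozen=True)
class CompoundSummary:
    """Across-site summary for one compound: mean residue over positive
    detections and the hazard quotients of that mean."""

    compound: str
    pclass: str
    mean_residue: float  # ppb, mean of positive detections (0 if none)
    n_detections: int
    mean_contact_phq: Optional[float]
    mean_oral_phq: Optional[float]


def summarize_compounds(
    residues: Sequence[ResidueRecord],
    toxdb: Mapping[str, CompoundTox],
) -> list[CompoundSummary]:
    """Per-compound summary across all sites.

    ``n_detections`` counts sites with a detected residue; ``mean_residue``
    averages the concentration over detected sites only (0 when never
    detected); mean PHQs divide that mean by the route LD50 (``None`` when
    the LD50 is missing, 0 when never detected).  Rows are sorted by
    descending mean contact PHQ with missing values last.
    """
    if not residues:
        raise ValueError("summarize_compounds needs at least one residue record")
    by_compound: dict[str, list[ResidueRecord]] = {}
    for r in residues:
        if r.compound not in toxdb:
            raise ValueError(f"compound {r.compound!r} missing from toxdb")
        by_compound.setdefault(r.compound, []).append(r)

    rows = []
    for name, recs in by_compound.items():
        tox = toxdb[name]
        detected = [r.concentration for r in recs if r.detected]
        n = len(detected)
        mean_res = sum(detected) / n if n else 0.0
        if n == 0:
            c_phq = 0.0 if tox.contact_ld50 is not None else None
            o_phq = 0.0 if tox.oral_ld50 is not None else None
        else:
            c_phq = phq_raw(mean_res, tox.contact_ld50)
            o_phq = phq_raw(mean_res, tox.oral_ld50)
        rows.append(
            CompoundSummary(
                compound=name,
                pclass=tox.pclass.value,
                mean_residue=mean_res,
                n_detections=n,
                mean_contact_phq=c_phq,
                mean_oral_phq=o_phq,
            )
        )
    rows.sort(
        key=lambda s: (
            s.mean_contact_phq is None,
            -(s.mean_contact_phq if s.mean_contact_phq is not None else 0.0),
            s.compound,
        )
    )
    return rows


def summary_rounded(rows: Sequence[CompoundSummary], ndigits: int = 1) -> list[dict]:
    """Report rows rounded half-up to ``ndigits`` decimals (internal
    computation stays full precision)."""
    out = []
    for s in rows:
        out.append(
            {
                "compound": s.compound,
                "pclass": s.pclass,
                "mean_residue_ppb": round_half_up(s.mean_residue, ndigits),
                "n_detections": s.n_detections,
                "mean_contact_phq": None if s.mean_contact_phq is None else round_half_up(s.mean_contact_phq, ndigits),
                "mean_oral_phq": None if s.mean_oral_phq is None else round_half_up(s.mean_oral_phq, ndigits),
            }
        )
    return out
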