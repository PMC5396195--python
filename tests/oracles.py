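"""Independent brute-force re-implementations of the hazard aggregations.

Plain double loops over sites and compounds, written against the metric
definitions only — deliberately sharing no code with pollenrisk.hazard —
used to cross-check site risk, compound summaries, the use index and the
spray-status attribution on small studies.
"""


def brute_site_totals(residues, toxdb, site_id):
    """(total contact PHQ, total oral PHQ) summed compound by compound."""
    tot_c = tot_o = 0.0
    for r in residues:
        if r.site_id != site_id or not r.detected:
            continue
        t = toxdb[r.compound]
        if t.contact_ld50 is not None:
            tot_c += r.concentration / t.contact_ld50
        if t.oral_ld50 is not None:
            tot_o += r.concentration / t.oral_ld50
    return tot_c, tot_o


def brute_nonspray_fractions(residues, toxdb, sprays, site_id):
    sprayed = set()
    for e in sprays:
        if e.site_id == site_id and e.during_bloom:
            sprayed.add(e.compound)
    out = []
    for route in ("contact", "oral"):
        tot = uns = 0.0
        for r in residues:
            if r.site_id != site_id or not r.detected:
                continue
            ld = getattr(toxdb[r.compound], f"{route}_ld50")
            if ld is None:
                continue
            v = r.concentration / ld
            tot += v
            if r.compound not in sprayed:
                uns += v
        out.append(uns / tot if tot > 0 else 0.0)
    return tuple(out)


def brute_pui(events, toxdb, site_id, panel=None):
    tot = tot_panel = 0.0
    for e in events:
        if e.site_id != site_id or not e.during_bloom:
            continue
        t = toxdb.get(e.compound)
        if t is None or t.contact_ld50 is None:
            continue
        term = (1.0 / t.contact_ld50) * (e.pct_ai / 100.0) * e.app_rate
        tot += term
        if panel is None or e.compound in panel:
            tot_panel += term
    return tot, tot_panel


def brute_compound_summary(residues, toxdb, compound):
    """(mean residue over detections, n detections, mean contact PHQ,
    mean oral PHQ); PHQ is None when the LD50 is missing."""
    vals = [
        r.concentration
        for r in residues
        if r.compound == compound and r.detected
    ]
    n = len(vals)
    mean = sum(vals) / n if n else 0.0
    t = toxdb[compound]
    c = None if t.contact_ld50 is None else (mean / t.contact_ld50 if n else 0.0)
    o = None if t.oral_ld50 is None else (mean / t.oral_ld50 if n else 0.0)
    return mean, n, c, o
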