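"""Synthetic orchard-study generator with known ground truth.

Generates complete studies — a categorical land-cover grid with hive sites
on a focal-crop (apple) density gradient, pollen morphotype slide counts,
beebread residue tables and during-bloom spray records — with the
statistical couplings the analysis assumes:

* apple pollen fraction is a linear function of apple area plus Gaussian
  noise, with the noise variance solved analytically so the EXPECTED SAMPLE
  R² of the ordinary least-squares fit matches a configured target
  (default 0.67);
* total fungicide residue is coupled to the latent apple-pollen fraction
  (target R² 0.46), total insecticide residue to pollen richness (target
  R² 0.12);
* each site receives a number of detected-but-not-sprayed compounds from a
  Bernoulli × zero-truncated-Poisson model matching a configured mean
  (default 2.8/site) and affected-site fraction (default 28/30).

Everything is deterministic given the seed; one pseudo-random stream per
component (landscape, pollen, residues, sprays) is split from the master
seed so changing one component's parameters does not perturb the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Mapping, Optional

import numpy as np

from .core import (
    CompoundTox,
    LandCoverGrid,
    PollenSample,
    ResidueRecord,
    SprayEvent,
)
from . import io as _io

__all__ = [
    "SynthConfig",
    "SyntheticStudy",
    "GroundTruth",
    "generate_study",
    "ground_truth",
    "FOCAL_MORPHOTYPE",
]

FOCAL_MORPHOTYPE = "Malus"

# 19 non-focal morphotypes (with the focal crop: a 20-type scheme); weights
# reflect a buckthorn-dominated non-crop flora typical of northeastern
# orchard surroundings.
_NONFOCAL_POOL = (
    ("Rhamnus", 8.0),
    ("Crataegus_Prunus", 3.0),
    ("Unknown_2", 3.0),
    ("Unknown_3", 2.5),
    ("Rubus", 2.0),
    ("Unknown_4", 1.5),
    ("Aesculus_hippocastanum", 1.2),
    ("Salix", 1.0),
    ("Unknown_1", 1.0),
    ("Unknown_5", 1.0),
    ("Chicorieae", 0.8),
    ("Lonicera", 0.8),
    ("Unknown_6", 0.8),
    ("Unknown_7", 0.7),
    ("Fragaria", 0.6),
    ("Prunus_cerasus", 0.6),
    ("Unknown_8", 0.6),
    ("Unknown_9", 0.5),
    ("Unknown_10", 0.5),
)

# land-cover codes used for synthetic grids (see data/landcover_groups.csv)
_APPLE_CODE = 68
_NATURAL_CODES = (141, 176)  # deciduous forest, grassland/pasture
_AGRI_CODES = (1, 36)  # corn, alfalfa
_BACKGROUND_CODES = (141, 176, 1, 36, 121)
_BACKGROUND_P = (0.30, 0.20, 0.25, 0.15, 0.10)

# per-site detection propensities, echoing the bundled survey's detection
# frequencies; compounds rarely applied during bloom are flagged prone to
# non-spray contamination
_FUNGICIDE_POOL = {
    "Cyprodinil": 0.80,
    "Difenoconazole": 0.73,
    "Trifloxystrobin": 0.60,
    "Fluxapyroxad": 0.40,
    "Penthiopyrad": 0.27,
    "Iprodione": 0.13,
    "Thiophanate-methyl": 0.05,
    "Myclobutanil": 0.05,
    "Boscalid": 0.03,
}
_INSECTICIDE_POOL = {
    "Carbaryl": 0.37,
    "Acetamiprid": 0.37,
    "Cyfluthrin": 0.20,
    "Thiamethoxam": 0.17,
    "Thiacloprid": 0.10,
    "Indoxacarb": 0.07,
    "Abamectin": 0.03,
    "Fenpyroximate": 0.03,
}
_NONSPRAY_PRONE = {
    "Cyfluthrin",
    "Fenpyroximate",
    "Fluxapyroxad",
    "Myclobutanil",
    "Boscalid",
    "Atrazine",
    "Thiamethoxam",
    "Chlorantraniliprole",
    "Clothianidin",
    "Imidacloprid",
}

_BLOOM_START = date(2015, 5, 7)
_BLOOM_DAYS = 16  # May 7-22 window


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the generator.

    The R² fields are calibration targets for the expected sample R² of the
    corresponding OLS fits at ``n_sites``; noise scales are solved from them
    analytically, never tuned.
    """

    n_sites: int = 30
    colonies_per_site: int = 4
    grains_per_slide: int = 300
    seed: int = 0
    r2_apple_pollen: float = 0.67
    r2_fungicide: float = 0.46
    r2_insecticide_richness: float = 0.12
    nonspray_rate: float = 2.8
    nonspray_site_fraction: float = 28 / 30
    # landscape
    apple_area_range: tuple[float, float] = (0.005, 0.35)
    buffer_radius_m: float = 3000.0
    cell_size_m: float = 30.0
    # couplings (intercept/slope of the latent linear responses)
    pollen_intercept: float = 0.06
    pollen_slope: float = 0.6
    pollen_noise_sd: Optional[float] = None  # None: solved from r2_apple_pollen
    fungicide_intercept_ppb: float = 800.0
    fungicide_slope_ppb: float = 8000.0
    insecticide_intercept_ppb: float = 120.0
    insecticide_slope_ppb: float = 5.2
    richness_range: tuple[int, int] = (4, 14)  # non-focal morphotypes per site

    def __post_init__(self) -> None:
        if self.n_sites < 3:
            raise ValueError("need n_sites >= 3")
        if self.grains_per_slide < 1 or self.colonies_per_site < 1:
            raise ValueError("grains_per_slide and colonies_per_site must be >= 1")
        for name in ("r2_apple_pollen", "r2_fungicide", "r2_insecticide_richness"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.nonspray_rate < 0 or not (0 < self.nonspray_site_fraction <= 1):
            raise ValueError("invalid non-spray contamination parameters")
        lo, hi = self.apple_area_range
        if not (0 <= lo < hi <= 1):
            raise ValueError("apple_area_range must satisfy 0 <= lo < hi <= 1")
        if self.richness_range[0] < 1 or self.richness_range[1] > len(_NONFOCAL_POOL):
            raise ValueError(
                f"richness_range must lie in [1, {len(_NONFOCAL_POOL)}]"
            )


@dataclass
class GroundTruth:
    """Latent parameters of a generated study, for recovery tests."""

    apple_area: dict[str, float]  # fraction of buffer, per site
    pollen_latent: dict[str, float]  # latent apple-pollen fraction
    pollen_intercept: float
    pollen_slope: float
    pollen_noise_sd: float
    richness_true: dict[str, int]  # retained morphotypes incl. focal
    fungicide_total: dict[str, float]  # ppb
    fungicide_noise_sd: float
    insecticide_total: dict[str, float]  # ppb
    insecticide_noise_sd: float
    unsprayed_compounds: dict[str, frozenset]
    nonspray_count: dict[str, int]
    nonspray_fraction_contact: dict[str, float]
    nonspray_fraction_oral: dict[str, float]


@dataclass
class SyntheticStudy:
    config: SynthConfig
    toxdb: dict[str, CompoundTox]
    grid: LandCoverGrid
    sites: dict[str, tuple[float, float]]
    sprays: list[SprayEvent]
    pollen: list[PollenSample]
    residues: list[ResidueRecord]
    truth: GroundTruth

    def write(self, out_dir) -> None:
        """Write the study as the pipeline's input files (CSV + .asc)."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _io.write_toxdb(self.toxdb, out / "toxdb.csv")
        _io.write_residues(self.residues, out / "residues.csv")
        _io.write_sprays(self.sprays, out / "sprays.csv")
        _io.write_pollen(self.pollen, out / "pollen_counts.csv")
        _io.write_sites(self.sites, out / "sites.csv")
        _io.write_grid(self.grid, out / "landcover.asc")
        import json
        import pandas as pd

        rows = [
            {"code": c, "name": lc.name, "group": lc.group}
            for c, lc in sorted(self.grid.class_map.items())
        ]
        pd.DataFrame(rows).to_csv(out / "class_map.csv", index=False)
        (out / "metadata.json").write_text(
            json.dumps({"seed": self.config.seed, "n_sites": self.config.n_sites}, indent=2)
        )


# ---------------------------------------------------------------------------
# calibration arithmetic

def _population_r2(r2_sample_target: float, n: int) -> float:
    """Population R² whose OLS sample R² has expectation ~ the target.

    E[R²] ≈ ρ² + (1 − ρ²)/(n − 1) for a simple regression on a fixed
    design, so the target is deflated accordingly before solving noise
    variances.  For targets below the null expectation 1/(n−1) (only
    reachable at very small n) the correction is skipped.
    """
    c = 1.0 / (n - 1)
    corrected = (r2_sample_target - c) / (1.0 - c)
    return corrected if corrected > 0 else r2_sample_target


def _solve_response_noise_sd(
    signal: np.ndarray, r2_sample_target: float, extra_noise_var: float = 0.0
) -> float:
    """Gaussian response-noise SD for R² = var(signal)/(var(signal)+var(noise)).

    ``extra_noise_var`` is measurement noise already present in the response
    (e.g. multinomial counting error), subtracted from the noise budget.
    """
    n = signal.size
    if r2_sample_target >= 0.999:
        return 0.0
    r2p = _population_r2(r2_sample_target, n)
    if r2p <= 0:
        raise ValueError(f"R² target {r2_sample_target} unattainable at n={n}")
    vs = float(np.var(signal, ddof=1))
    ve = vs * (1.0 - r2p) / r2p
    return math.sqrt(max(ve - extra_noise_var, 0.0))


def _solve_coupling_noise_sd(
    predictor: np.ndarray,
    slope: float,
    r2_sample_target: float,
    predictor_noise_var: float = 0.0,
) -> float:
    """Gaussian noise SD for a response coupled to a noisily-MEASURED predictor.

    The response is slope·p + ε but the regression runs on p̂ = p + u, which
    attenuates R² by λ = var(p)/(var(p)+var(u)); the noise variance solves
    λ·b²v_p/(b²v_p + v_ε) = target, i.e. v_ε = b²v_p(λ/target − 1).
    """
    n = predictor.size
    if r2_sample_target >= 0.999:
        return 0.0
    r2p = _population_r2(r2_sample_target, n)
    if r2p <= 0:
        raise ValueError(f"R² target {r2_sample_target} unattainable at n={n}")
    vp = float(np.var(predictor, ddof=1))
    lam = vp / (vp + predictor_noise_var)
    if lam <= r2p:
        raise ValueError(
            f"R² target {r2_sample_target} exceeds the attenuation ceiling {lam:.3f}"
        )
    return math.sqrt(slope**2 * vp * (lam / r2p - 1.0))


def _solve_ztp_lambda(mean: float) -> float:
    """Rate of a zero-truncated Poisson with the given mean (bisection)."""
    if mean <= 1:
        raise ValueError(f"zero-truncated Poisson mean must exceed 1, got {mean}")
    lo, hi = 1e-9, mean
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        m = mid / (1.0 - math.exp(-mid))
        if m < mean:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# generation

def _make_landscape(cfg: SynthConfig, rng: np.random.Generator):
    n = cfg.n_sites
    cs = cfg.cell_size_m
    R = cfg.buffer_radius_m
    apple_frac = rng.uniform(*cfg.apple_area_range, size=n)

    # site lattice with non-overlapping buffers
    ncols_l = math.ceil(math.sqrt(n))
    nrows_l = math.ceil(n / ncols_l)
    spacing = 2 * R + 200.0
    margin = R + 100.0
    width = (ncols_l - 1) * spacing + 2 * margin
    height = (nrows_l - 1) * spacing + 2 * margin
    ncols = math.ceil(width / cs)
    nrows = math.ceil(height / cs)

    codes = rng.choice(_BACKGROUND_CODES, size=(nrows, ncols), p=_BACKGROUND_P).astype(np.int32)

    sites: dict[str, tuple[float, float]] = {}
    for i in range(n):
        sid = f"S{i + 1:02d}"
        li, lj = divmod(i, ncols_l)
        cx = margin + lj * spacing
        cy = margin + li * spacing
        sites[sid] = (cx, cy)

        # fill the site's buffer disc: apple at the site's focal-crop
        # density, the rest a site-specific natural/agricultural mix
        col_lo = max(0, int((cx - R) / cs) - 1)
        col_hi = min(ncols, int((cx + R) / cs) + 2)
        row_top = nrows * cs
        row_lo = max(0, int((row_top - (cy + R)) / cs) - 1)
        row_hi = min(nrows, int((row_top - (cy - R)) / cs) + 2)
        cols = np.arange(col_lo, col_hi)
        rows = np.arange(row_lo, row_hi)
        xs = (cols + 0.5) * cs
        ys = (nrows - 1 - rows + 0.5) * cs
        inside = (xs[None, :] - cx) ** 2 + (ys[:, None] - cy) ** 2 <= R**2
        n_in = int(inside.sum())
        u = rng.random(n_in)
        nat_share = rng.uniform(0.35, 0.65)
        cell_codes = np.empty(n_in, dtype=np.int32)
        is_apple = u < apple_frac[i]
        cell_codes[is_apple] = _APPLE_CODE
        rest = ~is_apple
        v = rng.random(int(rest.sum()))
        rest_codes = np.where(
            v < nat_share,
            np.where(rng.random(v.size) < 0.5, *_NATURAL_CODES),
            np.where(rng.random(v.size) < 0.5, *_AGRI_CODES),
        )
        cell_codes[rest] = rest_codes
        sub = codes[row_lo:row_hi, col_lo:col_hi]
        sub[inside] = cell_codes

    grid = LandCoverGrid(
        codes=codes,
        cell_size=cs,
        xll=0.0,
        yll=0.0,
        class_map=_io.default_classmap(),
    )
    return grid, sites, apple_frac


def _make_pollen(cfg: SynthConfig, rng: np.random.Generator, apple_frac: np.ndarray):
    n = cfg.n_sites
    site_ids = [f"S{i + 1:02d}" for i in range(n)]
    p_mean = cfg.pollen_intercept + cfg.pollen_slope * apple_frac
    count_var = float(np.mean(p_mean * (1 - p_mean))) / cfg.grains_per_slide
    if cfg.pollen_noise_sd is not None:
        noise_sd = cfg.pollen_noise_sd
    else:
        noise_sd = _solve_response_noise_sd(
            cfg.pollen_slope * apple_frac, cfg.r2_apple_pollen, extra_noise_var=count_var
        )
    p_latent = np.clip(p_mean + rng.normal(0.0, noise_sd, size=n), 0.002, 0.9)

    names = [nm for nm, _ in _NONFOCAL_POOL]
    weights = np.array([w for _, w in _NONFOCAL_POOL])
    weights = weights / weights.sum()
    lo, hi = cfg.richness_range
    k = rng.integers(lo, hi + 1, size=n)

    samples = []
    richness_true = {}
    for i, sid in enumerate(site_ids):
        chosen = rng.choice(len(names), size=int(k[i]), replace=False, p=weights)
        rem = 1.0 - p_latent[i]
        # floor each non-focal type's share so none is sporadic by construction
        floor = min(0.04, 0.7 * rem / k[i])
        alpha = weights[chosen] * 20.0
        extra = rng.dirichlet(alpha) * (rem - floor * k[i])
        probs = np.concatenate(([p_latent[i]], floor + extra))
        counts = rng.multinomial(cfg.grains_per_slide, probs / probs.sum())
        cmap = {FOCAL_MORPHOTYPE: int(counts[0])}
        for j, ci in enumerate(chosen):
            cmap[names[ci]] = int(counts[j + 1])
        samples.append(
            PollenSample.from_counts(sid, {m: c for m, c in cmap.items() if c > 0})
        )
        richness_true[sid] = int(k[i]) + 1  # non-focal types + the focal crop
    return samples, p_latent, noise_sd, richness_true, count_var


def _allocate(
    total: float,
    pool: dict[str, float],
    n_compounds: int,
    toxdb: Mapping[str, CompoundTox],
    lods: Mapping[str, float],
    rng: np.random.Generator,
) -> dict[str, float]:
    """Split a class total across compounds; shares that would fall below a
    compound's LOD are merged into the largest share so the total is exact."""
    names = list(pool)
    w = np.array([pool[c] for c in names])
    chosen_idx = rng.choice(len(names), size=min(n_compounds, len(names)), replace=False, p=w / w.sum())
    chosen = [names[i] for i in chosen_idx]
    shares = rng.dirichlet(np.ones(len(chosen)) * 1.2) * total
    alloc = dict(zip(chosen, shares))
    # merge sub-LOD shares into the current largest
    while True:
        low = [c for c, v in alloc.items() if v < lods[c] and len(alloc) > 1]
        if not low:
            break
        c = low[0]
        v = alloc.pop(c)
        biggest = max(alloc, key=alloc.get)
        alloc[biggest] += v
    return {c: v for c, v in alloc.items() if v >= lods[c]}


def _make_residues(
    cfg: SynthConfig,
    rng: np.random.Generator,
    p_latent: np.ndarray,
    richness_true: dict[str, int],
    count_var: float,
    toxdb: Mapping[str, CompoundTox],
):
    n = cfg.n_sites
    site_ids = [f"S{i + 1:02d}" for i in range(n)]
    survey = _io.load_survey_residues()
    lods = dict(zip(survey["compound"], survey["lod_ppb"]))

    fung_sd = _solve_coupling_noise_sd(
        p_latent, cfg.fungicide_slope_ppb, cfg.r2_fungicide, predictor_noise_var=count_var
    )
    t_fung = np.clip(
        cfg.fungicide_intercept_ppb
        + cfg.fungicide_slope_ppb * p_latent
        + rng.normal(0.0, fung_sd, size=n),
        20.0,
        None,
    )
    rich = np.array([richness_true[s] for s in site_ids], dtype=float)
    if cfg.r2_insecticide_richness <= 0:
        # true null: richness carries no signal; noise at a realistic scale
        ins_slope = 0.0
        ins_sd = float(cfg.insecticide_slope_ppb * np.std(rich, ddof=1))
    else:
        ins_slope = cfg.insecticide_slope_ppb
        ins_sd = _solve_response_noise_sd(
            ins_slope * rich, cfg.r2_insecticide_richness
        )
    t_ins = np.clip(
        cfg.insecticide_intercept_ppb
        + ins_slope * rich
        + rng.normal(0.0, ins_sd, size=n),
        5.0,
        None,
    )

    residues: list[ResidueRecord] = []
    conc_by_site: dict[str, dict[str, float]] = {}
    for i, sid in enumerate(site_ids):
        conc: dict[str, float] = {}
        conc.update(
            _allocate(float(t_fung[i]), _FUNGICIDE_POOL, int(rng.integers(3, 7)), toxdb, lods, rng)
        )
        conc.update(
            _allocate(float(t_ins[i]), _INSECTICIDE_POOL, int(rng.integers(2, 6)), toxdb, lods, rng)
        )
        if rng.random() < 0.2:
            conc["Atrazine"] = float(rng.uniform(36.0, 80.0))  # above its LOD
        conc_by_site[sid] = conc
        for comp in toxdb:
            c = conc.get(comp, 0.0)
            residues.append(
                ResidueRecord.from_measurement(sid, comp, c, float(lods[comp]))
            )
    return residues, conc_by_site, dict(zip(site_ids, t_fung)), fung_sd, dict(zip(site_ids, t_ins)), ins_sd


def _make_sprays(
    cfg: SynthConfig,
    rng: np.random.Generator,
    conc_by_site: dict[str, dict[str, float]],
    toxdb: Mapping[str, CompoundTox],
):
    q = cfg.nonspray_site_fraction
    ztp_mean = cfg.nonspray_rate / q
    lam = _solve_ztp_lambda(ztp_mean) if cfg.nonspray_rate > 0 else 0.0

    sprays: list[SprayEvent] = []
    unsprayed: dict[str, frozenset] = {}
    nonspray_count: dict[str, int] = {}
    fung_names = list(_FUNGICIDE_POOL)
    for sid, conc in conc_by_site.items():
        detected = sorted(conc)
        if cfg.nonspray_rate > 0 and rng.random() < q:
            n_ns = 0
            while n_ns < 1:  # zero-truncated Poisson by rejection
                n_ns = int(rng.poisson(lam))
            n_ns = min(n_ns, len(detected))
        else:
            n_ns = 0
        w = np.array([5.0 if c in _NONSPRAY_PRONE else 1.0 for c in detected])
        ns_idx = rng.choice(len(detected), size=n_ns, replace=False, p=w / w.sum())
        ns_set = frozenset(detected[i] for i in ns_idx)
        unsprayed[sid] = ns_set
        nonspray_count[sid] = n_ns

        def _event(compound: str, bloom: bool) -> SprayEvent:
            offset = int(rng.integers(0, _BLOOM_DAYS)) if bloom else -int(rng.integers(5, 20))
            return SprayEvent(
                site_id=sid,
                compound=compound,
                date=_BLOOM_START + timedelta(days=offset),
                pct_ai=float(rng.uniform(20.0, 90.0)),
                app_rate=float(rng.uniform(0.5, 4.0)),
                during_bloom=bloom,
            )

        for comp in detected:
            if comp in ns_set:
                continue
            sprays.append(_event(comp, True))
            if rng.random() < 0.3:  # repeat application
                sprays.append(_event(comp, True))
        # during-bloom sprays of compounds that never showed up in beebread
        extra_pool = [c for c in fung_names if c not in conc and c not in ns_set]
        for comp in rng.choice(extra_pool, size=min(int(rng.integers(0, 3)), len(extra_pool)), replace=False):
            sprays.append(_event(str(comp), True))
        # pre-bloom events (never count toward the use index or attribution)
        for comp in rng.choice(detected, size=min(int(rng.integers(0, 3)), len(detected)), replace=False):
            sprays.append(_event(str(comp), False))
    return sprays, unsprayed, nonspray_count


def _true_nonspray_fractions(
    conc_by_site: dict[str, dict[str, float]],
    unsprayed: dict[str, frozenset],
    toxdb: Mapping[str, CompoundTox],
):
    frac_c: dict[str, float] = {}
    frac_o: dict[str, float] = {}
    for sid, conc in conc_by_site.items():
        for route, out in (("contact", frac_c), ("oral", frac_o)):
            tot = uns = 0.0
            for comp, c in conc.items():
                ld = toxdb[comp].ld50(route)
                if ld is None:
                    continue
                v = c / ld
                tot += v
                if comp in unsprayed[sid]:
                    uns += v
            out[sid] = uns / tot if tot > 0 else 0.0
    return frac_c, frac_o


def generate_study(config: SynthConfig = SynthConfig()) -> SyntheticStudy:
    """Generate a complete synthetic orchard study (deterministic per seed)."""
    toxdb = _io.default_toxdb()
    ss = np.random.SeedSequence(config.seed)
    rng_land, rng_pollen, rng_resid, rng_spray = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    grid, sites, apple_frac = _make_landscape(config, rng_land)
    samples, p_latent, pollen_sd, richness_true, count_var = _make_pollen(
        config, rng_pollen, apple_frac
    )
    residues, conc_by_site, t_fung, fung_sd, t_ins, ins_sd = _make_residues(
        config, rng_resid, p_latent, richness_true, count_var, toxdb
    )
    sprays, unsprayed, nonspray_count = _make_sprays(
        config, rng_spray, conc_by_site, toxdb
    )
    frac_c, frac_o = _true_nonspray_fractions(conc_by_site, unsprayed, toxdb)

    site_ids = list(sites)
    truth = GroundTruth(
        apple_area=dict(zip(site_ids, apple_frac.tolist())),
        pollen_latent=dict(zip(site_ids, p_latent.tolist())),
        pollen_intercept=config.pollen_intercept,
        pollen_slope=config.pollen_slope,
        pollen_noise_sd=pollen_sd,
        richness_true=richness_true,
        fungicide_total=t_fung,
        fungicide_noise_sd=fung_sd,
        insecticide_total=t_ins,
        insecticide_noise_sd=ins_sd,
        unsprayed_compounds=unsprayed,
        nonspray_count=nonspray_count,
        nonspray_fraction_contact=frac_c,
        nonspray_fraction_oral=frac_o,
    )
    return SyntheticStudy(
        config=config,
        toxdb=toxdb,
        grid=grid,
        sites=sites,
        sprays=sprays,
        pollen=samples,
        residues=residues,
        truth=truth,
    )


def ground_truth(study: SyntheticStudy) -> GroundTruth:
    """The latent parameters behind a generated study."""
    return study.truth
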