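"""Seed-reproducible synthetic datasets with known ground truth.

Three generators emulate the data a river-corridor exchange study needs,
each with an analytic or planted truth so every pipeline stage can be
validated without field data:

* :func:`generate_valley` — a glaciated-valley scene: a straight river
  flowing north with a planar stage surface, flanked by an alluvial
  aquifer whose piezometric surface is piecewise planar per reach
  (gaining reaches slope toward the river, losing reaches away from it).
  Reaches are separated by transition bands carrying no bank segments, so
  the surface stays continuous while each reach remains exactly planar
  and zone fluxes have a closed form 86400*K*i*A*sin(D)*L.
* :func:`generate_community` — 36 wetland sites with monthly temperature,
  phosphate and ammonia series plus substrate phosphorus, and floristic
  relevés whose species abundances peak at planted trophic / thermal
  optima (Poisson or negative-binomial counts).
* :func:`generate_stygofauna` — interstitial fauna samples whose stygobite
  counts scale with a configured per-zone upwelling intensity.

Default magnitudes mirror an alpine alluvial corridor: permeabilities
1e-5..1.3e-3 m/s, exchange cross-sections around 4.2 m, aquifer thickness
of order 10 m; noise is off (valley) or low (communities) by default so
oracle comparisons stay tight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import RivaqError
from .exchange import SECONDS_PER_DAY, BankSegment
from .macrophytes import BB_NUMERIC
from .stygofauna import STATUS_EPIGEAN, STATUS_STYGOBITE, load_stygobite_reference

# ---------------------------------------------------------------------------
# hydraulic valley


@dataclass
class ReachSpec:
    """One hydraulic reach: constant K and head gradient toward (+) or
    away from (−) the river over a y-band of the valley."""

    zone: str
    y_lo: float
    y_hi: float
    K: float  # m/s
    g: float  # head gradient component toward the river (dimensionless)


@dataclass
class ValleyConfig:
    x_river: float = 1500.0  # river line x (m); aquifer occupies x < x_river
    y_max: float = 4000.0
    stage_0: float = 205.0  # river stage at y = 0 (m)
    stage_dy: float = -5e-4  # stage trend along flow (falls northward)
    depth: float = 4.2  # stage minus riverbed (m)
    reaches: list[ReachSpec] = field(
        default_factory=lambda: [
            ReachSpec("Z_gain", 0.0, 1800.0, 1.3e-3, 2.0e-3),
            ReachSpec("Z_lose", 2200.0, 4000.0, 3.9e-4, -2.0e-3),
        ]
    )
    n_points: int = 600
    bank_offset: float = 5.0  # segments sit this far west of the river line
    river_halfwidth: float = 20.0  # river-stage TIN band half-width (m)
    segment_length: float = 100.0
    kp_0: float = 116.0  # KP at y = 0; KP decreases downstream (north)
    head_noise_sd: float = 0.0  # Gaussian noise on piezometric z (m)
    #: when False the head carries no along-valley trend, so groundwater
    #: flows exactly perpendicular to the river (D = +/-90 degrees)
    head_from_stage: bool = True
    seed: int = 0


@dataclass
class SimulatedValley:
    piezo_points: pd.DataFrame  # x, y, z
    river_points: pd.DataFrame
    segments: list[BankSegment]
    expected: pd.DataFrame  # zone, Qf_pos, Qf_neg (closed form)
    config: ValleyConfig


def _reach_gradient_fn(reaches: list[ReachSpec]):
    """g(y): constant within reaches, linear across the gaps between them."""
    ys, gs = [], []
    for r in sorted(reaches, key=lambda r: r.y_lo):
        ys += [r.y_lo, r.y_hi]
        gs += [r.g, r.g]
    return lambda y: np.interp(y, ys, gs)


def generate_valley(config: ValleyConfig | None = None) -> SimulatedValley:
    """Build the synthetic valley scene and its closed-form zone fluxes.

    The piezometric head is  h(x, y) = stage(y) + g(y) * (x_river − x),
    exactly planar inside each reach band.  Bank segments lie on a polyline
    ``bank_offset`` metres west of the river line, only inside reach bands,
    so the TIN pipeline and the closed form see the same planes.
    """
    cfg = config or ValleyConfig()
    rng = np.random.default_rng(cfg.seed)
    if not cfg.reaches:
        raise RivaqError("invalid geometry: no reaches configured")
    for r in cfg.reaches:
        if r.K <= 0:
            raise RivaqError(f"invalid geometry: K must be positive in {r.zone}")
        if not (0.0 <= r.y_lo < r.y_hi <= cfg.y_max):
            raise RivaqError(f"invalid geometry: reach {r.zone} outside domain")

    stage = lambda y: cfg.stage_0 + cfg.stage_dy * np.asarray(y, dtype=float)
    g_of_y = _reach_gradient_fn(cfg.reaches)

    # --- piezometric points: a grid with rows exactly at reach boundaries
    n_rows = max(8, int(round(math.sqrt(cfg.n_points / 2))))
    n_cols = max(6, int(math.ceil(cfg.n_points / n_rows)))
    y_rows = np.unique(
        np.concatenate(
            [np.linspace(0.0, cfg.y_max, n_rows)]
            + [[r.y_lo, r.y_hi] for r in cfg.reaches]
        )
    )
    x_cols = np.linspace(0.0, cfg.x_river, n_cols)
    dx = x_cols[1] - x_cols[0]
    px, py = [], []
    for y in y_rows:
        jitter = rng.uniform(-0.2 * dx, 0.2 * dx, size=n_cols)
        jitter[0] = jitter[-1] = 0.0  # keep the hull rectangular
        px.append(x_cols + jitter)
        py.append(np.full(n_cols, y))
    px, py = np.concatenate(px), np.concatenate(py)
    head_base = stage(py) if cfg.head_from_stage else np.full_like(py, cfg.stage_0)
    pz = head_base + g_of_y(py) * (cfg.x_river - px)
    if cfg.head_noise_sd > 0:
        pz = pz + rng.normal(0.0, cfg.head_noise_sd, size=pz.shape)
    piezo = pd.DataFrame({"x": px, "y": py, "z": pz})

    # --- river-stage points: narrow planar band around the river line
    rx, ry = np.meshgrid(
        np.array([-cfg.river_halfwidth, 0.0, cfg.river_halfwidth]) + cfg.x_river,
        y_rows,
    )
    river = pd.DataFrame(
        {"x": rx.ravel(), "y": ry.ravel(), "z": stage(ry.ravel())}
    )

    # --- bank segments inside reach bands, with closed-form fluxes
    xb = cfg.x_river - cfg.bank_offset
    segments: list[BankSegment] = []
    expected_rows = []
    margin = 1e-6
    for reach in cfg.reaches:
        qf_pos = qf_neg = 0.0
        n_seg = int((reach.y_hi - reach.y_lo) // cfg.segment_length)
        head_dy = cfg.stage_dy if cfg.head_from_stage else 0.0
        i_mag = math.hypot(reach.g, head_dy)
        aspect_p = math.degrees(math.atan2(reach.g, -head_dy)) % 360.0
        aspect_r = math.degrees(math.atan2(0.0, -cfg.stage_dy)) % 360.0
        D = (aspect_p - aspect_r) % 360.0
        if D > 180.0:
            D -= 360.0
        for j in range(n_seg):
            y0 = reach.y_lo + j * cfg.segment_length + margin
            y1 = min(y0 + cfg.segment_length, reach.y_hi) - margin
            ym = (y0 + y1) / 2.0
            riverbed = float(stage(ym)) - cfg.depth
            seg = BankSegment(
                segment_id=f"{reach.zone}-{j:03d}",
                start=(xb, y0),
                end=(xb, y1),
                zone=reach.zone,
                bank="left",
                kp_range=(cfg.kp_0 - y1 / 1000.0, cfg.kp_0 - y0 / 1000.0),
                K=reach.K,
                riverbed_z=riverbed,
            )
            segments.append(seg)
            head_ref = float(stage(ym)) if cfg.head_from_stage else cfg.stage_0
            head = head_ref + reach.g * cfg.bank_offset
            A = max(head - riverbed, 0.0)
            qe = SECONDS_PER_DAY * reach.K * i_mag * A * math.sin(math.radians(D))
            if qe > 0:
                qf_pos += qe * seg.L
            else:
                qf_neg += qe * seg.L
        expected_rows.append(
            {"zone": reach.zone, "Qf_pos": qf_pos, "Qf_neg": qf_neg}
        )
    expected = pd.DataFrame(expected_rows).set_index("zone").sort_index()
    return SimulatedValley(piezo, river, segments, expected, cfg)


# ---------------------------------------------------------------------------
# wetland communities


@dataclass
class CommunityConfig:
    n_sites: int = 36
    n_trophic_species: int = 24  # unimodal responders to the trophic gradient
    n_thermal_species: int = 16  # responders to temperature variability
    months: int = 12
    amplitude: float = 30.0  # expected count at a species' optimum class
    decay: float = 0.15  # abundance ratio per class step away from optimum
    nb_dispersion: float | None = None  # NB size parameter; None -> Poisson
    cv_range: tuple[float, float] = (2.0, 40.0)  # temperature CV spread (%)
    nh3_levels: tuple[float, ...] = (0.01, 0.05, 0.2, 0.8)  # mg/L per class
    po4_levels: tuple[float, ...] = (0.005, 0.03, 0.15, 0.8)  # mg/L per class
    env_lognoise_sd: float = 0.05  # log10-scale within-class spread
    seed: int = 0


@dataclass
class SimulatedCommunity:
    environment: dict  # per-variable site series
    releves: dict[str, dict[str, str]]  # site -> species -> BB code
    truth: dict  # planted site classes and species optima
    config: CommunityConfig


def _count_to_bb(count: int) -> str | None:
    if count <= 0:
        return None
    for code, hi in (("+", 1), ("1", 5), ("2", 12), ("3", 25), ("4", 50)):
        if count <= hi:
            return code
    return "5"


def generate_community(config: CommunityConfig | None = None) -> SimulatedCommunity:
    """Simulate wetlands, their physico-chemistry and floristic relevés.

    Each site carries a planted 4-level trophic class (phosphate, substrate
    P and ammonia all scale with it) and an independent temperature-
    variability level spanning ``cv_range`` (realized series are rescaled
    so the sample CV equals the planted value exactly).  Species counts
    follow a geometric unimodal response around each species' planted
    optimum class and are rendered as Braun-Blanquet codes.
    """
    cfg = config or CommunityConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_sites
    sites = [f"W{i:02d}" for i in range(n)]

    trophic_class = np.resize(np.arange(4), n)
    rng.shuffle(trophic_class)
    cv_values = np.linspace(*cfg.cv_range, n)
    rng.shuffle(cv_values)
    thermal_class = np.searchsorted(
        np.quantile(cv_values, [0.2, 0.4, 0.6, 0.8]), cv_values
    )

    def _lognoise(size):
        return 10 ** rng.normal(0.0, cfg.env_lognoise_sd, size=size)

    env_temp, env_po4, env_nh3, env_totp = {}, {}, {}, {}
    for idx, site in enumerate(sites):
        raw = rng.normal(size=cfg.months)
        sd_target = cv_values[idx] / 100.0 * 12.0
        temp = 12.0 + (raw - raw.mean()) / raw.std(ddof=1) * sd_target
        env_temp[site] = temp
        t = trophic_class[idx]
        env_po4[site] = cfg.po4_levels[t] * _lognoise(cfg.months)
        env_nh3[site] = cfg.nh3_levels[t] * _lognoise(cfg.months)
        env_totp[site] = 200.0 * cfg.po4_levels[t] * _lognoise(4)

    species_rows = []
    for j in range(cfg.n_trophic_species):
        species_rows.append(("T%02d" % j, "trophic", j % 4))
    for j in range(cfg.n_thermal_species):
        species_rows.append(("S%02d" % j, "thermal", j % 5))

    releves: dict[str, dict[str, str]] = {s: {} for s in sites}
    for name, kind, optimum in species_rows:
        site_class = trophic_class if kind == "trophic" else thermal_class
        mu = cfg.amplitude * cfg.decay ** np.abs(site_class - optimum)
        if cfg.nb_dispersion is None:
            counts = rng.poisson(mu)
        else:
            r = cfg.nb_dispersion
            counts = rng.negative_binomial(r, r / (r + mu))
        for idx, site in enumerate(sites):
            code = _count_to_bb(int(counts[idx]))
            if code is not None:
                releves[site][name] = code

    truth = {
        "sites": pd.DataFrame(
            {
                "site_id": sites,
                "trophic_class": trophic_class,
                "thermal_class": thermal_class,
                "temperature_cv": cv_values,
            }
        ).set_index("site_id"),
        "species": pd.DataFrame(
            species_rows, columns=["species", "kind", "optimum"]
        ).set_index("species"),
    }
    environment = {
        "temperature": env_temp,
        "po4": env_po4,
        "nh3": env_nh3,
        "substrate_totalp": env_totp,
    }
    return SimulatedCommunity(environment, releves, truth, cfg)


# ---------------------------------------------------------------------------
# interstitial fauna


def generate_stygofauna(
    upwelling: list[tuple[str, float, float, float]],
    seed: int = 0,
    n_sites_per_zone: int = 3,
    visits: int = 2,
    n_epigean: int = 8,
    epigean_mean: float = 3.0,
) -> pd.DataFrame:
    """Interstitial fauna samples with stygobite counts tied to upwelling.

    ``upwelling`` rows are (zone_id, kp_lo, kp_hi, intensity >= 0); expected
    stygobite counts per species scale linearly with intensity (Poisson
    draws), so zero-intensity zones yield strictly zero stygobites.  A
    background epigean community is always present.  Species names come
    from the packaged regional stygobite reference list.
    """
    rng = np.random.default_rng(seed)
    ref = load_stygobite_reference()
    styg_species = list(ref["species"])
    weights = np.array([0.4, 0.25, 0.15, 0.1, 0.05, 0.02, 0.01, 0.01, 0.01])
    weights = weights[: len(styg_species)] / weights[: len(styg_species)].sum()
    rows = []
    for zone_id, kp_lo, kp_hi, intensity in upwelling:
        if intensity < 0:
            raise RivaqError("upwelling intensity must be >= 0")
        lo, hi = min(kp_lo, kp_hi), max(kp_lo, kp_hi)
        kps = np.linspace(lo, hi, n_sites_per_zone + 2)[1:-1]
        for si, kp in enumerate(kps):
            site = f"{zone_id}-S{si}"
            for visit in range(visits):
                date = f"visit{visit}"
                for sp, w in zip(styg_species, weights):
                    count = int(rng.poisson(intensity * w))
                    rows.append((site, kp, "main_channel", date, sp,
                                 STATUS_STYGOBITE, count))
                for e in range(n_epigean):
                    count = int(rng.poisson(epigean_mean))
                    rows.append((site, kp, "main_channel", date, f"Epigean sp. {e}",
                                 STATUS_EPIGEAN, count))
    return pd.DataFrame(
        rows,
        columns=["site_id", "kp", "habitat", "date", "taxon", "status", "count"],
    )
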