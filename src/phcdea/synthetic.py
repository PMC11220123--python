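"""Synthetic provincial primary-healthcare panels with known ground truth.

The generator emulates the statistical structure the three-stage method
assumes: a smooth production frontier that shifts by a factor g per year
(Hicks-neutral technical change), input-oriented inefficiency applied
multiplicatively to the efficient input bundle, an inefficiency magnitude
that depends linearly on environmental covariates plus a spatially
autocorrelated (SAR) component over the province contiguity graph plus a
half-normal idiosyncratic term, and i.i.d. lognormal measurement noise.
Every draw is returned together with its ground truth so recovery tests
can compare estimated efficiency against exp(-u).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import ENV_COLS, INPUT_COLS, OUTPUT_COLS, PanelDataset

# ---------------------------------------------------------------------------
# 31-unit province fixture: labels (reporting order), regions (11 east /
# 8 central / 12 west), land-border contiguity with the Hainan-Guangdong
# strait join so the graph is connected, and approximate planar centroids
# (lon, lat) for k-nearest-neighbour weights.
# ---------------------------------------------------------------------------

PROVINCES = (
    "Beijing", "Tianjin", "Hebei", "Shanxi", "Inner Mongolia", "Liaoning",
    "Jilin", "Heilongjiang", "Shanghai", "Jiangsu", "Zhejiang", "Anhui",
    "Fujian", "Jiangxi", "Shandong", "Henan", "Hubei", "Hunan", "Guangdong",
    "Guangxi", "Hainan", "Chongqing", "Sichuan", "Guizhou", "Yunnan", "Tibet",
    "Shaanxi", "Gansu", "Qinghai", "Ningxia", "Xinjiang",
)

REGIONS = {
    **{p: "east" for p in ("Beijing", "Tianjin", "Hebei", "Liaoning", "Shanghai",
                           "Jiangsu", "Zhejiang", "Fujian", "Shandong",
                           "Guangdong", "Hainan")},
    **{p: "central" for p in ("Shanxi", "Jilin", "Heilongjiang", "Anhui",
                              "Jiangxi", "Henan", "Hubei", "Hunan")},
    **{p: "west" for p in ("Inner Mongolia", "Guangxi", "Chongqing", "Sichuan",
                           "Guizhou", "Yunnan", "Tibet", "Shaanxi", "Gansu",
                           "Qinghai", "Ningxia", "Xinjiang")},
}

CONTIGUITY_EDGES = (
    ("Beijing", "Tianjin"), ("Beijing", "Hebei"), ("Tianjin", "Hebei"),
    ("Hebei", "Liaoning"), ("Hebei", "Inner Mongolia"), ("Hebei", "Shanxi"),
    ("Hebei", "Henan"), ("Hebei", "Shandong"),
    ("Shanxi", "Inner Mongolia"), ("Shanxi", "Shaanxi"), ("Shanxi", "Henan"),
    ("Inner Mongolia", "Heilongjiang"), ("Inner Mongolia", "Jilin"),
    ("Inner Mongolia", "Liaoning"), ("Inner Mongolia", "Shaanxi"),
    ("Inner Mongolia", "Ningxia"), ("Inner Mongolia", "Gansu"),
    ("Liaoning", "Jilin"), ("Jilin", "Heilongjiang"),
    ("Shanghai", "Jiangsu"), ("Shanghai", "Zhejiang"),
    ("Jiangsu", "Zhejiang"), ("Jiangsu", "Anhui"), ("Jiangsu", "Shandong"),
    ("Zhejiang", "Anhui"), ("Zhejiang", "Jiangxi"), ("Zhejiang", "Fujian"),
    ("Anhui", "Jiangxi"), ("Anhui", "Hubei"), ("Anhui", "Henan"),
    ("Anhui", "Shandong"),
    ("Fujian", "Jiangxi"), ("Fujian", "Guangdong"),
    ("Jiangxi", "Guangdong"), ("Jiangxi", "Hunan"), ("Jiangxi", "Hubei"),
    ("Shandong", "Henan"),
    ("Henan", "Shaanxi"), ("Henan", "Hubei"),
    ("Hubei", "Shaanxi"), ("Hubei", "Chongqing"), ("Hubei", "Hunan"),
    ("Hunan", "Chongqing"), ("Hunan", "Guizhou"), ("Hunan", "Guangxi"),
    ("Hunan", "Guangdong"),
    ("Guangdong", "Guangxi"), ("Guangdong", "Hainan"),
    ("Guangxi", "Yunnan"), ("Guangxi", "Guizhou"),
    ("Chongqing", "Shaanxi"), ("Chongqing", "Guizhou"), ("Chongqing", "Sichuan"),
    ("Sichuan", "Qinghai"), ("Sichuan", "Gansu"), ("Sichuan", "Shaanxi"),
    ("Sichuan", "Guizhou"), ("Sichuan", "Yunnan"), ("Sichuan", "Tibet"),
    ("Guizhou", "Yunnan"),
    ("Yunnan", "Tibet"),
    ("Tibet", "Xinjiang"), ("Tibet", "Qinghai"),
    ("Shaanxi", "Gansu"), ("Shaanxi", "Ningxia"),
    ("Gansu", "Xinjiang"), ("Gansu", "Qinghai"), ("Gansu", "Ningxia"),
    ("Qinghai", "Xinjiang"),
)

COORDS = {
    "Beijing": (116.4, 39.9), "Tianjin": (117.2, 39.1), "Hebei": (114.5, 38.0),
    "Shanxi": (112.5, 37.9), "Inner Mongolia": (111.7, 40.8),
    "Liaoning": (123.4, 41.8), "Jilin": (125.3, 43.9),
    "Heilongjiang": (126.6, 45.8), "Shanghai": (121.5, 31.2),
    "Jiangsu": (118.8, 32.1), "Zhejiang": (120.2, 30.3), "Anhui": (117.3, 31.9),
    "Fujian": (119.3, 26.1), "Jiangxi": (115.9, 28.7), "Shandong": (117.0, 36.7),
    "Henan": (113.7, 34.8), "Hubei": (114.3, 30.6), "Hunan": (113.0, 28.2),
    "Guangdong": (113.3, 23.1), "Guangxi": (108.3, 22.8), "Hainan": (110.3, 20.0),
    "Chongqing": (106.5, 29.6), "Sichuan": (104.1, 30.7), "Guizhou": (106.7, 26.6),
    "Yunnan": (102.7, 25.0), "Tibet": (91.1, 29.7), "Shaanxi": (108.9, 34.3),
    "Gansu": (103.8, 36.1), "Qinghai": (101.8, 36.6), "Ningxia": (106.3, 38.5),
    "Xinjiang": (87.6, 43.8),
}


def province_fixture():
    """31 province labels, region mapping, contiguity edges and coordinates."""
    return (list(PROVINCES), dict(REGIONS), list(CONTIGUITY_EDGES),
            np.array([COORDS[p] for p in PROVINCES]))


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Study conditions of the generated panel.

    Defaults mirror the provincial panel the method targets: 31 units over
    9 years (2012-2020) with 3 inputs, 2 outputs and 4 environmental
    covariates.  Inefficiency is moderate (sigma_mu = 0.2 on the log-input
    scale), noise small relative to it (sigma_v = 0.05), the environment
    effect delta links standardized covariates to mean log-inefficiency
    with the sign pattern the stage-2 story implies (favourable economy /
    density reduce slack; urbanization and health expenditure raise it),
    spatial autocorrelation is substantial (rho = 0.5), and the frontier
    regresses slightly (g = 0.97 per year), matching a sector whose
    total-factor productivity drifts down.
    """

    n_dmus: int = 31
    n_years: int = 9
    start_year: int = 2012
    n_inputs: int = 3
    n_outputs: int = 2
    n_env: int = 4
    #: per-input frontier scale constants
    input_scale: tuple = (1.0, 8.0, 4.0)
    #: weight of output 1 in the CES output aggregate
    output_mix: float = 0.6
    #: CES exponent of the output aggregate; >= 1 keeps the production
    #: possibility set convex, so noise-free draws are exactly DEA-efficient
    ces_p: float = 2.0
    sigma_mu: float = 0.2
    sigma_v: float = 0.05
    #: env -> mean log-inefficiency, on standardized covariates
    delta: tuple = (-0.08, -0.05, 0.06, 0.05)
    rho: float = 0.5
    #: spatial component scale
    sigma_spatial: float = 0.2
    #: yearly Hicks-neutral frontier factor (>1 progress, <1 regress)
    g: float = 0.97
    seed: int = 0

    def validate(self):
        if not (0 <= self.rho < 1):
            raise ValueError("rho must be in [0, 1)")
        if min(self.sigma_mu, self.sigma_v, self.sigma_spatial) < 0 or self.g <= 0:
            raise ValueError("scales must be nonnegative and g positive")
        if self.n_dmus < 2 or self.n_years < 1:
            raise ValueError("need >= 2 DMUs and >= 1 year")
        if len(self.delta) != self.n_env or len(self.input_scale) != self.n_inputs:
            raise ValueError("delta / input_scale length mismatch")


@dataclass
class SimulationTruth:
    """Ground truth aligned to the generated panel (year-major row order)."""

    table: pd.DataFrame         # dmu, year, u, efficiency
    delta: np.ndarray
    sigma_mu: float
    sigma_v: float
    rho: float
    g: float
    edges: list


def _spatial_component(rng, labels, edges, rho, scale):
    from .spatial import weights_from_edges
    W = weights_from_edges(labels, edges, standardize=True).W
    eps = rng.standard_normal(len(labels))
    return scale * np.linalg.solve(np.eye(len(labels)) - rho * W, eps)


def generate_panel(config: SimulationConfig):
    """Draw one panel and its truth.  Same config (incl. seed) -> same panel."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    labels, regions, edges, coords = province_fixture()
    if config.n_dmus != len(labels):
        labels = [f"dmu{i:02d}" for i in range(config.n_dmus)]
        regions = {l: "east" for l in labels}
        ring = [(labels[i], labels[(i + 1) % len(labels)]) for i in range(len(labels))]
        edges = ring
    years = config.start_year + np.arange(config.n_years)
    n, T = config.n_dmus, config.n_years

    # persistent province size factor drives both outputs and environment scale
    size = rng.lognormal(mean=0.0, sigma=0.6, size=n)

    # environment: GDP pc lognormal, density lognormal, urbanization in
    # [20, 95]%, government health expenditure lognormal; mild yearly drift.
    # A west-to-east gradient (from the fixture longitudes) makes the
    # covariates spatially smooth, as provincial economies are.
    if config.n_dmus == len(PROVINCES):
        lon = np.array([COORDS[p][0] for p in labels])
    else:
        lon = np.arange(n, dtype=float)
    grad = (lon - lon.min()) / np.ptp(lon) - 0.5     # in [-0.5, 0.5]
    gdp = rng.lognormal(np.log(45000), 0.3, n) * np.exp(0.8 * grad)
    dens = rng.lognormal(np.log(300), 0.6, n) * np.exp(1.5 * grad)
    urb = np.clip(rng.uniform(35, 70, n) + 30 * grad, 20, 95)
    ghe = rng.lognormal(np.log(40), 0.5, n) * size
    drift = 1.0 + 0.03 * np.arange(T)

    # spatially autocorrelated inefficiency component, constant over years
    spatial = _spatial_component(rng, labels, edges, config.rho, config.sigma_spatial)

    rows, truth_rows = [], []
    a = config.output_mix
    for t_idx, year in enumerate(years):
        env = np.column_stack([gdp * drift[t_idx], dens, np.minimum(urb + 0.5 * t_idx, 95.0),
                               ghe * drift[t_idx] ** 2])
        z = (env - env.mean(axis=0)) / env.std(axis=0)
        mean_u = z @ np.asarray(config.delta)
        half_norm = np.abs(rng.standard_normal(n)) * config.sigma_mu
        u = np.maximum(0.0, mean_u + spatial + half_norm)

        # outputs: consultations and admissions (ten-thousands), scale with size
        y1 = size * rng.lognormal(np.log(8000), 0.15, n) / 1e3
        y2 = size * rng.lognormal(np.log(300), 0.2, n) / 1e3
        # CES aggregate on scale-matched outputs keeps the frontier convex
        p = config.ces_p
        agg = (a * (y1 / 8.0) ** p + (1 - a) * (y2 / 0.3) ** p) ** (1.0 / p)
        g_t = config.g ** t_idx
        x_eff = np.outer(agg, np.asarray(config.input_scale)) / g_t
        noise = rng.normal(0.0, config.sigma_v, size=(n, config.n_inputs))
        x_obs = x_eff * np.exp(u[:, None]) * np.exp(noise)

        for i, dmu in enumerate(labels):
            rows.append((dmu, int(year), regions[dmu], *x_obs[i], y1[i], y2[i], *env[i]))
            truth_rows.append((dmu, int(year), float(u[i]), float(np.exp(-u[i]))))

    cols = ["dmu", "year", "region", *INPUT_COLS, *OUTPUT_COLS, *ENV_COLS]
    panel = PanelDataset(pd.DataFrame(rows, columns=cols))
    truth = SimulationTruth(
        table=pd.DataFrame(truth_rows, columns=["dmu", "year", "u", "efficiency"]),
        delta=np.asarray(config.delta), sigma_mu=config.sigma_mu,
        sigma_v=config.sigma_v, rho=config.rho, g=config.g, edges=list(edges))
    return panel, truth
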