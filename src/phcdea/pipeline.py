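"""Three-stage pipeline orchestration, reporting and robustness checks.

Stage 1 runs contemporaneous-frontier DEA on the raw panel; stage 2 fits
one slack frontier per input and levels the inputs; stage 3 re-runs DEA on
the adjusted inputs with the original outputs.  The Malmquist index is
computed on the adjusted panel by default, Moran statistics on the yearly
stage-3 TE series.  Every run is audited against the multiplicative
identities (TE = PTE*SE, TFPCH = EFFCH*TECHCH, EFFCH = PECH*SECH,
sum of local I = global I * S0) before anything is written.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import dea, malmquist, sfa, spatial
from .panel import PanelDataset, read_panel, write_panel

log = logging.getLogger("phcdea")

DEFAULT_CONFIG = {
    "frontier_scope": "per_year",          # per_year | pooled
    "slack_definition": "radial_plus_slack",  # | slack_only
    "weights": "contiguity",               # contiguity | knn:<k>
    "n_perm": 999,
    "seed": 0,
    "malmquist_source": "adjusted",        # adjusted | raw
}


def load_config(path=None, **overrides) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            cfg.update(yaml.safe_load(fh) or {})
    cfg.update(overrides)
    unknown = set(cfg) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cfg


@dataclass
class ThreeStageResult:
    stage1: pd.DataFrame
    slack_table: pd.DataFrame
    fits: dict
    adjusted: object                   # AdjustedPanel
    stage3: pd.DataFrame
    malmquist_records: pd.DataFrame
    malmquist_summary: pd.DataFrame
    moran_by_year: pd.DataFrame
    local_by_year: dict
    regional: pd.DataFrame
    config: dict
    config_hash: str


def _pooled_scores(panel) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single frontier over all DMU-years (config: frontier_scope=pooled)."""
    frames = []
    slack_rows = []
    data = panel.sorted_data()
    X = data[list(panel.input_cols)].to_numpy(float)
    Y = data[list(panel.output_cols)].to_numpy(float)
    for i in range(len(data)):
        te, lam = dea.solve_radial(X, Y, i, "crs")
        pte, _ = dea.solve_radial(X, Y, i, "vrs")
        s_in, _ = dea.max_slacks(X, Y, i, pte, "vrs")
        frames.append((data["dmu"].iloc[i], int(data["year"].iloc[i]), te, pte,
                       te / pte, dea.classify_rts(lam)))
        total = (1.0 - pte) * X[i] + s_in
        for k, name in enumerate(panel.input_cols):
            slack_rows.append((data["dmu"].iloc[i], int(data["year"].iloc[i]),
                               name, float(total[k])))
    scores = pd.DataFrame(frames, columns=["dmu", "year", "te", "pte", "se", "rts"])
    return scores, pd.DataFrame(slack_rows, columns=["dmu", "year", "input", "slack"])


def _dea_stage(panel, config):
    if config["frontier_scope"] == "pooled":
        return _pooled_scores(panel)
    records, slacks = dea.run_dea_by_year(panel, config["slack_definition"])
    return dea.records_frame(records), slacks


def _audit(result: ThreeStageResult):
    for name, df in (("stage1", result.stage1), ("stage3", result.stage3)):
        dev = np.abs(df["te"] - df["pte"] * df["se"]).max()
        if dev > 1e-9:
            raise AssertionError(f"{name}: TE != PTE*SE (max dev {dev:.2e})")
    mal = result.malmquist_records
    feas = mal[mal["feasible"]]
    if len(feas):
        d1 = np.abs(feas["tfpch"] - feas["effch"] * feas["techch"]).max()
        d2 = np.abs(feas["effch"] - feas["pech"] * feas["sech"]).max()
        if max(d1, d2) > 1e-9:
            raise AssertionError(f"Malmquist identity violated ({d1:.2e}, {d2:.2e})")


def build_weights(panel, config, edges=None, coords=None) -> spatial.SpatialWeights:
    spec = config["weights"]
    labels = panel.dmu_ids
    if spec == "contiguity":
        if edges is None:
            raise ValueError("contiguity weights need an edge list")
        return spatial.weights_from_edges(labels, edges)
    if spec.startswith("knn"):
        k = int(spec.split(":", 1)[1]) if ":" in spec else 5
        if coords is None:
            raise ValueError("knn weights need coordinates")
        return spatial.weights_knn(labels, coords, k)
    raise ValueError(f"unknown weights spec {spec!r}")


def run_three_stage(panel: PanelDataset, weights: spatial.SpatialWeights,
                    config: dict | None = None) -> ThreeStageResult:
    """Full pipeline: DEA -> SFA adjustment -> DEA -> Malmquist -> Moran."""
    config = load_config(**(config or {}))
    weights = weights.align(panel.dmu_ids)
    log.info("stage 1: DEA on raw panel (%d DMUs x %d years)",
             len(panel.dmu_ids), len(panel.years))
    stage1, slack_table = _dea_stage(panel, config)

    log.info("stage 2: SFA slack frontiers for %d inputs", len(panel.input_cols))
    fits = sfa.fit_all_inputs(slack_table, panel)
    adjusted = sfa.adjust_inputs(panel, fits)
    for name, fit in fits.items():
        log.info("  %s: gamma=%.3f LR=%.2f converged=%s",
                 name, fit.gamma, fit.lr_stat, fit.converged)

    log.info("stage 3: DEA on adjusted inputs")
    stage3, _ = _dea_stage(adjusted.panel, config)

    mal_panel = adjusted.panel if config["malmquist_source"] == "adjusted" else panel
    mal_records = malmquist.records_frame(malmquist.run_malmquist(mal_panel))
    n_infeas = int((~mal_records["feasible"]).sum())
    if n_infeas:
        log.warning("Malmquist: %d infeasible VRS cross-period programs excluded",
                    n_infeas)
    mal_summary = malmquist.summarize_malmquist(mal_records, by="year_pair")

    moran_rows, local_by_year = [], {}
    seed = int(config["seed"])
    for year in panel.years:
        x = stage3[stage3["year"] == year].set_index("dmu").loc[
            panel.dmu_ids, "te"].to_numpy()
        if np.ptp(x) == 0:
            log.warning("year %s: constant TE, Moran undefined; skipped", year)
            continue
        res = spatial.moran_significance(x, weights, n_perm=int(config["n_perm"]),
                                         seed=seed + int(year))
        moran_rows.append((int(year), res.I, res.expected, res.z,
                           res.p_norm, res.p_perm))
        loc = spatial.local_moran(x, weights, n_perm=int(config["n_perm"]),
                                  seed=seed + int(year))
        s0 = weights.W.sum()
        if abs(sum(l.I_i for l in loc) - res.I * s0) > 1e-9 * max(1.0, abs(res.I * s0)):
            raise AssertionError("local Moran sum != global I * S0")
        local_by_year[int(year)] = spatial.local_frame(loc)
    moran_by_year = pd.DataFrame(
        moran_rows, columns=["year", "I", "expected", "z", "p_norm", "p_perm"])

    regional = regional_summary(stage1, stage3, panel.regions)
    cfg_hash = hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:12]
    result = ThreeStageResult(stage1=stage1, slack_table=slack_table, fits=fits,
                              adjusted=adjusted, stage3=stage3,
                              malmquist_records=mal_records,
                              malmquist_summary=mal_summary,
                              moran_by_year=moran_by_year,
                              local_by_year=local_by_year, regional=regional,
                              config=config, config_hash=cfg_hash)
    _audit(result)
    return result


# -- report-layer summaries -------------------------------------------------

def rank_dmus(records: pd.DataFrame) -> pd.Series:
    """Competition ranking on period-averaged TE (ties share the best rank)."""
    if records.empty:
        raise ValueError("no records")
    per_dmu = records.groupby("dmu", sort=False)["te"].mean()
    ranks = stats.rankdata(-per_dmu.round(9), method="min").astype(int)
    return pd.Series(ranks, index=per_dmu.index, name="rank")


def regional_summary(stage1: pd.DataFrame, stage3: pd.DataFrame,
                     scheme: dict, round_to: int = 3) -> pd.DataFrame:
    """Per-region arithmetic means of per-DMU TE/PTE/SE, before vs after."""
    out = []
    for label, df in (("before", stage1), ("after", stage3)):
        per_dmu = df.groupby("dmu", sort=False)[["te", "pte", "se"]].mean()
        unmapped = set(per_dmu.index) - set(scheme)
        if unmapped:
            raise ValueError(f"DMUs without a region: {sorted(unmapped)}")
        g = per_dmu.groupby(per_dmu.index.map(scheme)).mean().round(round_to)
        g.insert(0, "stage", label)
        out.append(g)
    res = pd.concat(out).rename_axis("region").reset_index()
    piv = res.pivot(index="region", columns="stage", values=["te", "pte", "se"])
    for m in ("te", "pte", "se"):
        piv[(m, "direction")] = np.where(
            piv[(m, "after")] > piv[(m, "before")], "up",
            np.where(piv[(m, "after")] < piv[(m, "before")], "down", "same"))
    return piv.sort_index(axis=1)


def _paired_stats(a: np.ndarray, b: np.ndarray) -> dict:
    """Wilcoxon signed-rank p, paired Cohen's d, Spearman rho (+p)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("misaligned score vectors")
    diff = a - b
    if np.allclose(diff, 0.0):
        wp, flag = 1.0, "all-zero-differences"
    else:
        wp = float(stats.wilcoxon(a, b, zero_method="wilcox").pvalue)
        flag = ""
    sd = diff.std(ddof=1)
    # paired Cohen's d = |mean diff| / sd(diff); a constant nonzero shift
    # has no within-pair variability, hence an infinite standardized effect
    if sd == 0:
        d = 0.0 if diff.mean() == 0 else float("inf")
    else:
        d = float(abs(diff.mean()) / sd)
    rho, rho_p = stats.spearmanr(a, b)
    return {"wilcoxon_p": wp, "cohens_d": d, "spearman_rho": float(rho),
            "spearman_p": float(rho_p), "flag": flag}


def sensitivity_analysis(panel, weights, config, drop_candidates) -> pd.DataFrame:
    """Leave-one-variable-out robustness of the stage-3 scores.

    Dropping an input removes it from every stage; dropping an
    environmental covariate only alters stage 2.  Each reduced model is
    compared with the full model by paired statistics over per-DMU mean
    stage-3 TE.
    """
    config = load_config(**(config or {}))
    full = run_three_stage(panel, weights, config)
    base = full.stage3.groupby("dmu", sort=False)["te"].mean()
    rows = [{"dropped": "none", "mean_score": float(base.mean()),
             "wilcoxon_p": np.nan, "cohens_d": np.nan,
             "spearman_rho": np.nan, "spearman_p": np.nan, "flag": ""}]
    for name in drop_candidates:
        if name in panel.input_cols:
            reduced_panel = panel.drop_input(name)
        elif name in panel.env_cols:
            reduced_panel = panel.drop_env(name)
        else:
            raise KeyError(f"{name!r} is neither an input nor an environmental variable")
        red = run_three_stage(reduced_panel, weights, config)
        scores = red.stage3.groupby("dmu", sort=False)["te"].mean()
        st = _paired_stats(base.loc[scores.index], scores)
        rows.append({"dropped": name, "mean_score": float(scores.mean()), **st})
    return pd.DataFrame(rows)


def year_stability(records: pd.DataFrame) -> pd.DataFrame:
    """Adjacent-year paired statistics of the TE distribution."""
    years = np.sort(records["year"].unique())
    if len(years) < 2:
        raise ValueError("need at least 2 years")
    dmus = records[records["year"] == years[0]]["dmu"].tolist()
    rows = []
    for t, t1 in zip(years[:-1], years[1:]):
        a = records[records["year"] == t].set_index("dmu").loc[dmus, "te"].to_numpy()
        b = records[records["year"] == t1].set_index("dmu").loc[dmus, "te"].to_numpy()
        rows.append({"year_pair": f"{t}-{t1}", **_paired_stats(a, b)})
    return pd.DataFrame(rows)


# -- file I/O ---------------------------------------------------------------

def write_reports(result: ThreeStageResult, outdir) -> dict:
    """Write the full report set; returns {name: path}."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    eff = result.stage1.groupby("dmu", sort=False)[["te", "pte", "se"]].mean()
    eff3 = result.stage3.groupby("dmu", sort=False)[["te", "pte", "se"]].mean()

    def modal_rts(df):
        return df.groupby("dmu", sort=False)["rts"].agg(
            lambda s: s.mode().iloc[0])

    tab4 = pd.DataFrame({
        "dmu": eff.index,
        "stage1_te": eff["te"].round(3).values, "stage1_pte": eff["pte"].round(3).values,
        "stage1_se": eff["se"].round(3).values,
        "stage1_rts": modal_rts(result.stage1).values,
        "stage1_rank": rank_dmus(result.stage1).values,
        "stage3_te": eff3["te"].round(3).values, "stage3_pte": eff3["pte"].round(3).values,
        "stage3_se": eff3["se"].round(3).values,
        "stage3_rts": modal_rts(result.stage3).values,
        "stage3_rank": rank_dmus(result.stage3).values})
    paths["table4"] = outdir / "table4.csv"
    tab4.to_csv(paths["table4"], index=False)

    sfa_rows = []
    for name, fit in result.fits.items():
        terms = ["const"] + [f"z{i+1}" for i in range(len(fit.beta) - 1)]
        for i, term in enumerate(terms):
            sfa_rows.append((name, term, fit.beta[i],
                             fit.beta_se[i] if fit.beta_se is not None else np.nan))
        sfa_rows += [(name, "sigma_sq", fit.sigma_sq, np.nan),
                     (name, "gamma", fit.gamma, np.nan),
                     (name, "loglik", fit.loglik, np.nan),
                     (name, "lr_stat", fit.lr_stat, np.nan)]
    paths["table5_sfa"] = outdir / "table5_sfa.csv"
    pd.DataFrame(sfa_rows, columns=["input", "term", "estimate", "std_error"]).to_csv(
        paths["table5_sfa"], index=False, float_format="%.4E")

    paths["table6_malmquist"] = outdir / "table6_malmquist.csv"
    result.malmquist_summary.round(3).to_csv(paths["table6_malmquist"], index=False)
    paths["table7_moran"] = outdir / "table7_moran.csv"
    result.moran_by_year.round(4).to_csv(paths["table7_moran"], index=False)
    paths["table9_regions"] = outdir / "table9_regions.csv"
    result.regional.to_csv(paths["table9_regions"])
    for year, df in result.local_by_year.items():
        p = outdir / f"lisa_{year}.csv"
        df.round(4).to_csv(p, index=False)
        paths[f"lisa_{year}"] = p
    paths["config"] = outdir / "config.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump({**result.config, "config_hash": result.config_hash}, fh)
    return paths
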