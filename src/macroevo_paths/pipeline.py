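"""Config-driven orchestration of the full analysis pipeline.

Runs, in dependency order: data simulation (or loading), tip-rate
estimation, the environment-dependent birth-death battery, disparity
analyses, OU regime tests, DEC ancestral ranges, and phylogenetic path
analysis.  Every stage writes its artifacts plus a JSON manifest (inputs,
parameters, seeds, package version) into the output directory; a stage
failure halts its dependents but preserves completed artifacts.
"""

from __future__ import annotations

import json
import logging
import time
import traceback
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import decrange, disparity, envbd, oushift, pathsynth, synthgen, \
    tiprates
from .treekit import CladeDef, read_newick

log = logging.getLogger("macroevo_paths")

STAGES = ("simulate", "tiprates", "envbd", "disparity", "ou", "dec", "ppa")

DEFAULTS = {
    "simulate": {"scenario": "merianieae_like", "seed": 1},
    "tiprates": {"penalty": "auto", "reps": 1000, "seed": 2},
    "envbd": {"f": 0.46, "df": 80, "starts": 2, "seed": 3},
    "disparity": {"sims": 1000, "rarefaction_n": 4, "rarefaction_reps": 100,
                  "seed": 4},
    "ou": {"seed": 5},
    "dec": {"free": ["d", "e"], "clado": "DEC", "seed": 6},
    "ppa": {"threshold": 2.0, "q_mode": "edges", "seed": 7},
}


class RunConfig:
    """Validated pipeline configuration (YAML or JSON mapping)."""

    def __init__(self, mapping, base_dir="."):
        self.raw = dict(mapping)
        self.base_dir = Path(base_dir)
        self.out_dir = Path(self.raw.get("out_dir", "pipeline_out"))
        self.stages = {}
        for stage in STAGES:
            if stage in self.raw:
                block = dict(DEFAULTS[stage])
                block.update(self.raw[stage] or {})
                self.stages[stage] = block

    @classmethod
    def from_yaml(cls, path):
        path = Path(path)
        with open(path) as fh:
            return cls(yaml.safe_load(fh), base_dir=path.parent)

    def validate(self):
        """Schema / cross-reference check; returns a list of findings."""
        problems = []
        if not self.stages:
            problems.append("no pipeline stages configured")
        for stage, block in self.stages.items():
            if "seed" not in block:
                problems.append(f"stage {stage!r}: missing seed")
        sim = self.stages.get("simulate", {})
        if "inputs" in sim:
            for key, rel in sim["inputs"].items():
                p = self.base_dir / rel
                if not p.exists():
                    problems.append(
                        f"simulate.inputs.{key}: file not found: {p}")
        ppa = self.stages.get("ppa", {})
        if ppa.get("model_set"):
            p = self.base_dir / ppa["model_set"]
            if not p.exists():
                problems.append(f"ppa.model_set: file not found: {p}")
            else:
                try:
                    models = pathsynth.models_from_json(
                        json.loads(p.read_text()))
                    for m in models:
                        m.graph  # acyclicity re-checked on construction
                except (ValueError, KeyError) as exc:
                    problems.append(f"ppa.model_set: {exc}")
        return problems


def _write_manifest(out_dir, stage, params, artifacts, started):
    manifest = {
        "stage": stage, "version": __version__, "parameters": params,
        "artifacts": sorted(artifacts),
        "wall_time_s": round(time.time() - started, 3),
    }
    path = Path(out_dir) / f"{stage}_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


def run(config):
    """Execute all configured stages; returns the report dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = {"version": __version__, "stages": {}}
    ws = {}  # in-memory workspace shared between stages
    for stage in STAGES:
        if stage not in config.stages:
            continue
        block = config.stages[stage]
        started = time.time()
        log.info("stage %s: starting (seed=%s)", stage, block.get("seed"))
        try:
            artifacts = _STAGE_FUNCS[stage](ws, block, out, config)
        except Exception as exc:
            log.error("stage %s failed: %s", stage, exc)
            report["stages"][stage] = {
                "status": "failed", "error": str(exc),
                "traceback": traceback.format_exc()}
            break
        _write_manifest(out, stage, block, artifacts, started)
        report["stages"][stage] = {
            "status": "ok", "artifacts": sorted(artifacts),
            "wall_time_s": round(time.time() - started, 3)}
        log.info("stage %s: done in %.1fs", stage,
                 time.time() - started)
    (out / "report.json").write_text(
        json.dumps(report, indent=2, default=str))
    return report


# ----------------------------------------------------------------------
# Stage implementations
# ----------------------------------------------------------------------

def _stage_simulate(ws, block, out, config):
    if "inputs" in block:
        ws.update(_load_inputs(block["inputs"], config.base_dir))
        return []
    kw = {k: v for k, v in block.items()
          if k not in ("scenario", "seed", "inputs")}
    bundle = synthgen.merianieae_like_scenario(seed=block["seed"], **kw)
    ws.update(bundle)
    arts = []

    def save(name, writer):
        path = out / name
        writer(path)
        arts.append(str(path.name))

    save("tree.nwk", lambda p: p.write_text(bundle["tree"].to_newick()))
    for key in ("traits_clim", "traits_veg", "traits_flor"):
        save(f"{key}.tsv", lambda p, k=key: bundle[k].to_csv(p, sep="\t"))
    save("bg.tsv", lambda p: bundle["bg"].to_csv(p, sep="\t"))
    save("ranges.tsv", lambda p: pd.Series(
        {k: ",".join(sorted(v)) for k, v in bundle["ranges"].items()},
        name="areas").to_csv(p, sep="\t"))
    save("clades.tsv", lambda p: pd.DataFrame(
        [{"clade": c.name, "tip": t, "sampling_fraction":
          c.sampling_fraction} for c in bundle["clades"]
         for t in sorted(c.tips)]).to_csv(p, sep="\t", index=False))
    save("temp_curve.csv",
         lambda p: bundle["temp_curve"].to_frame().to_csv(p, index=False))
    save("elev_curve.csv",
         lambda p: bundle["elev_curve"].to_frame().to_csv(p, index=False))
    save("sim_truth.json",
         lambda p: p.write_text(bundle["truth"].to_json(indent=2)))
    return arts


def _load_inputs(inputs, base_dir):
    base = Path(base_dir)
    ws = {}
    ws["tree"] = read_newick((base / inputs["tree"]).read_text())
    for key in ("traits_clim", "traits_veg", "traits_flor"):
        if key in inputs:
            ws[key] = pd.read_csv(base / inputs[key], sep="\t", index_col=0)
    if "bg" in inputs:
        ws["bg"] = pd.read_csv(base / inputs["bg"], sep="\t",
                               index_col=0).iloc[:, 0]
    if "ranges" in inputs:
        df = pd.read_csv(base / inputs["ranges"], sep="\t", index_col=0)
        ws["ranges"] = {i: frozenset(str(v).split(","))
                        for i, v in df.iloc[:, 0].items()}
        ws["areas"] = sorted({a for r in ws["ranges"].values() for a in r})
    for key, name in (("temp_curve", "temp"), ("elev_curve", "elev")):
        if key in inputs:
            ws[key] = envbd.PaleoCurve.from_csv(base / inputs[key],
                                                name=name)
    if "clades" in inputs:
        from .treekit import read_clade_tsv
        ws["clades"] = read_clade_tsv(base / inputs["clades"])
    return ws


def _stage_tiprates(ws, block, out, config):
    tree = ws["tree"]
    dr = tiprates.dr_statistic(tree)
    table = pd.DataFrame({"species": tree.tip_labels, "DR": dr.values})
    for space, key in (("clim", "traits_clim"), ("veg", "traits_veg"),
                       ("flor", "traits_flor")):
        if key not in ws:
            continue
        traits = ws[key].select_dtypes("number")
        _, per_tip = tiprates.ridge_rates(tree, traits,
                                          penalty=block["penalty"],
                                          seed=block["seed"])
        table[f"rate_{space}"] = per_tip["rate"].values
    table = table.set_index("species")
    ws["tip_rates"] = table
    path = out / "tip_rates.tsv"
    table.to_csv(path, sep="\t")
    arts = [path.name]
    if "shifted_tips" in ws and len(ws["shifted_tips"]) >= 2:
        clade = CladeDef("shifted", frozenset(ws["shifted_tips"]))
        p, eff = tiprates.rate_shift_test(table["DR"], clade,
                                          reps=block["reps"],
                                          seed=block["seed"])
        ws["shift_test"] = {"p": p, "effect": eff}
        (out / "shift_test.json").write_text(json.dumps(ws["shift_test"]))
        arts.append("shift_test.json")
    return arts


def _stage_envbd(ws, block, out, config):
    tree = ws["tree"]
    temp = ws["temp_curve"]
    elev = ws["elev_curve"]
    df = block["df"]
    temp_s = envbd.smooth_curve(temp.ages, temp.values,
                                df=min(df, len(temp.ages)), name="temp")
    elev_s = envbd.smooth_curve(elev.ages, elev.values,
                                df=min(df, len(elev.ages)), name="elev")
    fits = envbd.battery_14(tree, temp_s, elev_s, f=block["f"],
                            starts=block["starts"], seed=block["seed"])
    ws["bd_fits"] = fits
    table = envbd.fits_to_frame(fits)
    path = out / "envbd_fits.tsv"
    table.to_csv(path, sep="\t", index=False)
    diag = {"best_model": fits[0].model.name, "best_weight": fits[0].weight,
            "conditioning": "crown age + survival of both crown lineages",
            "n_models": len(fits)}
    (out / "envbd_diagnostics.json").write_text(json.dumps(diag, indent=2))
    return [path.name, "envbd_diagnostics.json"]


def _stage_disparity(ws, block, out, config):
    tree = ws["tree"]
    arts = []
    ws["morphospaces"] = {}
    ws["dtt"] = {}
    rng = np.random.default_rng(block["seed"])
    for space, key, n_axes in (("clim", "traits_clim", 2),
                               ("veg", "traits_veg", 2),
                               ("flor", "traits_flor", 3)):
        if key not in ws:
            continue
        table = ws[key]
        numeric = table.select_dtypes("number")
        if numeric.shape[1] == table.shape[1]:
            ms = disparity.ordinate(table, method="PCA")
        else:
            D = disparity.gower_distance(table)
            ms = disparity.ordinate(D, method="PCoA",
                                    correction="Cailliez")
        ws["morphospaces"][space] = ms
        scores = ms.axes(min(n_axes, ms.scores.shape[1]))
        scores.to_csv(out / f"scores_{space}.tsv", sep="\t")
        arts.append(f"scores_{space}.tsv")
        res = disparity.dtt(tree, scores, sims=block["sims"],
                            seed=int(rng.integers(2 ** 31)))
        ws["dtt"][space] = res
        pd.DataFrame({"age_ma": res.times, "observed": res.observed,
                      "null_median": res.null_median,
                      "null_low": res.null_low,
                      "null_high": res.null_high}).to_csv(
            out / f"dtt_{space}.csv", index=False)
        arts.append(f"dtt_{space}.csv")
        (out / f"dtt_{space}.json").write_text(json.dumps(
            {"mdi": res.mdi, "p": res.p_value, "sims": res.sims}))
        arts.append(f"dtt_{space}.json")
        if "clades" in ws:
            big = [c for c in ws["clades"]
                   if len(c.tips) >= block["rarefaction_n"]]
            if len(big) >= 2:
                dists, bc = disparity.rarefied_disparity(
                    scores, big, n=block["rarefaction_n"],
                    reps=block["rarefaction_reps"],
                    seed=int(rng.integers(2 ** 31)))
                bc.to_csv(out / f"bhattacharyya_{space}.tsv", sep="\t",
                          index=False)
                arts.append(f"bhattacharyya_{space}.tsv")
    return arts


def _stage_ou(ws, block, out, config):
    tree = ws["tree"]
    paintings = [oushift.RegimePainting.single_regime(tree, "neutral")]
    if "shifted_tips" in ws and len(ws["shifted_tips"]) >= 2:
        paintings.append(oushift.RegimePainting.from_clades(
            tree, [ws["shifted_tips"]], name="M1_andean"))
    if "clades" in ws and ws["clades"]:
        core = max(ws["clades"], key=lambda c: len(c.tips))
        paintings.append(oushift.RegimePainting.from_clades(
            tree, [sorted(core.tips)], name="M2_core"))
    rows = []
    edges = tree.n_nodes - 1
    ws["ou_fits"] = {}
    for space, ms in ws.get("morphospaces", {}).items():
        for ax in range(min(2, ms.scores.shape[1])):
            y = ms.scores.iloc[:, ax]
            fits = []
            for painting in paintings:
                bm = oushift.fit_bm(tree, y)
                fits.append(oushift.OUFit(
                    alpha=0.0, sigma2=bm["sigma2"],
                    theta=np.array([bm["root"]]), loglik=bm["loglik"],
                    m=1, n=tree.n_tips, name=f"BM"))
                fits.append(oushift.fit_ou(tree, y, painting,
                                           name=f"OU_{painting.name}"))
            # deduplicate the repeated BM entries
            seen = set()
            uniq = []
            for f_ in fits:
                if f_.name in seen:
                    continue
                seen.add(f_.name)
                uniq.append(f_)
            ranked = oushift.compare_ou(uniq, edges=edges, penalty="pBIC")
            ws["ou_fits"][(space, ax)] = ranked
            for rank, f_ in enumerate(ranked, 1):
                rows.append({"space": space, "axis": ax + 1,
                             "model": f_.name, "alpha": f_.alpha,
                             "sigma2": f_.sigma2, "m": f_.m,
                             "logL": f_.loglik, "BIC": f_.bic,
                             "pBIC": f_.pbic, "rank": rank})
    path = out / "ou_models.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return [path.name]


def _stage_dec(ws, block, out, config):
    tree = ws["tree"]
    ranges = ws["ranges"]
    space = decrange.RangeStateSpace(ws["areas"], max_range_size=5)
    params, ll, aicc = decrange.fit_dec(
        tree, ranges, space, free=tuple(block["free"]),
        clado=block["clado"], seed=block["seed"])
    marg = decrange.ancestral_ranges(tree, ranges, space, params,
                                     clado=block["clado"])
    ws["dec_fit"] = {"params": params, "loglik": ll, "aicc": aicc}
    ws["dec_marginals"] = marg
    (out / "dec_fit.json").write_text(json.dumps(
        {"d": params.d, "e": params.e, "j": params.j, "w": params.w,
         "logL": ll, "AICc": aicc}, indent=2))
    cols = [space.label(s) for s in range(space.n_states)]
    dfm = pd.DataFrame(marg, columns=cols)
    dfm.insert(0, "node", range(tree.n_nodes))
    dfm.to_csv(out / "dec_ancestral_ranges.tsv", sep="\t", index=False)
    return ["dec_fit.json", "dec_ancestral_ranges.tsv"]


def _stage_ppa(ws, block, out, config):
    tree = ws["tree"]
    rates = ws["tip_rates"]
    table = pd.DataFrame({
        "BG": ws["bg"].loc[tree.tip_labels].astype(float),
        "climR": rates["rate_clim"],
        "vegR": rates["rate_veg"],
        "florR": rates["rate_flor"],
        "SR": rates["DR"],
    })
    if block.get("model_set"):
        models = pathsynth.models_from_json(json.loads(
            (config.base_dir / block["model_set"]).read_text()))
    else:
        models = pathsynth.default_model_set()
    fits, averaged = pathsynth.rank_and_average(
        models, table, tree, threshold=block["threshold"],
        q_mode=block["q_mode"])
    ws["ppa_fits"] = fits
    ws["ppa_averaged"] = averaged
    pathsynth.ranking_frame(fits).to_csv(out / "ppa_ranking.tsv",
                                         sep="\t", index=False)
    averaged.to_csv(out / "ppa_averaged_coefficients.tsv", sep="\t",
                    index=False)
    best = fits[0]
    best.edge_coefficients.to_csv(out / "ppa_best_model_edges.tsv",
                                  sep="\t", index=False)
    return ["ppa_ranking.tsv", "ppa_averaged_coefficients.tsv",
            "ppa_best_model_edges.tsv"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "tiprates": _stage_tiprates,
    "envbd": _stage_envbd,
    "disparity": _stage_disparity,
    "ou": _stage_ou,
    "dec": _stage_dec,
    "ppa": _stage_ppa,
}
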