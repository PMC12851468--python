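"""End-to-end pipeline: simulate (or load) -> preprocess -> RSA/encoding ->
group statistics -> population dynamics, with every stage written to disk.

The pipeline is driven by a single configuration mapping (YAML-friendly);
a ``simulate`` block makes the whole analysis runnable with zero external
files.  All randomness flows from one seed through named substreams, so a
rerun with the same configuration produces byte-identical outputs.  The
default configuration is a compact study — 200 stimuli in 20 categories and
26 channels across five regions — chosen so a full run stays in the minutes
range on one CPU while exercising every stage at realistic geometry.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as nio
from .dynamics import (condition_mean_hgp, population_trajectories,
                       split_by_memorability, trajectory_divergence)
from .encoding import permutation_encoding_test
from .groupstats import bootstrap_subsample_selection, chi2_2x2, roi_summary
from .rdm import feature_rdm, population_rdm
from .rsa import mantel, partial_rsa, select_channels_rsa, time_resolved_rsa
from .signal import (bin_timecourse, epoch, extract_hgp, mean_response,
                     normalize_hgp, select_responsive)
from .synthdata import (ATTRIBUTES, make_feature_spaces, make_ground_truth,
                        make_recording, make_stimulus_set)

log = logging.getLogger("neurorsa")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "output_dir": "neurorsa_out",
    "simulate": {
        "n_categories": 20,
        "n_per_category": 10,
        "dims": [64, 64, 16],
        "cross_corr": [0.4, 0.3, 0.2],
        "fs": 1000.0,
        "effect_size": 2.0,
        "roster": {
            "VTC": {"visual": 4, "semantic": 2, "memorability": 1, "none": 2},
            "MTL": {"semantic": 4, "memorability": 1, "none": 1},
            "PFC": {"memorability": 4, "none": 1},
            "STG": {"none": 3},
            "MTG": {"none": 3},
        },
        "onset_latency": 0.1,
        "response_duration": 0.5,
    },
    "band": [70.0, 170.0],
    "epoch_window": [-0.5, 1.5],
    "response_window": [0.1, 0.6],
    "baseline_window": [-0.5, 0.0],
    "rdm_metric": "euclidean",
    "rsa": {"method": "spearman", "n_perm": 500, "alpha": 0.05,
            "min_run": 5, "bin_width": 0.3, "bin_step": 0.02},
    "encoding": {"model": "latent", "n_components": None,
                 "train_frac": 0.5, "n_perm": 200},
    "groupstats": {"p0": 0.05, "bootstrap_frac": 0.75, "bootstrap_n": 1000},
    "dynamics": {"k": 25, "n_components": 3, "n_perm": 200,
                 "bin_width": 0.2, "bin_step": 0.02},
}


_ATOMIC_KEYS = {"roster"}  # replaced wholesale, never key-merged


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if (isinstance(v, dict) and isinstance(out.get(k), dict)
                and k not in _ATOMIC_KEYS):
            out[k] = _merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> dict:
    """Default configuration merged with a YAML file and/or a dict."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        cfg = _merge(cfg, loaded)
    if overrides:
        cfg = _merge(cfg, overrides)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    sim = cfg.get("simulate") or {}
    if sim:
        if sim["n_categories"] < 2 or sim["n_per_category"] < 2:
            raise ValueError("simulate: need >=2 categories of >=2 stimuli")
        if sim["fs"] < 500:
            raise ValueError("simulate: fs must be >= 500 Hz")
    lo, hi = cfg["band"]
    if not 0 < lo < hi:
        raise ValueError("band must be an increasing positive pair")
    for key in ("rsa", "dynamics"):
        if cfg[key]["n_perm"] < 1:
            raise ValueError(f"{key}: n_perm must be >= 1")
    if not 0 < cfg["rsa"]["alpha"] < 1:
        raise ValueError("rsa: alpha must lie in (0, 1)")
    if not 0 < cfg["encoding"]["train_frac"] < 1:
        raise ValueError("encoding: train_frac must lie in (0, 1)")
    if not 0 < cfg["groupstats"]["p0"] < 1:
        raise ValueError("groupstats: p0 must lie in (0, 1)")
    if not 0 < cfg["groupstats"]["bootstrap_frac"] <= 1:
        raise ValueError("groupstats: bootstrap_frac must lie in (0, 1]")
    if cfg["dynamics"]["k"] < 1:
        raise ValueError("dynamics: k must be positive")


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()


def _named_seeds(seed: int, names: list[str]) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: int(c.generate_state(1)[0] % (2 ** 31))
            for name, c in zip(names, children)}


_STAGE_SEEDS = ["stimuli", "spaces", "ground_truth", "recording",
                "selection", "encoding", "population", "partial",
                "cross_region", "bootstrap", "dynamics"]


def _expand_roster(roster: dict, effect_size: float) -> list:
    entries = []
    for roi in sorted(roster):
        for attr in sorted(roster[roi]):
            count = roster[roi][attr]
            eff = 0.0 if attr == "none" else effect_size
            entries.append((roi, attr, eff, count))
    return entries


def run_all(cfg: dict, outdir: str | Path | None = None) -> dict:
    """Run the full analysis graph; returns the in-memory result bundle."""
    validate_config(cfg)
    outdir = Path(outdir if outdir is not None else cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _named_seeds(int(cfg["seed"]), _STAGE_SEEDS)
    results: dict = {}

    def stage(name):
        def wrap(fn):
            try:
                log.info("stage %s", name)
                return fn()
            except Exception as exc:  # noqa: BLE001
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    # ------------------------------------------------------------- simulate
    sim = cfg["simulate"]

    def do_simulate():
        stimuli0 = make_stimulus_set(sim["n_categories"], sim["n_per_category"],
                                     seed=seeds["stimuli"])
        spaces, stimuli = make_feature_spaces(
            stimuli0, dims=sim["dims"], cross_corr=sim["cross_corr"],
            seed=seeds["spaces"])
        gts = make_ground_truth(
            spaces, _expand_roster(sim["roster"], sim["effect_size"]),
            seed=seeds["ground_truth"], onset_latency=sim["onset_latency"],
            response_duration=sim["response_duration"])
        rec = make_recording(stimuli, spaces, gts, fs=sim["fs"],
                             seed=seeds["recording"], band=tuple(cfg["band"]))
        inp = outdir / "inputs"
        inp.mkdir(exist_ok=True)
        nio.write_recording(rec, inp)
        for attr, sp in spaces.items():
            nio.write_feature_space(sp, inp / f"features_{attr}.csv")
        nio.write_ground_truth(gts, inp / "ground_truth.json")
        pd.DataFrame({"stimulus_id": stimuli.stimulus_id,
                      "category": stimuli.category,
                      "memorability_score": stimuli.memorability_score}
                     ).to_csv(inp / "stimuli.tsv", sep="\t", index=False)
        return stimuli, spaces, gts, rec

    stimuli, spaces, gts, rec = stage("simulate")(do_simulate)
    roi_of = {gt.channel_id: gt.roi for gt in gts}

    # ----------------------------------------------------------- preprocess
    def do_preprocess():
        env = extract_hgp(rec, band=tuple(cfg["band"]))
        epochs = epoch(env, rec.fs, rec.events,
                       window=tuple(cfg["epoch_window"]),
                       channel_id=list(rec.channels["name"]))
        responsive = select_responsive(
            epochs, response_window=tuple(cfg["response_window"]),
            baseline_window=tuple(cfg["baseline_window"]),
            alpha=cfg["rsa"]["alpha"])
        nio.write_selection_table(responsive, outdir / "responsive.tsv")
        responses = mean_response(epochs, window=tuple(cfg["response_window"]),
                                  stimulus_order=list(stimuli.stimulus_id))
        responses.to_frame().to_csv(outdir / "response_matrix.csv")
        return epochs, responsive, responses

    epochs, responsive, responses = stage("preprocess")(do_preprocess)
    resp_channels = responsive.loc[responsive["responsive"],
                                   "channel_id"].tolist()
    if len(resp_channels) < 2:
        raise RuntimeError("stage 'preprocess' failed: fewer than 2 "
                           "responsive channels")
    resp_matrix = responses.subset(resp_channels)

    # ----------------------------------------------------------- RDM + RSA
    frdms = {attr: feature_rdm(spaces[attr], metric=cfg["rdm_metric"])
             for attr in ATTRIBUTES}

    def do_selection():
        table = select_channels_rsa(
            resp_matrix, frdms, n_perm=cfg["rsa"]["n_perm"],
            alpha=cfg["rsa"]["alpha"], seed=seeds["selection"],
            method=cfg["rsa"]["method"], roi=roi_of)
        table["responsive"] = True
        nio.write_selection_table(table, outdir / "selection_rdm.tsv")
        return table

    sel_rdm = stage("rdm_selection")(do_selection)

    # ------------------------------------------------------------- encoding
    enc_cfg = cfg["encoding"]

    def do_encoding():
        rows = []
        rng_seeds = _named_seeds(seeds["encoding"],
                                 [f"{c}:{a}" for c in resp_channels
                                  for a in ATTRIBUTES + ("memorability_score",)])
        for cid in resp_channels:
            r = resp_matrix.values[:, resp_matrix.channel_id.index(cid)]
            for attr in ATTRIBUTES:
                fit = permutation_encoding_test(
                    spaces[attr].matrix, r, model=enc_cfg["model"],
                    n_perm=enc_cfg["n_perm"],
                    train_frac=enc_cfg["train_frac"],
                    n_components=enc_cfg["n_components"],
                    seed=rng_seeds[f"{cid}:{attr}"])
                rows.append({"channel_id": cid, "roi": roi_of[cid],
                             "attribute": attr, "model": fit.model,
                             "rho": fit.r_obs, "p": fit.p,
                             "selected": fit.significant,
                             "n_components": fit.n_components,
                             "responsive": True})
            score_fit = permutation_encoding_test(
                stimuli.memorability_score[:, None], r, model="simple",
                n_perm=enc_cfg["n_perm"], train_frac=enc_cfg["train_frac"],
                seed=rng_seeds[f"{cid}:memorability_score"])
            rows.append({"channel_id": cid, "roi": roi_of[cid],
                         "attribute": "memorability_score", "model": "simple",
                         "rho": score_fit.r_obs, "p": score_fit.p,
                         "selected": score_fit.significant,
                         "n_components": None, "responsive": True})
        table = pd.DataFrame(rows)
        nio.write_selection_table(table, outdir / "selection_encoding.tsv")
        return table

    sel_enc = stage("encoding")(do_encoding)

    # ------------------------------------------------------------ groupstats
    gcfg = cfg["groupstats"]

    def do_groupstats():
        summary_rdm = roi_summary(sel_rdm, p0=gcfg["p0"])
        summary_enc = roi_summary(
            sel_enc[sel_enc["attribute"].isin(ATTRIBUTES)], p0=gcfg["p0"])
        summary_rdm.to_csv(outdir / "roi_summary_rdm.tsv", sep="\t",
                           index=False)
        summary_enc.to_csv(outdir / "roi_summary_encoding.tsv", sep="\t",
                           index=False)
        comparisons = {}
        for attr in ATTRIBUTES:
            k_rdm = int(sel_rdm.loc[sel_rdm["attribute"] == attr,
                                    "selected"].sum())
            k_enc = int(sel_enc.loc[sel_enc["attribute"] == attr,
                                    "selected"].sum())
            n = len(resp_channels)
            try:
                stat, p = chi2_2x2([[k_rdm, n - k_rdm], [k_enc, n - k_enc]])
            except ValueError:
                stat, p = float("nan"), float("nan")
            comparisons[attr] = {"k_rdm": k_rdm, "k_encoding": k_enc,
                                 "n": n, "chi2": stat, "p": p}
        nio.write_results_json(comparisons, outdir / "comparison_chi2.json")

        # dominant ROI per attribute by RDM-selection percentage
        dominant = {}
        for attr in ATTRIBUTES:
            sub = summary_rdm[summary_rdm["attribute"] == attr]
            dominant[attr] = (sub.sort_values(["percent", "n", "roi"],
                                              ascending=[False, False, True])
                              .iloc[0]["roi"] if len(sub) else None)

        boot = {}
        for attr in ATTRIBUTES:
            roi = dominant[attr]
            cell = sel_rdm[(sel_rdm["attribute"] == attr)
                           & (sel_rdm["roi"] == roi)]
            if len(cell) >= 2:
                res = bootstrap_subsample_selection(
                    cell["selected"].to_numpy(), frac=gcfg["bootstrap_frac"],
                    n_boot=gcfg["bootstrap_n"], seed=seeds["bootstrap"])
                boot[attr] = {"roi": roi, "observed": res.observed,
                              "interval": list(res.interval),
                              "inside": res.inside}
        nio.write_results_json(boot, outdir / "bootstrap.json")
        return summary_rdm, summary_enc, dominant

    summary_rdm, summary_enc, dominant = stage("groupstats")(do_groupstats)

    def selected_channels(attr: str, roi: str | None = None) -> list[str]:
        sub = sel_rdm[(sel_rdm["attribute"] == attr) & sel_rdm["selected"]]
        if roi is not None:
            sub = sub[sub["roi"] == roi]
        return sub["channel_id"].tolist()

    # --------------------------------------------- population + partial RSA
    rsa_cfg = cfg["rsa"]

    def do_population():
        out = {}
        for attr in ATTRIBUTES:
            roi = dominant[attr]
            chans = selected_channels(attr, roi)
            if len(chans) < 1:
                chans = [c for c in resp_channels if roi_of[c] == roi]
            nrdm = population_rdm(resp_matrix, chans)
            full = mantel(nrdm, frdms[attr], n_perm=rsa_cfg["n_perm"],
                          seed=seeds["population"],
                          method=rsa_cfg["method"])
            controls = [frdms[a] for a in ATTRIBUTES if a != attr]
            part = partial_rsa(nrdm, frdms[attr], controls,
                               n_perm=rsa_cfg["n_perm"],
                               seed=seeds["partial"],
                               method=rsa_cfg["method"])
            out[attr] = {"roi": roi, "n_channels": len(chans),
                         "rho": full.rho, "p": full.p,
                         "partial_rho": part.rho, "partial_p": part.p,
                         "n_perm": rsa_cfg["n_perm"],
                         "method": rsa_cfg["method"],
                         "controls": [a for a in ATTRIBUTES if a != attr]}
        nio.write_results_json(out, outdir / "population_rsa.json")
        return out

    population = stage("population_rsa")(do_population)

    def do_cross_region():
        out = {}
        pairs = [("visual", "semantic"), ("visual", "memorability"),
                 ("semantic", "memorability")]
        for a, b in pairs:
            ca = selected_channels(a, dominant[a])
            cb = selected_channels(b, dominant[b])
            if len(ca) < 1 or len(cb) < 1 or set(ca) == set(cb):
                continue
            res = mantel(population_rdm(resp_matrix, ca),
                         population_rdm(resp_matrix, cb),
                         n_perm=rsa_cfg["n_perm"], seed=seeds["cross_region"],
                         method=rsa_cfg["method"])
            out[f"{a}[{dominant[a]}]~{b}[{dominant[b]}]"] = {
                "rho": res.rho, "p": res.p}
        nio.write_results_json(out, outdir / "cross_region_rsa.json")
        return out

    cross_region = stage("cross_region_rsa")(do_cross_region)

    # ----------------------------------------------------- time-resolved RSA
    def do_timecourse():
        binned = bin_timecourse(epochs, rsa_cfg["bin_width"],
                                rsa_cfg["bin_step"])
        out = {}
        for attr in ATTRIBUTES:
            chans = selected_channels(attr, dominant[attr])
            if len(chans) < 2:
                chans = selected_channels(attr)
            if len(chans) < 2:
                continue
            tc = time_resolved_rsa(binned, frdms[attr], channels=chans,
                                   baseline_window=tuple(cfg["baseline_window"]),
                                   alpha=rsa_cfg["alpha"],
                                   min_run=rsa_cfg["min_run"],
                                   method=rsa_cfg["method"])
            out[attr] = {
                "roi": dominant[attr], "onset_s": tc.onset_latency,
                "peak_s": tc.peak_latency,
                "bins": [{"center_s": float(c), "rho_mean": float(m),
                          "significant": bool(s)}
                         for c, m, s in zip(tc.bin_centers, tc.rho_mean,
                                            tc.significant)]}
        nio.write_results_json(out, outdir / "timecourse_rsa.json")
        return out

    timecourse = stage("time_resolved_rsa")(do_timecourse)

    # --------------------------------------------------------------- dynamics
    dcfg = cfg["dynamics"]

    def do_dynamics():
        high, low = split_by_memorability(stimuli, k=dcfg["k"])
        norm = normalize_hgp(epochs,
                             baseline_window=tuple(cfg["baseline_window"]))
        binned = bin_timecourse(norm, dcfg["bin_width"], dcfg["bin_step"])
        out = {}
        for attr in ("visual", "semantic"):
            chans = selected_channels(attr)
            if len(chans) < dcfg["n_components"]:
                chans = resp_channels
            traj = population_trajectories(
                binned, chans, {"high": high, "low": low},
                n_components=dcfg["n_components"])
            d, p = trajectory_divergence(binned, chans, high, low,
                                         n_perm=dcfg["n_perm"],
                                         n_components=dcfg["n_components"],
                                         seed=seeds["dynamics"])
            curves = condition_mean_hgp(norm, chans,
                                        {"high": high, "low": low})
            out[attr] = {
                "n_channels": len(chans),
                "divergence": d, "p": p,
                "divergence_statistic": "time-summed inter-trajectory "
                                        "euclidean distance (design choice; "
                                        "no canonical scalar exists)",
                "bin_centers": traj.bin_centers,
                "coords": traj.coords,
                "explained_variance": traj.explained_variance,
                "mean_hgp": {name: {"mean": c["mean"],
                                    "sem": c["sem"]}
                             for name, c in curves.items()}}
        nio.write_results_json(out, outdir / "dynamics.json")
        return out

    dynamics_out = stage("dynamics")(do_dynamics)

    # --------------------------------------------------------------- manifest
    import pandas as _pd
    import scipy as _scipy
    import sklearn as _sk
    manifest = {
        "config": cfg,
        "config_hash": config_hash(cfg),
        "seed": int(cfg["seed"]),
        "stage_seeds": seeds,
        "versions": {"numpy": np.__version__, "scipy": _scipy.__version__,
                     "pandas": _pd.__version__, "scikit-learn": _sk.__version__},
        "conventions": {"units": "seconds",
                        "windows": "half-open [t0, t1)",
                        "utv_order": "row-major upper triangle, i < j"},
    }
    nio.write_results_json(manifest, outdir / "manifest.json")

    results.update({
        "responsive": responsive, "selection_rdm": sel_rdm,
        "selection_encoding": sel_enc, "roi_summary_rdm": summary_rdm,
        "roi_summary_encoding": summary_enc, "population_rsa": population,
        "cross_region_rsa": cross_region, "timecourse_rsa": timecourse,
        "dynamics": dynamics_out, "manifest": manifest,
    })
    return results
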