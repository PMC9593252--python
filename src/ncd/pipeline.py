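"""Configuration-driven orchestration of the full analysis.

A YAML config names the per-channel localization tables and the
parameters of each stage; :func:`run_pipeline` executes the stages in
dependency order (preprocess -> pair correlation / CBC / domains ->
dynamics) and writes per-stage CSV/JSON outputs plus a run manifest
recording the seed, a config hash, package versions, and every default
that filled an omitted field.  A fixed seed makes re-runs byte-identical.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cbc import CBCParams, cbc_values
from .domains import DomainParams, domain_polygons, find_domains, inout_density
from .dynamics import extract_trajectory, fit_state_model, transition_matrix
from .errors import NcdError, ParameterError
from .io_preprocess import (
    Dialect,
    GroupingParams,
    LocalizationTable,
    group_localizations,
    read_localizations,
    window_by_frames,
)
from .paircorr import RadialBins, bpcf, eom, pcf, rl_envelope
from .patterns import Window


class PipelineError(NcdError):
    """A stage failed; the message names the stage and the offending input."""


DEFAULTS = {
    "seed": None,  # mandatory
    "output_dir": "ncd_out",
    "channels": {},  # {"a": path, "b": path(optional)}
    "window": None,  # [x0, y0, x1, y1] nm; inferred from channel A if absent
    "grouping": {"max_off_frames": 3, "max_distance": 50.0},
    "bins": "0:1000:10",
    "edge_correction": "translation",
    "n_sims": 19,
    "cbc": {"n_rand": 19},
    "domains": {"d_th": 80.0, "min_cluster_size": 3, "buffer": 40.0},
    "windowing": None,  # {"frames_per_window": 250, "fps": 50, "n_frames": 12000}
    "roi": None,  # [x0, y0, x1, y1] nm, enables the dynamics stage
}


def normalize_config(raw: dict) -> tuple[dict, list]:
    """Merge a user config over the defaults; return it with the list of
    dotted keys that were filled from defaults (recorded in the manifest)."""
    cfg = copy.deepcopy(DEFAULTS)
    filled = []

    def merge(dst, src, prefix=""):
        for key, default in dst.items():
            if isinstance(default, dict) and default:
                sub = src.get(key) if isinstance(src.get(key), dict) else {}
                filled.extend(f"{prefix}{key}.{k}" for k in default if k not in sub)
                dst[key] = {**default, **sub}
            elif key in src:
                dst[key] = src[key]
            else:
                filled.append(f"{prefix}{key}")

    merge(cfg, raw)
    unknown = set(raw) - set(DEFAULTS)
    if unknown:
        raise ParameterError(f"unknown config keys: {sorted(unknown)}")
    if cfg["seed"] is None:
        raise ParameterError("config must set a seed (stochastic stages require it)")
    if "a" not in cfg["channels"]:
        raise ParameterError("config must name a channel 'a' input table")
    return cfg, filled


def load_config(path) -> tuple[dict, list]:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return normalize_config(raw)


def _stage_seed(root_seed: int, stage_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(root_seed), stage_index]))


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: dict, filled_defaults: Optional[list] = None, log=print) -> dict:
    """Execute the configured stages; returns {stage: output path} plus
    in-memory results under 'results'."""
    cfg = config
    out_dir = Path(cfg["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    bins = RadialBins.from_spec(cfg["bins"])
    edge = cfg["edge_correction"]
    outputs: dict = {"results": {}}
    window = Window(*cfg["window"]) if cfg["window"] else None

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    # --- preprocess ---------------------------------------------------
    gp = GroupingParams(**cfg["grouping"])
    wcfg = cfg["windowing"] or {}
    raw_tables = {}
    for ch, path in cfg["channels"].items():
        raw_tables[ch] = stage(
            "preprocess",
            read_localizations,
            path,
            window=window,
            fps=wcfg.get("fps"),
            n_frames=wcfg.get("n_frames"),
        )
    if window is None:  # shared window = union of per-channel extents
        wins = [t.window for t in raw_tables.values()]
        window = Window(
            min(w.x_min for w in wins),
            min(w.y_min for w in wins),
            max(w.x_max for w in wins),
            max(w.y_max for w in wins),
        )
        raw_tables = {
            ch: LocalizationTable(t.data, window, t.acquisition_fps, t.n_frames)
            for ch, t in raw_tables.items()
        }
    tables = {ch: stage("preprocess", group_localizations, t, gp) for ch, t in raw_tables.items()}
    pat_a = tables["a"].to_pattern(label="a")
    pat_b = tables["b"].to_pattern(label="b") if "b" in tables else None
    has_b = pat_b is not None and pat_b.n > 0
    if not has_b:
        log("ncd: channel B absent; co-clustering stages skipped")

    # --- pair correlation ---------------------------------------------
    g11 = stage("paircorr", pcf, pat_a, bins, edge) if pat_a.n >= 2 else None
    curves = pd.DataFrame({"r_center": bins.centers})
    curves["g11"] = g11.g if g11 is not None else np.nan
    if has_b:
        g22 = stage("paircorr", pcf, pat_b, bins, edge) if pat_b.n >= 2 else None
        g12 = stage("paircorr", bpcf, pat_a, pat_b, bins, edge)
        env = stage(
            "paircorr", rl_envelope, pat_a, pat_b, bins, cfg["n_sims"],
            _stage_seed(seed, 1), edge,
        )
        eom_curve = stage("paircorr", eom, g12, env)
        curves["g22"] = g22.g if g22 is not None else np.nan
        curves["g12"] = g12.g
        curves["rl_lo"] = env.lo
        curves["rl_hi"] = env.hi
        curves["rl_mean"] = env.mean_sim
        curves["eom"] = eom_curve.eom
        outputs["results"]["eom"] = eom_curve
    curves_path = out_dir / "curves.csv"
    curves.to_csv(curves_path, index=False)
    outputs["curves"] = str(curves_path)

    # --- CBC ----------------------------------------------------------
    if has_b:
        res = stage("cbc", cbc_values, pat_a, pat_b, CBCParams())
        cbc_df = pd.DataFrame(
            {"x": pat_a.points[:, 0], "y": pat_a.points[:, 1], "cbc_value": res.values}
        )
        cbc_path = out_dir / "cbc.csv"
        cbc_df.to_csv(cbc_path, index=False)
        outputs["cbc"] = str(cbc_path)
        outputs["results"]["cbc"] = res

    # --- domains -------------------------------------------------------
    dp = DomainParams(**cfg["domains"])
    ds = stage("domains", lambda: domain_polygons(find_domains(pat_a, dp)))
    dom_report = {
        "n_clusters": ds.n_clusters,
        "size_classes": ds.size_classes,
        "area_fraction": ds.area_fraction,
        "total_domain_area_um2": ds.total_domain_area_um2,
    }
    if has_b and ds.domain_union is not None:
        enrich = stage("domains", inout_density, ds, pat_b)
        dom_report["enrichment"] = enrich.to_dict()
        outputs["results"]["enrichment"] = enrich
    dom_path = out_dir / "domains.json"
    _json_dump(dom_report, dom_path)
    outputs["domains"] = str(dom_path)

    # --- dynamics -------------------------------------------------------
    if cfg["windowing"] and cfg["roi"] and has_b:
        fpw = int(wcfg["frames_per_window"])
        wins_a = stage("dynamics", window_by_frames, tables["a"], fpw)
        wins_b = stage("dynamics", window_by_frames, tables["b"], fpw)
        roi = Window(*cfg["roi"])
        traj = stage(
            "dynamics", extract_trajectory, wins_a, wins_b, roi,
            seed=_stage_seed(seed, 2), edge_correction=edge,
        )
        traj_df = pd.DataFrame(
            {
                "t": traj.times,
                "density_a": traj.density_a,
                "density_b": traj.density_b,
                "g_a": traj.g_a,
                "g_b": traj.g_b,
                "eom_short": traj.eom_short,
            }
        )
        traj_path = out_dir / "traj.csv"
        traj_df.to_csv(traj_path, index=False)
        outputs["traj"] = str(traj_path)
        outputs["results"]["trajectory"] = traj
        feats = traj.features("both")
        if feats.shape[0] >= 30:
            model = stage("states", fit_state_model, feats, seed)
            obs_a = np.column_stack([traj.density_a, traj.g_a])
            ok = np.isfinite(obs_a).all(axis=1)
            seqs = []
            if ok.sum() >= 2:
                seqs.append(model.predict(obs_a[ok]))
            obs_b = np.column_stack([traj.density_b, traj.g_b])
            ok_b = np.isfinite(obs_b).all(axis=1)
            if ok_b.sum() >= 2:
                seqs.append(model.predict(obs_b[ok_b]))
            states_out = {
                "state_means": model.means.tolist(),
                "state_weights": model.weights.tolist(),
            }
            if seqs:
                est = stage("states", transition_matrix, seqs)
                states_out["transition_matrix"] = est.matrix.tolist()
                states_out["stationary"] = est.stationary.tolist()
            states_path = out_dir / "states.json"
            _json_dump(states_out, states_path)
            outputs["states"] = str(states_path)
        else:
            log("ncd: too few defined (density, g) observations; state model skipped")

    # --- manifest -------------------------------------------------------
    cfg_text = json.dumps(cfg, sort_keys=True, default=str)
    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "seed": seed,
        "filled_defaults": sorted(filled_defaults or []),
        "versions": {"ncd": __version__, "numpy": np.__version__},
        "outputs": {k: v for k, v in outputs.items() if k != "results"},
    }
    manifest_path = out_dir / "manifest.json"
    _json_dump(manifest, manifest_path)
    outputs["manifest"] = str(manifest_path)
    return outputs
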