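"""Config-driven entry points tying the analysis stages together.

Each stage reads a (YAML or JSON) config, runs the corresponding module
function with a mandatory seed, and writes CSV/JSON outputs plus a run
manifest (config echo, seed, package version) to the output directory.

Stages: enumerate, dose-response, sweep, hysteresis, washout, dual-ec50,
tissue, synth.
"""

from __future__ import annotations

import argparse
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .examples import (autoreg_strong, toggle_fgf_level, toggle_linear_deep,
                       toggle_nonlinear)
from .memory_analysis import WashoutProtocol, hysteresis_curves, simulate_washout
from .model_core import ModelClass, ModelParameters
from .multi_threshold_tissue import (DualLoopModel, GradientProfile,
                                     dual_ec50_analysis, scaling_test,
                                     simulate_tissue)
from .parameter_sweep import (correlate_dnh_window, records_to_frame,
                              run_context_sweep, summarize_grid)
from .response_analysis import compute_dose_response, default_dose_grid, fit_hill
from .synthetic_data import NoiseModel, gen_dose_response, gen_gradient_profile
from .topology_space import class_counts, topologies_to_frame

STAGES = ("enumerate", "dose-response", "sweep", "hysteresis", "washout",
          "dual-ec50", "tissue", "synth")
_STOCHASTIC = {"sweep", "synth"}


def _params_from_config(cfg: dict) -> ModelParameters:
    if "params" in cfg:
        return ModelParameters.from_flat_dict(cfg["params"])
    preset = cfg.get("preset", "toggle_nonlinear")
    return {"toggle_nonlinear": toggle_nonlinear,
            "toggle_linear_deep": toggle_linear_deep,
            "autoreg_strong": autoreg_strong}[preset]()


def run(config: dict, outdir: str | Path) -> dict:
    """Run one stage; returns a summary dict (also written as JSON)."""
    stage = config.get("stage")
    if stage not in STAGES:
        raise ValueError(f"config.stage must be one of {STAGES}, "
                         f"got {stage!r}")
    seed = config.get("seed")
    if stage in _STOCHASTIC and seed is None:
        raise ValueError(f"config.seed is mandatory for stage {stage!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stage": stage, "seed": seed}

    if stage == "enumerate":
        topologies_to_frame().to_csv(outdir / "topologies.csv", index=False)
        summary["class_counts"] = class_counts()

    elif stage == "dose-response":
        params = _params_from_config(config)
        fgf = config.get("fgf_level", toggle_fgf_level())
        mc = ModelClass(config.get("model_class", "CIPF"))
        rows = []
        for level in (0.0, fgf):
            dr = compute_dose_response(mc, params, fgf_level=level)
            fit = fit_hill(dr)
            for d, y in zip(dr.doses, dr.responses):
                rows.append({"fgf_level": level, "dose": d, "response": y})
            summary[f"fit_fgf_{level:g}"] = {
                "ymax": fit.ymax, "ec50": fit.ec50, "nH": fit.nH}
        pd.DataFrame(rows).to_csv(outdir / "dose_response.csv", index=False)

    elif stage == "sweep":
        n = int(config.get("n", 500))
        classes = config.get("classes", ["STI", "SUI", "CFF", "CIPF"])
        contexts = config.get("contexts", [1, 2, 3, 4])
        records = []
        for cls in classes:
            for ctx in contexts:
                records += run_context_sweep(cls, ctx, n, seed)
        records_to_frame(records).to_csv(outdir / "sweep_records.csv",
                                         index=False)
        grid = summarize_grid(records)
        grid.to_csv(outdir / "property_grid.csv", index=False)
        cipf3 = [r for r in records
                 if r.model_class == "CIPF" and r.context_id == 3]
        if len(cipf3) >= 30:
            summary["corr_dnh_window_ctx3"] = correlate_dnh_window(cipf3)
        summary["n_records"] = len(records)

    elif stage == "hysteresis":
        params = _params_from_config(config)
        fgf = config.get("fgf_level", toggle_fgf_level())
        mc = ModelClass(config.get("model_class", "CIPF"))
        res = hysteresis_curves(mc, params, fgf_level=fgf)
        pd.DataFrame({
            "dose": res.off_curve.doses,
            "off": res.off_curve.responses,
            "on": res.on_curve.responses,
        }).to_csv(outdir / "hysteresis_curves.csv", index=False)
        summary.update(window_lo=res.window_lo, window_hi=res.window_hi,
                       window_size=res.window_size,
                       window_decades=res.window_decades)

    elif stage == "washout":
        params = _params_from_config(config)
        fgf = config.get("fgf_level", toggle_fgf_level())
        proto = WashoutProtocol(
            prestim_dose=config.get("prestim_dose", 100.0),
            prestim_duration=config.get("prestim_duration", 50.0),
            residual_tau=config.get("residual_tau", 5.0),
            reapplied_doses=np.asarray(config.get(
                "reapplied_doses", [0.0, 0.05, 0.1, 0.2, 0.5, 1, 2, 5])),
            readout_time=config.get("readout_time", 50.0),
            inhibitor_applied=config.get("inhibitor_applied", False))
        table = simulate_washout(ModelClass.CIPF, params, proto, fgf)
        table.to_csv(outdir / "washout.csv", index=False)
        summary["n_rows"] = len(table)

    elif stage == "dual-ec50":
        params = _params_from_config(config)
        fgf = config.get("fgf_level", toggle_fgf_level())
        model = DualLoopModel(
            shared=params, fgf_level=fgf,
            loop_deltas=config.get("loop_deltas",
                                   {"fb_k": 2.0, "bf_k": 2.0, "K_BI": 2.0}),
            downstream_deltas=config.get("downstream_deltas",
                                         {"kc5": 2.0, "K_BT": 2.0}))
        table = dual_ec50_analysis(model)
        table.to_csv(outdir / "dual_ec50.csv", index=False)
        summary["table"] = table.to_dict(orient="records")

    elif stage == "tissue":
        params = _params_from_config(config)
        L = config.get("L", 1000.0)
        bmp = GradientProfile(A=config.get("bmp_A", 50.0),
                              lam=config.get("bmp_lambda", 290.0),
                              source="right")
        fgf = GradientProfile(A=config.get("fgf_A", 5.0),
                              lam=config.get("fgf_lambda", 290.0),
                              source="left")
        pat = simulate_tissue(params, bmp, fgf, L,
                              n_cells=config.get("n_cells", 200))
        pd.DataFrame({"x": pat.x, "bmp": pat.bmp, "fgf": pat.fgf,
                      "bt": pat.bt_profile}).to_csv(
            outdir / "tissue_profile.csv", index=False)
        scal = scaling_test(params, bmp, fgf, L,
                            scales=config.get("scales", [0.5, 1.0, 2.0]))
        scal.to_csv(outdir / "scaling.csv", index=False)
        summary["border"] = pat.border_position
        summary["relative_borders"] = scal["relative_border"].tolist()

    elif stage == "synth":
        ds = gen_dose_response(seed=seed,
                               noise=NoiseModel(config.get("sigma", 0.1)))
        ds.data.to_csv(outdir / "synthetic_qpcr.csv", index=False)
        grad = gen_gradient_profile(seed=seed)
        grad.to_csv(outdir / "synthetic_gradient.csv", index=False)
        summary["n_rows"] = len(ds.data)

    manifest = {"config": config, "seed": seed, "version": __version__}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     default=str))
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2,
                                                    default=str))
    return summary


def main(argv=None) -> int:
    ap = argparse.ArgumentParser(
        prog="morphotoggle",
        description="BMP-FGF cross-inhibition analysis pipeline")
    ap.add_argument("--config", type=Path, default=None,
                    help="YAML/JSON config file")
    ap.add_argument("--stage", choices=STAGES, default=None)
    ap.add_argument("--seed", type=int, default=None)
    ap.add_argument("--out", type=Path, required=True)
    args = ap.parse_args(argv)

    config: dict = {}
    if args.config is not None:
        config = yaml.safe_load(args.config.read_text()) or {}
    if args.stage is not None:
        config["stage"] = args.stage
    if args.seed is not None:
        config["seed"] = args.seed
    try:
        summary = run(config, args.out)
    except (ValueError, KeyError) as e:
        print(f"config error: {e}", file=sys.stderr)
        return 2
    print(json.dumps(summary, indent=2, default=str))
    return 0


if __name__ == "__main__":
    sys.exit(main())
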