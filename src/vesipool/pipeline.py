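"""Configuration-driven orchestration of simulate -> analyze -> report runs.

A run is a YAML file with a seed, an output directory and an ordered list
of stages; every stage writes its outputs under the run directory together
with a JSON provenance record (config hash, seed, package version), so a
run is reproducible byte-for-byte from its config.

Supported stages
----------------
``simulate_frap``   draw per-group normalized FRAP traces (or raw traces
                    via the full generator) and write them as CSV
``extract``         read a stack TIFF + ROI zip and extract raw traces
``frap_fit``        biexponential fit per group -> JSON
``frap_ftest``      extra sum-of-squares F test across groups -> JSON
``frap_timepoint``  fixed-timepoint group comparison -> JSON
``report``          recovery-curve figure + group summary table
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .errors import InvalidInputError, InvalidParameterError, VesipoolError
from .frap import (
    extra_ss_f_test,
    fit_double_exponential,
    normalize_trace,
    qc_photobleaching,
    recovery_at_timepoint,
)
from .io import (
    frap_traces_to_csv,
    normalized_traces_to_csv,
    read_roi_zip,
    read_stack,
)
from .kinetics import RecoveryModel
from .sim import SimConfig, make_schedule, simulate_frap_trace, simulate_normalized_traces

log = logging.getLogger("vesipool")

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "make_report"]


class PipelineError(VesipoolError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


@dataclasses.dataclass
class RunConfig:
    """Parsed run configuration."""

    stages: list
    seed: int = 0
    outdir: str = "run_output"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            stages=raw.get("stages", []),
            seed=int(raw.get("seed", 0)),
            outdir=raw.get("outdir", "run_output"),
            log_level=raw.get("log_level", "INFO"),
        )

    def config_hash(self) -> str:
        # hash the analytic content only: the same stages and seed must
        # hash identically wherever the outputs land
        blob = json.dumps(
            {"stages": self.stages, "seed": self.seed}, sort_keys=True, default=str
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _provenance(config: RunConfig, stage: str) -> dict:
    return {
        "stage": stage,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "vesipool_version": __version__,
    }


def _write_json(path: Path, payload: dict):
    path.write_text(json.dumps(payload, indent=2, default=float))


def _stage_simulate_frap(config, params, state, outdir):
    noise_sd = params.get("noise_sd", 0.05)
    level = params.get("level", "normalized")
    schedule = make_schedule(params.get("schedule_mode", "standard"))
    groups = {}
    rng = np.random.default_rng(config.seed)
    for gspec in params["groups"]:
        model = RecoveryModel(
            gspec.get("plateau", 0.7),
            gspec.get("fast_fraction", 0.4),
            gspec.get("half_fast", 60.0),
            gspec.get("half_slow", 1200.0),
        )
        name = gspec["name"]
        n = int(gspec.get("n_traces", 20))
        if level == "normalized":
            traces = simulate_normalized_traces(
                model, schedule, noise_sd=noise_sd, n_traces=n, rng=rng
            )
        else:
            traces = []
            for i in range(n):
                raw, _ = simulate_frap_trace(
                    SimConfig(
                        recovery_model=model,
                        noise_sd=noise_sd,
                        n_boutons=1,
                        seed=int(rng.integers(2**31)),
                        schedule=schedule,
                    )
                )
                frap_traces_to_csv(raw, outdir / f"{name}_raw_{i}.csv")
                nt = normalize_trace(raw[0])
                qc_photobleaching(nt)
                traces.append(nt)
        for tr in traces:
            tr.trace_id = f"{name}_{tr.trace_id}"
        normalized_traces_to_csv(traces, outdir / f"traces_{name}.csv")
        groups[name] = traces
    state["groups"] = groups


def _stage_extract(config, params, state, outdir):
    from .stacks import RoiSet, extract_roi_traces

    stack_path = Path(params["stack"])
    if not stack_path.exists():
        raise InvalidInputError(f"stack file {stack_path} does not exist")
    stack = read_stack(stack_path)
    named = read_roi_zip(params["rois"])
    rois = RoiSet(
        bouton_rois=[r for k, r in sorted(named.items()) if k.startswith("bouton")],
        cell_rois=[r for k, r in sorted(named.items()) if k.startswith("cell")],
        background_roi=named.get("background"),
    )
    df = extract_roi_traces(stack, rois)
    df.to_csv(outdir / "extracted_traces.csv", index=False)
    state["extracted"] = df


def _stage_frap_fit(config, params, state, outdir):
    fits = {}
    for name, traces in state["groups"].items():
        fit = fit_double_exponential(traces, mode=params.get("mode", "pooled"))
        fits[name] = fit
        _write_json(
            outdir / f"fit_{name}.json",
            {
                "group": name,
                "plateau": fit.plateau,
                "fast_fraction": fit.fast_fraction,
                "half_fast_s": fit.half_fast,
                "half_slow_s": fit.half_slow,
                "residual_ss": fit.residual_ss,
                "n_points": fit.n_points,
                "param_sd": fit.param_sd,
                "flags": fit.flags,
                "provenance": _provenance(config, "frap_fit"),
            },
        )
    state["fits"] = fits


def _stage_frap_ftest(config, params, state, outdir):
    names = list(state["groups"])
    res = extra_ss_f_test(
        [state["groups"][n] for n in names],
        alpha=params.get("alpha", 0.05),
        mode=params.get("mode", "pooled"),
    )
    state["ftest"] = res
    _write_json(
        outdir / "ftest.json",
        {
            "groups": names,
            "f_ratio": res.f_ratio,
            "df_num": res.df_num,
            "df_den": res.df_den,
            "p_value": res.p_value,
            "ss_shared": res.ss_shared,
            "ss_separate": res.ss_separate,
            "verdict": res.verdict,
            "provenance": _provenance(config, "frap_ftest"),
        },
    )


def _stage_frap_timepoint(config, params, state, outdir):
    names = list(state["groups"])
    cmp_ = recovery_at_timepoint(
        [state["groups"][n] for n in names],
        query_time=params.get("query_time", 4080.0),
        test=params.get("test", "t"),
    )
    state["timepoint"] = cmp_
    _write_json(
        outdir / "timepoint.json",
        {
            "groups": names,
            "query_time_s": cmp_.query_time,
            "test": cmp_.test,
            "statistic": cmp_.statistic,
            "p_value": cmp_.p_value,
            "group_means": cmp_.group_means,
            "group_sems": cmp_.group_sems,
            "provenance": _provenance(config, "frap_timepoint"),
        },
    )


_STAGES = {
    "simulate_frap": _stage_simulate_frap,
    "extract": _stage_extract,
    "frap_fit": _stage_frap_fit,
    "frap_ftest": _stage_frap_ftest,
    "frap_timepoint": _stage_frap_timepoint,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order.

    Returns the in-memory state (groups, fits, test results).  A failing
    stage raises :class:`PipelineError` naming the stage; outputs of the
    stages already completed are kept on disk.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    state: dict = {}
    for spec in config.stages:
        spec = dict(spec)
        name = spec.pop("stage")
        if name == "report":
            make_report(state, outdir, config=config, **spec)
            continue
        if name not in _STAGES:
            raise PipelineError(name, "unknown stage")
        log.info("running stage %s", name)
        try:
            _STAGES[name](config, spec, state, outdir)
        except VesipoolError as exc:
            raise PipelineError(name, str(exc)) from exc
        except KeyError as exc:
            raise PipelineError(name, f"missing parameter or input {exc}") from exc
    _write_json(outdir / "run.json", _provenance(config, "run"))
    return state


def make_report(state: dict, outdir, config: RunConfig | None = None, **params):
    """Write a recovery-curve figure with fitted models and a group table.

    The table follows the n/N convention of the field: ``n`` counts
    traces (synapses/cells), ``N`` independent replicates when known.
    Missing stages are skipped with a warning.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    groups = state.get("groups")
    if not groups:
        log.warning("report: no groups in run state, nothing to plot")
        return
    fits = state.get("fits", {})
    fig, ax = plt.subplots(figsize=(6, 4))
    for name, traces in groups.items():
        t = traces[0].post_times
        vals = np.stack([tr.post_values for tr in traces])
        mean = vals.mean(axis=0)
        sem = vals.std(axis=0, ddof=1) / np.sqrt(len(traces))
        ax.errorbar(t / 60.0, mean, yerr=sem, fmt="o", ms=3, label=f"{name} (n={len(traces)})")
        if name in fits:
            tt = np.linspace(0, t.max(), 300)
            ax.plot(tt / 60.0, fits[name].predict(tt), "-", lw=1)
    ax.set_xlabel("time after bleach (min)")
    ax.set_ylabel("normalized recovery")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(outdir / "recovery_curves.png", dpi=150)
    plt.close(fig)
    rows = []
    for name, traces in groups.items():
        final = [tr.post_values[-1] for tr in traces]
        row = {
            "group": name,
            "n": len(traces),
            "N": params.get("n_replicates", {}).get(name, "") if params.get("n_replicates") else "",
            "mean_final_recovery": float(np.mean(final)),
            "sem_final_recovery": float(np.std(final, ddof=1) / np.sqrt(len(final))),
        }
        if name in fits:
            row.update(
                plateau=fits[name].plateau,
                half_fast_s=fits[name].half_fast,
                half_slow_s=fits[name].half_slow,
            )
        rows.append(row)
    if state.get("ftest") is not None:
        for row in rows:
            row["ftest_p"] = state["ftest"].p_value
            row["ftest_verdict"] = state["ftest"].verdict
    pd.DataFrame(rows).to_csv(outdir / "group_table.csv", index=False)
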