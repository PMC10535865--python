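"""Configuration-driven orchestration of the analysis stages.

One structured config (YAML mapping or dict) drives a run: it names the
stages to execute, the input files by role, the analysis options and the
seed.  Stages run in dependency order (``synth`` feeds ``kinetics`` when
no explicit traces are given); a failing stage aborts its dependents but
independent stages still complete.  Every output file carries the config
hash that produced it, and reruns with an identical config and seed are
byte-identical (logs aside).
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from . import __version__, energetics, io as pio, kinetics, resistance, synthetic
from . import trajectory as ptraj

log = logging.getLogger("pgpkit")

KNOWN_STAGES = ("synth", "kinetics", "doseresponse", "qpcr", "mmgbsa", "hbonds")
# stages whose inputs may come from an earlier stage
_DEPENDS = {"kinetics": ("synth",)}


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    """Validated run configuration."""

    stages: list
    outdir: Path
    seed: int = 0
    inputs: dict = field(default_factory=dict)
    options: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_mapping(cls, cfg: dict, base: Optional[Path] = None) -> "RunConfig":
        if "stages" not in cfg or not cfg["stages"]:
            raise ConfigError("config must list at least one stage")
        unknown = set(cfg["stages"]) - set(KNOWN_STAGES)
        if unknown:
            raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
        if "outdir" not in cfg:
            raise ConfigError("config must name an output directory (outdir)")
        base = base or Path.cwd()
        inputs = {}
        for role, p in (cfg.get("inputs") or {}).items():
            path = Path(p)
            if not path.is_absolute():
                path = base / path
            inputs[role] = path
        return cls(
            stages=list(cfg["stages"]),
            outdir=Path(cfg["outdir"]),
            seed=int(cfg.get("seed", 0)),
            inputs=inputs,
            options=dict(cfg.get("options") or {}),
            log_level=str(cfg.get("log_level", "INFO")),
        )

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        path = Path(path)
        cfg = yaml.safe_load(path.read_text())
        if not isinstance(cfg, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_mapping(cfg, base=path.parent)

    def canonical(self) -> dict:
        return {
            "stages": self.stages,
            "seed": self.seed,
            "inputs": {k: str(v) for k, v in sorted(self.inputs.items())},
            "options": self.options,
        }

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.canonical(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _required_inputs(config: RunConfig) -> dict:
    """Input roles each requested stage needs from disk (pre-flight check)."""
    need: dict[str, list] = {}
    if "kinetics" in config.stages and "synth" not in config.stages:
        need["kinetics"] = ["trace", "control_trace", "events"]
    if "doseresponse" in config.stages:
        need["doseresponse"] = ["dose_response"]
    if "qpcr" in config.stages:
        need["qpcr"] = ["qpcr"]
    if "mmgbsa" in config.stages:
        need["mmgbsa"] = ["energies"]
    if "hbonds" in config.stages:
        need["hbonds"] = ["trajectory", "annotations"]
    return need


def run_pipeline(config: Union[RunConfig, dict]) -> dict:
    """Execute the configured stages; returns the result bundle.

    The bundle maps stage name to ``{"status", "outputs", ...}`` plus a
    ``provenance`` record (config hash, seed, package version).  Missing
    input files fail pre-flight validation before any stage runs.
    """
    if isinstance(config, dict):
        config = RunConfig.from_mapping(config)
    logging.basicConfig(level=config.log_level)

    # pre-flight: every file a requested stage will read must exist
    for stage, roles in _required_inputs(config).items():
        for role in roles:
            if role not in config.inputs:
                raise ConfigError(f"stage {stage!r} needs input role {role!r}")
            if not config.inputs[role].exists():
                raise ConfigError(
                    f"stage {stage!r}: input file {config.inputs[role]} not found"
                )

    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "pgpkit_version": __version__,
    }
    bundle: dict = {"provenance": {**meta, "config": config.canonical()}}
    failed: set = set()

    runners = {
        "synth": _stage_synth,
        "kinetics": _stage_kinetics,
        "doseresponse": _stage_doseresponse,
        "qpcr": _stage_qpcr,
        "mmgbsa": _stage_mmgbsa,
        "hbonds": _stage_hbonds,
    }
    for stage in KNOWN_STAGES:
        if stage not in config.stages:
            continue
        blockers = [d for d in _DEPENDS.get(stage, ()) if d in failed]
        if blockers:
            bundle[stage] = {
                "status": "aborted",
                "reason": f"dependency failed: {', '.join(blockers)}",
            }
            log.error("stage %s aborted (failed dependency %s)", stage, blockers)
            continue
        try:
            bundle[stage] = runners[stage](config, outdir, meta, bundle)
            bundle[stage]["status"] = "ok"
            log.info("stage %s completed", stage)
        except Exception as exc:  # noqa: BLE001 - stage isolation is the point
            failed.add(stage)
            bundle[stage] = {"status": "failed", "error": f"{type(exc).__name__}: {exc}"}
            log.error("stage %s failed: %s", stage, exc)

    (outdir / "provenance.json").write_text(
        json.dumps(bundle["provenance"], indent=2, sort_keys=True) + "\n"
    )
    return bundle


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------


def _stage_synth(config: RunConfig, outdir: Path, meta: dict, _bundle: dict) -> dict:
    """Generate a control + inhibited trace pair (and their ground truth)."""
    opts = config.options.get("synth", {})
    cond = kinetics.AssayConditions()
    k_plus = float(opts.get("k_plus", synthetic.DEFAULT_K_PLUS))
    k_act = float(opts.get("k_act", synthetic.DEFAULT_K_ACT))
    inhibition = float(opts.get("inhibition", 0.5))  # fraction of pump blocked
    noise_sd = float(opts.get("noise_sd", 0.0))
    paths = {}
    truth = {}
    for label, ka in (("control", k_act), ("inhibited", (1.0 - inhibition) * k_act)):
        spec = synthetic.UptakeSpec(
            seed=config.seed,
            params=kinetics.TransportParams(k_plus=k_plus, k_act=ka),
            conditions=cond,
            noise_sd=noise_sd,
        )
        trace, params = synthetic.gen_uptake_trace(spec)
        path = outdir / f"trace_{label}.csv"
        pio.write_trace_csv(trace, path)
        paths[label] = path
        truth[label] = {"k_plus": params.k_plus, "k_act": params.k_act}
        events = trace.events
    (outdir / "synth_truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    return {"outputs": {k: str(v) for k, v in paths.items()}, "events": events,
            "truth": truth}


def _stage_kinetics(config: RunConfig, outdir: Path, meta: dict, bundle: dict) -> dict:
    opts = config.options.get("kinetics", {})
    cond = kinetics.AssayConditions()
    if "synth" in bundle and bundle["synth"].get("status") != "failed":
        synth = bundle["synth"]
        events = synth["events"]
        trace_i = pio.read_trace_csv(synth["outputs"]["inhibited"], events=events)
        trace_0 = pio.read_trace_csv(synth["outputs"]["control"], events=events)
    else:
        events = pio.read_events(config.inputs["events"])
        trace_i = pio.read_trace_csv(config.inputs["trace"], events=events)
        trace_0 = pio.read_trace_csv(config.inputs["control_trace"], events=events)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result, est_i, est_0 = kinetics.estimate_inhibition(
            trace_i, trace_0, cond, cond,
            window=float(opts.get("window", 300.0)),
        )
    rows = []
    for label, est in (("control", est_0), ("inhibited", est_i)):
        row = {"assay": label, **{k: v for k, v in vars(est).items()}}
        rows.append(row)
    df = pd.DataFrame(rows)
    df["r"] = [1.0, result.ratio]
    out = outdir / "kinetics.tsv"
    pio.write_tsv(df, out, metadata=meta)
    return {"outputs": {"table": str(out)}, "r": result.ratio}


def _stage_doseresponse(config: RunConfig, outdir: Path, meta: dict, _b: dict) -> dict:
    df = pio.read_dose_response_csv(config.inputs["dose_response"])
    data = resistance.DoseResponseData(
        doses=df["dose"].to_numpy(), viability=df["viability_pct"].to_numpy()
    )
    opts = config.options.get("doseresponse", {})
    fit = resistance.fit_dose_response(
        data,
        fix_top=opts.get("fix_top"),
        fix_bottom=opts.get("fix_bottom"),
    )
    out = outdir / "doseresponse.tsv"
    pio.write_tsv(pd.DataFrame([vars(fit)]), out, metadata=meta)
    return {"outputs": {"table": str(out)}, "ic50": fit.ic50, "converged": fit.converged}


def _stage_qpcr(config: RunConfig, outdir: Path, meta: dict, _b: dict) -> dict:
    opts = config.options.get("qpcr", {})
    df = pio.read_qpcr_csv(config.inputs["qpcr"])
    table = resistance.ddct_table(
        df,
        target_gene=opts.get("target_gene", "ABCB1"),
        reference_gene=opts.get("reference_gene", "GAPDH"),
        control_sample=opts.get("control_sample", "control"),
    )
    out = outdir / "qpcr.tsv"
    pio.write_tsv(table, out, metadata=meta)
    return {"outputs": {"table": str(out)}}


def _stage_mmgbsa(config: RunConfig, outdir: Path, meta: dict, _b: dict) -> dict:
    opts = config.options.get("mmgbsa", {})
    frames = pio.read_energy_csv(config.inputs["energies"])
    summary, per_replica = energetics.gbsa_from_frames(
        frames, temperature=float(opts.get("temperature", 310.0))
    )
    out = outdir / "mmgbsa.tsv"
    pio.write_tsv(pd.DataFrame([summary.as_dict()]), out, metadata=meta)
    out_rep = outdir / "mmgbsa_replicas.tsv"
    pio.write_tsv(per_replica, out_rep, metadata=meta)
    return {
        "outputs": {"summary": str(out), "replicas": str(out_rep)},
        "dG_bind": summary.dG_bind,
    }


def _stage_hbonds(config: RunConfig, outdir: Path, meta: dict, _b: dict) -> dict:
    opts = config.options.get("hbonds", {})
    traj_path = config.inputs["trajectory"]
    if str(traj_path).endswith(".pdb"):
        traj = pio.read_trajectory_pdb(traj_path, config.inputs["annotations"])
    else:
        traj = pio.read_trajectory_csv(traj_path, config.inputs["annotations"])
    table = ptraj.hbond_occupancy(
        traj,
        grouping=opts.get("grouping", "atom-pair"),
        distance_cutoff=float(opts.get("distance_cutoff", 3.5)),
        angle_cutoff=float(opts.get("angle_cutoff", 120.0)),
        min_occupancy=float(opts.get("min_occupancy", 30.0)),
    )
    mean, sd = ptraj.hbond_count_series(
        traj,
        distance_cutoff=float(opts.get("distance_cutoff", 3.5)),
        angle_cutoff=float(opts.get("angle_cutoff", 120.0)),
    )
    out = outdir / "hbonds.tsv"
    pio.write_tsv(table, out, metadata=meta)
    return {
        "outputs": {"table": str(out)},
        "count_mean": mean,
        "count_sd": sd,
    }
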