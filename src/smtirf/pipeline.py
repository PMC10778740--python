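"""Reproducible end-to-end runs: simulate -> detect -> stoich / spt.

A run is fully described by one structured config (YAML/dict) plus a root
seed; all module randomness flows from that seed through named substreams,
so the same config and seed reproduce byte-identical outputs.  Every filter
stage logs its in/out counts so attrition is auditable.
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

from . import __version__
from .simulate import (AcquisitionGeometry, StoichiometryModel, NoiseModel,
                       simulate_photobleaching_experiment,
                       simulate_tracking_experiment, _jsonable)
from .detect import DetectionParams, detect_movie, candidates_to_table
from .stoich import (StepCounterParams, extract_trace, exclude_sloped,
                     slope_r2, count_steps, aggregate_stoichiometry,
                     recovery_experiment, results_to_table)
from .spt import (LinkingParams, ClassifierParams, link_trajectories,
                  diffusion_report, tracks_to_table)

__all__ = ["RunConfig", "run", "report"]

log = logging.getLogger("smtirf")

KINDS = ("bleach", "track", "recover")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    kind: str
    seed: int
    out_dir: str
    geometry: AcquisitionGeometry
    noise: NoiseModel
    stoich: StoichiometryModel
    detection: DetectionParams
    counter: StepCounterParams
    linking: LinkingParams
    classifier: ClassifierParams
    options: dict

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        def block(name, klass, default=None):
            raw = cfg.get(name, {})
            if not isinstance(raw, dict):
                raise ValueError(f"config field '{name}' must be a mapping")
            try:
                return klass(**raw) if raw or default is None else default
            except (TypeError, ValueError) as exc:
                raise ValueError(f"invalid config block '{name}': {exc}") from exc

        kind = cfg.get("kind")
        if kind not in KINDS:
            raise ValueError(f"config field 'kind' must be one of {KINDS}, got {kind!r}")
        seed = cfg.get("seed")
        if not isinstance(seed, int):
            raise ValueError("config field 'seed' must be an integer")
        out_dir = cfg.get("out_dir", "run")
        geometry = block("geometry", AcquisitionGeometry, AcquisitionGeometry())
        if "stoichiometry" in cfg:
            raw = dict(cfg["stoichiometry"])
            if "fractions" in raw:
                raw["fractions"] = tuple(raw["fractions"])
            try:
                stoich = StoichiometryModel(**raw)
            except (TypeError, ValueError) as exc:
                raise ValueError(f"invalid config block 'stoichiometry': {exc}") from exc
        else:
            stoich = StoichiometryModel()
        return cls(
            kind=kind, seed=seed, out_dir=str(out_dir), geometry=geometry,
            noise=block("noise", NoiseModel, NoiseModel()),
            stoich=stoich,
            detection=block("detection", DetectionParams, DetectionParams()),
            counter=block("counter", StepCounterParams, StepCounterParams()),
            linking=block("linking", LinkingParams, LinkingParams()),
            classifier=block("classifier", ClassifierParams, ClassifierParams()),
            options=cfg.get("options", {}) or {},
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return _jsonable({
            "kind": self.kind, "seed": self.seed, "out_dir": self.out_dir,
            "geometry": self.geometry, "noise": self.noise,
            "stoichiometry": self.stoich, "detection": self.detection,
            "counter": self.counter, "linking": self.linking,
            "classifier": self.classifier, "options": self.options,
        })


def _config_hash(cfg_dict: dict) -> str:
    # out_dir is a storage location, not an analysis parameter: two runs of
    # the same analysis into different directories are the same run
    payload = {k: v for k, v in cfg_dict.items() if k != "out_dir"}
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")


def _substreams(seed: int, names: tuple[str, ...]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


# --------------------------------------------------------------------------
# run
# --------------------------------------------------------------------------

def run(config: RunConfig) -> Path:
    """Execute one configured run; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        cfg_dict = config.to_dict()
        manifest = {"package_version": __version__, "seed": config.seed,
                    "config": cfg_dict, "config_hash": _config_hash(cfg_dict)}
        _write_json(out / "manifest.json", manifest)
        rngs = _substreams(config.seed, ("simulate", "detect", "stoich", "spt"))
        if config.kind == "bleach":
            summary = _run_bleach(config, rngs, out)
        elif config.kind == "track":
            summary = _run_track(config, rngs, out)
        else:
            summary = _run_recover(config, rngs, out)
        summary["config_hash"] = manifest["config_hash"]
        summary["seed"] = config.seed
        _write_json(out / "summary.json", summary)
    finally:
        log.removeHandler(handler)
        handler.close()
    return out


def _run_bleach(config: RunConfig, rngs, out: Path) -> dict:
    opts = config.options
    movie, truth = simulate_photobleaching_experiment(
        config.stoich, config.geometry, config.noise, rngs["simulate"],
        density=opts.get("density", 0.2),
        n_particles=opts.get("n_particles"))
    if opts.get("write_movie", True):
        movie.write_tiff(out / "movie.tif")
    truth.to_particle_table().to_csv(out / "ground_truth.csv", index=False)

    det = detect_movie(movie, config.detection, mode="bleach")
    cands = det["candidates"]
    candidates_to_table(cands).to_csv(out / "detections.csv", index=False)
    kept = [c for c in cands if c.retained]
    log.info("detection: %d candidates, %d retained", len(cands), len(kept))

    traces, results, counts = [], [], []
    n_sloped = 0
    for i, c in enumerate(kept):
        tr = extract_trace(movie, c, window=config.detection.window, spot_id=i)
        tr.slope_fit_r2 = slope_r2(tr.intensities)
        if exclude_sloped(tr.intensities, opts.get("r2_threshold", 0.83)):
            tr.excluded, tr.exclusion_reason = True, "sloped_r2"
            n_sloped += 1
            traces.append(tr)
            results.append(None)
            continue
        res = count_steps(tr.intensities, config.counter)
        traces.append(tr)
        results.append(res)
        counts.append(res.n_steps)
    log.info("traces: %d extracted, %d excluded sloped, %d counted",
             len(traces), n_sloped, len(counts))
    results_to_table(traces, results).to_csv(out / "traces.csv", index=False)

    summary = {"kind": "bleach", "n_particles_true": len(truth),
               "n_candidates": len(cands), "n_retained": len(kept),
               "n_excluded_sloped": n_sloped, "counters": det["counters"]}
    if counts:
        dist = aggregate_stoichiometry(counts)
        summary["fractions"] = dist.fractions.tolist()
        summary["n_counted"] = dist.n_traces
        summary["n_zero_step"] = dist.n_zero_step
        summary["n_many_step"] = dist.n_many_step
    return summary


def _run_track(config: RunConfig, rngs, out: Path) -> dict:
    opts = config.options
    conditions = opts.get("conditions")
    if conditions is None:
        conditions = [{"name": "default",
                       "mode_fractions": opts.get("mode_fractions", [1.0, 0.0, 0.0]),
                       "D_by_mode": opts.get("D_by_mode", [0.1, 0.05, 0.0])}]
    summary = {"kind": "track", "conditions": {}}
    for cond in conditions:
        name = str(cond.get("name", "cond"))
        movie, truth = simulate_tracking_experiment(
            cond["mode_fractions"], cond["D_by_mode"], config.geometry,
            config.noise, rngs["simulate"],
            density=cond.get("density", opts.get("density", 0.05)),
            n_particles=cond.get("n_particles", opts.get("n_particles")),
            confinement_radius=cond.get("confinement_radius", 0.2),
            localization_noise_sd=cond.get("localization_noise_sd", 0.02))
        truth.to_frame_table().to_csv(out / f"ground_truth_{name}.csv", index=False)
        det = detect_movie(movie, config.detection, mode="track")
        tracks = link_trajectories(det["spots_by_frame"], config.linking,
                                   pixel_size=movie.pixel_size,
                                   frame_interval=movie.frame_interval)
        tracks_to_table(tracks).to_csv(out / f"tracks_{name}.csv", index=False)
        log.info("condition %s: %d detections -> %d tracks", name,
                 det["counters"]["detections"], len(tracks))
        if tracks:
            rep = diffusion_report(tracks, config.classifier)
            rep["_table"].to_csv(out / f"track_results_{name}.csv", index=False)
            del rep["_table"]
        else:
            rep = {"n_tracks": 0}
        rep["counters"] = det["counters"]
        summary["conditions"][name] = rep
    return summary


def _run_recover(config: RunConfig, rngs, out: Path) -> dict:
    opts = config.options
    rep = recovery_experiment(
        true_fractions=config.stoich.fractions,
        n_traces=opts.get("n_traces", 500),
        seed=rngs["stoich"],
        step_noise_ratio=opts.get("step_noise_ratio", 3.0),
        n_frames=config.geometry.n_frames,
        stoich=config.stoich,
        counter=config.counter,
        r2_threshold=opts.get("r2_threshold", 0.83),
        n_cells=opts.get("n_cells", 10))
    pd.DataFrame(rep["confusion_matrix"]).to_csv(out / "confusion_matrix.csv", index=False)
    rep["kind"] = "recover"
    return rep


# --------------------------------------------------------------------------
# report
# --------------------------------------------------------------------------

def report(run_dir) -> Path:
    """Render a human-readable report (tables + figures) for a finished run."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    summary_path = run_dir / "summary.json"
    if not summary_path.exists():
        raise FileNotFoundError(f"no summary.json in {run_dir}; run the pipeline first")
    summary = json.loads(summary_path.read_text())
    lines = [f"# Run report ({summary.get('kind', '?')})", ""]

    if summary.get("kind") == "recover":
        lines.append("| k-mer | true fraction | estimated |")
        lines.append("|---|---|---|")
        for k, (t, e) in enumerate(zip(summary["true_fractions"],
                                       summary["estimated_fractions"]), start=1):
            lines.append(f"| {k} | {t:.4f} | {e:.4f} |")
        lines.append("")
        lines.append(f"max abs error: {summary['max_abs_error']:.4f}")
        fig, ax = plt.subplots(figsize=(4, 3))
        k = np.arange(1, 5)
        ax.bar(k - 0.18, summary["true_fractions"][:4], width=0.36, label="true")
        ax.bar(k + 0.18, summary["estimated_fractions"], width=0.36, label="estimated")
        ax.set_xlabel("photobleaching steps")
        ax.set_ylabel("fraction")
        ax.legend()
        fig.tight_layout()
        fig.savefig(run_dir / "fractions.png", dpi=120)
        plt.close(fig)
    elif summary.get("kind") == "bleach":
        if "fractions" in summary:
            lines.append("| steps | fraction |")
            lines.append("|---|---|")
            for k, f in enumerate(summary["fractions"], start=1):
                lines.append(f"| {k} | {f:.4f} |")
    elif summary.get("kind") == "track":
        for name, rep in summary.get("conditions", {}).items():
            lines.append(f"## condition {name}")
            fr = rep.get("fractions", {})
            lines.append("fractions: " + ", ".join(f"{m}={v:.3f}" for m, v in fr.items()))
            for m, st in rep.get("D_pooled", {}).items():
                lines.append(f"D({m}) = {st['mean']:.4f} +/- {st['sd']:.4f} um^2/s (n={st['n']})")
            lines.append("")
            res_path = run_dir / f"track_results_{name}.csv"
            if res_path.exists():
                tbl = pd.read_csv(res_path)
                fig, ax = plt.subplots(figsize=(4, 3))
                for m in ("free", "confined", "immobile"):
                    d = tbl.loc[tbl["mode"] == m, "D"].dropna()
                    if len(d):
                        ax.hist(d, bins=30, alpha=0.6, label=m)
                ax.set_xlabel("D (um$^2$/s)")
                ax.set_ylabel("tracks")
                ax.legend()
                fig.tight_layout()
                fig.savefig(run_dir / f"D_hist_{name}.png", dpi=120)
                plt.close(fig)
    if "confusion_matrix" in summary:
        lines.append("")
        lines.append("confusion matrix (rows = true k, cols = counted steps 0..):")
        for row in summary["confusion_matrix"]:
            lines.append("  " + " ".join(f"{v:5d}" for v in row))
    path = run_dir / "report.md"
    path.write_text("\n".join(lines) + "\n")
    return path
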