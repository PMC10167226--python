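"""End-to-end orchestration: config-driven runs with a hashed manifest.

Two pipelines are composed from the library modules:

``run_amorphous``
    motif table -> hydropathy scores -> aggregation masses from a turbidity
    plate -> hydropathy/activity regression -> predictions for any variants
    without activity data.

``run_amyloid``
    ThT plate -> per-ratio sigmoid fits and half-time delays -> constrained
    global fits for each candidate free rate constant, ranked by residual
    sum of squares.

Every output file is listed in ``manifest.json`` with a SHA-256 content
hash; with a fixed seed the hashes are reproducible.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .activity import aggregation_mass, fit_activity_regression, predict_activity
from .errors import LoopchapError, StageError
from .hydropathy import load_scale, read_motif_table, score_panel
from .kinetics import fit_sigmoid, halftime_delay, normalize_tht, rank_global_fits
from .plateio import group_traces, read_plate_csv, read_well_map, traces_from_plate


@dataclass
class RunConfig:
    out_dir: str
    motif_table: str | None = None
    plate_csv: str | None = None
    well_map: str | None = None
    scale: str = "biological"
    ratio: float | None = None
    baseline_points: int = 3
    ci_level: float = 0.95
    m0: float = 3e-6
    n_c: float = 2.0
    n_2: float = 2.0
    n_starts: int = 16
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise LoopchapError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _require(cfg: RunConfig, *names):
    for name in names:
        path = getattr(cfg, name)
        if path is None:
            raise LoopchapError(f"config is missing '{name}'")
        if not Path(path).exists():
            raise LoopchapError(f"{name} file not found: {path}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out: Path, cfg: RunConfig, files: list[Path]) -> Path:
    manifest = {
        "loopchap_version": __version__,
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "outputs": {f.name: _sha256(f) for f in sorted(files)},
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def _stage(name):
    """Decorator: re-raise stage exceptions tagged with the stage name."""
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
        return inner
    return wrap


def run_amorphous(cfg: RunConfig) -> dict:
    """Scores, aggregation masses, regression and predictions in one pass."""
    _require(cfg, "motif_table", "plate_csv", "well_map")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    scale = _stage("load_scale")(load_scale)(cfg.scale)
    panel = _stage("read_motifs")(read_motif_table)(cfg.motif_table)
    scores = _stage("score_panel")(score_panel)(panel, scale)
    scores.to_csv(out / "scores.tsv", sep="\t", index=False)
    files.append(out / "scores.tsv")

    @_stage("aggregation_mass")
    def _masses():
        plate = read_plate_csv(cfg.plate_csv)
        wmap = read_well_map(cfg.well_map)
        groups = group_traces(traces_from_plate(plate, wmap))
        control = groups.pop((None, None), None)
        if control is None:
            raise LoopchapError("no substrate-alone control wells in well map")
        rows = []
        for (chap, ratio), traces in sorted(groups.items(), key=lambda kv: str(kv[0])):
            r = aggregation_mass(traces, control, cfg.baseline_points)
            rows.append({"variant_id": chap, "ratio": ratio,
                         "mass_pct": r.mass_pct, "sd_pct": r.sd_pct,
                         "n_replicates": r.n_replicates})
        return pd.DataFrame(rows)

    masses = _masses()
    masses.to_csv(out / "masses.tsv", sep="\t", index=False)
    files.append(out / "masses.tsv")

    model = _stage("fit_regression")(fit_activity_regression)(
        scores, masses, ratio=cfg.ratio
    )
    (out / "model.json").write_text(
        json.dumps(dataclasses.asdict(model), indent=2)
    )
    files.append(out / "model.json")

    @_stage("predict")
    def _predictions():
        rows = []
        for row in scores.itertuples():
            pred = predict_activity(model, row.combined, level=cfg.ci_level)
            rows.append({"variant_id": row.variant_id, "combined": row.combined,
                         "predicted_pct": pred.predicted_pct,
                         "ci_low": pred.ci_low, "ci_high": pred.ci_high})
        return pd.DataFrame(rows)

    preds = _predictions()
    preds.to_csv(out / "predictions.tsv", sep="\t", index=False)
    files.append(out / "predictions.tsv")

    manifest = _write_manifest(out, cfg, files)
    return {"scores": scores, "masses": masses, "model": model,
            "predictions": preds, "manifest": manifest}


def run_amyloid(cfg: RunConfig) -> dict:
    """Sigmoid fits, half-time delays and ranked constrained global fits."""
    _require(cfg, "plate_csv", "well_map")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    @_stage("normalize_tht")
    def _panel():
        plate = read_plate_csv(cfg.plate_csv)
        wmap = read_well_map(cfg.well_map)
        groups = group_traces(traces_from_plate(plate, wmap))
        panel = {}
        for (chap, ratio), traces in groups.items():
            key = 0.0 if ratio is None else float(ratio)
            panel[key] = (normalize_tht(traces), traces)
        if 0.0 not in panel:
            raise LoopchapError("ThT panel must include the 0% (control) ratio")
        return panel

    panel = _panel()

    @_stage("fit_sigmoids")
    def _fits():
        return {r: fit_sigmoid((nt.times, nt.signal))
                for r, (nt, _) in panel.items()}

    fits = _fits()
    delays = _stage("halftime_delay")(halftime_delay)(fits)
    fit_rows = pd.DataFrame(
        [{"ratio_pct": r, "f0": f.f0, "amplitude": f.amplitude,
          "r_max": f.r_max, "tau_half_s": f.tau_half, "r_squared": f.r_squared}
         for r, f in sorted(fits.items())]
    )
    fit_rows.to_csv(out / "sigmoid_fits.tsv", sep="\t", index=False)
    delays.to_csv(out / "halftime_delays.tsv", sep="\t", index=False)
    files += [out / "sigmoid_fits.tsv", out / "halftime_delays.tsv"]

    @_stage("global_fit")
    def _ranked():
        curves = {r: nt for r, (nt, _) in panel.items()}
        return rank_global_fits(curves, m0=cfg.m0, n_c=cfg.n_c, n_2=cfg.n_2,
                                n_starts=cfg.n_starts, seed=cfg.seed)

    ranked = _ranked()
    ranked_out = [
        {"rank": i + 1, "free_constant": f.free_constant,
         "residual_sum_squares": f.residual_sum_squares,
         "lambda0_per_s": f.lam0, "kappa0_per_s": f.kappa0,
         "kplus_kn": f.kplus_kn, "kplus_k2": f.kplus_k2,
         "factors": {str(k): v for k, v in sorted(f.factors.items())}}
        for i, f in enumerate(ranked)
    ]
    (out / "global_fits.json").write_text(json.dumps(ranked_out, indent=2))
    files.append(out / "global_fits.json")

    manifest = _write_manifest(out, cfg, files)
    return {"sigmoid_fits": fits, "halftime_delays": delays,
            "global_fits": ranked, "manifest": manifest}
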