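"""Workflow orchestration: simulate -> preprocess -> screen -> calibrate ->
predict -> flag -> report.

Every stage reads its inputs from and writes its artifacts to one output
directory, appending a log entry (parameters, derived seed, config digest)
to ``pipeline_log.json``.  All randomness flows from a single global seed
through named per-stage substreams, so a rerun with the same configuration
is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import composition as comp_mod
from .composition import MAJOR_SUGARS, load_composition
from .pls import CVConfig, CalibrationReport, DEFAULT_COMPONENTS, PLSModel, fit_sugar_models, predict_pls
from .preprocess import PreprocessConfig, area_normalize, baseline_correct, crop, smooth
from .screen import MahalanobisScreenReport, ScreenConfig, screen_batch
from .spectra import SpectraSet, base_id, load_spectra, save_spectra
from .synthsim import SimConfig, simulate_population

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

STAGES = ("simulate", "preprocess", "screen", "calibrate", "predict", "flag", "report")


@dataclass
class PipelineConfig:
    """Flat configuration with one section per stage; absent keys default."""

    seed: int = 0
    outdir: str = "nirscreen_out"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    components_map: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_COMPONENTS))
    k_sigma: float = 4.0
    min_calibration: int = 60
    sim: SimConfig = field(default_factory=SimConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        for key in ("seed", "outdir", "k_sigma", "min_calibration", "components_map"):
            if key in raw:
                kwargs[key] = raw[key]
        if "preprocess" in raw:
            kwargs["preprocess"] = PreprocessConfig(**raw["preprocess"])
        if "screen" in raw:
            kwargs["screen"] = ScreenConfig(**raw["screen"])
        if "cv" in raw:
            kwargs["cv"] = CVConfig(**raw["cv"])
        if "sim" in raw:
            sim = dict(raw["sim"])
            for k in ("baseline_offset_range", "baseline_slope_range"):
                if k in sim:
                    sim[k] = tuple(sim[k])
            kwargs["sim"] = SimConfig(**sim)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        return d

    def digest(self) -> str:
        payload = self.to_dict()
        payload.pop("outdir", None)  # digest reflects content, not location
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _stage_seed(seed: int, stage: str) -> int:
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([seed, idx]).generate_state(1)[0] % 2**31)


def _log_stage(outdir: Path, entry: dict) -> None:
    log_path = outdir / "pipeline_log.json"
    entries = []
    if log_path.exists():
        entries = json.loads(log_path.read_text())
    entries.append(entry)
    log_path.write_text(json.dumps(entries, indent=1, sort_keys=True))


def _require(outdir: Path, filename: str, needed_by: str, produced_by: str) -> Path:
    path = outdir / filename
    if not path.exists():
        raise FileNotFoundError(
            f"stage {needed_by!r} needs {filename}, produced by stage {produced_by!r}; "
            f"run that stage first"
        )
    return path


def _preprocess_for_regression(sset: SpectraSet, cfg: PreprocessConfig) -> SpectraSet:
    """crop/smooth/baseline/area-normalize without mean centering.

    PLS models center spectra internally against their own training mean,
    so the population-level centering step is not applied here.
    """
    out = crop(sset, cfg.crop_lo, cfg.crop_hi)
    out = smooth(out, cfg.smooth_window, cfg.smooth_polyorder)
    out = baseline_correct(out, cfg.baseline_method)
    return area_normalize(out)


def run_pipeline(
    config: PipelineConfig | str | Path,
    stages: list[str] | None = None,
    resume: bool = False,
) -> dict:
    """Run the requested stages in canonical order; return artifact paths.

    With ``resume=True`` a stage whose artifact already exists is skipped.
    """
    cfg = PipelineConfig.from_yaml(config) if not isinstance(config, PipelineConfig) else config
    requested = list(stages) if stages else list(STAGES)
    unknown = [s for s in requested if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages {unknown}; expected among {STAGES}")
    ordered = [s for s in STAGES if s in requested]

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    digest = cfg.digest()
    artifacts: dict[str, Path] = {}

    for stage in ordered:
        runner = _RUNNERS[stage]
        marker = outdir / _MARKERS[stage]
        if resume and marker.exists():
            artifacts[stage] = marker
            continue
        runner(cfg, outdir)
        artifacts[stage] = marker
        _log_stage(
            outdir,
            {
                "stage": stage,
                "seed": _stage_seed(cfg.seed, stage),
                "config_digest": digest,
            },
        )
    return artifacts


# ---------------------------------------------------------------------
# stage runners
# ---------------------------------------------------------------------

def _run_simulate(cfg: PipelineConfig, outdir: Path) -> None:
    sim_cfg = dataclasses.replace(cfg.sim, seed=_stage_seed(cfg.seed, "simulate"))
    sset, comp, truth = simulate_population(sim_cfg)
    save_spectra(sset, outdir / "spectra.csv")
    comp.to_csv(outdir / "composition.csv", float_format="%.17g")
    truth.to_json(outdir / "truth.json")


def _load_population(outdir: Path, needed_by: str) -> SpectraSet:
    path = _require(outdir, "spectra.csv", needed_by, "simulate")
    return load_spectra(path, meta_path=outdir / "spectra.meta.csv")


def _run_preprocess(cfg: PipelineConfig, outdir: Path) -> None:
    sset = _load_population(outdir, "preprocess")
    processed = _preprocess_for_regression(sset, cfg.preprocess)
    save_spectra(processed, outdir / "preprocessed.csv")


def _run_screen(cfg: PipelineConfig, outdir: Path) -> None:
    sset = _load_population(outdir, "screen")
    seed = _stage_seed(cfg.seed, "screen")
    consensus_all: dict[str, list] = {}
    for i, batch_id in enumerate(sset.batch_ids):
        scfg = dataclasses.replace(cfg.screen, seed=seed + i)
        report = screen_batch(sset, batch_id, scfg, cfg.preprocess)
        report.save(outdir / f"screen_{batch_id}.json")
        consensus_all[batch_id] = [list(t) for t in report.consensus]
    (outdir / "screen_consensus.json").write_text(
        json.dumps(consensus_all, indent=1, sort_keys=True)
    )


def _consensus_ids(outdir: Path, needed_by: str) -> list[str]:
    path = _require(outdir, "screen_consensus.json", needed_by, "screen")
    data = json.loads(path.read_text())
    return sorted({sid for pairs in data.values() for sid, _ in pairs})


def _run_calibrate(cfg: PipelineConfig, outdir: Path) -> None:
    processed = load_spectra(
        _require(outdir, "preprocessed.csv", "calibrate", "preprocess"),
        meta_path=outdir / "preprocessed.meta.csv",
    )
    comp = load_composition(_require(outdir, "composition.csv", "calibrate", "simulate"))
    outliers = _consensus_ids(outdir, "calibrate")
    refs = sorted(
        sid
        for sid, role in zip(processed.sample_ids, processed.meta["role"])
        if role == "reference" and base_id(sid) == sid
    )
    cal_ids = sorted(set(outliers) | set(refs))
    primaries = sorted(s for s in processed.sample_ids if base_id(s) == s)
    # top up with arbitrarily chosen leaves when the screen yields too few
    want = min(cfg.min_calibration, len(primaries))
    if len(cal_ids) < want:
        rng = np.random.default_rng(_stage_seed(cfg.seed, "calibrate"))
        pool = [s for s in primaries if s not in set(cal_ids)]
        extra = rng.choice(len(pool), size=want - len(cal_ids), replace=False)
        cal_ids = sorted(set(cal_ids) | {pool[i] for i in extra})
    cal_ids = [s for s in cal_ids if s in comp.index]

    cal_set = processed.select(cal_ids)
    cvc = CVConfig(K=cfg.cv.K, seed=_stage_seed(cfg.seed, "calibrate"))
    models, report = fit_sugar_models(
        cal_set.absorbance, comp, cfg.components_map, cv=cvc, sample_ids=cal_ids
    )
    payload = {
        "calibration_ids": cal_ids,
        "models": {s: m.to_dict() for s, m in models.items()},
    }
    (outdir / "pls_models.json").write_text(json.dumps(payload, sort_keys=True))
    report.save(outdir / "calibration_report.json")


def _run_predict(cfg: PipelineConfig, outdir: Path) -> None:
    processed = load_spectra(
        _require(outdir, "preprocessed.csv", "predict", "preprocess"),
        meta_path=outdir / "preprocessed.meta.csv",
    )
    payload = json.loads(_require(outdir, "pls_models.json", "predict", "calibrate").read_text())
    models = {s: PLSModel.from_dict(d) for s, d in payload["models"].items()}
    primaries = [s for s in processed.sample_ids if base_id(s) == s]
    sub = processed.select(primaries)
    out = pd.DataFrame(index=pd.Index(primaries, name="sample_id"))
    out["batch_id"] = sub.meta["batch_id"].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for sugar, model in sorted(models.items()):
            out[sugar] = predict_pls(model, sub.absorbance)
    out.to_csv(outdir / "predictions.csv", float_format="%.17g")


def _run_flag(cfg: PipelineConfig, outdir: Path) -> None:
    pred = pd.read_csv(
        _require(outdir, "predictions.csv", "flag", "predict"), dtype={"sample_id": str}
    ).set_index("sample_id")
    comp = load_composition(_require(outdir, "composition.csv", "flag", "simulate"))
    sset = _load_population(outdir, "flag")
    refs = [
        sid
        for sid, role in zip(sset.sample_ids, sset.meta["role"])
        if role == "reference" and base_id(sid) == sid
    ]
    batch_of = dict(zip(sset.meta["sample_id"].map(base_id), sset.meta["batch_id"]))
    var = comp_mod.reference_variability(comp, refs, grouping=batch_of)
    thresholds = comp_mod.thresholds_from_sigma(var, k=cfg.k_sigma)

    sugars = [s for s in MAJOR_SUGARS if s in pred.columns]
    baselines = pred.groupby("batch_id")[sugars].mean()
    diffs = comp_mod.percent_differences(pred[sugars], baselines, batch_of=batch_of)
    report = comp_mod.flag_sugar_outliers(diffs, thresholds, sugars)
    report.summary["reference_variability"] = {
        "mu": var.mu,
        "sigma": var.sigma,
        "n_references": var.n_references,
    }
    report.save(outdir / "outliers.tsv")


def _run_report(cfg: PipelineConfig, outdir: Path) -> None:
    screen_ids = _consensus_ids(outdir, "report")
    summary_path = _require(outdir, "outliers.summary.json", "report", "flag")
    flagged = json.loads(summary_path.read_text())["flagged"]
    combined = comp_mod.combine_outlier_sets(screen_ids, flagged)
    (outdir / "report.json").write_text(
        json.dumps(
            {
                "mahalanobis_consensus": sorted(screen_ids),
                "model_flagged": sorted(flagged),
                "combined": combined,
            },
            indent=1,
            sort_keys=True,
        )
    )


_RUNNERS = {
    "simulate": _run_simulate,
    "preprocess": _run_preprocess,
    "screen": _run_screen,
    "calibrate": _run_calibrate,
    "predict": _run_predict,
    "flag": _run_flag,
    "report": _run_report,
}

_MARKERS = {
    "simulate": "spectra.csv",
    "preprocess": "preprocessed.csv",
    "screen": "screen_consensus.json",
    "calibrate": "calibration_report.json",
    "predict": "predictions.csv",
    "flag": "outliers.tsv",
    "report": "report.json",
}
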