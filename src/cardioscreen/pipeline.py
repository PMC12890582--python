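"""End-to-end orchestration: simulate -> allocate -> pretrain -> fine-tune ->
predict -> evaluate, reproducible from one config and one seed."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .allocation import AllocationConfig, allocate_cohort
from .cohort import PatientRecord
from .detector import ModelConfig, VHDDetector, cross_validate, precompute_features
from .evaluation import EvalReport, evaluate_predictions, plot_reliability
from .io import (
    simconfig_from_dict,
    simconfig_to_dict,
    write_manifest,
    write_predictions,
    write_report,
)
from .preprocess import PreprocConfig
from .simulate import SimConfig, simulate_cohort

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger("cardioscreen")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


@dataclass
class RunConfig:
    """One reproducible run: all stage configs plus a global seed.

    The global seed deterministically reseeds every stage (simulation,
    allocation, model training, bootstrap evaluation), so two runs with an
    identical RunConfig produce byte-identical artefacts.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    allocation_ratio: tuple[float, float] = (79.0, 21.0)
    p_deterministic: float = 0.8
    pretrain: bool = True
    cv_folds: int = 0  # >= 2 enables out-of-fold training predictions
    spec_target: float = 0.82
    n_boot: int = 1000
    write_audio: bool = False
    seed: int = 0

    def stage_seeds(self) -> dict[str, int]:
        ss = np.random.SeedSequence(self.seed)
        names = ["sim", "alloc", "model", "eval", "cv"]
        return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, ss.spawn(len(names)))}

    def resolved(self) -> "RunConfig":
        s = self.stage_seeds()
        return replace(
            self,
            sim=replace(self.sim, seed=s["sim"]),
            model=replace(self.model, seed=s["model"]),
        )

    # -- YAML round trip ---------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        d = {
            "sim": simconfig_to_dict(self.sim),
            "preproc": {k: getattr(self.preproc, k) for k in vars(self.preproc)},
            "model": {k: getattr(self.model, k) for k in vars(self.model)},
            "allocation_ratio": list(self.allocation_ratio),
            "p_deterministic": self.p_deterministic,
            "pretrain": self.pretrain,
            "cv_folds": self.cv_folds,
            "spec_target": self.spec_target,
            "n_boot": self.n_boot,
            "write_audio": self.write_audio,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        if "sim" in d:
            kwargs["sim"] = simconfig_from_dict(d["sim"])
        if "preproc" in d:
            kwargs["preproc"] = PreprocConfig(**d["preproc"])
        if "model" in d:
            kwargs["model"] = ModelConfig(**d["model"])
        for k in ("p_deterministic", "pretrain", "cv_folds", "spec_target",
                  "n_boot", "write_audio", "seed"):
            if k in d:
                kwargs[k] = d[k]
        if "allocation_ratio" in d:
            kwargs["allocation_ratio"] = tuple(d["allocation_ratio"])
        return RunConfig(**kwargs)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.time()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
            log.info("stage %-10s done in %.1f s", name, time.time() - t0)
            return out
        return wrapped
    return deco


def run_pipeline(cfg: RunConfig, outdir: str | Path,
                 cohort: list[PatientRecord] | None = None
                 ) -> tuple[EvalReport, dict[str, Path]]:
    """Run the full pipeline and write all artefacts under ``outdir``.

    Returns the test-set evaluation report and the artefact paths.  Test-set
    patients are never seen by training or cross-validation (audited before
    the report is written).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rcfg = cfg.resolved()
    seeds = cfg.stage_seeds()
    paths: dict[str, Path] = {}

    cohort = _stage("simulate")(lambda: cohort if cohort is not None
                                else simulate_cohort(rcfg.sim))()
    paths["manifest"] = outdir / "manifest.csv"
    write_manifest(cohort, paths["manifest"],
                   audio_dir=outdir / "audio" if cfg.write_audio else None)

    alloc_cfg = AllocationConfig(target_ratio=rcfg.allocation_ratio,
                                 p_deterministic=rcfg.p_deterministic,
                                 seed=seeds["alloc"])
    split = _stage("allocate")(allocate_cohort)(cohort, {}, alloc_cfg)
    paths["split"] = outdir / "split.csv"
    import pandas as pd
    pd.DataFrame(sorted(split.items()), columns=["id", "group"]).to_csv(paths["split"], index=False)

    train = [p for p in cohort if split[p.id] == "train"]
    test = [p for p in cohort if split[p.id] == "test"]
    if not train or not test:
        raise PipelineError("stage 'allocate' failed: degenerate split")

    feats_train = _stage("features")(precompute_features)(train, rcfg.preproc)
    det = VHDDetector(train, rcfg.model, rcfg.preproc, features=feats_train)
    res = _stage("train")(det.fit)(pretrain=rcfg.pretrain)
    paths["models"] = outdir / "models"
    res.save(paths["models"])

    oof = None
    if rcfg.cv_folds >= 2:
        cv = _stage("cross_validate")(cross_validate)(
            train, [(replace(rcfg.model, seed=seeds["cv"]), rcfg.preproc)],
            k=rcfg.cv_folds, seed=seeds["cv"], pretrain=False)
        oof = cv["oof_probs"]
        oof_df = pd.DataFrame(
            [{"id": pid, "prob_fused": prob,
              "label": int(next(p for p in train if p.id == pid).significant)}
             for pid, prob in sorted(oof.items())])
        paths["train_oof_predictions"] = outdir / "train_oof_predictions.csv"
        oof_df.to_csv(paths["train_oof_predictions"], index=False, float_format="%.10g")
        # leakage audit: CV folds only ever contain training patients
        train_ids = {p.id for p in train}
        assert set(oof) <= train_ids

    feats_test = _stage("features")(precompute_features)(test, rcfg.preproc)
    preds = _stage("predict")(res.predict)(test, features=feats_test)
    paths["predictions"] = outdir / "test_predictions.csv"
    write_predictions(preds, paths["predictions"])

    test_ids = {p.id for p in test}
    train_ids = {p.id for p in train}
    if test_ids & train_ids:
        raise PipelineError("stage 'audit' failed: train/test overlap")

    report = _stage("evaluate")(evaluate_predictions)(
        preds["prob_fused"].to_numpy(), preds["label"].to_numpy(),
        spec_target=rcfg.spec_target, n_boot=rcfg.n_boot, seed=seeds["eval"])
    paths["report"] = outdir / "report.json"
    payload = report.to_dict()
    payload["config_seed"] = cfg.seed
    payload["stage_seeds"] = seeds
    payload["n_train"] = len(train)
    payload["n_test"] = len(test)
    if oof is not None:
        from .evaluation import auroc
        labels_tr = {p.id: int(p.significant) for p in train}
        payload["train_oof_auroc"] = auroc(
            np.array([oof[i] for i in sorted(oof)]),
            np.array([labels_tr[i] for i in sorted(oof)]))
    write_report(payload, paths["report"])
    paths["config"] = outdir / "config.yaml"
    cfg.to_yaml(paths["config"])
    paths["reliability_plot"] = outdir / "reliability.png"
    plot_reliability(report.reliability_bins, str(paths["reliability_plot"]))
    return report, paths
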