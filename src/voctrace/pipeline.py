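"""End-to-end orchestration of the traceability study on synthetic data.

Stage order mirrors the analytical workflow: generate (or ingest) the VOC
table and spectra, quantify against the internal standard, screen
differential flavor markers, preprocess spectra, fit the OPLS-DA
discriminant model with permutation validation, run the SVM search
factorial, optionally build per-sample 2DCOS images and train the residual
CNN, and finally calibrate PLSR models for the screened markers.  Every
stage writes plain CSV/JSON into the run directory and is recorded, with a
content hash, in ``manifest.json``; one global seed fans out
deterministically to the per-stage seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chemometrics, gcms, plsr, prep, splitters, svm_opt, synthetic, twodcos
from .containers import SpectrumSet, VocTable

log = logging.getLogger("voctrace")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str = "voctrace_run"
    seed: int = 0
    n_per_class: tuple[int, int, int] = (20, 15, 15)
    grid_step: float = 2.0
    preprocessing: str = "1stDer"
    classify_ratios: tuple[float, float] = (7, 3)
    quant_ratios: tuple[float, float] = (2, 1)
    n_permutations: int = 200
    svm_strategies: tuple[str, ...] = ("GS", "GA", "GWO")
    svm_space_overrides: dict | None = None
    run_cnn: bool = False
    cnn_image_size: int = 128
    cnn_epochs: int = 30
    stages: tuple[str, ...] = (
        "simulate",
        "quantify",
        "screen",
        "prep",
        "opls",
        "svm",
        "plsr",
    )

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(cfg: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(cfg), "stages": {}, "outputs": {}}
    state: dict = {}

    def record(stage: str, t0: float, files: list[Path]) -> None:
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 2)}
        for f in files:
            manifest["outputs"][f.name] = _sha256(f)

    for stage in cfg.stages:
        t0 = time.time()
        log.info("stage %s ...", stage)
        try:
            files = _STAGES[stage](cfg, out, state)
        except Exception:
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            log.exception("stage %s failed; partial outputs kept in %s", stage, out)
            raise
        record(stage, t0, files)

    if cfg.run_cnn and "cnn" not in cfg.stages:
        t0 = time.time()
        files = _stage_cnn(cfg, out, state)
        record("cnn", t0, files)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: RunConfig, out: Path, state: dict) -> list[Path]:
    scfg = synthetic.SyntheticConfig(
        n_per_class=cfg.n_per_class,
        wavenumber_grid=synthetic.default_grid(cfg.grid_step),
        seed=cfg.stage_seed("simulate"),
    )
    voc = synthetic.make_voc_table(scfg)
    spectra = synthetic.make_spectra(scfg, voc)
    voc.to_csv(out / "voc_table.csv")
    spectra.to_csv(out / "spectra.csv")
    state.update(scfg=scfg, voc=voc, spectra=spectra)
    return [out / "voc_table.csv", out / "spectra.csv"]


def _stage_quantify(cfg: RunConfig, out: Path, state: dict) -> list[Path]:
    scfg = state["scfg"]
    istd = gcms.InternalStandard(
        v_s=scfg.istd_volume_ul,
        c_s=scfg.istd_conc_ug_ml,
        mass_g=scfg.sample_mass_g,
        i_s=scfg.istd_area,
    )
    conc = gcms.quantify(state["voc"], istd)
    conc.to_csv(out / "concentrations.csv")
    state["conc"] = conc
    return [out / "concentrations.csv"]


def _stage_screen(cfg: RunConfig, out: Path, state: dict) -> list[Path]:
    conc: VocTable = state["conc"]
    X = conc.pivot("conc")
    y = conc.origins.loc[X.index].to_numpy()
    model, metrics = chemometrics.oplsda(X, y, scale="uv")
    vip = chemometrics.vip(model)
    screen = gcms.screen_markers(conc, vip)
    screen.table.to_csv(out / "marker_screen.csv", index=False)
    state["screen"] = screen
    state["voc_opls_metrics"] = metrics
    return [out / "marker_screen.csv"]


def _stage_prep(cfg: RunConfig, out: Path, state: dict) -> list[Path]:
    averaged = prep.average_replicates(state["spectra"])
    processed = prep.preprocess(averaged, cfg.preprocessing)
    processed.to_csv(out / "spectra_preprocessed.csv")
    state["processed"] = processed
    return [out / "spectra_preprocessed.csv"]


def _stage_opls(cfg: RunConfig, out: Path, state: dict) -> list[Path]:
    sp: SpectrumSet = state["processed"]
    X = sp.absorbance
    y = sp.sample_labels()
    sp_split = splitters.split(X, cfg.classify_ratios)
    train, test = sp_split.subsets
    model, metrics = chemometrics.oplsda(X[train], y[train])
    vip = chemometrics.vip(model)
    perm = chemometrics.permutation_test(
        X[train],
        y[train],
        n_ortho=metrics.n_ortho,
        n_perm=cfg.n_permutations,
        seed=cfg.stage_seed("opls"),
    )
    test_metrics = chemometrics.class_metrics(y[test], model.predict(X[test]))
    summary = {
        "R2X": metrics.r2x,
        "R2Y": metrics.r2y,
        "Q2": metrics.q2,
        "RMSE_CV": metrics.rmse_cv,
        "n_ortho": metrics.n_ortho,
        "permutation_valid": bool(perm.valid),
        "q2_intercept": perm.q2_intercept,
        "r2_intercept": perm.r2_intercept,
        "test_ACC": test_metrics.accuracy,
        "test_F1": test_metrics.f1,
    }
    (out / "oplsda.json").write_text(json.dumps(summary, indent=2))
    state.update(split=sp_split, spec_vip=vip, opls_metrics=metrics)
    return [out / "oplsda.json"]


def _stage_svm(cfg: RunConfig, out: Path, state: dict) -> list[Path]:
    sp: SpectrumSet = state["processed"]
    X = sp.absorbance
    y = sp.sample_labels()
    train, test = state["split"].subsets
    table = svm_opt.run_svm_pipeline(
        X[train],
        y[train],
        X[test],
        y[test],
        vip_scores=np.asarray(state["spec_vip"]),
        strategies=cfg.svm_strategies,
        seed=cfg.stage_seed("svm"),
        space_overrides=cfg.svm_space_overrides,
    )
    table.to_csv(out / "svm_results.csv", index=False)
    state["svm_table"] = table
    return [out / "svm_results.csv"]


def _stage_cnn(cfg: RunConfig, out: Path, state: dict) -> list[Path]:
    from . import resnet

    sp: SpectrumSet = state["spectra"]
    images = twodcos.per_sample_sync_images(
        sp, size=cfg.cnn_image_size, out_dir=out / "images"
    )
    ids = list(images)
    x = resnet.images_to_tensor([images[s] for s in ids])
    y = np.array([sp.origins[s] for s in ids])
    flat = x.reshape(x.shape[0], -1)
    tr, te, va = splitters.split(flat, (7, 2, 1)).subsets
    rcfg = resnet.ResNetConfig(
        input_size=cfg.cnn_image_size,
        max_epochs=cfg.cnn_epochs,
        seed=cfg.stage_seed("cnn"),
    )
    model = resnet.build_model(rcfg)
    report = resnet.train(model, x[tr], y[tr], x[te], y[te])
    report.external = resnet.evaluate_external(model, x[va], y[va], report.classes)
    report.history.to_csv(out / "cnn_history.csv", index=False)
    summary = {
        "n_params": report.meta["n_params"],
        "final_train_acc": report.history["train_acc"].iloc[-1],
        "final_test_acc": report.history["test_acc"].iloc[-1],
        "external_ACC": report.external.accuracy,
        "external_F1": report.external.f1,
    }
    (out / "cnn.json").write_text(json.dumps(summary, indent=2))
    return [out / "cnn_history.csv", out / "cnn.json"]


def _stage_plsr(cfg: RunConfig, out: Path, state: dict) -> list[Path]:
    targets = state["screen"].flagged or state["conc"].compounds[:2]
    table = plsr.quant_pipeline(
        state["spectra"],
        state["conc"],
        targets=targets[:2],
        methods=("raw", "1stDer", "SNV"),
        ratios=cfg.quant_ratios,
    )
    table.to_csv(out / "plsr_results.csv", index=False)
    state["plsr_table"] = table
    return [out / "plsr_results.csv"]


_STAGES = {
    "simulate": _stage_simulate,
    "quantify": _stage_quantify,
    "screen": _stage_screen,
    "prep": _stage_prep,
    "opls": _stage_opls,
    "svm": _stage_svm,
    "cnn": _stage_cnn,
    "plsr": _stage_plsr,
}
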