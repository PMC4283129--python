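"""End-to-end pipeline: simulate -> QC -> average -> derivative -> EMSC ->
markers / PCA / PLSR calibration, driven by one YAML config.

Each stage writes its artifacts into the run directory so every step is
independently inspectable, and a JSON manifest records the seed, per-stage
record counts, file checksums and timings.  Re-running an identical config
reproduces identical outputs.
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
import yaml

from . import __version__
from .chemometrics import (FATTY_ACID_REGION, calibrate, pca_region,
                           save_calibration)
from .markers import MarkerSettings, marker_table
from .preprocess import (EMSCSettings, SavGolSettings,
                         average_technical_replicates, emsc,
                         savgol_second_derivative)
from .qc import QualityThresholds, filter_set
from .spectra import default_grid, read_spectra, write_spectra
from .synthesis import StudyDesign, generate_study

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """Everything one reproducible run needs.

    Field groups mirror the pipeline stages; nested settings are plain
    dicts in YAML and are materialized into their dataclasses on use.
    """

    seed: int = 0
    spectra_path: str | None = None     # None -> simulate
    reference_path: str | None = None
    design: dict = field(default_factory=dict)
    grid: dict = field(default_factory=lambda: {
        "high": 4000.0, "low": 500.0, "spacing": 2.0})
    gc_noise_sd: float = 1.0
    gc_run_bias: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    savgol: dict = field(default_factory=dict)
    emsc: dict = field(default_factory=lambda: {"region": [3050.0, 700.0],
                                                "polynomial_order": 2})
    markers: dict = field(default_factory=dict)
    pca: dict = field(default_factory=lambda: {
        "region": list(FATTY_ACID_REGION), "n_components": 2})
    calibration: dict = field(default_factory=lambda: {
        "targets": ["SAT", "MUFA", "PUFA"], "max_factors": 15,
        "cv": "loo", "rule": "margin", "margin": 0.02})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute all stages; returns the manifest (also written as JSON).

    Stage order: simulate (or load), quality test, technical-replicate
    averaging, Savitzky-Golay second derivative, EMSC, then markers
    (on EMSC-corrected absorbance spectra), PCA of the fatty-acid region
    and PLSR calibration (both on EMSC-corrected derivative spectra).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"ftirlip_version": __version__,
                      "seed": config.seed, "stages": {}}
    config.to_yaml(out / "config.yaml")

    def stage(name):
        class _Stage:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(f"stage {name}: {exc}") from exc
                manifest["stages"].setdefault(name, {})["seconds"] = round(
                    time.perf_counter() - self.t0, 3)
                return False
        return _Stage()

    # -- simulate / load ----------------------------------------------
    with stage("simulate"):
        if config.spectra_path is None:
            design = StudyDesign(seed=config.seed, **config.design)
            grid = default_grid(**config.grid)
            bias = {int(k): tuple(v)
                    for k, v in (config.gc_run_bias or {}).items()} or None
            study = generate_study(design, grid=grid,
                                   gc_noise_sd=config.gc_noise_sd,
                                   gc_run_bias=bias)
            spectra, reference = study.spectra, study.reference
            study.ground_truth.to_csv(out / "ground_truth.csv", index=False)
        else:
            spectra = read_spectra(config.spectra_path)
            if config.reference_path is None:
                raise ValueError("spectra_path given without reference_path")
            reference = pd.read_csv(config.reference_path)
        write_spectra(spectra, out / "spectra.tsv")
        reference.to_csv(out / "reference.csv", index=False)
        manifest["stages"]["simulate"] = {"n_spectra": len(spectra),
                                          "n_reference_rows": len(reference)}

    # -- quality test -------------------------------------------------
    with stage("qc"):
        thresholds = QualityThresholds(**config.qc)
        passing, report = filter_set(spectra, thresholds)
        report.to_csv(out / "qc_report.csv", index=False)
        if len(passing) == 0:
            raise ValueError(
                "no spectra passed the quality test (thresholds "
                f"{thresholds}); see qc_report.csv")
        manifest["stages"]["qc"] = {"n_in": len(spectra),
                                    "n_pass": len(passing)}

    # -- averaging ----------------------------------------------------
    with stage("average"):
        averaged = average_technical_replicates(passing)
        write_spectra(averaged, out / "averaged.tsv")
        manifest["stages"]["average"] = {"n_in": len(passing),
                                         "n_out": len(averaged)}

    # -- second derivative -------------------------------------------
    with stage("derivative"):
        sg = SavGolSettings(**config.savgol)
        deriv = savgol_second_derivative(averaged, sg)
        write_spectra(deriv, out / "derivative.tsv")
        manifest["stages"]["derivative"] = {"n_out": len(deriv)}

    # -- EMSC ---------------------------------------------------------
    with stage("emsc"):
        es = EMSCSettings(region=tuple(config.emsc.get("region",
                                                       (3050.0, 700.0))),
                          polynomial_order=config.emsc.get(
                              "polynomial_order", 2))
        emsc_deriv = emsc(deriv, es)
        write_spectra(emsc_deriv.corrected, out / "preprocessed.tsv")
        emsc_deriv.parameters.to_csv(out / "emsc_parameters.csv",
                                     index=False)
        # absorbance-domain EMSC feeds the univariate markers
        emsc_abs = emsc(averaged, EMSCSettings(
            region=es.region, polynomial_order=es.polynomial_order))
        manifest["stages"]["emsc"] = {"n_out": len(emsc_deriv.corrected)}

    # -- markers ------------------------------------------------------
    with stage("markers"):
        ms = MarkerSettings(**{k: tuple(v) if isinstance(v, list) else v
                               for k, v in config.markers.items()})
        markers = marker_table(emsc_abs.corrected, ms)
        markers.to_csv(out / "markers.csv", index=False)
        manifest["stages"]["markers"] = {"n_rows": len(markers)}

    # -- PCA ----------------------------------------------------------
    with stage("pca"):
        pca = pca_region(emsc_deriv.corrected,
                         region=tuple(config.pca.get(
                             "region", FATTY_ACID_REGION)),
                         n_components=config.pca.get("n_components", 2))
        scores = pca.scores_frame()
        scores = scores.merge(emsc_deriv.corrected.metadata,
                              left_on="sample_id", right_on="spectrum_id",
                              how="left", suffixes=("", "_meta"))
        scores.to_csv(out / "pca_scores.csv", index=False)
        manifest["stages"]["pca"] = {
            "explained_variance_ratio":
                [round(float(v), 6) for v in pca.explained_variance_ratio]}

    # -- calibration --------------------------------------------------
    with stage("calibrate"):
        cal = dict(config.calibration)
        provenance = {
            "n_variables": emsc_deriv.corrected.wavenumbers.size,
            "savgol": [sg.window_points, sg.poly_order, sg.deriv_order],
            "emsc_region": list(es.region),
            "emsc_polynomial_order": es.polynomial_order,
        }
        results, report = calibrate(
            emsc_deriv.corrected, reference,
            targets=tuple(cal.get("targets", ("SAT", "MUFA", "PUFA"))),
            max_factors=cal.get("max_factors", 15),
            cv=cal.get("cv", "loo"), rule=cal.get("rule", "margin"),
            margin=cal.get("margin", 0.02), provenance=provenance)
        report.to_csv(out / "calibration_report.csv", index=False)
        for target, res in results.items():
            save_calibration(res, out / f"model_{target}.json")
        manifest["stages"]["calibrate"] = {
            "report": report.to_dict(orient="records")}

    manifest["checksums"] = {p.name: _sha256(p)
                             for p in sorted(out.iterdir())
                             if p.is_file() and p.name != "manifest.json"}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
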