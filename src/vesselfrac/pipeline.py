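"""End-to-end orchestration: volume -> MIP -> mask -> skeleton -> D_f ->
cohort statistics, with config, logging and provenance.

The two-rater study design is emulated by running the segmentation stage
twice with two (possibly different) parameter sets declared in the
config; the two dimension estimates feed the rater average and the
inter-rater ICC without any manual editing step.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohortstats import compare_groups
from .fractal import BoxCountConfig, average_raters, estimate_df, fit_loglog, scan
from .io import read_volume, write_image, write_mask
from .projection import Volume3D, max_intensity_project
from .segmentation import (
    clean_mask,
    classify_pixels,
    skeletonize,
    threshold_isodata,
)

__all__ = ["PipelineConfig", "PipelineStageError", "run_subject", "run_cohort"]

log = logging.getLogger("vesselfrac")


class PipelineStageError(RuntimeError):
    """An error in a named pipeline stage for a named subject."""

    def __init__(self, stage: str, subject_id: str, cause: Exception):
        super().__init__(f"[{subject_id}] stage '{stage}' failed: {cause}")
        self.stage = stage
        self.subject_id = subject_id
        self.cause = cause


@dataclass
class RaterParams:
    """Segmentation parameters of one simulated rater."""

    method: str = "isodata"
    min_component_px: int = 50
    classifier_seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("isodata", "classifier"):
            raise ValueError(f"unknown segmentation method {self.method!r}")
        if self.min_component_px < 0:
            raise ValueError("min_component_px must be >= 0")


@dataclass
class PipelineConfig:
    """All protocol constants of a run, serializable to/from TOML."""

    axis: str = "axial"
    method: str = "isodata"
    min_component_px: int = 50
    n_grid: int = 12
    max_frac: float = 0.45
    eps_min: int = 2
    qc_threshold: float = 0.995
    seed: int = 0
    strict_qc: bool = True
    rater1: RaterParams | None = None
    rater2: RaterParams | None = None

    def __post_init__(self) -> None:
        if isinstance(self.rater1, dict):
            self.rater1 = RaterParams(**self.rater1)
        if isinstance(self.rater2, dict):
            self.rater2 = RaterParams(**self.rater2)
        if self.rater1 is None:
            self.rater1 = RaterParams(method=self.method,
                                      min_component_px=self.min_component_px)
        if self.rater2 is None:
            self.rater2 = RaterParams(method=self.method,
                                      min_component_px=self.min_component_px)
        if not (0 < self.max_frac < 1):
            raise ValueError("max_frac must be in (0, 1)")
        if self.n_grid < 1:
            raise ValueError("n_grid must be >= 1")
        if self.eps_min < 1:
            raise ValueError("eps_min must be >= 1")
        if not (0 < self.qc_threshold <= 1):
            raise ValueError("qc_threshold must be in (0, 1]")

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def boxcount(self) -> BoxCountConfig:
        return BoxCountConfig(n_grid=self.n_grid, max_frac=self.max_frac,
                              eps_min=self.eps_min,
                              qc_threshold=self.qc_threshold, seed=self.seed)


def _segment(mip, params: RaterParams, training_labels=None):
    if params.method == "isodata":
        mask = threshold_isodata(mip)
    else:
        if training_labels is None:
            raise ValueError("classifier method requires training labels")
        mask = classify_pixels(mip, training_labels, seed=params.classifier_seed)
    return clean_mask(mask, params.min_component_px)


def run_subject(
    volume,
    config: PipelineConfig | None = None,
    out_dir=None,
    subject_id: str = "subject",
    training_labels=None,
) -> dict:
    """Process one volume to a rater-averaged dimension estimate.

    Parameters
    ----------
    volume : path to a NIfTI file or Volume3D
    config : PipelineConfig
    out_dir : optional directory for intermediate artifacts (MIP, masks,
        skeletons, scan table, estimate JSON)
    subject_id : used in artifact names and error messages

    Returns a record with the averaged ``d_f``, both per-rater estimates,
    QC flags, the config hash, and artifact paths.
    """
    config = config or PipelineConfig()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    record: dict = {"subject_id": subject_id, "config_hash": config.config_hash,
                    "version": __version__, "artifacts": {}}

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:  # noqa: BLE001 - re-raised with context
            raise PipelineStageError(name, subject_id, exc) from exc

    if not isinstance(volume, Volume3D):
        volume = stage("load", read_volume, volume)
    mip = stage("projection", max_intensity_project, volume, config.axis)
    if out is not None:
        record["artifacts"]["mip"] = str(write_image(mip, out / f"{subject_id}_mip.tif"))

    estimates = {}
    for rater_name, params in (("rater1", config.rater1), ("rater2", config.rater2)):
        mask = stage(f"segmentation/{rater_name}", _segment, mip, params,
                     training_labels)
        skel = stage(f"skeletonize/{rater_name}", skeletonize, mask)
        sc = stage(f"boxcount/{rater_name}", scan, skel,
                   n_grid=config.n_grid, max_frac=config.max_frac,
                   eps_min=config.eps_min, seed=config.seed)
        est = stage(f"fit/{rater_name}", fit_loglog, sc, config.qc_threshold)
        estimates[rater_name] = (est, sc)
        if out is not None:
            record["artifacts"][f"mask_{rater_name}"] = str(
                write_mask(mask, out / f"{subject_id}_mask_{rater_name}.tif"))
            record["artifacts"][f"skel_{rater_name}"] = str(
                write_mask(skel, out / f"{subject_id}_skel_{rater_name}.tif"))

    e1, s1 = estimates["rater1"]
    e2, s2 = estimates["rater2"]
    record["rater1"] = e1.to_dict()
    record["rater2"] = e2.to_dict()
    record["qc_pass"] = bool(e1.qc_pass and e2.qc_pass)
    record["d_f"] = stage("average", average_raters, e1, e2,
                          strict=config.strict_qc)
    if out is not None:
        est_path = out / f"{subject_id}_estimate.json"
        # artifact paths stay out of the JSON so reruns in different
        # directories remain byte-identical
        payload = {k: v for k, v in record.items() if k != "artifacts"}
        payload["scan_rater1"] = s1.to_dict()
        payload["scan_rater2"] = s2.to_dict()
        est_path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        record["artifacts"]["estimate"] = str(est_path)
    return record


_COVARIATES = ("age", "sex", "bmi", "sbp", "tchdl", "qrisk2")


def run_cohort(
    manifest,
    config: PipelineConfig | None = None,
    out_dir=None,
    strict: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Process a cohort manifest and run the group statistics.

    The manifest (CSV path or DataFrame) needs ``subject_id`` and
    ``group`` columns plus either a ``volume`` column of readable NIfTI
    paths or precomputed ``df_rater1``/``df_rater2`` columns; covariate
    columns (age, sex, bmi, sbp, tchdl, qrisk2) are carried through.

    In batch mode (default) per-subject failures are logged and the
    subject is dropped; with ``strict=True`` the first failure aborts.

    Returns the cohort table and the statistics report (which embeds the
    config hash, package version and per-subject QC).
    """
    config = config or PipelineConfig()
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)
    if "subject_id" not in manifest.columns or "group" not in manifest.columns:
        raise ValueError("manifest needs 'subject_id' and 'group' columns")
    if manifest["subject_id"].duplicated().any():
        dupes = manifest.loc[manifest["subject_id"].duplicated(), "subject_id"]
        raise ValueError(f"duplicated subject_id: {sorted(set(dupes))}")
    counts = manifest["group"].value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("need at least 2 subjects in each of two groups")

    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        fh = logging.FileHandler(out / "run.log")
        fh.setLevel(logging.INFO)
        log.addHandler(fh)

    have_precomputed = {"df_rater1", "df_rater2"}.issubset(manifest.columns)
    rows = []
    failures = []
    try:
        for _, mrow in manifest.iterrows():
            sid = str(mrow["subject_id"])
            row = {"subject_id": sid, "group": mrow["group"]}
            for cov in _COVARIATES:
                if cov in manifest.columns:
                    row[cov] = mrow[cov]
            if have_precomputed and not pd.isna(mrow.get("df_rater1")):
                row["df_rater1"] = float(mrow["df_rater1"])
                row["df_rater2"] = float(mrow["df_rater2"])
                row["qc_pass"] = True
            else:
                try:
                    rec = run_subject(mrow["volume"], config,
                                      out_dir=out, subject_id=sid)
                except PipelineStageError as exc:
                    log.error("%s", exc)
                    failures.append({"subject_id": sid, "stage": exc.stage,
                                     "error": str(exc.cause)})
                    if strict:
                        raise
                    continue
                row["df_rater1"] = rec["rater1"]["d_f"]
                row["df_rater2"] = rec["rater2"]["d_f"]
                row["qc_pass"] = rec["qc_pass"]
            row["df_mean"] = 0.5 * (row["df_rater1"] + row["df_rater2"])
            rows.append(row)
    finally:
        if out is not None:
            log.removeHandler(fh)
            fh.close()

    cohort = pd.DataFrame(rows)
    if cohort.empty or cohort["group"].nunique() < 2 or \
            cohort["group"].value_counts().min() < 2:
        raise ValueError("fewer than 2 usable subjects per group after processing")

    report = compare_groups(cohort)
    report["config_hash"] = config.config_hash
    report["version"] = __version__
    report["failures"] = failures
    report["subject_qc"] = {r["subject_id"]: bool(r.get("qc_pass", True))
                            for r in rows}
    if out is not None:
        cohort.to_csv(out / "cohort.csv", index=False)
        (out / "stats.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return cohort, report
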