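"""End-to-end orchestration of the analysis stages from one config.

A run starts from a declarative :class:`RunConfig` (YAML-serialisable,
thresholds defaulting to the study's analysis constants), executes the
enabled stages in dependency order -- simulate, behavior scoring, retinal
indices, fNIRS preprocessing + connectivity (optional), mixed models,
mediation -- and writes tidy CSV/JSON outputs plus a machine-readable
manifest (config hash, package version, per-stage row counts, QC logs).
Rerunning an identical config reproduces identical outputs; manifests
carry no timestamps for exactly that reason.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, granger
from .fnirs import (
    MbllParams,
    bandpass,
    channel_quality_check,
    default_montage,
    intensity_to_od,
    od_to_hemoglobin,
    pca_denoise,
    roi_average,
)
from .lmm import LmmSpec, check_assumptions, emmeans_contrasts, fit_lmm
from .mediation import fit_mediation
from .retina import indices_table
from .simulate import generate_study, load_profile, null_profile, paper_effects
from .stroop import summarize_trials, zscore_measures

__all__ = ["RunConfig", "PipelineError", "DependencyError", "run_pipeline"]

STAGES = ("simulate", "behavior", "retina", "fnirs", "lmm", "mediate")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


class DependencyError(PipelineError):
    """A stage was enabled without the stage(s) it consumes."""


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    profile: str = "paper_effects"  # packaged name or YAML path
    seed: int = 0
    n_subjects: int | None = None
    conditions: tuple[str, ...] = ("SIT", "MIC", "VIC")
    stages: tuple[str, ...] = ("simulate", "behavior", "retina", "lmm", "mediate")
    include_fnirs: bool = False
    fnirs_duration_s: float = 120.0
    # analysis constants (defaults = the modelled analysis settings)
    cv_threshold: float = 0.15
    fdr_q: float = 0.05
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    dpf: float = 6.0
    pca_components: int = 1
    max_var_order: int = 20
    n_boot: int = 10_000
    zscore_pool: str = "pre"
    outdir: str = "exercog_run"

    def __post_init__(self) -> None:
        self.conditions = tuple(self.conditions)
        self.stages = tuple(self.stages)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if "fnirs" in self.stages and not self.include_fnirs:
            raise DependencyError(
                "stage 'fnirs' is enabled but include_fnirs is false: "
                "no fNIRS inputs would exist"
            )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["conditions"] = list(self.conditions)
        d["stages"] = list(self.stages)
        return d

    @property
    def config_hash(self) -> str:
        canon = json.dumps(self.as_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _resolve_profile(config: RunConfig):
    if config.profile == "paper_effects":
        prof = paper_effects()
    elif config.profile == "null":
        prof = null_profile()
    else:
        prof = load_profile(config.profile)
    if config.n_subjects is not None:
        from dataclasses import replace

        prof = replace(prof, n_subjects=int(config.n_subjects))
    return prof


def _process_recording(rec, config: RunConfig):
    """QC -> OD -> MBLL -> band-pass -> PCA -> ROI averaging -> GCA."""
    qc = channel_quality_check(
        rec.intensity, rec.channel_names, rec.fs, threshold=config.cv_threshold
    )
    od = intensity_to_od(rec.intensity)
    mbll = MbllParams(dpf=config.dpf, distance_cm=rec.montage.distance_cm,
                      wavelengths_nm=rec.wavelengths_nm)
    hbo, hbr = od_to_hemoglobin(od, mbll)
    hbo = bandpass(hbo, rec.fs, config.band_low_hz, config.band_high_hz)
    hbo = pca_denoise(hbo, config.pca_components)
    roi = roi_average(
        {ch: hbo[i] for i, ch in enumerate(rec.channel_names)},
        rec.montage,
        retained=qc.retained,
        fs=rec.fs,
    )
    max_order = min(config.max_var_order,
                    (roi.data.shape[0] - 20) // (len(roi.rois) * 3))
    gc = granger.pairwise_conditional_gc(
        roi.data, max_order=max(1, max_order), fdr_q=config.fdr_q,
        check_stability=False,
    )
    return qc, roi, gc


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest (also on disk)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": config.as_dict(),
        "config_hash": config.config_hash,
        "stages": {},
    }
    stage = "simulate"
    try:
        profile = _resolve_profile(config)
        dataset = generate_study(
            profile,
            seed=config.seed,
            conditions=config.conditions,
            include_fnirs=config.include_fnirs,
            fnirs_duration_s=config.fnirs_duration_s,
        )
        dataset.covariates.to_csv(out / "covariates.csv", index=False)
        dataset.trials.to_csv(out / "trials.csv", index=False)
        dataset.vessel_widths.to_csv(out / "vessel_widths.csv", index=False)
        dataset.causal_density.to_csv(out / "causal_density.csv", index=False)
        manifest["stages"]["simulate"] = {
            **dataset.summary(),
            "implied_z_ies": dataset.calibration.implied_z_ies,
        }

        summaries = None
        if "behavior" in config.stages:
            stage = "behavior"
            summaries = zscore_measures(
                summarize_trials(dataset.trials), pool=config.zscore_pool
            )
            summaries.to_csv(out / "behavioral_summaries.csv", index=False)
            manifest["stages"]["behavior"] = {
                "n_cells": len(summaries),
                "n_dropped_cells": summaries.attrs.get("n_dropped_cells", 0),
                "pool": config.zscore_pool,
            }

        indices = None
        if "retina" in config.stages:
            stage = "retina"
            indices = indices_table(dataset.vessel_widths)
            indices.to_csv(out / "retinal_indices.csv", index=False)
            manifest["stages"]["retina"] = {
                "n_cells": len(indices),
                "n_flagged": int(indices["quality_flag"].sum()),
            }

        gca_rows = None
        if "fnirs" in config.stages:
            stage = "fnirs"
            if not dataset.fnirs:
                raise DependencyError("fnirs stage enabled but no recordings")
            edge_frames, density_rows, qc_log = [], [], {}
            for (subj, cond, tp), rec in dataset.fnirs.items():
                qc, roi, gc = _process_recording(rec, config)
                qc_log[f"{subj}/{cond}/{tp}"] = {
                    "excluded": qc.excluded,
                    "dropped_rois": roi.dropped_rois,
                }
                etab = granger.edges_table(gc)
                etab.insert(0, "subject", subj)
                etab.insert(1, "condition", cond)
                etab.insert(2, "timepoint", tp)
                edge_frames.append(etab)
                density_rows.append(
                    {
                        "subject": subj,
                        "condition": cond,
                        "timepoint": tp,
                        "state": "resting",
                        "cd_unweighted": gc.causal_density_unweighted,
                        "cd_weighted": gc.causal_density_weighted,
                        "var_order": gc.order,
                    }
                )
            pd.concat(edge_frames, ignore_index=True).to_csv(
                out / "gca_edges.csv", index=False
            )
            gca_rows = pd.DataFrame(density_rows)
            gca_rows.to_csv(out / "gca_density.csv", index=False)
            (out / "fnirs_qc.json").write_text(json.dumps(qc_log, indent=2))
            manifest["stages"]["fnirs"] = {
                "n_recordings": len(dataset.fnirs),
                "n_edges": sum(len(f) for f in edge_frames),
            }

        if "lmm" in config.stages:
            stage = "lmm"
            if summaries is None or indices is None:
                raise DependencyError(
                    "lmm stage needs the behavior and retina stages"
                )
            coef_frames, contrast_frames, diag_rows = [], [], []
            datasets = {}
            merged = summaries.merge(dataset.covariates, on="subject")
            for outcome in ("z_rt", "z_er", "z_ies"):
                datasets[outcome] = merged
            ret = indices.merge(dataset.covariates, on="subject")
            for outcome in ("crae", "crve", "avr"):
                datasets[outcome] = ret
            for state in ("resting", "task"):
                sub = dataset.causal_density.query("state == @state").merge(
                    dataset.covariates, on="subject"
                )
                datasets[f"cd_{state}"] = sub.rename(
                    columns={"causal_density": f"cd_{state}"}
                )
            for outcome, data in datasets.items():
                fit = fit_lmm(data, LmmSpec(outcome=outcome))
                coefs = fit.coef.reset_index(names="term")
                coefs.insert(0, "outcome", outcome)
                coef_frames.append(coefs)
                contrasts = emmeans_contrasts(fit, fdr_q=config.fdr_q)
                contrasts.insert(0, "outcome", outcome)
                contrast_frames.append(contrasts)
                diag_rows.append({"outcome": outcome, **check_assumptions(fit)})
            pd.concat(coef_frames, ignore_index=True).to_csv(
                out / "lmm_coefficients.csv", index=False
            )
            pd.concat(contrast_frames, ignore_index=True).to_csv(
                out / "lmm_contrasts.csv", index=False
            )
            pd.DataFrame(diag_rows).to_csv(out / "lmm_diagnostics.csv", index=False)
            manifest["stages"]["lmm"] = {"n_outcomes": len(datasets)}

        if "mediate" in config.stages:
            stage = "mediate"
            if summaries is None or indices is None:
                raise DependencyError(
                    "mediate stage needs the behavior and retina stages"
                )
            med_df = build_change_scores(
                indices, dataset.causal_density, summaries, dataset.covariates
            )
            med_df.to_csv(out / "mediation_inputs.csv", index=False)
            result = fit_mediation(
                med_df, n_boot=config.n_boot, seed=config.seed
            )
            (out / "mediation.json").write_text(
                json.dumps(result.to_dict(), indent=2)
            )
            manifest["stages"]["mediate"] = {
                "n": result.n,
                "indirect": result.indirect,
                "significant": result.significant,
            }
    except DependencyError:
        raise
    except Exception as exc:
        (out / "error.json").write_text(
            json.dumps({"stage": stage, "error": str(exc)}, indent=2)
        )
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def build_change_scores(
    indices: pd.DataFrame,
    causal_density: pd.DataFrame,
    summaries: pd.DataFrame,
    covariates: pd.DataFrame,
    exposure: str = "avr",
    mediator_state: str = "task",
    outcome: str = "z_rt",
    pooling: str = "pooled",
) -> pd.DataFrame:
    """Per-subject change-score triple (X, M, Y) for the mediation stage.

    Change = (post - pre) averaged across exercise conditions minus the
    sitting-control change (``pooling="pooled"``), or per condition with
    ``pooling="per_condition"`` (one row per subject x exercise condition).
    """

    def did(table: pd.DataFrame, col: str) -> pd.Series:
        wide = table.pivot_table(
            index=["subject", "condition"], columns="timepoint", values=col,
            aggfunc="mean",
        )
        change = (wide["post"] - wide["pre"]).unstack("condition")
        exercise = [c for c in change.columns if c != "SIT"]
        if not exercise or "SIT" not in change.columns:
            raise ValueError("change scores need SIT plus >= 1 exercise condition")
        if pooling == "pooled":
            return change[exercise].mean(axis=1) - change["SIT"]
        return change[exercise].sub(change["SIT"], axis=0).stack()

    x = did(indices, exposure)
    m = did(causal_density.query("state == @mediator_state"), "causal_density")
    y = did(summaries, outcome)
    df = pd.DataFrame({"x": x, "m": m, "y": y}).dropna().reset_index()
    return df.merge(covariates, on="subject")
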