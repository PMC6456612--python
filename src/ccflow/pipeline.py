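"""Reproducible simulate -> quantify -> analyze -> report pipeline.

Every stochastic draw flows from the single seed in :class:`RunConfig`;
running the same configuration twice produces byte-identical CSV/JSON
outputs and manifests.  Intermediates are plain TIFF/PNG/CSV/JSON so each
stage can be inspected or re-run on its own.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import stats as cstats
from .cohort import OUTCOME_COLUMNS, OUTCOMES, CohortSimConfig, CovariateModel, generate_cohort
from .quantify import QC_FLAGS, ThresholdParams, binarize_superficial, qc_filter, quantify
from .synthetic import SyntheticScene, SyntheticSceneConfig, generate_scene, load_scene, write_fixture

__all__ = ["RunConfig", "RunManifest", "StageError", "run", "report", "DEFAULT_FACTORS"]

log = logging.getLogger("ccflow.pipeline")

STAGES = ("simulate", "quantify", "analyze", "report")

#: Candidate systemic factors screened univariately for each outcome.
DEFAULT_FACTORS = (
    "age",
    "sex",
    "diabetes",
    "beta_blocker",
    "ccb",
    "acei_arb",
    "other_med",
    "n_meds_class",
    "bp_control",
    "sbp_overall",
    "sbp_day",
    "sbp_night",
    "dbp_overall",
    "dbp_day",
    "dbp_night",
    "egfr",
    "creatinine_umol_l",
    "urine_mcr_mg_g",
)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for the exit status."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Declarative configuration of one pipeline run."""

    out_dir: str = "ccflow_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    n_scenes: int = 4
    scene: SyntheticSceneConfig = field(default_factory=SyntheticSceneConfig)
    cohort: CohortSimConfig = field(default_factory=CohortSimConfig)
    threshold: ThresholdParams = field(default_factory=ThresholdParams)
    connectivity: int = 8
    cov_struct: str = "exchangeable"
    outcomes: tuple[str, ...] = OUTCOMES
    factors: tuple[str, ...] = DEFAULT_FACTORS
    p_threshold: float = 0.10
    forced_covariates: tuple[str, ...] = ("age", "sex", "diabetes")
    #: QC exclusions applied to enrolled subjects, reason -> count.
    qc_exclusions: Mapping[str, int] = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        bad = set(self.qc_exclusions) - set(QC_FLAGS)
        if bad:
            raise ValueError(f"unknown QC exclusion reasons {sorted(bad)}")
        total_excluded = sum(self.qc_exclusions.values())
        if total_excluded >= self.cohort.n_subjects:
            raise ValueError("QC exclusions leave no subjects to analyze")

    # -- (de)serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["qc_exclusions"] = dict(self.qc_exclusions)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "scene" in d and isinstance(d["scene"], Mapping):
            d["scene"] = SyntheticSceneConfig(**d["scene"])
        if "cohort" in d and isinstance(d["cohort"], Mapping):
            c = dict(d["cohort"])
            if isinstance(c.get("covariate_model"), Mapping):
                cm = dict(c["covariate_model"])
                for key in ("smoking_fracs", "height_mean_m", "creatinine_median_umol_l"):
                    if key in cm and isinstance(cm[key], list):
                        cm[key] = tuple(cm[key])
                c["covariate_model"] = CovariateModel(**cm)
            d["cohort"] = CohortSimConfig(**c)
        if "threshold" in d and isinstance(d["threshold"], Mapping):
            d["threshold"] = ThresholdParams(**d["threshold"])
        for key in ("stages", "outcomes", "factors", "forced_covariates"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass(frozen=True)
class RunManifest:
    """Record of one pipeline run: config echo, stage counts, file digests."""

    config: dict
    stages_run: tuple[str, ...]
    counts: dict
    outputs: dict  # relative path -> sha256

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")


# --- stages ------------------------------------------------------------------


def _stage_simulate(config: RunConfig, out: Path) -> dict:
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0)))
    scene_dir = out / "scenes"
    for i in range(config.n_scenes):
        scfg = dataclasses.replace(
            config.scene, seed=int(rng.integers(0, 2**31 - 1))
        )
        write_fixture(generate_scene(scfg), scene_dir / f"scene_{i:03d}")
    cohort_cfg = dataclasses.replace(config.cohort, seed=int(rng.integers(0, 2**31 - 1)))
    eyes = generate_cohort(cohort_cfg)
    # assign QC exclusion flags to whole subjects, deterministically by order
    subjects = eyes["subject_id"].drop_duplicates().tolist()
    for flag in QC_FLAGS:
        eyes[flag] = False
    pos = 0
    for reason in QC_FLAGS:  # fixed reason order keeps assignment stable
        n = int(config.qc_exclusions.get(reason, 0))
        flagged = subjects[pos : pos + n]
        eyes.loc[eyes["subject_id"].isin(flagged), reason] = True
        pos += n
    _write_csv(eyes, out / "cohort" / "eyes.csv")
    from .cohort import COHORT_DATA_DICTIONARY

    dd = pd.DataFrame(
        sorted(COHORT_DATA_DICTIONARY.items()), columns=["column", "description"]
    )
    _write_csv(dd, out / "cohort" / "data_dictionary.csv")
    log.info("simulate: %d scenes, %d eye rows", config.n_scenes, len(eyes))
    return {"scenes": config.n_scenes, "eye_rows": len(eyes)}


def _stage_quantify(config: RunConfig, out: Path) -> dict:
    scene_dirs = sorted((out / "scenes").glob("scene_*"))
    if not scene_dirs:
        raise StageError("quantify", f"no scenes found under {out / 'scenes'}")
    rows = []
    for d in scene_dirs:
        scene = load_scene(d)
        res = quantify(
            scene.superficial,
            scene.choriocapillaris,
            config.threshold,
            connectivity=config.connectivity,  # type: ignore[arg-type]
        )
        rows.append(
            {
                "scan_id": d.name,
                "area_pct": res.area_pct,
                "mean_size_px": res.mean_size_px,
                "n_voids": res.count,
                "threshold_value": res.threshold_value,
                "analyzable_px": res.analyzable_px,
                "excluded_px": res.excluded_px,
                "eta": config.threshold.eta,
                "sigma_um": config.threshold.sigma_um,
                "sd_mode": config.threshold.sd_mode,
                "connectivity": config.connectivity,
            }
        )
    _write_csv(pd.DataFrame(rows), out / "quantify" / "scan_metrics.csv")
    log.info("quantify: %d scans", len(rows))
    return {"scans_quantified": len(rows)}


def _stage_analyze(config: RunConfig, out: Path) -> dict:
    eyes_path = out / "cohort" / "eyes.csv"
    if not eyes_path.exists():
        raise StageError("analyze", f"missing cohort table {eyes_path}")
    eyes = pd.read_csv(eyes_path)
    subjects = eyes.drop_duplicates("subject_id")
    flag_cols = [c for c in QC_FLAGS if c in eyes.columns]
    records = [
        {"subject_id": r["subject_id"], **{f: bool(r[f]) for f in flag_cols}}
        for _, r in subjects.iterrows()
    ]
    included, _excluded, counts = qc_filter(records)
    keep_ids = {r["subject_id"] for r in included}
    analyzed = eyes[eyes["subject_id"].isin(keep_ids)].copy()
    participants = analyzed.drop_duplicates("subject_id")

    descr = cstats.compare_groups(
        participants,
        by="bp_control",
        continuous=["age", "bmi", "sbp_overall", "dbp_overall", "egfr",
                    "creatinine_umol_l", "urine_mcr_mg_g"],
        categorical=["sex", "diabetes", "hyperlipidemia", "smoking",
                     "beta_blocker", "ccb", "acei_arb", "other_med"],
    )
    _write_csv(descr, out / "tables" / "descriptives_by_bp_control.csv")

    all_rows = []
    selected_note = {}
    for outcome in config.outcomes:
        uni_rows, pvalues = cstats.univariate_screen(
            analyzed, list(config.factors), outcome, cov_struct=config.cov_struct
        )
        all_rows.extend(uni_rows)
        covs = cstats.select_covariates(
            pvalues, p_threshold=config.p_threshold, forced=config.forced_covariates
        )
        selected_note[outcome] = covs
        for design in cstats.multivariate_designs(covs):
            all_rows.extend(
                cstats.fit_multivariate(
                    analyzed, design, outcome, cov_struct=config.cov_struct
                )
            )
        _write_csv(
            cstats.association_table(
                [r for r in all_rows if r.outcome == outcome]
            ),
            out / "tables" / f"associations_{outcome}.csv",
        )
    (out / "tables" / "selected_covariates.json").write_text(
        json.dumps(selected_note, indent=2, sort_keys=True)
    )
    inter_eye = {
        o: dict(zip(("r", "p"), cstats.inter_eye_correlation(analyzed, o)))
        for o in config.outcomes
    }
    (out / "tables" / "inter_eye_correlation.json").write_text(
        json.dumps(inter_eye, indent=2, sort_keys=True)
    )
    log.info(
        "analyze: %d/%d subjects after QC, %d association rows",
        len(keep_ids), counts["enrolled"], len(all_rows),
    )
    return {
        "enrolled": counts["enrolled"],
        "excluded_by_reason": {f: counts[f] for f in QC_FLAGS if counts[f]},
        "analyzed_subjects": counts["analyzed"],
        "analyzed_eyes": int(len(analyzed)),
    }


def _overlay_png(scene: SyntheticScene, config: RunConfig, path: Path) -> None:
    """Color-coded audit image: flow voids green, superficial plexus red."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    res = quantify(scene.superficial, scene.choriocapillaris, config.threshold)
    cc = scene.choriocapillaris.intensities
    base = np.clip(cc / np.percentile(cc, 99), 0, 1)
    rgb = np.stack([base, base, base], axis=-1)
    vessels = binarize_superficial(scene.superficial).values
    rgb[res.label_map > 0] = (0.0, 0.8, 0.0)
    rgb[vessels] = (0.9, 0.0, 0.0)
    fig, ax = plt.subplots(figsize=(4, 4), dpi=120)
    ax.imshow(rgb, interpolation="nearest")
    ax.set_axis_off()
    ax.set_title(f"flow voids (green) / superficial plexus (red)\narea {res.area_pct:.1f}%")
    fig.savefig(path, bbox_inches="tight", metadata={"Software": "ccflow"})
    plt.close(fig)


def report(config: RunConfig, out: Path | str | None = None) -> Path:
    """Render a Markdown summary with association tables and figures."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out if out is not None else config.out_dir)
    tables = out / "tables"
    missing = [
        str(p)
        for p in [out / "cohort" / "eyes.csv", tables]
        if not p.exists()
    ]
    if missing:
        raise StageError("report", f"missing inputs: {missing}")
    lines = ["# Choriocapillaris flow-void run report", ""]

    descr_path = tables / "descriptives_by_bp_control.csv"
    if descr_path.exists():
        descr = pd.read_csv(descr_path)
        lines += ["## Cohort descriptives by BP control", "",
                  descr.to_markdown(index=False), ""]

    eyes = pd.read_csv(out / "cohort" / "eyes.csv")
    fig_dir = out / "report_figures"
    fig_dir.mkdir(parents=True, exist_ok=True)
    for outcome in config.outcomes:
        apath = tables / f"associations_{outcome}.csv"
        if not apath.exists():
            continue
        assoc = pd.read_csv(apath)
        assoc["p_value"] = assoc["p_value"].map(lambda p: f"{p:.3f}")
        lines += [f"## Associations: {outcome} of flow voids", ""]
        uni = assoc[assoc["model"] == "univariate"]
        hits = uni[uni["p_value"].astype(float) < config.p_threshold]
        if hits.empty:
            lines += [f"no factors at p < {config.p_threshold:.2f}", ""]
        lines += [assoc.to_markdown(index=False), ""]
        # scatter of the outcome against daytime systolic BP
        ycol = OUTCOME_COLUMNS[outcome]
        fig, ax = plt.subplots(figsize=(4, 3), dpi=120)
        ax.scatter(eyes["sbp_day"], eyes[ycol], s=8, alpha=0.6)
        b, a = np.polyfit(eyes["sbp_day"], eyes[ycol], 1)
        xs = np.array([eyes["sbp_day"].min(), eyes["sbp_day"].max()])
        ax.plot(xs, a + b * xs, "r-", lw=1)
        ax.set_xlabel("daytime systolic BP (mmHg)")
        ax.set_ylabel(ycol)
        ax.set_title(f"slope {10 * b:+.3f} per 10 mmHg")
        fig.tight_layout()
        fig.savefig(fig_dir / f"scatter_{outcome}_vs_sbp_day.png",
                    metadata={"Software": "ccflow"})
        plt.close(fig)
        lines += [f"![scatter](report_figures/scatter_{outcome}_vs_sbp_day.png)", ""]

    scene_dirs = sorted((out / "scenes").glob("scene_*"))
    if scene_dirs:
        _overlay_png(load_scene(scene_dirs[0]), config, fig_dir / "overlay_example.png")
        lines += ["## Example overlay", "",
                  "![overlay](report_figures/overlay_example.png)", ""]
    path = out / "report.md"
    path.write_text("\n".join(lines))
    log.info("report: wrote %s", path)
    return path


def run(config: RunConfig, out_dir: Path | str | None = None) -> RunManifest:
    """Execute the enabled stages in order and write ``manifest.json``."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict = {}
    stages_run = []
    for stage in STAGES:
        if stage not in config.stages:
            continue
        try:
            if stage == "simulate":
                counts.update(_stage_simulate(config, out))
            elif stage == "quantify":
                counts.update(_stage_quantify(config, out))
            elif stage == "analyze":
                counts.update(_stage_analyze(config, out))
            elif stage == "report":
                report(config, out)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - annotate with stage context
            raise StageError(stage, f"{type(exc).__name__}: {exc}") from exc
        stages_run.append(stage)
    if {"enrolled", "analyzed_subjects"} <= counts.keys():
        excl = sum(counts.get("excluded_by_reason", {}).values())
        assert counts["enrolled"] - excl == counts["analyzed_subjects"]
    outputs = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = RunManifest(
        config=config.to_dict(),
        stages_run=tuple(stages_run),
        counts=counts,
        outputs=outputs,
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
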