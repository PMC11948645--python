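"""End-to-end pipeline: simulate -> gradients -> normative -> topology -> mediation.

The pipeline mirrors the reference-cohort convention of large normative
studies: connectivity gradients and per-parcel normative models are fitted
on a typically-developing reference cohort, transferred to the study
cohort's TD group by intercept recalibration, and every study subject is
scored against the transferred models. Participation-coefficient centiles
are likewise scored against TD-fitted models for every subject, keeping
diagnosis-related topology deviations visible to the mediation stage. All
stages are deterministic given the config and seed; every run directory
carries the config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .atlas import ParcelAtlas, make_atlas
from .connectome import ConnectivityMatrix, binarize_positive_top
from .gradient import build_template, subject_gradients
from .hierarchy import (DEFAULT_AGE_BINS, age_bin_analysis, compare_centiles,
                        behavior_correlation, fit_score_trajectory,
                        score_cohort, sigma_age_effect)
from .mediation import mediation_by_stage
from .normative import (NormativeConfig, centile_scores, fit_normative,
                        transfer_recalibrate)
from .simulate import SimTruth, simulate_connectivity, simulate_dataset
from .topology import pc_centiles, pc_table

log = logging.getLogger(__name__)

STAGES = ("simulate", "gradients", "normative", "score", "topology",
          "mediate", "report")


@dataclasses.dataclass
class RunConfig:
    """Validated pipeline configuration (YAML-loadable)."""

    output_dir: str = "runs/gradnorm"
    seed: int = 0
    # synthetic-cohort generation (used unless explicit inputs are given)
    n_parcels: int = 200
    n_td: int = 300
    n_asd: int = 300
    n_reference: int = 300
    age_distribution: str = "uniform"
    symptom_rho: float = -0.4
    truth_overrides: dict = dataclasses.field(default_factory=dict)
    # explicit inputs (cohort CSV + matrix manifest + atlas TSV)
    cohort_csv: str | None = None
    matrix_manifest: str | None = None
    atlas_tsv: str | None = None
    # gradient estimation
    k: int = 10
    gradient_density: float = 0.10
    alpha: float = 0.5
    diffusion_time: float = 0.0
    # normative modeling
    normative: dict = dataclasses.field(default_factory=dict)
    # topology and mediation
    topology_density: float = 0.10
    bins: tuple = DEFAULT_AGE_BINS
    n_boot: int = 5000
    save_connectivity: bool = False

    def __post_init__(self) -> None:
        for name in ("gradient_density", "topology_density"):
            d = getattr(self, name)
            if not 0.0 < d < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {d}")
        if self.n_boot < 1:
            raise ValueError("n_boot must be positive")
        if self.seed < 0:
            raise ValueError("seed must be nonnegative")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def normative_config(self) -> NormativeConfig:
        return NormativeConfig(**self.normative)

    def truth(self) -> SimTruth:
        return SimTruth(seed=self.seed, **self.truth_overrides)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True,
                          default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig, stages=STAGES) -> dict:
    """Execute the pipeline and write versioned outputs to the run directory.

    Returns a results dictionary with the key tables and fitted summaries;
    the same content is persisted as CSV/JSON under ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"config_hash": config.config_hash()}
    ncfg = config.normative_config()

    # ---- stage: simulate / load -------------------------------------
    if config.cohort_csv is not None:
        atlas = ParcelAtlas.from_tsv(config.atlas_tsv)
        cohort = pd.read_csv(config.cohort_csv)
        manifest = pd.read_csv(config.matrix_manifest)
        matrices = {
            r.subject_id: ConnectivityMatrix(np.loadtxt(r.path))
            for r in manifest.itertuples(index=False)
        }
        reference, ref_matrices = None, None
    else:
        atlas = make_atlas(config.n_parcels)
        truth = config.truth()
        cohort, matrices = simulate_dataset(
            config.n_td, config.n_asd, truth, atlas,
            age_distribution=config.age_distribution,
            symptom_rho=config.symptom_rho)
        ref_truth = dataclasses.replace(truth, seed=truth.seed + 104729)
        reference, ref_matrices = simulate_dataset(
            config.n_reference, 0, ref_truth, atlas, symptom_rho=None)
        reference["subject_id"] = "ref-" + reference["subject_id"]
        ref_matrices = {f"ref-{k}": v for k, v in ref_matrices.items()}
    atlas.to_tsv(out / "atlas.tsv")
    cohort.to_csv(out / "cohort.csv", index=False)
    if reference is not None:
        reference.to_csv(out / "reference_cohort.csv", index=False)
    if config.save_connectivity:
        mdir = out / "connectivity"
        mdir.mkdir(exist_ok=True)
        for sid, mat in matrices.items():
            np.savetxt(mdir / f"{sid}.txt", mat.values)
    results.update(atlas=atlas, cohort=cohort)
    if "simulate" in stages and len(stages) == 1:
        return results

    # ---- stage: gradients -------------------------------------------
    ref_for_template = ref_matrices if ref_matrices else {
        sid: matrices[sid]
        for sid in cohort.loc[cohort["group"] == "TD", "subject_id"]}
    template = build_template(list(ref_for_template.values()),
                              k=config.k, density=config.gradient_density,
                              alpha=config.alpha,
                              diffusion_time=config.diffusion_time,
                              orient_atlas=atlas)

    def g1_table(mat_dict) -> pd.DataFrame:
        rows = {}
        for sid, mat in mat_dict.items():
            gs = subject_gradients(mat, template, k=config.k,
                                   density=config.gradient_density,
                                   alpha=config.alpha,
                                   diffusion_time=config.diffusion_time)
            rows[sid] = gs.g1
        return pd.DataFrame.from_dict(rows, orient="index",
                                      columns=list(atlas.parcel_ids))

    gradients = g1_table(matrices)
    gradients.to_csv(out / "gradients_g1.csv")
    ref_gradients = g1_table(ref_matrices) if ref_matrices else None
    results.update(template=template, gradients=gradients)

    # ---- stage: normative (per-parcel models + centiles) ------------
    if ref_gradients is not None:
        fit_cohort, fit_grads = reference, ref_gradients
    else:
        td_ids = cohort.loc[cohort["group"] == "TD", "subject_id"]
        fit_cohort, fit_grads = cohort[cohort["subject_id"].isin(td_ids)], \
            gradients.loc[td_ids]
    models = {}
    for parcel in atlas.parcel_ids:
        models[parcel] = fit_normative(
            fit_grads[parcel].to_numpy(float),
            fit_cohort["age"].to_numpy(float),
            fit_cohort["sex"].to_numpy(), ncfg)
    if ref_gradients is not None:
        # transfer to the study cohort's TD group (intercept recalibration)
        td = cohort[cohort["group"] == "TD"]
        td_grads = gradients.loc[td["subject_id"]]
        models = {
            parcel: transfer_recalibrate(
                models[parcel], td_grads[parcel].to_numpy(float),
                td["age"].to_numpy(float), td["sex"].to_numpy())
            for parcel in atlas.parcel_ids
        }
    centiles = pd.DataFrame({
        parcel: centile_scores(models[parcel],
                               gradients[parcel].to_numpy(float),
                               cohort["age"].to_numpy(float),
                               cohort["sex"].to_numpy())
        for parcel in atlas.parcel_ids
    }, index=gradients.index)
    centiles.to_csv(out / "centiles.csv")
    results.update(models=models, centiles=centiles)
    if set(stages) <= {"simulate", "gradients", "normative"}:
        return results

    # ---- stage: score (hierarchy) -----------------------------------
    scores = score_cohort(gradients, models, cohort)
    scores.to_csv(out / "hierarchy_scores.csv")
    trajectories = {}
    sigma_trends = {}
    # trajectory curves get GAIC-selected smoothing: peak-age extraction is
    # sensitive to spline wobble in sparsely sampled age regions
    traj_cfg = dataclasses.replace(ncfg, select_smoothing=True)
    for group in ("TD", "ASD"):
        if (cohort["group"] == group).sum() >= ncfg.min_n:
            trajectories[group] = fit_score_trajectory(scores, cohort, group,
                                                       traj_cfg)
            try:
                sigma_trends[group] = sigma_age_effect(scores, cohort, group,
                                                       ncfg)
            except ValueError as err:
                log.warning("sigma trend skipped for %s: %s", group, err)
    bin_table = age_bin_analysis(centiles, cohort, atlas, config.bins)
    bin_table.to_csv(out / "centile_bins.csv", index=False)
    parcel_t = compare_centiles(centiles, cohort, atlas, level="parcel")
    parcel_t.to_csv(out / "centile_parcel_t.csv", index=False)
    srs_cols = [c for c in cohort.columns if c.startswith("srs_")]
    behavior = behavior_correlation(scores, cohort) if srs_cols else None
    if behavior is not None:
        behavior.to_csv(out / "behavior_correlation.csv", index=False)
    results.update(scores=scores, trajectories=trajectories,
                   sigma_trends=sigma_trends, bin_table=bin_table,
                   parcel_t=parcel_t, behavior=behavior)

    # ---- stage: topology --------------------------------------------
    adjacency = {sid: binarize_positive_top(matrices[sid],
                                            config.topology_density)
                 for sid in cohort["subject_id"]}
    pc = pc_table(adjacency.values(), atlas, index=list(adjacency.keys()))
    pc.to_csv(out / "pc.csv")
    td_mask = (cohort["group"] == "TD").to_numpy()
    if td_mask.sum() >= ncfg.min_n:
        # fit PC normative models on the TD group, score everyone: keeps
        # diagnosis-related PC deviations visible to the mediation stage
        pc_cent, _ = pc_centiles(pc.loc[cohort["subject_id"]],
                                 cohort["age"].to_numpy(float),
                                 cohort["sex"].to_numpy(), ncfg,
                                 fit_mask=td_mask)
        pc_cent.to_csv(out / "pc_centiles.csv")
    else:
        pc_cent = None
    results.update(pc=pc, pc_centiles=pc_cent)

    # ---- stage: mediate ---------------------------------------------
    mediation = None
    if pc_cent is not None:
        ids = [s for s in cohort["subject_id"] if s in pc_cent.index]
        sub = cohort.set_index("subject_id").loc[ids]
        x = (sub["group"] == "ASD").astype(float).to_numpy()
        y = scores.loc[ids, "score"].to_numpy(float)
        # mediate on deviation z-scores (probit of the centile): monotone
        # with the centile but linear in deviation units, so extreme
        # deviations are not compressed against the centile ceiling
        from scipy.special import ndtri
        pc_dev = pd.DataFrame(ndtri(pc_cent.loc[ids].to_numpy()),
                              index=ids, columns=pc_cent.columns)
        mediation = mediation_by_stage(pc_dev, x, y,
                                       sub["age"].to_numpy(float),
                                       bins=config.bins,
                                       n_boot=config.n_boot,
                                       seed=config.seed)
        mediation.to_csv(out / "mediation.csv", index=False)
    results["mediation"] = mediation

    # ---- stage: report ----------------------------------------------
    report = _build_report(config, results)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    results["report"] = report
    return results


def _build_report(config: RunConfig, results: dict) -> dict:
    report = {
        "config_hash": results["config_hash"],
        "conventions": {
            "gradient_reference": "TD reference cohort (transferred)",
            "pc_centiles": "TD-referenced normative models, all subjects scored",
        },
    }
    traj = results.get("trajectories", {})
    for group, t in traj.items():
        report[f"{group.lower()}_slope_per_year"] = t.slope_per_year
        report[f"{group.lower()}_peak_age"] = t.peak_age
    sig = results.get("sigma_trends", {})
    for group, s in sig.items():
        report[f"{group.lower()}_sigma_trend"] = {
            "statistic": s.statistic, "p": s.p, "sign": s.sign}
    if results.get("behavior") is not None:
        report["behavior"] = results["behavior"].to_dict(orient="records")
    if results.get("bin_table") is not None:
        report["centile_bins"] = results["bin_table"].to_dict(orient="records")
    if results.get("mediation") is not None:
        report["mediation"] = results["mediation"].to_dict(orient="records")
    return report


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def make_fixtures(size: str = "tiny", base_dir: str = "fixtures",
                  seed: int = 7) -> Path:
    """Write the synthetic cohorts used by tests/demos with fixed seeds.

    ``tiny``: 20 parcels, 20 subjects per group — full pipeline in well
    under a minute. ``demo``: 200 parcels, 300 per group — exercises all
    seven networks and all three developmental stages.
    """
    presets = {
        "tiny": dict(n_parcels=21, n_td=25, n_asd=25, n_reference=60,
                     n_boot=500, normative={"min_n": 20}),
        "demo": dict(n_parcels=200, n_td=300, n_asd=300, n_reference=300,
                     n_boot=5000),
    }
    if size not in presets:
        raise ValueError(f"unknown fixture size {size!r}")
    out = Path(base_dir) / size
    config = RunConfig(output_dir=str(out), seed=seed, **presets[size])
    run_pipeline(config)
    return out
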