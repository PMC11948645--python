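"""Whole-brain hierarchy score and its developmental analysis.

The hierarchy score condenses a subject's whole-brain gradient map into a
single alignment measure: the cosine similarity between the subject's
principal gradient G1 (one value per parcel) and the normative median
gradient at the subject's age and sex,

    score = (NormG1_age . G1) / (||NormG1_age|| ||G1||).

A score of 1 means the subject's hierarchy matches the normative pattern
exactly; lower scores mean deviation. Group trajectories of the score are
fitted with the same SHASH normative machinery, yielding per-sex slopes,
an interior peak age when the curve is non-monotone, centile bands and a
variance (sigma) trend test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import NETWORKS, ParcelAtlas
from .normative import (NormativeConfig, NormativeModel, centile_scores,
                        fit_normative, sigma_age_test)
from .stats import fdr_bh, group_t_table, pearson_table

DEFAULT_AGE_BINS: tuple[tuple[float, float], ...] = (
    (5.0, 12.0), (12.0, 15.0), (15.0, 22.0))

SRS_SCALES: tuple[str, ...] = (
    "srs_total", "srs_awareness", "srs_cognition", "srs_communication",
    "srs_motivation", "srs_mannerisms")


def hierarchy_score(g1, norm_g1) -> float:
    """Cosine similarity between a subject gradient and the normative one."""
    g1 = np.asarray(g1, dtype=float)
    norm_g1 = np.asarray(norm_g1, dtype=float)
    if g1.shape != norm_g1.shape:
        raise ValueError(f"length mismatch: {g1.shape} vs {norm_g1.shape}")
    n1 = np.linalg.norm(g1)
    n2 = np.linalg.norm(norm_g1)
    if n1 == 0 or n2 == 0:
        raise ValueError("hierarchy score undefined for a zero vector")
    return float(g1 @ norm_g1 / (n1 * n2))


def score_cohort(gradients: pd.DataFrame, models: dict[str, NormativeModel],
                 cohort: pd.DataFrame) -> pd.DataFrame:
    """Hierarchy score per subject against per-parcel normative medians.

    ``gradients`` is subjects x parcels (aligned G1 loadings); ``models``
    maps each parcel to its fitted/transferred normative model. For every
    subject the normative gradient is the vector of per-parcel medians at
    that subject's age and sex.
    """
    missing = [p for p in gradients.columns if p not in models]
    if missing:
        raise ValueError(f"no normative model for parcels {missing[:5]}")
    parcels = list(gradients.columns)
    ages = cohort["age"].to_numpy(float)
    sexes = cohort["sex"].to_numpy()
    norm_g1 = np.column_stack([
        models[p].median(ages, sexes) for p in parcels])
    scores = [
        hierarchy_score(gradients.loc[sid].to_numpy(float), norm_g1[i])
        for i, sid in enumerate(cohort["subject_id"])
    ]
    return pd.DataFrame({"subject_id": cohort["subject_id"],
                         "score": scores}).set_index("subject_id")


@dataclass(frozen=True)
class TrajectoryFit:
    """Fitted group trajectory of the hierarchy score."""

    group: str
    age_grid: np.ndarray
    median: dict[str, np.ndarray]        # per sex
    band_low: dict[str, np.ndarray]      # 2.5% centile
    band_high: dict[str, np.ndarray]     # 97.5% centile
    slope_per_year: dict[str, float]     # mean derivative of the median
    peak_age: dict[str, float | None]    # interior argmax, when present
    model: NormativeModel

    def __post_init__(self) -> None:
        for sex in self.median:
            if not (np.all(self.band_low[sex] <= self.median[sex] + 1e-12)
                    and np.all(self.median[sex] <= self.band_high[sex] + 1e-12)):
                raise ValueError("centile bands must bracket the median")


def fit_score_trajectory(scores: pd.DataFrame, cohort: pd.DataFrame,
                         group: str, config: NormativeConfig | None = None,
                         n_grid: int = 200,
                         peak_margin: float = 0.5) -> TrajectoryFit:
    """Fit one group's hierarchy-score trajectory with the SHASH model.

    The slope per year is the mean finite-difference derivative of the
    median curve over the fitted range, reported per sex. A peak age is
    reported only when the curve's maximum lies at least ``peak_margin``
    years inside the range (interior maximum of an inverted-U shape).
    """
    config = config or NormativeConfig()
    sub = cohort[cohort["group"] == group]
    if sub.empty:
        raise ValueError(f"no subjects in group {group!r}")
    y = scores.loc[sub["subject_id"], "score"].to_numpy(float)
    age = sub["age"].to_numpy(float)
    sex = sub["sex"].to_numpy()
    model = fit_normative(y, age, sex, config)
    grid = np.linspace(model.age_lo, model.age_hi, n_grid)
    med, lo_band, hi_band, slope, peak = {}, {}, {}, {}, {}
    for sex_label in ("male", "female"):
        sex_vec = np.repeat(sex_label, n_grid)
        med[sex_label] = model.median(grid, sex_vec)
        lo_band[sex_label] = model.quantile(0.025, grid, sex_vec)
        hi_band[sex_label] = model.quantile(0.975, grid, sex_vec)
        deriv = np.gradient(med[sex_label], grid)
        slope[sex_label] = float(deriv.mean())
        peak[sex_label] = _interior_peak(grid, med[sex_label], peak_margin)
    return TrajectoryFit(group=group, age_grid=grid, median=med,
                         band_low=lo_band, band_high=hi_band,
                         slope_per_year=slope, peak_age=peak, model=model)


def _interior_peak(grid, curve, margin):
    i = int(np.argmax(curve))
    age = float(grid[i])
    if age - grid[0] < margin or grid[-1] - age < margin:
        return None
    return age


def sigma_age_effect(scores: pd.DataFrame, cohort: pd.DataFrame, group: str,
                     config: NormativeConfig | None = None):
    """Variance-trend (sigma) LR test of a group's hierarchy scores."""
    sub = cohort[cohort["group"] == group]
    if sub.empty:
        raise ValueError(f"no subjects in group {group!r}")
    y = scores.loc[sub["subject_id"], "score"].to_numpy(float)
    return sigma_age_test(y, sub["age"].to_numpy(float),
                          sub["sex"].to_numpy(), config)


def compare_centiles(centiles: pd.DataFrame, cohort: pd.DataFrame,
                     atlas: ParcelAtlas | None = None,
                     level: str = "parcel") -> pd.DataFrame:
    """ASD vs TD Welch t-tests on centile scores with BH correction.

    ``level="parcel"`` tests every column; ``level="network"`` first
    averages each subject's centiles within each of the 7 networks
    (requires ``atlas``). Positive t = ASD above TD.
    """
    asd = cohort.loc[cohort["group"] == "ASD", "subject_id"]
    td = cohort.loc[cohort["group"] == "TD", "subject_id"]
    if asd.empty or td.empty:
        raise ValueError("both groups must be non-empty")
    values = centiles
    if level == "network":
        if atlas is None:
            raise ValueError("network-level comparison requires an atlas")
        labels = atlas.labels()
        values = pd.DataFrame({
            net: centiles.loc[:, np.asarray(centiles.columns)[labels == net]]
                 .mean(axis=1)
            for net in NETWORKS}, index=centiles.index)
    elif level != "parcel":
        raise ValueError(f"unknown level {level!r}")
    return group_t_table(values, asd, td)


def age_bin_analysis(centiles: pd.DataFrame, cohort: pd.DataFrame,
                     atlas: ParcelAtlas,
                     bins=DEFAULT_AGE_BINS) -> pd.DataFrame:
    """Network-level ASD-vs-TD centile comparison within developmental bins.

    Bins are half-open [lo, hi), except the last which includes its upper
    edge; FDR is applied within each bin across the 7 networks. Bins where
    a group is empty (or has one subject) are flagged and skipped.
    """
    rows = []
    last_hi = bins[-1][1]
    for lo, hi in bins:
        name = f"{lo:g}-{hi:g}"
        age = cohort["age"].to_numpy(float)
        mask = (age >= lo) & ((age < hi) | ((hi == last_hi) & (age == hi)))
        sub = cohort[mask]
        counts = sub["group"].value_counts()
        if counts.get("ASD", 0) < 2 or counts.get("TD", 0) < 2:
            rows.append(pd.DataFrame({"bin": [name], "feature": [None],
                                      "t": [np.nan], "p": [np.nan],
                                      "q": [np.nan], "flagged": [True]}))
            continue
        tab = compare_centiles(centiles.loc[sub["subject_id"]], sub,
                               atlas, level="network")
        tab.insert(0, "bin", name)
        tab["flagged"] = False
        rows.append(tab)
    return pd.concat(rows, ignore_index=True)


def behavior_correlation(scores: pd.DataFrame, cohort: pd.DataFrame,
                         scales=SRS_SCALES) -> pd.DataFrame:
    """Pearson correlation of hierarchy scores with symptom scales (BH-FDR)."""
    present = [s for s in scales if s in cohort.columns]
    if not present:
        raise ValueError("no symptom columns present in the cohort table")
    merged = cohort.set_index("subject_id").join(scores, how="inner")
    return pearson_table(merged["score"], merged[present])
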