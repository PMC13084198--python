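"""Whole-brain ΔFC per nucleus and its inference.

ΔFC for one (subject, nucleus) is the whole-brain mean of the unsigned
voxelwise change in the nucleus's FC map between a baseline state (awake)
and a comparison state (deep sedation, or patient resting state against
the control-group mean map).  ΔFC values are z-scored over all
(subject × nucleus) entries of a comparison so that nuclei are
commensurable on one axis.

Inference follows the study design: a linear mixed model with the
target-nucleus indicator as fixed effect and a per-subject random
intercept tests whether the candidate nucleus's ΔFC exceeds the rest; a
repeated-measures F-test probes heterogeneity among the remaining nuclei;
paired contrasts of the target against each other nucleus and the
task-subgroup two-sample tests are Benjamini–Hochberg corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .connectivity import FCMap
from .io_cohort import NUCLEUS_LABELS, ParticipantTable

TABLE_COLUMNS = (
    "subject", "nucleus", "delta_fc", "z_delta_fc", "diagnosis", "task_response",
)


@dataclass
class NucleusTestResult:
    """Inference bundle for one candidate nucleus."""

    target: str
    t_statistic: float
    p_value: float
    model: str  # "mixed" or "paired_fallback"
    df: float
    anova_f: float | None = None
    anova_p: float | None = None
    pairwise: list[tuple[str, float]] = field(default_factory=list)


def delta_fc(
    map_a: FCMap,
    map_b: FCMap,
    brain_mask: np.ndarray | None = None,
    exclude_seed: bool = True,
) -> float:
    """Mean unsigned voxelwise FC change between two maps of one nucleus.

    Averaged over in-mask voxels that are valid (finite) in both maps;
    seed self-voxels are excluded by default since their |Δ| is ≈ 0 by
    construction and would dilute the statistic.
    """
    if map_a.values.shape != map_b.values.shape:
        raise ValueError("maps do not share a grid")
    if map_a.nucleus != map_b.nucleus:
        raise ValueError("maps are for different nuclei")
    if map_a.value_kind != map_b.value_kind:
        raise ValueError("maps have different value kinds")
    mask = map_a.brain_mask & map_b.brain_mask
    if brain_mask is not None:
        mask = mask & np.asarray(brain_mask, dtype=bool)
    if exclude_seed:
        mask = mask & ~map_a.seed_mask & ~map_b.seed_mask
    valid = mask & np.isfinite(map_a.values) & np.isfinite(map_b.values)
    if not valid.any():
        raise ValueError("no overlapping valid voxels")
    return float(np.abs(map_a.values[valid] - map_b.values[valid]).mean())


def delta_fc_table(
    fc_maps: dict[tuple[str, str, str], FCMap],
    design: str,
    participants: ParticipantTable,
    baseline_condition: str = "awake",
    comparison_condition: str = "deep",
    rest_condition: str = "rest",
    baseline_mode: str = "mean",
    exclude_seed: bool = True,
) -> pd.DataFrame:
    """Long-format ΔFC table, one row per (subject, nucleus).

    ``within_subject``: each subject's own baseline/comparison condition
    pair.  ``between_group``: each patient's map is differenced against a
    common per-nucleus control baseline — the voxelwise mean (or median,
    ``baseline_mode``) of the control group's maps.

    z-scoring uses the population convention (ddof = 0) over all rows of
    the table, so z values have mean 0 and sd 1 by identity.
    """
    by_participant = {p.id: p for p in participants}
    rows = []
    if design == "within_subject":
        subjects = sorted({k[0] for k in fc_maps})
        for subject in subjects:
            for nucleus in NUCLEUS_LABELS:
                a = fc_maps[(subject, baseline_condition, nucleus)]
                b = fc_maps[(subject, comparison_condition, nucleus)]
                rows.append((subject, nucleus, delta_fc(a, b, exclude_seed=exclude_seed)))
    elif design == "between_group":
        patients = sorted(
            p.id for p in participants if p.diagnosis != "control"
        )
        controls = sorted(
            p.id for p in participants if p.diagnosis == "control"
        )
        if not controls:
            raise ValueError("between_group design requires control subjects")
        for nucleus in NUCLEUS_LABELS:
            ctl_maps = [fc_maps[(c, rest_condition, nucleus)] for c in controls]
            stack = np.stack([m.values for m in ctl_maps])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                agg = np.nanmean if baseline_mode == "mean" else np.nanmedian
                baseline_values = agg(stack, axis=0)
            template = ctl_maps[0]
            baseline = FCMap(
                subject_id="control-baseline", condition=rest_condition,
                nucleus=nucleus, values=baseline_values,
                brain_mask=template.brain_mask, seed_mask=template.seed_mask,
                value_kind=template.value_kind,
            )
            for patient in patients:
                b = fc_maps[(patient, rest_condition, nucleus)]
                rows.append((
                    patient, nucleus, delta_fc(b, baseline, exclude_seed=exclude_seed)
                ))
        rows.sort(key=lambda r: (r[0], NUCLEUS_LABELS.index(r[1])))
    else:
        raise ValueError(f"unknown design {design!r}")

    df = pd.DataFrame(rows, columns=["subject", "nucleus", "delta_fc"])
    sd = df["delta_fc"].std(ddof=0)
    if sd == 0:
        raise ValueError("zero variance in delta_fc; cannot z-score")
    df["z_delta_fc"] = (df["delta_fc"] - df["delta_fc"].mean()) / sd
    df["diagnosis"] = [
        by_participant[s].diagnosis if s in by_participant else ""
        for s in df["subject"]
    ]
    df["task_response"] = [
        by_participant[s].task_response if s in by_participant else ""
        for s in df["subject"]
    ]
    return df[list(TABLE_COLUMNS)]


def _check_complete(table: pd.DataFrame) -> None:
    counts = table.groupby("subject")["nucleus"].nunique()
    if (counts != len(NUCLEUS_LABELS)).any():
        raise ValueError("every subject must carry all 7 nuclei")


def nucleus_vs_rest_mixed(
    table: pd.DataFrame, target: str, value_column: str = "z_delta_fc"
) -> NucleusTestResult:
    """Mixed-model test of the target nucleus's ΔFC against all others.

    Model: value ~ 1 + indicator(nucleus == target), random intercept per
    subject, fit by REML.  The fixed-effect t uses containment degrees of
    freedom (n_obs − n_subjects − 1).  On a singular or failed fit the
    estimator falls back to the subject-mean-centred OLS contrast (the
    fixed-effects / paired limit of the same model), flagged in ``model``.
    """
    if target not in NUCLEUS_LABELS:
        raise ValueError(f"unknown nucleus {target!r}")
    _check_complete(table)
    y = table[value_column].to_numpy(dtype=np.float64)
    x = (table["nucleus"] == target).to_numpy(dtype=np.float64)
    groups = table["subject"].to_numpy()
    n_obs = y.size
    n_subjects = len(np.unique(groups))
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    df_containment = n_obs - n_subjects - 1

    X = np.column_stack([np.ones_like(x), x])
    t_stat, model_used = _fit_mixed_t(y, X, groups)
    if model_used == "paired_fallback":
        t_stat = _paired_contrast_t(table, target, value_column)
        df_containment = n_subjects - 1
    p = 2.0 * stats.t.sf(abs(t_stat), df_containment)
    return NucleusTestResult(
        target=target, t_statistic=float(t_stat), p_value=float(p),
        model=model_used, df=float(df_containment),
    )


def _fit_mixed_t(y: np.ndarray, X: np.ndarray, groups: np.ndarray):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = MixedLM(y, X, groups=groups).fit(reml=True)
            t = fit.fe_params[1] / fit.bse_fe[1]
            if np.isfinite(t):
                return float(t), "mixed"
        except (np.linalg.LinAlgError, ValueError):
            pass
    return np.nan, "paired_fallback"


def _paired_contrast_t(table: pd.DataFrame, target: str, value_column: str) -> float:
    """Per-subject target-minus-rest contrast, one-sample t (paired limit)."""
    wide = table.pivot(index="subject", columns="nucleus", values=value_column)
    rest = [n for n in NUCLEUS_LABELS if n != target]
    contrast = wide[target] - wide[rest].mean(axis=1)
    return float(contrast.mean() / (contrast.std(ddof=1) / np.sqrt(len(contrast))))


def anova_rest(
    table: pd.DataFrame, excluding: str, value_column: str = "z_delta_fc"
) -> tuple[float, float]:
    """Omnibus repeated-measures F-test for a nucleus-label effect among
    the nuclei remaining after excluding the target.

    Within-subject centring removes the per-subject random intercept
    exactly on this balanced table:
    F = MS_nucleus / MS_error with df = (J−1, (n−1)(J−1)).
    """
    present = set(table["nucleus"])
    rest = [n for n in NUCLEUS_LABELS if n != excluding and n in present]
    if len(rest) < 2:
        raise ValueError("need at least 2 remaining nuclei")
    sub = table[table["nucleus"].isin(rest)]
    wide = sub.pivot(index="subject", columns="nucleus", values=value_column)
    wide = wide[rest]
    if wide.isna().any().any():
        raise ValueError("unbalanced table: every subject needs every nucleus")
    y = wide.to_numpy(dtype=np.float64)
    n, J = y.shape
    grand = y.mean()
    col_means = y.mean(axis=0)
    row_means = y.mean(axis=1, keepdims=True)
    ss_treat = n * ((col_means - grand) ** 2).sum()
    resid = y - row_means - col_means[None, :] + grand
    ss_err = (resid**2).sum()
    df1, df2 = J - 1, (n - 1) * (J - 1)
    f = (ss_treat / df1) / (ss_err / df2)
    p = float(stats.f.sf(f, df1, df2))
    return float(f), p


def pairwise_target_vs_each(
    table: pd.DataFrame, target: str, value_column: str = "z_delta_fc"
) -> list[tuple[str, float]]:
    """Paired contrasts of the target against each other nucleus, with
    Benjamini–Hochberg correction across the 6 comparisons."""
    wide = table.pivot(index="subject", columns="nucleus", values=value_column)
    others = [n for n in NUCLEUS_LABELS if n != target]
    raw = []
    for nucleus in others:
        diff = (wide[target] - wide[nucleus]).to_numpy(dtype=np.float64)
        t, p = stats.ttest_1samp(diff, 0.0)
        raw.append(p)
    _, corrected, _, _ = multipletests(raw, method="fdr_bh")
    return list(zip(others, (float(p) for p in corrected)))


def nucleus_inference(
    table: pd.DataFrame, target: str, value_column: str = "z_delta_fc"
) -> NucleusTestResult:
    """Composite inference for a candidate nucleus: mixed-model
    target-vs-rest test, rest-heterogeneity F-test, and BH-corrected
    pairwise contrasts."""
    result = nucleus_vs_rest_mixed(table, target, value_column)
    result.anova_f, result.anova_p = anova_rest(table, target, value_column)
    result.pairwise = pairwise_target_vs_each(table, target, value_column)
    return result


def subgroup_delta_test(
    table: pd.DataFrame, value_column: str = "delta_fc"
) -> pd.DataFrame:
    """Per-nucleus two-sample t of ΔFC between imagery-task responders
    (fMRI+) and non-responders (fMRI−), BH-FDR corrected across the 7
    nuclei.

    Returns a table (nucleus, mean_positive, mean_negative, difference,
    t, p_raw, p_fdr) sorted in canonical nucleus order; the row with the
    largest |difference| identifies the nucleus whose FC change best
    separates the subgroups.
    """
    pos = table[table["task_response"] == "positive"]
    neg = table[table["task_response"] == "negative"]
    if pos["subject"].nunique() < 2 or neg["subject"].nunique() < 2:
        raise ValueError("each subgroup needs at least 2 subjects")
    rows = []
    for nucleus in NUCLEUS_LABELS:
        a = neg.loc[neg["nucleus"] == nucleus, value_column].to_numpy()
        b = pos.loc[pos["nucleus"] == nucleus, value_column].to_numpy()
        t, p = stats.ttest_ind(a, b, equal_var=True)
        rows.append({
            "nucleus": nucleus,
            "mean_positive": float(b.mean()),
            "mean_negative": float(a.mean()),
            "difference": float(a.mean() - b.mean()),
            "t": float(t),
            "p_raw": float(p),
        })
    out = pd.DataFrame(rows)
    _, corrected, _, _ = multipletests(out["p_raw"], method="fdr_bh")
    out["p_fdr"] = corrected
    return out
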