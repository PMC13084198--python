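"""ΔFC statistic, z-table identities, and mixed-model / ANOVA inference."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from thalafc.connectivity import FCMap
from thalafc.delta_fc import (
    anova_rest,
    delta_fc,
    delta_fc_table,
    nucleus_vs_rest_mixed,
    pairwise_target_vs_each,
    subgroup_delta_test,
    _paired_contrast_t,
)
from thalafc.io_cohort import NUCLEUS_LABELS, ParticipantRecord, ParticipantTable


def fc_map(values, nucleus="Pu", subject="S0", seed_mask=None, kind="fisher_z"):
    values = np.asarray(values, dtype=float)
    mask = np.ones(values.shape, dtype=bool)
    if seed_mask is None:
        seed_mask = np.zeros(values.shape, dtype=bool)
    return FCMap(
        subject_id=subject, condition="c", nucleus=nucleus, values=values,
        brain_mask=mask, seed_mask=seed_mask, value_kind=kind,
    )


class TestDeltaFC:
    def test_identical_maps_give_zero(self):
        a = fc_map(np.random.default_rng(0).standard_normal((3, 3, 3)))
        b = fc_map(a.values.copy())
        assert delta_fc(a, b) == 0.0

    def test_printed_micro_fixture(self):
        a = fc_map(np.array([0.1, -0.2, 0.3]).reshape(3, 1, 1))
        b = fc_map(np.array([0.2, 0.0, 0.3]).reshape(3, 1, 1))
        assert delta_fc(a, b) == pytest.approx(0.1, abs=1e-15)

    def test_missing_voxel_averaged_over_remaining(self):
        a = fc_map(np.array([np.nan, 0.4, 0.0]).reshape(3, 1, 1))
        b = fc_map(np.array([0.2, 0.0, 0.2]).reshape(3, 1, 1))
        assert delta_fc(a, b) == pytest.approx((0.4 + 0.2) / 2)

    def test_seed_voxels_excluded_by_default(self):
        seed = np.zeros((3, 1, 1), dtype=bool)
        seed[0] = True
        a = fc_map(np.array([9.0, 0.1, 0.1]).reshape(3, 1, 1), seed_mask=seed)
        b = fc_map(np.array([0.0, 0.2, 0.3]).reshape(3, 1, 1), seed_mask=seed)
        assert delta_fc(a, b) == pytest.approx(0.15)
        assert delta_fc(a, b, exclude_seed=False) == pytest.approx(
            (9.0 + 0.1 + 0.2) / 3
        )

    def test_metric_mean_properties(self):
        rng = np.random.default_rng(1)
        a = fc_map(rng.standard_normal((4, 4, 4)))
        b = fc_map(rng.standard_normal((4, 4, 4)))
        assert delta_fc(a, b) == delta_fc(b, a)
        assert delta_fc(a, b) > 0
        assert delta_fc(a, a) == 0.0

    def test_mismatched_maps_rejected(self):
        a = fc_map(np.zeros((2, 2, 2)), nucleus="Pu")
        b = fc_map(np.zeros((2, 2, 2)), nucleus="MD")
        with pytest.raises(ValueError, match="different nuclei"):
            delta_fc(a, b)


def synthetic_table(
    n_subjects=8,
    nucleus_effects=None,
    subject_sd=1.0,
    noise_sd=1.0,
    rng=None,
    task_responses=None,
):
    """Directly generated ΔFC table under a random-intercept model."""
    rng = rng or np.random.default_rng(0)
    nucleus_effects = nucleus_effects or {}
    rows = []
    for i in range(n_subjects):
        u = rng.normal(0, subject_sd)
        tr = task_responses[i] if task_responses else "n/a"
        for nucleus in NUCLEUS_LABELS:
            y = u + nucleus_effects.get(nucleus, 0.0) + rng.normal(0, noise_sd)
            rows.append({
                "subject": f"S{i:02d}", "nucleus": nucleus, "delta_fc": y,
                "diagnosis": "UWS", "task_response": tr,
            })
    df = pd.DataFrame(rows)
    df["z_delta_fc"] = (df["delta_fc"] - df["delta_fc"].mean()) / df[
        "delta_fc"
    ].std(ddof=0)
    return df


@pytest.fixture(scope="module")
def within_maps():
    rng = np.random.default_rng(2)
    maps = {}
    for s in [f"S{i}" for i in range(4)]:
        for cond in ("awake", "deep"):
            for nucleus in NUCLEUS_LABELS:
                maps[(s, cond, nucleus)] = fc_map(
                    rng.standard_normal((3, 3, 3)), nucleus=nucleus,
                    subject=s,
                )
    return maps


@pytest.fixture(scope="module")
def participants4():
    return ParticipantTable([
        ParticipantRecord(
            id=f"S{i}", gender="M", age=30, aetiology="n/a",
            months_post_injury=None, diagnosis="control", crs_r=None,
            task_response="n/a",
        )
        for i in range(4)
    ])


class TestDeltaTable:
    def test_one_row_per_subject_nucleus(self, within_maps, participants4):
        table = delta_fc_table(within_maps, "within_subject", participants4)
        assert len(table) == 4 * 7
        assert set(table["nucleus"]) == set(NUCLEUS_LABELS)

    def test_z_scores_have_population_mean_zero_sd_one(
        self, within_maps, participants4
    ):
        table = delta_fc_table(within_maps, "within_subject", participants4)
        assert table["z_delta_fc"].mean() == pytest.approx(0.0, abs=1e-12)
        assert table["z_delta_fc"].std(ddof=0) == pytest.approx(1.0, abs=1e-12)

    def test_between_group_uses_control_mean_baseline(self):
        rng = np.random.default_rng(3)
        participants = ParticipantTable([
            ParticipantRecord("P1", "M", 30, "TBI", None, "UWS", 7, "negative"),
            ParticipantRecord("C1", "M", 30, "n/a", None, "control", None, "n/a"),
            ParticipantRecord("C2", "F", 30, "n/a", None, "control", None, "n/a"),
        ])
        maps = {}
        for s in ("P1", "C1", "C2"):
            for nucleus in NUCLEUS_LABELS:
                maps[(s, "rest", nucleus)] = fc_map(
                    rng.standard_normal((2, 2, 2)), nucleus=nucleus, subject=s
                )
        table = delta_fc_table(maps, "between_group", participants)
        assert set(table["subject"]) == {"P1"}  # only patients have rows
        nucleus = "VLV"
        baseline = (
            maps[("C1", "rest", nucleus)].values
            + maps[("C2", "rest", nucleus)].values
        ) / 2
        expected = np.abs(
            maps[("P1", "rest", nucleus)].values - baseline
        ).mean()
        got = table.loc[table["nucleus"] == nucleus, "delta_fc"].iloc[0]
        assert got == pytest.approx(expected, abs=1e-12)


class TestMixedModel:
    def test_zero_random_intercept_matches_paired_comparison(self):
        """With no subject effect in the generator, the mixed-model t is the
        ordinary paired target-vs-rest contrast, within tolerance."""
        table = synthetic_table(
            n_subjects=12, subject_sd=0.0,
            nucleus_effects={"Pu": 1.0}, rng=np.random.default_rng(4),
        )
        mixed = nucleus_vs_rest_mixed(table, "Pu", value_column="delta_fc")
        paired = _paired_contrast_t(table, "Pu", "delta_fc")
        assert mixed.model == "mixed"
        assert mixed.t_statistic == pytest.approx(paired, rel=0.15)

    def test_strong_effect_detected(self):
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(20):
            table = synthetic_table(
                n_subjects=8, nucleus_effects={"VLV": 2.0}, rng=rng
            )
            res = nucleus_vs_rest_mixed(table, "VLV", value_column="delta_fc")
            hits += res.p_value < 0.05
        assert hits >= 19

    def test_null_calibration_on_exchangeable_tables(self):
        """Type-I error of the target-vs-rest mixed test stays at the
        nominal 5% level on exchangeable random-intercept tables."""
        rng = np.random.default_rng(6)
        n_rep, rej = 300, 0
        for _ in range(n_rep):
            table = synthetic_table(n_subjects=8, rng=rng)
            res = nucleus_vs_rest_mixed(table, "Pu", value_column="delta_fc")
            rej += res.p_value < 0.05
        # 99% binomial band around 0.05 with n=300
        assert 6 <= rej <= 24

    def test_requires_complete_nuclei(self):
        table = synthetic_table(n_subjects=4)
        with pytest.raises(ValueError, match="all 7 nuclei"):
            nucleus_vs_rest_mixed(table[table["nucleus"] != "MD"], "Pu")


class TestAnovaRest:
    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(300):
            table = synthetic_table(n_subjects=8, rng=rng)
            _, p = anova_rest(table, excluding="Pu", value_column="delta_fc")
            ps.append(p)
        stat, ks_p = stats.kstest(ps, "uniform")
        assert ks_p > 0.01

    def test_planted_offsets_detected(self):
        rng = np.random.default_rng(8)
        hits = 0
        for _ in range(20):
            table = synthetic_table(
                n_subjects=8, nucleus_effects={"MD": 1.5, "VA": -1.5}, rng=rng
            )
            _, p = anova_rest(table, excluding="Pu", value_column="delta_fc")
            hits += p < 0.05
        assert hits >= 19

    def test_single_remaining_nucleus_rejected(self):
        table = synthetic_table(n_subjects=4)
        sub = table[table["nucleus"].isin(["Pu", "MD"])]
        with pytest.raises(ValueError, match="at least 2"):
            anova_rest(sub, excluding="Pu")


class TestPairwiseAndSubgroup:
    def test_pairwise_null_family_mostly_clean(self):
        rng = np.random.default_rng(9)
        clean = 0
        n_rep = 60
        for _ in range(n_rep):
            table = synthetic_table(n_subjects=8, rng=rng)
            pw = pairwise_target_vs_each(table, "Pu", value_column="delta_fc")
            clean += all(p > 0.05 for _, p in pw)
        assert clean / n_rep >= 0.9

    def test_pairwise_strong_target_all_significant(self):
        rng = np.random.default_rng(10)
        table = synthetic_table(
            n_subjects=16, nucleus_effects={"VLV": 3.0}, noise_sd=0.5, rng=rng
        )
        pw = pairwise_target_vs_each(table, "VLV", value_column="delta_fc")
        assert all(p < 0.05 for _, p in pw)

    def test_bh_correction_of_tied_raw_p_stays_tied(self):
        rng = np.random.default_rng(11)
        # construct a table whose 6 pairwise contrasts are identical
        table = synthetic_table(n_subjects=6, rng=rng)
        wide = table.pivot(index="subject", columns="nucleus",
                           values="delta_fc")
        for n in NUCLEUS_LABELS[1:]:
            wide[n] = wide[NUCLEUS_LABELS[1]]
        long = wide.reset_index().melt(
            id_vars="subject", var_name="nucleus", value_name="delta_fc"
        )
        long["z_delta_fc"] = long["delta_fc"]
        long["task_response"] = "n/a"
        pw = pairwise_target_vs_each(long, "Pu", value_column="delta_fc")
        ps = [p for _, p in pw]
        assert len(set(np.round(ps, 12))) == 1

    def test_identical_subgroups_give_large_p(self):
        rng = np.random.default_rng(12)
        base = synthetic_table(
            n_subjects=6, rng=rng,
            task_responses=["positive"] * 3 + ["negative"] * 3,
        )
        # make negative subjects exact copies of positive ones
        wide = base.pivot(index="subject", columns="nucleus", values="delta_fc")
        for i in range(3):
            wide.loc[f"S{i + 3:02d}"] = wide.loc[f"S{i:02d}"]
        long = wide.reset_index().melt(
            id_vars="subject", var_name="nucleus", value_name="delta_fc"
        )
        long["z_delta_fc"] = long["delta_fc"]
        long["task_response"] = [
            "positive" if s in [f"S{i:02d}" for i in range(3)] else "negative"
            for s in long["subject"]
        ]
        out = subgroup_delta_test(long)
        assert (out["p_fdr"] > 0.99).all()

    def test_planted_subgroup_difference_ranks_target_first(self):
        rng = np.random.default_rng(13)
        hits = 0
        for _ in range(20):
            table = synthetic_table(
                n_subjects=12, rng=rng,
                task_responses=["positive"] * 5 + ["negative"] * 7,
            )
            neg = table["task_response"] == "negative"
            vlv = table["nucleus"] == "VLV"
            table.loc[neg & vlv, "delta_fc"] += 4.0
            out = subgroup_delta_test(table)
            top = out.loc[out["difference"].abs().idxmax(), "nucleus"]
            hits += top == "VLV"
        assert hits >= 19
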