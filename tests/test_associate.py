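"""Group comparisons, trait correlations and cognitive-slope models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from csfnet.associate import (composite_cognition, differential_abundance,
                              fit_cognitive_slopes, leave_one_out_eigenprotein,
                              module_da_proportion, module_group_comparison,
                              trait_correlations)
from csfnet.containers import GREY, AbundanceMatrix, ModuleAssignment
from csfnet.network import module_eigenproteins
from csfnet.simulate import generate_cognition, generate_discovery_cohort


class TestCompositeCognition:
    def test_mean_of_domains(self):
        df = pd.DataFrame({"subject_id": ["A"], "visit_time": [0.0],
                           "memory": [1.0], "exec": [-1.0]})
        out = composite_cognition(df)
        assert out["global_z"].iloc[0] == 0.0

    def test_single_domain_passthrough(self):
        df = pd.DataFrame({"subject_id": ["A"], "visit_time": [0.0],
                           "memory": [0.7]})
        assert composite_cognition(df)["global_z"].iloc[0] == 0.7

    def test_available_case_mean_and_empty_visit_dropped(self):
        df = pd.DataFrame({
            "subject_id": ["A", "A"], "visit_time": [0.0, 1.0],
            "memory": [1.0, np.nan], "exec": [np.nan, np.nan],
            "lang": [3.0, np.nan]})
        out = composite_cognition(df)
        assert len(out) == 1
        assert out["global_z"].iloc[0] == 2.0


class TestCognitiveSlopes:
    def test_noiseless_trajectories_recovered_exactly(self, planted_small):
        _, md, truth = planted_small
        cog = generate_cognition(md, truth, resid_sd=0.0, n_visits=4, seed=0)
        est = fit_cognitive_slopes(cog, md)
        for subj in est.slopes.index:
            assert est.slopes[subj] == pytest.approx(truth.true_slopes[subj],
                                                     abs=1e-5)

    def test_recovery_under_noise_matches_design(self):
        # 120 subjects, 4 annual visits, slope spread ~0.15, residual SD 0.3
        _, md, truth = generate_discovery_cohort(
            n_proteins=60, n_samples=120, module_sizes=(30,), seed=5)
        cog = generate_cognition(md, truth, resid_sd=0.3, n_visits=4, seed=1)
        est = fit_cognitive_slopes(cog, md)
        joined = pd.concat([est.slopes, truth.true_slopes], axis=1).dropna()
        r = np.corrcoef(joined.iloc[:, 0], joined.iloc[:, 1])[0, 1]
        assert est.method == "lmm"
        assert r >= 0.85

    def test_recovery_improves_with_visit_count(self):
        _, md, truth = generate_discovery_cohort(
            n_proteins=60, n_samples=120, module_sizes=(30,), seed=8)
        rs = []
        for visits in (3, 5, 7):
            cog = generate_cognition(md, truth, resid_sd=0.5,
                                     n_visits=visits, seed=2)
            est = fit_cognitive_slopes(cog, md)
            joined = pd.concat([est.slopes, truth.true_slopes], axis=1).dropna()
            rs.append(np.corrcoef(joined.iloc[:, 0], joined.iloc[:, 1])[0, 1])
        assert rs[0] < rs[1] < rs[2]

    def test_single_visit_subjects_excluded(self, planted_small):
        _, md, truth = planted_small
        cog = generate_cognition(md, truth, n_visits=3, seed=0)
        lone = cog["subject_id"].iloc[0]
        cog = cog[~((cog["subject_id"] == lone) & (cog["visit_time"] > 0))]
        est = fit_cognitive_slopes(cog, md)
        assert est.n_excluded_single_visit == 1
        assert lone not in est.slopes.index


def _eigen_fixture(seed=0, shift=0.0, n_per_group=25):
    """Eigenprotein-like rows + metadata with a planted symptomatic shift."""
    rng = np.random.default_rng(seed)
    n = 3 * n_per_group
    status = (["control"] * n_per_group + ["presymptomatic"] * n_per_group
              + ["symptomatic"] * n_per_group)
    md = pd.DataFrame({
        "sample_id": [f"S{j}" for j in range(n)],
        "subject_id": [f"U{j}" for j in range(n)],
        "gene_group": ["control"] * n_per_group + ["GRN"] * (2 * n_per_group),
        "status": status,
        "age": rng.uniform(30, 75, n),
        "sex": rng.choice(["female", "male"], n),
    })
    e = rng.standard_normal(n)
    e[np.array(status) == "symptomatic"] += shift
    values = pd.DataFrame([e], index=["M1"], columns=md["sample_id"])
    from csfnet.containers import EigenproteinSet
    eig = EigenproteinSet(values, pd.Series({"M1": 0.5}),
                          pd.Series({"M1": 1}))
    return eig, md


class TestGroupComparison:
    def test_planted_shift_detected(self):
        eig, md = _eigen_fixture(seed=1, shift=1.0)
        table = module_group_comparison(eig, md)
        row = table[(table["group_a"] == "control")
                    & (table["group_b"] == "symptomatic")].iloc[0]
        assert row["p_tukey"] < 0.001
        assert row["diff"] < 0  # control minus symptomatic

    def test_tukey_familywise_error_calibrated(self):
        rng = np.random.default_rng(0)
        hits = 0
        n_sim = 1000
        for _ in range(n_sim):
            groups = [rng.standard_normal(20) for _ in range(3)]
            res = stats.tukey_hsd(*groups)
            if (res.pvalue[np.triu_indices(3, 1)] < 0.05).any():
                hits += 1
        assert abs(hits / n_sim - 0.05) <= 0.02

    def test_tukey_adjusted_p_not_below_t_test(self):
        eig, md = _eigen_fixture(seed=3, shift=0.4)
        table = module_group_comparison(eig, md, adjust=())
        e = eig.values.loc["M1"].to_numpy()
        status = md["status"].to_numpy()
        for _, row in table.iterrows():
            a = e[status == row["group_a"]]
            b = e[status == row["group_b"]]
            t_p = stats.ttest_ind(a, b).pvalue
            assert row["p_tukey"] >= t_p - 1e-12

    def test_constant_groups_give_null_boundary(self):
        from csfnet.associate import _anova_tukey
        values = np.zeros(30)
        groups = np.array(["control"] * 15 + ["symptomatic"] * 15)
        res = _anova_tukey(values, groups, ("control", "symptomatic"))
        assert res["F"] == 0.0 and res["p"] == 1.0
        assert res["pairs"][0]["p_tukey"] == 1.0

    def test_small_stratum_skipped(self):
        eig, md = _eigen_fixture(seed=2)
        md.loc[md["status"] == "presymptomatic", "status"] = "control"
        md.loc[md.index[:2], "status"] = "presymptomatic"
        table = module_group_comparison(eig, md)
        pairs = set(zip(table["group_a"], table["group_b"]))
        assert all("presymptomatic" not in p for pair in pairs for p in pair)


class TestTraitCorrelations:
    def test_monotone_transform_gives_rho_one(self):
        units = pd.DataFrame([np.arange(10.0)], index=["M1"],
                             columns=[f"S{j}" for j in range(10)])
        md = pd.DataFrame({"cdr_sb": np.exp(np.arange(10.0)),
                           "nfl": np.ones(10)},
                          index=[f"S{j}" for j in range(10)])
        table = trait_correlations(units, md, traits=("cdr_sb",))
        assert table.iloc[0]["rho"] == pytest.approx(1.0)

    def test_tied_trait_matches_midrank_formula(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0, 5.0, 3.0])
        y = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 8.0, 1.0, 6.0, 5.0, 4.0])
        units = pd.DataFrame([x], index=["M1"],
                             columns=[f"S{j}" for j in range(10)])
        md = pd.DataFrame({"cdr_sb": y, "nfl": np.ones(10)},
                          index=[f"S{j}" for j in range(10)])
        table = trait_correlations(units, md, traits=("cdr_sb",))

        def midrank(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j + 1 < len(v) and sv[j + 1] == sv[i]:
                    j += 1
                ranks[order[i:j + 1]] = (i + j) / 2 + 1
                i = j + 1
            return ranks

        expected = np.corrcoef(midrank(x), midrank(y))[0, 1]
        assert table.iloc[0]["rho"] == pytest.approx(expected, abs=1e-12)

    def test_null_trait_p_uniform(self):
        rng = np.random.default_rng(1)
        hits = 0
        n_sim = 1000
        for _ in range(n_sim):
            rho, p = stats.spearmanr(rng.standard_normal(30),
                                     rng.standard_normal(30))
            hits += p < 0.05
        assert abs(hits / n_sim - 0.05) <= 0.02

    def test_gene_stratified_runs_flagged_without_fdr(self):
        units = pd.DataFrame(np.random.default_rng(0).standard_normal((2, 20)),
                             index=["M1", "M2"],
                             columns=[f"S{j}" for j in range(20)])
        md = pd.DataFrame({"cdr_sb": np.random.default_rng(1).uniform(0, 10, 20),
                           "nfl": np.ones(20)},
                          index=[f"S{j}" for j in range(20)])
        table = trait_correlations(units, md, traits=("cdr_sb",),
                                   apply_fdr=False)
        assert (~table["fdr_applied"]).all()
        assert table["q"].isna().all()


@pytest.fixture(scope="module")
def da_setup():
    matrix, md, truth = generate_discovery_cohort(
            n_proteins=120, n_samples=150, module_sizes=(40,),
        group_effects={1: {"symptomatic": 1.0, "presymptomatic": 0.5}},
        seed=12)
    # plant a progranulin-like single-protein drop in both carrier stages
    target = matrix.protein_ids[-1]
    carrier = (md["status"] != "control").to_numpy()
    i = matrix.protein_ids.index(target)
    matrix.values[i, carrier] -= 1.5
    assignment = ModuleAssignment({
        p: f"M{truth.membership[p]}" if truth.membership[p] else GREY
        for p in matrix.protein_ids})
    table = differential_abundance(matrix, md, assignment=assignment,
                                   gene_stratified=False)
    return matrix, md, truth, target, assignment, table


class TestDifferentialAbundance:

    def test_planted_drop_is_extreme_in_both_contrasts(self, da_setup):
        *_, target, _, table = da_setup
        for stage in ("presymptomatic", "symptomatic"):
            sub = table[(table["group_a"] == "control")
                        & (table["group_b"] == stage)]
            row = sub.set_index("protein_id").loc[target]
            assert row["log2_diff"] == sub["log2_diff"].max()  # control - carrier
            assert row["log2_diff"] > 1.0

    def test_null_proteins_calibrated(self, da_setup):
        matrix, md, truth, target, _, table = da_setup
        null_ps = table[
            table["protein_id"].map(lambda p: truth.membership[p] == 0)
            & (table["protein_id"] != target)]["p_anova"]
        assert abs((null_ps < 0.05).mean() - 0.05) < 0.04

    def test_constant_protein_null_boundary(self):
        rng = np.random.default_rng(0)
        md = pd.DataFrame({
            "sample_id": [f"S{j}" for j in range(30)],
            "gene_group": ["control"] * 10 + ["GRN"] * 20,
            "status": ["control"] * 10 + ["presymptomatic"] * 10
                      + ["symptomatic"] * 10,
        })
        x = np.vstack([np.full(30, 2.0), rng.standard_normal(30)])
        m = AbundanceMatrix(x, ["P0", "P1"], ["P0", "P1"],
                            md["sample_id"].tolist())
        table = differential_abundance(m, md, gene_stratified=False)
        const = table[table["protein_id"] == "P0"]
        assert (const["log2_diff"] == 0).all()
        assert (const["p_tukey"] == 1.0).all()

    def test_module_da_proportion_peaks_in_planted_module(self, da_setup):
        _, _, truth, _, assignment, table = da_setup
        prop = module_da_proportion(table, assignment,
                                    contrast=("control", "symptomatic"))
        ranked = prop[prop["ranked"]]
        assert ranked.set_index("module")["fraction_da"].idxmax() == "M1"
        assert (prop[~prop["ranked"]]["module"] == GREY).all()

    def test_zero_threshold_gives_zero_fractions(self, da_setup):
        _, _, _, _, assignment, table = da_setup
        prop = module_da_proportion(table, assignment, threshold=0.0)
        assert (prop["fraction_da"] == 0).all()


class TestLeaveOneOut:
    def test_dropping_weak_member_barely_moves_eigenprotein(self, planted_small):
        matrix, _, truth = planted_small
        assignment = ModuleAssignment({
            p: f"M{truth.membership[p]}" if truth.membership[p] else GREY
            for p in matrix.protein_ids})
        full = module_eigenproteins(matrix, assignment)
        members = truth.module_proteins(1)
        weakest = min(members, key=lambda p: truth.loadings[p])
        loo = leave_one_out_eigenprotein(matrix, assignment, "M1", weakest)
        r = np.corrcoef(full.values.loc["M1"], loo.values.loc["M1"])[0, 1]
        assert r >= 0.99

    def test_outsider_protein_rejected(self, planted_small):
        matrix, _, truth = planted_small
        assignment = ModuleAssignment({
            p: f"M{truth.membership[p]}" if truth.membership[p] else GREY
            for p in matrix.protein_ids})
        outsider = truth.module_proteins(2)[0]
        with pytest.raises(ValueError, match="not a member"):
            leave_one_out_eigenprotein(matrix, assignment, "M1", outsider)

    def test_two_protein_module_rejected(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((2, 20))
        m = AbundanceMatrix(x, ["P0", "P1"], ["P0", "P1"],
                            [f"S{j}" for j in range(20)])
        a = ModuleAssignment({"P0": "M1", "P1": "M1"})
        with pytest.raises(ValueError, match="members"):
            leave_one_out_eigenprotein(m, a, "M1", "P0")
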