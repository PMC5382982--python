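import itertools

import numpy as np
import pandas as pd
import pytest

from rsnet.graphs import ConnectivityMatrix
from rsnet.stats import (
    GroupDesign,
    mixed_anova_global,
    nbs,
    nodal_auc_ttests,
    summarize_node_involvement,
)


def _design(n1, n2):
    ids = [f"l{i}" for i in range(n1)] + [f"s{i}" for i in range(n2)]
    return GroupDesign(tuple(ids), tuple(["lesion"] * n1 + ["sham"] * n2))


def _metric_table(rng, design, n_sp=10, offset=0.0):
    rows = []
    for sid, grp in zip(design.subject_ids, design.labels):
        base = rng.normal()
        for j in range(n_sp):
            val = base + rng.normal() + (offset if grp == "lesion" else 0.0)
            rows.append({"subject": sid, "group": grp, "sparsity": 0.05 * (j + 1), "value": val})
    return pd.DataFrame(rows)


def _null_matrices(rng, n_subj, n_nodes, t=120):
    mats = []
    for i in range(n_subj):
        z = rng.standard_normal((t, n_nodes))
        r = np.corrcoef(z, rowvar=False)
        np.fill_diagonal(r, 1.0)
        mats.append(ConnectivityMatrix(np.clip(r, -1, 1), subject_id=f"x{i}"))
    return mats


class TestGroupDesign:
    def test_counts(self):
        d = _design(13, 11)
        assert d.n_lesion == 13 and d.n_sham == 11 and d.n_subjects == 24

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            GroupDesign(("a", "b"), ("lesion", "lesion"))

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            GroupDesign(("a", "b"), ("lesion", "control"))


class TestMixedAnova:
    def test_hand_computed_sums_of_squares(self):
        """Balanced 2-subject-per-group, 2-sparsity table vs manual decomposition."""
        # subjects: l0 (3, 5), l1 (5, 7), s0 (2, 4), s1 (4, 8)
        data = {"l0": (3.0, 5.0), "l1": (5.0, 7.0), "s0": (2.0, 4.0), "s1": (4.0, 8.0)}
        rows = [
            {"subject": s, "group": "lesion" if s.startswith("l") else "sham",
             "sparsity": sp, "value": v}
            for s, vals in data.items()
            for sp, v in zip((0.1, 0.2), vals)
        ]
        res = mixed_anova_global(pd.DataFrame(rows))
        tab = res.table.set_index("Source")

        # manual two-factor mixed decomposition (a=2 groups, s=2 subjects each,
        # k=2 within levels); grand mean 4.75
        vals = np.array([[3, 5], [5, 7], [2, 4], [4, 8]], dtype=float)
        grand = vals.mean()
        subj_means = vals.mean(axis=1)
        group_means = np.array([vals[:2].mean(), vals[2:].mean()])
        sp_means = vals.mean(axis=0)
        k, s = 2, 2
        ss_group = k * s * ((group_means - grand) ** 2).sum()
        ss_subj_within = k * ((subj_means - np.repeat(group_means, s)) ** 2).sum()
        ss_sp = 2 * s * ((sp_means - grand) ** 2).sum()
        cell_means = np.array([vals[:2].mean(axis=0), vals[2:].mean(axis=0)])
        ss_inter = s * (
            (cell_means - group_means[:, None] - sp_means[None, :] + grand) ** 2
        ).sum()
        ss_total = ((vals - grand) ** 2).sum()
        ss_err_within = ss_total - ss_group - ss_subj_within - ss_sp - ss_inter

        f_group = (ss_group / 1) / (ss_subj_within / 2)
        f_sp = (ss_sp / 1) / (ss_err_within / 2)
        f_inter = (ss_inter / 1) / (ss_err_within / 2)
        assert tab.loc["group", "F"] == pytest.approx(f_group)
        assert tab.loc["sparsity", "F"] == pytest.approx(f_sp)
        assert tab.loc["interaction", "F"] == pytest.approx(f_inter)

    def test_single_sparsity_degenerates_to_t_test(self, rng):
        from scipy import stats as sstats

        d = _design(6, 5)
        df = _metric_table(rng, d, n_sp=1)
        res = mixed_anova_global(df)
        les = df[df.group == "lesion"]["value"]
        sha = df[df.group == "sham"]["value"]
        t, _ = sstats.ttest_ind(les, sha, equal_var=True)
        assert res.table["F"].iloc[0] == pytest.approx(t**2)

    def test_planted_offset_detected(self, rng):
        d = _design(10, 10)
        df = _metric_table(rng, d, offset=3.0)
        res = mixed_anova_global(df)
        p_group = res.table.set_index("Source").loc["group", "p_unc"]
        assert p_group < 0.01
        assert res.posthoc["significant"].any()

    def test_bonferroni_scales_posthoc_p(self, rng):
        d = _design(5, 5)
        res = mixed_anova_global(_metric_table(rng, d, n_sp=4))
        ph = res.posthoc
        np.testing.assert_allclose(
            ph["p_bonferroni"], np.minimum(1.0, ph["p_uncorrected"] * 4)
        )

    def test_missing_cell_rejected(self, rng):
        d = _design(3, 3)
        df = _metric_table(rng, d)
        df = df.iloc[:-1]  # drop one cell
        with pytest.raises(ValueError):
            mixed_anova_global(df)


class TestNodalTtests:
    def test_identical_groups_no_discoveries(self, rng):
        d = _design(5, 5)
        block = rng.standard_normal((5, 8))
        auc = pd.DataFrame(np.vstack([block, block]), index=list(d.subject_ids))
        res = nodal_auc_ttests(auc, d)
        np.testing.assert_allclose(res["t"], 0.0, atol=1e-12)
        assert not res["sig_uncorrected"].any()
        assert not res["sig_fdr"].any()

    @staticmethod
    def _bh_oracle(p):
        """Step-up BH q-values written out longhand."""
        p = np.asarray(p, dtype=float)
        order = np.argsort(p)
        q = np.empty_like(p)
        prev = 1.0
        for rank_from_end, idx in enumerate(order[::-1]):
            rank = p.size - rank_from_end
            prev = min(prev, p[idx] * p.size / rank)
            q[idx] = prev
        return q

    def test_bh_stepup_hand_example(self, rng):
        """q-values for p = (.01, .02, .03, .5) are (.04, .04, .04, .5)."""
        np.testing.assert_allclose(
            self._bh_oracle([0.01, 0.02, 0.03, 0.5]), [0.04, 0.04, 0.04, 0.5]
        )
        # and the implementation reproduces the longhand rule on real output
        d = _design(7, 7)
        auc = pd.DataFrame(rng.standard_normal((14, 12)), index=list(d.subject_ids))
        res = nodal_auc_ttests(auc, d)
        np.testing.assert_allclose(
            res["q_value"], self._bh_oracle(res["p_uncorrected"]), atol=1e-12
        )

    def test_q_values_dominate_p_and_are_monotone(self, rng):
        d = _design(8, 8)
        auc = pd.DataFrame(
            rng.standard_normal((16, 30)), index=list(d.subject_ids)
        )
        res = nodal_auc_ttests(auc, d)
        assert (res["q_value"] >= res["p_uncorrected"] - 1e-15).all()
        srt = res.sort_values("p_uncorrected")
        assert (np.diff(srt["q_value"]) >= -1e-15).all()

    def test_direction_codes_follow_group_means(self, rng):
        d = _design(6, 6)
        x = rng.standard_normal((12, 2))
        x[:6, 0] += 5.0  # lesion higher on node 0
        x[6:, 1] += 5.0  # sham higher on node 1
        auc = pd.DataFrame(x, index=list(d.subject_ids))
        res = nodal_auc_ttests(auc, d)
        assert res.loc[0, "direction"] == "I"
        assert res.loc[1, "direction"] == "D"

    def test_planted_reduction_power_at_paper_scale(self, rng):
        d = _design(13, 11)
        n_nodes, planted = 60, list(range(10))
        x = rng.standard_normal((24, n_nodes))
        x[:13, planted] -= 2.0  # strong reduction in the lesion group
        auc = pd.DataFrame(x, index=list(d.subject_ids))
        res = nodal_auc_ttests(auc, d)
        hits = res.loc[planted]
        n_detected = int((hits["sig_uncorrected"] & (hits["direction"] == "D")).sum())
        assert n_detected >= 8

    def test_zero_variance_everywhere_errors(self):
        d = _design(3, 3)
        auc = pd.DataFrame(np.ones((6, 4)), index=list(d.subject_ids))
        with pytest.raises(ValueError, match="zero-variance"):
            nodal_auc_ttests(auc, d)


class TestNbs:
    def test_threshold_above_max_t_gives_no_components(self, rng):
        mats = _null_matrices(rng, 12, 15)
        res = nbs(mats, _design(6, 6), primary_t=50.0, n_perm=100, seed=0)
        assert res.components == []
        assert res.p_fwer.size == 0

    def test_seed_determinism(self, rng):
        mats = _null_matrices(rng, 10, 12)
        d = _design(5, 5)
        a = nbs(mats, d, primary_t=2.0, n_perm=200, seed=7)
        b = nbs(mats, d, primary_t=2.0, n_perm=200, seed=7)
        np.testing.assert_array_equal(a.null_max_extent, b.null_max_extent)
        np.testing.assert_allclose(a.p_fwer, b.p_fwer)

    def test_label_swap_mirrors_tails(self, rng):
        """Swapping all group labels swaps the roles of the two one-sided tails."""
        mats = _null_matrices(rng, 10, 12)
        d = _design(5, 5)
        swapped = GroupDesign(
            d.subject_ids, tuple("sham" if g == "lesion" else "lesion" for g in d.labels)
        )
        a = nbs(mats, d, primary_t=2.0, n_perm=150, tail="lesion<sham", seed=3)
        b = nbs(mats, swapped, primary_t=2.0, n_perm=150, tail="lesion>sham", seed=3)
        assert sorted(a.extents.tolist()) == sorted(b.extents.tolist())

    def test_addone_permutation_convention(self, rng):
        mats = _null_matrices(rng, 10, 12)
        res = nbs(mats, _design(5, 5), primary_t=1.5, n_perm=100, seed=1)
        if res.p_fwer.size:
            assert (res.p_fwer >= 1 / 101).all()
            assert (res.p_fwer <= 1.0).all()

    def test_planted_block_recovered(self, rng):
        """A strongly reduced fully-connected 6-node block forms one significant component."""
        n_nodes, n1, n2 = 20, 10, 10
        block = list(range(6))
        mats = []
        for i in range(n1 + n2):
            z = np.random.default_rng(500 + i).standard_normal((200, n_nodes))
            if i < n1:  # lesion: decouple the block nodes from a shared factor
                z[:, block] += 0.2 * np.random.default_rng(900 + i).standard_normal((200, 1))
            else:
                z[:, block] += 1.5 * np.random.default_rng(900 + i).standard_normal((200, 1))
            r = np.corrcoef(z, rowvar=False)
            np.fill_diagonal(r, 1.0)
            mats.append(ConnectivityMatrix(np.clip(r, -1, 1), subject_id=f"x{i}"))
        res = nbs(mats, _design(n1, n2), primary_t=3.0, n_perm=500, seed=2)
        sig = res.significant(0.05)
        assert len(sig) >= 1
        comp = res.components[max(sig, key=lambda i: res.extents[i])]
        planted_edges = {tuple(e) for e in itertools.combinations(block, 2)}
        found = {tuple(sorted(map(int, e))) for e in comp}
        assert len(found & planted_edges) >= 0.8 * len(planted_edges)
        assert res.p_fwer[sig[0]] < 0.05

    def test_warns_on_small_permutation_space(self, rng):
        mats = _null_matrices(rng, 6, 8)
        with pytest.warns(UserWarning, match="distinct relabelings"):
            nbs(mats, _design(3, 3), primary_t=2.0, n_perm=100, seed=0)

    def test_invalid_primary_t(self, rng):
        mats = _null_matrices(rng, 10, 8)
        with pytest.raises(ValueError):
            nbs(mats, _design(5, 5), primary_t=0.0, n_perm=100)


class TestNodeInvolvement:
    def test_empty_result_all_zero(self):
        from rsnet.stats import NbsResult

        res = NbsResult(n_nodes=5, primary_t=3.0, tail="lesion<sham", n_perm=100)
        assert summarize_node_involvement(res).tolist() == [0] * 5

    def test_triangle_component_counts(self):
        from rsnet.stats import NbsResult

        comp = np.array([[0, 1], [1, 2], [0, 2]])
        res = NbsResult(
            n_nodes=4, primary_t=3.0, tail="lesion<sham", n_perm=100,
            components=[comp], extents=np.array([3]), p_fwer=np.array([0.01]),
        )
        assert summarize_node_involvement(res).tolist() == [2, 2, 2, 0]

    def test_matches_bruteforce_incidence(self, rng):
        from rsnet.stats import NbsResult

        edges = np.array([[0, 1], [0, 2], [3, 4], [1, 2]])
        res = NbsResult(
            n_nodes=6, primary_t=3.0, tail="lesion<sham", n_perm=100,
            components=[edges[:2], edges[2:]],
            extents=np.array([2, 2]),
            p_fwer=np.array([0.01, 0.2]),
        )
        counts = summarize_node_involvement(res, alpha=0.05)
        expected = np.zeros(6, dtype=int)
        for a, b in edges[:2]:  # only the significant component counts
            expected[a] += 1
            expected[b] += 1
        assert counts.tolist() == expected.tolist()
        assert counts.sum() == 2 * 2
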