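"""Descriptive summaries, nonparametric tests and table analogs."""

import numpy as np
import pandas as pd
import pytest

from carenet import metrics, networks, simulate, stats
from carenet.stats import UsageError

from conftest import make_messages, make_providers


class TestMedianIqr:
    def test_linear_interpolation_quartiles(self):
        d = stats.median_iqr([1, 2, 3, 4])
        assert (d.median, d.q25, d.q75) == (2.5, 1.75, 3.25)

    def test_constant_sample(self):
        d = stats.median_iqr([5, 5, 5])
        assert (d.median, d.q25, d.q75) == (5, 5, 5)

    def test_three_point_formatting_fixture(self):
        d = stats.median_iqr([0.4, 1.6, 6.6])
        assert d.median == pytest.approx(1.6)
        assert d.q25 <= d.median <= d.q75

    def test_empty_sample_rejected(self):
        with pytest.raises(UsageError):
            stats.median_iqr([])


class TestMannWhitney:
    def test_exact_enumeration_small_samples(self):
        cmp = stats.mann_whitney_u([1, 2], [3, 4])
        assert cmp.statistic == 0.0
        assert cmp.p_value == pytest.approx(1 / 3)

    def test_identical_samples_give_null_p(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert stats.mann_whitney_u(x, x).p_value >= 0.99

    def test_symmetric_in_sample_order(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=12), rng.normal(0.5, 1, size=15)
        assert stats.mann_whitney_u(x, y).p_value == pytest.approx(
            stats.mann_whitney_u(y, x).p_value
        )

    def test_empty_sample_rejected(self):
        with pytest.raises(UsageError):
            stats.mann_whitney_u([], [1.0])


class TestKruskalWallis:
    def test_identical_groups_null(self):
        cmp = stats.kruskal_wallis([[2, 2], [2, 2], [2, 2]])
        assert cmp.statistic == 0.0 and cmp.p_value == 1.0

    def test_hand_computed_h(self):
        cmp = stats.kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert cmp.statistic == pytest.approx(7.2)

    def test_requires_two_nonempty_groups(self):
        with pytest.raises(UsageError):
            stats.kruskal_wallis([[1.0, 2.0]])


class TestBonferroni:
    def test_scales_and_caps(self):
        assert stats.bonferroni_adjust([0.01, 0.5], 3) == [0.03, 1.0]

    def test_never_decreases(self):
        rng = np.random.default_rng(6)
        ps = rng.uniform(size=20)
        adj = stats.bonferroni_adjust(list(ps), 25)
        assert all(a >= p for a, p in zip(adj, ps))

    def test_m_must_cover_family(self):
        with pytest.raises(UsageError):
            stats.bonferroni_adjust([0.1, 0.2], 1)


class TestCategorical:
    def test_fisher_small_2x2(self):
        cmp = stats.categorical_association([[3, 1], [1, 3]])
        assert cmp.test == "fisher_exact"
        assert cmp.p_value == pytest.approx(0.4857, abs=1e-4)

    def test_chi_square_independent_table(self):
        cmp = stats.categorical_association([[10, 10], [10, 10]])
        assert cmp.test == "chi_square"
        assert cmp.statistic == 0.0 and cmp.p_value == 1.0

    def test_fisher_invariant_under_transposition(self):
        t = [[3, 1], [2, 4]]
        a = stats.categorical_association(t).p_value
        b = stats.categorical_association(np.array(t).T).p_value
        assert a == pytest.approx(b)

    def test_zero_margin_rejected(self):
        with pytest.raises(UsageError, match="margin"):
            stats.categorical_association([[0, 0], [3, 4]])


def _centrality_frame(role_values: dict[str, list[float]]) -> pd.DataFrame:
    rows = []
    for role, values in role_values.items():
        for i, v in enumerate(values):
            rows.append(
                {
                    "network_id": "net",
                    "provider_id": f"{role}{i}",
                    "role": role,
                    "degree": 1,
                    "betweenness": v,
                    "closeness": v,
                    "eigenvector": v,
                }
            )
    return pd.DataFrame(rows)


class TestCompareRoles:
    def test_disjoint_ranges_are_maximally_separated(self):
        frame = _centrality_frame(
            {
                "registered_nurse": list(np.linspace(0.0, 0.3, 30)),
                "physician": list(np.linspace(0.6, 0.9, 30)),
            }
        )
        res = stats.compare_roles_within_network(frame)
        assert (res.pairwise["adjusted_p"] < 0.001).all()

    def test_absent_role_skipped_with_warning(self):
        frame = _centrality_frame(
            {"registered_nurse": [0.1, 0.2, 0.3], "physician": [0.2, 0.1, 0.4]}
        )
        with pytest.warns(UserWarning, match="pharmacist"):
            res = stats.compare_roles_within_network(
                frame, roles=["registered_nurse", "physician", "pharmacist"]
            )
        assert res.skipped_roles == ["pharmacist"]

    def test_planted_frontline_boost_recovered(self):
        """Frontline providers given 3x activity weight end up with the
        highest eigenvector centrality, significantly above RN and MD."""
        cfg = simulate.default_config(seed=3)
        cfg.n_total_encounters = 400
        cfg.p_message_linked_encounter = 1.0
        cfg.base_rate = 0.3
        cfg.n_providers_by_role = {
            "registered_nurse": 120, "frontline_provider": 40, "physician": 30,
            "nursing_assistant": 35, "pharmacist": 18,
            "respiratory_therapist": 24, "other": 30,
        }
        cfg.role_activity_multiplier = {"frontline_provider": 3.0}
        cohort = simulate.generate_cohort(cfg)
        g = networks.build_global_network(cohort.messages, cohort.providers)
        table = metrics.centrality_table(g)
        res = stats.compare_roles_within_network(
            table, roles=["registered_nurse", "frontline_provider", "physician"]
        )
        eig = res.pairwise[res.pairwise["measure"] == "eigenvector"]
        flp_vs = eig[
            (eig["role_a"] == "frontline_provider")
            | (eig["role_b"] == "frontline_provider")
        ]
        assert (flp_vs["adjusted_p"] < 0.05).all()
        medians = table.groupby("role")["eigenvector"].median()
        assert medians["frontline_provider"] > medians["registered_nurse"]
        assert medians["frontline_provider"] > medians["physician"]


class TestCompareDetVsFree:
    def test_identical_strata_yield_null_p(self):
        a = _centrality_frame({"registered_nurse": [0.1, 0.2, 0.3, 0.4, 0.5]})
        a["network_id"] = "det"
        b = a.copy()
        b["network_id"] = "free"
        out = stats.compare_det_vs_free(pd.concat([a, b]), {"det"})
        assert (out["p_value"] >= 0.99).all()

    def test_role_absent_from_one_stratum_is_skipped(self):
        a = _centrality_frame({"registered_nurse": [0.1, 0.2]})
        a["network_id"] = "det"
        b = _centrality_frame({"pharmacist": [0.2, 0.3]})
        b["network_id"] = "free"
        out = stats.compare_det_vs_free(pd.concat([a, b]), {"det"})
        assert out["skipped"].all()

    def test_planted_frontline_cross_linking_detected(self):
        """Subnetworks where frontline providers both originate more
        messages and carry 3x activity weight show higher FLP eigenvector
        centrality than unperturbed subnetworks (100 vs ~1000 networks)."""

        def subnet_table(cfg, prefix):
            cohort = simulate.generate_cohort(cfg)
            subs = networks.build_encounter_subnetworks(
                cohort.messages, cohort.encounters, cohort.providers
            )
            frames = []
            for enc_id, g in sorted(subs.items()):
                t = metrics.centrality_table(g)
                t["network_id"] = prefix + enc_id
                frames.append(t)
            return pd.concat(frames, ignore_index=True)

        base = simulate.default_config(seed=11)
        base.base_rate = 0.08
        base.n_total_encounters = 1000
        base.p_message_linked_encounter = 1.0
        base.p_deterioration = 0.0

        boosted = simulate.default_config(seed=12)
        boosted.base_rate = 0.08
        boosted.n_total_encounters = 100
        boosted.p_message_linked_encounter = 1.0
        boosted.p_deterioration = 0.0
        boosted.role_activity_multiplier = {"frontline_provider": 3.0}
        boosted.sender_share_by_role = {
            "registered_nurse": 0.20, "frontline_provider": 0.55,
            "physician": 0.07, "nursing_assistant": 0.05, "pharmacist": 0.04,
            "respiratory_therapist": 0.04, "other": 0.05,
        }

        pooled = pd.concat(
            [subnet_table(base, "free_"), subnet_table(boosted, "det_")],
            ignore_index=True,
        )
        det_ids = {n for n in pooled["network_id"] if n.startswith("det_")}
        out = stats.compare_det_vs_free(pooled, det_ids)
        row = out[
            (out["role"] == "frontline_provider")
            & (out["measure"] == "eigenvector")
        ].iloc[0]
        assert row["median_det"] > row["median_free"]
        assert row["p_value"] < 0.05


class TestCompareEpochs:
    def _tables(self, per_window_nodes):
        sum_rows, cent_rows = [], []
        for win, node_counts in per_window_nodes.items():
            for i, n in enumerate(node_counts):
                sum_rows.append(
                    {
                        "window": str(win),
                        "network_id": f"{win}-{i}",
                        "n_nodes": n,
                        "n_edges": n + 1,
                        "clustering": 0.0,
                        "diameter": 2,
                        "radius": 1,
                    }
                )
                for j in range(3):
                    cent_rows.append(
                        {
                            "window": str(win),
                            "network_id": f"{win}-{i}",
                            "provider_id": f"p{j}",
                            "role": "registered_nurse",
                            "degree": 1,
                            "betweenness": 0.0,
                            "closeness": 0.5,
                            "eigenvector": 0.5,
                        }
                    )
        return pd.DataFrame(sum_rows), pd.DataFrame(cent_rows)

    def test_shared_fixture_across_windows_gives_p_one(self):
        windows = [(-36.0, -24.0), (-24.0, -12.0), (-12.0, 0.0)]
        summaries, cents = self._tables({w: [5, 5, 5] for w in windows})
        out = stats.compare_epochs(summaries, cents)
        network_rows = out[out["level"] == "network"]
        assert (network_rows["p_value"] == 1.0).all()

    def test_window_without_subnetworks_dropped_with_warning(self):
        windows = [(-24.0, -12.0), (-12.0, 0.0)]
        summaries, cents = self._tables({w: [4, 5, 6] for w in windows})
        with pytest.warns(UserWarning, match="-36"):
            out = stats.compare_epochs(summaries, cents)
        assert not out.empty


class TestCohortSummary:
    def test_printed_arithmetic_reproduced(self):
        s = stats.cohort_summary_from_counts(
            n_total_encounters=9305,
            n_linked_encounters=4328,
            n_det_encounters=120,
            cohort_days_det=3568,
            cohort_days_total=42369,
            msgs_det=105648,
            msgs_total=1065225,
            n_post_only=14,
        )
        assert s.display["pct_linked"] == 47
        assert s.display["pct_days"] == 8.4
        assert s.display["pct_msgs"] == 9.9
        assert s.n_subnetworks_analyzed == 4314

    def test_raw_proportions_are_exact(self):
        s = stats.cohort_summary_from_counts(9305, 4328, 120, 3568, 42369,
                                             105648, 1065225, 14)
        assert s.pct_linked == 100 * 4328 / 9305
        assert s.pct_days == 100 * 3568 / 42369
        assert s.pct_msgs == 100 * 105648 / 1065225
        assert s.pct_det_of_linked == 100 * 120 / 4328

    def test_zero_denominator_reported_missing(self):
        s = stats.cohort_summary_from_counts(0, 0, 0, 0, 0, 0, 0, 0)
        assert s.pct_linked is None and s.pct_days is None

    def test_summary_from_cohort_consistent(self, small_cohort):
        s = stats.cohort_summary(small_cohort)
        assert s.n_total_encounters == len(small_cohort.encounters)
        assert s.msgs_total == len(small_cohort.messages)
        assert 0 <= s.pct_det_of_linked <= 100


class TestRoleFlow:
    def test_single_message_two_recipients(self):
        providers = make_providers(
            {"rn": "registered_nurse", "f1": "frontline_provider",
             "f2": "frontline_provider"}
        )
        msgs = make_messages([("m1", "2022-10-01T08:00", "rn", ["f1", "f2"], "e1")])
        flow = stats.role_flow_matrix(msgs, providers)
        assert flow.pair_counts.loc["registered_nurse", "frontline_provider"] == 2
        assert flow.sender_share["registered_nurse"] == 1.0
        assert flow.n_messages == 1 and flow.n_pairs == 2

    def test_cell_sum_equals_delivered_pairs(self, small_cohort):
        flow = stats.role_flow_matrix(
            small_cohort.messages, small_cohort.providers
        )
        delivered = sum(len(r) for r in small_cohort.messages["recipient_ids"])
        assert int(flow.pair_counts.to_numpy().sum()) == delivered == flow.n_pairs

    def test_sender_share_tracks_generator_mix(self, default_cohort):
        flow = stats.role_flow_matrix(
            default_cohort.messages, default_cohort.providers
        )
        assert flow.sender_share["registered_nurse"] == pytest.approx(0.35, abs=0.02)
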