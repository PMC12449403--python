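"""Descriptive and comparative statistics for the network analysis.

Continuous quantities are summarized as median (25th, 75th percentile)
with linear-interpolation quantiles. Two-group comparisons use the
Mann-Whitney U test (exact enumeration for small tie-free samples, normal
approximation with tie and continuity corrections otherwise); multi-group
comparisons use Kruskal-Wallis with tie correction; families of pairwise
tests are Bonferroni-adjusted by the number of comparisons actually
performed. Categorical associations use chi-square, switching to Fisher's
exact test for 2×2 tables with any expected cell below 5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import Cohort
from .networks import EpochSpec


class UsageError(ValueError):
    pass


@dataclass
class DescriptiveSummary:
    label: str
    n: int
    median: float
    q25: float
    q75: float


@dataclass
class GroupComparison:
    test: str
    statistic: float
    p_value: float
    adjusted_p: Optional[float] = None
    group_summaries: list[DescriptiveSummary] = field(default_factory=list)


def median_iqr(values: Sequence[float], label: str = "") -> DescriptiveSummary:
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise UsageError("median_iqr requires a nonempty sample")
    q25, med, q75 = np.percentile(arr, [25, 50, 75])  # linear interpolation
    return DescriptiveSummary(label, int(arr.size), float(med), float(q25), float(q75))


# ---------------------------------------------------------------------------
# Hypothesis tests
# ---------------------------------------------------------------------------


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> GroupComparison:
    """Two-sided Mann-Whitney U; U reported for the first sample.

    ``mode='auto'`` uses exact enumeration when both samples have n <= 8
    and the pooled data is tie-free, otherwise the normal approximation
    with tie correction and continuity correction.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise UsageError("both samples must be nonempty")
    if mode not in ("auto", "exact", "approx"):
        raise UsageError(f"unknown mode '{mode}'")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == pooled.size
    if mode == "exact" or (mode == "auto" and x.size <= 8 and y.size <= 8 and no_ties):
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return GroupComparison(
        test="mann_whitney_u",
        statistic=float(res.statistic),
        p_value=float(min(1.0, res.pvalue)),
        group_summaries=[median_iqr(x, "x"), median_iqr(y, "y")],
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> GroupComparison:
    """Tie-corrected H with chi-square p (k−1 df); all-identical data → H=0, p=1."""
    arrays = [np.asarray(list(g), dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise UsageError("kruskal_wallis requires >= 2 nonempty groups")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*arrays)
    return GroupComparison(
        test="kruskal_wallis",
        statistic=float(h),
        p_value=float(p),
        group_summaries=[median_iqr(a, str(i)) for i, a in enumerate(arrays)],
    )


def bonferroni_adjust(p_values: Sequence[float], m: int) -> list[float]:
    """min(1, p·m) elementwise; m must cover the family size."""
    ps = list(p_values)
    if m < len(ps):
        raise UsageError("m must be >= number of p-values")
    return [min(1.0, p * m) for p in ps]


def categorical_association(table: Sequence[Sequence[float]]) -> GroupComparison:
    """Chi-square (no continuity correction), or Fisher's exact two-sided
    for 2×2 tables with any expected count < 5."""
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or (tab < 0).any():
        raise UsageError("table must be a 2-way nonnegative count table")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise UsageError("degenerate table: a margin is zero")
    expected = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tab.sum()
    if tab.shape == (2, 2) and (expected < 5).any():
        stat, p = sps.fisher_exact(tab, alternative="two-sided")
        name = "fisher_exact"
    else:
        stat, p, _, _ = sps.chi2_contingency(tab, correction=False)
        name = "chi_square"
    return GroupComparison(test=name, statistic=float(stat), p_value=float(p))


# ---------------------------------------------------------------------------
# Role-stratified comparisons
# ---------------------------------------------------------------------------

CENTRALITY_MEASURES = ("betweenness", "closeness", "eigenvector")


@dataclass
class RoleComparisonResult:
    kruskal: pd.DataFrame
    pairwise: pd.DataFrame
    skipped_roles: list[str] = field(default_factory=list)


def compare_roles_within_network(
    centralities: pd.DataFrame,
    roles: Sequence[str] | None = None,
    measures: Sequence[str] = CENTRALITY_MEASURES,
) -> RoleComparisonResult:
    """Kruskal-Wallis across roles per measure, then pairwise Mann-Whitney
    with Bonferroni over the pairs actually tested (per measure family)."""
    roles = list(roles) if roles is not None else sorted(centralities["role"].unique())
    present, skipped = [], []
    for role in roles:
        if (centralities["role"] == role).any():
            present.append(role)
        else:
            skipped.append(role)
            warnings.warn(f"role '{role}' has no nodes; skipped")
    if len(present) < 2:
        raise UsageError("need >= 2 roles with nodes")

    kw_rows, pair_rows = [], []
    for measure in measures:
        samples = {
            r: centralities.loc[centralities["role"] == r, measure].to_numpy()
            for r in present
        }
        kw = kruskal_wallis([samples[r] for r in present])
        kw_rows.append(
            {"measure": measure, "H": kw.statistic, "p_value": kw.p_value}
        )
        pairs = [
            (a, b) for i, a in enumerate(present) for b in present[i + 1:]
        ]
        raw = []
        for a, b in pairs:
            mw = mann_whitney_u(samples[a], samples[b])
            raw.append((a, b, mw))
        adjusted = bonferroni_adjust([mw.p_value for _, _, mw in raw], len(pairs))
        for (a, b, mw), adj in zip(raw, adjusted):
            pair_rows.append(
                {
                    "measure": measure,
                    "role_a": a,
                    "role_b": b,
                    "median_a": mw.group_summaries[0].median,
                    "median_b": mw.group_summaries[1].median,
                    "U": mw.statistic,
                    "p_value": mw.p_value,
                    "adjusted_p": adj,
                    "m": len(pairs),
                }
            )
    return RoleComparisonResult(
        kruskal=pd.DataFrame(kw_rows),
        pairwise=pd.DataFrame(pair_rows),
        skipped_roles=skipped,
    )


def compare_det_vs_free(
    centralities: pd.DataFrame,
    det_network_ids: set[str],
    measures: Sequence[str] = CENTRALITY_MEASURES,
) -> pd.DataFrame:
    """Node-level deterioration vs deterioration-free comparison by role.

    ``centralities`` pools per-encounter node rows (one observation per
    node per subnetwork); ``det_network_ids`` flags the networks built from
    pre-deterioration messages (post-only encounters must already have been
    excluded upstream). Roles absent from either stratum are recorded as
    skipped rows rather than tested.
    """
    is_det = centralities["network_id"].isin(det_network_ids)
    rows = []
    for role in sorted(centralities["role"].unique()):
        sel = centralities["role"] == role
        det_vals = centralities.loc[sel & is_det]
        free_vals = centralities.loc[sel & ~is_det]
        for measure in measures:
            if det_vals.empty or free_vals.empty:
                rows.append({"role": role, "measure": measure, "skipped": True})
                continue
            mw = mann_whitney_u(det_vals[measure], free_vals[measure])
            d, f = mw.group_summaries
            rows.append(
                {
                    "role": role,
                    "measure": measure,
                    "skipped": False,
                    "n_det": d.n,
                    "median_det": d.median,
                    "q25_det": d.q25,
                    "q75_det": d.q75,
                    "n_free": f.n,
                    "median_free": f.median,
                    "q25_free": f.q25,
                    "q75_free": f.q75,
                    "U": mw.statistic,
                    "p_value": mw.p_value,
                }
            )
    return pd.DataFrame(rows)


def compare_epochs(
    summaries: pd.DataFrame,
    centralities: pd.DataFrame,
    epochs: EpochSpec | None = None,
) -> pd.DataFrame:
    """Kruskal-Wallis across epoch windows.

    ``summaries`` has one row per (encounter, window) subnetwork with
    columns window, n_nodes, n_edges, clustering, diameter, radius;
    ``centralities`` pools node rows with a ``window`` column. Network-level
    and node-level variables are tested across windows; windows with zero
    subnetworks are dropped with a warning.
    """
    epochs = epochs or EpochSpec()
    windows = [w for w in epochs.windows]
    present = [w for w in windows if (summaries["window"] == str(w)).any()]
    for w in windows:
        if w not in present:
            warnings.warn(f"window {w} has no subnetworks; dropped")
    if len(present) < 2:
        raise UsageError("need >= 2 windows with subnetworks")

    rows = []
    network_vars = ["n_nodes", "n_edges", "clustering", "diameter", "radius"]
    for var in network_vars:
        groups = [
            summaries.loc[summaries["window"] == str(w), var].to_numpy()
            for w in present
        ]
        kw = kruskal_wallis(groups)
        row = {"variable": var, "level": "network", "H": kw.statistic,
               "p_value": kw.p_value}
        for w, s in zip(present, kw.group_summaries):
            row[f"n {w}"] = s.n
            row[f"median {w}"] = s.median
            row[f"q25 {w}"] = s.q25
            row[f"q75 {w}"] = s.q75
        rows.append(row)
    for var in CENTRALITY_MEASURES:
        groups = [
            centralities.loc[centralities["window"] == str(w), var].to_numpy()
            for w in present
        ]
        if any(g.size == 0 for g in groups):
            continue
        kw = kruskal_wallis(groups)
        row = {"variable": var, "level": "node", "H": kw.statistic,
               "p_value": kw.p_value}
        for w, s in zip(present, kw.group_summaries):
            row[f"n {w}"] = s.n
            row[f"median {w}"] = s.median
            row[f"q25 {w}"] = s.q25
            row[f"q75 {w}"] = s.q75
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohort summary and role flows
# ---------------------------------------------------------------------------


@dataclass
class CohortSummary:
    n_total_encounters: int
    n_linked_encounters: int
    pct_linked: Optional[float]  # raw percent
    n_det_encounters: int
    pct_det_of_linked: Optional[float]
    cohort_days_det: float
    cohort_days_total: float
    pct_days: Optional[float]
    msgs_det: int
    msgs_total: int
    pct_msgs: Optional[float]
    n_subnetworks_analyzed: int
    n_subnetworks_excluded_post_only: int

    @property
    def display(self) -> dict[str, Optional[float]]:
        """Percentages at printed precision: integer for encounter linkage,
        one decimal elsewhere. Raw values stay on the dataclass."""
        def r(v, nd):
            return None if v is None else round(v, nd) if nd else round(v)
        return {
            "pct_linked": r(self.pct_linked, 0),
            "pct_det_of_linked": r(self.pct_det_of_linked, 1),
            "pct_days": r(self.pct_days, 1),
            "pct_msgs": r(self.pct_msgs, 1),
        }


def _pct(num: float, den: float) -> Optional[float]:
    return None if den == 0 else 100.0 * num / den


def cohort_summary_from_counts(
    n_total_encounters: int,
    n_linked_encounters: int,
    n_det_encounters: int,
    cohort_days_det: float,
    cohort_days_total: float,
    msgs_det: int,
    msgs_total: int,
    n_post_only: int,
) -> CohortSummary:
    """Assemble the summary directly from the bookkeeping counts."""
    return CohortSummary(
        n_total_encounters=n_total_encounters,
        n_linked_encounters=n_linked_encounters,
        pct_linked=_pct(n_linked_encounters, n_total_encounters),
        n_det_encounters=n_det_encounters,
        pct_det_of_linked=_pct(n_det_encounters, n_linked_encounters),
        cohort_days_det=cohort_days_det,
        cohort_days_total=cohort_days_total,
        pct_days=_pct(cohort_days_det, cohort_days_total),
        msgs_det=msgs_det,
        msgs_total=msgs_total,
        pct_msgs=_pct(msgs_det, msgs_total),
        n_subnetworks_analyzed=n_linked_encounters - n_post_only,
        n_subnetworks_excluded_post_only=n_post_only,
    )


def cohort_summary(cohort: Cohort, n_post_only: int = 0) -> CohortSummary:
    """Compute the summary from a cohort; hospital days = (discharge−admit)."""
    enc = cohort.encounters
    linked_ids = {
        e for e in cohort.messages["encounter_id"] if e is not None
    } & set(enc["encounter_id"])
    det_ids = {
        r.encounter_id
        for r in enc.itertuples(index=False)
        if r.deterioration_times and r.encounter_id in linked_ids
    }
    days = {
        r.encounter_id: (r.discharge_at - r.admit_at).total_seconds() / 86400.0
        for r in enc.itertuples(index=False)
    }
    linked_msgs = cohort.messages["encounter_id"].isin(linked_ids)
    det_msgs = cohort.messages["encounter_id"].isin(det_ids)
    return cohort_summary_from_counts(
        n_total_encounters=cohort.n_total_encounters,
        n_linked_encounters=len(linked_ids),
        n_det_encounters=len(det_ids),
        cohort_days_det=sum(days[e] for e in det_ids),
        cohort_days_total=sum(days[e] for e in linked_ids),
        msgs_det=int(det_msgs.sum()),
        msgs_total=int(linked_msgs.sum()),
        n_post_only=n_post_only,
    )


@dataclass
class RoleFlowMatrix:
    pair_counts: pd.DataFrame  # sender role × recipient role, delivered pairs
    sender_share: pd.Series  # over messages (each message once)
    recipient_share: pd.Series  # over delivered pairs
    n_messages: int
    n_pairs: int


def role_flow_matrix(messages: pd.DataFrame, providers: pd.DataFrame) -> RoleFlowMatrix:
    """Role→role delivered-pair counts plus the two marginal framings."""
    role_of = dict(zip(providers["provider_id"], providers["role"]))
    roles = sorted(set(role_of.values()))
    sender_roles = np.array(
        [role_of.get(s, "other") for s in messages["sender_id"]], dtype=object
    )
    rec_lists = list(messages["recipient_ids"])
    lengths = np.array([len(r) for r in rec_lists], dtype=np.int64)
    pair_senders = np.repeat(sender_roles, lengths)
    pair_recipients = np.array(
        [role_of.get(r, "other") for lst in rec_lists for r in lst], dtype=object
    )
    mat = pd.DataFrame(0, index=roles, columns=roles, dtype=int)
    if len(pair_senders):
        ct = pd.crosstab(pd.Series(pair_senders), pd.Series(pair_recipients))
        mat = ct.reindex(index=roles, columns=roles, fill_value=0).astype(int)
    n_pairs = int(lengths.sum())
    n_messages = len(messages)
    counts = pd.Series(sender_roles).value_counts()
    sender_share = counts.reindex(roles, fill_value=0).astype(float)
    if n_messages:
        sender_share /= n_messages
    recipient_share = mat.sum(axis=0).astype(float)
    if n_pairs:
        recipient_share /= n_pairs
    return RoleFlowMatrix(
        pair_counts=mat,
        sender_share=sender_share,
        recipient_share=recipient_share,
        n_messages=n_messages,
        n_pairs=n_pairs,
    )
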