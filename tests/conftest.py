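import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helpers

from carenet import simulate
from carenet.networks import ProviderGraph


@pytest.fixture(scope="session")
def default_cohort():
    """A full default-configuration cohort (>=100k messages), shared."""
    return simulate.generate_cohort(simulate.default_config(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    cfg = simulate.default_config(seed=7)
    cfg.n_total_encounters = 60
    cfg.p_message_linked_encounter = 1.0
    cfg.p_deterioration = 0.25
    cfg.base_rate = 0.3
    return simulate.generate_cohort(cfg)


def make_messages(rows):
    """rows: (message_id, sent_at str, sender, recipients list, encounter)."""
    return pd.DataFrame(
        {
            "message_id": [r[0] for r in rows],
            "sent_at": [pd.Timestamp(r[1]) for r in rows],
            "sender_id": [r[2] for r in rows],
            "recipient_ids": [list(r[3]) for r in rows],
            "encounter_id": [r[4] for r in rows],
            "minutes_to_first_read": [1.0] * len(rows),
            "char_count": [10] * len(rows),
        }
    )


def make_providers(role_map):
    return pd.DataFrame(
        {"provider_id": list(role_map), "role": list(role_map.values())}
    )


def make_encounter(encounter_id, admit, discharge, deteriorations=()):
    return pd.Series(
        {
            "encounter_id": encounter_id,
            "admit_at": pd.Timestamp(admit),
            "discharge_at": pd.Timestamp(discharge),
            "deterioration_times": [pd.Timestamp(t) for t in deteriorations],
            "indication": None,
            "activating_service": None,
        }
    )


def graph_from_edges(edges, roles=None):
    g = ProviderGraph(network_id="fixture")
    for (u, v), w in edges.items():
        g.edges[(u, v)] = w
        g.roles.setdefault(u, "other")
        g.roles.setdefault(v, "other")
    if roles:
        g.roles.update(roles)
    return g


def path_graph(labels):
    edges = {}
    for a, b in zip(labels, labels[1:]):
        edges[(a, b)] = 1
    return graph_from_edges(edges)


def star_graph(n_leaves):
    edges = {("hub", f"leaf{i}"): 1 for i in range(n_leaves)}
    return graph_from_edges(edges)
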