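"""Seeded synthetic message-log generator.

Emulates the statistical structure of inpatient secure-messaging metadata
around clinical deterioration events so the whole analysis pipeline can be
exercised without access to hospital data:

* a shared provider pool with heavy-tailed (Pareto) activity weights, so
  the same high-activity providers recur across encounters and the global
  network acquires high-degree hubs;
* encounters with lognormal lengths of stay; a fraction are linked to
  messaging at all, and a small fraction of those experience a clinical
  deterioration (rapid-response / code activation) at a lognormal time
  after admission, resampled to fall within the stay;
* messages emitted as a homogeneous Poisson process per encounter-hour,
  with the rate stepped up by ``escalation_multiplier`` inside the
  ``escalation_window_h`` hours before Time 0 (the deterioration time);
* sender roles drawn from the observed sender-share mix (registered nurses
  dominate), recipients drawn without replacement from the encounter's
  care team, proportionally to provider activity weight.

Everything is driven by one ``numpy`` Generator seeded once, so the same
seed and config reproduce the cohort byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .model import Cohort, ROLES

MINUTES_PER_DAY = 1440.0


class ConfigurationError(ValueError):
    """The simulation configuration is internally infeasible."""


def _default_providers() -> dict[str, int]:
    # 800 providers at the observed role mix: RN 41%, frontline 13%,
    # physician 10%; remainder split across the supporting roles.
    return {
        "registered_nurse": 328,
        "frontline_provider": 104,
        "physician": 80,
        "nursing_assistant": 96,
        "pharmacist": 48,
        "respiratory_therapist": 64,
        "other": 80,
    }


def _default_sender_shares() -> dict[str, float]:
    # RN 35% and frontline 29% of message originations are observed values;
    # the remaining 36% is spread across the other roles.
    return {
        "registered_nurse": 0.35,
        "frontline_provider": 0.29,
        "physician": 0.10,
        "nursing_assistant": 0.08,
        "pharmacist": 0.05,
        "respiratory_therapist": 0.05,
        "other": 0.08,
    }


def _default_team_sizes() -> dict[str, int]:
    return {
        "registered_nurse": 5,
        "frontline_provider": 3,
        "physician": 2,
        "nursing_assistant": 2,
        "pharmacist": 1,
        "respiratory_therapist": 1,
        "other": 1,
    }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults are calibrated to the study conditions: 47% of encounters
    linked to messaging, deterioration prevalence 120/4328 ≈ 2.8% of linked
    encounters, admission-to-deterioration time lognormal with median
    1.6 days and sigma 2.1 (so that exp(±0.6745·σ)·1.6 reproduces the
    observed IQR 0.4–6.6 days), RN sender share 35% / frontline 29%, and a
    base messaging rate of one message per encounter-hour (≈25/day, the
    cohort-level message volume per hospital day).
    """

    seed: int = 0
    n_providers_by_role: dict[str, int] = field(default_factory=_default_providers)
    n_total_encounters: int = 1000
    p_message_linked_encounter: float = 0.47
    p_deterioration: float = 120 / 4328
    los_log_mean: float = math.log(5.9)  # median LOS 5.9 d -> mean ~9.8 d
    los_log_sd: float = 1.0
    det_time_log_median: float = 1.6  # days, admission -> deterioration
    det_time_log_sd: float = 2.1
    sender_share_by_role: dict[str, float] = field(
        default_factory=_default_sender_shares
    )
    base_rate: float = 1.0  # messages per encounter-hour
    escalation_multiplier: float = 2.0
    escalation_window_h: float = 12.0
    recipient_count_p: float = 0.6  # geometric, support >= 1
    team_size_by_role: dict[str, int] = field(default_factory=_default_team_sizes)
    activity_shape: float = 1.5  # Pareto tail exponent of activity weights
    role_activity_multiplier: dict[str, float] = field(default_factory=dict)
    start_date: str = "2022-10-01"
    study_days: int = 365
    char_count_log_median: float = 40.0
    char_count_log_sd: float = 0.8
    read_minutes_log_median: float = 2.0
    read_minutes_log_sd: float = 1.2
    p_read_missing: float = 0.05

    def validate(self) -> None:
        for name in ("p_message_linked_encounter", "p_deterioration",
                     "recipient_count_p", "p_read_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if abs(sum(self.sender_share_by_role.values()) - 1.0) > 1e-9:
            raise ConfigurationError("sender_share_by_role must sum to 1")
        if self.n_total_encounters <= 0:
            raise ConfigurationError("n_total_encounters must be positive")
        if any(v < 0 for v in self.n_providers_by_role.values()):
            raise ConfigurationError("provider counts must be non-negative")
        team_total = sum(self.team_size_by_role.values())
        if team_total < 2:
            raise ConfigurationError("care team must have at least 2 members")
        for role, share in self.sender_share_by_role.items():
            if share > 0 and self.team_size_by_role.get(role, 0) < 1:
                raise ConfigurationError(
                    f"role '{role}' sends messages but has no team slot"
                )
            if share > 0 and self.n_providers_by_role.get(role, 0) < 1:
                raise ConfigurationError(
                    f"role '{role}' sends messages but has no providers"
                )
        for role, size in self.team_size_by_role.items():
            if size > self.n_providers_by_role.get(role, 0):
                raise ConfigurationError(
                    f"team size for '{role}' exceeds provider pool"
                )
        if self.base_rate <= 0 or self.escalation_multiplier <= 0:
            raise ConfigurationError("rates must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        return cls(**data)


def default_config(seed: int = 0) -> SimulationConfig:
    """The documented default configuration (deterministic)."""
    return SimulationConfig(seed=seed)


def load_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return SimulationConfig.from_dict(data)


def save_config(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Sampling helpers
# ---------------------------------------------------------------------------


def sample_time_to_deterioration(
    config: SimulationConfig, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw admission-to-deterioration intervals (days), untruncated."""
    return rng.lognormal(
        mean=math.log(config.det_time_log_median),
        sigma=config.det_time_log_sd,
        size=n,
    )


def _weighted_sample_without_replacement(
    weights: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Indices of k items, weight-proportional, without replacement
    (Efraimidis–Spirakis via Gumbel keys)."""
    keys = np.log(weights) + rng.gumbel(size=len(weights))
    return np.argpartition(-keys, k - 1)[:k] if k < len(weights) else np.arange(len(weights))


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Generate a full synthetic cohort. Same config + seed → identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    # (1) providers with Pareto activity weights
    roles_present = [r for r in ROLES if config.n_providers_by_role.get(r, 0) > 0]
    provider_rows = []
    for role in roles_present:
        for _ in range(config.n_providers_by_role[role]):
            provider_rows.append({"provider_id": f"p{len(provider_rows) + 1:05d}",
                                  "role": role})
    providers = pd.DataFrame(provider_rows, columns=["provider_id", "role"])
    n_prov = len(providers)
    weights = 1.0 + rng.pareto(config.activity_shape, size=n_prov)
    role_mult = np.array(
        [config.role_activity_multiplier.get(r, 1.0) for r in providers["role"]]
    )
    weights = weights * role_mult
    idx_by_role = {
        role: np.flatnonzero((providers["role"] == role).to_numpy())
        for role in roles_present
    }

    # (2) encounters
    start_min = int(pd.Timestamp(config.start_date).value // 60_000_000_000)
    n_enc = config.n_total_encounters
    admit_min = start_min + rng.integers(0, config.study_days * 1440, size=n_enc)
    los_days = rng.lognormal(config.los_log_mean, config.los_log_sd, size=n_enc)
    los_min = np.maximum(60, np.rint(los_days * MINUTES_PER_DAY).astype(np.int64))
    linked = rng.random(n_enc) < config.p_message_linked_encounter

    indications = np.array(["respiratory", "seizure", "sepsis", "other"])
    indication_p = np.array([0.54, 0.12, 0.10, 0.24])
    services = np.array(["hospitalist", "intensive_care", "surgery", "other"])
    service_p = np.array([0.50, 0.20, 0.15, 0.15])

    enc_rows = []
    msg_rows: list[dict] = []
    shares = np.array([config.sender_share_by_role.get(r, 0.0) for r in roles_present])
    shares = shares / shares.sum()
    team_sizes = {r: config.team_size_by_role.get(r, 0) for r in roles_present}
    esc_window_min = config.escalation_window_h * 60.0

    msg_counter = 0
    for i in range(n_enc):
        enc_id = f"e{i + 1:05d}"
        a, los = int(admit_min[i]), int(los_min[i])
        d = a + los
        det_minutes: list[int] = []
        indication = None
        service = None

        is_det = bool(linked[i]) and (rng.random() < config.p_deterioration)
        if is_det:
            det_offset = None
            for _ in range(1000):
                days = float(sample_time_to_deterioration(config, 1, rng)[0])
                cand = int(round(days * MINUTES_PER_DAY))
                if 1 <= cand < los:
                    det_offset = cand
                    break
            if det_offset is None:
                raise ConfigurationError(
                    f"could not place a deterioration inside the stay of {enc_id} "
                    f"(length {los} min) after 1000 attempts"
                )
            det_minutes = [a + det_offset]
            indication = str(rng.choice(indications, p=indication_p))
            service = str(rng.choice(services, p=service_p))

        enc_rows.append(
            {
                "encounter_id": enc_id,
                "admit_at": pd.Timestamp(a * 60_000_000_000),
                "discharge_at": pd.Timestamp(d * 60_000_000_000),
                "deterioration_times": [
                    pd.Timestamp(t * 60_000_000_000) for t in det_minutes
                ],
                "indication": indication,
                "activating_service": service,
            }
        )

        if not linked[i]:
            continue

        # (3) care team: weight-proportional sample within each role
        team_idx: list[int] = []
        for role in roles_present:
            k = team_sizes[role]
            if k <= 0:
                continue
            pool = idx_by_role[role]
            chosen = pool[
                _weighted_sample_without_replacement(weights[pool], k, rng)
            ]
            team_idx.extend(sorted(chosen))
        team_idx = np.array(team_idx)
        team_ids = providers["provider_id"].to_numpy()[team_idx]
        team_roles = providers["role"].to_numpy()[team_idx]
        team_w = weights[team_idx]
        m = len(team_idx)

        # (5) message times: piecewise-constant Poisson process (minutes)
        t0 = det_minutes[0] if det_minutes else None
        segments: list[tuple[int, int, float]] = []
        if t0 is None:
            segments.append((a, d, 1.0))
        else:
            w_start = max(a, int(t0 - esc_window_min))
            if a < w_start:
                segments.append((a, w_start, 1.0))
            if w_start < t0:
                segments.append((w_start, t0, config.escalation_multiplier))
            if t0 < d:
                segments.append((t0, d, 1.0))
        times = []
        for lo, hi, mult in segments:
            lam = config.base_rate * ((hi - lo) / 60.0) * mult
            k = rng.poisson(lam)
            if k:
                times.append(np.floor(lo + rng.random(k) * (hi - lo)).astype(np.int64))
        if not times:
            continue
        times = np.sort(np.concatenate(times))
        n_msg = len(times)

        # sender roles then weight-proportional member of that role
        role_draw = rng.choice(len(roles_present), size=n_msg, p=shares)
        senders = np.empty(n_msg, dtype=np.int64)  # positions within team
        for ri, role in enumerate(roles_present):
            mask = role_draw == ri
            cnt = int(mask.sum())
            if cnt == 0:
                continue
            positions = np.flatnonzero(team_roles == role)
            pw = team_w[positions]
            senders[mask] = rng.choice(positions, size=cnt, p=pw / pw.sum())

        # recipient counts: geometric (support >= 1), capped at team size - 1
        n_recip = np.minimum(rng.geometric(config.recipient_count_p, size=n_msg), m - 1)

        # recipients: weighted, without replacement, excluding the sender
        keys = np.log(team_w)[None, :] + rng.gumbel(size=(n_msg, m))
        keys[np.arange(n_msg), senders] = -np.inf
        order = np.argsort(-keys, axis=1)

        char_counts = np.maximum(
            1,
            np.rint(
                rng.lognormal(
                    math.log(config.char_count_log_median),
                    config.char_count_log_sd,
                    size=n_msg,
                )
            ).astype(np.int64),
        )
        read_min = rng.lognormal(
            math.log(config.read_minutes_log_median),
            config.read_minutes_log_sd,
            size=n_msg,
        )
        read_missing = rng.random(n_msg) < config.p_read_missing

        for j in range(n_msg):
            msg_counter += 1
            r = int(n_recip[j])
            msg_rows.append(
                {
                    "message_id": f"m{msg_counter:07d}",
                    "sent_at": pd.Timestamp(int(times[j]) * 60_000_000_000),
                    "sender_id": str(team_ids[senders[j]]),
                    "recipient_ids": [str(x) for x in team_ids[order[j, :r]]],
                    "encounter_id": enc_id,
                    "minutes_to_first_read": (
                        np.nan if read_missing[j] else float(read_min[j])
                    ),
                    "char_count": int(char_counts[j]),
                }
            )

    encounters = pd.DataFrame(
        enc_rows,
        columns=[
            "encounter_id",
            "admit_at",
            "discharge_at",
            "deterioration_times",
            "indication",
            "activating_service",
        ],
    )
    messages = pd.DataFrame(
        msg_rows,
        columns=[
            "message_id",
            "sent_at",
            "sender_id",
            "recipient_ids",
            "encounter_id",
            "minutes_to_first_read",
            "char_count",
        ],
    )
    return Cohort(providers, encounters, messages, n_total_encounters=n_enc)
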