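"""Cohort data model and delimited-file I/O.

The unit of analysis is a *cohort*: the healthcare providers of one
hospital, the inpatient encounters over a study window, and the secure
text messages exchanged between providers, each message optionally linked
to an encounter. Messages carry only metadata (sender, recipients,
timestamp, time-to-first-read, character count) — never text content.

Tables are held as pandas DataFrames with a fixed column contract
(see ``MESSAGE_COLUMNS`` etc.); recipient lists and deterioration-time
lists live in object columns as Python lists. All timestamps are stored
at minute resolution, ISO-8601 (``YYYY-MM-DDTHH:MM``) on disk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Role vocabulary
# ---------------------------------------------------------------------------

#: Closed role vocabulary. Advanced practice providers and housestaff
#: (residents/fellows) are analyzed as a single "frontline provider" role;
#: attending physicians are "physician". Everything unrecognized maps to
#: "other" (the catch-all bucket of >30 miscellaneous roles).
ROLES: tuple[str, ...] = (
    "registered_nurse",
    "frontline_provider",
    "physician",
    "nursing_assistant",
    "pharmacist",
    "respiratory_therapist",
    "other",
)

ROLE_ALIASES: dict[str, str] = {
    "advanced_practice_provider": "frontline_provider",
    "nurse_practitioner": "frontline_provider",
    "physician_assistant": "frontline_provider",
    "housestaff": "frontline_provider",
    "resident": "frontline_provider",
    "fellow": "frontline_provider",
    "attending": "physician",
    "attending_physician": "physician",
    "rn": "registered_nurse",
    "nurse": "registered_nurse",
}

TIME_FORMAT = "%Y-%m-%dT%H:%M"

MESSAGE_COLUMNS = (
    "message_id",
    "sent_at",
    "sender_id",
    "recipient_ids",
    "encounter_id",
    "minutes_to_first_read",
    "char_count",
)
PROVIDER_COLUMNS = ("provider_id", "role")
ENCOUNTER_COLUMNS = (
    "encounter_id",
    "admit_at",
    "discharge_at",
    "deterioration_times",
    "indication",
    "activating_service",
)


class FormatError(ValueError):
    """A file does not match the expected delimited-table contract."""


class RowError(ValueError):
    """A specific row could not be parsed; the message names the row."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


class CohortIntegrityError(ValueError):
    """Cross-table references do not resolve."""


def canonical_role(label: object) -> str:
    """Map a raw role string onto the closed vocabulary.

    Known labels pass through, aliases are folded (e.g. housestaff →
    frontline_provider), anything else becomes ``other`` with a warning.
    """
    text = str(label).strip().lower().replace(" ", "_")
    if text in ROLES:
        return text
    if text in ROLE_ALIASES:
        return ROLE_ALIASES[text]
    warnings.warn(f"unknown role {label!r} mapped to 'other'", stacklevel=2)
    return "other"


def _parse_minute(value: str, *, context: str) -> pd.Timestamp:
    try:
        ts = pd.Timestamp(value)
    except (ValueError, TypeError) as exc:
        raise RowError(f"unparseable timestamp {value!r} ({context})") from exc
    return ts.floor("min")


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: object) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")


# ---------------------------------------------------------------------------
# Cohort container
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    """Providers, encounters and messages of one study window.

    ``n_total_encounters`` counts *all* inpatient encounters in the window,
    including those with no linked messages; it defaults to the number of
    rows in the encounter table (the synthetic generator emits every
    encounter, message-linked or not).
    """

    providers: pd.DataFrame
    encounters: pd.DataFrame
    messages: pd.DataFrame
    n_total_encounters: int = 0

    def __post_init__(self) -> None:
        if self.n_total_encounters == 0:
            self.n_total_encounters = len(self.encounters)

    @property
    def role_of(self) -> dict[str, str]:
        return dict(
            zip(self.providers["provider_id"], self.providers["role"])
        )

    def time0(self, encounter_id: str) -> Optional[pd.Timestamp]:
        """Time 0 of an encounter: its first deterioration, or None."""
        row = self.encounters.loc[
            self.encounters["encounter_id"] == encounter_id
        ]
        if row.empty:
            raise KeyError(encounter_id)
        dets = row.iloc[0]["deterioration_times"]
        return dets[0] if dets else None


@dataclass
class ValidationReport:
    """Bookkeeping from :func:`validate_cohort`."""

    n_messages: int
    n_linked: int
    n_unlinked: int
    n_unresolvable_encounter_ids: int
    n_encounters: int
    n_encounters_with_messages: int
    n_encounters_without_messages: int
    role_tally: dict[str, int] = field(default_factory=dict)
    findings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_provider_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, PROVIDER_COLUMNS, path)
    df = df[list(PROVIDER_COLUMNS)].copy()
    df["role"] = [canonical_role(r) for r in df["role"]]
    dupes = df["provider_id"][df["provider_id"].duplicated()]
    if len(dupes):
        raise ValidationError(
            f"{path}: duplicate provider ids: {sorted(set(dupes))}"
        )
    return df


def read_message_log(
    path: str | Path, providers: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Read a message log; returns ``(messages, n_dropped_no_recipient)``.

    Rows whose recipient cell is empty are dropped and counted (only
    messages with at least one recipient enter the analysis). Sender and
    recipient ids must resolve against the provider table.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(raw, MESSAGE_COLUMNS, path)
    known = set(providers["provider_id"])

    rows = []
    n_dropped = 0
    for i, rec in enumerate(raw.itertuples(index=False), start=2):  # header=1
        recipients = [r for r in str(rec.recipient_ids).split(";") if r.strip()]
        if not recipients:
            n_dropped += 1
            continue
        sent_at = _parse_minute(rec.sent_at, context=f"{path} row {i}")
        if rec.sender_id not in known:
            raise CohortIntegrityError(
                f"{path} row {i}: unknown sender '{rec.sender_id}'"
            )
        bad = [r for r in recipients if r not in known]
        if bad:
            raise CohortIntegrityError(f"{path} row {i}: unknown recipients {bad}")
        mttr = rec.minutes_to_first_read.strip()
        mttr_val = float(mttr) if mttr else np.nan
        if mttr_val < 0:
            raise ValidationError(
                f"{path} row {i}: negative minutes_to_first_read"
            )
        char_count = int(rec.char_count)
        if char_count <= 0:
            raise ValidationError(f"{path} row {i}: char_count must be positive")
        rows.append(
            {
                "message_id": rec.message_id,
                "sent_at": sent_at,
                "sender_id": rec.sender_id,
                "recipient_ids": recipients,
                "encounter_id": rec.encounter_id.strip() or None,
                "minutes_to_first_read": mttr_val,
                "char_count": char_count,
            }
        )
    messages = pd.DataFrame(rows, columns=list(MESSAGE_COLUMNS))
    return messages, n_dropped


def read_encounter_table(path: str | Path) -> pd.DataFrame:
    """Read encounters; deterioration lists are sorted ascending.

    A row with ``admit_at >= discharge_at``, or a deterioration outside the
    admission window, raises :class:`ValidationError` naming the encounter.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(raw, ENCOUNTER_COLUMNS, path)
    rows = []
    for i, rec in enumerate(raw.itertuples(index=False), start=2):
        admit = _parse_minute(rec.admit_at, context=f"{path} row {i}")
        discharge = _parse_minute(rec.discharge_at, context=f"{path} row {i}")
        if not admit < discharge:
            raise ValidationError(
                f"encounter '{rec.encounter_id}': admit_at must precede discharge_at"
            )
        dets = sorted(
            _parse_minute(t, context=f"{path} row {i}")
            for t in str(rec.deterioration_times).split(";")
            if t.strip()
        )
        for t in dets:
            if not (admit <= t <= discharge):
                raise ValidationError(
                    f"encounter '{rec.encounter_id}': deterioration at {t} "
                    f"outside admission window"
                )
        rows.append(
            {
                "encounter_id": rec.encounter_id,
                "admit_at": admit,
                "discharge_at": discharge,
                "deterioration_times": dets,
                "indication": rec.indication or None,
                "activating_service": rec.activating_service or None,
            }
        )
    return pd.DataFrame(rows, columns=list(ENCOUNTER_COLUMNS))


def read_cohort(directory: str | Path) -> tuple[Cohort, int]:
    """Read providers.csv / encounters.csv / messages.csv from a directory."""
    directory = Path(directory)
    providers = read_provider_table(directory / "providers.csv")
    encounters = read_encounter_table(directory / "encounters.csv")
    messages, n_dropped = read_message_log(directory / "messages.csv", providers)
    return Cohort(providers, encounters, messages), n_dropped


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def _fmt_time(ts: pd.Timestamp) -> str:
    return ts.strftime(TIME_FORMAT)


def write_provider_table(providers: pd.DataFrame, path: str | Path) -> None:
    providers[list(PROVIDER_COLUMNS)].to_csv(path, index=False)


def write_message_log(messages: pd.DataFrame, path: str | Path) -> None:
    out = messages.copy()
    out["sent_at"] = [_fmt_time(t) for t in out["sent_at"]]
    out["recipient_ids"] = [";".join(r) for r in out["recipient_ids"]]
    out["encounter_id"] = [e if e else "" for e in out["encounter_id"]]
    out["minutes_to_first_read"] = [
        "" if pd.isna(v) else repr(float(v)) for v in out["minutes_to_first_read"]
    ]
    out[list(MESSAGE_COLUMNS)].to_csv(path, index=False)


def write_encounter_table(encounters: pd.DataFrame, path: str | Path) -> None:
    out = encounters.copy()
    out["admit_at"] = [_fmt_time(t) for t in out["admit_at"]]
    out["discharge_at"] = [_fmt_time(t) for t in out["discharge_at"]]
    out["deterioration_times"] = [
        ";".join(_fmt_time(t) for t in ts) for ts in out["deterioration_times"]
    ]
    for col in ("indication", "activating_service"):
        out[col] = [v if v else "" for v in out[col]]
    out[list(ENCOUNTER_COLUMNS)].to_csv(path, index=False)


def write_cohort(cohort: Cohort, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_provider_table(cohort.providers, directory / "providers.csv")
    write_encounter_table(cohort.encounters, directory / "encounters.csv")
    write_message_log(cohort.messages, directory / "messages.csv")


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_cohort(cohort: Cohort) -> ValidationReport:
    """Check cross-table integrity and return linkage/role bookkeeping.

    Raises :class:`CohortIntegrityError` listing ids when a message refers
    to a provider that is not in the provider table. Messages whose
    encounter id does not resolve are counted as unlinked (and tallied
    separately) — they are excluded from encounter-level analyses.
    """
    known_providers = set(cohort.providers["provider_id"])
    known_encounters = set(cohort.encounters["encounter_id"])

    dangling: set[str] = set()
    n_linked = n_unlinked = n_unresolvable = 0
    for rec in cohort.messages.itertuples(index=False):
        if rec.sender_id not in known_providers:
            dangling.add(rec.sender_id)
        dangling.update(r for r in rec.recipient_ids if r not in known_providers)
        if rec.encounter_id is None or (
            isinstance(rec.encounter_id, float) and np.isnan(rec.encounter_id)
        ):
            n_unlinked += 1
        elif rec.encounter_id in known_encounters:
            n_linked += 1
        else:
            n_unlinked += 1
            n_unresolvable += 1
    if dangling:
        raise CohortIntegrityError(
            f"messages reference unknown providers: {sorted(dangling)}"
        )

    with_msgs = {
        e
        for e in cohort.messages["encounter_id"]
        if e is not None and e in known_encounters
    }
    tally = cohort.providers["role"].value_counts().to_dict()
    findings: list[str] = []
    if n_unresolvable:
        findings.append(
            f"{n_unresolvable} messages reference unknown encounter ids"
        )
    return ValidationReport(
        n_messages=len(cohort.messages),
        n_linked=n_linked,
        n_unlinked=n_unlinked,
        n_unresolvable_encounter_ids=n_unresolvable,
        n_encounters=len(cohort.encounters),
        n_encounters_with_messages=len(with_msgs),
        n_encounters_without_messages=len(cohort.encounters) - len(with_msgs),
        role_tally=tally,
        findings=findings,
    )
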