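"""End-to-end orchestration: simulate/ingest → build → metrics → compare.

A single YAML config drives a run; the output directory receives CSV
analogs of the study tables plus a JSON manifest with the config snapshot,
seed, input checksums and per-stage bookkeeping (messages read and
dropped, subnetworks built and excluded, tests run). Identical seed and
config produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import model, metrics, networks, simulate, stats

log = logging.getLogger("carenet")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunManifest:
    seed: int
    config: dict
    input_checksums: dict[str, str] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, manifest: RunManifest) -> None:
    df.to_csv(path, index=False)
    manifest.outputs.append(path.name)


def run_full_analysis(
    config: dict | str | Path,
    out_dir: str | Path,
    seed: Optional[int] = None,
) -> RunManifest:
    """Run the three-stage analysis and write all tables.

    ``config`` is a mapping (or YAML path) with optional keys:
    ``simulate`` (bool, default True), ``simulation`` (overrides for
    :class:`~carenet.simulate.SimulationConfig`), ``inputs`` (directory of
    providers/encounters/messages CSVs when not simulating), ``epochs``
    (list of [lower, upper] hour windows), ``directed_distances`` (bool).
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    cfg = dict(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sim_overrides = dict(cfg.get("simulation", {}))
    if seed is not None:
        sim_overrides["seed"] = seed
    seed = int(sim_overrides.get("seed", 0))
    manifest = RunManifest(seed=seed, config=cfg)
    directed = bool(cfg.get("directed_distances", False))
    if "epochs" in cfg:
        epochs = networks.EpochSpec([tuple(map(float, w)) for w in cfg["epochs"]])
    else:
        epochs = networks.EpochSpec()

    # -- stage: obtain the cohort -------------------------------------------
    try:
        if cfg.get("simulate", True):
            sim_cfg = simulate.SimulationConfig.from_dict(
                {**simulate.default_config().to_dict(), **sim_overrides}
            )
            cohort = simulate.generate_cohort(sim_cfg)
            manifest.config["simulation"] = sim_cfg.to_dict()
            n_dropped = 0
        else:
            indir = Path(cfg["inputs"])
            for name in ("providers.csv", "encounters.csv", "messages.csv"):
                manifest.input_checksums[name] = _sha256(indir / name)
            cohort, n_dropped = model.read_cohort(indir)
    except Exception as exc:
        manifest.write(out / "manifest.json")
        raise StageError(f"ingest: {exc}") from exc
    report = model.validate_cohort(cohort)
    manifest.counts.update(
        messages_read=report.n_messages,
        messages_dropped_no_recipient=n_dropped,
        messages_linked=report.n_linked,
        messages_unlinked=report.n_unlinked,
        encounters=report.n_encounters,
        encounters_with_messages=report.n_encounters_with_messages,
    )
    log.info("ingest: %d messages, %d encounters", report.n_messages,
             report.n_encounters)

    # -- stage 1: global network --------------------------------------------
    try:
        global_graph = networks.build_global_network(
            cohort.messages, cohort.providers
        )
        global_table = metrics.centrality_table(global_graph, directed=directed)
        _write_csv(global_table, out / "global_centrality.csv", manifest)
        summary = metrics.network_summary(global_graph)
        _write_csv(
            pd.DataFrame(
                [
                    {
                        "network_id": summary.network_id,
                        "n_nodes": summary.n_nodes,
                        "n_edges": summary.n_edges,
                        "density": summary.density,
                        "diameter": summary.diameter,
                        "radius": summary.radius,
                        "clustering": summary.clustering,
                    }
                ]
            ),
            out / "global_summary.csv",
            manifest,
        )
        role_cmp = stats.compare_roles_within_network(global_table)
        _write_csv(role_cmp.kruskal, out / "role_comparisons_kruskal.csv", manifest)
        _write_csv(role_cmp.pairwise, out / "role_comparisons_pairwise.csv", manifest)
        freq = metrics.degree_frequency(global_graph)
        _write_csv(
            pd.DataFrame(
                {"degree": list(freq.keys()), "n_nodes": list(freq.values())}
            ),
            out / "degree_frequency.csv",
            manifest,
        )
        flows = stats.role_flow_matrix(
            cohort.messages.loc[cohort.messages["encounter_id"].notna()],
            cohort.providers,
        )
        _write_csv(
            flows.pair_counts.reset_index(names="sender_role"),
            out / "role_flow_matrix.csv",
            manifest,
        )
        _write_csv(
            pd.DataFrame(
                {
                    "role": flows.sender_share.index,
                    "sender_share_of_messages": flows.sender_share.to_numpy(),
                    "recipient_share_of_pairs": flows.recipient_share.to_numpy(),
                }
            ),
            out / "role_flow_shares.csv",
            manifest,
        )
    except Exception as exc:
        manifest.write(out / "manifest.json")
        raise StageError(f"global network: {exc}") from exc

    # -- stage 2: encounter subnetworks -------------------------------------
    try:
        det_rows = {
            r.encounter_id: r
            for r in cohort.encounters.itertuples(index=False)
            if r.deterioration_times
        }
        det_frames, n_post_only = [], 0
        for enc_id in sorted(det_rows):
            row = cohort.encounters.loc[
                cohort.encounters["encounter_id"] == enc_id
            ].iloc[0]
            pre = networks.filter_pre_deterioration(cohort.messages, row)
            if pre.empty:
                n_post_only += 1
            else:
                det_frames.append(pre)
        free_messages = cohort.messages.loc[
            ~cohort.messages["encounter_id"].isin(det_rows)
        ]
        pre_det_messages = (
            pd.concat(det_frames) if det_frames else cohort.messages.iloc[0:0]
        )
        enc_messages = pd.concat([pre_det_messages, free_messages])
        subnets = networks.build_encounter_subnetworks(
            enc_messages, cohort.encounters, cohort.providers
        )
        det_ids = {e for e in det_rows if e in subnets}
        cent_frames, summary_rows = [], []
        for enc_id, g in sorted(subnets.items()):
            cent_frames.append(metrics.centrality_table(g, directed=directed))
            s = metrics.network_summary(g)
            summary_rows.append(
                {
                    "network_id": enc_id,
                    "deterioration": enc_id in det_ids,
                    "n_nodes": s.n_nodes,
                    "n_edges": s.n_edges,
                    "density": s.density,
                    "diameter": s.diameter,
                    "radius": s.radius,
                    "clustering": s.clustering,
                }
            )
        enc_centralities = (
            pd.concat(cent_frames, ignore_index=True)
            if cent_frames
            else pd.DataFrame()
        )
        _write_csv(
            pd.DataFrame(summary_rows), out / "encounter_summaries.csv", manifest
        )
        table1 = stats.compare_det_vs_free(enc_centralities, det_ids)
        _write_csv(table1, out / "table1_centrality_det_vs_free.csv", manifest)
        manifest.counts.update(
            encounter_subnetworks=len(subnets),
            deterioration_subnetworks=len(det_ids),
            subnetworks_excluded_post_only=n_post_only,
        )
    except Exception as exc:
        manifest.write(out / "manifest.json")
        raise StageError(f"encounter subnetworks: {exc}") from exc

    # -- stage 3: epoch subnetworks -----------------------------------------
    try:
        sum_rows, cent_frames = [], []
        for enc_id in sorted(det_rows):
            row = cohort.encounters.loc[
                cohort.encounters["encounter_id"] == enc_id
            ].iloc[0]
            per_window = networks.build_epoch_subnetworks(
                cohort.messages, row, cohort.providers, epochs
            )
            for win, g in per_window.items():
                s = metrics.network_summary(g)
                sum_rows.append(
                    {
                        "window": str(win),
                        "network_id": g.network_id,
                        "n_nodes": s.n_nodes,
                        "n_edges": s.n_edges,
                        "density": s.density,
                        "diameter": s.diameter,
                        "radius": s.radius,
                        "clustering": s.clustering,
                    }
                )
                ct = metrics.centrality_table(g, directed=directed)
                ct.insert(0, "window", str(win))
                cent_frames.append(ct)
        epoch_summaries = pd.DataFrame(sum_rows)
        epoch_centralities = (
            pd.concat(cent_frames, ignore_index=True)
            if cent_frames
            else pd.DataFrame()
        )
        _write_csv(epoch_summaries, out / "epoch_summaries.csv", manifest)
        _write_csv(epoch_centralities, out / "epoch_centralities.csv", manifest)
        if not epoch_summaries.empty:
            n_windows = epoch_summaries["window"].nunique()
            if n_windows >= 2:
                table2 = stats.compare_epochs(
                    epoch_summaries, epoch_centralities, epochs
                )
                _write_csv(table2, out / "table2_epoch_comparisons.csv", manifest)
        manifest.counts["epoch_subnetworks"] = len(sum_rows)
    except Exception as exc:
        manifest.write(out / "manifest.json")
        raise StageError(f"epoch subnetworks: {exc}") from exc

    # -- cohort summary ------------------------------------------------------
    try:
        summary = stats.cohort_summary(cohort, n_post_only=n_post_only)
        data = asdict(summary)
        data.update({f"display_{k}": v for k, v in summary.display.items()})
        with open(out / "cohort_summary.json", "w") as fh:
            json.dump(data, fh, indent=2, sort_keys=True)
            fh.write("\n")
        manifest.outputs.append("cohort_summary.json")
    except Exception as exc:
        manifest.write(out / "manifest.json")
        raise StageError(f"cohort summary: {exc}") from exc

    manifest.write(out / "manifest.json")
    return manifest
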