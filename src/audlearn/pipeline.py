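"""End-to-end orchestration: simulate (or ingest) -> metrics -> states ->
dynamics -> classify, with a manifest of checksummed stage outputs.

Every stage derives its own seed deterministically from the run's master
seed, so a stage can be re-run in isolation and a whole run is
byte-reproducible given the seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    BUTTONS,
    CONFIG_TARGETS,
    DEFAULT_ALLOCATION,
    DEFAULT_EFFECTS,
    CohortEffects,
    ParticipantRecord,
    RESPONSES,
    frame_to_records,
    generate_cohort,
    read_trial_log,
    write_trial_log,
)
from .classify import SUBSPACES, build_feature_table, stratified_cv
from .dynamics import button_effect_test, high_block_counts, pairwise_config_tests
from .metrics import block_series_frame, mean_cumulative_curves
from .states import fit_gmm_em, state_labels

logger = logging.getLogger("audlearn")

__all__ = ["RunConfig", "RunManifest", "validate_trial_log", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    block_size_q1: int = 10  # fine blocks for state modelling
    block_size_q3: int = 40  # coarse blocks for classification features
    k: int = 3  # mixture components
    cv_folds: int = 5
    allocation: Mapping[tuple[int, str], tuple[int, int]] | None = None
    config_effects: Mapping[int, float] | None = None
    button_effects: Mapping[str, float] | None = None
    subspaces: tuple[str, ...] = tuple(SUBSPACES)
    out_dir: str = "run"
    trial_log: str | None = None  # ingest this CSV instead of simulating

    def __post_init__(self) -> None:
        for bs in (self.block_size_q1, self.block_size_q3):
            if 240 % bs != 0:
                raise ValueError(f"block size {bs} does not divide 240")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    def effects(self) -> CohortEffects:
        if self.config_effects is None and self.button_effects is None:
            return DEFAULT_EFFECTS
        return CohortEffects(
            config=dict(self.config_effects or {}),
            button=dict(self.button_effects or {}),
        )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load a flat key-value (YAML) config file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "allocation" in raw and raw["allocation"] is not None:
            raw["allocation"] = {
                (int(k.split("/")[0]), k.split("/")[1]): tuple(v)
                for k, v in raw["allocation"].items()
            }
        if "config_effects" in raw and raw["config_effects"] is not None:
            raw["config_effects"] = {int(k): float(v) for k, v in raw["config_effects"].items()}
        if "subspaces" in raw and raw["subspaces"] is not None:
            raw["subspaces"] = tuple(raw["subspaces"])
        return cls(**raw)


@dataclass
class RunManifest:
    """What a run produced: stage outputs with content checksums."""

    config: dict
    outputs: dict[str, str] = field(default_factory=dict)  # name -> path
    checksums: dict[str, str] = field(default_factory=dict)  # name -> sha256
    version: str = __version__
    timestamp: str = ""

    def to_json(self, path) -> None:
        payload = dataclasses.asdict(self)
        alloc = payload["config"].get("allocation")
        if alloc is not None:
            payload["config"]["allocation"] = {
                f"{cfg}/{btn}": list(v) for (cfg, btn), v in alloc.items()
            }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def validate_trial_log(path) -> tuple[list[ParticipantRecord], list[str]]:
    """Parse and schema-check a trial-log CSV.

    Returns the parsed records plus a list of human-readable violations
    (missing trials, illegal field values, target flags inconsistent with
    the participant's configuration, correctness flags contradicting the
    response).  Row numbers refer to the CSV data rows (1-based).
    """
    frame = read_trial_log(path)
    violations: list[str] = []

    legal = {
        "config": set(CONFIG_TARGETS),
        "button": set(BUTTONS),
        "label": {"L", "notL"},
        "response": set(RESPONSES),
    }
    for col, values in legal.items():
        bad = ~frame[col].isin(values)
        for row in frame.index[bad]:
            violations.append(
                f"row {row + 1}: illegal {col} value {frame.at[row, col]!r}"
            )

    for pid, grp in frame.groupby("participant_id", sort=False):
        idx = sorted(grp["trial_index"])
        if idx != list(range(1, 241)):
            violations.append(
                f"participant {pid!r}: expected trial indices 1..240, got {len(idx)} trials"
            )
        config = grp["config"].iloc[0]
        if config in CONFIG_TARGETS:
            dur, dirn = CONFIG_TARGETS[int(config)]
            expect_target = (grp["duration"] == dur) & (grp["direction"] == dirn)
            for row in grp.index[grp["is_target"].astype(bool) != expect_target]:
                violations.append(
                    f"row {row + 1}: is_target inconsistent with config {config}"
                )
        expect_correct = (
            grp["is_target"].astype(bool) & (grp["response"] == "target_button")
        ) | (~grp["is_target"].astype(bool) & (grp["response"] == "nontarget_button"))
        for row in grp.index[grp["correct"].astype(bool) != expect_correct]:
            violations.append(
                f"row {row + 1}: correct flag contradicts response/target"
            )

    records = frame_to_records(frame) if not violations else []
    return records, violations


def _stage_seed(master: int, stage: int) -> int:
    return int(np.random.SeedSequence(master, spawn_key=(stage,)).generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig) -> RunManifest:
    """Run every stage and write outputs under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dataclasses.asdict(config))
    t0 = time.strftime("%Y-%m-%dT%H:%M:%S")

    def emit(name: str, path: Path) -> None:
        manifest.outputs[name] = str(path)
        manifest.checksums[name] = _sha256(path)

    def stage(name):
        logger.info("[%s] starting", name)

    # 1. cohort -----------------------------------------------------------
    stage("simulate")
    try:
        if config.trial_log is not None:
            records, violations = validate_trial_log(config.trial_log)
            if violations:
                raise ValueError(
                    f"{len(violations)} trial-log violations, first: {violations[0]}"
                )
            cohort = read_trial_log(config.trial_log)
        else:
            records = generate_cohort(
                allocation=config.allocation,
                effects=config.effects(),
                master_seed=_stage_seed(config.seed, 0),
            )
            cohort = None
        if cohort is None:
            cohort_path = out / "cohort.csv"
            write_trial_log(records, cohort_path)
            cohort = read_trial_log(cohort_path)
        else:
            cohort_path = out / "cohort.csv"
            cohort.to_csv(cohort_path, index=False)
        emit("cohort", cohort_path)
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    meta = cohort.drop_duplicates("participant_id")[
        ["participant_id", "config", "button", "label"]
    ]

    # 2. metrics ----------------------------------------------------------
    stage("metrics")
    try:
        blocks = {}
        for coeff in ("sensitivity", "specificity"):
            blocks[coeff] = block_series_frame(cohort, coeff, config.block_size_q1)
            p = out / f"blocks_{coeff}.csv"
            blocks[coeff].to_csv(p, index=False)
            emit(f"blocks_{coeff}", p)
            curves = mean_cumulative_curves(cohort, coeff)
            p = out / f"curves_{coeff}.csv"
            curves.to_csv(p)
            emit(f"curves_{coeff}", p)
    except Exception as exc:
        raise RuntimeError(f"stage 'metrics' failed: {exc}") from exc

    # 3. states -----------------------------------------------------------
    stage("states")
    try:
        state_frames = {}
        n_participants = meta.shape[0]
        for i, coeff in enumerate(("sensitivity", "specificity")):
            model = fit_gmm_em(
                blocks[coeff]["value"].to_numpy(),
                config.k,
                seed=_stage_seed(config.seed, 10 + i),
                coefficient=coeff,
            )
            model.to_json(out / f"model_{coeff}.json")
            emit(f"model_{coeff}", out / f"model_{coeff}.json")
            sf = blocks[coeff].copy()
            sf["state"] = state_labels(model, sf["value"].to_numpy())
            state_frames[coeff] = sf
            p = out / f"states_{coeff}.csv"
            sf.to_csv(p, index=False)
            emit(f"states_{coeff}", p)
    except Exception as exc:
        raise RuntimeError(f"stage 'states' failed: {exc}") from exc

    # 4. dynamics ---------------------------------------------------------
    stage("dynamics")
    try:
        dyn: dict = {}
        for coeff, sf in state_frames.items():
            counts = high_block_counts(sf, meta)
            counts.to_csv(out / f"high_counts_{coeff}.csv", index=False)
            emit(f"high_counts_{coeff}", out / f"high_counts_{coeff}.csv")
            entry = {"button_effect": dataclasses.asdict(button_effect_test(counts))}
            for scope in ["total", "partition_1", "partition_2", "partition_3"]:
                entry[f"config_pairs_{scope}"] = pairwise_config_tests(
                    counts, scope=scope
                ).to_dict(orient="records")
            dyn[coeff] = entry
        p = out / "dynamics.json"
        with open(p, "w") as fh:
            json.dump(dyn, fh, indent=2)
        emit("dynamics", p)
    except Exception as exc:
        raise RuntimeError(f"stage 'dynamics' failed: {exc}") from exc

    # 5. classify ---------------------------------------------------------
    stage("classify")
    try:
        table = build_feature_table(cohort)
        table.to_csv(out / "features.csv")
        emit("features", out / "features.csv")
        reports = {
            name: stratified_cv(
                table, name, k=config.cv_folds, seed=_stage_seed(config.seed, 20)
            ).to_dict()
            for name in config.subspaces
        }
        p = out / "classification.json"
        with open(p, "w") as fh:
            json.dump(reports, fh, indent=2)
        emit("classification", p)
    except Exception as exc:
        raise RuntimeError(f"stage 'classify' failed: {exc}") from exc

    manifest.timestamp = t0
    manifest.to_json(out / "manifest.json")
    return manifest
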