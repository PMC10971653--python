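"""I/O orchestration: CSV bundles in, results and agreement report out.

Interchange is plain CSV with header rows (UTF-8, '.' decimal, empty cell
for missing).  Schema violations in the input bundle fail fast with
itemized messages; participant-level computation failures are logged and
the run continues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List

import pandas as pd

from .agreement import run_comparisons
from .anthropometry import Site
from .densitometry import (
    Condition,
    ParticipantComputationError,
    ProtocolConfig,
    compute_participant,
)
from .participants import Participant

logger = logging.getLogger("hydrodensity")

PARTICIPANT_COLUMNS = {"participant_id", "sex", "age_yr", "height_cm", "mass_kg"}
GIRTH_COLUMNS = {"participant_id", "site", "trial_index", "value_mm"}
TRIAL_COLUMNS = {"participant_id", "condition", "trial_index", "weight_kg"}

RESULT_COLUMNS = [
    "participant_id", "sex", "condition", "n_trials", "quality",
    "selected_mean_kg", "hv_pred_l", "lung_volume_l", "db", "pbf",
]


@dataclass(frozen=True)
class RunConfig:
    """Run-level options wrapping the protocol constants."""

    protocol: ProtocolConfig = ProtocolConfig()
    strict_quality: bool = False
    loa_multiplier: float = 1.96


class SchemaError(ValueError):
    pass


def _require_columns(df: pd.DataFrame, required: set, name: str) -> None:
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{name}: missing columns {sorted(missing)}")


def load_bundle(input_dir) -> Dict[str, pd.DataFrame]:
    """Load and schema-check participants/girths/trials CSVs."""
    d = Path(input_dir)
    problems: List[str] = []
    frames: Dict[str, pd.DataFrame] = {}
    for name, required in (
        ("participants", PARTICIPANT_COLUMNS),
        ("girths", GIRTH_COLUMNS),
        ("trials", TRIAL_COLUMNS),
    ):
        path = d / f"{name}.csv"
        if not path.exists():
            problems.append(f"{name}.csv: not found in {d}")
            continue
        df = pd.read_csv(path)
        try:
            _require_columns(df, required, f"{name}.csv")
        except SchemaError as exc:
            problems.append(str(exc))
            continue
        frames[name] = df
    if problems:
        raise SchemaError("; ".join(problems))

    girths = frames["girths"]
    bad_site = girths.loc[~girths["site"].isin([s.value for s in Site])]
    for i, row in bad_site.iterrows():
        problems.append(f"girths.csv row {i}: unknown site {row['site']!r}")
    trials = frames["trials"]
    bad_cond = trials.loc[~trials["condition"].isin([c.value for c in Condition])]
    for i, row in bad_cond.iterrows():
        problems.append(f"trials.csv row {i}: unknown condition {row['condition']!r}")
    known = set(frames["participants"]["participant_id"])
    for name in ("girths", "trials"):
        orphans = set(frames[name]["participant_id"]) - known
        if orphans:
            problems.append(f"{name}.csv: unknown participant_id(s) {sorted(orphans)[:5]}")
    if problems:
        raise SchemaError("; ".join(problems))
    return frames


def compute_results(
    bundle: Dict[str, pd.DataFrame], config: RunConfig = RunConfig()
) -> pd.DataFrame:
    """Per-participant, per-condition body composition table."""
    participants = bundle["participants"]
    girths = bundle["girths"].sort_values(["participant_id", "site", "trial_index"], kind="stable")
    trials = bundle["trials"].sort_values(["participant_id", "condition", "trial_index"], kind="stable")

    girth_map = {
        (pid, site): grp["value_mm"].tolist()
        for (pid, site), grp in girths.groupby(["participant_id", "site"], sort=False)
    }
    trial_map = {
        (pid, cond): grp["weight_kg"].tolist()
        for (pid, cond), grp in trials.groupby(["participant_id", "condition"], sort=False)
    }

    rows: List[dict] = []
    for _, p in participants.iterrows():
        pid = p["participant_id"]
        participant = Participant(
            participant_id=str(pid),
            sex=p["sex"],
            age_yr=float(p["age_yr"]),
            height_cm=float(p["height_cm"]),
            mass_kg=float(p["mass_kg"]),
            water_temp_c=float(p["water_temp_c"]) if "water_temp_c" in p and pd.notna(p.get("water_temp_c")) else None,
        )
        p_girths = {
            site: girth_map[(pid, site.value)]
            for site in Site
            if (pid, site.value) in girth_map
        }
        p_trials = {
            cond: trial_map[(pid, cond.value)]
            for cond in Condition
            if (pid, cond.value) in trial_map
        }
        if not p_trials:
            logger.warning("participant %s: no weighing trials, skipped", pid)
            continue
        try:
            comps = compute_participant(participant, p_girths, p_trials, config.protocol)
        except ParticipantComputationError as exc:
            logger.warning("%s", exc)
            continue
        if not comps:
            logger.warning("participant %s: no condition met the consistency criterion", pid)
        for c in comps:
            logger.info(
                "participant %s %s: quality=%s trials=%d mean=%.3f kg pbf=%.2f%%",
                pid, c.condition.value, c.quality.value, c.n_trials, c.mw_kg, c.pbf_pct,
            )
            rows.append(
                {
                    "participant_id": c.participant_id,
                    "sex": participant.sex.value,
                    "condition": c.condition.value,
                    "n_trials": c.n_trials,
                    "quality": c.quality.value,
                    "selected_mean_kg": c.mw_kg,
                    "hv_pred_l": c.hv_pred_l,
                    "lung_volume_l": c.lung_volume_l,
                    "db": c.db_kg_l,
                    "pbf": c.pbf_pct,
                }
            )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def run_pipeline(
    input_dir, out_dir, config: RunConfig = RunConfig()
) -> Dict[str, Path]:
    """Full chain: load bundle, compute results, run the three comparisons.

    Writes ``results.csv``, ``agreement_report.csv`` and
    ``bland_altman_points.csv`` under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = load_bundle(input_dir)
    results = compute_results(bundle, config)
    paths = {"results": out / "results.csv"}
    results.to_csv(paths["results"], index=False)
    if results.empty:
        logger.warning("no results computed; agreement report skipped")
        return paths
    report, points = run_comparisons(
        results, loa_multiplier=config.loa_multiplier, strict_quality=config.strict_quality
    )
    paths["agreement_report"] = out / "agreement_report.csv"
    paths["bland_altman_points"] = out / "bland_altman_points.csv"
    report.to_csv(paths["agreement_report"], index=False)
    points.to_csv(paths["bland_altman_points"], index=False)
    return paths
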