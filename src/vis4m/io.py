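"""Readers/writers tying the pipeline together: arm-entry event logs,
tidy per-session summary tables, Circos tableviewer chord-table export,
and illumination-condition configuration.

Event logs are UTF-8 comma-delimited text with a mandatory header and one
row per arm entry:

    mouse_id,genotype,sex,age_months,condition,arm,t_enter_s,t_exit_s

Times are seconds (decimals) on a 0-based session clock starting at animal
placement.  Rows are grouped into sessions by (mouse_id, condition).

Chord tables follow the Circos tableviewer format: a leading label row,
then one row per origin arm holding integer transition counts (percentages
live in the summary table; the tableviewer consumes counts).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from . import maze
from .maze import (
    ARM_MODES,
    EntryEvent,
    Session,
    TransitionProfile,
    collapse_reentries,
)
from .photometry import (
    LED_BY_ARM,
    ArmStimulus,
    LEDSpectrum,
    LightCondition,
    SpectrumComponent,
    characterize_arm,
)

logger = logging.getLogger("vis4m")

__all__ = [
    "EVENT_LOG_COLUMNS",
    "read_sessions",
    "write_sessions",
    "write_circos_table",
    "read_circos_table",
    "summarize_cohort",
    "load_condition_config",
]

EVENT_LOG_COLUMNS = (
    "mouse_id",
    "genotype",
    "sex",
    "age_months",
    "condition",
    "arm",
    "t_enter_s",
    "t_exit_s",
)


class EventLogError(ValueError):
    """Validation failure in an event-log file, with the offending line."""


def _infer_mode(arms: set[str]) -> str:
    for mode, vocab in ARM_MODES.items():
        if arms <= set(vocab):
            return mode
    raise EventLogError(f"arm labels {sorted(arms)} match no known vocabulary")


def read_sessions(path: str | Path, arm_mode: str | None = None) -> list[Session]:
    """Parse an event-log CSV into Sessions grouped by (mouse_id, condition).

    Validation failures (missing columns, bad times, unknown arms,
    overlapping events) raise EventLogError citing the 1-based file line.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"mouse_id": str})
    missing = [c for c in EVENT_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise EventLogError(f"{path}: missing column(s) {', '.join(missing)}")
    df["_line"] = df.index + 2  # header is line 1

    for col in ("t_enter_s", "t_exit_s"):
        bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise EventLogError(
                f"{path}: line {int(bad.iloc[0]['_line'])}: non-numeric {col}"
            )
        df[col] = df[col].astype(float)
    bad = df[(df.t_enter_s < 0) | (df.t_exit_s < df.t_enter_s)]
    if len(bad):
        raise EventLogError(
            f"{path}: line {int(bad.iloc[0]['_line'])}: "
            f"t_exit_s < t_enter_s or negative time"
        )

    sessions: list[Session] = []
    for (mouse_id, condition), group in df.groupby(
        ["mouse_id", "condition"], sort=False
    ):
        group = group.sort_values("t_enter_s")
        arms = set(group["arm"])
        mode = arm_mode or _infer_mode(arms)
        vocab = set(ARM_MODES[mode])
        unknown = group[~group["arm"].isin(vocab)]
        if len(unknown):
            raise EventLogError(
                f"{path}: line {int(unknown.iloc[0]['_line'])}: "
                f"unknown arm label {unknown.iloc[0]['arm']!r} for mode {mode!r}"
            )
        prev_exit, prev_line = 0.0, None
        for _, row in group.iterrows():
            if row.t_enter_s < prev_exit - 1e-9:
                raise EventLogError(
                    f"{path}: line {int(row['_line'])}: event overlaps the one "
                    f"on line {prev_line}"
                )
            prev_exit, prev_line = row.t_exit_s, int(row["_line"])
        meta = group.iloc[0]
        duration = max(300.0, float(group.t_exit_s.max()))
        sessions.append(
            Session(
                mouse_id=str(mouse_id),
                genotype=str(meta.genotype),
                sex=str(meta.sex),
                age_months=float(meta.age_months),
                condition=str(condition),
                events=[
                    EntryEvent(str(r.arm), float(r.t_enter_s), float(r.t_exit_s))
                    for r in group.itertuples()
                ],
                duration_s=duration,
                arm_mode=mode,
            )
        )
        logger.info(
            "read session %s/%s: %d entries", mouse_id, condition, len(group)
        )
    return sessions


def write_sessions(sessions: Iterable[Session], path: str | Path) -> None:
    """Write sessions to the event-log CSV dialect (lossless round trip)."""
    rows = []
    for s in sessions:
        for ev in s.events:
            rows.append(
                {
                    "mouse_id": s.mouse_id,
                    "genotype": s.genotype,
                    "sex": s.sex,
                    "age_months": s.age_months,
                    "condition": s.condition,
                    "arm": ev.arm,
                    "t_enter_s": ev.t_enter,
                    "t_exit_s": ev.t_exit,
                }
            )
    pd.DataFrame(rows, columns=list(EVENT_LOG_COLUMNS)).to_csv(path, index=False)


def write_circos_table(
    profile: TransitionProfile,
    path: str | Path,
    quartile: str | None = None,
) -> None:
    """Write a Circos tableviewer TSV of transition counts.

    Rows are origin arms, columns destination arms, diagonal zero; the
    matrix sums to the session's total transitions.  With ``quartile``
    ("Q4_most_frequent" or "Q1_least_frequent") only the selected three
    transitions keep their counts, mirroring the chord diagrams that show
    only the most or least frequent transitions.
    """
    labels = sorted(profile.arms)
    keep = None
    if quartile is not None:
        keep = set(maze.select_quartile_transitions(profile, quartile))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("labels\t" + "\t".join(labels) + "\n")
        for a in labels:
            cells = []
            for b in labels:
                if a == b:
                    n = 0
                else:
                    n = profile.uni_counts[(a, b)]
                    if keep is not None and (a, b) not in keep:
                        n = 0
                cells.append(str(n))
            fh.write(a + "\t" + "\t".join(cells) + "\n")


def read_circos_table(path: str | Path) -> tuple[list[str], list[list[int]]]:
    """Read back a tableviewer TSV as (labels, count matrix)."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        labels = header[1:]
        matrix = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            matrix.append([int(x) for x in parts[1:]])
    return labels, matrix


def summarize_cohort(sessions: Sequence[Session]) -> pd.DataFrame:
    """Tidy per-session metric table: one row per session x metric.

    Metrics: total_entries, collapsed_reentries, percent_alternation,
    per-arm percent_entries/percent_time, the 12 unidirectional and 6
    bidirectional transition percentages, plus pass-through distance/speed
    when present.  Sessions too short to score (N < 4 after collapsing)
    keep their row with a missing alternation value and are flagged.
    """
    if not sessions:
        raise ValueError("no sessions to summarize")
    rows: list[dict] = []

    def emit(s: Session, metric: str, value, flag: str = "") -> None:
        rows.append(
            {
                "mouse_id": s.mouse_id,
                "genotype": s.genotype,
                "sex": s.sex,
                "age_months": s.age_months,
                "condition": s.condition,
                "metric": metric,
                "value": value,
                "flag": flag,
            }
        )

    for s in sessions:
        seq, n_collapsed = collapse_reentries(s.raw_sequence)
        emit(s, "total_entries", len(s.events))
        emit(s, "collapsed_reentries", n_collapsed)
        if n_collapsed:
            logger.warning(
                "session %s/%s: collapsed %d same-arm re-entries",
                s.mouse_id, s.condition, n_collapsed,
            )
        if len(seq) >= 4:
            alt = maze.percent_alternation(seq)
            emit(s, "percent_alternation", alt.percent)
        else:
            emit(s, "percent_alternation", float("nan"), flag="too_few_entries")
            logger.warning(
                "session %s/%s: N=%d < 4, alternation not scored",
                s.mouse_id, s.condition, len(seq),
            )
        if seq:
            for arm, pct in maze.percent_entries(seq, s.arms).items():
                emit(s, f"percent_entries_{arm}", pct)
        try:
            for arm, pct in maze.percent_time(s, s.arms).items():
                emit(s, f"percent_time_{arm}", pct)
        except ValueError:
            pass
        if len(seq) >= 2:
            prof = maze.transition_profile(seq, s.arms)
            for (a, b), pct in prof.uni_percent.items():
                emit(s, f"uni_{a}_{b}", pct)
            for pair, pct in prof.bi_percent.items():
                a, b = sorted(pair)
                emit(s, f"bi_{a}_{b}", pct)
        if s.distance_m is not None:
            emit(s, "distance_m", s.distance_m)
        if s.speed_mps is not None:
            emit(s, "speed_mps", s.speed_mps)
    return pd.DataFrame(rows)


def _parse_led(spec) -> LEDSpectrum:
    if isinstance(spec, str):
        return LED_BY_ARM[spec]
    comps = tuple(
        SpectrumComponent(
            peak_nm=float(c["peak_nm"]),
            fwhm_nm=float(c["fwhm_nm"]),
            weight=float(c.get("weight", 1.0)),
        )
        for c in spec["components"]
    )
    return LEDSpectrum(comps)


def load_condition_config(path: str | Path) -> list[LightCondition]:
    """Load an illumination-condition config (YAML or JSON).

    Schema::

        leds:                  # optional; defaults to the built-in arm LEDs
          R: {components: [{peak_nm: 628, fwhm_nm: 17}]}
        conditions:
          E:
            R: {ev: 4.585}     # either ev or lux per arm
            G: {lux: 60}
            ...
          NC: unlit            # all arms unlit

    Derived photometric/radiometric fields are filled in by the photometry
    module.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    try:
        cfg = (
            json.loads(text)
            if path.suffix.lower() == ".json"
            else yaml.safe_load(text)
        )
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ValueError(f"{path}: cannot parse condition config: {exc}") from exc
    if not isinstance(cfg, Mapping) or "conditions" not in cfg:
        raise ValueError(f"{path}: config must contain a 'conditions' mapping")

    leds = dict(LED_BY_ARM)
    for arm, spec in (cfg.get("leds") or {}).items():
        leds[arm] = _parse_led(spec)

    out: list[LightCondition] = []
    for name, arms_cfg in cfg["conditions"].items():
        if arms_cfg in (None, "unlit"):
            out.append(
                LightCondition(name=name, arms={a: None for a in leds})
            )
            continue
        stimuli: dict[str, ArmStimulus | None] = {}
        for arm in leds:
            if arm not in arms_cfg:
                raise ValueError(
                    f"{path}: condition {name!r}: missing entry for arm {arm!r}"
                )
            entry = arms_cfg[arm]
            ev = entry.get("ev")
            lux = entry.get("lux")
            if lux is not None and lux < 0:
                raise ValueError(
                    f"{path}: condition {name!r} arm {arm!r}: negative illuminance"
                )
            stimuli[arm] = characterize_arm(arm, leds[arm], ev=ev, lux=lux)
        out.append(LightCondition(name=name, arms=stimuli))
    return out
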