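"""Flat key-value configuration (INI) shared by all commands.

One file, one section per module; keys mirror the dataclass field names.
Command-line flags override config values, and overrides are logged by the
CLI so every run is auditable.

Example::

    [thresholds]
    significant_rise = 0.20
    large_rise = 0.40
    recheck_weeks = 6

    [simulate]
    n_patients = 200
    recurrence_fraction = 0.10
    seed = 1

    [labs]
    default = Central Hospital Laboratory
    97 = Lab North
    56 = Lab Eindhoven
"""

from __future__ import annotations

import configparser
import hashlib
from datetime import date, timedelta
from pathlib import Path

from .engine import Thresholds
from .simulator import SimulationConfig

__all__ = ["load_config", "load_thresholds", "load_simulation_config", "load_lab_directory", "config_hash"]


def load_config(path: str | Path) -> configparser.ConfigParser:
    parser = configparser.ConfigParser()
    read = parser.read(path)
    if not read:
        raise FileNotFoundError(f"config file not found: {path}")
    return parser


def config_hash(path: str | Path) -> str:
    """Short content hash of the config file, logged with every run."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]


def load_thresholds(parser: configparser.ConfigParser) -> Thresholds:
    if not parser.has_section("thresholds"):
        return Thresholds()
    section = parser["thresholds"]
    return Thresholds(
        significant_rise=section.getfloat("significant_rise", 0.20),
        large_rise=section.getfloat("large_rise", 0.40),
        recheck_interval=timedelta(weeks=section.getfloat("recheck_weeks", 6.0)),
        intensive_interval_months=section.getint("intensive_interval_months", 3),
        extended_interval_months=section.getint("extended_interval_months", 6),
        intensive_years=section.getint("intensive_years", 3),
        total_years=section.getint("total_years", 5),
    )


def load_simulation_config(
    parser: configparser.ConfigParser, seed_override: int | None = None
) -> SimulationConfig:
    defaults = SimulationConfig()
    if parser.has_section("simulate"):
        sec = parser["simulate"]
        get_float = sec.getfloat
        get_int = sec.getint
        start = (
            date.fromisoformat(sec["start_date"]) if sec.get("start_date") else defaults.start_date
        )
    else:
        get_float = lambda _k, d: d  # noqa: E731
        get_int = lambda _k, d: d  # noqa: E731
        start = defaults.start_date
    seed = seed_override if seed_override is not None else get_int("seed", defaults.seed)
    return SimulationConfig(
        n_patients=get_int("n_patients", defaults.n_patients),
        baseline_median=get_float("baseline_median", defaults.baseline_median),
        inter_cv=get_float("inter_cv", defaults.inter_cv),
        intra_cv=get_float("intra_cv", defaults.intra_cv),
        recurrence_fraction=get_float("recurrence_fraction", defaults.recurrence_fraction),
        onset_window_months=(
            get_int("onset_window_start_months", defaults.onset_window_months[0]),
            get_int("onset_window_end_months", defaults.onset_window_months[1]),
        ),
        doubling_time_days=get_float("doubling_time_days", defaults.doubling_time_days),
        signal_amplitude=get_float("signal_amplitude", defaults.signal_amplitude),
        adherence=get_float("adherence", defaults.adherence),
        arm_split=get_float("arm_split", defaults.arm_split),
        start_date=start,
        seed=seed,
    )


def load_lab_directory(parser: configparser.ConfigParser) -> tuple[dict[str, str], str | None]:
    """Return (prefix → lab name, default lab) from the [labs] section."""
    if not parser.has_section("labs"):
        return {}, None
    directory = {k: v for k, v in parser["labs"].items() if k != "default"}
    return directory, parser["labs"].get("default")
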