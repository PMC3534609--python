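"""Packaged Minnesota starvation-study data and series CSV input/output.

Two fixtures ship with the package, both transcribed from the published
group tables of the 24-week semi-starvation phase:

* the group's weekly body weight, total energy expenditure, mean intake
  and net intake (week 0 baseline plus S1–S24), and
* the 32 subjects' observed weekly weights S1–S24 together with the
  published model trajectories and per-subject R² values.

Fixture files carry recorded SHA-256 checksums that are verified on every
load, so silent corruption of the packaged data fails loudly.

The series CSV dialect is: header row, comma separated, ``.`` decimal,
columns ``week, body_weight_kg, tee_kcal_day, intake_kcal_day,
net_intake_kcal_day`` with week tokens ``0`` or ``S<k>``.
"""

from __future__ import annotations

import csv
import hashlib
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .diffusion_model import EnergyBalanceRecord, WeightSeries, parse_week, week_label

__all__ = [
    "SubjectRecord",
    "load_group_series",
    "load_subjects",
    "read_series_csv",
    "write_series_csv",
]

logger = logging.getLogger(__name__)

_GROUP_FILE = "minnesota_group_weekly.csv"
_SUBJECTS_FILE = "minnesota_subjects.csv"
_CHECKSUMS = {
    _GROUP_FILE: "000ac726ed828f2287eff3725ac22e60fe95e92540f1ca236006c126260eb66c",
    _SUBJECTS_FILE: "cef8f365f98ce19845b98f152bfff087ac3705bed77f0aac85ab90ce5a75dfd2",
}

_COLUMNS = [
    "week",
    "body_weight_kg",
    "tee_kcal_day",
    "intake_kcal_day",
    "net_intake_kcal_day",
]


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's observed weights plus the published model trajectory."""

    subject_id: str
    observed_weights: np.ndarray  # kg, weeks S1..S24
    printed_model_weights: np.ndarray  # kg, weeks S1..S24
    printed_r2: float

    def __post_init__(self) -> None:
        if len(self.observed_weights) != 24 or len(self.printed_model_weights) != 24:
            raise ValueError(f"subject {self.subject_id}: expected 24 weekly values")
        if not 0 < self.printed_r2 <= 1:
            raise ValueError(f"subject {self.subject_id}: printed_r2 out of (0, 1]")


def _fixture_text(name: str) -> str:
    data = resources.files("weightdiffusion.data").joinpath(name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise RuntimeError(
            f"packaged fixture {name} is corrupted: sha256 {digest} != {_CHECKSUMS[name]}"
        )
    return data.decode("utf-8")


def load_group_series() -> WeightSeries:
    """The group's weekly series: week 0 baseline plus S1–S24 (25 records)."""
    rows = list(csv.DictReader(_fixture_text(_GROUP_FILE).splitlines()))
    records = [
        EnergyBalanceRecord(
            week_index=parse_week(r["week"]),
            week_label=r["week"],
            body_weight=float(r["body_weight_kg"]),
            tee=float(r["tee_kcal_day"]),
            mean_intake=float(r["intake_kcal_day"]),
            net_intake=float(r["net_intake_kcal_day"]),
        )
        for r in rows
    ]
    return WeightSeries(records)


def load_subjects() -> list[SubjectRecord]:
    """All 32 subjects' observed and published-model weekly weights."""
    rows = list(csv.DictReader(_fixture_text(_SUBJECTS_FILE).splitlines()))
    week_cols = [f"S{k}" for k in range(1, 25)]
    by_subject: dict[str, dict[str, object]] = {}
    order: list[str] = []
    for r in rows:
        sid = r["subject"]
        if sid not in by_subject:
            by_subject[sid] = {}
            order.append(sid)
        weights = np.array([float(r[c]) for c in week_cols])
        by_subject[sid][r["series"]] = weights
        if r["series"] == "model":
            by_subject[sid]["r2"] = float(r["r2"])
    return [
        SubjectRecord(
            subject_id=sid,
            observed_weights=by_subject[sid]["observed"],
            printed_model_weights=by_subject[sid]["model"],
            printed_r2=by_subject[sid]["r2"],
        )
        for sid in order
    ]


def read_series_csv(path: str | Path) -> WeightSeries:
    """Parse a weekly series CSV; errors name the offending line.

    A file lacking the net-intake column but carrying TEE and intake has
    the net column computed as intake − TEE (logged).
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in _COLUMNS[:4] if c not in header]
        if missing:
            raise ValueError(f"{path}: missing required column(s) {missing}")
        derive_net = _COLUMNS[4] not in header
        if derive_net:
            logger.warning(
                "%s: no net_intake_kcal_day column; deriving net = intake - TEE", path
            )
        records = []
        for lineno, row in enumerate(reader, start=2):
            try:
                idx = parse_week(row["week"])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            try:
                weight = float(row["body_weight_kg"])
                tee = float(row["tee_kcal_day"])
                intake = float(row["intake_kcal_day"])
                net = intake - tee if derive_net else float(row["net_intake_kcal_day"])
            except (TypeError, ValueError):
                raise ValueError(f"{path}:{lineno}: unparseable numeric field") from None
            if records and idx <= records[-1].week_index:
                raise ValueError(
                    f"{path}:{lineno}: week {week_label(idx)} out of order "
                    f"(previous was {records[-1].week_label})"
                )
            try:
                records.append(
                    EnergyBalanceRecord(idx, week_label(idx), weight, tee, intake, net)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    if not records:
        raise ValueError(f"{path}: no data rows")
    return WeightSeries(records)


def _fmt(x: float) -> str:
    return format(x, ".10g")


def write_series_csv(series: WeightSeries, path: str | Path) -> None:
    """Write a weekly series in the standard dialect (round-trip exact)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for r in series:
            writer.writerow(
                [r.week_label, _fmt(r.body_weight), _fmt(r.tee), _fmt(r.mean_intake), _fmt(r.net_intake)]
            )
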