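"""Longitudinal rig log: an append-only record of QC results.

Every characterization procedure produces a small set of scalar metrics
(photon sensitivity, FWHMs, SNR per gain, maximum power, ...). Keeping
them in a shared, dated, append-only store lets a facility track drift,
schedule re-checks and decide when hardware needs service. The store is
newline-delimited JSON: human-diffable and trivially merged.

For PMT light-response means measured against a tritium reference source,
trend analysis also reports a decay-corrected series (divided by
k = exp(-d / 17.75) for an interval of d years): a decline beyond the decay
prediction is attributable to the detector, not the source.
"""

from __future__ import annotations

import datetime as _dt
import json
import numbers as _numbers
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .pmt import tritium_decay_factor

PROCEDURES = ("power", "fov_size", "homogeneity", "psf", "gdd", "pmt",
              "photon_flux")

#: Default re-check cadence in months.
DEFAULT_SCHEDULE = {
    "pmt": 1, "power": 1,
    "homogeneity": 3, "psf": 3,
    "fov_size": 6, "gdd": 6, "photon_flux": 6,
}


@dataclass
class RigLogRecord:
    timestamp: str                 # ISO 8601
    procedure_id: str
    metrics: dict                  # metric name -> numeric value
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.procedure_id not in PROCEDURES:
            raise ValueError(
                f"unknown procedure_id {self.procedure_id!r}; "
                f"expected one of {PROCEDURES}"
            )
        # validate the timestamp eagerly so bad records never enter the store
        _dt.datetime.fromisoformat(self.timestamp)
        for k, v in self.metrics.items():
            if isinstance(v, bool) or not isinstance(v, _numbers.Real):
                raise ValueError(f"metric {k!r} is not numeric: {v!r}")
        self.metrics = {k: float(v) for k, v in self.metrics.items()}


class RigLog:
    """Append-only NDJSON store of :class:`RigLogRecord`."""

    def __init__(self, path: str | Path):
        self.path = Path(path)

    def record(self, procedure_id: str, metrics: dict, *,
               timestamp: str | None = None, **metadata) -> RigLogRecord:
        """Append a record; returns it as stored. Duplicates are kept."""
        rec = RigLogRecord(
            timestamp=timestamp or _dt.datetime.now().isoformat(timespec="seconds"),
            procedure_id=procedure_id,
            metrics=metrics,
            metadata=metadata,
        )
        with open(self.path, "a") as fh:
            fh.write(json.dumps(asdict(rec)) + "\n")
        return rec

    def read_all(self) -> list[RigLogRecord]:
        if not self.path.exists():
            return []
        records = []
        with open(self.path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    records.append(RigLogRecord(**json.loads(line)))
        return records

    def due_report(self, schedule: dict | None = None,
                   today: _dt.date | None = None) -> list[str]:
        """Procedures whose most recent record is older than their interval.

        Intervals are in months (one month = 30.44 days). Procedures with
        no record at all are always due.
        """
        schedule = {**DEFAULT_SCHEDULE, **(schedule or {})}
        today = today or _dt.date.today()
        latest: dict[str, _dt.date] = {}
        for rec in self.read_all():
            d = _dt.datetime.fromisoformat(rec.timestamp).date()
            if rec.procedure_id not in latest or d > latest[rec.procedure_id]:
                latest[rec.procedure_id] = d
        due = []
        for proc, months in schedule.items():
            if months <= 0:
                raise ValueError(f"schedule interval for {proc!r} must be > 0")
            if proc not in latest:
                due.append(proc)
            elif (today - latest[proc]).days > months * 30.44:
                due.append(proc)
        return sorted(due)

    def trend(self, procedure_id: str, metric: str, *,
              tolerance: float | None = None,
              tritium_corrected: bool = False) -> dict:
        """Chronological series of one metric, with an optional drift flag.

        With ``tritium_corrected`` (PMT light-response means measured on a
        tritium source), a companion series divides each value by the decay
        factor for the elapsed time since the first record, so a flat
        corrected series means the detector itself is stable.

        ``tolerance`` flags the latest value when its relative change from
        the first (decay-corrected when applicable) exceeds it.
        """
        recs = [r for r in self.read_all() if r.procedure_id == procedure_id]
        recs = [r for r in recs if metric in r.metrics]
        if len(recs) < 2:
            raise ValueError(
                f"need >= 2 records of {procedure_id}/{metric}, found {len(recs)}"
            )
        recs.sort(key=lambda r: r.timestamp)
        times = [_dt.datetime.fromisoformat(r.timestamp) for r in recs]
        values = [r.metrics[metric] for r in recs]
        out = {"timestamps": [t.isoformat() for t in times], "values": values,
               "flag": False, "reason": ""}
        series = values
        if tritium_corrected:
            t0 = times[0]
            years = [(t - t0).days / 365.25 for t in times]
            corrected = [v / tritium_decay_factor(d) for v, d in zip(values, years)]
            out["decay_corrected"] = corrected
            series = corrected
        if tolerance is not None and series[0] != 0:
            change = (series[-1] - series[0]) / series[0]
            out["relative_change"] = change
            if abs(change) > tolerance:
                out["flag"] = True
                out["reason"] = (
                    f"{metric} changed {100 * change:+.1f}% "
                    f"(tolerance {100 * tolerance:.0f}%)"
                    + (" beyond expected tritium decay" if tritium_corrected else "")
                )
        return out
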