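"""Incubation time-series model, delimited-text I/O, rates and yields.

Measurements carry their unit explicitly (mM for solutes, Pa for gas partial
pressures, mmol_per_L for cumulative methane) and a detection-limit censoring
flag, so "formate was never detected" survives a round trip through text.

Derived quantities:

* :func:`consumption_rate` - windowed least-squares decline of a solute,
  estimated per replicate and averaged, censored points excluded;
* :func:`stoichiometric_yield` - observed vs expected product/substrate molar
  ratio, with headspace gases converted to mmol per liter of medium via the
  ideal gas law.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import (
    InsufficientDataError,
    ParseError,
    UndefinedRatioError,
    UsageError,
)
from .thermo_core import Reaction

UNITS = ("mM", "Pa", "mmol_per_L")

#: Ideal gas constant, J mol^-1 K^-1, for headspace mole conversions.
_R_J = 8.314462618

_COLUMNS = [
    "time_h",
    "replicate",
    "analyte",
    "value",
    "unit",
    "below_detection",
    "detection_limit",
]


@dataclass(frozen=True)
class Measurement:
    """One observation of one analyte in one replicate vial."""

    time: float
    replicate: str
    analyte: str
    value: float
    unit: str
    below_detection: bool = False
    detection_limit: float | None = None

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ParseError(f"unsupported unit {self.unit!r}; expected one of {UNITS}")
        if self.time < 0:
            raise ParseError(f"time must be >= 0 h, got {self.time}")
        if self.below_detection and self.detection_limit is None:
            raise ParseError(
                f"{self.analyte} at t={self.time}: censored measurement needs a "
                "detection_limit"
            )


@dataclass
class TimeSeries:
    """Ordered, replicated incubation measurements plus vial metadata."""

    measurements: list[Measurement]
    scenario: str = ""
    liquid_volume_mL: float = 30.0
    headspace_volume_mL: float = 20.0
    temperature: float = 303.15

    def __post_init__(self) -> None:
        self.measurements = sorted(
            self.measurements, key=lambda m: (m.analyte, m.replicate, m.time)
        )
        self._validate()

    def _validate(self) -> None:
        units: dict[str, str] = {}
        last: dict[tuple[str, str], float] = {}
        for m in self.measurements:
            if units.setdefault(m.analyte, m.unit) != m.unit:
                raise ParseError(
                    f"analyte {m.analyte!r} reported in both "
                    f"{units[m.analyte]!r} and {m.unit!r}"
                )
            key = (m.replicate, m.analyte)
            if key in last and m.time <= last[key]:
                raise ParseError(
                    f"time not strictly increasing for replicate {m.replicate!r}, "
                    f"analyte {m.analyte!r} at t={m.time}"
                )
            last[key] = m.time

    @property
    def analytes(self) -> tuple[str, ...]:
        return tuple(sorted({m.analyte for m in self.measurements}))

    @property
    def replicates(self) -> tuple[str, ...]:
        return tuple(sorted({m.replicate for m in self.measurements}))

    def unit_of(self, analyte: str) -> str:
        for m in self.measurements:
            if m.analyte == analyte:
                return m.unit
        raise UsageError(f"series has no analyte {analyte!r}")

    def select(self, analyte: str, replicate: str | None = None, censored: bool | None = None):
        out = [m for m in self.measurements if m.analyte == analyte]
        if replicate is not None:
            out = [m for m in out if m.replicate == replicate]
        if censored is not None:
            out = [m for m in out if m.below_detection == censored]
        return out

    def __len__(self) -> int:
        return len(self.measurements)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TimeSeries):
            return NotImplemented
        return (
            self.measurements == other.measurements
            and self.scenario == other.scenario
            and self.liquid_volume_mL == other.liquid_volume_mL
            and self.headspace_volume_mL == other.headspace_volume_mL
            and self.temperature == other.temperature
        )


# -- delimited text I/O ------------------------------------------------------

_META_KEYS = {
    "scenario": str,
    "liquid_volume_mL": float,
    "headspace_volume_mL": float,
    "temperature_K": float,
}


def write_timeseries(series: TimeSeries, target=None, delimiter: str = "\t") -> str:
    """Serialize to delimited text; returns the text, optionally writing it."""
    buf = io.StringIO()
    buf.write(f"# scenario = {series.scenario}\n")
    buf.write(f"# liquid_volume_mL = {series.liquid_volume_mL!r}\n")
    buf.write(f"# headspace_volume_mL = {series.headspace_volume_mL!r}\n")
    buf.write(f"# temperature_K = {series.temperature!r}\n")
    writer = csv.writer(buf, delimiter=delimiter, lineterminator="\n")
    writer.writerow(_COLUMNS)
    for m in series.measurements:
        writer.writerow(
            [
                repr(float(m.time)),
                m.replicate,
                m.analyte,
                repr(float(m.value)),
                m.unit,
                "true" if m.below_detection else "false",
                "" if m.detection_limit is None else repr(float(m.detection_limit)),
            ]
        )
    text = buf.getvalue()
    if target is not None:
        Path(target).write_text(text, encoding="utf-8")
    return text


def read_timeseries(source) -> TimeSeries:
    """Parse the delimited time-series format (comma- or tab-delimited).

    Malformed rows raise :class:`~syntherm.errors.ParseError` carrying the
    1-based line number.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text(encoding="utf-8")
    meta: dict = {}
    header: list[str] | None = None
    delimiter = "\t"
    measurements: list[Measurement] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                key, value = key.strip(), value.strip()
                if key in _META_KEYS:
                    try:
                        meta[key] = _META_KEYS[key](value)
                    except ValueError as exc:
                        raise ParseError(f"bad metadata {key}={value!r}", lineno) from exc
            continue
        if header is None:
            delimiter = "\t" if "\t" in raw else ","
            header = [h.strip() for h in next(csv.reader([raw], delimiter=delimiter))]
            if header != _COLUMNS:
                raise ParseError(f"expected columns {_COLUMNS}, got {header}", lineno)
            continue
        fields = next(csv.reader([raw], delimiter=delimiter))
        if len(fields) != len(_COLUMNS):
            raise ParseError(
                f"expected {len(_COLUMNS)} fields, got {len(fields)}", lineno
            )
        t, rep, analyte, value, unit, censored, limit = (f.strip() for f in fields)
        if censored.lower() not in ("true", "false"):
            raise ParseError(f"below_detection must be true/false, got {censored!r}", lineno)
        try:
            m = Measurement(
                time=float(t),
                replicate=rep,
                analyte=analyte,
                value=float(value),
                unit=unit,
                below_detection=censored.lower() == "true",
                detection_limit=float(limit) if limit else None,
            )
        except (ValueError, ParseError) as exc:
            raise ParseError(str(exc), lineno) from exc
        measurements.append(m)
    if header is None:
        raise ParseError("no header row found")
    kwargs = {}
    if "scenario" in meta:
        kwargs["scenario"] = meta["scenario"]
    if "liquid_volume_mL" in meta:
        kwargs["liquid_volume_mL"] = meta["liquid_volume_mL"]
    if "headspace_volume_mL" in meta:
        kwargs["headspace_volume_mL"] = meta["headspace_volume_mL"]
    if "temperature_K" in meta:
        kwargs["temperature"] = meta["temperature_K"]
    try:
        return TimeSeries(measurements, **kwargs)
    except ParseError:
        raise


# -- derived quantities ------------------------------------------------------


@dataclass(frozen=True)
class RateEstimate:
    """Replicate-averaged linear decline rate, mM/h (positive = consumption)."""

    rate: float
    per_replicate: dict[str, float]
    window: tuple[float, float]

    @property
    def sd(self) -> float:
        values = list(self.per_replicate.values())
        if len(values) < 2:
            return 0.0
        return float(np.std(values, ddof=1))


def default_decline_window(series: TimeSeries, analyte: str) -> tuple[float, float]:
    """Longest contiguous interval over which the replicate-mean declines.

    Means are taken across replicates at each sampled time; the window is the
    longest run of strictly decreasing consecutive means (the full range if
    the profile never increases).
    """
    points = series.select(analyte, censored=False)
    if not points:
        raise InsufficientDataError(f"no uncensored {analyte!r} measurements")
    by_time: dict[float, list[float]] = {}
    for m in points:
        by_time.setdefault(m.time, []).append(m.value)
    times = sorted(by_time)
    means = [float(np.mean(by_time[t])) for t in times]
    if len(times) < 2:
        return (times[0], times[0])
    best = (0, 0)
    start = 0
    for i in range(1, len(times)):
        if means[i] < means[i - 1]:
            if i - start > best[1] - best[0]:
                best = (start, i)
        else:
            start = i
    if best == (0, 0):
        return (times[0], times[-1])
    return (times[best[0]], times[best[1]])


def consumption_rate(
    series: TimeSeries,
    analyte: str,
    window: tuple[float, float] | None = None,
) -> RateEstimate:
    """Least-squares consumption rate of *analyte*, mM/h.

    The slope of value vs time is fitted per replicate inside *window*
    (default: the maximal monotone-decline interval), negated so that
    consumption is positive, and averaged across replicates.  Censored points
    are excluded.  Each replicate needs at least two uncensored points.
    """
    if window is None:
        window = default_decline_window(series, analyte)
    t0, t1 = window
    per_replicate: dict[str, float] = {}
    for rep in series.replicates:
        pts = [
            m
            for m in series.select(analyte, replicate=rep, censored=False)
            if t0 <= m.time <= t1
        ]
        if len(pts) < 2:
            raise InsufficientDataError(
                f"replicate {rep!r} has {len(pts)} uncensored {analyte!r} point(s) "
                f"in window {window}; need >= 2"
            )
        t = np.array([m.time for m in pts])
        v = np.array([m.value for m in pts])
        slope = np.polyfit(t, v, 1)[0]
        per_replicate[rep] = -float(slope)
    rate = float(np.mean(list(per_replicate.values())))
    return RateEstimate(rate=rate, per_replicate=per_replicate, window=window)


def _net_change_mmol_per_L(series: TimeSeries, analyte: str) -> float:
    """Net change (last minus first uncensored replicate-mean), mmol per liter
    of medium; Pa gas traces are converted via headspace volume and the ideal
    gas law."""
    unit = series.unit_of(analyte)
    first: list[float] = []
    last: list[float] = []
    for rep in series.replicates:
        pts = series.select(analyte, replicate=rep, censored=False)
        if len(pts) < 2:
            raise InsufficientDataError(
                f"replicate {rep!r} has too few uncensored {analyte!r} points"
            )
        first.append(pts[0].value)
        last.append(pts[-1].value)
    delta = float(np.mean(last)) - float(np.mean(first))
    if unit in ("mM", "mmol_per_L"):
        return delta
    # Pa -> mol in headspace -> mmol per liter of liquid medium
    v_head = series.headspace_volume_mL / 1e6  # m^3
    v_liq = series.liquid_volume_mL / 1000.0  # L
    mol = delta * v_head / (_R_J * series.temperature)
    return mol * 1000.0 / v_liq


@dataclass(frozen=True)
class YieldResult:
    """Observed vs stoichiometric product yield per liter of medium."""

    observed_ratio: float
    expected_ratio: float
    agreement_fraction: float
    delta_substrate_mmol_per_L: float
    delta_product_mmol_per_L: float

    @property
    def expected_product_mmol_per_L(self) -> float:
        return abs(self.delta_substrate_mmol_per_L) * self.expected_ratio


def stoichiometric_yield(
    series: TimeSeries,
    substrate: str,
    product: str,
    reaction: Reaction,
) -> YieldResult:
    """Compare the observed product/substrate molar ratio with *reaction*.

    ``observed_ratio = |d(product)| / |d(substrate)|`` over the series, both
    in mmol per liter of medium; ``expected_ratio`` from the reaction
    coefficients; ``agreement_fraction = observed / expected``.
    """
    cs = reaction.coefficient(substrate)
    cp = reaction.coefficient(product)
    if cs == 0 or cp == 0 or (cs < 0) == (cp < 0):
        raise UsageError(
            f"{substrate!r} and {product!r} must appear in {reaction.name!r} "
            "with opposite signs"
        )
    d_sub = _net_change_mmol_per_L(series, substrate)
    d_prod = _net_change_mmol_per_L(series, product)
    if d_sub == 0:
        raise UndefinedRatioError(f"no net {substrate!r} change; ratio undefined")
    expected = abs(float(cp / cs))
    observed = abs(d_prod) / abs(d_sub)
    return YieldResult(
        observed_ratio=observed,
        expected_ratio=expected,
        agreement_fraction=observed / expected,
        delta_substrate_mmol_per_L=d_sub,
        delta_product_mmol_per_L=d_prod,
    )


def apply_detection_limit(
    series: TimeSeries, analyte: str, limit: float, unit: str | None = None
) -> TimeSeries:
    """Censor every *analyte* value below *limit* (same unit as the analyte).

    Censored measurements keep the limit as their recorded value; applying
    the same limit twice is a no-op.  If *unit* is given it must match the
    unit the analyte is recorded in.
    """
    if not limit > 0:
        raise UsageError(f"detection limit must be > 0, got {limit}")
    if analyte not in series.analytes:
        raise UsageError(f"series has no analyte {analyte!r}")
    if unit is not None and unit != series.unit_of(analyte):
        raise UsageError(
            f"detection limit unit {unit!r} does not match {analyte!r} unit "
            f"{series.unit_of(analyte)!r}"
        )
    out = []
    for m in series.measurements:
        if m.analyte == analyte and m.value < limit:
            m = replace(m, value=limit, below_detection=True, detection_limit=limit)
        out.append(m)
    return TimeSeries(
        out,
        scenario=series.scenario,
        liquid_volume_mL=series.liquid_volume_mL,
        headspace_volume_mL=series.headspace_volume_mL,
        temperature=series.temperature,
    )
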