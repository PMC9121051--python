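"""HDMM motion-log parsing and intrafraction motion statistics.

During frameless Gamma Knife delivery an infrared camera (HDMM) tracks a
nose-tip marker relative to four mask-frame reflectors.  The control system
logs a record whenever the windowed radial displacement moves by more than a
trigger distance from the last record; delivery is paused whenever the radial
displacement exceeds the gating threshold, and after a repeat CBCT the
baseline is reset.  Two subtleties of the recorded data are preserved here
rather than "fixed":

* ``radial_mm`` is the trailing-window *mean* radial displacement, while
  ``x/y/z`` are *instantaneous* values from the end of the window — so the
  Euclidean norm of (x, y, z) generally disagrees with the recorded radial.
  Signed per-axis statistics use x/y/z; radial statistics use the windowed
  radial; the two are never mixed.
* The mean position over treatment is a time-weighted (trapezoidal) average
  over *treating* intervals only, with the radial curve truncated at the
  gating threshold — beyond it the beam was off, so larger excursions carry
  no delivered dose.

Log dialect (CSV): optional ``# key: value`` metadata lines, then a header
``t_s,x_mm,y_mm,z_mm,radial_mm,state,event`` with ``state`` in
{treating, paused} and ``event`` in {baseline, record, rebaseline, end}.
A baseline/rebaseline row carries the post-image-guidance residual.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .budget import UncertaintyComponent, vector_mean

__all__ = [
    "GatingConfig",
    "MarkerSample",
    "MotionTrace",
    "LogRow",
    "Segment",
    "TreatmentSession",
    "AUCResult",
    "LogParseError",
    "parse_log",
    "write_log_rows",
    "auc_mean",
    "session_auc",
    "post_cbct_residuals",
    "cohort_summary",
    "analyze_log_dir",
]

LOG_COLUMNS = ["t_s", "x_mm", "y_mm", "z_mm", "radial_mm", "state", "event"]
STATES = ("treating", "paused")
EVENTS = ("baseline", "record", "rebaseline", "end")


@dataclass(frozen=True)
class GatingConfig:
    """Motion-management configuration.

    threshold_mm : gating radius; beam pauses beyond it and the analysis
        truncates radial displacement at this value.
    record_trigger_mm : change in windowed radial (from the last emitted
        record) needed to emit a new record.
    window_ms : trailing averaging window for the radial readout.
    """

    threshold_mm: float = 1.5
    record_trigger_mm: float = 0.2
    window_ms: float = 500.0

    def __post_init__(self) -> None:
        if not (self.threshold_mm > self.record_trigger_mm > 0):
            raise ValueError("require threshold_mm > record_trigger_mm > 0")
        if not self.window_ms > 0:
            raise ValueError("require window_ms > 0")


@dataclass(frozen=True)
class MarkerSample:
    t_s: float
    x_mm: float
    y_mm: float
    z_mm: float
    radial_mm: float
    state: str = "treating"


@dataclass
class MotionTrace:
    """Time-ordered marker displacements relative to the current baseline."""

    t_s: np.ndarray
    xyz_mm: np.ndarray           # shape (n, 3), signed instantaneous
    radial_mm: np.ndarray        # windowed-mean radial, >= 0
    treating: np.ndarray         # bool; state holds until the next sample

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.xyz_mm = np.asarray(self.xyz_mm, dtype=float).reshape(-1, 3)
        self.radial_mm = np.asarray(self.radial_mm, dtype=float)
        self.treating = np.asarray(self.treating, dtype=bool)
        n = self.t_s.size
        if not (self.xyz_mm.shape[0] == self.radial_mm.size == self.treating.size == n):
            raise ValueError("trace arrays must have equal length")
        if not np.all(np.isfinite(self.t_s)):
            raise ValueError("timestamps must be finite")
        if n > 1 and not np.all(np.diff(self.t_s) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(self.radial_mm < 0):
            raise ValueError("radial displacement must be >= 0")

    def __len__(self) -> int:
        return int(self.t_s.size)

    @property
    def samples(self) -> list[MarkerSample]:
        return [
            MarkerSample(float(t), float(x), float(y), float(z), float(r),
                         "treating" if tr else "paused")
            for t, (x, y, z), r, tr in zip(self.t_s, self.xyz_mm, self.radial_mm, self.treating)
        ]


@dataclass(frozen=True)
class LogRow:
    t_s: float
    x_mm: float
    y_mm: float
    z_mm: float
    radial_mm: float
    state: str
    event: str


@dataclass
class Segment:
    """One image-guidance epoch: a baseline residual plus the trace after it."""

    residual_mm: tuple[float, float, float]
    residual_radial_mm: float
    trace: MotionTrace


@dataclass
class TreatmentSession:
    session_id: str
    gating: GatingConfig
    segments: list[Segment]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("a session needs at least one segment")

    def to_rows(self) -> list[LogRow]:
        """Re-serialize the session to dialect rows (lossless round trip)."""
        rows: list[LogRow] = []
        last_seg = len(self.segments) - 1
        for i, seg in enumerate(self.segments):
            for j, s in enumerate(seg.trace.samples):
                if j == 0:
                    event = "baseline" if i == 0 else "rebaseline"
                elif i == last_seg and j == len(seg.trace) - 1:
                    event = "end"
                else:
                    event = "record"
                rows.append(LogRow(s.t_s, s.x_mm, s.y_mm, s.z_mm, s.radial_mm, s.state, event))
        return rows


class LogParseError(ValueError):
    """Malformed motion-log file; message names the offending line."""


def write_log_rows(rows: Sequence[LogRow], destination, *, session_id: str | None = None,
                   gating: GatingConfig | None = None) -> None:
    """Write dialect rows with metadata header; floats keep full precision."""
    destination = Path(destination)
    with destination.open("w", newline="") as fh:
        if session_id is not None:
            fh.write(f"# session_id: {session_id}\n")
        if gating is not None:
            fh.write(f"# gating_threshold_mm: {gating.threshold_mm!r}\n")
            fh.write(f"# record_trigger_mm: {gating.record_trigger_mm!r}\n")
            fh.write(f"# window_ms: {gating.window_ms!r}\n")
        writer = csv.writer(fh)
        writer.writerow(LOG_COLUMNS)
        for r in rows:
            writer.writerow([repr(float(r.t_s)), repr(float(r.x_mm)), repr(float(r.y_mm)),
                             repr(float(r.z_mm)), repr(float(r.radial_mm)), r.state, r.event])


def parse_log(source) -> TreatmentSession:
    """Parse a motion log into a session segmented at baseline resets.

    Raises :class:`LogParseError` naming the line for malformed rows and for
    non-monotone timestamps.
    """
    source = Path(source)
    meta: dict[str, str] = {}
    rows: list[tuple[int, LogRow]] = []
    with source.open() as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if ":" in line:
                    key, _, value = line.lstrip("# ").partition(":")
                    meta[key.strip()] = value.strip()
                continue
            fields = next(csv.reader([line]))
            if not header_seen:
                if [f.strip() for f in fields] != LOG_COLUMNS:
                    raise LogParseError(f"{source} line {lineno}: bad header {fields!r}")
                header_seen = True
                continue
            if len(fields) != len(LOG_COLUMNS):
                raise LogParseError(f"{source} line {lineno}: expected "
                                    f"{len(LOG_COLUMNS)} fields, got {len(fields)}")
            try:
                t, x, y, z, r = (float(v) for v in fields[:5])
            except ValueError as exc:
                raise LogParseError(f"{source} line {lineno}: {exc}") from None
            state, event = fields[5].strip(), fields[6].strip()
            if state not in STATES:
                raise LogParseError(f"{source} line {lineno}: unknown state {state!r}")
            if event not in EVENTS:
                raise LogParseError(f"{source} line {lineno}: unknown event {event!r}")
            if r < 0:
                raise LogParseError(f"{source} line {lineno}: negative radial")
            rows.append((lineno, LogRow(t, x, y, z, r, state, event)))
    if not header_seen:
        raise LogParseError(f"{source}: empty file (no header)")
    if not rows:
        raise LogParseError(f"{source}: no data rows")
    if rows[0][1].event != "baseline":
        raise LogParseError(f"{source} line {rows[0][0]}: first row must be a baseline event")
    last_t = -math.inf
    for lineno, row in rows:
        if not row.t_s > last_t:
            raise LogParseError(f"{source} line {lineno}: non-monotone timestamp {row.t_s}")
        last_t = row.t_s

    gating = GatingConfig(
        threshold_mm=float(meta.get("gating_threshold_mm", 1.5)),
        record_trigger_mm=float(meta.get("record_trigger_mm", 0.2)),
        window_ms=float(meta.get("window_ms", 500.0)),
    )
    session_id = meta.get("session_id", source.stem)

    segments: list[Segment] = []
    current: list[LogRow] = []

    def flush() -> None:
        if not current:
            return
        head = current[0]
        trace = MotionTrace(
            t_s=[r.t_s for r in current],
            xyz_mm=[(r.x_mm, r.y_mm, r.z_mm) for r in current],
            radial_mm=[r.radial_mm for r in current],
            treating=[r.state == "treating" for r in current],
        )
        segments.append(Segment(residual_mm=(head.x_mm, head.y_mm, head.z_mm),
                                residual_radial_mm=head.radial_mm, trace=trace))

    for _, row in rows:
        if row.event in ("baseline", "rebaseline") and current:
            flush()
            current = []
        current.append(row)
    flush()
    return TreatmentSession(session_id=session_id, gating=gating, segments=segments)


# ---------------------------------------------------------------------------
# AUC statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AUCResult:
    """Time-weighted mean displacement over treating intervals."""

    mean_x_mm: float
    mean_y_mm: float
    mean_z_mm: float
    mean_radial_mm: float
    treating_duration_s: float


def _clipped_trapezoid(t: np.ndarray, r: np.ndarray, mask: np.ndarray, cap: float) -> float:
    """Exact integral of min(piecewise-linear r, cap) over masked intervals.

    Handles threshold crossings inside an interval analytically so the result
    is invariant to resampling the same piecewise-linear curve.
    """
    total = 0.0
    dt = np.diff(t)
    a, b = r[:-1], r[1:]
    for i in np.nonzero(mask)[0]:
        ai, bi, d = a[i], b[i], dt[i]
        if ai <= cap and bi <= cap:
            total += d * (ai + bi) / 2.0
        elif ai >= cap and bi >= cap:
            total += d * cap
        else:
            f = (cap - ai) / (bi - ai)  # crossing fraction, in (0, 1)
            if ai < cap:  # rises through the cap
                total += d * (f * (ai + cap) / 2.0 + (1.0 - f) * cap)
            else:         # falls through the cap
                total += d * (f * cap + (1.0 - f) * (cap + bi) / 2.0)
    return total


def auc_mean(segment: MotionTrace, gating: GatingConfig) -> AUCResult | None:
    """Trapezoidal time-weighted mean over treating intervals.

    The radial curve is truncated (pointwise clipped) at the gating threshold
    before integration; paused intervals contribute to neither numerator nor
    denominator.  Sample state holds until the next sample, so an interval
    spanning a state change is attributed to the state at its left endpoint
    (state changes occur exactly at record timestamps).  Returns ``None`` for
    a segment with no treating time (not an exception — an all-paused segment
    is a valid, empty observation).
    """
    if len(segment) == 0:
        raise ValueError("empty segment")
    if len(segment) == 1:
        return None
    t = segment.t_s
    mask = segment.treating[:-1]
    dt = np.diff(t)
    duration = float(np.sum(dt[mask]))
    if duration <= 0:
        return None
    means = []
    for j in range(3):
        v = segment.xyz_mm[:, j]
        trap = (dt * (v[:-1] + v[1:]) / 2.0)[mask].sum()
        means.append(float(trap) / duration)
    radial_int = _clipped_trapezoid(t, segment.radial_mm, segment.treating[:-1],
                                    gating.threshold_mm)
    return AUCResult(
        mean_x_mm=means[0], mean_y_mm=means[1], mean_z_mm=means[2],
        mean_radial_mm=radial_int / duration,
        treating_duration_s=duration,
    )


def session_auc(session: TreatmentSession) -> AUCResult | None:
    """Treating-time-weighted AUC across all segments of a session."""
    parts = [auc_mean(seg.trace, session.gating) for seg in session.segments]
    parts = [p for p in parts if p is not None]
    if not parts:
        return None
    w = np.array([p.treating_duration_s for p in parts])
    total = float(w.sum())

    def wmean(attr: str) -> float:
        return float(np.sum(w * np.array([getattr(p, attr) for p in parts])) / total)

    return AUCResult(
        mean_x_mm=wmean("mean_x_mm"), mean_y_mm=wmean("mean_y_mm"),
        mean_z_mm=wmean("mean_z_mm"), mean_radial_mm=wmean("mean_radial_mm"),
        treating_duration_s=total,
    )


def _axis_stats(arr: np.ndarray) -> tuple[tuple, tuple]:
    means = tuple(float(m) for m in arr.mean(axis=0))
    sds = tuple(float(s) for s in (arr.std(axis=0, ddof=1) if arr.shape[0] > 1
                                   else np.zeros(arr.shape[1])))
    return means, sds


def post_cbct_residuals(sessions: Iterable[TreatmentSession],
                        name: str = "Post-CBCT Residual") -> UncertaintyComponent:
    """Residual setup error remaining after each image-guidance correction.

    Pools every baseline/rebaseline residual across sessions.  Vector
    statistics use the *recorded* radial of each event (per-measurement
    magnitude convention) — not the norm of (x, y, z), which the log dialect
    records instantaneously and which therefore disagrees with the windowed
    radial.
    """
    residuals, radials = [], []
    for session in sessions:
        for seg in session.segments:
            residuals.append(seg.residual_mm)
            radials.append(seg.residual_radial_mm)
    if not residuals:
        raise ValueError("no sessions / baseline residuals provided")
    arr = np.asarray(residuals, dtype=float)
    means, sds = _axis_stats(arr)
    rad = np.asarray(radials, dtype=float)
    vec_mean = float(rad.mean())
    vec_sd = float(rad.std(ddof=1)) if rad.size > 1 else 0.0
    return UncertaintyComponent(
        name=name, vector_mean_mm=vec_mean, vector_sd_mm=vec_sd,
        axis_mean_mm=means, axis_sd_mm=sds, n=len(residuals),
        error_type="random", uncertainty_class="A",
    )


def cohort_summary(results: Sequence[AUCResult],
                   name: str = "Motion During Treatment") -> UncertaintyComponent:
    """Across-patient summary of per-session AUC means as a budget row.

    Per-axis statistics come from the signed AUC means; the vector mean/SD
    come from the per-session radial AUC means (per-measurement magnitudes).
    """
    if not results:
        raise ValueError("empty cohort")
    arr = np.array([[r.mean_x_mm, r.mean_y_mm, r.mean_z_mm] for r in results])
    means, sds = _axis_stats(arr)
    rad = np.array([r.mean_radial_mm for r in results])
    return UncertaintyComponent(
        name=name, vector_mean_mm=float(rad.mean()),
        vector_sd_mm=float(rad.std(ddof=1)) if rad.size > 1 else 0.0,
        axis_mean_mm=means, axis_sd_mm=sds, n=len(results),
        error_type="random", uncertainty_class="A",
    )


def analyze_log_dir(directory, pattern: str = "*.csv"
                    ) -> tuple[list[TreatmentSession], list[AUCResult]]:
    """Parse every log in *directory* and compute per-session AUC results."""
    directory = Path(directory)
    sessions = [parse_log(p) for p in sorted(directory.glob(pattern))]
    if not sessions:
        raise ValueError(f"no log files matching {pattern!r} in {directory}")
    results = [r for r in (session_auc(s) for s in sessions) if r is not None]
    return sessions, results
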