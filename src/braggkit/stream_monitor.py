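"""Hit-rate monitoring for serial-crystallography frame streams.

A frame is a "hit" when its strong-spot count reaches a threshold (default
16 spots); the hit rate is the fraction of hits among the frames inside a
trailing time window (default 5 s), evaluated at each frame's timestamp.
Totals are additive, so a stream split into contiguous chunks and processed
independently merges to exactly the serial result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InputError, OrderingError

__all__ = [
    "FrameRecord",
    "HitSeries",
    "RunSummary",
    "hit_flags",
    "sliding_hit_rate",
    "run_summary",
    "merge_summaries",
    "read_records_tsv",
    "write_rates_tsv",
]

DEFAULT_THRESHOLD = 16
DEFAULT_WINDOW = 5.0


@dataclass(frozen=True)
class FrameRecord:
    timestamp: float       # seconds, monotone non-decreasing within a run
    frame_id: int
    n_spots: int
    run_id: str | None = None

    def __post_init__(self):
        if self.n_spots < 0:
            raise InputError("n_spots must be non-negative")


@dataclass
class HitSeries:
    """Records plus the derived hit flags and windowed rates."""

    records: list[FrameRecord]
    threshold: int = DEFAULT_THRESHOLD
    window: float = DEFAULT_WINDOW
    rates: list[tuple[float, float]] = field(default_factory=list)

    @classmethod
    def build(
        cls,
        records: list[FrameRecord],
        threshold: int = DEFAULT_THRESHOLD,
        window: float = DEFAULT_WINDOW,
    ) -> "HitSeries":
        return cls(records, threshold, window, sliding_hit_rate(records, threshold, window))


@dataclass
class RunSummary:
    n_frames: int
    n_hits: int
    fraction: float
    per_run: dict[str, tuple[int, int]] = field(default_factory=dict)  # run -> (frames, hits)


def hit_flags(records: list[FrameRecord], threshold: int = DEFAULT_THRESHOLD) -> list[bool]:
    """flag_i = (n_spots_i >= threshold)."""
    if threshold < 0:
        raise InputError("threshold must be non-negative")
    return [r.n_spots >= threshold for r in records]


def sliding_hit_rate(
    records: list[FrameRecord],
    threshold: int = DEFAULT_THRESHOLD,
    window: float = DEFAULT_WINDOW,
) -> list[tuple[float, float]]:
    """Trailing-window hit rate at each record's timestamp.

    rate(t_i) = hits with timestamp in (t_i - window, t_i] divided by the
    frames observed in that interval.  The anchor frame is always inside its
    own window, so the denominator is never zero.
    """
    if window <= 0:
        raise InputError("window must be positive")
    for i in range(1, len(records)):
        if records[i].timestamp < records[i - 1].timestamp:
            raise OrderingError(i)
    flags = hit_flags(records, threshold)
    rates: list[tuple[float, float]] = []
    lo = 0
    n_hits_in = 0
    n_in = 0
    for i, rec in enumerate(records):
        n_in += 1
        n_hits_in += flags[i]
        while records[lo].timestamp <= rec.timestamp - window:
            n_in -= 1
            n_hits_in -= flags[lo]
            lo += 1
        rates.append((rec.timestamp, n_hits_in / n_in))
    return rates


def run_summary(
    records: list[FrameRecord], threshold: int = DEFAULT_THRESHOLD
) -> RunSummary:
    """Totals: frame count, hit count, overall fraction, per-run breakdown."""
    flags = hit_flags(records, threshold)
    n = len(records)
    n_hits = sum(flags)
    per_run: dict[str, tuple[int, int]] = {}
    for rec, flag in zip(records, flags):
        if rec.run_id is not None:
            f, h = per_run.get(rec.run_id, (0, 0))
            per_run[rec.run_id] = (f + 1, h + int(flag))
    return RunSummary(n, n_hits, n_hits / n if n else 0.0, per_run)


def merge_summaries(parts: list[RunSummary]) -> RunSummary:
    """Combine summaries of contiguous chunks; equals the serial summary."""
    n = sum(p.n_frames for p in parts)
    n_hits = sum(p.n_hits for p in parts)
    per_run: dict[str, tuple[int, int]] = {}
    for p in parts:
        for run, (f, h) in p.per_run.items():
            f0, h0 = per_run.get(run, (0, 0))
            per_run[run] = (f0 + f, h0 + h)
    return RunSummary(n, n_hits, n_hits / n if n else 0.0, per_run)


# --------------------------------------------------------------------------
# Plain-text I/O
# --------------------------------------------------------------------------

def read_records_tsv(path) -> list[FrameRecord]:
    """TSV/CSV columns: timestamp, frame_id, n_spots [, run_id]; '#' comments."""
    records: list[FrameRecord] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split("\t")
            parts = [p for p in (q.strip() for q in parts) if p]
            if parts[0].lower() in ("timestamp", "time"):
                continue
            if len(parts) < 3:
                raise InputError(f"stream row needs >= 3 columns: {raw!r}")
            records.append(
                FrameRecord(
                    timestamp=float(parts[0]),
                    frame_id=int(parts[1]),
                    n_spots=int(parts[2]),
                    run_id=parts[3] if len(parts) > 3 else None,
                )
            )
    return records


def write_rates_tsv(rates: list[tuple[float, float]], path) -> None:
    with open(path, "w") as fh:
        fh.write("window_end_time\thit_fraction\n")
        for t, r in rates:
            fh.write(f"{t:.6f}\t{r:.6f}\n")
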