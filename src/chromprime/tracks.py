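"""Piecewise-constant signal tracks with bedGraph semantics.

A :class:`TagTrack` stores, per chromosome, sorted non-overlapping intervals
with a non-negative value; bases not covered by any interval have value 0.
Windowed means and binned profiles are computed exactly from the cumulative
integral of the step function, so a window mean never depends on how the
track happens to be segmented.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = ["TagTrack", "read_bedgraph", "write_bedgraph"]


class TagTrack:
    def __init__(self, frame: pd.DataFrame) -> None:
        """``frame`` needs columns chrom, start, end, value."""
        required = {"chrom", "start", "end", "value"}
        if not required.issubset(frame.columns):
            raise ValueError(f"track frame needs columns {sorted(required)}")
        if (frame["value"] < 0).any():
            raise ValueError("track values must be >= 0")
        if (frame["end"] <= frame["start"]).any():
            raise ValueError("track intervals must have end > start")
        frame = frame.sort_values(["chrom", "start"]).reset_index(drop=True)
        self._chrom_data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, grp in frame.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy(dtype=np.int64)
            ends = grp["end"].to_numpy(dtype=np.int64)
            values = grp["value"].to_numpy(dtype=float)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping track intervals on {chrom}")
            # cum[i] = integral of the track over intervals 0..i-1
            cum = np.concatenate([[0.0], np.cumsum(values * (ends - starts))])
            self._chrom_data[str(chrom)] = (starts, ends, values, cum)
        self._frame = frame

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    def chroms(self) -> list[str]:
        return sorted(self._chrom_data)

    def integral(self, chrom: str, positions) -> np.ndarray:
        """Integral of the step function over [0, x) for each x in positions."""
        positions = np.asarray(positions, dtype=np.int64)
        if chrom not in self._chrom_data:
            return np.zeros(positions.shape, dtype=float)
        starts, ends, values, cum = self._chrom_data[chrom]
        pos = np.clip(positions, 0, None)
        idx = np.searchsorted(starts, pos, side="right")
        out = cum[idx]
        inside = idx > 0
        k = idx[inside] - 1
        partial = np.clip(pos[inside] - ends[k], None, 0)  # <= 0 within interval
        # subtract the part of interval k beyond pos (cum[idx] includes it fully)
        out[inside] += values[k] * partial
        return out

    def window_mean(self, chrom: str, start: int, end: int, divisor: int | None = None) -> float:
        """Mean value over [start, end); uncovered bases count as 0.

        Windows truncated at position 0 keep the full window width as the
        divisor (off-chromosome bases contribute zero coverage) unless an
        explicit ``divisor`` is given.
        """
        if end <= start:
            raise ValueError("window end must exceed start")
        div = (end - start) if divisor is None else divisor
        lo, hi = max(start, 0), max(end, 0)
        total = self.integral(chrom, [hi])[0] - self.integral(chrom, [lo])[0]
        return float(total / div)

    def binned_means(self, chrom: str, start: int, end: int, bin: int) -> np.ndarray:
        """Mean value per bin over [start, end) in steps of ``bin`` bp."""
        if (end - start) % bin != 0:
            raise ValueError("window must be divisible by bin")
        edges = np.arange(start, end + bin, bin)
        ints = self.integral(chrom, np.clip(edges, 0, None))
        return np.diff(ints) / bin


def read_bedgraph(path) -> TagTrack:
    """Read a 4-column bedGraph (track lines and comments skipped)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#", "browser")):
                continue
            c, s, e, v = line.split()[:4]
            rows.append((c, int(s), int(e), float(v)))
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    return TagTrack(frame)


def write_bedgraph(track: TagTrack, path) -> None:
    track.frame.to_csv(path, sep="\t", header=False, index=False,
                       columns=["chrom", "start", "end", "value"])
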