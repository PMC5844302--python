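"""Per-read-position methylation bias (M-bias) profiles and trim selection.

Library preparation distorts apparent methylation at particular read
positions, typically the read ends. The trim rule selects, per mate and
read-length class, the longest contiguous run of read positions whose
methylation level stays near the mid-read baseline:

1. positions must lie within +/- 3 SD of the mid-read mean,
2. the run must start and end with positions meeting the +/- 3 SD bound,
3. isolated (non-consecutive) outliers are tolerated inside the run as
   long as they stay within +/- 4 SD.

The mid-read mean/SD are computed over a fixed window per length class
(default positions 30-100 for PE150, 20-50 for PE75) on the library-level
profile. SD uses the n-1 denominator; a constant window falls back to a
small SD floor so the acceptance band never has zero width.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class InsufficientDataError(ValueError):
    pass


class EmptyRangeError(ValueError):
    pass


@dataclass
class MbiasProfile:
    """Methylation level per 1-based read position for one (mate, class)."""

    mate: int
    length_class: str
    level: np.ndarray     # index 0 <-> position 1; NaN where depth == 0
    depth: np.ndarray

    @property
    def length(self) -> int:
        return len(self.level)

    def level_at(self, pos: int) -> float:
        return float(self.level[pos - 1])


@dataclass
class TrimPolicy:
    midread_windows: dict = field(
        default_factory=lambda: {"PE150": (30, 100), "PE75": (20, 50)}
    )
    k_inner: float = 3.0
    k_outer: float = 4.0
    sd_floor: float = 0.002

    def __post_init__(self) -> None:
        if not self.k_outer >= self.k_inner > 0:
            raise ValueError("need k_outer >= k_inner > 0")

    def window(self, length_class: str) -> tuple[int, int]:
        try:
            return self.midread_windows[length_class]
        except KeyError:
            raise KeyError(f"no mid-read window for length class {length_class!r}")


@dataclass
class TrimRange:
    mate: int
    length_class: str
    start_pos: int
    end_pos: int
    kept_outliers: tuple
    mean: float
    sd: float


def compute_mbias(call_table: pd.DataFrame) -> dict:
    """Build one :class:`MbiasProfile` per (mate, length_class).

    ``call_table`` columns: mate, length_class, read_pos, nMeth, nUnmeth.
    Positions are made contiguous 1..L with L the largest observed
    position; unobserved positions get depth 0 and NaN level.
    """
    if (call_table[["nMeth", "nUnmeth"]].to_numpy() < 0).any():
        raise ValueError("negative counts in M-bias call table")
    profiles: dict[tuple, MbiasProfile] = {}
    for (mate, lc), grp in call_table.groupby(["mate", "length_class"]):
        agg = grp.groupby("read_pos")[["nMeth", "nUnmeth"]].sum()
        length = int(agg.index.max())
        depth = np.zeros(length, dtype=np.int64)
        meth = np.zeros(length, dtype=np.int64)
        idx = agg.index.to_numpy().astype(int) - 1
        depth[idx] = (agg["nMeth"] + agg["nUnmeth"]).to_numpy()
        meth[idx] = agg["nMeth"].to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            level = np.where(depth > 0, meth / np.maximum(depth, 1), np.nan)
        profiles[(int(mate), str(lc))] = MbiasProfile(
            int(mate), str(lc), level, depth
        )
    return profiles


def midread_stats(profile: MbiasProfile, policy: TrimPolicy) -> tuple[float, float]:
    """Mean and sample SD of the level over the mid-read window.

    Window positions with zero depth are excluded; fewer than two usable
    positions raise :class:`InsufficientDataError`.
    """
    w0, w1 = policy.window(profile.length_class)
    w1 = min(w1, profile.length)
    vals = profile.level[w0 - 1:w1]
    vals = vals[np.isfinite(vals)]
    if len(vals) < 2:
        raise InsufficientDataError(
            f"only {len(vals)} usable mid-read positions in window "
            f"{w0}-{w1} for mate {profile.mate} {profile.length_class}"
        )
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1))
    return mean, max(sd, policy.sd_floor)


def _classify(profile: MbiasProfile, mean: float, sd: float, policy: TrimPolicy
              ) -> np.ndarray:
    """Per position: 0 = inner (<= k_inner SD), 1 = outer (<= k_outer SD),
    2 = bad (beyond k_outer SD or zero depth)."""
    dev = np.abs(profile.level - mean)
    cls = np.full(profile.length, 2, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        cls[dev <= policy.k_outer * sd] = 1
        cls[dev <= policy.k_inner * sd] = 0
    cls[~np.isfinite(profile.level)] = 2
    return cls


def _run_is_valid(cls: np.ndarray, s: int, e: int) -> bool:
    """Literal rules 1-3 on the 1-based inclusive run [s, e]."""
    seg = cls[s - 1:e]
    if seg[0] != 0 or seg[-1] != 0:
        return False
    if (seg == 2).any():
        return False
    outer = seg == 1
    return not (outer[:-1] & outer[1:]).any()


def _pick_best(candidates: list[tuple[int, int]], window: tuple[int, int]
               ) -> tuple[int, int]:
    """Longest run; ties toward the run containing the window midpoint,
    then toward the earlier run."""
    mid = (window[0] + window[1]) / 2.0
    best_len = max(e - s for s, e in candidates)
    longest = [(s, e) for s, e in candidates if e - s == best_len]
    containing = [(s, e) for s, e in longest if s <= mid <= e]
    pool = containing if containing else longest
    return min(pool, key=lambda r: r[0])


def select_trim_range(profile: MbiasProfile, policy: TrimPolicy) -> TrimRange:
    """Select the retained read-position range under the trim rules.

    The candidate runs are the maximal bad-free segments split at every
    adjacent pair of outer-band positions, trimmed to inner-band
    endpoints; the longest valid run wins (ties per :func:`_pick_best`).
    """
    mean, sd = midread_stats(profile, policy)
    cls = _classify(profile, mean, sd, policy)
    L = profile.length
    if not (cls == 0).any():
        raise EmptyRangeError(
            f"no position within {policy.k_inner} SD of the mid-read mean "
            f"for mate {profile.mate} {profile.length_class}"
        )

    # segment boundaries: bad positions and adjacent outer-outer pairs
    candidates: list[tuple[int, int]] = []
    seg_start = None
    for pos in range(1, L + 2):
        bad = pos > L or cls[pos - 1] == 2
        pair_break = (
            seg_start is not None
            and pos <= L and pos > 1
            and cls[pos - 1] == 1 and cls[pos - 2] == 1
        )
        if bad or pair_break:
            if seg_start is not None:
                candidates.append((seg_start, pos - 1))
            seg_start = None if bad else pos
        elif seg_start is None and pos <= L:
            seg_start = pos

    trimmed = []
    for s, e in candidates:
        inner = np.nonzero(cls[s - 1:e] == 0)[0]
        if len(inner) == 0:
            continue
        trimmed.append((s + int(inner[0]), s + int(inner[-1])))
    if not trimmed:
        raise EmptyRangeError("no run with inner-band endpoints")

    s, e = _pick_best(trimmed, policy.window(profile.length_class))
    assert _run_is_valid(cls, s, e)
    kept = tuple(
        int(p) for p in range(s, e + 1) if cls[p - 1] == 1
    )
    return TrimRange(profile.mate, profile.length_class, s, e, kept, mean, sd)


def trim_report(profiles: dict, policy: TrimPolicy | None = None) -> pd.DataFrame:
    """TrimRange per (mate, length_class) as a tidy table."""
    policy = policy or TrimPolicy()
    rows = []
    for (mate, lc) in sorted(profiles):
        tr = select_trim_range(profiles[(mate, lc)], policy)
        rows.append({
            "mate": mate, "length_class": lc,
            "start_pos": tr.start_pos, "end_pos": tr.end_pos,
            "kept_outliers": ",".join(map(str, tr.kept_outliers)) or ".",
            "mean": round(tr.mean, 6), "sd": round(tr.sd, 6),
        })
    return pd.DataFrame(rows)
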