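"""M-bias profile computation and the trim-position selection rules.

The oracle enumerates every contiguous run and applies the three retention
rules literally; the implementation must match it exactly, including
tie-breaking.
"""

import numpy as np
import pandas as pd
import pytest

from methylome import io as mio
from methylome.mbias import (
    EmptyRangeError,
    InsufficientDataError,
    MbiasProfile,
    TrimPolicy,
    compute_mbias,
    midread_stats,
    select_trim_range,
)


def profile_from_levels(levels, length_class="PE75", mate=1, depth=1000):
    levels = np.asarray(levels, dtype=float)
    d = np.full(len(levels), depth, dtype=np.int64)
    d[~np.isfinite(levels)] = 0
    return MbiasProfile(mate, length_class, levels, d)


# ---------------------------------------------------------------------------
# literal-rule oracle
# ---------------------------------------------------------------------------

def oracle_trim_range(profile, policy):
    """Enumerate all contiguous runs; apply rules 1-3 literally."""
    mean, sd = midread_stats(profile, policy)
    L = profile.length

    def band(pos):
        lvl = profile.level[pos - 1]
        if profile.depth[pos - 1] == 0 or not np.isfinite(lvl):
            return "bad"
        dev = abs(lvl - mean)
        if dev <= policy.k_inner * sd:
            return "inner"
        if dev <= policy.k_outer * sd:
            return "outer"
        return "bad"

    valid = []
    for s in range(1, L + 1):
        for e in range(s, L + 1):
            bands = [band(p) for p in range(s, e + 1)]
            if bands[0] != "inner" or bands[-1] != "inner":
                continue
            if any(b == "bad" for b in bands):
                continue
            if any(
                bands[i] == "outer" and bands[i + 1] == "outer"
                for i in range(len(bands) - 1)
            ):
                continue
            valid.append((s, e))
    if not valid:
        raise EmptyRangeError("oracle: no valid run")
    best_len = max(e - s for s, e in valid)
    longest = [(s, e) for s, e in valid if e - s == best_len]
    w0, w1 = policy.window(profile.length_class)
    mid = (w0 + w1) / 2.0
    containing = [(s, e) for s, e in longest if s <= mid <= e]
    pool = containing if containing else longest
    return min(pool, key=lambda r: r[0])


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def test_compute_mbias_levels_and_zero_depth():
    table = pd.DataFrame({
        "mate": [1, 1, 1],
        "length_class": ["PE75"] * 3,
        "read_pos": [1, 2, 4],
        "nMeth": [8, 0, 5],
        "nUnmeth": [2, 10, 5],
    })
    prof = compute_mbias(table)[(1, "PE75")]
    assert prof.level_at(1) == pytest.approx(0.8)
    assert prof.level_at(2) == pytest.approx(0.0)
    assert np.isnan(prof.level_at(3))      # unobserved position
    assert prof.depth[2] == 0


def test_compute_mbias_rejects_negative_counts():
    table = pd.DataFrame({
        "mate": [1], "length_class": ["PE75"], "read_pos": [1],
        "nMeth": [-1], "nUnmeth": [2],
    })
    with pytest.raises(ValueError):
        compute_mbias(table)


def test_midread_stats_hand_case():
    """Window of 16 x 0.69 and 15 x 0.71: mean 0.6997, sd 0.0102."""
    levels = np.full(75, 0.70)
    levels[19:50] = [0.69, 0.71] * 15 + [0.69]
    prof = profile_from_levels(levels)
    mean, sd = midread_stats(prof, TrimPolicy())
    assert mean == pytest.approx(0.699677, abs=1e-6)
    assert sd == pytest.approx(0.010160, abs=1e-6)


def test_midread_stats_constant_window_uses_sd_floor():
    prof = profile_from_levels(np.full(75, 0.70))
    mean, sd = midread_stats(prof, TrimPolicy(sd_floor=0.002))
    assert mean == pytest.approx(0.70)
    assert sd == 0.002


def test_midread_stats_insufficient_window_errors():
    levels = np.full(75, np.nan)
    levels[24] = 0.7       # single usable window position
    levels[0:5] = 0.7
    with pytest.raises(InsufficientDataError):
        midread_stats(profile_from_levels(levels), TrimPolicy())


# ---------------------------------------------------------------------------
# trim-range selection
# ---------------------------------------------------------------------------

def window_alternating(length=75):
    """Profile whose mid-read window gives mean ~0.6997, sd ~0.0102."""
    levels = np.full(length, 0.70)
    levels[19:50] = [0.69, 0.71] * 15 + [0.69]
    return levels


def test_flat_profile_keeps_everything():
    prof = profile_from_levels(window_alternating())
    tr = select_trim_range(prof, TrimPolicy())
    assert (tr.start_pos, tr.end_pos) == (1, 75)
    assert tr.kept_outliers == ()


def test_biased_ends_trimmed_isolated_outlier_kept():
    """Rules 1-3 by hand: positions 1-4 far out, one isolated ~3.5 SD spike."""
    levels = window_alternating()
    levels[0:4] = 0.62                # |dev| ~ 0.08 >> 4 SD: excluded
    levels[59] = 0.735                # |dev| ~ 0.035: between 3 and 4 SD
    prof = profile_from_levels(levels)
    tr = select_trim_range(prof, TrimPolicy())
    assert (tr.start_pos, tr.end_pos) == (5, 75)
    assert tr.kept_outliers == (60,)
    assert (tr.start_pos, tr.end_pos) == oracle_trim_range(prof, TrimPolicy())


def test_consecutive_outliers_break_the_run():
    levels = window_alternating()
    levels[59] = 0.735
    levels[60] = 0.735                # adjacent pair, both within 4 SD
    prof = profile_from_levels(levels)
    tr = select_trim_range(prof, TrimPolicy())
    assert (tr.start_pos, tr.end_pos) == (1, 59)
    assert (tr.start_pos, tr.end_pos) == oracle_trim_range(prof, TrimPolicy())


def test_no_inner_position_raises():
    levels = window_alternating()
    policy = TrimPolicy(sd_floor=1e-9, k_inner=1e-6, k_outer=2e-6)
    prof = profile_from_levels(levels)
    with pytest.raises(EmptyRangeError):
        select_trim_range(prof, policy)


def random_profile(rng, length):
    """Random profile mixing inner, outer, extreme, and zero-depth positions."""
    base = 0.7
    levels = base + rng.normal(0.0, 0.004, size=length)
    n_perturb = rng.integers(0, max(2, length // 5))
    for _ in range(n_perturb):
        p = int(rng.integers(0, length))
        kind = rng.integers(0, 3)
        if kind == 0:
            levels[p] = base + rng.choice([-1, 1]) * rng.uniform(0.035, 0.045)
        elif kind == 1:
            levels[p] = base + rng.choice([-1, 1]) * rng.uniform(0.06, 0.2)
        else:
            levels[p] = np.nan
    return profile_from_levels(levels, length_class="PE75")


def test_matches_enumeration_oracle_on_random_profiles():
    rng = np.random.default_rng(42)
    policy = TrimPolicy(midread_windows={"PE75": (20, 50)})
    n_checked = 0
    for _ in range(60):
        prof = random_profile(rng, int(rng.integers(55, 150)))
        try:
            expected = oracle_trim_range(prof, policy)
        except (EmptyRangeError, InsufficientDataError):
            with pytest.raises((EmptyRangeError, InsufficientDataError)):
                select_trim_range(prof, policy)
            continue
        tr = select_trim_range(prof, policy)
        assert (tr.start_pos, tr.end_pos) == expected
        n_checked += 1
    assert n_checked >= 40


def test_widening_outer_band_never_shrinks_range():
    rng = np.random.default_rng(43)
    policy3 = TrimPolicy(midread_windows={"PE75": (20, 50)}, k_outer=3.5)
    policy4 = TrimPolicy(midread_windows={"PE75": (20, 50)}, k_outer=5.0)
    for _ in range(40):
        prof = random_profile(rng, 75)
        try:
            narrow = select_trim_range(prof, policy3)
            wide = select_trim_range(prof, policy4)
        except (EmptyRangeError, InsufficientDataError):
            continue
        assert (wide.end_pos - wide.start_pos) >= (narrow.end_pos - narrow.start_pos)


def test_planted_bias_recovered_from_simulated_calls(small_study):
    profiles = compute_mbias(small_study.mbias_table)
    policy = TrimPolicy()
    tr = select_trim_range(profiles[(1, "PE150")], policy)
    assert tr.start_pos == 6              # planted +0.1 bias at positions 1-5
    assert tr.end_pos == 150
    tr75 = select_trim_range(profiles[(2, "PE75")], policy)
    assert tr75.end_pos == 70             # planted -0.08 bias at positions 71-75
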