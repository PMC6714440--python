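"""Highly conserved region (HCR) window scan.

Same-order genomes are compared base-by-base upstream of this module; here the
per-scaffold difference positions are tiled into fixed-size windows (100 kb by
default), each window's difference count is tested for depletion against the
rest of the genome with Fisher's exact test, p-values are FDR-adjusted, and
the middle core (10 kb by default) of each significant window is reported as
an HCR. Scaffold ends are noisy in draft assemblies, which is why only the
window core is reported.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataIntegrityError, UndefinedStatisticError

DEFAULT_WINDOW_SIZE = 100_000
DEFAULT_CORE_SIZE = 10_000
DEFAULT_Q_THRESHOLD = 1e-4


@dataclass
class WindowStat:
    """One genomic window of the scan (0-based, half-open coordinates)."""

    scaffold: str
    start: int
    end: int
    diff_count: int
    effective_length: int
    p_value: float = float("nan")
    q_value: float = float("nan")
    significant: bool = False


@dataclass
class HCRegion:
    """The centered core of a significantly depleted window."""

    scaffold: str
    core_start: int
    core_end: int
    source_window: WindowStat


def count_window_diffs(
    variant_positions: Mapping[str, Sequence[int]],
    scaffold_lengths: Mapping[str, int],
    window_size: int = DEFAULT_WINDOW_SIZE,
    excluded: pd.DataFrame | None = None,
) -> list[WindowStat]:
    """Tile each scaffold into windows from coordinate 0 and count differences.

    ``excluded`` is an optional BED-like frame (scaffold, start, end) of gap/N
    regions subtracted from each window's effective length.
    """
    if window_size <= 0:
        raise ValueError(f"window_size must be positive, got {window_size}")
    windows: list[WindowStat] = []
    for scaffold in scaffold_lengths:
        length = int(scaffold_lengths[scaffold])
        positions = np.asarray(variant_positions.get(scaffold, ()), dtype=np.int64)
        if positions.size and (positions.min() < 0 or positions.max() >= length):
            bad = positions[(positions < 0) | (positions >= length)][0]
            raise DataIntegrityError(
                f"variant position {bad} outside scaffold {scaffold} (length {length})"
            )
        n_windows = -(-length // window_size)
        counts = np.bincount(positions // window_size, minlength=n_windows)
        gap_per_window = np.zeros(n_windows, dtype=np.int64)
        if excluded is not None:
            for row in excluded[excluded["scaffold"] == scaffold].itertuples(index=False):
                # clip the gap interval against every window it overlaps
                first = int(row.start) // window_size
                last = (int(row.end) - 1) // window_size
                for w in range(first, min(last, n_windows - 1) + 1):
                    lo = max(int(row.start), w * window_size)
                    hi = min(int(row.end), (w + 1) * window_size, length)
                    gap_per_window[w] += max(0, hi - lo)
        for w in range(n_windows):
            start = w * window_size
            end = min(start + window_size, length)
            windows.append(
                WindowStat(
                    scaffold=scaffold,
                    start=start,
                    end=end,
                    diff_count=int(counts[w]),
                    effective_length=end - start - int(gap_per_window[w]),
                )
            )
    return windows


def window_fisher(
    window_diff: int,
    window_len: int,
    genome_diff: int,
    genome_len: int,
    sided: Literal["less", "two"] = "less",
) -> float:
    """Fisher's exact test of one window's variation against the genome-wide
    level, on the 2x2 table [[window_diff, window_len - window_diff],
    [genome_diff, genome_len - genome_diff]].

    The genome totals must exclude the focal window so the two rows are
    independent. ``sided='less'`` is the depletion (conserved-region) test;
    ``'two'`` tests any difference.
    """
    if window_len == 0:
        raise UndefinedStatisticError("cannot test a zero-length window")
    if min(window_diff, genome_diff, genome_len) < 0:
        raise ValueError("counts must be nonnegative")
    if window_diff > window_len:
        raise ValueError("window_diff exceeds window_len")
    table = [
        [window_diff, window_len - window_diff],
        [genome_diff, genome_len - genome_diff],
    ]
    alternative = "less" if sided == "less" else "two-sided"
    return float(stats.fisher_exact(table, alternative=alternative).pvalue)


def adjust_fdr(p_values: Sequence[float], method: Literal["bh", "storey"] = "bh") -> np.ndarray:
    """FDR-adjusted q-values.

    ``bh`` is the Benjamini-Hochberg step-up procedure (default); ``storey``
    scales the BH values by a single-lambda (0.5) estimate of the null
    proportion pi0.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    q = stats.false_discovery_control(p, method="bh")
    if method == "storey":
        pi0 = min(1.0, float(np.mean(p > 0.5)) / 0.5) if p.size else 1.0
        q = np.clip(q * pi0, 0.0, 1.0)
    elif method != "bh":
        raise ValueError(f"unknown FDR method: {method}")
    return q


def call_hcrs(
    windows: Iterable[WindowStat],
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    core_size: int = DEFAULT_CORE_SIZE,
    window_size: int | None = None,
) -> list[HCRegion]:
    """Report the centered core of every window with q below threshold.

    Terminal windows shorter than ``core_size`` are skipped. Pass the nominal
    ``window_size`` to reject a core larger than the tiling window outright.
    """
    if core_size <= 0:
        raise ValueError("core_size must be positive")
    if window_size is not None and core_size > window_size:
        raise ValueError("core_size exceeds the window size")
    windows = list(windows)
    regions: list[HCRegion] = []
    for w in windows:
        if w.end - w.start < core_size:
            continue  # terminal short window: no room for a centered core
        if np.isnan(w.q_value) or w.q_value >= q_threshold:
            continue
        offset = (w.end - w.start - core_size) // 2
        regions.append(
            HCRegion(
                scaffold=w.scaffold,
                core_start=w.start + offset,
                core_end=w.start + offset + core_size,
                source_window=w,
            )
        )
    return regions


def scan_hcrs(
    variant_positions: Mapping[str, Sequence[int]],
    scaffold_lengths: Mapping[str, int],
    window_size: int = DEFAULT_WINDOW_SIZE,
    core_size: int = DEFAULT_CORE_SIZE,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    sided: Literal["less", "two"] = "less",
    fdr_method: Literal["bh", "storey"] = "bh",
    excluded: pd.DataFrame | None = None,
) -> tuple[list[WindowStat], list[HCRegion]]:
    """Full scan: count, test each window against the rest of the genome,
    adjust for multiple testing, and call HCR cores."""
    if core_size > window_size:
        raise ValueError("core_size cannot exceed window_size")
    windows = count_window_diffs(variant_positions, scaffold_lengths, window_size, excluded)
    total_diff = sum(w.diff_count for w in windows)
    total_len = sum(w.effective_length for w in windows)
    for w in windows:
        w.p_value = window_fisher(
            w.diff_count,
            w.effective_length,
            total_diff - w.diff_count,
            total_len - w.effective_length,
            sided=sided,
        )
    # stable (p, scaffold, start) order for the step-up pass
    order = sorted(range(len(windows)), key=lambda i: (windows[i].p_value, windows[i].scaffold, windows[i].start))
    q_sorted = adjust_fdr([windows[i].p_value for i in order], method=fdr_method)
    for rank, i in enumerate(order):
        windows[i].q_value = float(q_sorted[rank])
        windows[i].significant = windows[i].q_value < q_threshold
    return windows, call_hcrs(windows, q_threshold=q_threshold, core_size=core_size, window_size=window_size)


def windows_to_frame(windows: Iterable[WindowStat]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "scaffold": w.scaffold,
                "start": w.start,
                "end": w.end,
                "diff_count": w.diff_count,
                "effective_length": w.effective_length,
                "p_value": w.p_value,
                "q_value": w.q_value,
                "significant": w.significant,
            }
            for w in windows
        ]
    )


def hcrs_to_frame(regions: Iterable[HCRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "scaffold": r.scaffold,
                "start": r.core_start,
                "end": r.core_end,
                "source_window_start": r.source_window.start,
                "q_value": r.source_window.q_value,
            }
            for r in regions
        ],
        columns=["scaffold", "start", "end", "source_window_start", "q_value"],
    )
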