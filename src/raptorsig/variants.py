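"""Heterozygosity rate over callable regions and the abnormal-depth gene filter.

Genetic diversity is summarized as heterozygous SNVs per base of sufficiently
mapped sequence ("callable" = depth strictly greater than 5 by default).
Before gene-family analyses, genes with anomalous mapping depth are removed:
autosomal genes below half or above twice the genome-wide mean, sex-linked
genes below a quarter or above twice the mean (sex chromosomes sit at half
depth in the heterogametic sex, hence the laxer low bound).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedStatisticError

DEFAULT_MIN_DEPTH = 5


@dataclass
class GeneDepthRecord:
    gene_id: str
    scaffold: str
    sex_linked: bool
    mean_depth: float
    decision: str = ""  # keep | filtered
    reason: str = ""


@dataclass
class HetRateResult:
    het_count: int
    callable_length: int
    rate: float


def _as_intervals(depth_track: pd.DataFrame | Sequence[float]) -> pd.DataFrame:
    """Normalize a depth track to interval form (scaffold, start, end, depth).

    A bare sequence/array is treated as per-base depths on one scaffold.
    """
    if isinstance(depth_track, pd.DataFrame):
        return depth_track
    depths = np.asarray(depth_track, dtype=float)
    return pd.DataFrame(
        {
            "scaffold": "seq",
            "start": np.arange(depths.size),
            "end": np.arange(depths.size) + 1,
            "depth": depths,
        }
    )


def callable_length(
    depth_track: pd.DataFrame | Sequence[float],
    min_depth: float = DEFAULT_MIN_DEPTH,
) -> int:
    """Total bases with depth strictly greater than ``min_depth``."""
    track = _as_intervals(depth_track)
    if len(track) == 0:
        warnings.warn("empty depth track: callable length is 0", stacklevel=2)
        return 0
    if (track["depth"] < 0).any():
        raise ValueError("depths must be nonnegative")
    ok = track["depth"] > min_depth
    return int((track.loc[ok, "end"] - track.loc[ok, "start"]).sum())


def _callable_intervals(track: pd.DataFrame, min_depth: float) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    ok = track[track["depth"] > min_depth]
    for scaffold, sub in ok.groupby("scaffold"):
        sub = sub.sort_values("start")
        out[str(scaffold)] = (sub["start"].to_numpy(), sub["end"].to_numpy())
    return out


def het_rate(
    het_variants: Iterable[tuple[str, int]],
    depth_track: pd.DataFrame | Sequence[float],
    min_depth: float = DEFAULT_MIN_DEPTH,
    intersect: bool = True,
) -> HetRateResult:
    """Heterozygous SNVs per callable base.

    ``het_variants`` are (scaffold, 0-based position) pairs, already reduced
    to biallelic heterozygous SNVs. With ``intersect`` (default) only variants
    on callable bases are counted; the result is order-invariant in both the
    variants and the track intervals.
    """
    track = _as_intervals(depth_track)
    total_callable = callable_length(track, min_depth)
    if total_callable == 0:
        raise UndefinedStatisticError("no callable bases: heterozygosity rate undefined")
    variants = list(het_variants)
    if intersect:
        by_scaffold = _callable_intervals(track, min_depth)
        count = 0
        for scaffold, pos in variants:
            ivals = by_scaffold.get(str(scaffold))
            if ivals is None:
                continue
            starts, ends = ivals
            i = np.searchsorted(starts, pos, side="right") - 1
            if i >= 0 and pos < ends[i]:
                count += 1
    else:
        count = len(variants)
    return HetRateResult(het_count=count, callable_length=total_callable, rate=count / total_callable)


def depth_filter_genes(
    records: Iterable[GeneDepthRecord] | pd.DataFrame,
    genome_mean_depth: float,
    sex_scaffolds: Iterable[str] | None = None,
) -> list[GeneDepthRecord]:
    """Flag genes with anomalous mapping depth.

    An autosomal gene is filtered iff its depth is strictly below 0.5x or
    strictly above 2x the genome mean; a sex-linked gene iff strictly below
    0.25x or strictly above 2x. Genes exactly at a boundary are kept.
    """
    if genome_mean_depth <= 0:
        raise ValueError("genome_mean_depth must be positive")
    sex = {str(s) for s in (sex_scaffolds or ())}
    if isinstance(records, pd.DataFrame):
        records = [
            GeneDepthRecord(
                gene_id=str(r.gene_id),
                scaffold=str(r.scaffold),
                sex_linked=bool(getattr(r, "sex_linked", str(r.scaffold) in sex)),
                mean_depth=float(r.mean_depth),
            )
            for r in records.itertuples(index=False)
        ]
    out: list[GeneDepthRecord] = []
    for rec in records:
        if rec.mean_depth < 0:
            raise ValueError(f"{rec.gene_id}: negative depth")
        sex_linked = rec.sex_linked or rec.scaffold in sex
        low = 0.25 * genome_mean_depth if sex_linked else 0.5 * genome_mean_depth
        high = 2.0 * genome_mean_depth
        if rec.mean_depth < low:
            decision, reason = "filtered", "low_depth"
        elif rec.mean_depth > high:
            decision, reason = "filtered", "high_depth"
        else:
            decision, reason = "keep", "normal_depth"
        out.append(
            GeneDepthRecord(
                gene_id=rec.gene_id,
                scaffold=rec.scaffold,
                sex_linked=sex_linked,
                mean_depth=rec.mean_depth,
                decision=decision,
                reason=reason,
            )
        )
    return out


def gene_records_to_frame(records: Sequence[GeneDepthRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])
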