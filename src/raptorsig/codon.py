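"""Codon-level selection statistics.

The core estimator is the Nei-Gojobori (1986) counting method: each codon
position contributes fractional synonymous/nonsynonymous *sites* according to
how many of its possible single-nucleotide changes preserve the amino acid,
and observed codon differences are partitioned into synonymous and
nonsynonymous *differences* by averaging over all mutational pathways between
the two codons. Proportions are corrected for multiple hits with the
Jukes-Cantor formula, and omega = dN/dS.

Also here: the Mann-Whitney gene-set acceleration comparison, GC3 (third
codon position G+C) profiling with two-step z-normalization, and detection of
group-specific amino-acid sites in multiple alignments.
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy import stats

from .alignment import GAP_CHARS, AlignmentMatrix
from .errors import InvalidSequenceError, SaturationError, UndefinedStatisticError

_TABLE = CodonTable.unambiguous_dna_by_id[1]  # standard nuclear code
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(_TABLE.forward_table))
AA_OF = dict(_TABLE.forward_table)
_NUCS = "ACGT"


# ---------------------------------------------------------------- NG86 counting


def count_sites_ng86(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts (s_sites, n_sites) of a codon.

    At each of the 3 positions the synonymous fraction is the number of
    single-nucleotide changes that preserve the amino acid, divided by the
    number of changes that do not create a stop codon. s + n = 3 exactly.
    """
    codon = codon.upper()
    if codon not in AA_OF:
        raise InvalidSequenceError(f"not a sense codon: {codon!r}")
    aa = AA_OF[codon]
    s_sites = 0.0
    for pos in range(3):
        syn = 0
        non_stop = 0
        for nt in _NUCS:
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1:]
            if mutant in STOP_CODONS:
                continue
            non_stop += 1
            if AA_OF[mutant] == aa:
                syn += 1
        if non_stop:
            s_sites += syn / non_stop
    return s_sites, 3.0 - s_sites


def count_diffs_ng86(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous difference counts (s_diffs, n_diffs)
    between two sense codons, averaged over all mutational pathways.

    Pathways passing through a stop codon are discarded; if every pathway
    does, all pathways are used and a warning is emitted.
    """
    a, b = codon_a.upper(), codon_b.upper()
    for c in (a, b):
        if c not in AA_OF:
            raise InvalidSequenceError(f"not a sense codon: {c!r}")
    diff_pos = [i for i in range(3) if a[i] != b[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: Sequence[int]) -> tuple[float, float] | None:
        cur = a
        s = n = 0.0
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                return None  # pathway passes through a stop codon
            if AA_OF[cur] == AA_OF[nxt]:
                s += 1.0
            else:
                n += 1.0
            cur = nxt
        return s, n

    paths = [walk(order) for order in itertools.permutations(diff_pos)]
    valid = [p for p in paths if p is not None]
    if not valid:
        warnings.warn(
            f"no stop-free pathway between {a} and {b}; averaging over all pathways",
            stacklevel=2,
        )
        valid = [_walk_through_stops(a, b, order) for order in itertools.permutations(diff_pos)]
    s = sum(p[0] for p in valid) / len(valid)
    n = sum(p[1] for p in valid) / len(valid)
    return s, n


def _walk_through_stops(a: str, b: str, order: Sequence[int]) -> tuple[float, float]:
    """Pathway counts when stop-codon intermediates must be traversed; a step
    into or out of a stop codon counts as nonsynonymous."""
    cur = a
    s = n = 0.0
    for pos in order:
        nxt = cur[:pos] + b[pos] + cur[pos + 1:]
        cur_aa = AA_OF.get(cur, "*")
        nxt_aa = AA_OF.get(nxt, "*")
        if cur_aa == nxt_aa:
            s += 1.0
        else:
            n += 1.0
        cur = nxt
    return s, n


@dataclass
class DnDsEstimate:
    """Counting-method dN/dS for one pair of aligned coding sequences."""

    n_codons: int
    s_sites: float
    n_sites: float
    s_diffs: float
    n_diffs: float
    pS: float
    pN: float
    dS: float
    dN: float
    omega: float | None  # None when dS == 0 (undefined, never silent infinity)


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.4f} >= 3/4: Jukes-Cantor correction undefined")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def dnds_pair(cds_a: str, cds_b: str) -> DnDsEstimate:
    """NG86 dN/dS between two equal-length, in-frame coding sequences.

    Codons containing gaps, ambiguity characters, or stop codons in either
    sequence are skipped pairwise. Site counts are averaged between the two
    sequences, so the estimate is symmetric in its arguments.
    """
    a, b = cds_a.upper(), cds_b.upper()
    if len(a) != len(b):
        raise InvalidSequenceError("sequences differ in length")
    if len(a) % 3:
        raise InvalidSequenceError("sequence length is not a multiple of 3")
    s_sites_a = n_sites_a = s_sites_b = n_sites_b = 0.0
    s_diffs = n_diffs = 0.0
    n_codons = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if ca not in AA_OF or cb not in AA_OF:
            continue  # gap/ambiguity/stop codon: skipped pairwise
        n_codons += 1
        sa, na = count_sites_ng86(ca)
        sb, nb = count_sites_ng86(cb)
        s_sites_a += sa
        n_sites_a += na
        s_sites_b += sb
        n_sites_b += nb
        sd, nd = count_diffs_ng86(ca, cb)
        s_diffs += sd
        n_diffs += nd
    if n_codons == 0:
        raise UndefinedStatisticError("no comparable codons in the alignment")
    s_sites = (s_sites_a + s_sites_b) / 2.0
    n_sites = (n_sites_a + n_sites_b) / 2.0
    pS = s_diffs / s_sites if s_sites else 0.0
    pN = n_diffs / n_sites if n_sites else 0.0
    dS = _jukes_cantor(pS)
    dN = _jukes_cantor(pN)
    omega = dN / dS if dS > 0 else None
    return DnDsEstimate(
        n_codons=n_codons,
        s_sites=s_sites,
        n_sites=n_sites,
        s_diffs=s_diffs,
        n_diffs=n_diffs,
        pS=pS,
        pN=pN,
        dS=dS,
        dN=dN,
        omega=omega,
    )


# ---------------------------------------------------------------- acceleration


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U for group a, with ties counted half."""
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def geneset_acceleration(
    omegas_a: Sequence[float],
    omegas_b: Sequence[float],
    exact_max_n: int = 8,
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparison of two sets of per-gene omega values.

    Returns (U for group a, p). Exact enumeration over all group-A index
    assignments when both groups have at most ``exact_max_n`` members;
    otherwise the tie-corrected normal approximation. The exact two-sided p is
    P(|U - n_a n_b / 2| >= |U_obs - n_a n_b / 2|) over all assignments.
    """
    a = np.asarray(list(omegas_a), dtype=float)
    b = np.asarray(list(omegas_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    u_obs = _u_statistic(a, b)
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values tied across both groups: degenerate comparison", stacklevel=2)
        return u_obs, 1.0
    if a.size <= exact_max_n and b.size <= exact_max_n:
        center = a.size * b.size / 2.0
        dev_obs = abs(u_obs - center)
        hits = total = 0
        idx = np.arange(pooled.size)
        for combo in itertools.combinations(idx, a.size):
            mask = np.zeros(pooled.size, dtype=bool)
            mask[list(combo)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            # tolerance only guards float half-ties
            if abs(u - center) >= dev_obs - 1e-12:
                hits += 1
        return u_obs, hits / total
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue)


# ---------------------------------------------------------------- GC3


@dataclass
class GC3Record:
    gene_id: str
    species: str
    gc3: float
    n_codons_used: int


def gc3(cds: str, gene_id: str = "", species: str = "") -> GC3Record:
    """Fraction of G or C at third codon positions.

    An incomplete terminal codon is trimmed with a warning; codons whose third
    position is not an unambiguous A/C/G/T are excluded from the denominator.
    """
    seq = cds.upper()
    if len(seq) % 3:
        warnings.warn(f"{gene_id or 'sequence'}: trimming incomplete terminal codon", stacklevel=2)
        seq = seq[: len(seq) - len(seq) % 3]
    thirds = seq[2::3]
    usable = [c for c in thirds if c in _NUCS]
    if not usable:
        raise UndefinedStatisticError("no usable codons for GC3")
    frac = sum(c in "GC" for c in usable) / len(usable)
    return GC3Record(gene_id=gene_id, species=species, gc3=frac, n_codons_used=len(usable))


def _zscore(values: np.ndarray, ddof: int = 1) -> np.ndarray:
    sd = values.std(ddof=ddof) if values.size > ddof else 0.0
    if sd == 0:
        return np.zeros_like(values)  # degenerate: defined as 0, flagged by caller
    return (values - values.mean()) / sd


def gc3_profile(
    records: Iterable[GC3Record] | pd.DataFrame,
    gene_sets: Mapping[str, Sequence[str]],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Gene-set x species z-score matrix of normalized GC3.

    Step 1: within each species, z-score every gene's GC3 across that species'
    genes. Step 2: average the normalized values per gene set per species.
    Step 3: z-score each set's averages across species, so each output row has
    mean 0 and unit SD (zero-variance rows are defined as 0 and flagged).

    Returns (z_matrix, per_gene_z, set_means); the intermediates are emitted
    so alternative normalizations can be audited. Sets with fewer than two
    genes are excluded with a warning.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([r.__dict__ for r in records])
    required = {"gene_id", "species", "gc3"}
    if not required <= set(df.columns):
        raise ValueError(f"records need columns {sorted(required)}")
    df["gc3_z"] = df.groupby("species")["gc3"].transform(lambda v: _zscore(v.to_numpy()))
    species = sorted(df["species"].unique())
    rows = {}
    for name, genes in gene_sets.items():
        genes = list(genes)
        if len(genes) < 2:
            warnings.warn(f"gene set {name!r} has < 2 genes: excluded", stacklevel=2)
            continue
        sub = df[df["gene_id"].isin(genes)]
        missing = [sp for sp in species if sp not in set(sub["species"])]
        if missing:
            raise ValueError(f"gene set {name!r} has no records for species {missing}")
        rows[name] = sub.groupby("species")["gc3_z"].mean().reindex(species)
    set_means = pd.DataFrame(rows).T
    set_means.index.name = "gene_set"
    z_matrix = set_means.apply(lambda row: pd.Series(_zscore(row.to_numpy()), index=row.index), axis=1)
    return z_matrix, df, set_means


# ---------------------------------------------------------------- specific sites


@dataclass
class SpecificSite:
    """An alignment column where all target rows share a residue absent from
    every outgroup row."""

    column: int
    target_residue: str
    outgroup_residues: set[str] = field(default_factory=set)


def specific_residues(
    alignment: AlignmentMatrix,
    target_rows: Iterable[int],
    strict_gaps: bool = False,
) -> list[SpecificSite]:
    """Columns carrying a target-group-specific amino acid.

    A column qualifies when (a) every target row carries the same non-gap
    residue, (b) no outgroup row carries that residue, and (c) no target row
    has a gap. With ``strict_gaps`` outgroup gaps also disqualify the column.
    """
    targets = set(target_rows)
    if not (1 <= len(targets) < alignment.n_rows):
        raise ValueError("target_rows must be a non-empty proper subset of the rows")
    if not targets <= set(range(alignment.n_rows)):
        raise ValueError("target_rows out of range")
    out_idx = [i for i in range(alignment.n_rows) if i not in targets]
    sites: list[SpecificSite] = []
    for j in range(alignment.n_columns):
        col = alignment.column(j)
        target_res = {col[i] for i in targets}
        if len(target_res) != 1:
            continue
        residue = next(iter(target_res))
        if residue in GAP_CHARS:
            continue
        outgroup = {col[i] for i in out_idx}
        if strict_gaps and outgroup & GAP_CHARS:
            continue
        if residue in outgroup:
            continue
        sites.append(
            SpecificSite(column=j, target_residue=residue, outgroup_residues=outgroup - GAP_CHARS)
        )
    return sites
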