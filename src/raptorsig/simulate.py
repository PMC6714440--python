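"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator is a pure function of its seed and emulates one class of input
the comparative analyses consume: same-order genome difference tracks with
planted low-variation windows, olfactory-receptor-like coding genes with
planted lesions, pairwise codon alignments evolved at a chosen omega,
multi-species protein alignments with planted group-specific residues, and
per-gene depth / heterozygous-variant sets at planted rates. Depth is
simulated at the per-base/per-gene summary level (no reads).

The alphabet is uppercase ACGT throughout; ambiguity codes are never emitted.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import AlignmentMatrix
from .codon import AA_OF, SENSE_CODONS, STOP_CODONS
from .orrep import ORGene

_NUCS = np.array(list("ACGT"))
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# sense codons that are not ATG and not one base away from being misread as a
# start; used for flanks that must stay start/stop-free in frame
_SENSE_NO_START = tuple(c for c in SENSE_CODONS if c != "ATG")


@dataclass
class SimConfig:
    """Study conditions for the simulations.

    Defaults are the scan's study conditions: 100-kb windows over a 20-Mb
    genome (200 windows), a background difference rate of 5e-3 per bp with
    planted conserved windows at 5% of background, heterozygosity of 1e-3 per
    bp, and ~30x mean depth.
    """

    seed: int = 1
    genome_length: int = 20_000_000
    gc_content: float = 0.42  # typical avian genome-wide GC
    window_size: int = 100_000
    background_diff_rate: float = 5e-3
    planted_hcr_windows: list[tuple[int, float]] = field(
        default_factory=lambda: [(20, 0.05), (57, 0.05), (101, 0.05), (150, 0.05), (188, 0.05)]
    )
    het_rate: float = 1e-3
    mean_depth: float = 30.0
    omega_true: float = 1.0
    n_codons: int = 5000

    def __post_init__(self) -> None:
        for name in ("gc_content", "background_diff_rate", "het_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.genome_length <= 0 or self.window_size <= 0:
            raise ValueError("genome_length and window_size must be positive")
        if self.genome_length % self.window_size:
            raise ValueError("genome_length must be a multiple of window_size")
        if self.omega_true < 0:
            raise ValueError("omega_true must be nonnegative")
        if self.n_codons <= 0:
            raise ValueError("n_codons must be positive")
        for _, mult in self.planted_hcr_windows:
            if not 0.0 < mult < 1.0:
                raise ValueError(f"rate multiplier must be in (0, 1), got {mult}")


# ---------------------------------------------------------------- genome


def gen_genome(length: int, gc: float, seed: int) -> str:
    """Random nucleotide sequence with expected G+C fraction ``gc``."""
    if length <= 0:
        raise ValueError(f"length must be positive, got {length}")
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"gc must be in [0, 1], got {gc}")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return "".join(rng.choice(_NUCS, size=length, p=probs))


# ---------------------------------------------------------------- HCR scan input


def gen_order_differences(config: SimConfig) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Per-bp Bernoulli difference positions with planted conserved windows.

    Returns ({scaffold: sorted 0-based positions}, truth table with one row
    per window: window_index, start, end, rate, planted flag).
    """
    rng = np.random.default_rng(config.seed)
    ws = config.window_size
    n_windows = config.genome_length // ws
    rates = np.full(n_windows, config.background_diff_rate)
    planted = {idx: mult for idx, mult in config.planted_hcr_windows}
    for idx, mult in planted.items():
        if not 0 <= idx < n_windows:
            raise ValueError(f"planted window index {idx} out of range [0, {n_windows})")
        rates[idx] = config.background_diff_rate * mult
    positions: list[np.ndarray] = []
    for w in range(n_windows):
        count = rng.binomial(ws, rates[w]) if rates[w] > 0 else 0
        if count:
            offs = rng.choice(ws, size=count, replace=False)
            positions.append(w * ws + np.sort(offs))
    pos = np.concatenate(positions) if positions else np.empty(0, dtype=np.int64)
    truth = pd.DataFrame(
        {
            "window_index": np.arange(n_windows),
            "start": np.arange(n_windows) * ws,
            "end": (np.arange(n_windows) + 1) * ws,
            "rate": rates,
            "planted": [w in planted for w in range(n_windows)],
        }
    )
    return {"sim1": pos.astype(np.int64)}, truth


# ---------------------------------------------------------------- OR genes


def _random_sense_codons(rng: np.random.Generator, n: int, exclude_start: bool = False) -> list[str]:
    pool = _SENSE_NO_START if exclude_start else SENSE_CODONS
    return list(rng.choice(pool, size=n)) if n else []


def _frame_safe_flank(rng: np.random.Generator, n_codons: int) -> str:
    """A flank with no in-frame ATG and no in-frame stop codon."""
    pool = tuple(c for c in _SENSE_NO_START)
    return "".join(rng.choice(pool, size=n_codons)) if n_codons else ""


def gen_or_genes(
    n_intact: int,
    n_partial: int,
    n_pseudo: int,
    aa_length: int = 310,
    seed: int = 1,
    flank: int = 90,
) -> tuple[list[ORGene], dict[str, str], pd.DataFrame]:
    """OR-like coding genes embedded in scaffolds, with truth labels.

    Returns (genes, {scaffold id: scaffold sequence}, truth table). Intact
    genes are complete ORFs of ``aa_length`` residues (> 215 required).
    Partial genes lack the start and/or stop codon within their annotated
    span; alternating genes carry the missing codon in frame within the
    ``flank``, so extension rescues them to a complete ORF and their truth
    label is the post-extension status (intact when long enough), while the
    unrecoverable ones stay partial. Pseudogenes carry a planted 1- or 2-bp
    indel (frameshift) or an internal stop codon. Flanks are built from sense
    non-ATG codons so they never contain a spurious in-frame start or stop.
    """
    if n_intact > 0 and aa_length <= 215:
        raise ValueError("aa_length must exceed 215 when intact genes are requested")
    if min(n_intact, n_partial, n_pseudo) < 0:
        raise ValueError("gene counts must be nonnegative")
    rng = np.random.default_rng(seed)
    genes: list[ORGene] = []
    scaffolds: dict[str, str] = {}
    rows = []
    counter = 0

    def build_orf() -> str:
        # first body codon is never ATG, so removing the start codon cannot
        # accidentally leave a valid start in the annotated span
        head = _random_sense_codons(rng, 1, exclude_start=True)
        body = _random_sense_codons(rng, aa_length - 2)
        stop = str(rng.choice(list(STOP_CODONS)))
        return "ATG" + "".join(head + body) + stop

    def embed(cds: str, gid: str, left_extra: str = "", right_extra: str = "") -> ORGene:
        """Place cds on a scaffold between frame-safe flanks; ``left_extra``/
        ``right_extra`` sit immediately against the annotated span to plant
        recoverable start/stop codons."""
        left = _frame_safe_flank(rng, (flank - len(left_extra)) // 3) + left_extra
        right = right_extra + _frame_safe_flank(rng, (flank - len(right_extra)) // 3)
        scaffold_name = f"scaf_{gid}"
        scaffolds[scaffold_name] = left + cds + right
        start = len(left)
        return ORGene(
            id=gid,
            scaffold=scaffold_name,
            start=start,
            end=start + len(cds),
            strand="+",
            cds=cds,
        )

    for _ in range(n_intact):
        gid = f"or{counter:04d}"
        counter += 1
        genes.append(embed(build_orf(), gid))
        rows.append({"gene_id": gid, "truth": "intact", "lesion": ""})

    for k in range(n_partial):
        gid = f"or{counter:04d}"
        counter += 1
        orf = build_orf()
        mode = ["no_start", "no_stop", "no_both"][k % 3]
        recoverable = k % 2 == 0
        cds, left_extra, right_extra = orf, "", ""
        if mode in ("no_start", "no_both"):
            cds = cds[3:]
            if recoverable:
                left_extra = "ATG"
        if mode in ("no_stop", "no_both"):
            cds = cds[:-3]
            if recoverable:
                right_extra = str(rng.choice(list(STOP_CODONS)))
        # rescued genes translate to aa_length residues after extension
        truth = "intact" if (recoverable and aa_length > 215) else "partial"
        genes.append(embed(cds, gid, left_extra, right_extra))
        rows.append(
            {"gene_id": gid, "truth": truth, "lesion": f"{mode}{'_recoverable' if recoverable else ''}"}
        )

    for k in range(n_pseudo):
        gid = f"or{counter:04d}"
        counter += 1
        orf = build_orf()
        mode = ["internal_stop", "del1", "ins2"][k % 3]
        if mode == "internal_stop":
            at = int(rng.integers(1, aa_length - 1))
            stop = str(rng.choice(list(STOP_CODONS)))
            cds = orf[: 3 * at] + stop + orf[3 * at + 3 :]
            lesion = f"premature_stop@codon{at}"
        elif mode == "del1":
            at = int(rng.integers(3, len(orf) - 3))
            cds = orf[:at] + orf[at + 1 :]
            lesion = f"indel_del1@{at}"
        else:
            at = int(rng.integers(3, len(orf) - 3))
            ins = "".join(rng.choice(_NUCS, size=2))
            cds = orf[:at] + ins + orf[at:]
            lesion = f"indel_ins2@{at}"
        gene = embed(cds, gid)
        if mode != "internal_stop":
            gene.lesions.append("indel")
        genes.append(gene)
        rows.append({"gene_id": gid, "truth": "pseudogene", "lesion": lesion})

    return genes, scaffolds, pd.DataFrame(rows, columns=["gene_id", "truth", "lesion"])


# ---------------------------------------------------------------- codon evolution


def gen_codon_alignment(
    n_codons: int,
    omega: float,
    expected_subs_per_codon: float = 0.3,
    seed: int = 1,
) -> tuple[str, str]:
    """Evolve a descendant from a random ancestor under a selection filter.

    Single-nucleotide changes are proposed uniformly (random codon, random
    position, random alternative base); proposals creating a stop codon are
    rejected, nonsynonymous proposals are accepted with probability
    min(1, omega) and synonymous ones with min(1, 1/max(omega, 1)). The
    process runs until round(expected_subs_per_codon * n_codons) substitutions
    have been accepted, so divergence is held at the study condition.

    Each codon receives at most one substitution. This keeps the planted
    truth exact for the counting estimator: a codon hit twice by synonymous
    events can decompose into pathways with nonsynonymous steps, which would
    make a strictly purifying (omega = 0) simulation yield spurious
    nonsynonymous differences downstream; with single hits, omega = 0 gives
    exactly zero nonsynonymous differences while the neutral case is
    unaffected.
    """
    if n_codons <= 0:
        raise ValueError("n_codons must be positive")
    if omega < 0:
        raise ValueError("omega must be nonnegative")
    if expected_subs_per_codon < 0:
        raise ValueError("expected_subs_per_codon must be nonnegative")
    if expected_subs_per_codon > 1.0:
        raise ValueError("expected_subs_per_codon cannot exceed 1 (one substitution per codon)")
    rng = np.random.default_rng(seed)
    codons = list(rng.choice(SENSE_CODONS, size=n_codons))
    ancestor = "".join(codons)
    target = round(expected_subs_per_codon * n_codons)
    p_nonsyn = min(1.0, omega)
    p_syn = min(1.0, 1.0 / max(omega, 1.0))
    accepted = 0
    attempts = 0
    hit = np.zeros(n_codons, dtype=bool)
    max_attempts = 1000 * max(target, 1) + 10_000
    while accepted < target and attempts < max_attempts:
        attempts += 1
        ci = int(rng.integers(n_codons))
        if hit[ci]:
            continue
        pos = int(rng.integers(3))
        old = codons[ci]
        nt = str(rng.choice([n for n in "ACGT" if n != old[pos]]))
        new = old[:pos] + nt + old[pos + 1 :]
        if new in STOP_CODONS:
            continue
        p_accept = p_syn if AA_OF[new] == AA_OF[old] else p_nonsyn
        if p_accept >= 1.0 or rng.random() < p_accept:
            codons[ci] = new
            hit[ci] = True
            accepted += 1
    return ancestor, "".join(codons)


# ---------------------------------------------------------------- protein alignment


def gen_protein_alignment(
    n_target: int,
    n_outgroup: int,
    length: int,
    planted_sites: Sequence[int],
    seed: int = 1,
    noise_rate: float = 0.3,
    gap_rate: float = 0.05,
) -> tuple[AlignmentMatrix, pd.DataFrame]:
    """Multi-species protein alignment with planted target-specific columns.

    At planted columns every target row carries one residue X and every
    outgroup row a residue != X. All other columns share a consensus residue
    with noise constructed so the specificity rule is never satisfied: noise
    either breaks target unanimity (when there are >= 2 targets) or leaves the
    target residue present in an outgroup row.
    """
    if n_target < 1 or n_outgroup < 1:
        raise ValueError("need at least one target and one outgroup sequence")
    planted = sorted(set(int(j) for j in planted_sites))
    if planted and not (0 <= planted[0] and planted[-1] < length):
        raise ValueError("planted_sites must lie within [0, length)")
    rng = np.random.default_rng(seed)
    n_rows = n_target + n_outgroup
    matrix = np.empty((n_rows, length), dtype="<U1")
    planted_set = set(planted)
    truth_rows = []
    aa = np.array(list(AMINO_ACIDS))
    for j in range(length):
        if j in planted_set:
            x = str(rng.choice(aa))
            others = np.array([r for r in AMINO_ACIDS if r != x])
            matrix[:n_target, j] = x
            matrix[n_target:, j] = rng.choice(others, size=n_outgroup)
            truth_rows.append({"column": j, "target_residue": x})
            continue
        c = str(rng.choice(aa))
        matrix[:, j] = c
        if rng.random() < noise_rate:
            d = str(rng.choice(np.array([r for r in AMINO_ACIDS if r != c])))
            if n_target >= 2:
                matrix[int(rng.integers(n_target)), j] = d  # breaks unanimity
            elif n_outgroup >= 2:
                matrix[n_target + int(rng.integers(n_outgroup)), j] = d
        elif n_outgroup >= 2 and rng.random() < gap_rate:
            matrix[n_target + int(rng.integers(n_outgroup)), j] = "-"
    ids = [f"target{i}" for i in range(n_target)] + [f"outgroup{i}" for i in range(n_outgroup)]
    groups = {name: ("target" if name.startswith("target") else "outgroup") for name in ids}
    alignment = AlignmentMatrix(ids=ids, rows=["".join(row) for row in matrix], groups=groups)
    truth = pd.DataFrame(truth_rows, columns=["column", "target_residue"])
    return alignment, truth


# ---------------------------------------------------------------- depth & het


@dataclass
class DepthHetTruth:
    gene_decisions: pd.DataFrame  # gene_id, planted_class, expected_decision
    het_rate: float
    het_count: int
    callable_length: int


@dataclass
class DepthHetSim:
    gene_depths: pd.DataFrame  # gene_id, scaffold, sex_linked, mean_depth
    depth_track: pd.DataFrame  # scaffold, start, end, depth (0-based half-open)
    het_variants: list[tuple[str, int]]  # (scaffold, 0-based position)
    truth: DepthHetTruth


def make_gene_table(n_genes: int, genome_length: int, gene_span: int = 2000, sex_fraction: float = 0.2, seed: int = 1) -> pd.DataFrame:
    """Evenly spaced gene spans; a fraction live on a sex-linked scaffold."""
    rng = np.random.default_rng(seed)
    step = genome_length // max(n_genes, 1)
    rows = []
    for i in range(n_genes):
        sex = bool(rng.random() < sex_fraction)
        rows.append(
            {
                "gene_id": f"g{i:04d}",
                "scaffold": "simZ" if sex else "sim1",
                "start": i * step,
                "end": i * step + gene_span,
                "sex_linked": sex,
            }
        )
    return pd.DataFrame(rows)


def gen_depth_and_het(config: SimConfig, genes: pd.DataFrame, anomaly_fraction: float = 0.15) -> DepthHetSim:
    """Per-gene mean depths with planted anomalies, a binned per-base depth
    track, and heterozygous variants placed only on callable bases.

    Non-anomalous gene depths are drawn near the genome mean (clipped to
    [0.6x, 1.8x] so they never cross a filter boundary); anomalies are planted
    below 0.25x, between 0.25x and 0.5x, or above 2x the mean. The depth track
    is piecewise constant over 100-bp bins with a 10% fraction of
    low-coverage (uncallable) bins.
    """
    rng = np.random.default_rng(config.seed)
    mean = config.mean_depth

    # ---- depth track (on scaffold sim1), 100-bp bins
    bin_size = 100
    n_bins = config.genome_length // bin_size
    depths = rng.poisson(mean, size=n_bins).astype(float)
    low = rng.random(n_bins) < 0.10
    depths[low] = rng.integers(0, 6, size=int(low.sum()))  # <= 5: uncallable
    depths[~low] = np.maximum(depths[~low], 6.0)  # keep callable bins callable
    track = pd.DataFrame(
        {
            "scaffold": "sim1",
            "start": np.arange(n_bins) * bin_size,
            "end": (np.arange(n_bins) + 1) * bin_size,
            "depth": depths,
        }
    )

    # ---- heterozygous variants on callable bases only
    callable_bins = np.flatnonzero(depths > 5)
    callable_len = int(callable_bins.size * bin_size)
    het_positions: list[int] = []
    if config.het_rate > 0 and callable_len:
        count = rng.binomial(callable_len, config.het_rate)
        offsets = rng.choice(callable_len, size=count, replace=False)
        bin_idx = callable_bins[offsets // bin_size]
        het_positions = sorted(bin_idx * bin_size + offsets % bin_size)
    het_variants = [("sim1", int(p)) for p in het_positions]

    # ---- per-gene mean depths with planted anomalies
    n_genes = len(genes)
    n_anom = int(round(anomaly_fraction * n_genes))
    anom_idx = rng.choice(n_genes, size=n_anom, replace=False)
    classes = ["very_low", "low", "high"]
    gene_rows = []
    decision_rows = []
    for i, row in enumerate(genes.itertuples(index=False)):
        if i in anom_idx:
            cls = classes[int(np.where(anom_idx == i)[0][0]) % 3]
            if cls == "very_low":
                depth = mean * rng.uniform(0.02, 0.24)
            elif cls == "low":
                depth = mean * rng.uniform(0.26, 0.45)
            else:
                depth = mean * rng.uniform(2.05, 3.0)
        else:
            cls = "normal"
            depth = float(np.clip(rng.normal(mean, 0.08 * mean), 0.6 * mean, 1.8 * mean))
        sex_linked = bool(row.sex_linked)
        low_bound = 0.25 * mean if sex_linked else 0.5 * mean
        expected = "filtered" if (depth < low_bound or depth > 2 * mean) else "keep"
        gene_rows.append(
            {
                "gene_id": row.gene_id,
                "scaffold": row.scaffold,
                "sex_linked": sex_linked,
                "mean_depth": depth,
            }
        )
        decision_rows.append(
            {"gene_id": row.gene_id, "planted_class": cls, "expected_decision": expected}
        )

    truth = DepthHetTruth(
        gene_decisions=pd.DataFrame(decision_rows),
        het_rate=config.het_rate,
        het_count=len(het_variants),
        callable_length=callable_len,
    )
    return DepthHetSim(
        gene_depths=pd.DataFrame(gene_rows),
        depth_track=track,
        het_variants=het_variants,
        truth=truth,
    )
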