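"""Olfactory-receptor repertoire classification and diversity.

Candidate OR coding sequences (found by homology upstream) are optionally
extended into their genomic flanks to recover missing start/stop codons,
deduplicated at 100% identity, and classified as intact (complete ORF longer
than 215 aa, enough to span seven transmembrane domains), partial (missing
start and/or stop) or pseudogene (frameshift and/or premature stop).

Repertoire diversity of the intact genes of a clade is the mean Shannon
entropy (nats) of alignment columns, after excluding columns with more than
20% gaps.
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .alignment import GAP_CHARS, AlignmentMatrix
from .errors import InvalidSequenceError, UndefinedStatisticError

START_CODON = "ATG"
STOP_CODONS = ("TAA", "TAG", "TGA")
DEFAULT_MIN_AA = 215
DEFAULT_FLANK = 90
DEFAULT_GAP_THRESHOLD = 0.20

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ORGene:
    """A candidate olfactory-receptor coding sequence with genomic context."""

    id: str
    scaffold: str = ""
    start: int = 0  # 0-based, half-open
    end: int = 0
    strand: str = "+"
    cds: str = ""
    status: str | None = None  # intact | partial | pseudogene
    clade: str | None = None
    lesions: list[str] = field(default_factory=list)
    missing_start: bool = False
    missing_stop: bool = False


def extend_orf(
    gene: ORGene,
    genome: str,
    upstream: int = DEFAULT_FLANK,
    downstream: int = DEFAULT_FLANK,
) -> ORGene:
    """Extend a candidate lacking a start (stop) codon to the nearest in-frame
    ATG up to ``upstream`` bp before it (stop codon up to ``downstream`` bp
    after it) on the coding strand.

    If no codon is found within the flank the gene is returned unchanged with
    the corresponding missing-end flag set. Scans are truncated at scaffold
    boundaries.
    """
    start, end, strand = gene.start, gene.end, gene.strand
    if not (0 <= start < end <= len(genome)):
        raise ValueError(f"{gene.id}: interval [{start}, {end}) outside scaffold")

    def coding(s: int, e: int) -> str:
        seq = genome[s:e].upper()
        return seq if strand == "+" else _revcomp(seq)

    cds = coding(start, end)
    missing_start = not cds.startswith(START_CODON)
    missing_stop = cds[-3:] not in STOP_CODONS if len(cds) >= 3 else True

    if missing_start:
        for k in range(3, upstream + 1, 3):
            if strand == "+":
                s = start - k
                if s < 0:
                    break
                codon = genome[s : s + 3].upper()
            else:
                e = end + k
                if e > len(genome):
                    break
                codon = _revcomp(genome[e - 3 : e].upper())
            if codon == START_CODON:
                if strand == "+":
                    start -= k
                else:
                    end += k
                missing_start = False
                break
    if missing_stop:
        for k in range(3, downstream + 1, 3):
            if strand == "+":
                e = end + k
                if e > len(genome):
                    break
                codon = genome[e - 3 : e].upper()
            else:
                s = start - k
                if s < 0:
                    break
                codon = _revcomp(genome[s : s + 3].upper())
            if codon in STOP_CODONS:
                if strand == "+":
                    end += k
                else:
                    start -= k
                missing_stop = False
                break

    out = ORGene(
        id=gene.id,
        scaffold=gene.scaffold,
        start=start,
        end=end,
        strand=strand,
        cds=coding(start, end),
        clade=gene.clade,
        lesions=list(gene.lesions),
        missing_start=missing_start,
        missing_stop=missing_stop,
    )
    return out


def dedupe_identical(genes: Sequence[ORGene]) -> list[ORGene]:
    """Collapse byte-identical CDS strings, keeping the first occurrence;
    output order is stable. Idempotent."""
    seen: set[str] = set()
    out: list[ORGene] = []
    for g in genes:
        if g.cds not in seen:
            seen.add(g.cds)
            out.append(g)
    return out


def translate_cds(cds: str) -> tuple[str, bool, bool]:
    """Translate in the frame anchored at position 0.

    Returns (protein up to but excluding the first stop, has_internal_stop,
    ends_with_stop). A trailing partial codon is ignored for translation but
    is frameshift evidence for the caller.
    """
    from .codon import AA_OF  # local import avoids a cycle at import time

    aas = []
    internal_stop = False
    n_codons = len(cds) // 3
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        if codon in STOP_CODONS:
            if i < n_codons - 1:
                internal_stop = True
            break
        aas.append(AA_OF.get(codon, "X"))
    ends_with_stop = n_codons > 0 and cds[3 * (n_codons - 1) : 3 * n_codons] in STOP_CODONS
    return "".join(aas), internal_stop, ends_with_stop


def classify_or(gene: ORGene, min_aa: int = DEFAULT_MIN_AA) -> str:
    """Classify a candidate OR gene.

    Order of rules: pseudogene on frameshift evidence (CDS length not a
    multiple of 3, or an annotated indel lesion) or a premature stop in the
    frame anchored at the start; otherwise partial if the start and/or stop
    codon is missing; otherwise intact if the protein is longer than
    ``min_aa`` residues; a complete short ORF is partial (intactness is
    conjunctive: start, stop, and length).
    """
    cds = gene.cds.upper()
    if not cds:
        raise InvalidSequenceError(f"{gene.id}: empty CDS")
    bad = [i for i, c in enumerate(cds) if c not in "ACGT"]
    if bad:
        raise InvalidSequenceError(f"{gene.id}: non-ACGT characters at positions {bad[:10]}")

    lesions = list(gene.lesions)
    frameshift = len(cds) % 3 != 0 or any("indel" in l or "frameshift" in l for l in lesions)
    protein, internal_stop, ends_with_stop = translate_cds(cds)
    has_start = cds.startswith(START_CODON)

    if frameshift or internal_stop:
        if len(cds) % 3 != 0 and "frameshift" not in lesions:
            gene.lesions.append("frameshift")
        if internal_stop and "premature_stop" not in gene.lesions:
            gene.lesions.append("premature_stop")
        status = "pseudogene"
    elif not has_start or not ends_with_stop or gene.missing_start or gene.missing_stop:
        status = "partial"
    elif len(protein) > min_aa:
        status = "intact"
    else:
        status = "partial"  # complete but too short for 7 TM domains
    gene.status = status
    gene.protein = protein  # type: ignore[attr-defined]
    return status


# ---------------------------------------------------------------- diversity


@dataclass
class RepertoireDiversity:
    clade: str
    n_sequences: int
    n_columns_used: int
    mean_entropy: float  # nats
    has_nonstandard_residues: bool = False


def column_entropy(column: Iterable[str]) -> float:
    """Shannon entropy (nats) of a residue column, over non-gap residues."""
    residues = [c for c in column if c not in GAP_CHARS]
    if not residues:
        raise UndefinedStatisticError("all-gap column has no entropy")
    counts = Counter(residues)
    total = len(residues)
    return -sum((k / total) * math.log(k / total) for k in counts.values()) + 0.0


def repertoire_diversity(
    alignment: AlignmentMatrix,
    clade: str = "",
    gap_threshold: float = DEFAULT_GAP_THRESHOLD,
) -> RepertoireDiversity:
    """Mean column entropy of a clade's intact-gene alignment.

    Columns whose gap fraction exceeds ``gap_threshold`` (strictly) are
    excluded; a column at exactly the threshold is retained.
    """
    if alignment.n_rows < 2:
        raise UndefinedStatisticError("diversity needs at least 2 sequences")
    kept: list[float] = []
    nonstandard = False
    for j in range(alignment.n_columns):
        col = alignment.column(j)
        gap_frac = sum(c in GAP_CHARS for c in col) / len(col)
        if gap_frac > gap_threshold:
            continue
        if "X" in col.upper():
            nonstandard = True
        kept.append(column_entropy(col))
    if not kept:
        raise UndefinedStatisticError("no columns survive the gap filter")
    return RepertoireDiversity(
        clade=clade,
        n_sequences=alignment.n_rows,
        n_columns_used=len(kept),
        mean_entropy=sum(kept) / len(kept),
        has_nonstandard_residues=nonstandard,
    )
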