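"""File I/O shared by all pipeline stages.

Conventions: genomic intervals are 0-based half-open (BED) in memory and in
every TSV/BED the package writes; VCF is 1-based on disk (converted at the
boundary). All writers go through :func:`atomic_write` so a failed run never
leaves a partial output file.
"""
from __future__ import annotations

import os
import tempfile
from contextlib import contextmanager
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

from .errors import DataIntegrityError


@contextmanager
def atomic_write(path: str | Path, mode: str = "w"):
    """Yield a handle to a temp file that replaces ``path`` only on success."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name + ".")
    try:
        with os.fdopen(fd, mode) as handle:
            yield handle
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------- FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{id: uppercase sequence}`` preserving order."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with atomic_write(path) as handle:
        SeqIO.write(records, handle, "fasta")


# ---------------------------------------------------------------- tables


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    with atomic_write(path) as handle:
        df.to_csv(handle, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_scaffold_lengths(path: str | Path) -> dict[str, int]:
    """Scaffold lengths from a samtools ``.fai`` index or a 2-column TSV."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 2:
        raise DataIntegrityError(f"{path}: need at least 2 columns (scaffold, length)")
    return dict(zip(df[0].astype(str), df[1].astype(int)))


# ---------------------------------------------------------------- BED


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["scaffold", "start", "end", "name", "score", "strand"]
    df.columns = names[: df.shape[1]] + list(df.columns[len(names):])
    df["scaffold"] = df["scaffold"].astype(str)
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    with atomic_write(path) as handle:
        df.to_csv(handle, sep="\t", index=False, header=False)


# ---------------------------------------------------------------- variants


def read_positions(path: str | Path) -> dict[str, np.ndarray]:
    """Per-scaffold sorted 0-based difference positions.

    Accepts VCF v4.2 (``.vcf``) or a 2-column TSV of (scaffold,
    1-based position).
    """
    path = Path(path)
    out: dict[str, list[int]] = {}
    if path.suffix == ".vcf" or "".join(path.suffixes).endswith(".vcf.gz"):
        for v in VCF(str(path)):
            out.setdefault(v.CHROM, []).append(v.POS - 1)
    else:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        if df.shape[1] < 2:
            raise DataIntegrityError(f"{path}: need 2 columns (scaffold, position)")
        for scaf, pos in zip(df[0].astype(str), df[1].astype(int)):
            out.setdefault(scaf, []).append(pos - 1)
    return {k: np.sort(np.asarray(v, dtype=np.int64)) for k, v in out.items()}


def read_het_variants(path: str | Path) -> list[tuple[str, int]]:
    """Heterozygous biallelic SNVs from a VCF as (scaffold, 0-based position).

    Multiallelic records and non-SNVs are ignored; heterozygous means the
    first sample's genotype carries two distinct alleles.
    """
    out = []
    for v in VCF(str(path)):
        if not v.is_snp or len(v.ALT) != 1:
            continue
        if len(v.gt_types) and v.gt_types[0] == 1:  # cyvcf2: 1 == HET
            out.append((v.CHROM, v.POS - 1))
    return out


def write_vcf(
    variants: Iterable[tuple[str, int, str, str, str]],
    contigs: Mapping[str, int],
    path: str | Path,
    sample: str = "sample1",
) -> None:
    """Write (scaffold, 0-based pos, ref, alt, genotype) records as VCF v4.2."""
    with atomic_write(path) as handle:
        handle.write("##fileformat=VCFv4.2\n")
        for name, length in contigs.items():
            handle.write(f"##contig=<ID={name},length={length}>\n")
        handle.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        handle.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for scaf, pos0, ref, alt, gt in variants:
            handle.write(f"{scaf}\t{pos0 + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gt}\n")


# ---------------------------------------------------------------- depth / GFF


DEPTH_COLUMNS = ["scaffold", "start", "end", "depth"]


def read_depth_track(path: str | Path) -> pd.DataFrame:
    """Bedgraph-style depth intervals (scaffold, start, end, depth); a header
    row is detected and skipped if present."""
    first = pd.read_csv(path, sep="\t", nrows=1, header=None)
    header = 0 if str(first.iloc[0, 1]) == "start" else None
    df = pd.read_csv(path, sep="\t", header=header)
    df.columns = DEPTH_COLUMNS[: df.shape[1]]
    df["scaffold"] = df["scaffold"].astype(str)
    return df


def write_gff3(genes: pd.DataFrame, path: str | Path, source: str = "raptorsig") -> None:
    """Write gene spans (gene_id, scaffold, start, end[, strand]) as GFF3."""
    with atomic_write(path) as handle:
        handle.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            strand = getattr(row, "strand", "+")
            handle.write(
                f"{row.scaffold}\t{source}\tgene\t{row.start + 1}\t{row.end}\t.\t"
                f"{strand}\t.\tID={row.gene_id}\n"
            )
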