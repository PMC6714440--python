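"""Rectangular residue/codon alignments with row labels and group tags."""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import io
from .errors import DataIntegrityError

GAP_CHARS = frozenset("-.")


@dataclass
class AlignmentMatrix:
    """A rectangular multiple alignment.

    ``rows[i]`` is the aligned sequence for ``ids[i]``; ``groups`` optionally
    maps each id to a group label (species set, clade, ...).
    """

    ids: list[str]
    rows: list[str]
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise DataIntegrityError("ids and rows differ in length")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise DataIntegrityError(f"alignment is not rectangular: lengths {sorted(lengths)}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)

    def row_indices(self, labels: Sequence[str]) -> set[int]:
        """Indices of the rows whose ids are in ``labels``."""
        wanted = set(labels)
        missing = wanted - set(self.ids)
        if missing:
            raise DataIntegrityError(f"ids not in alignment: {sorted(missing)}")
        return {i for i, name in enumerate(self.ids) if name in wanted}

    def subset(self, labels: Sequence[str]) -> "AlignmentMatrix":
        keep = self.row_indices(labels)
        return AlignmentMatrix(
            ids=[self.ids[i] for i in sorted(keep)],
            rows=[self.rows[i] for i in sorted(keep)],
            groups={k: v for k, v in self.groups.items() if k in set(labels)},
        )

    @classmethod
    def from_fasta(cls, path: str | Path, groups: Mapping[str, str] | None = None) -> "AlignmentMatrix":
        seqs = io.read_fasta(path)
        return cls(ids=list(seqs), rows=list(seqs.values()), groups=dict(groups or {}))

    def to_fasta(self, path: str | Path) -> None:
        io.write_fasta(dict(zip(self.ids, self.rows)), path)
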