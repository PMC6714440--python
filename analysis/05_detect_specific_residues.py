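"""Detect nocturnal-specific amino-acid residues in a protein alignment.

Simulates a 12-species protein alignment (4 "nocturnal" target rows, 8
diurnal outgroup rows, 400 columns) with three planted target-specific
columns, runs the detector in both default and strict-gap modes, and scores
the calls against the planted truth. Writes the detected sites under
results/.
"""
from pathlib import Path

import pandas as pd

from raptorsig import codon, io, simulate

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1
PLANTED = [25, 120, 333]


def main() -> None:
    aln, truth = simulate.gen_protein_alignment(4, 8, 400, planted_sites=PLANTED, seed=SEED)
    targets = aln.row_indices([i for i in aln.ids if i.startswith("target")])
    sites = codon.specific_residues(aln, targets)
    strict = codon.specific_residues(aln, targets, strict_gaps=True)

    table = pd.DataFrame(
        [{"column": s.column, "target_residue": s.target_residue,
          "outgroup_residues": "".join(sorted(s.outgroup_residues))} for s in sites]
    )
    io.write_tsv(table, RESULTS / "specific_sites.tsv")
    found = [s.column for s in sites]
    print(f"planted columns: {PLANTED}; detected: {found} "
          f"({'exact recovery' if found == PLANTED else 'MISMATCH'})")
    print(f"strict-gap mode detects {len(strict)} of them "
          f"(outgroup gaps disqualify a column in strict mode)")


if __name__ == "__main__":
    main()
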