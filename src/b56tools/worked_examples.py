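"""Published B56-docking peptides and their expected scan results.

These 14-mer context peptides around predicted docking windows, the CIP2A
display peptide, the Cyk4 Plk1-substrate region and three synthetic
phospho-peptides are the standard worked examples for the scanner: each has
a known consensus window, flank D/E count or flank S/T occupancy, so a
correct implementation reproduces every row.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .motif import (
    FLANK_POSITIONS,
    find_motif_windows,
    predict_plk1_sites,
    scan_sequence,
)

#: Intrinsic-motif examples: gene, context peptide, expected flank D/E count
#: (motif positions 2, 7, 8, 9 of the detected consensus window).
INTRINSIC_EXAMPLES = [
    ("SMARCA4", "RAFLQAILEHEEQD", 2),
    ("GOLGA2", "PQPMPSIPEDLESR", 2),
    ("CEP350", "RGSLESIAEHVDAS", 2),
    ("ARHGEF2", "FTRMQDIPEETESR", 2),
    ("AXIN2", "CGYLPTLNEEEEWT", 3),
]

#: Phospho-responsive examples: gene, context peptide, expected flank S/T
#: occupancy string over positions 2, 7, 8, 9 (e.g. "2S7S").
PHOSPHO_EXAMPLES = [
    ("CEP295", "SSSLSQVDESERFQ", "2S7S"),
    ("CEP295b", "TKKLSQLGESELFA", "2S7S"),
    ("ANAPC1", "VVLLSPVPELRDSS", "2S"),
    ("LATS1", "RQMLQEIRESLRNL", "7S"),
    ("AKAP9", "NLELQVLLESEKVR", "7S"),
    ("GOLGA2b", "QEKLSELKETVELK", "2S7T"),
    ("SYNE1", "SSDLSTIQERMEEL", "2S"),
]

#: The CIP2A display peptide (peptide-local numbering) and its flank D/E count.
CIP2A_PEPTIDE = "FQHNRKLESVAEEHEI"
CIP2A_EXPECTED_NUMDE = 3

#: Cyk4/RACGAP1 context around its docking motif; the peptide starts at
#: residue 140 and the motif spans residues 143-151.  The unique Plk1 site
#: (S/T with D/E/N at -2) within the motif is S149.
CYK4_PEPTIDE = "NKRLSTIDESGSIL"
CYK4_OFFSET = 140
CYK4_EXPECTED_PLK1_SITE = 149

#: Phospho-peptides probing position-6 strictness: pS/pT at the E-position
#: abolishes consensus matching despite three acidic flanks.
POSITION6_PHOSPHO_PEPTIDES = ["LEPVRpSEE", "LEPIRpSEE", "LEPIRpTEE"]


@dataclass(frozen=True)
class Check:
    name: str
    expected: object
    computed: object

    @property
    def passed(self) -> bool:
        return self.expected == self.computed


def _flank_st_string(match) -> str:
    return "".join(f"{p}{match.window[p - 1]}" for p in match.phospho_positions)


def run_worked_examples() -> list[Check]:
    """Evaluate every worked example; returns one Check per row."""
    checks: list[Check] = []
    for gene, peptide, expected in INTRINSIC_EXAMPLES:
        matches = scan_sequence(gene, peptide)
        computed = matches[0].numDE if matches else None
        checks.append(Check(f"{gene} flank D/E count", expected, computed))
    for gene, peptide, expected in PHOSPHO_EXAMPLES:
        matches = scan_sequence(gene, peptide)
        computed = _flank_st_string(matches[0]) if matches else None
        checks.append(Check(f"{gene} flank S/T occupancy", expected, computed))

    cip2a = scan_sequence("CIP2A", CIP2A_PEPTIDE)
    checks.append(
        Check(
            "CIP2A one consensus window",
            1,
            len(cip2a),
        )
    )
    checks.append(
        Check(
            "CIP2A flank D/E count",
            CIP2A_EXPECTED_NUMDE,
            cip2a[0].numDE if cip2a else None,
        )
    )

    cep295 = scan_sequence("CEP295", PHOSPHO_EXAMPLES[0][1])
    checks.append(
        Check(
            "CEP295 classified phospho-responsive",
            "phospho_responsive",
            cep295[0].classification if cep295 else None,
        )
    )

    plk1 = predict_plk1_sites(CYK4_PEPTIDE, offset=CYK4_OFFSET)
    motif_sites = [s.position for s in plk1 if 143 <= s.position <= 151]
    checks.append(
        Check(
            "Cyk4 Plk1 site in docking motif",
            [CYK4_EXPECTED_PLK1_SITE],
            motif_sites,
        )
    )

    for pep in POSITION6_PHOSPHO_PEPTIDES:
        checks.append(
            Check(
                f"{pep} rejected (no pS/pT at position 6)",
                0,
                len(find_motif_windows(pep)),
            )
        )
    return checks


def report_worked_examples() -> pd.DataFrame:
    """Tabular expected-vs-computed report over all worked examples."""
    return pd.DataFrame(
        [
            {
                "check": c.name,
                "expected": str(c.expected),
                "computed": str(c.computed),
                "pass": c.passed,
            }
            for c in run_worked_examples()
        ]
    )
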