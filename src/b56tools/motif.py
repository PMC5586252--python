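"""The B56 docking consensus, window scanning and N-score classification.

PP2A holoenzymes carrying a B56 (B') regulatory subunit dock their substrates
through a short linear motif that occupies a nine-position frame on the B56
surface::

    position   1  2  3  4  5  6  7  8  9
    consensus [LMFI] x  x [ILV] x  E  x  x  x

Positions 1, 4 and 6 anchor the peptide in the hydrophobic groove; the
glutamate at position 6 is strictly required and cannot be replaced by
aspartate or by phospho-Ser/Thr.  Positions 2, 7, 8 and 9 ("flanks") face a
basic pocket: acidic residues or phosphorylated S/T there strengthen binding
while K/R weaken it.

The flank charge balance is summarised by the integer score

    N = numDE + numST - numKR          (counted over positions 2, 7, 8, 9)

and its phosphorylation-independent part N_intrinsic = numDE - numKR.  The
minimum N required for binding depends on how close positions 1 and 4 are to
the best anchors (L and I): 1 if both are best, 2 if one is a similar
residue, 4 if both are.  A window passing on N_intrinsic alone is an
*intrinsic* binder; one that needs the S/T contribution is
*phosphorylation-responsive* (it binds once those flanks are
phosphorylated).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from .errors import ParameterError
from .sequences import NONSTANDARD_AA, parse_phospho

logger = logging.getLogger(__name__)

MOTIF_SPAN = 9
#: 1-based motif positions whose charge/phospho state enters the N score.
FLANK_POSITIONS = (2, 7, 8, 9)

ACIDIC = frozenset("DE")
PHOSPHORYLATABLE = frozenset("ST")
BASIC = frozenset("KR")

BEST_ANCHOR1 = "L"
SIMILAR_ANCHOR1 = frozenset("MFI")
BEST_ANCHOR4 = "I"
SIMILAR_ANCHOR4 = frozenset("LV")

ANCHOR1_ALPHABET = frozenset("LMFI")
ANCHOR4_ALPHABET = frozenset("ILV")

# classification labels
INTRINSIC = "intrinsic"
PHOSPHO_RESPONSIVE = "phospho_responsive"
FAIL = "fail"

# anchor classes and their minimum N
ANCHOR_MIN_N = {"best_best": 1, "one_similar": 2, "both_similar": 4}


@dataclass(frozen=True)
class MotifPattern:
    """Nine ordered position constraints; ``None`` means wildcard.

    Position 6 (index 5) must be exactly ``{E}``; positions 1 and 4 must be
    non-empty subsets of the anchor alphabets [LMFI] and [ILV].
    """

    positions: tuple[Optional[frozenset[str]], ...]

    def __post_init__(self):
        if len(self.positions) != MOTIF_SPAN:
            raise ParameterError(f"pattern must have {MOTIF_SPAN} positions")
        p1, p4, p6 = self.positions[0], self.positions[3], self.positions[5]
        if p6 != frozenset("E"):
            raise ParameterError("position 6 constraint must be exactly {E}")
        if not p1 or not p1 <= ANCHOR1_ALPHABET:
            raise ParameterError("position 1 must be a non-empty subset of [LMFI]")
        if not p4 or not p4 <= ANCHOR4_ALPHABET:
            raise ParameterError("position 4 must be a non-empty subset of [ILV]")

    def __str__(self) -> str:
        parts = []
        for allowed in self.positions:
            if allowed is None:
                parts.append("x")
            elif len(allowed) == 1:
                parts.append(next(iter(allowed)))
            else:
                parts.append("[" + "".join(sorted(allowed)) + "]")
        return "".join(parts)


#: The merged B56-family consensus, [LMFI]xx[ILV]xE with free flanks.
B56_CONSENSUS = MotifPattern(
    (
        ANCHOR1_ALPHABET,
        None,
        None,
        ANCHOR4_ALPHABET,
        None,
        frozenset("E"),
        None,
        None,
        None,
    )
)


@dataclass(frozen=True)
class MotifMatch:
    """One scored consensus window on a protein (1-based ``start``)."""

    protein_id: str
    start: int
    window: str
    numDE: int
    numST: int
    numKR: int
    N: int
    N_intrinsic: int
    anchor_class: str
    min_N: int
    classification: str
    phospho_positions: tuple[int, ...]


@dataclass(frozen=True)
class PlkSite:
    """An S/T predicted phosphorylatable by Plk1 (D/E/N at its -2 position)."""

    protein_id: str
    position: int
    residue: str
    minus2: str


def find_motif_windows(
    sequence: str, pattern: MotifPattern = B56_CONSENSUS
) -> list[tuple[int, str]]:
    """All 9-residue windows of ``sequence`` matching ``pattern``.

    ``sequence`` may carry ``pS``/``pT`` marks.  A phosphorylated residue
    satisfies only wildcard positions — in particular pS/pT at position 6
    never substitutes for the required E.  Windows containing nonstandard
    residues are skipped (logged), other windows are unaffected.  Overlapping
    matches are all reported; ``start`` is 1-based in the plain sequence.
    """
    residues, phospho = parse_phospho(sequence) if sequence else ("", frozenset())
    matches: list[tuple[int, str]] = []
    for start0 in range(len(residues) - MOTIF_SPAN + 1):
        window = residues[start0 : start0 + MOTIF_SPAN]
        bad = set(window) & NONSTANDARD_AA
        if bad:
            logger.warning(
                "skipping window at %d: nonstandard residue(s) %s", start0 + 1, bad
            )
            continue
        ok = True
        for offset, allowed in enumerate(pattern.positions):
            if allowed is None:
                continue
            if window[offset] not in allowed or (start0 + offset + 1) in phospho:
                ok = False
                break
        if ok:
            matches.append((start0 + 1, window))
    return matches


def score_window(
    window: str, phospho_positions: frozenset[int] = frozenset()
) -> tuple[int, int, int, int, int]:
    """Flank counts for a consensus window.

    Returns ``(numDE, numST, numKR, N, N_intrinsic)`` counted over motif
    positions 2, 7, 8 and 9.  Phosphorylated S/T (``phospho_positions``,
    1-based within the window) count toward numST like unmodified S/T.
    """
    if len(window) != MOTIF_SPAN:
        raise ParameterError(f"window must be {MOTIF_SPAN} residues, got {window!r}")
    numDE = numST = numKR = 0
    for pos in FLANK_POSITIONS:
        res = window[pos - 1]
        if res in ACIDIC:
            numDE += 1
        elif res in PHOSPHORYLATABLE:
            numST += 1
        elif res in BASIC:
            numKR += 1
    return numDE, numST, numKR, numDE + numST - numKR, numDE - numKR


def anchor_class(window: str) -> tuple[str, int]:
    """Anchor class of a consensus window and its minimum N.

    Both positions 1 and 4 at the best residues (L, I) -> min N of 1; one
    replaced by a similar residue -> 2; both replaced -> 4.
    """
    if len(window) != MOTIF_SPAN:
        raise ParameterError(f"window must be {MOTIF_SPAN} residues, got {window!r}")
    best1 = window[0] == BEST_ANCHOR1
    best4 = window[3] == BEST_ANCHOR4
    if best1 and best4:
        cls = "best_best"
    elif best1 or best4:
        cls = "one_similar"
    else:
        cls = "both_similar"
    return cls, ANCHOR_MIN_N[cls]


def classify_window(
    window: str, phospho_flags: frozenset[int] = frozenset()
) -> MotifMatch:
    """Score and classify one consensus window (protein id and start unset)."""
    numDE, numST, numKR, n, n_intr = score_window(window, phospho_flags)
    cls, min_n = anchor_class(window)
    st_positions = tuple(
        p for p in FLANK_POSITIONS if window[p - 1] in PHOSPHORYLATABLE
    )
    if n_intr >= min_n:
        label = INTRINSIC
    elif n >= min_n:
        label = PHOSPHO_RESPONSIVE
    else:
        label = FAIL
    return MotifMatch(
        protein_id="",
        start=0,
        window=window,
        numDE=numDE,
        numST=numST,
        numKR=numKR,
        N=n,
        N_intrinsic=n_intr,
        anchor_class=cls,
        min_N=min_n,
        classification=label,
        phospho_positions=st_positions,
    )


def classify_match(match: MotifMatch) -> str:
    """Classification label implied by a match's scores (intrinsic first)."""
    if match.N_intrinsic >= match.min_N:
        return INTRINSIC
    if match.N >= match.min_N:
        return PHOSPHO_RESPONSIVE
    return FAIL


def scan_sequence(
    protein_id: str, sequence: str, pattern: MotifPattern = B56_CONSENSUS
) -> list[MotifMatch]:
    """Find, score and classify every consensus window of one sequence."""
    residues, phospho = parse_phospho(sequence) if sequence else ("", frozenset())
    out = []
    for start, window in find_motif_windows(sequence, pattern):
        local_flags = frozenset(
            p - start + 1 for p in phospho if start <= p < start + MOTIF_SPAN
        )
        m = classify_window(window, local_flags)
        out.append(
            MotifMatch(
                protein_id=protein_id,
                start=start,
                window=window,
                numDE=m.numDE,
                numST=m.numST,
                numKR=m.numKR,
                N=m.N,
                N_intrinsic=m.N_intrinsic,
                anchor_class=m.anchor_class,
                min_N=m.min_N,
                classification=m.classification,
                phospho_positions=m.phospho_positions,
            )
        )
    return out


def predict_plk1_sites(
    sequence: str, offset: int = 1, protein_id: str = ""
) -> list[PlkSite]:
    """Every S/T with D, E or N two residues upstream (the Plk1 consensus).

    ``offset`` is the full-protein residue number of the first residue of
    ``sequence``; the first two residues have no -2 context and are skipped.
    Sites are returned in ascending position.
    """
    residues, _ = parse_phospho(sequence) if sequence else ("", frozenset())
    sites = []
    for i in range(2, len(residues)):
        if residues[i] in PHOSPHORYLATABLE and residues[i - 2] in "DEN":
            sites.append(
                PlkSite(
                    protein_id=protein_id,
                    position=offset + i,
                    residue=residues[i],
                    minus2=residues[i - 2],
                )
            )
    return sites
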