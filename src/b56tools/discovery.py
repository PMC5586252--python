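"""De novo consensus discovery from an enriched peptide set.

Candidate motifs are degenerate templates with up to three defined
positions spread over a span of at most nine residues, the remaining
positions wildcards — the shape of known B56-docking consensi, which have
exactly three strong positions (1, 4, 6).  Support is the number of
peptides containing at least one occurrence of a template; significance is
the binomial upper tail of the support given the per-peptide occurrence
probability under a background residue model, Bonferroni-corrected over the
enumerated template space.

A significant seed template is then expanded into a full nine-position
degenerate pattern by aligning the peptides on their seed occurrences and
admitting, at each position, the residues enriched over background.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product
from math import comb

import numpy as np
from scipy import stats

from .errors import AlignmentError, InsufficientDataError, ParameterError
from .motif import (
    ANCHOR1_ALPHABET,
    ANCHOR4_ALPHABET,
    MOTIF_SPAN,
    MotifPattern,
)
from .sequences import STANDARD_AA, strip_phospho

#: Residue class allowed at defined template positions besides singletons.
HYDROPHOBIC = "LMFIV"
HYDROPHOBIC_SET = frozenset(HYDROPHOBIC)
#: Class symbols: one char per class; 'h' = hydrophobic [LMFIV].
CLASS_RESIDUES = {"h": HYDROPHOBIC_SET}

MAX_SPAN = 9


@dataclass(frozen=True)
class ScoredMotif:
    """A degenerate template with its support and binomial significance."""

    offsets: tuple[int, ...]  # 0-based offsets of defined positions; first is 0
    symbols: tuple[str, ...]  # residue or class symbol per defined position
    support: int
    n_peptides: int
    expected: float
    p_value: float
    p_adjusted: float

    @property
    def span(self) -> int:
        return self.offsets[-1] + 1

    @property
    def pattern_string(self) -> str:
        chars = ["."] * self.span
        for off, sym in zip(self.offsets, self.symbols):
            chars[off] = f"[{HYDROPHOBIC}]" if sym == "h" else sym
        return "".join(chars)


def _uniform_background() -> dict[str, float]:
    return {a: 1.0 / 20.0 for a in STANDARD_AA}


def _symbols_for(residue: str) -> tuple[str, ...]:
    if residue in HYDROPHOBIC_SET:
        return (residue, "h")
    return (residue,)


def _offset_patterns(max_defined: int) -> list[tuple[int, ...]]:
    patterns: list[tuple[int, ...]] = [(0,)] if max_defined >= 1 else []
    if max_defined >= 2:
        patterns += [(0, a) for a in range(1, MAX_SPAN)]
    if max_defined >= 3:
        patterns += [(0, a, b) for a, b in combinations(range(1, MAX_SPAN), 2)]
    return patterns


def template_space_size(max_defined: int = 3) -> int:
    """Number of enumerable templates (Bonferroni denominator)."""
    n_symbols = 20 + len(CLASS_RESIDUES)
    total = 0
    for k in range(1, max_defined + 1):
        n_offsets = 1 if k == 1 else comb(MAX_SPAN - 1, k - 1)
        total += n_offsets * n_symbols**k
    return total


def _templates_in(peptide: str, offset_patterns: list[tuple[int, ...]]):
    """Set of (offsets, symbols) templates occurring in one peptide."""
    found = set()
    L = len(peptide)
    for offsets in offset_patterns:
        span = offsets[-1] + 1
        for start in range(L - span + 1):
            symbol_options = [
                _symbols_for(peptide[start + off]) for off in offsets
            ]
            for symbols in product(*symbol_options):
                found.add((offsets, symbols))
    return found


def _match_probability(symbols: tuple[str, ...], background: dict[str, float]) -> float:
    p = 1.0
    for sym in symbols:
        if sym in CLASS_RESIDUES:
            p *= sum(background[a] for a in CLASS_RESIDUES[sym])
        else:
            p *= background[sym]
    return p


def enumerate_candidate_motifs(
    peptides: list[str],
    background: dict[str, float] | None = None,
    max_defined: int = 3,
    alpha: float = 0.05,
) -> list[ScoredMotif]:
    """Rank all templates observed in the peptides by corrected significance.

    Support counting is exact (a template is supported by a peptide iff it
    occurs at least once).  The per-peptide occurrence probability under the
    background treats positions as independent,
    ``q = 1 - (1 - p_match)^(L - span + 1)`` averaged over peptide lengths,
    and the p-value is the binomial upper tail of the support at that q,
    multiplied by the size of the enumerable template space (Bonferroni).
    Ties are broken by higher support, then lexicographic pattern.
    """
    if len(peptides) < 5:
        raise InsufficientDataError("need at least 5 peptides")
    if not 1 <= max_defined <= 3:
        raise ParameterError("max_defined must be in 1..3")
    background = background or _uniform_background()
    plain = [strip_phospho(p) for p in peptides]
    offset_patterns = _offset_patterns(max_defined)

    support: dict[tuple, int] = {}
    for pep in plain:
        for key in _templates_in(pep, offset_patterns):
            support[key] = support.get(key, 0) + 1

    n = len(plain)
    lengths = np.array([len(p) for p in plain])
    n_tests = template_space_size(max_defined)

    keys = list(support)
    counts = np.array([support[k] for k in keys])
    qbar = np.empty(len(keys))
    for i, (offsets, symbols) in enumerate(keys):
        span = offsets[-1] + 1
        p_match = _match_probability(symbols, background)
        windows = np.maximum(lengths - span + 1, 0)
        qbar[i] = float(np.mean(1.0 - (1.0 - p_match) ** windows))
    pvals = stats.binom.sf(counts - 1, n, qbar)
    adjusted = np.minimum(pvals * n_tests, 1.0)

    motifs = [
        ScoredMotif(
            offsets=offsets,
            symbols=symbols,
            support=int(c),
            n_peptides=n,
            expected=float(n * q),
            p_value=float(p),
            p_adjusted=float(pa),
        )
        for (offsets, symbols), c, q, p, pa in zip(keys, counts, qbar, pvals, adjusted)
    ]
    motifs.sort(key=lambda m: (m.p_value, -m.support, m.pattern_string))
    return motifs


def _occurrence_start(peptide: str, motif: ScoredMotif) -> int | None:
    """0-based start of the first occurrence of the template, else None."""
    for start in range(len(peptide) - motif.span + 1):
        ok = True
        for off, sym in zip(motif.offsets, motif.symbols):
            res = peptide[start + off]
            allowed = CLASS_RESIDUES.get(sym, frozenset(sym))
            if res not in allowed:
                ok = False
                break
        if ok:
            return start
    return None


def build_consensus(
    peptides: list[str],
    seed_motif: ScoredMotif,
    inclusion_threshold: float = 3.0,
    background: dict[str, float] | None = None,
) -> MotifPattern:
    """Expand a seed template into a nine-position degenerate pattern.

    Peptides are aligned on their first seed occurrence (template offset 0 =
    motif position 1) and a position-frequency matrix over the 9-position
    frame is built from occurrences that fit entirely inside their peptide.
    A residue is admitted at a position when its observed/background
    frequency ratio exceeds ``inclusion_threshold``; positions with no
    enriched residue become wildcards.  Position 6 is fixed to {E} and the
    anchor positions 1 and 4 are restricted to their consensus alphabets.
    """
    background = background or _uniform_background()
    plain = [strip_phospho(p) for p in peptides]
    frames = []
    n_occurrences = 0
    for pep in plain:
        start = _occurrence_start(pep, seed_motif)
        if start is None:
            continue
        n_occurrences += 1
        if start + MOTIF_SPAN <= len(pep):
            frames.append(pep[start : start + MOTIF_SPAN])
    if n_occurrences < 5:
        raise InsufficientDataError("seed motif must occur in at least 5 peptides")
    if len(frames) < 0.5 * n_occurrences:
        raise AlignmentError(
            "9-position frame extends past peptide bounds for most occurrences"
        )

    positions: list[frozenset[str] | None] = []
    n_frames = len(frames)
    for pos in range(MOTIF_SPAN):
        counts: dict[str, int] = {}
        for frame in frames:
            counts[frame[pos]] = counts.get(frame[pos], 0) + 1
        enriched = frozenset(
            a
            for a, c in counts.items()
            if c >= 2 and (c / n_frames) / background[a] > inclusion_threshold
        )
        positions.append(enriched or None)

    # anchor constraints of the docking-motif frame
    p1 = (positions[0] or frozenset()) & ANCHOR1_ALPHABET
    p4 = (positions[3] or frozenset()) & ANCHOR4_ALPHABET
    positions[0] = p1 or frozenset(max(
        ((a, c) for a, c in _position_counts(frames, 0).items() if a in ANCHOR1_ALPHABET),
        key=lambda t: t[1],
        default=("L", 0),
    )[0])
    positions[3] = p4 or frozenset(max(
        ((a, c) for a, c in _position_counts(frames, 3).items() if a in ANCHOR4_ALPHABET),
        key=lambda t: t[1],
        default=("I", 0),
    )[0])
    positions[5] = frozenset("E")
    return MotifPattern(tuple(positions))


def _position_counts(frames: list[str], pos: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for frame in frames:
        counts[frame[pos]] = counts.get(frame[pos], 0) + 1
    return counts
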