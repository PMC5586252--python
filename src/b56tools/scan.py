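"""Proteome-wide candidate search: scan, score, classify, annotate.

Composes the window scanner with an intrinsic-disorder filter and optional
per-protein annotations (known phosphosites, organelle/super-complex
locations, externally computed per-residue disorder) into a flat candidate
table, one row per surviving consensus window.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import AnnotationError, ParameterError
from .motif import (
    B56_CONSENSUS,
    FAIL,
    MOTIF_SPAN,
    MotifPattern,
    scan_sequence,
)
from .sequences import ProteinRecord

# Kyte-Doolittle hydropathy, used by the charge-hydropathy disorder heuristic.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}
CHARGE = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0}

CANDIDATE_COLUMNS = [
    "protein", "start", "window", "anchor_class",
    "numDE", "numST", "numKR", "N_intrinsic", "N",
    "class", "phospho_positions", "disorder_mean",
    "known_phosphosites", "locations",
]

LOCATION_VOCAB = frozenset({"kinetochore", "telomere", "spindle", "centrosome", "midbody"})


def disorder_profile(
    sequence: str,
    method: str = "builtin_heuristic",
    window_half_width: int = 10,
    external_scores: Mapping[int, float] | None = None,
) -> np.ndarray:
    """Per-residue disorder tendency, length = len(sequence).

    The builtin heuristic is a windowed charge-hydropathy score of FoldIndex
    form, ``2.785*<hydropathy> - |<net charge>| - 1.151`` with hydropathy
    rescaled to [0, 1], sign-flipped so that larger values mean more
    disordered.  ``external_scores`` (1-based position -> score) plugs in a
    table from any external predictor instead.
    """
    n = len(sequence)
    if method == "external_scores":
        if external_scores is None:
            raise ParameterError("external_scores table required")
        missing = [i for i in range(1, n + 1) if i not in external_scores]
        if missing:
            raise AnnotationError(
                f"external disorder table missing positions {missing[:5]}..."
            )
        return np.array([external_scores[i] for i in range(1, n + 1)], float)
    if method != "builtin_heuristic":
        raise ParameterError(f"unknown disorder method {method!r}")
    hydro = np.array([(KYTE_DOOLITTLE.get(a, 0.0) + 4.5) / 9.0 for a in sequence])
    charge = np.array([CHARGE.get(a, 0.0) for a in sequence])
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - window_half_width), min(n, i + window_half_width + 1)
        fold_index = 2.785 * hydro[lo:hi].mean() - abs(charge[lo:hi].mean()) - 1.151
        out[i] = -fold_index
    return out


def _format_phospho_positions(window: str, positions: tuple[int, ...]) -> str:
    return "".join(f"{p}{window[p - 1]}" for p in positions)


def scan_proteome(
    records: Iterable[ProteinRecord],
    pattern: MotifPattern = B56_CONSENSUS,
    mode: str = "n-rule",
    disorder: str = "builtin",
    min_disorder: float | None = None,
    window_half_width: int = 10,
    phosphosites: pd.DataFrame | None = None,
    locations: pd.DataFrame | None = None,
    external_disorder: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Candidate table over a proteome.

    ``mode='consensus-only'`` keeps every consensus window (classification is
    still reported); ``mode='n-rule'`` keeps only windows passing their
    anchor-class minimum N (intrinsic or phospho-responsive).  ``disorder``
    is ``builtin``/``external``/``off``; when not off, the mean window
    disorder is reported and, if ``min_disorder`` is given, used as a hard
    filter.  ``phosphosites`` (protein, position, residue) and ``locations``
    (protein, location) annotation tables are joined onto the output.
    Rows are sorted by (protein, start).
    """
    if mode not in ("consensus-only", "n-rule"):
        raise ParameterError(f"unknown scan mode {mode!r}")
    if disorder not in ("builtin", "external", "off"):
        raise ParameterError(f"unknown disorder option {disorder!r}")

    phospho_map: dict[str, set[int]] = {}
    if phosphosites is not None:
        for prot, grp in phosphosites.groupby("protein"):
            phospho_map[str(prot)] = set(int(p) for p in grp["position"])
    location_map: dict[str, list[str]] = {}
    if locations is not None:
        bad = set(locations["location"]) - LOCATION_VOCAB
        if bad:
            raise AnnotationError(f"unknown locations {sorted(bad)}")
        for prot, grp in locations.groupby("protein"):
            location_map[str(prot)] = sorted(set(grp["location"]))
    external_map: dict[str, dict[int, float]] = {}
    if external_disorder is not None:
        for prot, grp in external_disorder.groupby("protein"):
            external_map[str(prot)] = dict(
                zip(grp["position"].astype(int), grp["score"].astype(float))
            )

    rows = []
    for rec in records:
        profile = None
        if disorder == "builtin":
            profile = disorder_profile(
                rec.sequence, "builtin_heuristic", window_half_width
            )
        elif disorder == "external":
            profile = disorder_profile(
                rec.sequence,
                "external_scores",
                external_scores=external_map.get(rec.id, {}),
            )
        known = phospho_map.get(rec.id, set()) | rec.phosphosites
        for m in scan_sequence(rec.id, rec.sequence, pattern):
            if mode == "n-rule" and m.classification == FAIL:
                continue
            if profile is not None:
                dmean = float(profile[m.start - 1 : m.start - 1 + MOTIF_SPAN].mean())
                if min_disorder is not None and dmean < min_disorder:
                    continue
            else:
                dmean = float("nan")
            flank_abs = {m.start - 1 + p for p in (2, 7, 8, 9)}
            overlapping = sorted(known & flank_abs)
            rows.append(
                {
                    "protein": m.protein_id,
                    "start": m.start,
                    "window": m.window,
                    "anchor_class": m.anchor_class,
                    "numDE": m.numDE,
                    "numST": m.numST,
                    "numKR": m.numKR,
                    "N_intrinsic": m.N_intrinsic,
                    "N": m.N,
                    "class": m.classification,
                    "phospho_positions": _format_phospho_positions(
                        m.window, m.phospho_positions
                    ),
                    "disorder_mean": dmean,
                    "known_phosphosites": ",".join(str(p) for p in overlapping),
                    "locations": ";".join(
                        location_map.get(m.protein_id, list(rec.locations))
                    ),
                }
            )
    df = pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)
    return df.sort_values(["protein", "start"], kind="mergesort").reset_index(drop=True)
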