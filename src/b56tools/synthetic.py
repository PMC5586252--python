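"""Synthetic inputs for every pipeline stage.

Generates (a) background proteomes with B56 docking windows planted at
known positions and a ground-truth table, (b) tiled 16-mer/7-overlap phage
libraries with negative-binomial sequencing counts in which motif-bearing
tiles are enriched per bait and a small fraction of tiles is promiscuously
elevated in all baits, and (c) noisy 1:1 biolayer-interferometry traces.
All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binding import ASSOCIATION, DISSOCIATION, BindingTrace, bli_forward
from .errors import CapacityError, ParameterError
from .motif import (
    ANCHOR1_ALPHABET,
    ANCHOR4_ALPHABET,
    ANCHOR_MIN_N,
    MOTIF_SPAN,
    anchor_class,
)
from .sequences import STANDARD_AA, ProteinRecord

#: Residues that contribute nothing to the flank N score and never occur in
#: the consensus anchor alphabets — safe filler inside planted windows.
NEUTRAL_RESIDUES = "AGNQHPWY"

INTRINSIC = "intrinsic"
PHOSPHO_RESPONSIVE = "phospho_responsive"
DECOY = "decoy"

TRUTH_COLUMNS = ["protein", "start", "window", "target_class", "target_N"]


@dataclass(frozen=True)
class PlantSpec:
    """Specification for a family of planted windows.

    ``target_N`` is realised with single-letter flank residues (D/E for
    acidic, S for phosphorylatable, K for basic), so it must lie in
    [-4, 4].  Decoys conform to the consensus except for exactly one
    violated constraint (D instead of E at position 6).
    """

    target_class: str
    anchor1: str = "L"
    anchor4: str = "I"
    target_N: int = 2
    count: int = 1

    def __post_init__(self):
        if self.target_class not in (INTRINSIC, PHOSPHO_RESPONSIVE, DECOY):
            raise ParameterError(f"unknown target class {self.target_class!r}")
        if self.anchor1 not in ANCHOR1_ALPHABET:
            raise ParameterError("anchor1 must be one of L, M, F, I")
        if self.anchor4 not in ANCHOR4_ALPHABET:
            raise ParameterError("anchor4 must be one of I, L, V")
        if not -4 <= self.target_N <= 4:
            raise ParameterError("target_N must be in [-4, 4]")
        _, min_n = anchor_class(self.anchor1 + "AA" + self.anchor4 + "AEAAA")
        if self.target_class in (INTRINSIC, PHOSPHO_RESPONSIVE) and (
            self.target_N < min_n
        ):
            raise ParameterError(
                f"target_N={self.target_N} below anchor-class minimum {min_n}"
            )
        if self.count < 0:
            raise ParameterError("count must be >= 0")


@dataclass(frozen=True)
class CountSimConfig:
    """Parameters of the sequencing-count simulation."""

    tile_length: int = 16
    tile_overlap: int = 7
    enrichment_factor: float = 20.0
    dispersion: float = 5.0  # negative-binomial size; larger = less overdispersed
    promiscuous_fraction: float = 0.0
    background_mean: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.tile_overlap < self.tile_length:
            raise ParameterError("need 0 < tile_overlap < tile_length")
        if self.enrichment_factor < 1:
            raise ParameterError("enrichment_factor must be >= 1")
        if not 0 <= self.promiscuous_fraction < 1:
            raise ParameterError("promiscuous_fraction must be in [0, 1)")
        if self.dispersion <= 0 or self.background_mean <= 0:
            raise ParameterError("dispersion and background_mean must be positive")


def generate_background_proteome(
    n_proteins: int,
    length_range: tuple[int, int],
    aa_freqs: np.ndarray | None = None,
    seed: int = 0,
) -> list[ProteinRecord]:
    """Random proteome with i.i.d. residues drawn from ``aa_freqs``."""
    if n_proteins < 0:
        raise ParameterError("n_proteins must be >= 0")
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ParameterError("invalid length range")
    if aa_freqs is None:
        aa_freqs = np.full(20, 1.0 / 20.0)
    aa_freqs = np.asarray(aa_freqs, float)
    if aa_freqs.shape != (20,) or np.any(aa_freqs < 0) or not np.isclose(
        aa_freqs.sum(), 1.0
    ):
        raise ParameterError("aa_freqs must be a valid simplex over 20 residues")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list(STANDARD_AA))
    records = []
    for i in range(n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(alphabet, size=length, p=aa_freqs))
        records.append(ProteinRecord(id=f"synth{i:05d}", sequence=seq))
    return records


def _build_window(spec: PlantSpec, rng: np.random.Generator) -> str:
    """One 9-mer realising the spec's class and N, neutral elsewhere."""
    window = list(rng.choice(list(NEUTRAL_RESIDUES), size=MOTIF_SPAN))
    window[0] = spec.anchor1
    window[3] = spec.anchor4
    window[5] = "D" if spec.target_class == DECOY else "E"
    flanks = [1, 6, 7, 8]  # 0-based flank indices (positions 2, 7, 8, 9)
    rng.shuffle(flanks)
    n = spec.target_N
    if spec.target_class == PHOSPHO_RESPONSIVE:
        # all positive contributions from S/T so N_intrinsic stays at 0
        contributor = "S"
    else:
        contributor = "E"
    if n >= 0:
        for idx in flanks[:n]:
            window[idx] = contributor if n > 0 else window[idx]
    else:
        for idx in flanks[: -n]:
            window[idx] = "K"
    return "".join(window)


def plant_motifs(
    proteins: list[ProteinRecord],
    specs: list[PlantSpec],
    seed: int = 0,
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Overwrite non-overlapping stretches of the proteome with motif windows.

    Returns the modified records and a truth table (protein, 1-based start,
    window, target_class, target_N).  Each planted window is padded by one
    neutral residue on each side so the flank score of the planted frame is
    exactly the target.
    """
    rng = np.random.default_rng(seed)
    sequences = {r.id: list(r.sequence) for r in proteins}
    occupied: dict[str, list[tuple[int, int]]] = {r.id: [] for r in proteins}
    eligible = [r.id for r in proteins if len(r) >= MOTIF_SPAN + 2]
    if not eligible and any(s.count > 0 for s in specs):
        raise CapacityError("no protein long enough to hold a planted window")
    rows = []
    for spec in specs:
        for _ in range(spec.count):
            window = _build_window(spec, rng)
            placed = False
            for _ in range(200):
                pid = eligible[int(rng.integers(len(eligible)))]
                length = len(sequences[pid])
                start0 = int(rng.integers(1, length - MOTIF_SPAN))  # keep 1-res pad
                lo, hi = start0 - 1, start0 + MOTIF_SPAN + 1
                if any(a < hi and lo < b for a, b in occupied[pid]):
                    continue
                seq = sequences[pid]
                seq[start0 - 1] = "A"
                seq[start0 : start0 + MOTIF_SPAN] = list(window)
                if start0 + MOTIF_SPAN < length:
                    seq[start0 + MOTIF_SPAN] = "A"
                occupied[pid].append((lo, hi))
                rows.append(
                    {
                        "protein": pid,
                        "start": start0 + 1,
                        "window": window,
                        "target_class": spec.target_class,
                        "target_N": spec.target_N,
                    }
                )
                placed = True
                break
            if not placed:
                raise CapacityError("could not place planted window without overlap")
    out = [
        ProteinRecord(id=r.id, sequence="".join(sequences[r.id])) for r in proteins
    ]
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS).sort_values(
        ["protein", "start"]
    ).reset_index(drop=True)
    return out, truth


def tile_library(
    proteins: list[ProteinRecord],
    tile_length: int = 16,
    tile_overlap: int = 7,
    keep_short: bool = True,
) -> pd.DataFrame:
    """Tiled peptide library: (peptide, protein, 1-based start).

    Tiles advance by ``tile_length - tile_overlap``; a final tile anchored
    at ``length - tile_length + 1`` is added when needed so the C-terminus
    is always covered.  Proteins shorter than ``tile_length`` give a single
    full-sequence tile when ``keep_short`` (otherwise skipped).
    """
    if not 0 < tile_overlap < tile_length:
        raise ParameterError("need 0 < tile_overlap < tile_length")
    step = tile_length - tile_overlap
    rows = []
    for rec in proteins:
        length = len(rec)
        if length < tile_length:
            if keep_short:
                rows.append({"peptide": rec.sequence, "protein": rec.id, "start": 1})
            continue
        starts = list(range(0, length - tile_length + 1, step))
        if starts[-1] != length - tile_length:
            starts.append(length - tile_length)
        for s in starts:
            rows.append(
                {
                    "peptide": rec.sequence[s : s + tile_length],
                    "protein": rec.id,
                    "start": s + 1,
                }
            )
    return pd.DataFrame(rows, columns=["peptide", "protein", "start"])


def simulate_phage_counts(
    tiles: pd.DataFrame,
    truth: pd.DataFrame,
    baits: list[str],
    config: CountSimConfig,
) -> pd.DataFrame:
    """Sequencing counts per (peptide, bait) with planted enrichment.

    Background counts are negative-binomial (mean ``background_mean``, size
    ``dispersion``).  Tiles overlapping a non-decoy planted window have
    their mean multiplied by ``enrichment_factor`` in the bait assigned to
    that window (round-robin over baits by truth-table order).  A random
    ``promiscuous_fraction`` of tiles is elevated in every bait.
    """
    if not baits:
        raise ParameterError("need at least one bait")
    rng = np.random.default_rng(config.seed)
    tile_keys = list(zip(tiles["protein"], tiles["start"], tiles["peptide"]))

    motif_bait: dict[int, set[str]] = {}
    for row_i, (_, trow) in enumerate(truth.iterrows()):
        if trow["target_class"] == DECOY:
            continue
        bait = baits[row_i % len(baits)]
        w_lo, w_hi = int(trow["start"]), int(trow["start"]) + MOTIF_SPAN - 1
        for t_i, (pid, tstart, pep) in enumerate(tile_keys):
            if pid != trow["protein"]:
                continue
            t_lo, t_hi = int(tstart), int(tstart) + len(pep) - 1
            if t_lo <= w_lo and w_hi <= t_hi:  # tile fully contains the window
                motif_bait.setdefault(t_i, set()).add(bait)

    n_tiles = len(tile_keys)
    promiscuous = rng.random(n_tiles) < config.promiscuous_fraction
    r = config.dispersion
    rows = []
    for t_i, (pid, tstart, pep) in enumerate(tile_keys):
        for bait in baits:
            mu = config.background_mean
            if promiscuous[t_i] or bait in motif_bait.get(t_i, ()):
                mu *= config.enrichment_factor
            count = int(rng.negative_binomial(r, r / (r + mu)))
            rows.append(
                {
                    "peptide": pep,
                    "bait": bait,
                    "count": count,
                    "protein": pid,
                    "start": int(tstart),
                    "is_promiscuous": bool(promiscuous[t_i]),
                    "is_motif": bait in motif_bait.get(t_i, ()),
                }
            )
    return pd.DataFrame(rows)


def simulate_bli_traces(
    kon: float,
    koff: float,
    Rmax: float,
    concentrations: list[float],
    t_assoc: float = 400.0,
    t_dissoc: float = 300.0,
    n_points: int = 200,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[BindingTrace]:
    """Association + dissociation traces of the 1:1 model with Gaussian noise.

    Default phase durations follow a 400 s association / 300 s dissociation
    sensor program.
    """
    if any(c < 0 for c in concentrations):
        raise ParameterError("concentrations must be >= 0")
    rng = np.random.default_rng(seed)
    t_a = np.linspace(0.0, t_assoc, n_points)[1:]
    t_d = np.linspace(0.0, t_dissoc, n_points)[1:]
    traces = []
    for c in concentrations:
        assoc = np.asarray(bli_forward(kon, koff, Rmax, c, t_a), float)
        r_end = float(bli_forward(kon, koff, Rmax, c, t_assoc))
        dissoc = np.asarray(
            bli_forward(kon, koff, Rmax, c, t_d, DISSOCIATION, r_start=r_end), float
        )
        if noise_sd > 0:
            assoc = assoc + rng.normal(0, noise_sd, assoc.size)
            dissoc = dissoc + rng.normal(0, noise_sd, dissoc.size)
        traces.append(BindingTrace(t_a, assoc, c, ASSOCIATION))
        traces.append(BindingTrace(t_d, dissoc, c, DISSOCIATION))
    return traces
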