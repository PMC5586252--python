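"""Synthetic-data generators: determinism, tiling, planting, counts, traces."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from b56tools.errors import CapacityError, ParameterError
from b56tools.motif import scan_sequence
from b56tools.synthetic import (
    CountSimConfig,
    PlantSpec,
    generate_background_proteome,
    plant_motifs,
    simulate_bli_traces,
    simulate_phage_counts,
    tile_library,
)


def test_proteome_empty_and_deterministic():
    assert generate_background_proteome(0, (10, 20), seed=1) == []
    a = generate_background_proteome(5, (50, 50), seed=7)
    b = generate_background_proteome(5, (50, 50), seed=7)
    assert [r.sequence for r in a] == [r.sequence for r in b]
    assert all(len(r) == 50 for r in a)


def test_proteome_residue_frequencies_uniform():
    records = generate_background_proteome(1000, (100, 300), seed=3)
    joined = "".join(r.sequence for r in records)
    n = len(joined)
    se = np.sqrt(0.05 * 0.95 / n)
    for aa in "ACDEFGHIKLMNPQRSTVWY":
        freq = joined.count(aa) / n
        assert abs(freq - 0.05) < 3 * se


def test_proteome_invalid_simplex():
    with pytest.raises(ParameterError):
        generate_background_proteome(2, (10, 20), aa_freqs=np.ones(20), seed=0)


def test_tiling_step_arithmetic():
    from b56tools.sequences import ProteinRecord

    tiles = tile_library([ProteinRecord("p", "A" * 25)], 16, 7)
    assert list(tiles["start"]) == [1, 10]
    one = tile_library([ProteinRecord("p", "A" * 16)], 16, 7)
    assert len(one) == 1 and one["start"].iloc[0] == 1


def test_tiling_reconstructs_protein():
    proteome = generate_background_proteome(10, (40, 90), seed=5)
    tiles = tile_library(proteome, 16, 7)
    for rec in proteome:
        sub = tiles[tiles["protein"] == rec.id].sort_values("start")
        # coverage: union of [start, start+15] is [1, len]
        covered = set()
        for _, row in sub.iterrows():
            covered.update(range(row["start"], row["start"] + len(row["peptide"])))
        assert covered == set(range(1, len(rec) + 1))
        # overlap-trimmed concatenation reconstructs the sequence
        rebuilt = ""
        for _, row in sub.iterrows():
            start0 = row["start"] - 1
            rebuilt = rebuilt[:start0] + row["peptide"]
        assert rebuilt == rec.sequence


def test_plant_truth_table_fidelity():
    proteome = generate_background_proteome(60, (60, 120), seed=9)
    specs = [
        PlantSpec("intrinsic", "L", "I", 2, 20),
        PlantSpec("phospho_responsive", "M", "I", 2, 10),
        PlantSpec("decoy", "L", "I", 2, 10),
    ]
    planted, truth = plant_motifs(proteome, specs, seed=10)
    seqs = {r.id: r.sequence for r in planted}
    assert len(truth) == 40
    for _, row in truth.iterrows():
        window = seqs[row["protein"]][row["start"] - 1 : row["start"] + 8]
        assert window == row["window"]  # retrievable verbatim
        matches = {
            m.start: m for m in scan_sequence(row["protein"], seqs[row["protein"]])
        }
        if row["target_class"] == "decoy":
            assert row["start"] not in matches  # D at position 6 rejected
        else:
            m = matches[row["start"]]
            assert m.N == row["target_N"]
            assert m.classification == row["target_class"]


def test_plant_capacity_error():
    proteome = generate_background_proteome(1, (30, 30), seed=0)
    with pytest.raises(CapacityError):
        plant_motifs(proteome, [PlantSpec("intrinsic", count=10)], seed=0)


def test_plant_spec_validation():
    with pytest.raises(ParameterError):
        PlantSpec("intrinsic", "A", "I", 2, 1)
    with pytest.raises(ParameterError):
        PlantSpec("intrinsic", "M", "V", 2, 1)  # both_similar needs N >= 4
    with pytest.raises(ParameterError):
        PlantSpec("intrinsic", "L", "I", 7, 1)


def _counts_setup(enrichment, promiscuous=0.0, seed=42, n_proteins=60):
    proteome = generate_background_proteome(n_proteins, (60, 120), seed=seed)
    planted, truth = plant_motifs(
        proteome, [PlantSpec("intrinsic", "L", "I", 2, 30)], seed=seed + 1
    )
    tiles = tile_library(planted, 16, 7)
    cfg = CountSimConfig(
        enrichment_factor=enrichment,
        dispersion=20.0,
        promiscuous_fraction=promiscuous,
        background_mean=5.0,
        seed=seed + 2,
    )
    return simulate_phage_counts(tiles, truth, ["b1", "b2"], cfg)


def test_counts_null_case_indistinguishable():
    counts = _counts_setup(enrichment=1.0)
    motif = counts[counts["is_motif"]]["count"]
    background = counts[~counts["is_motif"] & ~counts["is_promiscuous"]]["count"]
    assert len(motif) >= 20
    p = stats.mannwhitneyu(motif, background).pvalue
    assert p > 0.01


def test_counts_enrichment_separates_motif_tiles():
    counts = _counts_setup(enrichment=20.0)
    background = counts[~counts["is_motif"] & ~counts["is_promiscuous"]]["count"]
    q95 = np.quantile(background, 0.95)
    motif = counts[counts["is_motif"]]["count"]
    assert (motif > q95).mean() >= 0.90


def test_counts_promiscuous_fraction():
    counts = _counts_setup(enrichment=20.0, promiscuous=0.05, n_proteins=120)
    per_tile = counts.groupby(["protein", "start"])["is_promiscuous"].first()
    n_tiles = len(per_tile)
    n_prom = int(per_tile.sum())
    expect = 0.05 * n_tiles
    sigma = np.sqrt(n_tiles * 0.05 * 0.95)
    assert abs(n_prom - expect) <= 3 * sigma
    # promiscuous tiles elevated in every bait
    prom = counts[counts["is_promiscuous"]]
    back = counts[~counts["is_promiscuous"] & ~counts["is_motif"]]
    for bait in ("b1", "b2"):
        assert (
            prom[prom["bait"] == bait]["count"].mean()
            > 3 * back[back["bait"] == bait]["count"].mean()
        )


def test_counts_negative_binomial_marginals():
    cfg = CountSimConfig(dispersion=5.0, background_mean=4.0, seed=3,
                         enrichment_factor=1.0)
    proteome = generate_background_proteome(700, (100, 200), seed=3)
    tiles = tile_library(proteome, 16, 7)
    truth = pd.DataFrame(columns=["protein", "start", "window", "target_class",
                                  "target_N"])
    counts = simulate_phage_counts(tiles, truth, ["b"], cfg)["count"]
    assert len(counts) >= 10_000
    mu, r = 4.0, 5.0
    var = mu + mu**2 / r
    assert abs(counts.mean() - mu) < 4 * np.sqrt(var / len(counts))
    assert abs(counts.var() / var - 1) < 0.1


def test_bli_traces_closed_forms():
    kon, koff, rmax = 1e5, 1e-2, 2.0
    traces = simulate_bli_traces(kon, koff, rmax, [0.0, 1e-7], t_assoc=1e5,
                                 noise_sd=0.0)
    zero_assoc = [t for t in traces if t.concentration == 0.0][0]
    assert np.allclose(zero_assoc.response, 0.0)
    # C = KD: association plateau at Rmax/2
    kd_trace = [
        t for t in traces if t.concentration == 1e-7 and t.phase == "association"
    ][0]
    assert np.isclose(kd_trace.response[-1], rmax / 2, rtol=1e-3)
    # determinism with noise
    a = simulate_bli_traces(kon, koff, rmax, [1e-6], noise_sd=0.05, seed=4)
    b = simulate_bli_traces(kon, koff, rmax, [1e-6], noise_sd=0.05, seed=4)
    assert np.array_equal(a[0].response, b[0].response)


def test_bli_traces_negative_concentration_rejected():
    with pytest.raises(ParameterError):
        simulate_bli_traces(1e5, 1e-2, 1.0, [-1e-6])
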