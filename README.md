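# b56tools

Tools for discovering, scoring and modelling the short linear motifs
(SLiMs) through which PP2A holoenzymes carrying a B56 (B′) regulatory
subunit dock their substrates.  It is aimed at people analysing proteomic
peptide phage display (ProP-PD) selections against B56-family baits, and at
anyone who wants to scan a proteome for intrinsic or
phosphorylation-responsive B56 docking sites.

## The motif and its scoring

B56 docking sites occupy a nine-position frame

```
position    1   2   3   4   5   6   7   8   9
consensus [LMFI] x   x [ILV] x   E   x   x   x
```

Positions 1, 4 and 6 anchor the peptide in the B56 groove; the glutamate at
position 6 is strictly required (neither D nor phospho-S/T substitutes for
it).  Positions 2, 7, 8 and 9 — the *flanks* — face a basic pocket: acidic
residues and phosphorylated S/T there strengthen binding, K/R weaken it.
The flank balance is summarised by

```
N = numDE + numST − numKR        (over positions 2, 7, 8, 9)
```

with the phosphorylation-independent part `N_intrinsic = numDE − numKR`.
The minimum N needed for binding depends on the anchors: 1 when positions 1
and 4 carry the best residues (L, I), 2 when one is replaced by a similar
residue (M/F/I at 1, L/V at 4), 4 when both are.  A window passing on
`N_intrinsic` alone is an **intrinsic** binder; one that reaches its
minimum only with the S/T contribution is **phosphorylation-responsive** —
it binds once those flanks are phosphorylated, e.g. by Plk1, whose
consensus (S/T with D/E/N at −2) is also predicted here.

The package implements, as a library plus a `b56tools` command line:

- `synthetic` — proteomes with planted docking windows and a ground-truth
  table, tiled 16-mer/7-overlap phage libraries with negative-binomial
  sequencing counts, noisy 1:1 binding traces;
- `propd` — count cutoffs, promiscuous-ligand removal, consensus rescue of
  below-cutoff peptides, peptide-to-proteome mapping, Venn-region overlaps;
- `discovery` — SLiMFinder-style degenerate template enumeration with
  binomial significance, and expansion into a nine-position consensus;
- `motif` / `scan` — window scanning, N-score classification, Plk1 site
  prediction, a FoldIndex-form disorder heuristic, and annotated
  proteome-wide candidate tables;
- `binding` — global 1:1 biolayer-interferometry kinetic fits, single-site
  Wiseman ITC isotherm fits, and a two-ligand competitive-displacement
  equilibrium solver.

## Worked example

```python
>>> from b56tools import scan_sequence, predict_plk1_sites
>>> m = scan_sequence("CEP350", "RGSLESIAEHVDAS")[0]
>>> m.window, m.numDE, m.anchor_class, m.classification
('LESIAEHVD', 2, 'best_best', 'intrinsic')
```

The scanner finds one consensus window in the CEP350 context peptide,
anchored L…I…E, with two acidic flank residues (E at position 2, D at 9).
Since `N_intrinsic = 2` exceeds the best-anchor minimum of 1, CEP350 is an
intrinsic B56 binder.  A phosphorylation-responsive case:

```python
>>> m = scan_sequence("CEP295", "SSSLSQVDESERFQ")[0]
>>> m.window, m.N_intrinsic, m.N, m.min_N, m.phospho_positions
('LSQVDESER', 0, 2, 2, (2, 7))
```

Here the L/V anchors demand N ≥ 2, which is reached only by counting the
two S residues at flank positions 2 and 7 — CEP295 binds B56 upon their
phosphorylation.  On Cyk4/RACGAP1, the Plk1 −2 rule pinpoints the
activating site:

```python
>>> [s.position for s in predict_plk1_sites("NKRLSTIDESGSIL", offset=140)]
[149]
```

The full synthetic pipeline (simulate → filter → discover → scan → report)
runs with `b56tools run --run-dir run`, and `b56tools check-examples` prints
the expected-versus-computed table for every bundled worked example.

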