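# Methods

## Consensus scanning and the N score

A candidate window is any nine-residue frame whose position 1 is in
{L,M,F,I}, position 4 in {I,L,V} and position 6 exactly E.  All overlapping
matches are reported; consumers who want one site per locus can keep the
max-N window.  Windows that would extend past the C-terminus are not
emitted (the frame needs all nine residues), and a window containing a
nonstandard residue code (B, J, O, U, X, Z) is skipped with a log message
without invalidating the rest of the protein.

Phosphorylation marks are written `pS`/`pT` in input sequences and parsed
into (residue, flag) pairs.  A flagged residue satisfies only wildcard
positions: in particular pS/pT at position 6 never substitutes for the
required glutamate, mirroring the experimental observation that neither D
nor phospho-S/T can replace E there.  At flank positions the flag is
recorded but the residue still counts as S/T.

Flank counting is restricted to motif positions 2, 7, 8 and 9:
`N = numDE + numST − numKR`, `N_intrinsic = numDE − numKR`.  Each flank
residue contributes to exactly one counter, so N is always in [−4, 4].
Anchor classes set the threshold: best/best (L,I) → min N = 1, one similar
residue → 2, both similar → 4.  "Similar" is {M,F,I} at position 1 and
{L,V} at position 4, i.e. the consensus alphabets minus the best residue.
Classification is intrinsic if `N_intrinsic ≥ min N`, else
phosphorylation-responsive if `N ≥ min N` (reporting every flank S/T
position as a potential activating site — including position 9, which some
published example tables omit without stated reason), else fail.

The Plk1 predictor implements the kinase's −2 requirement only: every S/T
whose residue two positions upstream is D, E or N.  The first two residues
of a sequence have no −2 context and are never called.  User-supplied known
phosphosites are passed through as annotations, not predictions.

## Disorder heuristic

Docking motifs live in intrinsically disordered regions, so candidate rows
carry a mean-disorder column.  The builtin predictor is a windowed
charge–hydropathy score of FoldIndex form, `2.785·⟨H⟩ − |⟨q⟩| − 1.151`,
with Kyte–Doolittle hydropathy rescaled to [0, 1], net charge ±1 for
D/E/K/R, a 21-residue window (half-width 10, truncated at the ends), and
the sign flipped so positive = disordered.  It is a coarse heuristic; a
per-residue score table from any external predictor can be plugged in
instead (`disorder="external"`).  By default the score is annotation-only;
a hard cutoff is applied only when `min_disorder` is set (0.0 is a natural
choice on the sign-flipped scale), since it is genuinely open whether a
hard disorder filter or mere annotation is the right default for a global
search.

## ProP-PD count processing

The cutoff retains peptides with count strictly greater than the cutoff by
default (`mode="gt"`): with at least one read per observed peptide, an
inclusive cutoff of 1 would be vacuous.  Both interpretations are exposed
(`gt`/`ge`).  Promiscuity is judged within the supplied baits — a peptide
passing the cutoff in more than `max_bait_fraction` (default 0.5) of baits
is removed as a background binder; historical display datasets are not
bundled, so cross-study frequency is out of scope.  Below-cutoff peptides
containing a consensus window are rescued into the ligand set with
provenance `rescued`, disjoint from `above_cutoff` by construction.
Cutoff and promiscuity filtering commute, which the suite checks on random
tables.

## Motif discovery

Templates have ≤3 defined positions over a span of ≤9 — the shape of the
docking consensus, which has exactly three strong positions — with each
defined slot a residue singleton or the hydrophobic class [LMFIV].
Support is exact containment counting.  Significance is the binomial upper
tail of the support at the mean per-peptide occurrence probability
`q = 1 − (1 − p_match)^(L − span + 1)` (positions treated as independent —
an approximation that slightly understates q for self-overlapping
templates), Bonferroni-corrected by the size of the full enumerable
template space (262,857 for three defined positions).  Bonferroni is
deliberately conservative; ranking ties break by higher support, then
pattern string.

Consensus expansion aligns peptides on their first seed occurrence and
admits, at each of the nine frame positions, residues with observed/
background frequency ratio above `inclusion_threshold` (default 3.0, with
a minimum count of 2 to suppress single-observation noise).  Position 6 is
forced to {E} and positions 1/4 are intersected with their anchor
alphabets (falling back to the most frequent anchor-alphabet residue when
the intersection is empty), so the emitted pattern is always a valid
docking pattern.

## Synthetic data

The generator reproduces the study's library design: 16-mer tiles with
7-residue overlap (step 9), plus a final C-terminus-anchored tile so
coverage is complete; proteins shorter than one tile yield a single
full-sequence tile.  Planted windows use single-letter flank contributors —
D/E for intrinsic targets, S for phosphorylation-responsive ones (keeping
`N_intrinsic` at 0), K for negative N — and neutral filler (A,G,N,Q,H,P,W,Y)
elsewhere, with a one-residue neutral pad on each side; this construction
guarantees the planted frame scores exactly its target N and creates no
accidental overlapping consensus match.  Decoys violate exactly one
constraint (D at position 6) so any rejection is attributable.

Sequencing counts are negative-binomial (mean 2 reads background,
dispersion 5), the standard overdispersed model for sequencing data; no
distributional detail is available to calibrate against, so these are
nominal sparse-display values.  Motif-bearing tiles have their mean
multiplied by the enrichment factor (default 20) in the bait assigned
round-robin to their planted window; a configurable fraction of tiles is
elevated in every bait to emulate promiscuous background binders.  Phage
amplification cycles and PCR/barcode errors are not modelled, so passing
tests show correct processing of overdispersed count tables, not
robustness to those artefacts.

BLI traces follow the noiseless 1:1 forms below plus i.i.d. Gaussian noise;
default phase durations are 400 s association / 300 s dissociation.

## Binding models

Association: `R(t) = Rmax·C/(C+KD)·(1 − e^{−(kon·C+koff)t})`; dissociation:
exponential decay with rate koff from the association end-point.  The fit
is global across concentrations with shared (kon, koff, Rmax), in log space
(positivity by construction), multi-started over a 3×3 log-spaced
(kon, koff) grid; a zero-concentration trace is used as subtracted blank;
KD is derived as koff/kon, never free.  Mass-transport limitation and
baseline drift are not modelled.

ITC uses the single-site Wiseman isotherm with the standard
overfilled-cell dilution corrections; parameters (Ka, ΔH, n) are fitted by
least squares with multi-start over Ka.  For weak binders the c-value
(n·Ka·[cell]) falls below ~10 and n and Ka become poorly separable: the
fitter warns when c leaves [1, 1000], and `fix_n=1` holds the
stoichiometry at a known value, the standard low-c practice.  The seeded
noisy-recovery tests use 5% proportional per-injection noise on a
25×10 µl titration of a 7.2 µM binder into a 30 µM cell at 1 mM syringe
concentration (c ≈ 4), with n fixed at 1; with n floating at that c, Ka is
not reliably recoverable at that noise level.

The competition model solves the two-ligand one-site equilibrium by
bracketed root-finding (Brent) on free receptor in [0, total receptor],
with tolerances tight enough that mass balance closes to 1e−9 relative;
the reporter bound fraction is `x/(KD_reporter + x)`.  The curve is
continuous and monotone non-increasing in competitor concentration.

## Pipeline and reproducibility

`b56tools run` executes simulate → count simulation → ProP-PD filtering →
discovery → scan, persisting each stage's TSV artifacts under
`inputs/`, `intermediate/` and `results/` with a run log; identical
configuration and seed give byte-identical outputs.  Default problem sizes
(200 proteins of 80–200 residues, 30 planted windows, two baits) complete
in seconds while leaving enough planted signal for meaningful
recall/precision reporting; the heavier validation suites use 500 proteins
with 50 planted windows and 100-seed discovery replicates.

## Known limitations

- The disorder heuristic is far cruder than modern predictors; use
  external scores for serious disorder filtering.
- The discovery background model assumes positional independence and a
  fixed residue background; compositional bias in real display data will
  inflate significance.
- Binding models are strictly 1:1/single-site; heterogeneous-ligand or 2:1
  schemes are out of scope.
- Flank S/T at position 9 is always reported as a potential
  phosphorylation-responsive site, although published example tables are
  inconsistent about it.
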