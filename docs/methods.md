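# Methods

This note documents the models, conventions and numerical choices behind
`polypro`, and what the synthetic-data experiments do and do not establish.

## Motif definition and coordinates

A polyproline motif is a **maximal** run of n ≥ 2 consecutive prolines with
flanking context X₋₂X₋₁–nP–X₊₁. A run of k prolines is one motif, never
k−1 overlapping dimers (the overlapping-dimer convention is used only
inside the Markov word statistics, where it is the natural counting unit).
All coordinates, in memory and in every TSV, are 1-based inclusive. The
motif **anchor** used by positional analyses is the first proline of the
run: the stall happens at the prolines, not at the upstream context.
Flanks that fall outside the sequence are recorded as missing.

## Strength classification

Stalling strength (STRONG > MEDIUM > WEAK > NONE, compared by rank only) is
predicted from a rule table with two layers:

1. **Flank effect classes** — each standard residue has an effect class
   (strong/medium/weak) at each of X₋₂, X₋₁, X₊₁. The packaged table
   (`data/stalling_rules_synthetic.yaml`) is a synthetic reconstruction
   from published arrest-peptide hierarchies: PPP, D/PP/D, PPW, APP,
   G/PP/G and PPN mark strong contexts; L/PP/L, CPP and HPP weak ones;
   H, K, Q, R, W at X₋₂ pronounce the arrest while C, G, L, S, T attenuate
   it; every other context defaults to weak arrest. It is not a
   transcription of any single experimental table, and users with their own
   calibration can supply a replacement file with the same schema.
2. **Combination rules** — a total lookup over (run-length category, three
   effect classes): n ≥ 3 is always STRONG (the proline triplet is itself a
   strong arrest element); for n = 2 the class is the stronger of the
   X₋₁/X₊₁ effects, promoted one rank by a strong-effect X₋₂ and demoted
   one rank by a weak-effect X₋₂, clamped to [WEAK, STRONG].

Missing flanks take the *neutral* class for their position: weak-effect at
X₋₁/X₊₁ (contributes nothing to the arrest), medium-effect at X₋₂ (whose
weak class is an active attenuator, not a neutral value). Excluding
terminal motifs instead would silently bias the N-terminal ramp analysis;
a flag on `classify_motif` callers can drop them if desired. Motifs with a
non-standard flank letter are reported as ambiguous: they stay in raw
occurrence counts but are excluded from every strength-stratified analysis.

## Shuffle null

Each sequence is permuted uniformly (Fisher–Yates contract via the PCG64
generator). Streams are split counter-style: replicate r of sequence i
draws from `SeedSequence(root_seed, spawn_key=(r, i))`, so any subset of
the computation is reproducible from the root seed alone.

The proteome fold change is FC = N_obs / N_exp with N_exp the mean total
count over R = 1,000 replicates (counts are summed across sequences within
a replicate before any ratio is formed; per-sequence ratios would divide by
zero for motif-free sequences). Empirical p-values use the pseudocount
form (1 + k)/(R + 1), which cannot return 0.

**Two-population comparisons** (core vs accessory, N-terminal vs the rest)
do *not* compare aggregate ratio vectors: each such vector is tight around
its own observed count, whose sampling noise a rank-sum test then misreads
as signal, making the comparison anticonservative by construction. Instead
each protein (or segment) gets one fold change — its observed count divided
by its mean shuffled count — and the two per-sequence populations are
compared by the Mann–Whitney–Wilcoxon test. Under equal motif densities
these populations are exchangeable, so the test is calibrated; sequences
whose null expectation is zero are dropped. For the N-terminal ramp the
"rest" of each protein is additionally cut into split-length tiles
(complete tiles only) so both populations share one length distribution —
rank-sum between count ratios of different discreteness is not calibrated
even at equal densities.

## Markov M0 null

The zero-order model treats letters as i.i.d. with the composition of the
analysed sequence set itself (estimated per test: whole proteome for
proteome tests, the extracted segments for region tests). For the
overlapping word PP in one sequence of length L with proline frequency p:

- E[N] = (L−1)p²;
- Var[N] = (L−1)(p²−p⁴) + 2(L−2)(p³−p⁴), since adjacent indicator pairs
  share one letter (Cov = p³−p⁴) and non-adjacent pairs are independent;
- totals over sequences add (independence).

Observed counts on the Markov side use the same overlapping-word semantics
(a run of k prolines counts k−1 occurrences), which keeps the null fold
change centred on 1; maximal-run counts against a word expectation would
sit at ≈(1−p)² under the null. Motif-anchor counts inside regions are kept
as a diagnostic. p-values come from the exact count distribution — a
dynamic programme over (position, previous-letter-is-P, count), convolved
across sequences — when the total length is at most 2,000, and otherwise
from a Gaussian approximation with continuity correction; the branch used
is always reported. Only the homopolymer word PP is supported; the test
refuses other patterns rather than silently mis-modelling overlap.

## Pan-proteome partition

A protein is core iff its orthologous group has at least one member in
every strain of the analysed set (paralog counts are irrelevant); members
of other groups and unassigned proteins are accessory. The partition is
exhaustive and exclusive, and enlarging the strain set can only shrink the
core. Strains are compared independently by default.

## Evolution of the stalling effect

**Regions.** Each motif's proline stretch is projected through the gap
structure of its group's alignment onto columns; overlapping column
intervals from different sequences merge transitively into one region
(split or shifted stretches across orthologs must land in one comparable
unit). A leaf's state is the maximal-rank strength among its motifs
overlapping the region (≥1 shared column suffices; stretches fragmented by
gaps are flagged), else NONE.

**Model.** States evolve under a symmetric 4-state Mk model with a single
rate α: p_same(t) = 1/4 + 3/4·e^(−4αt). The symmetric model is the minimal
assumption — nothing in the data identifies ordered-state rates from
single-region observations. α is estimated per region by maximising the
pruning-algorithm likelihood (uniform root prior) over [10⁻⁶, 100]: the
likelihood flattens as α → ∞ (every transition matrix tends to uniform), so
a 25-point log-spaced grid brackets the optimum before bounded Brent
refinement; without the grid the bounded search can stall on the plateau.

**Reconstruction.** Marginal posteriors come from the standard two-pass
(inside/outside) algorithm; each internal node takes the argmax state, with
exact ties (within 10⁻¹²) broken toward the weaker state — conservative
against inferring gain events. Both passes are validated against exhaustive
enumeration of all joint internal assignments on small trees (≤ 10⁻⁹).

**Events and PSEC.** On every branch (terminal branches included), a rank
increase parent→child is a gain, a decrease a loss. PSEC = B_g/B_cg −
B_l/B_cl, where a branch admits a gain iff its parent is not already STRONG
and a loss iff its parent is not NONE; a branch may appear in both
denominators, and a zero denominator contributes 0 so saturated trees stay
defined. PSEC ∈ [−1, 1] by construction.

**Midpoint rooting.** Implemented directly (not delegated) so the contract
is explicit: the diameter pair is chosen with lexicographic tie-breaking on
leaf labels, the root splits the midpoint edge preserving all pairwise leaf
distances, and an all-zero-length tree is rooted at the seed node and
flagged. Trees are consumed with their branch lengths as given; no
re-estimation.

## Positional conventions

Offset 0 is the anchor residue itself (domain start/end or TMH start);
negative offsets are upstream. Profiles normalise raw counts by the number
of anchor instances whose sequence covers each offset and smooth over a
3-point window (edges average the available points). Inter-domain linkers
span [e+1, s−1] between consecutive domains and are extended downstream to
a minimum length of 5, clipped at the protein end. TMH sites I–IV are
closed windows (−17..−1, +23..+32, +49..+59, +77..+87) relative to each TMH
start; instances extending beyond the protein are dropped, and an instance
is located "in TMH" when its midpoint residue lies inside any annotated
helix — robust to partial overlap. The transmembrane/soluble proportion
test is chi-squared without continuity correction (counts are large in any
realistic use). The typical 21-residue TMH length is a plotting annotation
only, never an input to computation.

## Expression

Translation efficiency is the exact ratio abundance/transcription over the
genes present in both tables (intersection semantics). Motif density is
motifs per 100 residues — length normalisation prevents protein length from
confounding the correlation; a raw-count mode exists. Spearman correlation
is computed on untransformed values (rank-invariant); log scales appear
only in reports. Profiling concordance is the fraction of genes at or above
an asymmetry-score threshold carrying at least one medium-or-strong motif;
genes absent from the motif table count as lacking motifs.

## Synthetic data: what it emulates and what it does not

Generators draw i.i.d. sequences from a bacterial amino-acid composition
(f_P ≈ 0.044) with lognormal lengths (median ≈ 270 residues, floor 60) and
plant motifs by overwriting letters (lengths and the length distribution
stay intact; composition shifts slightly and is visible to the nulls —
planted proteomes legitimately show fold changes above 1). Planted
depletion relocates a fraction q of proline stretches to isolated positions
in the same sequence, preserving the letter multiset exactly so the shuffle
expectation is unchanged and the expected fold change is 1−q. Pan-genomes
place core groups in all strains and accessory groups in random subsets;
trees are Yule (a single birth rate suffices for reconstruction tests);
state histories are simulated as a continuous-time jump process with an
optional directional bias (gain-rate multiplier, 0 = loss-only); expression
values are linked to motif-density ranks through a Gaussian copula at the
Pearson equivalent 2·sin(πρ_s/6) of the target Spearman ρ_s.

Synthetic sequences have no homology, domain grammar, secondary structure
or codon-level signal, and synthetic orthologs are generated ungapped with
point substitutions only. Passing tests therefore establishes that the
statistics are calibrated and that planted effects of realistic size are
recovered — not that real proteomes will show any particular effect.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale, chosen so the full suite
stays in the low minutes: proteomes of 40–5,000 sequences, 100 shuffle
replicates in most checks (1,000 where the default matters), 100–500
simulated trees of 8–16 leaves with the state rate set to ≈2 expected
events per tree (the regime where gain/loss direction is identifiable; a
saturated loss-only process drives most leaves to NONE and a symmetric
model then reads the survivors as gains), and n = 1,743 for the planted
Spearman recovery at ρ = −0.105 (±0.05 tolerance). Every random quantity
descends from one root seed through `SeedSequence` spawn keys; identical
seeds give byte-identical outputs.

## Known limitations

- The packaged rule table is a literature-informed reconstruction, not a
  fitted model; absolute strength-class proportions depend on it.
- The Markov machinery is specialised to the PP word (order 0); longer
  proline runs enter only through run-length categories.
- Marginal ML reconstruction under a symmetric Mk model cannot infer event
  direction on a star-like history where most leaves changed state; PSEC
  sign recovery degrades as the process saturates.
- The MWW comparison of per-sequence fold changes assumes sequences are
  exchangeable within each population; strong length or composition
  stratification between populations would call for a stratified test.
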