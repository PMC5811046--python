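# polypro

Evolutionary and positional analysis of polyproline ribosome-stalling
motifs in bacterial proteomes.

Translation of two or more consecutive prolines stalls the ribosome; the
elongation factor EF-P alleviates but does not eliminate the pause. A
polyproline motif is a maximal run of prolines with its flanking context,
X₋₂X₋₁–nP–X₊₁ (n ≥ 2), and its predicted arrest strength (strong, medium,
weak) follows from the run length and flank-residue rules. This package
implements the full analysis chain used to study how such motifs evolve in
a bacterial pan-proteome, and a synthetic-data module that generates every
input with recorded ground truth, so the whole pipeline is testable without
external downloads. Intended users are computational biologists studying
translational regulation or protein-level sequence selection.

## What it computes

- **Motif census** — scanning (`scan_motifs`, `scan_proteome`) and strength
  classification from a packaged rule table (`classify_motif`).
- **Enrichment/depletion** against two nulls: composition-preserving
  shuffling with the fold change `FC = N_obs / N_exp` (N_exp = mean count
  over 1,000 shuffled replicates), and a zero-order Markov model M0 for the
  overlapping diproline word, with E[N] = (L−1)·f_P² per sequence, a closed
  form variance for the self-overlapping word, an exact dynamic-programming
  count distribution for short inputs and a Gaussian tail otherwise.
- **Pan-proteome comparison** — core (orthologous group present in every
  strain) vs accessory occurrence, per-protein shuffle-normalised fold
  changes compared by Mann–Whitney–Wilcoxon test.
- **Evolution of the stalling effect** — motif-bearing alignment regions,
  midpoint rooting, maximum-likelihood ancestral states under a symmetric
  4-state Mk model (p_same(t) = 1/4 + 3/4·e^(−4αt)), gain/loss events, and
  the propensity of stalling-effect change
  `PSEC = ΣB_g/ΣB_cg − ΣB_l/ΣB_cl`,
  where B_g/B_l are branch lengths carrying gains/losses and B_cg/B_cl the
  branch lengths on which a gain/loss was possible. PSEC < 0 means the
  stalling effect tends to be lost.
- **Positional analyses** — N-terminal ramp (first 50 residues vs the
  rest), domain/linker enrichment, boundary profiles (3-residue smoothing),
  TMH-relative sites I–IV (−17..−1, +23..+32, +49..+59, +77..+87 from the
  TMH start) split by TMH/non-TMH location, and the transmembrane vs
  soluble motif-bearing proportion (chi-squared).
- **Expression** — translation efficiency TEᵢ = abundanceᵢ/transcriptionᵢ,
  Spearman correlation with motif density (motifs per 100 residues), and
  concordance of predicted strengths with ribosome-profiling asymmetry
  scores.

## Worked example

The `analysis/` scripts run the whole chain on synthetic data
(`01_simulate_data.py` writes FASTAs, orthology, annotations and expression
tables under `results/synthetic_data/`; later scripts consume them):

```bash
python analysis/01_simulate_data.py --seed 0
python analysis/04_pangenome.py
python analysis/05_evolution_psec.py
```

`04_pangenome.py` recovers the generator's core/accessory labels exactly and
detects the planted 0.8× core motif density:

```
agreement with generator ground truth: 1.0000
strain stratum  n_core_obs  n_accessory_obs  fc_core  fc_accessory  p_ranksum
   S00     ALL        1298              620     2.41          2.78   0.000962
   S01     ALL         852              418     1.86          2.34   2.75e-05
```

(`fc_*` are mean per-protein fold changes against each protein's own
shuffle null; both exceed 1 because the generator plants motifs on top of
the i.i.d. background, and core sits below accessory as planted.)

`05_evolution_psec.py` contrasts an unbiased stalling-state history with a
loss-biased one across 100 simulated orthologous groups:

```
unbiased:    99 regions, 121 gains / 113 losses, PSEC>0 36.4% vs PSEC<0 63.6%
loss_biased: 99 regions,  50 gains / 130 losses, PSEC>0 18.6% vs PSEC<0 81.4% (chi2 p=5.78e-09)
```

The loss-biased cohort — the synthetic analogue of a conserved core
proteome shedding stalling motifs — shows the strong negative-PSEC excess.

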