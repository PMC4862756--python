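# hybridnet

Comparative regulatory genomics of the eukaryotic G1/S cell-cycle network.

Animals drive the G1/S transition with the E2F/DP–pRb module; fungi use
SBF/MBF–Whi5, whose DNA-binding domain is a virally derived KilA-N domain
with no detectable homology to E2F. Basal fungi (chytrids such as
*Spizellomyces punctatus*) carry **both** modules — a *hybrid* network —
and the two transcription-factor families bind overlapping DNA sites
(e.g. the E2F site GCGCGAAA is also bound by yeast SBF). `hybridnet`
packages the analyses behind these observations as a tested, desk-scale
pipeline:

- **`hybridnet.simulate`** — synthetic inputs for every stage: universal
  probe arrays built from de Bruijn sequences (every 10-mer exactly once),
  probe intensities with a planted PWM signal and lognormal noise, toy
  proteomes from two unrelated family profiles, promoters with planted
  binding sites, and trees with multi-metric branch supports.
- **`hybridnet.escore` / `hybridnet.motifs`** — rank-based 8-mer
  enrichment scores (E-scores) from universal protein-binding-microarray
  (PBM) intensities; significance calling at E ≥ 0.37; classification of
  8-mers as common / A-only / B-only between two proteins; deterministic
  seed-anchored PFM motifs with IUPAC consensus.
- **`hybridnet.regions`** — promoter scanning by 8-mer lookup (1-nt step,
  both strands), binding-region calling (≥ 2 consecutive significant
  windows, minimum span 9 nt), and common-region classification (overlap
  by ≥ 1 full 8-mer), with BED and cohort-summary output.
- **`hybridnet.domains`** — dual domain-family scoring (ungapped
  position-specific log-odds profiles with Gumbel-calibrated E-values, or
  imported HMMER `domtblout` results), the two-tier significance scheme
  (marginal < 1e-5, high < 1e-10), per-family E-value cutoffs, and the
  orthogonality report for proteins hitting both families.
- **`hybridnet.presence`** — clade × family presence/absence matrices
  (present iff ≥ 1 member in ≥ 1 sequenced genome of the clade) and
  per-genome network states (ancestral_only / fungal_only / hybrid /
  neither).
- **`hybridnet.phylo`** — alignment-column masking by score quantile and
  the branch-support consensus rule (significant iff ≥ 2 metrics pass,
  at least one parametric — aBayes ≥ 0.9, PP ≥ 0.95 — and one
  non-parametric — SH-aLRT ≥ 0.80, RBS ≥ 70 %), with multi-metric
  newick I/O.

## The E-score

For an 8-mer *m*, split the array into foreground probes F (those
containing *m* on either strand) and background B. With F′ the top
⌈|F|/2⌉ foreground probes by intensity and B′ the top ⌈|B|/2⌉ background
probes,

```
E(m) = U / (|F′|·|B′|) − 1/2,    U = #{(x, y) ∈ F′×B′ : I(x) > I(y)} + ½·#ties
```

a rescaled Wilcoxon–Mann–Whitney statistic: E ∈ [−0.5, +0.5], +0.5 exactly
when every top-half foreground probe outranks every top-half background
probe, and invariant under any monotone transform of the intensities.
E ≥ 0.37 marks a significant binding site (null false-positive rate
≈ 0.001 on a universal array). Scores are reported per canonical 8-mer
(the lexicographic minimum of the 8-mer and its reverse complement;
(4⁸ + 4⁴)/2 = 32,896 of them).

## Worked example

A simulated cross-binding experiment: two "proteins" with overlapping
planted specificities (GCGCGAAA vs ACGCGAAA) on the order-10 universal
array, scored and compared exactly as a real E2F1-vs-Swi4 comparison
would be:

```
$ hybridnet simulate --kind array --out probes.fa
$ hybridnet simulate --kind intensities --out e2f.tsv --consensus GCGCGAAA --seed 5
$ hybridnet simulate --kind intensities --out sbf.tsv --consensus ACGCGAAA --seed 6
$ hybridnet escore --probes probes.fa --intensities e2f.tsv --protein-id E2F1 --out e2f_escores.tsv
wrote 32896 8-mer E-scores to e2f_escores.tsv
$ hybridnet escore --probes probes.fa --intensities sbf.tsv --protein-id Swi4 --out sbf_escores.tsv
$ hybridnet classify-kmers --table-a e2f_escores.tsv --table-b sbf_escores.tsv --out classes.tsv
class
neither    30412
A_only      1068
B_only       832
common       584
$ hybridnet motif --table e2f_escores.tsv --name E2F1 --out e2f_motif.txt
consensus GCGCGAWW from 1652 8-mers
```

The planted site itself reaches the E-score ceiling and is called a
shared site of the two proteins, the analogue of GCGCGAAA being bound by
both E2F1 and SBF:

```python
>>> import pandas as pd
>>> pd.read_csv("e2f_escores.tsv", sep="\t", index_col="kmer").loc["GCGCGAAA"]
escore              0.5
foreground_size    33.0
>>> pd.read_csv("classes.tsv", sep="\t", index_col="kmer")["class"]["GCGCGAAA"]
'common'
```

Every stage has an equivalent library call (`build_kmer_index`,
`escore_table`, `classify_kmers`, `build_motif`, ...); the CLI also
exposes `scan-promoters`, `scan-domains`, `import-hmmer`,
`classify-dual`, `presence`, `mask-columns`, `flag-branches` and
`merge-supports`.

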