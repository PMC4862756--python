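# Methods

This note documents the models and procedures implemented in `hybridnet`,
the defaults they use, and the choices made where the design was open.

## Universal arrays and the synthetic-data generators

**De Bruijn construction.** `de_bruijn_sequence(k)` returns the
lexicographically least de Bruijn sequence over ACGT by the
Fredricksen–Kessler–Maiorana construction (concatenation of Lyndon words
whose lengths divide k). It is deterministic — no seed — so the order-10
array (4¹⁰ = 1,048,576 nt; every 10-mer exactly once when read
circularly) is identical across machines and runs.

**Probe segmentation.** `segment_probes` tiles the circular sequence into
probes of `probe_length` (default 36 nt) stepping
`probe_length − overlap` (default overlap 9 = k − 1). The k − 1 overlap
guarantees no k-mer window is lost at a probe boundary, so coverage
(every k-mer in ≥ 1 probe) always holds. Exact *multiset* equality
between within-probe k-mers and the circular sequence's k-mers
additionally requires the step to divide the sequence length; the default
order-10/36-nt/9-nt geometry (step 27, 38,837 probes, last probe wrapping)
does not satisfy that, so a handful of windows near the wrap appear in
two probes. This is irrelevant to the rank statistics downstream and is
tested explicitly in both regimes. The 36-nt probe length and k − 1
overlap are conventions of universal-array designs, not constraints of
the method.

**Intensity model.** Simulated probe fluorescence is lognormal around a
planted signal:

    log I = baseline_mu + effect_size · max(0, best_lod) + ε,
    ε ~ Normal(0, noise_sd)

where `best_lod` is the highest log-odds of the planted PWM against the
uniform base background over all windows of the probe, on either strand
(probes are double-stranded). Defaults: baseline_mu = 7.0 log-intensity
units (an arbitrary fluorescence scale — the E-score is rank-based, so it
cancels), effect_size = 1.0, noise_sd = 0.3, no planted PWM. The
multiplicative-noise form reproduces the heavy right tail of fluorescence
data; with effect_size = 0 the intensities are i.i.d. lognormal, the null
for false-positive-rate calibration. `pwm_from_consensus` builds sharp
PWMs (consensus base probability 0.925 per column, remainder split
evenly), giving roughly a 3.6-log-odds penalty per mismatch — steep
enough that single-mismatch sites do not crowd out the planted consensus,
mild enough that they are visibly enriched, as in real PBM data.

**Proteomes.** Family members are copies of aligned exemplars with
per-site substitutions (default rate 0.05 — within the divergence where
profile recovery should be essentially perfect); `make_family_spec`
derives exemplar sets from an independent random ancestor per seed, so
two specs are non-homologous by construction. Background proteins are
i.i.d. uniform over the 20 amino acids (the same background the profile
log-odds assume). Default composition 10 + 10 family members and 25
background proteins of 200 residues — small enough to scan in
milliseconds, large enough that an E-value of 1e-10 is a meaningful bar.

**Promoters and trees.** Promoters are i.i.d. uniform ACGT (default
1000 bp, the proximal-promoter convention) with sites written at fixed
forward-strand offsets; overlapping plants are rejected as ambiguous
truth. Random supported trees are built by uniform random joins; each of
the n − 3 internal branches of the unrooted binary topology draws each
support metric uniformly over its legal range (probabilities in [0, 1],
bootstrap percents in [0, 100]).

**What the generators do not emulate:** spatial array artifacts,
replicate arrays, probe secondary structure, sequence composition bias in
promoters, gapped family divergence (indels), or realistic branch-support
correlation structure. Tests passing on these synthetics demonstrate the
*statistics and rules* are implemented correctly, not that real data will
be as well-behaved.

## E-scores

The E-score is the top-half Wilcoxon–Mann–Whitney variant rescaled to
[−0.5, +0.5]: foreground F = probes containing the 8-mer on either
strand, background B = all other probes, and only the brighter
⌈n/2⌉ probes of each group enter the U count (ties weighted ½). The
top-half restriction makes the statistic robust to the dim, uninformative
bulk of each group. Properties relied on and tested: bounds attained
exactly at perfect separation; invariance under strictly monotone
intensity transforms; agreement with an explicit pair-counting oracle.
Note one asymmetry of the top-half variant: reversing the intensity order
does not in general negate the score (top-half selection is not
equivariant under reversal); exact antisymmetry holds for the untruncated
statistic, available as `escore_from_values(..., top_half=False)`.

The whole-table path (`escore_table`) ranks the array once globally and
computes every canonical 8-mer's U from foreground rank positions — no
per-k-mer re-sorting — in O(total foreground size) after the sort. It
assumes continuous intensities (exact ties between foreground and
background are broken by probe order); the single-k-mer `escore` handles
ties exactly and the two agree on continuous data.

**Cutoff.** Significance is E ≥ 0.37, the published universal-PBM cutoff
corresponding to a false-positive rate of ~0.001; the comparison is
inclusive (≥). On the motif-free order-10 array the observed significant
fraction is ≤ 1e-3 (typically 0–2 of 32,896 canonical 8-mers).

## Motifs

Enriched 8-mer sets are summarized without stochastic alignment: the
highest-scoring 8-mer (ties: lexicographic) seeds the motif; every other
8-mer is placed at the offset in [−4, +4] and orientation maximizing
matched seed positions (ties: smaller |offset|, then forward, then
smaller offset); counts over the eight seed-anchored columns give the
PFM. The consensus letter per column is the IUPAC code of the base set
with frequency ≥ 0.2 — a threshold that reports genuine 2-way splits
(S, R, W...) while suppressing noise bases. A deterministic greedy
aligner replaces stochastic Gibbs alignment: at 8-mer scale with a
uniform prior the Gibbs posterior carries no information the greedy
placement lacks, and determinism makes motifs reproducible bit-for-bit.

## Promoter regions

Scanning is 8-mer E-score lookup per window (1-nt step, canonicalized,
so both strands are covered), not PWM log-odds. Windows containing
non-ACGT characters, or 8-mers absent from the score table, are
unavailable and never significant. A binding region is a maximal run of
≥ 2 consecutive significant windows; its interval is
[first_window, last_window + 8), hence ≥ 9 nt. Coordinates are 0-based
half-open on the supplied promoter sequence (position 0 = the upstream
end of the extracted region); promoter extraction from a genome build is
out of scope — the module consumes pre-extracted FASTA. Two TFs' regions
on one promoter are *common* when their intervals share ≥ 8 nt (one full
8-mer), whether nested or partially overlapping; regions in no common
pair keep their single-TF label. Cohort summaries count exclusive regions
individually and each common pair once; per-TF regions are reported, not
merged across TFs.

## Domain scanning and E-values

The internal scorer is an ungapped position-specific log-odds model:

    log_odds[p][a] = ln(((count_p(a) + pc·bg_a) / (n + pc)) / bg_a)

with pseudocount pc = 1 and uniform 1/20 background, scored by the best
ungapped placement over the protein. **This is the package's largest
deliberate simplification**: it is not a profile-HMM with insert/delete
states. The claims built on it — the two-tier threshold logic, per-family
cutoffs, and family orthogonality — do not depend on gapped alignment,
and genuine HMMER results enter through `read_domtblout` (the E-value
taken is the best-domain independent E-value, matching the
domain-threshold style of the per-family cutoffs).

E-values come from a Gumbel (type-I extreme-value) fit to the null:
scores of n_random (default 500) i.i.d. background sequences are fitted
by moment matching (β = sd·√6/π, μ = mean − γβ), and

    E(s) = N · (1 − exp(−exp(−(s − μ)/β)))

for a database of N sequences. The max-window score is a maximum of
correlated window sums, so the Gumbel is an approximation — good in the
right tail where the thresholds live, looser near the mode; calibration
length defaults to the median protein length so the number of placements
matches the search.

Classification tiers: *high* below 1e-10, *marginal* in [1e-10, 1e-5) —
the marginal band is reported for validation rather than trusted.
A protein significant for both families is labelled `both_flagged` and
surfaced by `orthogonality_report`, never silently assigned to either
family. Per-family presence cutoffs default to: 1e-20 for cyclins, pRb
and CDKs; 1e-50 for CDC20-family APC regulators; 1e-10 for E2F/DP, SMRC
(SBF/MBF), APSES, XBP1 and BQT4; 1e-5 for the fast-evolving WHI5 family;
1e-10 for general searches.

## Presence matrices and network states

A clade shows a family iff at least one member genome has count ≥ 1 —
a boolean OR, monotone under adding genomes. Sub-family assignment by
molecular phylogeny (the step between domain hits and counts in a full
analysis) is out of scope; the aggregation accepts calls at whatever
granularity the input table provides. The matrix stores explicit False
for absent families (display conventions that omit cells are a rendering
concern). Network states: *hybrid* iff ≥ 1 ancestral-side (E2F/DP-type)
and ≥ 1 fungal-side (KilA-N-type) family member, else
ancestral_only / fungal_only / neither.

## Column masking and branch support

`mask_columns` keeps the ⌈q·N⌉ highest-scoring alignment columns
(external scores, e.g. from a probabilistic masking tool), ties broken
toward lower column index, original order preserved. Ceiling was chosen
for the count; tie-break and rounding are stated because published
kept-column counts do not determine them.

A branch is significantly supported iff ≥ 2 metrics meet their
thresholds and the passing set contains at least one parametric and one
non-parametric metric. Defaults: aBayes ≥ 0.9 and posterior probability
PP ≥ 0.95 (parametric); SH-aLRT ≥ 0.80 and rapid bootstrap RBS ≥ 70 %
(non-parametric). The PP threshold is this package's choice (0.95, the
conventional Bayesian bar) — figure-legend thresholds exist for the other
three metrics only — and is configurable via `SupportPolicy`. Branches
are matched across trees by unordered leaf bipartitions on unrooted
topologies; when merging, a metric attaches only to branches whose split
exists in its source tree, and source splits absent from the reference
topology are reported as conflicts rather than grafted.

## Numerical and interface conventions

- Canonical k-mers are packed 2-bit codes; lexicographic string order
  equals numeric code order, so "canonical = min(code, rc code)".
- All generators are bit-reproducible under a fixed integer seed
  (numpy `default_rng`); the de Bruijn construction needs no seed.
- Degenerate inputs raise `ValueError` with the offending item named
  (unmapped genomes, unknown families/metrics, overlapping plants,
  foreground not a strict subset, zero calibration variance).
- `evalue` saturates at N in double precision deep in the left tail
  (scores far below μ); it is strictly decreasing wherever it is
  informative.

## Problem sizes

The shipped defaults are desk-scale by design: the order-10 array
(38,837 probes, 32,896 canonical 8-mers, full E-score table in
well under a second after a one-off index build), 45-protein proteomes,
50-promoter cohorts, and ≤ 12-taxon trees. Genome-scale surveys (100+
proteomes, full phylogenies) are outside this package's scope; the same
code paths apply unchanged to larger inputs.

## Known limitations

- The ungapped profile scorer under-detects genuinely gapped family
  members; use imported HMMER results for sensitive real-data searches.
- The Gumbel moment fit is biased for very small calibration samples
  (n_random < ~200) and approximate near the distribution mode.
- E-score tables assume continuous intensities; integer-quantized
  intensities with heavy ties should go through the exact single-k-mer
  scorer.
- PBM-derived sites over-predict in-vivo occupancy by design: the
  promoter scanner reports biochemical binding potential, not predicted
  occupancy in chromatin.
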