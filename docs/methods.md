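# Methods

This note records the models, defaults and design choices behind
`ligarray`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Consensus extraction

For each alignment column, base fractions are computed over **non-gap**
residues only; a degenerate input residue contributes 1/k to each of its k
expanded bases (unbiased treatment of ambiguous database entries). The
calling rule per column:

- gap fraction > `max_gap` (default 0.5) → the column is marked `'.'` and
  excluded from probe placement (probes must not span indel-rich regions);
- a single base with fraction ≥ `cutoff` (default 0.75) → that base;
- otherwise the minimal IUPAC code covering every base with fraction ≥
  `minor_floor` (default 0.01, so singleton sequencing errors in large sets
  do not degenerate the consensus).

Whether the ¾ denominator should include gapped rows is not specified by
the assay description; the non-gap denominator is our choice, as is the
floor. Both are keyword parameters. `U` is normalized to `T` and residues
are stored uppercase; alignment itself is out of scope (inputs must be
pre-aligned) and readers reject unequal-length records.

## Melting temperatures

Duplex stability uses the unified Watson–Crick nearest-neighbor parameters
of Allawi & SantaLucia (1997) with the entropic salt correction
ΔS′ = ΔS + 0.368 (N−1) ln[Na⁺] and
Tm = 1000·ΔH / (ΔS′ + R ln k) − 273.15, k = c₁ − c₂/2.

Defaults: 100 mM monovalent cation and 12.5 nM per strand — the probe
concentration of a 250 fmol / 20 µL ligation. Under these conditions a
random 36-mer of balanced composition melts near 68 °C, matching the
design target and the reported length/Tm profile of validated LDR panels
(mean half length ≈ 36 nt at Tm ≈ 68 °C). Degenerate probes are scored as
the mean Tm over their plain-base expansions — exhaustive up to 64, beyond
that a deterministic uniform-stride subsample of the canonical expansion
order (no RNG; the cap can only be exceeded transiently during scanning,
since accepted probes carry ≤ 4 degenerate bases). The implementation is
independent of Biopython's `Tm_NN` and is cross-checked against it to
< 0.1 °C in the test suite.

## Probe design

Candidates are enumerated per junction: the DP grows upstream from its
3′-anchor, the CP downstream, over contiguous non-`'.'` columns; each half
must satisfy 25–60 nt, Tm 68 ± 1 °C and ≤ 4 degenerate bases (the cap is
applied **per half**, the stricter reading of "maximum 4 degenerate
bases"). Ranking is deterministic: combined |Tm − 68| over both halves,
then total degeneracy, then leftmost junction. Specificity requires (i)
perfect match — at every footprint column the probe expansion intersects
the sequence expansion and the sequence is ungapped there — against
**every** positive-set sequence, and (ii) discrimination — no expansion
overlap at the junction column (a gap counts as discriminated) — against
**every** negative-set sequence. The discrimination window is strictly the
DP 3′-terminal base; design is on the given consensus strand only.
`design_panel` assigns the best passing candidate of each target the next
free probe-role zip and appends the reverse complement of the zip to the
CP as its cZip tail.

The zip library ships as a deterministic artifact: 25-mers rejection-
sampled at pairwise Hamming distance ≥ 8, anchored on the one published
hybridization-control sequence (Zip 66); Zip 63 is the ligation control.
The per-array capacity is 47 probe sets.

## Array model and simulation

One universal array is a 13 × 16 grid (208 spots): every assigned zip in
quadruplicate, 6 buffer-only blanks, Zip 63 and Zip 66 in quadruplicate,
the rest empty. Spot placement is deterministic pseudo-random under a
seed, since physical coordinates carry no assay meaning.

A template mix lists components in ng. Components given as raw sequences
are routed through `ligation_match` — an exact scan for the DP+CP
footprint with IUPAC-compatible pairing at every position, which at the
junction enforces the single-mismatch ligation rule; components referenced
by panel target name are credited to that probe directly. Human carrier
DNA is inert (an optional cross-hybridization rate, default 0, allows
stress tests). Spot intensity:

    IF = efficiency · (matched ng) · LN(cv) + max(N(bg_mean, bg_sd), 0)

with LN a mean-one lognormal of the configured CV (default 0.1),
background mean 500 and sd 50 units, and per-target efficiencies (default
5000 units/ng, chosen so a 10 ng single-target assay yields SNR of order
10²–10³, within the validated range). Controls draw from fixed mix-
independent means (Zip 63: 40 000; Zip 66: 30 000).

**Blank offset.** Buffer-only blanks draw the background **plus a constant
offset** of `blank_offset_frac` (default 0.1) × background mean; empty
spots draw the pure background. Rationale: on the validated arrays no
unmatched probe was ever called present across hundreds of comparisons,
which is only consistent with the probe-vs-blank test being conservative
under the null — an exact-level test at α = 0.01 would produce ~1 % false
calls. Physically, printing buffer retains slightly more unbound dye than
bare capture spots. The offset makes unmatched probes sit ~1 background-sd
below blanks, suppressing off-target calls while leaving true signals
(orders of magnitude above background) untouched; the calibration of the
t-test itself is verified separately on identically-distributed draws.

The synthetic sequence generator emulates the conserved/variable
architecture of the 16S gene: variable blocks of 40 columns (within-set
divergence 0.1 per column by default) alternate with conserved blocks of
140 columns; each long conserved block hosts one discriminating column at
its centre (positives share the ancestral base, negatives a fixed
substitute), and conserved columns are polymorphic at rate 0.01 with a
second base carried by a third of the set — the origin of degenerate probe
bases. Defaults (6 sequences per set, 400 columns) are sized so that
probe design succeeds for every target, as it did for the real panel. Not
emulated: real V-region coordinates, indels beyond optional uniform gap
columns, chimeras, inter-target homology. Tests passing on these sets
validate the machinery under this model; they say nothing about the
specificity of any real probe panel against the full 16S databases.

## Analysis pipeline

- **Outlier rule**: single-pass — the replicate mean is computed once and
  values outside [mean/2.5, 2.5·mean] are discarded. Discarding everything
  (possible when one huge value drags the mean) is an error by design, not
  silently ignored.
- **Normalization**: per array, the correction factor 50 000 / mean
  (retained Zip-63 IFs) multiplies probe *and* background intensities.
  Idempotent; arrays are never pooled.
- **Spot calling**: Welch's one-tailed two-sample t-test (probe > blank)
  on outlier-filtered values, quadruplicate vs the array's six blanks,
  α = 0.01 (a pooled-variance option exists). Both p-value and SNR are
  invariant to common rescaling, so calls do not depend on the
  normalization constant. Degenerate cases (zero variance on both sides)
  are decided on the means.
- **Efficiency**: mean sSNR/ng over the significant points of a dilution
  series, with the Pearson correlation of sSNR vs ng as a linearity
  diagnostic; scaling by efficiency is an explicit flag, default off for
  clinical-style reports (the published account is ambiguous on whether
  scaled data fed the clinical heatmaps).
- **Summaries**: prevalence is rounded to whole percent, agreement to one
  decimal, SNR aggregates to two decimals — the printed precisions of the
  source material. Abundance profiles zero out non-significant targets and
  express per-group mean intensities as percent of the group total.
- **Clustering**: average linkage on 1 − Pearson distance between sample
  profiles; identical profiles are at distance 0 and zero-variance
  profiles at distance 1 from everything else (deterministic tie rule).
  Cluster stability is the plain bootstrap probability over targets
  (default 1000 resamples, seeded); no multiscale/AU correction is
  applied, so values are not directly comparable to pvclust's AU
  percentages.
- Replicate calling pools the quadruplicate spots within one array only;
  cross-array pooling is deliberately not offered.

## Problem sizes

The simulation-backed checks use the panel scale of the real instrument
(22 targets, 208-spot arrays), 2000 null draws for type-I calibration,
5-point dilution series, 3-replicate mixtures for abundance recovery, and
1000 bootstrap resamples for cluster stability; the complete suite and the
acceptance script each run in well under a minute.

## Known limitations

- No image-level simulation (spot morphology, scanner gain/saturation) and
  no PCR amplification bias; amounts are taken as ng of clean amplicon.
- The ng→fmol conversion (0.7 fmol/ng for a ~1.5 kb amplicon) is a
  reporting constant, not asserted chemistry.
- In-silico specificity is only as good as the supplied negative sets;
  there is no live database matching.
- ANOVA-style site/subject comparisons and heatmap rendering are out of
  scope; the toolkit exports the matrices instead.
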