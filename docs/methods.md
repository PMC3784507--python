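# Methods

`fecmap` reimplements, as a tested library, the inference chain used to
localize a major fecundity gene segregating on a single mutant haplotype
(the *FecL* locus of Lacaune sheep, prolific allele *FecL^L^*, written
`L`; genotypes `+/+`, `L/+`, `L/L`). The chain has five analytical
stages — recombinant interval reduction, haplotype variant discovery,
allele-sharing exclusion, efficiency-corrected qPCR contrast, and
genotype-exclusive protein filtering — plus a forward simulator that
generates every input under the study design's assumptions.

## Coordinate model

Positions are 1-based bp, as in g.-style variant names. Interval length
is the difference `end − start`; this is the convention under which the
locus landmarks reproduce their conventional kb figures (488195 bp →
"488 kb", 197456 → "197 kb", 96349 → "96 kb", and the sequenced locus,
distal border at locus position 194639, → "194.6 kb" at 0.1 kb
precision, round-half-up). Reference-to-locus conversion is a piecewise
map of exact alignment blocks rather than a constant shift: a sequenced
locus differs from the reference assembly by indels, so the printed
coordinate pairs imply block-wise offsets that a single shift cannot
reproduce. Positions falling between blocks raise an explicit
`UnmappableError`; they are never interpolated. The packaged
polymorphism table stores the printed coordinate pairs verbatim instead
of recomputing them, because the underlying locus assembly is not an
input of this package.

## Forward simulator

The simulator (`fecmap.synthetic_data`) emulates the study design, not
sheep genetics in general. Its defaults are the study's stated
conditions; everything is overridable through `SimulationConfig`.

* **Region and sites.** 488,195 bp carrying 49 biallelic variant sites
  at uniform random positions; allele 1 is the L-haplotype-defining
  allele, and one designated site is causal. The single mutant founder
  haplotype carries allele 1 everywhere; the causal allele occurs on no
  wild chromosome, ever — the mutation is unique by assumption.
* **Wild sharing.** A wild chromosome carries the L-associated allele at
  a non-causal site with probability `share_rate · exp(−d/decay)`,
  where `d` is the distance to the causal site (default decay 200 kb).
  This is a direct parameterization of identity-by-descent sharing, not
  a coalescent model of breed history: the within-breed sharing
  structure of the wild populations is unknown, so it is a stand-in
  whose only job is to produce realistic `k/n` exclusion tables.
  Explicit per-site probabilities can be supplied instead.
* **Meiosis.** Crossovers are a Poisson process on the genetic map with
  no interference; the map is uniform at `cM_per_Mb` (default 1.0; the
  local recombination rate of the region is not known). Between two
  markers the recombination fraction therefore equals the Haldane value
  r = ½(1 − e^(−2d)), the same function used analytically by
  `prob_recombinant`. The gamete records its per-site lineage of origin
  as ground truth.
* **Pedigree.** One `L/L` founder ram × wild ewes → F1; F1 × wild → BC;
  F1 × BC → intercross. The default totals 189 non-founder animals,
  split 20/100/69 across F1/BC/F1×BC; the published design gives only
  the total, so the split is this package's choice and is configurable.
* **Genotype classification.** True class comes from causal-site lineage;
  the observed class is corrupted with probability 0.005 per animal
  (drawn uniformly among the wrong classes), reproducing the stated
  99.5% proxy-marker classification accuracy at the animal level.
* **Phenotypes.** Ovulation rate is additive Gaussian:
  OR = base + 1.5·copies + N(0, sd), base 1.2, per-copy effect 1.5
  ova/cycle, residual sd 0.8. Only differences of class means are ever
  tested, so the base is immaterial to recovery.
* **qPCR.** Ct = Ct_base − log_E(abundance) + N(0, sd), Ct_base 20,
  noise sd 0.25 cycles by default. Wild-type abundance is 1, mutant
  abundance is the configured fold (defaults: B4GALNT2 1000× in all
  three ovarian tissues, IGF2BP1 6× in granulosa only); the RPL19
  reference is unregulated. With zero noise the downstream ratio
  computation recovers each fold exactly — this exactness is a designed
  identity, not an approximation.
* **MS tables.** Exclusive proteins are identified in every mutant
  replicate (peptide counts ≥ 4 + Poisson, probabilities above 0.96)
  and in no wild-type replicate; background proteins appear everywhere;
  a configurable fraction of background peptides is shared between two
  proteins to exercise shared-peptide removal.
* **Sequences.** `simulate_sequence_pair` plants SNPs, a microsatellite
  repeat-count change and indels into a repeat-free random sequence
  with ≥40 bp separation. Planting is constructed so the planted
  placement is the unique minimal alignment (indel bases and local
  flanks drawn from disjoint alphabets; repeat runs broken at their
  flanks); this is what makes exact planted-truth recovery a fair test.

All randomness flows from one master seed through named substreams
(`substream(seed, stage)`), so any stage is bit-reproducible in
isolation and full reports are byte-identical under a fixed seed.

What the simulator does **not** emulate: sequencing reads and their
errors, genotyping failure patterns, crossover interference, population
structure beyond the sharing decay, follicle-stage expression
covariates, and peptide-level MS noise. Passing tests therefore
demonstrate correctness of the inference chain under the stated model,
not robustness to every artefact of real data.

## Recombinant interval reduction

Phasing is pedigree-certain only: an allele transmission is assigned
when the offspring is homozygous or one parent is homozygous; sites
where both the transmitting parent and the resolution are ambiguous are
flagged, never guessed, and Mendelian-inconsistent sites are excluded
per site. Lineage labels propagate from the mutant founder down the
pedigree: a gamete site takes its parent's lineage when either the
parent's two haplotypes agree there or the transmitted allele identifies
the parental haplotype.

A chromosome known to carry the causal allele constrains it to lie
inside the chromosome's L-lineage segments; a known non-carrier
chromosome excludes its L segments. Between informative markers,
lineage is imputed only when both flanks agree (minimal-recombination
assumption); terminal gaps inherit the nearest informative marker. A
double crossover inside one inter-marker gap is unobservable and is a
documented limitation, quantifiable via `prob_recombinant`. Carrier
status per chromosome comes from the animal's class: 0 or 2 copies fix
both chromosomes; one copy is resolved only when exactly one chromosome
shows L lineage, otherwise the pair is skipped.

The minimal interval is the intersection of all constraints, reported
between the closest excluded ("border") markers — the borders bound the
locus but are excluded from it. Segments are classified by how many
chromosomes exclude them (0 / 1 / ≥2 recombinants); the zero-count zone
*is* the reduced interval. If the constraints are jointly unsatisfiable
the cause is a mislabelled carrier (classification error), not
recombination; the implementation drops the most-excluding constraint
(the one most discordant with the consensus) with a warning until a
zero-recombinant zone reappears. A randomized brute-force
constraint-intersection oracle checks the atom-level logic in the test
suite.

## Variant discovery

The two homozygous haplotype sequences are aligned globally with edlib;
the alignment path is then post-processed here. Adjacent non-match
operations form one event; indel fragments split around short re-matches
(an equal-cost ambiguity inside repeat runs) are coalesced; equal-length
events are decomposed into positional mismatch runs, so separated
substitutions are always reported as distinct SNPs; pure indels are
left-normalized to their leftmost equivalent placement. A pure length
change inside a tandem run of a 2–6 bp motif with ≥5 copies is reported
as a microsatellite (position = run start, counts = wild and mutant
copy numbers); the ≥5-copy threshold is chosen so that every published
microsatellite in the packaged table qualifies. Everything else is an
indel/delins, positioned at the first differing base. Output is a
table-style TSV and a minimal VCF 4.2 (indels anchored on the preceding
base when the wild sequence is available).

## Allele-sharing screen

For each polymorphism, `k/n` counts wild chromosomes carrying the
L-associated allele over chromosomes typed; missing genotypes reduce
`n` rather than erroring (the published table's heterogeneous `n`
values reflect exactly this). Panels are applied in stages — initial
subset (5 chromosomes), carrier-breed family (103), two related
populations (173, 148), nine unrelated breeds (180) — and screening
stops at the first stage with `k > 0`, so counts are cumulative over
stages actually run. "Fully associated" means `k = 0` after all stages
and not a border marker. The published cumulative maximum is `n = 602`
while the stage sizes sum to 604 + the initial subset; the discrepancy
is left as printed, and the packaged table stores printed values
verbatim.

## Expression screen

Relative expression is the efficiency-corrected ratio
R = E_ref^Ct_ref / E_target^Ct_target (computed in log space),
with per-gene amplification efficiency E = e^(−1/slope) from the
dilution-series slope. Whether the published efficiencies came from a
natural-log or log10 dilution series is not stated, so the log10
variant E = 10^(−1/slope) is available behind a flag. Ratios are
computed per sample, then averaged per group; fold = mean(L/L) /
mean(+/+). The genotype contrast is a two-sided Welch t-test on the
ratio scale (log scale optional) — Welch because group variances on a
ratio scale are rarely equal; p > 0.05 is "not significant", with no
multiple-testing correction (none is part of the published analysis).
Zero-variance-in-both-groups degeneracy is resolved explicitly (p = 1
if means equal, else 0) so noiseless recovery tests are well defined. A
gene is an ectopic candidate when significant in ≥1 ovarian tissue
(granulosa small/large, theca large) and non-significant in every
non-ovarian tissue; candidates are ranked by maximal ovarian fold.

## MS differential filter

Identifications are retained at probability > 0.95 and ≥4 distinct
peptides. The peptide threshold is stated both as "at least four" and
"greater than four" in the source material; ≥4 is the default and the
threshold is a parameter. Spectra from peptides shared between proteins
are removed first (counts recomputed, spectral counts rescaled by the
retained fraction — idempotent by construction). A protein is
genotype-exclusive when retained in *every* replicate of one genotype
and in *none* of the other; presence/absence is the defining rule, with
the per-protein Welch t-test on normalized spectral counts (absent =
zero count) reported alongside rather than gating the set. Spectral
counts are normalized per replicate to a common total, preserving
within-replicate ordering.

## Numerical and size choices

* Welch t-tests throughout (`scipy.stats.ttest_ind(equal_var=False)`).
* kb formatting is round-half-up (`decimal`), not banker's rounding.
* The interval-soundness property runs 1000 replicates of a compact
  design (400 kb, 12 markers, 30 animals, error-free classification):
  small enough to be exhaustive-feeling in seconds, large enough that
  every replicate exercises phasing, carrier assignment and reduction.
* Haldane agreement uses 10^5 gametes on a 2-marker, 195 kb map and a
  χ² goodness-of-fit at p = 0.001.
* Recovery targets (per-copy effect 1.5, folds 1000 and 6) use 500
  animals per class / 5 samples per group, the scales at which the
  published contrasts are defined.

## Known limitations

* Phasing is pedigree-certain only; no statistical (EM/HMM) phasing, so
  sites ambiguous in both parents stay unused.
* Double crossovers within one inter-marker gap are invisible.
* The carrier-conflict resolution is a greedy consensus heuristic; with
  many simultaneous misclassifications it could drop an informative
  chromosome.
* The variant differ targets homozygous-vs-homozygous comparisons; no
  heterozygous calls, no quality model, and delins placement inside
  long repeat runs follows left-normalization conventions that may
  differ from other callers.
* The simulator's panel-sharing decay is a phenomenological stand-in
  for unknown population structure.
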