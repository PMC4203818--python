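# Methods

## The star-allele model

The unit of analysis is the CYP2D6 *star allele*: a haplotype over an
11-position panel (gene-relative positions −1584, 31, 100, 1023, 1846,
2549, 2615, 2850, 2988, 3183, 4180). Every site is treated as biallelic;
the 2549 and 2615 deletions are modelled as single-site `del`-vs-reference
states, matching a biallelic allelic-discrimination assay. The packaged
catalogue holds 13 base alleles — 12 sequence-defined (*1, *2, *3, *4, *9,
*10, *17, *29, *34, *35, *39, *41) plus the whole-gene deletion *5, which
has no sequence and is called exclusively from copy number — and the
duplication labels *1x2, *1x3, *2x2, *2x5, *4x2, *17x2, *35x2.

Assignment is by **perfect match only**: a fully observed haplotype either
equals a base definition at all 11 sites or is pooled as `Others`. This is
deliberately conservative; it mirrors how assay panels are interpreted when
resequencing is out of scope, and it means `Others` frequencies measure the
panel's blind spots rather than novel alleles.

Activity classes are none / reduced / normal / high / ND. Duplications
follow a closed rule derived from the catalogued cases: duplicating a
normal-function allele → high; a no-function allele → none; a
reduced-function or undetermined allele → ND. The rule reproduces every
catalogued duplication (*1x2 high, *4x2 none, *17x2 ND) and extends
consistently to labels the catalogue does not list (e.g. *39x2 → high).

## EM phasing

Haplotype frequencies are estimated by the Excoffier–Slatkin gene-counting
EM under Hardy–Weinberg random pairing. Each individual's genotype expands
into all compatible ordered haplotype pairs; missing sites are marginalized
(summed over both states) rather than imputed, which preserves sample size
at the cost of slightly flattening the likelihood. The E-step weighs pair
(i, j) by its ordered multiplicity times f_i·f_j; the M-step renormalizes
expected counts by the chromosome total.

Copy-number bookkeeping: individuals with one gene copy contribute a single
chromosome read directly from their homozygous-appearing calls (a
heterozygous call there is rejected as contradictory); zero-copy
individuals contribute nothing; individuals with ≥3 copies are phased as
diploids — the surplus copy shares a sequence with one of the two
haplotypes and is attached downstream.

Numerical choices: convergence at log-likelihood change < 1e-8, max 1000
iterations; 5 random Dirichlet restarts plus one allele-frequency-product
initialization, keeping the best final likelihood; deterministic given the
seed. Posterior phase ranking uses Hardy–Weinberg weights 2·f_i·f_j
(f_i² when homozygous); a record incompatible with every positive-frequency
haplotype is ranked with a 1e-12 floor frequency (effectively uniform), a
device that never perturbs the frequency estimates themselves. Equal-weight
resolutions are broken lexicographically on the state vectors and flagged
as tied.

## Copy number and diplotypes

The copy-number caller models a relative-quantification readout against a
2-copy calibrator: cn = round(2·RQ) (ties to even), z = |2·RQ − cn| / s
where s is the replicate standard deviation (default 0.05), and confidence
is the normal probability mass of the rounding interval. Calls are
accepted when confidence > 0.95 **and** z < 1.75; failed calls block
phenotyping for that individual rather than silently defaulting to two
copies.

Assembly rules: CN 2 keeps the two phased labels; CN 1 pairs the observed
haplotype with *5; CN 0 is *5/*5; CN k ≥ 3 with two copies of the same
base allele promotes one slot to base×(k−1); with two *different* base
alleles the duplication is ambiguous — both slots keep base labels, k−2
copies are carried as unassigned, and the call is flagged. Ambiguous
duplications therefore *undercount* ×N labels at the allele level while
still counting as duplication carriers; this asymmetry is intrinsic to
exon-targeted copy-number assays. Copy numbers above 6 are rejected as RQ
outliers. The assay cannot see a duplication balanced by a deletion
(e.g. *1x2/*5 reads as two copies); this is documented, not modelled away.

## Phenotype prediction

Dominance rules: active copies = Σ multipliers over slots whose base
allele has normal function; ≥3 → UM; ≥1 → EM; both slots inactive → PM;
otherwise (reduced+reduced or reduced+inactive) → IM. Any `Others` slot,
ND-activity allele, ambiguous duplication or blocked copy-number call
yields ND. Whether one ND allele should block classification when the
partner is normal is genuinely undecidable from the classification rules
alone; the default propagates ND (which keeps the ND share on the scale a
real unassignable-haplotype rate produces), and
`predict_phenotype(..., nd_dominant_partner=True)` switches to letting the
normal partner dominate. The CPIC activity-score system is deliberately
not used: the package targets drug-agnostic population description, not
gene/drug dosing.

## Population statistics

* **Frequencies** by gene counting: two slots per individual, a ×N label
  occupying one slot, so each stratum's chromosome total is exactly twice
  its individual count.
* **Activity-class table** over the *evaluable* denominator: slots with
  undetermined activity (Others, ND alleles) leave both numerator and
  denominator.
* **χ² and G tests**: Pearson χ² without continuity correction; the
  G-test (G² = 2 Σ O ln(O/E), df=(r−1)(c−1)) is the likelihood-ratio test
  of independence, i.e. what a multinomial log-linear model reduces to for
  a single categorical predictor — implemented in closed form rather than
  as an iterative fitter because the two are equivalent for this design.
  Rare alleles are pooled (default: total count < 5) before the
  allele-by-region test, since such tables are otherwise dominated by
  near-empty cells.
* **AMOVA**: two-level haplotypic analysis with label-identity distance
  (δ = 0 same allele, 1 otherwise), which makes Φ_ST a pure
  allele-frequency statistic. Sums of squares are computed from allele
  counts (algebraically identical to the distance-matrix form; the test
  suite checks this against an explicit distance-matrix oracle at 1e-10).
  The permutation test reassigns individuals — both chromosomes moving
  together — and reports the fraction of permutations with Φ_ST at least
  the observed value; default 10,000 permutations, seeded.
* **F_ST**: multi-allelic Weir–Cockerham θ, the per-allele a, b, c
  components summed over alleles, treating the star-allele locus as one
  multi-allelic locus of diploids. Percentile CIs from bootstrap
  resampling of individuals within groups (default 3,000 replicates);
  the CI lower bound truncates at 0 while negative point estimates are
  reported as computed. Monomorphic pairs return θ = 0 with a warning.
* **Ancestry association**: Kruskal–Wallis across phenotype classes
  (tie-corrected, χ² approximation), Mann–Whitney U pairwise (normal
  approximation, no continuity correction, so identical samples give
  p = 1 exactly), Benjamini–Hochberg step-up adjustment.

## The synthetic cohort

The generator emulates the statistical structure the analysis assumes —
not any real population. Each individual draws a (Amerindian, African,
European) ancestry triple from a per-region Dirichlet, then fills two
gene-copy slots by drawing an ancestral origin from that triple and a star
allele from the origin's haplotype-frequency profile. Haplotypes are drawn
as whole star alleles, so within-gene linkage is perfect and recombination
is absent — exactly the star-allele model, and the reason phasing recovers
nearly all diplotypes. Duplication events promote a slot to ×N (default
probability 0.042 per non-deleted haplotype, multiplier distribution
{2: 0.80, 3: 0.15, 4: 0.04, 5: 0.01}, total copies capped at 6), giving a
duplication-carrier rate around 8%. The RQ readout is true-CN/2 plus
normal noise (default SD 0.015, small relative to the caller's assumed
0.05 replicate SD so that >99% of calls pass, as in a well-run assay).
Self-reported color is drawn from weights loosely tied to the ancestry
triple — an invented rule that produces the loose ancestry–color
correlation typical of census self-classification.

The default profiles are invented numbers constrained only to reproduce
qualitative continental contrasts (*4 enriched in Europeans, *17/*29 in
Africans, high *1/*2 in Amerindians) and a Brazilian-like overall mix;
the per-region Dirichlet concentrations follow the documented admixture
gradient (Amerindian share highest in the North, African in the
Northeast, European in the South). Because the IM class is driven by
African-enriched reduced-function alleles, the generator reproduces the
IM-higher-African-ancestry association by construction.

What passing tests on this cohort do **not** show: robustness to
genotyping error, within-gene recombination or hybrid genes, allele
catalogues beyond the panel, assay batch effects, or real ancestry
estimation error. They do show that the pipeline's logic — phasing,
copy-number arithmetic, ambiguity handling, phenotype rules and every
statistic — is internally correct and correctly calibrated under its own
model.

## Problem sizes and determinism

Default analysis sizes: 1020-individual cohorts; AMOVA permutation
calibration checked on 200 null replicates of 99 permutations each;
bootstrap-CI coverage on 300 replicates of 500 bootstrap resamples at
250 individuals per group (the analytic large-n θ for the chosen profiles,
≈ 0.0102, serves as truth). All randomness flows from explicit seeds;
identical configuration and seed reproduce byte-identical cohort files
and report bundles.

## Known limitations

* Perfect-match calling cannot resolve suballeles and reports panel blind
  spots as `Others`.
* The exon-9-style copy-number model misses duplication/deletion
  compensation and hybrid-gene rearrangements.
* Heterozygous duplications remain ambiguous by design; allele-level ×N
  frequencies are lower bounds.
* The EM phaser estimates frequencies consistently but, like any
  HW-based phaser, can mis-phase rare double heterozygotes whose
  alternative resolution involves commoner haplotypes.
* The G-test equivalence to log-linear modelling holds for a single
  categorical predictor only; multi-factor models are out of scope.
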