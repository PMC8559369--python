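# Methods

This note documents the models and procedures implemented in `midpass`, the
parameter choices that matter, and what the synthetic cohort does and does
not emulate.

## Refinement pipeline

The pipeline operates on a sites × samples genotype matrix read from a
multi-sample VCF (GT required; GQ/DP where present). Stages, in order:

1. **GQ filter** (`callfilter.gq_filter`): every call with `GQ ≤ t` — or
   with no GQ at all — is set to missing; sites are never removed, so the
   imputation input keeps its full site list. Default `t = 17`. The filter
   is monotone: raising `t` only shrinks the set of surviving calls.
2. **Within-cohort imputation**: either an external tool invoked through a
   command template (`{in}`/`{out}` placeholders), or the built-in
   `naive_impute` scaffold (below).
3. **IM flags** (`imflag.merge_and_flag`): the imputed callset is compared
   per call with the *original, unfiltered* sequencing-based callset.
   Allele **sets** drive the rule: a genotype pair is inconsistent exactly
   when a sequencing-observed allele is absent from the imputed genotype
   (so 0/1 → 1/1 is inconsistent even though allele 1 gained a copy, while
   0/0 → 0/1 is merely an appearance and is "not inconsistent"). Flags:
   IM0 identical or not imputed; IM1 not inconsistent (including
   sequencing-missing); IM2 inconsistent from a het; IM3 inconsistent from
   a hom. Phase never matters; genotypes are unordered allele pairs.

   *Why the unfiltered baseline:* an imputer that only fills missing
   genotypes can never contradict a call it was given, so flagging against
   the post-filter callset would make IM2/IM3 structurally empty. The
   conflicts the flags are designed to expose are precisely those between
   imputation and the low-confidence calls the filter masked; the merge is
   therefore done against the original calls. `merge_and_flag` itself is a
   general two-callset operation — callers choose the baseline.
4. **Flag filter** (`filter_by_flag`): IM3 (optionally also IM2) calls are
   set to missing. Dropping IM0/IM1 is refused — those calls carry no
   conflict signal, and removing them would just discard data.
5. **Evaluation** (`concordance`): see below.

Sites are keyed by (chrom, pos, ref, alt **set**) everywhere: two records at
one position with different alt sets are different sites, and alt-order
differences between callsets are resolved by index remapping. A matched
position whose alt *set* differs is skipped and counted. Multiallelic
records are kept whole; half-calls (`./1`) are treated as missing.
VCF coordinates are 1-based, BED intervals 0-based half-open; a site lies in
an interval iff `start ≤ pos − 1 < end`. A FILTER of `.` is treated as
PASS-equivalent (the `bcftools view -f PASS` convention).

## Evaluation framework

Truth sets are prepared by dropping non-PASS sites and masking genotypes
with `GQ ≤ 20` (strict `> 20` retained); MAF-based analyses additionally
require a ≥ 50% call rate (inclusive boundary, configurable).

Per sample, a site counts as a variant call when the genotype is non-missing
and carries at least one alt allele. Then

* recall = TP / (TP + truth-only), precision = TP / (TP + test-only), with
  TP the variant sites called in both sets;
* NCR = concordant / (concordant + discordant) over sites shared by both
  callsets and non-missing in both, after excluding pairs where both calls
  are homozygous-reference and equal;
* minor-allele concordance applies the same exclusion to the *major*
  homozygote at sites with alt AF > 0.5. The AF source defaults to
  truth-cohort allele counting and is configurable; when every alt AF is
  ≤ 0.5 the two modes coincide exactly.

NCR is computed over sites non-missing in both callsets; truth-only sites
lower recall, not NCR. Pooled metrics are count-weighted sums over samples,
so they equal call-count-weighted means of per-sample metrics. Undefined
ratios (zero denominators) are reported as NaN, never silently as 0.
Stratification is the cartesian product of variant type, truth-MAF bin
(half-open `(lo, hi]`, default edge at 2% separating low-frequency
variants), and per-sample coverage bin; region restriction is applied
before site matching.

## Synthetic cohort model

`make_cohort` draws, per site, an alt-allele count `i ∈ {1, …, F−1}` over
`F` founder haplotypes with `P(i) ∝ 1/i` (the neutral-spectrum shape), and
assigns the alt alleles to a uniform random founder subset. Each sample
haplotype copies a founder left-to-right, re-drawing its source founder
with probability `switch_rate` between consecutive sites — a
Li–Stephens-flavoured mosaic that produces the block-wise haplotype sharing
within-cohort imputation exploits, with two parameters instead of a full
coalescent. Truth genotypes are the sums of the two haplotypes.

`simulate_midpass` then sequences each call: depth `d ~ Poisson(coverage)`;
each read copies one of the two true alleles uniformly and flips to the
other allele with probability ε; biallelic genotype likelihoods
`L(hom) = (1−ε)^matching · ε^mismatching`, `L(het) = (1/2)^d` with a flat
prior give the called genotype (argmax, ties broken hom-ref < het <
hom-alt) and `GQ = min(99, round(−10 log10(1 − posterior)))`; `DP = d`;
zero depth yields a missing call. Because reads are generated by exactly
the likelihood model used for calling, simulated GQ is phred-calibrated to
within a small factor (the flat prior vs. the true genotype frequencies is
the only mismatch); the acceptance script measures the worst per-stratum
fold error.

### Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `n_founders` | 8 | haplotypes | founder diversity is scaled down with the desk-scale cohort (~10× smaller than a real study) so the expected number of samples sharing a haplotype pair — what drives imputation — stays in the regime of a large bottlenecked cohort |
| `switch_rate` | 0.005 | per site | ~0.4 expected switches per 81-site window: long shared blocks |
| `coverage` | 4.0 | x-fold | the mid-pass design point; accepts a per-sample list |
| `error_rate` | 0.01 | per read | effective allele-miscall rate of a modern short-read caller input |
| `n_samples`, `n_sites` | 100, 1000 | — | desk-scale defaults; experiments state their own sizes |
| `naive_impute` `window`, `k` | 81 sites, 3 voters | — | window ≈ one haplotype block; few voters keep rare genotypes reachable |

Determinism: all randomness flows from a single integer seed with
per-sample sub-streams, so outputs are bit-identical for identical
configuration regardless of iteration order, and identical pipeline runs
produce byte-identical artifacts.

### The naive imputer

For each missing call, the `k` samples with the highest genotype agreement
with the target over the surrounding `window` sites (pairs with no shared
called sites score 0) vote with their genotype at the locus; the majority
wins, ties break toward the higher-cohort-frequency genotype and then the
lower dosage; a site with no callable voters receives the site-modal (or,
failing that, cohort-modal) genotype. Observed calls are never changed and
the output has no missing calls.

This is test scaffolding, not an imputation method: it is genotype-based
rather than haplotype-based, so it splits the vote at heterozygous targets
and under-calls rare heterozygotes, and its accuracy plateaus well below a
production imputer's. It exists so that the filter → impute → flag →
evaluate loop closes deterministically at desk scale; real runs should
plug in an external imputer via the command template.

## Experiment designs

**GQ sweep** (`gq_sweep`): filter at each threshold, impute, score recall /
precision / NCR against truth. The selected threshold maximizes NCR among
thresholds whose recall *and* precision are each within δ = 0.005 of their
column maxima, falling back to the NCR maximum when no threshold satisfies
both. (A recall-only constraint is degenerate here: at very high thresholds
the naive imputer hallucinates variant calls, inflating recall while
precision collapses, and would capture the constraint.) The NCR-vs-threshold
curve shows the expected interior optimum: no filtering leaves miscalls the
imputer then trusts, over-filtering starves it.

**Coverage dependence**: one mixed cohort with equal thirds at 1x/2x/4x —
matching the binned-by-sample-coverage design of mid-pass studies, where
all samples are imputed together and then grouped — evaluated per coverage
group at the sweep-selected threshold. Performance rises strictly with
coverage with the steepest loss at 1x. Simulating separate single-coverage
cohorts instead changes the result qualitatively (an all-1x cohort lets the
imputer lean entirely on cohort-modal votes), which is why the mixed design
is the one implemented in the acceptance script and tests.

**Flag quality**: per-IM-flag agreement of imputed genotypes with truth
reproduces the expected ordering IM0 ≥ IM1 ≥ IM2 ≥ IM3, with IM2∪IM3 a
small (≈ 1%) fraction of calls; dropping IM3 raises NCR at a recall cost
bounded by the dropped-call fraction. Problem sizes used by the tests and
the acceptance script: 180 samples × 1200 sites for the sweep/coverage
experiment, 150 × 1500 for flags, 500 × 2000 for calibration.

## What the simulation does not show

The generator is biallelic SNVs only (multiallelic and indel handling is
exercised by constructed fixtures); read depth is independent across sites
(no mappability or GC structure); errors are symmetric and independent (no
mapping artifacts, contamination or index hopping, which real IM2 calls
partly reflect); the founder pool is fixed rather than coalescent-derived
(site frequency spectrum and LD decay are stylized, not fitted); and the
naive imputer underestimates what production imputation achieves. Passing
tests demonstrate the pipeline's correctness and its qualitative behaviour
under the stated generative model — not absolute performance numbers on
real cohorts.

## Known limitations

* `vcf-compare`-style site matching only: no haplotype-aware comparison,
  no indel left-normalization, no phasing (switch-error) metrics.
* Reference-panel novelty matches on position + alleles; representation
  differences between cohort and panel (e.g. indel normalization) are not
  reconciled.
* Consequence classification is an exact-term lookup with precedence
  coding > regulatory > other for multi-term variants; unknown terms are
  reported as unclassified rather than guessed.
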