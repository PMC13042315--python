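# Methods

This note documents the models, estimators, defaults and numerical choices
behind `bafscreen`, and what the synthetic-data experiments do and do not
show about real sequencing data.

## The band model of contaminated allele fractions

Reads from a genome of ploidy `p` mapped to a reference give, at each
biallelic SNP site, an alternate-allele read fraction (B-allele frequency,
BAF) that concentrates around `k/p`, where `k` is the number of haplotypes
carrying the alternate allele. When a fraction `c` of reads originates from
a second individual of the same species, a site's expected BAF becomes

    (1 - c) * k/p + c * x,

where `x` is 1 if the contaminant carries the alternate allele and 0
otherwise. The observed distribution is therefore a mixture over band
positions `{(1-c)k/p : k=1..p}` (contaminant reference-like) and
`{(1-c)k/p + c : k=0..p}` (contaminant alternate), each spread binomially
with the site's read depth. `expected_bands` returns these positions
exactly; when the contaminant is known to match the reference everywhere
only the first family applies, so a haploid's single SNP band sits at
`1 - c`.

## Band-fit loss

`band_fit_loss` scores a candidate `(p, c)` model as the mean of truncated
squared z-scores: each site's distance to its nearest band, divided by the
binomial standard deviation `sqrt(pi*(1-pi)/d)` at the site's depth (band
position clipped to [0.005, 0.995] so the scale never vanishes at a band of
1.0), truncated at 3 standard deviations. Truncation keeps repeat-like
sites — which appear at arbitrary allele fractions — from dominating the
fit. Under a correct model the mean truncated z² is close to 1; underfitting
models (a band missing where data sit) score several-fold higher. The loss
threshold `ADEQUACY_LOSS = 1.5` encodes this: a model below it explains the
data adequately.

Two structural properties of this loss required care:

* **Nesting.** Band sets are nested across ploidies (every haploid band is
  also a diploid and tetraploid band), so a plain argmin over `p` drifts to
  `p = 4` on noise alone. Ploidy selection is therefore *adequacy-first
  parsimony*: the smallest `p` whose clean model is adequate wins; only if
  none is adequate does a margin-tied argmin apply.
* **Aliasing.** A min-distance assignment lets a dense band set straddle one
  true band with two model bands and roughly halve the residuals, so raw
  loss comparisons across models with different band counts are not
  meaningful. Two defenses are used: contaminated-model selection is also
  adequacy-first over ascending `p`, and the contamination fraction itself
  is never taken from the loss minimum (next section).

## Estimating the contamination fraction

At fixed `p`, `c` is grid-scanned over [0.01, 0.45] in steps of 0.005 to
seed the band assignment, then refined (twice) as the **median of per-site
implied fractions**: a site assigned to the scaled band `(1-c)k/p` implies
`c = 1 - b*p/k`; one assigned to the shifted band `(1-c)k/p + c` implies
`c = (b - k/p)/(1 - k/p)` (the `k = p` shifted band sits at 1.0 regardless
of `c` and carries no information). This estimator is unbiased where the
truncated loss is not — the loss minimum is dragged by sites that spill into
the saturated 1.0 band — and it dismantles aliasing: two model bands
straddling one true blob imply *opposite-signed* fractions whose median
collapses toward the truth (or toward zero for a clean genome).

The 0.45 ceiling reflects a real identifiability limit: a haploid
contaminated at fraction `1/p'` produces exactly the band positions of a
clean genome of ploidy `p'` (e.g. one third contamination mimics a
triploid), and near 0.5 the pattern merges with heterozygous diploidy. The
estimator prefers the clean interpretation in those regions, so
contamination at ~33% or ≥45% in a haploid is reported as polyploidy — by
design, since band positions alone cannot tell them apart.

## The contamination call and aneuploidy

A genome is called **contaminated** when all of: the fitted fraction is at
least the 5% threshold; at least 5% of SNP sites lie within ±0.03 of a
*secondary* band (a band of the contaminated model farther than 0.03 from
every clean band — for small `c` the shifted bands merge into the clean
ones and support is zero by construction); the secondary band is present at
that support level on every chromosome with ≥100 SNPs; and the genome-wide
median depth is at least 30×, below which the call is flagged unreliable
(near 1.0, contamination of a few percent is not separable from sequencing
error at low depth — also why the call threshold is 5%, not 1%).

Aneuploidy is the chromosome-local counterpart of genome-wide contamination
and is detected by two complementary routes: (i) if every chromosome is
adequately explained by a clean model but their ploidies disagree, the
genome is `aneuploidy_suspect` with the site-weighted majority ploidy
reported and no contamination scan performed; (ii) if a secondary band
clears the genome-wide support floor but is missing from some chromosome,
the same flag is raised. The two flags are mutually exclusive with
`contaminated`.

Defaults: per-site depth floor 10×; ploidy candidates 1–4; parsimony margin
5% (relative) for ties; all thresholds are keyword arguments.

## Synthetic data

The generator emulates the essentials of a resequencing experiment without
an aligner:

* **Reference**: uniform-random nucleotide chromosomes (≥2 chromosomes so
  genome-wide and chromosome-local signals are distinguishable).
* **Panels**: `simulate_panel` evolves haploid tips along a pure-birth tree
  under a single-rate (Jukes–Cantor-like) substitution process, branch
  lengths scaled to a mean pairwise divergence target (default 0.005,
  i.e. ~99.5% identity, typical of within-species strain panels) with a
  floor of 10% of tree height per branch so every split is resolvable from
  a finite alignment. `simulate_lineage_panel` instead builds a radiation:
  independent lineage stems from the root with short terminal branches
  (default 26 lineages × 2 strains = 52 tips), the shape of a structured
  population with named lineages. The phylogenetic experiments use the
  radiation panel because under it diagnostic variation is lineage-specific;
  a rescaled pure-birth tree concentrates much of its length on one basal
  branch shared by most tips, which no real strain panel resembles.
* **Strains**: ploidy 1–4; for polyploids a fraction `heterozygosity`
  (default 0.005) of sites gets a private mutation on 1..p-1 uniformly
  chosen haplotypes.
* **Read counts**: per site, depth `d ~ Poisson(λ)` (default λ = 80, inside
  the 30–165× range typical of the screening context; floored at 1),
  contaminant reads `m ~ Binomial(d, c)`, each read drawing one haplotype of
  its strain uniformly and flipped ref↔alt with error rate ε = 0.002.
  Only variant sites are emitted unless `all_sites` (for consensus-calling
  experiments) or an invariant background fraction is requested. A
  configurable 1% of repeat-like sites with uniform(0,1) allele fractions
  mimics mapping pile-ups in repetitive regions.
* **Mixing linearity** holds by construction: a site where the recipient is
  hom-alt and the contaminant hom-ref has expected BAF
  `(1-c)(1-ε) + cε`.
* `mix_fastq` performs the same mixing on real read pairs (sampling without
  replacement, mate pairing preserved) for users with FASTQ data.

What the generator does *not* model: read-level error profiles and quality
strings, indels and structural variation, mappability and coverage bias,
GC-dependence, or aligner behavior. Consequences: passing tests show the
estimators are correct under binomial read sampling, not that real
contaminated libraries — with overdispersed coverage and reference-biased
mapping — will yield equally tight fraction estimates. In real data the
recipient typically maps better than the contaminant, which sharpens the
`(1-c)` band but biases `c_hat` slightly low.

## Consensus calling

`call_site` is a deliberately small binomial genotype-likelihood caller:
per-site likelihoods `Binomial(alt; d, θ)` with `θ ∈ {ε, 0.5, 1-ε}` for
hom-ref/het/hom-alt (haploid mode drops the het state), flat prior,
`Q = min(99, -10·log10(1 - posterior))`, masking below Q40 (an estimated
error rate above 1 in 10,000), read depth capped at 100,000. Heterozygous
calls render as two-base IUPAC codes, masked calls as `N`; indels never
arise, so consensus length always equals the reference. Strand, mapping
quality and BAQ features of production callers are intentionally absent:
the downstream questions depend only on the genotype category and the Q40
mask. Diploid mode is the default for all ploidies, mirroring the common
practice of running a diploid-model caller across strain panels — which is
exactly why contamination surfaces as heterozygosity.

The characteristic signatures this produces (verified by the test suite):
high-quality heterozygous calls rise monotonically with `c` on a haploid
(a site at alt fraction `1-c` calls het once enough reference reads
accumulate); the masked proportion barely moves (borderline sites are a
tiny fraction of the genome), so contaminated data superficially look like
good data; and haploid heterozygosity reaches clean-diploid levels only
around 20% contamination.

## Distances, trees and placement

TN93 distances use the closed-form estimator with empirical base
frequencies from the pooled pair; F84 distances maximize the pairwise
likelihood numerically under the closed-form F84 transition matrix with the
transition:transversion ratio fixed (default 0.5, which at equal base
frequencies means no transition bias and reduces to Jukes–Cantor; the
implementation is cross-checked in tests against a matrix-exponential grid
oracle and reproduces R `ape` values). Any site where either sequence is
not an unambiguous A/C/G/T — including the IUPAC heterozygous codes — is
removed pairwise. This missing-data convention is the load-bearing fact of
the whole phylogenetic analysis: contamination converts lineage-diagnostic
sites into heterozygous calls, silently deleting them from the distance sums.
Saturated pairs (non-positive log arguments) are flagged undefined rather
than clamped. Pairwise deletion (not complete deletion) is used so one bad
sequence does not shrink the whole alignment; a complete-deletion variant
would only discard more sites.

Neighbor joining is the standard Saitou–Nei agglomeration, deterministic
(ties in the Q matrix resolve to the lowest index pair) with negative branch
lengths clamped to zero and the deficit moved to the sister branch of the
same join. It is exact on additive matrices (property-tested against random
trees and cross-checked against an independent implementation). Bootstrap
supports resample alignment columns with replacement; replicates with an
undefined distance are dropped and counted, and more than 20% drops is an
error. No gamma rate heterogeneity is applied anywhere.

`placement_report` roots a copy of the tree at an outgroup away from both
lineages and reports whether the focal taxon's sibling subtree lies entirely
within the contaminant (or recipient) lineage, plus the unrooted
Robinson–Foulds distance to a baseline tree (bipartition symmetric
difference).

In the end-to-end experiment the consensus of the (possibly contaminated)
recipient *replaces* the recipient's tip in the panel — the sequenced sample
is the only representative of itself, as in any real screening scenario;
its lineage remains represented by the sister strains. This matters: if a
pristine copy of the recipient stayed in the panel, the focal consensus
would remain at distance ≈0 from it at any contamination level (all
conflicting sites are het-masked in the focal) and the placement shift could
never be observed. The recipient/contaminant pair is chosen as the most
divergent pair of the panel, matching how a contamination experiment picks a
donor that is recognizably distinct.

Problem sizes in the shipped experiments: fraction-recovery runs use two
2 Mb chromosomes (~20–25k SNP sites at 0.5% divergence) over 20 seeds;
tree experiments use 52-taxon panels on 50 kb alignments over 10 seeds;
base-calling experiments use 200 kb genomes. These are the package's own
scaled stand-ins for multi-megabase genomes; all sizes are configuration
fields.

## Study-rate statistics

`fisher_exact_rx2` computes the exact two-sided p-value for homogeneity of
contamination rates across studies by enumerating every table with the
observed margins (compositions of the contaminated-column total across rows,
capped by row totals — 495 tables for a 5-study screen with 8 contaminated
genomes), with probabilities in log space (gammaln) and the
probability-ordering rejection criterion including ties at a 1e-7 relative
tolerance. This matches R's `fisher.test` for r×c tables to machine
precision and the classical 2×2 hypergeometric test exactly. `rate_summary`
returns per-study and pooled percentages unrounded.

## Reproducibility

Every stochastic operation takes an explicit seed; a global seed expands
into per-stage child seeds via `numpy.random.SeedSequence` (all below 2³¹),
so stages re-run identically in isolation. `run_experiment` reports are
byte-identical for a fixed configuration, and tabular outputs carry the
configuration hash in a header comment.

## Known limitations

* Contamination at fractions mimicking a ploidy band (≈1/3, ≈1/2) or above
  0.45 is reported as polyploidy — unidentifiable from band positions alone.
* Fractions of 1–4% are estimated but never flagged; at 30–50× depth they
  are not reliably separable from error, hence the 5% call threshold.
* Polyploid genotype likelihoods are not implemented; the diploid-mode
  caller is applied to triploid/tetraploid data as-is.
* Interspecies contamination, contamination *removal*, copy-number
  segmentation and loss-of-heterozygosity mapping are out of scope.
* The distance stage assumes all sequences share reference coordinates; no
  alignment is performed.
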