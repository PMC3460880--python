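# Methods

## The analysis

`pleioscan` quantifies genetic pleiotropy across six cardiovascular-risk
phenotype categories — blood pressure (BP), coronary artery disease (CAD),
type 2 diabetes (T2D), obesity, blood lipids and chronic kidney disease
(CKD) — from a curated table of published genome-wide association signals.
The unit of analysis is the **gene**, not the SNP: reported SNPs are
converted to positional genes, each phenotype accumulates a deduplicated
gene set, and pleiotropy is the membership of a gene in two or more of
those sets. The question the statistics answer is whether the observed
amount of sharing exceeds what finite gene lists drawn from a common pool
would share by chance.

### Inclusion rules

Catalog rows enter the analysis when their study used a genome-wide
discovery platform (≥ 100,000 SNPs; strict `<` excludes smaller platforms),
was neither a copy-number-variant section nor family-based in discovery
(meta-analyses reporting novel variants are kept), and the association
reaches P < 1×10⁻⁵ (strict inequality; the catalog's own reporting
criterion). A robustness rerun at P < 1×10⁻⁷ is a parameter, not a separate
code path. Rows with unparseable positions or p-values are retained with
missing-value markers and counted, never silently dropped, so every
exclusion is auditable.

Trait-to-phenotype and ancestry classification are keyword searches over
free text. Keyword lists are configuration with shipped defaults, because
the trait vocabulary varies across catalog releases; ties are resolved by
the declared phenotype priority order. A sample description naming several
distinct ancestry groups is classed `other_mixed` and contributes only to
the pooled stratum; only European and African strata are analysed
separately, mirroring the composition of the available studies.

### Positional gene assignment

A SNP inside a gene is assigned that gene; if several overlapping genes
contain it, all of them (the conservative superset — the catalog rule does
not address overlap). An intergenic SNP is assigned the nearest gene ending
before it and the nearest gene starting after it, *irrespective of
distance*; left/right are coordinate order, strand is ignored. Coordinates
are 1-based inclusive internally; BED input is shifted on read. Genes
overlapping the MHC region — a config interval, by default the GRCh37
extended MHC chr6:28,477,797–33,448,354, since the region is genome-build
specific — are excluded: its extreme polymorphism and gene density would
otherwise dominate overlap counts. Within one study, a gene counts once per
phenotype regardless of how many SNPs hit it, but the pre-dedup SNP
multiplicity is retained as a weight.

### Overlap nulls

For lists of sizes n₁…n_m drawn from a pool of N genes with observed
intersection k:

* **m = 2** — the exact hypergeometric upper tail P(X ≥ k),
  X ~ Hypergeom(N, n₁, n₂).
* **m ≥ 3** — there is no standard multi-list hypergeometric. Under
  independent uniform subsets, a given gene lies in every list with
  probability p = ∏ nᵢ/N; the intersection size is the sum of N such
  exchangeable indicators and is modelled **Binomial(N, p)** (not Poisson:
  the binomial tail is used directly). The indicators are weakly negatively
  dependent, so the binomial tail slightly overstates the variance-driven
  tail; the discrepancy is negligible when each nᵢ is a few percent of N —
  the regime of real catalog lists (85–219 of 4,105, i.e. 2–5%) — and grows
  with nᵢ/N (at nᵢ/N ≈ 0.1 the absolute error reaches ~0.005 on a tail of
  0.25). A without-replacement Monte Carlo sampler is built in as the
  oracle for this approximation and backs the test suite.
* **Weighted permutation** — catalog genes recur across SNPs and
  phenotypes, so the uniform-pool null is optimistic. Each gene is weighted
  by its number of distinct (SNP, phenotype) appearances (the pair rule; a
  deliberate resolution of an ambiguous "unique SNPs or unique phenotypes"
  counting rule), and each of R = 10,000 replicates redraws every phenotype
  list without replacement with probability proportional to weight. The
  p-value is the add-one estimator (1 + b)/(R + 1), which cannot be zero
  and is exact for exchangeable replicates; its floor is 1/(R + 1) ≈ 1e-4.

Weight-proportional sampling without replacement uses the
Efraimidis–Spirakis exponential-key construction (keys log Uᵢ/wᵢ, keep the
top nᵢ), which has exactly the law of sequential draws with weight
renormalization but vectorizes over replicates. With uniform weights it
reduces to uniform subsampling, so the permutation test then estimates the
exact hypergeometric tail — a cross-check the suite exercises.

Per-combination random substreams are derived from the top-level seed and a
CRC of the phenotype combination, so adding or removing a combination never
perturbs another's p-value. No multiple-testing correction is applied
across combinations, and effect directions and sizes are not modelled —
both are outside what the catalog rows support.

The pool size N defaults to the number of distinct non-MHC positional genes
actually ingested and can be pinned by config (e.g. to 4,105, the size of
the full-catalog pool the published list sizes refer to).

### Networks

The genetic graph has one node per phenotype with
`size_fraction = nᵢ / Σⱼ nⱼ` — the **with-multiplicity** denominator, so a
shared gene is attributed to every phenotype it touches (a distinct-gene
denominator is a toggle) — and an edge wherever a pairwise intersection is
non-empty, weighted by its size. The reference graph is a user-declared
epidemiological edge list (default: complete 6-clique; the canonical edge
set exists only as a figure in the source literature, so it is config). An
edge is *replicated* when present in both graphs; the replication fraction
is over reference edges. Graphs serialize to GraphML, DOT and a JSON
summary; rendering exists but no test compares pixels.

## Synthetic data

The generator emulates the catalog inputs at one tenth the scale of the
real snapshot, chosen once as the package's study conditions: a pool of 410
genes on 4 chromosomes, per-phenotype target list sizes
{BP 9, CAD 10, T2D 14, Obesity 22, Lipids 14, CKD 11}, 3 studies per
phenotype, ancestry mix 76% European / 5% African / 19% other (the
composition of the eligible studies), an intergenic SNP fraction of 0.44
(the fraction of intergenic signals in the real data), signal p-values
log-uniform on (10⁻¹², 10⁻⁶) so the stringent 10⁻⁷ rerun prunes some of
them, and decoy material straddling the 10⁻⁵ threshold. Decoy studies
violating each inclusion rule (family-based, CNV, 90,000-SNP platform), an
above-threshold association, an MHC-gene association and an unclassifiable
trait are emitted alongside and recorded as expected exclusions.

Fill genes are allocated disjointly across phenotypes, so overlap arises
only from planted pleiotropy (genes given one SNP per phenotype of a
declared combination) and — when the intergenic fraction is positive — from
the flanking rule, whose side-effect genes the generator records in the
ground truth as it places each SNP. Ground truth is therefore built during
generation, never by re-running the pipeline. One seed governs annotation
and catalog through derived substreams.

What the generator does **not** emulate: linkage disequilibrium, allele
frequencies, genotyping platforms' marker ascertainment, gene-size bias in
SNP capture, and correlated trait definitions across studies. Passing
recovery tests therefore demonstrates that the bookkeeping — filters,
positional rules, dedup, set algebra, null computations — is correct, not
that real catalog mining is free of those biases.

The null ensemble used for calibration emits draws at the gene-list level
(phenotype → gene list), since the calibration property consumes only list
sizes and intersections. Its default configuration — a 500-gene pool with
two lists of 50 — was fixed by a design calculation: the exact two-list
intersection tail there has P(X ≥ 9) = 0.048, so a nominal α = 0.05 test is
actually attainable despite the discreteness of intersection counts.
(Discreteness is the binding constraint on any such calibration study: with
a coarse intersection distribution no resampling test can reject at close
to the nominal rate.)

## Numerical and design notes

* Threshold comparisons are strict (`<`) everywhere; boundary values are
  excluded, matching the catalog's stated criteria.
* Two genes flanking one signal count as two genes (the positional
  definition); `collapse_regions` offers the per-region alternative in
  which such a pair becomes one `LEFT|RIGHT` unit.
* Overlap enumeration reports **all** combinations with non-empty
  intersections, not only maximal ones — nested 3-way overlaps inside a
  4-way are genuine results; the per-gene pleiotropy report gives the
  maximal view.
* Flank ties (two genes ending at the same coordinate) resolve by symbol
  order; SNP positions at a gene boundary are `within`.
* Monte Carlo and permutation computations are chunked over replicates to
  bound memory; results are invariant to chunk size given the seed.
* Test problem sizes (pools of a few hundred genes, 10⁵ oracle draws,
  500-instance calibration) were chosen so the full suite completes in a
  few minutes while keeping Monte Carlo standard errors well below the
  effects being verified.

## Known limitations

* The Binomial(N, ∏nᵢ/N) multi-way tail is an approximation whose accuracy
  degrades as list sizes approach ~10% of the pool; use the Monte Carlo
  method there. Published three-way values computed with an unstated
  multi-way formulation can differ from this closed form in the third
  decimal (e.g. 0.003 vs 0.0037); such rows are treated as near-match only.
* Keyword classification is as good as the keyword lists; shipped defaults
  cover common trait phrasings, not all of them.
* rsIDs are taken at face value (no dbSNP resolution), annotation build
  choice is the caller's, and no LD-based region definition is attempted —
  the flanking-gene rule is deliberately naive about LD.
* Absence of overlap in sparse strata (e.g. few African-ancestry studies)
  reflects data availability, not absence of pleiotropy; the stratified
  comparisons inherit this censoring.
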