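# Methods

## Model

A sample's observed library is treated as a finite population of $N$ reads
distributed over $k$ features with counts $n_1,\dots,n_k$. Rarefying to depth
$d$ asks: what data might have been observed had the sample yielded only $d$
reads?

- **Without replacement** the rarefied profile is a multivariate
  hypergeometric draw with parameters $(n_1,\dots,n_k;\,d)$: a uniformly
  random $d$-subset of the observed reads. This is the default because it is
  the literal answer to the question above — every rarefied count is bounded
  by its observed count, and at $d=N$ the draw is the identity.
- **With replacement** the profile is multinomial with $d$ trials at the
  observed proportions. It approximates the hypergeometric when $d \ll N$ but
  can inflate a rare variant beyond its observed count and omits rare variants
  slightly more often, which measurably lowers the mean Shannon index relative
  to without-replacement at matched depth on long-tailed communities.

Repeating the draw $R$ times (default $R=1000$, configurable because fewer
repetitions can suffice when libraries are deep relative to the chosen depth)
produces an ensemble whose spread is exactly the variability the
normalization itself introduces. The ensemble is the unit all downstream
analyses consume.

Without-replacement draws are generated by numpy's
`multivariate_hypergeometric(method="marginals")`, i.e. sequential
conditional (univariate) hypergeometric draws per feature — exact and
O(features) per draw without materializing an expanded read vector.

## Random-stream discipline

The stream for cell (rep $r$, sample $s$) is
`np.random.default_rng([seed, r, s_index])`, where `s_index` is the sample's
position in the *input* table (so dropping an undersized sample does not shift
its neighbours' streams). Consequences: ensembles are bit-identical across
runs and worker counts; different base seeds give independent ensembles; and
repetitions are independent across reps and samples by construction.

## Depth selection

`suggest_depths` enumerates each observed library size as a candidate depth,
marking the smallest one inclusive (no samples dropped) and listing, for every
larger candidate, the samples that would be excluded. The recommended practice
is a dual analysis: an inclusive smaller depth retaining all samples, and a
larger depth that drops shallow samples but preserves more diversity. The
analytic expected rarefaction curve
$E[S_d]=\sum_i\left[1-\binom{N-n_i}{d}/\binom{N}{d}\right]$ (log-gamma
arithmetic, exact for without-replacement draws, non-decreasing in $d$)
supports this choice without simulation; simulated curves add the
inter-repetition ribbon.

Samples below the chosen depth are dropped with a logged warning by default
(`undersized_policy="drop"`); an `"error"` policy is available for pipelines
that must not silently lose samples.

## Alpha diversity

Shannon index with the natural logarithm (so $\exp H$ equals the Hill number
of order 1 exactly; the identity is asserted to 1e-12 in the tests), computed
per rarefied profile; zero counts contribute nothing. Hill numbers
$^qD=(\sum p_i^q)^{1/(1-q)}$ use exact branches at $q=0$ (richness) and $q=1$
($\exp H$) and are continuous across $q=1$ to better than 1e-4 at
$q = 1 \pm 10^{-6}$. Orders 0, 1, 2 are reported by default. Chao1 is
deliberately absent: denoising pipelines remove singletons, which invalidates
it. Band bounds are empirical 2.5–97.5% quantiles (linear interpolation)
across repetitions — a choice; the band level is configurable.

## Beta diversity and ordination

Each rarefied replicate is Hellinger-transformed
($h_i=\sqrt{c_i/\sum_j c_j}$, applied *after* rarefaction) and all
(sample, rep) profiles are pooled into a single Bray–Curtis distance matrix,
so every replicate point lives in one common ordination space; this is what
makes the per-sample "patches" directly overlayable. The alternative —
ordinating each repetition separately and Procrustes-aligning — was rejected
as it introduces alignment artifacts. Raw-count Bray–Curtis and
presence/absence Jaccard are also available.

The ordination is classical scaling (principal coordinates): Gower double
centering of $-\tfrac12 D^{\circ 2}$, eigendecomposition, coordinates scaled
by $\sqrt{\lambda}$. Bray–Curtis is a semimetric, so negative eigenvalues
occur; they are truncated and counted, and explained-variance proportions are
taken over the sum of positive eigenvalues only. A Lingoes correction
(adding $2c$, $c=-\lambda_{\min}$, to off-diagonal squared dissimilarities) is
available behind `negative_correction="lingoes"` but off by default: the
corrected space subtly rescales all distances and the uncorrected truncation
is the conventional reporting. Axis signs are fixed so each axis's
largest-magnitude coordinate is positive, making coordinates reproducible.
`patch_dispersion` summarizes each sample's patch as the mean Euclidean
distance of its replicate points to their centroid in the retained axes.

## Synthetic communities

`generate_community` builds, per sample, a true composition from a rank-
abundance model — uniform, geometric series ($p_i \propto r^i$), or a sorted
Dirichlet draw — optionally truncated to a per-sample richness (top-$r$
features, renormalized), with optional group structure in which a chosen
fraction of features have their abundances permuted between groups. Counts
are drawn multinomially at the requested library size, so column sums match
the request exactly; `exact_totals=False` switches to independent Poisson
counts with the same expectations, whose totals fluctuate the way real
library sizes do.

The `paperlike` preset is six samples A–F over a 1000-feature pool with
geometric abundances (ratio 0.98), richness 500/400/300/200/120/60, library
sizes 35000/20000/12000/8000/3000/500, and two compositional groups (A–C vs
D–F, 25% divergence). The geometric series is the default skew because its
long tail is the regime where rarefaction visibly suppresses the Shannon
index; the size span forces the inclusive-vs-exclusive depth dilemma that
motivates repeated rarefaction in the first place. What the generator does
*not* emulate: taxonomic correlation structure, PCR/primer bias,
over-dispersion beyond multinomial sampling, chimeras, or sequencing error.
Passing tests therefore demonstrate correctness of the subsampling and
diversity machinery under known truth, not robustness to those real-data
artifacts.

## Numerical choices and edge cases

- Counts are validated as non-negative integers at ingestion; fractional
  cells are an error (never silently rounded).
- Library-size minima break ties to the first sample in table order.
- `expected_richness_analytic` uses log-gamma arithmetic; agreement with the
  enumeration oracle is ~1e-8 absolute, which the tests allow for.
- Dispersion of an unrarefied sample is zero up to eigendecomposition
  round-off (< 1e-9 in practice, asserted at that tolerance).
- Degenerate inputs: all-zero profiles are errors for proportions, Shannon,
  Hellinger; empty (0-feature) tables are legal for IO and filtering.
- Problem sizes used in the validation suite: enumeration-oracle checks use
  toy libraries (N ≤ 12 reads) at 100,000 draws; curve-vs-analytic checks use
  10,000 repetitions; ensemble-level trend checks use the six-sample preset
  at 100–1000 repetitions over the depth ladder 5000/1000/500/100. These
  sizes give Monte-Carlo noise well below the asserted effects while keeping
  the default suite fast on one CPU.

## Known limitations

- Repeated rarefaction characterizes the variability introduced by
  normalization; it does not quantify uncertainty about diversity in the
  source community the sample was drawn from.
- Studies focused on detecting very rare variants are poorly served by any
  rarefaction-based normalization, since rare variants are regularly
  discarded at reduced depths (`spike_rare_variants` exists to demonstrate
  precisely this).
- UniFrac-type phylogenetic distances, NMDS, differential-abundance testing,
  and alternative normalizations (CLR, variance-stabilizing transforms, etc.)
  are out of scope.
- TSV ingestion assumes features-as-rows (a `samples_as_rows` orientation
  override exists); BIOM is supported in both JSON 1.0 and HDF5 2.1 forms.
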