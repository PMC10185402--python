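# Methods

## Model and assumptions

Gene scoring treats the vector of inverse-normal-transformed SNP p-values
**z** (z_i = Phi^-1(1 - p_i/2), two-sided) for the SNPs in a gene region as
multivariate normal under the null, z ~ N(0, Sigma_G), where Sigma_G is the
SNP-SNP Pearson correlation matrix estimated from a reference genotype panel.
The score T_G = sum_i v_i z_i^2 (v_i = 1 unless SNP weights are supplied)
then follows Xi = sum_i lambda_i chi2_1 with lambda_i the eigenvalues of
Sigma_G (of D_v^{1/2} Sigma_G D_v^{1/2} in the weighted case), and the gene
p-value is P(Xi > T_G).

Assumptions worth stating explicitly: the GWAS z-scores are standardized
(hence correlation, not covariance, is the right second moment); the panel
population matches the GWAS population's LD; no correction is made for
sample overlap between the GWAS and the panel, for conditional signals, or
(in the cross tests) for trait correlation induced by shared samples.

## Tail probabilities of chi-square mixtures

`lincomb` evaluates S(q) = P(Xi > q) five ways.

**Ruben's series** (positive coefficients). The CDF is a mixture of central
chi-square CDFs, `sum_k a_k F_{chi2(N+2k)}(q/beta)`, with a_0 =
prod(beta/lambda_i)^{1/2}, g_k = (1/2) sum_i (1-beta/lambda_i)^k and a_k =
(1/k) sum_{j<k} g_{k-j} a_j. The scale parameter defaults to beta =
2*lmin*lmax/(lmin+lmax) (exposed as an option; any beta in (0, 2*lmin) is
accepted), which makes gamma = max_i |1-beta/lambda_i| = (lmax-lmin)/
(lmax+lmin) < 1. Truncation uses the rigorous coefficient-wise bound |a_k| <=
a_0 C(k+N/2-1, k) gamma^k (from dominating the generating function
a_0 exp(sum_k g_k t^k / k) term by term), summed geometrically once the term
ratio drops below one; the series stops when that remainder bound falls below
10^-digits *relative to the tail scale*. The tail scale is pre-estimated with
the saddle-point approximation; it also sets the extra working digits needed
to absorb the 1 - CDF cancellation when S(q) is tiny. Backends: vectorized
float64 for digits <= 15, mpmath beyond.

**Characteristic-function inversion** (any-sign coefficients). S(q) for
q > 0 is the Bromwich integral (1/2 pi i) \int M(s) e^{-sq}/s ds over a
vertical line through c in (0, 1/(2*lambda_max+)), with M(s) =
prod(1 - 2 lambda_i s)^{-1/2}. On the real axis (the classical inversion
grid) the integrand decays only polynomially for central chi-square terms,
which caps reachable absolute accuracy; we therefore deform the line onto two
conjugate rays s = c + r e^{+-i pi/3} anchored at the saddle point of
M(s)e^{-sq} (clamped inside the analyticity strip). The deformation is valid
because the sector between the vertical line and the rays contains no branch
cut (all cuts of M sit on the real axis), and on the rays the integrand
decays like e^{-qr/2} and does not oscillate, so quadrature converges at any
precision. Conjugate symmetry reduces the answer to S(q) = (1/pi) Im[e^{i
beta} \int_0^infty M(c+re^{i beta}) e^{-(c+re^{i beta})q}/(c+re^{i beta})
dr]. The float64 backend integrates log-graded composite Gauss-Legendre
panels out to r where e^{-qr cos beta} < 1e-300; the mpmath backend uses
adaptive quadrature with breakpoints at the scale of the nearest branch
point, escalating the quadrature degree until the reported integration error
plus the rigorous truncation bound |f(R)|/(q cos beta) is below
10^-digits/2 (again relative to the saddle-point tail scale). Special cases:
q = 0 uses the Gil-Pelaez integral on the real axis (smooth, non-oscillatory
at q = 0); q < 0 and all-negative specs reduce by S(q) = 1 -
S_{-lambda}(-q).

The two exact routes share no code path beyond the spec container, which is
what makes their 100+-digit agreement (see `scripts/acceptance.py`) a
meaningful cross-verification.

**Moment approximations.** Satterthwaite-Welch matches two moments to a
scaled chi-square (scale s2/s1, dof s1^2/s2 with s_r = sum lambda^r);
Imhof-Pearson matches three (dof h = s2^3/s3^2, abscissa h + (q-s1)
sqrt(2h/(2 s2))). Both are exact for equal coefficients and drift
anti-conservative (overestimate significance) deep in the tail for skewed
spectra — by an order of magnitude for Satterthwaite at p ~ 1e-8 — which the
test suite asserts.

**Saddle-point.** We use the *second-order* Lugannani-Rice formula: with
K(z) = -(1/2) sum log(1-2 lambda_i z), saddle K'(zhat) = q, w =
sign(zhat) sqrt(2(zhat q - K(zhat))), v = zhat sqrt(K''(zhat)), rho_r =
K^{(r)}/K''^{r/2},

    S(q) ~= PhiBar(w) + phi(w) [ (1/v - 1/w)
            + (rho4/8 - 5 rho3^2/24)/v - 1/v^3 - rho3/(2 v^2) + 1/w^3 ].

The common first-order form (PhiBar(w + log(v/w)/w)) was measured at ~10%
relative error at p ~ 1e-8 whenever one eigenvalue dominates — the generic
situation for LD spectra — while the second-order form stays within ~4%
there and within ~0.3% for near-equal spectra (verified against the exact
backends across spectra and tail depths down to 1e-10). Near the removable
singularity at the mean (|q - sum lambda| < 0.1 sd) the same expression is
evaluated at 60 working digits, because the 1/w and 1/w^3 terms cancel
analytically but catastrophically in float64; exactly at the mean the
midpoint of two symmetric nearby evaluations is returned. Mixed-sign
coefficients are supported (the strip and root bracketing handle them).

**Automatic switching** (`sf_auto`). The saddle-point approximation is the
default for positive spectra (hint `saddle`); hint `exact` (and every
mixed-sign spec, which always routes to the CF backend) evaluates at 15
digits and doubles the precision (15 -> 30 -> 60 -> 100, capped at 100)
while the value sits at or below the floor distinguishable from zero at the
current precision (10^-(d-5); the first-level trigger is the policy's
`tail_floor`, default 1e-10). Hint `auto` runs the saddle first and falls
back to the exact ladder when the approximate tail is below the floor. If
the maximum precision still cannot resolve the value the result is returned
flagged rather than raised. Every result carries provenance (method, digits)
and log10(p) computed at working precision, so downstream ranking never
relies on an underflowed double.

## Reference panel store

VCF (plain or gzipped, GT fields, biallelic; multi-allelic records are
skipped with a warning) is imported into one binary file per chromosome of
zlib-compressed, versioned per-variant records (documented byte layout in
`refpanel.py`) plus a JSON index by position and variant id. Only indices are
held in memory; payloads decode lazily, and the store pickles across worker
processes. Default filters: MAF >= 0 (off) and missing rate <= 0.05, both
configurable — conventional values, since panel QC is study-specific.
Missing genotypes are mean-imputed per variant before standardization;
monomorphic variants are dropped (a gene whose SNPs are all monomorphic is
reported unscorable). Duplicate variant ids: last wins in the panel (VCF
order), first wins in summary statistics, both logged.

## Gene scoring choices

- Default window: 50 kb each side of the transcript, symmetric regardless of
  strand (strand is carried but not used); configurable.
- p-value sanitization: p > 1 rejected; p <= 0 or < 1e-300 clipped to 1e-300
  with a warning (Phi^-1 stays finite at the floor: z ~ 37).
- Eigenvalue pruning: clip small negatives to zero, drop lambda < 1e-8 *
  lambda_max; near-zero eigenvalues carry no probability mass but would
  slow the exact backends.
- Per-gene failures never abort a run; genes with no qualifying SNPs are
  rows with NaN p and a note. Output tables are sorted by gene id and are
  byte-identical for any worker count and across reruns (the provenance
  hash excludes the worker count and output path).

## Cross-GWAS tests

Signed scores require effect signs and effect alleles in both studies.
Harmonization orients both GWAS to the panel's alt allele (sign flipped when
the effect allele is the panel ref), drops variants whose allele pair does
not match the panel, and by default drops strand-ambiguous A/T and C/G
variants — a wrong strand assumption would silently flip signs and corrupt
the product statistic, so the strict policy is the default (retainable by
flag).

The coherence null uses z_i w_i = ((z_i+w_i)^2 - (z_i-w_i)^2)/4: each
eigenvalue lambda of Sigma contributes the pair {+lambda/2, -lambda/2}
(coefficients sum to zero). The ratio test computes the plug-in tail P(Xi(r*)
> 0) where r* is the observed ratio and Xi(r) has the eigenvalues of the
block matrix [[-r Sigma, Sigma/2], [Sigma/2, 0]] (the similarity-reduced
form of M^T B(r) M with M = blockdiag(Sigma^{1/2}, Sigma^{1/2})); no
correction is applied for r* being estimated, matching the construction of
the underlying method. Both directional tails are reported separately; they
sum to one for the coherence test.

## Pathway scoring

Members of a gene set whose windowed regions overlap on the same chromosome
(transitive closure, computed by a sweep over start-sorted genes) are fused
into a meta-gene, rescored as a single gene on the union of member SNP
windows — this removes LD-induced correlation between member scores. The
fusion window defaults to the scoring window and is configurable. Gene
p-values are converted to ranks over the genome-wide background of scored
genes (average ranks on ties), u = rank/(M+1), then to chi2_1 quantiles at
1-u; the pathway statistic is the sum over the N scoring units and is tested
against chi2_N. Meta-genes replace their constituents in the ranking
background for that pathway's test only. Unscorable members are excluded
from both N and the sum, and counted in the report.

## Synthetic data

The generator draws, per LD block, a latent Gaussian with exchangeable
correlation rho and thresholds it at the Hardy-Weinberg cutpoints
Phi^-1((1-f)^2), Phi^-1(1-f^2) for an allele frequency f drawn uniformly
from [0.1, 0.5] (avoiding monomorphic fixtures). Thresholding attenuates
latent rho = 0.9 to genotype LD of roughly 0.6-0.8 at these frequencies
(measured at n = 5000); tests assert the measured band. Null summary
statistics draw z ~ N(0, Sigma) per contiguous variant chunk using the
panel's *empirical* correlation, so gene scoring sees exactly the null its
model assumes; signal GWAS add a mean shift to the causal gene's z before
the p conversion, leaving the same seed's null stream otherwise untouched.

What passing calibration tests show — and do not show. Because the synthetic
null is exactly multivariate normal with the panel's own Sigma, uniform gene
/ coherence / ratio / pathway p-values (KS tests over hundreds of genes and
seeded replicates) validate the distribution theory and its numerical
evaluation. They do not probe panel-vs-GWAS LD mismatch, non-normal effect
distributions, genotype imputation error, or real LD block structure, all of
which real data bring.

## Problem sizes in the test and acceptance runs

Calibration suites use 200-600 genes of 3 SNPs (panels of 300-400 samples)
with 2-3 replicates per family and random 10-gene sets for pathways; the
Monte-Carlo oracles use 2e6 draws (binomial SE sets the assertion width);
the high-precision cross-verification uses a 4-coefficient spectrum at
q = 50 and 100-digit precision. These sizes make the whole suite run in a
few tens of seconds while leaving every assertion statistically meaningful.

## Known limitations

- Per-term degrees of freedom are fixed at 1 and non-centrality at 0; the
  mixture is exactly the gene-score null, not a general quadratic-form
  engine.
- The float64 exact backends target ~1e-13 absolute accuracy; tails below
  the precision floor escalate to mpmath, which is pure-Python and slower.
- Ruben's series convergence degrades as lmax/lmin grows (gamma -> 1); the
  CF backend has no such sensitivity and is the fallback.
- BGEN/PLINK-BED input, dosage genotypes, conditional analysis and
  sample-overlap corrections are out of scope.
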