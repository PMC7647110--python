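# Methods

## Model

A medium contains n distinct genomes.  A *sample* is a random draw of
organisms from a large parent population, so the copy number tᵢⱼ of
genome j in sample i is a random variable, independent across genomes
and across samples.  Each sample is summarized by its barcode spectrum
(BS): the 4^k vector of k-word counts over both strands (k = 6 by
default, dimension 4096).  Ignoring sequencing error, sample spectra are
nonnegative integer combinations of the n genome spectra; the central
modeling assumption — well supported for real genomes, whose
oligonucleotide compositions differ systematically between species — is
that distinct genome spectra are linearly independent.  The number of
distinct genomes is then the linear dimension of the sample-spectrum
set, and copy-number fluctuations guarantee that repeated samples
explore the whole span.

Two copy-number models are implemented:

* **normal** — tᵢⱼ = max(0, round(N(m, σ))).  Rounding makes copies
  integral; the clip handles the negative tail the model ignores (at the
  default m = 10, σ = 3 the clipped mass is ≈ 4·10⁻⁴).  The mean
  absolute deviation of the rounded value from m is the series
  Σ_{d≥1} 2d·[Φ((d+½)/σ) − Φ((d−½)/σ)] = 0.7636, 1.5790, 2.3825 at
  σ = 1, 2, 3.
* **discrete** — tᵢⱼ drawn from a finite per-genome value set aⱼ
  (uniformly, or with supplied probabilities).  The two-value set {0, 1}
  is the worst case for basis building.

## Estimators

**Exact rank (error-free data).**  Samples are offered one at a time to
a growing orthonormal basis (modified Gram–Schmidt, two passes); a row
is dependent when its residual is < 10⁻⁸ of its own norm — safe for
integer count data, and verified against exact rational rank (Bareiss
fraction-free elimination) in the tests.  Termination: stop after
`stop_m` consecutive dependent samples; the probability that the basis
is complete is then ≥ 1 − (1 − p)^stop_m, where p ≥ 1 − s⁻¹ ≥ ½ is the
per-draw chance of an independent sample (λ/(1+λ) for non-uniform
measures, λ = exp(−1/(2σ₀²)) in the normal model).

**PCA marker pattern (noisy data).**  Rows are centered by their mean
and decomposed by SVD.  f(n) is the *sum of Euclidean distances* (not
squared distances — squares would change the derivative shapes) of all
rows to the span of the first n principal components, for n = 1 …
min(N−1, 4^k) − 1.  The normalized derivatives f′~ and f′′~ are formed
as finite differences divided by the current value; the genome count is
argmax f′′~ + 1.  Why +1: the last component still carrying genome
signal produces the final large relative drop f(n) → f(n+1) at
n = count − 1, so the f′′~ peak sits one below the count.  The estimate
carries an intrinsic ±1 band and all end-to-end checks use it.

Numerical guards: positions where f′~ < 10⁻¹² are masked from the argmax
(the formula divides by f′~); exact ties go to the lower n and are
flagged ambiguous; a curve with no positive f′′~ above 10⁻⁹ raises an
explicit "no marker pattern" error rather than guessing.  If f itself
reaches numerical zero (≤ 10⁻⁹ of the zero-component distance) the data
are exactly low rank; the first such n *is* the count, because with more
samples than rank the centered matrix generically retains the full rank
of the row span.  The `auto` dispatcher uses the exact path whenever the
row set is numerically rank-deficient and the PCA path otherwise, and
refuses marker detection below 5 samples.

## The simulator

The generator emulates pooled whole-metagenome sequencing at the
spectrum level (it produces no reads):

* **Synthetic genomes** are sampled from a per-genome random Markov
  chain of order 2 whose conditional letter distributions are
  Dirichlet(5).  This is the load-bearing fidelity choice: plain uniform
  i.i.d. letters make all 6-mer spectra collapse onto the
  flat-composition direction, differing only by O(√L) sampling noise —
  no two real species look like that, and the independence premise (and
  any recovery) fails.  Letter-level bias alone is also insufficient:
  it spans a 3-parameter manifold that cannot hold 10–15 spectra in
  general position.  Order-2 bias (48 free parameters per genome) gives
  a GC-content spread of ≈ ±0.10 and pairwise spectrum angles of
  roughly 0.3–1.3 rad — broad and bounded away from zero, as observed
  across real bacterial genome collections.  Default length 50 kb:
  large enough for well-conditioned spectra, cheap enough for hundreds
  of simulated metagenomes.
* **Sequencing loss and error**: each genome g gets a fragment set
  G(g, f) of 20 spectra (10 for the partition scheme), each the spectrum
  of a fragment covering fraction f of the genome with letters
  substituted independently at 10⁻³ (no indels).  `random_window` reads
  one contiguous window of length round(f·L) at a uniform start on the
  circular genome — the simplest reading of "a fragment comprising 75%
  of the genome", matching circular bacterial chromosomes; at f = 1 the
  window is not rotated, so the fragment equals the genome exactly.
  `partition_exclusion` (f = 0.9) cuts the genome into 10 equal parts
  and concatenates the 9 parts omitting each one in turn (pairwise
  difference 20%).
* **A sample row** sums, for each genome g with t_g copies, t_g fragment
  spectra drawn uniformly *with replacement* from G(g, f).  Coverage
  depth, read length, chimeras, abundance profiles from real surveys,
  and strain-level mixtures are all out of scope — so passing tests
  show that the *estimators* behave as designed under the stated noise
  model, not that real library preparation matches that model.

All stochastic steps consume one caller-provided RNG in documented
order, so every experiment is reproducible from its seed, and sample
sets carry their full generating configuration as provenance.

## Virtual samples

Known genomes (a spectra library) are appended to the real samples as
virtual rows; the estimated total dimension minus the number of distinct
library genomes added counts the genomes absent from the library.  Four
designs: one clean spectrum per row, clean random mixtures, one
error-bearing fragment spectrum per row, error-bearing mixtures.
Choices the underlying scheme leaves open, and how they are resolved
here:

* **Amplitude.**  Row scale is free (dependence is scale-invariant), but
  PCA geometry is not: a real row sums ~m·p fragment spectra, a virtual
  row holds one genome spectrum.  Virtual rows are rescaled to 0.2× the
  median real-row norm — about one genome's contribution to a sample:
  comfortably above the sequencing-noise floor without amplifying the
  virtual rows' own errors into spurious dimensions (full-norm scaling
  does exactly that to the error-bearing designs; at 0.05× the clean
  directions sit marginally at the floor).  The factor was fixed by a
  small calibration scan across all four designs and is exposed as
  `virtual_scale`.
* **Counts.**  Clean designs get one row per selected genome — clean
  spectra carry no information beyond the genome count, and redundant
  clean rows push an exact-zero residual tail into the detection range.
  Error-bearing mixtures get 2× (their rows are all linearly
  independent, so extras help).  Mixtures include each genome with
  probability ½ (empty mixtures redrawn) at integer coefficients
  uniform on {1, 2, 3}, mirroring small copy numbers.
* **Dispatch.**  Exact-rank vs PCA is decided on the *real* rows alone
  (a clean, rank-deficient virtual block must not drag noisy data onto
  the exact path), and within the PCA read-out the marker peak takes
  precedence over the stacked-rank zero tail (`prefer_peak`).

At desk scale the clean single-genome design is clearly the best, as
expected; among the rest the ordering differs from larger-scale
experience (clean mixtures suffer most here), driven by the 50 kb
stand-ins' smaller spectrum-to-noise ratio.

## Problem sizes in the checks

End-to-end verification runs at sizes chosen for a laptop-class budget:
recovery of 10 genomes from 20 samples over 50 simulated metagenomes
(expecting ≥ 80% of estimates within ±1), marker-peak position for 15
genomes / 30 samples over 25 metagenomes, σ = 3 vs σ = 1 ordering over
30 + 30, and the virtual-design comparison over 50.  The combinatorial
bounds are verified exhaustively for all n ≤ 6, s ≤ 3 with hundreds of
random spanning sets per instance (exact rational arithmetic), and the
n/p sampling-length law by 10⁵ simulated waiting times per grid point.

## Known limitations

* The marker read-out is deliberately primitive (a masked argmax); a
  human reading the curves, or a model-based elbow detector, would do
  better on marginal data.  No alternative intrinsic-dimension
  estimators (parallel analysis, Marchenko–Pastur thresholds) are
  provided.
* The method counts genomes; it cannot say *which* library genomes are
  present.
* Genomes of the same species/strain have (near-)identical spectra and
  are counted once; conversely the ±1 band is irreducible at realistic
  noise.
* Sensitivity degrades as the genome count approaches the number of
  samples (the residual curve needs room beyond the signal components)
  and as spectra shrink relative to fragment noise (short genomes, high
  error rates).
* Raw counts are used throughout; per-sample normalization is
  deliberately not applied before PCA (it would distort the copy-number
  signal that the method feeds on).
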