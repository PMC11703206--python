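# Methods

## The measurement being modelled

A degenerate peptide-display library (for instance eleven fully random
residues, X11, or five random residues on either side of a fixed central
tyrosine, X5YX5) is displayed on bacteria, enzymatically phosphorylated,
and repeatedly passed over beads carrying an immobilized phosphotyrosine-
recognition domain (an SH2 domain).  In every selection round the library
is deep-sequenced before (input) and after (bound) capture.  Sequences
that bind the domain are enriched in the bound sample; chaining rounds
compounds the enrichment.  The quantity of scientific interest is the
additive free-energy matrix ddG/RT: the per-position, per-residue
contribution of the sequence context around the phosphotyrosine to the
binding free energy.

## Enrichment model

For a peptide s of length L = 11 displayed between the constant scaffold
residues GQSGQ (left) and GGQSG (right), the predicted enrichment in
count table c is a sum of two binding-mode terms,

    kappa_c(s) = alpha_{c,NS} * sum_{x=1}^{L-w_NS+1} exp( X(s,x:x+w_NS) . beta_NS + gamma_x )
               + alpha_{c,S}  * sum_{x=1-f_S}^{L+f_S-w_S+1} exp( X(s,x:x+w_S) . beta_S )

where X(.) is the one-hot encoding of the subsequence at offset x.  The
specific mode uses windows of width w_S = 11 and slides over the variable
region padded with up to f_S = 5 flanking scaffold residues (a binding
site may straddle the boundary), giving exactly 11 offsets.  The
non-specific mode uses short windows (w_NS = 3 by default; 1 when a
3-mer window would be wide enough to absorb the main specific motif, as
happens for domains with compact motifs such as Grb2's YxN) plus a
per-offset bias gamma_x, and does not overlap the flanks.  Entries of
beta_S are log-fold binding effects, i.e. -ddG/RT.

To anchor the specific mode on phosphotyrosine, its central column can be
frozen to 0 for tyrosine and -10 for every other residue.  The -10 value
acts as a hard veto (e^-10 ~ 5e-5) while keeping the model differentiable.

## Likelihood

Each count table is treated as a single-round SELEX experiment.  With
eta_{c,I} and eta_{c,B} controlling relative sequencing depth, a read of
sequence s_i lands in the bound column with probability
eta_B kappa / (eta_I + eta_B kappa).  The data term is the scaled
binomial log-likelihood

    l_data = sum_c (1/k_c) sum_{i in S_c} [ k_{c,i,I} ln( eta_I / (eta_I + eta_B kappa_c(s_i)) )
                                          + k_{c,i,B} ln( eta_B kappa_c(s_i) / (eta_I + eta_B kappa_c(s_i)) ) ]

with k_c the table's total (input + bound) read count and S_c the set of
sequences observed in table c.  Because eta_B multiplies both activities
it is not identifiable and is fixed to 1; eta_I is a free per-table
parameter.  The 1/k_c scaling weights every table equally regardless of
sequencing depth; no other per-round weighting is applied.

Multi-round experiments are fitted jointly: one (alpha_NS, alpha_S,
eta_I) triple per round, one shared pair of coefficient matrices and one
shared gamma vector.

## Regularization

    l_reg = lambda ||beta||^2                             (L2, over free coefficients and gamma)
          + sum_b [ exp(b - B) + exp(-b - B) ]            (exponential barrier)
          - n_D sum_c sum_{m in {NS,S}} ln( alpha_{c,m} / sum_m' alpha_{c,m'} )   (Dirichlet)

Defaults: lambda = 1e-6 (weak shrinkage; the data term dominates),
barrier bound B = 20 (keeps coefficients in a numerically safe box
without influencing realistic fits, whose entries are O(1)), Dirichlet
pseudo-count n_D = 5 (resolves the residual scale freedom between the
two modes' activities).  Frozen constraint columns are excluded from all
penalties — the -10 veto entries would otherwise dominate the barrier.

## Optimization

The loss -l_data + l_reg is minimized with L-BFGS-B over the free
parameter vector: non-frozen beta_S entries, beta_NS, gamma, and the
logarithms of eta_I, alpha_NS, alpha_S (positivity by construction).
Gradients are analytic and verified against central finite differences
(max relative error below 1e-6 at step 1e-3; at much smaller steps the
comparison is limited by floating-point cancellation in the differences,
not by the gradient).  Affinities are accumulated via log-sum-exp, so the
loss is finite for coefficient magnitudes far beyond the fitted range.

Initialization: coefficients ~ N(0, 0.1^2), gamma = 0, equal activities,
eta_I matched to the observed input/bound read split at the initial
typical enrichment.  Optional random restarts (n_starts) guard against
local optima; in practice the loss surface at these problem sizes has
not shown start-dependence, and the default is a single start.
Convergence: projected-gradient tolerance 1e-7 or the iteration cap
(default 1000; fits at the problem sizes below are near-converged after
~200 iterations, which is the cap used in the bundled end-to-end
checks and the reproduction script to keep their runtime modest).

### Gauge fixing

Adding a constant to a full column of beta_S while multiplying every
alpha_{c,S} by the opposite exponential leaves every kappa unchanged
(each window covers each column exactly once), so raw fitted columns are
arbitrary up to offsets.  Fitted models are reported in the gauge where
every free column has mean zero, the shift being absorbed into the
activities; ddG/RT = -beta_S in this gauge.  The same centering is
applied to matrices before cross-model comparison, and comparisons
exclude the frozen center column.

## Read processing

Merged amplicon reads are scanned for a 33-bp variable region flanked by
the constant anchors GTAGCTGGCCAGTCTGGCCAG (left) and
GGAGGGCAGTCTGGGCAGTC (right), allowing up to five combined mismatches
across both anchors (the best-scoring placement wins; ties go to the
leftmost).  A per-anchor mismatch budget is a plausible alternative
reading; combined is the conservative choice and the scan is exposed so
either can be enforced upstream.  The cropped region is discarded if any
base has PHRED < 20, if any codon violates the NNS scheme (third base
must be G or C), if translation contains a stop (NNS admits the amber
codon; a displayed peptide cannot contain a stop), or if a
design-fixed position carries the wrong residue.  The PHRED filter is
applied to the cropped region only: anchor-region sequencing errors are
already tolerated by the mismatch budget, and rejecting reads for them
would bias against nothing but the constant scaffold.  Count tables are
serialized as 3-column TSV (sequence, input, bound) with the round label
in a header comment.

Down-sampling of count tables (used to compare libraries at matched
depth) treats each column as an urn of reads and draws without
replacement (multivariate hypergeometric), seeded.

## Synthetic experiments

The simulator emulates linear (non-saturating) selection, matching the
likelihood's generative assumption: bound-pool frequencies are
proportional to pool frequency times kappa, sequencing of both columns
is multinomial at the configured depth, and the bound frequencies become
the next round's pool (noiseless re-amplification).  Ground truth is a
model with central-Y-constrained specific matrix and free coefficients
drawn N(0, beta_sd^2); beta_sd = 1 gives a realistic dynamic range of
roughly +/- 2 ddG/RT units per position.  Two knobs emulate the main
experimental nuisances:

- nonspecific_fraction: the non-specific activity is calibrated on the
  drawn library so that this fraction of bound reads from a uniform pool
  is non-specific capture.  As selection concentrates the pool on true
  binders in later rounds, the realized non-specific share drops — which
  is exactly why joint multi-round fits outperform single-round fits in
  noisy regimes.
- phospho_efficiency: each tyrosine-containing library member is
  competent for specific binding with this probability; incompetent
  members keep only their non-specific term.  A single global efficiency
  stands in for sequence-dependent kinase preferences, which the
  simulator does not model.

What the simulator deliberately omits: sequencing base-call errors and
PCR amplification noise between rounds, codon-level biases (NNS residue
weighting is available but off by default), binding saturation, and
avidity effects.  Passing recovery tests therefore demonstrates the
estimator is correct under its own assumptions at realistic depths — not
that those assumptions hold for any particular wet-lab dataset.

## Problem sizes used in the bundled checks

The end-to-end recovery check fits a three-round X5YX5 experiment with
50,000 unique peptides, 200,000 reads per column and 30% non-specific
capture, recovering the true non-central ddG/RT with r^2 > 0.99 — far
above the 0.9 bar it asserts.  The reproduction script
(scripts/acceptance.py) uses 20,000 peptides at 100,000 reads per
column for the same pipeline, a deliberate economy that leaves the
conclusions unchanged.

The multi-round-benefit check uses the weak-binder regime the comparison
is about: an X11 library (only ~43% of members contain any tyrosine),
coefficient scale beta_sd = 0.5 (typical per-position effects well under
1 RT), 80% non-specific capture, and about half a read per sequence per
column, so that a single round of selection separates binders from
non-binders only marginally.  Within one such experiment, with every
count table sequenced at the same depth, the fit to round 1's table
alone is compared against the joint fit to all three rounds; the later
rounds start from pre-enriched pools in which true binders carry enough
reads to pin down the matrix.  In strong-signal regimes a single round
already saturates recovery and the comparison is uninformative.

## Numerical and tie-breaking conventions

- Natural logarithms throughout; ddG/RT is dimensionless.
- Ranked outputs (site scans) break score ties by lexicographic site id,
  making every ranking a total order.
- Variant direction calls use a neutral band of |log ratio| < 0.1
  ddG/RT; the band is a reporting choice, not a fitted quantity.
- Log-enrichment matrices use a pseudocount of 0.5 per residue-position
  cell by default; with a zero pseudocount, cells unobserved in both
  libraries are NaN and a residue enriched from zero input raises an
  error.
- The central-mode peptide score is the energy of the single window
  centered on the middle residue; the total-mode score is the log of the
  offset-summed specific affinity and therefore always dominates the
  best single offset.

## Known limitations

- One specific binding mode; no pairwise (epistatic) sequence features.
- No uncertainty quantification on fitted coefficients (bootstrap over
  sequences is straightforward but not built in).
- The likelihood assumes linear selection; strongly saturated selections
  will bias fitted activities and compress the recovered energy range.
- gamma is shared across count tables; per-table positional bias would
  add parameters the data rarely support.
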