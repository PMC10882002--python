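# Methods

## Model overview

`pepex` designs terminal extensions for a fixed parent peptide by sampling a
learned latent space instead of enumerating sequences.  Three probabilistic
components cooperate:

* a **sequence VAE** q(z|x), p(x|z) over tokenized extensions,
* a **Gaussian-mixture latent prior** approximating the marginal q(z),
* a **bootstrapped classifier ensemble** approximating the class posterior
  q(c|z) ("is this latent a binder?").

Binder-conditioned latents follow, by Bayes' rule, q(z|c) ∝ q(c|z)·q(z); a
Metropolis–Hastings random walk samples this unnormalized density and the
decoder maps accepted latents back to residue strings.  Scoring, ranking and
filtering operate downstream on whatever oracle supplies the four interface
metrics (I_sc, pep_sc, I_bsa, rmsALL_if) and optionally an MM/GBSA energy.

## Sequence representation

The vocabulary has 24 symbols: indices 0–3 are start, end, unknown residue
and padding; indices 4–23 hold the twenty amino acids in alphabetical
one-letter order (the ordering is a package choice fixed for
reproducibility).  A peptide splits into the parent *base* (15 residues by
default; the truncated 13-residue β-catenin parent is also supported) and a
terminal *extension*.  Both parts are framed with start/end tokens;
extensions are padded with the pad token to a total length of 35, so their
content may reach 33 residues even though practical designs use ≤ 9.
Extensions are always read N→C; a terminus flag, not token reversal, records
orientation.  Non-canonical residue codes (B, J, O, U, X, Z) map to the
unknown token rather than being dropped, preserving record counts.

## The VAE

Encoder: token embedding (M = 32 by default) → single-layer GRU with zero
initial hidden state → two linear heads giving the per-dimension mean and
log-variance of a diagonal Gaussian posterior (K = 16 by default, hidden
width 128).  Decoder: a linear map of z seeds the GRU hidden state; tokens
are predicted autoregressively, teacher-forced during training and greedy at
generation time.  Greedy decoding makes z → sequence a *function*, which the
sampler's string-level deduplication relies on; stochastic decoding is not
used in the pipeline.  The loss is the negative ELBO

    L = −Σ_l Σ_v x_lv log p(x̃_lv)  +  β · ½ Σ_k (μ_k² + σ_k² − log σ_k² − 1),

with cross-entropy accumulated only up to and including the end token
(padding is bookkeeping, not signal) and β ramped linearly over the first
10 % of epochs.  Optimization is Adam (lr 3×10⁻³), minibatch 64, everything
float64 and seeded.  The backward pass is hand-written backpropagation
through time; its correctness is pinned by a central-difference gradient
check in the test suite, and the closed-form KL is checked against numerical
quadrature to 10⁻⁶.

Two model instances share this architecture without sharing weights: one for
the fixed-length base peptide (representation completeness) and one for
variable-length extensions; only the extension model feeds sampling.
Log-variances are clamped to ±10 for numerical stability (gradients are
masked at the clamp).  During decoding the start and pad tokens are excluded
from the argmax so padding can never appear mid-sequence.

## Latent densities

**Prior.**  A Gaussian mixture is fitted to the training-set posterior
means.  The component count defaults to the BIC optimum over 1–10;
covariances are full up to K = 32 and diagonal above (conditioning at desk
scale).  Weights, means and Cholesky factors are cached so the log-density
costs a few small matmuls per call — it sits in the MH inner loop.

**Posterior.**  The labeled pool is split 80/20 (stratified per class) and
the training pool resampled four times at 80 % *without replacement*; one
probabilistic classifier is trained per resample and q(c|z) is their
arithmetic mean.  SVC members are Platt-calibrated inside 5-fold CV (margins
are not probabilities); XGBoost, logistic and random-forest families are
also available, and `evaluate_classifiers` produces the per-family held-out
table used for model selection.  Two numerical accommodations matter on the
small relabeled pools that fine-tuning produces: SVC uses balanced class
weights (the top-fraction rule yields ~10 % positives), and the calibration
fold count is clamped to the minority-class size.  Classification uses only
the extension encoding; the base peptide is constant within a campaign.

## Metropolis–Hastings sampling

The target is log q(c|z) + log q(z) (the constant q(c) drops).  Proposals
are symmetric Gaussian, so the acceptance ratio reduces to
min(1, exp(Δ log target)), computed in log space.  Chains start from a prior
draw (re-drawn up to 100 times if the initial density is zero), run 500
burn-in steps by default, and may be thinned.  Zero classifier probability
yields a −∞ log-target that is always rejected as a proposal.

The default proposal is *covariance-shaped*: increments are
(2.4/√K)·L·η with L the Cholesky factor of the prior's overall covariance
(law of total variance across mixture components).  With a weakly
regularized latent space the marginal scales are far from 1 and strongly
anisotropic; an isotropic 2.4/√K step either freezes the chain or fails to
mix.  An explicit `proposal_sigma` restores the isotropic form, which is
what the analytic-target tests exercise.  For throughput, independent chains
run in lockstep so each step costs one batched prior/ensemble call; greedy
decodes are cached per latent.  Extensions are collected per target length
(N-terminal campaigns use lengths 2–5; C-terminal 2–7 for the full parent or
4–9 truncated) until a per-length quota fills, deduplicated at string level
against everything previously generated; unreachable quotas return a partial
result with a warning rather than an error.

## Scoring and selection

Orientation conventions: lower is better for I_sc, pep_sc and rmsALL_if,
higher for I_bsa.  Rank scores are normalized ranks in [0, 1] with 0 the
best and midrank ties; the overall rank is the (optionally renormalized) sum
over the four metrics.  The combined binding score is the literal product
pep_sc·I_sc·I_bsa / rmsALL_if; because its sign flips with the sign of a
delta-convention rmsALL_if, *ranking* uses the orientation-stable variant
|pep_sc·I_sc|·I_bsa / max(|rms|, 0.01 Å), with the raw value reported
alongside.  Hard cutoffs (rmsALL_if < −0.2 Å, I_sc < −6 REU,
I_bsa > 250 Å²) are strict inequalities on delta-convention scores.  The
MM/GBSA threshold is control mean + 1 σ (one standard deviation toward less
favorable energy); records strictly above it are discarded.  IC50 entries
parse as (operator, value) pairs — an open lower bound like ">3" can never
count as improved.  Final candidate selection ranks by MM/GBSA and drops
extensions whose hydrophobic fraction (over {A,V,L,I,M,F,W,Y,P}) exceeds
0.6, mirroring the manual polarity inspection that precedes synthesis.

## Fine-tuning campaigns

Cycle 0 ("Pretrain") conditions sampling on a classifier trained on the
general binder/non-binder corpus.  Each later cycle rank-orders *all*
designs generated so far, labels the top 10 % positive (boundary ties break
lexicographically so relabeling is rerun-stable), refits the ensemble from
scratch on that pool — VAE weights stay frozen; the fine-tuning signal
enters purely through q(c|z) — and samples a fresh batch excluding every
extension already seen.  Relabeling uses the summed rank order of the four
metrics rather than the combined score: with delta-convention scores the
combined score's division by rms ≈ 0 would promote "no displacement"
peptides over genuinely better binders.  The third fine-tune variant can
additionally fold in 600 extra Pretrain designs, optionally with conserved
mutations (V/A/I/L) at the parent's last two positions.  Enrichment is
summarized by the rank difference — within-model rank minus pooled rank,
positive when a model's designs crowd the pooled top — whose size-weighted
mean over all models is identically ~0, a useful invariant.

## The synthetic study conditions

The corpus generator emulates the real training corpora: a positive class
whose residue composition is biased and a negative class uniform over the 20
letters, lengths uniform in a configurable range.  The default bias puts
five-fold weight on W/F/D/E — aromatic and acidic residues, the preference
the designed binders actually showed; pipeline-level tests use a milder
two-fold bias so the pretrain signal leaves headroom for fine-tuning to
demonstrate enrichment.  The synthetic docking oracle is a pure seeded
function of (peptide, parent): each metric is an affine function of the
extension's reward-residue fraction plus small Gaussian noise (seeded by a
stable hash), with ranges mimicking real delta-vs-parent tables (I_sc
−10..0 REU, I_bsa 100..350 Å², rmsALL_if −0.3..0.3 Å, MM/GBSA −55..−30
kcal/mol) and strictly monotone improvement in reward-residue count.

What this emulation does *not* capture: positional and pairwise epistasis,
structure-mediated effects (the oracle sees composition only), assay noise
correlated across peptides, and the scale of real corpora (hundreds of
thousands of sequences).  Passing tests therefore demonstrate that the
machinery — representation, densities, sampler, ranking, relabeling loop —
behaves correctly and that the closed loop enriches a composition-coded
signal; they do not validate binding predictions for real proteins.

Desk-scale problem sizes used by the tests and the acceptance script: a
600-sequence two-class corpus (lengths 2–6), extension VAE with M = 16,
K = 16, hidden 64, 60 epochs at β = 0.03 (chosen so the greedy decoder
stays nearly injective — over a thousand distinct decodes from prior
samples — which the exclusion-based novelty rule needs), quotas of 25–40
per length over lengths 2–5, two campaign cycles, three seeds.

## Known limitations

* The VAE is CPU-bound numpy; it is sized for corpora of 10²–10⁴ sequences,
  not the full database scale.
* Platt calibration on ~15 positives is rough; probabilities are usable for
  MH tilting but not as calibrated binding probabilities.
* Greedy decoding bounds the reachable sequence set; when the per-length
  quota exceeds the decodable set near the conditioned region, campaigns
  return partial batches (with warnings) by design.
* The combined score's orientation under delta-convention rms is inherently
  ambiguous; both the raw value and the orientation-stable ranking variant
  are reported so either convention can be audited.
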