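"""Conditionally sample binder-like extensions with Metropolis-Hastings.

Fits the Gaussian-mixture latent prior q(z) and the 4-member classifier
posterior q(c|z) on a labeled synthetic corpus, then samples q(z|c) and
decodes novel extensions for the 15-residue parent peptide.
"""

from collections import Counter

from pepex.corpus import assemble_labeled, synth_corpus
from pepex.latent import fit_posterior, fit_prior
from pepex.mh import MhConfig, concatenate, generate_extensions
from pepex.vae import GruVae, VaeConfig, tokens_matrix

PARENT = "YPEDILDKHLQRVIL"

pos, neg = synth_corpus(300, 300, length_range=(2, 6),
                        composition_bias={aa: 2.0 for aa in "WFDE"}, seed=0)
split = assemble_labeled(pos, neg, seed=0)

vae = GruVae(VaeConfig(embed_dim=16, latent_dim=16, hidden_dim=64,
                       epochs=60, kl_weight=0.03, seed=0))
vae.train(tokens_matrix(list(split.train)))

prior = fit_prior(vae.encode_strings([r.sequence for r in split.train]), seed=0)
ensemble = fit_posterior(split, vae.encode_strings, family="svc", seed=0)
print(f"prior: {prior.n_components} mixture components in {prior.latent_dim}-D latent space")

pairs = generate_extensions(
    vae, prior, ensemble, target_lengths=(2, 3, 4, 5), per_length_quota=10,
    terminus="N", config=MhConfig(seed=0, n_chains=32, thinning=3, burn_in=150),
)
by_len = Counter(len(e) for e, _ in pairs)
print(f"sampled {len(pairs)} unique extensions, per length: {dict(sorted(by_len.items()))}")
for ext, term in pairs[:8]:
    print(f"  {ext:>6} -> {concatenate(PARENT, ext, term)}")
print("extensions are biased toward W/F/D/E, the residues the positive class favors")
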