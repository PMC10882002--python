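"""Shared fixtures: a small trained pipeline reused across test modules."""

import numpy as np
import pytest

from pepex.corpus import assemble_labeled, synth_corpus
from pepex.latent import fit_prior
from pepex.oracle import SyntheticDockingOracle
from pepex.vae import GruVae, VaeConfig, tokens_matrix

PARENT = "YPEDILDKHLQRVIL"

#: desk-scale study conditions for pipeline-level tests: a 600-sequence
#: two-class corpus of short extensions with a mild binder-like composition
#: bias, and an extension VAE big enough to give a diverse decodable set
CAMPAIGN_BIAS = {aa: 2.0 for aa in "WFDE"}
CAMPAIGN_LENGTHS = (2, 6)
VAE_CFG = dict(embed_dim=16, latent_dim=16, hidden_dim=64, epochs=60, kl_weight=0.03)


def build_assets(seed: int):
    """Corpus + trained extension VAE + latent prior + synthetic oracle."""
    pos, neg = synth_corpus(
        300, 300, length_range=CAMPAIGN_LENGTHS, composition_bias=CAMPAIGN_BIAS, seed=seed
    )
    split = assemble_labeled(pos, neg, seed=seed)
    vae = GruVae(VaeConfig(seed=seed, **VAE_CFG))
    vae.train(tokens_matrix(list(split.train)))
    encodings = vae.encode_strings([r.sequence for r in split.train])
    prior = fit_prior(encodings, seed=seed, max_components=5)
    oracle = SyntheticDockingOracle(PARENT, seed=seed)
    return {
        "split": split,
        "vae": vae,
        "prior": prior,
        "oracle": oracle,
        "encodings": encodings,
        "seed": seed,
    }


@pytest.fixture(scope="session")
def pipeline_assets():
    return build_assets(seed=0)


class StandardNormalPrior:
    """Unit-Gaussian stand-in satisfying the prior duck type (no covariance hook)."""

    def __init__(self, dim: int):
        self.dim = dim

    def log_density(self, z):
        Z = np.atleast_2d(np.asarray(z, dtype=float))
        out = -0.5 * (Z**2).sum(axis=1) - 0.5 * self.dim * np.log(2 * np.pi)
        return out if np.asarray(z).ndim > 1 else float(out[0])

    def sample(self, n, rng):
        return rng.standard_normal((n, self.dim))


@pytest.fixture
def std_normal_prior():
    return StandardNormalPrior
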