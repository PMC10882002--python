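"""Metropolis-Hastings sampling of binder-conditioned latent vectors.

The target is the conditional latent density q(z|c) which, by Bayes' rule,
is proportional to q(c|z) * q(z): the classifier-ensemble posterior times the
Gaussian-mixture prior.  A symmetric Gaussian proposal means the proposal
density cancels from the acceptance ratio, which is computed in log space
for numerical stability.  Chains are initialized from the prior, run through
a burn-in, optionally thinned, and accepted latents are decoded greedily to
extension strings; decoding is many-to-one, so deduplication happens at the
string level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np


class MhError(RuntimeError):
    pass


@dataclass
class MhConfig:
    """Chain parameters; proposal sigma defaults to the 2.4/sqrt(K) scaling."""

    proposal_sigma: Optional[float] = None
    burn_in: int = 500
    thinning: int = 1
    max_iterations: int = 200_000
    seed: int = 0
    #: independent chains run in lockstep (vectorizes classifier calls)
    n_chains: int = 1

    def __post_init__(self):
        if self.burn_in < 0 or self.thinning < 1 or self.n_chains < 1:
            raise ValueError("burn_in >= 0, thinning >= 1, n_chains >= 1 required")
        if self.proposal_sigma is not None and self.proposal_sigma <= 0:
            raise ValueError("proposal_sigma must be positive")

    def sigma_for(self, dim: int, scale: float = 1.0) -> float:
        """Proposal width: explicit value, else 2.4/sqrt(dim) times the
        target's typical scale (the optimal-scaling heuristic)."""
        if self.proposal_sigma is not None:
            return self.proposal_sigma
        return 2.4 / np.sqrt(dim) * scale


def _prior_scale(prior) -> float:
    """Mean marginal std of the prior, 1.0 when the prior does not expose it."""
    std = getattr(prior, "marginal_std", None)
    return float(np.mean(std())) if callable(std) else 1.0


def _proposal_noise_fn(config: MhConfig, prior, dim: int):
    """Build the proposal-increment sampler.

    With an explicit ``proposal_sigma`` the proposal is isotropic.  Otherwise,
    when the prior exposes its overall covariance, increments are shaped by
    its Cholesky factor at the 2.4/sqrt(K) optimal scaling — an isotropic
    step of that size would be rejected almost surely along low-variance
    latent directions.
    """
    if config.proposal_sigma is not None:
        sigma = config.proposal_sigma
        return lambda rng, n: sigma * rng.standard_normal((n, dim))
    scale = 2.4 / np.sqrt(dim)
    cov_fn = getattr(prior, "overall_cov", None)
    if callable(cov_fn):
        L = np.linalg.cholesky(cov_fn() + 1e-12 * np.eye(dim))
        return lambda rng, n: scale * rng.standard_normal((n, dim)) @ L.T
    return lambda rng, n: scale * rng.standard_normal((n, dim))


@dataclass
class ChainState:
    """Current position, cached log-target and acceptance counters."""

    z: np.ndarray
    log_target: float
    accept_count: int = 0
    step_count: int = 0


def log_target(z: np.ndarray, prior, ensemble=None) -> float:
    """log q(c|z) + log q(z), dropping the constant q(c).

    ``ensemble`` may be None (or anything without members), meaning
    q(c|z) = 1 everywhere; a zero classifier probability yields -inf rather
    than an exception.
    """
    lp = prior.log_density(z)
    lp = float(lp) if np.ndim(lp) == 0 else float(lp)
    if ensemble is None:
        return lp
    p = float(np.atleast_1d(ensemble.predict_proba(np.atleast_2d(z)))[0])
    if p <= 0.0:
        return -np.inf
    return lp + float(np.log(p))


def _batch_log_target(Z: np.ndarray, prior, ensemble=None) -> np.ndarray:
    lp = np.atleast_1d(prior.log_density(Z))
    if ensemble is None:
        return lp
    p = np.asarray(ensemble.predict_proba(Z), dtype=float)
    with np.errstate(divide="ignore"):
        return lp + np.log(p)


def init_state(prior, ensemble, rng, max_tries: int = 100) -> ChainState:
    """Draw the chain start from the prior, re-drawing away from -inf targets."""
    for _ in range(max_tries):
        z = prior.sample(1, rng)[0]
        lt = log_target(z, prior, ensemble)
        if np.isfinite(lt):
            return ChainState(z=z, log_target=lt)
    raise MhError("could not find a finite-density starting point")


def mh_step(state: ChainState, config: MhConfig, prior, ensemble, rng) -> ChainState:
    """One symmetric-proposal step: accept with min(1, exp(logT' - logT))."""
    noise = _proposal_noise_fn(config, prior, state.z.shape[0])
    proposal = state.z + noise(rng, 1)[0]
    lt_new = log_target(proposal, prior, ensemble)
    log_ratio = lt_new - state.log_target
    accept = np.isfinite(lt_new) and (
        log_ratio >= 0 or np.log(rng.uniform()) < log_ratio
    )
    if accept:
        return ChainState(proposal, lt_new, state.accept_count + 1, state.step_count + 1)
    return ChainState(state.z, state.log_target, state.accept_count, state.step_count + 1)


def sample_chain(
    config: MhConfig,
    prior,
    ensemble=None,
    init_z: Optional[np.ndarray] = None,
    n_samples: Optional[int] = None,
) -> list:
    """Run one chain; discard burn-in, apply thinning, return kept latents.

    ``n_samples`` caps the number of returned samples (default: as many as
    ``max_iterations`` allows).  Raises if the iteration budget is exhausted
    before any post-burn-in sample is produced.
    """
    rng = np.random.default_rng(config.seed)
    if init_z is not None:
        z = np.asarray(init_z, dtype=float)
        state = ChainState(z=z, log_target=log_target(z, prior, ensemble))
        if not np.isfinite(state.log_target):
            state = init_state(prior, ensemble, rng)
    else:
        state = init_state(prior, ensemble, rng)
    samples = []
    for it in range(config.max_iterations):
        state = mh_step(state, config, prior, ensemble, rng)
        post = it + 1 - config.burn_in
        if post > 0 and post % config.thinning == 0:
            samples.append(state.z.copy())
            if n_samples is not None and len(samples) >= n_samples:
                break
    if not samples:
        raise MhError("max_iterations exhausted before any post-burn-in sample")
    return samples


def sample_chains_vectorized(
    config: MhConfig,
    prior,
    ensemble=None,
    n_steps: int = 1000,
    rng=None,
):
    """Run ``config.n_chains`` independent chains in lockstep.

    Proposals for all chains are evaluated in one batched prior/ensemble
    call per step, which keeps per-step classifier overhead constant.
    Yields the (n_chains, K) position matrix after each post-burn-in,
    thinned step, plus the running acceptance rate at the end.
    """
    rng = rng or np.random.default_rng(config.seed)
    C = config.n_chains
    Z = prior.sample(C, rng)
    lt = _batch_log_target(Z, prior, ensemble)
    for i in np.flatnonzero(~np.isfinite(lt)):
        st = init_state(prior, ensemble, rng)
        Z[i], lt[i] = st.z, st.log_target
    K = Z.shape[1]
    noise = _proposal_noise_fn(config, prior, K)
    kept = []
    accepts = 0
    for step in range(n_steps):
        prop = Z + noise(rng, C)
        lt_new = _batch_log_target(prop, prior, ensemble)
        log_u = np.log(rng.uniform(size=C))
        take = np.isfinite(lt_new) & (log_u < (lt_new - lt))
        Z[take] = prop[take]
        lt[take] = lt_new[take]
        accepts += int(take.sum())
        post = step + 1 - config.burn_in
        if post > 0 and post % config.thinning == 0:
            kept.append(Z.copy())
    accept_rate = accepts / (n_steps * C)
    return kept, accept_rate


def concatenate(parent: str, extension: str, terminus: str) -> str:
    """Join an extension onto the parent: N-terminal prepends, C-terminal appends."""
    if terminus == "N":
        return extension + parent
    if terminus == "C":
        return parent + extension
    raise ValueError(f"terminus must be 'N' or 'C', got {terminus!r}")


def sample_extensions(
    decoder: Callable[[np.ndarray], str],
    chain_samples: Sequence[np.ndarray],
    target_lengths: Sequence[int],
    per_length_quota: int,
    exclusion_set=frozenset(),
    terminus: str = "N",
) -> list:
    """Decode chain samples into unique, novel extensions per target length.

    Keeps the first ``per_length_quota`` distinct extensions of each target
    length that are not in ``exclusion_set``; warns (and returns a partial
    result) if the provided samples cannot satisfy a quota.
    """
    if per_length_quota < 1:
        raise ValueError("per_length_quota must be >= 1")
    target_lengths = sorted(set(int(x) for x in target_lengths))
    buckets = {length: [] for length in target_lengths}
    seen = set(exclusion_set)
    for z in chain_samples:
        if all(len(b) >= per_length_quota for b in buckets.values()):
            break
        ext = decoder(np.asarray(z))
        if not ext or ext in seen:
            continue
        bucket = buckets.get(len(ext))
        if bucket is None or len(bucket) >= per_length_quota:
            continue
        bucket.append(ext)
        seen.add(ext)
    short = {length: len(b) for length, b in buckets.items() if len(b) < per_length_quota}
    if short:
        warnings.warn(
            f"quota {per_length_quota} not reached for lengths {short}", stacklevel=2
        )
    return [(ext, terminus) for length in target_lengths for ext in buckets[length]]


def generate_extensions(
    vae,
    prior,
    ensemble,
    target_lengths: Sequence[int],
    per_length_quota: int,
    exclusion_set=frozenset(),
    terminus: str = "N",
    config: Optional[MhConfig] = None,
    max_rounds: int = 12,
    steps_per_round: int = 150,
):
    """Loop MH sampling + decoding until every length quota fills (or budget ends).

    Runs vectorized chains in rounds, decoding each round's kept latents and
    collecting unique novel extensions per length.  Returns the (extension,
    terminus) list; incomplete quotas surface as a warning from
    :func:`sample_extensions` semantics.
    """
    config = config or MhConfig()
    rng = np.random.default_rng(config.seed)
    target_lengths = sorted(set(int(x) for x in target_lengths))
    buckets = {length: [] for length in target_lengths}
    seen = set(exclusion_set)

    C = config.n_chains
    Z = prior.sample(C, rng)
    lt = _batch_log_target(Z, prior, ensemble)
    for i in np.flatnonzero(~np.isfinite(lt)):
        st = init_state(prior, ensemble, rng)
        Z[i], lt[i] = st.z, st.log_target
    noise = _proposal_noise_fn(config, prior, Z.shape[1])

    def advance(n_steps, collect):
        nonlocal Z, lt
        out = []
        for step in range(n_steps):
            prop = Z + noise(rng, C)
            lt_new = _batch_log_target(prop, prior, ensemble)
            take = np.isfinite(lt_new) & (np.log(rng.uniform(size=C)) < (lt_new - lt))
            Z[take] = prop[take]
            lt[take] = lt_new[take]
            if collect and (step + 1) % config.thinning == 0:
                out.append(Z.copy())
        return out

    advance(config.burn_in, collect=False)
    decode_cache: dict = {}  # greedy decoding is deterministic per z
    stagnant = 0
    for _ in range(max_rounds):
        if all(len(b) >= per_length_quota for b in buckets.values()):
            break
        added = 0
        for block in advance(steps_per_round, collect=True):
            for z in block:
                key = z.tobytes()
                ext = decode_cache.get(key)
                if ext is None:
                    ext = vae.decode_recursive(z)
                    decode_cache[key] = ext
                if not ext or ext in seen:
                    continue
                bucket = buckets.get(len(ext))
                if bucket is None or len(bucket) >= per_length_quota:
                    continue
                bucket.append(ext)
                seen.add(ext)
                added += 1
        stagnant = stagnant + 1 if added == 0 else 0
        if stagnant >= 2:  # chains have stopped discovering novel strings
            break
    short = {length: len(b) for length, b in buckets.items() if len(b) < per_length_quota}
    if short:
        warnings.warn(
            f"quota {per_length_quota} not reached for lengths {short}", stacklevel=2
        )
    return [(ext, terminus) for length in target_lengths for ext in buckets[length]]
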