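"""GRU-based variational autoencoder over tokenized peptide sequences.

The encoder embeds tokens, runs a single-layer GRU (initial hidden state 0)
and maps the hidden state at the end token through two linear heads onto the
per-dimension mean and log-variance of a diagonal Gaussian posterior
q(z|x) = N(mu, sigma^2).  The decoder projects z to the GRU initial hidden
state and predicts each next token from the previous ones (teacher-forced
during training, greedy and autoregressive at generation time).  Training
minimizes the negative evidence lower bound: masked token cross-entropy plus
the closed-form KL divergence of q(z|x) from the standard-normal prior,

    KL = 0.5 * sum_k (mu_k^2 + sigma_k^2 - log sigma_k^2 - 1).

Two model instances are used in practice — one for the fixed-length base
peptide, one for variable-length extensions — sharing this architecture but
not weights; only the extension model feeds conditional sampling.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import nn
from .codec import (
    END,
    EXT_PADDED_LEN,
    PAD,
    START,
    VOCAB,
    VOCAB_SIZE,
    TokenizedSequence,
    Vocabulary,
    detokenize,
    sequence_lengths,
    tokenize,
)

_LV_CLIP = 10.0  # log-variance clamp for numerical stability


class VaeError(RuntimeError):
    pass


@dataclass
class VaeConfig:
    """Hyperparameters; defaults are desk-scale seq-VAE practice."""

    embed_dim: int = 32
    latent_dim: int = 16
    hidden_dim: int = 128
    kl_weight: float = 1.0
    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 3e-3
    seed: int = 0
    #: fraction of epochs over which the KL weight ramps linearly from 0
    warmup_fraction: float = 0.1

    def __post_init__(self):
        for name in ("embed_dim", "latent_dim", "hidden_dim", "epochs", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.kl_weight < 0 or self.learning_rate <= 0:
            raise ValueError("kl_weight must be >= 0 and learning_rate > 0")


@dataclass(frozen=True)
class LatentEncoding:
    """Posterior mean/sd and a point sample for one sequence."""

    mean: np.ndarray
    sigma: np.ndarray
    sample: np.ndarray

    def __post_init__(self):
        if not (np.asarray(self.sigma) > 0).all():
            raise VaeError("sigma must be strictly positive elementwise")


@dataclass(frozen=True)
class LossBreakdown:
    """Reconstruction cross-entropy, KL term and their weighted total (nats)."""

    reconstruction_ce: float
    kl: float
    kl_weight: float = 1.0

    @property
    def total(self) -> float:
        return self.reconstruction_ce + self.kl_weight * self.kl


def gaussian_kl(mean: np.ndarray, sigma: np.ndarray) -> float:
    """Closed-form KL( N(mean, sigma^2) || N(0, 1) ), summed over dimensions."""
    mean = np.asarray(mean, dtype=float)
    var = np.asarray(sigma, dtype=float) ** 2
    return float(0.5 * np.sum(mean**2 + var - np.log(var) - 1.0))


def loss_breakdown(
    x: TokenizedSequence,
    x_recon_probs: np.ndarray,
    enc: LatentEncoding,
    kl_weight: float = 1.0,
) -> LossBreakdown:
    """Eq.-style VAE loss from explicit reconstruction probabilities.

    ``x_recon_probs`` is an L x V row-stochastic matrix aligned with the
    tokens of ``x``; cross-entropy is accumulated over non-pad positions only
    (padding is bookkeeping, not signal).
    """
    probs = np.asarray(x_recon_probs, dtype=float)
    if not np.isfinite(probs).all():
        raise VaeError("reconstruction probabilities must be finite")
    rowsums = probs.sum(axis=1)
    if np.abs(rowsums - 1.0).max() > 1e-6:
        raise VaeError("probability rows must sum to 1 within 1e-6")
    tokens = x.tokens if isinstance(x, TokenizedSequence) else np.asarray(x)
    mask = tokens != PAD
    picked = probs[np.arange(len(tokens)), tokens]
    with np.errstate(divide="ignore"):
        ce = -np.log(picked[mask]).sum()
    kl = gaussian_kl(enc.mean, enc.sigma)
    return LossBreakdown(float(ce), kl, kl_weight)


def _init_params(cfg: VaeConfig) -> dict:
    rng = np.random.default_rng(cfg.seed)
    M, H, K, V = cfg.embed_dim, cfg.hidden_dim, cfg.latent_dim, VOCAB_SIZE

    def mat(shape, scale):
        return rng.normal(0.0, scale, size=shape)

    return {
        "emb": mat((V, M), 0.1),
        "enc_Wx": mat((M, 3 * H), 1.0 / np.sqrt(M)),
        "enc_Wh": mat((H, 3 * H), 1.0 / np.sqrt(H)),
        "enc_bx": np.zeros(3 * H),
        "enc_bh": np.zeros(3 * H),
        "mu_W": mat((H, K), 1.0 / np.sqrt(H)),
        "mu_b": np.zeros(K),
        "lv_W": mat((H, K), 1.0 / np.sqrt(H)),
        "lv_b": np.zeros(K),
        "z2h_W": mat((K, H), 1.0 / np.sqrt(K)),
        "z2h_b": np.zeros(H),
        "dec_Wx": mat((M, 3 * H), 1.0 / np.sqrt(M)),
        "dec_Wh": mat((H, 3 * H), 1.0 / np.sqrt(H)),
        "dec_bx": np.zeros(3 * H),
        "dec_bh": np.zeros(3 * H),
        "out_W": mat((H, V), 1.0 / np.sqrt(H)),
        "out_b": np.zeros(V),
    }


class GruVae:
    """Sequence VAE with numpy forward/backward passes.

    Parameters live in ``self.params`` (a name -> float64 array dict); the
    forward pass is deterministic given parameters, and checkpoints reload to
    a bit-identical forward pass.
    """

    def __init__(self, config: Optional[VaeConfig] = None, vocab: Optional[Vocabulary] = None):
        self.config = config or VaeConfig()
        self.vocab = vocab or VOCAB
        self.params = _init_params(self.config)
        self.history: list = []

    # -- encoding ------------------------------------------------------------

    def _encoder_hidden(self, tokens2d: np.ndarray):
        p = self.params
        X = p["emb"][tokens2d].transpose(1, 0, 2)  # (T, B, M)
        h0 = np.zeros((tokens2d.shape[0], self.config.hidden_dim))
        Hs, cache = nn.gru_forward(X, h0, p["enc_Wx"], p["enc_Wh"], p["enc_bx"], p["enc_bh"])
        lengths = sequence_lengths(tokens2d)
        h_last = Hs[lengths, np.arange(tokens2d.shape[0])]
        return Hs, cache, lengths, h_last

    def encode_batch(self, tokens2d: np.ndarray):
        """Posterior (mean, sigma) arrays for a (B, T) token matrix."""
        tokens2d = np.atleast_2d(np.asarray(tokens2d, dtype=np.int64))
        if tokens2d.shape[1] > EXT_PADDED_LEN:
            raise VaeError("token length exceeds model capacity")
        p = self.params
        _, _, _, h_last = self._encoder_hidden(tokens2d)
        mu = h_last @ p["mu_W"] + p["mu_b"]
        lv = np.clip(h_last @ p["lv_W"] + p["lv_b"], -_LV_CLIP, _LV_CLIP)
        return mu, np.exp(0.5 * lv)

    def encode(self, tokens, sample: bool = False, rng=None) -> LatentEncoding:
        """Encode one tokenized sequence; sample = mean unless requested."""
        if isinstance(tokens, TokenizedSequence):
            tokens = tokens.tokens
        mu, sigma = self.encode_batch(np.asarray(tokens)[None, :])
        mu, sigma = mu[0], sigma[0]
        if sample:
            rng = rng or np.random.default_rng()
            z = mu + sigma * rng.standard_normal(mu.shape)
        else:
            z = mu.copy()
        return LatentEncoding(mean=mu, sigma=sigma, sample=z)

    def encode_strings(self, seqs: Sequence[str], role: str = "extension") -> np.ndarray:
        """Posterior means for a list of residue strings (rows of (n, K))."""
        toks = np.stack([tokenize(s, role=role).tokens for s in seqs])
        mu, _ = self.encode_batch(toks)
        return mu

    # -- decoding ------------------------------------------------------------

    def decode_recursive(self, z: np.ndarray, max_len: int = EXT_PADDED_LEN) -> str:
        """Greedy autoregressive decode: a pure function of (z, params).

        Starts from the start token with the latent projection as initial
        hidden state; stops at the end token or ``max_len`` steps.  Start and
        pad tokens are excluded from the argmax so padding never appears
        mid-sequence.
        """
        p = self.params
        z = np.asarray(z, dtype=float).reshape(-1)
        if z.shape[0] != self.config.latent_dim:
            raise VaeError("latent vector has wrong dimension")
        h = (z @ p["z2h_W"] + p["z2h_b"])[None, :]
        token = START
        out_tokens = []
        H = self.config.hidden_dim
        for _ in range(max_len):
            x = p["emb"][token][None, :]
            gx = x @ p["dec_Wx"] + p["dec_bx"]
            gh = h @ p["dec_Wh"] + p["dec_bh"]
            r = nn.sigmoid(gx[:, :H] + gh[:, :H])
            u = nn.sigmoid(gx[:, H : 2 * H] + gh[:, H : 2 * H])
            c = np.tanh(gx[:, 2 * H :] + r * gh[:, 2 * H :])
            h = (1.0 - u) * c + u * h
            logits = (h @ p["out_W"] + p["out_b"])[0].copy()
            logits[[START, PAD]] = -np.inf
            token = int(np.argmax(logits))
            if token == END:
                break
            out_tokens.append(token)
        return detokenize(np.array(out_tokens + [END]))

    # -- training ------------------------------------------------------------

    def _forward_backward(self, tokens2d: np.ndarray, kl_weight: float, rng):
        """One training step's loss and parameter gradients (mean over batch)."""
        p = self.params
        B, T = tokens2d.shape
        H, K = self.config.hidden_dim, self.config.latent_dim

        enc_Hs, enc_cache, lengths, h_last = self._encoder_hidden(tokens2d)
        mu = h_last @ p["mu_W"] + p["mu_b"]
        lv_raw = h_last @ p["lv_W"] + p["lv_b"]
        lv = np.clip(lv_raw, -_LV_CLIP, _LV_CLIP)
        clip_mask = (lv_raw > -_LV_CLIP) & (lv_raw < _LV_CLIP)
        sigma = np.exp(0.5 * lv)
        eps = rng.standard_normal(mu.shape)
        z = mu + sigma * eps

        # decoder: teacher forcing, predict tokens[1:] from tokens[:-1]
        dec_in = tokens2d[:, :-1]
        targets = tokens2d[:, 1:]
        Xd = p["emb"][dec_in].transpose(1, 0, 2)
        h0 = z @ p["z2h_W"] + p["z2h_b"]
        dec_Hs, dec_cache = nn.gru_forward(
            Xd, h0, p["dec_Wx"], p["dec_Wh"], p["dec_bx"], p["dec_bh"]
        )
        Hout = dec_Hs[1:]  # (T-1, B, H)
        logits = Hout @ p["out_W"] + p["out_b"]
        logp = nn.log_softmax(logits)
        # positions 0..len-2 of targets cover residues and the end token
        tmask = (np.arange(T - 1)[None, :] < (lengths - 1)[:, None]).T  # (T-1, B)
        tgt = targets.T
        picked = np.take_along_axis(logp, tgt[:, :, None], axis=2)[:, :, 0]
        ce = -(picked * tmask).sum() / B
        kl_vec = 0.5 * (mu**2 + np.exp(lv) - lv - 1.0)
        kl = kl_vec.sum() / B
        if not np.isfinite(ce) or not np.isfinite(kl):
            raise VaeError("non-finite loss")

        # ---- backward
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        probs = np.exp(logp)
        dlogits = probs.copy()
        np.put_along_axis(
            dlogits, tgt[:, :, None], np.take_along_axis(dlogits, tgt[:, :, None], axis=2) - 1.0, axis=2
        )
        dlogits *= tmask[:, :, None] / B
        grads["out_W"] = np.einsum("tbh,tbv->hv", Hout, dlogits)
        grads["out_b"] = dlogits.sum(axis=(0, 1))
        dH_inject = np.einsum("tbv,hv->tbh", dlogits, p["out_W"])
        dXd, dh0, dWx, dWh, dbx, dbh = nn.gru_backward(
            dH_inject, dec_Hs, dec_cache, p["dec_Wx"], p["dec_Wh"]
        )
        grads["dec_Wx"], grads["dec_Wh"] = dWx, dWh
        grads["dec_bx"], grads["dec_bh"] = dbx, dbh
        np.add.at(grads["emb"], dec_in, dXd.transpose(1, 0, 2))
        grads["z2h_W"] = z.T @ dh0
        grads["z2h_b"] = dh0.sum(axis=0)
        dz = dh0 @ p["z2h_W"].T

        beta = kl_weight
        dmu = dz + beta * mu / B
        dlv = dz * eps * 0.5 * sigma + beta * 0.5 * (np.exp(lv) - 1.0) / B
        dlv = dlv * clip_mask
        grads["mu_W"] = h_last.T @ dmu
        grads["mu_b"] = dmu.sum(axis=0)
        grads["lv_W"] = h_last.T @ dlv
        grads["lv_b"] = dlv.sum(axis=0)
        dh_last = dmu @ p["mu_W"].T + dlv @ p["lv_W"].T

        enc_inject = np.zeros((T, B, H))
        enc_inject[lengths - 1, np.arange(B)] = dh_last
        dXe, _, dWx, dWh, dbx, dbh = nn.gru_backward(
            enc_inject, enc_Hs, enc_cache, p["enc_Wx"], p["enc_Wh"]
        )
        grads["enc_Wx"], grads["enc_Wh"] = dWx, dWh
        grads["enc_bx"], grads["enc_bh"] = dbx, dbh
        np.add.at(grads["emb"], tokens2d, dXe.transpose(1, 0, 2))

        return LossBreakdown(float(ce), float(kl), beta), grads

    def train(self, tokens2d: np.ndarray, config: Optional[VaeConfig] = None) -> list:
        """Seeded minibatch training; returns the per-epoch loss trajectory."""
        if config is not None:
            self.config = config
            self.params = _init_params(config)
        cfg = self.config
        tokens2d = np.asarray(tokens2d, dtype=np.int64)
        if tokens2d.ndim != 2 or tokens2d.shape[0] == 0:
            raise VaeError("training corpus must be a non-empty (n, T) token matrix")
        rng = np.random.default_rng(cfg.seed + 1)
        opt = nn.Adam(self.params, lr=cfg.learning_rate)
        n = tokens2d.shape[0]
        warm_epochs = max(1, int(np.ceil(cfg.warmup_fraction * cfg.epochs)))
        self.history = []
        for epoch in range(cfg.epochs):
            beta = cfg.kl_weight * min(1.0, (epoch + 1) / warm_epochs)
            order = rng.permutation(n)
            ce_sum = kl_sum = 0.0
            n_batches = 0
            for start in range(0, n, cfg.batch_size):
                batch = tokens2d[order[start : start + cfg.batch_size]]
                try:
                    loss, grads = self._forward_backward(batch, beta, rng)
                except VaeError as exc:
                    raise VaeError(f"training diverged at epoch {epoch}: {exc}") from exc
                opt.step(grads)
                ce_sum += loss.reconstruction_ce
                kl_sum += loss.kl
                n_batches += 1
            self.history.append(
                LossBreakdown(ce_sum / n_batches, kl_sum / n_batches, beta)
            )
        return self.history

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        """Single-file checkpoint: weights + config + vocabulary."""
        meta = json.dumps({"config": asdict(self.config), "vocab": self.vocab.token_to_index})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **self.params)

    @classmethod
    def load(cls, path) -> "GruVae":
        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode())
        model = cls(VaeConfig(**meta["config"]), Vocabulary(meta["vocab"]))
        model.params = {k: data[k].copy() for k in data.files if k != "__meta__"}
        return model


def tokens_matrix(records, role: str = "extension") -> np.ndarray:
    """Stack PeptideRecords (or strings) into a (n, T) token matrix."""
    rows = []
    for r in records:
        seq = r if isinstance(r, str) else r.sequence
        rows.append(tokenize(seq, role=role).tokens)
    return np.stack(rows)
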