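"""Latent-space densities for conditional sampling.

Conditional generation needs two ingredients: the marginal latent density
q(z), approximated by a Gaussian mixture fitted to the training-set
encodings, and the class-posterior q(c|z) ("is this latent a binder?"),
estimated by an ensemble of four probabilistic classifiers — one per
bootstrap resample of the labeled pool — whose probabilities are averaged:

    q(c|z) = ( q_1(c|z) + q_2(c|z) + q_3(c|z) + q_4(c|z) ) / 4.

Margin classifiers (SVC) are Platt-calibrated inside 5-fold CV so that their
outputs are usable probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.special import logsumexp
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.mixture import GaussianMixture
from sklearn.model_selection import cross_val_score
from sklearn.svm import SVC
from xgboost import XGBClassifier


class LatentError(ValueError):
    pass


class LatentPrior:
    """Gaussian-mixture approximation of q(z) with a fast log-density.

    Wraps a fitted sklearn GaussianMixture; component weights, means and
    covariance Cholesky factors are cached so the per-point log-density costs
    a few small matmuls (the Metropolis-Hastings inner loop calls it once per
    step).
    """

    def __init__(self, mixture: GaussianMixture):
        self.mixture = mixture
        self.weights = mixture.weights_.copy()
        self.means = mixture.means_.copy()
        if abs(self.weights.sum() - 1.0) > 1e-9 or (self.weights < 0).any():
            raise LatentError("mixture weights must be non-negative and sum to 1")
        K = self.means.shape[1]
        covs = mixture.covariances_
        if mixture.covariance_type == "diag":
            covs = np.stack([np.diag(c) for c in covs])
        self._chol = []
        self._log_det = []
        for i, cov in enumerate(covs):
            try:
                L = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError as exc:
                raise LatentError(f"degenerate covariance in component {i}") from exc
            self._chol.append(L)
            self._log_det.append(2.0 * np.log(np.diag(L)).sum())
        self._log_norm = -0.5 * K * np.log(2.0 * np.pi)

    @property
    def n_components(self) -> int:
        return len(self.weights)

    @property
    def latent_dim(self) -> int:
        return self.means.shape[1]

    def marginal_std(self) -> np.ndarray:
        """Per-dimension standard deviation of the mixture (law of total variance)."""
        return np.sqrt(np.diag(self.overall_cov()))

    def overall_cov(self) -> np.ndarray:
        """Full covariance of the mixture: sum_i w_i (C_i + mu_i mu_i^T) - mu mu^T."""
        if not hasattr(self, "_overall_cov"):
            covs = self.mixture.covariances_
            if self.mixture.covariance_type == "diag":
                covs = np.stack([np.diag(c) for c in covs])
            mean_all = self.weights @ self.means
            second = sum(
                w * (C + np.outer(m, m))
                for w, C, m in zip(self.weights, covs, self.means)
            )
            self._overall_cov = second - np.outer(mean_all, mean_all)
        return self._overall_cov

    def log_density(self, z: np.ndarray) -> np.ndarray:
        """log q(z) for one point (K,) or a batch (n, K)."""
        Z = np.atleast_2d(np.asarray(z, dtype=float))
        comp = np.empty((Z.shape[0], self.n_components))
        for i in range(self.n_components):
            diff = (Z - self.means[i]).T
            y = solve_triangular(self._chol[i], diff, lower=True)
            maha = (y**2).sum(axis=0)
            comp[:, i] = (
                np.log(self.weights[i])
                + self._log_norm
                - 0.5 * self._log_det[i]
                - 0.5 * maha
            )
        out = logsumexp(comp, axis=1)
        return out if np.asarray(z).ndim > 1 else float(out[0])

    def sample(self, n: int, rng) -> np.ndarray:
        comp = rng.choice(self.n_components, size=n, p=self.weights)
        out = np.empty((n, self.latent_dim))
        for i in range(n):
            c = comp[i]
            out[i] = self.means[c] + self._chol[c] @ rng.standard_normal(self.latent_dim)
        return out


def fit_prior(
    encodings: np.ndarray,
    n_components: Optional[int] = None,
    seed: int = 0,
    max_components: int = 10,
    reg_covar: float = 1e-6,
) -> LatentPrior:
    """Fit a Gaussian mixture to latent encodings.

    When ``n_components`` is None the count is chosen by BIC over
    1..max_components.  Full covariances are used up to latent dimension 32,
    diagonal above (conditioning at desk scale).
    """
    Z = np.asarray(encodings, dtype=float)
    if Z.ndim != 2:
        raise LatentError("encodings must be an (n, K) array")
    K = Z.shape[1]
    cov_type = "full" if K <= 32 else "diag"

    def fit_one(k):
        if Z.shape[0] < k * (K + 1):
            return None
        gm = GaussianMixture(
            n_components=k,
            covariance_type=cov_type,
            random_state=seed,
            reg_covar=reg_covar,
            n_init=1,
        )
        gm.fit(Z)
        return gm

    if n_components is not None:
        gm = fit_one(n_components)
        if gm is None:
            raise LatentError(
                f"need at least n_components*(K+1) = {n_components * (K + 1)} points"
            )
    else:
        best, best_bic = None, np.inf
        for k in range(1, max_components + 1):
            cand = fit_one(k)
            if cand is None:
                break
            bic = cand.bic(Z)
            if bic < best_bic:
                best, best_bic = cand, bic
        if best is None:
            raise LatentError("too few points to fit even a single component")
        gm = best
    return LatentPrior(gm)


# ---------------------------------------------------------------------------
# bootstrapped classifier ensemble


def _make_classifier(family: str, seed: int, cv: int = 5):
    if family == "svc":
        # balanced weights: the top-fraction relabeling scheme yields pools
        # with ~10% positives, which would otherwise swamp the margin
        base = SVC(kernel="rbf", C=1.0, gamma="scale", class_weight="balanced", random_state=seed)
        return CalibratedClassifierCV(base, method="sigmoid", cv=cv)
    if family == "xgboost":
        return XGBClassifier(
            n_estimators=60,
            max_depth=3,
            learning_rate=0.2,
            random_state=seed,
            eval_metric="logloss",
        )
    if family == "logistic":
        return LogisticRegression(max_iter=500, random_state=seed)
    if family == "forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    raise LatentError(f"unknown classifier family {family!r}")


@dataclass
class PosteriorEnsemble:
    """Exactly four bootstrap-trained members; q(c|z) is their mean."""

    members: tuple
    family: str
    cv_metrics: pd.DataFrame

    def __post_init__(self):
        if len(self.members) != 4:
            raise LatentError("the posterior ensemble has exactly 4 members")

    def member_probs(self, z: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(np.asarray(z, dtype=float))
        return np.stack([m.predict_proba(Z)[:, 1] for m in self.members], axis=1)

    def predict_proba(self, z: np.ndarray) -> np.ndarray:
        """Mean positive-class probability over the four members, per row."""
        return self.member_probs(z).mean(axis=1)


def posterior_prob(ensemble: PosteriorEnsemble, z: np.ndarray) -> float:
    """q(c=positive | z) for a single latent vector; deterministic, in [0, 1]."""
    return float(ensemble.predict_proba(np.atleast_2d(z))[0])


def _features_labels(records, encoder: Callable):
    seqs = [r.sequence for r in records]
    y = np.array([1 if r.label == "positive" else 0 for r in records])
    return encoder(seqs), y


def fit_posterior(
    split,
    encoder: Callable,
    family: str = "svc",
    seed: int = 0,
) -> PosteriorEnsemble:
    """Train one classifier per bootstrap dataset on extension encodings.

    ``encoder`` maps a list of sequences to an (n, K) array (typically the
    extension VAE's posterior means).  Each member records its 5-fold CV
    accuracy; a single-class bootstrap is an error.
    """
    members = []
    rows = []
    for b_idx, boot in enumerate(split.bootstraps):
        X, y = _features_labels(boot, encoder)
        counts = np.bincount(y, minlength=2)
        if counts.min() == 0:
            raise LatentError(f"bootstrap {b_idx} contains a single class")
        # 5-fold CV, clamped when the minority class is smaller than 5
        cv_folds = int(min(5, counts.min()))
        if cv_folds < 2:
            raise LatentError(
                f"bootstrap {b_idx}: minority class too small for cross-validation"
            )
        clf = _make_classifier(family, seed + b_idx, cv=cv_folds)
        clf.fit(X, y)
        if counts.min() >= 10:
            cv_acc = cross_val_score(
                _make_classifier(family, seed + b_idx, cv=cv_folds),
                X, y, cv=5, scoring="accuracy",
            ).mean()
        else:  # too few minority examples for a meaningful outer CV
            cv_acc = np.nan
        members.append(clf)
        rows.append({"bootstrap": b_idx, "family": family, "cv_accuracy": cv_acc})
    return PosteriorEnsemble(
        members=tuple(members), family=family, cv_metrics=pd.DataFrame(rows)
    )


def evaluate_classifiers(
    families: Sequence[str],
    split,
    encoder: Callable,
    seed: int = 0,
) -> pd.DataFrame:
    """Held-out accuracy/AUROC per (family, bootstrap) for model selection."""
    if not families:
        raise LatentError("at least one classifier family is required")
    X_test, y_test = _features_labels(split.test, encoder)
    rows = []
    for family in families:
        for b_idx, boot in enumerate(split.bootstraps):
            X, y = _features_labels(boot, encoder)
            clf = _make_classifier(family, seed + b_idx)
            clf.fit(X, y)
            prob = clf.predict_proba(X_test)[:, 1]
            rows.append(
                {
                    "family": family,
                    "bootstrap": b_idx,
                    "accuracy": accuracy_score(y_test, prob >= 0.5),
                    "auroc": roc_auc_score(y_test, prob),
                }
            )
    return pd.DataFrame(rows)


def select_best_family(metrics: pd.DataFrame) -> str:
    """Family with the best mean held-out AUROC (ties: accuracy, then name)."""
    agg = (
        metrics.groupby("family")[["auroc", "accuracy"]]
        .mean()
        .sort_values(["auroc", "accuracy", "family"], ascending=[False, False, True])
    )
    return str(agg.index[0])
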