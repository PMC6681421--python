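"""Ordinary kriging with particle-swarm hyperparameter search.

The model interpolates a scalar atomic property y over feature vectors x as

    y_hat(x*) = mu_hat + sum_i a_i * phi(x* - x_i)

with the generalized-exponential kernel
phi(d) = exp(-sum_j theta_j |d_j|^{p_j}), per-feature widths theta_j > 0 and
exponents p_j in [1, 2].  Given hyperparameters, the generalized
least-squares mean mu_hat = (1' R^-1 y) / (1' R^-1 1) and the weights
a = R^-1 (y - 1 mu_hat) follow from a Cholesky factorization of the
correlation matrix R (never an explicit inverse).  Hyperparameters are
chosen by maximizing the concentrated log-likelihood

    -n/2 * ln(sigma2_hat) - 1/2 * ln det R,
    sigma2_hat = (y - 1 mu_hat)' R^-1 (y - 1 mu_hat) / n

with a global-best particle swarm over (log10 theta, p).  The predictor
passes through its training points (up to the nugget) and decays to mu_hat
far from all of them, which is what makes the mean-shift transfer
(``mu_fix``) between related systems meaningful.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.preprocessing import MinMaxScaler

logger = logging.getLogger(__name__)

__all__ = ["PSOConfig", "KrigingRegressor", "correlation",
           "fit_given_hyperparams", "concentrated_log_likelihood"]


@dataclass
class PSOConfig:
    """Global-best particle swarm settings for the hyperparameter search.

    Inertia and acceleration use the standard constriction values.  Bounds
    are on log10(theta) and on p.  The swarm stops early after ``patience``
    iterations without a relative likelihood improvement above ``tol``.
    """

    n_particles: int = 20
    n_iterations_max: int = 60
    inertia: float = 0.729
    cognitive: float = 1.494
    social: float = 1.494
    tol: float = 1e-8
    patience: int = 12
    seed: int = 0
    log_theta_bounds: tuple[float, float] = (-4.0, 2.0)
    p_bounds: tuple[float, float] = (1.0, 2.0)

    def __post_init__(self) -> None:
        if self.n_particles < 1 or self.n_iterations_max < 1:
            raise ValueError("n_particles and n_iterations_max must be >= 1")
        if self.log_theta_bounds[0] >= self.log_theta_bounds[1]:
            raise ValueError("log_theta_bounds must be ordered")
        if not (1.0 <= self.p_bounds[0] < self.p_bounds[1] <= 2.0):
            raise ValueError("p_bounds must be ordered within [1, 2]")


def correlation(x1, x2, theta, p) -> float:
    """Kernel correlation phi = exp(-sum_j theta_j |x1_j - x2_j|^{p_j})."""
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    theta = np.asarray(theta, float)
    p = np.asarray(p, float)
    if x1.shape != x2.shape:
        raise ValueError(f"length mismatch: {x1.shape} vs {x2.shape}")
    if np.any(theta <= 0):
        raise ValueError("theta must be positive")
    if np.any((p < 1) | (p > 2)):
        raise ValueError("p must lie in [1, 2]")
    return float(np.exp(-np.sum(theta * np.abs(x1 - x2) ** p)))


def _corr_from_absdiff(absdiff: np.ndarray, theta, p) -> np.ndarray:
    """exp(-sum_j theta_j d_j^p_j) over a (..., n_features) |diff| array."""
    acc = np.zeros(absdiff.shape[:-1])
    for j in range(absdiff.shape[-1]):
        acc += theta[j] * absdiff[..., j] ** p[j]
    return np.exp(-acc)


def _corr_matrix(X: np.ndarray, theta, p, nugget: float) -> np.ndarray:
    n = X.shape[0]
    iu = np.triu_indices(n, k=1)
    absdiff = np.abs(X[iu[0]] - X[iu[1]])
    vals = _corr_from_absdiff(absdiff, theta, p)
    R = np.eye(n) * (1.0 + nugget)
    R[iu] = vals
    R[(iu[1], iu[0])] = vals
    return R


def _factor_with_escalation(R0: np.ndarray, nugget: float,
                            nugget_max: float = 1e-6):
    """Cholesky of R0 + nugget*I, escalating the nugget x10 on failure."""
    n = R0.shape[0]
    nug = nugget
    while True:
        try:
            cf = cho_factor(R0 + (nug - nugget) * np.eye(n), lower=True)
            return cf, nug
        except LinAlgError:
            if nug >= nugget_max:
                raise LinAlgError(
                    f"correlation matrix not positive definite even with "
                    f"nugget {nug:g}; consider a larger nugget or fewer "
                    f"near-duplicate training points")
            nug *= 10
            logger.warning("Cholesky failed; escalating nugget to %g", nug)


def fit_given_hyperparams(X, y, theta, p, nugget: float = 1e-10):
    """Solve the ordinary-kriging system for fixed hyperparameters.

    Returns ``(mu_hat, a, log_likelihood)`` where ``a = R^-1 (y - 1 mu_hat)``
    and the likelihood is the concentrated form.  All solves go through one
    symmetric Cholesky factorization.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    theta = np.asarray(theta, float)
    p = np.asarray(p, float)
    n = X.shape[0]
    R = _corr_matrix(X, theta, p, nugget)
    cf, _ = _factor_with_escalation(R, nugget)
    ones = np.ones(n)
    Rinv_y = cho_solve(cf, y)
    Rinv_1 = cho_solve(cf, ones)
    mu_hat = float(ones @ Rinv_y) / float(ones @ Rinv_1)
    resid = y - mu_hat
    a = cho_solve(cf, resid)
    sigma2 = max(float(resid @ a) / n, 1e-300)
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    ll = -0.5 * n * np.log(sigma2) - 0.5 * logdet
    return mu_hat, a, float(ll)


def concentrated_log_likelihood(X, y, theta, p, nugget: float = 1e-10) -> float:
    """Concentrated ordinary-kriging log-likelihood of hyperparameters."""
    return fit_given_hyperparams(X, y, theta, p, nugget)[2]


class KrigingRegressor(BaseEstimator, RegressorMixin):
    """Ordinary kriging interpolator with PSO-optimized kernel hyperparameters.

    Parameters
    ----------
    theta, p : array-like or None
        Fixed kernel widths/exponents; ``None`` (default) optimizes them by
        particle swarm.
    nugget : float
        Diagonal regularizer added to the correlation matrix; escalated x10
        up to 1e-6 if the Cholesky factorization fails.
    normalize : bool
        Min-max scale inputs to [0, 1] column-wise using the training rows
        (test inputs may land outside).  Set ``False`` when X is already
        scaled.
    pso : PSOConfig or None
        Swarm settings; seeded and fully deterministic.

    Fitted attributes (trailing underscore): ``theta_``, ``p_``, ``mu_``,
    ``weights_``, ``X_train_``, ``y_train_``, ``log_likelihood_``,
    ``n_iter_``, ``nugget_``, ``scaler_``.
    """

    def __init__(self, theta=None, p=None, nugget: float = 1e-10,
                 normalize: bool = True, pso: PSOConfig | None = None):
        self.theta = theta
        self.p = p
        self.nugget = nugget
        self.normalize = normalize
        self.pso = pso

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, float))
        y = np.asarray(y, float).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y row counts differ")
        if X.shape[0] < 1:
            raise ValueError("need at least one training point")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite training data")
        if self.normalize:
            self.scaler_ = MinMaxScaler().fit(X)
            Xs = self.scaler_.transform(X)
        else:
            self.scaler_ = None
            Xs = X
        nf = X.shape[1]
        if self.theta is not None and self.p is not None:
            self.theta_ = np.broadcast_to(np.asarray(self.theta, float), (nf,)).copy()
            self.p_ = np.broadcast_to(np.asarray(self.p, float), (nf,)).copy()
            self.n_iter_ = 0
        else:
            self.theta_, self.p_, self.n_iter_ = self._pso_search(Xs, y)
        mu, a, ll = fit_given_hyperparams(Xs, y, self.theta_, self.p_,
                                          self.nugget)
        self.mu_ = mu
        self.weights_ = a
        self.log_likelihood_ = ll
        self.X_train_ = Xs
        self.y_train_ = y
        self.nugget_ = self.nugget
        return self

    def _pso_search(self, Xs, y):
        cfg = self.pso if self.pso is not None else PSOConfig()
        nf = Xs.shape[1]
        dim = 2 * nf
        lo = np.concatenate([np.full(nf, cfg.log_theta_bounds[0]),
                             np.full(nf, cfg.p_bounds[0])])
        hi = np.concatenate([np.full(nf, cfg.log_theta_bounds[1]),
                             np.full(nf, cfg.p_bounds[1])])
        rng = np.random.default_rng(cfg.seed)
        pos = rng.uniform(lo, hi, size=(cfg.n_particles, dim))
        vel = rng.uniform(-(hi - lo), hi - lo, size=(cfg.n_particles, dim)) * 0.1

        # Precompute the condensed |x_i - x_k| table once; every likelihood
        # evaluation reuses it.
        n = Xs.shape[0]
        iu = np.triu_indices(n, k=1)
        absdiff = np.abs(Xs[iu[0]] - Xs[iu[1]])

        def objective(q: np.ndarray) -> float:
            theta = 10.0 ** q[:nf]
            p = q[nf:]
            vals = _corr_from_absdiff(absdiff, theta, p)
            R = np.eye(n) * (1.0 + self.nugget)
            R[iu] = vals
            R[(iu[1], iu[0])] = vals
            try:
                cf, _ = _factor_with_escalation(R, self.nugget)
            except LinAlgError:
                return -np.inf
            ones = np.ones(n)
            Rinv_y = cho_solve(cf, y)
            Rinv_1 = cho_solve(cf, ones)
            mu = float(ones @ Rinv_y) / float(ones @ Rinv_1)
            resid = y - mu
            sigma2 = max(float(resid @ cho_solve(cf, resid)) / n, 1e-300)
            logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
            return -0.5 * n * np.log(sigma2) - 0.5 * logdet

        pbest = pos.copy()
        pbest_val = np.array([objective(q) for q in pos])
        if not np.any(np.isfinite(pbest_val)):
            raise RuntimeError("likelihood non-finite at every PSO particle")
        g = int(np.argmax(pbest_val))
        gbest, gbest_val = pbest[g].copy(), pbest_val[g]
        stagnant = 0
        it = 0
        for it in range(1, cfg.n_iterations_max + 1):
            r1 = rng.uniform(size=(cfg.n_particles, dim))
            r2 = rng.uniform(size=(cfg.n_particles, dim))
            vel = (cfg.inertia * vel
                   + cfg.cognitive * r1 * (pbest - pos)
                   + cfg.social * r2 * (gbest - pos))
            pos = np.clip(pos + vel, lo, hi)
            vals = np.array([objective(q) for q in pos])
            improved = vals > pbest_val
            pbest[improved] = pos[improved]
            pbest_val[improved] = vals[improved]
            g = int(np.argmax(pbest_val))
            if pbest_val[g] > gbest_val + cfg.tol * max(1.0, abs(gbest_val)):
                gbest, gbest_val = pbest[g].copy(), pbest_val[g]
                stagnant = 0
            else:
                stagnant += 1
                if stagnant >= cfg.patience:
                    break
        logger.info("PSO finished after %d iterations, log-likelihood %.6g",
                    it, gbest_val)
        return 10.0 ** gbest[:nf], gbest[nf:].copy(), it

    # -- prediction --------------------------------------------------------

    def _transform(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.X_train_.shape[1]:
            raise ValueError(
                f"expected {self.X_train_.shape[1]} features, got {X.shape[1]}")
        if self.scaler_ is not None:
            X = self.scaler_.transform(X)
        return X

    def predict(self, X) -> np.ndarray:
        """Evaluate y_hat(x*) = mu_hat + sum_i a_i phi(x* - x_i) rowwise."""
        if not hasattr(self, "weights_"):
            raise RuntimeError("model is not fitted")
        Xs = self._transform(X)
        absdiff = np.abs(Xs[:, None, :] - self.X_train_[None, :, :])
        phi = _corr_from_absdiff(absdiff, self.theta_, self.p_)
        return self.mu_ + phi @ self.weights_

    def predict_one(self, x_star) -> float:
        return float(self.predict(np.atleast_2d(x_star))[0])

    # -- model transfer ----------------------------------------------------

    def mu_fix(self, mu_new: float, mode: str = "shift") -> "KrigingRegressor":
        """Transfer the model to a related system by replacing the mean.

        ``shift`` keeps the weights and swaps the additive mean, displacing
        every prediction by ``mu_new - mu_``; ``refit`` also recomputes the
        weights as ``R^-1 (y - 1 mu_new)``.  Returns a new model; the
        original is untouched.
        """
        if not np.isfinite(mu_new):
            raise ValueError("mu_new must be finite")
        if mode not in ("shift", "refit"):
            raise ValueError("mode must be 'shift' or 'refit'")
        out = KrigingRegressor(theta=self.theta_, p=self.p_,
                               nugget=self.nugget, normalize=self.normalize,
                               pso=self.pso)
        for attr in ("theta_", "p_", "X_train_", "y_train_", "scaler_",
                     "log_likelihood_", "n_iter_", "nugget_"):
            setattr(out, attr, getattr(self, attr))
        out.mu_ = float(mu_new)
        if mode == "shift":
            out.weights_ = self.weights_.copy()
        else:
            R = _corr_matrix(self.X_train_, self.theta_, self.p_, self.nugget)
            cf, _ = _factor_with_escalation(R, self.nugget)
            out.weights_ = cho_solve(cf, self.y_train_ - mu_new)
        logger.info("mu_fix(%s): mu %.6g -> %.6g", mode, self.mu_, mu_new)
        return out

    # -- serialization -----------------------------------------------------

    def to_json(self, path=None) -> str:
        """Serialize the fitted model (hyperparameters, weights, scaler)."""
        if not hasattr(self, "weights_"):
            raise RuntimeError("model is not fitted")
        payload = {
            "format": "alfkrig-kriging-model",
            "version": 1,
            "theta": self.theta_.tolist(),
            "p": self.p_.tolist(),
            "mu": self.mu_,
            "weights": self.weights_.tolist(),
            "X_train": self.X_train_.tolist(),
            "y_train": self.y_train_.tolist(),
            "nugget": self.nugget_,
            "log_likelihood": self.log_likelihood_,
            "n_iter": self.n_iter_,
            "scaler": None if self.scaler_ is None else {
                "min": self.scaler_.data_min_.tolist(),
                "max": self.scaler_.data_max_.tolist(),
            },
            "training_data_sha256": hashlib.sha256(
                np.ascontiguousarray(self.X_train_).tobytes()
                + np.ascontiguousarray(self.y_train_).tobytes()).hexdigest(),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "KrigingRegressor":
        """Load a model serialized by :meth:`to_json` (path or JSON string)."""
        try:
            with open(source) as fh:
                payload = json.load(fh)
        except (OSError, TypeError):
            payload = json.loads(source)
        if payload.get("format") != "alfkrig-kriging-model":
            raise ValueError("not an alfkrig kriging model file")
        model = cls(nugget=payload["nugget"],
                    normalize=payload["scaler"] is not None)
        model.theta_ = np.array(payload["theta"])
        model.p_ = np.array(payload["p"])
        model.mu_ = payload["mu"]
        model.weights_ = np.array(payload["weights"])
        model.X_train_ = np.array(payload["X_train"])
        model.y_train_ = np.array(payload["y_train"])
        model.nugget_ = payload["nugget"]
        model.log_likelihood_ = payload["log_likelihood"]
        model.n_iter_ = payload["n_iter"]
        if payload["scaler"] is None:
            model.scaler_ = None
        else:
            sc = MinMaxScaler()
            dmin = np.array(payload["scaler"]["min"])
            dmax = np.array(payload["scaler"]["max"])
            sc.fit(np.vstack([dmin, dmax]))
            model.scaler_ = sc
        return model
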