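"""Maximum-likelihood CJS models with a transience structure.

The likelihood is the product of cohort multinomials over the m-array.
For a resident released at occasion ``t``, the probability of a first
recapture at occasion ``j`` is

    P(t, j) = phi_t * prod_{k=t+1}^{j-1} [(1 - p_k) * phi_k] * p_j .

A *newly marked* animal is a transient with probability ``tau`` and then
contributes nothing after its release; its first-interval apparent
survival is therefore ``(1 - tau) * phi_t`` while previously marked
(re-released) animals use the resident ``phi_t``.  ``tau`` is estimated
directly on a logit scale (optionally as a function of age group, time,
or a per-occasion covariate), which keeps it in [0, 1] and makes
covariate models natural; the classic two-class-survival parameterization
(separate first-interval survival, ``tau = 1 - phi_new / phi``) is
available for cross-checks.

Model selection uses AIC; the temporal signal in ``tau`` is attributed to
a covariate with an analysis of deviance (ANODEV) locating the covariate
model between the constant and fully time-dependent models.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import _numdiff
from .encounter import MArray

__all__ = [
    "ModelSpec",
    "FitResult",
    "TransientEstimates",
    "neg_log_likelihood",
    "fit",
    "tau_from_fit",
    "anodev",
    "aic_table",
    "IdentifiabilityError",
    "ConvergenceError",
]

_TINY = 1e-300

TAU_STRUCTURES = (
    "none", "const", "group", "cov", "group+cov", "group*cov", "time", "group+time",
)


class IdentifiabilityError(ValueError):
    """The requested model is not identifiable from the data's dimensions."""


class ConvergenceError(RuntimeError):
    """Optimization failed; carries the best incumbent fit."""

    def __init__(self, message: str, incumbent: "FitResult | None" = None):
        super().__init__(message)
        self.incumbent = incumbent


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class ModelSpec:
    """Structure of one transient-CJS model.

    ``phi`` and ``p`` are ``"const"`` or ``"time"``; ``tau`` is one of
    ``none | const | group | cov | group+cov | group*cov | time |
    group+time`` (additive terms on the logit scale; ``*`` adds per-group
    covariate slopes).  ``covariate`` is the per-occasion series (length =
    number of occasions), standardized internally before entering the
    design.  ``parameterization="twoclass"`` replaces the direct-tau block
    by a free newly-marked first-interval survival (const/group structures
    only).
    """

    phi: str = "const"
    p: str = "const"
    tau: str = "const"
    covariate: tuple[float, ...] | None = None
    parameterization: str = "direct"

    def __post_init__(self):
        if self.phi not in ("const", "time"):
            raise ValueError(f"unknown phi structure {self.phi!r}")
        if self.p not in ("const", "time"):
            raise ValueError(f"unknown p structure {self.p!r}")
        if self.tau not in TAU_STRUCTURES:
            raise ValueError(f"unknown tau structure {self.tau!r}")
        if self.parameterization not in ("direct", "twoclass"):
            raise ValueError(f"unknown parameterization {self.parameterization!r}")
        if self.parameterization == "twoclass" and self.tau not in (
            "none", "const", "group"
        ):
            raise ValueError("twoclass parameterization supports const/group only")
        if "cov" in self.tau and self.covariate is None:
            raise ValueError(f"tau structure {self.tau!r} requires a covariate")
        if self.covariate is not None:
            object.__setattr__(self, "covariate", tuple(float(v) for v in self.covariate))


class _Design:
    """Parameter layout and design matrices for a (spec, m-array) pair."""

    def __init__(self, spec: ModelSpec, marray: MArray):
        self.spec = spec
        K = marray.n_occasions
        G = len(marray.groups)
        if K < 2:
            raise IdentifiabilityError("need at least 2 occasions")
        self.K, self.G = K, G
        self.n_phi = 1 if spec.phi == "const" else K - 1
        self.n_p = 1 if spec.p == "const" else K - 1
        self.X_tau = self._tau_design(spec, marray)
        self.n_tau = self.X_tau.shape[1]
        self.n_params = self.n_phi + self.n_p + self.n_tau
        self.labels = (
            [f"phi[{i + 1}]" for i in range(self.n_phi)]
            + [f"p[{j + 1}]" for j in range(self.n_p)]
            + self.tau_labels
        )
    def check_identifiable(self, marray: MArray) -> None:
        """Raise if the model cannot be identified from these data.

        Called by :func:`fit`; plain likelihood evaluation is allowed for
        any dimensions.
        """
        K = self.K
        informative = int((marray.released[:, :, : K - 1] > 0).sum()) * (K - 1)
        if self.n_params > max(informative, 0):
            raise IdentifiabilityError(
                f"{self.n_params} parameters for {informative} informative cells"
            )
        if K < 3 and self.n_params > 1:
            raise IdentifiabilityError(
                "two occasions identify only the product phi*p"
            )
        if self.n_tau:
            rank = np.linalg.matrix_rank(self.X_tau)
            if rank < self.n_tau:
                raise IdentifiabilityError(
                    f"tau design matrix rank {rank} < {self.n_tau} columns"
                )

    def _tau_design(self, spec: ModelSpec, marray: MArray) -> np.ndarray:
        K, G = self.K, self.G
        grid = list(itertools.product(range(G), range(K - 1)))  # (g, t) rows
        cols: list[np.ndarray] = []
        self.tau_labels: list[str] = []
        structure = spec.tau
        if structure == "none":
            return np.zeros((len(grid), 0))
        x = None
        if "cov" in structure:
            x = np.asarray(spec.covariate, dtype=float)
            if x.shape != (K,):
                raise ValueError("covariate length must equal the number of occasions")
            sd = x.std()
            x = (x - x.mean()) / (sd if sd > 0 else 1.0)
        if "group" in structure:
            for g in range(G):
                cols.append(np.array([1.0 if gg == g else 0.0 for gg, _ in grid]))
                self.tau_labels.append(f"tau:alpha[{marray.groups[g]}]")
        else:
            cols.append(np.ones(len(grid)))
            self.tau_labels.append("tau:alpha")
        if structure in ("cov", "group+cov"):
            cols.append(np.array([x[t] for _, t in grid]))
            self.tau_labels.append("tau:beta")
        elif structure == "group*cov":
            for g in range(G):
                cols.append(np.array([x[t] if gg == g else 0.0 for gg, t in grid]))
                self.tau_labels.append(f"tau:beta[{marray.groups[g]}]")
        elif structure in ("time", "group+time"):
            for t in range(1, K - 1):
                cols.append(np.array([1.0 if tt == t else 0.0 for _, tt in grid]))
                self.tau_labels.append(f"tau:delta[{t + 1}]")
        return np.column_stack(cols)

    def split(self, theta: np.ndarray):
        a, b = self.n_phi, self.n_phi + self.n_p
        return theta[:a], theta[a:b], theta[b:]

    def phi_vector(self, theta_phi: np.ndarray) -> np.ndarray:
        v = _expit(theta_phi)
        return np.broadcast_to(v, (self.K - 1,)) if self.n_phi == 1 else v

    def p_vector(self, theta_p: np.ndarray) -> np.ndarray:
        v = _expit(theta_p)
        return np.broadcast_to(v, (self.K - 1,)) if self.n_p == 1 else v

    def tau_eta(self, theta_tau: np.ndarray) -> np.ndarray:
        """(G, K-1) linear predictor of the transient block."""
        if self.n_tau == 0:
            return np.full((self.G, self.K - 1), -np.inf)
        return (self.X_tau @ theta_tau).reshape(self.G, self.K - 1)


class _Statistics:
    """Pooled m-array statistics entering the likelihood."""

    def __init__(self, marray: MArray):
        K = marray.n_occasions
        self.m_pooled = marray.m.sum(axis=(0, 1))[: K - 1, :]     # (K-1, K)
        never = marray.never_seen_again
        self.never_old = never[:, 1, : K - 1].sum(axis=0)          # (K-1,)
        self.seen_new = marray.m[:, 0, : K - 1, :].sum(axis=2)     # (G, K-1)
        self.never_new = never[:, 0, : K - 1]                      # (G, K-1)
        self.marray = marray

    def saturated_loglik(self) -> float:
        ll = 0.0
        K = self.marray.n_occasions
        never = self.marray.never_seen_again
        for g, c, t in zip(*np.nonzero(self.marray.released[:, :, : K - 1])):
            R = self.marray.released[g, c, t]
            cells = np.append(self.marray.m[g, c, t, t + 1 :], never[g, c, t])
            nz = cells[cells > 0]
            ll += float((nz * np.log(nz / R)).sum())
        return ll


def _resident_logP(phi: np.ndarray, p: np.ndarray, K: int):
    """(K-1, K) matrix of log first-recapture probabilities for residents,
    and the (K-1,) log probability of never being seen again."""
    lphi = np.log(np.clip(phi, _TINY, 1.0))
    lp = np.log(np.clip(p, _TINY, 1.0))
    lq = np.log(np.clip(1.0 - p, _TINY, 1.0))
    # S[t] = sum of lphi[:t]; Q[t] = sum of lq[:t] (occasion t has detection p[t-1])
    S = np.concatenate([[0.0], np.cumsum(lphi)])
    Q = np.concatenate([[0.0], np.cumsum(lq)])
    t = np.arange(K - 1)[:, None]
    j = np.arange(K)[None, :]
    with np.errstate(invalid="ignore"):
        logP = (S[j] - S[t]) + (Q[np.maximum(j - 1, 0)] - Q[t]) + lp[
            np.clip(j - 1, 0, K - 2)
        ]
    logP = np.where(j > t, logP, -np.inf)
    P = np.exp(logP)
    nr = np.clip(1.0 - P.sum(axis=1), _TINY, 1.0)
    return logP, P, np.log(nr), nr


def neg_log_likelihood(theta: np.ndarray, marray: MArray, spec: ModelSpec) -> float:
    """Negative multinomial log-likelihood of the transient-CJS model."""
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("non-finite parameter vector")
    design = _Design(spec, marray)
    stats_ = _Statistics(marray)
    return _nll(theta, design, stats_)


def _nll(theta: np.ndarray, design: _Design, st: _Statistics) -> float:
    th_phi, th_p, th_tau = design.split(theta)
    phi = design.phi_vector(th_phi)
    p = design.p_vector(th_p)
    logP, P, log_nr, nr = _resident_logP(phi, p, design.K)
    ll = float(np.where(st.m_pooled > 0, st.m_pooled * np.where(np.isfinite(logP), logP, 0.0), 0.0).sum())
    ll += float((st.never_old * log_nr).sum())
    if design.spec.parameterization == "twoclass":
        # free newly-marked first-interval survival s1 (replaces (1-tau)*phi)
        eta = design.tau_eta(th_tau)
        s1 = _expit(eta)                        # (G, K-1)
        ratio = np.clip(s1 / np.clip(phi[None, :], _TINY, None), _TINY, None)
        log_ratio = np.log(ratio)
        never_cell = np.clip(1.0 - ratio * (1.0 - nr[None, :]), _TINY, 1.0)
    else:
        eta = design.tau_eta(th_tau)
        one_minus_tau = _expit(-eta)            # 1 - tau
        tau = _expit(eta)
        log_ratio = np.log(np.clip(one_minus_tau, _TINY, 1.0))
        never_cell = np.clip(tau + one_minus_tau * nr[None, :], _TINY, 1.0)
    ll += float((st.seen_new * log_ratio).sum())
    ll += float((st.never_new * np.log(never_cell)).sum())
    return -ll


@dataclass
class FitResult:
    """Maximum-likelihood fit of one model specification."""

    spec: ModelSpec
    groups: tuple[str, ...]
    n_occasions: int
    theta: np.ndarray
    labels: list[str]
    vcov: np.ndarray
    loglik: float
    deviance: float
    n_params: int
    aic: float
    converged: bool
    grad_norm: float
    boundary: bool
    n_released_total: int
    confounded_tail: bool = False

    def _design(self) -> _Design:
        # reconstruct layout (cheap; avoids holding the m-array)
        fake = MArray(
            self.groups,
            self.n_occasions,
            np.ones((len(self.groups), 2, self.n_occasions), dtype=np.int64),
            np.zeros((len(self.groups), 2, self.n_occasions, self.n_occasions), dtype=np.int64),
        )
        return _Design(self.spec, fake)

    @property
    def phi_estimates(self) -> np.ndarray:
        d = self._design()
        return d.phi_vector(d.split(self.theta)[0])

    @property
    def p_estimates(self) -> np.ndarray:
        d = self._design()
        return d.p_vector(d.split(self.theta)[1])

    def summary(self) -> pd.DataFrame:
        se = np.sqrt(np.clip(np.diag(self.vcov), 0, None))
        return pd.DataFrame(
            {"parameter": self.labels, "estimate": self.theta, "se": se}
        )

    def to_dict(self) -> dict:
        return {
            "spec": {
                "phi": self.spec.phi, "p": self.spec.p, "tau": self.spec.tau,
                "parameterization": self.spec.parameterization,
            },
            "loglik": self.loglik, "deviance": self.deviance,
            "n_params": self.n_params, "aic": self.aic,
            "converged": self.converged, "boundary": self.boundary,
            "estimates": dict(zip(self.labels, map(float, self.theta))),
        }


def fit(
    marray: MArray,
    spec: ModelSpec,
    starts: np.ndarray | None = None,
    n_restarts: int = 3,
    seed: int = 0,
    compute_vcov: bool = True,
    grad_tol: float = 1e-2,
) -> FitResult:
    """Fit a transient-CJS model by maximum likelihood.

    Quasi-Newton (L-BFGS-B) on the link scale from a zero start plus
    ``n_restarts`` random restarts; the best optimum is kept.  The
    covariance matrix is the inverse of a central-difference Hessian.
    Estimates with |logit| > 12 are flagged as boundary.

    Raises
    ------
    IdentifiabilityError
        Model has more parameters than the data can identify.
    ConvergenceError
        No restart converged; carries the best incumbent.
    """
    design = _Design(spec, marray)
    design.check_identifiable(marray)
    st = _Statistics(marray)
    rng = np.random.default_rng(seed)

    start_list = [np.zeros(design.n_params)]
    if starts is not None:
        start_list.insert(0, np.asarray(starts, dtype=float))
    for _ in range(n_restarts):
        start_list.append(rng.normal(0.0, 0.7, design.n_params))

    best = None
    any_success = False
    for x0 in start_list:
        res = optimize.minimize(_nll, x0, args=(design, st), method="L-BFGS-B",
                                options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res
        any_success = any_success or res.success

    theta = best.x
    grad = _numdiff.gradient(lambda v: _nll(v, design, st), theta)
    grad_norm = float(np.linalg.norm(grad, ord=np.inf))
    n_total = int(marray.released.sum())
    # scale-aware gradient tolerance: the likelihood is O(n_total)
    tol = grad_tol * max(1.0, n_total / 100.0)
    converged = bool(any_success and grad_norm <= tol)
    boundary = bool(np.any(np.abs(theta) > 12.0))

    if compute_vcov:
        H = _numdiff.hessian(lambda v: _nll(v, design, st), theta)
        try:
            vcov = np.linalg.inv(H)
            if np.any(np.diag(vcov) < 0):
                vcov = np.linalg.pinv(H)
        except np.linalg.LinAlgError:
            vcov = np.linalg.pinv(H)
    else:
        vcov = np.full((design.n_params, design.n_params), np.nan)

    loglik = -float(best.fun)
    deviance = 2.0 * (st.saturated_loglik() - loglik)
    result = FitResult(
        spec=spec, groups=marray.groups, n_occasions=marray.n_occasions,
        theta=theta, labels=design.labels, vcov=vcov, loglik=loglik,
        deviance=deviance, n_params=design.n_params,
        aic=2.0 * design.n_params - 2.0 * loglik,
        converged=converged, grad_norm=grad_norm, boundary=boundary,
        n_released_total=n_total,
        confounded_tail=(spec.phi == "time" and spec.p == "time"),
    )
    if not converged and not boundary:
        raise ConvergenceError(
            f"no converged optimum (grad norm {grad_norm:.3g} > {tol:.3g})", result
        )
    return result


@dataclass
class TransientEstimates:
    """Estimated transient probabilities per (group, release occasion)."""

    table: pd.DataFrame  # columns: group, occasion, tau, se, lo, hi
    undefined: bool = False

    def by_group(self, group: str) -> pd.DataFrame:
        return self.table[self.table["group"] == group].reset_index(drop=True)


def tau_from_fit(fit_result: FitResult, confidence: float = 0.95) -> TransientEstimates:
    """Transient probabilities with delta-method CIs on the logit scale.

    For the direct parameterization tau is read off the linear predictor;
    for the two-class parameterization tau = 1 - phi_new / phi with a
    delta-method standard error (flagged undefined if phi is estimated
    at 0).
    """
    design = fit_result._design()
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    rows = []
    if fit_result.spec.parameterization == "direct":
        if design.n_tau == 0:
            raise ValueError("model has no transient block")
        a, b = design.n_phi, design.n_phi + design.n_p
        X = design.X_tau
        V = fit_result.vcov[b:, b:]
        eta = X @ fit_result.theta[b:]
        se_eta = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", X, V, X), 0, None))
        tau = _expit(eta)
        lo = _expit(eta - z * se_eta)
        hi = _expit(eta + z * se_eta)
        se = tau * (1 - tau) * se_eta
        for r, (g, t) in enumerate(itertools.product(fit_result.groups,
                                                     range(design.K - 1))):
            rows.append((g, t + 1, tau[r], se[r], lo[r], hi[r]))
        return TransientEstimates(
            pd.DataFrame(rows, columns=["group", "occasion", "tau", "se", "lo", "hi"])
        )
    # two-class: tau = 1 - s1/phi (const phi assumed per structure restriction)
    th_phi, _, th_tau = design.split(fit_result.theta)
    phi = float(_expit(th_phi[0]))
    if phi <= 0:
        return TransientEstimates(pd.DataFrame(), undefined=True)
    undefined = phi < 1e-8
    a, b = design.n_phi, design.n_phi + design.n_p
    idx_phi = 0
    for r, (g, t) in enumerate(itertools.product(fit_result.groups,
                                                 range(design.K - 1))):
        x_row = design.X_tau[r]
        eta1 = float(x_row @ th_tau)
        s1 = float(_expit(eta1))
        tau = 1.0 - s1 / phi
        # gradient wrt (theta_phi, theta_tau_block)
        d_phi = s1 / phi * (1 - phi)          # d tau / d theta_phi
        d_s1 = -s1 * (1 - s1) / phi           # d tau / d eta1
        grad = np.zeros(fit_result.n_params)
        grad[idx_phi] = d_phi
        grad[b:] = d_s1 * x_row
        var = float(grad @ fit_result.vcov @ grad)
        se = np.sqrt(max(var, 0.0))
        rows.append((g, t + 1, tau, se, max(tau - z * se, 0.0), min(tau + z * se, 1.0)))
    return TransientEstimates(
        pd.DataFrame(rows, columns=["group", "occasion", "tau", "se", "lo", "hi"]),
        undefined=undefined,
    )


def anodev(fit_constant: FitResult, fit_covariate: FitResult,
           fit_time: FitResult) -> tuple[float, float, float]:
    """Analysis of deviance for a covariate between constant and time models.

    Returns ``(F, pct_deviance, p)`` where ``pct_deviance`` is the share of
    the temporal deviance explained by the covariate,
    ``(Dev_cst - Dev_cov) / (Dev_cst - Dev_t)``, and F has
    ``(np_cov - np_cst, np_t - np_cov)`` degrees of freedom.

    Raises
    ------
    ValueError
        Parameter counts are not strictly nested.
    """
    n_c, n_x, n_t = (fit_constant.n_params, fit_covariate.n_params,
                     fit_time.n_params)
    if not (n_c < n_x < n_t):
        raise ValueError(
            f"models must be nested constant < covariate < time "
            f"(got {n_c}, {n_x}, {n_t} parameters)"
        )
    d_c, d_x, d_t = (fit_constant.deviance, fit_covariate.deviance,
                     fit_time.deviance)
    df1, df2 = n_x - n_c, n_t - n_x
    num = (d_c - d_x) / df1
    den = (d_x - d_t) / df2
    F = num / den if den > 0 else np.inf
    pct = (d_c - d_x) / (d_c - d_t) if d_c != d_t else np.nan
    p = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return float(F), float(pct), p


def aic_table(fits: Sequence[FitResult]) -> pd.DataFrame:
    """AIC ranking with delta-AIC and Akaike weights.

    Refuses to rank fits of different datasets (occasion count or total
    releases differ).
    """
    if not fits:
        raise ValueError("no fits to rank")
    key = {(f.n_occasions, f.n_released_total) for f in fits}
    if len(key) > 1:
        raise ValueError("fits come from different datasets; refusing to rank")
    rows = []
    for f in fits:
        rows.append({
            "model": f"phi({f.spec.phi}) p({f.spec.p}) tau({f.spec.tau})",
            "n_params": f.n_params, "loglik": f.loglik,
            "deviance": f.deviance, "aic": f.aic,
        })
    df = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    df["delta_aic"] = df["aic"] - df["aic"].iloc[0]
    w = np.exp(-0.5 * df["delta_aic"].to_numpy())
    df["weight"] = w / w.sum()
    return df
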