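"""Coefficient interpretation and the logistic-ratio comparison.

Under the ``{-1, +1}`` outcome coding the number of positive outcomes is
``S = sum_i (Y_i + 1)/2``, so replacing ``m`` individuals by counterparts
one unit higher in covariate ``j`` changes ``E(S)`` by ``m * beta_j / 2``.
For binary covariates coded ``{-1, +1}`` a level change spans two units
and the division by two drops out.

Coefficient magnitudes of a logistic fit are not comparable to the linear
model's, but their pairwise *ratios* are, and the two sets of ratios agree
in the small-signal limit (logit(p) ~ 2 * (2p - 1) near p = 1/2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .exceptions import OptimizationFailureError, SeparationError
from .model import BINARY_PM1, CONTINUOUS, BinaryDataset, LpmFit, _check_rank

_RATIO_EPS = 1e-12


@dataclass
class EffectStatement:
    """A coefficient rendered as an expected-count change."""

    covariate_name: str
    coefficient: float
    covariate_kind: str
    m: int
    expected_change: float

    @property
    def text(self) -> str:
        direction = "increase" if self.expected_change >= 0 else "decrease"
        unit = (
            "switching level (a two-unit change under {-1,+1} coding)"
            if self.covariate_kind == BINARY_PM1
            else "one unit higher"
        )
        return (
            f"replacing {self.m} individuals by counterparts {unit} in "
            f"{self.covariate_name!r} changes the expected number of positive "
            f"outcomes by {self.expected_change:+.4g} "
            f"(a {abs(self.expected_change):.4g}-count {direction})"
        )


@dataclass
class RatioComparison:
    """Pairwise coefficient ratios of the linear and logistic fits."""

    lpm_coefficients: np.ndarray
    logit_coefficients: np.ndarray
    ratio_matrix_lpm: np.ndarray
    ratio_matrix_logit: np.ndarray
    max_relative_discrepancy: float
    names: tuple


def effect_statement(
    fit: LpmFit, covariate_name: str, m: int, kind: str
) -> EffectStatement:
    """Expected-count effect of a unit (or level) change for ``m`` individuals."""
    if m <= 0:
        raise ValueError("m must be a positive integer")
    if kind not in (BINARY_PM1, CONTINUOUS):
        raise ValueError(f"unknown covariate kind {kind!r}")
    try:
        j = fit.column_names.index(covariate_name)
    except ValueError as exc:
        raise KeyError(
            f"covariate {covariate_name!r} not in fit "
            f"(have {list(fit.column_names)})"
        ) from exc
    beta_j = float(fit.beta_hat[j])
    change = m * beta_j if kind == BINARY_PM1 else m * beta_j / 2.0
    return EffectStatement(
        covariate_name=covariate_name,
        coefficient=beta_j,
        covariate_kind=kind,
        m=int(m),
        expected_change=float(change),
    )


def fit_logistic(
    data: BinaryDataset, tol: float = 1e-8, max_iter: int = 100
):
    """Logistic regression on the ``Z = (Y + 1)/2`` recode by Newton-Raphson.

    Returns ``(beta, cov)`` with ``cov`` the inverse Fisher information at
    the optimum.  Raises :class:`SeparationError` when the iterates diverge
    in the way characteristic of perfectly separated data.
    """
    if data.has_missing:
        raise ValueError("resolve missingness before fitting")
    X = data.X
    z = (data.y + 1.0) / 2.0
    _check_rank(X, data.column_names)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        if np.max(np.abs(eta)) > 500.0 or np.linalg.norm(beta) > 1e6:
            raise SeparationError(
                "fitted log odds diverging; data appear perfectly separated"
            )
        mu = expit(eta)
        score = X.T @ (z - mu)
        if np.max(np.abs(score)) < tol:
            # a vanishing score with every fitted probability pinned at its
            # observed outcome is the signature of perfect separation (the
            # likelihood has no interior maximum)
            if np.all(np.abs(z - mu) < 1e-6) and np.max(np.abs(eta)) > 30.0:
                raise SeparationError(
                    "all fitted probabilities pinned at the outcomes; "
                    "data appear perfectly separated"
                )
            w = mu * (1.0 - mu)
            info = (X * w[:, None]).T @ X
            cov = np.linalg.inv(info)
            return beta, 0.5 * (cov + cov.T)
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        info = (X * w[:, None]).T @ X
        step = np.linalg.solve(info, score)
        # step-halving on the Bernoulli log likelihood; the slack is
        # relative because near the optimum the improvement drops below
        # the rounding noise of the sum
        ll0 = np.sum(z * eta - np.logaddexp(0.0, eta))
        slack = 1e-10 * (abs(ll0) + 1.0)
        t = 1.0
        while t > 1e-10:
            cand = beta + t * step
            eta_c = X @ cand
            if np.sum(z * eta_c - np.logaddexp(0.0, eta_c)) >= ll0 - slack:
                break
            t *= 0.5
        else:
            t = 1.0  # concave objective: full Newton step is safe this close in
        beta = beta + t * step
    raise OptimizationFailureError(
        f"logistic fit did not converge in {max_iter} iterations", last_beta=beta
    )


def _ratio_matrix(beta: np.ndarray) -> np.ndarray:
    denom = np.where(np.abs(beta) > _RATIO_EPS, beta, np.nan)
    return beta[:, None] / denom[None, :]


def compare_ratios(
    lpm: LpmFit, logit_beta: np.ndarray, exclude_intercept: bool = True
) -> RatioComparison:
    """Pairwise coefficient ratios of both fits and their worst discrepancy.

    Ratios whose denominator magnitude is at or below 1e-12 are reported
    as NaN (undefined), and pairs undefined in either fit are excluded
    from the discrepancy maximum.
    """
    logit_beta = np.asarray(logit_beta, dtype=float)
    if logit_beta.shape != lpm.beta_hat.shape:
        raise ValueError(
            f"coefficient length mismatch: lpm has {lpm.beta_hat.size}, "
            f"logistic has {logit_beta.size}"
        )
    sl = slice(1, None) if exclude_intercept else slice(None)
    b_lpm = lpm.beta_hat[sl]
    b_log = logit_beta[sl]
    names = lpm.column_names[sl]
    r_lpm = _ratio_matrix(b_lpm)
    r_log = _ratio_matrix(b_log)
    defined = np.isfinite(r_lpm) & np.isfinite(r_log)
    np.fill_diagonal(defined, False)
    if defined.any():
        rel = np.abs(r_lpm - r_log) / np.maximum(np.abs(r_log), _RATIO_EPS)
        max_disc = float(np.max(rel[defined]))
    else:
        max_disc = np.nan
    return RatioComparison(
        lpm_coefficients=b_lpm,
        logit_coefficients=b_log,
        ratio_matrix_lpm=r_lpm,
        ratio_matrix_logit=r_log,
        max_relative_discrepancy=max_disc,
        names=tuple(names),
    )
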