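"""Out-of-range diagnostics for fitted linear-in-probability models.

Even when the model holds, estimation noise pushes some fitted linear
predictors outside ``[-1, 1]``.  The number of such rows, ``R``, has a
model-based expectation ``lambda = sum_i p_i`` with

    p_i = Phi((-1 + delta_i) / s_i) + Phi((-1 - delta_i) / s_i),

``s_i^2 = x_i' Sigma_beta x_i`` the variance of the estimated predictor.
An observed ``R`` much larger than ``lambda`` casts doubt on the model.

``var(R)`` exceeds the independence value ``sum p_i (1 - p_i)`` because the
summands share the estimation error of beta; the pairwise corrections are
bivariate-normal quadrant probabilities evaluated at the standardised
thresholds with correlation ``rho_ij = x_i'Sigma x_j / (s_i s_j)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .exceptions import DegenerateCorrelationError, DegenerateVarianceError
from .model import BinaryDataset, LpmFit

_SQRT_2PI = np.sqrt(2.0 * np.pi)

# composite Gauss-Legendre rule: 12 equal segments x 24 nodes covers the
# effective support of the integrand to well below 1e-10 absolute error
_N_SEGMENTS = 12
_GL_X, _GL_W = np.polynomial.legendre.leggauss(24)


def _phi(s):
    return np.exp(-0.5 * s * s) / _SQRT_2PI


@dataclass
class RangeDiagnostic:
    """Observed and predicted out-of-range counts with variance estimates."""

    r_observed: int
    lambda_hat: float
    p_i: np.ndarray
    var_r_independent: float | None = None
    var_r_full: float | None = None
    var_r_poisson_bound: float | None = None
    method_note: str = ""
    out_of_range_rows: np.ndarray = field(default_factory=lambda: np.array([], int))

    @property
    def doubt_cast(self) -> bool | None:
        """True when |R - lambda| exceeds twice the full standard deviation."""
        if self.var_r_full is None:
            return None
        sd = np.sqrt(max(self.var_r_full, 0.0))
        return bool(abs(self.r_observed - self.lambda_hat) > 2.0 * sd)

    def summary_dict(self) -> dict:
        return {
            "r_observed": int(self.r_observed),
            "lambda_hat": float(self.lambda_hat),
            "var_r_independent": None
            if self.var_r_independent is None
            else float(self.var_r_independent),
            "var_r_full": None if self.var_r_full is None else float(self.var_r_full),
            "var_r_poisson_bound": None
            if self.var_r_poisson_bound is None
            else float(self.var_r_poisson_bound),
            "doubt_cast": self.doubt_cast,
            "method_note": self.method_note,
            "out_of_range_rows": [int(i) for i in self.out_of_range_rows],
        }


def out_of_range_probability(delta_i: float, s_i: float) -> float:
    """Probability that an estimated linear predictor falls outside [-1, 1].

    ``s_i`` is the variance ``x_i' Sigma_beta x_i`` of the estimated
    predictor; the result is the two-tailed normal probability and is
    symmetric in the sign of ``delta_i``.
    """
    if s_i <= 0.0:
        raise DegenerateVarianceError("predictor variance s_i must be positive")
    sd = np.sqrt(s_i)
    return float(ndtr((-1.0 + delta_i) / sd) + ndtr((-1.0 - delta_i) / sd))


def _predictor_variances(cov: np.ndarray, X: np.ndarray) -> np.ndarray:
    return np.einsum("ij,jk,ik->i", X, cov, X)


def _p_vector(delta: np.ndarray, s: np.ndarray) -> np.ndarray:
    sd = np.sqrt(s)
    return ndtr((-1.0 + delta) / sd) + ndtr((-1.0 - delta) / sd)


def predicted_out_of_range(fit: LpmFit, data: BinaryDataset) -> RangeDiagnostic:
    """Predicted expected out-of-range count (variances left empty)."""
    if fit.cov_hat is None:
        raise DegenerateVarianceError("fit carries no covariance estimate")
    s = _predictor_variances(fit.cov_hat, data.X)
    bad = np.flatnonzero(s <= 0.0)
    if bad.size:
        raise DegenerateVarianceError(
            f"nonpositive predictor variance at row(s) {bad[:5].tolist()}"
        )
    p = _p_vector(fit.delta_hat, s)
    oor = np.flatnonzero(np.abs(fit.delta_hat) > 1.0)
    return RangeDiagnostic(
        r_observed=int(oor.size),
        lambda_hat=float(p.sum()),
        p_i=p,
        out_of_range_rows=oor,
    )


def _bvn_upper_numeric(z1, z2, rho):
    """P(Z1 > z1, Z2 > z2), standard bivariate normal, vectorised.

    Reduces to the one-dimensional integral
    ``int_{z1}^{inf} Phi((rho s - z2)/sqrt(1-rho^2)) phi(s) ds``
    evaluated by a composite Gauss-Legendre rule on ``[z1, max(z1,0)+9]``;
    the discarded tail is below ``Phi(-9) < 1e-18``.  ``|rho|`` within
    1e-9 of 1 falls back to the comonotone closed forms.
    """
    z1, z2, rho = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (z1, z2, rho))
    )
    out = np.empty(z1.shape, dtype=float)

    hi = rho >= 1.0 - 1e-9
    lo = rho <= -1.0 + 1e-9
    zero = rho == 0.0
    general = ~(hi | lo | zero)

    if hi.any():
        out[hi] = ndtr(-np.maximum(z1[hi], z2[hi]))
    if lo.any():
        out[lo] = np.maximum(0.0, ndtr(-z2[lo]) - ndtr(z1[lo]))
    if zero.any():
        out[zero] = ndtr(-z1[zero]) * ndtr(-z2[zero])
    if general.any():
        a = z1[general]
        b = np.maximum(a, 0.0) + 9.0
        zz = z2[general]
        r = rho[general]
        denom = np.sqrt(1.0 - r * r)
        acc = np.zeros(a.shape)
        seg = (b - a) / _N_SEGMENTS
        for k in range(_N_SEGMENTS):
            left = a + k * seg
            half = 0.5 * seg
            mid = left + half
            s = mid[..., None] + half[..., None] * _GL_X
            f = ndtr((r[..., None] * s - zz[..., None]) / denom[..., None]) * _phi(s)
            acc += half * (f @ _GL_W)
        out[general] = acc
    return np.clip(out, 0.0, 1.0)


def _bvn_upper_approx(z1, z2, rho):
    """Conditional-expectation approximation of P(Z1 > z1, Z2 > z2).

    Replaces ``E[Phi((rho S - z2)/sqrt(1-rho^2)) | S > z1]`` by the same
    function of ``E[S | S > z1] = phi(z1)/Phi(-z1)`` (the truncated-normal
    mean).  The thresholds are interchanged so that the conditioning event
    is always the one with the larger probability ``Phi(-z)``.
    """
    z1, z2, rho = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (z1, z2, rho))
    )
    out = np.empty(z1.shape, dtype=float)

    hi = rho >= 1.0 - 1e-12
    lo = rho <= -1.0 + 1e-12
    general = ~(hi | lo)
    if hi.any():
        out[hi] = ndtr(-np.maximum(z1[hi], z2[hi]))
    if lo.any():
        out[lo] = np.maximum(0.0, ndtr(-z2[lo]) - ndtr(z1[lo]))
    if general.any():
        a = np.where(z1[general] <= z2[general], z1[general], z2[general])
        c = np.where(z1[general] <= z2[general], z2[general], z1[general])
        r = rho[general]
        lead = ndtr(-a)
        with np.errstate(divide="ignore", invalid="ignore"):
            mills = np.where(lead > 0.0, _phi(a) / np.where(lead > 0, lead, 1.0), 0.0)
            val = lead * ndtr((r * mills - c) / np.sqrt(1.0 - r * r))
        out[general] = np.where(lead > 0.0, val, 0.0)
    return np.clip(out, 0.0, 1.0)


def quadrant_probability(
    z_i: float, z_j: float, rho: float, mode: str = "numeric"
) -> float:
    """P(Z_i > z_i, Z_j > z_j) for a standard bivariate normal pair."""
    if not (np.isfinite(z_i) and np.isfinite(z_j)):
        raise ValueError("thresholds must be finite")
    if mode == "numeric":
        if abs(rho) >= 1.0:
            raise DegenerateCorrelationError(
                "numeric mode requires |rho| < 1 (approx mode handles rho = +/-1)"
            )
        return float(_bvn_upper_numeric(z_i, z_j, rho))
    if mode == "approx":
        if abs(rho) > 1.0:
            raise DegenerateCorrelationError("|rho| must be <= 1")
        return float(_bvn_upper_approx(z_i, z_j, rho))
    raise ValueError(f"unknown mode {mode!r}")


def _pair_prob_both(zu_i, zu_j, zd_i, zd_j, rho, fn):
    """P(both predictors out of range) as four quadrant probabilities.

    ``zu`` is the standardised distance to the upper limit +1, ``zd`` to
    the lower limit -1; reflecting a threshold flips the sign of the
    correlation for that member of the pair.
    """
    return (
        fn(zu_i, zu_j, rho)
        + fn(zu_i, zd_j, -rho)
        + fn(zd_i, zu_j, -rho)
        + fn(zd_i, zd_j, rho)
    )


def variance_out_of_range(
    fit: LpmFit,
    data: BinaryDataset,
    pair_mode: str = "numeric",
    max_pairs: int = 1_000_000,
    seed: int = 0,
    p_floor: float = 1e-12,
) -> RangeDiagnostic:
    """Full variance of the out-of-range count R.

        var(R) = sum_i p_i(1 - p_i)
                 + sum_{i != j} { P(both i and j out of range) - p_i p_j }

    Rows with ``p_i <= p_floor`` are excluded from the pairwise sum (each
    excluded term is bounded by ``p_floor``).  When the number of ordered
    pairs among the remaining rows exceeds ``max_pairs`` the pairwise sum
    is estimated from a seeded simple random subsample of unordered pairs
    and scaled up; the note field records what was done.
    """
    if pair_mode not in ("numeric", "approx"):
        raise ValueError(f"unknown pair_mode {pair_mode!r}")
    diag = predicted_out_of_range(fit, data)
    p = diag.p_i
    s = _predictor_variances(fit.cov_hat, data.X)
    sd = np.sqrt(s)
    delta = fit.delta_hat
    z_up = (1.0 - delta) / sd
    z_dn = (1.0 + delta) / sd

    var_indep = float(np.sum(p * (1.0 - p)))

    keep = np.flatnonzero(p > p_floor)
    k = keep.size
    note = f"pair_mode={pair_mode}; {k}/{data.n} rows above p_floor={p_floor:g}"
    pair_sum = 0.0
    if k >= 2:
        cov_rows = data.X[keep] @ fit.cov_hat @ data.X[keep].T
        d = np.sqrt(np.diag(cov_rows))
        rho = cov_rows / np.outer(d, d)
        np.fill_diagonal(rho, 0.0)

        iu, ju = np.triu_indices(k, 1)
        n_unordered = iu.size
        scale = 1.0
        if 2 * n_unordered > max_pairs:
            m = max(1, max_pairs // 2)
            rng = np.random.default_rng(seed)
            sel = rng.choice(n_unordered, size=m, replace=False)
            iu, ju = iu[sel], ju[sel]
            scale = n_unordered / m
            note += f"; subsampled {m}/{n_unordered} unordered pairs (scale {scale:.4g})"
        else:
            note += f"; exact summation over {n_unordered} unordered pairs"

        fn = _bvn_upper_numeric if pair_mode == "numeric" else _bvn_upper_approx
        gi, gj = keep[iu], keep[ju]
        terms = np.zeros(iu.size)
        chunk = 20_000
        for start in range(0, iu.size, chunk):
            sl = slice(start, start + chunk)
            both = _pair_prob_both(
                z_up[gi[sl]],
                z_up[gj[sl]],
                z_dn[gi[sl]],
                z_dn[gj[sl]],
                rho[iu[sl], ju[sl]],
                fn,
            )
            terms[sl] = both - p[gi[sl]] * p[gj[sl]]
        pair_sum = 2.0 * scale * float(terms.sum())

    diag.var_r_independent = var_indep
    diag.var_r_full = var_indep + pair_sum
    diag.var_r_poisson_bound = diag.lambda_hat
    diag.method_note = note
    return diag
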