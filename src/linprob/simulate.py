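"""Synthetic data generation for the linear-in-probability model.

Draws mixed binary (``{-1, +1}``-coded) and bounded continuous covariates,
enforces feasibility of the coefficient vector (``|beta'x| <= 1 - margin``
for every sampled row), generates outcomes from
``pr(Y = +1 | x) = (1 + beta'x) / 2``, and optionally injects MCAR
covariate missingness and a controlled number of out-of-range
"contaminated" rows (covariates outside the stated support, carrying the
outcome whose model probability is negative there) that refute the model
under formal likelihood theory while barely moving least squares.

:func:`nlsy_like_spec` provides an illustrative five-covariate study
emulating the structure of a large longitudinal survey (three ``{-1,+1}``
binaries, two bounded continuous scores, missingness on three covariates).
All of its numbers are package fixtures, not estimates from any real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import FeasibilityError
from .model import BINARY_PM1, CONSTANT, CONTINUOUS, INTERCEPT_NAME, BinaryDataset

DEFAULT_FEASIBILITY_MARGIN = 0.02


@dataclass(frozen=True)
class CovariateSpec:
    """One covariate: ``binary_pm1`` with P(+1) = ``p_success``, or
    ``continuous`` uniform on ``(lower, upper)``."""

    name: str
    kind: str
    p_success: float | None = None
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self):
        if self.kind == BINARY_PM1:
            if self.p_success is None or not 0.0 < self.p_success < 1.0:
                raise ValueError(f"{self.name}: p_success must be in (0, 1)")
        elif self.kind == CONTINUOUS:
            if self.lower is None or self.upper is None or not self.lower < self.upper:
                raise ValueError(f"{self.name}: need lower < upper support bounds")
        else:
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")

    @property
    def support(self):
        if self.kind == BINARY_PM1:
            return (-1.0, 1.0)
        return (self.lower, self.upper)


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of a synthetic study.

    ``beta`` includes the intercept as its first entry.  Under
    ``feasibility_mode='rescale'`` the coefficient vector is shrunk once,
    up front, so the worst corner of the covariate support box satisfies
    ``|beta'x| <= 1 - margin``; under ``'reject'`` offending rows are
    redrawn (with a cap).  ``missing_rates`` maps covariate names to MCAR
    cell-deletion probabilities.  ``contamination`` rows violating
    ``|beta'x| <= 1`` are appended last and flagged in the truth record.
    """

    n: int
    covariate_specs: tuple
    beta: tuple
    feasibility_mode: str = "rescale"
    missing_rates: dict = field(default_factory=dict)
    contamination: int = 0
    seed: int = 0
    margin: float = DEFAULT_FEASIBILITY_MARGIN

    def __post_init__(self):
        object.__setattr__(self, "covariate_specs", tuple(self.covariate_specs))
        object.__setattr__(self, "beta", tuple(float(b) for b in self.beta))
        if len(self.beta) != len(self.covariate_specs) + 1:
            raise ValueError("beta must have one entry per covariate plus intercept")
        if self.feasibility_mode not in ("reject", "rescale"):
            raise ValueError(f"unknown feasibility_mode {self.feasibility_mode!r}")
        names = {c.name for c in self.covariate_specs}
        for name, rate in self.missing_rates.items():
            if name not in names:
                raise ValueError(f"missing rate for unknown covariate {name!r}")
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"missing rate for {name!r} must be in [0, 1)")
        if self.contamination < 0:
            raise ValueError("contamination must be >= 0")
        if not 0.0 < self.margin < 1.0:
            raise ValueError("margin must be in (0, 1)")

    def worst_corner(self, beta=None) -> float:
        """max over the support box of |beta'x| (interval arithmetic)."""
        beta = np.asarray(self.beta if beta is None else beta, dtype=float)
        hi = lo = beta[0]
        for b, c in zip(beta[1:], self.covariate_specs):
            a, d = c.support
            hi += max(b * a, b * d)
            lo += min(b * a, b * d)
        return max(abs(hi), abs(lo), hi, -lo)

    def feasible_beta(self) -> np.ndarray:
        """The coefficient vector actually used under rescale mode."""
        beta = np.asarray(self.beta, dtype=float)
        if self.feasibility_mode != "rescale":
            return beta
        worst = self.worst_corner()
        limit = 1.0 - self.margin
        if worst > limit and worst > 0:
            beta = beta * (limit / worst)
        return beta


def _draw_rows(rng, specs, n):
    cols = []
    for c in specs:
        if c.kind == BINARY_PM1:
            cols.append(np.where(rng.random(n) < c.p_success, 1.0, -1.0))
        else:
            cols.append(rng.uniform(c.lower, c.upper, size=n))
    return np.column_stack([np.ones(n)] + cols)


def simulate(spec: SimulationSpec):
    """Generate a :class:`BinaryDataset` plus a truth record.

    The truth record carries the effective coefficient vector (after any
    rescaling), the per-row linear predictors, contaminated row indices
    and the seed, so downstream tests can condition on the generator.
    """
    rng = np.random.default_rng(spec.seed)
    beta = spec.feasible_beta()
    limit = 1.0 - spec.margin

    X = _draw_rows(rng, spec.covariate_specs, spec.n)
    delta = X @ beta
    if spec.feasibility_mode == "reject":
        cap = 100 * spec.n + 1000
        redraws = 0
        bad = np.flatnonzero(np.abs(delta) > limit)
        while bad.size:
            redraws += bad.size
            if redraws > cap:
                raise FeasibilityError(
                    f"could not draw feasible rows after {redraws} redraws; "
                    "the coefficient vector is too large for the support"
                )
            X[bad] = _draw_rows(rng, spec.covariate_specs, bad.size)
            delta[bad] = X[bad] @ beta
    elif np.any(np.abs(delta) > limit):  # pragma: no cover - rescale guarantees this
        raise AssertionError("rescaled beta produced infeasible rows")

    y = np.where(rng.random(spec.n) < (1.0 + delta) / 2.0, 1.0, -1.0)

    contaminated_idx = np.array([], dtype=int)
    if spec.contamination > 0:
        Xc, deltac = _draw_contaminated(rng, spec, beta)
        # the aberrant outcome: the level whose model probability is
        # negative at beta, so the likelihood at the true parameter is -inf
        yc = -np.sign(deltac)
        contaminated_idx = np.arange(spec.n, spec.n + spec.contamination)
        X = np.vstack([X, Xc])
        y = np.concatenate([y, yc])
        delta = np.concatenate([delta, deltac])

    n_total = X.shape[0]
    mask = np.zeros_like(X, dtype=bool)
    names = [INTERCEPT_NAME] + [c.name for c in spec.covariate_specs]
    for name, rate in spec.missing_rates.items():
        if rate <= 0:
            continue
        j = names.index(name)
        mask[:, j] = rng.random(n_total) < rate

    meta = [CONSTANT] + [c.kind for c in spec.covariate_specs]
    data = BinaryDataset(
        y=y,
        X=np.where(mask, 0.0, X),
        missing_mask=mask,
        column_meta=tuple(meta),
        column_names=tuple(names),
    )
    truth = {
        "beta": beta,
        "beta_requested": np.asarray(spec.beta, dtype=float),
        "delta": delta,
        "contaminated_rows": contaminated_idx,
        "seed": spec.seed,
        "margin": spec.margin,
    }
    return data, truth


def _draw_contaminated(rng, spec: SimulationSpec, beta):
    """Rows outside the support (continuous coordinates stretched by 1.5
    around the support midpoint, escalating if needed) with |beta'x| > 1."""
    rows = np.empty((spec.contamination, len(beta)))
    deltas = np.empty(spec.contamination)
    for r in range(spec.contamination):
        scale = 1.5
        for _ in range(200):
            cols = [1.0]
            for c in spec.covariate_specs:
                if c.kind == BINARY_PM1:
                    cols.append(1.0 if rng.random() < c.p_success else -1.0)
                else:
                    mid = 0.5 * (c.lower + c.upper)
                    half = 0.5 * (c.upper - c.lower) * scale
                    cols.append(rng.uniform(mid - half, mid + half))
            x = np.array(cols)
            d = float(x @ beta)
            if abs(d) > 1.0:
                rows[r] = x
                deltas[r] = d
                break
            scale *= 1.5
        else:
            raise FeasibilityError(
                "could not construct a contaminated row with |beta'x| > 1; "
                "beta may be identically zero on the continuous covariates"
            )
    return rows, deltas


def nlsy_like_spec(n: int, seed: int) -> SimulationSpec:
    """Illustrative five-covariate study specification.

    Three ``{-1,+1}`` binaries and two bounded continuous covariates, with
    MCAR missingness on the two continuous covariates and one binary.
    Coefficients are fixtures chosen to be of realistic order; the vector
    is rescaled for feasibility at simulation time.
    """
    if n < 100:
        raise ValueError("n must be at least 100")
    covariates = (
        CovariateSpec("gender", BINARY_PM1, p_success=0.5),
        CovariateSpec("test_score", CONTINUOUS, lower=0.0, upper=100.0),
        CovariateSpec("log_income", CONTINUOUS, lower=3.0, upper=11.23),
        CovariateSpec("race", BINARY_PM1, p_success=0.3),
        CovariateSpec("lives_with_parent", BINARY_PM1, p_success=0.9),
    )
    beta = (-1.4, -0.06, 0.02, 0.06, 0.22, -0.03)
    return SimulationSpec(
        n=n,
        covariate_specs=covariates,
        beta=beta,
        feasibility_mode="rescale",
        missing_rates={"test_score": 0.043, "log_income": 0.512, "lives_with_parent": 0.051},
        seed=seed,
    )
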