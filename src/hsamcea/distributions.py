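"""Uncertainty distributions for probabilistic sensitivity analysis.

Every uncertain model input carries a :class:`DistributionSpec`.  Three
parametric families cover the model's inputs:

* **log-normal**, fitted either from a symmetric *scalar* range expressed as
  multipliers of the point estimate (e.g. 0.5-1.5x) or from a 95% CI on the
  natural scale (e.g. a risk ratio of 0.81 with CI 0.68-0.97);
* **beta**, used for the intervention uptake proportion;
* **gamma**, parameterized by its mean and a relative standard deviation
  (used for the per-person program administration cost).

A ``fixed`` kind represents a degenerate (certain) parameter.

The scalar-range fit treats the two printed multipliers as the 2.5th and
97.5th percentiles of the sampled value, so

    sigma = ln(hi/lo) / (2 * 1.96),   mu = ln(point * sqrt(lo * hi)).

For a symmetric multiplicative range such as 0.5-1.5 the fitted median is
sqrt(0.75) times the point estimate; the fit honors both printed bounds
exactly rather than centering on the point estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

_Z975 = 1.959963984540054  # scipy.stats.norm.ppf(0.975)

KINDS = ("lognormal_scalar", "lognormal_ci", "beta", "gamma_relsd", "fixed")


@dataclass(frozen=True)
class DistributionSpec:
    """A fitted sampling distribution for one uncertain parameter."""

    kind: str
    params: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        p = self.params
        if self.kind in ("lognormal_scalar", "lognormal_ci"):
            if p["sigma"] < 0:
                raise ValueError("sigma must be >= 0")
        elif self.kind == "beta":
            if p["alpha"] <= 0 or p["beta"] <= 0:
                raise ValueError("beta requires alpha > 0 and beta > 0")
        elif self.kind == "gamma_relsd":
            if p["mean"] <= 0 or p["rel_sd"] <= 0:
                raise ValueError("gamma requires mean > 0 and rel_sd > 0")
        elif self.kind == "fixed":
            if set(p) != {"value"}:
                raise ValueError("fixed spec takes exactly one parameter: value")

    # -- frozen scipy view -------------------------------------------------
    def _frozen(self):
        p = self.params
        if self.kind in ("lognormal_scalar", "lognormal_ci"):
            if p["sigma"] == 0.0:
                return None
            return stats.lognorm(s=p["sigma"], scale=np.exp(p["mu"]))
        if self.kind == "beta":
            return stats.beta(p["alpha"], p["beta"])
        if self.kind == "gamma_relsd":
            shape = 1.0 / p["rel_sd"] ** 2
            scale = p["mean"] * p["rel_sd"] ** 2
            return stats.gamma(shape, scale=scale)
        return None  # fixed

    def _degenerate_value(self) -> float:
        p = self.params
        if self.kind == "fixed":
            return p["value"]
        return float(np.exp(p["mu"]))  # zero-sigma lognormal

    def mean(self) -> float:
        """Analytic mean of the distribution."""
        frozen = self._frozen()
        if frozen is None:
            return self._degenerate_value()
        return float(frozen.mean())

    def ppf(self, q) -> float | np.ndarray:
        """Quantile function (inverse CDF)."""
        frozen = self._frozen()
        if frozen is None:
            v = self._degenerate_value()
            return v if np.isscalar(q) else np.full(np.shape(q), v)
        return frozen.ppf(q)

    def cdf(self, x) -> float | np.ndarray:
        frozen = self._frozen()
        if frozen is None:
            v = self._degenerate_value()
            return np.asarray(x >= v, dtype=float)
        return frozen.cdf(x)

    def rvs(self, rng: np.random.Generator, size=None):
        """Draw from the distribution using ``rng`` (deterministic per state)."""
        frozen = self._frozen()
        if frozen is None:
            v = self._degenerate_value()
            return v if size is None else np.full(size, v)
        return frozen.rvs(size=size, random_state=rng)

    @property
    def is_fixed(self) -> bool:
        return self.kind == "fixed" or (
            self.kind.startswith("lognormal") and self.params["sigma"] == 0.0
        )


def fixed(value: float) -> DistributionSpec:
    return DistributionSpec("fixed", {"value": float(value)})


def fit_lognormal_scalar(
    point: float, lo_mult: float, hi_mult: float
) -> DistributionSpec:
    """Log-normal whose 95% interval is [lo_mult*point, hi_mult*point]."""
    if point <= 0 or lo_mult <= 0 or hi_mult <= 0:
        raise ValueError("point and multipliers must be positive")
    if not (lo_mult <= 1.0 <= hi_mult):
        raise ValueError("multipliers must bracket 1 (lo_mult <= 1 <= hi_mult)")
    sigma = np.log(hi_mult / lo_mult) / (2.0 * _Z975)
    mu = np.log(point * np.sqrt(lo_mult * hi_mult))
    return DistributionSpec("lognormal_scalar", {"mu": float(mu), "sigma": float(sigma)})


def fit_lognormal_from_ci(lo: float, hi: float) -> DistributionSpec:
    """Log-normal with 95% CI [lo, hi] on the natural scale."""
    if lo <= 0 or hi <= 0:
        raise ValueError("CI bounds must be positive")
    if lo > hi:
        raise ValueError("lower CI bound exceeds upper bound")
    sigma = np.log(hi / lo) / (2.0 * _Z975)
    mu = np.log(np.sqrt(lo * hi))
    return DistributionSpec("lognormal_ci", {"mu": float(mu), "sigma": float(sigma)})


def beta_spec(alpha: float, beta: float) -> DistributionSpec:
    return DistributionSpec("beta", {"alpha": float(alpha), "beta": float(beta)})


def gamma_relsd(mean: float, rel_sd: float) -> DistributionSpec:
    """Gamma with the given mean and SD = rel_sd * mean."""
    return DistributionSpec("gamma_relsd", {"mean": float(mean), "rel_sd": float(rel_sd)})
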