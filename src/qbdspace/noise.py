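"""Measurement-noise models estimated from center-point replicates.

The uncertainty model underlying the Monte-Carlo design space: each CQA's
relative standard deviation (RSD) is estimated once from the replicated
center runs of the design and assumed to hold at every other run, so a run
measured at value ``v`` is regenerated with mean ``v`` and standard
deviation ``rsd * v``.  Replicated center runs are regenerated from the
center distribution itself (mean = replicate mean, SD = replicate SD)
rather than from their individual measurements.

Four distribution families are supported.  In every family the
*distribution's* mean and SD are moment-matched to the target mean/SD:

``normal``
    Draws are N(m, s) directly.
``lognormal``
    ln X is normal; closed-form inversion
    ``sigma^2 = ln(1 + s^2/m^2)``, ``mu = ln m - sigma^2/2``.
``sqrt-normal``
    sqrt(X) is normal, i.e. X = Z^2 with Z ~ N(mu, sigma).  From
    E[X] = mu^2 + sigma^2 and Var X = 4 mu^2 sigma^2 + 2 sigma^4 the
    inversion is also closed form: ``sigma^2 = m - sqrt(m^2 - s^2/2)``.
``reciprocal-normal``
    1/X is normal, X = 1/Z.  The moments of 1/Z exist only conditionally
    (Z restricted away from 0); for the small RSDs this model is used at
    (~6%) the mass near zero is negligible.  The coefficient of variation
    of 1/Z depends only on that of Z, so matching reduces to a 1-D root
    find on cv(Z) with moments evaluated by Gauss-Hermite quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .doe import DesignTable

__all__ = ["FAMILIES", "NoiseModel", "estimate_noise", "draw_responses"]

FAMILIES = ("normal", "lognormal", "sqrt-normal", "reciprocal-normal")

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(201)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()  # probabilist's weights -> E[.]


@dataclass(frozen=True)
class NoiseModel:
    """Per-CQA center statistics plus the draw distribution family."""

    family: str
    cqa_names: tuple[str, ...]
    center_mean: np.ndarray  # (n_cqas,)
    center_sd: np.ndarray
    center_runs: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if np.any(self.center_mean <= 0):
            raise ValueError("center means must be > 0")
        if np.any(self.center_sd < 0):
            raise ValueError("center SDs must be >= 0")

    @property
    def rsd(self) -> np.ndarray:
        return self.center_sd / self.center_mean

    @property
    def degenerate(self) -> np.ndarray:
        """True per CQA when the replicates were identical (zero RSD)."""
        return self.center_sd == 0


def estimate_noise(design: DesignTable, family: str = "normal") -> NoiseModel:
    """Estimate the noise model from the design's largest replicate group.

    The sample mean and sample SD (n-1 denominator) of each CQA over the
    replicate group become the center mean/SD; RSD = SD / mean.
    """
    reps = design.center_replicates()
    vals = design.responses[reps]
    return NoiseModel(
        family=family,
        cqa_names=tuple(design.cqa_names),
        center_mean=vals.mean(axis=0),
        center_sd=vals.std(axis=0, ddof=1),
        center_runs=reps,
    )


def _lognormal_params(m, s):
    sigma2 = np.log1p((s / m) ** 2)
    mu = np.log(m) - sigma2 / 2.0
    return mu, np.sqrt(sigma2)


def _sqrtnormal_params(m, s):
    disc = m**2 - s**2 / 2.0
    if np.any(disc < 0):
        raise ValueError("sqrt-normal family needs RSD <= sqrt(2)")
    sigma2 = m - np.sqrt(disc)
    mu = np.sqrt(np.maximum(m - sigma2, 0.0))
    return mu, np.sqrt(sigma2)


def _recip_moments(cv: float) -> tuple[float, float]:
    """Mean and SD of 1/(1 + cv*U), U standard normal restricted to the
    positive-argument region, via Gauss-Hermite quadrature."""
    z = 1.0 + cv * _GH_NODES
    good = z > 1e-9
    w = _GH_WEIGHTS[good] / _GH_WEIGHTS[good].sum()
    inv = 1.0 / z[good]
    m1 = float(w @ inv)
    m2 = float(w @ inv**2)
    return m1, float(np.sqrt(max(m2 - m1**2, 0.0)))


def _recipnormal_params(m, s):
    """Moment-match 1/Z, Z ~ N(mu, sigma): 1-D solve for cv(Z)."""
    m = np.asarray(m, dtype=float)
    s = np.asarray(s, dtype=float)

    def solve_cv(cv_x: float) -> float:
        if cv_x == 0:
            return 0.0
        f = lambda c: _recip_moments(c)[1] / _recip_moments(c)[0] - cv_x
        return float(optimize.brentq(f, 1e-8, 0.8, xtol=1e-12))

    cv_x = s / m
    cv_z = np.vectorize(solve_cv)(cv_x)
    h1 = np.vectorize(lambda c: _recip_moments(c)[0])(cv_z)
    mu = h1 / m
    return mu, cv_z * mu


def draw_responses(
    design: DesignTable,
    noise: NoiseModel,
    rng: np.random.Generator,
    n_sims: int = 1,
) -> np.ndarray:
    """Regenerate the design's response table under the noise model.

    Returns an ``(n_sims, n_runs, n_cqas)`` array.  Target means are the
    measured values, except that runs in the replicate group share the
    center mean; target SDs are ``rsd * mean``.  CQAs whose replicates were
    identical (zero RSD) are returned unperturbed.
    """
    if tuple(design.cqa_names) != noise.cqa_names:
        raise ValueError("noise model CQAs do not match the design")
    if np.any(design.responses <= 0):
        raise ValueError("all measured responses must be > 0 to regenerate")
    M = design.responses.copy()  # (n, q) target means
    if noise.center_runs.size:
        M[noise.center_runs] = noise.center_mean
    S = noise.rsd[None, :] * M
    shape = (n_sims,) + M.shape
    if noise.family == "normal":
        out = rng.normal(M, np.maximum(S, 0.0), size=shape)
    elif noise.family == "lognormal":
        mu, sigma = _lognormal_params(M, np.maximum(S, 1e-300))
        out = np.exp(rng.normal(mu, sigma, size=shape))
    elif noise.family == "sqrt-normal":
        mu, sigma = _sqrtnormal_params(M, S)
        out = rng.normal(mu, sigma, size=shape) ** 2
    elif noise.family == "reciprocal-normal":
        mu, sigma = _recipnormal_params(M, np.maximum(S, 1e-300))
        out = 1.0 / rng.normal(mu, sigma, size=shape)
    else:  # pragma: no cover - guarded by NoiseModel
        raise ValueError(noise.family)
    zero = noise.rsd == 0
    if zero.any():
        out[:, :, zero] = M[:, zero]
    return out
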