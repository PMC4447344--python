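"""Monte-Carlo probability-based design space.

The calculation regenerates the measured response table many times under
the estimated noise model, stepwise-refits the quadratic model of every
CQA on each regenerated data set, and evaluates the whole model ensemble
over a grid of process settings.  A grid cell's probability is the
fraction of simulated data sets whose six refitted models *jointly*
predict every CQA inside its acceptance limits at that cell.  The design
space is the region where this probability reaches the acceptance
threshold (0.95 by default), with the discrete extraction-number factor
held at one of its levels per slice.

Stability of the whole computation is summarised by repeating it with
independent random streams: ADSS is the mean dimensionless design-space
size (fraction of the coded [-1,1]^2 slice inside the space) and RSDDSS
its relative standard deviation across repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator

from .doe import CQASpec, DesignTable, code_factors, decode_factors
from .noise import NoiseModel, draw_responses, estimate_noise
from .rsm import (
    TERMS,
    DesignCache,
    batch_refit,
    fit_cqa_models,
    mask_to_terms,
    stepwise_batch,
    term_matrix,
)

__all__ = [
    "SimulationConfig",
    "ProbabilityMap",
    "DesignSpaceResult",
    "MonteCarloDesignSpace",
    "probability_map",
    "design_space",
    "design_space_stability",
    "verify_point",
    "compare_distributions",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Settings of one Monte-Carlo design-space computation.

    step_length is in coded units; the grid spans coded [-1, 1] per free
    factor with ``round(2/step_length) + 1`` points per axis (201 at the
    default 0.01).
    """

    n_sims: int = 10000
    step_length: float = 0.01
    alpha: float = 0.35
    threshold: float = 0.95
    family: str = "normal"
    n_repeats: int = 10
    seed: int | None = None

    def __post_init__(self):
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if not 0 < self.step_length <= 2:
            raise ValueError("step_length must be in (0, 2]")
        if not self.threshold > 0:
            raise ValueError("threshold must be > 0")
        # thresholds above 1 are allowed but yield an empty design space

    def grid(self) -> np.ndarray:
        n_points = int(round(2.0 / self.step_length)) + 1
        return np.linspace(-1.0, 1.0, n_points)


@dataclass(frozen=True)
class ProbabilityMap:
    """Joint-acceptance probability over one coded-factor slice.

    ``prob[i, j]`` is the probability at ``x1[i]``, ``x2[j]`` (the two free
    factors in design order) with the sliced factor fixed at
    ``slice_value`` (coded units).
    """

    slice_factor: int
    slice_value: float
    x1: np.ndarray
    x2: np.ndarray
    prob: np.ndarray
    n_sims: int

    def mask(self, threshold: float) -> np.ndarray:
        return self.prob >= threshold

    def dss(self, threshold: float) -> float:
        """Dimensionless design-space size: masked fraction of the slice."""
        return float(self.mask(threshold).mean())


@dataclass(frozen=True)
class DesignSpaceResult:
    """A thresholded probability map plus size/stability metrics."""

    map: ProbabilityMap
    threshold: float
    dss: float
    dss_repeats: tuple[float, ...] = ()
    adss: float = float("nan")
    rsddss: float = float("nan")

    @property
    def mask(self) -> np.ndarray:
        return self.map.mask(self.threshold)


class EnsembleError(RuntimeError):
    """Raised when too many simulated refits fail."""


class MonteCarloDesignSpace(BaseEstimator):
    """Monte-Carlo design-space estimator for a designed experiment.

    Parameters mirror :class:`SimulationConfig`.  ``fit`` consumes a
    :class:`~qbdspace.doe.DesignTable`: it estimates the noise model from
    the center replicates, regenerates the response table ``n_sims`` times,
    and stepwise-refits every CQA on every regenerated data set.  The
    fitted ensemble then serves probability maps, design-space extraction
    and point verification.

    Attributes
    ----------
    noise_ : NoiseModel
    coefs_ : (n_cqas, n_sims, 10) ndarray
        Ensemble coefficients (intercept first, then :data:`qbdspace.rsm.TERMS`).
    masks_ : (n_cqas, n_sims) int ndarray
        Selected term sets per simulation as bitmasks.
    point_models_ : dict
        Stepwise fits of the measured (unperturbed) data, one per CQA.
    n_failed_ : int
        Simulations dropped because stepwise selection did not converge.
    """

    def __init__(
        self,
        n_sims: int = 10000,
        step_length: float = 0.01,
        alpha: float = 0.35,
        threshold: float = 0.95,
        family: str = "normal",
        n_repeats: int = 10,
        random_state: int | np.random.SeedSequence | None = None,
    ):
        self.n_sims = n_sims
        self.step_length = step_length
        self.alpha = alpha
        self.threshold = threshold
        self.family = family
        self.n_repeats = n_repeats
        self.random_state = random_state

    def config(self) -> SimulationConfig:
        seed = self.random_state
        return SimulationConfig(
            n_sims=self.n_sims,
            step_length=self.step_length,
            alpha=self.alpha,
            threshold=self.threshold,
            family=self.family,
            n_repeats=self.n_repeats,
            seed=seed if isinstance(seed, (int, type(None))) else None,
        )

    def fit(self, design: DesignTable, limits: list[CQASpec] | None = None):
        if limits is not None:
            self._check_limits(design, limits)
            self.limits_ = list(limits)
        self.design_ = design
        self.noise_ = estimate_noise(design, self.family)
        rng = np.random.default_rng(self.random_state)
        draws = draw_responses(design, self.noise_, rng, n_sims=self.n_sims)
        cache = DesignCache(design.coded_settings())
        self.cache_ = cache
        q = len(design.cqa_names)
        coefs = np.zeros((q, self.n_sims, 1 + len(TERMS)))
        masks = np.zeros((q, self.n_sims), dtype=np.int64)
        failed = np.zeros(self.n_sims, dtype=bool)
        for qi in range(q):
            Y = np.ascontiguousarray(draws[:, :, qi].T)
            try:
                masks[qi] = stepwise_batch(cache, Y, self.alpha, self.alpha)
            except Exception:
                # isolate failing columns: rerun one by one
                for s in range(self.n_sims):
                    try:
                        masks[qi, s] = stepwise_batch(
                            cache, Y[:, s], self.alpha, self.alpha
                        )[0]
                    except Exception:
                        failed[s] = True
            good = ~failed
            coefs[qi][good], _ = batch_refit(cache, masks[qi][good], Y[:, good])
        self.n_failed_ = int(failed.sum())
        if self.n_failed_ > 0.01 * self.n_sims:
            raise EnsembleError(
                f"{self.n_failed_}/{self.n_sims} simulated refits failed"
            )
        keep = ~failed
        self.keep_idx_ = np.flatnonzero(keep)
        self.coefs_ = coefs[:, keep, :]
        self.masks_ = masks[:, keep]
        self.point_models_ = fit_cqa_models(design, alpha=self.alpha)
        return self

    @staticmethod
    def _check_limits(design: DesignTable, limits) -> None:
        names = [l.name for l in limits]
        if names != list(design.cqa_names):
            raise ValueError(
                f"limit names {names} do not match design CQAs {design.cqa_names}"
            )

    # -- ensemble evaluation -------------------------------------------

    def ensemble_predictions(self, coded_points: np.ndarray) -> np.ndarray:
        """Predictions of every ensemble member, (n_cqas, n_kept, n_points)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "coefs_")
        pts = np.atleast_2d(np.asarray(coded_points, dtype=float))
        basis = np.column_stack([np.ones(len(pts)), term_matrix(pts)])  # (p, 10)
        return self.coefs_ @ basis.T

    def joint_probability(
        self, coded_points: np.ndarray, limits: list[CQASpec], chunk: int = 4096
    ) -> np.ndarray:
        """Probability that all CQAs meet their limits, per coded point.

        Evaluated in point chunks with preallocated work buffers so large
        grids stay within memory; each probability is the exact empirical
        fraction of ensemble members whose predictions all lie inside the
        limits.
        """
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "coefs_")
        self._check_limits(self.design_, limits)
        pts = np.atleast_2d(np.asarray(coded_points, dtype=float))
        lower = np.array([l.lower for l in limits])
        upper = np.array([l.upper for l in limits])
        n_pts = len(pts)
        n_kept = self.coefs_.shape[1]
        chunk = min(chunk, n_pts)
        # (points x sims) orientation keeps the skinny matmul BLAS-friendly
        preds = np.empty((chunk, n_kept))
        ok = np.empty((chunk, n_kept), dtype=bool)
        tmp = np.empty((chunk, n_kept), dtype=bool)
        out = np.empty(n_pts)
        coefs_t = [np.ascontiguousarray(self.coefs_[qi].T) for qi in range(len(limits))]
        for start in range(0, n_pts, chunk):
            block = pts[start : start + chunk]
            b = len(block)
            basis = np.column_stack([np.ones(b), term_matrix(block)])  # (b, 10)
            pv, okv, tv = preds[:b], ok[:b], tmp[:b]
            okv.fill(True)
            for qi in range(len(limits)):
                np.matmul(basis, coefs_t[qi], out=pv)
                np.greater_equal(pv, lower[qi], out=tv)
                okv &= tv
                np.less_equal(pv, upper[qi], out=tv)
                okv &= tv
            out[start : start + b] = np.count_nonzero(okv, axis=1) / n_kept
        return out

    def probability_map(
        self,
        limits: list[CQASpec],
        slice_value: float = 0.0,
        slice_factor: int | None = None,
    ) -> ProbabilityMap:
        """Joint-acceptance probability over the coded grid of one slice.

        ``slice_factor`` defaults to the design's discrete factor (or the
        last factor if none is flagged discrete); ``slice_value`` is in
        coded units.
        """
        if slice_factor is None:
            slice_factor = self._default_slice_factor()
        grid = self.config().grid()
        free = [i for i in range(len(self.design_.factors)) if i != slice_factor]
        A, B = np.meshgrid(grid, grid, indexing="ij")
        pts = np.empty((A.size, len(self.design_.factors)))
        pts[:, free[0]] = A.ravel()
        pts[:, free[1]] = B.ravel()
        pts[:, slice_factor] = slice_value
        prob = self.joint_probability(pts, limits).reshape(A.shape)
        return ProbabilityMap(
            slice_factor=slice_factor,
            slice_value=float(slice_value),
            x1=grid.copy(),
            x2=grid.copy(),
            prob=prob,
            n_sims=self.coefs_.shape[1],
        )

    def _default_slice_factor(self) -> int:
        for i, f in enumerate(self.design_.factors):
            if f.discrete:
                return i
        return len(self.design_.factors) - 1


# ---------------------------------------------------------------------------
# Functional layer


def probability_map(
    design: DesignTable,
    limits: list[CQASpec],
    cfg: SimulationConfig,
    slice_value: float = 0.0,
    slice_factor: int | None = None,
) -> ProbabilityMap:
    """One-shot probability map: fit the ensemble and grid it."""
    est = _estimator(cfg).fit(design, limits)
    return est.probability_map(limits, slice_value=slice_value, slice_factor=slice_factor)


def design_space(pmap: ProbabilityMap, cfg: SimulationConfig) -> DesignSpaceResult:
    """Threshold a probability map into a design space with its size."""
    dss = pmap.dss(cfg.threshold)
    return DesignSpaceResult(map=pmap, threshold=cfg.threshold, dss=dss)


def design_space_stability(
    design: DesignTable,
    limits: list[CQASpec],
    cfg: SimulationConfig,
    slice_value: float = 0.0,
    slice_factor: int | None = None,
) -> DesignSpaceResult:
    """Repeat the full computation ``cfg.n_repeats`` times for ADSS/RSDDSS.

    Each repeat draws fresh data, refits the whole ensemble and recomputes
    the map from an independent substream of the master seed.  The returned
    result carries the last repeat's map, the per-repeat sizes, their mean
    (ADSS) and relative standard deviation in percent (RSDDSS).
    """
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_repeats)
    sizes = []
    pmap = None
    for ss in seeds:
        est = _estimator(cfg, random_state=ss).fit(design, limits)
        pmap = est.probability_map(limits, slice_value=slice_value, slice_factor=slice_factor)
        sizes.append(pmap.dss(cfg.threshold))
    sizes_arr = np.asarray(sizes)
    adss = float(sizes_arr.mean())
    if adss == 0:
        raise ZeroDivisionError("mean design-space size is 0; RSDDSS undefined")
    rsddss = float(100.0 * sizes_arr.std(ddof=1) / adss)
    return DesignSpaceResult(
        map=pmap,
        threshold=cfg.threshold,
        dss=sizes[-1],
        dss_repeats=tuple(sizes),
        adss=adss,
        rsddss=rsddss,
    )


def verify_point(
    design: DesignTable,
    limits: list[CQASpec],
    cfg: SimulationConfig,
    point_uncoded,
    estimator: MonteCarloDesignSpace | None = None,
) -> dict:
    """Predictions and joint probability at one uncoded operating point.

    Returns per-CQA point-estimate predictions (from the stepwise fits of
    the measured data), ensemble-mean predictions, within-limits flags and
    the joint acceptance probability.  Points outside the coded [-1, 1]
    cube are evaluated with a warning flag set.
    """
    est = estimator if estimator is not None else _estimator(cfg).fit(design, limits)
    coded = code_factors(np.asarray(point_uncoded, dtype=float), design.factors)
    extrapolated = bool(np.any(np.abs(coded) > 1 + 1e-12))
    preds_point = {
        name: float(est.point_models_[name].predict(coded[None])[0])
        for name in design.cqa_names
    }
    ens = est.ensemble_predictions(coded[None])[:, :, 0]  # (q, m)
    preds_ens = {
        name: float(ens[qi].mean()) for qi, name in enumerate(design.cqa_names)
    }
    prob = float(est.joint_probability(coded[None], limits)[0])
    within = {
        l.name: bool(l.lower <= preds_point[l.name] <= l.upper) for l in limits
    }
    return {
        "point_uncoded": [float(v) for v in np.asarray(point_uncoded, dtype=float)],
        "point_coded": [float(v) for v in coded],
        "extrapolated": extrapolated,
        "point_estimate": preds_point,
        "ensemble_mean": preds_ens,
        "within_limits": within,
        "joint_probability": prob,
    }


def compare_distributions(
    design: DesignTable,
    limits: list[CQASpec],
    cfg: SimulationConfig,
    families=("normal", "lognormal", "sqrt-normal", "reciprocal-normal"),
    slice_value: float = 0.0,
) -> dict:
    """Design space and mean model criteria per distribution family.

    Every family reuses the same master seed so the comparison is paired;
    reported per family: mean R2 / adjusted / predicted R2, AIC, BIC over
    the ensemble, and the design-space result at the given slice.
    """
    out = {}
    for fam in families:
        fam_cfg = replace(cfg, family=fam)
        est = _estimator(fam_cfg).fit(design, limits)
        crit_means = _ensemble_criteria(est)
        pmap = est.probability_map(limits, slice_value=slice_value)
        out[fam] = {
            "criteria": crit_means,
            "result": design_space(pmap, fam_cfg),
        }
    return out


def _ensemble_criteria(est: MonteCarloDesignSpace) -> dict:
    """Mean model criteria over the fitted ensemble, per CQA."""
    rng = np.random.default_rng(est.random_state)
    draws = draw_responses(est.design_, est.noise_, rng, n_sims=est.n_sims)
    means: dict[str, dict[str, float]] = {}
    for qi, name in enumerate(est.design_.cqa_names):
        Y = np.ascontiguousarray(draws[:, :, qi].T)
        _, crit = batch_refit(est.cache_, est.masks_[qi], Y[:, est.keep_idx_])
        means[name] = {
            k: float(np.mean(crit[k])) for k in ("r2", "r2_adj", "r2_pred", "aic", "bic")
        }
    return means


def _estimator(cfg: SimulationConfig, random_state=None) -> MonteCarloDesignSpace:
    return MonteCarloDesignSpace(
        n_sims=cfg.n_sims,
        step_length=cfg.step_length,
        alpha=cfg.alpha,
        threshold=cfg.threshold,
        family=cfg.family,
        n_repeats=cfg.n_repeats,
        random_state=cfg.seed if random_state is None else random_state,
    )


def map_to_frame(pmap: ProbabilityMap, design: DesignTable, threshold: float):
    """Long-format DataFrame of a probability map with uncoded axes."""
    import pandas as pd

    free = [i for i in range(len(design.factors)) if i != pmap.slice_factor]
    A, B = np.meshgrid(pmap.x1, pmap.x2, indexing="ij")
    coded = np.zeros((A.size, len(design.factors)))
    coded[:, free[0]] = A.ravel()
    coded[:, free[1]] = B.ravel()
    coded[:, pmap.slice_factor] = pmap.slice_value
    uncoded = decode_factors(coded, design.factors)
    f1, f2 = design.factors[free[0]].name, design.factors[free[1]].name
    return pd.DataFrame(
        {
            f"{f1}_coded": A.ravel(),
            f"{f2}_coded": B.ravel(),
            f"{f1}_uncoded": uncoded[:, free[0]],
            f"{f2}_uncoded": uncoded[:, free[1]],
            "probability": pmap.prob.ravel(),
            "in_design_space": pmap.prob.ravel() >= threshold,
        }
    )


def plot_probability_map(pmap: ProbabilityMap, design: DesignTable, threshold: float, path):
    """Minimal filled-contour export with the threshold iso-line (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    free = [i for i in range(len(design.factors)) if i != pmap.slice_factor]
    f1, f2 = design.factors[free[0]], design.factors[free[1]]
    u1 = f1.decode(pmap.x1)
    u2 = f2.decode(pmap.x2)
    fig, ax = plt.subplots(figsize=(5, 4))
    cs = ax.contourf(u2, u1, pmap.prob, levels=np.linspace(0, 1, 21), cmap="viridis")
    ax.contour(u2, u1, pmap.prob, levels=[threshold], colors="white", linewidths=1.5)
    fig.colorbar(cs, ax=ax, label="probability of meeting all CQA limits")
    ax.set_xlabel(f"{f2.name} ({f2.unit})")
    ax.set_ylabel(f"{f1.name} ({f1.unit})")
    sliced = design.factors[pmap.slice_factor]
    ax.set_title(f"{sliced.name} = {sliced.decode(pmap.slice_value):g}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
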