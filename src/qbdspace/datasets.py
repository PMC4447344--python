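"""Packaged study data and synthetic designed experiments.

``load_study`` returns the built-in worked example: the 15-run, 3-factor
Danhong extraction design with six measured CQAs, the factor coding and
the CQA acceptance limits.  ``generate_synthetic`` produces designs with
the same layout but responses computed from known quadratic coefficients
plus multiplicative noise — the ground truth for recovery tests.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .doe import (
    CQASpec,
    DesignTable,
    FactorSpec,
    read_design_csv,
    read_factors_csv,
    read_limits_csv,
)
from .rsm import TERMS, term_matrix

__all__ = ["load_study", "load_paper_fixture", "SyntheticSpec", "generate_synthetic", "STUDY_LAYOUT"]

# sha256 of the packaged CSVs, guarding against silent corruption
_CHECKSUMS = {
    "factors.csv": "a006d3fc8d88bc302aded632cc6ce605960f8f3c18f1e6b7993e65d60882b44e",
    "cqa_limits.csv": "67864a52c77c3a8e482c27e13c33b4a71bd55d0f2cbe186d0961d6ee9718e809",
    "design_table.csv": "aa3ad7ce182fabc5d158e6575c9175a6d8d05f154efc6cbacd98dd5ee19c02e8",
}

#: Coded layout of the built-in 15-run three-level design (one row per run).
STUDY_LAYOUT: tuple[tuple[float, float, float], ...] = (
    (-0.3333333333333333, -1, 1),
    (-1, 1, 0),
    (-1, 0, 1),
    (-0.3333333333333333, 1, 1),
    (-0.3333333333333333, 0, 0),
    (-0.3333333333333333, 1, -1),
    (1, 0, -1),
    (-0.3333333333333333, -1, -1),
    (-1, 0, -1),
    (1, 0, 1),
    (1, 1, 0),
    (-0.3333333333333333, 0, 0),
    (-1, -1, 0),
    (-0.3333333333333333, 0, 0),
    (1, -1, 0),
)


class PackagingError(RuntimeError):
    """Raised when a packaged fixture file fails its checksum."""


def _data_path(name: str):
    ref = resources.files("qbdspace.data").joinpath(name)
    content = ref.read_bytes()
    expected = _CHECKSUMS.get(name)
    if expected:
        digest = hashlib.sha256(content).hexdigest()
        if digest != expected:
            raise PackagingError(
                f"packaged fixture {name} is corrupted (sha256 {digest})"
            )
    return ref


def load_study() -> tuple[DesignTable, list[CQASpec], list[FactorSpec]]:
    """The built-in worked example: design table, CQA limits, factors."""
    with resources.as_file(_data_path("factors.csv")) as p:
        factors = read_factors_csv(p)
    with resources.as_file(_data_path("cqa_limits.csv")) as p:
        limits = read_limits_csv(p)
    with resources.as_file(_data_path("design_table.csv")) as p:
        design = read_design_csv(p, factors)
    return design, limits, factors


#: Alias kept for symmetry with the synthetic generator.
load_paper_fixture = load_study


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground truth for a synthetic designed experiment.

    ``true_coefficients`` maps response name -> length-10 sequence
    (intercept first, then :data:`qbdspace.rsm.TERMS`).  Noise is
    multiplicative normal: ``response = surface * (1 + eps)`` with
    ``eps ~ N(0, noise_rsd)``, mirroring RSD-proportional measurement
    error.  Draws that land non-positive are redrawn (count reported via
    the returned table's metadata is unnecessary: see ``generate_synthetic``).
    """

    factors: tuple[FactorSpec, ...]
    true_coefficients: dict[str, tuple[float, ...]]
    noise_rsd: float = 0.05
    layout: tuple[tuple[float, ...], ...] = STUDY_LAYOUT
    seed: int | None = None

    def __post_init__(self):
        if self.noise_rsd < 0:
            raise ValueError("noise_rsd must be >= 0")
        for name, c in self.true_coefficients.items():
            if len(c) != 1 + len(TERMS):
                raise ValueError(
                    f"{name!r}: expected {1 + len(TERMS)} coefficients "
                    "(intercept + 9 terms)"
                )
        lay = np.asarray(self.layout, dtype=float)
        if lay.ndim != 2 or lay.shape[1] != len(self.factors):
            raise ValueError("layout must be (n_runs, n_factors)")
        span = (lay.min(axis=0) <= -1 + 1e-9) & (lay.max(axis=0) >= 1 - 1e-9)
        if not span.all():
            raise ValueError("layout must span coded [-1, 1] for every factor")


def default_synthetic_spec(seed: int | None = None, noise_rsd: float = 0.05) -> SyntheticSpec:
    """A convenient ground truth with effects of mixed size on the study layout."""
    _, _, factors = load_study()
    coeffs = {
        "resp_a": (2.2, 1.0, 0.15, 0.8, 0.0, 0.37, -0.07, 0.0, 0.0, -0.27),
        "resp_b": (470.0, 27.0, 33.0, 110.0, -13.0, 17.0, -19.0, 0.0, -22.0, -40.0),
    }
    return SyntheticSpec(
        factors=tuple(factors),
        true_coefficients=coeffs,
        noise_rsd=noise_rsd,
        seed=seed,
    )


def generate_synthetic(spec: SyntheticSpec, max_redraws: int = 100) -> DesignTable:
    """Generate a design table from known coefficients plus noise.

    Reproducible given ``spec.seed``; non-positive draws are redrawn (up to
    ``max_redraws`` rounds) so the resulting table satisfies the positive-
    response invariant of :class:`~qbdspace.doe.DesignTable`.
    """
    rng = np.random.default_rng(spec.seed)
    coded = np.asarray(spec.layout, dtype=float)
    n = coded.shape[0]
    from .doe import decode_factors

    settings = decode_factors(coded, list(spec.factors))
    basis = np.column_stack([np.ones(n), term_matrix(coded)])
    names = list(spec.true_coefficients)
    surface = np.column_stack(
        [basis @ np.asarray(spec.true_coefficients[k], dtype=float) for k in names]
    )
    if np.any(surface <= 0):
        raise ValueError("true surface must be positive at every design point")
    responses = surface * (1.0 + rng.normal(0.0, spec.noise_rsd, size=surface.shape))
    for _ in range(max_redraws):
        bad = responses <= 0
        if not bad.any():
            break
        responses[bad] = surface[bad] * (
            1.0 + rng.normal(0.0, spec.noise_rsd, size=int(bad.sum()))
        )
    else:
        raise RuntimeError("could not generate positive responses; lower noise_rsd")
    return DesignTable(
        factors=list(spec.factors),
        cqa_names=names,
        run_order=np.arange(1, n + 1),
        settings=settings,
        responses=responses,
    )
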