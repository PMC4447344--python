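"""Designed-experiment geometry: factors, coded/uncoded transforms, design tables.

Factors are coded affinely so that the extreme levels of the design map to
-1 and +1: ``coded = (uncoded - center) / half_range``.  The center is the
midpoint of the extreme levels, which makes intermediate levels land at
fractional coded values (an extraction time of 1 h on a 0.5-2 h range codes
to -1/3).  All modelling downstream happens in coded units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "CQASpec",
    "DesignTable",
    "code_factors",
    "decode_factors",
    "read_factors_csv",
    "read_limits_csv",
    "read_design_csv",
]


class SpecificationError(ValueError):
    """Raised when a factor/CQA specification is inconsistent with the data."""


@dataclass(frozen=True)
class FactorSpec:
    """One critical process parameter and its coding.

    Parameters
    ----------
    name : str
        Factor name as it appears in the design table header.
    unit : str
        Uncoded unit (e.g. ``h`` or ``g/g``).
    center : float
        Uncoded value that codes to 0 (midpoint of the extreme levels).
    half_range : float
        Uncoded distance from the center to either extreme level; must be
        positive.
    discrete : bool
        True for factors that only take integer settings in practice
        (extraction number).  The factor is still carried as a real in the
        models; the flag controls which slices a design space is computed at.
    """

    name: str
    unit: str
    center: float
    half_range: float
    discrete: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.center):
            raise SpecificationError(f"factor {self.name!r}: center must be finite")
        if not (self.half_range > 0) or not np.isfinite(self.half_range):
            raise SpecificationError(f"factor {self.name!r}: half_range must be > 0")

    def code(self, uncoded):
        return (np.asarray(uncoded, dtype=float) - self.center) / self.half_range

    def decode(self, coded):
        return np.asarray(coded, dtype=float) * self.half_range + self.center


@dataclass(frozen=True)
class CQASpec:
    """Acceptance limits for one critical quality attribute.

    ``basis`` names the mass basis the yield is reported against (e.g.
    ``Danshen``, ``Honghua`` or ``Material``); it is metadata used when
    computing yields from raw measurements and does not affect the limits.
    """

    name: str
    unit: str
    lower: float
    upper: float
    basis: str = ""

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise SpecificationError(
                f"CQA {self.name!r}: lower limit {self.lower} must be < upper {self.upper}"
            )

    def contains(self, value) -> np.ndarray:
        v = np.asarray(value, dtype=float)
        return (v >= self.lower) & (v <= self.upper)


def code_factors(uncoded, factors: Sequence[FactorSpec]) -> np.ndarray:
    """Map uncoded factor settings to coded units, one column per factor.

    Accepts a 1-D point or a 2-D (n_points, n_factors) array.
    """
    u = np.atleast_2d(np.asarray(uncoded, dtype=float))
    if u.shape[-1] != len(factors):
        raise SpecificationError(
            f"expected {len(factors)} factor values, got {u.shape[-1]}"
        )
    if not np.all(np.isfinite(u)):
        raise SpecificationError("uncoded factor values must be finite")
    centers = np.array([f.center for f in factors])
    halves = np.array([f.half_range for f in factors])
    coded = (u - centers) / halves
    return coded[0] if np.ndim(uncoded) == 1 else coded


def decode_factors(coded, factors: Sequence[FactorSpec]) -> np.ndarray:
    """Exact inverse of :func:`code_factors`."""
    c = np.atleast_2d(np.asarray(coded, dtype=float))
    if c.shape[-1] != len(factors):
        raise SpecificationError(
            f"expected {len(factors)} factor values, got {c.shape[-1]}"
        )
    centers = np.array([f.center for f in factors])
    halves = np.array([f.half_range for f in factors])
    un = c * halves + centers
    return un[0] if np.ndim(coded) == 1 else un


@dataclass
class DesignTable:
    """A designed experiment: factor settings and measured responses per run.

    Attributes
    ----------
    factors : list of FactorSpec
        Ordered factor definitions; column order of ``settings``.
    cqa_names : list of str
        Ordered response names; column order of ``responses``.
    run_order : (n_runs,) int array
    settings : (n_runs, n_factors) float array, uncoded units
    responses : (n_runs, n_cqas) float array
    """

    factors: list[FactorSpec]
    cqa_names: list[str]
    run_order: np.ndarray
    settings: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        self.run_order = np.asarray(self.run_order, dtype=int)
        self.settings = np.asarray(self.settings, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        n = len(self.run_order)
        if self.settings.shape != (n, len(self.factors)):
            raise SpecificationError("settings shape does not match runs x factors")
        if self.responses.shape != (n, len(self.cqa_names)):
            raise SpecificationError("responses shape does not match runs x CQAs")
        if not np.all(np.isfinite(self.settings)):
            raise SpecificationError("factor settings must be finite")
        if not np.all(np.isfinite(self.responses) & (self.responses > 0)):
            raise SpecificationError("responses must be finite and > 0")

    @property
    def n_runs(self) -> int:
        return len(self.run_order)

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    def coded_settings(self) -> np.ndarray:
        return code_factors(self.settings, self.factors)

    def response(self, cqa: str) -> np.ndarray:
        try:
            j = self.cqa_names.index(cqa)
        except ValueError:
            raise SpecificationError(f"unknown CQA {cqa!r}") from None
        return self.responses[:, j]

    def replicate_groups(self) -> list[np.ndarray]:
        """Indices of runs sharing identical uncoded settings, largest first.

        Only groups with at least two runs are returned.  Equality is exact
        (settings come from a parsed design table, not measurements).
        """
        groups: dict[tuple, list[int]] = {}
        for i, row in enumerate(self.settings):
            groups.setdefault(tuple(row), []).append(i)
        reps = [np.array(ix) for ix in groups.values() if len(ix) >= 2]
        return sorted(reps, key=len, reverse=True)

    def center_replicates(self) -> np.ndarray:
        """The largest replicate group; raises if the design has none."""
        reps = self.replicate_groups()
        if not reps:
            raise SpecificationError(
                "design has no replicate group; cannot estimate measurement noise"
            )
        return reps[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"run": self.run_order})
        for j, f in enumerate(self.factors):
            df[f.name] = self.settings[:, j]
        for j, name in enumerate(self.cqa_names):
            df[name] = self.responses[:, j]
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_factors_csv(path) -> list[FactorSpec]:
    """Read a factor specification CSV: ``name,unit,center,half_range,discrete``."""
    df = pd.read_csv(path)
    required = {"name", "unit", "center", "half_range", "discrete"}
    missing = required - set(df.columns)
    if missing:
        raise SpecificationError(f"factor CSV {path}: missing columns {sorted(missing)}")
    return [
        FactorSpec(
            name=str(r["name"]),
            unit=str(r["unit"]),
            center=float(r["center"]),
            half_range=float(r["half_range"]),
            discrete=bool(r["discrete"]),
        )
        for _, r in df.iterrows()
    ]


def read_limits_csv(path) -> list[CQASpec]:
    """Read a CQA limits CSV: ``name,unit,lower,upper[,basis]``."""
    df = pd.read_csv(path)
    required = {"name", "unit", "lower", "upper"}
    missing = required - set(df.columns)
    if missing:
        raise SpecificationError(f"limits CSV {path}: missing columns {sorted(missing)}")
    has_basis = "basis" in df.columns
    return [
        CQASpec(
            name=str(r["name"]),
            unit=str(r["unit"]),
            lower=float(r["lower"]),
            upper=float(r["upper"]),
            basis=str(r["basis"]) if has_basis else "",
        )
        for _, r in df.iterrows()
    ]


def read_design_csv(path, factors: Sequence[FactorSpec]) -> DesignTable:
    """Read a design-table CSV: ``run,<factor names...>,<cqa names...>``.

    Factor columns are matched by name against ``factors``; every remaining
    column is treated as a CQA response.
    """
    df = pd.read_csv(path)
    if "run" not in df.columns:
        raise SpecificationError(f"design CSV {path}: missing 'run' column")
    fnames = [f.name for f in factors]
    missing = [n for n in fnames if n not in df.columns]
    if missing:
        raise SpecificationError(f"design CSV {path}: missing factor columns {missing}")
    cqa_names = [c for c in df.columns if c != "run" and c not in fnames]
    if not cqa_names:
        raise SpecificationError(f"design CSV {path}: no response columns found")
    for col in fnames + cqa_names:
        bad = df[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
            raise SpecificationError(
                f"design CSV {path}: empty or non-numeric value in column "
                f"{col!r} at line {row}"
            )
    return DesignTable(
        factors=list(factors),
        cqa_names=cqa_names,
        run_order=df["run"].to_numpy(),
        settings=df[fnames].to_numpy(dtype=float),
        responses=df[cqa_names].to_numpy(dtype=float),
    )
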