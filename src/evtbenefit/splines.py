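"""Spline bases for nonlinear continuous predictors.

Two parameterizations of a nonlinear glucose effect are supported:

* a piecewise-linear ("hinge") form with a single knot, giving separate
  slopes below and above the knot, and
* Harrell's restricted cubic spline, linear in the tails, with ``k - 2``
  truncated-power basis terms for ``k`` knots.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["GlucoseTerm", "hinge_basis", "restricted_cubic_basis", "spline_basis"]


@dataclass(frozen=True)
class GlucoseTerm:
    """Configuration of the glucose transform.

    Parameters
    ----------
    form
        ``"piecewise_linear"`` (default) or ``"restricted_cubic"``.
    knot
        Knot of the piecewise-linear form, in mg/dL. The default of
        120 mg/dL separates the normo- and hyperglycemic slopes.
    rcs_knots
        Strictly increasing knots of the restricted cubic form, mg/dL.
    """

    form: str = "piecewise_linear"
    knot: float = 120.0
    rcs_knots: tuple[float, ...] = (90.0, 120.0, 180.0)

    def __post_init__(self) -> None:
        if self.form not in ("piecewise_linear", "restricted_cubic"):
            raise ValueError(f"unknown glucose form {self.form!r}")
        knots = np.asarray(self.rcs_knots, dtype=float)
        if self.form == "restricted_cubic":
            if knots.size < 3:
                raise ValueError("restricted cubic spline needs >= 3 knots")
            if not np.all(np.diff(knots) > 0):
                raise ValueError("spline knots must be strictly increasing")

    @property
    def n_columns(self) -> int:
        if self.form == "piecewise_linear":
            return 2
        return len(self.rcs_knots) - 1

    @property
    def column_names(self) -> list[str]:
        if self.form == "piecewise_linear":
            return ["glucose", "glucose_hinge"]
        return ["glucose"] + [f"glucose_rcs{j + 1}" for j in range(len(self.rcs_knots) - 2)]


def _check_finite(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("spline input contains non-finite values")
    return np.atleast_1d(x)


def hinge_basis(x, knot: float) -> np.ndarray:
    """Piecewise-linear basis ``(x, max(0, x - knot))``, shape (n, 2)."""
    x = _check_finite(x)
    return np.column_stack([x, np.maximum(0.0, x - knot)])


def restricted_cubic_basis(x, knots: Sequence[float]) -> np.ndarray:
    """Restricted cubic spline basis (Harrell's parameterization).

    Returns the linear term plus ``k - 2`` truncated-cubic terms that are
    identically zero for ``x <= knots[0]`` and linear beyond ``knots[-1]``.
    Nonlinear terms are normalized by ``(knots[-1] - knots[0])**2`` so they
    stay on the scale of ``x``.
    """
    x = _check_finite(x)
    t = np.asarray(knots, dtype=float)
    if t.size < 3 or not np.all(np.diff(t) > 0):
        raise ValueError("knots must be >= 3 and strictly increasing")
    k = t.size
    norm = (t[-1] - t[0]) ** 2

    def cube(knot: float) -> np.ndarray:
        return np.maximum(0.0, x - knot) ** 3

    cols = [x]
    last = cube(t[-1])
    second_last = cube(t[-2])
    span = t[-1] - t[-2]
    for j in range(k - 2):
        b = (
            cube(t[j])
            - second_last * (t[-1] - t[j]) / span
            + last * (t[-2] - t[j]) / span
        )
        cols.append(b / norm)
    return np.column_stack(cols)


def spline_basis(x, term: GlucoseTerm) -> np.ndarray:
    """Evaluate the glucose basis configured by ``term`` at ``x``."""
    if term.form == "piecewise_linear":
        return hinge_basis(x, term.knot)
    return restricted_cubic_basis(x, term.rcs_knots)
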