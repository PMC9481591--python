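"""Restricted cubic spline basis (Harrell parameterization).

For knots t_1 < ... < t_k the basis has k-1 columns: a linear term centred
at a reference age, and k-2 truncated-cubic terms constrained so the fitted
function is linear beyond the boundary knots, each normalized by
(t_k - t_1)^2 so coefficients share the scale of the linear term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_KNOTS = (2.0, 12.0, 22.0, 32.0, 42.0, 52.0, 67.0, 82.0)
DEFAULT_CENTER_AGE = 60.0


@dataclass(frozen=True)
class SplineSpec:
    """Knot locations (years) and centring age for the age smooth."""
    knots: tuple[float, ...] = DEFAULT_KNOTS
    center_age: float = DEFAULT_CENTER_AGE

    def __post_init__(self):
        knots = tuple(float(t) for t in self.knots)
        object.__setattr__(self, "knots", knots)
        if len(knots) < 3:
            raise ValueError("need at least 3 knots")
        if any(b <= a for a, b in zip(knots, knots[1:])):
            raise ValueError("knots must be strictly increasing")

    @property
    def basis_dimension(self) -> int:
        """Number of basis columns (linear term included)."""
        return len(self.knots) - 1

    def column_names(self) -> list[str]:
        return [f"rcs{j + 1}" for j in range(self.basis_dimension)]


def rcs_basis(ages, spec: SplineSpec) -> np.ndarray:
    """Evaluate the restricted cubic spline basis at ``ages``.

    Returns an array of shape (len(ages), k-1).  Column 1 is
    ``age - center_age``; column j+1 (j = 1..k-2) is

        [(x-t_j)+^3 - (x-t_{k-1})+^3 (t_k-t_j)/(t_k-t_{k-1})
                    + (x-t_k)+^3 (t_{k-1}-t_j)/(t_k-t_{k-1})] / (t_k-t_1)^2,

    which is linear in x below t_1 and above t_k.
    """
    x = np.atleast_1d(np.asarray(ages, dtype=float))
    if x.size == 0:
        raise ValueError("age vector is empty")
    t = np.asarray(spec.knots)
    k = len(t)
    norm = (t[-1] - t[0]) ** 2

    def tp3(v):  # truncated cube
        return np.maximum(v, 0.0) ** 3

    cols = [x - spec.center_age]
    for j in range(k - 2):
        term = (tp3(x - t[j])
                - tp3(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
                + tp3(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2]))
        cols.append(term / norm)
    return np.column_stack(cols)
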