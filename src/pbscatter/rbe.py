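"""Linear-quadratic variable RBE model with LET_d-dependent RBE_max/RBE_min.

The phenomenological LQ-based model (McNamara-type) expresses the proton
RBE at physical dose D (Gy), photon alpha/beta ratio (Gy) and dose-averaged
LET (keV/um) as

    RBE = (1 / 2D) * ( sqrt( (a/b)^2 + 4 D (a/b) RBE_max
                             + 4 RBE_min^2 D^2 ) - a/b )

with
    RBE_max = 0.99064 + 0.35605 * LET_d / (a/b)
    RBE_min = 1.1012  - 0.0038703 * sqrt(a/b) * LET_d

RBE_max and RBE_min are the asymptotes at D -> 0 and D -> infinity.  The
model interface is pluggable so alternative dose/LET-response models can be
swapped in for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RBEParams", "rbe", "rbe_max", "rbe_min", "ConstantRBE"]


@dataclass(frozen=True)
class RBEParams:
    """Model coefficients; defaults are the published fit values."""

    c0: float = 0.99064  # RBE_max intercept
    c1: float = 0.35605  # Gy/(keV/um), RBE_max LET slope over alpha/beta
    c2: float = 1.1012  # RBE_min intercept
    c3: float = 0.0038703  # Gy^(-1/2)/(keV/um), RBE_min slope with sqrt(a/b)
    alpha_beta_surface: float = 3.0  # Gy, normal tissue at the surface point
    alpha_beta_target: float = 10.0  # Gy, at the target centre

    def __post_init__(self) -> None:
        if self.alpha_beta_surface <= 0 or self.alpha_beta_target <= 0:
            raise ValueError("alpha/beta must be positive")


DEFAULT_PARAMS = RBEParams()


def rbe_max(letd, alpha_beta: float, params: RBEParams = DEFAULT_PARAMS):
    """Low-dose RBE asymptote."""
    return params.c0 + params.c1 * np.asarray(letd) / alpha_beta


def rbe_min(letd, alpha_beta: float, params: RBEParams = DEFAULT_PARAMS):
    """High-dose RBE asymptote."""
    return params.c2 - params.c3 * np.sqrt(alpha_beta) * np.asarray(letd)


def rbe(dose, alpha_beta: float, letd, params: RBEParams = DEFAULT_PARAMS):
    """Variable RBE at physical dose `dose` (Gy) and LET_d (keV/um).

    Raises for non-positive dose; the D -> 0 limit is available directly
    as :func:`rbe_max`.
    """
    d = np.asarray(dose, dtype=float)
    if np.any(d <= 0):
        raise ValueError("dose must be positive; use rbe_max for the D->0 limit")
    lmax = rbe_max(letd, alpha_beta, params)
    lmin = rbe_min(letd, alpha_beta, params)
    ab = alpha_beta
    root = np.sqrt(ab * ab + 4.0 * d * ab * lmax + 4.0 * (lmin * d) ** 2)
    out = (root - ab) / (2.0 * d)
    return float(out) if np.isscalar(dose) else out


class ConstantRBE:
    """Constant-RBE stub (clinical RBE = 1.1 by default); same call
    signature as :func:`rbe`, for model-swap regression tests."""

    def __init__(self, value: float = 1.1):
        self.value = value

    def __call__(self, dose, alpha_beta, letd, params=None):
        d = np.asarray(dose, dtype=float)
        if np.any(d <= 0):
            raise ValueError("dose must be positive")
        return self.value if np.isscalar(dose) else np.full_like(d, self.value)
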