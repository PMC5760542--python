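"""Elementary rate laws shared by both models.

All fluxes are in units of 1/min; concentrations are dimensionless
activities, as throughout the package.
"""

from __future__ import annotations

import numpy as np

__all__ = ["hill_activation", "mm_flux", "goldbeter_koshland"]


def hill_activation(x, k, h):
    """Hill activation function ``x^h / (k^h + x^h)``.

    Parameters
    ----------
    x : float or ndarray
        Activator level, >= 0.
    k : float
        Half-saturation constant, > 0.  At ``x == k`` the function
        returns exactly 0.5 for any Hill coefficient.
    h : float
        Hill coefficient, >= 1.

    Returns
    -------
    float or ndarray in [0, 1], strictly increasing in ``x``.
    """
    if k <= 0:
        raise ValueError(f"half-saturation constant must be > 0, got {k}")
    if h < 1:
        raise ValueError(f"Hill coefficient must be >= 1, got {h}")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("activator level must be >= 0")
    xh = (x / k) ** h
    out = xh / (1.0 + xh)
    return float(out) if out.ndim == 0 else out


def mm_flux(substrate, enzyme_activity, kcat, Km):
    """Michaelis-Menten flux ``kcat * E * S / (Km + S)``.

    Saturates at ``kcat * enzyme_activity`` for ``substrate >> Km``.
    """
    if Km <= 0:
        raise ValueError(f"Michaelis constant must be > 0, got {Km}")
    s = np.asarray(substrate, dtype=float)
    if np.any(s < 0) or enzyme_activity < 0 or kcat < 0:
        raise ValueError("mm_flux arguments must be >= 0")
    out = kcat * enzyme_activity * s / (Km + s)
    return float(out) if out.ndim == 0 else out


def goldbeter_koshland(va, vi, Ja, Ji):
    """Steady-state active fraction of a covalent modification cycle.

    Standard zero-order-ultrasensitivity solution used for the
    Wee1/Cdc25/TF switches of the cell-cycle submodel.
    """
    b = vi - va + Ja * vi + Ji * va
    disc = b * b - 4.0 * (vi - va) * va * Ji
    return 2.0 * va * Ji / (b + np.sqrt(np.maximum(disc, 0.0)))
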