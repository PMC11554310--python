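"""Two-state protein melting curves and thermal-window integration.

A protein's soluble fraction after a brief heat challenge is modelled as a
descending two-state logistic in temperature with an optional non-denaturing
plateau: a fraction of the pool that never aggregates within the assay.  A
PISA measurement pools equal volumes of samples heated at several
temperatures across a window, so the quantity a TMT reporter represents is
the *mean* soluble fraction over that temperature grid (an integrated
melting curve).  A ligand-induced shift in melting temperature (dTm)
therefore shows up as a log2 fold change of the pooled soluble abundance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MeltingCurveParams",
    "soluble_fraction",
    "integrate_window",
    "expected_log2fc",
    "window_grid",
]


@dataclass(frozen=True)
class MeltingCurveParams:
    """Two-state denaturation parameters for one protein.

    Parameters
    ----------
    tm : float
        Melting temperature in deg C: the midpoint of the denaturing
        transition, where half of the non-plateau pool remains soluble.
    slope : float
        Temperature scale of the transition in deg C (> 0).  Smaller values
        give sharper melting.
    plateau : float
        Non-denaturing soluble fraction in [0, 0.3]: the asymptote the curve
        approaches at high temperature.
    """

    tm: float
    slope: float
    plateau: float = 0.0

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError(f"slope must be positive, got {self.slope}")
        if not 0.0 <= self.plateau <= 0.3:
            raise ValueError(f"plateau must lie in [0, 0.3], got {self.plateau}")


def soluble_fraction(params: MeltingCurveParams, temperature):
    """Soluble fraction f(T) = plateau + (1 - plateau) / (1 + exp((T - tm)/slope)).

    Strictly decreasing and continuous in ``temperature``;
    f(tm) = plateau + (1 - plateau)/2 exactly.  Accepts scalar or array
    temperatures.
    """
    t = np.asarray(temperature, dtype=float)
    f = params.plateau + (1.0 - params.plateau) / (1.0 + np.exp((t - params.tm) / params.slope))
    if np.isscalar(temperature) or t.ndim == 0:
        return float(f)
    return f


def window_grid(window_low: float, window_high: float, n_temperatures: int) -> np.ndarray:
    """Equally spaced temperature grid, inclusive of both window endpoints."""
    if not window_low < window_high:
        raise ValueError(
            f"window_low must be below window_high, got [{window_low}, {window_high}]"
        )
    if n_temperatures < 2:
        raise ValueError(f"n_temperatures must be >= 2, got {n_temperatures}")
    return np.linspace(window_low, window_high, n_temperatures)


def integrate_window(
    params: MeltingCurveParams,
    window_low: float,
    window_high: float,
    n_temperatures: int = 10,
) -> float:
    """Pooled (mean) soluble fraction S_M over the thermal window.

    Equal-volume pooling of ``n_temperatures`` samples heated at equally
    spaced temperatures (endpoints included) makes the pooled abundance the
    arithmetic mean of the per-temperature soluble fractions.
    """
    temps = window_grid(window_low, window_high, n_temperatures)
    return float(np.mean(soluble_fraction(params, temps)))


def expected_log2fc(
    params: MeltingCurveParams,
    delta_tm: float,
    window_low: float = 48.0,
    window_high: float = 58.0,
    n_temperatures: int = 10,
) -> float:
    """Noise-free log2 fold change in pooled solubility for a Tm shift.

    Shifting the melting temperature by ``delta_tm`` while keeping the
    window fixed changes S_M; the expected screen readout is
    log2(S_M(tm + delta_tm) / S_M(tm)).  The sign matches the sign of
    ``delta_tm`` whenever the transition overlaps the window.
    """
    shifted = MeltingCurveParams(params.tm + delta_tm, params.slope, params.plateau)
    s0 = integrate_window(params, window_low, window_high, n_temperatures)
    s1 = integrate_window(shifted, window_low, window_high, n_temperatures)
    return float(np.log2(s1 / s0))


def _soluble_fraction_matrix(
    tm: np.ndarray, slope: np.ndarray, plateau: np.ndarray, temps: np.ndarray
) -> np.ndarray:
    """Vectorised pooled soluble fraction for many proteins at once.

    Returns the mean over ``temps`` for each protein (1-D array).
    """
    z = (temps[None, :] - tm[:, None]) / slope[:, None]
    f = plateau[:, None] + (1.0 - plateau[:, None]) / (1.0 + np.exp(z))
    return f.mean(axis=1)
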