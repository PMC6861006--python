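"""Two-component FRAP recovery kinetics.

The fluorescence recovery of a bleached bouton exchanging synaptic vesicles
with the axonal super-pool is modelled as a sum of two saturating
exponentials parameterized by half-lives:

    R(t) = P * [ f * (1 - 2**(-t / h_f)) + (1 - f) * (1 - 2**(-t / h_s)) ]

where ``P`` is the plateau (mobile fraction: the asymptotic fraction of
pre-bleach fluorescence that is replenished), ``f`` the share of the plateau
carried by the fast component, and ``h_f < h_s`` the component half-lives in
seconds.  Half-lives relate to exponential time constants as ``h = tau *
ln 2``.

The same functional form is the solution of a linear two-compartment
exchange between the bouton vesicle cluster and an effectively infinite,
unbleached axonal super-pool when the cluster itself holds two kinetically
distinct sub-pools; the biexponential is therefore used directly as the
generative model rather than integrating the ODE system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError

LN2 = float(np.log(2.0))

__all__ = ["RecoveryModel", "recovery_curve", "half_life_to_tau", "tau_to_half_life"]


def half_life_to_tau(h: float) -> float:
    """Convert a half-life (s) to an exponential time constant tau (s)."""
    return h / LN2


def tau_to_half_life(tau: float) -> float:
    """Convert an exponential time constant tau (s) to a half-life (s)."""
    return tau * LN2


@dataclass(frozen=True)
class RecoveryModel:
    """Ground-truth / fitted parameters of a biexponential FRAP recovery.

    Parameters
    ----------
    plateau:
        Mobile fraction P, the fraction of pre-bleach signal recovered as
        t -> infinity.  Must lie in [0, 1.05] (small overshoot tolerated).
    fast_fraction:
        Share f of the plateau recovered by the fast component, in [0, 1].
    half_fast, half_slow:
        Component half-lives in seconds, 0 < half_fast < half_slow.
    """

    plateau: float
    fast_fraction: float
    half_fast: float
    half_slow: float

    def __post_init__(self):
        if not 0.0 <= self.plateau <= 1.05:
            raise InvalidParameterError(
                f"plateau must be in [0, 1.05], got {self.plateau}"
            )
        if not 0.0 <= self.fast_fraction <= 1.0:
            raise InvalidParameterError(
                f"fast_fraction must be in [0, 1], got {self.fast_fraction}"
            )
        if not 0.0 < self.half_fast < self.half_slow:
            raise InvalidParameterError(
                "half-lives must satisfy 0 < half_fast < half_slow, got "
                f"half_fast={self.half_fast}, half_slow={self.half_slow}"
            )


def recovery_curve(model: RecoveryModel, t) -> np.ndarray:
    """Evaluate the recovery fraction R(t) at times ``t`` (seconds, >= 0).

    R(0) = 0, R is nondecreasing and saturates at ``model.plateau``.
    Returns an array matching the shape of ``t`` (scalar in, 0-d array out).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidParameterError("recovery_curve requires t >= 0 elementwise")
    P, f = model.plateau, model.fast_fraction
    fast = 1.0 - np.exp2(-t / model.half_fast)
    slow = 1.0 - np.exp2(-t / model.half_slow)
    return P * (f * fast + (1.0 - f) * slow)
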