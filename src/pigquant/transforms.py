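"""Observed-scale <-> liability-scale heritability transformation.

For a binary trait with incidence ``p`` (proportion of the "1" category),
the Dempster-Lerner relation converts an observed-scale heritability to the
underlying continuous liability scale:

    h2_liability = h2_observed * p (1 - p) / z**2

where ``z`` is the standard normal density at the threshold
``t = Phi^{-1}(1 - p)``.  The transformation is defined on a *normal*
liability; applying it to heritabilities from a logistic-link model (as is
common practice for comparing scales) is an approximation, documented in the
methods note.  The pair of functions here is exactly inverse.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

__all__ = ["observed_to_liability", "liability_to_observed", "dempster_lerner_multiplier"]


def _check_p(p: float) -> None:
    if not 0.0 < p < 1.0:
        raise ValueError(f"incidence p must lie strictly inside (0, 1); got {p}")


def dempster_lerner_multiplier(p: float) -> float:
    """The factor p(1-p)/z² mapping observed- to liability-scale h².

    Symmetric in ``p <-> 1 - p`` and minimal (pi/2) at p = 0.5.
    """
    _check_p(p)
    t = stats.norm.ppf(1.0 - p)
    z = stats.norm.pdf(t)
    return p * (1.0 - p) / z**2


def observed_to_liability(h2_obs: float, p: float) -> float:
    """Observed-scale h² of a binary trait -> liability-scale h²."""
    _check_p(p)
    if h2_obs < 0:
        raise ValueError("heritability must be non-negative")
    h2_liab = h2_obs * dempster_lerner_multiplier(p)
    if h2_liab > 1.0:
        warnings.warn(
            f"transformed liability h² = {h2_liab:.3f} exceeds 1; the observed-scale "
            "input is inconsistent with a threshold model at this incidence"
        )
    return h2_liab


def liability_to_observed(h2_liab: float, p: float) -> float:
    """Liability-scale h² -> observed (0/1) scale; exact inverse of
    :func:`observed_to_liability`."""
    _check_p(p)
    if h2_liab < 0:
        raise ValueError("heritability must be non-negative")
    return h2_liab / dempster_lerner_multiplier(p)
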