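"""Model specification and design-matrix assembly for the animal models.

Every trait is analysed with the same random structure — a common-litter
(permanent environmental) effect and an additive animal effect with
covariance proportional to the numerator relationship matrix — while the
fixed factors vary with the production stage at which the trait is recorded:

* preweaning (backtests, injection, piglet scale, preweaning gain):
  sex + breed
* rearing (load/scale scores, first lesion score, rearing gain):
  sex + breed + rearing housing
* post-mixing lesions: sex + breed + rearing housing + unfamiliar-pig class
* finishing (load/scale scores, finishing gain): sex + breed + finishing
  housing
* lifetime gain: sex + breed + rearing housing + finishing housing

The first observed level of every factor is constrained to zero (any
full-rank constraint yields the same REML variance components).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .pedigree import Pedigree

__all__ = ["ModelSpec", "DesignError", "Design", "build_design", "preset_model", "STUDY_MODEL_FACTORS"]

KNOWN_FACTORS = ("sex", "breed", "rearing", "finishing", "familiar")

#: per-stage fixed-factor sets of the study's five univariate models
STUDY_MODEL_FACTORS = {
    "bt1": ("sex", "breed"),
    "bt2": ("sex", "breed"),
    "inj": ("sex", "breed"),
    "pss": ("sex", "breed"),
    "pdg": ("sex", "breed"),
    "rls": ("sex", "breed", "rearing"),
    "rss": ("sex", "breed", "rearing"),
    "ls1": ("sex", "breed", "rearing"),
    "rdg": ("sex", "breed", "rearing"),
    "ls2": ("sex", "breed", "rearing", "familiar"),
    "lsd": ("sex", "breed", "rearing", "familiar"),
    "fls": ("sex", "breed", "finishing"),
    "fss": ("sex", "breed", "finishing"),
    "fdg": ("sex", "breed", "finishing"),
    "adg": ("sex", "breed", "rearing", "finishing"),
}


class DesignError(ValueError):
    """Invalid or rank-deficient model design."""


@dataclass(frozen=True)
class ModelSpec:
    """A univariate animal-model specification.

    ``fixed_factors`` are column names of the phenotype table; an intercept
    is always included.  Random terms (litter, animal, residual) are implied.
    """

    trait: str
    fixed_factors: tuple = field(default_factory=tuple)

    def __post_init__(self):
        for f in self.fixed_factors:
            if f not in KNOWN_FACTORS:
                raise DesignError(f"unknown fixed factor {f!r}; expected one of {KNOWN_FACTORS}")


def preset_model(trait: str) -> ModelSpec:
    """The study's per-stage model for a named trait."""
    key = trait.lower()
    if key not in STUDY_MODEL_FACTORS:
        raise DesignError(
            f"no preset model for trait {trait!r}; known: {sorted(STUDY_MODEL_FACTORS)}"
        )
    return ModelSpec(trait=trait, fixed_factors=STUDY_MODEL_FACTORS[key])


class Design(NamedTuple):
    """Assembled matrices for one trait's records."""

    y: np.ndarray            # (n,) responses, missing rows dropped
    X: np.ndarray            # (n, p) fixed-effect design, full column rank
    P: np.ndarray            # (n, q) litter incidence
    animal_pos: np.ndarray   # (n,) pedigree position of each record's animal
    animals: np.ndarray      # (n,) animal ids
    litters: np.ndarray      # (q,) litter labels in column order of P
    x_names: tuple           # column labels of X


def build_design(data: pd.DataFrame, ped: Pedigree, spec: ModelSpec) -> Design:
    """Build y, X, P and the animal map for a trait.

    Rows with a missing phenotype are dropped from the record set (the
    animals stay in the pedigree).  Raises :class:`DesignError` when the
    fixed-effect block is rank deficient after the zero-first-level
    constraints, naming the confounded columns.
    """
    if spec.trait not in data.columns:
        raise DesignError(f"trait column {spec.trait!r} not in phenotype table")
    for col in ("animal", "litter", *spec.fixed_factors):
        if col not in data.columns:
            raise DesignError(f"required column {col!r} not in phenotype table")

    rows = data.loc[data[spec.trait].notna()].reset_index(drop=True)
    if len(rows) < 2:
        raise DesignError(f"trait {spec.trait!r} has fewer than 2 records")
    y = rows[spec.trait].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise DesignError(f"trait {spec.trait!r} is constant")

    cols = [np.ones(len(rows))]
    names = ["intercept"]
    for f in spec.fixed_factors:
        levels = np.unique(rows[f].to_numpy())
        for lev in levels[1:]:  # first level constrained to zero
            cols.append((rows[f].to_numpy() == lev).astype(float))
            names.append(f"{f}={lev}")
    X = np.column_stack(cols)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(X, pivoting=True, mode="economic")
        bad = sorted(names[j] for j in piv[rank:])
        raise DesignError(f"confounded fixed-effect columns: {', '.join(bad)}")

    litters, inv = np.unique(rows["litter"].to_numpy(), return_inverse=True)
    P = np.zeros((len(rows), len(litters)))
    P[np.arange(len(rows)), inv] = 1.0

    animal_pos = ped.positions(rows["animal"])
    return Design(y, X, P, animal_pos, rows["animal"].to_numpy(), litters, tuple(names))
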