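"""Functional estimation interface.

Thin wrappers over :class:`~famcr.model.FamilyUnitModel` for callers who
prefer ``fit_mle(data, constraints)`` to building the model object, plus
re-exports of the parameter transform. ``FitResult`` is an alias of
:class:`~famcr.model.FamilyUnitResults`.
"""

from __future__ import annotations

from .data import Dataset
from .model import FamilyUnitModel, FamilyUnitResults
from .params import (ConstraintMap, ParameterSet, inverse_transform,
                     transform_parameters)

FitResult = FamilyUnitResults


def fit_mle(data: Dataset, constraints: ConstraintMap | None = None,
            template: ParameterSet | None = None, starts: int = 5,
            seed: int = 0, **options) -> FitResult:
    """Maximum-likelihood fit; see :meth:`FamilyUnitModel.fit`."""
    model = FamilyUnitModel(data, constraints=constraints, template=template)
    return model.fit(starts=starts, seed=seed, **options)


def fit_mcmc(data: Dataset, constraints: ConstraintMap | None = None,
             template: ParameterSet | None = None, seed: int = 0,
             **options) -> FitResult:
    """Bayesian fit under uniform priors; see :meth:`FamilyUnitModel.fit_mcmc`."""
    model = FamilyUnitModel(data, constraints=constraints, template=template)
    return model.fit_mcmc(seed=seed, **options)
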