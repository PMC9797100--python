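"""Model adapters: uniform fit/predict wrappers around the two competitors.

An adapter's ``fit(train)`` returns a predictor callable ``(X, times) ->
CifCurve`` for the cause-1 cumulative incidence, which is all the 5x2-cv
machinery needs to know about a model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import finegray, forest
from .metrics import CifCurve
from .simulate import CompetingRisksSample

__all__ = ["FineGrayAdapter", "ForestAdapter", "ConstantCifAdapter"]


@dataclass(frozen=True)
class FineGrayAdapter:
    name: str = "fine-gray"
    cause: int = 1
    tol: float = 1e-8
    max_iter: int = 50

    def fit(self, train: CompetingRisksSample):
        fg = finegray.fit_finegray(train, cause=self.cause, tol=self.tol,
                                   max_iter=self.max_iter)
        return lambda X, times: finegray.predict_cif(fg, X, times)


@dataclass(frozen=True)
class ForestAdapter:
    config: forest.ForestConfig = forest.ForestConfig()
    name: str = "rsf-cr"
    cause: int = 1

    def fit(self, train: CompetingRisksSample):
        trees = forest.grow_forest(train, self.config)
        return lambda X, times: forest.predict_cif_forest(trees, X, times,
                                                          cause=self.cause)

    def reseeded(self, seed: int) -> "ForestAdapter":
        return replace(self, config=replace(self.config, seed=seed))


@dataclass(frozen=True)
class ConstantCifAdapter:
    """Uninformative predictor: constant CIF at every time (0.5 by default,
    the 0.25-Brier null benchmark)."""

    level: float = 0.5
    name: str = "constant"

    def fit(self, train: CompetingRisksSample):
        def predict(X, times):
            X = np.atleast_2d(X)
            return CifCurve(times, np.full((X.shape[0], len(times)), self.level))

        return predict
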