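"""Competitive comparison of the six 10-parameter model types.

Every model starts from 10 independent parameters:

* ``shape_only``   — the 10 torso shape parameters PC1..PC10;
* ``anthro_sa``    — 5 size measures + 5 surface areas;
* ``anthro_vol``   — 5 size measures + 5 volumes;
* ``anthro_shape`` — 5 size measures + best 5 shape parameters;
* ``shape_sa``     — 5 surface areas + best 5 shape parameters;
* ``shape_vol``    — 5 volumes + best 5 shape parameters;

for each of the two dependents (body-fat %, trunk:peripheral fat ratio).
"Best 5" is the exhaustive 252-subset search minimizing training MSE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .regression import (RelativeWeightTable, StepwiseOLS, StepwiseResults,
                         best_shape_subset)

__all__ = ["ModelComparison", "ModelRow", "MODEL_TYPES", "GROUPS",
           "SHAPE_COLS", "SIZE_COLS", "VOLUME_COLS", "SA_COLS"]

SHAPE_COLS = [f"PC{i}" for i in range(1, 11)]
SIZE_COLS = ["hip_girth", "torso_length", "wht5r", "avg_thigh_girth",
             "avg_bicep_girth"]
VOLUME_COLS = ["torso_volume", "avg_leg_volume", "avg_arm_volume",
               "torso_limbs_volume_ratio", "legs_arms_volume_ratio"]
SA_COLS = ["torso_sa", "avg_leg_sa", "avg_arm_sa", "torso_limbs_sa_ratio",
           "legs_arms_sa_ratio"]

MODEL_TYPES = ("shape_only", "anthro_sa", "anthro_vol", "anthro_shape",
               "shape_sa", "shape_vol")

# group definitions used for report aggregates
GROUPS = {
    "shape_containing": ("anthro_shape", "shape_sa", "shape_vol"),
    "size_only": ("anthro_sa", "anthro_vol"),
    "shape_only": ("shape_only",),
}


@dataclass
class ModelRow:
    """One fitted model's report row."""

    model_type: str
    dependent: str
    n_terms: int
    adj_r2: float
    rmse: float
    cv_rmse: float
    shape_subset: tuple[str, ...] | None
    weights: RelativeWeightTable = field(repr=False, default=None)
    results: StepwiseResults = field(repr=False, default=None)


class ModelComparison:
    """Fit the six model types for one dependent and collect report rows.

    ``data`` must hold PC1..PC10, the three 5-parameter size subsets and
    the dependent column(s).  ``fit`` is deterministic given (data, seed).
    """

    def __init__(self, data: pd.DataFrame, cv_folds: int = 10,
                 drop_tol: float = 0.01, hierarchy: bool = False):
        missing = [c for c in SHAPE_COLS + SIZE_COLS + VOLUME_COLS + SA_COLS
                   if c not in data.columns]
        if missing:
            raise ValueError(f"data is missing parameter columns: {missing}")
        self.data = data.reset_index(drop=True)
        self.cv_folds = cv_folds
        self.drop_tol = drop_tol
        self.hierarchy = hierarchy

    def _base_terms(self, model_type: str, dependent: str,
                    seed: int) -> tuple[pd.DataFrame, tuple[str, ...] | None]:
        d = self.data
        y = d[dependent]
        if model_type == "shape_only":
            return d[SHAPE_COLS], None
        if model_type == "anthro_sa":
            return d[SIZE_COLS + SA_COLS], None
        if model_type == "anthro_vol":
            return d[SIZE_COLS + VOLUME_COLS], None
        size_map = {"anthro_shape": SIZE_COLS, "shape_sa": SA_COLS,
                    "shape_vol": VOLUME_COLS}
        if model_type not in size_map:
            raise ValueError(f"unknown model type {model_type!r}")
        search = best_shape_subset(y, d[SHAPE_COLS], d[size_map[model_type]],
                                   drop_tol=self.drop_tol,
                                   hierarchy=self.hierarchy)
        subset = search.subset
        return d[list(subset) + size_map[model_type]], subset

    def fit_one(self, model_type: str, dependent: str, seed: int = 0) -> ModelRow:
        exog, subset = self._base_terms(model_type, dependent, seed)
        res = StepwiseOLS(self.data[dependent], exog, drop_tol=self.drop_tol,
                          hierarchy=self.hierarchy).fit()
        cv = res.cross_validate(k=self.cv_folds, seed=seed)
        return ModelRow(model_type=model_type, dependent=dependent,
                        n_terms=res.n_terms, adj_r2=res.rsquared_adj,
                        rmse=res.rmse, cv_rmse=cv, shape_subset=subset,
                        weights=res.relative_weights(), results=res)

    def fit(self, dependent: str, seed: int = 0,
            model_types: tuple[str, ...] = MODEL_TYPES) -> list[ModelRow]:
        return [self.fit_one(mt, dependent, seed) for mt in model_types]
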