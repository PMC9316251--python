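"""Result surfaces: per-model tables, group aggregates and top-weight tables.

Every aggregate printed by a report is recomputed from the report's own rows
at render time; rounding (adjusted R^2 to 4 dp, RMSE to 2-3 dp, inflation to
1 dp) happens only at presentation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

from .comparison import GROUPS, ModelRow
from .regression import RelativeWeightTable

__all__ = ["ComparisonReport", "aggregate_group_r2", "cv_inflation",
           "top_weights_table"]


def aggregate_group_r2(adj_r2_values) -> float:
    """Arithmetic mean adjusted R^2 over a group of models."""
    vals = list(adj_r2_values)
    if not vals:
        raise ValueError("empty model group")
    return float(sum(vals) / len(vals))


def cv_inflation(trained_rmse: float, cv_rmse: float) -> float:
    """Percent increase of cross-validated over trained RMSE."""
    if trained_rmse <= 0:
        raise ValueError("trained RMSE must be positive")
    return 100.0 * (cv_rmse / trained_rmse - 1.0)


def top_weights_table(weights: RelativeWeightTable, k: int = 3,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Top-k significant terms by relative weight (p < alpha)."""
    return weights.top_significant(k=k, alpha=alpha)


@dataclass
class ComparisonReport:
    """Per-dependent model-comparison report with recomputable aggregates."""

    rows: list[ModelRow]
    dependent: str
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "model_type": r.model_type,
            "n_terms": r.n_terms,
            "adj_r2": r.adj_r2,
            "rmse": r.rmse,
            "cv_rmse": r.cv_rmse,
            "cv_inflation_pct": cv_inflation(r.rmse, r.cv_rmse),
            "shape_subset": " ".join(s.removeprefix("PC") for s in r.shape_subset)
                            if r.shape_subset else "",
        } for r in self.rows])

    def group_mean_r2(self, group: str) -> float:
        members = GROUPS[group]
        vals = [r.adj_r2 for r in self.rows if r.model_type in members]
        return aggregate_group_r2(vals)

    def group_mean_inflation(self, group: str) -> float:
        members = GROUPS[group]
        vals = [cv_inflation(r.rmse, r.cv_rmse) for r in self.rows
                if r.model_type in members]
        if not vals:
            raise ValueError("empty model group")
        return float(sum(vals) / len(vals))

    def top_weights(self, k: int = 3, alpha: float = 0.05) -> dict[str, pd.DataFrame]:
        return {r.model_type: top_weights_table(r.weights, k, alpha)
                for r in self.rows if r.weights is not None}

    # -- rendering ---------------------------------------------------------

    def to_markdown(self) -> str:
        f = self.frame()
        lines = [f"# Model comparison — dependent: {self.dependent}", ""]
        lines.append("| model | terms | adj. R² | RMSE | CV RMSE | CV inflation % | shape subset |")
        lines.append("|---|---|---|---|---|---|---|")
        for _, r in f.iterrows():
            lines.append(
                f"| {r.model_type} | {r.n_terms} | {r.adj_r2:.4f} | {r.rmse:.3f} "
                f"| {r.cv_rmse:.3f} | {r.cv_inflation_pct:.1f} | {r.shape_subset} |")
        lines.append("")
        for group in GROUPS:
            try:
                lines.append(f"- mean adj. R² ({group}): "
                             f"{self.group_mean_r2(group):.4f}; "
                             f"mean CV inflation: "
                             f"{self.group_mean_inflation(group):.1f}%")
            except (ValueError, KeyError):
                continue
        lines.append("")
        for model_type, tbl in self.top_weights().items():
            lines.append(f"## Top relative weights — {model_type}")
            lines.append("")
            lines.append("| term | % of R² | p |")
            lines.append("|---|---|---|")
            for _, w in tbl.iterrows():
                lines.append(f"| {w.term} | {w.pct_of_r2:.1f} | {w.p_value:.3g} |")
            lines.append("")
        return "\n".join(lines)

    def to_json(self) -> str:
        payload = {
            "dependent": self.dependent,
            "seed": self.seed,
            "meta": self.meta,
            "rows": json.loads(self.frame().to_json(orient="records")),
            "group_mean_adj_r2": {g: self.group_mean_r2(g) for g in GROUPS},
            "group_mean_cv_inflation_pct": {g: self.group_mean_inflation(g)
                                            for g in GROUPS},
        }
        return json.dumps(payload, indent=2)

    def to_csv(self, path) -> None:
        self.frame().to_csv(path, index=False)
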