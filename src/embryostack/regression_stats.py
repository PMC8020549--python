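"""Multivariable logistic-regression companion analysis.

Fits maximum-likelihood logistic regressions of the selected features on the
three outcomes (SET pregnancy, DET pregnancy, DET twin) and pairs the Wald
p-values with the tree model's split-count importance, to expose the cases
where statistical significance and predictive importance diverge: a feature
can be non-significant in the regression yet heavily used by the trees (and
vice versa), for instance when its effect is nonlinear or interactive.

Feature sets follow the hierarchy: embryo morphology enters only the SET
(per-embryo) regression; the engineered scores P1 + P2 and P1 × P2 enter only
the DET regressions.  Rows with any missing used feature are dropped
(complete-case analysis) and the dropped count is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .cohort_io import DEFAULT_SCHEMA, FeatureSchema, TransferRecord, encode_features
from .errors import EstimationError
from .hierarchical_model import (
    HierarchicalModel,
    LEVEL2_ENGINEERED,
    build_first_level_training,
    build_second_level_features,
)

__all__ = [
    "RegressionResult",
    "fit_multivariable_logistic",
    "regress_outcome",
    "significance_vs_importance",
]

OUTCOMES = ("set_pregnancy", "det_pregnancy", "det_twin")


@dataclass
class RegressionResult:
    """Coefficients, standard errors and Wald p-values for one outcome."""

    outcome: str
    table: pd.DataFrame  # index = term (incl. intercept); columns coef, se, p
    n_used: int
    n_dropped: int  # incomplete rows removed

    def pvalue(self, term: str) -> float:
        return float(self.table.loc[term, "p"])

    @property
    def feature_terms(self) -> list[str]:
        return [t for t in self.table.index if t != "intercept"]


def fit_multivariable_logistic(
    design: pd.DataFrame, outcome, outcome_name: str = "outcome"
) -> RegressionResult:
    """Maximum-likelihood logistic fit (IRLS) with Wald z p-values.

    Complete cases only: rows with a missing value in any design column are
    dropped and counted.  Separation or non-convergence raises — no silent
    coefficients.
    """
    y = pd.Series(np.asarray(outcome, dtype=float), index=design.index, name="y")
    complete = ~(design.isna().any(axis=1) | y.isna())
    n_dropped = int((~complete).sum())
    X = design.loc[complete].astype(float)
    y = y.loc[complete]
    if len(X) == 0:
        raise EstimationError("no complete cases to fit on")
    if y.nunique() < 2:
        raise EstimationError("degenerate training labels: need both classes present")
    X_const = sm.add_constant(X, has_constant="add")
    model = sm.GLM(y, X_const, family=sm.families.Binomial())
    try:
        with warnings.catch_warnings():
            # the transient mid-IRLS warning is not diagnostic; separation is
            # detected from the fitted parameters below
            warnings.simplefilter("ignore", PerfectSeparationWarning)
            fit = model.fit(maxiter=100, tol=1e-8)
    except Exception as exc:
        raise EstimationError(f"logistic fit failed: {exc}") from exc
    if not fit.converged:
        raise EstimationError("logistic fit did not converge in 100 IRLS iterations")
    # under separation the MLE diverges: coefficients and Wald SEs explode
    if np.max(np.abs(fit.params.to_numpy())) > 50 or np.max(fit.bse.to_numpy()) > 500:
        raise EstimationError("logistic fit unstable: separation suspected")
    table = pd.DataFrame(
        {"coef": fit.params, "se": fit.bse, "p": fit.pvalues}
    ).rename(index={"const": "intercept"})
    return RegressionResult(
        outcome=outcome_name, table=table, n_used=int(len(X)), n_dropped=n_dropped
    )


def regress_outcome(
    records: Sequence[TransferRecord],
    outcome: str,
    model: HierarchicalModel | None = None,
    schema: FeatureSchema = DEFAULT_SCHEMA,
) -> RegressionResult:
    """Fit the outcome-specific multivariable logistic regression.

    * ``set_pregnancy``: per-embryo rows of attributable SET/DET outcomes on
      all 19 selected features (reference-level handling is moot: the selected
      set is numeric/binary).
    * ``det_pregnancy`` / ``det_twin``: DET rows on the 16 patient features
      plus P1 + P2 and P1 × P2, which require a trained hierarchy to score.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}; expected one of {OUTCOMES}")
    if outcome == "set_pregnancy":
        set_records = [r for r in records if r.transfer_type == "SET"]
        table = build_first_level_training(set_records, schema)
        design = encode_features(table.X, schema, schema.selected, drop_reference=True)
        return fit_multivariable_logistic(design, table.y, outcome)
    if model is None or model.level1 is None:
        raise EstimationError(f"{outcome} regression needs a trained level-1 scorer for P1, P2")
    det_records = [r for r in records if r.transfer_type == "DET"]
    det_table = build_second_level_features(model.level1, det_records, schema)
    design = det_table.X  # 16 patient features + p_sum + p_product
    y = det_table.y_pregnancy if outcome == "det_pregnancy" else det_table.y_twin
    return fit_multivariable_logistic(design, y, outcome)


def significance_vs_importance(
    regression: RegressionResult,
    importance: Mapping[str, int],
    alpha: float = 0.05,
    top_k: int = 7,
) -> pd.DataFrame:
    """Pair each feature's Wald p-value with its split-count importance rank.

    Flags ``important_not_significant`` features (p > alpha yet within the
    top-k by split count) and ``significant_not_important`` ones (p ≤ alpha
    yet zero splits).  The two flag sets are disjoint by construction.
    """
    features = regression.feature_terms
    unknown = set(importance) - set(features) - set(LEVEL2_ENGINEERED)
    if unknown:
        raise ValueError(f"importance map has features outside the regression: {sorted(unknown)}")
    counts = {f: int(importance.get(f, 0)) for f in features}
    order = sorted(features, key=lambda f: (-counts[f], f))
    rank = {f: i + 1 for i, f in enumerate(order)}
    rows = []
    for f in features:
        p = regression.pvalue(f)
        in_top = rank[f] <= top_k and counts[f] > 0
        rows.append(
            {
                "feature": f,
                "p": p,
                "significant": p <= alpha,
                "split_count": counts[f],
                "importance_rank": rank[f],
                "important_not_significant": in_top and p > alpha,
                "significant_not_important": (p <= alpha) and counts[f] == 0,
            }
        )
    return pd.DataFrame(rows).set_index("feature")
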