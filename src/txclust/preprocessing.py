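"""Cohort preprocessing: inclusion criteria, chained-equation imputation,
and the mixed-type Gower dissimilarity consumed by the clustering.

The imputation produces a single completed dataset (the clustering consumes
one table, so no Rubin-style pooling): missing cells are initialized by
random draws from the observed values of their column, then cycled
variable-by-variable — continuous targets are imputed from a linear model on
all other variables plus a residual-noise draw, binary/categorical/ordinal
targets from a multinomial-logistic probability draw.  Observed cells are
never altered and the run is deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LinearRegression, LogisticRegression

from .cohort import CohortError, CohortTable, DistanceMatrix

logger = logging.getLogger(__name__)


@dataclass
class InclusionCriteria:
    """Cohort filter: high-KDPI deceased-donor recipients, kidney-only,
    within the study window."""

    kdpi_min: float = 85.0
    exclude_multi_organ: bool = True
    year_range: tuple[int, int] | None = (2010, 2019)

    def __post_init__(self) -> None:
        if not 0 <= self.kdpi_min <= 100:
            raise CohortError("kdpi_min must lie in [0, 100]")


def apply_inclusion(
    cohort: CohortTable, criteria: InclusionCriteria
) -> CohortTable:
    """Return the subset of rows satisfying all active criteria, preserving
    row order.  KDPI threshold is inclusive (>=)."""
    keep = pd.Series(True, index=cohort.data.index)
    if criteria.kdpi_min > 0:
        if "kdpi" not in cohort.data.columns:
            raise CohortError("inclusion requires a 'kdpi' column")
        keep &= cohort.data["kdpi"] >= criteria.kdpi_min
    if criteria.exclude_multi_organ:
        if "multi_organ" not in cohort.data.columns:
            raise CohortError("inclusion requires a 'multi_organ' column")
        keep &= cohort.data["multi_organ"].astype(bool) == False  # noqa: E712
    if criteria.year_range is not None:
        if "transplant_year" not in cohort.data.columns:
            raise CohortError("inclusion requires a 'transplant_year' column")
        lo, hi = criteria.year_range
        keep &= cohort.data["transplant_year"].between(lo, hi)
    n_in = int(keep.sum())
    logger.info("inclusion: %d of %d rows retained", n_in, cohort.n)
    return CohortTable(
        data=cohort.data.loc[keep].reset_index(drop=True),
        schema=dict(cohort.schema),
        missing_mask=cohort.missing_mask.loc[keep].reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# Chained-equation imputation


def _encode_predictors(
    data: pd.DataFrame, cohort: CohortTable, exclude: str
) -> np.ndarray:
    """Numeric design matrix from all schema variables except ``exclude``:
    continuous as-is, ordinal as level ranks, binary/categorical one-hot."""
    blocks = []
    for name in cohort.variables:
        if name == exclude:
            continue
        spec = cohort.schema[name]
        col = data[name]
        if spec.kind == "continuous":
            blocks.append(col.to_numpy(dtype=float)[:, None])
        elif spec.kind == "ordinal":
            ranks = col.map({lvl: i for i, lvl in enumerate(spec.levels)})
            blocks.append(ranks.to_numpy(dtype=float)[:, None])
        else:
            onehot = np.column_stack(
                [(col == lvl).to_numpy(dtype=float) for lvl in spec.levels[:-1]]
            )
            blocks.append(onehot)
    return np.column_stack(blocks)


def impute_chained(
    cohort: CohortTable, n_cycles: int = 10, seed: int = 0
) -> CohortTable:
    """Impute missing schema cells by chained equations; see module
    docstring for the algorithm.  The missingness mask is retained for
    audit."""
    if n_cycles < 1:
        raise CohortError("n_cycles must be >= 1")
    missing = cohort.data[cohort.variables].isna()
    fully_missing = [v for v in cohort.variables if missing[v].all()]
    if fully_missing:
        raise CohortError(f"columns fully missing: {fully_missing}")
    out = cohort.copy()
    if not missing.any().any():
        return out

    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    data = out.data
    targets = [v for v in cohort.variables if missing[v].any()]

    def _set(name: str, positions: np.ndarray, values) -> None:
        j = data.columns.get_loc(name)
        data.iloc[positions, j] = values

    # initialization: random draws from the observed values of each column
    for name in targets:
        obs = data[name].dropna().to_numpy()
        pos = np.flatnonzero(missing[name].to_numpy())
        _set(name, pos, rng.choice(obs, size=len(pos)))

    for _ in range(n_cycles):
        for name in targets:
            spec = cohort.schema[name]
            miss_pos = np.flatnonzero(missing[name].to_numpy())
            obs_pos = np.flatnonzero(~missing[name].to_numpy())
            X = _encode_predictors(data, cohort, exclude=name)
            try:
                if spec.kind == "continuous":
                    y = data[name].to_numpy(dtype=float)
                    model = LinearRegression().fit(X[obs_pos], y[obs_pos])
                    resid = y[obs_pos] - model.predict(X[obs_pos])
                    sigma = float(np.std(resid, ddof=min(len(resid) - 1, 1)))
                    pred = model.predict(X[miss_pos])
                    _set(name, miss_pos, pred + rng.normal(0.0, sigma, len(miss_pos)))
                else:
                    y = data[name]
                    classes = y.iloc[obs_pos].unique()
                    if len(classes) < 2:
                        _set(name, miss_pos, classes[0])
                        continue
                    import warnings as _warnings

                    with _warnings.catch_warnings():
                        _warnings.simplefilter("ignore", ConvergenceWarning)
                        model = LogisticRegression(max_iter=200).fit(
                            X[obs_pos], y.iloc[obs_pos].astype(str)
                        )
                    proba = model.predict_proba(X[miss_pos])
                    draws = [
                        model.classes_[rng.choice(len(model.classes_), p=p)]
                        for p in proba
                    ]
                    # logistic classes are strings; map back to declared levels
                    back = {str(lvl): lvl for lvl in spec.levels}
                    _set(name, miss_pos, [back[d] for d in draws])
            except Exception:  # non-convergent / singular model on a cycle
                logger.warning(
                    "imputation model failed for %r; falling back to "
                    "observed-value draws",
                    name,
                )
                obs = data[name].iloc[obs_pos].to_numpy()
                _set(name, miss_pos, rng.choice(obs, size=len(miss_pos)))

    for name in cohort.variables:
        if cohort.schema[name].kind == "continuous":
            data[name] = data[name].astype(float)
    assert out.is_complete()
    return out


def impute_column_mean(cohort: CohortTable) -> CohortTable:
    """Baseline imputer: column mean for continuous, mode otherwise.
    Used as the comparison arm when benchmarking chained equations."""
    out = cohort.copy()
    for name in cohort.variables:
        col = out.data[name]
        if not col.isna().any():
            continue
        if cohort.schema[name].kind == "continuous":
            out.data[name] = col.fillna(col.mean())
        else:
            out.data[name] = col.fillna(col.mode().iloc[0]).infer_objects(
                copy=False
            )
    return out


# ---------------------------------------------------------------------------
# Gower dissimilarity


def gower_distance(cohort: CohortTable) -> DistanceMatrix:
    """Pairwise Gower dissimilarity over the schema variables.

    Continuous and ordinal variables contribute |x_i - x_j| / range (ordinal
    via integer level ranks); binary and categorical contribute 0/1
    mismatch; the per-variable contributions are averaged.  Zero-range
    variables contribute 0 and are logged.
    """
    if not cohort.is_complete():
        raise CohortError(
            "cohort has missing cells; run impute_chained before gower_distance"
        )
    n = cohort.n
    total = np.zeros((n, n))
    degenerate = []
    for name in cohort.variables:
        spec = cohort.schema[name]
        col = cohort.data[name]
        if spec.kind in ("continuous", "ordinal"):
            if spec.kind == "ordinal":
                x = col.map(
                    {lvl: i for i, lvl in enumerate(spec.levels)}
                ).to_numpy(dtype=float)
            else:
                x = col.to_numpy(dtype=float)
            rng_ = x.max() - x.min()
            if rng_ <= 0:
                degenerate.append(name)
                continue
            total += np.abs(x[:, None] - x[None, :]) / rng_
        else:
            codes = pd.Categorical(col, categories=spec.levels).codes
            total += (codes[:, None] != codes[None, :]).astype(float)
    if degenerate:
        logger.warning("zero-range variables contribute no distance: %s", degenerate)
    values = total / len(cohort.variables)
    np.fill_diagonal(values, 0.0)
    values = (values + values.T) / 2  # symmetrize away float noise
    return DistanceMatrix(values=values, subject_ids=list(cohort.subject_ids))


def onehot_euclidean_distance(cohort: CohortTable) -> DistanceMatrix:
    """Sensitivity-check alternative to Gower: min-max scale continuous and
    ordinal-rank columns, one-hot encode the rest, then Euclidean distance
    rescaled to [0, 1] by its maximum."""
    if not cohort.is_complete():
        raise CohortError(
            "cohort has missing cells; run impute_chained before computing distances"
        )
    blocks = []
    for name in cohort.variables:
        spec = cohort.schema[name]
        col = cohort.data[name]
        if spec.kind in ("continuous", "ordinal"):
            if spec.kind == "ordinal":
                x = col.map(
                    {lvl: i for i, lvl in enumerate(spec.levels)}
                ).to_numpy(dtype=float)
            else:
                x = col.to_numpy(dtype=float)
            rng_ = x.max() - x.min()
            blocks.append(((x - x.min()) / rng_ if rng_ > 0 else x * 0.0)[:, None])
        else:
            blocks.append(
                np.column_stack(
                    [(col == lvl).to_numpy(dtype=float) for lvl in spec.levels]
                )
            )
    X = np.column_stack(blocks)
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    values = np.sqrt(np.maximum(sq, 0.0))
    peak = values.max()
    if peak > 0:
        values = values / peak
    np.fill_diagonal(values, 0.0)
    values = (values + values.T) / 2
    return DistanceMatrix(values=values, subject_ids=list(cohort.subject_ids))
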