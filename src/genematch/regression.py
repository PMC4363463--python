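"""Correlations and OLS models of log2 CLIP tag depth on abundance and length."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .universe import GeneUniverse, filter_universe

#: (label, covariate names) for each model in the tag-depth model table.
MODEL_FORMULAS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("count ~ abundance", ("log_expr",)),
    ("count ~ cds_length", ("cds_len_log2",)),
    ("count ~ tx_length", ("tx_len_log2",)),
    ("count ~ abundance + cds_length", ("log_expr", "cds_len_log2")),
    ("count ~ abundance + tx_length", ("log_expr", "tx_len_log2")),
    ("count ~ abundance + cds_length + tx_length", ("log_expr", "cds_len_log2", "tx_len_log2")),
)


@dataclass(frozen=True)
class RegressionFit:
    """An OLS fit: slopes on the log2 scale, r², overall F-test p, and n."""

    response_name: str
    covariate_names: tuple[str, ...]
    coefficients: Mapping[str, float]  # includes "intercept"
    stderr: Mapping[str, float]
    r_squared: float
    model_p: float
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0):
            raise ValueError(f"r_squared out of [0, 1]: {self.r_squared}")
        if self.n < len(self.coefficients) + 1:
            raise ValueError("too few observations for the number of coefficients")


@dataclass(frozen=True)
class Table1Result:
    """One RegressionFit per (model formula, CLIP-count filter) pair."""

    rows: tuple[tuple[str, int, RegressionFit], ...]  # (formula, min_count, fit)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "formula": formula,
                    "min_clip_count": min_count,
                    "n": fit.n,
                    "r_squared": fit.r_squared,
                    "model_p": fit.model_p,
                }
                for formula, min_count, fit in self.rows
            ]
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; errors on constant input."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1 or xa.size < 3:
        raise ValueError("pearson_correlation needs two equal-length vectors of >= 3 values")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("correlation undefined for a constant input")
    return float(np.corrcoef(xa, ya)[0, 1])


def ols_fit(
    response: Sequence[float],
    covariates: Mapping[str, Sequence[float]],
    response_name: str = "response",
) -> RegressionFit:
    """Ordinary least squares with intercept.

    ``covariates`` maps column name -> values. Raises on rank deficiency,
    naming the collinear columns.
    """
    y = np.asarray(response, dtype=float)
    names = tuple(covariates)
    X = np.column_stack([np.asarray(covariates[c], dtype=float) for c in names])
    if X.shape[0] != y.shape[0]:
        raise ValueError("response and covariates differ in length")
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(f"design matrix is rank deficient; check columns {names} for collinearity")
    res = sm.OLS(y, design).fit()
    coef = {"intercept": float(res.params[0])}
    se = {"intercept": float(res.bse[0])}
    for i, c in enumerate(names, start=1):
        coef[c] = float(res.params[i])
        se[c] = float(res.bse[i])
    return RegressionFit(
        response_name=response_name,
        covariate_names=names,
        coefficients=coef,
        stderr=se,
        r_squared=float(res.rsquared),
        model_p=float(res.f_pvalue),
        n=n,
    )


def table1(
    universe: GeneUniverse,
    clip_filters: Sequence[int] = (1, 17),
) -> Table1Result:
    """Fit the tag-depth model family at each minimum-CLIP-count filter.

    Each entry of ``clip_filters`` keeps genes with ``clip_count >= value``
    (so a strictly-greater-than-16 filter is requested as 17). The response is
    log2 of the CLIP count; genes missing any covariate are excluded.
    """
    rows: list[tuple[str, int, RegressionFit]] = []
    for min_count in clip_filters:
        sub = filter_universe(
            universe,
            require_cds_len=True,
            require_tx_len=True,
            min_clip_count=max(1, int(min_count)),
        )
        y = np.log2(sub.covariate("clip_count"))
        cols = {c: sub.covariate(c) for c in ("log_expr", "cds_len_log2", "tx_len_log2")}
        for formula, names in MODEL_FORMULAS:
            fit = ols_fit(y, {c: cols[c] for c in names}, response_name="log2_clip_count")
            rows.append((formula, int(min_count), fit))
    return Table1Result(rows=tuple(rows))
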