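"""Per-gene expression summaries across experiments.

The model's expression covariates are the mean, the *population*
(divisor-N) standard deviation, and their ratio — the coefficient of
variation (CV) — of a gene's expression values across N experiments.
Also provides the precision-versus-number-of-experiments curve
Error(N) = |CV(N) − CV(N_total)| / CV(N_total) × 100%, estimated by
subsampling experiments.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = ["GE_MEAN", "GE_STDEV", "GE_CV"]


def read_expression_tsv(path) -> pd.DataFrame:
    """Expression matrix: rows = genes (first column gene_id), columns = experiments."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 2:
        raise ValueError("expression matrix needs >= 2 experiment columns")
    return df


def summarize_expression(matrix: pd.DataFrame) -> pd.DataFrame:
    """GE_MEAN, GE_STDEV (divisor N) and GE_CV per gene.

    Genes with zero mean get GE_CV = NaN (flagged, logged); negative
    expression values raise.
    """
    values = matrix.to_numpy(dtype=float)
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 experiments for dispersion statistics")
    if not np.isfinite(values).all():
        raise ValueError("expression matrix contains non-finite values")
    if (values < 0).any():
        raise ValueError("expression matrix contains negative values")
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), np.nan)
    n_zero = int((mean == 0).sum())
    if n_zero:
        logger.warning("%d genes with zero mean expression: CV flagged missing", n_zero)
    return pd.DataFrame(
        {"GE_MEAN": mean, "GE_STDEV": sd, "GE_CV": cv}, index=matrix.index
    )


def _cv(values: np.ndarray) -> np.ndarray:
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), np.nan)


def cv_precision_curve(
    matrix: pd.DataFrame,
    n_grid: list[int],
    reps: int = 50,
    seed: int = 0,
    aggregator: str = "median",
) -> pd.DataFrame:
    """Error(N) of the CV estimate from N experiments vs. all experiments.

    For each N in ``n_grid``, draws ``reps`` random subsets of N experiment
    columns (without replacement, seeded), computes per-gene CV(N) and the
    relative error against CV on the full matrix, then aggregates over genes
    and repetitions (median by default). Genes whose full-matrix CV is zero
    (constant expression) contribute zero error; genes with zero mean are
    excluded.

    Returns a DataFrame with columns ``N`` and ``ERROR_PCT``.
    """
    if aggregator not in ("median", "mean"):
        raise ValueError(f"unknown aggregator {aggregator!r}")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    values = matrix.to_numpy(dtype=float)
    n_total = values.shape[1]
    if any(n < 2 for n in n_grid):
        raise ValueError("every N in n_grid must be >= 2")
    if max(n_grid) > n_total:
        raise ValueError(f"n_grid maximum {max(n_grid)} exceeds {n_total} experiments")

    cv_full = _cv(values)
    keep = ~np.isnan(cv_full)
    values = values[keep]
    cv_full = cv_full[keep]
    rng = np.random.default_rng(seed)
    agg = np.median if aggregator == "median" else np.mean

    rows = []
    for n in n_grid:
        errors = np.empty((reps, values.shape[0]))
        for r in range(reps):
            cols = np.sort(rng.choice(n_total, size=n, replace=False))
            # a full-size subset IS the full set: self-referential error 0
            cv_n = cv_full if n == n_total else _cv(values[:, cols])
            with np.errstate(divide="ignore", invalid="ignore"):
                err = np.abs(cv_n - cv_full) / np.where(cv_full > 0, cv_full, 1.0) * 100.0
            errors[r] = np.where(cv_full > 0, err, 0.0)
        rows.append({"N": n, "ERROR_PCT": float(agg(errors))})
    return pd.DataFrame(rows)


def write_summary(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")
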