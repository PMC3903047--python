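"""The sixmer methylation model.

The method's core idea: gene-level quantities (methylation, expression CV,
compositional features) are transferred onto the 4,096 possible sixmer
types by occurrence-weighted averaging,

    value(sixmer) = sum_i value(gene_i) * n(sixmer)_i / sum_i n(sixmer)_i,

where n(sixmer)_i counts the sixmer's occurrences in gene i. At the sixmer
level, methylation is strongly linear in the expression CV,

    Met(sixmer) = slope * GE_CV(sixmer) + intercept,

(published constants: slope = -1.66, intercept = 1.7567). A gene's
methylation is reconstructed from its sixmer content,

    Met'(gene) = sum_sixmer Met(sixmer) * n(sixmer) / l,   Met(sixmer) > 0,

with l the CDS length in nucleotides, and mapped to the observed
methylation scale by an exponential calibration fitted after moving-average
smoothing (published constants: Met = 6e-4 * exp(21.33 * Met')).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .seqfeatures import SixmerDecomposition

logger = logging.getLogger(__name__)

BASES = "ACGT"
N_SIXMER_TYPES = 4 ** 6

DEFAULT_SMOOTHING_WINDOW = 101
DEFAULT_DISPERSION_CUTOFF = 0.1

#: published model constants (Results of the source study)
PUBLISHED_SLOPE = -1.66
PUBLISHED_INTERCEPT = 1.7567
PUBLISHED_AMPLITUDE = 6e-4
PUBLISHED_RATE = 21.33


def all_sixmers() -> list[str]:
    """Every possible sixmer type, lexicographic (4^6 = 4,096 of them)."""
    return ["".join(p) for p in itertools.product(BASES, repeat=6)]


# ---------------------------------------------------------------------------
# occurrence-weighted aggregation (gene level -> sixmer level)

def build_occurrence_frame(decomps) -> pd.DataFrame:
    """Long table of sixmer occurrences: columns gene_id, sixmer, count."""
    records = [
        (d.gene_id, sixmer, count)
        for d in decomps
        for sixmer, count in d.counts.items()
    ]
    return pd.DataFrame(records, columns=["gene_id", "sixmer", "count"])


def aggregate_by_sixmer(
    occurrences: pd.DataFrame, values: pd.Series, name: str = "VALUE"
) -> pd.DataFrame:
    """Occurrence-weighted mean and SD of a gene-level value per sixmer type.

    Genes missing from ``values`` (or with NaN) are skipped with a log
    entry. Sixmers absent from every contributing gene are omitted. The
    dispersion column ``SD_<name>`` is the occurrence-weighted population
    standard deviation across occurrences.
    """
    vals = values.dropna()
    skipped = set(occurrences["gene_id"].unique()) - set(vals.index)
    if skipped:
        logger.info("aggregate %s: skipping %d genes with missing values",
                    name, len(skipped))
    occ = occurrences.loc[occurrences["gene_id"].isin(vals.index)].copy()
    v = vals.reindex(occ["gene_id"]).to_numpy()
    n = occ["count"].to_numpy(dtype=float)
    occ["_nv"] = n * v
    occ["_nv2"] = n * v * v
    grouped = occ.groupby("sixmer", sort=True)[["count", "_nv", "_nv2"]].sum()
    total = grouped["count"].to_numpy(dtype=float)
    mean = grouped["_nv"].to_numpy() / total
    var = np.maximum(grouped["_nv2"].to_numpy() / total - mean ** 2, 0.0)
    return pd.DataFrame(
        {"OCC_TOTAL": grouped["count"].astype(int), name: mean,
         f"SD_{name}": np.sqrt(var)},
        index=grouped.index,
    )


def aggregate_feature_table(
    occurrences: pd.DataFrame, gene_table: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate every column of a per-gene table onto sixmer types.

    Returns ``(values, dispersions)``: two sixmer-indexed DataFrames with
    one column per gene-level feature, plus an ``OCC_TOTAL`` column on the
    values frame. This mirrors the published per-sixmer supplementary
    table (mean methylation, GC3, GE_MEAN, GE_STDEV, GE_CV, GEN_SIG, GCL,
    GCM, GCR, l, GRADLM, GRADMR per sixmer type).
    """
    values, dispersions = None, {}
    for col in gene_table.columns:
        agg = aggregate_by_sixmer(occurrences, gene_table[col], name=col)
        if values is None:
            values = agg[["OCC_TOTAL"]].copy()
        values[col] = agg[col]
        dispersions[col] = agg[f"SD_{col}"]
    return values, pd.DataFrame(dispersions)


def dispersion_screen(
    dispersions: pd.DataFrame, cutoff: float = DEFAULT_DISPERSION_CUTOFF
) -> list[str]:
    """Features whose median per-sixmer dispersion is within the cutoff.

    A feature is retained when the median (across sixmer types) of its
    occurrence-weighted standard deviation is <= cutoff.
    """
    medians = dispersions.median(axis=0)
    retained = [c for c in dispersions.columns if medians[c] <= cutoff]
    logger.info("dispersion screen (cutoff %g): retained %s", cutoff, retained)
    return retained


# ---------------------------------------------------------------------------
# model fits

@dataclass
class LinearFit:
    slope: float
    intercept: float
    r: float
    pvalue: float
    n: int


def fit_linear_sixmer_model(x: pd.Series, y: pd.Series) -> LinearFit:
    """Ordinary least squares of sixmer methylation on sixmer GE_CV."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    mask = np.isfinite(xv) & np.isfinite(yv)
    xv, yv = xv[mask], yv[mask]
    if len(xv) < 3:
        raise ValueError("need >= 3 sixmers with finite x and y")
    if np.ptp(xv) == 0:
        raise ValueError("zero variance in GE_CV across sixmers")
    res = stats.linregress(xv, yv)
    return LinearFit(res.slope, res.intercept, res.rvalue, res.pvalue, len(xv))


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average, window truncated at the series edges."""
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be a positive odd integer")
    s = pd.Series(values)
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


def fit_exponential_calibration(
    met_prime: np.ndarray,
    met_obs: np.ndarray,
    window: int = DEFAULT_SMOOTHING_WINDOW,
    smoothing: str = "geometric",
) -> tuple[float, float, float, float]:
    """Fit Met = amplitude * exp(rate * Met') after moving-average smoothing.

    Genes are sorted by Met'; the observed levels are smoothed with a
    centered odd ``window`` (truncated at the edges) and the exponential is
    fitted by log-linear least squares. With the default ``"geometric"``
    smoothing the moving average is taken on log(Met) and the *same*
    averaging is applied to Met', so data lying exactly on an exponential
    curve are recovered exactly; ``"arithmetic"`` smoothing averages the
    raw levels instead. Only genes with Met > 0 enter the log-linear fit.

    Returns ``(amplitude, rate, r2, sse)``; r2 and SSE compare the fitted
    exponential with the smoothed series on the original scale.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be a positive odd integer")
    if smoothing not in ("geometric", "arithmetic"):
        raise ValueError(f"unknown smoothing {smoothing!r}")
    x = np.asarray(met_prime, dtype=float)
    y = np.asarray(met_obs, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y) & (y > 0)
    x, y = x[mask], y[mask]
    if len(x) < window:
        raise ValueError(f"need at least window={window} genes with Met > 0, "
                         f"got {len(x)}")
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]

    if smoothing == "geometric":
        sx = moving_average(x, window)
        sly = moving_average(np.log(y), window)
        smoothed = np.exp(sly)
    else:
        sx = moving_average(x, window)
        sy = moving_average(y, window)
        if (sy <= 0).all():
            raise ValueError("all smoothed methylation values are <= 0")
        pos = sy > 0
        sx, sy = sx[pos], sy[pos]
        smoothed, sly = sy, np.log(sy)

    if np.ptp(sx) == 0:
        raise ValueError("zero variance in Met' after smoothing")
    res = stats.linregress(sx, sly)
    rate = float(res.slope)
    amplitude = float(math.exp(res.intercept))
    fitted = amplitude * np.exp(rate * sx)
    sse = float(np.sum((smoothed - fitted) ** 2))
    sstot = float(np.sum((smoothed - smoothed.mean()) ** 2))
    r2 = 1.0 - sse / sstot if sstot > 0 else (1.0 if sse == 0 else 0.0)
    return amplitude, rate, r2, sse


# ---------------------------------------------------------------------------
# the fitted model and prediction

@dataclass
class CalibrationModel:
    """Fitted constants of the sixmer-linear and exponential-calibration maps."""

    slope: float
    intercept: float
    amplitude: float
    rate: float
    smoothing_window: int = DEFAULT_SMOOTHING_WINDOW
    r2: float = math.nan
    sse: float = math.nan
    linear_r: float = math.nan
    preset: str = "fit"

    def __post_init__(self) -> None:
        # plain Python scalars so the YAML serialization never sees numpy types
        for name in ("slope", "intercept", "amplitude", "rate",
                     "r2", "sse", "linear_r"):
            setattr(self, name, float(getattr(self, name)))
        self.smoothing_window = int(self.smoothing_window)
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be a positive odd integer")

    def sixmer_met(self, ge_cv):
        """Predicted sixmer methylation: slope * GE_CV + intercept."""
        return self.slope * np.asarray(ge_cv, dtype=float) + self.intercept

    def calibrate(self, met_prime):
        """Map reconstructed Met' to the observed methylation scale."""
        return self.amplitude * np.exp(self.rate * np.asarray(met_prime, dtype=float))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "CalibrationModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def published_model(smoothing_window: int = DEFAULT_SMOOTHING_WINDOW) -> CalibrationModel:
    """The model with the published constants, usable without refitting."""
    return CalibrationModel(
        slope=PUBLISHED_SLOPE, intercept=PUBLISHED_INTERCEPT,
        amplitude=PUBLISHED_AMPLITUDE, rate=PUBLISHED_RATE,
        smoothing_window=smoothing_window, preset="published",
    )


def reconstruct_gene_met(
    decomp: SixmerDecomposition,
    length_nt: int,
    met_by_sixmer: pd.Series,
) -> tuple[float, float]:
    """Reconstruct a gene's methylation from its sixmer content.

    Met'(gene) = sum of table-methylation * occurrence count over the
    gene's sixmer types with table value > 0, divided by the CDS length in
    nucleotides. Sixmers absent from the table contribute zero and reduce
    the coverage diagnostic (fraction of the gene's occurrences whose
    sixmer type is present in the table).
    """
    if length_nt <= 0:
        raise ValueError(f"gene {decomp.gene_id}: nonpositive length {length_nt}")
    table = met_by_sixmer
    acc = 0.0
    covered = 0
    for sixmer, count in decomp.counts.items():
        try:
            value = table[sixmer]
        except KeyError:
            continue
        covered += count
        if value > 0:
            acc += value * count
    coverage = covered / decomp.total if decomp.total else 0.0
    return acc / length_nt, coverage


def predict_gene_methylation(
    decomp: SixmerDecomposition,
    length_nt: int,
    ge_cv_by_sixmer: pd.Series,
    model: CalibrationModel,
) -> tuple[float, float, float]:
    """Predict one gene's methylation level (the per-gene half of the flow).

    Applies the linear sixmer model to the sixmer GE_CV table, reconstructs
    Met' from the gene's sixmer content, and calibrates exponentially.
    Returns ``(met_pred, met_prime, coverage)``; a gene sharing no sixmer
    with the table raises.
    """
    met_table = pd.Series(
        model.sixmer_met(ge_cv_by_sixmer.to_numpy()), index=ge_cv_by_sixmer.index
    )
    met_prime, coverage = reconstruct_gene_met(decomp, length_nt, met_table)
    if coverage == 0.0:
        raise ValueError(
            f"gene {decomp.gene_id}: no sixmer present in the GE_CV table")
    return float(model.calibrate(met_prime)), met_prime, coverage


def predict_table(
    decomps,
    lengths: pd.Series,
    ge_cv_by_sixmer: pd.Series,
    model: CalibrationModel,
) -> pd.DataFrame:
    """Batch prediction: DataFrame ``MET_PRED MET_PRIME SIXMER_COVERAGE``.

    Genes without any table sixmer are dropped with a log entry.
    """
    met_table = pd.Series(
        model.sixmer_met(ge_cv_by_sixmer.to_numpy()), index=ge_cv_by_sixmer.index
    )
    lookup = met_table.to_dict()
    rows = []
    for d in decomps:
        acc, covered = 0.0, 0
        for sixmer, count in d.counts.items():
            value = lookup.get(sixmer)
            if value is None:
                continue
            covered += count
            if value > 0:
                acc += value * count
        if covered == 0:
            logger.info("gene %s: no sixmer present in the table, dropped",
                        d.gene_id)
            continue
        met_prime = acc / float(lengths[d.gene_id])
        rows.append((d.gene_id, float(model.calibrate(met_prime)), met_prime,
                     covered / d.total))
    return pd.DataFrame(
        rows, columns=["gene_id", "MET_PRED", "MET_PRIME", "SIXMER_COVERAGE"]
    ).set_index("gene_id")


def write_sixmer_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="SIXMER")


def read_sixmer_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="SIXMER")
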