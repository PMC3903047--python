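"""Per-gene methylation levels from bisulfite counts.

Each cytosine's methylation level is the fraction of reads that failed
bisulfite conversion (methylated reads / total reads), kept only when the
site has at least ``min_reads`` coverage. A gene's body methylation is the
average of surviving site levels over its exonic regions (all sequence
contexts pooled by default). Gene levels follow a bimodal distribution
with a valley near 1e-4, which splits genes into an unmethylated
(< valley) and a methylated (>= valley) class.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_MIN_READS = 5
DEFAULT_VALLEY = 1e-4
CONTEXTS = ("CG", "CHG", "CHH")

SITE_COLUMNS = ["gene_id", "position", "context", "meth_reads", "total_reads"]


def read_site_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene_id": str})


def read_gene_methylation_tsv(path) -> pd.Series:
    """Per-gene methylation levels from TSV ``gene_id <tab> MET``."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].rename("MET")


def call_site_levels(sites: pd.DataFrame, min_reads: int = DEFAULT_MIN_READS) -> pd.DataFrame:
    """Per-site methylation levels for sites with sufficient coverage.

    Adds a ``LEVEL`` column (meth_reads / total_reads) and drops sites with
    total_reads < min_reads. Inconsistent counts raise.
    """
    if (sites["meth_reads"] > sites["total_reads"]).any():
        bad = sites.loc[sites["meth_reads"] > sites["total_reads"], "gene_id"].iloc[0]
        raise ValueError(f"meth_reads > total_reads at a site of gene {bad}")
    if (sites[["meth_reads", "total_reads"]] < 0).any().any():
        raise ValueError("negative read counts")
    kept = sites.loc[sites["total_reads"] >= min_reads].copy()
    kept["LEVEL"] = kept["meth_reads"] / kept["total_reads"]
    return kept


def _in_exons(positions: pd.Series, intervals: list[tuple[int, int]]) -> np.ndarray:
    mask = np.zeros(len(positions), dtype=bool)
    pos = positions.to_numpy()
    for start, end in intervals:
        mask |= (pos >= start) & (pos < end)
    return mask


def gene_body_methylation(
    sites: pd.DataFrame,
    exon_intervals: dict[str, list[tuple[int, int]]] | None = None,
    min_reads: int = DEFAULT_MIN_READS,
    contexts: tuple[str, ...] | None = None,
    weighted: bool = False,
    valley: float = DEFAULT_VALLEY,
) -> tuple[pd.DataFrame, list[str]]:
    """Average gene-body methylation per gene over exonic sites.

    Parameters
    ----------
    sites:
        Site table with columns ``gene_id position context meth_reads
        total_reads``.
    exon_intervals:
        0-based half-open intervals per gene; sites outside them are
        ignored. ``None`` treats every site as exonic.
    contexts:
        Restrict to these sequence contexts (e.g. ``("CG",)``); default all.
    weighted:
        If True, weight site levels by read depth instead of the default
        unweighted mean.

    Returns the per-gene table (``MET``, ``LEVEL_CLASS``) and the list of
    gene ids with no surviving site (flagged missing, excluded).
    """
    called = call_site_levels(sites, min_reads=min_reads)
    if contexts is not None:
        called = called.loc[called["context"].isin(contexts)]
    parts = []
    for gene_id, sub in called.groupby("gene_id", sort=False):
        if exon_intervals is not None and gene_id in exon_intervals:
            sub = sub.loc[_in_exons(sub["position"], exon_intervals[gene_id])]
        if len(sub) == 0:
            continue
        if weighted:
            level = float(np.average(sub["LEVEL"], weights=sub["total_reads"]))
        else:
            level = float(sub["LEVEL"].mean())
        parts.append((gene_id, level))
    out = pd.DataFrame(parts, columns=["gene_id", "MET"]).set_index("gene_id")
    out["LEVEL_CLASS"] = classify(out["MET"], valley=valley)
    missing = sorted(set(sites["gene_id"]) - set(out.index))
    for gene_id in missing:
        logger.info("gene %s: no site with >= %d reads in exons, "
                    "methylation missing", gene_id, min_reads)
    return out, missing


def classify(levels: pd.Series, valley: float = DEFAULT_VALLEY) -> pd.Series:
    """'methylated' iff level >= valley, else 'unmethylated'."""
    return pd.Series(
        np.where(levels >= valley, "methylated", "unmethylated"),
        index=levels.index, name="LEVEL_CLASS",
    )


def partition_by_methylation(
    levels: pd.Series, valley: float = DEFAULT_VALLEY
) -> tuple[list[str], list[str]]:
    """Split gene ids into (unmethylated, methylated) at the valley.

    The boundary level exactly equal to ``valley`` is methylated.
    """
    meth = levels >= valley
    return list(levels.index[~meth]), list(levels.index[meth])


def write_gene_methylation(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")
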