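"""Coding-sequence features and the codon-pair (sixmer) decomposition.

A gene's coding sequence is summarised by a small set of compositional
statistics — GC content at third codon positions (GC3, overall and within
the left/middle/right thirds of the CDS), the CpG genome signature
rho = f(CG)/(f(C)·f(G)), the GC3 gradients between thirds, and the CDS
length — and decomposed into *sixmers*: 6-nt words formed by every pair of
adjacent codons (a codon-aligned sliding window of width 6 and step 3).
A CDS of n codons therefore yields n − 1 sixmer occurrences.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

#: column order of the features table written by :func:`features_frame`
FEATURE_COLUMNS = [
    "GC3", "GEN_SIG", "GCL", "GCM", "GCR", "GRADLM", "GRADMR", "LENGTH_NT",
]


class GeneRejected(ValueError):
    """A gene failed validation; ``reason`` is a machine-readable code."""

    def __init__(self, gene_id: str, reason: str, message: str = ""):
        self.gene_id = gene_id
        self.reason = reason
        super().__init__(message or f"{gene_id}: {reason}")


@dataclass
class GeneModel:
    """One gene model: identifier, coding sequence, optional exon intervals.

    ``exon_intervals`` are 0-based half-open ``(start, end)`` pairs used only
    for methylation averaging; all compositional features are CDS-only.
    """

    gene_id: str
    cds: str
    exon_intervals: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        self.cds = self.cds.upper()

    @property
    def length_nt(self) -> int:
        return len(self.cds)

    @property
    def n_codons(self) -> int:
        return len(self.cds) // 3


@dataclass
class SixmerDecomposition:
    """Occurrence counts of each sixmer type in one gene."""

    gene_id: str
    counts: dict[str, int]
    total: int


@dataclass
class GeneFeatures:
    """The gene-level covariates of the methylation model.

    Sequence-derived fields are filled by :func:`compute_gene_features`;
    the expression fields (``ge_mean``/``ge_stdev``/``ge_cv``) are filled
    later from an expression matrix and default to NaN.
    """

    gene_id: str
    gc3: float
    gen_sig: float
    gcl: float
    gcm: float
    gcr: float
    gradlm: float
    gradmr: float
    length_nt: int
    ge_mean: float = field(default=math.nan)
    ge_stdev: float = field(default=math.nan)
    ge_cv: float = field(default=math.nan)


def _validate_cds(gene: GeneModel, min_len: int = 6) -> None:
    seq = gene.cds
    if len(seq) == 0:
        raise GeneRejected(gene.gene_id, "empty_sequence")
    if len(seq) % 3 != 0:
        raise GeneRejected(gene.gene_id, "length_not_codon_multiple",
                           f"{gene.gene_id}: CDS length {len(seq)} not divisible by 3")
    if len(seq) < min_len:
        raise GeneRejected(gene.gene_id, "too_short",
                           f"{gene.gene_id}: CDS length {len(seq)} < {min_len}")
    if not VALID_BASES.issuperset(seq):
        raise GeneRejected(gene.gene_id, "ambiguous_base",
                           f"{gene.gene_id}: non-ACGT character in CDS")


def extract_sixmers(gene: GeneModel, on_ambiguous: str = "reject") -> SixmerDecomposition:
    """Decompose a CDS into codon-pair sixmers.

    Windows of 6 nt are taken at offsets 0, 3, 6, … so that every pair of
    adjacent codons yields one sixmer; a gene of n codons gives n − 1
    occurrences.

    Parameters
    ----------
    on_ambiguous:
        ``"reject"`` (default) raises :class:`GeneRejected` on any non-ACGT
        character; ``"skip"`` silently drops windows containing one.
    """
    if on_ambiguous not in ("reject", "skip"):
        raise ValueError(f"on_ambiguous must be 'reject' or 'skip', got {on_ambiguous!r}")
    seq = gene.cds
    if len(seq) == 0:
        raise GeneRejected(gene.gene_id, "empty_sequence")
    if len(seq) % 3 != 0:
        raise GeneRejected(gene.gene_id, "length_not_codon_multiple")
    if len(seq) < 6:
        raise GeneRejected(gene.gene_id, "too_short")
    if on_ambiguous == "reject" and not VALID_BASES.issuperset(seq):
        raise GeneRejected(gene.gene_id, "ambiguous_base")

    counts: Counter[str] = Counter()
    total = 0
    for off in range(0, len(seq) - 5, 3):
        word = seq[off:off + 6]
        if on_ambiguous == "skip" and not VALID_BASES.issuperset(word):
            continue
        counts[word] += 1
        total += 1
    return SixmerDecomposition(gene.gene_id, dict(counts), total)


def gc3(gene: GeneModel) -> float:
    """Fraction of third codon positions that are G or C."""
    _validate_cds(gene, min_len=3)
    thirds = gene.cds[2::3]
    return sum(b in "GC" for b in thirds) / len(thirds)


def genome_signature(gene: GeneModel) -> float:
    """CpG genome signature rho = f(CG) / (f(C) · f(G)) over the CDS.

    Dinucleotide frequency uses overlapping windows (length − 1 of them);
    mononucleotide frequencies are plain base fractions. Returns NaN (and
    logs) when the sequence has no C or no G, 0.0 when CG never occurs.
    """
    seq = gene.cds
    if len(seq) < 2:
        raise GeneRejected(gene.gene_id, "too_short",
                           f"{gene.gene_id}: need >= 2 nt for dinucleotide frequency")
    n = len(seq)
    f_c = seq.count("C") / n
    f_g = seq.count("G") / n
    if f_c * f_g == 0.0:
        logger.warning("gene %s: f(C)*f(G)=0, genome signature undefined", gene.gene_id)
        return math.nan
    n_cg = sum(1 for i in range(n - 1) if seq[i:i + 2] == "CG")
    f_cg = n_cg / (n - 1)
    return f_cg / (f_c * f_g)


def positional_gc3(gene: GeneModel) -> tuple[float, float, float]:
    """GC3 within the left, middle and right thirds of the CDS.

    With q = floor(n_codons / 3) the blocks are codons [0, q), [q, 2q) and
    [2q, n_codons); the remainder codons go to the right block.
    """
    _validate_cds(gene, min_len=9)
    ncod = gene.n_codons
    if ncod < 3:
        raise GeneRejected(gene.gene_id, "too_short",
                           f"{gene.gene_id}: need >= 3 codons for positional GC3")
    q = ncod // 3
    blocks = (gene.cds[: 3 * q], gene.cds[3 * q: 6 * q], gene.cds[6 * q:])
    return tuple(
        sum(b in "GC" for b in blk[2::3]) / (len(blk) // 3) for blk in blocks
    )


def gradients(gcl: float, gcm: float, gcr: float) -> tuple[float, float]:
    """GC3 gradients: left→middle and middle→right differences."""
    return gcm - gcl, gcr - gcm


def compute_gene_features(gene: GeneModel) -> GeneFeatures:
    """All sequence-derived features for one gene (expression fields NaN)."""
    _validate_cds(gene)
    g3 = gc3(gene)
    rho = genome_signature(gene)
    gcl, gcm, gcr = positional_gc3(gene)
    gradlm, gradmr = gradients(gcl, gcm, gcr)
    return GeneFeatures(
        gene_id=gene.gene_id, gc3=g3, gen_sig=rho,
        gcl=gcl, gcm=gcm, gcr=gcr, gradlm=gradlm, gradmr=gradmr,
        length_nt=gene.length_nt,
    )


def features_frame(genes: list[GeneModel]) -> tuple[pd.DataFrame, list[GeneRejected]]:
    """Features for a batch of genes; rejected genes are returned, not raised.

    Returns a DataFrame indexed by gene_id with :data:`FEATURE_COLUMNS`,
    in input order, plus the list of rejections (each with a reason code).
    """
    rows, dropped = [], []
    for gene in genes:
        try:
            f = compute_gene_features(gene)
        except GeneRejected as exc:
            logger.info("dropping gene %s: %s", exc.gene_id, exc.reason)
            dropped.append(exc)
            continue
        rows.append({
            "gene_id": f.gene_id, "GC3": f.gc3, "GEN_SIG": f.gen_sig,
            "GCL": f.gcl, "GCM": f.gcm, "GCR": f.gcr,
            "GRADLM": f.gradlm, "GRADMR": f.gradmr, "LENGTH_NT": f.length_nt,
        })
    df = pd.DataFrame(rows, columns=["gene_id"] + FEATURE_COLUMNS)
    return df.set_index("gene_id"), dropped


def read_cds_fasta(path) -> list[GeneModel]:
    """Read one GeneModel per FASTA record (record id = gene id)."""
    genes = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate gene id in FASTA: {rec.id}")
        seen.add(rec.id)
        genes.append(GeneModel(rec.id, str(rec.seq)))
    return genes


def read_exon_intervals(path) -> dict[str, list[tuple[int, int]]]:
    """Read BED-like TSV (gene_id, start, end; 0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["gene_id", "start", "end"], comment="#")
    intervals: dict[str, list[tuple[int, int]]] = {}
    for row in df.itertuples(index=False):
        if row.end <= row.start:
            raise ValueError(f"empty exon interval for {row.gene_id}: "
                             f"[{row.start}, {row.end})")
        intervals.setdefault(row.gene_id, []).append((int(row.start), int(row.end)))
    return intervals


def write_features(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")
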