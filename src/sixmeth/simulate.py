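"""Synthetic corpora with the statistical structure the method assumes.

The generator manufactures a corpus by inverting the prediction flow.
Sense codons are partitioned into disjoint groups and every gene samples
its codons from a single group, so each sixmer type occurs in genes of
exactly one group. Each group carries a latent expression CV; because all
genes contributing to a sixmer share that CV, occurrence-weighted
aggregation recovers the latent value exactly on any subset of genes —
the idealisation that makes noise-free round trips exact. Group CVs map
to sixmer methylation through the planted linear model, genes'
methylation propensities Met' follow by sixmer reconstruction, and
observed methylation is the planted exponential calibration of Met'
(times multiplicative noise). A configured fraction of genes is forced
below the 1e-4 valley to reproduce the bimodal methylation distribution;
these silenced genes are off-model by construction.

Grouping codons by third-position GC makes the group structure double as
the two GC3 classes of rice genes, so the positional-GC3 and gradient
features are exercised meaningfully.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import model as _model
from .methylation import DEFAULT_VALLEY, classify
from .seqfeatures import GeneModel, extract_sixmers

BASES = "ACGT"
ALL_CODONS = ["".join(p) for p in itertools.product(BASES, repeat=3)]
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
SENSE_CODONS = [c for c in ALL_CODONS if c not in STOP_CODONS]


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic corpus.

    Defaults emulate the shape of the real data: ~2,000 genes of rice-like
    CDS length, 30 expression experiments, the published model constants
    planted, 5% multiplicative noise, and roughly a third of genes in the
    silenced (sub-valley) class.
    """

    n_genes: int = 2000
    codon_range: tuple[int, int] = (60, 400)
    n_experiments: int = 30
    planted_slope: float = _model.PUBLISHED_SLOPE
    planted_intercept: float = _model.PUBLISHED_INTERCEPT
    planted_amplitude: float = _model.PUBLISHED_AMPLITUDE
    planted_rate: float = _model.PUBLISHED_RATE
    noise_sd_expression: float = 0.05
    noise_sd_methylation: float = 0.05
    bimodal_fraction_unmethylated: float = 0.3
    seed: int = 7
    n_classes: int = 16
    cv_range: tuple[float, float] = (0.55, 1.05)

    def __post_init__(self) -> None:
        if self.n_genes < 6:
            raise ValueError("n_genes must be >= 6")
        if self.codon_range[0] < 3:
            raise ValueError("codon_range minimum must be >= 3 codons")
        if min(self.noise_sd_expression, self.noise_sd_methylation) < 0:
            raise ValueError("noise SDs must be >= 0")
        if not 0 <= self.bimodal_fraction_unmethylated <= 1:
            raise ValueError("bimodal_fraction_unmethylated must be in [0,1]")
        if not 1 <= self.n_classes <= len(SENSE_CODONS) // 2:
            raise ValueError("n_classes out of range")


@dataclass
class Corpus:
    """A generated corpus plus its ground truth."""

    spec: FixtureSpec
    genes: list[GeneModel]
    expression: pd.DataFrame
    methylation: pd.Series
    sixmer_table: pd.DataFrame   # latent per-sixmer GE_CV and MET
    truth: dict = field(repr=False)

    @property
    def decompositions(self):
        return [extract_sixmers(g) for g in self.genes]

    @property
    def lengths(self) -> pd.Series:
        return pd.Series({g.gene_id: g.length_nt for g in self.genes},
                         name="LENGTH_NT")

    def write(self, outdir) -> None:
        """Serialize in the formats the pipeline reads (all plain text)."""
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "genes.fasta", "w") as fh:
            for g in self.genes:
                fh.write(f">{g.gene_id}\n{g.cds}\n")
        self.expression.to_csv(outdir / "expression.tsv", sep="\t")
        met = self.methylation.to_frame("MET")
        met["LEVEL_CLASS"] = classify(self.methylation)
        met.to_csv(outdir / "methylation.tsv", sep="\t")
        _model.write_sixmer_table(self.sixmer_table, outdir / "sixmer_table.tsv")
        with open(outdir / "exons.tsv", "w") as fh:
            for g in self.genes:
                fh.write(f"{g.gene_id}\t0\t{g.length_nt}\n")
        truth = dict(self.truth)
        truth["spec"] = asdict(self.spec)
        with open(outdir / "ground_truth.yaml", "w") as fh:
            yaml.safe_dump(_to_plain(truth), fh, sort_keys=True)


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    return obj


def codon_classes(n_classes: int) -> list[list[str]]:
    """Disjoint sense-codon groups, ordered AT-ending first then GC-ending.

    Contiguous grouping after sorting by third-position GC makes the low
    groups GC3-poor and the high groups GC3-rich, emulating the two GC3
    classes of rice coding sequences.
    """
    ordered = sorted(SENSE_CODONS, key=lambda c: (c[2] in "GC", c))
    return [list(chunk) for chunk in np.array_split(np.array(ordered), n_classes)]


def _expression_series(
    rng: np.random.Generator, mu: float, cv: float, n: int, noise_sd: float
) -> np.ndarray:
    """Nonnegative series of length n with population CV exactly ``cv``.

    A lognormal shape vector is standardised (mean 0, population SD 1) and
    scaled, giving mean mu and SD mu*cv to machine precision before noise.
    The lognormal's own CV is set to ~2*cv so the standardised minimum
    stays above -1/cv (positivity); the rare failing draw is redrawn.
    """
    if cv == 0.0:
        if noise_sd > 0:
            raise ValueError("target CV 0 with nonzero expression noise "
                             "is infeasible")
        return np.full(n, mu)
    sigma = np.sqrt(np.log1p(4.0 * cv * cv))
    for _ in range(100):
        y = rng.lognormal(0.0, sigma, n)
        sd = y.std(ddof=0)
        if sd == 0:
            continue
        z = (y - y.mean()) / sd
        values = mu * (1.0 + cv * z)
        if (values > 0).all():
            break
    else:  # pragma: no cover - vanishingly unlikely
        raise RuntimeError("could not realise a positive expression series")
    if noise_sd > 0:
        values = values * np.exp(rng.normal(0.0, noise_sd, n))
    return values


def generate_corpus(spec: FixtureSpec) -> Corpus:
    """Generate a corpus (sequences, expression, methylation, ground truth).

    All randomness flows from ``spec.seed``. The ground truth records the
    planted constants, per-gene latent values, and the achieved aggregation
    residual (max |aggregated CV - latent CV| over sixmer types) so that
    round-trip tests can be honest about their attainable tolerance.
    """
    rng = np.random.default_rng(spec.seed)
    groups = codon_classes(spec.n_classes)
    class_cv = rng.uniform(spec.cv_range[0], spec.cv_range[1], spec.n_classes)

    genes: list[GeneModel] = []
    gene_class = np.empty(spec.n_genes, dtype=int)
    ncodons = rng.integers(spec.codon_range[0], spec.codon_range[1] + 1,
                           spec.n_genes)
    for i in range(spec.n_genes):
        cls = int(rng.integers(spec.n_classes))
        gene_class[i] = cls
        pool = groups[cls]
        idx = rng.integers(len(pool), size=ncodons[i])
        cds = "".join(pool[j] for j in idx)
        genes.append(GeneModel(f"g{i:05d}", cds))
    gene_ids = [g.gene_id for g in genes]
    gene_cv = class_cv[gene_class]

    # expression matrix realising the latent per-gene CVs
    mu = rng.lognormal(5.5, 0.8, spec.n_genes)
    matrix = np.empty((spec.n_genes, spec.n_experiments))
    for i in range(spec.n_genes):
        matrix[i] = _expression_series(rng, mu[i], gene_cv[i],
                                       spec.n_experiments,
                                       spec.noise_sd_expression)
    expression = pd.DataFrame(
        matrix, index=pd.Index(gene_ids, name="gene_id"),
        columns=[f"exp{j:03d}" for j in range(spec.n_experiments)],
    )

    # planted sixmer-scale methylation and per-gene reconstruction
    class_met = spec.planted_slope * class_cv + spec.planted_intercept
    ratio = (ncodons - 1) / (3.0 * ncodons)          # (n_codons-1)/l
    met_prime = class_met[gene_class] * ratio
    met_noisefree = spec.planted_amplitude * np.exp(spec.planted_rate * met_prime)
    met_obs = met_noisefree.copy()
    if spec.noise_sd_methylation > 0:
        met_obs = met_obs * np.exp(
            rng.normal(0.0, spec.noise_sd_methylation, spec.n_genes))

    n_unmeth = int(round(spec.bimodal_fraction_unmethylated * spec.n_genes))
    unmeth_idx = rng.choice(spec.n_genes, size=n_unmeth, replace=False)
    if n_unmeth:
        met_obs[unmeth_idx] = 10.0 ** -(
            4.2 + np.abs(rng.normal(0.0, 0.6, n_unmeth)))
    methylation = pd.Series(met_obs, index=pd.Index(gene_ids, name="gene_id"),
                            name="MET")

    # latent sixmer table over the sixmer types that actually occur
    decomps = [extract_sixmers(g) for g in genes]
    occ = _model.build_occurrence_frame(decomps)
    codon_to_class = {c: k for k, grp in enumerate(groups) for c in grp}
    sixmers = np.sort(occ["sixmer"].unique())
    sixmer_class = np.array([codon_to_class[s[:3]] for s in sixmers])
    sixmer_table = pd.DataFrame(
        {"GE_CV": class_cv[sixmer_class], "MET": class_met[sixmer_class]},
        index=pd.Index(sixmers, name="SIXMER"),
    )

    # honesty diagnostic: aggregation of the latent gene CVs vs latent table
    agg = _model.aggregate_by_sixmer(
        occ, pd.Series(gene_cv, index=gene_ids), name="GE_CV")
    residual = float(np.abs(
        agg["GE_CV"] - sixmer_table["GE_CV"].reindex(agg.index)).max())

    truth = {
        "planted": {
            "slope": spec.planted_slope, "intercept": spec.planted_intercept,
            "amplitude": spec.planted_amplitude, "rate": spec.planted_rate,
        },
        "class_cv": class_cv,
        "gene_class": gene_class,
        "gene_cv": pd.Series(gene_cv, index=gene_ids),
        "met_prime": pd.Series(met_prime, index=gene_ids),
        "met_noisefree": pd.Series(met_noisefree, index=gene_ids),
        "unmethylated_ids": [gene_ids[i] for i in sorted(unmeth_idx)],
        "aggregation_residual": residual,
    }
    return Corpus(spec=spec, genes=genes, expression=expression,
                  methylation=methylation, sixmer_table=sixmer_table,
                  truth=truth)


def generate_bisulfite_sites(
    genes: list[GeneModel],
    levels: pd.Series,
    depth_mean: float = 20.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cytosine bisulfite counts emulating the method's raw input.

    One site per cytosine of each CDS; read depth is Poisson around
    ``depth_mean`` (so some sites fall under the 5-read filter) and
    methylated counts are binomial at the gene's level. Context is read
    off the sequence (CG / CHG / CHH).
    """
    if depth_mean <= 0:
        raise ValueError("depth_mean must be > 0")
    if ((levels < 0) | (levels > 1)).any():
        raise ValueError("methylation levels must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for gene in genes:
        level = float(levels[gene.gene_id])
        seq = gene.cds
        for pos, base in enumerate(seq):
            if base != "C":
                continue
            if pos + 1 < len(seq) and seq[pos + 1] == "G":
                context = "CG"
            elif pos + 2 < len(seq) and seq[pos + 2] == "G":
                context = "CHG"
            else:
                context = "CHH"
            total = int(rng.poisson(depth_mean))
            meth = int(rng.binomial(total, level)) if total else 0
            rows.append((gene.gene_id, pos, context, meth, total))
    return pd.DataFrame(
        rows, columns=["gene_id", "position", "context",
                       "meth_reads", "total_reads"])


def saturating_gene(gene_id: str = "saturator") -> GeneModel:
    """A single CDS containing every one of the 4,096 sixmer types.

    Built from a de Bruijn sequence of order 2 over the 64-codon alphabet:
    4,097 codons whose adjacent-codon pairs cover all 64^2 = 4,096 sixmers.
    """
    k = len(ALL_CODONS)
    a = [0] * (k * 2)
    seq: list[int] = []

    def db(t: int, p: int) -> None:
        if t > 2:
            if 2 % p == 0:
                seq.extend(a[1:p + 1])
        else:
            a[t] = a[t - p]
            db(t + 1, p)
            for j in range(a[t - p] + 1, k):
                a[t] = j
                db(t + 1, t)

    db(1, 1)
    codons = seq + [seq[0]]
    return GeneModel(gene_id, "".join(ALL_CODONS[i] for i in codons))
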