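"""End-to-end orchestration of the prediction flow.

Corpus-level work (features, expression summaries, sixmer aggregation,
model fitting) is done once; the per-gene half (sixmer decomposition,
reconstruction, calibration) is then applied to every gene. Every dropped
gene is recorded with a machine-readable reason, and the resolved
configuration is written next to the outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import expression as _expr
from . import methylation as _meth
from . import model as _model
from . import seqfeatures as _seq
from . import validate as _val
from .config import RunConfig

logger = logging.getLogger(__name__)


def run_pipeline(config: RunConfig) -> dict:
    """Execute features -> expression -> aggregation -> fit -> predict -> validate.

    Returns the machine-readable run summary (also written as
    ``summary.json`` in the output directory).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "run_config.yaml")

    genes = _seq.read_cds_fasta(config.cds_fasta)
    features, dropped = _seq.features_frame(genes)
    _seq.write_features(features, out / "features.tsv")
    accepted = {g.gene_id: g for g in genes if g.gene_id in features.index}

    matrix = _expr.read_expression_tsv(config.expression_tsv)
    summary = _expr.summarize_expression(matrix)
    _expr.write_summary(summary, out / "expression_summary.tsv")

    if config.sites_tsv:
        sites = _meth.read_site_tsv(config.sites_tsv)
        exons = _seq.read_exon_intervals(config.exons_tsv) \
            if config.exons_tsv else None
        contexts = tuple(config.contexts) if config.contexts else None
        met_df, missing = _meth.gene_body_methylation(
            sites, exons, min_reads=config.min_reads, contexts=contexts,
            valley=config.valley)
        met = met_df["MET"]
        for gene_id in missing:
            dropped.append(_seq.GeneRejected(gene_id, "no_covered_site"))
    elif config.methylation_tsv:
        met = _meth.read_gene_methylation_tsv(config.methylation_tsv)
    else:
        raise ValueError("either methylation_tsv or sites_tsv is required")
    met_out = met.to_frame("MET")
    met_out["LEVEL_CLASS"] = _meth.classify(met, valley=config.valley)
    _meth.write_gene_methylation(met_out, out / "gene_methylation.tsv")

    # genes entering the model: accepted CDS + expression + methylation
    ge_cv = summary["GE_CV"].dropna()
    for gene_id in set(summary.index) - set(ge_cv.index):
        dropped.append(_seq.GeneRejected(gene_id, "zero_mean_expression"))
    usable = [g for g in accepted.values()
              if g.gene_id in ge_cv.index and g.gene_id in met.index]
    decomps = [_seq.extract_sixmers(g) for g in usable]
    lengths = pd.Series({g.gene_id: g.length_nt for g in usable})

    gene_table = features.loc[[g.gene_id for g in usable]].copy()
    gene_table[["GE_MEAN", "GE_STDEV", "GE_CV"]] = \
        summary.loc[gene_table.index, ["GE_MEAN", "GE_STDEV", "GE_CV"]]
    gene_table["MET"] = met.reindex(gene_table.index)

    occ = _model.build_occurrence_frame(decomps)
    sixmer_values, sixmer_disp = _model.aggregate_feature_table(occ, gene_table)
    _model.write_sixmer_table(sixmer_values, out / "sixmer_table.tsv")
    retained = _model.dispersion_screen(
        sixmer_disp.drop(columns=["MET"]), cutoff=config.dispersion_cutoff)

    if config.sixmer_table_tsv:
        supplied = _model.read_sixmer_table(config.sixmer_table_tsv)
        met_table = supplied["MET"]
    else:
        met_table = None

    dataset = _val.Dataset(decomps=decomps, lengths=lengths,
                           ge_cv=ge_cv, met=met, features=features)
    if config.preset == "published":
        model = _model.published_model(config.smoothing_window)
        linear = None
    elif config.preset == "fit":
        model, linear, _ = _val._fit_on(
            decomps, dataset, config.smoothing_window, config.valley,
            met_table, config.aggregation_set, config.calibration_set,
            config.smoothing)
    else:
        raise ValueError(f"unknown preset {config.preset!r}")
    model.save(out / "model.yaml")

    ge_cv_table = sixmer_values["GE_CV"]
    predictions = _model.predict_table(decomps, lengths, ge_cv_table, model)
    predictions.to_csv(out / "predictions.tsv", sep="\t")

    report = _val.split_half_validate(
        dataset, seed=config.seed, window=config.smoothing_window,
        valley=config.valley, sixmer_met_table=met_table,
        aggregation_set=config.aggregation_set,
        calibration_set=config.calibration_set, smoothing=config.smoothing)
    (out / "validation.txt").write_text(report.to_text())

    pd.DataFrame(
        [(d.gene_id, d.reason) for d in dropped],
        columns=["gene_id", "reason"],
    ).to_csv(out / "dropped_genes.tsv", sep="\t", index=False)

    summary_dict = {
        "n_genes_input": len(genes),
        "n_genes_modelled": len(usable),
        "n_dropped": len(dropped),
        "n_sixmer_types": int(len(sixmer_values)),
        "retained_features": retained,
        "model": model.to_dict(),
        "r_test": report.r_test,
        "r_train": report.r_train,
        "extras": {k: (float(v) if isinstance(v, float) else v)
                   for k, v in report.extras.items()},
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary_dict, fh, indent=2, default=float)
    logger.info("pipeline complete: %d genes modelled, r_test=%.3f",
                len(usable), report.r_test)
    return summary_dict
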