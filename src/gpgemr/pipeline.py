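"""End-to-end orchestration of the synthetic drug-repurposing pipeline.

Chains the stages the way the study runs them: simulate (or load) inputs,
compute per-tissue TWAS associations for the outcome and for each drug's
primary indication, gate outcome hits at the Bonferroni threshold, derive
gene risk directions, map and filter drug-gene pairs, and evaluate each
surviving pair by mechanism-harmonized tissue MR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import defaults
from .drugmr import EmptyInstruments, evaluate_drug_target, summarize_drug_mr
from .drugs import (
    annotate_hepatotoxicity,
    apply_exclusions,
    concordance_filter,
    gene_directions_from_gpge,
    map_drug_gene_pairs,
)
from .simulate import SimulationConfig, simulate_drug_catalog, simulate_expression_models, simulate_ld_panel, simulate_trait_gwas
from .twas import gpge_associate, significant_gpge

logger = logging.getLogger(__name__)

OUTCOME_TRAIT = "outcome"


@dataclass
class PipelineResult:
    gpge_outcome: list = field(default_factory=list)
    gpge_indication: dict = field(default_factory=dict)  # indication -> [GPGEResult]
    significant_outcome: list = field(default_factory=list)
    directions: list = field(default_factory=list)
    ambiguous_genes: list = field(default_factory=list)
    pairs: list = field(default_factory=list)
    removed: list = field(default_factory=list)
    drug_mr: list = field(default_factory=list)
    untestable: list = field(default_factory=list)
    report: pd.DataFrame = field(default_factory=pd.DataFrame)


def run_synthetic_pipeline(
    config: SimulationConfig,
    catalogue: pd.DataFrame | None = None,
    bonferroni: float = defaults.GPGE_BONFERRONI,
    instrument_p: float = defaults.INSTRUMENT_P_THRESHOLD,
    het_alpha: float = defaults.HETEROGENEITY_ALPHA,
    livertox: pd.DataFrame | None = None,
    dilirank: pd.DataFrame | None = None,
) -> PipelineResult:
    """Run the whole pipeline on one synthetic cohort.

    ``config.expr_trait_effect`` must contain the key ``"outcome"``; every
    other key is treated as a drug primary indication. The catalogue's
    ``indication`` labels select which indication GWAS proxies each drug;
    by default a catalogue is simulated over the significant genes.
    """
    if OUTCOME_TRAIT not in config.expr_trait_effect:
        raise ValueError("config.expr_trait_effect must define the 'outcome' trait")

    panel = simulate_ld_panel(config)
    models, truth = simulate_expression_models(config, panel)

    res = PipelineResult()
    traits = {t: dict(config.expr_trait_effect[t]) for t in config.expr_trait_effect}
    sumstats = {}
    for trait_id in traits:
        records, _ = simulate_trait_gwas(config, panel, models, trait_id)
        sumstats[trait_id] = {r.variant.id: r for r in records}

    for trait_id, stats_map in sumstats.items():
        results = []
        for m in models:
            r = gpge_associate(m, stats_map, panel.ld)
            if r is not None:
                results.append(r)
        if trait_id == OUTCOME_TRAIT:
            res.gpge_outcome = results
        else:
            res.gpge_indication[trait_id] = results

    res.significant_outcome = significant_gpge(res.gpge_outcome, bonferroni)
    res.directions, res.ambiguous_genes = gene_directions_from_gpge(res.significant_outcome)

    if catalogue is None:
        catalogue = simulate_drug_catalog([d.gene for d in res.directions], seed=config.seed)
    pairs = map_drug_gene_pairs(res.directions, catalogue)
    pairs, removed_disc = concordance_filter(pairs, res.directions)
    pairs, removed_excl = apply_exclusions(pairs)
    pairs = annotate_hepatotoxicity(pairs, livertox, dilirank)
    res.pairs = pairs
    res.removed = removed_disc + removed_excl

    for pair in pairs:
        gpge_ind = res.gpge_indication.get(pair.primary_indication)
        if gpge_ind is None:
            res.untestable.append((pair.drug_name, pair.gene, "no indication GWAS"))
            continue
        try:
            res.drug_mr.append(
                evaluate_drug_target(pair, gpge_ind, res.gpge_outcome, instrument_p, het_alpha)
            )
        except EmptyInstruments as exc:
            logger.info("%s", exc)
            res.untestable.append((pair.drug_name, pair.gene, "no qualifying tissue instrument"))
    res.report = summarize_drug_mr(res.drug_mr)
    return res
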