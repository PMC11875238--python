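"""Summary-statistic TWAS: association of genetically predicted expression.

Given a sparse per-gene weight vector ``w`` over cis variants, GWAS marginal
effects ``beta_l`` with standard errors, and reference LD, the gene-level
z-score is

    Z_g = sum_l w_l * (sigma_l / sigma_g) * (beta_l / se_l)

with ``sigma_g^2 = w' Sigma w`` the variance of the predicted expression
score under the reference LD (Sigma_lm = sigma_l sigma_m r_lm), and the
effect of one SD of predicted expression on the trait

    effect = sum_l w_l * (sigma_l^2 / sigma_g^2) * beta_l,    se = effect / Z_g.

p-values are computed and stored in log10 space; strong loci reach values
far below float64 underflow.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._stats import log10_pvalue_from_z
from .sumstats import AssociationRecord, HarmonizationDrop, LDMatrix, Variant, harmonize_alleles

logger = logging.getLogger(__name__)


class DegenerateModelError(ValueError):
    """The prediction model has zero variance under the reference LD."""


@dataclass(frozen=True)
class ModelWeight:
    """One variant's expression-prediction weight with allele orientation."""

    variant_id: str
    weight: float
    effect_allele: str
    other_allele: str


@dataclass
class ExpressionModel:
    """Per gene x tissue sparse prediction-weight vector over cis variants."""

    gene: str
    tissue: str
    weights: dict[str, ModelWeight]
    cis_region: tuple[str, int, int]

    def __post_init__(self) -> None:
        if not any(w.weight != 0 for w in self.weights.values()):
            raise ValueError(f"{self.gene}/{self.tissue}: model needs >= 1 nonzero weight")

    @property
    def variant_ids(self) -> list[str]:
        return list(self.weights)


@dataclass(frozen=True)
class GPGEResult:
    """Gene x tissue x trait predicted-expression association."""

    gene: str
    tissue: str
    trait_id: str
    zscore: float
    effect_per_sd: float
    se: float
    log10_pvalue: float
    n_variants_used: int
    sigma_g: float

    @property
    def pvalue(self) -> float:
        """Linear-scale p (underflows to 0 below ~1e-308; use log10_pvalue)."""
        return 10.0 ** self.log10_pvalue


def predicted_expression_sd(model: ExpressionModel, ld: LDMatrix) -> float:
    """SD of the weighted genotype score under reference LD: sqrt(w' Sigma w)."""
    missing = [v for v in model.weights if v not in ld]
    if missing:
        raise KeyError(f"model variants missing from LD: {', '.join(missing)}")
    ids = model.variant_ids
    idx = [ld.index_of(v) for v in ids]
    w = np.array([model.weights[v].weight for v in ids])
    sd = ld.sd[idx]
    sigma = ld.r[np.ix_(idx, idx)] * np.outer(sd, sd)
    var = float(w @ sigma @ w)
    if var <= 0 or math.sqrt(var) == 0.0:
        raise DegenerateModelError(f"{model.gene}/{model.tissue}: predicted expression has zero variance")
    return math.sqrt(var)


def gpge_associate(
    model: ExpressionModel,
    sumstats: Mapping[str, AssociationRecord] | Iterable[AssociationRecord],
    ld: LDMatrix,
) -> GPGEResult | None:
    """Gene-level association of predicted expression with a trait.

    Sumstat records are harmonized to the model's allele orientation;
    model variants without a usable GWAS record are dropped from the sums
    (weights are not renormalized — ``n_variants_used`` reports coverage).
    Returns None when no model variant has a harmonized record.
    """
    if not isinstance(sumstats, Mapping):
        sumstats = {r.variant.id: r for r in sumstats}
    sigma_g = predicted_expression_sd(model, ld)

    used: list[tuple[float, float, float, float]] = []  # w, sigma_l, beta, se
    trait_id = None
    for vid, mw in model.weights.items():
        rec = sumstats.get(vid)
        if rec is None:
            logger.debug("%s/%s: variant %s absent from sumstats", model.gene, model.tissue, vid)
            continue
        ref = Variant(vid, rec.variant.chromosome, rec.variant.position, mw.effect_allele, mw.other_allele)
        harm = harmonize_alleles(rec, ref)
        if isinstance(harm, HarmonizationDrop):
            logger.debug("%s/%s: variant %s dropped (%s)", model.gene, model.tissue, vid, harm.reason)
            continue
        trait_id = harm.trait_id
        used.append((mw.weight, ld.sd[ld.index_of(vid)], harm.beta, harm.se))
    if not used:
        return None

    w, sig_l, beta, se = (np.array(col) for col in zip(*used))
    z = float(np.sum(w * (sig_l / sigma_g) * (beta / se)))
    effect = float(np.sum(w * (sig_l**2 / sigma_g**2) * beta))
    se_eff = effect / z if z != 0 else float("nan")
    return GPGEResult(
        gene=model.gene,
        tissue=model.tissue,
        trait_id=trait_id,
        zscore=z,
        effect_per_sd=effect,
        se=abs(se_eff) if np.isfinite(se_eff) else float("nan"),
        log10_pvalue=float(log10_pvalue_from_z(z)),
        n_variants_used=len(used),
        sigma_g=sigma_g,
    )


def significant_gpge(results: Iterable[GPGEResult], alpha_bonferroni: float) -> list[GPGEResult]:
    """Results with p strictly below the Bonferroni threshold, best first."""
    if not (0 < alpha_bonferroni < 1):
        raise ValueError("threshold must be in (0,1)")
    log10_alpha = math.log10(alpha_bonferroni)
    hits = [r for r in results if r.log10_pvalue < log10_alpha]
    return sorted(hits, key=lambda r: r.log10_pvalue)


# ---------------------------------------------------------------------------
# Weight-table I/O: TSV `gene tissue variant_id effect_allele other_allele weight`


def read_weight_models(path) -> list[ExpressionModel]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    models: list[ExpressionModel] = []
    for (gene, tissue), grp in df.groupby(["gene", "tissue"], sort=True):
        weights = {
            row.variant_id: ModelWeight(row.variant_id, float(row.weight), row.effect_allele, row.other_allele)
            for row in grp.itertuples(index=False)
        }
        region = (str(grp.chrom.iloc[0]), int(grp.cis_start.iloc[0]), int(grp.cis_end.iloc[0]))
        models.append(ExpressionModel(gene=gene, tissue=tissue, weights=weights, cis_region=region))
    return models


def write_weight_models(models: Sequence[ExpressionModel], path) -> None:
    rows = []
    for m in models:
        chrom, start, end = m.cis_region
        for mw in m.weights.values():
            rows.append(
                {
                    "gene": m.gene,
                    "tissue": m.tissue,
                    "variant_id": mw.variant_id,
                    "effect_allele": mw.effect_allele,
                    "other_allele": mw.other_allele,
                    "weight": repr(mw.weight),
                    "chrom": chrom,
                    "cis_start": start,
                    "cis_end": end,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def gpge_results_frame(results: Iterable[GPGEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "tissue": r.tissue,
                "trait_id": r.trait_id,
                "zscore": r.zscore,
                "effect_per_sd": r.effect_per_sd,
                "se": r.se,
                "log10_pvalue": r.log10_pvalue,
                "n_variants_used": r.n_variants_used,
                "sigma_g": r.sigma_g,
            }
            for r in results
        ]
    )
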