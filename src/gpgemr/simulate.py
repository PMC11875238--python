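"""Synthetic cohorts with known ground truth for every pipeline stage.

The generator emulates the shape of the study's inputs — a reference LD
panel, sparse expression-prediction weights shared across tissues, two-trait
GWAS summary statistics with configurable true expression->trait effects and
optional direct (pleiotropic) variant effects, and a drug-gene catalogue —
so that TWAS, colocalization, MR and the drug rules can all be tested for
parameter recovery without any restricted data.

Genotypes come from a Gaussian AR(1) copula: each haplotype is a latent
AR(1) Gaussian thresholded at the normal quantile of the variant's MAF, and
the dosage is the sum of two independent haplotypes. Adjacent-variant LD
rises with ``ld_rho`` and the chain restarts at each gene's cis block, so
genes are unlinked. Traits are generated as

    y = sum_g theta_g * standardize(X w_g) + X alpha + N(0, 1)

with ``w_g`` the gene's causal-tissue weight vector and ``alpha`` i.i.d.
N(0, pleiotropy_sd) direct effects; per-variant marginal least squares then
yields the summary statistics, with exact standard errors from the residual
variance.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import log10_pvalue_from_z
from .sumstats import AssociationRecord, LDMatrix, Variant, ld_from_genotypes
from .twas import ExpressionModel, ModelWeight

# non-palindromic allele pairs only, so harmonization is lossless downstream
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]

_POS_SPACING = 5_000  # bp between simulated variants


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults give a small multi-gene cohort."""

    n_individuals: int = 10_000
    n_variants: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.5
    n_genes: int = 10
    n_tissues: int = 5
    weights_per_gene: int = 3
    tissue_sharing: float = 0.7
    expr_trait_effect: dict[str, dict[str, float]] = field(default_factory=dict)
    pleiotropy_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_individuals", "n_variants", "n_genes", "n_tissues"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be ordered within (0, 0.5]")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must be in [0,1)")
        if not (0 <= self.tissue_sharing <= 1):
            raise ValueError("tissue_sharing must be in [0,1]")
        if self.pleiotropy_sd < 0:
            raise ValueError("pleiotropy_sd must be >= 0")
        if self.weights_per_gene <= 0:
            raise ValueError("weights_per_gene must be positive")
        if self.n_variants // self.n_genes < self.weights_per_gene:
            raise ValueError("weights_per_gene exceeds variants per gene cis block")

    @property
    def block_size(self) -> int:
        return self.n_variants // self.n_genes

    def gene_names(self) -> list[str]:
        return [f"G{i:03d}" for i in range(self.n_genes)]

    def tissue_names(self) -> list[str]:
        return [f"tissue_{i:02d}" for i in range(self.n_tissues)]

    def gene_block(self, g: int) -> np.ndarray:
        """Variant indices of gene g's cis block."""
        start = g * self.block_size
        end = start + self.block_size if g < self.n_genes - 1 else self.n_variants
        return np.arange(start, end)


@dataclass
class SimulatedPanel:
    """Genotype dosages with their variant metadata and empirical LD."""

    genotypes: np.ndarray  # individuals x variants, float32 dosages in {0,1,2}
    variants: list[Variant]
    maf: np.ndarray
    ld: LDMatrix

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]


@dataclass
class GroundTruth:
    """Generative parameters, serialized alongside every synthetic output."""

    seed: int
    causal_variants: dict = field(default_factory=dict)  # gene -> tissue -> [variant_id]
    true_weights: dict = field(default_factory=dict)  # gene -> tissue -> {variant_id: w}
    expr_trait_effect: dict = field(default_factory=dict)  # trait -> gene -> theta
    direct_effects: dict = field(default_factory=dict)  # trait -> {variant_id: alpha}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, sort_keys=True)


def _trait_rng(seed: int, trait_id: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(trait_id.encode()) & 0x7FFFFFFF])


def simulate_ld_panel(config: SimulationConfig) -> SimulatedPanel:
    """Draw a genotype panel under the AR(1) copula; deterministic in seed."""
    rng = np.random.default_rng([config.seed, 1])
    n, m = config.n_individuals, config.n_variants
    maf = rng.uniform(*config.maf_range, size=m)
    thresh = stats.norm.ppf(maf).astype(np.float32)

    block_starts = {config.gene_block(g)[0] for g in range(config.n_genes)}
    rho = np.float32(config.ld_rho)
    innov_sd = np.float32(np.sqrt(1.0 - config.ld_rho**2))

    dosage = np.empty((n, m), dtype=np.float32)
    for hap in range(2):
        latent = rng.standard_normal((n, m), dtype=np.float32)
        for j in range(1, m):
            if j in block_starts:
                continue  # LD chain restarts at each gene's cis block
            latent[:, j] = rho * latent[:, j - 1] + innov_sd * latent[:, j]
        alleles = (latent < thresh).astype(np.float32)
        if hap == 0:
            dosage[:] = alleles
        else:
            dosage += alleles

    # guard against monomorphic columns at small n (negligible at n >= 1000)
    sd = dosage.std(axis=0)
    for j in np.where(sd == 0)[0]:
        i = int(rng.integers(n))
        dosage[i, j] = 1.0 if dosage[i, j] != 1.0 else 0.0

    pair_idx = rng.integers(len(_ALLELE_PAIRS), size=m)
    variants = [
        Variant(
            id=f"rs{j:05d}",
            chromosome="1",
            position=1 + j * _POS_SPACING,
            effect_allele=_ALLELE_PAIRS[pair_idx[j]][0],
            other_allele=_ALLELE_PAIRS[pair_idx[j]][1],
        )
        for j in range(m)
    ]
    ld = ld_from_genotypes(dosage, [v.id for v in variants])
    return SimulatedPanel(genotypes=dosage, variants=variants, maf=maf, ld=ld)


def simulate_expression_models(
    config: SimulationConfig, panel: SimulatedPanel
) -> tuple[list[ExpressionModel], GroundTruth]:
    """Sparse per-gene, per-tissue weight vectors with tunable tissue sharing.

    Tissue 0 is the causal tissue whose weights define the genetic component
    of expression used by :func:`simulate_trait_gwas`; other tissues reuse
    each of its causal variants with probability ``tissue_sharing`` and
    otherwise pick a fresh cis variant. A shared causal variant's weight is
    redrawn in magnitude but keeps the causal tissue's sign — cross-tissue
    eQTLs are overwhelmingly direction-concordant in real data, and the
    per-gene risk direction downstream is only meaningful under that
    concordance.
    """
    rng = np.random.default_rng([config.seed, 2])
    truth = GroundTruth(seed=config.seed)
    models: list[ExpressionModel] = []
    genes, tissues = config.gene_names(), config.tissue_names()
    for g, gene in enumerate(genes):
        block = config.gene_block(g)
        base = rng.choice(block, size=config.weights_per_gene, replace=False)
        base_weights = rng.standard_normal(config.weights_per_gene)
        chrom = panel.variants[block[0]].chromosome
        region = (chrom, panel.variants[block[0]].position, panel.variants[block[-1]].position)
        truth.causal_variants[gene] = {}
        truth.true_weights[gene] = {}
        for t, tissue in enumerate(tissues):
            if t == 0:
                causal = base.copy()
                w = base_weights.copy()
            else:
                causal = []
                w = []
                available = [j for j in block if j not in base]
                rng.shuffle(available)
                for j, wj in zip(base, base_weights):
                    if rng.random() < config.tissue_sharing or not available:
                        causal.append(j)
                        w.append(np.sign(wj) * abs(rng.standard_normal()))
                    else:
                        causal.append(available.pop())
                        w.append(rng.standard_normal())
                causal = np.array(causal)
                w = np.array(w)
            weights = {}
            for j, wj in zip(causal, w):
                v = panel.variants[j]
                weights[v.id] = ModelWeight(v.id, float(wj), v.effect_allele, v.other_allele)
            models.append(ExpressionModel(gene=gene, tissue=tissue, weights=weights, cis_region=region))
            truth.causal_variants[gene][tissue] = [panel.variants[j].id for j in causal]
            truth.true_weights[gene][tissue] = {panel.variants[j].id: float(wj) for j, wj in zip(causal, w)}
    return models, truth


def genetic_expression_scores(
    config: SimulationConfig, panel: SimulatedPanel, models: Sequence[ExpressionModel]
) -> dict[str, np.ndarray]:
    """Standardized causal-tissue genetic expression score per gene."""
    causal_tissue = config.tissue_names()[0]
    idx = {v: i for i, v in enumerate(panel.variant_ids)}
    scores: dict[str, np.ndarray] = {}
    for m in models:
        if m.tissue != causal_tissue:
            continue
        cols = [idx[v] for v in m.weights]
        w = np.array([m.weights[v].weight for v in m.weights], dtype=np.float32)
        s = panel.genotypes[:, cols] @ w
        sd = s.std()
        scores[m.gene] = ((s - s.mean()) / sd if sd > 0 else s - s.mean()).astype(np.float64)
    return scores


def _marginal_gwas(genotypes: np.ndarray, y: np.ndarray, block: int = 256):
    """Per-variant OLS slope, exact se, z; vectorized over variant blocks."""
    n, m = genotypes.shape
    yc = y - y.mean()
    syy = float(yc @ yc)
    beta = np.empty(m)
    se = np.empty(m)
    for start in range(0, m, block):
        gb = genotypes[:, start : start + block].astype(np.float64)
        gb -= gb.mean(axis=0)
        sxx = np.einsum("ij,ij->j", gb, gb)
        sxy = gb.T @ yc
        b = sxy / sxx
        rss = syy - b * sxy
        sigma2 = rss / (n - 2)
        beta[start : start + block] = b
        se[start : start + block] = np.sqrt(sigma2 / sxx)
    z = beta / se
    return beta, se, z


def trait_phenotype(
    config: SimulationConfig,
    panel: SimulatedPanel,
    models: Sequence[ExpressionModel],
    trait_id: str,
) -> tuple[np.ndarray, dict[str, float]]:
    """Individual-level phenotype vector for a configured trait.

    Deterministic in (seed, trait_id); returns (y, direct_effects). Exposed
    so individual-level oracles can regress on exactly the phenotype behind
    the summary statistics.
    """
    if trait_id not in config.expr_trait_effect:
        raise ValueError(f"unknown trait_id {trait_id!r}: not in expr_trait_effect")
    effects = config.expr_trait_effect[trait_id]
    unknown = set(effects) - set(config.gene_names())
    if unknown:
        raise ValueError(f"expr_trait_effect names unknown genes: {sorted(unknown)}")

    rng = _trait_rng(config.seed, trait_id)
    scores = genetic_expression_scores(config, panel, models)
    y = rng.standard_normal(config.n_individuals)
    for gene, theta in effects.items():
        y += theta * scores[gene]
    direct: dict[str, float] = {}
    if config.pleiotropy_sd > 0:
        alpha = rng.normal(0.0, config.pleiotropy_sd, size=config.n_variants)
        y += panel.genotypes.astype(np.float64) @ alpha
        direct = {v.id: float(a) for v, a in zip(panel.variants, alpha)}
    return y, direct


def simulate_trait_gwas(
    config: SimulationConfig,
    panel: SimulatedPanel,
    models: Sequence[ExpressionModel],
    trait_id: str,
) -> tuple[list[AssociationRecord], GroundTruth]:
    """Marginal GWAS summary statistics for one trait of the configured pair.

    ``trait_id`` must be a key of ``config.expr_trait_effect`` (an empty
    effect map means a null trait is still allowed if the key is present).
    """
    effects = config.expr_trait_effect.get(trait_id, {})
    y, direct = trait_phenotype(config, panel, models, trait_id)
    beta, se, z = _marginal_gwas(panel.genotypes, y)
    log10p = log10_pvalue_from_z(z)
    records = [
        AssociationRecord(
            variant=panel.variants[j],
            beta=float(beta[j]),
            se=float(se[j]),
            pvalue=float(max(10.0 ** log10p[j], 5e-324)),
            log10_pvalue=float(log10p[j]),
            trait_id=trait_id,
            eaf=float(panel.maf[j]),
            n=config.n_individuals,
        )
        for j in range(config.n_variants)
    ]
    truth = GroundTruth(
        seed=config.seed,
        expr_trait_effect={trait_id: dict(effects)},
        direct_effects={trait_id: direct},
    )
    return records, truth


def simulate_drug_catalog(
    genes: Sequence[str],
    seed: int,
    drugs_per_gene: tuple[int, int] = (1, 3),
    oncology_fraction: float = 0.15,
) -> pd.DataFrame:
    """Toy drug-gene catalogue mimicking a curated interaction database.

    Each gene receives 1-3 drugs with a mechanism (agonist/inhibitor), a
    primary-indication label, an oncology flag, and an optional LiverTox-like
    hepatotoxicity class.
    """
    if len(genes) == 0:
        raise ValueError("gene list must be non-empty")
    rng = np.random.default_rng([seed, 4])
    indications = ["hypertension", "type2_diabetes", "hyperlipidemia", "depression", "asthma", "oncology"]
    rows = []
    counter = 0
    for gene in genes:
        for _ in range(int(rng.integers(drugs_per_gene[0], drugs_per_gene[1] + 1))):
            oncology = bool(rng.random() < oncology_fraction)
            indication = "oncology" if oncology else indications[int(rng.integers(len(indications) - 1))]
            rows.append(
                {
                    "drug_name": f"drug_{counter:03d}",
                    "gene": gene,
                    "mechanism": ["agonist", "inhibitor"][int(rng.integers(2))],
                    "indication": indication,
                    "oncology": oncology,
                    "livertox_class": ["A", "B", "C", "none"][int(rng.integers(4))],
                }
            )
            counter += 1
    return pd.DataFrame(rows)
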