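"""Parameter-recovery and calibration experiments on synthetic data.

Each function runs one self-contained experiment against the package's own
synthetic generator (or a direct summary-level generative model where that
is the natural scale) and returns the measured quantity. They serve as the
package's validation battery: oracle agreement for the TWAS statistic,
enumeration checks for colocalization, recovery and calibration for the MR
stages, and exactness for the drug rule engine.

All randomness flows from the single ``seed`` argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .cismr import EmptyInstrumentSet, bh_fdr, mr_ivw_correlated, select_cis_instruments
from .coloc import ColocPriors, coloc_abf, coloc_abf_enumerate, log_abf
from .drugmr import TissueInstrument, cochran_q, harmonize_by_mechanism, mr_egger_tissue, mr_ivw_tissue
from .drugs import GeneDirection, apply_exclusions, concordance_filter, map_drug_gene_pairs
from .pipeline import run_synthetic_pipeline
from .simulate import (
    SimulationConfig,
    simulate_expression_models,
    simulate_ld_panel,
    simulate_trait_gwas,
    trait_phenotype,
)
from .sumstats import AssociationRecord, Variant
from .twas import gpge_associate


# ---------------------------------------------------------------------------
# TWAS: summary-statistic z vs individual-level predicted-expression regression


def twas_oracle_correlation(
    seed: int,
    n_genes: int = 50,
    n_individuals: int = 50_000,
    n_variants: int = 2_000,
) -> tuple[float, int]:
    """Correlation between summary-stat TWAS z and the individual-level z.

    One cohort, ``n_genes`` genes with true per-SD expression effects spread
    over [-0.3, 0.3]; for each gene the oracle regresses the phenotype on
    the explicitly computed predicted-expression score.
    """
    effects = {f"G{i:03d}": float(e) for i, e in enumerate(np.linspace(-0.3, 0.3, n_genes))}
    cfg = SimulationConfig(
        n_individuals=n_individuals,
        n_variants=n_variants,
        n_genes=n_genes,
        n_tissues=1,
        weights_per_gene=5,
        ld_rho=0.5,
        expr_trait_effect={"outcome": effects},
        seed=seed,
    )
    panel = simulate_ld_panel(cfg)
    models, _ = simulate_expression_models(cfg, panel)
    records, _ = simulate_trait_gwas(cfg, panel, models, "outcome")
    recmap = {r.variant.id: r for r in records}
    y, _ = trait_phenotype(cfg, panel, models, "outcome")
    yc = y - y.mean()
    idx = {v.id: i for i, v in enumerate(panel.variants)}

    z_summary, z_individual = [], []
    for m in models:
        cols = [idx[v] for v in m.weights]
        w = np.array([mw.weight for mw in m.weights.values()])
        score = panel.genotypes[:, cols].astype(float) @ w
        sc = score - score.mean()
        b = (sc @ yc) / (sc @ sc)
        rss = yc @ yc - b * (sc @ yc)
        se = np.sqrt(rss / (len(y) - 2) / (sc @ sc))
        z_individual.append(b / se)
        z_summary.append(gpge_associate(m, recmap, panel.ld).zscore)
    corr = float(np.corrcoef(z_summary, z_individual)[0, 1])
    return corr, n_genes


# ---------------------------------------------------------------------------
# Colocalization


def coloc_enumeration_errors(seed: int, n_loci: int = 200, max_variants: int = 12) -> tuple[float, float]:
    """Vectorized posteriors vs brute-force enumeration on random small loci.

    Returns (max absolute posterior difference, max |sum(PP) - 1|).
    """
    rng = np.random.default_rng([seed, 10])
    priors = ColocPriors()
    max_diff = 0.0
    max_sum_err = 0.0
    for _ in range(n_loci):
        m = int(rng.integers(1, max_variants + 1))
        se_a = rng.uniform(0.02, 0.1)
        se_b = rng.uniform(0.02, 0.1)
        za = rng.normal(0, 3, m)
        zb = rng.normal(0, 3, m)
        rec_a = _records_from_z(za, se_a, "a")
        rec_b = _records_from_z(zb, se_b, "b")
        fast = coloc_abf(rec_a, rec_b, priors, "quant", "cc")
        la = np.array([log_abf(z * se_a, se_a, priors.prior_effect_sd_quant) for z in za])
        lb = np.array([log_abf(z * se_b, se_b, priors.prior_effect_sd_cc) for z in zb])
        slow = coloc_abf_enumerate(la, lb, priors)
        max_diff = max(max_diff, float(np.max(np.abs(fast.posteriors - slow.posteriors))))
        max_sum_err = max(max_sum_err, abs(float(fast.posteriors.sum()) - 1.0))
    return max_diff, max_sum_err


def _records_from_z(zs, se, trait, positions=None):
    out = []
    for i, z in enumerate(zs):
        pos = 1000 + i if positions is None else positions[i]
        v = Variant(f"v{i:04d}", "1", pos, "A", "G")
        zz = float(z)
        pval = float(max(2 * stats.norm.sf(abs(zz)), 5e-324))
        out.append(AssociationRecord(v, beta=zz * se, se=se, pvalue=pval, trait_id=trait, eaf=0.3))
    return out


def coloc_discrimination(
    seed: int, n_reps: int = 100, n_variants: int = 100, z_causal: float = 10.0, rho: float = 0.9
) -> tuple[float, float]:
    """Shared- vs distinct-causal discrimination rates under AR(1) LD.

    z-scores are drawn from N(R e_c z, R) with R the AR(1) correlation
    matrix — the standard distribution of marginal GWAS z-scores around a
    single causal variant. Returns (P[PP.H4 > 0.8 | shared],
    P[PP.H3 > PP.H4 | distinct]).
    """
    rng = np.random.default_rng([seed, 11])
    idx = np.arange(n_variants)
    corr = rho ** np.abs(idx[:, None] - idx[None, :])
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(n_variants))
    se = 0.02

    def draw(causal: int) -> np.ndarray:
        lam = corr[:, causal] * z_causal
        return lam + chol @ rng.standard_normal(n_variants)

    shared_hits = 0
    distinct_hits = 0
    for _ in range(n_reps):
        c = int(rng.integers(10, n_variants - 10))
        res = coloc_abf(_records_from_z(draw(c), se, "a"), _records_from_z(draw(c), se, "b"))
        shared_hits += res.pp_h4 > 0.8

        c1 = int(rng.integers(5, n_variants // 2 - 15))
        c2 = int(rng.integers(n_variants // 2 + 15, n_variants - 5))
        res = coloc_abf(_records_from_z(draw(c1), se, "a"), _records_from_z(draw(c2), se, "b"))
        distinct_hits += res.pp_h3 > res.pp_h4
    return shared_hits / n_reps, distinct_hits / n_reps


# ---------------------------------------------------------------------------
# cis-MR parameter recovery and calibration


def _cis_mr_once(theta: float, seed: int, n_individuals: int) -> tuple[float, float]:
    """One synthetic protein -> outcome MR; returns (estimate, p-value).

    The exposure trait carries the gene's standardized genetic score with
    coefficient 1 (a noisy 'protein'), the outcome with coefficient theta,
    so the MR slope's estimand is exactly theta.
    """
    cfg = SimulationConfig(
        n_individuals=n_individuals,
        n_variants=40,
        n_genes=1,
        n_tissues=1,
        weights_per_gene=3,
        ld_rho=0.5,
        expr_trait_effect={"protein": {"G000": 1.0}, "outcome": {"G000": theta}},
        seed=seed,
    )
    panel = simulate_ld_panel(cfg)
    models, _ = simulate_expression_models(cfg, panel)
    exposure, _ = simulate_trait_gwas(cfg, panel, models, "protein")
    outcome, _ = simulate_trait_gwas(cfg, panel, models, "outcome")
    region = ("1", panel.variants[0].position, panel.variants[-1].position)
    inst = select_cis_instruments(exposure, outcome, region, panel.ld, target_id="G000")
    est = mr_ivw_correlated(inst)
    return est.beta_mr, est.pvalue


def cismr_recovery(seed: int, thetas=(-0.3, 0.0, 0.3), n_seeds: int = 50, n_individuals: int = 10_000):
    """Mean LD-aware IVW estimate per true effect over repeated cohorts."""
    rng = np.random.default_rng([seed, 12])
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_seeds)
    means = {}
    for theta in thetas:
        estimates = [_cis_mr_once(theta, int(s), n_individuals) [0] for s in sub_seeds]
        means[theta] = float(np.mean(estimates))
    return means


def cismr_type1_error(seed: int, n_reps: int = 400, n_individuals: int = 10_000, alpha: float = 0.05) -> float:
    """Empirical rejection rate of the MR test under a null outcome effect."""
    rng = np.random.default_rng([seed, 13])
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_reps)
    rejections = 0
    tested = 0
    for s in sub_seeds:
        try:
            _, p = _cis_mr_once(0.0, int(s), n_individuals)
        except EmptyInstrumentSet:
            continue
        tested += 1
        rejections += p < alpha
    return rejections / tested


# ---------------------------------------------------------------------------
# Proxied-drug MR end-to-end


def drugmr_end_to_end(
    seed: int,
    n_seeds: int = 50,
    theta_indication: float = 0.4,
    theta_outcome: float = -0.3,
    n_tissues: int = 10,
    n_individuals: int = 20_000,
) -> tuple[float, int]:
    """Pipeline recovery of the outcome-per-indication MR slope.

    True effects per SD expression: ``theta_indication`` on the drug's
    primary indication and ``theta_outcome`` on the disease outcome, so the
    estimand is theta_outcome / theta_indication. Returns (mean pipeline
    beta_mr over seeds, number of seeds that produced an estimate).
    """
    rng = np.random.default_rng([seed, 14])
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_seeds)
    catalogue = pd.DataFrame(
        [
            {
                "drug_name": "drugX",
                "gene": "G000",
                "mechanism": "agonist",
                "indication": "indication",
                "oncology": False,
            }
        ]
    )
    estimates = []
    for s in sub_seeds:
        cfg = SimulationConfig(
            n_individuals=n_individuals,
            n_variants=60,
            n_genes=1,
            n_tissues=n_tissues,
            weights_per_gene=3,
            tissue_sharing=0.7,
            ld_rho=0.5,
            expr_trait_effect={
                "outcome": {"G000": theta_outcome},
                "indication": {"G000": theta_indication},
            },
            seed=int(s),
        )
        res = run_synthetic_pipeline(cfg, catalogue=catalogue)
        if res.drug_mr:
            estimates.append(res.drug_mr[0].beta_mr)
    return float(np.mean(estimates)), len(estimates)


# ---------------------------------------------------------------------------
# Heterogeneity and pleiotropy calibration (tissue-instrument level)


def _instrument_batch(rng, k, theta, se_y, pleio_mean=0.0, pleio_sd=0.0):
    bx = rng.uniform(0.2, 1.0, size=k)
    alpha = rng.normal(pleio_mean, pleio_sd, size=k) if (pleio_mean or pleio_sd) else np.zeros(k)
    by = theta * bx + alpha + rng.normal(0, se_y, size=k)
    return [
        TissueInstrument("G", f"t{i}", float(bx[i]), 0.01, 0.01, float(by[i]), se_y)
        for i in range(k)
    ]


def q_uniformity_ks(seed: int, n_seeds: int = 500, k: int = 10, theta: float = -0.75, se_y: float = 0.05) -> float:
    """KS p-value of Cochran-Q p-values against Uniform(0,1) under homogeneity."""
    rng = np.random.default_rng([seed, 15])
    pvals = []
    for _ in range(n_seeds):
        ins = _instrument_batch(rng, k, theta, se_y)
        beta, _ = mr_ivw_tissue(ins)
        pvals.append(cochran_q(ins, beta).pvalue)
    return float(stats.kstest(pvals, "uniform").pvalue)


def egger_calibration(
    seed: int,
    n_null: int = 500,
    n_alt: int = 100,
    k: int = 20,
    theta: float = -0.75,
    se_y: float = 0.05,
    pleio_mean: float = 0.2,
    pleio_sd: float = 0.05,
) -> tuple[float, float]:
    """Egger-intercept rejection rate without and with directional pleiotropy."""
    rng = np.random.default_rng([seed, 16])
    null_rej = sum(
        mr_egger_tissue(_instrument_batch(rng, k, theta, se_y)).intercept_p < 0.05 for _ in range(n_null)
    )
    alt_rej = sum(
        mr_egger_tissue(_instrument_batch(rng, k, theta, se_y, pleio_mean, pleio_sd)).intercept_p < 0.05
        for _ in range(n_alt)
    )
    return null_rej / n_null, alt_rej / n_alt


def mechanism_flip_invariance(seed: int, k: int = 5) -> float:
    """Max |beta_mr difference| between agonist and inhibitor harmonization."""
    rng = np.random.default_rng([seed, 17])
    ins = _instrument_batch(rng, k, -0.75, 0.05)
    beta_a, _ = mr_ivw_tissue(harmonize_by_mechanism(ins, "agonist"))
    beta_i, _ = mr_ivw_tissue(harmonize_by_mechanism(ins, "inhibitor"))
    return abs(beta_a - beta_i)


# ---------------------------------------------------------------------------
# BH-FDR empirical control


def bh_empirical_fdr(
    seed: int, n_mixtures: int = 200, m: int = 100, null_fraction: float = 0.6, q: float = 0.05
) -> float:
    """Mean false-discovery proportion of BH over simulated p-value mixtures."""
    rng = np.random.default_rng([seed, 18])
    n_null = int(m * null_fraction)
    fdps = []
    for _ in range(n_mixtures):
        p_null = rng.uniform(size=n_null)
        z_alt = rng.normal(3.0, 1.0, size=m - n_null)
        p_alt = 2 * stats.norm.sf(np.abs(z_alt))
        pvals = np.concatenate([p_null, p_alt])
        is_null = np.concatenate([np.ones(n_null, bool), np.zeros(m - n_null, bool)])
        reject = np.array(bh_fdr(np.clip(pvals, 1e-300, 1.0).tolist(), q))
        n_rej = reject.sum()
        fdps.append((reject & is_null).sum() / n_rej if n_rej else 0.0)
    return float(np.mean(fdps))


# ---------------------------------------------------------------------------
# Drug rule engine exactness


TOY_CATALOGUE_ROWS = [
    ("drugA", "GENE_UP", "inhibitor", "htn", False),
    ("drugB", "GENE_UP", "agonist", "htn", False),
    ("drugC", "GENE_DOWN", "agonist", "t2d", False),
    ("drugD", "GENE_DOWN", "inhibitor", "t2d", False),
    ("drugE", "GENE_UP", "inhibitor", "cancer", True),
    ("drugA", "GENE_UP", "inhibitor", "htn", False),
    ("drugA", "GENE_DOWN", "inhibitor", "htn", False),
    ("drugC", "GENE_DOWN", "agonist", "t2d", False),
]


def toy_catalogue_survivors() -> set[tuple[str, str]]:
    """The concordant, non-excluded pairs of the 8-row toy catalogue."""
    directions = [
        GeneDirection("GENE_UP", "risk_increasing", 3),
        GeneDirection("GENE_DOWN", "risk_decreasing", 3),
    ]
    cat = pd.DataFrame(TOY_CATALOGUE_ROWS, columns=["drug_name", "gene", "mechanism", "indication", "oncology"])
    pairs = map_drug_gene_pairs(directions, cat)
    pairs, _ = concordance_filter(pairs, directions)
    pairs, _ = apply_exclusions(pairs)
    return {(p.drug_name, p.gene) for p in pairs}
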