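"""Mechanism-harmonized drug-target MR over tissue-level TWAS instruments.

For each concordant drug-gene pair, the per-tissue TWAS associations of the
target gene with the drug's primary indication (exposure) and with the
disease outcome form one instrument per tissue. Instruments are harmonized
to the drug's mechanism of action — for an inhibitor both effects are
restated per one SD *decrease* in expression, a joint flip that leaves the
MR ratio invariant — then:

* the exposure changes are pooled by DerSimonian-Laird random-effects
  meta-analysis (the drug's predicted effect on its own indication);
* the effect on the outcome is estimated by fixed-effects IVW across
  tissues (Wald ratio when only one tissue qualifies);
* MR-Egger (>= 3 tissues) probes directional pleiotropy, Cochran's Q probes
  heterogeneity, and when Q rejects, standard errors are inflated
  multiplicatively by sqrt(Q / (k-1)) (random-effects IVW).

Treating tissues as independent instruments ignores their shared eQTL
architecture; this is an acknowledged approximation, reported per row.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from ._stats import log10_pvalue_from_z, pvalue_from_z
from .drugs import DrugGenePair
from .twas import GPGEResult

logger = logging.getLogger(__name__)

from .defaults import HETEROGENEITY_ALPHA, INSTRUMENT_P_THRESHOLD  # noqa: E402

EGGER_MIN_INSTRUMENTS = 3


class EmptyInstruments(Exception):
    """No tissue qualifies as an instrument for this gene."""


@dataclass(frozen=True)
class TissueInstrument:
    """One tissue's (indication, outcome) TWAS effect pair for a gene."""

    gene: str
    tissue: str
    beta_exposure: float
    se_exposure: float
    p_exposure: float
    beta_outcome: float
    se_outcome: float
    mechanism_flipped: bool = False

    def __post_init__(self) -> None:
        if self.se_exposure <= 0 or self.se_outcome <= 0:
            raise ValueError(f"{self.gene}/{self.tissue}: standard errors must be > 0")

    @property
    def wald(self) -> float:
        return self.beta_outcome / self.beta_exposure


@dataclass(frozen=True)
class EggerResult:
    intercept: float
    intercept_se: float
    intercept_p: float
    slope: float
    slope_se: float


@dataclass(frozen=True)
class QResult:
    q: float
    df: int
    pvalue: float


@dataclass
class DrugMRResult:
    """Pooled result for one (indication, gene, drug) row of the report."""

    gene: str
    drug: str
    primary_indication: str
    n_tissues: int
    pooled_exposure_change: float
    pooled_exposure_se: float
    tau2: float
    beta_mr: float
    se_mr: float
    pvalue: float
    log10_pvalue: float
    method: str  # "wald" | "ivw_fixed" | "ivw_random"
    q_stat: float | None = None
    q_pvalue: float | None = None
    egger_intercept: float | None = None
    egger_intercept_p: float | None = None

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta_mr)

    @property
    def ci95_or(self) -> tuple[float, float]:
        return (math.exp(self.beta_mr - 1.96 * self.se_mr), math.exp(self.beta_mr + 1.96 * self.se_mr))


def build_tissue_instruments(
    gene: str,
    gpge_indication: Sequence[GPGEResult],
    gpge_outcome: Sequence[GPGEResult],
    p_threshold: float = INSTRUMENT_P_THRESHOLD,
) -> list[TissueInstrument]:
    """One instrument per tissue with exposure p < threshold and an outcome hit."""
    log10_thr = math.log10(p_threshold)
    out_by_tissue = {r.tissue: r for r in gpge_outcome if r.gene == gene}
    instruments: list[TissueInstrument] = []
    for r in gpge_indication:
        if r.gene != gene:
            continue
        if not (r.log10_pvalue < log10_thr):
            logger.debug("%s/%s dropped: exposure p >= %g", gene, r.tissue, p_threshold)
            continue
        out = out_by_tissue.get(r.tissue)
        if out is None:
            logger.debug("%s/%s dropped: no outcome GPGE", gene, r.tissue)
            continue
        instruments.append(
            TissueInstrument(
                gene=gene,
                tissue=r.tissue,
                beta_exposure=r.effect_per_sd,
                se_exposure=r.se,
                p_exposure=r.pvalue,
                beta_outcome=out.effect_per_sd,
                se_outcome=out.se,
            )
        )
    if not instruments:
        raise EmptyInstruments(f"{gene}: no tissue passes the instrument p-threshold with outcome data")
    return instruments


def harmonize_by_mechanism(instruments: Sequence[TissueInstrument], mechanism: str) -> list[TissueInstrument]:
    """Orient instruments to the drug's direction of action.

    Inhibitors act like one SD *decrease* in expression, so both effects are
    negated jointly (the instrument is redefined; the MR ratio is invariant).
    Agonists pass through. Re-harmonizing flipped instruments is a no-op
    with a warning.
    """
    if mechanism not in ("agonist", "inhibitor"):
        raise ValueError(f"mechanism must be agonist or inhibitor, got {mechanism!r}")
    out = []
    for ins in instruments:
        if mechanism == "inhibitor" and not ins.mechanism_flipped:
            out.append(
                replace(
                    ins,
                    beta_exposure=-ins.beta_exposure,
                    beta_outcome=-ins.beta_outcome,
                    mechanism_flipped=True,
                )
            )
        else:
            if mechanism == "inhibitor":
                logger.warning("%s/%s already mechanism-harmonized; leaving unchanged", ins.gene, ins.tissue)
            out.append(ins)
    return out


def meta_exposure_dl(instruments: Sequence[TissueInstrument]) -> tuple[float, float, float]:
    """DerSimonian-Laird random-effects pooling of the exposure changes.

    Returns (pooled, se, tau2); k = 1 collapses to the single estimate.
    """
    if not instruments:
        raise ValueError("need >= 1 instrument")
    eff = np.array([i.beta_exposure for i in instruments])
    se = np.array([i.se_exposure for i in instruments])
    k = len(eff)
    w = 1.0 / se**2
    mu_fixed = float(np.sum(w * eff) / np.sum(w))
    if k == 1:
        return float(eff[0]), float(se[0]), 0.0
    q = float(np.sum(w * (eff - mu_fixed) ** 2))
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0
    w_star = 1.0 / (se**2 + tau2)
    pooled = float(np.sum(w_star * eff) / np.sum(w_star))
    pooled_se = float(np.sqrt(1.0 / np.sum(w_star)))
    return pooled, pooled_se, tau2


def _ivw_fixed(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> tuple[float, float]:
    w = bx**2 / sy**2
    beta = float(np.sum(bx * by / sy**2) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    return beta, se


def mr_ivw_tissue(instruments: Sequence[TissueInstrument]) -> tuple[float, float]:
    """Fixed-effects IVW across tissues (treated as independent instruments)."""
    if len(instruments) < 2:
        raise ValueError("mr_ivw_tissue needs >= 2 instruments; use the Wald path")
    bx = np.array([i.beta_exposure for i in instruments])
    by = np.array([i.beta_outcome for i in instruments])
    sy = np.array([i.se_outcome for i in instruments])
    return _ivw_fixed(bx, by, sy)


def mr_wald_single(instrument: TissueInstrument) -> tuple[float, float]:
    """Wald ratio with delta-method se for a single-tissue gene."""
    if instrument.beta_exposure == 0:
        raise ValueError("Wald ratio undefined for beta_exposure = 0")
    return (
        instrument.beta_outcome / instrument.beta_exposure,
        instrument.se_outcome / abs(instrument.beta_exposure),
    )


def mr_egger_tissue(instruments: Sequence[TissueInstrument]) -> EggerResult | None:
    """MR-Egger weighted regression; None below 3 instruments (report N/A).

    Exposure effects are oriented non-negative (outcome flipped jointly)
    before fitting b_y = a + b*b_x with weights 1/se_y^2; a nonzero
    intercept indicates directional pleiotropy.
    """
    if len(instruments) < EGGER_MIN_INSTRUMENTS:
        return None
    bx = np.array([i.beta_exposure for i in instruments])
    by = np.array([i.beta_outcome for i in instruments])
    sy = np.array([i.se_outcome for i in instruments])
    flip = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * flip, by * flip
    w = 1.0 / sy**2
    x = np.column_stack([np.ones_like(bx), bx])
    xtwx = x.T @ (w[:, None] * x)
    try:
        cov = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError:
        return None
    coef = cov @ (x.T @ (w * by))
    intercept, slope = float(coef[0]), float(coef[1])
    # scale covariance by the weighted residual mean square (classic Egger)
    resid = by - x @ coef
    df = len(bx) - 2
    sigma2 = float(np.sum(w * resid**2) / df) if df > 0 else 1.0
    sigma2 = max(sigma2, 1.0)  # never deflate below the fixed-effect model
    cov = cov * sigma2
    intercept_se = float(np.sqrt(cov[0, 0]))
    slope_se = float(np.sqrt(cov[1, 1]))
    intercept_p = float(pvalue_from_z(intercept / intercept_se))
    return EggerResult(intercept, intercept_se, intercept_p, slope, slope_se)


def cochran_q(instruments: Sequence[TissueInstrument], beta_ivw: float) -> QResult | None:
    """Heterogeneity of per-tissue Wald ratios around the IVW estimate."""
    if len(instruments) < 2:
        return None
    bx = np.array([i.beta_exposure for i in instruments])
    by = np.array([i.beta_outcome for i in instruments])
    sy = np.array([i.se_outcome for i in instruments])
    theta = by / bx
    w = bx**2 / sy**2
    q = float(np.sum(w * (theta - beta_ivw) ** 2))
    df = len(bx) - 1
    return QResult(q=q, df=df, pvalue=float(stats.chi2.sf(q, df)))


def mr_random_effects(beta: float, se_fixed: float, q_result: QResult) -> float:
    """Multiplicative random-effects se inflation: se * max(1, sqrt(Q/df))."""
    return se_fixed * max(1.0, math.sqrt(q_result.q / q_result.df))


def evaluate_drug_target(
    pair: DrugGenePair,
    gpge_indication: Sequence[GPGEResult],
    gpge_outcome: Sequence[GPGEResult],
    p_threshold: float = INSTRUMENT_P_THRESHOLD,
    het_alpha: float = HETEROGENEITY_ALPHA,
) -> DrugMRResult:
    """Full per-pair evaluation: instruments, harmonization, meta, MR, checks."""
    instruments = build_tissue_instruments(pair.gene, gpge_indication, gpge_outcome, p_threshold)
    instruments = harmonize_by_mechanism(instruments, pair.mechanism)
    pooled, pooled_se, tau2 = meta_exposure_dl(instruments)

    k = len(instruments)
    if k == 1:
        beta, se = mr_wald_single(instruments[0])
        method = "wald"
        q_res = None
    else:
        beta, se = mr_ivw_tissue(instruments)
        method = "ivw_fixed"
        q_res = cochran_q(instruments, beta)
        if q_res.pvalue < het_alpha:
            se = mr_random_effects(beta, se, q_res)
            method = "ivw_random"
    egger = mr_egger_tissue(instruments)
    z = beta / se
    return DrugMRResult(
        gene=pair.gene,
        drug=pair.drug_name,
        primary_indication=pair.primary_indication,
        n_tissues=k,
        pooled_exposure_change=pooled,
        pooled_exposure_se=pooled_se,
        tau2=tau2,
        beta_mr=beta,
        se_mr=se,
        pvalue=float(max(pvalue_from_z(z), 5e-324)),
        log10_pvalue=float(log10_pvalue_from_z(z)),
        method=method,
        q_stat=None if q_res is None else q_res.q,
        q_pvalue=None if q_res is None else q_res.pvalue,
        egger_intercept=None if egger is None else egger.intercept,
        egger_intercept_p=None if egger is None else egger.intercept_p,
    )


def summarize_drug_mr(results: Iterable[DrugMRResult]):
    """Report table: one row per (indication, gene, drug), OR scale.

    Rows estimated with random-effects IVW carry a footnote marker in the
    method column (standard errors inflated for significant heterogeneity).
    """
    import pandas as pd

    rows = []
    for r in results:
        lo, hi = r.ci95_or
        rows.append(
            {
                "primary_indication": r.primary_indication,
                "gene": r.gene,
                "drug": r.drug,
                "n_tissues": r.n_tissues,
                "pooled_exposure_change": r.pooled_exposure_change,
                "pooled_exposure_se": r.pooled_exposure_se,
                "ivw_or": r.odds_ratio,
                "or_ci95_low": lo,
                "or_ci95_high": hi,
                "pvalue": r.pvalue,
                "log10_pvalue": r.log10_pvalue,
                "egger_pvalue": "N/A" if r.egger_intercept_p is None else r.egger_intercept_p,
                "method": r.method + ("*" if r.method == "ivw_random" else ""),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(["primary_indication", "gene", "drug"]).reset_index(drop=True)
    return df
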