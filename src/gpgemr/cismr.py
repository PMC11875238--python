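"""cis-instrument Mendelian randomization with LD-aware IVW.

Instruments are cis variants of the exposure (protein or expression) GWAS
passing a genome-wide threshold inside a window around the encoding gene,
LD-pruned so residual correlation is small; the causal effect on the
outcome is estimated by generalized-least-squares IVW

    beta = (b_x' O^-1 b_x)^-1 b_x' O^-1 b_y,   O_ij = se_yi se_yj r_ij

which reduces to the textbook inverse-variance weighting when the LD matrix
is the identity, and to the Wald ratio for a single instrument. Discovery
across many targets is controlled at a given false discovery rate by
Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from ._stats import clip_psd, log10_pvalue_from_z, pvalue_from_z
from .sumstats import AssociationRecord, HarmonizationDrop, LDMatrix, greedy_ld_prune, harmonize_alleles

logger = logging.getLogger(__name__)

from .defaults import CIS_WINDOW_BP, FDR_Q, PQTL_P_THRESHOLD, R2_MAX  # noqa: E402


class EmptyInstrumentSet(Exception):
    """No variant survives instrument selection for this target."""


@dataclass
class InstrumentSet:
    """Aligned exposure/outcome records over LD-pruned cis instruments."""

    target_id: str
    records_exposure: list[AssociationRecord]
    records_outcome: list[AssociationRecord]
    ld_sub: LDMatrix

    def __post_init__(self) -> None:
        ids_x = [r.variant.id for r in self.records_exposure]
        ids_y = [r.variant.id for r in self.records_outcome]
        if ids_x != ids_y or ids_x != self.ld_sub.variant_ids:
            raise ValueError(f"{self.target_id}: exposure/outcome/LD variant order mismatch")

    @property
    def n_instruments(self) -> int:
        return len(self.records_exposure)


@dataclass(frozen=True)
class MREstimate:
    target_id: str
    beta_mr: float
    se: float
    pvalue: float
    log10_pvalue: float
    method: str  # "wald" | "ivw_correlated"
    n_instruments: int

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.beta_mr - 1.96 * self.se, self.beta_mr + 1.96 * self.se)


def _estimate(target_id: str, beta: float, se: float, method: str, k: int) -> MREstimate:
    z = beta / se
    return MREstimate(
        target_id=target_id,
        beta_mr=beta,
        se=se,
        pvalue=float(max(pvalue_from_z(z), 5e-324)),
        log10_pvalue=float(log10_pvalue_from_z(z)),
        method=method,
        n_instruments=k,
    )


def select_cis_instruments(
    exposure: Sequence[AssociationRecord],
    outcome: Sequence[AssociationRecord],
    gene_region: tuple[str, int, int],
    ld: LDMatrix,
    target_id: str = "",
    window_bp: int = CIS_WINDOW_BP,
    p_threshold: float = PQTL_P_THRESHOLD,
    r2_max: float = R2_MAX,
) -> InstrumentSet:
    """Build the LD-pruned cis instrument set and align outcome records.

    Exposure variants within ``gene_region`` +/- ``window_bp`` with
    p < ``p_threshold`` are greedily LD-pruned at ``r2_max``; outcome
    records are then attached by a harmonized join on the surviving
    variants. Raises :class:`EmptyInstrumentSet` when nothing survives.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    chrom, start, end = gene_region
    lo, hi = start - window_bp, end + window_bp
    candidates = [
        r
        for r in exposure
        if r.variant.chromosome == chrom and lo <= r.variant.position <= hi and r.pvalue < p_threshold
    ]
    if not candidates:
        raise EmptyInstrumentSet(f"{target_id}: no cis variant passes p < {p_threshold} in window")
    pruned = greedy_ld_prune(candidates, ld, r2_max)

    out_by_id = {r.variant.id: r for r in outcome}
    exp_kept, out_kept = [], []
    for rx in pruned:
        ry = out_by_id.get(rx.variant.id)
        if ry is None:
            logger.debug("%s: instrument %s missing from outcome GWAS", target_id, rx.variant.id)
            continue
        harm = harmonize_alleles(ry, rx.variant)
        if isinstance(harm, HarmonizationDrop):
            logger.debug("%s: instrument %s dropped (%s)", target_id, rx.variant.id, harm.reason)
            continue
        exp_kept.append(rx)
        out_kept.append(harm)
    if not exp_kept:
        raise EmptyInstrumentSet(f"{target_id}: no instrument with usable outcome record")
    ld_sub = ld.subset([r.variant.id for r in exp_kept])
    return InstrumentSet(target_id, exp_kept, out_kept, ld_sub)


def wald_ratio(beta_x: float, beta_y: float, se_y: float, target_id: str = "") -> MREstimate:
    """Single-instrument ratio estimate with first-order delta-method se."""
    if beta_x == 0:
        raise ValueError("wald_ratio requires beta_x != 0")
    return _estimate(target_id, beta_y / beta_x, se_y / abs(beta_x), "wald", 1)


def mr_ivw_correlated(instruments: InstrumentSet, ridge: float = 1e-8) -> MREstimate:
    """LD-aware IVW (GLS through the origin) over correlated instruments.

    With one instrument this contractually delegates to the Wald ratio.
    """
    k = instruments.n_instruments
    if k == 1:
        rx, ry = instruments.records_exposure[0], instruments.records_outcome[0]
        return wald_ratio(rx.beta, ry.beta, ry.se, instruments.target_id)
    bx = np.array([r.beta for r in instruments.records_exposure])
    by = np.array([r.beta for r in instruments.records_outcome])
    sy = np.array([r.se for r in instruments.records_outcome])
    omega = clip_psd(np.outer(sy, sy) * instruments.ld_sub.r)
    omega[np.diag_indices(k)] += ridge * np.diag(omega).mean()
    try:
        oi_bx = np.linalg.solve(omega, bx)
        oi_by = np.linalg.solve(omega, by)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"{instruments.target_id}: Omega singular even after regularization; prune instruments harder"
        ) from exc
    denom = float(bx @ oi_bx)
    if denom <= 0:
        raise np.linalg.LinAlgError(f"{instruments.target_id}: degenerate instrument design")
    beta = float(bx @ oi_by) / denom
    se = float(np.sqrt(1.0 / denom))
    return _estimate(instruments.target_id, beta, se, "ivw_correlated", k)


def bh_fdr(pvalues: Sequence[float], q: float = FDR_Q) -> list[bool]:
    """Benjamini-Hochberg step-up rejections at level q, original order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0,1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return [bool(r) for r in reject]
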