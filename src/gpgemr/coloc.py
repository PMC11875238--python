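"""Approximate-Bayes-factor colocalization of two traits at one locus.

Implements the single-causal-variant enumeration over hypotheses

    H0: no causal variant for either trait
    H1/H2: causal variant for trait A / B only
    H3: distinct causal variants
    H4: one shared causal variant

using per-variant Wakefield log approximate Bayes factors

    lABF = 1/2 log(1 - r) + z^2 r / 2,    r = W / (W + V),
    V = se^2,  W = prior_sd^2,  z = beta / se

and per-variant configuration priors p1, p2, p12. All sums are carried in
log space (log-sum-exp) and the five posteriors are renormalized at the end;
the single-causal-variant-per-trait assumption is inherited from the
enumeration itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .sumstats import AssociationRecord, HarmonizationDrop, harmonize_alleles


@dataclass(frozen=True)
class ColocPriors:
    """Per-variant prior probabilities and effect-size prior SDs.

    Defaults are the field-standard ones for this model family: p1 = p2 =
    1e-4, p12 = 1e-5; prior effect SD 0.15 for quantitative traits and 0.2
    (log-odds) for case-control traits.
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    prior_effect_sd_quant: float = 0.15
    prior_effect_sd_cc: float = 0.2

    def __post_init__(self) -> None:
        if min(self.p1, self.p2, self.p12) <= 0:
            raise ValueError("priors must be > 0")
        if self.p1 + self.p2 + self.p12 >= 1:
            raise ValueError("p1 + p2 + p12 must be < 1")

    def effect_sd(self, trait_type: str) -> float:
        if trait_type == "quant":
            return self.prior_effect_sd_quant
        if trait_type == "cc":
            return self.prior_effect_sd_cc
        raise ValueError(f"trait_type must be 'quant' or 'cc', got {trait_type!r}")


@dataclass(frozen=True)
class ColocResult:
    """Posterior probabilities over the five colocalization hypotheses."""

    locus_id: str
    pp_h0: float
    pp_h1: float
    pp_h2: float
    pp_h3: float
    pp_h4: float
    n_variants: int

    @property
    def posteriors(self) -> np.ndarray:
        return np.array([self.pp_h0, self.pp_h1, self.pp_h2, self.pp_h3, self.pp_h4])


def log_abf(beta: float, se: float, prior_sd: float) -> float:
    """Wakefield log approximate Bayes factor for one association."""
    if se <= 0:
        raise ValueError("se must be > 0")
    if prior_sd < 0:
        raise ValueError("prior_sd must be >= 0")
    v = se * se
    w = prior_sd * prior_sd
    r = w / (w + v)
    z = beta / se
    return 0.5 * math.log1p(-r) + 0.5 * z * z * r


def _labf_vector(records: Sequence[AssociationRecord], prior_sd: float) -> np.ndarray:
    return np.array([log_abf(rec.beta, rec.se, prior_sd) for rec in records])


def coloc_abf(
    records_a: Sequence[AssociationRecord],
    records_b: Sequence[AssociationRecord],
    priors: ColocPriors | None = None,
    trait_type_a: str = "quant",
    trait_type_b: str = "cc",
    locus_id: str = "locus",
) -> ColocResult:
    """Colocalize two summary-stat datasets restricted to shared variants.

    Records are intersected on variant id and dataset B is harmonized to
    dataset A's allele orientation (orientation only affects effect signs,
    which enter through z^2, but the harmonized join also drops ambiguous
    palindromic and mismatching variants).
    """
    priors = priors or ColocPriors()
    by_id_b = {r.variant.id: r for r in records_b}
    a_kept: list[AssociationRecord] = []
    b_kept: list[AssociationRecord] = []
    for ra in records_a:
        rb = by_id_b.get(ra.variant.id)
        if rb is None:
            continue
        harm = harmonize_alleles(rb, ra.variant)
        if isinstance(harm, HarmonizationDrop):
            continue
        a_kept.append(ra)
        b_kept.append(harm)
    if not a_kept:
        raise ValueError(f"{locus_id}: no shared variants between datasets after harmonization")

    la = _labf_vector(a_kept, priors.effect_sd(trait_type_a))
    lb = _labf_vector(b_kept, priors.effect_sd(trait_type_b))
    return _posterior_from_labf(la, lb, priors, locus_id)


def _posterior_from_labf(la: np.ndarray, lb: np.ndarray, priors: ColocPriors, locus_id: str) -> ColocResult:
    lsum_a = logsumexp(la)
    lsum_b = logsumexp(lb)
    lsum_ab = logsumexp(la + lb)

    lh0 = 0.0
    lh1 = math.log(priors.p1) + lsum_a
    lh2 = math.log(priors.p2) + lsum_b
    # sum over i != j of BF_a_i * BF_b_j = (sum_i)(sum_j) - sum_i(a_i b_i)
    cross = lsum_a + lsum_b
    if len(la) == 1:
        lh3 = -np.inf  # no distinct-variant configuration exists
    else:
        # log(exp(cross) - exp(lsum_ab)), guarded against cancellation
        ratio = math.exp(min(lsum_ab - cross, 0.0))
        diff = -np.inf if ratio >= 1.0 else cross + math.log1p(-ratio)
        lh3 = math.log(priors.p1) + math.log(priors.p2) + diff
    lh4 = math.log(priors.p12) + lsum_ab

    lall = np.array([lh0, lh1, lh2, lh3, lh4])
    pp = np.exp(lall - logsumexp(lall))
    pp = pp / pp.sum()
    return ColocResult(locus_id, *(float(x) for x in pp), n_variants=len(la))


def coloc_abf_enumerate(
    la: np.ndarray, lb: np.ndarray, priors: ColocPriors | None = None, locus_id: str = "locus"
) -> ColocResult:
    """Brute-force configuration enumeration (oracle for small loci).

    Walks every (causal-for-A, causal-for-B) variant assignment explicitly
    instead of using the factorized sums; O(m^2), intended for tests.
    """
    priors = priors or ColocPriors()
    m = len(la)
    bf_a = np.exp(np.asarray(la, dtype=np.longdouble))
    bf_b = np.exp(np.asarray(lb, dtype=np.longdouble))
    s0 = np.longdouble(1.0)
    s1 = sum(priors.p1 * bf_a[i] for i in range(m))
    s2 = sum(priors.p2 * bf_b[j] for j in range(m))
    s3 = sum(priors.p1 * priors.p2 * bf_a[i] * bf_b[j] for i in range(m) for j in range(m) if i != j)
    s4 = sum(priors.p12 * bf_a[i] * bf_b[i] for i in range(m))
    total = s0 + s1 + s2 + s3 + s4
    pp = np.array([s0, s1, s2, s3, s4], dtype=np.longdouble) / total
    return ColocResult(locus_id, *(float(x) for x in pp), n_variants=m)


def coloc_decision(result: ColocResult, threshold: float) -> bool:
    """Strict PP.H4 gate: 0.8 in the eQTL context, 0.7 in the pQTL context."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0,1)")
    return result.pp_h4 > threshold
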