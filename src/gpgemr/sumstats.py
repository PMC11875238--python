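"""GWAS summary-statistic data model, I/O, allele harmonization and LD.

Conventions
-----------
* Coordinates are 1-based, as in conventional GWAS summary-statistic files.
* Effect sizes are per effect-allele copies, on the trait scale (or log-odds
  for case-control traits).
* Alleles are uppercase DNA strings; single-base A/T and C/G pairs are
  strand-palindromic and handled conservatively during harmonization.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._stats import clip_psd, z_from_pvalue

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default header names for summary-statistic TSV files
DEFAULT_COLUMNS: dict[str, str] = {
    "variant_id": "variant_id",
    "chrom": "chrom",
    "pos": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "beta": "beta",
    "se": "se",
    "pvalue": "pvalue",
    "eaf": "eaf",
    "n": "n",
}


class SumstatsFormatError(ValueError):
    """A summary-statistic file violates the expected layout."""


@dataclass(frozen=True)
class Variant:
    """A biallelic genetic variant with 1-based coordinates."""

    id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str

    def __post_init__(self) -> None:
        ea = self.effect_allele.upper()
        oa = self.other_allele.upper()
        object.__setattr__(self, "effect_allele", ea)
        object.__setattr__(self, "other_allele", oa)
        if ea == oa:
            raise ValueError(f"variant {self.id}: effect and other allele identical ({ea})")
        if not (set(ea) <= set("ACGT") and set(oa) <= set("ACGT")):
            raise ValueError(f"variant {self.id}: alleles must be A/C/G/T strings")

    @property
    def is_palindromic(self) -> bool:
        """True for single-base A/T or C/G pairs (strand-ambiguous)."""
        if len(self.effect_allele) != 1 or len(self.other_allele) != 1:
            return False
        return _COMPLEMENT[self.effect_allele] == self.other_allele

    @property
    def multi_base(self) -> bool:
        """Indels cannot be strand-checked; flagged, not rejected."""
        return len(self.effect_allele) > 1 or len(self.other_allele) > 1


@dataclass(frozen=True)
class AssociationRecord:
    """One variant's marginal GWAS effect for one trait."""

    variant: Variant
    beta: float
    se: float
    pvalue: float
    trait_id: str
    eaf: float | None = None
    n: int | None = None
    log10_pvalue: float | None = None

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"{self.variant.id}: se must be > 0, got {self.se}")
        if not (0 < self.pvalue <= 1) and self.log10_pvalue is None:
            raise ValueError(f"{self.variant.id}: pvalue must be in (0,1]")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise ValueError(f"{self.variant.id}: eaf must be in (0,1)")

    @property
    def zscore(self) -> float:
        return self.beta / self.se

    def check_consistency(self, rel_tol: float = 0.10) -> bool:
        """|beta/se| vs the p-value under the two-sided normal, 10% slack."""
        z_p = float(z_from_pvalue(self.pvalue))
        z_b = abs(self.zscore)
        if z_p < 1e-8:
            return True
        return abs(z_b - z_p) <= rel_tol * max(z_p, 1e-8)


@dataclass(frozen=True)
class HarmonizationDrop:
    """Signal that a record cannot be harmonized to the reference."""

    variant_id: str
    reason: str


@dataclass
class LDMatrix:
    """Pairwise variant correlations plus per-variant genotype SDs.

    The correlation matrix is PSD-clipped on construction (eigenvalue
    truncation at zero, then rescaled back to unit diagonal) so that the
    generalized least-squares inverses downstream are well defined.
    """

    variant_ids: list[str]
    r: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        k = len(self.variant_ids)
        if self.r.shape != (k, k):
            raise ValueError(f"r has shape {self.r.shape}, expected ({k},{k})")
        if self.sd.shape != (k,):
            raise ValueError("sd length must equal variant count")
        if np.any(self.sd < 0):
            raise ValueError("genotype sd must be >= 0")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-6):
            raise ValueError("correlation matrix diagonal must be 1")
        clipped = clip_psd(self.r)
        if clipped is not self.r:
            d = np.sqrt(np.clip(np.diag(clipped), 1e-12, None))
            clipped = clipped / np.outer(d, d)
            np.fill_diagonal(clipped, 1.0)
        self.r = clipped
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def index_of(self, variant_id: str) -> int:
        try:
            return self._index[variant_id]
        except KeyError:
            raise KeyError(f"variant {variant_id} not in LD matrix") from None

    def subset(self, variant_ids: Sequence[str]) -> "LDMatrix":
        idx = [self.index_of(v) for v in variant_ids]
        return LDMatrix(list(variant_ids), self.r[np.ix_(idx, idx)], self.sd[idx])


# ---------------------------------------------------------------------------
# I/O


def _open_text(path):
    p = str(path)
    if p.endswith(".gz"):
        return gzip.open(p, "rt")
    return open(p, "rt")


def read_sumstats(
    path,
    trait_id: str,
    columns: Mapping[str, str] | None = None,
) -> list[AssociationRecord]:
    """Read a tab-separated GWAS summary-statistic file.

    Rows with missing beta or non-positive se are dropped (counted in a
    warning). ``columns`` remaps the required logical names to the file's
    header names; defaults follow :data:`DEFAULT_COLUMNS`.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", dtype={colmap["chrom"]: str})
    mandatory = ["variant_id", "chrom", "pos", "effect_allele", "other_allele", "beta", "se", "pvalue"]
    for key in mandatory:
        if colmap[key] not in df.columns:
            raise SumstatsFormatError(f"column {colmap[key]} not found in {path}")
    has_eaf = colmap["eaf"] in df.columns
    has_n = colmap["n"] in df.columns

    records: list[AssociationRecord] = []
    n_dropped = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = dict(zip(df.columns, row))
        try:
            beta = float(row[colmap["beta"]])
            se = float(row[colmap["se"]])
            pval = float(row[colmap["pvalue"]])
        except (TypeError, ValueError) as exc:
            raise SumstatsFormatError(f"{path}: unparsable numeric value at line {i}: {exc}") from exc
        if not np.isfinite(beta) or not (se > 0):
            n_dropped += 1
            continue
        eaf = None
        if has_eaf:
            v = row[colmap["eaf"]]
            eaf = None if pd.isna(v) else float(v)
        n = None
        if has_n:
            v = row[colmap["n"]]
            n = None if pd.isna(v) else int(v)
        variant = Variant(
            id=str(row[colmap["variant_id"]]),
            chromosome=str(row[colmap["chrom"]]),
            position=int(row[colmap["pos"]]),
            effect_allele=str(row[colmap["effect_allele"]]),
            other_allele=str(row[colmap["other_allele"]]),
        )
        records.append(
            AssociationRecord(variant=variant, beta=beta, se=se, pvalue=min(pval, 1.0) if pval > 0 else pval,
                              trait_id=trait_id, eaf=eaf, n=n)
        )
    if n_dropped:
        logger.warning("%s: dropped %d rows with missing beta or non-positive se", path, n_dropped)
    return records


def write_sumstats(records: Iterable[AssociationRecord], path) -> None:
    """Write records in the TSV dialect read_sumstats expects."""
    rows = []
    for r in records:
        rows.append(
            {
                "variant_id": r.variant.id,
                "chrom": r.variant.chromosome,
                "pos": r.variant.position,
                "effect_allele": r.variant.effect_allele,
                "other_allele": r.variant.other_allele,
                "beta": repr(r.beta),
                "se": repr(r.se),
                "pvalue": repr(r.pvalue),
                "eaf": "" if r.eaf is None else repr(r.eaf),
                "n": "" if r.n is None else r.n,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Allele harmonization


def _complement(allele: str) -> str:
    return "".join(_COMPLEMENT[b] for b in allele)


def harmonize_alleles(
    record: AssociationRecord,
    reference: Variant,
    palindrome_eaf_band: tuple[float, float] = (0.42, 0.58),
) -> AssociationRecord | HarmonizationDrop:
    """Orient a record's effect to a reference variant's effect allele.

    Matching alleles pass through; swapped alleles negate beta and flip eaf;
    strand-flipped alleles are complemented first. Palindromic variants whose
    eaf is missing or inside ``palindrome_eaf_band`` cannot be oriented and
    yield a drop signal — a conservative policy, since a wrong strand call
    silently flips the effect sign.
    """
    v = record.variant
    lo, hi = palindrome_eaf_band
    if v.is_palindromic and (record.eaf is None or lo <= record.eaf <= hi):
        return HarmonizationDrop(v.id, "palindromic-ambiguous")

    def _swap(rec: AssociationRecord) -> AssociationRecord:
        new_variant = Variant(v.id, v.chromosome, v.position, reference.effect_allele, reference.other_allele)
        return replace(
            rec,
            variant=new_variant,
            beta=-rec.beta,
            eaf=None if rec.eaf is None else 1.0 - rec.eaf,
        )

    ea, oa = v.effect_allele, v.other_allele
    if (ea, oa) == (reference.effect_allele, reference.other_allele):
        return record
    if (ea, oa) == (reference.other_allele, reference.effect_allele):
        return _swap(record)
    if not v.multi_base and not reference.multi_base:
        cea, coa = _complement(ea), _complement(oa)
        if (cea, coa) == (reference.effect_allele, reference.other_allele):
            new_variant = Variant(v.id, v.chromosome, v.position, cea, coa)
            return replace(record, variant=new_variant)
        if (cea, coa) == (reference.other_allele, reference.effect_allele):
            return _swap(record)
    return HarmonizationDrop(v.id, "allele mismatch")


def harmonize_records(
    records: Iterable[AssociationRecord],
    references: Mapping[str, Variant],
) -> tuple[list[AssociationRecord], list[HarmonizationDrop]]:
    """Harmonize records against a reference map; partition kept vs dropped."""
    kept: list[AssociationRecord] = []
    dropped: list[HarmonizationDrop] = []
    for rec in records:
        ref = references.get(rec.variant.id)
        if ref is None:
            dropped.append(HarmonizationDrop(rec.variant.id, "not in reference"))
            continue
        out = harmonize_alleles(rec, ref)
        if isinstance(out, HarmonizationDrop):
            dropped.append(out)
        else:
            kept.append(out)
    return kept, dropped


# ---------------------------------------------------------------------------
# LD


def ld_from_genotypes(genotypes: np.ndarray, variant_ids: Sequence[str]) -> LDMatrix:
    """Pearson-correlation LD matrix and per-variant dosage SDs.

    ``genotypes`` is individuals x variants (dosages). Monomorphic variants
    make the correlation undefined and raise, naming the offending ids.
    """
    g = np.asarray(genotypes, dtype=float)
    if g.ndim != 2 or g.shape[0] < 2:
        raise ValueError("genotype matrix must be individuals x variants with >= 2 individuals")
    if g.shape[1] != len(variant_ids):
        raise ValueError("variant_ids length must match genotype columns")
    sd = g.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [variant_ids[i] for i in np.where(sd == 0)[0]]
        raise ValueError(f"monomorphic variant(s): {', '.join(bad)}")
    r = np.corrcoef(g, rowvar=False)
    r = np.atleast_2d(r)
    return LDMatrix(list(variant_ids), r, sd)


def read_ld_matrix(corr_path, sd_path) -> LDMatrix:
    """Read a precomputed correlation TSV (ids in header) plus an sd table."""
    corr = pd.read_csv(corr_path, sep="\t", index_col=0)
    sd = pd.read_csv(sd_path, sep="\t")
    sd = sd.set_index("variant_id")["sd"].reindex(corr.columns)
    return LDMatrix(list(corr.columns), corr.to_numpy(), sd.to_numpy())


def write_ld_matrix(ld: LDMatrix, corr_path, sd_path) -> None:
    pd.DataFrame(ld.r, index=ld.variant_ids, columns=ld.variant_ids).to_csv(corr_path, sep="\t")
    pd.DataFrame({"variant_id": ld.variant_ids, "sd": ld.sd}).to_csv(sd_path, sep="\t", index=False)


def greedy_ld_prune(
    records: Sequence[AssociationRecord],
    ld: LDMatrix,
    r2_max: float,
) -> list[AssociationRecord]:
    """Greedy p-value-ordered LD pruning.

    Records are ranked by ascending p (ties broken lexicographically on
    variant id); the best remaining record is kept and every record with
    r^2 > ``r2_max`` against it is discarded, until none remain.
    """
    for rec in records:
        if rec.variant.id not in ld:
            raise KeyError(f"variant {rec.variant.id} absent from LD matrix")
    order = sorted(records, key=lambda r: (r.pvalue, r.variant.id))
    kept: list[AssociationRecord] = []
    kept_idx: list[int] = []
    for rec in order:
        i = ld.index_of(rec.variant.id)
        if all(ld.r[i, j] ** 2 <= r2_max for j in kept_idx):
            kept.append(rec)
            kept_idx.append(i)
    return kept
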