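"""Drug-gene mapping, directional concordance and hepatotoxicity annotation.

A putative causal gene whose increased expression raises disease risk is a
plausible target for an inhibitor; one whose increased expression lowers
risk, for an agonist. This module joins genes to a drug catalogue, keeps
only such direction-concordant pairs, removes oncology drugs and duplicate
medications, and annotates hepatotoxicity from user-supplied LiverTox-style
and DILIrank-style tables. Hepatotoxicity annotates but never filters.
"""

from __future__ import annotations

import logging

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .twas import GPGEResult

logger = logging.getLogger(__name__)

#: catalogue mechanism terms collapsed onto the two classes the rules use
MECHANISM_SYNONYMS: dict[str, str] = {
    "agonist": "agonist",
    "activator": "agonist",
    "positive modulator": "agonist",
    "positive allosteric modulator": "agonist",
    "inducer": "agonist",
    "inhibitor": "inhibitor",
    "blocker": "inhibitor",
    "antagonist": "inhibitor",
    "negative modulator": "inhibitor",
    "negative allosteric modulator": "inhibitor",
    "channel blocker": "inhibitor",
}

#: salt/ester suffixes stripped when normalizing drug names for joins
SALT_SUFFIXES: tuple[str, ...] = (
    "hydrochloride",
    "citrate",
    "sodium",
    "sulfate",
    "maleate",
    "tartrate",
    "mesylate",
    "ethyl",
)


@dataclass(frozen=True)
class GeneDirection:
    """Risk direction of a gene's expression, from significant TWAS hits."""

    gene: str
    masld_direction: str  # "risk_increasing" | "risk_decreasing"
    source_tissue_count: int


@dataclass(frozen=True)
class DrugGenePair:
    drug_name: str
    gene: str
    mechanism: str  # "agonist" | "inhibitor"
    primary_indication: str
    oncology: bool = False
    livertox_class: str = "none"  # A..E or none
    dili_concern: str = "none"  # most | less | no | none
    duplicate_of: str | None = None  # set when the same drug maps via another gene


@dataclass(frozen=True)
class RemovalRecord:
    drug_name: str
    gene: str
    reason: str


def normalize_drug_name(name: str, salt_suffixes: Sequence[str] = SALT_SUFFIXES) -> str:
    """Case-fold and strip trailing salt/ester suffixes for table joins."""
    tokens = name.strip().lower().split()
    while len(tokens) > 1 and tokens[-1] in salt_suffixes:
        tokens.pop()
    return " ".join(tokens)


def normalize_mechanism(term: str, synonyms: Mapping[str, str] = MECHANISM_SYNONYMS) -> str:
    key = term.strip().lower()
    if key not in synonyms:
        raise ValueError(f"unrecognized mechanism term {term!r}")
    return synonyms[key]


def gene_directions_from_gpge(results: Iterable[GPGEResult]) -> tuple[list[GeneDirection], list[str]]:
    """Per-gene risk direction by tissue-majority sign of significant hits.

    Genes whose significant tissue effects split evenly are excluded with
    reason "ambiguous direction" and returned in the second list.
    """
    by_gene: dict[str, list[float]] = {}
    for r in results:
        by_gene.setdefault(r.gene, []).append(r.effect_per_sd)
    directions: list[GeneDirection] = []
    ambiguous: list[str] = []
    for gene, effects in sorted(by_gene.items()):
        pos = sum(e > 0 for e in effects)
        neg = sum(e < 0 for e in effects)
        if pos == neg:
            logger.info("gene %s excluded: ambiguous direction (%d up, %d down)", gene, pos, neg)
            ambiguous.append(gene)
            continue
        directions.append(
            GeneDirection(
                gene=gene,
                masld_direction="risk_increasing" if pos > neg else "risk_decreasing",
                source_tissue_count=len(effects),
            )
        )
    return directions, ambiguous


def map_drug_gene_pairs(genes: Sequence[GeneDirection], catalogue: pd.DataFrame) -> list[DrugGenePair]:
    """Join gene directions to the catalogue; dedupe on (drug, gene)."""
    wanted = {g.gene for g in genes}
    pairs: dict[tuple[str, str], DrugGenePair] = {}
    for i, row in enumerate(catalogue.to_dict("records")):
        try:
            gene = str(row["gene"])
            if gene not in wanted:
                continue
            pair = DrugGenePair(
                drug_name=str(row["drug_name"]),
                gene=gene,
                mechanism=normalize_mechanism(str(row["mechanism"])),
                primary_indication=str(row.get("indication", "")),
                oncology=bool(row.get("oncology", False)),
            )
        except (KeyError, ValueError) as exc:
            raise ValueError(f"malformed catalogue row {i}: {exc}") from exc
        pairs.setdefault((pair.drug_name, pair.gene), pair)
    return list(pairs.values())


def concordance_filter(
    pairs: Sequence[DrugGenePair], directions: Sequence[GeneDirection]
) -> tuple[list[DrugGenePair], list[RemovalRecord]]:
    """Keep (inhibitor, risk_increasing) and (agonist, risk_decreasing) pairs."""
    dir_by_gene = {d.gene: d.masld_direction for d in directions}
    kept: list[DrugGenePair] = []
    removed: list[RemovalRecord] = []
    for p in pairs:
        if p.gene not in dir_by_gene:
            raise KeyError(f"no risk direction available for gene {p.gene}")
        direction = dir_by_gene[p.gene]
        concordant = (p.mechanism == "inhibitor" and direction == "risk_increasing") or (
            p.mechanism == "agonist" and direction == "risk_decreasing"
        )
        if concordant:
            kept.append(p)
        else:
            removed.append(RemovalRecord(p.drug_name, p.gene, f"discordant: {p.mechanism} vs {direction}"))
    return kept, removed


def apply_exclusions(pairs: Sequence[DrugGenePair]) -> tuple[list[DrugGenePair], list[RemovalRecord]]:
    """Drop oncology drugs; flag duplicate medications across genes.

    A drug mapped via several genes keeps all its pairs in the table, but
    only the first (gene-lexicographic) counts as the drug's primary pair;
    the rest carry ``duplicate_of`` so downstream counts of unique
    medications are unambiguous.
    """
    kept: list[DrugGenePair] = []
    removed: list[RemovalRecord] = []
    primary_gene: dict[str, str] = {}
    for p in sorted(pairs, key=lambda p: (p.drug_name, p.gene)):
        if p.oncology:
            removed.append(RemovalRecord(p.drug_name, p.gene, "oncology indication"))
            continue
        if p.drug_name in primary_gene:
            kept.append(replace(p, duplicate_of=primary_gene[p.drug_name]))
        else:
            primary_gene[p.drug_name] = p.gene
            kept.append(p)
    return kept, removed


def annotate_hepatotoxicity(
    pairs: Sequence[DrugGenePair],
    livertox_table: pd.DataFrame | None = None,
    dilirank_table: pd.DataFrame | None = None,
) -> list[DrugGenePair]:
    """Fill livertox_class / dili_concern by normalized drug-name join."""
    lt = {}
    if livertox_table is not None:
        lt = {normalize_drug_name(r["drug_name"]): str(r["class"]) for r in livertox_table.to_dict("records")}
    dr = {}
    if dilirank_table is not None:
        dr = {normalize_drug_name(r["drug_name"]): str(r["concern"]) for r in dilirank_table.to_dict("records")}
    out = []
    n_matched = 0
    for p in pairs:
        key = normalize_drug_name(p.drug_name)
        cls = lt.get(key, "none")
        concern = dr.get(key, "none")
        if cls != "none" or concern != "none":
            n_matched += 1
        out.append(replace(p, livertox_class=cls, dili_concern=concern))
    if pairs:
        logger.info("hepatotoxicity annotation matched %d/%d drugs", n_matched, len(pairs))
    return out


def pairs_frame(pairs: Iterable[DrugGenePair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "drug_name": p.drug_name,
                "gene": p.gene,
                "mechanism": p.mechanism,
                "indication": p.primary_indication,
                "oncology": p.oncology,
                "livertox_class": p.livertox_class,
                "dili_concern": p.dili_concern,
                "duplicate_of": p.duplicate_of or "",
            }
            for p in pairs
        ]
    )
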