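"""Drug -> target -> gene-region bookkeeping.

Drug-target MR proxies a drug by the genes encoding its protein targets.
This module turns a user-supplied drug table (TSV with columns ``drug``,
``target`` and optionally ``mechanism``) into per-(drug, target) analysis
units, merging drugs with identical target sets and skipping targets that
lack a mapped gene region.  Target retrieval itself (literature / drug
databases) is out of scope: the table is an input.

A small bundled table covers the 11 ovarian-cancer targets analysed in the
package's worked example; the same TSV schema supports arbitrarily large
user tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .exceptions import ConfigurationError
from .instruments import InstrumentCriteria
from .summary_data import GeneRegion

logger = logging.getLogger(__name__)

__all__ = [
    "DrugRecord",
    "AnalysisUnit",
    "load_drug_targets",
    "load_ovarian_drug_table",
    "dedupe_by_target_set",
    "build_analysis_units",
]


@dataclass
class DrugRecord:
    """One drug (or merged drug group) and its protein-target genes."""

    drug: str
    targets: list[str]
    mechanism: str | None = None

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError(f"{self.drug}: targets must be non-empty")
        if len(set(self.targets)) != len(self.targets):
            raise ValueError(f"{self.drug}: duplicate target symbols")


@dataclass
class AnalysisUnit:
    """One (drug, target) pair ready for instrument selection."""

    drug: str
    target: str
    region: GeneRegion
    criteria: InstrumentCriteria


def load_drug_targets(path: str | Path) -> list[DrugRecord]:
    """Read a drug-target TSV into one record per drug.

    Rows sharing a drug are aggregated (targets de-duplicated, file order
    kept); rows with an empty target cell are dropped and logged — drugs
    left with no target at all are excluded, mirroring the usual screening
    rule that drugs with unclear targets cannot be analysed.

    Raises
    ------
    ConfigurationError
        If the ``drug`` or ``target`` column is missing.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("drug", "target"):
        if col not in df.columns:
            raise ConfigurationError(f"{path}: drug table lacks column {col!r}")
    has_mech = "mechanism" in df.columns
    records: dict[str, DrugRecord] = {}
    for row in df.itertuples(index=False):
        drug = str(row.drug).strip()
        target = "" if pd.isna(row.target) else str(row.target).strip()
        if not target:
            logger.info("drug table: %s has an empty target cell, row dropped", drug)
            continue
        mech = getattr(row, "mechanism", None) if has_mech else None
        if drug not in records:
            records[drug] = DrugRecord(drug, [target], mech if pd.notna(mech) else None)
        elif target not in records[drug].targets:
            records[drug].targets.append(target)
    dropped = set(df["drug"].astype(str).str.strip()) - set(records)
    for d in sorted(dropped):
        logger.info("drug table: %s excluded (no usable targets)", d)
    return list(records.values())


def load_ovarian_drug_table() -> list[DrugRecord]:
    """Bundled drug table for the 11 ovarian-cancer targets (partial list).

    Covers the drug groups of the package's worked example — statins,
    lonafarnib, aspirin, quinacrine — mapped to 11 distinct gene symbols.
    """
    return load_drug_targets(
        resources.files("targetmr.data").joinpath("ovarian_drug_targets.tsv")
    )


def dedupe_by_target_set(records: list[DrugRecord]) -> list[DrugRecord]:
    """Merge drugs whose target sets are identical.

    Merged records concatenate the drug names with ``+`` (input order);
    the operation is idempotent and never increases the record count.
    """
    by_set: dict[frozenset, DrugRecord] = {}
    order: list[frozenset] = []
    for rec in records:
        key = frozenset(rec.targets)
        if key in by_set:
            prev = by_set[key]
            merged_name = f"{prev.drug}+{rec.drug}"
            by_set[key] = DrugRecord(merged_name, prev.targets, prev.mechanism)
            logger.info("dedupe: merged %s into %s (identical target set)",
                        rec.drug, merged_name)
        else:
            by_set[key] = rec
            order.append(key)
    return [by_set[k] for k in order]


def build_analysis_units(
    records: list[DrugRecord],
    regions: dict[str, GeneRegion],
    criteria: InstrumentCriteria | None = None,
) -> list[AnalysisUnit]:
    """One analysis unit per (drug, target) with a known gene region.

    Targets missing from the region map are logged and skipped, never
    fatal — the empty-instrument case downstream handles targets that map
    but yield no SNPs.
    """
    criteria = criteria or InstrumentCriteria()
    units: list[AnalysisUnit] = []
    for rec in records:
        for target in rec.targets:
            region = regions.get(target)
            if region is None:
                logger.info("%s: target %s has no mapped region, skipped",
                            rec.drug, target)
                continue
            units.append(AnalysisUnit(rec.drug, target, region, criteria))
    return units
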