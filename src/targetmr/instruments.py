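"""Instrument selection and grading for cis drug-target MR.

A valid drug-target instrument is a SNP that (i) lies in the cis window of
the gene encoding the target (gene body plus symmetric flanks), (ii) is
genome-wide significantly associated with the exposure, (iii) is not in
strong LD with a better instrument, and (iv) is strong enough that weak
instrument bias is negligible (conventionally F >= 10).

The defaults mirror the usual drug-target MR recipe: a 100 kb flank,
p < 5e-8, pairwise r^2 < 0.3, F >= 10.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    DomainError,
    EmptyInstrumentSetError,
    MissingSNPError,
)
from .summary_data import GeneRegion, HarmonizedSet, SummaryStat

logger = logging.getLogger(__name__)

__all__ = [
    "InstrumentCriteria",
    "GenotypeRef",
    "read_genotype_ref",
    "select_cis",
    "ld_clump",
    "variance_explained",
    "f_statistic",
    "f_from_beta_se",
    "annotate_strength",
    "filter_weak",
]


@dataclass
class InstrumentCriteria:
    """Thresholds governing instrument selection.

    window_bp
        Flank added on both sides of the gene body, in base pairs.
    p_threshold
        Exposure association must satisfy p < p_threshold (strict).
    r2_threshold
        Pairwise LD ceiling for clumping; retained SNPs are mutually below it.
    f_min
        Minimum per-SNP F-statistic; weaker instruments are filtered.
    """

    window_bp: int = 100_000
    p_threshold: float = 5e-8
    r2_threshold: float = 0.3
    f_min: float = 10.0

    def __post_init__(self) -> None:
        if self.window_bp < 0:
            raise DomainError("window_bp must be >= 0")
        if not 0 < self.p_threshold < 1:
            raise DomainError("p_threshold must be in (0, 1)")
        if not 0 < self.r2_threshold <= 1:
            raise DomainError("r2_threshold must be in (0, 1]")


@dataclass
class GenotypeRef:
    """LD reference: a dosage matrix (individuals x SNPs, values in [0, 2])."""

    snp_ids: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2 or self.dosages.shape[1] != len(self.snp_ids):
            raise ValueError(
                "dosages must be (individuals x SNPs) with one column per snp_id"
            )
        self._index = {s: j for j, s in enumerate(self.snp_ids)}

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    def column(self, snp_id: str) -> np.ndarray:
        try:
            return self.dosages[:, self._index[snp_id]]
        except KeyError:
            raise MissingSNPError(f"SNP {snp_id!r} absent from genotype reference") from None


def read_genotype_ref(path: str | Path) -> GenotypeRef:
    """Read a dosage matrix from a headered TSV (columns = SNP ids)."""
    df = pd.read_csv(path, sep="\t")
    return GenotypeRef(snp_ids=list(df.columns), dosages=df.to_numpy(float))


def select_cis(
    stats: list[SummaryStat],
    region: GeneRegion,
    positions: dict[str, tuple[str, int]],
    criteria: InstrumentCriteria,
) -> list[SummaryStat]:
    """Keep SNPs inside the cis window that pass the significance threshold.

    The window is ``[start - window_bp, end + window_bp]`` on the region's
    chromosome, closed on both boundaries; the p filter is strict
    (``p < p_threshold``).  SNPs with no known position are skipped with a
    log line (they cannot be placed, hence cannot be retained).

    Raises
    ------
    ConfigurationError
        If the region's chromosome does not occur in the position map at
        all — a symptom of mismatched genome annotations.
    """
    chroms = {c for c, _ in positions.values()}
    if region.chrom not in chroms:
        raise ConfigurationError(
            f"region {region.gene}: chromosome {region.chrom!r} absent from "
            f"the position map (chromosomes present: {sorted(chroms)})"
        )
    lo = region.start - criteria.window_bp
    hi = region.end + criteria.window_bp
    kept: list[SummaryStat] = []
    for s in stats:
        if s.snp_id not in positions:
            logger.info("select_cis: no position for %s, skipped", s.snp_id)
            continue
        chrom, pos = positions[s.snp_id]
        if chrom == region.chrom and lo <= pos <= hi and s.pval < criteria.p_threshold:
            kept.append(s)
    return kept


def ld_clump(
    stats: list[SummaryStat],
    ref: GenotypeRef,
    r2_threshold: float,
) -> list[SummaryStat]:
    """Greedy LD clumping against a dosage reference.

    SNPs are visited in order of ascending p-value (ties broken by snp_id,
    so output is deterministic and independent of input order); a SNP is
    accepted iff its squared Pearson correlation with every
    already-accepted SNP's dosage column stays below ``r2_threshold``.
    All retained pairs therefore mutually satisfy r^2 < threshold.

    Raises
    ------
    MissingSNPError
        If any input SNP lacks a reference column (no silent pass-through).
    DomainError
        If a required dosage column is constant (correlation undefined).
    """
    for s in stats:
        if s.snp_id not in ref._index:
            raise MissingSNPError(f"SNP {s.snp_id!r} absent from genotype reference")
    order = sorted(stats, key=lambda s: (s.pval, s.snp_id))
    accepted: list[SummaryStat] = []
    accepted_cols: list[np.ndarray] = []
    for s in order:
        g = ref.column(s.snp_id)
        if np.std(g) == 0:
            raise DomainError(
                f"SNP {s.snp_id!r}: constant dosage column, LD undefined"
            )
        ok = True
        for h in accepted_cols:
            r = np.corrcoef(g, h)[0, 1]
            if r * r >= r2_threshold:
                ok = False
                break
        if ok:
            accepted.append(s)
            accepted_cols.append(g)
    # restore input order among the accepted SNPs? No: keep significance
    # order, the natural reading order of a clumped instrument list.
    return accepted


def variance_explained(beta: float, eaf: float) -> float:
    """Per-SNP fraction of trait variance explained, unit-variance trait.

    ``2 * beta^2 * eaf * (1 - eaf)`` — the variance contributed by an
    additive biallelic SNP with per-allele effect ``beta`` on a trait
    standardised to unit variance.
    """
    if not 0 < eaf < 1:
        raise DomainError(f"eaf must be in (0, 1), got {eaf}")
    return 2.0 * beta * beta * eaf * (1.0 - eaf)


def f_statistic(r2: float, n: float, k: int = 1) -> float:
    """Instrument-strength F from variance explained.

    ``F = r2 * (n - k - 1) / (k * (1 - r2))`` for ``k`` instruments jointly
    explaining fraction ``r2`` of the exposure in a sample of ``n``.  Per
    SNP (k=1) this is the square of the first-stage t statistic.
    """
    if not 0 <= r2 < 1:
        raise DomainError(f"r2 must be in [0, 1), got {r2}")
    if not n > k + 1:
        raise DomainError(f"n must exceed k + 1, got n={n}, k={k}")
    return r2 * (n - k - 1) / (k * (1.0 - r2))


def f_from_beta_se(beta: float, se: float) -> float:
    """Companion F convention: the squared Wald ratio ``(beta / se)^2``."""
    if not se > 0:
        raise DomainError("se must be positive")
    return (beta / se) ** 2


def annotate_strength(
    hset: HarmonizedSet,
    n: float | None = None,
    eaf: dict[str, float] | None = None,
) -> HarmonizedSet:
    """Fill ``r2_exposure`` and ``f_stat`` on a harmonised set.

    With per-SNP effect-allele frequencies and an exposure sample size, the
    R²-based convention is used (:func:`variance_explained` then
    :func:`f_statistic`); otherwise F falls back to the squared Wald ratio
    of the exposure association and R² stays NaN.
    """
    rows = hset.rows.copy()
    if eaf is not None and n is not None:
        r2 = [
            variance_explained(b, eaf[s])
            for s, b in zip(rows["snp_id"], rows["beta_exposure"])
        ]
        rows["r2_exposure"] = r2
        rows["f_stat"] = [f_statistic(v, n) for v in r2]
    else:
        rows["f_stat"] = [
            f_from_beta_se(b, s)
            for b, s in zip(rows["beta_exposure"], rows["se_exposure"])
        ]
    return HarmonizedSet(hset.target, rows, hset.outcome_id)


def filter_weak(hset: HarmonizedSet, f_min: float = 10.0) -> HarmonizedSet:
    """Drop rows whose F-statistic falls below ``f_min``.

    Requires ``f_stat`` populated on every row (see
    :func:`annotate_strength`).  Dropped snp_ids are logged.

    Raises
    ------
    EmptyInstrumentSetError
        If no instrument survives.
    """
    f = hset.rows["f_stat"]
    if f.isna().any():
        raise ConfigurationError(
            f"{hset.target}: f_stat not populated on every row; run "
            "annotate_strength first"
        )
    keep = f >= f_min
    dropped = hset.rows.loc[~keep, "snp_id"].tolist()
    if dropped:
        logger.info("%s: filtered weak instruments (F < %g): %s",
                    hset.target, f_min, ", ".join(dropped))
    if not keep.any():
        raise EmptyInstrumentSetError(
            f"{hset.target}: every instrument has F < {f_min}"
        )
    return HarmonizedSet(hset.target, hset.rows[keep.to_numpy()], hset.outcome_id)
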