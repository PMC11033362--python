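"""GWAS summary-statistic data model, I/O, and exposure/outcome harmonisation.

The unit of analysis in two-sample Mendelian randomisation is a table of
per-SNP associations: each row holds a SNP's effect on the exposure (here, a
drug-target gene product) and on the outcome (a disease), expressed relative
to a common effect allele.  This module defines

* :class:`SummaryStat` — one SNP's association with one trait;
* :class:`HarmonizedSet` — the aligned per-target exposure/outcome table that
  the estimators in :mod:`targetmr.mr_core` consume;
* :class:`GeneRegion` — a gene's genomic interval (0-based, half-open);
* readers/writers for headered TSV summary statistics and BED regions;
* :func:`harmonize`, which aligns two summary-stat lists to a shared effect
  allele, flipping outcome signs where the allele coding is reversed;
* :func:`load_ovarian_instruments`, the bundled 77-row instrument table for
  11 ovarian-cancer drug targets used throughout the test-suite and docs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    EmptyInputError,
    NoOverlapError,
    UnknownTargetError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SummaryStat",
    "HarmonizedSet",
    "GeneRegion",
    "read_summary_stats",
    "write_summary_stats",
    "read_gene_regions",
    "read_snp_positions",
    "harmonize",
    "load_ovarian_instruments",
    "FIXTURE_TARGETS",
    "HARMONIZED_COLUMNS",
]

#: Column schema of :attr:`HarmonizedSet.rows`.
HARMONIZED_COLUMNS = [
    "snp_id",
    "beta_exposure",
    "se_exposure",
    "p_exposure",
    "beta_outcome",
    "se_outcome",
    "p_outcome",
    "r2_exposure",
    "f_stat",
]

#: Default column names expected in a summary-statistics TSV.  Override any
#: of them through the ``column_map`` argument of :func:`read_summary_stats`.
DEFAULT_COLUMN_MAP = {
    "snp_id": "SNP",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "eaf": "eaf",
    "n": "n",
}

_MANDATORY_FIELDS = ("snp_id", "effect_allele", "beta", "se", "pval")

_PALINDROMIC_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

_FIXTURE_RESOURCE = "ovarian_cancer_instruments.tsv"

#: Gene symbols present in the bundled ovarian-cancer instrument table.
FIXTURE_TARGETS = (
    "CASP1",
    "CASP3",
    "CCND1",
    "FNTA",
    "FNTB",
    "HMGCR",
    "HSPA5",
    "ITGAL",
    "NEU1",
    "PLA2G4A",
    "PTGS1",
)


@dataclass
class SummaryStat:
    """A single SNP–trait association from a GWAS.

    Parameters
    ----------
    snp_id : str
        Variant identifier (typically an rsID).
    effect_allele : str
        Allele to which ``beta`` refers; uppercase base(s).
    beta : float
        Per-allele effect on the trait (log-odds for binary traits).
    se : float
        Standard error of ``beta``; must be positive (``inf`` marks a
        degenerate record from a monomorphic genotype column).
    pval : float
        Two-sided association p-value, in (0, 1].
    other_allele : str, optional
        The non-effect allele, if known.
    eaf : float, optional
        Effect-allele frequency in (0, 1).
    n : float, optional
        Sample size of the association.
    trait_id : str
        Identifier of the trait/cohort the statistic refers to.
    """

    snp_id: str
    effect_allele: str
    beta: float
    se: float
    pval: float
    other_allele: str | None = None
    eaf: float | None = None
    n: float | None = None
    trait_id: str = ""

    def __post_init__(self) -> None:
        self.effect_allele = str(self.effect_allele).upper()
        if self.other_allele is not None:
            self.other_allele = str(self.other_allele).upper()
        if not self.se > 0:
            raise ValueError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if not 0 < self.pval <= 1:
            raise ValueError(f"{self.snp_id}: pval must be in (0, 1], got {self.pval}")
        if self.eaf is not None and not 0 < self.eaf < 1:
            raise ValueError(f"{self.snp_id}: eaf must be in (0, 1), got {self.eaf}")

    @property
    def is_palindromic(self) -> bool:
        """True when effect/other alleles are complementary (A/T or C/G)."""
        if self.other_allele is None:
            return False
        return (self.effect_allele, self.other_allele) in _PALINDROMIC_PAIRS

    @property
    def degenerate(self) -> bool:
        """True for placeholder records emitted for monomorphic SNPs."""
        return not math.isfinite(self.se)


@dataclass
class GeneRegion:
    """A gene's genomic interval, 0-based half-open.

    1-based inclusive inputs must be converted at the boundary
    (``start - 1``) before constructing a region; BED input is native.
    """

    chrom: str
    start: int
    end: int
    gene: str
    strand: str = "."

    def __post_init__(self) -> None:
        self.chrom = str(self.chrom)
        if self.start < 0:
            raise ValueError(f"{self.gene}: start must be non-negative")
        if not self.start < self.end:
            raise ValueError(f"{self.gene}: start must be < end")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"{self.gene}: strand must be '+', '-' or '.'")


@dataclass
class HarmonizedSet:
    """Aligned exposure/outcome instrument table for one target gene.

    ``rows`` is a DataFrame with the columns of :data:`HARMONIZED_COLUMNS`;
    its effect alleles are, by contract, already aligned between exposure
    and outcome (the job of :func:`harmonize`).  ``r2_exposure`` and
    ``f_stat`` may be NaN until instrument grading fills them.
    """

    target: str
    rows: pd.DataFrame
    outcome_id: str = ""

    def __post_init__(self) -> None:
        rows = self.rows.reset_index(drop=True)
        missing = [c for c in HARMONIZED_COLUMNS if c not in rows.columns]
        if missing:
            raise ValueError(f"{self.target}: rows missing columns {missing}")
        if len(rows) == 0:
            raise ValueError(f"{self.target}: a HarmonizedSet needs >= 1 row")
        if rows["snp_id"].duplicated().any():
            dups = rows.loc[rows["snp_id"].duplicated(), "snp_id"].tolist()
            raise ValueError(f"{self.target}: duplicate snp_ids {dups}")
        for col in ("se_exposure", "se_outcome"):
            if not (rows[col] > 0).all():
                raise ValueError(f"{self.target}: {col} must be positive")
        self.rows = rows[HARMONIZED_COLUMNS].copy()

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def n_snp(self) -> int:
        return len(self.rows)

    @property
    def snp_ids(self) -> list[str]:
        return self.rows["snp_id"].tolist()

    # Short accessors used throughout the estimators.
    @property
    def bx(self) -> np.ndarray:
        return self.rows["beta_exposure"].to_numpy(float)

    @property
    def sx(self) -> np.ndarray:
        return self.rows["se_exposure"].to_numpy(float)

    @property
    def by(self) -> np.ndarray:
        return self.rows["beta_outcome"].to_numpy(float)

    @property
    def sy(self) -> np.ndarray:
        return self.rows["se_outcome"].to_numpy(float)

    def subset(self, mask: np.ndarray | list[bool] | list[int]) -> "HarmonizedSet":
        """Return a new set restricted to ``mask`` (boolean or index array)."""
        sub = self.rows.iloc[np.asarray(mask)] if np.asarray(mask).dtype != bool else self.rows[np.asarray(mask)]
        return HarmonizedSet(self.target, sub.reset_index(drop=True), self.outcome_id)

    def drop_snp(self, snp_id: str) -> "HarmonizedSet":
        """Return a new set with ``snp_id`` removed (for leave-one-out)."""
        return HarmonizedSet(
            self.target,
            self.rows[self.rows["snp_id"] != snp_id].reset_index(drop=True),
            self.outcome_id,
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_id: str = "",
) -> list[SummaryStat]:
    """Read a headered, tab-separated summary-statistics file.

    Rows whose beta or SE fail to parse as finite positive-SE reals are
    dropped (and counted in the log), mirroring the tolerant ingestion that
    real GWAS exports require.  Row order is preserved.

    Raises
    ------
    ConfigurationError
        If a mandatory mapped column is absent, naming the column.
    EmptyInputError
        If the file holds a header but no data rows.
    """
    path = Path(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for field_name in _MANDATORY_FIELDS:
        if cmap[field_name] not in df.columns:
            raise ConfigurationError(
                f"{path}: mandatory column {cmap[field_name]!r} (for "
                f"{field_name!r}) not found; present: {list(df.columns)}"
            )
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no data rows")

    # Python's float() is a correctly rounded parser; pandas' fast path is
    # not round-trip-exact at extreme exponents.
    def _numeric(col: pd.Series) -> pd.Series:
        def conv(v: object) -> float:
            try:
                return float(v)
            except (TypeError, ValueError):
                return float("nan")

        return col.map(conv)

    beta = _numeric(df[cmap["beta"]])
    se = _numeric(df[cmap["se"]])
    pval = _numeric(df[cmap["pval"]])
    ok = beta.notna() & se.notna() & (se > 0) & pval.notna()
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("%s: dropped %d rows with unparseable beta/se/p", path, n_dropped)

    has_other = cmap["other_allele"] in df.columns
    has_eaf = cmap["eaf"] in df.columns
    has_n = cmap["n"] in df.columns
    eaf = pd.to_numeric(df[cmap["eaf"]], errors="coerce") if has_eaf else None
    nn = pd.to_numeric(df[cmap["n"]], errors="coerce") if has_n else None

    out: list[SummaryStat] = []
    for i in df.index[ok]:
        out.append(
            SummaryStat(
                snp_id=str(df.at[i, cmap["snp_id"]]),
                effect_allele=str(df.at[i, cmap["effect_allele"]]),
                other_allele=(
                    str(df.at[i, cmap["other_allele"]])
                    if has_other and pd.notna(df.at[i, cmap["other_allele"]])
                    else None
                ),
                beta=float(beta[i]),
                se=float(se[i]),
                pval=float(np.clip(pval[i], np.nextafter(0, 1), 1.0)),
                eaf=float(eaf[i]) if eaf is not None and pd.notna(eaf[i]) and 0 < eaf[i] < 1 else None,
                n=float(nn[i]) if nn is not None and pd.notna(nn[i]) else None,
                trait_id=trait_id,
            )
        )
    return out


def write_summary_stats(stats: Iterable[SummaryStat], path: str | Path) -> None:
    """Write summary statistics as a headered TSV, full ``repr`` precision."""
    rows = []
    for s in stats:
        rows.append(
            {
                "SNP": s.snp_id,
                "effect_allele": s.effect_allele,
                "other_allele": s.other_allele if s.other_allele is not None else "",
                "beta": repr(s.beta),
                "se": repr(s.se),
                "pval": repr(s.pval),
                "eaf": repr(s.eaf) if s.eaf is not None else "",
                "n": repr(s.n) if s.n is not None else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gene_regions(path: str | Path) -> dict[str, GeneRegion]:
    """Read gene regions from a BED file (3+ columns, 0-based half-open).

    Column 4, when present, is the gene symbol; otherwise a symbol is
    synthesised from the coordinates.  Returns a gene → region mapping.
    """
    regions: dict[str, GeneRegion] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ConfigurationError(f"{path}: BED line with <3 columns: {line!r}")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            gene = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
            strand = parts[5] if len(parts) > 5 and parts[5] in {"+", "-"} else "."
            regions[gene] = GeneRegion(chrom, start, end, gene, strand)
    return regions


def read_snp_positions(path: str | Path) -> dict[str, tuple[str, int]]:
    """Read SNP positions from a headered TSV (snp_id, chrom, pos)."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str, "pos": int})
    for col in ("snp_id", "chrom", "pos"):
        if col not in df.columns:
            raise ConfigurationError(f"{path}: positions file lacks column {col!r}")
    return {r.snp_id: (r.chrom, int(r.pos)) for r in df.itertuples()}


# ---------------------------------------------------------------------------
# Harmonisation
# ---------------------------------------------------------------------------

def _complement(allele: str) -> str:
    table = {"A": "T", "T": "A", "C": "G", "G": "C"}
    return "".join(table.get(b, b) for b in allele)


def harmonize(
    exposure: list[SummaryStat],
    outcome: list[SummaryStat],
    palindrome_policy: str = "drop",
    ambiguity_band: tuple[float, float] = (0.42, 0.58),
) -> HarmonizedSet:
    """Align outcome statistics to the exposure's effect allele per SNP.

    The exposure defines the reference coding.  Where the outcome reports
    the opposite allele (directly, or on the complementary strand for
    non-palindromic SNPs), the outcome beta sign is flipped and its EAF
    complemented.  Palindromic SNPs (A/T, C/G), whose strand cannot be told
    from allele letters, are handled per ``palindrome_policy``:

    ``drop``
        exclude them (conservative default);
    ``keep``
        trust that both studies report the same strand and align by letter;
    ``freq-infer``
        use allele frequencies to orient, dropping SNPs whose EAF falls in
        ``ambiguity_band`` on either side or is missing.

    Result rows are ordered by snp_id.  SNPs with irreconcilable alleles are
    dropped and logged.

    Raises
    ------
    NoOverlapError
        If no SNP survives intersection and allele reconciliation.
    """
    if palindrome_policy not in {"drop", "keep", "freq-infer"}:
        raise ConfigurationError(f"unknown palindrome_policy {palindrome_policy!r}")
    if not exposure or not outcome:
        raise NoOverlapError("harmonize: empty exposure or outcome list")

    exp_by_id = {s.snp_id: s for s in exposure}
    out_by_id = {s.snp_id: s for s in outcome}
    shared = sorted(set(exp_by_id) & set(out_by_id))

    records = []
    for snp in shared:
        e, o = exp_by_id[snp], out_by_id[snp]
        if e.degenerate or o.degenerate:
            continue
        flip: bool | None = None
        if e.is_palindromic:
            if palindrome_policy == "drop":
                logger.info("harmonize: dropping palindromic SNP %s", snp)
                continue
            if palindrome_policy == "keep":
                flip = _letter_alignment(e, o)
            else:  # freq-infer
                flip = _freq_alignment(e, o, ambiguity_band)
        else:
            flip = _letter_alignment(e, o)
            if flip is None:
                # try the complementary strand for the outcome coding
                flip = _letter_alignment(e, o, complement=True)
        if flip is None:
            logger.warning("harmonize: allele mismatch at %s (%s/%s vs %s/%s), dropped",
                           snp, e.effect_allele, e.other_allele,
                           o.effect_allele, o.other_allele)
            continue
        beta_out = -o.beta if flip else o.beta
        records.append(
            {
                "snp_id": snp,
                "beta_exposure": e.beta,
                "se_exposure": e.se,
                "p_exposure": e.pval,
                "beta_outcome": beta_out,
                "se_outcome": o.se,
                "p_outcome": o.pval,
                "r2_exposure": np.nan,
                "f_stat": np.nan,
            }
        )
    if not records:
        raise NoOverlapError(
            "harmonize: no SNPs shared between exposure and outcome after "
            "allele reconciliation"
        )
    target = exposure[0].trait_id or ""
    outcome_id = outcome[0].trait_id or ""
    return HarmonizedSet(target=target, rows=pd.DataFrame(records), outcome_id=outcome_id)


def _letter_alignment(e: SummaryStat, o: SummaryStat, complement: bool = False) -> bool | None:
    """Return False (aligned), True (flip), or None (irreconcilable)."""
    oe = _complement(o.effect_allele) if complement else o.effect_allele
    oo = _complement(o.other_allele) if complement and o.other_allele else o.other_allele
    if oe == e.effect_allele and (oo is None or e.other_allele is None or oo == e.other_allele):
        return False
    if oe == e.other_allele or (oo is not None and oo == e.effect_allele):
        return True
    return None


def _freq_alignment(e: SummaryStat, o: SummaryStat, band: tuple[float, float]) -> bool | None:
    lo, hi = band
    if e.eaf is None or o.eaf is None:
        return None
    if lo < e.eaf < hi or lo < o.eaf < hi:
        return None  # too close to 0.5 to orient
    return (e.eaf < 0.5) != (o.eaf < 0.5)


# ---------------------------------------------------------------------------
# Bundled ovarian-cancer instrument table
# ---------------------------------------------------------------------------

def _fixture_frame() -> pd.DataFrame:
    with resources.files("targetmr.data").joinpath(_FIXTURE_RESOURCE).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_ovarian_instruments(target: str = "all") -> HarmonizedSet | dict[str, HarmonizedSet]:
    """Load the bundled cis-instrument table for ovarian-cancer drug targets.

    The table holds 77 instruments across 11 drug-target genes, each row
    carrying the exposure association (beta, SE, p relative to allele A1),
    the aligned ovarian-cancer outcome association, the per-SNP variance
    explained (R²) and F-statistic.  The rows are pre-harmonised: the
    outcome beta already refers to the exposure's effect allele, so the
    table feeds the estimators directly.

    Each target carries an outcome cohort label (``ieu-a-1120`` — the
    ovarian-cancer consortium GWAS — or ``ieu-b-4963`` — the biobank GWAS).
    The per-target assignment is inferred from how the source results were
    reported, not stated row-by-row, and should be treated as a label only.

    Parameters
    ----------
    target : str
        A gene symbol from :data:`FIXTURE_TARGETS`, or ``"all"`` for a
        dict mapping every symbol to its set.

    Raises
    ------
    UnknownTargetError
        For symbols not in the table; the message lists valid names.
    """
    df = _fixture_frame()
    rename = {
        "SNP": "snp_id",
        "beta_exp": "beta_exposure",
        "se_exp": "se_exposure",
        "p_exp": "p_exposure",
        "beta_out": "beta_outcome",
        "se_out": "se_outcome",
        "p_out": "p_outcome",
        "R2": "r2_exposure",
        "F": "f_stat",
    }
    df = df.rename(columns=rename)

    def one(sym: str) -> HarmonizedSet:
        block = df[df["TARGET"] == sym]
        return HarmonizedSet(
            target=sym,
            rows=block[HARMONIZED_COLUMNS].reset_index(drop=True),
            outcome_id=str(block["OUTCOME"].iloc[0]),
        )

    if target == "all":
        return {sym: one(sym) for sym in FIXTURE_TARGETS}
    if target not in FIXTURE_TARGETS:
        raise UnknownTargetError(
            f"unknown target {target!r}; valid: {', '.join(FIXTURE_TARGETS)} or 'all'"
        )
    return one(target)
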