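"""Orchestration: per-target stage order, full runs, and TSV reports.

The per-target stage order is the standard drug-target MR recipe:

    select_cis -> ld_clump -> harmonize -> filter_weak
        -> estimators (wald / ivw / egger / weighted median)
        -> sensitivity (Q, Egger intercept, PRESSO, leave-one-out)

Targets are isolated: a target that yields no instruments (or fails any
stage) is reported as *skipped* with a reason and never aborts the run —
the screening workflow this implements drops unretrievable targets rather
than failing on them.

Method naming in reports: ``ivw`` is the default multiplicative
random-effects-floored estimator; ``wald`` denotes the fixed-effect
inverse-variance combination of the per-SNP Wald ratios (identical to the
single-SNP Wald ratio when only one instrument remains); ``egger`` and
``weighted_median`` are as in :mod:`targetmr.mr_core`.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .drugmap import AnalysisUnit, build_analysis_units, dedupe_by_target_set, load_drug_targets
from .exceptions import ConfigurationError, TargetMRError
from .instruments import (
    GenotypeRef,
    InstrumentCriteria,
    annotate_strength,
    filter_weak,
    ld_clump,
    read_genotype_ref,
    select_cis,
)
from .mr_core import MREstimate, egger, ivw, weighted_median
from .sensitivity import SensitivityReport, sensitivity_report
from .summary_data import (
    HarmonizedSet,
    SummaryStat,
    harmonize,
    load_ovarian_instruments,
    read_gene_regions,
    read_snp_positions,
    read_summary_stats,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "TargetResult",
    "setup_logging",
    "estimate_all_methods",
    "run_target",
    "run_fixture",
    "run_all",
    "write_report",
]

_METHOD_ORDER = ("ivw", "egger", "weighted_median", "wald")


def setup_logging(level: int = logging.INFO, logfile: str | Path | None = None) -> None:
    """Structured logging to stderr, optionally duplicated to a file."""
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


@dataclass
class RunConfig:
    """Everything a full pipeline run needs.

    Paths may be None when the corresponding stage is bypassed (e.g.
    ``fixture=True`` runs the bundled instrument table and needs no input
    files at all).
    """

    drug_table: str | None = None
    regions: str | None = None
    exposure_stats: str | None = None
    outcome_stats: str | None = None
    positions: str | None = None
    genotype_ref: str | None = None
    fixture: bool = False
    criteria: InstrumentCriteria = field(default_factory=InstrumentCriteria)
    ivw_mode: str = "mre_floor"
    palindrome_policy: str = "drop"
    n_boot: int = 10_000
    presso_n_sim: int = 1_000
    seed: int = 0
    outdir: str = "targetmr_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        crit_keys = {"window_bp", "p_threshold", "r2_threshold", "f_min"}
        criteria = InstrumentCriteria(**{k: raw.pop(k) for k in list(raw) if k in crit_keys})
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(criteria=criteria, **raw)

    def validate(self) -> None:
        """Fail fast on unusable configuration, before any analysis."""
        if not self.fixture:
            required = {
                "drug_table": self.drug_table,
                "regions": self.regions,
                "exposure_stats": self.exposure_stats,
                "outcome_stats": self.outcome_stats,
                "positions": self.positions,
            }
            for name, p in required.items():
                if p is None:
                    raise ConfigurationError(f"config: {name} is required unless fixture=True")
                if not Path(p).exists():
                    raise ConfigurationError(f"config: {name} path does not exist: {p}")
            if self.genotype_ref is not None and not Path(self.genotype_ref).exists():
                raise ConfigurationError(f"config: genotype_ref path does not exist: {self.genotype_ref}")
        if self.n_boot <= 0 or self.presso_n_sim <= 0:
            raise ConfigurationError("n_boot and presso_n_sim must be positive")


@dataclass
class TargetResult:
    """Outcome of one (drug, target) analysis: estimates or a skip reason."""

    target: str
    drug: str
    outcome_id: str
    estimates: dict[str, MREstimate] = field(default_factory=dict)
    sensitivity: SensitivityReport | None = None
    n_snp: int = 0
    skipped: str | None = None


def estimate_all_methods(
    hset: HarmonizedSet,
    ivw_mode: str = "mre_floor",
    n_boot: int = 10_000,
    seed: int = 0,
) -> dict[str, MREstimate]:
    """All four estimators on one harmonised set.

    ``egger`` and ``weighted_median`` need >= 3 instruments and are
    omitted below that; ``wald`` (the fixed-effect ratio combination) and
    ``ivw`` are always present.
    """
    out: dict[str, MREstimate] = {}
    est_ivw = ivw(hset, mode=ivw_mode)
    out["ivw"] = est_ivw
    fixed = ivw(hset, mode="fixed")
    out["wald"] = MREstimate(
        "wald", fixed.beta, fixed.se, fixed.pval, fixed.or_,
        fixed.ci_low, fixed.ci_high, fixed.n_snp, fixed.level,
    )
    if hset.n_snp >= 3:
        out["egger"] = egger(hset)[0]
        out["weighted_median"] = weighted_median(hset, n_boot=n_boot, seed=seed)
    return out


def run_target(
    unit: AnalysisUnit,
    exposure_stats: list[SummaryStat],
    outcome_stats: list[SummaryStat],
    positions: dict[str, tuple[str, int]],
    ref: GenotypeRef | None,
    config: RunConfig,
) -> TargetResult:
    """Full per-target pipeline; errors become a skip, never an abort."""
    result = TargetResult(target=unit.target, drug=unit.drug, outcome_id="")
    try:
        cis = select_cis(exposure_stats, unit.region, positions, unit.criteria)
        if not cis:
            result.skipped = "no instruments"
            logger.info("%s: skipped (%s)", unit.target, result.skipped)
            return result
        if ref is not None:
            cis = ld_clump(cis, ref, unit.criteria.r2_threshold)
        hset = harmonize(cis, outcome_stats, palindrome_policy=config.palindrome_policy)
        hset = HarmonizedSet(unit.target, hset.rows, hset.outcome_id)
        eaf = {s.snp_id: s.eaf for s in cis if s.eaf is not None}
        n_exp = next((s.n for s in cis if s.n is not None), None)
        if n_exp is not None and len(eaf) == len(hset):
            hset = annotate_strength(hset, n=n_exp, eaf=eaf)
        else:
            hset = annotate_strength(hset)
        hset = filter_weak(hset, unit.criteria.f_min)
        result.outcome_id = hset.outcome_id
        result.n_snp = hset.n_snp
        result.estimates = estimate_all_methods(
            hset, ivw_mode=config.ivw_mode, n_boot=config.n_boot, seed=config.seed
        )
        result.sensitivity = sensitivity_report(
            hset, n_sim=config.presso_n_sim, seed=config.seed, ivw_mode=config.ivw_mode
        )
    except TargetMRError as exc:
        result.skipped = f"{type(exc).__name__}: {exc}"
        logger.warning("%s: skipped (%s)", unit.target, result.skipped)
    return result


def run_fixture(config: RunConfig | None = None) -> list[TargetResult]:
    """Analyse the bundled ovarian-cancer instrument table (selection bypassed).

    The bundled rows are already harmonised and graded, so the run goes
    straight to the estimators and diagnostics, one target at a time, in
    alphabetical target order.
    """
    config = config or RunConfig(fixture=True)
    results = []
    sets = load_ovarian_instruments("all")
    for target in sorted(sets):
        hset = sets[target]
        res = TargetResult(target=target, drug="", outcome_id=hset.outcome_id, n_snp=hset.n_snp)
        res.estimates = estimate_all_methods(
            hset, ivw_mode=config.ivw_mode, n_boot=config.n_boot, seed=config.seed
        )
        res.sensitivity = sensitivity_report(
            hset, n_sim=config.presso_n_sim, seed=config.seed, ivw_mode=config.ivw_mode
        )
        results.append(res)
    return results


def run_all(config: RunConfig) -> list[TargetResult]:
    """Run every analysis unit of a configured study.

    Fails fast on invalid configuration; afterwards each target is
    isolated (log-and-continue).  Returns results in deterministic
    (target, drug) order.
    """
    config.validate()
    if config.fixture:
        results = run_fixture(config)
    else:
        records = dedupe_by_target_set(load_drug_targets(config.drug_table))
        regions = read_gene_regions(config.regions)
        units = build_analysis_units(records, regions, config.criteria)
        exposure = read_summary_stats(config.exposure_stats, trait_id="exposure")
        outcome = read_summary_stats(config.outcome_stats, trait_id="outcome")
        positions = read_snp_positions(config.positions)
        ref = read_genotype_ref(config.genotype_ref) if config.genotype_ref else None
        results = [
            run_target(u, exposure, outcome, positions, ref, config)
            for u in sorted(units, key=lambda u: (u.target, u.drug))
        ]
    analysed = [r for r in results if r.skipped is None]
    logger.info(
        "run_all: %d targets analysed (%d SNPs), %d skipped",
        len(analysed),
        sum(r.n_snp for r in analysed),
        len(results) - len(analysed),
    )
    return results


def _fmt(x: float) -> str:
    return f"{x:.12g}"


def write_report(results: list[TargetResult], outdir: str | Path) -> dict[str, Path]:
    """Serialise a run to three TSVs under ``outdir``.

    ``estimates.tsv``
        one row per (target, method): beta, SE, OR, CI, p, plus a
        Bonferroni-adjusted p across targets per method — a convenience
        column only; the primary screening procedure applies no
        multiple-testing correction.
    ``sensitivity.tsv``
        one row per target: Q, Egger intercept, PRESSO global p/outliers.
    ``leave_one_out.tsv``
        forest-plot-ready rows (target, left_out_snp, OR, CI).

    Skipped targets appear in ``estimates.tsv`` with a ``skipped`` note.
    Numbers are written at 12 significant digits, so a round-trip read
    preserves them.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    est_rows, sens_rows, loo_rows = [], [], []
    n_targets_by_method: dict[str, int] = {}
    for r in results:
        for m in r.estimates:
            n_targets_by_method[m] = n_targets_by_method.get(m, 0) + 1
    for r in results:
        if r.skipped is not None:
            est_rows.append(
                {"target": r.target, "outcome_id": r.outcome_id, "method": "",
                 "n_snp": 0, "beta": "", "se": "", "OR": "", "ci_low": "",
                 "ci_high": "", "pval": "", "pval_bonferroni": "", "skipped": r.skipped}
            )
            continue
        for m in _METHOD_ORDER:
            if m not in r.estimates:
                continue
            e = r.estimates[m]
            bonf = min(e.pval * n_targets_by_method[m], 1.0)
            est_rows.append(
                {"target": r.target, "outcome_id": r.outcome_id, "method": m,
                 "n_snp": e.n_snp, "beta": _fmt(e.beta), "se": _fmt(e.se),
                 "OR": _fmt(e.or_), "ci_low": _fmt(e.ci_low),
                 "ci_high": _fmt(e.ci_high), "pval": _fmt(e.pval),
                 "pval_bonferroni": _fmt(bonf), "skipped": ""}
            )
        s = r.sensitivity
        if s is not None:
            sens_rows.append(
                {"target": r.target, "q": _fmt(s.q), "q_df": s.q_df,
                 "q_pval": _fmt(s.q_pval),
                 "egger_intercept": _fmt(s.egger_intercept),
                 "egger_intercept_se": _fmt(s.egger_intercept_se),
                 "egger_intercept_pval": _fmt(s.egger_intercept_pval),
                 "presso_global_pval": _fmt(s.presso_global_pval),
                 "presso_outliers": ",".join(s.presso_outliers)}
            )
            for row in s.loo:
                e = row["estimate"]
                loo_rows.append(
                    {"target": r.target, "left_out_snp": row["left_out_snp"],
                     "OR": _fmt(e.or_), "ci_low": _fmt(e.ci_low),
                     "ci_high": _fmt(e.ci_high), "pval": _fmt(e.pval)}
                )
    est_cols = ["target", "outcome_id", "method", "n_snp", "beta", "se", "OR",
                "ci_low", "ci_high", "pval", "pval_bonferroni", "skipped"]
    sens_cols = ["target", "q", "q_df", "q_pval", "egger_intercept",
                 "egger_intercept_se", "egger_intercept_pval",
                 "presso_global_pval", "presso_outliers"]
    loo_cols = ["target", "left_out_snp", "OR", "ci_low", "ci_high", "pval"]
    paths = {
        "estimates": outdir / "estimates.tsv",
        "sensitivity": outdir / "sensitivity.tsv",
        "leave_one_out": outdir / "leave_one_out.tsv",
    }
    pd.DataFrame(est_rows, columns=est_cols).to_csv(paths["estimates"], sep="\t", index=False)
    pd.DataFrame(sens_rows, columns=sens_cols).to_csv(paths["sensitivity"], sep="\t", index=False)
    pd.DataFrame(loo_rows, columns=loo_cols).to_csv(paths["leave_one_out"], sep="\t", index=False)
    return paths
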