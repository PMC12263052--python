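"""Panel screening and bidirectional classification.

``run_mr_suite`` chains instrument QC (p-threshold, confounder exclusion,
LD clumping, F filter), harmonization, and the full estimator battery for
one exposure-outcome pair.  ``run_panel`` maps it over a panel of exposures
and flags the significant subset by the IVW p-value, the primary analysis.
``reverse_mr``/``classify_direction`` implement bidirectional screening:
a trait significant in both directions is labelled bidirectional and
excluded from downstream mediation, since reverse causation disqualifies it
as a clean exposure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import (DataError, EmptyOverlapError, InsufficientInstrumentsError,
                     NoInstrumentsError, PairingError)
from .estimators import (EggerIntercept, MREstimate, QTest, ivw, mr_egger,
                         weighted_median, weighted_mode)
from .gwas_io import HarmonizedSet, SummaryDataset, harmonize
from .instruments import (InstrumentCriteria, LDMatrix, exclude_snps,
                          f_filter, ld_clump, select_by_pvalue)
from .synthetic import derive_seed

logger = logging.getLogger("mrchain.screening")

DEFAULT_METHODS = ("ivw_fixed", "ivw_random", "egger",
                   "weighted_median", "weighted_mode")

#: IVW flavor whose p-value defines "significant" throughout screening
PRIMARY_METHOD = "ivw_random"


@dataclass
class MRSuiteResult:
    """Full estimator battery for one exposure-outcome pair."""

    exposure_id: str
    outcome_id: str
    direction: str  # "forward" | "reverse"
    k: int
    estimates: dict[str, MREstimate]
    skipped: dict[str, str]
    q: Optional[QTest]
    egger_intercept: Optional[EggerIntercept]
    harmonized: Optional[HarmonizedSet] = None
    qc_tally: dict = field(default_factory=dict)

    @property
    def primary(self) -> MREstimate:
        return self.estimates[PRIMARY_METHOD]

    def is_significant(self, alpha: float) -> bool:
        return self.primary.pval < alpha


@dataclass
class PanelRow:
    trait_id: str
    status: str  # "ok" or an error tag
    result: Optional[MRSuiteResult] = None
    message: str = ""


@dataclass
class PanelResult:
    """Per-exposure suite results plus the significant subset."""

    outcome_id: str
    direction: str
    rows: list[PanelRow]
    alpha: float

    @property
    def results(self) -> list[MRSuiteResult]:
        return [r.result for r in self.rows if r.status == "ok"]

    @property
    def significant(self) -> list[MRSuiteResult]:
        sig = [r for r in self.results if r.is_significant(self.alpha)]
        return sorted(sig, key=lambda r: (r.primary.pval, r.exposure_id))

    def summary_frame(self) -> pd.DataFrame:
        """One row per exposure with primary estimate, nominal and BH-FDR p."""
        rows = []
        for row in self.rows:
            rec = {"trait_id": row.trait_id, "status": row.status,
                   "direction": self.direction}
            if row.status == "ok":
                est = row.result.primary
                rec.update(k=row.result.k, beta=est.beta, se=est.se,
                           pval=est.pval, or_=est.or_, ci_low=est.ci_low,
                           ci_high=est.ci_high,
                           significant=est.pval < self.alpha)
            else:
                rec["message"] = row.message
            rows.append(rec)
        df = pd.DataFrame(rows)
        if "pval" in df.columns and df["pval"].notna().any():
            mask = df["pval"].notna()
            df.loc[mask, "pval_fdr"] = multipletests(
                df.loc[mask, "pval"], method="fdr_bh")[1]
        if "pval" in df.columns:
            df = df.sort_values("pval", na_position="last",
                                kind="stable").reset_index(drop=True)
        return df


@dataclass
class DirectionClassification:
    """Truth table of forward/reverse significance for one trait pair."""

    pair_id: str
    forward_sig: bool
    reverse_sig: bool
    label: str  # forward_only | reverse_only | bidirectional | null
    mediation_eligible: bool


def select_instruments(exposure: SummaryDataset,
                       criteria: InstrumentCriteria,
                       ld: Optional[LDMatrix] = None) -> SummaryDataset:
    """QC chain: p-threshold -> confounder exclusion -> clump -> F filter."""
    sel = select_by_pvalue(exposure, criteria.p_threshold)
    tally = {"candidates": len(exposure), "pass_pvalue": len(sel)}
    sel = exclude_snps(sel, criteria.exclusion_ids)
    tally["pass_exclusion"] = len(sel)
    sel = ld_clump(sel, ld, criteria)
    tally["pass_clump"] = len(sel)
    sel, _ = f_filter(sel, criteria.f_min)
    tally["pass_f"] = len(sel)
    sel.qc_tally.update(tally)
    return sel


def run_mr_suite(exposure: SummaryDataset, outcome: SummaryDataset,
                 criteria: InstrumentCriteria = InstrumentCriteria(),
                 ld: Optional[LDMatrix] = None,
                 direction: str = "forward",
                 methods: tuple = DEFAULT_METHODS,
                 n_boot: int = 1000, seed: int = 0,
                 bandwidth_phi: float = 1.0) -> MRSuiteResult:
    """Instrument selection, harmonization and all requested estimators.

    Estimators whose k precondition fails are recorded in ``skipped`` with
    reason ``insufficient_instruments`` rather than raising.  Raises
    :class:`NoInstrumentsError` when no instrument survives QC or none
    overlaps the outcome.
    """
    sel = select_instruments(exposure, criteria, ld)
    if len(sel) == 0:
        raise NoInstrumentsError(
            f"no instruments survive QC for {exposure.trait_id}",
            tally=sel.qc_tally)
    try:
        h = harmonize(sel, outcome)
    except EmptyOverlapError as exc:
        raise NoInstrumentsError(str(exc), tally=sel.qc_tally)

    estimates: dict[str, MREstimate] = {}
    skipped: dict[str, str] = {}
    q = egger_int = None
    for method in methods:
        try:
            if method == "ivw_fixed":
                estimates[method], q0 = ivw(h, mode="fixed")
                q = q if q is not None else q0
            elif method == "ivw_random":
                estimates[method], q = ivw(h, mode="random")
            elif method == "egger":
                estimates[method], egger_int = mr_egger(h)
            elif method == "weighted_median":
                estimates[method] = weighted_median(h, n_boot, seed)
            elif method == "weighted_mode":
                estimates[method] = weighted_mode(h, bandwidth_phi,
                                                  n_boot, seed)
            else:
                raise DataError(f"unknown method {method!r}")
        except InsufficientInstrumentsError:
            skipped[method] = "insufficient_instruments"
    return MRSuiteResult(exposure.trait_id, outcome.trait_id, direction,
                         h.k, estimates, skipped, q, egger_int,
                         harmonized=h, qc_tally=sel.qc_tally)


def run_panel(exposures, outcome: SummaryDataset,
              criteria: InstrumentCriteria = InstrumentCriteria(),
              ld: Optional[LDMatrix] = None, alpha: float = 0.05,
              direction: str = "forward",
              methods: tuple = DEFAULT_METHODS,
              n_boot: int = 1000, seed: int = 0) -> PanelResult:
    """Run the MR suite for every exposure; failures become rows, not errors.

    Significance is the nominal IVW p < alpha (default 0.05) with a BH-FDR
    column available in :meth:`PanelResult.summary_frame`.
    """
    if not (0 < alpha <= 1):
        raise DataError(f"alpha must be in (0, 1], got {alpha}")
    rows = []
    for i, exp in enumerate(exposures):
        try:
            res = run_mr_suite(exp, outcome, criteria, ld, direction,
                               methods, n_boot, seed=derive_seed(seed, i))
            rows.append(PanelRow(exp.trait_id, "ok", res))
        except NoInstrumentsError as exc:
            logger.warning("panel exposure %s: %s", exp.trait_id, exc)
            rows.append(PanelRow(exp.trait_id, "no_instruments",
                                 message=str(exc)))
        except DataError as exc:
            logger.warning("panel exposure %s: %s", exp.trait_id, exc)
            rows.append(PanelRow(exp.trait_id, "error", message=str(exc)))
    return PanelResult(outcome.trait_id, direction, rows, alpha)


def reverse_mr(outcome_as_exposure: SummaryDataset,
               exposure_as_outcome: SummaryDataset,
               criteria: InstrumentCriteria = InstrumentCriteria(),
               ld: Optional[LDMatrix] = None, **kwargs) -> MRSuiteResult:
    """MR with the roles swapped: the disease drives, the trait responds."""
    kwargs.setdefault("direction", "reverse")
    return run_mr_suite(outcome_as_exposure, exposure_as_outcome,
                        criteria, ld, **kwargs)


def classify_direction(forward: MRSuiteResult, reverse: MRSuiteResult,
                       alpha: float = 0.05) -> DirectionClassification:
    """Truth-table classification of one pair from both directions.

    Bidirectional pairs are flagged mediation-ineligible: a significant
    reverse effect means the trait cannot serve as a clean exposure in
    two-step mediation.
    """
    if (forward.exposure_id != reverse.outcome_id
            or forward.outcome_id != reverse.exposure_id):
        raise PairingError(
            f"mismatched pair: forward {forward.exposure_id}->"
            f"{forward.outcome_id} vs reverse {reverse.exposure_id}->"
            f"{reverse.outcome_id}")
    fsig = forward.is_significant(alpha)
    rsig = reverse.is_significant(alpha)
    label = {(True, True): "bidirectional", (True, False): "forward_only",
             (False, True): "reverse_only", (False, False): "null"}[(fsig, rsig)]
    return DirectionClassification(
        pair_id=f"{forward.exposure_id}|{forward.outcome_id}",
        forward_sig=fsig, reverse_sig=rsig, label=label,
        mediation_eligible=(label == "forward_only"))
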