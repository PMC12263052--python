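"""Two-step MR mediation: decompose a total effect into direct and mediated.

For a triplet exposure X -> mediator M -> outcome Y, two univariable MR fits
(X->M and M->Y) give the mediated path; combined with the total X->Y effect,

* product of coefficients: indirect = beta_xm * beta_my,
  direct = total - indirect;
* difference method: direct comes from multivariable IVW (X and M jointly
  instrumenting Y), indirect = total - direct.

The proportion mediated is indirect/total.  SEs use the delta method with
cross-estimate covariances set to zero (three non-overlapping samples).
Proportions outside [0, 1] or with an indirect effect whose sign opposes the
total are reported with flags, never truncated.

``screen_mediators`` applies the two-step gate the screening design implies:
a triplet is quantified only when both the X->M and the M->Y IVW p-values
pass the significance level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import stats

from .errors import (DataError, NoInstrumentsError, UndefinedProportionError)
from .estimators import MREstimate, mvmr_ivw
from .gwas_io import SummaryDataset, harmonize
from .instruments import InstrumentCriteria, LDMatrix
from .screening import MRSuiteResult, run_mr_suite, select_instruments
from .synthetic import derive_seed

logger = logging.getLogger("mrchain.mediation")


@dataclass
class MediationEstimate:
    """Total/direct/indirect decomposition for one X-M-Y triplet."""

    exposure_id: str
    mediator_id: str
    outcome_id: str
    method: str  # "product" | "difference"
    beta_total: float
    beta_xm: float
    beta_my: float
    indirect: float
    indirect_se: float
    direct: float
    prop_mediated: float
    prop_se: float
    pval_indirect: float
    sign_consistent: bool = True
    flags: list[str] = field(default_factory=list)


def _normal_p(est: float, se: float) -> float:
    if se <= 0:
        return float("nan")
    return float(2.0 * stats.norm.sf(abs(est) / se))


def _finish(exposure_id, mediator_id, outcome_id, method, total,
            beta_xm, beta_my, indirect, indirect_se) -> MediationEstimate:
    direct = total.beta - indirect
    pval = _normal_p(indirect, indirect_se)
    flags: list[str] = []
    sign_ok = bool(np.sign(indirect) == np.sign(total.beta)) or indirect == 0
    if total.beta == 0:
        est = MediationEstimate(
            exposure_id, mediator_id, outcome_id, method, total.beta,
            beta_xm, beta_my, indirect, indirect_se, direct,
            float("nan"), float("nan"), pval, sign_ok,
            ["undefined_proportion"])
        raise UndefinedProportionError(
            f"total effect is zero for {exposure_id}->{outcome_id}; "
            "proportion mediated undefined", estimate=est)
    prop = indirect / total.beta
    # delta method, indirect and total treated as independent
    prop_se = float(np.sqrt(
        (indirect_se / total.beta) ** 2
        + (indirect * total.se / total.beta**2) ** 2))
    if not sign_ok:
        flags.append("sign_inconsistent")
    if not (0.0 <= prop <= 1.0):
        flags.append("prop_outside_unit")
    return MediationEstimate(
        exposure_id, mediator_id, outcome_id, method, total.beta,
        beta_xm, beta_my, indirect, indirect_se, direct,
        prop, prop_se, pval, sign_ok, flags)


def mediation_product(total: MREstimate, xm: MREstimate, my: MREstimate,
                      exposure_id: str = "X", mediator_id: str = "M",
                      outcome_id: str = "Y") -> MediationEstimate:
    """Product-of-coefficients decomposition.

    indirect = beta_xm * beta_my with delta-method SE
    sqrt(beta_my^2 se_xm^2 + beta_xm^2 se_my^2); direct = total - indirect.
    """
    indirect = xm.beta * my.beta
    indirect_se = float(np.sqrt(
        my.beta**2 * xm.se**2 + xm.beta**2 * my.se**2))
    return _finish(exposure_id, mediator_id, outcome_id, "product",
                   total, xm.beta, my.beta, indirect, indirect_se)


def mediation_difference(total: MREstimate, direct_mvmr: MREstimate,
                         exposure_id: str = "X", mediator_id: str = "M",
                         outcome_id: str = "Y",
                         beta_xm: float = float("nan"),
                         beta_my: float = float("nan")) -> MediationEstimate:
    """Difference-method decomposition.

    ``direct_mvmr`` is the exposure's coefficient from multivariable IVW with
    exposure and mediator modeled jointly; indirect = total - direct with the
    conservative independent-SE combination sqrt(se_total^2 + se_direct^2).
    """
    indirect = total.beta - direct_mvmr.beta
    indirect_se = float(np.sqrt(total.se**2 + direct_mvmr.se**2))
    est = _finish(exposure_id, mediator_id, outcome_id, "difference",
                  total, beta_xm, beta_my, indirect, indirect_se)
    est.direct = direct_mvmr.beta  # report the MVMR direct effect itself
    return est


def mvmr_direct_effect(exposure: SummaryDataset, mediator: SummaryDataset,
                       outcome: SummaryDataset,
                       criteria: InstrumentCriteria = InstrumentCriteria(),
                       ld: Optional[LDMatrix] = None) -> MREstimate:
    """Exposure's direct effect on the outcome, adjusting for the mediator.

    Instruments are the union of the exposure's and the mediator's QC-passing
    instruments; each must be present in all three datasets.  Effects for the
    mediator and the outcome are harmonized to the exposure dataset's allele
    convention before the joint weighted regression.
    """
    inst_x = select_instruments(exposure, criteria, ld)
    inst_m = select_instruments(mediator, criteria, ld)
    wanted = list(dict.fromkeys(inst_x.variant_ids + inst_m.variant_ids))
    if not wanted:
        raise NoInstrumentsError("no instruments for the joint model")
    # exposure rows for the union; mediator-only instruments are looked up in
    # the full exposure GWAS (their exposure effect may be near zero)
    x_rows = exposure.subset(wanted)
    h_xm = harmonize(x_rows, mediator)
    h_xy = harmonize(x_rows, outcome)
    common = [v for v in h_xm.variant_ids if v in set(h_xy.variant_ids)]
    if len(common) <= 2:
        raise NoInstrumentsError(
            f"only {len(common)} variants shared across the three datasets; "
            "joint model needs k > 2")
    ix = {v: i for i, v in enumerate(h_xm.variant_ids)}
    iy = {v: i for i, v in enumerate(h_xy.variant_ids)}
    sel_m = [ix[v] for v in common]
    sel_y = [iy[v] for v in common]
    bx_mat = np.column_stack([h_xy.bx[sel_y], h_xm.by[sel_m]])
    se_mat = np.column_stack([h_xy.se_x[sel_y], h_xm.se_y[sel_m]])
    estimates = mvmr_ivw(bx_mat, se_mat, h_xy.by[sel_y], h_xy.se_y[sel_y])
    return estimates[0]


@dataclass
class MediationScreenRow:
    exposure_id: str
    mediator_id: str
    status: str  # ok | step1_null | step2_null | <error tag>
    estimates: list = field(default_factory=list)
    message: str = ""


def screen_mediators(exposures, mediators, outcome: SummaryDataset,
                     criteria: InstrumentCriteria = InstrumentCriteria(),
                     ld: Optional[LDMatrix] = None, alpha: float = 0.05,
                     methods: tuple = ("ivw_fixed", "ivw_random"),
                     n_boot: int = 1000, seed: int = 0,
                     totals: Optional[dict] = None,
                     exclude_exposure_instruments: bool = True
                     ) -> tuple[list[MediationEstimate], list[MediationScreenRow]]:
    """Quantify mediation for every gated exposure-mediator triplet.

    A triplet is quantified only when both step-1 (X->M) and step-2 (M->Y)
    IVW p-values fall below ``alpha``; others are recorded with the failed
    gate as reason.  ``exposures`` must already be restricted to
    forward-only traits (bidirectional ones excluded upstream).  Pre-computed
    total-effect suites can be passed via ``totals`` (trait_id -> result) to
    avoid refitting X->Y.

    With ``exclude_exposure_instruments`` (default), the mediator-to-outcome
    step drops variants that are QC-passing instruments of the exposure:
    such variants reach the outcome through the exposure's direct path,
    violating the exclusion restriction for the mediator and inflating the
    mediated fraction.  This is the in-silico analogue of screening mediator
    instruments against upstream-trait associations in a variant-phenotype
    database.

    Returns (estimates, per-triplet screen rows); both the product and, when
    the joint model is feasible, the difference method are reported.
    """
    estimates: list[MediationEstimate] = []
    rows: list[MediationScreenRow] = []
    my_cache: dict[tuple, MRSuiteResult] = {}
    totals = dict(totals or {})
    for i, exposure in enumerate(exposures):
        step2_criteria = criteria
        if exclude_exposure_instruments:
            x_inst = select_instruments(exposure, criteria, ld)
            step2_criteria = replace(
                criteria, exclusion_ids=frozenset(
                    criteria.exclusion_ids | set(x_inst.variant_ids)))
        try:
            total_res = totals.get(exposure.trait_id) or run_mr_suite(
                exposure, outcome, criteria, ld, methods=methods,
                n_boot=n_boot, seed=derive_seed(seed, i, 0))
        except DataError as exc:
            for mediator in mediators:
                rows.append(MediationScreenRow(
                    exposure.trait_id, mediator.trait_id, "total_failed",
                    message=str(exc)))
            continue
        total = total_res.primary
        for j, mediator in enumerate(mediators):
            row = MediationScreenRow(exposure.trait_id, mediator.trait_id, "ok")
            rows.append(row)
            try:
                xm_res = run_mr_suite(exposure, mediator, criteria, ld,
                                      methods=methods, n_boot=n_boot,
                                      seed=derive_seed(seed, i, j, 1))
                if xm_res.primary.pval >= alpha:
                    row.status = "step1_null"
                    continue
                cache_key = (exposure.trait_id if exclude_exposure_instruments
                             else None, mediator.trait_id)
                if cache_key not in my_cache:
                    my_cache[cache_key] = run_mr_suite(
                        mediator, outcome, step2_criteria, ld,
                        methods=methods, n_boot=n_boot,
                        seed=derive_seed(seed, j, 2))
                my_res = my_cache[cache_key]
                if my_res.primary.pval >= alpha:
                    row.status = "step2_null"
                    continue
                prod = mediation_product(
                    total, xm_res.primary, my_res.primary,
                    exposure.trait_id, mediator.trait_id, outcome.trait_id)
                row.estimates.append(prod)
                estimates.append(prod)
                try:
                    direct = mvmr_direct_effect(exposure, mediator, outcome,
                                                criteria, ld)
                    diff = mediation_difference(
                        total, direct, exposure.trait_id, mediator.trait_id,
                        outcome.trait_id, beta_xm=xm_res.primary.beta,
                        beta_my=my_res.primary.beta)
                    row.estimates.append(diff)
                    estimates.append(diff)
                except DataError as exc:
                    logger.info("difference method unavailable for %s|%s: %s",
                                exposure.trait_id, mediator.trait_id, exc)
            except UndefinedProportionError as exc:
                row.status = "undefined_proportion"
                row.message = str(exc)
            except DataError as exc:
                row.status = "error"
                row.message = str(exc)
    return estimates, rows
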