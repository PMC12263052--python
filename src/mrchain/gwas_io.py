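"""Reading, validating and harmonizing GWAS summary statistics.

A summary-statistics table has one row per variant with the effect estimate of
that variant on one trait.  The canonical column set is

    variant_id  chrom  pos  effect_allele  other_allele  eaf  beta  se  pval  n

with ``beta`` the per-allele effect on the trait (log-odds for binary traits,
SD units for continuous ones) aligned to ``effect_allele``, ``se`` its
standard error, and ``eaf`` the effect-allele frequency (optional, but needed
to resolve palindromic variants during harmonization).

Harmonization aligns an exposure/outcome pair of tables to a shared
effect-allele convention so that per-variant Wald ratios are meaningful:
swapped alleles flip the outcome beta sign, strand flips (A<->T, C<->G) are
recognized and aligned, and palindromic variants whose strand cannot be
resolved from allele frequencies are dropped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, EmptyOverlapError

logger = logging.getLogger("mrchain.gwas_io")

CANONICAL_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]
MANDATORY_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "beta", "se", "pval",
]

#: column_map preset for GWAS-Catalog-style harmonised headers
GWAS_CATALOG_COLUMN_MAP = {
    "hm_rsid": "variant_id",
    "hm_chrom": "chrom",
    "hm_pos": "pos",
    "hm_effect_allele": "effect_allele",
    "hm_other_allele": "other_allele",
    "hm_effect_allele_frequency": "eaf",
    "hm_beta": "beta",
    "standard_error": "se",
    "p_value": "pval",
    "n": "n",
}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_ALLELES = frozenset(_COMPLEMENT)

DROP_REASONS = ("allele_mismatch", "palindromic_ambiguous",
                "missing_in_outcome", "duplicate")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class VariantAssociation:
    """One variant's effect estimate in one GWAS."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: int | None = None


@dataclass
class SummaryDataset:
    """A validated GWAS summary-statistics table for one trait.

    ``table`` holds the canonical columns, unique by ``variant_id``.
    ``qc_tally`` counts rows dropped during validation, keyed by reason.
    """

    trait_id: str
    trait_type: str  # "continuous" | "binary"
    table: pd.DataFrame
    qc_tally: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.trait_type not in ("continuous", "binary"):
            raise ConfigError(
                f"trait_type must be 'continuous' or 'binary', got {self.trait_type!r}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def variant_ids(self) -> list[str]:
        return self.table["variant_id"].tolist()

    def subset(self, variant_ids) -> "SummaryDataset":
        """Rows whose variant_id is in ``variant_ids``, original order kept."""
        keep = self.table["variant_id"].isin(set(variant_ids))
        return SummaryDataset(self.trait_id, self.trait_type,
                              self.table.loc[keep].reset_index(drop=True),
                              dict(self.qc_tally))

    @classmethod
    def from_frame(cls, trait_id: str, trait_type: str, frame: pd.DataFrame,
                   validate: bool = True) -> "SummaryDataset":
        """Build a dataset from a canonical-column frame.

        With ``validate`` (default), rows violating the per-variant invariants
        (se <= 0, pval outside (0, 1], invalid alleles, eaf outside [0, 1])
        are dropped and tallied; duplicate variant_ids keep the smallest
        p-value.
        """
        df = frame.copy()
        missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
        if missing:
            raise ConfigError(f"missing mandatory column(s): {missing}")
        for col in ("eaf", "n"):
            if col not in df.columns:
                df[col] = np.nan
        df = df[CANONICAL_COLUMNS]
        df["variant_id"] = df["variant_id"].astype(str)
        df["chrom"] = df["chrom"].astype(str)
        df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
        df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
        df["other_allele"] = df["other_allele"].astype(str).str.upper()
        for col in ("eaf", "beta", "se", "pval", "n"):
            df[col] = pd.to_numeric(df[col], errors="coerce")

        tally: dict[str, int] = {}
        if validate:
            def drop(mask: pd.Series, reason: str):
                nonlocal df
                n_bad = int(mask.sum())
                if n_bad:
                    tally[reason] = tally.get(reason, 0) + n_bad
                    df = df.loc[~mask]

            drop(~(df["se"] > 0) | ~np.isfinite(df["se"]), "invalid_se")
            drop(~(df["pval"] > 0) | (df["pval"] > 1), "invalid_pval")
            drop(~np.isfinite(df["beta"]), "invalid_beta")
            drop(~df["effect_allele"].isin(_VALID_ALLELES)
                 | ~df["other_allele"].isin(_VALID_ALLELES)
                 | (df["effect_allele"] == df["other_allele"]), "invalid_allele")
            drop(df["eaf"].notna() & ((df["eaf"] < 0) | (df["eaf"] > 1)),
                 "invalid_eaf")
            drop(~np.isfinite(df["pos"]) | (df["pos"] < 1), "invalid_pos")

            dup = df.duplicated("variant_id", keep=False)
            if dup.any():
                n_before = len(df)
                # keep the smallest p per variant, first occurrence on ties
                df = (df.sort_values("pval", kind="stable")
                        .drop_duplicates("variant_id", keep="first")
                        .sort_index())
                tally["duplicate"] = n_before - len(df)

        df = df.reset_index(drop=True)
        df["pos"] = df["pos"].astype(np.int64)
        if tally:
            logger.info("dataset %s: dropped rows %s", trait_id, tally)
        return cls(trait_id, trait_type, df, tally)


@dataclass
class HarmonizedSet:
    """Allele-aligned effect arrays for one exposure-outcome pair.

    All betas refer to the exposure's effect allele; ``dropped`` records
    overlap variants excluded during alignment as (variant_id, reason).
    """

    exposure_id: str
    outcome_id: str
    variant_ids: list[str]
    bx: np.ndarray
    se_x: np.ndarray
    by: np.ndarray
    se_y: np.ndarray
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        self.bx = np.asarray(self.bx, dtype=float)
        self.se_x = np.asarray(self.se_x, dtype=float)
        self.by = np.asarray(self.by, dtype=float)
        self.se_y = np.asarray(self.se_y, dtype=float)
        k = len(self.variant_ids)
        if not (len(self.bx) == len(self.se_x) == len(self.by)
                == len(self.se_y) == k):
            raise DataError("harmonized arrays have unequal lengths")
        if k and (np.any(self.se_x <= 0) or np.any(self.se_y <= 0)):
            raise DataError("harmonized SEs must be strictly positive")

    @property
    def k(self) -> int:
        return len(self.variant_ids)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_summary_tsv(path, trait_id: str | None = None,
                     trait_type: str = "continuous",
                     column_map: dict | None = None) -> SummaryDataset:
    """Read a tab-separated summary-statistics file (gzip-transparent).

    ``column_map`` maps dialect column names to canonical ones (e.g.
    :data:`GWAS_CATALOG_COLUMN_MAP`); canonical names always pass through.
    Rows violating invariants are dropped and tallied in ``qc_tally``.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, comment="#")
    except FileNotFoundError:
        raise ConfigError(f"summary-statistics file not found: {path}")
    except pd.errors.EmptyDataError:
        raise DataError(f"empty summary-statistics file: {path}")
    if column_map:
        df = df.rename(columns=column_map)
    if df.empty:
        raise DataError(f"summary-statistics file has no rows: {path}")
    tid = trait_id if trait_id is not None else _stem(path)
    return SummaryDataset.from_frame(tid, trait_type, df)


def write_summary_tsv(dataset: SummaryDataset, path) -> str:
    dataset.table.to_csv(path, sep="\t", index=False)
    return str(path)


def _stem(path) -> str:
    name = str(path).rsplit("/", 1)[-1]
    for suffix in (".gz", ".tsv", ".txt"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
    return name


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT[a1] == a2


def harmonize(exposure: SummaryDataset, outcome: SummaryDataset,
              palindrome_eaf_window: tuple[float, float] = (0.42, 0.58),
              ) -> HarmonizedSet:
    """Align an exposure/outcome pair to the exposure's effect allele.

    For each exposure variant present in the outcome:

    * identical allele pair: outcome beta kept as is;
    * swapped alleles: outcome beta negated (and eaf complemented);
    * strand-complemented pair (possibly swapped): aligned accordingly;
    * palindromic (A/T or C/G) variants: strand is unresolvable from the
      alleles, so the effect-allele frequencies decide — concordant sides of
      0.5 keep, discordant flip; missing eaf or eaf inside the ambiguity
      window drops the variant with reason ``palindromic_ambiguous``;
    * anything else drops with ``allele_mismatch``.

    Output order follows the exposure.  Raises :class:`EmptyOverlapError`
    when no variant survives.
    """
    if len(exposure) == 0 or len(outcome) == 0:
        raise DataError("harmonize requires non-empty datasets")
    lo, hi = palindrome_eaf_window
    out = outcome.table.set_index("variant_id")

    ids: list[str] = []
    bx: list[float] = []
    se_x: list[float] = []
    by: list[float] = []
    se_y: list[float] = []
    dropped: list[tuple[str, str]] = []

    for row in exposure.table.itertuples(index=False):
        vid = row.variant_id
        if vid not in out.index:
            dropped.append((vid, "missing_in_outcome"))
            continue
        orow = out.loc[vid]
        ea_x, oa_x = row.effect_allele, row.other_allele
        ea_y, oa_y = orow["effect_allele"], orow["other_allele"]
        beta_y = float(orow["beta"])

        if _is_palindromic(ea_x, oa_x):
            if {ea_y, oa_y} != {ea_x, oa_x}:
                dropped.append((vid, "allele_mismatch"))
                continue
            eaf_x = row.eaf
            eaf_y = orow["eaf"]
            # align by label first (as for any swapped pair), then let the
            # frequencies decide whether a strand flip undoes that alignment
            if ea_y != ea_x:
                beta_y = -beta_y
                eaf_y = 1.0 - eaf_y if not _isnan(eaf_y) else eaf_y
            if (_isnan(eaf_x) or _isnan(eaf_y)
                    or lo < eaf_x < hi or lo < eaf_y < hi):
                dropped.append((vid, "palindromic_ambiguous"))
                continue
            same_side = (eaf_x - 0.5) * (eaf_y - 0.5) > 0
            aligned_by = beta_y if same_side else -beta_y
        elif (ea_y, oa_y) == (ea_x, oa_x):
            aligned_by = beta_y
        elif (ea_y, oa_y) == (oa_x, ea_x):
            aligned_by = -beta_y
        elif (_COMPLEMENT[ea_y], _COMPLEMENT[oa_y]) == (ea_x, oa_x):
            aligned_by = beta_y
        elif (_COMPLEMENT[ea_y], _COMPLEMENT[oa_y]) == (oa_x, ea_x):
            aligned_by = -beta_y
        else:
            dropped.append((vid, "allele_mismatch"))
            continue

        ids.append(vid)
        bx.append(float(row.beta))
        se_x.append(float(row.se))
        by.append(aligned_by)
        se_y.append(float(orow["se"]))

    if not ids:
        raise EmptyOverlapError(
            f"no usable overlapping variants between {exposure.trait_id} "
            f"and {outcome.trait_id} "
            f"({len(dropped)} overlap candidates all dropped)"
            if dropped else
            f"zero overlapping variants between {exposure.trait_id} and "
            f"{outcome.trait_id}")
    logger.debug("harmonized %s vs %s: k=%d, dropped=%d",
                 exposure.trait_id, outcome.trait_id, len(ids), len(dropped))
    return HarmonizedSet(exposure.trait_id, outcome.trait_id, ids,
                         bx, se_x, by, se_y, dropped)


def _isnan(x) -> bool:
    try:
        return x is None or math.isnan(float(x))
    except (TypeError, ValueError):
        return True


# ---------------------------------------------------------------------------
# results serialization
# ---------------------------------------------------------------------------

def _fmt3(x: float) -> str:
    return "" if x is None or not np.isfinite(x) else f"{x:.3f}"


def results_to_frame(results) -> pd.DataFrame:
    """Flatten MR-suite and mediation results into one row per (pair, method).

    Full-precision numeric columns are kept alongside display columns rounded
    the way forest plots print them (OR and CI to 3 decimals, p to 3 decimals).
    """
    rows = []
    for res in results:
        if hasattr(res, "estimates"):  # MRSuiteResult
            for method, est in res.estimates.items():
                rows.append({
                    "exposure_id": res.exposure_id,
                    "outcome_id": res.outcome_id,
                    "direction": res.direction,
                    "method": method,
                    "k": est.k,
                    "beta": est.beta, "se": est.se, "pval": est.pval,
                    "or": est.or_, "ci_low": est.ci_low, "ci_high": est.ci_high,
                    "or_display": _fmt3(est.or_),
                    "ci_display": f"{_fmt3(est.ci_low)}-{_fmt3(est.ci_high)}",
                    "p_display": _fmt3(est.pval),
                    "q_stat": res.q.Q if res.q is not None else np.nan,
                    "q_pval": res.q.pval if res.q is not None else np.nan,
                    "egger_intercept": (res.egger_intercept.intercept
                                        if res.egger_intercept else np.nan),
                    "egger_intercept_pval": (res.egger_intercept.pval
                                             if res.egger_intercept else np.nan),
                })
            for method, reason in res.skipped.items():
                rows.append({
                    "exposure_id": res.exposure_id,
                    "outcome_id": res.outcome_id,
                    "direction": res.direction,
                    "method": method, "k": res.k,
                    "beta": np.nan, "se": np.nan, "pval": np.nan,
                    "or": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                    "or_display": "", "ci_display": "", "p_display": "",
                    "status": reason,
                })
        elif hasattr(res, "indirect"):  # MediationEstimate
            rows.append({
                "exposure_id": res.exposure_id,
                "mediator_id": res.mediator_id,
                "outcome_id": res.outcome_id,
                "method": res.method,
                "beta_total": res.beta_total,
                "beta_xm": res.beta_xm, "beta_my": res.beta_my,
                "indirect": res.indirect, "indirect_se": res.indirect_se,
                "direct": res.direct,
                "prop_mediated": res.prop_mediated, "prop_se": res.prop_se,
                "pval_indirect": res.pval_indirect,
                "prop_display": ("" if res.prop_mediated is None
                                 or not np.isfinite(res.prop_mediated)
                                 else f"{100 * res.prop_mediated:.2f}%"),
                "sign_consistent": res.sign_consistent,
                "flags": ";".join(res.flags),
            })
        else:
            raise ConfigError(f"cannot serialize result of type {type(res)!r}")
    return pd.DataFrame(rows)


def write_results_tsv(results, path) -> str:
    """Write results as TSV; numeric columns round-trip at full precision."""
    results = list(results)
    if not results:
        raise DataError("no results to write")
    frame = results_to_frame(results)
    try:
        # 17 significant digits guarantees a bit-exact float round trip
        frame.to_csv(path, sep="\t", index=False,
                     float_format=lambda x: format(x, ".17g"))
    except OSError as exc:
        raise ConfigError(f"cannot write results to {path}: {exc}")
    return str(path)


def write_drops_tsv(harmonized: HarmonizedSet, path) -> str:
    """Write the (variant_id, reason) drop log of a harmonized pair."""
    pd.DataFrame(harmonized.dropped, columns=["variant_id", "reason"]).to_csv(
        path, sep="\t", index=False)
    return str(path)
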