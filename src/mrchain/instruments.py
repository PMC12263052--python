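"""Instrument selection and quality control.

Instruments are variants strongly associated with the exposure that are
mutually independent and not confounder-linked.  The selection chain is

    p-value threshold -> confounder exclusion list -> LD clumping -> F filter

with defaults p < 5e-5, clump at r^2 > 0.001 within 10,000 kb, F > 10.
The F statistic is the squared per-variant Wald z, (beta/se)^2, the standard
summary-data approximation needing no sample size or variance explained.

LD is supplied by the caller as a precomputed r^2 matrix; when absent,
variants are treated as independent and clumping is a no-op.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .gwas_io import SummaryDataset

logger = logging.getLogger("mrchain.instruments")


@dataclass(frozen=True)
class InstrumentCriteria:
    """Thresholds governing instrument selection."""

    p_threshold: float = 5e-5
    clump_r2: float = 0.001
    clump_window_kb: int = 10_000
    f_min: float = 10.0
    exclusion_ids: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if not (0 < self.p_threshold <= 1):
            raise ConfigError(f"p_threshold must be in (0, 1], got {self.p_threshold}")
        if not (0 <= self.clump_r2 <= 1):
            raise ConfigError(f"clump_r2 must be in [0, 1], got {self.clump_r2}")
        if self.clump_window_kb <= 0:
            raise ConfigError("clump_window_kb must be positive")
        if self.f_min < 0:
            raise ConfigError("f_min must be nonnegative")
        object.__setattr__(self, "exclusion_ids", frozenset(self.exclusion_ids))


@dataclass
class LDMatrix:
    """Symmetric matrix of squared allelic correlations with unit diagonal."""

    variant_ids: list[str]
    r2: np.ndarray

    def __post_init__(self):
        self.variant_ids = list(self.variant_ids)
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.variant_ids)
        if self.r2.shape != (n, n):
            raise ConfigError("LD matrix shape does not match variant count")
        if np.any(self.r2 < 0) or np.any(self.r2 > 1):
            raise ConfigError("LD r2 values must be in [0, 1]")
        if not np.allclose(self.r2, self.r2.T):
            raise ConfigError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ConfigError("LD matrix diagonal must be 1")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def covers(self, variant_ids) -> bool:
        return all(v in self._index for v in variant_ids)

    def lookup(self, id_a: str, id_b: str) -> float:
        return float(self.r2[self._index[id_a], self._index[id_b]])

    @classmethod
    def from_pairs_tsv(cls, path) -> "LDMatrix":
        """Read long-format (id_a, id_b, r2) pairs; unlisted pairs get r2 = 0."""
        df = pd.read_csv(path, sep="\t")
        need = {"id_a", "id_b", "r2"}
        if not need.issubset(df.columns):
            raise ConfigError(f"LD pairs file must have columns {sorted(need)}")
        ids = sorted(set(df["id_a"].astype(str)) | set(df["id_b"].astype(str)))
        idx = {v: i for i, v in enumerate(ids)}
        mat = np.eye(len(ids))
        for a, b, r2 in df[["id_a", "id_b", "r2"]].itertuples(index=False):
            i, j = idx[str(a)], idx[str(b)]
            mat[i, j] = mat[j, i] = float(r2)
        return cls(ids, mat)

    @classmethod
    def from_matrix_tsv(cls, path) -> "LDMatrix":
        """Read a square matrix file with a header row of variant ids."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(c) for c in df.columns], df.to_numpy(dtype=float))


def select_by_pvalue(dataset: SummaryDataset, p_threshold: float) -> SummaryDataset:
    """Records with pval strictly below the threshold, order preserved."""
    keep = dataset.table["pval"] < p_threshold
    return SummaryDataset(dataset.trait_id, dataset.trait_type,
                          dataset.table.loc[keep].reset_index(drop=True),
                          dict(dataset.qc_tally))


def exclude_snps(dataset: SummaryDataset, exclusion_ids) -> SummaryDataset:
    """Remove confounder-associated variants listed in ``exclusion_ids``.

    The list interface replaces interactive confounder-database lookups so
    runs are reproducible.
    """
    exclusion_ids = set(exclusion_ids)
    if not exclusion_ids:
        return dataset
    present = exclusion_ids & set(dataset.variant_ids)
    absent = exclusion_ids - present
    if absent:
        logger.debug("%d exclusion ids not present in %s",
                     len(absent), dataset.trait_id)
    out = dataset.subset(set(dataset.variant_ids) - present)
    out.qc_tally["confounder_excluded"] = (
        out.qc_tally.get("confounder_excluded", 0) + len(present))
    logger.info("excluded %d confounder-linked variants from %s",
                len(present), dataset.trait_id)
    return out


def ld_clump(dataset: SummaryDataset, ld: LDMatrix | None,
             criteria: InstrumentCriteria) -> SummaryDataset:
    """Greedy p-value-ordered clumping.

    Repeatedly take the remaining variant with the smallest p-value as an
    index and remove every remaining variant whose r^2 with it exceeds
    ``clump_r2`` AND whose position lies within ``clump_window_kb`` on the
    same chromosome.  Ties on p break lexicographically on variant_id.
    Without an LD matrix variants are treated as independent (no removals).
    """
    if ld is None or len(dataset) == 0:
        return dataset
    if not ld.covers(dataset.variant_ids):
        missing = [v for v in dataset.variant_ids if v not in ld._index]
        raise ConfigError(
            f"LD matrix missing {len(missing)} dataset variants, "
            f"e.g. {missing[:3]}")
    df = dataset.table
    order = df.sort_values(["pval", "variant_id"], kind="stable")
    alive = set(df["variant_id"])
    retained: set[str] = set()
    window_bp = criteria.clump_window_kb * 1000
    info = {r.variant_id: (r.chrom, r.pos) for r in df.itertuples(index=False)}
    for row in order.itertuples(index=False):
        vid = row.variant_id
        if vid not in alive:
            continue
        retained.add(vid)
        alive.discard(vid)
        chrom, pos = info[vid]
        for other in list(alive):
            ochrom, opos = info[other]
            if (ochrom == chrom and abs(opos - pos) < window_bp
                    and ld.lookup(vid, other) > criteria.clump_r2):
                alive.discard(other)
    keep = df["variant_id"].isin(retained)
    return SummaryDataset(dataset.trait_id, dataset.trait_type,
                          df.loc[keep].reset_index(drop=True),
                          dict(dataset.qc_tally))


def f_statistics(dataset: SummaryDataset) -> pd.Series:
    """Per-variant instrument-strength F = (beta/se)^2, indexed by variant_id."""
    t = dataset.table
    return pd.Series((t["beta"] / t["se"]) ** 2).set_axis(t["variant_id"])


def f_filter(dataset: SummaryDataset, f_min: float
             ) -> tuple[SummaryDataset, pd.Series]:
    """Retain variants with F strictly above ``f_min``; return all F values."""
    fstats = f_statistics(dataset)
    keep = (fstats > f_min).to_numpy()
    out = SummaryDataset(dataset.trait_id, dataset.trait_type,
                         dataset.table.loc[keep].reset_index(drop=True),
                         dict(dataset.qc_tally))
    return out, fstats


def read_exclusion_list(path) -> frozenset:
    """One variant_id per line; blank lines and '#' comments ignored."""
    with open(path) as fh:
        return frozenset(line.strip() for line in fh
                         if line.strip() and not line.startswith("#"))
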