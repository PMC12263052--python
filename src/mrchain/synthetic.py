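"""Synthetic GWAS summary statistics with known causal structure.

The generator emulates the study design the pipeline targets: three
summary-level GWAS — an exposure X (e.g. a lipid species), a mediator M
(an immune or inflammatory trait) and an outcome Y (disease liability) —
linked by the linear structural model

    X = r * Y           + sum_j b_j  G_j + e_X      (r = reverse_theta)
    M = theta_xm * X    + sum_j m_j  G_j + e_M
    Y = theta_direct * X + theta_my * M + sum_j g_j G_j + alpha' G + e_Y

so the total forward effect is theta_total = theta_direct + theta_xm*theta_my
and the mediated fraction is theta_xm*theta_my / theta_total.  X, M and (when
reverse_theta != 0) Y each get a disjoint block of instruments, which keeps
the two-sample and no-overlap assumptions clean.  Per-SNP true effects on
(X, M, Y) solve the simultaneous system exactly, so a nonzero reverse_theta
yields genuinely bidirectional structure rather than a one-way approximation.

Observed summary statistics add sampling noise with the standard
standardized-trait SE approximation se = 1/sqrt(2*maf*(1-maf)*n); p-values
are two-sided Wald.  Horizontal pleiotropy (alpha) attaches direct
SNP-to-outcome effects to the exposure's instruments: none, balanced
(mean zero) or directional (nonzero mean).

All randomness flows from one seed through named SeedSequence spawns, so each
component stream is reproducible independently of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .gwas_io import SummaryDataset

PLEIOTROPY_MODES = ("none", "balanced", "directional")

#: chromosome/position layout spacing; > the default 10,000 kb clump window
#: so synthetic panels are clump-neutral unless an LD matrix says otherwise
_POS_SPACING = 20_000_000


@dataclass(frozen=True)
class SimConfig:
    """Structural-model parameters for one simulated study.

    Defaults mirror the real data sources the pipeline was designed around:
    a lipidomics exposure GWAS of ~7k individuals, an immune-trait mediator
    GWAS of ~4k, and a disease outcome GWAS at biobank scale, with 100
    candidate instruments explaining 5% of exposure variance.
    """

    seed: int
    n_snps: int = 100
    n_x: int = 7174
    n_m: int = 3757
    n_y: int = 100_000
    theta_xm: float = 0.0
    theta_my: float = 0.0
    theta_direct: float = 0.0
    pleiotropy: str = "none"
    pleiotropy_scale: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    exposure_h2: float = 0.05
    reverse_theta: float = 0.0

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.n_snps < 1:
            raise ConfigError("n_snps must be >= 1")
        for name in ("n_x", "n_m", "n_y"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.pleiotropy not in PLEIOTROPY_MODES:
            raise ConfigError(
                f"pleiotropy must be one of {PLEIOTROPY_MODES}, "
                f"got {self.pleiotropy!r}")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must lie within (0, 0.5]")
        if not (0 < self.exposure_h2 < 1):
            raise ConfigError(
                f"exposure_h2 must be in (0, 1), got {self.exposure_h2} "
                f"(infeasible for any instrument set)")
        if self.reverse_theta * self.theta_total() == 1:
            raise ConfigError("feedback loop reverse_theta * theta_total = 1 "
                              "has no stable solution")

    def theta_total(self) -> float:
        return self.theta_direct + self.theta_xm * self.theta_my


@dataclass(frozen=True)
class TruthRecord:
    """Closed-form expected effects implied by a SimConfig."""

    theta_total: float
    theta_direct: float
    indirect: float
    proportion: Optional[float]
    proportion_defined: bool


def truth_table(config: SimConfig) -> TruthRecord:
    """Expected total/direct/indirect effects and proportion mediated."""
    total = config.theta_total()
    indirect = config.theta_xm * config.theta_my
    if total == 0:
        return TruthRecord(total, config.theta_direct, indirect, None, False)
    return TruthRecord(total, config.theta_direct, indirect,
                       indirect / total, True)


def _scaled_effects(rng: np.random.Generator, maf: np.ndarray,
                    h2: float) -> np.ndarray:
    """Draw per-SNP effects whose summed variance explained equals h2."""
    raw = rng.standard_normal(maf.shape[0])
    var = 2.0 * maf * (1.0 - maf)
    total = float(np.sum(var * raw**2))
    if total <= 0:
        raise ConfigError("degenerate instrument effect draw")
    return raw * np.sqrt(h2 / total)


def _observe(true_beta: np.ndarray, maf: np.ndarray, n: int,
             rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)
    beta = true_beta + rng.normal(0.0, se)
    pval = 2.0 * stats.norm.sf(np.abs(beta / se))
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    return beta, se, pval


def simulate_triplet(config: SimConfig,
                     trait_ids: tuple[str, str, str] = ("X", "M", "Y"),
                     ) -> tuple[SummaryDataset, SummaryDataset, SummaryDataset]:
    """Generate (exposure, mediator, outcome) summary datasets.

    Each trait reports every panel SNP; X, M and Y each contribute a
    disjoint block of ``n_snps`` instruments (the outcome's own disease
    loci feed back into X only when ``reverse_theta != 0``).  Deterministic
    given the config seed.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_struct, rng_pleio, rng_x, rng_m, rng_y = (
        np.random.default_rng(child) for child in ss.spawn(5))

    lo, hi = config.maf_range
    n_total = config.n_snps * 3
    maf = rng_struct.uniform(lo, hi, n_total)

    sl_x = slice(0, config.n_snps)
    sl_m = slice(config.n_snps, 2 * config.n_snps)
    sl_y = slice(2 * config.n_snps, n_total)

    # direct (pre-structural) SNP effects on each trait's own equation; the
    # outcome always carries its own disease instruments — their effects
    # propagate back to X only when reverse_theta != 0
    e = np.zeros((n_total, 3))
    e[sl_x, 0] = _scaled_effects(rng_struct, maf[sl_x], config.exposure_h2)
    e[sl_m, 1] = _scaled_effects(rng_struct, maf[sl_m], config.exposure_h2)
    e[sl_y, 2] = _scaled_effects(rng_struct, maf[sl_y], config.exposure_h2)

    if config.pleiotropy != "none":
        scale = config.pleiotropy_scale
        mean = scale if config.pleiotropy == "directional" else 0.0
        alpha = rng_pleio.normal(mean, scale, config.n_snps)
        # pleiotropic effects are defined relative to the exposure-increasing
        # allele (allele coding is arbitrary); without this, reorienting
        # variants would cancel any directional component by symmetry
        e[sl_x, 2] += alpha * np.sign(e[sl_x, 0])

    # structural coefficient matrix B: row i lists the effects *on* trait i
    B = np.array([
        [0.0, 0.0, config.reverse_theta],              # X <- r*Y
        [config.theta_xm, 0.0, 0.0],                   # M <- theta_xm*X
        [config.theta_direct, config.theta_my, 0.0],   # Y <- direct + via M
    ])
    true = np.linalg.solve(np.eye(3) - B, e.T).T  # per-SNP effects on (X,M,Y)

    chrom = np.array([str(j % 22 + 1) for j in range(n_total)])
    pos = 1_000_000 + (np.arange(n_total) // 22) * _POS_SPACING
    ids = np.array([f"rs{100001 + j}" for j in range(n_total)])

    datasets = []
    for col, (tid, n, rng, ttype) in enumerate([
            (trait_ids[0], config.n_x, rng_x, "continuous"),
            (trait_ids[1], config.n_m, rng_m, "continuous"),
            (trait_ids[2], config.n_y, rng_y, "binary")]):
        beta, se, pval = _observe(true[:, col], maf, n, rng)
        frame = pd.DataFrame({
            "variant_id": ids, "chrom": chrom, "pos": pos,
            "effect_allele": "A", "other_allele": "G",
            "eaf": maf, "beta": beta, "se": se, "pval": pval, "n": n,
        })
        datasets.append(SummaryDataset.from_frame(tid, ttype, frame))
    return tuple(datasets)


def simulate_reverse(config: SimConfig,
                     trait_ids: tuple[str, str, str] = ("X", "M", "Y"),
                     ) -> tuple[SummaryDataset, SummaryDataset, SummaryDataset]:
    """Triplet with genuine reverse (Y -> X) structure.

    Identical to :func:`simulate_triplet`: the outcome's disjoint
    instrument block propagates back to X with weight ``reverse_theta``,
    and with ``reverse_theta = 0`` this reduces exactly to the forward-only
    generator.
    """
    return simulate_triplet(config, trait_ids)


def derive_seed(base_seed: int, *indices: int) -> int:
    """Deterministic child seed below 2**31 for a component or replicate."""
    return int(np.random.SeedSequence([int(base_seed), *map(int, indices)])
               .generate_state(1)[0] % (2**31))


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    return replace(config, seed=seed)
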