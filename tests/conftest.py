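import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mrchain import HarmonizedSet, SimConfig, SummaryDataset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_dataset(rows, trait_id="T", trait_type="continuous", validate=True):
    """Build a SummaryDataset from (variant_id, chrom, pos, ea, oa, eaf,
    beta, se, pval) tuples; eaf may be None."""
    frame = pd.DataFrame(rows, columns=[
        "variant_id", "chrom", "pos", "effect_allele", "other_allele",
        "eaf", "beta", "se", "pval"])
    return SummaryDataset.from_frame(trait_id, trait_type, frame,
                                     validate=validate)


@pytest.fixture
def small_exposure():
    return make_dataset([
        ("rs1", "1", 1_000_000, "A", "G", 0.3, 0.10, 0.02, 1e-8),
        ("rs2", "1", 2_000_000, "C", "T", 0.2, 0.08, 0.02, 1e-6),
        ("rs3", "2", 1_000_000, "G", "T", 0.4, -0.06, 0.02, 1e-5),
    ], trait_id="X")


@pytest.fixture
def small_outcome():
    return make_dataset([
        ("rs1", "1", 1_000_000, "A", "G", 0.3, 0.05, 0.03, 0.10),
        ("rs2", "1", 2_000_000, "T", "C", 0.8, -0.04, 0.03, 0.18),
        ("rs3", "2", 1_000_000, "C", "A", 0.6, -0.03, 0.03, 0.30),
    ], trait_id="Y", trait_type="binary")


def make_harmonized(bx, by, se_y, se_x=None, exposure_id="X", outcome_id="Y"):
    bx = np.asarray(bx, dtype=float)
    se_x = (np.full_like(bx, 1e-4) if se_x is None
            else np.asarray(se_x, dtype=float))
    ids = [f"rs{i + 1}" for i in range(len(bx))]
    return HarmonizedSet(exposure_id, outcome_id, ids, bx, se_x,
                         np.asarray(by, dtype=float),
                         np.asarray(se_y, dtype=float))


@pytest.fixture
def strong_config():
    """Large-sample structural model with one true mediated path."""
    return SimConfig(seed=20260928, n_snps=100, n_x=500_000, n_m=500_000,
                     n_y=500_000, theta_xm=0.4, theta_my=0.5,
                     theta_direct=0.3, exposure_h2=0.05)
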