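"""Configuration-driven orchestration of the full study design.

A study runs four components in order: (1) bidirectional MR between every
exposure and the outcome; (2) direction classification with exclusion of
bidirectional traits; (3) forward MR of exposures on candidate mediators and
of mediators on the outcome; (4) two-step mediation with the product and
difference decompositions.  Outputs are TSV tables (the machine-readable twin
of forest plots), a QC/drops log, and a run manifest that fully determines
the outputs: same manifest, same bytes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, DataError
from .gwas_io import (SummaryDataset, read_summary_tsv, results_to_frame,
                      write_results_tsv)
from .instruments import InstrumentCriteria, LDMatrix, read_exclusion_list
from .mediation import screen_mediators
from .screening import (DirectionClassification, classify_direction,
                        run_panel, reverse_mr, select_instruments)
from .synthetic import derive_seed

logger = logging.getLogger("mrchain.pipeline")


@dataclass
class StudyConfig:
    """Everything a study run needs; the seed is mandatory."""

    outcome_path: str
    exposure_manifest: str
    output_dir: str
    seed: int
    mediator_manifest: Optional[str] = None
    ld_path: Optional[str] = None
    exclusion_path: Optional[str] = None
    criteria: InstrumentCriteria = field(default_factory=InstrumentCriteria)
    reverse_p_threshold: Optional[float] = None  # defaults to forward
    alpha: float = 0.05
    n_boot: int = 1000
    outcome_trait_type: str = "binary"

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "StudyConfig":
        raw = dict(raw)
        crit = raw.pop("criteria", {})
        if isinstance(crit, dict):
            if "exclusion_ids" in crit:
                crit["exclusion_ids"] = frozenset(crit["exclusion_ids"])
            crit = InstrumentCriteria(**crit)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        missing = {"outcome_path", "exposure_manifest", "output_dir",
                   "seed"} - set(raw)
        if missing:
            raise ConfigError(f"missing config keys: {sorted(missing)}")
        return cls(criteria=crit, **raw)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__
             if k != "criteria"}
        c = self.criteria
        d["criteria"] = {
            "p_threshold": c.p_threshold, "clump_r2": c.clump_r2,
            "clump_window_kb": c.clump_window_kb, "f_min": c.f_min,
            "exclusion_ids": sorted(c.exclusion_ids)}
        return d

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class StudyBundle:
    """In-memory results of one study run plus the paths written."""

    config: StudyConfig
    forward: object  # PanelResult
    reverse_rows: list
    classifications: list[DirectionClassification]
    mediation_estimates: list
    mediation_rows: list
    step1_panels: list = field(default_factory=list)
    step2_panel: object = None
    paths: dict = field(default_factory=dict)


def read_manifest(path) -> list[SummaryDataset]:
    """Panel manifest: TSV of (trait_id, path, trait_type); paths relative
    to the manifest's directory."""
    mpath = Path(path)
    if not mpath.exists():
        raise ConfigError(f"manifest not found: {path}")
    df = pd.read_csv(mpath, sep="\t")
    need = {"trait_id", "path", "trait_type"}
    if not need.issubset(df.columns):
        raise ConfigError(f"manifest must have columns {sorted(need)}")
    datasets = []
    for row in df.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = mpath.parent / p
        datasets.append(read_summary_tsv(p, trait_id=str(row.trait_id),
                                         trait_type=str(row.trait_type)))
    return datasets


def run_study(config: StudyConfig) -> StudyBundle:
    """Execute the four-component study and write the report bundle."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    outcome = read_summary_tsv(config.outcome_path, trait_type=config.outcome_trait_type)
    exposures = read_manifest(config.exposure_manifest)
    mediators = (read_manifest(config.mediator_manifest)
                 if config.mediator_manifest else [])
    ld = LDMatrix.from_pairs_tsv(config.ld_path) if config.ld_path else None
    criteria = config.criteria
    if config.exclusion_path:
        excl = read_exclusion_list(config.exclusion_path)
        criteria = InstrumentCriteria(
            criteria.p_threshold, criteria.clump_r2, criteria.clump_window_kb,
            criteria.f_min, criteria.exclusion_ids | excl)

    # (1) bidirectional MR between exposures and outcome
    logger.info("forward panel: %d exposures -> %s",
                len(exposures), outcome.trait_id)
    forward = run_panel(exposures, outcome, criteria, ld, config.alpha,
                        n_boot=config.n_boot, seed=derive_seed(config.seed, 1))
    rev_thresh = config.reverse_p_threshold or criteria.p_threshold
    reverse_rows = []
    forward_ok = {r.exposure_id: r for r in forward.results}
    for i, exp in enumerate(exposures):
        if exp.trait_id not in forward_ok:
            continue
        # the disease's instrument set must not contain the trait's own
        # instruments, or reverse MR merely rediscovers the forward pathway
        # (each such variant's reverse Wald ratio is 1/theta_total)
        trait_inst = select_instruments(exp, criteria, ld)
        rev_criteria = InstrumentCriteria(
            rev_thresh, criteria.clump_r2, criteria.clump_window_kb,
            criteria.f_min,
            criteria.exclusion_ids | frozenset(trait_inst.variant_ids))
        try:
            rev = reverse_mr(outcome, exp, rev_criteria, ld,
                             n_boot=config.n_boot,
                             seed=derive_seed(config.seed, 2, i))
            reverse_rows.append(rev)
        except DataError as exc:
            logger.warning("reverse MR failed for %s: %s", exp.trait_id, exc)

    # (2) direction classification, bidirectional exclusion
    rev_by_outcome = {r.outcome_id: r for r in reverse_rows}
    classifications = []
    for res in forward.results:
        rev = rev_by_outcome.get(res.exposure_id)
        if rev is None:
            continue
        classifications.append(classify_direction(res, rev, config.alpha))
    eligible_ids = {c.pair_id.split("|")[0] for c in classifications
                    if c.mediation_eligible}
    eligible = [e for e in exposures if e.trait_id in eligible_ids]
    logger.info("mediation-eligible exposures: %d of %d",
                len(eligible), len(exposures))

    # (3)+(4) mediator screen and two-step mediation
    med_estimates, med_rows = [], []
    if mediators and eligible:
        med_estimates, med_rows = screen_mediators(
            eligible, mediators, outcome, criteria, ld, config.alpha,
            n_boot=config.n_boot, seed=derive_seed(config.seed, 3),
            totals=forward_ok)

    bundle = StudyBundle(config, forward, reverse_rows, classifications,
                         med_estimates, med_rows)
    _write_bundle(bundle, out_dir)
    return bundle


def _write_bundle(bundle: StudyBundle, out_dir: Path) -> None:
    cfg = bundle.config
    paths = bundle.paths
    paths["forward"] = str(out_dir / "forward_results.tsv")
    write_results_tsv(bundle.forward.results, paths["forward"]) \
        if bundle.forward.results else _touch_empty(paths["forward"])
    bundle.forward.summary_frame().to_csv(
        out_dir / "forward_summary.tsv", sep="\t", index=False)
    paths["reverse"] = str(out_dir / "reverse_results.tsv")
    if bundle.reverse_rows:
        write_results_tsv(bundle.reverse_rows, paths["reverse"])
    else:
        _touch_empty(paths["reverse"])

    paths["direction"] = str(out_dir / "direction.tsv")
    pd.DataFrame([{
        "pair_id": c.pair_id, "forward_sig": c.forward_sig,
        "reverse_sig": c.reverse_sig, "label": c.label,
        "mediation_eligible": c.mediation_eligible}
        for c in bundle.classifications]).to_csv(
        paths["direction"], sep="\t", index=False)

    paths["mediation"] = str(out_dir / "mediation.tsv")
    if bundle.mediation_estimates:
        write_results_tsv(bundle.mediation_estimates, paths["mediation"])
    else:
        _touch_empty(paths["mediation"])
    pd.DataFrame([{
        "exposure_id": r.exposure_id, "mediator_id": r.mediator_id,
        "status": r.status, "message": r.message}
        for r in bundle.mediation_rows]).to_csv(
        out_dir / "mediation_screen.tsv", sep="\t", index=False)

    drops = []
    for res in bundle.forward.results + bundle.reverse_rows:
        if res.harmonized is not None:
            for vid, reason in res.harmonized.dropped:
                drops.append({"exposure_id": res.exposure_id,
                              "outcome_id": res.outcome_id,
                              "direction": res.direction,
                              "variant_id": vid, "reason": reason})
    paths["drops"] = str(out_dir / "drops.tsv")
    pd.DataFrame(drops, columns=["exposure_id", "outcome_id", "direction",
                                 "variant_id", "reason"]).to_csv(
        paths["drops"], sep="\t", index=False)

    paths["manifest"] = str(out_dir / "run_manifest.json")
    with open(paths["manifest"], "w") as fh:
        json.dump({"config": cfg.to_dict(),
                   "config_hash": cfg.content_hash(),
                   "seed": cfg.seed,
                   "mrchain_version": __version__}, fh, indent=2,
                  sort_keys=True)
    paths["report"] = str(out_dir / "report.txt")
    with open(paths["report"], "w") as fh:
        fh.write(render_report(bundle))


def _touch_empty(path) -> None:
    Path(path).write_text("")


def _or_ci(est) -> str:
    return f"{est.or_:.3f} ({est.ci_low:.3f}-{est.ci_high:.3f})"


def render_report(bundle: StudyBundle) -> str:
    """Plain-text summary: per-direction tables sorted by p, mediation
    proportions as percentages to two decimals."""
    lines = []
    fwd = bundle.forward
    sig = fwd.significant
    lines.append(f"mrchain study report  (seed={bundle.config.seed}, "
                 f"alpha={bundle.config.alpha})")
    lines.append("")
    lines.append(f"Forward MR: {len(fwd.results)} pairs analysed, "
                 f"{len(sig)} significant at alpha={fwd.alpha}.")
    if not sig:
        lines.append("  No significant forward associations found.")
    for res in sig:
        est = res.primary
        lines.append(f"  {res.exposure_id} -> {res.outcome_id}: "
                     f"OR {_or_ci(est)}, p={est.pval:.3f}, k={res.k}")
    lines.append("")
    bidir = [c for c in bundle.classifications if c.label == "bidirectional"]
    lines.append(f"Direction classification: {len(bundle.classifications)} "
                 f"pairs, {len(bidir)} bidirectional (excluded from mediation).")
    for c in bidir:
        lines.append(f"  {c.pair_id}: bidirectional, mediation-ineligible")
    lines.append("")
    meds = [m for m in bundle.mediation_estimates if m.method == "product"]
    lines.append(f"Mediation (product method): {len(meds)} gated triplets.")
    if not meds:
        lines.append("  Zero mediation findings.")
    for m in sorted(meds, key=lambda m: m.pval_indirect):
        prop = ("undefined" if m.prop_mediated != m.prop_mediated
                else f"{100 * m.prop_mediated:.2f}%")
        flag = f" [{';'.join(m.flags)}]" if m.flags else ""
        lines.append(f"  {m.exposure_id} -> {m.mediator_id} -> {m.outcome_id}: "
                     f"proportion mediated {prop}, "
                     f"indirect {m.indirect:.4f} (se {m.indirect_se:.4f}), "
                     f"p={m.pval_indirect:.3f}{flag}")
    if not bundle.forward.rows and not bundle.mediation_rows:
        logger.warning("empty bundle: nothing to report")
    return "\n".join(lines) + "\n"
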