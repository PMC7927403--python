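"""End-to-end orchestration: structures -> template -> score screen ->
trajectory verdicts -> pharmacology report.

Stages whose inputs are absent from the config are skipped (and logged in
the manifest); every produced table is written under the output directory
and summarised in report.md. All stages are deterministic given the config
and inputs, so re-running a config reproduces the report byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import pharmacology as pharm
from . import screening, structio, trajectory

ACTIVE_REF_DEFAULT = 14.53
INACTIVE_REF_DEFAULT = 12.96


@dataclass
class PipelineConfig:
    structures_dir: str | None = None
    states_csv: str | None = None
    scores_csv: str | None = None
    candidates_csv: str | None = None
    trajectory_csvs: list[str] = field(default_factory=list)
    assay_camp_csv: str | None = None
    assay_prolif_csv: str | None = None
    pair: str = "84:249"
    chain: str = "A"
    anneal_ns: float = 50.0
    bin_frames: int = 20
    threshold: str | float = "auto"
    active_ref: float = ACTIVE_REF_DEFAULT
    inactive_ref: float = INACTIVE_REF_DEFAULT
    hot_kd: float = 65e-9
    hot_conc: float = 300e-9
    seed: int = 0
    out_dir: str = "conformo_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def descriptor_pair(self) -> structio.ResiduePairDescriptor:
        a, b = (int(x) for x in str(self.pair).split(":"))
        return structio.ResiduePairDescriptor(a, b)


def validate_config(config: PipelineConfig) -> list[str]:
    """Collect every violation; an empty list means the config is runnable."""
    violations: list[str] = []
    try:
        config.descriptor_pair()
    except Exception as exc:
        violations.append(f"pair: {exc}")
    for name in ("structures_dir", "scores_csv", "candidates_csv", "assay_camp_csv", "assay_prolif_csv"):
        path = getattr(config, name)
        if path is not None and not Path(path).exists():
            violations.append(f"{name}: path {path} does not exist")
    for path in config.trajectory_csvs:
        if not Path(path).exists():
            violations.append(f"trajectory_csvs: path {path} does not exist")
            continue
        try:
            series = trajectory.read_series_csv(path, anneal_ns=config.anneal_ns)
            if config.anneal_ns >= series.total_ns:
                violations.append(
                    f"trajectory_csvs: anneal_ns {config.anneal_ns} >= total span of {path}"
                )
        except Exception as exc:
            violations.append(f"trajectory_csvs: {path}: {exc}")
    if config.hot_kd <= 0:
        violations.append("hot_kd: must be positive")
    if config.hot_conc < 0:
        violations.append("hot_conc: must be non-negative")
    if config.bin_frames < 1:
        violations.append("bin_frames: must be >= 1")
    if config.anneal_ns < 0:
        violations.append("anneal_ns: must be non-negative")
    if config.active_ref <= config.inactive_ref:
        violations.append("active_ref must exceed inactive_ref")
    if not isinstance(config.threshold, (int, float)) and config.threshold != "auto":
        violations.append("threshold: must be 'auto' or a number")
    has_stage = any(
        [config.structures_dir, config.scores_csv, config.trajectory_csvs,
         config.assay_camp_csv, config.assay_prolif_csv]
    )
    if not has_stage:
        violations.append("no stage inputs provided")
    return violations


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig, log=sys.stderr) -> dict:
    """Run all stages with available inputs; returns the manifest dict."""
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    out = Path(config.out_dir)
    tables = out / "tables"
    tables.mkdir(parents=True, exist_ok=True)
    pair = config.descriptor_pair()
    manifest: dict = {
        "tool": "conformo",
        "version": __version__,
        "config": asdict(config),
        "inputs": {},
        "outputs": [],
        "stages": {},
        "warnings": [],
    }
    report: list[str] = ["# conformo pipeline report", ""]

    def log_stage(name, msg):
        print(f"[conformo] {name}: {msg}", file=log)

    # -- structures ---------------------------------------------------------
    if config.structures_dir:
        pdbs = sorted(Path(config.structures_dir).glob("*.pdb"))
        states = {}
        if config.states_csv:
            sdf = pd.read_csv(config.states_csv)
            states = dict(zip(sdf["structure_id"].astype(str), sdf["state"].astype(str)))
            manifest["inputs"][config.states_csv] = _digest(config.states_csv)
        models = []
        for p in pdbs:
            manifest["inputs"][str(p)] = _digest(p)
            models.append(
                structio.read_structure(p, chain_id=config.chain, state=states.get(p.stem, "unknown"))
            )
        template_id, dist_table = structio.select_template(models, pair, mode="max")
        alignment = structio.align_ensemble(models)
        stab = structio.residue_stability(alignment, pair.residue_b)
        _write_csv(dist_table, tables / "distances.csv")
        manifest["outputs"].append("tables/distances.csv")
        manifest["stages"]["structures"] = {
            "n_structures": len(models),
            "template": template_id,
            "stability_residue": pair.residue_b,
            "stability_rmsd_A": round(stab.rmsd_from_mean, 4),
        }
        report += [
            "## Structures",
            "",
            f"- structures analysed: {len(models)}",
            f"- selected docking template (max {pair.residue_a}-{pair.residue_b} "
            f"C-alpha distance): **{template_id}** "
            f"({dist_table['distance_A'].max():.2f} A)",
            f"- residue {pair.residue_b} stability (RMSD about the aligned-ensemble mean): "
            f"{stab.rmsd_from_mean:.2f} A",
            "",
        ]
        log_stage("structures", f"{len(models)} structures, template {template_id}")
    else:
        log_stage("structures", "skipped (no inputs)")

    # -- score screen -------------------------------------------------------
    threshold_value: float | None = None
    if config.scores_csv:
        manifest["inputs"][config.scores_csv] = _digest(config.scores_csv)
        sets = screening.read_score_csv(config.scores_csv)
        stage: dict = {}
        if "agonist" in sets and "antagonist" in sets:
            scan = screening.scan_threshold(sets["agonist"], sets["antagonist"])
            _write_csv(screening.scan_table(sets["agonist"], sets["antagonist"]), tables / "threshold_scan.csv")
            manifest["outputs"].append("tables/threshold_scan.csv")
            sep = screening.median_separation(sets["agonist"], sets["antagonist"])
            stage.update(
                best_threshold=round(scan.best_threshold, 4),
                best_mcc=round(scan.best_mcc, 4),
                median_agonist=round(sep.median_pos, 4),
                median_antagonist=round(sep.median_neg, 4),
                mw_p=sep.mw_p,
            )
            threshold_value = scan.best_threshold
            report += [
                "## Docking-score screen",
                "",
                f"- agonist / antagonist medians: {sep.median_pos:.2f} / {sep.median_neg:.2f} "
                f"(Mann-Whitney p = {sep.mw_p:.3g})",
                f"- MCC-optimal threshold: **{scan.best_threshold:.2f}** (MCC = {scan.best_mcc:.3f})",
                "",
            ]
        if isinstance(config.threshold, (int, float)):
            threshold_value = float(config.threshold)
        cand = sets.get("candidate")
        if cand is None and config.candidates_csv:
            manifest["inputs"][config.candidates_csv] = _digest(config.candidates_csv)
            cand = screening.read_score_csv(config.candidates_csv).get("candidate")
        if cand is not None and threshold_value is not None:
            ids = screening.shortlist(cand, threshold_value)
            _write_csv(pd.DataFrame({"compound_id": ids}), tables / "shortlist.csv")
            manifest["outputs"].append("tables/shortlist.csv")
            stage.update(threshold_used=round(threshold_value, 4), shortlisted=ids)
            report += [
                f"- shortlist (score < {threshold_value:.2f}): {len(ids)} of {len(cand)} "
                f"candidates: {', '.join(ids)}",
                "",
            ]
        manifest["stages"]["scores"] = stage
        log_stage("scores", f"threshold {threshold_value}")
    else:
        log_stage("scores", "skipped (no inputs)")

    # -- trajectories -------------------------------------------------------
    if config.trajectory_csvs:
        verdict_rows = []
        series_list = []
        for path in config.trajectory_csvs:
            manifest["inputs"][path] = _digest(path)
            s = trajectory.read_series_csv(path, anneal_ns=config.anneal_ns)
            series_list.append(s)
            seg = trajectory.production_segment(s)
            verdict_rows.append(
                {
                    "label": s.label,
                    "n_frames": s.n_frames,
                    "production_median_A": float(np.median(seg)),
                    "verdict": trajectory.classify_state(s, config.active_ref, config.inactive_ref),
                }
            )
        verdicts = pd.DataFrame(verdict_rows)
        _write_csv(verdicts, tables / "trajectory_verdicts.csv")
        manifest["outputs"].append("tables/trajectory_verdicts.csv")
        comp_rows = []
        for i in range(len(series_list)):
            for j in range(i + 1, len(series_list)):
                c = trajectory.compare_distributions(series_list[i], series_list[j])
                comp_rows.append(
                    {
                        "label_a": c.label_a, "label_b": c.label_b,
                        "median_a": c.median_a, "median_b": c.median_b,
                        "mw_p": c.mw_p, "ks_p": c.ks_p,
                    }
                )
        if comp_rows:
            _write_csv(pd.DataFrame(comp_rows), tables / "trajectory_comparisons.csv")
            manifest["outputs"].append("tables/trajectory_comparisons.csv")
        manifest["stages"]["trajectories"] = {
            "n_series": len(series_list),
            "verdicts": {r["label"]: r["verdict"] for r in verdict_rows},
        }
        report += ["## Trajectory verdicts", ""]
        report += [
            f"- {r['label']}: production median {r['production_median_A']:.2f} A -> **{r['verdict']}**"
            for r in verdict_rows
        ]
        report += [""]
        log_stage("trajectories", f"{len(series_list)} series")
    else:
        log_stage("trajectories", "skipped (no inputs)")

    # -- pharmacology -------------------------------------------------------
    if config.assay_camp_csv or config.assay_prolif_csv:
        report += ["## Pharmacology", ""]
        stage = {}
        if config.assay_camp_csv:
            manifest["inputs"][config.assay_camp_csv] = _digest(config.assay_camp_csv)
            df = pd.read_csv(config.assay_camp_csv)
            fit_rows = []
            for (cid, ctx), grp in df.groupby(["compound_id", "cell_context"], sort=True):
                fit = pharm.fit_3pl(grp)
                fit_rows.append(
                    {
                        "compound_id": cid, "cell_context": ctx,
                        "pec50": fit.pec50, "se_pec50": fit.se_pec50,
                        "basal": fit.basal, "emax": fit.emax, "range": fit.range,
                        "converged": fit.converged,
                    }
                )
            fits = pd.DataFrame(fit_rows)
            _write_csv(fits, tables / "camp_fits.csv")
            manifest["outputs"].append("tables/camp_fits.csv")
            stage["n_camp_fits"] = len(fits)
            report += [f"- cAMP dose-response fits: {len(fits)} (tables/camp_fits.csv)"]
        if config.assay_prolif_csv:
            manifest["inputs"][config.assay_prolif_csv] = _digest(config.assay_prolif_csv)
            df = pd.read_csv(config.assay_prolif_csv)
            rows = []
            for (cid, ctx), grp in df.groupby(["compound_id", "cell_context"], sort=True):
                fit = pharm.fit_3pl(grp, basal_fixed=100.0)
                span = 100.0 - fit.emax
                res = pharm.proliferation_factor(fit.pec50, span)
                rows.append(
                    {
                        "compound_id": cid, "cell_context": ctx,
                        "pic50": fit.pec50, "span": span,
                        "proliferation_factor": res.proliferation_factor,
                        "anti_proliferative": res.anti_proliferative,
                    }
                )
            prolif = pd.DataFrame(rows)
            _write_csv(prolif, tables / "proliferation.csv")
            manifest["outputs"].append("tables/proliferation.csv")
            stage["n_prolif_fits"] = len(prolif)
            report += [f"- proliferation fits + factors: {len(prolif)} (tables/proliferation.csv)"]
        manifest["stages"]["pharmacology"] = stage
        report += [""]
        log_stage("pharmacology", "done")
    else:
        log_stage("pharmacology", "skipped (no inputs)")

    (out / "report.md").write_text("\n".join(report))
    manifest["outputs"].append("report.md")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest
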