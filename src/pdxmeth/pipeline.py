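"""End-to-end pipeline driver.

Runs the stages in dependency order — synthesis, probe QC, fidelity
statistics, enrichment — writing every artifact under one output directory
together with a manifest recording the parameters and master seed that
produced it, so any output can be regenerated exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from pdxmeth import _seeds, enrichment, fidelity, io, qc, synth

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of an end-to-end run.

    When ``beta`` / ``annotation`` paths are given the pipeline consumes
    them; otherwise the synthesis stage generates all inputs.  One master
    seed governs every stochastic stage.
    """

    outdir: str = "pdxmeth_out"
    seed: int = 0
    # synthesis
    n_probes: int = synth.FIXTURE_N_PROBES
    n_patients: int = 3
    frac_changing: float = 0.027
    min_shift: float = 0.51
    frac_cross_hyb: float = 0.05
    # optional external inputs (paths)
    beta: str | None = None
    annotation: str | None = None
    # QC
    detection_p: float = 0.01
    bead_min: int = 3
    bead_sample_frac: float = 0.05
    drop_sex: bool = True
    # fidelity / enrichment
    thresholds_grid: tuple[float, ...] = (0.51, 0.41, 0.31, 0.21)
    enrich_reps: int = 1000
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a config file; keyword overrides (e.g. CLI flags) win."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "thresholds_grid" in data:
            data["thresholds_grid"] = tuple(data["thresholds_grid"])
        config = cls(**data)
        config.validate()
        return config

    def validate(self) -> None:
        for name in ("beta", "annotation"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"config references missing {name} file: {path}")

    def qc_thresholds(self) -> qc.QCThresholds:
        return qc.QCThresholds(
            detection_p=self.detection_p,
            bead_min=self.bead_min,
            bead_sample_frac=self.bead_sample_frac,
            drop_sex=self.drop_sex,
        )


def _synth_stage(config: RunConfig, outdir: Path) -> dict:
    """Generate annotation, paired beta matrix, detp/bead matrices, mouse detp."""
    if config.annotation is not None:
        annotation = io.read_annotation_tsv(config.annotation)
    else:
        annotation = synth.generate_annotation(config.n_probes, seed=config.seed)
    n_probes = len(annotation)

    planted = {}
    if config.beta is not None:
        beta = io.read_beta_tsv(config.beta)
        pairs = []
    else:
        model = synth.MethylomeModel(n_probes=n_probes, seed=config.seed)
        patients = synth.generate_pool(model, config.n_patients, annotation)
        patients.columns = [f"T{i + 1}P" for i in range(config.n_patients)]
        columns, pairs = [], []
        for i, pid in enumerate(patients.columns):
            plan = synth.PairPlan(
                frac_changing=config.frac_changing,
                min_shift=config.min_shift,
                seed=config.seed + i + 1,
            )
            xeno, planted_set = synth.generate_pdx_pair(patients[pid], plan)
            xeno.name = f"T{i + 1}X1"
            columns += [patients[pid], xeno]
            pairs.append((pid, xeno.name))
            planted[xeno.name] = planted_set
        beta = pd.concat(columns, axis=1)

    rng = _seeds.child_rng(config.seed, 99)
    detp = pd.DataFrame(
        rng.uniform(1e-6, 0.005, size=beta.shape), index=beta.index, columns=beta.columns
    )
    n_fail = max(1, int(0.005 * n_probes))
    fail_idx = rng.choice(n_probes, size=n_fail, replace=False)
    detp.iloc[fail_idx, 0] = rng.uniform(0.02, 0.5, size=n_fail)
    beads = pd.DataFrame(10, index=beta.index, columns=beta.columns)
    n_lowbead = max(1, int(0.002 * n_probes))
    low_idx = rng.choice(n_probes, size=n_lowbead, replace=False)
    beads.iloc[low_idx, :] = 2
    mouse_detp = synth.generate_mouse_qc(
        n_probes, config.frac_cross_hyb, seed=config.seed, probe_ids=beta.index
    )

    io.write_annotation_tsv(annotation, outdir / "annotation.tsv")
    io.write_matrix_tsv(beta, outdir / "beta.tsv")
    io.write_matrix_tsv(detp, outdir / "detp.tsv")
    io.write_matrix_tsv(beads, outdir / "beads.tsv")
    mouse_detp.to_frame().to_csv(outdir / "mouse_detp.tsv", sep="\t")
    return {
        "annotation": annotation,
        "beta": beta,
        "detp": detp,
        "beads": beads,
        "mouse_detp": mouse_detp,
        "pairs": pairs,
        "planted": planted,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run synthesis -> QC -> fidelity -> enrichment; return artifact summary.

    Writes all reports plus ``manifest.json`` (parameters, seed, per-stage
    counts) under ``config.outdir``.  A stage failure raises with the stage
    named; nothing is written past the failed stage.
    """
    logging.basicConfig(level=config.log_level)
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": dataclasses.asdict(config), "seed": config.seed, "stages": {}}

    stage = "synth"
    try:
        data = _synth_stage(config, outdir)
        manifest["stages"]["synth"] = {
            "n_probes": int(len(data["beta"])),
            "n_samples": int(data["beta"].shape[1]),
        }
        logger.info("synth: %d probes, %d samples", len(data["beta"]), data["beta"].shape[1])

        stage = "qc"
        thresholds = config.qc_thresholds()
        beta_qc, report = qc.apply_qc(
            data["beta"],
            detp=data["detp"],
            beads=data["beads"],
            detp_mouse=data["mouse_detp"],
            annotation=data["annotation"],
            thresholds=thresholds,
        )
        report.to_frame().to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
        for rule, ids in report.removed_by_rule.items():
            io.write_probe_list(ids, outdir / f"qc_removed_{rule}.txt")
        manifest["stages"]["qc"] = {k: int(v) for k, v in report.counts.items()}
        logger.info("qc: retained %d of %d probes", len(beta_qc), len(data["beta"]))

        stage = "fidelity"
        threshold = fidelity.ReversalThreshold()
        pair_deltas, rows, reversed_sets = [], [], {}
        for patient_id, xeno_id in data["pairs"]:
            pair = fidelity.delta_beta(beta_qc, patient_id, xeno_id)
            summary = fidelity.reversed_fraction(pair, threshold)
            pair_deltas.append(pair)
            reversed_sets[xeno_id] = summary.probes
            rows.append((patient_id, xeno_id, summary.count, summary.percent))
        reversal = pd.DataFrame(rows, columns=["patient", "xenograft", "count", "percent"])
        reversal.to_csv(outdir / "reversal_report.tsv", sep="\t", index=False)
        if pair_deltas:
            sens = fidelity.threshold_sensitivity(pair_deltas, config.thresholds_grid)
            sens.to_csv(outdir / "threshold_sensitivity.tsv", sep="\t", index=False)
            hist = fidelity.feature_histograms(beta_qc, data["annotation"])
            hist.to_csv(outdir / "feature_histograms.tsv", sep="\t", index=False)
            first = pair_deltas[0]
            first_set = reversed_sets[first.xenograft_id]
            if len(first_set):
                scores = first.delta.abs().loc[first_set].to_dict()
                io.write_bed(first_set, data["annotation"], outdir / "reversed_probes.bed", scores)
        manifest["stages"]["fidelity"] = {
            "pairs": len(pair_deltas),
            "reversed_counts": {x: int(c) for _, x, c, _ in rows},
        }

        stage = "enrich"
        if pair_deltas and len(reversed_sets[pair_deltas[0].xenograft_id]):
            target = reversed_sets[pair_deltas[0].xenograft_id]
            enr = enrichment.resampling_enrichment(
                target, beta_qc.index, data["annotation"],
                n_reps=config.enrich_reps, seed=config.seed,
            )
            enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            manifest["stages"]["enrich"] = {"target_size": int(len(target))}
            if len(reversed_sets) >= 2 and all(len(s) for s in reversed_sets.values()):
                ov = enrichment.overlap_percentages(reversed_sets)
                with open(outdir / "overlap_report.tsv", "w") as fh:
                    fh.write("comparison\tpercent\n")
                    for pair_key, pct in ov["pairwise"].items():
                        fh.write(f"{'&'.join(sorted(pair_key))}\t{pct:.4f}\n")
                    fh.write(f"all\t{ov['all']:.4f}\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
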