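"""End-to-end pipeline: simulate (or load) -> quantify -> test -> screen.

``run_pipeline`` chains the modules on disk artifacts: RNA-seq counts are
size-factor normalized, TPM-transformed and Wald-tested; droplet wells
are quantified to copies/uL; the two arms are intersected by the
three-gate screen; and every table, the resolved configuration, a summary
and a checksum manifest are written to the output directory.  Outputs are
deterministic given the seed and inputs — no timestamps, sorted JSON keys
— so two runs of the same configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .ddpcr import quantify_panel
from .errors import ValidationError
from .rnaseq import CountData, nb_wald_test, size_factors, tpm
from .screen import ScreenReport, ScreenThresholds, ddpcr_group_test, run_screen
from .simulate import LfcDistribution, SimConfig, simulate_experiment

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved settings for one pipeline run; round-trips through YAML.

    In simulate mode (``simulate=True``) inputs are generated from ``sim``;
    otherwise ``counts``/``lengths``/``samples``/``droplets`` paths must
    point at existing TSV files.
    """

    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    thresholds: ScreenThresholds = field(default_factory=ScreenThresholds)
    ddpcr_test_mode: str = "auto"
    counts: str | None = None
    lengths: str | None = None
    samples: str | None = None
    droplets: str | None = None
    annotations: str | None = None
    seed: int | None = None  # overrides sim.seed when set

    def to_yaml(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        doc = dict(doc)
        if "sim" in doc and isinstance(doc["sim"], dict):
            sim = dict(doc["sim"])
            if "lfc" in sim and isinstance(sim["lfc"], dict):
                sim["lfc"] = LfcDistribution(**sim["lfc"])
            for key in ("baseline_log10_range", "library_size_range", "gene_length_range",
                        "droplet_count_range", "group_names"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            if isinstance(sim.get("nb_dispersion"), list):
                sim["nb_dispersion"] = tuple(sim["nb_dispersion"])
            doc["sim"] = SimConfig(**sim)
        if "thresholds" in doc and isinstance(doc["thresholds"], dict):
            doc["thresholds"] = ScreenThresholds(**doc["thresholds"])
        return cls(**doc)


def _load_inputs(cfg: PipelineConfig):
    problems = []
    for name in ("counts", "lengths", "samples", "droplets"):
        if getattr(cfg, name) is None:
            problems.append(f"missing required input path: {name}")
    if problems:
        raise ValidationError("; ".join(problems))
    counts = gio.read_matrix(cfg.counts)
    lengths = gio.read_lengths(cfg.lengths)
    groups = gio.read_samples(cfg.samples)
    wells = gio.read_droplets(cfg.droplets)
    data = CountData(counts=counts, lengths=lengths, groups=groups)
    return data, wells, None


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> ScreenReport:
    """Run the full chain and write all artifacts under ``out_dir``.

    Returns the :class:`ScreenReport`.  On failure, partially written
    outputs are removed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run(config, out, written)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _run(config: PipelineConfig, out: Path, written: list[Path]) -> ScreenReport:
    cfg = config
    if cfg.seed is not None and cfg.simulate:
        cfg = dataclasses.replace(cfg, sim=dataclasses.replace(cfg.sim, seed=cfg.seed))

    truth = None
    if cfg.simulate:
        data, wells, truth = simulate_experiment(cfg.sim)
        log.info("simulated %d genes x %d samples, %d wells",
                 len(data.counts), data.counts.shape[1], len(wells))
        written.append(gio.write_table(
            data.counts, out / "counts.tsv",
            schema={"gene": "gene id", "<sample>": "read count (int)"}))
        written.append(gio.write_table(
            data.lengths.to_frame(), out / "lengths.tsv",
            schema={"gene": "gene id", "length": "gene length in bp"}))
        written.append(gio.write_table(
            data.groups.to_frame(), out / "samples.tsv", index_label="sample",
            schema={"sample": "sample id", "group": "group label"}))
        droplets_df = gio.wells_to_frame(wells, truth.saturated)
        written.append(gio.write_table(
            droplets_df, out / "droplets.tsv", index_label=None,
            schema={"gene": "gene id", "sample": "sample id",
                    "n_droplets": "accepted droplets", "n_positive": "positive droplets",
                    "droplet_volume_ul": "droplet volume (uL)",
                    "flags": "simulation flags"}))
        truth.to_dir(out)
        written += [out / f"truth_{t}.tsv" for t in ("genes", "samples", "lambda", "saturated")]
    else:
        data, wells, _ = _load_inputs(cfg)

    # RNA-seq arm
    sf = size_factors(data.counts)
    tpm_mat = tpm(data.counts, data.lengths)
    de_rna = nb_wald_test(data, sf, alpha_sig=cfg.thresholds.alpha_rnaseq)
    log.info("RNA-seq arm: %d/%d genes significant (BH p < %g)",
             int(de_rna["significant"].sum()), len(de_rna), cfg.thresholds.alpha_rnaseq)
    written.append(gio.write_table(
        tpm_mat, out / "tpm.tsv",
        schema={"gene": "gene id", "<sample>": "transcripts per million"}))
    written.append(gio.write_table(
        de_rna, out / "de_rnaseq.tsv",
        schema={"gene": "gene id", "log2fc": "log2 fold change group2 vs group1",
                "se": "standard error of log2fc", "stat": "Wald z",
                "p_raw": "two-sided Wald p", "p_adj": "BH-adjusted p",
                "direction": "up/down/none", "testable": "bool",
                "dispersion": "NB dispersion (method of moments)",
                "significant": "p_adj below threshold"}))

    # ddPCR arm
    copies, qc = quantify_panel(wells)
    de_dd = ddpcr_group_test(copies, data.groups, mode=cfg.ddpcr_test_mode,
                             alpha_sig=cfg.thresholds.alpha_ddpcr,
                             group_order=data.group_order)
    log.info("ddPCR arm: %d/%d genes significant (raw p < %g)",
             int(de_dd["significant"].sum()), len(de_dd), cfg.thresholds.alpha_ddpcr)
    written.append(gio.write_table(
        copies, out / "copies_per_ul.tsv",
        schema={"gene": "gene id", "<sample>": "copies/uL (empty = saturated/missing)"}))
    written.append(gio.write_table(
        qc, out / "ddpcr_qc.tsv", index_label=None,
        schema={"gene": "gene id", "sample": "sample id",
                "n_droplets": "total droplets", "n_positive": "positive droplets",
                "lambda_hat": "copies/uL", "ci_low": "95% CI lower",
                "ci_high": "95% CI upper", "flags": "semicolon-joined QC flags"}))
    written.append(gio.write_table(
        de_dd, out / "de_ddpcr.tsv",
        schema={"gene": "gene id", "mean_diff": "mean copies/uL group2 - group1",
                "p": "two-group p", "test_used": "t_student/mann_whitney",
                "direction": "up/down/none", "testable": "bool",
                "significant": "p below threshold",
                "n_group1": "values used", "n_group2": "values used"}))

    annotations = None
    if cfg.annotations is not None:
        annotations = pd.read_csv(cfg.annotations, sep="\t").set_index("gene")

    report = run_screen(de_rna, de_dd, tpm_mat, copies,
                        thresholds=cfg.thresholds, annotations=annotations)
    s = report.summary
    log.info("screen funnel: %d genes -> %d sDE RNA-seq / %d sDE ddPCR -> "
             "%d both -> %d direction-agree -> %d candidates",
             s["n_genes"], s["n_sde_rnaseq"], s["n_sde_ddpcr"],
             s["n_sde_both"], s["n_direction_agree"], s["n_candidates"])

    written.append(gio.write_table(
        report.records, out / "screen_report.tsv",
        schema={"gene": "gene id", "...": "per-gene gate outcomes; see module docs"}))
    for arm, frame, eff, pcol in (
        ("rnaseq", de_rna, "log2fc", "p_adj"),
        ("ddpcr", de_dd, "mean_diff", "p"),
    ):
        vol = pd.DataFrame(
            {"effect": frame[eff],
             "neg_log10_p": -np.log10(frame[pcol].astype(float))},
            index=frame.index)
        written.append(gio.write_table(
            vol, out / f"volcano_{arm}.tsv",
            schema={"gene": "gene id", "effect": eff, "neg_log10_p": f"-log10({pcol})"}))

    with open(out / "summary.json", "w") as fh:
        json.dump(report.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(out / "summary.json")

    cfg.to_yaml(out / "resolved_config.yaml")
    written.append(out / "resolved_config.yaml")

    manifest = {p.name: gio.sha256_of(p) for p in sorted(written) if p.exists()}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return report
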