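"""Cross-platform candidate screening.

The selection procedure intersects the two measurement arms gene by gene:

1. ``sde_both`` — the gene is significantly differentially expressed on
   the RNA-seq arm (BH-adjusted Wald p < alpha) AND on the ddPCR arm
   (two-group test on copies/uL, raw p < alpha);
2. ``direction_agree`` — the sign of the RNA-seq log2 fold change matches
   the sign of the ddPCR mean difference (zero effect counts as
   disagreement); evaluated only for genes passing gate 1;
3. ``correlated`` — the gene's TPM and copies/uL vectors, pooled across
   the samples of both groups, show a significant Spearman correlation
   (p < alpha).

A gene passing all three gates is a candidate.  Candidates can be joined
with a user-supplied annotation table carrying ``has_modulator`` and
``previously_studied`` flags to produce a ranked shortlist (druggable,
not previously studied first); the scientific judgment behind those flags
is outside the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .stats import CorrelationResult, spearman, two_group_test

__all__ = [
    "ScreenThresholds",
    "ScreenReport",
    "ddpcr_group_test",
    "overall_concordance",
    "per_gene_concordance",
    "run_screen",
]


@dataclass(frozen=True)
class ScreenThresholds:
    """Per-gate significance levels (all applied as strict p < alpha).

    RNA-seq uses the BH-adjusted p (the sequencing arm is corrected for
    multiple comparisons); ddPCR and the correlation gate use raw p.
    """

    alpha_rnaseq: float = 0.05
    alpha_ddpcr: float = 0.05
    alpha_corr: float = 0.05

    def __post_init__(self) -> None:
        for name in ("alpha_rnaseq", "alpha_ddpcr", "alpha_corr"):
            a = getattr(self, name)
            if not 0.0 < a < 1.0:
                raise ValidationError(f"{name} must lie in (0, 1), got {a}")


def ddpcr_group_test(
    copies: pd.DataFrame,
    groups: pd.Series,
    mode: str = "auto",
    alpha_sig: float = 0.05,
    group_order: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Per-gene two-group comparison of absolute concentrations.

    Missing cells (saturated or failed wells) are dropped per gene; genes
    left with fewer than 3 values in either group are untestable.  Effect
    is the mean difference group2 - group1 in copies/uL.
    """
    labels = pd.unique(groups.loc[copies.columns])
    if len(labels) != 2:
        raise ValidationError("need exactly two groups")
    if group_order is None:
        group_order = (str(labels[0]), str(labels[1]))
    g1, g2 = group_order
    cols1 = [c for c in copies.columns if groups.loc[c] == g1]
    cols2 = [c for c in copies.columns if groups.loc[c] == g2]

    rows = []
    for gene in copies.index:
        a = copies.loc[gene, cols1].dropna().to_numpy(dtype=float)
        b = copies.loc[gene, cols2].dropna().to_numpy(dtype=float)
        if a.size < 3 or b.size < 3:
            rows.append(
                {"mean_diff": np.nan, "p": np.nan, "test_used": "none",
                 "direction": "none", "testable": False, "significant": False,
                 "n_group1": a.size, "n_group2": b.size}
            )
            continue
        res = two_group_test(a, b, mode=mode)
        direction = "up" if res.mean_diff > 0 else ("down" if res.mean_diff < 0 else "none")
        rows.append(
            {"mean_diff": res.mean_diff, "p": res.p, "test_used": res.test_used,
             "direction": direction, "testable": True,
             "significant": bool(res.p < alpha_sig),
             "n_group1": a.size, "n_group2": b.size}
        )
    return pd.DataFrame(rows, index=copies.index)


def overall_concordance(tpm: pd.DataFrame, copies: pd.DataFrame) -> CorrelationResult:
    """Single Spearman over all gene x sample pairs of the two platforms.

    Pools every gene in every sample of both groups into one scatter (the
    'one dot per gene per sample' view); cells missing on either platform
    are dropped pairwise.
    """
    genes = tpm.index.intersection(copies.index)
    samp = tpm.columns.intersection(copies.columns)
    if len(genes) == 0 or len(samp) == 0:
        raise ValidationError("matrices share no genes or samples")
    a = tpm.loc[genes, samp].to_numpy(dtype=float).ravel()
    b = copies.loc[genes, samp].to_numpy(dtype=float).ravel()
    keep = ~(np.isnan(a) | np.isnan(b))
    if keep.sum() < 10:
        raise ValidationError(f"only {int(keep.sum())} shared pairs; need >= 10")
    return spearman(a[keep], b[keep])


def per_gene_concordance(
    tpm: pd.DataFrame, copies: pd.DataFrame, gene: str
) -> CorrelationResult:
    """Spearman across samples between one gene's TPM and copies/uL vectors.

    Samples missing on either platform reduce n; fewer than 4 complete
    pairs (or a constant vector) leaves the gene untestable, which the
    screen treats as a failed correlation gate.
    """
    if gene not in tpm.index or gene not in copies.index:
        raise ValidationError(f"gene {gene!r} absent from one platform")
    samp = tpm.columns.intersection(copies.columns)
    a = tpm.loc[gene, samp].to_numpy(dtype=float)
    b = copies.loc[gene, samp].to_numpy(dtype=float)
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if a.size < 4:
        return CorrelationResult(float("nan"), float("nan"), int(a.size), "undefined")
    return spearman(a, b)


@dataclass
class ScreenReport:
    """Outcome of a screen: per-gene records, summary funnel, settings."""

    records: pd.DataFrame
    overall: CorrelationResult
    thresholds: ScreenThresholds
    summary: dict = field(default_factory=dict)

    def recompute_summary(self) -> dict:
        r = self.records
        up_r = r["rnaseq_significant"] & (r["rnaseq_direction"] == "up")
        dn_r = r["rnaseq_significant"] & (r["rnaseq_direction"] == "down")
        up_d = r["ddpcr_significant"] & (r["ddpcr_direction"] == "up")
        dn_d = r["ddpcr_significant"] & (r["ddpcr_direction"] == "down")
        return {
            "n_genes": int(len(r)),
            "n_sde_rnaseq": int(r["rnaseq_significant"].sum()),
            "n_sde_rnaseq_up": int(up_r.sum()),
            "n_sde_rnaseq_down": int(dn_r.sum()),
            "n_sde_ddpcr": int(r["ddpcr_significant"].sum()),
            "n_sde_ddpcr_up": int(up_d.sum()),
            "n_sde_ddpcr_down": int(dn_d.sum()),
            "n_sde_both": int(r["sde_both"].sum()),
            "n_direction_agree": int((r["sde_both"] & r["direction_agree"]).sum()),
            "n_correlated": int(r["correlated"].sum()),
            "n_candidates": int(r["candidate"].sum()),
            "overall_rho": float(self.overall.rho),
            "overall_rho_p": float(self.overall.p),
        }

    def validate(self) -> None:
        s = self.recompute_summary()
        if s != self.summary:
            raise ValidationError("summary counts do not match records")
        if not (
            s["n_candidates"] <= s["n_sde_both"]
            <= min(s["n_sde_rnaseq"], s["n_sde_ddpcr"])
        ):
            raise ValidationError("gate funnel counts are inconsistent")

    @property
    def candidates(self) -> pd.DataFrame:
        return self.records[self.records["candidate"]]


def run_screen(
    de_rnaseq: pd.DataFrame,
    de_ddpcr: pd.DataFrame,
    tpm: pd.DataFrame,
    copies: pd.DataFrame,
    thresholds: ScreenThresholds = ScreenThresholds(),
    annotations: pd.DataFrame | None = None,
) -> ScreenReport:
    """Apply the three-gate screen and assemble the report.

    ``de_rnaseq`` must carry ``log2fc``/``p_adj``/``direction`` indexed by
    gene (as produced by :func:`gpcrscreen.rnaseq.nb_wald_test`);
    ``de_ddpcr`` must carry ``mean_diff``/``p``/``direction`` (as produced
    by :func:`ddpcr_group_test`).  Both must cover the same gene panel.
    ``annotations``, when given, is indexed by gene with boolean columns
    ``has_modulator`` and ``previously_studied``; annotation genes outside
    the panel are ignored with a warning column in the report summary.
    """
    genes = de_rnaseq.index
    if not genes.equals(de_ddpcr.index):
        common = genes.intersection(de_ddpcr.index)
        if len(common) != len(genes) or len(common) != len(de_ddpcr.index):
            raise ValidationError("RNA-seq and ddPCR results cover different gene panels")
        de_ddpcr = de_ddpcr.loc[genes]

    th = thresholds
    sig_rna = de_rnaseq["testable"] & (de_rnaseq["p_adj"] < th.alpha_rnaseq)
    sig_dd = de_ddpcr["testable"] & (de_ddpcr["p"] < th.alpha_ddpcr)
    sde_both = (sig_rna & sig_dd).to_numpy()

    dir_rna = de_rnaseq["direction"].to_numpy()
    dir_dd = de_ddpcr["direction"].to_numpy()
    agree = (dir_rna == dir_dd) & (dir_rna != "none")
    # direction gate only defined where both platforms call the gene
    direction_agree = np.where(sde_both, agree, False)

    rho = np.full(len(genes), np.nan)
    corr_p = np.full(len(genes), np.nan)
    corr_n = np.zeros(len(genes), dtype=int)
    correlated = np.zeros(len(genes), dtype=bool)
    for i, gene in enumerate(genes):
        res = per_gene_concordance(tpm, copies, gene)
        rho[i], corr_p[i], corr_n[i] = res.rho, res.p, res.n
        correlated[i] = bool(np.isfinite(res.p) and res.p < th.alpha_corr)

    candidate = sde_both & direction_agree & correlated

    records = pd.DataFrame(
        {
            "rnaseq_log2fc": de_rnaseq["log2fc"],
            "rnaseq_p_adj": de_rnaseq["p_adj"],
            "rnaseq_significant": sig_rna,
            "rnaseq_direction": dir_rna,
            "ddpcr_mean_diff": de_ddpcr["mean_diff"],
            "ddpcr_p": de_ddpcr["p"],
            "ddpcr_significant": sig_dd,
            "ddpcr_direction": dir_dd,
            "cross_rho": rho,
            "cross_p": corr_p,
            "cross_n": corr_n,
            "sde_both": sde_both,
            "direction_agree": direction_agree,
            "correlated": correlated,
            "candidate": candidate,
        },
        index=genes,
    )

    if annotations is not None:
        extra = annotations.index.difference(genes)
        ann = annotations.loc[annotations.index.intersection(genes)]
        records = records.join(ann[["has_modulator", "previously_studied"]])
        records["has_modulator"] = records["has_modulator"].fillna(False).astype(bool)
        records["previously_studied"] = (
            records["previously_studied"].fillna(True).astype(bool)
        )
        # druggable-and-novel candidates rank first
        records["shortlist_rank"] = np.where(
            records["candidate"] & records["has_modulator"] & ~records["previously_studied"], 0,
            np.where(records["candidate"] & records["has_modulator"], 1,
                     np.where(records["candidate"], 2, 3)),
        )
        if len(extra) > 0:
            records.attrs["annotation_genes_ignored"] = list(map(str, extra))

    overall = overall_concordance(tpm, copies)
    report = ScreenReport(records=records, overall=overall, thresholds=th)
    report.summary = report.recompute_summary()
    report.validate()
    return report
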