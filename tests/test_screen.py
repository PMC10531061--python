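"""Cross-platform concordance and the three-gate candidate screen."""

import numpy as np
import pandas as pd
import pytest

from gpcrscreen import (
    ScreenThresholds,
    ValidationError,
    overall_concordance,
    per_gene_concordance,
    run_screen,
    spearman,
)

# Frozen reference run: default configuration (288 genes, 40 planted with
# |log2FC| >= 1, seed 0).  All 18 recovered candidates are planted genes.
FROZEN_CANDIDATES = [
    "g006", "g022", "g048", "g049", "g062", "g064", "g103", "g113", "g120",
    "g133", "g144", "g165", "g175", "g182", "g197", "g216", "g235", "g239",
]
FROZEN_RECOVERY = 18 / 40
FROZEN_OVERALL_RHO = 0.8323631596229653


def _de_frames(genes, rna_sig, rna_dir, dd_sig, dd_dir):
    de_rna = pd.DataFrame(
        {
            "log2fc": [1.0 if d == "up" else -1.0 if d == "down" else 0.0 for d in rna_dir],
            "p_adj": [0.01 if s else 0.5 for s in rna_sig],
            "direction": rna_dir,
            "testable": True,
        },
        index=genes,
    )
    de_dd = pd.DataFrame(
        {
            "mean_diff": [1.0 if d == "up" else -1.0 if d == "down" else 0.0 for d in dd_dir],
            "p": [0.01 if s else 0.5 for s in dd_sig],
            "direction": dd_dir,
            "testable": True,
        },
        index=genes,
    )
    return de_rna, de_dd


def _correlated_matrices(genes, n=10, seed=0):
    """TPM/copies pairs that correlate perfectly per gene (rank-identical)."""
    rng = np.random.default_rng(seed)
    tpm = pd.DataFrame(rng.random((len(genes), n)) * 100, index=genes,
                       columns=[f"s{j}" for j in range(n)])
    copies = np.log1p(tpm)  # monotone transform: rho = 1 per gene
    return tpm, copies


class TestOverallConcordance:
    def test_monotone_transform_gives_rho_one(self):
        genes = [f"g{i}" for i in range(20)]
        tpm, copies = _correlated_matrices(genes)
        assert overall_concordance(tpm, copies).rho == pytest.approx(1.0)

    def test_independent_matrices_near_zero(self):
        rng = np.random.default_rng(123)
        genes = [f"g{i}" for i in range(288)]
        cols = [f"s{j}" for j in range(10)]
        a = pd.DataFrame(rng.random((288, 10)), index=genes, columns=cols)
        b = pd.DataFrame(rng.random((288, 10)), index=genes, columns=cols)
        assert abs(overall_concordance(a, b).rho) < 0.05

    def test_too_few_pairs_raises(self):
        genes = ["g1"]
        tpm = pd.DataFrame([[1.0, 2.0]], index=genes, columns=["s1", "s2"])
        with pytest.raises(ValidationError, match="pairs"):
            overall_concordance(tpm, tpm)

    def test_frozen_reference_rho(self, default_run):
        report, _, _ = default_run
        assert report.overall.rho == pytest.approx(FROZEN_OVERALL_RHO, abs=1e-12)


class TestPerGeneConcordance:
    def test_log_transform_invariance(self):
        genes = ["g1", "g2"]
        tpm, copies = _correlated_matrices(genes)
        res = per_gene_concordance(tpm, copies, "g1")
        assert res.rho == pytest.approx(1.0)

    def test_constant_platform_untestable(self):
        genes = ["g1"]
        cols = [f"s{j}" for j in range(6)]
        tpm = pd.DataFrame([[1, 2, 3, 4, 5, 6]], index=genes, columns=cols, dtype=float)
        copies = pd.DataFrame([[7.0] * 6], index=genes, columns=cols)
        res = per_gene_concordance(tpm, copies, "g1")
        assert res.method == "undefined"

    def test_missing_cells_reduce_n(self):
        genes = ["g1"]
        cols = [f"s{j}" for j in range(10)]
        tpm = pd.DataFrame([np.arange(10.0)], index=genes, columns=cols)
        copies = tpm.copy()
        copies.iloc[0, :3] = np.nan
        assert per_gene_concordance(tpm, copies, "g1").n == 7

    def test_exact_and_approximate_decisions_agree_at_n8(self):
        """Away from the decision boundary (|rho| outside [0.55, 0.75]), the
        exact permutation p and the t approximation make the same call at
        alpha = 0.05 for n = 8 paired values."""
        from scipy import stats as sps

        rng = np.random.default_rng(42)
        checked = 0
        while checked < 100:
            x = rng.normal(size=8)
            y = 0.5 * x + rng.normal(size=8)
            exact = spearman(x, y)  # n=8 -> exact permutation path
            if 0.55 <= abs(exact.rho) <= 0.75:
                continue
            t = exact.rho * np.sqrt(6 / (1 - exact.rho**2)) if abs(exact.rho) < 1 else np.inf
            p_t = 2 * sps.t.sf(abs(t), df=6)
            assert (exact.p < 0.05) == (p_t < 0.05)
            checked += 1


class TestRunScreen:
    def test_opposite_directions_fail_direction_gate(self):
        genes = ["g1"]
        de_rna, de_dd = _de_frames(genes, [True], ["up"], [True], ["down"])
        tpm, copies = _correlated_matrices(genes)
        rep = run_screen(de_rna, de_dd, tpm, copies)
        rec = rep.records.loc["g1"]
        assert rec["sde_both"] and not rec["direction_agree"] and not rec["candidate"]

    def test_single_platform_significance_fails_first_gate(self):
        genes = ["g1"]
        de_rna, de_dd = _de_frames(genes, [True], ["up"], [False], ["up"])
        tpm, copies = _correlated_matrices(genes)
        rec = run_screen(de_rna, de_dd, tpm, copies).records.loc["g1"]
        assert not rec["sde_both"] and not rec["candidate"]

    def test_all_gates_pass_makes_candidate(self):
        genes = [f"g{i}" for i in range(12)]
        de_rna, de_dd = _de_frames(
            genes, [True] * 12, ["up"] * 12, [True] * 12, ["up"] * 12
        )
        tpm, copies = _correlated_matrices(genes)
        rep = run_screen(de_rna, de_dd, tpm, copies)
        assert rep.records["candidate"].all()

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValidationError):
            ScreenThresholds(alpha_rnaseq=1.2)

    def test_annotation_join_ranks_novel_druggable_first(self):
        genes = [f"g{i}" for i in range(3)]
        de_rna, de_dd = _de_frames(genes, [True] * 3, ["up"] * 3, [True] * 3, ["up"] * 3)
        tpm, copies = _correlated_matrices(genes)
        ann = pd.DataFrame(
            {"has_modulator": [True, True, False],
             "previously_studied": [False, True, False]},
            index=genes,
        )
        rep = run_screen(de_rna, de_dd, tpm, copies, annotations=ann)
        ranks = rep.records["shortlist_rank"]
        assert ranks["g0"] < ranks["g1"] < ranks["g2"]

    def test_summary_counts_re_derivable(self, default_run):
        report, _, _ = default_run
        report.validate()  # raises if summary does not match records
        s = report.summary
        assert s["n_candidates"] <= s["n_sde_both"] <= min(
            s["n_sde_rnaseq"], s["n_sde_ddpcr"]
        )

    def test_frozen_candidate_set_and_recovery(self, default_run):
        """Default seeded experiment reproduces the reference candidate set
        bit-exactly and recovers planted genes within 3 MC SDs of the
        frozen rate."""
        report, truth, _ = default_run
        assert sorted(report.candidates.index) == FROZEN_CANDIDATES
        planted = set(truth.genes[truth.genes["is_de"]].index)
        tp = [g for g in report.candidates.index if g in planted]
        recovery = len(tp) / len(planted)
        mc_sd = np.sqrt(FROZEN_RECOVERY * (1 - FROZEN_RECOVERY) / len(planted))
        assert recovery >= FROZEN_RECOVERY - 3 * mc_sd

    def test_candidates_match_planted_direction(self, default_run):
        """Every true-positive candidate's effect sign equals the planted sign
        (all planted effects have |log2FC| >= 1 by construction)."""
        report, truth, _ = default_run
        planted = truth.genes[truth.genes["is_de"]]
        tp = report.candidates.index.intersection(planted.index)
        assert len(tp) > 0
        obs = np.sign(report.records.loc[tp, "rnaseq_log2fc"])
        true = np.sign(planted.loc[tp, "log2fc"])
        assert (obs == true).all()
        dd = np.sign(report.records.loc[tp, "ddpcr_mean_diff"])
        assert (dd == true).all()

    def test_tighter_thresholds_never_add_candidates(self, default_run):
        """Candidate sets shrink monotonically as any alpha is lowered."""
        report, truth, out = default_run
        import gpcrscreen as g

        de_rna = pd.read_csv(out / "de_rnaseq.tsv", sep="\t", index_col="gene")
        de_dd = pd.read_csv(out / "de_ddpcr.tsv", sep="\t", index_col="gene")
        tpm = pd.read_csv(out / "tpm.tsv", sep="\t", index_col="gene")
        copies = pd.read_csv(out / "copies_per_ul.tsv", sep="\t", index_col="gene")
        base = set(report.candidates.index)
        for th in (
            ScreenThresholds(alpha_rnaseq=0.01),
            ScreenThresholds(alpha_ddpcr=0.01),
            ScreenThresholds(alpha_corr=0.01),
        ):
            stricter = g.run_screen(de_rna, de_dd, tpm, copies, thresholds=th)
            assert set(stricter.candidates.index) <= base
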