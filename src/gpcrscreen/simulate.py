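"""Seeded synthetic two-group experiments with known ground truth.

Emulates the study design the screen targets: two groups (diseased vs.
sham-operated) of five animals each, a panel of ~288 receptor genes
measured both by bulk RNA-seq (negative-binomial gene counts with
library-size variation) and by droplet digital PCR (wells of
15,000-20,000 droplets with Poisson occupancy), with a configurable
fraction of planted differentially expressed genes whose log2 fold
changes are shared across the two platforms.

Cross-platform linkage: the true ddPCR concentration of gene g in sample
j is ``ddpcr_scale`` times the gene's true relative abundance (TPM units)
times a gene-specific lognormal assay-efficiency factor times a
gene-by-sample lognormal replicate deviation.  The two platforms
therefore correlate by construction, but imperfectly.

Randomness is split into one independent child stream per artifact
(design/truth, RNA-seq counts, droplets, amplitudes) derived from the
master seed, so adding one output type never perturbs the others, and a
fixed seed reproduces every artifact bit for bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ddpcr import DEFAULT_DROPLET_VOLUME_UL, DropletWell
from .errors import ValidationError

__all__ = [
    "LfcDistribution",
    "AmplitudeParams",
    "SimConfig",
    "SimTruth",
    "simulate_experiment",
    "simulate_amplitudes",
]


@dataclass(frozen=True)
class LfcDistribution:
    """Distribution of planted |log2FC|: normal truncated below, signed.

    Magnitudes are drawn N(magnitude_mean, magnitude_sd) truncated at
    ``magnitude_min`` (default 1.0, i.e. at least a two-fold change —
    planted effects are meant to be unambiguous); the sign is + with
    probability ``prob_up``.
    """

    magnitude_mean: float = 1.5
    magnitude_sd: float = 0.5
    magnitude_min: float = 1.0
    prob_up: float = 0.5


@dataclass(frozen=True)
class AmplitudeParams:
    """Two-Gaussian fluorescence model with optional uniform 'rain'.

    Negative and positive droplet clusters at ``neg_mean``/``pos_mean``
    (arbitrary fluorescence units); a ``rain_fraction`` of droplets is
    re-drawn uniformly between the two cluster means, emulating
    intermediate-amplitude droplets that complicate thresholding.
    """

    neg_mean: float = 2000.0
    neg_sd: float = 200.0
    pos_mean: float = 8000.0
    pos_sd: float = 400.0
    rain_fraction: float = 0.0


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults are the study conditions being emulated.

    288 panel genes, 5 animals per group, 40 planted DE genes
    (frac_de = 40/288), NB dispersion 0.1, size factors in [0.7, 1.3],
    droplet counts uniform in [15000, 20000], droplet volume 8.5e-4 uL.
    ``ddpcr_scale`` converts TPM units to copies/uL; its lognormal
    gene-specific noise (sd ``ddpcr_gene_noise_sd`` on the natural-log
    scale) and the per-well replicate noise (``ddpcr_sample_noise_sd``)
    are free parameters of the platform-noise model, documented in the
    methods note.
    """

    n_genes: int = 288
    n_per_group: int = 5
    frac_de: float = 40.0 / 288.0
    lfc: LfcDistribution = field(default_factory=LfcDistribution)
    baseline_log10_range: tuple[float, float] = (0.5, 3.5)
    nb_dispersion: float | tuple[float, float] = 0.1
    library_size_range: tuple[float, float] = (0.7, 1.3)
    gene_length_range: tuple[int, int] = (500, 5000)
    droplet_count_range: tuple[int, int] = (15_000, 20_000)
    droplet_volume_ul: float = DEFAULT_DROPLET_VOLUME_UL
    ddpcr_scale: float = 0.02
    ddpcr_gene_noise_sd: float = 1.5
    ddpcr_sample_noise_sd: float = 0.25
    group_names: tuple[str, str] = ("SHAM", "TAC")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_per_group < 2:
            raise ValidationError("need n_genes >= 1 and n_per_group >= 2")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValidationError("frac_de must lie in [0, 1]")
        for name in ("baseline_log10_range", "library_size_range",
                     "gene_length_range", "droplet_count_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValidationError(f"{name} must be a non-degenerate interval")
        if self.library_size_range[0] <= 0 or self.gene_length_range[0] <= 0:
            raise ValidationError("library sizes and gene lengths must be positive")
        if self.droplet_volume_ul <= 0 or self.ddpcr_scale <= 0:
            raise ValidationError("droplet_volume_ul and ddpcr_scale must be positive")
        disp = self.nb_dispersion
        if isinstance(disp, tuple):
            if not 0 < disp[0] < disp[1]:
                raise ValidationError("nb_dispersion range must be positive and increasing")
        elif disp <= 0:
            raise ValidationError("nb_dispersion must be positive")

    @property
    def n_de(self) -> int:
        return int(round(self.frac_de * self.n_genes))


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment.

    ``genes``: per-gene baseline mean, true log2FC (exactly 0 for non-DE),
    DE flag, length, ddPCR gene factor.  ``samples``: group and true size
    factor.  ``lambda_true``: genes x samples true copies/uL.
    ``saturated``: boolean genes x samples mask of wells whose expected
    negative-droplet count fell below 1 ("simulated saturation").
    """

    genes: pd.DataFrame
    samples: pd.DataFrame
    lambda_true: pd.DataFrame
    saturated: pd.DataFrame

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.genes.to_csv(path / "truth_genes.tsv", sep="\t", index_label="gene")
        self.samples.to_csv(path / "truth_samples.tsv", sep="\t", index_label="sample")
        self.lambda_true.to_csv(path / "truth_lambda.tsv", sep="\t", index_label="gene")
        self.saturated.to_csv(path / "truth_saturated.tsv", sep="\t", index_label="gene")

    @classmethod
    def from_dir(cls, path: str | Path) -> "SimTruth":
        path = Path(path)
        return cls(
            genes=pd.read_csv(path / "truth_genes.tsv", sep="\t", index_col="gene"),
            samples=pd.read_csv(path / "truth_samples.tsv", sep="\t", index_col="sample"),
            lambda_true=pd.read_csv(path / "truth_lambda.tsv", sep="\t", index_col="gene"),
            saturated=pd.read_csv(path / "truth_saturated.tsv", sep="\t", index_col="gene"),
        )


def _truncnorm_min(rng: np.random.Generator, mean: float, sd: float,
                   lower: float, size: int) -> np.ndarray:
    """Normal truncated below at ``lower`` by rejection (cheap at these sizes)."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled) + 8)
        draw = draw[draw >= lower]
        take = min(draw.size, size - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def simulate_experiment(
    config: SimConfig,
) -> tuple["CountData", list[DropletWell], SimTruth]:
    """Generate one two-group experiment: counts, droplet wells, truth.

    RNA-seq counts are NB(mean = size_factor * baseline * 2^(log2FC * x),
    dispersion); each ddPCR well draws n_droplets ~ U(droplet_count_range)
    and positives ~ Binomial(n_droplets, 1 - exp(-lambda V)) at the true
    gene x sample concentration.  Wells whose expected negative count is
    below 1 are emitted saturated and flagged in ``truth.saturated``
    rather than silently clipped.  Identical config and seed reproduce
    identical outputs.
    """
    from .rnaseq import CountData  # local import avoids a cycle at module load

    ss = np.random.SeedSequence(config.seed)
    s_design, s_counts, s_drop, _s_amp = ss.spawn(4)
    rng = np.random.default_rng(s_design)

    n, npg = config.n_genes, config.n_per_group
    n_samples = 2 * npg
    width = max(3, len(str(n)))
    genes = [f"g{i + 1:0{width}d}" for i in range(n)]
    g1, g2 = config.group_names
    samples = [f"{g1}_{i + 1}" for i in range(npg)] + [f"{g2}_{i + 1}" for i in range(npg)]
    group = np.array([g1] * npg + [g2] * npg)
    x = (group == g2).astype(float)

    baseline = 10.0 ** rng.uniform(*config.baseline_log10_range, size=n)
    lengths = rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1, size=n)

    lfc = np.zeros(n)
    de_flag = np.zeros(n, dtype=bool)
    n_de = config.n_de
    if n_de > 0:
        idx = np.sort(rng.choice(n, size=n_de, replace=False))
        mags = _truncnorm_min(rng, config.lfc.magnitude_mean, config.lfc.magnitude_sd,
                              config.lfc.magnitude_min, n_de)
        signs = np.where(rng.random(n_de) < config.lfc.prob_up, 1.0, -1.0)
        lfc[idx] = mags * signs
        de_flag[idx] = True

    sf = rng.uniform(*config.library_size_range, size=n_samples)
    disp = config.nb_dispersion
    alpha = (rng.uniform(*disp, size=n) if isinstance(disp, tuple)
             else np.full(n, float(disp)))
    gene_factor = np.exp(rng.normal(0.0, config.ddpcr_gene_noise_sd, size=n))
    well_noise = np.exp(rng.normal(0.0, config.ddpcr_sample_noise_sd, size=(n, n_samples)))

    # RNA-seq counts
    mu_bio = baseline[:, None] * 2.0 ** (lfc[:, None] * x[None, :])
    mu = mu_bio * sf[None, :]
    rng_counts = np.random.default_rng(s_counts)
    r = 1.0 / alpha[:, None]
    p = r / (r + mu)
    counts = rng_counts.negative_binomial(np.broadcast_to(r, mu.shape), p)
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    counts_df.index.name = "gene"

    # True ddPCR concentrations in copies/uL, linked through TPM units.
    # The denominator is the group-independent baseline total: the panel is
    # a tiny slice of the transcriptome, so planted effects within it must
    # not shift every other gene's relative abundance (a panel-only
    # denominator would create a compositional artifact the real
    # whole-transcriptome TPM does not have).
    rpk = mu_bio / (lengths[:, None] / 1000.0)
    rpk_base = baseline / (lengths / 1000.0)
    tpm_true = rpk / rpk_base.sum() * 1e6
    lam = config.ddpcr_scale * tpm_true * gene_factor[:, None] * well_noise

    # droplet wells
    rng_drop = np.random.default_rng(s_drop)
    lo, hi = config.droplet_count_range
    n_droplets = rng_drop.integers(lo, hi + 1, size=(n, n_samples))
    v = config.droplet_volume_ul
    p_pos = 1.0 - np.exp(-lam * v)
    n_pos = rng_drop.binomial(n_droplets, p_pos)
    saturated = n_droplets * np.exp(-lam * v) < 1.0

    wells = [
        DropletWell(
            gene=genes[i], sample=samples[j],
            n_droplets=int(n_droplets[i, j]), n_positive=int(n_pos[i, j]),
            droplet_volume_ul=v,
        )
        for i in range(n)
        for j in range(n_samples)
    ]

    truth = SimTruth(
        genes=pd.DataFrame(
            {
                "baseline_mean": baseline,
                "log2fc": lfc,
                "is_de": de_flag,
                "length": lengths,
                "dispersion": alpha,
                "ddpcr_gene_factor": gene_factor,
            },
            index=pd.Index(genes, name="gene"),
        ),
        samples=pd.DataFrame(
            {"group": group, "size_factor": sf},
            index=pd.Index(samples, name="sample"),
        ),
        lambda_true=pd.DataFrame(lam, index=pd.Index(genes, name="gene"), columns=samples),
        saturated=pd.DataFrame(saturated, index=pd.Index(genes, name="gene"), columns=samples),
    )
    data = CountData(
        counts=counts_df,
        lengths=pd.Series(lengths, index=pd.Index(genes, name="gene"), name="length"),
        groups=pd.Series(group, index=pd.Index(samples, name="sample"), name="group"),
        group_order=(g1, g2),
    )
    return data, wells, truth


def simulate_amplitudes(
    well: DropletWell,
    params: AmplitudeParams = AmplitudeParams(),
    rng: np.random.Generator | int | None = None,
) -> tuple[DropletWell, np.ndarray, bool]:
    """Attach synthetic fluorescence amplitudes to a well.

    Positive droplets draw from the high Gaussian cluster, negative from
    the low one; a ``rain_fraction`` of droplets is overwritten with
    amplitudes uniform between the two cluster means.  Returns
    ``(well_with_amplitudes, true_labels, overlap_warning)`` where
    ``true_labels`` is the hidden per-droplet positive mask (in the same
    order as the amplitudes) and ``overlap_warning`` is True when the
    cluster means are separated by less than 2 pooled SDs, in which case
    threshold recovery is not guaranteed.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    p = params
    if not 0.0 <= p.rain_fraction < 1.0:
        raise ValidationError("rain_fraction must lie in [0, 1)")
    n, k = well.n_droplets, well.n_positive
    labels = np.zeros(n, dtype=bool)
    labels[:k] = True
    rng.shuffle(labels)
    amps = np.where(
        labels,
        rng.normal(p.pos_mean, p.pos_sd, size=n),
        rng.normal(p.neg_mean, p.neg_sd, size=n),
    )
    if p.rain_fraction > 0:
        n_rain = int(round(p.rain_fraction * n))
        rain_idx = rng.choice(n, size=n_rain, replace=False)
        amps[rain_idx] = rng.uniform(p.neg_mean, p.pos_mean, size=n_rain)
    pooled_sd = float(np.sqrt(0.5 * (p.neg_sd**2 + p.pos_sd**2)))
    warn = (p.pos_mean - p.neg_mean) < 2.0 * pooled_sd
    new_well = dataclasses.replace(well, amplitudes=tuple(float(a) for a in amps))
    return new_well, labels, warn
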