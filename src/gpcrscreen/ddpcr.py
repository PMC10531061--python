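"""Absolute quantification from droplet digital PCR (ddPCR) wells.

A ddPCR reaction partitions the sample into roughly 15,000-20,000
nanolitre-scale droplets, PCR-amplifies the target in each droplet, and
reads each droplet out as positive (template present) or negative.  Under
Poisson occupancy with concentration ``lambda`` (copies/uL) and droplet
volume ``V`` (uL), the probability that a droplet is negative is
``exp(-lambda * V)``, so the maximum-likelihood estimate from ``k``
positives out of ``n`` droplets is

    lambda_hat = -ln(n_neg / n) / V

This module implements that estimator with a delta-method confidence
interval, an amplitude thresholder for instruments that report per-droplet
fluorescence, and panel-level assembly of a genes x samples concentration
matrix with QC flags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "DropletWell",
    "ConcentrationEstimate",
    "ThresholdResult",
    "threshold_droplets",
    "estimate_concentration",
    "merge_replicate_wells",
    "quantify_panel",
]

#: default droplet volume in microlitres (nominal for the QX200 droplet
#: generator class); always overridable per well, never baked into the math.
DEFAULT_DROPLET_VOLUME_UL = 8.5e-4

#: wells with fewer droplets than this are kept but flagged.
LOW_DROPLET_COUNT = 10_000


@dataclass(frozen=True)
class DropletWell:
    """One ddPCR reaction: droplet counts for one gene in one sample.

    Parameters
    ----------
    gene, sample
        Identifiers linking the well into the panel.
    n_droplets
        Total accepted droplets in the well.
    n_positive
        Droplets classified as template-positive.
    droplet_volume_ul
        Volume of a single droplet in microlitres.
    amplitudes
        Optional per-droplet fluorescence values (arbitrary units).  When
        present their length must equal ``n_droplets``.
    """

    gene: str
    sample: str
    n_droplets: int
    n_positive: int
    droplet_volume_ul: float = DEFAULT_DROPLET_VOLUME_UL
    amplitudes: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_droplets <= 0:
            raise ValidationError(f"{self.gene}/{self.sample}: n_droplets must be > 0")
        if not 0 <= self.n_positive <= self.n_droplets:
            raise ValidationError(
                f"{self.gene}/{self.sample}: need 0 <= n_positive <= n_droplets, "
                f"got {self.n_positive}/{self.n_droplets}"
            )
        if self.droplet_volume_ul <= 0:
            raise ValidationError("droplet_volume_ul must be positive")
        if self.amplitudes is not None and len(self.amplitudes) != self.n_droplets:
            raise ValidationError(
                f"{self.gene}/{self.sample}: {len(self.amplitudes)} amplitudes "
                f"for {self.n_droplets} droplets"
            )


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Point estimate of template concentration with 95% CI and QC flags.

    ``lambda_hat`` is NaN for saturated wells (all droplets positive): the
    Poisson MLE is unbounded there and the well is carried as missing rather
    than assigned a lower bound.  Flags are a subset of
    ``{"ok", "empty", "saturated", "low_droplet_count"}``.
    """

    lambda_hat: float
    ci_low: float
    ci_high: float
    n_droplets: int
    n_positive: int
    flags: frozenset[str] = field(default_factory=frozenset)

    @property
    def ok(self) -> bool:
        return "saturated" not in self.flags

    @property
    def saturated(self) -> bool:
        return "saturated" in self.flags

    @property
    def empty(self) -> bool:
        return "empty" in self.flags


@dataclass(frozen=True)
class ThresholdResult:
    n_positive: int
    threshold: float
    flags: frozenset[str] = field(default_factory=frozenset)


def _optimal_split(sorted_amps: np.ndarray) -> int:
    """Index of the 2-partition of a sorted vector minimizing within-cluster SSE.

    For 1-D data the optimal 2-means partition is a contiguous split of the
    sorted values, so an O(n) cumulative-sum scan over split points suffices.
    Returns the size of the lower cluster (in 1..n-1).
    """
    n = sorted_amps.size
    csum = np.cumsum(sorted_amps)
    csum2 = np.cumsum(sorted_amps**2)
    k = np.arange(1, n)  # lower-cluster sizes
    lo_sum, lo_sum2 = csum[k - 1], csum2[k - 1]
    hi_sum, hi_sum2 = csum[-1] - lo_sum, csum2[-1] - lo_sum2
    sse = (lo_sum2 - lo_sum**2 / k) + (hi_sum2 - hi_sum**2 / (n - k))
    return int(k[np.argmin(sse)])


def threshold_droplets(
    amplitudes: Sequence[float] | np.ndarray,
    method: str = "two_cluster",
    threshold: float | None = None,
) -> ThresholdResult:
    """Classify droplets as positive/negative from fluorescence amplitudes.

    ``manual`` uses the caller-supplied ``threshold``; ``two_cluster`` finds
    the contiguous 2-partition of the sorted amplitudes minimizing
    within-cluster variance and places the threshold at the midpoint of the
    gap between the two clusters.  If the resulting clusters are separated
    by less than 4 pooled within-cluster standard deviations the
    distribution is treated as unimodal (no positive cluster): all droplets
    are called negative and the ``no_positive_cluster`` flag is set rather
    than guessing a threshold.  (Splitting a single Gaussian in two always
    yields a separation of about 2.65 pooled within-cluster SDs, so the
    cutoff must sit above that; genuinely bimodal ddPCR wells sit far
    higher.)

    Droplets strictly above the threshold are positive.
    """
    amps = np.asarray(amplitudes, dtype=float)
    if amps.ndim != 1 or amps.size < 2:
        raise ValidationError("need a 1-D vector of at least 2 amplitudes")
    flags: set[str] = set()
    if amps.size < 100:
        flags.add("low_amplitude_count")

    if method == "manual":
        if threshold is None:
            raise ValidationError("manual thresholding requires an explicit threshold")
        n_pos = int(np.sum(amps > threshold))
        return ThresholdResult(n_pos, float(threshold), frozenset(flags))

    if method != "two_cluster":
        raise ValidationError(f"unknown thresholding method {method!r}")

    srt = np.sort(amps)
    k = _optimal_split(srt)
    lo, hi = srt[:k], srt[k:]
    sep = hi.mean() - lo.mean()
    pooled_var = (
        ((lo.size - 1) * lo.var(ddof=1) if lo.size > 1 else 0.0)
        + ((hi.size - 1) * hi.var(ddof=1) if hi.size > 1 else 0.0)
    ) / max(amps.size - 2, 1)
    pooled_sd = math.sqrt(max(pooled_var, 0.0))
    if pooled_sd > 0 and sep < 4.0 * pooled_sd:
        flags.add("no_positive_cluster")
        return ThresholdResult(0, float(srt[-1]), frozenset(flags))

    thr = 0.5 * (lo[-1] + hi[0])
    return ThresholdResult(int(np.sum(amps > thr)), float(thr), frozenset(flags))


def estimate_concentration(well: DropletWell) -> ConcentrationEstimate:
    """Poisson MLE of template concentration (copies/uL) for one well.

    ``lambda_hat = -ln(n_neg / n) / V``.  The 95% CI comes from the delta
    method on ``-ln(p_neg)``: ``SE = sqrt((1 - p_neg) / (n * p_neg)) / V``,
    ``CI = lambda_hat +/- 1.96 SE`` floored at zero.  Boundary wells:
    all-negative wells report 0 with the ``empty`` flag; all-positive wells
    are ``saturated`` with no finite estimate (NaN).
    """
    n, k, v = well.n_droplets, well.n_positive, well.droplet_volume_ul
    flags: set[str] = set()
    if n < LOW_DROPLET_COUNT:
        flags.add("low_droplet_count")

    if k == n:
        flags.add("saturated")
        nan = float("nan")
        return ConcentrationEstimate(nan, nan, nan, n, k, frozenset(flags))
    if k == 0:
        flags.add("empty")
        flags.add("ok")
        return ConcentrationEstimate(0.0, 0.0, 0.0, n, k, frozenset(flags))

    p_neg = (n - k) / n
    lam = -math.log(p_neg) / v
    se = math.sqrt((1.0 - p_neg) / (n * p_neg)) / v
    flags.add("ok")
    return ConcentrationEstimate(
        lambda_hat=lam,
        ci_low=max(lam - 1.96 * se, 0.0),
        ci_high=lam + 1.96 * se,
        n_droplets=n,
        n_positive=k,
        flags=frozenset(flags),
    )


def merge_replicate_wells(wells: Sequence[DropletWell]) -> DropletWell:
    """Pool replicate wells of the same gene x sample by summing droplets.

    Merging before estimation is the documented pre-step for replicates:
    the pooled counts carry the full binomial information.
    """
    if not wells:
        raise ValidationError("no wells to merge")
    gene, sample = wells[0].gene, wells[0].sample
    vol = wells[0].droplet_volume_ul
    for w in wells[1:]:
        if (w.gene, w.sample) != (gene, sample):
            raise ValidationError("can only merge wells of the same gene and sample")
        if w.droplet_volume_ul != vol:
            raise ValidationError("replicate wells disagree on droplet volume")
    return DropletWell(
        gene=gene,
        sample=sample,
        n_droplets=sum(w.n_droplets for w in wells),
        n_positive=sum(w.n_positive for w in wells),
        droplet_volume_ul=vol,
    )


def quantify_panel(
    wells: Iterable[DropletWell],
    merge_replicates: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Estimate concentrations for a panel of wells.

    Returns ``(copies, qc)`` where ``copies`` is a genes x samples DataFrame
    of copies/uL (NaN for saturated wells, carried forward as missing) and
    ``qc`` is a per-well table of counts, estimates, CI bounds and flags.

    Duplicate gene x sample wells raise unless ``merge_replicates`` is set,
    in which case droplets and positives are summed before estimation.
    """
    by_key: dict[tuple[str, str], list[DropletWell]] = {}
    order: list[tuple[str, str]] = []
    for w in wells:
        key = (w.gene, w.sample)
        if key not in by_key:
            by_key[key] = []
            order.append(key)
        by_key[key].append(w)

    if not by_key:
        raise ValidationError("no wells supplied")

    rows = []
    for key in order:
        grp = by_key[key]
        if len(grp) > 1:
            if not merge_replicates:
                raise ValidationError(
                    f"duplicate well for gene={key[0]} sample={key[1]}; "
                    "pass merge_replicates=True to pool them"
                )
            well = merge_replicate_wells(grp)
        else:
            well = grp[0]
        est = estimate_concentration(well)
        rows.append(
            {
                "gene": well.gene,
                "sample": well.sample,
                "n_droplets": est.n_droplets,
                "n_positive": est.n_positive,
                "lambda_hat": est.lambda_hat,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "flags": ";".join(sorted(est.flags)),
            }
        )
    qc = pd.DataFrame(rows)
    copies = qc.pivot(index="gene", columns="sample", values="lambda_hat")
    copies.index.name = "gene"
    copies.columns.name = None
    # preserve first-seen panel order rather than alphabetical
    gene_order = list(dict.fromkeys(g for g, _ in order))
    sample_order = list(dict.fromkeys(s for _, s in order))
    copies = copies.reindex(index=gene_order, columns=sample_order)
    return copies, qc
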