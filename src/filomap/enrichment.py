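"""Tip-vs-shaft enrichment scoring against a plasma-membrane reference.

For each filopodium the enrichment ratio is the mean intensity over the tip
bins (1-6) divided by the mean over the shaft bins (7-40).  Per-protein
cohorts of ratios are summarized as Tukey boxplot statistics (median,
quartiles, whiskers at 1.5x the interquartile range), and a protein is
called tip- or shaft-localized when its median ratio shows at least a
two-fold change over the plasma-membrane reference cohort's median AND a
two-sided Welch t-test on the log2 ratios is significant.  Plasma membrane
rather than F-actin anchors the comparison because the membrane itself is
slightly tip-enriched (the bud at the filopodium end), so a raw ratio of 1
is not a neutral baseline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .config import EnrichmentParams
from .errors import InsufficientDataError, ParameterError
from .mapping import BinnedProfile, POICohort, is_positive

logger = logging.getLogger("filomap")

__all__ = [
    "TukeyStats", "EnrichmentSummary", "enrichment_ratio", "tukey_stats",
    "summarize_enrichment", "classify_localization", "adjust_p_values",
    "plot_enrichment",
]


@dataclass
class TukeyStats:
    """Five-number boxplot summary with 1.5x IQR whiskers."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


@dataclass
class EnrichmentSummary:
    """Per-protein enrichment ratios with their Tukey summary."""

    poi_name: str
    ratios: np.ndarray
    stats: TukeyStats
    n_excluded: int = 0
    classification: Optional[str] = None  # "tip" | "shaft" | "none"
    p_value: Optional[float] = None

    @property
    def median_ratio(self) -> float:
        return self.stats.median


def enrichment_ratio(binned: BinnedProfile,
                     params: EnrichmentParams | None = None) -> float:
    """mean(tip bins 1-6) / mean(shaft bins 7-40) for one filopodium.

    Returns NaN (never an epsilon-padded value) when the shaft mean is zero;
    callers exclude such filopodia and log the reason.
    """
    params = params or EnrichmentParams()
    bins = binned.bins
    if bins.size != params.n_bins:
        raise ParameterError(
            f"profile has {bins.size} bins; enrichment geometry expects {params.n_bins}"
        )
    tip_mean = float(np.mean(bins[: params.tip_last_bin]))
    shaft_mean = float(np.mean(bins[params.tip_last_bin:]))
    if shaft_mean <= 0:
        return math.nan
    return tip_mean / shaft_mean


def tukey_stats(values: Sequence[float]) -> TukeyStats:
    """Median, quartiles and 1.5x-IQR whiskers of a sample.

    Whiskers extend to the most extreme data points within 1.5x IQR of the
    quartiles; anything beyond is listed as an outlier.
    """
    v = np.sort(np.asarray(values, dtype=np.float64))
    if v.size == 0:
        raise InsufficientDataError("no values for a Tukey summary")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return TukeyStats(
        median=float(med), q1=float(q1), q3=float(q3),
        whisker_low=float(inside.min()), whisker_high=float(inside.max()),
        outliers=v[(v < lo_fence) | (v > hi_fence)],
    )


def summarize_enrichment(
    cohort: POICohort,
    params: EnrichmentParams | None = None,
    positives_only: bool = True,
    mapping_params=None,
) -> EnrichmentSummary:
    """Collect a cohort's per-filopodium ratios and their Tukey summary.

    ``positives_only`` (default) restricts to filopodia positive for the
    protein — a ratio for an absent protein measures noise. Filopodia with a
    zero shaft mean are excluded and counted in ``n_excluded``.
    """
    params = params or EnrichmentParams()
    profiles = cohort.profiles
    if positives_only:
        profiles = [b for b in profiles if is_positive(b, mapping_params)]
    ratios, n_excluded = [], 0
    for b in profiles:
        r = enrichment_ratio(b, params)
        if math.isnan(r):
            n_excluded += 1
            logger.info("filopodium %s excluded: zero shaft mean", b.filopodium_id)
        else:
            ratios.append(r)
    if len(ratios) < 3:
        raise InsufficientDataError(
            f"cohort {cohort.poi_name!r}: only {len(ratios)} usable ratios (< 3)"
        )
    ratios = np.asarray(ratios)
    return EnrichmentSummary(
        poi_name=cohort.poi_name, ratios=ratios, stats=tukey_stats(ratios),
        n_excluded=n_excluded,
    )


def classify_localization(
    poi: EnrichmentSummary,
    reference: EnrichmentSummary,
    params: EnrichmentParams | None = None,
) -> tuple[str, float]:
    """Tip/shaft/none call for a protein against the membrane reference.

    tip:   median ratio >= fold_threshold x reference median, test significant
    shaft: median ratio <= reference median / fold_threshold, test significant
    none:  otherwise.  Both criteria are conjunctive.  The test is a Welch
    unpaired two-tailed t-test on log2 ratios (Mann-Whitney U behind the
    ``test`` parameter).
    """
    params = params or EnrichmentParams()
    if reference.median_ratio <= 0:
        raise ParameterError("reference cohort has non-positive median ratio")
    poi_log = np.log2(poi.ratios[poi.ratios > 0])
    ref_log = np.log2(reference.ratios[reference.ratios > 0])
    if params.test == "welch":
        p = float(stats.ttest_ind(poi_log, ref_log, equal_var=False).pvalue)
    else:
        p = float(stats.mannwhitneyu(poi_log, ref_log,
                                     alternative="two-sided").pvalue)
    label = "none"
    if p < params.alpha:
        if poi.median_ratio >= params.fold_threshold * reference.median_ratio:
            label = "tip"
        elif poi.median_ratio <= reference.median_ratio / params.fold_threshold:
            label = "shaft"
    poi.classification, poi.p_value = label, p
    return label, p


def adjust_p_values(p_values: Sequence[float]) -> np.ndarray:
    """Optional Benjamini-Hochberg correction across proteins (off by default)."""
    return stats.false_discovery_control(np.asarray(p_values), method="bh")


def plot_enrichment(summaries: Sequence[EnrichmentSummary], path=None,
                    params: EnrichmentParams | None = None):
    """Tukey boxplots of per-filopodium ratios on a log axis, one per protein."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    params = params or EnrichmentParams()
    order = sorted(summaries, key=lambda s: s.median_ratio, reverse=True)
    fig, ax = plt.subplots(figsize=(max(4.0, 0.6 * len(order) + 2), 4),
                           constrained_layout=True)
    ax.boxplot([s.ratios for s in order], whis=1.5,
               tick_labels=[s.poi_name for s in order])
    ax.set_yscale("log")
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_ylabel("tip / shaft enrichment ratio")
    ax.tick_params(axis="x", rotation=60)
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
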