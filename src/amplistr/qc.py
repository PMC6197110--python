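"""Evaluation statistics: depth, heterozygote balance, stutter, noise.

These summarise typed samples the way a laboratory validation does:
per-locus read-depth distributions with box-and-whisker outliers,
heterozygote balance (Hb), stutter ratios with same-length A/B/C ranking,
the stutter-versus-repeat-number regression, and SNP noise exceedance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .calling import StutterObservation

__all__ = ["LocusDepthStats", "depth_stats", "str_hb", "stutter_summary",
           "stutter_vs_repeats", "noise_summary", "rank_same_length_stutters"]


@dataclass
class LocusDepthStats:
    locus: str
    n: int
    median: float
    mean: float
    sd: float
    cv_percent: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: list = field(default_factory=list)


def depth_stats(depths_by_locus: dict[str, list[float]]) -> dict[str, LocusDepthStats]:
    """Median, SD, CV and 1.5xIQR whiskers/outliers per locus.

    CV is the standard deviation over the *mean* in per cent.  Whiskers
    extend to the most extreme data point within 1.5 interquartile ranges
    of the box; points beyond are outliers.
    """
    out: dict[str, LocusDepthStats] = {}
    for locus, values in depths_by_locus.items():
        arr = np.asarray(values, dtype=float)
        if arr.size == 0:
            raise ValueError(f"{locus}: no depth observations")
        q1, med, q3 = np.percentile(arr, [25, 50, 75])
        iqr = q3 - q1
        lo_limit, hi_limit = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = arr[(arr >= lo_limit) & (arr <= hi_limit)]
        mean = float(arr.mean())
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        out[locus] = LocusDepthStats(
            locus=locus, n=int(arr.size), median=float(med), mean=mean, sd=sd,
            cv_percent=100.0 * sd / mean if mean else 0.0,
            q1=float(q1), q3=float(q3),
            whisker_low=float(inside.min()) if inside.size else float(med),
            whisker_high=float(inside.max()) if inside.size else float(med),
            outliers=sorted(arr[(arr < lo_limit) | (arr > hi_limit)].tolist()))
    return out


def str_hb(reads_long: int, reads_short: int) -> float:
    """STR heterozygote balance: longest-allele reads / shortest-allele reads."""
    if reads_short <= 0:
        raise ValueError("shortest-allele read count must be positive")
    return reads_long / reads_short


def rank_same_length_stutters(observations: list[StutterObservation]
                              ) -> dict[int, str]:
    """A/B/C designation within a same-length stutter group.

    Ranks by descending stutter reads: the deepest is A, then B, then C.
    Returns observation index -> rank label.
    """
    order = sorted(range(len(observations)),
                   key=lambda i: -observations[i].stutter_reads)
    return {idx: chr(ord("A") + rank) for rank, idx in enumerate(order)}


def stutter_summary(observations: list[StutterObservation]) -> pd.DataFrame:
    """Per-locus stutter ratio means and ranges (n-1 only by default use).

    Same-length groups (same locus, parent and resulting repeat length but
    different slipped block) are ranked A/B/C by read depth and summarised
    separately, mirroring how compound repeats are reported.
    """
    rows = []
    by_group: dict[tuple, list[StutterObservation]] = {}
    for obs in observations:
        key = (obs.locus, obs.parent.sequence, obs.relation)
        by_group.setdefault(key, []).append(obs)
    for key, group in by_group.items():
        ranks = rank_same_length_stutters(group)
        for i, obs in enumerate(group):
            rows.append({
                "locus": obs.locus, "relation": obs.relation,
                "slipped_block": obs.slipped_block,
                "rank": ranks[i] if len(group) > 1 else "A",
                "parent_reads": obs.parent_reads,
                "stutter_reads": obs.stutter_reads, "ratio": obs.ratio,
            })
    if not rows:
        return pd.DataFrame(columns=["locus", "rank", "n", "mean_ratio",
                                     "min_ratio", "max_ratio"])
    df = pd.DataFrame(rows)
    agg = (df.groupby(["locus", "relation", "rank"])
             .agg(n=("ratio", "size"), mean_ratio=("ratio", "mean"),
                  min_ratio=("ratio", "min"), max_ratio=("ratio", "max"))
             .reset_index())
    return agg


def stutter_vs_repeats(observations: list[StutterObservation]
                       ) -> dict | None:
    """Least-squares fit of stutter ratio on the parent's uninterrupted
    repeat count at the slipped block; None for degenerate inputs."""
    xs, ys = [], []
    for obs in observations:
        xs.append(obs.parent.counts[obs.slipped_block])
        ys.append(obs.ratio)
    if len(set(xs)) < 3:
        return None
    res = stats.linregress(xs, ys)
    return {"slope": res.slope, "intercept": res.intercept,
            "r": res.rvalue, "n": len(xs)}


def noise_summary(noise_by_locus: dict[str, list[float]],
                  threshold: float = 0.01) -> dict:
    """Per-locus median noise plus the panel-wide exceedance fraction."""
    medians = {locus: float(np.median(vals))
               for locus, vals in noise_by_locus.items() if vals}
    all_values = [v for vals in noise_by_locus.values() for v in vals]
    n_above = sum(1 for v in all_values if v > threshold)
    return {
        "medians": medians,
        "n_genotypes": len(all_values),
        "n_above_threshold": n_above,
        "fraction_above_threshold": (n_above / len(all_values)
                                     if all_values else 0.0),
        "threshold": threshold,
    }
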