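"""Germline intensity-profile quantitation along the distal-proximal axis.

Per-gonad line-profile intensities (arbitrary units vs micrometers from
the distal end) are resampled onto a common grid, averaged per genotype
with pointwise 95% confidence intervals, normalized to the wild-type
mean's maximum over the distal 100 um, and compared between genotypes by
pooled per-gonad window means with an unpaired equal-variance t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from fbekit.peak_stats import pooled_t_test

DEFAULT_GRID = np.arange(0.0, 101.0, 1.0)  # 0-100 um at 1-um steps
DEFAULT_WINDOWS = ((0.0, 10.0), (70.0, 80.0), (90.0, 100.0))


@dataclass(frozen=True)
class IntensityProfile:
    """One gonad's intensity profile: position (um) vs intensity (a.u.)."""

    gonad_id: str
    genotype: str
    positions: tuple[float, ...]
    intensities: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.intensities):
            raise ValueError(
                f"gonad {self.gonad_id!r}: positions/intensities length mismatch"
            )
        pos = np.asarray(self.positions)
        if pos.size and np.any(np.diff(pos) <= 0):
            raise ValueError(
                f"gonad {self.gonad_id!r}: positions must be strictly increasing"
            )
        if np.any(np.asarray(self.intensities) < 0):
            raise ValueError(f"gonad {self.gonad_id!r}: negative intensity")

    def resample(self, grid: np.ndarray) -> np.ndarray:
        """Linear interpolation onto ``grid``; NaN outside the profile's
        range (those positions contribute nothing to means)."""
        pos = np.asarray(self.positions, dtype=float)
        vals = np.asarray(self.intensities, dtype=float)
        out = np.interp(grid, pos, vals)
        out[(grid < pos[0]) | (grid > pos[-1])] = np.nan
        return out


@dataclass(frozen=True)
class ProfileSummary:
    """Per-genotype profile mean with pointwise 95% CI on a common grid."""

    genotype: str
    grid: np.ndarray
    mean: np.ndarray
    ci95_low: np.ndarray
    ci95_high: np.ndarray
    n_gonads: int


def mean_profile(
    profiles: Sequence[IntensityProfile],
    grid: np.ndarray | None = None,
) -> ProfileSummary:
    """Pointwise mean and 95% t-interval across gonads of one genotype.

    The CI uses the t-distribution with (n_contributing - 1) df at each
    grid point; positions outside a gonad's measured range are excluded
    for that gonad.
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 profiles per genotype")
    genotypes = {p.genotype for p in profiles}
    if len(genotypes) != 1:
        raise ValueError(f"mixed genotypes in one summary: {sorted(genotypes)}")
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)

    stack = np.vstack([p.resample(grid) for p in profiles])
    n = np.sum(~np.isnan(stack), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1)
    sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    tcrit = np.where(n > 1, stats.t.ppf(0.975, np.maximum(n - 1, 1)), np.nan)
    half = tcrit * sem
    return ProfileSummary(
        genotype=profiles[0].genotype,
        grid=grid,
        mean=mean,
        ci95_low=mean - half,
        ci95_high=mean + half,
        n_gonads=len(profiles),
    )


def wt_max(summary: ProfileSummary, distal_limit: float = 100.0) -> float:
    """Maximum of a summary's mean over the distal 0..``distal_limit`` um."""
    sel = (summary.grid >= 0) & (summary.grid <= distal_limit)
    vals = summary.mean[sel]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no mean values in the distal window")
    return float(vals.max())


def normalize_to_wt_max(
    summaries: Sequence[ProfileSummary],
    wt_label: str,
    distal_limit: float = 100.0,
) -> list[ProfileSummary]:
    """Scale every genotype's mean and CI by the wild-type mean's maximum
    over the distal 0-100 um, so the wild-type maximum becomes 1.0."""
    by_label = {s.genotype: s for s in summaries}
    if wt_label not in by_label:
        raise ValueError(f"wild-type label {wt_label!r} not among summaries")
    scale = wt_max(by_label[wt_label], distal_limit)
    if scale <= 0:
        raise ValueError("wild-type maximum is zero; cannot normalize")
    return [
        replace(
            s,
            mean=s.mean / scale,
            ci95_low=s.ci95_low / scale,
            ci95_high=s.ci95_high / scale,
        )
        for s in summaries
    ]


def window_mean(profile: IntensityProfile, window: tuple[float, float],
                grid: np.ndarray | None = None) -> float:
    """One gonad's mean intensity over a position window (grid-sampled)."""
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    lo, hi = window
    sel = (grid >= lo) & (grid <= hi)
    if not np.any(sel):
        raise ValueError(f"window {window} contains no grid points")
    vals = profile.resample(grid)[sel]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError(
            f"gonad {profile.gonad_id!r} has no data in window {window}"
        )
    return float(vals.mean())


def window_compare(
    profiles_a: Sequence[IntensityProfile],
    profiles_b: Sequence[IntensityProfile],
    window: tuple[float, float],
    *,
    scale: float = 1.0,
    grid: np.ndarray | None = None,
):
    """Compare two genotypes over a window by pooled per-gonad means.

    Each gonad contributes its mean intensity (divided by ``scale``,
    typically the wild-type maximum) within the window; groups are
    compared by an unpaired equal-variance two-sided t-test.
    """
    if len(profiles_a) < 2 or len(profiles_b) < 2:
        raise ValueError("need >= 2 gonads per group")
    a = [window_mean(p, window, grid) / scale for p in profiles_a]
    b = [window_mean(p, window, grid) / scale for p in profiles_b]
    label_a = profiles_a[0].genotype
    label_b = profiles_b[0].genotype
    return pooled_t_test(a, b, label_a, label_b)


def significance_stars(p: float) -> str:
    """Map a p-value to the conventional star annotation."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
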