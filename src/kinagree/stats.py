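"""Agreement statistics for sample-wise joint-angle comparison.

Accuracy is summarized by the 5-95% inter-percentile range (IPR) of the
sample-wise differences, banded into good (within +-10 deg), medium
(within +-15 deg) and poor (beyond); by Lin's concordance correlation
coefficient with McBride's strength-of-agreement bands; and by a modified
Bland-Altman analysis that plots the reference angle (not the two-system
average) on the x-axis, since the reference is treated as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import AngleSeries, aligned_pair
from .errors import AlignmentError, ConfigError, StatsError

IPR_GOOD = 10.0  # deg
IPR_MEDIUM = 15.0  # deg

MCBRIDE_EDGES = (0.90, 0.95, 0.99)
MCBRIDE_BANDS = ("poor", "moderate", "substantial", "almost_perfect")


@dataclass
class CCCResult:
    ccc: float
    mean_ref: float
    mean_vr: float
    sd_ref: float
    sd_vr: float
    cov: float
    mcbride_band: str
    undefined: bool = False


@dataclass
class BlandAltmanResult:
    mean: float
    loa_low: float
    loa_high: float
    n_total: int
    sample_ref: np.ndarray = field(default_factory=lambda: np.empty(0))
    sample_diff: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class RomSummary:
    q25: float
    q50: float
    q75: float
    mean: float
    sd: float
    min: float
    max: float


@dataclass
class AngleAgreement:
    """Full per-angle agreement record."""

    angle: str
    n: int
    ipr: tuple[float, float]
    median_diff: float
    accuracy_class: str
    ccc: CCCResult
    bland_altman: BlandAltmanResult
    rom_ref: RomSummary
    rom_vr: RomSummary


def angle_differences(ref_concat: AngleSeries, vr_concat: AngleSeries) -> AngleSeries:
    """Elementwise VR - reference (positive = VR overestimates)."""
    if len(ref_concat) != len(vr_concat):
        raise AlignmentError(
            f"length mismatch {len(ref_concat)} vs {len(vr_concat)}"
        )
    valid = ref_concat.valid & vr_concat.valid
    values = np.where(valid, vr_concat.values - ref_concat.values, np.nan)
    return AngleSeries(ref_concat.name, ref_concat.times.copy(), values, valid)


def ipr_and_class(differences: np.ndarray) -> tuple[tuple[float, float], str]:
    """5th/95th percentiles of differences and the accuracy class.

    Class from max(|p5|, |p95|): within 10 deg good, within 15 deg medium,
    else poor.  Percentiles use linear interpolation.
    """
    d = np.asarray(differences, dtype=float)
    d = d[np.isfinite(d)]
    if len(d) < 20:
        raise StatsError(f"need >= 20 samples for the IPR, got {len(d)}")
    p5, p95 = np.percentile(d, [5.0, 95.0])
    worst = max(abs(p5), abs(p95))
    cls = "good" if worst <= IPR_GOOD else ("medium" if worst <= IPR_MEDIUM else "poor")
    return (float(p5), float(p95)), cls


def concordance(ref: np.ndarray, vr: np.ndarray) -> CCCResult:
    """Lin's concordance correlation coefficient (population moments).

    ccc = 2*cov / ((mean_ref - mean_vr)^2 + var_ref + var_vr), with
    McBride bands: < 0.90 poor, < 0.95 moderate, < 0.99 substantial,
    >= 0.99 almost perfect.
    """
    q = np.asarray(ref, dtype=float)
    v = np.asarray(vr, dtype=float)
    m = np.isfinite(q) & np.isfinite(v)
    q, v = q[m], v[m]
    if len(q) < 2:
        raise StatsError("need >= 2 samples for the CCC")
    mq, mv = float(np.mean(q)), float(np.mean(v))
    sq2 = float(np.mean((q - mq) ** 2))
    sv2 = float(np.mean((v - mv) ** 2))
    cov = float(np.mean((q - mq) * (v - mv)))
    denom = (mq - mv) ** 2 + sq2 + sv2
    if denom < 1e-15:
        return CCCResult(np.nan, mq, mv, 0.0, 0.0, 0.0, "poor", undefined=True)
    ccc = 2.0 * cov / denom
    band = MCBRIDE_BANDS[int(np.searchsorted(MCBRIDE_EDGES, ccc, side="right"))]
    return CCCResult(float(ccc), mq, mv, float(np.sqrt(sq2)), float(np.sqrt(sv2)), cov, band)


def bland_altman(
    ref_values: np.ndarray,
    differences: np.ndarray,
    n_points: int = 2500,
    seed: int = 0,
    index_mode: str = "uniform",
) -> BlandAltmanResult:
    """Modified Bland-Altman: reference on x, VR - reference on y.

    Mean and limits of agreement (mean +- 1.96 SD) come from all samples;
    only the scatter is a random subsample of ``n_points`` unique indices
    drawn with ``seed``.  ``index_mode='uniform'`` samples indices without
    replacement; ``'gaussian'`` draws them from a normal distribution over
    index positions (kept unique), weighting the middle of the series.
    """
    x = np.asarray(ref_values, dtype=float)
    d = np.asarray(differences, dtype=float)
    if len(x) != len(d):
        raise AlignmentError("reference/difference length mismatch")
    m = np.isfinite(x) & np.isfinite(d)
    x, d = x[m], d[m]
    n = len(d)
    if n < 2:
        raise StatsError("need >= 2 samples for Bland-Altman")
    mean = float(np.mean(d))
    sd = float(np.std(d))
    k = n_points
    if k > n:
        import warnings

        warnings.warn(f"n_points {k} > {n} samples; clamped")
        k = n
    rng = np.random.default_rng(seed)
    if index_mode == "gaussian":
        chosen: set[int] = set()
        while len(chosen) < k:
            draw = rng.normal(n / 2.0, n / 4.0, size=k)
            for i in np.clip(np.round(draw), 0, n - 1).astype(int):
                if len(chosen) >= k:
                    break
                chosen.add(int(i))
        idx = np.sort(np.fromiter(chosen, dtype=int))
    else:
        idx = np.sort(rng.choice(n, size=k, replace=False))
    return BlandAltmanResult(
        mean=mean,
        loa_low=mean - 1.96 * sd,
        loa_high=mean + 1.96 * sd,
        n_total=n,
        sample_ref=x[idx],
        sample_diff=d[idx],
    )


def summarize_rom(values: np.ndarray) -> RomSummary:
    """Quartiles / mean / SD / min / max of one system's angle distribution."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        raise StatsError("empty distribution")
    q25, q50, q75 = np.percentile(v, [25.0, 50.0, 75.0])
    return RomSummary(
        q25=float(q25),
        q50=float(q50),
        q75=float(q75),
        mean=float(np.mean(v)),
        sd=float(np.std(v)),
        min=float(np.min(v)),
        max=float(np.max(v)),
    )


def ergonomic_band(angle_value: float, scheme_thresholds: tuple[float, ...]) -> int:
    """Half-open threshold banding used by observational risk schemes.

    With thresholds (10, 20): values <= 10 are band 0, (10, 20] band 1,
    > 20 band 2.
    """
    thr = tuple(scheme_thresholds)
    if any(b <= a for a, b in zip(thr, thr[1:])):
        raise ConfigError("thresholds must be strictly increasing")
    band = 0
    for t in thr:
        if angle_value > t:
            band += 1
    return band


def agreement_for_angle(
    ref_concat: AngleSeries,
    vr_concat: AngleSeries,
    n_points: int = 2500,
    seed: int = 0,
) -> AngleAgreement:
    """Full agreement record from aligned concatenated linked segments."""
    _, ref, vr = aligned_pair(ref_concat, vr_concat)
    diffs = vr - ref
    ipr, cls = ipr_and_class(diffs)
    return AngleAgreement(
        angle=ref_concat.name,
        n=len(ref),
        ipr=ipr,
        median_diff=float(np.median(diffs)),
        accuracy_class=cls,
        ccc=concordance(ref, vr),
        bland_altman=bland_altman(ref, diffs, n_points=n_points, seed=seed),
        rom_ref=summarize_rom(ref),
        rom_vr=summarize_rom(vr),
    )
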