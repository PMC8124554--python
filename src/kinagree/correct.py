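"""Angle-dependent polynomial correction of systematic over/underestimation.

The two systems solve inverse kinematics differently, which leaves smooth,
angle-dependent over- and underestimation in the VR stream even after
offset correction.  A polynomial regression of the sample-wise difference
(VR - reference) against the VR angle value is fitted on the pooled linked
segments of all subjects and then subtracted per subject.

The fit uses a Chebyshev basis on the rescaled fit domain for numerical
stability at the default degree of 12; outside the fit domain the
correction is clamped to the endpoint values, since extrapolating a
high-degree polynomial is explosive.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import chebyshev

from .core import AngleSeries, aligned_pair
from .errors import FitError, UsageError

DEFAULT_DEGREE = 12


@dataclass
class CorrectionFunction:
    """Fitted correction for one angle: predicts (VR - reference) from VR."""

    angle: str
    degree: int
    domain: tuple[float, float]
    coefficients: list[float]  # Chebyshev coefficients on `domain`
    n_samples: int
    monomial_coefficients: list[float] = field(default_factory=list)
    fit_hash: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coefficients)):
            raise FitError("non-finite correction coefficients")
        if not self.monomial_coefficients:
            cheb = chebyshev.Chebyshev(self.coefficients, domain=self.domain)
            self.monomial_coefficients = [
                float(c) for c in cheb.convert(kind=np.polynomial.Polynomial).coef
            ]
        if not self.fit_hash:
            payload = json.dumps(
                [self.angle, self.degree, list(self.domain), self.coefficients],
                sort_keys=True,
            )
            self.fit_hash = hashlib.sha256(payload.encode()).hexdigest()[:16]

    def __call__(self, values: np.ndarray) -> np.ndarray:
        x = np.clip(np.asarray(values, dtype=float), *self.domain)
        cheb = chebyshev.Chebyshev(np.asarray(self.coefficients), domain=self.domain)
        return cheb(x)

    def to_json(self) -> dict:
        return {
            "angle": self.angle,
            "degree": self.degree,
            "basis": "chebyshev",
            "domain": list(self.domain),
            "coefficients": list(self.coefficients),
            "monomial_coefficients": self.monomial_coefficients,
            "n_samples": self.n_samples,
            "fit_hash": self.fit_hash,
        }

    @classmethod
    def from_json(cls, d: dict) -> "CorrectionFunction":
        return cls(
            angle=d["angle"],
            degree=d["degree"],
            domain=tuple(d["domain"]),
            coefficients=list(d["coefficients"]),
            n_samples=d["n_samples"],
            monomial_coefficients=list(d.get("monomial_coefficients", [])),
            fit_hash=d.get("fit_hash", ""),
        )


def fit_correction(
    vr_concat: AngleSeries,
    ref_concat: AngleSeries,
    degree: int = DEFAULT_DEGREE,
) -> CorrectionFunction:
    """Least-squares polynomial of ``degree`` for (VR value, VR - reference).

    Requires at least ``10 * (degree + 1)`` aligned valid samples.  On rank
    deficiency the degree is reduced with a warning.
    """
    _, ref, vr = aligned_pair(ref_concat, vr_concat)
    need = 10 * (degree + 1)
    if len(ref) < need:
        raise FitError(
            f"{vr_concat.name}: {len(ref)} samples < {need} required for degree {degree}"
        )
    diff = vr - ref
    lo, hi = float(np.min(vr)), float(np.max(vr))
    if hi - lo < 1e-9:
        lo, hi = lo - 0.5, hi + 0.5
    deg = degree
    # distinct support must exceed the number of coefficients
    n_distinct = len(np.unique(np.round(vr, 6)))
    if n_distinct <= deg:
        import warnings

        deg = max(1, n_distinct - 1)
        warnings.warn(
            f"{vr_concat.name}: rank-deficient fit, degree reduced to {deg}"
        )
    cheb = chebyshev.Chebyshev.fit(vr, diff, deg, domain=[lo, hi])
    return CorrectionFunction(
        angle=vr_concat.name,
        degree=deg,
        domain=(lo, hi),
        coefficients=[float(c) for c in cheb.coef],
        n_samples=int(len(ref)),
    )


def apply_correction(series: AngleSeries, fn: CorrectionFunction) -> AngleSeries:
    """Subtract the predicted systematic difference from a VR angle series."""
    if fn.angle != series.name:
        raise UsageError(
            f"correction fitted for {fn.angle!r} applied to {series.name!r}"
        )
    values = series.values.copy()
    values[series.valid] = values[series.valid] - fn(values[series.valid])
    return AngleSeries(series.name, series.times.copy(), values, series.valid.copy())


def select_degree(
    vr_concat: AngleSeries,
    ref_concat: AngleSeries,
    candidates: list[int] | None = None,
    folds: int = 5,
    mode: str = "cv",
    tie_tol: float = 1e-3,
) -> int:
    """Polynomial degree minimizing cross-validated RMS of corrected differences.

    ``mode='train'`` ranks on training error instead.  Ties break toward the
    lowest degree: a higher degree must improve the RMS by more than the
    relative ``tie_tol`` to be preferred, so chance cross-validation
    fluctuations on structureless differences do not inflate the degree.
    """
    if not candidates:
        raise UsageError("no candidate degrees")
    if folds < 2:
        raise UsageError("need at least 2 folds")
    _, ref, vr = aligned_pair(ref_concat, vr_concat)
    diff = vr - ref
    n = len(ref)
    lo, hi = float(np.min(vr)), float(np.max(vr))
    # interleaved folds keep every fold's support spread over the domain
    fold_of = np.arange(n) % folds
    best_deg, best_rms = None, np.inf
    for deg in sorted(candidates):
        errs = []
        if mode == "train":
            cheb = chebyshev.Chebyshev.fit(vr, diff, deg, domain=[lo, hi])
            errs.append(np.sqrt(np.mean((diff - cheb(vr)) ** 2)))
        else:
            for k in range(folds):
                tr = fold_of != k
                te = ~tr
                if tr.sum() <= deg + 1 or te.sum() == 0:
                    continue
                cheb = chebyshev.Chebyshev.fit(vr[tr], diff[tr], deg, domain=[lo, hi])
                pred = cheb(np.clip(vr[te], lo, hi))
                errs.append(np.sqrt(np.mean((diff[te] - pred) ** 2)))
        if not errs:
            continue
        rms = float(np.mean(errs))
        if rms < best_rms * (1.0 - tie_tol):
            best_deg, best_rms = deg, rms
    if best_deg is None:
        raise FitError("no degree could be evaluated")
    return best_deg
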