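"""Marker-retention profiles and linear vs exponential tract models.

The central statistic of the package: for each vector marker, the fraction
of analyzed clones that retained the viral allele, plotted against the
marker's distance from the selection cassette.  Under uniformly
distributed crossover resolution the expected profile is linear
(``1 - d/L`` for ends-out targeting); exponentially decaying profiles are
the signature of tract-length-controlled mechanisms reported in other
systems, so both models can be fitted and compared by residual sum of
squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .markers import Arm, CloneTable

__all__ = [
    "RetentionProfile",
    "FitResult",
    "ModelComparison",
    "retention_profile",
    "fit_retention_model",
    "compare_models",
]

Model = Literal["LINEAR", "EXPONENTIAL"]


@dataclass(frozen=True)
class MarkerRetention:
    marker_id: str
    signed_distance: int
    n_retained: int
    n_total: int

    @property
    def freq(self) -> float:
        return self.n_retained / self.n_total if self.n_total else float("nan")


@dataclass
class RetentionProfile:
    """Per-marker retention counts and frequencies vs signed distance."""

    rows: list[MarkerRetention]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": [r.marker_id for r in self.rows],
                "signed_distance": [r.signed_distance for r in self.rows],
                "n_retained": [r.n_retained for r in self.rows],
                "n_total": [r.n_total for r in self.rows],
                "freq": [r.freq for r in self.rows],
            }
        )

    def arm_points(self, arm: Arm) -> tuple[np.ndarray, np.ndarray]:
        """Unsigned distances and frequencies of usable markers on one arm."""
        want_neg = arm == "LEFT"
        pts = [
            (abs(r.signed_distance), r.freq)
            for r in self.rows
            if r.n_total > 0 and (r.signed_distance < 0) == want_neg
        ]
        pts.sort()
        if not pts:
            return np.array([]), np.array([])
        d, f = zip(*pts)
        return np.asarray(d, dtype=float), np.asarray(f, dtype=float)


@dataclass(frozen=True)
class FitResult:
    """Parameters and goodness of fit of a retention model on one arm."""

    model: Model
    params: dict[str, float]
    r_squared: float
    rss: float
    n_points: int


@dataclass(frozen=True)
class ModelComparison:
    preferred: Model
    delta_rss: float  # rss(EXPONENTIAL) - rss(LINEAR); positive favours LINEAR
    fits: dict[str, FitResult]


def retention_profile(
    table: CloneTable, count_sectored_as_retained: bool = True
) -> RetentionProfile:
    """Per-marker viral-allele retention across the clones of a table.

    A sectored colony demonstrably carries the viral allele at the marker,
    so S calls count as retained by default; no-calls shrink the
    denominator for that marker only.
    """
    if not table.clones:
        raise ValueError("retention_profile requires a non-empty clone table")
    retained_calls = {"V", "S"} if count_sectored_as_retained else {"V"}
    rows = []
    for marker in table.map.genotyped_markers:
        n_ret = 0
        n_tot = 0
        for clone in table.clones:
            try:
                call = clone.calls[marker.id]
            except KeyError:
                raise ValueError(
                    f"clone {clone.clone_id!r} has no call for marker {marker.id!r}"
                ) from None
            if call == "N":
                continue
            n_tot += 1
            if call in retained_calls:
                n_ret += 1
        rows.append(
            MarkerRetention(
                marker_id=marker.id,
                signed_distance=marker.signed_distance,
                n_retained=n_ret,
                n_total=n_tot,
            )
        )
    return RetentionProfile(rows=rows)


def _r_squared(f: np.ndarray, fitted: np.ndarray) -> tuple[float, float]:
    rss = float(np.sum((f - fitted) ** 2))
    tss = float(np.sum((f - f.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss == 0 else 0.0)
    return r2, rss


def fit_retention_model(
    profile: RetentionProfile,
    arm: Arm,
    model: Model = "LINEAR",
    weighted: bool = False,
) -> FitResult:
    """Fit retention frequency vs unsigned marker distance on one arm.

    LINEAR is ordinary least squares with intercept.  EXPONENTIAL fits
    ``A * exp(-k d)`` by nonlinear least squares, initialized from a
    log-linear fit on the positive-frequency points; its R-squared is
    computed about the mean, exactly as for the linear model, so the two
    are comparable.  ``weighted`` applies inverse binomial-variance
    weights (frequencies clipped away from 0/1 for stability).
    """
    d, f = profile.arm_points(arm)
    if len(d) < 3:
        raise ValueError(
            f"need at least 3 usable markers on the {arm} arm, got {len(d)}"
        )
    if weighted:
        n_tot = np.array(
            [
                r.n_total
                for r in sorted(
                    (
                        r
                        for r in profile.rows
                        if r.n_total > 0
                        and (r.signed_distance < 0) == (arm == "LEFT")
                    ),
                    key=lambda r: abs(r.signed_distance),
                )
            ],
            dtype=float,
        )
        p = np.clip(f, 1.0 / (n_tot + 2), 1.0 - 1.0 / (n_tot + 2))
        w = n_tot / (p * (1 - p))
    else:
        w = np.ones_like(f)

    if model == "LINEAR":
        W = np.diag(w)
        X = np.column_stack([d, np.ones_like(d)])
        beta, *_ = np.linalg.lstsq(np.sqrt(W) @ X, np.sqrt(w) * f, rcond=None)
        slope, intercept = float(beta[0]), float(beta[1])
        r2, rss = _r_squared(f, slope * d + intercept)
        return FitResult(
            model="LINEAR",
            params={"slope": slope, "intercept": intercept},
            r_squared=r2,
            rss=rss,
            n_points=len(d),
        )
    if model == "EXPONENTIAL":
        pos = f > 0
        if not pos.any():
            raise ValueError("exponential fit impossible: all frequencies are zero")
        if pos.sum() >= 2:
            k0_slope, loga, *_ = stats.linregress(d[pos], np.log(f[pos]))[:2]
            a0, k0 = float(np.exp(loga)), float(max(-k0_slope, 1e-12))
        else:
            a0, k0 = float(f.max()), 1.0 / float(d.max())

        def expmodel(x, a, k):
            return a * np.exp(-k * x)

        try:
            popt, _ = optimize.curve_fit(
                expmodel,
                d,
                f,
                p0=(a0, k0),
                sigma=1.0 / np.sqrt(w),
                absolute_sigma=False,
                maxfev=10000,
            )
        except RuntimeError:
            popt = (a0, k0)
        a, k = float(popt[0]), float(popt[1])
        r2, rss = _r_squared(f, expmodel(d, a, k))
        return FitResult(
            model="EXPONENTIAL",
            params={"amplitude": a, "decay_rate": k},
            r_squared=r2,
            rss=rss,
            n_points=len(d),
        )
    raise ValueError(f"unknown model {model!r}")


def compare_models(profile: RetentionProfile, arm: Arm) -> ModelComparison:
    """Fit both retention models on one arm and prefer the lower RSS.

    Ties break to LINEAR (the simpler model: a uniform crossover
    distribution needs no tract-length parameter).
    """
    linear = fit_retention_model(profile, arm, "LINEAR")
    expo = fit_retention_model(profile, arm, "EXPONENTIAL")
    delta = expo.rss - linear.rss
    preferred: Model = "LINEAR" if linear.rss <= expo.rss else "EXPONENTIAL"
    return ModelComparison(
        preferred=preferred,
        delta_rss=delta,
        fits={"LINEAR": linear, "EXPONENTIAL": expo},
    )
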