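"""Initial-velocity estimation for defined-overhang ligation timecourses.

Each timecourse records fraction of substrate converted to product versus
time for one defined cohesive-end substrate and replicate.  The initial
velocity is the ordinary-least-squares slope over the early linear regime:
points are retained up to a conversion cap (default 25% product); the
first point exceeding the cap and all later points are excluded.  Replicate
fits are averaged arithmetically; because the reported per-fit error is the
standard error of the slope, replicate errors are combined in quadrature
(sqrt(sum se_i^2)/n, the standard error of the mean of independent
estimates), and the plain standard deviation of the replicate slopes is
reported alongside so either reading of "error" is recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class Timecourse:
    """Product-fraction timecourse for one substrate and replicate.

    times are minutes (strictly increasing), fractions in [0, 1];
    ``substrate_conc`` in nM converts fractional velocity to nM/min.
    """

    times: np.ndarray
    fraction_product: np.ndarray
    substrate_conc: float | None = None
    replicate: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.fraction_product = np.asarray(self.fraction_product, dtype=float)
        if self.times.shape != self.fraction_product.shape or self.times.ndim != 1:
            raise ValueError("times and fraction_product must be matching 1-D arrays")
        if len(self.times) < 2:
            raise ValueError("a timecourse needs at least 2 timepoints")
        if not (np.diff(self.times) > 0).all():
            raise ValueError("times must be strictly increasing")
        if ((self.fraction_product < 0) | (self.fraction_product > 1)).any():
            raise ValueError("fraction_product values must lie in [0, 1]")


@dataclass
class VelocityFit:
    slope: float  # fraction/min
    stderr: float
    n_points_used: int
    points_used: tuple[int, ...]
    slope_nM_per_min: float | None = None
    replicate: str = ""


def initial_velocity(tc: Timecourse, cap: float = 0.25) -> VelocityFit:
    """OLS slope of the linear portion of a timecourse.

    Retains the leading points with conversion <= ``cap``; the first point
    above the cap and everything after it are excluded, so added late
    points never change the fit.  Raises if fewer than 2 points remain.
    """
    above = np.flatnonzero(tc.fraction_product > cap)
    cut = above[0] if len(above) else len(tc.times)
    if cut < 2:
        raise ValueError(
            f"need >=2 points at or below the {cap:.0%} conversion cap, have {cut}"
        )
    x = tc.times[:cut]
    y = tc.fraction_product[:cut]
    fit = stats.linregress(x, y)
    stderr = float(fit.stderr)
    # a 2-point or exactly collinear fit has zero residual: stderr is 0
    residual = y - (fit.intercept + fit.slope * x)
    if not np.isfinite(stderr) or np.allclose(residual, 0, atol=1e-12):
        stderr = 0.0
    return VelocityFit(
        slope=float(fit.slope),
        stderr=stderr,
        n_points_used=int(cut),
        points_used=tuple(range(cut)),
        slope_nM_per_min=(
            float(fit.slope) * tc.substrate_conc if tc.substrate_conc else None
        ),
        replicate=tc.replicate,
    )


@dataclass
class ReplicateSummary:
    mean_slope: float
    reported_error: float  # quadrature-combined fit standard errors
    replicate_sd: float  # plain SD of the replicate slopes
    n_replicates: int
    fits: list = field(default_factory=list)


def average_replicates(fits: list[VelocityFit]) -> ReplicateSummary:
    """Arithmetic mean of replicate slopes with propagated fit error."""
    if not fits:
        raise ValueError("need at least one fit")
    slopes = np.array([f.slope for f in fits])
    errors = np.array([f.stderr for f in fits])
    return ReplicateSummary(
        mean_slope=float(slopes.mean()),
        reported_error=float(np.sqrt((errors**2).sum()) / len(fits)),
        replicate_sd=float(slopes.std(ddof=1)) if len(fits) > 1 else 0.0,
        n_replicates=len(fits),
        fits=list(fits),
    )


def fold_ratio(summary_a: ReplicateSummary, summary_b: ReplicateSummary) -> float:
    """Unit-free velocity ratio A/B between two substrates or conditions."""
    if summary_b.mean_slope == 0:
        raise ZeroDivisionError("denominator velocity is zero")
    return summary_a.mean_slope / summary_b.mean_slope


def read_timecourses_csv(path) -> dict[str, list[Timecourse]]:
    """Read timecourses from a CSV with columns
    substrate, replicate, time_min, fraction_product (optional substrate_conc_nM)."""
    frame = pd.read_csv(path)
    required = {"substrate", "replicate", "time_min", "fraction_product"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out: dict[str, list[Timecourse]] = {}
    for (substrate, replicate), group in frame.groupby(["substrate", "replicate"]):
        group = group.sort_values("time_min")
        conc = None
        if "substrate_conc_nM" in group.columns:
            conc = float(group["substrate_conc_nM"].iloc[0])
        out.setdefault(str(substrate), []).append(
            Timecourse(
                times=group["time_min"].to_numpy(),
                fraction_product=group["fraction_product"].to_numpy(),
                substrate_conc=conc,
                replicate=str(replicate),
            )
        )
    return out


def velocity_table(timecourses: dict[str, list[Timecourse]], cap: float = 0.25) -> pd.DataFrame:
    """Per-substrate velocity summary (and fold ratios vs the fastest)."""
    rows = []
    for substrate, courses in timecourses.items():
        summary = average_replicates([initial_velocity(tc, cap) for tc in courses])
        rows.append(
            {
                "substrate": substrate,
                "mean_slope_per_min": summary.mean_slope,
                "reported_error": summary.reported_error,
                "replicate_sd": summary.replicate_sd,
                "n_replicates": summary.n_replicates,
            }
        )
    table = pd.DataFrame(rows)
    fastest = table["mean_slope_per_min"].max()
    table["fold_vs_fastest"] = table["mean_slope_per_min"] / fastest
    return table
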