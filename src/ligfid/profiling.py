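"""Bias, fidelity and mismatch statistics of a pair-count matrix.

All statistics are defined over ordered counts of the dual-orientation
256 x 256 matrix (or, for closed-form oracles, over an expected probability
matrix — every function accepts either a :class:`~ligfid.extract.PairCountMatrix`
or a raw symmetric nonnegative array):

* normalised ligation frequency — the relative representation of each
  overhang across all ligation products, scaled so uniform usage is 1.0
  (the profile sums to 256);
* fidelity — the fraction of ligation events joining an overhang to its
  Watson-Crick partner, overall and per overhang;
* GC stratification — per-GC-bin (0/25/50/75/100%) means and medians, with
  bin populations 16/64/96/64/16;
* mismatch spectra — frequency of each mismatched base-pair label by
  junction position class (edge N1:N4 vs middle N2:N3), and the
  distribution of mismatch counts per product;
* pattern-group summaries (e.g. the TNNA / CNNG families), Pearson
  cross-sample correlation, the control-hexamer synthesis-bias correction,
  and the Bioanalyzer yield formula.

Every statistic is invariant under a positive rescaling of the counts and
under relabelling top <-> bottom.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import overhangs as oh
from .extract import PairCountMatrix
from .overhangs import (
    ALPHABET,
    EDGE_MISMATCH_MASK,
    GC_COUNTS,
    MISMATCH_MASKS,
    N_MISMATCHES,
    OVERHANGS,
    RC_INDEX,
    WC_MASK,
    position_class,
)

GC_BINS = (0, 25, 50, 75, 100)
#: Number of overhangs per GC bin: C(4,k) * 2^k * ... enumerated exactly.
GC_BIN_POPULATIONS = {0: 16, 25: 64, 50: 96, 75: 64, 100: 16}


def _as_array(M) -> np.ndarray:
    if isinstance(M, PairCountMatrix):
        arr = M.counts
    else:
        arr = np.asarray(M, dtype=float)
    if arr.shape != (256, 256):
        raise ValueError(f"expected a 256x256 matrix, got shape {arr.shape}")
    if (arr < 0).any():
        raise ValueError("matrix entries must be nonnegative")
    return arr.astype(float)


def _total(arr: np.ndarray) -> float:
    total = arr.sum()
    if total <= 0:
        raise ValueError("matrix has zero total count")
    return total


def normalized_frequency(M) -> pd.Series:
    """Per-overhang normalised ligation frequency (uniform usage -> 1.0).

    freq(o) = 256 * (ordered counts with top overhang o) / total ordered
    counts; the 256 values sum to 256, i.e. average 1.
    """
    arr = _as_array(M)
    freq = arr.sum(axis=1) / _total(arr) * 256
    return pd.Series(freq, index=list(OVERHANGS), name="normalized_frequency")


def overall_fidelity(M) -> float:
    """Fraction of ligation events that are Watson-Crick correct."""
    arr = _as_array(M)
    return float(arr[WC_MASK].sum() / _total(arr))


def per_overhang_fidelity(M) -> pd.Series:
    """Fraction of each overhang's events joined to its Watson-Crick partner.

    Overhangs with zero events are reported as NaN (undefined), never 0.
    A palindromic overhang's correct partner is itself (the diagonal cell).
    """
    arr = _as_array(M)
    _total(arr)
    row = arr.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fid = arr[np.arange(256), RC_INDEX] / row
    fid[row == 0] = np.nan
    return pd.Series(fid, index=list(OVERHANGS), name="fidelity")


def events_per_overhang(M) -> pd.Series:
    arr = _as_array(M)
    return pd.Series(arr.sum(axis=1), index=list(OVERHANGS), name="n_events")


def gc_binned_summary(values: pd.Series) -> pd.DataFrame:
    """Mean/median/n of a per-overhang statistic grouped by GC content.

    Bins are 0/25/50/75/100% GC with populations 16/64/96/64/16; NaN
    (undefined) values are excluded from the means rather than treated as 0.
    """
    if len(values) == 0:
        raise ValueError("empty value map")
    gc = pd.Series(
        [oh.gc_percent(o) for o in values.index], index=values.index, name="gc_percent"
    )
    rows = []
    for bin_pct in GC_BINS:
        members = values[gc == bin_pct].dropna()
        rows.append(
            {
                "gc_percent": bin_pct,
                "mean": members.mean() if len(members) else np.nan,
                "median": members.median() if len(members) else np.nan,
                "n": int(len(members)),
            }
        )
    return pd.DataFrame(rows).set_index("gc_percent")


def gc_bin_tests(values: pd.Series) -> pd.DataFrame:
    """Two-sided Mann-Whitney rank tests between adjacent GC bins."""
    gc = np.array([oh.gc_percent(o) for o in values.index])
    rows = []
    for lo, hi in zip(GC_BINS[:-1], GC_BINS[1:]):
        a = values[gc == lo].dropna()
        b = values[gc == hi].dropna()
        if len(a) and len(b):
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        else:
            stat, p = np.nan, np.nan
        rows.append({"bin_a": lo, "bin_b": hi, "U": stat, "p_value": p})
    return pd.DataFrame(rows)


def mismatch_spectrum(M) -> pd.DataFrame:
    """Frequency of each mismatched base-pair label by position class.

    Mismatches of every ordered pair are enumerated with count weights;
    labels are oriented 'top:bottom' (both T:G and G:T arise because each
    product is counted in both orientations).  Edge aggregates positions 1
    and 4; middle aggregates 2 and 3.  Frequencies are normalised within
    each position class.
    """
    arr = _as_array(M)
    _total(arr)
    records = []
    for pos in range(1, oh.OVERHANG_LENGTH + 1):
        cls = position_class(pos)
        mask = MISMATCH_MASKS[pos - 1]
        top_code = oh.CODES[:, pos - 1].astype(int)
        opp_code = oh.CODES[:, oh.OVERHANG_LENGTH - pos].astype(int)
        combo = top_code[:, None] * 4 + opp_code[None, :]
        weights = np.zeros(16)
        np.add.at(weights, combo[mask], arr[mask])
        for t in range(4):
            for b in range(4):
                if weights[t * 4 + b] > 0:
                    records.append(
                        {
                            "label": f"{ALPHABET[t]}:{ALPHABET[b]}",
                            "position_class": cls,
                            "count": weights[t * 4 + b],
                        }
                    )
    if not records:
        return pd.DataFrame(columns=["label", "position_class", "count", "frequency"])
    frame = (
        pd.DataFrame(records)
        .groupby(["label", "position_class"], as_index=False)["count"]
        .sum()
    )
    frame["frequency"] = frame["count"] / frame.groupby("position_class")[
        "count"
    ].transform("sum")
    return frame.sort_values(["position_class", "label"]).reset_index(drop=True)


def mismatch_count_distribution(M) -> dict[int, float]:
    """Fraction of products carrying 0..4 junction mismatches.

    Computed over ordered events, which equals the per-product distribution
    under the dual-orientation counting convention.  Sums to 1; the
    0-mismatch fraction equals the overall fidelity.
    """
    arr = _as_array(M)
    total = _total(arr)
    return {
        k: float(arr[N_MISMATCHES == k].sum() / total)
        for k in range(oh.OVERHANG_LENGTH + 1)
    }


def double_mismatch_edge_fraction(M) -> float:
    """Among products with exactly two mismatches, the fraction with at
    least one mismatch in the edge position; NaN if no such product exists."""
    arr = _as_array(M)
    double = N_MISMATCHES == 2
    denom = arr[double].sum()
    if denom == 0:
        return float("nan")
    return float(arr[double & EDGE_MISMATCH_MASK].sum() / denom)


def pattern_group_summary(freqs: pd.Series, patterns: list[str]) -> pd.DataFrame:
    """Mean normalised frequency over each N-wildcard overhang family.

    e.g. TNNA covers 16 overhangs; values well below 1.0 flag a family the
    ligase joins inefficiently.
    """
    rows = []
    for pattern in patterns:
        members = [o for o in freqs.index if oh.matches_pattern(o, pattern)]
        if not members:
            raise ValueError(f"pattern {pattern!r} matches no overhang in the profile")
        sub = freqs[members].dropna()
        rows.append({"pattern": pattern, "mean": sub.mean(), "n": len(members)})
    return pd.DataFrame(rows).set_index("pattern")


def pearson_correlation(freq_a: pd.Series, freq_b: pd.Series) -> float:
    """Product-moment correlation between two per-overhang profiles.

    NaN (undefined) when either profile has zero variance.
    """
    a, b = freq_a.align(freq_b, join="inner")
    if len(a) != 256:
        raise ValueError("profiles must cover the same 256 overhangs")
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(stats.pearsonr(a, b)[0])


def synthesis_bias_correction(
    freqs: pd.Series, control_tallies: np.ndarray | None
) -> pd.Series:
    """Correct a frequency profile for oligo-synthesis composition bias.

    Per-position base frequencies are estimated from the randomised control
    hexamers (positions independent); the expected relative abundance of an
    overhang under synthesis bias alone is the product of the four per-base
    frequencies (overhang positions 1-4 map to control positions 1-4,
    relative to the uniform 1/4 baseline).  Corrected frequency = observed /
    expected, renormalised to mean 1.  If tallies are missing or any
    position has no observations the correction is skipped with a warning
    and the input returned unchanged.
    """
    if control_tallies is None:
        warnings.warn("no control-hexamer tallies available; correction skipped")
        return freqs
    tallies = np.asarray(control_tallies, dtype=float)
    if tallies.ndim != 2 or tallies.shape[1] != 4 or tallies.shape[0] < 4:
        raise ValueError(f"control tallies must be (>=4, 4), got {tallies.shape}")
    position_totals = tallies.sum(axis=1)
    if (position_totals[:4] == 0).any():
        warnings.warn("a control position has zero observations; correction skipped")
        return freqs
    base_freqs = tallies[:4] / position_totals[:4, None]
    expected = np.ones(256)
    for pos in range(4):
        expected *= base_freqs[pos, oh.CODES[:, pos].astype(int)] / 0.25
    corrected = freqs.to_numpy() / expected
    corrected = corrected / np.nanmean(corrected)
    return pd.Series(corrected, index=freqs.index, name="corrected_frequency")


def yield_percent(product_conc: float, substrate_conc: float) -> float:
    """Ligation yield: 100 * [product] / ([substrate] + [product])."""
    if product_conc < 0 or substrate_conc < 0:
        raise ValueError("concentrations must be nonnegative")
    if product_conc == 0 and substrate_conc == 0:
        raise ValueError("substrate and product cannot both be zero")
    return 100.0 * product_conc / (substrate_conc + product_conc)


# ---------------------------------------------------------------------------
# Report assembly and serialisation.

@dataclass
class ProfileReport:
    """All reported statistics of one sample, with CSV/JSON writers."""

    per_overhang: pd.DataFrame
    overall_fidelity: float
    gc_frequency_summary: pd.DataFrame
    gc_fidelity_summary: pd.DataFrame
    spectrum: pd.DataFrame
    mismatch_count_distribution: dict[int, float]
    double_mismatch_edge_fraction: float
    pattern_groups: pd.DataFrame
    metadata: dict = field(default_factory=dict)
    correlations: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_matrix(
        cls,
        M: PairCountMatrix,
        correction: bool = False,
        patterns: tuple[str, ...] = ("TNNA", "CNNG"),
    ) -> "ProfileReport":
        freqs = normalized_frequency(M)
        if correction:
            tallies = M.control_tallies if isinstance(M, PairCountMatrix) else None
            freqs = synthesis_bias_correction(freqs, tallies).rename(
                "normalized_frequency"
            )
        fid = per_overhang_fidelity(M)
        table = pd.DataFrame(
            {
                "overhang": list(OVERHANGS),
                "gc_percent": [oh.gc_percent(o) for o in OVERHANGS],
                "normalized_frequency": freqs.to_numpy(),
                "fidelity": fid.to_numpy(),
                "n_events": events_per_overhang(M).to_numpy(),
            }
        )
        return cls(
            per_overhang=table,
            overall_fidelity=overall_fidelity(M),
            gc_frequency_summary=gc_binned_summary(freqs),
            gc_fidelity_summary=gc_binned_summary(fid),
            spectrum=mismatch_spectrum(M),
            mismatch_count_distribution=mismatch_count_distribution(M),
            double_mismatch_edge_fraction=double_mismatch_edge_fraction(M),
            pattern_groups=pattern_group_summary(freqs, list(patterns)),
            metadata=dict(M.metadata) if isinstance(M, PairCountMatrix) else {},
        )

    def summary_dict(self) -> dict:
        return {
            "metadata": self.metadata,
            "overall_fidelity": self.overall_fidelity,
            "mismatch_count_distribution": {
                str(k): v for k, v in self.mismatch_count_distribution.items()
            },
            "double_mismatch_edge_fraction": self.double_mismatch_edge_fraction,
            "gc_frequency_summary": self.gc_frequency_summary.reset_index().to_dict(
                orient="records"
            ),
            "gc_fidelity_summary": self.gc_fidelity_summary.reset_index().to_dict(
                orient="records"
            ),
            "pattern_groups": self.pattern_groups.reset_index().to_dict(
                orient="records"
            ),
            "correlations": self.correlations,
        }

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.per_overhang.to_csv(out / "per_overhang.csv", index=False)
        self.spectrum.to_csv(out / "mismatch_spectrum.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2, default=float)


def compare_profiles(report_a: ProfileReport, report_b: ProfileReport) -> dict:
    """Condition-difference report (e.g. standard buffer vs +PEG).

    Reports the overall-fidelity delta, paired per-overhang frequency and
    fidelity deltas, and per-GC-bin median shifts, all as B minus A.
    """
    a, b = report_a.per_overhang, report_b.per_overhang
    if list(a["overhang"]) != list(b["overhang"]):
        raise ValueError("profiles cover different overhang sets")
    deltas = pd.DataFrame(
        {
            "overhang": a["overhang"],
            "gc_percent": a["gc_percent"],
            "delta_frequency": b["normalized_frequency"] - a["normalized_frequency"],
            "delta_fidelity": b["fidelity"] - a["fidelity"],
        }
    )
    bin_shift = (
        report_b.gc_fidelity_summary["median"] - report_a.gc_fidelity_summary["median"]
    )
    return {
        "overall_fidelity_delta": report_b.overall_fidelity - report_a.overall_fidelity,
        "per_overhang_deltas": deltas,
        "gc_bin_median_fidelity_shift": bin_shift,
        "frequency_correlation": pearson_correlation(
            a.set_index("overhang")["normalized_frequency"],
            b.set_index("overhang")["normalized_frequency"],
        ),
    }


def plot_frequency_by_gc(report: ProfileReport, path) -> None:
    """Scatter of normalised frequency per overhang, coloured by GC bin."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = report.per_overhang.sort_values("normalized_frequency", ascending=False)
    colors = {0: "#8b0000", 25: "#f08080", 50: "#808080", 75: "#add8e6", 100: "#00008b"}
    fig, ax = plt.subplots(figsize=(10, 3))
    ax.bar(
        range(len(table)),
        table["normalized_frequency"],
        color=[colors[g] for g in table["gc_percent"]],
        width=1.0,
    )
    ax.axhline(1.0, color="black", lw=0.5, ls="--")
    ax.set_xlabel("overhang (ranked)")
    ax.set_ylabel("normalized ligation frequency")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
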