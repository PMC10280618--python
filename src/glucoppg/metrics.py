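"""Regression accuracy metrics and Clarke error grid analysis.

The accuracy of a glucose estimator is summarised by the Pearson
correlation R, the mean absolute error (with the SD of the absolute
errors), the root-mean-square error and the mean absolute relative
deviation (MARD), all in mmol/L except the dimensionless R and MARD.

Clinical acceptability is assessed with the Clarke error grid: each
(reference, estimate) pair, converted to mg/dL, falls in one of five
zones -- A (clinically accurate) through E (erroneous, potentially
dangerous).  The zone inequalities follow the original 1987 formulation;
boundary points are assigned to the better (earlier-letter) zone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MMOL_TO_MGDL",
    "MetricReport",
    "ClarkeReport",
    "regression_metrics",
    "clarke_zone",
    "clarke_percentages",
    "plot_clarke",
]

#: mmol/L -> mg/dL conversion (glucose molar mass 180.18 g/mol).
MMOL_TO_MGDL = 18.018

ZONES = ("A", "B", "C", "D", "E")


@dataclass
class MetricReport:
    """R, MAE +/- SD of absolute errors, RMSE (mmol/L) and MARD (fraction)."""

    r: float
    mae: float
    sd_ae: float
    rmse: float
    mard: float

    def as_dict(self) -> dict[str, float]:
        return {"r": self.r, "mae": self.mae, "sd_ae": self.sd_ae, "rmse": self.rmse, "mard": self.mard}


@dataclass
class ClarkeReport:
    """Counts and percentages of pairs per Clarke zone A..E."""

    zone_counts: dict
    zone_percentages: dict

    def as_dict(self) -> dict:
        return {"counts": dict(self.zone_counts), "percentages": dict(self.zone_percentages)}


def regression_metrics(ref, est) -> MetricReport:
    """Accuracy metrics of estimates against reference glucose.

    R is the Pearson product-moment correlation (reported as 0 with a
    warning when either sequence is constant); MARD divides each absolute
    error by its reference value, so references must be positive.
    """
    ref = np.asarray(ref, dtype=float)
    est = np.asarray(est, dtype=float)
    if ref.size != est.size or ref.size < 2:
        raise ValueError("ref and est must have equal length >= 2")
    if np.any(ref <= 0):
        raise ValueError("reference glucose must be positive for MARD")
    ae = np.abs(est - ref)
    if np.std(ref) == 0 or np.std(est) == 0:
        warnings.warn("constant sequence: correlation undefined, reporting r = 0", stacklevel=2)
        r = 0.0
    else:
        r = float(np.corrcoef(ref, est)[0, 1])
    return MetricReport(
        r=r,
        mae=float(np.mean(ae)),
        sd_ae=float(np.std(ae, ddof=1)),
        rmse=float(np.sqrt(np.mean((est - ref) ** 2))),
        mard=float(np.mean(ae / ref)),
    )


def clarke_zone(ref: float, est: float) -> str:
    """Clarke error grid zone of one (reference, estimate) pair in mmol/L."""
    if ref <= 0 or est <= 0:
        raise ValueError("glucose values must be positive")
    r = ref * MMOL_TO_MGDL
    e = est * MMOL_TO_MGDL
    if (r < 70 and e < 70) or (0.8 * r <= e <= 1.2 * r):
        return "A"
    if (r >= 180 and e <= 70) or (r <= 70 and e >= 180):
        return "E"
    if (70 <= r <= 290 and e >= r + 110) or (130 <= r <= 180 and e <= 1.4 * r - 182):
        return "C"
    if (r >= 240 and 70 <= e <= 180) or (r <= 175 / 3 and 70 <= e <= 180) or (
        175 / 3 <= r <= 70 and e >= 1.2 * r
    ):
        return "D"
    return "B"


def clarke_percentages(ref, est=None) -> ClarkeReport:
    """Zone counts and percentages over a set of pairs.

    Accepts either two sequences or one sequence of (ref, est) pairs.
    """
    if est is None:
        pairs = [(float(a), float(b)) for a, b in ref]
    else:
        pairs = list(zip(np.asarray(ref, dtype=float), np.asarray(est, dtype=float)))
    if not pairs:
        raise ValueError("need at least one pair")
    counts = dict.fromkeys(ZONES, 0)
    for r, e in pairs:
        counts[clarke_zone(r, e)] += 1
    total = len(pairs)
    pct = {z: 100.0 * c / total for z, c in counts.items()}
    return ClarkeReport(zone_counts=counts, zone_percentages=pct)


def plot_clarke(ref, est, ax=None):
    """Scatter the pairs on a Clarke error grid (mg/dL axes).

    Requires matplotlib; returns the axes.  Zone boundaries are drawn as
    the standard straight-line segments.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    r = np.asarray(ref, dtype=float) * MMOL_TO_MGDL
    e = np.asarray(est, dtype=float) * MMOL_TO_MGDL
    ax.scatter(r, e, s=12, c="tab:blue", alpha=0.8, zorder=3)
    lim = max(400.0, float(max(r.max(), e.max())) * 1.05)
    ax.plot([0, lim], [0, lim], "k:", lw=0.8)
    # zone A wedge
    ax.plot([0, lim], [0, 1.2 * lim], "k-", lw=0.8)
    ax.plot([0, lim], [0, 0.8 * lim], "k-", lw=0.8)
    ax.axvline(70, color="k", lw=0.8)
    ax.axhline(70, color="k", lw=0.8)
    ax.axhline(180, color="k", lw=0.8)
    ax.set_xlim(0, lim)
    ax.set_ylim(0, lim)
    ax.set_xlabel("reference glucose (mg/dL)")
    ax.set_ylabel("estimated glucose (mg/dL)")
    ax.set_title("Clarke error grid")
    return ax
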