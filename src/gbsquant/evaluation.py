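"""Accuracy evaluation of abundance estimates against design truth.

Covers false positive / false negative detection accounting, the fraction
of abundance mass assigned to absent strains, per-unit Pearson
correlation + ordinary-least-squares regression (with 95 % CIs), and
head-to-head comparison of two estimation methods.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import stats as sps

from .quantification import AbundanceTable

STRONG = "strong"
MODERATE = "moderate"
WEAK = "weak"
UNDEFINED = "undefined"


def classify_strength(r: float | None) -> str:
    """Fixed cutpoints: strong r > 0.7, moderate 0.5 <= r <= 0.7, else weak."""
    if r is None or r != r:
        return UNDEFINED
    if r > 0.7:
        return STRONG
    if r >= 0.5:
        return MODERATE
    return WEAK


@dataclass
class DetectionReport:
    per_strain: pd.DataFrame  # index strain, columns FP FN TP TN
    details: pd.DataFrame  # sample × strain outcome rows

    def total_fp(self) -> int:
        return int(self.per_strain["FP"].sum())

    def total_fn(self) -> int:
        return int(self.per_strain["FN"].sum())


def _aligned(observed: AbundanceTable, expected: AbundanceTable):
    obs_samples = set(observed.sample_ids)
    exp_samples = set(expected.sample_ids)
    if obs_samples != exp_samples:
        raise ValueError(
            "sample sets differ; only in observed: "
            f"{sorted(obs_samples - exp_samples)}, only in expected: "
            f"{sorted(exp_samples - obs_samples)}"
        )
    strains = sorted(set(observed.strain_ids) | set(expected.strain_ids))
    samples = sorted(obs_samples)
    obs = observed.values.reindex(index=samples, columns=strains).fillna(0.0)
    exp = expected.values.reindex(index=samples, columns=strains).fillna(0.0)
    return obs, exp


def detect(
    observed: AbundanceTable,
    expected: AbundanceTable,
    presence_threshold: float = 0.0,
) -> DetectionReport:
    """Tally FP/FN/TP/TN per strain.

    A strain is "detected" in a sample iff its observed abundance is
    strictly above ``presence_threshold``; it is "present" iff its
    expected abundance is positive.
    """
    obs, exp = _aligned(observed, expected)
    detected = obs > presence_threshold
    present = exp > 0
    rows = []
    for sample in obs.index:
        for strain in obs.columns:
            d, p = bool(detected.at[sample, strain]), bool(present.at[sample, strain])
            label = "TP" if (d and p) else "FP" if d else "FN" if p else "TN"
            rows.append((sample, strain, p, d, label))
    details = pd.DataFrame(
        rows, columns=["sample_id", "strain_id", "present", "detected", "outcome"]
    )
    per_strain = (
        details.pivot_table(
            index="strain_id", columns="outcome", values="sample_id", aggfunc="count"
        )
        .reindex(columns=["FP", "FN", "TP", "TN"])
        .fillna(0)
        .astype(int)
    )
    per_strain.index.name = None
    per_strain.columns.name = None
    return DetectionReport(per_strain=per_strain, details=details)


def false_signal_rate(
    observed: AbundanceTable, expected: AbundanceTable
) -> tuple[pd.Series, float]:
    """Per sample, the abundance mass assigned to strains absent from the
    design; plus the mean over samples."""
    obs, exp = _aligned(observed, expected)
    absent_mass = obs.where(exp == 0, 0.0).sum(axis=1)
    return absent_mass, float(absent_mass.mean())


def correlate(
    observed: AbundanceTable,
    expected: AbundanceTable,
    unit: str = "sample",
    include_absent: bool = True,
) -> pd.DataFrame:
    """Pearson r and OLS regression of observed on expected, per unit.

    ``unit="sample"`` pairs the strains within each sample;
    ``unit="strain"`` pairs the samples for each strain.  With
    ``include_absent=False``, pairs whose expected value is 0 are
    dropped first.  Units with fewer than 3 pairs or zero variance on
    either axis are reported as not computable (class "undefined"),
    never as NaN statistics.
    """
    if unit not in ("sample", "strain"):
        raise ValueError("unit must be 'sample' or 'strain'")
    obs, exp = _aligned(observed, expected)
    if unit == "strain":
        obs, exp = obs.T, exp.T
    rows = []
    for name in obs.index:
        y = obs.loc[name].to_numpy(dtype=float)
        x = exp.loc[name].to_numpy(dtype=float)
        if not include_absent:
            keep = x > 0
            x, y = x[keep], y[keep]
        rows.append(_regress(name, x, y))
    return pd.DataFrame(rows).set_index("unit")


def _regress(name: str, x: np.ndarray, y: np.ndarray) -> dict:
    base = {
        "unit": name,
        "n": len(x),
        "r": np.nan,
        "r2": np.nan,
        "slope": np.nan,
        "intercept": np.nan,
        "slope_lo": np.nan,
        "slope_hi": np.nan,
        "computable": False,
        "strength": UNDEFINED,
    }
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return base
    r = float(sps.pearsonr(x, y).statistic)
    fit = sps.linregress(x, y)
    tcrit = float(sps.t.ppf(0.975, len(x) - 2))
    base.update(
        r=r,
        r2=r * r,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        slope_lo=float(fit.slope - tcrit * fit.stderr),
        slope_hi=float(fit.slope + tcrit * fit.stderr),
        computable=True,
        strength=classify_strength(r),
    )
    return base


def compare_methods(a: pd.DataFrame, b: pd.DataFrame, labels=("GBS", "LM")):
    """Per-unit winner by Pearson r, plus summary counts.

    ``a`` and ``b`` are ``correlate`` outputs over the same units.  Units
    not computable in either method are skipped in the summary.
    """
    if set(a.index) != set(b.index):
        raise ValueError("method tables cover different units")
    rows = []
    summary = {labels[0]: 0, labels[1]: 0, "tie": 0, "skipped": 0}
    for unit in a.index:
        ra, rb = a.at[unit, "r"], b.at[unit, "r"]
        if not (a.at[unit, "computable"] and b.at[unit, "computable"]):
            winner = "skipped"
        elif ra > rb:
            winner = labels[0]
        elif rb > ra:
            winner = labels[1]
        else:
            winner = "tie"
        summary[winner] += 1
        rows.append((unit, ra, rb, winner))
    table = pd.DataFrame(
        rows, columns=["unit", f"r_{labels[0]}", f"r_{labels[1]}", "winner"]
    ).set_index("unit")
    return table, summary


def plot_regressions(
    observed: AbundanceTable,
    expected: AbundanceTable,
    path: str,
    unit: str = "strain",
) -> None:
    """Optional per-unit regression panels (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    stats = correlate(observed, expected, unit=unit)
    obs, exp = _aligned(observed, expected)
    if unit == "strain":
        obs, exp = obs.T, exp.T
    n = len(stats)
    ncols = min(3, n)
    nrows = -(-n // ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 3.5 * nrows), squeeze=False)
    for ax, name in zip(axes.flat, stats.index):
        x, y = exp.loc[name], obs.loc[name]
        ax.scatter(x, y, s=12)
        row = stats.loc[name]
        if row["computable"]:
            xs = np.linspace(float(x.min()), float(x.max()), 10)
            ax.plot(xs, row["slope"] * xs + row["intercept"], lw=1)
            ax.set_title(f"{name}  r={row['r']:.2f}")
        else:
            ax.set_title(f"{name}  (n.c.)")
        ax.set_xlabel("expected")
        ax.set_ylabel("observed")
    for ax in axes.flat[n:]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
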