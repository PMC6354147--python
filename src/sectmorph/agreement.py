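"""Agreement statistics between paired morphometric series.

The primary statistic is Lin's concordance correlation coefficient (CCC),

    rho_c = 2 s_xy / (s_x^2 + s_y^2 + (xbar - ybar)^2),

with moment estimators using 1/n denominators, as in Lin's defining paper.
Unlike the Pearson coefficient, which measures only linearity, the CCC
penalizes both scatter about the best-fit line (precision) and departure of
that line from the identity (accuracy); |CCC| <= |r| always. The 95% CI uses
the inverse-hyperbolic-tangent transformation with Lin's asymptotic standard
error (in its corrected form), back-transformed.

Mean difference +/- SD and Bland-Altman limits of agreement summarize the
differences on the measurement scale; a two-way absolute-agreement
single-measure ICC is provided as a comparator statistic (it assumes equal
marginal distributions, which is exactly what the CCC does not).

Difference sign convention: first-listed series minus comparator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from scipy import stats

#: the nine comparisons of one agreement table, in publication row order
TABLE_ROWS = (
    ("vs_hm", "original"),
    ("vs_hm", "offset+4"),
    ("vs_hm", "offset-4"),
    ("vs_hm", "rotation+10"),
    ("vs_hm", "rotation-10"),
    ("vs_original", "offset+4"),
    ("vs_original", "offset-4"),
    ("vs_original", "rotation+10"),
    ("vs_original", "rotation-10"),
)

VARIANTS = ("hm", "original", "offset+4", "offset-4", "rotation+10", "rotation-10")


@dataclass
class PairedMeasurements:
    """Two equal-length series of paired measurements.

    ``x`` is the reference series (listed first, e.g. the physical-section
    percent area), ``y`` the comparator.
    """

    x: np.ndarray
    y: np.ndarray
    labels: tuple[str, str] = ("x", "y")

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.ndim != 1 or self.x.shape != self.y.shape:
            raise ValueError("x and y must be 1D arrays of equal length")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("measurements must be finite")

    @property
    def n(self) -> int:
        return self.x.size


@dataclass
class AgreementResult:
    """One row of an agreement table."""

    ccc: float
    ci_lower: float
    ci_upper: float
    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    pearson_r: float
    n: int
    degenerate: bool = False
    labels: tuple[str, str] = ("x", "y")

    def as_dict(self) -> dict:
        return {
            "ccc": self.ccc, "ci_lower": self.ci_lower, "ci_upper": self.ci_upper,
            "mean_diff": self.mean_diff, "sd_diff": self.sd_diff,
            "loa_lower": self.loa_lower, "loa_upper": self.loa_upper,
            "pearson_r": self.pearson_r, "n": self.n,
        }


def _moments(x: np.ndarray, y: np.ndarray):
    mx, my = x.mean(), y.mean()
    sx2 = np.mean((x - mx) ** 2)          # 1/n estimators, per Lin
    sy2 = np.mean((y - my) ** 2)
    sxy = np.mean((x - mx) * (y - my))
    return mx, my, sx2, sy2, sxy


def ccc(paired: PairedMeasurements, ci_level: float = 0.95):
    """Lin's concordance correlation coefficient with its z-transform CI.

    Returns ``(estimate, ci_lower, ci_upper, degenerate)``. Requires n >= 3
    and at least one non-constant series; a single constant series yields
    CCC = 0 with the degenerate flag set and NaN confidence limits.
    """
    x, y, n = paired.x, paired.y, paired.n
    if n < 3:
        raise ValueError(f"need n >= 3 for a confidence interval, got {n}")
    mx, my, sx2, sy2, sxy = _moments(x, y)
    if sx2 == 0 and sy2 == 0:
        raise ValueError("both series are constant; CCC is undefined")
    est = 2 * sxy / (sx2 + sy2 + (mx - my) ** 2)
    if sx2 == 0 or sy2 == 0:
        return 0.0, float("nan"), float("nan"), True

    r = sxy / np.sqrt(sx2 * sy2)
    if abs(est) >= 1 - 1e-15 or r == 0:
        # perfect (anti)concordance or orthogonal series: the asymptotic
        # variance formula degenerates; the interval collapses to the point
        return float(est), float(est), float(est), True
    u = (mx - my) / (sx2 * sy2) ** 0.25
    # Lin's asymptotic variance of z = atanh(ccc), corrected form
    var_z = (
        (1 - r**2) * est**2 / ((1 - est**2) * r**2)
        + 4 * est**3 * (1 - est) * u**2 / (r * (1 - est**2) ** 2)
        - 2 * est**4 * u**4 / (r**2 * (1 - est**2) ** 2)
    ) / (n - 2)
    z = np.arctanh(est)
    half = stats.norm.ppf(0.5 + ci_level / 2) * np.sqrt(max(var_z, 0.0))
    return float(est), float(np.tanh(z - half)), float(np.tanh(z + half)), False


def pearson(paired: PairedMeasurements) -> float:
    mx, my, sx2, sy2, sxy = _moments(paired.x, paired.y)
    if sx2 == 0 or sy2 == 0:
        return float("nan")
    return float(sxy / np.sqrt(sx2 * sy2))


def mean_diff_sd(paired: PairedMeasurements) -> tuple[float, float]:
    """Mean and sample SD (n-1 denominator) of x - y."""
    if paired.n < 2:
        raise ValueError(f"need n >= 2, got {paired.n}")
    d = paired.x - paired.y
    return float(d.mean()), float(d.std(ddof=1))


@dataclass
class BlandAltman:
    bias: float
    sd: float
    loa_lower: float
    loa_upper: float
    points: pd.DataFrame  # columns: mean, diff


def bland_altman(paired: PairedMeasurements, multiplier: float = 1.96) -> BlandAltman:
    """Bland-Altman bias and 95% limits of agreement (bias +/- 1.96 SD)."""
    if paired.n < 2:
        raise ValueError(f"need n >= 2, got {paired.n}")
    d = paired.x - paired.y
    m = (paired.x + paired.y) / 2.0
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(
        bias=bias,
        sd=sd,
        loa_lower=bias - multiplier * sd,
        loa_upper=bias + multiplier * sd,
        points=pd.DataFrame({"mean": m, "diff": d}),
    )


def icc(paired: PairedMeasurements) -> float:
    """Two-way mixed, absolute-agreement, single-measure ICC (comparator).

    Computed from the standard mean-squares decomposition with k = 2 raters.
    """
    if paired.n < 3:
        raise ValueError(f"need n >= 3, got {paired.n}")
    data = np.stack([paired.x, paired.y], axis=1)  # subjects x raters
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((data - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if abs(denom) < 1e-300:
        raise ValueError(
            "degenerate variance decomposition: "
            f"MSR={msr:.3g} MSC={msc:.3g} MSE={mse:.3g}"
        )
    return float((msr - mse) / denom)


def agreement_stats(
    x: np.ndarray, y: np.ndarray, labels: tuple[str, str] = ("x", "y")
) -> AgreementResult:
    """Full agreement summary for one paired comparison."""
    paired = PairedMeasurements(x=x, y=y, labels=labels)
    est, lo, hi, degenerate = ccc(paired)
    md, sd = mean_diff_sd(paired)
    ba = bland_altman(paired)
    return AgreementResult(
        ccc=est, ci_lower=lo, ci_upper=hi,
        mean_diff=md, sd_diff=sd,
        loa_lower=ba.loa_lower, loa_upper=ba.loa_upper,
        pearson_r=pearson(paired), n=paired.n,
        degenerate=degenerate, labels=labels,
    )


def agreement_table(measurements: pd.DataFrame, phase: str) -> pd.DataFrame:
    """The nine-row agreement table for one phase ('bone' or 'graft').

    ``measurements`` must be tidy with columns ``specimen``, ``variant`` and
    ``pct_bone`` / ``pct_graft``; every specimen must contribute all six
    variants (physical-section proxy plus the five virtual sections). Block
    ``vs_hm`` compares the proxy with each virtual section; block
    ``vs_original`` compares the matched virtual section with the four
    perturbed ones. Differences are reference minus comparator.
    """
    if phase not in ("bone", "graft", "noncalcified"):
        raise ValueError(f"unknown phase {phase!r}")
    col = f"pct_{phase}"
    wide = measurements.pivot(index="specimen", columns="variant", values=col)
    for specimen, row in wide.iterrows():
        for variant in VARIANTS:
            if variant not in wide.columns or pd.isna(row.get(variant)):
                raise ValueError(
                    f"specimen {specimen!r} is missing variant {variant!r}"
                )
    rows = []
    for block, variant in TABLE_ROWS:
        ref = "hm" if block == "vs_hm" else "original"
        res = agreement_stats(
            wide[ref].to_numpy(), wide[variant].to_numpy(), labels=(ref, variant)
        )
        rows.append({
            "block": block, "comparison": variant, "phase": phase,
            **res.as_dict(), "sign_convention": f"{ref} - {variant}",
        })
    return pd.DataFrame(rows)
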