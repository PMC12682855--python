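"""Agreement between two phenotyping platforms' genotype-level values.

Three complementary views, applied to paired per-genotype values (one pair
per genotype, typically n = 26):

* Pearson correlation with a two-sided t-based p-value — linear association.
* Lin's concordance correlation coefficient (CCC) — agreement proper,
  penalizing location and scale shifts as well as decorrelation; its
  significance comes from a Fisher z-transform with Lin's (1989)
  asymptotic standard error.
* Bland-Altman limits of agreement — mean difference +/- k * SD (k = 1.96),
  with genotypes outside the limits flagged as discordant.

CCC uses population (1/n) moments per its originating definition; the
Bland-Altman SD is the sample (n-1) SD, as in the method's construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .trial_io import P_MINUS, P_PLUS, MetricTable

__all__ = [
    "AgreementReport",
    "BlandAltman",
    "pearson_with_p",
    "lin_ccc",
    "bland_altman",
    "compare_platforms",
    "correlation_matrix",
]


def _paired(x, y, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    return x, y


def pearson_with_p(x, y) -> tuple[float, float]:
    """Product-moment correlation with its two-sided t-test p-value."""
    x, y = _paired(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def lin_ccc(x, y) -> tuple[float, float]:
    """Lin's concordance correlation coefficient and its p-value.

    ``ccc = 2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2)`` with
    population (1/n) moments.  The p-value tests ccc = 0 through the
    Fisher z-transform with Lin's asymptotic standard error.
    """
    x, y = _paired(x, y)
    n = x.size
    sx2 = x.var()
    sy2 = y.var()
    if sx2 == 0 and sy2 == 0:
        raise ValueError("CCC undefined when both sequences are constant")
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    dmean = x.mean() - y.mean()
    ccc = 2.0 * sxy / (sx2 + sy2 + dmean * dmean)

    if abs(ccc) >= 1.0:  # exact agreement: z-transform degenerates
        return float(ccc), 0.0
    if sx2 == 0 or sy2 == 0:
        return float(ccc), 1.0  # no association estimable against a constant
    r = sxy / np.sqrt(sx2 * sy2)
    z = np.arctanh(ccc)
    u2 = dmean * dmean / np.sqrt(sx2 * sy2)  # squared location shift, scale-free
    c2 = ccc * ccc
    r2 = r * r
    # Lin (1989) asymptotic variance of the z-transformed CCC.
    var_z = (
        (1 - r2) * c2 / ((1 - c2) * r2)
        + 2 * ccc ** 3 * (1 - ccc) * u2 / (r * (1 - c2) ** 2)
        - c2 * c2 * u2 * u2 / (2 * r2 * (1 - c2) ** 2)
    ) / (n - 2)
    if var_z <= 0:
        return float(ccc), 1.0
    p = 2.0 * stats.norm.sf(abs(z) / np.sqrt(var_z))
    return float(ccc), float(p)


@dataclass
class BlandAltman:
    """Limits-of-agreement summary of paired differences x - y."""

    mean_difference: float
    sd_difference: float
    loa_low: float
    loa_high: float
    k: float
    outliers: tuple[str, ...]

    def __post_init__(self) -> None:
        assert self.loa_low <= self.mean_difference <= self.loa_high


def bland_altman(x, y, labels: Sequence[str] | None = None, k: float = 1.96) -> BlandAltman:
    """Mean difference and k-SD limits of agreement for paired values.

    ``labels`` names the pairs (for outlier reporting); defaults to the
    pair's 0-based position rendered as a string.
    """
    x, y = _paired(x, y)
    d = x - y
    if labels is None:
        labels = [str(i) for i in range(d.size)]
    elif len(labels) != d.size:
        raise ValueError("labels length must match number of pairs")
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    lo, hi = mean_d - k * sd_d, mean_d + k * sd_d
    outliers = tuple(str(lab) for lab, di in zip(labels, d) if di < lo or di > hi)
    return BlandAltman(mean_d, sd_d, lo, hi, k, outliers)


@dataclass
class AgreementReport:
    """All three agreement views for one pair of platforms."""

    n: int
    pearson_r: float
    pearson_p: float
    ccc: float
    ccc_p: float
    bland_altman: BlandAltman

    def to_dict(self) -> dict:
        ba = self.bland_altman
        return {
            "n": self.n,
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
            "ccc": self.ccc,
            "ccc_p": self.ccc_p,
            "bland_altman": {
                "mean_difference": ba.mean_difference,
                "sd_difference": ba.sd_difference,
                "loa_low": ba.loa_low,
                "loa_high": ba.loa_high,
                "k": ba.k,
                "outliers": list(ba.outliers),
            },
        }


def compare_platforms(x, y, labels: Sequence[str] | None = None, k: float = 1.96) -> AgreementReport:
    """Pearson + CCC + Bland-Altman for paired per-genotype values."""
    x_arr, y_arr = _paired(x, y)
    r, rp = pearson_with_p(x_arr, y_arr)
    c, cp = lin_ccc(x_arr, y_arr)
    ba = bland_altman(x_arr, y_arr, labels=labels, k=k)
    return AgreementReport(n=x_arr.size, pearson_r=r, pearson_p=rp, ccc=c, ccc_p=cp,
                           bland_altman=ba)


def correlation_matrix(
    table: MetricTable,
    metrics: Sequence[str] = ("pae", "prae", "pue"),
    condition: str = P_MINUS,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations of per-level metrics across genotypes.

    Returns ``(r, p, masked)`` DataFrames; ``masked`` hides (NaN) cells
    whose p-value is >= ``alpha``, mirroring the convention of plotting
    only significant coefficients.  The diagonal is exactly 1 and never
    masked.
    """
    if condition not in (P_MINUS, P_PLUS):
        raise ValueError(f"condition must be {P_MINUS!r} or {P_PLUS!r}")
    metrics = list(metrics)
    if len(metrics) < 2:
        raise ValueError("need at least two metrics")
    cols = {m: table.metric_mean(m, condition).to_numpy(dtype=float) for m in metrics}
    if len(next(iter(cols.values()))) < 3:
        raise ValueError("need at least three genotypes")

    r = pd.DataFrame(np.eye(len(metrics)), index=metrics, columns=metrics)
    p = pd.DataFrame(np.zeros((len(metrics), len(metrics))), index=metrics, columns=metrics)
    for i, a in enumerate(metrics):
        for b in metrics[i + 1:]:
            rij, pij = pearson_with_p(cols[a], cols[b])
            r.loc[a, b] = r.loc[b, a] = rij
            p.loc[a, b] = p.loc[b, a] = pij
    masked = r.where((p < alpha) | np.eye(len(metrics), dtype=bool))
    return r, p, masked
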