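"""Inferential statistics for the factorial trial.

Two-way ANOVA with interaction (genotype x P level), the distributional
checks run before it (Brown-Forsythe Levene, Shapiro-Wilk), and the
within-genotype P+ vs P- pairwise t-tests with Bonferroni correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

from .trial_io import HarvestRecord, records_to_frame

__all__ = [
    "AnovaResult",
    "two_way_anova",
    "assumption_checks",
    "pairwise_t_bonferroni",
]


@dataclass
class AnovaResult:
    """Decomposition table: df, SS, F and p per term plus the residual row.

    ``table`` is indexed by term name (``genotype``, ``p_level``,
    ``genotype:p_level``, ``residual``); the residual row carries NaN for
    F and p.  ``typ`` records the sum-of-squares flavor used.
    """

    table: pd.DataFrame
    typ: int
    balanced: bool

    def p(self, term: str) -> float:
        return float(self.table.loc[term, "p"])

    def f(self, term: str) -> float:
        return float(self.table.loc[term, "F"])


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    if records and isinstance(records[0], HarvestRecord):
        return records_to_frame(records)
    return pd.DataFrame(records)


def two_way_anova(records, response: str = "shoot_dw") -> AnovaResult:
    """Genotype x P-level ANOVA with interaction on one response.

    Balanced designs use the classical decomposition (where Type I and
    Type II sums of squares coincide); unbalanced designs fall back to
    Type II.  The interaction requires at least one cell with two or more
    replicates and no empty cell.
    """
    frame = _as_frame(records)
    for col in ("genotype", "p_level", response):
        if col not in frame.columns:
            raise ValueError(f"records lack column {col!r}")
    y = frame[response].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("response is constant; ANOVA undefined")
    cell_sizes = frame.groupby(["genotype", "p_level"], sort=False).size()
    n_geno = frame["genotype"].nunique()
    n_lev = frame["p_level"].nunique()
    if n_geno < 2 or n_lev < 2:
        raise ValueError("need at least two levels of each factor")
    if len(cell_sizes) < n_geno * n_lev:
        raise ValueError("empty genotype x P-level cell; interaction inestimable")
    if (cell_sizes < 2).all():
        raise ValueError("interaction requires >=2 replicates in at least one cell")
    balanced = cell_sizes.nunique() == 1

    data = frame[["genotype", "p_level", response]].rename(columns={response: "_y"})
    model = ols("_y ~ C(genotype) * C(p_level)", data=data).fit()
    typ = 1 if balanced else 2
    raw = anova_lm(model, typ=typ)

    rename = {
        "C(genotype)": "genotype",
        "C(p_level)": "p_level",
        "C(genotype):C(p_level)": "genotype:p_level",
        "Residual": "residual",
    }
    table = raw.rename(index=rename)[["df", "sum_sq", "F", "PR(>F)"]]
    table.columns = ["df", "sum_sq", "F", "p"]
    table = table.reindex(["genotype", "p_level", "genotype:p_level", "residual"])
    return AnovaResult(table=table, typ=typ, balanced=balanced)


def assumption_checks(groups) -> dict[str, tuple[float, float]]:
    """Levene (Brown-Forsythe) and Shapiro-Wilk checks on grouped data.

    ``groups`` is a sequence of 1-D samples, one per factorial cell.
    Levene is median-centered (robust to non-normality); Shapiro-Wilk is
    run on the pooled residuals from group means, valid for 3 <= n <= 5000.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size < 3 for g in groups):
        raise ValueError("Levene needs >=3 observations per group")
    if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
        # identical constant groups: no dispersion anywhere
        levene = (0.0, 1.0)
    else:
        w, p = stats.levene(*groups, center="median")
        levene = (float(w), float(p))
    residuals = np.concatenate([g - g.mean() for g in groups])
    if not 3 <= residuals.size <= 5000:
        raise ValueError("Shapiro-Wilk valid for 3 <= n <= 5000")
    sw, sp = stats.shapiro(residuals)
    return {"levene": levene, "shapiro_wilk": (float(sw), float(sp))}


def pairwise_t_bonferroni(
    records,
    response: str = "shoot_dw",
    p_plus: str = "P+",
    p_minus: str = "P-",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Within-genotype P+ vs P- Student t-tests, Bonferroni-adjusted.

    Equal-variance two-sided t per genotype; adjusted p is
    ``min(1, raw_p * m)`` where m is the number of genotypes actually
    tested.  Genotypes with fewer than two replicates in either level are
    skipped with a warning.

    Returns a DataFrame indexed by genotype with columns
    ``t``, ``p_raw``, ``p_adj``, ``significant``.
    """
    frame = _as_frame(records)
    rows = {}
    skipped = []
    for geno, sub in frame.groupby("genotype", sort=False):
        a = sub.loc[sub["p_level"] == p_plus, response].to_numpy(dtype=float)
        b = sub.loc[sub["p_level"] == p_minus, response].to_numpy(dtype=float)
        if a.size < 2 or b.size < 2:
            skipped.append(geno)
            continue
        t, p = stats.ttest_ind(a, b, equal_var=True)
        rows[geno] = (float(t), float(p))
    if skipped:
        warnings.warn(f"skipping genotypes with <2 replicates per level: {skipped}",
                      stacklevel=2)
    if not rows:
        raise ValueError("no genotype had both levels with >=2 replicates")
    m = len(rows)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["t", "p_raw"])
    out.index.name = "genotype"
    out["p_adj"] = np.minimum(1.0, out["p_raw"] * m)
    out["significant"] = out["p_adj"] < alpha
    return out
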