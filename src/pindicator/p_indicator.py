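"""The composite 0-5 "P indicator" and the efficiency/responsiveness quadrants.

The indicator min-max normalizes each of the five P-efficiency metrics
across genotypes to [0, 1], orients every component so that larger means
"better under the chosen P regime", and sums them, yielding a score between
0 (lowest overall efficiency) and 5 (best performer).  By default the
indicator is built for the deficient condition (P-), with the two level-free
metrics (relative efficiency, APUE) shared between conditions.

Component orientation: PAE, PUE, relative efficiency and APUE score higher
when larger.  PRAE (uptake per unit root biomass) scores higher when
*smaller*: at a given uptake, low PRAE identifies genotypes that invested in
a large root system — the root-foraging trait the deficient condition
selects for.  Orientations are configurable per component.

Quadrant classification crosses efficiency (whole-plant dry matter under
P-) with responsiveness (APUE) at their across-genotype mean (or median):
ER efficient+responsive, ENR efficient only, NER responsive only, NENR
neither.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trial_io import P_MINUS, P_PLUS, MetricTable

__all__ = [
    "DEFAULT_ORIENTATIONS",
    "IndicatorResult",
    "QuadrantClassification",
    "minmax_normalize",
    "compute_indicator",
    "classify_quadrants",
]

#: +1: larger raw metric is better; -1: smaller raw metric is better.
DEFAULT_ORIENTATIONS: dict[str, int] = {
    "pae": 1,
    "prae": -1,
    "pue": 1,
    "relative_efficiency": 1,
    "apue": 1,
}

_COMPONENTS = ("pae", "prae", "pue", "relative_efficiency", "apue")


def minmax_normalize(values) -> np.ndarray:
    """Affinely map a sequence onto [0, 1] (min -> 0, max -> 1).

    A constant input has no range to normalize; it maps to all 0.5 with a
    warning, so that a degenerate metric contributes the same neutral
    amount to every genotype.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values to normalize")
    bad = np.flatnonzero(~np.isfinite(x))
    if bad.size:
        raise ValueError(f"non-finite value at position {bad[0]}")
    lo, hi = x.min(), x.max()
    if hi == lo:
        warnings.warn("constant input to min-max normalization; returning 0.5",
                      stacklevel=2)
        return np.full_like(x, 0.5)
    return (x - lo) / (hi - lo)


@dataclass
class IndicatorResult:
    """Per-genotype components, composite score and rank of the P indicator.

    ``data`` is indexed by genotype with the five normalized component
    columns (each in [0, 1], already oriented), ``score`` (their sum, in
    [0, 5]) and ``rank`` (dense, 1 = best, ties share a rank).
    """

    data: pd.DataFrame
    condition: str
    platform_label: str = ""
    orientations: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_ORIENTATIONS))
    excluded: tuple[str, ...] = ()

    @property
    def scores(self) -> pd.Series:
        return self.data["score"]

    def to_csv(self, path) -> None:
        self.data.reset_index(names="genotype").to_csv(path, index=False)


def compute_indicator(
    table: MetricTable,
    condition: str = P_MINUS,
    orientations: dict[str, int] | None = None,
) -> IndicatorResult:
    """Build the composite P indicator for one platform and condition.

    Components are the condition's PAE, PRAE and PUE genotype means plus
    the level-free relative efficiency and APUE, each min-max normalized
    across genotypes and oriented per ``orientations`` (a -1 orientation
    flips the normalized component to ``1 - value``).  Genotypes missing
    any component are excluded with a warning and normalization runs over
    the remainder.  Deterministic: no randomness enters.
    """
    if condition not in (P_MINUS, P_PLUS):
        raise ValueError(f"condition must be {P_MINUS!r} or {P_PLUS!r}")
    orient = dict(DEFAULT_ORIENTATIONS)
    if orientations:
        unknown = set(orientations) - set(_COMPONENTS)
        if unknown:
            raise KeyError(f"unknown components: {sorted(unknown)}")
        orient.update(orientations)

    raw = pd.DataFrame({m: table.metric_mean(m, condition) for m in _COMPONENTS})
    keep = raw.dropna()
    excluded = tuple(raw.index.difference(keep.index))
    if excluded:
        warnings.warn(f"excluding genotypes with missing metrics: {list(excluded)}",
                      stacklevel=2)
    if len(keep) < 2:
        raise ValueError("need at least two complete genotypes")

    comps = {}
    for metric in _COMPONENTS:
        normalized = minmax_normalize(keep[metric].to_numpy())
        comps[metric] = normalized if orient[metric] > 0 else 1.0 - normalized
    out = pd.DataFrame(comps, index=keep.index)
    out["score"] = out[list(_COMPONENTS)].sum(axis=1)
    out["rank"] = out["score"].rank(method="dense", ascending=False).astype(int)
    return IndicatorResult(
        data=out,
        condition=condition,
        platform_label=table.platform_label,
        orientations=orient,
        excluded=excluded,
    )


@dataclass
class QuadrantClassification:
    """Efficiency/responsiveness classes with the thresholds that split them."""

    classes: pd.Series  # genotype -> one of ER / ENR / NER / NENR
    apue_threshold: float
    dw_threshold: float
    rule: str

    def counts(self) -> dict[str, int]:
        c = self.classes.value_counts()
        return {k: int(c.get(k, 0)) for k in ("ER", "ENR", "NER", "NENR")}


def classify_quadrants(
    apue_values: pd.Series,
    dw_pminus: pd.Series,
    rule: str = "mean",
) -> QuadrantClassification:
    """Cross P responsiveness (APUE) with efficiency (dry matter at P-).

    Thresholds are the across-genotype ``mean`` (default) or ``median`` of
    each axis.  Boundary values classify upward (>=): a genotype exactly on
    both thresholds is ER.

    * ER   — efficient and responsive   (dw >= t_dw, apue >= t_apue)
    * ENR  — efficient, non-responsive  (dw >= t_dw, apue <  t_apue)
    * NER  — non-efficient, responsive  (dw <  t_dw, apue >= t_apue)
    * NENR — neither                    (otherwise)
    """
    if rule not in ("mean", "median"):
        raise ValueError(f"rule must be 'mean' or 'median', got {rule!r}")
    apue_values = pd.Series(apue_values)
    dw_pminus = pd.Series(dw_pminus)
    if set(apue_values.index) != set(dw_pminus.index):
        diff = set(apue_values.index) ^ set(dw_pminus.index)
        raise ValueError(f"genotype sets differ between inputs: {sorted(diff)}")
    dw_pminus = dw_pminus.reindex(apue_values.index)

    agg = np.mean if rule == "mean" else np.median
    t_apue = float(agg(apue_values.to_numpy(dtype=float)))
    t_dw = float(agg(dw_pminus.to_numpy(dtype=float)))

    responsive = apue_values >= t_apue
    efficient = dw_pminus >= t_dw
    labels = np.where(
        efficient & responsive, "ER",
        np.where(efficient, "ENR", np.where(responsive, "NER", "NENR")),
    )
    return QuadrantClassification(
        classes=pd.Series(labels, index=apue_values.index, name="class"),
        apue_threshold=t_apue,
        dw_threshold=t_dw,
        rule=rule,
    )
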