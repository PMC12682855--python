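"""The five phosphorus-efficiency metrics and their trial-level aggregation.

Per-plant metrics (computed per replicate, then summarized as mean +/- sample
SD per genotype x P level):

* PAE  — P acquisition efficiency: ``P_uptake / P_applied * 100`` (percent).
* PUE  — P utilization efficiency by the balance method:
  ``DW / P_concentration * DW`` i.e. ``DW^2 / P_concentration``.
* PRAE — P root acquisition efficiency: ``P_uptake / root_biomass``
  (g P per g root).

Genotype-level metrics (computed once per genotype, from genotype-mean
whole-plant dry weight at each level):

* APUE — agronomic P use efficiency:
  ``(DW_P+ - DW_P-) / (available_P+ - available_P-)`` (g DW per g P).
* P relative efficiency — ``biomass_P- / biomass_P+ * 100`` (percent),
  100 meaning no biomass penalty under deficiency.

The PUE formula is implemented literally as DW^2/concentration; the
concentration unit is carried as a label and never converted silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trial_io import (
    METRIC_COLUMNS,
    HarvestRecord,
    MetricTable,
    TrialDesign,
    records_to_frame,
)

__all__ = [
    "MetricConfig",
    "pae",
    "pue",
    "prae",
    "apue",
    "relative_efficiency",
    "compute_metric_table",
]


@dataclass(frozen=True)
class MetricConfig:
    """Unit and aggregation conventions left open by the metric formulas.

    concentration_unit
        Label of the tissue-P concentration unit fed to PUE (default mM).
    aggregation
        Only ``"replicate-then-mean"`` is defined: per-plant metrics are
        computed per replicate and then averaged per genotype x level.
    apue_on_means
        APUE and relative efficiency are computed from genotype-mean dry
        weights (they are single level-free values per genotype).
    biomass
        ``"total"`` uses shoot+root DW for PUE/APUE/relative efficiency;
        ``"shoot"`` restricts to shoot DW.
    """

    concentration_unit: str = "mM"
    aggregation: str = "replicate-then-mean"
    apue_on_means: bool = True
    biomass: str = "total"

    def __post_init__(self) -> None:
        if self.aggregation != "replicate-then-mean":
            raise ValueError(f"unsupported aggregation {self.aggregation!r}")
        if self.biomass not in ("total", "shoot"):
            raise ValueError(f"biomass must be 'total' or 'shoot', got {self.biomass!r}")


def pae(p_uptake, p_applied):
    """P acquisition efficiency: uptake as a percentage of P supplied."""
    p_uptake = np.asarray(p_uptake, dtype=float)
    p_applied = np.asarray(p_applied, dtype=float)
    if np.any(p_applied <= 0):
        raise ValueError("p_applied must be > 0")
    if np.any(p_uptake < 0):
        raise ValueError("p_uptake must be >= 0")
    return p_uptake / p_applied * 100.0


def pue(dry_weight, p_concentration):
    """P utilization efficiency (balance method): DW^2 / concentration."""
    dry_weight = np.asarray(dry_weight, dtype=float)
    p_concentration = np.asarray(p_concentration, dtype=float)
    if np.any(p_concentration <= 0):
        raise ValueError("p_concentration must be > 0")
    if np.any(dry_weight < 0):
        raise ValueError("dry_weight must be >= 0")
    return dry_weight * dry_weight / p_concentration


def prae(p_uptake, root_biomass):
    """P root acquisition efficiency: uptake per unit root biomass."""
    p_uptake = np.asarray(p_uptake, dtype=float)
    root_biomass = np.asarray(root_biomass, dtype=float)
    if np.any(root_biomass <= 0):
        raise ValueError("root_biomass must be > 0")
    if np.any(p_uptake < 0):
        raise ValueError("p_uptake must be >= 0")
    return p_uptake / root_biomass


def apue(dw_pplus, dw_pminus, avail_pplus, avail_pminus):
    """Agronomic P use efficiency: extra dry matter per extra available P.

    Negative values (biomass higher under deficiency) are preserved.
    """
    dw_pplus = np.asarray(dw_pplus, dtype=float)
    dw_pminus = np.asarray(dw_pminus, dtype=float)
    if not np.all(np.asarray(avail_pplus) > np.asarray(avail_pminus)):
        raise ValueError("available P under P+ must exceed available P under P-")
    return (dw_pplus - dw_pminus) / (np.asarray(avail_pplus, float) - np.asarray(avail_pminus, float))


def relative_efficiency(biomass_pminus, biomass_pplus):
    """Biomass under deficiency as a percentage of biomass at optimal P."""
    biomass_pminus = np.asarray(biomass_pminus, dtype=float)
    biomass_pplus = np.asarray(biomass_pplus, dtype=float)
    if np.any(biomass_pplus <= 0):
        raise ValueError("biomass at P+ must be > 0")
    return biomass_pminus / biomass_pplus * 100.0


def uptake_from_compartments(shoot_dw, shoot_conc, root_dw, root_conc):
    """Whole-plant P uptake as the sum of compartment DW x concentration.

    Used when uptake was not measured directly; concentrations must share
    a mass-fraction unit (g P per g DW) for the result to be in g.
    """
    return (
        np.asarray(shoot_dw, float) * np.asarray(shoot_conc, float)
        + np.asarray(root_dw, float) * np.asarray(root_conc, float)
    )


def compute_metric_table(
    records: list[HarvestRecord],
    design: TrialDesign,
    cfg: MetricConfig | None = None,
) -> MetricTable:
    """Aggregate harvest records into a genotype-level five-metric table.

    PAE/PRAE/PUE are computed per replicate and summarized as mean and
    sample (n-1) SD per genotype x P level.  APUE and relative efficiency
    are computed once per genotype from genotype-mean dry weight
    (whole plant by default).  A genotype missing one level gets NaN for
    the two level-free metrics; its per-level summaries are still emitted.
    """
    cfg = cfg or MetricConfig()
    frame = records_to_frame(records)
    if frame.empty:
        raise ValueError("no harvest records to aggregate")

    dw = frame["shoot_dw"] if cfg.biomass == "shoot" else frame["shoot_dw"] + frame["root_dw"]
    frame = frame.assign(
        _dw=dw,
        _pae=pae(frame["p_uptake"], frame["p_level"].map(design.p_applied_for)),
        _prae=prae(frame["p_uptake"], frame["root_dw"]),
        _pue=pue(dw, frame["plant_p_concentration"]),
    )

    suffix = {design.p_minus: "pminus", design.p_plus: "pplus"}
    out = pd.DataFrame(index=pd.Index(design.genotypes, name="genotype"),
                       columns=list(METRIC_COLUMNS), dtype=float)
    grouped = frame.groupby(["genotype", "p_level"], sort=False)
    means = grouped[["_pae", "_prae", "_pue", "_dw"]].mean()
    sds = grouped[["_pae", "_prae", "_pue"]].std(ddof=1)
    for (geno, level), row in means.iterrows():
        s = suffix[level]
        out.loc[geno, [f"pae_{s}_mean", f"prae_{s}_mean", f"pue_{s}_mean"]] = (
            row[["_pae", "_prae", "_pue"]].to_numpy()
        )
        out.loc[geno, [f"pae_{s}_sd", f"prae_{s}_sd", f"pue_{s}_sd"]] = (
            sds.loc[(geno, level), ["_pae", "_prae", "_pue"]].to_numpy()
        )

    dw_means = means["_dw"].unstack("p_level")
    avail_hi = design.p_applied_for(design.p_plus)
    avail_lo = design.p_applied_for(design.p_minus)
    for geno in design.genotypes:
        if geno not in dw_means.index:
            continue
        hi = dw_means.loc[geno].get(design.p_plus, np.nan)
        lo = dw_means.loc[geno].get(design.p_minus, np.nan)
        if np.isnan(hi) or np.isnan(lo):
            continue  # level-free metrics stay NaN for incomplete genotypes
        out.loc[geno, "apue"] = apue(hi, lo, avail_hi, avail_lo)
        out.loc[geno, "relative_efficiency"] = relative_efficiency(lo, hi)

    return MetricTable(
        out,
        platform_label=design.platform_label,
        n_per_cell=design.replicates_per_cell,
    )
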