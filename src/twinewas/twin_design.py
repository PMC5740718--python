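"""Pair-level analysis tables for the intra-pair difference design.

For each lung-function metric the twin with the higher z-score is labelled
"superior" and all differenced quantities (outcome z, methylation M values,
covariates) are superior minus inferior under that metric's ordering.  Sex
and age are identical within a monozygotic pair and therefore enter at pair
level rather than as differences.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .methylation import CELL_TYPES

__all__ = [
    "PairDesignTable",
    "SMOKING_CODES",
    "LOG_METRICS",
    "CROSS_SECTIONAL_METRICS",
    "LONGITUDINAL_METRICS",
    "order_pair",
    "transform_predictor",
    "difference_covariates",
    "difference_methylation",
    "build_design",
]

SMOKING_CODES = {"never": 0, "non-current": 1, "current": 2}

#: Metrics whose intra-pair difference is natural-log transformed.
LOG_METRICS = frozenset({"zFEV1", "zFVC", "zFEV1-change", "zFVC-change"})

CROSS_SECTIONAL_METRICS = ("zFEV1", "zFVC", "zFEV1/FVC")
LONGITUDINAL_METRICS = ("zFEV1-change", "zFVC-change", "zFEV1/FVC-change")

CELL_DIFF_COLS = tuple(f"d_{ct}" for ct in CELL_TYPES)


def order_pair(
    id_a: str, z_a: float, id_b: str, z_b: float
) -> tuple[str, str, float, bool]:
    """Order a twin pair by a metric.

    Returns ``(superior_id, inferior_id, delta_z, tied)`` with
    ``delta_z = z_superior - z_inferior >= 0``.  The result does not depend
    on the order of the inputs; exact ties are flagged.
    """
    if not (math.isfinite(z_a) and math.isfinite(z_b)):
        raise ValueError("z-scores must be finite")
    if z_a == z_b:
        sup, inf = sorted([id_a, id_b])  # arbitrary but order-invariant
        return sup, inf, 0.0, True
    if z_a > z_b:
        return id_a, id_b, z_a - z_b, False
    return id_b, id_a, z_b - z_a, False


def transform_predictor(delta_z: float, metric: str) -> float:
    """Predictor transform: ln(delta_z) for the volume metrics, identity
    for the FEV1/FVC ratio metrics."""
    if delta_z < 0:
        raise ValueError("delta_z must be >= 0")
    if metric in LOG_METRICS:
        if delta_z == 0:
            raise ValueError(
                f"delta_z = 0 is not log-transformable for metric {metric!r}"
            )
        return math.log(delta_z)
    return float(delta_z)


def difference_covariates(
    pair_rows: pd.DataFrame,
    superior_id: str,
    inferior_id: str,
    cell_fractions: pd.DataFrame,
    flavour: str,
) -> dict:
    """Differenced and pair-level covariates under a fixed ordering.

    Cross-sectional: follow-up BMI, total pack-years.  Longitudinal: BMI
    change over follow-up, follow-up-period pack-years.  Raises ``KeyError``
    on a missing covariate (caller drops the pair and logs it).
    """
    if flavour not in ("cross-sectional", "longitudinal"):
        raise ValueError(f"unknown flavour {flavour!r}")
    sup = pair_rows.loc[superior_id]
    inf = pair_rows.loc[inferior_id]

    if flavour == "cross-sectional":
        bmi_sup, bmi_inf = sup["bmi_followup"], inf["bmi_followup"]
        py_sup, py_inf = sup["pack_years_total"], inf["pack_years_total"]
    else:
        bmi_sup = sup["bmi_followup"] - sup["bmi_baseline"]
        bmi_inf = inf["bmi_followup"] - inf["bmi_baseline"]
        py_sup = sup["pack_years_followup_period"]
        py_inf = inf["pack_years_followup_period"]

    row = {
        "sex": 1.0 if sup["sex"] == "M" else 0.0,
        "age": float(sup["age_followup"]),
        "d_bmi": float(bmi_sup - bmi_inf),
        "d_pack_years": float(py_sup - py_inf),
        "d_smoking_status": float(
            SMOKING_CODES[sup["smoking_status"]] - SMOKING_CODES[inf["smoking_status"]]
        ),
    }
    frac_sup = cell_fractions.loc[superior_id]
    frac_inf = cell_fractions.loc[inferior_id]
    for ct in CELL_TYPES:
        row[f"d_{ct}"] = float(frac_sup[ct] - frac_inf[ct])
    for key, value in row.items():
        if not math.isfinite(value):
            raise KeyError(f"covariate {key} is missing/non-finite")
    return row


@dataclass
class PairDesignTable:
    """One analysis-ready row per twin pair for a (metric, flavour) pair.

    ``table`` columns: pair_id (index), superior_id, inferior_id, delta_z,
    predictor, sex, age, d_bmi, d_pack_years, d_smoking_status and the five
    d_<cell type> columns.  ``exclusions`` accounts for every input pair not
    analyzed.
    """

    metric: str
    flavour: str
    table: pd.DataFrame
    exclusions: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.table) and (self.table["delta_z"] < 0).any():
            raise ValueError("delta_z must be >= 0")

    @property
    def n_pairs(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#metric\t{self.metric}\n")
            fh.write(f"#flavour\t{self.flavour}\n")
            for pair_id, reason in self.exclusions:
                fh.write(f"#excluded\t{pair_id}\t{reason}\n")
            self.table.rename_axis("pair_id").to_csv(fh, sep="\t")


def build_design(
    cohort: pd.DataFrame,
    zpanel,
    cell_fractions: pd.DataFrame,
    metric: str,
    flavour: str,
) -> PairDesignTable:
    """Assemble the pair design table for one metric and model flavour."""
    if flavour == "cross-sectional" and metric not in CROSS_SECTIONAL_METRICS:
        raise ValueError(f"{metric!r} is not a cross-sectional metric")
    if flavour == "longitudinal" and metric not in LONGITUDINAL_METRICS:
        raise ValueError(f"{metric!r} is not a longitudinal metric")

    z = zpanel.value(metric)
    subjects = cohort.set_index("subject_id")
    rows = {}
    exclusions: list[tuple[str, str]] = []
    for pair_id, grp in cohort.groupby("pair_id", sort=True):
        if len(grp) != 2:
            exclusions.append((str(pair_id), "incomplete_pair"))
            continue
        ids = list(grp["subject_id"])
        sup, inf, delta, tied = order_pair(ids[0], z[ids[0]], ids[1], z[ids[1]])
        if tied:
            exclusions.append((str(pair_id), "tied"))
            continue
        try:
            predictor = transform_predictor(delta, metric)
        except ValueError:
            exclusions.append((str(pair_id), "zero_delta_log_metric"))
            continue
        try:
            cov = difference_covariates(subjects, sup, inf, cell_fractions, flavour)
        except KeyError as err:
            exclusions.append((str(pair_id), f"missing_covariate:{err.args[0]}"))
            continue
        rows[str(pair_id)] = {
            "superior_id": sup,
            "inferior_id": inf,
            "delta_z": delta,
            "predictor": predictor,
            **cov,
        }
    for pair_id, reason in exclusions:
        warnings.warn(f"pair {pair_id} excluded from {metric}/{flavour}: {reason}")
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "pair_id"
    return PairDesignTable(metric=metric, flavour=flavour, table=table,
                           exclusions=exclusions)


def difference_methylation(
    m_matrix: pd.DataFrame, design: PairDesignTable
) -> pd.DataFrame:
    """Per-pair M-value differences, superior minus inferior.

    ``m_matrix`` is probes x samples; the result is probes x pairs with the
    design's pair IDs as columns.  Orderings differ between metrics, so a
    separate matrix exists per design table.
    """
    for col in ("superior_id", "inferior_id"):
        missing = [s for s in design.table[col] if s not in m_matrix.columns]
        if missing:
            raise KeyError(f"samples missing from M matrix: {missing}")
    sup = m_matrix[list(design.table["superior_id"])].to_numpy()
    inf = m_matrix[list(design.table["inferior_id"])].to_numpy()
    return pd.DataFrame(sup - inf, index=m_matrix.index, columns=design.table.index)
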