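"""LMS-based lung-function z-scores and longitudinal change scores.

A reference distribution for each spirometry metric is parameterized per sex
on an age grid by the LMS triplet: skewness power L, median M and coefficient
of variation S.  Height enters through a per-metric power scaling of the
median relative to a sex-specific reference height.  The z-score of a
measured value ``y`` is::

    z = ((y / M)^L - 1) / (L * S)        (L != 0)
    z = ln(y / M) / S                    (L -> 0 limit)

Baseline z-scores are computed with baseline age but follow-up height, and
the change score is follow-up z minus baseline z.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LMSBlock",
    "LMSCoefficientTable",
    "ZScorePanel",
    "interpolate_lms",
    "lms_zscore",
    "lms_inverse",
    "zscore_change",
    "standardize_cohort",
    "METRICS",
    "Z_LEVEL_METRICS",
    "Z_CHANGE_METRICS",
]

#: Raw spirometry metrics, in the column-name form used throughout.
METRICS = ("FEV1", "FVC", "FEV1/FVC")
Z_LEVEL_METRICS = ("zFEV1", "zFVC", "zFEV1/FVC")
Z_CHANGE_METRICS = ("zFEV1-change", "zFVC-change", "zFEV1/FVC-change")

SEXES = ("M", "F")


@dataclass
class LMSBlock:
    """L/M/S coefficients for one (metric, sex) stratum on an age grid."""

    ages: np.ndarray
    L: np.ndarray
    M: np.ndarray
    S: np.ndarray
    reference_height_cm: float
    height_exponent: float

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.L = np.asarray(self.L, dtype=float)
        self.M = np.asarray(self.M, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        n = self.ages.size
        if not (self.L.size == self.M.size == self.S.size == n):
            raise ValueError("L, M, S and age arrays must have equal length")
        if n == 0:
            raise ValueError("empty LMS block")
        if n > 1 and not np.all(np.diff(self.ages) > 0):
            raise ValueError("age grid must be strictly increasing")
        if np.any(self.S <= 0):
            raise ValueError("S must be > 0 everywhere")
        if np.any(self.M <= 0):
            raise ValueError("M must be > 0 everywhere")
        if self.reference_height_cm <= 0:
            raise ValueError("reference height must be positive")


@dataclass
class LMSCoefficientTable:
    """Collection of LMS blocks keyed by (metric, sex).

    Serializes to a TSV with ``#``-prefixed per-block header lines
    (``#metric``, ``#sex``, ``#reference_height_cm``, ``#height_exponent``)
    followed by ``age  L  M  S`` columns.
    """

    blocks: dict[tuple[str, str], LMSBlock] = field(default_factory=dict)

    def block(self, metric: str, sex: str) -> LMSBlock:
        try:
            return self.blocks[(metric, sex)]
        except KeyError:
            raise KeyError(
                f"no LMS coefficients for metric={metric!r}, sex={sex!r}"
            ) from None

    def to_tsv(self, path) -> None:
        buf = io.StringIO()
        for (metric, sex), b in self.blocks.items():
            buf.write(f"#metric\t{metric}\n")
            buf.write(f"#sex\t{sex}\n")
            buf.write(f"#reference_height_cm\t{float(b.reference_height_cm)!r}\n")
            buf.write(f"#height_exponent\t{float(b.height_exponent)!r}\n")
            buf.write("age\tL\tM\tS\n")
            for a, l, m, s in zip(b.ages, b.L, b.M, b.S):
                buf.write(f"{float(a)!r}\t{float(l)!r}\t{float(m)!r}\t{float(s)!r}\n")
            buf.write("\n")
        with open(path, "w") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def from_tsv(cls, path) -> "LMSCoefficientTable":
        blocks: dict[tuple[str, str], LMSBlock] = {}
        header: dict[str, str] = {}
        rows: list[tuple[float, float, float, float]] = []

        def flush() -> None:
            if not rows:
                return
            arr = np.array(rows, dtype=float)
            key = (header["metric"], header["sex"])
            blocks[key] = LMSBlock(
                ages=arr[:, 0],
                L=arr[:, 1],
                M=arr[:, 2],
                S=arr[:, 3],
                reference_height_cm=float(header["reference_height_cm"]),
                height_exponent=float(header["height_exponent"]),
            )
            rows.clear()

        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                if line.startswith("#"):
                    key, _, value = line[1:].partition("\t")
                    if key == "metric" and rows:
                        flush()
                        header = {}
                    header[key] = value
                elif line.startswith("age\t"):
                    continue
                else:
                    parts = line.split("\t")
                    rows.append(tuple(float(x) for x in parts[:4]))
        flush()
        return cls(blocks)


def interpolate_lms(
    table: LMSCoefficientTable, metric: str, sex: str, age: float, height: float
) -> tuple[float, float, float]:
    """Interpolate (L, M, S) at ``age`` and scale M by height.

    L and S are linearly interpolated in age; M is interpolated then
    multiplied by ``(height / reference_height) ** height_exponent``.
    Ages outside the grid raise — no extrapolation.
    """
    b = table.block(metric, sex)
    if age < b.ages[0] or age > b.ages[-1]:
        raise ValueError(
            f"age {age} outside LMS grid [{b.ages[0]}, {b.ages[-1]}] "
            f"for metric={metric!r}, sex={sex!r}"
        )
    L = float(np.interp(age, b.ages, b.L))
    M = float(np.interp(age, b.ages, b.M))
    S = float(np.interp(age, b.ages, b.S))
    M *= (height / b.reference_height_cm) ** b.height_exponent
    return L, M, S


def lms_zscore(y, L, M, S):
    """z-score of measurement ``y`` under LMS parameters.

    Uses ``expm1(L * ln(y/M)) / (L*S)`` so the L -> 0 limit ``ln(y/M)/S``
    is reached continuously to full floating-point precision; ``L == 0``
    exactly takes the log form.
    """
    y = np.asarray(y, dtype=float)
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any(y <= 0):
        raise ValueError("measured value must be > 0")
    if np.any(M <= 0) or np.any(S <= 0):
        raise ValueError("M and S must be > 0")
    r = np.log(y / M)
    denom = L * S  # underflows for subnormal L: fall back to the log form
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(denom == 0, r / S, np.expm1(L * r) / denom)
    if z.ndim == 0:
        return float(z)
    return z


def lms_inverse(z, L, M, S):
    """Reconstruct the measurement from its z-score (closed-form inverse)."""
    z = np.asarray(z, dtype=float)
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    denom = L * S
    with np.errstate(divide="ignore", invalid="ignore"):
        y = np.where(denom == 0, M * np.exp(S * z),
                     M * np.exp(np.log1p(denom * z) / L))
    if y.ndim == 0:
        return float(y)
    return y


def zscore_change(z_baseline, z_followup):
    """Change score: follow-up z minus baseline z."""
    z_baseline = np.asarray(z_baseline, dtype=float)
    z_followup = np.asarray(z_followup, dtype=float)
    if not (np.all(np.isfinite(z_baseline)) and np.all(np.isfinite(z_followup))):
        raise ValueError("z-scores must be finite")
    out = z_followup - z_baseline
    if out.ndim == 0:
        return float(out)
    return out


#: Cohort columns holding raw spirometry, keyed by (metric, visit).
_RAW_COLS = {
    ("FEV1", "baseline"): "fev1_baseline_l",
    ("FEV1", "followup"): "fev1_followup_l",
    ("FVC", "baseline"): "fvc_baseline_l",
    ("FVC", "followup"): "fvc_followup_l",
}


@dataclass
class ZScorePanel:
    """Per-subject z-scores at both visits plus change scores.

    ``scores`` is indexed by subject_id with columns
    ``zFEV1_baseline``, ``zFEV1_followup``, ..., ``zFEV1-change``, ...
    """

    scores: pd.DataFrame

    def level(self, metric: str) -> pd.Series:
        """Follow-up z-score column for a level metric, e.g. ``zFEV1``."""
        if metric not in Z_LEVEL_METRICS:
            raise KeyError(f"not a level metric: {metric!r}")
        return self.scores[f"{metric}_followup"]

    def change(self, metric: str) -> pd.Series:
        if metric not in Z_CHANGE_METRICS:
            raise KeyError(f"not a change metric: {metric!r}")
        return self.scores[metric]

    def value(self, metric: str) -> pd.Series:
        """Analysis value for any of the six metrics."""
        if metric in Z_LEVEL_METRICS:
            return self.level(metric)
        return self.change(metric)

    def to_tsv(self, path) -> None:
        long = self.scores.reset_index().melt(
            id_vars="subject_id", var_name="score", value_name="z"
        )
        long.to_csv(path, sep="\t", index=False)


def _raw_value(cohort: pd.DataFrame, metric: str, visit: str) -> pd.Series:
    if metric == "FEV1/FVC":
        return (
            cohort[_RAW_COLS[("FEV1", visit)]] / cohort[_RAW_COLS[("FVC", visit)]]
        )
    return cohort[_RAW_COLS[(metric, visit)]]


def standardize_cohort(cohort: pd.DataFrame, table: LMSCoefficientTable) -> ZScorePanel:
    """Compute all six z-scores for every subject.

    Baseline z-scores use baseline age but follow-up height (the only
    objectively measured height).  The FEV1/FVC ratio is standardized from
    the measured ratio with its own coefficient rows, never as a ratio of
    z-scores.
    """
    missing = cohort.loc[
        cohort["height_followup_cm"].isna(), "subject_id"
    ].tolist()
    if missing:
        raise ValueError(f"missing follow-up height for subjects: {missing}")

    out = pd.DataFrame(index=pd.Index(cohort["subject_id"], name="subject_id"))
    age_col = {"baseline": "age_baseline", "followup": "age_followup"}
    for metric, zname in zip(METRICS, Z_LEVEL_METRICS):
        for visit in ("baseline", "followup"):
            y = _raw_value(cohort, metric, visit).to_numpy()
            z = np.empty(len(cohort))
            for i, (_, row) in enumerate(cohort.iterrows()):
                L, M, S = interpolate_lms(
                    table, metric, row["sex"], row[age_col[visit]],
                    row["height_followup_cm"],
                )
                z[i] = lms_zscore(y[i], L, M, S)
            out[f"{zname}_{visit}"] = z
    for zname, cname in zip(Z_LEVEL_METRICS, Z_CHANGE_METRICS):
        out[cname] = zscore_change(
            out[f"{zname}_baseline"].to_numpy(), out[f"{zname}_followup"].to_numpy()
        )
    return ZScorePanel(out)
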