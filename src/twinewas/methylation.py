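"""Probe QC filtering, beta/M transforms, and blood-cell deconvolution."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "MethylationDataset",
    "QCReport",
    "CellReferencePanel",
    "CellFractionTable",
    "BETA_CLIP",
    "clip_beta",
    "qc_filter",
    "beta_to_m",
    "m_to_beta",
    "estimate_cell_fractions",
    "fill_cell_fractions",
    "CELL_TYPES",
]

CELL_TYPES = ("monocytes", "lymphocytes", "basophils", "neutrophils", "eosinophils")

# beta of exactly 0/1 arises from rounding, not biology; clip before logit
BETA_CLIP = 1e-6

DETECTION_P_MAX = 0.01
MIN_BEADS = 3
MAX_FAIL_FRACTION = 0.05  # strict: removed iff failed fraction > 5%


@dataclass
class MethylationDataset:
    """450K-style beta matrix with per-measurement QC metadata.

    All matrices are probes x samples DataFrames sharing index and columns.
    ``manifest`` is indexed by probe_id with columns ``chromosome``, ``bp``,
    ``gene`` (NaN for intergenic) and ``cgi_feature``.
    """

    beta: pd.DataFrame
    detection_p: pd.DataFrame
    bead_count: pd.DataFrame
    manifest: pd.DataFrame
    blacklist: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.beta.index.is_unique:
            raise ValueError("probe IDs must be unique")
        for name in ("detection_p", "bead_count"):
            other = getattr(self, name)
            if other.shape != self.beta.shape:
                raise ValueError(f"{name} shape {other.shape} != beta {self.beta.shape}")
            if not (other.index.equals(self.beta.index)
                    and other.columns.equals(self.beta.columns)):
                raise ValueError(f"{name} index/columns do not match beta")
        vals = self.beta.to_numpy()
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")

    @property
    def n_probes(self) -> int:
        return self.beta.shape[0]

    @property
    def samples(self) -> list[str]:
        return list(self.beta.columns)


@dataclass
class QCReport:
    """Per-rule accounting of removed probes."""

    n_input: int
    removed_by_rule: dict[str, set]
    measurement_failures: dict[str, int]

    @property
    def removed(self) -> set:
        out: set = set()
        for s in self.removed_by_rule.values():
            out |= s
        return out

    @property
    def n_removed(self) -> int:
        return len(self.removed)

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"rule": rule, "n_probes_removed": len(probes)}
            for rule, probes in self.removed_by_rule.items()
        ]
        rows.append({"rule": "total_unique", "n_probes_removed": self.n_removed})
        return pd.DataFrame(rows)


def qc_filter(dataset: MethylationDataset) -> tuple[MethylationDataset, QCReport]:
    """Remove low-quality and blacklisted probes.

    A measurement fails if bead count < 3, detection p > 0.01, or signal is
    zero/missing (beta missing, or exactly 0 with zero beads).  A probe is
    removed if it fails in strictly more than 5% of samples, or if it is on
    the cross-reactive blacklist.
    """
    if dataset.detection_p.isna().any().any() or dataset.bead_count.isna().any().any():
        raise ValueError("QC metadata (detection p, bead counts) must be complete")

    beta = dataset.beta.to_numpy()
    detp = dataset.detection_p.to_numpy()
    beads = dataset.bead_count.to_numpy()

    low_beads = beads < MIN_BEADS
    high_detp = detp > DETECTION_P_MAX
    zero_signal = np.isnan(beta) | ((beta == 0) & (beads == 0))
    failed = low_beads | high_detp | zero_signal

    fail_frac = failed.mean(axis=1)
    probes = dataset.beta.index
    high_failure = set(probes[fail_frac > MAX_FAIL_FRACTION])
    blacklisted = set(probes) & set(dataset.blacklist)

    report = QCReport(
        n_input=dataset.n_probes,
        removed_by_rule={"blacklist": blacklisted, "high_failure": high_failure},
        measurement_failures={
            "low_bead_count": int(low_beads.sum()),
            "high_detection_p": int(high_detp.sum()),
            "zero_signal": int(zero_signal.sum()),
        },
    )
    keep = ~probes.isin(report.removed)
    filtered = MethylationDataset(
        beta=dataset.beta.loc[keep],
        detection_p=dataset.detection_p.loc[keep],
        bead_count=dataset.bead_count.loc[keep],
        manifest=dataset.manifest.loc[dataset.manifest.index.isin(probes[keep])],
        blacklist=set(dataset.blacklist),
    )
    return filtered, report


def clip_beta(beta):
    """Clip beta into [BETA_CLIP, 1 - BETA_CLIP] so the logit stays finite."""
    return np.clip(beta, BETA_CLIP, 1.0 - BETA_CLIP)


def beta_to_m(beta):
    """M-value: base-2 logit of beta, ``log2(beta / (1 - beta))``."""
    arr = np.asarray(beta, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("beta values must lie in [0, 1]")
    arr = clip_beta(arr)
    out = np.log2(arr / (1.0 - arr))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(out, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(out, index=beta.index)
    if out.ndim == 0:
        return float(out)
    return out


def m_to_beta(m):
    """Inverse M-value transform: ``2^M / (1 + 2^M)``."""
    arr = np.asarray(m, dtype=float)
    # exp-based sigmoid is stable at both tails
    out = 1.0 / (1.0 + np.exp2(-arr))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(out, index=m.index, columns=m.columns)
    if isinstance(m, pd.Series):
        return pd.Series(out, index=m.index)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class CellReferencePanel:
    """Reference beta profiles for the five leukocyte subtypes."""

    reference_betas: pd.DataFrame  # probes x cell types

    def __post_init__(self) -> None:
        missing = [c for c in CELL_TYPES if c not in self.reference_betas.columns]
        if missing:
            raise ValueError(f"panel missing cell types: {missing}")
        self.reference_betas = self.reference_betas[list(CELL_TYPES)]
        vals = self.reference_betas.to_numpy()
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError("reference betas must lie in [0, 1]")
        for i in range(len(CELL_TYPES)):
            for j in range(i + 1, len(CELL_TYPES)):
                if np.mean(np.abs(vals[:, i] - vals[:, j])) == 0:
                    raise ValueError(
                        f"reference columns {CELL_TYPES[i]} and {CELL_TYPES[j]} "
                        "are identical"
                    )

    def to_tsv(self, path) -> None:
        self.reference_betas.rename_axis("probe_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "CellReferencePanel":
        return cls(pd.read_csv(path, sep="\t", index_col="probe_id"))


def _solve_simplex_lsq(R: np.ndarray, b: np.ndarray) -> np.ndarray:
    """min ||R f - b||^2 s.t. f >= 0, sum f = 1 (small dense QP via SLSQP)."""
    k = R.shape[1]
    G = R.T @ R
    c = R.T @ b

    def obj(f):
        return 0.5 * f @ G @ f - c @ f

    def grad(f):
        return G @ f - c

    x0 = np.full(k, 1.0 / k)
    res = minimize(
        obj, x0, jac=grad, method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda f: f.sum() - 1.0,
                      "jac": lambda f: np.ones(k)}],
        options={"maxiter": 200, "ftol": 1e-12},
    )
    f = np.clip(res.x, 0.0, None)
    return f / f.sum()


def estimate_cell_fractions(sample_beta: pd.Series, panel: CellReferencePanel) -> pd.Series:
    """Deconvolve one sample's leukocyte fractions.

    Constrained projection: least squares of the sample's beta values onto
    the reference profiles subject to non-negativity and sum-to-one.
    """
    ref = panel.reference_betas
    common = ref.index.intersection(sample_beta.index)
    b = sample_beta.loc[common]
    usable = b.notna()
    common = common[usable.to_numpy()]
    for ct in CELL_TYPES:
        if ref.loc[common, ct].notna().sum() < 2:
            raise ValueError(
                f"fewer than 2 usable panel probes for cell type {ct!r}"
            )
    R = ref.loc[common].to_numpy()
    y = sample_beta.loc[common].to_numpy()
    f = _solve_simplex_lsq(R, y)
    return pd.Series(f, index=list(CELL_TYPES))


@dataclass
class CellFractionTable:
    """Per-sample leukocyte fractions plus their provenance flag."""

    fractions: pd.DataFrame  # samples x cell types
    source: pd.Series  # 'measured' | 'imputed'

    def __post_init__(self) -> None:
        vals = self.fractions[list(CELL_TYPES)].to_numpy()
        if np.any(vals < 0):
            raise ValueError("fractions must be >= 0")
        sums = vals.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("fractions must sum to 1 within 1e-6")
        if not self.source.index.equals(self.fractions.index):
            raise ValueError("source flags must align with fraction rows")

    def to_tsv(self, path) -> None:
        out = self.fractions.copy()
        out["source"] = self.source
        out.rename_axis("sample_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "CellFractionTable":
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
        return cls(df[list(CELL_TYPES)], df["source"])


def fill_cell_fractions(
    measured: pd.DataFrame | None,
    dataset: MethylationDataset,
    panel: CellReferencePanel,
) -> CellFractionTable:
    """Complete the cell-fraction table for every sample in the dataset.

    Measured rows (counts or fractions; rows are normalized to sum to one)
    pass through flagged ``measured``; samples absent from the measured
    table are deconvolved from their methylome and flagged ``imputed``.
    """
    samples = dataset.samples
    rows = {}
    flags = {}
    if measured is not None:
        measured = measured[list(CELL_TYPES)].dropna()
        norm = measured.div(measured.sum(axis=1), axis=0)
    else:
        norm = pd.DataFrame(columns=list(CELL_TYPES))
    for s in samples:
        if s in norm.index:
            rows[s] = norm.loc[s]
            flags[s] = "measured"
        else:
            rows[s] = estimate_cell_fractions(dataset.beta[s], panel)
            flags[s] = "imputed"
    fractions = pd.DataFrame.from_dict(rows, orient="index").loc[samples]
    source = pd.Series(flags).loc[samples]
    return CellFractionTable(fractions, source)
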