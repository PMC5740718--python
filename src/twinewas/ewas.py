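"""Mass univariate pair-difference regression with FDR control.

Each probe's intra-pair M-value difference is regressed on the transformed
lung-function difference plus covariates by ordinary least squares; the
reported estimate/se/t/p refer to the lung-function predictor coefficient.
Significance thresholds are strict: p < 1e-6 "significant", p < 1e-5
"reported in tables".  Direction labels describe the inferior twin relative
to the superior twin: a negative estimate means the inferior twin is
relatively hyper-methylated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import qr as _qr

from .twin_design import PairDesignTable, CELL_DIFF_COLS

__all__ = [
    "EwasRun",
    "SIGNIFICANT_P",
    "REPORT_P",
    "DESIGN_COLUMNS",
    "design_matrix",
    "fit_probe",
    "run_ewas",
    "bh_adjust",
    "genomic_inflation",
    "classify_direction",
    "select_hits",
    "annotate_hits",
    "manhattan_qq_tables",
]

SIGNIFICANT_P = 1e-6
REPORT_P = 1e-5

# neutrophils dropped: the five fraction differences sum to zero, so the
# largest fraction serves as the reference category
_CELL_COLS_IN_MODEL = tuple(c for c in CELL_DIFF_COLS if c != "d_neutrophils")
DESIGN_COLUMNS = (
    "intercept", "predictor", "sex", "age", "d_bmi", "d_pack_years",
    "d_smoking_status", *_CELL_COLS_IN_MODEL,
)

_RESULT_COLUMNS = [
    "probe_id", "estimate", "se", "t", "p", "fdr", "direction",
    "n_pairs", "metric", "flavour",
]


def design_matrix(design: PairDesignTable, covariates: bool = True) -> tuple[np.ndarray, list[str]]:
    """Covariate-adjusted design matrix [intercept, predictor, covariates]."""
    tab = design.table
    cols: list[str] = ["intercept", "predictor"]
    X = [np.ones(len(tab)), tab["predictor"].to_numpy()]
    if covariates:
        for c in DESIGN_COLUMNS[2:]:
            X.append(tab[c].to_numpy(dtype=float))
            cols.append(c)
    return np.column_stack(X), cols


def _check_rank(X: np.ndarray, names: list[str]) -> int:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # pivoted QR: columns past the rank are the collinear ones
        _, _, piv = _qr(X, mode="economic", pivoting=True)
        collinear = [names[j] for j in piv[rank:]]
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    return rank


def fit_probe(
    delta_m: np.ndarray, X: np.ndarray, names: list[str] | None = None,
    predictor_index: int = 1,
) -> tuple[float, float, float, float]:
    """OLS of one probe's pair differences on the design matrix.

    Returns ``(estimate, se, t, p)`` for the predictor column, with a
    two-sided p-value on ``n - rank`` degrees of freedom.  A numerically
    zero residual yields the ``p = 0`` sentinel with a warning.
    """
    y = np.asarray(delta_m, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if names is None:
        names = [f"x{j}" for j in range(k)]
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} pairs, got {n}")
    rank = _check_rank(X, list(names))

    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    df = n - rank
    xtx_inv = np.linalg.inv(X.T @ X)
    est = float(coef[predictor_index])
    tss = float(y @ y)
    if rss <= 1e-12 * max(tss, 1.0):
        warnings.warn("zero residual: perfect fit, p-value set to 0 sentinel")
        return est, 0.0, np.inf if est != 0 else 0.0, 0.0
    sigma2 = rss / df
    se = float(np.sqrt(sigma2 * xtx_inv[predictor_index, predictor_index]))
    t = est / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    return est, se, t, p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order.

    ``adj_(i) = min_{j >= i} p_(j) * n / j`` along the sorted p-values,
    capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(n)
    out[order] = adj_sorted
    return out


_CHI2_MEDIAN = stats.chi2.ppf(0.5, df=1)  # 0.4549...


def genomic_inflation(p_values) -> float:
    """Genomic inflation factor: median observed chi-square(1) quantile over
    the theoretical chi-square(1) median."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / _CHI2_MEDIAN)


def classify_direction(estimate: float) -> str:
    """Methylation direction of the inferior twin relative to the superior.

    ``estimate`` is (superior - inferior) per unit predictor, so a negative
    estimate means the inferior twin is relatively hyper-methylated.
    """
    if estimate < 0:
        return "Hyper"
    if estimate > 0:
        return "Hypo"
    return "undefined"


@dataclass
class EwasRun:
    """All per-probe results of one metric/flavour analysis."""

    results: pd.DataFrame
    metric: str
    flavour: str
    lambda_gc: float
    significant_p: float = SIGNIFICANT_P
    report_p: float = REPORT_P

    @property
    def n_tests(self) -> int:
        return len(self.results)


def run_ewas(
    delta_m: pd.DataFrame,
    design: PairDesignTable,
    covariates: bool = True,
) -> EwasRun:
    """Fit every probe against one pair design (vectorized OLS).

    The design matrix is shared across probes, so the hat matrix is formed
    once; per-probe coefficients, residual variances and t-tests follow from
    matrix products.  Results match :func:`fit_probe` probe by probe.
    """
    if not delta_m.columns.equals(design.table.index):
        raise ValueError("delta_m columns must align with design pair IDs")
    X, names = design_matrix(design, covariates=covariates)
    n, k = X.shape
    rank = _check_rank(X, names)
    df = n - rank

    Y = delta_m.to_numpy(dtype=float)  # probes x pairs
    xtx_inv = np.linalg.inv(X.T @ X)
    B = xtx_inv @ X.T  # k x n
    coef = Y @ B.T  # probes x k
    resid = Y - coef @ X.T
    rss = np.einsum("ij,ij->i", resid, resid)
    sigma2 = rss / df
    j = names.index("predictor")
    est = coef[:, j]
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2 * xtx_inv[j, j])
        t = np.where(se > 0, est / se, np.where(est == 0, 0.0, np.inf))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    # zero-residual sentinel
    degenerate = rss <= 1e-12 * np.maximum(np.einsum("ij,ij->i", Y, Y), 1.0)
    p = np.where(degenerate, 0.0, p)
    p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)
    p = np.where(degenerate, 0.0, p)

    fdr = bh_adjust(np.where(p == 0, np.nextafter(0.0, 1.0), p))
    results = pd.DataFrame({
        "probe_id": delta_m.index,
        "estimate": est,
        "se": se,
        "t": t,
        "p": p,
        "fdr": fdr,
        "direction": [classify_direction(e) for e in est],
        "n_pairs": n,
        "metric": design.metric,
        "flavour": design.flavour,
    })
    lam = genomic_inflation(np.where(p == 0, np.nextafter(0.0, 1.0), p))
    return EwasRun(results=results, metric=design.metric,
                   flavour=design.flavour, lambda_gc=lam)


def select_hits(run: EwasRun) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Strict-threshold hit lists: (p < 1e-6 significant, p < 1e-5 table)."""
    res = run.results
    significant = res[res["p"] < run.significant_p]
    table = res[res["p"] < run.report_p]
    return significant, table


def annotate_hits(rows: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Join manifest annotation (chromosome, bp, gene, CGI feature) onto
    result rows; pure join, row count preserved, idempotent."""
    missing = [p for p in rows["probe_id"] if p not in manifest.index]
    if missing:
        raise KeyError(f"probes absent from manifest: {missing}")
    out = rows.drop(columns=["chromosome", "bp", "gene", "cgi_feature"],
                    errors="ignore")
    ann = manifest.loc[out["probe_id"], ["chromosome", "bp", "gene", "cgi_feature"]]
    ann.index = out.index
    return pd.concat([out, ann], axis=1)


def _chrom_sort_key(chrom) -> tuple[int, str]:
    s = str(chrom)
    try:
        return (int(s), "")
    except ValueError:
        return (10_000, s)


def manhattan_qq_tables(
    run: EwasRun, manifest: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plot-ready data tables.

    Manhattan: (chromosome, bp, -log10 p) sorted by genome position.
    QQ: expected ``-log10((i - 0.5) / n)`` vs observed quantiles.
    """
    ann = annotate_hits(run.results, manifest)
    man = ann[["probe_id", "chromosome", "bp", "p"]].copy()
    man["neg_log10_p"] = -np.log10(man["p"].clip(lower=np.nextafter(0.0, 1.0)))
    man = man.drop(columns="p")
    man["_key"] = man["chromosome"].map(_chrom_sort_key)
    man = man.sort_values(["_key", "bp"], kind="mergesort").drop(columns="_key")
    man = man.reset_index(drop=True)

    n = run.n_tests
    obs = np.sort(run.results["p"].to_numpy())
    qq = pd.DataFrame({
        "expected_neg_log10_p": -np.log10((np.arange(1, n + 1) - 0.5) / n),
        "observed_neg_log10_p": -np.log10(np.clip(obs, np.nextafter(0.0, 1.0), 1.0)),
    })
    return man, qq
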