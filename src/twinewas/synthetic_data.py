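"""Synthetic twin-pair cohorts, methylomes, manifests and gene sets.

Generates data with the statistical structure the downstream analysis
assumes: monozygotic pairs sharing sex and age exactly, LMS-consistent
spirometry at two visits, bimodal beta distributions with a controllable
within-pair correlation, five-type leukocyte mixtures, smoking-discordant
pairs, and optional planted probe-level associations between intra-pair
methylation differences and intra-pair lung-function differences.  All
generators are deterministic given their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import standardization as stdz
from .methylation import (
    BETA_CLIP,
    CELL_TYPES,
    CellReferencePanel,
    MethylationDataset,
    beta_to_m,
    clip_beta,
    m_to_beta,
)
from .twin_design import LOG_METRICS
from .standardization import (
    LMSBlock,
    LMSCoefficientTable,
    METRICS,
    SEXES,
    Z_CHANGE_METRICS,
    Z_LEVEL_METRICS,
    lms_inverse,
    interpolate_lms,
    standardize_cohort,
)

__all__ = [
    "CohortConfig",
    "PlantedEffect",
    "generate_cohort",
    "generate_lms_table",
    "default_lms_table",
    "generate_manifest",
    "generate_cell_reference_panel",
    "generate_methylomes",
    "generate_genesets",
    "simulate_bundle",
    "PHENOTYPE_COLUMNS",
]

ALL_METRICS = Z_LEVEL_METRICS + Z_CHANGE_METRICS

PHENOTYPE_COLUMNS = [
    "subject_id", "pair_id", "sex",
    "age_baseline", "age_followup", "height_followup_cm",
    "weight_followup_kg", "bmi_baseline", "bmi_followup",
    "pack_years_total", "pack_years_followup_period", "smoking_status",
    "fev1_baseline_l", "fvc_baseline_l", "fev1_followup_l", "fvc_followup_l",
]


@dataclass
class CohortConfig:
    """Parameters of the synthetic twin cohort."""

    n_male_pairs: int = 86
    n_female_pairs: int = 83
    age_range: tuple[float, float] = (56.0, 79.0)
    followup_years: tuple[float, float, float] = (11.0, 9.6, 13.4)  # mean, min, max
    smoking_discordance: dict = field(
        default_factory=lambda: {"M": 14.0, "F": 8.0}
    )
    z_pair_correlation: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_male_pairs <= 0 or self.n_female_pairs <= 0:
            raise ValueError("pair counts must be > 0")
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError("age range min must be < max")
        mean, lo, hi = self.followup_years
        if not lo < mean < hi:
            raise ValueError("follow-up mean must lie within (min, max)")
        if not 0 <= self.z_pair_correlation < 1:
            raise ValueError("z_pair_correlation must be in [0, 1)")


@dataclass
class PlantedEffect:
    """A true probe-level association to inject into the methylomes.

    ``slope`` is the M-value difference added per unit transformed
    intra-pair z difference — exactly the coefficient the pair-difference
    regression estimates.
    """

    probe_id: str
    metric: str
    slope: float
    noise_sd: float | None = None

    def __post_init__(self) -> None:
        if self.metric not in ALL_METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")


# ---------------------------------------------------------------------------
# LMS coefficient tables

_LMS_SHAPES = {
    # metric -> (M0 by sex, M slope per year past 40, S0, height exponent)
    "FEV1": ({"M": 4.0, "F": 2.9}, -0.022, 0.13, 2.0),
    "FVC": ({"M": 5.1, "F": 3.7}, -0.020, 0.12, 2.0),
    "FEV1/FVC": ({"M": 0.82, "F": 0.83}, -0.0008, 0.07, 0.0),
}
_REFERENCE_HEIGHT = {"M": 174.0, "F": 162.0}


def generate_lms_table(
    metrics=METRICS,
    sex_levels=SEXES,
    age_grid=None,
    seed: int = 0,
) -> LMSCoefficientTable:
    """Smooth synthetic L/M/S curves on an age grid.

    The median M decreases with age and scales with height through the
    per-metric exponent; S is positive everywhere.  A small seeded
    perturbation varies the curves between seeds without breaking the
    shape constraints.
    """
    if age_grid is None:
        age_grid = np.arange(40.0, 86.0, 2.5)
    age_grid = np.asarray(age_grid, dtype=float)
    if age_grid.size == 0:
        raise ValueError("empty age grid")
    if age_grid.size > 1 and not np.all(np.diff(age_grid) > 0):
        raise ValueError("age grid must be strictly increasing")
    rng = np.random.default_rng(seed)
    blocks = {}
    for metric in metrics:
        m0_by_sex, m_slope, s0, h_exp = _LMS_SHAPES[metric]
        for sex in sex_levels:
            wiggle = 1.0 + 0.02 * rng.standard_normal()
            m0 = m0_by_sex[sex] * wiggle
            M = m0 * (1.0 + m_slope / m0_by_sex[sex] * (age_grid - 40.0))
            M = np.maximum(M, 0.05 * m0)
            L = 0.9 + 0.002 * (age_grid - 60.0) + 0.05 * rng.standard_normal()
            S = s0 * (1.0 + 0.002 * (age_grid - 40.0)) * (
                1.0 + 0.05 * abs(rng.standard_normal())
            )
            blocks[(metric, sex)] = LMSBlock(
                ages=age_grid.copy(), L=L, M=M, S=S,
                reference_height_cm=_REFERENCE_HEIGHT[sex],
                height_exponent=h_exp,
            )
    return LMSCoefficientTable(blocks)


def default_lms_table() -> LMSCoefficientTable:
    return generate_lms_table(seed=0)


# ---------------------------------------------------------------------------
# Cohort

_HEIGHT = {"M": (174.0, 6.5), "F": (161.9, 5.5)}
_BMI = {"M": (27.0, 3.2), "F": (25.5, 3.8)}
_PACK_YEAR_MEAN = {"M": 28.0, "F": 14.0}
_P_NEVER_PAIR = {"M": 0.30, "F": 0.45}


def generate_cohort(
    config: CohortConfig, lms_table: LMSCoefficientTable | None = None
) -> pd.DataFrame:
    """Generate the phenotype table for a cohort of MZ twin pairs.

    Within every pair sex and ages are identical.  True lung-function
    z-scores are drawn standard normal with within-pair correlation
    ``config.z_pair_correlation`` and inverted through the LMS table to raw
    spirometry, using follow-up height for both visits (the same convention
    the standardization applies), so re-standardizing recovers the z-scores.
    """
    if lms_table is None:
        lms_table = default_lms_table()
    rng = np.random.default_rng(config.seed)
    rows = []
    pair_counter = 0
    rho = config.z_pair_correlation
    for sex, n_pairs in (("M", config.n_male_pairs), ("F", config.n_female_pairs)):
        h_mu, h_sd = _HEIGHT[sex]
        b_mu, b_sd = _BMI[sex]
        disc = float(config.smoking_discordance.get(sex, 0.0))
        for _ in range(n_pairs):
            pair_counter += 1
            pair_id = f"P{pair_counter:04d}"
            age_fu = rng.uniform(*config.age_range)
            gap = rng.uniform(config.followup_years[1], config.followup_years[2])
            age_bl = age_fu - gap
            pair_height = rng.normal(h_mu, h_sd)

            # smoking: pair-shared base, discordance-controlled split
            never_pair = rng.random() < _P_NEVER_PAIR[sex]
            base_py = 0.0 if never_pair else rng.gamma(
                1.3, _PACK_YEAR_MEAN[sex] / 1.3
            )
            d = rng.normal(0.0, disc * np.sqrt(np.pi / 2.0)) if disc > 0 else 0.0
            py = np.maximum([base_py + d / 2.0, base_py - d / 2.0], 0.0)

            # true z-scores: shared pair factor + individual deviation
            u = rng.standard_normal(2)  # pair factor for FEV1, FVC
            twins = []
            for t in range(2):
                e = rng.standard_normal(2)
                z_fu = np.sqrt(rho) * u + np.sqrt(1.0 - rho) * e
                z_change = rng.normal(0.1, 0.7, size=2)
                z_bl = z_fu - z_change
                height = pair_height + rng.normal(0.0, 1.0)
                bmi_fu = rng.normal(b_mu, b_sd)
                bmi_bl = bmi_fu + rng.normal(-0.5, 1.0)
                twins.append((z_fu, z_bl, height, bmi_fu, bmi_bl))

            for t, suffix in enumerate("AB"):
                z_fu, z_bl, height, bmi_fu, bmi_bl = twins[t]
                pack_years = float(py[t])
                if pack_years == 0.0:
                    status = "never"
                    quit_years_ago = np.inf
                    # keep the rng stream aligned between twins
                    rng.random()
                    rng.uniform(0.0, 25.0)
                else:
                    still = rng.random() < 0.35
                    draw = rng.uniform(0.0, 25.0)
                    quit_years_ago = 0.0 if still else draw
                    # quit < 2 years prior counts as current
                    status = "current" if quit_years_ago < 2.0 else "non-current"
                if pack_years == 0.0 or quit_years_ago >= gap:
                    py_fu = 0.0
                else:
                    years_smoked = max(age_fu - 18.0 - quit_years_ago, 1.0)
                    py_fu = pack_years / years_smoked * (gap - quit_years_ago)
                raw = {}
                for metric, z_f, z_b in (
                    ("FEV1", z_fu[0], z_bl[0]),
                    ("FVC", z_fu[1], z_bl[1]),
                ):
                    L, M, S = interpolate_lms(lms_table, metric, sex, age_fu, height)
                    raw[f"{metric}_followup"] = lms_inverse(z_f, L, M, S)
                    L, M, S = interpolate_lms(lms_table, metric, sex, age_bl, height)
                    raw[f"{metric}_baseline"] = lms_inverse(z_b, L, M, S)
                rows.append({
                    "subject_id": f"{pair_id}{suffix}",
                    "pair_id": pair_id,
                    "sex": sex,
                    "age_baseline": age_bl,
                    "age_followup": age_fu,
                    "height_followup_cm": height,
                    "weight_followup_kg": bmi_fu * (height / 100.0) ** 2,
                    "bmi_baseline": bmi_bl,
                    "bmi_followup": bmi_fu,
                    "pack_years_total": pack_years,
                    "pack_years_followup_period": py_fu,
                    "smoking_status": status,
                    "fev1_baseline_l": raw["FEV1_baseline"],
                    "fvc_baseline_l": raw["FVC_baseline"],
                    "fev1_followup_l": raw["FEV1_followup"],
                    "fvc_followup_l": raw["FVC_followup"],
                })
    return pd.DataFrame(rows, columns=PHENOTYPE_COLUMNS)


# ---------------------------------------------------------------------------
# Manifest, reference panel, methylomes

_GENIC_CONTEXTS = ("TSS200", "TSS1500", "5'UTR", "1stExon", "Body", "3'UTR")
_ISLAND_CONTEXTS = ("island", "shore", "shelf", "open sea")


def generate_manifest(
    n_probes: int, n_genes: int, na_fraction: float, seed: int = 0
) -> pd.DataFrame:
    """Synthetic probe manifest: chromosome, hg19 bp, proximal gene (or NA
    at ``na_fraction``), CGI feature crossed with gene context."""
    if not 0 <= na_fraction < 1:
        raise ValueError("na_fraction must lie in [0, 1)")
    if n_genes == 0:
        raise ValueError("n_genes = 0 leaves no annotatable genes")
    rng = np.random.default_rng(seed)
    probe_ids = [f"cg{i:08d}" for i in range(n_probes)]
    genes = np.array([f"GENE{i:05d}" for i in range(n_genes)])
    chrom = rng.integers(1, 23, size=n_probes)
    bp = rng.integers(1, 250_000_000, size=n_probes)
    is_na = rng.random(n_probes) < na_fraction
    gene = np.where(is_na, None, rng.choice(genes, size=n_probes))
    islands = rng.choice(_ISLAND_CONTEXTS, size=n_probes)
    contexts = np.where(
        is_na, "IGR", rng.choice(_GENIC_CONTEXTS, size=n_probes)
    )
    manifest = pd.DataFrame({
        "chromosome": chrom,
        "bp": bp,
        "gene": gene,
        "cgi_feature": [f"{c}-{i}" for c, i in zip(contexts, islands)],
    }, index=pd.Index(probe_ids, name="probe_id"))
    return manifest


def generate_cell_reference_panel(probe_ids, seed: int = 0) -> CellReferencePanel:
    """Reference beta profiles per leukocyte subtype over all probes.

    Baseline betas are bimodal (mixture of low- and high-methylation Beta
    draws); per-cell-type logit-scale offsets make the columns distinct.
    """
    rng = np.random.default_rng(seed)
    n = len(probe_ids)
    low = rng.beta(2.0, 12.0, size=n)
    high = rng.beta(12.0, 2.0, size=n)
    base = np.where(rng.random(n) < 0.5, low, high)
    m_base = beta_to_m(clip_beta(base))
    ref = {}
    for j, ct in enumerate(CELL_TYPES):
        offsets = rng.normal(0.0, 0.8, size=n)
        ref[ct] = m_to_beta(m_base + offsets)
    return CellReferencePanel(
        pd.DataFrame(ref, index=pd.Index(probe_ids, name="probe_id"))
    )


_CELL_BASE = np.array([0.08, 0.30, 0.02, 0.55, 0.05])  # matches CELL_TYPES order


def generate_methylomes(
    cohort: pd.DataFrame,
    manifest: pd.DataFrame,
    planted: list[PlantedEffect],
    panel: CellReferencePanel,
    pair_correlation: float = 0.5,
    seed: int = 0,
    lms_table: LMSCoefficientTable | None = None,
    zpanel=None,
    noise_sd: float = 0.1,
    qc_fail_fraction: float = 0.002,
) -> tuple[MethylationDataset, pd.DataFrame]:
    """Generate the beta matrix, QC metadata and true cell fractions.

    Subject methylomes are cell-reference mixtures weighted by Dirichlet
    leukocyte fractions; a pair-shared random intercept on the M scale sets
    the within-pair correlation, and planted effects add
    ``slope * transformed_delta_z`` to the superior-minus-inferior M
    difference of their probe (split +/- half between the twins).
    Returns ``(dataset, true_fractions)``.
    """
    if not 0 <= pair_correlation < 1:
        raise ValueError("pair_correlation must be in [0, 1)")
    probes = manifest.index
    probe_pos = {p: i for i, p in enumerate(probes)}
    for eff in planted:
        if eff.probe_id not in probe_pos:
            raise KeyError(f"planted probe {eff.probe_id!r} absent from manifest")
    ref = panel.reference_betas.loc[probes].to_numpy()

    rng = np.random.default_rng(seed)
    subjects = list(cohort["subject_id"])
    n_sub = len(subjects)
    n_probes = len(probes)

    fractions = rng.dirichlet(_CELL_BASE * 200.0, size=n_sub)  # subjects x 5
    b_mix = ref @ fractions.T  # probes x subjects
    M = beta_to_m(clip_beta(b_mix))

    pairs = list(dict.fromkeys(cohort["pair_id"]))
    pair_of = dict(zip(cohort["subject_id"], cohort["pair_id"]))
    pair_col = {p: i for i, p in enumerate(pairs)}
    sub_pair_idx = np.array([pair_col[pair_of[s]] for s in subjects])

    sd_pair = noise_sd * np.sqrt(pair_correlation)
    sd_ind = noise_sd * np.sqrt(1.0 - pair_correlation)
    pair_effect = rng.normal(0.0, 1.0, size=(n_probes, len(pairs)))
    ind_effect = rng.normal(0.0, 1.0, size=(n_probes, n_sub))
    scale_pair = np.full(n_probes, sd_pair)
    scale_ind = np.full(n_probes, sd_ind)
    for eff in planted:
        if eff.noise_sd is not None:
            i = probe_pos[eff.probe_id]
            scale_pair[i] = eff.noise_sd * np.sqrt(pair_correlation)
            scale_ind[i] = eff.noise_sd * np.sqrt(1.0 - pair_correlation)
    M += pair_effect[:, sub_pair_idx] * scale_pair[:, None]
    M += ind_effect * scale_ind[:, None]

    if planted:
        if zpanel is None:
            if lms_table is None:
                lms_table = default_lms_table()
            zpanel = standardize_cohort(cohort, lms_table)
        sub_col = {s: j for j, s in enumerate(subjects)}
        by_pair = cohort.groupby("pair_id")["subject_id"].apply(list)
        for eff in planted:
            z = zpanel.value(eff.metric)
            i = probe_pos[eff.probe_id]
            for pid in pairs:
                a, b = by_pair[pid]
                za, zb = z[a], z[b]
                if za == zb:
                    continue
                sup, inf = (a, b) if za > zb else (b, a)
                delta = abs(za - zb)
                pred = np.log(delta) if eff.metric in LOG_METRICS else delta
                shift = eff.slope * pred / 2.0
                M[i, sub_col[sup]] += shift
                M[i, sub_col[inf]] -= shift

    beta = clip_beta(m_to_beta(M))

    detection_p = rng.uniform(0.0, 0.005, size=(n_probes, n_sub))
    bead_count = rng.poisson(12.0, size=(n_probes, n_sub)) + 4
    fail = rng.random((n_probes, n_sub)) < qc_fail_fraction
    fail_mode = rng.random((n_probes, n_sub)) < 0.5
    low_bead_draw = rng.integers(0, 3, size=(n_probes, n_sub))
    high_detp_draw = rng.uniform(0.011, 0.8, size=(n_probes, n_sub))
    bead_count = np.where(fail & fail_mode, low_bead_draw, bead_count)
    detection_p = np.where(fail & ~fail_mode, high_detp_draw, detection_p)

    cols = pd.Index(subjects, name="sample_id")
    dataset = MethylationDataset(
        beta=pd.DataFrame(beta, index=probes, columns=cols),
        detection_p=pd.DataFrame(detection_p, index=probes, columns=cols),
        bead_count=pd.DataFrame(bead_count, index=probes, columns=cols),
        manifest=manifest,
        blacklist=set(),
    )
    true_fractions = pd.DataFrame(fractions, index=cols, columns=list(CELL_TYPES))
    return dataset, true_fractions


# ---------------------------------------------------------------------------
# Gene sets


def generate_genesets(
    genes,
    n_sets: int,
    size_range: tuple[int, int] = (5, 40),
    seed: int = 0,
    spiked_genes=None,
) -> dict[str, list[str]]:
    """Random gene sets drawn from the universe, plus an optional spiked set
    concentrated on supplied (e.g. planted-effect) genes."""
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene universe")
    lo, hi = size_range
    if hi > len(genes):
        raise ValueError("size_range max exceeds number of genes")
    rng = np.random.default_rng(seed)
    sets: dict[str, list[str]] = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        sets[f"SET{i:03d}"] = sorted(members)
    if spiked_genes is not None:
        spiked = [g for g in spiked_genes if g in set(genes)]
        if spiked:
            sets["SPIKED"] = sorted(set(spiked))
    return sets


# ---------------------------------------------------------------------------
# Full input bundle on disk


def simulate_bundle(
    outdir,
    config: CohortConfig | None = None,
    n_probes: int = 2000,
    n_genes: int = 400,
    na_fraction: float = 0.2,
    n_planted: int = 0,
    planted_metric: str = "zFEV1",
    planted_slope: float = -0.05,
    pair_correlation: float = 0.5,
    n_gene_sets: int = 20,
    set_size_range: tuple[int, int] = (5, 40),
    qc_fail_fraction: float = 0.002,
    blacklist_fraction: float = 0.01,
    n_missing_cell_counts: int = 6,
) -> dict:
    """Write the complete synthetic input bundle and its truth sidecar.

    Files: phenotypes.tsv, lms.tsv, beta.tsv, detection_p.tsv,
    bead_count.tsv, manifest.tsv, blacklist.txt, cell_panel.tsv,
    cell_counts.tsv (with gaps to exercise imputation), genesets.gmt and
    truth.json.  Returns the truth dictionary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config is None:
        config = CohortConfig()
    seed = config.seed
    lms_table = generate_lms_table(seed=seed)
    cohort = generate_cohort(config, lms_table)
    manifest = generate_manifest(n_probes, n_genes, na_fraction, seed=seed + 1)
    panel = generate_cell_reference_panel(manifest.index, seed=seed + 2)

    rng = np.random.default_rng(seed + 3)
    annotated = manifest[manifest["gene"].notna()]
    planted: list[PlantedEffect] = []
    if n_planted > 0:
        chosen = rng.choice(annotated.index.to_numpy(), size=n_planted, replace=False)
        planted = [
            PlantedEffect(probe_id=p, metric=planted_metric, slope=planted_slope)
            for p in chosen
        ]
    dataset, true_fractions = generate_methylomes(
        cohort, manifest, planted, panel,
        pair_correlation=pair_correlation, seed=seed + 4,
        lms_table=lms_table, qc_fail_fraction=qc_fail_fraction,
    )

    # blacklist drawn from non-planted probes so planted effects survive QC
    planted_ids = {e.probe_id for e in planted}
    eligible = [p for p in manifest.index if p not in planted_ids]
    n_black = int(round(blacklist_fraction * n_probes))
    blacklist = sorted(rng.choice(eligible, size=n_black, replace=False)) if n_black else []

    planted_genes = sorted(
        {manifest.loc[e.probe_id, "gene"] for e in planted
         if pd.notna(manifest.loc[e.probe_id, "gene"])}
    )
    universe = sorted(set(annotated["gene"]))
    hi = min(set_size_range[1], len(universe))
    set_size_range = (min(set_size_range[0], hi), hi)
    sets = generate_genesets(
        universe, n_gene_sets, set_size_range, seed=seed + 5,
        spiked_genes=planted_genes or None,
    )

    # measured cell counts (scaled fractions) with gaps for imputation
    counts = (true_fractions * 7.0e9).copy()
    if n_missing_cell_counts:
        missing = list(true_fractions.index[:n_missing_cell_counts])
        counts = counts.drop(index=missing)
    else:
        missing = []

    cohort.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)
    lms_table.to_tsv(outdir / "lms.tsv")
    dataset.beta.rename_axis("probe_id").to_csv(outdir / "beta.tsv", sep="\t")
    dataset.detection_p.rename_axis("probe_id").to_csv(
        outdir / "detection_p.tsv", sep="\t")
    dataset.bead_count.rename_axis("probe_id").to_csv(
        outdir / "bead_count.tsv", sep="\t")
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", na_rep="NA")
    (outdir / "blacklist.txt").write_text("".join(f"{p}\n" for p in blacklist))
    panel.to_tsv(outdir / "cell_panel.tsv")
    counts.rename_axis("sample_id").to_csv(outdir / "cell_counts.tsv", sep="\t")
    from .enrichment import write_gmt
    write_gmt(outdir / "genesets.gmt", sets)

    truth = {
        "seed": seed,
        "n_pairs": config.n_male_pairs + config.n_female_pairs,
        "planted": [
            {"probe_id": e.probe_id, "metric": e.metric, "slope": e.slope}
            for e in planted
        ],
        "planted_genes": planted_genes,
        "blacklist_size": len(blacklist),
        "missing_cell_counts": missing,
        "pair_correlation": pair_correlation,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return truth
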