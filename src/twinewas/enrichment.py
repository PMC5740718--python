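"""Hypergeometric over-representation analysis against an array-restricted
gene universe.

For a hit list of k genes drawn from a universe of N array genes, each gene
set contributes C = |set ∩ universe| reference genes, overlaps the hits in
O genes, has expected overlap E = k*C/N, enrichment ratio R = O/E, and an
upper-tail hypergeometric rawP = P(X >= O); adjP is BH across the sets of
one database.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ewas import bh_adjust

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "probes_to_genes",
    "ora_test",
    "run_enrichment",
]

ENRICHMENT_COLUMNS = ["pathway", "genes", "C", "O", "E", "R", "rawP", "adjP",
                      "flagged", "significant"]


@dataclass
class GeneSetCollection:
    """Named gene sets plus the gene universe they are tested against.

    Set members outside the universe are ignored when computing C and O;
    effective membership is always intersected with the universe.
    """

    sets: dict[str, list[str]]
    universe: set
    descriptions: dict[str, str] = field(default_factory=dict)

    def effective(self, name: str) -> set:
        return set(self.sets[name]) & self.universe


def read_gmt(path) -> tuple[dict[str, list[str]], dict[str, str]]:
    """Parse a GMT file into (sets, descriptions)."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed GMT line: {line!r}")
            name, desc, members = fields[0], fields[1], fields[2:]
            sets[name] = [g for g in members if g]
            descriptions[name] = desc
    return sets, descriptions


def write_gmt(path, sets: dict[str, list[str]], descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def probes_to_genes(hit_rows: pd.DataFrame, manifest: pd.DataFrame) -> list[str]:
    """Unique proximal genes of annotated hit probes, intergenic dropped.

    Order of first appearance is preserved (deterministic given row order).
    """
    if "gene" in hit_rows.columns:
        genes = hit_rows["gene"]
    else:
        genes = manifest.loc[hit_rows["probe_id"], "gene"]
    out: list[str] = []
    seen = set()
    for g in genes:
        if pd.isna(g) or g == "NA" or g == "":
            continue
        if g not in seen:
            seen.add(g)
            out.append(g)
    return out


def ora_test(hit_genes, category_genes, universe) -> dict:
    """One gene set's over-representation statistics (without adjP).

    rawP is the upper-tail hypergeometric probability of drawing at least O
    category genes when k hits are drawn from the N-gene universe containing
    C category genes; O = 0 returns rawP = 1 by convention.
    """
    universe = set(universe)
    N = len(universe)
    if N == 0:
        raise ValueError("empty universe")
    hits = set(hit_genes)
    outside = hits - universe
    if outside:
        raise ValueError(f"hit genes outside universe: {sorted(outside)}")
    k = len(hits)
    cat = set(category_genes) & universe
    C = len(cat)
    overlap = sorted(cat & hits)
    O = len(overlap)
    E = k * C / N
    R = O / E if E > 0 else 0.0
    if O == 0:
        rawP = 1.0
    else:
        rawP = float(stats.hypergeom.sf(O - 1, N, C, k))
        rawP = min(rawP, 1.0)
    return {"C": C, "O": O, "E": E, "R": R, "rawP": rawP,
            "genes": ";".join(overlap)}


def run_enrichment(
    hit_genes,
    collection: GeneSetCollection,
    min_category_size: int = 2,
) -> pd.DataFrame:
    """Test every gene set of one database and BH-adjust across them.

    Sets with fewer than ``min_category_size`` universe members are skipped.
    Rows are sorted by rawP; ``flagged`` marks adjP < 0.1 and
    ``significant`` marks adjP < 0.05.
    """
    if not collection.sets:
        raise ValueError("empty gene set collection")
    hit_genes = list(hit_genes)
    if not hit_genes:
        warnings.warn("empty hit gene list: no enrichment rows")
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    rows = []
    for name, members in collection.sets.items():
        eff = collection.effective(name)
        if len(eff) < max(1, min_category_size):
            continue
        stats_row = ora_test(hit_genes, eff, collection.universe)
        rows.append({"pathway": name, **stats_row})
    if not rows:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    df = pd.DataFrame(rows)
    df["adjP"] = bh_adjust(df["rawP"].to_numpy())
    df["flagged"] = df["adjP"] < 0.1
    df["significant"] = df["adjP"] < 0.05
    df = df.sort_values("rawP", kind="mergesort").reset_index(drop=True)
    return df[ENRICHMENT_COLUMNS]
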