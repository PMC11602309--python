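"""Whole-panel cross enumeration, group summaries and two-trait strategies.

Every unordered pair of accessions is a candidate cross; its recombination
potential per trait is the 95th percentile of the simulated progeny
genotypic-value distribution (module :mod:`soycross.crossim`).  Crosses are
summarised within and between subpopulation (maturity-group) sets, and three
strategies pick 10 crosses improving two traits simultaneously:

* *A-first*: top ``pool`` (100) crosses by trait A, re-ranked by trait B,
  keep ``final`` (10);
* *B-first*: the mirror image;
* *balance*: intersect the top ``pool`` (2000) sets of both traits and keep
  the ``final`` crosses of smallest within-trait rank sum.

All sorts are stable with documented tie-breaks, so results are reproducible
under a fixed master seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .allelematrix import QTLAlleleMatrix
from .crossim import cross_potential, percentile, predict_values, qtl_loci, simulate_progeny, _cross_rng, _parent_alleles
from .iokit import GeneticMap

__all__ = [
    "CrossCatalogue",
    "StrategyResult",
    "all_pairs",
    "enumerate_crosses",
    "group_summary",
    "strategy_first",
    "strategy_balance",
]


@dataclass
class CrossCatalogue:
    """All unordered parent pairs with per-trait 95th-percentile predictions.

    ``table`` columns: p1, p2, pair_id, group1, group2, p95_<traitA>,
    p95_<traitB>, parent values per trait.  Pair count is n(n-1)/2.
    """

    table: pd.DataFrame
    trait_a: str
    trait_b: str

    @property
    def n_crosses(self) -> int:
        return len(self.table)

    def p95(self, trait: str) -> pd.Series:
        return self.table[f"p95_{trait}"]


@dataclass
class StrategyResult:
    strategy: str
    pool: int
    final: int
    selected: pd.DataFrame  # catalogue rows in selection order

    def mean_p95(self, trait: str) -> float:
        return float(self.selected[f"p95_{trait}"].mean())


def all_pairs(accessions: list[str]) -> list[tuple[str, str]]:
    """All n(n-1)/2 unordered parent pairs, in lexicographic order."""
    return list(combinations(sorted(accessions), 2))


def enumerate_crosses(
    matrix_a: QTLAlleleMatrix,
    matrix_b: QTLAlleleMatrix | None,
    gmap: GeneticMap | None = None,
    groups: pd.Series | None = None,
    n_progeny: int = 2000,
    p: int = 95,
    seed: int = 0,
    accessions: list[str] | None = None,
) -> CrossCatalogue:
    """Simulate every pairwise cross and record per-trait p95 potentials.

    When two trait matrices are given they must share the accession panel;
    each cross is simulated once over the union of both traits' QTL loci, so
    the two traits' predictions come from the same progeny population.
    Deterministic under ``seed`` and independent of pair order (per-cross
    streams are keyed by the sorted parent names).
    """
    acc = accessions if accessions is not None else matrix_a.accession_ids
    if matrix_b is not None and set(matrix_b.accession_ids) != set(matrix_a.accession_ids):
        raise ValueError("trait matrices cover different accession panels")

    matrices = [matrix_a] + ([matrix_b] if matrix_b is not None else [])
    loci_union: dict[str, list[tuple[str, float]]] = {}
    for mat in matrices:
        for chrom, items in qtl_loci(mat, gmap).items():
            loci_union.setdefault(chrom, []).extend(items)
    for chrom in loci_union:
        loci_union[chrom] = sorted(set(loci_union[chrom]), key=lambda t: (t[1], t[0]))

    parent_alleles = {
        a: {
            **{qid: m.alleles.at[a, qid] for m in matrices for qid in m.alleles.columns},
        }
        for a in acc
    }
    parent_values = {m.trait: m.predicted_values() for m in matrices}

    rows = []
    for p1, p2 in all_pairs(acc):
        rng = _cross_rng(seed, p1, p2)
        progeny = simulate_progeny(parent_alleles[p1], parent_alleles[p2], loci_union, n_progeny, rng)
        row = {
            "p1": p1,
            "p2": p2,
            "pair_id": f"{p1}x{p2}",
            "group1": groups.get(p1) if groups is not None else "",
            "group2": groups.get(p2) if groups is not None else "",
        }
        for mat in matrices:
            values = predict_values(progeny[list(mat.alleles.columns)], mat)
            row[f"p95_{mat.trait}"] = percentile(values, p)
            row[f"parent1_{mat.trait}"] = float(parent_values[mat.trait].loc[p1])
            row[f"parent2_{mat.trait}"] = float(parent_values[mat.trait].loc[p2])
        rows.append(row)
    table = pd.DataFrame(rows)
    trait_b = matrix_b.trait if matrix_b is not None else matrix_a.trait
    return CrossCatalogue(table=table, trait_a=matrix_a.trait, trait_b=trait_b)


def group_summary(
    catalogue: CrossCatalogue,
    contrasts: list[tuple[set[str], set[str]]],
) -> pd.DataFrame:
    """Per-contrast (N, min, max, mean) of the p95 potentials per trait.

    A contrast of a set with itself summarises within-group crosses (both
    parents in the set); two disjoint sets summarise between-group crosses
    (one parent in each).  Overlapping distinct sets are an error.
    """
    t = catalogue.table
    traits = sorted({c.removeprefix("p95_") for c in t.columns if c.startswith("p95_")})
    rows = []
    for left, right in contrasts:
        if left == right:
            mask = t["group1"].isin(left) & t["group2"].isin(left)
            label = f"within {'+'.join(sorted(left))}"
        else:
            if left & right:
                raise ValueError(f"overlapping sets in between-contrast: {left & right}")
            mask = (t["group1"].isin(left) & t["group2"].isin(right)) | (
                t["group1"].isin(right) & t["group2"].isin(left)
            )
            label = f"{'+'.join(sorted(left))} x {'+'.join(sorted(right))}"
        sub = t[mask]
        row = {"contrast": label, "N": len(sub)}
        for trait in traits:
            col = sub[f"p95_{trait}"]
            row[f"{trait}_min"] = float(col.min()) if len(sub) else float("nan")
            row[f"{trait}_max"] = float(col.max()) if len(sub) else float("nan")
            row[f"{trait}_mean"] = float(col.mean()) if len(sub) else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def _ranked(t: pd.DataFrame, primary: str, secondary: str) -> pd.DataFrame:
    return t.sort_values(
        by=[f"p95_{primary}", f"p95_{secondary}", "pair_id"],
        ascending=[False, False, True],
        kind="stable",
    )


def strategy_first(
    catalogue: CrossCatalogue,
    primary_trait: str,
    secondary_trait: str,
    pool: int = 100,
    final: int = 10,
) -> StrategyResult:
    """Primary-trait-first selection: top ``pool`` by primary p95, then the
    top ``final`` of those by secondary p95."""
    t = catalogue.table
    if pool > len(t):
        warnings.warn(f"pool {pool} exceeds catalogue size {len(t)}; clamped")
        pool = len(t)
    shortlist = _ranked(t, primary_trait, secondary_trait).head(pool)
    selected = _ranked(shortlist, secondary_trait, primary_trait).head(final)
    return StrategyResult(
        strategy=f"{primary_trait}_first", pool=pool, final=final,
        selected=selected.reset_index(drop=True),
    )


def strategy_balance(
    catalogue: CrossCatalogue,
    trait_a: str,
    trait_b: str,
    pool: int = 2000,
    final: int = 10,
) -> StrategyResult:
    """Balanced selection: crosses common to both traits' top ``pool`` lists,
    ordered by the sum of their within-trait ranks (ties: better trait-B
    rank, then pair id)."""
    t = catalogue.table
    pool = min(pool, len(t))
    rank_a = {pid: i for i, pid in enumerate(_ranked(t, trait_a, trait_b)["pair_id"])}
    rank_b = {pid: i for i, pid in enumerate(_ranked(t, trait_b, trait_a)["pair_id"])}
    top_a = {pid for pid, r in rank_a.items() if r < pool}
    top_b = {pid for pid, r in rank_b.items() if r < pool}
    common = top_a & top_b
    if len(common) < final:
        warnings.warn(
            f"only {len(common)} crosses common to both top-{pool} lists (< {final})"
        )
    order = sorted(common, key=lambda pid: (rank_a[pid] + rank_b[pid], rank_b[pid], pid))
    chosen = order[:final]
    selected = t.set_index("pair_id").loc[chosen].reset_index()
    return StrategyResult(
        strategy="balance", pool=pool, final=final, selected=selected
    )
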