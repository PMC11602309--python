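"""QTL-allele matrix assembly, allele dynamics across subpopulations, and the
candidate-gene interval screen.

The QTL-allele matrix is the compact genetic constitution of a panel for one
trait: rows are detected QTLs, columns are accessions, cells are the signed
additive effect of the allele (block haplotype) each accession carries.
Because effects are in frequency-weighted sum-to-zero coding, an accession's
predicted genotypic value is the population mean plus its column sum.

Allele dynamics compares sub-panels (e.g. early vs late maturity groups):
an allele present in both groups is *inherited*, present only in the early
group *emerged*, present only in the late group *excluded* — each split by
effect sign (effect >= 0 counts as positive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .iokit import GeneAnnotation, GenotypePanel
from .rtmgwas import QTLRecord, ScanResult
from .snpldb import SNPLDBSet

__all__ = [
    "QTLAlleleMatrix",
    "AlleleDynamics",
    "build_matrix",
    "allele_dynamics",
    "genes_near_qtl",
    "gene_block_association",
]


@dataclass
class QTLAlleleMatrix:
    """Accession x QTL allele (haplotype) and effect tables for one trait.

    ``alleles``: DataFrame (accessions x qtl_ids) of haplotype strings;
    ``effects``: same shape, the corresponding signed effects in trait units.
    """

    trait: str
    population_mean: float
    qtls: list[QTLRecord]
    alleles: pd.DataFrame
    effects: pd.DataFrame

    @property
    def accession_ids(self) -> list[str]:
        return list(self.alleles.index)

    def predicted_values(self) -> pd.Series:
        """Population mean + row sum of allele effects, per accession."""
        return self.population_mean + self.effects.sum(axis=1)

    def subset(self, accessions: list[str]) -> "QTLAlleleMatrix":
        """Sub-matrix for a subset of accessions (e.g. one maturity group)."""
        missing = [a for a in accessions if a not in self.alleles.index]
        if missing:
            raise ValueError(f"accessions not in matrix: {missing[:3]}")
        return QTLAlleleMatrix(
            trait=self.trait,
            population_mean=self.population_mean,
            qtls=self.qtls,
            alleles=self.alleles.loc[accessions],
            effects=self.effects.loc[accessions],
        )

    def to_frame(self) -> pd.DataFrame:
        """Matrix TSV layout: rows = QTLs sorted by rising positive-allele
        frequency, columns = accessions, cells = signed effects."""
        pos_freq = {}
        for q in self.qtls:
            pos_freq[q.qtl_id] = sum(
                f for h, f in q.allele_freqs.items() if q.allele_effects.get(h, 0.0) >= 0
            )
        order = sorted(pos_freq, key=lambda q: (pos_freq[q], q))
        return self.effects[order].T

    @classmethod
    def from_frames(
        cls,
        trait: str,
        population_mean: float,
        qtls: list[QTLRecord],
        alleles: pd.DataFrame,
    ) -> "QTLAlleleMatrix":
        effect_lookup = {q.qtl_id: q.allele_effects for q in qtls}
        effects = alleles.copy()
        for qid in alleles.columns:
            effects[qid] = alleles[qid].map(effect_lookup[qid])
        return cls(trait, population_mean, qtls, alleles, effects.astype(float))


@dataclass
class AlleleDynamics:
    """Allele accounting for one group contrast (early vs late sub-panels).

    Counts are (negative, positive) pairs split by effect sign.  Identities:
    inherited + emerged = early-group total; inherited + excluded =
    late-group total.
    """

    contrast: str
    early_total: tuple[int, int]
    late_total: tuple[int, int]
    inherited: tuple[int, int]
    emerged: tuple[int, int]
    excluded: tuple[int, int]

    def as_row(self) -> dict:
        def split(name, pair):
            return {f"{name}_neg": pair[0], f"{name}_pos": pair[1], f"{name}_total": sum(pair)}

        row = {"contrast": self.contrast}
        for name, pair in [
            ("early", self.early_total),
            ("late", self.late_total),
            ("inherited", self.inherited),
            ("emerged", self.emerged),
            ("excluded", self.excluded),
        ]:
            row.update(split(name, pair))
        return row


def build_matrix(
    scan: ScanResult, snpldb_set: SNPLDBSet, pheno_means: pd.Series
) -> QTLAlleleMatrix:
    """Assemble the QTL-allele matrix from a completed scan.

    Only main-effect QTLs (classification ``main_only``/``both``) carry
    per-accession effects; interaction-only QTLs have no main allele effects
    and are excluded from the matrix.
    """
    main_qtls = [q for q in scan.qtls if q.classification != "qei_only"]
    acc = snpldb_set.accession_ids
    allele_cols = {}
    for q in main_qtls:
        j = q.block_index
        block = snpldb_set.blocks[j]
        assign = snpldb_set.assignment[:, j]
        haps = [block.haplotypes[a] for a in assign]
        unknown = [h for h in set(haps) if h not in q.allele_effects]
        if unknown:
            raise ValueError(f"accession carries haplotype outside {q.qtl_id} catalogue: {unknown}")
        allele_cols[q.qtl_id] = haps
    alleles = pd.DataFrame(allele_cols, index=acc)
    mean = float(pheno_means.reindex(acc).mean())
    return QTLAlleleMatrix.from_frames(scan.trait, mean, main_qtls, alleles)


def _group_alleles(matrix: QTLAlleleMatrix, accessions: list[str]) -> set[tuple[str, str]]:
    """Set of (qtl_id, haplotype) alleles carried by >= 1 accession of the group."""
    sub = matrix.alleles.loc[accessions]
    out = set()
    for qid in sub.columns:
        for h in sub[qid].unique():
            out.add((qid, h))
    return out


def _sign_split(matrix: QTLAlleleMatrix, alleles: set[tuple[str, str]]) -> tuple[int, int]:
    effect = {q.qtl_id: q.allele_effects for q in matrix.qtls}
    neg = sum(1 for qid, h in alleles if effect[qid][h] < 0)
    pos = sum(1 for qid, h in alleles if effect[qid][h] >= 0)
    return neg, pos


def allele_dynamics(
    matrix: QTLAlleleMatrix,
    groups: pd.Series,
    early: set[str],
    late: set[str],
    contrast: str | None = None,
) -> AlleleDynamics:
    """Account alleles of the early group against the late group.

    ``groups`` maps accession -> group label; ``early``/``late`` are sets of
    labels.  An allele is present in a side iff at least one accession of
    that side carries it.  Inherited = in both; emerged = early only;
    excluded = late only.
    """
    early_acc = [a for a in matrix.accession_ids if groups.get(a) in early]
    late_acc = [a for a in matrix.accession_ids if groups.get(a) in late]
    if not early_acc or not late_acc:
        raise ValueError("empty group in dynamics contrast")
    a_early = _group_alleles(matrix, early_acc)
    a_late = _group_alleles(matrix, late_acc)
    label = contrast or f"{'+'.join(sorted(early))} vs {'+'.join(sorted(late))}"
    return AlleleDynamics(
        contrast=label,
        early_total=_sign_split(matrix, a_early),
        late_total=_sign_split(matrix, a_late),
        inherited=_sign_split(matrix, a_early & a_late),
        emerged=_sign_split(matrix, a_early - a_late),
        excluded=_sign_split(matrix, a_late - a_early),
    )


def genes_near_qtl(
    qtl: QTLRecord,
    annotation: GeneAnnotation,
    snpldb_set: SNPLDBSet,
    flank: int = 50_000,
) -> pd.DataFrame:
    """Genes whose [start, end] intersects the QTL block ± ``flank`` bp.

    Both interval ends are closed: a gene touching block_end + flank exactly
    is included.
    """
    block = snpldb_set.blocks[qtl.block_index]
    lo = block.start_bp - flank
    hi = block.end_bp + flank
    df = annotation.data
    hit = (
        (df["chromosome"] == block.chromosome)
        & (df["end"] >= lo)
        & (df["start"] <= hi)
    )
    return df[hit].reset_index(drop=True)


def gene_block_association(
    panel: GenotypePanel,
    snpldb_set: SNPLDBSet,
    block_id: str,
    gene: pd.Series,
    alpha: float = 0.05,
) -> dict:
    """Chi-square screen of a candidate gene against a QTL block.

    For every SNP inside the gene body, test independence of the block
    haplotype assignment and the SNP genotype with a Pearson chi-square (no
    continuity correction).  The gene is flagged significant if any in-gene
    SNP rejects at ``alpha``.  Returns
    ``{"testable", "significant", "min_p", "per_snp"}``; a gene with no
    in-gene SNP is untestable.
    """
    j = snpldb_set.block_index()[block_id]
    assign = snpldb_set.assignment[:, j]
    mk = panel.markers
    in_gene = (
        (mk["chromosome"] == gene["chromosome"])
        & (mk["pos_bp"] >= gene["start"])
        & (mk["pos_bp"] <= gene["end"])
    )
    idx = np.nonzero(in_gene.to_numpy())[0]
    if len(idx) == 0:
        return {"testable": False, "significant": False, "min_p": float("nan"), "per_snp": []}
    per_snp = []
    for m in idx:
        calls = panel.calls[:, m]
        ok = calls >= 0
        table = pd.crosstab(assign[ok], calls[ok]).to_numpy()
        table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
        if table.shape[0] < 2 or table.shape[1] < 2:
            continue
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        per_snp.append({"marker_id": mk.loc[m, "marker_id"], "chi2": float(chi2), "p": float(p)})
    if not per_snp:
        return {"testable": False, "significant": False, "min_p": float("nan"), "per_snp": []}
    min_p = min(s["p"] for s in per_snp)
    return {
        "testable": True,
        "significant": min_p <= alpha,
        "min_p": min_p,
        "per_snp": per_snp,
    }
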