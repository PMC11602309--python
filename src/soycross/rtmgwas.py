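"""Restricted two-stage multi-locus association scan on SNPLDB markers.

The scan treats each SNPLDB as one multi-allelic marker whose haplotypes are
the alleles, and proceeds in two stages on accession means:

1. a single-locus prescan — per block, the F-test of the haplotype term in an
   OLS model containing an intercept and the top eigenvectors of the genetic
   similarity matrix (population-structure correction); blocks with
   p <= alpha1 survive;
2. multi-locus stepwise regression over the survivors — forward addition by
   smallest partial-F p (<= alpha2), backward elimination of members whose
   partial p rises above alpha2, with the total explained variance of the
   marker terms capped by the trait's heritability ("restricted": the QTL
   system cannot claim more variance than is heritable).

Allele effects are reported in frequency-weighted sum-to-zero coding, so a
line's genotypic value is the population mean plus the sum of its allele
effects — the form the cross-simulation consumes.

QTL x environment classification is a separate plot-level pass: each selected
QTL gets a marker-by-environment interaction F-test, and stage-1 survivors
outside the main model can enter through their interaction term alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .iokit import PhenotypeTable
from .snpldb import SNPLDBSet

__all__ = [
    "StructureCovariates",
    "QTLRecord",
    "ScanResult",
    "similarity_matrix",
    "similarity_eigenvectors",
    "stage1_scan",
    "stage2_stepwise",
    "classify_qei",
]


@dataclass
class StructureCovariates:
    """Top eigenvectors of the accession genetic-similarity matrix."""

    eigenvectors: np.ndarray  # (n_accessions, k), ordered by falling eigenvalue
    eigenvalues: np.ndarray

    @property
    def k(self) -> int:
        return self.eigenvectors.shape[1]


@dataclass
class QTLRecord:
    """One detected QTL (an associated SNPLDB) and its allele system."""

    qtl_id: str
    block_id: str
    chromosome: str
    position_bp: int
    main_R2: float  # % of phenotypic variance (accession means)
    p_main: float
    allele_effects: dict[str, float]  # haplotype string -> effect, trait units
    allele_freqs: dict[str, float]
    qei_R2: float = float("nan")
    p_qei: float = float("nan")
    classification: str = "main_only"  # main_only | qei_only | both
    block_index: int = -1


@dataclass
class ScanResult:
    survivors: list[tuple[int, float]]  # (block index, stage-1 p)
    qtls: list[QTLRecord]
    total_main_R2: float
    total_qei_R2: float
    h2_cap: float  # the restriction, as a fraction
    population_mean: float
    trait: str

    @property
    def unmapped_R2(self) -> float:
        """h2 share (in %) not claimed by the detected QTL system."""
        return max(0.0, 100.0 * self.h2_cap - self.total_main_R2)


# ---------------------------------------------------------------------------
# structure covariates


def similarity_matrix(snpldb_set: SNPLDBSet) -> np.ndarray:
    """s_ij = share of blocks where accessions i and j carry the same haplotype."""
    a = snpldb_set.assignment
    n, m = a.shape
    if m == 0:
        raise ValueError("no blocks")
    s = np.zeros((n, n))
    for j in range(m):
        col = a[:, j]
        s += col[:, None] == col[None, :]
    return s / m


def similarity_eigenvectors(snpldb_set: SNPLDBSet, k: int = 10) -> StructureCovariates:
    """Top-k eigenvectors of the genetic-similarity matrix."""
    n = len(snpldb_set.accession_ids)
    if k >= n:
        raise ValueError(f"k={k} must be < n accessions ({n})")
    s = similarity_matrix(snpldb_set)
    vals, vecs = np.linalg.eigh(s)
    order = np.argsort(vals)[::-1][:k]
    return StructureCovariates(eigenvectors=vecs[:, order], eigenvalues=vals[order])


# ---------------------------------------------------------------------------
# design-matrix helpers


def _block_dummies(snpldb_set: SNPLDBSet, j: int) -> tuple[np.ndarray, list[int]]:
    """Treatment-coded dummies for block j's realized haplotypes.

    Reference level is the most frequent realized haplotype.  Returns the
    (n, k-1) dummy matrix and the haplotype indices of the non-reference
    columns (reference listed first in the returned level order is implied).
    """
    col = snpldb_set.assignment[:, j]
    levels, counts = np.unique(col, return_counts=True)
    order = np.argsort(-counts, kind="stable")
    levels = levels[order]
    dummies = np.column_stack([(col == l).astype(float) for l in levels[1:]]) if len(levels) > 1 else np.empty((len(col), 0))
    return dummies, [int(l) for l in levels]


def _rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and rank of an OLS fit."""
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    return float(np.sum((y - fitted) ** 2)), int(rank)


def _partial_f(
    X0: np.ndarray, X1: np.ndarray, y: np.ndarray
) -> tuple[float, float, float]:
    """Partial F-test of the columns X1 adds over X0.

    Returns (p, F, partial SS).  Degrees of freedom come from the rank
    increase, so collinear additions are handled gracefully; a zero rank
    increase gives p = 1.
    """
    n = len(y)
    rss0, rank0 = _rss(X0, y)
    rss1, rank1 = _rss(np.column_stack([X0, X1]), y)
    q = rank1 - rank0
    df_res = n - rank1
    if q <= 0 or df_res <= 0:
        return 1.0, 0.0, 0.0
    ss = rss0 - rss1
    if ss <= 1e-12 * max(rss0, 1.0):
        return 1.0, 0.0, 0.0  # no usable SS gain (e.g. model already saturated)
    if rss1 <= 0:
        return 0.0, np.inf, ss
    f = (ss / q) / (rss1 / df_res)
    return float(stats.f.sf(f, q, df_res)), float(f), float(ss)


def _align_means(snpldb_set: SNPLDBSet, pheno_means: pd.Series) -> np.ndarray:
    y = pheno_means.reindex(snpldb_set.accession_ids)
    if y.isna().any():
        missing = list(y.index[y.isna()])[:3]
        raise ValueError(f"phenotype means missing for accessions {missing}")
    return y.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# stage 1


def stage1_scan(
    snpldb_set: SNPLDBSet,
    pheno_means: pd.Series,
    covariates: StructureCovariates,
    alpha1: float = 0.05,
) -> list[tuple[int, float]]:
    """Single-locus prescan: per-block haplotype F-test with structure covariates.

    Returns (block index, p) for blocks with p <= alpha1, in genomic order.
    Blocks monomorphic in the assignment are skipped.
    """
    y = _align_means(snpldb_set, pheno_means)
    n = len(y)
    X0 = np.column_stack([np.ones(n), covariates.eigenvectors])
    survivors = []
    for j in range(snpldb_set.n_blocks):
        dummies, _ = _block_dummies(snpldb_set, j)
        if dummies.shape[1] == 0:
            continue
        p, _, _ = _partial_f(X0, dummies, y)
        if p <= alpha1:
            survivors.append((j, p))
    return survivors


# ---------------------------------------------------------------------------
# stage 2


def _model_stats(
    X0: np.ndarray,
    y: np.ndarray,
    dummies: dict[int, np.ndarray],
    selected: list[int],
    ss_tot: float,
) -> tuple[float, dict[int, float], dict[int, float]]:
    """Joint marker R2, per-marker partial R2 and partial p in the current model."""
    X_all = np.column_stack([X0] + [dummies[j] for j in selected]) if selected else X0
    rss_full, rank_full = _rss(X_all, y)
    rss0, _ = _rss(X0, y)
    joint_r2 = (rss0 - rss_full) / ss_tot
    partial_r2: dict[int, float] = {}
    partial_p: dict[int, float] = {}
    n = len(y)
    for j in selected:
        rest = [k for k in selected if k != j]
        X_rest = np.column_stack([X0] + [dummies[k] for k in rest]) if rest else X0
        rss_rest, rank_rest = _rss(X_rest, y)
        ss = rss_rest - rss_full
        q = rank_full - rank_rest
        df_res = n - rank_full
        partial_r2[j] = ss / ss_tot
        if q <= 0 or df_res <= 0 or rss_full <= 0:
            partial_p[j] = 1.0 if q <= 0 else 0.0
        else:
            f = (ss / q) / (rss_full / df_res)
            partial_p[j] = float(stats.f.sf(f, q, df_res))
    return joint_r2, partial_r2, partial_p


def stage2_stepwise(
    snpldb_set: SNPLDBSet,
    survivors: list[tuple[int, float]],
    pheno_means: pd.Series,
    covariates: StructureCovariates,
    alpha2: float = 0.05,
    r2_cap: float = 1.0,
    trait: str = "trait",
) -> ScanResult:
    """Forward-addition / backward-elimination stepwise over stage-1 survivors.

    The restriction: an addition is rejected (and forward selection halts)
    when either the joint marker R2 (structure covariates partialled out) or
    the sum of per-QTL partial R2 would exceed ``r2_cap`` (a fraction,
    normally the trait's combined-environment h2).
    """
    y = _align_means(snpldb_set, pheno_means)
    n = len(y)
    X0 = np.column_stack([np.ones(n), covariates.eigenvectors])
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("phenotype means are constant")

    dummies: dict[int, np.ndarray] = {}
    levels: dict[int, list[int]] = {}
    candidates: list[int] = []
    for j, _ in survivors:
        d, lv = _block_dummies(snpldb_set, j)
        if d.shape[1] == 0:
            continue
        dummies[j] = d
        levels[j] = lv
        candidates.append(j)

    selected: list[int] = []
    while True:
        best: tuple[float, float, int] | None = None  # (p, -partial_r2, position)
        X_cur = np.column_stack([X0] + [dummies[j] for j in selected]) if selected else X0
        for j in candidates:
            if j in selected:
                continue
            p, f, ss = _partial_f(X_cur, dummies[j], y)
            if ss <= 0 and p >= 1.0:
                continue  # collinear duplicate of current model
            if p > alpha2:
                continue
            key = (p, -ss / ss_tot, snpldb_set.blocks[j].start_bp, j)
            if best is None or key < best:
                best = key
        if best is None:
            break
        j_new = best[3]
        trial = selected + [j_new]
        joint_r2, partial_r2, partial_p = _model_stats(X0, y, dummies, trial, ss_tot)
        if joint_r2 > r2_cap or sum(partial_r2.values()) > r2_cap:
            break  # restriction: stay within heritability
        selected = trial
        # backward pass
        while True:
            _, _, partial_p = _model_stats(X0, y, dummies, selected, ss_tot)
            worst = max(selected, key=lambda j: partial_p[j])
            if partial_p[worst] > alpha2 and len(selected) > 1:
                selected.remove(worst)
            elif partial_p[worst] > alpha2 and len(selected) == 1:
                selected = []
                break
            else:
                break
        if not selected:
            break

    # final model: effects and per-QTL R2
    qtls: list[QTLRecord] = []
    total_r2 = 0.0
    if selected:
        selected = sorted(selected, key=lambda j: (snpldb_set.blocks[j].chromosome, snpldb_set.blocks[j].start_bp))
        joint_r2, partial_r2, partial_p = _model_stats(X0, y, dummies, selected, ss_tot)
        X_full = np.column_stack([X0] + [dummies[j] for j in selected])
        beta, *_ = np.linalg.lstsq(X_full, y, rcond=None)
        col = X0.shape[1]
        per_chrom_counter: dict[str, int] = {}
        for j in selected:
            block = snpldb_set.blocks[j]
            k = dummies[j].shape[1]
            coefs = np.concatenate([[0.0], beta[col : col + k]])  # ref level first
            col += k
            freqs_all = snpldb_set.frequencies(j)
            lv = levels[j]
            f_lv = np.array([freqs_all[l] for l in lv])
            f_lv = f_lv / f_lv.sum()
            effects = coefs - float(f_lv @ coefs)
            hap_strings = [block.haplotypes[l] for l in lv]
            chrom_num = "".join(ch for ch in block.chromosome if ch.isdigit()) or block.chromosome
            idx = per_chrom_counter.get(block.chromosome, 0) + 1
            per_chrom_counter[block.chromosome] = idx
            qtls.append(
                QTLRecord(
                    qtl_id=f"q{trait}-{int(chrom_num) if chrom_num.isdigit() else chrom_num}-{idx}",
                    block_id=block.block_id,
                    chromosome=block.chromosome,
                    position_bp=(block.start_bp + block.end_bp) // 2,
                    main_R2=100.0 * partial_r2[j],
                    p_main=partial_p[j],
                    allele_effects=dict(zip(hap_strings, effects)),
                    allele_freqs=dict(zip(hap_strings, f_lv)),
                    block_index=j,
                )
            )
            total_r2 += 100.0 * partial_r2[j]

    return ScanResult(
        survivors=survivors,
        qtls=qtls,
        total_main_R2=total_r2,
        total_qei_R2=0.0,
        h2_cap=r2_cap,
        population_mean=float(np.mean(y)),
        trait=trait,
    )


# ---------------------------------------------------------------------------
# QTL x environment classification


def _plot_design(
    snpldb_set: SNPLDBSet,
    pheno: PhenotypeTable,
    trait: str,
    covariates: StructureCovariates,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, np.ndarray]:
    """Plot-level rows aligned to the panel, env dummies and covariate matrix."""
    df = pheno.data
    df = df[(df["trait"] == trait) & df["value"].notna()].copy()
    acc_index = {a: i for i, a in enumerate(snpldb_set.accession_ids)}
    df = df[df["accession"].isin(acc_index)].reset_index(drop=True)
    rows = df["accession"].map(acc_index).to_numpy()
    envs = sorted(df["environment"].unique())
    env_d = np.column_stack([(df["environment"] == e).to_numpy(float) for e in envs[1:]]) if len(envs) > 1 else np.empty((len(df), 0))
    cov = covariates.eigenvectors[rows]
    return df, rows, env_d, cov


def classify_qei(
    scan: ScanResult,
    snpldb_set: SNPLDBSet,
    pheno: PhenotypeTable,
    covariates: StructureCovariates,
    alpha: float = 0.05,
    total_r2_cap: float | None = None,
) -> ScanResult:
    """Classify QTLs by environment interaction and admit interaction-only QTLs.

    Each main-model QTL gets a marker-by-environment F-test in a plot-level
    model holding environment, structure covariates and all selected markers.
    Stage-1 survivors outside the main model are then scanned forward for
    interaction-only entry at ``alpha``; if ``total_r2_cap`` is given, the
    running total of main + interaction R2 (as a share of the within-
    environment plot sum of squares) may not exceed it.

    With a single environment every QTL is classified ``main_only`` and the
    interaction fields stay NaN.
    """
    df, rows, env_d, cov = _plot_design(snpldb_set, pheno, scan.trait, covariates)
    n_env = env_d.shape[1] + 1
    if n_env < 2:
        for q in scan.qtls:
            q.classification = "main_only"
        return scan
    y = df["value"].to_numpy(float)
    # within-environment centered total SS: the denominator for interaction R2
    env_means = df.groupby("environment")["value"].transform("mean").to_numpy()
    ss_tot = float(np.sum((y - env_means) ** 2))

    main_d: dict[int, np.ndarray] = {}
    inter_d: dict[int, np.ndarray] = {}
    for j, _ in scan.survivors:
        d, _ = _block_dummies(snpldb_set, j)
        if d.shape[1] == 0:
            continue
        d_rows = d[rows]
        main_d[j] = d_rows
        inter_d[j] = np.column_stack(
            [d_rows[:, a] * env_d[:, b] for a in range(d_rows.shape[1]) for b in range(env_d.shape[1])]
        )

    selected = [q.block_index for q in scan.qtls if q.block_index in main_d]
    base = np.column_stack(
        [np.ones(len(y)), env_d, cov] + [main_d[j] for j in selected]
    )

    total_qei = 0.0
    for q in scan.qtls:
        j = q.block_index
        if j not in inter_d:
            continue
        p, f, ss = _partial_f(base, inter_d[j], y)
        q.p_qei = p
        q.qei_R2 = 100.0 * ss / ss_tot
        q.classification = "both" if p <= alpha else "main_only"
        if p <= alpha:
            total_qei += q.qei_R2

    # interaction-only entries among remaining survivors
    running_total = scan.total_main_R2 + total_qei
    entered: list[int] = []
    X_cur = base
    remaining = [j for j, _ in scan.survivors if j not in selected and j in inter_d]
    qei_records: list[QTLRecord] = []
    while True:
        best = None
        for j in remaining:
            if j in entered:
                continue
            p, f, ss = _partial_f(X_cur, inter_d[j], y)
            if p > alpha:
                continue
            key = (p, -ss, snpldb_set.blocks[j].start_bp, j)
            if best is None or key < best:
                best = key
        if best is None:
            break
        p_best, neg_ss, _, j_new = best
        r2_new = 100.0 * (-neg_ss) / ss_tot
        if total_r2_cap is not None and running_total + r2_new > 100.0 * total_r2_cap:
            break
        entered.append(j_new)
        running_total += r2_new
        total_qei += r2_new
        X_cur = np.column_stack([X_cur, inter_d[j_new]])
        block = snpldb_set.blocks[j_new]
        qei_records.append(
            QTLRecord(
                qtl_id=f"q{scan.trait}-{block.block_id}-qei",
                block_id=block.block_id,
                chromosome=block.chromosome,
                position_bp=(block.start_bp + block.end_bp) // 2,
                main_R2=0.0,
                p_main=float("nan"),
                allele_effects={},
                allele_freqs={},
                qei_R2=r2_new,
                p_qei=p_best,
                classification="qei_only",
                block_index=j_new,
            )
        )

    scan.qtls = scan.qtls + qei_records
    scan.total_qei_R2 = total_qei
    return scan
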