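"""Biparental cross simulation under the linkage model and progeny prediction.

For a cross between two homozygous parents, recombinant inbred progeny are
produced by single-seed descent: the F1 is heterozygous everywhere the
parents differ; each selfing generation performs two independent meioses of
the current plant, and descent continues until the line is homozygous at
every QTL locus (hard cap 50 generations, residual heterozygous loci then
resolved by a fair coin — at 2^-49 expected residual heterozygosity per
locus the coin is practically unreachable).

Meiosis follows the no-interference Poisson model: the crossover count on a
chromosome of genetic length L cM is Poisson(L/100) with positions uniform
on (0, L) — a homogeneous Poisson process.  Restricted to the QTL loci this
process is Markov, so gametes are sampled locus-by-locus: the first locus
copies a uniformly chosen strand, and between consecutive loci d cM apart
the strand switches with the Haldane probability (1 - exp(-2d/100))/2.  The
two formulations are identical in distribution at the loci; the explicit
position sampler is kept for crossover-count calibration.

A progeny's genotypic value is the population mean plus the sum of its
allele effects across QTLs; the distribution's percentiles (nearest-rank,
95th by default) summarise the cross's recombination potential.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .allelematrix import QTLAlleleMatrix
from .iokit import GeneticMap

__all__ = [
    "MeiosisModel",
    "CrossPrediction",
    "sample_meiosis_crossovers",
    "qtl_loci",
    "simulate_progeny",
    "predict_values",
    "percentile",
    "cross_potential",
]

MAX_SELFING_GENERATIONS = 50


@dataclass
class MeiosisModel:
    """Poisson crossover model: count ~ Poisson(L/100), positions uniform, no
    interference."""

    lengths_cM: dict[str, float]

    def mean_crossovers(self, chromosome: str) -> float:
        return self.lengths_cM[chromosome] / 100.0


@dataclass
class CrossPrediction:
    """Simulated progeny genotypic-value distribution of one parent pair."""

    parent1: str
    parent2: str
    trait: str
    n_progeny: int
    values: np.ndarray
    percentiles: dict[int, float]
    parent1_value: float
    parent2_value: float

    @property
    def p95(self) -> float:
        return self.percentiles[95]


def sample_meiosis_crossovers(
    length_cM: float, n: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Explicit crossover positions for ``n`` meioses on one chromosome.

    Counts are Poisson(L/100); positions uniform on (0, L), sorted.
    """
    counts = rng.poisson(length_cM / 100.0, size=n)
    return [np.sort(rng.uniform(0.0, length_cM, size=k)) for k in counts]


def _gamete_origins(
    positions_cM: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Strand of origin (0/1) at each locus for n independent gametes.

    Locus-wise sampling of the Poisson crossover process: uniform start
    strand, switch between consecutive loci with the Haldane probability.
    """
    m = len(positions_cM)
    origins = np.empty((n, m), dtype=np.int8)
    origins[:, 0] = rng.integers(0, 2, size=n)
    if m > 1:
        d = np.diff(positions_cM)
        r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
        switches = rng.random((n, m - 1)) < r[None, :]
        flips = np.cumsum(switches, axis=1) % 2
        origins[:, 1:] = (origins[:, [0]] + flips) % 2
    return origins


def qtl_loci(
    matrix: QTLAlleleMatrix, gmap: GeneticMap | None
) -> dict[str, list[tuple[str, float]]]:
    """Per-chromosome ordered (qtl_id, pos_cM) lists for a matrix's QTLs.

    Genetic positions default to physical position x 1 cM/Mb when no map is
    given.  A QTL beyond its chromosome's stated length is an error.
    """
    loci: dict[str, list[tuple[str, float]]] = {}
    for q in matrix.qtls:
        if gmap is not None:
            pos = gmap.genetic_pos(q.chromosome, q.position_bp)
        else:
            pos = q.position_bp / 1e6
        loci.setdefault(q.chromosome, []).append((q.qtl_id, pos))
    for chrom in loci:
        loci[chrom].sort(key=lambda t: (t[1], t[0]))
    return loci


def simulate_progeny(
    p1_alleles: dict[str, str],
    p2_alleles: dict[str, str],
    loci: dict[str, list[tuple[str, float]]],
    n: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Parental origin of each QTL allele for ``n`` single-seed-descent lines.

    Parents are given as qtl_id -> haplotype string; the result holds, per
    progeny line and QTL, the inherited parent's haplotype string.  Loci
    where the parents carry the same allele are fixed without simulation.
    """
    qtl_order = [qid for chrom in sorted(loci) for qid, _ in loci[chrom]]
    origin = np.zeros((n, len(qtl_order)), dtype=np.int8)
    col_of = {qid: i for i, qid in enumerate(qtl_order)}

    for chrom in sorted(loci):
        seg = [(qid, pos) for qid, pos in loci[chrom] if p1_alleles[qid] != p2_alleles[qid]]
        if not seg:
            continue
        cols = np.array([col_of[qid] for qid, _ in seg])
        positions = np.array([pos for _, pos in seg])
        m = len(seg)
        # diplotype state per line: parental origin on each strand
        h = np.zeros((2, n, m), dtype=np.int8)
        h[1] = 1  # F1: strand 0 from P1, strand 1 from P2
        unfixed = np.arange(n)
        for _ in range(MAX_SELFING_GENERATIONS):
            if len(unfixed) == 0:
                break
            k = len(unfixed)
            g1 = _gamete_origins(positions, k, rng)
            g2 = _gamete_origins(positions, k, rng)
            rows = np.arange(k)[:, None]
            colz = np.arange(m)[None, :]
            new0 = h[g1, unfixed[:, None], colz]
            new1 = h[g2, unfixed[:, None], colz]
            h[0, unfixed] = new0
            h[1, unfixed] = new1
            still = (new0 != new1).any(axis=1)
            unfixed = unfixed[still]
        if len(unfixed):  # residual heterozygotes: fair coin per locus
            pick = rng.integers(0, 2, size=(len(unfixed), m))
            rows = np.arange(len(unfixed))[:, None]
            resolved = h[pick, unfixed[:, None], np.arange(m)[None, :]]
            h[0, unfixed] = resolved
            h[1, unfixed] = resolved
        origin[:, cols] = h[0][:, :]

    data = {}
    for qid in qtl_order:
        col = origin[:, col_of[qid]]
        a1, a2 = p1_alleles[qid], p2_alleles[qid]
        data[qid] = np.where(col == 0, a1, a2)
    return pd.DataFrame(data)


def predict_values(progeny: pd.DataFrame, matrix: QTLAlleleMatrix) -> np.ndarray:
    """Genotypic value per progeny: population mean + sum of allele effects."""
    values = np.full(len(progeny), matrix.population_mean, dtype=float)
    effect = {q.qtl_id: q.allele_effects for q in matrix.qtls}
    for qid in progeny.columns:
        lookup = effect[qid]
        unknown = set(progeny[qid].unique()) - set(lookup)
        if unknown:
            raise ValueError(f"unknown allele(s) {sorted(unknown)} at {qid}")
        values += progeny[qid].map(lookup).to_numpy()
    return values


def percentile(values: np.ndarray, p: float = 95) -> float:
    """Nearest-rank percentile: sorted ascending, element ceil(p/100 * n)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty value list")
    srt = np.sort(values)
    rank = int(np.ceil(p / 100.0 * len(srt)))
    rank = min(max(rank, 1), len(srt))
    return float(srt[rank - 1])


def _cross_rng(master_seed: int, p1: str, p2: str) -> np.random.Generator:
    """Reproducible, order-independent per-cross stream."""
    a, b = sorted([p1, p2])
    tag = zlib.crc32(f"{a}|{b}".encode())
    return np.random.default_rng(np.random.SeedSequence([master_seed & 0x7FFFFFFF, tag]))


def _parent_alleles(matrix: QTLAlleleMatrix, acc: str) -> dict[str, str]:
    if acc not in matrix.alleles.index:
        raise ValueError(f"parent {acc!r} not in matrix")
    return matrix.alleles.loc[acc].to_dict()


def cross_potential(
    p1: str,
    p2: str,
    matrix: QTLAlleleMatrix,
    gmap: GeneticMap | None = None,
    n: int = 2000,
    p: int = 95,
    seed: int = 0,
) -> CrossPrediction:
    """Predict the recombination potential of one cross for one trait.

    Simulates ``n`` homozygous progeny, predicts their genotypic values and
    summarises the distribution; the ``p``-th nearest-rank percentile (95th
    by default) is the recombination-potential indicator.
    """
    loci = qtl_loci(matrix, gmap)
    rng = _cross_rng(seed, p1, p2)
    a, b = sorted([p1, p2])  # canonical order: (P1,P2) == (P2,P1) exactly
    progeny = simulate_progeny(
        _parent_alleles(matrix, a), _parent_alleles(matrix, b), loci, n, rng
    )
    values = predict_values(progeny, matrix)
    pvals = matrix.predicted_values()
    wanted = sorted({5, 25, 50, 75, 95, int(p)})
    return CrossPrediction(
        parent1=p1,
        parent2=p2,
        trait=matrix.trait,
        n_progeny=n,
        values=values,
        percentiles={q: percentile(values, q) for q in wanted},
        parent1_value=float(pvals.loc[p1]),
        parent2_value=float(pvals.loc[p2]),
    )
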