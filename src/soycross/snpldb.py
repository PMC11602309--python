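"""SNP linkage-disequilibrium block (SNPLDB) construction.

A SNPLDB is a run of consecutive, tightly linked SNPs treated as one
multi-allelic marker: its alleles are the observed haplotypes.  Because the
panel is fully homozygous, haplotypes are read directly off the genotype
calls — no phasing.

Blocks are built per chromosome by greedy left-to-right extension: a block
grows while every pairwise normalized disequilibrium |D'| among its markers
stays at or above a threshold (default 0.7) and its physical span stays
within a cap (default 200 kb).  Haplotypes rarer than a frequency threshold
(default 1%) are merged into the nearest common haplotype by Hamming
distance, and lines with missing calls inside a block are assigned the most
frequent compatible haplotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .iokit import GeneticMap, GenotypePanel

__all__ = ["LDStats", "Block", "SNPLDBSet", "d_prime", "build_blocks"]


@dataclass
class LDStats:
    """Pairwise LD between two biallelic markers on homozygous lines.

    ``d`` is the raw coefficient p_AB - p_A p_B; ``d_prime`` is |D| divided
    by its maximum attainable magnitude given the allele frequencies, in
    [0, 1].  ``counts`` is the 2x2 haplotype count table
    [[n_AB, n_Ab], [n_aB, n_ab]] with A/B the "0" alleles.
    """

    d: float
    d_prime: float
    counts: np.ndarray


@dataclass
class Block:
    block_id: str
    chromosome: str
    first: int  # marker index into the panel, inclusive
    last: int  # inclusive
    start_bp: int
    end_bp: int
    pos_cM: float  # genetic position of the physical midpoint
    haplotypes: list[str]  # SNP-allele strings, ordered by falling frequency
    frequencies: np.ndarray

    @property
    def n_snps(self) -> int:
        return self.last - self.first + 1

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)


@dataclass
class SNPLDBSet:
    """Blocks partitioning the marker list, plus accession allele assignments.

    ``assignment`` is (n_accessions, n_blocks) int16 haplotype indices into
    each block's catalogue; every accession has an assignment (missing calls
    are resolved to the most frequent compatible haplotype at build time).
    """

    blocks: list[Block]
    assignment: np.ndarray
    accession_ids: list[str]

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def block_index(self) -> dict[str, int]:
        return {b.block_id: i for i, b in enumerate(self.blocks)}

    def frequencies(self, j: int) -> np.ndarray:
        """Realized haplotype frequencies of block j from the assignment."""
        counts = np.bincount(self.assignment[:, j], minlength=self.blocks[j].n_haplotypes)
        return counts / counts.sum()

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "block_id": b.block_id,
                "chrom": b.chromosome,
                "start_bp": b.start_bp,
                "end_bp": b.end_bp,
                "n_snps": b.n_snps,
                "n_haplotypes": b.n_haplotypes,
                "haplotype_strings": ",".join(b.haplotypes),
                "frequencies": ",".join(f"{f:.6g}" for f in b.frequencies),
            }
            for b in self.blocks
        ]
        return pd.DataFrame(rows)


def _ld_from_counts(n_ab_table: np.ndarray) -> tuple[float, float]:
    """(D, D') from a 2x2 haplotype count table [[AB, Ab], [aB, ab]]."""
    n = n_ab_table.sum()
    if n == 0:
        raise ValueError("no complete observations")
    p = n_ab_table / n
    p_a = p[0].sum()  # freq of allele A at locus 1
    p_b = p[:, 0].sum()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise ValueError("monomorphic marker in LD computation")
    d = p[0, 0] - p_a * p_b
    if d > 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    dp = 0.0 if d == 0 else abs(d) / d_max
    return float(d), float(min(dp, 1.0))


def d_prime(panel: GenotypePanel, marker_i: int, marker_j: int) -> LDStats:
    """Normalized LD between two markers, over lines non-missing at both.

    Lines are homozygous, so two-locus haplotypes are observed directly.
    Raises if either marker is monomorphic among the complete lines.
    """
    a = panel.calls[:, marker_i]
    b = panel.calls[:, marker_j]
    ok = (a >= 0) & (b >= 0)
    a, b = a[ok], b[ok]
    counts = np.array(
        [
            [(np.sum((a == 0) & (b == 0))), np.sum((a == 0) & (b == 1))],
            [(np.sum((a == 1) & (b == 0))), np.sum((a == 1) & (b == 1))],
        ],
        dtype=np.int64,
    )
    d, dp = _ld_from_counts(counts)
    return LDStats(d=d, d_prime=dp, counts=counts)


def _pair_d_prime_or_none(panel: GenotypePanel, i: int, j: int) -> float | None:
    try:
        return d_prime(panel, i, j).d_prime
    except ValueError:
        return None


def _haplotype_strings(calls_block: np.ndarray) -> np.ndarray:
    """Per-accession haplotype string over a block; '.' marks missing."""
    chars = np.full(calls_block.shape, ".", dtype="<U1")
    chars[calls_block == 0] = "0"
    chars[calls_block == 1] = "1"
    return np.array(["".join(row) for row in chars])


def _resolve_block(
    calls_block: np.ndarray, rare_hap_freq: float
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Catalogue, frequencies and per-accession assignment for one block."""
    strings = _haplotype_strings(calls_block)
    complete = np.array(["." not in s for s in strings])
    if not complete.any():
        raise ValueError("block has no complete haplotype observation")
    uniq, counts = np.unique(strings[complete], return_counts=True)
    order = np.argsort(-counts, kind="stable")
    uniq, counts = uniq[order], counts[order]
    freqs = counts / counts.sum()

    # merge rare haplotypes into the nearest common one (Hamming distance,
    # ties toward the more frequent target)
    common = freqs >= rare_hap_freq
    if not common.any():
        common = np.zeros_like(common)
        common[0] = True  # keep at least the modal haplotype
    catalogue = [uniq[i] for i in range(len(uniq)) if common[i]]
    merged_counts = counts[common].astype(float)
    cat_arr = np.array([list(h) for h in catalogue])
    for i in np.nonzero(~common)[0]:
        h = np.array(list(uniq[i]))
        dist = (cat_arr != h).sum(axis=1)
        target = int(np.argmin(dist))  # catalogue sorted by frequency: stable
        merged_counts[target] += counts[i]
    merge_map = {}
    for i, h in enumerate(uniq):
        if common[i]:
            merge_map[h] = catalogue.index(h)
        else:
            arr = np.array(list(h))
            merge_map[h] = int(np.argmin((cat_arr != arr).sum(axis=1)))
    freqs_out = merged_counts / merged_counts.sum()

    # assignment; missing-call lines get the most frequent compatible haplotype
    assign = np.empty(len(strings), dtype=np.int16)
    for idx, s in enumerate(strings):
        if "." not in s:
            assign[idx] = merge_map[s]
        else:
            obs = np.array([c != "." for c in s])
            sarr = np.array(list(s))
            compatible = [
                k
                for k, h in enumerate(catalogue)
                if np.all(cat_arr[k][obs] == sarr[obs])
            ]
            assign[idx] = compatible[0] if compatible else 0
    return catalogue, freqs_out, assign


def build_blocks(
    panel: GenotypePanel,
    gmap: GeneticMap | None = None,
    d_prime_threshold: float = 0.7,
    max_span_bp: int = 200_000,
    rare_hap_freq: float = 0.01,
) -> SNPLDBSet:
    """Partition the sorted marker list into SNPLDBs by greedy extension.

    A block absorbs the next marker while (i) every pairwise |D'| among block
    members stays >= ``d_prime_threshold`` and (ii) the physical span stays
    <= ``max_span_bp``.  A pair whose LD is undefined (monomorphic among the
    jointly complete lines) never extends a block.  Single-marker blocks get
    the two single-SNP haplotypes "0"/"1".
    """
    markers = panel.markers
    blocks: list[Block] = []
    assignments: list[np.ndarray] = []
    for chrom, idx in markers.groupby("chromosome", sort=False).groups.items():
        idx = np.asarray(idx)
        if len(idx) == 0:
            continue
        start = 0
        while start < len(idx):
            members = [idx[start]]
            end = start
            while end + 1 < len(idx):
                cand = idx[end + 1]
                span = markers.loc[cand, "pos_bp"] - markers.loc[members[0], "pos_bp"]
                if span > max_span_bp:
                    break
                ok = True
                for m in members:
                    dp = _pair_d_prime_or_none(panel, m, cand)
                    if dp is None or dp < d_prime_threshold:
                        ok = False
                        break
                if not ok:
                    break
                members.append(cand)
                end += 1
            first, last = int(members[0]), int(members[-1])
            calls_block = panel.calls[:, first : last + 1]
            catalogue, freqs, assign = _resolve_block(calls_block, rare_hap_freq)
            start_bp = int(markers.loc[first, "pos_bp"])
            end_bp = int(markers.loc[last, "pos_bp"])
            mid_bp = (start_bp + end_bp) // 2
            pos_cM = (
                gmap.genetic_pos(str(chrom), mid_bp)
                if gmap is not None
                else float(markers.loc[first:last, "pos_cM"].mean())
            )
            blocks.append(
                Block(
                    block_id=f"{chrom}:{start_bp}-{end_bp}",
                    chromosome=str(chrom),
                    first=first,
                    last=last,
                    start_bp=start_bp,
                    end_bp=end_bp,
                    pos_cM=pos_cM,
                    haplotypes=catalogue,
                    frequencies=freqs,
                )
            )
            assignments.append(assign)
            start = end + 1
    assignment = (
        np.stack(assignments, axis=1)
        if assignments
        else np.empty((panel.n_accessions, 0), np.int16)
    )
    return SNPLDBSet(blocks=blocks, assignment=assignment, accession_ids=list(panel.accession_ids))
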