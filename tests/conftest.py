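import numpy as np
import pandas as pd
import pytest

from soycross.iokit import apply_qc
from soycross.quantstats import estimate_components, heritability
from soycross.rtmgwas import similarity_eigenvectors, stage1_scan, stage2_stepwise
from soycross.snpldb import Block, SNPLDBSet, build_blocks
from soycross.synthdata import SimConfig, simulate_panel, simulate_phenotypes


@pytest.fixture(scope="session")
def small_run():
    """One small but complete pipeline run shared across tests.

    150 accessions, 6 chromosomes x 50 markers, 5 planted QTLs, 2 env x 4
    reps at h2 = 0.8 — large enough for the scan to have power, small enough
    to build once per session.
    """
    cfg = SimConfig(
        n_accessions=150,
        n_chromosomes=6,
        markers_per_chrom=50,
        n_qtl=5,
        seed=11,
    )
    panel, subpop, gmap, truth = simulate_panel(cfg)
    pheno = simulate_phenotypes(panel, truth, cfg)
    qc, qc_report = apply_qc(panel)
    vc = estimate_components(pheno, cfg.trait_id)
    h2 = heritability(vc)
    blocks = build_blocks(qc, gmap)
    cov = similarity_eigenvectors(blocks, k=10)
    means = pheno.accession_means(cfg.trait_id)
    survivors = stage1_scan(blocks, means, cov)
    scan = stage2_stepwise(blocks, survivors, means, cov, r2_cap=h2, trait="SW")
    return {
        "config": cfg,
        "panel": panel,
        "subpop": subpop,
        "gmap": gmap,
        "truth": truth,
        "pheno": pheno,
        "qc": qc,
        "qc_report": qc_report,
        "vc": vc,
        "h2": h2,
        "blocks": blocks,
        "cov": cov,
        "means": means,
        "survivors": survivors,
        "scan": scan,
    }


def make_snpldb(assignments: np.ndarray, n_haps: list[int], accession_ids=None) -> SNPLDBSet:
    """Build a minimal SNPLDBSet from an (n x m) haplotype-index array.

    Each block j gets ``n_haps[j]`` catalogued haplotypes with synthetic
    2-character allele strings and 100 kb of physical space on one chromosome.
    """
    n, m = assignments.shape
    if accession_ids is None:
        accession_ids = [f"A{i:03d}" for i in range(n)]
    blocks = []
    for j in range(m):
        k = n_haps[j]
        counts = np.bincount(assignments[:, j], minlength=k)
        blocks.append(
            Block(
                block_id=f"chr01:{j * 100000 + 1}-{j * 100000 + 50000}",
                chromosome="chr01",
                first=j,
                last=j,
                start_bp=j * 100000 + 1,
                end_bp=j * 100000 + 50000,
                pos_cM=(j * 100000 + 25000) / 1e6,
                haplotypes=[format(h, "02b") for h in range(k)],
                frequencies=counts / counts.sum(),
            )
        )
    return SNPLDBSet(
        blocks=blocks,
        assignment=assignments.astype(np.int16),
        accession_ids=list(accession_ids),
    )


def tiny_panel(calls: np.ndarray, chrom: str = "chr01", spacing_bp: int = 10_000):
    """GenotypePanel from a raw (accessions x markers) call array."""
    from soycross.iokit import GenotypePanel

    n, m = calls.shape
    markers = pd.DataFrame(
        {
            "marker_id": [f"m{j}" for j in range(m)],
            "chromosome": chrom,
            "pos_bp": [1 + j * spacing_bp for j in range(m)],
            "pos_cM": [(1 + j * spacing_bp) / 1e6 for j in range(m)],
        }
    )
    return GenotypePanel([f"A{i}" for i in range(n)], markers, calls.astype(np.int8))
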