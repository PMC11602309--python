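"""Synthetic inbred-line panels with block-wise LD, structure and planted QTLs.

The generator emulates the statistical structure of a germplasm panel of fully
homozygous accessions genotyped genome-wide:

* markers come in blocks of consecutive sites; within a block every accession
  carries one of a small set of founder haplotypes, which creates strong LD
  inside blocks and (by independence) weak LD between them;
* haplotype frequencies are Dirichlet-distributed and shifted between
  subpopulations, creating population structure on the same axis a maturity-
  group classification would;
* a planted set of blocks act as multi-allelic QTLs whose haplotypes carry
  additive effects (frequency-weighted sum-to-zero, so the population mean is
  the intercept of the genotypic values), optionally with QTL x environment
  interaction effects;
* phenotypes add environment main effects, replicate effects and residual
  error whose variance is calibrated so the realized broad-sense heritability
  across environments matches a target.

Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .iokit import GeneticMap, GenotypePanel, PhenotypeTable

__all__ = [
    "SimConfig",
    "TruthSet",
    "simulate_panel",
    "simulate_phenotypes",
    "plant_trait",
    "evaluate_scan",
]

# per-subpop Dirichlet concentration around the base haplotype frequencies;
# smaller -> stronger subpopulation differentiation
_SUBPOP_CONCENTRATION = 15.0
# QEI effect scale relative to main allele-effect scale
_QEI_RELATIVE_SD = 0.5
# environment main-effect SD relative to genotypic SD
_ENV_RELATIVE_SD = 0.5


@dataclass
class SimConfig:
    """Panel and trial dimensions plus genetic-architecture knobs.

    Defaults mirror a mid-size germplasm study: 300 lines over 20 chromosomes
    of 100 cM, 100 markers per chromosome in founder blocks of 5 sites with up
    to 4 haplotypes each, 8 planted QTLs, 3 subpopulations, a 2-environment x
    4-replicate trial at a broad-sense heritability of 0.8, with a quarter of
    the genetic variance carried by a polygenic background rather than the
    planted QTLs.
    """

    n_accessions: int = 300
    n_chromosomes: int = 20
    chrom_length_cM: float = 100.0
    markers_per_chrom: int = 100
    block_size_markers: int = 5
    n_haplotypes_per_block: int = 4
    n_qtl: int = 8
    allele_effect_sd: float = 0.8
    n_subpops: int = 3
    n_environments: int = 2
    n_replicates: int = 4
    heritability_target: float = 0.8
    qei_fraction: float = 0.25
    polygenic_fraction: float = 0.25
    trait_mean: float = 20.0
    trait_id: str = "trait"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.heritability_target <= 1):
            raise ValueError("heritability_target must lie in (0, 1]")
        for name in (
            "n_accessions",
            "n_chromosomes",
            "markers_per_chrom",
            "block_size_markers",
            "n_haplotypes_per_block",
            "n_subpops",
            "n_environments",
            "n_replicates",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_haplotypes_per_block > 2**self.block_size_markers:
            raise ValueError(
                f"{self.n_haplotypes_per_block} haplotypes do not fit in "
                f"{self.block_size_markers} biallelic sites"
            )


@dataclass
class TruthSet:
    """Ground truth of a simulated panel, for parameter-recovery tests.

    ``qtl_blocks`` maps each planted QTL to the marker ids of its founder
    block; ``allele_effects`` holds, per QTL, the frequency-weighted
    sum-to-zero effect of each founder haplotype; ``qei_effects`` holds, for
    QTLs flagged with interaction, a (haplotype x environment) effect array.
    ``accession_haplotype`` is the (accession x QTL) founder-haplotype index.
    """

    qtl_blocks: dict[str, list[str]]
    allele_effects: dict[str, np.ndarray]
    qei_effects: dict[str, np.ndarray]
    accession_haplotype: pd.DataFrame
    population_mean: float
    genotypic_values: pd.Series
    block_of_marker: pd.Series
    realized_h2: float | None = None
    error_sd: float | None = None
    subpops: pd.Series | None = None
    # polygenic-background blocks: marker ids of blocks carrying small real
    # effects that are not counted among the planted QTLs
    background_blocks: dict[str, list[str]] = field(default_factory=dict)
    # full founder-block state (accession x block haplotype indices and
    # per-block frequencies), kept so further traits can be planted on the
    # same panel
    block_assignment_full: pd.DataFrame | None = None
    block_frequencies: dict[str, np.ndarray] = field(default_factory=dict)

    def genetic_positions(self, panel: GenotypePanel, gmap: GeneticMap) -> dict[str, tuple[str, float]]:
        """(chromosome, cM) of each planted QTL (midpoint of its block)."""
        mk = panel.markers.set_index("marker_id")
        out = {}
        for qtl, markers in self.qtl_blocks.items():
            present = [m for m in markers if m in mk.index]
            chrom = mk.loc[present[0], "chromosome"]
            mid = float(np.mean([mk.loc[m, "pos_bp"] for m in present]))
            out[qtl] = (chrom, gmap.genetic_pos(chrom, int(mid)))
        return out


def _center(effects: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    return effects - float(np.dot(freqs, effects))


def simulate_panel(
    config: SimConfig,
) -> tuple[GenotypePanel, pd.Series, GeneticMap, TruthSet]:
    """Simulate genotypes, subpopulation labels, the genetic map and the truth set.

    Genotypes are drawn block-wise: each block of ``block_size_markers``
    consecutive markers is one of ``n_haplotypes_per_block`` founder
    haplotypes, with per-subpopulation Dirichlet frequencies.  Lines are fully
    homozygous, so one call per site suffices.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_accessions
    n_blocks_per_chrom = config.markers_per_chrom // config.block_size_markers
    if n_blocks_per_chrom < 1:
        raise ValueError("markers_per_chrom must be >= block_size_markers")

    # subpopulation labels, balanced assignment
    subpop = pd.Series(
        [f"G{i % config.n_subpops}" for i in range(n)],
        index=[f"A{i:04d}" for i in range(n)],
        name="subpop",
    )
    acc_ids = list(subpop.index)
    sub_idx = np.array([i % config.n_subpops for i in range(n)])

    length_bp = int(config.chrom_length_cM * 1e6)  # 1 cM/Mb physical scale
    within_block_spacing_bp = 10_000  # markers of a block sit tight, as in real LD blocks
    markers_rows = []
    call_cols = []
    block_of_marker = []
    block_haplotypes: dict[str, np.ndarray] = {}  # block_id -> (n_hap, size) 0/1
    block_assignment: dict[str, np.ndarray] = {}  # block_id -> accession hap index
    block_freqs: dict[str, np.ndarray] = {}
    block_ids: list[str] = []

    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1:02d}"
        # block anchors spread over the chromosome; block members clustered
        block_span = (config.block_size_markers - 1) * within_block_spacing_bp
        anchors = np.linspace(1, max(length_bp - block_span, 1), n_blocks_per_chrom, dtype=int)
        pos_bp = np.concatenate(
            [
                a + np.arange(config.block_size_markers) * within_block_spacing_bp
                for a in anchors
            ]
        )
        for b in range(n_blocks_per_chrom):
            block_id = f"{chrom}_b{b:03d}"
            size = config.block_size_markers
            # distinct founder haplotypes as binary codes
            codes = rng.choice(2**size, size=config.n_haplotypes_per_block, replace=False)
            haps = ((codes[:, None] >> np.arange(size)[None, :]) & 1).astype(np.int8)
            base = rng.dirichlet(np.ones(config.n_haplotypes_per_block) * 1.5)
            per_sub = np.stack(
                [
                    rng.dirichlet(np.maximum(base * _SUBPOP_CONCENTRATION, 1e-3))
                    for _ in range(config.n_subpops)
                ]
            )
            # accession haplotype draw from its subpopulation's frequencies
            u = rng.random(n)
            cum = np.cumsum(per_sub, axis=1)
            hap_idx = (u[:, None] > cum[sub_idx]).sum(axis=1)
            block_haplotypes[block_id] = haps
            block_assignment[block_id] = hap_idx
            block_freqs[block_id] = np.bincount(hap_idx, minlength=len(haps)) / n
            block_ids.append(block_id)
            call_cols.append(haps[hap_idx])  # (n, size)
            for k in range(size):
                j = b * size + k
                markers_rows.append(
                    (f"{chrom}_m{j:04d}", chrom, int(pos_bp[j]), pos_bp[j] / 1e6)
                )
                block_of_marker.append(block_id)

    markers = pd.DataFrame(
        markers_rows, columns=["marker_id", "chromosome", "pos_bp", "pos_cM"]
    )
    calls = np.concatenate(call_cols, axis=1)
    panel = GenotypePanel(acc_ids, markers, calls)
    gmap = GeneticMap(
        lengths_cM={f"chr{c + 1:02d}": config.chrom_length_cM for c in range(config.n_chromosomes)}
    )

    # plant QTLs on blocks spread over chromosomes (at most one per block)
    n_qtl = config.n_qtl
    qtl_block_ids = rng.choice(len(block_ids), size=n_qtl, replace=False)
    marker_block = pd.Series(block_of_marker, index=markers["marker_id"].to_numpy())

    qtl_blocks: dict[str, list[str]] = {}
    allele_effects: dict[str, np.ndarray] = {}
    qei_effects: dict[str, np.ndarray] = {}
    acc_hap = {}
    n_qei = int(round(config.qei_fraction * n_qtl))
    qei_flags = np.zeros(n_qtl, dtype=bool)
    if n_qei:
        qei_flags[rng.choice(n_qtl, size=n_qei, replace=False)] = True

    g = np.zeros(n)
    qei_by_env = np.zeros((n, config.n_environments))
    for qi, bi in enumerate(sorted(qtl_block_ids)):
        block_id = block_ids[bi]
        qtl_id = f"QTL{qi + 1:02d}"
        freqs = block_freqs[block_id]
        hap_idx = block_assignment[block_id]
        eff = _center(rng.normal(0.0, 1.0, len(freqs)), freqs)
        # equal per-QTL variance contribution: allele_effect_sd is the
        # genetic SD each planted QTL contributes, in trait units
        sd_realized = float(np.std(eff[hap_idx]))
        if sd_realized > 0:
            eff = eff * (config.allele_effect_sd / sd_realized)
        qtl_blocks[qtl_id] = list(marker_block.index[marker_block == block_id])
        allele_effects[qtl_id] = eff
        acc_hap[qtl_id] = hap_idx
        g = g + eff[hap_idx]
        if qei_flags[qi]:
            qe = rng.normal(
                0.0, _QEI_RELATIVE_SD * config.allele_effect_sd, (len(freqs), config.n_environments)
            )
            qe -= qe.mean(axis=1, keepdims=True)  # no main-effect leakage
            qe = qe - (freqs @ qe)[None, :]  # frequency-weighted zero per env
            qei_effects[qtl_id] = qe
            qei_by_env += qe[hap_idx]

    # polygenic background: small effects on non-QTL blocks, scaled to carry
    # polygenic_fraction of the genetic variance
    bg = np.zeros(n)
    background_blocks: dict[str, list[str]] = {}
    if config.polygenic_fraction > 0:
        others = [i for i in range(len(block_ids)) if i not in set(qtl_block_ids)]
        n_bg = min(len(others), 50)
        for bi in rng.choice(others, size=n_bg, replace=False):
            block_id = block_ids[bi]
            freqs = block_freqs[block_id]
            eff = _center(rng.normal(0.0, 1.0, len(freqs)), freqs)
            bg = bg + eff[block_assignment[block_id]]
            background_blocks[block_id] = list(
                marker_block.index[marker_block == block_id]
            )
        var_q = float(np.var(g))
        var_bg = float(np.var(bg))
        if var_bg > 0 and var_q > 0:
            target = var_q * config.polygenic_fraction / (1 - config.polygenic_fraction)
            bg *= np.sqrt(target / var_bg)
    g_total = g + bg

    truth = TruthSet(
        qtl_blocks=qtl_blocks,
        allele_effects=allele_effects,
        qei_effects=qei_effects,
        accession_haplotype=pd.DataFrame(acc_hap, index=acc_ids),
        population_mean=config.trait_mean,
        genotypic_values=pd.Series(g_total, index=acc_ids, name="g"),
        block_of_marker=marker_block,
        subpops=subpop,
        background_blocks=background_blocks,
        block_assignment_full=pd.DataFrame(block_assignment, index=acc_ids)[block_ids],
        block_frequencies=block_freqs,
    )
    return panel, subpop, gmap, truth


def simulate_phenotypes(
    panel: GenotypePanel, truth: TruthSet, config: SimConfig
) -> PhenotypeTable:
    """Simulate the plot-level trial: value = mu + g + env + QEI + rep + error.

    The residual variance is calibrated so the broad-sense heritability of
    accession means over the trial design hits ``heritability_target``; the
    realized value is recorded on ``truth.realized_h2``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    acc_ids = list(truth.genotypic_values.index)
    missing = [a for a in acc_ids if a not in panel.accession_ids]
    if missing:
        raise ValueError(f"truth accessions not in panel: {missing[:3]}")
    n = len(acc_ids)
    t, r = config.n_environments, config.n_replicates
    g = truth.genotypic_values.to_numpy()

    qei = np.zeros((n, t))
    for qtl_id, qe in truth.qei_effects.items():
        qei += qe[truth.accession_haplotype[qtl_id].to_numpy()]

    var_g = float(np.var(g))
    var_gt = float(np.var(qei)) if truth.qei_effects else 0.0
    h2 = config.heritability_target
    # h2 = var_g / (var_g + var_gt/t + sig2/(t r))  ->  solve for sig2
    sig2 = t * r * (var_g * (1 - h2) / h2 - var_gt / t)
    if sig2 <= 0:
        sig2 = 1e-12
    error_sd = float(np.sqrt(sig2))

    g_sd = np.sqrt(var_g) if var_g > 0 else 1.0
    env_eff = rng.normal(0.0, _ENV_RELATIVE_SD * g_sd, t)
    env_eff -= env_eff.mean()  # mu stays the grand mean; 1 env -> no shift
    rep_eff = rng.normal(0.0, 0.1 * error_sd, (t, r))
    eps = rng.normal(0.0, error_sd, (n, t, r))

    values = (
        config.trait_mean
        + g[:, None, None]
        + env_eff[None, :, None]
        + qei[:, :, None]
        + rep_eff[None, :, :]
        + eps
    )
    records = {
        "accession": np.repeat(acc_ids, t * r),
        "environment": np.tile(np.repeat([f"E{j + 1}" for j in range(t)], r), n),
        "replicate": np.tile([f"R{k + 1}" for k in range(r)], n * t),
        "trait": config.trait_id,
        "value": values.ravel(),
    }
    pheno = PhenotypeTable(pd.DataFrame(records))

    means = pheno.accession_means(config.trait_id).loc[acc_ids].to_numpy()
    var_means = float(np.var(means, ddof=1))
    realized = var_g / var_means if var_means > 0 else 1.0
    truth.realized_h2 = float(min(realized, 1.0))
    truth.error_sd = error_sd
    return pheno


def evaluate_scan(truth: TruthSet, scan, snpldb_set, panel: GenotypePanel, slack_markers: int | None = None):
    """Score a completed association scan against the planted truth.

    A planted QTL counts as recovered when some detected QTL's block lies
    within one block of it: the detected marker range, widened by
    ``slack_markers`` on each side (default: the truth block's size), must
    intersect the truth block's markers.  A detected QTL matching no planted
    QTL under the same rule is checked against the polygenic-background
    blocks — those carry genuine (small) effects, so hitting one is not a
    false positive; only detections matching neither are false.  The
    allele-effect correlation pools, over matched QTLs, each accession's
    planted effect against its estimated effect.

    Returns a dict with ``recovered``, ``n_truth``, ``background_hits``,
    ``false_qtls`` (ids), ``false_r2_ge_1`` and ``effect_correlation``.
    """
    mk_pos = {m: i for i, m in enumerate(panel.markers["marker_id"])}
    truth_ranges = {}
    for tq, markers in truth.qtl_blocks.items():
        idxs = [mk_pos[m] for m in markers if m in mk_pos]
        if idxs:
            truth_ranges[tq] = (min(idxs), max(idxs), len(idxs))

    main = [q for q in scan.qtls if q.classification != "qei_only"]
    det_ranges = {}
    for q in main:
        b = snpldb_set.blocks[q.block_index]
        det_ranges[q.qtl_id] = (b.first, b.last)

    bg_ranges = {}
    for bid, markers in truth.background_blocks.items():
        idxs = [mk_pos[m] for m in markers if m in mk_pos]
        if idxs:
            bg_ranges[bid] = (min(idxs), max(idxs), len(idxs))

    def _overlaps(lo, hi, ranges):
        for key, (tlo, thi, tsize) in ranges.items():
            slack = tsize if slack_markers is None else slack_markers
            if hi + slack >= tlo and lo - slack <= thi:
                return key
        return None

    matches: dict[str, list[str]] = {tq: [] for tq in truth_ranges}
    false_qtls = []
    background_hits = 0
    for q in main:
        lo, hi = det_ranges[q.qtl_id]
        hit = _overlaps(lo, hi, truth_ranges)
        if hit is not None:
            matches[hit].append(q.qtl_id)
        elif _overlaps(lo, hi, bg_ranges) is not None:
            background_hits += 1
        else:
            false_qtls.append(q.qtl_id)

    planted_eff, est_eff = [], []
    qtl_by_id = {q.qtl_id: q for q in main}
    for tq, dqs in matches.items():
        if not dqs:
            continue
        hap = truth.accession_haplotype[tq].to_numpy()
        planted = truth.allele_effects[tq][hap]
        # largest-R2 match carries the effect comparison
        dq = max(dqs, key=lambda d: qtl_by_id[d].main_R2)
        q = qtl_by_id[dq]
        block = snpldb_set.blocks[q.block_index]
        assign = snpldb_set.assignment[:, q.block_index]
        est = np.array([q.allele_effects[block.haplotypes[a]] for a in assign])
        planted_eff.extend(planted)
        est_eff.extend(est)

    corr = float(np.corrcoef(planted_eff, est_eff)[0, 1]) if planted_eff else float("nan")
    return {
        "recovered": sum(1 for v in matches.values() if v),
        "n_truth": len(truth_ranges),
        "background_hits": background_hits,
        "false_qtls": false_qtls,
        "false_r2_ge_1": sum(1 for qid in false_qtls if qtl_by_id[qid].main_R2 >= 1.0),
        "effect_correlation": corr,
    }


def plant_trait(
    panel: GenotypePanel, base_truth: TruthSet, config: SimConfig
) -> TruthSet:
    """Plant a second trait's QTL system on an already-simulated panel.

    Chooses ``config.n_qtl`` founder blocks disjoint from ``base_truth``'s
    QTL blocks, assigns frequency-weighted sum-to-zero effects of equal
    per-QTL variance (``config.allele_effect_sd`` trait units each) and a
    fresh polygenic background, and returns a new TruthSet sharing the
    panel's block state.  Phenotypes for the new trait come from
    :func:`simulate_phenotypes` with the returned truth.
    """
    if base_truth.block_assignment_full is None:
        raise ValueError("base truth lacks the panel's block state")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 211]))
    assign_all = base_truth.block_assignment_full
    freqs_all = base_truth.block_frequencies
    marker_block = base_truth.block_of_marker
    n = len(assign_all)

    used = {marker_block[m] for ms in base_truth.qtl_blocks.values() for m in ms}
    candidates = [b for b in assign_all.columns if b not in used]
    chosen = list(rng.choice(candidates, size=config.n_qtl, replace=False))

    qtl_blocks, allele_effects, acc_hap = {}, {}, {}
    g = np.zeros(n)
    qei_effects: dict[str, np.ndarray] = {}
    n_qei = int(round(config.qei_fraction * config.n_qtl))
    qei_flags = np.zeros(config.n_qtl, dtype=bool)
    if n_qei:
        qei_flags[rng.choice(config.n_qtl, size=n_qei, replace=False)] = True
    for qi, block_id in enumerate(sorted(chosen)):
        qtl_id = f"QTL{qi + 1:02d}"
        freqs = freqs_all[block_id]
        hap_idx = assign_all[block_id].to_numpy()
        eff = _center(rng.normal(0.0, 1.0, len(freqs)), freqs)
        sd_realized = float(np.std(eff[hap_idx]))
        if sd_realized > 0:
            eff = eff * (config.allele_effect_sd / sd_realized)
        qtl_blocks[qtl_id] = list(marker_block.index[marker_block == block_id])
        allele_effects[qtl_id] = eff
        acc_hap[qtl_id] = hap_idx
        g = g + eff[hap_idx]
        if qei_flags[qi]:
            qe = rng.normal(
                0.0,
                _QEI_RELATIVE_SD * config.allele_effect_sd,
                (len(freqs), config.n_environments),
            )
            qe -= qe.mean(axis=1, keepdims=True)
            qe = qe - (freqs @ qe)[None, :]
            qei_effects[qtl_id] = qe

    bg = np.zeros(n)
    background_blocks: dict[str, list[str]] = {}
    if config.polygenic_fraction > 0:
        others = [b for b in assign_all.columns if b not in set(chosen) | used]
        for block_id in rng.choice(others, size=min(len(others), 50), replace=False):
            freqs = freqs_all[block_id]
            eff = _center(rng.normal(0.0, 1.0, len(freqs)), freqs)
            bg = bg + eff[assign_all[block_id].to_numpy()]
            background_blocks[block_id] = list(marker_block.index[marker_block == block_id])
        var_q, var_bg = float(np.var(g)), float(np.var(bg))
        if var_bg > 0 and var_q > 0:
            target = var_q * config.polygenic_fraction / (1 - config.polygenic_fraction)
            bg *= np.sqrt(target / var_bg)

    return TruthSet(
        qtl_blocks=qtl_blocks,
        allele_effects=allele_effects,
        qei_effects=qei_effects,
        accession_haplotype=pd.DataFrame(acc_hap, index=assign_all.index),
        population_mean=config.trait_mean,
        genotypic_values=pd.Series(g + bg, index=assign_all.index, name="g"),
        block_of_marker=marker_block,
        subpops=base_truth.subpops,
        background_blocks=background_blocks,
        block_assignment_full=assign_all,
        block_frequencies=freqs_all,
    )
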