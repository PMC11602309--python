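"""Shared configuration for the analysis scripts.

The synthetic panel emulates a northern inbred soybean germplasm collection:
300 fully homozygous accessions in 3 maturity-group-like subpopulations,
genotyped at 2,000 SNPs over 20 chromosomes, phenotyped for a seed-size
trait (SW100, g) and a seed-oil trait (SOC, %) in a 2-environment x
4-replicate trial.  Trait means, heritabilities and genetic CVs follow the
magnitudes typical of such panels (seed weight ~18 g at h2 ~ 0.82 and GCV
~ 12%; oil ~22% at h2 ~ 0.86 and GCV ~ 4%).
"""

import dataclasses
from pathlib import Path

from soycross.synthdata import SimConfig

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"

MASTER_SEED = 2026

# per-QTL genetic SD chosen so total genetic SD matches the target GCV:
# sd = GCV * mean * sqrt((1 - polygenic_fraction) / n_qtl)
CFG_SW = SimConfig(
    trait_id="SW100",
    trait_mean=18.4,
    allele_effect_sd=0.66,
    heritability_target=0.82,
    seed=MASTER_SEED,
)
CFG_SOC = dataclasses.replace(
    CFG_SW,
    trait_id="SOC",
    trait_mean=22.4,
    allele_effect_sd=0.28,
    heritability_target=0.86,
    seed=MASTER_SEED + 1,
)

# maturity-group-style contrast: earliest subpopulation vs the later ones
EARLY_GROUPS = {"G0"}
LATE_GROUPS = {"G1", "G2"}
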