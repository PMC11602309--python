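"""Simulate the germplasm panel: genotypes, map, groups and two traits.

Writes the canonical on-disk formats under scratch/data/ (plus a pickled
truth sidecar for the downstream scripts) and a panel summary under
results/.
"""

import pickle
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from analysis_config import CFG_SOC, CFG_SW, DATA, RESULTS

from soycross.iokit import write_genetic_map, write_genotypes, write_phenotypes
from soycross.synthdata import plant_trait, simulate_panel, simulate_phenotypes


def main():
    DATA.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    panel, subpop, gmap, truth_sw = simulate_panel(CFG_SW)
    pheno_sw = simulate_phenotypes(panel, truth_sw, CFG_SW)
    truth_soc = plant_trait(panel, truth_sw, CFG_SOC)
    pheno_soc = simulate_phenotypes(panel, truth_soc, CFG_SOC)

    write_genotypes(panel, DATA / "genotypes.tsv")
    write_genetic_map(gmap, DATA / "map.tsv")
    subpop.rename("group").to_csv(DATA / "groups.csv", index_label="accession")
    pheno = pd.concat([pheno_sw.data, pheno_soc.data], ignore_index=True)
    pheno.to_csv(DATA / "phenotypes.csv", index=False)
    with open(DATA / "truth.pkl", "wb") as fh:
        pickle.dump({"SW100": truth_sw, "SOC": truth_soc}, fh)

    summary = pd.DataFrame(
        [
            {
                "n_accessions": panel.n_accessions,
                "n_markers": panel.n_markers,
                "n_chromosomes": panel.markers["chromosome"].nunique(),
                "n_subpops": subpop.nunique(),
                "trait": trait,
                "planted_qtls": len(t.qtl_blocks),
                "realized_h2": round(t.realized_h2, 3),
            }
            for trait, t in [("SW100", truth_sw), ("SOC", truth_soc)]
        ]
    )
    summary.to_csv(RESULTS / "panel_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print(f"\npanel written to {DATA}; plot records: {len(pheno)}")


if __name__ == "__main__":
    main()
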