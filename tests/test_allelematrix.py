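import numpy as np
import pandas as pd
import pytest

from soycross.allelematrix import (
    QTLAlleleMatrix,
    allele_dynamics,
    build_matrix,
    gene_block_association,
    genes_near_qtl,
)
from soycross.iokit import GeneAnnotation
from soycross.rtmgwas import QTLRecord

from conftest import tiny_panel


def toy_matrix(alleles: dict, effects: dict, mean=20.0, trait="T"):
    """alleles: {qtl_id: list per accession}; effects: {qtl_id: {hap: eff}}."""
    n = len(next(iter(alleles.values())))
    acc = [f"A{i}" for i in range(n)]
    qtls = []
    for i, (qid, eff) in enumerate(effects.items()):
        col = alleles[qid]
        freqs = pd.Series(col).value_counts(normalize=True).to_dict()
        qtls.append(
            QTLRecord(
                qtl_id=qid,
                block_id=f"b{i}",
                chromosome="chr01",
                position_bp=100_000 * (i + 1),
                main_R2=10.0,
                p_main=1e-6,
                allele_effects=eff,
                allele_freqs={h: freqs.get(h, 0.0) for h in eff},
                block_index=i,
            )
        )
    frame = pd.DataFrame(alleles, index=acc)
    return QTLAlleleMatrix.from_frames(trait, mean, qtls, frame)


class TestBuildMatrix:
    def test_two_allele_qtl_has_two_distinct_cell_values(self):
        m = toy_matrix(
            {"q1": ["a", "b", "a", "b"]}, {"q1": {"a": 1.0, "b": -1.0}}
        )
        assert set(m.effects["q1"]) == {1.0, -1.0}

    def test_predicted_mean_equals_population_mean(self, small_run):
        matrix = build_matrix(
            small_run["scan"], small_run["blocks"], small_run["means"]
        )
        # frequency-weighted sum-to-zero coding: mean prediction = mean
        assert matrix.predicted_values().mean() == pytest.approx(
            matrix.population_mean, abs=1e-6
        )

    def test_cells_match_qtl_catalogue(self, small_run):
        matrix = build_matrix(
            small_run["scan"], small_run["blocks"], small_run["means"]
        )
        for q in matrix.qtls:
            col = matrix.alleles[q.qtl_id]
            eff = matrix.effects[q.qtl_id]
            for a, e in zip(col, eff):
                assert e == q.allele_effects[a]

    def test_matrix_frame_rows_ordered_by_positive_allele_frequency(self):
        m = toy_matrix(
            {
                "q1": ["a"] * 9 + ["b"],  # positive allele b freq 0.1
                "q2": ["c"] * 2 + ["d"] * 8,  # positive allele d freq 0.8
            },
            {"q1": {"a": -0.1, "b": 0.9}, "q2": {"c": -2.0, "d": 0.5}},
        )
        frame = m.to_frame()
        assert list(frame.index) == ["q1", "q2"]

    def test_round_trip_through_tsv(self, tmp_path, small_run):
        matrix = build_matrix(
            small_run["scan"], small_run["blocks"], small_run["means"]
        )
        path = tmp_path / "matrix.tsv"
        matrix.effects.to_csv(path, sep="\t")
        back = pd.read_csv(path, sep="\t", index_col=0)
        pd.testing.assert_frame_equal(back, matrix.effects, check_names=False)


class TestAlleleDynamics:
    def test_identity_contrast_all_inherited(self):
        m = toy_matrix(
            {"q1": ["a", "b", "a", "b"]}, {"q1": {"a": 1.0, "b": -1.0}}
        )
        groups = pd.Series({"A0": "G0", "A1": "G0", "A2": "G1", "A3": "G1"})
        dyn = allele_dynamics(m, groups, {"G0", "G1"}, {"G0", "G1"})
        assert dyn.emerged == (0, 0)
        assert dyn.excluded == (0, 0)
        assert dyn.inherited == dyn.early_total

    def test_allele_unique_to_early_group_counts_as_emerged(self):
        m = toy_matrix(
            {"q1": ["a", "b", "c", "a", "b", "a"]},
            {"q1": {"a": 0.5, "b": -0.5, "c": 0.2}},
        )
        groups = pd.Series(
            {"A0": "E", "A1": "E", "A2": "E", "A3": "L", "A4": "L", "A5": "L"}
        )
        dyn = allele_dynamics(m, groups, {"E"}, {"L"})
        assert dyn.emerged == (0, 1)  # allele c, positive effect
        assert dyn.inherited == (1, 1)
        assert dyn.excluded == (0, 0)

    def test_counts_match_set_arithmetic_oracle(self):
        rng = np.random.default_rng(12)
        n, n_qtl = 60, 10
        alleles = {}
        effects = {}
        for q in range(n_qtl):
            k = rng.integers(2, 5)
            haps = [f"h{j}" for j in range(k)]
            alleles[f"q{q}"] = [haps[i] for i in rng.integers(0, k, n)]
            effects[f"q{q}"] = {h: float(e) for h, e in zip(haps, rng.normal(0, 1, k))}
        m = toy_matrix(alleles, effects)
        labels = ["E" if i < 20 else "L" for i in range(n)]
        groups = pd.Series(labels, index=m.accession_ids)
        dyn = allele_dynamics(m, groups, {"E"}, {"L"})

        # brute-force set arithmetic
        early = {(q, a) for q in alleles for a in set(pd.Series(alleles[q])[:20])}
        late = {(q, a) for q in alleles for a in set(pd.Series(alleles[q])[20:])}

        def split(s):
            neg = sum(1 for q, a in s if effects[q][a] < 0)
            return (neg, len(s) - neg)

        assert dyn.early_total == split(early)
        assert dyn.late_total == split(late)
        assert dyn.inherited == split(early & late)
        assert dyn.emerged == split(early - late)
        assert dyn.excluded == split(late - early)

    def test_conservation_identities(self, small_run):
        matrix = build_matrix(
            small_run["scan"], small_run["blocks"], small_run["means"]
        )
        groups = small_run["subpop"]
        dyn = allele_dynamics(matrix, groups, {"G0"}, {"G1", "G2"})
        assert tuple(
            e + i for e, i in zip(dyn.emerged, dyn.inherited)
        ) == dyn.early_total
        assert tuple(
            x + i for x, i in zip(dyn.excluded, dyn.inherited)
        ) == dyn.late_total

    def test_empty_group_rejected(self):
        m = toy_matrix({"q1": ["a", "b"]}, {"q1": {"a": 1.0, "b": -1.0}})
        groups = pd.Series({"A0": "G0", "A1": "G0"})
        with pytest.raises(ValueError, match="empty group"):
            allele_dynamics(m, groups, {"G0"}, {"G9"})


def annotation_frame(rows):
    return GeneAnnotation(
        pd.DataFrame(
            rows, columns=["gene_id", "chromosome", "start", "end", "strand", "description"]
        )
    )


class TestGenesNearQTL:
    def make_block_set(self):
        from conftest import make_snpldb

        assign = np.array([[0, 1], [1, 0], [0, 1], [1, 1]])
        return make_snpldb(assign, [2, 2])

    def qtl(self, block_index=0):
        return QTLRecord(
            qtl_id="qT-1-1",
            block_id="b",
            chromosome="chr01",
            position_bp=25_000,
            main_R2=5.0,
            p_main=1e-4,
            allele_effects={"00": 1.0, "01": -1.0},
            allele_freqs={"00": 0.5, "01": 0.5},
            block_index=block_index,
        )

    def test_boundary_gene_inclusion_is_closed_interval(self):
        sset = self.make_block_set()
        block = sset.blocks[0]  # spans 1..50000
        ann = annotation_frame(
            [
                ("at_limit", "chr01", block.end_bp + 50_000, block.end_bp + 50_100, "+", ""),
                ("beyond", "chr01", block.end_bp + 50_001, block.end_bp + 50_200, "+", ""),
            ]
        )
        hits = genes_near_qtl(self.qtl(), ann, sset, flank=50_000)
        assert hits["gene_id"].tolist() == ["at_limit"]
        ann2 = annotation_frame(
            [("beyond", "chr01", block.end_bp + 50_001, block.end_bp + 50_200, "+", "")]
        )
        assert genes_near_qtl(self.qtl(), ann2, sset, flank=50_000).empty

    def test_matches_brute_force_interval_check(self):
        rng = np.random.default_rng(5)
        sset = self.make_block_set()
        block = sset.blocks[0]
        rows = []
        for i in range(200):
            start = int(rng.integers(1, 300_000))
            end = start + int(rng.integers(1, 20_000))
            rows.append((f"g{i}", "chr01", start, end, "+", ""))
        ann = annotation_frame(rows)
        flank = 50_000
        hits = set(genes_near_qtl(self.qtl(), ann, sset, flank=flank)["gene_id"])
        lo, hi = block.start_bp - flank, block.end_bp + flank
        expected = {
            g for g, c, s, e, *_ in rows if not (e < lo or s > hi)
        }
        assert hits == expected


class TestGeneBlockAssociation:
    def test_in_gene_block_member_snp_perfectly_associated(self):
        calls = np.array([[0, 0]] * 30 + [[1, 1]] * 30, dtype=np.int8)
        panel = tiny_panel(calls, spacing_bp=100)
        from soycross.snpldb import build_blocks

        sset = build_blocks(panel, d_prime_threshold=0.5)
        gene = pd.Series({"gene_id": "g", "chromosome": "chr01", "start": 1, "end": 200})
        res = gene_block_association(panel, sset, sset.blocks[0].block_id, gene)
        assert res["testable"] and res["significant"]
        assert res["min_p"] < 1e-10

    def test_no_in_gene_snp_untestable(self):
        calls = np.array([[0], [1], [0], [1]], dtype=np.int8)
        panel = tiny_panel(calls)
        from soycross.snpldb import build_blocks

        sset = build_blocks(panel)
        gene = pd.Series(
            {"gene_id": "g", "chromosome": "chr01", "start": 900_000, "end": 950_000}
        )
        res = gene_block_association(panel, sset, sset.blocks[0].block_id, gene)
        assert not res["testable"]

    def test_hand_chi_square_value(self):
        from scipy.stats import chi2_contingency

        # 2x2 table [[30,10],[10,30]]: expected all 20, chi2 = 4*100/20 = 20
        chi2, p, _, _ = chi2_contingency([[30, 10], [10, 30]], correction=False)
        assert chi2 == pytest.approx(20.0, abs=1e-12)
        assert p < 0.001
        # the same table arises from a block and an in-gene SNP
        calls = np.zeros((80, 2), dtype=np.int8)
        calls[:30] = [0, 0]
        calls[30:40] = [0, 1]
        calls[40:50] = [1, 0]
        calls[50:] = [1, 1]
        panel = tiny_panel(calls, spacing_bp=400_000)  # far apart: 2 blocks
        from soycross.snpldb import build_blocks

        sset = build_blocks(panel)
        assert sset.n_blocks == 2
        gene = pd.Series(
            {"gene_id": "g", "chromosome": "chr01", "start": 300_000, "end": 500_000}
        )
        res = gene_block_association(panel, sset, sset.blocks[0].block_id, gene)
        assert res["per_snp"][0]["chi2"] == pytest.approx(20.0, abs=1e-10)

    def test_permuted_snp_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(3)
        n = 100
        block_col = rng.integers(0, 2, n).astype(np.int8)
        rejections = 0
        n_perm = 200
        for _ in range(n_perm):
            snp = rng.permutation(block_col)
            calls = np.column_stack([block_col, snp]).astype(np.int8)
            panel = tiny_panel(calls, spacing_bp=400_000)
            from soycross.snpldb import build_blocks

            sset = build_blocks(panel)
            gene = pd.Series(
                {"gene_id": "g", "chromosome": "chr01", "start": 300_000, "end": 500_000}
            )
            res = gene_block_association(panel, sset, sset.blocks[0].block_id, gene)
            if res["testable"] and res["significant"]:
                rejections += 1
        assert rejections / n_perm == pytest.approx(0.05, abs=0.04)
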