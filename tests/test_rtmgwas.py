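from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from soycross.iokit import PhenotypeTable
from soycross.rtmgwas import (
    _block_dummies,
    _model_stats,
    _partial_f,
    classify_qei,
    similarity_eigenvectors,
    similarity_matrix,
    stage1_scan,
    stage2_stepwise,
)

from conftest import make_snpldb


def stepwise_instance(seed, n=50, m=6, planted=(0, 1), noise_sd=1.0):
    """Toy SNPLDB set with two planted block effects plus noise."""
    rng = np.random.default_rng(seed)
    n_haps = [int(rng.integers(2, 5)) for _ in range(m)]
    assign = np.column_stack([rng.integers(0, k, n) for k in n_haps])
    sset = make_snpldb(assign, n_haps)
    y = np.zeros(n)
    for j in planted:
        eff = rng.normal(0, 1.0, n_haps[j])
        y += eff[assign[:, j]]
    y += rng.normal(0, noise_sd, n)
    return sset, pd.Series(y, index=sset.accession_ids)


class TestSimilarity:
    def test_identical_and_complementary_accessions(self):
        assign = np.array([[0, 1, 0], [0, 1, 0], [1, 0, 1]])
        s = similarity_matrix(make_snpldb(assign, [2, 2, 2]))
        assert s[0, 1] == pytest.approx(1.0)
        assert s[0, 2] == pytest.approx(0.0)
        assert np.allclose(np.diag(s), 1.0)

    def test_hand_counted_toy(self):
        assign = np.array(
            [[0, 0, 0, 0], [0, 0, 1, 1], [1, 1, 1, 1], [0, 1, 0, 1], [2, 0, 1, 0]]
        )
        s = similarity_matrix(make_snpldb(assign, [3, 2, 2, 2]))
        # accession 0 vs 1 share blocks 0,1 -> 2/4
        assert s[0, 1] == pytest.approx(0.5)
        # accession 0 vs 4 share block 1 and block 3 -> wait: [0,0,0,0] vs
        # [2,0,1,0]: blocks 1 and 3 match -> 2/4
        assert s[0, 4] == pytest.approx(0.5)
        # [1,1,1,1] vs [0,1,0,1]: blocks 1 and 3 match -> 2/4
        assert s[2, 3] == pytest.approx(0.5)

    def test_eigenvectors_ordered_and_orthogonal(self, small_run):
        cov = small_run["cov"]
        assert np.all(np.diff(cov.eigenvalues) <= 1e-9)
        gram = cov.eigenvectors.T @ cov.eigenvectors
        assert np.allclose(gram, np.eye(cov.k), atol=1e-8)

    def test_k_at_least_n_rejected(self):
        assign = np.zeros((3, 2), dtype=int)
        with pytest.raises(ValueError, match="must be <"):
            similarity_eigenvectors(make_snpldb(assign, [1, 1]), k=3)


class TestStage1:
    def test_planted_strong_qtl_survives_with_tiny_p(self):
        rng = np.random.default_rng(1)
        n = 300
        n_haps = [3] + [2] * 9
        assign = np.column_stack([rng.integers(0, k, n) for k in n_haps])
        sset = make_snpldb(assign, n_haps)
        eff = np.array([-1.0, 0.0, 1.0])
        y = eff[assign[:, 0]] + rng.normal(0, 0.8, n)  # QTL explains ~35%
        means = pd.Series(y, index=sset.accession_ids)
        cov = similarity_eigenvectors(sset, k=3)
        survivors = dict(stage1_scan(sset, means, cov, alpha1=0.05))
        assert 0 in survivors
        assert survivors[0] < 1e-10

    def test_alpha_one_keeps_every_polymorphic_block(self, small_run):
        survivors = stage1_scan(
            small_run["blocks"], small_run["means"], small_run["cov"], alpha1=1.0
        )
        assert len(survivors) == small_run["blocks"].n_blocks

    def test_permuted_phenotype_survival_near_alpha(self, small_run):
        """Type-I error: ~5% of blocks survive on permuted phenotypes."""
        blocks, cov = small_run["blocks"], small_run["cov"]
        means = small_run["means"]
        rates = []
        rng = np.random.default_rng(0)
        for _ in range(20):
            perm = pd.Series(
                rng.permutation(means.to_numpy()), index=means.index
            )
            survivors = stage1_scan(blocks, perm, cov, alpha1=0.05)
            rates.append(len(survivors) / blocks.n_blocks)
        assert np.mean(rates) == pytest.approx(0.05, abs=0.02)


class TestStage2:
    def test_noiseless_single_qtl_recovered_exactly(self):
        rng = np.random.default_rng(7)
        n = 200
        n_haps = [4, 2, 3]
        assign = np.column_stack([rng.integers(0, k, n) for k in n_haps])
        sset = make_snpldb(assign, n_haps)
        freqs = sset.frequencies(0)
        eff = rng.normal(0, 1, 4)
        eff -= freqs @ eff  # frequency-weighted sum-to-zero truth
        y = 20.0 + eff[assign[:, 0]]
        means = pd.Series(y, index=sset.accession_ids)
        cov = similarity_eigenvectors(sset, k=2)
        survivors = stage1_scan(sset, means, cov)
        scan = stage2_stepwise(sset, survivors, means, cov, r2_cap=1.0)
        assert [q.block_index for q in scan.qtls] == [0]
        got = scan.qtls[0].allele_effects
        for h, e in zip(sset.blocks[0].haplotypes, eff):
            assert got[h] == pytest.approx(e, abs=1e-8)

    def test_zero_cap_selects_nothing(self, small_run):
        scan = stage2_stepwise(
            small_run["blocks"],
            small_run["survivors"],
            small_run["means"],
            small_run["cov"],
            r2_cap=0.0,
        )
        assert scan.qtls == []
        assert scan.unmapped_R2 == pytest.approx(0.0)

    def test_restriction_invariant_on_real_run(self, small_run):
        scan = small_run["scan"]
        assert scan.total_main_R2 <= 100 * scan.h2_cap + 1e-9
        assert sum(q.main_R2 for q in scan.qtls) == pytest.approx(scan.total_main_R2)

    def test_effects_sum_to_zero_frequency_weighted(self, small_run):
        for q in small_run["scan"].qtls:
            s = sum(q.allele_freqs[h] * e for h, e in q.allele_effects.items())
            assert s == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("seed", range(10))
    def test_selection_is_a_stable_set_of_the_alpha_rule(self, seed):
        """Exhaustive-enumeration oracle: the stepwise selection must be a
        stable subset (members significant, outsiders not), and must equal it
        when the stable subset is unique."""
        sset, means = stepwise_instance(seed)
        cov = similarity_eigenvectors(sset, k=2)
        survivors = [(j, 0.01) for j in range(sset.n_blocks)]
        scan = stage2_stepwise(sset, survivors, means, cov, alpha2=0.05, r2_cap=1.0)
        selected = {q.block_index for q in scan.qtls}

        y = means.to_numpy(float)
        n = len(y)
        X0 = np.column_stack([np.ones(n), cov.eigenvectors])
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        dummies = {}
        for j in range(sset.n_blocks):
            d, _ = _block_dummies(sset, j)
            if d.shape[1]:
                dummies[j] = d
        cands = sorted(dummies)
        stable = []
        for r in range(len(cands) + 1):
            for sub in map(list, combinations(cands, r)):
                if sub:
                    joint, pr2, pp = _model_stats(X0, y, dummies, sub, ss_tot)
                    if any(pp[j] > 0.05 for j in sub):
                        continue
                X_cur = (
                    np.column_stack([X0] + [dummies[j] for j in sub]) if sub else X0
                )
                if all(
                    _partial_f(X_cur, dummies[j], y)[0] > 0.05
                    for j in cands
                    if j not in sub
                ):
                    stable.append(set(sub))
        assert selected in stable
        if len(stable) == 1:
            assert selected == stable[0]

    def test_noise_augmentation_does_not_change_selection(self):
        """Adding pure-noise blocks to the survivor list leaves the selected
        set unchanged when they never reach significance."""
        sset, means = stepwise_instance(3, n=300, m=4, noise_sd=0.5)
        rng = np.random.default_rng(99)
        n = len(means)
        extra = np.column_stack([rng.integers(0, 2, n) for _ in range(20)])
        aug = np.column_stack([sset.assignment, extra])
        aug_set = make_snpldb(aug, [b.n_haplotypes for b in sset.blocks] + [2] * 20)
        cov = similarity_eigenvectors(sset, k=2)
        cov_aug = similarity_eigenvectors(aug_set, k=2)
        base = stage2_stepwise(
            sset, [(j, 0.01) for j in range(4)], means, cov, r2_cap=1.0
        )
        aug_scan = stage2_stepwise(
            aug_set, [(j, 0.01) for j in range(24)], means, cov_aug, r2_cap=1.0
        )
        base_sel = {q.block_index for q in base.qtls}
        aug_sel = {q.block_index for q in aug_scan.qtls if q.block_index < 4}
        assert base_sel == aug_sel


def plot_table(assign_col, effects_by_env, n_reps=3, noise_sd=0.1, seed=0, extra=None):
    """Plot-level phenotype with per-environment block effects."""
    rng = np.random.default_rng(seed)
    n = len(assign_col)
    rows = []
    for e, env_eff in enumerate(effects_by_env):
        for i in range(n):
            g = env_eff[assign_col[i]] + (extra[i] if extra is not None else 0.0)
            for r in range(n_reps):
                rows.append(
                    {
                        "accession": f"A{i:03d}",
                        "environment": f"E{e + 1}",
                        "replicate": f"R{r + 1}",
                        "trait": "T",
                        "value": 20 + g + rng.normal(0, noise_sd),
                    }
                )
    return PhenotypeTable(pd.DataFrame(rows))


class TestClassifyQEI:
    def make_sets(self, seed=5, n=200):
        rng = np.random.default_rng(seed)
        n_haps = [2, 2, 2, 2]
        assign = np.column_stack([rng.integers(0, k, n) for k in n_haps])
        return make_snpldb(assign, n_haps), assign

    def test_planted_qei_only_qtl_enters_interaction_scan(self):
        sset, assign = self.make_sets()
        # block 0: main effect; block 1: pure QEI (opposite effects by env)
        main = np.array([-1.0, 1.0])
        qei = np.array([-0.8, 0.8])
        pheno = plot_table(
            assign[:, 0],
            [main, main],
            extra=None,
            seed=1,
        )
        # add block-1 interaction on top
        df = pheno.data.copy()
        env_sign = {"E1": 1.0, "E2": -1.0}
        acc_idx = {f"A{i:03d}": i for i in range(len(assign))}
        df["value"] += [
            env_sign[e] * qei[assign[acc_idx[a], 1]]
            for a, e in zip(df["accession"], df["environment"])
        ]
        pheno = PhenotypeTable(df)
        means = pheno.accession_means("T")
        cov = similarity_eigenvectors(sset, k=2)
        survivors = stage1_scan(sset, means, cov, alpha1=0.5)
        if 1 not in dict(survivors):
            survivors.append((1, 0.5))
        scan = stage2_stepwise(sset, survivors, means, cov, r2_cap=1.0, trait="T")
        scan = classify_qei(scan, sset, pheno, cov, alpha=0.05)
        by_block = {q.block_index: q.classification for q in scan.qtls}
        assert by_block.get(0) in {"main_only", "both"}
        assert by_block.get(1) == "qei_only"

    def test_planted_main_only_rarely_flagged(self):
        flags = 0
        for seed in range(20):
            sset, assign = self.make_sets(seed=seed, n=150)
            main = np.array([-1.0, 1.0])
            pheno = plot_table(assign[:, 0], [main, main], seed=seed + 100, noise_sd=0.3)
            means = pheno.accession_means("T")
            cov = similarity_eigenvectors(sset, k=2)
            survivors = stage1_scan(sset, means, cov)
            scan = stage2_stepwise(sset, survivors, means, cov, r2_cap=1.0, trait="T")
            scan = classify_qei(scan, sset, pheno, cov, alpha=0.05)
            main_qtl = [q for q in scan.qtls if q.block_index == 0]
            if main_qtl and main_qtl[0].classification == "both":
                flags += 1
        assert flags <= 2

    def test_duplicated_environment_has_zero_interaction(self):
        sset, assign = self.make_sets(seed=9, n=100)
        main = np.array([-1.0, 1.0])
        pheno = plot_table(assign[:, 0], [main], n_reps=2, seed=2, noise_sd=0.2)
        # duplicate environment means as a second environment
        df = pheno.data.copy()
        dup = df.copy()
        dup["environment"] = "E2"
        pheno2 = PhenotypeTable(pd.concat([df, dup], ignore_index=True))
        means = pheno2.accession_means("T")
        cov = similarity_eigenvectors(sset, k=2)
        survivors = stage1_scan(sset, means, cov)
        scan = stage2_stepwise(sset, survivors, means, cov, r2_cap=1.0, trait="T")
        scan = classify_qei(scan, sset, pheno2, cov, alpha=0.05)
        for q in scan.qtls:
            if q.classification != "qei_only":
                assert q.p_qei == pytest.approx(1.0)
                assert q.classification == "main_only"

    def test_single_environment_all_main_only(self):
        sset, assign = self.make_sets(seed=3, n=100)
        pheno = plot_table(assign[:, 0], [np.array([-1.0, 1.0])], seed=4)
        means = pheno.accession_means("T")
        cov = similarity_eigenvectors(sset, k=2)
        survivors = stage1_scan(sset, means, cov)
        scan = stage2_stepwise(sset, survivors, means, cov, r2_cap=1.0, trait="T")
        scan = classify_qei(scan, sset, pheno, cov)
        assert all(q.classification == "main_only" for q in scan.qtls)
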