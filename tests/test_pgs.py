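"""Weight-table parsing, allele matching, and polygenic scoring."""

import numpy as np
import pandas as pd
import pytest

import heightrez as hr
from heightrez.pgs import MatchedWeights


def write_weights(tmp_path, rows, header="variant_id\teffect_allele\tother_allele\tweight"):
    path = tmp_path / "weights.tsv"
    path.write_text(header + "\n" + "\n".join(rows) + ("\n" if rows else ""))
    return path


def make_geno(dosages, alleles, ids=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    meta = pd.DataFrame({
        "variant_id": [f"rs{j+1}" for j in range(m)],
        "chrom": 1, "pos": np.arange(m) + 1,
        "allele1": [a[0] for a in alleles],
        "allele2": [a[1] for a in alleles],
        "freq": np.nanmean(dosages, axis=0) / 2,
    })
    ids = ids or [f"P{i}" for i in range(n)]
    return hr.GenotypeMatrix(dosages=dosages, snp_meta=meta, ids=np.array(ids))


class TestReadWeightTable:
    def test_well_formed(self, tmp_path):
        path = write_weights(tmp_path, ["rs1\tA\tG\t0.5", "rs2\tC\tT\t-0.2",
                                        "rs3\tG\tA\t1e-3"])
        wt = hr.read_weight_table(path)
        assert len(wt) == 3
        assert wt.table["weight"].tolist() == [0.5, -0.2, 0.001]

    def test_duplicate_id_names_the_offender(self, tmp_path):
        path = write_weights(tmp_path, ["rs1\tA\tG\t0.5", "rs1\tC\tT\t0.1"])
        with pytest.raises(hr.DataError, match="rs1"):
            hr.read_weight_table(path)

    def test_non_numeric_weight_reports_line(self, tmp_path):
        path = write_weights(tmp_path, ["rs1\tA\tG\t0.5", "rs2\tC\tT\tnotanumber"])
        with pytest.raises(hr.DataError, match="line"):
            hr.read_weight_table(path)

    def test_missing_column(self, tmp_path):
        path = write_weights(tmp_path, ["rs1\tA\t0.5"], header="variant_id\teffect_allele\tweight")
        with pytest.raises(hr.DataError, match="missing"):
            hr.read_weight_table(path)


class TestMatchAlleles:
    @pytest.fixture
    def weights(self):
        return hr.WeightTable(pd.DataFrame({
            "variant_id": ["rs1", "rs2", "rs3", "rs4"],
            "effect_allele": ["A", "A", "A", "A"],
            "other_allele": ["G", "G", "G", "G"],
            "weight": [0.5, -0.2, 1.0, 0.7],
        }))

    def test_keep_flip_exclude(self, weights):
        geno = make_geno(np.zeros((2, 3)), [("A", "G"), ("G", "A"), ("A", "C")])
        matched = hr.match_alleles(weights, geno.snp_meta)
        assert matched.snp_index.tolist() == [0, 1]
        assert matched.flip.tolist() == [False, True]
        reasons = dict(zip(matched.excluded["variant_id"], matched.excluded["reason"]))
        assert reasons == {"rs3": "allele-mismatch", "rs4": "absent"}
        assert len(matched.weights) + len(matched.excluded) == len(weights)

    def test_exclusion_count_matches_set_oracle(self):
        rng = np.random.default_rng(8)
        m = 60
        bases = np.array(list("ACGT"))
        meta_alleles = [tuple(rng.choice(bases, size=2, replace=False)) for _ in range(m)]
        geno = make_geno(np.zeros((2, m)), meta_alleles)
        wt_rows = []
        for j in range(m):
            a, b = rng.choice(bases, size=2, replace=False)
            wt_rows.append((f"rs{j+1}", a, b, 0.1))
        wt = hr.WeightTable(pd.DataFrame(wt_rows, columns=["variant_id",
                            "effect_allele", "other_allele", "weight"]))
        matched = hr.match_alleles(wt, geno.snp_meta)
        # oracle: per-SNP set comparison
        n_mismatch = sum({a, b} != set(meta_alleles[j])
                         for j, (_, a, b, _) in enumerate(wt_rows))
        assert len(matched.excluded) == n_mismatch
        assert len(matched.weights) == m - n_mismatch

    def test_drop_ambiguous_flag(self, weights):
        geno = make_geno(np.zeros((2, 4)),
                         [("A", "T"), ("C", "G"), ("A", "G"), ("A", "G")])
        wt = hr.WeightTable(pd.DataFrame({
            "variant_id": ["rs1", "rs2", "rs3"],
            "effect_allele": ["A", "C", "A"],
            "other_allele": ["T", "G", "G"],
            "weight": [0.1, 0.2, 0.3]}))
        matched = hr.match_alleles(wt, geno.snp_meta, drop_ambiguous=True)
        assert set(matched.excluded["reason"]) == {"strand-ambiguous"}
        assert len(matched.weights) == 1


class TestComputePgs:
    def test_hand_dot_product(self):
        geno = make_geno([[2, 1, 0]], [("A", "G")] * 3)
        matched = MatchedWeights(snp_index=np.array([0, 1, 2]),
                                 weights=np.array([0.5, -0.2, 1.0]),
                                 flip=np.zeros(3, bool),
                                 excluded=pd.DataFrame())
        assert hr.compute_pgs(geno, matched)[0] == pytest.approx(0.8)

    def test_zero_weights_zero_scores(self, small_sim):
        _, geno, _, _ = small_sim
        wt = hr.WeightTable(pd.DataFrame({
            "variant_id": geno.snp_meta["variant_id"],
            "effect_allele": geno.snp_meta["allele1"],
            "other_allele": geno.snp_meta["allele2"],
            "weight": 0.0}))
        matched = hr.match_alleles(wt, geno.snp_meta)
        assert np.allclose(hr.compute_pgs(geno, matched), 0.0)

    def test_flip_symmetry_all_snps(self, small_sim):
        """Swapping every SNP's allele labels (dosage -> 2-d) leaves scores
        unchanged."""
        _, geno, _, truth = small_sim
        wt = hr.WeightTable(hr.weight_table_from_truth(geno, truth))
        matched = hr.match_alleles(wt, geno.snp_meta)
        scores = hr.compute_pgs(geno, matched)
        swapped = hr.GenotypeMatrix(
            dosages=2.0 - geno.dosages,
            snp_meta=geno.snp_meta.rename(columns={"allele1": "allele2",
                                                   "allele2": "allele1"}),
            ids=geno.ids)
        matched2 = hr.match_alleles(wt, swapped.snp_meta)
        assert matched2.flip.all()
        scores2 = hr.compute_pgs(swapped, matched2)
        np.testing.assert_allclose(scores, scores2, atol=1e-10)

    def test_brute_force_equivalence(self):
        rng = np.random.default_rng(30)
        dosages = rng.integers(0, 3, size=(50, 100)).astype(float)
        alleles = [("A", "G")] * 100
        geno = make_geno(dosages, alleles)
        w = rng.normal(size=100)
        flip = rng.random(100) < 0.5
        matched = MatchedWeights(snp_index=np.arange(100), weights=w,
                                 flip=flip, excluded=pd.DataFrame())
        scores = hr.compute_pgs(geno, matched)
        brute = np.array([
            sum(w[j] * ((2 - dosages[i, j]) if flip[j] else dosages[i, j])
                for j in range(100)) for i in range(50)])
        np.testing.assert_allclose(scores, brute, atol=1e-12)

    def test_linearity_over_weight_tables(self):
        rng = np.random.default_rng(31)
        dosages = rng.integers(0, 3, size=(20, 30)).astype(float)
        geno = make_geno(dosages, [("A", "G")] * 30)
        w1, w2 = rng.normal(size=30), rng.normal(size=30)

        def score(w):
            m = MatchedWeights(snp_index=np.arange(30), weights=w,
                               flip=np.zeros(30, bool), excluded=pd.DataFrame())
            return hr.compute_pgs(geno, m)

        np.testing.assert_allclose(score(w1 + w2), score(w1) + score(w2),
                                   atol=1e-10)

    def test_missing_dosage_mean_imputed(self):
        d = np.array([[2.0, 1.0], [0.0, np.nan], [1.0, 1.0], [1.0, 0.0]])
        geno = make_geno(d, [("A", "G")] * 2)
        matched = MatchedWeights(snp_index=np.array([0, 1]),
                                 weights=np.array([1.0, 1.0]),
                                 flip=np.zeros(2, bool), excluded=pd.DataFrame())
        scores = hr.compute_pgs(geno, matched)
        mean_d2 = np.nanmean(d[:, 1])
        assert scores[1] == pytest.approx(0.0 + mean_d2)

    def test_out_of_range_dosage_names_participant(self):
        geno = make_geno([[2.5]], [("A", "G")], ids=["X1"])
        matched = MatchedWeights(snp_index=np.array([0]),
                                 weights=np.array([1.0]),
                                 flip=np.zeros(1, bool), excluded=pd.DataFrame())
        with pytest.raises(hr.DataError, match="X1"):
            hr.compute_pgs(geno, matched)
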