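import numpy as np
import pandas as pd
import pytest

from homoeoseq.config import ConfigError, DEParams, DEFAULT_REPLICATE_SCHEME
from homoeoseq.expression import (
    assign_reads,
    block_concordance,
    estimate_dispersion,
    glm_wald_test,
    merge_pseudo_replicates,
    nb_exact_test,
    size_factors,
    tissue_nb_test,
)
from homoeoseq.io import GeneReads, ReadSet
from homoeoseq.phasing import HomoeologSequenceSet, SplitRecord
from homoeoseq.simulate import SimulationParams, simulate_counts


def _seqset(length=40, sites=(10, 30)):
    seq_a = np.zeros(length, dtype=np.uint8)
    seq_b = np.zeros(length, dtype=np.uint8)
    for s in sites:
        seq_b[s] = 1
    rec = SplitRecord(transcript="g", block_id=1, start=0, end=length,
                      seq_a=seq_a, seq_b=seq_b,
                      phased_positions=np.array(sites, dtype=np.int64),
                      fixed_positions=np.empty(0, dtype=np.int64))
    return {"g": HomoeologSequenceSet(transcript="g", records=[rec])}


def _readset(starts, seqs, pair_ids, variety="Svevo", tissue="leaf"):
    seq = np.array(seqs, dtype=np.uint8)
    gr = GeneReads(start=np.array(starts), seq=seq,
                   qual=np.full(seq.shape, 30, dtype=np.uint8),
                   pair_id=np.array(pair_ids))
    return ReadSet(variety=variety, tissue=tissue, genes={"g": gr})


class TestAssignReads:
    def test_pair_without_divergent_site_dropped(self):
        # pair covering [0,5) and [20,25): no phased site at 10 or 30
        rs = _readset([0, 20], [[0] * 5, [0] * 5], [0, 0])
        counts = assign_reads(rs, _seqset())
        assert counts.to_numpy().sum() == 0

    def test_pair_matching_a_allele_counted_once_for_a(self):
        rs = _readset([8, 20], [[0] * 5, [0] * 5], [0, 0])   # covers site 10, ref = A allele
        counts = assign_reads(rs, _seqset())
        assert int(counts.loc[("g", "block1", "A")].iloc[0]) == 1
        assert int(counts.loc[("g", "block1", "B")].iloc[0]) == 0

    def test_pair_matching_b_allele_counted_for_b(self):
        seq = [0, 0, 1, 0, 0]                                # alt base at site 10
        rs = _readset([8, 20], [seq, [0] * 5], [0, 0])
        counts = assign_reads(rs, _seqset())
        assert int(counts.loc[("g", "block1", "B")].iloc[0]) == 1

    def test_conflicting_votes_tie_dropped(self):
        # mate 1 votes A at site 10, mate 2 votes B at site 30
        rs = _readset([8, 28], [[0] * 5, [0, 0, 1, 0, 0]], [0, 0])
        counts = assign_reads(rs, _seqset())
        assert counts.to_numpy().sum() == 0


class TestMergePseudoReplicates:
    def _counts(self, varieties, tissues=("grain", "leaf", "root"), value=10):
        cols = [f"{v}:{t}" for v in varieties for t in tissues]
        idx = pd.MultiIndex.from_tuples(
            [("g1", "b1", "A"), ("g1", "b1", "B")],
            names=["gene", "block", "subgenome"])
        return pd.DataFrame(value, index=idx, columns=cols)

    def test_default_scheme_gives_fifteen_columns(self):
        varieties = [v for g in DEFAULT_REPLICATE_SCHEME.values() for v in g]
        merged = merge_pseudo_replicates(self._counts(varieties))
        assert merged.shape[1] == 15
        assert list(merged.columns.get_level_values("tissue"))[:5] == ["grain"] * 5

    def test_total_counts_conserved(self):
        varieties = [v for g in DEFAULT_REPLICATE_SCHEME.values() for v in g]
        counts = self._counts(varieties)
        merged = merge_pseudo_replicates(counts)
        assert merged.to_numpy().sum() == counts.to_numpy().sum()

    def test_singleton_scheme_is_identity(self):
        params = DEParams(pseudo_replicate_scheme={"g1": ("Svevo",), "g2": ("Kofa",)})
        counts = self._counts(["Svevo", "Kofa"])
        merged = merge_pseudo_replicates(counts, params)
        assert merged.to_numpy().sum() == counts.to_numpy().sum()
        assert merged.shape == (2, 6)

    def test_unscheduled_variety_rejected(self):
        with pytest.raises(ConfigError, match="absent"):
            merge_pseudo_replicates(self._counts(["NotAVariety"]))


class TestSizeFactors:
    def test_doubled_column_has_doubled_factor(self, rng):
        col = rng.integers(10, 100, size=50).astype(float)
        mat = np.column_stack([col, 2 * col])
        f = size_factors(mat)
        assert f[1] / f[0] == pytest.approx(2.0)

    def test_single_column_factor_one(self, rng):
        mat = rng.integers(1, 100, size=(30, 1)).astype(float)
        assert size_factors(mat)[0] == pytest.approx(1.0)

    def test_depth_multipliers_recovered(self):
        params = SimulationParams(n_genes=2000, bias_fraction=0.0, seed=21)
        counts, _, depths = simulate_counts(params)
        f = size_factors(counts)
        # factors are defined up to a common scale
        ratio = f / depths
        rel = ratio / np.exp(np.mean(np.log(ratio)))
        assert np.abs(rel - 1).max() < 0.05

    def test_no_all_positive_row_warns(self):
        mat = np.array([[0.0, 5.0], [5.0, 0.0]])
        with pytest.warns(UserWarning, match="positive"):
            size_factors(mat)


class TestDispersion:
    def _cols(self, n_per=5, tissues=("grain", "leaf", "root")):
        return np.repeat(tissues, n_per)

    def test_poisson_counts_give_small_trend(self, rng):
        mu = rng.uniform(100, 1000, size=1500)
        mat = rng.poisson(mu[:, None], size=(1500, 15)).astype(float)
        alpha, (a0, a1), _ = estimate_dispersion(mat, np.ones(15), self._cols())
        assert a0 + a1 / 100 < 0.05

    def test_constant_counts_fall_back_to_trend_floor(self):
        mat = np.full((10, 15), 50.0)
        alpha, (a0, a1), raw = estimate_dispersion(mat, np.ones(15), self._cols())
        assert (raw <= 0).all()
        assert (alpha >= 1e-8).all()

    def test_nb_dispersion_recovered_within_twenty_percent(self, rng):
        alpha_true = 0.2
        size = 1 / alpha_true
        mu = rng.uniform(50, 500, size=2000)
        mat = rng.negative_binomial(size, size / (size + mu[:, None]),
                                    size=(2000, 15)).astype(float)
        alpha, (a0, a1), _ = estimate_dispersion(mat, np.ones(15), self._cols())
        assert np.median(alpha) == pytest.approx(alpha_true, rel=0.2)


class TestNbExactTest:
    def test_identical_counts_p_one(self):
        s = np.ones(5)
        assert nb_exact_test(200, 200, s, 0.05) == pytest.approx(1.0)

    def test_extreme_split_small_p(self):
        s = np.ones(5)
        assert nb_exact_test(400, 10, s, 0.05) < 1e-6

    def test_symmetry_in_arguments(self):
        s = np.ones(5)
        assert nb_exact_test(120, 300, s, 0.1) == pytest.approx(
            nb_exact_test(300, 120, s, 0.1))

    def test_asymptotic_branch_tracks_exact(self):
        s = np.ones(5)
        exact = nb_exact_test(6000, 5000, s, 0.02)
        approx = nb_exact_test(6000, 5000, s, 0.02, exact_limit=1000)
        assert approx == pytest.approx(exact, rel=0.25)


@pytest.fixture(scope="module")
def biased_counts():
    params = SimulationParams(n_genes=120, bias_fraction=0.5, bias_log2fc=2.0,
                              expr_mean=800.0, seed=31)
    counts, truth, _ = simulate_counts(params)
    return counts, truth


class TestTests:

    def test_glm_swapping_subgenomes_negates_lfc(self, biased_counts):
        counts, _ = biased_counts
        swapped = counts.copy()
        swapped.index = pd.MultiIndex.from_tuples(
            [(g, b, "B" if s == "A" else "A") for g, b, s in counts.index],
            names=counts.index.names)
        swapped = swapped.sort_index()
        r1 = glm_wald_test(counts).set_index("gene")
        r2 = glm_wald_test(swapped).set_index("gene")
        assert np.allclose(r1["lfc"], -r2["lfc"], atol=1e-9)
        assert np.allclose(r1["pvalue"], r2["pvalue"], rtol=1e-6)

    def test_glm_detects_injected_bias_direction(self, biased_counts):
        counts, truth = biased_counts
        res = glm_wald_test(counts).set_index("gene").join(truth)
        sig = res[res["significant"]]
        assert len(sig) > 0
        assert (np.sign(sig["lfc"]) == np.sign(sig["log2_ratio"])).all()
        assert res.loc[~res["biased"], "significant"].sum() == 0

    def test_tissue_test_reports_direction_split(self, biased_counts):
        counts, truth = biased_counts
        res = tissue_nb_test(counts, "grain").set_index("gene").join(truth)
        sig = res[res["significant"]]
        assert set(sig["direction"]) <= {"A-up", "B-up"}
        a_up = sig[sig["direction"] == "A-up"]
        assert (a_up["log2_ratio"] > 0).all()

    def test_tissue_test_family_wise_error_controlled(self):
        params = SimulationParams(n_genes=1000, bias_fraction=0.0, seed=41)
        counts, _, _ = simulate_counts(params)
        res = pd.concat([tissue_nb_test(counts, t) for t in ("grain", "leaf", "root")])
        assert int(res["significant"].sum()) == 0

    def test_lfc_cap_excludes_extreme_units(self):
        idx = pd.MultiIndex.from_tuples(
            [("g1", "b1", "A"), ("g1", "b1", "B")],
            names=["gene", "block", "subgenome"])
        cols = pd.MultiIndex.from_tuples(
            [(t, f"rep{r}") for t in ("grain", "leaf", "root") for r in range(1, 6)],
            names=["tissue", "group"])
        mat = pd.DataFrame(0, index=idx, columns=cols)
        mat.loc[("g1", "b1", "A")] = 4000   # |lfc| ~ 12.9 > 7
        res = glm_wald_test(mat, sf=np.ones(15),
                            dispersions=pd.Series(0.05, index=idx))
        assert not res["significant"].any()
        assert res["lfc"].abs().iloc[0] > 7


class TestConcordance:
    def _res(self, rows):
        return pd.DataFrame(rows, columns=["gene", "block", "lfc"])

    def test_same_sign_blocks_concordant(self):
        df = block_concordance(self._res([("g", "b1", 1.2), ("g", "b2", 0.3)]))
        assert df.attrs["n_genes"] == 1 and df.attrs["n_concordant"] == 1

    def test_opposite_sign_blocks_discordant(self):
        df = block_concordance(self._res([("g", "b1", 1.2), ("g", "b2", -0.4)]))
        assert df.attrs["n_concordant"] == 0

    def test_single_block_genes_not_considered(self):
        df = block_concordance(self._res([("g", "b1", 1.2)]))
        assert df.attrs["n_genes"] == 0
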