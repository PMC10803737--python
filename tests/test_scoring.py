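import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mars.errors import DataError, ProviderError
from mars.psm_io import AMINO_ACIDS, CandidateRecord, FilterConfig, SpectrumCandidateSet
from mars.scoring import (
    DEFAULT_WEIGHTS,
    ModelWeights,
    PssmMProvider,
    RNormalization,
    Rescorer,
    RTCalibration,
    ScoreVector,
    TableMProvider,
    TableRTPredictor,
    calibrate_rt,
    composite_score,
    m_score,
    r_score,
    toy_pssm_rank,
)
from mars.synthetic_data import MotifModel


class TestMScore:
    def test_minimum_over_alleles(self):
        provider = TableMProvider(
            {("PEPTLDEK", "HLA-A*02:01"): 0.5, ("PEPTLDEK", "HLA-B*07:02"): 12.0}
        )
        assert m_score("PEPTLDEK", ["HLA-A*02:01", "HLA-B*07:02"], provider) == 0.5

    def test_single_allele_identity(self):
        provider = TableMProvider({("PEPTLDEK", "HLA-A*02:01"): 3.2})
        assert m_score("PEPTLDEK", ["HLA-A*02:01"], provider) == 3.2

    def test_table_loaded_rank_from_file(self, tmp_path):
        # the rank printed for an identified lncRNA-derived 9-mer
        path = tmp_path / "prov.tsv"
        path.write_text("peptide\tallele\tm_rank\nVLLTDVFQK\tHLA-A*03:01\t0.181\n")
        provider = TableMProvider.from_tsv(path)
        assert m_score("VLLTDVFQK", ["HLA-A*03:01"], provider) == 0.181

    def test_missing_allele_names_it(self):
        provider = TableMProvider({("PEPTLDEK", "HLA-A*02:01"): 0.5})
        with pytest.raises(ProviderError, match="HLA-B\\*07:02"):
            m_score("PEPTLDEK", ["HLA-B*07:02"], provider)


class TestToyPssmRank:
    def test_consensus_scores_near_top(self):
        pssm = MotifModel.default(anchor_prob=0.9).pssms[9]
        consensus = "".join(AMINO_ACIDS[i] for i in pssm.argmax(axis=1))
        rank = toy_pssm_rank(consensus, pssm, n_background=10_000, seed=3)
        assert rank <= 1.0

    def test_uninformative_pssm_ranks_are_uniform(self):
        # under a motif-free (random, continuous) PSSM, random queries draw
        # their score from the background distribution, so ranks ~ U(0,100]
        rng = np.random.default_rng(5)
        pssm = rng.normal(size=(9, 20))
        aas = np.array(list(AMINO_ACIDS))
        ranks = [
            toy_pssm_rank("".join(rng.choice(aas, 9)), pssm, n_background=500, seed=11)
            for _ in range(200)
        ]
        assert 40.0 < float(np.median(ranks)) < 60.0
        assert 20.0 < float(np.percentile(ranks, 25)) < 30.0

    def test_rank_is_fraction_of_background_at_least_query(self):
        # query strictly above all background draws leaves only itself-level
        # mass: rank is bounded by the counting resolution
        motif = MotifModel.default(anchor_prob=0.95)
        pssm = motif.pssms[9]
        consensus = "".join(AMINO_ACIDS[i] for i in pssm.argmax(axis=1))
        n = 1000
        rank = toy_pssm_rank(consensus, pssm, n_background=n, seed=2)
        assert rank == pytest.approx(100.0 * round(rank * n / 100.0) / n)
        assert rank <= 100.0 / n * 5  # a strong consensus beats ~all draws

    def test_determinism_and_length_mismatch(self):
        pssm = np.zeros((9, 20))
        r1 = toy_pssm_rank("AAAAKAAAK", pssm, seed=9)
        r2 = toy_pssm_rank("AAAAKAAAK", pssm, seed=9)
        assert r1 == r2
        with pytest.raises(DataError, match="incompatible"):
            toy_pssm_rank("AAAAKAAAKK", pssm)

    def test_provider_matches_function_convention(self):
        motif = MotifModel.default(anchor_prob=0.9)
        provider = PssmMProvider({"HLA-A*02:01": motif.pssms}, n_background=2000, seed=1)
        rank = provider.rank("ALAKAAAAV", "HLA-A*02:01")
        assert 0.0 <= rank <= 100.0
        with pytest.raises(ProviderError, match="allele"):
            provider.rank("ALAKAAAAV", "HLA-B*07:02")
        with pytest.raises(ProviderError, match="length"):
            provider.rank("AAAA", "HLA-A*02:01")


class TestCalibrateRT:
    def test_exact_affine_recovery(self):
        predictor = TableRTPredictor({f"PEP{aa}LDEK": float(i) for i, aa in enumerate("ACDEFGHK")})
        anchors = [(f"PEP{aa}LDEK", 2.0 * i + 5.0) for i, aa in enumerate("ACDEFGHK")]
        cal = calibrate_rt(anchors, predictor)
        assert cal.slope == pytest.approx(2.0)
        assert cal.intercept == pytest.approx(5.0)
        assert cal.residual_sd == pytest.approx(0.0, abs=1e-9)
        assert cal.anchor_count == 8

    def test_noisy_recovery_within_tolerance(self):
        rng = np.random.default_rng(42)
        raw = rng.uniform(0, 30, size=200)
        obs = 2.0 * raw + 5.0 + rng.normal(0, 0.5, size=200)
        peptides = [f"P{i:03d}EPTLDEK" for i in range(200)]  # ids only
        predictor = TableRTPredictor(dict(zip(peptides, raw)))
        cal = calibrate_rt(list(zip(peptides, obs)), predictor)
        assert cal.slope == pytest.approx(2.0, abs=0.05)
        assert cal.residual_sd == pytest.approx(0.5, abs=0.15)

    def test_single_anchor_rejected(self):
        predictor = TableRTPredictor({"PEPTLDEK": 1.0})
        with pytest.raises(DataError, match="lower the ALC threshold"):
            calibrate_rt([("PEPTLDEK", 10.0)], predictor)

    def test_zero_variance_rejected(self):
        predictor = TableRTPredictor({"PEPTLDEK": 1.0, "PEPTLDKE": 1.0})
        with pytest.raises(DataError, match="variance"):
            calibrate_rt([("PEPTLDEK", 10.0), ("PEPTLDKE", 11.0)], predictor)


class TestRScore:
    NORM = RNormalization(delta_min=0.5, delta_max=4.5)

    @pytest.mark.parametrize(
        "delta,expected", [(0.5, 100.0), (4.5, 0.0), (2.5, 50.0)]
    )
    def test_endpoints_and_midpoint(self, delta, expected):
        assert r_score(delta, self.NORM) == pytest.approx(expected)

    def test_clamping_and_degenerate(self):
        assert r_score(0.0, self.NORM) == 100.0
        assert r_score(99.0, self.NORM) == 0.0
        assert r_score(3.0, RNormalization(1.0, 1.0)) == 100.0

    def test_negative_delta_rejected(self):
        with pytest.raises(DataError):
            r_score(-0.1, self.NORM)

    def test_shift_invariance(self):
        # shifting all deltas and both bounds by a constant leaves R unchanged
        for shift in (0.0, 1.7, 10.0):
            norm = RNormalization(0.5 + shift, 4.5 + shift)
            assert r_score(2.0 + shift, norm) == pytest.approx(
                r_score(2.0, self.NORM)
            )


class TestCompositeScore:
    def test_maxima_give_100(self):
        sv = ScoreVector(a=100, m=0, r=100)
        for w in (ModelWeights(0, 0), ModelWeights(0.71, 0.08), ModelWeights(0.5, 0.5)):
            assert composite_score(sv, w) == pytest.approx(100.0)

    def test_fixed_weights_worked_example(self):
        assert composite_score(
            ScoreVector(a=80, m=10, r=50), ModelWeights(0.71, 0.08)
        ) == pytest.approx(84.7)

    def test_two_factor_reduction(self):
        assert composite_score(
            ScoreVector(a=60, m=5, r=33.3), ModelWeights(0.3, 0.0)
        ) == pytest.approx(70.5)

    def test_invalid_weights_rejected(self):
        with pytest.raises(DataError):
            ModelWeights(0.7, 0.4)
        with pytest.raises(DataError):
            ModelWeights(-0.1, 0.0)

    @given(
        a=st.floats(0, 100),
        m=st.floats(0, 100),
        r=st.floats(0, 100),
        alpha=st.floats(0, 1),
        frac=st.floats(0, 1),
    )
    @settings(max_examples=300, deadline=None)
    def test_range_and_monotonicity(self, a, m, r, alpha, frac):
        beta = (1.0 - alpha) * frac
        w = ModelWeights(alpha, beta)
        c = composite_score(ScoreVector(a, m, r), w)
        assert -1e-9 <= c <= 100 + 1e-9
        # monotone: better components never lower the composite
        assert composite_score(ScoreVector(min(a + 5, 100), m, r), w) >= c - 1e-9
        assert composite_score(ScoreVector(a, max(m - 5, 0), r), w) >= c - 1e-9
        assert composite_score(ScoreVector(a, m, min(r + 5, 100)), w) >= c - 1e-9

    @given(
        a=st.floats(0, 100), m=st.floats(0, 100),
        r1=st.floats(0, 100), r2=st.floats(0, 100), alpha=st.floats(0, 1),
    )
    @settings(max_examples=100, deadline=None)
    def test_two_factor_independent_of_r(self, a, m, r1, r2, alpha):
        w = ModelWeights(alpha, 0.0)
        assert composite_score(ScoreVector(a, m, r1), w) == composite_score(
            ScoreVector(a, m, r2), w
        )


def _toy_set(peptide_alc_pairs, spectrum_id="s1", rt=30.0):
    cands = [
        CandidateRecord(spectrum_id, pep, alc, i + 1)
        for i, (pep, alc) in enumerate(peptide_alc_pairs)
    ]
    return SpectrumCandidateSet(spectrum_id, "S", rt, cands)


class TestRescorer:
    def _rescorer(self, m_table, rt_table, weights=DEFAULT_WEIGHTS):
        return Rescorer(
            m_provider=TableMProvider(m_table),
            rt_predictor=TableRTPredictor(rt_table),
            calibration=RTCalibration(1.0, 0.0, 2, 0.0),
            weights=weights,
            filters=FilterConfig(),
        )

    def test_lower_m_wins_at_equal_alc(self):
        cset = _toy_set([("AAAAKAAAK", 90.0), ("CCCCKCCCK", 90.0)])
        rescorer = self._rescorer(
            {("AAAAKAAAK", "X"): 8.0, ("CCCCKCCCK", "X"): 0.5},
            {"AAAAKAAAK": 30.0, "CCCCKCCCK": 30.0},
        )
        results, _ = rescorer.rescore_run([cset], {"S": ["X"]})
        assert results[0].identification.record.peptide == "CCCCKCCCK"

    def test_all_m_gated_is_unassigned(self):
        cset = _toy_set([("AAAAKAAAK", 90.0), ("CCCCKCCCK", 85.0)])
        rescorer = self._rescorer(
            {("AAAAKAAAK", "X"): 30.0, ("CCCCKCCCK", "X"): 11.0},
            {"AAAAKAAAK": 30.0, "CCCCKCCCK": 30.0},
        )
        results, _ = rescorer.rescore_run([cset], {"S": ["X"]})
        assert results[0].identification is None
        assert "M-rank" in results[0].unassigned_reason

    def test_zero_weights_keep_alc_order(self):
        pairs = [("AAAAKAAAK", 95.0), ("CCCCKCCCK", 80.0), ("DDDDKDDDK", 60.0)]
        cset = _toy_set(pairs)
        rescorer = self._rescorer(
            {(p, "X"): 1.0 for p, _ in pairs},
            {p: 5.0 for p, _ in pairs},
            weights=ModelWeights(0.0, 0.0),
        )
        results, _ = rescorer.rescore_run([cset], {"S": ["X"]})
        assert [rc.record.peptide for rc in results[0].ranked] == [p for p, _ in pairs]

    def test_alc_gate_applies_per_candidate(self):
        cset = _toy_set([("AAAAKAAAK", 49.9), ("CCCCKCCCK", 50.0)])
        rescorer = self._rescorer(
            {("AAAAKAAAK", "X"): 0.5, ("CCCCKCCCK", "X"): 0.5},
            {"AAAAKAAAK": 30.0, "CCCCKCCCK": 30.0},
        )
        results, _ = rescorer.rescore_run([cset], {"S": ["X"]})
        assert [rc.record.peptide for rc in results[0].ranked] == ["CCCCKCCCK"]
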