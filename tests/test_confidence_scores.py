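import json
import math

import numpy as np
import pytest

from ubiqpair import constants
from ubiqpair.confidence_scores import (
    ConfidenceError,
    PredictionConfidence,
    ScoreParams,
    interface_iptm,
    ipsae,
    load_confidence,
    mean_interface_pae,
    pdockq,
    pdockq2,
)
from ubiqpair.constants import tm_d0
from ubiqpair.synthetic_fixtures import make_confidence


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive double loops)
# ---------------------------------------------------------------------------

def oracle_ipsae_direction(pae, rows, cols, threshold, d0_floor):
    qualifying = [(i, j) for i in rows for j in cols if pae[i, j] < threshold]
    if not qualifying:
        return 0.0
    scored = {j for _, j in qualifying}
    d0 = tm_d0(len(scored), d0_floor)
    return sum(1.0 / (1.0 + (pae[i, j] / d0) ** 2) for i, j in qualifying) / len(qualifying)


def oracle_mean_pae(pae, ia, ib):
    values = [pae[i, j] for i in ia for j in ib] + [pae[j, i] for i in ia for j in ib]
    return sum(values) / len(values)


def oracle_pdockq2(pae, plddt, ia, ib):
    pl = sum(plddt[i] for i in list(ia) + list(ib)) / (len(ia) + len(ib))
    terms = [1.0 / (1.0 + (pae[i, j] / constants.PDOCKQ2_D0) ** 2)
             for i in ia for j in ib]
    terms += [1.0 / (1.0 + (pae[j, i] / constants.PDOCKQ2_D0) ** 2)
              for i in ia for j in ib]
    x = pl * sum(terms) / len(terms)
    return constants.PDOCKQ2_L / (1 + math.exp(-constants.PDOCKQ2_K * (x - constants.PDOCKQ2_X0))) \
        + constants.PDOCKQ2_B


def oracle_iptm(pae, rows, cols, d0):
    best = 0.0
    for i in rows:
        mean = sum(1.0 / (1.0 + (pae[i, j] / d0) ** 2) for j in cols) / len(cols)
        best = max(best, mean)
    return best


def _random_conf(rng, n_a=30, n_b=40):
    n = n_a + n_b
    pae = rng.uniform(0, 25, size=(n, n))
    plddt = rng.uniform(40, 100, size=n)
    return PredictionConfidence(plddt, pae, {"A": (0, n_a), "B": (n_a, n)})


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

class TestLoadConfidence:
    def test_af3_round_trip(self, tmp_path):
        conf, manifest = make_confidence((10, 8, 6), 3.0, 4.0, seed=1, out_dir=tmp_path)
        loaded = load_confidence(tmp_path / "toy.af3.json", "af3")
        assert loaded.chain_spans == conf.chain_spans
        np.testing.assert_allclose(loaded.pae, conf.pae)
        np.testing.assert_allclose(loaded.plddt, conf.plddt)
        assert loaded.chain_pair_iptm[("A", "B")] == pytest.approx(
            conf.chain_pair_iptm[("A", "B")])

    def test_cross_dialect_equality(self, tmp_path):
        conf, _ = make_confidence((10, 8, 6), 3.0, 4.0, seed=2, out_dir=tmp_path)
        af3 = load_confidence(tmp_path / "toy.af3.json", "af3")
        colab = load_confidence(tmp_path / "toy.colabfold.json", "colabfold",
                                chain_spans=conf.chain_spans)
        np.testing.assert_allclose(af3.pae, colab.pae)
        np.testing.assert_allclose(af3.plddt, colab.plddt)
        assert af3.chain_spans == colab.chain_spans

    def test_spans_sum_to_dimension(self, tmp_path):
        conf, _ = make_confidence((10, 8, 6), 3.0, 4.0, seed=3)
        assert sum(e - s for s, e in conf.chain_spans.values()) == conf.pae.shape[0]

    def test_dimension_mismatch_raises(self, tmp_path):
        _, _ = make_confidence((10, 8), 3.0, 4.0, seed=4, out_dir=tmp_path)
        with pytest.raises(ConfidenceError):
            load_confidence(tmp_path / "toy.af3.json", "af3", n_residues=99)

    def test_colabfold_requires_spans(self, tmp_path):
        make_confidence((10, 8), 3.0, 4.0, seed=5, out_dir=tmp_path)
        with pytest.raises(ConfidenceError):
            load_confidence(tmp_path / "toy.colabfold.json", "colabfold")

    def test_bad_spans_rejected(self):
        with pytest.raises(ConfidenceError):
            PredictionConfidence(np.zeros(5), np.zeros((5, 5)), {"A": (0, 3)})

    def test_negative_pae_rejected(self):
        pae = np.zeros((4, 4))
        pae[0, 1] = -1.0
        with pytest.raises(ConfidenceError):
            PredictionConfidence(np.zeros(4), pae, {"A": (0, 4)})


# ---------------------------------------------------------------------------
# Mean interface PAE
# ---------------------------------------------------------------------------

class TestMeanInterfacePae:
    def test_uniform_matrix(self):
        conf = PredictionConfidence(
            np.full(10, 80.0), np.full((10, 10), 5.0), {"A": (0, 5), "B": (5, 10)})
        assert mean_interface_pae(conf, "A", "B", [0, 1], [0, 1]) == pytest.approx(5.0)

    def test_empty_interface_absent(self):
        conf = PredictionConfidence(
            np.full(10, 80.0), np.full((10, 10), 5.0), {"A": (0, 5), "B": (5, 10)})
        assert mean_interface_pae(conf, "A", "B", [], [0]) is None

    def test_planted_block_oracle(self):
        rng = np.random.default_rng(0)
        conf = _random_conf(rng, 12, 9)
        ia = [0, 3, 5]
        ib = [1, 2, 8]
        gi = [i for i in ia]
        gj = [9 + 3 + j for j in ib]  # global indices in chain B (span starts at 12)
        gj = [12 + j for j in ib]
        expected = oracle_mean_pae(conf.pae, gi, gj)
        assert mean_interface_pae(conf, "A", "B", ia, ib) == pytest.approx(expected, abs=1e-9)


# ---------------------------------------------------------------------------
# ipSAE
# ---------------------------------------------------------------------------

class TestIpsae:
    def test_zero_pae_is_one(self):
        conf = PredictionConfidence(
            np.full(20, 90.0), np.zeros((20, 20)), {"A": (0, 10), "B": (10, 20)})
        assert ipsae(conf, ("A", "B")).aggregate == pytest.approx(1.0)

    def test_all_above_threshold_is_zero(self):
        conf = PredictionConfidence(
            np.full(20, 90.0), np.full((20, 20), 15.0), {"A": (0, 10), "B": (10, 20)})
        assert ipsae(conf, ("A", "B")).aggregate == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        conf = _random_conf(rng)
        params = ScoreParams()
        score = ipsae(conf, ("A", "B"), params)
        rows_a = list(range(0, 30))
        rows_b = list(range(30, 70))
        expected_ab = oracle_ipsae_direction(conf.pae, rows_a, rows_b,
                                             params.pae_threshold, params.d0_floor)
        expected_ba = oracle_ipsae_direction(conf.pae, rows_b, rows_a,
                                             params.pae_threshold, params.d0_floor)
        assert score.ab == pytest.approx(expected_ab, abs=1e-9)
        assert score.ba == pytest.approx(expected_ba, abs=1e-9)
        assert score.aggregate == pytest.approx(max(expected_ab, expected_ba), abs=1e-9)

    def test_uniform_inflation_never_increases(self):
        # no-dropout regime: all entries stay below the threshold
        rng = np.random.default_rng(7)
        n = 30
        pae = rng.uniform(0, 6, size=(n, n))
        conf = PredictionConfidence(np.full(n, 90.0), pae, {"A": (0, 15), "B": (15, n)})
        base = ipsae(conf, ("A", "B")).aggregate
        inflated = PredictionConfidence(np.full(n, 90.0), pae + 2.0,
                                        {"A": (0, 15), "B": (15, n)})
        assert ipsae(inflated, ("A", "B")).aggregate <= base

    def test_chain_relabel_invariance(self):
        rng = np.random.default_rng(8)
        conf = _random_conf(rng)
        relabeled = PredictionConfidence(
            conf.plddt, conf.pae, {"X": (0, 30), "Y": (30, 70)})
        assert ipsae(conf, ("A", "B")).aggregate == \
            ipsae(relabeled, ("X", "Y")).aggregate


# ---------------------------------------------------------------------------
# pDockQ2 / pDockQ
# ---------------------------------------------------------------------------

class TestPdockq2:
    def test_perfect_prediction_saturates(self):
        n = 20
        perfect = PredictionConfidence(
            np.full(n, 100.0), np.zeros((n, n)), {"A": (0, 10), "B": (10, n)})
        degraded = PredictionConfidence(
            np.full(n, 80.0), np.full((n, n), 5.0), {"A": (0, 10), "B": (10, n)})
        ia = ib = list(range(5))
        top = pdockq2(perfect, "A", "B", ia, ib)
        assert 0 < top < 1
        assert top > pdockq2(degraded, "A", "B", ia, ib)

    def test_pae_scaling_monotone(self):
        n = 20
        ia = ib = list(range(8))
        base_pae = np.full((n, n), 4.0)
        spans = {"A": (0, 10), "B": (10, n)}
        low = pdockq2(PredictionConfidence(np.full(n, 85.0), base_pae, spans),
                      "A", "B", ia, ib)
        high = pdockq2(PredictionConfidence(np.full(n, 85.0), base_pae * 2, spans),
                       "A", "B", ia, ib)
        assert high <= low

    def test_empty_interface_absent(self):
        conf = PredictionConfidence(
            np.full(10, 80.0), np.zeros((10, 10)), {"A": (0, 5), "B": (5, 10)})
        assert pdockq2(conf, "A", "B", [], []) is None

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        conf = _random_conf(rng, 20, 25)
        ia = sorted(rng.choice(20, size=6, replace=False).tolist())
        ib = sorted(rng.choice(25, size=7, replace=False).tolist())
        expected = oracle_pdockq2(conf.pae, conf.plddt,
                                  [i for i in ia], [20 + j for j in ib])
        assert pdockq2(conf, "A", "B", ia, ib) == pytest.approx(expected, abs=1e-9)

    def test_pdockq_v1_monotone_in_contacts(self):
        n = 20
        conf = PredictionConfidence(
            np.full(n, 90.0), np.zeros((n, n)), {"A": (0, 10), "B": (10, n)})
        ia = ib = list(range(5))
        assert pdockq(conf, "A", "B", ia, ib, 20) > pdockq(conf, "A", "B", ia, ib, 5)
        assert pdockq(conf, "A", "B", ia, ib, 0) is None


# ---------------------------------------------------------------------------
# ipTM
# ---------------------------------------------------------------------------

class TestInterfaceIptm:
    def test_stored_value_passthrough(self):
        conf = PredictionConfidence(
            np.full(10, 80.0), np.zeros((10, 10)), {"A": (0, 5), "B": (5, 10)},
            {("A", "B"): 0.87})
        assert interface_iptm(conf, ("A", "B")) == 0.87
        assert interface_iptm(conf, ("B", "A")) == 0.87

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        conf = _random_conf(rng, 25, 30)
        d0 = tm_d0(55)
        expected = max(
            oracle_iptm(conf.pae, range(0, 25), range(25, 55), d0),
            oracle_iptm(conf.pae, range(25, 55), range(0, 25), d0),
        )
        assert interface_iptm(conf, ("A", "B")) == pytest.approx(expected, abs=1e-9)

    def test_swap_invariance(self):
        rng = np.random.default_rng(33)
        conf = _random_conf(rng)
        assert interface_iptm(conf, ("A", "B")) == interface_iptm(conf, ("B", "A"))

    def test_missing_sources_raise(self):
        conf = PredictionConfidence(
            np.full(10, 80.0), np.zeros((10, 10)), {"A": (0, 5), "B": (5, 10)})
        with pytest.raises(ConfidenceError):
            interface_iptm(conf, ("A", "Z"))

    def test_uniform_inflation_never_increases(self):
        rng = np.random.default_rng(44)
        conf = _random_conf(rng)
        inflated = PredictionConfidence(
            conf.plddt, conf.pae + 3.0, dict(conf.chain_spans))
        assert interface_iptm(inflated, ("A", "B")) <= interface_iptm(conf, ("A", "B"))


class TestBounds:
    @pytest.mark.parametrize("seed", range(3))
    def test_all_scores_bounded(self, seed):
        rng = np.random.default_rng(300 + seed)
        conf = _random_conf(rng)
        ia = list(range(10))
        ib = list(range(10))
        score = ipsae(conf, ("A", "B"))
        assert 0.0 <= score.ab <= 1.0 and 0.0 <= score.ba <= 1.0
        assert 0.0 <= interface_iptm(conf, ("A", "B")) <= 1.0
        pq2 = pdockq2(conf, "A", "B", ia, ib)
        assert 0.0 <= pq2 <= 1.0
        assert mean_interface_pae(conf, "A", "B", ia, ib) >= 0.0
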