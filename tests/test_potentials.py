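"""Statistical-potential training, correction and scoring."""

import numpy as np
import pytest

import episeq as eq
from episeq.potentials import (
    RT,
    FrequencyModel,
    corrected_ratio,
    model_from_tsv,
    model_to_tsv,
)
from episeq.seqdata import AMINO_ACIDS, AntigenRecord, Corpus

import _oracles


def test_two_residue_hand_count():
    """On "AA" labeled E,N with I=3 each centre sees both positions, so
    every (state, A) singlet cell counts 2 and the pair cell {A,A} counts 1
    per centre."""
    corpus = Corpus([AntigenRecord(id="t", sequence="AA", labels="EN")])
    m = eq.train_frequency_model(corpus, "epitope", interval=3)
    a = AMINO_ACIDS.index("A")
    assert m.counts_single[0, a] == 2  # state E
    assert m.counts_single[1, a] == 2  # state N
    assert m.counts_pair[0, a, a] == 1
    assert m.counts_pair[1, a, a] == 1
    singles, pairs, _ = _oracles.count_incidences(corpus, "epitope", 3)
    assert singles[("E", "A")] == 2 and pairs[("N", ("A", "A"))] == 1


@pytest.mark.parametrize("interval", [1, 3, 5, 7])
def test_counts_match_brute_force(rng, interval):
    corpus = _oracles.random_toy_corpus(rng)
    m = eq.train_frequency_model(corpus, "epitope", interval=interval)
    singles, pairs, states = _oracles.count_incidences(corpus, "epitope", interval)
    for ui, u in enumerate(states):
        for si, s in enumerate(AMINO_ACIDS):
            assert m.counts_single[ui, si] == singles[(u, s)]
        for a in range(20):
            for b in range(a, 20):
                key = (u, (AMINO_ACIDS[a], AMINO_ACIDS[b]))
                assert m.counts_pair[ui, a, b] == pairs[key]


def test_corrected_ratio_closed_forms():
    """Zero-count cells give ratio 1 (potential 0); a raw ratio of 1 is a
    fixed point; sigma=10, n=10, r=2 gives 1.5."""
    m = FrequencyModel(task="epitope", states=("E", "N"), interval=3, sigma=10.0)
    # counts chosen so that for (E, A): n_s=10, r = 5*40/(10*10) = 2
    m.counts_single[0, 0] = 5   # E,A
    m.counts_single[0, 1] = 5   # E,C
    m.counts_single[1, 0] = 5   # N,A
    m.counts_single[1, 1] = 25  # N,C
    assert corrected_ratio(m, "single", "E", "A") == pytest.approx(1.5, abs=1e-12)
    # unseen type: exactly 1, hence delta_w exactly 0
    assert corrected_ratio(m, "single", "E", "D") == 1.0
    assert m.delta_w1("E", "D") == 0.0
    # raw ratio 1 stays 1: make (N, C) cell with r=1
    m2 = FrequencyModel(task="epitope", states=("E", "N"), interval=3, sigma=10.0)
    m2.counts_single[0, 0] = 10
    m2.counts_single[0, 1] = 10
    m2.counts_single[1, 0] = 10
    m2.counts_single[1, 1] = 10
    assert corrected_ratio(m2, "single", "E", "A") == pytest.approx(1.0, abs=1e-15)


def test_corrected_ratio_large_n_limit():
    """At n = 1e6 incidences the shrinkage is below 1e-5."""
    m = FrequencyModel(task="epitope", states=("E", "N"), interval=3, sigma=10.0)
    m.counts_single[0, 0] = 500_000
    m.counts_single[0, 1] = 500_000
    m.counts_single[1, 0] = 500_000
    m.counts_single[1, 1] = 2_500_000
    raw = 2.0  # 5e5 * 4e6 / (1e6 * 1e6)
    assert abs(corrected_ratio(m, "single", "E", "A") - raw) < 1e-5


def test_degenerate_interval_one():
    """I=1 leaves the pair table empty; dW1 is the residue's own propensity."""
    corpus = Corpus(
        [AntigenRecord(id="t", sequence="ADKA", labels="ENEN")]
    )
    m = eq.train_frequency_model(corpus, "epitope", interval=1)
    assert m.n_pair == 0
    s = eq.score_residue(m, "ADKA", 0, "E")
    assert s.dw2 == 0.0
    assert s.dw1 == pytest.approx(m.delta_w1("E", "A"), abs=1e-12)


def test_record_order_invariance(toy):
    m1 = eq.train_frequency_model(toy, "epitope", interval=5)
    rev = Corpus(list(toy.records[::-1]))
    m2 = eq.train_frequency_model(rev, "epitope", interval=5)
    np.testing.assert_array_equal(m1.counts_single, m2.counts_single)
    np.testing.assert_array_equal(m1.counts_pair, m2.counts_pair)


def test_training_error_on_single_state():
    corpus = Corpus([AntigenRecord(id="t", sequence="ACDE", labels="EEEE")])
    with pytest.raises(eq.potentials.TrainingError):
        eq.train_frequency_model(corpus, "epitope", interval=3)


@pytest.mark.parametrize("interval", [3, 7])
def test_scores_match_brute_force(rng, interval, toy):
    """scan_sequence equals the independent dictionary/double-loop oracle."""
    m = eq.train_frequency_model(toy, "epitope", interval=interval)
    singles, pairs, _ = _oracles.count_incidences(toy, "epitope", interval)
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=50))
    got = eq.scan_sequence(m, seq, "E")
    for i in range(len(seq)):
        s1, s2 = _oracles.score(singles, pairs, seq, i, "E", interval, 10.0, RT)
        assert got[i] == pytest.approx(s1 + s2, abs=1e-10)
        ps = eq.score_residue(m, seq, i, "E")
        assert ps.dw == pytest.approx(s1 + s2, abs=1e-10)


def test_terminus_truncation(toy):
    """The window of the first residue covers offsets 0..+w only."""
    m = eq.train_frequency_model(toy, "epitope", interval=7)
    seq = toy.records[0].sequence
    first = eq.score_residue(m, seq, 0, "E")
    manual = sum(m.delta_w1("E", seq[j]) for j in range(4))
    assert first.dw1 == pytest.approx(manual, abs=1e-12)


def test_unknown_neighbor_skipped(toy):
    m = eq.train_frequency_model(toy, "epitope", interval=3)
    clean = eq.score_residue(m, "ADK", 1, "E")
    masked = eq.score_residue(m, "XDK", 1, "E")
    expect_dw1 = m.delta_w1("E", "D") + m.delta_w1("E", "K")
    assert masked.dw1 == pytest.approx(expect_dw1, abs=1e-12)
    assert masked.dw1 != pytest.approx(clean.dw1, abs=1e-12)


def test_palindrome_symmetry(toy):
    m = eq.train_frequency_model(toy, "epitope", interval=5)
    seq = "ACDKDCA"
    scores = eq.scan_sequence(m, seq, "E")
    np.testing.assert_allclose(scores, scores[::-1], atol=1e-12)


def test_model_tsv_roundtrip(tmp_path, toy):
    m = eq.train_frequency_model(toy, "epitope", interval=5)
    path = tmp_path / "model.tsv"
    model_to_tsv(m, path)
    m2 = model_from_tsv(path)
    assert (m2.task, m2.states, m2.interval, m2.sigma, m2.rt) == (
        m.task, m.states, m.interval, m.sigma, m.rt,
    )
    np.testing.assert_array_equal(m.counts_single, m2.counts_single)
    np.testing.assert_array_equal(m.counts_pair, m2.counts_pair)
    seq = toy.records[1].sequence
    np.testing.assert_allclose(
        eq.scan_sequence(m, seq, "E"), eq.scan_sequence(m2, seq, "E"), atol=0
    )


def test_marginal_consistency(toy):
    """Marginals of each table share one total and sum to 1."""
    m = eq.train_frequency_model(toy, "epitope", interval=5)
    f_states = [m.freq_state(u) for u in m.states]
    f_types = [m.freq_type(s) for s in AMINO_ACIDS]
    assert sum(f_states) == pytest.approx(1.0, abs=1e-12)
    assert sum(f_types) == pytest.approx(1.0, abs=1e-12)
    joint = sum(
        m.freq_state_type(u, s) for u in m.states for s in AMINO_ACIDS
    )
    assert joint == pytest.approx(1.0, abs=1e-12)


def test_null_corpus_signed_bias_and_sqrt_n_decay():
    """With labels independent of sequence the potentials converge to 0: the
    per-residue noise shrinks like 1/sqrt(n) and the signed mean (the -ln
    convexity bias) is an order of magnitude smaller."""
    from episeq.synthgen import SynthConfig

    means = {}
    for n_rec in (100, 400):
        corp = eq.generate_corpus(
            SynthConfig(n_records=n_rec, length_range=(100, 140)), seed=5
        )
        m = eq.train_frequency_model(corp, "epitope", interval=7)
        dw = np.concatenate(
            [eq.scan_sequence(m, r.sequence, "E") for r in corp]
        )
        means[n_rec] = (np.abs(dw).mean() / RT, abs(dw.mean()) / RT)
    ratio = means[100][0] / means[400][0]
    assert 1.5 < ratio < 2.7  # ~sqrt(4) = 2
    assert means[400][1] < 0.2 * means[400][0]
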