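"""Consensus mapping, semi-global alignment, encoding, EM, posteriors."""

import numpy as np
import pytest

from linenahr.hmm import (
    COL_CIS,
    COL_INDEL,
    HMMParams,
    ObsSequence,
    align_read_semiglobal,
    baum_welch,
    build_consensus,
    call_case,
    cluster_calls,
    encode_observations,
    posterior_breakpoint,
    sample_observations,
    semiglobal_score,
    switch_posterior,
)
from linenahr.synthetic import mutate, random_sequence, revcomp


# ---------------------------------------------------------------------------
# consensus / cis-morphism map
# ---------------------------------------------------------------------------

def test_identical_sequences_have_no_informative_columns():
    s = "ACGTACGTACGT" * 10
    cis = build_consensus(s, s)
    assert cis.informative == []
    assert cis.consensus == s


def test_three_substitutions_yield_three_cis_morphisms():
    left = "AAAACCCCGGGGTTTTAAAACCCC"
    right = "AAAACCACGGGGTATTAAAACGCC"
    cis = build_consensus(left, right)
    assert len(cis.informative) == 3
    for col, la, ra in cis.informative:
        assert left[col] == la and right[col] == ra
        assert cis.flags[col] == COL_CIS


def test_indel_columns_flagged_not_informative():
    left = "AAAACCCCGGGGTTTT"
    right = "AAAACCCGGGGTTTT"  # one C deleted
    cis = build_consensus(left, right)
    assert (cis.flags == COL_INDEL).sum() == 1
    assert cis.informative == []


def test_informative_density_tracks_planted_divergence():
    rng = np.random.default_rng(17)
    anc = random_sequence(rng, 6000)
    a = mutate(rng, anc, 0.015, 0.0)
    b = mutate(rng, anc, 0.015, 0.0)
    n_diff = sum(x != y for x, y in zip(a, b)) if len(a) == len(b) else None
    cis = build_consensus(a, b)
    assert n_diff is not None
    assert abs(len(cis.informative) - n_diff) <= 0.1 * n_diff


# ---------------------------------------------------------------------------
# semi-global alignment
# ---------------------------------------------------------------------------

def _brute_semiglobal(read, ref):
    """Independent O(mn) python DP oracle (free ref end-gaps)."""
    m, n = len(read), len(ref)
    prev = [0] * (n + 1)
    for i in range(1, m + 1):
        cur = [prev[0] - 2] + [0] * n
        for j in range(1, n + 1):
            s = 1 if read[i - 1] == ref[j - 1] else -1
            cur[j] = max(prev[j - 1] + s, prev[j] - 2, cur[j - 1] - 2)
        prev = cur
    return max(prev)


def test_exact_substring_alignment():
    rng = np.random.default_rng(2)
    ref = random_sequence(rng, 3000)
    read = ref[1200:1700]
    aln = align_read_semiglobal(read, ref)
    assert aln.score == 500
    assert aln.identity == 100.0
    assert list(aln.columns) == list(range(1200, 1700))


def test_two_substitutions_closed_form_score():
    rng = np.random.default_rng(3)
    ref = random_sequence(rng, 2000)
    read = list(ref[500:1000])
    read[100] = "A" if read[100] != "A" else "C"
    read[300] = "A" if read[300] != "A" else "C"
    aln = align_read_semiglobal("".join(read), ref)
    assert aln.score == 498 * 1 + 2 * (-1)


def test_scores_equal_bruteforce_oracle_on_random_instances():
    rng = np.random.default_rng(4)
    for _ in range(100):
        n = int(rng.integers(20, 81))
        m = int(rng.integers(5, n + 1))
        ref = random_sequence(rng, n)
        read = random_sequence(rng, m)
        got = semiglobal_score(read, ref)
        assert got == _brute_semiglobal(read, ref)


def test_reverse_complement_read_recovered():
    rng = np.random.default_rng(5)
    ref = random_sequence(rng, 1500)
    aln = align_read_semiglobal(revcomp(ref[300:700]), ref)
    assert aln.orientation == "reverse"
    assert aln.score == 400


def test_empty_read_rejected():
    with pytest.raises(ValueError, match="empty"):
        align_read_semiglobal("", "ACGT")


# ---------------------------------------------------------------------------
# observation encoding
# ---------------------------------------------------------------------------

def _junction_fixture(seed=7, length=1500, div=0.01):
    rng = np.random.default_rng(seed)
    anc = random_sequence(rng, length)
    a = mutate(rng, anc, div, 0.0)
    b = mutate(rng, anc, div, 0.0)
    return a, b, build_consensus(a, b)


def test_left_copy_read_encodes_all_L():
    a, b, cis = _junction_fixture()
    aln = align_read_semiglobal(a[200:900], cis.consensus)
    obs = encode_observations(aln, cis, [40] * 700)
    body_informative = [s for s in obs.body if s != "N"]
    assert body_informative and set(body_informative) == {"L"}
    assert obs.symbols[0] == "S" and obs.symbols[-1] == "E"


def test_junction_read_is_L_then_R():
    a, b, cis = _junction_fixture()
    cut = 750
    hybrid_read = a[200:cut] + b[cut:1300]
    aln = align_read_semiglobal(hybrid_read, cis.consensus)
    obs = encode_observations(aln, cis, [40] * len(hybrid_read))
    informative = [(c, s) for c, s in zip(obs.columns, obs.body) if s != "N"]
    switch_seen = "".join(s for _, s in informative)
    assert "RL" not in switch_seen  # monotone L -> R
    assert "L" in switch_seen and "R" in switch_seen


def test_phred_weight_mapping():
    a, b, cis = _junction_fixture()
    aln = align_read_semiglobal(a[100:400], cis.consensus)
    obs = encode_observations(aln, cis, [30] * 300)
    informative_w = [w for w, s in zip(obs.weights, obs.body) if s != "N"]
    assert informative_w and all(w == pytest.approx(0.999) for w in informative_w)


def test_obs_sequence_invariants():
    with pytest.raises(ValueError, match="start with S"):
        ObsSequence("LLRE", np.ones(2), np.arange(2))
    with pytest.raises(ValueError, match="L, R or N"):
        ObsSequence("SLXE", np.ones(2), np.arange(2))


# ---------------------------------------------------------------------------
# forward-backward and posteriors
# ---------------------------------------------------------------------------

def _brute_switch_posterior(obs, p):
    """Exhaustive oracle: enumerate every switch placement."""
    rows = p.emission_rows()
    t_len = len(obs.body)
    e = np.empty((t_len, 2))
    for t, s in enumerate(obs.body):
        if s == "N":
            e[t] = rows["N"]
        else:
            w = obs.weights[t]
            o = "R" if s == "L" else "L"
            e[t] = w * rows[s] + (1 - w) * rows[o]
    g = p.gamma
    probs = np.array(
        [
            (1 - g) ** k * g * np.prod(e[:k, 0]) * np.prod(e[k:, 1])
            for k in range(t_len + 1)
        ]
    )
    return probs / probs.sum()


def test_posterior_equals_exhaustive_enumeration():
    rng = np.random.default_rng(23)
    p = HMMParams(alpha=0.98, beta=0.97, gamma=0.02, rho=0.4)
    for _ in range(200):
        t_len = int(rng.integers(2, 13))
        body = "".join(rng.choice(list("LRN"), size=t_len))
        w = rng.uniform(0.4, 1.0, size=t_len)
        obs = ObsSequence("S" + body + "E", w, np.arange(t_len))
        xi, _ = switch_posterior(obs, p, force_switch=True)
        assert np.abs(xi - _brute_switch_posterior(obs, p)).max() < 1e-10


def test_posterior_normalizes_when_switch_forced():
    obs = ObsSequence("S" + "L" * 30 + "R" * 30 + "E", np.ones(60), np.arange(60))
    xi, _ = switch_posterior(obs, HMMParams(), force_switch=True)
    assert xi.sum() == pytest.approx(1.0, abs=1e-9)


def test_unambiguous_junction_localized_exactly():
    a, b, cis = _junction_fixture(seed=31, length=4000, div=0.02)
    cols = cis.informative_columns
    # pick a wide inter-cis-morphism gap near the middle: with many switch
    # positions inside it, an error-free L...R read puts ~all mass there
    gaps = np.diff(cols)
    mid = len(cols) // 2
    k = mid - 20 + int(np.argmax(gaps[mid - 20:mid + 20]))
    assert cols[k + 1] - cols[k] >= 20
    cut = (cols[k] + cols[k + 1]) // 2 + 1  # between the two cis-morphisms
    read = a[max(0, cut - 400):cut] + b[cut:cut + 400]
    aln = align_read_semiglobal(read, cis.consensus)
    obs = encode_observations(aln, cis, [40] * len(read))
    call = posterior_breakpoint(obs, HMMParams(alpha=0.98, beta=0.98, gamma=0.01, rho=0.5), cis)
    assert call.map_interval == (cols[k], cols[k + 1])
    assert call.map_mass > 0.9


def test_uninformative_weights_recover_model_prior():
    t_len = 40
    p = HMMParams(alpha=0.98, beta=0.98, gamma=0.01, rho=0.5)
    obs = ObsSequence(
        "S" + "LR" * (t_len // 2) + "E", np.full(t_len, 0.5), np.arange(t_len)
    )
    xi, _ = switch_posterior(obs, p, force_switch=True)
    g = p.gamma
    prior = np.array([(1 - g) ** k * g for k in range(t_len + 1)])
    prior /= prior.sum()
    assert np.abs(xi - prior).max() < 1e-12
    # for gamma * T << 1 this prior is nearly uniform over switch points
    assert xi.max() / xi.min() < 1.6


# ---------------------------------------------------------------------------
# Baum-Welch
# ---------------------------------------------------------------------------

def test_em_trace_monotone_on_fixtures():
    truth = HMMParams(alpha=0.95, beta=0.9, gamma=0.03, rho=0.6)
    obs = sample_observations(truth, 30, 80, seed=3)
    _, trace = baum_welch(obs)
    diffs = np.diff(trace)
    assert (diffs >= -1e-8).all()


def test_parameter_recovery_from_simulated_reads():
    truth = HMMParams(alpha=0.98, beta=0.98, gamma=0.02, rho=0.50)
    obs = sample_observations(truth, 200, 100, seed=7)
    est, _ = baum_welch(obs)
    assert est.alpha == pytest.approx(0.98, abs=0.02)
    assert est.beta == pytest.approx(0.98, abs=0.02)
    assert est.gamma == pytest.approx(0.02, abs=0.02)
    assert est.rho == pytest.approx(0.50, abs=0.02)
    assert est.trained


def test_no_switch_evidence_pulls_gamma_to_prior():
    obs = [ObsSequence("S" + "L" * 50 + "E", np.ones(50), np.arange(50))]
    est, _ = baum_welch(obs, force_switch=False)
    a, b = est.priors["gamma"]
    prior_mode_scale = a / (a + b)
    assert est.gamma < 2 * prior_mode_scale  # stays near the prior, not inflated


def test_quality_weighted_emissions_soften_calls():
    """A conflicting vote at low weight should not reset the posterior."""
    p = HMMParams(alpha=0.99, beta=0.99, gamma=0.01, rho=0.3)
    clean = ObsSequence("S" + "L" * 10 + "R" * 10 + "E", np.ones(20), np.arange(20))
    noisy_w = np.ones(20)
    noisy_w[4] = 0.55  # the 5th L becomes nearly uninformative
    noisy = ObsSequence("S" + "L" * 4 + "R" + "L" * 5 + "R" * 10 + "E", noisy_w, np.arange(20))
    xi_clean, _ = switch_posterior(clean, p)
    xi_noisy, _ = switch_posterior(noisy, p)
    assert int(np.argmax(xi_clean)) == 10
    assert int(np.argmax(xi_noisy)) == 10  # low-quality R at t=5 is discounted


# ---------------------------------------------------------------------------
# case pooling
# ---------------------------------------------------------------------------

def test_pooled_call_matches_and_sharpens_single_read():
    a, b, cis = _junction_fixture(seed=37, length=3000, div=0.015)
    cols = cis.informative_columns
    k = len(cols) // 2
    cut = (cols[k] + cols[k + 1]) // 2
    reads = []
    for i in range(4):
        start = max(0, cut - 500 + 30 * i)
        seq = a[start:cut] + b[cut:cut + 400 + 20 * i]
        reads.append((f"r{i}", seq, [40] * len(seq)))
    single = call_case(reads[:1], a, b)
    pooled = call_case(reads, a, b)
    assert pooled.map_interval == single.map_interval == (cols[k], cols[k + 1])
    assert pooled.map_mass >= single.map_mass - 1e-9
    assert pooled.n_reads == 4


def test_three_distinct_crossovers_form_three_clusters():
    a, b, cis = _junction_fixture(seed=41, length=6000, div=0.02)
    cols = cis.informative_columns
    cuts = [int(cols[10]) + 20, int(cols[len(cols) // 2]) + 20, int(cols[-10]) - 20]
    calls = []
    for cut in cuts:
        reads = [
            ("r", a[cut - 450:cut] + b[cut:cut + 450], [40] * 900),
            ("r2", a[cut - 500:cut] + b[cut:cut + 400], [40] * 900),
        ]
        calls.append(call_case(reads, a, b))
    labels = cluster_calls(calls, max_distance=500)
    assert len(set(labels)) == 3


def test_non_junction_reads_all_dropped_raises():
    a, b, _ = _junction_fixture(seed=43)
    rng = np.random.default_rng(0)
    junk = [("x", random_sequence(rng, 400), [40] * 400)]
    with pytest.raises(ValueError, match="no reads aligned"):
        call_case(junk, a, b)
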