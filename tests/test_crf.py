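import itertools
import math
import random

import numpy as np
import pytest

from deidkit.crf import (
    CRFModel,
    CRFTrainConfig,
    decode,
    load_model,
    objective,
    save_model,
    sequence_log_prob,
    sequence_score,
    train_crf,
)

# ---------------------------------------------------------------------------
# Brute-force oracles: enumerate all |tags|^n sequences directly
# ---------------------------------------------------------------------------


def random_model(rng: np.random.Generator, n_tags: int, n_feats: int) -> CRFModel:
    return CRFModel(
        tags=[f"T{k}" for k in range(n_tags)],
        feature_index={f"f{j}": j for j in range(n_feats)},
        obs_weights=rng.normal(size=(n_feats, n_tags)),
        trans_weights=rng.normal(size=(n_tags, n_tags)),
    )


def random_obs(rng: np.random.Generator, n_feats: int, n: int) -> list[list[str]]:
    return [
        [f"f{j}" for j in rng.choice(n_feats, size=rng.integers(1, 4), replace=False)]
        for _ in range(n)
    ]


def all_sequences(model: CRFModel, n: int):
    return itertools.product(model.tags, repeat=n)


def brute_force_argmax(model: CRFModel, obs) -> tuple[list[str], float]:
    best, best_score = None, -math.inf
    for seq in all_sequences(model, len(obs)):
        s = sequence_score(model, obs, list(seq))
        if s > best_score:
            best, best_score = list(seq), s
    return best, best_score


@pytest.mark.parametrize("seed", range(30))
def test_viterbi_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    n_tags = int(rng.integers(2, 6))
    n = int(rng.integers(1, 5))
    model = random_model(rng, n_tags, 6)
    obs = random_obs(rng, 6, n)
    expected, expected_score = brute_force_argmax(model, obs)
    got = decode(model, obs)
    assert sequence_score(model, obs, got) == pytest.approx(expected_score)
    assert got == expected


@pytest.mark.parametrize("seed", range(15))
def test_probabilities_sum_to_one(seed):
    rng = np.random.default_rng(100 + seed)
    n_tags = int(rng.integers(2, 6))
    n = int(rng.integers(1, 5))
    model = random_model(rng, n_tags, 6)
    obs = random_obs(rng, 6, n)
    total = sum(
        math.exp(sequence_log_prob(model, obs, list(seq)))
        for seq in all_sequences(model, n)
    )
    assert total == pytest.approx(1.0, abs=1e-9)


def test_zero_weight_model_is_uniform():
    model = CRFModel(
        tags=["A", "B", "C"],
        feature_index={"f0": 0},
        obs_weights=np.zeros((1, 3)),
        trans_weights=np.zeros((3, 3)),
    )
    obs = [["f0"], ["f0"], ["f0"], ["f0"]]
    for seq in [["A"] * 4, ["B", "A", "C", "B"]]:
        assert sequence_log_prob(model, obs, seq) == pytest.approx(
            -4 * math.log(3)
        )
    # tie-break: first tag index everywhere
    assert decode(model, obs) == ["A"] * 4


def test_unseen_features_contribute_zero():
    rng = np.random.default_rng(3)
    model = random_model(rng, 3, 4)
    obs = [["f0", "f1"], ["f2"]]
    obs_extra = [["f0", "f1", "UNSEEN=yes"], ["f2", "other"]]
    assert decode(model, obs) == decode(model, obs_extra)
    assert sequence_log_prob(model, obs, ["T0", "T1"]) == pytest.approx(
        sequence_log_prob(model, obs_extra, ["T0", "T1"])
    )


def test_gradient_matches_finite_differences():
    """Analytic gradient (empirical - expected counts) vs central differences."""
    rng = np.random.default_rng(7)
    data = []
    for _ in range(3):
        n = int(rng.integers(2, 5))
        obs = random_obs(rng, 4, n)
        tags = [f"T{int(rng.integers(0, 2))}" for _ in range(n)]
        data.append((obs, tags))
    model = train_crf(data, CRFTrainConfig(epochs=0))
    model.obs_weights[:] = rng.normal(size=model.obs_weights.shape)
    model.trans_weights[:] = rng.normal(size=model.trans_weights.shape)
    l2 = 0.1
    _, grad = objective(model, data, l2=l2)
    nf, nt = model.obs_weights.shape
    theta0 = np.concatenate(
        [model.obs_weights.ravel(), model.trans_weights.ravel()]
    )
    h = 1e-5
    for j in range(len(theta0)):
        for sign, store in ((+1, "hi"), (-1, "lo")):
            theta = theta0.copy()
            theta[j] += sign * h
            model.obs_weights[:] = theta[: nf * nt].reshape(nf, nt)
            model.trans_weights[:] = theta[nf * nt :].reshape(nt, nt)
            val, _ = objective(model, data, l2=l2)
            if sign > 0:
                hi = val
            else:
                lo = val
        numeric = (hi - lo) / (2 * h)
        assert abs(grad[j] - numeric) <= 1e-5 * max(1.0, abs(grad[j]))
    model.obs_weights[:] = theta0[: nf * nt].reshape(nf, nt)
    model.trans_weights[:] = theta0[nf * nt :].reshape(nt, nt)


# ---------------------------------------------------------------------------
# Training behavior
# ---------------------------------------------------------------------------


def separable_fixture(n_sentences=50, seed=0):
    """Deterministic toy language: a digit token is B(DATE) iff it follows
    the word 'on'; everything else is O."""
    rng = random.Random(seed)
    words = ["on", "at", "seen", "well", "stable"]
    data = []
    for _ in range(n_sentences):
        n = rng.randint(2, 6)
        toks = []
        for _ in range(n):
            toks.append(
                str(rng.randint(1000, 9999)) if rng.random() < 0.4 else rng.choice(words)
            )
        obs, tags = [], []
        for i, w in enumerate(toks):
            prev = toks[i - 1] if i else "BOS"
            obs.append(
                {
                    "token": w,
                    "all_digits": w.isdigit(),
                    "prev_x_digits": f"{prev == 'on'}|{w.isdigit()}",
                }
            )
            tags.append("B(DATE)" if w.isdigit() and prev == "on" else "O")
        data.append((obs, tags))
    return data


@pytest.fixture(scope="module")
def trained_separable():
    data = separable_fixture()
    return data, train_crf(data, CRFTrainConfig(epochs=150))


def test_separable_fixture_reaches_perfect_training_accuracy(trained_separable):
    data, model = trained_separable
    correct = total = 0
    for obs, tags in data:
        pred = decode(model, obs)
        correct += sum(p == t for p, t in zip(pred, tags))
        total += len(tags)
    assert correct == total


def test_generalizes_to_unseen_digit_token(trained_separable):
    _, model = trained_separable
    new = [
        {"token": "on", "all_digits": False, "prev_x_digits": "False|False"},
        {"token": "2071", "all_digits": True, "prev_x_digits": "True|True"},
    ]
    assert decode(model, new) == ["O", "B(DATE)"]


def test_gold_has_highest_probability_after_training(trained_separable):
    data, model = trained_separable
    obs, tags = next((o, t) for o, t in data if 2 <= len(t) <= 4)
    gold_lp = sequence_log_prob(model, obs, tags)
    assert all(
        gold_lp >= sequence_log_prob(model, obs, list(seq)) - 1e-12
        for seq in all_sequences(model, len(tags))
    )


def test_training_is_deterministic():
    data = separable_fixture(n_sentences=20)
    m1 = train_crf(data, CRFTrainConfig(epochs=30, seed=4))
    m2 = train_crf(data, CRFTrainConfig(epochs=30, seed=4))
    assert np.array_equal(m1.obs_weights, m2.obs_weights)
    assert np.array_equal(m1.trans_weights, m2.trans_weights)


def test_log_likelihood_non_decreasing():
    data = separable_fixture(n_sentences=20)
    model = train_crf(data, CRFTrainConfig(epochs=40))
    assert all(a <= b + 1e-9 for a, b in zip(model.history, model.history[1:]))


def test_single_sentence_single_tag():
    data = [([{"token": "x"}], ["O"])]
    model = train_crf(data, CRFTrainConfig(epochs=5))
    assert decode(model, [{"token": "x"}]) == ["O"]


def test_empty_data_rejected():
    with pytest.raises(ValueError):
        train_crf([], CRFTrainConfig())


def test_stronger_l2_does_not_increase_weight_norm():
    data = separable_fixture(n_sentences=20)
    norms = []
    for l2 in (0.0003, 0.03, 3.0):
        m = train_crf(data, CRFTrainConfig(epochs=60, l2=l2))
        norms.append(
            np.linalg.norm(m.obs_weights) + np.linalg.norm(m.trans_weights)
        )
    assert norms[0] >= norms[1] >= norms[2]


def test_lbfgs_optimizer_also_fits():
    data = separable_fixture(n_sentences=20)
    model = train_crf(data, CRFTrainConfig(epochs=80, optimizer="lbfgs"))
    correct = total = 0
    for obs, tags in data:
        pred = decode(model, obs)
        correct += sum(p == t for p, t in zip(pred, tags))
        total += len(tags)
    assert correct / total > 0.99
    assert all(a <= b + 1e-9 for a, b in zip(model.history, model.history[1:]))


def test_model_container_round_trip(tmp_path):
    data = separable_fixture(n_sentences=10)
    model = train_crf(data, CRFTrainConfig(epochs=10))
    path = tmp_path / "crf.json"
    save_model(model, path)
    back = load_model(path)
    assert back.tags == model.tags
    assert back.feature_index == model.feature_index
    assert np.allclose(back.obs_weights, model.obs_weights)
    obs, tags = data[0]
    assert decode(back, obs) == decode(model, obs)
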