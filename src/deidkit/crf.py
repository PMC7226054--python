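"""Linear-chain conditional random field over indicator feature functions.

The model assigns a tag sequence T = (t_1..t_n) for an observed token
sequence S the conditional probability

    P(T|S) = exp( sum_i [ sum_{f in obs(i)} W[f, t_i] ] +
                  sum_{i>1} A[t_{i-1}, t_i] ) / Z(S)

where ``obs(i)`` is the set of (string-valued) observation features active
at position i — the unified feature set plus feature crosses, rendered as
``name=value`` strings — W holds one weight per (observation feature, tag)
indicator, A one weight per tag bigram, and Z is the partition function
computed by the forward algorithm.

Training maximizes the L2-penalized conditional log-likelihood with batch
gradient ascent (gradient = empirical minus expected feature counts, via
forward-backward marginals). The configured learning rate seeds a
deterministic backtracking line search, so the reported per-epoch training
log-likelihood is non-decreasing by construction; scipy's L-BFGS is
available as an alternative optimizer. Decoding is Viterbi; ties break
toward the lowest tag index. Observation features unseen in training
contribute nothing at decode time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.special import logsumexp

logger = logging.getLogger(__name__)


@dataclass
class CRFTrainConfig:
    learning_rate: float = 0.0005  # initial step size for gradient ascent
    l2: float = 0.0003  # coefficient of the squared-norm penalty
    epochs: int = 100
    seed: int = 0
    optimizer: str = "gd"  # "gd" (backtracking gradient ascent) or "lbfgs"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.l2 < 0 or self.epochs < 0:
            raise ValueError("learning_rate must be > 0, l2 and epochs >= 0")


@dataclass
class CRFModel:
    tags: list[str]
    feature_index: dict[str, int]
    obs_weights: np.ndarray  # (n_features, n_tags)
    trans_weights: np.ndarray  # (n_tags, n_tags), [prev, next]
    history: list[float] = field(default_factory=list)  # per-epoch train LL

    def tag_index(self) -> dict[str, int]:
        return {t: k for k, t in enumerate(self.tags)}


def featurize(vectors: list[dict]) -> list[list[str]]:
    """Render per-token feature dicts as observation feature strings."""
    return [[f"{k}={v}" for k, v in sorted(vec.items())] for vec in vectors]


def _as_strings(vectors) -> list[list[str]]:
    if vectors and isinstance(vectors[0], dict):
        return featurize(vectors)
    return [list(v) for v in vectors]


def _emissions(model: CRFModel, obs: list[list[str]]) -> np.ndarray:
    n, k = len(obs), len(model.tags)
    e = np.zeros((n, k))
    for i, feats in enumerate(obs):
        for f in feats:
            j = model.feature_index.get(f)
            if j is not None:
                e[i] += model.obs_weights[j]
    return e


def _forward_logz(emis: np.ndarray, trans: np.ndarray) -> float:
    alpha = emis[0].copy()
    for i in range(1, len(emis)):
        alpha = emis[i] + logsumexp(alpha[:, None] + trans, axis=0)
    return float(logsumexp(alpha))


def _forward_backward(emis: np.ndarray, trans: np.ndarray):
    """Log partition, unary marginals (n,K), summed pairwise marginals (K,K)."""
    n, k = emis.shape
    alphas = np.empty((n, k))
    alphas[0] = emis[0]
    for i in range(1, n):
        alphas[i] = emis[i] + logsumexp(alphas[i - 1][:, None] + trans, axis=0)
    betas = np.empty((n, k))
    betas[-1] = 0.0
    for i in range(n - 2, -1, -1):
        betas[i] = logsumexp(trans + emis[i + 1] + betas[i + 1], axis=1)
    logz = float(logsumexp(alphas[-1]))
    unary = np.exp(alphas + betas - logz)
    pair = np.zeros((k, k))
    for i in range(n - 1):
        lp = (
            alphas[i][:, None]
            + trans
            + emis[i + 1][None, :]
            + betas[i + 1][None, :]
            - logz
        )
        pair += np.exp(lp)
    return logz, unary, pair


def sequence_score(model: CRFModel, vectors, tags: list[str]) -> float:
    """Unnormalized log score of a tag sequence."""
    obs = _as_strings(vectors)
    tag_idx = model.tag_index()
    idx = [tag_idx[t] for t in tags]
    emis = _emissions(model, obs)
    s = float(sum(emis[i, t] for i, t in enumerate(idx)))
    s += float(sum(model.trans_weights[a, b] for a, b in zip(idx, idx[1:])))
    return s


def sequence_log_prob(model: CRFModel, vectors, tags: list[str]) -> float:
    """log P(T|S): sequence score minus the forward-algorithm log Z."""
    obs = _as_strings(vectors)
    emis = _emissions(model, obs)
    return sequence_score(model, obs, tags) - _forward_logz(
        emis, model.trans_weights
    )


def decode(model: CRFModel, vectors) -> list[str]:
    """Viterbi argmax tag sequence; ties break toward the lowest tag index."""
    obs = _as_strings(vectors)
    if not obs:
        return []
    emis = _emissions(model, obs)
    n, k = emis.shape
    delta = emis[0].copy()
    back = np.zeros((n, k), dtype=int)
    for i in range(1, n):
        scores = delta[:, None] + model.trans_weights
        back[i] = np.argmax(scores, axis=0)
        delta = emis[i] + scores[back[i], np.arange(k)]
    path = [int(np.argmax(delta))]
    for i in range(n - 1, 0, -1):
        path.append(int(back[i, path[-1]]))
    return [model.tags[t] for t in reversed(path)]


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _build_design(data):
    """Index features/tags and assemble a corpus-wide sparse design matrix."""
    obs_seqs = [_as_strings(vectors) for vectors, _ in data]
    tag_set = sorted({t for _, tags in data for t in tags})
    feat_set = sorted({f for seq in obs_seqs for feats in seq for f in feats})
    feature_index = {f: j for j, f in enumerate(feat_set)}
    rows, cols = [], []
    offsets = [0]
    r = 0
    for seq in obs_seqs:
        for feats in seq:
            for f in feats:
                rows.append(r)
                cols.append(feature_index[f])
            r += 1
        offsets.append(r)
    x = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(r, len(feat_set))
    )
    return obs_seqs, tag_set, feature_index, x, offsets


def _objective_and_grad(theta, x, offsets, gold_idx, n_feat, n_tag, l2):
    w = theta[: n_feat * n_tag].reshape(n_feat, n_tag)
    trans = theta[n_feat * n_tag :].reshape(n_tag, n_tag)
    emis_all = np.asarray(x @ w)
    ll = 0.0
    marg_all = np.zeros_like(emis_all)
    pair_exp = np.zeros((n_tag, n_tag))
    pair_emp = np.zeros((n_tag, n_tag))
    for s in range(len(offsets) - 1):
        a, b = offsets[s], offsets[s + 1]
        emis = emis_all[a:b]
        idx = gold_idx[a:b]
        logz, unary, pair = _forward_backward(emis, trans)
        ll += float(emis[np.arange(b - a), idx].sum())
        ll += float(trans[idx[:-1], idx[1:]].sum())
        ll -= logz
        marg_all[a:b] = unary
        pair_exp += pair
        np.add.at(pair_emp, (idx[:-1], idx[1:]), 1.0)
    gold_onehot = np.zeros_like(emis_all)
    gold_onehot[np.arange(len(gold_idx)), gold_idx] = 1.0
    grad_w = np.asarray(x.T @ (gold_onehot - marg_all))
    grad_t = pair_emp - pair_exp
    ll -= l2 * float(theta @ theta)
    grad = np.concatenate([grad_w.ravel(), grad_t.ravel()]) - 2.0 * l2 * theta
    if not np.isfinite(ll):
        raise FloatingPointError(
            f"non-finite CRF objective (ll={ll}); check features and step size"
        )
    return ll, grad


def train_crf(data, config: CRFTrainConfig | None = None) -> CRFModel:
    """Fit CRF weights by penalized maximum likelihood.

    ``data`` is a list of (per-token feature dicts or observation strings,
    gold tag list) pairs. Deterministic given the config and data order.
    """
    if not data:
        raise ValueError("empty training data")
    for vectors, tags in data:
        if len(vectors) != len(tags):
            raise ValueError("feature/tag length mismatch in training pair")
    config = config or CRFTrainConfig()
    obs_seqs, tag_set, feature_index, x, offsets = _build_design(data)
    n_feat, n_tag = len(feature_index), len(tag_set)
    tag_idx = {t: k for k, t in enumerate(tag_set)}
    gold_idx = np.array(
        [tag_idx[t] for _, tags in data for t in tags], dtype=int
    )
    theta = np.zeros(n_feat * n_tag + n_tag * n_tag)
    history: list[float] = []

    if config.optimizer == "lbfgs":
        from scipy.optimize import minimize

        def neg(thet):
            ll, grad = _objective_and_grad(
                thet, x, offsets, gold_idx, n_feat, n_tag, config.l2
            )
            history.append(ll)
            return -ll, -grad

        res = minimize(
            neg,
            theta,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max(config.epochs, 1)},
        )
        theta = res.x
        # line-search evaluations are not monotone; report the running best
        history[:] = np.maximum.accumulate(history).tolist()
    elif config.optimizer == "gd":
        lr = config.learning_rate
        ll, grad = _objective_and_grad(
            theta, x, offsets, gold_idx, n_feat, n_tag, config.l2
        )
        for epoch in range(config.epochs):
            improved = False
            step = lr
            for _ in range(25):
                cand = theta + step * grad
                cand_ll, cand_grad = _objective_and_grad(
                    cand, x, offsets, gold_idx, n_feat, n_tag, config.l2
                )
                if cand_ll >= ll:
                    theta, ll, grad = cand, cand_ll, cand_grad
                    lr = step * 1.2
                    improved = True
                    break
                step *= 0.5
            history.append(ll)
            logger.info("crf epoch %d: log-likelihood %.6f", epoch + 1, ll)
            if not improved:
                break
    else:
        raise ValueError(f"unknown optimizer {config.optimizer!r}")

    w = theta[: n_feat * n_tag].reshape(n_feat, n_tag)
    trans = theta[n_feat * n_tag :].reshape(n_tag, n_tag)
    return CRFModel(
        tags=tag_set,
        feature_index=feature_index,
        obs_weights=w,
        trans_weights=trans,
        history=history,
    )


def objective(model: CRFModel, data, l2: float = 0.0):
    """Penalized log-likelihood and gradient at the model's current weights.

    Exposed for gradient checking: the gradient is analytic (empirical minus
    expected counts from forward-backward).
    """
    obs_seqs, tag_set, feature_index, x, offsets = _build_design(data)
    if tag_set != model.tags or feature_index != model.feature_index:
        raise ValueError("data features/tags do not match the model's index")
    tag_idx = model.tag_index()
    gold_idx = np.array([tag_idx[t] for _, tags in data for t in tags], dtype=int)
    theta = np.concatenate(
        [model.obs_weights.ravel(), model.trans_weights.ravel()]
    )
    return _objective_and_grad(
        theta, x, offsets, gold_idx, len(feature_index), len(model.tags), l2
    )


# JSON model container -------------------------------------------------------


def save_model(model: CRFModel, path) -> None:
    import json

    obj = {
        "format": "deidkit-crf",
        "version": 1,
        "tags": model.tags,
        "features": sorted(model.feature_index, key=model.feature_index.get),
        "obs_weights": model.obs_weights.tolist(),
        "trans_weights": model.trans_weights.tolist(),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh)


def load_model(path) -> CRFModel:
    import json

    with open(path, encoding="utf-8") as fh:
        obj = json.load(fh)
    if obj.get("format") != "deidkit-crf":
        raise ValueError(f"{path}: not a CRF model container")
    return CRFModel(
        tags=list(obj["tags"]),
        feature_index={f: j for j, f in enumerate(obj["features"])},
        obs_weights=np.array(obj["obs_weights"], dtype=float),
        trans_weights=np.array(obj["trans_weights"], dtype=float),
    )
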