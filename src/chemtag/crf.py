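"""Linear-chain conditional random fields over featurized token sequences.

The model assigns a label sequence score

    s(y | x) = sum_t  w_emit(f(x, t), y_t)  +  sum_t  w_trans(y_{t-k..t-1}, y_t)

with k = ``order`` (1 or 2).  Emission weights are tied to the current label;
label-history dependence is carried by the transition table, which for order
2 ranges over label triples (a begin-of-sequence pseudo-label pads the
history).  Second-order decoding is realised by expanding each Viterbi /
forward-backward state to a (previous label, label) pair over the first-order
machinery -- exactly the classical state-expansion construction, and verified
against brute-force enumeration in the test-suite.

Transitions that would violate the IOB scheme (I-c after anything but B-c or
I-c) are structural zeros: they receive -inf score in training and decoding,
so every decoded sequence is IOB-valid by construction.

Training maximises the L2-penalised conditional log-likelihood with L-BFGS;
the objective is convex and the initial point is the origin, so training is
deterministic.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import minimize
from scipy.special import logsumexp

from .corpus_io import check_iob
from .errors import ChemtagError, ModelFormatError

__all__ = ["CRFConfig", "CRFModel", "train", "decode", "save", "load"]

FORMAT_VERSION = "chemtag-crf-1"
NEG_INF = -np.inf


@dataclass(frozen=True)
class CRFConfig:
    """Model structure and optimiser settings.

    ``labels`` is the full label alphabet (joint: O plus B/I per class;
    single-class: O, B-c, I-c).  ``offset`` records the feature context
    window the sequences were featurized with (bookkeeping only).
    """

    labels: tuple[str, ...]
    order: int = 2
    offset: int = 1
    max_iterations: int = 200
    c2: float = 1.0
    tol: float = 1e-4
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.order not in (1, 2):
            raise ValueError("order must be 1 or 2")
        if self.offset < 0:
            raise ValueError("offset must be >= 0")
        if "O" not in self.labels:
            raise ValueError("label alphabet must contain 'O'")


def iob_transition_mask(labels: Sequence[str]) -> np.ndarray:
    """(m+1, m) matrix of 0 / -inf; row m is the begin-of-sequence state."""
    m = len(labels)
    mask = np.zeros((m + 1, m))
    for j, cur in enumerate(labels):
        if not cur.startswith("I-"):
            continue
        cls = cur[2:]
        ok = {f"B-{cls}", cur}
        for i in range(m + 1):
            prev = labels[i] if i < m else None  # None = BOS
            if prev not in ok:
                mask[i, j] = NEG_INF
    return mask


# ---------------------------------------------------------------------------
# first-order inference


def _forward_backward_o1(E, Wt, mask):
    """Return (logZ, posteriors (T, m), expected transition counts (m+1, m))."""
    T, m = E.shape
    B = m
    trans = Wt[:m] + mask[:m]  # (m, m) with structural zeros
    alpha = np.empty((T, m))
    alpha[0] = E[0] + Wt[B] + mask[B]
    for t in range(1, T):
        alpha[t] = logsumexp(alpha[t - 1][:, None] + trans, axis=0) + E[t]
    logZ = logsumexp(alpha[T - 1])
    beta = np.zeros((T, m))
    for t in range(T - 2, -1, -1):
        beta[t] = logsumexp(trans + (E[t + 1] + beta[t + 1])[None, :], axis=1)
    post = np.exp(alpha + beta - logZ)
    expT = np.zeros((m + 1, m))
    expT[B] = post[0]
    for t in range(1, T):
        with np.errstate(invalid="ignore"):
            xi = np.exp(
                alpha[t - 1][:, None] + trans + (E[t] + beta[t])[None, :] - logZ
            )
        expT[:m] += np.nan_to_num(xi)
    return logZ, post, expT


def _viterbi_o1(E, Wt, mask):
    T, m = E.shape
    B = m
    trans = Wt[:m] + mask[:m]
    delta = E[0] + Wt[B] + mask[B]
    ptrs = np.empty((T, m), dtype=np.intp)
    for t in range(1, T):
        scores = delta[:, None] + trans
        ptrs[t] = np.argmax(scores, axis=0)
        delta = scores[ptrs[t], np.arange(m)] + E[t]
    path = np.empty(T, dtype=np.intp)
    path[T - 1] = int(np.argmax(delta))
    for t in range(T - 1, 0, -1):
        path[t - 1] = ptrs[t, path[t]]
    return path


def _score_o1(E, Wt, mask, y):
    T, m = E.shape
    B = m
    s = E[np.arange(T), y].sum() + Wt[B, y[0]] + mask[B, y[0]]
    for t in range(1, T):
        s += Wt[y[t - 1], y[t]] + mask[y[t - 1], y[t]]
    return s


# ---------------------------------------------------------------------------
# second-order inference (expanded pair states)


def _forward_o2(E, Wt, mask):
    """Forward pass; returns (logZ, a0, list of pair matrices M_t, t>=1)."""
    T, m = E.shape
    B = m
    a0 = E[0] + Wt[B, B, :m] + mask[B]
    if T == 1:
        return logsumexp(a0), a0, []
    Ms = []
    M = a0[:, None] + Wt[B, :m, :] + mask[:m] + E[1][None, :]
    Ms.append(M)
    core = Wt[:m, :m, :]  # (a, b, c)
    for t in range(2, T):
        S = logsumexp(M[:, :, None] + core, axis=0)
        M = S + mask[:m] + E[t][None, :]
        Ms.append(M)
    return logsumexp(M), a0, Ms


def _forward_backward_o2(E, Wt, mask):
    """Return (logZ, posteriors (T, m), expected triple counts (m+1, m+1, m))."""
    T, m = E.shape
    B = m
    expT = np.zeros((m + 1, m + 1, m))
    logZ, a0, Ms = _forward_o2(E, Wt, mask)
    if T == 1:
        post = np.exp(a0 - logZ)[None, :]
        expT[B, B] += post[0]
        return logZ, post, expT
    core = Wt[:m, :m, :]
    # backward over pair states: Bw[t][b, c] sums suffixes given
    # (y_{t-1}=b, y_t=c)
    Bw = [None] * T
    Bw[T - 1] = np.zeros((m, m))
    for t in range(T - 2, 0, -1):
        inner = core + (mask[:m] + E[t + 1][None, :] + Bw[t + 1])[None, :, :]
        Bw[t] = logsumexp(inner, axis=2)
    post = np.empty((T, m))
    with np.errstate(invalid="ignore"):
        if T >= 2:
            bw0 = logsumexp(
                Wt[B, :m, :] + mask[:m] + E[1][None, :] + Bw[1], axis=1
            )
            post[0] = np.nan_to_num(np.exp(a0 + bw0 - logZ))
            expT[B, B] += post[0]
        for t in range(1, T):
            pair = np.nan_to_num(np.exp(Ms[t - 1] + Bw[t] - logZ))
            post[t] = pair.sum(axis=0)
            if t == 1:
                expT[B, :m, :] += pair
        for t in range(2, T):
            xi = np.exp(
                Ms[t - 2][:, :, None]
                + core
                + (mask[:m] + E[t][None, :] + Bw[t])[None, :, :]
                - logZ
            )
            expT[:m, :m, :] += np.nan_to_num(xi)
    return logZ, post, expT


def _viterbi_o2(E, Wt, mask):
    T, m = E.shape
    B = m
    a0 = E[0] + Wt[B, B, :m] + mask[B]
    if T == 1:
        return np.array([int(np.argmax(a0))], dtype=np.intp)
    M = a0[:, None] + Wt[B, :m, :] + mask[:m] + E[1][None, :]
    core = Wt[:m, :m, :]
    ptrs = []
    for t in range(2, T):
        scores = M[:, :, None] + core  # (a, b, c)
        p = np.argmax(scores, axis=0)  # (b, c)
        ptrs.append(p)
        bi = np.arange(m)[:, None]
        ci = np.arange(m)[None, :]
        M = scores[p, bi, ci] + mask[:m] + E[t][None, :]
    flat = int(np.argmax(M))
    b, c = divmod(flat, m)
    path = [b, c]
    for p in reversed(ptrs):
        a = int(p[b, c])
        path.insert(0, a)
        b, c = a, b
    return np.asarray(path, dtype=np.intp)


def _score_o2(E, Wt, mask, y):
    T, m = E.shape
    B = m
    s = E[np.arange(T), y].sum() + Wt[B, B, y[0]] + mask[B, y[0]]
    if T >= 2:
        s += Wt[B, y[0], y[1]] + mask[y[0], y[1]]
    for t in range(2, T):
        s += Wt[y[t - 2], y[t - 1], y[t]] + mask[y[t - 1], y[t]]
    return s


# ---------------------------------------------------------------------------
# model object


@dataclass
class CRFModel:
    """A trained chain CRF: feature vocabulary, label alphabet, weights."""

    config: CRFConfig
    feature_index: dict[str, int]
    W_emit: np.ndarray  # (F, m)
    W_trans: np.ndarray  # order 1: (m+1, m); order 2: (m+1, m+1, m)
    mask: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.mask = iob_transition_mask(self.config.labels)

    @property
    def labels(self) -> tuple[str, ...]:
        return self.config.labels

    def emissions(self, seq: Sequence[Iterable[str]]) -> np.ndarray:
        """Sum of emission weights of the *known* features at each position;
        unknown features contribute zero."""
        E = np.zeros((len(seq), len(self.labels)))
        idx = self.feature_index
        for t, feats in enumerate(seq):
            rows = [idx[f] for f in feats if f in idx]
            if rows:
                E[t] = self.W_emit[rows].sum(axis=0)
        return E

    def decode(self, seq: Sequence[Iterable[str]]) -> list[str]:
        if len(seq) == 0:
            return []
        E = self.emissions(seq)
        if self.config.order == 1:
            path = _viterbi_o1(E, self.W_trans, self.mask)
        else:
            path = _viterbi_o2(E, self.W_trans, self.mask)
        labels = [self.labels[i] for i in path]
        check_iob(labels)
        return labels

    def marginals(self, seq: Sequence[Iterable[str]]) -> np.ndarray:
        """(T, m) posterior label probabilities per position."""
        if len(seq) == 0:
            return np.zeros((0, len(self.labels)))
        E = self.emissions(seq)
        fb = _forward_backward_o1 if self.config.order == 1 else _forward_backward_o2
        _, post, _ = fb(E, self.W_trans, self.mask)
        return post


def decode(model: CRFModel, seq: Sequence[Iterable[str]]) -> list[str]:
    """Viterbi-optimal, IOB-valid label sequence (module-level convenience)."""
    return model.decode(seq)


# ---------------------------------------------------------------------------
# training


def train(
    corpus: Sequence[tuple[Sequence[Iterable[str]], Sequence[str]]],
    config: CRFConfig,
) -> CRFModel:
    """Fit weights by penalised maximum likelihood.

    ``corpus`` pairs featurized sequences with IOB-valid label sequences
    drawn from ``config.labels``.  The objective is convex and initialised
    at the origin, so the result is deterministic.
    """
    if not corpus:
        raise ChemtagError("empty training corpus")
    labels = config.labels
    lab_idx = {lab: i for i, lab in enumerate(labels)}
    m = len(labels)
    B = m

    seqs = []
    for feats, labs in corpus:
        if len(feats) != len(labs):
            raise ChemtagError("feature/label length mismatch")
        if len(feats) == 0:
            continue
        for lab in labs:
            if lab not in lab_idx:
                raise ChemtagError(f"label {lab!r} outside the model alphabet")
        check_iob(labs)
        seqs.append((feats, np.array([lab_idx[l] for l in labs], dtype=np.intp)))
    if not seqs:
        raise ChemtagError("no non-empty training sequences")

    # build the global sparse design matrix
    feature_index: dict[str, int] = {}
    rows, cols = [], []
    n = 0
    bounds = [0]
    y_list = []
    for feats, y in seqs:
        for tok_feats in feats:
            for f in tok_feats:
                j = feature_index.setdefault(f, len(feature_index))
                rows.append(n)
                cols.append(j)
            n += 1
        bounds.append(n)
        y_list.append(y)
    F = len(feature_index)
    X = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, F), dtype=np.float64
    )
    XT = X.T.tocsr()
    Yoh = np.zeros((n, m))
    y_all = np.concatenate(y_list)
    Yoh[np.arange(n), y_all] = 1.0

    mask = iob_transition_mask(labels)
    t_shape = (m + 1, m) if config.order == 1 else (m + 1, m + 1, m)
    t_size = int(np.prod(t_shape))

    # observed transition counts are constant across iterations
    obsT = np.zeros(t_shape)
    for y in y_list:
        if config.order == 1:
            obsT[B, y[0]] += 1
            for t in range(1, len(y)):
                obsT[y[t - 1], y[t]] += 1
        else:
            obsT[B, B, y[0]] += 1
            if len(y) >= 2:
                obsT[B, y[0], y[1]] += 1
            for t in range(2, len(y)):
                obsT[y[t - 2], y[t - 1], y[t]] += 1

    fb = _forward_backward_o1 if config.order == 1 else _forward_backward_o2
    score = _score_o1 if config.order == 1 else _score_o2

    def objective(w):
        W_emit = w[: F * m].reshape(F, m)
        Wt = w[F * m :].reshape(t_shape)
        E_all = X @ W_emit
        ll = 0.0
        P_all = np.empty((n, m))
        expT = np.zeros(t_shape)
        for k, y in enumerate(y_list):
            s, e = bounds[k], bounds[k + 1]
            E = E_all[s:e]
            logZ, post, eT = fb(E, Wt, mask)
            P_all[s:e] = post
            expT += eT
            ll += score(E, Wt, mask, y) - logZ
        grad_emit = XT @ (P_all - Yoh)
        gradT = expT - obsT
        nll = -ll + 0.5 * config.c2 * float(w @ w)
        grad = np.concatenate([grad_emit.ravel(), gradT.ravel()]) + config.c2 * w
        return nll, grad

    w0 = np.zeros(F * m + t_size)
    res = minimize(
        objective,
        w0,
        jac=True,
        method="L-BFGS-B",
        options={
            "maxiter": config.max_iterations,
            "maxfun": 4 * config.max_iterations,
            "gtol": config.tol,
            "ftol": 1e-10,
        },
    )
    w = res.x
    return CRFModel(
        config=config,
        feature_index=feature_index,
        W_emit=w[: F * m].reshape(F, m).copy(),
        W_trans=w[F * m :].reshape(t_shape).copy(),
    )


# ---------------------------------------------------------------------------
# persistence


def save(model: CRFModel, path: str | Path) -> None:
    feats = np.array(
        sorted(model.feature_index, key=model.feature_index.get), dtype=str
    )
    cfg = json.dumps(asdict(model.config))
    with open(path, "wb") as fh:
        np.savez_compressed(
            fh,
            format_version=np.array(FORMAT_VERSION),
            config=np.array(cfg),
            features=feats,
            W_emit=model.W_emit,
            W_trans=model.W_trans,
        )


def load(path: str | Path) -> CRFModel:
    try:
        with np.load(path, allow_pickle=False) as data:
            if "format_version" not in data:
                raise ModelFormatError(f"{path}: not a chemtag CRF model")
            version = str(data["format_version"])
            if version != FORMAT_VERSION:
                raise ModelFormatError(
                    f"{path}: unsupported model version {version!r}"
                )
            cfg_dict = json.loads(str(data["config"]))
            cfg_dict["labels"] = tuple(cfg_dict["labels"])
            config = CRFConfig(**cfg_dict)
            feats = [str(f) for f in data["features"]]
            model = CRFModel(
                config=config,
                feature_index={f: i for i, f in enumerate(feats)},
                W_emit=data["W_emit"].astype(np.float64),
                W_trans=data["W_trans"].astype(np.float64),
            )
    except (OSError, ValueError, KeyError, zipfile.BadZipFile) as exc:
        raise ModelFormatError(f"{path}: cannot read model ({exc})") from exc
    if model.W_emit.shape[1] != len(config.labels):
        raise ModelFormatError(f"{path}: inconsistent label dimension")
    return model
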