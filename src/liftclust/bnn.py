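"""Bayesian-regularized feed-forward network with evidence-based model selection.

A three-layer tanh network is trained by Levenberg-Marquardt on the
regularized objective ``G = beta*K_S + alpha*K_W`` with ``K_S`` half the sum
of squared output errors and ``K_W = ||w||^2 / 2``.  After each accepted step
the hyper-parameters are re-estimated from the effective number of parameters
``gamma = c - alpha * tr(A^-1)`` (Gauss-Newton ``A = beta*J'J + alpha*I``),
i.e. ``alpha <- gamma / (2 K_W)`` and ``beta <- (N - gamma) / (2 K_S)``.

Architecture (hidden-node count) is chosen by the Gaussian-approximation log
evidence at the converged optimum, including the hidden-unit permutation/sign
symmetry terms and the hyper-parameter uncertainty terms.

Cluster labels are one-hot coded in {-1, +1}; the predicted class is the
argmax over the tanh outputs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "NetworkSpec",
    "TrainConfig",
    "HyperParamState",
    "EvidencePoint",
    "ClassificationReport",
    "init_weights",
    "forward",
    "jacobian",
    "train",
    "log_evidence",
    "sweep_hidden_nodes",
    "evaluate",
    "split_train_test",
    "one_hot_targets",
]


@dataclass(frozen=True)
class NetworkSpec:
    """m inputs -> l tanh hidden units -> q tanh outputs."""

    m: int
    l: int
    q: int

    def __post_init__(self) -> None:
        if min(self.m, self.l, self.q) < 1:
            raise ValueError("all layer sizes must be >= 1")

    @property
    def n_params(self) -> int:
        return self.l * (self.m + 1) + self.q * (self.l + 1)


@dataclass
class TrainConfig:
    max_epochs: int = 600
    mu_init: float = 5e-3
    mu_factor: float = 10.0
    mu_max: float = 1e100
    grad_min: float = 1e-20
    alpha_init: float = 0.0
    beta_init: float = 1.0
    # Residual noise floor (per error term, on the +/-1 target scale) used in
    # the beta re-estimation only.  With noise-free separable labels a tanh
    # output layer can drive K_S to ~0 through saturation, sending beta (and
    # the log evidence) to infinity; flooring K_S at N*noise_floor^2/2 keeps
    # the evidence finite while leaving genuinely noisy tasks untouched.
    noise_floor: float = 0.01
    # Epochs of plain (alpha=0, beta=1) Levenberg-Marquardt before the
    # hyper-parameter re-estimation starts.  The first alpha estimate divides
    # by K_W, so it must see weights that have already grown to fit the data;
    # updating from near-zero initial weights collapses small networks.
    hyper_warmup: int = 30


@dataclass
class HyperParamState:
    alpha: float
    beta: float
    gamma: float
    c: int  # total parameter count
    n_errors: int  # training targets x outputs


@dataclass
class EvidencePoint:
    hidden_nodes: int
    log_evidence: float


@dataclass
class ClassificationReport:
    confusion: np.ndarray  # rows = true class, cols = predicted class
    recall: np.ndarray
    precision: np.ndarray  # NaN where a class was never predicted
    accuracy: float
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray


def _unpack(spec: NetworkSpec, w: np.ndarray):
    m, l, q = spec.m, spec.l, spec.q
    i = 0
    W1 = w[i : i + l * m].reshape(l, m)
    i += l * m
    b1 = w[i : i + l]
    i += l
    W2 = w[i : i + q * l].reshape(q, l)
    i += q * l
    b2 = w[i : i + q]
    return W1, b1, W2, b2


def init_weights(spec: NetworkSpec, rng: np.random.Generator) -> np.ndarray:
    """Small uniform weights scaled by the fan-in of each layer."""
    r1 = 1.0 / math.sqrt(spec.m)
    r2 = 1.0 / math.sqrt(spec.l)
    parts = [
        rng.uniform(-r1, r1, spec.l * spec.m),
        rng.uniform(-r1, r1, spec.l),
        rng.uniform(-r2, r2, spec.q * spec.l),
        rng.uniform(-r2, r2, spec.q),
    ]
    return np.concatenate(parts)


def forward(spec: NetworkSpec, w: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Network outputs z = tanh(b2 + W2 tanh(b1 + W1 x)) for each row of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != spec.m:
        raise ValueError(f"expected {spec.m} input features, got {X.shape[1]}")
    if w.size != spec.n_params:
        raise ValueError("weight vector size mismatch")
    W1, b1, W2, b2 = _unpack(spec, w)
    H = np.tanh(X @ W1.T + b1)
    return np.tanh(H @ W2.T + b2)


def jacobian(spec: NetworkSpec, w: np.ndarray, X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Outputs and the Jacobian dz/dw, shape (n_samples, q, c)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    m, l, q = spec.m, spec.l, spec.q
    W1, b1, W2, b2 = _unpack(spec, w)
    H = np.tanh(X @ W1.T + b1)  # (n, l)
    Z = np.tanh(H @ W2.T + b2)  # (n, q)
    dZ = 1.0 - Z**2  # (n, q)
    dH = 1.0 - H**2  # (n, l)
    J = np.zeros((n, q, spec.n_params))
    # back-propagated signal to each hidden unit for each output
    G1 = dZ[:, :, None] * W2[None, :, :] * dH[:, None, :]  # (n, q, l)
    J[:, :, : l * m] = (G1[:, :, :, None] * X[:, None, None, :]).reshape(n, q, l * m)
    J[:, :, l * m : l * m + l] = G1
    off = l * (m + 1)
    # output-layer weights: dz_k/dW2[k, i] = dZ[:, k] * H[:, i]
    W2_block = np.zeros((n, q, q, l))
    idx = np.arange(q)
    W2_block[:, idx, idx, :] = dZ[:, :, None] * H[:, None, :]
    J[:, :, off : off + q * l] = W2_block.reshape(n, q, q * l)
    off += q * l
    b2_block = np.zeros((n, q, q))
    b2_block[:, idx, idx] = dZ
    J[:, :, off :] = b2_block
    return Z, J


def one_hot_targets(labels, q: Optional[int] = None) -> np.ndarray:
    """{-1, +1} one-hot coding of integer labels 1..q (tanh output range)."""
    labels = np.asarray(labels, dtype=int)
    if labels.min() < 1:
        raise ValueError("labels must be 1-based")
    if q is None:
        q = int(labels.max())
    elif labels.max() > q:
        raise ValueError("label outside 1..q")
    T = -np.ones((labels.size, q))
    T[np.arange(labels.size), labels - 1] = 1.0
    return T


def train(
    X,
    T,
    spec: NetworkSpec,
    config: Optional[TrainConfig] = None,
    seed: int = 0,
):
    """Levenberg-Marquardt training with Bayesian regularization.

    Returns ``(weights, HyperParamState, history)`` where ``history`` records,
    per epoch, the objective before/after the accepted step together with the
    hyper-parameters in force, so the monotonicity of accepted steps can be
    audited.  Stops at the epoch cap, the damping cap, or the gradient floor.
    """
    if config is None:
        config = TrainConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    T = np.atleast_2d(np.asarray(T, dtype=float))
    if T.shape[1] != spec.q:
        raise ValueError("target width must equal the number of outputs")
    if spec.q >= 2 and np.unique(np.argmax(T, axis=1)).size < 2:
        raise ValueError("training data must contain at least 2 classes")
    n = X.shape[0]
    c = spec.n_params
    N = n * spec.q
    rng = np.random.default_rng(seed)
    w = init_weights(spec, rng)
    alpha, beta = config.alpha_init, config.beta_init
    mu = config.mu_init
    gamma = float(c)
    history: List[dict] = []
    stop_reason = "max_epochs"
    identity = np.eye(c)
    hyper_started = False

    for epoch in range(config.max_epochs):
        Z, J = jacobian(spec, w, X)
        E = Z - T  # residuals
        e = E.reshape(-1)
        Jf = J.reshape(N, c)
        K_S = 0.5 * float(e @ e)
        K_W = 0.5 * float(w @ w)
        JtJ = Jf.T @ Jf
        # hyper-parameter re-estimation at the current point
        if epoch > config.hyper_warmup:
            hyper_started = True
        if hyper_started:
            A = beta * JtJ + max(alpha, 1e-300) * identity
            try:
                trace_inv = float(np.trace(np.linalg.inv(A)))
            except np.linalg.LinAlgError:
                trace_inv = float(np.trace(np.linalg.pinv(A)))
            # gamma cannot meaningfully exceed the number of error terms; the
            # 0.9 N cap keeps the implied noise estimate positive and prevents
            # over-parameterized nets (c >= N) from collapsing to zero weights
            gamma = float(np.clip(c - alpha * trace_inv, 0.0, min(c, 0.9 * N)))
            alpha = max(gamma / (2.0 * K_W), 1e-12) if K_W > 0 else 1e-12
            ks_eff = max(K_S, 0.5 * N * config.noise_floor**2)
            beta = max((N - gamma) / (2.0 * ks_eff), 1e-12)
        G = beta * K_S + alpha * K_W
        grad = beta * (Jf.T @ e) + alpha * w
        if float(np.linalg.norm(grad)) < config.grad_min:
            if not hyper_started:  # converged during warmup: regularize now
                hyper_started = True
                continue
            stop_reason = "grad_min"
            break
        accepted = False
        while mu <= config.mu_max:
            try:
                delta = np.linalg.solve(beta * JtJ + (alpha + mu) * identity, -grad)
            except np.linalg.LinAlgError:
                mu *= config.mu_factor
                continue
            w_new = w + delta
            Z_new = forward(spec, w_new, X)
            e_new = (Z_new - T).reshape(-1)
            G_new = beta * 0.5 * float(e_new @ e_new) + alpha * 0.5 * float(w_new @ w_new)
            if G_new < G:
                w = w_new
                mu = max(mu / config.mu_factor, 1e-20)
                accepted = True
                history.append(
                    {
                        "epoch": epoch,
                        "G_before": G,
                        "G_after": G_new,
                        "alpha": alpha,
                        "beta": beta,
                        "gamma": gamma,
                        "mu": mu,
                    }
                )
                break
            mu *= config.mu_factor
        if not accepted:
            if not hyper_started:  # stalled during warmup: regularize now
                hyper_started = True
                mu = config.mu_init
                continue
            stop_reason = "mu_max"
            break

    # final state at the converged weights
    Z, J = jacobian(spec, w, X)
    e = (Z - T).reshape(-1)
    K_S = 0.5 * float(e @ e)
    K_W = 0.5 * float(w @ w)
    Jf = J.reshape(N, c)
    A = beta * (Jf.T @ Jf) + max(alpha, 1e-300) * identity
    try:
        trace_inv = float(np.trace(np.linalg.inv(A)))
    except np.linalg.LinAlgError:
        trace_inv = float(np.trace(np.linalg.pinv(A)))
    gamma = float(np.clip(c - alpha * trace_inv, 0.0, c))
    state = HyperParamState(alpha=alpha, beta=beta, gamma=gamma, c=c, n_errors=N)
    if history:
        history[-1]["stop_reason"] = stop_reason
    return w, state, history


def log_evidence(
    w: np.ndarray,
    state: HyperParamState,
    spec: NetworkSpec,
    X,
    T,
) -> EvidencePoint:
    """Gaussian-approximation log evidence of the trained network.

    ``-alpha K_W - beta K_S - 0.5 ln|A| + (W/2) ln alpha + (N/2) ln beta
    + ln M! + M ln 2 + 0.5 ln(2/gamma) + 0.5 ln(2/(N-gamma))`` with
    ``A = beta J'J + alpha I`` the Gauss-Newton Hessian of G at the optimum,
    ``W`` the parameter count and ``M`` the hidden-node count.  Raises if A is
    not positive definite (the point must then be excluded from a sweep).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    T = np.atleast_2d(np.asarray(T, dtype=float))
    Z, J = jacobian(spec, w, X)
    e = (Z - T).reshape(-1)
    K_S = 0.5 * float(e @ e)
    K_W = 0.5 * float(w @ w)
    c = spec.n_params
    Jf = J.reshape(-1, c)
    A = state.beta * (Jf.T @ Jf) + state.alpha * np.eye(c)
    sign, logdet = np.linalg.slogdet(A)
    if sign <= 0:
        raise np.linalg.LinAlgError("Hessian of G is not positive definite")
    N = state.n_errors
    M = spec.l
    gamma = min(max(state.gamma, 1e-12), N - 1e-12)
    value = (
        -state.alpha * K_W
        - state.beta * K_S
        - 0.5 * logdet
        + 0.5 * c * math.log(max(state.alpha, 1e-300))
        + 0.5 * N * math.log(max(state.beta, 1e-300))
        + math.lgamma(M + 1)
        + M * math.log(2.0)
        + 0.5 * math.log(2.0 / gamma)
        + 0.5 * math.log(2.0 / (N - gamma))
    )
    if not np.isfinite(value):
        raise FloatingPointError("log evidence is not finite")
    return EvidencePoint(hidden_nodes=M, log_evidence=float(value))


def sweep_hidden_nodes(
    X,
    labels,
    l_values: Sequence[int] = tuple(range(1, 16)),
    config: Optional[TrainConfig] = None,
    seed: int = 0,
    n_init: int = 1,
):
    """Train networks per hidden-node count and pick the argmax-evidence spec.

    ``n_init`` restarts are trained per ``l`` and the best-evidence restart
    kept.  Returns ``(best_spec, best_weights, points)`` where ``points``
    holds an :class:`EvidencePoint` for every requested ``l`` (evidence
    ``-inf`` when a point failed).  Ties go to the smallest ``l``.
    """
    l_values = list(l_values)
    if not l_values:
        raise ValueError("l_values must be non-empty")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    T = one_hot_targets(labels)
    q = T.shape[1]
    points = []
    trained = {}
    for i, l in enumerate(l_values):
        spec = NetworkSpec(m=X.shape[1], l=int(l), q=q)
        best = None
        for j in range(max(1, n_init)):
            try:
                w, state, _hist = train(
                    X, T, spec, config=config, seed=seed + i + j * len(l_values)
                )
                point = log_evidence(w, state, spec, X, T)
            except (np.linalg.LinAlgError, FloatingPointError) as exc:
                warnings.warn(f"evidence point l={l} failed: {exc}", stacklevel=2)
                continue
            if best is None or point.log_evidence > best[0].log_evidence:
                best = (point, w)
        if best is None:
            points.append(EvidencePoint(hidden_nodes=int(l), log_evidence=-np.inf))
            continue
        points.append(best[0])
        trained[int(l)] = (spec, best[1])
    if not trained:
        raise RuntimeError("all evidence points failed")
    best_l = max(
        sorted(trained), key=lambda l: next(p.log_evidence for p in points if p.hidden_nodes == l)
    )
    best_spec, best_w = trained[best_l]
    return best_spec, best_w, points


def evaluate(w: np.ndarray, spec: NetworkSpec, X, labels) -> ClassificationReport:
    """Per-class recall/precision and overall accuracy; predicted class = argmax output."""
    labels = np.asarray(labels, dtype=int)
    if labels.min() < 1 or labels.max() > spec.q:
        raise ValueError("label outside 1..q")
    Z = forward(spec, w, X)
    pred = np.argmax(Z, axis=1) + 1
    q = spec.q
    confusion = np.zeros((q, q), dtype=np.int64)
    np.add.at(confusion, (labels - 1, pred - 1), 1)
    tp = np.diag(confusion).astype(float)
    fn = confusion.sum(axis=1) - tp
    fp = confusion.sum(axis=0) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(tp + fn > 0, tp / (tp + fn), np.nan)
        precision = np.where(tp + fp > 0, tp / (tp + fp), np.nan)
    accuracy = float(tp.sum() / labels.size)
    return ClassificationReport(
        confusion=confusion,
        recall=recall,
        precision=precision,
        accuracy=accuracy,
        tp=tp,
        fp=fp,
        fn=fn,
    )


def split_train_test(
    labels,
    fraction: float = 0.5,
    seed: int = 0,
    train_size: Optional[int] = None,
):
    """Stratified train/test split of trial indices.

    Each stratum contributes ``ceil(fraction * n_s)`` members to the training
    side; an explicit ``train_size`` overrides the total (members are then
    shifted one at a time to/from the largest strata, deterministically).
    Returns ``(train_index, test_index)``: disjoint, covering, each stratum
    present on both sides.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every stratum needs at least 2 members")
    n_train = {u: int(math.ceil(fraction * c)) for u, c in zip(uniq, counts)}
    if train_size is not None:
        count_of = dict(zip(uniq, counts))
        while sum(n_train.values()) > train_size:
            u = max(uniq, key=lambda u: (n_train[u], str(u)))
            if n_train[u] <= 1:
                raise ValueError("train_size too small for stratification")
            n_train[u] -= 1
        while sum(n_train.values()) < train_size:
            u = max(uniq, key=lambda u: (count_of[u] - n_train[u], str(u)))
            if n_train[u] >= count_of[u] - 1:
                raise ValueError("train_size too large for stratification")
            n_train[u] += 1
    rng = np.random.default_rng(seed)
    train_idx: List[int] = []
    test_idx: List[int] = []
    for u in uniq:
        members = np.flatnonzero(labels == u)
        perm = rng.permutation(members)
        train_idx.extend(perm[: n_train[u]].tolist())
        test_idx.extend(perm[n_train[u] :].tolist())
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))
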