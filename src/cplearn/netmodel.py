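"""Two-phase neural-network model of learned categorical perception.

The model is trained on binary N-dimensional stimuli in which k of the N
dimensions covary perfectly with a binary category label and the remaining
N−k dimensions are independent fair coin flips — the vector analogue of the
texture stimuli. Training has two phases:

1. **Unsupervised** — an autoencoder (input → h tanh hidden units → linear
   reconstruction) is trained on the stimuli with no category information,
   modelling mere passive exposure.
2. **Supervised** — a linear category head is added on the hidden layer and
   trained (by default fine-tuning the encoder) against ±1-coded category
   targets with corrective feedback, modelling trial-and-error training.

Both phases minimize an L2-regularized mean squared error by full-batch
gradient descent. A net counts as a *Learner* when its final regularized MSE
on the last (category) layer is at or below 10⁻³.

Categorical perception is measured in hidden-unit space: the mean pairwise
Euclidean distance between hidden representations of stimuli from different
categories (between) and the same category (within), snapshotted after the
unsupervised phase ("before" category learning) and after the supervised
phase ("after"). Separation = between_post − between_pre; compression =
within_pre − within_post. Dimensional reduction is tracked as each input
dimension's salience: the Euclidean norm of its encoder weight row, before
vs. after the supervised phase.

The tanh hidden nonlinearity keeps all hidden activations strictly inside
(−1, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "NetConfig",
    "BinaryStimulusSet",
    "NetState",
    "NetCPResult",
    "CategoryNet",
    "CategoryNetResults",
    "gen_binary_stimuli",
    "train_autoencoder",
    "train_supervised",
    "classify_net",
    "cp_effect",
    "sweep_k",
]

SUCCESS_THRESHOLD = 1e-3


@dataclass(frozen=True)
class NetConfig:
    """Architecture and training hyperparameters for one net."""

    n_dims: int = 12
    k_cov: int = 6
    h: int = 8
    learning_rate: float = 0.1
    epochs_unsupervised: int = 300
    epochs_supervised: int = 300
    l2_penalty: float = 1e-5
    success_threshold: float = SUCCESS_THRESHOLD
    finetune_encoder: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.k_cov <= self.n_dims:
            raise ValueError("k_cov must be in 1..n_dims")
        if self.h < 1:
            raise ValueError("h must be >= 1")
        if self.success_threshold <= 0:
            raise ValueError("success_threshold must be positive")


@dataclass(frozen=True)
class BinaryStimulusSet:
    vectors: np.ndarray   # n_items × n_dims, values 0/1
    labels: np.ndarray    # n_items, values 0/1
    covariant_dims: tuple

    @property
    def signed(self) -> np.ndarray:
        """±1 coding of the binary vectors used by the net."""
        return 2.0 * self.vectors - 1.0

    @property
    def signed_labels(self) -> np.ndarray:
        return 2.0 * self.labels - 1.0


@dataclass(frozen=True)
class NetState:
    """All weights of the net plus its phase tag and final supervised loss."""

    w_enc: np.ndarray   # n_dims × h
    b_enc: np.ndarray   # h
    w_dec: np.ndarray   # h × n_dims
    b_dec: np.ndarray   # n_dims
    w_cls: np.ndarray   # h
    b_cls: float
    phase: str          # "init" | "post-unsupervised" | "post-supervised"
    final_mse: float = float("nan")

    def hidden(self, signed_inputs: np.ndarray) -> np.ndarray:
        """Hidden-unit representations; values strictly in (−1, 1)."""
        return np.tanh(signed_inputs @ self.w_enc + self.b_enc)

    def reconstruct(self, signed_inputs: np.ndarray) -> np.ndarray:
        return self.hidden(signed_inputs) @ self.w_dec + self.b_dec

    def predict(self, signed_inputs: np.ndarray) -> np.ndarray:
        return self.hidden(signed_inputs) @ self.w_cls + self.b_cls

    def salience(self) -> np.ndarray:
        """Per-input-dimension weight magnitude: norm of the encoder row."""
        return np.linalg.norm(self.w_enc, axis=1)


@dataclass(frozen=True)
class NetCPResult:
    between_pre: float
    between_post: float
    within_pre: float
    within_post: float
    learner: bool
    salience_pre: np.ndarray
    salience_post: np.ndarray
    covariant_dims: tuple

    @property
    def separation(self) -> float:
        return self.between_post - self.between_pre

    @property
    def compression(self) -> float:
        return self.within_pre - self.within_post


def gen_binary_stimuli(
    cfg: NetConfig,
    n_per_category: int = 40,
    seed: int = 0,
    scheme_from: BinaryStimulusSet | None = None,
) -> BinaryStimulusSet:
    """Balanced labeled binary vectors: k covariant dims, the rest fair flips.

    The covariant dimension set and its category-0 polarities are drawn from a
    dedicated substream of ``seed`` unless ``scheme_from`` is given, in which
    case they are copied from that set — required for probe sets, which must
    share the category structure of the training set while resampling the
    non-covariant dimensions.
    """
    if n_per_category < 2:
        raise ValueError("need at least 2 items per category")
    rng = substream(seed, "net-stimuli")
    if scheme_from is not None:
        dims = scheme_from.covariant_dims
        if len(dims) != cfg.k_cov:
            raise ValueError("scheme_from has a different k_cov")
        cat0 = scheme_from.vectors[scheme_from.labels == 0][0]
        cat0_bits = cat0[list(dims)].astype(int)
    else:
        dims = tuple(
            sorted(rng.choice(cfg.n_dims, size=cfg.k_cov, replace=False).tolist())
        )
        cat0_bits = rng.integers(0, 2, size=cfg.k_cov)
    n = 2 * n_per_category
    labels = np.repeat([0, 1], n_per_category)
    vectors = rng.integers(0, 2, size=(n, cfg.n_dims))
    for j, d in enumerate(dims):
        vectors[:, d] = np.where(labels == 0, cat0_bits[j], 1 - cat0_bits[j])
    return BinaryStimulusSet(
        vectors=vectors.astype(float), labels=labels, covariant_dims=dims
    )


def _init_state(cfg: NetConfig) -> NetState:
    rng = substream(cfg.seed, "net-init")
    scale = 1.0 / np.sqrt(cfg.n_dims)
    return NetState(
        w_enc=rng.normal(0, scale, size=(cfg.n_dims, cfg.h)),
        b_enc=np.zeros(cfg.h),
        w_dec=rng.normal(0, 1.0 / np.sqrt(cfg.h), size=(cfg.h, cfg.n_dims)),
        b_dec=np.zeros(cfg.n_dims),
        w_cls=rng.normal(0, 1.0 / np.sqrt(cfg.h), size=cfg.h),
        b_cls=0.0,
        phase="init",
    )


def train_autoencoder(cfg: NetConfig, stimuli: BinaryStimulusSet) -> NetState:
    """Unsupervised phase: full-batch GD on L2-regularized reconstruction MSE."""
    state = _init_state(cfg)
    x = stimuli.signed
    n, d = x.shape
    w_enc, b_enc = state.w_enc.copy(), state.b_enc.copy()
    w_dec, b_dec = state.w_dec.copy(), state.b_dec.copy()
    lr, l2 = cfg.learning_rate, cfg.l2_penalty
    for _ in range(cfg.epochs_unsupervised):
        h = np.tanh(x @ w_enc + b_enc)
        r = h @ w_dec + b_dec
        d_r = 2.0 * (r - x) / (n * d)
        g_wdec = h.T @ d_r + 2 * l2 * w_dec
        g_bdec = d_r.sum(axis=0)
        d_h = d_r @ w_dec.T
        d_z = d_h * (1 - h**2)
        g_wenc = x.T @ d_z + 2 * l2 * w_enc
        g_benc = d_z.sum(axis=0)
        w_dec -= lr * g_wdec
        b_dec -= lr * g_bdec
        w_enc -= lr * g_wenc
        b_enc -= lr * g_benc
        if not np.isfinite(w_enc).all():
            raise FloatingPointError("autoencoder training diverged")
    return replace(
        state, w_enc=w_enc, b_enc=b_enc, w_dec=w_dec, b_dec=b_dec,
        phase="post-unsupervised",
    )


def train_supervised(
    state: NetState, stimuli: BinaryStimulusSet, cfg: NetConfig
) -> NetState:
    """Supervised phase: category head on the hidden layer, ±1 targets.

    Minimizes mean((output − target)²) + l2·mean(w_cls²); the encoder is
    fine-tuned unless ``cfg.finetune_encoder`` is False. The value of this
    regularized last-layer MSE at the final epoch is recorded on the state.
    """
    if state.phase != "post-unsupervised":
        raise ValueError("supervised phase requires a post-unsupervised state")
    x = stimuli.signed
    y = stimuli.signed_labels
    n = x.shape[0]
    w_enc, b_enc = state.w_enc.copy(), state.b_enc.copy()
    w_cls, b_cls = state.w_cls.copy(), float(state.b_cls)
    lr, l2 = cfg.learning_rate, cfg.l2_penalty
    h_dim = w_cls.size
    for _ in range(cfg.epochs_supervised):
        h = np.tanh(x @ w_enc + b_enc)
        o = h @ w_cls + b_cls
        d_o = 2.0 * (o - y) / n
        g_wcls = h.T @ d_o + 2 * l2 * w_cls / h_dim
        g_bcls = d_o.sum()
        if cfg.finetune_encoder:
            d_h = np.outer(d_o, w_cls)
            d_z = d_h * (1 - h**2)
            g_wenc = x.T @ d_z + 2 * l2 * w_enc
            g_benc = d_z.sum(axis=0)
            w_enc -= lr * g_wenc
            b_enc -= lr * g_benc
        w_cls -= lr * g_wcls
        b_cls -= lr * g_bcls
        if not np.isfinite(w_cls).all():
            raise FloatingPointError("supervised training diverged")
    h = np.tanh(x @ w_enc + b_enc)
    o = h @ w_cls + b_cls
    final = float(np.mean((o - y) ** 2) + l2 * np.mean(w_cls**2))
    return replace(
        state, w_enc=w_enc, b_enc=b_enc, w_cls=w_cls, b_cls=b_cls,
        phase="post-supervised", final_mse=final,
    )


def classify_net(state: NetState, threshold: float = SUCCESS_THRESHOLD) -> bool:
    """Learner iff the final regularized last-layer MSE is <= threshold (inclusive)."""
    if state.phase != "post-supervised":
        raise ValueError("net must be post-supervised to classify")
    return bool(state.final_mse <= threshold)


def _mean_pairwise(hidden: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Mean pairwise Euclidean hidden distance (between, within categories)."""
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(hidden))
    iu = np.triu_indices(len(labels), k=1)
    same = labels[iu[0]] == labels[iu[1]]
    dists = d[iu]
    return float(dists[~same].mean()), float(dists[same].mean())


def cp_effect(
    state_pre: NetState,
    state_post: NetState,
    probe: BinaryStimulusSet,
    threshold: float = SUCCESS_THRESHOLD,
) -> NetCPResult:
    """Hidden-space CP statistics between two snapshots of the same net."""
    labels = probe.labels
    if len(np.unique(labels)) < 2:
        raise ValueError("probe set must contain both categories")
    x = probe.signed
    b_pre, w_pre = _mean_pairwise(state_pre.hidden(x), labels)
    b_post, w_post = _mean_pairwise(state_post.hidden(x), labels)
    return NetCPResult(
        between_pre=b_pre,
        between_post=b_post,
        within_pre=w_pre,
        within_post=w_post,
        learner=classify_net(state_post, threshold)
        if state_post.phase == "post-supervised"
        else False,
        salience_pre=state_pre.salience(),
        salience_post=state_post.salience(),
        covariant_dims=probe.covariant_dims,
    )


# --------------------------------------------------------------------------
# statsmodels-style model / results wrapper


class CategoryNet:
    """Two-phase categorical-perception net as a fittable model.

    Parameters
    ----------
    config : NetConfig
        Architecture and training hyperparameters (includes the seed).

    Examples
    --------
    >>> model = CategoryNet(NetConfig(n_dims=12, k_cov=6, seed=3))
    >>> res = model.fit()
    >>> res.learner, round(res.cp.separation, 3)  # doctest: +SKIP
    """

    def __init__(self, config: NetConfig):
        self.config = config

    def fit(
        self,
        stimuli: BinaryStimulusSet | None = None,
        probe: BinaryStimulusSet | None = None,
        n_per_category: int = 40,
    ) -> "CategoryNetResults":
        cfg = self.config
        if stimuli is None:
            stimuli = gen_binary_stimuli(cfg, n_per_category, seed=cfg.seed)
        if probe is None:
            probe = gen_binary_stimuli(
                cfg, n_per_category, seed=cfg.seed + 1, scheme_from=stimuli
            )
        state_pre = train_autoencoder(cfg, stimuli)
        state_post = train_supervised(state_pre, stimuli, cfg)
        cp = cp_effect(state_pre, state_post, probe, cfg.success_threshold)
        return CategoryNetResults(
            model=self, stimuli=stimuli, probe=probe,
            state_pre=state_pre, state_post=state_post, cp=cp,
        )


@dataclass(frozen=True)
class CategoryNetResults:
    """Fit results: trained states, learner flag, CP and salience measures."""

    model: CategoryNet
    stimuli: BinaryStimulusSet
    probe: BinaryStimulusSet
    state_pre: NetState
    state_post: NetState
    cp: NetCPResult

    @property
    def learner(self) -> bool:
        return self.cp.learner

    @property
    def final_mse(self) -> float:
        return self.state_post.final_mse

    def salience_contrast(self) -> tuple[float, float]:
        """(mean covariant, mean non-covariant) post-supervised salience."""
        cov = np.zeros(self.model.config.n_dims, dtype=bool)
        cov[list(self.cp.covariant_dims)] = True
        s = self.cp.salience_post
        non = float(s[~cov].mean()) if (~cov).any() else float("nan")
        return float(s[cov].mean()), non

    def summary(self) -> str:
        cfg = self.model.config
        cov_sal, non_sal = self.salience_contrast()
        lines = [
            "Two-phase categorical-perception net",
            "=" * 48,
            f"n_dims {cfg.n_dims}   k_cov {cfg.k_cov}   hidden {cfg.h}   "
            f"seed {cfg.seed}",
            f"final regularized MSE (last layer): {self.final_mse:.3e}"
            f"   learner: {self.learner}",
            "-" * 48,
            f"between-category distance  pre {self.cp.between_pre:.4f}"
            f"  post {self.cp.between_post:.4f}",
            f"within-category distance   pre {self.cp.within_pre:.4f}"
            f"  post {self.cp.within_post:.4f}",
            f"separation  {self.cp.separation:+.4f}",
            f"compression {self.cp.compression:+.4f}",
            f"salience post-supervised: covariant {cov_sal:.4f}"
            f"  non-covariant {non_sal:.4f}",
        ]
        return "\n".join(lines)


def sweep_k(
    k_values,
    seeds,
    base_config: NetConfig | None = None,
    n_per_category: int = 40,
) -> pd.DataFrame:
    """Fit one net per (k, seed) and tabulate learner flags and CP measures."""
    base = base_config if base_config is not None else NetConfig()
    rows = []
    for k in k_values:
        for seed in seeds:
            cfg = replace(base, k_cov=int(k), seed=int(seed))
            res = CategoryNet(cfg).fit(n_per_category=n_per_category)
            cov_sal, non_sal = res.salience_contrast()
            rows.append(
                {
                    "k_cov": int(k),
                    "n_dims": cfg.n_dims,
                    "seed": int(seed),
                    "learner": res.learner,
                    "final_mse": res.final_mse,
                    "separation": res.cp.separation,
                    "compression": res.cp.compression,
                    "salience_covariant": cov_sal,
                    "salience_noncovariant": non_sal,
                }
            )
    return pd.DataFrame(rows)
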