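"""Time-sensitive attentive neural network (TSANN) and its ablations.

The full model (TSANN-II) scores one patient's observed window as:

1. **Concept embedding** — each code index maps to a D_c-dimensional
   vector through the concept embedding matrix W_c (V_c x D_c; padding
   row frozen at zero).
2. **Code-level attention** — within visit i, each code vector C_ij is
   scored by u_ij = tanh(W_v C_ij + b_v) against a learned context
   vector u_v; softmax weights alpha_ij produce the visit vector
   v_i = sum_j alpha_ij C_ij.
3. **Elapsed-time embedding** — the whole-day gap between visit i and
   the prediction date indexes a time embedding matrix (V_t = 365 rows,
   m columns); the row is concatenated to v_i.  The ``step`` variant
   indexes by visit order rank instead; ablations without time
   concatenate zeros so shapes are stable.
4. **LSTM** — a standard recurrence with sigmoid gates over the visit
   sequence (candidate/output activation configurable: tanh, ReLU or
   leaky ReLU).
5. **Visit-level attention** — hidden states h_i are scored by
   u_i = tanh(W_p h_i + b_p) against context u_p; softmax weights
   beta_i give the patient summary r_p = sum_i beta_i h_i.  The -I
   variants skip this layer and use the final LSTM state.
6. **Output** — a dense layer with nonlinear activation (optional batch
   normalization) followed by a 2-way softmax; P is the exacerbation
   class probability.

Baselines MLP / LSTM / ALSTM replace the code-level attention by a
plain average of the code vectors (MLP also drops the recurrence).  The
logistic-regression baseline operates on bag-of-codes frequency
features and lives in :mod:`tsann.train_eval`.

Padded positions never influence the output: attention masks assign
them exactly zero weight and the recurrence carries state through
padded visits unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autograd import Tensor, concat, embedding, masked_softmax, stack
from .encoding import EncodedSequence, MAX_GAP

__all__ = [
    "ModelConfig",
    "VariantSpec",
    "RiskOutput",
    "Batch",
    "TSANNModel",
    "pad_batch",
    "cross_entropy",
    "code_level_attention",
    "attach_time_embedding",
    "lstm_forward",
    "visit_level_attention",
]

NEURAL_VARIANTS = ("MLP", "LSTM", "ALSTM", "TSANN_I", "TSANN_I_STEP", "TSANN_II")
VARIANT_NAMES = ("LR",) + NEURAL_VARIANTS

_ACTIVATIONS = {
    "tanh": lambda t: t.tanh(),
    "relu": lambda t: t.relu(),
    "leaky_relu": lambda t: t.leaky_relu(0.01),
}


@dataclass(frozen=True)
class VariantSpec:
    """Which architecture to run and whether elapsed time enters it."""

    name: str
    use_time: bool = True

    def __post_init__(self):
        if self.name not in VARIANT_NAMES:
            raise ValueError(f"unknown variant {self.name!r}; expected one of {VARIANT_NAMES}")

    @property
    def has_code_attention(self) -> bool:
        return self.name.startswith("TSANN")

    @property
    def has_visit_attention(self) -> bool:
        return self.name in ("ALSTM", "TSANN_II")

    @property
    def uses_lstm(self) -> bool:
        return self.name != "MLP"


@dataclass
class ModelConfig:
    """Architecture sizes and head options.

    ``concept_dim`` (D_c) and ``time_dim`` (m) default to the tuned
    values of the emulated study (100 and 20); ``hidden_dim`` (H) is a
    package choice.  ``activation`` applies to the LSTM candidate/output
    nonlinearity and the dense head; gate activations stay sigmoid.
    """

    concept_dim: int = 100
    time_dim: int = 20
    hidden_dim: int = 64
    time_vocab: int = 365
    activation: str = "leaky_relu"
    batch_norm: bool = False

    def __post_init__(self):
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"activation must be one of {sorted(_ACTIVATIONS)}")


@dataclass
class RiskOutput:
    """Probability plus the attention weights used for interpretation."""

    probability: float
    alpha: list[np.ndarray]       # per visit, sums to 1 over that visit's real codes
    beta: np.ndarray | None       # over visits, sums to 1; None for final-state variants
    class_probs: np.ndarray = field(default=None)


@dataclass
class Batch:
    codes: np.ndarray       # (B, L, C) int indices, right-padded with 0
    code_mask: np.ndarray   # (B, L, C) 1.0 on real codes
    visit_mask: np.ndarray  # (B, L) 1.0 on real visits
    gaps: np.ndarray        # (B, L) day gaps
    ranks: np.ndarray       # (B, L) reverse visit order (prediction visit = 0)
    labels: np.ndarray      # (B,)
    patient_ids: list[str]

    @property
    def size(self) -> int:
        return self.codes.shape[0]


def pad_batch(seqs: list[EncodedSequence]) -> Batch:
    """Right-pad a list of encoded sequences into dense arrays with masks.

    Padded visits get one dummy padding code with ``code_mask`` zero but a
    single unmasked slot so that attention softmaxes stay well defined;
    the visit mask removes their influence downstream.
    """
    B = len(seqs)
    L = max(len(s.visits) for s in seqs)
    C = max(max(len(idxs) for idxs, _ in s.visits) for s in seqs)
    codes = np.zeros((B, L, C), dtype=np.int64)
    code_mask = np.zeros((B, L, C))
    visit_mask = np.zeros((B, L))
    gaps = np.zeros((B, L), dtype=np.int64)
    ranks = np.zeros((B, L), dtype=np.int64)
    labels = np.zeros(B, dtype=np.int64)
    for b, s in enumerate(seqs):
        n = len(s.visits)
        for t, (idxs, gap) in enumerate(s.visits):
            codes[b, t, : len(idxs)] = idxs
            code_mask[b, t, : len(idxs)] = 1.0
            gaps[b, t] = gap
            ranks[b, t] = min(n - 1 - t, MAX_GAP)
        visit_mask[b, :n] = 1.0
        code_mask[b, n:, 0] = 1.0  # keep padded-visit softmax well defined
        labels[b] = s.label
    return Batch(codes, code_mask, visit_mask, gaps, ranks, labels, [s.patient_id for s in seqs])


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


class TSANNModel:
    """A trainable risk model (any neural variant) with seeded initialization."""

    def __init__(self, variant: VariantSpec, config: ModelConfig, vocab_size: int, seed: int = 0):
        if variant.name == "LR":
            raise ValueError("the LR baseline is feature-based; see tsann.train_eval.train_lr")
        self.variant = variant
        self.config = config
        self.vocab_size = vocab_size
        rng = np.random.default_rng(seed)
        D, m, H = config.concept_dim, config.time_dim, config.hidden_dim
        din = D + m if variant.uses_lstm else D
        p: dict[str, Tensor] = {}
        Wc = rng.uniform(-0.05, 0.05, size=(vocab_size, D))
        Wc[0] = 0.0  # padding embeds to a frozen zero vector
        p["Wc"] = Tensor(Wc, requires_grad=True)
        p["Wt"] = Tensor(rng.uniform(-0.05, 0.05, size=(config.time_vocab, m)), requires_grad=True)
        if variant.has_code_attention:
            p["Wv"] = Tensor(_glorot(rng, D, D), requires_grad=True)
            p["bv"] = Tensor(np.zeros(D), requires_grad=True)
            p["uv"] = Tensor(rng.uniform(-0.05, 0.05, size=D), requires_grad=True)
        if variant.uses_lstm:
            p["Wx"] = Tensor(_glorot(rng, din, 4 * H), requires_grad=True)
            p["Wh"] = Tensor(_glorot(rng, H, 4 * H), requires_grad=True)
            p["b"] = Tensor(np.zeros(4 * H), requires_grad=True)
        if variant.has_visit_attention:
            p["Wp"] = Tensor(_glorot(rng, H, H), requires_grad=True)
            p["bp"] = Tensor(np.zeros(H), requires_grad=True)
            p["up"] = Tensor(rng.uniform(-0.05, 0.05, size=H), requires_grad=True)
        head_in = H if variant.uses_lstm else D
        p["Wd"] = Tensor(_glorot(rng, head_in, H), requires_grad=True)
        p["bd"] = Tensor(np.zeros(H), requires_grad=True)
        p["Wo"] = Tensor(_glorot(rng, H, 2), requires_grad=True)
        p["bo"] = Tensor(np.zeros(2), requires_grad=True)
        if config.batch_norm:
            p["bn_gamma"] = Tensor(np.ones(H), requires_grad=True)
            p["bn_beta"] = Tensor(np.zeros(H), requires_grad=True)
        self.params = p
        self._bn_mean = np.zeros(H)
        self._bn_var = np.ones(H)
        self._bn_momentum = 0.9

    # ------------------------------------------------------------------ #

    def forward(self, batch: Batch, training: bool = False):
        """Run the variant's pipeline; returns (logits Tensor, aux dict).

        ``aux`` carries the attention weights (``alpha`` (B,L,C) and
        ``beta`` (B,L), numpy) where the variant defines them.
        """
        p = self.params
        act = _ACTIVATIONS[self.config.activation]
        v = self.variant
        B, L, C = batch.codes.shape
        aux: dict = {"alpha": None, "beta": None}

        E = embedding(p["Wc"], batch.codes)  # (B,L,C,D)
        if v.has_code_attention:
            u = (E @ p["Wv"] + p["bv"]).tanh()
            scores = u @ p["uv"]  # (B,L,C)
            alpha = masked_softmax(scores, batch.code_mask, axis=-1)
            vis = (alpha.reshape(B, L, C, 1) * E).sum(axis=2)  # (B,L,D)
            aux["alpha"] = alpha.data
        else:
            cm = batch.code_mask[..., None]
            cnt = np.maximum(batch.code_mask.sum(axis=-1, keepdims=True), 1.0)
            vis = (E * cm).sum(axis=2) * (1.0 / cnt)

        if not v.uses_lstm:  # MLP: average every code vector in the record
            w = batch.code_mask * batch.visit_mask[:, :, None]
            tot = np.maximum(w.sum(axis=(1, 2)), 1.0)
            pooled = (E * w[..., None]).sum(axis=(1, 2)) * (1.0 / tot)[:, None]
            return self._head(pooled, act, training), aux

        if v.use_time:
            idx = batch.ranks if v.name == "TSANN_I_STEP" else batch.gaps
            T = embedding(p["Wt"], idx)  # (B,L,m)
        else:
            T = Tensor(np.zeros((B, L, self.config.time_dim)))
        x = concat([vis, T], axis=-1)  # (B,L,D+m)

        H = self.config.hidden_dim
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        hs = []
        for t in range(L):
            x_t = x[:, t, :]
            z = x_t @ p["Wx"] + h @ p["Wh"] + p["b"]
            f = z[:, 0 * H:1 * H].sigmoid()
            i = z[:, 1 * H:2 * H].sigmoid()
            o = z[:, 2 * H:3 * H].sigmoid()
            g = act(z[:, 3 * H:4 * H])
            c_new = f * c + i * g
            h_new = o * act(c_new)
            m = batch.visit_mask[:, t:t + 1]  # carry state through padded visits
            h = h_new * m + h * (1.0 - m)
            c = c_new * m + c * (1.0 - m)
            hs.append(h)

        if v.has_visit_attention:
            Hseq = stack(hs, axis=1)  # (B,L,H)
            uvis = (Hseq @ p["Wp"] + p["bp"]).tanh()
            s = uvis @ p["up"]  # (B,L)
            beta = masked_softmax(s, batch.visit_mask, axis=-1)
            r = (beta.reshape(B, L, 1) * Hseq).sum(axis=1)
            aux["beta"] = beta.data
        else:
            r = h  # final LSTM state (prediction-date visit)

        return self._head(r, act, training), aux

    def _head(self, r: Tensor, act, training: bool) -> Tensor:
        p = self.params
        d = act(r @ p["Wd"] + p["bd"])
        if self.config.batch_norm:
            if training and r.shape[0] > 1:
                mu = d.mean(axis=0, keepdims=True)
                var = ((d - mu) ** 2).mean(axis=0, keepdims=True)
                self._bn_mean = self._bn_momentum * self._bn_mean + (1 - self._bn_momentum) * mu.data[0]
                self._bn_var = self._bn_momentum * self._bn_var + (1 - self._bn_momentum) * var.data[0]
            else:
                mu = Tensor(self._bn_mean[None, :])
                var = Tensor(self._bn_var[None, :])
            d = (d - mu) / (var + 1e-5).sqrt()
            d = d * p["bn_gamma"] + p["bn_beta"]
        return d @ p["Wo"] + p["bo"]

    # ------------------------------------------------------------------ #

    def predict_proba(self, seqs: list[EncodedSequence], batch_size: int = 256) -> np.ndarray:
        """Exacerbation-class probability P for each sequence."""
        out = []
        for i in range(0, len(seqs), batch_size):
            logits, _ = self.forward(pad_batch(seqs[i:i + batch_size]), training=False)
            out.append(_softmax_np(logits.data)[:, 1])
        return np.concatenate(out)

    def predict(self, encoded: EncodedSequence) -> RiskOutput:
        """Score one patient and expose the attention weights."""
        batch = pad_batch([encoded])
        logits, aux = self.forward(batch, training=False)
        probs = _softmax_np(logits.data)[0]
        alpha = []
        if aux["alpha"] is not None:
            for t, (idxs, _gap) in enumerate(encoded.visits):
                alpha.append(aux["alpha"][0, t, : len(idxs)].copy())
        beta = None
        if aux["beta"] is not None:
            beta = aux["beta"][0, : len(encoded.visits)].copy()
        return RiskOutput(probability=float(probs[1]), alpha=alpha, beta=beta, class_probs=probs)


def _softmax_np(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: Tensor, labels: np.ndarray, class_weight=(1.0, 1.0)) -> Tensor:
    """Class-weighted cross-entropy from raw logits (numerically stable)."""
    zmax = logits.data.max(axis=-1, keepdims=True)
    shifted = logits - zmax
    logz = shifted.exp().sum(axis=-1, keepdims=True).log()
    logp = shifted - logz
    w = np.asarray(class_weight, dtype=float)[labels]
    picked = logp[np.arange(len(labels)), labels]
    return -(picked * w).sum() * (1.0 / w.sum())


# ---------------------------------------------------------------------- #
# Stand-alone single-visit operations (NumPy, no autograd) — the model's
# building blocks exposed for direct use and independent checking.

def code_level_attention(code_vectors: np.ndarray, Wv: np.ndarray, bv: np.ndarray,
                         uv: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Additive attention over one visit's code vectors.

    u_j = tanh(W_v C_j + b_v);  alpha = softmax(u_j . u_v);
    v = sum_j alpha_j C_j.  Returns (visit vector, alpha).
    """
    C = np.atleast_2d(np.asarray(code_vectors, dtype=float))
    if C.shape[0] == 0:
        raise ValueError("a visit must contain at least one code")
    u = np.tanh(C @ Wv + bv)
    s = u @ uv
    e = np.exp(s - s.max())
    alpha = e / e.sum()
    return alpha @ C, alpha


def attach_time_embedding(visit_vector: np.ndarray, gap: int, time_matrix: np.ndarray,
                          use_time: bool = True, rank: int | None = None) -> np.ndarray:
    """Concatenate the elapsed-time (or order-rank) embedding row to a visit vector."""
    m = time_matrix.shape[1]
    if not use_time:
        return np.concatenate([visit_vector, np.zeros(m)])
    idx = rank if rank is not None else gap
    if not (0 <= idx < time_matrix.shape[0]):
        raise ValueError(f"time index {idx} outside [0, {time_matrix.shape[0] - 1}]")
    return np.concatenate([visit_vector, time_matrix[idx]])


def lstm_forward(xs: np.ndarray, Wx: np.ndarray, Wh: np.ndarray, b: np.ndarray,
                 activation: str = "tanh") -> np.ndarray:
    """Standard LSTM over a (T, Din) sequence; returns (T, H) hidden states."""
    actf = {"tanh": np.tanh,
            "relu": lambda a: np.maximum(a, 0.0),
            "leaky_relu": lambda a: np.where(a > 0, a, 0.01 * a)}[activation]
    H = Wh.shape[0]
    h = np.zeros(H)
    c = np.zeros(H)
    out = []
    for x in np.atleast_2d(xs):
        z = x @ Wx + h @ Wh + b
        sig = lambda a: 1.0 / (1.0 + np.exp(-a))
        f, i, o = sig(z[:H]), sig(z[H:2 * H]), sig(z[2 * H:3 * H])
        g = actf(z[3 * H:])
        c = f * c + i * g
        h = o * actf(c)
        out.append(h)
    return np.stack(out)


def visit_level_attention(hidden_states: np.ndarray, Wp: np.ndarray, bp: np.ndarray,
                          up: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Additive attention over LSTM hidden states; returns (r_p, beta)."""
    Hs = np.atleast_2d(np.asarray(hidden_states, dtype=float))
    u = np.tanh(Hs @ Wp + bp)
    s = u @ up
    e = np.exp(s - s.max())
    beta = e / e.sum()
    return beta @ Hs, beta
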