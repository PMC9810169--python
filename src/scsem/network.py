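"""ZINB autoencoder with a self-expressive layer and its two-phase training.

Architecture (all layers fully connected; gene order carries no spatial
structure, so convolutions would be meaningless here):

* encoder g: G' -> 256 -> 32 -> 10 (ReLU on hidden layers, linear embedding Y)
* self-expressive layer: Y_se = C_masked @ Y with trainable C (N x N); the
  diagonal of C is structurally masked to zero everywhere C is consumed
* decoder h: 10 -> 32 -> 256 (ReLU), last hidden output D
* four parallel heads on D: reconstruction X_hat (z-score space), and the
  ZINB parameter heads M = diag(s_i) exp(D W_mu), theta = exp(D W_theta),
  pi = sigmoid(D W_pi)

Composite loss:

    L = (lambda1 * 1/2 ||X - X_hat||_F^2
         + lambda2 * 1/2 ||Y - Y C||_F^2
         + lambda3 * ||C||_F^2) * 1/10
        + sum_ij -log ZINB(X_ij; pi_ij, mu_ij, theta_ij)

Training is full batch (the self-expression term couples all cells):
a pre-training phase (lr 0.002) optimizes the autoencoder and heads with C
frozen and only the reconstruction + ZINB terms active, then a fine-tuning
phase (lr 0.001) optimizes everything under the full loss.

C is initialized to the identity matrix; because the zero-diagonal mask is
applied at every use, the *effective* initial coefficient matrix is zero,
which satisfies the hard constraint diag(C) = 0 from the first step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from scsem import autodiff as ad
from scsem.autodiff import Adam, Tensor
from scsem.data import PreprocessedData
from scsem.errors import CapacityError, TrainingDivergenceError
from scsem.zinb import MU_MAX, MU_MIN, PI_EPS, THETA_MAX, THETA_MIN, ZINBParams

log = logging.getLogger(__name__)


@dataclass
class ModelConfig:
    encoder_widths: list[int] = field(default_factory=lambda: [256, 32, 10])
    lambda1: float = 0.2
    lambda2: float = 1.0
    lambda3: float = 0.5
    global_scale: float = 0.1
    pretrain_lr: float = 0.002
    finetune_lr: float = 0.001
    pretrain_epochs: int = 100
    finetune_epochs: int = 40
    seed: int = 0
    activation: str = "relu"
    use_rec: bool = True    # loss toggle for the reconstruction term
    use_zinb: bool = True   # loss toggle for the ZINB likelihood term
    reg_norm: str = "fro"   # 'fro' (squared Frobenius) or 'l1' on C
    grad_clip: float = 5.0
    max_cells: int = 15000  # dense N x N coefficient matrix guard
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if len(self.encoder_widths) < 1 or self.encoder_widths[-1] < 2:
            raise ValueError("embedding dimension must be >= 2")
        if self.activation != "relu":
            raise ValueError("only relu activation is supported")
        if self.reg_norm not in ("fro", "l1"):
            raise ValueError("reg_norm must be 'fro' or 'l1'")

    @property
    def embedding_dim(self) -> int:
        return self.encoder_widths[-1]


@dataclass
class ModelState:
    """All trainable tensors plus bookkeeping to rebuild the forward pass."""

    params: dict[str, Tensor]
    config: ModelConfig
    n_cells: int
    n_genes: int
    loss_trace: list[dict] = field(default_factory=list)

    @property
    def sem(self) -> np.ndarray:
        """Effective self-expressive matrix (zero diagonal enforced)."""
        c = np.array(self.params["C"].data, dtype=np.float64)
        np.fill_diagonal(c, 0.0)
        return c

    def trainable(self, include_c: bool) -> list[Tensor]:
        return [t for k, t in self.params.items() if include_c or k != "C"]

    def save(self, path: str) -> None:
        arrays = {k: np.asarray(t.data) for k, t in self.params.items()}
        arrays["_loss_trace"] = np.array(
            [
                [e["phase"], e["epoch"], e["total"], e["rec"], e["se"], e["reg"], e["zinb"]]
                for e in self.loss_trace
            ],
            dtype=np.float64,
        )
        arrays["_meta"] = np.array([self.n_cells, self.n_genes])
        import json

        arrays["_config"] = np.frombuffer(
            json.dumps(self.config.__dict__).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str) -> "ModelState":
        import json

        with np.load(path) as data:
            cfg = ModelConfig(**json.loads(bytes(data["_config"]).decode()))
            n_cells, n_genes = (int(v) for v in data["_meta"])
            trace = [
                dict(
                    phase=int(r[0]), epoch=int(r[1]), total=r[2],
                    rec=r[3], se=r[4], reg=r[5], zinb=r[6],
                )
                for r in data["_loss_trace"]
            ]
            params = {
                k: Tensor(data[k], requires_grad=True)
                for k in data.files
                if not k.startswith("_")
            }
        return cls(params, cfg, n_cells, n_genes, trace)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(dtype)


def init_state(cfg: ModelConfig, n_cells: int, n_genes: int) -> ModelState:
    """Seeded Glorot-uniform weights; biases zero; C = identity."""
    rng = np.random.default_rng(cfg.seed)
    dt = np.dtype(cfg.dtype)
    widths = [n_genes] + list(cfg.encoder_widths)
    params: dict[str, Tensor] = {}
    for i in range(len(widths) - 1):
        params[f"enc_W{i}"] = Tensor(_glorot(rng, widths[i], widths[i + 1], dt), True)
        params[f"enc_b{i}"] = Tensor(np.zeros(widths[i + 1], dtype=dt), True)
    dec_widths = list(reversed(cfg.encoder_widths))  # e.g. 10 -> 32 -> 256
    for i in range(len(dec_widths) - 1):
        params[f"dec_W{i}"] = Tensor(_glorot(rng, dec_widths[i], dec_widths[i + 1], dt), True)
        params[f"dec_b{i}"] = Tensor(np.zeros(dec_widths[i + 1], dtype=dt), True)
    d_last = dec_widths[-1]
    for head in ("rec", "mu", "theta", "pi"):
        params[f"head_W_{head}"] = Tensor(_glorot(rng, d_last, n_genes, dt), True)
        params[f"head_b_{head}"] = Tensor(np.zeros(n_genes, dtype=dt), True)
    params["C"] = Tensor(np.eye(n_cells, dtype=dt), True)
    return ModelState(params, cfg, n_cells, n_genes)


def _masked_c(state: ModelState, diag_mask: Tensor) -> Tensor:
    return state.params["C"] * diag_mask


def forward(
    state: ModelState,
    data: PreprocessedData,
    _cache: dict | None = None,
) -> dict:
    """One full forward pass; returns tensors keyed Y, Y_se, X_hat, mu, theta, pi, C_eff."""
    p = state.params
    cfg = state.config
    dt = np.dtype(cfg.dtype)
    cache = _cache if _cache is not None else {}
    if "x_enc" not in cache:
        cache["x_enc"] = Tensor(np.ascontiguousarray(data.encoder_input, dtype=dt))
        cache["s_col"] = Tensor(data.size_factors.astype(dt)[:, None])
        cache["diag_mask"] = Tensor(
            (1.0 - np.eye(data.n_cells)).astype(dt)
        )
    h = cache["x_enc"]
    n_enc = len(cfg.encoder_widths)
    for i in range(n_enc):
        h = h @ p[f"enc_W{i}"] + p[f"enc_b{i}"]
        if i < n_enc - 1:
            h = ad.relu(h)
    y = h  # N x d_emb, linear embedding
    c_eff = _masked_c(state, cache["diag_mask"])
    y_se = c_eff @ y
    h = y
    for i in range(n_enc - 1):
        h = ad.relu(h @ p[f"dec_W{i}"] + p[f"dec_b{i}"])
    d_out = h  # last decoder hidden output
    x_hat = d_out @ p["head_W_rec"] + p["head_b_rec"]
    mu = cache["s_col"] * ad.exp(
        ad.clip(d_out @ p["head_W_mu"] + p["head_b_mu"], -30.0, 30.0)
    )
    theta = ad.exp(ad.clip(d_out @ p["head_W_theta"] + p["head_b_theta"], -30.0, 30.0))
    pi = ad.sigmoid(d_out @ p["head_W_pi"] + p["head_b_pi"])
    mu = ad.clip(mu, MU_MIN, MU_MAX)
    theta = ad.clip(theta, THETA_MIN, THETA_MAX)
    pi = ad.clip(pi, PI_EPS, 1.0 - PI_EPS)
    for name, t in (("Y", y), ("X_hat", x_hat), ("mu", mu)):
        if not np.all(np.isfinite(t.data)):
            raise TrainingDivergenceError(f"non-finite activations in {name}")
    return {
        "Y": y, "Y_se": y_se, "X_hat": x_hat,
        "mu": mu, "theta": theta, "pi": pi, "C_eff": c_eff,
    }


def zinb_params_from_forward(fw: dict) -> ZINBParams:
    return ZINBParams(
        mean=np.asarray(fw["mu"].data, dtype=np.float64),
        dispersion=np.asarray(fw["theta"].data, dtype=np.float64),
        dropout=np.asarray(fw["pi"].data, dtype=np.float64),
    )


def _zinb_nll_graph(fw: dict, cache: dict) -> Tensor:
    """Differentiable sum_ij -log ZINB(X_ij) (zero branch via log-sum-exp)."""
    return ad.zinb_nll_fused(
        fw["mu"], fw["theta"], fw["pi"],
        cache["x_raw"], cache["zero_mask"], cache["lgamma_x1"],
    )


def composite_loss(
    fw: dict,
    data: PreprocessedData,
    cfg: ModelConfig,
    _cache: dict | None = None,
    phase: int = 2,
) -> dict:
    """Composite training objective and its parts.

    ``phase=1`` (pre-training) drops the self-expression and C-regression
    terms; ``phase=2`` is the full objective.  The loss toggles in the
    config disable the reconstruction / ZINB terms for ablation runs.
    Returns {'total': Tensor, 'rec', 'se', 'reg', 'zinb': floats}.
    """
    dt = np.dtype(cfg.dtype)
    cache = _cache if _cache is not None else {}
    if "x_raw" not in cache:
        xr = data.raw.counts.astype(dt)
        cache["x_raw"] = xr
        cache["zero_mask"] = xr == 0
        cache["lgamma_x1"] = gammaln(xr + 1.0).astype(dt)
        cache["x_enc"] = cache.get("x_enc", Tensor(data.encoder_input.astype(dt)))
    rec = 0.5 * ad.square_sum(cache["x_enc"] - fw["X_hat"])
    se = 0.5 * ad.square_sum(fw["Y"] - fw["Y_se"])
    if cfg.reg_norm == "fro":
        reg = ad.square_sum(fw["C_eff"])
    else:
        reg = ad.abs_sum(fw["C_eff"])
    zinb = _zinb_nll_graph(fw, cache)

    terms = []
    if cfg.use_rec:
        terms.append(cfg.lambda1 * rec)
    if phase == 2:
        terms.append(cfg.lambda2 * se)
        terms.append(cfg.lambda3 * reg)
    total = None
    if terms:
        weighted = terms[0]
        for t in terms[1:]:
            weighted = weighted + t
        total = weighted * cfg.global_scale
    if cfg.use_zinb:
        total = zinb if total is None else total + zinb
    if total is None:  # every term toggled off: constant-zero objective
        total = Tensor(np.zeros(()), requires_grad=True)
    return {
        "total": total,
        "rec": rec.item(),
        "se": se.item(),
        "reg": reg.item(),
        "zinb": zinb.item(),
    }


def _run_phase(
    state: ModelState,
    data: PreprocessedData,
    cfg: ModelConfig,
    phase: int,
    epochs: int,
    lr: float,
    cache: dict,
) -> None:
    params = state.trainable(include_c=(phase == 2))
    opt = Adam(params, lr=lr, clip_norm=cfg.grad_clip)
    for epoch in range(epochs):
        fw = forward(state, data, _cache=cache)
        parts = composite_loss(fw, data, cfg, _cache=cache, phase=phase)
        total = parts["total"]
        tval = total.item()
        if not np.isfinite(tval):
            raise TrainingDivergenceError(
                f"non-finite loss at phase {phase} epoch {epoch}: "
                f"rec={parts['rec']:.4g} se={parts['se']:.4g} "
                f"reg={parts['reg']:.4g} zinb={parts['zinb']:.4g}"
            )
        opt.zero_grad()
        total.backward()
        opt.step()
        state.loss_trace.append(
            dict(phase=phase, epoch=epoch, total=tval,
                 rec=parts["rec"], se=parts["se"], reg=parts["reg"],
                 zinb=parts["zinb"])
        )
        log.debug(
            "phase %d epoch %3d  total=%.5g rec=%.4g se=%.4g reg=%.4g zinb=%.5g",
            phase, epoch, tval, parts["rec"], parts["se"], parts["reg"],
            parts["zinb"],
        )
        if epoch % 20 == 0 or epoch == epochs - 1:
            log.info(
                "phase %d epoch %3d  total=%.5g rec=%.4g se=%.4g reg=%.4g zinb=%.5g",
                phase, epoch, tval, parts["rec"], parts["se"], parts["reg"],
                parts["zinb"],
            )


def train(data: PreprocessedData, cfg: ModelConfig | None = None) -> ModelState:
    """Two-phase full-batch training; returns the final state with loss trace."""
    cfg = cfg or ModelConfig()
    n = data.n_cells
    if n > cfg.max_cells:
        raise CapacityError(
            f"{n} cells exceeds max_cells={cfg.max_cells}; the dense N x N "
            "self-expressive matrix would not fit"
        )
    state = init_state(cfg, n, data.n_genes)
    cache: dict = {}
    if cfg.pretrain_epochs > 0 and (cfg.use_rec or cfg.use_zinb):
        _run_phase(state, data, cfg, phase=1, epochs=cfg.pretrain_epochs,
                   lr=cfg.pretrain_lr, cache=cache)
    if cfg.finetune_epochs > 0:
        _run_phase(state, data, cfg, phase=2, epochs=cfg.finetune_epochs,
                   lr=cfg.finetune_lr, cache=cache)
    return state
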