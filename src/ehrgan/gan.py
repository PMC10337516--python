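"""Generative-adversarial semisupervised learner with an (M+1)-way critic.

The discriminator classifies samples into the M real classes plus a fake
class (code M).  Its loss combines four terms:

* a Wasserstein critic term with gradient penalty, using the real-vs-fake
  log-odds ``s(x) = logsumexp(real logits) - fake logit`` as critic score;
* a semisupervised term: cross-entropy over the M real classes on labeled
  samples, plus ``-λ0·[E log(1-P(fake|x_real)) + E log P(fake|x_fake)]``;
* conditional-entropy regularization over the real classes on unlabeled
  samples, sharpening predictions;
* a pull-away term — the mean squared pairwise cosine similarity of
  last-hidden-layer features of fake samples — which spreads generated
  samples across the low-density gap between classes.

The generator minimizes ``-E s(fake)`` plus the same pull-away term.  After
training, the discriminator's renormalized softmax over the M real classes
serves as the classifier.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import MLP, Adam

__all__ = [
    "GanConfig",
    "LossBreakdown",
    "TrainedGanModel",
    "build_generator",
    "build_discriminator",
    "loss_semisupervised",
    "loss_entropy",
    "pull_away_term",
    "critic_score",
    "wgan_gp_terms",
    "train",
    "predict_proba",
    "generate_samples",
    "export_last_layer",
    "save_model",
    "load_model",
]

_EPS = 1e-8


@dataclass(frozen=True)
class GanConfig:
    z_dim: int = 100
    gen_layers: tuple = (128, 128)
    disc_layers: tuple = (128, 128)
    lam0: float = 1.0        # weight of the unsupervised real/fake term
    lam_ent: float = 1.0     # weight of the entropy regularizer
    lam_pt: float = 1.0      # weight of the pull-away term
    lam_gp: float = 10.0     # gradient-penalty weight
    lr: float = 0.003
    adam_beta1: float = 0.5
    batch: int = 128
    max_epochs: int = 200
    disc_steps_per_gen_step: int = 1
    seed: int = 0
    batchnorm_in_disc: bool = False
    supervised_only: bool = False  # ablation: cross-entropy on labeled reals only
    stop_tol: float = 1e-4
    stop_patience: int = 10

    def __post_init__(self):
        if min(self.lam0, self.lam_ent, self.lam_pt, self.lam_gp) < 0:
            raise ValueError("loss weights must be non-negative")
        if self.batch < 2:
            raise ValueError("batch must be >= 2 (pull-away term needs pairs)")


@dataclass
class LossBreakdown:
    loss_sup: float = 0.0
    loss_un: float = 0.0
    loss_ent: float = 0.0
    loss_pt: float = 0.0
    loss_pt_gen: float = 0.0  # pull-away value of the generator step's fakes
    loss_Dwgp: float = 0.0
    loss_Gwgp: float = 0.0
    loss_D_total: float = 0.0
    loss_G_total: float = 0.0


@dataclass
class TrainedGanModel:
    generator: Optional[MLP]
    discriminator: MLP
    config: GanConfig
    history: list[LossBreakdown]
    input_width: int
    feature_dim: int  # >0: first columns of a sample are original features
    M: int
    input_mode: str = "concat_features"

    def __post_init__(self):
        if self.M < 2:
            raise ValueError("need at least 2 real classes")


# ---------------------------------------------------------------------
# network builders
# ---------------------------------------------------------------------

def build_generator(cfg: GanConfig, out_dim: int, rng: np.random.Generator) -> MLP:
    """Fully connected z -> sample map with batch normalization."""
    if out_dim < 1:
        raise ValueError("out_dim must be >= 1")
    return MLP(cfg.z_dim, list(cfg.gen_layers), out_dim, rng,
               activation="relu", batchnorm=True)


def build_discriminator(cfg: GanConfig, in_dim: int, M: int, rng: np.random.Generator) -> MLP:
    """(M+1)-way classifier; ``forward(..., return_hidden=True)`` exposes h_n."""
    if M < 2:
        raise ValueError("need at least 2 real classes")
    return MLP(in_dim, list(cfg.disc_layers), M + 1, rng,
               activation="leaky_relu", batchnorm=cfg.batchnorm_in_disc)


# ---------------------------------------------------------------------
# loss terms
# ---------------------------------------------------------------------

def loss_semisupervised(labeled_logits, labels, unlabeled_logits, fake_logits):
    """(loss_sup, loss_un) of the semisupervised objective.

    loss_sup: cross-entropy of the softmax renormalized over the M real
    classes at the true labels.  loss_un: ``-[E log(1 - P(fake|x_real_un)) +
    E log P(fake|x_fake)]``.  Empty batches contribute 0 to their term.
    Combine as ``loss_sup + λ0 · loss_un``.
    """
    labeled_logits = ad.as_tensor(labeled_logits)
    M = labeled_logits.shape[-1] - 1

    if labeled_logits.shape[0] > 0:
        log_q = ad.log_softmax(labeled_logits[:, :M], axis=1)
        labels = np.asarray(labels, dtype=np.int64)
        picked = log_q[np.arange(len(labels)), labels]
        loss_sup = -ad.mean(picked)
    else:
        loss_sup = Tensor(0.0)

    terms = []
    unlabeled_logits = ad.as_tensor(unlabeled_logits)
    if unlabeled_logits.shape[0] > 0:
        # log(1 - P(M|x)) = lse(real logits) - lse(all logits)
        log_real_mass = ad.logsumexp(unlabeled_logits[:, :M], axis=1) - ad.logsumexp(
            unlabeled_logits, axis=1
        )
        terms.append(ad.mean(log_real_mass))
    fake_logits = ad.as_tensor(fake_logits)
    if fake_logits.shape[0] > 0:
        log_p_fake = fake_logits[:, M] - ad.logsumexp(fake_logits, axis=1)
        terms.append(ad.mean(log_p_fake))
    loss_un = -sum(terms, Tensor(0.0)) if terms else Tensor(0.0)
    return loss_sup, loss_un


def loss_entropy(unlabeled_logits):
    """Mean conditional entropy over the M real classes; in [0, ln M]."""
    unlabeled_logits = ad.as_tensor(unlabeled_logits)
    if unlabeled_logits.shape[0] == 0:
        return Tensor(0.0)
    M = unlabeled_logits.shape[-1] - 1
    log_q = ad.log_softmax(unlabeled_logits[:, :M], axis=1)
    q = ad.exp(log_q)
    return ad.mean(-ad.sum_(ad.mul(q, log_q), axis=1))


def pull_away_term(features):
    """Mean squared pairwise cosine similarity of the feature rows; in [0, 1]."""
    f = ad.as_tensor(features)
    n = f.shape[0]
    if n < 2:
        raise ValueError("pull-away term needs a batch of >= 2 feature vectors")
    norms = ad.sqrt(ad.sum_(ad.power(f, 2.0), axis=1, keepdims=True) + 1e-24)
    fhat = f / norms
    gram = ad.matmul(fhat, ad.transpose(fhat))
    # subtract the actual squared diagonal (zero-norm rows have diag 0, not 1)
    diag = gram[np.arange(n), np.arange(n)]
    return (ad.sum_(ad.power(gram, 2.0)) - ad.sum_(ad.power(diag, 2.0))) / (n * (n - 1))


def critic_score(logits):
    """Real-vs-fake log-odds of the (M+1)-way softmax: lse(real) - fake logit."""
    logits = ad.as_tensor(logits)
    M = logits.shape[-1] - 1
    return ad.logsumexp(logits[:, :M], axis=1) - logits[:, M]


def wgan_gp_terms(disc_logits_fn, real_batch, fake_batch, lam_gp: float,
                  rng: np.random.Generator):
    """Wasserstein terms with gradient penalty.

    ``disc_logits_fn`` maps a Tensor batch to (M+1)-way logits.  Returns
    (loss_Dwgp, loss_Gwgp) as Tensors; the penalty is evaluated at samples
    interpolated uniformly between paired real and fake rows and carries a
    differentiable graph back to the discriminator parameters.
    """
    real_batch = ad.as_tensor(real_batch).detach()
    fake_batch = ad.as_tensor(fake_batch)
    n = min(real_batch.shape[0], fake_batch.shape[0])

    s_real = critic_score(disc_logits_fn(real_batch))
    s_fake = critic_score(disc_logits_fn(fake_batch))
    loss_Gwgp = -ad.mean(s_fake)
    wasserstein = ad.mean(s_fake) - ad.mean(s_real)

    eps = rng.random((n, 1))
    x_hat = Tensor(
        eps * real_batch.data[:n] + (1 - eps) * fake_batch.data[:n], requires_grad=True
    )
    s_hat = ad.sum_(critic_score(disc_logits_fn(x_hat)))
    (gx,) = ad.grad(s_hat, [x_hat], create_graph=True)
    gnorm = ad.sqrt(ad.sum_(ad.power(gx, 2.0), axis=1) + 1e-12)
    penalty = ad.mean(ad.power(gnorm - 1.0, 2.0))
    loss_Dwgp = wasserstein + lam_gp * penalty
    return loss_Dwgp, loss_Gwgp


# ---------------------------------------------------------------------
# training
# ---------------------------------------------------------------------

class _Cycler:
    """Seeded endless shuffled iteration over an index array."""

    def __init__(self, idx: np.ndarray, rng: np.random.Generator):
        self.idx = np.asarray(idx)
        self.rng = rng
        self.pos = len(self.idx)
        self.order = self.idx.copy()

    def take(self, b: int) -> np.ndarray:
        out = []
        while b > 0:
            if self.pos >= len(self.order):
                self.order = self.rng.permutation(self.idx)
                self.pos = 0
            chunk = self.order[self.pos : self.pos + b]
            out.append(chunk)
            self.pos += len(chunk)
            b -= len(chunk)
        return np.concatenate(out)


def _check_finite(value: float, term: str, epoch: int) -> None:
    if not np.isfinite(value):
        raise RuntimeError(f"non-finite {term} at epoch {epoch}; training aborted")


def train(real_samples, y, mask, cfg: GanConfig,
          feature_dim: int = 0, input_mode: str = "concat_features",
          verbose: bool = False) -> TrainedGanModel:
    """Adversarial semisupervised training loop.

    ``real_samples`` is the (n, width) real-sample matrix (embeddings or
    features+embeddings), ``y`` class codes, ``mask`` label visibility.
    Per step a labeled batch, an unlabeled batch, a generic real batch and a
    generated batch are drawn; the discriminator and generator are updated
    with Adam(lr, β1) on their composite losses.  Training stops at
    ``max_epochs`` or when the moving-average discriminator loss changes by
    less than ``stop_tol`` for ``stop_patience`` epochs.  Fully seeded.
    """
    import logging

    log = logging.getLogger(__name__)
    X = np.asarray(real_samples, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    mask = np.asarray(mask, dtype=bool)
    n, width = X.shape
    M = int(y.max()) + 1
    if M < 2:
        raise ValueError("need at least 2 classes")
    for c in range(M):
        if not np.any(mask & (y == c)):
            raise ValueError(f"class {c} has no labeled sample")
    b = min(cfg.batch, n)

    rng = np.random.default_rng(cfg.seed)
    disc = build_discriminator(cfg, width, M, rng)
    gen = None if cfg.supervised_only else build_generator(cfg, width, rng)
    opt_d = Adam(disc.parameters(), lr=cfg.lr, beta1=cfg.adam_beta1)
    opt_g = Adam(gen.parameters(), lr=cfg.lr, beta1=cfg.adam_beta1) if gen else None

    labeled = _Cycler(np.flatnonzero(mask), rng)
    unlabeled_idx = np.flatnonzero(~mask)
    unlabeled = _Cycler(unlabeled_idx, rng) if len(unlabeled_idx) else None
    reals = _Cycler(np.arange(n), rng)

    history: list[LossBreakdown] = []
    ma_prev, stable = None, 0
    steps_per_epoch = max(1, n // b)
    for epoch in range(cfg.max_epochs):
        acc = LossBreakdown()
        for step in range(steps_per_epoch):
            lab_rows = labeled.take(b)
            xl = Tensor(X[lab_rows])
            yl = y[lab_rows]
            if unlabeled is not None:
                xu = Tensor(X[unlabeled.take(b)])
            else:
                xu = Tensor(np.zeros((0, width)))
            xr = Tensor(X[reals.take(b)])

            if cfg.supervised_only:
                logits_l = disc(xl, training=True)
                l_sup, _ = loss_semisupervised(logits_l, yl, Tensor(np.zeros((0, M + 1))),
                                               Tensor(np.zeros((0, M + 1))))
                loss_d = l_sup
                grads = ad.grad(loss_d, disc.parameters())
                opt_d.step(grads)
                sup_v = l_sup.item()
                _check_finite(sup_v, "loss_sup", epoch)
                acc.loss_sup += sup_v
                acc.loss_D_total += sup_v
                continue

            # ---- discriminator step -------------------------------
            with ad.no_grad():
                z = rng.standard_normal((b, cfg.z_dim))
                xf_data = gen.forward(Tensor(z), training=True).data
            xf = Tensor(xf_data)

            logits_l = disc(xl, training=True)
            logits_u = disc(xu, training=True) if xu.shape[0] else Tensor(np.zeros((0, M + 1)))
            logits_f, h_f = disc.forward(xf, training=True, return_hidden=True)

            l_sup, l_un = loss_semisupervised(logits_l, yl, logits_u, logits_f)
            l_ent = loss_entropy(logits_u) if xu.shape[0] else Tensor(0.0)
            l_pt = pull_away_term(h_f) if xf.shape[0] >= 2 else Tensor(0.0)
            l_dwgp, _ = wgan_gp_terms(lambda t: disc(t, training=True), xr, xf,
                                      cfg.lam_gp, rng)
            loss_d = l_dwgp + l_sup + cfg.lam0 * l_un + cfg.lam_ent * l_ent + cfg.lam_pt * l_pt
            grads = ad.grad(loss_d, disc.parameters())
            opt_d.step(grads)

            for name, t in [("loss_sup", l_sup), ("loss_un", l_un), ("loss_ent", l_ent),
                            ("loss_pt", l_pt), ("loss_Dwgp", l_dwgp), ("loss_D_total", loss_d)]:
                v = t.item()
                _check_finite(v, name, epoch)
                setattr(acc, name, getattr(acc, name) + v)

            # ---- generator step -----------------------------------
            if step % cfg.disc_steps_per_gen_step == 0:
                z = Tensor(rng.standard_normal((b, cfg.z_dim)))
                xf = gen.forward(z, training=True)
                logits_f, h_f = disc.forward(xf, training=True, return_hidden=True)
                l_gwgp = -ad.mean(critic_score(logits_f))
                l_pt_g = pull_away_term(h_f)
                loss_g = l_gwgp + cfg.lam_pt * l_pt_g
                grads_g = ad.grad(loss_g, gen.parameters())
                opt_g.step(grads_g)
                for name, t in [("loss_Gwgp", l_gwgp), ("loss_pt_gen", l_pt_g),
                                ("loss_G_total", loss_g)]:
                    v = t.item()
                    _check_finite(v, name, epoch)
                    setattr(acc, name, getattr(acc, name) + v)

        for f_ in acc.__dataclass_fields__:
            setattr(acc, f_, getattr(acc, f_) / steps_per_epoch)
        history.append(acc)
        if verbose:
            log.info("epoch %d: %s", epoch, acc)

        # moving-average early stop on discriminator-loss stability
        window = [h.loss_D_total for h in history[-5:]]
        ma = float(np.mean(window))
        if ma_prev is not None and abs(ma - ma_prev) < cfg.stop_tol:
            stable += 1
            if stable >= cfg.stop_patience:
                break
        else:
            stable = 0
        ma_prev = ma

    return TrainedGanModel(
        generator=gen, discriminator=disc, config=cfg, history=history,
        input_width=width, feature_dim=feature_dim, M=M, input_mode=input_mode,
    )


# ---------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------

def predict_proba(model: TrainedGanModel, samples) -> np.ndarray:
    """Class probabilities over the M real classes (renormalized softmax)."""
    X = np.atleast_2d(np.asarray(samples, dtype=np.float64))
    if X.shape[1] != model.input_width:
        raise ValueError(
            f"sample width {X.shape[1]} != model input width {model.input_width}"
        )
    with ad.no_grad():
        logits = model.discriminator(Tensor(X), training=False)
        probs = ad.softmax(logits[:, : model.M], axis=1)
    return probs.data


def generate_samples(model: TrainedGanModel, n: int, seed: int = 0) -> np.ndarray:
    """Draw n synthetic samples from the trained generator (eval-mode BN)."""
    if model.generator is None:
        raise ValueError("model was trained without a generator")
    if n == 0:
        return np.zeros((0, model.input_width))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, model.config.z_dim))
    with ad.no_grad():
        out = model.generator.forward(Tensor(z), training=False)
    return out.data


def synthetic_feature_view(model: TrainedGanModel, samples: np.ndarray) -> np.ndarray:
    """Feature-space columns of generated samples (concat input mode only)."""
    if model.feature_dim <= 0:
        raise ValueError("model input space carries no original-feature columns")
    return np.asarray(samples)[:, : model.feature_dim]


def export_last_layer(model: TrainedGanModel, samples) -> np.ndarray:
    """Last-hidden-layer discriminator features (for external 2-D projection)."""
    X = np.atleast_2d(np.asarray(samples, dtype=np.float64))
    with ad.no_grad():
        _, h = model.discriminator.forward(Tensor(X), training=False, return_hidden=True)
    return h.data


# ---------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------

def save_model(model: TrainedGanModel, path) -> None:
    """Single-file checkpoint (npz archive of parameters + JSON header)."""
    arrays = {}
    if model.generator is not None:
        arrays.update({f"gen_{k}": v for k, v in model.generator.state().items()})
    arrays.update({f"disc_{k}": v for k, v in model.discriminator.state().items()})
    header = {
        "config": asdict(model.config),
        "input_width": model.input_width,
        "feature_dim": model.feature_dim,
        "M": model.M,
        "input_mode": model.input_mode,
        "history": [asdict(h) for h in model.history],
        "has_generator": model.generator is not None,
    }
    buf = io.BytesIO()
    np.savez(buf, header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8), **arrays)
    with open(path, "wb") as fh:
        fh.write(buf.getvalue())


def load_model(path) -> TrainedGanModel:
    with np.load(path) as arch:
        header = json.loads(bytes(arch["header"]).decode())
        cfgd = dict(header["config"])
        cfgd["gen_layers"] = tuple(cfgd["gen_layers"])
        cfgd["disc_layers"] = tuple(cfgd["disc_layers"])
        cfg = GanConfig(**cfgd)
        rng = np.random.default_rng(0)
        disc = build_discriminator(cfg, header["input_width"], header["M"], rng)
        disc.load_state({k[5:]: arch[k] for k in arch.files if k.startswith("disc_")})
        gen = None
        if header["has_generator"]:
            gen = build_generator(cfg, header["input_width"], rng)
            gen.load_state({k[4:]: arch[k] for k in arch.files if k.startswith("gen_")})
    return TrainedGanModel(
        generator=gen, discriminator=disc, config=cfg,
        history=[LossBreakdown(**h) for h in header["history"]],
        input_width=header["input_width"], feature_dim=header["feature_dim"],
        M=header["M"], input_mode=header["input_mode"],
    )
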