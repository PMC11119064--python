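"""Conditional auxiliary-classifier GAN for functional-connectivity matrices.

Generator: a latent vector of total length 50 — uniform noise concatenated
with the condition (one-hot class label + phenotype encoding) — is mapped
through a small dense stack to a region-embedding matrix X in R^(N x d)
(d = 10), and the synthetic FC matrix is A = tanh(X X^T).  The inner product
guarantees symmetry and the tanh bounds every entry in (-1, 1), so outputs
are structurally valid correlation-like matrices (the diagonal is
tanh(||x_i||^2), not exactly 1; that relaxation applies to generated
samples only).

Discriminator: a BrainNetCNN — an edge-to-edge layer (cross-shaped filters,
16 maps), an edge-to-node layer (64 filters), a node-to-graph layer (128
filters), each followed by batch-norm, LeakyReLU(0.2) and dropout 0.5; then
dense(64), fusion with a dense(16) projection of the phenotype vector,
dense(32), and two heads: sigmoid validity (real vs generated) and softmax
class label.  The same backbone with only the class head is the standalone
BrainNetCNN baseline classifier.

Losses follow the AC-GAN recipe: the discriminator minimises validity BCE on
real and generated samples plus class cross-entropy on real samples; the
generator minimises validity BCE towards "real" plus class cross-entropy
towards its conditioned label.  Optimiser: Adam(lr=1e-4, beta1=0.5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .autodiff import Adam, Tensor, glorot_uniform
from .data_model import Cohort, FCMatrix

logger = logging.getLogger(__name__)

__all__ = ["GANConfig", "GeneratorParams", "DiscriminatorParams",
           "generator_forward", "e2e_forward", "e2n_forward", "n2g_forward",
           "discriminator_forward", "train_gan", "train_brainnetcnn",
           "generate_samples", "GANTrainResult"]


@dataclass
class GANConfig:
    """Hyper-parameters; defaults follow the published configuration."""

    latent_total: int = 50
    embed_dim: int = 10
    gen_hidden: int = 128
    ece_maps: int = 16
    ecn_filters: int = 64
    ncg_filters: int = 128
    disc_dense: int = 64
    phen_dense: int = 16
    joint_dense: int = 32
    dropout: float = 0.5
    leaky_slope: float = 0.2
    learning_rate: float = 1e-4
    beta1: float = 0.5
    epochs: int = 300
    batch_size: int = 16
    class_loss_on_fake_for_d: bool = False  # semi-supervised variant, off by default
    seed: int = 0

    def noise_len(self, n_classes: int, phen_len: int) -> int:
        n = self.latent_total - n_classes - phen_len
        if n <= 0:
            raise ValueError(
                f"latent_total={self.latent_total} leaves no room for noise "
                f"(condition length {n_classes + phen_len})")
        return n


# ---------------------------------------------------------------------------
# reference BrainNetCNN primitives (single map, plain numpy)


def e2e_forward(M: np.ndarray, row_w: np.ndarray, col_w: np.ndarray,
                bias: float = 0.0) -> np.ndarray:
    """Cross-shaped edge-to-edge filter on one N x N map.

    out(i, j) = sum_k row_w[k] M(i, k) + sum_k col_w[k] M(k, j) + bias.
    """
    M, row_w, col_w = np.asarray(M), np.asarray(row_w), np.asarray(col_w)
    if M.shape[0] != M.shape[1] or row_w.size != M.shape[0] or col_w.size != M.shape[0]:
        raise ValueError("e2e_forward: shape mismatch")
    rows = M @ row_w          # (N,)  weighted row sums
    cols = col_w @ M          # (N,)  weighted column sums
    return rows[:, None] + cols[None, :] + bias


def e2n_forward(M: np.ndarray, w: np.ndarray, bias: float = 0.0) -> np.ndarray:
    """Edge-to-node filter: out(i) = sum_j w[j] M(i, j) + bias."""
    M, w = np.asarray(M), np.asarray(w)
    if M.shape[1] != w.size:
        raise ValueError("e2n_forward: shape mismatch")
    return M @ w + bias


def n2g_forward(v: np.ndarray, w: np.ndarray, bias: float = 0.0) -> float:
    """Node-to-graph filter: weighted sum of node values plus bias."""
    v, w = np.asarray(v), np.asarray(w)
    if v.shape != w.shape:
        raise ValueError("n2g_forward: shape mismatch")
    return float(v @ w + bias)


# ---------------------------------------------------------------------------
# generator


class GeneratorParams:
    """Latent -> region-embedding map (dense, LeakyReLU, dense, reshape)."""

    def __init__(self, n_regions: int, cfg: GANConfig, n_classes: int,
                 phen_len: int, rng: np.random.Generator) -> None:
        self.n_regions, self.cfg = n_regions, cfg
        self.n_classes, self.phen_len = n_classes, phen_len
        d = cfg.embed_dim
        self.W1 = Tensor(glorot_uniform(rng, (cfg.latent_total, cfg.gen_hidden)),
                         requires_grad=True)
        self.b1 = Tensor(np.zeros(cfg.gen_hidden), requires_grad=True)
        self.W2 = Tensor(glorot_uniform(rng, (cfg.gen_hidden, n_regions * d)),
                         requires_grad=True)
        self.b2 = Tensor(np.zeros(n_regions * d), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return [self.W1, self.b1, self.W2, self.b2]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {n: getattr(self, n).data.copy() for n in ("W1", "b1", "W2", "b2")}


def _generator_graph(gp: GeneratorParams, latent: Tensor) -> Tensor:
    """Differentiable generator forward: latent (B, L) -> matrices (B, N, N)."""
    cfg = gp.cfg
    h = (latent @ gp.W1 + gp.b1).leaky_relu(cfg.leaky_slope)
    x = (h @ gp.W2 + gp.b2).reshape(-1, gp.n_regions, cfg.embed_dim)
    return (x @ x.transpose_last()).tanh()


def generator_forward(gp: GeneratorParams, noise: np.ndarray,
                      condition: np.ndarray) -> np.ndarray:
    """Generate one FC-shaped matrix from noise plus condition vector.

    ``condition`` is the concatenation of the one-hot class label and the
    phenotype encoding; ``len(noise) + len(condition)`` must equal the
    configured latent length.  Output is exactly symmetric with entries in
    (-1, 1).
    """
    noise, condition = np.asarray(noise).ravel(), np.asarray(condition).ravel()
    if noise.size + condition.size != gp.cfg.latent_total:
        raise ValueError(
            f"latent length {noise.size}+{condition.size} != "
            f"{gp.cfg.latent_total}")
    latent = np.concatenate([noise, condition])[None, :]
    out = _generator_graph(gp, Tensor(latent)).data[0]
    out = 0.5 * (out + out.T)  # exact symmetry despite float rounding
    # tanh saturates to exactly +-1.0 in float64 for |x| > ~19; keep the
    # open-interval guarantee by clipping to the nearest representable value
    bound = np.nextafter(1.0, 0.0)
    return np.clip(out, -bound, bound)


# ---------------------------------------------------------------------------
# discriminator (BrainNetCNN backbone)


class DiscriminatorParams:
    """BrainNetCNN backbone with phenotype fusion and two heads."""

    def __init__(self, n_regions: int, phen_len: int, n_classes: int,
                 cfg: GANConfig, rng: np.random.Generator) -> None:
        self.n_regions, self.phen_len, self.n_classes = n_regions, phen_len, n_classes
        self.cfg = cfg
        N = n_regions

        def param(shape, fan_in, fan_out):
            return Tensor(glorot_uniform(rng, shape, fan_in, fan_out),
                          requires_grad=True)

        F1, F2, F3 = cfg.ece_maps, cfg.ecn_filters, cfg.ncg_filters
        self.ece_row = param((F1, 1, N), 2 * N, F1)
        self.ece_col = param((F1, 1, N), 2 * N, F1)
        self.ece_b = Tensor(np.zeros(F1), requires_grad=True)
        self.ecn_w = param((F2, F1, N), F1 * N, F2)
        self.ecn_b = Tensor(np.zeros(F2), requires_grad=True)
        self.ncg_w = param((F3, F2, N), F2 * N, F3)
        self.ncg_b = Tensor(np.zeros(F3), requires_grad=True)
        self.W_dense = param((F3, cfg.disc_dense), F3, cfg.disc_dense)
        self.b_dense = Tensor(np.zeros(cfg.disc_dense), requires_grad=True)
        self.W_phen = param((phen_len, cfg.phen_dense), phen_len, cfg.phen_dense)
        self.b_phen = Tensor(np.zeros(cfg.phen_dense), requires_grad=True)
        joint_in = cfg.disc_dense + cfg.phen_dense
        self.W_joint = param((joint_in, cfg.joint_dense), joint_in, cfg.joint_dense)
        self.b_joint = Tensor(np.zeros(cfg.joint_dense), requires_grad=True)
        self.W_valid = param((cfg.joint_dense, 1), cfg.joint_dense, 1)
        self.b_valid = Tensor(np.zeros(1), requires_grad=True)
        self.W_class = param((cfg.joint_dense, n_classes), cfg.joint_dense, n_classes)
        self.b_class = Tensor(np.zeros(n_classes), requires_grad=True)

        # batch-norm scale/shift + running statistics per normalised layer
        self.bn: dict[str, dict] = {}
        for name, channels, spatial in (("ece", F1, (1, 1)), ("ecn", F2, (1,)),
                                        ("ncg", F3, ()), ("dense", cfg.disc_dense, ())):
            shape = (1, channels) + tuple(1 for _ in spatial)
            self.bn[name] = {
                "gamma": Tensor(np.ones(shape), requires_grad=True),
                "beta": Tensor(np.zeros(shape), requires_grad=True),
                "mean": np.zeros(shape), "var": np.ones(shape),
            }

    def parameters(self) -> list[Tensor]:
        ps = [self.ece_row, self.ece_col, self.ece_b, self.ecn_w, self.ecn_b,
              self.ncg_w, self.ncg_b, self.W_dense, self.b_dense,
              self.W_phen, self.b_phen, self.W_joint, self.b_joint,
              self.W_valid, self.b_valid, self.W_class, self.b_class]
        for entry in self.bn.values():
            ps.extend([entry["gamma"], entry["beta"]])
        return ps

    def state_dict(self) -> dict[str, np.ndarray]:
        names = ["ece_row", "ece_col", "ece_b", "ecn_w", "ecn_b", "ncg_w",
                 "ncg_b", "W_dense", "b_dense", "W_phen", "b_phen", "W_joint",
                 "b_joint", "W_valid", "b_valid", "W_class", "b_class"]
        state = {n: getattr(self, n).data.copy() for n in names}
        for bn_name, entry in self.bn.items():
            state[f"bn_{bn_name}_gamma"] = entry["gamma"].data.copy()
            state[f"bn_{bn_name}_beta"] = entry["beta"].data.copy()
            state[f"bn_{bn_name}_mean"] = entry["mean"].copy()
            state[f"bn_{bn_name}_var"] = entry["var"].copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for key, value in state.items():
            if key.startswith("bn_"):
                _, name, which = key.split("_", 2)
                if which in ("gamma", "beta"):
                    self.bn[name][which].data = np.array(value)
                else:
                    self.bn[name][which][...] = value
            else:
                getattr(self, key).data = np.array(value, dtype=np.float64)


def _bn(dp: DiscriminatorParams, name: str, x: Tensor, axes: tuple[int, ...],
        training: bool) -> Tensor:
    entry = dp.bn[name]
    return x.batch_norm(entry["gamma"], entry["beta"], axes,
                        entry["mean"], entry["var"], training)


def _discriminator_graph(dp: DiscriminatorParams, M: Tensor, phen: Tensor,
                         training: bool,
                         rng: Optional[np.random.Generator] = None
                         ) -> tuple[Tensor, Tensor]:
    """Forward to (validity logits (B,1), class logits (B,C))."""
    cfg = dp.cfg
    slope, p = cfg.leaky_slope, cfg.dropout
    x = M.reshape(M.shape[0], 1, dp.n_regions, dp.n_regions)
    x = x.edge_to_edge(dp.ece_row, dp.ece_col, dp.ece_b)      # (B,16,N,N)
    x = _bn(dp, "ece", x, (0, 2, 3), training).leaky_relu(slope)
    if training:
        x = x.dropout(p, rng, training)
    x = x.edge_to_node(dp.ecn_w, dp.ecn_b)                    # (B,64,N)
    x = _bn(dp, "ecn", x, (0, 2), training).leaky_relu(slope)
    if training:
        x = x.dropout(p, rng, training)
    x = x.node_to_graph(dp.ncg_w, dp.ncg_b)                   # (B,128)
    x = _bn(dp, "ncg", x, (0,), training).leaky_relu(slope)
    if training:
        x = x.dropout(p, rng, training)
    x = x @ dp.W_dense + dp.b_dense                           # (B,64)
    x = _bn(dp, "dense", x, (0,), training).leaky_relu(slope)
    if training:
        x = x.dropout(p, rng, training)
    ph = phen @ dp.W_phen + dp.b_phen                          # (B,16)
    joint = Tensor.concat([x, ph], axis=-1) @ dp.W_joint + dp.b_joint
    joint = joint.leaky_relu(slope)
    return joint @ dp.W_valid + dp.b_valid, joint @ dp.W_class + dp.b_class


def discriminator_forward(dp: DiscriminatorParams, fc_values: np.ndarray,
                          phen_vector: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Eval-mode forward: (validity in (0,1), class probabilities).

    Accepts a single subject ((N, N) and (p,)) or a batch.
    """
    single = fc_values.ndim == 2
    M = fc_values[None] if single else fc_values
    phen = phen_vector[None] if phen_vector.ndim == 1 else phen_vector
    if M.shape[-1] != dp.n_regions:
        raise ValueError(f"matrix N={M.shape[-1]} but discriminator expects "
                         f"{dp.n_regions}")
    v_logit, c_logit = _discriminator_graph(dp, Tensor(M), Tensor(phen),
                                            training=False)
    validity = 1.0 / (1.0 + np.exp(-v_logit.data[:, 0]))
    probs = c_logit.softmax()
    if single:
        return float(validity[0]), probs[0]
    return validity, probs


# ---------------------------------------------------------------------------
# training


@dataclass
class GANTrainResult:
    generator: GeneratorParams
    discriminator: DiscriminatorParams
    history: dict[str, list[float]] = field(default_factory=dict)


def _condition_batch(rng: np.random.Generator, labels: np.ndarray,
                     phen: np.ndarray, n_classes: int, batch: int
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample conditioning (label one-hot ++ phenotype) from the empirical
    training distribution, mirroring how real subjects pair the two."""
    pick = rng.integers(0, labels.size, size=batch)
    y = labels[pick]
    onehot = np.zeros((batch, n_classes))
    onehot[np.arange(batch), y] = 1.0
    return y, onehot, phen[pick]


def train_gan(cohort_train: Cohort, cfg: GANConfig,
              validation: Optional[Cohort] = None,
              site_levels: Optional[Sequence[str]] = None) -> GANTrainResult:
    """Adversarial training of the conditional AC-GAN.

    Alternates one discriminator and one generator Adam step per batch.
    History records per-epoch validity accuracy and real-sample class
    accuracy.  With a validation cohort, the discriminator parameters with
    the best validation class accuracy are restored at the end (validity
    accuracy nearest 0.5 breaks ties).  Deterministic given ``cfg.seed``.
    """
    y = cohort_train.labels()
    n_classes = len(cohort_train.label_names)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    if site_levels is None:
        site_levels = cohort_train.site_levels
    X = cohort_train.matrices()
    P = cohort_train.phenotype_matrix(site_levels)
    phen_len = P.shape[1]
    noise_len = cfg.noise_len(n_classes, phen_len)

    rng = np.random.default_rng(cfg.seed)
    gp = GeneratorParams(cohort_train.n_regions, cfg, n_classes, phen_len, rng)
    dp = DiscriminatorParams(cohort_train.n_regions, phen_len, n_classes, cfg, rng)
    opt_g = Adam(gp.parameters(), lr=cfg.learning_rate, beta1=cfg.beta1)
    opt_d = Adam(dp.parameters(), lr=cfg.learning_rate, beta1=cfg.beta1)

    if validation is not None:
        Xv = validation.matrices()
        Pv = validation.phenotype_matrix(site_levels)
        yv = validation.labels()
    # lexicographic: validation class accuracy first, then validity accuracy
    # closest to 0.5 (an equilibrium discriminator) as tie-breaker
    best_key = (-1.0, -np.inf)
    best_state = None

    history: dict[str, list[float]] = {"d_loss": [], "g_loss": [],
                                       "validity_acc": [], "class_acc": []}
    n = X.shape[0]
    for epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        d_losses, g_losses, v_correct, v_total, c_correct = [], [], 0, 0, 0
        for start in range(0, n, cfg.batch_size):
            batch = perm[start:start + cfg.batch_size]
            B = batch.size
            # --- discriminator step
            y_f, onehot_f, phen_f = _condition_batch(rng, y, P, n_classes, B)
            noise = rng.uniform(-1.0, 1.0, size=(B, noise_len))
            latent = np.concatenate([noise, onehot_f, phen_f], axis=1)
            fake = _generator_graph(gp, Tensor(latent)).data  # detached for D

            v_real, c_real = _discriminator_graph(dp, Tensor(X[batch]),
                                                  Tensor(P[batch]), True, rng)
            v_fake, c_fake = _discriminator_graph(dp, Tensor(fake),
                                                  Tensor(phen_f), True, rng)
            d_loss = (v_real.binary_cross_entropy_with_logits(1.0)
                      + v_fake.binary_cross_entropy_with_logits(0.0)
                      + c_real.cross_entropy(y[batch]))
            if cfg.class_loss_on_fake_for_d:
                d_loss = d_loss + c_fake.cross_entropy(y_f)
            opt_d.zero_grad()
            d_loss.backward()
            opt_d.step()
            if not np.isfinite(d_loss.data):
                raise FloatingPointError(
                    f"discriminator loss diverged at epoch {epoch}")

            v_correct += int(np.sum(v_real.data[:, 0] > 0))
            v_correct += int(np.sum(v_fake.data[:, 0] <= 0))
            v_total += 2 * B
            c_correct += int(np.sum(c_real.softmax().argmax(axis=1) == y[batch]))
            d_losses.append(float(d_loss.data))

            # --- generator step (fresh noise, D frozen for this loss)
            y_g, onehot_g, phen_g = _condition_batch(rng, y, P, n_classes, B)
            noise = rng.uniform(-1.0, 1.0, size=(B, noise_len))
            latent_t = Tensor(np.concatenate([noise, onehot_g, phen_g], axis=1))
            fake_t = _generator_graph(gp, latent_t)
            v_g, c_g = _discriminator_graph(dp, fake_t, Tensor(phen_g), True, rng)
            g_loss = (v_g.binary_cross_entropy_with_logits(1.0)
                      + c_g.cross_entropy(y_g))
            opt_g.zero_grad()
            opt_d.zero_grad()  # discard D grads from the generator pass
            g_loss.backward()
            opt_g.step()
            if not np.isfinite(g_loss.data):
                raise FloatingPointError(
                    f"generator loss diverged at epoch {epoch}")
            g_losses.append(float(g_loss.data))

        val_acc_epoch = v_correct / max(v_total, 1)
        history["d_loss"].append(float(np.mean(d_losses)))
        history["g_loss"].append(float(np.mean(g_losses)))
        history["validity_acc"].append(val_acc_epoch)
        history["class_acc"].append(c_correct / n)

        if validation is not None:
            _, probs = discriminator_forward(dp, Xv, Pv)
            acc = float(np.mean(probs.argmax(axis=1) == yv))
            key = (acc, -abs(val_acc_epoch - 0.5))
            if key > best_key:
                best_key = key
                best_state = dp.state_dict()
    if best_state is not None:
        dp.load_state_dict(best_state)
        logger.info("train_gan: restored best validation class accuracy %.3f",
                    best_key[0])
    return GANTrainResult(generator=gp, discriminator=dp, history=history)


def train_brainnetcnn(cohort_train: Cohort, cfg: GANConfig,
                      validation: Optional[Cohort] = None,
                      site_levels: Optional[Sequence[str]] = None
                      ) -> DiscriminatorParams:
    """Train the BrainNetCNN backbone as a plain classifier (class head only).

    Same architecture and optimiser settings as the GAN discriminator, but no
    generator and no validity loss — the published baseline.
    """
    y = cohort_train.labels()
    n_classes = len(cohort_train.label_names)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    if site_levels is None:
        site_levels = cohort_train.site_levels
    X = cohort_train.matrices()
    P = cohort_train.phenotype_matrix(site_levels)

    rng = np.random.default_rng(cfg.seed)
    dp = DiscriminatorParams(cohort_train.n_regions, P.shape[1], n_classes, cfg, rng)
    opt = Adam(dp.parameters(), lr=cfg.learning_rate, beta1=cfg.beta1)

    if validation is not None:
        Xv = validation.matrices()
        Pv = validation.phenotype_matrix(site_levels)
        yv = validation.labels()
    best_acc, best_state = -1.0, None

    n = X.shape[0]
    for epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            batch = perm[start:start + cfg.batch_size]
            _, c_logit = _discriminator_graph(dp, Tensor(X[batch]),
                                              Tensor(P[batch]), True, rng)
            loss = c_logit.cross_entropy(y[batch])
            opt.zero_grad()
            loss.backward()
            opt.step()
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"loss diverged at epoch {epoch}")
        if validation is not None:
            _, probs = discriminator_forward(dp, Xv, Pv)
            acc = float(np.mean(probs.argmax(axis=1) == yv))
            if acc > best_acc:
                best_acc, best_state = acc, dp.state_dict()
    if best_state is not None:
        dp.load_state_dict(best_state)
    return dp


def generate_samples(gp: GeneratorParams, n: int, cohort: Cohort,
                     seed: int, site_levels: Optional[Sequence[str]] = None
                     ) -> list[tuple[FCMatrix, np.ndarray, int]]:
    """Draw n synthetic matrices with conditions resampled from ``cohort``.

    Returns (FCMatrix, phenotype vector, class index) triples; matrices are
    exactly symmetric with entries in (-1, 1) and are flagged
    ``unit_diagonal=False``.
    """
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    if site_levels is None:
        site_levels = cohort.site_levels
    labels = cohort.labels()
    P = cohort.phenotype_matrix(site_levels)
    n_classes = len(cohort.label_names)
    noise_len = gp.cfg.noise_len(n_classes, P.shape[1])
    out = []
    for i in range(n):
        y, onehot, phen = _condition_batch(rng, labels, P, n_classes, 1)
        noise = rng.uniform(-1.0, 1.0, size=noise_len)
        values = generator_forward(gp, noise, np.concatenate([onehot[0], phen[0]]))
        fc = FCMatrix(values=values, region_ids=list(cohort.region_ids),
                      unit_diagonal=False)
        out.append((fc, phen[0], int(y[0])))
    return out
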