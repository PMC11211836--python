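"""The spectrum-embedding network and its training loop.

Architecture
------------
The spectrum encoder stacks six residual blocks of dilated 1-D
convolutions with stride-2 pooling: dilations shrink block by block
(32, 16, 8, 4, 2, 1) so early blocks see wide receptive fields and deep
blocks narrow ones, while channel counts grow by ~1.5x per block.  The
pooled feature map is flattened into a dense layer; the meta vector
(charge one-hot, scaled precursor mass, scaled NCE) passes through a
sigmoid-activated linear layer and is concatenated before the final dense
layer, whose 256-dimensional output is L2-normalized.  A peptide branch
(two dense layers on the 30x20 one-hot) maps sequences into the same
latent space; cosine similarity is then a plain dot product.

Training minimizes an additive-margin softmax loss between spectrum
embeddings and the peptide-branch embeddings of the batch's unique
peptides (each unique peptide is one class), plus an auxiliary
mean-squared reconstruction of the clean binned spectrum from the latent
vector.  Gaussian noise is added to input spectra during training only.
One model is trained per precursor charge (2+ and 3+).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .nn import autograd as ag
from .nn.layers import Dense, Module, TCNBlock
from .nn.optim import make_optimizer
from .spectra_io import Spectrum
from .vectorize import (
    META_DIM,
    MAX_PEPTIDE_LEN,
    N_AMINO_ACIDS,
    VectorizationConfig,
    add_gaussian_noise,
    encode_peptide,
    make_input_matrix,
)


@dataclass(frozen=True)
class EncoderConfig:
    n_tcn_blocks: int = 6
    base_channels: int = 16
    channel_growth: float = 1.5
    kernel_size: int = 7
    dilation_schedule: tuple[int, ...] = (32, 16, 8, 4, 2, 1)
    latent_dim: int = 256
    meta_dim: int = 32
    flatten_hidden: int = 84
    shortcut_dim: int = 32
    intensity_power: float = 0.5
    input_len: int = 20480
    peptide_hidden: int = 512
    decoder_hidden: int = 256

    def __post_init__(self) -> None:
        if len(self.dilation_schedule) != self.n_tcn_blocks:
            raise ValueError("dilation_schedule length must equal n_tcn_blocks")
        if any(a <= b for a, b in zip(self.dilation_schedule, self.dilation_schedule[1:])):
            raise ValueError("dilations must be strictly decreasing")
        if self.latent_dim <= 0:
            raise ValueError("latent_dim must be positive")
        if self.input_len % (2**self.n_tcn_blocks):
            raise ValueError("input_len must be divisible by 2^n_tcn_blocks")

    @property
    def block_channels(self) -> tuple[int, ...]:
        return tuple(
            int(round(self.base_channels * self.channel_growth**i))
            for i in range(self.n_tcn_blocks)
        )

    @classmethod
    def reduced(cls) -> "EncoderConfig":
        """Desk-scale encoder matched to VectorizationConfig.reduced()."""
        return cls(
            base_channels=4,
            flatten_hidden=64,
            meta_dim=8,
            shortcut_dim=64,
            input_len=2048,
            peptide_hidden=128,
            decoder_hidden=64,
        )


@dataclass(frozen=True)
class LossConfig:
    am_scale: float = 30.0
    am_margin: float = 0.35
    recon_weight: float = 0.1

    def __post_init__(self) -> None:
        if self.am_scale <= 0:
            raise ValueError("am_scale must be > 0")
        if not 0 <= self.am_margin < 1:
            raise ValueError("am_margin must be in [0, 1)")
        if self.recon_weight < 0:
            raise ValueError("recon_weight must be >= 0")


@dataclass(frozen=True)
class TrainingConfig:
    charge: int = 2
    learning_rate: float = 0.0072
    epochs: int = 150
    batch_size: int = 32
    noise_sigma: float = 0.01
    replicate_cap: int = 10
    seed: int = 1
    use_radam: bool = True  # plain-Adam fallback when False


class SpectrumEncoder(Module):
    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        self.config = config
        chans = config.block_channels
        self.blocks = [
            TCNBlock(
                c_in=2 if i == 0 else chans[i - 1],
                c_out=chans[i],
                kernel=config.kernel_size,
                dilation=config.dilation_schedule[i],
                rng=rng,
            )
            for i in range(config.n_tcn_blocks)
        ]
        self.final_len = config.input_len // (2**config.n_tcn_blocks)
        self.flat = Dense(chans[-1] * self.final_len, config.flatten_hidden, rng)
        self.meta = Dense(META_DIM, config.meta_dim, rng)
        # linear shortcut from the raw binned vector: lets the model exploit
        # raw-spectrum similarity from the first step while the convolutional
        # stack learns refined features (greatly speeds up convergence)
        self.shortcut = Dense(config.input_len, config.shortcut_dim, rng)
        self.out = Dense(
            config.flatten_hidden + config.meta_dim + config.shortcut_dim,
            config.latent_dim,
            rng,
        )

    def __call__(self, x: ag.Tensor, meta: ag.Tensor) -> ag.Tensor:
        h = x
        for block in self.blocks:
            h = block(h)
        h = ag.reshape(h, (h.shape[0], h.shape[1] * h.shape[2]))
        h = ag.relu(self.flat(h))
        m = ag.sigmoid(self.meta(meta))
        sc = ag.relu(self.shortcut(ag.take_channel(x, 0)))
        return ag.l2_normalize(self.out(ag.concat([h, m, sc], axis=1)))


class PeptideEncoder(Module):
    """Two dense layers from the 30x20 one-hot into the shared latent space."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        n_in = MAX_PEPTIDE_LEN * N_AMINO_ACIDS
        self.d1 = Dense(n_in, config.peptide_hidden, rng)
        self.d2 = Dense(config.peptide_hidden, config.latent_dim, rng)

    def __call__(self, onehot_flat: ag.Tensor) -> ag.Tensor:
        return ag.l2_normalize(self.d2(ag.relu(self.d1(onehot_flat))))


class Decoder(Module):
    """Auxiliary head reconstructing the clean binned spectrum from the
    latent vector, discouraging information loss in the embedding."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        self.d1 = Dense(config.latent_dim, config.decoder_hidden, rng)
        self.d2 = Dense(config.decoder_hidden, config.input_len, rng)

    def __call__(self, latent: ag.Tensor) -> ag.Tensor:
        return self.d2(ag.relu(self.d1(latent)))


def am_softmax_loss(
    spectrum_vecs: np.ndarray,
    class_anchor_vecs: np.ndarray,
    class_labels: np.ndarray,
    loss_config: LossConfig = LossConfig(),
) -> float:
    """Additive-margin softmax loss between unit-norm spectrum vectors and
    class anchors; with margin 0 and scale 1 this is plain softmax
    cross-entropy on cosine logits."""
    s_t = ag.constant(spectrum_vecs)
    a_t = ag.constant(class_anchor_vecs)
    logits = ag.matmul(s_t, ag.transpose2d(a_t))
    loss = ag.margin_cross_entropy(
        logits, np.asarray(class_labels), loss_config.am_scale, loss_config.am_margin
    )
    return float(loss.data)


def reconstruction_loss(decoded: np.ndarray, binned_target: np.ndarray) -> float:
    """Mean squared error between decoder output and the clean binned spectrum."""
    decoded = np.asarray(decoded, dtype=np.float64)
    target = np.asarray(binned_target, dtype=np.float64)
    if decoded.shape != target.shape:
        raise ValueError("shape mismatch between decoded and target")
    return float(((decoded - target) ** 2).mean())


class SpecEmbedModel:
    """Bundle of spectrum encoder, peptide branch and decoder for one
    precursor charge, plus the vectorization config they were built for."""

    def __init__(
        self,
        encoder_config: EncoderConfig,
        vec_config: VectorizationConfig,
        charge: int = 2,
        seed: int = 0,
    ):
        if vec_config.padded_len != encoder_config.input_len:
            raise ValueError("vectorization padded_len must equal encoder input_len")
        rng = np.random.default_rng(seed)
        self.encoder_config = encoder_config
        self.vec_config = vec_config
        self.charge = charge
        self.encoder = SpectrumEncoder(encoder_config, rng)
        self.peptide_encoder = PeptideEncoder(encoder_config, rng)
        self.decoder = Decoder(encoder_config, rng)

    # -- inference ---------------------------------------------------------

    def _inputs(self, spectra: list[Spectrum]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Model inputs: binned/reversed channels (intensity-power compressed
        to tame the dynamic range), meta vectors, and the clean compressed
        binned vectors (the reconstruction target)."""
        mats = [make_input_matrix(s, self.vec_config) for s in spectra]
        power = self.encoder_config.intensity_power
        clean = np.stack([m.binned for m in mats])
        if power != 1.0:
            clean = clean**np.float32(power)
        x = np.stack([clean, clean[:, ::-1]], axis=1)
        meta = np.stack([m.meta for m in mats])
        return x, meta, clean

    def embed_spectra(
        self, spectra: list[Spectrum], batch_size: int = 64, check_charge: bool = True
    ) -> np.ndarray:
        """Unit-norm latent vectors, one row per spectrum, order preserved."""
        if check_charge:
            bad = [s.title or str(i) for i, s in enumerate(spectra) if s.charge != self.charge]
            if bad:
                raise ValueError(
                    f"charge mismatch with model (charge {self.charge}): {bad[:5]}"
                    + ("..." if len(bad) > 5 else "")
                )
        out = []
        for lo in range(0, len(spectra), batch_size):
            x, meta, _ = self._inputs(spectra[lo : lo + batch_size])
            vec = self.encoder(ag.constant(x), ag.constant(meta))
            out.append(vec.data.copy())
        return np.concatenate(out) if out else np.zeros((0, self.encoder_config.latent_dim))

    def embed_peptides(self, peptides: list[str]) -> np.ndarray:
        oh = np.stack([encode_peptide(p).matrix.ravel() for p in peptides])
        return self.peptide_encoder(ag.constant(oh)).data.copy()

    def embed_peptide(self, peptide: str) -> np.ndarray:
        return self.embed_peptides([peptide])[0]

    # -- persistence -------------------------------------------------------

    def _all_params(self):
        return (
            self.encoder.parameters()
            + self.peptide_encoder.parameters()
            + self.decoder.parameters()
        )

    def config_dict(self) -> dict:
        return {
            "encoder": asdict(self.encoder_config),
            "vectorization": asdict(self.vec_config),
            "charge": self.charge,
        }

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.config_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def save(self, path: str | Path) -> None:
        arrays = {f"p{i:04d}": p.data for i, p in enumerate(self._all_params())}
        np.savez(
            path,
            __config__=np.frombuffer(
                json.dumps(self.config_dict(), sort_keys=True).encode(), dtype=np.uint8
            ),
            **arrays,
        )

    @classmethod
    def load(cls, path: str | Path, expect_config: EncoderConfig | None = None) -> "SpecEmbedModel":
        import zipfile

        try:
            with np.load(path) as data:
                cfg = json.loads(bytes(data["__config__"]).decode())
                arrays = [data[k] for k in sorted(k for k in data.files if k != "__config__")]
        except (OSError, ValueError, KeyError, EOFError, zipfile.BadZipFile) as exc:
            raise ValueError(f"cannot load weights from {path}: {exc}") from exc
        enc_cfg = EncoderConfig(
            **{**cfg["encoder"], "dilation_schedule": tuple(cfg["encoder"]["dilation_schedule"])}
        )
        if expect_config is not None and expect_config != enc_cfg:
            raise ValueError(
                f"weights config {enc_cfg} does not match expected {expect_config}"
            )
        vc = VectorizationConfig(**cfg["vectorization"])
        model = cls(enc_cfg, vc, charge=cfg["charge"])
        params = model._all_params()
        if len(params) != len(arrays):
            raise ValueError("weights file truncated or from a different architecture")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("weights/config shape mismatch")
            p.data = a.astype(np.float32, copy=True)
        return model


@dataclass
class TrainResult:
    model: SpecEmbedModel
    history: pd.DataFrame  # epoch, train_loss, val_accuracy
    best_epoch: int
    best_val_accuracy: float
    n_classes: int
    n_train: int
    n_val: int


def _split_replicates(
    spectra: list[Spectrum], cap: int, rng: np.random.Generator
) -> tuple[list[str], list[int], list[int], np.ndarray]:
    """Apply the replicate cap, hold out one replicate per multi-replicate
    peptide for validation, and drop singleton peptides entirely."""
    by_pep: dict[str, list[int]] = {}
    for i, s in enumerate(spectra):
        if s.peptide:
            by_pep.setdefault(s.peptide, []).append(i)
    classes, train_idx, val_idx, labels = [], [], [], []
    for pep in sorted(by_pep):
        idxs = by_pep[pep]
        if len(idxs) < 2:
            continue  # no replicates: unused for either role
        idxs = list(idxs)
        if len(idxs) > cap:
            idxs = [idxs[j] for j in rng.choice(len(idxs), size=cap, replace=False)]
        hold = int(rng.integers(len(idxs)))
        val_idx.append(idxs[hold])
        cls = len(classes)
        classes.append(pep)
        for j, idx in enumerate(idxs):
            if j != hold:
                train_idx.append(idx)
                labels.append(cls)
    return classes, train_idx, val_idx, np.asarray(labels)


def train(
    spectra: list[Spectrum],
    encoder_config: EncoderConfig,
    vec_config: VectorizationConfig,
    loss_config: LossConfig = LossConfig(),
    training_config: TrainingConfig = TrainingConfig(),
) -> TrainResult:
    """Train one per-charge model on annotated replicate spectra.

    Replicates are capped (10 per unique peptide by default), one replicate
    per multi-replicate peptide is held out for cross-validation, and
    singleton peptides are dropped.  Each epoch adds fresh Gaussian noise to
    the training inputs.  The returned model carries the weights from the
    epoch with the best held-out top-1 retrieval accuracy (retrieval against
    the peptide anchors of all training classes).
    """
    tc = training_config
    charges = {s.charge for s in spectra}
    if len(charges) > 1:
        raise ValueError(f"mixed charges in training set: {sorted(charges)}")
    if charges != {tc.charge}:
        raise ValueError(f"training set charge {charges} != model charge {tc.charge}")
    rng = np.random.default_rng(tc.seed)
    classes, train_idx, val_idx, labels = _split_replicates(spectra, tc.replicate_cap, rng)
    if len(classes) < 2:
        raise ValueError("need at least 2 peptide classes with replicates")

    model = SpecEmbedModel(encoder_config, vec_config, charge=tc.charge, seed=tc.seed)
    x_all, meta_all, clean_all = model._inputs(spectra)
    onehots = np.stack([encode_peptide(p).matrix.ravel() for p in classes])

    params = model._all_params()
    opt = make_optimizer(params, lr=tc.learning_rate, use_radam=tc.use_radam)

    x_val, meta_val = x_all[val_idx], meta_all[val_idx]
    val_labels = np.arange(len(classes))  # val_idx[i] is a replicate of classes[i]

    history = []
    best_acc, best_epoch, best_state = -1.0, -1, None
    n_train = len(train_idx)
    train_idx_arr = np.asarray(train_idx)

    for epoch in range(tc.epochs):
        order = rng.permutation(n_train)
        epoch_loss = 0.0
        n_batches = 0
        for lo in range(0, n_train, tc.batch_size):
            sel = train_idx_arr[order[lo : lo + tc.batch_size]]
            lab = labels[order[lo : lo + tc.batch_size]]
            if len(sel) < 2 or len(np.unique(lab)) < 2:
                continue
            binned = clean_all[sel]
            if tc.noise_sigma > 0:
                noisy = np.clip(
                    binned + rng.normal(0, tc.noise_sigma, size=binned.shape).astype(np.float32),
                    0,
                    None,
                )
            else:
                noisy = binned
            x = np.stack([noisy, noisy[:, ::-1]], axis=1)
            uniq, lab_local = np.unique(lab, return_inverse=True)

            s_vec = model.encoder(ag.constant(x), ag.constant(meta_all[sel]))
            a_vec = model.peptide_encoder(ag.constant(onehots[uniq]))
            logits = ag.matmul(s_vec, ag.transpose2d(a_vec))
            loss = ag.margin_cross_entropy(
                logits, lab_local, loss_config.am_scale, loss_config.am_margin
            )
            if loss_config.recon_weight > 0:
                recon = model.decoder(s_vec)
                loss = ag.add(loss, ag.scale(ag.mse(recon, binned), loss_config.recon_weight))
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1

        # held-out top-1 retrieval against all training-class anchors
        anchors = model.embed_peptides(classes)
        val_vecs = model.encoder(ag.constant(x_val), ag.constant(meta_val)).data
        acc = float((np.argmax(val_vecs @ anchors.T, axis=1) == val_labels).mean())
        history.append(
            {"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1), "val_accuracy": acc}
        )
        if acc > best_acc:
            best_acc, best_epoch = acc, epoch
            best_state = [p.data.copy() for p in params]

    if best_state is not None:
        for p, a in zip(params, best_state):
            p.data = a
    return TrainResult(
        model=model,
        history=pd.DataFrame(history),
        best_epoch=best_epoch,
        best_val_accuracy=best_acc,
        n_classes=len(classes),
        n_train=n_train,
        n_val=len(val_idx),
    )
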