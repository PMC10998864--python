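"""The seven-component dual-aligned VAE translator.

Two modality-specific encoders map processed profiles into 128-dimensional
embeddings; a shared translator turns a source embedding into a mean and
log-variance, draws a latent sample by reparameterization, and maps it through
a *target-specific* output block (shared across sources, so chromatin-to-RNA
translation reuses the same RNA output block as RNA-to-RNA mapping); two
decoders reconstruct profiles; two discriminators judge whether an embedding
is native or translated.  The chromatin encoder/decoder use independent
per-chromosome blocks — no parameters connect peaks on different chromosomes.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .containers import ChromosomeIndex

__all__ = [
    "ModelConfig",
    "LatentBatch",
    "Encoder",
    "Decoder",
    "Translator",
    "Discriminator",
    "make_encoder",
    "make_decoder",
    "ModelState",
]

ADT_KL_WEIGHT = 1.0 / 150.0


@dataclass
class ModelConfig:
    """Hyperparameters of the translator.

    ``kl_weight`` per side follows the rule 20/I for transcriptome and
    chromatin sides and a constant 1/150 for a protein side (to guard against
    posterior collapse on low-dimensional panels); the integrative phase
    weights the summed KL terms by the sum of the per-side weights.
    """

    rna_hidden: int = 256
    latent_dim: int = 128
    atac_per_chrom_dim: int = 32
    adt_hidden: int = 128
    dropout_rate: float = 0.1
    leaky_slope: float = 0.01
    mask_rate_rna: float = 0.5
    mask_rate_atac: float = 0.3
    mask_rate_adt: float = 0.0
    w_r: float = 1.0
    w_a: float = 2.0
    w_dis: float = 1.0
    lr_main: float = 1e-3
    lr_disc: float = 5e-3
    pretrain_epochs: int = 100
    train_epochs: int = 200
    patience: int = 50
    batch_size: int = 64
    val_fraction: float = 0.2
    soft_label_pos: tuple[float, float] = (0.8, 1.0)
    soft_label_neg: tuple[float, float] = (0.0, 0.2)

    def __post_init__(self):
        for name in ("mask_rate_rna", "mask_rate_atac", "mask_rate_adt", "dropout_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("rna_hidden", "latent_dim", "atac_per_chrom_dim", "adt_hidden",
                     "pretrain_epochs", "train_epochs", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("w_r", "w_a", "w_dis"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def mask_rate(self, kind: str) -> float:
        return {"rna": self.mask_rate_rna, "atac": self.mask_rate_atac,
                "adt": self.mask_rate_adt}[kind]

    def kl_weight(self, kind: str, n_features: int) -> float:
        if kind == "adt":
            return ADT_KL_WEIGHT
        return 20.0 / n_features


@dataclass
class LatentBatch:
    """A batch in latent space: variational mean/log-variance and the
    (possibly sampled) translated embedding."""

    embedding: np.ndarray
    mean: np.ndarray
    logvar: np.ndarray
    sampled: bool


class Encoder:
    """Input mask -> hidden stack -> 128-dim embedding."""

    def __init__(self, net: nn.Sequential, mask: nn.InputMask, kind: str, n_features: int):
        self.net = net
        self.mask = mask
        self.kind = kind
        self.n_features = n_features

    def forward(self, x, *, training=False, rng=None):
        masked, mcache = self.mask.forward(x, training=training, rng=rng)
        y, caches = self.net.forward(masked, training=training, rng=rng)
        return y, (mcache, caches)

    def backward(self, cache, grad_out):
        mcache, caches = cache
        g = self.net.backward(caches, grad_out)
        return self.mask.backward(mcache, g)

    def __call__(self, x, *, training=False, rng=None):
        return self.forward(x, training=training, rng=rng)[0]

    def parameters(self):
        return self.net.parameters()


class Decoder:
    def __init__(self, net: nn.Sequential, kind: str, n_features: int):
        self.net = net
        self.kind = kind
        self.n_features = n_features

    def forward(self, emb, *, training=False, rng=None):
        return self.net.forward(emb, training=training, rng=rng)

    def backward(self, cache, grad_out):
        return self.net.backward(cache, grad_out)

    def __call__(self, emb, *, training=False, rng=None):
        return self.forward(emb, training=training, rng=rng)[0]

    def parameters(self):
        return self.net.parameters()


def make_encoder(kind: str, n_features: int, cfg: ModelConfig,
                 rng: np.random.Generator,
                 chrom_index: ChromosomeIndex | None = None) -> Encoder:
    act = lambda: nn.LeakyReLU(cfg.leaky_slope)  # noqa: E731
    drop = lambda: nn.Dropout(cfg.dropout_rate)  # noqa: E731
    if kind == "rna":
        net = nn.Sequential(
            nn.Dense(n_features, cfg.rna_hidden, rng), act(), drop(),
            nn.Dense(cfg.rna_hidden, cfg.latent_dim, rng), act(),
        )
    elif kind == "atac":
        if chrom_index is None:
            raise ValueError("chromatin encoder requires a ChromosomeIndex")
        blocks = chrom_index.block_indices()
        if chrom_index.n_features != n_features:
            raise ValueError(
                f"chromosome index covers {chrom_index.n_features} features, "
                f"matrix has {n_features}"
            )
        net = nn.Sequential(
            nn.BlockDense(blocks, cfg.atac_per_chrom_dim, rng), act(), drop(),
            nn.Dense(cfg.atac_per_chrom_dim * len(blocks), cfg.latent_dim, rng), act(),
        )
    elif kind == "adt":
        net = nn.Sequential(
            nn.Dense(n_features, cfg.adt_hidden, rng), act(), drop(),
            nn.Dense(cfg.adt_hidden, cfg.latent_dim, rng), act(),
        )
    else:
        raise ValueError(f"unknown modality kind {kind!r}")
    return Encoder(net, nn.InputMask(cfg.mask_rate(kind)), kind, n_features)


def make_decoder(kind: str, n_features: int, cfg: ModelConfig,
                 rng: np.random.Generator,
                 chrom_index: ChromosomeIndex | None = None) -> Decoder:
    act = lambda: nn.LeakyReLU(cfg.leaky_slope)  # noqa: E731
    drop = lambda: nn.Dropout(cfg.dropout_rate)  # noqa: E731
    if kind == "rna":
        # linear output: processed transcriptome is log-space, unbounded above
        net = nn.Sequential(
            nn.Dense(cfg.latent_dim, cfg.rna_hidden, rng), act(), drop(),
            nn.Dense(cfg.rna_hidden, n_features, rng),
        )
    elif kind == "atac":
        if chrom_index is None:
            raise ValueError("chromatin decoder requires a ChromosomeIndex")
        blocks = chrom_index.block_indices()
        net = nn.Sequential(
            nn.Dense(cfg.latent_dim, cfg.atac_per_chrom_dim * len(blocks), rng),
            act(), drop(),
            nn.BlockScatterDense(blocks, cfg.atac_per_chrom_dim, n_features, rng),
            nn.Sigmoid(),
        )
    elif kind == "adt":
        net = nn.Sequential(
            nn.Dense(cfg.latent_dim, cfg.adt_hidden, rng), act(), drop(),
            nn.Dense(cfg.adt_hidden, n_features, rng),
        )
    else:
        raise ValueError(f"unknown modality kind {kind!r}")
    return Decoder(net, kind, n_features)


class Translator:
    """Latent-space translator with weight sharing across source modalities.

    One *input block* per source side computes the variational mean and
    log-variance (two parallel dense+LeakyReLU sub-blocks); one *output block*
    per target side maps the latent draw to the translated embedding, and that
    same block serves every source.
    """

    def __init__(self, sides: tuple[str, str], latent_dim: int, slope: float,
                 rng: np.random.Generator):
        self.sides = sides
        self.mean_blocks = {}
        self.logvar_blocks = {}
        self.out_blocks = {}
        for s in sides:
            self.mean_blocks[s] = nn.Sequential(
                nn.Dense(latent_dim, latent_dim, rng), nn.LeakyReLU(slope))
            self.logvar_blocks[s] = nn.Sequential(
                nn.Dense(latent_dim, latent_dim, rng), nn.LeakyReLU(slope))
        for s in sides:
            self.out_blocks[s] = nn.Sequential(
                nn.Dense(latent_dim, latent_dim, rng), nn.LeakyReLU(slope))

    def encode_latent(self, emb, source: str):
        """Mean/log-variance of the source-specific variational posterior."""
        if source not in self.mean_blocks:
            raise KeyError(f"translator has no input block for side {source!r}")
        mean, mc = self.mean_blocks[source].forward(emb)
        logvar, lc = self.logvar_blocks[source].forward(emb)
        return mean, logvar, (mc, lc)

    def backward_latent(self, source: str, cache, grad_mean, grad_logvar):
        mc, lc = cache
        g1 = self.mean_blocks[source].backward(mc, grad_mean)
        g2 = self.logvar_blocks[source].backward(lc, grad_logvar)
        return g1 + g2

    def decode_latent(self, z, target: str):
        if target not in self.out_blocks:
            raise KeyError(f"translator has no output block for side {target!r}")
        return self.out_blocks[target].forward(z)

    def backward_out(self, target: str, cache, grad_out):
        return self.out_blocks[target].backward(cache, grad_out)

    def translate(self, emb, source: str, target: str, *, sample: bool,
                  rng: np.random.Generator | None = None) -> LatentBatch:
        """Full source->target latent translation (inference-style API)."""
        mean, logvar, _ = self.encode_latent(emb, source)
        if sample:
            if rng is None:
                raise ValueError("sampling requires an rng")
            eps = rng.standard_normal(mean.shape)
            z = mean + np.exp(logvar / 2.0) * eps
        else:
            z = mean
        out, _ = self.decode_latent(z, target)
        return LatentBatch(embedding=out, mean=mean, logvar=logvar, sampled=sample)

    def parameters(self):
        ps = []
        for s in self.sides:
            ps += self.mean_blocks[s].parameters()
            ps += self.logvar_blocks[s].parameters()
        for s in self.sides:
            ps += self.out_blocks[s].parameters()
        return ps

    def side_parameters(self, side: str):
        """Parameters touched when pretraining one side in isolation."""
        return (self.mean_blocks[side].parameters()
                + self.logvar_blocks[side].parameters()
                + self.out_blocks[side].parameters())


class Discriminator:
    """128-dim dense+LeakyReLU block followed by a sigmoid output unit;
    returns a per-cell probability that the embedding is native."""

    def __init__(self, latent_dim: int, slope: float, rng: np.random.Generator):
        self.net = nn.Sequential(
            nn.Dense(latent_dim, latent_dim, rng), nn.LeakyReLU(slope),
            nn.Dense(latent_dim, 1, rng), nn.Sigmoid(),
        )

    def forward(self, emb):
        return self.net.forward(emb)

    def backward(self, cache, grad_out):
        return self.net.backward(cache, grad_out)

    def __call__(self, emb):
        return self.forward(emb)[0]

    def parameters(self):
        return self.net.parameters()


class ModelState:
    """All parameters and configuration of a trained (or initialized) model.

    ``sides`` maps the two role names ("r", "a") to modality kinds; the "a"
    role may be chromatin, protein, or a second transcriptome (perturbation
    models).
    """

    def __init__(self, cfg: ModelConfig, side_kinds: dict[str, str],
                 side_features: dict[str, int], seed: int,
                 chrom_index: ChromosomeIndex | None = None):
        self.cfg = cfg
        self.side_kinds = dict(side_kinds)
        self.side_features = dict(side_features)
        self.chrom_index = chrom_index
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.encoders = {}
        self.decoders = {}
        self.discriminators = {}
        for side in ("r", "a"):
            kind = self.side_kinds[side]
            nf = self.side_features[side]
            ci = chrom_index if kind == "atac" else None
            self.encoders[side] = make_encoder(kind, nf, cfg, rng, ci)
            self.decoders[side] = make_decoder(kind, nf, cfg, rng, ci)
            self.discriminators[side] = Discriminator(cfg.latent_dim, cfg.leaky_slope, rng)
        self.translator = Translator(("r", "a"), cfg.latent_dim, cfg.leaky_slope, rng)

    # --- parameter groupings -------------------------------------------------
    def generator_parameters(self):
        ps = []
        for side in ("r", "a"):
            ps += self.encoders[side].parameters()
            ps += self.decoders[side].parameters()
        ps += self.translator.parameters()
        return ps

    def discriminator_parameters(self):
        return (self.discriminators["r"].parameters()
                + self.discriminators["a"].parameters())

    def side_parameters(self, side: str):
        return (self.encoders[side].parameters()
                + self.translator.side_parameters(side)
                + self.decoders[side].parameters())

    def all_parameters(self):
        return self.generator_parameters() + self.discriminator_parameters()

    # --- serialization -------------------------------------------------------
    def _named_params(self):
        names = []
        for side in ("r", "a"):
            for tag, comp in (("en", self.encoders[side]), ("de", self.decoders[side]),
                              ("dis", self.discriminators[side])):
                for i, p in enumerate(comp.parameters()):
                    names.append((f"{tag}_{side}.{i}", p))
        for i, p in enumerate(self.translator.parameters()):
            names.append((f"trans.{i}", p))
        return names

    def save(self, path) -> None:
        """Serialize to a single .npz container (bit-exact round trip)."""
        arrays = {name: p.value for name, p in self._named_params()}
        meta = {
            "config": asdict(self.cfg),
            "side_kinds": self.side_kinds,
            "side_features": self.side_features,
            "seed": self.seed,
            "chrom_index": (self.chrom_index.to_dict()
                            if self.chrom_index is not None else None),
        }
        arrays["__meta__"] = np.frombuffer(
            json.dumps(meta).encode("utf-8"), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "ModelState":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"].tobytes()).decode("utf-8"))
            cfg_d = meta["config"]
            cfg_d["soft_label_pos"] = tuple(cfg_d["soft_label_pos"])
            cfg_d["soft_label_neg"] = tuple(cfg_d["soft_label_neg"])
            cfg = ModelConfig(**cfg_d)
            ci = (ChromosomeIndex.from_dict(meta["chrom_index"])
                  if meta["chrom_index"] is not None else None)
            state = cls(cfg, meta["side_kinds"], meta["side_features"],
                        meta["seed"], chrom_index=ci)
            for name, p in state._named_params():
                p.value[...] = data[name]
        return state

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        for name, p in self._named_params():
            h.update(name.encode())
            buf = _io.BytesIO()
            np.save(buf, p.value)
            h.update(buf.getvalue())
        return h.hexdigest()[:16]
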