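"""Loss functions and the two-phase optimization schedule.

Reduction convention for every loss: sum over features, mean over cells.
Pretraining fits each side's encoder, within-modality translator blocks and
decoder as a stand-alone VAE (reconstruction + KL); the integrative phase then
alternates, per mini-batch, a discriminator update (SGD) with a generator
update (Adam) over the four reconstruction/translation outputs, the two KL
terms, and the negated adversarial term.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .model import ModelConfig, ModelState

__all__ = [
    "loss_mse",
    "loss_bce",
    "loss_kl",
    "loss_discriminator",
    "TrainingLog",
    "pretrain_side",
    "train_integrative",
]

_EPS = 1e-7


def loss_mse(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean over cells of the squared Euclidean feature-space error."""
    diff = pred - target
    return float((diff * diff).sum() / pred.shape[0])


def _mse_grad(pred, target):
    return 2.0 * (pred - target) / pred.shape[0]


def loss_bce(pred: np.ndarray, target: np.ndarray) -> float:
    """Binary cross-entropy, feature-sum and cell-mean.

    Predictions are clamped to [1e-7, 1-1e-7] before the logs.
    """
    p = np.clip(pred, _EPS, 1.0 - _EPS)
    ll = target * np.log(p) + (1.0 - target) * np.log(1.0 - p)
    return float(-ll.sum() / pred.shape[0])


def _bce_grad(pred, target):
    p = np.clip(pred, _EPS, 1.0 - _EPS)
    return (p - target) / (p * (1.0 - p)) / pred.shape[0]


def loss_kl(mean: np.ndarray, logvar: np.ndarray) -> float:
    """KL divergence of N(mean, exp(logvar)) from N(0, I); dim-sum, cell-mean."""
    term = 1.0 + logvar - mean**2 - np.exp(logvar)
    return float(-0.5 * term.sum() / mean.shape[0])


def _kl_grads(mean, logvar):
    n = mean.shape[0]
    return mean / n, -0.5 * (1.0 - np.exp(logvar)) / n


def _draw_soft_labels(rng, n, lo, hi):
    return rng.uniform(lo, hi, size=(n, 1))


def _disc_forward(state: ModelState, native_r, trans_r, native_a, trans_a,
                  rng, cfg: ModelConfig):
    """Run both discriminators on native and translated embeddings with fresh
    soft labels; returns per-term probabilities, labels and caches."""
    pos_lo, pos_hi = cfg.soft_label_pos
    neg_lo, neg_hi = cfg.soft_label_neg
    terms = []
    for disc_side, emb, is_native in (
        ("a", trans_a, False), ("a", native_a, True),
        ("r", trans_r, False), ("r", native_r, True),
    ):
        lo, hi = (pos_lo, pos_hi) if is_native else (neg_lo, neg_hi)
        labels = _draw_soft_labels(rng, emb.shape[0], lo, hi)
        p, cache = state.discriminators[disc_side].forward(emb)
        terms.append({"side": disc_side, "emb": emb, "native": is_native,
                      "labels": labels, "p": p, "cache": cache})
    total = sum(loss_bce(t["p"], t["labels"]) for t in terms)
    return total, terms


def loss_discriminator(native_r, trans_r, native_a, trans_a,
                       state: ModelState, rng, cfg: ModelConfig) -> float:
    """Soft-label adversarial loss: four BCE terms (translated embeddings
    against labels drawn from U[0, 0.2], native ones against U[0.8, 1])."""
    total, _ = _disc_forward(state, native_r, trans_r, native_a, trans_a, rng, cfg)
    return total


@dataclass
class TrainingLog:
    """Per-epoch loss terms plus the early-stopping bookkeeping."""

    phase: str
    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1
    seed: int | None = None
    wall_seconds: list[float] = field(default_factory=list)

    def record(self, entry: dict, wall: float) -> None:
        self.epochs.append(entry)
        self.wall_seconds.append(wall)

    @property
    def val_losses(self):
        return [e["val_loss"] for e in self.epochs]

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.epochs)
        df["wall_seconds"] = self.wall_seconds
        return df

    def save(self, csv_path, json_path=None) -> None:
        """Per-epoch losses as CSV plus an optional JSON summary."""
        import json as _json

        self.to_dataframe().to_csv(csv_path, index=False)
        if json_path is not None:
            summary = {"phase": self.phase, "best_epoch": self.best_epoch,
                       "stopped_epoch": self.stopped_epoch, "seed": self.seed,
                       "best_val_loss": float(min(self.val_losses)),
                       "n_epochs": len(self.epochs)}
            with open(json_path, "w") as fh:
                _json.dump(summary, fh, indent=2)


def _split_validation(n: int, frac: float, rng) -> tuple[np.ndarray, np.ndarray]:
    perm = rng.permutation(n)
    n_val = max(1, int(round(frac * n)))
    if n_val >= n:
        raise ValueError(f"cannot hold out {n_val} of {n} samples for validation")
    return perm[n_val:], perm[:n_val]


def _recon_loss(kind: str):
    return loss_bce if kind == "atac" else loss_mse


def _recon_grad(kind: str):
    return _bce_grad if kind == "atac" else _mse_grad


def pretrain_side(state: ModelState, side: str, x: np.ndarray,
                  rng: np.random.Generator,
                  x_val: np.ndarray | None = None) -> TrainingLog:
    """Single-modality VAE pretraining of one side of the model.

    Trains the side's encoder, within-modality translator blocks, and decoder
    on reconstruction + KL, with early stopping on a held-out validation set
    (20% of the rows when ``x_val`` is not given) and best-epoch weight
    restoration.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("pretraining needs at least two cells")
    cfg = state.cfg
    kind = state.side_kinds[side]
    enc, dec, trans = state.encoders[side], state.decoders[side], state.translator
    rec_fn, rec_grad = _recon_loss(kind), _recon_grad(kind)
    w_kl = cfg.kl_weight(kind, x.shape[1])
    params = state.side_parameters(side)
    opt = nn.Adam(params, lr=cfg.lr_main)
    if x_val is None:
        train_idx, val_idx = _split_validation(x.shape[0], cfg.val_fraction, rng)
        x, x_val = x[np.sort(train_idx)], x[val_idx]
    train_idx = np.arange(x.shape[0])
    log = TrainingLog(phase=f"pretrain_{side}")
    best_val, best_params = np.inf, None
    for epoch in range(cfg.pretrain_epochs):
        t0 = time.perf_counter()
        order = rng.permutation(train_idx)
        rec_sum = kl_sum = 0.0
        n_batches = 0
        for start in range(0, len(order), cfg.batch_size):
            xb = x[order[start:start + cfg.batch_size]]
            if xb.shape[0] < 2:
                continue
            opt.zero_grad()
            h, ec = enc.forward(xb, training=True, rng=rng)
            mean, logvar, lc = trans.encode_latent(h, side)
            eps = rng.standard_normal(mean.shape)
            z = mean + np.exp(logvar / 2.0) * eps
            out, oc = trans.decode_latent(z, side)
            pred, dc = dec.forward(out, training=True, rng=rng)
            rec = rec_fn(pred, xb)
            kl = loss_kl(mean, logvar)
            g_out = dec.backward(dc, rec_grad(pred, xb))
            gz = trans.backward_out(side, oc, g_out)
            km, kv = _kl_grads(mean, logvar)
            g_mean = gz + w_kl * km
            g_logvar = gz * eps * 0.5 * np.exp(logvar / 2.0) + w_kl * kv
            gh = trans.backward_latent(side, lc, g_mean, g_logvar)
            enc.backward(ec, gh)
            opt.step()
            rec_sum += rec
            kl_sum += kl
            n_batches += 1
        val_loss = _pretrain_val_loss(state, side, x_val, rec_fn, w_kl)
        entry = {
            "epoch": epoch,
            "recon": rec_sum / max(n_batches, 1),
            "kl": kl_sum / max(n_batches, 1),
            "train_loss": (rec_sum + w_kl * kl_sum) / max(n_batches, 1),
            "val_loss": val_loss,
        }
        log.record(entry, time.perf_counter() - t0)
        if val_loss < best_val:
            best_val = val_loss
            log.best_epoch = epoch
            best_params = nn.snapshot(params)
        if epoch - log.best_epoch >= cfg.patience:
            break
    log.stopped_epoch = log.epochs[-1]["epoch"]
    if best_params is not None:
        nn.restore(params, best_params)
    return log


def _pretrain_val_loss(state, side, xv, rec_fn, w_kl) -> float:
    enc, dec, trans = state.encoders[side], state.decoders[side], state.translator
    h = enc(xv, training=False)
    mean, logvar, _ = trans.encode_latent(h, side)
    out, _ = trans.decode_latent(mean, side)  # mean path for a deterministic monitor
    pred = dec(out, training=False)
    return rec_fn(pred, xv) + w_kl * loss_kl(mean, logvar)


def _generator_step(state: ModelState, x_r, x_a, opt, rng, w_elbo):
    """One Adam update of encoders/translator/decoders on the full objective;
    discriminator parameters receive gradients but are never stepped here."""
    cfg = state.cfg
    enc_r, enc_a = state.encoders["r"], state.encoders["a"]
    dec_r, dec_a = state.decoders["r"], state.decoders["a"]
    trans = state.translator
    kind_r, kind_a = state.side_kinds["r"], state.side_kinds["a"]
    opt.zero_grad()

    # forward, both sides
    fwd = {}
    for side, xb, enc in (("r", x_r, enc_r), ("a", x_a, enc_a)):
        h, ec = enc.forward(xb, training=True, rng=rng)
        mean, logvar, lc = trans.encode_latent(h, side)
        eps = rng.standard_normal(mean.shape)
        z = mean + np.exp(logvar / 2.0) * eps
        fwd[side] = dict(x=xb, h=h, ec=ec, mean=mean, logvar=logvar, lc=lc,
                         eps=eps, z=z)
    outs = {}
    for src in ("r", "a"):
        for tgt in ("r", "a"):
            o, oc = trans.decode_latent(fwd[src]["z"], tgt)
            outs[(src, tgt)] = {"emb": o, "cache": oc}
    preds = {}
    for (src, tgt), o in outs.items():
        dec = dec_r if tgt == "r" else dec_a
        p, dc = dec.forward(o["emb"], training=True, rng=rng)
        preds[(src, tgt)] = {"pred": p, "cache": dc}

    rg_r, rg_a = _recon_grad(kind_r), _recon_grad(kind_a)
    rf_r, rf_a = _recon_loss(kind_r), _recon_loss(kind_a)
    rec_r = rf_r(preds[("r", "r")]["pred"], x_r) + rf_r(preds[("a", "r")]["pred"], x_r)
    rec_a = rf_a(preds[("a", "a")]["pred"], x_a) + rf_a(preds[("r", "a")]["pred"], x_a)
    kl_r = loss_kl(fwd["r"]["mean"], fwd["r"]["logvar"])
    kl_a = loss_kl(fwd["a"]["mean"], fwd["a"]["logvar"])
    disc_total, disc_terms = _disc_forward(
        state, fwd["r"]["h"], outs[("a", "r")]["emb"],
        fwd["a"]["h"], outs[("r", "a")]["emb"], rng, cfg)

    # backward: reconstruction/translation paths
    g_emb = {}
    for (src, tgt), p in preds.items():
        w = cfg.w_r if tgt == "r" else cfg.w_a
        rg = rg_r if tgt == "r" else rg_a
        dec = dec_r if tgt == "r" else dec_a
        xb = x_r if tgt == "r" else x_a
        g_emb[(src, tgt)] = dec.backward(p["cache"], w * rg(p["pred"], xb))

    # adversarial term: gradient w.r.t. embeddings through frozen discriminators,
    # entering the generator objective with weight -w_dis
    g_h_disc = {"r": 0.0, "a": 0.0}
    for t in disc_terms:
        g_p = -cfg.w_dis * _bce_grad(t["p"], t["labels"])
        g_in = state.discriminators[t["side"]].backward(t["cache"], g_p)
        if t["native"]:
            g_h_disc[t["side"]] = g_h_disc[t["side"]] + g_in
        else:
            # translated embedding of side t["side"]: produced by output block
            src = "r" if t["side"] == "a" else "a"
            g_emb[(src, t["side"])] = g_emb[(src, t["side"])] + g_in

    for src in ("r", "a"):
        gz = np.zeros_like(fwd[src]["z"])
        for tgt in ("r", "a"):
            gz += trans.backward_out(tgt, outs[(src, tgt)]["cache"], g_emb[(src, tgt)])
        mean, logvar, eps = fwd[src]["mean"], fwd[src]["logvar"], fwd[src]["eps"]
        km, kv = _kl_grads(mean, logvar)
        g_mean = gz + w_elbo * km
        g_logvar = gz * eps * 0.5 * np.exp(logvar / 2.0) + w_elbo * kv
        gh = trans.backward_latent(src, fwd[src]["lc"], g_mean, g_logvar)
        gh = gh + g_h_disc[src]
        enc = enc_r if src == "r" else enc_a
        enc.backward(fwd[src]["ec"], gh)

    opt.step()
    total = (cfg.w_r * rec_r + cfg.w_a * rec_a + w_elbo * (kl_r + kl_a)
             - cfg.w_dis * disc_total)
    return {"recon_r": rec_r, "recon_a": rec_a, "kl_r": kl_r, "kl_a": kl_a,
            "disc": disc_total, "total": total}


def _discriminator_step(state: ModelState, x_r, x_a, opt, rng):
    """One SGD update of both discriminators on the soft-label loss."""
    trans = state.translator
    opt.zero_grad()
    embs = {}
    for side, xb in (("r", x_r), ("a", x_a)):
        h = state.encoders[side](xb, training=True, rng=rng)
        lb = trans.translate(h, side, "a" if side == "r" else "r",
                             sample=True, rng=rng)
        embs[side] = {"native": h, "translated_to_other": lb.embedding}
    total, terms = _disc_forward(
        state,
        embs["r"]["native"], embs["a"]["translated_to_other"],
        embs["a"]["native"], embs["r"]["translated_to_other"],
        rng, state.cfg)
    for t in terms:
        g_p = _bce_grad(t["p"], t["labels"])
        state.discriminators[t["side"]].backward(t["cache"], g_p)
    opt.step()
    return total


def _integrative_val_loss(state: ModelState, x_r, x_a, w_elbo) -> float:
    """Deterministic validation monitor: reconstruction/translation + KL on
    the mean path (the adversarial term is excluded from the monitor)."""
    cfg = state.cfg
    trans = state.translator
    rf = {"r": _recon_loss(state.side_kinds["r"]), "a": _recon_loss(state.side_kinds["a"])}
    total = 0.0
    for src, xb in (("r", x_r), ("a", x_a)):
        h = state.encoders[src](xb, training=False)
        mean, logvar, _ = trans.encode_latent(h, src)
        total += w_elbo * loss_kl(mean, logvar)
        for tgt, xt in (("r", x_r), ("a", x_a)):
            out, _ = trans.decode_latent(mean, tgt)
            dec = state.decoders[tgt]
            pred = dec(out, training=False)
            w = cfg.w_r if tgt == "r" else cfg.w_a
            total += w * rf[tgt](pred, xt)
    return total


def train_integrative(state: ModelState, x_r: np.ndarray, x_a: np.ndarray,
                      rng: np.random.Generator,
                      val_r: np.ndarray | None = None,
                      val_a: np.ndarray | None = None) -> TrainingLog:
    """Adversarial integrative training on row-aligned paired matrices.

    ``x_r[i]`` and ``x_a[i]`` must describe the same (possibly augmented)
    training pair.  Per mini-batch the discriminators are updated first by
    SGD, then the encoders/translator/decoders by Adam on the combined
    objective with the re-evaluated adversarial term.  Early stopping
    monitors the held-out pairs (``val_r``/``val_a`` when given, else a 20%
    row split) on the deterministic mean path.
    """
    x_r = np.asarray(x_r, dtype=np.float64)
    x_a = np.asarray(x_a, dtype=np.float64)
    if x_r.shape[0] != x_a.shape[0]:
        raise ValueError("paired matrices must have the same number of rows")
    cfg = state.cfg
    if x_r.shape[1] != state.side_features["r"] or x_a.shape[1] != state.side_features["a"]:
        raise ValueError("matrix widths do not match the model's side features")
    w_elbo = (cfg.kl_weight(state.side_kinds["r"], x_r.shape[1])
              + cfg.kl_weight(state.side_kinds["a"], x_a.shape[1]))
    gen_opt = nn.Adam(state.generator_parameters(), lr=cfg.lr_main)
    dis_opt = nn.SGD(state.discriminator_parameters(), lr=cfg.lr_disc)
    if val_r is None:
        train_idx, val_idx = _split_validation(x_r.shape[0], cfg.val_fraction, rng)
        val_r, val_a = x_r[val_idx], x_a[val_idx]
        x_r, x_a = x_r[np.sort(train_idx)], x_a[np.sort(train_idx)]
    train_idx = np.arange(x_r.shape[0])
    log = TrainingLog(phase="integrative")
    best_val, best_params = np.inf, None
    all_params = state.all_parameters()
    for epoch in range(cfg.train_epochs):
        t0 = time.perf_counter()
        order = rng.permutation(train_idx)
        sums = {"recon_r": 0.0, "recon_a": 0.0, "kl_r": 0.0, "kl_a": 0.0,
                "disc": 0.0, "total": 0.0}
        n_batches = 0
        for start in range(0, len(order), cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            if len(sel) < 2:
                continue
            xb_r, xb_a = x_r[sel], x_a[sel]
            _discriminator_step(state, xb_r, xb_a, dis_opt, rng)
            terms = _generator_step(state, xb_r, xb_a, gen_opt, rng, w_elbo)
            for k in sums:
                sums[k] += terms[k]
            n_batches += 1
        entry = {k: v / max(n_batches, 1) for k, v in sums.items()}
        entry["epoch"] = epoch
        entry["val_loss"] = _integrative_val_loss(state, val_r, val_a, w_elbo)
        log.record(entry, time.perf_counter() - t0)
        if entry["val_loss"] < best_val:
            best_val = entry["val_loss"]
            log.best_epoch = epoch
            best_params = nn.snapshot(all_params)
        if epoch - log.best_epoch >= cfg.patience:
            break
    log.stopped_epoch = log.epochs[-1]["epoch"]
    if best_params is not None:
        nn.restore(all_params, best_params)
    return log
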