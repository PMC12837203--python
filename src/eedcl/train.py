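"""Contrastive pretraining and supervised fine-tuning.

Pretraining minimizes the InfoNCE loss over augmented pairs: cosine
similarity of L2-normalized projections, softmax over one positive and K
negatives at temperature τ.  Fine-tuning minimizes a class-weighted
cross-entropy, with the representation stack either frozen or trained at a
reduced learning rate to preserve the pretrained features.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .augment import AugmentConfig, ContrastiveBatch, make_pairs
from .model import EEDModel
from .nn import AdamW, Tensor, as_tensor, concat
from .types import Segment, segments_to_batch


@dataclass
class ContrastiveConfig:
    tau: float = 0.1
    epochs: int = 50
    batch_size: int = 64
    lr: float = 1e-4
    weight_decay: float = 0.01
    pair_mode: str = "class_conditioned"
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    seed: int = 0

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class FinetuneConfig:
    freeze_policy: str = "reduced_lr"   # none | freeze_encoder | reduced_lr
    encoder_lr_scale: float = 0.1
    class_weights: list[float] | None = None   # default: N / (n_classes * N_c)
    epochs: int = 50
    batch_size: int = 64
    lr: float = 1e-3
    weight_decay: float = 0.01
    label_fraction: float = 1.0
    augment: AugmentConfig | None = None       # per-batch training augmentation
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.encoder_lr_scale <= 1:
            raise ValueError("encoder_lr_scale must be in (0, 1]")
        if not 0 < self.label_fraction <= 1:
            raise ValueError("label_fraction must be in (0, 1]")
        if self.freeze_policy not in ("none", "freeze_encoder", "reduced_lr"):
            raise ValueError(f"unknown freeze policy {self.freeze_policy!r}")


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _ensure_unit(z: Tensor, name: str) -> Tensor:
    norms = np.linalg.norm(z.data, axis=-1)
    if not np.allclose(norms, 1.0, atol=1e-4):
        warnings.warn(f"{name} not unit-norm; normalizing internally")
        n = ((z * z).sum(axis=-1, keepdims=True) + 1e-12) ** 0.5
        z = z / n
    return z


def info_nce(z_i, z_pos, z_negs, tau: float = 0.1) -> Tensor:
    """InfoNCE for one anchor: −log σ-softmax of the positive similarity
    against K negative similarities at temperature ``tau``.

    ``z_negs`` may be empty (K = 0), in which case the loss is exactly 0.
    """
    def wrap(z):
        return z if isinstance(z, Tensor) else Tensor(
            np.asarray(z, dtype=np.float64))

    z_i = _ensure_unit(wrap(z_i), "anchor")
    z_pos = _ensure_unit(wrap(z_pos), "positive")
    pos = (z_i * z_pos).sum() * (1.0 / tau)
    z_negs = [wrap(z) for z in z_negs]
    if not z_negs:
        return pos * 0.0
    terms = [pos]
    for z in z_negs:
        z = _ensure_unit(z, "negative")
        terms.append((z_i * z).sum() * (1.0 / tau))
    logits = concat([t.reshape(1) for t in terms], axis=0)
    shift = Tensor(logits.data.max())
    lse = ((logits - shift).exp().sum()).log() + shift
    return lse - pos


def info_nce_batch(z_a: Tensor, z_p: Tensor, neg_mask: np.ndarray,
                   tau: float) -> Tensor:
    """Mean InfoNCE over a batch with in-batch negatives.

    Candidate columns are [positives | anchors]; ``neg_mask`` (B, 2B) marks
    which candidates count as negatives for each anchor row.
    """
    cand = concat([z_p, z_a], axis=0)             # (2B, d)
    sims = (z_a @ cand.transpose(1, 0)) * (1.0 / tau)   # (B, 2B)
    b = z_a.shape[0]
    pos = (z_a * z_p).sum(axis=-1) * (1.0 / tau)  # (B,)
    shift = Tensor(np.maximum(sims.data.max(axis=1), pos.data))
    exp_neg = ((sims - shift.reshape(b, 1)).exp()
               * Tensor(neg_mask.astype(sims.dtype))).sum(axis=1)
    exp_pos = (pos - shift).exp()
    loss = -((exp_pos / (exp_pos + exp_neg)).log())
    return loss.mean()


def weighted_ce(probs: Tensor, labels: np.ndarray, weights: np.ndarray,
                normalize: bool = True) -> Tensor:
    """Class-weighted cross-entropy on probability rows.

    Per sample: −w_label · log(p_label), with p clamped at 1e-12; the batch
    loss is the weight-normalized mean (so uniform weights reduce to plain
    cross-entropy).
    """
    probs = as_tensor(probs)
    labels = np.asarray(labels, dtype=int)
    weights = np.asarray(weights, dtype=np.float64)
    b = probs.shape[0]
    clamped = probs + Tensor(np.where(probs.data < 1e-12, 1e-12, 0.0))
    picked = clamped[np.arange(b), labels]
    w = Tensor(weights[labels].astype(probs.dtype))
    loss = -(w * picked.log()).sum()
    denom = weights[labels].sum() if normalize else float(b)
    return loss * (1.0 / denom)


def default_class_weights(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Inverse-frequency weights N / (n_classes · N_c)."""
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels, minlength=n_classes).astype(np.float64)
    if (counts == 0).any():
        raise ValueError(
            f"classes {np.flatnonzero(counts == 0).tolist()} have no samples; "
            "reduce n_classes or supply more data")
    return labels.size / (n_classes * counts)


# ---------------------------------------------------------------------------
# training loops
# ---------------------------------------------------------------------------

def _neg_mask(batch: ContrastiveBatch) -> np.ndarray:
    """In-batch negative mask from pair constraints (B anchors, 2B candidates)."""
    b = len(batch.anchors)
    mask = np.zeros((b, 2 * b), dtype=bool)
    for i, anchor in enumerate(batch.anchors):
        for j, cand in enumerate(batch.positives + batch.anchors):
            col = j
            if batch.pair_mode == "class_conditioned":
                ok = cand.class_label != anchor.class_label
            else:
                ok = not (cand.subject_id == anchor.subject_id
                          and cand.trial_id == anchor.trial_id
                          and cand.t_start == anchor.t_start)
            if ok:
                mask[i, col] = True
    return mask


def pretrain(segments: list[Segment], model: EEDModel,
             ccfg: ContrastiveConfig) -> list[float]:
    """Contrastive pretraining; returns the per-epoch mean loss curve."""
    if not segments:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(ccfg.seed)
    opt = AdamW(model.parameters(), lr=ccfg.lr, weight_decay=ccfg.weight_decay)
    curve: list[float] = []
    model.train()
    for _epoch in range(ccfg.epochs):
        order = rng.permutation(len(segments))
        losses = []
        for start in range(0, len(order), ccfg.batch_size):
            idx = order[start:start + ccfg.batch_size]
            if idx.size < 2:
                continue
            batch = make_pairs([segments[i] for i in idx], ccfg.pair_mode,
                               ccfg.augment, rng)
            if len(batch.anchors) < 2:
                continue
            xa = segments_to_batch(batch.anchors)
            xp = segments_to_batch(batch.positives)
            z = model.project(np.concatenate([xa, xp]))
            b = xa.shape[0]
            loss = info_nce_batch(z[:b], z[b:], _neg_mask(batch), ccfg.tau)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        curve.append(float(np.mean(losses)) if losses else float("nan"))
    return curve


def subsample_labels(segments: list[Segment], fraction: float,
                     rng: np.random.Generator) -> list[Segment]:
    """Stratified subsampling by (subject, class); keeps round(frac·n) per
    stratum (at least one)."""
    if fraction >= 1.0:
        return list(segments)
    groups: dict[tuple, list[int]] = {}
    for i, s in enumerate(segments):
        groups.setdefault((s.subject_id, s.class_label), []).append(i)
    keep: list[int] = []
    for key in sorted(groups, key=str):
        idx = np.array(groups[key])
        n_keep = max(1, int(round(fraction * idx.size)))
        keep.extend(rng.permutation(idx)[:n_keep].tolist())
    kept = [segments[i] for i in sorted(keep)]
    classes = {s.class_label for s in segments}
    if {s.class_label for s in kept} != classes:
        raise ValueError(
            "a class vanished after label subsampling; increase "
            "label_fraction or trials per class")
    return kept


def finetune(model: EEDModel, segments: list[Segment],
             fcfg: FinetuneConfig,
             parents: dict | None = None) -> list[dict]:
    """Supervised fine-tuning; returns a per-epoch training log.

    ``parents`` maps trial_id to the preprocessed parent recording and
    enables window-shift augmentation when ``fcfg.augment`` is set.
    """
    if any(s.class_label is None for s in segments):
        raise ValueError("fine-tuning requires labelled segments")
    rng = np.random.default_rng(fcfg.seed)
    segments = subsample_labels(segments, fcfg.label_fraction, rng)
    labels_all = np.array([s.class_label for s in segments])
    n_classes = model.cfg.head.n_classes
    if fcfg.class_weights is not None:
        weights = np.asarray(fcfg.class_weights, dtype=np.float64)
    else:
        weights = default_class_weights(labels_all, n_classes)

    enc_params = model.encoder_parameters()
    cls_params = model.classifier_parameters()
    if fcfg.freeze_policy == "freeze_encoder":
        opt = AdamW(cls_params, lr=fcfg.lr, weight_decay=fcfg.weight_decay)
    elif fcfg.freeze_policy == "reduced_lr":
        opt = AdamW(cls_params, lr=fcfg.lr, weight_decay=fcfg.weight_decay)
        opt.add_group(enc_params, lr=fcfg.lr * fcfg.encoder_lr_scale,
                      weight_decay=fcfg.weight_decay)
    else:
        opt = AdamW(model.parameters(), lr=fcfg.lr,
                    weight_decay=fcfg.weight_decay)

    from .augment import augment_view
    from .nn import softmax

    log: list[dict] = []
    model.train()
    for epoch in range(fcfg.epochs):
        order = rng.permutation(len(segments))
        losses = []
        for start in range(0, len(order), fcfg.batch_size):
            idx = order[start:start + fcfg.batch_size]
            batch = [segments[i] for i in idx]
            if fcfg.augment is not None:
                batch = [augment_view(
                    s, fcfg.augment, rng,
                    parent=parents.get(s.trial_id) if parents else None)
                    for s in batch]
            x = segments_to_batch(batch)
            y = labels_all[idx]
            probs = softmax(model.logits(x), axis=-1)
            loss = weighted_ce(probs, y, weights)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        log.append({"epoch": epoch, "loss": float(np.mean(losses)),
                    "lr": fcfg.lr})
    model.eval()
    return log


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: EEDModel, path: str | Path, seed: int = 0,
                    config_hash: str = "") -> Path:
    """Single-file checkpoint: weights + config hash + seed."""
    path = Path(path)
    state = model.state_dict()
    meta = {"config_hash": config_hash, "seed": seed,
            "variant": model.cfg.variant}
    np.savez(path, __meta__=json.dumps(meta), **state)
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_checkpoint(model: EEDModel, path: str | Path) -> dict:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        state = {k: data[k] for k in data.files if k != "__meta__"}
    model.load_state_dict(state)
    return meta
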