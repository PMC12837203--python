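"""Desk-scale synthetic benchmarks: the study conditions, training recipe,
and end-to-end protocols used by the self-tests and the acceptance script.

Conditions (fixed once; the methods note discusses the choices):

* recordings: 8 channels at 64 Hz, 12 s per trial — small enough for CPU
  training, long enough for five 4-s windows at 50 % overlap;
* preprocessing: 4–28 Hz band (the 64 Hz rate caps the upper edge below
  the usual 47 Hz), common-average reference, z-score, 4 s / 50 % windows;
* model: the reduced-width configuration of :func:`eedcl.model.desk_config`
  with band-pass temporal-filter initialization;
* fine-tuning: AdamW, the full augmentation suite per batch (window shift,
  time warp, σ = 0.2 noise), trial-level prediction by window-probability
  averaging.

A trial's windows never straddle a train/test split.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .augment import AugmentConfig
from .encoder import bandpass_filter_init
from .evalharness import predict_segments
from .model import EEDModel, ModelConfig, desk_config
from .preprocess import PreprocessConfig, bandpass, rereference, zscore, segment
from .synthio import GeneratorConfig, generate_dataset
from .train import (ContrastiveConfig, FinetuneConfig, finetune, pretrain,
                    save_checkpoint, load_checkpoint)
from .types import Recording, Segment


def desk_generator_config(**overrides) -> GeneratorConfig:
    base = dict(n_subjects=3, n_classes=2, trials_per_class=40, n_channels=8,
                duration_s=12.0, fs=64.0, class_effect=2.0, seed=0)
    base.update(overrides)
    return GeneratorConfig(**base)


def desk_preprocess_config() -> PreprocessConfig:
    return PreprocessConfig(low_hz=4.0, high_hz=28.0)


def desk_augment_config() -> AugmentConfig:
    return AugmentConfig(noise_sigma=0.2, warp_max=0.1,
                         shift_overlap=(0.3, 0.5))


def desk_finetune_config(seed: int = 0, epochs: int = 35,
                         lr: float = 5e-3) -> FinetuneConfig:
    return FinetuneConfig(epochs=epochs, batch_size=64, lr=lr,
                          freeze_policy="none", augment=desk_augment_config(),
                          seed=seed)


@dataclass
class TrialData:
    """Preprocessed trials: windows, parents, and labels, keyed by trial."""

    windows: dict[str, list[Segment]]
    parents: dict[str, Recording]
    labels: dict[str, int]
    trial_ids: list[str]

    def segments_of(self, trials) -> list[Segment]:
        return [w for t in trials for w in self.windows[t]]


def prepare_trials(gcfg: GeneratorConfig,
                   pcfg: PreprocessConfig | None = None) -> TrialData:
    pcfg = pcfg or desk_preprocess_config()
    windows, parents, labels = {}, {}, {}
    order = []
    for rec in generate_dataset(gcfg):
        clean = zscore(rereference(bandpass(rec, pcfg.low_hz, pcfg.high_hz,
                                            pcfg.order)))
        windows[rec.trial_id] = segment(clean, pcfg.win_s, pcfg.overlap)
        parents[rec.trial_id] = clean
        labels[rec.trial_id] = rec.class_label
        order.append(rec.trial_id)
    return TrialData(windows=windows, parents=parents, labels=labels,
                     trial_ids=order)


def make_desk_model(seed: int, gcfg: GeneratorConfig,
                    cfg: ModelConfig | None = None,
                    variant: str = "full") -> EEDModel:
    cfg = cfg or desk_config(n_channels=gcfg.n_channels,
                             n_classes=gcfg.n_classes)
    if variant != cfg.variant:
        cfg = replace(cfg, variant=variant)
    model = EEDModel(cfg, seed)
    if hasattr(model.encoder, "dw_temporal") or hasattr(model.encoder,
                                                        "temporal"):
        bandpass_filter_init(model.encoder, gcfg.fs,
                             np.random.default_rng(seed + 7919))
    return model


def trial_accuracy(model: EEDModel, data: TrialData,
                   trials: list[str]) -> float:
    """Window-probability-averaged (sliding-window) accuracy over trials."""
    segs = data.segments_of(trials)
    probs = predict_segments(model, segs)
    correct = 0
    pos = 0
    for t in trials:
        n = len(data.windows[t])
        p = probs[pos:pos + n].mean(axis=0)
        correct += int(np.argmax(p) == data.labels[t])
        pos += n
    return correct / len(trials)


def endtoend_crossval(gcfg: GeneratorConfig | None = None, seeds=(0, 1, 2),
                      n_folds: int = 5, epochs: int = 35,
                      variant: str = "full") -> dict:
    """Trial-grouped k-fold accuracy of the fully fine-tuned model,
    averaged over training seeds (the end-to-end synthetic check)."""
    gcfg = gcfg or desk_generator_config()
    data = prepare_trials(gcfg)
    trials = np.array(data.trial_ids)
    per_seed = []
    per_fold_all = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(trials))
        folds = np.array_split(order, n_folds)
        fold_accs = []
        for k, te_idx in enumerate(folds):
            te_t = [trials[i] for i in te_idx]
            tr_t = [t for t in trials if t not in set(te_t)]
            model = make_desk_model(seed * 100 + k, gcfg, variant=variant)
            fcfg = desk_finetune_config(seed=seed * 100 + k, epochs=epochs)
            finetune(model, data.segments_of(tr_t), fcfg,
                     parents=data.parents)
            fold_accs.append(trial_accuracy(model, data, te_t))
        per_seed.append(float(np.mean(fold_accs)))
        per_fold_all.extend(fold_accs)
    return {"accuracy_pct": 100.0 * float(np.mean(per_seed)),
            "per_seed_pct": [100.0 * a for a in per_seed],
            "per_fold_pct": [100.0 * a for a in per_fold_all],
            "n_folds": n_folds, "epochs": epochs,
            "n_trials": len(trials)}


def label_efficiency_run(seeds=(0, 1, 2), label_fraction: float = 0.25,
                         gcfg: GeneratorConfig | None = None,
                         pretrain_epochs: int = 8,
                         finetune_epochs: int = 20) -> dict:
    """Contrastive pretraining vs. training from scratch at a reduced label
    budget (the scaled-down label-ratio comparison).

    Moderate difficulty: class_effect 1.6, five subjects.  Pretraining is
    self-supervised (augmentation positives, no labels) on every training
    window; both arms then fine-tune on the same labelled trial subset and
    are scored by trial-averaged accuracy on held-out trials.
    """
    gcfg = gcfg or desk_generator_config(n_subjects=5, trials_per_class=12,
                                         class_effect=1.6)
    data = prepare_trials(gcfg)
    trials = np.array(data.trial_ids)
    label_of = data.labels
    acc_pre, acc_scratch = [], []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(trials))
        n_test = len(trials) // 3          # larger test split: finer accuracy
        te_t = [trials[i] for i in order[:n_test]]
        tr_t = [trials[i] for i in order[n_test:]]
        # stratified trial-level label subset
        keep = []
        for subj in sorted({t.split("_")[0] for t in tr_t}):
            for cls in range(gcfg.n_classes):
                grp = [t for t in tr_t
                       if t.startswith(subj) and label_of[t] == cls]
                n_keep = max(1, int(round(label_fraction * len(grp))))
                keep.extend(list(rng.permutation(grp))[:n_keep])
        labelled = data.segments_of(keep)

        # arm 1: contrastive pretraining on all training windows (no labels)
        model_pre = make_desk_model(seed, gcfg)
        ccfg = ContrastiveConfig(epochs=pretrain_epochs, batch_size=64,
                                 lr=1e-3, pair_mode="self_supervised",
                                 augment=desk_augment_config(), seed=seed)
        pretrain(data.segments_of(tr_t), model_pre, ccfg)
        fcfg = desk_finetune_config(seed=seed, epochs=finetune_epochs,
                                    lr=3e-3)
        fcfg = replace(fcfg, freeze_policy="reduced_lr")
        finetune(model_pre, labelled, fcfg, parents=data.parents)
        acc_pre.append(trial_accuracy(model_pre, data, te_t))

        # arm 2: identical fine-tuning from a fresh model
        model_raw = make_desk_model(seed, gcfg)
        fcfg2 = desk_finetune_config(seed=seed, epochs=finetune_epochs,
                                     lr=3e-3)
        finetune(model_raw, labelled, fcfg2, parents=data.parents)
        acc_scratch.append(trial_accuracy(model_raw, data, te_t))
    return {
        "pretrain_finetune_pct": 100.0 * float(np.mean(acc_pre)),
        "finetune_only_pct": 100.0 * float(np.mean(acc_scratch)),
        "per_seed_pretrain_pct": [100.0 * a for a in acc_pre],
        "per_seed_scratch_pct": [100.0 * a for a in acc_scratch],
        "label_fraction": label_fraction,
    }
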