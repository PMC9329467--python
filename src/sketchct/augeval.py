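"""Data-augmentation evaluation: does pretraining a histology classifier
on generated images improve accuracy on real images?

The protocol mirrors the augmentation study: a batch of images is
generated from the edge images of held-out tumors (one per edge for the
baseline model, several latents per edge for the style model); a small
CNN classifier is pretrained on the generated images (all layers), then
only its fully connected layers are fine-tuned on real images; accuracy
is reported as mean +/- sd over repeated stratified k-fold
cross-validation (three repeats of three folds by default).  Fold
splitting is stratified by class at tumor (VOI) granularity so that no
slice of a test tumor can leak into its training folds.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._nn import (SGD, Conv2d, Linear, Module, Tensor, no_grad, relu,
                  softmax_cross_entropy)
from .networks import ModelBundle, generate
from .phantoms import CLASS_LABELS

__all__ = [
    "SplitPlan", "ClassifierConfig", "SmallCNNClassifier", "CVResult",
    "generate_augmented_set", "pretrain_then_finetune", "cross_validate",
    "make_folds", "run_augmentation_study",
]


@dataclass(frozen=True)
class SplitPlan:
    """Per-class sample budget for the three experiment roles.

    Defaults follow the study's split: 26 tumors per class for the
    classification task, 10 per class as generation-test (their edges
    drive augmentation), the rest as generation-training material.
    """

    class_labels: tuple = CLASS_LABELS
    n_classification_per_class: int = 26
    n_generation_test_per_class: int = 10
    n_folds: int = 3
    n_repeats: int = 3


@dataclass(frozen=True)
class ClassifierConfig:
    """SGD settings for pretraining (all layers, on generated images) and
    fine-tuning (fully connected layers only, on real images)."""

    pretrain_lr: float = 1e-5
    pretrain_epochs: int = 100
    pretrain_batch: int = 32
    finetune_lr: float = 1e-4
    finetune_epochs: int = 100
    finetune_batch: int = 8

    def __post_init__(self):
        for name in ("pretrain_lr", "pretrain_batch",
                     "finetune_lr", "finetune_epochs", "finetune_batch"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        # pretrain_epochs = 0 is the documented fine-tune-only limit
        if self.pretrain_epochs < 0:
            raise ValueError("pretrain_epochs must be >= 0")


class SmallCNNClassifier(Module):
    """Compact AlexNet-like classifier: three stride-2 convolution stages
    followed by two fully connected layers."""

    def __init__(self, image_size=32, n_classes=3, seed=0):
        if image_size % 8 != 0:
            raise ValueError("image_size must be divisible by 8")
        rng = np.random.default_rng(seed)
        self.conv1 = Conv2d(1, 8, 3, 2, 1, rng, w_std=0.1)
        self.conv2 = Conv2d(8, 16, 3, 2, 1, rng, w_std=0.1)
        self.conv3 = Conv2d(16, 32, 3, 2, 1, rng, w_std=0.1)
        s = image_size // 8
        self.fc1 = Linear(32 * s * s, 64, rng)
        self.fc2 = Linear(64, n_classes, rng)
        self.image_size = image_size

    def forward(self, x):
        h = x if isinstance(x, Tensor) else Tensor(x)
        h = relu(self.conv1(h))
        h = relu(self.conv2(h))
        h = relu(self.conv3(h))
        h = h.reshape(h.shape[0], -1)
        h = relu(self.fc1(h))
        return self.fc2(h)

    def conv_parameters(self):
        return (self.conv1.parameters() + self.conv2.parameters()
                + self.conv3.parameters())

    def fc_parameters(self):
        return self.fc1.parameters() + self.fc2.parameters()

    def conv_hash(self):
        """Digest of the convolutional weights (freezing contract check)."""
        h = hashlib.sha256()
        for p in self.conv_parameters():
            h.update(np.ascontiguousarray(p.data).tobytes())
        return h.hexdigest()

    def predict(self, images):
        with no_grad():
            logits = self.forward(_prep_images(images)).data
        return logits.argmax(axis=1)


# ---------------------------------------------------------------------------
# Generation for augmentation

def generate_augmented_set(bundle: ModelBundle, edges_by_class,
                           n_per_edge: int, seed: int = 0):
    """Per class: ``n_edges * n_per_edge`` generated images.

    The baseline model is one-to-one, so ``n_per_edge > 1`` would only
    duplicate images; a warning is raised and one image per edge is kept
    (the documented deduplicated count).  The style model draws fresh
    latents for every image.  Returns ``{label: [images in [-1, 1]]}``.
    """
    if n_per_edge < 1:
        raise ValueError("n_per_edge must be >= 1")
    if not bundle.use_style and n_per_edge > 1:
        warnings.warn("baseline generator is one-to-one; generating a "
                      "single image per edge instead of duplicates")
        n_per_edge = 1
    rng = np.random.default_rng(seed)
    out = {}
    for label, edges in edges_by_class.items():
        images = []
        for edge in edges:
            images.extend(generate(bundle, edge, n=n_per_edge,
                                   seed=int(rng.integers(2 ** 31 - 1))))
        out[label] = images
    return out


# ---------------------------------------------------------------------------
# Classifier training

def _prep_images(images):
    arr = np.stack([np.asarray(im, dtype=np.float32) for im in images])
    if arr.ndim == 4:          # RGB -> single channel
        arr = arr.mean(axis=-1)
    if arr.max() > 1.5:        # 8-bit -> [-1, 1]
        arr = arr / 127.5 - 1.0
    return arr[:, None]


def _labels_to_int(labels, class_labels=CLASS_LABELS):
    lut = {lab: i for i, lab in enumerate(class_labels)}
    return np.array([lut[l] for l in labels], dtype=int)


def _sgd_epochs(clf, params, images, labels, lr, epochs, batch, rng):
    opt = SGD(params, lr=lr)
    n = images.shape[0]
    losses = []
    for _ in range(epochs):
        order = rng.permutation(n)
        ep_loss, nb = 0.0, 0
        for k in range(0, n, batch):
            idx = order[k:k + batch]
            opt.zero_grad()
            loss = softmax_cross_entropy(clf(Tensor(images[idx])),
                                         labels[idx])
            loss.backward()
            opt.step()
            ep_loss += loss.item()
            nb += 1
        losses.append(ep_loss / nb)
    return losses


def pretrain_then_finetune(generated_set, real_set, config: ClassifierConfig,
                           seed: int = 0, image_size: int = 32):
    """Pretrain all layers on generated images, then fine-tune only the
    fully connected layers on real images (convolutional weights frozen).

    Both sets are lists of ``(image, label)``; all three classes must be
    present in each.  Returns ``(classifier, history_dict)``; the history
    carries per-epoch losses and the pre/post fine-tune hash of the frozen
    convolutional weights.
    """
    for name, s in (("generated", generated_set), ("real", real_set)):
        present = {lab for _, lab in s}
        if set(CLASS_LABELS) - present:
            raise ValueError(f"{name} set is missing classes "
                             f"{set(CLASS_LABELS) - present}")
    rng = np.random.default_rng(seed)
    clf = SmallCNNClassifier(image_size=image_size, seed=seed)

    g_imgs = _prep_images([im for im, _ in generated_set])
    g_labels = _labels_to_int([lab for _, lab in generated_set])
    pre_losses = _sgd_epochs(clf, clf.parameters(), g_imgs, g_labels,
                             config.pretrain_lr, config.pretrain_epochs,
                             config.pretrain_batch, rng)

    frozen_before = clf.conv_hash()
    r_imgs = _prep_images([im for im, _ in real_set])
    r_labels = _labels_to_int([lab for _, lab in real_set])
    ft_losses = _sgd_epochs(clf, clf.fc_parameters(), r_imgs, r_labels,
                            config.finetune_lr, config.finetune_epochs,
                            config.finetune_batch, rng)
    history = {
        "pretrain_losses": pre_losses,
        "finetune_losses": ft_losses,
        "conv_hash_before_finetune": frozen_before,
        "conv_hash_after_finetune": clf.conv_hash(),
    }
    return clf, history


# ---------------------------------------------------------------------------
# Cross-validation

@dataclass
class CVResult:
    fold_accuracies: list = field(default_factory=list)
    mean: float = 0.0
    sd: float = 0.0
    counts: dict = field(default_factory=dict)


def make_folds(items, n_folds, rng):
    """Stratified fold assignment at VOI granularity.

    ``items``: list of ``(voi_id, label)``.  Returns ``{voi_id: fold}``
    with classes balanced across folds.
    """
    by_class = {}
    for voi_id, label in items:
        by_class.setdefault(label, []).append(voi_id)
    assignment = {}
    for label, ids in sorted(by_class.items()):
        if len(ids) < n_folds:
            raise ValueError(f"class {label} has fewer VOIs than folds")
        ids = list(ids)
        rng.shuffle(ids)
        for i, voi_id in enumerate(ids):
            assignment[voi_id] = i % n_folds
    return assignment


def cross_validate(real_set, generated_set, config: ClassifierConfig,
                   n_repeats: int = 3, n_folds: int = 3, seed: int = 0,
                   image_size: int = 32) -> CVResult:
    """Repeated stratified k-fold accuracy of the augmented classifier.

    ``real_set``: list of ``(image, label, voi_id)`` — one representative
    image per tumor.  ``generated_set``: list of ``(image, label)`` used
    for pretraining, or ``None`` for the no-pretraining baseline (then all
    layers are trained on the real training folds).  Reports mean and
    standard deviation over ``n_repeats * n_folds`` fold accuracies.
    """
    rng = np.random.default_rng(seed)
    accs = []
    voi_items = sorted({(v, lab) for _, lab, v in real_set})
    for _ in range(n_repeats):
        folds = make_folds(voi_items, n_folds, rng)
        for fold in range(n_folds):
            train_rows = [(im, lab) for im, lab, v in real_set
                          if folds[v] != fold]
            test_rows = [(im, lab) for im, lab, v in real_set
                         if folds[v] == fold]
            fit_seed = int(rng.integers(2 ** 31 - 1))
            if generated_set is not None:
                clf, _ = pretrain_then_finetune(
                    generated_set, train_rows, config,
                    seed=fit_seed, image_size=image_size)
            else:
                clf = SmallCNNClassifier(image_size=image_size,
                                         seed=fit_seed)
                imgs = _prep_images([im for im, _ in train_rows])
                labels = _labels_to_int([lab for _, lab in train_rows])
                _sgd_epochs(clf, clf.parameters(), imgs, labels,
                            config.finetune_lr, config.finetune_epochs,
                            config.finetune_batch,
                            np.random.default_rng(fit_seed))
            pred = clf.predict([im for im, _ in test_rows])
            truth = _labels_to_int([lab for _, lab in test_rows])
            accs.append(float((pred == truth).mean()))
    return CVResult(
        fold_accuracies=accs,
        mean=float(np.mean(accs)),
        sd=float(np.std(accs)),
        counts={"n_real": len(real_set),
                "n_generated": 0 if generated_set is None
                else len(generated_set),
                "n_folds": n_folds, "n_repeats": n_repeats},
    )


# ---------------------------------------------------------------------------
# Desk-scale end-to-end study

def run_augmentation_study(seed: int = 0, image_size: int = 32,
                           n_generation_train: int = 45,
                           n_classification: int = 15,
                           n_generation_test: int = 12,
                           gan_epochs: int = 60,
                           n_per_edge: int = 5,
                           oblique_stride: int = 7):
    """Full augmentation experiment on phantoms, at desk scale.

    Three disjoint phantom cohorts are drawn: generation-training (one
    representative slice pair per tumor, used to train the style model),
    classification (one representative real image per tumor; deliberately
    scarce — five tumors per class — because augmentation targets the
    data-scarce regime), and generation-test, whose *oblique-slice* edge
    sets (every ``oblique_stride``-th of the 98 training slices per tumor)
    drive generation with ``n_per_edge`` fresh latents per edge.  Repeated
    stratified 3-fold cross-validation then compares a classifier
    pretrained on the generated images (fully connected layers fine-tuned
    on the real training folds) against a classifier trained on the real
    training folds alone.

    Returns a dict with both :class:`CVResult` objects, the trained
    bundle, the training history, and the per-class generated counts.
    """
    from .networks import GeneratorConfig, build_model_bundle
    from .phantoms import make_paired_dataset
    from .preprocess import preprocess_volume
    from .training import TrainConfig, train

    rng = np.random.default_rng(seed)
    seeds = [int(rng.integers(2 ** 31 - 1)) for _ in range(5)]

    def representative(n, child_seed):
        data = make_paired_dataset(n, seed=child_seed)
        return [(preprocess_volume(v, train_mode=False,
                                   size=image_size)[0], lab)
                for v, lab in data]

    gen_train = representative(n_generation_train, seeds[0])
    cls_rows = [(p.ct_image, lab, f"voi{i}") for i, (p, lab)
                in enumerate(representative(n_classification, seeds[1]))]

    edges_by_class = {}
    for vol, lab in make_paired_dataset(n_generation_test, seed=seeds[2]):
        pairs = preprocess_volume(vol, train_mode=True,
                                  size=image_size)[::oblique_stride]
        edges_by_class.setdefault(lab, []).extend(
            p.sketch_image for p in pairs)

    depth = min(7, int(np.log2(image_size)))
    config = GeneratorConfig(depth=depth, base_channels=8,
                             image_size=image_size, use_style=True,
                             latent_dim=64)
    bundle = build_model_bundle(config, seed=seeds[3])
    bundle, history = train(
        [p for p, _ in gen_train], bundle,
        TrainConfig(learning_rate=2e-3, epochs=gan_epochs, batch_size=5,
                    seed=seeds[3]))

    generated = generate_augmented_set(bundle, edges_by_class, n_per_edge,
                                       seed=seeds[4])
    generated_set = [(im, lab) for lab, ims in generated.items()
                     for im in ims]

    clf_config = ClassifierConfig(
        pretrain_lr=0.1, pretrain_epochs=30, pretrain_batch=16,
        finetune_lr=0.1, finetune_epochs=60, finetune_batch=8)
    augmented = cross_validate(cls_rows, generated_set, clf_config,
                               seed=seeds[4], image_size=image_size)
    baseline = cross_validate(cls_rows, None, clf_config,
                              seed=seeds[4], image_size=image_size)
    return {
        "augmented": augmented,
        "baseline": baseline,
        "bundle": bundle,
        "history": history,
        "generated_per_class": {lab: len(ims)
                                for lab, ims in generated.items()},
    }
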