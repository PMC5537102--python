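"""Feature extraction and the cost-sensitive random-forest cascade.

The classifier consumes one fixed-length feature vector per 256x256
patch. Feature extraction is pluggable: the bundled ``"default"``
extractor computes a hand-crafted texture descriptor (16-bin intensity
histogram, grey-level co-occurrence contrast/homogeneity/energy/
correlation at 4 offsets, and 2-level wavelet sub-band energies, 39
values in total) so the pipeline runs end to end at desk scale; an
``"embedding"`` extractor delegates to a user-supplied function — e.g. a
CNN penultimate layer — and enforces the 1024-feature contract expected
of such embeddings.

The cascade is an averaged committee of 10 independently seeded random
forests of 100 trees. Cost sensitivity enters twice: training instances
are weighted by the cost of misclassifying their class, and prediction
picks the label with minimum expected cost under the 2x2 cost matrix
(rows/columns ordered benign, malignant; zero diagonal). With equal
off-diagonal costs this reduces to plain argmax of the averaged
malignant probability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pywt
from skimage.feature import graycomatrix, graycoprops
from sklearn.ensemble import RandomForestClassifier

from .augmentation import BENIGN, MALIGNANT, Sample
from .errors import ContractError, ValidationError

EMBEDDING_DIM = 1024
N_MEMBERS = 10
N_TREES = 100

_GLCM_PROPS = ("contrast", "homogeneity", "energy", "correlation")


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    extractor_id: str
    parent_id: str = ""
    crop_index: int = -1

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("feature values must be finite")


@dataclass(frozen=True)
class CostMatrix:
    """2x2 misclassification costs, (benign, malignant) ordering.

    ``matrix[i][j]`` is the cost of predicting class j when the truth is
    class i; the diagonal is zero.
    """

    benign_as_malignant: float  # C[benign][malignant]
    malignant_as_benign: float  # C[malignant][benign]

    def __post_init__(self) -> None:
        if self.benign_as_malignant <= 0 or self.malignant_as_benign <= 0:
            raise ValidationError("off-diagonal costs must be > 0")

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[0.0, self.benign_as_malignant],
                         [self.malignant_as_benign, 0.0]])


def default_texture_features(patch: np.ndarray) -> np.ndarray:
    """39-dim texture descriptor: histogram + GLCM + wavelet energies."""
    patch = np.asarray(patch)
    hist = np.bincount((patch // 16).ravel().astype(np.int64), minlength=16)[:16]
    hist = hist / patch.size

    # co-occurrence on 32 grey levels, distance 1, 4 directions
    q = (patch // 8).astype(np.uint8)
    glcm = graycomatrix(q, distances=[1],
                        angles=[0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
                        levels=32, symmetric=True, normed=True)
    glcm_feats = np.concatenate(
        [graycoprops(glcm, p).ravel() for p in _GLCM_PROPS])

    coeffs = pywt.wavedec2(patch.astype(float), "db2", level=2)
    energies = [float(np.mean(coeffs[0] ** 2))]
    for detail in coeffs[1:]:
        energies.extend(float(np.mean(d ** 2)) for d in detail)
    energies = np.log1p(np.array(energies))

    return np.concatenate([hist, glcm_feats, energies])


#: registry of pluggable embedding functions: patch -> 1-D float array
_EMBEDDINGS: dict[str, Callable[[np.ndarray], np.ndarray]] = {}


def register_embedding(name: str, fn: Callable[[np.ndarray], np.ndarray]) -> None:
    """Register a named embedding extractor (must return 1024 features)."""
    _EMBEDDINGS[name] = fn


def extract_features(sample: Sample, extractor: str = "default",
                     patch_size: int = 256) -> FeatureVector:
    """Compute the feature vector of one sample; deterministic per input."""
    patch = sample.patch
    if patch.shape != (patch_size, patch_size):
        raise ValidationError(
            f"patch must be {patch_size}x{patch_size}, got {patch.shape}")
    if extractor == "default":
        values = default_texture_features(patch)
    elif extractor in _EMBEDDINGS:
        values = np.asarray(_EMBEDDINGS[extractor](patch), dtype=float).ravel()
        if values.size != EMBEDDING_DIM:
            raise ContractError(
                f"embedding {extractor!r} returned {values.size} features; "
                f"expected {EMBEDDING_DIM}")
    else:
        raise ValidationError(f"unknown extractor {extractor!r}")
    return FeatureVector(values=values, extractor_id=extractor,
                         parent_id=sample.parent_id,
                         crop_index=sample.crop_index)


def feature_matrix(samples: Sequence[Sample], extractor: str = "default",
                   patch_size: int = 256) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack features/labels of a sample list; labels coded 0=benign 1=malignant."""
    feats = [extract_features(s, extractor, patch_size) for s in samples]
    X = np.vstack([f.values for f in feats])
    y = np.array([1 if s.label == MALIGNANT else 0 for s in samples])
    parents = [s.parent_id for s in samples]
    return X, y, parents


def build_cost_matrix(class_counts: tuple[int, int]) -> CostMatrix:
    """Cost matrix from the class distribution (n_benign, n_malignant).

    Misclassifying class i costs in proportion to how outnumbered it is:
    C[malignant][benign] = n_benign / n_malignant and
    C[benign][malignant] = 1, so the rarer the malignant class the more a
    missed malignancy costs (and vice versa when benign is rarer).
    """
    n_benign, n_malignant = class_counts
    if n_benign < 1 or n_malignant < 1:
        raise ValidationError("both class counts must be >= 1")
    return CostMatrix(benign_as_malignant=1.0,
                      malignant_as_benign=n_benign / n_malignant)


@dataclass
class CascadeModel:
    """Committee of cost-sensitive random forests with its cost matrix."""

    members: list
    cost: CostMatrix
    member_seeds: list[int]
    extractor_id: str
    n_features: int

    def __post_init__(self) -> None:
        if len(self.members) != N_MEMBERS:
            raise ValidationError(f"cascade must have exactly {N_MEMBERS} members")


def train_cascade(features: np.ndarray, labels: np.ndarray, cost: CostMatrix,
                  seed: int, extractor_id: str = "default") -> CascadeModel:
    """Fit the 10-member cascade.

    Each member is a 100-tree random forest with its own derived seed.
    Instances are weighted by the cost of misclassifying their class, so
    a forest grown on them minimizes expected cost rather than raw error.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if features.ndim != 2 or features.shape[0] != labels.shape[0]:
        raise ValidationError("features must be 2-D with one row per label")
    if not np.all(np.isfinite(features)):
        raise ValidationError("features must be finite")
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValidationError("training data must contain both classes")
    for cls in (0, 1):
        if np.sum(labels == cls) < 2:
            raise ValidationError("need at least 2 samples per class")

    # weight of an instance = cost of getting its class wrong
    weights = np.where(labels == 1, cost.malignant_as_benign,
                       cost.benign_as_malignant)
    rng = np.random.default_rng(seed)
    member_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=N_MEMBERS)]
    members = []
    for ms in member_seeds:
        rf = RandomForestClassifier(n_estimators=N_TREES, random_state=ms,
                                    n_jobs=1)
        rf.fit(features, labels, sample_weight=weights)
        members.append(rf)
    return CascadeModel(members=members, cost=cost, member_seeds=member_seeds,
                        extractor_id=extractor_id,
                        n_features=features.shape[1])


def predict(model: CascadeModel, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Score and label a feature matrix.

    The score is the committee mean of the members' malignant-class
    probability. The label minimizes expected cost: predict malignant when
    P(mal) * C[mal][ben] >= P(ben) * C[ben][mal], ties toward malignant
    (the clinically conservative direction).
    """
    features = np.asarray(features, dtype=float)
    if features.ndim == 1:
        features = features[None, :]
    if features.shape[1] != model.n_features:
        raise ContractError(
            f"feature dimension {features.shape[1]} does not match the "
            f"model's {model.n_features}")
    probs = np.zeros(features.shape[0])
    for rf in model.members:
        mal_idx = int(np.where(rf.classes_ == 1)[0][0])
        probs += rf.predict_proba(features)[:, mal_idx]
    probs /= len(model.members)
    cost_pred_benign = probs * model.cost.malignant_as_benign
    cost_pred_malignant = (1.0 - probs) * model.cost.benign_as_malignant
    labels = (cost_pred_benign >= cost_pred_malignant).astype(int)
    return probs, labels


MODEL_FORMAT_VERSION = 1


def save_model(model: CascadeModel, path) -> None:
    """Serialize a cascade to a single joblib archive with metadata."""
    import joblib

    joblib.dump({
        "format_version": MODEL_FORMAT_VERSION,
        "extractor_id": model.extractor_id,
        "n_features": model.n_features,
        "member_seeds": model.member_seeds,
        "cost": (model.cost.benign_as_malignant, model.cost.malignant_as_benign),
        "members": model.members,
    }, path)


def load_model(path) -> CascadeModel:
    import joblib

    blob = joblib.load(path)
    if blob.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValidationError(
            f"unsupported model format {blob.get('format_version')!r}")
    cb, cm = blob["cost"]
    return CascadeModel(members=blob["members"],
                        cost=CostMatrix(cb, cm),
                        member_seeds=blob["member_seeds"],
                        extractor_id=blob["extractor_id"],
                        n_features=blob["n_features"])
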