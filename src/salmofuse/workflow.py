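"""End-to-end convenience wrappers over the two-block pipeline.

These functions wire the canonical chain together — TIC-normalize the
spectral block, fuse (mid-level by default: Pareto-scaled spectra, unit-
variance elements, 85% cumulative-variance compression), classify, and
cross-validate with all transforms re-fit per fold.
"""

from __future__ import annotations

from . import chemometrics as cm
from .evaluation import CVResult, FusedClassifier, kfold_cv
from .preprocess import tic_normalize
from .synthetic_data import Dataset

#: default per-block scaling before compression
DEFAULT_SCALING = {"reims": "pareto", "icpms": "uv"}


def make_classifier(name: str, seed: int = 0):
    """Classifier by name with the workflow's published hyperparameters."""
    if name == "plsda":
        return cm.PLSDAClassifier(n_components=25)
    if name == "oplsda":
        return cm.OPLSDAClassifier(n_ortho=1)
    if name == "knn":
        return cm.KNNClassifier(k=5)
    if name == "lda":
        return cm.LDAClassifier()
    if name == "pca_lda":
        return cm.PCALDAClassifier(n_pcs=25)
    if name == "rf":
        return cm.make_random_forest(seed=seed)
    if name == "svm":
        return cm.make_svm(seed=seed)
    raise ValueError(f"unknown classifier {name!r}")


def dataset_blocks(ds: Dataset, test: bool = False):
    """(blocks, labels) ready for fusion: spectra TIC-normalized, elements
    as-is. ``test=True`` returns the replicated test rows instead."""
    spectra = ds.test_spectra if test else ds.spectra
    elements = ds.test_elements if test else ds.elements
    blocks = [
        (tic_normalize(spectra).data, "reims"),
        (elements.data, "icpms"),
    ]
    y = ds.test_labels if test else ds.labels
    return blocks, y


def pipeline_cv(
    ds: Dataset,
    classifier: str = "plsda",
    level: str = "mid",
    threshold: float = 0.85,
    folds: int = 5,
    seed: int = 0,
    labels=None,
) -> CVResult:
    """Cross-validate the full fusion pipeline on a synthetic dataset.

    ``labels`` overrides the dataset labels (e.g. a permuted vector for
    null calibration).
    """
    blocks, y = dataset_blocks(ds)
    y = y.to_numpy() if labels is None else labels
    pipe = FusedClassifier(
        make_classifier(classifier, seed=seed),
        level=level,
        threshold=threshold,
        scaling=DEFAULT_SCALING,
    )
    return kfold_cv(pipe, blocks, y, folds=folds, seed=seed)
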