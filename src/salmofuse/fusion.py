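"""Low- and mid-level fusion of multiblock data.

Low-level fusion concatenates the column-scaled raw blocks. Mid-level fusion
first compresses each block by PCA to the smallest number of components
whose cumulative explained variance reaches a threshold (default 85%), then
concatenates the scores. Every transform fitted on the training data
(centering, scaling, loadings, min-max extrema) is stored so held-out
samples can be projected without re-fitting.

Default block scaling before compression: spectral blocks are mean-centered
and Pareto scaled (division by the square root of the column standard
deviation, the usual mild shrinkage for MS fingerprints); element blocks are
mean-centered and unit-variance scaled, the standard choice when variables
live on heterogeneous concentration scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import MinMaxParams, apply_minmax, minmax_scale

__all__ = [
    "BlockCompression",
    "FusedMatrix",
    "compress_block",
    "low_level_fuse",
    "mid_level_fuse",
    "project",
]

MAX_COMPONENTS_DEFAULT = 250


class AlignmentError(ValueError):
    pass


class DegenerateInputError(ValueError):
    pass


def _scale_vector(X: np.ndarray, mode: str) -> np.ndarray:
    sd = X.std(axis=0, ddof=1)
    if mode == "none":
        return np.ones(X.shape[1])
    if mode == "uv":
        s = sd.copy()
    elif mode == "pareto":
        s = np.sqrt(sd)
    else:
        raise ValueError(f"unknown scaling mode {mode!r}")
    s[s == 0] = 1.0  # constant columns carry no information either way
    return s


@dataclass
class BlockCompression:
    """Fitted PCA compression of one block."""

    name: str
    mean: np.ndarray
    scale: np.ndarray
    mode: str
    loadings: np.ndarray            # variables x k, orthonormal columns
    explained_variance: np.ndarray  # fraction per retained component
    k: int
    threshold: float
    columns: list = field(default_factory=list)

    def transform(self, X) -> np.ndarray:
        X = self._align(X)
        return ((X - self.mean) / self.scale) @ self.loadings

    def _align(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if self.columns and list(X.columns) != list(self.columns):
                if set(X.columns) != set(self.columns):
                    raise AlignmentError(
                        f"block {self.name!r}: variable axis mismatch"
                    )
                X = X[self.columns]
            return X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.mean.size:
            raise AlignmentError(f"block {self.name!r}: variable axis mismatch")
        return X


def compress_block(
    matrix,
    threshold: float = 0.85,
    scaling: str = "uv",
    max_components: int = MAX_COMPONENTS_DEFAULT,
    name: str = "block",
):
    """PCA-compress one block at a cumulative-explained-variance threshold.

    k is the smallest component count whose cumulative explained variance
    reaches ``threshold`` (ties toward fewer components), capped at
    ``min(n-1, p, max_components)``. Returns ``(BlockCompression, scores)``.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    frame = pd.DataFrame(matrix)
    X = frame.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2:
        raise DegenerateInputError("need at least 2 samples")
    mean = X.mean(axis=0)
    scale = _scale_vector(X, scaling)
    Xs = (X - mean) / scale
    total = float((Xs**2).sum())
    if total <= 0:
        raise DegenerateInputError(f"block {name!r} has zero variance")
    # economy SVD: exact PCA, cheap even at thousands of variables
    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    evr = s**2 / (s**2).sum()
    cap = min(n - 1, p, max_components)
    cum = np.cumsum(evr)
    reach = np.flatnonzero(cum >= threshold - 1e-9)
    k = int(reach[0]) + 1 if reach.size else cap
    k = max(1, min(k, cap))
    comp = BlockCompression(
        name=name,
        mean=mean,
        scale=scale,
        mode=scaling,
        loadings=Vt[:k].T.copy(),
        explained_variance=evr[:k].copy(),
        k=k,
        threshold=threshold,
        columns=list(frame.columns),
    )
    scores = Xs @ comp.loadings
    return comp, scores


@dataclass
class FusedMatrix:
    """Samples x features with per-feature block provenance and the fitted
    transforms needed to project new samples."""

    data: pd.DataFrame
    provenance: list          # (block name, component/variable id) per column
    level: str                # "low" | "mid"
    transforms: dict          # block name -> BlockCompression | MinMaxParams
    block_order: list
    weights: dict = field(default_factory=dict)  # per-block score multiplier

    @property
    def width(self) -> int:
        return self.data.shape[1]

    def block_widths(self) -> dict:
        out: dict = {}
        for b, _ in self.provenance:
            out[b] = out.get(b, 0) + 1
        return out


def _check_alignment(blocks):
    index = None
    for mat, name in blocks:
        mat = pd.DataFrame(mat)
        if index is None:
            index = mat.index
        elif len(mat.index) != len(index) or list(mat.index) != list(index):
            raise AlignmentError(f"block {name!r}: sample rows are not aligned")
    return index


def low_level_fuse(blocks) -> FusedMatrix:
    """Concatenate column-wise min-max scaled blocks.

    ``blocks`` is a list of ``(matrix, name)``; matrices must share aligned
    sample rows.
    """
    index = _check_alignment(blocks)
    pieces, provenance, transforms, order = [], [], {}, []
    for mat, name in blocks:
        frame = pd.DataFrame(mat)
        scaled, params = minmax_scale(frame)
        scaled.columns = [f"{name}:{c}" for c in frame.columns]
        pieces.append(scaled)
        provenance += [(name, c) for c in frame.columns]
        transforms[name] = params
        order.append(name)
    return FusedMatrix(
        data=pd.concat(pieces, axis=1),
        provenance=provenance,
        level="low",
        transforms=transforms,
        block_order=order,
    )


def mid_level_fuse(
    blocks,
    threshold: float = 0.85,
    scaling=None,
    max_components: int = MAX_COMPONENTS_DEFAULT,
    weighting: str = "none",
) -> FusedMatrix:
    """Per-block PCA compression at ``threshold``, scores concatenated.

    ``scaling`` maps block name -> mode ("none" | "uv" | "pareto"); blocks
    not listed default to "uv". ``weighting="variance"`` rescales each
    block's scores by its total retained variance fraction; the default is
    no reweighting.
    """
    if weighting not in ("none", "variance"):
        raise ValueError(f"unknown weighting {weighting!r}")
    index = _check_alignment(blocks)
    scaling = scaling or {}
    pieces, provenance, transforms, order, weights = [], [], {}, [], {}
    for mat, name in blocks:
        frame = pd.DataFrame(mat)
        comp, scores = compress_block(
            frame,
            threshold=threshold,
            scaling=scaling.get(name, "uv"),
            max_components=max_components,
            name=name,
        )
        w = float(comp.explained_variance.sum()) if weighting == "variance" else 1.0
        weights[name] = w
        cols = [f"{name}:PC{i + 1}" for i in range(comp.k)]
        pieces.append(pd.DataFrame(scores * w, index=index, columns=cols))
        provenance += [(name, f"PC{i + 1}") for i in range(comp.k)]
        transforms[name] = comp
        order.append(name)
    return FusedMatrix(
        data=pd.concat(pieces, axis=1),
        provenance=provenance,
        level="mid",
        transforms=transforms,
        block_order=order,
        weights=weights,
    )


def project(fused: FusedMatrix, new_blocks: dict) -> pd.DataFrame:
    """Map new samples into the fused feature space using the stored
    transforms; never re-fits."""
    missing = [b for b in fused.block_order if b not in new_blocks]
    if missing:
        raise AlignmentError(f"missing blocks for projection: {missing}")
    index = None
    pieces = []
    for name in fused.block_order:
        mat = pd.DataFrame(new_blocks[name])
        if index is None:
            index = mat.index
        elif list(mat.index) != list(index):
            raise AlignmentError(f"block {name!r}: sample rows are not aligned")
        tf = fused.transforms[name]
        if isinstance(tf, MinMaxParams):
            piece = apply_minmax(mat, tf)
            piece.columns = [f"{name}:{c}" for c in mat.columns]
        else:
            scores = tf.transform(mat) * fused.weights.get(name, 1.0)
            piece = pd.DataFrame(
                scores,
                index=index,
                columns=[f"{name}:PC{i + 1}" for i in range(tf.k)],
            )
        pieces.append(piece)
    out = pd.concat(pieces, axis=1)
    return out[fused.data.columns]
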