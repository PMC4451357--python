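"""Eigenimage decomposition of key-slice stacks.

Each stack of N vectorized slice images (N subjects x A pixels) is
standardized per pixel, then decomposed by PCA. Because N << A, the
eigendecomposition is done on the small N x N matrix Z Z^T / (N - 1); its
eigenvectors are mapped back to pixel space and unit-normalized, giving at
most N - 1 orthonormal eigenimages ("eigenbrains"). Per-subject projection
scores onto each eigenbrain are the downstream classification features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DataError
from .slices import SliceStack

__all__ = [
    "StandardizedStack",
    "EigenbrainSet",
    "standardize",
    "compute_eigenbrains",
    "reshape_eigenbrain",
    "RANK_TOL",
]

#: Relative eigenvalue cutoff below which components are treated as null space.
RANK_TOL = 1e-10


@dataclass
class StandardizedStack:
    """Per-pixel standardized, vectorized slice stack.

    ``Z`` is N x A with every non-constant pixel column at sample mean 0 and
    sample SD 1 (N-1 denominator); constant pixels are zeroed and flagged in
    ``constant_mask``.
    """

    Z: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    constant_mask: np.ndarray
    image_shape: tuple[int, int]
    key_index: int
    axis: int
    subject_ids: list[str]

    @property
    def n_subjects(self) -> int:
        return self.Z.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.Z.shape[1]


@dataclass
class EigenbrainSet:
    """Sorted eigenimages, their eigenvalues, and subject scores for one slice.

    ``U`` is A x n_eig with orthonormal columns; ``eigvals`` descending;
    ``scores`` is N x n_eig with column sample variance equal to the matching
    eigenvalue.
    """

    U: np.ndarray
    eigvals: np.ndarray
    scores: np.ndarray
    image_shape: tuple[int, int]
    key_index: int
    axis: int
    subject_ids: list[str]

    @property
    def n_eig(self) -> int:
        return self.U.shape[1]


def vectorize(images: np.ndarray) -> np.ndarray:
    """Row-major flatten of (N, H, W) images to an (N, H*W) matrix."""
    n = images.shape[0]
    return images.reshape(n, -1)


def standardize(stack: SliceStack, mode: str = "voxel") -> StandardizedStack:
    """Standardize the vectorized stack to mean 0, sample SD 1 (N-1 denominator).

    ``mode="voxel"`` (default, the PCA convention) standardizes each pixel
    column across subjects; pixels constant across subjects have zero SD, so
    their columns are zeroed and flagged rather than divided.
    ``mode="sample"`` standardizes each subject row across its pixels instead.
    """
    n = stack.n_subjects
    if n < 2:
        raise DataError("standardization requires at least 2 subjects")
    if mode not in ("voxel", "sample"):
        raise ConfigurationError(f"unknown standardize mode {mode!r}")
    X = vectorize(stack.images).astype(float)
    if mode == "sample":
        mu = X.mean(axis=1, keepdims=True)
        sigma = X.std(axis=1, ddof=1, keepdims=True)
        safe = np.where(sigma == 0, 1.0, sigma)
        Z = (X - mu) / safe
        return StandardizedStack(
            Z=Z,
            mu=mu.ravel(),
            sigma=sigma.ravel(),
            constant_mask=np.zeros(X.shape[1], dtype=bool),
            image_shape=stack.image_shape,
            key_index=stack.key_index,
            axis=stack.axis,
            subject_ids=list(stack.subject_ids),
        )
    mu = X.mean(axis=0)
    sigma = X.std(axis=0, ddof=1)
    constant = sigma == 0
    safe_sigma = np.where(constant, 1.0, sigma)
    Z = (X - mu) / safe_sigma
    Z[:, constant] = 0.0
    return StandardizedStack(
        Z=Z,
        mu=mu,
        sigma=sigma,
        constant_mask=constant,
        image_shape=stack.image_shape,
        key_index=stack.key_index,
        axis=stack.axis,
        subject_ids=list(stack.subject_ids),
    )


def compute_eigenbrains(std: StandardizedStack, rank_tol: float = RANK_TOL) -> EigenbrainSet:
    """PCA via the small N x N covariance trick.

    Eigendecomposes C' = Z Z^T / (N-1); the nonzero eigenvalues of C' equal
    those of the full A x A covariance Z^T Z / (N-1), and the eigenimages are
    the unit-normalized images of Z^T applied to C' eigenvectors. Components
    with eigenvalue below ``rank_tol`` times the largest are dropped. Each
    eigenimage's sign is flipped so its largest-magnitude element is positive,
    making the output deterministic.
    """
    Z = std.Z
    n = Z.shape[0]
    c_small = Z @ Z.T / (n - 1)
    w, v = np.linalg.eigh(c_small)
    order = np.argsort(w)[::-1]
    w = w[order]
    v = v[:, order]
    if w.size == 0 or w[0] <= 0:
        warnings.warn("degenerate all-zero stack: no eigenbrains retained")
        empty_u = np.zeros((Z.shape[1], 0))
        return EigenbrainSet(
            U=empty_u,
            eigvals=np.zeros(0),
            scores=np.zeros((n, 0)),
            image_shape=std.image_shape,
            key_index=std.key_index,
            axis=std.axis,
            subject_ids=list(std.subject_ids),
        )
    keep = w > rank_tol * w[0]
    w = w[keep]
    v = v[:, keep]
    U = Z.T @ v
    U /= np.linalg.norm(U, axis=0, keepdims=True)
    # deterministic sign: largest-|.| element of each eigenimage is positive
    flip = U[np.abs(U).argmax(axis=0), np.arange(U.shape[1])] < 0
    U[:, flip] *= -1.0
    scores = Z @ U
    return EigenbrainSet(
        U=U,
        eigvals=w,
        scores=scores,
        image_shape=std.image_shape,
        key_index=std.key_index,
        axis=std.axis,
        subject_ids=list(std.subject_ids),
    )


def reshape_eigenbrain(eig: EigenbrainSet, i: int) -> np.ndarray:
    """Row-major reshape of the i-th eigenimage vector to its H x W image."""
    if not 0 <= i < eig.n_eig:
        raise ConfigurationError(f"eigenbrain index {i} out of range (n_eig={eig.n_eig})")
    h, w = eig.image_shape
    return eig.U[:, i].reshape(h, w)


def decompose_stacks(
    stacks: list[SliceStack], mode: str = "voxel"
) -> list[EigenbrainSet]:
    """Standardize and decompose every key-slice stack (pooled over classes)."""
    return [compute_eigenbrains(standardize(s, mode=mode)) for s in stacks]
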