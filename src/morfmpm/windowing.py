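"""Window preprocessing: zero-padding, window slicing, per-window feature
evaluation, and per-residue cumulative averaging over multiple window sizes.

For a sequence of length L and a window of length N, the sequence is padded
with N0 = floor((N-1)/2) zeros on each side and the window slides with step
1, giving L0 - N + 1 windows (L0 = L + 2*N0). Each window's feature vector
is assigned to every residue the window covers; a residue's final vector is
the average of all vectors assigned to it. Window sizes default to
(10, 45, 90) — a short window to isolate MoRF-local composition, a long one
to capture the flanking disordered context, and a middle one (half the long
window) to damp long-window noise. Concatenating the per-size blocks gives
each residue a |features| x |sizes| dimensional vector (48 by default).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .features import (
    KIND_SCALE,
    FeatureSet,
    ScaleRegistry,
    evaluate_features,
    scale_value_rows,
    shannon_entropy,
    topological_entropy,
)
from .io_formats import AAINDEX_ORDER, AnnotatedSequence, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_SIZES = (10, 45, 90)


@dataclass(frozen=True)
class WindowSpec:
    """Ordered window sizes; strictly increasing positive integers."""

    sizes: tuple = DEFAULT_WINDOW_SIZES

    def __post_init__(self) -> None:
        object.__setattr__(self, "sizes", tuple(int(n) for n in self.sizes))
        if not self.sizes:
            raise ValidationError("WindowSpec needs at least one size")
        if any(n < 1 for n in self.sizes):
            raise ValidationError("window sizes must be positive")
        if any(b <= a for a, b in zip(self.sizes, self.sizes[1:])):
            raise ValidationError("window sizes must be strictly increasing")


@dataclass
class ResidueFeatureMatrix:
    """L x (K * |sizes|) per-residue feature matrix with layout metadata.

    Columns are blocked by window size (ascending spec order), features in
    declaration order within each block.
    """

    values: np.ndarray
    sequence_id: str
    window_sizes: tuple
    feature_names: tuple

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = len(self.feature_names) * len(self.window_sizes)
        if self.values.ndim != 2 or self.values.shape[1] != expected:
            raise ValidationError(
                f"{self.sequence_id}: expected {expected} feature columns, "
                f"got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"{self.sequence_id}: non-finite feature values")

    @property
    def column_labels(self) -> list:
        return [
            f"w{n}:{name}" for n in self.window_sizes for name in self.feature_names
        ]


def pad_and_slice(residues: str, N: int) -> tuple:
    """Slice a zero-padded sequence into windows of length N, step 1.

    Returns ``(windows, N0, L0)`` where each window is
    ``(window_text, pad_count)``: the residue letters the window covers and
    the number of padded positions it includes. There are exactly
    ``L0 - N + 1`` windows.
    """
    if N < 1:
        raise ValidationError("window length must be >= 1")
    L = len(residues)
    if L == 0:
        raise ValidationError("sequence must be nonempty")
    n0 = (N - 1) // 2
    l0 = L + 2 * n0
    windows = []
    for i in range(l0 - N + 1):  # i = 0-based start in the padded sequence
        res_lo = max(0, i - n0)
        res_hi = min(L, i + N - n0)
        text = residues[res_lo:res_hi] if res_hi > res_lo else ""
        windows.append((text, N - (res_hi - res_lo)))
    return windows, n0, l0


def _coverage_spans(L: int, N: int) -> list:
    """Half-open residue index span covered by each window (same order as
    pad_and_slice); identical to each window's residue part."""
    n0 = (N - 1) // 2
    l0 = L + 2 * n0
    return [
        (max(0, i - n0), min(L, i + N - n0)) for i in range(l0 - N + 1)
    ]


_CODE = {aa: k for k, aa in enumerate(AAINDEX_ORDER)}


def window_feature_matrix(
    residues: str,
    N: int,
    feature_set: FeatureSet,
    registry: ScaleRegistry,
) -> tuple:
    """Feature vectors v_i for every window: an (n_windows x K) matrix plus
    the residue span each window covers.

    Vectorized equivalent of calling ``evaluate_features`` on each window
    of ``pad_and_slice`` (agreement is pinned by tests).
    """
    L = len(residues)
    spans = _coverage_spans(L, N)
    V = np.zeros((len(spans), len(feature_set)), dtype=float)

    scale_cols, scale_mat, scale_means = scale_value_rows(feature_set, registry)
    if scale_cols:
        # per-residue scale values; unknown residues take the scale mean
        codes = np.array([_CODE.get(c, -1) for c in residues])
        rows = np.where(
            (codes >= 0)[:, None],
            scale_mat[np.clip(codes, 0, None)],
            scale_means[None, :],
        )
        for i, (lo, hi) in enumerate(spans):
            if hi > lo:
                V[i, scale_cols] = rows[lo:hi].sum(axis=0) / N

    entropy_cols = [
        (k, d.kind) for k, d in enumerate(feature_set.descriptors) if d.kind != KIND_SCALE
    ]
    if entropy_cols:
        for i, (lo, hi) in enumerate(spans):
            text = residues[lo:hi]
            for k, kind in entropy_cols:
                V[i, k] = (
                    shannon_entropy(text) if kind == "shannon-entropy"
                    else topological_entropy(text)
                )
    return V, spans


def average_over_windows(V: np.ndarray, spans: Sequence, L: int) -> np.ndarray:
    """Assign each window's vector to every residue it covers, then divide
    each residue's accumulated sum by its coverage count (the cumulative
    averaging rule, in its naive accumulate-and-divide form)."""
    X = np.zeros((L, V.shape[1]), dtype=float)
    counts = np.zeros(L, dtype=float)
    for (lo, hi), v in zip(spans, V):
        X[lo:hi] += v
        counts[lo:hi] += 1
    if np.any(counts == 0):
        raise ValidationError("residue not covered by any window")
    return X / counts[:, None]


def coverage_counts(L: int, N: int) -> np.ndarray:
    """Closed-form per-residue window counts.

    Residue j (1-based) is covered by windows i in
    [max(1, j + N0 - N + 1), min(L0 - N + 1, j + N0)]; for odd N this
    reduces to the familiar three regimes (j + N0 at the left edge, N in
    the interior, L0 - j - N0 + 1 at the right edge). Even window lengths
    shift the left boundary by one, which the interval form handles
    exactly.
    """
    n0 = (N - 1) // 2
    l0 = L + 2 * n0
    j = np.arange(1, L + 1)
    hi = np.minimum(l0 - N + 1, j + n0)
    lo = np.maximum(1, j + n0 - N + 1)
    return (hi - lo + 1).astype(float)


def residue_vectors(
    residues: str,
    N: int,
    feature_set: FeatureSet,
    registry: ScaleRegistry,
    sequence_id: str = "",
) -> np.ndarray:
    """Per-residue L x K feature matrix for one window size.

    Sequences shorter than the window clamp the effective window length to
    L (logged); real proteins are routinely shorter than the 90-residue
    default long window.
    """
    L = len(residues)
    n_eff = min(N, L)
    if n_eff != N:
        logger.info(
            "sequence %s: window %d clamped to sequence length %d",
            sequence_id or "<anonymous>", N, L,
        )
    V, spans = window_feature_matrix(residues, n_eff, feature_set, registry)
    return average_over_windows(V, spans, L)


def build_feature_matrix(
    sequence: AnnotatedSequence,
    window_spec: WindowSpec,
    feature_set: FeatureSet,
    registry: ScaleRegistry,
) -> ResidueFeatureMatrix:
    """Concatenate per-size residue vectors into the full per-residue
    feature matrix (48 columns for the 16-feature, 3-window defaults)."""
    blocks = [
        residue_vectors(sequence.residues, n, feature_set, registry, sequence.id)
        for n in window_spec.sizes
    ]
    return ResidueFeatureMatrix(
        values=np.hstack(blocks),
        sequence_id=sequence.id,
        window_sizes=window_spec.sizes,
        feature_names=tuple(feature_set.names),
    )


def stack_corpus(
    sequences: Sequence[AnnotatedSequence],
    window_spec: WindowSpec,
    feature_set: FeatureSet,
    registry: ScaleRegistry,
) -> tuple:
    """Stack per-sequence feature matrices and masks for training or
    evaluation: returns (X, y) with y the concatenated per-residue masks
    (possibly containing -1 ignore flags)."""
    mats = []
    ys = []
    for seq in sequences:
        mats.append(build_feature_matrix(seq, window_spec, feature_set, registry).values)
        ys.append(seq.mask)
    return np.vstack(mats), np.concatenate(ys)
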