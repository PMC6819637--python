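"""Per-window feature values: property-scale averages and sequence entropies.

Each feature is a map from a window of residues to a real number. Three
kinds exist: the average of an amino-acid property scale over the window
(zero-padding positions count toward the denominator but contribute zero),
Shannon entropy of the residue composition (bits), and a finite-sequence
topological entropy normalized to [0, 1]. The default 16-feature set is 13
physicochemical scales plus topological entropy and two disorder
propensities.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

from .io_formats import (
    AAINDEX_ORDER,
    PropertyScale,
    ValidationError,
    read_aaindex1,
)

ALPHABET_SIZE = 20

KIND_SCALE = "scale-average"
KIND_SHANNON = "shannon-entropy"
KIND_TOPOLOGICAL = "topological-entropy"
_KINDS = (KIND_SCALE, KIND_SHANNON, KIND_TOPOLOGICAL)


class ConfigurationError(ValueError):
    """A feature set references something the registry cannot resolve."""


@dataclass(frozen=True)
class FeatureDescriptor:
    """One feature: its kind, display name, and (for scale averages) the
    accession of the property scale it uses."""

    kind: str
    name: str
    scale_ref: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ConfigurationError(f"unknown feature kind {self.kind!r}")
        if self.kind == KIND_SCALE and not self.scale_ref:
            raise ConfigurationError(
                f"feature {self.name!r}: scale-average requires scale_ref"
            )
        if self.kind != KIND_SCALE and self.scale_ref:
            raise ConfigurationError(
                f"feature {self.name!r}: scale_ref only applies to scale averages"
            )
        if not self.name:
            raise ConfigurationError("feature name must be nonempty")


@dataclass(frozen=True)
class FeatureSet:
    """An ordered list of feature descriptors; the order defines the
    layout of every feature vector and model file."""

    descriptors: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "descriptors", tuple(self.descriptors))
        names = [d.name for d in self.descriptors]
        if len(set(names)) != len(names):
            raise ConfigurationError("feature names must be unique")
        if not names:
            raise ConfigurationError("feature set must be nonempty")

    def __len__(self) -> int:
        return len(self.descriptors)

    @property
    def names(self) -> list:
        return [d.name for d in self.descriptors]


class ScaleRegistry:
    """Accession -> PropertyScale lookup with completeness checks."""

    def __init__(self, scales: Iterable[PropertyScale] = ()) -> None:
        self._scales: dict = {}
        for s in scales:
            self.add(s)

    def add(self, scale: PropertyScale) -> None:
        if scale.accession in self._scales:
            raise ConfigurationError(f"duplicate scale accession {scale.accession!r}")
        self._scales[scale.accession] = scale

    def __contains__(self, accession: str) -> bool:
        return accession in self._scales

    def __len__(self) -> int:
        return len(self._scales)

    @property
    def accessions(self) -> list:
        return list(self._scales)

    @property
    def complete_accessions(self) -> list:
        """Accessions of scales with all 20 values present (usable in a
        feature set or selection pool)."""
        return [a for a, s in self._scales.items() if s.is_complete()]

    def resolve(self, accession: str) -> PropertyScale:
        """Fetch a scale for active use; incomplete (NA) scales are rejected."""
        scale = self._scales.get(accession)
        if scale is None:
            raise ConfigurationError(f"scale {accession!r} not in registry")
        if not scale.is_complete():
            raise ConfigurationError(
                f"scale {accession!r} has NA values and cannot be used"
            )
        return scale

    @classmethod
    def from_files(cls, paths: Iterable) -> "ScaleRegistry":
        reg = cls()
        for p in paths:
            for scale in read_aaindex1(p):
                reg.add(scale)
        return reg


def load_default_registry() -> ScaleRegistry:
    """The vendored scale registry.

    The shipped table (``data/scales_synthetic.aaindex1``) carries synthetic
    stand-in values under the accession codes the default feature set uses;
    swap in a real AAindex1 file via ``ScaleRegistry.from_files`` for
    production scales.
    """
    ref = resources.files("morfmpm").joinpath("data/scales_synthetic.aaindex1")
    with resources.as_file(ref) as path:
        return ScaleRegistry.from_files([path])


#: Table-2 accession codes in column order, followed by the structural trio.
DEFAULT_SCALE_ACCESSIONS = (
    "CIDH920101", "EISD860103", "NISK860101", "QIAN880105",
    "ROBB760101", "ROBB760108", "ROBB760112", "ROBB760113",
    "CORJ870103", "CORJ870106", "CORJ870107", "CORJ870108",
    "MIYS990104",
)
REMARK465_ACCESSION = "GLOB_R465"
DELEAGE_ROUX_ACCESSION = "GLOB_DLRX"
BFACTOR_2STD_ACCESSION = "GLOB_BF2S"


def default_feature_set() -> FeatureSet:
    """The 16-feature default: 13 property scales, then topological entropy
    and the Remark-465 and Deleage/Roux disorder propensities."""
    descriptors = [
        FeatureDescriptor(kind=KIND_SCALE, name=acc, scale_ref=acc)
        for acc in DEFAULT_SCALE_ACCESSIONS
    ]
    descriptors.append(FeatureDescriptor(kind=KIND_TOPOLOGICAL, name="topological_entropy"))
    descriptors.append(
        FeatureDescriptor(kind=KIND_SCALE, name="remark465", scale_ref=REMARK465_ACCESSION)
    )
    descriptors.append(
        FeatureDescriptor(kind=KIND_SCALE, name="deleage_roux", scale_ref=DELEAGE_ROUX_ACCESSION)
    )
    return FeatureSet(descriptors=tuple(descriptors))


# ---------------------------------------------------------------------------
# Feature primitives


def _strip_unknown(window_text: str) -> str:
    return window_text.replace("X", "")


def scale_average(window_text: str, scale: PropertyScale, pad_count: int = 0) -> float:
    """Average property value over a window, zero-padding included.

    Pads contribute zero to the numerator but count in the denominator
    ``N = len(window_text) + pad_count``; unknown residues take the scale
    mean.
    """
    if pad_count < 0:
        raise ValidationError("pad_count must be >= 0")
    n = len(window_text) + pad_count
    if n == 0:
        raise ValidationError("empty window (no residues, no pads)")
    if not window_text:
        return 0.0
    total = float(np.sum([scale.value(c) for c in window_text]))
    return total / n


def shannon_entropy(window_text: str) -> float:
    """Shannon entropy of the residue composition, in bits.

    Unknown residues (X) are excluded from the alphabet; the empty window
    is defined as 0.
    """
    text = _strip_unknown(window_text)
    if not text:
        return 0.0
    _, counts = np.unique(np.frombuffer(text.encode(), dtype=np.uint8), return_counts=True)
    freqs = counts / counts.sum()
    return float(-(freqs * np.log2(freqs)).sum())


def _topo_word_length(length: int) -> int:
    """Largest n with 20^n + n - 1 <= length; short sequences fall back to 1."""
    n = 1
    while ALPHABET_SIZE ** (n + 1) + n <= length:
        n += 1
    if ALPHABET_SIZE ** n + n - 1 > length:
        return 1
    return n


def topological_entropy(window_text: str) -> float:
    """Finite-sequence topological entropy, normalized to [0, 1].

    With alphabet size A = 20 and word length n calibrated to the window
    length (n = max{n : A^n + n - 1 <= len}, falling back to n = 1 for
    windows shorter than 20), the distinct n-subwords p of the first
    min(len, A^n + n - 1) characters give
    ``log(p) / (n * log(min(A^n, len - n + 1)))``. Homopolymers score 0.
    """
    text = _strip_unknown(window_text)
    length = len(text)
    if length == 0:
        return 0.0
    n = _topo_word_length(length)
    prefix = text[: min(length, ALPHABET_SIZE ** n + n - 1)]
    if len(prefix) < n:
        return 0.0
    p = len({prefix[i : i + n] for i in range(len(prefix) - n + 1)})
    base = min(ALPHABET_SIZE ** n, length - n + 1)
    if base <= 1 or p <= 1:
        return 0.0
    h = math.log(p) / (n * math.log(base))
    return min(max(h, 0.0), 1.0)


def evaluate_features(
    window_text: str,
    pad_count: int,
    feature_set: FeatureSet,
    registry: ScaleRegistry,
) -> np.ndarray:
    """The per-window feature vector v_i, ordered as the descriptors.

    Scale averages see the pads (as zeros in the numerator, counted in the
    denominator); entropies are computed on the residue part only. An
    all-pad window yields the zero vector.
    """
    out = np.empty(len(feature_set), dtype=float)
    for k, desc in enumerate(feature_set.descriptors):
        if desc.kind == KIND_SCALE:
            out[k] = scale_average(window_text, registry.resolve(desc.scale_ref), pad_count)
        elif desc.kind == KIND_SHANNON:
            out[k] = shannon_entropy(window_text)
        else:
            out[k] = topological_entropy(window_text)
    return out


def scale_value_rows(feature_set: FeatureSet, registry: ScaleRegistry) -> tuple:
    """Support for vectorized windowing: (column indices of scale-average
    features, a 20 x n_scales value matrix in canonical residue order, and
    the per-scale mean used for unknown residues)."""
    cols = [k for k, d in enumerate(feature_set.descriptors) if d.kind == KIND_SCALE]
    if not cols:
        return [], np.zeros((ALPHABET_SIZE, 0)), np.zeros(0)
    mat = np.column_stack(
        [registry.resolve(feature_set.descriptors[k].scale_ref).as_array() for k in cols]
    )
    return cols, mat, mat.mean(axis=0)
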