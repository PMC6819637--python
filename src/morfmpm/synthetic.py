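"""Synthetic corpora with planted MoRF segments.

Generates FASTA-style sequences plus per-residue masks in which short
segments (5-25 residues by default) are drawn from a residue composition
that diverges from the background, emulating the class structure the
predictor assumes: MoRF residues compositionally distinct from their
context. Residues are i.i.d. within each region (no Markov structure); the
effect size is an exponential-tilt exponent between the background and a
hydrophobic/aromatic-enriched target composition, so 0 gives the exact
null and 1 the full planted contrast.

Defaults mirror the corpus statistics of curated MoRF benchmarks: about a
hundred sequences of a few hundred residues each, one MoRF per sequence,
~2% positive residues overall.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io_formats import AnnotatedSequence, ValidationError

AA = "ARNDCQEGHILKMFPWYVST"

#: Swiss-Prot-style average residue frequencies (renormalized).
BACKGROUND_FREQ = {
    "A": 0.0826, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0137,
    "Q": 0.0393, "E": 0.0674, "G": 0.0708, "H": 0.0227, "I": 0.0593,
    "L": 0.0965, "K": 0.0582, "M": 0.0241, "F": 0.0386, "P": 0.0472,
    "S": 0.0660, "T": 0.0535, "W": 0.0110, "Y": 0.0292, "V": 0.0687,
}

#: Enrichment factors defining the MoRF target composition: binding
#: segments are hydrophobic/aromatic-enriched relative to disordered
#: context, and depleted in disorder-promoting residues.
MORF_ENRICHMENT = {
    "W": 3.0, "F": 3.0, "Y": 3.0, "I": 2.5, "L": 2.5, "M": 2.5, "V": 2.0,
    "R": 1.3, "P": 0.5, "S": 0.5, "G": 0.5, "E": 0.5, "K": 0.5, "Q": 0.7,
}

END_MARGIN = 10  # keep planted segments this far from sequence ends

#: Effect-size presets: 1.0 is the realistic default contrast; the strong
#: preset plants an unambiguous compositional signal for end-to-end
#: recovery checks.
DEFAULT_EFFECT_SIZE = 1.0
STRONG_EFFECT_SIZE = 2.0


def _simplex(freqs: dict) -> np.ndarray:
    v = np.array([freqs.get(a, 0.0) for a in AA], dtype=float)
    if np.any(v < 0) or v.sum() <= 0:
        raise ValidationError("composition must be non-negative and non-zero")
    return v / v.sum()


def default_background() -> np.ndarray:
    return _simplex(BACKGROUND_FREQ)


def default_morf_target() -> np.ndarray:
    bg = default_background()
    factors = np.array([MORF_ENRICHMENT.get(a, 1.0) for a in AA])
    return _simplex(dict(zip(AA, bg * factors)))


def tilt(background: np.ndarray, target: np.ndarray, effect_size: float) -> np.ndarray:
    """Exponential tilt between two compositions: proportional to
    background^(1-e) * target^e. e=0 reproduces the background exactly,
    e=1 the target; e>1 extrapolates."""
    if effect_size < 0:
        raise ValidationError("effect_size must be >= 0")

    def term(weight: float, p: np.ndarray) -> np.ndarray:
        # convention 0 * log(0) = 0 so a zero-weight factor drops out
        if weight == 0:
            return np.zeros_like(p)
        with np.errstate(divide="ignore"):
            return weight * np.log(p)

    logp = term(1 - effect_size, background) + term(effect_size, target)
    finite_max = np.max(logp[np.isfinite(logp)], initial=-np.inf)
    if not np.isfinite(finite_max):
        raise ValidationError("tilted composition is degenerate")
    p = np.exp(logp - finite_max)
    p[~np.isfinite(p)] = 0.0
    return p / p.sum()


@dataclass(frozen=True)
class SyntheticConfig:
    n_sequences: int = 100
    length_range: tuple = (150, 1000)
    morf_length_range: tuple = (5, 25)
    morfs_per_sequence: int = 1
    background_composition: np.ndarray = field(default_factory=default_background)
    morf_composition: np.ndarray = field(default_factory=default_morf_target)
    effect_size: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("background_composition", "morf_composition"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (20,) or np.any(v < 0) or abs(v.sum() - 1.0) > 1e-8:
                raise ValidationError(f"{name} must be a 20-simplex")
            object.__setattr__(self, name, v)
        lo, hi = self.length_range
        mlo, mhi = self.morf_length_range
        if not (1 <= lo <= hi) or not (1 <= mlo <= mhi):
            raise ValidationError("invalid length ranges")
        if self.morfs_per_sequence < 0 or self.n_sequences < 1:
            raise ValidationError("invalid counts")

    @property
    def effective_morf_composition(self) -> np.ndarray:
        return tilt(self.background_composition, self.morf_composition, self.effect_size)


def _place_segments(rng, L: int, lengths: list) -> list:
    """Uniform placements separated by at least one background residue
    (touching segments would merge into one over-long region), and
    >= END_MARGIN from the ends when the sequence is long enough."""
    gaps = len(lengths) - 1
    margin = END_MARGIN if L >= sum(lengths) + 2 * END_MARGIN + gaps else 0
    if sum(lengths) + 2 * margin + gaps > L:
        raise ValidationError(
            f"cannot place {len(lengths)} MoRF segment(s) totalling "
            f"{sum(lengths)} residues in a sequence of length {L}"
        )
    for _ in range(1000):
        placed = []
        ok = True
        for m in lengths:
            start = int(rng.integers(margin, L - margin - m + 1))
            if any(start <= e and s <= start + m for s, e in placed):
                ok = False
                break
            placed.append((start, start + m))
        if ok:
            return sorted(placed)
    raise ValidationError("could not place non-overlapping MoRF segments")


def generate(config: SyntheticConfig) -> list:
    """Generate ``AnnotatedSequence`` objects with planted MoRF masks;
    byte-reproducible from the config seed."""
    rng = np.random.default_rng(config.seed)
    aa = np.array(list(AA))
    bg = config.background_composition
    morf_comp = config.effective_morf_composition
    lo, hi = config.length_range
    mlo, mhi = config.morf_length_range
    out = []
    for k in range(config.n_sequences):
        L = int(rng.integers(lo, hi + 1))
        residues = rng.choice(aa, size=L, p=bg)
        mask = np.zeros(L, dtype=np.int8)
        if config.morfs_per_sequence:
            lengths = [int(rng.integers(mlo, mhi + 1))
                       for _ in range(config.morfs_per_sequence)]
            for start, end in _place_segments(rng, L, lengths):
                residues[start:end] = rng.choice(aa, size=end - start, p=morf_comp)
                mask[start:end] = 1
        out.append(
            AnnotatedSequence(id=f"syn{k:04d}", residues="".join(residues), mask=mask)
        )
    return out


def mask_regions(sequences, keep: str = "short", cutoff: int = 30) -> list:
    """Flag MoRF regions outside the kept length class as ignored (-1).

    ``keep="short"`` evaluates only regions of up to ``cutoff`` residues
    (longer ones neither count as positives nor negatives);
    ``keep="long"`` is the complement.
    """
    if cutoff < 1:
        raise ValidationError("cutoff must be >= 1")
    if keep not in ("short", "long"):
        raise ValidationError("keep must be 'short' or 'long'")
    from .io_formats import mask_to_intervals

    out = []
    for seq in sequences:
        mask = seq.mask.copy()
        for start, end in mask_to_intervals(seq.mask, state=1):
            length = end - start
            drop = length > cutoff if keep == "short" else length <= cutoff
            if drop:
                mask[start:end] = -1
        out.append(AnnotatedSequence(id=seq.id, residues=seq.residues, mask=mask))
    return out
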