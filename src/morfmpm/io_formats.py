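"""Readers and writers for every external format the predictor touches.

Covers multi-record FASTA, per-residue interval labels (TSV, BED-like
0-based half-open coordinates), AAindex1 property-scale flat files,
per-residue score tables (1-based positions, human-readable), and trained
model files (JSON text).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: canonical AAindex1 residue ordering (two I-block rows of ten)
AAINDEX_ORDER = "ARNDCQEGHILKMFPWYVST"
STANDARD_AA = frozenset(AAINDEX_ORDER)
UNKNOWN_RESIDUE = "X"

SCORE_DECIMALS = 6


class FormatError(ValueError):
    """An input file violates its format contract."""


class ValidationError(ValueError):
    """Well-formed input fails a semantic check."""


@dataclass
class AnnotatedSequence:
    """A protein sequence with a per-residue MoRF mask.

    The mask is ``1`` for MoRF residues, ``0`` for background, and ``-1``
    for residues excluded from evaluation (used by the short/long-region
    masking protocol; training always sees binary masks).
    """

    id: str
    residues: str
    mask: np.ndarray = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence id must be nonempty")
        if self.mask is None:
            self.mask = np.zeros(len(self.residues), dtype=np.int8)
        self.mask = np.asarray(self.mask, dtype=np.int8)
        if self.mask.shape != (len(self.residues),):
            raise ValidationError(
                f"{self.id}: mask length {self.mask.shape} != sequence length "
                f"{len(self.residues)}"
            )
        if not np.all(np.isin(self.mask, (-1, 0, 1))):
            raise ValidationError(f"{self.id}: mask entries must be in {{-1, 0, 1}}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PropertyScale:
    """A named 20-value amino-acid -> number map (one AAindex entry).

    Unknown or ambiguous residues (X, B, Z, U, ...) are imputed with the
    mean of the 20 values so that window averages are not biased.
    """

    accession: str
    values: dict
    description: str = ""

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValidationError("scale accession must be nonempty")
        if set(self.values) != STANDARD_AA:
            raise ValidationError(
                f"{self.accession}: scale must map exactly the 20 standard residues"
            )

    @property
    def mean(self) -> float:
        return float(np.nanmean([self.values[a] for a in AAINDEX_ORDER]))

    def is_complete(self) -> bool:
        """True when all 20 values are finite (no 'NA' entries)."""
        return all(np.isfinite(self.values[a]) for a in AAINDEX_ORDER)

    def value(self, letter: str) -> float:
        v = self.values.get(letter)
        if v is None:
            return self.mean
        return v

    def as_array(self) -> np.ndarray:
        """Values in canonical AAindex order, as a length-20 float array."""
        return np.array([self.values[a] for a in AAINDEX_ORDER], dtype=float)


# ---------------------------------------------------------------------------
# FASTA


def _sanitize(raw: str, seq_id: str) -> str:
    out = []
    replaced = set()
    for ch in raw.upper():
        if ch in STANDARD_AA:
            out.append(ch)
        else:
            out.append(UNKNOWN_RESIDUE)
            if ch != UNKNOWN_RESIDUE:
                replaced.add(ch)
    if replaced:
        logger.warning(
            "sequence %s: non-standard residue(s) %s mapped to X",
            seq_id,
            "".join(sorted(replaced)),
        )
    return "".join(out)


def read_fasta(path) -> list:
    """Read a multi-record FASTA file into ``AnnotatedSequence`` objects.

    Letters are uppercased; anything outside the 20-letter alphabet becomes
    ``X`` with a logged warning. Masks are all-zero. Record order is
    preserved. Empty files and duplicate ids are format errors.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    seen = set()
    out = []
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        residues = _sanitize(str(rec.seq), rec.id)
        if not residues:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        out.append(AnnotatedSequence(id=rec.id, residues=residues))
    return out


def write_fasta(path, sequences: Iterable[AnnotatedSequence], width: int = 60) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Interval labels


def read_labels(path, sequences: Sequence[AnnotatedSequence]) -> list:
    """Apply a TSV interval file (seq_id, start, end; 0-based half-open)
    to ``sequences``, returning new objects with MoRF masks set.

    Overlapping intervals are unioned; the result does not depend on the
    order of lines in the file.
    """
    by_id = {s.id: s for s in sequences}
    masks = {s.id: np.zeros(len(s), dtype=np.int8) for s in sequences}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 'seq_id<TAB>start<TAB>end'"
                )
            seq_id, start_s, end_s = parts
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if seq_id not in by_id:
                raise ValidationError(f"{path}:{lineno}: unknown sequence id {seq_id!r}")
            L = len(by_id[seq_id])
            if not (0 <= start < end <= L):
                raise ValidationError(
                    f"{path}:{lineno}: interval [{start}, {end}) out of range "
                    f"for sequence {seq_id!r} of length {L}"
                )
            masks[seq_id][start:end] = 1
    return [
        AnnotatedSequence(id=s.id, residues=s.residues, mask=masks[s.id])
        for s in sequences
    ]


def write_labels(path, sequences: Iterable[AnnotatedSequence]) -> None:
    """Write the maximal runs of mask==1 as 0-based half-open intervals."""
    with open(path, "w") as fh:
        for s in sequences:
            for start, end in mask_to_intervals(s.mask):
                fh.write(f"{s.id}\t{start}\t{end}\n")


def mask_to_intervals(mask: np.ndarray, state: int = 1) -> list:
    """Maximal runs of ``mask == state`` as (start, end) half-open pairs."""
    hits = np.flatnonzero(np.asarray(mask) == state)
    if hits.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(hits) > 1)
    starts = np.concatenate(([hits[0]], hits[breaks + 1]))
    ends = np.concatenate((hits[breaks] + 1, [hits[-1] + 1]))
    return list(zip(starts.tolist(), ends.tolist()))


# ---------------------------------------------------------------------------
# AAindex1


def read_aaindex1(path) -> list:
    """Parse an AAindex1 flat file into ``PropertyScale`` objects.

    Only the H (accession), D (description) and I (value) blocks are used.
    Values follow the canonical two-row A R N D C Q E G H I / L K M F P W
    Y V S T layout; ``NA`` parses to NaN and is rejected later, when a
    feature set actually resolves the scale.
    """
    scales = []
    entry_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.strip() == "//":
                if entry_lines:
                    scales.append(_parse_aaindex_entry(entry_lines, path))
                    entry_lines = []
            elif line.strip():
                entry_lines.append(line)
    if entry_lines:
        scales.append(_parse_aaindex_entry(entry_lines, path))
    if not scales:
        raise FormatError(f"{path}: no AAindex1 entries found")
    return scales


def _parse_aaindex_entry(lines: list, path) -> PropertyScale:
    accession = ""
    description = ""
    value_tokens: list[str] = []
    current_key = ""
    for line in lines:
        if line[:1].strip():  # new keyed block
            current_key = line[0]
            body = line[2:] if len(line) > 2 else ""
        else:  # continuation
            body = line
        if current_key == "H":
            accession = body.strip() or accession
        elif current_key == "D":
            description = (description + " " + body.strip()).strip()
        elif current_key == "I":
            if line[:1].strip():
                continue  # the I header row itself (A/L ... I/V)
            value_tokens.extend(body.split())
    if not accession:
        raise FormatError(f"{path}: AAindex entry without an H (accession) line")
    if len(value_tokens) != 20:
        raise FormatError(
            f"{path}: entry {accession}: expected 20 values in the I block, "
            f"got {len(value_tokens)}"
        )
    values = {}
    for letter, tok in zip(AAINDEX_ORDER, value_tokens):
        if tok.upper() == "NA":
            values[letter] = float("nan")
        else:
            try:
                values[letter] = float(tok)
            except ValueError as exc:
                raise FormatError(
                    f"{path}: entry {accession}: malformed value {tok!r}"
                ) from exc
    return PropertyScale(accession=accession, values=values, description=description)


# ---------------------------------------------------------------------------
# Per-residue score tables

_SCORE_HEADER = ["seq_id", "position", "residue", "score", "call"]


def write_scores(path, sequence: AnnotatedSequence, scores, threshold: float = 0.0,
                 append: bool = False) -> None:
    """Write a per-residue score table: seq_id, 1-based position, residue,
    score (fixed decimals), and the binary call ``score > threshold``."""
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (len(sequence),):
        raise ValidationError(
            f"{sequence.id}: {scores.size} scores for {len(sequence)} residues"
        )
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        if not append:
            fh.write("\t".join(_SCORE_HEADER) + "\n")
        for j, (aa, s) in enumerate(zip(sequence.residues, scores), start=1):
            call = 1 if s > threshold else 0
            fh.write(f"{sequence.id}\t{j}\t{aa}\t{s:.{SCORE_DECIMALS}f}\t{call}\n")


def read_scores(path) -> dict:
    """Read a score table back into ``{seq_id: (residues, scores, calls)}``."""
    out: dict = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _SCORE_HEADER:
            raise FormatError(f"{path}: unexpected score-table header {header}")
        for line in fh:
            seq_id, pos, aa, score, call = line.rstrip("\n").split("\t")
            res, sc, ca = out.setdefault(seq_id, ([], [], []))
            if int(pos) != len(res) + 1:
                raise FormatError(f"{path}: non-contiguous positions for {seq_id}")
            res.append(aa)
            sc.append(float(score))
            ca.append(int(call))
    return {
        k: ("".join(res), np.array(sc), np.array(ca, dtype=np.int8))
        for k, (res, sc, ca) in out.items()
    }


# ---------------------------------------------------------------------------
# Model files (JSON text; layout documented in morfmpm.mpm.MPMModel)

MODEL_FORMAT = "morfmpm-model"
MODEL_FORMAT_VERSION = 1


def write_model(path, model) -> None:
    payload = {"format": MODEL_FORMAT, "version": MODEL_FORMAT_VERSION}
    payload.update(model.to_dict())
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def read_model(path):
    from .mpm import MPMModel  # local import: io_formats is the lower layer

    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != MODEL_FORMAT:
        raise FormatError(f"{path}: not a {MODEL_FORMAT} file")
    if payload.get("version") != MODEL_FORMAT_VERSION:
        raise FormatError(f"{path}: unsupported model version {payload.get('version')}")
    return MPMModel.from_dict(payload)
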