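"""Cross-genome spectrum adjustment and cosine comparison.

A 96-channel SNV spectrum observed on one genome is adjusted to another
genome's trinucleotide composition by reweighting each channel with the
target-to-source context frequency ratio and renormalizing — the standard
signature-translation convention used to compare, e.g., worm spectra against
human cancer profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import ReferenceGenome
from .spectra import SCHEME

__all__ = [
    "CONTEXTS_32",
    "TrinucFreqs",
    "trinuc_frequencies",
    "adjust_spectrum",
    "cosine_similarity",
    "write_freqs",
    "read_freqs",
]

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: the 32 pyrimidine-centered trinucleotide contexts, C-centered first
CONTEXTS_32 = tuple(
    f"{five}{center}{three}" for center in "CT" for five in _BASES for three in _BASES
)
_CTX_INDEX = {c: i for i, c in enumerate(CONTEXTS_32)}

#: context id of each of the 96 SNV channels
_SNV_CONTEXT = np.array(
    [(0 if k < 48 else 16) + k % 16 for k in range(96)]
)


def _collapse(tri: str) -> str | None:
    if any(b not in _BASES for b in tri):
        return None
    if tri[1] in "CT":
        return tri
    return "".join(_COMP[b] for b in reversed(tri))


@dataclass(frozen=True)
class TrinucFreqs:
    """Normalized pyrimidine-centered trinucleotide frequencies of a genome."""

    source: str
    freqs: np.ndarray  # (32,), aligned to CONTEXTS_32

    def __post_init__(self) -> None:
        object.__setattr__(self, "freqs", np.asarray(self.freqs, float))
        if self.freqs.shape != (32,):
            raise ValueError("frequencies must have length 32")
        if (self.freqs < 0).any():
            raise ValueError("frequencies must be non-negative")
        if abs(self.freqs.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")

    def __getitem__(self, context: str) -> float:
        return float(self.freqs[_CTX_INDEX[context]])


def trinuc_frequencies(ref: ReferenceGenome, source: str = "") -> TrinucFreqs:
    """Count every overlapping trinucleotide (collapsed onto the 32
    pyrimidine-centered classes; windows containing N are skipped) and
    normalize."""
    code_of = np.full(256, -1, dtype=np.int16)
    for i, b in enumerate(_BASES):
        code_of[ord(b)] = i
    collapse_map = np.empty(64, dtype=np.int64)
    for c0 in range(4):
        for c1 in range(4):
            for c2 in range(4):
                tri = _BASES[c0] + _BASES[c1] + _BASES[c2]
                collapse_map[16 * c0 + 4 * c1 + c2] = _CTX_INDEX[_collapse(tri)]
    counts = np.zeros(32)
    for chrom in ref.chroms:
        arr = code_of[np.frombuffer(ref[chrom].encode("ascii"), dtype=np.uint8)]
        if len(arr) < 3:
            continue
        valid = (arr[:-2] >= 0) & (arr[1:-1] >= 0) & (arr[2:] >= 0)
        tri_codes = (16 * arr[:-2] + 4 * arr[1:-1] + arr[2:])[valid]
        counts += np.bincount(collapse_map[tri_codes], minlength=32)
    total = counts.sum()
    if total == 0:
        raise ValueError("genome contains no valid trinucleotide")
    return TrinucFreqs(source=source, freqs=counts / total)


def adjust_spectrum(
    spectrum: np.ndarray,
    from_freqs: TrinucFreqs,
    to_freqs: TrinucFreqs,
) -> np.ndarray:
    """Reweight each SNV channel by to/from context frequency, renormalize.

    Accepts a 96-vector (SNV-only) or a full 119-vector, in which case the
    non-SNV channels pass through unweighted before the final renormalization.
    Returns a normalized spectrum (sums to 1).
    """
    s = np.asarray(spectrum, float)
    if s.shape not in ((96,), (119,)):
        raise ValueError("spectrum must have length 96 or 119")
    if (s < 0).any():
        raise ValueError("spectrum must be non-negative")
    src = from_freqs.freqs[_SNV_CONTEXT]
    if np.any((s[:96] > 0) & (src == 0)):
        raise ValueError("zero source frequency for a context with observed mutations")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(src > 0, to_freqs.freqs[_SNV_CONTEXT] / np.maximum(src, 1e-300), 0.0)
    out = s.copy()
    out[:96] = s[:96] * ratio
    total = out.sum()
    if total == 0:
        raise ValueError("adjusted spectrum is identically zero")
    return out / total


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """dot(a, b) / (|a| |b|); scale-invariant, in [0, 1] for non-negative inputs."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


def write_freqs(freqs: TrinucFreqs, path: str | Path) -> None:
    pd.DataFrame({"context": CONTEXTS_32, "frequency": freqs.freqs}).to_csv(
        path, sep="\t", index=False
    )


def read_freqs(path: str | Path, source: str = "") -> TrinucFreqs:
    df = pd.read_csv(path, sep="\t")
    vec = np.empty(32)
    for _, row in df.iterrows():
        vec[_CTX_INDEX[row["context"]]] = row["frequency"]
    return TrinucFreqs(source=source or str(path), freqs=vec)
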