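"""The fixed 119-channel mutation classification and per-sample count spectra.

The scheme follows the COSMIC pyrimidine-centered convention for the 96 SNV
channels (6 substitution types x 16 flanking-base contexts), adds one DNV and
one MNV aggregate channel, 14 indel channels binned by type and size, and 7
structural-variant channels — 119 in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import ReferenceGenome, SvType, VarClass, VariantRecord

__all__ = [
    "ChannelScheme",
    "MutationSpectrum",
    "UnclassifiableVariant",
    "SCHEME",
    "classify_variant",
    "count_spectrum",
    "class_totals",
    "aggregate_spectra",
    "write_spectrum_matrix",
    "read_spectrum_matrix",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

SUBSTITUTION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_FLANKS = "ACGT"

#: indel size bins: (label suffix, lo, hi) on the pure event length
_DEL_BINS = (("1", 1, 1), ("2-5", 2, 5), ("6-50", 6, 50), ("51-400", 51, 400), (">400", 401, None))
_INS_BINS = _DEL_BINS
_DELINS_BINS = (("1-5", 1, 5), ("6-50", 6, 50), ("51-400", 51, 400), (">400", 401, None))

SV_TYPES = ("TD", "DEL", "INV", "COMPLEX", "TRSL", "INTCHR", "FOLDBACK")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class UnclassifiableVariant(Exception):
    """Variant has no defined channel (N in context, or chromosome-boundary SNV)."""


def _build_labels() -> tuple[str, ...]:
    labels = [
        f"{five}[{sub}]{three}"
        for sub in SUBSTITUTION_TYPES
        for five in _FLANKS
        for three in _FLANKS
    ]
    labels += ["DNV", "MNV"]
    labels += [f"DEL:{b[0]}" for b in _DEL_BINS]
    labels += [f"INS:{b[0]}" for b in _INS_BINS]
    labels += [f"DELINS:{b[0]}" for b in _DELINS_BINS]
    labels += [f"SV:{t}" for t in SV_TYPES]
    return tuple(labels)


@dataclass(frozen=True)
class ChannelScheme:
    """Ordered labels of the 119 channels; index lookup is a bijection."""

    labels: tuple[str, ...] = field(default_factory=_build_labels)

    def __post_init__(self) -> None:
        assert len(self.labels) == 119, len(self.labels)
        assert len(set(self.labels)) == 119
        assert self.n_snv == 96 and self.n_indel == 14 and self.n_sv == 7

    n_snv = 96
    n_substitution = 98  # 96 SNV + DNV + MNV
    n_indel = 14
    n_sv = 7

    def __len__(self) -> int:
        return 119

    def index(self, label: str) -> int:
        return self.labels.index(label)

    @property
    def snv_slice(self) -> slice:
        return slice(0, 96)

    @property
    def substitution_slice(self) -> slice:
        return slice(0, 98)

    @property
    def indel_slice(self) -> slice:
        return slice(98, 112)

    @property
    def sv_slice(self) -> slice:
        return slice(112, 119)

    def class_of(self, index: int) -> str:
        """Reporting class of a channel: snv, dnv, mnv, indel or sv."""
        if index < 96:
            return "snv"
        if index == 96:
            return "dnv"
        if index == 97:
            return "mnv"
        if index < 112:
            return "indel"
        return "sv"

    def class_indices(self) -> np.ndarray:
        """Integer class code per channel (0=snv, 1=dnv, 2=mnv, 3=indel, 4=sv)."""
        codes = {"snv": 0, "dnv": 1, "mnv": 2, "indel": 3, "sv": 4}
        return np.array([codes[self.class_of(k)] for k in range(119)])


SCHEME = ChannelScheme()

_SNV_INDEX = {lab: i for i, lab in enumerate(SCHEME.labels[:96])}
_SV_INDEX = {t: 112 + i for i, t in enumerate(SV_TYPES)}


def _size_bin_index(bins, base: int, length: int) -> int:
    for i, (_, lo, hi) in enumerate(bins):
        if length >= lo and (hi is None or length <= hi):
            return base + i
    raise AssertionError("unreachable: bins cover all lengths >= 1")


def snv_channel(five: str, ref: str, alt: str, three: str) -> int:
    """Channel index of a single-base substitution given its flanks.

    Purine reference bases are reverse-complemented (mutated base and both
    flanks) onto the pyrimidine-centered channel.
    """
    if ref in "AG":
        five, ref, alt, three = revcomp(three), revcomp(ref), revcomp(alt), revcomp(five)
    return _SNV_INDEX[f"{five}[{ref}>{alt}]{three}"]


def classify_variant(v: VariantRecord, ref_genome: ReferenceGenome) -> int:
    """Map one variant to its channel index in the 119-channel scheme.

    Raises :class:`UnclassifiableVariant` for SNVs whose trinucleotide context
    is undefined (chromosome boundary or N), and ``ValueError`` when the
    reference base disagrees with the supplied genome.
    """
    if v.var_class is VarClass.SV:
        return _SV_INDEX[v.sv_type.value]
    if v.var_class is VarClass.SNV:
        if v.pos < 2 or v.pos + 1 > ref_genome.length(v.chrom):
            raise UnclassifiableVariant(f"{v.chrom}:{v.pos} at chromosome boundary")
        context = ref_genome.slice(v.chrom, v.pos - 1, v.pos + 1)
        if context[1] != v.ref:
            raise ValueError(
                f"reference mismatch at {v.chrom}:{v.pos}: genome has {context[1]}, record {v.ref}"
            )
        if "N" in context:
            raise UnclassifiableVariant(f"{v.chrom}:{v.pos} context contains N")
        return snv_channel(context[0], v.ref, v.alt, context[2])
    if v.var_class is VarClass.DNV:
        return 96
    if v.var_class is VarClass.MNV:
        return 97
    if v.var_class is VarClass.DEL:
        return _size_bin_index(_DEL_BINS, 98, len(v.ref))
    if v.var_class is VarClass.INS:
        return _size_bin_index(_INS_BINS, 103, len(v.alt))
    if v.var_class is VarClass.INDEL:
        return _size_bin_index(_DELINS_BINS, 108, len(v.ref))
    raise AssertionError(f"unhandled class {v.var_class}")


@dataclass
class MutationSpectrum:
    """Per-sample (or aggregated) counts over the 119 channels."""

    sample_id: str
    counts: np.ndarray
    unclassified: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (119,):
            raise ValueError(f"counts must have length 119, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("negative channel counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def count_spectrum(
    variants: Iterable[VariantRecord],
    ref_genome: ReferenceGenome,
    sample_id: str | None = None,
) -> MutationSpectrum:
    """Count one sample's variants into a 119-channel spectrum.

    Unclassifiable records (undefined SNV context) are excluded from the
    counts and reported via ``unclassified``; classified + unclassified always
    equals the number of input records.
    """
    counts = np.zeros(119, dtype=np.int64)
    unclassified = 0
    sid = sample_id
    for v in variants:
        if sid is None:
            sid = v.sample_id
        try:
            counts[classify_variant(v, ref_genome)] += 1
        except UnclassifiableVariant:
            unclassified += 1
    return MutationSpectrum(sample_id=sid or "", counts=counts, unclassified=unclassified)


def class_totals(s: MutationSpectrum) -> dict[str, int]:
    """Totals per reporting class: substitutions (SNV+DNV+MNV), indels, SVs."""
    c = s.counts
    return {
        "substitutions": int(c[SCHEME.substitution_slice].sum()),
        "indels": int(c[SCHEME.indel_slice].sum()),
        "SVs": int(c[SCHEME.sv_slice].sum()),
    }


def aggregate_spectra(spectra: Sequence[MutationSpectrum], label: str) -> MutationSpectrum:
    counts = np.sum([s.counts for s in spectra], axis=0) if spectra else np.zeros(119, int)
    return MutationSpectrum(
        sample_id=label,
        counts=counts,
        unclassified=sum(s.unclassified for s in spectra),
    )


def write_spectrum_matrix(spectra: Sequence[MutationSpectrum], path: str | Path) -> None:
    """Spectrum matrix TSV: rows = samples, 119 labeled columns + 'unclassified'."""
    df = pd.DataFrame(
        [list(s.counts) + [s.unclassified] for s in spectra],
        index=[s.sample_id for s in spectra],
        columns=list(SCHEME.labels) + ["unclassified"],
    )
    df.index.name = "sample"
    df.to_csv(path, sep="\t")


def read_spectrum_matrix(path: str | Path) -> list[MutationSpectrum]:
    df = pd.read_csv(path, sep="\t", index_col="sample")
    out = []
    for sample, row in df.iterrows():
        out.append(
            MutationSpectrum(
                sample_id=str(sample),
                counts=row[list(SCHEME.labels)].to_numpy(dtype=np.int64),
                unclassified=int(row.get("unclassified", 0)),
            )
        )
    return out
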