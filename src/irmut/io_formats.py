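"""Record model and readers/writers for the standard formats the pipeline touches.

Coordinates are 1-based inclusive throughout (VCF convention). Indels are
normalized to an *unanchored* internal form: ``ref`` holds the deleted bases,
``alt`` the inserted bases, with the shared VCF anchor base left-trimmed, so
that classification sees pure event lengths.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pysam
from Bio import SeqIO

__all__ = [
    "VarClass",
    "SvType",
    "VariantRecord",
    "SampleMeta",
    "ReferenceGenome",
    "VcfParseError",
    "read_variants",
    "write_variants",
    "read_reference",
    "write_reference",
    "read_sample_sheet",
    "write_sample_sheet",
]


class VarClass(str, Enum):
    SNV = "SNV"
    DNV = "DNV"
    MNV = "MNV"
    INS = "INS"
    DEL = "DEL"
    INDEL = "INDEL"  # deletion-with-insertion (replacement of unequal length)
    SV = "SV"


class SvType(str, Enum):
    TD = "TD"
    DEL = "DEL"
    INV = "INV"
    TRSL = "TRSL"
    INTCHR = "INTCHR"
    FOLDBACK = "FOLDBACK"
    COMPLEX = "COMPLEX"


#: SVTYPE INFO strings -> internal 7-type enum.
SVTYPE_MAP: Mapping[str, SvType] = {
    "DUP": SvType.TD,
    "TD": SvType.TD,
    "DEL": SvType.DEL,
    "INV": SvType.INV,
    "TRSL": SvType.TRSL,
    "INTCHR": SvType.INTCHR,
    "FOLDBACK": SvType.FOLDBACK,
    "COMPLEX": SvType.COMPLEX,
}

_INTRA_CHROM_SV = {SvType.TD, SvType.DEL, SvType.INV, SvType.TRSL, SvType.FOLDBACK, SvType.COMPLEX}

_BASES = set("ACGT")


class VcfParseError(ValueError):
    """Raised when a VCF body line cannot be converted to a VariantRecord."""


@dataclass(frozen=True, order=True)
class VariantRecord:
    """One called mutation attributed to a sample.

    ``pos`` is the 1-based position of the first affected reference base.
    For pure insertions, the insertion occurs immediately before ``pos``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    var_class: VarClass = field(compare=False)
    sample_id: str = field(default="", compare=False)
    sv_type: SvType | None = field(default=None, compare=False)
    sv_end_chrom: str | None = field(default=None, compare=False)
    sv_end: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.var_class is VarClass.SV:
            if self.sv_type is None:
                raise ValueError("SV records require sv_type")
            if self.sv_type in _INTRA_CHROM_SV and self.sv_end is None:
                raise ValueError(f"intra-chromosomal SV type {self.sv_type.value} requires sv_end")
        else:
            if self.sv_type is not None:
                raise ValueError("sv_type only allowed for var_class=SV")
            for allele, name in ((self.ref, "ref"), (self.alt, "alt")):
                if set(allele) - _BASES:
                    raise ValueError(f"{name} contains non-ACGT characters: {allele!r}")
            expected = _classify_alleles(self.ref, self.alt)
            if expected is not self.var_class:
                raise ValueError(
                    f"ref={self.ref!r} alt={self.alt!r} implies {expected}, got {self.var_class}"
                )


def _classify_alleles(ref: str, alt: str) -> VarClass:
    """Classify an unanchored ref/alt pair into the non-SV variant classes."""
    if ref == alt:
        raise ValueError("ref equals alt")
    if len(ref) == len(alt):
        if len(ref) == 1:
            return VarClass.SNV
        if len(ref) == 2:
            return VarClass.DNV
        if len(ref) >= 3:
            return VarClass.MNV
        raise ValueError("empty ref and alt")
    if not ref:
        return VarClass.INS
    if not alt:
        return VarClass.DEL
    return VarClass.INDEL


def _trim_anchor(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Left-trim the shared prefix of an anchored VCF ref/alt pair."""
    i = 0
    while i < len(ref) and i < len(alt) and ref[i] == alt[i]:
        i += 1
    return pos + i, ref[i:], alt[i:]


@dataclass(frozen=True)
class SampleMeta:
    """Sample-sheet row: one sequenced clonal line."""

    sample_id: str
    genotype: str
    dose_gy: float
    replicate: int
    generation: str = "F1"

    def __post_init__(self) -> None:
        if not (0 <= self.dose_gy <= 200):
            raise ValueError(f"dose_gy outside sanity bound [0, 200]: {self.dose_gy}")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")


class ReferenceGenome:
    """In-memory reference: chrom -> uppercase sequence over {A,C,G,T,N}."""

    def __init__(self, sequences: Mapping[str, str]):
        if not sequences:
            raise ValueError("reference genome is empty")
        self._seqs: dict[str, str] = {c: s.upper() for c, s in sequences.items()}

    @property
    def chroms(self) -> list[str]:
        return list(self._seqs)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def base(self, chrom: str, pos: int) -> str:
        """Base at a 1-based position."""
        return self.slice(chrom, pos, pos)

    def slice(self, chrom: str, start: int, end: int) -> str:
        """1-based inclusive slice [start, end]."""
        seq = self._seqs[chrom]
        if start < 1 or end > len(seq) or start > end:
            raise IndexError(f"{chrom}:{start}-{end} outside [1, {len(seq)}]")
        return seq[start - 1 : end]


def read_reference(fasta_path: str | Path) -> ReferenceGenome:
    """Read a FASTA into memory, uppercasing; duplicate names are an error."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate chromosome name in FASTA: {rec.id}")
        seqs[rec.id] = str(rec.seq).upper()
    return ReferenceGenome(seqs)


def write_reference(genome: ReferenceGenome, fasta_path: str | Path, width: int = 60) -> None:
    with open(fasta_path, "w") as fh:
        for chrom in genome.chroms:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_SHEET_COLUMNS = ["sample", "genotype", "dose_gy", "replicate", "generation"]


def read_sample_sheet(tsv_path: str | Path) -> list[SampleMeta]:
    """Read the TSV sample sheet (columns sample, genotype, dose_gy, replicate, generation)."""
    df = pd.read_csv(tsv_path, sep="\t", dtype={"sample": str, "genotype": str, "generation": str})
    missing = set(_SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if df["sample"].duplicated().any():
        dups = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"duplicate sample ids in sheet: {dups}")
    metas = []
    for row in df.itertuples(index=False):
        if row.dose_gy < 0:
            raise ValueError(f"negative dose for sample {row.sample}: {row.dose_gy}")
        metas.append(
            SampleMeta(
                sample_id=row.sample,
                genotype=row.genotype,
                dose_gy=float(row.dose_gy),
                replicate=int(row.replicate),
                generation=str(row.generation),
            )
        )
    return metas


def write_sample_sheet(metas: Iterable[SampleMeta], tsv_path: str | Path) -> None:
    df = pd.DataFrame(
        [(m.sample_id, m.genotype, m.dose_gy, m.replicate, m.generation) for m in metas],
        columns=_SHEET_COLUMNS,
    )
    df.to_csv(tsv_path, sep="\t", index=False)


_BND_RE = re.compile(r"[\[\]]([^\[\]:]+):(\d+)[\[\]]")


def _sv_record(
    sample_id: str,
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    svtype_str: str,
    end: int | None,
    strict: bool,
    lineno: int,
) -> VariantRecord:
    alt_u = alt.upper()
    if svtype_str == "BND" or "[" in alt_u or "]" in alt_u:
        m = _BND_RE.search(alt_u)
        if m is None:
            raise VcfParseError(f"line {lineno}: unparseable breakend ALT {alt!r}")
        mate_chrom, mate_pos = m.group(1), int(m.group(2))
        if mate_chrom == chrom:
            return VariantRecord(
                chrom=chrom, pos=pos, ref="", alt="", var_class=VarClass.SV,
                sample_id=sample_id, sv_type=SvType.TRSL, sv_end_chrom=chrom, sv_end=mate_pos,
            )
        return VariantRecord(
            chrom=chrom, pos=pos, ref="", alt="", var_class=VarClass.SV,
            sample_id=sample_id, sv_type=SvType.INTCHR, sv_end_chrom=mate_chrom, sv_end=mate_pos,
        )
    sv_type = SVTYPE_MAP.get(svtype_str)
    if sv_type is None:
        if strict:
            raise VcfParseError(f"line {lineno}: unknown SVTYPE {svtype_str!r}")
        warnings.warn(f"line {lineno}: unknown SVTYPE {svtype_str!r} mapped to COMPLEX")
        sv_type = SvType.COMPLEX
    if end is None and sv_type in _INTRA_CHROM_SV:
        raise VcfParseError(f"line {lineno}: SVTYPE={svtype_str} without END")
    return VariantRecord(
        chrom=chrom, pos=pos, ref="", alt="", var_class=VarClass.SV,
        sample_id=sample_id, sv_type=sv_type,
        sv_end_chrom=chrom if end is not None else None, sv_end=end,
    )


def read_variants(vcf_path: str | Path, sample_id: str, strict: bool = False) -> list[VariantRecord]:
    """Read a VCF v4.x into VariantRecords, sorted by (chrom, pos, ref, alt).

    Multi-allelic lines are split into one record per ALT. SVTYPE strings are
    mapped onto the 7-type enum via :data:`SVTYPE_MAP`; breakend (BND) ALTs
    become TRSL when intra-chromosomal and INTCHR otherwise. With
    ``strict=True`` an unknown SVTYPE is an error instead of COMPLEX.
    """
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        header_lines = str(vcf.header).count("\n")
        for i, rec in enumerate(vcf):
            lineno = header_lines + 1 + i
            try:
                records.extend(_parse_vcf_record(rec, sample_id, strict, lineno))
            except VcfParseError:
                raise
            except ValueError as exc:
                raise VcfParseError(f"line {lineno}: {exc}") from exc
    records.sort(key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    return records


def _parse_vcf_record(
    rec: pysam.VariantRecord, sample_id: str, strict: bool, lineno: int
) -> list[VariantRecord]:
    try:
        svtype = rec.info.get("SVTYPE")
    except (KeyError, ValueError):  # SVTYPE not defined in this header
        svtype = None
    out = []
    for alt in rec.alts or ():
        if svtype is not None or alt.startswith("<") or "[" in alt or "]" in alt:
            # pysam folds INFO/END into rec.stop (0-based exclusive == 1-based inclusive)
            end = rec.stop if rec.stop > rec.pos else None
            out.append(
                _sv_record(sample_id, rec.chrom, rec.pos, rec.ref, alt,
                           str(svtype) if svtype else "BND", end, strict, lineno)
            )
            continue
        pos, ref_t, alt_t = _trim_anchor(rec.pos, rec.ref.upper(), alt.upper())
        if ref_t == alt_t:
            raise VcfParseError(f"line {lineno}: ref equals alt after anchor trimming")
        var_class = _classify_alleles(ref_t, alt_t)
        out.append(
            VariantRecord(chrom=rec.chrom, pos=pos, ref=ref_t, alt=alt_t,
                          var_class=var_class, sample_id=sample_id)
        )
    return out


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Structural variant type">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of structural variant">
{contigs}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_variants(
    records: Iterable[VariantRecord],
    vcf_path: str | Path,
    genome: ReferenceGenome,
) -> None:
    """Write records as VCF v4.2, re-anchoring indels against the reference.

    SVs are written with symbolic ALTs (``<DUP>``, ``<DEL>``, ``<INV>``,
    ``<COMPLEX>``, ``<FOLDBACK>``) plus SVTYPE/END, except translocations and
    inter-chromosomal events which use breakend notation.
    """
    contigs = "".join(f"##contig=<ID={c},length={genome.length(c)}>\n" for c in genome.chroms)
    lines = [_VCF_HEADER.format(contigs=contigs)]
    order = {c: i for i, c in enumerate(genome.chroms)}
    for r in sorted(records, key=lambda r: (order.get(r.chrom, 1 << 30), r.pos, r.ref, r.alt)):
        lines.append(_format_vcf_line(r, genome) + "\n")
    Path(vcf_path).write_text("".join(lines))


def _format_vcf_line(r: VariantRecord, genome: ReferenceGenome) -> str:
    if r.var_class is VarClass.SV:
        ref = genome.base(r.chrom, r.pos)
        if r.sv_type is SvType.INTCHR:
            alt = f"{ref}[{r.sv_end_chrom}:{r.sv_end}["
            info = "SVTYPE=BND"
        elif r.sv_type is SvType.TRSL:
            alt = f"{ref}[{r.sv_end_chrom}:{r.sv_end}["
            info = "SVTYPE=BND"
        else:
            symbolic = {"TD": "DUP", "DEL": "DEL", "INV": "INV",
                        "COMPLEX": "COMPLEX", "FOLDBACK": "FOLDBACK"}[r.sv_type.value]
            alt = f"<{symbolic}>"
            info = f"SVTYPE={symbolic};END={r.sv_end}"
        return f"{r.chrom}\t{r.pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}"
    if len(r.ref) == len(r.alt) and r.ref:
        # substitution: written unanchored
        return f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t."
    # indel: re-anchor on the base before the event
    anchor_pos = r.pos - 1
    if anchor_pos < 1:
        raise ValueError(f"cannot anchor indel at {r.chrom}:{r.pos} (chromosome start)")
    anchor = genome.base(r.chrom, anchor_pos)
    return f"{r.chrom}\t{anchor_pos}\t.\t{anchor}{r.ref}\t{anchor}{r.alt}\t.\tPASS\t."
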