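"""Synthetic irradiation experiments with the statistical structure the analysis assumes.

Each simulated sample is a clonal F1 line: channel-k counts are drawn as
Poisson(background_k + (dose/80) * ir_rate_k * exp(lfc_{genotype,k})) and
realized as concrete variant records placed on a generated toy genome, with a
configurable fraction of substitutions and indels re-placed into tight
clusters (by default 2-3 mutations spanning 10-20 bp, emulating the clustered
lesions ionizing radiation leaves behind).

The defaults of :func:`default_wildtype_config` are the wild-type study
conditions: triplicate lines at 0/20/40/60/80 Gy, a flat ionizing-radiation
SNV signature totalling 36.63 SNVs per 80 Gy, 1.3 DNVs, 4 indels and 1.4 SVs
per 80 Gy, and 6% of mutations in clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io_formats import (
    ReferenceGenome,
    SampleMeta,
    SvType,
    VarClass,
    VariantRecord,
    write_reference,
    write_sample_sheet,
    write_variants,
)
from .spectra import SCHEME, SUBSTITUTION_TYPES

__all__ = [
    "SimConfig",
    "default_wildtype_config",
    "simulate_experiment",
    "write_experiment",
    "WILDTYPE",
]

WILDTYPE = "wild-type"

_BASES = "ACGT"
_PYRIMIDINES = "CT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

# per-80-Gy wild-type class totals (expected counts per genome)
WT_SNV_PER_80GY = 36.63
WT_DNV_PER_80GY = 1.3
WT_MNV_PER_80GY = 0.0
WT_INDEL_PER_80GY = 4.0
WT_SV_PER_80GY = 1.4
WT_CLUSTER_FRACTION = 0.06


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    genome: tuple[tuple[str, int], ...] = (
        ("chrI", 1_000_000),
        ("chrII", 1_000_000),
        ("chrIII", 1_000_000),
        ("chrIV", 1_000_000),
        ("chrV", 1_000_000),
    )
    doses_gy: tuple[float, ...] = (0.0, 20.0, 40.0, 60.0, 80.0)
    replicates_per_dose: int = 3
    background_per_genome: np.ndarray = field(
        default_factory=lambda: np.full(119, 1.0 / 119)
    )
    ir_rate_per_80gy: np.ndarray = field(default_factory=lambda: np.zeros(119))
    genotype_lfc: dict[str, np.ndarray] = field(
        default_factory=lambda: {WILDTYPE: np.zeros(119)}
    )
    cluster_fraction: float = 0.0
    cluster_size_range: tuple[int, int] = (2, 3)
    cluster_span_range: tuple[int, int] = (10, 20)
    generation: str = "F1"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "background_per_genome", np.asarray(self.background_per_genome, float)
        )
        object.__setattr__(self, "ir_rate_per_80gy", np.asarray(self.ir_rate_per_80gy, float))
        for name, vec in (
            ("background_per_genome", self.background_per_genome),
            ("ir_rate_per_80gy", self.ir_rate_per_80gy),
        ):
            if vec.shape != (119,):
                raise ValueError(f"{name} must have length 119")
            if (vec < 0).any():
                raise ValueError(f"{name} must be non-negative")
        lfc = {g: np.asarray(v, float) for g, v in self.genotype_lfc.items()}
        for g, v in lfc.items():
            if v.shape != (119,):
                raise ValueError(f"genotype_lfc[{g!r}] must have length 119")
        object.__setattr__(self, "genotype_lfc", lfc)
        if not (0.0 <= self.cluster_fraction <= 1.0):
            raise ValueError("cluster_fraction must lie in [0, 1]")
        lo, hi = self.cluster_size_range
        if not (2 <= lo <= hi <= 10):
            raise ValueError("cluster_size_range must lie within [2, 10]")
        lo, hi = self.cluster_span_range
        if not (2 <= lo <= hi <= 1000):
            raise ValueError("cluster_span_range must lie within [2, 1000]")
        if self.replicates_per_dose < 1:
            raise ValueError("replicates_per_dose must be >= 1")
        if not self.genome:
            raise ValueError("genome must list at least one chromosome")

    def with_genotype(self, genotype: str, lfc: np.ndarray) -> "SimConfig":
        """Return a copy with an additional genotype and its per-channel LFC."""
        new = dict(self.genotype_lfc)
        new[genotype] = np.asarray(lfc, float)
        return replace(self, genotype_lfc=new)

    def expected_counts(self, genotype: str, dose_gy: float) -> np.ndarray:
        """Per-channel Poisson mean for one sample."""
        return self.background_per_genome + (dose_gy / 80.0) * self.ir_rate_per_80gy * np.exp(
            self.genotype_lfc[genotype]
        )


def default_wildtype_config(seed: int = 0) -> SimConfig:
    """Wild-type study conditions: flat within-class per-80-Gy IR rates.

    The SNV signature is flat across all 96 trinucleotide channels (ionizing
    radiation affects all nucleotides roughly equally); indel and SV mass is
    spread evenly over their channels. Background (dose-independent) burden is
    a flat vector totalling 1 mutation per genome.
    """
    ir = np.zeros(119)
    ir[SCHEME.snv_slice] = WT_SNV_PER_80GY / 96
    ir[96] = WT_DNV_PER_80GY
    ir[97] = WT_MNV_PER_80GY
    ir[SCHEME.indel_slice] = WT_INDEL_PER_80GY / 14
    ir[SCHEME.sv_slice] = WT_SV_PER_80GY / 7
    return SimConfig(
        seed=seed,
        ir_rate_per_80gy=ir,
        cluster_fraction=WT_CLUSTER_FRACTION,
        cluster_size_range=(2, 3),
        cluster_span_range=(10, 20),
    )


# ---------------------------------------------------------------------------
# genome construction and context indexing

_CONTEXTS_32 = tuple(
    f"{five}{center}{three}" for center in "CT" for five in _BASES for three in _BASES
)
_CTX_ID = {c: i for i, c in enumerate(_CONTEXTS_32)}


def _collapse(ctx: str) -> str:
    """Collapse a trinucleotide onto its pyrimidine-centered representative."""
    if ctx[1] in _PYRIMIDINES:
        return ctx
    return "".join(_COMP[b] for b in reversed(ctx))


def generate_genome(cfg: SimConfig, rng: np.random.Generator) -> ReferenceGenome:
    """I.i.d. uniform-base toy genome; all 32 contexts present w.h.p."""
    base_bytes = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs = {}
    for chrom, length in cfg.genome:
        codes = rng.integers(0, 4, size=length)
        seqs[chrom] = base_bytes[codes].tobytes().decode("ascii")
    return ReferenceGenome(seqs)


class _GenomeIndex:
    """Positions of every pyrimidine-collapsed trinucleotide context."""

    def __init__(self, genome: ReferenceGenome):
        self.genome = genome
        self.chroms = genome.chroms
        self.lengths = np.array([genome.length(c) for c in self.chroms])
        self.starts = np.concatenate([[0], np.cumsum(self.lengths)])[:-1]
        code_of = np.full(256, -1, dtype=np.int8)
        for i, b in enumerate(_BASES):
            code_of[ord(b)] = i
        ctx_chunks, pos_chunks = [], []
        # map 64 trinucleotide codes onto the 32 collapsed context ids
        collapse_map = np.empty(64, dtype=np.int8)
        for c0 in range(4):
            for c1 in range(4):
                for c2 in range(4):
                    tri = _BASES[c0] + _BASES[c1] + _BASES[c2]
                    collapse_map[16 * c0 + 4 * c1 + c2] = _CTX_ID[_collapse(tri)]
        for ci, chrom in enumerate(self.chroms):
            arr = code_of[np.frombuffer(genome[chrom].encode("ascii"), dtype=np.uint8)]
            if len(arr) < 3:
                continue
            tri_codes = 16 * arr[:-2] + 4 * arr[1:-1] + arr[2:]
            valid = (arr[:-2] >= 0) & (arr[1:-1] >= 0) & (arr[2:] >= 0)
            ctx = np.where(valid, collapse_map[np.clip(tri_codes, 0, 63)], -1)
            ctx_chunks.append(ctx)
            # global 0-based index of the center base
            pos_chunks.append(np.arange(1, len(arr) - 1, dtype=np.int64) + self.starts[ci])
        all_ctx = np.concatenate(ctx_chunks)
        all_pos = np.concatenate(pos_chunks)
        keep = all_ctx >= 0
        all_ctx, all_pos = all_ctx[keep], all_pos[keep]
        order = np.argsort(all_ctx, kind="stable")
        sorted_ctx = all_ctx[order]
        sorted_pos = all_pos[order]
        bounds = np.searchsorted(sorted_ctx, np.arange(33))
        self.context_positions = [sorted_pos[bounds[i] : bounds[i + 1]] for i in range(32)]

    def locate(self, gpos: int) -> tuple[str, int]:
        """Global 0-based index -> (chrom, 1-based position)."""
        ci = int(np.searchsorted(self.starts, gpos, side="right")) - 1
        return self.chroms[ci], int(gpos - self.starts[ci]) + 1


# ---------------------------------------------------------------------------
# record realization

def _snv_alt(base: str, sub: str) -> str:
    """Alt base at a genome position for a pyrimidine-centered substitution type."""
    target = sub[2]
    return target if base in _PYRIMIDINES else _COMP[target]


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _substituted(rng: np.random.Generator, ref: str) -> str:
    """Random same-length alt with every base changed."""
    out = []
    for b in ref:
        choices = [x for x in _BASES if x != b]
        out.append(choices[rng.integers(0, 3)])
    return "".join(out)


_DEL_SIZE = [(1, 1), (2, 5), (6, 50), (51, 400), (401, 1000)]
_DELINS_SIZE = [(1, 5), (6, 50), (51, 400), (401, 1000)]


def _draw_len(rng: np.random.Generator, lo: int, hi: int) -> int:
    return int(rng.integers(lo, hi + 1))


class _Realizer:
    def __init__(self, cfg: SimConfig, index: _GenomeIndex, rng: np.random.Generator):
        self.cfg = cfg
        self.idx = index
        self.rng = rng
        self.genome = index.genome

    def _random_locus(self, margin_left: int = 2, margin_right: int = 2) -> tuple[str, int]:
        weights = self.idx.lengths / self.idx.lengths.sum()
        ci = int(self.rng.choice(len(self.idx.chroms), p=weights))
        chrom = self.idx.chroms[ci]
        length = int(self.idx.lengths[ci])
        pos = int(self.rng.integers(margin_left, length - margin_right + 1))
        return chrom, pos

    def realize(self, sample_id: str, channel: int) -> VariantRecord:
        rng, genome = self.rng, self.genome
        if channel < 96:
            sub = SUBSTITUTION_TYPES[channel // 16]
            ctx_id = (0 if channel < 48 else 16) + channel % 16
            positions = self.idx.context_positions[ctx_id]
            if len(positions) == 0:
                raise RuntimeError(f"context {_CONTEXTS_32[ctx_id]} absent from toy genome")
            gpos = int(positions[rng.integers(0, len(positions))])
            chrom, pos = self.idx.locate(gpos)
            base = genome.base(chrom, pos)
            return VariantRecord(
                chrom=chrom, pos=pos,
                ref=base, alt=_snv_alt(base, sub),
                var_class=VarClass.SNV, sample_id=sample_id,
            )
        if channel == 96:  # DNV
            chrom, pos = self._random_locus(2, 2)
            ref = genome.slice(chrom, pos, pos + 1)
            return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=_substituted(rng, ref),
                                 var_class=VarClass.DNV, sample_id=sample_id)
        if channel == 97:  # MNV
            chrom, pos = self._random_locus(2, 3)
            ref = genome.slice(chrom, pos, pos + 2)
            return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=_substituted(rng, ref),
                                 var_class=VarClass.MNV, sample_id=sample_id)
        if channel < 103:  # DEL bins
            lo, hi = _DEL_SIZE[channel - 98]
            n = _draw_len(rng, lo, hi)
            chrom, pos = self._random_locus(2, n + 1)
            return VariantRecord(chrom=chrom, pos=pos, ref=genome.slice(chrom, pos, pos + n - 1),
                                 alt="", var_class=VarClass.DEL, sample_id=sample_id)
        if channel < 108:  # INS bins
            lo, hi = _DEL_SIZE[channel - 103]
            n = _draw_len(rng, lo, hi)
            chrom, pos = self._random_locus(2, 2)
            return VariantRecord(chrom=chrom, pos=pos, ref="", alt=_random_bases(rng, n),
                                 var_class=VarClass.INS, sample_id=sample_id)
        if channel < 112:  # DELINS bins (binned by deleted length)
            lo, hi = _DELINS_SIZE[channel - 108]
            n = _draw_len(rng, lo, hi)
            alt_choices = [m for m in (1, 2, 3) if m != n]
            alt_len = alt_choices[rng.integers(0, len(alt_choices))]
            chrom, pos = self._random_locus(2, n + 1)
            return VariantRecord(chrom=chrom, pos=pos, ref=genome.slice(chrom, pos, pos + n - 1),
                                 alt=_random_bases(rng, alt_len),
                                 var_class=VarClass.INDEL, sample_id=sample_id)
        # SV channels
        sv_type = SvType(SCHEME.labels[channel].split(":")[1])
        if sv_type is SvType.INTCHR:
            if len(self.idx.chroms) < 2:
                raise RuntimeError("inter-chromosomal SV requires >= 2 chromosomes")
            ci, cj = self.rng.choice(len(self.idx.chroms), size=2, replace=False)
            chrom = self.idx.chroms[int(ci)]
            mate = self.idx.chroms[int(cj)]
            pos = int(rng.integers(2, self.genome.length(chrom)))
            end = int(rng.integers(2, self.genome.length(mate)))
            return VariantRecord(chrom=chrom, pos=pos, ref="", alt="", var_class=VarClass.SV,
                                 sample_id=sample_id, sv_type=sv_type,
                                 sv_end_chrom=mate, sv_end=end)
        chrom, pos = self._random_locus(2, 2)
        length = self.genome.length(chrom)
        span = int(rng.integers(1000, min(50_000, length // 10) + 1))
        end = min(pos + span, length)
        return VariantRecord(chrom=chrom, pos=pos, ref="", alt="", var_class=VarClass.SV,
                             sample_id=sample_id, sv_type=sv_type,
                             sv_end_chrom=chrom, sv_end=end)

    # -- cluster re-placement -------------------------------------------------

    def replace_into_cluster(self, members: list[VariantRecord]) -> list[VariantRecord]:
        """Re-place substitution/indel records into one tight cluster.

        Member start positions realize a span drawn uniformly from the
        configured range; substitutions keep their pyrimidine-centered
        substitution type (the nearest genome base of the matching purine/
        pyrimidine pair is used), other event types keep their channel by
        construction since their ref is re-read from the genome.
        """
        rng = self.rng
        span_lo, span_hi = self.cfg.cluster_span_range
        span = int(rng.integers(span_lo, span_hi + 1))
        for _ in range(200):
            chrom, anchor = self._random_locus(2, span + 1200)
            offsets = self._member_offsets(len(members), span)
            placed = []
            ok = True
            for rec, off in zip(members, offsets):
                new = self._reposition(rec, chrom, anchor + off)
                if new is None:
                    ok = False
                    break
                placed.append(new)
            if ok and len({p.pos for p in placed}) == len(placed):
                return placed
        raise RuntimeError("failed to place a mutation cluster after 200 attempts")

    def _member_offsets(self, n: int, span: int) -> list[int]:
        if n == 2:
            return [0, span]
        middle = sorted(self.rng.choice(np.arange(1, span), size=n - 2, replace=False).tolist())
        return [0] + [int(m) for m in middle] + [span]

    def _reposition(self, rec: VariantRecord, chrom: str, pos: int) -> VariantRecord | None:
        genome = self.genome
        if rec.var_class is VarClass.SNV:
            # preserve the pyrimidine-centered substitution type: find the
            # nearest genome base equal to the record's ref or its complement
            for delta in (0, 1, -1, 2, -2, 3, -3, 4, -4, 5, -5):
                p = pos + delta
                if p < 2 or p > genome.length(chrom) - 1:
                    continue
                base = genome.base(chrom, p)
                if base == rec.ref:
                    alt = rec.alt
                elif base == _COMP[rec.ref]:
                    alt = _COMP[rec.alt]
                else:
                    continue
                return VariantRecord(chrom=chrom, pos=p, ref=base, alt=alt,
                                     var_class=VarClass.SNV, sample_id=rec.sample_id)
            return None
        n_ref = len(rec.ref)
        if pos + max(n_ref, 1) > genome.length(chrom):
            return None
        ref = genome.slice(chrom, pos, pos + n_ref - 1) if n_ref else ""
        if rec.var_class in (VarClass.DNV, VarClass.MNV):
            return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=_substituted(self.rng, ref),
                                 var_class=rec.var_class, sample_id=rec.sample_id)
        if rec.var_class is VarClass.DEL:
            return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt="",
                                 var_class=VarClass.DEL, sample_id=rec.sample_id)
        if rec.var_class is VarClass.INS:
            return VariantRecord(chrom=chrom, pos=pos, ref="", alt=rec.alt,
                                 var_class=VarClass.INS, sample_id=rec.sample_id)
        if rec.var_class is VarClass.INDEL:
            alt = rec.alt if len(rec.alt) != n_ref else rec.alt + "A"
            return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt,
                                 var_class=VarClass.INDEL, sample_id=rec.sample_id)
        raise AssertionError("SVs are never clustered")


# ---------------------------------------------------------------------------

def simulate_experiment(
    cfg: SimConfig,
    genome: ReferenceGenome | None = None,
) -> tuple[list[VariantRecord], list[SampleMeta], ReferenceGenome]:
    """Simulate all samples of one irradiation experiment.

    Deterministic given ``cfg.seed``. A pre-built ``genome`` may be supplied
    to share one reference across configs; otherwise one is generated from the
    seed.
    """
    rng = np.random.default_rng(cfg.seed)
    if genome is None:
        genome = generate_genome(cfg, rng)
    index = _GenomeIndex(genome)
    realizer = _Realizer(cfg, index, rng)

    records: list[VariantRecord] = []
    metas: list[SampleMeta] = []
    for genotype in cfg.genotype_lfc:
        gtag = genotype.replace(" ", "_")
        for dose in cfg.doses_gy:
            for rep in range(1, cfg.replicates_per_dose + 1):
                sample_id = f"{gtag}_d{dose:g}_r{rep}"
                metas.append(SampleMeta(sample_id=sample_id, genotype=genotype,
                                        dose_gy=float(dose), replicate=rep,
                                        generation=cfg.generation))
                records.extend(_simulate_sample(cfg, realizer, sample_id, genotype, dose))
    records.sort(key=lambda r: (r.sample_id, r.chrom, r.pos, r.ref, r.alt))
    return records, metas, genome


def _simulate_sample(
    cfg: SimConfig, realizer: _Realizer, sample_id: str, genotype: str, dose: float
) -> list[VariantRecord]:
    rng = realizer.rng
    lam = cfg.expected_counts(genotype, dose)
    counts = rng.poisson(lam)
    recs: list[VariantRecord] = []
    for k in np.flatnonzero(counts):
        for _ in range(int(counts[k])):
            recs.append(realizer.realize(sample_id, int(k)))
    if cfg.cluster_fraction <= 0:
        return recs
    eligible = [i for i, r in enumerate(recs) if r.var_class is not VarClass.SV]
    n_target = int(round(cfg.cluster_fraction * len(eligible)))
    if n_target < 2:
        return recs
    pool = list(rng.permutation(eligible))
    lo, hi = cfg.cluster_size_range
    remaining = n_target
    while remaining >= 2 and len(pool) >= 2:
        size = min(int(rng.integers(lo, hi + 1)), remaining, len(pool))
        if size < 2:
            break
        member_idx = [pool.pop() for _ in range(size)]
        placed = realizer.replace_into_cluster([recs[i] for i in member_idx])
        for i, new in zip(member_idx, placed):
            recs[i] = new
        remaining -= size
    return recs


def write_experiment(
    cfg: SimConfig,
    outdir: str | Path,
    genome: ReferenceGenome | None = None,
) -> tuple[Path, Path, Path]:
    """Emit one VCF per sample, the FASTA reference and the TSV sample sheet.

    Returns (variants directory, fasta path, sample sheet path). Byte-identical
    output for identical seeds.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, metas, genome = simulate_experiment(cfg, genome=genome)
    vcf_dir = outdir / "variants"
    vcf_dir.mkdir(exist_ok=True)
    by_sample: dict[str, list[VariantRecord]] = {m.sample_id: [] for m in metas}
    for r in records:
        by_sample[r.sample_id].append(r)
    for sid, recs in by_sample.items():
        write_variants(recs, vcf_dir / f"{sid}.vcf", genome)
    fasta = outdir / "reference.fa"
    write_reference(genome, fasta)
    sheet = outdir / "samples.tsv"
    write_sample_sheet(metas, sheet)
    return vcf_dir, fasta, sheet
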