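"""Shared fixtures: tiny genomes, a hand-classified VCF, and seeded simulations."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from irmut.io_formats import ReferenceGenome, write_reference
from irmut.spectra import count_spectrum
from irmut.synthetic_data import default_wildtype_config, simulate_experiment


@pytest.fixture(scope="session")
def toy_genome() -> ReferenceGenome:
    """Two deterministic chromosomes long enough for every context to appear."""
    rng = np.random.default_rng(20210901)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return ReferenceGenome(
        {
            "chrI": bases[rng.integers(0, 4, 3000)].tobytes().decode(),
            "chrII": bases[rng.integers(0, 4, 3000)].tobytes().decode(),
        }
    )


# a fixed 40-bp context around which the fixture VCF is hand-classified
_FIX_CHR1 = "ATACATTTGGCGCGTACGTACGATCCAGGCTTAAGGCCTA"
_FIX_CHR2 = "TTGACCATGGCATGCAATTCCGGATCGATCGAAGCTTGCA"


@pytest.fixture(scope="session")
def fixture_genome() -> ReferenceGenome:
    return ReferenceGenome({"chrI": _FIX_CHR1, "chrII": _FIX_CHR2})


@pytest.fixture()
def fixture_vcf(tmp_path, fixture_genome):
    """Seven body lines: SNV, DNV, insertion, deletion, DUP, INV, inter-chrom BND."""
    header = (
        "##fileformat=VCFv4.2\n"
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n'
        '##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">\n'
        "##contig=<ID=chrI,length=40>\n"
        "##contig=<ID=chrII,length=40>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
    )
    # chrI: pos4 C>T (context A.C.A), pos7-8 TT>GA DNV, pos10 G ins AC,
    # pos15-17 del TAC (anchored at 14), chrII DUP/INV/BND
    body = (
        "chrI\t4\t.\tC\tT\t.\tPASS\t.\n"
        "chrI\t7\t.\tTT\tGA\t.\tPASS\t.\n"
        "chrI\t10\t.\tG\tGAC\t.\tPASS\t.\n"
        "chrI\t14\t.\tGTAC\tG\t.\tPASS\t.\n"
        "chrII\t5\t.\tC\t<DUP>\t.\tPASS\tSVTYPE=DUP;END=35\n"
        "chrII\t9\t.\tG\t<INV>\t.\tPASS\tSVTYPE=INV;END=38\n"
        "chrII\t12\t.\tA\tA[chrI:30[\t.\tPASS\tSVTYPE=BND\n"
    )
    path = tmp_path / "fixture.vcf"
    path.write_text(header + body)
    return path


@pytest.fixture(scope="session")
def wildtype_experiment():
    """Default wild-type study design, one seed, shared across tests."""
    cfg = default_wildtype_config(seed=2)
    records, metas, genome = simulate_experiment(cfg)
    by_sample: dict[str, list] = {m.sample_id: [] for m in metas}
    for r in records:
        by_sample[r.sample_id].append(r)
    spectra = [count_spectrum(by_sample[m.sample_id], genome, m.sample_id) for m in metas]
    return cfg, records, metas, genome, spectra


@pytest.fixture(scope="session")
def small_genome_config():
    """Default rates on a smaller toy genome, for speed-sensitive repetitions."""
    cfg = default_wildtype_config(seed=0)
    return replace(cfg, genome=(("chrI", 300_000), ("chrII", 300_000), ("chrIII", 300_000)))
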