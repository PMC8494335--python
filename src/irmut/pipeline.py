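"""End-to-end orchestration: spectra -> screen -> signature fit -> comparisons
-> clustering -> humanization, with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import (
    DEFAULT_WINDOW_BP,
    HmmParams,
    call_clusters_hmm,
    call_clusters_window,
    cluster_input_positions,
    summarize_clusters,
    write_clusters_bed,
)
from .dose_response import fit_rate, screen_dose_response
from .humanization import adjust_spectrum, read_freqs, trinuc_frequencies, write_freqs
from .io_formats import read_reference, read_sample_sheet, read_variants
from .signature_model import (
    SamplerSettings,
    compare_to_wildtype,
    fit_signature_model,
    profile_divergence,
)
from .spectra import SCHEME, class_totals, count_spectrum, write_spectrum_matrix

log = logging.getLogger("irmut")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    variants_dir: str
    reference: str
    sample_sheet: str
    output_dir: str
    seed: int = 0
    screen_alpha: float = 0.05
    fdr_q: float = 0.05
    clustering_method: str = "window"  # "window" or "hmm"
    window_bp: int = DEFAULT_WINDOW_BP
    hmm_p_enter: float = 0.1
    hmm_p_exit: float = 0.01
    sampler_chains: int = 4
    sampler_warmup: int = 1000
    sampler_draws: int = 1000
    target_freqs: str | None = None  # TSV of trinucleotide frequencies to adjust onto
    wildtype: str = "wild-type"
    skip_screen_failures: bool = True

    def __post_init__(self) -> None:
        for name in ("screen_alpha", "fdr_q"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.clustering_method not in ("window", "hmm"):
            raise ValueError("clustering_method must be 'window' or 'hmm'")

    def validate_paths(self) -> None:
        for name in ("variants_dir", "reference", "sample_sheet"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name} does not exist: {p}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run all stages; returns the manifest of written outputs.

    Re-running with identical config and inputs reproduces every output
    byte-identically (the sampler is seeded from the config).
    """
    cfg.validate_paths()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    # -- stage 1: spectra
    genome = read_reference(cfg.reference)
    metas = read_sample_sheet(cfg.sample_sheet)
    spectra = []
    all_variants = {}
    for m in metas:
        vcf = Path(cfg.variants_dir) / f"{m.sample_id}.vcf"
        if not vcf.exists():
            raise FileNotFoundError(f"stage spectra: missing VCF for sample {m.sample_id}: {vcf}")
        variants = read_variants(vcf, m.sample_id)
        all_variants[m.sample_id] = variants
        spectra.append(count_spectrum(variants, genome, sample_id=m.sample_id))
        log.info("spectra: %s %d records -> %d classified",
                 m.sample_id, len(variants), spectra[-1].total)
    outputs["spectrum_matrix"] = outdir / "spectrum_matrix.tsv"
    write_spectrum_matrix(spectra, outputs["spectrum_matrix"])

    # -- stage 2: dose-response screen + per-class rates
    screen = screen_dose_response(spectra, metas, alpha=cfg.screen_alpha)
    by_id = {s.sample_id: s for s in spectra}
    rate_rows = []
    for genotype in screen:
        ms = [m for m in metas if m.genotype == genotype]
        for cls in ("substitutions", "indels", "SVs"):
            pairs = [(m.dose_gy, class_totals(by_id[m.sample_id])[cls]) for m in ms]
            est = fit_rate(pairs, genotype=genotype, class_label=cls)
            rate_rows.append(
                dict(genotype=genotype, mutation_class=cls, background=est.background,
                     per80=est.per80, se_per80=est.se_per80,
                     ci95_lo=est.ci95[0], ci95_hi=est.ci95[1],
                     pearson_r=screen[genotype].pearson_r[cls],
                     pearson_p=screen[genotype].p_value[cls],
                     passes_screen=screen[genotype].passes)
            )
    outputs["screen_table"] = outdir / "screen_rates.tsv"
    pd.DataFrame(rate_rows).to_csv(outputs["screen_table"], sep="\t", index=False)

    # -- stage 3: signature model (genotypes failing the screen excluded)
    keep_genotypes = {g for g, r in screen.items() if r.passes or not cfg.skip_screen_failures}
    keep_genotypes.add(cfg.wildtype)
    fit_metas = [m for m in metas if m.genotype in keep_genotypes]
    fit_spectra = [by_id[m.sample_id] for m in fit_metas]
    settings = SamplerSettings(chains=cfg.sampler_chains, warmup=cfg.sampler_warmup,
                               draws=cfg.sampler_draws, seed=cfg.seed)
    fit = fit_signature_model(fit_spectra, fit_metas, settings, wildtype=cfg.wildtype)
    outputs["signature_fit"] = outdir / "signature_fit.json"
    outputs["signature_fit"].write_text(json.dumps(fit.to_dict(), indent=1))

    # -- stage 4: comparisons + profile divergence
    comparisons = compare_to_wildtype(fit, alpha=cfg.fdr_q)
    comp_rows = [asdict(c) for c in comparisons]
    if not fit.flagged:
        for genotype in fit.genotypes[1:]:
            pd_res = profile_divergence(fit, genotype, alpha=cfg.fdr_q, comparisons=comparisons)
            comp_rows.append(dict(genotype=genotype, class_label="profile_cosine_distance",
                                  z=float("nan"), p=float("nan"), q=float("nan"),
                                  direction=f"{pd_res.cosine_distance:.4g}"
                                            f" [{pd_res.ci95[0]:.4g},{pd_res.ci95[1]:.4g}]"
                                            f"{' *' if pd_res.significant else ''}"))
    outputs["comparisons"] = outdir / "comparisons.tsv"
    pd.DataFrame(comp_rows).to_csv(outputs["comparisons"], sep="\t", index=False)

    # -- stage 5: clustering
    genome_length = sum(genome.length(c) for c in genome.chroms)
    calls_by_sample = {}
    eligible_by_sample = {}
    for sid, variants in all_variants.items():
        positions = cluster_input_positions(variants)
        eligible_by_sample[sid] = int(sum(len(p) for p in positions.values()))
        if cfg.clustering_method == "window":
            calls = call_clusters_window(positions, cfg.window_bp, sample_id=sid)
        else:
            calls = call_clusters_hmm(
                positions, HmmParams(p_enter=cfg.hmm_p_enter, p_exit=cfg.hmm_p_exit),
                genome_length=genome_length, sample_id=sid,
            )
        calls_by_sample[sid] = calls
    all_calls = [c for calls in calls_by_sample.values() for c in calls]
    outputs["clusters_bed"] = outdir / "clusters.bed"
    write_clusters_bed(all_calls, outputs["clusters_bed"])
    summaries = summarize_clusters(calls_by_sample, eligible_by_sample, metas)
    outputs["cluster_summary"] = outdir / "cluster_summary.tsv"
    pd.DataFrame([asdict(s) for s in summaries.values()]).to_csv(
        outputs["cluster_summary"], sep="\t", index=False
    )

    # -- stage 6: humanization of the wild-type IR signature
    source_freqs = trinuc_frequencies(genome, source="reference")
    if cfg.target_freqs:
        target = read_freqs(cfg.target_freqs, source="target")
    else:
        target = source_freqs
    adjusted = adjust_spectrum(fit.ir_mean, source_freqs, target)
    outputs["humanized_spectrum"] = outdir / "humanized_spectrum.tsv"
    pd.DataFrame({"channel": SCHEME.labels, "fraction": adjusted}).to_csv(
        outputs["humanized_spectrum"], sep="\t", index=False
    )
    freq_path = outdir / "reference_trinuc_freqs.tsv"
    write_freqs(source_freqs, freq_path)

    # -- manifest
    manifest = {
        "irmut_version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": asdict(cfg),
        "outputs": {k: str(v) for k, v in outputs.items()},
        "n_samples": len(metas),
        "genotypes_fit": fit.genotypes,
        "fit_flagged": fit.flagged,
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    outputs["manifest"] = manifest_path
    return outputs
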