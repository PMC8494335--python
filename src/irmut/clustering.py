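"""Clustered-mutation detection and per-genotype clustering statistics.

Two callers are provided. The sliding-window caller assigns clustered status
to maximal runs of >= 2 substitution/indel start points in which every
consecutive gap is at most the window (1000 bp by default) — the connected
components any fixed-window scan would link. The HMM caller Viterbi-decodes
a two-state model over inter-mutation distances with geometric emissions
(defaults: 0.1 for entering the clustered state, 0.01 for leaving it).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import statsmodels.api as sm

from .dose_response import RateEstimate, fit_rate
from .io_formats import SampleMeta, VarClass, VariantRecord
from .signature_model import ComparisonResult, bh_adjust, z_test

__all__ = [
    "ClusterCall",
    "ClusterSummary",
    "HmmParams",
    "cluster_input_positions",
    "call_clusters_window",
    "call_clusters_hmm",
    "summarize_clusters",
    "clustering_dose_model",
    "compare_clustering",
    "write_clusters_bed",
]

DEFAULT_WINDOW_BP = 1000


@dataclass(frozen=True)
class ClusterCall:
    chrom: str
    positions: tuple[int, ...]  # sorted member start points
    sample_id: str = ""

    def __post_init__(self) -> None:
        if len(self.positions) < 2:
            raise ValueError("a cluster has >= 2 members")
        if list(self.positions) != sorted(self.positions):
            raise ValueError("member positions must be sorted")

    @property
    def n(self) -> int:
        return len(self.positions)

    @property
    def span_bp(self) -> int:
        return self.positions[-1] - self.positions[0]


@dataclass(frozen=True)
class HmmParams:
    """Two-state HMM over inter-mutation gaps.

    ``p_enter``: non-clustered -> clustered transition probability;
    ``p_exit``: clustered -> non-clustered. Emissions are geometric on the
    gap length with state-specific means.
    """

    p_enter: float = 0.1
    p_exit: float = 0.01
    mean_gap_clustered: float = 100.0
    mean_gap_background: float | None = None  # default: genome_length / n_mutations

    def __post_init__(self) -> None:
        for p in (self.p_enter, self.p_exit):
            if not (0.0 < p < 1.0):
                raise ValueError("transition probabilities must lie in (0, 1)")
        if not np.isfinite(self.mean_gap_clustered) or self.mean_gap_clustered <= 1:
            raise ValueError("mean_gap_clustered must be finite and > 1")


def cluster_input_positions(
    variants: Iterable[VariantRecord],
) -> dict[str, np.ndarray]:
    """Start points of all substitutions and indels, sorted per chromosome."""
    by_chrom: dict[str, list[int]] = {}
    for v in variants:
        if v.var_class is VarClass.SV:
            continue
        by_chrom.setdefault(v.chrom, []).append(v.pos)
    return {c: np.array(sorted(p), dtype=np.int64) for c, p in by_chrom.items()}


def call_clusters_window(
    positions_by_chrom: Mapping[str, np.ndarray],
    window_bp: int = DEFAULT_WINDOW_BP,
    sample_id: str = "",
) -> list[ClusterCall]:
    """Maximal runs of >= 2 positions with every consecutive gap <= window_bp."""
    calls = []
    for chrom, positions in positions_by_chrom.items():
        pos = np.sort(np.asarray(positions, dtype=np.int64))
        if len(pos) < 2:
            continue
        gaps = np.diff(pos)
        run_start = 0
        for i, gap in enumerate(gaps):
            if gap > window_bp:
                if i + 1 - run_start >= 2:
                    calls.append(ClusterCall(chrom, tuple(int(p) for p in pos[run_start : i + 1]),
                                             sample_id))
                run_start = i + 1
        if len(pos) - run_start >= 2:
            calls.append(ClusterCall(chrom, tuple(int(p) for p in pos[run_start:]), sample_id))
    return calls


def _geometric_logpmf(gap: np.ndarray, mean: float) -> np.ndarray:
    """log P(gap) for a geometric distribution on {1, 2, ...} with given mean."""
    p = 1.0 / max(mean, 1.0 + 1e-9)
    g = np.maximum(gap, 1)
    return np.log(p) + (g - 1) * np.log1p(-p)


def call_clusters_hmm(
    positions_by_chrom: Mapping[str, np.ndarray],
    params: HmmParams = HmmParams(),
    genome_length: float | None = None,
    sample_id: str = "",
) -> list[ClusterCall]:
    """Viterbi-decode clustered segments from inter-mutation distances.

    State 0 = non-clustered, state 1 = clustered. Each gap between successive
    mutations emits from the geometric distribution of the state of the later
    mutation; a run of clustered-state gaps of length m covers m+1 mutations.
    """
    n_total = sum(len(p) for p in positions_by_chrom.values())
    if params.mean_gap_background is not None:
        bg_mean = params.mean_gap_background
    elif genome_length is not None and n_total > 0:
        bg_mean = max(genome_length / n_total, 2.0)
    else:
        all_gaps = np.concatenate(
            [np.diff(np.sort(np.asarray(p))) for p in positions_by_chrom.values() if len(p) > 1]
            or [np.array([1000.0])]
        )
        bg_mean = max(float(all_gaps.mean()), 2.0)
    if not np.isfinite(bg_mean):
        raise ValueError("non-finite background emission mean")

    calls = []
    for chrom, positions in positions_by_chrom.items():
        pos = np.sort(np.asarray(positions, dtype=np.int64))
        if len(pos) < 2:
            continue
        gaps = np.diff(pos).astype(float)
        states = _viterbi_two_state(gaps, params, bg_mean)
        # decode runs of clustered gaps
        i = 0
        while i < len(states):
            if states[i] == 1:
                j = i
                while j < len(states) and states[j] == 1:
                    j += 1
                calls.append(
                    ClusterCall(chrom, tuple(int(p) for p in pos[i : j + 1]), sample_id)
                )
                i = j
            else:
                i += 1
    return calls


def _viterbi_two_state(gaps: np.ndarray, params: HmmParams, bg_mean: float) -> np.ndarray:
    """Exact Viterbi over the two-state chain emitting the gap sequence."""
    log_trans = np.log(
        np.array(
            [
                [1 - params.p_enter, params.p_enter],
                [params.p_exit, 1 - params.p_exit],
            ]
        )
    )
    # stationary start distribution of the transition chain
    pi1 = params.p_enter / (params.p_enter + params.p_exit)
    log_start = np.log(np.array([1 - pi1, pi1]))
    emit = np.stack(
        [_geometric_logpmf(gaps, bg_mean), _geometric_logpmf(gaps, params.mean_gap_clustered)],
        axis=1,
    )  # (T, 2)
    T = len(gaps)
    delta = log_start + emit[0]
    back = np.empty((T, 2), dtype=np.int8)
    for t in range(1, T):
        cand = delta[:, None] + log_trans  # (from, to)
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], [0, 1]] + emit[t]
    states = np.empty(T, dtype=np.int8)
    states[-1] = int(np.argmax(delta))
    for t in range(T - 1, 0, -1):
        states[t - 1] = back[t][states[t]]
    return states


@dataclass(frozen=True)
class ClusterSummary:
    genotype: str
    clusters_per_80gy_per_genome: float
    se_clusters_per_80gy: float
    prop_clustered: float
    n_clusters: int
    span_median: float
    span_iqr: tuple[float, float]
    size_median: float
    size_iqr: tuple[float, float]


def _median_iqr(values: Sequence[float]) -> tuple[float, tuple[float, float]]:
    if not values:
        return 0.0, (0.0, 0.0)
    arr = np.asarray(values, float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return float(med), (float(q1), float(q3))


def summarize_clusters(
    calls_by_sample: Mapping[str, Sequence[ClusterCall]],
    eligible_by_sample: Mapping[str, int],
    metas: Sequence[SampleMeta],
) -> dict[str, ClusterSummary]:
    """Per-genotype clustering summary.

    ``eligible_by_sample`` holds each sample's total substitution+indel count
    (the denominator of the clustered proportion). Clusters per genome are
    normalized to 80 Gy by the additive Poisson dose-response fit of
    per-sample cluster counts versus dose.
    """
    by_genotype: dict[str, list[SampleMeta]] = {}
    for m in metas:
        by_genotype.setdefault(m.genotype, []).append(m)
    out = {}
    for genotype, ms in by_genotype.items():
        pairs = []
        clustered = total = 0
        spans: list[float] = []
        sizes: list[float] = []
        n_clusters = 0
        for m in ms:
            calls = calls_by_sample.get(m.sample_id, [])
            pairs.append((m.dose_gy, len(calls)))
            n_clusters += len(calls)
            clustered += sum(c.n for c in calls)
            total += eligible_by_sample.get(m.sample_id, 0)
            spans.extend(c.span_bp for c in calls)
            sizes.extend(c.n for c in calls)
        if len({d for d, _ in pairs}) >= 2:
            est = fit_rate(pairs, genotype=genotype, class_label="clusters")
            per80, se80 = est.per80, est.se_per80
        else:
            per80 = float(np.mean([c for _, c in pairs])) if pairs else 0.0
            se80 = float("nan")
        span_med, span_iqr = _median_iqr(spans)
        size_med, size_iqr = _median_iqr(sizes)
        out[genotype] = ClusterSummary(
            genotype=genotype,
            clusters_per_80gy_per_genome=per80,
            se_clusters_per_80gy=se80,
            prop_clustered=clustered / total if total else 0.0,
            n_clusters=n_clusters,
            span_median=span_med,
            span_iqr=span_iqr,
            size_median=size_med,
            size_iqr=size_iqr,
        )
    return out


@dataclass(frozen=True)
class ClusteringDoseFit:
    slope: float
    se_slope: float
    intercept: float
    se_intercept: float
    sigma2: float


def clustering_dose_model(
    doses: Sequence[float], responses: Sequence[float]
) -> ClusteringDoseFit:
    """OLS of a per-sample clustering response (e.g. clustered proportion) on dose."""
    d = np.asarray(doses, float)
    y = np.asarray(responses, float)
    if len(np.unique(d)) < 3:
        raise ValueError("clustering_dose_model requires >= 3 dose levels")
    X = sm.add_constant(d)
    res = sm.OLS(y, X).fit()
    return ClusteringDoseFit(
        slope=float(res.params[1]),
        se_slope=float(res.bse[1]),
        intercept=float(res.params[0]),
        se_intercept=float(res.bse[0]),
        sigma2=float(res.scale),
    )


def compare_clustering(
    estimates: Mapping[str, tuple[float, float]],
    wildtype: str = "wild-type",
    alpha: float = 0.05,
) -> list[ComparisonResult]:
    """Z-test of each genotype's clustering rate (estimate, SE) vs wild-type, BH-adjusted."""
    if wildtype not in estimates:
        raise ValueError(f"estimates must include {wildtype!r}")
    r_wt, se_wt = estimates[wildtype]
    rows = []
    for genotype, (r_g, se_g) in estimates.items():
        if genotype == wildtype:
            continue
        z, p = z_test(r_g, se_g, r_wt, se_wt)
        rows.append((genotype, z, p))
    qs = bh_adjust([p for _, _, p in rows])
    return [
        ComparisonResult(genotype=g, class_label="clustering", z=z, p=p, q=float(q),
                         direction="up" if z >= 0 else "down")
        for (g, z, p), q in zip(rows, qs)
    ]


def write_clusters_bed(calls: Sequence[ClusterCall], path: str | Path) -> None:
    """BED output (0-based half-open); name column = number of member mutations."""
    with open(path, "w") as fh:
        for c in sorted(calls, key=lambda c: (c.chrom, c.positions[0])):
            fh.write(f"{c.chrom}\t{c.positions[0] - 1}\t{c.positions[-1]}\t{c.n}\n")
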