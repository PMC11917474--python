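"""Copy-number estimation from read depth, normalised to single-copy exons.

The estimator: haploid copy number of an rDNA region = mean per-base read
depth of the region divided by the mean per-base depth of 16 single-copy
exons; diploid copy number is exactly twice that. Depth summaries
(mean/median/mode), consensus dead-zone detection across samples, 1.5×IQR
outlier flagging, and region-vs-region OLS regressions live here too.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import DepthProfile
from .stats import ols


@dataclass
class RegionSummary:
    """Depth summaries for one region in one sample, over unmasked positions."""

    region: str
    sample_id: str
    mean_depth: float
    median_depth: float
    mode_depth: int
    n_masked: int
    L_effective: int


@dataclass
class CopyNumberEstimate:
    """Haploid/diploid copy number of one region in one sample."""

    sample_id: str
    region: str
    haploid_cn: float
    diploid_cn: float
    exon_mean_depth: float


def _mask_to_bool(mask: Iterable[tuple[int, int]] | None, L: int) -> np.ndarray:
    """Convert 1-based inclusive intervals to a boolean masked-position array."""
    out = np.zeros(L, dtype=bool)
    for start, end in (mask or ()):
        if start < 1 or end > L or start > end:
            raise ValueError(f"mask interval ({start},{end}) outside [1,{L}]")
        out[start - 1:end] = True
    return out


def summarize_depth(profile: DepthProfile,
                    mask: Iterable[tuple[int, int]] | None = None) -> RegionSummary:
    """Mean/median/mode depth over unmasked positions.

    Mode ties break to the smallest value. A fully masked profile is an
    error — there is nothing to summarise.
    """
    masked = _mask_to_bool(mask, profile.L)
    depth = profile.depth[~masked]
    if depth.size == 0:
        raise ValueError(
            f"profile {profile.region}/{profile.sample_id} fully masked")
    values, counts = np.unique(depth, return_counts=True)
    mode = int(values[np.argmax(counts)])  # np.unique sorts: smallest-among-ties
    return RegionSummary(
        region=profile.region, sample_id=profile.sample_id,
        mean_depth=float(depth.mean()), median_depth=float(np.median(depth)),
        mode_depth=mode, n_masked=int(masked.sum()), L_effective=int(depth.size),
    )


@dataclass
class DeadZoneReport:
    """Consensus low-depth intervals for one region across samples."""

    region: str
    intervals: list[tuple[int, int]]
    masked_fraction: float
    exclude: bool


def detect_dead_zones(profiles: Sequence[DepthProfile],
                      rel_threshold: float = 0.05,
                      sample_frac: float = 0.90,
                      min_run: int = 50) -> DeadZoneReport:
    """Find intervals with consistently near-zero depth across samples.

    A position is flagged in a sample when its depth falls below
    ``rel_threshold`` times that sample's median over positive-depth
    positions; positions flagged in at least ``sample_frac`` of samples
    and forming runs of at least ``min_run`` nt are reported as dead
    zones. The region is marked for exclusion when more than half of it is
    consensus-flagged (the situation that forced dropping IGS1 for the
    hybrid lineage in real data).
    """
    if len(profiles) < 2:
        raise ValueError("dead-zone detection needs >= 2 samples")
    region = profiles[0].region
    L = profiles[0].L
    for p in profiles:
        if p.region != region or p.L != L:
            raise ValueError("profiles must share region and length")
    flagged = np.zeros(L, dtype=np.int64)
    for p in profiles:
        positive = p.depth[p.depth > 0]
        ref = float(np.median(positive)) if positive.size else 0.0
        flagged += (p.depth < rel_threshold * ref).astype(np.int64)
    consensus = flagged >= np.ceil(sample_frac * len(profiles))
    intervals: list[tuple[int, int]] = []
    i = 0
    while i < L:
        if consensus[i]:
            j = i
            while j + 1 < L and consensus[j + 1]:
                j += 1
            if j - i + 1 >= min_run:
                intervals.append((i + 1, j + 1))
            i = j + 1
        else:
            i += 1
    masked_fraction = float(consensus.sum()) / L
    return DeadZoneReport(region=region, intervals=intervals,
                          masked_fraction=masked_fraction,
                          exclude=masked_fraction > 0.5)


def pooled_exon_mean(exon_summaries: Sequence[RegionSummary],
                     method: str = "pooled") -> float:
    """Mean exon depth, length-weighted over the exon concatenation.

    ``pooled`` (default) weights each exon's mean by its effective length,
    equalling the per-base mean over all exon positions; ``mean_of_means``
    averages the 16 per-exon means unweighted.
    """
    if not exon_summaries:
        raise ValueError("no exon summaries")
    if method == "pooled":
        total = sum(s.mean_depth * s.L_effective for s in exon_summaries)
        length = sum(s.L_effective for s in exon_summaries)
        return total / length
    if method == "mean_of_means":
        return float(np.mean([s.mean_depth for s in exon_summaries]))
    raise ValueError(f"unknown pooling method {method!r}")


def estimate_copy_number(region_summaries: Sequence[RegionSummary],
                         exon_summaries: Sequence[RegionSummary],
                         method: str = "pooled") -> list[CopyNumberEstimate]:
    """Depth-ratio copy number for each region summary of one sample."""
    exon_mean = pooled_exon_mean(exon_summaries, method=method)
    if exon_mean <= 0:
        sample = exon_summaries[0].sample_id if exon_summaries else "?"
        raise ValueError(f"zero exon depth for sample {sample!r}")
    out = []
    for s in region_summaries:
        haploid = s.mean_depth / exon_mean
        out.append(CopyNumberEstimate(
            sample_id=s.sample_id, region=s.region,
            haploid_cn=haploid, diploid_cn=2.0 * haploid,
            exon_mean_depth=exon_mean,
        ))
    return out


def copy_number_table(profiles_by_sample: Mapping[str, Mapping[str, DepthProfile]],
                      rdna_regions: Sequence[str],
                      masks: Mapping[str, Sequence[tuple[int, int]]] | None = None,
                      method: str = "pooled") -> pd.DataFrame:
    """Copy-number estimates for many samples as one tidy table.

    ``profiles_by_sample`` maps sample_id -> region name -> DepthProfile;
    regions not listed in ``rdna_regions`` are treated as exons. ``masks``
    maps region name -> mask intervals (applied to every sample).
    """
    masks = masks or {}
    rows = []
    for sample_id, profs in profiles_by_sample.items():
        region_sums, exon_sums = [], []
        for region, prof in profs.items():
            summary = summarize_depth(prof, masks.get(region))
            (region_sums if region in rdna_regions else exon_sums).append(summary)
        for est, s in zip(estimate_copy_number(region_sums, exon_sums, method),
                          region_sums):
            rows.append({
                "sample_id": sample_id, "region": est.region,
                "mean_depth": s.mean_depth, "median_depth": s.median_depth,
                "mode_depth": s.mode_depth, "exon_mean": est.exon_mean_depth,
                "haploid_cn": est.haploid_cn, "diploid_cn": est.diploid_cn,
            })
    return pd.DataFrame(rows)


def flag_outliers_iqr(values: Sequence[float], k: float = 1.5) -> np.ndarray:
    """Boolean flags for values outside [Q1 - k*IQR, Q3 + k*IQR].

    Quartiles use linear interpolation (type-7), so flags are
    reproducible across environments. Boundary equality is inside.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("IQR outlier flagging needs n >= 4")
    q1, q3 = np.percentile(values, [25, 75])  # numpy default = type-7
    iqr = q3 - q1
    return (values < q1 - k * iqr) | (values > q3 + k * iqr)


def regress_regions(cn_table: pd.DataFrame, region_a: str, region_b: str) -> dict:
    """OLS of region_a diploid copy number on region_b across samples."""
    wide = cn_table.pivot(index="sample_id", columns="region",
                          values="diploid_cn")
    pair = wide[[region_a, region_b]].dropna()
    if len(pair) < 3:
        raise ValueError("region regression needs >= 3 paired estimates")
    return ols(pair[region_b].to_numpy(), pair[region_a].to_numpy())
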