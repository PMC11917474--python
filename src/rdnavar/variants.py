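"""SNP filtering and allele-frequency computation for rDNA pooled copies.

Because every individual carries hundreds of rDNA copies, a "SNP" here is
a site where the copies within an individual disagree; per-sample allele
frequencies are read-count fractions over the four nucleotides. The
retention procedure:

1. at each (sample, site), nucleotide counts below ``min_allele`` (5) are
   set to 0 and the total is recomputed;
2. cells whose recomputed total is below ``min_total`` (99) are missing;
3. a site is dropped when the mean reference-allele frequency across
   samples with data exceeds ``max_ref_freq`` (0.990) — i.e. the site is
   effectively invariant in the lineage.

"Allele 1" is the reference base; "allele 2" is the non-reference
nucleotide with the largest lineage-wide summed count. Sites where a
third allele carries appreciable frequency are flagged multi-allelic and
kept out of the biallelic haplotype encoding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_NUCS = ["A", "C", "G", "T"]
_COUNT_COLS = ["nA", "nC", "nG", "nT"]


def filter_counts(matrix: pd.DataFrame, min_allele: int = 5,
                  min_total: int = 99) -> pd.DataFrame:
    """Apply the per-cell count thresholds; idempotent.

    Counts below ``min_allele`` zero out; the total is recomputed; cells
    with recomputed total strictly below ``min_total`` are marked
    ``retained = False`` (missing downstream). Both rules use strict
    comparisons: a count of exactly 5 survives, a total of exactly 99 is
    retained.
    """
    out = matrix.copy()
    counts = out[_COUNT_COLS].to_numpy(copy=True)
    counts[counts < min_allele] = 0
    out[_COUNT_COLS] = counts
    out["total"] = counts.sum(axis=1)
    out["retained"] = out["total"] >= min_total
    return out


@dataclass
class AlleleFrequencyMatrix:
    """Per-sample allele-2 frequencies at retained biallelic SNP sites.

    ``freq`` is samples × sites (columns labelled "region:position");
    ``mask`` marks missing cells (site filtered out in that sample);
    ``sites`` carries per-site metadata: ref/allele-2 bases, lineage mean
    reference frequency, mean residual ("others") frequency mass, and the
    multi-allelic exclusion flag.
    """

    freq: pd.DataFrame
    mask: pd.DataFrame
    sites: pd.DataFrame

    @property
    def values(self) -> np.ndarray:
        return self.freq.to_numpy()

    @property
    def observed(self) -> np.ndarray:
        return ~self.mask.to_numpy()


def site_frequencies(filtered: pd.DataFrame,
                     max_ref_freq: float = 0.990,
                     max_third_allele_freq: float = 0.01) -> AlleleFrequencyMatrix:
    """Build the sample × site allele-2 frequency matrix from filtered counts.

    Frequencies are computed over the recomputed total (all four
    nucleotides), so freq(ref) + freq(allele2) + freq(others) = 1 per
    cell. Mean reference frequency per site averages over samples with
    non-missing cells; sites with mean ref frequency strictly above
    ``max_ref_freq`` are dropped, as are sites missing in every sample.
    Sites whose best third allele exceeds ``max_third_allele_freq`` mean
    frequency are flagged ``multiallelic`` and excluded from ``freq``.
    """
    if "retained" not in filtered.columns:
        raise ValueError("input must be a filtered count matrix (run filter_counts)")
    df = filtered[filtered["retained"]].copy()
    df["site"] = df["region"].astype(str) + ":" + df["position"].astype(str)
    samples = sorted(filtered["sample_id"].unique())
    site_rows = []
    freq_cols: dict[str, pd.Series] = {}
    for site, grp in df.groupby("site", sort=True):
        ref = grp["ref_base"].iloc[0]
        totals = grp["total"].to_numpy(dtype=float)
        counts = grp[_COUNT_COLS].to_numpy(dtype=float)
        freqs = counts / totals[:, None]
        ref_idx = _NUCS.index(ref)
        mean_ref = float(freqs[:, ref_idx].mean())
        lineage_counts = counts.sum(axis=0)
        nonref = [i for i in range(4) if i != ref_idx]
        # allele 2 = largest lineage-wide summed count among non-ref bases
        alt_idx = max(nonref, key=lambda i: lineage_counts[i])
        other_idx = [i for i in nonref if i != alt_idx]
        mean_others = float(freqs[:, other_idx].sum(axis=1).mean())
        dropped = mean_ref > max_ref_freq
        multiallelic = (not dropped) and mean_others > max_third_allele_freq
        region, position = site.split(":")
        site_rows.append({
            "site": site, "region": region, "position": int(position),
            "ref_base": ref, "alt_base": _NUCS[alt_idx],
            "mean_ref_freq": mean_ref, "mean_others_freq": mean_others,
            "n_samples": len(grp), "dropped_invariant": dropped,
            "multiallelic": multiallelic,
        })
        if not dropped and not multiallelic:
            freq_cols[site] = pd.Series(freqs[:, alt_idx].astype(float),
                                        index=grp["sample_id"].to_numpy())
    sites = pd.DataFrame(site_rows)
    if sites.empty:
        sites = pd.DataFrame(columns=[
            "site", "region", "position", "ref_base", "alt_base",
            "mean_ref_freq", "mean_others_freq", "n_samples",
            "dropped_invariant", "multiallelic"])
    keep = [s["site"] for s in site_rows
            if not s["dropped_invariant"] and not s["multiallelic"]]
    freq = pd.DataFrame(index=samples, columns=keep, dtype=float)
    for site in keep:
        freq[site] = freq_cols[site].reindex(samples)
    mask = freq.isna()
    return AlleleFrequencyMatrix(freq=freq, mask=mask, sites=sites)


def snp_report(matrices: dict[str, AlleleFrequencyMatrix]) -> pd.DataFrame:
    """Per-lineage, per-region retained SNP counts plus shared-site counts.

    Sites are identified by (region, position); the report includes one
    row per lineage × region and, for each lineage pair, the size of the
    shared retained-site set.
    """
    rows = []
    site_sets: dict[str, set[tuple[str, int]]] = {}
    for lineage, afm in matrices.items():
        retained = afm.sites[~afm.sites["dropped_invariant"]
                             & ~afm.sites["multiallelic"]]
        site_sets[lineage] = set(zip(retained["region"], retained["position"]))
        for region, grp in retained.groupby("region"):
            rows.append({"lineage": lineage, "region": region,
                         "n_snps": len(grp), "kind": "per_region"})
        rows.append({"lineage": lineage, "region": "all",
                     "n_snps": len(retained), "kind": "total"})
    lineages = sorted(site_sets)
    for i, a in enumerate(lineages):
        for b in lineages[i + 1:]:
            rows.append({"lineage": f"{a}&{b}", "region": "all",
                         "n_snps": len(site_sets[a] & site_sets[b]),
                         "kind": "shared"})
    return pd.DataFrame(rows)
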