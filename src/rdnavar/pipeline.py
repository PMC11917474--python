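"""End-to-end orchestration: simulate → copy number → rates → variants →
haplotypes → stats, as one reproducible, file-driven run.

Every stage consumes and produces plain TSV files, so any stage can be
re-run standalone; a manifest records each output with its row count and
content hash. Re-running with the same config and seed reproduces every
table byte for byte. One top-level seed fans out to named per-stage
generators via :func:`rdnavar.simulate.derive_seed`.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import change_rates as cr
from . import copy_number as cn
from . import haplotypes as hp
from . import variants as vr
from .io_formats import (metadata_frame, read_depth_table, read_metadata,
                         read_table, write_depth_table, write_metadata,
                         write_table)
from .simulate import (DEFAULT_REGION_LENGTHS, SimConfig, derive_seed,
                       simulate_dataset, write_truth)
from .stats import chisq_direction, gated_location_test, one_sample_t

logger = logging.getLogger(__name__)

RDNA_REGIONS = tuple(DEFAULT_REGION_LENGTHS)


@dataclass
class RunConfig:
    """Thresholds, study dimensions and seed for one pipeline run.

    Every filtering threshold carries its canonical default (allele count
    5, total depth 99, invariant-site mean reference frequency 0.990,
    1.5×IQR whiskers, α = 0.05); the seed is recorded in every output
    directory via the echoed effective config.
    """

    seed: int = 0
    n_lines: int = 10
    generations: int = 50
    n_haplotypes: int = 4
    n_snps: int = 25
    event_rate: float = 0.2
    site_depth_mean: float = 0.0  # 0 = scale with each sample's copy number
    min_allele: int = 5
    min_total: int = 99
    max_ref_freq: float = 0.990
    iqr_k: float = 1.5
    alpha: float = 0.05
    auto_k: bool = True
    k: int = 4
    n_restarts: int = 20
    lineage: str = "SX"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse a key=value config file ('#' comments allowed)."""
        kwargs = {}
        fields = {f: t for f, t in cls.__annotations__.items()}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            typ = fields[key]
            if typ == "bool":
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif typ == "int":
                kwargs[key] = int(value)
            elif typ == "float":
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def echo(self, outdir: Path) -> None:
        lines = [f"{k} = {v}" for k, v in asdict(self).items()]
        (outdir / "effective_config.txt").write_text("\n".join(lines) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class Manifest:
    def __init__(self, outdir: Path) -> None:
        self.outdir = outdir
        self.rows: list[dict] = []

    def add(self, path: Path, stage: str, n_rows: int) -> None:
        self.rows.append({"file": str(path.relative_to(self.outdir)),
                          "stage": stage, "n_rows": n_rows,
                          "sha256": _sha256(path)})

    def write(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows)
        write_table(df, self.outdir / "manifest.tsv")
        return df


def stage_simulate(config: RunConfig, outdir: Path, manifest: Manifest) -> None:
    sim = SimConfig(n_haplotypes=config.n_haplotypes, n_snps=config.n_snps,
                    event_rate=config.event_rate,
                    generations=config.generations,
                    seed=derive_seed(config.seed, "simulate"))
    data = simulate_dataset(sim, config.n_lines,
                            seed=derive_seed(config.seed, "simulate"),
                            lineage=config.lineage,
                            site_depth_mean=config.site_depth_mean or None)
    depth_dir = outdir / "depth"
    depth_dir.mkdir(parents=True, exist_ok=True)
    for sample_id, profiles in data["depth_profiles"].items():
        path = depth_dir / f"{sample_id}.depth.tsv"
        write_depth_table(profiles.values(), path)
        manifest.add(path, "simulate", sum(p.L for p in profiles.values()))
    counts_path = outdir / "allele_counts.tsv"
    write_table(data["allele_counts"], counts_path)
    manifest.add(counts_path, "simulate", len(data["allele_counts"]))
    meta_path = outdir / "metadata.tsv"
    write_metadata(data["metadata"], meta_path)
    manifest.add(meta_path, "simulate", len(data["metadata"]))
    write_truth(data["states"], data["H"], data["P_true"], outdir / "truth")
    for name in ("truth_copy_number", "truth_haplotypes", "truth_frequencies"):
        path = outdir / "truth" / f"{name}.tsv"
        manifest.add(path, "simulate", len(read_table(path)))


def stage_copynumber(config: RunConfig, outdir: Path, manifest: Manifest,
                     depth_dir: Path | None = None) -> pd.DataFrame:
    depth_dir = depth_dir or outdir / "depth"
    if not depth_dir.is_dir():
        raise FileNotFoundError(f"depth directory not found: {depth_dir}")
    profiles = {}
    for path in sorted(depth_dir.glob("*.depth.tsv")):
        sample_id = path.name.split(".")[0]
        profiles[sample_id] = {p.region: p
                               for p in read_depth_table(path, sample_id)}
    table = cn.copy_number_table(profiles, RDNA_REGIONS)
    flags = []
    for region, grp in table.groupby("region"):
        flagged = cn.flag_outliers_iqr(grp["diploid_cn"].to_numpy(), config.iqr_k)
        flags.append(pd.Series(flagged, index=grp.index))
    table["outlier_flag"] = pd.concat(flags).sort_index()
    path = outdir / "copy_number.tsv"
    write_table(table, path)
    manifest.add(path, "copynumber", len(table))
    return table


def stage_rates(config: RunConfig, outdir: Path, manifest: Manifest,
                cn_table: pd.DataFrame | None = None) -> pd.DataFrame:
    if cn_table is None:
        cn_table = read_table(outdir / "copy_number.tsv")
    meta = metadata_frame(read_metadata(outdir / "metadata.tsv"))
    table = cn_table[cn_table["region"] == "28S"].merge(meta, on="sample_id")
    controls = table[table["treatment"] == "control"]
    baseline = cr.progenitor_baseline(controls["diploid_cn"].to_numpy())
    rates = [cr.rate_from_baseline(row.diploid_cn, int(row.generation),
                                   baseline, line_id=row.sample_id)
             for row in table.itertuples()]
    rates_df = cr.rates_frame(rates)
    path = outdir / "change_rates.tsv"
    write_table(rates_df, path)
    manifest.add(path, "rates", len(rates_df))
    n_inc, n_dec, n_tie = cr.direction_counts(rates)
    summary_rows = [
        {"quantity": "baseline_diploid_cn", "value": baseline},
        {"quantity": "n_increase", "value": n_inc},
        {"quantity": "n_decrease", "value": n_dec},
        {"quantity": "n_tie", "value": n_tie},
    ]
    if n_inc + n_dec >= 1:
        chi2, p, _ = chisq_direction(n_inc, n_dec)
        summary_rows += [{"quantity": "direction_chi2", "value": chi2},
                         {"quantity": "direction_p", "value": p}]
    try:
        t, p = cr.signed_rate_test(rates)
        summary_rows += [{"quantity": "signed_rate_t", "value": t},
                         {"quantity": "signed_rate_p", "value": p}]
    except ValueError:
        pass
    summary = pd.DataFrame(summary_rows)
    path = outdir / "rate_summary.tsv"
    write_table(summary, path)
    manifest.add(path, "rates", len(summary))
    return rates_df


def stage_variants(config: RunConfig, outdir: Path, manifest: Manifest
                   ) -> vr.AlleleFrequencyMatrix:
    counts = read_table(outdir / "allele_counts.tsv")
    filtered = vr.filter_counts(counts, config.min_allele, config.min_total)
    path = outdir / "filtered_counts.tsv"
    write_table(filtered, path)
    manifest.add(path, "variants", len(filtered))
    afm = vr.site_frequencies(filtered, config.max_ref_freq)
    freq = afm.freq.reset_index(names="sample_id")
    path = outdir / "freq_matrix.tsv"
    write_table(freq, path)
    manifest.add(path, "variants", len(freq))
    path = outdir / "site_report.tsv"
    write_table(afm.sites, path)
    manifest.add(path, "variants", len(afm.sites))
    return afm


def stage_haplotypes(config: RunConfig, outdir: Path, manifest: Manifest,
                     afm: vr.AlleleFrequencyMatrix | None = None
                     ) -> hp.HaplotypeModel:
    if afm is None:
        freq = read_table(outdir / "freq_matrix.tsv").set_index("sample_id")
        F = freq.to_numpy(dtype=float)
        sample_ids = list(freq.index)
    else:
        F = afm.values
        sample_ids = list(afm.freq.index)
    seed = derive_seed(config.seed, "haplotypes")
    K = hp.select_k(F, seed=seed) if config.auto_k else min(
        config.k, hp.haplotype_cap(F.shape[1]))
    model = hp.deconvolve(F, K, n_restarts=config.n_restarts, seed=seed)
    hdf = pd.DataFrame(model.H, columns=[f"site{s + 1}" for s in
                                         range(model.H.shape[1])])
    hdf.insert(0, "haplotype", np.arange(1, model.K + 1))
    path = outdir / "haplotypes.tsv"
    write_table(hdf, path)
    manifest.add(path, "haplotypes", len(hdf))
    pdf = model.frequencies_frame(sample_ids)
    path = outdir / "haplotype_frequencies.tsv"
    write_table(pdf, path)
    manifest.add(path, "haplotypes", len(pdf))
    if model.K >= 2:
        D, _ = hp.pairwise_differences(model.H)
        ddf = pd.DataFrame(D, columns=[f"hap{k + 1}" for k in range(model.K)])
        ddf.insert(0, "haplotype", [f"hap{k + 1}" for k in range(model.K)])
        path = outdir / "haplotype_distances.tsv"
        write_table(ddf, path)
        manifest.add(path, "haplotypes", len(ddf))
        net = hp.network_frame(hp.build_network(D))
        path = outdir / "haplotype_network.tsv"
        write_table(net, path)
        manifest.add(path, "haplotypes", len(net))
    return model


def stage_stats(config: RunConfig, outdir: Path, manifest: Manifest) -> pd.DataFrame:
    cn_table = read_table(outdir / "copy_number.tsv")
    meta = metadata_frame(read_metadata(outdir / "metadata.tsv"))
    table = cn_table[cn_table["region"] == "28S"].merge(meta, on="sample_id")
    rows = []
    groups = {t: g["diploid_cn"].to_numpy()
              for t, g in table.groupby("treatment")}
    if len(groups) >= 2 and min(len(v) for v in groups.values()) >= 3:
        res = gated_location_test(groups, alpha_gate=config.alpha,
                                  alpha=config.alpha)
        rows.append({"test": "cn_by_treatment", "branch": res.branch,
                     "shapiro_p": res.shapiro_p, "statistic": res.statistic,
                     "p": res.p,
                     "excluded": ";".join(res.excluded_samples)})
    rates_df = read_table(outdir / "change_rates.tsv")
    if len(rates_df) >= 2 and rates_df["rate"].var() > 0:
        t, p = one_sample_t(rates_df["rate"].to_numpy())
        rows.append({"test": "signed_rate_vs_0", "branch": "t",
                     "shapiro_p": np.nan, "statistic": t, "p": p,
                     "excluded": ""})
    report = pd.DataFrame(rows)
    path = outdir / "stats_report.tsv"
    write_table(report, path)
    manifest.add(path, "stats", len(report))
    return report


def run_pipeline(config: RunConfig, outdir: str | Path) -> pd.DataFrame:
    """Run every stage; returns the manifest of produced tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.echo(outdir)
    manifest = Manifest(outdir)
    stage = "simulate"
    try:
        stage_simulate(config, outdir, manifest)
        stage = "copynumber"
        cn_table = stage_copynumber(config, outdir, manifest)
        stage = "rates"
        stage_rates(config, outdir, manifest, cn_table)
        stage = "variants"
        afm = stage_variants(config, outdir, manifest)
        stage = "haplotypes"
        stage_haplotypes(config, outdir, manifest, afm)
        stage = "stats"
        stage_stats(config, outdir, manifest)
    except Exception:
        manifest.write()
        logger.error("pipeline aborted in stage %r", stage)
        raise
    return manifest.write()
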