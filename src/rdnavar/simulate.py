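"""Forward simulator of rDNA arrays evolving by unequal crossing-over.

The model: each diploid individual carries two haploid tandem arrays of
repeat units; every unit bears one of K sequence haplotypes, laid out in
clustered blocks as inferred for real arrays. Each generation (a
single-individual bottleneck, as in a mutation-accumulation design) each
haploid array independently experiences at most one unequal-crossover
event with probability ``event_rate``: a *gain* duplicates a contiguous
block of ``m`` units in place (tandem duplication, preserving clustering);
a *loss* deletes a contiguous block of ``min(m, n_units - 1)`` units, so
an array never empties. Event magnitudes ``m`` are geometric; the gain
probability is ``direction_bias`` (0.5 = unbiased drift).

On top of the array process the simulator emits the two sequencing
observables the analysis pipeline consumes, with known ground truth:

* per-base read depth for the rDNA regions (mean proportional to diploid
  copy number) and for 16 single-copy exons (mean = ``exon_mean_depth``),
  Poisson or negative-binomial, with optional zero-depth "dead zones";
* per-SNP-site nucleotide counts drawn from the array's exact haplotype
  composition with a symmetric per-base miscall rate.

All randomness flows from one seed through named per-operation streams so
each stage is independently reproducible.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import DepthProfile, write_table

#: Region lengths (nt) of the four rDNA references after end-trimming.
DEFAULT_REGION_LENGTHS = {"18S": 2292, "28S": 4376, "IGS1": 571, "IGS2": 3123}

#: Lengths of the 16 single-copy exons used for depth normalisation. The
#: real exon set has heterogeneous lengths; these emulate that spread.
DEFAULT_EXON_LENGTHS = (
    312, 258, 447, 390, 201, 528, 366, 285, 423, 336, 249, 477, 309, 381, 294, 432,
)


def derive_seed(base_seed: int, name: str) -> int:
    """Deterministic per-stream seed below 2**31, derived from one base seed."""
    digest = hashlib.blake2s(f"{base_seed}:{name}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclass
class SimConfig:
    """Study conditions for one simulated lineage.

    Defaults mirror the cyclically parthenogenetic (SX-like) lineage: 4
    haplotypes segregating at 25 SNP sites, progenitor haploid arrays of
    190 units (diploid 380), ~100 generations of propagation, 100× exon
    depth. ``event_rate`` is per haploid array per generation;
    ``magnitude_dist`` is geometric with the given success probability
    (mean 1/p units gained or lost per event).
    """

    n_haplotypes: int = 4
    n_snps: int = 25
    haplotype_matrix_seed: int = 7
    progenitor_haploid_cn: int = 190
    block_structure: tuple[tuple[int, int], ...] | None = None
    event_rate: float = 0.2
    magnitude_dist: tuple[str, float] = ("geometric", 0.1)
    direction_bias: float = 0.5
    generations: int = 100
    exon_mean_depth: float = 100.0
    overdispersion: float = 0.0
    error_rate: float = 0.001
    dead_zones: tuple[tuple[str, int, int], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.event_rate <= 1.0:
            raise ValueError("event_rate must lie in [0, 1]")
        if not 0.0 <= self.error_rate < 0.25:
            raise ValueError("error_rate must lie in [0, 0.25)")
        if self.block_structure is None:
            self.block_structure = default_blocks(
                self.n_haplotypes, self.progenitor_haploid_cn
            )
        total = sum(run for _, run in self.block_structure)
        if total != self.progenitor_haploid_cn:
            raise ValueError(
                "block_structure run lengths must sum to progenitor_haploid_cn"
            )
        for hap, _ in self.block_structure:
            if not 1 <= hap <= self.n_haplotypes:
                raise ValueError("block haplotype ids must lie in 1..K")


def default_blocks(K: int, haploid_cn: int) -> tuple[tuple[int, int], ...]:
    """K near-equal clustered blocks covering the progenitor array."""
    base, extra = divmod(haploid_cn, K)
    return tuple((k + 1, base + (1 if k < extra else 0)) for k in range(K))


@dataclass
class ArrayState:
    """Unit-level state of one diploid individual's two rDNA arrays."""

    arrays: tuple[np.ndarray, np.ndarray]
    generation: int = 0

    @property
    def diploid_cn(self) -> int:
        return int(sum(a.size for a in self.arrays))

    @property
    def haploid_cn(self) -> float:
        return self.diploid_cn / 2.0

    def haplotype_counts(self, K: int) -> np.ndarray:
        """Unit counts per haplotype id (1..K) across both arrays."""
        counts = np.zeros(K, dtype=np.int64)
        for arr in self.arrays:
            counts += np.bincount(arr, minlength=K + 1)[1:]
        return counts

    def haplotype_frequencies(self, K: int) -> np.ndarray:
        counts = self.haplotype_counts(K)
        return counts / counts.sum()


def progenitor_state(config: SimConfig) -> ArrayState:
    """Two identical haploid arrays laid out per the block structure."""
    units = np.concatenate([
        np.full(run, hap, dtype=np.int16) for hap, run in config.block_structure
    ])
    return ArrayState(arrays=(units.copy(), units.copy()), generation=0)


def make_haplotypes(K: int, S: int, seed: int) -> np.ndarray:
    """Draw K distinct binary haplotype rows over S SNP sites.

    Row k gives the allele-2 indicator of haplotype k at each site.
    Raises if K > 2**S (distinct rows infeasible).
    """
    if K < 1 or S < 1:
        raise ValueError("K and S must be >= 1")
    if S < 63 and K > 2**S:
        raise ValueError(f"cannot draw {K} distinct binary rows over {S} sites")
    rng = np.random.default_rng(seed)
    rows: list[tuple[int, ...]] = []
    seen: set[tuple[int, ...]] = set()
    while len(rows) < K:
        cand = tuple(rng.integers(0, 2, size=S).tolist())
        if cand not in seen:
            seen.add(cand)
            rows.append(cand)
    return np.array(rows, dtype=np.int8)


def _draw_magnitude(rng: np.random.Generator, dist: tuple[str, float]) -> int:
    name, param = dist
    if name == "geometric":
        return int(rng.geometric(param))
    if name == "constant":
        return int(param)
    raise ValueError(f"unknown magnitude distribution {name!r}")


def _apply_event(units: np.ndarray, rng: np.random.Generator,
                 magnitude_dist: tuple[str, float], direction_bias: float) -> np.ndarray:
    """One unequal-crossover event on one haploid array."""
    n = units.size
    m = _draw_magnitude(rng, magnitude_dist)
    gain = rng.random() < direction_bias
    if gain:
        m = min(m, n)  # a duplicated block must exist within the array
        start = int(rng.integers(0, n - m + 1))
        block = units[start:start + m]
        return np.concatenate([units[:start + m], block, units[start + m:]])
    m = min(m, n - 1)  # array never empties
    if m == 0:
        return units
    start = int(rng.integers(0, n - m + 1))
    return np.concatenate([units[:start], units[start + m:]])


def propagate_line(state: ArrayState, config: SimConfig, n_gen: int,
                   seed: int) -> list[ArrayState]:
    """Propagate one line for ``n_gen`` generations; returns one state per
    generation (the input state is not included).

    With ``event_rate`` 0 the copy number and haplotype composition are
    exactly conserved.
    """
    rng = np.random.default_rng(seed)
    out: list[ArrayState] = []
    arrays = [a.copy() for a in state.arrays]
    # bulk-draw the per-array event indicators once for speed
    events = rng.random((n_gen, 2)) < config.event_rate
    for g in range(n_gen):
        for j in range(2):
            if events[g, j]:
                arrays[j] = _apply_event(arrays[j], rng, config.magnitude_dist,
                                         config.direction_bias)
        out.append(ArrayState(arrays=(arrays[0].copy(), arrays[1].copy()),
                              generation=state.generation + g + 1))
    return out


def force_gain(state: ArrayState, array_index: int, start: int, m: int) -> ArrayState:
    """Deterministically duplicate units[start:start+m]; for tests/demos."""
    units = state.arrays[array_index]
    block = units[start:start + m]
    new = np.concatenate([units[:start + m], block, units[start + m:]])
    arrays = list(state.arrays)
    arrays[array_index] = new
    return ArrayState(arrays=tuple(arrays), generation=state.generation)


def simulate_cn_trajectories(n_lines: int, n_gen: int, config: SimConfig,
                             seed: int,
                             snapshot_generations: Sequence[int] | None = None
                             ) -> np.ndarray:
    """Vectorised diploid-copy-number-only propagation.

    Implements the same marginal event law as :func:`propagate_line` (two
    independent haploid arrays, per-array event probability, geometric
    magnitudes clamped so gains never exceed and losses never empty an
    array) without tracking unit identities. Returns an array of shape
    ``(n_lines, len(snapshot_generations))`` of diploid copy numbers
    (default: a single snapshot at ``n_gen``).
    """
    if snapshot_generations is None:
        snapshot_generations = [n_gen]
    name, p = config.magnitude_dist
    if name != "geometric":
        raise ValueError("fast path supports geometric magnitudes only")
    rng = np.random.default_rng(seed)
    # haploid unit counts per array
    cn = np.full((n_lines, 2), config.progenitor_haploid_cn, dtype=np.int64)
    snaps = np.empty((n_lines, len(snapshot_generations)), dtype=np.int64)
    snap_at = {g: i for i, g in enumerate(snapshot_generations)}
    for g in range(1, n_gen + 1):
        hit = rng.random((n_lines, 2)) < config.event_rate
        m = rng.geometric(config.magnitude_dist[1], size=(n_lines, 2))
        gain = rng.random((n_lines, 2)) < config.direction_bias
        delta = np.where(gain, np.minimum(m, cn), -np.minimum(m, cn - 1))
        cn = cn + np.where(hit, delta, 0)
        if g in snap_at:
            snaps[:, snap_at[g]] = cn.sum(axis=1)
    return snaps


def _draw_counts(rng: np.random.Generator, mean: float, size: int,
                 overdispersion: float) -> np.ndarray:
    """Poisson counts, or negative binomial with var = mu + a*mu^2."""
    if overdispersion <= 0:
        return rng.poisson(mean, size=size)
    n = 1.0 / overdispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


def emit_depth(state: ArrayState, config: SimConfig,
               region_lengths: dict[str, int] | None = None,
               seed: int = 0,
               exon_lengths: Sequence[int] | None = None,
               sample_id: str = "sim") -> dict[str, DepthProfile]:
    """Emit per-base depth for the rDNA regions and the 16 exons.

    Exon depth has mean ``exon_mean_depth``; rDNA depth has mean
    ``exon_mean_depth * diploid_cn / 2`` (depth scales with haploid copy
    number). Dead-zone positions are forced to 0 after the draw.
    """
    region_lengths = dict(region_lengths or DEFAULT_REGION_LENGTHS)
    exon_lengths = tuple(exon_lengths or DEFAULT_EXON_LENGTHS)
    rng = np.random.default_rng(seed)
    d = config.exon_mean_depth
    rdna_mean = d * state.diploid_cn / 2.0
    profiles: dict[str, DepthProfile] = {}
    for region, L in region_lengths.items():
        depth = _draw_counts(rng, rdna_mean, L, config.overdispersion)
        profiles[region] = DepthProfile(region=region, sample_id=sample_id, depth=depth)
    for i, L in enumerate(exon_lengths, start=1):
        name = f"exon{i:02d}"
        depth = _draw_counts(rng, d, L, config.overdispersion)
        profiles[name] = DepthProfile(region=name, sample_id=sample_id, depth=depth)
    for region, start, end in config.dead_zones:
        if region in profiles:
            profiles[region].depth[start - 1:end] = 0
    return profiles


def default_site_map(S: int, region_lengths: dict[str, int] | None = None
                     ) -> pd.DataFrame:
    """Place S SNP sites across 28S and IGS2 with fixed ref/alt bases.

    Mirrors the empirical pattern that retained rDNA SNPs concentrate in
    the 28S gene and the second intergenic spacer.
    """
    region_lengths = dict(region_lengths or DEFAULT_REGION_LENGTHS)
    n_28s = S // 3
    rows = []
    refs = "ACGT"
    alts = {"A": "G", "C": "T", "G": "A", "T": "C"}
    for s in range(S):
        if s < n_28s:
            region = "28S"
            pos = 100 + s * (region_lengths["28S"] - 200) // max(n_28s, 1)
        else:
            region = "IGS2"
            j = s - n_28s
            pos = 50 + j * (region_lengths["IGS2"] - 100) // max(S - n_28s, 1)
        ref = refs[s % 4]
        rows.append({"site_index": s, "region": region, "position": int(pos),
                     "ref_base": ref, "alt_base": alts[ref]})
    return pd.DataFrame(rows)


def emit_allele_counts(state: ArrayState, H: np.ndarray, config: SimConfig,
                       site_depth_mean: float, seed: int,
                       site_map: pd.DataFrame | None = None,
                       sample_id: str = "sim") -> pd.DataFrame:
    """Emit per-site ACGT counts from the exact haplotype composition.

    At each site the true allele-2 frequency is the fraction of units
    whose haplotype carries allele 2 there; reads are multinomial with
    allele-2 probability ``f(1-e) + (1-f)e/3`` (the remaining error mass
    split over the two off-target nucleotides), depth Poisson around
    ``site_depth_mean``.
    """
    K, S = H.shape
    if site_map is None:
        site_map = default_site_map(S)
    rng = np.random.default_rng(seed)
    hap_freq = state.haplotype_frequencies(K)
    f_alt = hap_freq @ H  # true allele-2 frequency per site
    eps = config.error_rate
    records = []
    for s in range(S):
        info = site_map.iloc[s]
        ref, alt = info["ref_base"], info["alt_base"]
        others = [b for b in "ACGT" if b not in (ref, alt)]
        f = float(f_alt[s])
        p = dict.fromkeys("ACGT", 0.0)
        p[alt] = f * (1 - eps) + (1 - f) * (eps / 3)
        p[ref] = (1 - f) * (1 - eps) + f * (eps / 3)
        for b in others:
            p[b] = eps / 3
        depth = int(rng.poisson(site_depth_mean))
        draws = rng.multinomial(depth, [p["A"], p["C"], p["G"], p["T"]])
        records.append({
            "sample_id": sample_id, "region": info["region"],
            "position": int(info["position"]), "ref_base": ref,
            "nA": int(draws[0]), "nC": int(draws[1]),
            "nG": int(draws[2]), "nT": int(draws[3]),
        })
    df = pd.DataFrame.from_records(records)
    df["total"] = df[["nA", "nC", "nG", "nT"]].sum(axis=1)
    return df


def write_truth(states: dict[str, ArrayState], H: np.ndarray,
                P_true: pd.DataFrame, outdir: str | Path) -> None:
    """Write ground-truth tables (copy number per sample, haplotype matrix,
    per-sample haplotype frequencies) for test harnesses; round-trip stable."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cn = pd.DataFrame(
        [(sid, st.generation, st.diploid_cn) for sid, st in states.items()],
        columns=["sample_id", "generation", "diploid_cn"],
    )
    write_table(cn, outdir / "truth_copy_number.tsv")
    hdf = pd.DataFrame(H, columns=[f"site{s}" for s in range(H.shape[1])])
    hdf.insert(0, "haplotype", np.arange(1, H.shape[0] + 1))
    write_table(hdf, outdir / "truth_haplotypes.tsv")
    write_table(P_true, outdir / "truth_frequencies.tsv")


def simulate_frequency_matrix(config: SimConfig, n_lines: int, seed: int,
                              noise_sd: float = 0.01
                              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate lines and return (F, P_true, H) for deconvolution tests.

    F = P_true @ H + Gaussian noise (sd ``noise_sd``), clipped to [0, 1] —
    the allele-frequency matrix an error-free variant pipeline would see,
    with measurement noise.
    """
    K, S = config.n_haplotypes, config.n_snps
    H = make_haplotypes(K, S, config.haplotype_matrix_seed)
    P = np.empty((n_lines, K))
    for i in range(n_lines):
        line_seed = derive_seed(seed, f"line{i}")
        states = propagate_line(progenitor_state(config), config,
                                config.generations, line_seed)
        P[i] = states[-1].haplotype_frequencies(K)
    rng = np.random.default_rng(derive_seed(seed, "freq-noise"))
    F = P @ H + rng.normal(0.0, noise_sd, size=(n_lines, S))
    return np.clip(F, 0.0, 1.0), P, H


def simulate_dataset(config: SimConfig, n_lines: int, seed: int,
                     sampling_generation: int | None = None,
                     lineage: str = "SX",
                     treatments: Sequence[str] | None = None,
                     site_depth_mean: float | None = None) -> dict:
    """Simulate a full observable dataset for ``n_lines`` lines.

    SNP sites lie inside the rDNA array, so by default each sample's
    per-site depth is ``exon_mean_depth x diploid_cn / 2`` — the same
    scaling the depth profiles follow; pass ``site_depth_mean`` to
    override with a flat depth. Returns a dict with per-sample depth
    profiles, a pooled allele-count table, metadata records, the truth
    haplotype matrix H, truth frequencies P, and truth diploid copy
    numbers.
    """
    from .io_formats import LineRecord

    gen = sampling_generation or config.generations
    K, S = config.n_haplotypes, config.n_snps
    H = make_haplotypes(K, S, config.haplotype_matrix_seed)
    site_map = default_site_map(S)
    if treatments is None:
        treatments = ["control"] * n_lines
    depth_profiles: dict[str, dict[str, DepthProfile]] = {}
    counts_frames = []
    records = []
    states: dict[str, ArrayState] = {}
    P_rows = []
    for i in range(n_lines):
        sid = f"{lineage}{i + 1:03d}_{gen}"
        line_seed = derive_seed(seed, f"line{i}")
        traj = propagate_line(progenitor_state(config), config, gen, line_seed)
        st = traj[-1]
        states[sid] = st
        depth_profiles[sid] = emit_depth(
            st, config, seed=derive_seed(seed, f"depth{i}"), sample_id=sid)
        depth = (site_depth_mean if site_depth_mean is not None
                 else config.exon_mean_depth * st.diploid_cn / 2.0)
        counts_frames.append(emit_allele_counts(
            st, H, config, depth,
            seed=derive_seed(seed, f"counts{i}"), site_map=site_map, sample_id=sid))
        records.append(LineRecord(sample_id=sid, lineage=lineage,
                                  treatment=treatments[i], line_number=i + 1,
                                  generation=gen))
        P_rows.append(st.haplotype_frequencies(K))
    P_true = pd.DataFrame(np.array(P_rows),
                          columns=[f"hap{k + 1}" for k in range(K)])
    P_true.insert(0, "sample_id", list(states))
    return {
        "config": config, "H": H, "site_map": site_map,
        "depth_profiles": depth_profiles, "allele_counts": pd.concat(
            counts_frames, ignore_index=True),
        "metadata": records, "states": states, "P_true": P_true,
    }
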