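"""Synthetic genomes, callsets, peak experiments and segmentations.

The generator is the test-bed for the whole pipeline: every quantity the
analysis estimates is *injected* at the level at which it is estimated, so
parameter recovery is well-posed:

* breakpoints are drawn from a piecewise-constant density over
  distance-to-gene rings (relative weight β^(1−i/m) in ring i, 1 outside;
  with the default single ring at the gene threshold this is the two-level
  genophilic/genophobic model: β > 1 attracts breakpoints to genes, β < 1
  repels them);
* peak experiments place coverage so that the per-base coverage *odds* are
  2^θ-fold higher inside the breakpoint vicinity than outside (optionally
  with separate θ near/far from genes, and an extra gene-affinity log2-odds
  term decaying over rings), under a total coverage budget.  Peaks follow a
  Boolean model with intensity μ = −ln(1−p)/L and wrap around inside each
  placement region, so the realized per-base coverage probability equals the
  solved p without edge bias;
* segmentations tile each chromosome with geometric-length blocks whose
  states are drawn from configurable weights;
* synergy groups plant sites shared by exactly two proteins with a higher
  vicinity rate ratio than single-protein sites, giving a known log2 OR gap.

All randomness flows from one integer seed through independent child
streams per section, so adding peak experiments never perturbs the callset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from .chromstate import StateSegmentation
from .genome import GenomeLayout, IntervalSet, distance_partition
from .io import PeakExperiment, SMCallset, SMEvent

__all__ = [
    "SimConfig",
    "GenomeSpec",
    "GeneSpec",
    "EventSpec",
    "PeakSpec",
    "SegmentationSpec",
    "simulate_genome_and_genes",
    "simulate_callset",
    "simulate_peaks",
    "simulate_segmentation",
    "simulate_binding_group",
    "shuffle_pairings",
    "simulate_study",
    "write_study",
]

DEFAULT_STATES = (
    "1_Active_Promoter",
    "2_Weak_Promoter",
    "3_Poised_Promoter",
    "4_Strong_Enhancer",
    "5_Strong_Enhancer",
    "6_Weak_Enhancer",
    "7_Weak_Enhancer",
    "8_Insulator",
    "9_Txn_Transition",
    "10_Txn_Elongation",
    "11_Weak_Txn",
    "12_Repressed",
    "13_Heterochrom_lo",
    "14_Repetitive_CNV",
    "15_Repetitive_CNV",
)


@dataclass
class GenomeSpec:
    chrom_lengths: tuple[int, ...] = (5_000_000, 3_000_000, 2_000_000)


@dataclass
class GeneSpec:
    count: int = 100
    mean_length: int = 10_000
    sd_length: int = 3_000
    min_length: int = 200


@dataclass
class EventSpec:
    count: int = 250
    interchrom_fraction: float = 0.3
    gene_bias: float = 1.0  # β: breakpoint density weight near genes
    bias_ring_cutoffs: tuple[int, ...] | None = None  # default: (gene_threshold,)
    intra_distance_mean: int = 50_000


@dataclass
class PeakSpec:
    count: int = 2_000
    length: int = 500
    theta: float | tuple[float, float] = 0.0  # log2 coverage OR in the vicinity
    gene_affinity: float = 0.0  # extra log2 coverage odds at gene bodies
    affinity_decay: float = 0.5
    affinity_ring_cutoffs: tuple[int, ...] | None = None

    @property
    def theta_near(self) -> float:
        return self.theta[0] if isinstance(self.theta, (tuple, list)) else self.theta

    @property
    def theta_far(self) -> float:
        return self.theta[1] if isinstance(self.theta, (tuple, list)) else self.theta


@dataclass
class SegmentationSpec:
    states: tuple[str, ...] = DEFAULT_STATES
    mean_block_length: int = 20_000
    weights: tuple[float, ...] | None = None  # default uniform


@dataclass
class SimConfig:
    """Study conditions for one synthetic run (scaled-down genome).

    The default vicinity radius (2 kb) and gene threshold (5 kb) are the
    50 kb / 60 kb analysis parameters shrunk to keep the vicinity and the
    near-gene stratum at workable fractions (~20% each) of a 10 Mb genome.
    """

    seed: int = 0
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    genes: GeneSpec = field(default_factory=GeneSpec)
    events: EventSpec = field(default_factory=EventSpec)
    peaks: PeakSpec = field(default_factory=PeakSpec)
    segmentation: SegmentationSpec = field(default_factory=SegmentationSpec)
    vicinity_radius: int = 2_000
    gene_threshold: int = 5_000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        sections = {
            "genome": GenomeSpec,
            "genes": GeneSpec,
            "events": EventSpec,
            "peaks": PeakSpec,
            "segmentation": SegmentationSpec,
        }
        for key, val in raw.items():
            if key in sections:
                val = {
                    k: tuple(v) if isinstance(v, list) else v for k, v in val.items()
                }
                kwargs[key] = sections[key](**val)
            else:
                kwargs[key] = val
        return cls(**kwargs)


# fixed child-stream indices: adding experiments never perturbs earlier stages
_STREAMS = {"genes": 0, "callset": 1, "segmentation": 2, "peaks": 3, "synergy": 4}


def _rng(seed: int, section: str, index: int = 0) -> np.random.Generator:
    ss = np.random.SeedSequence(seed, spawn_key=(_STREAMS[section], index))
    return np.random.default_rng(ss)


# -- low-level samplers -----------------------------------------------------


def _sample_in_set(rng: np.random.Generator, iset: IntervalSet, n: int) -> list[tuple[str, int]]:
    """n positions uniform over the covered bases of ``iset``."""
    pairs = iset.to_pairs()
    lengths = np.array([e - s for _, s, e in pairs], dtype=np.int64)
    cum = np.cumsum(lengths)
    draws = rng.integers(0, cum[-1], size=n)
    idx = np.searchsorted(cum, draws, side="right")
    out = []
    for d, i in zip(draws, idx):
        chrom, s, _ = pairs[i]
        offset = int(d) - (int(cum[i - 1]) if i > 0 else 0)
        out.append((chrom, s + offset))
    return out


def _sample_weighted(
    rng: np.random.Generator,
    regions: list[IntervalSet],
    weights: list[float],
    n: int,
) -> list[tuple[str, int]]:
    """n positions from a piecewise-constant density (weight per region)."""
    mass = np.array([w * r.size for w, r in zip(weights, regions)], dtype=float)
    if mass.sum() <= 0:
        raise ValueError("no positive-mass region to sample from")
    counts = rng.multinomial(n, mass / mass.sum())
    out = []
    for region, c in zip(regions, counts):
        if c:
            out.extend(_sample_in_set(rng, region, int(c)))
    return out


# -- generators -------------------------------------------------------------


def simulate_genome_and_genes(config: SimConfig) -> tuple[GenomeLayout, IntervalSet]:
    """Autosome-like layout plus non-overlapping gene spans (rejection-placed)."""
    layout = GenomeLayout(
        [(f"chr{i + 1}", l) for i, l in enumerate(config.genome.chrom_lengths)]
    )
    rng = _rng(config.seed, "genes")
    spec = config.genes
    placed: dict[str, list[tuple[int, int]]] = {n: [] for n in layout.names}
    chrom_lengths = np.array([l for _, l in layout], dtype=float)
    chrom_probs = chrom_lengths / chrom_lengths.sum()
    attempts, max_attempts = 0, max(1000, 100 * spec.count)
    n_placed = 0
    while n_placed < spec.count:
        if attempts >= max_attempts:
            raise ValueError(
                f"could not place {spec.count} genes after {max_attempts} attempts; "
                "reduce count or gene length"
            )
        attempts += 1
        ci = rng.choice(len(layout.names), p=chrom_probs)
        chrom, length = layout.chromosomes[ci]
        glen = int(
            max(spec.min_length, rng.normal(spec.mean_length, spec.sd_length))
        )
        if glen >= length:
            continue
        start = int(rng.integers(0, length - glen))
        end = start + glen
        if any(start < e and s < end for s, e in placed[chrom]):
            continue
        placed[chrom].append((start, end))
        n_placed += 1
    pairs = [(c, s, e) for c, spans in placed.items() for s, e in spans]
    return layout, IntervalSet.from_pairs(layout, pairs)


def _gene_rings(
    genes: IntervalSet, cutoffs: tuple[int, ...], layout: GenomeLayout
) -> list[IntervalSet]:
    """Distance rings: [genes themselves + ring1, ..., outside]."""
    return distance_partition(genes, list(cutoffs), layout)


def simulate_callset(
    config: SimConfig,
    layout: GenomeLayout,
    genes: IntervalSet,
    label: str = "sim",
) -> SMCallset:
    """Breakpoint pairs with gene-proximity bias β and an inter/intra mix."""
    spec = config.events
    rng = _rng(config.seed, "callset")
    if spec.count == 0:
        return SMCallset(label=label, events=[])
    if spec.gene_bias <= 0:
        raise ValueError("gene_bias must be positive")
    cutoffs = spec.bias_ring_cutoffs or (config.gene_threshold,)
    if genes.is_empty:
        rings = [IntervalSet.whole_genome(layout)]
        weights = [1.0]
    else:
        rings = _gene_rings(genes, cutoffs, layout)
        m = len(cutoffs)
        weights = [spec.gene_bias ** (1.0 - i / m) for i in range(m)] + [1.0]
        # rings = m+1 sets: the last is the outside-the-largest-cutoff remainder
        weights = weights[: len(rings) - 1] + [1.0]
    n_inter = int(rng.binomial(spec.count, spec.interchrom_fraction))
    if n_inter > 0 and len(layout.names) < 2:
        raise ValueError("interchromosomal events need at least two chromosomes")
    first_ends = _sample_weighted(rng, rings, weights, spec.count)
    events: list[SMEvent] = []
    for i, (chrom1, pos1) in enumerate(first_ends):
        if i < n_inter:
            for _ in range(1000):
                (chrom2, pos2), = _sample_weighted(rng, rings, weights, 1)
                if chrom2 != chrom1:
                    break
            else:
                raise ValueError("could not draw a second end on another chromosome")
        else:
            length = layout.length(chrom1)
            chrom2 = chrom1
            for _ in range(100):
                d = 1 + int(rng.exponential(spec.intra_distance_mean))
                pos2 = pos1 + d if rng.random() < 0.5 else pos1 - d
                if 0 <= pos2 < length:
                    break
                pos2 = pos1 - d if pos2 >= length else pos1 + d
                if 0 <= pos2 < length:
                    break
            else:
                pos2 = int(np.clip(pos1 + 1, 0, length - 1))
        events.append(
            SMEvent(event_id=f"sim{i}", chrom1=chrom1, pos1=pos1, chrom2=chrom2, pos2=int(pos2))
        )
    return SMCallset(label=label, events=events)


def _place_boolean_peaks(
    rng: np.random.Generator,
    region: IntervalSet,
    p: float,
    peak_length: int,
) -> list[tuple[str, int, int]]:
    """Boolean-model peaks inside ``region`` with per-base coverage prob p.

    Peak starts form a Poisson process of intensity −ln(1−p)/L per base and
    wrap around within each region interval, so coverage probability is
    exactly p for intervals longer than L (shorter intervals saturate).
    """
    if p <= 0 or region.is_empty:
        return []
    if p >= 1.0 - 1e-12:
        return region.to_pairs()
    mu = -math.log1p(-p) / peak_length
    pieces: list[tuple[str, int, int]] = []
    for chrom, s, e in region.to_pairs():
        ivl_len = e - s
        n = rng.poisson(mu * ivl_len)
        if n == 0:
            continue
        if ivl_len <= peak_length:
            pieces.append((chrom, s, e))
            continue
        offs = rng.integers(0, ivl_len, size=n)
        for off in offs:
            off = int(off)
            stop = off + peak_length
            pieces.append((chrom, s + off, s + min(stop, ivl_len)))
            if stop > ivl_len:  # wrap-around remainder
                pieces.append((chrom, s, s + stop - ivl_len))
    return pieces


def _coverage_regions(
    config: SimConfig,
    layout: GenomeLayout,
    vicinity: IntervalSet,
    genes: IntervalSet | None,
    theta_near: float,
    theta_far: float,
) -> list[tuple[IntervalSet, float]]:
    """(region, log2-odds offset) decomposition for peak placement."""
    spec = config.peaks
    needs_strata = genes is not None and (
        theta_near != theta_far or spec.gene_affinity != 0.0
    )
    vic_parts = [(vicinity, True), (vicinity.complement(), False)]
    if not needs_strata:
        return [(r, theta_near if in_v else 0.0) for r, in_v in vic_parts]
    cutoffs = spec.affinity_ring_cutoffs or (
        config.gene_threshold // 4,
        config.gene_threshold // 2,
        config.gene_threshold,
    )
    rings = _gene_rings(genes, cutoffs, layout)
    m = len(rings) - 1
    ring_offsets = [
        spec.gene_affinity * (spec.affinity_decay**i) for i in range(m)
    ] + [0.0]
    near = genes.dilate(config.gene_threshold)
    out: list[tuple[IntervalSet, float]] = []
    for vic_set, in_v in vic_parts:
        for ring, ring_off in zip(rings, ring_offsets):
            piece = vic_set.intersect(ring)
            if piece.is_empty:
                continue
            # a ring is near-gene iff its outer cutoff ≤ gene threshold; with
            # default cutoffs every proper ring is near and the remainder far
            in_near = not near.intersect(piece).is_empty and near.intersect(piece).size == piece.size
            theta = (theta_near if in_near else theta_far) if in_v else 0.0
            out.append((piece, theta + ring_off))
    return out


def simulate_peaks(
    config: SimConfig,
    layout: GenomeLayout,
    vicinity: IntervalSet,
    genes: IntervalSet | None = None,
    *,
    index: int = 0,
    target: str | None = None,
    cell_line: str = "simCL",
    lab: str = "simLAB",
    assay_class: str = "chipseq",
) -> PeakExperiment:
    """One experiment with per-base coverage odds 2^θ-fold higher in the vicinity.

    Coverage probabilities p_in/p_out per region are solved so that the
    coverage odds ratios match the configured θ (and gene-affinity offsets)
    under the total budget count × length; the index selects an independent
    random stream per experiment.
    """
    spec = config.peaks
    if vicinity.is_empty:
        raise ValueError("vicinity is empty")
    if vicinity.size >= layout.total_size:
        raise ValueError("vicinity covers the whole genome: coverage OR undefined")
    budget = float(spec.count * spec.length)
    if budget >= layout.total_size:
        raise ValueError("coverage budget exceeds genome size")
    regions = _coverage_regions(
        config, layout, vicinity, genes, spec.theta_near, spec.theta_far
    )
    sizes = np.array([r.size for r, _ in regions], dtype=float)
    offsets_ln = np.array([o for _, o in regions], dtype=float) * math.log(2.0)

    def covered(ln_base: float) -> float:
        return float((expit(ln_base + offsets_ln) * sizes).sum()) - budget

    ln_base = brentq(covered, -60.0, 60.0, xtol=1e-12)
    probs = expit(ln_base + offsets_ln)
    rng = _rng(config.seed, "peaks", index)
    pieces: list[tuple[str, int, int]] = []
    for (region, _), p in zip(regions, probs):
        pieces.extend(_place_boolean_peaks(rng, region, float(p), spec.length))
    return PeakExperiment(
        target=target if target is not None else f"protein{index}",
        cell_line=cell_line,
        lab=lab,
        assay_class=assay_class,
        peaks=IntervalSet.from_pairs(layout, pieces),
    )


def simulate_segmentation(config: SimConfig, layout: GenomeLayout) -> StateSegmentation:
    """Geometric-length blocks with states drawn by weight, tiling exactly."""
    spec = config.segmentation
    k = len(spec.states)
    weights = np.full(k, 1.0 / k) if spec.weights is None else np.asarray(spec.weights, float)
    if abs(weights.sum() - 1.0) > 1e-9 or (weights < 0).any():
        raise ValueError("state weights must be non-negative and sum to 1")
    if spec.mean_block_length <= 0:
        raise ValueError("mean block length must be positive")
    rng = _rng(config.seed, "segmentation")
    starts, ends, codes = {}, {}, {}
    for chrom, length in layout:
        s_list, e_list, c_list = [], [], []
        pos = 0
        while pos < length:
            block = int(rng.geometric(1.0 / spec.mean_block_length))
            state = int(rng.choice(k, p=weights))
            end = min(length, pos + block)
            if c_list and c_list[-1] == state:  # merge same-state neighbours
                e_list[-1] = end
            else:
                s_list.append(pos)
                e_list.append(end)
                c_list.append(state)
            pos = end
        starts[chrom] = np.asarray(s_list, dtype=np.int64)
        ends[chrom] = np.asarray(e_list, dtype=np.int64)
        codes[chrom] = np.asarray(c_list, dtype=np.int64)
    return StateSegmentation(
        layout=layout,
        catalog=list(spec.states),
        starts=starts,
        ends=ends,
        codes=codes,
        cell_line="simCL",
        lab="simLAB",
    )


def simulate_binding_group(
    config: SimConfig,
    layout: GenomeLayout,
    vicinity: IntervalSet,
    *,
    index: int = 0,
    proteins: tuple[str, str] = ("protA", "protB"),
    n_single: int = 800,
    n_shared: int = 400,
    site_length: int = 300,
    log2_rate_single: float = 0.5,
    log2_rate_shared: float = 1.5,
):
    """A two-protein group with a planted 2-vs-1 vicinity log2 rate-ratio gap.

    Single-protein sites go to one protein each with vicinity-vs-outside rate
    ratio 2^log2_rate_single per base; shared sites enter both proteins' peak
    sets with ratio 2^log2_rate_shared, so the planted synergy gap is
    log2_rate_shared − log2_rate_single.
    """
    from .synergy import BindingGroup

    rng = _rng(config.seed, "synergy", index)
    regions = [vicinity, vicinity.complement()]

    def sites(n: int, log2_ratio: float) -> IntervalSet:
        centers = _sample_weighted(rng, regions, [2.0**log2_ratio, 1.0], n)
        pairs = []
        for chrom, pos in centers:
            length = layout.length(chrom)
            s = max(0, pos - site_length // 2)
            e = min(length, s + site_length)
            pairs.append((chrom, s, e))
        return IntervalSet.from_pairs(layout, pairs)

    shared = sites(n_shared, log2_rate_shared)
    peak_sets = {
        name: sites(n_single, log2_rate_single).union(shared) for name in proteins
    }
    return BindingGroup(cell_line=f"simCL{index}", lab="simLAB", proteins=peak_sets)


def shuffle_pairings(callset: SMCallset, rng: np.random.Generator) -> SMCallset:
    """Random re-pairing of breakpoint ends (the independence null)."""
    firsts = [(e.chrom1, e.pos1) for e in callset.events]
    seconds = [(e.chrom2, e.pos2) for e in callset.events]
    perm = rng.permutation(len(seconds))
    events = [
        SMEvent(
            event_id=f"shuf{i}",
            chrom1=c1,
            pos1=p1,
            chrom2=seconds[j][0],
            pos2=seconds[j][1],
        )
        for i, ((c1, p1), j) in enumerate(zip(firsts, perm))
    ]
    return SMCallset(label=f"{callset.label}:shuffled", events=events)


def gene_bias_scenario(beta: float, seed: int = 0) -> SimConfig:
    """Study conditions emulating genophilic/genophobic cancers.

    Breakpoint weights decay from β at gene bodies over 2.5/5/10 kb rings and
    peak coverage carries a gene-affinity gradient (2 extra log2 odds at gene
    bodies, decaying by 0.4 per ring) plus vicinity coupling only far from
    genes (θ_near = 0, θ_far = 1.2).  With β > 1 the vicinity occupies the
    gene-proximal, high-coverage part of the near stratum (near-gene log2 OR
    > 0); with β < 1 it occupies the outer fringe (near-gene log2 OR < 0);
    the far-from-genes odds ratio exceeds the near one in both cases.
    """
    cfg = SimConfig(seed=seed)
    cfg.gene_threshold = 10_000
    cfg.events.gene_bias = beta
    cfg.events.bias_ring_cutoffs = (2_500, 5_000, 10_000)
    cfg.peaks.theta = (0.0, 1.2)
    cfg.peaks.gene_affinity = 2.0
    cfg.peaks.affinity_decay = 0.4
    cfg.peaks.affinity_ring_cutoffs = (2_500, 5_000, 10_000)
    return cfg


# -- whole-study convenience ------------------------------------------------


@dataclass
class SimulatedStudy:
    config: SimConfig
    layout: GenomeLayout
    genes: IntervalSet
    callset: SMCallset
    segmentation: StateSegmentation
    experiments: list[PeakExperiment]


def simulate_study(config: SimConfig, n_experiments: int = 1) -> SimulatedStudy:
    layout, genes = simulate_genome_and_genes(config)
    callset = simulate_callset(config, layout, genes)
    segmentation = simulate_segmentation(config, layout)
    vicinity = callset.breakpoints(layout).expand(config.vicinity_radius)
    experiments = [
        simulate_peaks(config, layout, vicinity, genes, index=i)
        for i in range(n_experiments)
    ]
    return SimulatedStudy(
        config=config,
        layout=layout,
        genes=genes,
        callset=callset,
        segmentation=segmentation,
        experiments=experiments,
    )


def write_study(study: SimulatedStudy, outdir: str | Path) -> dict[str, Path]:
    """Write all study files plus a peak manifest consumable by the pipeline."""
    from . import io as sio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["chrom_sizes"] = outdir / "chrom.sizes"
    with open(paths["chrom_sizes"], "w") as fh:
        for name, length in study.layout:
            fh.write(f"{name}\t{length}\n")
    paths["genes"] = outdir / "genes.bed"
    sio.write_bed(study.genes, paths["genes"])
    paths["callset"] = outdir / "callset.tsv"
    sio.write_sm_callset(study.callset, paths["callset"])
    paths["segmentation"] = outdir / "segmentation.bed"
    sio.write_segmentation(study.segmentation, paths["segmentation"])
    peak_dir = outdir / "peaks"
    peak_dir.mkdir(exist_ok=True)
    manifest_rows = []
    for i, exp in enumerate(study.experiments):
        p = peak_dir / f"exp{i}.bed"
        sio.write_bed(exp.peaks, p)
        manifest_rows.append(
            f"{exp.target}\t{exp.cell_line}\t{exp.lab}\t{exp.assay_class}\tpeaks/exp{i}.bed"
        )
    paths["manifest"] = outdir / "manifest.tsv"
    paths["manifest"].write_text(
        "target\tcell_line\tlab\tassay_class\tpath\n" + "\n".join(manifest_rows) + "\n"
    )
    return paths
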