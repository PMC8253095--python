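"""Deterministic generator of a complete toy multi-sample cistrome study.

The generator emits, for a configurable number of samples (default 4), the
data streams the analysis consumes: a random genome (FASTA + chrom.sizes), a
TSS annotation, dual-caller peak BEDs per sample and factor, fragment BEDs,
a JASPAR PWM library with one planted motif, gene sets (GMT), an expression
count table, and a JSON record of the planted ground truth.

Planted structure, mirroring the study design the analysis assumes:

* a large core peak set shared by every sample plus small per-sample specific
  sets, with core sites carrying ``core_signal_multiplier`` times the
  fragment intensity of specific sites;
* an active histone mark (H3K27ac) present at all core sites and at a planted
  "active" subset of the AR sample-specific sites in *every* sample,
  independent of AR occupancy (enhancers stay active where the factor is
  absent);
* H3K27me3 as a coverage-only background track (no peaks are called for it);
* a sequence motif planted preferentially in core sites;
* gene sets constructed so that one hallmark-like set and one essential-gene
  set are enriched among core-linked genes;
* a 4-sample expression matrix, negative-binomial, identical across samples
  except for exactly ``n_de_genes`` genes split between two 2-sample groups.

All randomness flows from one seed through named substreams, so individual
data streams are reproducible in isolation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import Genome, GenomicInterval, IntervalSet, write_bed, write_fasta
from .motifs import PWM, write_jaspar

PEAK_FACTORS = ("AR", "FOXA1", "CTCF", "H3K27ac")
COVERAGE_ONLY_FACTORS = ("H3K27me3",)
FACTORS = PEAK_FACTORS + COVERAGE_ONLY_FACTORS

# substream ids: one independent RNG per data stream
_STREAMS = {
    "genome": 0,
    "regions": 1,
    "genes": 2,
    "fragments": 3,
    "expression": 4,
    "motifs": 5,
    "callers": 6,
    "gene_sets": 7,
    "intensity": 8,
}


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chroms: int = 3
    chrom_length: int = 1_000_000
    n_genes: int = 200
    n_samples: int = 4
    n_core_peaks: int = 500
    n_specific_per_sample: int = 100
    peak_width_median: int = 300
    peak_width_sigma: float = 0.15
    core_signal_multiplier: float = 3.0
    specific_peak_fragments: float = 40.0  # mean fragments per specific peak
    background_rate: float = 0.003  # fragments per bp per track
    motif_plant_prob_core: float = 0.8
    motif_plant_prob_specific: float = 0.3
    active_fraction: float = 0.5  # of AR specific sites carrying H3K27ac
    n_de_genes: int = 2
    de_log2fc: float = 3.0
    nb_dispersion: float = 0.05
    read_length: int = 65
    caller2_jitter: int = 50
    caller2_dropout: float = 0.05
    n_library_pwms: int = 10  # planted motif + random decoys
    edge_margin: int = 2_500  # keep planted regions away from chrom ends
    min_region_gap: int = 2_000  # keeps +/-2 kb signal windows free of neighbors
    # planted regions occupy only the head of each chromosome; the tail is a
    # region-free "gene desert" so TSS-proximity linkage stays informative
    region_zone_fraction: float = 0.72

    def __post_init__(self) -> None:
        if min(
            self.n_chroms,
            self.chrom_length,
            self.n_genes,
            self.n_samples,
            self.n_core_peaks,
            self.n_specific_per_sample,
        ) <= 0:
            raise ValueError("all counts must be positive")
        for p in (
            self.motif_plant_prob_core,
            self.motif_plant_prob_specific,
            self.active_fraction,
            self.caller2_dropout,
        ):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_samples)]

    @property
    def group_a(self) -> list[str]:
        return self.sample_ids[: self.n_samples // 2]

    @property
    def group_b(self) -> list[str]:
        return self.sample_ids[self.n_samples // 2 :]


@dataclass
class SyntheticTruth:
    """Planted parameters the pipeline is asked to recover."""

    core_regions: list[tuple[str, int, int]]
    specific_regions: dict[str, list[tuple[str, int, int]]]  # sample -> AR specific
    active_specific: dict[str, list[tuple[str, int, int]]]  # active subset
    motif_id: str
    motif_placements: list[tuple[str, int]]  # (chrom, offset)
    de_genes: dict[str, float]  # gene id -> planted log2FC (group B vs A)
    shared_fraction: float  # per-sample planted core/(core+specific)
    region_intensity: dict[str, float]  # "chrom:start-end" -> base fragments
    expected_fragments: dict[str, float]  # "sample_factor" -> expected total

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["core_regions"] = [tuple(r) for r in d["core_regions"]]
        d["specific_regions"] = {
            s: [tuple(r) for r in rs] for s, rs in d["specific_regions"].items()
        }
        d["active_specific"] = {
            s: [tuple(r) for r in rs] for s, rs in d["active_specific"].items()
        }
        d["motif_placements"] = [tuple(p) for p in d["motif_placements"]]
        return cls(**d)

    def core_set(self) -> IntervalSet:
        return IntervalSet(GenomicInterval(*r) for r in self.core_regions)

    def specific_set(self, sample_id: str) -> IntervalSet:
        return IntervalSet(GenomicInterval(*r) for r in self.specific_regions[sample_id])

    def active_set(self, sample_id: str) -> IntervalSet:
        return IntervalSet(GenomicInterval(*r) for r in self.active_specific[sample_id])


@dataclass
class SyntheticDataset:
    """Paths of one generated dataset plus its in-memory truth."""

    root: Path
    config: SimulationConfig
    genome: Genome
    truth: SyntheticTruth

    @property
    def fasta(self) -> Path:
        return self.root / "genome.fa"

    @property
    def chrom_sizes(self) -> Path:
        return self.root / "genome.chrom.sizes"

    @property
    def genes_bed(self) -> Path:
        return self.root / "genes.bed"

    def caller_bed(self, sample_id: str, factor: str, caller: int) -> Path:
        return self.root / "peaks" / f"{sample_id}_{factor}_caller{caller}.bed"

    def fragments_bed(self, sample_id: str, factor: str) -> Path:
        return self.root / "fragments" / f"{sample_id}_{factor}.bed"

    @property
    def pwm_library(self) -> Path:
        return self.root / "motifs" / "library.jaspar"

    @property
    def gene_sets_gmt(self) -> Path:
        return self.root / "gene_sets.gmt"

    @property
    def expression_tsv(self) -> Path:
        return self.root / "expression_counts.tsv"

    @property
    def truth_json(self) -> Path:
        return self.root / "truth.json"


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

_MOTIF_CONSENSUS = "AGAACAGCATGTTCT"  # palindromic-core steroid-response-like site


def _planted_pwm(motif_id: str = "PLANTED_ARE") -> PWM:
    m = len(_MOTIF_CONSENSUS)
    matrix = np.full((m, 4), 0.05)
    for i, base in enumerate(_MOTIF_CONSENSUS):
        matrix[i, "ACGT".index(base)] = 0.85
    return PWM(motif_id, matrix)


def _random_pwm(rng: np.random.Generator, motif_id: str) -> PWM:
    m = int(rng.integers(10, 15))
    consensus = rng.integers(0, 4, size=m)
    matrix = np.full((m, 4), 0.05)
    matrix[np.arange(m), consensus] = 0.85
    return PWM(motif_id, matrix)


def _place_regions(
    cfg: SimulationConfig, n_regions: int, rng: np.random.Generator
) -> list[GenomicInterval]:
    """Place disjoint regions with >= min_region_gap bp separation.

    Regions are spread over chromosomes proportionally to length; gaps are a
    minimum separation plus a random (multinomial) share of the free space, so
    placement always succeeds when the genome is large enough.
    """
    widths = np.rint(
        rng.lognormal(np.log(cfg.peak_width_median), cfg.peak_width_sigma, n_regions)
    ).astype(int)
    widths = np.clip(widths, 150, 600)
    # deterministic even split across chromosomes (roles are shuffled below)
    base, rem = divmod(n_regions, cfg.n_chroms)
    per_chrom = [base + (1 if ci < rem else 0) for ci in range(cfg.n_chroms)]
    regions: list[GenomicInterval] = []
    idx = 0
    for ci, n_c in enumerate(per_chrom):
        if n_c == 0:
            continue
        chrom = f"chr{ci + 1}"
        w = widths[idx : idx + n_c]
        idx += n_c
        zone = int(cfg.region_zone_fraction * cfg.chrom_length)
        usable = zone - 2 * cfg.edge_margin
        need = int(w.sum()) + (int(n_c) + 1) * cfg.min_region_gap
        free = usable - need
        if free < 0:
            raise ValueError(
                f"genome too small: need {need} bp on {chrom}, have {usable}"
            )
        extra = rng.multinomial(free, np.full(n_c + 1, 1 / (n_c + 1)))
        pos = cfg.edge_margin
        for i in range(n_c):
            pos += cfg.min_region_gap + int(extra[i])
            regions.append(GenomicInterval(chrom, pos, pos + int(w[i])))
            pos += int(w[i])
    perm = rng.permutation(len(regions))
    return [regions[i] for i in perm]


def _sample_fragments(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    genome_sizes: dict[str, int],
    enriched: list[tuple[GenomicInterval, float]],
) -> IntervalSet:
    """Poisson background plus peak-shaped (triangular) enrichment."""
    rl = cfg.read_length
    frags: list[GenomicInterval] = []
    for chrom, length in genome_sizes.items():
        n_bg = rng.poisson(cfg.background_rate * length)
        starts = rng.integers(0, length - rl + 1, size=n_bg)
        frags.extend(GenomicInterval(chrom, int(s), int(s) + rl) for s in starts)
    for iv, intensity in enriched:
        # planted sites carry exactly their planted intensity; placement is
        # the stochastic part (the truth table maps region -> intensity)
        n = int(round(intensity))
        if n == 0:
            continue
        # triangular center distribution -> peaked coverage profile
        u = rng.random((n, 2)).sum(axis=1) - 1.0
        centers = iv.midpoint + u * (iv.length / 2)
        starts = np.clip(
            np.rint(centers - rl / 2).astype(int),
            0,
            genome_sizes[iv.chrom] - rl,
        )
        frags.extend(GenomicInterval(iv.chrom, int(s), int(s) + rl) for s in starts)
    return IntervalSet(frags).sort()


def _nearest_tss_links(
    regions: list[GenomicInterval],
    tss: list[tuple[str, int, str]],  # (chrom, pos, gene_id)
    window: int = 20_000,
) -> set[str]:
    linked = set()
    for iv in regions:
        mid = iv.midpoint
        best_d, best_genes = None, []
        for chrom, pos, gid in tss:
            if chrom != iv.chrom:
                continue
            d = abs(pos - mid)
            if best_d is None or d < best_d:
                best_d, best_genes = d, [gid]
            elif d == best_d:
                best_genes.append(gid)
        if best_d is not None and best_d <= window:
            linked.update(best_genes)
    return linked


def simulate_dataset(cfg: SimulationConfig, outdir: str | Path) -> SyntheticDataset:
    """Generate the full on-disk dataset and its planted truth."""
    root = Path(outdir)
    for sub in ("peaks", "fragments", "motifs"):
        (root / sub).mkdir(parents=True, exist_ok=True)
    samples = cfg.sample_ids

    # --- region scaffold: core + per-sample specific sets -------------------
    # One specific scaffold is shared by AR, FOXA1 and CTCF (pioneer-factor
    # co-binding at the same enhancers); each factor gets its own fragments.
    rng_regions = cfg.rng("regions")
    spec_factors = ("AR", "FOXA1", "CTCF")
    n_total = cfg.n_core_peaks + cfg.n_samples * cfg.n_specific_per_sample
    scaffold = _place_regions(cfg, n_total, rng_regions)
    pos = 0

    def take(n: int) -> list[GenomicInterval]:
        nonlocal pos
        out = scaffold[pos : pos + n]
        pos += n
        return out

    core = take(cfg.n_core_peaks)
    specific: dict[str, list[GenomicInterval]] = {
        s: take(cfg.n_specific_per_sample) for s in samples
    }

    n_active = int(round(cfg.active_fraction * cfg.n_specific_per_sample))
    active: dict[str, list[GenomicInterval]] = {}
    for s in samples:
        picks = rng_regions.choice(
            cfg.n_specific_per_sample, size=n_active, replace=False
        )
        active[s] = [specific[s][i] for i in sorted(picks)]
    active_union = [iv for s in samples for iv in active[s]]
    # Active enhancers span a wide dynamic range; emulate it as two tiers
    # (strong = core-level signal, moderate = specific-level). Tier is a
    # property of the locus, shared by every sample's H3K27ac track.
    strong_mark = {
        (iv.chrom, iv.start): bool(rng_regions.random() < 0.5)
        for iv in active_union
    }

    # --- genome sequence with planted motif instances ----------------------
    rng_genome = cfg.rng("genome")
    sizes = {f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_chroms)}
    sequence = {
        c: np.frombuffer(b"ACGT", dtype=np.uint8)[
            rng_genome.integers(0, 4, size=n)
        ].tobytes().decode("ascii")
        for c, n in sizes.items()
    }

    rng_motifs = cfg.rng("motifs")
    planted_pwm = _planted_pwm()
    motif_len = len(_MOTIF_CONSENSUS)
    placements: list[tuple[str, int]] = []
    seq_arrays = {c: bytearray(s, "ascii") for c, s in sequence.items()}

    def plant(iv: GenomicInterval, prob: float) -> None:
        if rng_motifs.random() >= prob or iv.length <= motif_len:
            return
        off = iv.start + int(rng_motifs.integers(0, iv.length - motif_len))
        seq_arrays[iv.chrom][off : off + motif_len] = _MOTIF_CONSENSUS.encode()
        placements.append((iv.chrom, off))

    for iv in core:
        plant(iv, cfg.motif_plant_prob_core)
    for s in samples:
        for iv in specific[s]:
            plant(iv, cfg.motif_plant_prob_specific)
    sequence = {c: bytes(a).decode("ascii") for c, a in seq_arrays.items()}
    genome = Genome(chrom_sizes=sizes, sequence=sequence)
    write_fasta(sequence, root / "genome.fa")
    with open(root / "genome.chrom.sizes", "w") as fh:
        for c, n in sizes.items():
            fh.write(f"{c}\t{n}\n")

    pwms = [planted_pwm] + [
        _random_pwm(rng_motifs, f"DECOY_{i:02d}")
        for i in range(1, cfg.n_library_pwms)
    ]
    write_jaspar(pwms, root / "motifs" / "library.jaspar")

    # --- gene annotation ----------------------------------------------------
    # Genes are anchored to regulatory regions (TSS 0.5-1.5 kb from a site
    # midpoint, half of them to core sites, half to specific sites) so that
    # nearest-TSS linkage carries signal: the nearest gene of a core region is
    # preferentially a core-anchored gene.
    rng_genes = cfg.rng("genes")
    all_specific = [iv for s in samples for iv in specific[s]]
    n_core_anchored = int(0.4 * cfg.n_genes)
    n_spec_anchored = int(0.2 * cfg.n_genes)
    anchors: list[GenomicInterval | None] = [
        core[int(i)]
        for i in rng_genes.choice(len(core), size=n_core_anchored, replace=False)
    ]
    anchors += [
        all_specific[int(i)]
        for i in rng_genes.choice(
            len(all_specific),
            size=n_spec_anchored,
            replace=n_spec_anchored > len(all_specific),
        )
    ]
    anchors += [None] * (cfg.n_genes - len(anchors))  # desert genes
    desert_lo = int(cfg.region_zone_fraction * cfg.chrom_length) + 25_000
    if desert_lo >= cfg.chrom_length - 12_000:  # tiny genomes: no usable desert
        desert_lo = 0
    gene_rows = []
    tss_list: list[tuple[str, int, str]] = []
    for gi in range(cfg.n_genes):
        gid = f"GENE{gi + 1:04d}"
        anchor = anchors[gi]
        strand = "+" if rng_genes.random() < 0.5 else "-"
        glen = int(rng_genes.integers(2_000, 8_000))
        if anchor is not None:
            chrom = anchor.chrom
            offset = int(rng_genes.integers(500, 1_500))
            if rng_genes.random() < 0.5:
                offset = -offset
            tss = anchor.midpoint + offset
        else:
            chrom = f"chr{int(rng_genes.integers(0, cfg.n_chroms)) + 1}"
            tss = int(rng_genes.integers(desert_lo, cfg.chrom_length - 10_000))
        tss = int(np.clip(tss, 0, cfg.chrom_length - glen - 1))
        if strand == "+":
            start = tss
        else:
            start = max(0, tss + 1 - glen)
            tss = start + glen - 1
        gene_rows.append((chrom, start, start + glen, gid, 0, strand))
        tss_list.append((chrom, tss, gid))
    gene_rows.sort()
    with open(root / "genes.bed", "w") as fh:
        for row in gene_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")

    # --- gene sets: hallmark-like + essential enriched in core-linked ------
    rng_sets = cfg.rng("gene_sets")
    all_genes = [f"GENE{gi + 1:04d}" for gi in range(cfg.n_genes)]
    core_linked = sorted(_nearest_tss_links(core, tss_list))
    other_genes = sorted(set(all_genes) - set(core_linked))

    def enriched_set(size: int, frac_core: float) -> list[str]:
        n_core_g = min(int(round(size * frac_core)), len(core_linked))
        picked = list(
            rng_sets.choice(core_linked, size=n_core_g, replace=False)
        ) + list(
            rng_sets.choice(other_genes, size=size - n_core_g, replace=False)
        )
        return sorted(picked)

    gene_sets: dict[str, list[str]] = {
        "HALLMARK_LIKE_CORE_PROGRAM": enriched_set(40, 0.85),
        "ESSENTIAL_GENES": enriched_set(30, 0.85),
    }
    for i in range(6):
        size = int(rng_sets.integers(20, 41))
        gene_sets[f"RANDOM_SET_{i + 1}"] = sorted(
            rng_sets.choice(all_genes, size=size, replace=False)
        )
    with open(root / "gene_sets.gmt", "w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, "synthetic"] + list(members)) + "\n")

    # Per-factor per-site binding strength, shared by every sample of that
    # factor: correlation structure of reads-in-peaks is then driven by
    # factor rather than by sample. The histone mark is exempt — its signal
    # tiers (strong/moderate/absent) are the planted stratification truth.
    rng_intensity = cfg.rng("intensity")
    tf_multiplier = {
        f: {
            (iv.chrom, iv.start): float(rng_intensity.lognormal(0.0, 0.5))
            for iv in scaffold
        }
        for f in spec_factors
    }
    # FOXA1/CTCF occupy their own ~60% repertoire of the scaffold (pattern
    # shared across samples); AR occupancy is the planted truth and stays full.
    for f in ("FOXA1", "CTCF"):
        mult = tf_multiplier[f]
        for key in mult:
            if rng_intensity.random() >= 0.6:
                mult[key] = 0.0

    # --- per sample/factor peaks (two callers) -----------------------------
    rng_callers = cfg.rng("callers")
    peak_sets: dict[tuple[str, str], list[GenomicInterval]] = {}
    for s in samples:
        for f in spec_factors:
            mult = tf_multiplier[f]
            peak_sets[(s, f)] = [
                iv for iv in core + specific[s] if mult[(iv.chrom, iv.start)] > 0
            ]
        peak_sets[(s, "H3K27ac")] = core + active_union
    for (s, f), ivs in peak_sets.items():
        caller1 = IntervalSet(ivs).sort()
        write_bed(caller1, root / "peaks" / f"{s}_{f}_caller1.bed")
        jittered = []
        for iv in caller1:
            if rng_callers.random() < cfg.caller2_dropout:
                continue
            shift = int(
                rng_callers.integers(-cfg.caller2_jitter, cfg.caller2_jitter + 1)
            )
            start = max(0, iv.start + shift)
            jittered.append(GenomicInterval(iv.chrom, start, iv.end + shift))
        write_bed(IntervalSet(jittered).sort(), root / "peaks" / f"{s}_{f}_caller2.bed")

    # --- fragments ----------------------------------------------------------
    rng_frags = cfg.rng("fragments")
    expected_fragments: dict[str, float] = {}
    core_intensity = cfg.core_signal_multiplier * cfg.specific_peak_fragments
    intensity_table: dict[str, float] = {}
    for iv in core:
        intensity_table[f"{iv.chrom}:{iv.start}-{iv.end}"] = core_intensity
    for s in samples:
        for iv in specific[s]:
            intensity_table.setdefault(
                f"{iv.chrom}:{iv.start}-{iv.end}", cfg.specific_peak_fragments
            )


    for s in samples:
        for f in FACTORS:
            if f == "H3K27me3":
                enriched: list[tuple[GenomicInterval, float]] = []
            elif f == "H3K27ac":
                enriched = [(iv, core_intensity) for iv in core] + [
                    (
                        iv,
                        core_intensity
                        if strong_mark[(iv.chrom, iv.start)]
                        else cfg.specific_peak_fragments,
                    )
                    for iv in active_union
                ]
            else:
                mult = tf_multiplier[f]
                enriched = [
                    (iv, core_intensity * mult[(iv.chrom, iv.start)]) for iv in core
                ] + [
                    (iv, cfg.specific_peak_fragments * mult[(iv.chrom, iv.start)])
                    for iv in specific[s]
                ]
            frag_set = _sample_fragments(cfg, rng_frags, sizes, enriched)
            expected_fragments[f"{s}_{f}"] = cfg.background_rate * sum(
                sizes.values()
            ) + sum(round(x) for _, x in enriched)
            write_bed(frag_set, root / "fragments" / f"{s}_{f}.bed")

    # --- expression ---------------------------------------------------------
    rng_expr = cfg.rng("expression")
    base_means = rng_expr.lognormal(np.log(100.0), 1.5, cfg.n_genes)
    de_ids = [f"GENE{gi + 1:04d}" for gi in range(cfg.n_de_genes)]
    de_genes: dict[str, float] = {}
    means = np.tile(base_means[:, None], (1, cfg.n_samples))
    fc = 2.0**cfg.de_log2fc
    for j, gid in enumerate(de_ids):
        gi = j  # planted genes occupy the first rows
        means[gi, :] = 60.0
        sign = 1.0 if j % 2 == 0 else -1.0
        cols = [samples.index(s) for s in cfg.group_b]
        means[gi, cols] = 60.0 * fc if sign > 0 else 60.0 / fc
        de_genes[gid] = sign * cfg.de_log2fc
    lib_factors = rng_expr.uniform(0.7, 1.4, cfg.n_samples)
    alpha = cfg.nb_dispersion
    mu = means * lib_factors[None, :]
    counts = rng_expr.negative_binomial(1.0 / alpha, 1.0 / (1.0 + alpha * mu))
    pd.DataFrame(counts, index=all_genes, columns=samples).to_csv(
        root / "expression_counts.tsv", sep="\t", index_label="gene_id"
    )

    truth = SyntheticTruth(
        core_regions=[(iv.chrom, iv.start, iv.end) for iv in core],
        specific_regions={
            s: [(iv.chrom, iv.start, iv.end) for iv in specific[s]] for s in samples
        },
        active_specific={
            s: [(iv.chrom, iv.start, iv.end) for iv in active[s]] for s in samples
        },
        motif_id=planted_pwm.motif_id,
        motif_placements=placements,
        de_genes=de_genes,
        shared_fraction=cfg.n_core_peaks
        / (cfg.n_core_peaks + cfg.n_specific_per_sample),
        region_intensity=intensity_table,
        expected_fragments=expected_fragments,
    )
    truth.to_json(root / "truth.json")
    return SyntheticDataset(root=root, config=cfg, genome=genome, truth=truth)


# ---------------------------------------------------------------------------
# recovery report
# ---------------------------------------------------------------------------


def interval_jaccard(a: IntervalSet, b: IntervalSet) -> float:
    """Jaccard on region identity via >=1 bp overlap matching."""
    from .intervals import overlapping_indices

    if len(a) == 0 and len(b) == 0:
        return 1.0
    hits_a = overlapping_indices(a, b)
    hits_b = overlapping_indices(b, a)
    inter = min(len(hits_a), len(hits_b))
    union = len(a) + len(b) - inter
    return inter / union if union else 1.0


def truth_compare(
    truth: SyntheticTruth,
    membership,
    selected_active: dict[str, IntervalSet] | None = None,
    motif_ranking: list[str] | None = None,
    de_passed: list[str] | None = None,
) -> dict:
    """Recovery report: planted vs recovered structure.

    ``membership`` is the consensus MembershipTable for the AR factor. The
    recovered shared fraction is, per sample, shared_all / (shared_all +
    that sample's specific regions) — partial regions (mostly caller-dropout
    artifacts) are excluded, matching the shared-vs-specific contrast the
    downstream analysis runs — averaged over samples.
    """
    unknown = set(membership.samples) - set(truth.specific_regions)
    if unknown:
        raise ValueError(
            f"sample ids absent from truth: {sorted(unknown)} "
            f"(truth has {sorted(truth.specific_regions)})"
        )
    # QC may have excluded samples; recovery is assessed on those that remain
    samples = list(membership.samples)
    from .consensus import SAMPLE_SPECIFIC, SHARED_ALL

    shared = membership.subset(SHARED_ALL)
    n_shared = len(shared)
    fractions = []
    jacc_specific = {}
    for s in samples:
        spec_rec = membership.subset(SAMPLE_SPECIFIC, sample_id=s)
        denom = n_shared + len(spec_rec)
        fractions.append(n_shared / denom if denom else float("nan"))
        jacc_specific[s] = interval_jaccard(spec_rec, truth.specific_set(s))
    recovered_fraction = float(np.mean(fractions))

    report = {
        "shared_fraction_planted": truth.shared_fraction,
        "shared_fraction_recovered": recovered_fraction,
        "shared_fraction_error": recovered_fraction - truth.shared_fraction,
        "jaccard_core": interval_jaccard(shared, truth.core_set()),
        "jaccard_specific": jacc_specific,
    }
    if selected_active is not None:
        report["jaccard_active"] = {
            s: interval_jaccard(sel, truth.active_set(s))
            for s, sel in selected_active.items()
        }
    if motif_ranking is not None:
        report["planted_motif_rank"] = (
            motif_ranking.index(truth.motif_id) + 1
            if truth.motif_id in motif_ranking
            else None
        )
    if de_passed is not None:
        planted = set(truth.de_genes)
        called = set(de_passed)
        tp = len(planted & called)
        report["de_precision"] = tp / len(called) if called else float("nan")
        report["de_recall"] = tp / len(planted) if planted else float("nan")
        report["de_called"] = sorted(called)
    return report
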