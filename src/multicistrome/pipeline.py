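"""End-to-end orchestration of the multi-sample cistrome concordance analysis.

Stages run in dependency order::

    consensus -> qc -> membership -> noise -> quantify -> stratify
              -> annotate -> motifs -> expression -> concordance -> report

Every stage writes plain-text outputs (TSV/BED/JSON) into the run directory
and is skipped on resume when its outputs already exist; QC exclusions drop a
sample/factor from all downstream stages. All thresholds, seeds and inputs
are echoed into ``run_config.yaml`` so a run is fully reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import annotate, concordance, consensus, motifs, nullmodel, signal, stratify
from . import transcriptome
from .intervals import (
    Genome,
    GenomicInterval,
    IntervalSet,
    read_bed,
    read_genes_bed,
    read_genome,
    read_gmt,
    write_bed,
)

STAGES = (
    "consensus",
    "qc",
    "membership",
    "noise",
    "quantify",
    "stratify",
    "annotate",
    "motifs",
    "expression",
    "concordance",
    "report",
)

DEFAULT_THRESHOLDS: dict[str, Any] = {
    "min_peaks": 10_000,
    "tss_window": 20_000,
    "promoter_flank": 1_000,
    "flank": 2_000,
    "flank_wide": 5_000,
    "bin_size": 25,
    "k": 3,
    "n_top": 2,
    "de_fdr": 0.05,
    "de_lfc": 2.0,
    "expression_floor": 4.0,
    "score_fraction": 0.8,
    "top_n_sets": 12,
}


@dataclass
class RunConfig:
    """Validated run configuration (see ``load_config`` for the YAML schema)."""

    samples: dict[str, dict[str, dict[str, str]]]  # sample -> factor -> file paths
    genome_fasta: str | None
    chrom_sizes: str
    genes_bed: str
    gene_sets_gmt: str | None
    pwm_library: str | None
    expression_tsv: str | None
    group_a: list[str]
    group_b: list[str]
    seed: int = 1729
    thresholds: dict[str, Any] = field(default_factory=dict)
    stratify_factor: str = "AR"
    mark_factor: str = "H3K27ac"

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_THRESHOLDS)
        merged.update(self.thresholds)
        self.thresholds = merged

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples)

    def peak_factors(self) -> list[str]:
        factors: list[str] = []
        for fdict in self.samples.values():
            for f, paths in fdict.items():
                if "caller1" in paths and f not in factors:
                    factors.append(f)
        return factors

    def validate(self) -> None:
        for s, fdict in self.samples.items():
            for f, paths in fdict.items():
                for key, p in paths.items():
                    if not Path(p).exists():
                        raise FileNotFoundError(f"{s}/{f}/{key}: {p}")
        for p in (self.chrom_sizes, self.genes_bed):
            if not Path(p).exists():
                raise FileNotFoundError(p)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig(
        samples=raw["samples"],
        genome_fasta=raw.get("genome", {}).get("fasta"),
        chrom_sizes=raw["genome"]["chrom_sizes"],
        genes_bed=raw["annotation"]["genes_bed"],
        gene_sets_gmt=raw.get("gene_sets"),
        pwm_library=raw.get("pwm_library"),
        expression_tsv=raw.get("expression", {}).get("counts"),
        group_a=raw.get("expression", {}).get("group_a", []),
        group_b=raw.get("expression", {}).get("group_b", []),
        seed=raw.get("seed", 1729),
        thresholds=raw.get("thresholds", {}),
        stratify_factor=raw.get("stratify_factor", "AR"),
        mark_factor=raw.get("mark_factor", "H3K27ac"),
    )


def config_for_synthetic(dataset) -> RunConfig:
    """Build a RunConfig pointing at a generated synthetic dataset."""
    from .synthetic import FACTORS, PEAK_FACTORS

    cfg = dataset.config
    samples: dict[str, dict[str, dict[str, str]]] = {}
    for s in cfg.sample_ids:
        samples[s] = {}
        for f in FACTORS:
            paths = {"fragments": str(dataset.fragments_bed(s, f))}
            if f in PEAK_FACTORS:
                paths["caller1"] = str(dataset.caller_bed(s, f, 1))
                paths["caller2"] = str(dataset.caller_bed(s, f, 2))
            samples[s][f] = paths
    return RunConfig(
        samples=samples,
        genome_fasta=str(dataset.fasta),
        chrom_sizes=str(dataset.chrom_sizes),
        genes_bed=str(dataset.genes_bed),
        gene_sets_gmt=str(dataset.gene_sets_gmt),
        pwm_library=str(dataset.pwm_library),
        expression_tsv=str(dataset.expression_tsv),
        group_a=cfg.group_a,
        group_b=cfg.group_b,
        seed=cfg.seed if cfg.seed != 0 else 1729,
        thresholds={"min_peaks": 0},  # toy scale: the 10k floor is full-scale
    )


def write_config(cfg: RunConfig, path: str | Path) -> None:
    raw = {
        "samples": cfg.samples,
        "genome": {"fasta": cfg.genome_fasta, "chrom_sizes": cfg.chrom_sizes},
        "annotation": {"genes_bed": cfg.genes_bed},
        "gene_sets": cfg.gene_sets_gmt,
        "pwm_library": cfg.pwm_library,
        "expression": {
            "counts": cfg.expression_tsv,
            "group_a": cfg.group_a,
            "group_b": cfg.group_b,
        },
        "seed": cfg.seed,
        "thresholds": cfg.thresholds,
        "stratify_factor": cfg.stratify_factor,
        "mark_factor": cfg.mark_factor,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


class PipelineRun:
    """One analysis run rooted at ``outdir``; stages cache to disk."""

    def __init__(self, config: RunConfig, outdir: str | Path, resume: bool = False):
        config.validate()
        self.cfg = config
        self.out = Path(outdir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.resume = resume
        self.log: list[str] = []
        self._genome: Genome | None = None
        self._peaks: dict[tuple[str, str], IntervalSet] = {}
        self._membership: dict[str, consensus.MembershipTable] = {}
        self._noise: dict[str, IntervalSet] = {}
        self._fragments: dict[tuple[str, str], signal.FragmentSet] = {}
        self._active: dict[str, IntervalSet] = {}
        self._excluded: set[tuple[str, str]] = set()
        write_config(config, self.out / "run_config.yaml")

    # -- helpers ------------------------------------------------------------

    def _log(self, msg: str) -> None:
        self.log.append(msg)
        with open(self.out / "pipeline.log", "a") as fh:
            fh.write(msg + "\n")

    def _done(self, *paths: Path) -> bool:
        return self.resume and all(p.exists() for p in paths)

    @property
    def genome(self) -> Genome:
        if self._genome is None:
            self._genome = read_genome(self.cfg.chrom_sizes, self.cfg.genome_fasta)
        return self._genome

    def fragments(self, sample_id: str, factor: str) -> signal.FragmentSet:
        key = (sample_id, factor)
        if key not in self._fragments:
            path = self.cfg.samples[sample_id][factor]["fragments"]
            if path.endswith(".bam"):
                self._fragments[key] = signal.FragmentSet.from_bam(
                    path, sample_id, factor
                )
            else:
                self._fragments[key] = signal.FragmentSet.from_bed(
                    path, sample_id, factor
                )
        return self._fragments[key]

    def consensus_peaks(self, sample_id: str, factor: str) -> IntervalSet:
        key = (sample_id, factor)
        if key not in self._peaks:
            path = self.out / "consensus" / f"{sample_id}_{factor}.bed"
            self._peaks[key] = read_bed(path)
        return self._peaks[key]

    def membership(self, factor: str) -> consensus.MembershipTable:
        if factor not in self._membership:
            path = self.out / "membership" / f"{factor}_membership.tsv"
            df = pd.read_csv(path, sep="\t")
            samples = [
                c
                for c in df.columns
                if c not in ("chrom", "start", "end", "class", "specific_sample")
            ]
            regions = IntervalSet(
                GenomicInterval(r.chrom, int(r.start), int(r.end))
                for r in df.itertuples()
            )
            occ = df[samples].to_numpy(dtype=bool)
            self._membership[factor] = consensus.MembershipTable(
                regions=regions, samples=samples, occupancy=occ
            )
        return self._membership[factor]

    def noise(self, factor: str) -> IntervalSet:
        if factor not in self._noise:
            self._noise[factor] = read_bed(self.out / "noise" / f"{factor}_noise.bed")
        return self._noise[factor]

    def active_regions(self, sample_id: str) -> IntervalSet:
        if sample_id not in self._active:
            self._active[sample_id] = read_bed(
                self.out / "stratify" / f"{sample_id}_active.bed"
            )
        return self._active[sample_id]

    def included_samples(self, factor: str) -> list[str]:
        qc_path = self.out / "qc" / "qc_report.tsv"
        if qc_path.exists() and not self._excluded:
            df = pd.read_csv(qc_path, sep="\t")
            for r in df.itertuples():
                if r.excluded:
                    self._excluded.add((r.sample_id, r.factor))
        return [
            s
            for s in self.cfg.sample_ids
            if factor in self.cfg.samples[s] and (s, factor) not in self._excluded
        ]

    # -- stages ---------------------------------------------------------------

    def stage_consensus(self) -> None:
        d = self.out / "consensus"
        d.mkdir(exist_ok=True)
        for s in self.cfg.sample_ids:
            for f in self.cfg.peak_factors():
                if f not in self.cfg.samples[s]:
                    continue
                path = d / f"{s}_{f}.bed"
                if self._done(path):
                    continue
                paths = self.cfg.samples[s][f]
                peaks = consensus.intersect_caller_peaks(
                    read_bed(paths["caller1"]), read_bed(paths["caller2"])
                )
                self._peaks[(s, f)] = peaks
                write_bed(peaks, path)
                self._log(f"consensus: {s}/{f}: {len(peaks)} dual-caller peaks")

    def stage_qc(self) -> None:
        d = self.out / "qc"
        d.mkdir(exist_ok=True)
        path = d / "qc_report.tsv"
        if self._done(path):
            return
        frames = []
        for f in self.cfg.peak_factors():
            counts = {
                s: len(self.consensus_peaks(s, f))
                for s in self.cfg.sample_ids
                if f in self.cfg.samples[s]
            }
            report = consensus.qc_filter(
                counts, factor=f, min_peaks=self.cfg.thresholds["min_peaks"]
            )
            for r in report.records:
                if r.excluded:
                    self._excluded.add((r.sample_id, f))
                    self._log(f"qc: excluding {r.sample_id}/{f}: {r.exclusion_reason}")
            frames.append(report.to_frame())
        pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)

    def stage_membership(self) -> None:
        d = self.out / "membership"
        d.mkdir(exist_ok=True)
        for f in self.cfg.peak_factors():
            path = d / f"{f}_membership.tsv"
            if self._done(path):
                continue
            included = self.included_samples(f)
            peak_sets = [
                consensus.PeakSet(
                    s, f, consensus.merge_intervals(self.consensus_peaks(s, f))
                )
                for s in included
            ]
            table = consensus.build_membership(peak_sets)
            self._membership[f] = table
            table.to_frame().to_csv(path, sep="\t", index=False)
            named = IntervalSet(
                GenomicInterval(iv.chrom, iv.start, iv.end, name=cls)
                for iv, cls in zip(table.regions, table.classes)
            )
            write_bed(named, d / f"{f}_consensus.bed")
            upset = pd.DataFrame(
                [
                    {"pattern": "&".join(k), "count": v}
                    for k, v in sorted(table.upset_counts().items())
                ]
            )
            upset.to_csv(d / f"{f}_upset_counts.tsv", sep="\t", index=False)
            self._log(f"membership: {f}: {table.class_counts()}")

    def stage_noise(self) -> None:
        d = self.out / "noise"
        d.mkdir(exist_ok=True)
        for f in self.cfg.peak_factors():
            path = d / f"{f}_noise.bed"
            if self._done(path):
                continue
            concatenated = IntervalSet(
                iv
                for s in self.included_samples(f)
                for iv in self.consensus_peaks(s, f)
            )
            noise = nullmodel.matched_shuffle(
                concatenated,
                self.genome,
                seed=self.cfg.seed,
                source_factor=f,
            )
            self._noise[f] = noise.intervals
            write_bed(noise.intervals, path, header=f"matched shuffle seed={self.cfg.seed}")
            self._log(f"noise: {f}: {len(noise.intervals)} regions")

    def stage_quantify(self) -> None:
        """Counts + rank-sum ordering of shared vs specific vs noise signal."""
        d = self.out / "quantify"
        d.mkdir(exist_ok=True)
        tests_path = d / "signal_tests.tsv"
        if self._done(tests_path):
            return
        tf = self.cfg.stratify_factor
        table = self.membership(tf)
        shared = table.subset(consensus.SHARED_ALL)
        noise_regions = consensus.merge_intervals(self.noise(tf))
        rows = []
        for quant_factor in (tf, self.cfg.mark_factor):
            for s in self.included_samples(quant_factor):
                frags = self.fragments(s, quant_factor)
                specific = table.subset(consensus.SAMPLE_SPECIFIC, sample_id=s)
                counts = {
                    "shared": frags.count_in(shared),
                    "specific": frags.count_in(specific),
                    "noise": frags.count_in(noise_regions),
                }
                cm = signal.build_count_matrix([frags], shared)
                signal.cpm_normalize(cm)
                for cls, c in counts.items():
                    np.savetxt(
                        d / f"{s}_{quant_factor}_{cls}_counts.txt", c, fmt="%d"
                    )
                for a, b in (("shared", "specific"), ("specific", "noise")):
                    if len(counts[a]) == 0 or len(counts[b]) == 0:
                        continue
                    res = signal.rank_sum_test(
                        signal.log_counts(counts[a]), signal.log_counts(counts[b])
                    )
                    rows.append(
                        {
                            "data_factor": quant_factor,
                            "sample_id": s,
                            "contrast": f"{a}_vs_{b}",
                            "n_a": res.n_a,
                            "n_b": res.n_b,
                            "statistic": res.statistic,
                            "p_value": res.p_value,
                            "method": res.method,
                        }
                    )
        pd.DataFrame(rows).to_csv(tests_path, sep="\t", index=False)
        # binned signal at shared sites: heatmap matrix (narrow flank) and
        # column-mean profiles at both configured flanks
        th = self.cfg.thresholds
        for s in self.included_samples(tf):
            frags = self.fragments(s, tf)
            mat = signal.signal_matrix(
                frags, shared, self.genome, flank=th["flank"], bin_size=th["bin_size"]
            )
            ordered = mat.to_frame().iloc[mat.display_order()]
            ordered.to_csv(d / f"{s}_{tf}_shared_heatmap.tsv", sep="\t")
            for flank in (th["flank"], th["flank_wide"]):
                wide = signal.signal_matrix(
                    frags, shared, self.genome, flank=flank, bin_size=th["bin_size"]
                )
                profile = pd.Series(
                    wide.profile(),
                    index=[
                        -flank + i * th["bin_size"] for i in range(wide.n_bins)
                    ],
                    name="mean_cpm",
                )
                profile.to_csv(
                    d / f"{s}_{tf}_shared_profile_{flank}.tsv", sep="\t",
                    index_label="offset",
                )

    def stage_stratify(self) -> None:
        """H3K27ac k-means over AR sample-specific sites; top clusters = active."""
        d = self.out / "stratify"
        d.mkdir(exist_ok=True)
        th = self.cfg.thresholds
        tf, mark = self.cfg.stratify_factor, self.cfg.mark_factor
        table = self.membership(tf)
        for s in self.included_samples(tf):
            path = d / f"{s}_active.bed"
            if self._done(path):
                continue
            specific = table.subset(consensus.SAMPLE_SPECIFIC, sample_id=s)
            if len(specific) < th["k"]:
                self._log(f"stratify: {s}: too few specific regions, skipped")
                continue
            mat = signal.signal_matrix(
                self.fragments(s, mark),
                specific,
                self.genome,
                flank=th["flank"],
                bin_size=th["bin_size"],
            )
            strata = stratify.kmeans_stratify(
                mat, k=th["k"], seed=self.cfg.seed, n_top=th["n_top"]
            )
            strata.to_frame().to_csv(d / f"{s}_strata.tsv", sep="\t", index=False)
            self._active[s] = strata.selected_regions()
            write_bed(self._active[s], path)
            self._log(
                f"stratify: {s}: {int(strata.selected.sum())}/{len(specific)} "
                f"active (k={th['k']}, seed={self.cfg.seed})"
            )

    def stage_annotate(self) -> None:
        d = self.out / "annotate"
        d.mkdir(exist_ok=True)
        th = self.cfg.thresholds
        genes = read_genes_bed(self.cfg.genes_bed)
        universe = {g.gene_id for g in genes}
        tf = self.cfg.stratify_factor
        table = self.membership(tf)
        shared = table.subset(consensus.SHARED_ALL)

        ctx_rows = []
        for label, regions in (
            ("shared_all", shared),
            *(
                (f"{s}_specific", table.subset(consensus.SAMPLE_SPECIFIC, sample_id=s))
                for s in self.included_samples(tf)
            ),
        ):
            if len(regions) == 0:
                continue
            dist = annotate.genomic_context(
                regions, genes, promoter_flank=th["promoter_flank"]
            )
            ctx_rows.append({"regions": label, **dist})
        pd.DataFrame(ctx_rows).to_csv(
            d / "genomic_context.tsv", sep="\t", index=False
        )

        gene_sets = read_gmt(self.cfg.gene_sets_gmt) if self.cfg.gene_sets_gmt else {}
        shared_genes, links = annotate.link_regions_to_genes(
            shared, genes, window=th["tss_window"]
        )
        links.to_csv(d / "shared_region_genes.tsv", sep="\t", index=False)
        if gene_sets:
            res = annotate.hypergeometric_enrichment(
                shared_genes, gene_sets, universe, top_n=th["top_n_sets"]
            )
            annotate.enrichment_to_frame(res).to_csv(
                d / "shared_enrichment.tsv", sep="\t", index=False
            )
        for s in self.included_samples(tf):
            try:
                active = self.active_regions(s)
            except FileNotFoundError:
                continue
            if len(active) == 0:
                continue
            qgenes, qlinks = annotate.link_regions_to_genes(
                active, genes, window=th["tss_window"]
            )
            qlinks.to_csv(d / f"{s}_active_genes.tsv", sep="\t", index=False)
            if gene_sets:
                res = annotate.hypergeometric_enrichment(
                    qgenes, gene_sets, universe, top_n=th["top_n_sets"]
                )
                annotate.enrichment_to_frame(res).to_csv(
                    d / f"{s}_active_enrichment.tsv", sep="\t", index=False
                )

    def stage_motifs(self) -> None:
        d = self.out / "motifs"
        d.mkdir(exist_ok=True)
        path = d / "shared_motif_enrichment.tsv"
        if self._done(path) or not self.cfg.pwm_library or not self.cfg.genome_fasta:
            return
        pwms = motifs.read_jaspar(self.cfg.pwm_library)
        tf = self.cfg.stratify_factor
        shared = self.membership(tf).subset(consensus.SHARED_ALL)
        bg = nullmodel.matched_shuffle(
            shared, self.genome, seed=self.cfg.seed + 1, source_factor=tf
        ).intervals
        ranked = motifs.rank_motifs(
            shared,
            bg,
            self.genome,
            pwms,
            score_fraction=self.cfg.thresholds["score_fraction"],
        )
        pd.DataFrame(
            [
                {
                    "rank": i + 1,
                    "motif_id": r.motif_id,
                    "f_fg": r.f_fg,
                    "f_bg": r.f_bg,
                    "z_score": r.z_score,
                    "n_fg": r.n_fg,
                    "n_bg": r.n_bg,
                }
                for i, r in enumerate(ranked)
            ]
        ).to_csv(path, sep="\t", index=False)

    def stage_expression(self) -> None:
        d = self.out / "expression"
        d.mkdir(exist_ok=True)
        if not self.cfg.expression_tsv:
            return
        path = d / "de_results.tsv"
        if self._done(path):
            return
        th = self.cfg.thresholds
        counts = pd.read_csv(self.cfg.expression_tsv, sep="\t", index_col=0)
        m = transcriptome.ExpressionMatrix(counts=counts)
        transcriptome.size_factors(m)
        m.size_factors.to_csv(d / "size_factors.tsv", sep="\t")
        logm = transcriptome.filter_and_log(m, floor=th["expression_floor"])
        logm.to_csv(d / "filtered_log_expression.tsv", sep="\t")
        if self.cfg.group_a and self.cfg.group_b:
            de = transcriptome.differential_expression(
                m,
                self.cfg.group_a,
                self.cfg.group_b,
                fdr_cutoff=th["de_fdr"],
                lfc_cutoff=th["de_lfc"],
            )
            de.table.to_csv(path, sep="\t", index_label="gene_id")
            self._log(f"expression: {len(de.passed_genes())} DE genes pass")

    def stage_concordance(self) -> None:
        d = self.out / "concordance"
        d.mkdir(exist_ok=True)
        tf = self.cfg.stratify_factor
        table = self.membership(tf)
        regions = table.regions
        columns = {}
        for f in self.cfg.peak_factors():
            for s in self.included_samples(f):
                frags = self.fragments(s, f)
                columns[f"{s}_{f}"] = (
                    frags.count_in(regions) * 1e6 / frags.library_size
                )
        cpm = pd.DataFrame(columns)
        corr = concordance.correlation_matrix(np.log1p(cpm))
        corr.to_frame().to_csv(d / "chip_correlation.tsv", sep="\t")
        dend = concordance.hierarchical_cluster(corr)
        with open(d / "chip_dendrogram.newick", "w") as fh:
            fh.write(dend.to_newick() + "\n")
        if self.cfg.expression_tsv:
            logm = pd.read_csv(
                self.out / "expression" / "filtered_log_expression.tsv",
                sep="\t",
                index_col=0,
            )
            ecorr = concordance.correlation_matrix(logm)
            ecorr.to_frame().to_csv(d / "expression_correlation.tsv", sep="\t")
            edend = concordance.hierarchical_cluster(ecorr)
            with open(d / "expression_dendrogram.newick", "w") as fh:
                fh.write(edend.to_newick() + "\n")

    def stage_report(self) -> None:
        d = self.out / "report"
        d.mkdir(exist_ok=True)
        summary: dict[str, Any] = {"stages": [], "seed": self.cfg.seed}
        for stage_dir in self.out.iterdir():
            if stage_dir.is_dir() and stage_dir.name != "report":
                summary["stages"].append(
                    {
                        "stage": stage_dir.name,
                        "outputs": sorted(p.name for p in stage_dir.iterdir()),
                    }
                )
        summary["stages"].sort(key=lambda x: x["stage"])
        with open(d / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1)
        self._plots(d)
        index = ["<html><body><h1>multicistrome run</h1><ul>"]
        for st in summary["stages"]:
            index.append(f"<li><b>{st['stage']}</b>: {', '.join(st['outputs'])}</li>")
        index.append("</ul></body></html>")
        with open(d / "index.html", "w") as fh:
            fh.write("\n".join(index))

    def _plots(self, d: Path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        corr_path = self.out / "concordance" / "chip_correlation.tsv"
        if corr_path.exists():
            corr = pd.read_csv(corr_path, sep="\t", index_col=0)
            fig, ax = plt.subplots(figsize=(6, 5))
            im = ax.imshow(corr.values, vmin=0, vmax=1, cmap="Greens")
            ax.set_xticks(range(len(corr)), corr.columns, rotation=90, fontsize=6)
            ax.set_yticks(range(len(corr)), corr.index, fontsize=6)
            fig.colorbar(im, label="Pearson r")
            fig.tight_layout()
            fig.savefig(d / "chip_correlation.png", dpi=120)
            plt.close(fig)

    def run(self, stages: list[str] | None = None) -> Path:
        todo = list(stages) if stages else list(STAGES)
        unknown = set(todo) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for name in STAGES:
            if name not in todo:
                continue
            try:
                getattr(self, f"stage_{name}")()
            except Exception as exc:
                raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
            self._log(f"stage {name}: done")
        return self.out


def run_pipeline(
    config: RunConfig,
    outdir: str | Path,
    resume: bool = False,
    stages: list[str] | None = None,
) -> Path:
    return PipelineRun(config, outdir, resume=resume).run(stages)
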