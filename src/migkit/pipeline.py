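"""End-to-end synthetic pipeline orchestration.

``run_pipeline`` drives simulate -> scan -> depth -> qc -> diversity ->
het-accuracy -> linkage/qtl on generated data, writes every table as TSV and
a manifest (config, seed, package version, sha256 per output) so a rerun
with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__, io as mio
from . import depth_profile as dpm
from . import diversity as divm
from . import genotype_qc as qcm
from . import het_accuracy as hetm
from . import linkage as lkm
from . import simulate as sim
from . import ssr_scan as ssrm


@dataclass
class PipelineConfig:
    seed: int = 1
    out_dir: str = "migkit_out"
    # stage toggles
    stages: Dict[str, bool] = field(default_factory=lambda: {
        "scan": True, "depth": True, "qc": True, "diversity": True,
        "het_accuracy": True, "linkage": True, "qtl": True,
    })
    # simulation
    genome_length_bp: int = 400_000
    n_chromosomes: int = 2
    ssr_density: float = 120.0
    panel_size: int = 6
    panel_pi: float = 0.0025
    cross_design: str = "RIL"
    ril_generation: int = 6
    n_progeny: int = 120
    cM_per_Mb: float = 3.0
    mean_read_pairs: int = 60_000
    overdispersion: float = 1.0
    # analysis parameters (printed defaults)
    min_dp_mask_f2: int = 10
    min_dp_mask_ril: int = 5
    genotype_rate_f2: float = 0.97
    genotype_rate_ril: float = 0.95
    diversity_min_dp: int = 5
    mapped_base_min_dp: int = 10
    n_permutations: int = 1000
    alpha: float = 0.05
    qtl_effect: float = 2.0
    qtl_noise_sd: float = 3.0
    ref_markers: int = 3257
    ref_pi: float = 0.002548
    target_markers: int = 1000

    @classmethod
    def from_dict(cls, data: Dict) -> "PipelineConfig":
        cfg = cls()
        for key, value in data.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key: {key}")
            if key == "stages":
                cfg.stages.update(value)
            else:
                setattr(cfg, key, value)
        return cfg


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_report(tables: Dict[str, pd.DataFrame], out_dir: str) -> List[str]:
    """Write each table as <name>.tsv; an empty table yields a header-only
    file.  Tables must be DataFrames; anything else raises with the offending
    name."""
    paths = []
    for name, table in tables.items():
        if not isinstance(table, pd.DataFrame):
            raise TypeError(f"table {name!r} is not a DataFrame")
        path = os.path.join(out_dir, f"{name}.tsv")
        table.to_csv(path, sep="\t", index=False)
        paths.append(path)
    return paths


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Execute the configured stages; returns a manifest dict (also written
    to manifest.json in the output directory)."""
    os.makedirs(config.out_dir, exist_ok=True)
    tables: Dict[str, pd.DataFrame] = {}
    summary: Dict[str, object] = {}

    def stage_on(name: str) -> bool:
        return config.stages.get(name, True)

    try:
        genome = sim.simulate_genome(
            length_bp=config.genome_length_bp,
            n_chromosomes=config.n_chromosomes,
            ssr_density=config.ssr_density,
            seed=config.seed,
        )
        mio.write_fasta(genome.sequences, os.path.join(config.out_dir, "genome.fasta"))
        mio.write_bed(genome.ssr_loci, os.path.join(config.out_dir, "ssr_truth.bed"))
    except Exception as exc:  # pragma: no cover - wrapped for stage context
        raise RuntimeError(f"stage 'simulate-genome' failed: {exc}") from exc

    if stage_on("scan"):
        loci = ssrm.scan_ssrs(genome.sequences)
        counts, total = ssrm.count_targeted_ssrs(loci)
        mio.write_bed(loci, os.path.join(config.out_dir, "ssr_loci.bed"))
        tables["ssr_summary"] = pd.DataFrame([{
            "genome_size": genome.length_bp, "targeted_ssr_total": total,
            **{f"n_{k}": v for k, v in sorted(counts.items())},
        }])
        summary["targeted_ssr_total"] = total

    panel = sim.simulate_panel(genome, config.panel_size, config.panel_pi,
                               seed=config.seed + 1)
    model = sim.CoverageModel(overdispersion=config.overdispersion)
    depth_tables, panel_matrix = sim.simulate_migseq_depths(
        genome, panel, model, config.mean_read_pairs, seed=config.seed + 2
    )
    mio.write_vcf(panel_matrix, os.path.join(config.out_dir, "panel.vcf"),
                  contig_lengths=genome.chrom_lengths)
    for name, pbd in depth_tables.items():
        dpm.write_depth_table(pbd, os.path.join(config.out_dir, f"depth_{name}.tsv"))

    if stage_on("depth"):
        rows = []
        for name, pbd in depth_tables.items():
            s = dpm.summarize_sample(pbd, thresholds=(config.diversity_min_dp,
                                                      config.mapped_base_min_dp))
            for t, c in s.mapped_base_count.items():
                rows.append({"sample": name, "min_dp": t, "mapped_base_count": c})
        tables["depth_summary"] = pd.DataFrame(rows)
        tables["variant_dp_summary"] = dpm.variant_dp_summary(panel_matrix.dp)

    if stage_on("qc"):
        filtered, markers = qcm.qc_preset(panel_matrix, "panel")
        tables["qc_panel_markers"] = pd.DataFrame(
            [{"chrom": c, "pos": p} for c, p in markers.keys]
        )
        summary["panel_markers_kept"] = len(markers)

    if stage_on("diversity"):
        pairs = divm.pairwise_diversity(panel_matrix, depth_tables,
                                        min_dp=config.diversity_min_dp)
        threshold = divm.predict_min_diversity(
            config.target_markers, config.ref_markers, config.ref_pi
        )
        labels = {s: ("g1" if i < config.panel_size // 2 else "g2")
                  for i, s in enumerate(panel_matrix.samples)}
        groups = divm.summarize_by_group(pairs, labels, threshold)
        tables["diversity_pairs"] = pd.DataFrame([{
            "sample_a": p.sample_a, "sample_b": p.sample_b,
            "snp_count": p.snp_count, "common_bases": p.common_bases,
            "pi": p.pi, "relation": p.relation,
        } for p in pairs])
        summary["predicted_min_diversity"] = {
            "target_markers": config.target_markers,
            "ref_markers": config.ref_markers,
            "ref_pi": config.ref_pi,
            "value": threshold,
        }
        summary["diversity_by_group"] = groups

    # cross, phenotype, linkage & QTL
    parents = list(panel.variants)
    cross = sim.simulate_cross(
        panel.variants[parents[0]], panel.variants[parents[1]],
        design=config.cross_design, n_progeny=config.n_progeny,
        cM_per_Mb=config.cM_per_Mb, seed=config.seed + 3,
        chrom_lengths=genome.chrom_lengths, generation=config.ril_generation,
    )
    qtl_marker = (str(cross.marker_chrom[cross.n_markers // 2]),
                  int(cross.marker_pos[cross.n_markers // 2]))
    phenotype = sim.simulate_phenotype(
        cross, [(qtl_marker, config.qtl_effect)],
        noise_sd=config.qtl_noise_sd, seed=config.seed + 4,
    )
    tables["phenotypes"] = pd.DataFrame(
        {"individual": cross.progeny, "phenotype": phenotype}
    )

    if stage_on("het_accuracy"):
        rng = np.random.default_rng(config.seed + 5)
        n_markers = min(cross.n_markers, 2000)
        reps = []
        for rep in range(8):
            base = rng.poisson(8.0, size=n_markers)
            reps.append(hetm.make_virtual_f1(base, rng.poisson(8.0, size=n_markers),
                                             replicate=rep))
        tables["het_accuracy_curves"] = hetm.error_missing_curves(reps)

    if stage_on("linkage"):
        pop = "F2" if cross.design == "F2" else "RIL"
        geno = cross.genotypes
        ordered = lkm.map_from_genotypes(geno, cross.marker_chrom,
                                         cross.marker_pos, population=pop)
        total, n, spacing = lkm.map_summary(ordered)
        tables["map_summary"] = pd.DataFrame([{
            "total_cM": total, "n_markers": n, "avg_spacing_cM": spacing,
        }])
        ratio = [1, 2, 1] if pop == "F2" else [1, 1]
        tables["segregation_distortion"] = lkm.segregation_distortion(geno, ratio)

    if stage_on("qtl"):
        names = [f"{c}_{p}" for c, p in zip(cross.marker_chrom, cross.marker_pos)]
        profile = lkm.qtl_scan(
            cross.genotypes, phenotype, marker_names=names,
            n_perm=config.n_permutations, alpha=config.alpha,
            seed=config.seed + 6,
        )
        t = profile.table.copy()
        t["threshold"] = profile.threshold
        tables["qtl_profile"] = t
        summary["qtl"] = {
            "peak_marker": str(profile.table.loc[profile.peak_index, "marker"]),
            "peak_lod": float(profile.table.loc[profile.peak_index, "lod"]),
            "threshold": profile.threshold,
            **profile.provenance,
        }

    write_report(tables, config.out_dir)
    checksums = {
        name: _sha256(os.path.join(config.out_dir, name))
        for name in sorted(os.listdir(config.out_dir))
        if name != "manifest.json"
    }
    manifest = {
        "version": __version__,
        "config": asdict(config),
        "summary": summary,
        "checksums": checksums,
    }
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
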