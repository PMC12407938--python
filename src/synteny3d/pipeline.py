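"""End-to-end orchestration: demo (synthetic) and user-data runs.

Stages run in dependency order (pairs -> insulation -> expression;
loops -> enrich; dispersion independent). Every output table is TSV; a
manifest records the full parameter set and the SHA-256 of each written
table, so a rerun with the same config and seed is byte-identical.

Per-pair analyses that scale quadratically (co-expression, intervening
genes, repeats) run on all interacting pairs plus a seeded subsample of the
NOT_CONSERVED majority (``pair_subsample`` rows), keeping the demo fast
without touching any classification logic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    expression_metrics as em,
    gene_pairs as gp,
    insulation as ins,
    loops as lp,
    region_enrichment as re_,
    synteny_dispersion as sd,
    synthetic_data as syn,
)
from .io_formats import (
    read_bedgraph, read_expression, read_genes, read_genome_spec, read_loops,
    read_orthologs, read_repeats, read_sparse_contacts, read_alignment_blocks,
    write_bedgraph,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("pairs", "insulation", "expression", "loops", "enrich", "dispersion")


@dataclass
class RunConfig:
    """Serializable run description; defaults are the analysis thresholds."""

    species: list[str] = field(default_factory=lambda: ["squid", "cuttlefish", "octopus"])
    outgroup: str = "scallop"
    reference: str = "squid"
    paths: dict = field(default_factory=dict)  # per data type, see load_inputs
    threshold: float = gp.DEFAULT_THRESHOLD
    insulation_window: int = ins.DEFAULT_WINDOW
    insulation_threshold: float = ins.DEFAULT_CLASS_THRESHOLD
    resolution: int = 100_000
    fine_resolution: int = 50_000
    max_loop_size: int | None = None
    atac_threshold: float = re_.ACCESSIBILITY_THRESHOLD
    min_alignment_len: int = sd.MIN_ALIGNMENT_LEN
    pair_universe: str = "all"
    max_separation: int | None = None
    pair_subsample: int = 2000
    seed: int = 0
    outdir: str = "results"

    @property
    def decapods(self) -> tuple[str, str]:
        return tuple(self.species[:2])

    @property
    def octopus(self) -> str:
        return self.species[2]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class PipelineData:
    """In-memory inputs for one run, however they were obtained."""

    genomes: dict
    genes: dict
    orthologs: object
    contacts: dict
    loop_calls: dict  # species -> {resolution: raw calls}
    expression: pd.DataFrame | None = None
    alignment_blocks: list = field(default_factory=list)
    repeats: list = field(default_factory=list)
    accessibility: list = field(default_factory=list)


def load_inputs(config: RunConfig) -> PipelineData:
    """Read every input named in config.paths.

    Expected keys: per species ``genome_<sp>``, ``genes_<sp>``,
    ``contacts_<sp>``, ``loops_<sp>_<res>``; shared ``orthologs``; optional
    ``expression``, ``alignments``, ``repeats``, ``accessibility``,
    ``genome_<outgroup>``, ``genes_<outgroup>``.
    """
    p = config.paths
    required = ["orthologs"]
    for sp in config.species:
        required += [f"genome_{sp}", f"genes_{sp}", f"contacts_{sp}"]
    required += [f"genome_{config.outgroup}", f"genes_{config.outgroup}"]
    missing = [k for k in required if k not in p]
    if missing:
        raise FileNotFoundError(f"config missing input paths: {missing}")
    for key, path in p.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"input {key!r}: no such file {path}")
    genomes, genes, contacts, loop_calls = {}, {}, {}, {}
    for sp in config.species + [config.outgroup]:
        genomes[sp] = read_genome_spec(p[f"genome_{sp}"], sp)
        genes[sp] = read_genes(p[f"genes_{sp}"])
    for sp in config.species:
        contacts[sp] = read_sparse_contacts(
            p[f"contacts_{sp}"], config.resolution, genomes[sp], sp
        )
        calls = {}
        for res in (config.fine_resolution, config.resolution):
            key = f"loops_{sp}_{res // 1000}kb"
            if key in p:
                calls[res] = read_loops(p[key], res)
        loop_calls[sp] = calls
    data = PipelineData(
        genomes=genomes, genes=genes,
        orthologs=read_orthologs(p["orthologs"], config.reference),
        contacts=contacts, loop_calls=loop_calls,
    )
    if "expression" in p:
        data.expression = read_expression(p["expression"])
    if "alignments" in p:
        data.alignment_blocks = read_alignment_blocks(p["alignments"])
    if "repeats" in p:
        data.repeats = read_repeats(p["repeats"])
    if "accessibility" in p:
        data.accessibility = read_bedgraph(p["accessibility"])
    return data


def _write(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")
    manifest["outputs"][path.name] = hashlib.sha256(path.read_bytes()).hexdigest()


def _subsample_pairs(records, config: RunConfig):
    """All interacting pairs plus a seeded subsample of NOT_CONSERVED."""
    interacting = [
        r for r in records
        if r.category not in (gp.InteractionCategory.NOT_CONSERVED,
                              gp.InteractionCategory.UNCLASSIFIED)
    ]
    rest = [r for r in records if r.category == gp.InteractionCategory.NOT_CONSERVED]
    if len(rest) > config.pair_subsample:
        rng = np.random.default_rng(config.seed + 17)
        keep = rng.choice(len(rest), size=config.pair_subsample, replace=False)
        rest = [rest[k] for k in sorted(keep)]
    return interacting + rest


def run_all(
    data: PipelineData, config: RunConfig, stages: tuple[str, ...] | None = None
) -> dict:
    """Execute the requested stages, writing TSVs under config.outdir.

    Returns the manifest (parameters, per-stage counts, output hashes).
    Raises on the first failing stage; previously written outputs remain.
    """
    stages = tuple(stages or ALL_STAGES)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    if "expression" in stages and data.expression is None:
        raise FileNotFoundError("expression stage requested but no expression matrix provided")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": {
            k: v for k, v in dataclasses.asdict(config).items()
            if k not in ("paths", "outdir")  # no filesystem paths: manifests
        },                                   # must be reproducible byte-wise
        "stages": {}, "outputs": {},
    }

    records = None
    if "pairs" in stages or "expression" in stages:
        logger.info("stage pairs: building cross-species gene-pair table")
        records = gp.build_pair_table(
            data.contacts, data.genes, data.orthologs,
            ref_species=config.reference, decapods=config.decapods,
            octopus=config.octopus, outgroup=config.outgroup,
            threshold=config.threshold, universe=config.pair_universe,
            max_separation=config.max_separation,
        )
        counts = pd.Series([r.category.value for r in records]).value_counts()
        manifest["stages"]["pairs"] = {"n_pairs": len(records), **counts.to_dict()}
        logger.info("pairs per category: %s", counts.to_dict())

    tracks = None
    if "insulation" in stages:
        logger.info("stage insulation: scoring at %d bp window", config.insulation_window)
        tracks = {
            sp: ins.insulation_score(data.contacts[sp], data.genomes[sp],
                                     config.insulation_window)
            for sp in config.species
        }
        for sp, track in tracks.items():
            bg = track.to_bedgraph(data.genomes[sp])
            path = outdir / f"insulation_{sp}.bedgraph"
            write_bedgraph(bg, path)
            manifest["outputs"][path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
        if records is not None:
            gene_maps = {sp: {g.gene_id: g for g in data.genes[sp]} for sp in config.species}
            ins.annotate_pairs_with_insulation(
                records, tracks, gene_maps, data.orthologs, config.reference,
                config.decapods, config.octopus, config.insulation_threshold,
            )
            cls_counts = pd.Series([r.insulation_class for r in records]).value_counts()
            manifest["stages"]["insulation"] = cls_counts.to_dict()

    if records is not None:
        _write(gp.pair_table_to_frame(records), outdir / "pairs.tsv", manifest)

    if "expression" in stages:
        logger.info("stage expression: co-expression and tissue specificity")
        subset = _subsample_pairs(records, config)
        per_pair, tests = em.coexpression(subset, data.expression)
        _write(per_pair, outdir / "pair_coexpression.tsv", manifest)
        _write(tests, outdir / "coexpression_tests.tsv", manifest)
        gene_sets = gp.exclusive_gene_sets(records)
        tau_table = em.tau_by_category(gene_sets, data.expression)
        _write(tau_table, outdir / "tau.tsv", manifest)
        manifest["stages"]["expression"] = {
            "n_pairs_tested": int(per_pair["r"].notna().sum()),
            "n_genes_tau": len(tau_table),
        }

    merged = None
    if "loops" in stages or "enrich" in stages:
        logger.info("stage loops: merging, gene association, conservation")
        merged = {}
        for sp in config.species:
            calls = data.loop_calls.get(sp, {})
            fine = calls.get(config.fine_resolution, [])
            coarse = calls.get(config.resolution, [])
            loops_sp = lp.merge_resolutions(fine, coarse, sample_id=sp)
            merged[sp] = lp.associate_genes(loops_sp, data.genes[sp], config.max_loop_size)
        edges, groups = lp.conserved_loops(merged, data.orthologs, config.reference)
        genome_sizes = {sp: data.genomes[sp].genome_size for sp in config.species}
        slopes, p_slope = lp.scaling_slopes(groups, genome_sizes)
        all_loops = pd.concat([lp.loops_to_frame(v) for v in merged.values()],
                              ignore_index=True)
        _write(all_loops, outdir / "loops_merged.tsv", manifest)
        _write(
            pd.DataFrame({"slope_bp_per_bp": slopes}), outdir / "loop_slopes.tsv", manifest
        )
        conserved_rows = [
            {"species_a": a, "species_b": b, "n_conserved_pairs": len(v)}
            for (a, b), v in edges.items()
        ]
        _write(pd.DataFrame(conserved_rows), outdir / "loops_conserved.tsv", manifest)
        manifest["stages"]["loops"] = {
            "n_loops": {sp: len(v) for sp, v in merged.items()},
            "n_conservation_groups": len(groups),
            "slope_signed_rank_p": None if np.isnan(p_slope) else p_slope,
        }

    if "enrich" in stages:
        logger.info("stage enrich: partitions, CNE density, accessibility")
        ref = config.reference
        partition = re_.build_partition(merged[ref], data.genomes[ref])
        cnes = [b for b in data.alignment_blocks if not b.is_coding]
        per_region, tests = re_.cne_density(partition, cnes)
        _write(per_region, outdir / "cne_density.tsv", manifest)
        _write(tests, outdir / "cne_density_tests.tsv", manifest)
        stage_info = {"regions": {w: partition.class_length(w) for w in re_.REGION_CLASSES}}
        if data.accessibility:
            cov, cov_tests = re_.accessibility_enrichment(
                partition, data.accessibility, config.atac_threshold
            )
            _write(cov, outdir / "atac_coverage.tsv", manifest)
            _write(cov_tests, outdir / "atac_coverage_tests.tsv", manifest)
        if records is not None:
            subset = _subsample_pairs(records, config)
            gene_map = {g.gene_id: g for g in data.genes[ref]}
            gaps = []
            for r in subset:
                a, b = gene_map[r.gene_a], gene_map[r.gene_b]
                up, down = (a, b) if a.start <= b.start else (b, a)
                gaps.append(
                    (r.category.value, r.chrom, up.end, down.start,
                     {r.gene_a, r.gene_b})
                )
            coverage = re_.intervening_gene_coverage(gaps, data.genes[ref])
            _write(coverage, outdir / "gene_coverage.tsv", manifest)
            if data.repeats:
                _per_pair, composition = re_.repeat_density(subset, data.repeats, gene_map)
                _write(composition, outdir / "repeat_composition.tsv", manifest)
        manifest["stages"]["enrich"] = stage_info

    if "dispersion" in stages:
        logger.info("stage dispersion: homology map and alignment dispersion")
        ref = config.reference
        rows = []
        window_rows = []
        for other in [s for s in config.species if s != ref] + [config.outgroup]:
            hom = sd.chromosome_homology(
                data.orthologs, data.genes[ref], data.genes[other], ref, other
            )
            for a, b in sorted(hom.pairs):
                rows.append({"species_a": ref, "species_b": other,
                             "chrom_a": a, "chrom_b": b})
            for window in (1_000_000, 10_000_000, 50_000_000):
                wc = sd.window_homology_counts(
                    data.genes[ref], data.genes[other], data.orthologs, ref, other,
                    data.genomes[ref], data.genomes[other], window,
                )
                wc.insert(0, "species_b", other)
                window_rows.append(wc)
        _write(pd.DataFrame(rows), outdir / "homology_map.tsv", manifest)
        _write(pd.concat(window_rows, ignore_index=True),
               outdir / "window_homology.tsv", manifest)
        disp_rows = []
        if data.alignment_blocks:
            partners = {b.other_species for b in data.alignment_blocks}
            for other in sorted(partners):
                blocks = [b for b in data.alignment_blocks if b.other_species == other]
                hom = sd.chromosome_homology(
                    data.orthologs, data.genes[ref], data.genes[other], ref, other
                )
                res = sd.dispersion_counts(blocks, hom, config.min_alignment_len)
                for subset_name, tallies in res.items():
                    disp_rows.append({"species_b": other, "subset": subset_name, **tallies})
        _write(pd.DataFrame(disp_rows), outdir / "dispersion.tsv", manifest)
        manifest["stages"]["dispersion"] = {"n_homologous_pairs": len(rows)}

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def run_demo(
    seed: int,
    outdir: str | Path,
    sim_config: syn.SimulationConfig | None = None,
    stages: tuple[str, ...] | None = None,
) -> dict:
    """Generate the synthetic multi-species dataset and run the pipeline on
    it in one call. Data files land in <outdir>/data, results in
    <outdir>/results."""
    outdir = Path(outdir)
    ds = syn.simulate_all(sim_config, seed=seed)
    syn.write_dataset(ds, outdir / "data")
    data = PipelineData(
        genomes=ds.genomes, genes=ds.genes, orthologs=ds.orthologs,
        contacts=ds.contacts, loop_calls=ds.loop_calls, expression=ds.expression,
        alignment_blocks=ds.alignment_blocks, repeats=ds.repeats,
        accessibility=ds.accessibility,
    )
    config = RunConfig(
        species=list(ds.config.ingroup_species), outgroup=ds.config.outgroup_species,
        reference=ds.ref_species, resolution=ds.config.resolution,
        fine_resolution=ds.config.resolution // 2,
        seed=seed, outdir=str(outdir / "results"),
    )
    manifest = run_all(data, config, stages)
    # input hashes make the manifest a complete provenance record
    manifest["inputs"] = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted((outdir / "data").glob("*")) if p.is_file()
    }
    (Path(config.outdir) / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
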