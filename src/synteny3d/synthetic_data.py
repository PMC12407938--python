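"""Multi-species toy data generator with the statistical structure the
pipeline assumes.

The outgroup genome carries the ancestral gene order; each ingroup genome
is derived from it by a per-lineage rearrangement plan (chromosome fissions,
and fusions optionally followed by within-chromosome shuffling of gene
order, i.e. fusion-with-mixing). Contact maps follow a power-law distance
decay P(s) ~ s^-alpha with planted compartment blocks (within-block boost)
and planted focal loops; realised values are Gamma-distributed around their
expectation, mimicking balanced Micro-C weights. Expression is log-normal
with a planted log-scale correlation for interacting gene pairs. CNEs and
repeats are scattered with a configurable fraction of CNEs dispersed to
non-homologous chromosomes.

Every quantity is drawn from one seeded generator: a fixed seed gives
byte-identical output files. Planted truth is always emitted alongside the
data so downstream recovery tests can consume it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    AlignmentBlock,
    GenomeSpec,
    GeneRecord,
    OrthologTable,
    RepeatFeature,
    SignalInterval,
    SparseContacts,
    write_alignment_blocks,
    write_bedgraph,
    write_expression,
    write_genes_bed,
    write_genome_spec,
    write_loops_bedpe,
    write_orthologs,
    write_repeats,
    write_sparse_contacts,
)

# rearrangement events: ("fission", chrom, gene_split_index)
#                       ("fusion", chrom_a, chrom_b, mix: bool)
Plan = list[tuple]


def _default_plans() -> dict[str, Plan]:
    # one shared decapod-style fusion; the octopus lineage is more derived
    return {
        "squid": [("fusion", "c1", "c2", True)],
        "cuttlefish": [("fusion", "c1", "c2", True)],
        "octopus": [("fusion", "c1", "c2", True), ("fusion", "c3", "c4", True)],
    }


@dataclass
class SimulationConfig:
    """Stated world of the toy simulation.

    Scales are chosen so the full pipeline runs in well under two minutes:
    four ancestral chromosomes of 300 genes each (1200 genes), 100 kb bins,
    chromosomes <= 30 Mb. Genome sizes keep the qualitative ordering of the
    real system (large decapod genomes, intermediate octopus, compact
    outgroup). The planted loop strength of 60 KR units (6x the interaction
    threshold) reflects that focal loops in balanced maps stand several-fold
    above their local background; under Gamma(shape 4) noise it leaves
    ~98.5% of planted pairs above threshold in all three species at once.
    The 19-tissue expression panel mirrors a typical adult tissue survey.
    """

    seed: int = 0
    ingroup_species: tuple[str, str, str] = ("squid", "cuttlefish", "octopus")
    outgroup_species: str = "scallop"
    n_outgroup_chroms: int = 4
    genes_per_chrom: int = 300
    gene_length: int = 10_000
    resolution: int = 100_000
    genome_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "squid": 120_000_000,
            "cuttlefish": 110_000_000,
            "octopus": 60_000_000,
            "scallop": 60_000_000,
        }
    )
    rearrangement_plans: dict[str, Plan] = field(default_factory=_default_plans)
    # contacts
    decay_exponent: float = 1.0
    contact_scale: float = 30.0
    gamma_shape: float = 4.0
    compartment_boost: float = 3.0
    compartment_block_bins: int = 25
    compartment_gap_bins: int = 6
    # loops
    n_conserved_loops: int = 12
    n_private_loops: int = 4  # per ingroup species, species-specific
    loop_strength: float = 60.0
    loop_gene_separation: tuple[int, int] = (30, 90)  # ancestral gene-index gap
    # expression
    n_tissues: int = 19
    coexpression_rho: float = 0.6
    expression_log_mean: float = 2.0
    expression_log_sd: float = 1.0
    n_silent_genes: int = 5
    # CNEs / repeats / accessibility
    cne_count: int = 1000
    cne_dispersal: float = 0.3
    cne_length_range: tuple[int, int] = (120, 400)
    n_coding_blocks: int = 300
    coding_dispersal: float = 0.15
    cne_partner_species: str = "cuttlefish"
    repeat_count: int = 2000
    repeat_class_mix: dict[str, float] = field(
        default_factory=lambda: {
            "LINE": 0.3, "SINE": 0.2, "LTR": 0.2, "DNA": 0.2, "Simple_repeat": 0.1,
        }
    )
    atac_tile: int = 5_000
    atac_anchor_boost: float = 2.5

    def validate(self) -> None:
        if not 0.0 <= self.coexpression_rho <= 1.0:
            raise ValueError("coexpression_rho must lie in [0, 1]")
        if not 0.0 <= self.cne_dispersal <= 1.0:
            raise ValueError("cne_dispersal must lie in [0, 1]")
        if self.compartment_boost <= 1.0:
            raise ValueError("compartment_boost must exceed 1")
        if self.n_tissues < 3:
            raise ValueError("n_tissues must be >= 3")
        known = set(self.ingroup_species) | {self.outgroup_species}
        for sp, plan in self.rearrangement_plans.items():
            if sp not in known:
                raise ValueError(f"plan references unknown species {sp!r}")


@dataclass
class SimDataset:
    """Everything one simulation run produces, truth ledgers included."""

    config: SimulationConfig
    genomes: dict[str, GenomeSpec]
    genes: dict[str, list[GeneRecord]]
    orthologs: OrthologTable
    contacts: dict[str, SparseContacts]
    loop_calls: dict[str, dict[int, list[dict]]]
    expression: pd.DataFrame
    alignment_blocks: list[AlignmentBlock]
    repeats: list[RepeatFeature]
    accessibility: list[SignalInterval]
    truth: dict[str, pd.DataFrame]

    @property
    def ref_species(self) -> str:
        return self.config.ingroup_species[0]


# ---------------------------------------------------------------------------
# genomes and orthologs
# ---------------------------------------------------------------------------


def _apply_plan(
    chrom_genes: dict[str, list[int]], plan: Plan, rng: np.random.Generator
) -> dict[str, list[int]]:
    """Apply fission/fusion(-with-mixing) events to chromosome gene lists
    (gene identity = ancestral index)."""
    out = {c: list(v) for c, v in chrom_genes.items()}
    for event in plan:
        kind = event[0]
        if kind == "fission":
            _, chrom, split = event
            if chrom not in out:
                raise ValueError(f"fission references unknown chromosome {chrom!r}")
            genes = out.pop(chrom)
            if not 0 < split < len(genes):
                raise ValueError(f"fission split {split} out of range for {chrom!r}")
            out[f"{chrom}a"] = genes[:split]
            out[f"{chrom}b"] = genes[split:]
        elif kind == "fusion":
            _, ca, cb, mix = event
            if ca not in out or cb not in out:
                raise ValueError(f"fusion references unknown chromosome {ca!r}/{cb!r}")
            merged = out.pop(ca) + out.pop(cb)
            if mix:
                merged = list(rng.permutation(merged))
            out[f"{ca}{cb}"] = merged
        else:
            raise ValueError(f"unknown rearrangement event {kind!r}")
    return out


def _lay_out_genes(
    species: str,
    chrom_genes: dict[str, list[int]],
    genome_size: int,
    gene_length: int,
    rng: np.random.Generator,
) -> tuple[GenomeSpec, list[GeneRecord], dict[int, str]]:
    """Place genes along chromosomes, scaling intergenic gaps so chromosome
    lengths split the target genome size in proportion to gene counts."""
    n_total = sum(len(v) for v in chrom_genes.values())
    chroms = []
    genes: list[GeneRecord] = []
    id_of: dict[int, str] = {}
    for chrom in sorted(chrom_genes):
        members = chrom_genes[chrom]
        length = int(round(genome_size * len(members) / n_total))
        slot = length / len(members)
        for k, anc in enumerate(members):
            jitter = rng.integers(0, max(1, int(slot) - gene_length))
            start = int(k * slot) + int(jitter)
            gid = f"{species}_g{anc:04d}"
            genes.append(GeneRecord(gid, chrom, start, start + gene_length,
                                    "+" if rng.random() < 0.5 else "-"))
            id_of[anc] = gid
        chroms.append((chrom, length))
    genome = GenomeSpec(species, tuple(chroms))
    return genome, sorted(genes, key=lambda g: (g.chrom, g.start)), id_of


def simulate_genomes(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[str, GenomeSpec], dict[str, list[GeneRecord]], OrthologTable, dict]:
    """Ancestral outgroup plus rearranged ingroup genomes and the true
    ortholog table. Also returns per-species ancestral-index -> gene-id maps."""
    config.validate()
    anc: dict[str, list[int]] = {}
    idx = 0
    for c in range(1, config.n_outgroup_chroms + 1):
        anc[f"c{c}"] = list(range(idx, idx + config.genes_per_chrom))
        idx += config.genes_per_chrom

    genomes: dict[str, GenomeSpec] = {}
    genes: dict[str, list[GeneRecord]] = {}
    id_maps: dict[str, dict[int, str]] = {}
    all_species = list(config.ingroup_species) + [config.outgroup_species]
    for sp in all_species:
        plan = config.rearrangement_plans.get(sp, [])
        layout = _apply_plan(anc, plan, rng) if plan else anc
        genomes[sp], genes[sp], id_maps[sp] = _lay_out_genes(
            sp, layout, config.genome_sizes[sp], config.gene_length, rng
        )

    ref = config.ingroup_species[0]
    others = [sp for sp in all_species if sp != ref]
    table = pd.DataFrame(
        {sp: [id_maps[sp][a] for a in range(idx)] for sp in others},
        index=[id_maps[ref][a] for a in range(idx)],
    )
    orthologs = OrthologTable(table, ref)
    return genomes, genes, orthologs, id_maps


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------


def _compartment_blocks(n_bins: int, config: SimulationConfig) -> list[tuple[int, int]]:
    """Deterministic alternating boosted blocks separated by short seams."""
    blocks = []
    pos = config.compartment_gap_bins
    while pos + config.compartment_block_bins <= n_bins - config.compartment_gap_bins:
        blocks.append((pos, pos + config.compartment_block_bins))
        pos += config.compartment_block_bins + config.compartment_gap_bins
    return blocks


def simulate_contacts(
    genome: GenomeSpec,
    config: SimulationConfig,
    rng: np.random.Generator,
    planted_loops: list[tuple[str, int, int, float]] | None = None,
) -> tuple[SparseContacts, dict[str, list[tuple[int, int]]]]:
    """Gamma-noised power-law contact map with planted compartments/loops.

    Expectation for bins i <= j at separation s = j - i:
    ``scale * max(s, 1)^-alpha``, multiplied by the compartment boost when
    both bins fall inside one planted block, plus the loop strength at
    planted anchor bin pairs. Values are Gamma(shape k, mean expectation).
    Returns the contacts and the per-chromosome planted block coordinates.
    """
    rows = []
    blocks_by_chrom: dict[str, list[tuple[int, int]]] = {}
    loops = planted_loops or []
    for chrom, _length in genome.chromosomes:
        n = genome.n_bins(chrom, config.resolution)
        i, j = np.triu_indices(n)
        s = (j - i).astype(float)
        mean = config.contact_scale * np.maximum(s, 1.0) ** (-config.decay_exponent)
        blocks = _compartment_blocks(n, config)
        blocks_by_chrom[chrom] = blocks
        for bs, be in blocks:
            inside = (i >= bs) & (i < be) & (j >= bs) & (j < be)
            mean[inside] *= config.compartment_boost
        for lc, bi, bj, strength in loops:
            if lc != chrom:
                continue
            hit = (i == min(bi, bj)) & (j == max(bi, bj))
            mean[hit] += strength
        values = rng.gamma(config.gamma_shape, mean / config.gamma_shape)
        rows.append(pd.DataFrame({"chrom": chrom, "bin1": i, "bin2": j, "value": values}))
    entries = pd.concat(rows, ignore_index=True)
    return SparseContacts(genome.species_id, config.resolution, entries), blocks_by_chrom


# ---------------------------------------------------------------------------
# loops
# ---------------------------------------------------------------------------


def _plan_conserved_loops(
    config: SimulationConfig,
    genes: dict[str, list[GeneRecord]],
    id_maps: dict[str, dict[int, str]],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Pick ancestral gene-index anchor pairs that are co-chromosomal in
    every ingroup species, spread across ancestral chromosomes."""
    gene_of = {
        sp: {g.gene_id: g for g in genes[sp]} for sp in config.ingroup_species
    }
    lo, hi = config.loop_gene_separation
    n_anc = config.n_outgroup_chroms * config.genes_per_chrom
    chosen = []
    attempts = 0
    while len(chosen) < config.n_conserved_loops and attempts < 10_000:
        attempts += 1
        a = int(rng.integers(0, n_anc - hi))
        b = a + int(rng.integers(lo, hi))
        ok = True
        for sp in config.ingroup_species:
            ga = gene_of[sp][id_maps[sp][a]]
            gb = gene_of[sp][id_maps[sp][b]]
            if ga.chrom != gb.chrom:
                ok = False
                break
            sep = abs(gb.start - ga.start) // config.resolution
            if not lo // 3 <= sep:  # keep anchors well separated in bins too
                ok = False
                break
        if ok and all(c[0] != a and c[1] != b for c in chosen):
            chosen.append((a, b))
    rows = []
    for k, (a, b) in enumerate(chosen):
        rows.append({"loop_truth_id": f"conserved_{k}", "anc_a": a, "anc_b": b,
                     "species": ",".join(config.ingroup_species)})
    return pd.DataFrame(rows)


def _loops_for_species(
    sp: str,
    truth: pd.DataFrame,
    genes: dict[str, list[GeneRecord]],
    id_maps: dict[str, dict[int, str]],
    config: SimulationConfig,
) -> list[tuple[str, int, int, float]]:
    gene_of = {g.gene_id: g for g in genes[sp]}
    res = config.resolution
    planted = []
    for r in truth.itertuples(index=False):
        if sp not in r.species.split(","):
            continue
        ga = gene_of[id_maps[sp][r.anc_a]]
        gb = gene_of[id_maps[sp][r.anc_b]]
        # boost every bin pair the two anchor genes occupy, so the pair's
        # bin-averaged value carries the full loop strength
        bins_a = range(ga.start // res, (ga.end - 1) // res + 1)
        bins_b = range(gb.start // res, (gb.end - 1) // res + 1)
        for bi in bins_a:
            for bj in bins_b:
                planted.append((ga.chrom, min(bi, bj), max(bi, bj), config.loop_strength))
    return planted


def _anchor_bins_for_species(
    sp: str,
    truth: pd.DataFrame,
    genes: dict[str, list[GeneRecord]],
    id_maps: dict[str, dict[int, str]],
    config: SimulationConfig,
) -> list[tuple[str, int, int]]:
    """One (chrom, anchor_gene_start_a, anchor_gene_start_b) row per truth
    loop, ordered along the chromosome."""
    gene_of = {g.gene_id: g for g in genes[sp]}
    out = []
    for r in truth.itertuples(index=False):
        if sp not in r.species.split(","):
            continue
        ga = gene_of[id_maps[sp][r.anc_a]]
        gb = gene_of[id_maps[sp][r.anc_b]]
        pa, pb = sorted((ga.start, gb.start))
        out.append((ga.chrom, pa, pb))
    return out


def _loop_calls(
    anchors: list[tuple[str, int, int]], config: SimulationConfig
) -> dict[int, list[dict]]:
    """Emit BEDPE-style calls at the working resolution, plus the first two
    loops re-called at 50 kb (anchored at the 50 kb bin holding the anchor
    gene's start) so multi-resolution merging has duplicates to drop."""
    res = config.resolution

    def call(c, pa, pb, r):
        bi, bj = pa // r, pb // r
        return {"chrom": c, "a1": (bi * r, (bi + 1) * r), "a2": (bj * r, (bj + 1) * r),
                "fdr": 0.01, "resolution": r}

    fine = res // 2
    return {
        res: [call(c, pa, pb, res) for c, pa, pb in anchors],
        fine: [call(c, pa, pb, fine) for c, pa, pb in anchors[:2]],
    }


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def simulate_expression(
    genes: list[GeneRecord],
    planted_pairs: list[tuple[str, str]],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """TPM matrix (genes x tissues); planted pairs share a bivariate
    log-normal with log-scale Pearson correlation rho, the rest are
    independent; a few genes are silent (all-zero) to exercise
    zero-variance handling downstream."""
    if not 0.0 <= config.coexpression_rho <= 1.0:
        raise ValueError("coexpression_rho must lie in [0, 1]")
    ids = [g.gene_id for g in genes]
    n = len(ids)
    z = rng.normal(size=(n, config.n_tissues))
    pos = {g: k for k, g in enumerate(ids)}
    rho = config.coexpression_rho
    for ga, gb in planted_pairs:
        ia, ib = pos[ga], pos[gb]
        shared = z[ia]
        z[ib] = rho * shared + np.sqrt(1 - rho**2) * rng.normal(size=config.n_tissues)
    tpm = np.exp(config.expression_log_mean + config.expression_log_sd * z)
    mat = pd.DataFrame(tpm, index=ids, columns=[f"tissue_{t:02d}" for t in range(config.n_tissues)])
    silent = rng.choice(n, size=min(config.n_silent_genes, n), replace=False)
    mat.iloc[silent] = 0.0
    return mat


# ---------------------------------------------------------------------------
# CNEs, repeats, accessibility
# ---------------------------------------------------------------------------


def _truth_homology(
    config: SimulationConfig, sp_a: str, sp_b: str
) -> set[tuple[str, str]]:
    """True homologous chromosome pairs: share >= 1 ancestral chromosome.

    Chromosome names record their ancestral composition ('c1c2' is the
    fusion of c1 and c2), so composition is recovered by name parsing."""
    def sources(chrom: str) -> set[str]:
        import re

        return set(re.findall(r"c\d+", chrom))

    def chroms(sp: str) -> list[str]:
        plan = config.rearrangement_plans.get(sp, [])
        layout = {f"c{c}": [] for c in range(1, config.n_outgroup_chroms + 1)}
        rng = np.random.default_rng(0)  # events only rename; mixing irrelevant here
        return list(_apply_plan(layout, plan, rng)) if plan else list(layout)

    return {
        (a, b)
        for a in chroms(sp_a)
        for b in chroms(sp_b)
        if sources(a) & sources(b)
    }


def _random_intergenic_pos(
    genome: GenomeSpec, genes_by_chrom: dict[str, list[GeneRecord]],
    chrom: str, length: int, rng: np.random.Generator,
) -> int:
    """Start position of a feature of ``length`` not overlapping any gene."""
    limit = genome.chrom_length[chrom] - length
    occupied = genes_by_chrom.get(chrom, [])
    for _ in range(200):
        start = int(rng.integers(0, limit))
        if not any(g.start < start + length and g.end > start for g in occupied):
            return start
    raise RuntimeError("could not place intergenic feature")


def simulate_cnes_and_repeats(
    config: SimulationConfig,
    genomes: dict[str, GenomeSpec],
    genes: dict[str, list[GeneRecord]],
    rng: np.random.Generator,
    enriched_regions: dict[str, list[tuple[int, int]]] | None = None,
    enrichment_factor: float = 1.0,
) -> tuple[list[AlignmentBlock], list[RepeatFeature], pd.DataFrame]:
    """Scatter alignment blocks (CNE and coding) and repeats on the
    reference genome.

    A fraction ``cne_dispersal`` of CNE blocks (``coding_dispersal`` of
    coding blocks) is placed on non-homologous partner chromosomes; the
    rest land on true homologs. ``enriched_regions`` optionally biases CNE
    reference placement into given intervals by ``enrichment_factor``.
    Returns blocks, repeats, and the per-block truth table.
    """
    ref = config.ingroup_species[0]
    partner = config.cne_partner_species
    genome = genomes[ref]
    hom = _truth_homology(config, ref, partner)
    partner_chroms = [c for c, _ in genomes[partner].chromosomes]
    ref_chroms = [c for c, _ in genome.chromosomes]
    weights = np.array([genome.chrom_length[c] for c in ref_chroms], float)
    weights /= weights.sum()
    genes_by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes[ref]:
        genes_by_chrom.setdefault(g.chrom, []).append(g)

    blocks: list[AlignmentBlock] = []
    truth_rows = []

    def place(n: int, dispersal: float, coding: bool, tag: str):
        for k in range(n):
            length = int(rng.integers(*config.cne_length_range))
            chrom = str(rng.choice(ref_chroms, p=weights))
            if coding:
                # drop onto a gene body
                g = genes_by_chrom[chrom][int(rng.integers(0, len(genes_by_chrom[chrom])))]
                start = g.start + int(rng.integers(0, max(1, g.end - g.start - 50)))
            elif enriched_regions and rng.random() < (
                enrichment_factor / (1.0 + enrichment_factor)
            ):
                regions = enriched_regions.get(chrom)
                if regions:
                    s, e = regions[int(rng.integers(0, len(regions)))]
                    start = int(rng.integers(s, max(s + 1, e - length)))
                else:
                    start = _random_intergenic_pos(genome, genes_by_chrom, chrom, length, rng)
            else:
                start = _random_intergenic_pos(genome, genes_by_chrom, chrom, length, rng)
            dispersed = bool(rng.random() < dispersal)
            homs = [b for b in partner_chroms if (chrom, b) in hom]
            nonhoms = [b for b in partner_chroms if (chrom, b) not in hom]
            pool = nonhoms if dispersed and nonhoms else homs
            other_chrom = str(pool[int(rng.integers(0, len(pool)))])
            other_start = int(rng.integers(0, genomes[partner].chrom_length[other_chrom] - length))
            blocks.append(
                AlignmentBlock(chrom, start, start + length, partner,
                               other_chrom, other_start, other_start + length, coding)
            )
            truth_rows.append(
                {"block": f"{tag}_{k}", "ref_chrom": chrom, "is_coding": coding,
                 "dispersed": dispersed and bool(nonhoms)}
            )

    place(config.cne_count, config.cne_dispersal, coding=False, tag="cne")
    place(config.n_coding_blocks, config.coding_dispersal, coding=True, tag="coding")

    repeat_classes = list(config.repeat_class_mix)
    probs = np.array([config.repeat_class_mix[c] for c in repeat_classes], float)
    probs /= probs.sum()
    repeats = []
    for _ in range(config.repeat_count):
        chrom = str(rng.choice(ref_chroms, p=weights))
        length = int(rng.integers(100, 1000))
        start = int(rng.integers(0, genome.chrom_length[chrom] - length))
        cls = str(rng.choice(repeat_classes, p=probs))
        repeats.append(RepeatFeature(chrom, start, start + length, cls))
    return blocks, repeats, pd.DataFrame(truth_rows)


def simulate_accessibility(
    genome: GenomeSpec,
    anchor_regions: dict[str, list[tuple[int, int]]],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[SignalInterval]:
    """Tiled signal track with baseline Gamma noise (mostly <= 1) boosted
    inside anchor regions so the demo shows accessible anchors."""
    out = []
    tile = config.atac_tile
    for chrom, length in genome.chromosomes:
        anchors = anchor_regions.get(chrom, [])
        for start in range(0, length, tile):
            end = min(start + tile, length)
            base = rng.gamma(2.0, 0.25)  # mean 0.5
            if any(start < ae and end > as_ for as_, ae in anchors):
                base *= config.atac_anchor_boost
            out.append(SignalInterval(chrom, start, end, float(base)))
    return out


# ---------------------------------------------------------------------------
# orchestration and serialisation
# ---------------------------------------------------------------------------


def simulate_all(config: SimulationConfig | None = None, seed: int | None = None) -> SimDataset:
    """Run the whole generator; a fixed seed gives byte-identical outputs."""
    config = config or SimulationConfig()
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    config.validate()
    rng = np.random.default_rng(config.seed)

    genomes, genes, orthologs, id_maps = simulate_genomes(config, rng)
    loop_truth = _plan_conserved_loops(config, genes, id_maps, rng)

    # species-private loops extend the truth table
    private_rows = []
    n_anc = config.n_outgroup_chroms * config.genes_per_chrom
    lo, hi = config.loop_gene_separation
    gene_of = {sp: {g.gene_id: g for g in genes[sp]} for sp in config.ingroup_species}
    for sp in config.ingroup_species:
        placed = 0
        while placed < config.n_private_loops:
            a = int(rng.integers(0, n_anc - hi))
            b = a + int(rng.integers(lo, hi))
            ga = gene_of[sp][id_maps[sp][a]]
            gb = gene_of[sp][id_maps[sp][b]]
            if ga.chrom != gb.chrom:
                continue
            private_rows.append(
                {"loop_truth_id": f"private_{sp}_{placed}", "anc_a": a, "anc_b": b,
                 "species": sp}
            )
            placed += 1
    loop_truth = pd.concat([loop_truth, pd.DataFrame(private_rows)], ignore_index=True)

    contacts: dict[str, SparseContacts] = {}
    loop_calls: dict[str, dict[int, list[dict]]] = {}
    compartments: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for sp in config.ingroup_species:
        planted = _loops_for_species(sp, loop_truth, genes, id_maps, config)
        contacts[sp], compartments[sp] = simulate_contacts(genomes[sp], config, rng, planted)
        loop_calls[sp] = _loop_calls(
            _anchor_bins_for_species(sp, loop_truth, genes, id_maps, config), config
        )

    ref = config.ingroup_species[0]
    conserved = loop_truth[loop_truth["species"].str.contains(",")]
    planted_pairs = [
        (id_maps[ref][int(r.anc_a)], id_maps[ref][int(r.anc_b)])
        for r in conserved.itertuples(index=False)
    ]
    expression = simulate_expression(genes[ref], planted_pairs, config, rng)

    blocks, repeats, block_truth = simulate_cnes_and_repeats(config, genomes, genes, rng)

    anchor_regions: dict[str, list[tuple[int, int]]] = {}
    for calls in loop_calls[ref].values():
        for c in calls:
            anchor_regions.setdefault(c["chrom"], []).extend([c["a1"], c["a2"]])
    accessibility = simulate_accessibility(genomes[ref], anchor_regions, config, rng)

    comp_rows = [
        {"species": sp, "chrom": chrom, "start_bin": s, "end_bin": e,
         "boost": config.compartment_boost}
        for sp, per_chrom in compartments.items()
        for chrom, blocks_ in per_chrom.items()
        for s, e in blocks_
    ]
    pair_rows = [
        {"gene_a": a, "gene_b": b, "rho": config.coexpression_rho} for a, b in planted_pairs
    ]
    truth = {
        "loops": loop_truth,
        "compartments": pd.DataFrame(comp_rows),
        "planted_pairs": pd.DataFrame(pair_rows),
        "alignment_blocks": block_truth,
    }
    return SimDataset(
        config=config, genomes=genomes, genes=genes, orthologs=orthologs,
        contacts=contacts, loop_calls=loop_calls, expression=expression,
        alignment_blocks=blocks, repeats=repeats, accessibility=accessibility,
        truth=truth,
    )


def write_dataset(ds: SimDataset, outdir: str | Path) -> None:
    """Serialise every component in the formats the readers consume, plus
    truth/*.tsv ledgers."""
    outdir = Path(outdir)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)
    for sp, genome in ds.genomes.items():
        write_genome_spec(genome, outdir / f"{sp}.chrom.sizes")
        write_genes_bed(ds.genes[sp], outdir / f"{sp}.genes.bed")
    write_orthologs(ds.orthologs, outdir / "orthologs.tsv")
    for sp, con in ds.contacts.items():
        write_sparse_contacts(con, outdir / f"{sp}.contacts.tsv")
    for sp, by_res in ds.loop_calls.items():
        for res, calls in by_res.items():
            write_loops_bedpe(calls, outdir / f"{sp}.loops_{res // 1000}kb.bedpe")
    write_expression(ds.expression, outdir / f"{ds.ref_species}.tpm.tsv")
    write_alignment_blocks(ds.alignment_blocks, outdir / "alignment_blocks.tsv")
    write_repeats(ds.repeats, outdir / f"{ds.ref_species}.repeats.bed")
    write_bedgraph(ds.accessibility, outdir / f"{ds.ref_species}.atac.bedgraph")
    for name, table in ds.truth.items():
        table.to_csv(outdir / "truth" / f"{name}.tsv", sep="\t", index=False)
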