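"""Cross-species gene-pair interaction table and conservation classes.

The central comparative statistic: every unordered pair of same-chromosome
genes in a reference species, with one-to-one orthologs in two further
ingroup species and an outgroup, carries one KR-normalised contact value per
species (the mean over all bin pairs the two genes occupy). A pair is
"interacting" in a species when that value reaches the threshold T (default
10 KR-normalised reads, inclusive); the cross-species pattern of
interacting/non-interacting assigns a conservation category. Orthologs are
additionally classed by outgroup chromosome co-residence and ancestral
separation distance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from .io_formats import GeneRecord, OrthologTable, SparseContacts, ValidationError

#: interaction threshold in KR-normalised reads; >= T is "interacting"
DEFAULT_THRESHOLD = 10.0

#: outgroup ancestral-distance class edges (bp), inclusive upper bounds
DISTANCE_CLASS_EDGES = (5_000_000, 15_000_000)


class InteractionCategory(str, Enum):
    ALL_COLEOIDS = "ALL_COLEOIDS"
    DECAPODS_ONLY = "DECAPODS_ONLY"
    OCTOPUS_ONLY = "OCTOPUS_ONLY"
    NOT_CONSERVED = "NOT_CONSERVED"
    UNCLASSIFIED = "UNCLASSIFIED"


class OutgroupOrigin(str, Enum):
    SAME_CHROM = "SAME_CHROM"
    DIFF_CHROM = "DIFF_CHROM"


class DistanceClass(str, Enum):
    LE_5MB = "LE_5MB"
    GT5_LE15MB = "GT5_LE15MB"
    GT_15MB = "GT_15MB"
    NA = "NA"


@dataclass
class GenePairRecord:
    """One orthologous gene pair; genes named in reference-species ids,
    ordered by reference start coordinate."""

    gene_a: str
    gene_b: str
    chrom: str
    values: dict[str, float]  # species -> mean KR value
    distances: dict[str, int]  # species -> downstream.start - upstream.end
    category: InteractionCategory = InteractionCategory.UNCLASSIFIED
    outgroup_origin: OutgroupOrigin | None = None
    outgroup_distance_class: DistanceClass = DistanceClass.NA
    insulation_means: dict[str, float] = field(default_factory=dict)
    insulation_class: str | None = None


def genes_in_bin(
    genes: list[GeneRecord], chrom: str, bin_index: int, resolution: int
) -> set[str]:
    """Ids of genes whose interval overlaps bin [bin*res, (bin+1)*res)."""
    lo = bin_index * resolution
    hi = lo + resolution
    return {g.gene_id for g in genes if g.chrom == chrom and g.start < hi and g.end > lo}


def bin_gene_index(genes: list[GeneRecord], resolution: int) -> dict[tuple[str, int], list[str]]:
    """(chrom, bin) -> gene ids overlapping that bin, for all occupied bins."""
    idx: dict[tuple[str, int], list[str]] = {}
    for g in genes:
        for b in range(g.start // resolution, (g.end - 1) // resolution + 1):
            idx.setdefault((g.chrom, b), []).append(g.gene_id)
    return idx


def extract_pair_values(
    contacts: SparseContacts, genes: list[GeneRecord]
) -> dict[tuple[str, str], float]:
    """Mean KR value per unordered gene pair over all bin pairs they occupy.

    Bin pairs with no genes on either side contribute nothing; self-pairs
    (one gene spanning both bins) are removed; a pair seen at several bin
    pairs gets the arithmetic mean of those values.
    """
    idx = bin_gene_index(genes, contacts.resolution)
    sums: dict[tuple[str, str], float] = {}
    counts: dict[tuple[str, str], int] = {}
    for chrom, b1, b2, value in contacts.entries.itertuples(index=False):
        g1 = idx.get((chrom, b1))
        g2 = idx.get((chrom, b2))
        if not g1 or not g2:
            continue
        seen = set()
        for a in g1:
            for b in g2:
                if a == b:
                    continue
                key = (a, b) if a < b else (b, a)
                if key in seen:  # same pair via both orders within one entry
                    continue
                seen.add(key)
                sums[key] = sums.get(key, 0.0) + value
                counts[key] = counts.get(key, 0) + 1
    return {k: sums[k] / counts[k] for k in sums}


def classify_interaction(
    values: dict[str, float],
    decapods: tuple[str, str],
    octopus: str,
    threshold: float = DEFAULT_THRESHOLD,
) -> InteractionCategory:
    """Conservation category from per-species values; >= threshold counts as
    interacting (the threshold is inclusive)."""
    d1 = values[decapods[0]] >= threshold
    d2 = values[decapods[1]] >= threshold
    oc = values[octopus] >= threshold
    if d1 and d2 and oc:
        return InteractionCategory.ALL_COLEOIDS
    if d1 and d2 and not oc:
        return InteractionCategory.DECAPODS_ONLY
    if oc and not d1 and not d2:
        return InteractionCategory.OCTOPUS_ONLY
    if not (d1 or d2 or oc):
        return InteractionCategory.NOT_CONSERVED
    return InteractionCategory.UNCLASSIFIED


def pair_distance(g1: GeneRecord, g2: GeneRecord) -> int:
    """Start of the downstream gene minus end of the upstream gene (may be
    negative when the two intervals overlap)."""
    up, down = (g1, g2) if g1.start <= g2.start else (g2, g1)
    return down.start - up.end


def classify_outgroup(
    gene_a: str,
    gene_b: str,
    outgroup_genes: dict[str, GeneRecord],
    ortho_map: dict[str, str],
) -> tuple[OutgroupOrigin, DistanceClass, int | None]:
    """Outgroup chromosome co-residence and ancestral distance class.

    Distance classes use inclusive upper bounds: <=5 Mb, >5 and <=15 Mb,
    >15 Mb. Returns (origin, class, distance-or-None).
    """
    oa = outgroup_genes[ortho_map[gene_a]]
    ob = outgroup_genes[ortho_map[gene_b]]
    if oa.chrom != ob.chrom:
        return OutgroupOrigin.DIFF_CHROM, DistanceClass.NA, None
    d = pair_distance(oa, ob)
    if d <= DISTANCE_CLASS_EDGES[0]:
        cls = DistanceClass.LE_5MB
    elif d <= DISTANCE_CLASS_EDGES[1]:
        cls = DistanceClass.GT5_LE15MB
    else:
        cls = DistanceClass.GT_15MB
    return OutgroupOrigin.SAME_CHROM, cls, d


def build_pair_table(
    contacts_by_species: dict[str, SparseContacts],
    genes_by_species: dict[str, list[GeneRecord]],
    orthologs: OrthologTable,
    ref_species: str,
    decapods: tuple[str, str],
    octopus: str,
    outgroup: str,
    threshold: float = DEFAULT_THRESHOLD,
    universe: str = "all",
    max_separation: int | None = None,
) -> list[GenePairRecord]:
    """Build and classify the cross-species gene-pair table.

    The pair universe (``universe="all"``, the default) is every unordered
    same-chromosome combination of reference genes; ``"observed"`` restricts
    to pairs with at least one sparse entry in the reference map. In both
    modes pairs must have one-to-one orthologs in all ingroup species and
    the outgroup, with the two ingroup orthologs co-chromosomal in every
    ingroup species. Values absent from a species' sparse map are 0.
    ``max_separation`` optionally caps reference-species separation (bp).
    """
    ingroup = [decapods[0], decapods[1], octopus]
    if ref_species not in ingroup:
        raise ValueError("reference species must be one of the ingroup species")
    gene_maps = {}
    for sp in ingroup + [outgroup]:
        gene_maps[sp] = {g.gene_id: g for g in genes_by_species[sp]}
    ortho = {
        sp: orthologs.mapping(ref_species, sp) for sp in ingroup + [outgroup] if sp != ref_species
    }

    pair_values = {
        sp: extract_pair_values(contacts_by_species[sp], genes_by_species[sp])
        for sp in ingroup
    }

    # candidate reference genes: orthologs everywhere, present in annotations
    ref_genes = [
        g
        for g in genes_by_species[ref_species]
        if all(g.gene_id in ortho[sp] for sp in ortho)
    ]
    for g in ref_genes:
        for sp in ortho:
            og = ortho[sp][g.gene_id]
            if og not in gene_maps[sp]:
                raise ValidationError(
                    f"gene {og!r} (ortholog of {g.gene_id}) missing from {sp} annotation"
                )

    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in ref_genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    records: list[GenePairRecord] = []
    for chrom, chrom_genes in sorted(by_chrom.items()):
        chrom_genes.sort(key=lambda g: (g.start, g.gene_id))
        for ga, gb in itertools.combinations(chrom_genes, 2):
            if max_separation is not None and pair_distance(ga, gb) > max_separation:
                continue
            key = (ga.gene_id, gb.gene_id) if ga.gene_id < gb.gene_id else (gb.gene_id, ga.gene_id)
            if universe == "observed" and key not in pair_values[ref_species]:
                continue
            # intrachromosomal orthologs in all three ingroup species
            ok = True
            for sp in ingroup:
                if sp == ref_species:
                    a, b = ga, gb
                else:
                    a = gene_maps[sp][ortho[sp][ga.gene_id]]
                    b = gene_maps[sp][ortho[sp][gb.gene_id]]
                if a.chrom != b.chrom:
                    ok = False
                    break
            if not ok:
                continue
            values, distances = {}, {}
            for sp in ingroup:
                if sp == ref_species:
                    a, b = ga, gb
                else:
                    a = gene_maps[sp][ortho[sp][ga.gene_id]]
                    b = gene_maps[sp][ortho[sp][gb.gene_id]]
                k = (a.gene_id, b.gene_id) if a.gene_id < b.gene_id else (b.gene_id, a.gene_id)
                values[sp] = pair_values[sp].get(k, 0.0)
                distances[sp] = pair_distance(a, b)
            rec = GenePairRecord(
                gene_a=ga.gene_id, gene_b=gb.gene_id, chrom=chrom,
                values=values, distances=distances,
            )
            rec.category = classify_interaction(values, decapods, octopus, threshold)
            origin, dclass, _ = classify_outgroup(
                ga.gene_id, gb.gene_id, gene_maps[outgroup], ortho[outgroup]
            )
            rec.outgroup_origin = origin
            rec.outgroup_distance_class = dclass
            records.append(rec)
    return records


def exclusive_gene_sets(
    records: list[GenePairRecord],
) -> dict[InteractionCategory, set[str]]:
    """Per-category gene sets for single-gene analyses.

    Genes of interacting categories are all retained; NOT_CONSERVED keeps
    only genes that appear in no interacting category's pairs.
    """
    sets: dict[InteractionCategory, set[str]] = {
        c: set() for c in InteractionCategory if c != InteractionCategory.UNCLASSIFIED
    }
    for r in records:
        if r.category in sets:
            sets[r.category].update((r.gene_a, r.gene_b))
    interacting = (
        sets[InteractionCategory.ALL_COLEOIDS]
        | sets[InteractionCategory.DECAPODS_ONLY]
        | sets[InteractionCategory.OCTOPUS_ONLY]
    )
    sets[InteractionCategory.NOT_CONSERVED] -= interacting
    return sets


def pair_table_to_frame(records: list[GenePairRecord]) -> pd.DataFrame:
    """Flat table (one row per pair) for pairs.tsv output."""
    rows = []
    for r in records:
        row = {"gene_a": r.gene_a, "gene_b": r.gene_b, "chrom": r.chrom}
        for sp, v in r.values.items():
            row[f"value_{sp}"] = v
        for sp, d in r.distances.items():
            row[f"distance_{sp}"] = d
        row["category"] = r.category.value
        row["outgroup_origin"] = r.outgroup_origin.value if r.outgroup_origin else "NA"
        row["outgroup_distance_class"] = r.outgroup_distance_class.value
        for sp, m in r.insulation_means.items():
            row[f"insulation_{sp}"] = m
        row["insulation_class"] = r.insulation_class or "NA"
        rows.append(row)
    return pd.DataFrame(rows)
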