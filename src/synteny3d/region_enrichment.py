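"""Anchor/interloop/background genome partitions and enrichment tests.

The genome is split into three disjoint classes from a loop set: the merged
union of all anchors; the interloop spans between each loop's paired
anchors (minus anchor overlap); and the background complement. CNE density
(elements per kb) and open-chromatin coverage are compared between classes
with rank-sum tests; each merged interval is one statistical observation.
Also here: intervening-gene coverage of gaps and repeat-class composition
of intergenic regions per interaction category.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _intervals as iv
from .expression_metrics import bh_adjust
from .io_formats import AlignmentBlock, GeneRecord, GenomeSpec, RepeatFeature, SignalInterval

logger = logging.getLogger(__name__)

MAX_INTERVENING_GENE_LEN = 1_500_000
ACCESSIBILITY_THRESHOLD = 1.0

REGION_CLASSES = ("anchor", "interloop", "background")


@dataclass
class RegionPartition:
    """Disjoint anchor/interloop/background interval sets covering a genome."""

    genome: GenomeSpec
    anchors: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    interloops: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    background: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def regions(self, which: str) -> list[tuple[str, int, int]]:
        store = getattr(self, {"anchor": "anchors", "interloop": "interloops",
                               "background": "background"}[which])
        return [(c, s, e) for c, ivs in sorted(store.items()) for s, e in ivs]

    def class_length(self, which: str) -> int:
        return sum(e - s for _, s, e in self.regions(which))


def build_partition(loops, genome: GenomeSpec) -> RegionPartition:
    """Partition the genome into anchors, interloop spans, and background.

    Anchors are the merged union of all anchor intervals; interloops the
    merged union of (anchor1.end, anchor2.start) spans with anchors
    subtracted; background the complement. Intervals extending past a
    chromosome end are clipped with a warning.
    """
    part = RegionPartition(genome)
    anchors_raw: dict[str, list[tuple[int, int]]] = {c: [] for c, _ in genome.chromosomes}
    spans_raw: dict[str, list[tuple[int, int]]] = {c: [] for c, _ in genome.chromosomes}
    for lp in loops:
        if lp.chrom not in anchors_raw:
            raise ValueError(f"loop on unknown chromosome {lp.chrom!r}")
        limit = genome.chrom_length[lp.chrom]
        for a in (lp.anchor1, lp.anchor2):
            if a[1] > limit:
                warnings.warn(f"anchor {a} extends past {lp.chrom} end {limit}; clipped")
        anchors_raw[lp.chrom] += iv.clip([lp.anchor1, lp.anchor2], limit)
        gap = (lp.anchor1[1], lp.anchor2[0])
        spans_raw[lp.chrom] += iv.clip([gap], limit)
    for chrom, length in genome.chromosomes:
        anc = iv.merge(anchors_raw[chrom])
        inter = iv.subtract(spans_raw[chrom], anc)
        part.anchors[chrom] = anc
        part.interloops[chrom] = inter
        part.background[chrom] = iv.subtract(iv.complement(anc, length), inter)
    return part


def _pairwise_region_tests(per_region: pd.DataFrame, value_col: str) -> pd.DataFrame:
    rows = []
    for ra, rb in itertools.combinations(REGION_CLASSES, 2):
        xa = per_region.loc[per_region["region_class"] == ra, value_col]
        xb = per_region.loc[per_region["region_class"] == rb, value_col]
        if len(xa) == 0 or len(xb) == 0:
            continue
        p = float(stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
        rows.append(
            {"class_a": ra, "class_b": rb, "n_a": len(xa), "n_b": len(xb),
             "median_a": float(xa.median()), "median_b": float(xb.median()), "p": p}
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
    return df


def cne_density(
    partition: RegionPartition, cnes: list[AlignmentBlock]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """CNEs per kilobase for every merged partition interval, plus pairwise
    rank-sum tests between region classes (BH-adjusted).

    A CNE straddling a boundary is counted once in every region it
    overlaps; zero-length regions are excluded.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for b in cnes:
        by_chrom.setdefault(b.ref_chrom, []).append((b.ref_start, b.ref_end))
    rows = []
    for which in REGION_CLASSES:
        for chrom, s, e in partition.regions(which):
            if e <= s:
                continue
            n = iv.count_overlapping([(s, e)], by_chrom.get(chrom, []))[0]
            rows.append(
                {"region_class": which, "chrom": chrom, "start": s, "end": e,
                 "n_cne": n, "density_per_kb": n / ((e - s) / 1000)}
            )
    per_region = pd.DataFrame(rows)
    return per_region, _pairwise_region_tests(per_region, "density_per_kb")


def call_peaks(
    signal: list[SignalInterval], threshold: float = ACCESSIBILITY_THRESHOLD
) -> dict[str, list[tuple[int, int]]]:
    """Open-chromatin peaks: merged intervals with signal strictly above the
    threshold (a value of exactly 1.0 is not a peak)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for s in signal:
        if s.value > threshold:
            by_chrom.setdefault(s.chrom, []).append((s.start, s.end))
    return {c: iv.merge(ivs) for c, ivs in by_chrom.items()}


def accessibility_enrichment(
    partition: RegionPartition,
    signal: list[SignalInterval],
    threshold: float = ACCESSIBILITY_THRESHOLD,
    statistic: str = "fraction",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-region open-chromatin coverage and between-class rank tests.

    ``statistic="fraction"`` (default) reports the fraction of region bases
    under peaks; ``"count"`` reports the number of overlapping peaks.
    """
    peaks = call_peaks(signal, threshold)
    rows = []
    for which in REGION_CLASSES:
        for chrom, s, e in partition.regions(which):
            if e <= s:
                continue
            p = peaks.get(chrom, [])
            if statistic == "fraction":
                val = iv.covered_fraction((s, e), p)
            elif statistic == "count":
                val = iv.count_overlapping([(s, e)], p)[0]
            else:
                raise ValueError(f"unknown statistic {statistic!r}")
            rows.append(
                {"region_class": which, "chrom": chrom, "start": s, "end": e,
                 "coverage": float(val)}
            )
    per_region = pd.DataFrame(rows)
    return per_region, _pairwise_region_tests(per_region, "coverage")


def intervening_gene_coverage(
    gaps: list[tuple[str, str, int, int, set[str]]],
    genes: list[GeneRecord],
    max_gene_len: int = MAX_INTERVENING_GENE_LEN,
) -> pd.DataFrame:
    """Percent of each gap covered by the union of intervening genes.

    ``gaps`` rows are (category, chrom, gap_start, gap_end, exclude_ids)
    where exclude_ids are the flanking genes themselves. Genes longer than
    ``max_gene_len`` are dropped as likely misannotations. Gaps that are
    empty (adjacent flanks), negative (overlapping flanks), or contain no
    retained intervening gene are excluded; exclusion counts are logged.
    """
    retained = [g for g in genes if g.end - g.start <= max_gene_len]
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in retained:
        by_chrom.setdefault(g.chrom, []).append(g)
    rows = []
    n_negative = n_empty = 0
    for category, chrom, s, e, exclude in gaps:
        if e <= s:
            n_negative += 1
            continue
        inside = [
            (max(g.start, s), min(g.end, e))
            for g in by_chrom.get(chrom, [])
            if g.gene_id not in exclude and g.start < e and g.end > s
        ]
        if not inside:
            n_empty += 1
            continue
        covered = iv.total_length(inside)
        rows.append(
            {"category": category, "chrom": chrom, "start": s, "end": e,
             "n_genes": len(inside), "coverage_pct": 100.0 * covered / (e - s)}
        )
    if n_negative or n_empty:
        logger.info(
            "intervening-gene coverage: excluded %d empty/negative gaps, "
            "%d gaps with no retained intervening gene", n_negative, n_empty,
        )
    return pd.DataFrame(rows)


def repeat_density(
    pair_records,
    repeats: list[RepeatFeature],
    genes: dict[str, GeneRecord],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Repeat-class composition of intergenic regions per interaction category.

    Per pair, the intergenic region is (upstream end, downstream start); the
    per-class repeat count is divided by the intergenic length to give a
    density. Pairs with no overlapping repeat, or zero/negative intergenic
    length, are skipped. Per category the class densities are summed and
    rescaled to percentages summing to 100.
    """
    by_chrom: dict[str, list[RepeatFeature]] = {}
    for r in repeats:
        by_chrom.setdefault(r.chrom, []).append(r)
    rows = []
    for rec in pair_records:
        a, b = genes[rec.gene_a], genes[rec.gene_b]
        up, down = (a, b) if a.start <= b.start else (b, a)
        s, e = up.end, down.start
        if e <= s:
            continue
        counts: dict[str, int] = {}
        for r in by_chrom.get(a.chrom, []):
            if r.start < e and r.end > s:
                counts[r.repeat_class] = counts.get(r.repeat_class, 0) + 1
        if not counts:
            continue
        for cls, n in counts.items():
            rows.append(
                {"gene_a": rec.gene_a, "gene_b": rec.gene_b,
                 "category": getattr(rec.category, "value", rec.category),
                 "repeat_class": cls, "density": n / (e - s)}
            )
    per_pair = pd.DataFrame(rows)
    if per_pair.empty:
        return per_pair, pd.DataFrame(columns=["category", "repeat_class", "percent"])
    sums = per_pair.groupby(["category", "repeat_class"])["density"].sum().reset_index()
    totals = sums.groupby("category")["density"].transform("sum")
    sums["percent"] = 100.0 * sums["density"] / totals
    return per_pair, sums[["category", "repeat_class", "percent"]]
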