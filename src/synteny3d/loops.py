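"""Chromatin-loop merging, gene association, cross-species conservation,
size scaling, chromosomal context, and context-specific overlap.

Loops arrive as BEDPE-like calls at one or two resolutions. 50 kb and
100 kb calls are merged with the coarser call dropped when both anchor
starts fall within 50 kb of a finer call's. A loop is gene-associated when
at least one gene overlaps each anchor; loops sharing an identical
associated-gene set are merged to the outermost coordinates. Conservation
between species requires one orthologous gene per anchor (anchors matchable
in either order). For each loop conserved in two or more species, the OLS
slope of loop size on genome size tests whether loops dilate with genome
expansion (one-sample Wilcoxon signed-rank on the per-loop slopes).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneRecord, OrthologTable
from .expression_metrics import bh_adjust

logger = logging.getLogger(__name__)

#: duplicate window for multi-resolution merging (bp, applied to anchor starts)
MERGE_WINDOW = 50_000


@dataclass
class LoopRecord:
    loop_id: str
    sample_id: str
    chrom: str
    anchor1: tuple[int, int]
    anchor2: tuple[int, int]
    source_resolution: int
    genes1: frozenset[str] = frozenset()
    genes2: frozenset[str] = frozenset()
    conserved_in: set[str] = field(default_factory=set)
    spans_diff_chroms_vs: dict[str, bool] = field(default_factory=dict)

    @property
    def size(self) -> int:
        """Distance from the start of the start bin to the end of the end bin."""
        return self.anchor2[1] - self.anchor1[0]

    @property
    def gene_key(self) -> tuple[str, ...]:
        """Canonical sorted union of associated genes; identity for merging
        and gene-set overlap."""
        return tuple(sorted(self.genes1 | self.genes2))

    @property
    def gene_associated(self) -> bool:
        return bool(self.genes1) and bool(self.genes2)


def _raw_to_records(calls: list[dict], sample_id: str, prefix: str) -> list[LoopRecord]:
    return [
        LoopRecord(
            loop_id=f"{sample_id}:{prefix}:{k}",
            sample_id=sample_id,
            chrom=c["chrom"],
            anchor1=tuple(c["a1"]),
            anchor2=tuple(c["a2"]),
            source_resolution=c["resolution"],
        )
        for k, c in enumerate(calls)
    ]


def merge_resolutions(
    calls_50kb: list[dict], calls_100kb: list[dict], sample_id: str = "sample"
) -> list[LoopRecord]:
    """Union of fine and coarse calls, dropping coarse duplicates.

    A 100 kb call is a duplicate of a 50 kb call when both of its anchor
    start positions lie within +-50 kb of the corresponding anchor starts of
    that call, on the same chromosome.
    """
    fine = _raw_to_records(calls_50kb, sample_id, "50kb")
    out = list(fine)
    for lp in _raw_to_records(calls_100kb, sample_id, "100kb"):
        dup = any(
            f.chrom == lp.chrom
            and abs(f.anchor1[0] - lp.anchor1[0]) <= MERGE_WINDOW
            and abs(f.anchor2[0] - lp.anchor2[0]) <= MERGE_WINDOW
            for f in fine
        )
        if not dup:
            out.append(lp)
    return out


def associate_genes(
    loops: list[LoopRecord],
    genes: list[GeneRecord],
    max_loop_size: int | None = None,
) -> list[LoopRecord]:
    """Attach anchor gene sets and merge loops with identical gene sets.

    genes1/genes2 are the genes overlapping anchor1/anchor2. Loops with an
    empty anchor gene set are retained, flagged gene-less, and exempt from
    gene-set merging. Gene-associated loops sharing an identical associated
    gene set are collapsed to the outermost start and end coordinates, and
    size recomputed. ``max_loop_size`` drops outsized loops (off by
    default; mimics manual outlier inspection).
    """
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    def overlap_set(chrom: str, iv: tuple[int, int]) -> frozenset[str]:
        return frozenset(
            g.gene_id
            for g in by_chrom.get(chrom, [])
            if g.start < iv[1] and g.end > iv[0]
        )

    annotated = []
    for lp in loops:
        lp.genes1 = overlap_set(lp.chrom, lp.anchor1)
        lp.genes2 = overlap_set(lp.chrom, lp.anchor2)
        annotated.append(lp)

    groups: dict[tuple[str, tuple[str, ...]], list[LoopRecord]] = {}
    out: list[LoopRecord] = []
    for lp in annotated:
        if not lp.gene_associated:
            out.append(lp)
            continue
        groups.setdefault((lp.chrom, lp.gene_key), []).append(lp)
    for (chrom, _key), members in groups.items():
        lead = members[0]
        if len(members) > 1:
            a1 = (min(m.anchor1[0] for m in members), max(m.anchor1[1] for m in members))
            a2 = (min(m.anchor2[0] for m in members), max(m.anchor2[1] for m in members))
            lead = LoopRecord(
                loop_id=lead.loop_id,
                sample_id=lead.sample_id,
                chrom=chrom,
                anchor1=a1,
                anchor2=a2,
                source_resolution=min(m.source_resolution for m in members),
                genes1=frozenset().union(*(m.genes1 for m in members)),
                genes2=frozenset().union(*(m.genes2 for m in members)),
            )
        out.append(lead)
    if max_loop_size is not None:
        n_before = len(out)
        out = [lp for lp in out if lp.size <= max_loop_size]
        if len(out) < n_before:
            logger.info("dropped %d loops above size cap %d", n_before - len(out), max_loop_size)
    return sorted(out, key=lambda lp: (lp.chrom, lp.anchor1[0], lp.anchor2[0]))


def _pair_conserved(
    L: LoopRecord, M: LoopRecord, ortho_ab: dict[str, str]
) -> bool:
    """One ortholog per anchor, anchors matchable in either order; a single
    gene's ortholog may not satisfy both anchors."""
    o1 = {ortho_ab[g] for g in L.genes1 if g in ortho_ab}
    o2 = {ortho_ab[g] for g in L.genes2 if g in ortho_ab}
    for m_first, m_second in ((M.genes1, M.genes2), (M.genes2, M.genes1)):
        hits1 = o1 & m_first
        hits2 = o2 & m_second
        if hits1 and hits2 and (len(hits1 | hits2) >= 2 or hits1 != hits2):
            return True
    return False


def conserved_loops(
    loops_by_species: dict[str, list[LoopRecord]],
    orthologs: OrthologTable,
    ref_species: str,
) -> tuple[dict[tuple[str, str], list[tuple[str, str]]], list[dict]]:
    """Pairwise loop conservation and multi-species conservation groups.

    Returns (edges, groups): ``edges`` maps each species pair to the list of
    (loop_id_A, loop_id_B) conserved matches; ``groups`` are connected
    components of the conservation graph, each a dict with the member loop
    ids, the species covered, and the mean loop size per species. Each
    loop's ``conserved_in`` is updated in place.
    """
    species = list(loops_by_species)
    ga_loops = {
        sp: [lp for lp in loops_by_species[sp] if lp.gene_associated] for sp in species
    }
    edges: dict[tuple[str, str], list[tuple[str, str]]] = {}
    adjacency: dict[str, set[str]] = {}
    by_id = {lp.loop_id: lp for sp in species for lp in ga_loops[sp]}
    for sp_a, sp_b in itertools.combinations(species, 2):
        ortho_ab = orthologs.mapping(sp_a, sp_b)
        matches = []
        for L in ga_loops[sp_a]:
            for M in ga_loops[sp_b]:
                if _pair_conserved(L, M, ortho_ab):
                    matches.append((L.loop_id, M.loop_id))
                    L.conserved_in.update({sp_a, sp_b})
                    M.conserved_in.update({sp_a, sp_b})
                    adjacency.setdefault(L.loop_id, set()).add(M.loop_id)
                    adjacency.setdefault(M.loop_id, set()).add(L.loop_id)
        edges[(sp_a, sp_b)] = matches

    sp_of = {lp.loop_id: sp for sp in species for lp in ga_loops[sp]}
    seen: set[str] = set()
    groups: list[dict] = []
    for lid in sorted(adjacency):
        if lid in seen:
            continue
        stack, comp = [lid], set()
        while stack:
            cur = stack.pop()
            if cur in comp:
                continue
            comp.add(cur)
            stack.extend(adjacency.get(cur, ()))
        seen |= comp
        members = sorted(comp)
        comp_species = sorted({sp_of[m] for m in members})
        sizes = {
            sp: float(np.mean([by_id[m].size for m in members if sp_of[m] == sp]))
            for sp in comp_species
        }
        groups.append({"loops": members, "species": comp_species, "sizes": sizes})
    return edges, groups


def scaling_slopes(
    groups: list[dict], genome_sizes: dict[str, int]
) -> tuple[list[float], float]:
    """Per-conserved-loop OLS slope of loop size on genome size, and the
    two-sided one-sample Wilcoxon signed-rank p for median slope != 0.

    Groups spanning a single species, or species with identical genome
    sizes, are skipped with a warning.
    """
    slopes = []
    for grp in groups:
        sps = [sp for sp in grp["species"] if sp in genome_sizes]
        if len(sps) < 2:
            continue
        g = np.array([genome_sizes[sp] for sp in sps], float)
        s = np.array([grp["sizes"][sp] for sp in sps], float)
        if np.ptp(g) == 0:
            warnings.warn("all member genome sizes equal; skipping loop group")
            continue
        slopes.append(0.0 if np.ptp(s) == 0 else float(np.polyfit(g, s, 1)[0]))
    if not slopes:
        return slopes, float("nan")
    nonzero = [s for s in slopes if s != 0]
    if not nonzero:
        return slopes, 1.0
    p = float(stats.wilcoxon(slopes, alternative="two-sided").pvalue)
    return slopes, p


def cross_chromosome_class(
    loop: LoopRecord,
    other_genes: dict[str, GeneRecord],
    ortho_map: dict[str, str],
) -> bool:
    """True when >= 2 of the loop's associated genes have orthologs on
    different chromosomes in the comparison species."""
    chroms = {
        other_genes[ortho_map[g]].chrom
        for g in (loop.genes1 | loop.genes2)
        if g in ortho_map and ortho_map[g] in other_genes
    }
    return len(chroms) >= 2


def size_vs_ancestral_spacing(
    loops: list[LoopRecord],
    other_genes: dict[str, GeneRecord],
    ortho_map: dict[str, str],
) -> float | None:
    """R^2 of loop size against mean orthologous intergenic spacing.

    For each gene-associated loop whose anchor gene pairs are co-chromosomal
    in the comparison species, the predictor is the mean (downstream start -
    upstream end) distance over orthologous anchor1 x anchor2 gene pairs.
    None when fewer than 3 informative loops exist.
    """
    xs, ys = [], []
    for lp in loops:
        if not lp.gene_associated:
            continue
        dists = []
        for ga in lp.genes1:
            for gb in lp.genes2:
                if ga == gb:
                    continue
                oa = ortho_map.get(ga)
                ob = ortho_map.get(gb)
                if oa is None or ob is None or oa not in other_genes or ob not in other_genes:
                    continue
                A, B = other_genes[oa], other_genes[ob]
                if A.chrom != B.chrom:
                    continue
                up, down = (A, B) if A.start <= B.start else (B, A)
                dists.append(down.start - up.end)
        if dists:
            xs.append(float(np.mean(dists)))
            ys.append(float(lp.size))
    if len(xs) < 3:
        return None
    ys_arr = np.asarray(ys)
    if np.ptp(ys_arr) == 0 or np.ptp(np.asarray(xs)) == 0:
        return 0.0
    res = stats.linregress(xs, ys)
    return float(res.rvalue**2)


def loop_identity_overlap(
    samples: dict[str, list[LoopRecord]], mode: str = "GENESET"
) -> pd.DataFrame:
    """Pairwise loop sharing across contexts (stages/tissues) with
    hypergeometric enrichment and depletion tests, BH-adjusted.

    GENESET identity: the canonical associated-gene set (gene-associated
    loops only). COORD identity: (chromosome, start bin of anchor1, start
    bin of anchor2); all samples must share one resolution. The universe is
    the union of identity keys over all supplied contexts.
    """
    def keys(loops: list[LoopRecord]) -> set:
        if mode == "GENESET":
            return {lp.gene_key for lp in loops if lp.gene_associated}
        if mode == "COORD":
            res = {lp.source_resolution for ctx in samples.values() for lp in ctx}
            if len(res) > 1:
                raise ValueError(f"COORD mode requires a single resolution, got {sorted(res)}")
            r = res.pop()
            return {(lp.chrom, lp.anchor1[0] // r, lp.anchor2[0] // r) for lp in loops}
        raise ValueError(f"unknown mode {mode!r}")

    key_sets = {ctx: keys(lps) for ctx, lps in samples.items()}
    universe: set = set().union(*key_sets.values()) if key_sets else set()
    N = len(universe)
    rows = []
    for ctx_a, ctx_b in itertools.combinations(sorted(key_sets), 2):
        a, b = key_sets[ctx_a], key_sets[ctx_b]
        k = len(a & b)
        n_a, n_b = len(a), len(b)
        hg = stats.hypergeom(N, n_a, n_b)
        rows.append(
            {
                "context_a": ctx_a, "context_b": ctx_b,
                "n_a": n_a, "n_b": n_b, "overlap": k, "universe": N,
                "p_enrich": float(hg.sf(k - 1)),
                "p_deplete": float(hg.cdf(k)),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["q_enrich"] = bh_adjust(df["p_enrich"].to_numpy())
        df["q_deplete"] = bh_adjust(df["p_deplete"].to_numpy())
    return df


def loops_to_frame(loops: list[LoopRecord]) -> pd.DataFrame:
    rows = []
    for lp in loops:
        rows.append(
            {
                "loop_id": lp.loop_id, "sample_id": lp.sample_id, "chrom": lp.chrom,
                "start1": lp.anchor1[0], "end1": lp.anchor1[1],
                "start2": lp.anchor2[0], "end2": lp.anchor2[1],
                "resolution": lp.source_resolution, "size": lp.size,
                "genes1": ",".join(sorted(lp.genes1)), "genes2": ",".join(sorted(lp.genes2)),
                "gene_associated": lp.gene_associated,
                "conserved_in": ",".join(sorted(lp.conserved_in)),
            }
        )
    return pd.DataFrame(rows)
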