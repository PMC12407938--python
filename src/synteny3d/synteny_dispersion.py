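"""Chromosome homology from orthologs, windowed homology multiplicity, and
dispersion of conserved (coding and non-coding) alignments.

Homologous chromosome pairs between two species are called from the shared
one-to-one ortholog count; a pair qualifies when the count reaches a
minimum AND exceeds several-fold the expectation under independent
placement, so fission/fusion products map one-to-many while stray
translocations do not create calls. Dispersion is the fraction of aligned
blocks (>= 100 bp) landing on non-homologous chromosomes; it rises with
translocation activity and is computed separately for all alignments and
for the conserved non-coding subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .io_formats import AlignmentBlock, GeneRecord, GenomeSpec, OrthologTable

MIN_ALIGNMENT_LEN = 100
MIN_CNE_LEN = 100
MIN_CNE_THIRD_SPECIES_LEN = 50
DEFAULT_MIN_SHARE = 5
DEFAULT_HOMOLOGY_ALPHA = 1e-4
DEFAULT_WINDOW_MIN_ORTHOLOGS = 3


@dataclass
class ChromHomologyMap:
    """Homologous chromosome pairs for one species pair."""

    species_a: str
    species_b: str
    pairs: set[tuple[str, str]] = field(default_factory=set)
    min_share: int = DEFAULT_MIN_SHARE

    def homologous(self, chrom_a: str, chrom_b: str) -> bool:
        return (chrom_a, chrom_b) in self.pairs

    def partners_of(self, chrom_a: str) -> set[str]:
        return {b for a, b in self.pairs if a == chrom_a}


def _chrom_of(genes: list[GeneRecord]) -> dict[str, str]:
    return {g.gene_id: g.chrom for g in genes}


def chromosome_homology(
    orthologs: OrthologTable,
    genes_a: list[GeneRecord],
    genes_b: list[GeneRecord],
    species_a: str,
    species_b: str,
    min_share: int = DEFAULT_MIN_SHARE,
    alpha: float = DEFAULT_HOMOLOGY_ALPHA,
) -> ChromHomologyMap:
    """Call homologous chromosome pairs from shared ortholog counts.

    (a, b) is homologous when shared orthologs >= min_share and the count
    is binomially significant against independent placement: under the
    null, each of chromosome a's mapped genes lands on b with probability
    col_b / total, so the call requires
    ``P(X >= count | X ~ Bin(row_a, col_b/total)) < alpha`` (default
    1e-4: ~0.1 expected false pairs even across a 30x30 chromosome grid). A pure fold
    threshold cannot work with few chromosomes (a perfect 1:1 match tops
    out at total/row_a times expectation), whereas the tail test is
    essentially never passed by a shuffled table yet astronomically
    significant for true homologs. One-to-many calls are allowed,
    capturing fissions and fusions.
    """
    mapping = orthologs.mapping(species_a, species_b)
    ca = _chrom_of(genes_a)
    cb = _chrom_of(genes_b)
    counts: dict[tuple[str, str], int] = {}
    for ga, gb in mapping.items():
        if ga in ca and gb in cb:
            key = (ca[ga], cb[gb])
            counts[key] = counts.get(key, 0) + 1
    total = sum(counts.values())
    row = {}
    col = {}
    for (a, b), n in counts.items():
        row[a] = row.get(a, 0) + n
        col[b] = col.get(b, 0) + n
    pairs = set()
    for (a, b), n in counts.items():
        if n < min_share or not total:
            continue
        p_null = col[b] / total
        p_tail = float(stats.binom.sf(n - 1, row[a], p_null))
        if p_tail < alpha:
            pairs.add((a, b))
    return ChromHomologyMap(species_a, species_b, pairs, min_share)


def window_homology_counts(
    genes_a: list[GeneRecord],
    genes_b: list[GeneRecord],
    orthologs: OrthologTable,
    species_a: str,
    species_b: str,
    genome_a: GenomeSpec,
    genome_b: GenomeSpec,
    window: int,
    min_orthologs: int = DEFAULT_WINDOW_MIN_ORTHOLOGS,
) -> pd.DataFrame:
    """Single- vs multi-mapping homology counts for tiled windows, both
    directions.

    Windows tile each chromosome (last window truncated). Window u in A
    maps to window v in B when >= min_orthologs of u's genes have their
    ortholog inside v. Each window is summarised by its number of targets
    (0, 1, or >=2); one-to-many mapping signals within-chromosome mixing or
    fission/fusion.
    """
    rows = []
    for direction, (ga, gb, sa, sb, gna) in {
        "a_to_b": (genes_a, genes_b, species_a, species_b, genome_a),
        "b_to_a": (genes_b, genes_a, species_b, species_a, genome_b),
    }.items():
        mapping = orthologs.mapping(sa, sb)
        pos_b = {g.gene_id: (g.chrom, g.start // window) for g in gb}
        win_targets: dict[tuple[str, int], dict[tuple[str, int], int]] = {}
        for g in ga:
            og = mapping.get(g.gene_id)
            if og is None or og not in pos_b:
                continue
            u = (g.chrom, g.start // window)
            tgt = pos_b[og]
            win_targets.setdefault(u, {})
            win_targets[u][tgt] = win_targets[u].get(tgt, 0) + 1
        n_zero = n_single = n_multi = 0
        for chrom, length in gna.chromosomes:
            for w in range(-(-length // window)):
                targets = win_targets.get((chrom, w), {})
                n = sum(1 for cnt in targets.values() if cnt >= min_orthologs)
                if n == 0:
                    n_zero += 1
                elif n == 1:
                    n_single += 1
                else:
                    n_multi += 1
        rows.append(
            {"direction": direction, "window": window, "n_unmapped": n_zero,
             "n_single": n_single, "n_multi": n_multi}
        )
    return pd.DataFrame(rows)


def classify_cne(
    blocks: list[AlignmentBlock],
    coding_intervals: list[GeneRecord],
) -> list[AlignmentBlock]:
    """Set is_coding flags: a block is coding iff it overlaps any coding
    interval by >= 1 bp (CDS features when available, else gene spans)."""
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in coding_intervals:
        by_chrom.setdefault(g.chrom, []).append(g)
    out = []
    for b in blocks:
        coding = any(
            g.start < b.ref_end and g.end > b.ref_start
            for g in by_chrom.get(b.ref_chrom, [])
        )
        out.append(
            AlignmentBlock(
                b.ref_chrom, b.ref_start, b.ref_end, b.other_species,
                b.other_chrom, b.other_start, b.other_end, coding,
            )
        )
    return out


def select_cnes(
    blocks: list[AlignmentBlock],
    min_len: int = MIN_CNE_LEN,
) -> list[AlignmentBlock]:
    """Non-coding blocks of at least ``min_len`` (default 100 bp; use 50 bp
    when testing orthology of an established CNE to a third species)."""
    return [b for b in blocks if not b.is_coding and b.length >= min_len]


def dispersion_counts(
    blocks: list[AlignmentBlock],
    homology: ChromHomologyMap,
    min_len: int = MIN_ALIGNMENT_LEN,
) -> dict:
    """Counts of aligned blocks on homologous vs non-homologous chromosomes.

    Blocks shorter than ``min_len`` are excluded; a chromosome absent from
    the homology map counts as non-homologous with a warning. Returns
    tallies and the dispersion rate (non-homologous / total) for all blocks
    and for the non-coding (CNE) subset.
    """
    kept = [b for b in blocks if b.length >= min_len]
    known_a = {a for a, _ in homology.pairs}
    warned = False

    def tally(subset):
        nonlocal warned
        n_hom = n_non = 0
        for b in subset:
            if b.ref_chrom not in known_a and not warned:
                warnings.warn(
                    f"chromosome {b.ref_chrom!r} absent from homology map; "
                    "counting as non-homologous"
                )
                warned = True
            if homology.homologous(b.ref_chrom, b.other_chrom):
                n_hom += 1
            else:
                n_non += 1
        total = n_hom + n_non
        return {
            "n_homologous": n_hom,
            "n_non_homologous": n_non,
            "n_total": total,
            "dispersion_rate": (n_non / total) if total else float("nan"),
        }

    return {
        "all": tally(kept),
        "cne": tally([b for b in kept if not b.is_coding]),
    }
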