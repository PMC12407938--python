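"""Insulation scores and gene-pair boundary/domain classing.

The score at bin *i* is the mean contact weight in the w x w square of
matrix entries linking the w bins upstream of *i* to the w bins downstream
(the diagonal itself is excluded by construction: a < i < b), log2-normalised
by the chromosome mean. Local minima mark domain boundaries, so boundaries
are negative and compartment interiors positive under this convention.
Default window: 350 kb, chosen to resolve loop- and domain-scale structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .io_formats import GeneRecord, GenomeSpec, SignalInterval, SparseContacts

DEFAULT_WINDOW = 350_000
DEFAULT_CLASS_THRESHOLD = 0.2


@dataclass
class InsulationTrack:
    sample_id: str
    resolution: int
    window: int
    scores: dict[str, np.ndarray] = field(default_factory=dict)  # chrom -> per-bin, NaN missing

    def to_bedgraph(self, genome: GenomeSpec | None = None) -> list[SignalInterval]:
        out = []
        for chrom, vec in self.scores.items():
            limit = genome.chrom_length[chrom] if genome else None
            for i, v in enumerate(vec):
                if not np.isfinite(v):
                    continue
                start = i * self.resolution
                end = start + self.resolution
                if limit is not None:
                    end = min(end, limit)
                out.append(SignalInterval(chrom, start, end, float(v)))
        return out


class InsulationClass(str, Enum):
    WITHIN_DOMAINS = "WITHIN_DOMAINS"
    BOUNDARY_ALL = "BOUNDARY_ALL"
    BOUNDARY_OCTOPUS_ONLY = "BOUNDARY_OCTOPUS_ONLY"
    BOUNDARY_DECAPODS_ONLY = "BOUNDARY_DECAPODS_ONLY"
    OTHER = "OTHER"
    NA = "NA"


def insulation_score(
    contacts: SparseContacts, genome: GenomeSpec, window: int = DEFAULT_WINDOW
) -> InsulationTrack:
    """Sliding-square insulation with chromosome-mean log2 normalisation.

    raw(i) = mean of M[a, b] over a in [i-w, i-1], b in [i+1, i+w], absent
    sparse entries counting as true zeros; bins whose square leaves the
    chromosome are missing; score(i) = log2(raw(i) / mean of raw over
    non-missing bins). An all-zero chromosome is entirely missing.
    """
    w = window // contacts.resolution
    if w < 1:
        raise ValueError(f"window {window} smaller than one bin at resolution {contacts.resolution}")
    track = InsulationTrack(contacts.sample_id, contacts.resolution, window)
    for chrom, _ in genome.chromosomes:
        n = genome.n_bins(chrom, contacts.resolution)
        m = contacts.matrix(chrom, n)
        raw = np.full(n, np.nan)
        for i in range(w, n - w):
            raw[i] = m[i - w : i, i + 1 : i + w + 1].mean()
        valid = np.isfinite(raw)
        mean_raw = np.nanmean(raw) if valid.any() else np.nan
        scores = np.full(n, np.nan)
        if valid.any() and mean_raw > 0:
            with np.errstate(divide="ignore"):
                scores[valid] = np.log2(raw[valid] / mean_raw)
        track.scores[chrom] = scores
    return track


def pair_mean_insulation(
    track: InsulationTrack, gene_a: GeneRecord, gene_b: GeneRecord
) -> float:
    """Mean score over the bins spanned between a gene pair.

    Span: from the bin containing the upstream gene's last base through the
    bin containing the downstream gene's start, inclusive. Missing bins are
    dropped; an all-missing span returns NaN.
    """
    if gene_a.chrom != gene_b.chrom:
        raise ValueError("pair_mean_insulation requires genes on one chromosome")
    up, down = (gene_a, gene_b) if gene_a.start <= gene_b.start else (gene_b, gene_a)
    res = track.resolution
    b1 = (up.end - 1) // res
    b2 = down.start // res
    lo, hi = min(b1, b2), max(b1, b2)
    vec = track.scores[gene_a.chrom][lo : hi + 1]
    vec = vec[np.isfinite(vec)]
    return float(vec.mean()) if vec.size else math.nan


def classify_insulation(
    means: dict[str, float],
    decapods: tuple[str, str],
    octopus: str,
    threshold: float = DEFAULT_CLASS_THRESHOLD,
) -> InsulationClass:
    """Cross-species domain/boundary class from per-species pair means.

    >= t in all species: within continuous interaction domains; <= -t in
    all: boundary in all; the two mixed patterns are lineage-specific
    boundaries; anything else (including the (-t, t) dead zone) is OTHER.
    Any missing mean gives NA.
    """
    vals = [means.get(sp, math.nan) for sp in (*decapods, octopus)]
    if any(math.isnan(v) for v in vals):
        return InsulationClass.NA
    d1, d2, oc = vals
    t = threshold
    if d1 >= t and d2 >= t and oc >= t:
        return InsulationClass.WITHIN_DOMAINS
    if d1 <= -t and d2 <= -t and oc <= -t:
        return InsulationClass.BOUNDARY_ALL
    if d1 >= t and d2 >= t and oc <= -t:
        return InsulationClass.BOUNDARY_OCTOPUS_ONLY
    if d1 <= -t and d2 <= -t and oc >= t:
        return InsulationClass.BOUNDARY_DECAPODS_ONLY
    return InsulationClass.OTHER


def annotate_pairs_with_insulation(
    records,
    tracks: dict[str, InsulationTrack],
    genes_by_species: dict[str, dict[str, GeneRecord]],
    orthologs,
    ref_species: str,
    decapods: tuple[str, str],
    octopus: str,
    threshold: float = DEFAULT_CLASS_THRESHOLD,
) -> None:
    """Fill insulation_means and insulation_class on GenePairRecords in place."""
    ortho = {
        sp: orthologs.mapping(ref_species, sp)
        for sp in tracks
        if sp != ref_species
    }
    for rec in records:
        means = {}
        for sp, track in tracks.items():
            if sp == ref_species:
                a = genes_by_species[sp][rec.gene_a]
                b = genes_by_species[sp][rec.gene_b]
            else:
                a = genes_by_species[sp][ortho[sp][rec.gene_a]]
                b = genes_by_species[sp][ortho[sp][rec.gene_b]]
            means[sp] = pair_mean_insulation(track, a, b)
        rec.insulation_means = means
        rec.insulation_class = classify_insulation(means, decapods, octopus, threshold).value
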