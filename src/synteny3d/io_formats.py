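"""Readers, writers and domain containers for every on-disk format the
pipeline touches.

Every interval is converted to 0-based half-open coordinates on read:
GFF3 (1-based inclusive) has 1 subtracted from starts, BED-family formats
pass through unchanged. Contact dumps are triplet text
(``chrom  pos_i  pos_j  value``) with positions equal to bin start
coordinates, as produced by concatenating per-chromosome sparse dumps of a
KR-balanced matrix.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file does not parse as the expected format."""


class ValidationError(ValueError):
    """A parsed record violates a documented invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome complement of one assembly.

    ``chromosomes`` is an ordered list of (name, length-in-bp); genome size is
    their sum (used, e.g., as the predictor in loop-size scaling).
    """

    species_id: str
    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self):
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate chromosome names in {self.species_id}")
        if any(ln <= 0 for _, ln in self.chromosomes):
            raise ValidationError("chromosome lengths must be positive")

    @property
    def genome_size(self) -> int:
        return sum(ln for _, ln in self.chromosomes)

    @property
    def chrom_length(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def n_bins(self, chrom: str, resolution: int) -> int:
        return -(-self.chrom_length[chrom] // resolution)


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )


@dataclass(frozen=True)
class AlignmentBlock:
    """A conserved aligned segment between the reference and another species.

    ``is_coding`` is False for putative conserved non-coding elements (CNEs).
    """

    ref_chrom: str
    ref_start: int
    ref_end: int
    other_species: str
    other_chrom: str
    other_start: int
    other_end: int
    is_coding: bool = False

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start


@dataclass(frozen=True)
class RepeatFeature:
    chrom: str
    start: int
    end: int
    repeat_class: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValidationError("repeat with start >= end")


@dataclass(frozen=True)
class SignalInterval:
    chrom: str
    start: int
    end: int
    value: float

    def __post_init__(self):
        if self.start >= self.end:
            raise ValidationError("signal interval with start >= end")


class OrthologTable:
    """Strict one-to-one ortholog map across species.

    Backed by a DataFrame indexed by the reference species' gene id with one
    column per other species. No gene may appear in two rows of the same
    column.
    """

    def __init__(self, table: pd.DataFrame, ref_species: str):
        self.ref_species = ref_species
        self.table = table.copy()
        for col in self.table.columns:
            dup = self.table[col].dropna().duplicated()
            if dup.any():
                raise ValidationError(
                    f"ortholog table not one-to-one: duplicated {col} gene "
                    f"{self.table[col][dup].iloc[0]!r}"
                )
        if self.table.index.duplicated().any():
            raise ValidationError("duplicated reference gene in ortholog table")

    @property
    def species(self) -> list[str]:
        return [self.ref_species] + list(self.table.columns)

    def mapping(self, species_a: str, species_b: str) -> dict[str, str]:
        """One-to-one gene-id map from species_a to species_b (rows where
        both are present)."""
        if species_a == species_b:
            raise ValueError("mapping between a species and itself")
        a = (
            pd.Series(self.table.index, index=self.table.index)
            if species_a == self.ref_species
            else self.table[species_a]
        )
        b = (
            pd.Series(self.table.index, index=self.table.index)
            if species_b == self.ref_species
            else self.table[species_b]
        )
        mask = a.notna() & b.notna()
        return dict(zip(a[mask], b[mask]))

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class SparseContacts:
    """Per-sample intrachromosomal KR-balanced contacts at one resolution.

    ``entries`` has columns chrom, bin1, bin2, value with bin1 <= bin2
    (canonical upper-triangle order) and no duplicate (chrom, bin1, bin2).
    """

    sample_id: str
    resolution: int
    entries: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["chrom", "bin1", "bin2", "value"]))

    def matrix(self, chrom: str, n_bins: int) -> np.ndarray:
        """Dense symmetric matrix for one chromosome (absent entries are 0)."""
        m = np.zeros((n_bins, n_bins))
        sub = self.entries[self.entries["chrom"] == chrom]
        i = sub["bin1"].to_numpy(int)
        j = sub["bin2"].to_numpy(int)
        v = sub["value"].to_numpy(float)
        m[i, j] = v
        m[j, i] = v
        return m

    def value_lookup(self) -> dict[tuple[str, int, int], float]:
        return {
            (c, int(i), int(j)): float(v)
            for c, i, j, v in self.entries.itertuples(index=False)
        }


# ---------------------------------------------------------------------------
# gene annotations
# ---------------------------------------------------------------------------

_GFF_ID_RE = re.compile(r"(?:^|;)\s*ID=([^;]+)")


def read_genes(path: str | Path, feature_filter: str = "gene") -> list[GeneRecord]:
    """Read gene records from GFF3 or BED.

    GFF3 rows are filtered to ``feature_filter`` in column 3 and converted
    from 1-based inclusive to 0-based half-open; BED passes through. Records
    are returned sorted by (chrom, start); duplicate gene ids raise.
    """
    path = Path(path)
    is_gff = path.suffix.lower() in {".gff", ".gff3", ".gtf"}
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if is_gff:
                    if len(fields) < 9:
                        raise FormatError("expected 9 GFF3 columns")
                    if fields[2] != feature_filter:
                        continue
                    start = int(fields[3]) - 1
                    end = int(fields[4])
                    m = _GFF_ID_RE.search(fields[8])
                    if not m:
                        raise FormatError("no ID= attribute")
                    gid = m.group(1)
                    strand = fields[6] if fields[6] in "+-" else "."
                    rec = GeneRecord(gid, fields[0], start, end, strand)
                else:
                    if len(fields) < 4:
                        raise FormatError("expected >= 4 BED columns")
                    strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
                    rec = GeneRecord(fields[3], fields[0], int(fields[1]), int(fields[2]), strand)
            except ValidationError:
                raise
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            genes.append(rec)
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        seen, dups = set(), set()
        for i in ids:
            (dups if i in seen else seen).add(i)
        raise ValidationError(f"duplicate gene ids: {sorted(dups)[:5]}")
    return sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))


def write_genes_bed(genes: list[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t.\t{g.strand}\n")


# ---------------------------------------------------------------------------
# sparse contacts
# ---------------------------------------------------------------------------


def read_sparse_contacts(
    path: str | Path,
    resolution: int,
    genome: GenomeSpec | None = None,
    sample_id: str | None = None,
) -> SparseContacts:
    """Read a concatenated triplet dump into canonical bin-index form.

    Rows are ``chrom pos_i pos_j value`` (an optional second chromosome
    column, ``chrom_i pos_i chrom_j pos_j value``, is accepted but must match
    chrom_i). Positions must be multiples of the resolution; rows are swapped
    so bin1 <= bin2; rows with non-finite values (KR balancing artefacts) are
    dropped with a counted warning.
    """
    path = Path(path)
    rows = []
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            try:
                if len(f) == 4:
                    chrom, pi, pj, val = f[0], int(f[1]), int(f[2]), float(f[3])
                elif len(f) == 5:
                    chrom, pi, chrom_j, pj, val = f[0], int(f[1]), f[2], int(f[3]), float(f[4])
                    if chrom_j != chrom:
                        raise FormatError(
                            f"interchromosomal row ({chrom} vs {chrom_j}); only "
                            "intrachromosomal contacts are supported"
                        )
                else:
                    raise FormatError(f"expected 4 or 5 columns, got {len(f)}")
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if not np.isfinite(val):
                n_dropped += 1
                continue
            if val < 0:
                raise ValidationError(f"{path}:{lineno}: negative contact value {val}")
            if pi % resolution or pj % resolution:
                raise FormatError(
                    f"{path}:{lineno}: position not a multiple of resolution {resolution}"
                )
            bi, bj = pi // resolution, pj // resolution
            if bi > bj:
                bi, bj = bj, bi
            if genome is not None:
                if chrom not in genome.chrom_length:
                    raise ValidationError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                if bj * resolution >= genome.chrom_length[chrom]:
                    raise ValidationError(
                        f"{path}:{lineno}: bin {bj} outside chromosome {chrom}"
                    )
            rows.append((chrom, bi, bj, val))
    if n_dropped:
        warnings.warn(f"{path}: dropped {n_dropped} rows with non-finite values")
    df = pd.DataFrame(rows, columns=["chrom", "bin1", "bin2", "value"])
    if df.duplicated(["chrom", "bin1", "bin2"]).any():
        raise ValidationError(f"{path}: duplicate (chrom, bin, bin) entries")
    return SparseContacts(sample_id or path.stem, resolution, df)


def write_sparse_contacts(contacts: SparseContacts, path: str | Path) -> None:
    res = contacts.resolution
    with open(path, "w") as fh:
        for chrom, b1, b2, v in contacts.entries.itertuples(index=False):
            fh.write(f"{chrom}\t{b1 * res}\t{b2 * res}\t{v:.10g}\n")


# ---------------------------------------------------------------------------
# loop calls (BEDPE)
# ---------------------------------------------------------------------------


def read_loops(path: str | Path, resolution: int) -> list[dict]:
    """Read BEDPE-like loop calls.

    Returns dicts with chrom, a1/a2 anchor intervals (anchor1 left of
    anchor2) and fdr (None if absent). Interchromosomal rows are skipped with
    a warning.
    """
    out = []
    n_skip = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise FormatError(f"{path}:{lineno}: expected >= 6 BEDPE columns")
            c1, s1, e1, c2, s2, e2 = f[0], int(f[1]), int(f[2]), f[3], int(f[4]), int(f[5])
            if c1 != c2:
                n_skip += 1
                continue
            fdr = float(f[6]) if len(f) > 6 and f[6] not in (".", "") else None
            if s1 > s2:
                (s1, e1), (s2, e2) = (s2, e2), (s1, e1)
            out.append(
                {"chrom": c1, "a1": (s1, e1), "a2": (s2, e2),
                 "fdr": fdr, "resolution": resolution}
            )
    if n_skip:
        warnings.warn(f"{path}: skipped {n_skip} interchromosomal loop calls")
    return out


def write_loops_bedpe(loops, path: str | Path) -> None:
    with open(path, "w") as fh:
        for lp in loops:
            c = lp["chrom"] if isinstance(lp, dict) else lp.chrom
            a1 = lp["a1"] if isinstance(lp, dict) else lp.anchor1
            a2 = lp["a2"] if isinstance(lp, dict) else lp.anchor2
            fh.write(f"{c}\t{a1[0]}\t{a1[1]}\t{c}\t{a2[0]}\t{a2[1]}\n")


# ---------------------------------------------------------------------------
# tables: orthologs, expression, genome spec
# ---------------------------------------------------------------------------


def read_orthologs(path: str | Path, ref_species: str) -> OrthologTable:
    """TSV with header: first column reference gene id, one column per other
    species."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df = df.set_index(df.columns[0])
    return OrthologTable(df, ref_species)


def write_orthologs(table: OrthologTable, path: str | Path) -> None:
    out = table.table.copy()
    out.index.name = table.ref_species
    out.to_csv(path, sep="\t")


def read_expression(path: str | Path) -> pd.DataFrame:
    """Genes x samples TPM matrix; first column = gene id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValidationError("negative TPM values in expression matrix")
    if df.index.duplicated().any():
        raise ValidationError("duplicate gene ids in expression matrix")
    return df


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    out = matrix.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.6g")


def read_genome_spec(path: str | Path, species_id: str | None = None) -> GenomeSpec:
    """Two-column TSV chrom/length (chrom-sizes file) with header."""
    df = pd.read_csv(path, sep="\t")
    sid = species_id or Path(path).stem
    return GenomeSpec(sid, tuple(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(int))))


def write_genome_spec(genome: GenomeSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tlength\n")
        for name, ln in genome.chromosomes:
            fh.write(f"{name}\t{ln}\n")


# ---------------------------------------------------------------------------
# alignment blocks, repeats, signal
# ---------------------------------------------------------------------------

_ALN_COLS = ["ref_chrom", "ref_start", "ref_end", "other_species",
             "other_chrom", "other_start", "other_end", "is_coding"]


def read_alignment_blocks(path: str | Path) -> list[AlignmentBlock]:
    """BED-pair TSV with header columns matching AlignmentBlock fields."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_ALN_COLS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return [
        AlignmentBlock(
            r.ref_chrom, int(r.ref_start), int(r.ref_end), r.other_species,
            r.other_chrom, int(r.other_start), int(r.other_end), bool(r.is_coding),
        )
        for r in df.itertuples(index=False)
    ]


def write_alignment_blocks(blocks: list[AlignmentBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_ALN_COLS) + "\n")
        for b in blocks:
            fh.write(
                f"{b.ref_chrom}\t{b.ref_start}\t{b.ref_end}\t{b.other_species}\t"
                f"{b.other_chrom}\t{b.other_start}\t{b.other_end}\t{b.is_coding}\n"
            )


def read_repeats(path: str | Path) -> list[RepeatFeature]:
    """BED4: chrom start end repeat_class."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 BED columns")
            out.append(RepeatFeature(f[0], int(f[1]), int(f[2]), f[3]))
    return out


def write_repeats(repeats: list[RepeatFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in repeats:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.repeat_class}\n")


def read_bedgraph(path: str | Path) -> list[SignalInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            out.append(SignalInterval(f[0], int(f[1]), int(f[2]), float(f[3])))
    return out


def write_bedgraph(track: list[SignalInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in track:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.value:.10g}\n")
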