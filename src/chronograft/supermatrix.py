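"""Sequence filtering rules and supermatrix construction/statistics.

Implements the vetting steps applied to per-gene sequence pulls before
concatenation into a sites-by-taxa DNA supermatrix:

* keep only the unique longest sequence per taxon, and only if its
  (ungapped) length is strictly greater than 200 bp;
* screen coding alignments for internal stop codons under the appropriate
  genetic code (standard for nuclear exons, vertebrate mitochondrial for
  mtDNA fragments);
* concatenate gene alignments into a partitioned supermatrix, padding
  missing taxon-gene cells with gaps;
* compute matrix statistics: percent completeness (ungapped cells over all
  cells), GC content of ungapped ACGT cells, mean coverage (ungapped cells
  per column), and mean pairwise site identity.

A reference table of the 31 mammalian gene fragments used by the intended
supermatrix design (gene, region, aligned sites) ships with the package as
``data/gene_fragments.csv``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "GeneAlignment",
    "Supermatrix",
    "MatrixStats",
    "AlignmentError",
    "select_longest_per_taxon",
    "detect_internal_stops",
    "concatenate",
    "matrix_stats",
    "gene_fragment_table",
]

GAP_CHARS = {"-", "?"}
_AMBIG = set("RYSWKMBDHVN")
_GENETIC_CODE_IDS = {"standard": 1, "vertebrate-mito": 2}


class AlignmentError(ValueError):
    pass


def ungapped_length(seq: str) -> int:
    return sum(1 for c in seq if c not in GAP_CHARS)


@dataclass
class GeneAlignment:
    """One gene's aligned sequences (taxon label -> gapped nucleotide string).

    ``frame`` is the reading-frame offset (0, 1, 2) or ``"noncoding"``;
    ``code`` names the genetic code (``standard`` or ``vertebrate-mito``).
    """

    name: str
    seqs: dict[str, str]
    frame: int | str = "noncoding"
    code: str = "standard"

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.seqs.values()}
        if len(lengths) > 1:
            raise AlignmentError(
                f"{self.name}: unequal sequence lengths {sorted(lengths)}"
            )
        if self.code not in _GENETIC_CODE_IDS:
            raise AlignmentError(f"unknown genetic code {self.code!r}")
        self.seqs = {t: s.upper() for t, s in self.seqs.items()}

    @property
    def n_sites(self) -> int:
        return len(next(iter(self.seqs.values()))) if self.seqs else 0

    @property
    def taxa(self) -> list[str]:
        return list(self.seqs)

    @classmethod
    def read_fasta(cls, path, name: str, frame="noncoding", code="standard"):
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        return cls(name, seqs, frame, code)

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for taxon, seq in self.seqs.items():
                fh.write(f">{taxon}\n{seq}\n")


def select_longest_per_taxon(
    records: list[tuple[str, str]], min_length: int = 200
) -> list[tuple[str, str]]:
    """Keep the single longest sequence per taxon id, discarding any whose
    ungapped length is not strictly greater than ``min_length``.

    Ties in length are broken by input order (first record wins), so the
    operation is deterministic and idempotent.
    """
    best: dict[str, tuple[int, str]] = {}
    order: list[str] = []
    for taxon, seq in records:
        n = ungapped_length(seq)
        if taxon not in best:
            best[taxon] = (n, seq)
            order.append(taxon)
        elif n > best[taxon][0]:
            best[taxon] = (n, seq)
    return [
        (taxon, best[taxon][1]) for taxon in order if best[taxon][0] > min_length
    ]


def _stop_codons(code: str) -> frozenset[str]:
    table = CodonTable.unambiguous_dna_by_id[_GENETIC_CODE_IDS[code]]
    return frozenset(table.stop_codons)


def detect_internal_stops(aln: GeneAlignment) -> dict[str, bool]:
    """Flag sequences containing an in-frame stop codon before the final codon.

    Codons are read in alignment coordinates from the frame offset; codons
    containing gaps or ambiguity characters are skipped. A stop in the last
    complete codon of a sequence (a legitimate terminal stop) is not flagged.
    """
    if aln.frame == "noncoding":
        raise AlignmentError(f"{aln.name}: stop-codon screen needs a reading frame")
    offset = int(aln.frame)
    stops = _stop_codons(aln.code)
    flags: dict[str, bool] = {}
    for taxon, seq in aln.seqs.items():
        codons = [
            seq[i : i + 3]
            for i in range(offset, len(seq) - 2, 3)
            if all(c in "ACGT" for c in seq[i : i + 3])
        ]
        flags[taxon] = any(c in stops for c in codons[:-1])
    return flags


@dataclass
class Supermatrix:
    """Concatenated alignment with ordered, contiguous gene partitions.

    ``partitions`` maps gene name -> (start, end), 1-based inclusive column
    spans that tile the matrix without overlap. Taxa absent from a gene are
    all-gap across that gene's span.
    """

    seqs: dict[str, str]
    partitions: dict[str, tuple[int, int]]
    gene_meta: dict[str, dict] = field(default_factory=dict)

    @property
    def n_taxa(self) -> int:
        return len(self.seqs)

    @property
    def n_sites(self) -> int:
        return len(next(iter(self.seqs.values()))) if self.seqs else 0

    def gene_alignment(self, gene: str) -> GeneAlignment:
        """Slice one gene's span back out (taxa all-gap in it are dropped)."""
        start, end = self.partitions[gene]
        meta = self.gene_meta.get(gene, {})
        seqs = {}
        for taxon, row in self.seqs.items():
            piece = row[start - 1 : end]
            if ungapped_length(piece) > 0:
                seqs[taxon] = piece
        return GeneAlignment(
            gene, seqs, meta.get("frame", "noncoding"), meta.get("code", "standard")
        )

    # -- writers ---------------------------------------------------------

    def write_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.n_taxa} {self.n_sites}\n")
            for taxon, seq in self.seqs.items():
                fh.write(f"{taxon.replace(' ', '_')}  {seq}\n")

    def write_nexus(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#NEXUS\nbegin data;\n")
            fh.write(f"  dimensions ntax={self.n_taxa} nchar={self.n_sites};\n")
            fh.write('  format datatype=dna gap=- missing=?;\n  matrix\n')
            for taxon, seq in self.seqs.items():
                fh.write(f"    {taxon.replace(' ', '_')}  {seq}\n")
            fh.write("  ;\nend;\n")

    def write_raxml_partitions(self, path) -> None:
        with open(path, "w") as fh:
            for gene, (start, end) in self.partitions.items():
                fh.write(f"DNA, {gene} = {start}-{end}\n")


def concatenate(alns: list[GeneAlignment], taxa=None) -> Supermatrix:
    """Concatenate gene alignments into a supermatrix.

    ``taxa`` fixes the taxon universe (default: union over genes in first-seen
    order). Cells for taxa missing from a gene are filled with ``-``.
    """
    names = [a.name for a in alns]
    if len(set(names)) != len(names):
        raise AlignmentError("duplicate gene names in concatenation")
    if taxa is None:
        taxa = []
        seen = set()
        for aln in alns:
            for t in aln.taxa:
                if t not in seen:
                    seen.add(t)
                    taxa.append(t)
    taxa = list(taxa)

    partitions: dict[str, tuple[int, int]] = {}
    meta: dict[str, dict] = {}
    pieces: dict[str, list[str]] = {t: [] for t in taxa}
    col = 0
    for aln in alns:
        n = aln.n_sites
        partitions[aln.name] = (col + 1, col + n)
        meta[aln.name] = {"frame": aln.frame, "code": aln.code}
        blank = "-" * n
        for t in taxa:
            pieces[t].append(aln.seqs.get(t, blank))
        col += n
    seqs = {t: "".join(parts) for t, parts in pieces.items()}
    return Supermatrix(seqs, partitions, meta)


@dataclass
class MatrixStats:
    completeness_pct: float
    gc_pct: float
    mean_coverage: float
    identical_sites_pct: float


def matrix_stats(m: Supermatrix, max_pairs: int | None = None) -> MatrixStats:
    """Completeness, GC, mean coverage, and mean pairwise site identity.

    Completeness counts ambiguity codes as ungapped; the GC denominator is
    restricted to unambiguous A/C/G/T cells. Pairwise identity is averaged
    over taxon pairs with at least one ungapped overlapping column (pairs
    with zero overlap are skipped); ``max_pairs`` optionally caps the number
    of pairs scanned for large matrices.
    """
    if m.n_taxa == 0 or m.n_sites == 0:
        raise AlignmentError("empty supermatrix")
    arr = np.frombuffer(
        "".join(m.seqs.values()).encode(), dtype="S1"
    ).reshape(m.n_taxa, m.n_sites)
    ungapped = ~np.isin(arr, [b"-", b"?"])
    n_cells = arr.size
    n_ungapped = int(ungapped.sum())
    completeness = 100.0 * n_ungapped / n_cells
    mean_cov = n_ungapped / m.n_sites

    acgt = np.isin(arr, [b"A", b"C", b"G", b"T"])
    gc = np.isin(arr, [b"G", b"C"])
    n_acgt = int(acgt.sum())
    gc_pct = 100.0 * int(gc.sum()) / n_acgt if n_acgt else float("nan")

    idents: list[float] = []
    pairs = [(i, j) for i in range(m.n_taxa) for j in range(i + 1, m.n_taxa)]
    if max_pairs is not None:
        pairs = pairs[:max_pairs]
    for i, j in pairs:
        overlap = ungapped[i] & ungapped[j]
        n_overlap = int(overlap.sum())
        if n_overlap == 0:
            continue
        same = int((arr[i][overlap] == arr[j][overlap]).sum())
        idents.append(100.0 * same / n_overlap)
    ident_pct = float(np.mean(idents)) if idents else float("nan")
    return MatrixStats(completeness, gc_pct, mean_cov, ident_pct)


def gene_fragment_table() -> pd.DataFrame:
    """The 31 mammalian gene fragments (gene, region, aligned sites)."""
    with importlib.resources.files("chronograft.data").joinpath(
        "gene_fragments.csv"
    ).open() as fh:
        return pd.read_csv(fh)
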