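"""QTL interval construction, SNP location classes, and gene overlap.

A QTL is the +/-100 kb window around a run of significant SNPs: within a
chromosome, consecutive sorted SNPs whose inter-SNP gap is at most the flank
join one cluster (single linkage on positions, *not* interval merging —
which is why two QTLs in the same report may overlap), and each cluster's
interval is ``[min(members) - flank, max(members) + flank]``, floored at
base 1.  All coordinates are 1-based inclusive; BED export converts to
0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QTL",
    "GeneModels",
    "cluster_snps_to_qtls",
    "classify_snp_location",
    "overlap_genes",
    "qtls_to_frame",
    "qtls_to_bed",
]


@dataclass
class QTL:
    """One clustered QTL interval (1-based inclusive bounds)."""

    chrom: str
    start: int
    end: int
    members: list  # sorted member SNP positions
    genes: list = field(default_factory=list)

    def __post_init__(self):
        self.members = sorted(int(p) for p in self.members)
        if not self.members:
            raise ValueError("a QTL needs at least one member SNP")
        if self.start > self.members[0] or self.end < self.members[-1]:
            raise ValueError("interval must contain all member SNPs")


def cluster_snps_to_qtls(significant_snps, flank: int = 100_000) -> list:
    """Cluster significant SNPs into QTL intervals by gap-based single linkage.

    Parameters
    ----------
    significant_snps : DataFrame with ``chrom``/``pos`` columns, or an
        iterable of ``(chrom, pos)`` pairs.  Input order is irrelevant.
    flank : int
        Flank size in bp; also the largest inter-SNP gap joining a cluster.

    Returns
    -------
    list of :class:`QTL`, ordered by chromosome (input appearance order)
    and start position.
    """
    if isinstance(significant_snps, pd.DataFrame):
        pairs = list(zip(significant_snps["chrom"], significant_snps["pos"]))
    else:
        pairs = [(c, p) for c, p in significant_snps]
    by_chrom: dict = {}
    for chrom, pos in pairs:
        by_chrom.setdefault(chrom, []).append(int(pos))

    qtls = []
    for chrom, positions in by_chrom.items():
        positions = sorted(positions)
        cluster = [positions[0]]
        for pos in positions[1:]:
            if pos - cluster[-1] <= flank:
                cluster.append(pos)
            else:
                qtls.append(_make_qtl(chrom, cluster, flank))
                cluster = [pos]
        qtls.append(_make_qtl(chrom, cluster, flank))
    return qtls


def _make_qtl(chrom, members, flank):
    return QTL(
        chrom=chrom,
        start=max(1, members[0] - flank),
        end=members[-1] + flank,
        members=members,
    )


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


class GeneModels:
    """Gene/exon/UTR intervals used for SNP classification and QTL overlap.

    All tables use 1-based inclusive coordinates and carry at least
    ``chrom``, ``start``, ``end``; ``genes`` additionally has ``gene_id``,
    ``name`` and ``biotype``, and the feature tables have ``gene_id``.
    """

    def __init__(self, genes: pd.DataFrame, exons=None, utr5=None, utr3=None):
        empty = pd.DataFrame(columns=["chrom", "start", "end", "gene_id"])
        self.genes = genes.reset_index(drop=True)
        self.exons = empty if exons is None or len(exons) == 0 else exons.reset_index(drop=True)
        self.utr5 = empty if utr5 is None or len(utr5) == 0 else utr5.reset_index(drop=True)
        self.utr3 = empty if utr3 is None or len(utr3) == 0 else utr3.reset_index(drop=True)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_gff3(cls, path) -> "GeneModels":
        """Load gene models from a GFF3 file (gene/exon/UTR features).

        Structurally malformed lines (wrong column count) are skipped with a
        warning; parent resolution follows the GFF3 ``Parent`` chain up to
        the enclosing gene.
        """
        import gffutils

        with open(path) as fh:
            lines = fh.read().splitlines()
        kept = []
        for ln, line in enumerate(lines, 1):
            if not line.strip() or line.startswith("#"):
                kept.append(line)
                continue
            if len(line.split("\t")) != 9:
                warnings.warn(f"{path}:{ln}: malformed GFF3 record skipped", stacklevel=2)
                continue
            kept.append(line)
        db = gffutils.create_db(
            "\n".join(kept),
            dbfn=":memory:",
            from_string=True,
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )

        def gene_of(feature):
            for parent in db.parents(feature, featuretype=("gene", "ncRNA_gene")):
                return parent.id
            return None

        gene_rows, exon_rows, utr5_rows, utr3_rows = [], [], [], []
        for g in list(db.features_of_type("gene")) + list(db.features_of_type("ncRNA_gene")):
            name = g.attributes.get("Name", [g.id])[0]
            biotype = g.attributes.get("biotype", g.attributes.get("gene_biotype", ["unknown"]))[0]
            gene_rows.append((g.seqid, g.start, g.end, g.id, name, biotype))
        for ftype, rows in (
            ("exon", exon_rows),
            ("five_prime_UTR", utr5_rows),
            ("three_prime_UTR", utr3_rows),
        ):
            for f in db.features_of_type(ftype):
                rows.append((f.seqid, f.start, f.end, gene_of(f)))
        genes = pd.DataFrame(
            gene_rows, columns=["chrom", "start", "end", "gene_id", "name", "biotype"]
        )
        cols = ["chrom", "start", "end", "gene_id"]
        return cls(
            genes,
            pd.DataFrame(exon_rows, columns=cols),
            pd.DataFrame(utr5_rows, columns=cols),
            pd.DataFrame(utr3_rows, columns=cols),
        )

    @classmethod
    def from_bed12(cls, path) -> "GeneModels":
        """Load gene models from BED12 (0-based half-open on disk).

        Blocks become exons; exon stretches outside the thick (CDS) range
        become UTRs, sided by strand.  A zero-width thick range means a
        non-coding transcript (no UTRs).
        """
        names = [
            "chrom", "start", "end", "name", "score", "strand",
            "thickStart", "thickEnd", "itemRgb", "blockCount",
            "blockSizes", "blockStarts",
        ]
        bed = pd.read_csv(path, sep="\t", header=None, names=names, comment="#")
        gene_rows, exon_rows, utr5_rows, utr3_rows = [], [], [], []
        for _, row in bed.iterrows():
            gid = str(row["name"])
            start1, end1 = int(row["start"]) + 1, int(row["end"])
            gene_rows.append((row["chrom"], start1, end1, gid, gid, "unknown"))
            sizes = [int(s) for s in str(row["blockSizes"]).rstrip(",").split(",")]
            offsets = [int(s) for s in str(row["blockStarts"]).rstrip(",").split(",")]
            thick_lo, thick_hi = int(row["thickStart"]) + 1, int(row["thickEnd"])
            coding = thick_hi >= thick_lo
            for size, off in zip(sizes, offsets):
                ex_lo = int(row["start"]) + off + 1
                ex_hi = ex_lo + size - 1
                exon_rows.append((row["chrom"], ex_lo, ex_hi, gid))
                if not coding:
                    continue
                left = (ex_lo, min(ex_hi, thick_lo - 1))
                right = (max(ex_lo, thick_hi + 1), ex_hi)
                for lo, hi in (left, right):
                    if lo > hi:
                        continue
                    five_prime = (hi < thick_lo) == (row["strand"] != "-")
                    (utr5_rows if five_prime else utr3_rows).append(
                        (row["chrom"], lo, hi, gid)
                    )
        genes = pd.DataFrame(
            gene_rows, columns=["chrom", "start", "end", "gene_id", "name", "biotype"]
        )
        cols = ["chrom", "start", "end", "gene_id"]
        return cls(
            genes,
            pd.DataFrame(exon_rows, columns=cols),
            pd.DataFrame(utr5_rows, columns=cols),
            pd.DataFrame(utr3_rows, columns=cols),
        )


def _contains(table: pd.DataFrame, chrom, pos) -> bool:
    if len(table) == 0:
        return False
    hit = (table["chrom"] == chrom) & (table["start"] <= pos) & (pos <= table["end"])
    return bool(hit.any())


def classify_snp_location(chrom, pos, gene_models: GeneModels) -> str:
    """Hierarchical location class of a SNP against any overlapping transcript.

    Priority: UTR (5' before 3') > exon > intron > intergenic; strand is
    ignored for containment.
    """
    pos = int(pos)
    if _contains(gene_models.utr5, chrom, pos):
        return "5'-UTR"
    if _contains(gene_models.utr3, chrom, pos):
        return "3'-UTR"
    if _contains(gene_models.exons, chrom, pos):
        return "exon"
    if _contains(gene_models.genes, chrom, pos):
        return "intron"
    return "intergenic"


def overlap_genes(qtls, gene_models: GeneModels):
    """Attach to each QTL the genes whose span intersects its interval.

    Intersection is 1-based inclusive on both sides (a gene ending exactly
    at the QTL start is reported) and strand-agnostic.  Returns the same
    QTL list with ``genes`` filled (gene names, falling back to ids).
    """
    g = gene_models.genes
    for qtl in qtls:
        if len(g) == 0:
            qtl.genes = []
            continue
        hit = (g["chrom"] == qtl.chrom) & (g["start"] <= qtl.end) & (g["end"] >= qtl.start)
        qtl.genes = list(g.loc[hit, "name"].fillna(g.loc[hit, "gene_id"]))
    return qtls


def qtls_to_frame(qtls) -> pd.DataFrame:
    """Tabular QTL report (1-based inclusive coordinates)."""
    return pd.DataFrame(
        {
            "chrom": [q.chrom for q in qtls],
            "start": [q.start for q in qtls],
            "end": [q.end for q in qtls],
            "n_snps": [len(q.members) for q in qtls],
            "snp_positions": [",".join(map(str, q.members)) for q in qtls],
            "genes": [",".join(q.genes) for q in qtls],
        }
    )


def qtls_to_bed(qtls) -> pd.DataFrame:
    """BED-style frame (0-based half-open) for interoperability."""
    return pd.DataFrame(
        {
            "chrom": [q.chrom for q in qtls],
            "start": [q.start - 1 for q in qtls],
            "end": [q.end for q in qtls],
            "name": [f"QTL_{q.chrom}_{q.start}" for q in qtls],
        }
    )
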