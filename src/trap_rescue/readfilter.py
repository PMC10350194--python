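"""UTR read filtering and gene-level counting.

Amplified TRAP RNA is 3'-biased, so reads overlapping annotated UTRs are
removed from the alignment before counting.  "Overlapping" means >= 1 bp of
any read block intersecting any UTR interval; a flag restricts the filter to
3'UTRs, and strand-aware matching is optional (off by default, since the
filter is applied before any gene assignment).

Counting follows the featureCounts default: a read is assigned to a gene if
it overlaps intervals of exactly one gene; reads touching two or more genes
are discarded as ambiguous.

Coordinates: GTF input is 1-based inclusive; everything internal is 0-based
half-open, converted exactly once at parse time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from trap_rescue.errors import DataError

REGION_CLASSES = ("CDS", "UTR5", "UTR3", "other_exon")

_GTF_FEATURE_MAP = {
    "CDS": "CDS",
    "five_prime_utr": "UTR5",
    "three_prime_utr": "UTR3",
    "5UTR": "UTR5",
    "3UTR": "UTR3",
    "exon": "other_exon",
}


@dataclass
class AlignedRead:
    read_id: str
    chromosome: str
    blocks: list[tuple[int, int]]  # 0-based half-open
    strand: str = "+"
    mapped: bool = True

    def __post_init__(self) -> None:
        if self.mapped:
            if not self.blocks:
                raise DataError(f"mapped read {self.read_id} has no blocks")
            for s, e in self.blocks:
                if s >= e:
                    raise DataError(f"read {self.read_id} has empty block ({s}, {e})")


@dataclass
class _Gene:
    gene_id: str
    chromosome: str
    strand: str
    intervals: list[tuple[int, int, str]]  # 1-based inclusive, region class


class GeneAnnotation:
    """Gene models indexed for interval overlap queries.

    Built from GTF or from (gene_id, chrom, strand, start, end, class)
    records with 1-based inclusive coordinates.
    """

    def __init__(self, genes: dict[str, _Gene]):
        self.genes = genes
        self.gene_ids = list(genes)
        # trees keyed by chromosome; data = (gene_id, region_class, strand)
        self._all: dict[str, IntervalTree] = {}
        self._utr: dict[str, IntervalTree] = {}
        for g in genes.values():
            for s1, e1, cls in g.intervals:
                if s1 > e1:
                    raise DataError(f"gene {g.gene_id}: interval start {s1} > end {e1}")
                lo, hi = s1 - 1, e1  # to 0-based half-open
                item = (g.gene_id, cls, g.strand)
                self._all.setdefault(g.chromosome, IntervalTree()).addi(lo, hi, item)
                if cls in ("UTR5", "UTR3"):
                    self._utr.setdefault(g.chromosome, IntervalTree()).addi(lo, hi, item)

    @classmethod
    def from_records(cls, records) -> "GeneAnnotation":
        genes: dict[str, _Gene] = {}
        for gid, chrom, strand, s1, e1, region in records:
            if region not in REGION_CLASSES:
                raise DataError(f"unknown region class {region!r} for gene {gid}")
            g = genes.setdefault(gid, _Gene(gid, chrom, strand, []))
            if (g.chromosome, g.strand) != (chrom, strand):
                raise DataError(f"gene {gid} spans chromosomes or strands")
            g.intervals.append((int(s1), int(e1), region))
        return cls(genes)

    @classmethod
    def from_gtf(cls, path: str) -> "GeneAnnotation":
        """Parse a GTF file; requires a gene_id attribute on kept features.

        Bare ``UTR`` features (GENCODE style) are classed 5' or 3' by their
        position relative to the gene's CDS span and strand.
        """
        frame = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=["chrom", "source", "feature", "start", "end", "score", "strand",
                   "frame", "attributes"],
            dtype={"chrom": str},
        )
        keep = frame["feature"].isin(list(_GTF_FEATURE_MAP) + ["UTR"])
        frame = frame[keep].copy()
        gid = frame["attributes"].str.extract(r'gene_id "?([^";]+)"?', expand=False)
        if gid.isna().any():
            bad = frame.index[gid.isna()][0]
            raise DataError(f"GTF line without gene_id attribute (row {bad})")
        frame["gene_id"] = gid

        records = []
        for g, grp in frame.groupby("gene_id", sort=False):
            cds = grp[grp["feature"] == "CDS"]
            cds_span = (cds["start"].min(), cds["end"].max()) if len(cds) else None
            for row in grp.itertuples(index=False):
                feat = row.feature
                if feat == "UTR":
                    if cds_span is None:
                        region = "UTR3"
                    elif row.end < cds_span[0]:
                        region = "UTR5" if row.strand == "+" else "UTR3"
                    elif row.start > cds_span[1]:
                        region = "UTR3" if row.strand == "+" else "UTR5"
                    else:
                        region = "other_exon"
                else:
                    region = _GTF_FEATURE_MAP[feat]
                records.append((g, row.chrom, row.strand, row.start, row.end, region))
        return cls.from_records(records)

    def to_gtf(self, path: str, source: str = "trap_rescue") -> None:
        inv = {"CDS": "CDS", "UTR5": "five_prime_utr", "UTR3": "three_prime_utr",
               "other_exon": "exon"}
        with open(path, "w") as fh:
            for g in self.genes.values():
                for s1, e1, cls in sorted(g.intervals):
                    fh.write(
                        f"{g.chromosome}\t{source}\t{inv[cls]}\t{s1}\t{e1}\t.\t"
                        f'{g.strand}\t.\tgene_id "{g.gene_id}";\n'
                    )

    def reference_lengths(self) -> dict[str, int]:
        return {chrom: tree.end() + 1000 for chrom, tree in self._all.items()}


def classify_read(
    read: AlignedRead,
    annotation: GeneAnnotation,
    utr3_only: bool = False,
    stranded: bool = False,
) -> str:
    """Return ``utr`` on any UTR overlap, else ``non_utr`` on any gene overlap,
    else ``unassigned``."""
    if not read.mapped:
        raise DataError(f"read {read.read_id} is unmapped; pre-filter unmapped reads")
    utr_tree = annotation._utr.get(read.chromosome)
    all_tree = annotation._all.get(read.chromosome)
    hit_gene = False
    for lo, hi in read.blocks:
        if utr_tree is not None:
            for iv in utr_tree.overlap(lo, hi):
                _gid, cls, strand = iv.data
                if utr3_only and cls != "UTR3":
                    continue
                if stranded and strand != read.strand:
                    continue
                return "utr"
        if not hit_gene and all_tree is not None:
            for iv in all_tree.overlap(lo, hi):
                if stranded and iv.data[2] != read.strand:
                    continue
                hit_gene = True
                break
    return "non_utr" if hit_gene else "unassigned"


def filter_utr_reads(
    reads,
    annotation: GeneAnnotation,
    utr3_only: bool = False,
    stranded: bool = False,
):
    """Drop UTR-overlapping reads; order preserved.

    Returns ``(kept_reads, summary)`` with summary counts for kept / removed /
    unassigned (unassigned reads are kept: they carry no UTR evidence).
    """
    kept: list[AlignedRead] = []
    summary = {"kept": 0, "removed": 0, "unassigned": 0}
    for read in reads:
        verdict = classify_read(read, annotation, utr3_only=utr3_only, stranded=stranded)
        if verdict == "utr":
            summary["removed"] += 1
        else:
            if verdict == "unassigned":
                summary["unassigned"] += 1
            kept.append(read)
            summary["kept"] += 1
    return kept, summary


def count_reads(reads, annotation: GeneAnnotation, stranded: bool = False) -> pd.Series:
    """Count reads per gene; reads overlapping more than one gene are discarded."""
    counts = dict.fromkeys(annotation.gene_ids, 0)
    for read in reads:
        tree = annotation._all.get(read.chromosome)
        if tree is None:
            continue
        hits: set[str] = set()
        for lo, hi in read.blocks:
            for iv in tree.overlap(lo, hi):
                gid, _cls, strand = iv.data
                if stranded and strand != read.strand:
                    continue
                hits.add(gid)
        if len(hits) == 1:
            counts[hits.pop()] += 1
    return pd.Series(counts, name="count", dtype=int)


# ---------------------------------------------------------------------------
# SAM I/O (pysam)
# ---------------------------------------------------------------------------


def write_sam(reads: list[AlignedRead], path: str, annotation: GeneAnnotation) -> None:
    """Write ungapped single-end records as SAM text."""
    import pysam

    lengths = annotation.reference_lengths()
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": n} for c, n in lengths.items()],
    }
    ref_index = {c: i for i, c in enumerate(lengths)}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for read in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = read.read_id
            lo, hi = read.blocks[0]
            a.reference_id = ref_index[read.chromosome]
            a.reference_start = lo
            a.cigarstring = f"{hi - lo}M"
            a.flag = 16 if read.strand == "-" else 0
            a.mapping_quality = 60
            a.query_sequence = "N" * (hi - lo)
            out.write(a)


def read_sam(path: str):
    """Yield :class:`AlignedRead` for each mapped record of a SAM/BAM file."""
    import pysam

    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            blocks = [(int(s), int(e)) for s, e in rec.get_blocks()]
            if not blocks:
                raise DataError(f"mapped record {rec.query_name} has no aligned blocks")
            yield AlignedRead(
                read_id=rec.query_name,
                chromosome=rec.reference_name,
                blocks=blocks,
                strand="-" if rec.is_reverse else "+",
            )
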