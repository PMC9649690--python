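"""Transcript models, reference-based classification, naming, TSS evidence.

Coordinate conventions: GTF exons are 1-based closed intervals; BED peaks
are 0-based half-open. All internal arithmetic is 1-based closed; BED
intervals are converted on load (``start + 1``) and on write.

Query transcripts assembled outside the reference annotation are placed
into one of seven categories against a reference transcript set, checked in
a fixed precedence order (first match wins):

1. ``annotated_match``  — intron chain identical to a reference transcript
   (mono-exon queries: identical exon coordinates);
2. ``contain_Ref``      — the query's intron chain strictly contains a
   reference transcript's complete chain;
3. ``match_Refjunction``— shares at least one splice junction with the
   reference;
4. ``retain_Refintron`` — a query exon completely spans a reference intron
   together with flanking exonic bases (retained intron);
5. ``overlap_Refexon``  — other same-strand exonic overlap;
6. ``within_Refintron`` — the query lies entirely inside one reference
   intron;
7. ``intergenic``       — no overlap with any reference gene span on
   either strand.

A readthrough transcript is one whose exons overlap exons of two or more
distinct same-strand reference genes. Unannotated transcripts are renamed
``<gene>-u<k>`` and annotated ones ``<gene>-a<k>``, counters running per
gene per class in ascending genomic-start order; transcripts not
attributable to a single gene keep their input identifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gffutils
import pandas as pd
from intervaltree import IntervalTree

from .errors import DataError

__all__ = [
    "TranscriptModel",
    "ClassificationResult",
    "EvidenceCall",
    "parse_gtf",
    "write_gtf",
    "read_bed",
    "write_bed",
    "classify_against_reference",
    "detect_readthrough",
    "assign_names",
    "tss_evidence",
]

CATEGORIES = (
    "annotated_match",
    "contain_Ref",
    "match_Refjunction",
    "retain_Refintron",
    "overlap_Refexon",
    "within_Refintron",
    "intergenic",
)


@dataclass(frozen=True)
class TranscriptModel:
    """Stranded exon-chain gene model (1-based closed coordinates)."""

    id: str
    gene_ids: tuple[str, ...]
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # sorted by genomic start

    def __post_init__(self) -> None:
        exons = tuple(sorted((int(a), int(b)) for a, b in self.exons))
        object.__setattr__(self, "exons", exons)
        for (a, b), (c, d) in zip(exons, exons[1:]):
            if c <= b:
                raise DataError(f"transcript {self.id}: overlapping/unsorted exons")
        if self.strand not in ("+", "-"):
            raise DataError(f"transcript {self.id}: strand must be + or -")

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons, 1-based closed; empty if mono-exon."""
        return tuple(
            (a_end + 1, b_start - 1)
            for (_, a_end), (b_start, _) in zip(self.exons, self.exons[1:])
        )

    @property
    def tss(self) -> int:
        """5' end respecting strand: min start on +, max end on -."""
        return self.exons[0][0] if self.strand == "+" else self.exons[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class ClassificationResult:
    transcript_id: str
    category: str
    is_readthrough: bool = False
    assigned_name: str | None = None
    matched_gene: str | None = None


@dataclass
class EvidenceCall:
    transcript_id: str
    has_cage: bool
    has_chromatin: bool

    @property
    def label(self) -> str:
        if self.has_cage and self.has_chromatin:
            return "both"
        if self.has_cage:
            return "cage_only"
        if self.has_chromatin:
            return "chromatin_only"
        return "none"


def parse_gtf(path) -> list[TranscriptModel]:
    """Parse transcript models from a GTF file via gffutils.

    Only ``exon`` features are required; models are grouped by the
    ``transcript_id`` attribute and exon file order is irrelevant.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    grouped: dict[str, list] = {}
    for exon in db.features_of_type("exon"):
        tid = exon.attributes["transcript_id"][0]
        grouped.setdefault(tid, []).append(exon)
    models = []
    for tid, exons in grouped.items():
        chroms = {e.seqid for e in exons}
        strands = {e.strand for e in exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise DataError(f"transcript {tid}: exons on mixed chrom/strand")
        genes = tuple(
            dict.fromkeys(e.attributes.get("gene_id", ["."])[0] for e in exons)
        )
        models.append(
            TranscriptModel(
                id=tid,
                gene_ids=genes,
                chrom=chroms.pop(),
                strand=strands.pop(),
                exons=tuple((e.start, e.end) for e in exons),
            )
        )
    return models


def write_gtf(models, path, source: str = "txaxes") -> None:
    """Write transcript + exon features as GTF (1-based closed)."""
    with open(path, "w") as fh:
        for m in models:
            gene = m.gene_ids[0]
            attrs = f'gene_id "{gene}"; transcript_id "{m.id}";'
            s, e = m.span
            fh.write(
                f"{m.chrom}\t{source}\ttranscript\t{s}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            for a, b in m.exons:
                fh.write(
                    f"{m.chrom}\t{source}\texon\t{a}\t{b}\t.\t{m.strand}\t.\t{attrs}\n"
                )


BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path) -> pd.DataFrame:
    """Read a BED3/BED6 file into a DataFrame (0-based half-open kept as is)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise DataError(f"{path}: BED needs at least 3 columns")
    df = df.iloc[:, :6]
    df.columns = BED_COLUMNS[: df.shape[1]]
    for col, default in (("name", "."), ("score", 0), ("strand", ".")):
        if col not in df:
            df[col] = default
    if (df["end"] <= df["start"]).any():
        raise DataError(f"{path}: BED intervals must satisfy start < end")
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    df.loc[:, BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def _junction_set(model: TranscriptModel) -> set[tuple[str, str, int, int]]:
    return {(model.chrom, model.strand, a, b) for a, b in model.introns}


def _exonic_overlap(q: TranscriptModel, r: TranscriptModel) -> bool:
    if q.chrom != r.chrom:
        return False
    return any(
        qa <= rb and qe >= ra for qa, qe in q.exons for ra, rb in r.exons
    )


def _chain_contains(query: TranscriptModel, ref: TranscriptModel) -> bool:
    """True if ref's full intron chain occurs as a contiguous subsequence of
    the query's chain and the query chain is strictly longer."""
    qc, rc = query.introns, ref.introns
    if not rc or len(qc) <= len(rc):
        return False
    for i in range(len(qc) - len(rc) + 1):
        if qc[i : i + len(rc)] == rc:
            return True
    return False


def classify_against_reference(
    query: TranscriptModel, reference: list[TranscriptModel]
) -> ClassificationResult:
    """Assign the single category of a query transcript (precedence above).

    Same-strand comparisons throughout, except the final intergenic test
    which uses gene spans on either strand.
    """
    same = [
        r for r in reference if r.chrom == query.chrom and r.strand == query.strand
    ]
    q_start, q_end = query.span

    # 1. identical intron chain (mono-exon: identical exons)
    for r in same:
        if query.introns:
            if query.introns == r.introns:
                return ClassificationResult(query.id, "annotated_match",
                                            matched_gene=r.gene_ids[0])
        elif not r.introns and query.exons == r.exons:
            return ClassificationResult(query.id, "annotated_match",
                                        matched_gene=r.gene_ids[0])

    # 2. strict containment of a reference chain
    for r in same:
        if _chain_contains(query, r):
            return ClassificationResult(query.id, "contain_Ref",
                                        matched_gene=r.gene_ids[0])

    # 3. at least one shared junction
    ref_junctions = set().union(*(_junction_set(r) for r in same)) if same else set()
    if _junction_set(query) & ref_junctions:
        return ClassificationResult(query.id, "match_Refjunction")

    # 4. a query exon fully spans a reference intron (with flanking bases)
    for r in same:
        for ia, ib in r.introns:
            if any(qa < ia and qe > ib for qa, qe in query.exons):
                return ClassificationResult(query.id, "retain_Refintron",
                                            matched_gene=r.gene_ids[0])

    # 5. same-strand exonic overlap
    for r in same:
        if _exonic_overlap(query, r):
            return ClassificationResult(query.id, "overlap_Refexon",
                                        matched_gene=r.gene_ids[0])

    # 6. entirely inside one reference intron
    for r in same:
        if any(ia <= q_start and q_end <= ib for ia, ib in r.introns):
            return ClassificationResult(query.id, "within_Refintron",
                                        matched_gene=r.gene_ids[0])

    # 7. intergenic: no gene-span overlap on either strand
    any_overlap = [
        r
        for r in reference
        if r.chrom == query.chrom
        and r.span[0] <= q_end
        and r.span[1] >= q_start
    ]
    if not any_overlap:
        return ClassificationResult(query.id, "intergenic")

    # residual (opposite-strand overlap only): nearest structural category
    for r in any_overlap:
        if any(ia <= q_start and q_end <= ib for ia, ib in r.introns):
            return ClassificationResult(query.id, "within_Refintron",
                                        matched_gene=r.gene_ids[0])
    return ClassificationResult(query.id, "overlap_Refexon",
                                matched_gene=any_overlap[0].gene_ids[0])


def detect_readthrough(query: TranscriptModel, reference: list[TranscriptModel]) -> bool:
    """True iff query exons overlap exons of >= 2 distinct same-strand genes."""
    genes = {
        r.gene_ids[0]
        for r in reference
        if r.chrom == query.chrom
        and r.strand == query.strand
        and _exonic_overlap(query, r)
    }
    return len(genes) >= 2


def _overlapping_genes(query: TranscriptModel, reference: list[TranscriptModel]) -> list[str]:
    """Genes whose span overlaps the query span; same strand preferred."""
    q_start, q_end = query.span
    hits = [
        r
        for r in reference
        if r.chrom == query.chrom and r.span[0] <= q_end and r.span[1] >= q_start
    ]
    same = [r for r in hits if r.strand == query.strand]
    pool = same if same else hits
    return list(dict.fromkeys(r.gene_ids[0] for r in pool))


def assign_names(
    queries: list[TranscriptModel],
    results: dict[str, ClassificationResult],
    reference: list[TranscriptModel],
) -> dict[str, ClassificationResult]:
    """Rename classified transcripts by host gene: ``<gene>-a<k>`` for
    annotated matches, ``<gene>-u<k>`` for other single-gene transcripts,
    counters starting at 1 in ascending genomic-start order; multi-gene or
    geneless transcripts keep their input id."""
    counters: dict[tuple[str, str], int] = {}
    for q in sorted(queries, key=lambda m: (m.chrom, m.span[0], m.span[1], m.id)):
        res = results[q.id]
        annotated = res.category == "annotated_match"
        genes = (
            [res.matched_gene]
            if annotated and res.matched_gene
            else _overlapping_genes(q, reference)
        )
        if len(genes) == 1:
            cls = "a" if annotated else "u"
            key = (genes[0], cls)
            counters[key] = counters.get(key, 0) + 1
            res.assigned_name = f"{genes[0]}-{cls}{counters[key]}"
            res.matched_gene = genes[0]
        else:
            res.assigned_name = q.id
    return results


def _peak_tree(peaks: pd.DataFrame) -> dict[str, IntervalTree]:
    """Index BED peaks per chromosome, converted to 1-based closed (stored
    half-open as [start+1, end+1) so closed end == BED end)."""
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in peaks.groupby("chrom"):
        trees[str(chrom)] = IntervalTree.from_tuples(
            (int(s) + 1, int(e) + 1) for s, e in zip(sub["start"], sub["end"])
        )
    return trees


def tss_evidence(
    models: list[TranscriptModel],
    cage_peaks: pd.DataFrame,
    chromatin_peaks: pd.DataFrame,
    window: int = 500,
) -> list[EvidenceCall]:
    """Flag transcripts with a CAGE / active-chromatin peak within ``window``
    nt of the TSS (closed window, so a peak exactly ``window`` nt away still
    counts as evidence)."""
    cage = _peak_tree(cage_peaks)
    chrom_st = _peak_tree(chromatin_peaks)
    model_chroms = {m.chrom for m in models}
    for name, trees in (("CAGE", cage), ("chromatin", chrom_st)):
        stray = set(trees) - model_chroms
        if stray and trees:
            warnings.warn(
                f"{name} peaks on chromosomes absent from models: "
                f"{ {c: len(trees[c]) for c in sorted(stray)} }"
            )
    calls = []
    for m in models:
        lo, hi = m.tss - window, m.tss + window
        has_cage = bool(cage.get(m.chrom, IntervalTree()).overlap(lo, hi + 1))
        has_chromatin = bool(chrom_st.get(m.chrom, IntervalTree()).overlap(lo, hi + 1))
        calls.append(EvidenceCall(m.id, has_cage, has_chromatin))
    return calls
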