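"""Genome annotation model, promoter windows, and genomic-location classes.

Coordinates are 0-based half-open throughout.  GFF3 input (1-based,
inclusive) is converted on read; BED input is used natively.

The central convention of the whole pipeline lives here: a gene's
*promoter-proximal window* runs from ``upstream`` bp 5' of the translation
start (ATG) to ``downstream`` bp 3' of it, in transcription direction
(default -2000..+200, inclusive at both ends).  A ChIP-seq summit is
"promoter-proximal" for a gene when its signed distance to the ATG falls in
that window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from intervaltree import IntervalTree

from .errors import AnnotationError, InputFormatError

#: default promoter window, bp upstream / downstream of the ATG
DEFAULT_UPSTREAM = 2000
DEFAULT_DOWNSTREAM = 200

LOCATION_CATEGORIES = (
    "promoter",
    "gene_body",
    "three_prime_end",
    "distal_upstream",
    "other",
)


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [lo, hi) on one chromosome."""

    chrom: str
    lo: int
    hi: int

    def __post_init__(self) -> None:
        if not (0 <= self.lo <= self.hi):
            raise ValueError(f"invalid interval [{self.lo}, {self.hi})")

    def __len__(self) -> int:
        return self.hi - self.lo

    def contains(self, pos: int) -> bool:
        return self.lo <= pos < self.hi


@dataclass(frozen=True)
class GeneModel:
    """One annotated protein-coding gene.

    ``atg`` is the 0-based genomic coordinate of the first base of the start
    codon; for minus-strand genes this is the *rightmost* base of the CDS.
    ``is_tf`` flags DNA-binding transcription-factor genes; ``categories``
    carries free-text pathway/GO/KEGG labels.
    """

    gene_id: str
    chrom: str
    strand: str
    span_lo: int
    span_hi: int
    atg: int
    is_tf: bool = False
    categories: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.span_lo < self.span_hi:
            raise ValueError(f"{self.gene_id}: empty span")
        if not (self.span_lo <= self.atg < self.span_hi):
            raise ValueError(f"{self.gene_id}: ATG outside gene span")


class GenomeAnnotation:
    """A set of gene models plus chromosome sizes, with interval indexes."""

    def __init__(self, genes: Iterable[GeneModel], chrom_sizes: Mapping[str, int]):
        self.genes: list[GeneModel] = list(genes)
        self.chrom_sizes: dict[str, int] = dict(chrom_sizes)
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise AnnotationError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            if g.chrom not in self.chrom_sizes:
                raise AnnotationError(
                    f"{g.gene_id}: chromosome {g.chrom!r} has no declared size"
                )
            if g.span_hi > self.chrom_sizes[g.chrom]:
                raise AnnotationError(f"{g.gene_id}: span exceeds chromosome")
        self.genes_by_id: dict[str, GeneModel] = {g.gene_id: g for g in self.genes}
        self._promoter_index: dict[tuple, dict[str, IntervalTree]] = {}

    def __len__(self) -> int:
        return len(self.genes)

    def promoter_trees(
        self,
        upstream: int = DEFAULT_UPSTREAM,
        downstream: int = DEFAULT_DOWNSTREAM,
    ) -> dict[str, IntervalTree]:
        """Per-chromosome interval trees of promoter windows (cached)."""
        key = (upstream, downstream)
        if key not in self._promoter_index:
            trees: dict[str, IntervalTree] = {c: IntervalTree() for c in self.chrom_sizes}
            for g in self.genes:
                w = promoter_window(
                    g, upstream, downstream, chrom_len=self.chrom_sizes[g.chrom]
                )
                if len(w) > 0:
                    trees[g.chrom].addi(w.lo, w.hi, g.gene_id)
            self._promoter_index[key] = trees
        return self._promoter_index[key]


def promoter_window(
    gene: GeneModel,
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
    *,
    chrom_len: int,
) -> GenomicInterval:
    """Strand-aware promoter window around the ATG, clipped to the chromosome.

    Contains exactly the positions whose signed distance to the ATG lies in
    [-upstream, +downstream] (both bounds inclusive), so an unclipped window
    has upstream + downstream + 1 bases.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream/downstream must be >= 0")
    if chrom_len is None:
        raise AnnotationError(f"{gene.gene_id}: chromosome length missing")
    if gene.strand == "+":
        lo, hi = gene.atg - upstream, gene.atg + downstream + 1
    else:
        lo, hi = gene.atg - downstream, gene.atg + upstream + 1
    lo = max(0, lo)
    hi = min(chrom_len, hi)
    if hi < lo:  # fully clipped off the chromosome
        hi = lo
    return GenomicInterval(gene.chrom, lo, hi)


def signed_distance_to_atg(pos: int, gene: GeneModel) -> int:
    """Signed distance from ``pos`` to the gene's ATG; negative = upstream.

    Measured in transcription direction: on the minus strand, upstream of the
    ATG means a *higher* genomic coordinate.
    """
    return pos - gene.atg if gene.strand == "+" else gene.atg - pos


class LocationClassifier:
    """Classify genomic positions relative to an annotation.

    Fixed priority: promoter > gene_body > three_prime_end > distal_upstream
    > other.  ``three_prime_extent`` bounds the "3' end" region past a gene
    span; ``distal_cap`` bounds how far upstream still counts as
    distal_upstream (positions beyond -upstream down to -distal_cap).
    """

    def __init__(
        self,
        annotation: GenomeAnnotation,
        upstream: int = DEFAULT_UPSTREAM,
        downstream: int = DEFAULT_DOWNSTREAM,
        three_prime_extent: int = 500,
        distal_cap: int = 10_000,
    ):
        self.annotation = annotation
        self.upstream = upstream
        self.downstream = downstream
        self.promoter = annotation.promoter_trees(upstream, downstream)
        self.body: dict[str, IntervalTree] = {c: IntervalTree() for c in annotation.chrom_sizes}
        self.three_prime: dict[str, IntervalTree] = {
            c: IntervalTree() for c in annotation.chrom_sizes
        }
        self.distal: dict[str, IntervalTree] = {c: IntervalTree() for c in annotation.chrom_sizes}
        for g in annotation.genes:
            clen = annotation.chrom_sizes[g.chrom]
            self.body[g.chrom].addi(g.span_lo, g.span_hi, g.gene_id)
            if g.strand == "+":
                t_lo, t_hi = g.span_hi, min(clen, g.span_hi + three_prime_extent)
                d_lo = max(0, g.atg - distal_cap)
                d_hi = max(0, g.atg - upstream)  # exclusive: d <= -(upstream+1)
            else:
                t_lo, t_hi = max(0, g.span_lo - three_prime_extent), g.span_lo
                d_lo = min(clen, g.atg + upstream + 1)
                d_hi = min(clen, g.atg + distal_cap + 1)
            if t_hi > t_lo:
                self.three_prime[g.chrom].addi(t_lo, t_hi, g.gene_id)
            if d_hi > d_lo:
                self.distal[g.chrom].addi(d_lo, d_hi, g.gene_id)

    def classify(self, chrom: str, pos: int) -> str:
        if chrom not in self.annotation.chrom_sizes:
            raise AnnotationError(f"unknown chromosome {chrom!r}")
        for name, trees in (
            ("promoter", self.promoter),
            ("gene_body", self.body),
            ("three_prime_end", self.three_prime),
            ("distal_upstream", self.distal),
        ):
            if trees[chrom].overlaps(pos, pos + 1):
                # gene_body means inside a span but not in ANY promoter window
                if name == "gene_body" and self.promoter[chrom].overlaps(pos, pos + 1):
                    continue
                return name
        return "other"


def classify_location(
    chrom: str,
    pos: int,
    annotation: GenomeAnnotation,
    **kwargs,
) -> str:
    """One-shot convenience wrapper around :class:`LocationClassifier`."""
    return LocationClassifier(annotation, **kwargs).classify(chrom, pos)


# ---------------------------------------------------------------------------
# readers


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Chromosome sizes from a 2+-column TSV (or a samtools/pyfaidx .fai)."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise InputFormatError(f"{path}: expected >=2 tab-separated columns")
            try:
                sizes[parts[0]] = int(parts[1])
            except ValueError as e:
                raise InputFormatError(f"{path}: bad length for {parts[0]!r}") from e
    return sizes


def read_gene_categories(path: str | Path) -> dict[str, set[str]]:
    """gene_id -> set of category labels from a 2-column TSV."""
    cats: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise InputFormatError(f"{path}: expected 2 columns (gene_id, label)")
            cats.setdefault(parts[0], set()).add(parts[1])
    return cats


def read_gene_list(path: str | Path) -> set[str]:
    """One gene_id per line (e.g. the TF gene list)."""
    with open(path) as fh:
        return {ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")}


def read_annotation(
    gff_path: str | Path,
    chrom_sizes: Mapping[str, int] | str | Path,
    categories: Mapping[str, set[str]] | str | Path | None = None,
    tf_genes: Iterable[str] | str | Path | None = None,
) -> GenomeAnnotation:
    """Load a GFF3 into a :class:`GenomeAnnotation`.

    The ATG is taken from CDS features: the 5'-most CDS start in
    transcription direction among all CDS lines of the gene.  Genes without
    CDS children fall back to the strand-appropriate end of the gene span.
    """
    import gffutils

    if isinstance(chrom_sizes, (str, Path)):
        chrom_sizes = read_chrom_sizes(chrom_sizes)
    if isinstance(categories, (str, Path)):
        categories = read_gene_categories(categories)
    if isinstance(tf_genes, (str, Path)):
        tf_genes = read_gene_list(tf_genes)
    tf_set = set(tf_genes) if tf_genes else set()
    cat_map = dict(categories) if categories else {}

    try:
        db = gffutils.create_db(
            str(gff_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as e:  # noqa: BLE001 - surface as format error with context
        raise InputFormatError(f"{gff_path}: failed to parse GFF3 ({e})") from e

    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        span_lo, span_hi = feat.start - 1, feat.end  # GFF3 1-based inclusive
        cds = [c for c in db.children(feat, featuretype="CDS")]
        if cds:
            if feat.strand == "+":
                atg = min(c.start for c in cds) - 1
            else:
                atg = max(c.end for c in cds) - 1
        else:
            atg = span_lo if feat.strand == "+" else span_hi - 1
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=feat.seqid,
                strand=feat.strand,
                span_lo=span_lo,
                span_hi=span_hi,
                atg=atg,
                is_tf=gid in tf_set,
                categories=frozenset(cat_map.get(gid, ())),
            )
        )
    return GenomeAnnotation(genes, chrom_sizes)
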