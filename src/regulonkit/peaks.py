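"""Summit reconciliation, dual-epitope peak-set union, and promoter assignment.

The reproducibility rule is positional: summits from two independent
biological replicates are kept only when they lie within ``max_dist`` bp of
each other (default 100), and the two epitope-tagged peak sets are then
combined by the same distance criterion.  A reconciled summit is assigned to
*every* gene whose promoter window contains it, so a summit between two
divergently transcribed genes counts for both — bidirectional promoters are
first-class citizens, not ties to break.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import pandas as pd

from .errors import InputFormatError
from .genome import (
    DEFAULT_DOWNSTREAM,
    DEFAULT_UPSTREAM,
    GenomeAnnotation,
    LocationClassifier,
    signed_distance_to_atg,
)


@dataclass(frozen=True)
class Summit:
    """One ChIP-seq peak summit (single base, 0-based)."""

    chrom: str
    pos: int
    height: float = 0.0
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError("summit pos must be >= 0")
        if self.height < 0:
            raise ValueError("summit height must be >= 0")


@dataclass(frozen=True)
class ReconciledPeak:
    """A merged summit with its source summits and provenance tags."""

    chrom: str
    pos: int
    members: tuple = ()
    provenance: frozenset = field(default_factory=frozenset)
    sources: frozenset = field(default_factory=frozenset)

    @property
    def height(self) -> float:
        if not self.members:
            return 0.0
        return sum(m.height for m in self.members) / len(self.members)


class ReconciliationResult(NamedTuple):
    peaks: list
    unmatched_a: list
    unmatched_b: list


class MergeResult(NamedTuple):
    peaks: list
    shared: int
    shared_fraction: float


@dataclass(frozen=True)
class PromoterAssignment:
    """One (gene, summit) pairing inside the promoter window."""

    gene_id: str
    peak: ReconciledPeak
    distance: int  # signed bp to the ATG, negative = upstream


class AssignmentResult(NamedTuple):
    assignments: list
    unassigned: list  # (peak, location category) pairs


def _check_unique(summits: Sequence[Summit]) -> None:
    keys = [(s.chrom, s.pos, s.sample_id) for s in summits]
    if len(set(keys)) != len(keys):
        raise InputFormatError("duplicate (chrom, pos, sample) summit in input")


def _greedy_pairs(
    a_pos: list[int], b_pos: list[int], max_dist: int
) -> list[tuple[int, int]]:
    """Greedy one-to-one matching by increasing distance.

    Candidates are all (i, j) with |a[i] - b[j]| <= max_dist; they are taken
    in order of (distance, lower coordinate) and each summit is used once.
    """
    cands: list[tuple[int, int, int, int, int]] = []
    order = sorted(range(len(b_pos)), key=b_pos.__getitem__)
    sorted_b = [b_pos[j] for j in order]
    import bisect

    for i, pa in enumerate(a_pos):
        lo = bisect.bisect_left(sorted_b, pa - max_dist)
        hi = bisect.bisect_right(sorted_b, pa + max_dist)
        for k in range(lo, hi):
            j = order[k]
            pb = b_pos[j]
            cands.append((abs(pa - pb), min(pa, pb), max(pa, pb), i, j))
    cands.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, _, _, i, j in cands:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
    return pairs


def reconcile_replicates(
    rep_a: Sequence[Summit],
    rep_b: Sequence[Summit],
    max_dist: int = 100,
) -> ReconciliationResult:
    """Keep only summits reproduced across two biological replicates.

    Summits on the same chromosome within ``max_dist`` bp are paired
    one-to-one (greedy by increasing distance, ties toward the lower
    coordinate); each pair becomes one peak at floor((posA+posB)/2).
    Unpaired summits are returned separately and excluded.
    """
    _check_unique(list(rep_a) + list(rep_b))
    by_chrom_a: dict[str, list[Summit]] = {}
    by_chrom_b: dict[str, list[Summit]] = {}
    for s in rep_a:
        by_chrom_a.setdefault(s.chrom, []).append(s)
    for s in rep_b:
        by_chrom_b.setdefault(s.chrom, []).append(s)

    peaks: list[ReconciledPeak] = []
    unmatched_a: list[Summit] = []
    unmatched_b: list[Summit] = []
    for chrom in sorted(set(by_chrom_a) | set(by_chrom_b)):
        sa = sorted(by_chrom_a.get(chrom, []), key=lambda s: s.pos)
        sb = sorted(by_chrom_b.get(chrom, []), key=lambda s: s.pos)
        pairs = _greedy_pairs([s.pos for s in sa], [s.pos for s in sb], max_dist)
        matched_a = {i for i, _ in pairs}
        matched_b = {j for _, j in pairs}
        for i, j in sorted(pairs, key=lambda p: sa[p[0]].pos):
            a, b = sa[i], sb[j]
            peaks.append(
                ReconciledPeak(
                    chrom=chrom,
                    pos=(a.pos + b.pos) // 2,
                    members=(a, b),
                    provenance=frozenset({a.sample_id, b.sample_id}),
                )
            )
        unmatched_a.extend(s for i, s in enumerate(sa) if i not in matched_a)
        unmatched_b.extend(s for j, s in enumerate(sb) if j not in matched_b)
    return ReconciliationResult(peaks, unmatched_a, unmatched_b)


def merge_peak_sets(
    set_a: Sequence[ReconciledPeak],
    set_b: Sequence[ReconciledPeak],
    merge_dist: int = 100,
    label_a: str = "setA",
    label_b: str = "setB",
) -> MergeResult:
    """Union of two peak sets with distance-based duplicate collapsing.

    Peaks within ``merge_dist`` across the sets merge to their midpoint with
    provenance from both; the rest carry single-set provenance.  The shared
    fraction is |shared| / |smaller set|.
    """
    by_chrom_a: dict[str, list[ReconciledPeak]] = {}
    by_chrom_b: dict[str, list[ReconciledPeak]] = {}
    for p in set_a:
        by_chrom_a.setdefault(p.chrom, []).append(p)
    for p in set_b:
        by_chrom_b.setdefault(p.chrom, []).append(p)

    merged: list[ReconciledPeak] = []
    shared = 0
    for chrom in sorted(set(by_chrom_a) | set(by_chrom_b)):
        pa = sorted(by_chrom_a.get(chrom, []), key=lambda p: p.pos)
        pb = sorted(by_chrom_b.get(chrom, []), key=lambda p: p.pos)
        pairs = _greedy_pairs([p.pos for p in pa], [p.pos for p in pb], merge_dist)
        matched_a = {i for i, _ in pairs}
        matched_b = {j for _, j in pairs}
        for i, j in pairs:
            a, b = pa[i], pb[j]
            merged.append(
                ReconciledPeak(
                    chrom=chrom,
                    pos=(a.pos + b.pos) // 2,
                    members=tuple(a.members) + tuple(b.members),
                    provenance=a.provenance | b.provenance,
                    sources=frozenset({label_a, label_b}),
                )
            )
            shared += 1
        for i, p in enumerate(pa):
            if i not in matched_a:
                merged.append(
                    ReconciledPeak(chrom, p.pos, p.members, p.provenance, frozenset({label_a}))
                )
        for j, p in enumerate(pb):
            if j not in matched_b:
                merged.append(
                    ReconciledPeak(chrom, p.pos, p.members, p.provenance, frozenset({label_b}))
                )
    merged.sort(key=lambda p: (p.chrom, p.pos))
    smaller = min(len(set_a), len(set_b))
    fraction = shared / smaller if smaller else 0.0
    return MergeResult(merged, shared, fraction)


def assign_summits_to_genes(
    peaks: Sequence[ReconciledPeak],
    annotation: GenomeAnnotation,
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
) -> AssignmentResult:
    """Assign each summit to every gene whose promoter window contains it.

    Summits in no window are returned unassigned together with their
    genomic-location category (gene body, 3' end, distal upstream, other).
    """
    trees = annotation.promoter_trees(upstream, downstream)
    classifier: LocationClassifier | None = None
    assignments: list[PromoterAssignment] = []
    unassigned: list[tuple[ReconciledPeak, str]] = []
    for peak in peaks:
        if peak.chrom not in trees:
            raise InputFormatError(f"summit on unknown chromosome {peak.chrom!r}")
        hits = trees[peak.chrom][peak.pos]
        if hits:
            for iv in sorted(hits, key=lambda iv: iv.data):
                gene = annotation.genes_by_id[iv.data]
                assignments.append(
                    PromoterAssignment(
                        gene_id=gene.gene_id,
                        peak=peak,
                        distance=signed_distance_to_atg(peak.pos, gene),
                    )
                )
        else:
            if classifier is None:
                classifier = LocationClassifier(annotation, upstream, downstream)
            unassigned.append((peak, classifier.classify(peak.chrom, peak.pos)))
    return AssignmentResult(assignments, unassigned)


def count_sites_per_promoter(assignments: Sequence[PromoterAssignment]) -> pd.DataFrame:
    """Distinct binding sites per bound promoter.

    Returns a frame indexed by gene_id with columns ``n_sites`` and
    ``multi_site`` (n_sites >= 2) — the homotypic-cluster readout.
    """
    per_gene: dict[str, set[tuple[str, int]]] = {}
    for a in assignments:
        per_gene.setdefault(a.gene_id, set()).add((a.peak.chrom, a.peak.pos))
    rows = sorted((g, len(sites)) for g, sites in per_gene.items())
    df = pd.DataFrame(rows, columns=["gene_id", "n_sites"]).set_index("gene_id")
    df["multi_site"] = df["n_sites"] >= 2
    return df


# ---------------------------------------------------------------------------
# I/O


def read_summits_bed(path: str | Path, sample_id: str | None = None) -> list[Summit]:
    """BED6 summits: chrom, start, end, name (sample_id), score (height)."""
    summits: list[Summit] = []
    with open(path) as fh:
        for n, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputFormatError(f"{path}:{n}: expected >=3 BED columns")
            try:
                pos = int(parts[1])
                height = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            except ValueError as e:
                raise InputFormatError(f"{path}:{n}: malformed BED line") from e
            name = sample_id or (parts[3] if len(parts) > 3 else "")
            summits.append(Summit(parts[0], pos, height, name))
    return summits


def read_summits_narrowpeak(path: str | Path, sample_id: str | None = None) -> list[Summit]:
    """ENCODE narrowPeak: summit position = start + 10th-column offset."""
    summits: list[Summit] = []
    with open(path) as fh:
        for n, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 10:
                raise InputFormatError(f"{path}:{n}: narrowPeak needs 10 columns")
            try:
                start, offset = int(parts[1]), int(parts[9])
                height = float(parts[6])
            except ValueError as e:
                raise InputFormatError(f"{path}:{n}: malformed narrowPeak line") from e
            if offset < 0:
                raise InputFormatError(f"{path}:{n}: negative summit offset")
            name = sample_id or parts[3]
            summits.append(Summit(parts[0], start + offset, height, name))
    return summits


def write_peaks_bed(peaks: Sequence[ReconciledPeak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in sorted(peaks, key=lambda p: (p.chrom, p.pos)):
            name = "|".join(sorted(p.provenance)) or "."
            fh.write(f"{p.chrom}\t{p.pos}\t{p.pos + 1}\t{name}\t{p.height:g}\t.\n")


def peaks_to_frame(peaks: Sequence[ReconciledPeak]) -> pd.DataFrame:
    rows = [
        {
            "chrom": p.chrom,
            "pos": p.pos,
            "height": p.height,
            "n_members": len(p.members),
            "provenance": "|".join(sorted(p.provenance)),
            "sources": "|".join(sorted(p.sources)),
        }
        for p in sorted(peaks, key=lambda p: (p.chrom, p.pos))
    ]
    return pd.DataFrame(rows, columns=["chrom", "pos", "height", "n_members", "provenance", "sources"])


def assignments_to_frame(assignments: Sequence[PromoterAssignment]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": a.gene_id,
            "chrom": a.peak.chrom,
            "pos": a.peak.pos,
            "distance_to_atg": a.distance,
            "height": a.peak.height,
        }
        for a in sorted(assignments, key=lambda a: (a.gene_id, a.peak.chrom, a.peak.pos))
    ]
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "pos", "distance_to_atg", "height"]
    )


def apply_site_edits(
    peaks: Sequence[ReconciledPeak],
    allowlist: Sequence[Summit] = (),
    denylist: Sequence[Summit] = (),
    tol: int = 0,
) -> list[ReconciledPeak]:
    """Explicit replacement for interactive browser-based peak rescue.

    Allowlisted positions are appended as single-member peaks; peaks within
    ``tol`` bp of a denylisted position are dropped.
    """
    deny = {(s.chrom, s.pos) for s in denylist}

    def denied(p: ReconciledPeak) -> bool:
        return any(c == p.chrom and abs(q - p.pos) <= tol for c, q in deny)

    kept = [p for p in peaks if not denied(p)]
    for s in allowlist:
        kept.append(
            ReconciledPeak(
                s.chrom, s.pos, (s,), frozenset({s.sample_id or "allowlist"}),
                frozenset({"allowlist"}),
            )
        )
    kept.sort(key=lambda p: (p.chrom, p.pos))
    return kept
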