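"""ChIP occupancy quantification.

Reads are single 5'-position records; each is extended to a fixed fragment
size (default 200 bp, the typical sonicated-fragment length), piled up, and
normalized to an FPKM-style density: every fragment contributes
``10^9 / (total_mapped * fragment_length)`` to each base it covers, so a
region exactly tiled by C fragments of its own length reads C x 10^9 /
(L x N) — fragments per kilobase per million mapped reads.  The density is
independent of the bin size used to store it.

A raw depth track (fragments covering each base) is kept alongside for
book-keeping checks: sum over bins of mean depth x bin length equals the
total fragment-genome overlap length exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .errors import InputFormatError
from .genome import GenomicInterval


@dataclass(frozen=True)
class ReadStart:
    """A mapped read reduced to its 5' position and strand."""

    chrom: str
    five_prime_pos: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("read strand must be '+' or '-'")
        if self.five_prime_pos < 0:
            raise ValueError("read position must be >= 0")


@dataclass
class CoverageTrack:
    """Binned per-chromosome signal (mean per-base value within each bin)."""

    values: dict  # chrom -> np.ndarray of per-bin means
    bin_size: int
    total_mapped: int
    units: str = "FPKM"

    def chrom_len(self, chrom: str) -> int:
        # lengths are remembered at build time
        return self._chrom_lens[chrom]


def extend_reads(
    reads: Sequence[ReadStart],
    extsize: int = 200,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[GenomicInterval]:
    """Extend 5' read positions to ``extsize``-bp fragments, clipped.

    Plus-strand reads extend rightward from the 5' base; minus-strand reads
    extend leftward so that the 5' base is the fragment's last base.
    """
    if extsize < 1:
        raise ValueError("extsize must be >= 1")
    frags: list[GenomicInterval] = []
    for r in reads:
        if r.strand == "+":
            lo, hi = r.five_prime_pos, r.five_prime_pos + extsize
        else:
            lo, hi = r.five_prime_pos - extsize + 1, r.five_prime_pos + 1
        lo = max(0, lo)
        if chrom_sizes is not None:
            hi = min(hi, chrom_sizes[r.chrom])
        if hi > lo:
            frags.append(GenomicInterval(r.chrom, lo, hi))
    return frags


def _binned_track(
    fragments: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    bin_size: int,
    weight_fn,
) -> dict:
    values: dict = {}
    by_chrom: dict[str, list[GenomicInterval]] = {c: [] for c in chrom_sizes}
    for f in fragments:
        if f.chrom not in by_chrom:
            raise InputFormatError(f"fragment on unknown chromosome {f.chrom!r}")
        by_chrom[f.chrom].append(f)
    for chrom, clen in chrom_sizes.items():
        diff = np.zeros(clen + 1)
        for f in by_chrom[chrom]:
            w = weight_fn(f)
            diff[f.lo] += w
            diff[f.hi] -= w
        base = np.cumsum(diff[:-1])
        n_bins = -(-clen // bin_size)
        padded = np.zeros(n_bins * bin_size)
        padded[:clen] = base
        sums = padded.reshape(n_bins, bin_size).sum(axis=1)
        lens = np.full(n_bins, bin_size, dtype=float)
        if clen % bin_size:
            lens[-1] = clen % bin_size
        values[chrom] = sums / lens  # mean per-base value in each bin
    return values


def pileup_depth(
    fragments: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    bin_size: int = 10,
) -> CoverageTrack:
    """Raw fragment depth per bin (mean fragments covering each base)."""
    track = CoverageTrack(
        values=_binned_track(fragments, chrom_sizes, bin_size, lambda f: 1.0),
        bin_size=bin_size,
        total_mapped=len(fragments),
        units="depth",
    )
    track._chrom_lens = dict(chrom_sizes)
    return track


def pileup_fpkm(
    fragments: Sequence[GenomicInterval],
    total_mapped: int,
    chrom_sizes: Mapping[str, int],
    bin_size: int = 10,
) -> CoverageTrack:
    """FPKM-normalized pileup of extended fragments.

    Per-base signal is the sum over covering fragments of
    10^9 / (total_mapped x fragment_length); bins store per-base means.
    """
    if total_mapped < 1:
        raise ValueError("total_mapped must be >= 1")
    track = CoverageTrack(
        values=_binned_track(
            fragments, chrom_sizes, bin_size, lambda f: 1e9 / (total_mapped * len(f))
        ),
        bin_size=bin_size,
        total_mapped=total_mapped,
        units="FPKM",
    )
    track._chrom_lens = dict(chrom_sizes)
    return track


def window_signal(track: CoverageTrack, interval: GenomicInterval) -> float:
    """Length-weighted mean signal over an interval.

    Each bin contributes its value weighted by its overlap with the
    interval, so for bin_size=1 this equals the per-base mean exactly.
    """
    if len(interval) == 0:
        raise ValueError("empty interval")
    vals = track.values[interval.chrom]
    bs = track.bin_size
    first = interval.lo // bs
    last = (interval.hi - 1) // bs
    total = 0.0
    for b in range(first, last + 1):
        b_lo, b_hi = b * bs, (b + 1) * bs
        ov = min(b_hi, interval.hi) - max(b_lo, interval.lo)
        total += vals[b] * ov
    return total / len(interval)


def signal_matrix(
    track: CoverageTrack,
    summits: Sequence,  # objects with .chrom and .pos
    flank: int = 1500,
) -> np.ndarray:
    """Per-summit signal profiles over +/-``flank`` bp, one row per summit.

    Rows are per-bin values across the window (the heatmap input); windows
    are clipped at chromosome ends with missing bins set to 0.
    """
    bs = track.bin_size
    n_bins = (2 * flank) // bs
    mat = np.zeros((len(summits), n_bins))
    for i, s in enumerate(summits):
        vals = track.values[s.chrom]
        start_bin = (s.pos - flank) // bs
        for k in range(n_bins):
            b = start_bin + k
            if 0 <= b < len(vals):
                mat[i, k] = vals[b]
    return mat


class OccupancyComparison(NamedTuple):
    statistic: float
    pvalue: float
    degenerate: bool = False


def compare_occupancy(group_a: Sequence[float], group_b: Sequence[float]) -> OccupancyComparison:
    """Welch two-sample t test between two sets of occupancy values.

    Zero-variance degenerate inputs are resolved deterministically rather
    than erroring: p=1 when the constant groups share a mean, p=0 when they
    differ, with the ``degenerate`` flag raised.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    var_a = a.var(ddof=1) if a.size > 1 else 0.0
    var_b = b.var(ddof=1) if b.size > 1 else 0.0
    if var_a == 0.0 and var_b == 0.0:
        if np.isclose(a.mean(), b.mean()):
            return OccupancyComparison(0.0, 1.0, True)
        sign = 1.0 if a.mean() > b.mean() else -1.0
        return OccupancyComparison(sign * np.inf, 0.0, True)
    if a.size < 2 or b.size < 2:
        raise ValueError("groups with nonzero variance need >= 2 values each")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return OccupancyComparison(float(t), float(p), False)


# ---------------------------------------------------------------------------
# I/O


def read_read_starts(path) -> list[ReadStart]:
    """BED6 of read 5' positions (chrom, pos, pos+1, name, score, strand)."""
    reads: list[ReadStart] = []
    with open(path) as fh:
        for n, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise InputFormatError(f"{path}:{n}: read BED needs 6 columns")
            try:
                reads.append(ReadStart(parts[0], int(parts[1]), parts[5]))
            except ValueError as e:
                raise InputFormatError(f"{path}:{n}: malformed read line") from e
    return reads


def write_read_starts(reads: Sequence[ReadStart], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"{r.chrom}\t{r.five_prime_pos}\t{r.five_prime_pos + 1}\tread\t0\t{r.strand}\n")


def write_bedgraph(track: CoverageTrack, path) -> None:
    """bedGraph dump of a track (one line per bin, zero bins skipped)."""
    bs = track.bin_size
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            vals = track.values[chrom]
            clen = track.chrom_len(chrom)
            for b, v in enumerate(vals):
                if v != 0:
                    fh.write(f"{chrom}\t{b * bs}\t{min((b + 1) * bs, clen)}\t{v:.6g}\n")
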