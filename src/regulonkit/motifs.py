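"""IUPAC degenerate motif scanning around ChIP-seq summits.

The repressor's recognition site SYGGRG (S=C/G, Y=C/T, R=A/G) and related
CGGG-core consensus patterns are scanned — not discovered — on both strands.
Matches may overlap; minus-strand matches are reported in plus-strand
coordinates (offset of the match's leftmost base).  An ``N`` in the scanned
sequence matches only an ``N`` motif position.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputFormatError

IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

# complement over the full degenerate alphabet
IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


@dataclass(frozen=True)
class IupacMotif:
    name: str
    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty motif pattern")
        bad = set(self.pattern.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC code(s) {sorted(bad)} in {self.pattern!r}")
        object.__setattr__(self, "pattern", self.pattern.upper())

    def __len__(self) -> int:
        return len(self.pattern)

    def reverse_complement(self) -> "IupacMotif":
        rc = "".join(IUPAC_COMPLEMENT[c] for c in reversed(self.pattern))
        return IupacMotif(self.name, rc)


@dataclass(frozen=True)
class MotifHit:
    offset: int  # 0-based start on the + strand
    strand: str
    chrom: str = ""


def expand_iupac(pattern: str) -> set[str]:
    """All exact ACGT words matching a degenerate pattern."""
    pattern = pattern.upper()
    bad = set(pattern) - set(IUPAC)
    if bad:
        raise ValueError(f"invalid IUPAC code(s) {sorted(bad)}")
    words = [""]
    for c in pattern:
        words = [w + b for w in words for b in IUPAC[c]]
    return set(words)


def _regex(pattern: str) -> re.Pattern:
    # N in the motif also matches N in the sequence; other codes never do
    parts = []
    for c in pattern:
        opts = IUPAC[c] + ("N" if c == "N" else "")
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile(f"(?=({''.join(parts)}))")  # lookahead -> overlapping hits


def scan_sequence(
    seq: str,
    motif: IupacMotif,
    both_strands: bool = True,
    chrom: str = "",
) -> list[MotifHit]:
    """All (possibly overlapping) motif matches in a sequence.

    Minus-strand matches are found by scanning the reverse-complement
    pattern on the forward sequence; their offsets are + strand coordinates
    of the leftmost matched base.
    """
    seq = seq.upper()
    hits = [
        MotifHit(m.start(), "+", chrom) for m in _regex(motif.pattern).finditer(seq)
    ]
    if both_strands:
        rc = motif.reverse_complement()
        hits += [
            MotifHit(m.start(), "-", chrom) for m in _regex(rc.pattern).finditer(seq)
        ]
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def count_in_window(
    summit_pos: int,
    seq: str,
    motif: IupacMotif,
    window: int = 100,
    both_strands: bool = True,
) -> int:
    """Motif occurrences in a ``window``-bp window spanning a summit.

    The window covers [summit - window//2, summit - window//2 + window),
    clipped at sequence ends; a hit counts when its start lies inside.
    """
    w_lo = max(0, summit_pos - window // 2)
    w_hi = min(len(seq), summit_pos - window // 2 + window)
    if w_hi <= w_lo:
        return 0
    # scan a margin so matches starting near w_hi are still visible
    s_hi = min(len(seq), w_hi + len(motif) - 1)
    region = seq[w_lo:s_hi]
    return sum(1 for h in scan_sequence(region, motif, both_strands) if w_lo + h.offset < w_hi)


def motif_presence_matrix(
    peaks: Sequence,  # objects with .chrom and .pos
    genome: Mapping[str, str],
    motifs: Sequence[IupacMotif],
    window: int = 100,
) -> pd.DataFrame:
    """Per-peak presence/absence flags for each motif plus ``any_motif``."""
    if not motifs:
        raise ValueError("motifs must be nonempty")
    rows = []
    for p in peaks:
        seq = genome[p.chrom]
        row = {"chrom": p.chrom, "pos": p.pos}
        for m in motifs:
            row[m.name] = count_in_window(p.pos, seq, m, window) > 0
        rows.append(row)
    df = pd.DataFrame(rows, columns=["chrom", "pos"] + [m.name for m in motifs])
    df["any_motif"] = df[[m.name for m in motifs]].any(axis=1)
    return df


def motif_frequency_profile(
    peaks: Sequence,
    genome: Mapping[str, str],
    motif: IupacMotif,
    span: int = 1000,
    bin: int = 20,
) -> pd.DataFrame:
    """Positional motif frequency across summit-centered windows.

    For each offset bin across a ``span``-bp window centered on the summits,
    the fraction of peaks with at least one hit starting in that bin.
    Mirrors a motif-density metaplot over binding sites.
    """
    if len(peaks) == 0:
        raise ValueError("peaks must be nonempty")
    if span % 2 != 0:
        raise ValueError("span must be even")
    n_bins = span // bin
    counts = np.zeros(n_bins)
    for p in peaks:
        seq = genome[p.chrom]
        lo = p.pos - span // 2
        s_lo = max(0, lo)
        s_hi = min(len(seq), lo + span + len(motif) - 1)
        present = np.zeros(n_bins, dtype=bool)
        for h in scan_sequence(seq[s_lo:s_hi], motif):
            off = s_lo + h.offset - lo  # offset within the window, 0..span-1
            if 0 <= off < span:
                present[off // bin] = True
        counts += present
    offsets = np.arange(n_bins) * bin - span // 2
    return pd.DataFrame(
        {"offset": offsets, "frequency": counts / len(peaks)}
    )


# ---------------------------------------------------------------------------
# I/O

#: default motif table: the established recognition motif plus two
#: CGGG-core consensus stand-ins (synthetic IUPAC approximations of
#: secondary motifs that are published only as sequence logos)
DEFAULT_MOTIFS = (
    IupacMotif("SYGGRG", "SYGGRG"),
    IupacMotif("motif2", "YCGGGG"),
    IupacMotif("motif4", "CGGGWR"),
)


def read_motif_table(path: str | Path) -> list[IupacMotif]:
    """Motifs from a 2-column TSV: name, IUPAC pattern."""
    motifs: list[IupacMotif] = []
    with open(path) as fh:
        for n, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise InputFormatError(f"{path}:{n}: expected name<TAB>pattern")
            try:
                motifs.append(IupacMotif(parts[0], parts[1]))
            except ValueError as e:
                raise InputFormatError(f"{path}:{n}: {e}") from e
    return motifs


def write_hits_bed(hits: Sequence[MotifHit], motif: IupacMotif, path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.chrom}\t{h.offset}\t{h.offset + len(motif)}\t{motif.name}\t0\t{h.strand}\n"
            )


def load_genome_fasta(path: str | Path) -> dict[str, str]:
    """Whole-genome FASTA into a chrom -> sequence dict (via pyfaidx)."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}
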