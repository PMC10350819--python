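"""iCLIP crosslink-track normalization/smoothing and G-quadruplex motif scanning.

Crosslink tracks are per-position counts over a strand-specific genomic
window (0-based half-open, bedGraph conventions).  Normalization scales to
crosslinks per million library crosslinks; smoothing is a centered rolling
mean with a shrinking window at the edges (positions closer than half a
window to an edge average over the positions that exist).

The G4 scanner enumerates windows holding four G-tracts of at least
``min_tract`` consecutive G's within ``max_len`` nt, then resolves
overlapping candidates to the highest-scoring non-overlapping set.  The
score is QGRS-style — longer tracts dominate, then even and short loops —
but is a documented variant: motif presence and tract structure are the
contract, not any external tool's numeric score.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "CrosslinkTrack",
    "read_bedgraph",
    "write_bedgraph",
    "normalize_track",
    "smooth_track",
    "G4Motif",
    "g4_candidates",
    "scan_g4",
    "motifs_to_frame",
]


@dataclass
class CrosslinkTrack:
    """Per-position crosslink counts over one strand-specific window."""

    chrom: str
    strand: str
    start: int
    end: int
    counts: np.ndarray
    library_size: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.end - self.start != len(self.counts):
            raise ValueError(
                f"window length {self.end - self.start} != counts length {len(self.counts)}"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.library_size < int(self.counts.sum()):
            raise ValueError("library_size must be at least the window's total counts")


def read_bedgraph(
    path: str | Path, chrom: str, start: int, end: int, strand: str, library_size: int
) -> CrosslinkTrack:
    """Load a window from a 4-column bedGraph (chrom, start, end, value; 0-based half-open)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": int, "end": int, "value": float},
    )
    counts = np.zeros(end - start, dtype=float)
    sel = df[(df["chrom"] == chrom) & (df["end"] > start) & (df["start"] < end)]
    for r in sel.itertuples():
        s, e = max(r.start, start), min(r.end, end)
        counts[s - start : e - start] += r.value
    return CrosslinkTrack(
        chrom=chrom, strand=strand, start=start, end=end,
        counts=counts, library_size=library_size,
    )


def write_bedgraph(track: CrosslinkTrack, path: str | Path, values=None) -> Path:
    """Write a track (or replacement per-position values) as bedGraph; zero runs skipped."""
    vals = track.counts if values is None else np.asarray(values)
    path = Path(path)
    with open(path, "w") as fh:
        for i, v in enumerate(vals):
            if v != 0:
                pos = track.start + i
                fh.write(f"{track.chrom}\t{pos}\t{pos + 1}\t{v:g}\n")
    return path


def normalize_track(track: CrosslinkTrack) -> np.ndarray:
    """Crosslinks per million: counts * 1e6 / library_size."""
    if track.library_size <= 0:
        raise ValueError("library_size must be > 0 for normalization")
    return track.counts.astype(float) * 1e6 / track.library_size


def smooth_track(values: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered rolling mean with shrinking windows at the edges.

    ``window`` must be odd; window 1 is the identity and a window larger
    than the vector yields the global mean everywhere.
    """
    values = np.asarray(values, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    if window > len(values):
        return np.full_like(values, values.mean() if len(values) else 0.0)
    return (
        pd.Series(values).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


# ---------------------------------------------------------------------------
# G-quadruplex scanning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class G4Motif:
    """One G-quadruplex candidate: four equal-length G-tracts and three loops."""

    start: int
    end: int
    tract_starts: tuple[int, int, int, int]
    tract_length: int
    loops: tuple[int, int, int]
    score: float

    def __post_init__(self) -> None:
        if self.tract_length < 2:
            raise ValueError("G-tracts must be at least 2 nt")
        if any(l < 0 for l in self.loops):
            raise ValueError("loops must be >= 0")


def _score(tract_length: int, loops: tuple[int, int, int]) -> float:
    # Longer tracts dominate (weight 100 per nt, so no loop geometry can
    # outrank a longer-tract candidate); among equal tracts, prefer even
    # loops (spread penalty) and then compact motifs (total-loop penalty).
    return 100.0 * tract_length - 2.0 * (max(loops) - min(loops)) - sum(loops)


def _g_run_starts(seq: str, g: int) -> list[int]:
    """All positions i where seq[i:i+g] is g consecutive G's."""
    return [i for i in range(len(seq) - g + 1) if seq[i : i + g] == "G" * g]


def g4_candidates(
    sequence: str, min_tract: int = 2, max_len: int = 30, max_loop: int = 36
) -> Iterator[G4Motif]:
    """Enumerate every 4-tract candidate (all tract lengths, all placements).

    Tracts are runs of exactly ``tract_length`` G's (taken anywhere within
    longer runs); loops are the gaps between consecutive tracts, each in
    [0, max_loop]; the whole motif spans at most ``max_len`` nt.  U is not
    G and N breaks tracts, so RNA and masked sequences scan unchanged.
    """
    from bisect import bisect_left, bisect_right

    seq = sequence.upper().replace("U", "T")
    n = len(seq)
    max_g = min(max_len // 4, n)
    for g in range(min_tract, max_g + 1):
        starts = _g_run_starts(seq, g)
        if len(starts) < 4:
            continue

        def successors(prev: int, limit: int) -> list[int]:
            # tract starts following the tract at `prev` within the window
            lo = bisect_left(starts, prev + g)
            hi = bisect_right(starts, min(limit - g, prev + g + max_loop))
            return starts[lo:hi]

        for a in starts:
            limit = a + max_len
            for b in successors(a, limit):
                for c in successors(b, limit):
                    for d in successors(c, limit):
                        loops = (b - (a + g), c - (b + g), d - (c + g))
                        yield G4Motif(
                            start=a,
                            end=d + g,
                            tract_starts=(a, b, c, d),
                            tract_length=g,
                            loops=loops,
                            score=_score(g, loops),
                        )


def scan_g4(
    sequence: str, min_tract: int = 2, max_len: int = 30, max_loop: int = 36
) -> list[G4Motif]:
    """Highest-scoring non-overlapping G4 motifs in a sequence.

    Candidates from :func:`g4_candidates` are sorted by score (descending),
    then by span length (ascending) and start (ascending) as tie-breaks,
    and kept greedily when they do not overlap an already-kept motif.
    """
    cands = list(g4_candidates(sequence, min_tract=min_tract, max_len=max_len, max_loop=max_loop))
    cands.sort(key=lambda m: (-m.score, m.end - m.start, m.start))
    kept: list[G4Motif] = []
    for m in cands:
        if all(m.end <= k.start or m.start >= k.end for k in kept):
            kept.append(m)
    kept.sort(key=lambda m: m.start)
    return kept


def motifs_to_frame(motifs: list[G4Motif]) -> pd.DataFrame:
    """Motif list as a TSV-ready table (start, end, tract columns, loops, score)."""
    return pd.DataFrame(
        [
            {
                "start": m.start,
                "end": m.end,
                "tract_length": m.tract_length,
                "tract_starts": ",".join(map(str, m.tract_starts)),
                "loops": ",".join(map(str, m.loops)),
                "score": m.score,
            }
            for m in motifs
        ],
        columns=["start", "end", "tract_length", "tract_starts", "loops", "score"],
    )
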