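"""Fragment-to-coverage conversion, bedgraph I/O, and track merging.

The MNase-seq coverage convention used throughout: after selecting
nucleosome-sized fragments (130-200 bp inclusive), only the 3 bases at
the centre of each fragment contribute coverage, at 1-bp resolution.
Tracks are stored run-length-encoded per chromosome and serialised as
4-column bedgraph (0-based half-open).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Conventional effective genome size for mouse mm10 (deeptools value for
#: 50-bp reads).  It cancels after per-promoter sum-normalization and is
#: retained only so raw tracks from different depths are comparable.
MM10_EFFECTIVE_GENOME_SIZE = 2_652_783_500

FRAGMENT_COLUMNS = ["chrom", "start", "end"]


class CoverageError(ValueError):
    """Raised for invalid fragments, tracks, or bedgraph input."""


def fragments_frame(records: Iterable[tuple[str, int, int]]) -> pd.DataFrame:
    """Build a validated fragment table from (chrom, start, end) records."""
    df = pd.DataFrame(list(records), columns=FRAGMENT_COLUMNS)
    return validate_fragments(df)


def validate_fragments(frags: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in FRAGMENT_COLUMNS if c not in frags.columns]
    if missing:
        raise CoverageError(f"fragment table missing column(s) {missing}")
    if len(frags) and not (frags["end"] > frags["start"]).all():
        bad = frags.index[frags["end"] <= frags["start"]][0]
        raise CoverageError(f"fragment at index {bad} has end <= start")
    return frags


def read_fragments_bed(path: str | Path) -> pd.DataFrame:
    """Read fragments from a 3-column BED file (one line per fragment)."""
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                     names=FRAGMENT_COLUMNS,
                     dtype={"chrom": str, "start": np.int64, "end": np.int64})
    return validate_fragments(df)


def write_fragments_bed(frags: pd.DataFrame, path: str | Path) -> None:
    frags[FRAGMENT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


@dataclass
class CoverageTrack:
    """Per-chromosome 1-bp coverage, run-length encoded.

    ``runs`` maps chromosome -> DataFrame(start, end, value) with sorted,
    non-overlapping half-open intervals and non-negative values.  Bases
    not covered by any run have value 0.
    """

    runs: dict[str, pd.DataFrame] = field(default_factory=dict)
    scale_note: str = "raw"

    def chroms(self) -> list[str]:
        return sorted(self.runs)

    def total_mass(self) -> float:
        total = 0.0
        for df in self.runs.values():
            total += float(((df["end"] - df["start"]) * df["value"]).sum())
        return total

    def dense(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values over [start, end); uncovered bases are 0."""
        out = np.zeros(end - start, dtype=float)
        df = self.runs.get(chrom)
        if df is None or not len(df):
            return out
        s = df["start"].to_numpy()
        e = df["end"].to_numpy()
        v = df["value"].to_numpy()
        lo = np.searchsorted(e, start, side="right")
        hi = np.searchsorted(s, end, side="left")
        a = np.clip(s[lo:hi], start, end).astype(np.int64) - start
        b = np.clip(e[lo:hi], start, end).astype(np.int64) - start
        lengths = b - a
        keep = lengths > 0
        a, lengths, vals = a[keep], lengths[keep], v[lo:hi][keep]
        # exact per-base assignment (runs are disjoint): expand each run
        total = int(lengths.sum())
        run_origin = np.repeat(np.cumsum(lengths) - lengths, lengths)
        pos = np.repeat(a, lengths) + (np.arange(total) - run_origin)
        out[pos] = np.repeat(vals, lengths)
        return out

    def scaled(self, factor: float, scale_note: str | None = None) -> "CoverageTrack":
        runs = {
            c: df.assign(value=df["value"] * factor)
            for c, df in self.runs.items()
        }
        return CoverageTrack(runs, scale_note or self.scale_note)

    @staticmethod
    def from_dense(chrom_arrays: dict[str, np.ndarray],
                   scale_note: str = "raw") -> "CoverageTrack":
        """Run-length encode dense per-base arrays (zero runs are dropped)."""
        runs: dict[str, pd.DataFrame] = {}
        for chrom, arr in chrom_arrays.items():
            arr = np.asarray(arr, dtype=float)
            if np.any(arr < 0):
                raise CoverageError(f"{chrom}: negative coverage value")
            runs[chrom] = _rle(arr, offset=0)
        return CoverageTrack(runs, scale_note)


def _rle(arr: np.ndarray, offset: int) -> pd.DataFrame:
    """Collapse a dense array into (start, end, value) runs, omitting zeros."""
    if arr.size == 0:
        return pd.DataFrame(columns=["start", "end", "value"])
    change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [arr.size]))
    vals = arr[starts]
    keep = vals != 0
    return pd.DataFrame({
        "start": starts[keep] + offset,
        "end": ends[keep] + offset,
        "value": vals[keep],
    }).reset_index(drop=True)


def size_filter(frags: pd.DataFrame, min_len: int = 130,
                max_len: int = 200) -> pd.DataFrame:
    """Retain fragments with min_len <= length <= max_len (both inclusive).

    The 130-200 bp default keeps mononucleosome-sized MNase fragments.
    """
    if min_len > max_len:
        raise CoverageError(f"min_len {min_len} > max_len {max_len}")
    validate_fragments(frags)
    length = frags["end"] - frags["start"]
    return frags[(length >= min_len) & (length <= max_len)].reset_index(drop=True)


def center_coverage(frags: pd.DataFrame,
                    chrom_sizes: dict[str, int] | None = None) -> CoverageTrack:
    """1-bp coverage from the 3 central bases of each fragment.

    The fragment centre is c = floor((start+end)/2) (right-of-middle base
    for even lengths); positions c-1, c, c+1 each gain +1.  Contributions
    falling below 0 (or past the chromosome end, when sizes are given)
    are truncated with a warning.
    """
    validate_fragments(frags)
    dense: dict[str, np.ndarray] = {}
    truncated = 0
    for chrom, sub in frags.groupby("chrom", sort=True):
        start = sub["start"].to_numpy(np.int64)
        end = sub["end"].to_numpy(np.int64)
        c = (start + end) // 2
        pos = np.concatenate([c - 1, c, c + 1])
        size = chrom_sizes.get(str(chrom)) if chrom_sizes else None
        if size is None:
            size = int(pos.max()) + 1 if pos.size else 0
        ok = (pos >= 0) & (pos < size)
        truncated += int((~ok).sum())
        arr = np.bincount(pos[ok], minlength=size).astype(float)
        dense[str(chrom)] = arr
    if truncated:
        logger.warning("center_coverage: %d centre bases truncated at "
                       "chromosome edges", truncated)
    return CoverageTrack.from_dense(dense, scale_note="raw")


def genome_normalize(track: CoverageTrack,
                     effective_genome_size: int = MM10_EFFECTIVE_GENOME_SIZE
                     ) -> CoverageTrack:
    """Scale a track to 1x genome depth: multiply by G / total mass."""
    mass = track.total_mass()
    if mass <= 0:
        raise CoverageError("cannot normalize a track with zero total signal")
    return track.scaled(effective_genome_size / mass, scale_note="genome-normalized")


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a track as 4-column bedgraph, run-length collapsed.

    Values are printed with ``repr`` so the read/write round trip is
    bit-faithful for double-precision values.
    """
    with open(path, "w") as fh:
        for chrom in track.chroms():
            df = track.runs[chrom]
            for s, e, v in zip(df["start"], df["end"], df["value"]):
                fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{v!r}\n")


def read_bedgraph(path: str | Path) -> CoverageTrack:
    """Read a 4-column bedgraph; rejects overlapping or unsorted intervals."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"],
                     dtype={"chrom": str, "start": np.int64,
                            "end": np.int64, "value": float},
                     float_precision="round_trip")
    runs: dict[str, pd.DataFrame] = {}
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.reset_index(drop=True)
        if not (sub["end"] > sub["start"]).all():
            raise CoverageError(f"{path}: empty or inverted interval on {chrom}")
        if len(sub) > 1:
            if not (sub["start"].to_numpy()[1:] >= sub["end"].to_numpy()[:-1]).all():
                raise CoverageError(
                    f"{path}: overlapping or unsorted intervals on {chrom}")
        if (sub["value"] < 0).any():
            raise CoverageError(f"{path}: negative coverage on {chrom}")
        runs[str(chrom)] = sub[["start", "end", "value"]].copy()
    return CoverageTrack(runs)


def merge_tracks(tracks: Sequence[CoverageTrack],
                 names: Sequence[str] | None = None) -> pd.DataFrame:
    """Combine tracks into a per-base matrix, one column per sample.

    Restores the 1-bp window size of run-length tracks: the output has
    one row per base in the union of covered bases (unionbedg dialect:
    chrom, start, end=start+1, then one value column per sample; bases a
    sample does not cover get 0).
    """
    if names is None:
        names = [f"sample_{i}" for i in range(len(tracks))]
    if len(names) != len(tracks):
        raise CoverageError("names and tracks length mismatch")
    chroms = sorted({c for t in tracks for c in t.runs})
    parts: list[pd.DataFrame] = []
    for chrom in chroms:
        lo, hi = None, None
        for t in tracks:
            df = t.runs.get(chrom)
            if df is not None and len(df):
                lo = int(df["start"].min()) if lo is None else min(lo, int(df["start"].min()))
                hi = int(df["end"].max()) if hi is None else max(hi, int(df["end"].max()))
        if lo is None:
            continue
        cols = {n: t.dense(chrom, lo, hi) for n, t in zip(names, tracks)}
        cov = np.zeros(hi - lo + 1, dtype=np.int64)
        for t in tracks:
            df = t.runs.get(chrom)
            if df is None or not len(df):
                continue
            np.add.at(cov, df["start"].to_numpy() - lo, 1)
            np.add.at(cov, df["end"].to_numpy() - lo, -1)
        covered = np.cumsum(cov[:-1]) > 0
        pos = np.flatnonzero(covered) + lo
        part = pd.DataFrame({"chrom": chrom, "start": pos, "end": pos + 1})
        for n in names:
            part[n] = cols[n][pos - lo]
        parts.append(part)
    if not parts:
        return pd.DataFrame(columns=["chrom", "start", "end", *names])
    return pd.concat(parts, ignore_index=True)


def fragment_size_histogram(frags: pd.DataFrame) -> pd.Series:
    """Exact counts per integer fragment length, ascending index.

    On MNase digests this is the mono/di-nucleosome size distribution
    (modes near ~150 and ~300 bp).
    """
    validate_fragments(frags)
    length = (frags["end"] - frags["start"]).astype(int)
    return length.value_counts().sort_index()
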