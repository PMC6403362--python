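"""Strand-aware base-resolution coverage tracks backed by run-length runs.

A :class:`CoverageTrack` stores, per ``(chrom, strand)``, sorted disjoint
runs ``[start, end) -> value`` (implicit zero elsewhere), the library size
and a normalization state (``raw`` / ``RPM`` / ``RPKM``) that is recorded
once and guarded against double application. bedGraph is the on-disk form;
integer-valued tracks round-trip bit-identically.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .intervals import GenomicInterval

log = logging.getLogger(__name__)

Key = tuple[str, str]  # (chrom, strand)


@dataclass
class _Runs:
    starts: np.ndarray  # int64, sorted
    ends: np.ndarray
    values: np.ndarray  # float64, non-negative


@dataclass
class CoverageTrack:
    runs: dict[Key, _Runs] = field(default_factory=dict)
    library_size: int = 0
    normalization: str = "raw"
    stranded: bool = True

    _warned_unstranded: bool = field(default=False, repr=False)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_sites(
        cls, sites: dict[Key, np.ndarray], library_size: int, stranded: bool = True
    ) -> "CoverageTrack":
        """Build a count track from arrays of single-base positions."""
        track = cls(library_size=library_size, stranded=stranded)
        for key, pos in sites.items():
            pos = np.asarray(pos, dtype=np.int64)
            pos = pos[pos >= 0]
            if pos.size == 0:
                continue
            uniq, counts = np.unique(pos, return_counts=True)
            track.runs[key] = _Runs(uniq, uniq + 1, counts.astype(float))
        return track

    @classmethod
    def from_array(
        cls, chrom: str, strand: str, arr: np.ndarray, library_size: int, offset: int = 0
    ) -> "CoverageTrack":
        """Build a track from a dense per-base array (zeros are dropped)."""
        track = cls(library_size=library_size, stranded=strand != ".")
        arr = np.asarray(arr, dtype=float)
        if np.any(arr < 0):
            raise ValueError("negative coverage values")
        # run-length encode
        change = np.flatnonzero(np.diff(arr) != 0) + 1
        bounds = np.concatenate(([0], change, [arr.size]))
        starts, ends, values = [], [], []
        for a, b in zip(bounds[:-1], bounds[1:]):
            v = arr[a]
            if v != 0:
                starts.append(a + offset)
                ends.append(b + offset)
                values.append(v)
        if starts:
            track.runs[(chrom, strand)] = _Runs(
                np.array(starts, dtype=np.int64),
                np.array(ends, dtype=np.int64),
                np.array(values, dtype=float),
            )
        return track

    def _key_for(self, chrom: str, strand: str) -> Key | None:
        if (chrom, strand) in self.runs:
            return (chrom, strand)
        if (chrom, ".") in self.runs:
            if strand != "." and not self._warned_unstranded:
                log.warning("unstranded track queried with strand %s; matching either strand", strand)
                self._warned_unstranded = True
            return (chrom, ".")
        return None

    # -- queries -----------------------------------------------------------

    def values(self, chrom: str, start: int, end: int, strand: str = ".") -> np.ndarray:
        """Dense per-base signal over ``[start, end)`` (zeros where absent)."""
        out = np.zeros(end - start, dtype=float)
        key = self._key_for(chrom, strand)
        if key is None:
            return out
        r = self.runs[key]
        i0 = int(np.searchsorted(r.ends, start, side="right"))
        i1 = int(np.searchsorted(r.starts, end, side="left"))
        for i in range(i0, i1):
            a = max(r.starts[i], start)
            b = min(r.ends[i], end)
            if b > a:
                out[a - start : b - start] = r.values[i]
        return out

    def window_sum(self, chrom: str, start: int, end: int, strand: str = ".") -> float:
        key = self._key_for(chrom, strand)
        if key is None:
            return 0.0
        r = self.runs[key]
        i0 = int(np.searchsorted(r.ends, start, side="right"))
        i1 = int(np.searchsorted(r.starts, end, side="left"))
        total = 0.0
        for i in range(i0, i1):
            a = max(r.starts[i], start)
            b = min(r.ends[i], end)
            if b > a:
                total += float(r.values[i]) * (b - a)
        return total

    def total(self) -> float:
        return float(
            sum(np.sum(r.values * (r.ends - r.starts)) for r in self.runs.values())
        )

    # -- normalization -----------------------------------------------------

    def scaled(self, factor: float, normalization: str | None = None) -> "CoverageTrack":
        out = CoverageTrack(
            library_size=self.library_size,
            normalization=normalization or self.normalization,
            stranded=self.stranded,
        )
        for key, r in self.runs.items():
            out.runs[key] = _Runs(r.starts.copy(), r.ends.copy(), r.values * factor)
        return out

    def rpm(self) -> "CoverageTrack":
        """Reads-per-million normalization; refuses to double-apply."""
        if self.normalization != "raw":
            raise ValueError(f"track already normalized ({self.normalization}); refusing to re-normalize")
        if self.library_size <= 0:
            raise ValueError("cannot RPM-normalize a track with library_size 0")
        return self.scaled(1e6 / self.library_size, normalization="RPM")

    # -- algebra -----------------------------------------------------------

    def binary_op(self, other: "CoverageTrack", fn) -> "CoverageTrack":
        """Per-base combination of two tracks (piecewise over run boundaries)."""
        out = CoverageTrack(
            library_size=self.library_size, normalization=self.normalization,
            stranded=self.stranded and other.stranded,
        )
        keys = set(self.runs) | set(other.runs)
        for key in keys:
            bounds = set()
            for trk in (self, other):
                if key in trk.runs:
                    r = trk.runs[key]
                    bounds.update(r.starts.tolist())
                    bounds.update(r.ends.tolist())
            edges = np.array(sorted(bounds), dtype=np.int64)
            if edges.size < 2:
                continue
            mids_s, mids_e = edges[:-1], edges[1:]
            va = _piecewise_values(self.runs.get(key), mids_s)
            vb = _piecewise_values(other.runs.get(key), mids_s)
            vals = fn(va, vb)
            keep = vals != 0
            if np.any(keep):
                out.runs[key] = _Runs(mids_s[keep], mids_e[keep], vals[keep].astype(float))
        return out


def _piecewise_values(r: _Runs | None, points: np.ndarray) -> np.ndarray:
    if r is None:
        return np.zeros(points.size)
    idx = np.searchsorted(r.starts, points, side="right") - 1
    vals = np.zeros(points.size)
    ok = (idx >= 0) & (points < r.ends[np.clip(idx, 0, None)])
    vals[ok] = r.values[idx[ok]]
    return vals


# ---------------------------------------------------------------------------
# bedGraph I/O
# ---------------------------------------------------------------------------

def read_bedgraph(
    paths: dict[str, str] | str,
    library_size: int | None = None,
) -> CoverageTrack:
    """Read stranded bedGraph(s) into one track.

    ``paths`` is either ``{"+": plus_path, "-": minus_path}`` for stranded
    data or a single path for a declared-unstranded track (stored under
    strand ``.``). Metadata comment lines (``# exodecay ...``) written by
    :func:`write_bedgraph` restore library size and normalization state;
    ``library_size`` overrides them. Overlapping intervals within one file
    are an error, as are negative values.
    """
    if isinstance(paths, str):
        paths = {".": paths}
    track = CoverageTrack(stranded=set(paths) != {"."})
    meta_lib, meta_norm = None, None
    for strand, path in paths.items():
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if line.startswith("# exodecay"):
                    for token in line.split()[2:]:
                        k, _, v = token.partition("=")
                        if k == "library_size":
                            meta_lib = int(v)
                        elif k == "normalization":
                            meta_norm = v
                    continue
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                if len(f) < 4:
                    raise ValueError(f"{path}:{lineno}: bedGraph line has <4 columns")
                value = float(f[3])
                if value < 0:
                    raise ValueError(f"{path}:{lineno}: negative signal value {value}")
                per_chrom.setdefault(f[0], []).append((int(f[1]), int(f[2]), value))
        for chrom, items in per_chrom.items():
            items.sort()
            starts = np.array([s for s, _, _ in items], dtype=np.int64)
            ends = np.array([e for _, e, _ in items], dtype=np.int64)
            values = np.array([v for _, _, v in items], dtype=float)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"{path}: overlapping bedGraph intervals on {chrom}")
            keep = values != 0
            track.runs[(chrom, strand)] = _Runs(starts[keep], ends[keep], values[keep])
    if library_size is not None:
        track.library_size = library_size
    elif meta_lib is not None:
        track.library_size = meta_lib
    else:
        total = track.total()
        track.library_size = int(round(total)) if total > 0 else 0
        if track.normalization == "raw" and track.library_size == 0:
            warnings.warn("empty bedGraph: library size unknown")
    if meta_norm is not None:
        track.normalization = meta_norm
    return track


def write_bedgraph(track: CoverageTrack, paths: dict[str, str] | str) -> None:
    """Write the track back to bedGraph, one file per strand.

    A ``# exodecay`` comment records library size and normalization so a
    read/write round trip preserves them.
    """
    if isinstance(paths, str):
        strands = {s for _, s in track.runs} or {"."}
        if len(strands) > 1:
            raise ValueError("stranded track needs one output path per strand")
        paths = {strands.pop(): paths}
    for strand, path in paths.items():
        with open(path, "w") as fh:
            fh.write(
                f"# exodecay library_size={track.library_size} normalization={track.normalization}\n"
            )
            keys = sorted(k for k in track.runs if k[1] == strand)
            for key in keys:
                r = track.runs[key]
                for s, e, v in zip(r.starts, r.ends, r.values):
                    sval = int(v) if float(v).is_integer() else repr(float(v))
                    fh.write(f"{key[0]}\t{s}\t{e}\t{sval}\n")


def read_signal(
    plus: str | None = None,
    minus: str | None = None,
    unstranded: str | None = None,
    library_size: int | None = None,
) -> CoverageTrack:
    """Convenience wrapper: stranded pair or declared-unstranded single file."""
    if unstranded is not None:
        if plus or minus:
            raise ValueError("give either an unstranded path or a stranded pair, not both")
        return read_bedgraph(unstranded, library_size)
    paths: dict[str, str] = {}
    if plus:
        paths["+"] = plus
    if minus:
        paths["-"] = minus
    if not paths:
        raise ValueError("no signal paths given")
    return read_bedgraph(paths, library_size)


def reads_to_coverage(
    reads: list, library_size: int | None = None
) -> CoverageTrack:
    """Pile up BED6 read intervals into a stranded count track."""
    from .intervals import Bed6Record  # local import to avoid cycle in typing

    per_key: dict[Key, list[tuple[int, int]]] = {}
    n = 0
    for r in reads:
        iv: GenomicInterval = r.interval if isinstance(r, Bed6Record) else r
        per_key.setdefault((iv.chrom, iv.strand), []).append((iv.start, iv.end))
        n += 1
    track = CoverageTrack(library_size=library_size if library_size is not None else n)
    for key, items in per_key.items():
        # sweep-line pileup: +1 at read starts, -1 at read ends
        starts = np.array([s for s, _ in items], dtype=np.int64)
        ends = np.array([e for _, e in items], dtype=np.int64)
        edges = np.unique(np.concatenate([starts, ends]))
        delta = np.zeros(edges.size, dtype=np.int64)
        delta += np.bincount(np.searchsorted(edges, starts), minlength=edges.size)
        delta -= np.bincount(np.searchsorted(edges, ends), minlength=edges.size)
        depth = np.cumsum(delta)
        seg_s, seg_e, seg_v = edges[:-1], edges[1:], depth[:-1].astype(float)
        keep = seg_v > 0
        track.runs[key] = _Runs(seg_s[keep], seg_e[keep], seg_v[keep])
    return track
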