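"""Readers and writers: BED regions, bedGraph/wiggle tracks, profile
matrices, cluster exports.

All parsers accept an iterable of text lines (an open file works) and
report errors with 1-based line numbers.
"""

from __future__ import annotations

import io
from typing import Iterable, Mapping

import numpy as np

from .core import (
    CatchError,
    ClusterNode,
    GenomicRegion,
    ParseError,
    Profile,
    SignalTrack,
)

__all__ = [
    "parse_bed",
    "parse_bedgraph",
    "parse_wiggle",
    "write_bedgraph",
    "extract_profile",
    "write_cluster_exports",
    "write_profiles_tsv",
    "read_profiles_tsv",
]

_SKIP_PREFIXES = ("#", "track", "browser")


def _lines(stream: Iterable[str] | str) -> Iterable[str]:
    if isinstance(stream, str):
        return io.StringIO(stream)
    return stream


def parse_bed(stream: Iterable[str] | str) -> list[GenomicRegion]:
    """Parse BED (3-6 columns) into regions, preserving file order.

    Coordinates are 0-based half-open. Column 4 (name) and column 6
    (strand) are captured when present; other strand values become ``.``.
    """
    regions: list[GenomicRegion] = []
    for lineno, raw in enumerate(_lines(stream), start=1):
        line = raw.strip()
        if not line or line.startswith(_SKIP_PREFIXES):
            continue
        fields = line.split()
        if len(fields) < 3:
            raise ParseError(f"BED line {lineno}: expected >= 3 fields, got {len(fields)}")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise ParseError(f"BED line {lineno}: non-integer coordinates") from None
        name = fields[3] if len(fields) >= 4 else None
        strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
        try:
            regions.append(GenomicRegion(chrom, start, end, name=name, strand=strand))
        except CatchError as exc:
            raise ParseError(f"BED line {lineno}: {exc}") from None
    return regions


def parse_bedgraph(stream: Iterable[str] | str, name: str) -> SignalTrack:
    """Parse bedGraph (``chrom start end value``) into a signal track.

    Intervals are 0-based half-open; overlapping intervals are an error
    (they would make the signal ambiguous).
    """
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    for lineno, raw in enumerate(_lines(stream), start=1):
        line = raw.strip()
        if not line or line.startswith(_SKIP_PREFIXES):
            continue
        fields = line.split()
        if len(fields) < 4:
            raise ParseError(
                f"bedGraph line {lineno}: expected 4 fields, got {len(fields)}"
            )
        try:
            start, end = int(fields[1]), int(fields[2])
            value = float(fields[3])
        except ValueError:
            raise ParseError(f"bedGraph line {lineno}: malformed coordinates/value") from None
        if start >= end or start < 0:
            raise ParseError(f"bedGraph line {lineno}: invalid interval [{start}, {end})")
        intervals.setdefault(fields[0], []).append((start, end, value))
    try:
        return SignalTrack.from_intervals(name, intervals)
    except CatchError as exc:
        raise ParseError(str(exc)) from None


def parse_wiggle(stream: Iterable[str] | str, name: str) -> SignalTrack:
    """Parse wiggle (fixedStep/variableStep) into a signal track.

    Wiggle positions are 1-based in the file and converted to 0-based
    half-open intervals of length ``span``. Default span is 1 for
    variableStep and ``step`` for fixedStep (contiguous coverage).
    """
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    mode: str | None = None
    chrom = ""
    pos = 0  # next 0-based start for fixedStep
    step = span = 1
    last_start = -1

    def declaration(fields: list[str], lineno: int) -> dict[str, str]:
        out = {}
        for f in fields[1:]:
            if "=" not in f:
                raise ParseError(f"wiggle line {lineno}: malformed declaration field {f!r}")
            key, _, val = f.partition("=")
            out[key] = val
        return out

    for lineno, raw in enumerate(_lines(stream), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split()
        if fields[0] == "fixedStep":
            attrs = declaration(fields, lineno)
            try:
                chrom = attrs["chrom"]
                pos = int(attrs["start"]) - 1
                step = int(attrs["step"])
                span = int(attrs.get("span", attrs["step"]))
            except (KeyError, ValueError):
                raise ParseError(f"wiggle line {lineno}: bad fixedStep declaration") from None
            if pos < 0 or step < 1 or span < 1 or span > step:
                raise ParseError(f"wiggle line {lineno}: bad fixedStep parameters")
            mode = "fixed"
            last_start = -1
            continue
        if fields[0] == "variableStep":
            attrs = declaration(fields, lineno)
            try:
                chrom = attrs["chrom"]
                span = int(attrs.get("span", "1"))
            except (KeyError, ValueError):
                raise ParseError(f"wiggle line {lineno}: bad variableStep declaration") from None
            if span < 1:
                raise ParseError(f"wiggle line {lineno}: span must be >= 1")
            mode = "variable"
            last_start = -1
            continue
        if mode is None:
            raise ParseError(f"wiggle line {lineno}: data before any step declaration")
        if mode == "fixed":
            if len(fields) != 1:
                raise ParseError(f"wiggle line {lineno}: fixedStep expects one value per line")
            try:
                value = float(fields[0])
            except ValueError:
                raise ParseError(f"wiggle line {lineno}: non-numeric value {fields[0]!r}") from None
            intervals.setdefault(chrom, []).append((pos, pos + span, value))
            pos += step
        else:
            if len(fields) != 2:
                raise ParseError(f"wiggle line {lineno}: variableStep expects 'pos value'")
            try:
                start = int(fields[0]) - 1
                value = float(fields[1])
            except ValueError:
                raise ParseError(f"wiggle line {lineno}: malformed data line") from None
            if start < 0:
                raise ParseError(f"wiggle line {lineno}: position must be >= 1")
            if start <= last_start:
                raise ParseError(f"wiggle line {lineno}: non-monotone position within block")
            last_start = start
            intervals.setdefault(chrom, []).append((start, start + span, value))
    try:
        return SignalTrack.from_intervals(name, intervals)
    except CatchError as exc:
        raise ParseError(str(exc)) from None


def write_bedgraph(track: SignalTrack) -> str:
    """Serialize a track to bedGraph text (inverse of parse_bedgraph)."""
    out = []
    for chrom in sorted(track.data):
        starts, ends, values = track.data[chrom]
        for s, e, v in zip(starts, ends, values):
            out.append(f"{chrom}\t{s}\t{e}\t{v:.10g}")
    return "\n".join(out) + ("\n" if out else "")


def extract_profile(
    tracks: list[SignalTrack], region: GenomicRegion, bin_size: int
) -> Profile:
    """Extract a binned multi-track profile for one region.

    Each bin is the mean of *defined* per-base signal within the bin (so
    bin values are resolution-independent). Bins without any defined
    signal are filled by linear interpolation between the nearest defined
    bins of the same track; runs at the edges take the nearest defined
    value. A track with no signal anywhere in the region yields zeros.
    A chromosome absent from a track is simply all-missing.
    """
    if bin_size < 1:
        raise CatchError(f"bin_size must be >= 1, got {bin_size}")
    n_bins = len(region) // bin_size
    if n_bins < 1:
        raise CatchError(
            f"bin_size {bin_size} exceeds region length {len(region)}"
        )
    rstart = region.start
    rend = rstart + n_bins * bin_size
    values = np.zeros((len(tracks), n_bins))
    for t, track in enumerate(tracks):
        wsum = np.zeros(n_bins)
        wlen = np.zeros(n_bins)
        if region.chrom in track.data:
            starts, ends, vals = track.data[region.chrom]
            i0 = int(np.searchsorted(ends, rstart, side="right"))
            i1 = int(np.searchsorted(starts, rend, side="left"))
            for idx in range(i0, i1):
                s = max(int(starts[idx]), rstart)
                e = min(int(ends[idx]), rend)
                if s >= e:
                    continue
                b0 = (s - rstart) // bin_size
                b1 = (e - 1 - rstart) // bin_size
                for b in range(b0, b1 + 1):
                    bs = rstart + b * bin_size
                    be = bs + bin_size
                    ov = min(e, be) - max(s, bs)
                    wsum[b] += vals[idx] * ov
                    wlen[b] += ov
        defined = wlen > 0
        if not defined.any():
            continue  # all-missing track stays zero
        row = np.full(n_bins, np.nan)
        row[defined] = wsum[defined] / wlen[defined]
        idx_def = np.flatnonzero(defined)
        # np.interp gives linear interior interpolation and constant
        # extrapolation at the edges, exactly the missing-value rules
        values[t] = np.interp(np.arange(n_bins), idx_def, row[idx_def])
    return Profile(
        id=region.label,
        values=values,
        bin_size=bin_size,
        weight=1,
        coverage=np.ones(n_bins, dtype=np.int64),
        track_names=[t.name for t in tracks],
    )


def write_cluster_exports(
    node: ClusterNode, leaves: Mapping[str, GenomicRegion]
) -> tuple[str, str]:
    """Render a node's average profile (TSV) and member list (BED).

    The TSV has one row per bin with one column per track plus a coverage
    column. The BED lists each leaf's original region with the leaf's
    orientation in the node frame in the strand column and its bin offset
    in the score column.
    """
    rep = node.representative
    header = ["bin"] + list(rep.track_names) + ["coverage"]
    lines = ["\t".join(header)]
    for i in range(rep.n_bins):
        row = [str(i)]
        row += [f"{rep.values[t, i]:.10g}" for t in range(rep.n_tracks)]
        row.append(str(int(rep.coverage[i])))
        lines.append("\t".join(row))
    tsv = "\n".join(lines) + "\n"

    bed_lines = []
    for leaf_id in sorted(node.placements):
        pl = node.placements[leaf_id]
        if leaf_id not in leaves:
            raise CatchError(f"write_cluster_exports: no region for leaf {leaf_id}")
        reg = leaves[leaf_id]
        strand = "-" if pl.mirrored else "+"
        bed_lines.append(
            f"{reg.chrom}\t{reg.start}\t{reg.end}\t{leaf_id}\t{pl.offset}\t{strand}"
        )
    bed = "\n".join(bed_lines) + ("\n" if bed_lines else "")
    return tsv, bed


def write_profiles_tsv(profiles: list[Profile]) -> str:
    """Serialize profiles to the long-format TSV layout
    (``profile_id  track  bin  value``, bin_size 1)."""
    lines = ["profile_id\ttrack\tbin\tvalue"]
    for p in profiles:
        for t, track in enumerate(p.track_names):
            for b in range(p.n_bins):
                lines.append(f"{p.id}\t{track}\t{b}\t{p.values[t, b]:.10g}")
    return "\n".join(lines) + "\n"


def read_profiles_tsv(stream: Iterable[str] | str) -> list[Profile]:
    """Read the long-format profile TSV written by :func:`write_profiles_tsv`.

    Profiles appear in first-occurrence order; every (profile, track) must
    cover bins 0..L-1 and all tracks of one profile must agree on L.
    """
    rows: dict[str, dict[str, dict[int, float]]] = {}
    order: list[str] = []
    track_order: dict[str, list[str]] = {}
    for lineno, raw in enumerate(_lines(stream), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[:4] == ["profile_id", "track", "bin", "value"]:
            continue
        if len(fields) != 4:
            raise ParseError(f"profiles TSV line {lineno}: expected 4 fields")
        pid, track = fields[0], fields[1]
        try:
            b = int(fields[2])
            v = float(fields[3])
        except ValueError:
            raise ParseError(f"profiles TSV line {lineno}: malformed bin/value") from None
        if pid not in rows:
            rows[pid] = {}
            order.append(pid)
            track_order[pid] = []
        if track not in rows[pid]:
            rows[pid][track] = {}
            track_order[pid].append(track)
        rows[pid][track][b] = v
    profiles = []
    for pid in order:
        tracks = track_order[pid]
        lengths = {len(rows[pid][t]) for t in tracks}
        if len(lengths) != 1:
            raise ParseError(f"profile {pid}: tracks have differing bin counts")
        length = lengths.pop()
        values = np.zeros((len(tracks), length))
        for t, track in enumerate(tracks):
            bins = rows[pid][track]
            if set(bins) != set(range(length)):
                raise ParseError(f"profile {pid}/{track}: bins are not 0..{length - 1}")
            for b, v in bins.items():
                values[t, b] = v
        profiles.append(Profile(id=pid, values=values, track_names=tracks))
    return profiles
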