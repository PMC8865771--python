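"""Post-calling SV quality filtering and population-level merging.

Filters drop very short calls (30 bp or less), calls without split-read or
paired-end support, and calls whose locus coverage falls outside the sample's
expected range — heterozygous calls at roughly twice the expected coverage
are characteristic false positives (collapsed repeats / duplications).
Filtered calls are merged into population calls by single-linkage clustering:
two calls link iff they share type and strand and both breakpoints lie within
``max_dist`` (strictly) of each other.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np

from .datamodel import CoverageWindow, MergedSV, SVRecord

DEFAULT_MIN_LEN = 31
DEFAULT_MAX_DIST = 100


def default_windows(
    coverages: Mapping[str, Sequence[float]],
    k_lo: float = 0.5,
    k_hi: float = 1.5,
) -> dict[str, CoverageWindow]:
    """Per-sample coverage window [k_lo * median, k_hi * median].

    A stand-in for per-sample manual inspection of coverage distributions;
    the multipliers are this package's parameterization.
    """
    out = {}
    for sample, depths in coverages.items():
        if len(depths) == 0:
            raise ValueError(f"empty depth list for sample {sample!r}")
        med = float(np.median(depths))
        out[sample] = CoverageWindow(sample=sample, lo=k_lo * med, hi=k_hi * med)
    return out


def filter_svs(
    records: Iterable[SVRecord],
    windows: Mapping[str, CoverageWindow],
    min_len: int = DEFAULT_MIN_LEN,
) -> list[SVRecord]:
    """Keep calls with length >= min_len, any read support, and in-window coverage."""
    out = []
    for r in records:
        w = windows.get(r.sample)
        if w is None:
            raise KeyError(f"no coverage window for sample {r.sample!r}")
        if r.length < min_len:
            continue
        if r.support_sr <= 0 and r.support_pe <= 0:
            continue
        if not (w.lo <= r.sample_coverage <= w.hi):
            continue
        out.append(r)
    return out


def _stratum_key(r: SVRecord, default_strand: str = "+/+") -> tuple[str, str, str]:
    strand = r.strand_pair if r.strand_pair else default_strand
    return (r.chrom, r.sv_type, strand)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def merge_svs(
    records: Sequence[SVRecord],
    max_dist: int = DEFAULT_MAX_DIST,
    any_breakpoint: bool = False,
) -> list[MergedSV]:
    """Single-linkage merge of SV calls into population calls.

    Within each (chrom, sv_type, strand_pair) stratum, two calls link iff
    |start1 - start2| < max_dist and |end1 - end2| < max_dist (both strictly;
    with ``any_breakpoint=True`` either breakpoint suffices). Clusters are the
    transitive closure of the link relation, so chains may span more than
    ``max_dist`` end to end. The representative is the member with smallest
    (start, end, sample); output is sorted by (chrom, representative coords).
    """
    if max_dist <= 0:
        raise ValueError("max_dist must be > 0")
    strata: dict[tuple, list[int]] = {}
    for i, r in enumerate(records):
        strata.setdefault(_stratum_key(r), []).append(i)

    uf = _UnionFind(len(records))
    for idxs in strata.values():
        # sweep over start-sorted calls; only neighbors with start distance
        # < max_dist can link, so the inner loop terminates early
        idxs = sorted(idxs, key=lambda i: (records[i].start, records[i].end))
        starts = [records[i].start for i in idxs]
        for a in range(len(idxs)):
            for b in range(a + 1, len(idxs)):
                ds = starts[b] - starts[a]
                if ds >= max_dist:
                    break
                de = abs(records[idxs[b]].end - records[idxs[a]].end)
                if any_breakpoint:
                    linked = ds < max_dist or de < max_dist
                else:
                    linked = de < max_dist
                if linked:
                    uf.union(idxs[a], idxs[b])
        if any_breakpoint:
            # the start-sweep misses pairs linked only through their ends
            ends = sorted(idxs, key=lambda i: (records[i].end, records[i].start))
            for a in range(len(ends)):
                for b in range(a + 1, len(ends)):
                    if records[ends[b]].end - records[ends[a]].end >= max_dist:
                        break
                    uf.union(ends[a], ends[b])

    clusters: dict[int, list[int]] = {}
    for i in range(len(records)):
        clusters.setdefault(uf.find(i), []).append(i)

    merged = []
    for members in clusters.values():
        members_sorted = sorted(
            members, key=lambda i: (records[i].start, records[i].end, records[i].sample)
        )
        rep = records[members_sorted[0]]
        merged.append(
            MergedSV(
                representative=rep,
                members=[(records[i].sample, records[i]) for i in members_sorted],
                n_samples=len({records[i].sample for i in members}),
            )
        )
    merged.sort(
        key=lambda m: (
            m.representative.chrom,
            m.representative.start,
            m.representative.end,
            m.representative.sv_type,
        )
    )
    return merged
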