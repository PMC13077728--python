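"""Genomic range sets: the SNP-selection masks for cell-type PRS strategies.

A :class:`RangeSet` is a label plus a set of merged, sorted, 0-based half-open
intervals. Three constructors mirror the three SNP-selection strategies:

* :func:`gene_windows` — gene bodies padded by a symmetric flank (the
  transcriptome-derived strategy, default 30 kb);
* :func:`peak_ranges` — accessible-chromatin peaks taken verbatim (the
  chromatin-derived strategy);
* :func:`multiomic_ranges` — subtype peaks kept only when near a
  neuron-specific gene (the multi-omic neuron-subtype strategy, 300 kb).

:func:`subtract_region` removes a padded exclusion zone (e.g. the APOE locus
± 1 Mb) and :func:`snps_in_ranges` maps 1-based variant positions onto the
half-open masks.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.start >= self.end:
            raise ValueError(f"empty or inverted interval: {self}")

    @property
    def length(self) -> int:
        return self.end - self.start


def _merge_arrays(starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Merge overlapping/abutting intervals; returns an (n, 2) array."""
    if len(starts) == 0:
        return np.empty((0, 2), dtype=np.int64)
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out = []
    cur_s, cur_e = int(starts[0]), int(ends[0])
    for s, e in zip(starts[1:], ends[1:]):
        if s <= cur_e:  # overlap or abutment
            cur_e = max(cur_e, int(e))
        else:
            out.append((cur_s, cur_e))
            cur_s, cur_e = int(s), int(e)
    out.append((cur_s, cur_e))
    return np.asarray(out, dtype=np.int64)


@dataclass
class RangeSet:
    """Merged, sorted, per-chromosome 0-based half-open intervals."""

    label: str = ""
    _by_chrom: dict = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, intervals, label: str = "") -> "RangeSet":
        """Build a normalized RangeSet from an iterable of intervals.

        Accepts :class:`GenomicInterval` objects or ``(chrom, start, end)``
        tuples.
        """
        by_chrom: dict = {}
        for iv in intervals:
            if isinstance(iv, GenomicInterval):
                chrom, start, end = iv.chrom, iv.start, iv.end
            else:
                chrom, start, end = iv
            if start < 0 or start >= end:
                raise ValueError(f"invalid interval {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((start, end))
        normalized = {}
        for chrom in sorted(by_chrom):
            arr = np.asarray(by_chrom[chrom], dtype=np.int64)
            normalized[chrom] = _merge_arrays(arr[:, 0], arr[:, 1])
        return cls(label=label, _by_chrom=normalized)

    @property
    def intervals(self) -> list:
        return [
            GenomicInterval(chrom, int(s), int(e))
            for chrom in sorted(self._by_chrom)
            for s, e in self._by_chrom[chrom]
        ]

    @property
    def n_intervals(self) -> int:
        return sum(len(a) for a in self._by_chrom.values())

    def total_length(self) -> int:
        """Total number of genome positions covered."""
        return int(sum((a[:, 1] - a[:, 0]).sum() for a in self._by_chrom.values()))

    def is_empty(self) -> bool:
        return self.n_intervals == 0

    def normalize(self) -> "RangeSet":
        """Re-normalization is the identity on an already-normalized set."""
        return RangeSet.from_intervals(self.intervals, label=self.label)

    def intersect(self, other: "RangeSet") -> "RangeSet":
        out = []
        for chrom, arr in self._by_chrom.items():
            oth = other._by_chrom.get(chrom)
            if oth is None:
                continue
            for s, e in arr:
                lo = np.searchsorted(oth[:, 1], s, side="right")
                for os, oe in oth[lo:]:
                    if os >= e:
                        break
                    a, b = max(s, os), min(e, oe)
                    if a < b:
                        out.append((chrom, int(a), int(b)))
        return RangeSet.from_intervals(out, label=self.label)

    def union(self, other: "RangeSet") -> "RangeSet":
        ivs = [(c, int(s), int(e)) for c, a in self._by_chrom.items() for s, e in a]
        ivs += [(c, int(s), int(e)) for c, a in other._by_chrom.items() for s, e in a]
        return RangeSet.from_intervals(ivs, label=self.label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(iv.chrom, iv.start, iv.end) for iv in self.intervals],
            columns=["chrom", "start", "end"],
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, RangeSet):
            return NotImplemented
        if set(self._by_chrom) != set(other._by_chrom):
            return False
        return all(
            np.array_equal(self._by_chrom[c], other._by_chrom[c])
            for c in self._by_chrom
        )


def gene_windows(genes: pd.DataFrame, flank_bp: int = 30_000, label: str = "") -> RangeSet:
    """Gene bodies padded by ``flank_bp`` on both sides, clamped at 0, merged.

    ``genes`` needs columns ``chrom``, ``start``, ``end`` (0-based half-open);
    strand is ignored — the window is symmetric around the gene body.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    if len(genes) == 0:
        raise ValueError("empty gene list")
    ivs = [
        (row.chrom, max(0, int(row.start) - flank_bp), int(row.end) + flank_bp)
        for row in genes.itertuples()
    ]
    return RangeSet.from_intervals(ivs, label=label)


def peak_ranges(peaks, annotations: pd.DataFrame, label: str = "") -> RangeSet:
    """Verbatim spans of the given peak ids, merged.

    ``annotations`` maps ``feature_id`` to ``chrom``/``start``/``end``.
    """
    peaks = set(peaks)
    if not peaks:
        raise ValueError("empty peak set")
    ann = annotations.set_index("feature_id")
    missing = sorted(peaks - set(ann.index))
    if missing:
        raise KeyError(f"peaks without annotation: {missing[:10]}")
    sub = ann.loc[sorted(peaks)]
    ivs = list(zip(sub["chrom"], sub["start"].astype(int), sub["end"].astype(int)))
    return RangeSet.from_intervals(ivs, label=label)


def multiomic_ranges(
    subtype_peaks: RangeSet,
    neuron_genes: pd.DataFrame,
    flank_bp: int = 300_000,
    label: str = "",
) -> RangeSet:
    """Retain subtype peak intervals within ``flank_bp`` of a neuron gene span.

    Distance between a peak and a gene is the gap in bases between their
    half-open spans (overlap counts as 0); a peak is retained when its
    distance to the NEAREST gene is <= ``flank_bp``.
    """
    gene_by_chrom: dict = {}
    for row in neuron_genes.itertuples():
        gene_by_chrom.setdefault(row.chrom, []).append((int(row.start), int(row.end)))
    kept = []
    for iv in subtype_peaks.intervals:
        spans = gene_by_chrom.get(iv.chrom)
        if not spans:
            continue
        for gs, ge in spans:
            gap = max(gs - iv.end, iv.start - ge, 0)
            if gap <= flank_bp:
                kept.append(iv)
                break
    return RangeSet.from_intervals(kept, label=label or subtype_peaks.label)


def subtract_region(
    ranges: RangeSet,
    exclusion_center: GenomicInterval,
    flank_bp: int = 1_000_000,
) -> RangeSet:
    """Subtract ``exclusion_center`` padded by ``flank_bp`` from the ranges.

    Used for the APOE ± 1 Mb exclusion; intervals on other chromosomes are
    untouched. An empty result is valid (a warning is emitted).
    """
    ex_s = max(0, exclusion_center.start - flank_bp)
    ex_e = exclusion_center.end + flank_bp
    out = []
    for iv in ranges.intervals:
        if iv.chrom != exclusion_center.chrom or iv.end <= ex_s or iv.start >= ex_e:
            out.append((iv.chrom, iv.start, iv.end))
            continue
        if iv.start < ex_s:
            out.append((iv.chrom, iv.start, ex_s))
        if iv.end > ex_e:
            out.append((iv.chrom, ex_e, iv.end))
    result = RangeSet.from_intervals(out, label=ranges.label)
    if result.is_empty() and not ranges.is_empty():
        warnings.warn(
            f"RangeSet {ranges.label!r} is empty after exclusion", stacklevel=2
        )
    return result


def snps_in_ranges(variants: pd.DataFrame, ranges: RangeSet) -> set:
    """Variant ids whose (1-based) position falls inside the range set.

    A variant at position ``pos`` is inside ``[start, end)`` iff
    ``start <= pos - 1 < end``. Membership is tested on position only;
    allele length (indels) is ignored.
    """
    hit = set()
    for chrom, grp in variants.groupby("chrom", observed=True):
        arr = ranges._by_chrom.get(chrom)
        if arr is None or len(arr) == 0:
            continue
        pos0 = grp["pos"].to_numpy(dtype=np.int64) - 1
        idx = np.searchsorted(arr[:, 0], pos0, side="right") - 1
        ok = (idx >= 0) & (pos0 < arr[np.clip(idx, 0, None), 1])
        hit.update(grp["variant_id"].to_numpy()[ok])
    return hit


def overlap_counts(sets: dict) -> pd.DataFrame:
    """Exact-combination intersection sizes across labeled variant sets.

    For every nonempty label combination, counts the variants belonging to
    exactly that combination (UpSet-plot semantics). Counts sum to the size
    of the union.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    labels = list(sets)
    membership: dict = {}
    for v in set().union(*sets.values()):
        key = frozenset(l for l in labels if v in sets[l])
        membership[key] = membership.get(key, 0) + 1
    rows = []
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            key = frozenset(combo)
            count = membership.get(key, 0)
            rows.append(
                {**{l: (l in key) for l in labels}, "degree": r, "count": count}
            )
    return pd.DataFrame(rows)
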