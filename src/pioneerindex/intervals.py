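"""Genomic intervals, BED I/O and overlap queries.

Binding sites, ATAC accessibility peaks and chromatin-mark regions are all
plain half-open genomic intervals (BED convention: 0-based start, exclusive
end).  This module provides the interval containers used throughout the
pipeline, BED3/BED4 (and narrowPeak) reading/writing, ``>=1 bp`` overlap
queries, the replicate-reproducible binding-site universe, and the binary
accessibility labelling of sites against pre-induction ATAC peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "read_bed",
    "write_bed",
    "overlap_any",
    "intersect_replicates",
    "label_accessibility",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic region ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    site_id: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if not self.site_id:
            object.__setattr__(self, "site_id", f"{self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share at least one base pair."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class PeakSet:
    """An ordered, validated collection of :class:`GenomicInterval`.

    Intervals are sorted by ``(chrom, start, end)`` on construction and
    site_ids must be unique within the set.

    Parameters
    ----------
    intervals
        Any iterable of :class:`GenomicInterval`.
    label
        Free-text provenance (TF name, dose, replicate ...).
    normalize_chrom_names
        When True, chromosome names are normalised by stripping a leading
        ``chr`` prefix before comparison ("chr1" and "1" become equal).
        Off by default: names are compared verbatim.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        label: str = "",
        normalize_chrom_names: bool = False,
    ) -> None:
        self.label = label
        self.normalize_chrom_names = normalize_chrom_names
        ivals = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        seen: set[str] = set()
        for iv in ivals:
            if iv.site_id in seen:
                raise ValueError(f"duplicate site_id {iv.site_id!r} in PeakSet")
            seen.add(iv.site_id)
        self.intervals: list[GenomicInterval] = ivals
        self._trees: dict[str, IntervalTree] | None = None

    def _chrom_key(self, chrom: str) -> str:
        if self.normalize_chrom_names and chrom.startswith("chr"):
            return chrom[3:]
        return chrom

    def _tree_index(self) -> dict[str, IntervalTree]:
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for iv in self.intervals:
                trees.setdefault(self._chrom_key(iv.chrom), IntervalTree()).addi(
                    iv.start, iv.end, iv
                )
            self._trees = trees
        return self._trees

    def overlaps_interval(self, iv: GenomicInterval) -> bool:
        tree = self._tree_index().get(self._chrom_key(iv.chrom))
        return bool(tree is not None and tree.overlaps(iv.start, iv.end))

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PeakSet(n={len(self)}, label={self.label!r})"


def read_bed(path: str | Path, label: str = "") -> PeakSet:
    """Read a BED3/BED4 (or narrowPeak; extra columns ignored) file.

    Lines must have >=3 tab-separated columns.  A 4th column, when present,
    supplies the site_id; otherwise ids default to ``chrom:start-end``.
    Track/browser/comment lines are skipped.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            site_id = fields[3] if len(fields) >= 4 and fields[3] not in (".", "") else ""
            try:
                intervals.append(GenomicInterval(fields[0], start, end, site_id))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(intervals, label=label or path.name)


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    """Write a PeakSet as BED4 (chrom, start, end, site_id)."""
    with open(path, "w") as fh:
        for iv in peaks:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.site_id}\n")


def overlap_any(query: PeakSet, subject: PeakSet) -> dict[str, bool]:
    """Flag each query interval that shares >=1 bp with any subject interval.

    Returns a mapping of query ``site_id`` to boolean, in half-open
    semantics: touching intervals ([100,200) vs [200,300)) do not overlap.
    """
    return {iv.site_id: subject.overlaps_interval(iv) for iv in query}


def intersect_replicates(
    rep1: PeakSet, rep2: PeakSet, keep: str = "rep1"
) -> PeakSet:
    """Build the replicate-reproducible binding-site universe.

    Returns the rep1 intervals that overlap (>=1 bp) at least one rep2
    interval — the anchor replicate's own coordinates are kept, which makes
    the universe deterministic.  ``keep="rep2"`` anchors on rep2 instead.
    """
    if keep not in ("rep1", "rep2"):
        raise ValueError(f"keep must be 'rep1' or 'rep2', got {keep!r}")
    if keep == "rep2":
        rep1, rep2 = rep2, rep1
    if len(rep1) == 0 or len(rep2) == 0:
        warnings.warn("intersect_replicates: empty input PeakSet", stacklevel=2)
    flags = overlap_any(rep1, rep2)
    kept = [iv for iv in rep1 if flags[iv.site_id]]
    return PeakSet(kept, label=f"{rep1.label}&{rep2.label}")


def label_accessibility(sites: PeakSet, atac_peaks: PeakSet) -> dict[str, str]:
    """Classify each binding site as accessible or inaccessible.

    A site is *accessible* iff it overlaps (>=1 bp) an ATAC peak called in
    the uninduced (-dox) condition, else *inaccessible*.  The two labels
    partition the site set.
    """
    flags = overlap_any(sites, atac_peaks)
    return {
        sid: ("accessible" if hit else "inaccessible") for sid, hit in flags.items()
    }


def peaks_from_frame(df, label: str = "") -> PeakSet:
    """Build a PeakSet from a DataFrame with chrom/start/end[/site_id] columns."""
    ids = df["site_id"] if "site_id" in df.columns else [""] * len(df)
    return PeakSet(
        [
            GenomicInterval(c, int(s), int(e), sid)
            for c, s, e, sid in zip(df["chrom"], df["start"], df["end"], ids)
        ],
        label=label,
    )
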