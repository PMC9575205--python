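"""Chromatin-mark and DNA-methylation annotation of binding sites.

Sites are flagged for overlap (>=1 bp) with regions carrying each histone
mark (H3K27Ac activity, H3K4me1 enhancers, H3K9me3 and H3K27me3 silencing),
and CpG methylation is aggregated per site: CpGs with at least 10 reads of
coverage are averaged (unweighted) and the site-level mean is binned into
tertiles of the percent scale.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, PeakSet

__all__ = [
    "STANDARD_MARKS",
    "MIN_CPG_COVERAGE",
    "annotate_marks",
    "read_methylation_table",
    "site_methylation",
    "bin_methylation",
    "annotate_sites",
]

#: Histone marks annotated by default.
STANDARD_MARKS = ("H3K27Ac", "H3K4me1", "H3K9me3", "H3K27me3")

#: Minimum bisulfite read coverage for a CpG to enter the site average.
MIN_CPG_COVERAGE = 10

# Tertile edges on the percent scale, left-closed: [0, 100/3), [100/3, 200/3),
# [200/3, 100].  The verbal "<33 / 33-66 / >66" bins leave the boundaries
# unassigned; exact thirds with left-closed intervals resolve that.
_LOW_EDGE = 100.0 / 3.0
_HIGH_EDGE = 200.0 / 3.0


def annotate_marks(
    sites: PeakSet,
    mark_beds: Mapping[str, PeakSet],
    allowed_marks: Sequence[str] | None = STANDARD_MARKS,
) -> pd.DataFrame:
    """Flag each site for >=1 bp overlap with each mark's regions.

    Flags are independent: a site may carry several marks.  Passing
    ``allowed_marks=None`` accepts any mark names.
    """
    if allowed_marks is not None:
        unknown = set(mark_beds) - set(allowed_marks)
        if unknown:
            raise ValueError(f"unknown mark name(s): {sorted(unknown)}")
    rows = []
    for iv in sites:
        row: dict = {"site_id": iv.site_id}
        for mark, regions in mark_beds.items():
            row[mark] = regions.overlaps_interval(iv)
        rows.append(row)
    return pd.DataFrame(rows).set_index("site_id")


def read_methylation_table(path: str | Path) -> pd.DataFrame:
    """Read a CpG methylation TSV: chrom, position (0-based), coverage,
    percent_methylated.  A header naming these columns is expected."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "position", "coverage", "percent_methylated"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {required - set(df.columns)}")
    if (df["coverage"] < 0).any():
        raise ValueError(f"{path}: negative coverage")
    pm = df["percent_methylated"]
    if ((pm < 0) | (pm > 100)).any():
        raise ValueError(f"{path}: percent_methylated outside [0, 100]")
    if df.duplicated(subset=["chrom", "position"]).any():
        raise ValueError(f"{path}: duplicate CpG positions")
    return df


def site_methylation(
    site: GenomicInterval,
    records: pd.DataFrame,
    min_coverage: int = MIN_CPG_COVERAGE,
) -> float | None:
    """Mean percent methylation over qualifying CpGs in the site, or None.

    CpGs inside ``[start, end)`` with coverage >= ``min_coverage`` (coverage
    of exactly 10 qualifies at the default) contribute equally — the mean
    is unweighted by coverage.
    """
    sel = records[
        (records["chrom"] == site.chrom)
        & (records["position"] >= site.start)
        & (records["position"] < site.end)
        & (records["coverage"] >= min_coverage)
    ]
    if sel.empty:
        return None
    return float(sel["percent_methylated"].mean())


def bin_methylation(mean_percent: float) -> str:
    """Tertile bin of a site-level mean methylation percentage.

    low = [0, 33.3%), mid = [33.3%, 66.7%), high = [66.7%, 100].
    """
    if not 0.0 <= mean_percent <= 100.0:
        raise ValueError(f"methylation percent outside [0, 100]: {mean_percent}")
    if mean_percent < _LOW_EDGE:
        return "low"
    if mean_percent < _HIGH_EDGE:
        return "mid"
    return "high"


def annotate_sites(
    sites: PeakSet,
    mark_beds: Mapping[str, PeakSet] | None = None,
    methylation: pd.DataFrame | None = None,
    min_coverage: int = MIN_CPG_COVERAGE,
) -> pd.DataFrame:
    """Combined per-site annotation table: mark flags, mean methylation, bin."""
    if mark_beds is not None:
        df = annotate_marks(sites, mark_beds)
    else:
        df = pd.DataFrame(index=pd.Index([iv.site_id for iv in sites], name="site_id"))
    if methylation is not None:
        # group CpGs by site once instead of scanning the table per site
        means = {
            iv.site_id: site_methylation(iv, methylation, min_coverage)
            for iv in sites
        }
        df["mean_methylation"] = pd.Series(means)
        df["methylation_bin"] = df["mean_methylation"].map(
            lambda m: bin_methylation(m) if pd.notna(m) else None
        )
    return df
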