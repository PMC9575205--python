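"""The pioneer activity index and dox50 distribution summaries.

A transcription factor's pioneer activity — its ability to bind DNA that is
occluded by nucleosomes — is quantified here as the ratio of its mean dox50
at accessible sites to its mean dox50 at inaccessible sites.  Equal affinity
in both compartments gives an index of 1 (maximal pioneer activity); any
loss of affinity at inaccessible sites raises their mean dox50 and pulls
the index toward 0.  Because both means come from the same nuclei at the
same induction series, the absolute dox (and hence TF concentration) scale
cancels out of the ratio, making indices comparable between factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PioneerIndexResult",
    "pioneer_activity_index",
    "bootstrap_index_ci",
    "bin_by_motif_count",
    "summarize_dox50",
    "MOTIF_BINS",
]

#: Motif-count strata: fewer than 2 motifs, 2-3 motifs, 4 or more.
MOTIF_BINS = ("lt2", "ge2_lt4", "ge4")


@dataclass(frozen=True)
class PioneerIndexResult:
    """Group means of dox50 by accessibility and their ratio (the index)."""

    mean_dox50_accessible: float
    mean_dox50_inaccessible: float
    index: float
    n_accessible: int
    n_inaccessible: int

    def to_dict(self) -> dict:
        return asdict(self)


def pioneer_activity_index(
    dox50s: Mapping[str, float],
    labels: Mapping[str, str],
    use_median: bool = False,
) -> PioneerIndexResult:
    """Compute the pioneer activity index from per-site dox50s and labels.

    Parameters
    ----------
    dox50s
        site_id -> consensus dox50 (ug/ml), all positive.
    labels
        site_id -> "accessible" / "inaccessible".  Sites missing a label
        are ignored; sites missing a dox50 (filtered/unconverged) likewise.
    use_median
        Use class medians instead of arithmetic means (robust variant).
    """
    acc, inacc = [], []
    for sid, k in dox50s.items():
        if k is None:
            continue
        if k <= 0:
            raise ValueError(f"{sid}: dox50 must be positive, got {k}")
        lab = labels.get(sid)
        if lab == "accessible":
            acc.append(k)
        elif lab == "inaccessible":
            inacc.append(k)
        elif lab is not None:
            raise ValueError(f"{sid}: unknown accessibility label {lab!r}")
    if not acc:
        raise ValueError("no sites in class 'accessible'")
    if not inacc:
        raise ValueError("no sites in class 'inaccessible'")
    center = np.median if use_median else np.mean
    m_acc = float(center(acc))
    m_inacc = float(center(inacc))
    return PioneerIndexResult(
        mean_dox50_accessible=m_acc,
        mean_dox50_inaccessible=m_inacc,
        index=m_acc / m_inacc,
        n_accessible=len(acc),
        n_inaccessible=len(inacc),
    )


def bootstrap_index_ci(
    dox50s: Mapping[str, float],
    labels: Mapping[str, str],
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the index, resampling sites within class.

    This interval is an extension beyond the point estimate itself: the
    index is defined without an uncertainty measure, so the CI is provided
    as a clearly-labelled add-on.
    """
    rng = np.random.default_rng(seed)
    acc = np.array(
        [k for s, k in dox50s.items() if k is not None and labels.get(s) == "accessible"]
    )
    inacc = np.array(
        [
            k
            for s, k in dox50s.items()
            if k is not None and labels.get(s) == "inaccessible"
        ]
    )
    stats = [
        np.mean(rng.choice(acc, acc.size)) / np.mean(rng.choice(inacc, inacc.size))
        for _ in range(n_boot)
    ]
    lo, hi = np.quantile(stats, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


def bin_by_motif_count(motif_counts: Mapping[str, int]) -> dict[str, str]:
    """Assign each site to a motif-count stratum: [0,2), [2,4), [4,inf).

    Sites with a missing (None) count are excluded with a warning.
    """
    bins: dict[str, str] = {}
    missing = 0
    for sid, c in motif_counts.items():
        if c is None:
            missing += 1
            continue
        if c < 0:
            raise ValueError(f"{sid}: negative motif count {c}")
        bins[sid] = "lt2" if c < 2 else ("ge2_lt4" if c < 4 else "ge4")
    if missing:
        warnings.warn(f"{missing} sites lacked a motif count; excluded", stacklevel=2)
    return bins


def summarize_dox50(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Distribution summaries (n, mean, median, variance, quartiles) per group.

    Single-element groups report a variance of 0 (population convention is
    irrelevant at n=1; ddof=1 would be undefined).
    """
    rows = []
    for name, vals in groups.items():
        v = np.asarray(list(vals), dtype=float)
        if v.size == 0:
            raise ValueError(f"group {name!r} is empty")
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        rows.append(
            {
                "group": name,
                "n": int(v.size),
                "mean": float(v.mean()),
                "median": float(med),
                "variance": float(v.var(ddof=1)) if v.size > 1 else 0.0,
                "q1": float(q1),
                "q3": float(q3),
                "min": float(v.min()),
                "max": float(v.max()),
            }
        )
    return pd.DataFrame(rows)
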