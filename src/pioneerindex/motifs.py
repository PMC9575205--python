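"""PWM motif scanning with exact p-value score thresholds.

Motif occurrences inside binding peaks are called the way FIMO calls them:
each window of the sequence (both strands) is scored against the motif's
log-odds position-specific scoring matrix (PSSM), and a window is a hit
when its score exceeds the threshold corresponding to a chosen p-value
under the background model.  The p-value -> score conversion is exact: the
null distribution of the (discretised) score under the i.i.d. background is
computed by dynamic programming over motif positions, so the reported
threshold is the smallest score whose upper-tail probability is <= alpha.

Scores are discretised to 1e-3 bits per matrix cell, rounding observed
scores down, so a reported p-value is never understated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import motifs as bio_motifs

__all__ = [
    "ALPHABET",
    "PWM",
    "MotifHit",
    "MotifScanner",
    "read_jaspar_pfm",
    "pwm_log_odds",
    "pvalue_score_threshold",
    "scan_sequence",
    "count_motifs_per_site",
    "reverse_complement",
]

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Score-discretisation step (bits) for the exact null distribution.
DEFAULT_PRECISION = 1e-3

UNIFORM_BACKGROUND = np.full(4, 0.25)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PWM:
    """A position weight matrix over A/C/G/T.

    ``probabilities`` has shape (width, 4), each row summing to 1 after
    pseudocount regularisation.  The pseudocount (a fraction of the
    background distribution added to each position) keeps log-odds finite
    at zero-probability cells.
    """

    motif_id: str
    probabilities: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4:
            raise ValueError("probabilities must have shape (width, 4)")
        if np.any(p < 0):
            raise ValueError("probabilities must be nonnegative")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or np.any(bg <= 0) or not math.isclose(bg.sum(), 1.0):
            raise ValueError("background must be 4 positive values summing to 1")
        object.__setattr__(self, "probabilities", p / p.sum(axis=1, keepdims=True))
        object.__setattr__(self, "background", bg)

    @classmethod
    def from_counts(
        cls,
        motif_id: str,
        counts: np.ndarray,
        background: np.ndarray | None = None,
        pseudocount: float = 0.01,
    ) -> "PWM":
        """Build from a count matrix (width, 4); scaling counts by any
        constant leaves the resulting probabilities unchanged."""
        c = np.asarray(counts, dtype=float)
        totals = c.sum(axis=1, keepdims=True)
        if np.any(totals <= 0):
            raise ValueError("each position needs a positive total count")
        return cls(
            motif_id,
            c / totals,
            UNIFORM_BACKGROUND.copy() if background is None else background,
            pseudocount,
        )

    @property
    def width(self) -> int:
        return self.probabilities.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probabilities.argmax(axis=1))

    def regularized(self) -> np.ndarray:
        """Probabilities after adding pseudocount x background, renormalised."""
        p = self.probabilities + self.pseudocount * self.background
        return p / p.sum(axis=1, keepdims=True)


def read_jaspar_pfm(path: str | Path, motif_id: str | None = None, **kwargs) -> PWM:
    """Read a JASPAR-style position frequency matrix.

    Accepts both the ``>header`` JASPAR flavour and the bare 4-row (A/C/G/T)
    flat PFM format.
    """
    path = Path(path)
    text = path.read_text()
    fmt = "jaspar" if text.lstrip().startswith(">") else "pfm"
    with open(path) as fh:
        m = bio_motifs.read(fh, fmt)
    counts = np.array([m.counts[b] for b in ALPHABET], dtype=float).T
    name = motif_id or getattr(m, "matrix_id", None) or m.name or path.stem
    return PWM.from_counts(name, counts, **kwargs)


def write_jaspar_pfm(pwm: PWM, path: str | Path, scale: float = 100.0) -> None:
    """Write a PWM as a JASPAR count matrix (probabilities x ``scale``)."""
    counts = pwm.probabilities * scale
    with open(path, "w") as fh:
        fh.write(f">{pwm.motif_id} {pwm.motif_id}\n")
        for i, base in enumerate(ALPHABET):
            row = " ".join(f"{v:.6g}" for v in counts[:, i])
            fh.write(f"{base} [ {row} ]\n")


def pwm_log_odds(pwm: PWM) -> np.ndarray:
    """Log-odds PSSM: score[pos, base] = log2(p_reg[pos, base] / bg[base]).

    With a zero pseudocount a zero-probability cell has no finite log-odds
    and is rejected.
    """
    p = pwm.regularized()
    if np.any(p == 0):
        raise ValueError(
            f"{pwm.motif_id}: zero-probability cell with no pseudocount; "
            "set pseudocount > 0"
        )
    return np.log2(p / pwm.background)


@dataclass(frozen=True)
class MotifHit:
    """One above-threshold match of the motif in a scanned sequence."""

    offset: int
    strand: str
    score: float
    pvalue: float
    site_id: str = ""


def _discretize(pssm: np.ndarray, precision: float) -> np.ndarray:
    # floor keeps observed scores conservative (never rounded up)
    return np.floor(pssm / precision + 1e-12).astype(np.int64)


def _null_distribution(int_pssm: np.ndarray, background: np.ndarray) -> dict[int, float]:
    """Exact distribution of the total discretised score under i.i.d.
    background, by DP over positions."""
    dist: dict[int, float] = {0: 1.0}
    for row in int_pssm:
        nxt: dict[int, float] = {}
        for s, p in dist.items():
            for b in range(4):
                key = s + int(row[b])
                nxt[key] = nxt.get(key, 0.0) + p * background[b]
        dist = nxt
    return dist


def _tail_probabilities(dist: dict[int, float]) -> tuple[np.ndarray, np.ndarray]:
    """Scores descending and P(S >= score) for each."""
    scores = np.array(sorted(dist, reverse=True), dtype=np.int64)
    probs = np.array([dist[int(s)] for s in scores])
    return scores, np.cumsum(probs)


def pvalue_score_threshold(
    pssm: np.ndarray,
    alpha: float,
    background: np.ndarray | None = None,
    precision: float = DEFAULT_PRECISION,
) -> float:
    """Smallest score with P(score >= s | background) <= alpha.

    The null distribution is computed exactly on the discretised score;
    the returned threshold is that discretised score converted back to
    score units.  alpha = 1 returns the minimal attainable score; an alpha
    below the smallest attainable tail (< 1/4^width under a uniform
    background) returns the maximal score with a warning.
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    int_pssm = _discretize(pssm, precision)
    dist = _null_distribution(int_pssm, bg)
    scores, tails = _tail_probabilities(dist)
    ok = tails <= alpha + 1e-15
    if not ok.any():
        warnings.warn(
            f"alpha={alpha} below the minimal attainable tail; returning the "
            "maximal score (no window can ever match)",
            stacklevel=2,
        )
        return float(scores[0] + 1) * precision
    return float(scores[ok][-1]) * precision


class MotifScanner:
    """Bundles a PWM with its PSSM, null distribution and score threshold.

    Building the scanner once amortises the DP over many sequences; the
    scanner then reports hits on both strands at p <= alpha, overlapping
    hits included, windows containing N skipped.
    """

    def __init__(
        self,
        pwm: PWM,
        alpha: float = 1e-3,
        precision: float = DEFAULT_PRECISION,
    ) -> None:
        self.pwm = pwm
        self.alpha = alpha
        self.precision = precision
        self.pssm = pwm_log_odds(pwm)
        self._int_pssm = _discretize(self.pssm, precision)
        # reverse strand: reversed positions, complemented bases (A<->T, C<->G)
        self._int_pssm_rc = self._int_pssm[::-1, ::-1]
        dist = _null_distribution(self._int_pssm, pwm.background)
        self._tail_scores, self._tail_probs = _tail_probabilities(dist)
        self.threshold = pvalue_score_threshold(
            self.pssm, alpha, pwm.background, precision
        )
        self._int_threshold = int(round(self.threshold / precision))

    @property
    def width(self) -> int:
        return self.pwm.width

    def score_pvalue(self, int_score: int) -> float:
        """Exact P(null discretised score >= int_score)."""
        idx = np.searchsorted(-self._tail_scores, -int_score, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self._tail_probs[idx])

    def _encode(self, sequence: str) -> np.ndarray:
        seq = sequence.upper()
        codes = np.full(len(seq), -1, dtype=np.int64)
        for b, i in _BASE_INDEX.items():
            codes[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
        return codes

    def _window_scores(self, codes: np.ndarray, int_pssm: np.ndarray) -> np.ndarray:
        w = self.width
        n = codes.size - w + 1
        if n <= 0:
            return np.empty(0, dtype=np.int64)
        scores = np.zeros(n, dtype=np.int64)
        valid = np.ones(n, dtype=bool)
        for j in range(w):
            window = codes[j : j + n]
            valid &= window >= 0
            scores += int_pssm[j, np.where(window >= 0, window, 0)]
        scores[~valid] = np.iinfo(np.int64).min
        return scores

    def scan(self, sequence: str, site_id: str = "") -> list[MotifHit]:
        """All hits with score >= threshold on either strand.

        A window containing any non-ACGT character is skipped.  Offsets are
        0-based positions of the window start on the forward sequence for
        both strands.
        """
        codes = self._encode(sequence)
        hits: list[MotifHit] = []
        for strand, mat in (("+", self._int_pssm), ("-", self._int_pssm_rc)):
            scores = self._window_scores(codes, mat)
            for off in np.flatnonzero(scores >= self._int_threshold):
                s = int(scores[off])
                hits.append(
                    MotifHit(
                        offset=int(off),
                        strand=strand,
                        score=s * self.precision,
                        pvalue=self.score_pvalue(s),
                        site_id=site_id,
                    )
                )
        hits.sort(key=lambda h: (h.offset, h.strand))
        return hits

    def count(self, sequence: str) -> int:
        return len(self.scan(sequence))


def scan_sequence(
    sequence: str,
    pwm: PWM,
    alpha: float = 1e-3,
    precision: float = DEFAULT_PRECISION,
) -> list[MotifHit]:
    """Convenience wrapper: scan one sequence at p <= alpha."""
    return MotifScanner(pwm, alpha=alpha, precision=precision).scan(sequence)


def load_genome(path: str | Path):
    """Open an indexed FASTA genome (pyfaidx) for use as a sequence source."""
    from pyfaidx import Fasta

    return Fasta(str(path))


def _fetch_sequence(genome, chrom: str, start: int, end: int) -> str:
    """Extract [start, end) from a genome source.

    Supports a mapping of chromosome -> string and pyfaidx.Fasta-like
    objects (anything indexable by chromosome returning a sliceable record).
    """
    if isinstance(genome, Mapping):
        seq = genome[chrom][start:end]
    else:
        record = genome[chrom]
        seq = record[start:end]
        seq = getattr(seq, "seq", seq)
    return str(seq)


def count_motifs_per_site(
    sites,
    genome,
    pwm: PWM,
    alpha: float = 1e-3,
    precision: float = DEFAULT_PRECISION,
) -> dict[str, int]:
    """Number of motif hits (p <= alpha, both strands) in each site.

    ``genome`` may be a pyfaidx.Fasta, a chrom -> sequence mapping, or a
    site_id -> sequence mapping (pre-extracted peak sequences); sequences
    are uppercased before scanning.  Overlapping and opposite-strand hits
    are counted separately.
    """
    scanner = MotifScanner(pwm, alpha=alpha, precision=precision)
    counts: dict[str, int] = {}
    for iv in sites:
        if isinstance(genome, Mapping) and iv.site_id in genome:
            seq = genome[iv.site_id]
        else:
            try:
                seq = _fetch_sequence(genome, iv.chrom, iv.start, iv.end)
            except KeyError as exc:
                raise KeyError(
                    f"site {iv.site_id}: chromosome {iv.chrom!r} absent from genome"
                ) from exc
            if len(seq) < iv.length:
                raise ValueError(
                    f"site {iv.site_id} extends past the end of {iv.chrom}"
                )
        counts[iv.site_id] = scanner.count(seq.upper())
    return counts


def write_hits_tsv(hits: Iterable[MotifHit], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "site_id": h.site_id,
                "offset": h.offset,
                "strand": h.strand,
                "score": h.score,
                "p_value": h.pvalue,
            }
            for h in hits
        ]
    ).to_csv(path, sep="\t", index=False)
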