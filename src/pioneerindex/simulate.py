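"""Synthetic dose-response experiments with known ground truth.

Generates everything the pipeline consumes — binding-peak BEDs per
replicate, pre-induction ATAC peaks, per-site RPKM signal matrices across
the dose grid, peak sequences with embedded motifs, chromatin-mark BEDs and
CpG methylation tables — from a known per-site truth (dox50, accessibility
class, binding modality, motif count, mark membership, methylation level),
so every stage of the analysis can be validated by parameter recovery.

Generative model
----------------
Per-site affinities are log-normal within each accessibility class (dox50
is a positive scale parameter and observed genome-wide distributions are
right-skewed).  Raw signal at dose ``d`` is

    rpkm(d) = amplitude * shape(d) * exp(eps),   eps ~ Normal(0, cv^2)

i.e. multiplicative noise, reflecting read-count normalisation.  The shape
is the binding isotherm ``d / (d + dox50)`` for saturation sites; for
anti-cooperative sites it is multiplied by a high-dose inhibition term
``1 / (1 + d / d_inhibit)`` — a phenomenological mechanism (consistent with
a TF whose dimeric form at high expression cannot co-bind) chosen so the
noiseless curve peaks exactly at an interior dose; it is a test fixture,
not a biological claim.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .dose_response import (
    DEFAULT_DOSES,
    DoseGrid,
    SignalProfile,
    binding_isotherm,
    write_signal_matrix,
)
from .intervals import GenomicInterval, PeakSet, write_bed
from .motifs import ALPHABET, PWM, MotifScanner

__all__ = [
    "SimulationConfig",
    "SimulatedExperiment",
    "simulate_binding_dataset",
    "simulate_sequences",
    "simulate_annotation_tracks",
    "write_dataset",
    "TOY_PWM",
]

#: Width-8, strongly non-palindromic toy motif used by default when
#: embedding sequences (consensus TTGACTCA-like, AP-1 flavoured).
TOY_PWM = PWM.from_counts(
    "TOY1",
    np.array(
        [
            [1, 1, 1, 17],
            [1, 1, 1, 17],
            [1, 1, 17, 1],
            [17, 1, 1, 1],
            [1, 17, 1, 1],
            [1, 1, 1, 17],
            [1, 17, 1, 1],
            [17, 1, 1, 1],
        ]
    ),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic experiment.

    Defaults emulate the real induction series: six doses over a 1000-fold
    range, two replicates, ~10% multiplicative signal noise, accessible
    sites with higher affinity (log-mean dox50 ln 0.2) than inaccessible
    ones (ln 0.5) and a common log-sd of 0.5 that keeps essentially all
    sites within the assayed dose range.
    """

    n_accessible: int = 1000
    n_inaccessible: int = 1000
    doses: tuple[float, ...] = DEFAULT_DOSES
    log_mean_dox50_accessible: float = float(np.log(0.2))
    log_mean_dox50_inaccessible: float = float(np.log(0.5))
    log_sd_dox50: float = 0.5
    log_mean_amplitude: float = float(np.log(10.0))
    log_sd_amplitude: float = 0.5
    noise_cv: float = 0.1
    frac_anti_cooperative_accessible: float = 0.0
    frac_anti_cooperative_inaccessible: float = 0.0
    #: 1-based interior dose positions at which anti-cooperative curves peak.
    anti_coop_peak_positions: tuple[int, ...] = (3, 4)
    n_replicates: int = 2
    site_length: int = 200
    site_gap: int = 300
    atac_margin: int = 50
    chrom: str = "chr1"
    motif_count_mean: float = 2.0
    #: Per-mark membership probability for (accessible, inaccessible) sites;
    #: loosely mirrors active marks enriched at accessible sites and
    #: silencing marks confined to inaccessible ones.
    mark_probabilities: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "H3K27Ac": (0.6, 0.1),
            "H3K4me1": (0.4, 0.2),
            "H3K9me3": (0.0, 0.05),
            "H3K27me3": (0.02, 0.15),
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (
            self.frac_anti_cooperative_accessible,
            self.frac_anti_cooperative_inaccessible,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("anti-cooperative fractions must lie in [0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    @property
    def grid(self) -> DoseGrid:
        return DoseGrid(self.doses)


@dataclass
class SimulatedExperiment:
    """A complete synthetic experiment plus its ground truth."""

    config: SimulationConfig
    sites: PeakSet            # replicate-1 peaks: the binding-site universe
    rep2_peaks: PeakSet       # jittered replicate-2 peaks (all overlap rep1)
    atac_peaks: PeakSet       # pre-induction accessibility peaks
    profiles: list[SignalProfile]
    truth: pd.DataFrame       # one row per site

    @property
    def grid(self) -> DoseGrid:
        return self.config.grid


def _curve_shape(doses: np.ndarray, dox50: float, d_inhibit: float | None) -> np.ndarray:
    shape = binding_isotherm(doses, dox50)
    if d_inhibit is not None:
        shape = shape / (1.0 + doses / d_inhibit)
    return shape


def simulate_binding_dataset(config: SimulationConfig) -> SimulatedExperiment:
    """Draw one full experiment from the generative model.

    Sites are laid head-to-tail along a toy chromosome with a fixed gap;
    accessible and inaccessible sites are interleaved in seeded random
    order, and ATAC peaks cover exactly the accessible sites (extended by
    ``atac_margin``).  Replicate-2 peaks are replicate-1 peaks jittered by
    at most a quarter of the site length, so every replicate pair overlaps.
    Identical configs give identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    doses = grid.array
    n_total = config.n_accessible + config.n_inaccessible
    if config.site_gap <= 2 * config.atac_margin:
        raise ValueError("site_gap must exceed twice atac_margin")

    classes = np.array(
        ["accessible"] * config.n_accessible
        + ["inaccessible"] * config.n_inaccessible
    )
    rng.shuffle(classes)

    records = []
    site_ivals, rep2_ivals, atac_ivals = [], [], []
    step = config.site_length + config.site_gap
    jitter_max = config.site_length // 4
    for i, cls in enumerate(classes):
        start = config.site_gap + i * step
        end = start + config.site_length
        sid = f"site{i:05d}"
        site_ivals.append(GenomicInterval(config.chrom, start, end, sid))
        jit = int(rng.integers(-jitter_max, jitter_max + 1))
        rep2_ivals.append(
            GenomicInterval(config.chrom, start + jit, end + jit, f"rep2_{sid}")
        )
        if cls == "accessible":
            atac_ivals.append(
                GenomicInterval(
                    config.chrom,
                    start - config.atac_margin,
                    end + config.atac_margin,
                    f"atac_{sid}",
                )
            )
        frac_ac = (
            config.frac_anti_cooperative_accessible
            if cls == "accessible"
            else config.frac_anti_cooperative_inaccessible
        )
        anti = bool(rng.random() < frac_ac)
        log_mu = (
            config.log_mean_dox50_accessible
            if cls == "accessible"
            else config.log_mean_dox50_inaccessible
        )
        dox50 = float(rng.lognormal(log_mu, config.log_sd_dox50))
        if anti:
            pos = int(rng.choice(config.anti_coop_peak_positions))
            d_peak = doses[pos - 1]
            d_inhibit = float(d_peak**2 / dox50)
        else:
            d_inhibit = np.nan
        records.append(
            {
                "site_id": sid,
                "chrom": config.chrom,
                "start": start,
                "end": end,
                "accessibility": cls,
                "true_dox50": dox50,
                "modality": "anti_cooperative" if anti else "saturation",
                "d_inhibit": d_inhibit,
                "true_motif_count": int(rng.poisson(config.motif_count_mean)),
            }
        )

    truth = pd.DataFrame(records)
    for mark, (p_acc, p_inacc) in config.mark_probabilities.items():
        p = np.where(truth["accessibility"] == "accessible", p_acc, p_inacc)
        truth[mark] = rng.random(n_total) < p
    # methylation: accessible regions skew hypomethylated, inaccessible
    # sites sit in broadly methylated chromatin
    meth = np.where(
        truth["accessibility"] == "accessible",
        rng.beta(1.5, 5.0, n_total),
        rng.beta(2.0, 2.0, n_total),
    )
    truth["true_methylation"] = 100.0 * meth

    amplitudes = rng.lognormal(
        config.log_mean_amplitude, config.log_sd_amplitude, n_total
    )
    profiles: list[SignalProfile] = []
    for rep in range(1, config.n_replicates + 1):
        rep_id = f"rep{rep}"
        for j, row in enumerate(truth.itertuples()):
            d_inh = None if np.isnan(row.d_inhibit) else row.d_inhibit
            shape = _curve_shape(doses, row.true_dox50, d_inh)
            eps = (
                rng.normal(0.0, config.noise_cv, len(doses))
                if config.noise_cv > 0
                else np.zeros(len(doses))
            )
            profiles.append(
                SignalProfile(
                    site_id=row.site_id,
                    replicate_id=rep_id,
                    rpkm=amplitudes[j] * shape * np.exp(eps),
                )
            )

    return SimulatedExperiment(
        config=config,
        sites=PeakSet(site_ivals, label="rep1"),
        rep2_peaks=PeakSet(rep2_ivals, label="rep2"),
        atac_peaks=PeakSet(atac_ivals, label="atac"),
        profiles=profiles,
        truth=truth,
    )


def simulate_sequences(
    truth: pd.DataFrame,
    pwm: PWM = TOY_PWM,
    background: np.ndarray | None = None,
    seed: int = 0,
    alpha: float = 1e-3,
    max_attempts: int = 100,
) -> dict[str, str]:
    """Per-site sequences containing exactly the true number of motif hits.

    Each site's sequence carries its ``true_motif_count`` consensus
    embeddings at recorded non-overlapping offsets inside background
    sequence that is rejection-sampled until a scan at ``alpha`` finds
    exactly that many hits (no spurious background or reverse-strand
    matches).  Embedding offsets are written back into the truth frame as
    ``motif_offsets`` (comma-separated).
    """
    rng = np.random.default_rng(seed)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    scanner = MotifScanner(pwm, alpha=alpha)
    w = pwm.width
    consensus = pwm.consensus
    seqs: dict[str, str] = {}
    offsets_col = []
    for row in truth.itertuples():
        length = row.end - row.start
        count = int(row.true_motif_count)
        if count * (w + 1) > length:
            raise ValueError(
                f"{row.site_id}: cannot place {count} motifs of width {w} "
                f"in {length} bp"
            )
        for attempt in range(max_attempts):
            bases = rng.choice(4, size=length, p=bg)
            seq = np.array(list(ALPHABET), dtype="U1")[bases]
            # choose non-overlapping offsets on a lattice, then jitter-free
            slots = length // w
            chosen = sorted(rng.choice(slots, size=count, replace=False)) if count else []
            offs = [int(s * w) for s in chosen]
            for off in offs:
                seq[off : off + w] = list(consensus)
            s = "".join(seq)
            hits = scanner.scan(s)
            if len(hits) == count and all(
                h.offset in offs and h.strand == "+" for h in hits
            ):
                seqs[row.site_id] = s
                offsets_col.append(",".join(str(o) for o in offs))
                break
        else:
            raise RuntimeError(
                f"{row.site_id}: no hit-clean background found in "
                f"{max_attempts} attempts; use longer sites or a stricter alpha"
            )
    truth["motif_offsets"] = offsets_col
    return seqs


def simulate_annotation_tracks(
    truth: pd.DataFrame,
    seed: int = 0,
    mean_cpg_per_site: float = 5.0,
    mean_coverage: float = 20.0,
    percent_sd: float = 5.0,
) -> tuple[dict[str, PeakSet], pd.DataFrame]:
    """Chromatin-mark regions and a CpG methylation table matching truth.

    Mark regions are exactly the intervals of the sites flagged for that
    mark (sites never overlap each other, so non-flagged sites stay clear).
    Each site receives ``1 + Poisson(mean_cpg_per_site - 1)`` CpGs at unique
    positions, coverage ~ Poisson(mean_coverage) and percent methylation
    drawn around the site's true level.
    """
    rng = np.random.default_rng(seed)
    mark_cols = [
        c
        for c in truth.columns
        if truth[c].dtype == bool
    ]
    marks: dict[str, PeakSet] = {}
    for mark in mark_cols:
        flagged = truth[truth[mark]]
        marks[mark] = PeakSet(
            [
                GenomicInterval(r.chrom, r.start, r.end, f"{mark}_{r.site_id}")
                for r in flagged.itertuples()
            ],
            label=mark,
        )
    rows = []
    for r in truth.itertuples():
        n_cpg = 1 + int(rng.poisson(max(mean_cpg_per_site - 1.0, 0.0)))
        n_cpg = min(n_cpg, r.end - r.start)
        positions = rng.choice(r.end - r.start, size=n_cpg, replace=False) + r.start
        for pos in sorted(int(p) for p in positions):
            pct = float(np.clip(rng.normal(r.true_methylation, percent_sd), 0, 100))
            rows.append(
                {
                    "chrom": r.chrom,
                    "position": pos,
                    "coverage": int(rng.poisson(mean_coverage)),
                    "percent_methylated": pct,
                }
            )
    return marks, pd.DataFrame(rows)


def write_dataset(
    experiment: SimulatedExperiment,
    outdir: str | Path,
    sequences: Mapping[str, str] | None = None,
    marks: Mapping[str, PeakSet] | None = None,
    methylation: pd.DataFrame | None = None,
    detection_rpkm: float = 1.0,
) -> dict[str, Path]:
    """Write the experiment in the on-disk formats the pipeline consumes.

    Emits per-replicate top-dose peak BEDs plus, per lower dose, the peaks
    whose expected signal clears a detection floor (so peak numbers grow
    with induction, as in the real assay), the ATAC BED, the two-replicate
    signal matrix TSV, mark BEDs, the methylation TSV, site sequences as
    FASTA and the truth table.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    cfg = experiment.config
    grid = experiment.grid

    top = grid.top
    write_bed(experiment.sites, outdir / f"peaks_rep1_{top}.bed")
    write_bed(experiment.rep2_peaks, outdir / f"peaks_rep2_{top}.bed")
    paths["peaks_rep1"] = outdir / f"peaks_rep1_{top}.bed"
    paths["peaks_rep2"] = outdir / f"peaks_rep2_{top}.bed"

    by_rep: dict[str, dict[str, np.ndarray]] = {}
    for p in experiment.profiles:
        by_rep.setdefault(p.replicate_id, {})[p.site_id] = p.rpkm
    for d_idx, dose in enumerate(grid.doses[:-1]):
        rep1 = by_rep.get("rep1", {})
        called = [
            iv
            for iv in experiment.sites
            if rep1.get(iv.site_id) is not None
            and rep1[iv.site_id][d_idx] >= detection_rpkm
        ]
        path = outdir / f"peaks_rep1_{dose}.bed"
        write_bed(PeakSet(called, label=f"rep1@{dose}"), path)
        paths[f"peaks_rep1_{dose}"] = path

    write_bed(experiment.atac_peaks, outdir / "atac.bed")
    paths["atac"] = outdir / "atac.bed"

    write_signal_matrix(experiment.profiles, grid, outdir / "signal_matrix.tsv")
    paths["signal_matrix"] = outdir / "signal_matrix.tsv"

    if sequences is not None:
        fasta = outdir / "sites.fa"
        with open(fasta, "w") as fh:
            for sid, seq in sequences.items():
                fh.write(f">{sid}\n{seq}\n")
        paths["fasta"] = fasta
    if marks is not None:
        for mark, peaks in marks.items():
            path = outdir / f"mark_{mark}.bed"
            write_bed(peaks, path)
            paths[f"mark_{mark}"] = path
    if methylation is not None:
        path = outdir / "methylation.tsv"
        methylation.to_csv(path, sep="\t", index=False)
        paths["methylation"] = path

    truth_path = outdir / "truth.tsv"
    experiment.truth.to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    return paths
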