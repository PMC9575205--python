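"""End-to-end orchestration: peaks + signal in, pioneer index out.

Stages run in the order of the experimental analysis: build the
replicate-reproducible binding-site universe, label accessibility against
pre-induction ATAC peaks, normalise signal to fraction bound, filter
early-peaking sites, fit per-replicate dox50s, classify binding modalities,
average replicates, count motifs, annotate chromatin marks and methylation,
compute the pioneer activity index and partition dox50 variance.  Every
stage is a pure function of (inputs, config, seed); a manifest with the
config hash makes reruns checkable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .annotation import annotate_sites
from .dose_response import (
    BindingCurveFit,
    DoseGrid,
    SignalProfile,
    average_replicate_dox50,
    classify_modality,
    fit_dox50,
    fraction_bound,
    read_signal_matrix,
    write_fit_table,
)
from .intervals import PeakSet, intersect_replicates, label_accessibility, read_bed
from .motifs import PWM, count_motifs_per_site, read_jaspar_pfm
from .pioneer import (
    PioneerIndexResult,
    bin_by_motif_count,
    bootstrap_index_ci,
    pioneer_activity_index,
    summarize_dox50,
)
from .variance import accessibility_variance_report

logger = logging.getLogger("pioneerindex")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "analyze"]


@dataclass
class RunConfig:
    """Declarative description of one pipeline run (paths + thresholds)."""

    peaks_rep1: str
    peaks_rep2: str
    atac_peaks: str
    signal_matrix: str
    outdir: str
    doses: Sequence[float] = (0.005, 0.05, 0.1, 0.25, 0.5, 5.0)
    sequences_fasta: str | None = None
    pwm: str | None = None
    mark_beds: Mapping[str, str] = field(default_factory=dict)
    methylation: str | None = None
    motif_alpha: float = 1e-3
    strict_filter: bool = False
    bootstrap_ci: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def validate(self) -> None:
        required = {
            "peaks_rep1": self.peaks_rep1,
            "peaks_rep2": self.peaks_rep2,
            "atac_peaks": self.atac_peaks,
            "signal_matrix": self.signal_matrix,
        }
        optional = {
            "sequences_fasta": self.sequences_fasta,
            "pwm": self.pwm,
            "methylation": self.methylation,
        } | {f"mark_beds[{k}]": v for k, v in self.mark_beds.items()}
        for name, path in required.items():
            if not path or not Path(path).exists():
                raise FileNotFoundError(f"config field {name}: missing file {path!r}")
        for name, path in optional.items():
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"config field {name}: missing file {path!r}")

    def content_hash(self) -> str:
        payload = json.dumps(
            {k: (dict(v) if isinstance(v, Mapping) else v) for k, v in asdict(self).items()},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    universe: PeakSet
    accessibility: dict[str, str]
    fits: list[BindingCurveFit]
    consensus_dox50: dict[str, float]
    dropped: dict[str, str]
    modalities: dict[str, str]
    index: PioneerIndexResult
    variance: pd.DataFrame
    motif_counts: dict[str, int] | None = None
    motif_bins: dict[str, str] | None = None
    annotations: pd.DataFrame | None = None
    bootstrap_ci: tuple[float, float] | None = None
    manifest: dict = field(default_factory=dict)

    def site_accounting(self) -> dict[str, int]:
        """Reconciles the universe: reported + dropped = total."""
        return {
            "universe": len(self.universe),
            "reported": len(self.consensus_dox50),
            "dropped": len(self.dropped),
        }


def analyze(
    universe: PeakSet,
    accessibility: Mapping[str, str],
    profiles: Sequence[SignalProfile],
    grid: DoseGrid,
    sequences: Mapping[str, str] | None = None,
    pwm: PWM | None = None,
    mark_beds: Mapping[str, PeakSet] | None = None,
    methylation: pd.DataFrame | None = None,
    motif_alpha: float = 1e-3,
    strict_filter: bool = False,
    bootstrap: bool = False,
    seed: int = 0,
) -> PipelineResult:
    """Run the analysis stages on in-memory inputs (the library-level API)."""
    universe_ids = {iv.site_id for iv in universe}
    profiles = [p for p in profiles if p.site_id in universe_ids]
    logger.info("universe: %d sites, %d profiles", len(universe_ids), len(profiles))

    fits: list[BindingCurveFit] = []
    normalized: dict[str, list[SignalProfile]] = {}
    for p in profiles:
        p = fraction_bound(p, grid)
        if not p.unnormalizable:
            normalized.setdefault(p.site_id, []).append(p)
        fits.append(fit_dox50(p, grid, strict_greater=strict_filter))

    n_filtered = sum(1 for f in fits if f.filtered)
    n_unconverged = sum(1 for f in fits if not f.filtered and not f.converged)
    logger.info(
        "fits: %d total, %d filtered, %d unconverged",
        len(fits),
        n_filtered,
        n_unconverged,
    )

    consensus, dropped = average_replicate_dox50(fits)
    logger.info("consensus dox50 at %d sites (%d dropped)", len(consensus), len(dropped))

    # classify modality on the replicate-averaged normalised profile
    modalities: dict[str, str] = {}
    for sid, plist in normalized.items():
        mean_fb = np.mean([p.fraction_bound for p in plist], axis=0)
        modalities[sid] = classify_modality(mean_fb)

    index = pioneer_activity_index(consensus, accessibility)
    logger.info(
        "pioneer index %.3f (accessible %d, inaccessible %d)",
        index.index,
        index.n_accessible,
        index.n_inaccessible,
    )

    motif_counts = motif_bins = None
    if sequences is not None and pwm is not None:
        motif_counts = count_motifs_per_site(universe, sequences, pwm, alpha=motif_alpha)
        motif_bins = bin_by_motif_count(motif_counts)

    annotations = None
    if mark_beds or methylation is not None:
        annotations = annotate_sites(universe, mark_beds or None, methylation)

    mark_flags = None
    if annotations is not None and mark_beds:
        mark_flags = annotations[[m for m in mark_beds]].loc[
            [s for s in consensus if s in annotations.index]
        ]
    variance = accessibility_variance_report(consensus, dict(accessibility), mark_flags)

    ci = (
        bootstrap_index_ci(consensus, dict(accessibility), seed=seed)
        if bootstrap
        else None
    )
    return PipelineResult(
        universe=universe,
        accessibility=dict(accessibility),
        fits=fits,
        consensus_dox50=consensus,
        dropped=dropped,
        modalities=modalities,
        index=index,
        variance=variance,
        motif_counts=motif_counts,
        motif_bins=motif_bins,
        annotations=annotations,
        bootstrap_ci=ci,
    )


def _read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Load inputs per ``config``, run :func:`analyze`, write all outputs."""
    config.validate()
    grid = DoseGrid(tuple(config.doses))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    rep1 = read_bed(config.peaks_rep1, label="rep1")
    rep2 = read_bed(config.peaks_rep2, label="rep2")
    universe = intersect_replicates(rep1, rep2)
    atac = read_bed(config.atac_peaks, label="atac")
    accessibility = label_accessibility(universe, atac)
    profiles = read_signal_matrix(config.signal_matrix, grid)

    sequences = _read_fasta(config.sequences_fasta) if config.sequences_fasta else None
    pwm = read_jaspar_pfm(config.pwm) if config.pwm else None
    mark_beds = {
        mark: read_bed(path, label=mark) for mark, path in config.mark_beds.items()
    }
    methylation = None
    if config.methylation:
        from .annotation import read_methylation_table

        methylation = read_methylation_table(config.methylation)

    result = analyze(
        universe,
        accessibility,
        profiles,
        grid,
        sequences=sequences,
        pwm=pwm,
        mark_beds=mark_beds or None,
        methylation=methylation,
        motif_alpha=config.motif_alpha,
        strict_filter=config.strict_filter,
        bootstrap=config.bootstrap_ci,
        seed=config.seed,
    )

    # ---- outputs -----------------------------------------------------
    write_fit_table(
        result.fits,
        result.consensus_dox50,
        outdir / "fits.tsv",
        sites=universe,
        modalities=result.modalities,
    )
    groups: dict[str, list[float]] = {"accessible": [], "inaccessible": []}
    dist_rows = []
    for sid, k in result.consensus_dox50.items():
        lab = accessibility[sid]
        groups[lab].append(k)
        dist_rows.append({"group": lab, "site_id": sid, "dox50": k})
    pd.DataFrame(dist_rows).to_csv(outdir / "dox50_by_group.tsv", sep="\t", index=False)
    summarize_dox50({k: v for k, v in groups.items() if v}).to_csv(
        outdir / "dox50_summary.tsv", sep="\t", index=False
    )
    report = {"tf": universe.label, **result.index.to_dict()}
    if result.bootstrap_ci is not None:
        report["bootstrap_ci"] = list(result.bootstrap_ci)
    (outdir / "index_report.json").write_text(json.dumps(report, indent=2))
    result.variance.to_csv(outdir / "variance_fractions.tsv", sep="\t", index=False)
    if result.annotations is not None:
        result.annotations.to_csv(outdir / "annotations.tsv", sep="\t")
    if result.motif_counts is not None:
        pd.DataFrame(
            {
                "site_id": list(result.motif_counts),
                "motif_count": list(result.motif_counts.values()),
                "motif_bin": [result.motif_bins.get(s) for s in result.motif_counts],
            }
        ).to_csv(outdir / "motif_counts.tsv", sep="\t", index=False)

    result.manifest = {
        "config_hash": config.content_hash(),
        "version": __version__,
        "seed": config.seed,
        "sites": result.site_accounting(),
    }
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
    return result
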