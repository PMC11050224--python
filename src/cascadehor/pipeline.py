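"""End-to-end pipeline: spectrum -> monomers -> families -> scan -> HOR report.

``run_pipeline`` executes the five discovery stages on a FASTA assembly and
returns (optionally writing) the full report bundle: tandem regions, monomer
families, the enumerated track, MD series, monomer-level GRM spectrum, HOR
array regions with canonical units, copies, cascading schemes and a summary
table.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import discovery, families as fam_mod, hor, scanning
from .io import (
    read_fasta,
    track_to_frame,
    write_bed,
    write_fasta,
    write_json,
    write_tsv,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "run_pipeline_on_sequence"]

log = logging.getLogger("cascadehor")


@dataclass
class PipelineConfig:
    """All thresholds of the pipeline, with their documented defaults."""

    word_length: int = 12
    max_period: int = 6000
    window: int = 6000
    target_period: int = 171
    period_tolerance: int = 10
    density_threshold: float = 0.25
    min_region_monomers_discovery: int = 5
    family_threshold: float = 5.0
    linkage: str = "average"
    matrix_cap: float = 15.0
    accept_threshold: float = 25.0
    min_scan_members: int = 3
    min_length_fraction: float = 0.8
    max_gap_fraction: float = 0.5
    break_gap_monomers: int = 10
    support_fraction: float = 0.20
    subfragment_min_copy_fraction: float = 0.5
    secondary_min_fraction: float = 0.01
    secondary_min_count: int = 6
    min_region_monomers: int = 50
    interspersed_min_fraction: float = 0.10
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def validate(self) -> None:
        if not 0 < self.family_threshold <= 20:
            raise ValueError("family_threshold out of range (0, 20]")
        if not 0 < self.accept_threshold < 50:
            raise ValueError("accept_threshold out of range (0, 50)")
        if not 0 < self.support_fraction <= 1:
            raise ValueError("support_fraction out of range (0, 1]")
        if self.word_length < 8:
            raise ValueError("word_length must be >= 8")


@dataclass
class RegionReport:
    """Everything inferred about one HOR array region."""

    region: hor.HORArrayRegion
    units: tuple[tuple[int, ...], ...]
    copies: list[hor.HORCopy]
    scheme: hor.CascadingScheme
    hor_type: str

    @property
    def n(self) -> int:
        return self.region.primary_period

    @property
    def tau(self) -> int | None:
        return None if len(self.units) > 1 else self.scheme.n_types

    @property
    def canonical_fraction(self) -> float:
        if not self.copies:
            return 0.0
        return sum(c.label == "canonical" for c in self.copies) / len(self.copies)


@dataclass
class PipelineResult:
    sequence_id: str
    config: PipelineConfig
    spectrum: discovery.RawSpectrum
    regions: list[discovery.TandemRegion]
    candidates: list[str]
    families: list[fam_mod.MonomerFamily]
    scan_families: list[fam_mod.MonomerFamily]
    track: scanning.MonomerTrack
    md_points: list[hor.MDPoint]
    monomer_spectrum: dict[int, int]
    hor_regions: list[RegionReport] = field(default_factory=list)
    timings: dict[str, float] = field(default_factory=dict)

    def summary(self) -> list[dict]:
        out = []
        for i, rep in enumerate(self.hor_regions, start=1):
            n_copies = len(rep.copies)
            if len(rep.units) > 1:
                per_unit = {
                    f"{len(u)}mer": sum(
                        1 for c in rep.copies if c.family_ids == tuple(u)
                    )
                    for u in rep.units
                }
            else:
                per_unit = None
            out.append(
                {
                    "notation": f"hor{i}",
                    "n": rep.n,
                    "n_units": sorted(len(u) for u in rep.units),
                    "tau": rep.tau,
                    "n_copies": n_copies,
                    "copies_per_unit": per_unit,
                    "canonical_fraction": round(rep.canonical_fraction, 4),
                    "hor_type": rep.hor_type,
                    "subfragment_periods": sorted(rep.region.subfragment_periods),
                    "secondary_periods": sorted(rep.region.secondary_periods),
                    "enumeration_span": [rep.region.first, rep.region.last],
                    "genomic_span": list(rep.region.genomic_span or ()),
                }
            )
        return out


def _classify(rep_units, scheme) -> str:
    if len(rep_units) > 1:
        return "interspersed_willard"
    return "willard" if scheme.n_rows == 1 else "cascading"


def run_pipeline_on_sequence(
    sequence: str, config: PipelineConfig | None = None, sequence_id: str = "assembly"
) -> PipelineResult:
    """Run the five discovery stages on an in-memory sequence."""
    cfg = config or PipelineConfig()
    cfg.validate()
    if not sequence:
        raise ValueError("empty sequence")
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    spectrum = discovery.raw_repeat_spectrum(
        sequence, cfg.word_length, cfg.max_period, cfg.window
    )
    timings["spectrum"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    regions = discovery.find_tandem_regions(
        sequence,
        spectrum,
        target_period=cfg.target_period,
        tolerance=cfg.period_tolerance,
        min_monomers=cfg.min_region_monomers_discovery,
        density_threshold=cfg.density_threshold,
    )
    candidates = discovery.extract_candidate_monomers(sequence, regions)
    timings["monomers"] = time.perf_counter() - t0
    log.info("found %d tandem regions, %d candidate monomers", len(regions), len(candidates))
    if not candidates:
        raise ValueError("no candidate monomers detected; not an alpha-satellite-like input?")

    t0 = time.perf_counter()
    fams, _labels = fam_mod.build_families(
        candidates, threshold=cfg.family_threshold, method=cfg.linkage, cap=cfg.matrix_cap
    )
    scan_fams, merged = fam_mod.merge_rotated_families(fams, threshold=cfg.family_threshold)
    # low-support families are kept in the report but excluded from the scan:
    # a 1-2 member "family" is usually an outlier monomer that would always
    # win back its own locus and corrupt the type sequence there
    strong = [f for f in scan_fams if f.member_count >= cfg.min_scan_members]
    if strong:
        scan_fams = strong
    timings["families"] = time.perf_counter() - t0
    log.info("%d families (%d kept after rotation merge)", len(fams), len(scan_fams))

    t0 = time.perf_counter()
    track = scanning.scan(
        sequence,
        scan_fams,
        accept_threshold=cfg.accept_threshold,
        min_length_fraction=cfg.min_length_fraction,
        assembly_id=sequence_id,
    )
    track = scanning.tandem_enumerate(
        track, max_gap_fraction=cfg.max_gap_fraction, break_gap_monomers=cfg.break_gap_monomers
    )
    timings["scan"] = time.perf_counter() - t0
    log.info("track: %d instances, %d enumerated", len(track.instances), len(track.enumerated()))

    t0 = time.perf_counter()
    md_points = hor.md_series(track)
    mono_spec = hor.monomer_grm_spectrum(md_points)
    hor_regions_raw = hor.detect_hor_arrays(
        md_points,
        min_region_monomers=cfg.min_region_monomers,
        support_fraction=cfg.support_fraction,
        track=track,
    )
    reports: list[RegionReport] = []
    for region in hor_regions_raw:
        region.subfragment_periods = hor.subfragment_periods(
            md_points, region, min_copy_fraction=cfg.subfragment_min_copy_fraction
        )
        region.secondary_periods = hor.secondary_periods(
            md_points,
            region,
            min_fraction=cfg.secondary_min_fraction,
            min_count=cfg.secondary_min_count,
        )
        units = hor.infer_canonical_unit(
            track, region, interspersed_min_fraction=cfg.interspersed_min_fraction
        )
        copies = hor.segment_copies(track, region, units)
        scheme = hor.build_scheme(units[0])
        reports.append(RegionReport(region, units, copies, scheme, _classify(units, scheme)))
    timings["hor"] = time.perf_counter() - t0

    return PipelineResult(
        sequence_id=sequence_id,
        config=cfg,
        spectrum=spectrum,
        regions=regions,
        candidates=candidates,
        families=fams,
        scan_families=scan_fams,
        track=track,
        md_points=md_points,
        monomer_spectrum=mono_spec,
        hor_regions=reports,
        timings=timings,
    )


def run_pipeline(
    fasta_path,
    config: PipelineConfig | None = None,
    out_dir=None,
    plot: bool = False,
) -> PipelineResult:
    """Run the pipeline on a FASTA file and optionally write the report bundle."""
    records = read_fasta(fasta_path)
    rec = records[0]
    if len(records) > 1:
        log.warning("multiple FASTA records; analysing the first (%s)", rec.id)
    result = run_pipeline_on_sequence(str(rec.seq), config, sequence_id=rec.id)
    if out_dir is not None:
        write_report(result, out_dir, plot=plot)
    return result


def write_report(result: PipelineResult, out_dir, plot: bool = False) -> None:
    """Write the full artifact bundle for a pipeline run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cid = result.sequence_id

    write_tsv(
        out / "raw_spectrum.tsv",
        pd.DataFrame(
            sorted(result.spectrum.counts.items()), columns=["period_bp", "count"]
        ),
    )
    write_bed(
        out / "tandem_regions.bed",
        [(cid, r.start, r.end, f"period_{r.base_period}") for r in result.regions],
    )
    write_fasta(
        out / "families.fa",
        [
            (f"family_{f.family_id} n={f.member_count}", f.consensus)
            for f in result.families
        ],
    )
    write_bed(
        out / "track.bed",
        [
            (cid, m.start, m.end, m.family_id, int(round(m.divergence * 10)), m.strand)
            for m in result.track.instances
        ],
    )
    write_tsv(out / "track.tsv", track_to_frame(result.track))
    write_tsv(
        out / "md_series.tsv",
        pd.DataFrame(
            {
                "enumeration_index": [p.enumeration_index for p in result.md_points],
                "family_id": [p.family_id for p in result.md_points],
                "period": [p.period for p in result.md_points],
            }
        ),
    )
    write_tsv(
        out / "monomer_grm.tsv",
        pd.DataFrame(
            sorted(result.monomer_spectrum.items()), columns=["period_monomers", "count"]
        ),
    )
    write_bed(
        out / "hor_arrays.bed",
        [
            (
                cid,
                rep.region.genomic_span[0] if rep.region.genomic_span else 0,
                rep.region.genomic_span[1] if rep.region.genomic_span else 0,
                f"{rep.n}mer_{rep.hor_type}",
            )
            for rep in result.hor_regions
        ],
    )
    copy_rows = []
    for i, rep in enumerate(result.hor_regions, start=1):
        for j, c in enumerate(rep.copies, start=1):
            copy_rows.append(
                {
                    "region": f"hor{i}",
                    "copy": j,
                    "first": c.enumeration_indices[0],
                    "last": c.enumeration_indices[-1],
                    "n_monomers": len(c),
                    "label": c.label,
                    "signature": ",".join(f"t{t}" for t in c.local_types),
                }
            )
    write_tsv(out / "copies.tsv", pd.DataFrame(copy_rows))
    with open(out / "schemes.txt", "w") as fh:
        for i, rep in enumerate(result.hor_regions, start=1):
            fh.write(
                f"# hor{i}: n={rep.n} tau={rep.tau if rep.tau is not None else '-'} "
                f"rows={rep.scheme.n_rows} type={rep.hor_type}\n"
            )
            fh.write(rep.scheme.render() + "\n\n")
    write_json(out / "summary.json", {"config": result.config.to_dict(), "arrays": result.summary()})
    if plot:
        from .plotting import plot_grm_spectrum, plot_md_diagram

        plot_grm_spectrum(result.monomer_spectrum, out / "grm_monomer.png")
        plot_md_diagram(result.md_points, out / "md_diagram.png")
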