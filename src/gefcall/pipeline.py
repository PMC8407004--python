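"""Pipeline driver: simulate -> trim -> map -> call -> compare -> scan.

One flat YAML config holds every module default plus the seed and condition
names; :func:`run_pipeline` executes the stages per condition, reconciles
read/fragment counts across stages, and writes deterministic TSV/BED outputs
(identical seed + config => byte-identical files).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import compare, footprint, motif, simgen
from .ioformats import ConfigError, DataError, write_bed, write_bedgraph, BedRecord
from .motif import IUPACPattern
from .readprep import GenomeIndex, LENGTH_SLACK, trim_adapter, map_read_pair

__version__ = "0.1.0"

log = logging.getLogger("gefcall")


@dataclass
class SiteConfig:
    site_id: str
    pattern: str
    position: int
    occupancy: dict[str, float]
    strand: str = "+"


@dataclass
class PipelineConfig:
    """Every knob of the end-to-end run; round-trips losslessly through YAML."""

    seed: int | None = None
    conditions: list[str] = field(default_factory=lambda: list(compare.DEFAULT_CONDITIONS))
    ref_condition: str = "0min"
    # simulation
    genome_length: int = 100_000
    gc_fraction: float = 0.5
    read_length: int = 100
    adapter_seq: str = simgen.DEFAULT_ADAPTER
    protected_len_min: int = 70
    protected_len_max: int = 110
    background_fragments: int = 20_000
    enrichment_depth: int = 200
    error_rate: float = 0.0
    sites: list[SiteConfig] = field(default_factory=list)
    # read prep
    min_overlap: int = 3
    max_mismatch_rate: float = 0.1
    # caller
    ewf: int = 70
    ewt: int = 110
    base_threshold: int = 90
    end_support_min: int = 3
    max_components_per_peak: int | None = None
    # motif
    consensus_pattern: str = motif.CONSENSUS_PRESETS["known"]
    fasta_flank: int = 0

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("a seed is required for a reproducible run")
        if not self.conditions:
            raise ConfigError("at least one condition is required")
        if self.ref_condition not in self.conditions:
            raise ConfigError(f"ref_condition {self.ref_condition!r} not in conditions")
        if not 0 < self.ewf <= self.ewt:
            raise ConfigError(f"need 0 < ewf <= ewt, got ewf={self.ewf} ewt={self.ewt}")
        try:
            self.sim_config().validate()
            self.caller_config().validate()
            for s in self.sites:
                IUPACPattern(s.pattern)
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc
        for s in self.sites:
            missing = [c for c in self.conditions if c not in s.occupancy]
            if missing:
                raise ConfigError(f"site {s.site_id!r}: occupancy missing for {missing}")

    def sim_config(self) -> simgen.SimConfig:
        return simgen.SimConfig(
            genome_length=self.genome_length,
            gc_fraction=self.gc_fraction,
            read_length=self.read_length,
            adapter_seq=self.adapter_seq,
            protected_len_min=self.protected_len_min,
            protected_len_max=self.protected_len_max,
            background_fragments=self.background_fragments,
            enrichment_depth=self.enrichment_depth,
            error_rate=self.error_rate,
            seed=self.seed if self.seed is not None else 0,
        )

    def caller_config(self) -> footprint.CallerConfig:
        return footprint.CallerConfig(
            ewf=self.ewf,
            ewt=self.ewt,
            base_threshold=self.base_threshold,
            end_support_min=self.end_support_min,
            max_components_per_peak=self.max_components_per_peak,
        )

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["version"] = __version__
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.pop("version", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigError(f"unknown config key(s): {unknown}")
        sites = [SiteConfig(**s) for s in data.pop("sites", [])]
        return cls(sites=sites, **data)


def demo_config(seed: int = 1, genome_length: int = 100_000) -> PipelineConfig:
    """The four-condition cell-cycle experiment on a 100 kb genome.

    Twelve planted sites: an origin-like site occupied almost exclusively
    before initiation, a transient site occupied only 10 min after initiation,
    and ten constitutive sites; occupancy schedules and enrichment depth are
    the package's canonical study conditions (see docs/methods.md).
    """
    n_sites = 12
    spacing = genome_length // (n_sites + 1)
    sites = []
    known = motif.CONSENSUS_PRESETS["known"]
    schedules = {
        "oriC_like": {"0min": 0.9, "10min": 0.05, "20min": 0.05, "random": 0.2},
        "ttcA_like": {"0min": 0.05, "10min": 0.8, "20min": 0.05, "random": 0.2},
    }
    for k in range(n_sites):
        pos = spacing * (k + 1)
        if k == 0:
            sites.append(SiteConfig("oriC_like", known, pos, schedules["oriC_like"]))
        elif k == 1:
            sites.append(
                SiteConfig("ttcA_like", motif.CONSENSUS_PRESETS["ttca"], pos, schedules["ttcA_like"])
            )
        else:
            sites.append(
                SiteConfig(
                    f"constitutive_{k - 1}",
                    known,
                    pos,
                    {c: 0.6 for c in compare.DEFAULT_CONDITIONS},
                )
            )
    return PipelineConfig(seed=seed, genome_length=genome_length, sites=sites)


# --------------------------------------------------------------------------
# run log
# --------------------------------------------------------------------------

@dataclass
class RunLog:
    """Structured per-stage counts; totals must reconcile across stages."""

    records: list[dict] = field(default_factory=list)

    def record(self, stage: str, condition: str = "", **counts) -> None:
        self.records.append({"stage": stage, "condition": condition, **counts})
        log.info("%s %s %s", stage, condition, counts)

    def reconcile(self, condition: str) -> None:
        """Assert pairs_in == mapped + ambiguous + unmapped + dropped_length."""
        for rec in self.records:
            if rec["stage"] == "map" and rec["condition"] == condition:
                accounted = (
                    rec["mapped"] + rec["ambiguous"] + rec["unmapped"] + rec["dropped_length"]
                )
                if accounted != rec["pairs_in"]:
                    raise DataError(
                        f"{condition}: {rec['pairs_in']} pairs in but {accounted} accounted for"
                    )

    def to_tsv(self, path) -> None:
        keys = sorted({k for rec in self.records for k in rec} - {"stage", "condition"})
        with open(path, "w") as fh:
            fh.write("stage\tcondition\t" + "\t".join(keys) + "\n")
            for rec in self.records:
                fh.write(
                    f"{rec['stage']}\t{rec['condition']}\t"
                    + "\t".join(str(rec.get(k, "")) for k in keys)
                    + "\n"
                )


@dataclass
class RunResult:
    outdir: Path
    genome: str
    truth: simgen.TruthSet
    fragments: dict[str, list]
    components: dict[str, list]
    thresholds: dict[str, int]
    total_mapped: dict[str, int]
    occupancy: compare.OccupancyTable
    specificity: "object"          # pandas DataFrame
    runlog: RunLog


# --------------------------------------------------------------------------
# driver
# --------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, outdir, with_reads: bool = True) -> RunResult:
    """Execute the full pipeline into ``outdir``.

    ``with_reads=False`` skips the FASTQ round trip and feeds the simulated
    fragment intervals straight to the caller — the fast path used for
    replicated experiments, exact on error-free data since trimming+mapping
    recovers the intervals (verified separately by the round-trip tests).
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    runlog = RunLog()
    seed_rng = np.random.default_rng(config.seed)

    def next_seed() -> int:
        return int(seed_rng.integers(2**31))

    genome = simgen.generate_genome(config.genome_length, config.gc_fraction, next_seed())
    specs = [
        simgen.SiteSpec(s.site_id, IUPACPattern(s.pattern), s.position, s.occupancy, s.strand)
        for s in config.sites
    ]
    genome, truth = simgen.plant_sites(genome, specs, next_seed())
    simgen.write_truth(outdir, truth, config.conditions)
    config.to_yaml(outdir / "pipeline_config.yaml")
    runlog.record("simulate_genome", length=len(genome), sites=len(truth.sites))

    index = GenomeIndex(genome) if with_reads else None
    cfg = config.caller_config()
    max_fragment = config.ewt + LENGTH_SLACK

    fragments: dict[str, list] = {}
    profiles: dict[str, footprint.DepthProfile] = {}
    end_profiles: dict[str, footprint.EndProfile] = {}
    for cond in config.conditions:
        cdir = outdir / cond
        cdir.mkdir(exist_ok=True)
        # both seeds are always drawn so the fragment stream is identical
        # whether or not the FASTQ round trip runs
        frag_seed, read_seed = next_seed(), next_seed()
        true_frags = simgen.simulate_fragments(
            truth,
            cond,
            config.background_fragments,
            config.enrichment_depth,
            frag_seed,
            protected_len_min=config.protected_len_min,
            protected_len_max=config.protected_len_max,
        )
        runlog.record("simulate_fragments", cond, fragments=len(true_frags))
        if with_reads:
            pairs = simgen.fragments_to_reads(
                true_frags, genome, config.read_length, config.adapter_seq,
                error_rate=config.error_rate, seed=read_seed,
            )
            simgen.write_sim_outputs(cdir, config.sim_config(), true_frags, pairs, cond)
            counts = {"pairs_in": len(pairs), "mapped": 0, "ambiguous": 0, "unmapped": 0,
                      "dropped_length": 0}
            frags = []
            with open(cdir / "rejects.log", "w") as rejects:
                for r1, r2 in pairs:
                    t1 = trim_adapter(r1.seq, config.adapter_seq, config.min_overlap,
                                      config.max_mismatch_rate)
                    t2 = trim_adapter(r2.seq, config.adapter_seq, config.min_overlap,
                                      config.max_mismatch_rate)
                    verdict = map_read_pair(t1, t2, index, max_fragment=max_fragment)
                    if verdict.status == "mapped":
                        counts["mapped"] += 1
                        frags.append(verdict.fragment)
                    else:
                        key = "dropped_length" if "length" in verdict.reason else verdict.status
                        counts[key] += 1
                        rejects.write(f"{r1.name}\t{verdict.status}\t{verdict.reason}\n")
            runlog.record("map", cond, **counts)
            runlog.reconcile(cond)
        else:
            frags = true_frags
        frags.sort()
        fragments[cond] = frags
        write_bed(
            cdir / "fragments.bed",
            (BedRecord(f.chrom, f.start, f.end, f"frag{i}", 0, "+") for i, f in enumerate(frags)),
        )
        depth, ends = footprint.compute_profiles(frags, len(genome))
        profiles[cond], end_profiles[cond] = depth, ends
        write_bedgraph(cdir / "depth.bedgraph", depth.depth)
        write_bedgraph(cdir / "ends_left.bedgraph", ends.left_ends)
        write_bedgraph(cdir / "ends_right.bedgraph", ends.right_ends)

    total_mapped = {c: len(fragments[c]) for c in config.conditions}
    ref_mapped = total_mapped[config.ref_condition]
    thresholds = {
        c: footprint.scale_threshold(config.base_threshold, ref_mapped, total_mapped[c])
        for c in config.conditions
    }
    scales = {c: compare.display_scale(ref_mapped, total_mapped[c]) for c in config.conditions}

    components: dict[str, list] = {}
    for cond in config.conditions:
        comps = footprint.call_components(
            profiles[cond], end_profiles[cond], cfg, thresholds[cond], fragments=fragments[cond]
        )
        peaks = footprint.merge_peaks(comps)
        components[cond] = comps
        cdir = outdir / cond
        footprint.export_components(comps, peaks, cdir / "components.bed", cdir / "components.tsv")
        footprint.export_peaks(peaks, cdir / "peaks.bed")
        runlog.record("call", cond, threshold=thresholds[cond], components=len(comps), peaks=len(peaks))

    table = compare.build_occupancy_table(
        components, fragments, total_mapped, thresholds,
        conditions=config.conditions, caller_cfg=cfg, depth_profiles=profiles,
    )
    table.to_tsv(outdir / "occupancy.tsv")
    compare.to_long_format(table).to_csv(outdir / "occupancy_long.tsv", sep="\t", index=False)
    spec_kwargs = {}
    if "0min" not in config.conditions or "10min" not in config.conditions:
        spec_kwargs = {"pre_condition": config.conditions[0],
                       "transient_condition": config.conditions[min(1, len(config.conditions) - 1)]}
    specificity = compare.classify_table(table, **spec_kwargs)
    specificity.to_csv(outdir / "specificity.tsv", sep="\t", index=False)
    with open(outdir / "display_scales.tsv", "w") as fh:
        fh.write("condition\ttotal_mapped\tthreshold\tdisplay_scale\n")
        for c in config.conditions:
            fh.write(f"{c}\t{total_mapped[c]}\t{thresholds[c]}\t{scales[c]:.2f}\n")

    ref_rows = table.df[table.df[f"above_{config.ref_condition}"]] if not table.df.empty else table.df
    if not ref_rows.empty:
        regions = [(int(r.start), int(r.end)) for r in ref_rows.itertuples()]
        summary = motif.consensus_fraction(regions, genome, config.consensus_pattern)
        motif.export_region_fasta(regions, genome, outdir / "regions_ref.fasta", flank=config.fasta_flank)
        with open(outdir / "consensus.tsv", "w") as fh:
            fh.write("pattern\tn_with_match\tn_total\tfraction\n")
            fh.write(f"{config.consensus_pattern}\t{summary.n_with_match}\t{summary.n_total}\t{summary.fraction:.4f}\n")
        runlog.record("scan", config.ref_condition, regions=summary.n_total, with_consensus=summary.n_with_match)

    runlog.to_tsv(outdir / "run_log.tsv")
    return RunResult(
        outdir=outdir, genome=genome, truth=truth, fragments=fragments,
        components=components, thresholds=thresholds, total_mapped=total_mapped,
        occupancy=table, specificity=specificity, runlog=runlog,
    )
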