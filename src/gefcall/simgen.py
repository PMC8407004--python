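"""Synthetic genome, planted binding sites, protected fragments and reads.

The generator emulates the statistical structure that the footprint caller
assumes: a bacterial-scale random genome; degenerate-consensus binding sites
with condition-dependent occupancy (a pre-initiation-specific origin-like
site, a transiently bound site appearing only 10 min after initiation,
constitutive sites); DNase I protection fragments of 70-110 bp that always
contain the bound motif; uniform background digestion fragments; and 100 bp
paired-end reads that run through short fragments into the library adapter.

All randomness flows through a single integer seed; identical seed + config
gives byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .ioformats import BedRecord, FastqRead, write_bed, write_fasta, write_fastq, write_flat_config
from .motif import IUPACPattern, reverse_complement
from .readprep import Fragment

#: standard Illumina read-through adapter (TruSeq), used for both mates
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"


@dataclass
class SimConfig:
    """Parameters of one synthetic experiment (genome + libraries)."""

    genome_length: int
    gc_fraction: float = 0.5
    read_length: int = 100
    adapter_seq: str = DEFAULT_ADAPTER
    protected_len_min: int = 70
    protected_len_max: int = 110
    background_fragments: int = 20_000
    enrichment_depth: int = 200          # expected protected fragments at full occupancy
    error_rate: float = 0.0              # optional uniform substitution rate on reads
    seed: int = 0

    def validate(self) -> None:
        if self.genome_length < 1:
            raise ValueError("genome_length must be >= 1")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")
        if self.read_length <= 0:
            raise ValueError("read_length must be > 0")
        if not 0 < self.protected_len_min <= self.protected_len_max:
            raise ValueError("need 0 < protected_len_min <= protected_len_max")
        if self.background_fragments < 0 or self.enrichment_depth < 0:
            raise ValueError("counts must be nonnegative")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")


@dataclass(frozen=True)
class SiteSpec:
    """Request to plant one site: pattern + position + occupancy schedule."""

    site_id: str
    pattern: IUPACPattern
    position: int                      # 0-based motif start on the genome
    occupancy: Mapping[str, float]     # condition -> probability in [0, 1]
    strand: str = "+"


@dataclass(frozen=True)
class PlantedSite:
    """A concrete planted site; ``motif`` is the instantiated sequence."""

    site_id: str
    position: int
    strand: str
    motif: str                         # plus-strand genomic sequence at position
    pattern: IUPACPattern
    occupancy: Mapping[str, float]

    @property
    def end(self) -> int:
        return self.position + len(self.motif)


@dataclass
class TruthSet:
    """Ground truth for one synthetic genome."""

    genome: str
    sites: list[PlantedSite]
    fragments_per_site_per_condition: dict[str, dict[str, int]] = field(default_factory=dict)


# --------------------------------------------------------------------------
# genome + sites
# --------------------------------------------------------------------------

def generate_genome(length: int, gc_fraction: float, seed: int) -> str:
    """Random circular genome as a string over {A,C,G,T}."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=[at, gc, gc, at])
    return bases.tobytes().decode("ascii")


def plant_sites(
    genome: str,
    site_specs: Sequence[SiteSpec],
    seed: int,
) -> tuple[str, TruthSet]:
    """Instantiate each degenerate pattern and write it into the genome.

    Degenerate codes are replaced by uniformly sampled allowed bases; minus
    strand sites are planted as the reverse complement of the instance.  The
    genome is unchanged outside the planted intervals.  Sites may not overlap
    and may not span the linearization origin (the caller excludes a guard
    band there; keep sites at least a fragment length away from position 0).
    """
    rng = np.random.default_rng(seed)
    occupied: list[tuple[int, int, str]] = []
    g = list(genome.upper())
    sites: list[PlantedSite] = []
    for spec in site_specs:
        plen = len(spec.pattern)
        if spec.position < 0 or spec.position + plen > len(genome):
            raise ValueError(
                f"site {spec.site_id!r} at {spec.position} spans the genome end "
                f"(length {len(genome)}); sites must not cross the linearization origin"
            )
        for lo, hi, other in occupied:
            if spec.position < hi and lo < spec.position + plen:
                raise ValueError(f"site {spec.site_id!r} overlaps site {other!r}")
        for occ in spec.occupancy.values():
            if not 0.0 <= occ <= 1.0:
                raise ValueError(f"site {spec.site_id!r}: occupancy {occ} outside [0,1]")
        if spec.strand not in "+-":
            raise ValueError(f"site {spec.site_id!r}: strand must be '+' or '-'")
        instance = spec.pattern.instantiate(rng)
        planted = instance if spec.strand == "+" else reverse_complement(instance)
        g[spec.position : spec.position + plen] = planted
        occupied.append((spec.position, spec.position + plen, spec.site_id))
        sites.append(
            PlantedSite(
                site_id=spec.site_id,
                position=spec.position,
                strand=spec.strand,
                motif=planted,
                pattern=spec.pattern,
                occupancy=dict(spec.occupancy),
            )
        )
    return "".join(g), TruthSet(genome="".join(g), sites=sites)


# --------------------------------------------------------------------------
# fragments
# --------------------------------------------------------------------------

def simulate_fragments(
    truth: TruthSet,
    condition: str,
    n_background: int,
    enrichment_depth: int,
    seed: int,
    protected_len_min: int = 70,
    protected_len_max: int = 110,
    chrom: str = "genome",
) -> list[Fragment]:
    """Draw protected + background fragments for one condition.

    Each site contributes Binomial(enrichment_depth, occupancy[condition])
    protected fragments whose length is uniform on the configured range and
    whose interval fully contains the motif (start jittered uniformly subject
    to containment).  Background fragments start uniformly over the genome.
    Site fragments come first in the returned list, in site order, and per-site
    counts are recorded on ``truth.fragments_per_site_per_condition``.
    """
    if enrichment_depth < 0:
        raise ValueError("enrichment_depth must be >= 0")
    if n_background < 0:
        raise ValueError("n_background must be >= 0")
    for site in truth.sites:
        if condition not in site.occupancy:
            raise ValueError(f"condition {condition!r} missing from site {site.site_id!r}")
    rng = np.random.default_rng(seed)
    glen = len(truth.genome)
    lmin, lmax = protected_len_min, protected_len_max
    frags: list[Fragment] = []
    counts: dict[str, int] = {}
    for site in truth.sites:
        n = int(rng.binomial(enrichment_depth, site.occupancy[condition]))
        counts[site.site_id] = n
        for _ in range(n):
            length = int(rng.integers(max(lmin, len(site.motif)), lmax + 1))
            lo = max(0, site.end - length)
            hi = min(glen - length, site.position)
            start = int(rng.integers(lo, hi + 1))
            frags.append(Fragment(chrom, start, start + length))
    for _ in range(n_background):
        length = int(rng.integers(lmin, lmax + 1))
        start = int(rng.integers(0, glen - length + 1))
        frags.append(Fragment(chrom, start, start + length))
    truth.fragments_per_site_per_condition[condition] = counts
    return frags


# --------------------------------------------------------------------------
# reads
# --------------------------------------------------------------------------

def fragments_to_reads(
    fragments: Sequence[Fragment],
    genome: str,
    read_length: int = 100,
    adapter_seq: str = DEFAULT_ADAPTER,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[tuple[FastqRead, FastqRead]]:
    """Paired reads: fragment sequence padded into the adapter to read length.

    Read 1 is the top-strand fragment sequence, read 2 the reverse complement;
    fragments at least as long as the read yield pure genomic prefixes.  Base
    qualities are a constant high value (the caller never uses them).  An
    optional uniform substitution rate models sequencing errors.
    """
    min_frag = min((f.length for f in fragments), default=read_length)
    if len(adapter_seq) < read_length - min_frag:
        raise ValueError(
            f"adapter ({len(adapter_seq)} bp) too short to pad a {min_frag} bp "
            f"fragment to read length {read_length}"
        )
    rng = np.random.default_rng(seed) if error_rate > 0 else None
    qual = "I" * read_length
    pairs = []
    for i, frag in enumerate(fragments):
        if frag.end > len(genome):
            raise ValueError(f"fragment [{frag.start},{frag.end}) outside genome")
        insert = genome[frag.start : frag.end]
        r1 = (insert + adapter_seq)[:read_length]
        r2 = (reverse_complement(insert) + adapter_seq)[:read_length]
        if rng is not None:
            r1 = _mutate(r1, error_rate, rng)
            r2 = _mutate(r2, error_rate, rng)
        name = f"sim:{i}:{frag.chrom}:{frag.start}-{frag.end}"
        pairs.append(
            (FastqRead(name + "/1", r1, qual[: len(r1)]), FastqRead(name + "/2", r2, qual[: len(r2)]))
        )
    return pairs


_OTHERS = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    if hits.size == 0:
        return seq
    chars = list(seq)
    for p in hits:
        base = chars[p]
        if base in _OTHERS:
            chars[p] = _OTHERS[base][rng.integers(3)]
    return "".join(chars)


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------

def write_truth(outdir, truth: TruthSet, conditions: Sequence[str], chrom: str = "genome") -> None:
    """Truth files: genome FASTA, per-condition site BED (score = occupancy*1000), TSV."""
    from pathlib import Path

    outdir = Path(outdir)
    write_fasta(outdir / "genome.fasta", {chrom: truth.genome})
    for cond in conditions:
        recs = [
            BedRecord(chrom, s.position, s.end, s.site_id, round(1000 * s.occupancy.get(cond, 0.0)), s.strand)
            for s in truth.sites
        ]
        write_bed(outdir / f"truth_sites_{cond}.bed", recs)
    with open(outdir / "truth_sites.tsv", "w") as fh:
        fh.write("site_id\tposition\tstrand\tmotif\tpattern\t" + "\t".join(f"occupancy_{c}" for c in conditions) + "\n")
        for s in truth.sites:
            occ = "\t".join(f"{s.occupancy.get(c, 0.0):g}" for c in conditions)
            fh.write(f"{s.site_id}\t{s.position}\t{s.strand}\t{s.motif}\t{s.pattern}\t{occ}\n")


def write_sim_outputs(outdir, cfg: SimConfig, fragments: Sequence[Fragment], reads, condition: str) -> None:
    """FASTQ pair + truth fragment BED + flat config echo for one condition."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fastq(outdir / f"reads_{condition}_R1.fastq", (r1 for r1, _ in reads))
    write_fastq(outdir / f"reads_{condition}_R2.fastq", (r2 for _, r2 in reads))
    write_bed(
        outdir / f"truth_fragments_{condition}.bed",
        (BedRecord(f.chrom, f.start, f.end, f"frag{i}", 0, "+") for i, f in enumerate(fragments)),
    )
    write_flat_config(outdir / "simconfig.txt", asdict(cfg))
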