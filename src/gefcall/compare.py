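"""Cross-condition occupancy analysis of called components.

Occupancy is compared across cell-cycle timepoints without a statistical
test, the way footprint studies with library-size-scaled thresholds do it:
each component gets a normalized read number (overlapping fragments divided by
the library's total mapped fragments), an above/below-threshold flag per
timepoint, a rank within a timepoint, and a specificity label derived purely
from the flag pattern (e.g. "pre-initiation-specific" for a site above
threshold only before replication initiation).  Small helpers cover the
qPCR-style arithmetic used alongside sequencing (purification yield percent
and origin/terminus copy ratios normalized to a reference timepoint) and the
vertical display-scale factors implied by mapped-read ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .footprint import CallerConfig, Component, DepthProfile, compute_profiles
from .readprep import Fragment

#: canonical condition order for the cell-cycle experiment
DEFAULT_CONDITIONS = ("0min", "10min", "20min", "random")

LABEL_PRE = "pre-initiation-specific"
LABEL_TRANSIENT = "post-initiation-transient"
LABEL_CONSTITUTIVE = "constitutive"
LABEL_SPORADIC = "sporadic"


# --------------------------------------------------------------------------
# elementary quantities
# --------------------------------------------------------------------------

def count_overlapping(
    component,
    fragments: Sequence[Fragment] | None = None,
    starts: np.ndarray | None = None,
    ends: np.ndarray | None = None,
) -> int:
    """Number of fragments sharing >=1 base with the component interval.

    Counts fragments with start < component end and end > component start,
    using independently sorted start and end arrays (pass ``starts``/``ends``
    to reuse them across many components).
    """
    if starts is None or ends is None:
        if fragments is None:
            raise ValueError("need fragments or precomputed starts/ends")
        starts = np.sort(np.fromiter((f.start for f in fragments), dtype=np.int64, count=len(fragments)))
        ends = np.sort(np.fromiter((f.end for f in fragments), dtype=np.int64, count=len(fragments)))
    c_start, c_end = (component.start, component.end) if hasattr(component, "start") else component
    n_start_before_end = int(np.searchsorted(starts, c_end, side="left"))
    n_end_at_or_before_start = int(np.searchsorted(ends, c_start, side="right"))
    return n_start_before_end - n_end_at_or_before_start


def normalized_reads(read_count: int, total_mapped: int) -> float:
    """Component fragment count divided by the library's total mapped count."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be > 0")
    if not 0 <= read_count <= total_mapped:
        raise ValueError("need 0 <= read_count <= total_mapped")
    return read_count / total_mapped


def display_scale(ref_mapped: int, sample_mapped: int) -> float:
    """Vertical-scale expansion factor from the mapped-read ratio (full precision).

    Presentation rounding (2 decimals by default) belongs to report time only.
    """
    if ref_mapped <= 0 or sample_mapped <= 0:
        raise ValueError("mapped counts must be > 0")
    return sample_mapped / ref_mapped


def chap_yield(purified_qty: float, input_qty: float) -> float:
    """Affinity-purification yield in percent: 100 * purified / input."""
    if input_qty <= 0:
        raise ValueError("input quantity must be > 0")
    if purified_qty < 0:
        raise ValueError("purified quantity must be >= 0")
    return 100.0 * purified_qty / input_qty


def copy_ratio(
    locus_a: Mapping[str, float],
    locus_b: Mapping[str, float],
    reference_timepoint: str,
) -> dict[str, float]:
    """Per-timepoint a/b quantity ratios normalized to the reference timepoint.

    r(t) = (a(t)/b(t)) / (a(ref)/b(ref)); r(reference) == 1 exactly.
    """
    if reference_timepoint not in locus_a or reference_timepoint not in locus_b:
        raise ValueError(f"reference timepoint {reference_timepoint!r} missing")
    for name, table in (("locus_a", locus_a), ("locus_b", locus_b)):
        for t, q in table.items():
            if q <= 0:
                raise ValueError(f"{name}[{t!r}] must be > 0")
    ref = locus_a[reference_timepoint] / locus_b[reference_timepoint]
    return {t: (locus_a[t] / locus_b[t]) / ref for t in locus_a if t in locus_b}


# --------------------------------------------------------------------------
# specificity labels
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SpecificityCall:
    component: object
    label: str
    flags: tuple[bool, ...]


def classify_specificity(
    flags: Mapping[str, bool],
    conditions: Sequence[str] = DEFAULT_CONDITIONS,
    pre_condition: str = "0min",
    transient_condition: str = "10min",
) -> str:
    """Label a component from its above-threshold pattern over conditions.

    pre-initiation-specific   <=> above at the pre-initiation timepoint only
    post-initiation-transient <=> above at the transient timepoint only
    constitutive              <=> above at every condition
    sporadic                  otherwise
    The mapping is total and deterministic.
    """
    missing = [c for c in conditions if c not in flags]
    if missing:
        raise ValueError(f"missing condition flag(s): {missing}")
    pattern = {c: bool(flags[c]) for c in conditions}
    above = {c for c, f in pattern.items() if f}
    if above == {pre_condition}:
        return LABEL_PRE
    if above == {transient_condition}:
        return LABEL_TRANSIENT
    if above == set(conditions):
        return LABEL_CONSTITUTIVE
    return LABEL_SPORADIC


# --------------------------------------------------------------------------
# occupancy table
# --------------------------------------------------------------------------

@dataclass
class OccupancyTable:
    """Union components x condition matrix of occupancy quantities."""

    df: pd.DataFrame                 # index: row id; columns: start, end + per-condition blocks
    conditions: tuple[str, ...]
    thresholds: dict[str, int]

    def flags(self, row_id) -> dict[str, bool]:
        return {c: bool(self.df.loc[row_id, f"above_{c}"]) for c in self.conditions}

    def row_containing(self, position: int):
        """Row id of the union component containing ``position``, or None."""
        hit = self.df[(self.df["start"] <= position) & (position < self.df["end"])]
        return None if hit.empty else hit.index[0]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# read_count: fragments overlapping the union interval by >=1 bp\n")
            fh.write("# normalized_reads: read_count / total mapped fragments of that library\n")
            fh.write("# above_*: avg_depth >= that library's scaled threshold "
                     f"({', '.join(f'{c}:{t}' for c, t in self.thresholds.items())})\n")
            self.df.to_csv(fh, sep="\t", index_label="row_id", float_format="%.6g")


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


def _cluster_components(
    items: list[tuple[str, Component]], reciprocal: float
) -> list[list[tuple[str, Component]]]:
    """Transitive clustering by pairwise reciprocal overlap >= ``reciprocal``."""
    items = sorted(items, key=lambda it: (it[1].start, it[1].end))
    parent = list(range(len(items)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    active: list[int] = []
    for idx, (_, comp) in enumerate(items):
        active = [a for a in active if items[a][1].end > comp.start]
        for a in active:
            other = items[a][1]
            if _reciprocal_overlap((comp.start, comp.end), (other.start, other.end)) >= reciprocal:
                parent[find(idx)] = find(a)
        active.append(idx)
    clusters: dict[int, list[tuple[str, Component]]] = {}
    for idx, item in enumerate(items):
        clusters.setdefault(find(idx), []).append(item)
    return sorted(clusters.values(), key=lambda cl: min(c.start for _, c in cl))


def _best_window_mean(depth: np.ndarray, start: int, end: int, ewf: int, ewt: int) -> float:
    """Max mean depth over any [ewf, ewt]-wide window inside [start, end)."""
    start, end = max(0, start), min(len(depth), end)
    if end - start < ewf:
        lo = max(0, min(start, len(depth) - ewf))
        start, end = lo, min(len(depth), lo + ewf)
        if end - start < ewf:
            return float(depth[start:end].mean()) if end > start else 0.0
    seg = depth[start:end]
    csum = np.concatenate(([0], np.cumsum(seg)))
    best = 0.0
    for w in range(ewf, min(ewt, len(seg)) + 1):
        means = (csum[w:] - csum[:-w]) / w
        if means.size:
            best = max(best, float(means.max()))
    return best


def build_occupancy_table(
    components: Mapping[str, Sequence[Component]],
    fragments: Mapping[str, Sequence[Fragment]],
    total_mapped: Mapping[str, int],
    thresholds: Mapping[str, int],
    conditions: Sequence[str] = DEFAULT_CONDITIONS,
    caller_cfg: CallerConfig | None = None,
    depth_profiles: Mapping[str, DepthProfile] | None = None,
    genome_length: int | None = None,
    reciprocal: float = 0.5,
) -> OccupancyTable:
    """Merge per-condition components into union rows and score each condition.

    Components (within and across conditions) are merged when they overlap
    >= ``reciprocal`` reciprocally (transitively).  Per condition, a row's
    avg_depth is the max member-component avg_depth when that condition
    contributed a member, else the best caller-width window mean inside the
    union interval; the above-threshold flag is avg_depth >= that library's
    scaled threshold.  Rows below threshold in every condition are dropped.
    """
    cfg = caller_cfg or CallerConfig()
    conditions = tuple(conditions)
    if depth_profiles is None:
        if genome_length is None:
            raise ValueError("need depth_profiles or genome_length")
        depth_profiles = {
            c: compute_profiles(fragments[c], genome_length)[0] for c in conditions
        }
    sorted_frags = {
        c: (
            np.sort(np.fromiter((f.start for f in fragments[c]), dtype=np.int64, count=len(fragments[c]))),
            np.sort(np.fromiter((f.end for f in fragments[c]), dtype=np.int64, count=len(fragments[c]))),
        )
        for c in conditions
    }
    items = [(c, comp) for c in conditions for comp in components.get(c, ())]
    rows = []
    for cluster in _cluster_components(items, reciprocal):
        start = min(c.start for _, c in cluster)
        end = max(c.end for _, c in cluster)
        row: dict = {"start": start, "end": end, "n_members": len(cluster)}
        any_above = False
        for cond in conditions:
            members = [c for cc, c in cluster if cc == cond]
            if members:
                avg = max(c.avg_depth for c in members)
            else:
                avg = _best_window_mean(depth_profiles[cond].depth, start, end, cfg.ewf, cfg.ewt)
            starts_arr, ends_arr = sorted_frags[cond]
            rc = count_overlapping((start, end), starts=starts_arr, ends=ends_arr)
            above = avg >= thresholds[cond]
            any_above = any_above or above
            row[f"read_count_{cond}"] = rc
            row[f"normalized_{cond}"] = normalized_reads(rc, total_mapped[cond])
            row[f"avg_depth_{cond}"] = avg
            row[f"above_{cond}"] = above
        if any_above:
            rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["start", "end"]).reset_index(drop=True)
    return OccupancyTable(df=df, conditions=conditions, thresholds=dict(thresholds))


def rank_components(table: OccupancyTable, condition: str) -> pd.DataFrame:
    """Rows ordered for one condition: descending avg_depth, ties broken by
    normalized reads then genomic position.  Rank 1 is the highest-binding region."""
    if condition not in table.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    if table.df.empty:
        raise ValueError("empty occupancy table")
    df = table.df.sort_values(
        by=[f"avg_depth_{condition}", f"normalized_{condition}", "start"],
        ascending=[False, False, True],
        kind="mergesort",
    ).copy()
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def classify_table(table: OccupancyTable, **kwargs) -> pd.DataFrame:
    """Specificity labels for every row of an occupancy table."""
    records = []
    for row_id in table.df.index:
        flags = table.flags(row_id)
        records.append(
            {
                "row_id": row_id,
                "start": int(table.df.loc[row_id, "start"]),
                "end": int(table.df.loc[row_id, "end"]),
                "label": classify_specificity(flags, conditions=table.conditions, **kwargs),
                **{f"above_{c}": flags[c] for c in table.conditions},
            }
        )
    return pd.DataFrame(records)


def to_long_format(table: OccupancyTable) -> pd.DataFrame:
    """Bar-chart-ready long format: one row per (component, condition)."""
    records = []
    for row_id in table.df.index:
        for cond in table.conditions:
            records.append(
                {
                    "row_id": row_id,
                    "start": int(table.df.loc[row_id, "start"]),
                    "end": int(table.df.loc[row_id, "end"]),
                    "condition": cond,
                    "normalized_reads": table.df.loc[row_id, f"normalized_{cond}"],
                    "above_threshold": bool(table.df.loc[row_id, f"above_{cond}"]),
                }
            )
    return pd.DataFrame(records)
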