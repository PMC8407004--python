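"""Depth/end profiles, component calling, peak grouping, export."""

import numpy as np
import pytest

from gefcall import (
    CallerConfig,
    Component,
    Fragment,
    IUPACPattern,
    SiteSpec,
    call_components,
    compute_profiles,
    generate_genome,
    load_fragments,
    merge_peaks,
    plant_sites,
    scale_threshold,
    simulate_fragments,
)
from gefcall.footprint import enumerate_candidates, export_components, greedy_select

from oracles import brute_force_candidates, brute_force_select


def frag(s, e):
    return Fragment("genome", s, e)


def random_fragments(rng, glen, n, lmin=70, lmax=110):
    lengths = rng.integers(lmin, lmax + 1, size=n)
    starts = rng.integers(0, glen - lmax, size=n)
    return [frag(int(s), int(s + l)) for s, l in zip(starts, lengths)]


class TestComputeProfiles:
    def test_single_fragment_unit_case(self):
        depth, ends = compute_profiles([frag(10, 90)], 200)
        assert depth.depth[9] == 0 and depth.depth[10] == 1 and depth.depth[89] == 1 and depth.depth[90] == 0
        assert ends.left_ends[10] == 1 and ends.right_ends[89] == 1
        assert ends.left_ends.sum() == ends.right_ends.sum() == 1

    def test_identical_fragments_add(self):
        depth, _ = compute_profiles([frag(10, 90)] * 2, 200)
        assert (depth.depth[10:90] == 2).all()

    def test_conservation_identity(self, rng):
        frags = random_fragments(rng, 5_000, 300)
        depth, ends = compute_profiles(frags, 5_000)
        assert depth.depth.sum() == sum(f.length for f in frags)
        assert ends.left_ends.sum() == ends.right_ends.sum() == len(frags)
        # direct per-position re-count for a slice
        for p in (0, 1_234, 4_999):
            assert depth.depth[p] == sum(1 for f in frags if f.start <= p < f.end)

    def test_out_of_bounds_fragment_rejected(self):
        with pytest.raises(ValueError):
            compute_profiles([frag(4_990, 5_080)], 5_000)


class TestScaleThreshold:
    def test_identity_when_sample_equals_reference(self):
        for t, n in ((10_000, 15_289_849), (7, 3)):
            assert scale_threshold(t, n, n) == t

    def test_floor_not_round(self):
        # 10 * 19 / 4 = 47.5: floor, never round-half-up
        assert scale_threshold(10, 4, 19) == 47

    @pytest.mark.parametrize("args", [(0, 1, 1), (1, 0, 1), (1, 1, 0), (-3, 5, 5), (10.5, 5, 5)])
    def test_nonpositive_or_noninteger_inputs_rejected(self, args):
        with pytest.raises(ValueError):
            scale_threshold(*args)


class TestCallComponents:
    def test_no_fragments_yields_no_components(self):
        depth, ends = compute_profiles([], 1_000)
        assert call_components(depth, ends, CallerConfig(), threshold=10) == []

    def test_planted_site_called_and_all_components_contain_motif(self):
        genome = generate_genome(10_000, 0.5, seed=31)
        genome, truth = plant_sites(
            genome, [SiteSpec("s", IUPACPattern("WATCARnnnnTTR"), 5_000, {"c": 1.0})], seed=32
        )
        frags = simulate_fragments(truth, "c", n_background=0, enrichment_depth=500, seed=33)
        depth, ends = compute_profiles(frags, len(genome))
        comps = call_components(depth, ends, CallerConfig(), threshold=50)
        site = truth.sites[0]
        assert comps, "site not called"
        for c in comps:
            assert c.start <= site.position and c.end >= site.end
            assert 70 <= c.width <= 110
        assert len(merge_peaks(comps)) == 1

    def test_matches_brute_force_oracle(self, rng):
        glen = 3_000
        frags = random_fragments(rng, glen, 800)
        depth, ends = compute_profiles(frags, glen)
        cfg = CallerConfig(end_support_min=2)
        threshold = 20
        cands = enumerate_candidates(depth, ends, cfg, threshold)
        oracle_cands = brute_force_candidates(
            depth.depth, ends.left_ends, ends.right_ends, cfg.ewf, cfg.ewt, cfg.end_support_min, threshold
        )
        assert sorted(cands, key=lambda c: (c[1], c[2])) == sorted(oracle_cands, key=lambda c: (c[1], c[2]))
        assert greedy_select(cands) == brute_force_select(oracle_cands)

    def test_threshold_monotonicity(self, rng):
        glen = 3_000
        frags = random_fragments(rng, glen, 1_000)
        depth, ends = compute_profiles(frags, glen)
        cfg = CallerConfig(end_support_min=2)
        sets = []
        for t in (15, 25, 35):
            comps = call_components(depth, ends, cfg, threshold=t)
            sets.append({(c.start, c.end) for c in comps})
        assert sets[2] <= sets[1] <= sets[0]

    def test_scaling_consistency_under_exact_duplication(self, rng):
        glen = 3_000
        frags = random_fragments(rng, glen, 600)
        depth1, ends1 = compute_profiles(frags, glen)
        depth2, ends2 = compute_profiles(frags + frags, glen)
        # support 1 so the qualifying edge set is invariant under duplication
        cfg = CallerConfig(end_support_min=1)
        c1 = call_components(depth1, ends1, cfg, threshold=20)
        c2 = call_components(depth2, ends2, cfg, threshold=40)
        assert [(c.start, c.end) for c in c1] == [(c.start, c.end) for c in c2]
        for a, b in zip(c1, c2):
            assert b.avg_depth == pytest.approx(2 * a.avg_depth)

    def test_invalid_threshold_rejected(self):
        depth, ends = compute_profiles([frag(0, 80)], 200)
        with pytest.raises(ValueError):
            call_components(depth, ends, CallerConfig(), threshold=0)

    def test_parameter_recovery_at_high_enrichment(self):
        recovered = total = 0
        for seed in (41, 42):
            genome = generate_genome(100_000, 0.5, seed=seed)
            specs = [
                SiteSpec(f"s{k}", IUPACPattern("WATCARnnnnTTR"), 6_000 + 8_000 * k, {"c": occ})
                for k, occ in enumerate([0.5, 0.6, 0.7, 0.8, 0.9, 1.0] * 2)
            ]
            genome, truth = plant_sites(genome, specs, seed=seed + 100)
            frags = simulate_fragments(truth, "c", n_background=20_000, enrichment_depth=200, seed=seed + 200)
            depth, ends = compute_profiles(frags, len(genome))
            comps = call_components(depth, ends, CallerConfig(), threshold=60)
            for site in truth.sites:
                total += 1
                if any(c.start <= site.position and c.end >= site.end for c in comps):
                    recovered += 1
        assert recovered / total >= 0.95

    def test_no_false_positives_on_background_only_data(self):
        genome_length = 100_000
        n = 20_000
        frags = random_fragments(np.random.default_rng(77), genome_length, n)
        depth, ends = compute_profiles(frags, genome_length)
        mean_depth = depth.depth.sum() / genome_length
        comps = call_components(depth, ends, CallerConfig(), threshold=5 * mean_depth)
        assert comps == []


class TestMergePeaks:
    def test_overlapping_components_form_one_peak(self):
        comps = [Component("g", 100, 180, 5.0), Component("g", 150, 240, 4.0)]
        (peak,) = merge_peaks(comps)
        assert (peak.start, peak.end, len(peak.members)) == (100, 240, 2)

    def test_abutting_components_stay_separate(self):
        comps = [Component("g", 100, 180, 5.0), Component("g", 180, 260, 4.0)]
        assert len(merge_peaks(comps)) == 2

    def test_two_adjacent_planted_sites_give_one_peak_with_two_edge_groups(self):
        genome = generate_genome(10_000, 0.5, seed=55)
        specs = [
            SiteSpec("a", IUPACPattern("WATCARnnnnTTR"), 5_000, {"c": 1.0}),
            SiteSpec("b", IUPACPattern("WATCARnnnnTTR"), 5_050, {"c": 1.0}),
        ]
        genome, truth = plant_sites(genome, specs, seed=56)
        frags = simulate_fragments(truth, "c", n_background=0, enrichment_depth=400, seed=57)
        depth, ends = compute_profiles(frags, len(genome))
        comps = call_components(depth, ends, CallerConfig(), threshold=40)
        peaks = merge_peaks(comps)
        assert len(peaks) == 1
        assert len(peaks[0].members) >= 2

    def test_empty_input(self):
        assert merge_peaks([]) == []


class TestExport:
    def test_one_based_inclusive_reporting_convention(self, tmp_path):
        comp = Component("ecoli", 3_925_748, 3_925_842, avg_depth=30_601.5, read_count=12_345, component_id=57)
        export_components([comp], merge_peaks([comp]), tmp_path / "c.bed", tmp_path / "c.tsv")
        row = (tmp_path / "c.tsv").read_text().splitlines()[1].split("\t")
        assert row[2] == "3,925,749" and row[3] == "3,925,842"
        assert int(row[4]) == 94 and 70 <= int(row[4]) <= 110

    def test_bed_round_trip(self, tmp_path, rng):
        comps = [
            Component("genome", int(s), int(s) + 80, avg_depth=9.0, component_id=i + 1)
            for i, s in enumerate(rng.integers(0, 5_000, size=50))
        ]
        export_components(comps, merge_peaks(sorted(comps, key=lambda c: c.start)), tmp_path / "c.bed", tmp_path / "c.tsv")
        loaded = load_fragments(tmp_path / "c.bed")
        assert sorted((f.start, f.end) for f in loaded) == sorted((c.start, c.end) for c in comps)

    def test_empty_set_writes_header_only(self, tmp_path):
        export_components([], [], tmp_path / "c.bed", tmp_path / "c.tsv")
        assert (tmp_path / "c.bed").read_text() == ""
        assert (tmp_path / "c.tsv").read_text().startswith("component_id\t")
        assert len((tmp_path / "c.tsv").read_text().splitlines()) == 1
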