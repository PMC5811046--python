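"""N-terminal ramp, domain/linker machinery, boundary profiles, TMH sites."""

import numpy as np
import pandas as pd
import pytest

from polypro.motifs import StrengthClass, scan_proteome
from polypro.positional import (
    DEFAULT_TMH_SITES,
    AnnotationTrack,
    boundary_profile,
    define_linkers,
    nterminal_ramp_test,
    region_enrichment,
    smooth3,
    tmh_site_analysis,
    tp_proportion_test,
)
from polypro.simulate import (
    SyntheticSpec,
    generate_annotations,
    generate_proteome,
    plant_in_windows,
    thin_motifs,
)


@pytest.fixture(scope="module")
def proteome_and_motifs():
    """Unplanted i.i.d. proteome: the null case for enrichment machinery."""
    from polypro.motifs import default_rule_table

    rules = default_rule_table()
    spec = SyntheticSpec(seed=50, proteome_size=400)
    proteome, _ = generate_proteome(spec, rules)
    table, counts = scan_proteome(proteome, rules)
    return proteome, table, counts, rules


class TestRampTest:
    def test_motif_in_short_protein_counts_nterminal(self, rules):
        proteome = {"a": "M" + "A" * 20 + "PP" + "A" * 16}  # length 39 < split
        table, _ = scan_proteome(proteome, rules)
        res = nterminal_ramp_test(proteome, table, split=50, replicates=10, seed=0)
        assert res["n_nterm_obs"] == 1
        assert res["n_rest_obs"] == 0
        assert res["flagged"]  # no complete rest tile: comparison impossible

    def test_uniform_density_null(self, proteome_and_motifs):
        proteome, table, _, _ = proteome_and_motifs
        res = nterminal_ramp_test(proteome, table, split=50, replicates=60, seed=51)
        assert res["p_ranksum"] > 0.01

    def test_planted_nterminal_enrichment_detected(self, rules):
        spec = SyntheticSpec(seed=52, proteome_size=600,
                             plant_per_protein={StrengthClass.WEAK: 0.5})
        proteome, _ = generate_proteome(spec, rules)
        windows = [(pid, 3, 45) for pid in proteome]
        proteome, _ = plant_in_windows(proteome, windows, StrengthClass.WEAK,
                                       probability=0.8, seed=53)
        table, _ = scan_proteome(proteome, rules)
        res = nterminal_ramp_test(proteome, table, split=50, replicates=60, seed=54)
        assert res["fc_nterm"] > res["fc_rest"]
        assert res["p_ranksum"] < 1e-3


class TestLinkers:
    @pytest.mark.parametrize(
        "domains, length, expected",
        [
            ([(1, 100), (111, 200)], 200, [(101, 110)]),
            ([(1, 100), (103, 200)], 200, [(101, 105)]),  # short span extended
            ([(1, 100), (101, 200)], 200, [(101, 105)]),  # abutting domains
            ([(1, 100), (111, 200), (221, 300)], 300, [(101, 110), (201, 220)]),
        ],
    )
    def test_linker_rule(self, domains, length, expected):
        assert define_linkers(domains, length) == expected

    def test_extension_clipped_at_protein_end(self):
        assert define_linkers([(1, 100), (102, 103)], 103) == [(101, 103)]

    def test_overlapping_domains_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            define_linkers([(1, 100), (90, 150)], 150)

    def test_emitted_linkers_at_least_five_unless_clipped(self, rng):
        for _ in range(50):
            length = int(rng.integers(150, 400))
            starts = np.sort(rng.choice(np.arange(1, length - 40), 3, replace=False))
            domains, cursor = [], 1
            for s in starts:
                s = max(s, cursor)
                e = min(s + int(rng.integers(20, 60)), length)
                if s > e:
                    continue
                domains.append((int(s), int(e)))
                cursor = e + 2
            if len(domains) < 2:
                continue
            for lo, hi in define_linkers(domains, length):
                assert hi - lo + 1 >= 5 or hi == length


class TestRegionEnrichment:
    def test_null_segments_fold_change_near_one(self, proteome_and_motifs):
        proteome, table, _, _ = proteome_and_motifs
        intervals = {pid: [(11, len(seq) - 10)] for pid, seq in proteome.items()
                     if len(seq) > 40}
        res = region_enrichment(proteome, table, intervals)
        assert 0.85 < res.fold_change < 1.25

    def test_prolines_removed_gives_zero_observed(self, rules):
        proteome = {"a": "MKLAVILKAVGA" * 20}
        table, _ = scan_proteome(proteome, rules)
        res = region_enrichment(proteome, table, {"a": [(1, 200)]},
                                alternative="depletion")
        assert res.n_obs == 0
        assert res.degenerate  # no prolines at all: expectation 0 under M0

    def test_planted_thinning_recovers_half(self, rules):
        spec = SyntheticSpec(seed=60, proteome_size=800)
        proteome, _ = generate_proteome(spec, rules)
        thinned = thin_motifs(proteome, 0.5, seed=61)
        table, _ = scan_proteome(thinned, rules)
        intervals = {pid: [(1, len(seq))] for pid, seq in thinned.items()}
        res = region_enrichment(thinned, table, intervals)
        # thinning dismantles half the stretches; relocated isolated
        # prolines keep the composition (hence the expectation) constant
        assert abs(res.fold_change - 0.5) < 0.12

    def test_empty_segment_set_rejected(self, proteome_and_motifs):
        proteome, table, _, _ = proteome_and_motifs
        with pytest.raises(ValueError):
            region_enrichment(proteome, table, {})


class TestBoundaryProfile:
    def test_single_anchor_offset(self, rules):
        proteome = {"a": "A" * 200}
        seq = list(proteome["a"])
        seq[94:96] = "PP"  # anchor position 95, domain start 100 -> offset -5
        proteome = {"a": "".join(seq)}
        table, _ = scan_proteome(proteome, rules)
        track = AnnotationTrack(kind="DOMAIN", intervals={"a": [(100, 160)]})
        prof = boundary_profile(proteome, table, track, "DOMAIN_START")
        assert prof.raw_counts[list(prof.offsets).index(-5)] == 1
        assert prof.raw_counts.sum() == 1

    def test_no_motifs_zero_profile(self, rules):
        proteome = {"a": "AKLV" * 60}
        table, _ = scan_proteome(proteome, rules)
        track = AnnotationTrack(kind="DOMAIN", intervals={"a": [(100, 150)]})
        prof = boundary_profile(proteome, table, track, "DOMAIN_END")
        assert prof.raw_counts.sum() == 0
        assert np.all(prof.smoothed == 0)

    def test_smoothing_rule(self):
        freq = np.array([0.0, 3.0, 0.0, 0.0, 6.0])
        sm = smooth3(freq)
        np.testing.assert_allclose(sm, [1.5, 1.0, 1.0, 2.0, 3.0])
        const = np.full(7, 0.4)
        np.testing.assert_allclose(smooth3(const), const)  # idempotent on constants

    def test_planted_boundary_enrichment_located(self, rules):
        hits = 0
        n_sim = 40
        for i in range(n_sim):
            spec = SyntheticSpec(seed=70 + i, proteome_size=150)
            proteome, _ = generate_proteome(spec, rules)
            ann = generate_annotations(spec, proteome, stream=i)
            windows = [
                (pid, max(s - 12, 3), s - 2)
                for pid, ivs in ann["domains"].intervals.items()
                for s, _ in ivs
                if s > 14
            ]
            proteome, _ = plant_in_windows(proteome, windows, StrengthClass.WEAK,
                                           probability=0.7, seed=71 + i)
            table, _ = scan_proteome(proteome, rules)
            prof = boundary_profile(proteome, table, ann["domains"], "DOMAIN_START")
            best = prof.offsets[int(np.argmax(prof.smoothed))]
            hits += -12 <= best <= -2
        assert hits >= 0.9 * n_sim


class TestTmhSites:
    def test_site_interval_arithmetic(self):
        # TMH at [10, 30]: site II (+23..+32 from start) = absolute [33, 42]
        start = 10
        lo, hi = DEFAULT_TMH_SITES["II"]
        assert (start + lo, start + hi) == (33, 42)
        lo, hi = DEFAULT_TMH_SITES["I"]
        assert (start + lo, start + hi) == (-7, 9)  # truncated: dropped in analysis

    def test_instance_in_downstream_tmh_labelled_tmh(self, rules):
        proteome = {"a": "A" * 300}
        table, _ = scan_proteome(proteome, rules)
        track = AnnotationTrack(kind="TMH", intervals={"a": [(30, 50), (75, 95)]})
        res = tmh_site_analysis(proteome, table, track)
        # site III of the second TMH is far downstream; site II of TMH1
        # ([53,62]) lies between the helices -> non-TMH; site I of TMH2
        # ([58,74]) has midpoint 66 -> non-TMH; site I of TMH1 truncated.
        assert set(res["location"]) <= {"TMH", "non-TMH"}
        site2 = res[(res["site"] == "II") & (res["location"] == "non-TMH")]
        assert site2["n_instances"].sum() >= 1

    def test_planted_site_enrichment_detected(self, rules):
        detected = 0
        n_sim = 30
        for i in range(n_sim):
            spec = SyntheticSpec(seed=150 + i, proteome_size=250,
                                 plant_per_protein={StrengthClass.WEAK: 0.2})
            proteome, _ = generate_proteome(spec, rules)
            ann = generate_annotations(spec, proteome, tmh_fraction=0.8, stream=i)
            lo, hi = DEFAULT_TMH_SITES["III"]
            windows = []
            for pid, ivs in ann["tmh"].intervals.items():
                length = len(proteome[pid])
                for s, _ in ivs:
                    a, b = s + lo, s + hi
                    if a < 3 or b > length - 3:
                        continue
                    mid = (a + b) // 2
                    if any(x <= mid <= y for x, y in ivs):
                        continue  # only plant in non-TMH instances
                    windows.append((pid, a, b))
            proteome2, planted = plant_in_windows(proteome, windows, StrengthClass.WEAK,
                                                  probability=0.9, seed=151 + i)
            table, _ = scan_proteome(proteome2, rules)
            res = tmh_site_analysis(proteome2, table, ann["tmh"],
                                    alternative="enrichment")
            row = res[(res["site"] == "III") & (res["location"] == "non-TMH")]
            if len(row) and row.iloc[0]["p_value"] < 0.05 and row.iloc[0]["fold_change"] > 1:
                detected += 1
        assert detected >= 0.9 * n_sim

    def test_empty_track_rejected(self, rules):
        proteome = {"a": "A" * 100}
        table, _ = scan_proteome(proteome, rules)
        with pytest.raises(ValueError):
            tmh_site_analysis(proteome, table, AnnotationTrack(kind="TMH", intervals={}))


class TestTpProportions:
    def test_arithmetic_and_scaling(self, rules):
        proteome = {f"t{i}": ("APPV" + "A" * 50 if i < 4 else "A" * 54) for i in range(10)}
        proteome.update({f"s{i}": ("APPV" + "A" * 50 if i < 3 else "A" * 54) for i in range(10)})
        table, _ = scan_proteome(proteome, rules)
        res = tp_proportion_test([f"t{i}" for i in range(10)],
                                 [f"s{i}" for i in range(10)], table)
        assert res["tp_fraction"] == pytest.approx(0.4)
        assert res["soluble_fraction"] == pytest.approx(0.3)

    def test_equal_proportions_not_significant(self, rules):
        rng = np.random.default_rng(5)
        proteome = {}
        for i in range(400):
            has = rng.random() < 0.35
            proteome[f"p{i}"] = ("APPV" + "A" * 40) if has else "A" * 44
        table, _ = scan_proteome(proteome, rules)
        ids = sorted(proteome)
        res = tp_proportion_test(ids[:200], ids[200:], table)
        assert res["p_value"] > 0.01

    def test_doubling_cells_decreases_p(self, rules):
        from scipy.stats import chi2_contingency

        cells = np.array([[358, 554], [978, 2022]])
        p1 = chi2_contingency(cells, correction=False)[1]
        p2 = chi2_contingency(cells * 2, correction=False)[1]
        assert p2 < p1

    def test_overlap_rejected(self, rules):
        proteome = {"a": "A" * 40, "b": "A" * 40}
        table, _ = scan_proteome(proteome, rules)
        with pytest.raises(ValueError):
            tp_proportion_test(["a"], ["a", "b"], table)
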