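"""Differentiating-ion selection and occupancy computation."""

import numpy as np
import pytest

from acylswath import (
    AcylPeptide,
    SimPeptideSpec,
    SimScenario,
    differentiating_ions,
    fragment_ions,
    load_window_scheme,
    ms1_stoichiometry,
    quantify_multisite,
    quantify_site,
    read_run,
    read_targets,
    results_to_frames,
    simulate_run,
)
from acylswath.stoich import _median_lower


def ac(seq, sites, states=None):
    states = states or ["light"] * len(sites)
    return AcylPeptide(seq, 2, tuple((p, "acetyl", s) for p, s in zip(sites, states)))


class TestDifferentiatingIons:
    def test_single_internal_lysine_strict_set(self):
        names = {f.name for f in differentiating_ions(ac("GFKRIAE", (3,)), 3)}
        assert names == {"b3", "b4", "b5", "b6", "y5", "y6"}

    def test_n_terminal_lysine_has_b_ions_only(self):
        names = {f.name for f in differentiating_ions(ac("KIVIANRGE", (1,)), 1)}
        assert names == {f"b{i}" for i in range(1, 9)}
        assert "b3" in names

    def test_two_lysine_peptide_strict_runs(self):
        pep = ac("FCKAFNAKTDSIE", (3, 8))
        first = {f.name for f in differentiating_ions(pep, 3)}
        second = {f.name for f in differentiating_ions(pep, 8)}
        assert first == {f"b{i}" for i in range(3, 8)}
        assert second == {f"y{j}" for j in range(6, 11)}

    def test_extended_mode_adds_multisite_fragments(self):
        pep = ac("FCKAFNAKTDSIE", (3, 8))
        ext = {f.name for f in differentiating_ions(pep, 3, "extended")}
        strict = {f.name for f in differentiating_ions(pep, 3, "strict")}
        assert strict < ext
        assert "b8" in ext  # contains both lysines

    def test_non_site_position_rejected(self):
        with pytest.raises(ValueError, match="not an acyl site"):
            differentiating_ions(ac("GFKRIAE", (3,)), 4)

    def test_strict_sets_match_bruteforce_enumeration(self, rng):
        residues = list("AGILPSTVFYNQHRMW")
        for _ in range(200):
            n = int(rng.integers(6, 15))
            seq = list(rng.choice(residues, n))
            k = int(rng.integers(1, 3))
            pos = sorted(rng.choice(np.arange(2, n), size=k, replace=False))
            for p in pos:
                seq[p - 1] = "K"
            pep = ac("".join(seq), tuple(pos))
            for site in pos:
                got = {f.name for f in differentiating_ions(pep, site)}
                brute = {
                    f.name for f in fragment_ions(pep)
                    if f.contained_sites == (site,)
                }
                assert got == brute


class TestMedianRule:
    def test_odd_count_is_central_value(self):
        assert _median_lower([0.3, 0.1, 0.2]) == 0.2

    def test_even_count_takes_lower_central(self):
        assert _median_lower([0.4, 0.1, 0.2, 0.3]) == 0.2

    def test_invariant_to_ordering(self, rng):
        vals = list(rng.uniform(0, 1, 7))
        ref = _median_lower(vals)
        for _ in range(5):
            rng.shuffle(vals)
            assert _median_lower(vals) == ref


class TestQuantifySite:
    def quantify_theta(self, tmp_path, theta, abundance=2e5, min_heavy_area=1000.0):
        scenario = SimScenario(
            peptides=[SimPeptideSpec("GFKRIAE", (3,), (theta,), abundance=abundance)],
            noise=0.0, purity=1.0, seed=42,
        )
        bundle = simulate_run(scenario, tmp_path)
        scheme = load_window_scheme(bundle.scheme_path)
        run = read_run(bundle.mzml_path, scheme)
        target = read_targets(bundle.targets_path)[0]
        return quantify_site(run, scheme, target, min_heavy_area=min_heavy_area)

    def test_fully_heavy_site_gives_zero(self, tmp_path):
        r = self.quantify_theta(tmp_path, 0.0)
        assert r.median_ratio == 0.0 and r.rank1_ratio == 0.0

    def test_equal_light_heavy_gives_half(self, tmp_path):
        r = self.quantify_theta(tmp_path, 0.5)
        assert r.median_ratio == pytest.approx(0.5, abs=1e-9)

    def test_light_fallback_keeps_high_stoichiometry_fragments(self, tmp_path):
        # heavy channel far below threshold, light far above: the fragment
        # must survive via the light-channel fallback
        r = self.quantify_theta(tmp_path, 0.999, abundance=5e5, min_heavy_area=2000.0)
        passing = [f for f in r.fragments if f.passes]
        assert passing and all(f.heavy_area < 2000.0 for f in passing)
        assert r.median_ratio == pytest.approx(0.999, abs=1e-6)

    def test_low_stoichiometry_recovered_exactly_noise_free(self, tmp_path):
        r = self.quantify_theta(tmp_path, 0.005)
        assert r.median_ratio == pytest.approx(0.005, abs=1e-6)

    def test_all_ratios_within_unit_interval(self, tmp_path):
        r = self.quantify_theta(tmp_path, 0.3)
        for f in r.fragments:
            if f.ratio is not None:
                assert 0.0 <= f.ratio <= 1.0

    def test_nothing_above_threshold_is_flagged(self, tmp_path):
        r = self.quantify_theta(tmp_path, 0.5, abundance=10.0)
        assert r.median_ratio is None
        assert any("no fragments above threshold" in n for n in r.qc_notes)

    def test_rank1_is_largest_summed_area(self, loaded_single):
        run, scheme, target = loaded_single
        r = quantify_site(run, scheme, target)
        passing = [f for f in r.fragments if f.passes]
        best = max(passing, key=lambda f: f.light_area + f.heavy_area)
        assert best.rank == 1 and r.rank1_ratio == best.ratio


class TestMultisite:
    def test_two_site_noise_free_twin(self, two_site_bundle):
        scheme = load_window_scheme(two_site_bundle.scheme_path)
        run = read_run(two_site_bundle.mzml_path, scheme)
        target = read_targets(two_site_bundle.targets_path)[0]
        first, second = quantify_multisite(run, scheme, target)
        assert first.median_ratio == pytest.approx(0.923, abs=1e-6)
        assert second.median_ratio == pytest.approx(0.016, abs=1e-6)
        assert {f.series for f in first.fragments} == {"b"}
        assert {f.series for f in second.fragments} == {"y"}

    def test_symmetric_half_occupancies(self, tmp_path):
        scenario = SimScenario(
            peptides=[SimPeptideSpec("FCKAFNAKTDSIE", (3, 8), (0.5, 0.5))],
            noise=0.0, seed=9,
        )
        b = simulate_run(scenario, tmp_path)
        scheme = load_window_scheme(b.scheme_path)
        run = read_run(b.mzml_path, scheme)
        rs = quantify_multisite(run, scheme, read_targets(b.targets_path)[0])
        for r in rs:
            assert r.median_ratio == pytest.approx(0.5, abs=1e-9)

    def test_three_site_middle_estimate_noise_free(self, tmp_path):
        scenario = SimScenario(
            peptides=[SimPeptideSpec("FAKAGKALKTIAE", (3, 6, 9), (0.1, 0.3, 0.7))],
            noise=0.0, seed=10,
        )
        b = simulate_run(scenario, tmp_path)
        scheme = load_window_scheme(b.scheme_path)
        run = read_run(b.mzml_path, scheme)
        first, middle, last = quantify_multisite(run, scheme, read_targets(b.targets_path)[0])
        assert first.median_ratio == pytest.approx(0.1, abs=1e-6)
        assert middle.median_ratio == pytest.approx(0.3, abs=1e-6)
        assert last.median_ratio == pytest.approx(0.7, abs=1e-6)
        assert any("extended-mode" in n for n in middle.qc_notes)

    def test_split_permutations_flagged_without_values(self, tmp_path):
        # VVAVSKLGDIE: light/heavy pair straddles a default-scheme boundary
        scenario = SimScenario(
            peptides=[SimPeptideSpec("VVAVSKLGDIE", (6,), (0.1,))], noise=0.0, seed=13,
        )
        b = simulate_run(scenario, tmp_path)
        scheme = load_window_scheme(b.scheme_path)
        run = read_run(b.mzml_path, scheme)
        r = quantify_site(run, scheme, read_targets(b.targets_path)[0])
        assert not r.co_isolated and r.median_ratio is None
        assert any("co-isolation failure" in n for n in r.qc_notes)


class TestMs1Stoichiometry:
    def test_noise_free_round_trip(self, loaded_single):
        run, _, target = loaded_single
        r = ms1_stoichiometry(run, target)
        assert r.ms1_ratio == pytest.approx(0.10, abs=0.005)
        assert len(r.ms1_isotope_areas) == 3

    def test_multisite_target_refused(self, two_site_bundle):
        scheme = load_window_scheme(two_site_bundle.scheme_path)
        run = read_run(two_site_bundle.mzml_path, scheme)
        target = read_targets(two_site_bundle.targets_path)[0]
        with pytest.raises(ValueError, match="cannot resolve multi-lysine"):
            ms1_stoichiometry(run, target)

    def test_empty_channels_flagged(self, tmp_path):
        scenario = SimScenario(
            peptides=[SimPeptideSpec("GFKRIAE", (3,), (0.1,), apex_rt=5.0)],
            noise=0.0, seed=1,
        )
        b = simulate_run(scenario, tmp_path)
        scheme = load_window_scheme(b.scheme_path)
        run = read_run(b.mzml_path, scheme)
        target = read_targets(b.targets_path)[0]
        other = type(target)(
            sequence="LQKDGRISNVE", protein="x", site_numbers=(3,),
            peptide_positions=(3,), family="acetyl", charge=2,
            rt_borders=target.rt_borders,
        )
        r = ms1_stoichiometry(run, other)
        assert r.ms1_ratio is None
        assert any("no MS1 signal" in n for n in r.qc_notes)


def test_results_frames_have_site_and_fragment_rows(loaded_single):
    run, scheme, target = loaded_single
    r = quantify_site(run, scheme, target)
    frag_df, site_df = results_to_frames([r])
    assert len(site_df) == 1
    assert len(frag_df) == len(r.fragments)
    assert site_df.loc[0, "median_ratio"] == pytest.approx(0.10, abs=1e-9)
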