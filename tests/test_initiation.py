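"""AUG enumeration, initiation scores, metagene profiles, site selection."""

import re

import numpy as np
import pytest

from asdscan import (
    enumerate_aug_sites,
    initiation_score,
    metagene_profile,
    score_sites,
    select_sites,
    simulate_libraries,
)
from asdscan.annotation import region_sequence
from asdscan.initiation import StartSite
from asdscan.thermo import AffinityScheme
from asdscan.tracks import CoverageTrack, rpm_normalize

from .conftest import make_track


class TestEnumerate:
    def test_single_gene_with_three_internal_augs(self, toy_genome):
        genome, genes = toy_genome
        sites, census = enumerate_aug_sites(genome, [genes[0]])
        assert census == {"annotated": 1, "non_annotated": 3,
                          "non_aug_start": 0}
        annotated = [s for s in sites if s.annotated]
        assert len(annotated) == 1
        assert annotated[0].pos_A == genes[0].start

    def test_minus_strand_codon_check_passes(self, toy_genome):
        genome, genes = toy_genome
        sites, census = enumerate_aug_sites(genome, [genes[1]])
        ann = [s for s in sites if s.annotated]
        assert len(ann) == 1
        # the A of the minus-strand AUG is the highest coordinate of the codon
        assert ann[0].pos_A == genes[1].end - 1
        assert ann[0].upstream_window[30:33] == "AUG"

    def test_context_window_covers_minus_30_to_plus_10(self, toy_genome):
        genome, genes = toy_genome
        sites, _ = enumerate_aug_sites(genome, genes)
        for s in sites:
            if not s.context_truncated:
                assert len(s.upstream_window) == 41
                assert s.upstream_window[30:33] == "AUG"

    def test_census_matches_regex_oracle_on_simulated_genome(self, small_sim):
        cfg, tx, _ = small_sim
        sites, census = enumerate_aug_sites(tx.genome, tx.genes)
        expected = 0
        seen = set()
        for gene in tx.genes:
            cds = region_sequence(
                tx.genome, gene.replicon, gene.strand, gene.start, gene.end
            )
            for m in re.finditer("(?=ATG)", cds):
                if m.start() == 0:
                    continue
                pos = (gene.start + m.start() if gene.strand == "+"
                       else gene.end - 1 - m.start())
                seen.add((gene.strand, pos))
        assert census["non_annotated"] == len(seen)
        assert census["annotated"] == cfg.n_genes

    def test_non_aug_start_counted_and_excluded(self, toy_genome):
        from asdscan import Gene

        genome, genes = toy_genome
        shifted = Gene("bad", "toy", "+", genes[0].start + 1, genes[0].end + 1)
        _, census = enumerate_aug_sites(genome, [shifted])
        assert census["non_aug_start"] == 1
        assert census["annotated"] == 0


def _site(pos=60, strand="+"):
    return StartSite(replicon="chr", strand=strand, pos_A=pos, annotated=True)


class TestInitiationScore:
    def test_uniform_track_gives_is_one(self):
        track = make_track({"chr": 200}, chr_plus=[5.0] * 200)
        site = initiation_score(track, _site())
        assert site.eligible
        assert site.is_score == pytest.approx(1.0)
        assert site.log2_is == pytest.approx(0.0)

    def test_exactly_ten_reads_is_ineligible(self):
        vec = np.zeros(200)
        vec[60] = 10.0  # exactly 10 raw reads in the window: ">10" is strict
        track = make_track({"chr": 200}, chr_plus=vec)
        site = initiation_score(track, _site())
        assert not site.eligible and site.is_score is None
        vec[60] = 11.0
        site = initiation_score(make_track({"chr": 200}, chr_plus=vec), _site())
        assert site.eligible

    def test_toy_peak_matches_direct_arithmetic(self):
        # 10 everywhere in -50..+50 except 40 at each of +3..+21:
        # IS = 40 / ((82*10 + 19*40) / 101)
        vec = np.full(200, 10.0)
        vec[63:82] = 40.0  # +3..+21 inclusive for A at 60
        track = make_track({"chr": 200}, chr_plus=vec)
        site = initiation_score(track, _site())
        expected = 40.0 / ((82 * 10 + 19 * 40) / 101)
        assert site.is_score == pytest.approx(expected, abs=1e-12)

    def test_minus_strand_mirror_scores_identically(self):
        n = 200
        vec = np.full(n, 10.0)
        vec[63:82] = 40.0
        plus = make_track({"chr": n}, chr_plus=vec)
        minus = make_track({"chr": n}, chr_minus=vec[::-1])
        s_plus = initiation_score(plus, _site(60, "+"))
        s_minus = initiation_score(minus, _site(n - 1 - 60, "-"))
        assert s_minus.is_score == pytest.approx(s_plus.is_score)
        assert s_minus.window_reads == s_plus.window_reads

    def test_window_crossing_replicon_end_is_flagged(self):
        track = make_track({"chr": 200}, chr_plus=[5.0] * 200)
        site = initiation_score(track, _site(pos=20))
        assert site.window_truncated and not site.eligible

    def test_is_invariant_to_rpm_units_but_eligibility_uses_raw(self):
        vec = np.full(200, 2.0)
        vec[63:82] = 8.0
        raw = make_track({"chr": 200}, chr_plus=vec)
        rpm = rpm_normalize(raw)
        from_raw = initiation_score(raw, _site())
        from_rpm = initiation_score(rpm, _site(), raw_track=raw)
        assert from_rpm.is_score == pytest.approx(from_raw.is_score)
        # with a sparse raw track the rpm values alone must not confer
        # eligibility
        sparse = np.zeros(200)
        sparse[60] = 4.0
        sparse_raw = make_track({"chr": 200}, chr_plus=sparse)
        scaled = rpm_normalize(sparse_raw)
        site = initiation_score(scaled, _site(), raw_track=sparse_raw)
        assert not site.eligible


class TestMetagene:
    def test_flat_coverage_gives_uniform_profile(self):
        track = make_track({"chr": 300}, chr_plus=[4.0] * 300)
        sites = [_site(100), _site(150)]
        score_sites(track, sites)
        offsets, profile, n = metagene_profile(track, sites)
        assert n == 2
        assert profile == pytest.approx(np.full(101, 1 / 101))
        assert offsets[0] == -50 and offsets[-1] == 50

    def test_profile_sums_to_one(self, small_sim):
        cfg, tx, libs = small_sim
        track = rpm_normalize(libs[("C", True)].fp_raw)
        sites = [s for s in tx.sites if s.annotated]
        score_sites(track, sites, raw_track=libs[("C", True)].fp_raw)
        _, profile, n = metagene_profile(track, sites)
        assert n > 0
        assert profile.sum() == pytest.approx(1.0, abs=1e-9)

    def test_two_hand_built_sites_average_normalized_vectors(self):
        vec = np.zeros(400)
        vec[50:151] = 1.0            # site A window: flat
        vec[250] = 3.0               # site B window: all mass at offset -50
        vec[360] = 99.0              # outside both windows
        track = make_track({"chr": 400}, chr_plus=vec)
        sites = [_site(100), _site(300)]
        score_sites(track, sites, min_window_reads=0)
        _, profile, n = metagene_profile(track, sites)
        expected = np.full(101, 1 / 101) / 2
        expected[0] += 0.5           # site B contributes 1.0 at offset -50
        assert n == 2
        assert profile == pytest.approx(expected)

    def test_no_eligible_sites_is_error(self):
        track = make_track({"chr": 300}, chr_plus=np.zeros(300))
        sites = [_site(100)]
        score_sites(track, sites)
        with pytest.raises(ValueError, match="no eligible"):
            metagene_profile(track, sites)


class TestSelectSites:
    def _sites_with_scores(self, scores):
        sites = []
        for i, s in enumerate(scores):
            site = _site(100 + i)
            site.log2_is = s
            site.eligible = s is not None
            sites.append(site)
        return sites

    def test_log2_is_threshold(self):
        sites = self._sites_with_scores([0.2, 1.6, 3.0])
        subset, census = select_sites(sites, log2_is_gt=1.5)
        assert len(subset) == 2
        assert census["selected"] == 2

    def test_affinity_conjunction_matches_set_logic_oracle(self, nn_params):
        import random

        from asdscan.thermo import ASD_VARIANTS, classify_affinity, \
            duplex_delta_g

        rng = random.Random(5)
        scheme = AffinityScheme()
        sites = []
        for i in range(50):
            site = _site(100 + i)
            window = "".join(rng.choices("ACGU", k=10))
            for v in ("S", "O", "A"):
                site.dg_by_asd[v] = duplex_delta_g(
                    window, ASD_VARIANTS[v].asd_seq, nn_params
                ).delta_g
            sites.append(site)
        subset, _ = select_sites(
            sites, affinity=(["S", "O", "A"], "none", scheme)
        )
        oracle = [
            s for s in sites
            if all("none" in classify_affinity(s.dg_by_asd[v], scheme)
                   for v in ("S", "O", "A"))
        ]
        assert subset == oracle

    def test_annotated_and_weak_wt_affinity_foreground(self):
        sites = []
        for i, (annotated, dg) in enumerate(
            [(True, 0.5), (True, -3.0), (False, 0.5)]
        ):
            site = _site(100 + i)
            site.annotated = annotated
            site.dg_by_asd["C"] = dg
            sites.append(site)
        subset, _ = select_sites(
            sites, annotated=True, affinity=(["C"], "low", AffinityScheme())
        )
        assert subset == [sites[0]]

    def test_unknown_variant_counted_as_missing(self):
        sites = self._sites_with_scores([1.0])
        subset, census = select_sites(
            sites, affinity=(["C"], "none", AffinityScheme())
        )
        assert subset == [] and census["missing_fields"] == 1
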