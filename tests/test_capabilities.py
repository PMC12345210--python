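"""Capability rules, sHdr synteny detection, QC, autotrophy, summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from sulfurcycle.capabilities import (
    SHDR_ORDER,
    CapabilityProfile,
    GeneHit,
    GenomeRecord,
    call_autotrophy,
    call_sulfur_capabilities,
    confirm_pathway,
    detect_shdr_clusters,
    parse_rank,
    qc_filter_genomes,
    summarize_capabilities,
)
from sulfurcycle.pathways import PathwayDefinition

from conftest import genome_with, shdr_scaffold


class TestQcFilter:
    @pytest.mark.parametrize(
        "completeness,contamination,kept",
        [
            (50.0, 5.0, False),   # boundary: "over 50%" is strict
            (50.1, 5.0, True),
            (100.0, 0.0, True),
            (80.0, 10.0, False),  # boundary: "less than 10%" is strict
            (80.0, 9.9, True),
        ],
    )
    def test_strict_boundaries(self, completeness, contamination, kept):
        rec = genome_with(["sqr"], completeness=completeness, contamination=contamination)
        assert (len(qc_filter_genomes([rec])) == 1) is kept

    def test_random_table_matches_brute_force_row_scan(self):
        rng = np.random.default_rng(4)
        records = [
            genome_with([], genome_id=f"G{i}",
                        completeness=float(rng.uniform(0, 100)),
                        contamination=float(rng.uniform(0, 20)))
            for i in range(1000)
        ]
        kept = {r.genome_id for r in qc_filter_genomes(records)}
        expected = {
            r.genome_id for r in records if r.completeness > 50 and r.contamination < 10
        }
        assert kept == expected

    def test_missing_qc_fields_error_lists_genomes(self):
        rec = genome_with(["sqr"], genome_id="GBAD")
        rec.completeness = None
        with pytest.raises(ValueError, match="GBAD"):
            qc_filter_genomes([rec])


def _window_is_canonical(subtypes):
    for canon in (SHDR_ORDER, SHDR_ORDER[::-1]):
        for off in range(len(canon) - len(subtypes) + 1):
            if tuple(canon[off:off + len(subtypes)]) == tuple(subtypes):
                return True
    return False


def _shdr_brute_force(hits, min_len=5):
    """All-windows oracle: enumerate every window of coordinate-sorted
    genes, keep windows of only-sHdr genes whose subtypes follow the
    canonical order, then select greedily leftmost-longest."""
    genes = sorted(hits, key=lambda h: (h.start, h.end))
    n = len(genes)
    spans = []
    i = 0
    while i < n:
        best = None
        for j in range(i + min_len, n + 1):
            window = genes[i:j]
            if any(g.family != "shdr_subunit" for g in window):
                break
            if _window_is_canonical([g.subtype for g in window]):
                best = j
        if best is not None:
            spans.append((genes[i].start, genes[best - 1].end))
            i = best
        else:
            i += 1
    return spans


class TestShdrDetection:
    def test_six_subunits_in_canonical_order_one_cluster(self):
        hits = shdr_scaffold(SHDR_ORDER)
        clusters = detect_shdr_clusters(hits)
        assert len(clusters) == 1 and len(clusters[0]) == 6
        assert clusters[0].orientation == "forward"

    def test_reverse_order_accepted_as_minus_strand_operon(self):
        hits = shdr_scaffold(SHDR_ORDER[::-1])
        clusters = detect_shdr_clusters(hits)
        assert len(clusters) == 1 and clusters[0].orientation == "reverse"

    def test_four_ordered_subunits_is_no_cluster(self):
        hits = shdr_scaffold(SHDR_ORDER[:4])
        assert detect_shdr_clusters(hits) == []

    def test_five_subunit_suffix_counts(self):
        hits = shdr_scaffold(SHDR_ORDER[1:])
        assert len(detect_shdr_clusters(hits)) == 1

    def test_shuffled_subunits_rejected(self):
        hits = shdr_scaffold(("HdrA", "HdrC1", "HdrB2", "HdrB1", "HYP", "HdrC2"))
        assert detect_shdr_clusters(hits) == []

    def test_intervening_gene_breaks_run_unless_gap_allowed(self):
        hits = shdr_scaffold(SHDR_ORDER, other_between={3})
        assert detect_shdr_clusters(hits) == []
        assert len(detect_shdr_clusters(hits, max_gap=1)) == 1

    def test_random_scaffolds_match_all_windows_oracle(self):
        """Randomized scaffolds with planted valid runs and shuffled
        decoys: detected spans equal the brute-force enumeration."""
        rng = np.random.default_rng(12)
        for trial in range(200):
            n_genes = int(rng.integers(1, 51))
            hits = []
            pos = 1
            i = 0
            while i < n_genes:
                roll = rng.random()
                if roll < 0.15 and n_genes - i >= 5:
                    # plant a valid run (possibly reversed)
                    length = int(rng.integers(5, 7))
                    offset = int(rng.integers(0, 7 - length))
                    run = list(SHDR_ORDER[offset:offset + length])
                    if rng.random() < 0.5:
                        run.reverse()
                    for sub in run:
                        hits.append(GeneHit("G", "sc", "shdr_subunit", sub, pos, pos + 500))
                        pos += 1000
                        i += 1
                elif roll < 0.55:
                    sub = SHDR_ORDER[int(rng.integers(6))]
                    hits.append(GeneHit("G", "sc", "shdr_subunit", sub, pos, pos + 500))
                    pos += 1000
                    i += 1
                else:
                    hits.append(GeneHit("G", "sc", "sqr", None, pos, pos + 500))
                    pos += 1000
                    i += 1
            detected = [(c.start, c.end) for c in detect_shdr_clusters(hits)]
            assert detected == _shdr_brute_force(hits), f"trial {trial}"

    def test_empty_input(self):
        assert detect_shdr_clusters([]) == []


SULFIDE_ZVS_FAMILIES = ("sqr", "fccB", "pdo", "rdsrA", "rdsrB", "sor")
THIO_SULFITE_FAMILIES = (
    "soxA", "soxB", "soxX", "soxY", "soxZ", "tsdA", "doxD",
    "sat_oxidative", "aprA_oxidative", "aprB_oxidative", "sorA", "suox",
)


def _expected_calls(present):
    """Independent truth-table oracle: the stated boolean rules written out
    directly over a presence set."""
    sox = all(g in present for g in ("soxA", "soxB", "soxX", "soxY", "soxZ"))
    return {
        "sulfide": "sqr" in present or "fccB" in present,
        "zerovalent_sulfur": (
            "pdo" in present
            or ("rdsrA" in present and "rdsrB" in present)
            or "sor" in present
        ),
        "thiosulfate": sox or "tsdA" in present or "doxD" in present,
        "sulfite": (
            all(g in present for g in ("sat_oxidative", "aprA_oxidative", "aprB_oxidative"))
            or "sorA" in present
            or "suox" in present
        ),
    }


class TestCapabilityRules:
    def test_single_gene_fires_single_rule(self):
        profile = call_sulfur_capabilities(genome_with(["sqr"]))
        assert profile.substrates == {
            "sulfide": True, "zerovalent_sulfur": False,
            "thiosulfate": False, "sulfite": False,
        }
        assert profile.pathways["sulfide"] == ["SQR"]

    def test_sox_without_soxD_calls_thiosulfate_with_flag(self):
        profile = call_sulfur_capabilities(
            genome_with(["soxA", "soxB", "soxX", "soxY", "soxZ"])
        )
        assert profile.substrates["thiosulfate"]
        assert profile.flags["sox_lacks_soxD"]

    def test_sat_without_aprab_does_not_call_sulfite(self):
        profile = call_sulfur_capabilities(genome_with(["sat_oxidative"]))
        assert not profile.substrates["sulfite"]

    def test_soxB_only_with_tsdA_flag(self):
        profile = call_sulfur_capabilities(genome_with(["soxB", "tsdA"]))
        assert profile.flags["soxB_only_with_tsdA"]
        assert profile.substrates["thiosulfate"]  # via TsdA

    def test_putative_sulfur_reducer_flag(self):
        profile = call_sulfur_capabilities(
            genome_with(["dsrA_reductive", "dsrB_reductive", "phsA"])
        )
        assert profile.flags["putative_sulfur_reducer"]

    @pytest.mark.parametrize("families", [SULFIDE_ZVS_FAMILIES, THIO_SULFITE_FAMILIES])
    def test_rule_engine_equals_exhaustive_truth_table(self, families):
        """Every presence combination of the relevant families yields the
        same calls as a direct evaluation of the boolean rules."""
        for bits in itertools.product([False, True], repeat=len(families)):
            present = [f for f, b in zip(families, bits) if b]
            profile = call_sulfur_capabilities(genome_with(present))
            expected = _expected_calls(set(present))
            assert profile.substrates == expected, present

    def test_input_order_invariance(self):
        families = ["soxZ", "sqr", "soxA", "pdo", "soxB", "soxX", "soxY", "tsdA"]
        a = call_sulfur_capabilities(genome_with(families))
        b = call_sulfur_capabilities(genome_with(families[::-1]))
        assert a.substrates == b.substrates and a.flags == b.flags

    def test_adding_a_gene_never_removes_a_capability(self):
        rng = np.random.default_rng(21)
        pool = list(SULFIDE_ZVS_FAMILIES + THIO_SULFITE_FAMILIES)
        for _ in range(50):
            base = [f for f in pool if rng.random() < 0.3]
            extra = pool[int(rng.integers(len(pool)))]
            before = call_sulfur_capabilities(genome_with(base)).substrates
            after = call_sulfur_capabilities(genome_with(base + [extra])).substrates
            for sub in before:
                assert after[sub] >= before[sub]

    def test_removing_soxD_keeps_call_but_toggles_flag(self):
        with_d = call_sulfur_capabilities(
            genome_with(["soxA", "soxB", "soxX", "soxY", "soxZ", "soxD"])
        )
        without_d = call_sulfur_capabilities(
            genome_with(["soxA", "soxB", "soxX", "soxY", "soxZ"])
        )
        assert with_d.substrates["thiosulfate"] and without_d.substrates["thiosulfate"]
        assert not with_d.flags["sox_lacks_soxD"]
        assert without_d.flags["sox_lacks_soxD"]

    def test_unknown_family_warns_not_errors(self):
        with pytest.warns(UserWarning, match="unknown"):
            profile = call_sulfur_capabilities(genome_with(["sqr", "mystery_gene"]))
        assert profile.substrates["sulfide"]

    def test_shdr_cluster_grants_zvs_capability(self):
        rec = genome_with([])
        rec.hits = shdr_scaffold(SHDR_ORDER, genome_id="G1")
        profile = call_sulfur_capabilities(rec)
        assert profile.substrates["zerovalent_sulfur"]
        assert "sHdr" in profile.pathways["zerovalent_sulfur"]


class TestAutotrophy:
    def test_seventy_percent_of_genes_confirms(self):
        pw = PathwayDefinition("p", frozenset(["m1", "m2"]),
                               frozenset([f"a{i}" for i in range(8)]))
        present = {"m1", "m2", "a0", "a1", "a2", "a3", "a4"}  # 7/10
        assert confirm_pathway(pw, present)["confirmed"]

    def test_marker_branch_with_majority_accessory_confirms(self):
        pw = PathwayDefinition("p", frozenset(["m1", "m2"]),
                               frozenset([f"a{i}" for i in range(8)]))
        present = {"m1", "m2", "a0", "a1", "a2", "a3", "a4"}  # 5/8 = 62.5% > 50%
        v = confirm_pathway(pw, present)
        assert v["confirmed"] and v["markers_present"]
        # 8/12 < 70% overall but 6/10 accessory > 50%: marker branch alone
        pw_wide = PathwayDefinition("q", frozenset(["m1", "m2"]),
                                    frozenset([f"a{i}" for i in range(10)]))
        barely = {"m1", "m2", "a0", "a1", "a2", "a3", "a4", "a5"}
        v2 = confirm_pathway(pw_wide, barely)
        assert v2["present_fraction"] < 0.70 and v2["confirmed"]

    def test_exactly_half_accessory_fails_marker_branch(self):
        pw = PathwayDefinition("p", frozenset(["m"]), frozenset(["a1", "a2", "a3", "a4"]))
        present = {"m", "a1", "a2"}  # 2/4 accessory, not > 50%; 3/5 < 70%
        assert not confirm_pathway(pw, present)["confirmed"]

    def test_no_genes_not_confirmed(self):
        pw = PathwayDefinition("p", frozenset(["m"]), frozenset(["a"]))
        assert not confirm_pathway(pw, set())["confirmed"]

    def test_markerless_accessory_free_pathway_confirmed_by_markers_alone(self):
        pw = PathwayDefinition("p", frozenset(["m1", "m2"]), frozenset())
        assert confirm_pathway(pw, {"m1", "m2"})["confirmed"]
        assert not confirm_pathway(pw, {"m1"})["confirmed"]

    def test_trophic_label(self):
        pw = [PathwayDefinition("p", frozenset(["m"]), frozenset())]
        autotroph = genome_with(["m"])
        hetero = genome_with(["sqr"])
        assert call_autotrophy(autotroph, pw)[0] == "autotroph"
        assert call_autotrophy(hetero, pw)[0] == "heterotroph_or_mixotroph"


class TestSummaries:
    def _profiles(self, flags):
        out = []
        for i, capable in enumerate(flags):
            subs = {"sulfide": capable, "zerovalent_sulfur": False,
                    "thiosulfate": False, "sulfite": False}
            paths = {"sulfide": ["SQR"] if capable else [], "zerovalent_sulfur": [],
                     "thiosulfate": [], "sulfite": []}
            out.append(CapabilityProfile(f"G{i}", subs, paths, {}))
        return out

    def test_printed_count_fractions(self):
        """3,511 capable of 5,233 genomes is 67.1%; 567 with complete
        Sat-AprAB is 10.8%."""
        profiles = self._profiles([i < 3511 for i in range(5233)])
        for i in range(567):
            profiles[i].pathways["sulfite"] = ["Sat-AprAB"]
            profiles[i].substrates["sulfite"] = True
        _, community = summarize_capabilities(profiles)
        assert round(community["pct_capable"], 1) == 67.1
        assert round(community["pct_sat_aprab_complete"], 1) == 10.8

    def test_single_capable_genome_is_100_percent_by_both_weightings(self):
        profiles = self._profiles([True])
        per_taxon, community = summarize_capabilities(
            profiles, abundances={"G0": 0.4}, taxonomy={"G0": "d__B;p__Proteobacteria"}
        )
        assert community["pct_capable"] == 100.0
        row = per_taxon.iloc[0]
        assert row["any_count_ratio"] == 1.0 and row["any_abundance_ratio"] == 1.0

    def test_count_and_abundance_ratios_coincide_for_equal_abundances(self):
        profiles = self._profiles([True, True, False, True])
        ab = {f"G{i}": 2.5 for i in range(4)}
        per_taxon, _ = summarize_capabilities(profiles, abundances=ab)
        row = per_taxon.iloc[0]
        assert row["any_count_ratio"] == pytest.approx(row["any_abundance_ratio"])

    def test_ratios_bounded(self):
        rng = np.random.default_rng(9)
        profiles = self._profiles(list(rng.random(100) < 0.5))
        ab = {f"G{i}": float(rng.lognormal()) for i in range(100)}
        tax = {f"G{i}": f"d__B;p__P{int(rng.integers(5))}" for i in range(100)}
        per_taxon, community = summarize_capabilities(profiles, ab, tax)
        ratio_cols = [c for c in per_taxon.columns if c.endswith("_ratio")]
        assert ((per_taxon[ratio_cols] >= 0) & (per_taxon[ratio_cols] <= 1)).all().all()
        assert 0 <= community["pct_capable"] <= 100

    def test_missing_abundance_excluded_with_warning(self):
        profiles = self._profiles([True, False])
        with pytest.warns(UserWarning, match="missing abundance"):
            summarize_capabilities(profiles, abundances={"G0": 1.0})


def test_parse_rank():
    lineage = "d__Bacteria;p__Proteobacteria;c__Gammaproteobacteria"
    assert parse_rank(lineage, "phylum") == "Proteobacteria"
    assert parse_rank(lineage, "class") == "Gammaproteobacteria"
    assert parse_rank(lineage, "order") == "Unclassified"
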