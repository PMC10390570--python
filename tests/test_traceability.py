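"""Same-chromosome mechanism rules vs the brute-force excision oracle."""

import itertools

import numpy as np
import pytest

from tcrtrace.chain_model import build_profiles, CellProfile
from tcrtrace.contig_io import apply_qc_filters, read_contig_table
from tcrtrace.locus_model import functional_v_genes, known_gene_names
from tcrtrace.synth_data import SynthConfig, generate_sample, write_contig_table
from tcrtrace.traceability import (
    RearrangementEvent,
    brute_force_excision_oracle,
    classify_cell_mechanism,
    event_from_chain,
    oracle_feasible_pair,
    tra_trec_compatible,
    trb_inversion_compatible,
    trb_trec_compatible,
)

from conftest import make_chain, make_profile


def beta(v, d, j, c):
    return RearrangementEvent("TRB", v_call=v, d_call=d, j_call=j, c_call=c)


def alpha(v, j):
    return RearrangementEvent("TRA", v_call=v, j_call=j, c_call="TRAC")


class TestTrbTrec:
    def test_cluster1_circle_cluster2_chromosome(self, human_maps):
        a = beta("TRBV19", "TRBD1", "TRBJ1-5", "TRBC1")
        b = beta("TRBV5-1", "TRBD2", "TRBJ2-3", "TRBC2")
        lm = human_maps["TRB"]
        assert trb_trec_compatible(a, b, lm)
        # role asymmetry: never both orders
        assert not trb_trec_compatible(b, a, lm)
        # oracle agreement, a rearranges first on the same chromosome
        assert brute_force_excision_oracle([a, b], lm, [[0, 1]])
        assert not brute_force_excision_oracle([a, b], lm, [[1, 0]])

    def test_same_cluster_infeasible(self, human_maps):
        a = beta("TRBV19", "TRBD1", "TRBJ1-5", "TRBC1")
        b = beta("TRBV5-1", "TRBD1", "TRBJ1-2", "TRBC1")
        lm = human_maps["TRB"]
        assert not trb_trec_compatible(a, b, lm)
        assert not oracle_feasible_pair(a, b, lm)
        assert not oracle_feasible_pair(b, a, lm)

    def test_downstream_second_v_infeasible(self, human_maps):
        """b's V downstream of a's V: the excised interval misses a's join."""
        a = beta("TRBV5-1", "TRBD1", "TRBJ1-2", "TRBC1")
        b = beta("TRBV19", "TRBD2", "TRBJ2-1", "TRBC2")
        lm = human_maps["TRB"]
        assert not trb_trec_compatible(a, b, lm)
        assert not oracle_feasible_pair(a, b, lm)

    def test_reverse_v_cannot_ride_circle(self, human_maps):
        a = beta("TRBV30", "TRBD1", "TRBJ1-5", "TRBC1")
        b = beta("TRBV5-1", "TRBD2", "TRBJ2-3", "TRBC2")
        assert not trb_trec_compatible(a, b, human_maps["TRB"])


class TestTraTrec:
    def test_nested_interval_feasible(self, human_maps):
        a = alpha("TRAV26-1", "TRAJ39")
        b = alpha("TRAV8-4", "TRAJ20")   # V upstream, J downstream of a's
        lm = human_maps["TRA"]
        assert tra_trec_compatible(a, b, lm)
        assert not tra_trec_compatible(b, a, lm)
        assert brute_force_excision_oracle([a, b], lm, [[0, 1]])

    def test_shared_j_infeasible(self, human_maps):
        a = alpha("TRAV26-1", "TRAJ39")
        b = alpha("TRAV8-4", "TRAJ39")
        lm = human_maps["TRA"]
        assert not tra_trec_compatible(a, b, lm)
        assert not oracle_feasible_pair(a, b, lm)

    def test_non_nested_j_infeasible(self, human_maps):
        """b's V upstream but b's J also upstream: a's join not contained."""
        a = alpha("TRAV26-1", "TRAJ20")
        b = alpha("TRAV8-4", "TRAJ39")
        lm = human_maps["TRA"]
        assert not tra_trec_compatible(a, b, lm)
        assert not oracle_feasible_pair(a, b, lm)
        assert not oracle_feasible_pair(b, a, lm)


class TestTrbInversion:
    def test_reverse_v_cluster2_with_forward_cluster1(self, human_maps):
        a = beta("TRBV30", "TRBD2", "TRBJ2-5", "TRBC2")
        b = beta("TRBV12-3", "TRBD1", "TRBJ1-1", "TRBC1")
        lm = human_maps["TRB"]
        assert trb_inversion_compatible(a, b, lm)
        assert trb_inversion_compatible(b, a, lm)   # symmetric
        # the oracle finds both temporal orders feasible
        assert brute_force_excision_oracle([a, b], lm, [[0, 1]])
        assert brute_force_excision_oracle([a, b], lm, [[1, 0]])

    def test_neither_v_reverse_infeasible(self, human_maps):
        a = beta("TRBV19", "TRBD2", "TRBJ2-5", "TRBC2")
        b = beta("TRBV12-3", "TRBD1", "TRBJ1-1", "TRBC1")
        assert not trb_inversion_compatible(a, b, human_maps["TRB"])

    def test_both_claiming_reverse_v_infeasible(self, human_maps):
        a = beta("TRBV30", "TRBD2", "TRBJ2-5", "TRBC2")
        b = beta("TRBV30", "TRBD1", "TRBJ1-1", "TRBC1")
        lm = human_maps["TRB"]
        assert not trb_inversion_compatible(a, b, lm)
        assert not oracle_feasible_pair(a, b, lm)
        assert not oracle_feasible_pair(b, a, lm)

    def test_mouse_v31(self, mouse_maps):
        a = beta("TRBV31", "TRBD2", "TRBJ2-5", "TRBC2")
        b = beta("TRBV13-1", "TRBD1", "TRBJ1-1", "TRBC1")
        assert trb_inversion_compatible(a, b, mouse_maps["TRB"])


def _toy_events(toy_map):
    events = []
    for v in toy_map.segments("V"):
        for cluster in ("DJC1", "DJC2"):
            d = toy_map.segments("D", cluster=cluster)[0]
            c = toy_map.segments("C", cluster=cluster)[0]
            for j in toy_map.segments("J", cluster=cluster):
                events.append(beta(v.name, d.name, j.name, c.name))
    return events


class TestRuleOracleEquivalence:
    def test_toy_locus_exhaustive(self, toy_map):
        """Over all ordered toy-locus event pairs, the rule-based predicates
        exactly reproduce oracle feasibility on one chromosome."""
        events = _toy_events(toy_map)
        n_checked = 0
        for a, b in itertools.product(events, repeat=2):
            if a == b:
                continue
            n_checked += 1
            rule = (trb_trec_compatible(a, b, toy_map)
                    or trb_inversion_compatible(a, b, toy_map))
            assert rule == oracle_feasible_pair(a, b, toy_map), (a, b)
        assert n_checked == 16 * 15

    @pytest.mark.parametrize("species", ["human", "mouse"])
    def test_random_packaged_trb_pairs(self, species):
        rng = np.random.default_rng(29)
        from tcrtrace.locus_model import load_locus
        lm = load_locus(species, "TRB")
        vs = lm.segments("V")
        for _ in range(500):
            evs = []
            for _k in range(2):
                v = vs[int(rng.integers(len(vs)))]
                cluster = "DJC1" if rng.random() < 0.5 else "DJC2"
                d = lm.segments("D", cluster=cluster)[0]
                js = lm.segments("J", cluster=cluster)
                j = js[int(rng.integers(len(js)))]
                c = lm.segments("C", cluster=cluster)[0]
                evs.append(beta(v.name, d.name, j.name, c.name))
            a, b = evs
            if a == b:
                continue
            rule = (trb_trec_compatible(a, b, lm)
                    or trb_inversion_compatible(a, b, lm))
            assert rule == oracle_feasible_pair(a, b, lm), (a, b)

    @pytest.mark.parametrize("species", ["human", "mouse"])
    def test_random_packaged_tra_pairs(self, species):
        rng = np.random.default_rng(31)
        from tcrtrace.locus_model import load_locus
        lm = load_locus(species, "TRA")
        vs, js = lm.segments("V"), lm.segments("J")
        for _ in range(500):
            a = alpha(vs[int(rng.integers(len(vs)))].name,
                      js[int(rng.integers(len(js)))].name)
            b = alpha(vs[int(rng.integers(len(vs)))].name,
                      js[int(rng.integers(len(js)))].name)
            if a == b:
                continue
            assert tra_trec_compatible(a, b, lm) == \
                oracle_feasible_pair(a, b, lm), (a, b)

    def test_trec_role_asymmetry_everywhere(self, toy_map):
        for a, b in itertools.combinations(_toy_events(toy_map), 2):
            assert not (trb_trec_compatible(a, b, toy_map)
                        and trb_trec_compatible(b, a, toy_map))


class TestOracleSchemes:
    def test_segment_reuse_rejected(self, human_maps):
        """Two D1-cluster joins can never share one chromosome."""
        lm = human_maps["TRB"]
        a = beta("TRBV19", "TRBD1", "TRBJ1-5", "TRBC1")
        b = beta("TRBV5-1", "TRBD1", "TRBJ1-2", "TRBC1")
        for order in ([[0, 1]], [[1, 0]]):
            assert not brute_force_excision_oracle([a, b], lm, order)

    def test_two_chromosome_scheme_always_ok(self, human_maps):
        lm = human_maps["TRB"]
        a = beta("TRBV19", "TRBD1", "TRBJ1-5", "TRBC1")
        b = beta("TRBV5-1", "TRBD1", "TRBJ1-2", "TRBC1")
        assert brute_force_excision_oracle([a, b], lm, [[0], [1]])

    def test_bad_scheme_errors(self, human_maps):
        a = beta("TRBV19", "TRBD1", "TRBJ1-5", "TRBC1")
        with pytest.raises(ValueError):
            brute_force_excision_oracle([a], human_maps["TRB"], [[0, 0]])
        with pytest.raises(ValueError):
            brute_force_excision_oracle([a], human_maps["TRB"], [[1]])

    def test_nested_tra_chain_on_one_chromosome(self, human_maps):
        """Three strictly nested V-J excisions are oracle-feasible."""
        lm = human_maps["TRA"]
        inner = alpha("TRAV26-1", "TRAJ39")
        mid = alpha("TRAV8-4", "TRAJ20")
        outer = alpha("TRAV1-2", "TRAJ4")
        assert brute_force_excision_oracle([inner, mid, outer], lm, [[0, 1, 2]])
        assert not brute_force_excision_oracle([inner, mid, outer], lm, [[2, 1, 0]])


class TestClassifyCellMechanism:
    def test_trec_beta_among_three_beta_events(self, human_maps):
        chains = [
            make_chain("TRB", "F", v_call="TRBV19", d_call="TRBD1",
                       j_call="TRBJ1-5", c_call="TRBC1"),
            make_chain("TRB", "F", v_call="TRBV5-1", d_call="TRBD2",
                       j_call="TRBJ2-3", c_call="TRBC2"),
            make_chain("TRB", "N", v_call="TRBV28", d_call="TRBD1",
                       j_call="TRBJ1-1", c_call="TRBC1"),
        ]
        call = classify_cell_mechanism(make_profile(*chains), human_maps)
        assert "trec_circle_beta" in call.feasible
        assert "unexplained" not in call.feasible
        # both D1-cluster events can ride the circle excised by the
        # TRBV5-1/D2 rearrangement; both role assignments are reported
        trec_roles = {(r.circle.v_call, r.chromosome.v_call)
                      for r in call.roles if r.mechanism == "trec_circle_beta"}
        assert ("TRBV19", "TRBV5-1") in trec_roles

    def test_incompatible_pair_is_biallelic(self, human_maps):
        chains = [
            make_chain("TRB", "F", v_call="TRBV5-1", d_call="TRBD1",
                       j_call="TRBJ1-2", c_call="TRBC1"),
            make_chain("TRB", "F", v_call="TRBV19", d_call="TRBD2",
                       j_call="TRBJ2-1", c_call="TRBC2"),
        ]
        call = classify_cell_mechanism(make_profile(*chains), human_maps)
        assert call.feasible == frozenset({"two_chromosomes"})

    def test_three_same_cluster_events_unexplained(self, human_maps):
        chains = [
            make_chain("TRB", "F", v_call=v, d_call="TRBD1",
                       j_call=j, c_call="TRBC1")
            for v, j in [("TRBV19", "TRBJ1-5"), ("TRBV5-1", "TRBJ1-2"),
                         ("TRBV28", "TRBJ1-1")]
        ]
        call = classify_cell_mechanism(make_profile(*chains), human_maps)
        assert call.per_locus["TRB"] == frozenset({"unexplained"})

    def test_n_chains_participate_like_f(self, human_maps):
        """Non-functional chains trace identically to functional ones."""
        chains = [
            make_chain("TRB", "N", v_call="TRBV19", d_call="TRBD1",
                       j_call="TRBJ1-5", c_call="TRBC1"),
            make_chain("TRB", "N", v_call="TRBV5-1", d_call="TRBD2",
                       j_call="TRBJ2-3", c_call="TRBC2"),
        ]
        call = classify_cell_mechanism(make_profile(*chains), human_maps)
        assert "trec_circle_beta" in call.feasible

    def test_missing_d_call_inferred_from_cluster(self, human_maps):
        chain = make_chain("TRB", "F", v_call="TRBV19", d_call="",
                           j_call="TRBJ2-3", c_call="TRBC2")
        event = event_from_chain(chain, human_maps["TRB"])
        assert event.d_call == "TRBD2"

    def test_jc_cluster_mismatch_rejected(self, human_maps):
        chain = make_chain("TRB", "F", v_call="TRBV19", d_call="TRBD1",
                           j_call="TRBJ1-5", c_call="TRBC2")
        with pytest.raises(ValueError, match="inconsistent"):
            event_from_chain(chain, human_maps["TRB"])


def test_planted_mechanism_recovery(tmp_path, human_maps):
    """Planted same-chromosome mechanisms are recovered for >=99% of
    planted cells; unplanted biallelic cells only trigger by chance gene
    draws (rate measured)."""
    config = SynthConfig(
        n_cells=2000, seed=42,
        mechanism_plant_rates={"trec_circle_beta": 0.10,
                               "trec_circle_alpha": 0.05,
                               "inversion_v30": 0.02},
    )
    contigs, truth = generate_sample(config)
    path = tmp_path / "s.csv"
    write_contig_table(contigs, path, "tenx_csv")
    kept, _ = apply_qc_filters(read_contig_table(path, "tenx_csv"))
    profiles = {p.barcode: p for p in build_profiles(
        kept, functional_v_genes("human"), known_gene_names("human"))}

    recovered = total = 0
    chance_hits = chance_total = 0
    same_chrom = {"trec_circle_beta", "trec_circle_alpha", "inversion_v30"}
    for _, row in truth.iterrows():
        profile = profiles[row["barcode"]]
        multi_locus = any(
            sum(1 for c in profile.chains if c.locus == locus) >= 2
            for locus in ("TRA", "TRB"))
        if not multi_locus:
            continue
        call = classify_cell_mechanism(profile, human_maps)
        if row["planted_mechanism"] != "none":
            total += 1
            recovered += row["planted_mechanism"] in call.feasible
        else:
            chance_total += 1
            chance_hits += bool(call.feasible & same_chrom)
    assert total == 340  # 10% + 5% + 2% of 2000
    assert recovered / total >= 0.99
    if chance_total:
        # chance-compatible biallelic rate, logged for the record
        print(f"chance-compatible rate: {chance_hits}/{chance_total}")
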