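"""Differential contact analysis: set identities, deltas, unions, rankings."""

import numpy as np
import pytest

from pcnkit import (bc_gain_ranking, build_pcn, degree_change_summary,
                    diff_contacts, union_contacts)
from pcnkit import synth

from conftest import network_from_edges


class TestDiffContacts:
    def test_identical_networks_empty_diff(self, mixed_chain):
        net = build_pcn(mixed_chain)
        rep = diff_contacts(net, net)
        assert rep.made == () and rep.lost == ()
        assert (rep.metric_deltas == 0).all().all()

    def test_cutoff_mismatch_refused(self, mixed_chain):
        with pytest.raises(ValueError, match="cutoff"):
            diff_contacts(build_pcn(mixed_chain, 7.0), build_pcn(mixed_chain, 8.0))

    def test_injected_contact_found_with_degree_delta(self, two_helix_near):
        spec = synth.SyntheticSpec(
            n_residues=32, segments=(("helix", 32),),
            contact_edits=((1, 19, "inject"),), seed=5)
        mut = synth.make_mutant(two_helix_near, spec)
        rep = diff_contacts(build_pcn(two_helix_near), build_pcn(mut))
        assert rep.made_pairs == {(1, 19)} and rep.lost_pairs == set()
        assert rep.metric_deltas.loc[1, "degree"] == 1
        assert rep.metric_deltas.loc[19, "degree"] == 1

    def test_antisymmetry(self, mixed_chain):
        mut, _, _ = synth.random_mutant(mixed_chain, seed=11, n_edits=3)
        a = diff_contacts(build_pcn(mixed_chain), build_pcn(mut))
        b = diff_contacts(build_pcn(mut), build_pcn(mixed_chain))
        assert a.made_pairs == b.lost_pairs and a.lost_pairs == b.made_pairs
        assert np.allclose(a.metric_deltas.values, -b.metric_deltas.values)

    def test_contact_count_conservation(self, mixed_chain):
        mut, _, _ = synth.random_mutant(mixed_chain, seed=13, n_edits=4)
        ref_net, mut_net = build_pcn(mixed_chain), build_pcn(mut)
        rep = diff_contacts(ref_net, mut_net)
        assert mut_net.n_edges == ref_net.n_edges + len(rep.made) - len(rep.lost)

    @pytest.mark.parametrize("seed", range(20))
    def test_ground_truth_recovery(self, mixed_chain, seed):
        """Injected/removed contact sets are recovered exactly."""
        mut, made, lost = synth.random_mutant(mixed_chain, seed, n_edits=3)
        rep = diff_contacts(build_pcn(mixed_chain), build_pcn(mut))
        assert rep.made_pairs == made
        assert rep.lost_pairs == lost

    def test_unmatched_residue_contacts_excluded(self, mixed_chain):
        truncated = type(mixed_chain)(id="trunc",
                                      residues=mixed_chain.residues[:-1],
                                      ss_source=mixed_chain.ss_source)
        rep = diff_contacts(build_pcn(mixed_chain), build_pcn(truncated))
        last = mixed_chain.author_numbers[-1]
        assert all(last not in c.pair for c in rep.made + rep.lost)
        assert all(last in p for p in rep.excluded_ref)

    def test_tallies_consistent_with_flags(self, mixed_chain):
        mut, _, _ = synth.random_mutant(mixed_chain, seed=17, n_edits=4)
        rep = diff_contacts(build_pcn(mixed_chain), build_pcn(mut))
        t = rep.tallies["made"]
        assert t["total"] == len(rep.made)
        assert t["long_range"] == sum(c.range_class == "long" for c in rep.made)
        assert t["long_range"] + t["short_range"] == t["total"]
        assert t["involves_loop"] == sum(c.involves_loop for c in rep.made)


class TestUnionContacts:
    def _reports(self, ref, seeds):
        ref_net = build_pcn(ref)
        out = []
        truth = []
        for s in seeds:
            mut, made, lost = synth.random_mutant(ref, s, n_edits=3)
            mut2 = mut.with_coords(mut.coords, id=f"mut{s}")
            out.append(diff_contacts(ref_net, build_pcn(mut2)))
            truth.append((made, lost))
        return out, truth

    def test_single_report_union_is_itself(self, mixed_chain):
        reports, _ = self._reports(mixed_chain, [1])
        u = union_contacts(reports)
        assert {c.pair for c in u.unique_made} == reports[0].made_pairs
        assert {c.pair for c in u.unique_lost} == reports[0].lost_pairs

    def test_dedupe_counts(self, mixed_chain):
        reports, truth = self._reports(mixed_chain, [2, 3, 4])
        u = union_contacts(reports)
        want_made = set().union(*(m for m, _ in truth))
        want_lost = set().union(*(l for _, l in truth))
        assert {c.pair for c in u.unique_made} == want_made
        assert {c.pair for c in u.unique_lost} == want_lost
        assert len(u.unique_made) <= sum(len(r.made) for r in reports)

    def test_mixed_references_refused(self, mixed_chain, two_helix_near):
        r1 = diff_contacts(build_pcn(mixed_chain), build_pcn(mixed_chain))
        r2 = diff_contacts(build_pcn(two_helix_near), build_pcn(two_helix_near))
        with pytest.raises(ValueError, match="mix"):
            union_contacts([r1, r2])

    def test_empty_report_list_refused(self):
        with pytest.raises(ValueError):
            union_contacts([])


class TestDegreeChangeSummary:
    def test_identity_has_zero_changes(self, mixed_chain):
        net = build_pcn(mixed_chain)
        df = degree_change_summary([diff_contacts(net, net)])
        assert df.loc["average", "changed_fraction"] == 0.0
        assert df["max_abs_change"].max() == 0

    def test_single_injection_changes_two_residues(self, two_helix_near):
        spec = synth.SyntheticSpec(
            n_residues=32, segments=(("helix", 32),),
            contact_edits=((1, 19, "inject"),), seed=5)
        mut = synth.make_mutant(two_helix_near, spec)
        df = degree_change_summary(
            [diff_contacts(build_pcn(two_helix_near), build_pcn(mut))])
        assert df.iloc[0]["changed_fraction"] == pytest.approx(2 / 32)
        assert df.iloc[0]["max_abs_change"] == 1


class TestBcGainRanking:
    def test_all_zero_deltas_rank_by_residue_number(self, mixed_chain):
        net = build_pcn(mixed_chain)
        r = bc_gain_ranking(diff_contacts(net, net), top_k=5)
        assert list(r.index) == [1, 2, 3, 4, 5]
        assert (r == 0).all()

    def test_bridge_endpoints_top_ranking(self):
        """Adding the only bridge between two cliques sends the bridge
        endpoints to the top of the betweenness-gain ranking."""
        import itertools
        from pcnkit.diff import diff_contacts as dc
        k = 5
        base_edges = list(itertools.combinations(range(k), 2)) + \
            [(u + k, v + k) for u, v in itertools.combinations(range(k), 2)]
        ref = network_from_edges(2 * k, base_edges)
        mut = network_from_edges(2 * k, base_edges + [(0, k)])
        rep = dc(ref, mut)
        top2 = set(bc_gain_ranking(rep, top_k=2).index)
        assert top2 == {1, k + 1}

    def test_top_k_truncates_with_warning(self, mixed_chain):
        net = build_pcn(mixed_chain)
        rep = diff_contacts(net, net)
        with pytest.warns(UserWarning):
            r = bc_gain_ranking(rep, top_k=1000)
        assert len(r) == len(mixed_chain)
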