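"""Bray-Curtis dedup, target clustering and promiscuity labels."""

import numpy as np
import pytest
from scipy.spatial.distance import braycurtis as scipy_braycurtis

from bindscape import redundancy
from bindscape._aa import AA_ORDER
from bindscape.core_io import Residue, TargetChain, Atom
from bindscape.pockets import BindingPocket, composition_from_types


def make_pocket(types, compound_id="LIG", structure_id="s1", chain_id="A"):
    comp = composition_from_types(types)
    return BindingPocket(compound_id, structure_id, chain_id,
                         [(str(i), t) for i, t in enumerate(types)], comp)


def make_chain(seq, structure_id="s1", chain_id="A"):
    residues = [Residue(chain_id, str(i + 1), t,
                        [Atom("CA", "C", np.zeros(3), True)])
                for i, t in enumerate(seq)]
    return TargetChain(structure_id, chain_id, residues)


class TestBrayCurtis:
    def test_identity(self):
        a = composition_from_types(["A", "A", "H"])
        assert redundancy.bray_curtis(a, a) == 0.0

    def test_disjoint_support(self):
        a = composition_from_types(["A"])
        b = composition_from_types(["G"])
        assert redundancy.bray_curtis(a, b) == 1.0

    def test_worked_example(self):
        a = composition_from_types(["A", "A", "H"])
        b = composition_from_types(["A", "H", "G", "G"])
        assert redundancy.bray_curtis(a, b) == pytest.approx(3 / 7)

    def test_both_zero_undefined(self):
        z = np.zeros(20)
        with pytest.raises(redundancy.UndefinedDissimilarityError):
            redundancy.bray_curtis(z, z)

    def test_semimetric_properties_vs_oracle(self, rng):
        for _ in range(300):
            a = rng.integers(0, 6, 20).astype(float)
            b = rng.integers(0, 6, 20).astype(float)
            if a.sum() + b.sum() == 0:
                continue
            d = redundancy.bray_curtis(a, b)
            assert d == pytest.approx(scipy_braycurtis(a, b), abs=1e-12)
            assert d == pytest.approx(redundancy.bray_curtis(b, a), abs=0)
            assert 0.0 <= d <= 1.0
            assert (d == 0.0) == bool((a == b).all())


def brute_force_complete_linkage(comps, cutoff):
    """Agglomerate clusters greedily by minimal complete-linkage distance."""
    clusters = [[i] for i in range(len(comps))]

    def diameter_between(c1, c2):
        return max(redundancy.bray_curtis(comps[i], comps[j])
                   for i in c1 for j in c2)

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = diameter_between(clusters[i], clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        if best[0] > cutoff:
            break
        d, i, j = best
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return {frozenset(c) for c in clusters}


class TestDedupPockets:
    def test_identical_pockets_collapse(self):
        p = make_pocket(["A", "H", "G"])
        q = make_pocket(["A", "H", "G"], structure_id="s2")
        assert len(redundancy.dedup_pockets([p, q])) == 1

    def test_distant_pair_kept(self):
        p = make_pocket(["A"] * 3)
        q = make_pocket(["G", "G", "A"], structure_id="s2")  # d = 4/6 > 0.3
        assert len(redundancy.dedup_pockets([p, q])) == 2

    def test_tight_triple_collapses(self):
        ps = [make_pocket(["A"] * 9 + ["H"], structure_id=f"s{i}")
              for i in range(3)]
        ps[1] = make_pocket(["A"] * 10, structure_id="sX")  # d = 1/10 pairs
        assert len(redundancy.dedup_pockets(ps)) == 1

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(60):
            n = int(rng.integers(2, 13))
            comps = [rng.integers(0, 4, 20).astype(float) for _ in range(n)]
            comps = [c if c.sum() else c + 1 for c in comps]
            ps = [BindingPocket("LIG", f"s{i}", "A",
                                [("1", "A")], comps[i]) for i in range(n)]
            expected = brute_force_complete_linkage(comps, 0.3)
            reps = redundancy.dedup_pockets(ps)
            assert len(reps) == len(expected)

    def test_representative_is_member(self):
        ps = [make_pocket(["A", "H", "G"], structure_id="s2"),
              make_pocket(["A", "H", "G", "G"], structure_id="s1")]
        reps = redundancy.dedup_pockets(ps)
        assert reps[0] in ps
        assert reps[0].n_residues == 4  # largest pocket wins


class TestClusterTargets:
    def test_identical_sequences_merge(self):
        a = make_chain("ACDEFGHIKLMNPQRSTVWY" * 2, "s1")
        b = make_chain("ACDEFGHIKLMNPQRSTVWY" * 2, "s2")
        cl = redundancy.cluster_targets([a, b])
        assert len(cl) == 1 and len(cl[0].members) == 2

    def test_unrelated_sequences_split(self, rng):
        aa = np.array(list(AA_ORDER))
        a = make_chain("".join(rng.choice(aa, 80)), "s1")
        b = make_chain("".join(rng.choice(aa, 80)), "s2")
        ident, *_ = redundancy.pairwise_identity(a.sequence, b.sequence)
        assert ident < 0.30  # oracle precondition for this fixture
        assert len(redundancy.cluster_targets([a, b])) == 2

    def test_single_linkage_transitivity(self, rng):
        aa = np.array(list(AA_ORDER))
        sa = "".join(rng.choice(aa, 100))
        sc = "".join(rng.choice(aa, 100))
        # point substitutions only, so alignments stay gapless: B shares
        # positions 0-54 with A and 55-99 with C; A~C remain unrelated
        sb = sa[:55] + sc[55:]
        a, b, c = (make_chain(s, f"s{i}") for i, s in enumerate([sa, sb, sc]))
        iab, *_ = redundancy.pairwise_identity(sa, sb)
        ibc, *_ = redundancy.pairwise_identity(sb, sc)
        iac, *_ = redundancy.pairwise_identity(sa, sc)
        assert iab >= 0.30 and ibc >= 0.30 and iac < 0.30
        clusters = redundancy.cluster_targets([a, b, c])
        assert len(clusters) == 1 and len(clusters[0].members) == 3

    def test_cluster_count_nonincreasing_in_cutoff(self, rng):
        aa = np.array(list(AA_ORDER))
        base = "".join(rng.choice(aa, 60))
        chains = [make_chain(base, "s0")]
        for i in range(1, 5):
            mutated = list(base)
            for pos in rng.choice(60, size=10 * i, replace=False):
                mutated[pos] = str(rng.choice(aa))
            chains.append(make_chain("".join(mutated), f"s{i}"))
        counts = [len(redundancy.cluster_targets(chains, cutoff))
                  for cutoff in (0.2, 0.4, 0.6, 0.8)]
        assert counts == sorted(counts)

    def test_empty_input_error(self):
        with pytest.raises(ValueError):
            redundancy.cluster_targets([])


class TestNonredundantEvents:
    def test_homologous_chains_collapse(self):
        seq = "ACDEFGHIKLMNPQRSTVWY" * 3
        chains = [make_chain(seq, f"s{i}") for i in range(5)]
        ps = {"LIG": [make_pocket(["A", "H", "G"], structure_id=f"s{i}")
                      for i in range(5)]}
        out = redundancy.nonredundant_events(ps, chains)
        assert len(out["LIG"]) == 1

    def test_unrelated_targets_kept(self, rng):
        aa = np.array(list(AA_ORDER))
        chains = [make_chain("".join(rng.choice(aa, 80)), f"s{i}")
                  for i in range(3)]
        ps = {"LIG": [make_pocket(["A", "H", "G"], structure_id=f"s{i}")
                      for i in range(3)]}
        out = redundancy.nonredundant_events(ps, chains)
        assert len(out["LIG"]) == 3

    def test_compound_without_pockets_absent(self):
        chains = [make_chain("ACDEFGHIKL", "s0")]
        out = redundancy.nonredundant_events({"LIG": []}, chains)
        assert "LIG" not in out


class TestClassifyPromiscuity:
    @pytest.mark.parametrize("n,label", [
        (3, "promiscuous"), (2, "selective"), (1, "selective"),
        (10, "promiscuous"),
    ])
    def test_threshold(self, n, label):
        (out,) = redundancy.classify_promiscuity({"LIG": n})
        assert out.label == label and out.n_pockets == n

    def test_partition(self, rng):
        events = {f"C{i}": int(rng.integers(0, 8)) for i in range(50)}
        labels = redundancy.classify_promiscuity(events)
        n_with_events = sum(1 for v in events.values() if v >= 1)
        assert len(labels) == n_with_events
        assert (sum(l.label == "promiscuous" for l in labels)
                + sum(l.label == "selective" for l in labels)
                == n_with_events)
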