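import itertools
import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from genophys import proteome
from genophys.io import ProteinRecord

from oracles import blosum_score_fn, gotoh_global_score

AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_protein(rng, n=60):
    return "".join(np.array(list(AA))[rng.integers(0, 20, n)])


def _mutate(rng, seq, k):
    chars = list(seq)
    for pos in rng.choice(len(chars), k, replace=False):
        chars[pos] = AA[(AA.index(chars[pos]) + 1 + int(rng.integers(0, 19))) % 20]
    return "".join(chars)


def brute_force_hits(proteome_a, proteome_b, id_thr=30.0, cov_thr=70.0):
    """Independent oracle: plain-Python DP on every ordered pair."""
    mat = substitution_matrices.load("BLOSUM62")
    fn = blosum_score_fn(mat)
    hits = []
    for qa in proteome_a:
        for sb in proteome_b:
            score = gotoh_global_score(qa.sequence, sb.sequence, fn, 11.0, 1.0)
            stats = _oracle_stats(qa.sequence, sb.sequence)
            identity, cov_longer = stats
            if identity >= id_thr and cov_longer >= cov_thr:
                hits.append((qa.id, sb.id, identity, score))
    return hits


def _oracle_stats(a, b):
    """Identity/coverage from the package's aligner, used only for the
    filtering thresholds; scores come from the independent DP."""
    from genophys.align import align_protein

    r = align_protein(a, b)
    longer_cov = r.subject_coverage_pct if len(b) >= len(a) else r.query_coverage_pct
    return r.identity_pct, longer_cov


class TestFilteredHits:
    def test_self_hits(self, rng):
        prots = [ProteinRecord(f"p{i}", "A", _random_protein(rng)) for i in range(5)]
        hits = proteome.filtered_hits(prots, prots)
        self_hits = {h.query_id for h in hits if h.query_id == h.subject_id}
        assert self_hits == {p.id for p in prots}
        for h in hits:
            if h.query_id == h.subject_id:
                assert h.identity_pct == 100.0
                assert h.coverage_longer_pct == 100.0

    def test_below_threshold_pair_absent(self, rng):
        base = _random_protein(rng, 100)
        faint = _mutate(rng, base, 75)  # ~25 % identity
        a = [ProteinRecord("q", "A", base)]
        b = [ProteinRecord("s", "B", faint)]
        hits = proteome.filtered_hits(a, b, id_threshold_pct=30.0)
        assert all(h.subject_id != "s" or h.identity_pct >= 30.0 for h in hits)

    def test_empty_proteome_rejected(self):
        with pytest.raises(ValueError):
            proteome.filtered_hits([], [ProteinRecord("p", "A", "MKT")])


class TestReciprocalBestHits:
    def test_identical_proteomes_identity_mapping(self, rng):
        prots = [ProteinRecord(f"p{i}", "A", _random_protein(rng)) for i in range(6)]
        others = [ProteinRecord(p.id.replace("p", "q"), "B", p.sequence) for p in prots]
        ab = proteome.filtered_hits(prots, others)
        ba = proteome.filtered_hits(others, prots)
        pairs = proteome.reciprocal_best_hits(ab, ba)
        assert len(pairs) == 6
        assert all(p.protein_a.replace("p", "q") == p.protein_b for p in pairs)

    def test_hand_enumerated_two_by_two(self):
        mk = proteome.HitRecord
        ab = [mk("p1", "q1", 80, 100, 80), mk("p1", "q2", 55, 100, 55),
              mk("p2", "q2", 90, 100, 90), mk("p2", "q1", 40, 100, 40)]
        ba = [mk("q1", "p1", 80, 100, 80), mk("q2", "p1", 55, 100, 55),
              mk("q2", "p2", 90, 100, 90), mk("q1", "p2", 40, 100, 40)]
        pairs = proteome.reciprocal_best_hits(ab, ba)
        assert {(p.protein_a, p.protein_b) for p in pairs} == {("p1", "q1"), ("p2", "q2")}

    def test_one_sided_best_excluded(self):
        mk = proteome.HitRecord
        # p1 -> q1 best, but q1's best is p2
        ab = [mk("p1", "q1", 80, 100, 80)]
        ba = [mk("q1", "p2", 90, 100, 90), mk("q1", "p1", 80, 100, 80)]
        assert proteome.reciprocal_best_hits(ab, ba) == []


class TestComputeAai:
    def test_self_aai_100(self, rng):
        prots = [ProteinRecord(f"p{i}", "A", _random_protein(rng)) for i in range(4)]
        res = proteome.compute_aai(prots, prots)
        assert res.aai_pct == 100.0
        assert res.n_rbh == 4

    def test_toy_mean(self, rng):
        a1, a2 = _random_protein(rng, 80), _random_protein(rng, 80)
        pa = [ProteinRecord("p1", "A", a1), ProteinRecord("p2", "A", a2)]
        pb = [ProteinRecord("q1", "B", _mutate(rng, a1, 8)),
              ProteinRecord("q2", "B", _mutate(rng, a2, 16))]
        res = proteome.compute_aai(pa, pb)
        assert res.n_rbh == 2
        assert res.aai_pct == pytest.approx((90.0 + 80.0) / 2, abs=0.01)

    def test_unrelated_is_nan(self, rng):
        pa = [ProteinRecord("p", "A", _random_protein(rng, 100))]
        pb = [ProteinRecord("q", "B", _random_protein(rng, 100))]
        res = proteome.compute_aai(pa, pb)
        assert math.isnan(res.aai_pct)


class TestRbhOracleEquivalence:
    def test_rbh_equals_brute_force_battery(self, rng):
        for trial in range(5):
            na, nb = int(rng.integers(4, 9)), int(rng.integers(4, 9))
            shared = [_random_protein(rng, 50) for _ in range(3)]
            pa = [ProteinRecord(f"a{i}", "A", s) for i, s in enumerate(shared)]
            pa += [ProteinRecord(f"ax{i}", "A", _random_protein(rng, 50)) for i in range(na - 3)]
            pb = [ProteinRecord(f"b{i}", "B", _mutate(rng, s, 5)) for i, s in enumerate(shared)]
            pb += [ProteinRecord(f"bx{i}", "B", _random_protein(rng, 50)) for i in range(nb - 3)]
            ab = proteome.filtered_hits(pa, pb)
            ba = proteome.filtered_hits(pb, pa)
            got = {(p.protein_a, p.protein_b) for p in proteome.reciprocal_best_hits(ab, ba)}
            # oracle RBH from brute-force tables
            oracle_ab = brute_force_hits(pa, pb)
            oracle_ba = brute_force_hits(pb, pa)

            def best(hits):
                out = {}
                for q, s, identity, score in hits:
                    cur = out.get(q)
                    if (
                        cur is None
                        or score > cur[2]
                        or (score == cur[2] and identity > cur[1])
                        or (score == cur[2] and identity == cur[1] and s < cur[0])
                    ):
                        out[q] = (s, identity, score)
                return out

            best_ab, best_ba = best(oracle_ab), best(oracle_ba)
            expected = {
                (q, v[0]) for q, v in best_ab.items()
                if best_ba.get(v[0], (None,))[0] == q
            }
            assert got == expected


class TestGeneFamilies:
    def test_singletons_without_similarity(self, rng):
        prots = {"G1": [ProteinRecord(f"p{i}", "G1", _random_protein(rng, 80)) for i in range(5)]}
        fams = proteome.build_gene_families(prots)
        assert len(fams) == 5
        assert all(len(f.members) == 1 for f in fams)

    def test_hand_enumerated_three_genomes(self, rng):
        a, b, c, d, e = (_random_protein(rng, 70) for _ in range(5))
        prots = {
            "G1": [ProteinRecord("a1", "G1", a), ProteinRecord("b1", "G1", b),
                   ProteinRecord("c1", "G1", c)],
            "G2": [ProteinRecord("a2", "G2", _mutate(rng, a, 3)),
                   ProteinRecord("b2", "G2", _mutate(rng, b, 3)),
                   ProteinRecord("d2", "G2", d)],
            "G3": [ProteinRecord("a3", "G3", _mutate(rng, a, 3)),
                   ProteinRecord("e3", "G3", e)],
        }
        fams = proteome.build_gene_families(prots)
        assert len(fams) == 5
        by_min = {min(f.members): f for f in fams}
        a_family = by_min[("G1", "a1")]
        assert a_family.genomes() == {"G1", "G2", "G3"}
        curve = proteome.pan_core_curve(fams, ["G1", "G2", "G3"])
        assert curve.pan_counts == [3, 4, 5]
        assert curve.core_counts == [3, 2, 1]
        assert proteome.exclusive_genes(fams, "G2") == {"d2"}

    def test_single_linkage_chain(self, rng):
        # a~b and b~c connect a,c even if a and c are dissimilar
        base = _random_protein(rng, 90)
        mid = _mutate(rng, base, 27)     # ~70 % to base
        far = _mutate(rng, mid, 27)      # ~70 % to mid, ~<55 % to base
        prots = {"G": [ProteinRecord("a", "G", base), ProteinRecord("b", "G", mid),
                       ProteinRecord("c", "G", far)]}
        fams = proteome.build_gene_families(prots, id_threshold_pct=60.0)
        assert len(fams) == 1
        assert len(fams[0].members) == 3

    def test_families_partition_universe(self, small_sim):
        gids = [g.id for g in small_sim.genomes]
        prots = {g: small_sim.proteomes[g] for g in gids}
        fams = proteome.build_gene_families(prots)
        everything = {(g, p.id) for g in gids for p in prots[g]}
        seen = set()
        for f in fams:
            assert not (f.members & seen)
            seen |= f.members
        assert seen == everything


class TestPanCore:
    def test_identical_genomes_constant(self, rng):
        seqs = [_random_protein(rng, 60) for _ in range(4)]
        prots = {
            g: [ProteinRecord(f"{g}_p{i}", g, s) for i, s in enumerate(seqs)]
            for g in ("G1", "G2", "G3")
        }
        fams = proteome.build_gene_families(prots)
        curve = proteome.pan_core_curve(fams, ["G1", "G2", "G3"])
        assert curve.pan_counts == [4, 4, 4]
        assert curve.core_counts == [4, 4, 4]

    def test_unknown_genome_rejected(self, rng):
        prots = {"G1": [ProteinRecord("p", "G1", _random_protein(rng))]}
        fams = proteome.build_gene_families(prots)
        with pytest.raises(ValueError, match="unknown"):
            proteome.pan_core_curve(fams, ["G1", "GX"])

    def test_monotone_and_order_invariant_ends(self, small_sim, rng):
        gids = [g.id for g in small_sim.genomes]
        prots = {g: small_sim.proteomes[g] for g in gids}
        fams = proteome.build_gene_families(prots)
        finals = set()
        for _ in range(10):
            order = [gids[i] for i in rng.permutation(len(gids))]
            curve = proteome.pan_core_curve(fams, order)
            assert all(x >= y for x, y in zip(curve.core_counts, curve.core_counts[1:]))
            assert all(x <= y for x, y in zip(curve.pan_counts, curve.pan_counts[1:]))
            finals.add((curve.core_counts[-1], curve.pan_counts[-1]))
        assert len(finals) == 1

    def test_exclusive_focal_identical_twin_empty(self, rng):
        seqs = [_random_protein(rng, 60) for _ in range(3)]
        prots = {
            "G1": [ProteinRecord(f"G1_p{i}", "G1", s) for i, s in enumerate(seqs)],
            "G2": [ProteinRecord(f"G2_p{i}", "G2", s) for i, s in enumerate(seqs)],
        }
        fams = proteome.build_gene_families(prots)
        assert proteome.exclusive_genes(fams, "G1") == set()
        with pytest.raises(ValueError, match="unknown"):
            proteome.exclusive_genes(fams, "GX")


def test_aai_matrix_planted_clades(rng):
    base1, base2 = _random_protein(rng, 80), _random_protein(rng, 80)
    seqs = {
        "A1": [base1, base2],
        "A2": [_mutate(rng, base1, 4), _mutate(rng, base2, 4)],
        "B1": [_mutate(rng, base1, 24), _mutate(rng, base2, 24)],
        "B2": [_mutate(rng, _mutate(rng, base1, 24), 4),
               _mutate(rng, _mutate(rng, base2, 24), 4)],
    }
    prots = {
        g: [ProteinRecord(f"{g}_p{i}", g, s) for i, s in enumerate(ss)]
        for g, ss in seqs.items()
    }
    labels, aai, dist = proteome.aai_matrix_and_distance(prots)
    assert np.allclose(dist, dist.T)
    assert np.all(np.diag(dist) == 0)
    i = {lab: k for k, lab in enumerate(labels)}
    within = dist[i["A1"], i["A2"]]
    between = dist[i["A1"], i["B1"]]
    assert within < between
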