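"""BBH orthology, AAI, fragment ANI, and species clustering."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ensipipe.errors import DataError, NoOrthologsError, UnmappableError
from ensipipe.homology import (SimilarityHit, averaged_ani,
                               bidirectional_best_hits, cluster_species,
                               compute_aai, compute_one_way_ani,
                               read_hit_table, shared_specific_sets,
                               write_hit_table)
from ensipipe.simulate import FixtureSpec, gen_divergent_pair, gen_hit_tables


def hit(q, s, ident=85.0, alen=None, ev=1e-50, score=100.0, qlen=100, slen=100):
    return SimilarityHit(query_id=q, subject_id=s, percent_identity=ident,
                         alignment_length=alen if alen is not None else qlen,
                         evalue=ev, bitscore=score,
                         query_length=qlen, subject_length=slen)


def bbh_oracle(hitsAB, hitsBA, min_identity, min_coverage):
    """Brute-force reciprocal-maximum oracle, independent of the library's
    best-hit bookkeeping: scan each query's hits exhaustively."""
    def best(hits, query):
        cands = [h for h in hits if h.query_id == query]
        return min(cands, key=lambda h: (-h.bitscore, h.evalue,
                                         -h.alignment_length, h.subject_id),
                   default=None)

    pairs = set()
    for a in {h.query_id for h in hitsAB}:
        hab = best(hitsAB, a)
        if hab is None:
            continue
        hba = best(hitsBA, hab.subject_id)
        if hba is None or hba.subject_id != a:
            continue
        if all(h.percent_identity >= min_identity
               and 100.0 * h.alignment_length / h.query_length >= min_coverage
               for h in (hab, hba)):
            pairs.add((a, hab.subject_id))
    return pairs


class TestBBH:
    def test_reciprocal_pair_returned(self):
        pairs = bidirectional_best_hits([hit("a", "b")], [hit("b", "a")])
        assert [(p.idA, p.idB) for p in pairs] == [("a", "b")]

    def test_non_reciprocal_excluded(self):
        # a's best is b, but b's best is a2
        ab = [hit("a", "b", score=100)]
        ba = [hit("b", "a", score=50), hit("b", "a2", score=90)]
        assert bidirectional_best_hits(ab, ba) == []

    def test_identity_threshold_excludes(self):
        pairs = bidirectional_best_hits([hit("a", "b", ident=65)],
                                        [hit("b", "a", ident=65)], 70, 70)
        assert pairs == []

    def test_duplicate_rows_keep_highest_bitscore(self):
        ab = [hit("a", "b", score=10, ident=60), hit("a", "b", score=90, ident=95)]
        ba = [hit("b", "a", score=90, ident=95)]
        pairs = bidirectional_best_hits(ab, ba)
        assert pairs and pairs[0].identityAB == 95

    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_brute_force_oracle_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        n_a, n_b = int(rng.integers(1, 8)), int(rng.integers(1, 8))
        def random_table(qs, ss):
            rows = []
            for _ in range(int(rng.integers(0, 25))):
                rows.append(hit(f"q{int(rng.integers(n_a))}" if qs == "q" else f"s{int(rng.integers(n_b))}",
                                f"s{int(rng.integers(n_b))}" if ss == "s" else f"q{int(rng.integers(n_a))}",
                                ident=float(rng.integers(40, 101)),
                                alen=int(rng.integers(50, 101)),
                                ev=float(10.0 ** -rng.integers(5, 50)),
                                score=float(rng.integers(50, 300))))
            return rows
        ab, ba = random_table("q", "s"), random_table("s", "q")
        got = {(p.idA, p.idB) for p in bidirectional_best_hits(ab, ba, 60, 60)}
        assert got == bbh_oracle(ab, ba, 60, 60)


class TestAAI:
    def test_mean_of_pair_means(self):
        ab = [hit("a1", "b1", ident=50), hit("a2", "b2", ident=60)]
        ba = [hit("b1", "a1", ident=50), hit("b2", "a2", ident=60)]
        assert compute_aai(ab, ba) == pytest.approx(55.0)

    def test_evalue_filter_applies(self):
        ab = [hit("a1", "b1", ident=50), hit("a2", "b2", ident=90, ev=1e-6)]
        ba = [hit("b1", "a1", ident=50), hit("b2", "a2", ident=90, ev=1e-6)]
        assert compute_aai(ab, ba) == pytest.approx(50.0)

    def test_no_orthologs_is_an_error_not_zero(self):
        ab = [hit("a1", "b1", ident=20)]
        ba = [hit("b1", "a1", ident=20)]
        with pytest.raises(NoOrthologsError):
            compute_aai(ab, ba)

    def test_recovers_planted_mean_identity(self):
        spec = FixtureSpec(seed=21, n_orthologs=20, ortholog_identity=98.9,
                           ortholog_identity_spread=1.0)
        hab, hba, planted = gen_hit_tables(spec)
        planted_mean = np.mean([ident for _, _, ident in planted])
        assert compute_aai(hab, hba) == pytest.approx(planted_mean, abs=1e-9)


class TestANI:
    def test_self_ani_is_exactly_100(self):
        genome = [s for s in gen_divergent_pair(FixtureSpec(seed=22, n_scaffolds=1,
                  length_range=(20_000, 20_000), divergence=0))[0]]
        ani, n = compute_one_way_ani(genome, genome)
        assert ani == 100.0 and n == 20

    def test_recovers_planted_divergence(self):
        spec = FixtureSpec(seed=23, n_scaffolds=1, length_range=(100_000, 100_000),
                           divergence=0.02)
        a, b, planted = gen_divergent_pair(spec)
        res = averaged_ani(a, b)
        assert abs(res.averaged - 100 * planted) <= 0.5
        assert res.averaged == pytest.approx((res.one_way_ab + res.one_way_ba) / 2)

    def test_symmetry_of_averaged_ani(self):
        spec = FixtureSpec(seed=24, n_scaffolds=1, length_range=(30_000, 30_000),
                           divergence=0.03)
        a, b, _ = gen_divergent_pair(spec)
        assert averaged_ani(a, b).averaged == pytest.approx(averaged_ani(b, a).averaged)

    def test_short_query_has_no_fragments(self):
        with pytest.raises(UnmappableError):
            compute_one_way_ani(["A" * 500], ["A" * 5000], fragment_length=1000)

    def test_unrelated_genomes_unmappable(self):
        spec = FixtureSpec(seed=25, n_scaffolds=1, length_range=(5_000, 5_000),
                           divergence=1.0)
        a, b, _ = gen_divergent_pair(spec)
        with pytest.raises(UnmappableError):
            compute_one_way_ani(a, b)


def sym_matrix(values):
    """values: {(i, j): v} upper triangle; diagonal filled with 100."""
    strains = sorted({s for pair in values for s in pair})
    m = {i: {j: 100.0 for j in strains} for i in strains}
    for (i, j), v in values.items():
        m[i][j] = m[j][i] = v
    return m


class TestSpeciesClustering:
    def test_pair_above_threshold_forms_one_species(self):
        ani = sym_matrix({("A", "B"): 98.5, ("A", "C"): 80, ("B", "C"): 80})
        aai = sym_matrix({("A", "B"): 98.9, ("A", "C"): 75, ("B", "C"): 75})
        part = cluster_species(ani, aai, 96)
        assert set(part.clusters) == {frozenset({"A", "B"}), frozenset({"C"})}

    def test_all_identical_single_cluster(self):
        ani = sym_matrix({("A", "B"): 100, ("A", "C"): 100, ("B", "C"): 100})
        assert len(cluster_species(ani, None, 96).clusters) == 1

    def test_both_measures_must_pass_by_default(self):
        ani = sym_matrix({("A", "B"): 98})
        aai = sym_matrix({("A", "B"): 90})
        assert len(cluster_species(ani, aai, 96).clusters) == 2
        assert len(cluster_species(ani, aai, 96, require_both=False).clusters) == 1

    def test_asymmetric_matrix_rejected(self):
        m = sym_matrix({("A", "B"): 98})
        m["A"]["B"] = 97.0
        with pytest.raises(DataError):
            cluster_species(m, None, 96)

    @given(st.integers(min_value=0, max_value=5_000))
    def test_lowering_threshold_never_splits_clusters(self, seed):
        rng = np.random.default_rng(seed)
        strains = [f"s{i}" for i in range(5)]
        vals = {}
        for i, a in enumerate(strains):
            for b in strains[i + 1:]:
                vals[(a, b)] = float(rng.uniform(80, 100))
        m = sym_matrix(vals)
        hi = len(cluster_species(m, None, 97).clusters)
        lo = len(cluster_species(m, None, 93).clusters)
        assert lo <= hi


class TestSharedSpecificSets:
    CLUSTERS = {"f1": {"A", "B", "C"}, "f2": {"A", "B", "C", "D"}, "f3": {"A"}}

    def test_in_group_specific(self):
        assert shared_specific_sets(self.CLUSTERS, {"A", "B", "C"}, {"D"}) == {"f1"}

    def test_empty_in_group_errors(self):
        with pytest.raises(DataError):
            shared_specific_sets(self.CLUSTERS, set(), {"D"})

    def test_uncovered_strain_errors(self):
        with pytest.raises(DataError):
            shared_specific_sets(self.CLUSTERS, {"A"}, {"Z"})


class TestHitTableIO:
    def test_roundtrip_14_column(self, tmp_path):
        hits = [hit("a", "b", ident=91.5, alen=80, ev=1e-20, score=150.5,
                    qlen=90, slen=95)]
        path = tmp_path / "hits.tsv"
        write_hit_table(hits, path)
        assert read_hit_table(path) == hits

    def test_12_column_requires_length_sidecar(self, tmp_path):
        path = tmp_path / "hits12.tsv"
        path.write_text("a\tb\t90\t80\t0\t0\t0\t0\t0\t0\t1e-20\t150\n")
        with pytest.raises(DataError):
            read_hit_table(path)
        back = read_hit_table(path, lengths={"a": 90, "b": 95})
        assert back[0].query_length == 90 and back[0].subject_length == 95
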