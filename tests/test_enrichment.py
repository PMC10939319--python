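"""ID resolution, ortholog augmentation and hypergeometric over-representation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

from thermorev.enrichment import (augment_by_ortholog, categorize_evidence,
                                  hypergeom_enrich, resolve_ids, run_categorized)
from thermorev.exceptions import ValidationError
from thermorev.io import GeneSetCollection


def _mapping(rows):
    return pd.DataFrame(rows, columns=["source", "from_id", "to_id"])


class TestResolveIds:
    def test_unanimous_kept(self):
        m = _mapping([(f"s{i}", "A", "X") for i in range(3)])
        assert resolve_ids(m) == {"A": "X"}

    def test_majority_wins(self):
        m = _mapping([("s1", "A", "X"), ("s2", "A", "X"), ("s3", "A", "Y")])
        assert resolve_ids(m) == {"A": "X"}

    def test_tie_dropped(self):
        m = _mapping([("s1", "A", "X"), ("s2", "A", "Y"), ("s1", "B", "Z")])
        assert resolve_ids(m) == {"B": "Z"}

    def test_idempotent(self):
        m = _mapping([("s1", "A", "X"), ("s2", "A", "X"), ("s3", "A", "Y"),
                      ("s1", "B", "Z")])
        first = resolve_ids(m)
        again = resolve_ids(_mapping([("resolved", k, v) for k, v in first.items()]))
        assert again == first


class TestOrthologAugmentation:
    def _coll(self, mapping):
        coll = GeneSetCollection()
        for term, genes in mapping.items():
            coll.add(term, term, genes)
        return coll

    def test_empty_donor_is_identity(self):
        native = self._coll({"T1": ["g1", "g2"]})
        donor = GeneSetCollection()
        out = augment_by_ortholog(native, {"g1": "H1"}, donor)
        assert out.genes_of("T1") == {"g1", "g2"}

    def test_unannotated_gene_inherits_ortholog_terms(self):
        native = self._coll({"T1": ["g1"]})
        donor = self._coll({"T9": ["H2"]})
        out = augment_by_ortholog(native, {"g2": "H2"}, donor)
        assert out.genes_of("T9") == {"g2"}

    def test_union_property_random(self, rng):
        genes = [f"g{i}" for i in range(25)]
        humans = [f"H{i}" for i in range(25)]
        ortho = {g: h for g, h in zip(genes, humans) if rng.random() < 0.7}
        native = GeneSetCollection()
        donor = GeneSetCollection()
        for t in range(6):
            native.add(f"N{t}", f"N{t}", rng.choice(genes, 5, replace=False))
            donor.add(f"D{t}", f"D{t}", rng.choice(humans, 5, replace=False))
        out = augment_by_ortholog(native, ortho, donor)
        by_gene = out.annotations_by_gene()
        nat = native.annotations_by_gene()
        don = donor.annotations_by_gene()
        for g in genes:
            expected = set(nat.get(g, set()))
            if g in ortho:
                expected |= don.get(ortho[g], set())
            assert by_gene.get(g, set()) == expected


class TestHypergeom:
    def _annotation(self, members):
        coll = GeneSetCollection()
        coll.add("T1", "term one", members)
        return coll

    def test_fully_contained_list(self):
        universe = [f"g{i}" for i in range(20)]
        term = universe[:5]
        res = hypergeom_enrich(term, universe, self._annotation(term),
                               min_term_size=1, max_term_size=500)
        assert res.iloc[0]["p"] == pytest.approx(1 / comb(20, 5, exact=True), rel=1e-9)
        assert res.iloc[0]["fold"] == pytest.approx(4.0)

    def test_term_equal_to_universe(self):
        universe = [f"g{i}" for i in range(12)]
        res = hypergeom_enrich(universe[:4], universe, self._annotation(universe),
                               min_term_size=1, max_term_size=500)
        assert res.iloc[0]["p"] == pytest.approx(1.0)

    def test_matches_pmf_sum_oracle(self, rng):
        for _ in range(200):
            n_univ = int(rng.integers(10, 60))
            universe = [f"g{i}" for i in range(n_univ)]
            big_k = int(rng.integers(1, n_univ))
            n_list = int(rng.integers(1, n_univ))
            term = list(rng.choice(universe, big_k, replace=False))
            lst = list(rng.choice(universe, n_list, replace=False))
            res = hypergeom_enrich(lst, universe, self._annotation(term),
                                   min_term_size=0, max_term_size=10**6)
            k = len(set(term) & set(lst))
            oracle = sum(stats.hypergeom.pmf(j, n_univ, big_k, n_list)
                         for j in range(k, min(big_k, n_list) + 1))
            assert res.iloc[0]["p"] == pytest.approx(oracle, rel=1e-9, abs=1e-12)

    def test_p_monotone_decreasing_in_k(self):
        # fixed N, K, n: larger overlap is always more surprising
        ps = [float(stats.hypergeom.sf(k - 1, 50, 10, 15)) for k in range(0, 11)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_size_bounds_skip_terms(self):
        universe = [f"g{i}" for i in range(30)]
        coll = GeneSetCollection()
        coll.add("small", "s", universe[:2])
        coll.add("ok", "o", universe[:10])
        res = hypergeom_enrich(universe[:5], universe, coll,
                               min_term_size=5, max_term_size=20)
        assert list(res["term"]) == ["ok"]

    def test_list_outside_universe_rejected(self):
        with pytest.raises(ValidationError):
            hypergeom_enrich(["x"], ["a", "b"], self._annotation(["a"]))


class TestCategorized:
    def _evidence(self):
        return pd.DataFrame(
            {"deg_direction": ["up", "up", "down", "none", "none"],
             "dsg": [False, True, False, False, False],
             "corr_sign": ["+", "none", "none", "-", "none"]},
            index=[f"g{i}" for i in range(5)])

    def test_gene_can_sit_in_two_categories(self):
        cats = categorize_evidence(self._evidence())
        assert "g0" in cats["↑Exp"] and "g0" in cats["+Corr"]

    def test_results_equal_direct_call(self):
        ev = self._evidence()
        universe = list(ev.index) + [f"h{i}" for i in range(10)]
        coll = GeneSetCollection()
        coll.add("T1", "t", universe[:8])
        out = run_categorized(ev, coll, universe, min_term_size=1)
        direct = hypergeom_enrich(["g0", "g1"], universe, coll, min_term_size=1)
        pd.testing.assert_frame_equal(
            out["↑Exp"].drop(columns="category"), direct)

    def test_empty_categories_skipped(self):
        ev = self._evidence()
        ev["corr_sign"] = "none"
        ev["dsg"] = False
        coll = GeneSetCollection()
        coll.add("T1", "t", list(ev.index))
        out = run_categorized(ev, coll, list(ev.index), min_term_size=1)
        assert set(out) == {"↑Exp", "↓Exp"}
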