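import itertools

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq
from hypothesis import given
from hypothesis import strategies as st

from mlde.library import (
    IUPAC_NT,
    LibraryDesign,
    acquire,
    build_filtered_library,
    expand_degenerate_codon,
    expected_coverage,
    observed_coverage,
    scheme_22c,
    scheme_nnk,
    screening_reduction,
    theoretical_size,
)
from mlde.variants import Substitution, parse_variant


def _oracle_expansion(triplet):
    """Brute-force oracle: enumerate concrete codons and translate each
    independently with biopython's Seq.translate."""
    out = []
    for bases in itertools.product(*(IUPAC_NT[s] for s in triplet)):
        codon = "".join(bases)
        out.append((codon, str(Seq(codon).translate())))
    return out


class TestDegenerateCodons:
    def test_nnk_expansion_against_bruteforce_oracle(self):
        dc = expand_degenerate_codon("NNK")
        oracle = _oracle_expansion("NNK")
        assert sorted(dc.codons) == sorted(c for c, _ in oracle)
        assert len(dc.codons) == 32
        assert dc.residues == {aa for _, aa in oracle if aa != "*"}
        assert len(dc.residues) == 20
        assert dc.n_stops == 1  # TAG only

    def test_ndt_is_stop_free_with_12_distinct_residues(self):
        dc = expand_degenerate_codon("NDT")
        oracle = _oracle_expansion("NDT")
        assert len(dc.codons) == 12
        assert dc.n_stops == 0
        assert dc.residues == {aa for _, aa in oracle}
        assert len(dc.residues) == 12

    def test_single_codon_tgg_is_trp(self):
        dc = expand_degenerate_codon("TGG")
        assert dc.codons == ("TGG",)
        assert dc.translation == {"W": 1}

    def test_invalid_symbol_rejected_by_name(self):
        with pytest.raises(ValueError, match="'X'"):
            expand_degenerate_codon("NXT")

    @given(st.text(alphabet=sorted(IUPAC_NT), min_size=3, max_size=3))
    def test_codon_bookkeeping_property(self, triplet):
        # expansion size = product of per-position degeneracies = translation size
        dc = expand_degenerate_codon(triplet)
        degeneracy = np.prod([len(IUPAC_NT[s]) for s in triplet])
        assert len(dc.codons) == degeneracy
        assert sum(dc.translation.values()) == degeneracy


class TestScheme22c:
    def test_union_has_22_codons_20_residues_no_stops(self):
        scheme = scheme_22c()
        oracle = [entry for t in ("NDT", "VHG", "TGG") for entry in _oracle_expansion(t)]
        assert len(scheme.all_codons) == 22 == len(oracle)
        assert scheme.n_stops == 0
        assert scheme.residues == {aa for _, aa in oracle} == set("ACDEFGHIKLMNPQRSTVWY")

    def test_leucine_and_valine_encoded_twice(self):
        counts = {}
        for codon in scheme_22c().all_codons:
            aa = str(Seq(codon).translate())
            counts[aa] = counts.get(aa, 0) + 1
        assert {aa for aa, c in counts.items() if c == 2} == {"L", "V"}

    def test_ratio_tuned_residue_probabilities_are_near_uniform(self):
        probs = scheme_22c().residue_probabilities()
        assert sum(probs.values()) == pytest.approx(1.0)
        # 12:9:1 mixing makes every concrete codon equiprobable (1/22)
        assert probs["W"] == pytest.approx(1 / 22)
        assert probs["L"] == pytest.approx(2 / 22)


class TestSizesAndCoverage:
    def test_combining_all_beneficial_residues_gives_29400(self):
        assert theoretical_size([6, 14, 10, 5, 7]) == 29_400

    def test_five_site_full_randomization(self):
        assert theoretical_size([20] * 5) == 3_200_000

    def test_single_site(self):
        assert theoretical_size([1]) == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            theoretical_size([])

    @pytest.mark.parametrize(
        "unique, theoretical, expected",
        [(762, 3_200_000, 0.024), (651, 8_000, 8.1375), (0, 999, 0.0)],
    )
    def test_observed_coverage(self, unique, theoretical, expected):
        assert observed_coverage(unique, theoretical) == pytest.approx(expected, rel=1e-2)

    def test_expected_coverage_limits(self):
        p = np.full(100, 1 / 100)
        assert expected_coverage(p, 0) == 0.0
        assert expected_coverage(p, 10_000_000) == pytest.approx(100.0)

    def test_expected_coverage_matches_monte_carlo_oracle(self):
        # single NNK site, 45 transformants, against 1e5 simulated experiments
        probs = scheme_nnk().residue_probabilities()
        residues = sorted(r for r in probs if r != "*")
        p = np.array([probs[r] for r in residues])
        p_full = np.append(p, 1.0 - p.sum())  # stop codon reads
        analytic = expected_coverage(p, 45)

        rng = np.random.default_rng(12345)
        n_rep = 100_000
        draws = rng.choice(len(p_full), size=(n_rep, 45), p=p_full)
        seen = np.zeros(n_rep)
        for k in range(len(residues)):
            seen += np.any(draws == k, axis=1)
        mc = 100.0 * float(seen.mean()) / len(residues)
        assert analytic == pytest.approx(mc, abs=1.0)

    @given(transformants=st.integers(min_value=0, max_value=500))
    def test_expected_coverage_monotone_and_bounded(self, transformants):
        p = np.array([0.1, 0.05, 0.0, 0.2])
        now = expected_coverage(p, transformants)
        nxt = expected_coverage(p, transformants + 1)
        assert nxt >= now - 1e-12
        support = np.count_nonzero(p)
        assert now <= 100.0 * support / p.size + 1e-9

    def test_probabilities_above_one_rejected(self):
        with pytest.raises(ValueError):
            expected_coverage([1.2], 10)


class TestFilteredLibrary:
    WT = {174: "L", 238: "A", 241: "L", 242: "M", 245: "Q"}

    def _design(self):
        # three modulated substrate-binding sites (5 x 5 x 3 residues) with
        # two positions fixed to their evolved residues
        return LibraryDesign(
            parent_name="M2",
            modulated={174: "LMIVF", 238: "AKGRL", 241: "MQS"},
            fixed=(Substitution(242, "M", "W"), Substitution(245, "Q", "S")),
            wt_residues=self.WT,
        )

    def test_75_members_all_carrying_fixed_substitutions(self):
        members = build_filtered_library(self._design())
        assert len(members) == 75
        for m in members:
            subs = {s.position: s.mut for s in m.substitutions}
            assert subs[242] == "W" and subs[245] == "S"

    def test_names_unique_and_deterministic_order(self):
        a = build_filtered_library(self._design())
        b = build_filtered_library(self._design())
        names = [m.name for m in a]
        assert len(set(names)) == 75
        assert names == [m.name for m in b]

    def test_members_reparse_consistently_with_the_design(self):
        design = self._design()
        for m in build_filtered_library(design):
            rebuilt = parse_variant(m.name, parent="M2")
            for s in rebuilt.substitutions:
                if s.position in design.modulated:
                    assert s.mut in design.modulated[s.position]
                    assert s.wt == self.WT[s.position]
                else:
                    assert (s.position, s.wt, s.mut) in {(242, "M", "W"), (245, "Q", "S")}

    def test_parent_only_alphabet_yields_single_member(self):
        design = LibraryDesign(
            parent_name="M2",
            modulated={174: "L"},
            fixed=(Substitution(242, "M", "W"),),
            wt_residues=self.WT,
        )
        members = build_filtered_library(design)
        assert len(members) == 1
        assert members[0].name == "M242W"

    def test_fixed_modulated_conflict_rejected(self):
        with pytest.raises(ValueError, match="174"):
            LibraryDesign(
                parent_name="M2",
                modulated={174: "LM"},
                fixed=(Substitution(174, "L", "M"),),
                wt_residues=self.WT,
            )


class TestAcquisition:
    def _ranked(self, n=30):
        return pd.DataFrame(
            {"predicted_mean": np.linspace(3, 0.1, n), "rank": range(1, n + 1)},
            index=pd.Index([f"V{i:03d}" for i in range(n)], name="variant_name"),
        )

    def test_24_exploit_plus_6_explore(self):
        sel = acquire(self._ranked(), n_top=24, n_explore=6, seed=1)
        assert len(sel) == 30
        assert (sel["provenance"] == "exploit").sum() == 24
        assert (sel["provenance"] == "explore").sum() == 6
        assert list(sel.index[:24]) == [f"V{i:03d}" for i in range(24)]

    def test_pure_exploitation_is_deterministic_top_n(self):
        sel = acquire(self._ranked(), n_top=5, n_explore=0, seed=99)
        assert list(sel.index) == [f"V{i:03d}" for i in range(5)]

    def test_same_seed_same_exploratory_picks(self):
        a = acquire(self._ranked(), n_top=10, n_explore=5, seed=7)
        b = acquire(self._ranked(), n_top=10, n_explore=5, seed=7)
        assert list(a.index) == list(b.index)

    def test_insufficient_candidates_rejected(self):
        with pytest.raises(ValueError):
            acquire(self._ranked(10), n_top=8, n_explore=3, seed=0)


class TestScreeningReduction:
    @pytest.mark.parametrize(
        "reference, filtered, expected",
        [(29_400, 75, 392.0), (3_200_000, 75, 42_666.666_67), (100, 100, 1.0)],
    )
    def test_burden_factors(self, reference, filtered, expected):
        assert screening_reduction(reference, filtered) == pytest.approx(expected)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            screening_reduction(0, 75)
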