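"""Enzyme/reaction/pathway aggregation, marker profiles, amino-acid calls."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from magtx.model_io import CostTable, EnzymeGroup, PathwayDefinition, Reaction
from magtx.model_io import AMINO_ACIDS
from magtx.pathways import (
    aa_pathway_id,
    amino_acid_matrix,
    call_all_pathways,
    denitrification_profile,
    enzyme_group_rpkm,
    functional_family_profile,
    pathway_call,
    reaction_rpkm,
)

from conftest import build_expression


class TestEnzymeGroupRpkm:
    def test_complex_takes_minimum_subunit(self):
        group = EnzymeGroup("complex", ("a", "b", "c"))
        assert enzyme_group_rpkm(group, {"a": 3, "b": 8, "c": 2}) == 2

    def test_single_gene_is_its_own_value(self):
        assert enzyme_group_rpkm(EnzymeGroup("single", ("a",)),
                                 {"a": 5}) == 5

    def test_zero_subunit_propagates_zero(self):
        group = EnzymeGroup("complex", ("a", "b"))
        assert enzyme_group_rpkm(group, {"a": 0, "b": 7}) == 0

    def test_bounded_by_subunit_extremes(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            members = tuple(f"m{i}" for i in range(rng.integers(1, 6)))
            values = {m: float(rng.gamma(2, 5)) for m in members}
            for kind in ("single", "complex"):
                v = enzyme_group_rpkm(EnzymeGroup(kind, members), values)
                assert min(values.values()) <= v <= max(values.values())


class TestReactionRpkm:
    def _rxn(self, *groups):
        return Reaction("r", False, tuple(groups))

    def test_isozymes_take_maximum(self):
        rxn = self._rxn(EnzymeGroup("single", ("a",)),
                        EnzymeGroup("single", ("b",)))
        assert reaction_rpkm(rxn, {"a": 5, "b": 9}, {"a", "b"}) == 9

    def test_single_group_passthrough(self):
        rxn = self._rxn(EnzymeGroup("single", ("a",)))
        assert reaction_rpkm(rxn, {"a": 5}, {"a"}) == 5

    def test_min_then_max_composition(self):
        # complex {3, 2} -> 2; single copy -> 4; isozyme max -> 4
        rxn = self._rxn(EnzymeGroup("complex", ("a", "b")),
                        EnzymeGroup("single", ("c",)))
        values = {"a": 3, "b": 2, "c": 4}
        assert reaction_rpkm(rxn, values, set(values)) == 4

    def test_unresolvable_groups_excluded(self):
        rxn = self._rxn(EnzymeGroup("single", ("other_genome_orf",)),
                        EnzymeGroup("single", ("a",)))
        assert reaction_rpkm(rxn, {"a": 5}, {"a"}) == 5


def _pathway(reaction_values, keys=(), pid="p"):
    """Pathway with one single-gene group per reaction; member orf ids g0.."""
    reactions = tuple(
        Reaction(f"r{i}", i in keys,
                 (EnzymeGroup("single", (f"g{i}",)),))
        for i in range(len(reaction_values)))
    return PathwayDefinition(pathway_id=pid, name=pid, reactions=reactions)


class TestPathwayCall:
    def _expr(self, values):
        # one genome holding ORFs g0.. with the given RPKMs
        _, _, table = build_expression({"A": values})
        table.data["orf_id"] = [f"g{i}" for i in range(len(values))]
        return table

    def test_mean_over_reactions(self):
        expr = self._expr([9, 2, 4, 5])
        call = pathway_call(_pathway([9, 2, 4, 5]), "A", expr)
        assert call.pathway_rpkm == pytest.approx(5.0)
        assert call.present and call.completeness == 1.0

    def test_missing_key_reaction_blocks_presence(self):
        expr = self._expr([9, 2, 4])  # g0..g2 present, g3 missing
        call = pathway_call(_pathway([9, 2, 4, 5], keys=(3,)), "A", expr)
        assert call.completeness == pytest.approx(0.75)
        assert not call.key_ok and not call.present

    def test_completeness_threshold_applies(self):
        expr = self._expr([9, 2])  # 2 of 4 reactions assigned
        call = pathway_call(_pathway([9, 2, 4, 5]), "A", expr,
                            completeness_threshold=0.75)
        assert call.completeness == pytest.approx(0.5)
        assert not call.present
        call_low = pathway_call(_pathway([9, 2, 4, 5]), "A", expr,
                                completeness_threshold=0.5)
        assert call_low.present

    def test_no_assigned_reactions_undefined_rpkm(self):
        expr = self._expr([1])
        call = pathway_call(_pathway(["x"], pid="q"), "A",
                            build_expression({"B": [1, 2, 3]})[2])
        assert not call.present
        assert np.isnan(call.pathway_rpkm)

    def test_unassigned_as_zero_flag(self):
        expr = self._expr([9, 2])
        call = pathway_call(_pathway([9, 2, 4, 5]), "A", expr,
                            unassigned_as_zero=True,
                            completeness_threshold=0.5)
        assert call.pathway_rpkm == pytest.approx((9 + 2 + 0 + 0) / 4)

    def test_relativized_by_genome_median(self):
        expr = self._expr([2, 4, 6])  # median RPKM 4
        call = pathway_call(_pathway([2, 4, 6]), "A", expr)
        assert call.rel_pathway_expr == pytest.approx(call.pathway_rpkm / 4)

    def test_monotone_in_any_gene_rpkm(self):
        """Raising one gene's RPKM never lowers the pathway RPKM (min and
        max aggregation are both componentwise monotone)."""
        rng = np.random.default_rng(9)
        for _ in range(100):
            n_rxn = int(rng.integers(1, 5))
            reactions = []
            members = []
            for i in range(n_rxn):
                groups = []
                for j in range(rng.integers(1, 3)):
                    kind = "complex" if rng.random() < 0.5 else "single"
                    size = int(rng.integers(2, 4)) if kind == "complex" else 1
                    ids = tuple(f"g{i}_{j}_{k}" for k in range(size))
                    members.extend(ids)
                    groups.append(EnzymeGroup(kind, ids))
                reactions.append(Reaction(f"r{i}", False, tuple(groups)))
            pwy = PathwayDefinition("p", "p", tuple(reactions))
            values = [int(rng.integers(0, 50)) for _ in members]
            _, _, expr = build_expression({"A": values})
            expr.data["orf_id"] = members
            base = pathway_call(pwy, "A", expr).pathway_rpkm
            bump = members[rng.integers(0, len(members))]
            expr.data.loc[expr.data["orf_id"] == bump, "rpkm"] += 10
            assert pathway_call(pwy, "A", expr).pathway_rpkm >= base - 1e-12


class TestDenitrificationProfile:
    def _setup(self, markers, values):
        _, _, expr = build_expression({"A": values})
        orf_ids = [f"g{i}" for i in range(len(values))]
        expr.data["orf_id"] = orf_ids
        from magtx.model_io import GenomeBin
        bins = [GenomeBin("A", "", (("A_c1", 100_000),),
                          tuple(orf_ids))]
        ann = pd.DataFrame(
            [{"orf_id": o, "namespace": "marker", "family_code": code,
              "location": "cytoplasmic"}
             for o, code in markers.items()])
        return bins, ann, expr

    def test_zero_subunit_complex_flagged_but_present(self):
        # narGHI expressed except the membrane anchor subunit: the step is
        # present, its RPKM 0 by the min rule, and the zero subunit flagged
        bins, ann, expr = self._setup(
            {"g0": "narGHIJ", "g1": "narGHIJ", "g2": "narGHIJ"},
            [6, 8, 0])
        prof = denitrification_profile(bins, ann, expr).set_index("step")
        row = prof.loc["NO3->NO2"]
        assert row["present"] and row["zero_subunit_flag"]
        assert row["step_rpkm"] == 0
        assert np.isnan(row["log2_step_rpkm"])

    def test_only_nosz_gives_single_step(self):
        bins, ann, expr = self._setup({"g0": "nosZ"}, [4])
        prof = denitrification_profile(bins, ann, expr).set_index("step")
        assert prof.loc["N2O->N2", "present"]
        assert not prof.drop("N2O->N2")["present"].any()
        assert prof.loc["N2O->N2", "log2_step_rpkm"] == pytest.approx(2.0)

    def test_nir_isozymes_take_maximum(self):
        bins, ann, expr = self._setup({"g0": "nirK", "g1": "nirS"}, [4, 6])
        prof = denitrification_profile(bins, ann, expr).set_index("step")
        assert prof.loc["NO2->NO", "step_rpkm"] == 6


class TestAminoAcidMatrix:
    @staticmethod
    def _cost(order=None):
        order = order or AMINO_ACIDS
        return CostTable(ranks={aa: i + 1 for i, aa in enumerate(order)})

    @staticmethod
    def _calls(bin_id, biosynthesis, degradation):
        rows = []
        for aa in AMINO_ACIDS:
            for direction, present_set in (("biosynthesis", biosynthesis),
                                           ("degradation", degradation)):
                rows.append({
                    "bin_id": bin_id,
                    "pathway_id": aa_pathway_id(aa, direction),
                    "present": aa in present_set,
                    "rel_pathway_expr": 1.5 if aa in present_set
                    else float("nan"),
                })
        return pd.DataFrame(rows)

    def test_missing_biosynthesis_is_auxotrophy(self):
        calls = self._calls("A", set(AMINO_ACIDS) - {"Val"},
                            set(AMINO_ACIDS))
        matrix, _ = amino_acid_matrix(calls, self._cost(), seed=1,
                                      n_permutations=50)
        aux = matrix[(matrix["amino_acid"] == "Val")
                     & (matrix["direction"] == "biosynthesis")]
        assert bool(aux["auxotroph"].iloc[0])
        others = matrix[(matrix["amino_acid"] != "Val")]
        assert not others["auxotroph"].any()

    def test_all_pathways_present_no_auxotrophy(self):
        calls = self._calls("A", set(AMINO_ACIDS), set(AMINO_ACIDS))
        matrix, _ = amino_acid_matrix(calls, self._cost(), seed=1,
                                      n_permutations=50)
        assert not matrix["auxotroph"].any()

    def test_degrading_cheapest_ten_is_significant(self):
        cost = self._cost()
        cheapest = {aa for aa in AMINO_ACIDS if cost.rank(aa) > 10}
        calls = self._calls("A", set(AMINO_ACIDS), cheapest)
        _, stats = amino_acid_matrix(calls, cost, n_permutations=10_000,
                                     seed=4)
        assert stats.loc[0, "n_degraded"] == 10
        assert stats.loc[0, "p_value"] < 0.05

    def test_permutation_statistic_deterministic_under_seed(self):
        calls = self._calls("A", set(AMINO_ACIDS), set(AMINO_ACIDS[:7]))
        _, s1 = amino_acid_matrix(calls, self._cost(), seed=42,
                                  n_permutations=2000)
        _, s2 = amino_acid_matrix(calls, self._cost(), seed=42,
                                  n_permutations=2000)
        pd.testing.assert_frame_equal(s1, s2)

    def test_degrading_everything_has_undefined_p(self):
        calls = self._calls("A", set(AMINO_ACIDS), set(AMINO_ACIDS))
        _, stats = amino_acid_matrix(calls, self._cost(), seed=1,
                                     n_permutations=50)
        assert np.isnan(stats.loc[0, "p_value"])


class TestFunctionalFamilyProfile:
    def _setup(self):
        from magtx.model_io import GenomeBin
        values = [2, 4, 6, 1, 3]
        _, _, expr = build_expression({"A": values})
        orf_ids = list(expr.data["orf_id"])
        bins = [GenomeBin("A", "", (("A_c1", 100_000),), tuple(orf_ids))]
        return bins, orf_ids, expr

    def test_count_and_mean_per_family_location(self):
        bins, orf_ids, expr = self._setup()
        # rel_expr for rpkm [2,4,6,...] with median 3: [2/3, 4/3, 2, ...]
        ann = pd.DataFrame([
            {"orf_id": orf_ids[i], "namespace": "peptidase",
             "family_code": "S08A", "location": "extracellular"}
            for i in range(3)])
        prof = functional_family_profile(bins, ann, expr)
        assert len(prof) == 1
        row = prof.iloc[0]
        assert row["n_orfs"] == 3
        expected = np.mean([expr.orf_rel_expr()[o] for o in orf_ids[:3]])
        assert row["mean_rel_expr"] == pytest.approx(expected)

    def test_absent_families_give_no_rows(self):
        bins, orf_ids, expr = self._setup()
        ann = pd.DataFrame([{"orf_id": "not_in_genome",
                             "namespace": "peptidase",
                             "family_code": "S08A",
                             "location": "extracellular"}])
        assert functional_family_profile(bins, ann, expr).empty

    def test_counts_conserved_over_random_annotations(self):
        bins, orf_ids, expr = self._setup()
        rng = np.random.default_rng(12)
        rows = []
        for o in orf_ids:
            for _ in range(rng.integers(0, 3)):
                rows.append({
                    "orf_id": o,
                    "namespace": str(rng.choice(
                        ["peptidase", "glycoside_hydrolase", "transporter"])),
                    "family_code": str(rng.choice(["F1", "F2", "F3"])),
                    "location": str(rng.choice(
                        ["extracellular", "periplasm", "cytoplasmic"])),
                })
        ann = pd.DataFrame(rows)
        prof = functional_family_profile(bins, ann, expr)
        for ns in ann["namespace"].unique():
            assert (prof.loc[prof["namespace"] == ns, "n_orfs"].sum()
                    == (ann["namespace"] == ns).sum())
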