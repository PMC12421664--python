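import numpy as np
import pytest

from ledkit import (
    HARTREE_TO_KCAL,
    ComponentSet,
    FragmentInfo,
    LEDRecord,
    assemble_fp_nbody,
    assemble_standard_nbody,
    assemble_twobody,
    cooperativity,
    generate_ground_truth,
    grand_total,
    interaction_energy,
)
from ledkit.errors import AlignmentError, CompletenessError, PartitionError
from ledkit.inputgen import SubsystemSpec


def _frag(label, x=0.0):
    return FragmentInfo(label=label, elements=["He"], coords=np.array([[x, 0.0, 0.0]]))


def _simple_record(labels, intra, pairs, total=None):
    rec = LEDRecord(fragments=[_frag(l, x=float(l)) for l in labels])
    for l, (ref, corr) in intra.items():
        rec.intra[l] = {"ref": ref, "corr": corr}
    for p, comps in pairs.items():
        rec.pairwise[frozenset(p)] = ComponentSet(**comps)
    rec.recompute_totals()
    if total is not None:
        rec.total_energy = total
    return rec


EPS0 = {"elstat": 0.0, "exch": 0.0, "no_disp": 0.0, "disp": 0.0}


class TestInteractionEnergy:
    def test_null_interaction(self):
        sup = _simple_record([1, 2], {1: (-1.0, 0.0), 2: (-2.0, 0.0)}, {(1, 2): EPS0})
        p1 = _simple_record([1], {1: (-1.0, 0.0)}, {})
        p2 = _simple_record([2], {2: (-2.0, 0.0)}, {})
        assert interaction_energy(sup, [p1, p2]) == pytest.approx(0.0, abs=1e-12)

    def test_unit_conversion(self):
        sup = _simple_record([1, 2], {1: (-100.0, 0.0), 2: (-100.05, 0.0)}, {(1, 2): EPS0})
        p1 = _simple_record([1], {1: (-100.0, 0.0)}, {})
        p2 = _simple_record([2], {2: (-100.0, 0.0)}, {})
        val = interaction_energy(sup, [p1, p2])
        assert val == pytest.approx(-0.05 * HARTREE_TO_KCAL, rel=1e-12)
        assert val == pytest.approx(-31.3755, abs=5e-5)

    def test_part_order_irrelevant(self):
        sup = _simple_record([1, 2], {1: (-1.1, 0.0), 2: (-2.2, 0.0)}, {(1, 2): EPS0})
        p1 = _simple_record([1], {1: (-1.0, 0.0)}, {})
        p2 = _simple_record([2], {2: (-2.0, 0.0)}, {})
        assert interaction_energy(sup, [p1, p2]) == interaction_energy(sup, [p2, p1])

    def test_overlapping_parts_rejected(self):
        sup = _simple_record([1, 2], {1: (-1.0, 0.0), 2: (-2.0, 0.0)}, {(1, 2): EPS0})
        p1 = _simple_record([1, 2], {1: (-1.0, 0.0), 2: (-2.0, 0.0)}, {(1, 2): EPS0})
        p2 = _simple_record([2], {2: (-2.0, 0.0)}, {})
        with pytest.raises(PartitionError):
            interaction_energy(sup, [p1, p2])


class TestStandardNBody:
    def test_null_system_all_zero(self):
        """Supersystem identical to its non-interacting parts -> zero matrices."""
        subs = [SubsystemSpec("A", [1]), SubsystemSpec("B", [2])]
        sup = _simple_record([1, 2], {1: (-1.0, -0.1), 2: (-2.0, -0.2)}, {(1, 2): EPS0})
        p1 = _simple_record([1], {1: (-1.0, -0.1)}, {})
        p2 = _simple_record([2], {2: (-2.0, -0.2)}, {})
        ms = assemble_standard_nbody(sup, [p1, p2], subs)
        for name, mat in ms.components.items():
            np.testing.assert_allclose(mat, 0.0, atol=1e-12)

    def test_two_single_fragment_subsystems_layout_and_conservation(self):
        subs = [SubsystemSpec("A", [1]), SubsystemSpec("B", [2])]
        eps = {"elstat": -0.010, "exch": -0.002, "no_disp": -0.001, "disp": -0.003}
        sup = _simple_record([1, 2], {1: (-1.01, -0.11), 2: (-2.02, -0.22)}, {(1, 2): eps})
        p1 = _simple_record([1], {1: (-1.0, -0.1)}, {})
        p2 = _simple_record([2], {2: (-2.0, -0.2)}, {})
        ms = assemble_standard_nbody(sup, [p1, p2], subs)
        assert ms.components["elprep"][0, 0] == pytest.approx(-0.02 * HARTREE_TO_KCAL)
        assert ms.components["elprep"][1, 1] == pytest.approx(-0.04 * HARTREE_TO_KCAL)
        assert ms.components["elprep"][0, 1] == 0.0  # standard layout: diagonal-only
        assert ms.components["total"][0, 1] == pytest.approx(-0.016 * HARTREE_TO_KCAL)
        assert grand_total(ms) == pytest.approx(interaction_energy(sup, [p1, p2]), abs=1e-9)

    def test_dna_like_2x3_differential_cells_only_same_strand(self):
        gt = generate_ground_truth(2, (3, 3), seed=4)
        recs = gt.records("main", "uncorrected")
        ms = assemble_standard_nbody(recs["super"], list(recs["subsystems"].values()), gt.subsystems)
        t = gt.plants["main"]
        for (x, y), comps in t["epsN"].items():
            i, j = x - 1, y - 1
            same = (x <= 3) == (y <= 3)
            expected = comps["elstat"] - (t["epsSub"]["uncorrected"][(x, y)]["elstat"] if same else 0.0)
            assert ms.components["elstat"][i, j] == pytest.approx(expected * HARTREE_TO_KCAL, abs=1e-9)
        # 3 same-strand pairs per strand carry differential terms
        same_pairs = [(x, y) for (x, y) in t["epsSub"]["uncorrected"]]
        assert len(same_pairs) == 6

    def test_component_closure(self):
        gt = generate_ground_truth(2, (2, 2), seed=8, solvation=True)
        recs = gt.records("main", "corrected")
        ms = assemble_standard_nbody(recs["super"], list(recs["subsystems"].values()), gt.subsystems)
        closure = (
            ms.components["elprep"]
            + ms.components["elstat"]
            + ms.components["exch"]
            + ms.components["no_disp"]
            + ms.components["disp"]
            + ms.components["solv"]
        )
        np.testing.assert_allclose(closure, ms.components["total"], atol=1e-9)


class TestFpNBody:
    def _std(self, elprep_diag, eps_value=-1.0):
        f = len(elprep_diag)
        subs = [SubsystemSpec(chr(65 + i), [i + 1]) for i in range(f)]
        sup_intra = {i + 1: (-1.0 + elprep_diag[i] / HARTREE_TO_KCAL, 0.0) for i in range(f)}
        pairs = {
            (i + 1, j + 1): {**EPS0, "elstat": eps_value / HARTREE_TO_KCAL}
            for i in range(f)
            for j in range(i + 1, f)
        }
        sup = _simple_record(list(range(1, f + 1)), sup_intra, pairs)
        parts = [_simple_record([i + 1], {i + 1: (-1.0, 0.0)}, {}) for i in range(f)]
        return assemble_standard_nbody(sup, parts, subs)

    def test_two_fragment_forced_by_conservation(self):
        std = self._std([3.0, 5.0])
        for scheme in ("equal", "prop_eps"):
            fp = assemble_fp_nbody(std, partitioner=scheme)
            assert fp.components["elprep"][0, 1] == pytest.approx(8.0, abs=1e-9)
            assert fp.components["elprep"][0, 0] == 0.0

    def test_equal_split_three_fragments(self):
        fp = assemble_fp_nbody(self._std([3.0, 3.0, 3.0]), partitioner="equal")
        off = fp.components["elprep"][np.triu_indices(3, 1)]
        np.testing.assert_allclose(off, 3.0, atol=1e-9)

    def test_prop_eps_zero_partner_and_conservation(self):
        std = self._std([4.0, 2.0, 6.0])
        # zero out one pair's eps so it attracts no proportional share
        for name in ("elstat", "total"):
            std.components[name][0, 1] = std.components[name][1, 0] = 0.0
        fp = assemble_fp_nbody(std, partitioner="prop_eps")
        diag_sum = np.trace(std.components["elprep"])
        pair_sum = float(np.sum(fp.components["elprep"][np.triu_indices(3, 1)]))
        assert pair_sum == pytest.approx(diag_sum, abs=1e-9)

    def test_eps_components_identical_between_layouts(self):
        gt = generate_ground_truth(2, (2, 3), seed=3)
        recs = gt.records("main", "uncorrected")
        std = assemble_standard_nbody(recs["super"], list(recs["subsystems"].values()), gt.subsystems)
        fp = assemble_fp_nbody(std)
        for name in ("elstat", "exch", "no_disp", "disp"):
            np.testing.assert_allclose(fp.components[name], std.components[name], atol=1e-12)


class TestTwoBody:
    def test_two_single_fragment_subsystems_equal_nbody(self):
        """For two-fragment systems N-body and two-body are functionally identical."""
        gt = generate_ground_truth(2, (1, 1), seed=6)
        recs = gt.records("main", "uncorrected")
        subs = gt.subsystems
        nb = assemble_standard_nbody(recs["super"], list(recs["subsystems"].values()), subs)
        tb = assemble_twobody(
            [recs["super"]], list(recs["subsystems"].values()), subs, bsse=False, layout="standard"
        )
        for name in nb.components:
            np.testing.assert_allclose(tb.components[name], nb.components[name], atol=1e-9)
        coop = cooperativity(nb, tb)
        np.testing.assert_allclose(np.nan_to_num(coop.components["total"]), 0.0, atol=1e-9)

    def test_2x3_mask_counts(self):
        gt = generate_ground_truth(2, (3, 3), seed=1)
        recs = gt.records("main", "uncorrected")
        tb = assemble_twobody(
            list(recs["pairs"].values()), list(recs["monomers"].values()), gt.subsystems, bsse=False, layout="fp"
        )
        iu = np.triu_indices(6, 1)
        populated = int((~tb.absent_mask[iu]).sum())
        absent_offdiag = int(tb.absent_mask[iu].sum())
        assert populated == 9
        assert absent_offdiag == 6
        assert np.isnan(tb.components["total"][0, 1])  # same-subsystem cell empty, not zero

    def test_empty_pair_list_raises(self):
        gt = generate_ground_truth(2, (1, 1), seed=0)
        with pytest.raises(CompletenessError):
            assemble_twobody([], [], gt.subsystems, bsse=False)

    def test_missing_pair_named_in_error(self):
        gt = generate_ground_truth(2, (2, 1), seed=0)
        recs = gt.records("main", "uncorrected")
        pairs = [r for k, r in recs["pairs"].items() if k != frozenset({1, 3})]
        with pytest.raises(CompletenessError, match=r"\(1, 3\)"):
            assemble_twobody(pairs, list(recs["monomers"].values()), gt.subsystems, bsse=False)


class TestCooperativity:
    def test_self_subtraction_zero(self):
        gt = generate_ground_truth(2, (2, 2), seed=9)
        recs = gt.records("main", "uncorrected")
        nb = assemble_standard_nbody(recs["super"], list(recs["subsystems"].values()), gt.subsystems)
        coop = cooperativity(nb, nb)
        np.testing.assert_allclose(np.nan_to_num(coop.components["total"]), 0.0, atol=1e-12)

    def test_absent_twobody_cell_passes_nbody_value_flagged(self):
        gt = generate_ground_truth(2, (2, 2), seed=10)
        recs = gt.records("main", "uncorrected")
        nb_std = assemble_standard_nbody(recs["super"], list(recs["subsystems"].values()), gt.subsystems)
        nb = assemble_fp_nbody(nb_std)
        tb = assemble_twobody(
            list(recs["pairs"].values()), list(recs["monomers"].values()), gt.subsystems, bsse=False, layout="fp"
        )
        coop = cooperativity(nb, tb)
        # (1,2) is intra-subsystem: absent in two-body, fully cooperative
        assert coop.fully_coop_mask[0, 1]
        assert coop.components["total"][0, 1] == pytest.approx(nb.components["total"][0, 1], abs=1e-12)
        # spanning cells are plain differences
        assert coop.components["total"][0, 2] == pytest.approx(
            nb.components["total"][0, 2] - tb.components["total"][0, 2], abs=1e-9
        )

    def test_label_mismatch_raises(self):
        gt_a = generate_ground_truth(2, (1, 1), seed=1)
        gt_b = generate_ground_truth(2, (2, 1), seed=1)
        ra = gt_a.records("main", "uncorrected")
        rb = gt_b.records("main", "uncorrected")
        nb_a = assemble_standard_nbody(ra["super"], list(ra["subsystems"].values()), gt_a.subsystems)
        nb_b = assemble_standard_nbody(rb["super"], list(rb["subsystems"].values()), gt_b.subsystems)
        with pytest.raises(AlignmentError):
            cooperativity(nb_a, nb_b)


class TestHFLDMode:
    def test_filtered_records_give_zero_no_disp_and_ref_only_elprep(self):
        from ledkit import exclude_redundant_hfld

        gt = generate_ground_truth(2, (2, 1), seed=12)
        recs = gt.records("main", "uncorrected")
        for rec in [recs["super"], *recs["subsystems"].values()]:
            rec.method = "HFLD"
        sup = exclude_redundant_hfld(recs["super"])
        parts = [exclude_redundant_hfld(r) for r in recs["subsystems"].values()]
        ms = assemble_standard_nbody(sup, parts, gt.subsystems)
        np.testing.assert_allclose(ms.components["no_disp"], 0.0, atol=1e-12)
        np.testing.assert_allclose(ms.components["elprep_corr"], 0.0, atol=1e-12)
        np.testing.assert_allclose(
            np.diag(ms.components["elprep"]), np.diag(ms.components["elprep_ref"]), atol=1e-12
        )
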