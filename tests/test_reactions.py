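"""Reaction engine and the measured AtITPK4 substrate/product table."""

import pytest

from insptools.algebra import PhosphoInositol, enantiomer, parse_name
from insptools.reactions import (
    Direction,
    EnzymeProfile,
    ITPK4_PROFILE,
    ReactionSpec,
    infer_transfer_position,
    phosphorylate,
    reverse_transfer,
    table1_dataframe,
    table1_fixture,
)


def ins(*positions):
    return PhosphoInositol(frozenset(positions))


class TestPhosphorylate:
    @pytest.mark.parametrize(
        "substrate, position, product",
        [
            ({1, 4, 6}, 3, {1, 3, 4, 6}),
            ({3, 4, 5}, 6, {3, 4, 5, 6}),
            ({1, 4, 5, 6}, 3, {1, 3, 4, 5, 6}),
            ({1, 4}, 3, {1, 3, 4}),
        ],
    )
    def test_measured_products(self, substrate, position, product):
        rec = phosphorylate(ins(*substrate), position)
        assert rec.product.phosphates == frozenset(product)

    def test_occupied_position_rejected(self):
        with pytest.raises(ValueError):
            phosphorylate(ins(1, 4, 6), 4)

    def test_position_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            phosphorylate(ins(1, 4, 6), 7)

    def test_nucleotide_ledger(self):
        rec = phosphorylate(ins(1, 4), 3)
        assert (rec.atp_delta, rec.adp_delta) == (-1, 1)
        assert rec.phosphate_balance == 0

    def test_enzyme_without_kinase_activity_refuses(self):
        dead = EnzymeProfile("dead", hydroxy_kinase=False)
        with pytest.raises(ValueError):
            phosphorylate(ins(1, 4), 3, profile=dead)

    def test_enantiomer_equivariance_over_all_states(self, all_states):
        for s in all_states:
            for p in sorted(s.free_hydroxyls):
                lhs = phosphorylate(enantiomer(s), {1: 3, 2: 2, 3: 1, 4: 6, 5: 5, 6: 4}[p]).product
                rhs = enantiomer(phosphorylate(s, p).product)
                assert lhs == rhs


class TestInferTransferPosition:
    @pytest.mark.parametrize(
        "substrate, product, position",
        [
            ({1, 4}, {1, 3, 4}, 3),
            ({3, 4, 6}, {1, 3, 4, 6}, 1),
            ({1, 4, 6}, {1, 3, 4, 6}, 3),
        ],
    )
    def test_identified_products(self, substrate, product, position):
        assert infer_transfer_position(ins(*substrate), ins(*product)) == position

    def test_no_transfer_rejected(self):
        with pytest.raises(ValueError):
            infer_transfer_position(ins(1, 4, 6), ins(1, 4, 6))

    def test_double_addition_rejected(self):
        with pytest.raises(ValueError):
            infer_transfer_position(ins(1), ins(1, 3, 4))


class TestReverseTransfer:
    def test_racemic_pair_flagged(self):
        results = reverse_transfer(ins(1, 3, 4, 6), {1, 3})
        products = {rec.product.phosphates for rec, _ in results}
        assert products == {frozenset({3, 4, 6}), frozenset({1, 4, 6})}
        for _, flags in results:
            assert flags["chromatographically_unresolvable_pair"]
            assert "unequal amounts" in flags["note"]

    def test_single_candidate_inverse_of_forward(self):
        [(rec, flags)] = reverse_transfer(ins(1, 3, 4), {3})
        assert rec.product == ins(1, 4)
        assert flags == {}
        assert (rec.atp_delta, rec.adp_delta) == (1, -1)
        assert rec.phosphate_balance == 0

    def test_unphosphorylated_candidate_rejected(self):
        with pytest.raises(ValueError):
            reverse_transfer(ins(1, 4, 6), {2})

    def test_roundtrip_reverse_then_forward_is_identity(self, all_states):
        for s in all_states:
            for p in sorted(s.phosphates):
                [(rec, _)] = reverse_transfer(s, {p})
                assert phosphorylate(rec.product, p).product == s


class TestReactionSpec:
    def test_forward_requires_free_hydroxyl(self):
        with pytest.raises(ValueError):
            ReactionSpec(ins(1, 4), 1, Direction.FORWARD_KINASE)

    def test_reverse_requires_phosphate(self):
        with pytest.raises(ValueError):
            ReactionSpec(ins(1, 4), 3, Direction.REVERSE_TO_ADP)

    def test_reverse_from_pyrophosphate_rejected(self):
        s = PhosphoInositol(frozenset({1, 2, 3, 4, 5}), frozenset({5}))
        with pytest.raises(ValueError):
            ReactionSpec(s, 5, Direction.REVERSE_TO_ADP)

    def test_nucleotide_side_labels(self):
        fwd = ReactionSpec(ins(1, 4), 3, Direction.FORWARD_KINASE)
        rev = ReactionSpec(ins(1, 4), 4, Direction.REVERSE_TO_ADP)
        assert fwd.nucleotide_side == "ATP->ADP"
        assert rev.nucleotide_side == "ADP->ATP"


class TestTable1:
    @pytest.fixture
    def rows(self):
        return table1_fixture()

    def test_row_counts(self, rows):
        kinase = [r for r in rows if r.section == "kinase"]
        transfer = [r for r in rows if r.section == "phosphotransfer"]
        assert len(kinase) == 23
        assert len(transfer) == 4

    def test_insp5_block_all_inactive(self, rows):
        insp5 = [
            r
            for r in rows
            if r.section == "kinase" and r.substrate.n_phosphate_positions == 5
        ]
        assert len(insp5) == 6
        assert all(not r.grade.any_activity for r in insp5)
        assert all(not r.products for r in insp5)

    def test_graded_examples(self, rows):
        by_name = {(r.section, r.substrate_name): r for r in rows}
        r = by_name[("kinase", "Ins(1,3,4)P3")]
        assert r.product_name == "Ins(1,3,4,5)P4"
        assert (r.grade.regeneration, r.grade.standard) == ("+", "*")
        r = by_name[("kinase", "Ins(4,5,6)P3")]
        assert not r.products
        r = by_name[("kinase", "Ins(1,4,6)P3")]
        assert (r.grade.regeneration, r.grade.standard) == ("+++", "***")

    def test_every_verified_kinase_product_is_consistent(self, rows):
        for r in rows:
            if r.section != "kinase" or not r.products or not r.verified:
                continue
            (product,) = r.products
            pos = infer_transfer_position(r.substrate, product)
            assert phosphorylate(r.substrate, pos).product == product

    def test_enantiomeric_substrates_share_the_meso_product(self, rows):
        by_name = {r.substrate_name: r for r in rows if r.section == "kinase"}
        p1 = by_name["Ins(1,4,6)P3"].products[0]
        p2 = by_name["Ins(3,4,6)P3"].products[0]
        assert p1 == p2 == ins(1, 3, 4, 6)
        assert enantiomer(p1) == p1  # meso
        # 3-kinase on one enantiomer, 1-kinase on the other
        assert infer_transfer_position(parse_name("Ins(1,4,6)P3"), p1) == 3
        assert infer_transfer_position(parse_name("Ins(3,4,6)P3"), p2) == 1

    def test_reverse_row_carries_the_unresolvable_pair(self, rows):
        r = next(
            r
            for r in rows
            if r.section == "phosphotransfer" and r.substrate_name == "Ins(1,3,4,6)P4"
        )
        assert r.verified
        assert set(r.products) == {ins(1, 4, 6), ins(3, 4, 6)}

    def test_not_verified_rows_flagged(self, rows):
        unverified = [r for r in rows if not r.verified]
        assert {r.substrate_name for r in unverified} == {
            "Ins(1,3,4)P3",
            "Ins(1,4,6)P3",
            "Ins(1,4,5,6)P4",
        }
        assert all(r.section == "phosphotransfer" for r in unverified)

    def test_dataframe_mirrors_fixture(self, rows):
        df = table1_dataframe()
        assert len(df) == len(rows)
        assert list(df.columns) == [
            "section",
            "substrate",
            "product",
            "regeneration",
            "standard",
            "verified",
        ]
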