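"""Network generator: species inventory, reaction families, invariants."""

import numpy as np
import pytest

from bipfold import (
    ConfigurationError,
    CoopPolicy,
    Form,
    ModelSpec,
    ParameterSet,
    Tag,
    build_network,
)
from bipfold.network import (
    BIP,
    SCJ1,
    aggregate,
    bound_state,
    misfolded,
    slide_state,
    unfolded,
)
from bipfold.sbml import network_stoichiometry

# Hand enumeration of the single-site model (done independently, before the
# generator was written):
#   species: Pore, Sec63, PoreSec63, N, BiP, Scj1, F, I               ( 8)
#            slide + bound pore complexes                             ( 2)
#            U/M x BiP occupancy {0,1} x Scj1 {no,yes}                (16)
#            A2/A3/A4 x BiP {0,1} x Scj1 {no,yes}                     (12)
#            counters excluded                                        -> 30
#   reactions: translocation 4, triage 15, aggregation 7,
#              disaggregation 15, sequestration 12                    -> 53
K1_SPECIES, K1_REACTIONS = 30, 53
K1_FAMILY_COUNTS = {
    Tag.TRANSLOCATION: 4,
    Tag.TRIAGE: 15,
    Tag.AGGREGATION: 7,
    Tag.DISAGGREGATION: 15,
    Tag.SEQUESTRATION: 12,
}


class TestInventory:
    def test_k1_matches_hand_enumeration(self, network_k1):
        assert network_k1.n_species == K1_SPECIES
        assert network_k1.n_reactions == K1_REACTIONS
        by_tag = {}
        for rxn in network_k1.reactions:
            by_tag[rxn.tag] = by_tag.get(rxn.tag, 0) + 1
        assert by_tag == K1_FAMILY_COUNTS

    def test_largest_model_printed_counts(self, network_k4):
        assert network_k4.n_species == 60
        assert network_k4.n_reactions == 125

    def test_counts_monotone_in_k(self, networks):
        sizes = [(networks[k].n_species, networks[k].n_reactions)
                 for k in (1, 2, 3, 4)]
        assert sizes == sorted(sizes)

    def test_species_registered_exactly_once(self, networks):
        for net in networks.values():
            assert len(set(net.species)) == len(net.species)
            used = set()
            for rxn in net.reactions:
                used.update(sp for sp, _ in rxn.reactants)
                used.update(sp for sp, _ in rxn.products)
            assert used == set(net.species)

    def test_no_duplicate_reactions(self, networks):
        for net in networks.values():
            keys = [r.key for r in net.reactions]
            assert len(set(keys)) == len(keys)

    def test_deterministic_build(self):
        a = build_network(ModelSpec(k=3))
        b = build_network(ModelSpec(k=3))
        assert a.species == b.species
        assert a.reactions == b.reactions


class TestValidation:
    @pytest.mark.parametrize("k", [0, 5, -1])
    def test_invalid_k_rejected(self, k):
        with pytest.raises(ConfigurationError, match="k"):
            build_network(ModelSpec(k=k))

    def test_c_below_one_rejected(self):
        with pytest.raises(ConfigurationError, match="C"):
            build_network(ModelSpec(k=2, C=0.5))

    def test_nonpositive_rate_names_field(self):
        with pytest.raises(ConfigurationError, match="k_fold"):
            build_network(ModelSpec(k=2, params=ParameterSet(k_fold=-1.0)))


class TestCooperativity:
    def test_c1_identity(self, networks):
        for k in (1, 2, 3, 4):
            coop = build_network(ModelSpec(k=k, C=10.0))
            base = networks[k]
            assert coop.species == base.species
            assert len(coop.reactions) == len(base.reactions)
            for rc, rb in zip(coop.reactions, base.reactions):
                assert rc.key == rb.key
                factor = rc.rate_constant / rb.rate_constant
                if rc.coop_scaled:
                    assert factor == pytest.approx(10.0)
                else:
                    assert rc.rate_constant == rb.rate_constant

    def test_c_scaling_is_exactly_multiplicative(self):
        base = build_network(ModelSpec(k=4, C=1.0))
        coop = build_network(ModelSpec(k=4, C=7.0))
        for rb, rc in zip(base.reactions, coop.reactions):
            expected = rb.rate_constant * (7.0 if rb.coop_scaled else 1.0)
            assert rc.rate_constant == expected

    def test_model1_has_no_coop_scaled_reactions(self, network_k1):
        assert not any(r.coop_scaled for r in network_k1.reactions)

    def test_coop_applies_only_to_multibip_complexes(self, network_k4):
        for rxn in network_k4.reactions:
            if rxn.coop_scaled:
                (sp, _), = rxn.reactants
                assert sp.n_bip >= 2
                assert rxn.tag in (Tag.TRIAGE, Tag.DISAGGREGATION)

    def test_two_bip_assisted_folding_scales_by_c(self):
        coop = build_network(ModelSpec(k=2, C=10.0))
        base = build_network(ModelSpec(k=2, C=1.0))
        target = unfolded(2)
        for rb, rc in zip(base.reactions, coop.reactions):
            if rb.tag is Tag.TRIAGE and rb.reactants == ((target, 1),):
                if any(sp.form is Form.FOLDED for sp, _ in rb.products):
                    assert rc.rate_constant == pytest.approx(
                        10.0 * rb.rate_constant
                    )
                    break
        else:
            pytest.fail("no assisted folding reaction for 2-BiP complex")

    def test_per_extra_bip_policy(self):
        spec = ModelSpec(k=4, C=3.0, coop_policy=CoopPolicy.PER_EXTRA_BIP)
        net = build_network(spec)
        base = build_network(ModelSpec(k=4, C=1.0))
        for rb, rc in zip(base.reactions, net.reactions):
            if rb.coop_scaled:
                (sp, _), = rb.reactants
                assert rc.rate_constant == pytest.approx(
                    rb.rate_constant * 3.0 ** (sp.n_bip - 1)
                )


class TestTranslocation:
    def test_k1_single_slide_and_bind(self, network_k1):
        slide_states = [s for s in network_k1.species
                        if s.form is Form.PORE_COMPLEX
                        and s.n_bip == s.slide_pos - 1]
        binds = [r for r in network_k1.reactions
                 if r.tag is Tag.TRANSLOCATION
                 and any(sp is BIP for sp, _ in r.reactants)]
        assert len(slide_states) == 1
        assert len(binds) == 1

    def test_k4_release_carries_four_bips(self, network_k4):
        release = [
            r for r in network_k4.reactions
            if r.tag is Tag.TRANSLOCATION
            and any(sp.form is Form.UNFOLDED for sp, _ in r.products)
        ]
        assert len(release) == 1
        released = next(sp for sp, _ in release[0].products
                        if sp.form is Form.UNFOLDED)
        assert released.n_bip == 4

    def test_slides_have_no_reverse_partner(self, networks):
        for net in networks.values():
            keys = {r.key for r in net.reactions}
            for rxn in net.reactions:
                if rxn.tag is not Tag.TRANSLOCATION:
                    continue
                has_bip_reactant_complex = any(
                    sp.form is Form.PORE_COMPLEX and sp.n_bip > 0
                    for sp, _ in rxn.reactants
                )
                if has_bip_reactant_complex and len(rxn.reactants) == 1:
                    reverse = (rxn.products, rxn.reactants, rxn.tag)
                    assert reverse not in keys


class TestTriage:
    def test_no_chaperone_free_unfolding(self, networks):
        for net in networks.values():
            for rxn in net.reactions:
                produces_u = any(
                    sp.form is Form.UNFOLDED for sp, _ in rxn.products
                )
                from_m = any(
                    sp.form is Form.MISFOLDED for sp, _ in rxn.reactants
                )
                if from_m and produces_u:
                    (sp, _), = rxn.reactants
                    assert sp.n_bip >= 1

    def test_protected_u_cannot_misfold_or_aggregate(self, network_k4):
        for rxn in network_k4.reactions:
            reactant_u = [sp for sp, _ in rxn.reactants
                          if sp.form is Form.UNFOLDED and sp.n_bip >= 1]
            if not reactant_u:
                continue
            assert not any(
                sp.form in (Form.MISFOLDED, Form.AGGREGATE)
                for sp, _ in rxn.products
            )

    def test_scj1_assisted_association_is_faster(self, network_k1, default_params):
        plain = assisted = None
        for rxn in network_k1.reactions:
            if rxn.tag is not Tag.TRIAGE:
                continue
            if not any(sp is BIP for sp, _ in rxn.reactants):
                continue
            partner = next(sp for sp, _ in rxn.reactants if sp is not BIP)
            if partner.form is Form.UNFOLDED and partner.n_bip == 0:
                if partner.scj1_bound:
                    assisted = rxn.rate_constant
                else:
                    plain = rxn.rate_constant
        assert assisted == pytest.approx(plain * default_params.scj1_assist)

    def test_folding_releases_all_chaperones(self, network_k4):
        for rxn in network_k4.reactions:
            if not any(sp.form is Form.FOLDED for sp, _ in rxn.products):
                continue
            (reactant, _), = rxn.reactants
            released_bip = sum(
                n for sp, n in rxn.products if sp is BIP
            )
            released_scj1 = sum(
                n for sp, n in rxn.products if sp is SCJ1
            )
            assert released_bip == reactant.n_bip
            assert released_scj1 == int(reactant.scj1_bound)


class TestAggregation:
    def test_nucleation_is_one_tenth_of_growth(self, network_k1, default_params):
        nuc = [r for r in network_k1.reactions if r.tag is Tag.AGGREGATION
               and all(sp.form is not Form.AGGREGATE for sp, _ in r.reactants)]
        growth = [r for r in network_k1.reactions if r.tag is Tag.AGGREGATION
                  and any(sp.form is Form.AGGREGATE for sp, _ in r.reactants)]
        assert {r.rate_constant for r in nuc} == {0.1 * default_params.k_agg}
        assert {r.rate_constant for r in growth} == {default_params.k_agg}
        assert len(nuc) == 3 and len(growth) == 4

    def test_no_aggregate_beyond_four(self, networks):
        for net in networks.values():
            for rxn in net.reactions:
                for sp, _ in rxn.products:
                    assert sp.agg_size <= 4

    def test_only_chaperone_free_species_aggregate(self, network_k4):
        for rxn in network_k4.reactions:
            if rxn.tag is not Tag.AGGREGATION:
                continue
            for sp, _ in rxn.reactants:
                assert sp.n_bip == 0 and not sp.scj1_bound

    def test_no_spontaneous_shrinkage(self, networks):
        # any reaction reducing aggregate size must start from a
        # BiP-carrying complex (chaperone-mediated extraction)
        for net in networks.values():
            for rxn in net.reactions:
                smaller = any(
                    sp.form is Form.AGGREGATE or sp.form is Form.MISFOLDED
                    for sp, _ in rxn.products
                )
                big_reactant = [sp for sp, _ in rxn.reactants
                                if sp.form is Form.AGGREGATE]
                if big_reactant and smaller and len(rxn.reactants) == 1:
                    assert big_reactant[0].n_bip >= 1


class TestDisaggregation:
    def test_k1_aggregates_hold_single_bip(self, network_k1):
        for sp in network_k1.species:
            if sp.form is Form.AGGREGATE:
                assert sp.n_bip <= 1

    def test_site_cap_min_k_size(self, networks):
        for k, net in networks.items():
            for sp in net.species:
                if sp.form is Form.AGGREGATE:
                    assert sp.n_bip <= min(k, sp.agg_size)

    def test_extraction_conserves_monomers(self, network_k4):
        for rxn in network_k4.reactions:
            if rxn.tag is not Tag.DISAGGREGATION:
                continue
            before = sum(sp.monomer_content * n for sp, n in rxn.reactants)
            after = sum(sp.monomer_content * n for sp, n in rxn.products)
            assert before == after

    def test_extraction_yields_single_chaperone_monomer(self, network_k4):
        extractions = [
            r for r in network_k4.reactions
            if r.tag is Tag.DISAGGREGATION and len(r.reactants) == 1
            and r.reactants[0][0].n_bip >= 1
        ]
        assert extractions
        for rxn in extractions:
            extracted = [sp for sp, _ in rxn.products
                         if sp.form is Form.MISFOLDED and sp.n_bip == 1
                         and not sp.scj1_bound]
            assert extracted

    def test_k4_c10_extraction_rate(self):
        net = build_network(ModelSpec(k=4, C=10.0))
        a4_full = aggregate(4, 4, False)
        rates = [r.rate_constant for r in net.reactions
                 if r.tag is Tag.DISAGGREGATION
                 and r.reactants == ((a4_full, 1),)]
        assert rates == [pytest.approx(10.0)]


class TestSequestration:
    def test_one_reaction_per_aggregate_species(self, networks):
        for net in networks.values():
            aggs = [s for s in net.species if s.form is Form.AGGREGATE]
            seqs = [r for r in net.reactions if r.tag is Tag.SEQUESTRATION]
            assert len(seqs) == len(aggs)
            sequestered = {r.reactants[0][0] for r in seqs}
            assert sequestered == set(aggs)

    def test_free_monomers_not_sequestered(self, network_k4):
        for rxn in network_k4.reactions:
            if rxn.tag is Tag.SEQUESTRATION:
                (sp, _), = rxn.reactants
                assert sp.form is Form.AGGREGATE

    def test_bookkeeping_counters(self, network_k4):
        a3_2bip = aggregate(3, 2, True)
        rxn = next(r for r in network_k4.reactions
                   if r.tag is Tag.SEQUESTRATION
                   and r.reactants == ((a3_2bip, 1),))
        products = dict((sp.form, n) for sp, n in rxn.products)
        assert products[Form.LOST_PROTEIN] == 3
        assert products[Form.LOST_BIP] == 2
        assert products[Form.LOST_SCJ1] == 1
        assert products[Form.INERT] == 1


class TestConservationStructure:
    """Left-null-vector checks on the stoichiometry matrix."""

    @pytest.mark.parametrize("C", [1.0, 10.0])
    def test_conserved_quantities(self, k, C):
        net = build_network(ModelSpec(k=k, C=C))
        mat = network_stoichiometry(net)
        for content in ("monomer_content", "bip_content", "scj1_content"):
            vec = np.array([getattr(s, content) for s in net.species], float)
            assert np.abs(vec @ mat).max() == 0.0

    def test_at_most_bimolecular(self, networks):
        for net in networks.values():
            assert all(r.order <= 2 for r in net.reactions)
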