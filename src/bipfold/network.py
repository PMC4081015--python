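"""Programmatic enumeration of the k-binding-site chaperone reaction network.

The model family is indexed by ``k``, the number of chaperone (BiP) binding
sites per substrate protein (k = 1..4).  Species are labelled by a small
structured state: molecular form, aggregate size, number of bound BiPs,
Scj1 occupancy, and (for translocating chains) the sliding position.  Five
reaction families are generated independently and merged:

* translocation  - pore activation, nascent engagement, alternating
  slide / BiP-bind steps (slides irreversible once a BiP "stopper" is in
  place), and release of the unfolded chain into the lumen;
* triage         - BiP/Scj1 association, BiP dissociation, spontaneous and
  assisted folding, misfolding of unprotected monomers, and
  chaperone-mediated unfolding;
* aggregation    - nucleation (penalised tenfold) and growth by addition of
  chaperone-free monomers, capped at tetramers;
* disaggregation - chaperone binding to aggregates and one-by-one monomer
  extraction;
* sequestration  - irreversible conversion of every aggregate species into
  the inert pool, entrapping its chaperones.

Cooperativity (entropic pulling) multiplies the folding, unfolding and
extraction rates of complexes carrying at least two BiPs by a factor C.

Bookkeeping counters (lost protein / BiP / Scj1 inside the inert pool) are
carried as pseudo-species so that the stoichiometry matrix has exact
conservation left-null-vectors; they are excluded from the species count.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field, replace

from .params import ConfigurationError, ParameterSet

MAX_AGGREGATE = 4


class Form(enum.Enum):
    PORE = "Pore"
    SEC63 = "Sec63"
    PORE_SEC63 = "PoreSec63"
    NASCENT = "N"
    BIP = "BiP"
    SCJ1 = "Scj1"
    FOLDED = "F"
    UNFOLDED = "U"
    MISFOLDED = "M"
    AGGREGATE = "A"
    INERT = "I"
    PORE_COMPLEX = "PC"
    # bookkeeping counters (not chemical species)
    LOST_PROTEIN = "lostP"
    LOST_BIP = "lostBiP"
    LOST_SCJ1 = "lostScj1"


_COUNTER_FORMS = frozenset(
    {Form.LOST_PROTEIN, Form.LOST_BIP, Form.LOST_SCJ1}
)

#: deterministic ordering of forms for species sorting
_FORM_ORDER = {f: i for i, f in enumerate(Form)}


@dataclass(frozen=True, order=False)
class SpeciesState:
    """Structured label for one chemical species."""

    form: Form
    agg_size: int = 1
    n_bip: int = 0
    scj1_bound: bool = False
    #: sliding index for pore complexes: site ``slide_pos`` is exposed.
    slide_pos: int = 0

    def __post_init__(self) -> None:
        if self.form is Form.AGGREGATE:
            if not 2 <= self.agg_size <= MAX_AGGREGATE:
                raise ValueError(f"aggregate size {self.agg_size} out of range")
        elif self.agg_size != 1:
            raise ValueError("agg_size must be 1 for non-aggregate forms")
        if self.form is not Form.PORE_COMPLEX and self.slide_pos != 0:
            raise ValueError("slide_pos only valid for pore complexes")
        if self.n_bip < 0:
            raise ValueError("negative BiP occupancy")
        if self.form in (Form.FOLDED, Form.INERT) and (
            self.n_bip or self.scj1_bound
        ):
            raise ValueError(f"{self.form.value} carries no occupancy")

    # -- bookkeeping ---------------------------------------------------
    @property
    def is_counter(self) -> bool:
        return self.form in _COUNTER_FORMS

    @property
    def monomer_content(self) -> int:
        """Protein monomer-equivalents embedded in one copy of this species."""
        if self.form in (
            Form.NASCENT, Form.UNFOLDED, Form.MISFOLDED, Form.FOLDED,
            Form.PORE_COMPLEX, Form.LOST_PROTEIN,
        ):
            return 1
        if self.form is Form.AGGREGATE:
            return self.agg_size
        return 0

    @property
    def bip_content(self) -> int:
        if self.form is Form.BIP or self.form is Form.LOST_BIP:
            return 1
        return self.n_bip

    @property
    def scj1_content(self) -> int:
        if self.form is Form.SCJ1 or self.form is Form.LOST_SCJ1:
            return 1
        return int(self.scj1_bound)

    @property
    def is_non_native(self) -> bool:
        """True for species embedding protein that is not yet folded nor lost."""
        return self.form in (
            Form.NASCENT, Form.UNFOLDED, Form.MISFOLDED,
            Form.AGGREGATE, Form.PORE_COMPLEX,
        )

    def sort_key(self):
        return (
            _FORM_ORDER[self.form], self.agg_size, self.n_bip,
            int(self.scj1_bound), self.slide_pos,
        )

    @property
    def name(self) -> str:
        f = self.form
        if f is Form.PORE_COMPLEX:
            stage = "B" if self.n_bip == self.slide_pos else "S"
            label = f"PC_{stage}{self.slide_pos}"
            if self.n_bip:
                label += f"_{self.n_bip}BiP"
            return label
        if f is Form.AGGREGATE:
            label = f"A{self.agg_size}"
        else:
            label = f.value
        if self.n_bip:
            label += f"_{self.n_bip}BiP"
        if self.scj1_bound:
            label += "_Scj1"
        return label

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<{self.name}>"


class Tag(enum.Enum):
    TRANSLOCATION = "translocation"
    TRIAGE = "triage"
    AGGREGATION = "aggregation"
    DISAGGREGATION = "disaggregation"
    SEQUESTRATION = "sequestration"


Stoich = tuple[tuple[SpeciesState, int], ...]


def _normalise(side) -> Stoich:
    counts: dict[SpeciesState, int] = {}
    for item in side:
        if isinstance(item, tuple):
            sp, n = item
        else:
            sp, n = item, 1
        counts[sp] = counts.get(sp, 0) + n
    return tuple(sorted(counts.items(), key=lambda kv: kv[0].sort_key()))


@dataclass(frozen=True)
class Reaction:
    """One irreversible mass-action reaction (at most bimolecular)."""

    reactants: Stoich
    products: Stoich
    rate_constant: float
    tag: Tag
    coop_scaled: bool = False

    @property
    def order(self) -> int:
        return sum(n for _, n in self.reactants)

    @property
    def is_bimolecular(self) -> bool:
        return self.order == 2

    @property
    def key(self):
        return (self.reactants, self.products, self.tag)

    def __str__(self) -> str:
        lhs = " + ".join(
            (f"{n} " if n > 1 else "") + sp.name for sp, n in self.reactants
        )
        rhs = " + ".join(
            (f"{n} " if n > 1 else "") + sp.name for sp, n in self.products
        )
        return f"{lhs} -> {rhs} ; {self.rate_constant:.6g} ; {self.tag.value}"


class CoopPolicy(enum.Enum):
    """How the cooperativity factor scales multi-BiP reaction rates."""

    #: one constant factor C for any complex with >= 2 bound BiPs (default)
    THRESHOLD = "threshold"
    #: C**(n_bip - 1): each BiP beyond the first contributes a factor C
    PER_EXTRA_BIP = "per-extra-bip"


@dataclass(frozen=True)
class ModelSpec:
    """Number of binding sites, cooperativity factor, and parameters."""

    k: int = 4
    C: float = 1.0
    params: ParameterSet = field(default_factory=ParameterSet)
    coop_policy: CoopPolicy = CoopPolicy.THRESHOLD

    def validate(self) -> None:
        if self.k not in (1, 2, 3, 4):
            raise ConfigurationError(f"k must be in 1..4, got {self.k!r}")
        if not self.C >= 1.0:
            raise ConfigurationError(f"C must be >= 1, got {self.C!r}")
        self.params.validate()

    def coop_factor(self, n_bip: int) -> float:
        """Rate multiplier for a cooperative reaction on an n_bip complex."""
        if n_bip < 2:
            return 1.0
        if self.coop_policy is CoopPolicy.PER_EXTRA_BIP:
            return self.C ** (n_bip - 1)
        return self.C

    def max_sites(self, agg_size: int = 1) -> int:
        """Binding sites on a monomer (agg_size 1) or an aggregate."""
        if agg_size == 1:
            return self.k
        return min(self.k, agg_size)


@dataclass(frozen=True)
class ReactionNetwork:
    species: tuple[SpeciesState, ...]
    reactions: tuple[Reaction, ...]
    k: int
    C: float
    spec: ModelSpec

    @property
    def n_species(self) -> int:
        """Chemical species count (bookkeeping counters excluded)."""
        return sum(1 for s in self.species if not s.is_counter)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def species_index(self) -> dict[SpeciesState, int]:
        return {s: i for i, s in enumerate(self.species)}

    def find(self, name: str) -> SpeciesState:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(name)

    def reaction_list(self) -> str:
        """Plain-text dump, one reaction per line, for diffing."""
        return "\n".join(str(r) for r in self.reactions) + "\n"


# ---------------------------------------------------------------------------
# species shorthands

PORE = SpeciesState(Form.PORE)
SEC63 = SpeciesState(Form.SEC63)
PORE_SEC63 = SpeciesState(Form.PORE_SEC63)
NASCENT = SpeciesState(Form.NASCENT)
BIP = SpeciesState(Form.BIP)
SCJ1 = SpeciesState(Form.SCJ1)
FOLDED = SpeciesState(Form.FOLDED)
INERT = SpeciesState(Form.INERT)
LOST_PROTEIN = SpeciesState(Form.LOST_PROTEIN)
LOST_BIP = SpeciesState(Form.LOST_BIP)
LOST_SCJ1 = SpeciesState(Form.LOST_SCJ1)


def unfolded(n_bip: int = 0, scj1: bool = False) -> SpeciesState:
    return SpeciesState(Form.UNFOLDED, n_bip=n_bip, scj1_bound=scj1)


def misfolded(n_bip: int = 0, scj1: bool = False) -> SpeciesState:
    return SpeciesState(Form.MISFOLDED, n_bip=n_bip, scj1_bound=scj1)


def aggregate(size: int, n_bip: int = 0, scj1: bool = False) -> SpeciesState:
    return SpeciesState(Form.AGGREGATE, agg_size=size, n_bip=n_bip, scj1_bound=scj1)


def slide_state(pos: int) -> SpeciesState:
    """Pore complex with site ``pos`` exposed and pos-1 BiPs already bound."""
    return SpeciesState(Form.PORE_COMPLEX, n_bip=pos - 1, slide_pos=pos)


def bound_state(pos: int) -> SpeciesState:
    """Pore complex with ``pos`` BiPs bound (site ``pos`` occupied)."""
    return SpeciesState(Form.PORE_COMPLEX, n_bip=pos, slide_pos=pos)


# ---------------------------------------------------------------------------
# reaction-family generators


def gen_translocation(spec: ModelSpec) -> list[Reaction]:
    """Pore activation, engagement, alternating slide/bind steps, release.

    The chain is strictly ordered: each exposed site is occupied by BiP
    before the next forward slide, and a bound BiP acts as a stopper so
    slides have no reverse partner.  Release of the fully translocated
    chain breaks the pore complex back into its constituents in one step.
    """
    p = spec.params
    k = spec.k
    rxns = [
        Reaction(
            _normalise([PORE, SEC63]), _normalise([PORE_SEC63]),
            p.k_pore_on, Tag.TRANSLOCATION,
        ),
        Reaction(
            _normalise([PORE_SEC63, NASCENT]), _normalise([slide_state(1)]),
            p.k_engage, Tag.TRANSLOCATION,
        ),
    ]
    # Sec63 recruits BiP at the pore, so binding runs at the assisted rate.
    pore_bind = p.k_on * p.scj1_assist
    for j in range(1, k + 1):
        rxns.append(
            Reaction(
                _normalise([slide_state(j), BIP]), _normalise([bound_state(j)]),
                pore_bind, Tag.TRANSLOCATION,
            )
        )
        if j < k:
            rxns.append(
                Reaction(
                    _normalise([bound_state(j)]), _normalise([slide_state(j + 1)]),
                    p.k_slide, Tag.TRANSLOCATION,
                )
            )
    rxns.append(
        Reaction(
            _normalise([bound_state(k)]),
            _normalise([PORE, SEC63, unfolded(n_bip=k)]),
            p.k_slide, Tag.TRANSLOCATION,
        )
    )
    return rxns


def gen_triage(spec: ModelSpec) -> list[Reaction]:
    """Folding triage of luminal monomers.

    * Scj1 binds chaperone-free U/M; once a complex carries Scj1 every
      subsequent BiP association runs ``scj1_assist`` times faster and the
      bound BiPs are secured (no dissociation route until resolution).
    * Bound BiP passively protects: misfolding occurs only from the fully
      chaperone-free unfolded monomer.
    * Misfolded monomers cannot unfold spontaneously - unfolding requires
      at least one bound BiP and is cooperative for multi-BiP complexes.
    """
    p = spec.params
    k = spec.k
    rxns: list[Reaction] = []
    for make in (unfolded, misfolded):
        rxns.append(
            Reaction(
                _normalise([make(0, False), SCJ1]), _normalise([make(0, True)]),
                p.k_scj1_on, Tag.TRIAGE,
            )
        )
        for scj1 in (False, True):
            kon = p.k_on * (p.scj1_assist if scj1 else 1.0)
            for i in range(k):
                rxns.append(
                    Reaction(
                        _normalise([make(i, scj1), BIP]),
                        _normalise([make(i + 1, scj1)]),
                        kon, Tag.TRIAGE,
                    )
                )
        for i in range(1, k + 1):
            rxns.append(
                Reaction(
                    _normalise([make(i, False)]),
                    _normalise([make(i - 1, False), BIP]),
                    p.k_off, Tag.TRIAGE,
                )
            )
    # productive folding releases all bound chaperones
    for scj1 in (False, True):
        for i in range(k + 1):
            products = [FOLDED]
            if i:
                products.append((BIP, i))
            if scj1:
                products.append(SCJ1)
            rxns.append(
                Reaction(
                    _normalise([unfolded(i, scj1)]), _normalise(products),
                    p.k_fold * spec.coop_factor(i), Tag.TRIAGE,
                    coop_scaled=i >= 2,
                )
            )
    rxns.append(
        Reaction(
            _normalise([unfolded(0, False)]), _normalise([misfolded(0, False)]),
            p.k_misfold, Tag.TRIAGE,
        )
    )
    for scj1 in (False, True):
        for i in range(1, k + 1):
            rxns.append(
                Reaction(
                    _normalise([misfolded(i, scj1)]),
                    _normalise([unfolded(i, scj1)]),
                    p.k_unfold * spec.coop_factor(i), Tag.TRIAGE,
                    coop_scaled=i >= 2,
                )
            )
    return rxns


def gen_aggregation(spec: ModelSpec) -> list[Reaction]:
    """Nucleation and growth by chaperone-free monomer addition, capped at 4."""
    p = spec.params
    free_monomers = [unfolded(0, False), misfolded(0, False)]
    rxns: list[Reaction] = []
    for a, b in itertools.combinations_with_replacement(free_monomers, 2):
        rxns.append(
            Reaction(
                _normalise([a, b]), _normalise([aggregate(2)]),
                p.k_nuc, Tag.AGGREGATION,
            )
        )
    for size in range(2, MAX_AGGREGATE):
        for mono in free_monomers:
            rxns.append(
                Reaction(
                    _normalise([aggregate(size), mono]),
                    _normalise([aggregate(size + 1)]),
                    p.k_agg, Tag.AGGREGATION,
                )
            )
    return rxns


def gen_disaggregation(spec: ModelSpec) -> list[Reaction]:
    """Chaperone binding to aggregates and monomer extraction.

    Scj1 docks onto a naked aggregate and accelerates every subsequent BiP
    association; chaperone binding commits the aggregate (no BiP
    dissociation route - the complex is stabilised until extraction or
    sequestration).  Extraction removes one misfolded monomer carrying one
    BiP; the terminal extraction from a dimer leaves a monomer complex.
    """
    p = spec.params
    rxns: list[Reaction] = []
    for size in range(2, MAX_AGGREGATE + 1):
        m = spec.max_sites(size)
        rxns.append(
            Reaction(
                _normalise([aggregate(size, 0, False), SCJ1]),
                _normalise([aggregate(size, 0, True)]),
                p.k_scj1_on, Tag.DISAGGREGATION,
            )
        )
        for scj1 in (False, True):
            kon = p.k_on * (p.scj1_assist if scj1 else 1.0)
            for i in range(m):
                rxns.append(
                    Reaction(
                        _normalise([aggregate(size, i, scj1), BIP]),
                        _normalise([aggregate(size, i + 1, scj1)]),
                        kon, Tag.DISAGGREGATION,
                    )
                )
            for i in range(1, m + 1):
                if size == 2:
                    remainder = misfolded(i - 1, scj1)
                else:
                    remainder = aggregate(size - 1, i - 1, scj1)
                rxns.append(
                    Reaction(
                        _normalise([aggregate(size, i, scj1)]),
                        _normalise([remainder, misfolded(1, False)]),
                        p.k_disagg * spec.coop_factor(i), Tag.DISAGGREGATION,
                        coop_scaled=i >= 2,
                    )
                )
    return rxns


def gen_sequestration(spec: ModelSpec) -> list[Reaction]:
    """Every aggregate species collapses irreversibly into the inert pool."""
    p = spec.params
    rxns: list[Reaction] = []
    for size in range(2, MAX_AGGREGATE + 1):
        m = spec.max_sites(size)
        for scj1 in (False, True):
            for i in range(m + 1):
                products: list = [INERT, (LOST_PROTEIN, size)]
                if i:
                    products.append((LOST_BIP, i))
                if scj1:
                    products.append(LOST_SCJ1)
                rxns.append(
                    Reaction(
                        _normalise([aggregate(size, i, scj1)]),
                        _normalise(products),
                        p.k_seq, Tag.SEQUESTRATION,
                    )
                )
    return rxns


_FAMILIES = (
    gen_translocation, gen_triage, gen_aggregation,
    gen_disaggregation, gen_sequestration,
)


def build_network(spec: ModelSpec) -> ReactionNetwork:
    """Assemble the full reaction network for one model specification.

    Deterministic: the same spec yields an identical species ordering and
    reaction list.  A duplicate (reactants, products, tag) key across the
    generated families is a build error, never a silent merge.
    """
    spec.validate()
    reactions: list[Reaction] = []
    seen: dict = {}
    for family in _FAMILIES:
        for rxn in family(spec):
            if rxn.order > 2:
                raise ConfigurationError(f"reaction exceeds bimolecular: {rxn}")
            if rxn.key in seen:
                raise ConfigurationError(f"duplicate reaction generated: {rxn}")
            seen[rxn.key] = rxn
            reactions.append(rxn)

    species = set()
    for rxn in reactions:
        for sp, _ in rxn.reactants:
            species.add(sp)
        for sp, _ in rxn.products:
            species.add(sp)
    ordered = tuple(sorted(species, key=SpeciesState.sort_key))
    return ReactionNetwork(
        species=ordered, reactions=tuple(reactions), k=spec.k, C=spec.C,
        spec=spec,
    )
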