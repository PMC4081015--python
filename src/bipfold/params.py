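"""Model parameters: rate constants, copy numbers and compartment volume.

Values that are fixed by design (aggregation rate, nucleation penalty,
disaggregation rate, sequestration rate, ER volume, initial unfolded pool)
are hard defaults.  The remaining kinetic constants and copy numbers are
not pinned by a single authoritative source; the defaults below are
literature-plausible order-of-magnitude choices, annotated per value.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

#: Avogadro constant, 1/mol (CODATA 2018 exact value).
N_AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class ParameterSet:
    """Rate constants (M^-1 s^-1 for bimolecular, s^-1 for unimolecular),
    initial copy numbers, and the luminal volume.

    All rates must be positive; copy numbers non-negative.
    """

    # --- chaperone / substrate kinetics -------------------------------
    #: BiP-substrate association without co-chaperone assistance.
    #: Hsp70-peptide association spans ~1e4..1e7 M^-1 s^-1 depending on
    #: substrate and nucleotide state; J-protein assistance multiplies it
    #: further (see scj1_assist).
    k_on: float = 5.0e6
    #: BiP-substrate dissociation (ADP-state complexes are long lived).
    k_off: float = 1.0e-2
    #: Fold-increase of BiP association when a J co-chaperone (Scj1) is
    #: part of the complex.  The unassisted:assisted ratio is 1/scj1_assist.
    scj1_assist: float = 10.0
    #: Scj1-substrate association.
    k_scj1_on: float = 1.0e6

    # --- folding triage ----------------------------------------------
    #: Productive folding (spontaneous and chaperone-assisted share one
    #: constant; cooperativity multiplies the assisted multi-BiP route).
    k_fold: float = 1.0
    #: Terminal misfolding of a chaperone-free unfolded monomer.
    k_misfold: float = 0.1
    #: Chaperone-mediated unfolding of a misfolded monomer; conformational
    #: remodelling is slow relative to folding from the unfolded state.
    k_unfold: float = 0.05

    # --- aggregation / disaggregation / sequestration ----------------
    #: Monomer addition to an existing aggregate (fixed by design).
    k_agg: float = 1.0e7
    #: Nucleation penalty: the first (dimerisation) step runs at
    #: nucleation_factor * k_agg (fixed by design, rate limiting).
    nucleation_factor: float = 0.1
    #: Chaperone-mediated extraction of one monomer from an aggregate
    #: (fixed by design).
    k_disagg: float = 1.0
    #: Irreversible entrapment of any aggregate into an inert body
    #: (fixed by design).
    k_seq: float = 1.0

    # --- translocation ------------------------------------------------
    #: Pore activation by Sec63 binding.
    k_pore_on: float = 1.0e6
    #: Nascent-chain engagement with an active pore.
    k_engage: float = 1.0e7
    #: Forward slide of the nascent chain, exposing the next site.  Slow
    #: post-translational ratcheting: together with the small active-pore
    #: pool this caps translocation throughput.
    k_slide: float = 1.0

    # --- copy numbers and geometry ------------------------------------
    bip_total: float = 3.0e5
    u0: float = 1.0e6
    #: Co-chaperone pool; at least an order of magnitude below BiP.
    scj1_total: float = 2.0e4
    #: Active translocons are scarce; throughput-limiting by design.
    pore_total: float = 20.0
    sec63_total: float = 20.0
    #: Luminal volume in cubic micrometres (fixed by design).
    volume_um3: float = 0.7

    @property
    def k_nuc(self) -> float:
        return self.nucleation_factor * self.k_agg

    @property
    def volume_l(self) -> float:
        return self.volume_um3 * 1.0e-15

    def replace(self, **changes: float) -> "ParameterSet":
        return dataclasses.replace(self, **changes)

    def validate(self) -> None:
        rate_fields = (
            "k_on", "k_off", "scj1_assist", "k_scj1_on", "k_fold",
            "k_misfold", "k_unfold", "k_agg", "nucleation_factor",
            "k_disagg", "k_seq", "k_pore_on", "k_engage", "k_slide",
            "volume_um3",
        )
        for name in rate_fields:
            value = getattr(self, name)
            if not value > 0.0:
                raise ConfigurationError(
                    f"parameter {name!r} must be positive, got {value!r}"
                )
        for name in ("bip_total", "u0", "scj1_total", "pore_total", "sec63_total"):
            value = getattr(self, name)
            if value < 0.0:
                raise ConfigurationError(
                    f"copy number {name!r} must be non-negative, got {value!r}"
                )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class ConfigurationError(ValueError):
    """Raised for invalid model configuration (bad k, rates, volumes...)."""


#: Names of the seven kinetic constants examined in the single-parameter
#: correlation study and the global sensitivity analysis.
STUDY_PARAMETERS = (
    "k_on", "k_off", "k_agg", "k_unfold", "k_misfold", "k_fold", "k_seq",
)
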