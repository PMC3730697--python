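"""The RNAPII transcription cycle with CTD phosphorylation rules.

The model tracks one gene (a single DNA agent whose binding sites e1..eN
tile the coding region in 30-nt polymerase footprints, followed by
pA1..pAM maturation sites), a pool of RNAPII molecules carrying two
representative heptad repeats (serines 2, 5 and 7 on repeats ``a`` and
``b``, each ``u`` or ``p``), and the kinases and phosphatases that act
on the CTD in four mutually exclusive contexts:

* promoter  -- RNAPII site ``p`` bound to DNA ``prom``: TFIIH/Kin28
  phosphorylates Ser5 and Ser7 of each repeat; Srb10 competes for the
  fully unphosphorylated substrate and aborts initiation.
* elongation -- site ``a`` bound to some e-site with ``e`` free: Ctk1
  and Bur1 act as Ser2 kinases on (Ser2~U, Ser5~P) repeats, Rtr1
  removes Ser5~P (either Ser2 state), Fcp1 removes Ser2~P, and the
  optional Ctk1 Ser5-kinase activity acts per the selected variant.
* 3'-UTR   -- site ``e`` bound to a pA-site: Ssu72 removes Ser5~P and
  Ser7~P; Pcf11 (which requires Ser2~P and gates entry) and Rtt103 ride
  the complex until the mature transcript is released.
* free     -- no DNA bonds: Fcp1 recycles Ser2~P and Ser5~P; a slow
  lumped step clears residual Ser7~P so the fully unphosphorylated
  initiation substrate is regenerated.

Every enzyme works as a bind/release pair: binding carries the substrate
specificity at a p0-derived rate tier (phosph0 = p0, phosph1 = p0/2,
phosph2 = p0/10) and the release step performs the modification at
phosph3 = p3.  Nascent transcript length is a counter on RNAPII
incremented by one footprint per elongation step.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, fields, replace

from .sitegraph_engine import (
    A,
    AgentSignature,
    DefinitionError,
    Model,
    Rule,
)

__all__ = [
    "GeneConfig",
    "RateConfig",
    "CopyNumbers",
    "VariantSpec",
    "SimConfig",
    "CTK1_SER5_VARIANTS",
    "REPEAT_LABELS",
    "build_model",
    "render_rules",
    "species_expansion",
    "default_config",
]

CTK1_SER5_VARIANTS = ("NONE", "FROM_UU", "FROM_PU", "BOTH")
REPEAT_LABELS = "abcdefgh"


@dataclass(frozen=True)
class GeneConfig:
    """Gene geometry: 80 x 30-nt elongation sites and 20 pA sites by default,
    giving a 2400-nt coding region; an optional pause site extends the
    dwell at that site to an exponential with the given mean."""
    n_elongation_sites: int = 80
    footprint_nt: int = 30
    n_polyA_sites: int = 20
    n_repeats: int = 2
    pause_site: int | None = None
    pause_duration_mean: float = 30.0

    def __post_init__(self):
        if self.n_elongation_sites < 1 or self.n_polyA_sites < 1:
            raise DefinitionError("need at least one elongation and pA site")
        if not 1 <= self.n_repeats <= len(REPEAT_LABELS):
            raise DefinitionError("unsupported repeat count")
        if self.pause_site is not None and not (
                1 <= self.pause_site <= self.n_elongation_sites):
            raise DefinitionError("pause_site outside the gene")

    @property
    def coding_nt(self) -> int:
        return self.n_elongation_sites * self.footprint_nt

    @property
    def repeats(self) -> str:
        return REPEAT_LABELS[: self.n_repeats]

    def site_start_nt(self, i: int) -> int:
        """1-based start coordinate of elongation site i (TSS = nt 1)."""
        return (i - 1) * self.footprint_nt + 1

    def site_for_nt(self, nt: float) -> int:
        """First site whose span begins at or after the given coordinate."""
        import math
        return min(self.n_elongation_sites,
                   max(1, math.ceil(nt / self.footprint_nt) + 1))


@dataclass(frozen=True)
class RateConfig:
    """All free rate parameters, in per-second units.

    ``p0`` is the kinase/phosphatase binding meta-parameter (reference
    0.1/s) from which the tiers phosph0 = p0, phosph1 = p0/2 and
    phosph2 = p0/10 derive; ``p3`` (reference 100/s) is the shared
    release/catalysis rate.  Rtr1 binds at ``rtr1_bind_multiplier``
    times the Ser2-kinase rate phosph1 (default 2.0, i.e. Rtr1 at p0).
    The transcription-cycle rates are calibrated, not measured; see the
    methods note.
    """
    p0: float = 0.1
    p3: float = 100.0
    rtr1_bind_multiplier: float = 2.0
    activator_bind: float = 1.0
    mediator_bind: float = 1.0
    rnapii_bind: float = 0.056
    tfiih_bind: float = 1.0
    kin28: float = 2.0
    initiation: float = 2.0
    elongation_step: float = 2.36
    maturation_step: float = 2.36
    pcf11_bind: float = 0.1
    rtt103_bind: float = 0.1
    release: float = 1.0

    def __post_init__(self):
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise DefinitionError(f"rate {f.name} must be positive")

    @property
    def phosph0(self) -> float:
        return self.p0

    @property
    def phosph1(self) -> float:
        return self.p0 / 2.0

    @property
    def phosph2(self) -> float:
        return self.p0 / 10.0

    @property
    def phosph3(self) -> float:
        return self.p3

    @property
    def rtr1_bind(self) -> float:
        return self.rtr1_bind_multiplier * self.phosph1


@dataclass(frozen=True)
class CopyNumbers:
    """Molecule counts.  One gene; the enzyme copies multiply the
    p0-derived binding tiers into effective per-repeat rates and are
    part of the calibration (see the methods note)."""
    dna: int = 1
    rnapii: int = 20
    ctk1: int = 7
    bur1: int = 1
    rtr1: int = 6
    fcp1: int = 1
    ssu72: int = 5
    srb10: int = 2
    activator: int = 5
    mediator: int = 5
    tfiih: int = 5
    pcf11: int = 15
    rtt103: int = 8

    def __post_init__(self):
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise DefinitionError(f"copy number {f.name} must be >= 0")
        if self.dna != 1:
            raise DefinitionError("exactly one gene copy is modelled")


@dataclass(frozen=True)
class VariantSpec:
    """Which Ctk1 Ser5-kinase activity the model includes during
    elongation: from the (Ser2~U, Ser5~U) substrate (FROM_UU, the
    retained default), from (Ser2~P, Ser5~U) (FROM_PU), BOTH, or NONE."""
    ctk1_ser5_variant: str = "FROM_UU"

    def __post_init__(self):
        if self.ctk1_ser5_variant not in CTK1_SER5_VARIANTS:
            raise DefinitionError(
                f"unknown variant {self.ctk1_ser5_variant!r}; "
                f"expected one of {CTK1_SER5_VARIANTS}")


@dataclass(frozen=True)
class SimConfig:
    """Bundle of all model configuration."""
    gene: GeneConfig = field(default_factory=GeneConfig)
    rates: RateConfig = field(default_factory=RateConfig)
    copies: CopyNumbers = field(default_factory=CopyNumbers)
    variant: VariantSpec = field(default_factory=VariantSpec)

    def replace(self, **kw):
        return replace(self, **kw)


def default_config() -> SimConfig:
    return SimConfig()


# ----------------------------------------------------------------------
# Signatures
# ----------------------------------------------------------------------

def _signatures(gene: GeneConfig):
    e_sites = {f"e{i}": () for i in range(1, gene.n_elongation_sites + 1)}
    pa_sites = {f"pA{j}": () for j in range(1, gene.n_polyA_sites + 1)}
    dna = AgentSignature(
        "DNA", {"act": (), "med": (), "prom": (), "tfiih": (),
                **e_sites, **pa_sites})
    ser_sites = {}
    for r in gene.repeats:
        for pos in ("2", "5", "7"):
            ser_sites[f"ser{pos}{r}"] = ("u", "p")
    rnapii = AgentSignature(
        "RNAPII",
        {"p": (), "a": (), "e": (), "pcf": (), "rtt": (),
         "cap": ("no", "yes"), **ser_sites},
        counters=("rna", "polya"))
    enzymes = [AgentSignature(n, {"a": ()})
               for n in ("Ctk1", "Bur1", "Rtr1", "Fcp1", "Ssu72", "Srb10")]
    factors = [AgentSignature(n, {"d": ()})
               for n in ("Activator", "Mediator", "TFIIH", "Pcf11", "Rtt103")]
    mrna = AgentSignature("mRNA")
    return [dna, rnapii, *enzymes, *factors, mrna]


# ----------------------------------------------------------------------
# Rule construction
# ----------------------------------------------------------------------

def build_model(gene: GeneConfig | None = None,
                rates: RateConfig | None = None,
                variant: VariantSpec | None = None,
                copies: CopyNumbers | None = None,
                config: SimConfig | None = None) -> Model:
    """Construct the full transcription + CTD phosphorylation model."""
    if config is not None:
        gene, rates, variant, copies = (config.gene, config.rates,
                                        config.variant, config.copies)
    gene = gene or GeneConfig()
    rates = rates or RateConfig()
    variant = variant or VariantSpec()
    copies = copies or CopyNumbers()

    sigs = _signatures(gene)
    rules = []
    fp = gene.footprint_nt
    N = gene.n_elongation_sites
    M = gene.n_polyA_sites
    all_u = [f"ser{pos}{r}~u" for r in gene.repeats for pos in ("2", "5", "7")]

    # ---- initiation -------------------------------------------------
    rules.append(Rule(
        "activator_binds",
        [A("DNA", "act"), A("Activator", "d")],
        [A("DNA", "act!1"), A("Activator", "d!1")],
        rates.activator_bind, "activator_bind"))
    rules.append(Rule(
        "mediator_binds",
        [A("DNA", "med", "act!_"), A("Mediator", "d")],
        [A("DNA", "med!1", "act!_"), A("Mediator", "d!1")],
        rates.mediator_bind, "mediator_bind"))
    rules.append(Rule(
        "rnapii_binds_promoter",
        [A("DNA", "prom", "med!_"),
         A("RNAPII", "p", "a", "e", "cap~no", *all_u)],
        [A("DNA", "prom!1", "med!_"),
         A("RNAPII", "p!1", "a", "e", "cap~no", *all_u)],
        rates.rnapii_bind, "rnapii_bind"))
    rules.append(Rule(
        "tfiih_binds",
        [A("DNA", "tfiih", "prom!_"), A("TFIIH", "d")],
        [A("DNA", "tfiih!1", "prom!_"), A("TFIIH", "d!1")],
        rates.tfiih_bind, "tfiih_bind"))
    for r in gene.repeats:
        rules.append(Rule(
            f"kin28_phosphorylates_{r}",
            [A("DNA", "prom!1", "tfiih!_"),
             A("RNAPII", "p!1", f"ser5{r}~u")],
            [A("DNA", "prom!1", "tfiih!_"),
             A("RNAPII", "p!1", f"ser5{r}~p", f"ser7{r}~p?")],
            rates.kin28, "kin28"))
    ser5_all_p = [f"ser5{r}~p?" for r in gene.repeats]
    esc = Rule(
        "promoter_escape",
        [A("DNA", "prom!1", "e1"), A("RNAPII", "p!1", *ser5_all_p)],
        [A("DNA", "prom", "e1!2"),
         A("RNAPII", "p", "a!2", "cap~yes", *ser5_all_p)],
        rates.initiation, "initiation")
    esc.with_counters((1, f"rna:={fp}"))
    rules.append(esc)

    # Srb10 competes with Kin28 on the fully unphosphorylated promoter
    # substrate (before TFIIH arrival) and aborts initiation.
    rules.append(Rule(
        "srb10_binds",
        [A("DNA", "prom!1", "tfiih"),
         A("RNAPII", "p!1", "ser5a~u",
           *[s for s in all_u if not s.startswith("ser5a")]),
         A("Srb10", "a")],
        [A("DNA", "prom!1", "tfiih"),
         A("RNAPII", "p!1", "ser5a~u!2",
           *[s for s in all_u if not s.startswith("ser5a")]),
         A("Srb10", "a!2")],
        rates.phosph2, "phosph2"))
    rules.append(Rule(
        "srb10_aborts",
        [A("Srb10", "a!1"), A("RNAPII", "ser5a~u!1", "p!_")],
        [A("Srb10", "a"), A("RNAPII", "ser5a~p", "p")],
        rates.phosph3, "phosph3"))

    # ---- elongation -------------------------------------------------
    for i in range(1, N):
        rate, sym = rates.elongation_step, "elongation_step"
        if gene.pause_site is not None and i == gene.pause_site:
            rate, sym = 1.0 / gene.pause_duration_mean, "pause_resume"
        step = Rule(
            f"advance_e{i}",
            [A("DNA", f"e{i}!1", f"e{i + 1}"), A("RNAPII", "a!1", "e")],
            [A("DNA", f"e{i}", f"e{i + 1}!1"), A("RNAPII", "a!1", "e")],
            rate, sym)
        step.with_counters((1, f"rna+={fp}"))
        rules.append(step)

    # ---- 3' maturation ----------------------------------------------
    rate, sym = rates.maturation_step, "maturation_step"
    if gene.pause_site == N:
        rate, sym = 1.0 / gene.pause_duration_mean, "pause_resume"
    entry = Rule(
        "utr_entry",
        [A("DNA", f"e{N}!1", "pA1"), A("RNAPII", "a!1", "e", "pcf!_")],
        [A("DNA", f"e{N}", "pA1!2"), A("RNAPII", "a", "e!2", "pcf!_")],
        rate, sym)
    entry.with_counters((1, f"rna+={fp}"))
    rules.append(entry)
    for j in range(1, M):
        step = Rule(
            f"advance_pA{j}",
            [A("DNA", f"pA{j}!1", f"pA{j + 1}"), A("RNAPII", "e!1")],
            [A("DNA", f"pA{j}", f"pA{j + 1}!1"), A("RNAPII", "e!1")],
            rates.maturation_step, "maturation_step")
        step.with_counters((1, "polya+=1"))
        rules.append(step)
    for r in gene.repeats:
        rules.append(Rule(
            f"pcf11_binds_{r}",
            [A("Pcf11", "d"), A("RNAPII", "pcf", "a!_", "e", f"ser2{r}~p?")],
            [A("Pcf11", "d!1"), A("RNAPII", "pcf!1", "a!_", "e",
                                  f"ser2{r}~p?")],
            rates.pcf11_bind, "pcf11_bind"))
    rules.append(Rule(
        "rtt103_binds",
        [A("Rtt103", "d"), A("RNAPII", "rtt", "e!_")],
        [A("Rtt103", "d!1"), A("RNAPII", "rtt!1", "e!_")],
        rates.rtt103_bind, "rtt103_bind"))
    rel = Rule(
        "release_mature",
        [A("DNA", f"pA{M}!1"),
         A("RNAPII", "e!1", "pcf!2", "rtt!3", "cap~yes"),
         A("Pcf11", "d!2"), A("Rtt103", "d!3")],
        [A("DNA", f"pA{M}"),
         A("RNAPII", "e", "pcf", "rtt", "cap~no"),
         A("Pcf11", "d"), A("Rtt103", "d"),
         A("mRNA")],
        rates.release, "release")
    rel.with_counters((1, "rna:=0"), (1, "polya:=0"))
    rules.append(rel)

    # ---- CTD phosphorylation during elongation ----------------------
    elong = ("e", "a!_")
    for k, r in enumerate(gene.repeats, start=1):
        # Ctk1 as Ser2 kinase, substrate (Ser2~U, Ser5~P)
        rules.append(Rule(
            f"ctk1_ser2_binds_{r}",
            [A("Ctk1", "a"), A("RNAPII", *elong, f"ser2{r}~u", f"ser5{r}~p?")],
            [A("Ctk1", "a!1"),
             A("RNAPII", *elong, f"ser2{r}~u!1", f"ser5{r}~p?")],
            rates.phosph1, "phosph1"))
        rules.append(Rule(
            f"ctk1_ser2_release_{r}",
            [A("Ctk1", "a!1"), A("RNAPII", f"ser2{r}~u!1", f"ser5{r}~p?")],
            [A("Ctk1", "a"), A("RNAPII", f"ser2{r}~p", f"ser5{r}~p?")],
            rates.phosph3, "phosph3"))
        # Bur1 as Ser2 kinase (recruited via Ser5~P)
        rules.append(Rule(
            f"bur1_ser2_binds_{r}",
            [A("Bur1", "a"), A("RNAPII", *elong, f"ser2{r}~u", f"ser5{r}~p?")],
            [A("Bur1", "a!1"),
             A("RNAPII", *elong, f"ser2{r}~u!1", f"ser5{r}~p?")],
            rates.phosph1, "phosph1"))
        rules.append(Rule(
            f"bur1_ser2_release_{r}",
            [A("Bur1", "a!1"), A("RNAPII", f"ser2{r}~u!1")],
            [A("Bur1", "a"), A("RNAPII", f"ser2{r}~p")],
            rates.phosph3, "phosph3"))
        # Ctk1 as Ser5 kinase from the (Ser2~U, Ser5~U) substrate --
        # serine 5 is phosphorylated on release
        if variant.ctk1_ser5_variant in ("FROM_UU", "BOTH"):
            rules.append(Rule(
                f"binds{k}",
                [A("Ctk1", "a"),
                 A("RNAPII", *elong, f"ser2{r}~u", f"ser5{r}~u")],
                [A("Ctk1", "a!1"),
                 A("RNAPII", *elong, f"ser2{r}~u!1", f"ser5{r}~u")],
                rates.phosph1, "phosph1"))
            rules.append(Rule(
                f"release{k}",
                [A("Ctk1", "a!1"), A("RNAPII", f"ser2{r}~u!1", f"ser5{r}~u")],
                [A("Ctk1", "a"), A("RNAPII", f"ser2{r}~u", f"ser5{r}~p")],
                rates.phosph3, "phosph3"))
        # Ctk1 as Ser5 kinase from the (Ser2~P, Ser5~U) substrate
        if variant.ctk1_ser5_variant in ("FROM_PU", "BOTH"):
            rules.append(Rule(
                f"ctk1_ser5_pu_binds_{r}",
                [A("Ctk1", "a"),
                 A("RNAPII", *elong, f"ser2{r}~p?", f"ser5{r}~u")],
                [A("Ctk1", "a!1"),
                 A("RNAPII", *elong, f"ser2{r}~p?", f"ser5{r}~u!1")],
                rates.phosph1, "phosph1"))
            rules.append(Rule(
                f"ctk1_ser5_pu_release_{r}",
                [A("Ctk1", "a!1"),
                 A("RNAPII", f"ser5{r}~u!1", f"ser2{r}~p?")],
                [A("Ctk1", "a"), A("RNAPII", f"ser5{r}~p", f"ser2{r}~p?")],
                rates.phosph3, "phosph3"))
        # Rtr1 removes Ser5~P regardless of the Ser2 state
        rules.append(Rule(
            f"rtr1_binds_{r}",
            [A("Rtr1", "a"), A("RNAPII", "a!_", "e", f"ser5{r}~p")],
            [A("Rtr1", "a!1"), A("RNAPII", "a!_", "e", f"ser5{r}~p!1")],
            rates.rtr1_bind, "rtr1_bind"))
        rules.append(Rule(
            f"rtr1_release_{r}",
            [A("Rtr1", "a!1"), A("RNAPII", f"ser5{r}~p!1")],
            [A("Rtr1", "a"), A("RNAPII", f"ser5{r}~u")],
            rates.phosph3, "phosph3"))
        # Fcp1 removes Ser2~P during elongation
        rules.append(Rule(
            f"fcp1_ser2_binds_{r}",
            [A("Fcp1", "a"), A("RNAPII", *elong, f"ser2{r}~p")],
            [A("Fcp1", "a!1"), A("RNAPII", *elong, f"ser2{r}~p!1")],
            rates.phosph1, "phosph1"))
        rules.append(Rule(
            f"fcp1_ser2_release_{r}",
            [A("Fcp1", "a!1"), A("RNAPII", f"ser2{r}~p!1")],
            [A("Fcp1", "a"), A("RNAPII", f"ser2{r}~u")],
            rates.phosph3, "phosph3"))
        # ---- 3'-UTR: Ssu72 removes Ser5~P and Ser7~P -----------------
        rules.append(Rule(
            f"ssu72_ser5_binds_{r}",
            [A("Ssu72", "a"), A("RNAPII", "e!_", f"ser5{r}~p")],
            [A("Ssu72", "a!1"), A("RNAPII", "e!_", f"ser5{r}~p!1")],
            rates.phosph0, "phosph0"))
        rules.append(Rule(
            f"ssu72_ser5_release_{r}",
            [A("Ssu72", "a!1"), A("RNAPII", f"ser5{r}~p!1")],
            [A("Ssu72", "a"), A("RNAPII", f"ser5{r}~u")],
            rates.phosph3, "phosph3"))
        rules.append(Rule(
            f"ssu72_ser7_binds_{r}",
            [A("Ssu72", "a"), A("RNAPII", "e!_", f"ser7{r}~p")],
            [A("Ssu72", "a!1"), A("RNAPII", "e!_", f"ser7{r}~p!1")],
            rates.phosph0, "phosph0"))
        rules.append(Rule(
            f"ssu72_ser7_release_{r}",
            [A("Ssu72", "a!1"), A("RNAPII", f"ser7{r}~p!1")],
            [A("Ssu72", "a"), A("RNAPII", f"ser7{r}~u")],
            rates.phosph3, "phosph3"))
        # ---- recycling on free RNAPII --------------------------------
        rules.append(Rule(
            f"fcp1_recycle_ser2_binds_{r}",
            [A("Fcp1", "a"), A("RNAPII", "p", "a", "e", f"ser2{r}~p")],
            [A("Fcp1", "a!1"), A("RNAPII", "p", "a", "e", f"ser2{r}~p!1")],
            rates.phosph0, "phosph0"))
        rules.append(Rule(
            f"fcp1_recycle_ser5_binds_{r}",
            [A("Fcp1", "a"), A("RNAPII", "p", "a", "e", f"ser5{r}~p")],
            [A("Fcp1", "a!1"), A("RNAPII", "p", "a", "e", f"ser5{r}~p!1")],
            rates.phosph0, "phosph0"))
        rules.append(Rule(
            f"fcp1_recycle_ser5_release_{r}",
            [A("Fcp1", "a!1"), A("RNAPII", f"ser5{r}~p!1")],
            [A("Fcp1", "a"), A("RNAPII", f"ser5{r}~u")],
            rates.phosph3, "phosph3"))
        rules.append(Rule(
            f"ser7_cleanup_{r}",
            [A("RNAPII", "p", "a", "e", f"ser7{r}~p")],
            [A("RNAPII", "p", "a", "e", f"ser7{r}~u")],
            rates.phosph2, "phosph2"))

    counts = {
        "DNA": copies.dna, "RNAPII": copies.rnapii, "Ctk1": copies.ctk1,
        "Bur1": copies.bur1, "Rtr1": copies.rtr1, "Fcp1": copies.fcp1,
        "Ssu72": copies.ssu72, "Srb10": copies.srb10,
        "Activator": copies.activator, "Mediator": copies.mediator,
        "TFIIH": copies.tfiih, "Pcf11": copies.pcf11,
        "Rtt103": copies.rtt103,
    }
    model = Model(sigs, rules, initial_counts=counts)
    model.gene = gene
    model.rates = rates
    model.variant = variant
    model.copies = copies
    return model


def render_rules(model: Model) -> str:
    """Deterministic, name-sorted, Kappa-like listing of every rule."""
    return model.render_rules()


# ----------------------------------------------------------------------
# Species-based expansion arithmetic
# ----------------------------------------------------------------------

def species_expansion(n_positions: int, n_repeats: int,
                      n_serines_per_repeat: int):
    """Size of the species-based equivalent of the positional CTD model.

    Explicitly constructs (not merely counts) every species -- a
    phosphorylation pattern over ``n_repeats`` repeats of
    ``n_serines_per_repeat`` modifiable serines, crossed with a DNA
    position -- and every transition, taken as a position advance
    combined with one of the per-state phosphorylation changes (one per
    modifiable serine; four ways for two repeats of two serines).
    Returns ``(n_species, n_transitions)``.
    """
    if min(n_positions, n_repeats, n_serines_per_repeat) < 1:
        raise DefinitionError("all arguments must be >= 1")
    n_bits = n_repeats * n_serines_per_repeat
    states = list(itertools.product((0, 1), repeat=n_bits))
    species = [(s, pos) for pos in range(1, n_positions + 1) for s in states]
    transitions = []
    for pos in range(1, n_positions):
        for s in states:
            for bit in range(n_bits):
                t = list(s)
                t[bit] ^= 1
                transitions.append(((s, pos), (tuple(t), pos + 1)))
    return len(species), len(transitions)
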