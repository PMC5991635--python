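"""Topology of the whole-body glucose/lipid/cholesterol network.

The model tracks metabolite pools (µmol per animal) in four compartments —
intestinal lumen, plasma, liver and periphery — plus three cumulative
bookkeeping sinks (fecal cholesterol, fecal bile acids, oxidized
acetyl-CoA).  Fluxes between pools are declared here as a :class:`FluxTable`;
rate laws are evaluated in :mod:`metsim.model`.

Species-class accounting uses fixed stoichiometric conversion factors:
3 fatty acids per triglyceride, 8 acetyl-CoA per fatty acid (palmitate
scale, hence 24 acetyl-CoA per TG), 18 acetyl-CoA per cholesterol, and
2 acetyl-CoA per glucose equivalent entering through glycolysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "POOLS",
    "SINKS",
    "COMPARTMENTS",
    "SPECIES_CLASSES",
    "Flux",
    "FluxTable",
    "build_flux_table",
    "ACOA_PER_FA",
    "FA_PER_TG",
    "ACOA_PER_TG",
    "ACOA_PER_CHOL",
    "ACOA_PER_GLC",
]

# stoichiometric conversion factors between species classes
FA_PER_TG = 3.0
ACOA_PER_FA = 8.0
ACOA_PER_TG = FA_PER_TG * ACOA_PER_FA  # 24
ACOA_PER_CHOL = 18.0
ACOA_PER_GLC = 2.0  # glycolysis: glucose -> 2 pyruvate -> 2 acetyl-CoA

#: canonical pool ordering; the last three entries are cumulative sinks
POOLS = (
    # intestinal lumen
    "lG", "lTG", "lFC", "lBA",
    # plasma
    "pG", "pI", "pFFA", "pTGc", "pTGv", "pCv", "pCh",
    # liver
    "hG6P", "hACoA", "hTG", "hFC", "hCE", "hBA",
    # periphery
    "aTG", "aACoA",
    # bookkeeping sinks (monotonically non-decreasing)
    "fecC", "fecBA", "oxC",
)

SINKS = ("fecC", "fecBA", "oxC")

COMPARTMENTS = {
    "lumen": ("lG", "lTG", "lFC", "lBA"),
    "plasma": ("pG", "pI", "pFFA", "pTGc", "pTGv", "pCv", "pCh"),
    "liver": ("hG6P", "hACoA", "hTG", "hFC", "hCE", "hBA"),
    "periphery": ("aTG", "aACoA"),
    "sinks": SINKS,
}

#: pools grouped by chemical species class, used for mass-balance checks.
#: pFFA is carried in fatty-acid units and counts as 1/3 TG-equivalent;
#: bile acids and both cholesterol sinks count 1:1 in cholesterol units.
SPECIES_CLASSES = {
    "glucose": {"lG": 1.0, "pG": 1.0, "hG6P": 1.0},
    "tg": {"lTG": 1.0, "pTGc": 1.0, "pTGv": 1.0, "hTG": 1.0, "aTG": 1.0,
           "pFFA": 1.0 / FA_PER_TG},
    "cholesterol": {"lFC": 1.0, "hFC": 1.0, "hCE": 1.0, "pCv": 1.0,
                    "pCh": 1.0, "hBA": 1.0, "lBA": 1.0,
                    "fecC": 1.0, "fecBA": 1.0},
    "acoa": {"hACoA": 1.0, "aACoA": 1.0, "oxC": 1.0},
    "insulin": {"pI": 1.0},
}


@dataclass(frozen=True)
class Flux:
    """One reaction/transport step of the network.

    Parameters
    ----------
    name
        Identifier; mass-action fluxes have a rate constant ``k_<name>``.
    substrate, product
        Pool names (``None`` for dietary inflows / insulin clearance).
    stoich
        Signed stoichiometric coefficients applied to the scalar rate.
        The rate itself is expressed in substrate units (or product units
        for zero-order inflows).
    kind
        ``"mass_action"``, ``"zero_order"`` (dietary inflow or
        gluconeogenesis) or ``"hill"`` (insulin secretion).
    modifier
        Insulin-action tag: ``"dnl"``/``"uptake"`` (stimulated,
        ``×(1+a·Î)``) or ``"lipolysis"``/``"gng"`` (suppressed,
        ``×1/(1+a·Î)``); ``None`` for unmodulated fluxes.
    diet_key
        For dietary inflows, the key into the dietary-inflow vector.
    """

    name: str
    substrate: str | None
    product: str | None
    stoich: dict[str, float]
    kind: str = "mass_action"
    modifier: str | None = None
    diet_key: str | None = None


@dataclass(frozen=True)
class FluxTable:
    """Immutable ordered collection of :class:`Flux` entries."""

    fluxes: tuple[Flux, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [f.name for f in self.fluxes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate flux names")
        for f in self.fluxes:
            for pool in f.stoich:
                if pool not in POOLS:
                    raise ValueError(
                        f"flux {f.name!r} references unknown pool {pool!r}")

    def __iter__(self):
        return iter(self.fluxes)

    def __len__(self) -> int:
        return len(self.fluxes)

    def __getitem__(self, name: str) -> Flux:
        for f in self.fluxes:
            if f.name == name:
                return f
        raise KeyError(name)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.fluxes)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def to_records(self) -> list[dict]:
        """Serializable description (JSON/YAML friendly)."""
        return [
            {
                "name": f.name,
                "substrate": f.substrate,
                "product": f.product,
                "stoich": dict(f.stoich),
                "kind": f.kind,
                "modifier": f.modifier,
                "diet_key": f.diet_key,
            }
            for f in self.fluxes
        ]


def _ma(name: str, sub: str, prod: str | None, *,
        sub_coef: float = 1.0, prod_coef: float = 1.0,
        modifier: str | None = None) -> Flux:
    stoich = {sub: -sub_coef}
    if prod is not None:
        stoich[prod] = stoich.get(prod, 0.0) + prod_coef
    return Flux(name, sub, prod, stoich, "mass_action", modifier)


def build_flux_table() -> FluxTable:
    """Return the canonical network of ~36 fluxes.

    Dietary inflows are zero-order and driven by the diet composition;
    gluconeogenesis is zero-order with insulin suppression; insulin
    secretion follows a Hill function of plasma glucose; every other
    step is first-order mass action in its substrate pool, optionally
    modulated by insulin.
    """
    fluxes = [
        # dietary inflows (zero order, set by the diet)
        Flux("diet_carb", None, "lG", {"lG": 1.0}, "zero_order",
             diet_key="carb"),
        Flux("diet_fat", None, "lTG", {"lTG": 1.0}, "zero_order",
             diet_key="fat"),
        Flux("diet_chol", None, "lFC", {"lFC": 1.0}, "zero_order",
             diet_key="chol"),
        # intestinal absorption
        _ma("glc_absorption", "lG", "pG"),
        _ma("tg_absorption", "lTG", "pTGc"),
        _ma("chol_absorption", "lFC", "hFC"),
        # fecal excretion
        _ma("fecal_chol", "lFC", "fecC"),
        _ma("fecal_ba", "lBA", "fecBA"),
        # trans-intestinal cholesterol excretion (TICE)
        _ma("tice", "pCv", "lFC"),
        # biliary secretion and enterohepatic reuptake
        _ma("biliary_chol", "hFC", "lFC"),
        _ma("biliary_ba", "hBA", "lBA"),
        _ma("ba_reuptake", "lBA", "hBA"),
        _ma("ba_synthesis", "hFC", "hBA"),
        # hepatic carbohydrate handling
        _ma("hep_glc_uptake", "pG", "hG6P"),
        _ma("hep_glc_output", "hG6P", "pG"),
        Flux("gng", None, "hG6P", {"hG6P": 1.0}, "zero_order",
             modifier="gng"),
        _ma("glycolysis", "hG6P", "hACoA", prod_coef=ACOA_PER_GLC),
        # hepatic lipid handling
        _ma("dnl", "hACoA", "hTG", prod_coef=1.0 / ACOA_PER_TG,
            modifier="dnl"),
        _ma("hep_beta_ox", "hTG", "hACoA", prod_coef=ACOA_PER_TG),
        _ma("chol_synthesis", "hACoA", "hFC", prod_coef=1.0 / ACOA_PER_CHOL),
        _ma("acat", "hFC", "hCE"),
        _ma("ceh", "hCE", "hFC"),
        _ma("hep_fa_uptake", "pFFA", "hTG", prod_coef=1.0 / FA_PER_TG),
        # lipoprotein metabolism
        _ma("vldl_tg_secretion", "hTG", "pTGv"),
        _ma("vldl_c_secretion", "hFC", "pCv"),
        _ma("lpl_vldl", "pTGv", "pFFA", prod_coef=FA_PER_TG),
        _ma("lpl_chylo", "pTGc", "pFFA", prod_coef=FA_PER_TG),
        _ma("remnant_uptake", "pTGc", "hTG"),
        _ma("vldl_tg_uptake", "pTGv", "hTG"),
        _ma("ldl_c_uptake", "pCv", "hFC"),
        _ma("cetp", "pCh", "pCv"),
        _ma("hdl_production", "hFC", "pCh"),
        _ma("hdl_uptake", "pCh", "hFC"),
        # peripheral metabolism
        _ma("per_ffa_uptake", "pFFA", "aTG", prod_coef=1.0 / FA_PER_TG),
        _ma("per_lipolysis", "aTG", "pFFA", prod_coef=FA_PER_TG,
            modifier="lipolysis"),
        _ma("per_beta_ox", "aTG", "aACoA", prod_coef=ACOA_PER_TG),
        _ma("per_glc_uptake", "pG", "aACoA", prod_coef=ACOA_PER_GLC,
            modifier="uptake"),
        # acetyl-CoA oxidation (bookkept in oxC)
        _ma("acoa_ox_hep", "hACoA", "oxC"),
        _ma("acoa_ox_per", "aACoA", "oxC"),
        # insulin turnover
        Flux("ins_secretion", None, "pI", {"pI": 1.0}, "hill"),
        _ma("ins_clearance", "pI", None),
    ]
    return FluxTable(tuple(fluxes))
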