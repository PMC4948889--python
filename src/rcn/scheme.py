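"""Species registry and the 26-process reaction scheme.

State variables (24 total): 20 molecular concentrations plus the four
adhesivity factors sigma.  Fifteen variables are independent (carry ODEs in
the reduced system); nine concentrations are dependent, fixed by five rapid
binding equilibria (processes 1, 2, 6, 8, 11) and the conservation of the
four constitutive molecules (Wnt3a, APC, TCF, axin/GSK-3beta).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

__all__ = [
    "Species",
    "Reaction",
    "SPECIES",
    "INDEPENDENT",
    "DEPENDENT",
    "SIGMA",
    "REACTIONS",
    "RAPID_EQUILIBRIA",
    "CONSERVED_FAMILIES",
    "export_scheme_csv",
]


@dataclass(frozen=True)
class Species:
    name: str
    symbol: str
    independent: bool
    description: str
    is_sigma: bool = False


SPECIES: tuple[Species, ...] = (
    # independent (11 concentrations) --------------------------------------
    Species("bcat", "B", True, "free cytoplasmic beta-catenin"),
    Species("bcat_p", "Bp", True, "phosphorylated beta-catenin"),
    Species("bdc", "D", True,
            "assembled beta-catenin destruction complex (inactive form)"),
    Species("lrp_i", "Li", True, "immature (un-N-glycosylated) LRP5/6"),
    Species("lrp_m", "Lm", True, "mature membrane LRP5/6, unbound"),
    Species("dpagt1_mrna", "X13", True, "DPAGT1 mRNA"),
    Species("gpt", "X14", True, "GPT enzyme (DPAGT1 product)"),
    Species("ecad_er", "E_ER", True, "E-cadherin/beta-catenin complex, ER pool"),
    Species("ecad_m", "E_M", True, "E-cadherin/beta-catenin complex, membrane pool"),
    Species("ecad_erc", "E_ERC", True, "E-cadherin/beta-catenin complex, ERC pool"),
    Species("ecad_aj", "E_AJ", True, "E-cadherin/beta-catenin in adherens junctions"),
    # independent (4 adhesivity factors) -----------------------------------
    Species("sigma_er", "sER", True, "adhesivity of ER E-cadherin", is_sigma=True),
    Species("sigma_m", "sM", True, "adhesivity of membrane E-cadherin", is_sigma=True),
    Species("sigma_erc", "sERC", True, "adhesivity of ERC E-cadherin", is_sigma=True),
    Species("sigma_aj", "sAJ", True, "adhesivity of junctional E-cadherin", is_sigma=True),
    # dependent (9 concentrations) -----------------------------------------
    Species("wnt", "W", False, "free Wnt3a"),
    Species("wnt_lrp", "WL", False, "Wnt3a/LRP5-6 complex"),
    Species("wnt_bdc", "WD", False, "Wnt3a/LRP5-6-bound destruction complex"),
    Species("bdc_act", "Da", False, "activated destruction complex"),
    Species("bdc_bcat", "DB", False, "beta-catenin bound to the active destruction complex"),
    Species("tcf", "T", False, "free TCF"),
    Species("bcat_tcf", "BT", False, "beta-catenin/TCF transcription-factor complex"),
    Species("apc", "APC", False, "free APC"),
    Species("axin_gsk", "AG", False, "free axin/GSK-3beta complex"),
)

INDEPENDENT: tuple[str, ...] = tuple(s.name for s in SPECIES if s.independent)
DEPENDENT: tuple[str, ...] = tuple(s.name for s in SPECIES if not s.independent)
SIGMA: tuple[str, ...] = tuple(s.name for s in SPECIES if s.is_sigma)


@dataclass(frozen=True)
class Reaction:
    rid: int
    category: str  # binding | synthesis | conversion | transcription | transport | aj
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    parameters: tuple[str, ...]
    rapid: bool = False
    description: str = ""


REACTIONS: tuple[Reaction, ...] = (
    Reaction(1, "binding", ("wnt", "lrp_m"), ("wnt_lrp",), ("K1",), rapid=True,
             description="Wnt3a binds mature LRP5/6 (rapid equilibrium)"),
    Reaction(2, "binding", ("wnt_lrp", "bdc"), ("wnt_bdc",), ("K2",), rapid=True,
             description="Wnt3a/LRP engages the destruction complex (rapid equilibrium)"),
    Reaction(3, "binding", ("apc", "axin_gsk"), ("bdc",), ("k3", "km3"),
             description="destruction-complex assembly"),
    Reaction(4, "conversion", ("wnt_bdc",), ("wnt_lrp", "apc", "axin_gsk"), ("k4",),
             description="Wnt-induced disassembly of the receptor-bound complex"),
    Reaction(5, "conversion", ("bcat_p",), (), ("k5",),
             description="degradation of phosphorylated beta-catenin"),
    Reaction(6, "binding", ("bcat", "bdc_act"), ("bdc_bcat",), ("K6",), rapid=True,
             description="beta-catenin binds the active destruction complex (rapid equilibrium)"),
    Reaction(7, "conversion", ("bdc_bcat",), ("bdc_act", "bcat_p"), ("k7",),
             description="phosphorylation of complex-bound beta-catenin"),
    Reaction(8, "conversion", ("bdc",), ("bdc_act",), ("K8",), rapid=True,
             description="destruction-complex activation (rapid equilibrium)"),
    Reaction(9, "synthesis", (), ("bcat",), ("nu9",),
             description="beta-catenin synthesis"),
    Reaction(10, "conversion", ("bcat",), (), ("k10",),
             description="axin-independent beta-catenin degradation"),
    Reaction(11, "binding", ("bcat", "tcf"), ("bcat_tcf",), ("K11",), rapid=True,
             description="beta-catenin/TCF transcription-factor complex (rapid equilibrium)"),
    Reaction(12, "transcription", (), ("dpagt1_mrna",), ("Tmax", "KTmRNA", "n"),
             description="Hill-type DPAGT1 transcription driven by beta-catenin/TCF"),
    Reaction(13, "conversion", ("dpagt1_mrna",), (), ("k13",),
             description="DPAGT1 mRNA degradation"),
    Reaction(14, "synthesis", ("dpagt1_mrna",), ("dpagt1_mrna", "gpt"), ("Pmax",),
             description="GPT translation"),
    Reaction(15, "synthesis", (), ("lrp_i",), ("nu15",),
             description="LRP5/6 synthesis (immature)"),
    Reaction(16, "conversion", ("lrp_i",), ("lrp_m",), ("k16",),
             description="GPT-dependent N-glycosylation and membrane positioning of LRP5/6"),
    Reaction(17, "conversion", ("lrp_i",), (), ("k17",),
             description="degradation of immature LRP5/6"),
    Reaction(18, "conversion", ("lrp_m",), (), ("k18",),
             description="turnover of mature LRP5/6"),
    Reaction(19, "conversion", ("gpt",), (), ("k19",),
             description="GPT degradation"),
    Reaction(20, "synthesis", (), ("ecad_er",), ("nu20", "lam", "KM"),
             description="co-synthesis of E-cadherin with beta-catenin in the ER; "
                         "GPT sets the N-glycosylation extent of the nascent pool"),
    Reaction(21, "transport", ("ecad_er",), ("ecad_m",), ("K21",),
             description="ER exit of the E-cadherin/beta-catenin complex to the membrane"),
    Reaction(22, "transport", ("ecad_m",), ("ecad_erc",), ("k22",),
             description="internalization of membrane E-cadherin into the ERC"),
    Reaction(23, "transport", ("ecad_erc",), ("ecad_m",), ("k23",),
             description="recycling of ERC E-cadherin to the membrane"),
    Reaction(24, "aj", ("ecad_m",), ("ecad_aj",), ("kappa24",),
             description="adhesivity-coupled AJ assembly (forward); disassembly "
                         "internalizes the complex into the ERC (reverse)"),
    Reaction(25, "conversion", ("ecad_erc",), (), ("k25",),
             description="lysosomal degradation of the ERC complex"),
    Reaction(26, "conversion", ("ecad_erc",), ("bcat",), ("k26",),
             description="E-cadherin degradation releasing beta-catenin to the cytoplasm"),
)

RAPID_EQUILIBRIA: tuple[int, ...] = tuple(r.rid for r in REACTIONS if r.rapid)

#: species families whose summed concentration is conserved along any
#: trajectory (the constitutive molecules), mapping total-parameter name to
#: the members holding one copy of that molecule.
CONSERVED_FAMILIES: dict[str, tuple[str, ...]] = {
    "WNT0": ("wnt", "wnt_lrp", "wnt_bdc"),
    "APC0": ("apc", "bdc", "bdc_act", "bdc_bcat", "wnt_bdc"),
    "TCF0": ("tcf", "bcat_tcf"),
    "AXG0": ("axin_gsk", "bdc", "bdc_act", "bdc_bcat", "wnt_bdc"),
}


def export_scheme_csv(path) -> None:
    """Write the machine-readable reaction table (audit export)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "type", "rapid_equilibrium", "reactants", "products",
                    "parameters", "description"])
        for r in REACTIONS:
            w.writerow([r.rid, r.category, int(r.rapid), "+".join(r.reactants),
                        "+".join(r.products), ";".join(r.parameters),
                        r.description])
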