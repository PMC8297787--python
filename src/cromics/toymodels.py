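"""Bespoke minimal stoichiometric models for the shipped scenarios.

These are deliberately small (<= 10 reactions) networks engineered to
reproduce the qualitative exchange topology of the two communities:

* a lactose consumer auxotrophic for methionine that secretes acetate
  and galactose as overflow products (even at zero growth, because ATP
  maintenance forces fermentation);
* an acetate/galactose consumer that secretes methionine in a fixed
  ratio to growth (r_meth mmol per g_DW; r_meth = 0 is the
  non-secreting wild type);
* a glucose/O2 consumer with respiratory and fermentative (acetate
  overflow) routes and an EPS-synthesis reaction that duplicates the
  biomass reaction's precursor costs gram for gram, coupled to growth
  by the yield f_EPS.  With equal per-gram costs the LP growth optimum
  under a fixed substrate supply scales exactly as 1/(1 + f_EPS).

They are not genome-scale models and make no quantitative claim about
specific organisms; coefficients were chosen to give realistic growth
rates (0.5-1.5 h^-1 on saturating substrate) and, for the
cross-feeding pair, a composition fixed point that is reached within
the biomass-doubling capacity of a reduced domain, mirroring the
convergence the full-scale community exhibits.
"""

from __future__ import annotations

from .metabolism import Reaction, ToyStoichModel

__all__ = [
    "toy_lactose_consumer",
    "toy_methionine_secreter",
    "toy_glucose_aerobe",
]

_BIG = 1e4


def toy_lactose_consumer(maintenance: float = 2.0) -> ToyStoichModel:
    """Methionine-auxotroph lactose consumer with overflow secretion.

    Lactose splits into a carbon unit and galactose (secreted);
    fermentation of carbon yields ATP and acetate; biomass requires
    carbon, ATP and imported methionine.  The ATP maintenance demand
    (mmol g_DW^-1 h^-1) keeps acetate/galactose flowing at zero growth.
    """
    return ToyStoichModel(
        name="ecoli_dmetB",
        reactions=[
            Reaction("EX_lac", {"LAC": -1}, lb=-10, ub=0),
            Reaction("EX_meth", {"METH": -1}, lb=-10, ub=0),
            Reaction("EX_ac", {"AC": -1}, lb=0, ub=_BIG),
            Reaction("EX_gal", {"GAL": -1}, lb=0, ub=_BIG),
            Reaction("v_split", {"LAC": -1, "C": 1, "GAL": 1}),
            Reaction("v_ferm", {"C": -1, "AC": 2, "ATP": 4}),
            Reaction("v_maint", {"ATP": -1}),
            Reaction("v_bio", {"C": -8, "ATP": -30, "METH": -0.15}),
        ],
        objective="v_bio",
        exchanges={
            "EX_lac": "lactose",
            "EX_meth": "methionine",
            "EX_ac": "acetate",
            "EX_gal": "galactose",
        },
        maintenance=("v_maint", maintenance),
    )


def toy_methionine_secreter(r_meth: float = 0.5, maintenance: float = 0.1) -> ToyStoichModel:
    """Acetate/galactose consumer secreting methionine in ratio to growth.

    ``r_meth`` (mmol g_DW^-1) couples the methionine-synthesis flux to
    v_bio exactly; 0 gives the non-secreting wild type (meth-), 0.5 the
    secreting mutant (meth+).  Methionine costs 1 C + 1 ATP per mmol.
    """
    name = "senterica_methp" if r_meth > 0 else "senterica_methm"
    return ToyStoichModel(
        name=name,
        reactions=[
            Reaction("EX_ac", {"AC": -1}, lb=-10, ub=0),
            Reaction("EX_gal", {"GAL": -1}, lb=-10, ub=0),
            Reaction("EX_meth", {"METH": -1}, lb=0, ub=_BIG),
            Reaction("v_ac", {"AC": -1, "C": 1}),
            Reaction("v_gal", {"GAL": -1, "C": 2}),
            Reaction("v_cat", {"C": -1, "ATP": 2}),
            Reaction("v_maint", {"ATP": -1}),
            Reaction("v_meth", {"C": -1, "ATP": -1, "METH": 1}),
            Reaction("v_bio", {"C": -17, "ATP": -10}),
        ],
        objective="v_bio",
        exchanges={"EX_ac": "acetate", "EX_gal": "galactose", "EX_meth": "methionine"},
        maintenance=("v_maint", maintenance),
        couplings={"v_meth": r_meth},
    )


def toy_glucose_aerobe(f_eps: float = 0.0, maintenance: float = 0.0) -> ToyStoichModel:
    """Glucose/O2 consumer with overflow acetate and optional EPS yield.

    Respiration (C + 3 O2 -> 12 ATP) dominates when O2 is available;
    under O2 limitation the fermentative route secretes acetate; with
    neither substrate the optimum is v_bio = 0 (an inactive cell).  The
    EPS reaction duplicates the biomass precursor costs and is coupled
    as v_EPS = f_eps * v_bio (g EPS per g_DW), so the growth optimum
    under fixed substrate supply is the f_eps = 0 optimum / (1 + f_eps).
    """
    suffix = "wt" if f_eps == 0 else f"eps{f_eps:g}"
    rxns = [
        Reaction("EX_glc", {"GLC": -1}, lb=-10, ub=0),
        Reaction("EX_o2", {"O2": -1}, lb=-15, ub=0),
        Reaction("EX_ac", {"AC": -1}, lb=-17, ub=_BIG),
        Reaction("v_gly", {"GLC": -1, "C": 2, "ATP": 2}),
        Reaction("v_resp", {"C": -1, "O2": -3, "ATP": 12}),
        Reaction("v_ferm", {"C": -1, "AC": 1, "ATP": 1}),
        Reaction("v_acresp", {"AC": -1, "O2": -2, "ATP": 8}),
        Reaction("v_bio", {"C": -30, "ATP": -100}),
        Reaction("v_eps", {"C": -30, "ATP": -100}),
    ]
    maint = None
    if maintenance > 0:
        rxns.append(Reaction("v_maint", {"ATP": -1}))
        maint = ("v_maint", maintenance)
    return ToyStoichModel(
        name=f"ecoli_{suffix}",
        reactions=rxns,
        objective="v_bio",
        exchanges={"EX_glc": "glucose", "EX_o2": "O2", "EX_ac": "acetate"},
        maintenance=maint,
        couplings={"v_eps": f_eps},
    )
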