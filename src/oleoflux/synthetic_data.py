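"""Deterministic generator of small oleaginous-microbe toy networks.

The toy model reproduces, at ~40 reactions, the structural motifs a
DHA-producer pipeline exercises end to end:

* glucose and glycerol uptake feeding a lumped glycolysis;
* an oxidative pentose phosphate branch (G6PD, PGD) producing NADPH and the
  nucleotide precursor ribulose-5-P;
* a TCA backbone (pyruvate carboxylase, citrate synthase, a lumped oxidative
  leg to malate) with malate and citrate exchanges;
* the three canonical acetyl-CoA sources — pyruvate dehydrogenase (an AND
  complex of two genes), ATP-citrate lyase, acetyl-CoA synthetase — and
  malic enzyme as the anaplerotic NADPH source;
* a lumped PKS reaction, 11 acetyl-CoA + 14 NADPH -> 1 DHA (a C22:6
  acetyl-unit accounting over the iterative KS/KR/DH/ER cycles), with a DHA
  transporter and exchange;
* amino-acid biosynthesis pathways paired with uptake transporters (so the
  genes are essential on minimal medium only), one isozyme pair (hexokinase)
  and a biomass reaction draining amino acids, ribulose-5-P, a lumped lipid
  and ATP.

Every structural ground truth — which genes are essential where, which gap
reactions restore growth on lactose, the analytic carbon bound on DHA yield
— is recorded in a manifest and re-verified at generation time with the
package's own solvers; generation fails loudly if the constructed network
ever stops having the advertised properties.

All randomness (gene-id naming) flows from the single seed, and the emitted
files are byte-identical for identical seeds.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np

from .essentiality import essentiality_screen
from .fba_core import lexicographic_max, parsimonious_fba, solve_fba
from .media import Medium, apply_medium, make_standard_medium
from .model import GPR, MetabolicModel, Metabolite, Reaction, parse_gpr
from .model_io import format_equation, parse_equation, write_model
from .nutrition_scan import check_gap_candidates, supplement_scan

__all__ = ["ToySpec", "GenerationError", "generate_toy_model",
           "candidate_reactions", "write_toy"]

#: growth fraction at which toy DHA ground truths are evaluated; at the full
#: growth optimum the toy LP leaves no slack and wild-type DHA is exactly 0
PRODUCTION_FRACTION = 0.9

#: lumped PKS stoichiometry (acetyl-CoA, NADPH per DHA)
PKS_ACCOA = 11.0
PKS_NADPH = 14.0

# amino-acid pathways in generation order: (code, biomass coefficient)
_AA_TABLE: List[Tuple[str, float]] = [
    ("ala", 0.10), ("cys", 0.05), ("ser", 0.30), ("gly", 0.10), ("thr", 0.10),
]

_SUB = {
    "carb": "carbohydrate metabolism",
    "aa": "amino acid metabolism",
    "lip": "lipid metabolism",
    "nrg": "energy metabolism",
    "nuc": "nucleotide metabolism",
    "tpt": "transport reactions",
    "ex": "exchange reactions",
    "other": "other metabolisms",
}


class GenerationError(RuntimeError):
    """The generated network failed one of its own ground-truth checks."""


@dataclass
class ToySpec:
    seed: int = 0
    include_pks: bool = True
    include_gaps: int = 0  # 0 = no lactose pathway, 1/2 = gaps of that size
    n_amino_acid_pathways: int = 2
    bottleneck: str = "nadph"  # nadph | accoa | none

    def validate(self) -> None:
        if not (1 <= self.n_amino_acid_pathways <= len(_AA_TABLE)):
            raise GenerationError(
                f"n_amino_acid_pathways must be 1..{len(_AA_TABLE)}"
            )
        if self.include_gaps not in (0, 1, 2):
            raise GenerationError(
                "include_gaps must be 0, 1 or 2 (the lactose pathway is 2 "
                "reactions long; more gaps than reactions is contradictory)"
            )
        if self.bottleneck not in ("nadph", "accoa", "none"):
            raise GenerationError("bottleneck must be nadph, accoa or none")


def _gene_namer(seed: int):
    rng = np.random.default_rng(seed)
    taken = set()

    def name(tag: str) -> str:
        while True:
            gid = f"g{tag}_{int(rng.integers(0, 10000)):04d}"
            if gid not in taken:
                taken.add(gid)
                return gid

    return name


def _build(spec: ToySpec) -> Tuple[MetabolicModel, Dict[str, str], dict]:
    k = spec.n_amino_acid_pathways
    aa_used = _AA_TABLE[:k]
    gene = _gene_namer(spec.seed)

    mets: List[Metabolite] = []

    def met(mid: str, comp: str, name: str = "") -> str:
        mets.append(Metabolite(mid, name or mid, comp))
        return mid

    ex_species = ["glc", "glyc", "o2", "nh3", "pi", "so4", "h2o", "h", "co2",
                  "dha", "mal", "cit", "ac", "xyl"]
    names = {"glc": "D-glucose", "glyc": "glycerol", "o2": "oxygen",
             "nh3": "ammonia", "pi": "orthophosphate", "so4": "sulfate",
             "h2o": "water", "h": "proton", "co2": "carbon dioxide",
             "dha": "docosahexaenoate", "mal": "malate", "cit": "citrate",
             "ac": "acetate", "xyl": "xylose", "lac": "lactose"}
    for sp in ex_species:
        met(f"{sp}_e", "e", names.get(sp, sp))
    for sp, _c in aa_used:
        met(f"{sp}_e", "e", sp)
    for mid in ["g6p", "pg6", "ru5p", "pyr", "accoa", "oaa", "cit", "mal",
                "nadph", "nadp", "nadh", "nad", "atp", "adp", "dha", "lip"]:
        met(f"{mid}_c", "c")
    for sp, _c in aa_used:
        met(f"{sp}_c", "c", sp)

    genes: Dict[str, str] = {}  # role tag -> generated gene id

    def g(tag: str) -> str:
        genes[tag] = gene(tag)
        return genes[tag]

    # fixed role order so gene naming is reproducible per seed
    for tag in ["HEX1", "HEX2", "GLK", "EMP", "G6PD", "PGD", "PDC1", "PDC2",
                "PC", "CS", "ACL", "TCA", "ME", "ACS", "OXP", "LIPS", "PKS",
                "DHAt", "MALt", "CITt"]:
        g(tag)
    for sp, _c in aa_used:
        g(sp.upper() + "S")
        g(sp.upper() + "t")
    if spec.include_gaps:
        g("LACH")
        g("GALK")

    rxns: List[Reaction] = []

    def rxn(rid: str, eq: str, sub: str, gpr: str = "",
            lb: float = 0.0, ub: float = 1000.0, name: str = "") -> Reaction:
        stoich, _ = parse_equation(eq, rid)
        r = Reaction(rid, stoich, lb, ub, _SUB[sub],
                     parse_gpr(gpr) if gpr else None, name or rid)
        rxns.append(r)
        return r

    # exchanges ship closed (no uptake); media open them
    for sp in ex_species + [sp for sp, _c in aa_used]:
        rxn(f"EX_{sp}", f"{sp}_e[e] =>", "ex", name=f"Exchange of {names.get(sp, sp)}")

    G = genes
    rxn("DHAt", "dha_c[c] => dha_e[e]", "tpt", G["DHAt"])
    rxn("MALt", "mal_e[e] => mal_c[c]", "tpt", G["MALt"])
    rxn("CITt", "cit_e[e] => cit_c[c]", "tpt", G["CITt"])

    rxn("HEX", "glc_e[e] + atp_c[c] => g6p_c[c] + adp_c[c]", "carb",
        f"{G['HEX1']} or {G['HEX2']}", name="hexokinase (isozymes)")
    rxn("GLYCK", "glyc_e[e] + atp_c[c] + nad_c[c] => 0.5 g6p_c[c] + adp_c[c] + nadh_c[c]",
        "carb", G["GLK"], name="glycerol assimilation (lumped)")
    rxn("GLYCO", "g6p_c[c] + 2 adp_c[c] + 2 nad_c[c] => 2 pyr_c[c] + 2 atp_c[c] + 2 nadh_c[c]",
        "carb", G["EMP"], name="glycolysis (lumped)")
    rxn("G6PD", "g6p_c[c] + nadp_c[c] => pg6_c[c] + nadph_c[c]", "carb",
        G["G6PD"], name="glucose-6-phosphate dehydrogenase")
    rxn("PGD", "pg6_c[c] + nadp_c[c] => ru5p_c[c] + co2_e[e] + nadph_c[c]", "carb",
        G["PGD"], name="phosphogluconate dehydrogenase")
    rxn("PDC", "pyr_c[c] + nad_c[c] => accoa_c[c] + co2_e[e] + nadh_c[c]", "nrg",
        f"{G['PDC1']} and {G['PDC2']}", name="pyruvate dehydrogenase complex")
    rxn("PC", "pyr_c[c] + atp_c[c] + co2_e[e] => oaa_c[c] + adp_c[c]", "nrg",
        G["PC"], name="pyruvate carboxylase")
    rxn("CS", "accoa_c[c] + oaa_c[c] => cit_c[c]", "nrg", G["CS"],
        name="citrate synthase")
    rxn("ACL", "cit_c[c] + atp_c[c] => accoa_c[c] + oaa_c[c] + adp_c[c]", "lip",
        G["ACL"], name="ATP-citrate lyase")
    rxn("TCA", "cit_c[c] + 2 nad_c[c] => mal_c[c] + 2 co2_e[e] + 2 nadh_c[c]", "nrg",
        G["TCA"], name="TCA oxidative leg (lumped)")
    rxn("ME", "mal_c[c] + nadp_c[c] => pyr_c[c] + co2_e[e] + nadph_c[c]", "nrg",
        G["ME"], name="malic enzyme")
    rxn("ACS", "ac_e[e] + atp_c[c] => accoa_c[c] + adp_c[c]", "lip", G["ACS"],
        name="acetyl-CoA synthetase")
    rxn("OXPHOS", "nadh_c[c] + 0.5 o2_e[e] + 2 adp_c[c] => nad_c[c] + 2 atp_c[c]",
        "nrg", G["OXP"], name="oxidative phosphorylation (lumped)")
    rxn("ATPM", "atp_c[c] => adp_c[c]", "nrg", name="ATP maintenance sink")
    rxn("LIPS", "3 accoa_c[c] + nadph_c[c] => lip_c[c] + nadp_c[c]", "lip",
        G["LIPS"], name="bulk lipid synthesis (lumped)")
    if spec.include_pks:
        rxn("PKS",
            f"{_num(PKS_ACCOA)} accoa_c[c] + {_num(PKS_NADPH)} nadph_c[c] => "
            f"dha_c[c] + {_num(PKS_NADPH)} nadp_c[c]",
            "lip", G["PKS"], name="PKS DHA synthesis (lumped KS/KR/DH/ER cycles)")

    for sp, _coef in aa_used:
        extra = " + so4_e[e]" if sp == "cys" else ""
        rxn(sp.upper() + "S", f"pyr_c[c] + nh3_e[e]{extra} => {sp}_c[c]", "aa",
            G[sp.upper() + "S"], name=f"{sp} biosynthesis (lumped)")
        rxn(sp.upper() + "t", f"{sp}_e[e] => {sp}_c[c]", "tpt", G[sp.upper() + "t"],
            name=f"{sp} uptake")

    biomass_terms = [f"{_num(c)} {sp}_c[c]" for sp, c in aa_used]
    biomass_terms += ["0.3 ru5p_c[c]", "0.6 lip_c[c]", "6 atp_c[c]", "0.3 pi_e[e]"]
    rxn("BIOMASS", " + ".join(biomass_terms) + " => 6 adp_c[c]", "nrg",
        name="biomass assembly")
    rxns[-1].subsystem = _SUB["nuc"]  # counted under nucleotide/biomass bucket

    # lactose pathway: 2 reactions; include_gaps removes the last 1 or 2
    gap_info: Optional[dict] = None
    if spec.include_gaps:
        mets.append(Metabolite("lac_e", names["lac"], "e"))
        mets.append(Metabolite("gal_c", "galactose", "c"))
        rxn("EX_lac", "lac_e[e] =>", "ex", name="Exchange of lactose")
        lach = Reaction("LACH", parse_equation("lac_e[e] => glc_e[e] + gal_c[c]", "LACH")[0],
                        0.0, 1000.0, _SUB["other"], parse_gpr(G["LACH"]),
                        "lactose galactohydrolase")
        galk = Reaction("GALK", parse_equation("gal_c[c] + atp_c[c] => g6p_c[c] + adp_c[c]", "GALK")[0],
                        0.0, 1000.0, _SUB["carb"], parse_gpr(G["GALK"]),
                        "galactose assimilation")
        removed = [lach] if spec.include_gaps == 1 else [lach, galk]
        kept = [] if spec.include_gaps == 2 else [galk]
        rxns.extend(kept)
        gap_info = {
            "source_exchange": "EX_lac",
            "uptake": 1.0,
            "removed": [r.id for r in removed],
            "minimal_fix": [r.id for r in removed],
            "candidates": {
                r.id: {"equation": None, "gpr": r.gpr.to_string(), "name": r.name,
                       "subsystem": r.subsystem}
                for r in removed
            },
        }

    model = MetabolicModel(
        id=f"toy_oleo_seed{spec.seed}",
        metabolites=mets,
        reactions=rxns,
        genes=sorted(genes.values()),
        objective_id="BIOMASS",
        dha_exchange_id="EX_dha",
    )

    # serialise candidate equations now that the model knows all metabolites
    if gap_info is not None:
        tmp = model.copy()
        for r in ([lach] if spec.include_gaps == 1 else [lach, galk]):
            tmp.reactions.append(r)
        for r in ([lach] if spec.include_gaps == 1 else [lach, galk]):
            gap_info["candidates"][r.id]["equation"] = format_equation(r, tmp)

    caps = {}
    if spec.bottleneck == "nadph":
        # NADPH beyond the growth-coupled PPP flux can only come from malic
        # enzyme; capping the TCA leg that feeds it makes NADPH the binding
        # constraint on DHA at held growth
        model.reaction("TCA").upper_bound = 0.2
        caps["TCA"] = 0.2
    elif spec.bottleneck == "accoa":
        mg = make_standard_medium("MG_glucose", model)
        ref = parsimonious_fba(apply_medium(model, mg))
        cap = float(ref.fluxes["PDC"])
        model.reaction("PDC").upper_bound = cap
        caps["PDC"] = cap

    model.validate()
    manifest = {
        "spec": asdict(spec),
        "genes": genes,
        "caps": caps,
        "gap": gap_info,
        "deadend_exchange": "EX_xyl",
        "pks": {"accoa_per_dha": PKS_ACCOA, "nadph_per_dha": PKS_NADPH},
        "production_fraction": PRODUCTION_FRACTION,
        "amino_acids": [sp for sp, _c in aa_used],
    }
    return model, genes, manifest


def _num(x: float) -> str:
    return format(float(x), ".10g")


def _expected_essentials(spec: ToySpec, genes: Dict[str, str]):
    both = {genes[t] for t in ("EMP", "PDC1", "PDC2", "G6PD", "PGD", "LIPS", "OXP")}
    only_mg = {genes[sp.upper() + "S"] for sp, _c in _AA_TABLE[: spec.n_amino_acid_pathways]}
    partial_ye = {genes["SERS"]} if spec.n_amino_acid_pathways >= 3 else set()
    return both, only_mg, partial_ye


def _verify(model: MetabolicModel, media: Dict[str, Medium], spec: ToySpec,
            genes: Dict[str, str], manifest: dict) -> None:
    def check(cond: bool, msg: str) -> None:
        if not cond:
            raise GenerationError(f"toy ground truth violated: {msg}")

    n = len(model.reactions)
    check(20 <= n <= 45, f"reaction count {n} outside expected range")

    growth = {}
    for name, medium in media.items():
        sol = solve_fba(apply_medium(model, medium))
        check(sol.optimal and sol.objective_value > 1e-6, f"no growth in {name}")
        growth[name] = sol.objective_value
    check(growth["MG_glycerol"] < growth["MG_glucose"],
          "glycerol growth should be below glucose growth")
    check(growth["YE"] >= growth["MG_glucose"] - 1e-9,
          "amino-acid supplementation should not slow growth")
    manifest["growth"] = growth

    mg_sol = solve_fba(apply_medium(model, media["MG_glucose"]))
    check(abs(mg_sol.fluxes["EX_glc"] + 1.4) < 1e-6,
          "glucose uptake should be saturated at the MG optimum")
    manifest["glucose_uptake_at_optimum"] = -mg_sol.fluxes["EX_glc"]

    if spec.include_pks:
        screen_media = {"MG_glucose": media["MG_glucose"], "YE": media["YE"]}
        result = essentiality_screen(model, screen_media)
        both, only_mg, partial_ye = _expected_essentials(spec, genes)
        check(result.essential_in_all() == both,
              f"essential-in-both set {sorted(result.essential_in_all())} != expected {sorted(both)}")
        check(result.essential_only_in("MG_glucose") == only_mg,
              "essential-only-in-MG set mismatch")
        df = result.records
        ye_partial = set(df[(df["medium"] == "YE") & (df["class"] == "partially_essential")]["gene"])
        check(ye_partial == partial_ye, "partially-essential-in-YE set mismatch")
        for tag in ("HEX1", "HEX2", "PKS"):
            klass = df[(df["gene"] == genes[tag]) & (df["medium"] == "MG_glucose")]["class"].iloc[0]
            check(klass == "non_essential", f"{tag} should be non-essential (isozyme/product-only)")
        manifest["essential_in_both"] = sorted(both)
        manifest["essential_only_MG"] = sorted(only_mg)
        manifest["partially_essential_YE"] = sorted(partial_ye)

        # PKS deletion kills product formation but not growth
        from .essentiality import delete_gene  # local import avoids cycle at module load

        no_pks = delete_gene(apply_medium(model, media["MG_glucose"]), genes["PKS"])
        check(solve_fba(no_pks, "EX_dha").objective_value < 1e-9,
              "PKS knockout should abolish DHA production")
        ratio = solve_fba(no_pks).objective_value / growth["MG_glucose"]
        check(abs(ratio - 1.0) < 1e-6, "PKS knockout should leave growth unchanged")

        # analytic carbon bound: 6 C per glucose at 1.4 vs 22 C per DHA
        bound = 6.0 * 1.4 / 22.0
        max_dha = solve_fba(apply_medium(model, media["MG_glucose"]), "EX_dha").objective_value
        check(max_dha <= bound + 1e-6, "DHA exceeded the analytic carbon yield bound")
        manifest["dha_carbon_yield_bound"] = bound
        manifest["max_dha_unconstrained_growth"] = max_dha

        frac = PRODUCTION_FRACTION
        dha = {}
        for name in ("MG_glucose", "YE"):
            conditioned = apply_medium(model, media[name])
            _g, prod, _fd = lexicographic_max(conditioned, "BIOMASS", "EX_dha", frac)
            check(prod > 1e-9, f"wild-type DHA at fraction {frac} should be positive in {name}")
            dha[f"wild_{name}"] = prod
        if spec.bottleneck == "nadph":
            res = supplement_scan(model, media["YE"], [("EX_mal", 1.0)], "EX_dha", frac)
            check(res[0].percent_change > 1.0,
                  "malate should relieve the NADPH bottleneck and raise DHA")
            dha["malate_gain_pct"] = res[0].percent_change
        if spec.bottleneck == "accoa":
            res = supplement_scan(model, media["YE"], [("EX_cit", 1.0)], "EX_dha", frac)
            check(res[0].percent_change > 1.0,
                  "citrate should relieve the acetyl-CoA bottleneck and raise DHA")
            dha["citrate_gain_pct"] = res[0].percent_change
        manifest["dha"] = dha
    else:
        sol = solve_fba(apply_medium(model, media["MG_glucose"]), "EX_dha")
        check(sol.objective_value < 1e-9, "no PKS: DHA production must be zero")

    if manifest["gap"] is not None:
        gap = manifest["gap"]
        base = media["MG_glucose"].without(["EX_glc"])
        lac = (gap["source_exchange"], "carbon", gap["uptake"])
        no_growth = solve_fba(
            apply_medium(model, base.with_bound("EX_lac", -gap["uptake"]))
        ).objective_value
        check(no_growth < 1e-9, "gapped model should not grow on lactose")
        found = check_gap_candidates(model, candidate_reactions(manifest), lac, base)
        check(sorted(found) == sorted(gap["minimal_fix"]),
              f"gap fix {found} != expected {gap['minimal_fix']}")


def candidate_reactions(manifest: dict) -> List[Reaction]:
    """Reconstruct the gap candidate reactions recorded in a toy manifest."""
    gap = manifest.get("gap")
    if not gap:
        return []
    out = []
    for rid, info in gap["candidates"].items():
        stoich, _ = parse_equation(info["equation"], rid)
        out.append(
            Reaction(rid, stoich, 0.0, 1000.0, info["subsystem"],
                     parse_gpr(info["gpr"]) if info["gpr"] else None, info["name"])
        )
    return out


def generate_toy_model(
    spec: Optional[ToySpec] = None,
    verify: bool = True,
) -> Tuple[MetabolicModel, Dict[str, Medium], dict]:
    """Build the toy model, its standard media and the ground-truth manifest.

    With ``verify`` (default) every manifest claim is re-derived with the
    package's own solvers; a violation raises :class:`GenerationError`.
    """
    spec = spec or ToySpec()
    spec.validate()
    model, genes, manifest = _build(spec)
    media = {
        kind: make_standard_medium(kind, model)
        for kind in ("MG_glucose", "MG_glycerol", "YE")
    }
    manifest["media"] = {
        name: {rid: list(b) for rid, b in sorted(m.bounds.items())}
        for name, m in media.items()
    }
    manifest["model"] = model.summary()
    if verify:
        _verify(model, media, spec, genes, manifest)
    return model, media, manifest


def write_toy(
    outdir: Union[str, Path],
    spec: Optional[ToySpec] = None,
    verify: bool = True,
) -> dict:
    """Emit SBML + tabular model, media JSON and manifest JSON to *outdir*."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model, media, manifest = generate_toy_model(spec, verify=verify)
    write_model(model, outdir / "model.tsv", format="tabular")
    write_model(model, outdir / "model.xml", format="sbml")
    for name, medium in media.items():
        medium.to_json(outdir / f"medium_{name}.json")
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
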