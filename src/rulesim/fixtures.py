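"""Programmatic generation of test models.

Three families:

* **toys** with closed-form or exactly enumerable behavior (two-species
  binding equilibrium, isomerization, homodimerization, multisite
  phosphorylation with 2^k phosphoforms, unbounded chain polymerization,
  and a cooperative two-ligand receptor whose binding cycle carries a
  nontrivial detailed-balance constraint);
* a **reduced ERBB model**: an original, authored model of EGF/HRG-driven
  EGFR/ERBB3 signaling — ligand binding, ligand-dependent dimerization,
  transphosphorylation of the 13 receptor tyrosines, SHC1/GRB2/SOS1/GAB1/
  PI3K adapter recruitment (tier 1), plus per-site dephosphorylation, a
  Ras-RAF-MEK-ERK and PI3K-Akt backbone and an ERK-to-SOS1 negative
  feedback (tier 2).  It is *not* a transcription of any published model
  file; it is a synthetic stand-in whose structure mirrors the classic
  ERBB adapter-recruitment picture, and its manifest says so;
* **random models** for property-based round-trip and matching tests.

Every generated model ships with a :class:`FixtureManifest` whose counts
are recomputed from the model itself, so manifest and model cannot drift.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import bngl
from .core import Compartment, Model, validate_model
from .ensemble import convert_concentration
from .trajectory import Addition, Protocol

TOY_NAMES = ("binding", "isomerization", "dimerization", "multisite_phospho",
             "chain", "cooperative")

EGFR_SHC1_SITES = ("y1148", "y1173")
EGFR_GRB2_SITES = ("y1068", "y1086", "y992")
EGFR_DUAL_SITE = "y1114"
ERBB3_PI3K_SITES = ("y1035", "y1178", "y1203", "y1241", "y1257", "y1270")
ERBB3_SHC1_SITE = "y1328"


@dataclass
class FixtureManifest:
    name: str
    counts: dict[str, int] = field(default_factory=dict)
    rule_groups: dict[str, list[str]] = field(default_factory=dict)
    binding_edges: list[tuple] = field(default_factory=list)
    inert_rules: list[str] = field(default_factory=list)
    notes: str = ""
    synthetic: bool = True

    def matches(self, model: Model) -> bool:
        return self.counts == _count(model)


def _count(model: Model) -> dict[str, int]:
    return {
        "molecule_types": len(model.molecule_types),
        "rules": len(model.rules),
        "parameters": len(model.parameters),
        "observables": len(model.observables),
        "seed_species": len(model.seed_species),
    }


def _finish(name: str, text: str, rule_groups=None, binding_edges=None,
            notes: str = "") -> tuple[Model, FixtureManifest]:
    model = bngl.parse_model(text)
    errors = [d for d in validate_model(model) if d.severity == "error"]
    if errors:  # pragma: no cover - authoring bug
        raise AssertionError(f"fixture {name} invalid: {errors}")
    manifest = FixtureManifest(name, _count(model), rule_groups or {},
                               binding_edges or [], notes=notes)
    return model, manifest


# ---------------------------------------------------------------------------
# Toys

def build_toy(name: str, **kw) -> Model:
    model, _ = build_toy_with_manifest(name, **kw)
    return model


def build_toy_with_manifest(name: str, **kw) -> tuple[Model, FixtureManifest]:
    if name == "binding":
        nA = kw.get("nA", 100)
        nB = kw.get("nB", 100)
        kon = kw.get("kon", 1e-3)
        koff = kw.get("koff", 0.05)
        text = f"""
begin parameters
  kon {kon}
  koff {koff}
end parameters
begin molecule types
  A(b)
  B(a)
end molecule types
begin seed species
  A(b) {nA}
  B(a) {nB}
end seed species
begin observables
  Molecules AB A(b!1).B(a!1)
  Molecules freeA A(b)
  Molecules freeB B(a)
end observables
begin reaction rules
  bind: A(b) + B(a) <-> A(b!1).B(a!1) kon, koff
end reaction rules
"""
        return _finish("binding", text,
                       {"binding": ["bind_fwd", "bind_rev"]},
                       [(("A", "b"), ("B", "a"))],
                       notes="3-species network; equilibrium AB solves the "
                             "mass-action quadratic")
    if name == "isomerization":
        n = kw.get("n", 50)
        kf = kw.get("kf", 0.1)
        kr = kw.get("kr", 0.1)
        text = f"""
begin parameters
  kf {kf}
  kr {kr}
end parameters
begin molecule types
  A(s~X~Y)
end molecule types
begin seed species
  A(s~X) {n}
end seed species
begin observables
  Molecules inX A(s~X!?)
  Molecules inY A(s~Y!?)
end observables
begin reaction rules
  iso: A(s~X) <-> A(s~Y) kf, kr
end reaction rules
"""
        return _finish("isomerization", text,
                       notes="two-state flip; equal rates give mean "
                             "fraction 1/2 in each state")
    if name == "dimerization":
        n = kw.get("n", 60)
        kon = kw.get("kon", 1e-3)
        koff = kw.get("koff", 0.1)
        text = f"""
begin parameters
  kon {kon}
  koff {koff}
end parameters
begin molecule types
  A(b)
end molecule types
begin seed species
  A(b) {n}
end seed species
begin observables
  Molecules dimer A(b!1).A(b!1)
  Molecules freeA A(b)
end observables
begin reaction rules
  dim: A(b) + A(b) <-> A(b!1).A(b!1) kon, koff
end reaction rules
"""
        return _finish("dimerization", text,
                       notes="homotypic A+A rule exercising the symmetry "
                             "factor 2")
    if name == "multisite_phospho":
        k = kw.get("n_sites", 3)
        n = kw.get("nR", 40)
        kp = kw.get("kphos", 0.05)
        kd = kw.get("kdeph", 0.05)
        sites = [f"s{i + 1}" for i in range(k)]
        comps = ",".join(f"{s}~U~P" for s in sites)
        seed = ",".join(f"{s}~U" for s in sites)
        rules = "\n".join(
            f"  phos_{s}: R({s}~U) -> R({s}~P) kp\n"
            f"  deph_{s}: R({s}~P) -> R({s}~U) kd"
            for s in sites)
        obs = "\n".join(f"  Molecules p_{s} R({s}~P!?)" for s in sites)
        text = f"""
begin parameters
  kp {kp}
  kd {kd}
end parameters
begin molecule types
  R({comps})
end molecule types
begin seed species
  R({seed}) {n}
end seed species
begin observables
{obs}
end observables
begin reaction rules
{rules}
end reaction rules
"""
        return _finish("multisite_phospho", text,
                       notes=f"{k} independent sites -> 2^{k} = {2 ** k} "
                             "phosphoforms; each site relaxes as an "
                             "independent telegraph process")
    if name == "chain":
        n = kw.get("n", 30)
        kon = kw.get("kon", 1e-3)
        koff = kw.get("koff", 0.01)
        text = f"""
begin parameters
  kon {kon}
  koff {koff}
end parameters
begin molecule types
  M(l,r)
end molecule types
begin seed species
  M(l,r) {n}
end seed species
begin observables
  Molecules bonds M(r!1).M(l!1)
  Molecules freeM M(l,r)
end observables
begin reaction rules
  grow: M(r) + M(l) <-> M(r!1).M(l!1) kon, koff
end reaction rules
"""
        return _finish("chain", text,
                       notes="head-to-tail polymerization; the implied "
                             "network (one species per chain length) is "
                             "unbounded")
    if name == "cooperative":
        text = f"""
begin parameters
  kon1 {kw.get('kon1', 1e-3)}
  koff1 {kw.get('koff1', 0.1)}
  kon1c {kw.get('kon1c', 1e-3)}
  koff1c {kw.get('koff1c', 0.1)}
  kon2 {kw.get('kon2', 1e-3)}
  koff2 {kw.get('koff2', 0.1)}
  kon2c {kw.get('kon2c', 1e-3)}
  koff2c {kw.get('koff2c', 0.1)}
end parameters
begin molecule types
  R(a,b)
  L1(r)
  L2(r)
end molecule types
begin seed species
  R(a,b) {kw.get('nR', 50)}
  L1(r) {kw.get('nL', 50)}
  L2(r) {kw.get('nL', 50)}
end seed species
begin observables
  Molecules RL1 L1(r!1).R(a!1)
  Molecules RL2 L2(r!1).R(b!1)
end observables
begin reaction rules
  b1: L1(r) + R(a,b) <-> L1(r!1).R(a!1,b) kon1, koff1
  b1c: L1(r) + R(a,b!+) <-> L1(r!1).R(a!1,b!+) kon1c, koff1c
  b2: L2(r) + R(b,a) <-> L2(r!1).R(b!1,a) kon2, koff2
  b2c: L2(r) + R(b,a!+) <-> L2(r!1).R(b!1,a!+) kon2c, koff2c
end reaction rules
"""
        return _finish("cooperative", text,
                       notes="context-dependent two-ligand binding; the "
                             "R/RL1/RL2/RL1L2 cycle imposes the "
                             "detailed-balance constraint "
                             "K1*K2c = K2*K1c")
    raise ValueError(f"unknown toy {name!r}; choose from {TOY_NAMES}")


# ---------------------------------------------------------------------------
# Reduced ERBB model

DEFAULT_ERBB_COPIES = {
    "EGFR": 6000, "ERBB3": 3000, "SHC1": 6000, "GRB2": 10000,
    "SOS1": 2000, "GAB1": 2000, "PI3K": 4000,
    "RAS": 10000, "RAF": 4000, "MEK": 6000, "ERK": 6000, "AKT": 6000,
}

# Nominal values chosen from within the feasible class ranges so that
# receptor activation and adapter recruitment are visible within minutes of
# simulated time at the reduced copy numbers above: association at the
# diffusion-limited end, slow dissociation, fast kinase / slow phosphatase.
DEFAULT_ERBB_PARAMS = {
    "kon_lig": 1e-5, "koff_lig": 1e-2,
    "kon_dim": 1e-5, "koff_dim": 1e-2,
    "kon_ad": 1e-5, "koff_ad": 1e-2,
    "kphos": 1e-1, "kdephos": 1e-3, "kcat2": 1e-5,
}


@dataclass
class ErbbConfig:
    tier: int = 2
    copies: dict[str, int] = field(default_factory=dict)
    params: dict[str, float] = field(default_factory=dict)
    ex_volume_l: float = 1e-12      # extracellular volume, litres
    cyto_volume_l: float = 1e-12


def build_erbb_mini(config: Optional[ErbbConfig] = None) -> Model:
    model, _ = build_erbb_mini_with_manifest(config)
    return model


def build_erbb_mini_with_manifest(config: Optional[ErbbConfig] = None) \
        -> tuple[Model, FixtureManifest]:
    cfg = config or ErbbConfig()
    if cfg.tier not in (1, 2):
        raise ValueError("tier must be 1 or 2")
    copies = {**DEFAULT_ERBB_COPIES, **cfg.copies}
    params = {**DEFAULT_ERBB_PARAMS, **cfg.params}

    egfr_sites = EGFR_SHC1_SITES + EGFR_GRB2_SITES + (EGFR_DUAL_SITE,)
    erbb3_sites = ERBB3_PI3K_SITES + (ERBB3_SHC1_SITE,)

    P = [f"  {k} {v}" for k, v in params.items()]
    if cfg.tier == 1:
        P = [p for p in P if not any(x in p for x in ("kdephos", "kcat2"))]

    types = [
        "  EGF(r)@Ex",
        "  HRG(r)@Ex",
        "  EGFR(l,d," + ",".join(f"{s}~U~P" for s in sorted(egfr_sites)) + ")@M",
        "  ERBB3(l,d," + ",".join(f"{s}~U~P" for s in sorted(erbb3_sites)) + ")@M",
        "  SHC1(ptb,y317~U~P)@C",
        "  GRB2(sh2,sh3n,sh3c)@C",
        "  SOS1(pr" + (",s1134~U~P" if cfg.tier >= 2 else "") + ")@C",
        "  GAB1(pr)@C",
        "  PI3K(sh2)@C",
    ]
    seeds = [
        "  EGFR(l,d," + ",".join(f"{s}~U" for s in sorted(egfr_sites)) +
        f") {copies['EGFR']}",
        "  ERBB3(l,d," + ",".join(f"{s}~U" for s in sorted(erbb3_sites)) +
        f") {copies['ERBB3']}",
        f"  SHC1(ptb,y317~U) {copies['SHC1']}",
        f"  GRB2(sh2,sh3n,sh3c) {copies['GRB2']}",
        "  SOS1(pr" + (",s1134~U" if cfg.tier >= 2 else "") +
        f") {copies['SOS1']}",
        f"  GAB1(pr) {copies['GAB1']}",
        f"  PI3K(sh2) {copies['PI3K']}",
    ]

    groups: dict[str, list[str]] = {}

    def grp(gname, rname):
        groups.setdefault(gname, []).append(rname)

    rules = []

    def rule(gname, line, reversible=True):
        rname = line.split(":")[0].strip()
        rules.append("  " + line)
        base = rname
        if reversible:
            grp(gname, base + "_fwd")
            grp(gname, base + "_rev")
        else:
            grp(gname, base)

    rule("ligand_binding",
         "lig_egf: EGF(r) + EGFR(l) <-> EGF(r!1).EGFR(l!1) kon_lig, koff_lig")
    rule("ligand_binding",
         "lig_hrg: HRG(r) + ERBB3(l) <-> HRG(r!1).ERBB3(l!1) kon_lig, koff_lig")
    rule("dimerization",
         "dim_ee: EGFR(l!+,d) + EGFR(l!+,d) <-> "
         "EGFR(l!+,d!1).EGFR(l!+,d!1) kon_dim, koff_dim")
    rule("dimerization",
         "dim_e3: EGFR(l!+,d) + ERBB3(l!+,d) <-> "
         "EGFR(l!+,d!1).ERBB3(l!+,d!1) kon_dim, koff_dim")
    for s in sorted(egfr_sites):
        rule("transphosphorylation",
             f"tp_egfr_{s}@enzyme=EGFR: EGFR(d!+,{s}~U) -> "
             f"EGFR(d!+,{s}~P) kphos", reversible=False)
    for s in sorted(erbb3_sites):
        rule("transphosphorylation",
             f"tp_erbb3_{s}@enzyme=EGFR: ERBB3(d!+,{s}~U) -> "
             f"ERBB3(d!+,{s}~P) kphos", reversible=False)
    for s in sorted(EGFR_SHC1_SITES + (EGFR_DUAL_SITE,)):
        rule("adapter_recruitment",
             f"rec_shc1_{s}: SHC1(ptb) + EGFR({s}~P) <-> "
             f"SHC1(ptb!1).EGFR({s}~P!1) kon_ad, koff_ad")
    rule("adapter_recruitment",
         f"rec_shc1_{ERBB3_SHC1_SITE}: SHC1(ptb) + ERBB3({ERBB3_SHC1_SITE}~P)"
         f" <-> SHC1(ptb!1).ERBB3({ERBB3_SHC1_SITE}~P!1) kon_ad, koff_ad")
    for s in sorted(EGFR_GRB2_SITES + (EGFR_DUAL_SITE,)):
        rule("adapter_recruitment",
             f"rec_grb2_{s}: GRB2(sh2) + EGFR({s}~P) <-> "
             f"GRB2(sh2!1).EGFR({s}~P!1) kon_ad, koff_ad")
    for s in sorted(ERBB3_PI3K_SITES):
        rule("adapter_recruitment",
             f"rec_pi3k_{s}: PI3K(sh2) + ERBB3({s}~P) <-> "
             f"PI3K(sh2!1).ERBB3({s}~P!1) kon_ad, koff_ad")
    rule("adapter_phosphorylation",
         "shc1_phos@enzyme=EGFR: SHC1(ptb!+,y317~U) -> SHC1(ptb!+,y317~P) "
         "kphos", reversible=False)
    rule("adapter_recruitment",
         "grb2_shc1: GRB2(sh2) + SHC1(y317~P) <-> "
         "GRB2(sh2!1).SHC1(y317~P!1) kon_ad, koff_ad")
    sos1_ctx = ",s1134~U" if cfg.tier >= 2 else ""
    rule("adapter_recruitment",
         f"sos1_grb2: SOS1(pr{sos1_ctx}) + GRB2(sh3n) <-> "
         f"SOS1(pr!1{sos1_ctx}).GRB2(sh3n!1) kon_ad, koff_ad")
    rule("adapter_recruitment",
         "gab1_grb2: GAB1(pr) + GRB2(sh3c) <-> "
         "GAB1(pr!1).GRB2(sh3c!1) kon_ad, koff_ad")

    obs = []
    for s in sorted(egfr_sites):
        obs.append(f"  Molecules pEGFR_{s} EGFR({s}~P!?)")
    for s in sorted(erbb3_sites):
        obs.append(f"  Molecules pERBB3_{s} ERBB3({s}~P!?)")
    obs.append("  Molecules pSHC1_y317 SHC1(y317~P!?)")

    if cfg.tier >= 2:
        types += [
            "  RAS(gs~D~T)@M",
            "  RAF(s338~U~P)@C",
            "  MEK(s218~U~P)@C",
            "  ERK(t185~U~P)@C",
            "  AKT(t308~U~P)@C",
        ]
        seeds += [
            f"  RAS(gs~D) {copies['RAS']}",
            f"  RAF(s338~U) {copies['RAF']}",
            f"  MEK(s218~U) {copies['MEK']}",
            f"  ERK(t185~U) {copies['ERK']}",
            f"  AKT(t308~U) {copies['AKT']}",
        ]
        for s in sorted(egfr_sites):
            rule("dephosphorylation",
                 f"dp_egfr_{s}: EGFR({s}~P) -> EGFR({s}~U) kdephos",
                 reversible=False)
        for s in sorted(erbb3_sites):
            rule("dephosphorylation",
                 f"dp_erbb3_{s}: ERBB3({s}~P) -> ERBB3({s}~U) kdephos",
                 reversible=False)
        rule("dephosphorylation",
             "dp_shc1: SHC1(y317~P) -> SHC1(y317~U) kdephos",
             reversible=False)
        backbone = [
            ("act_ras@enzyme=SOS1",
             "RAS(gs~D) + SOS1(pr!+) -> RAS(gs~T) + SOS1(pr!+) kcat2"),
            ("act_raf@enzyme=RAS",
             "RAF(s338~U) + RAS(gs~T) -> RAF(s338~P) + RAS(gs~T) kcat2"),
            ("act_mek@enzyme=RAF",
             "MEK(s218~U) + RAF(s338~P) -> MEK(s218~P) + RAF(s338~P) kcat2"),
            ("act_erk@enzyme=MEK",
             "ERK(t185~U) + MEK(s218~P) -> ERK(t185~P) + MEK(s218~P) kcat2"),
            ("act_akt@enzyme=PI3K",
             "AKT(t308~U) + PI3K(sh2!+) -> AKT(t308~P) + PI3K(sh2!+) kcat2"),
            ("fb_sos1@enzyme=ERK",
             "SOS1(s1134~U) + ERK(t185~P) -> SOS1(s1134~P) + ERK(t185~P) "
             "kcat2"),
        ]
        for rname, body in backbone:
            rule("kinase_cascade", f"{rname}: {body}", reversible=False)
        for rname, body in [
                ("deact_ras", "RAS(gs~T) -> RAS(gs~D) kdephos"),
                ("dp_raf", "RAF(s338~P) -> RAF(s338~U) kdephos"),
                ("dp_mek", "MEK(s218~P) -> MEK(s218~U) kdephos"),
                ("dp_erk", "ERK(t185~P) -> ERK(t185~U) kdephos"),
                ("dp_akt", "AKT(t308~P) -> AKT(t308~U) kdephos"),
                ("dp_sos1", "SOS1(s1134~P) -> SOS1(s1134~U) kdephos")]:
            rule("dephosphorylation", f"{rname}: {body}", reversible=False)
        obs += [
            "  Molecules pSOS1_s1134 SOS1(s1134~P!?)",
            "  Molecules RAS_GTP RAS(gs~T!?)",
            "  Molecules pRAF_s338 RAF(s338~P!?)",
            "  Molecules pMEK_s218 MEK(s218~P!?)",
            "  Molecules pERK_t185 ERK(t185~P!?)",
            "  Molecules pAKT_t308 AKT(t308~P!?)",
        ]

    text = "\n".join(
        ["begin parameters"] + P + ["end parameters",
         "begin compartments",
         f"  Ex 3 {cfg.ex_volume_l}",
         "  M 2 1.0",
         f"  C 3 {cfg.cyto_volume_l}",
         f"  En 3 {cfg.ex_volume_l / 5}",
         "end compartments",
         "begin molecule types"] + types + ["end molecule types",
         "begin seed species"] + seeds + ["end seed species",
         "begin observables"] + obs + ["end observables",
         "begin reaction rules"] + rules + ["end reaction rules"])

    binding_edges = [
        (("EGF", "r"), ("EGFR", "l")),
        (("HRG", "r"), ("ERBB3", "l")),
        (("EGFR", "d"), ("EGFR", "d")),
        (("EGFR", "d"), ("ERBB3", "d")),
        (("GRB2", "sh2"), ("SHC1", "y317")),
        (("GRB2", "sh3n"), ("SOS1", "pr")),
        (("GAB1", "pr"), ("GRB2", "sh3c")),
    ]
    binding_edges += [(("EGFR", s), ("SHC1", "ptb"))
                      for s in sorted(EGFR_SHC1_SITES + (EGFR_DUAL_SITE,))]
    binding_edges += [(("ERBB3", ERBB3_SHC1_SITE), ("SHC1", "ptb"))]
    binding_edges += [(("EGFR", s), ("GRB2", "sh2"))
                      for s in sorted(EGFR_GRB2_SITES + (EGFR_DUAL_SITE,))]
    binding_edges += [(("ERBB3", s), ("PI3K", "sh2"))
                      for s in sorted(ERBB3_PI3K_SITES)]

    notes = ("Original reduced ERBB model authored for this package; it "
             "mirrors the classic EGF/HRG-EGFR/ERBB3 adapter-recruitment "
             "structure (13 receptor tyrosines, SHC1/GRB2/SOS1/GAB1/PI3K) "
             "and, at tier 2, a Ras-RAF-MEK-ERK / PI3K-Akt backbone with "
             "ERK-to-SOS1 negative feedback. It is a synthetic stand-in, "
             "not a transcription of any published model file. Residue "
             "names are illustrative.")
    model, manifest = _finish(f"erbb_mini_tier{cfg.tier}", text, groups,
                              binding_edges, notes=notes)
    return model, manifest


def ligand_dose_protocol(model: Model, egf_nm: float = 5.0,
                         hrg_nm: float = 5.0, scale: float = 1.0,
                         equilibrate: float = 0.0,
                         at: float = 0.0) -> Protocol:
    """Dose EGF/HRG at the given nanomolar concentrations at time ``at``.

    Copies are computed from the extracellular compartment volume with the
    given scale factor applied.
    """
    ex = model.compartments["Ex"]
    eff = Compartment(ex.name, ex.dimension, ex.size, scale)
    additions = []
    if egf_nm > 0:
        additions.append(Addition(at, "EGF(r)",
                                  convert_concentration(egf_nm * 1e-9, eff)))
    if hrg_nm > 0:
        additions.append(Addition(at, "HRG(r)",
                                  convert_concentration(hrg_nm * 1e-9, eff)))
    return Protocol(equilibrate=equilibrate, additions=additions)


def erbb_class_map(model: Model) -> dict[str, str]:
    """Parameter-class assignment for the reduced ERBB model."""
    out = {}
    for name in model.parameters:
        if name.startswith("kon") or name == "kcat2":
            out[name] = "bimolecular_association"
        elif name.startswith("koff"):
            out[name] = "unimolecular_dissociation"
        elif name in ("kphos", "kdephos"):
            out[name] = "phosphatase_catalyzed"
        else:
            out[name] = "fixed"
    return out


# ---------------------------------------------------------------------------
# Random models for property tests

_COMP_POOL = ("a", "b", "c", "d")
_STATE_SETS = ((), ("U", "P"), ("U", "P", "Q"))


def random_model(n_types: int = 4, n_rules: int = 8, max_sites: int = 3,
                 seed: int = 0) -> Model:
    model, _ = random_model_with_manifest(n_types, n_rules, max_sites, seed)
    return model


def random_model_with_manifest(n_types: int = 4, n_rules: int = 8,
                               max_sites: int = 3, seed: int = 0) \
        -> tuple[Model, FixtureManifest]:
    if n_types > 8 or n_rules > 20:
        raise ValueError("random models are intentionally small "
                         "(<=8 types, <=20 rules)")
    rng = np.random.default_rng(seed)
    types = []
    for i in range(n_types):
        n_comp = int(rng.integers(1, max_sites + 1))
        comps = []
        for j in range(n_comp):
            cname = _COMP_POOL[int(rng.integers(len(_COMP_POOL)))]
            states = _STATE_SETS[int(rng.integers(len(_STATE_SETS)))]
            comps.append((cname, states))
        # repeated names must agree on states (validation invariant)
        by_name = {}
        fixed = []
        for cname, states in comps:
            if cname in by_name:
                states = by_name[cname]
            by_name[cname] = states
            fixed.append((cname, states))
        types.append((f"T{i}", fixed))

    lines_t = []
    lines_s = []
    for tname, comps in types:
        decl = ",".join(c + "".join(f"~{s}" for s in st) for c, st in comps)
        seed_spec = ",".join(c + (f"~{st[0]}" if st else "")
                             for c, st in comps)
        lines_t.append(f"  {tname}({decl})")
        lines_s.append(f"  {tname}({seed_spec}) {int(rng.integers(5, 40))}")

    lines_p = []
    lines_r = []
    n_made = 0
    attempts = 0
    while n_made < n_rules and attempts < n_rules * 20:
        attempts += 1
        kind = rng.choice(["bind", "flip"])
        k1 = 10.0 ** rng.uniform(-3, -1)
        if kind == "bind":
            ti = int(rng.integers(len(types)))
            tj = int(rng.integers(len(types)))
            ci = types[ti][1][int(rng.integers(len(types[ti][1])))][0]
            cj = types[tj][1][int(rng.integers(len(types[tj][1])))][0]
            k2 = 10.0 ** rng.uniform(-2, 0)
            name = f"r{n_made}"
            lines_p.append(f"  k{n_made}f {k1:.6g}")
            lines_p.append(f"  k{n_made}r {k2:.6g}")
            lines_r.append(
                f"  {name}: {types[ti][0]}({ci}) + {types[tj][0]}({cj}) <-> "
                f"{types[ti][0]}({ci}!1).{types[tj][0]}({cj}!1) "
                f"k{n_made}f, k{n_made}r")
            n_made += 1
        else:
            ti = int(rng.integers(len(types)))
            stateful = [(c, st) for c, st in types[ti][1] if st]
            if not stateful:
                continue
            c, st = stateful[int(rng.integers(len(stateful)))]
            s_from, s_to = rng.choice(len(st), size=2, replace=False)
            name = f"r{n_made}"
            lines_p.append(f"  k{n_made}f {k1:.6g}")
            lines_r.append(
                f"  {name}: {types[ti][0]}({c}~{st[s_from]}) -> "
                f"{types[ti][0]}({c}~{st[s_to]}) k{n_made}f")
            n_made += 1

    obs = [f"  Molecules free0 {types[0][0]}({types[0][1][0][0]})"]
    text = "\n".join(
        ["begin parameters"] + lines_p + ["end parameters",
         "begin molecule types"] + lines_t + ["end molecule types",
         "begin seed species"] + lines_s + ["end seed species",
         "begin observables"] + obs + ["end observables",
         "begin reaction rules"] + lines_r + ["end reaction rules"])
    model, manifest = _finish(f"random_{seed}", text)

    # Reachability audit: rules that never fire within a bounded expansion
    # are flagged inert in the manifest.
    from .onthefly import NetworkCapReached, generate_network
    try:
        net = generate_network(model, max_species=200)
        used = {rx.rule for rx in net.reactions}
    except NetworkCapReached:  # pragma: no cover
        used = set()
    manifest.inert_rules = sorted(
        r.name for r in model.rules if r.name not in used) if used else []
    return model, manifest
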