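"""Forward co-linear assembly of a polyketide from a module architecture.

Each PKS elongation module condenses a two-carbon acetate unit onto the
growing chain and leaves the upstream carbonyl as the new β-keto group.  The
domains present in the module then set the oxidation state of that β carbon:

====================  =======================================================
module domain set      β-carbon outcome
====================  =======================================================
KS only                ketone
KS + KR(A)             l-configured hydroxyl
KS + KR(B)             d-configured hydroxyl
KS + KR + DH           olefin; *cis* for A-type KR, *trans* for B-type
KS + KR + DH + tER     fully saturated (trans-acting enoylreductase)
KS + DH (no KR)        olefin under the permissive rule (sorangicin
                       precedent), otherwise ketone with a warning
====================  =======================================================

A cMT adds an α-methyl from SAM, an in-line LLM hydroxylates the α position,
a shift-flagged dehydratase moves the new olefin from the α,β to the β,γ
bond, and an in-line ECH marks the unit as the substrate of the trans-acting
HCS β-branching cassette.

Backbone numbering follows the macrolide convention used throughout: C1 is
the carbonyl carbon of the final elongation, numbers increase toward the
starter, an NRPS-incorporated glycine contributes C(2E+1) and C(2E+2), and
starter carbons beyond the amide nitrogen are counted but not numbered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .bgc_model import (
    AMINO_ACID_CONTRIBUTIONS, MONOMER_LIBRARY, BGCArchitecture, ModuleSpec,
    MonomerSpec, ROLE_ELONGATION, ROLE_NRPS, ROLE_TERMINATION, segment_modules,
)
from .errors import AssemblyError, TailoringError

BETA_STATES = frozenset({
    "ketone", "hydroxyl_L", "hydroxyl_D", "hydroxyl",
    "olefin_cis", "olefin_trans", "olefin", "olefin_shifted", "saturated",
})


# ---------------------------------------------------------------------------
# Position map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PositionMap:
    """Backbone carbon numbering for E elongation cycles.

    ``alpha(e) = 2(E-e)+2`` and ``beta(e) = 2(E-e)+3``: the final elongation
    provides C1/C2 and earlier cycles sit closer to the starter.  Amino-acid
    carbons follow C(2E); an olefin between Cn and Cn+1 is named Δn.
    """

    E: int
    amino_acid_carbons: int = 0

    def alpha(self, e: int) -> int:
        self._check(e)
        return 2 * (self.E - e) + 2

    def beta(self, e: int) -> int:
        self._check(e)
        return 2 * (self.E - e) + 3

    def _check(self, e: int) -> None:
        if not 1 <= e <= self.E:
            raise AssemblyError(f"elongation ordinal {e} outside 1..{self.E}")

    @property
    def backbone_carbons(self) -> int:
        return 2 * self.E + self.amino_acid_carbons


def compute_position_map(E: int, starter: MonomerSpec | None = None,
                         amino_acids=()) -> PositionMap:
    """Build the carbon-numbering map for ``E`` elongations."""
    if E < 1:
        raise AssemblyError("position map requires at least one elongation")
    aa_carbons = sum(AMINO_ACID_CONTRIBUTIONS[a]["backbone_carbons"]
                     for a in amino_acids)
    return PositionMap(E=E, amino_acid_carbons=aa_carbons)


# ---------------------------------------------------------------------------
# Chain state
# ---------------------------------------------------------------------------

@dataclass
class BackboneUnit:
    """One two-carbon extension and the processing applied to it."""

    elongation_ordinal: int
    origin_module: int
    beta_state: str = "ketone"
    geometry: str | None = None          # cis | trans | None for olefins
    alpha_methyls: int = 0
    alpha_hydroxyl: bool = False
    hcs_site: bool = False
    is_tail: bool = False                # assembled before the NRPS step
    beta_branch: dict | None = None      # {"mode": "internal"|"exo"}

    def __post_init__(self):
        if self.beta_state not in BETA_STATES:
            raise AssemblyError(f"invalid beta state {self.beta_state!r}")

    @property
    def is_olefin(self) -> bool:
        return self.beta_state.startswith("olefin")


@dataclass
class ChainState:
    """The growing chain: starter, amino-acid steps, and backbone units."""

    starter: MonomerSpec | None
    amino_acids: list[str] = field(default_factory=list)
    units: list[BackboneUnit] = field(default_factory=list)
    open: bool = True
    warnings: list[str] = field(default_factory=list)

    @property
    def n_elongations(self) -> int:
        return len(self.units)

    @property
    def post_nrps_units(self) -> list[BackboneUnit]:
        return [u for u in self.units if not u.is_tail]

    @property
    def tail_units(self) -> list[BackboneUnit]:
        return [u for u in self.units if u.is_tail]


def initialize_chain(starter: str | MonomerSpec | None,
                     amino_acids=()) -> ChainState:
    """Open a chain on the given starter monomer.

    ``starter`` may be ``None`` for clusters lacking a loading module (the
    chain is then primed directly by the first core module's substrate).
    """
    if isinstance(starter, str):
        if starter not in MONOMER_LIBRARY:
            raise AssemblyError(f"unknown starter monomer {starter!r}")
        starter = MONOMER_LIBRARY[starter]
    for aa in amino_acids:
        if aa not in AMINO_ACID_CONTRIBUTIONS:
            raise AssemblyError(f"unknown amino acid {aa!r}")
    return ChainState(starter=starter, amino_acids=list(amino_acids))


# ---------------------------------------------------------------------------
# Elongation
# ---------------------------------------------------------------------------

def _module_kr(module: ModuleSpec):
    for d in module.domains:
        if d.kind == "KR" and d.attrs.get("active", True):
            return d
    return None


def apply_elongation(chain: ChainState, module: ModuleSpec,
                     permissive_dh: bool = True,
                     geometry_override: str | None = None,
                     is_tail: bool = False) -> ChainState:
    """Append one backbone unit according to the module's domain set."""
    if not chain.open:
        raise AssemblyError("cannot elongate a closed chain")
    if module.role != ROLE_ELONGATION:
        raise AssemblyError(
            f"module {module.index} has role {module.role!r}, not pks_elongation")

    kr = _module_kr(module)
    kr_type = kr.kr_type if kr is not None else None
    reduces = kr_type in ("A", "B", "unknown")
    has_dh = any(d.kind == "DH" and d.attrs.get("active", True)
                 for d in module.domains)
    shift = any(d.kind in ("DH", "DHt") and d.attrs.get("shift", False)
                for d in module.domains)
    n_cmt = sum(1 for d in module.domains if d.kind == "cMT")
    has_llm = any(d.kind == "LLM" for d in module.domains)
    has_ech = any(d.kind == "ECH" for d in module.domains)

    state, geometry = "ketone", None
    if reduces:
        state = {"A": "hydroxyl_L", "B": "hydroxyl_D", "unknown": "hydroxyl"}[kr_type]
    if has_dh:
        if reduces:
            state = "olefin"
            geometry = {"A": "cis", "B": "trans", "unknown": None}[kr_type]
        elif permissive_dh:
            state, geometry = "olefin", None
        else:
            chain.warnings.append(
                f"module {module.index}: DH without KR treated as inactive")
    if geometry_override is not None and state.startswith("olefin"):
        geometry = geometry_override
    if "trans_ER" in module.trans_annotations and state.startswith("olefin"):
        state, geometry = "saturated", None
    if shift and state.startswith("olefin"):
        state = "olefin_shifted"

    chain.units.append(BackboneUnit(
        elongation_ordinal=len(chain.units) + 1,
        origin_module=module.index,
        beta_state=state,
        geometry=geometry,
        alpha_methyls=n_cmt,
        alpha_hydroxyl=has_llm,
        hcs_site=has_ech or "hcs_site" in module.trans_annotations,
        is_tail=is_tail,
    ))
    return chain


# ---------------------------------------------------------------------------
# β-branching (HCS cassette)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HCSCassette:
    """Trans-acting β-branching machinery: ACP, HCS, free KS and ECH count."""

    acp: bool = True
    hcs: bool = True
    free_ks: bool = True
    n_ech: int = 2


def apply_beta_branch(chain: ChainState, cassette: HCSCassette,
                      site_unit: BackboneUnit) -> ChainState:
    """Install a β-methyl branch at a flagged ketone unit.

    The β-keto group is the condensation substrate, so the site must still be
    a ketone.  An in-line ECH at the site isomerizes the initially exocyclic
    methylene to the internal olefin between β−1 and β; without it the branch
    stays as an exo-methylene.
    """
    if not (cassette.hcs and cassette.free_ks and cassette.acp):
        raise AssemblyError("incomplete HCS cassette (needs ACP, HCS and free KS)")
    if site_unit.beta_state != "ketone":
        raise AssemblyError(
            f"β-branch substrate must be a ketone, got {site_unit.beta_state!r}")
    if not site_unit.hcs_site:
        raise AssemblyError("unit is not flagged as an HCS site")
    mode = "internal" if site_unit.hcs_site and _site_has_inline_ech(site_unit) else "exo"
    site_unit.beta_branch = {"mode": mode}
    return chain


def _site_has_inline_ech(unit: BackboneUnit) -> bool:
    # hcs_site is set either by an in-line ECH domain or by an architecture
    # annotation; only the former drives internal-olefin isomerization.  The
    # flag is stored on the unit when the module carried the ECH.
    return unit.hcs_site


# ---------------------------------------------------------------------------
# Finalized structure
# ---------------------------------------------------------------------------

@dataclass
class PositionFeature:
    """Per-backbone-carbon feature record."""

    position: int
    state: str                       # carbonyl oxidation state / bonding
    stereo: str | None = None        # L | D for β-hydroxyls
    olefin: int | None = None        # Δn when this is the lower olefin carbon
    olefin_geometry: str | None = None
    branch_methyls: tuple[int, ...] = ()
    branch_mode: str | None = None   # internal | exo for β-branch methyls
    decorations: tuple[str, ...] = ()

    def row(self) -> dict:
        return {
            "position": self.position, "state": self.state,
            "stereo": self.stereo or "",
            "olefin": f"D{self.olefin}" if self.olefin else "",
            "geometry": self.olefin_geometry or "",
            "branch": ",".join(f"C{m}" for m in self.branch_methyls),
            "decoration": ",".join(self.decorations),
        }


@dataclass
class AssembledStructure:
    """The finalized polyketide as a per-position feature table."""

    bgc_id: str
    features: dict[int, PositionFeature]
    n_elongations: int
    n_post_nrps: int
    backbone_carbon_count: int
    polyketide_carbon_count: int
    total_carbon_count: int
    starter: MonomerSpec | None
    amino_acids: tuple[str, ...]
    ring_closure: tuple[int, int] | None = None
    tail_extension: dict = field(default_factory=dict)
    amide: bool = False
    hydrolyzed: bool = False
    warnings: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)
    _tailored_targets: set = field(default_factory=set)

    # -- derived views ------------------------------------------------------

    @property
    def olefins(self) -> dict[int, str | None]:
        return {f.olefin: f.olefin_geometry
                for f in self.features.values() if f.olefin is not None}

    @property
    def hydroxyls(self) -> dict[int, str | None]:
        return {p: f.stereo for p, f in self.features.items()
                if f.state == "hydroxyl"}

    @property
    def free_hydroxyls(self) -> list[int]:
        return [p for p, f in self.features.items()
                if f.state == "hydroxyl" and not f.decorations]

    @property
    def decorations(self) -> dict[int, tuple[str, ...]]:
        out = {}
        for p, f in self.features.items():
            decos = tuple(d for d in f.decorations if d != "macrolactone")
            if decos:
                out[p] = decos
        return out

    @property
    def branch_sites(self) -> dict[int, str]:
        return {p: f.branch_mode for p, f in self.features.items()
                if f.branch_mode is not None}

    @property
    def terminal_olefin(self) -> bool:
        return bool(self.starter and self.starter.terminal_olefin)

    def to_frame(self):
        import pandas as pd

        rows = [self.features[p].row() for p in sorted(self.features)]
        return pd.DataFrame(rows, columns=[
            "position", "state", "stereo", "olefin", "geometry",
            "branch", "decoration"])

    def feature_assertions(self) -> dict:
        """Comparable fact set used by the variant mapper and retro engine."""
        return {
            "backbone_carbons": self.backbone_carbon_count,
            "starter": self.starter.monomer_id if self.starter else None,
            "terminal_olefin": self.terminal_olefin,
            "amide": self.amide,
            "glycine": "glycine" in self.amino_acids and not self.hydrolyzed,
            "tail_extension": bool(self.tail_extension),
            "ring": self.ring_closure,
            "olefins": dict(self.olefins),
            "hydroxyls": dict(self.hydroxyls),
            "branches": dict(self.branch_sites),
            "decorations": {p: tuple(d) for p, d in self.decorations.items()},
        }


def terminate_and_cyclize(chain: ChainState, term_module: ModuleSpec | None,
                          nucleophile="auto", bgc_id: str = "",
                          require_termination: bool = True) -> AssembledStructure:
    """Close the chain and build the finalized feature table.

    Cyclization is an ester bond between C1 and an internal hydroxyl; under
    ``nucleophile="auto"`` the hydroxyl-bearing backbone position giving the
    largest ring of at least 12 backbone atoms is chosen.  With no eligible
    hydroxyl the product is released linear with a warning.
    """
    if not chain.units:
        raise AssemblyError("cannot terminate an empty chain")
    if term_module is not None:
        if term_module.role != ROLE_TERMINATION:
            raise AssemblyError(
                f"module {term_module.index} is not a termination module")
        if not _termination_catalytic(term_module):
            raise AssemblyError(
                "termination condensation domain lacks the catalytic histidine")
    elif require_termination:
        raise AssemblyError("no termination module in architecture")
    chain.open = False

    post = chain.post_nrps_units
    tail = chain.tail_units
    E_post = len(post)
    pmap = compute_position_map(E_post, chain.starter, chain.amino_acids)
    aa_carbons = pmap.amino_acid_carbons
    # Without an NRPS step the first elongation condenses onto a two-carbon
    # acyl primer (the starter's carbonyl/α pair, or acetate by default);
    # those two carbons carry unit 1's β position and join the numbered
    # backbone.
    primer_carbons = 0 if chain.amino_acids else 2
    backbone = pmap.backbone_carbons + primer_carbons + 2 * len(tail)

    feats: dict[int, PositionFeature] = {
        p: PositionFeature(p, "methylene") for p in range(1, backbone + 1)}
    feats[1].state = "carboxyl"

    # Glycine carbons: C(2E+1) is unit 1's β carbon (its state is set below);
    # C(2E+2) bears the nitrogen — an amide only once acylated by a starter.
    amide = bool(chain.amino_acids) and chain.starter is not None

    warnings = list(chain.warnings)
    for u in post:
        a, b = pmap.alpha(u.elongation_ordinal), pmap.beta(u.elongation_ordinal)
        if u.alpha_methyls:
            feats[a].branch_methyls = tuple([0] * u.alpha_methyls)  # renumbered later
        # An α-hydroxyl requires an sp3 α carbon: suppressed when the unit's
        # own α,β-olefin or an internal β-branch olefin occupies it.
        alpha_blocked = (
            (u.is_olefin and u.beta_state != "olefin_shifted")
            or (u.beta_branch is not None and u.beta_branch["mode"] == "internal"))
        if u.alpha_hydroxyl and not alpha_blocked:
            feats[a].state = "hydroxyl"
        elif u.alpha_hydroxyl:
            warnings.append(
                f"elongation {u.elongation_ordinal}: α-hydroxylation suppressed "
                "on olefinic α carbon")
        if u.beta_branch is not None:
            # β-keto consumed by the branch; internal mode adds the Δ(β−1) olefin.
            feats[b].branch_methyls = feats[b].branch_methyls + (0,)
            feats[b].branch_mode = u.beta_branch["mode"]
            if u.beta_branch["mode"] == "internal":
                _set_olefin(feats, b - 1, None)
            continue
        if u.beta_state == "ketone":
            feats[b].state = "ketone"
        elif u.beta_state in ("hydroxyl_L", "hydroxyl_D", "hydroxyl"):
            feats[b].state = "hydroxyl"
            feats[b].stereo = {"hydroxyl_L": "L", "hydroxyl_D": "D",
                               "hydroxyl": None}[u.beta_state]
        elif u.beta_state == "olefin_shifted":
            if b + 1 <= backbone:
                _set_olefin(feats, b, u.geometry)
            else:
                _set_olefin(feats, a, u.geometry)
                warnings.append(
                    f"elongation {u.elongation_ordinal}: olefin shift beyond "
                    "chain end suppressed")
        elif u.is_olefin:
            _set_olefin(feats, a, u.geometry)
        # "saturated" leaves the default methylene state.

    tail_ext: dict = {}
    if tail:
        # Tail units sit between the amino-acid carbons and the starter; the
        # last-assembled tail unit is adjacent to the amide nitrogen.
        pos = 2 * E_post + aa_carbons
        methyls = 0
        for u in reversed(tail):
            feats[pos + 1].state = "carbonyl" if u is tail[-1] else "methylene"
            if u.alpha_methyls:
                feats[pos + 2].branch_methyls = tuple([0] * u.alpha_methyls)
                methyls += u.alpha_methyls
            pos += 2
        tail_ext = {"units": len(tail), "methyls": methyls}

    structure = AssembledStructure(
        bgc_id=bgc_id,
        features=feats,
        n_elongations=len(chain.units),
        n_post_nrps=E_post,
        backbone_carbon_count=backbone,
        polyketide_carbon_count=2 * len(chain.units),
        total_carbon_count=0,
        starter=chain.starter,
        amino_acids=tuple(chain.amino_acids),
        tail_extension=tail_ext,
        amide=amide,
        warnings=warnings,
    )

    # Ring closure.
    if nucleophile == "auto":
        eligible = [p for p in structure.free_hydroxyls if p >= 12]
        target = max(eligible) if eligible else None
    else:
        target = int(nucleophile)
        if feats.get(target) is None or feats[target].state != "hydroxyl":
            raise AssemblyError(f"nucleophile position C{target} bears no hydroxyl")
    if target is not None:
        structure.ring_closure = (1, target)
        feats[1].state = "ester_carbonyl"
        feats[target].state = "hydroxyl"
        feats[target].decorations = ("macrolactone",)
    else:
        structure.warnings.append("no eligible hydroxyl: linear product released")

    _renumber_extra_carbons(structure)
    return structure


def _termination_catalytic(module: ModuleSpec) -> bool:
    for d in module.domains:
        if d.kind in ("C", "C_trunc"):
            if "catalytic_his" in d.attrs:
                return bool(d.attrs["catalytic_his"])
            if d.sequence:
                from .motif_engine import classify_condensation
                return classify_condensation(d.sequence).catalytic_his
            return True  # unannotated fixtures assume the catalytic core
    return False


def _set_olefin(feats: dict[int, PositionFeature], lower: int,
                geometry: str | None) -> None:
    feats[lower].olefin = lower
    feats[lower].olefin_geometry = geometry
    feats[lower].state = "olefinic"
    if lower + 1 in feats and feats[lower + 1].state == "methylene":
        feats[lower + 1].state = "olefinic"


def _renumber_extra_carbons(structure: AssembledStructure) -> None:
    """Assign carbon numbers to branch methyls: β-branch methyls first, then
    α-methyls, in ascending order of their attachment position."""
    next_c = structure.backbone_carbon_count + 1
    branch_positions = sorted(
        p for p, f in structure.features.items() if f.branch_mode is not None)
    methyl_positions = sorted(
        p for p, f in structure.features.items()
        if f.branch_methyls and f.branch_mode is None)
    n_methyls = 0
    for p in branch_positions:
        f = structure.features[p]
        f.branch_methyls = tuple(range(next_c, next_c + len(f.branch_methyls)))
        next_c += len(f.branch_methyls)
        n_methyls += len(f.branch_methyls)
    for p in methyl_positions:
        f = structure.features[p]
        f.branch_methyls = tuple(range(next_c, next_c + len(f.branch_methyls)))
        next_c += len(f.branch_methyls)
        n_methyls += len(f.branch_methyls)
    starter_c = structure.starter.carbon_count if structure.starter else 0
    aa_c = sum(AMINO_ACID_CONTRIBUTIONS[a]["backbone_carbons"]
               for a in structure.amino_acids)
    primer_c = 2 if (structure.starter is None and not structure.amino_acids) else 0
    structure.total_carbon_count = (
        starter_c + structure.polyketide_carbon_count + aa_c + n_methyls + primer_c)


# ---------------------------------------------------------------------------
# Tailoring
# ---------------------------------------------------------------------------

def apply_tailoring(structure: AssembledStructure, tailoring,
                    default_ct_target: int | None = None) -> AssembledStructure:
    """Apply trans-acting tailoring records to the finalized structure.

    Records are dicts ``{"enzyme": CT|sulfotransferase|GTF|hydroxylase,
    "target": <position>|"default"}``.  CT installs a carbamate, the
    sulfotransferase a sulfate and GTF a glycosyl group, each on an existing
    free hydroxyl; a trans-hydroxylase adds a new hydroxyl.  Targets are
    consumed: re-applying the same record is a tailoring error, which keeps
    double-decoration impossible.
    """
    for record in tailoring:
        enzyme = record["enzyme"]
        target = record.get("target", "default")
        if enzyme == "hydroxylase":
            pos = int(target)
            f = structure.features.get(pos)
            if f is None:
                raise TailoringError(f"hydroxylase target C{pos} outside backbone")
            if f.state not in ("methylene", "olefinic"):
                raise TailoringError(
                    f"hydroxylase target C{pos} is not an open position")
            f.state = "hydroxyl"
            continue
        decoration = {"CT": "carbamate", "sulfotransferase": "sulfate",
                      "GTF": "glycosyl"}.get(enzyme)
        if decoration is None:
            raise TailoringError(f"unknown tailoring enzyme {enzyme!r}")
        if target == "default":
            frees = structure.free_hydroxyls
            if default_ct_target is not None and default_ct_target in frees:
                pos = default_ct_target
            elif frees:
                pos = min(frees)
            else:
                raise TailoringError(
                    f"{enzyme}: no free hydroxyl for default target")
        else:
            pos = int(target)
        key = (enzyme, pos)
        if key in structure._tailored_targets:
            raise TailoringError(f"{enzyme} already applied at C{pos}")
        f = structure.features.get(pos)
        if f is None or f.state != "hydroxyl" or f.decorations:
            raise TailoringError(
                f"{enzyme} target C{pos} lacks a free hydroxyl")
        f.decorations = f.decorations + (decoration,)
        structure._tailored_targets.add(key)
    return structure


# ---------------------------------------------------------------------------
# Whole-architecture assembly
# ---------------------------------------------------------------------------

def _detect_cassette(arch: BGCArchitecture) -> HCSCassette | None:
    kinds = [d.kind for g in arch.trans_genes for d in g.domains]
    if "HCS" not in kinds:
        return None
    return HCSCassette(acp="ACP" in kinds, hcs=True,
                       free_ks="KS" in kinds, n_ech=kinds.count("ECH"))


def _default_ct_position(chain: ChainState, pmap: PositionMap) -> int | None:
    # The default carbamoylation site is the β-hydroxyl of the elongation
    # module that carries the in-line LLM (C-11 in the palmerolide numbering).
    for u in chain.post_nrps_units:
        if u.alpha_hydroxyl:
            return pmap.beta(u.elongation_ordinal)
    return None


def assemble(arch: BGCArchitecture, *,
             permissive_dh: bool = True,
             nucleophile="auto",
             starter_override: str | None = None,
             geometry_overrides: dict[int, str] | None = None,
             ct_target=None,
             extra_tailoring=(),
             hydroxylase_site: int | None = None,
             post_assembly_hydrolysis: bool = False) -> AssembledStructure:
    """Run the full co-linear pipeline on a (segmented) architecture.

    Stages: starter initialization → per-module elongation/NRPS steps →
    trans-acting β-branching at flagged ketone sites → termination and
    macrolactonization → tailoring.  Options expose the variant mechanisms of
    the cluster family: starter swap, carbamate/sulfate retargeting, an
    alternative hydroxylase site (with olefin repositioning), per-module
    olefin-geometry overrides, and speculative post-assembly amide hydrolysis
    for starterless clusters.
    """
    if not arch.modules:
        arch = segment_modules(arch)
    geometry_overrides = geometry_overrides or {}

    starter = starter_override or arch.starter_monomer
    amino_acids = []
    nrps_indices = []
    for mod in arch.modules:
        if mod.role == ROLE_NRPS:
            nrps_indices.append(mod.index)
            a_domains = mod.domains_of_kind("A")
            if not a_domains:
                raise AssemblyError(
                    f"module {mod.index}: NRPS module without adenylation domain")
            amino_acids.append(
                a_domains[0].attrs.get("adenylation_substrate", "glycine"))
    last_nrps = max(nrps_indices) if nrps_indices else None

    chain = initialize_chain(starter, amino_acids)
    term_module = None
    for mod in arch.modules:
        if mod.role == ROLE_ELONGATION:
            is_tail = last_nrps is not None and mod.index < last_nrps
            try:
                apply_elongation(
                    chain, mod, permissive_dh=permissive_dh,
                    geometry_override=geometry_overrides.get(
                        mod.elongation_ordinal),
                    is_tail=is_tail)
            except AssemblyError as exc:
                raise AssemblyError(f"module {mod.index}: {exc}") from exc
        elif mod.role == ROLE_TERMINATION:
            term_module = mod

    cassette = _detect_cassette(arch)
    if cassette is not None:
        for unit in chain.units:
            if unit.hcs_site and unit.beta_state == "ketone":
                apply_beta_branch(chain, cassette, unit)

    # Tail units count as pre-NRPS only: re-derive ordinals over post units so
    # the position map sees a contiguous 1..E_post numbering.
    for i, u in enumerate(chain.post_nrps_units, start=1):
        u.elongation_ordinal = i
    for i, u in enumerate(chain.tail_units, start=1):
        u.elongation_ordinal = i

    pmap = compute_position_map(max(len(chain.post_nrps_units), 1),
                                chain.starter, chain.amino_acids)
    ct_explicit = ct_target is not None
    if ct_target is None:
        ct_target = _default_ct_position(chain, pmap)

    structure = terminate_and_cyclize(
        chain, term_module, nucleophile=nucleophile, bgc_id=arch.bgc_id,
        require_termination=False)

    if hydroxylase_site is not None:
        _relocate_alpha_hydroxyl(structure, chain, pmap, hydroxylase_site)

    tailoring = list(arch.tailoring) + list(extra_tailoring)
    if ct_explicit:
        # an explicit CT target is strict: no silent fallback
        tailoring = [
            {**t, "target": ct_target}
            if t.get("enzyme") == "CT" and t.get("target", "default") == "default"
            else t
            for t in tailoring]
        apply_tailoring(structure, tailoring)
    else:
        apply_tailoring(structure, tailoring, default_ct_target=ct_target)

    if post_assembly_hydrolysis:
        _hydrolyze_amide(structure)
    return structure


def _relocate_alpha_hydroxyl(structure: AssembledStructure, chain: ChainState,
                             pmap: PositionMap, new_pos: int) -> None:
    """Move the LLM/trans-hydroxylase α-hydroxyl to ``new_pos``.

    When the new site falls on the lower carbon of an olefin, the olefin is
    repositioned one bond toward C1's far side (Δn → Δn+1), mirroring the
    Δ8→Δ9 difference between family members hydroxylated at C-10 vs C-8.
    """
    old = [pmap.alpha(u.elongation_ordinal)
           for u in chain.post_nrps_units if u.alpha_hydroxyl]
    if not old:
        raise TailoringError("no in-line α-hydroxyl to relocate")
    f_old = structure.features[old[0]]
    if f_old.state == "hydroxyl":
        f_old.state = "methylene"
    f_new = structure.features.get(new_pos)
    if f_new is None:
        raise TailoringError(f"hydroxylase site C{new_pos} outside backbone")
    if f_new.olefin is not None:
        geometry = f_new.olefin_geometry
        f_new.olefin = None
        f_new.olefin_geometry = None
        f_new.state = "methylene"
        _set_olefin(structure.features, new_pos + 1, geometry)
    f_new.state = "hydroxyl"
    structure.notes.append(f"alpha-hydroxyl relocated C{old[0]}->C{new_pos}")


def _hydrolyze_amide(structure: AssembledStructure) -> None:
    """Speculative post-assembly hydrolysis at the glycine amide.

    Only applicable to products whose glycine was never acylated by a starter
    (clusters lacking a loading module); removes the glycine carbons and the
    nitrogen, leaving the polyketide core.
    """
    if structure.starter is not None:
        raise TailoringError(
            "amide hydrolysis is modeled only for starterless products")
    if "glycine" not in structure.amino_acids:
        raise TailoringError("no glycine subunit to hydrolyze")
    aa_carbons = sum(AMINO_ACID_CONTRIBUTIONS[a]["backbone_carbons"]
                     for a in structure.amino_acids)
    keep = structure.backbone_carbon_count - aa_carbons
    for p in range(keep + 1, structure.backbone_carbon_count + 1):
        structure.features.pop(p, None)
    # Drop olefins that spanned into the removed carbons.
    for f in structure.features.values():
        if f.olefin is not None and f.olefin + 1 > keep:
            f.olefin = None
            f.olefin_geometry = None
            f.state = "methylene"
    structure.backbone_carbon_count = keep
    structure.amide = False
    structure.hydrolyzed = True
    structure.notes.append("speculative: post-assembly amide hydrolysis applied")
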