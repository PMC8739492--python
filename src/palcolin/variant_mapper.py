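"""Compare cluster copies and map them to palmerolide family analogues.

The family's structural diversity is modeled through three mechanism
classes, mirroring the levels at which near-identical cluster copies can
diverge chemically:

1. ``trans_sites`` — alternative sites of action for trans-acting enzymes:
   carbamoyl transfer retargeted from the default β-hydroxyl to the next
   free secondary alcohol with sulfation of the freed hydroxyl, and/or the
   α-hydroxylase acting two carbons down-chain with repositioning of the
   neighbouring olefin;
2. ``starter_swap`` — promiscuous selection of the isomeric
   3-methyl-3-butenoate starter, giving a terminal olefin on the tail;
3. ``geometry_override`` — cis instead of trans geometry from one module's
   ketoreductase (mechanism unresolved; represented only as an override);

plus a speculative ``post_assembly_hydrolysis`` flag, applicable only to
clusters that lack a loading module (their glycine is never acylated), which
trims the glycine subunit from the released product.

``variant_budget`` bounds how many mechanism *classes* may be combined per
candidate product (default 2; all family assignments need at most two).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .assembly_engine import AssembledStructure, assemble
from .bgc_model import BGCArchitecture, ModuleSpec, ROLE_ELONGATION, ROLE_NRPS
from .errors import AssemblyError, TailoringError, ValidationError

MECHANISM_CLASSES = ("trans_sites", "starter_swap", "geometry_override",
                     "post_assembly_hydrolysis")


# ---------------------------------------------------------------------------
# Architecture diffing
# ---------------------------------------------------------------------------

def module_signature(module: ModuleSpec) -> tuple:
    """Hashable summary of a module: role, domain kinds with the attributes
    that change chemistry, and trans annotations."""
    doms = tuple(
        (d.kind,
         d.kr_type if d.kind == "KR" else None,
         bool(d.attrs.get("shift", False)))
        for d in module.domains)
    return (module.role, doms, tuple(sorted(module.trans_annotations)))


@dataclass
class ArchitectureDiff:
    """Module-level edit script from architecture ``a`` to ``b``."""

    insertions: list[tuple[int, tuple]] = field(default_factory=list)
    deletions: list[tuple[int, tuple]] = field(default_factory=list)
    starter_change: tuple | None = None
    trans_gene_changes: tuple[frozenset, frozenset] = (frozenset(), frozenset())

    @property
    def is_module_identical(self) -> bool:
        return not self.insertions and not self.deletions


def diff_architectures(a: BGCArchitecture, b: BGCArchitecture) -> ArchitectureDiff:
    """Minimal module-level edit script via longest common subsequence over
    module signatures.  ``patch_signatures`` applied to ``a`` reproduces
    ``b`` (asserted here)."""
    if not a.modules or not b.modules:
        raise ValidationError("diff requires segmented architectures")
    sa = [module_signature(m) for m in a.modules]
    sb = [module_signature(m) for m in b.modules]
    # LCS table
    la, lb = len(sa), len(sb)
    lcs = [[0] * (lb + 1) for _ in range(la + 1)]
    for i in range(la - 1, -1, -1):
        for j in range(lb - 1, -1, -1):
            if sa[i] == sb[j]:
                lcs[i][j] = lcs[i + 1][j + 1] + 1
            else:
                lcs[i][j] = max(lcs[i + 1][j], lcs[i][j + 1])
    deletions, insertions = [], []
    i = j = 0
    while i < la and j < lb:
        if sa[i] == sb[j]:
            i += 1
            j += 1
        elif lcs[i + 1][j] >= lcs[i][j + 1]:
            deletions.append((i, sa[i]))
            i += 1
        else:
            insertions.append((j, sb[j]))
            j += 1
    deletions.extend((k, sa[k]) for k in range(i, la))
    insertions.extend((k, sb[k]) for k in range(j, lb))

    starter_change = (None if a.starter_monomer == b.starter_monomer
                      else (a.starter_monomer, b.starter_monomer))
    ta, tb = frozenset(a.trans_domain_kinds()), frozenset(b.trans_domain_kinds())
    diff = ArchitectureDiff(
        insertions=insertions, deletions=deletions,
        starter_change=starter_change,
        trans_gene_changes=(ta - tb, tb - ta))
    assert patch_signatures(sa, diff) == sb, "diff failed self-check"
    return diff


def patch_signatures(signatures: list[tuple], diff: ArchitectureDiff) -> list[tuple]:
    """Apply a module-level diff to a signature list."""
    out = [s for k, s in enumerate(signatures)
           if k not in {i for i, _ in diff.deletions}]
    for pos, sig in sorted(diff.insertions):
        out.insert(pos, sig)
    return out


# ---------------------------------------------------------------------------
# Analogue definitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalogueDefinition:
    name: str
    assertions: dict
    allowed_mechanisms: frozenset
    speculative: bool = False
    note: str = ""

    def __post_init__(self):
        unknown = self.allowed_mechanisms - set(MECHANISM_CLASSES)
        if unknown:
            raise ValidationError(
                f"analogue {self.name!r}: unknown mechanisms {sorted(unknown)}")


def load_analogue_definitions(source=None) -> list[AnalogueDefinition]:
    """Load analogue definitions from YAML (the shipped A–H set by default)."""
    if source is None:
        from importlib import resources
        text = resources.files("palcolin.data").joinpath(
            "palmerolides.yaml").read_text()
    elif hasattr(source, "read"):
        text = source.read()
    else:
        text = open(source).read()
    doc = yaml.safe_load(text)
    defs = []
    for entry in doc["analogues"]:
        defs.append(AnalogueDefinition(
            name=entry["name"],
            assertions=entry.get("assertions", {}),
            allowed_mechanisms=frozenset(entry.get("allowed_mechanisms", [])),
            speculative=bool(entry.get("speculative", False)),
            note=entry.get("note", "")))
    return defs


def structure_satisfies(structure: AssembledStructure, assertions: dict) -> bool:
    """Check a structure against an analogue's required feature assertions.

    Map-valued assertions (hydroxyls, olefins, decorations, branches) are
    per-position requirements; scalar assertions must match exactly.
    """
    facts = structure.feature_assertions()
    for key, expected in assertions.items():
        if key in ("hydroxyls", "olefins", "branches", "decorations"):
            actual = facts[key]
            for pos, val in expected.items():
                pos = int(pos)
                if pos not in actual:
                    return False
                if key == "decorations":
                    if tuple(val) != tuple(actual[pos]):
                        return False
                elif actual[pos] != val:
                    return False
        elif key == "ring":
            want = tuple(expected) if expected else None
            if facts["ring"] != want:
                return False
        else:
            if facts.get(key) != expected:
                return False
    return True


# ---------------------------------------------------------------------------
# Variant enumeration
# ---------------------------------------------------------------------------

@dataclass
class VariantProduct:
    mechanisms: frozenset
    details: tuple[str, ...]
    structure: AssembledStructure
    speculative: bool = False


def _site_swap_options(base: AssembledStructure) -> dict | None:
    """Derive the concrete positions for the trans-site mechanisms from the
    default product: the default carbamoylation site, the alternative
    secondary alcohol, and the α-hydroxyl relocation site."""
    carb = [p for p, d in base.decorations.items() if "carbamate" in d]
    alpha = [p for p, s in base.hydroxyls.items() if s is None]
    if not carb:
        return None
    p0 = carb[0]
    beta_free = [p for p in base.free_hydroxyls
                 if base.hydroxyls.get(p) in ("L", "D")]
    alt = max((p for p in beta_free if p < p0), default=None)
    return {
        "ct_default": p0,
        "ct_alt": alt,
        "alpha_site": alpha[0] if alpha else None,
        "alpha_alt": alpha[0] - 2 if alpha else None,
    }


def enumerate_variants(arch: BGCArchitecture,
                       variant_budget: int = 2) -> list[VariantProduct]:
    """Assemble every allowed mechanism combination for one architecture."""
    try:
        base = assemble(arch)
    except (AssemblyError, TailoringError) as exc:
        raise AssemblyError(f"{arch.bgc_id}: base assembly failed: {exc}") from exc
    sites = _site_swap_options(base)

    has_nrps = any(m.role == ROLE_NRPS for m in arch.modules)
    post_elong = [m for m in arch.modules if m.role == ROLE_ELONGATION
                  and not (has_nrps and m.index < max(
                      mm.index for mm in arch.modules if mm.role == ROLE_NRPS))]

    # Each class expands to concrete assemble() option sets.
    class_options: dict[str, list[tuple[tuple[str, ...], dict]]] = {}
    if arch.starter_monomer == "3-methylcrotonic acid":
        class_options["starter_swap"] = [(
            ("starter promiscuity: 3-methyl-3-butenoic acid selected",),
            {"starter_override": "3-methyl-3-butenoic acid"})]
    if sites is not None:
        opts = []
        if sites["ct_alt"] is not None:
            opts.append((
                (f"CT retargeted C{sites['ct_default']}->C{sites['ct_alt']}; "
                 f"sulfate on freed C{sites['ct_default']} (genome-encoded "
                 "sulfatase, outside the BGC)",),
                {"ct_target": sites["ct_alt"],
                 "extra_tailoring": ({"enzyme": "sulfotransferase",
                                      "target": sites["ct_default"]},)}))
        if sites["alpha_site"] is not None:
            opts.append((
                (f"hydroxylase site C{sites['alpha_site']}->"
                 f"C{sites['alpha_alt']} with olefin repositioning",),
                {"hydroxylase_site": sites["alpha_alt"]}))
        if len(opts) == 2:
            opts.append((opts[0][0] + opts[1][0],
                         {**opts[0][1], **opts[1][1]}))
        if opts:
            class_options["trans_sites"] = opts
    if len(post_elong) >= 2:
        ordinal = post_elong[1].elongation_ordinal
        class_options["geometry_override"] = [(
            ("cis geometry override on the diene-forming module "
             "(biosynthetic mechanism unknown)",),
            {"geometry_overrides": {ordinal: "cis"}})]
    if arch.starter_monomer is None and has_nrps:
        class_options["post_assembly_hydrolysis"] = [(
            ("speculative post-assembly hydrolysis of the glycine amide",),
            {"post_assembly_hydrolysis": True})]

    variants = [VariantProduct(frozenset(), (), base)]
    names = sorted(class_options)
    for mask in range(1, 1 << len(names)):
        chosen = [names[k] for k in range(len(names)) if mask >> k & 1]
        if len(chosen) > variant_budget:
            continue
        pools = [class_options[c] for c in chosen]
        for combo in _product(pools):
            details: tuple[str, ...] = ()
            options: dict = {}
            for d, o in combo:
                details += d
                options.update(o)
            try:
                structure = assemble(arch, **options)
            except (AssemblyError, TailoringError):
                continue
            variants.append(VariantProduct(
                frozenset(chosen), details, structure,
                speculative="post_assembly_hydrolysis" in chosen))
    return variants


def _product(pools):
    if not pools:
        yield ()
        return
    for head in pools[0]:
        for rest in _product(pools[1:]):
            yield (head,) + rest


# ---------------------------------------------------------------------------
# Assignment
# ---------------------------------------------------------------------------

@dataclass
class AnalogueAssignment:
    analogue: str
    mechanisms: frozenset
    details: tuple[str, ...]
    speculative: bool


def assign_analogues(archs, defs=None, variant_budget: int = 2
                     ) -> dict[str, list[AnalogueAssignment]]:
    """Map each architecture to the analogues its variants can produce.

    An analogue is assigned when some ≤budget mechanism combination yields a
    structure satisfying every required assertion, using only mechanisms the
    definition allows.  Products of speculative mechanisms are labeled.
    """
    if defs is None:
        defs = load_analogue_definitions()
    out: dict[str, list[AnalogueAssignment]] = {}
    for arch in archs:
        hits: dict[str, AnalogueAssignment] = {}
        for variant in enumerate_variants(arch, variant_budget):
            for d in defs:
                if d.name in hits:
                    continue
                if not variant.mechanisms <= d.allowed_mechanisms:
                    continue
                if structure_satisfies(variant.structure, d.assertions):
                    hits[d.name] = AnalogueAssignment(
                        analogue=d.name, mechanisms=variant.mechanisms,
                        details=variant.details,
                        speculative=variant.speculative or d.speculative)
        out[arch.bgc_id] = sorted(hits.values(), key=lambda h: h.analogue)
    return out


def assignment_table(assignments: dict[str, list[AnalogueAssignment]]):
    """Long-format DataFrame of the BGC→analogue mapping for TSV export."""
    import pandas as pd

    rows = []
    for bgc_id, hits in assignments.items():
        if not hits:
            rows.append({"bgc_id": bgc_id, "analogue": "", "mechanisms": "",
                         "speculative": "", "details": "no analogue matched"})
        for h in hits:
            rows.append({
                "bgc_id": bgc_id, "analogue": h.analogue,
                "mechanisms": "+".join(sorted(h.mechanisms)) or "none",
                "speculative": "yes" if h.speculative else "no",
                "details": "; ".join(h.details)})
    return pd.DataFrame(rows, columns=["bgc_id", "analogue", "mechanisms",
                                       "speculative", "details"])
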