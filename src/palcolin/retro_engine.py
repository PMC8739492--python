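"""Retrobiosynthesis: predict a module architecture from a structure.

The retro engine inverts the forward per-module rules.  Walking the numbered
backbone from the thioester end in two-carbon pairs, the oxidation state at
each β position implies the domain set of the elongation module that built
it; branch methyls imply the trans-acting HCS cassette, an α-hydroxyl an
LLM-or-hydroxylase, a carbamate the carbamoyl transferase, and the amide plus
two backbone carbons an NRPS glycine module.

Because several domain sets produce the same chemistry, predictions are
capability *requirements* rather than exact domain strings.  The documented
degeneracies are:

* a β-ketone requires only a KS — modules with a C-type (non-reducing) or
  inactive KR are indistinguishable from KR-less modules;
* an olefin without recorded geometry requires a DH but leaves the KR
  unconstrained (permissive DH-only modules produce the same feature);
* a fully saturated unit fixes KR + DH + trans-ER but erases the KR type;
* an α-hydroxyl can come from an in-line LLM or a trans-acting hydroxylase;
* sulfation is available genome-wide (non-BGC sulfatases), so a sulfate
  requirement never counts as missing.

The congruence score against a candidate architecture is the Jaccard-style
fraction |matched| / (|matched| + |missing| + |extra|) over the fixed
feature-assertion vocabulary (version 1).  The score is this package's own
construction — a quantitative stand-in for qualitative congruence
judgements — and is labeled as such in output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .assembly_engine import AssembledStructure, compute_position_map
from .bgc_model import (
    BGCArchitecture, DomainAnnotation, ModuleSpec,
    ROLE_ELONGATION, ROLE_LOADING, ROLE_NRPS, ROLE_TERMINATION,
)
from .errors import StructureError

ASSERTION_VOCABULARY_VERSION = 1

#: Trans-acting requirements that are satisfiable outside the cluster.
_ALWAYS_AVAILABLE = ("sulfotransferase",)


@dataclass
class RetroPrediction:
    """Predicted module architecture plus the assertion set used to score."""

    modules: list[ModuleSpec]
    starter_monomer: str | None
    trans_requirements: set[str]
    assertions: set[str]
    provenance: dict[str, str] = field(default_factory=dict)
    vocabulary_version: int = ASSERTION_VOCABULARY_VERSION

    @property
    def n_elongations(self) -> int:
        return sum(1 for m in self.modules if m.role == ROLE_ELONGATION)


@dataclass
class CongruenceReport:
    score: float
    matched: set[str]
    missing: set[str]
    extra: set[str]
    note: str = ("congruence score is a package-defined Jaccard-style "
                 "statistic over assertion vocabulary v1")


# ---------------------------------------------------------------------------
# Structure -> assertions
# ---------------------------------------------------------------------------

def _beta_assertion(e: int, state: str, geometry: str | None) -> str:
    if state == "hydroxyl":
        return f"e{e}:beta=hydroxyl:{geometry or 'any'}"
    if state == "olefin":
        return f"e{e}:beta=olefin:{geometry or 'any'}"
    if state == "olefin_shifted":
        return f"e{e}:beta=olefin_shifted:{geometry or 'any'}"
    return f"e{e}:beta={state}"


def structure_assertions(structure: AssembledStructure) -> tuple[set[str], dict[str, str]]:
    """Derive the per-position feature-assertion set from a finalized
    structure, with provenance notes keyed by assertion."""
    E = structure.n_post_nrps
    pmap = compute_position_map(E)
    out: set[str] = set()
    notes: dict[str, str] = {}
    for e in range(1, E + 1):
        a, b = pmap.alpha(e), pmap.beta(e)
        fa = structure.features.get(a)
        fb = structure.features.get(b)
        if fa is None:
            raise StructureError(f"backbone position C{a} missing")
        out.add(f"e{e}:extend")
        if fb is None:
            # β carbon trimmed (post-assembly hydrolysis): only the
            # extension itself remains observable.
            continue
        if fb.branch_mode is not None:
            out.add(f"e{e}:beta_branch:{fb.branch_mode}")
            out.add("hcs_cassette")
            notes[f"e{e}:beta_branch:{fb.branch_mode}"] = (
                f"branch methyl on C{b} implies an HCS-cassette site (ketone "
                "substrate with in-line ECH)")
        else:
            state, geometry = _read_beta(structure, a, b)
            out.add(_beta_assertion(e, state, geometry))
        if fa.branch_methyls and fa.branch_mode is None:
            out.add(f"e{e}:alpha_methyl:{len(fa.branch_methyls)}")
        if fa.state == "hydroxyl" and fa.stereo is None:
            out.add(f"e{e}:alpha_hydroxyl")
            notes[f"e{e}:alpha_hydroxyl"] = (
                f"hydroxyl on the α carbon C{a}: LLM or trans-acting "
                "hydroxylase required")
    if structure.starter is not None:
        out.add(f"starter:{structure.starter.monomer_id}")
    for aa in structure.amino_acids:
        if not structure.hydrolyzed:
            out.add(f"nrps:{aa}")
    # Release machinery is required whether or not a macrolactone formed.
    out.add("termination")
    if structure.tail_extension:
        te = structure.tail_extension
        out.add(f"tail_extension:units={te['units']}:methyls={te['methyls']}")
    for pos, decos in structure.decorations.items():
        for deco in decos:
            if deco == "macrolactone":
                continue
            enzyme = {"carbamate": "CT", "sulfate": "sulfotransferase",
                      "glycosyl": "GTF"}.get(deco, deco)
            out.add(f"tailoring:{enzyme}:C{pos}")
    return out, notes


def _read_beta(structure: AssembledStructure, a: int, b: int):
    fa, fb = structure.features[a], structure.features[b]
    if fb.state == "hydroxyl":
        return "hydroxyl", fb.stereo
    if fb.state == "ketone":
        return "ketone", None
    if fa.olefin == a:
        return "olefin", fa.olefin_geometry
    if fb.olefin == b:
        return "olefin_shifted", fb.olefin_geometry
    if fb.state == "methylene":
        return "saturated", None
    if fb.state == "olefinic":
        # β carbon participates in a neighbouring unit's olefin (e.g. a
        # shifted bond landing on this carbonyl): the module itself reduced
        # nothing beyond what the neighbour explains.
        return "ketone", None
    return fb.state, None


# ---------------------------------------------------------------------------
# Retro prediction
# ---------------------------------------------------------------------------

def retro_predict(structure: AssembledStructure) -> RetroPrediction:
    """Predict the minimal module architecture for a structure feature table.

    The predicted elongation count is ``polyketide backbone carbons / 2``;
    each elongation pair's β-state implies a required domain set (the inverse
    of the forward elongation rules).
    """
    assertions, notes = structure_assertions(structure)
    E = structure.n_post_nrps
    pmap = compute_position_map(E)

    def domain(kind, **attrs):
        return DomainAnnotation(kind=kind, gene_id="predicted", attrs=attrs)

    modules: list[ModuleSpec] = []
    trans_req: set[str] = set()
    index = 1
    if structure.starter is not None:
        modules.append(ModuleSpec(
            index=index, role=ROLE_LOADING,
            domains=(domain("ACP"), domain("ACP_beta"), domain("ACP"))))
        index += 1
        trans_req.add("trans_AT_relaxed")
    if structure.amino_acids and not structure.hydrolyzed:
        for aa in structure.amino_acids:
            modules.append(ModuleSpec(
                index=index, role=ROLE_NRPS,
                domains=(domain("C"), domain("A", adenylation_substrate=aa),
                         domain("PCP"))))
            index += 1
    for e in range(1, E + 1):
        doms = [domain("KS")]
        ann = set()
        a, b = pmap.alpha(e), pmap.beta(e)
        fa, fb = structure.features[a], structure.features[b]
        if fb.branch_mode is not None:
            doms.append(domain("ECH"))
            trans_req.add("hcs_cassette")
        else:
            state, geometry = _read_beta(structure, a, b)
            if state == "hydroxyl":
                kr = {"L": "A", "D": "B", None: "unknown"}[geometry]
                doms.append(domain("KR", kr_type=kr))
            elif state in ("olefin", "olefin_shifted"):
                if geometry in ("cis", "trans"):
                    doms.append(domain("KR",
                                       kr_type={"cis": "A", "trans": "B"}[geometry]))
                shift = state == "olefin_shifted"
                doms.append(domain("DH", shift=shift) if shift else domain("DH"))
            elif state == "saturated":
                doms.append(domain("KR", kr_type="unknown"))
                doms.append(domain("DH"))
                ann.add("trans_ER")
                trans_req.add("trans_ER")
        if fa.branch_methyls and fa.branch_mode is None:
            doms.extend(domain("cMT") for _ in fa.branch_methyls)
        if fa.state == "hydroxyl" and fa.stereo is None:
            doms.append(domain("LLM"))
            trans_req.add("hydroxylase_or_LLM")
        doms.append(domain("ACP"))
        modules.append(ModuleSpec(
            index=index, role=ROLE_ELONGATION, domains=tuple(doms),
            elongation_ordinal=e, trans_annotations=frozenset(ann)))
        index += 1
    modules.append(ModuleSpec(
        index=index, role=ROLE_TERMINATION,
        domains=(domain("C_trunc", catalytic_his=True),)))
    for pos, decos in structure.decorations.items():
        if "carbamate" in decos:
            trans_req.add("CT")
        if "sulfate" in decos:
            trans_req.add("sulfotransferase")
        if "glycosyl" in decos:
            trans_req.add("GTF")
    return RetroPrediction(
        modules=modules, starter_monomer=(
            structure.starter.monomer_id if structure.starter else None),
        trans_requirements=trans_req, assertions=assertions, provenance=notes)


# ---------------------------------------------------------------------------
# Architecture -> capabilities
# ---------------------------------------------------------------------------

def architecture_capabilities(arch: BGCArchitecture) -> set[str]:
    """Express a segmented architecture in the assertion vocabulary.

    This is a per-module reading of what each domain set can produce — not a
    forward assembly — so congruence compares expectation against capability
    position by position.
    """
    from .bgc_model import segment_modules

    if not arch.modules:
        arch = segment_modules(arch)
    caps: set[str] = set()

    nrps_indices = [m.index for m in arch.modules if m.role == ROLE_NRPS]
    last_nrps = max(nrps_indices) if nrps_indices else None
    elong = [m for m in arch.modules if m.role == ROLE_ELONGATION]
    tail = [m for m in elong if last_nrps is not None and m.index < last_nrps]
    post = [m for m in elong if m not in tail]
    E = len(post)
    pmap = compute_position_map(E) if E else None

    trans_kinds = arch.trans_domain_kinds()
    cassette_ok = {"HCS", "KS", "ACP"} <= trans_kinds

    amino_acids = []
    for m in arch.modules:
        if m.role == ROLE_NRPS:
            a = m.domains_of_kind("A")
            if a:
                amino_acids.append(a[0].attrs.get("adenylation_substrate", "glycine"))

    for e, m in enumerate(post, start=1):
        caps.add(f"e{e}:extend")
        kr = next((d for d in m.domains
                   if d.kind == "KR" and d.attrs.get("active", True)), None)
        kr_type = kr.kr_type if kr else None
        reduces = kr_type in ("A", "B", "unknown")
        has_dh = any(d.kind == "DH" and d.attrs.get("active", True)
                     for d in m.domains)
        shift = any(d.kind in ("DH", "DHt") and d.attrs.get("shift", False)
                    for d in m.domains)
        has_ech = any(d.kind == "ECH" for d in m.domains)
        n_cmt = sum(1 for d in m.domains if d.kind == "cMT")
        has_llm = any(d.kind == "LLM" for d in m.domains)

        if has_ech and not reduces and not has_dh and cassette_ok:
            caps.add(f"e{e}:beta_branch:internal")
            caps.add("hcs_cassette")
        elif "trans_ER" in m.trans_annotations and has_dh:
            caps.add(f"e{e}:beta=saturated")
        elif has_dh:  # permissive DH-only modules still dehydrate
            geometry = ({"A": "cis", "B": "trans"}.get(kr_type, "any")
                        if reduces else "any")
            kind = "olefin_shifted" if shift else "olefin"
            caps.add(f"e{e}:beta={kind}:{geometry}")
        elif reduces:
            config = {"A": "L", "B": "D", "unknown": "any"}[kr_type]
            caps.add(f"e{e}:beta=hydroxyl:{config}")
        else:
            caps.add(f"e{e}:beta=ketone")
        if n_cmt:
            caps.add(f"e{e}:alpha_methyl:{n_cmt}")
        branch_cap = has_ech and not reduces and not has_dh and cassette_ok
        saturated_cap = "trans_ER" in m.trans_annotations and has_dh
        alpha_blocked = branch_cap or (has_dh and not shift and not saturated_cap)
        if has_llm and not alpha_blocked:
            caps.add(f"e{e}:alpha_hydroxyl")

    if arch.starter_monomer:
        caps.add(f"starter:{arch.starter_monomer}")
    for aa in amino_acids:
        caps.add(f"nrps:{aa}")
    if any(m.role == ROLE_TERMINATION for m in arch.modules):
        caps.add("termination")
    if tail:
        methyls = sum(1 for m in tail for d in m.domains if d.kind == "cMT")
        caps.add(f"tail_extension:units={len(tail)}:methyls={methyls}")
    if "CT" in trans_kinds and any(t.get("enzyme") == "CT" for t in arch.tailoring):
        # The realized carbamoylation position depends on the assembled
        # hydroxyl pattern (ring competition included); capability asserts
        # availability with an unconstrained position.
        caps.add("tailoring:CT:any")
    if "GTF" in trans_kinds and any(t.get("enzyme") == "GTF" for t in arch.tailoring):
        caps.add("tailoring:GTF:any")
    return caps


# ---------------------------------------------------------------------------
# Congruence
# ---------------------------------------------------------------------------

def _compatible(req: str, cap: str) -> bool:
    """Degeneracy-aware assertion matching (requirement vs capability)."""
    if req == cap:
        return True
    r, c = req.split(":"), cap.split(":")
    if r[:2] != c[:2] or len(r) != len(c):
        return False
    # trailing stereochemistry/geometry field: 'any' on either side matches
    return all(x == y or "any" in (x, y) for x, y in zip(r[2:], c[2:]))


def congruence_score(pred: RetroPrediction,
                     arch: BGCArchitecture) -> CongruenceReport:
    """Score a retro prediction against a candidate architecture.

    ``matched`` are requirement assertions satisfied by a compatible
    capability; ``missing`` are unsatisfied requirements; ``extra`` are
    capabilities predicting features absent from the structure.  Sulfation
    requirements match unconditionally (genome-encoded sulfatases outside
    the cluster).
    """
    caps = architecture_capabilities(arch)
    matched: set[str] = set()
    missing: set[str] = set()
    used: set[str] = set()
    for req in sorted(pred.assertions):
        if any(req.startswith(f"tailoring:{e}:") for e in _ALWAYS_AVAILABLE):
            matched.add(req)
            continue
        hit = next((c for c in sorted(caps - used) if _compatible(req, c)), None)
        if hit is not None:
            matched.add(req)
            used.add(hit)
        else:
            missing.add(req)
    extra = caps - used
    total = len(matched) + len(missing) + len(extra)
    score = len(matched) / total if total else 1.0
    return CongruenceReport(score=score, matched=matched, missing=missing,
                            extra=extra)
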