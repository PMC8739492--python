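"""Data model for trans-AT PKS-NRPS gene-cluster architectures.

A biosynthetic gene cluster (BGC) is represented as an ordered list of genes,
each carrying an ordered list of annotated enzymatic domains.  Core
(cis-acting) genes form a single concatenated domain stream that is segmented
into biosynthetic modules; standalone acyltransferases, the HCS cassette,
tailoring enzymes and transporters are flagged ``is_trans_acting`` and stay
outside the module count.

Module boundaries are never stored in fixture files — they are always
recomputed by :func:`segment_modules` so that the segmentation rule itself is
testable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable

from .errors import ParseError, SegmentationError, ValidationError

# Closed enumeration of domain codes.  Unknown codes in fixtures are mapped to
# OTHER (with a warning) rather than dropped, so hypothetical proteins stay
# visible in the architecture.
DOMAIN_KINDS = frozenset({
    "KS", "AT", "KR", "DH", "DHt", "ER", "cMT", "ECH",
    "ACP", "ACP_beta", "PCP", "CARRIER_UNRESOLVED",
    "C", "C_trunc", "A", "LLM", "HCS", "CT", "GTF", "LO", "TE", "OTHER",
})

#: Domain kinds that tether the growing chain (phosphopantetheine carriers).
CARRIER_KINDS = frozenset({"ACP", "ACP_beta", "PCP", "CARRIER_UNRESOLVED"})

#: Module roles.
ROLE_LOADING = "loading"
ROLE_NRPS = "nrps"
ROLE_ELONGATION = "pks_elongation"
ROLE_TERMINATION = "termination"

KR_TYPES = frozenset({"A", "B", "C", "unknown"})


@dataclass(frozen=True)
class DomainAnnotation:
    """One enzymatic domain within a gene.

    ``attrs`` carries optional key-value flags: ``kr_type`` (A/B/C/unknown,
    KR domains only), ``active`` (bool), ``adenylation_substrate`` (amino-acid
    name on A domains), ``shift`` (bool; olefin-shifting dehydratase).
    """

    kind: str
    gene_id: str = ""
    ordinal: int = 0
    attrs: dict = field(default_factory=dict)
    sequence: str | None = None

    def __post_init__(self):
        if self.kind not in DOMAIN_KINDS:
            raise ValidationError(f"unknown domain kind {self.kind!r}")
        if "kr_type" in self.attrs:
            if self.kind != "KR":
                raise ValidationError(
                    f"kr_type attribute on non-KR domain in gene {self.gene_id!r}")
            if self.attrs["kr_type"] not in KR_TYPES:
                raise ValidationError(
                    f"invalid kr_type {self.attrs['kr_type']!r} in gene {self.gene_id!r}")

    @property
    def kr_type(self) -> str:
        return self.attrs.get("kr_type", "unknown")

    @property
    def is_carrier(self) -> bool:
        return self.kind in CARRIER_KINDS

    def to_dict(self) -> dict:
        d: dict = {"kind": self.kind}
        if self.attrs:
            d["attrs"] = dict(self.attrs)
        if self.sequence is not None:
            d["sequence"] = self.sequence
        return d


@dataclass(frozen=True)
class GeneRecord:
    """One gene and its ordered domain annotations."""

    gene_id: str
    domains: tuple[DomainAnnotation, ...]
    is_trans_acting: bool = False

    def __post_init__(self):
        if not self.domains:
            raise ValidationError(f"gene {self.gene_id!r} has no domains")

    def to_dict(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "trans_acting": self.is_trans_acting,
            "domains": [d.to_dict() for d in self.domains],
        }


@dataclass(frozen=True)
class ModuleSpec:
    """One core biosynthetic module (computed, never stored)."""

    index: int                     # 1-based position among core modules
    role: str
    domains: tuple[DomainAnnotation, ...]
    elongation_ordinal: int | None = None   # 1..E over pks_elongation modules
    trans_annotations: frozenset = frozenset()   # {trans_ER, hcs_site, llm_site}

    def __post_init__(self):
        if (self.role == ROLE_ELONGATION) != (self.elongation_ordinal is not None):
            raise ValidationError(
                f"module {self.index}: elongation_ordinal present iff role is pks_elongation")

    def domains_of_kind(self, kind: str) -> tuple[DomainAnnotation, ...]:
        return tuple(d for d in self.domains if d.kind == kind)

    @property
    def kinds(self) -> tuple[str, ...]:
        return tuple(d.kind for d in self.domains)


@dataclass(frozen=True)
class MonomerSpec:
    """A starter/extender monomer and its carbon bookkeeping."""

    monomer_id: str
    carbon_count: int
    backbone_carbons: int = 0
    heteroatoms: dict = field(default_factory=dict)
    terminal_olefin: bool = False
    beta_branch_in_starter: bool = False

    def __post_init__(self):
        if self.backbone_carbons > self.carbon_count:
            raise ValidationError("backbone_carbons exceeds carbon_count")
        if self.carbon_count < 0 or self.backbone_carbons < 0 or any(
                v < 0 for v in self.heteroatoms.values()):
            raise ValidationError("monomer counts must be non-negative")


#: Starter units referenced by the palmerolide clusters.  Starter carbons lie
#: beyond the amide nitrogen and are excluded from the numbered backbone.
MONOMER_LIBRARY: dict[str, MonomerSpec] = {
    "3-methylcrotonic acid": MonomerSpec(
        "3-methylcrotonic acid", carbon_count=5,
        beta_branch_in_starter=True),
    "3-methyl-3-butenoic acid": MonomerSpec(
        "3-methyl-3-butenoic acid", carbon_count=5,
        beta_branch_in_starter=True, terminal_olefin=True),
    "acetate": MonomerSpec("acetate", carbon_count=2),
}

#: Amino-acid contributions of NRPS modules: numbered backbone carbons and
#: heteroatoms added per residue.
AMINO_ACID_CONTRIBUTIONS: dict[str, dict] = {
    "glycine": {"backbone_carbons": 2, "heteroatoms": {"N": 1}},
}


@dataclass(frozen=True)
class BGCArchitecture:
    """An ordered gene/domain architecture plus computed modules."""

    bgc_id: str
    genes: tuple[GeneRecord, ...]
    modules: tuple[ModuleSpec, ...] = ()
    starter_monomer: str | None = None
    tailoring: tuple[dict, ...] = ()
    trans_er_modules: frozenset = frozenset()

    def __post_init__(self):
        if not self.genes:
            raise ValidationError(f"architecture {self.bgc_id!r} has no genes")

    @property
    def core_genes(self) -> tuple[GeneRecord, ...]:
        return tuple(g for g in self.genes if not g.is_trans_acting)

    @property
    def trans_genes(self) -> tuple[GeneRecord, ...]:
        return tuple(g for g in self.genes if g.is_trans_acting)

    @property
    def core_domain_stream(self) -> tuple[DomainAnnotation, ...]:
        return tuple(d for g in self.core_genes for d in g.domains)

    @property
    def elongation_modules(self) -> tuple[ModuleSpec, ...]:
        return tuple(m for m in self.modules if m.role == ROLE_ELONGATION)

    def trans_domain_kinds(self) -> set[str]:
        return {d.kind for g in self.trans_genes for d in g.domains}


# ---------------------------------------------------------------------------
# Fixture parsing / serialization
# ---------------------------------------------------------------------------

def _parse_domain(raw: dict, gene_id: str, ordinal: int) -> DomainAnnotation:
    if not isinstance(raw, dict) or "kind" not in raw:
        raise ParseError(f"gene {gene_id!r}: domain {ordinal} lacks a 'kind'")
    kind = raw["kind"]
    attrs = dict(raw.get("attrs", {}))
    if kind not in DOMAIN_KINDS:
        warnings.warn(
            f"gene {gene_id!r}: unknown domain code {kind!r} mapped to OTHER",
            stacklevel=3)
        attrs.setdefault("original_kind", kind)
        kind = "OTHER"
    return DomainAnnotation(kind=kind, gene_id=gene_id, ordinal=ordinal,
                            attrs=attrs, sequence=raw.get("sequence"))


def parse_architecture(text: str) -> BGCArchitecture:
    """Parse a JSON architecture fixture.

    Gene and domain order is preserved; ``modules`` is left empty until
    :func:`segment_modules` is called.  Unknown domain codes map to ``OTHER``
    with a warning.
    """
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"malformed architecture fixture: {exc}") from exc
    if not isinstance(raw, dict):
        raise ParseError("architecture fixture must be a JSON object")
    genes_raw = raw.get("genes", [])
    if not genes_raw:
        raise ValidationError("architecture fixture has an empty gene list")
    genes = []
    for g in genes_raw:
        gene_id = g.get("gene_id")
        if not gene_id:
            raise ParseError("gene record without gene_id")
        if not g.get("domains"):
            raise ParseError(f"gene {gene_id!r} has no domains")
        domains = tuple(_parse_domain(d, gene_id, i)
                        for i, d in enumerate(g["domains"]))
        genes.append(GeneRecord(gene_id=gene_id, domains=domains,
                                is_trans_acting=bool(g.get("trans_acting", False))))
    return BGCArchitecture(
        bgc_id=raw.get("bgc_id", "unnamed"),
        genes=tuple(genes),
        starter_monomer=raw.get("starter_monomer"),
        tailoring=tuple(raw.get("tailoring", [])),
        trans_er_modules=frozenset(raw.get("trans_er_modules", [])),
    )


def serialize_architecture(arch: BGCArchitecture) -> str:
    """Serialize to the JSON fixture format (module boundaries not stored)."""
    doc = {
        "bgc_id": arch.bgc_id,
        "starter_monomer": arch.starter_monomer,
        "tailoring": [dict(t) for t in arch.tailoring],
        "trans_er_modules": sorted(arch.trans_er_modules),
        "genes": [g.to_dict() for g in arch.genes],
    }
    return json.dumps(doc, indent=1, sort_keys=False) + "\n"


def load_architecture(path) -> BGCArchitecture:
    with open(path) as fh:
        return parse_architecture(fh.read())


# ---------------------------------------------------------------------------
# Module segmentation
# ---------------------------------------------------------------------------

def _is_boundary(domain: DomainAnnotation) -> bool:
    return domain.kind in {"KS", "C", "C_trunc"}


def _segment_role(segment: list[DomainAnnotation]) -> str:
    head = segment[0].kind
    if head == "KS":
        return ROLE_ELONGATION
    if head == "C_trunc":
        return ROLE_TERMINATION
    # Full condensation domain: NRPS module (validated downstream if the A
    # domain is missing).
    return ROLE_NRPS


def segment_modules(arch: BGCArchitecture) -> BGCArchitecture:
    """Segment the concatenated core-gene domain stream into modules.

    A new module starts at each KS or condensation (C / truncated C) domain.
    Domains preceding the first boundary seed the loading module; when the
    first KS segment consists solely of the KS and carrier proteins it is the
    starter-accepting KS and is merged into the loading module rather than
    counted as an elongation.  A trailing truncated C domain forms the
    termination module.
    """
    stream = arch.core_domain_stream
    if not any(d.kind == "KS" for d in stream):
        raise SegmentationError(
            f"{arch.bgc_id}: no elongation machinery (zero KS domains in core genes)")

    segments: list[list[DomainAnnotation]] = []
    leading: list[DomainAnnotation] = []
    current: list[DomainAnnotation] | None = None
    for dom in stream:
        if _is_boundary(dom):
            current = [dom]
            segments.append(current)
        elif current is None:
            leading.append(dom)
        else:
            current.append(dom)

    modules: list[tuple[str, list[DomainAnnotation]]] = []
    start = 0
    if leading:
        loading = list(leading)
        first = segments[0]
        if first[0].kind == "KS" and all(
                d.kind == "KS" or d.is_carrier for d in first):
            # Starter-accepting KS (no chain-processing domains): part of the
            # loading module, not an elongation.
            loading += first
            start = 1
        modules.append((ROLE_LOADING, loading))
    for seg in segments[start:]:
        modules.append((_segment_role(seg), seg))

    specs = []
    ordinal = 0
    for idx, (role, domains) in enumerate(modules, start=1):
        if role == ROLE_ELONGATION:
            ordinal += 1
            e: int | None = ordinal
        else:
            e = None
        ann = set()
        if idx in arch.trans_er_modules:
            ann.add("trans_ER")
        if any(d.kind == "ECH" for d in domains):
            ann.add("hcs_site")
        if any(d.kind == "LLM" for d in domains):
            ann.add("llm_site")
        specs.append(ModuleSpec(index=idx, role=role, domains=tuple(domains),
                                elongation_ordinal=e,
                                trans_annotations=frozenset(ann)))
    return replace(arch, modules=tuple(specs))


# ---------------------------------------------------------------------------
# Validation (report-only)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationEntry:
    module_index: int | None
    code: str
    message: str


@dataclass
class ValidationReport:
    entries: list[ValidationEntry] = field(default_factory=list)

    def add(self, module_index, code, message):
        self.entries.append(ValidationEntry(module_index, code, message))

    def codes(self) -> set[str]:
        return {e.code for e in self.entries}

    def __bool__(self):
        return bool(self.entries)

    def __iter__(self) -> Iterable[ValidationEntry]:
        return iter(self.entries)


def validate_architecture(arch: BGCArchitecture) -> ValidationReport:
    """List rule violations of a segmented architecture without raising.

    A DH without an accompanying KR is flagged (the olefin then requires the
    permissive rule established for clusters like sorangicin); structural
    invariant breaches (two KS in one module, NRPS without C+A) are reported
    as violations.
    """
    report = ValidationReport()
    if not arch.modules:
        report.add(None, "not_segmented", "architecture has no computed modules")
        return report
    for mod in arch.modules:
        kinds = list(mod.kinds)
        n_ks = kinds.count("KS")
        if mod.role == ROLE_ELONGATION:
            if n_ks != 1:
                report.add(mod.index, "multiple_ks",
                           f"elongation module has {n_ks} KS domains")
            has_kr = any(d.kind == "KR" and d.kr_type in ("A", "B", "unknown")
                         for d in mod.domains)
            if "DH" in kinds and not has_kr:
                report.add(mod.index, "dh_without_kr",
                           "DH without KR: needs permissive olefin rule")
        elif mod.role == ROLE_NRPS:
            if "C" not in kinds or "A" not in kinds:
                report.add(mod.index, "incomplete_nrps",
                           "NRPS module must contain a C and an A domain")
        if not any(d.is_carrier for d in mod.domains) and mod.role != ROLE_TERMINATION:
            report.add(mod.index, "no_carrier", "module lacks a carrier protein")
    if arch.starter_monomer is not None and arch.starter_monomer not in MONOMER_LIBRARY:
        report.add(None, "unknown_starter",
                   f"starter monomer {arch.starter_monomer!r} not in library")
    return report
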