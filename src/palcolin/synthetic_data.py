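"""Synthetic test-data generators.

Three generators cover every input the pipeline consumes, so the test suite
needs no downloads: random valid module architectures with independently
computed ground-truth products, protein sequences with motifs embedded at
known offsets (and verified motif-free decoys), and alignments evolved under
the Jukes-Cantor substitution process along a known tree.

All generators are pure functions of their configuration and seed; each
draws from its own seed-derived stream, so adding a generator never
perturbs existing fixtures.  The ground-truth interpreter in this module is
an intentionally naive, position-by-position re-derivation of the product
chemistry that shares no code with the assembly engine (it renumbers carbons
by walking the finished chain from the thioester end) — it exists to serve
as the independent oracle in dual-implementation tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bgc_model import (
    BGCArchitecture, parse_architecture, segment_modules,
    serialize_architecture,
)
from .errors import SimulationError
from .motif_engine import AMINO_ACIDS, MotifDefinition, DEFAULT_MOTIFS
from .phylo_engine import NUCLEOTIDE_ALPHABET


@dataclass(frozen=True)
class SimulationConfig:
    """Architecture-grammar parameters (probabilities per elongation module)."""

    seed: int
    min_elongations: int = 2
    max_elongations: int = 8
    p_kr: float = 0.7
    p_dh_given_kr: float = 0.5
    p_dh_alone: float = 0.1
    p_shift_given_dh: float = 0.15
    p_cmt: float = 0.2
    p_trans_er: float = 0.1
    p_hcs_site: float = 0.1
    p_llm: float = 0.1
    p_nrps: float = 0.7
    p_starter: float = 0.8
    p_ct: float = 0.4
    kr_type_probs: tuple = (("A", 0.45), ("B", 0.45), ("C", 0.10))

    def __post_init__(self):
        probs = [self.p_kr, self.p_dh_given_kr, self.p_dh_alone,
                 self.p_shift_given_dh, self.p_cmt, self.p_trans_er,
                 self.p_hcs_site, self.p_llm, self.p_nrps, self.p_starter,
                 self.p_ct]
        if any(not 0 <= p <= 1 for p in probs):
            raise SimulationError("probabilities must lie in [0, 1]")
        if self.min_elongations > self.max_elongations or self.min_elongations < 1:
            raise SimulationError("empty elongation-count range")


def _rng(cfg_seed: int, stream: str) -> np.random.Generator:
    import zlib

    return np.random.default_rng([cfg_seed, zlib.crc32(stream.encode())])


# ---------------------------------------------------------------------------
# Architecture grammar + naive ground truth
# ---------------------------------------------------------------------------

def simulate_architecture(cfg: SimulationConfig):
    """Draw one architecture and its independently derived ground truth.

    Returns ``(BGCArchitecture, ground_truth_dict)`` where the ground truth
    matches the shape of ``AssembledStructure.feature_assertions()``.
    """
    rng = _rng(cfg.seed, "architecture")
    E = int(rng.integers(cfg.min_elongations, cfg.max_elongations + 1))
    has_nrps = rng.random() < cfg.p_nrps
    has_starter = has_nrps and rng.random() < cfg.p_starter

    modules: list[list[dict]] = []
    for _ in range(E):
        dom = [{"kind": "KS"}]
        kr_type = None
        if rng.random() < cfg.p_kr:
            types, probs = zip(*cfg.kr_type_probs)
            kr_type = str(rng.choice(types, p=np.array(probs) / sum(probs)))
            dom.append({"kind": "KR", "attrs": {"kr_type": kr_type}})
        reduces = kr_type in ("A", "B")
        has_dh = (rng.random() < cfg.p_dh_given_kr) if reduces else (
            rng.random() < cfg.p_dh_alone)
        if has_dh:
            attrs = {}
            if rng.random() < cfg.p_shift_given_dh:
                attrs["shift"] = True
            dom.append({"kind": "DH", "attrs": attrs} if attrs
                       else {"kind": "DH"})
        trans_er = reduces and has_dh and rng.random() < cfg.p_trans_er
        if rng.random() < cfg.p_cmt:
            dom.append({"kind": "cMT"})
        if rng.random() < cfg.p_llm:
            dom.append({"kind": "LLM"})
        hcs = (kr_type is None or kr_type == "C") and not has_dh \
            and rng.random() < cfg.p_hcs_site
        if hcs:
            dom.append({"kind": "ECH"})
        dom.append({"kind": "ACP"})
        modules.append({"domains": dom, "trans_er": trans_er})

    any_branch = any(any(d["kind"] == "ECH" for d in m["domains"])
                     for m in modules)

    genes = []
    if has_starter:
        genes.append({"gene_id": "synA", "trans_acting": False, "domains": [
            {"kind": "ACP"}, {"kind": "ACP_beta"}, {"kind": "ACP"},
            {"kind": "KS"}, {"kind": "PCP"}]})
    if has_nrps:
        genes.append({"gene_id": "synN", "trans_acting": False, "domains": [
            {"kind": "C"},
            {"kind": "A", "attrs": {"adenylation_substrate": "glycine"}},
            {"kind": "ACP"}]})
    core: list[dict] = []
    for m in modules:
        core.extend(m["domains"])
    core.append({"kind": "C_trunc", "attrs": {"catalytic_his": True}})
    genes.append({"gene_id": "synB", "trans_acting": False, "domains": core})
    if any_branch:
        genes.append({"gene_id": "synK", "trans_acting": True,
                      "domains": [{"kind": "ACP"}]})
        genes.append({"gene_id": "synL", "trans_acting": True,
                      "domains": [{"kind": "HCS"}]})
        genes.append({"gene_id": "synM", "trans_acting": True,
                      "domains": [{"kind": "KS"}]})
        genes.append({"gene_id": "synO", "trans_acting": True,
                      "domains": [{"kind": "ECH"}, {"kind": "ECH"}]})

    # Core-module offset used to map to segmented module indices: loading
    # and NRPS modules precede the elongation modules.
    offset = 1 + (1 if has_starter else 0) + (1 if has_nrps else 0)
    trans_er_modules = [offset + k for k, m in enumerate(modules)
                        if m["trans_er"]]

    import json
    doc = {
        "bgc_id": f"synthetic_{cfg.seed}",
        "starter_monomer": "3-methylcrotonic acid" if has_starter else None,
        "tailoring": [],
        "trans_er_modules": trans_er_modules,
        "genes": genes,
    }
    truth = _naive_ground_truth(modules, has_nrps, has_starter, tailoring=[])
    if truth["hydroxyls_free"] and rng.random() < cfg.p_ct:
        doc["tailoring"] = [{"enzyme": "CT", "target": "default"}]
        genes.append({"gene_id": "synQ", "trans_acting": True,
                      "domains": [{"kind": "CT"}]})
        truth = _naive_ground_truth(modules, has_nrps, has_starter,
                                    tailoring=doc["tailoring"])
    truth.pop("hydroxyls_free")
    arch = segment_modules(parse_architecture(json.dumps(doc)))
    return arch, truth


def _naive_ground_truth(modules, has_nrps, has_starter, tailoring):
    """Step-by-step interpreter, independent of the assembly engine.

    Walks the chain as a list of per-unit outcomes, then numbers carbons by
    walking the finished chain from the thioester end (C1) toward the
    starter.
    """
    E = len(modules)
    outcomes = []
    for k, m in enumerate(modules):
        kinds = [d["kind"] for d in m["domains"]]
        kr = next((d for d in m["domains"] if d["kind"] == "KR"), None)
        kr_type = kr["attrs"]["kr_type"] if kr else None
        dh = "DH" in kinds
        shift = any(d["kind"] == "DH" and d.get("attrs", {}).get("shift")
                    for d in m["domains"])
        out = {
            "n_methyl": kinds.count("cMT"),
            "llm": "LLM" in kinds,
            "branch": False,
            "state": "ketone",
            "geometry": None,
            "shifted": False,
        }
        if kr_type == "A":
            out["state"], out["geometry"] = "hydroxyl", "L"
        elif kr_type == "B":
            out["state"], out["geometry"] = "hydroxyl", "D"
        if dh and out["state"] == "hydroxyl":
            out["state"] = "olefin"
            out["geometry"] = {"L": "cis", "D": "trans"}[out["geometry"]]
        elif dh:
            out["state"], out["geometry"] = "olefin", None
        if m["trans_er"] and out["state"] == "olefin":
            out["state"], out["geometry"] = "saturated", None
        if shift and out["state"] == "olefin":
            out["shifted"] = True
        if "ECH" in kinds and out["state"] == "ketone":
            out["branch"] = True  # cassette genes are present whenever drawn
        outcomes.append(out)

    # walk from the thioester end: unit k (0-based, assembly order) has its
    # alpha carbon at 2*(E-k) and beta at 2*(E-k)+1
    backbone = 2 * E + 2  # glycine or primer pair beyond the last unit
    olefins: dict[int, str | None] = {}
    hydroxyls: dict[int, str | None] = {}
    branches: dict[int, str] = {}
    for k, out in enumerate(outcomes):
        alpha = 2 * (E - k - 1) + 2
        beta = alpha + 1
        alpha_is_olefinic = (out["state"] == "olefin"
                             and not out["shifted"]) or out["branch"]
        if out["llm"] and not alpha_is_olefinic:
            hydroxyls[alpha] = None
        if out["branch"]:
            branches[beta] = "internal"
            olefins[beta - 1] = None
        if out["state"] == "hydroxyl":
            hydroxyls[beta] = out["geometry"]
        elif out["state"] == "olefin" and out["shifted"]:
            olefins[beta] = out["geometry"]
        elif out["state"] == "olefin":
            olefins[alpha] = out["geometry"]

    ring = None
    ring_eligible = [p for p in hydroxyls if p >= 12]
    if ring_eligible:
        ring = (1, max(ring_eligible))
    decorations: dict[int, tuple] = {}
    free = [p for p in sorted(hydroxyls) if p != (ring[1] if ring else None)]
    for record in tailoring:
        if record["enzyme"] == "CT" and free:
            # default target: the beta-hydroxyl of the LLM-bearing unit,
            # else the lowest-numbered free hydroxyl
            target = None
            for k, out in enumerate(outcomes):
                if out["llm"]:
                    target = 2 * (E - k - 1) + 3
                    break
            if target is None or target not in free:
                target = min(free)
            decorations[target] = ("carbamate",)
            free.remove(target)
    return {
        "backbone_carbons": backbone,
        "starter": "3-methylcrotonic acid" if has_starter else None,
        "terminal_olefin": False,
        "amide": has_nrps and has_starter,
        "glycine": has_nrps,
        "tail_extension": False,
        "ring": ring,
        "olefins": olefins,
        "hydroxyls": hydroxyls,
        "branches": branches,
        "decorations": decorations,
        "hydroxyls_free": free,
    }


# ---------------------------------------------------------------------------
# Protein sequence generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinRecord:
    seq_id: str
    sequence: str
    embedded: dict = field(default_factory=dict)   # motif_id -> offset

    @property
    def is_decoy(self) -> bool:
        return not self.embedded


def _naive_motif_scan(seq: str, motif: MotifDefinition) -> list[int]:
    """Plain sliding-window matcher used to certify decoys (and as the
    independent oracle in tests)."""
    hits = []
    k = len(motif)
    for i in range(len(seq) - k + 1):
        if all(seq[i + j] in allowed for j, allowed in enumerate(motif.positions)):
            hits.append(i)
    return hits


def simulate_proteins(n_embedded: int = 20, n_decoys: int = 20,
                      length: int = 200, seed: int = 0,
                      motifs=None) -> list[ProteinRecord]:
    """Generate labeled sequences with motifs at known offsets plus decoys.

    Every embedded instance satisfies its motif definition; decoys are
    certified motif-free by the naive scanner (re-drawn until clean).
    """
    if motifs is None:
        motifs = list(DEFAULT_MOTIFS.values())
    for m in motifs:
        if len(m) > length:
            raise SimulationError(
                f"motif {m.motif_id} longer than sequence length {length}")
    rng = _rng(seed, "proteins")
    records = []

    def background() -> str:
        return "".join(rng.choice(list(AMINO_ACIDS), size=length))

    def clean_background() -> str:
        for _ in range(1000):
            seq = background()
            if all(not _naive_motif_scan(seq, m) for m in motifs):
                return seq
        raise SimulationError("could not draw a motif-free background")

    for i in range(n_embedded):
        motif = motifs[i % len(motifs)]
        for _ in range(1000):
            seq = clean_background()
            offset = int(rng.integers(0, length - len(motif) + 1))
            instance = "".join(
                str(rng.choice(sorted(allowed))) for allowed in motif.positions)
            seq = seq[:offset] + instance + seq[offset + len(motif):]
            # every hit (including motifs nested inside the embedded
            # instance, e.g. GXDS within the attachment-site motif) must lie
            # inside the embedded window; junction artifacts force a redraw
            hits = {(m.motif_id, j, len(m))
                    for m in motifs for j in _naive_motif_scan(seq, m)}
            inside = all(offset <= j and j + k <= offset + len(motif)
                         for _, j, k in hits)
            if (motif.motif_id, offset, len(motif)) in hits and inside:
                break
        else:
            raise SimulationError("could not embed a clean motif instance")
        records.append(ProteinRecord(
            f"embedded_{i}", seq, {mid: j for mid, j, _ in hits}))
    for i in range(n_decoys):
        records.append(ProteinRecord(f"decoy_{i}", clean_background()))
    return records


def proteins_to_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.seq_id}\n{r.sequence}\n")


# ---------------------------------------------------------------------------
# Tree + alignment simulation (Jukes-Cantor process)
# ---------------------------------------------------------------------------

def random_tree(n_taxa: int, seed: int = 0,
                branch_range: tuple[float, float] = (0.05, 0.3)):
    """Random unrooted binary topology with uniform branch lengths."""
    from skbio import TreeNode

    if n_taxa < 3:
        raise SimulationError("need at least 3 taxa")
    rng = _rng(seed, "tree")

    def bl() -> float:
        return float(rng.uniform(*branch_range))

    tips = [TreeNode(name=f"t{i}", length=bl()) for i in range(n_taxa)]
    root = TreeNode()
    for t in tips[:3]:
        root.append(t)
    attachable = list(tips[:3])
    for tip in tips[3:]:
        target = attachable[int(rng.integers(0, len(attachable)))]
        parent = target.parent
        mid = TreeNode(length=bl())
        parent.remove(target)
        parent.append(mid)
        mid.append(target)
        mid.append(tip)
        attachable.append(tip)
        attachable.append(mid)
    return root


def simulate_alignment(tree, length: int, seed: int = 0,
                       alphabet: str = NUCLEOTIDE_ALPHABET):
    """Evolve i.i.d. columns under the Jukes-Cantor process along ``tree``.

    Along a branch of length t (expected substitutions per site) a site
    changes to a uniformly chosen different state with probability
    ((k-1)/k) * (1 - exp(-k*t/(k-1))).
    """
    from .phylo_engine import Alignment

    if length < 1:
        raise SimulationError("alignment length must be positive")
    rng = _rng(seed, "alignment")
    k = len(alphabet)
    letters = np.array(list(alphabet))

    def evolve(states: np.ndarray, t: float) -> np.ndarray:
        if t < 0:
            raise SimulationError("branch lengths must be non-negative")
        p_change = (k - 1) / k * (1 - np.exp(-k * t / (k - 1)))
        out = states.copy()
        hit = rng.random(length) < p_change
        if hit.any():
            shifts = rng.integers(1, k, size=int(hit.sum()))
            out[hit] = (out[hit] + shifts) % k
        return out

    root_states = rng.integers(0, k, size=length)
    labels, rows = [], []

    def descend(node, states):
        for child in node.children:
            child_states = evolve(states, child.length or 0.0)
            if child.is_tip():
                labels.append(child.name)
                rows.append("".join(letters[child_states]))
            else:
                descend(child, child_states)

    descend(tree, root_states)
    return Alignment(tuple(labels), tuple(rows))


# ---------------------------------------------------------------------------
# Convenience
# ---------------------------------------------------------------------------

def write_architecture(arch: BGCArchitecture, path) -> None:
    with open(path, "w") as fh:
        fh.write(serialize_architecture(arch))
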