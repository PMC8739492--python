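"""Active-site motif scanning and domain classification.

Classification is driven by short, position-restricted residue patterns
written in a compact notation: a plain letter matches itself, ``X`` matches
any residue, and a bracketed set such as ``[DE]`` or ``[LI]`` matches any of
its members.  The defaults cover the motifs that diagnose domain function in
trans-AT PKS-NRPS clusters:

* ``GXDS`` — β-branch-accepting carrier protein (ACP-β),
* ``[DE]XGXDS[LI]`` — phosphopantetheine attachment site of carrier proteins
  (the terminal residue may be leucine or isoleucine),
* ``HHXXDDG`` — condensation-domain catalytic core; the second histidine is
  the catalytic residue and degenerate matches are tolerated elsewhere,
* ``LDD`` — B-type ketoreductase fingerprint (d-configured hydroxyls),
* ``GGNGSGKST`` — ABC-transporter nucleotide-binding domain.

Ketoreductases lacking LDD but carrying the active-site tryptophan are A-type
(l-configured hydroxyls); those with neither are C-type and perform no
reduction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import InputSequenceError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID = frozenset(AMINO_ACIDS + "X")


@dataclass(frozen=True)
class MotifDefinition:
    """A named residue pattern with an optional sequence-coordinate window."""

    motif_id: str
    pattern: str
    min_region: int | None = None
    max_region: int | None = None

    def __post_init__(self):
        if not self.pattern:
            raise ValueError("motif pattern must be non-empty")
        if (self.min_region is not None and self.max_region is not None
                and self.min_region > self.max_region):
            raise ValueError("motif window must satisfy min <= max")
        self.positions  # validate eagerly

    @property
    def positions(self) -> tuple[frozenset, ...]:
        """Pattern compiled to one allowed-residue set per position."""
        out: list[frozenset] = []
        i, pat = 0, self.pattern
        while i < len(pat):
            ch = pat[i]
            if ch == "[":
                j = pat.index("]", i)
                out.append(frozenset(pat[i + 1:j]))
                i = j + 1
            elif ch == "X":
                out.append(frozenset(AMINO_ACIDS))
                i += 1
            else:
                out.append(frozenset(ch))
                i += 1
        return tuple(out)

    def __len__(self):
        return len(self.positions)


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    start: int          # 0-based offset
    matched: str


DEFAULT_MOTIFS: dict[str, MotifDefinition] = {
    m.motif_id: m for m in (
        MotifDefinition("acp_beta_gxds", "GXDS"),
        MotifDefinition("ppant_attachment", "[DE]XGXDS[LI]"),
        MotifDefinition("condensation_core", "HHXXDDG"),
        MotifDefinition("kr_type_b_ldd", "LDD"),
        MotifDefinition("abc_nbd", "GGNGSGKST"),
    )
}


def _check_sequence(seq: str) -> None:
    if not seq:
        raise InputSequenceError("empty sequence")
    bad = [i for i, ch in enumerate(seq) if ch not in _VALID]
    if bad:
        raise InputSequenceError(
            f"illegal characters at positions {bad[:10]}"
            + ("..." if len(bad) > 10 else ""))


def scan_motifs(seq: str, motifs=None) -> list[MotifHit]:
    """Return all motif windows matching ``seq``, sorted by start offset.

    Overlapping matches are reported.  ``X`` in the query sequence matches
    only pattern positions that allow any residue.
    """
    if motifs is None:
        motifs = DEFAULT_MOTIFS.values()
    elif isinstance(motifs, dict):
        motifs = motifs.values()
    _check_sequence(seq)
    hits: list[MotifHit] = []
    for motif in motifs:
        regex = re.compile("".join(
            "." if pos == frozenset(AMINO_ACIDS) else "[" + "".join(sorted(pos)) + "]"
            for pos in motif.positions))
        lo = motif.min_region or 0
        hi = motif.max_region if motif.max_region is not None else len(seq)
        region = seq[lo:hi]
        for i in range(len(region) - len(motif) + 1):
            if regex.fullmatch(region[i:i + len(motif)]):
                hits.append(MotifHit(motif.motif_id, lo + i, region[i:i + len(motif)]))
    hits.sort(key=lambda h: (h.start, h.motif_id))
    return hits


# ---------------------------------------------------------------------------
# Domain classifiers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KRClassification:
    kr_type: str                 # A | B | C
    predicted_config: str        # L | D | none
    evidence: tuple = ()


def classify_kr(seq: str, trp_window: tuple[int, int] | None = None) -> KRClassification:
    """Type a ketoreductase domain and predict hydroxyl configuration.

    LDD present -> B-type, d-configured product (LDD takes precedence over a
    tryptophan when both occur).  No LDD but a tryptophan in the active-site
    window (whole domain by default) -> A-type, l-configured.  Neither -> C
    type, no reduction.
    """
    _check_sequence(seq)
    ldd = scan_motifs(seq, [DEFAULT_MOTIFS["kr_type_b_ldd"]])
    if ldd:
        return KRClassification("B", "D", tuple(ldd))
    lo, hi = trp_window if trp_window else (0, len(seq))
    w = seq.find("W", lo, hi)
    if w >= 0:
        return KRClassification(
            "A", "L", (MotifHit("kr_type_a_trp", w, "W"),))
    return KRClassification("C", "none")


@dataclass(frozen=True)
class CondensationClassification:
    form: str                    # canonical | truncated
    catalytic_his: bool
    evidence: tuple = ()


def classify_condensation(seq: str, length_threshold: int = 250,
                          max_mismatches: int = 2) -> CondensationClassification:
    """Classify a condensation domain as canonical or truncated.

    Truncation is a pure length call (default threshold 250 aa, between the
    133-residue truncated termination domain and the ~450-residue canonical
    form).  The catalytic histidine is sought with a degenerate HHXXDDG
    match: the second histidine must be present, and up to ``max_mismatches``
    of the remaining fixed positions (H-, -DD, G) may differ.
    """
    _check_sequence(seq)
    form = "truncated" if len(seq) < length_threshold else "canonical"
    motif = DEFAULT_MOTIFS["condensation_core"].positions
    hits = []
    for i in range(len(seq) - len(motif) + 1):
        window = seq[i:i + len(motif)]
        if window[1] != "H":          # catalytic histidine is non-negotiable
            continue
        mismatches = sum(1 for j, pos in enumerate(motif)
                         if j != 1 and window[j] not in pos
                         and pos != frozenset(AMINO_ACIDS))
        if mismatches <= max_mismatches:
            hits.append(MotifHit("condensation_core", i, window))
    return CondensationClassification(form, bool(hits), tuple(hits))


def classify_at(seq: str, ser_window: tuple[int, int] | None = None,
                phe_window: tuple[int, int] | None = None) -> str:
    """Classify an acyltransferase: malonate_specific, relaxed or inactive.

    The catalytic serine is required for any activity; with serine present,
    an active-site phenylalanine confers malonate specificity and its absence
    leaves substrate selection relaxed.
    """
    _check_sequence(seq)
    s_lo, s_hi = ser_window if ser_window else (0, len(seq))
    if seq.find("S", s_lo, s_hi) < 0:
        return "inactive"
    f_lo, f_hi = phe_window if phe_window else (0, len(seq))
    if seq.find("F", f_lo, f_hi) >= 0:
        return "malonate_specific"
    return "relaxed"


@dataclass(frozen=True)
class CarrierClassification:
    attachment_site_present: bool
    terminal_residue: str        # L | I | other
    evidence: tuple = ()


def classify_carrier_motif(seq: str) -> CarrierClassification:
    """Detect the phosphopantetheine attachment site on a carrier protein.

    Both leucine- and isoleucine-terminated variants of the attachment motif
    count as present; the observed terminal residue is reported.
    """
    _check_sequence(seq)
    hits = scan_motifs(seq, [DEFAULT_MOTIFS["ppant_attachment"]])
    if not hits:
        return CarrierClassification(False, "other")
    terminal = hits[0].matched[-1]
    return CarrierClassification(True, terminal if terminal in "LI" else "other",
                                 tuple(hits))


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

def hits_to_frame(records: dict[str, list[MotifHit]]):
    """Flatten per-sequence hit lists to a DataFrame (sequence_id, motif_id,
    start, matched) for TSV export."""
    import pandas as pd

    rows = [
        {"sequence_id": sid, "motif_id": h.motif_id,
         "start": h.start, "matched": h.matched}
        for sid, hits in records.items() for h in hits
    ]
    return pd.DataFrame(rows, columns=["sequence_id", "motif_id", "start", "matched"])
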