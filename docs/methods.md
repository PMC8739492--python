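# Methods

`palcolin` models the biosynthetic logic of the palmerolide family: a
trans-AT type I PKS-NRPS assembly line encoded in five near-identical gene
cluster copies from *Candidatus* Synoicihabitans palmerolidicus, the
verrucomicrobial symbiont of the Antarctic ascidian *Synoicum adareanum*.
This note records the model, its assumptions, the parameters that matter,
and the design choices made where the underlying biology leaves the design
open.

## The co-linearity model

A cluster is an ordered list of genes, each an ordered list of annotated
domains.  Genes are either core (cis-acting, forming the assembly line) or
trans-acting (standalone acyltransferases, the HCS β-branching cassette,
carbamoyl transferase, transporters, hypotheticals).  The concatenated core
domain stream is segmented into modules; each module performs one chemical
step; the module order equals the order of transformations in the product.

**Segmentation rule.** A new module starts at every ketosynthase (KS) or
condensation (C, or truncated C) domain.  Domains preceding the first
boundary seed the loading module.  When the first KS segment contains
nothing but the KS and carrier proteins, it is the starter-accepting KS and
is merged into the loading module rather than counted as an elongation; a
KS segment that carries any processing domain (KR, DH, cMT, ER, ECH, LLM)
is always an elongation module.  A trailing truncated C domain is the
termination module.  This single rule reproduces the 14-module, 11-
elongation segmentation of the palmerolide A cluster and still splits a toy
stream `[ACP, KS, KR, ACP]` into a loading module plus one elongation.
Module boundaries are never stored in fixture files — always recomputed —
so the rule itself stays under test.

**Elongation chemistry.**  Each elongation adds two carbons and leaves the
upstream carbonyl as the β-keto group.  The module's domain set fixes the β
outcome: no reductive domains → ketone; A-type KR → l-hydroxyl; B-type KR →
d-hydroxyl; C-type KR → no reduction (epimerase); KR+DH → olefin whose
geometry follows the KR type (A → cis, B → trans); a trans-acting
enoylreductase annotation on a KR+DH module → fully saturated unit.  A DH
without any reducing KR forms an olefin under the *permissive* rule
(`permissive_dh=True`, the default, following clusters where an
unaccompanied DH is demonstrably active); the strict alternative treats it
as inactive with a warning.  A shift-flagged dehydratase moves the module's
olefin from the α,β to the β,γ bond.  A cMT adds an α-methyl from SAM; an
in-line LLM (luciferase-like monooxygenase acting as a hydroxylase)
hydroxylates the α carbon — suppressed, in both the engine and the
independent oracle, when the α carbon is olefinic (the unit's own unshifted
olefin or an internal β-branch olefin), since hydroxylation requires an sp3
center.

**β-branching.**  An in-line enoyl-CoA hydratase (ECH) marks a ketone unit
as the substrate of the trans-acting HCS cassette (ACP + HCS + free KS + 2
ECH).  The branch methyl is installed at the β carbon; with the in-line ECH
present the exocyclic methylene isomerizes to the internal olefin between
β−1 and β (the conjugated trisubstituted olefin of the palmerolides),
otherwise it is recorded as an exo-methylene.

**Termination and macrolactonization.**  The line ends in a truncated
condensation domain (~133 aa against a ~450 aa canonical C domain) whose
second histidine of the HHXXDDG core is the catalytic residue.  Ring
closure is an ester between C1 and an internal hydroxyl; the automatic rule
selects the hydroxyl giving the largest ring of ≥ 12 backbone atoms, which
picks C-19 for the palmerolide scaffold without hard-coding it and releases
a linear product (with a warning) when no hydroxyl qualifies.

**Backbone numbering.**  C1 is the carbonyl of the final elongation; for E
elongations, cycle e (1-based, assembly order) has α = 2(E−e)+2 and β =
2(E−e)+3, so the β carbon of cycle e is the carbonyl added by cycle e−1.
An NRPS glycine contributes C(2E+1) and C(2E+2) (its carboxyl carbon *is*
cycle 1's β position — the diene amide of the palmerolides spans into the
glycine carbons); the nitrogen and starter carbons lie beyond and are
counted but not numbered.  Clusters without an NRPS step are primed by a
two-carbon acyl pair (the starter's carbonyl/α, or acetate by default)
which occupies C(2E+1)/C(2E+2); `polyketide_carbon_count` stays 2E.  Branch
carbons are numbered after the backbone: β-branch methyls first, then
α-methyls, each in ascending order of attachment position — yielding C-25
on C-17 and C-26/C-27 for the SAM methyls of the reference scaffold.
Olefins are named Δn by the lower carbon.

**Tailoring.**  Carbamoyl transfer defaults to the β-hydroxyl of the
LLM-bearing module (C-11 here), falling back to the lowest-numbered free
hydroxyl; sulfation and glycosylation decorate free hydroxyls likewise.
Targets are consumed, so re-applying a tailoring record is an error —
double decoration is structurally impossible.  Stereochemistry is carried
as l/d labels exactly as the classification provides them; conversion to
CIP R/S is out of scope, and the SMILES writer emits the labels as a fixed
tetrahedral-parity convention (documented in `smiles.py`), not CIP.

## Retrobiosynthesis and congruence

The retro engine inverts the forward rules position pair by position pair,
emitting capability *requirements* rather than exact domain strings.
Documented degeneracies: a ketone cannot distinguish a KR-less module from
one with a C-type or inactive KR; an olefin without geometry leaves the KR
unconstrained; full saturation erases the KR type; an α-hydroxyl may come
from an in-line LLM or a trans-acting hydroxylase; sulfation is satisfiable
by genome-encoded sulfatases outside the cluster and never counts as
missing; release machinery is required whether or not a ring formed; and
the carbamoylation *position* is a property of the assembled product, so an
architecture asserts CT availability with an unconstrained position.

The congruence score is |matched| / (|matched| + |missing| + |extra|) over
a fixed, versioned assertion vocabulary (v1).  It is this package's own
Jaccard-style construction — the source analyses argue congruence
qualitatively — and all outputs label it as such.  Under these conventions
the forward→retro round trip scores exactly 1.0 on every simulated
architecture, and the palmerolide A feature table scores 1.0 against its
cluster with an empty missing set.

## Family variant mapping

Structural diversity across the five cluster copies is modeled as three
mechanism classes plus one speculative flag: (1) trans-acting site swaps —
carbamate retargeted to the next free secondary alcohol with sulfate on the
freed hydroxyl, and/or the α-hydroxylase acting two carbons down-chain with
the neighbouring olefin repositioned one bond; (2) starter promiscuity
(the isomeric 3-methyl-3-butenoate, giving a terminal olefin); (3) a cis
geometry override on the diene-forming module (mechanism unknown); and the
post-assembly hydrolysis of an un-acylated glycine amide, enumerable only
for clusters lacking a loading module and labeled speculative in output.
`variant_budget` (default 2) bounds how many *classes* a candidate product
may combine — the class reading keeps every published assignment within
budget.  Analogue definitions are per-position feature assertions in YAML;
the C and G definitions are deliberately limited to the features the
modeled mechanisms explain (noted in the YAML header).

Architecture comparison is a longest-common-subsequence edit script over
module signatures (role, domain kinds with chemistry-bearing attributes,
trans annotations); the diff patches its source onto its target as a
self-check.

## Phylogenetics

Distances use the alphabet-generalized Jukes-Cantor correction
d = −((k−1)/k)·ln(1 − (k/(k−1))p) with k = 4 (nucleotide) or k = 20
(protein), chosen by alphabet detection; gaps are pairwise-deleted, and
p at or beyond (k−1)/k raises a saturation error rather than clamping.
`log1p` keeps d ≥ p down to the smallest proportions.  Neighbour joining is
the standard Q-criterion agglomeration with ties broken toward the lowest
taxon-index pair and negative branch lengths clamped to zero with a
recorded warning; on additive matrices the generating topology and lengths
are exact (property-tested to 8 taxa, cross-checked against an independent
library implementation).  Bootstrap support (default 100 replicates,
mandatory seed) is the percentage of column-resampled replicate trees
containing each internal bipartition; saturated replicates are discarded
and count against support.  Clade classification assigns a query the label
of its smallest enclosing NJ bipartition side whose reference members carry
one label, with that bipartition's support; mixed labels yield
`unclassified` with diagnostics.  Bayesian estimation and ML are out of
scope.

## Synthetic data: what it emulates and what it does not

The architecture grammar draws loading/NRPS/elongation/termination modules
with per-domain probabilities (defaults: P(KR)=0.7 with types A/B/C at
0.45/0.45/0.10, P(DH|reducing KR)=0.5, P(DH alone)=0.1, P(shift|DH)=0.15,
P(cMT)=0.2, P(trans-ER|KR+DH)=0.1, P(ECH site)=0.1, P(LLM)=0.1,
P(NRPS)=0.7, P(starter|NRPS)=0.8, P(CT)=0.4 when a free hydroxyl exists) —
a caricature of the structural grammar of trans-AT clusters, not of any
particular genome.  Ground truth comes from a deliberately naive per-rule
interpreter that shares no code with the assembly engine and renumbers
carbons by walking the finished chain from the thioester end; engine/oracle
equivalence is asserted over 500 draws.  Protein sequences embed motif
instances at known offsets (nested motifs inside an embedded window, e.g.
the GXDS core inside the attachment-site motif, are part of the label set)
and decoys are certified motif-free by the naive scanner.  Alignments
evolve i.i.d. columns under the Jukes-Cantor process along random trees
with uniform branch lengths (default 0.05–0.3 expected substitutions per
site).

What passing these tests does *not* show: the generators produce no
sequencing error, no alignment uncertainty, no rate heterogeneity across
sites, no domain-annotation noise, and no module architectures outside the
grammar (iterative "stuttering" modules, split modules across unusual gene
boundaries).  Real annotation pipelines feeding this package inherit those
error sources upstream.

All generators are pure functions of (configuration, seed); each draws
from its own CRC-derived stream so adding a generator never perturbs
existing fixtures.

## Numerical and procedural choices

- Condensation truncation threshold: 250 aa (between the 133-aa truncated
  termination domain and the ~450-aa canonical form), configurable.
- Degenerate HHXXDDG matching: the catalytic (second) histidine must match;
  up to 2 mismatches among the other fixed positions.
- KR typing precedence: LDD (B-type) over active-site tryptophan (A-type)
  when both occur; active-site windows default to the whole domain (the
  published motifs come without coordinates — a documented assumption) and
  can be user-restricted.
- Problem sizes in the test suite: 500 simulated architectures for the
  dual-implementation oracle, 150 for the retro round trip, 100 five-taxon
  300-column alignments for topology recovery (≥95% required), 10 random
  additive matrices per taxon count up to n=8, 100+100
  embedded/decoy proteins for scanner precision/recall — sizes chosen so
  the statistical assertions are stable under the fixed seeds.

## Known limitations

- Stereochemistry is label-level (l/d, cis/trans); no 3D or CIP reasoning.
- The congruence statistic has no published counterpart; scores are
  comparable across runs of this package (vocabulary v1) but not to other
  tools.
- Carrier-protein clade classification needs user-supplied reference
  alignments; the shipped tests use synthetic references only.
- The palmerolide C/G analogue definitions are intentionally partial (see
  above), and palmerolide E rests on a speculative hydrolysis step, always
  labeled as such in output.
- Module 5 carries a non-canonical DHt whose role (cyclization assistance
  vs olefin shifting) is unresolved in the source analyses; the shipped
  fixtures attach the olefin shifts to modules 3 and 4 via the shift flag,
  and the DHt is representable but inert by default.  Likewise the C-10
  hydroxyl is modeled via the in-line LLM route; a hydroxymalonate
  incorporation route is representable through a trans-hydroxylase
  tailoring record.
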