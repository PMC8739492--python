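# palcolin

Co-linear assembly and retrobiosynthetic analysis of trans-AT type I
PKS-NRPS biosynthetic gene clusters, built around the palmerolide family —
macrolide V-ATPase inhibitors produced by *Candidatus* Synoicihabitans
palmerolidicus, the bacterial symbiont of the Antarctic ascidian *Synoicum
adareanum*.

The package is for natural-product bioinformaticians who annotate modular
polyketide synthase clusters and want the prediction logic as tested,
composable code rather than a manual exercise: given an ordered gene/domain
architecture, predict the polyketide; given a chemical structure, predict
the architecture it requires and score a candidate cluster against it; and
given several near-identical cluster copies, map them onto a family of
structural analogues.

## The model

In a co-linear trans-AT PKS, elongation module *e* of *E* adds a two-carbon
acetate unit and its domain set fixes the oxidation state of the β carbon
(the upstream carbonyl):

| module domains | β outcome |
|---|---|
| KS | ketone |
| KS + KR(A) | l-hydroxyl |
| KS + KR(B) | d-hydroxyl |
| KS + KR + DH | olefin — *cis* (A-type KR) or *trans* (B-type) |
| KS + KR + DH + trans-ER | fully saturated |
| KS + DH (no KR) | olefin under the permissive rule |

with α-methylation by cMT, α-hydroxylation by an in-line LLM, olefin shifts
to the β,γ bond by shift-flagged dehydratases, and β-branching at
ECH-marked ketones by the trans-acting HCS cassette.  Backbone numbering
puts C1 at the final elongation's carbonyl, α(e) = 2(E−e)+2,
β(e) = 2(E−e)+3, glycine at C(2E+1)/C(2E+2); olefins are named Δn by the
lower carbon.  KR stereotypes come from active-site motifs (LDD → B-type →
d-hydroxyl; active-site tryptophan → A-type → l-hydroxyl; neither → C-type,
no reduction).  The retro engine inverts these rules into capability
requirements and scores a candidate architecture by the Jaccard-style
congruence |matched| / (|matched| + |missing| + |extra|).  Carrier-protein
and KS classification uses Jukes-Cantor distances
(d = −((k−1)/k)·ln(1 − (k/(k−1))p)), neighbour joining, and 100-replicate
bootstrap.  Details and design rationale: `docs/methods.md`.

## Worked example

The shipped fixture `pal_bgc_4.json` encodes the 25-gene palmerolide A
cluster.  Assemble it:

```bash
palcolin assemble --arch src/palcolin/data/pal_bgc_4.json --smiles pal4.smi
```

prints

```
pal_bgc_4: E=11, polyketide C22, backbone C24
```

— eleven elongation cycles build 22 contiguous polyketide carbons, and the
NRPS glycine step extends the backbone to 24.  The feature table
(`pal_bgc_4_features.tsv`) realizes the published chemistry position by
position; the first rows:

```
# ring: 1,19
position  state           stereo  olefin  geometry  ...  decoration
1         ester_carbonyl  .       .       .              .
2         olefinic        .       D2      trans          .
...
7         hydroxyl        D       .       .              .
8         olefinic        .       D8      trans          .
10        hydroxyl        .       .       .              .
11        hydroxyl        D       .       .              carbamate
```

trans olefins at Δ2/Δ8/Δ14 from the B-type-KR+DH modules 13/10/7, the
d-configured C-7 hydroxyl from module 11, the C-10 α-hydroxyl (LLM) and
C-11 carbamate from module 9 plus the carbamoyl transferase, the C-25
β-branch methyl on C-17 with its conjugated Δ16 olefin, shifted Δ21/Δ23
olefins in the diene tail, and macrolactonization at the module-5 C-19
hydroxyl (`ring: 1,19`).  The SMILES output is the corresponding molecule:

```
CC(C)=CC(=O)NC=CC(C)=CC(C)[C@H]1CC(C)=CC=CCC[C@@H](OC(N)=O)C(O)C=C[C@@H](O)CCCC=CC(=O)O1
```

Running the structure back through the retro engine against its own
cluster,

```bash
palcolin retro --features src/palcolin/data/features/palmerolide_A.tsv \
               --against src/palcolin/data/pal_bgc_4.json
# congruence vs pal_bgc_4: 1.000
```

every feature of the structure is explained by the cluster (empty missing
set).  The family mapper assigns all five cluster copies:

```bash
palcolin map-variants --out variant_map.tsv
```

| cluster | analogues | via |
|---|---|---|
| pal_bgc_4 | A, B, C, F, G | trans-site swaps, starter swap, geometry override |
| pal_bgc_1, pal_bgc_3 | D, H | extra tail elongation module (+ swaps for H) |
| pal_bgc_2 | — | 10-carbon product matches no known analogue |
| pal_bgc_5 | E | speculative post-assembly amide hydrolysis |

Other subcommands: `validate`, `scan` (motif scanning), `tree` /
`classify-carrier` (NJ + bootstrap phylogenetics), `simulate` (synthetic
architectures, labeled proteins, JC alignments).  Every command writes a
manifest with input paths, options, seeds and output hashes; identical
inputs and seeds give byte-identical outputs.

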