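"""Readers/writers for the pipeline's file formats.

Formats: JSON for architectures and manifests, TSV for feature tables and
reports, FASTA for sequences, newick for trees, YAML for motif and analogue
definitions.  Column orders and line endings are fixed so outputs are
byte-reproducible for identical inputs, options and seeds.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from .assembly_engine import AssembledStructure, PositionFeature
from .bgc_model import MONOMER_LIBRARY
from .errors import ParseError

FEATURE_TABLE_VERSION = 1
_COLUMNS = ("position", "state", "stereo", "olefin", "geometry",
            "branch", "branch_mode", "decoration")


def write_feature_table(structure: AssembledStructure, path) -> None:
    """Serialize a finalized structure as a commented TSV feature table."""
    lines = [f"# palcolin feature table v{FEATURE_TABLE_VERSION}"]
    meta = {
        "bgc_id": structure.bgc_id,
        "n_elongations": structure.n_elongations,
        "post_nrps_elongations": structure.n_post_nrps,
        "backbone_carbons": structure.backbone_carbon_count,
        "polyketide_carbons": structure.polyketide_carbon_count,
        "total_carbons": structure.total_carbon_count,
        "starter": structure.starter.monomer_id if structure.starter else "none",
        "amino_acids": ",".join(structure.amino_acids) or "none",
        "amide": str(structure.amide).lower(),
        "hydrolyzed": str(structure.hydrolyzed).lower(),
        "tail_units": structure.tail_extension.get("units", 0),
        "tail_methyls": structure.tail_extension.get("methyls", 0),
        "ring": (f"{structure.ring_closure[0]},{structure.ring_closure[1]}"
                 if structure.ring_closure else "none"),
    }
    lines.extend(f"# {k}: {v}" for k, v in meta.items())
    lines.append("\t".join(_COLUMNS))
    for p in sorted(structure.features):
        f = structure.features[p]
        lines.append("\t".join(str(x) for x in (
            f.position, f.state, f.stereo or ".",
            f"D{f.olefin}" if f.olefin else ".", f.olefin_geometry or ".",
            ",".join(f"C{m}" for m in f.branch_methyls) or ".",
            f.branch_mode or ".",
            ",".join(f.decorations) or ".")))
    Path(path).write_text("\n".join(lines) + "\n")


def read_feature_table(path) -> AssembledStructure:
    """Parse a feature-table TSV back into an :class:`AssembledStructure`."""
    meta: dict[str, str] = {}
    rows: list[dict] = []
    header: list[str] | None = None
    for raw in Path(path).read_text().splitlines():
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line.lstrip("# ")
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
            continue
        parts = line.split("\t")
        if header is None:
            header = parts
            if tuple(header) != _COLUMNS:
                raise ParseError(f"unexpected feature-table columns {header}")
            continue
        rows.append(dict(zip(header, parts)))
    if header is None or not rows:
        raise ParseError(f"{path}: empty feature table")

    def _none(v):
        return None if v == "." else v

    features: dict[int, PositionFeature] = {}
    for r in rows:
        p = int(r["position"])
        olefin = _none(r["olefin"])
        branch = _none(r["branch"])
        features[p] = PositionFeature(
            position=p,
            state=r["state"],
            stereo=_none(r["stereo"]),
            olefin=int(olefin[1:]) if olefin else None,
            olefin_geometry=_none(r["geometry"]),
            branch_methyls=tuple(int(b[1:]) for b in branch.split(","))
            if branch else (),
            branch_mode=_none(r["branch_mode"]),
            decorations=tuple(_none(r["decoration"]).split(","))
            if _none(r["decoration"]) else (),
        )
    starter_name = meta.get("starter", "none")
    starter = MONOMER_LIBRARY.get(starter_name) if starter_name != "none" else None
    aa = meta.get("amino_acids", "none")
    amino_acids = tuple(aa.split(",")) if aa != "none" else ()
    ring = meta.get("ring", "none")
    tail_units = int(meta.get("tail_units", 0))
    structure = AssembledStructure(
        bgc_id=meta.get("bgc_id", Path(path).stem),
        features=features,
        n_elongations=int(meta["n_elongations"]),
        n_post_nrps=int(meta["post_nrps_elongations"]),
        backbone_carbon_count=int(meta["backbone_carbons"]),
        polyketide_carbon_count=int(meta["polyketide_carbons"]),
        total_carbon_count=int(meta.get("total_carbons", 0)),
        starter=starter,
        amino_acids=amino_acids,
        ring_closure=tuple(int(x) for x in ring.split(",")) if ring != "none" else None,
        tail_extension=({"units": tail_units,
                         "methyls": int(meta.get("tail_methyls", 0))}
                        if tail_units else {}),
        amide=meta.get("amide", "false") == "true",
        hydrolyzed=meta.get("hydrolyzed", "false") == "true",
    )
    return structure


# ---------------------------------------------------------------------------
# Motif definitions (YAML)
# ---------------------------------------------------------------------------

def load_motif_definitions(path):
    import yaml

    from .motif_engine import MotifDefinition

    doc = yaml.safe_load(Path(path).read_text())
    return {
        m["motif_id"]: MotifDefinition(
            motif_id=m["motif_id"], pattern=m["pattern"],
            min_region=m.get("min_region"), max_region=m.get("max_region"))
        for m in doc["motifs"]
    }


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------

def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(out_dir, subcommand: str, inputs: dict, options: dict,
                   outputs: list) -> Path:
    """Write a machine-readable record of one CLI run next to its outputs."""
    from . import __version__

    manifest = {
        "tool": "palcolin",
        "version": __version__,
        "subcommand": subcommand,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "options": options,
        "outputs": [{"path": str(p), "sha256": sha256_of(p)} for p in outputs],
    }
    path = Path(out_dir) / f"{subcommand}_manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return path
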