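"""palcolin: co-linear assembly and retrobiosynthetic analysis of the
palmerolide trans-AT PKS-NRPS gene-cluster family."""

from importlib import resources

from .bgc_model import (
    BGCArchitecture, DomainAnnotation, GeneRecord, ModuleSpec, MonomerSpec,
    MONOMER_LIBRARY, load_architecture, parse_architecture,
    segment_modules, serialize_architecture, validate_architecture,
)
from .assembly_engine import (
    AssembledStructure, ChainState, HCSCassette, PositionMap,
    apply_beta_branch, apply_elongation, apply_tailoring, assemble,
    compute_position_map, initialize_chain, terminate_and_cyclize,
)
from .smiles import to_smiles

__version__ = "0.1.0"

PAL_BGC_IDS = ("pal_bgc_1", "pal_bgc_2", "pal_bgc_3", "pal_bgc_4", "pal_bgc_5")


def load_pal_bgc(bgc_id: str, segmented: bool = True) -> BGCArchitecture:
    """Load one of the shipped palmerolide cluster fixtures."""
    if bgc_id not in PAL_BGC_IDS:
        raise KeyError(f"unknown cluster {bgc_id!r}; choose from {PAL_BGC_IDS}")
    text = resources.files("palcolin.data").joinpath(f"{bgc_id}.json").read_text()
    arch = parse_architecture(text)
    return segment_modules(arch) if segmented else arch
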