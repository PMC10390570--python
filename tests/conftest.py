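import itertools

import pytest

from tcrtrace.chain_model import CellProfile, ChainAnnotation
from tcrtrace.locus_model import functional_v_genes, known_gene_names, load_locus


@pytest.fixture(scope="session")
def human_maps():
    return {locus: load_locus("human", locus) for locus in ("TRA", "TRB")}


@pytest.fixture(scope="session")
def mouse_maps():
    return {locus: load_locus("mouse", locus) for locus in ("TRA", "TRB")}


@pytest.fixture(scope="session")
def toy_map():
    return load_locus("toy", "TRB")


@pytest.fixture(scope="session")
def functional_v_human():
    return functional_v_genes("human")


@pytest.fixture(scope="session")
def known_genes_human():
    return known_gene_names("human")


_COUNTER = itertools.count()


def make_chain(locus: str, status: str, **overrides) -> ChainAnnotation:
    """A distinct chain of the given locus/status with plausible gene calls."""
    i = next(_COUNTER)
    if locus == "TRB":
        fields = dict(locus="TRB", v_call="TRBV19", d_call="TRBD1",
                      j_call="TRBJ1-5", c_call="TRBC1",
                      junction_aa=f"CASSB{i}F", status=status)
    else:
        fields = dict(locus="TRA", v_call="TRAV2", d_call="",
                      j_call="TRAJ33", c_call="TRAC",
                      junction_aa=f"CAVA{i}F", status=status)
    fields.update(overrides)
    return ChainAnnotation(**fields)


def make_profile(*chain_specs, barcode: str = "CELLTEST-1") -> CellProfile:
    """Build a CellProfile from (locus, status) pairs or ChainAnnotations."""
    chains = []
    for spec in chain_specs:
        if isinstance(spec, ChainAnnotation):
            chains.append(spec)
        else:
            locus, status = spec
            chains.append(make_chain(locus, status))
    return CellProfile(barcode=barcode, chains=tuple(sorted(chains)))
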