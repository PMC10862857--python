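import pytest

from rnasplit.mmcif_io import RnaChain, load_component_dictionary
from rnasplit.synthetic import TOY_DICTIONARY


def make_chain(
    full_id: str = "1abc_A",
    sequence: str = "ACGU" * 10,
    resolution: float | None = 2.0,
    method: str = "X-RAY DIFFRACTION",
    n_modified: int = 0,
) -> RnaChain:
    structure_id, chain_id = full_id.split("_", 1)
    return RnaChain(
        structure_id=structure_id,
        chain_id=chain_id,
        sequence=sequence,
        resolution=resolution,
        method=method,
        n_modified=n_modified,
    )


@pytest.fixture(scope="session")
def toy_map():
    """Modification map built from the bundled toy component dictionary."""
    return load_component_dictionary(TOY_DICTIONARY)


# A hand-written two-chain structure: chain X is RNA (with one pseudouridine
# and one stray amino acid), chain Y is a protein and must not be admitted.
TWO_CHAIN_MMCIF = """\
data_9xyz
_entry.id 9XYZ
_exptl.method 'X-RAY DIFFRACTION'
_refine.ls_d_res_high 2.50
_reflns.d_resolution_high 2.40
loop_
_chem_comp.id
_chem_comp.type
A 'RNA linking'
C 'RNA linking'
G 'RNA linking'
U 'RNA linking'
PSU 'RNA linking'
GLY 'peptide linking'
ALA 'peptide linking'
loop_
_pdbx_poly_seq_scheme.asym_id
_pdbx_poly_seq_scheme.entity_id
_pdbx_poly_seq_scheme.seq_id
_pdbx_poly_seq_scheme.mon_id
_pdbx_poly_seq_scheme.pdb_strand_id
A 1 1 G X
A 1 2 PSU X
A 1 3 C X
A 1 4 GLY X
A 1 5 U X
B 2 1 GLY Y
B 2 2 ALA Y
B 2 3 GLY Y
"""

NMR_MMCIF = """\
data_2nmr
_entry.id 2NMR
_exptl.method 'SOLUTION NMR'
loop_
_chem_comp.id
_chem_comp.type
A 'RNA linking'
U 'RNA linking'
loop_
_pdbx_poly_seq_scheme.asym_id
_pdbx_poly_seq_scheme.entity_id
_pdbx_poly_seq_scheme.seq_id
_pdbx_poly_seq_scheme.mon_id
_pdbx_poly_seq_scheme.pdb_strand_id
A 1 1 A B
A 1 2 U B
A 1 3 A B
"""
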